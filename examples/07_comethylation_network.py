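"""Signed co-methylation network and module-diagnosis association.

Plants two latent co-methylation modules (one loaded on diagnosis),
builds the signed biweight-midcorrelation network with topological
overlap, extracts modules, and tests each module eigengene against
diagnosis in a donor-random-intercept model.
"""

import numpy as np

from methcortex import network as nw, synthdata as sd

rng = np.random.default_rng(3)
design = sd.SyntheticDesign(
    n_probes=900,
    n_chromosomes=2,
    n_donors_per_group={"CTL": 25, "iASD": 25},
    regions=("PFC", "TC"),
    noise_sd=0.03,
    donor_sd=0.01,
    sex_chrom=False,
    baseline_beta_profile=np.random.default_rng(99).uniform(0.2, 0.8, 900),
    seed=3,
)
manifest = sd.generate_manifest(design)
design = design.with_(
    planted_modules=sd.plant_modules(
        manifest, sizes=[150, 150], loading=0.04, diagnosis_shift={"iASD": 0.5}, rng=rng
    )
)
beta, _, pheno, truth = sd.generate_cohort(design, manifest)

adjusted = nw.residualize(beta, pheno, remove=("age",))
labels, eigengenes = nw.build_network(adjusted, soft_power=7, min_module_size=100)
print(f"detected modules: {int(labels.max())}")
for m in sorted(set(labels) - {0}):
    members = set(labels.index[labels == m])
    planted = set(truth.modules["probe_id"])
    print(f"  M{m}: {len(members)} probes, {len(members & planted)} from planted modules")

assoc = nw.module_trait_association(eigengenes, pheno, contrasts=(("iASD", "CTL"),))
for _, row in assoc.iterrows():
    flag = " *" if row["significant"] else ""
    print(
        f"  {row['module']} vs diagnosis: effect {row['effect']:+.3f} SD, "
        f"FDR = {row['fdr']:.3g}{flag}"
    )
# Both planted modules are recovered; because their latent factors carry
# a +0.5 SD shift in cases, their eigengenes associate with diagnosis.
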