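"""Per-probe differential methylation: within-region OLS and the
cross-cortex donor-random-intercept mixed model.

Spikes 30 DMPs into a two-region cohort, fits both models, assigns the
discovery (p < 5e-5) and Bonferroni experiment-wide tiers, and reports
how many planted probes each model recovers.
"""

import numpy as np

from methcortex import dmp, synthdata as sd

rng = np.random.default_rng(2)
design = sd.SyntheticDesign(
    n_probes=4000,
    n_chromosomes=4,
    probe_spacing_bp=150,
    n_donors_per_group={"CTL": 20, "iASD": 20},
    regions=("PFC", "TC"),
    noise_sd=0.03,
    donor_sd=0.02,
    seed=2,
)
manifest = sd.generate_manifest(design)
design = design.with_(
    spiked_dmps=sd.plant_dmps(manifest, 30, (0.05, 0.10), diagnoses=("iASD",), rng=rng)
)
beta, _, pheno, truth = sd.generate_cohort(design, manifest)
spiked = set(truth.spiked_dmps["probe_id"])

ols = dmp.call_dmps(dmp.fit_ols(beta, pheno, case="iASD", region="PFC"))
lme = dmp.call_dmps(dmp.fit_lme(beta, pheno, case="iASD"))

print(f"experiment-wide threshold (0.05 / {beta.shape[0]}): "
      f"{dmp.experiment_wide_threshold(beta.shape[0]):.3e}")
for name, res in (("PFC OLS", ols), ("cross-cortex LME", lme)):
    called = set(res.index[res["tier"] != ""])
    print(
        f"{name:17s}: {len(called):3d} DMPs called, "
        f"{len(called & spiked):2d}/{len(spiked)} planted recovered"
    )
# The mixed model pools both cortical regions per donor, so it recovers
# more of the planted probes than a single-region scan at the same n.

top = lme.loc[list(spiked)].nsmallest(1, "p_value").iloc[0]
print(f"top planted probe: effect {top['effect']:+.3f}, p = {top['p_value']:.2e}")
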