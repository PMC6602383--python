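"""Synthetic 450K-style cohorts with known ground truth.

The generator emulates the statistical structure of a multi-region
post-mortem brain methylation study: a probe grid with genomic
coordinates and gene annotations, donors nested within diagnostic groups
(controls, idiopathic ASD, chromosome-15q11-13 duplication carriers),
up to three brain regions per donor sharing a donor-level random
intercept in cortex, case/control beta shifts at spiked differentially
methylated positions (DMPs) and spatially clustered regions (DMRs), a
two-cell-type (neuron/glia) mixture with reference profiles, a
chromosome-15 duplication with proportional total-intensity gain and a
focal hyper/hypo-methylated domain, planted co-methylation modules
driven by latent factors, age-dependent clock CpGs, and additive brain
bank (batch) effects.

Every planted effect is recorded in a :class:`TruthTables` object so
recovery can be checked probe by probe. All randomness flows from the
design's single seed; identical designs give bit-identical cohorts.

Beta noise is Gaussian with clipping to [0, 1] rather than
beta-distributed — simpler, and sufficient for the linear models the
pipeline fits; see the methods note for the resulting limitations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .ioformats import CellReference, ClockModel, validate_manifest, validate_phenotypes

__all__ = [
    "DesignError",
    "SyntheticDesign",
    "SpikedDmp",
    "SpikedDmr",
    "PlantedModule",
    "DuplicationSpec",
    "SyntheticClock",
    "TruthTables",
    "generate_manifest",
    "generate_cohort",
    "generate_pathways",
    "make_cell_reference",
    "make_synthetic_clock",
    "plant_dmps",
    "plant_dmrs",
    "plant_modules",
]

BETA_OFFSET = 100.0  # denominator offset of the beta transform M/(M+U+100)


class DesignError(ValueError):
    """Raised when a synthetic design is internally inconsistent."""


@dataclass(frozen=True)
class SpikedDmp:
    probe_id: str
    delta: dict[str, float]  # diagnosis -> additive beta shift


@dataclass(frozen=True)
class SpikedDmr:
    chrom: str
    start: int
    end: int
    probe_ids: tuple[str, ...]
    delta: dict[str, float]


@dataclass(frozen=True)
class PlantedModule:
    name: str
    probe_ids: tuple[str, ...]
    loading: float  # beta-scale amplitude of the latent factor
    diagnosis_shift: dict[str, float] = field(default_factory=dict)  # factor SD units


@dataclass(frozen=True)
class DuplicationSpec:
    """A copy-number gain with an optional focal methylation domain.

    Coordinates are 1-based inclusive. ``hyper``/``hypo`` are
    sub-intervals of the duplicated locus whose probes gain/lose
    methylation in carriers, mimicking the imprinted-domain signature.
    """

    chrom: str = "chr15"
    start: int = 1
    end: int = 10**9
    copy_number: int = 3
    hyper: tuple[int, int] | None = None
    hyper_delta: float = 0.10
    hypo: tuple[int, int] | None = None
    hypo_delta: float = -0.10


@dataclass(frozen=True)
class SyntheticClock:
    """A clock model plus the generative mapping used to plant it.

    Clock CpG betas are constructed as ``b0 + w * F(age)`` where ``F`` is
    the standard log-linear age transform and ``w = c / sum(c^2)``, so the
    linear predictor ``intercept + c @ beta`` recovers ``F(age)`` exactly
    in the noise-free limit.
    """

    model: ClockModel
    baseline: pd.Series  # b0 per clock CpG
    weights: pd.Series  # w per clock CpG


@dataclass(frozen=True)
class SyntheticDesign:
    """All parameters of one synthetic cohort.

    Defaults mirror the scale of a three-brain-bank, three-region cohort
    (38 controls, 36 idiopathic ASD and 7 dup15q donors); tests shrink
    ``n_probes`` and donor counts for speed.
    """

    n_probes: int = 20_000
    n_chromosomes: int = 22
    probe_spacing_bp: int = 1_500
    n_donors_per_group: dict[str, int] = field(
        default_factory=lambda: {"CTL": 38, "iASD": 36, "dup15q": 7}
    )
    regions: tuple[str, ...] = ("PFC", "TC", "CB")
    baseline_beta_profile: np.ndarray | None = None
    noise_sd: float = 0.03
    donor_sd: float = 0.02
    age_range: tuple[float, float] = (2.0, 60.0)
    banks: tuple[str, ...] = ("bankA", "bankB", "bankC")
    batch_effects: dict[str, float] = field(default_factory=dict)
    spiked_dmps: tuple[SpikedDmp, ...] = ()
    spiked_dmrs: tuple[SpikedDmr, ...] = ()
    planted_modules: tuple[PlantedModule, ...] = ()
    dup15q_locus: DuplicationSpec | None = None
    cell_ref: CellReference | None = None
    neuronal_range: tuple[float, float] = (0.25, 0.55)
    clock: SyntheticClock | None = None
    age_shift: dict[str, float] = field(default_factory=dict)  # diagnosis -> years
    sex_chrom: bool = True
    sex_effect: float = 0.12
    frac_flagged: float = 0.02
    base_intensity: float = 5_000.0
    intensity_noise_sd: float = 0.10  # multiplicative log-normal, total intensity
    channel_noise_sd: float = 0.02  # multiplicative log-normal, per channel
    seed: int = 0

    def with_(self, **kwargs) -> "SyntheticDesign":
        return replace(self, **kwargs)


@dataclass
class TruthTables:
    """Ground truth of every planted effect, keyed like the outputs."""

    spiked_dmps: pd.DataFrame  # probe_id, diagnosis, delta
    spiked_dmrs: pd.DataFrame  # chrom, start, end, n_probes, diagnosis, delta
    modules: pd.DataFrame  # module, probe_id, loading
    module_factors: pd.DataFrame  # samples x modules latent factors
    dup15q: DuplicationSpec | None
    dup15q_donors: tuple[str, ...]
    dup_locus_probes: tuple[str, ...]
    neuronal_proportion: pd.Series  # per sample (NaN for CB)
    age: pd.Series  # chronological age per sample
    age_shift: dict[str, float]
    clock: SyntheticClock | None
    batch_effects: dict[str, float]
    sex: pd.Series
    donor_sd: float
    noise_sd: float

    def to_frames(self) -> dict[str, pd.DataFrame]:
        """Flatten to named DataFrames for CSV export."""
        frames = {
            "spiked_dmps": self.spiked_dmps,
            "spiked_dmrs": self.spiked_dmrs,
            "modules": self.modules,
            "module_factors": self.module_factors.reset_index(),
            "neuronal_proportion": self.neuronal_proportion.rename("proportion").reset_index(),
        }
        if self.dup15q is not None:
            frames["dup15q"] = pd.DataFrame(
                {
                    "chrom": [self.dup15q.chrom],
                    "start": [self.dup15q.start],
                    "end": [self.dup15q.end],
                    "copy_number": [self.dup15q.copy_number],
                    "donors": [";".join(self.dup15q_donors)],
                }
            )
        return frames


# ---------------------------------------------------------------------------
# manifest
# ---------------------------------------------------------------------------

def generate_manifest(design: SyntheticDesign) -> pd.DataFrame:
    """Build a probe manifest: sorted coordinates, gene annotations, QC flags.

    Probes are laid out chromosome by chromosome with strictly increasing
    positions (inter-probe gaps drawn around ``probe_spacing_bp``). Genes
    are assigned in runs of consecutive probes so that per-gene probe
    counts vary, as they do on the real array; about 25% of probes are
    intergenic and a few percent are annotated to two genes. Roughly
    ``frac_flagged`` of probes carry one of the three exclusion flags.
    """
    if design.n_probes < 1:
        raise DesignError("n_probes must be >= 1")
    if design.probe_spacing_bp <= 0:
        raise DesignError("probe_spacing_bp must be positive")
    if design.n_chromosomes < 1:
        raise DesignError("n_chromosomes must be >= 1")
    rng = np.random.default_rng(design.seed)

    chroms = [f"chr{i + 1}" for i in range(design.n_chromosomes)]
    if design.sex_chrom and design.n_chromosomes >= 2:
        chroms[-1] = "chrX"
    # balanced split with remainder on the first chromosomes
    base, extra = divmod(design.n_probes, len(chroms))
    counts = [base + (1 if i < extra else 0) for i in range(len(chroms))]

    rows: dict[str, list] = {c: [] for c in ["chrom", "pos"]}
    for chrom, n in zip(chroms, counts):
        if n == 0:
            continue
        gaps = rng.integers(1, 2 * design.probe_spacing_bp, size=n)
        pos = 1_000_000 + np.cumsum(gaps)
        rows["chrom"].extend([chrom] * n)
        rows["pos"].extend(pos.tolist())

    n = design.n_probes
    df = pd.DataFrame(rows)
    df["probe_id"] = [f"cg{i:08d}" for i in range(n)]
    df["design_type"] = np.where(rng.random(n) < 0.3, "I", "II")

    # gene annotation in runs of consecutive probes
    genes: list[str] = []
    tss: list[str] = []
    gene_counter = 0
    i = 0
    while i < n:
        run = int(rng.geometric(1 / 6.0))
        gene_counter += 1
        gname = f"GENE{gene_counter:05d}"
        for j in range(i, min(i + run, n)):
            r = rng.random()
            if r < 0.25:  # intergenic
                genes.append("")
                tss.append("")
            else:
                g_list = [gname]
                d_list = [int(rng.integers(-3_000, 20_000))]
                if r > 0.85:  # second annotation (overlapping gene)
                    g_list.append(f"GENE{gene_counter + 1:05d}")
                    d_list.append(int(rng.integers(-3_000, 20_000)))
                genes.append(";".join(g_list))
                tss.append(";".join(str(d) for d in d_list))
        i += run

    df["genes"] = genes
    df["tss_distance"] = tss

    for flag in ["flag_snp_probe", "flag_cross_reactive", "flag_snp_within_10bp"]:
        df[flag] = rng.random(n) < design.frac_flagged / 3.0
    df["flag_sex_chrom"] = (df["chrom"] == "chrX").to_numpy()

    order = {c: i for i, c in enumerate(chroms)}
    df = df.sort_values(["chrom", "pos"], key=lambda s: s.map(order) if s.name == "chrom" else s)
    return validate_manifest(df.set_index("probe_id"))


# ---------------------------------------------------------------------------
# planting helpers
# ---------------------------------------------------------------------------

def _eligible(manifest: pd.DataFrame) -> pd.Index:
    flags = manifest[[c for c in manifest.columns if c.startswith("flag_")]].any(axis=1)
    return manifest.index[~flags]


def plant_dmps(
    manifest: pd.DataFrame,
    n: int,
    delta_range: tuple[float, float],
    diagnoses: tuple[str, ...] = ("iASD", "dup15q"),
    rng: np.random.Generator | None = None,
    sign_mix: bool = True,
) -> tuple[SpikedDmp, ...]:
    """Pick ``n`` unflagged autosomal probes and attach beta shifts."""
    rng = rng or np.random.default_rng(0)
    pool = _eligible(manifest)
    pool = pool[~manifest.loc[pool, "flag_sex_chrom"]]
    probes = rng.choice(pool.to_numpy(), size=n, replace=False)
    lo, hi = delta_range
    mags = rng.uniform(lo, hi, size=n)
    signs = rng.choice([-1.0, 1.0], size=n) if sign_mix else np.ones(n)
    return tuple(
        SpikedDmp(probe_id=str(p), delta={d: float(s * m) for d in diagnoses})
        for p, m, s in zip(probes, mags, signs)
    )


def plant_dmrs(
    manifest: pd.DataFrame,
    n_regions: int,
    n_probes_each: int,
    delta: float,
    diagnoses: tuple[str, ...] = ("iASD",),
    rng: np.random.Generator | None = None,
    max_span: int = 300,
) -> tuple[SpikedDmr, ...]:
    """Plant runs of consecutive probes whose pairwise gaps are <= ``max_span``.

    Runs are drawn from stretches of the manifest that are dense enough;
    all probes in a run receive the same beta shift, producing a spatially
    clustered differential signal.
    """
    rng = rng or np.random.default_rng(0)
    man = manifest.sort_values(["chrom", "pos"], kind="stable")
    ok = _eligible(man)
    dmrs: list[SpikedDmr] = []
    by_chrom = {c: g for c, g in man.groupby("chrom", sort=False) if not g["flag_sex_chrom"].any()}
    chroms = list(by_chrom)
    attempts = 0
    while len(dmrs) < n_regions and attempts < 50 * n_regions:
        attempts += 1
        g = by_chrom[chroms[int(rng.integers(len(chroms)))]]
        if len(g) < n_probes_each:
            continue
        i = int(rng.integers(0, len(g) - n_probes_each + 1))
        window = g.iloc[i : i + n_probes_each]
        gaps = np.diff(window["pos"].to_numpy())
        if len(gaps) and gaps.max() > max_span:
            continue
        if not window.index.isin(ok).all():
            continue
        if any(set(window.index) & set(d.probe_ids) for d in dmrs):
            continue
        dmrs.append(
            SpikedDmr(
                chrom=str(window["chrom"].iloc[0]),
                start=int(window["pos"].iloc[0]),
                end=int(window["pos"].iloc[-1]),
                probe_ids=tuple(window.index),
                delta={d: float(delta) for d in diagnoses},
            )
        )
    if len(dmrs) < n_regions:
        raise DesignError(
            f"could only place {len(dmrs)}/{n_regions} DMRs; "
            "decrease probe_spacing_bp or the DMR probe count"
        )
    return tuple(dmrs)


def plant_modules(
    manifest: pd.DataFrame,
    sizes: list[int],
    loading: float = 0.04,
    diagnosis_shift: dict[str, float] | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[PlantedModule, ...]:
    """Assign disjoint random probe sets to latent co-methylation factors."""
    rng = rng or np.random.default_rng(0)
    pool = _eligible(manifest).to_numpy()
    rng.shuffle(pool)
    modules = []
    offset = 0
    for k, size in enumerate(sizes):
        probes = pool[offset : offset + size]
        if len(probes) < size:
            raise DesignError("not enough unflagged probes for planted modules")
        offset += size
        modules.append(
            PlantedModule(
                name=f"module_{k + 1}",
                probe_ids=tuple(str(p) for p in probes),
                loading=loading,
                diagnosis_shift=dict(diagnosis_shift or {}),
            )
        )
    return tuple(modules)


def make_cell_reference(
    manifest: pd.DataFrame, n_markers: int = 50, rng: np.random.Generator | None = None
) -> CellReference:
    """Neuron/glia reference profiles at randomly chosen marker probes.

    Marker probes are strongly differential between the two cell types
    (|neuron - glia| in 0.3-0.5), as NeuN-sorted reference data are.
    """
    rng = rng or np.random.default_rng(0)
    pool = _eligible(manifest)
    pool = pool[~manifest.loc[pool, "flag_sex_chrom"]]
    markers = rng.choice(pool.to_numpy(), size=n_markers, replace=False)
    low = rng.uniform(0.05, 0.45, size=n_markers)
    sep = rng.uniform(0.3, 0.5, size=n_markers)
    neuron_high = rng.random(n_markers) < 0.5
    neuron = np.where(neuron_high, low + sep, low)
    glia = np.where(neuron_high, low, low + sep)
    return CellReference(
        profiles=pd.DataFrame({"neuron": neuron, "glia": glia}, index=pd.Index(markers, name="cpg"))
    )


def make_synthetic_clock(
    manifest: pd.DataFrame,
    n_cpgs: int = 30,
    adult_age: float = 20.0,
    rng: np.random.Generator | None = None,
) -> SyntheticClock:
    """A small clock whose CpGs move linearly with transformed age."""
    rng = rng or np.random.default_rng(0)
    pool = _eligible(manifest)
    pool = pool[~manifest.loc[pool, "flag_sex_chrom"]]
    cpgs = rng.choice(pool.to_numpy(), size=n_cpgs, replace=False)
    coef = rng.uniform(0.3, 1.0, size=n_cpgs) * rng.choice([-1.0, 1.0], size=n_cpgs)
    b0 = rng.uniform(0.35, 0.65, size=n_cpgs)
    w = coef / np.sum(coef**2)
    intercept = -float(np.sum(coef * b0))
    model = ClockModel(
        intercept=intercept,
        coefficients=pd.Series(coef, index=pd.Index(cpgs, name="cpg")),
        adult_age=adult_age,
    )
    idx = pd.Index(cpgs, name="cpg")
    return SyntheticClock(model=model, baseline=pd.Series(b0, index=idx), weights=pd.Series(w, index=idx))


def _age_transform(age: np.ndarray, adult_age: float) -> np.ndarray:
    """Forward log-linear transform of chronological age (inverse of dnam_age)."""
    age = np.asarray(age, dtype=float)
    return np.where(
        age < adult_age,
        np.log(age + 1.0) - np.log(adult_age + 1.0),
        (age - adult_age) / (adult_age + 1.0),
    )


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------

def generate_cohort(
    design: SyntheticDesign, manifest: pd.DataFrame
) -> tuple[pd.DataFrame, tuple[pd.DataFrame, pd.DataFrame], pd.DataFrame, TruthTables]:
    """Simulate beta values, M/U intensities, phenotypes and truth tables.

    Per-sample beta is baseline + diagnosis effects + bank shift +
    cell-mixture term + module factors + donor intercept (cortex) +
    Gaussian noise, clipped to [0, 1]. Intensities satisfy
    ``M/(M+U+100) ~= beta`` and total intensity scales with copy number
    inside the duplication locus for carrier samples.
    """
    _check_design(design, manifest)
    rng = np.random.default_rng(np.random.SeedSequence([design.seed, 1]))
    probe_ids = manifest.index
    n_probes = len(probe_ids)
    probe_pos = {p: i for i, p in enumerate(probe_ids)}

    # --- donors and samples -------------------------------------------------
    donors, diag, age_d, sex_d, bank_d = [], [], [], [], []
    for group, count in design.n_donors_per_group.items():
        for i in range(count):
            donors.append(f"{group}{i + 1:03d}")
            diag.append(group)
            age_d.append(float(rng.uniform(*design.age_range)))
            sex_d.append("M" if rng.random() < 0.5 else "F")
            # banks cycle within each group: samples randomised with respect
            # to diagnosis and bank, so the two are never confounded
            bank_d.append(design.banks[i % len(design.banks)])
    donor_df = pd.DataFrame(
        {"donor_id": donors, "diagnosis": diag, "age": age_d, "sex": sex_d, "bank": bank_d}
    )

    records = []
    for _, d in donor_df.iterrows():
        for region in design.regions:
            records.append(
                {
                    "sample_id": f"{d.donor_id}_{region}",
                    "donor_id": d.donor_id,
                    "region": region,
                    "diagnosis": d.diagnosis,
                    "age": d.age,
                    "sex": d.sex,
                    "bank": d.bank,
                }
            )
    pheno = pd.DataFrame(records).set_index("sample_id")
    n_samples = len(pheno)
    sample_ids = pheno.index

    # --- baseline + effects -------------------------------------------------
    if design.baseline_beta_profile is not None:
        baseline = np.asarray(design.baseline_beta_profile, dtype=float)
        if baseline.shape != (n_probes,):
            raise DesignError("baseline_beta_profile length must equal n_probes")
    else:
        baseline = 0.05 + 0.90 * rng.beta(0.4, 0.4, size=n_probes)

    beta = np.tile(baseline[:, None], (1, n_samples))
    dx = pheno["diagnosis"].to_numpy()
    region = pheno["region"].to_numpy()
    is_cortex = np.isin(region, ["PFC", "TC"])

    # spiked DMPs / DMRs
    for spike in design.spiked_dmps:
        i = probe_pos[spike.probe_id]
        for d, delta in spike.delta.items():
            beta[i, dx == d] += delta
    for dmr in design.spiked_dmrs:
        idx = [probe_pos[p] for p in dmr.probe_ids]
        for d, delta in dmr.delta.items():
            beta[np.ix_(idx, dx == d)] += delta

    # duplication focal domain
    dup = design.dup15q_locus
    dup_probe_ids: tuple[str, ...] = ()
    if dup is not None:
        on_chrom = manifest["chrom"] == dup.chrom
        in_locus = on_chrom & manifest["pos"].between(dup.start, dup.end)
        dup_probe_ids = tuple(manifest.index[in_locus])
        carriers = dx == "dup15q"
        for interval, delta in [(dup.hyper, dup.hyper_delta), (dup.hypo, dup.hypo_delta)]:
            if interval is None:
                continue
            sel = on_chrom & manifest["pos"].between(*interval)
            beta[np.ix_(np.flatnonzero(sel.to_numpy()), carriers)] += delta

    # brain-bank (batch) shifts
    for bank, shift in design.batch_effects.items():
        beta[:, (pheno["bank"] == bank).to_numpy()] += shift

    # cell mixture at marker probes (cortex only; CB has no estimate)
    neuronal = pd.Series(np.nan, index=sample_ids, dtype=float)
    if design.cell_ref is not None:
        ref = design.cell_ref
        props = rng.uniform(*design.neuronal_range, size=n_samples)
        props[~is_cortex] = np.nan
        neuronal[:] = props
        midx = [probe_pos[p] for p in ref.markers]
        nprof = ref.neuron.to_numpy()[:, None]
        gprof = ref.glia.to_numpy()[:, None]
        p_row = np.where(np.isnan(props), 0.5, props)[None, :]
        beta[midx, :] = p_row * nprof + (1.0 - p_row) * gprof

    # clock CpGs track transformed (possibly shifted) age
    ages = pheno["age"].to_numpy(copy=True)
    if design.clock is not None:
        clk = design.clock
        eff_age = ages.copy()
        for d, shift in design.age_shift.items():
            eff_age[dx == d] = np.maximum(eff_age[dx == d] + shift, 0.0)
        f = _age_transform(eff_age, clk.model.adult_age)
        cidx = [probe_pos[p] for p in clk.model.coefficients.index]
        beta[cidx, :] = clk.baseline.to_numpy()[:, None] + clk.weights.to_numpy()[:, None] * f[None, :]

    # planted co-methylation modules
    factors = {}
    for mod in design.planted_modules:
        f = rng.normal(size=n_samples)
        for d, shift in mod.diagnosis_shift.items():
            f[dx == d] += shift
        jitter = rng.uniform(0.8, 1.2, size=len(mod.probe_ids))
        midx = [probe_pos[p] for p in mod.probe_ids]
        beta[midx, :] += mod.loading * jitter[:, None] * f[None, :]
        factors[mod.name] = f
    module_factors = pd.DataFrame(factors, index=sample_ids)

    # sex effect on X-chromosome probes
    sexes = pheno["sex"].to_numpy()
    if design.sex_chrom:
        xsel = np.flatnonzero((manifest["chrom"] == "chrX").to_numpy())
        if len(xsel):
            beta[np.ix_(xsel, sexes == "F")] += design.sex_effect

    # SNP genotyping probes: a per-donor genotype (0 / 0.5 / 1) shared by
    # every sample of that donor, so fingerprints match within donors
    donor_codes_all = pd.Categorical(pheno["donor_id"]).codes
    snp_rows = np.flatnonzero(manifest["flag_snp_probe"].to_numpy())
    if len(snp_rows):
        genotypes = rng.choice([0.0, 0.5, 1.0], size=(len(snp_rows), len(donor_df)), p=[0.25, 0.5, 0.25])
        beta[snp_rows, :] = genotypes[:, donor_codes_all]

    # donor random intercept shared by the cortical samples of a donor
    if design.donor_sd > 0:
        donor_codes = pd.Categorical(pheno["donor_id"]).codes
        intercepts = rng.normal(0.0, design.donor_sd, size=(n_probes, len(donor_df)))
        beta[:, is_cortex] += intercepts[:, donor_codes[is_cortex]]

    if design.noise_sd > 0:
        beta += rng.normal(0.0, design.noise_sd, size=beta.shape)
    np.clip(beta, 0.0, 1.0, out=beta)

    # --- intensities --------------------------------------------------------
    # per-probe brightness is log-normal, as on real arrays (long upper tail)
    t0 = design.base_intensity * np.exp(rng.normal(0.0, 0.5, size=n_probes))
    total = t0[:, None] * np.exp(rng.normal(0.0, design.intensity_noise_sd, size=beta.shape))
    if dup is not None and len(dup_probe_ids):
        carriers = dx == "dup15q"
        didx = [probe_pos[p] for p in dup_probe_ids]
        total[np.ix_(didx, carriers)] *= dup.copy_number / 2.0
    beta_for_int = np.minimum(beta, total / (total + BETA_OFFSET))
    M = beta_for_int * (total + BETA_OFFSET)
    U = np.maximum(total - M, 0.0)
    if design.channel_noise_sd > 0:
        M = M * np.exp(rng.normal(0.0, design.channel_noise_sd, size=M.shape))
        U = U * np.exp(rng.normal(0.0, design.channel_noise_sd, size=U.shape))

    beta_df = pd.DataFrame(beta, index=probe_ids, columns=sample_ids)
    m_df = pd.DataFrame(M, index=probe_ids, columns=sample_ids)
    u_df = pd.DataFrame(U, index=probe_ids, columns=sample_ids)
    pheno["neuronal_proportion"] = np.nan  # filled by the composition stage
    pheno = validate_phenotypes(pheno.reset_index())

    truth = TruthTables(
        spiked_dmps=pd.DataFrame(
            [
                {"probe_id": s.probe_id, "diagnosis": d, "delta": v}
                for s in design.spiked_dmps
                for d, v in s.delta.items()
            ],
            columns=["probe_id", "diagnosis", "delta"],
        ),
        spiked_dmrs=pd.DataFrame(
            [
                {
                    "chrom": r.chrom,
                    "start": r.start,
                    "end": r.end,
                    "n_probes": len(r.probe_ids),
                    "probe_ids": ";".join(r.probe_ids),
                    "diagnosis": d,
                    "delta": v,
                }
                for r in design.spiked_dmrs
                for d, v in r.delta.items()
            ],
            columns=["chrom", "start", "end", "n_probes", "probe_ids", "diagnosis", "delta"],
        ),
        modules=pd.DataFrame(
            [
                {"module": m.name, "probe_id": p, "loading": m.loading}
                for m in design.planted_modules
                for p in m.probe_ids
            ],
            columns=["module", "probe_id", "loading"],
        ),
        module_factors=module_factors,
        dup15q=dup,
        dup15q_donors=tuple(donor_df.loc[donor_df["diagnosis"] == "dup15q", "donor_id"]),
        dup_locus_probes=dup_probe_ids,
        neuronal_proportion=neuronal,
        age=pheno["age"].astype(float),
        age_shift=dict(design.age_shift),
        clock=design.clock,
        batch_effects=dict(design.batch_effects),
        sex=pheno["sex"],
        donor_sd=design.donor_sd,
        noise_sd=design.noise_sd,
    )
    return beta_df, (m_df, u_df), pheno, truth


def _check_design(design: SyntheticDesign, manifest: pd.DataFrame) -> None:
    known = set(manifest.index)
    for spike in design.spiked_dmps:
        if spike.probe_id not in known:
            raise DesignError(f"spiked DMP probe {spike.probe_id!r} not in manifest")
    for dmr in design.spiked_dmrs:
        missing = set(dmr.probe_ids) - known
        if missing:
            raise DesignError(f"spiked DMR probes not in manifest: {sorted(missing)[:3]}")
    for mod in design.planted_modules:
        missing = set(mod.probe_ids) - known
        if missing:
            raise DesignError(f"module probes not in manifest: {sorted(missing)[:3]}")
    if design.clock is not None:
        missing = set(design.clock.model.coefficients.index) - known
        if missing:
            raise DesignError(f"clock CpGs not in manifest: {sorted(missing)[:3]}")
    if design.cell_ref is not None:
        missing = set(design.cell_ref.markers) - known
        if missing:
            raise DesignError(f"cell-reference markers not in manifest: {sorted(missing)[:3]}")
    if not design.n_donors_per_group:
        raise DesignError("need at least one diagnostic group")


# ---------------------------------------------------------------------------
# pathways
# ---------------------------------------------------------------------------

def generate_pathways(
    manifest: pd.DataFrame,
    n_pathways: int,
    enriched_genes: set[str] | None = None,
    seed: int = 0,
    size_range: tuple[int, int] = (5, 3000),
) -> tuple[dict[str, tuple[str, frozenset[str]]], pd.DataFrame]:
    """Random gene sets plus one designated enriched pathway.

    Sizes are drawn log-uniformly over ``size_range`` so that, at the
    default range, some pathways fall below and above the 10-2000-gene
    testing window. Returns the GMT-style mapping and a truth table with
    each pathway's size and its overlap with ``enriched_genes``.
    """
    rng = np.random.default_rng(seed)
    universe = sorted({g for gs in manifest["genes"] for g in str(gs).split(";") if g})
    db: dict[str, tuple[str, frozenset[str]]] = {}
    rows = []
    lo, hi = size_range
    for i in range(n_pathways):
        size = int(np.exp(rng.uniform(np.log(lo), np.log(min(hi, max(lo, len(universe)))))))
        size = min(size, len(universe))
        genes = frozenset(rng.choice(universe, size=size, replace=False))
        pid = f"PW{i + 1:04d}"
        db[pid] = (f"random pathway {i + 1}", genes)
        overlap = len(genes & enriched_genes) if enriched_genes else 0
        rows.append({"pathway_id": pid, "size": size, "overlap": overlap, "enriched": False})
    if enriched_genes:
        genes = frozenset(enriched_genes)
        db["PW_ENRICHED"] = ("planted enriched pathway", genes)
        rows.append(
            {
                "pathway_id": "PW_ENRICHED",
                "size": len(genes),
                "overlap": len(genes),
                "enriched": True,
            }
        )
    return db, pd.DataFrame(rows, columns=["pathway_id", "size", "overlap", "enriched"])
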