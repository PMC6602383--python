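"""Sample and probe quality control, normalisation and batch adjustment.

The QC stage mirrors standard 450K practice: probes failing detection in
too many samples are dropped, as are SNP genotyping probes, cross-reactive
probes and probes with a common SNP near the single-base-extension site;
sample sex is verified by multidimensional scaling of sex-chromosome
probes; SNP-probe fingerprints confirm that tissues dissected from the
same donor really came from one individual.

Normalisation quantile-normalises methylated and unmethylated intensities
separately within each probe design type (the two Infinium chemistries
have different beta distributions) before recomputing betas. Batch
adjustment is a parametric empirical-Bayes location/scale model in the
ComBat family: batch means are shrunk through a normal prior and batch
variances through an inverse-gamma prior with method-of-moments
hyperparameters, while protected covariates (diagnosis, age, sex by
default) are held out of the correction and restored afterwards.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ioformats import FormatError

logger = logging.getLogger(__name__)

__all__ = [
    "QCReport",
    "detection_p_filter",
    "blacklist_filter",
    "sex_check",
    "fingerprint_match",
    "normalize_by_probe_type",
    "eb_batch_adjust",
    "run_qc",
]

BLACKLIST_FLAGS = ["flag_snp_probe", "flag_cross_reactive", "flag_snp_within_10bp"]


@dataclass
class QCReport:
    """What QC removed and why, plus sample-identity diagnostics."""

    probes_in: int = 0
    probes_out: int = 0
    probes_removed_by_reason: dict[str, int] = field(default_factory=dict)
    samples_flagged_sex_mismatch: list[str] = field(default_factory=list)
    donor_match_matrix: pd.DataFrame | None = None
    donor_mismatch_pairs: list[tuple[str, str, float]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "probes_in": self.probes_in,
            "probes_out": self.probes_out,
            "probes_removed_by_reason": dict(self.probes_removed_by_reason),
            "samples_flagged_sex_mismatch": list(self.samples_flagged_sex_mismatch),
            "donor_mismatch_pairs": [list(t) for t in self.donor_mismatch_pairs],
        }


# ---------------------------------------------------------------------------
# probe filters
# ---------------------------------------------------------------------------

def detection_p_filter(
    detection_p: pd.DataFrame, alpha: float = 0.05, frac: float = 0.01
) -> pd.Index:
    """Retain probes whose detection p exceeds ``alpha`` in fewer than
    ``ceil(frac * n_samples)`` samples (at least one sample must fail).

    With n <= 100 samples at the default 1% rule a probe failing in any
    single sample is removed, matching the practical behaviour of the
    standard p-filter.
    """
    vals = detection_p.to_numpy(dtype=float)
    if np.nanmin(vals) < 0 or np.nanmax(vals) > 1:
        raise FormatError("detection p-values must lie in [0, 1]")
    n_samples = detection_p.shape[1]
    threshold = max(1, math.ceil(frac * n_samples))
    n_fail = (vals > alpha).sum(axis=1)
    return detection_p.index[n_fail < threshold]


def blacklist_filter(manifest: pd.DataFrame) -> pd.Index:
    """Retain probes carrying none of the SNP/cross-reactivity flags."""
    flagged = manifest[BLACKLIST_FLAGS].any(axis=1)
    return manifest.index[~flagged]


# ---------------------------------------------------------------------------
# sample checks
# ---------------------------------------------------------------------------

def _classical_mds(x: np.ndarray, k: int = 2) -> np.ndarray:
    """Classical (Torgerson) MDS of rows of ``x`` from Euclidean distances."""
    sq = (x**2).sum(axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * x @ x.T
    np.maximum(d2, 0.0, out=d2)
    n = d2.shape[0]
    j = np.eye(n) - np.full((n, n), 1.0 / n)
    b = -0.5 * j @ d2 @ j
    w, v = np.linalg.eigh(b)
    order = np.argsort(w)[::-1][:k]
    w_top = np.clip(w[order], 0.0, None)
    return v[:, order] * np.sqrt(w_top)[None, :]


def _two_means_1d(x: np.ndarray) -> np.ndarray:
    """Exact 2-means on a 1-D array: best split of the sorted values."""
    order = np.argsort(x, kind="stable")
    xs = x[order]
    n = len(xs)
    csum = np.cumsum(xs)
    total = csum[-1]
    best_ss, best_i = np.inf, 1
    for i in range(1, n):
        left = csum[i - 1]
        right = total - left
        ss = (xs[:i] ** 2).sum() - left**2 / i + (xs[i:] ** 2).sum() - right**2 / (n - i)
        if ss < best_ss:
            best_ss, best_i = ss, i
    labels = np.zeros(n, dtype=int)
    labels[order[best_i:]] = 1
    return labels


def sex_check(
    beta: pd.DataFrame, manifest: pd.DataFrame, phenotypes: pd.DataFrame
) -> pd.DataFrame:
    """Predict sample sex from sex-chromosome probes and flag mismatches.

    A 2-D classical MDS of Euclidean distances over sex-chromosome probes
    is split by 2-means on the first coordinate; each cluster is labelled
    by the majority reported sex of its members.
    """
    sex_probes = manifest.index[manifest["flag_sex_chrom"]]
    sex_probes = sex_probes.intersection(beta.index)
    if len(sex_probes) < 2:
        raise FormatError("sex check needs at least 2 sex-chromosome probes")
    reported = phenotypes.loc[beta.columns, "sex"].to_numpy()
    if len(set(reported)) < 2:
        logger.warning("all samples report the same sex; sex check skipped")
        return pd.DataFrame(
            {"reported": reported, "predicted": reported, "mismatch": False},
            index=beta.columns,
        )
    coords = _classical_mds(beta.loc[sex_probes].to_numpy(dtype=float).T, k=2)
    labels = _two_means_1d(coords[:, 0])
    cluster_sex = {}
    for lab in (0, 1):
        members = reported[labels == lab]
        vals, counts = np.unique(members, return_counts=True)
        cluster_sex[lab] = vals[np.argmax(counts)] if len(vals) else "?"
    if cluster_sex[0] == cluster_sex[1]:
        logger.warning("sex clusters have the same majority label; check cohort balance")
    predicted = np.array([cluster_sex[lab] for lab in labels])
    return pd.DataFrame(
        {"reported": reported, "predicted": predicted, "mismatch": predicted != reported},
        index=beta.columns,
    )


def fingerprint_match(beta: pd.DataFrame, manifest: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation of SNP-probe betas for every sample pair.

    SNP genotyping probes behave like genotypes, so samples from the same
    donor correlate near 1 while cross-donor pairs sit much lower.
    """
    snp_probes = manifest.index[manifest["flag_snp_probe"]].intersection(beta.index)
    if len(snp_probes) < 2:
        raise FormatError("fingerprint match needs at least 2 SNP probes")
    sub = beta.loc[snp_probes]
    corr = np.corrcoef(sub.to_numpy(dtype=float).T)
    return pd.DataFrame(corr, index=beta.columns, columns=beta.columns)


def donor_concordance(
    match: pd.DataFrame, phenotypes: pd.DataFrame, threshold: float = 0.9
) -> list[tuple[str, str, float]]:
    """Same-donor sample pairs whose fingerprint correlation is below threshold."""
    donors = phenotypes.loc[match.index, "donor_id"]
    bad = []
    ids = match.index.to_list()
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            if donors[a] == donors[b] and match.loc[a, b] < threshold:
                bad.append((a, b, float(match.loc[a, b])))
    return bad


# ---------------------------------------------------------------------------
# normalisation
# ---------------------------------------------------------------------------

def _quantile_normalize(x: np.ndarray) -> np.ndarray:
    """Map each column of ``x`` onto the mean of the column-sorted values.

    Ties are broken by row order (ordinal ranks), the convention of the
    classic limma implementation for distinct values.
    """
    order = np.argsort(x, axis=0, kind="stable")
    ranks = np.empty_like(order)
    rows = np.arange(x.shape[0])[:, None]
    np.put_along_axis(ranks, order, rows, axis=0)
    ref = np.sort(x, axis=0).mean(axis=1)
    return ref[ranks]


def normalize_by_probe_type(
    M: pd.DataFrame, U: pd.DataFrame, manifest: pd.DataFrame
) -> pd.DataFrame:
    """Quantile-normalise M and U within each probe design type, then
    recompute ``beta = M / (M + U + 100)``.

    This is a stratified quantile normalisation in the spirit of the
    wateRmelon between-array methods: the type I and type II chemistries
    are normalised separately so the bimodal type I distribution is not
    forced onto type II probes.
    """
    if (M.to_numpy() < 0).any() or (U.to_numpy() < 0).any():
        raise FormatError("intensities must be non-negative")
    if not M.index.equals(U.index) or not M.columns.equals(U.columns):
        raise FormatError("M and U matrices must share probes and samples")
    design_type = manifest.loc[M.index, "design_type"]
    m_norm = M.to_numpy(dtype=float).copy()
    u_norm = U.to_numpy(dtype=float).copy()
    for dt in ("I", "II"):
        sel = np.flatnonzero((design_type == dt).to_numpy())
        if len(sel) == 0:
            continue
        m_norm[sel, :] = _quantile_normalize(m_norm[sel, :])
        u_norm[sel, :] = _quantile_normalize(u_norm[sel, :])
    beta = m_norm / (m_norm + u_norm + 100.0)
    return pd.DataFrame(beta, index=M.index, columns=M.columns)


# ---------------------------------------------------------------------------
# empirical-Bayes batch adjustment
# ---------------------------------------------------------------------------

def eb_batch_adjust(
    beta: pd.DataFrame,
    batch: pd.Series,
    covariates: pd.DataFrame | None = None,
    shrink: bool = True,
    clip: bool = True,
    max_iter: int = 100,
    tol: float = 1e-6,
) -> pd.DataFrame:
    """Empirical-Bayes location/scale batch correction (ComBat-style).

    Per probe, data are standardised on the residuals of a model with
    batch indicators plus protected covariates; per-batch means are shrunk
    through a normal prior and per-batch variances through an inverse-gamma
    prior (method-of-moments hyperparameters); the adjusted data are
    rescaled and the protected effects restored. With ``shrink=False`` the
    raw per-batch location/scale estimates are used (no EB pooling), which
    exactly equalises per-batch means.

    ``covariates`` is a numeric design of protected effects (no
    intercept); build one from a phenotype table with
    :func:`methcortex._design.build_design`.
    """
    batch = batch.loc[beta.columns]
    levels = pd.unique(batch)
    counts = batch.value_counts()
    small = counts[counts < 2]
    if len(small):
        raise FormatError(f"batch {small.index[0]!r} has fewer than 2 samples")
    if len(levels) == 1:
        return beta.copy()

    y = beta.to_numpy(dtype=float)
    n_probes, n = y.shape
    onehot = pd.get_dummies(batch).astype(float)
    onehot = onehot[[c for c in levels]]  # stable batch order
    b_mat = onehot.to_numpy()
    n_batches = b_mat.shape[1]
    batch_frac = b_mat.sum(axis=0) / n

    c_mat = None
    if covariates is not None:
        c_mat = covariates.loc[beta.columns].to_numpy(dtype=float)

    x = b_mat if c_mat is None else np.hstack([b_mat, c_mat])
    coef, *_ = np.linalg.lstsq(x, y.T, rcond=None)  # (n_params, n_probes)
    batch_coef = coef[:n_batches]
    grand_mean = batch_frac @ batch_coef  # (n_probes,)
    fitted = x @ coef
    resid = y.T - fitted
    pooled_var = (resid**2).mean(axis=0)  # per probe, 1/n convention
    pooled_var = np.maximum(pooled_var, 1e-12)

    stand_mean = np.tile(grand_mean, (n, 1))
    if c_mat is not None:
        stand_mean = stand_mean + c_mat @ coef[n_batches:]
    z = (y.T - stand_mean) / np.sqrt(pooled_var)[None, :]  # samples x probes

    gamma_star = np.zeros((n_batches, n_probes))
    delta_star = np.ones((n_batches, n_probes))
    for j in range(n_batches):
        sel = b_mat[:, j] == 1
        nj = sel.sum()
        zj = z[sel]
        gamma_hat = zj.mean(axis=0)
        delta_hat = zj.var(axis=0, ddof=1)
        if not shrink:
            gamma_star[j] = gamma_hat
            delta_star[j] = np.maximum(delta_hat, 1e-12)
            continue
        gamma_bar = gamma_hat.mean()
        tau2 = gamma_hat.var(ddof=1)
        m = delta_hat.mean()
        s2 = delta_hat.var(ddof=1)
        a_prior = (2.0 * s2 + m**2) / s2 if s2 > 0 else 2.0
        b_prior = (m * s2 + m**3) / s2 if s2 > 0 else 1.0
        g_new = gamma_hat.copy()
        d_new = np.maximum(delta_hat, 1e-12)
        for _ in range(max_iter):
            g_old, d_old = g_new, d_new
            g_new = (nj * tau2 * gamma_hat + d_old * gamma_bar) / (nj * tau2 + d_old)
            sse = ((zj - g_new[None, :]) ** 2).sum(axis=0)
            d_new = (0.5 * sse + b_prior) / (nj / 2.0 + a_prior - 1.0)
            d_new = np.maximum(d_new, 1e-12)
            change = max(
                np.abs(g_new - g_old).max(initial=0.0), np.abs(d_new - d_old).max(initial=0.0)
            )
            if change < tol:
                break
        gamma_star[j] = g_new
        delta_star[j] = d_new

    z_adj = z.copy()
    for j in range(n_batches):
        sel = b_mat[:, j] == 1
        z_adj[sel] = (z[sel] - gamma_star[j][None, :]) / np.sqrt(delta_star[j])[None, :]
    y_adj = (z_adj * np.sqrt(pooled_var)[None, :] + stand_mean).T
    if clip:
        np.clip(y_adj, 0.0, 1.0, out=y_adj)
    return pd.DataFrame(y_adj, index=beta.index, columns=beta.columns)


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def run_qc(
    beta: pd.DataFrame,
    manifest: pd.DataFrame,
    phenotypes: pd.DataFrame,
    detection_p: pd.DataFrame | None = None,
    alpha: float = 0.05,
    frac: float = 0.01,
) -> tuple[pd.DataFrame, QCReport]:
    """Apply the probe filters in sequence and run the sample checks.

    Removal counts are attributed sequentially (detection p first, then
    each blacklist flag) so that they sum exactly to the number of probes
    dropped; the retained set itself is order-independent.
    """
    report = QCReport(probes_in=beta.shape[0])
    retained = beta.index
    if detection_p is not None:
        if detection_p.shape[0] != beta.shape[0]:
            raise FormatError("detection p matrix does not match beta probes")
        keep = detection_p_filter(detection_p.loc[retained], alpha=alpha, frac=frac)
        report.probes_removed_by_reason["detection_p"] = len(retained) - len(keep)
        retained = keep
    man = manifest.loc[retained]
    for flag in BLACKLIST_FLAGS:
        keep = man.index[~man[flag]]
        report.probes_removed_by_reason[flag] = len(man) - len(keep)
        man = man.loc[keep]
    retained = man.index
    report.probes_out = len(retained)

    try:
        sexes = sex_check(beta, manifest, phenotypes)
        report.samples_flagged_sex_mismatch = list(sexes.index[sexes["mismatch"]])
    except FormatError:
        logger.warning("sex check skipped (insufficient sex-chromosome probes)")
    try:
        match = fingerprint_match(beta, manifest)
        report.donor_match_matrix = match
        report.donor_mismatch_pairs = donor_concordance(match, phenotypes)
    except FormatError:
        logger.warning("fingerprint match skipped (insufficient SNP probes)")
    return beta.loc[retained], report
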