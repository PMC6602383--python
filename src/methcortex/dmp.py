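"""Per-probe differential methylation analysis.

Within a brain region, each probe's beta value is regressed on a 0/1
diagnosis indicator plus covariates (age, sex, brain bank and, in
cortex, the estimated neuronal proportion); the diagnosis coefficient is
the effect in beta units (delta-beta, case minus control) and its
two-sided t-test gives the p-value. Across the two cortical regions the
same fixed effects plus a region term enter a donor-random-intercept
linear mixed model fitted by restricted maximum likelihood, profiled
over the ratio of donor to residual variance; inference on the diagnosis
effect uses a Wald z statistic (no small-sample degrees-of-freedom
correction, an approximation documented in the methods note).

Downstream helpers assign significance tiers (a discovery threshold of
5e-5 and a Bonferroni experiment-wide threshold of 0.05 / number of
probes), cluster samples at the called DMPs, compare effect sizes
between patient groups (including Fisher's z test for two correlations),
and integrate differential-expression results.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from ._design import build_design, diagnosis_indicator
from .ioformats import FormatError, manifest_genes

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_COVARIATES",
    "fit_probe_ols",
    "fit_ols",
    "fit_probe_lme",
    "fit_lme",
    "experiment_wide_threshold",
    "call_dmps",
    "global_methylation_summary",
    "cluster_samples_at_dmps",
    "effect_concordance",
    "fisher_z_diff",
    "integrate_expression",
]

DEFAULT_COVARIATES = ("age", "sex", "bank", "cets")
DISCOVERY_P = 5e-05
RESULT_COLUMNS = ["effect", "se", "stat", "p_value", "n_used", "model", "region_scope"]


def _region_covariates(covariates: tuple[str, ...], region: str | None, pheno: pd.DataFrame) -> list[str]:
    """Drop the cell-composition covariate where it is not applicable."""
    covs = list(covariates)
    is_cets = lambda c: c in ("cets", "neuronal_proportion")  # noqa: E731
    if region == "CB":
        covs = [c for c in covs if not is_cets(c)]
    if any(is_cets(c) for c in covs) and pheno["neuronal_proportion"].isna().all():
        logger.warning("neuronal_proportion entirely missing; dropping it from the model")
        covs = [c for c in covs if not is_cets(c)]
    return covs


def _assemble(index, effect, se, stat, p, n_used, model, scope) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "effect": effect,
            "se": se,
            "stat": stat,
            "p_value": p,
            "n_used": n_used,
            "model": model,
            "region_scope": scope,
        },
        index=pd.Index(index, name="probe_id"),
    )[RESULT_COLUMNS]


def _ols_block(y: np.ndarray, x: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """OLS of each row of ``y`` (probes x samples) on the shared design ``x``.

    Returns effect (column 1 of the design), its standard error, t and
    two-sided p. Probes with zero residual variance get p = 1 when the
    effect is also (numerically) zero and p = 0 otherwise.
    """
    n, p = x.shape
    if n < p + 1:
        raise FormatError(f"need at least {p + 1} samples for {p} parameters")
    if np.linalg.matrix_rank(x) < p:
        raise np.linalg.LinAlgError("singular design")
    xtx_inv = np.linalg.inv(x.T @ x)
    coefs = y @ x @ xtx_inv.T  # probes x p
    resid = y - coefs @ x.T
    dof = n - p
    s2 = (resid**2).sum(axis=1) / dof
    effect = coefs[:, 1]
    se = np.sqrt(np.maximum(s2 * xtx_inv[1, 1], 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = effect / se
    pvals = 2.0 * stats.t.sf(np.abs(t), dof)
    zero_var = se == 0.0
    pvals[zero_var & (np.abs(effect) < 1e-12)] = 1.0
    pvals[zero_var & (np.abs(effect) >= 1e-12)] = 0.0
    t[zero_var] = 0.0
    return effect, se, t, pvals


def fit_ols(
    beta: pd.DataFrame,
    phenotypes: pd.DataFrame,
    case: str,
    control: str = "CTL",
    region: str | None = None,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
) -> pd.DataFrame:
    """Per-probe OLS association for one region (or all samples).

    Missing beta values are handled by listwise deletion per probe. A
    singular design (for example, bank perfectly confounded with
    diagnosis) yields flagged rows with missing p-values.
    """
    ph = phenotypes.loc[beta.columns]
    if region is not None:
        ph = ph[ph["region"] == region]
    dx, used = diagnosis_indicator(ph, case, control)
    ph = ph.loc[used]
    covs = _region_covariates(covariates, region, ph)
    design = build_design(ph, covs, add_intercept=False)
    x_full = np.column_stack(
        [np.ones(len(ph)), dx.to_numpy(), design.to_numpy() if design.shape[1] else np.empty((len(ph), 0))]
    )
    y = beta[used].to_numpy(dtype=float)
    scope = region or "all"

    complete = ~np.isnan(y).any(axis=1)
    n, p = x_full.shape
    eff = np.full(beta.shape[0], np.nan)
    se = np.full_like(eff, np.nan)
    tstat = np.full_like(eff, np.nan)
    pval = np.full_like(eff, np.nan)
    n_used = np.full(beta.shape[0], 0, dtype=int)
    try:
        if complete.any():
            e, s, t, pv = _ols_block(y[complete], x_full)
            eff[complete], se[complete], tstat[complete], pval[complete] = e, s, t, pv
            n_used[complete] = n
    except np.linalg.LinAlgError:
        logger.warning("singular design for scope %s; results flagged", scope)
        n_used[complete] = n
        return _assemble(beta.index, eff, se, tstat, pval, n_used, "OLS", scope)

    for i in np.flatnonzero(~complete):
        ok = ~np.isnan(y[i])
        if ok.sum() < p + 1:
            continue
        sub_x = x_full[ok]
        if len(np.unique(sub_x[:, 1])) < 2:
            continue
        try:
            e, s, t, pv = _ols_block(y[i][None, ok], sub_x)
        except (np.linalg.LinAlgError, FormatError):
            continue
        eff[i], se[i], tstat[i], pval[i] = e[0], s[0], t[0], pv[0]
        n_used[i] = int(ok.sum())
    return _assemble(beta.index, eff, se, tstat, pval, n_used, "OLS", scope)


def fit_probe_ols(
    beta_row: pd.Series,
    phenotypes: pd.DataFrame,
    case: str,
    control: str = "CTL",
    region: str | None = None,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
) -> pd.Series:
    """Single-probe convenience wrapper around :func:`fit_ols`."""
    name = beta_row.name if beta_row.name is not None else "probe"
    res = fit_ols(beta_row.to_frame(name).T, phenotypes, case, control, region, covariates)
    return res.iloc[0]


# ---------------------------------------------------------------------------
# donor-random-intercept mixed model (profiled REML)
# ---------------------------------------------------------------------------

def _reml_criterion(
    lam: np.ndarray, d: np.ndarray, xr: np.ndarray, yr: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """-2 x restricted log-likelihood (up to constants) for per-probe lambda.

    Works in the eigenbasis of Z Z^T: the marginal covariance is
    sigma^2 diag(1 + lambda d), so GLS reduces to weighted least squares.
    Returns (criterion, rss, coefs, A) for each probe.
    """
    n, p = xr.shape
    w = 1.0 / (1.0 + lam[:, None] * d[None, :])  # probes x n
    a = np.einsum("ni,kn,nj->kij", xr, w, xr, optimize=True)
    wy = w * yr
    b = np.einsum("ni,kn->ki", xr, wy, optimize=True)
    coefs = np.linalg.solve(a, b[..., None])[..., 0]
    rss = (wy * yr).sum(axis=1) - (coefs * b).sum(axis=1)
    rss = np.maximum(rss, 1e-300)
    sign, logdet_a = np.linalg.slogdet(a)
    crit = (
        (n - p) * np.log(rss)
        + np.log1p(lam[:, None] * d[None, :]).sum(axis=1)
        + logdet_a
    )
    return crit, rss, coefs, a


def fit_lme(
    beta: pd.DataFrame,
    phenotypes: pd.DataFrame,
    case: str,
    control: str = "CTL",
    regions: tuple[str, ...] = ("PFC", "TC"),
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
    include_region_effect: bool = True,
    grid: np.ndarray | None = None,
    refine_iter: int = 60,
) -> pd.DataFrame:
    """Cross-region donor-random-intercept model for every probe.

    The variance ratio (donor variance over residual variance) is
    profiled: the REML criterion is evaluated on a log-spaced grid shared
    by all probes, then refined per probe by golden-section search; the
    boundary value 0 (no donor variance, reducing the model exactly to
    pooled OLS) is always a candidate. Wald z inference on the diagnosis
    fixed effect.
    """
    ph = phenotypes.loc[beta.columns]
    ph = ph[ph["region"].isin(regions)]
    dx, used = diagnosis_indicator(ph, case, control)
    ph = ph.loc[used]
    if ph["donor_id"].value_counts().gt(1).sum() < 2 and len(set(ph["region"])) > 1:
        raise FormatError("need at least 2 donors measured in more than one region")
    covs = _region_covariates(covariates, None, ph)
    if include_region_effect and len(set(ph["region"])) > 1:
        covs = covs + ["region"]
    design = build_design(ph, covs, add_intercept=False)
    x = np.column_stack(
        [np.ones(len(ph)), dx.to_numpy(), design.to_numpy() if design.shape[1] else np.empty((len(ph), 0))]
    )
    n, p = x.shape
    if np.linalg.matrix_rank(x) < p:
        logger.warning("singular fixed-effect design; LME results flagged")
        nanvec = np.full(beta.shape[0], np.nan)
        return _assemble(beta.index, nanvec, nanvec, nanvec, nanvec, np.zeros(beta.shape[0], int), "LME", "+".join(regions))

    donor_codes = pd.Categorical(ph["donor_id"]).codes
    z = np.zeros((n, donor_codes.max() + 1))
    z[np.arange(n), donor_codes] = 1.0
    g = z @ z.T
    d, q = np.linalg.eigh(g)
    d = np.clip(d, 0.0, None)
    xr = q.T @ x
    y = beta[used].to_numpy(dtype=float)
    complete = ~np.isnan(y).any(axis=1)
    if not complete.all():
        logger.warning(
            "%d probes have missing values; they are dropped from the mixed model",
            int((~complete).sum()),
        )
    yr = y[complete] @ q
    k = yr.shape[0]

    if grid is None:
        grid = np.concatenate([[0.0], np.logspace(-5, 3, 33)])
    crits = np.empty((len(grid), k))
    for gi, lam in enumerate(grid):
        crits[gi], *_ = _reml_criterion(np.full(k, lam), d, xr, yr)
    best = np.argmin(crits, axis=0)

    # golden-section refinement on log-lambda between the flanking grid points
    interior = (best > 0) & (best < len(grid) - 1)
    lam_hat = grid[best].astype(float)
    if interior.any():
        idx = np.flatnonzero(interior)
        lo = np.log(np.where(best[idx] > 1, grid[best[idx] - 1], grid[1] * 1e-2))
        hi = np.log(grid[np.minimum(best[idx] + 1, len(grid) - 1)])
        invphi = (np.sqrt(5.0) - 1.0) / 2.0
        a_t, b_t = lo.copy(), hi.copy()
        c_t = b_t - invphi * (b_t - a_t)
        d_t = a_t + invphi * (b_t - a_t)
        fc, *_ = _reml_criterion(np.exp(c_t), d, xr, yr[idx])
        fd, *_ = _reml_criterion(np.exp(d_t), d, xr, yr[idx])
        for _ in range(refine_iter):
            go_left = fc < fd
            b_t = np.where(go_left, d_t, b_t)
            a_t = np.where(go_left, a_t, c_t)
            c_new = b_t - invphi * (b_t - a_t)
            d_new = a_t + invphi * (b_t - a_t)
            c_t, d_t = c_new, d_new
            fc, *_ = _reml_criterion(np.exp(c_t), d, xr, yr[idx])
            fd, *_ = _reml_criterion(np.exp(d_t), d, xr, yr[idx])
            if np.max(b_t - a_t) < 1e-10:
                break
        lam_ref = np.exp(0.5 * (a_t + b_t))
        crit_ref, *_ = _reml_criterion(lam_ref, d, xr, yr[idx])
        improved = crit_ref < crits[best[idx], idx]
        lam_hat[idx] = np.where(improved, lam_ref, lam_hat[idx])

    crit, rss, coefs, a = _reml_criterion(lam_hat, d, xr, yr)
    sigma2 = rss / (n - p)
    a_inv = np.linalg.inv(a)
    eff_c = coefs[:, 1]
    se_c = np.sqrt(np.maximum(sigma2 * a_inv[:, 1, 1], 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        zstat = eff_c / se_c
    pv = 2.0 * stats.norm.sf(np.abs(zstat))
    zero_var = se_c == 0.0
    pv[zero_var & (np.abs(eff_c) < 1e-12)] = 1.0

    eff = np.full(beta.shape[0], np.nan)
    se = np.full_like(eff, np.nan)
    stat = np.full_like(eff, np.nan)
    pvals = np.full_like(eff, np.nan)
    lam_out = np.full_like(eff, np.nan)
    eff[complete], se[complete], stat[complete], pvals[complete] = eff_c, se_c, zstat, pv
    lam_out[complete] = lam_hat
    n_used = np.where(complete, n, 0)
    out = _assemble(beta.index, eff, se, stat, pvals, n_used, "LME", "+".join(regions))
    out["variance_ratio"] = lam_out
    return out


def fit_probe_lme(
    beta_row: pd.Series,
    phenotypes: pd.DataFrame,
    case: str,
    control: str = "CTL",
    **kwargs,
) -> pd.Series:
    """Single-probe convenience wrapper around :func:`fit_lme`."""
    name = beta_row.name if beta_row.name is not None else "probe"
    return fit_lme(beta_row.to_frame(name).T, phenotypes, case, control, **kwargs).iloc[0]


# ---------------------------------------------------------------------------
# thresholds and summaries
# ---------------------------------------------------------------------------

def experiment_wide_threshold(n_probes: int, family_alpha: float = 0.05) -> float:
    """Bonferroni experiment-wide significance threshold ``alpha / n``."""
    if n_probes < 1:
        raise FormatError("n_probes must be positive")
    return family_alpha / n_probes


def call_dmps(
    results: pd.DataFrame,
    discovery: float = DISCOVERY_P,
    n_probes: int | None = None,
) -> pd.DataFrame:
    """Assign significance tiers to association results.

    ``discovery`` is a strict upper bound; the experiment-wide tier uses
    the Bonferroni threshold 0.05 / ``n_probes`` (defaulting to the
    number of analysed probes) and is a subset of the discovery tier.
    """
    out = results.copy()
    if len(out) == 0:
        out["tier"] = pd.Series(dtype=str)
        return out
    n = n_probes if n_probes is not None else int(out["p_value"].notna().sum())
    ew = experiment_wide_threshold(max(n, 1))
    p = out["p_value"]
    tier = np.where(p < min(ew, discovery), "experiment-wide", np.where(p < discovery, "discovery", ""))
    tier[p.isna().to_numpy()] = ""
    out["tier"] = tier
    return out


def global_methylation_summary(
    beta: pd.DataFrame, phenotypes: pd.DataFrame, control: str = "CTL"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Grand mean beta by diagnosis x region, with per-region t-tests of
    per-sample means against the control group."""
    ph = phenotypes.loc[beta.columns]
    sample_means = beta.mean(axis=0)
    summary = (
        pd.DataFrame({"mean_beta": sample_means, "diagnosis": ph["diagnosis"], "region": ph["region"]})
        .groupby(["diagnosis", "region"], sort=True)["mean_beta"]
        .mean()
        .unstack()
    )
    rows = []
    for region, sub in ph.groupby("region", sort=False):
        ctl = sample_means[sub.index[sub["diagnosis"] == control]]
        for dx in sorted(set(sub["diagnosis"]) - {control}):
            grp = sample_means[sub.index[sub["diagnosis"] == dx]]
            if len(grp) < 2 or len(ctl) < 2:
                continue
            if np.isclose(grp.var(), 0) and np.isclose(ctl.var(), 0) and np.isclose(grp.mean(), ctl.mean()):
                p = 1.0
            else:
                p = float(stats.ttest_ind(grp, ctl, equal_var=False).pvalue)
            rows.append({"region": region, "diagnosis": dx, "delta": float(grp.mean() - ctl.mean()), "p_value": p})
    return summary, pd.DataFrame(rows, columns=["region", "diagnosis", "delta", "p_value"])


def cluster_samples_at_dmps(
    beta: pd.DataFrame,
    dmp_probes: list[str] | pd.Index,
    phenotypes: pd.DataFrame,
    case: str,
    control: str = "CTL",
) -> tuple[np.ndarray, pd.DataFrame]:
    """Average-linkage clustering of samples on (1 - Pearson) distance over
    the DMP probes, cut into two clusters; returns the linkage matrix and
    each cluster's case fraction."""
    probes = pd.Index(dmp_probes).intersection(beta.index)
    if len(probes) < 2:
        raise FormatError("need at least 2 DMPs to cluster samples")
    sub = beta.loc[probes]
    corr = np.corrcoef(sub.to_numpy(dtype=float).T)
    dist = np.clip(1.0 - corr, 0.0, 2.0)
    np.fill_diagonal(dist, 0.0)
    link = linkage(squareform(dist, checks=False), method="average")
    labels = fcluster(link, t=2, criterion="maxclust")
    ph = phenotypes.loc[beta.columns]
    is_case = diagnosis_indicator(ph, case, control)[0].reindex(beta.columns)
    rows = []
    for lab in sorted(set(labels)):
        members = beta.columns[labels == lab]
        frac = float(is_case.loc[members].mean())
        rows.append({"cluster": lab, "n": len(members), "case_fraction": frac})
    return link, pd.DataFrame(rows)


def effect_concordance(
    effects_a: pd.Series,
    effects_b: pd.Series,
    probes: list[str] | pd.Index | None = None,
    manifest: pd.DataFrame | None = None,
    interval: tuple[str, int, int] | None = None,
) -> pd.DataFrame:
    """Pearson correlation of effect sizes over a probe set, optionally
    stratified inside/outside a genomic interval (1-based inclusive)."""
    idx = pd.Index(probes) if probes is not None else effects_a.index
    idx = idx.intersection(effects_a.index).intersection(effects_b.index)
    strata = {"all": idx}
    if interval is not None:
        if manifest is None:
            raise FormatError("stratifying on an interval requires the manifest")
        chrom, start, end = interval
        man = manifest.loc[idx]
        inside = man.index[(man["chrom"] == chrom) & man["pos"].between(start, end)]
        strata["inside"] = inside
        strata["outside"] = idx.difference(inside)
    rows = []
    for name, s_idx in strata.items():
        a = effects_a.loc[s_idx].astype(float)
        b = effects_b.loc[s_idx].astype(float)
        ok = a.notna() & b.notna()
        n = int(ok.sum())
        if n < 3 or a[ok].std() == 0 or b[ok].std() == 0:
            rows.append({"stratum": name, "r": np.nan, "p_value": np.nan, "n": n})
            continue
        r, p = stats.pearsonr(a[ok], b[ok])
        rows.append({"stratum": name, "r": float(r), "p_value": float(p), "n": n})
    return pd.DataFrame(rows).set_index("stratum")


def fisher_z_diff(r1: float, n1: int, r2: float, n2: int) -> tuple[float, float]:
    """Fisher's z test for the difference between two independent
    correlations; returns (z, two-sided normal p)."""
    if n1 <= 3 or n2 <= 3:
        raise FormatError("Fisher's z test needs more than 3 observations per group")
    z = (np.arctanh(r1) - np.arctanh(r2)) / np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    return float(z), float(2.0 * stats.norm.sf(abs(z)))


def integrate_expression(
    results: pd.DataFrame,
    dmp_probes: list[str] | pd.Index,
    manifest: pd.DataFrame,
    de_table: pd.DataFrame,
    fdr_cut: float = 0.1,
) -> dict:
    """Overlap DMPs with differential-expression calls and correlate effects.

    Every gene annotated to a DMP contributes a probe-gene pair (a probe
    annotated to two differentially expressed genes contributes two
    pairs). Returns the number of gene-annotated DMPs, how many overlap a
    DE transcript at ``fdr < fdr_cut``, and the Pearson correlation
    between delta-beta and log-fold-change over the significant pairs
    (missing when fewer than 3 pairs).
    """
    genes_by_probe = manifest_genes(manifest)
    de = de_table.set_index("gene")
    de_sig = de[de["fdr"] < fdr_cut]
    pairs = []
    n_annotated = 0
    n_overlap = 0
    for probe in pd.Index(dmp_probes):
        genes = genes_by_probe.get(probe, [])
        if not genes:
            continue
        n_annotated += 1
        hit = False
        for gene in genes:
            if gene in de_sig.index:
                hit = True
                pairs.append((float(results.loc[probe, "effect"]), float(de_sig.loc[gene, "log_fold_change"])))
        n_overlap += int(hit)
    if len(pairs) >= 3:
        db, lfc = np.array(pairs).T
        r = float(stats.pearsonr(db, lfc)[0]) if db.std() > 0 and lfc.std() > 0 else np.nan
    else:
        r = np.nan
    return {
        "n_dmps_annotated": n_annotated,
        "n_overlap_de": n_overlap,
        "n_pairs": len(pairs),
        "effect_correlation": r,
    }
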