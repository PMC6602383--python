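"""Signed co-methylation networks, modules and module-trait models.

The construction follows the weighted-correlation-network recipe:
variable probes are kept (methylation range above 5% in the middle 80%
of samples), nuisance covariates are regressed out, a signed adjacency
``((1 + bicor) / 2) ^ power`` is built from biweight midcorrelations,
similarity is re-weighted by topological overlap (shared neighbours),
and modules come from average-linkage clustering of the topological
overlap dissimilarity. Branches are extracted with a static
relative-height rule rather than the dynamic-hybrid tree cut; this is a
deliberate simplification (the cut fraction is a parameter) — see the
methods note for its consequences. Modules whose eigengenes are
nearly collinear are merged, and each module's eigengene (first
principal component, unit variance, sign-anchored to the module mean) is
tested against diagnosis in a donor-random-intercept model with
Benjamini-Hochberg correction across modules.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans
from statsmodels.stats.multitest import multipletests

from ._design import build_design
from .dmp import fit_lme
from .ioformats import FormatError

logger = logging.getLogger(__name__)

__all__ = [
    "variable_probe_filter",
    "residualize",
    "bicor",
    "bicor_matrix",
    "signed_adjacency",
    "topological_overlap",
    "detect_modules",
    "module_eigengene",
    "module_trait_association",
    "build_network",
]

UNASSIGNED = 0  # module label for probes outside every named module


def variable_probe_filter(
    beta: pd.DataFrame, min_range: float = 0.05, central_frac: float = 0.80
) -> pd.Index:
    """Probes whose beta range within the central fraction of samples
    strictly exceeds ``min_range``.

    With the default 80% central fraction this is the 0.9 quantile minus
    the 0.1 quantile (linear-interpolation quantiles); a probe whose
    central range equals the threshold exactly is removed.
    """
    lo = (1.0 - central_frac) / 2.0
    vals = beta.to_numpy(dtype=float)
    q_lo, q_hi = np.nanquantile(vals, [lo, 1.0 - lo], axis=1)
    return beta.index[(q_hi - q_lo) > min_range]


def residualize(
    beta: pd.DataFrame,
    phenotypes: pd.DataFrame,
    remove: tuple[str, ...] = ("cets", "age"),
    keep: tuple[str, ...] = ("diagnosis", "sex", "region", "bank"),
) -> pd.DataFrame:
    """Remove selected covariate effects while protecting others.

    Per probe, an OLS on the full covariate set (remove + keep) is fit
    and only the fitted contribution of the removal set is subtracted,
    so effects correlated with protected covariates (diagnosis above all)
    are not stripped. An empty removal set returns the data unchanged.
    """
    if not remove:
        return beta.copy()
    ph = phenotypes.loc[beta.columns]
    x_rm = build_design(ph, list(remove), add_intercept=False)
    x_keep = build_design(ph, list(keep), add_intercept=False) if keep else None
    parts = [np.ones((len(ph), 1)), x_rm.to_numpy(dtype=float)]
    if x_keep is not None and x_keep.shape[1]:
        parts.append(x_keep.to_numpy(dtype=float))
    x = np.hstack(parts)
    if np.isnan(x).any():
        raise FormatError("covariates contain missing values; impute or drop those samples")
    y = beta.to_numpy(dtype=float)
    coef, *_ = np.linalg.lstsq(x, y.T, rcond=None)
    rm_slice = slice(1, 1 + x_rm.shape[1])
    contribution = x[:, rm_slice] @ coef[rm_slice]
    return pd.DataFrame(y - contribution.T, index=beta.index, columns=beta.columns)


# ---------------------------------------------------------------------------
# correlation and topology
# ---------------------------------------------------------------------------

def _bicor_prepare(x: np.ndarray) -> np.ndarray:
    """Tukey-biweight-standardised rows, unit norm; Pearson fallback at MAD 0."""
    med = np.median(x, axis=1, keepdims=True)
    mad = np.median(np.abs(x - med), axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        u = (x - med) / (9.0 * mad)
    w = np.where(np.abs(u) < 1.0, (1.0 - u**2) ** 2, 0.0)
    xt = (x - med) * w
    fallback = (mad == 0).ravel()
    if fallback.any():
        xt[fallback] = x[fallback] - x[fallback].mean(axis=1, keepdims=True)
    norm = np.sqrt((xt**2).sum(axis=1, keepdims=True))
    norm[norm == 0] = 1.0
    return xt / norm


def bicor(x: np.ndarray | pd.Series, y: np.ndarray | pd.Series) -> float:
    """Biweight midcorrelation of two vectors.

    Weights ``(1 - u^2)^2`` for ``|u| < 1`` with ``u = (x - median) /
    (9 MAD)``; observations beyond nine MADs get weight zero, making the
    statistic robust to outliers. When MAD is zero for a vector the
    Pearson centring is used for it instead.
    """
    a = np.asarray(x, dtype=float)[None, :]
    b = np.asarray(y, dtype=float)[None, :]
    if a.shape != b.shape:
        raise FormatError("bicor needs two vectors of equal length")
    ra = _bicor_prepare(a)
    rb = _bicor_prepare(b)
    return float(np.clip((ra * rb).sum(), -1.0, 1.0))


def bicor_matrix(x: np.ndarray | pd.DataFrame) -> np.ndarray:
    """Pairwise biweight midcorrelation of the rows of ``x``."""
    arr = x.to_numpy(dtype=float) if isinstance(x, pd.DataFrame) else np.asarray(x, dtype=float)
    xt = _bicor_prepare(arr)
    r = xt @ xt.T
    np.clip(r, -1.0, 1.0, out=r)
    np.fill_diagonal(r, 1.0)
    return r


def signed_adjacency(correlation: np.ndarray, soft_power: float = 7) -> np.ndarray:
    """Signed adjacency ``((1 + r) / 2)^power`` with zero diagonal.

    Anti-correlated probes get adjacency near 0 and perfectly correlated
    ones near 1; the soft power sharpens the distinction. The diagonal
    is zeroed for the topological-overlap computation.
    """
    a = ((1.0 + np.asarray(correlation, dtype=float)) / 2.0) ** soft_power
    np.clip(a, 0.0, 1.0, out=a)
    np.fill_diagonal(a, 0.0)
    return a


def topological_overlap(adjacency: np.ndarray) -> np.ndarray:
    """Topological overlap matrix: shared-neighbour-weighted similarity.

    ``w_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij)`` with
    ``k`` the connectivity (row sum); the diagonal is 1.
    """
    a = np.asarray(adjacency, dtype=float)
    k = a.sum(axis=1)
    shared = a @ a
    denom = np.minimum(k[:, None], k[None, :]) + 1.0 - a
    with np.errstate(divide="ignore", invalid="ignore"):
        w = (shared + a) / denom
    w[~np.isfinite(w)] = 0.0
    np.fill_diagonal(w, 1.0)
    return w


# ---------------------------------------------------------------------------
# modules
# ---------------------------------------------------------------------------

def module_eigengene(data: pd.DataFrame, probes: list[str] | pd.Index) -> pd.Series:
    """First principal component of a module, one score per sample.

    Probe rows are z-scored before the SVD; the eigengene is scaled to
    unit variance and sign-flipped to correlate positively with the
    module's mean methylation.
    """
    sub = data.loc[pd.Index(probes)]
    x = sub.to_numpy(dtype=float)
    mean = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    sd[sd == 0] = 1.0
    z = (x - mean) / sd
    _, _, vt = np.linalg.svd(z, full_matrices=False)
    eig = vt[0]
    sd_e = eig.std(ddof=1)
    if sd_e > 0:
        eig = eig / sd_e
    mean_meth = x.mean(axis=0)
    if np.std(mean_meth) > 0 and np.corrcoef(eig, mean_meth)[0, 1] < 0:
        eig = -eig
    return pd.Series(eig, index=data.columns, name="eigengene")


def _static_cut(
    tom: np.ndarray, min_module_size: int, cut_fraction: float = 0.995, absolute_cut: float = 0.9
) -> np.ndarray:
    """Branch extraction from average-linkage clustering of 1 - TOM.

    A subtree is named a module when it is large enough and completes
    below ``cut_fraction`` times the height at which it joins the rest
    of the tree — the branch hangs clearly below its attachment point.
    Chained noise, whose merge heights are nearly equal, therefore
    shatters into unassigned probes while coherent branches survive.
    The root has no attachment point; it qualifies when its height is
    below the ``absolute_cut`` dissimilarity (the classic static
    cut-height idea), covering the case where the whole input is one
    co-methylated block. This two-parameter static rule replaces the
    dynamic-hybrid tree cut.
    """
    n = tom.shape[0]
    if n < 2:
        return np.zeros(n, dtype=int)
    dist = np.clip(1.0 - tom, 0.0, None)
    np.fill_diagonal(dist, 0.0)
    link = linkage(squareform(dist, checks=False), method="average")

    n_nodes = n + link.shape[0]
    left = np.full(n_nodes, -1, dtype=int)
    right = np.full(n_nodes, -1, dtype=int)
    height = np.zeros(n_nodes)
    size = np.ones(n_nodes, dtype=int)
    for i, (a, b, h, s) in enumerate(link):
        node = n + i
        left[node], right[node] = int(a), int(b)
        height[node], size[node] = h, int(s)

    out = np.zeros(n, dtype=int)
    next_label = 1
    split_fraction = 0.9  # a branch splits when both halves end well below it

    def leaves(node: int) -> list[int]:
        stack, acc = [node], []
        while stack:
            v = stack.pop()
            if v < n:
                acc.append(v)
            else:
                stack.extend((left[v], right[v]))
        return acc

    def label_or_split(node: int) -> None:
        nonlocal next_label
        stack = [node]
        while stack:
            v = stack.pop()
            l, r = left[v], right[v]
            if (
                v >= n
                and size[l] >= min_module_size
                and size[r] >= min_module_size
                and height[l] <= split_fraction * height[v]
                and height[r] <= split_fraction * height[v]
            ):
                stack.extend((l, r))
            else:
                out[leaves(v)] = next_label
                next_label += 1

    # walk down from the root; a subtree that completes clearly below the
    # height at which it joins the rest becomes a module (chained noise,
    # whose merge heights are nearly equal, shatters instead)
    stack = [(n_nodes - 1, np.inf)]  # (node, parent height)
    while stack:
        node, parent_h = stack.pop()
        if size[node] < min_module_size:
            continue
        if (
            height[node] <= cut_fraction * parent_h
            if np.isfinite(parent_h)
            else height[node] <= absolute_cut
        ):
            label_or_split(node)
            continue
        if node >= n:
            stack.append((left[node], height[node]))
            stack.append((right[node], height[node]))
    return out


def _merge_modules(
    labels: np.ndarray,
    data: pd.DataFrame,
    merge_cut_height: float,
) -> np.ndarray:
    """Iteratively merge modules whose eigengenes correlate > 1 - cut."""
    labels = labels.copy()
    while True:
        mods = [m for m in np.unique(labels) if m != UNASSIGNED]
        if len(mods) < 2:
            break
        eigs = {m: module_eigengene(data, data.index[labels == m]).to_numpy() for m in mods}
        best_pair, best_r = None, 1.0 - merge_cut_height
        for i, a in enumerate(mods):
            for b in mods[i + 1 :]:
                r = float(np.corrcoef(eigs[a], eigs[b])[0, 1])
                if r > best_r:
                    best_pair, best_r = (a, b), r
        if best_pair is None:
            break
        a, b = best_pair
        labels[labels == b] = a
    return labels


def detect_modules(
    tom: np.ndarray,
    data: pd.DataFrame | None = None,
    min_module_size: int = 100,
    merge_cut_height: float = 0.1,
    cut_fraction: float = 0.995,
) -> pd.Series:
    """Extract modules from a topological overlap matrix.

    Components of the average-linkage dendrogram below ``cut_fraction``
    of the maximum merge height become candidate modules; components
    smaller than ``min_module_size`` stay unassigned (label 0). When
    ``data`` is given, modules whose eigengenes correlate above
    ``1 - merge_cut_height`` are merged. Labels are renumbered 1..k by
    decreasing module size.
    """
    n = tom.shape[0]
    index = data.index if data is not None else pd.RangeIndex(n)
    if n < min_module_size:
        logger.warning("fewer probes (%d) than min_module_size; all unassigned", n)
        return pd.Series(np.zeros(n, dtype=int), index=index, name="module")
    labels = _static_cut(tom, min_module_size, cut_fraction)
    if data is not None and (labels != UNASSIGNED).any():
        labels = _merge_modules(labels, data, merge_cut_height)
    # renumber by size
    sizes = pd.Series(labels[labels != UNASSIGNED]).value_counts()
    mapping = {old: new for new, old in enumerate(sizes.index, start=1)}
    relabelled = np.array([mapping.get(lab, UNASSIGNED) for lab in labels])
    return pd.Series(relabelled, index=index, name="module")


def build_network(
    beta_adjusted: pd.DataFrame,
    soft_power: float = 7,
    min_module_size: int = 100,
    merge_cut_height: float = 0.1,
    max_block_size: int = 15_000,
    cut_fraction: float = 0.995,
    random_state: int = 0,
) -> tuple[pd.Series, pd.DataFrame]:
    """Full network stage: bicor -> signed adjacency -> TOM -> modules.

    Above ``max_block_size`` probes, the probes are first split into
    blocks by k-means on a principal-component embedding and modules are
    detected per block, then merged across blocks by eigengene
    correlation. Probe order does not affect the result (probes are
    canonically sorted first).
    """
    data = beta_adjusted.sort_index(kind="stable")
    n = data.shape[0]
    if n <= max_block_size:
        blocks = [data.index]
    else:
        x = data.to_numpy(dtype=float)
        x = (x - x.mean(axis=1, keepdims=True))
        n_blocks = int(np.ceil(n / max_block_size))
        # embed probes by their leading principal-component loadings
        _, _, vt = np.linalg.svd(x, full_matrices=False)
        embed = x @ vt[: min(10, vt.shape[0])].T
        km = KMeans(n_clusters=n_blocks, n_init=5, random_state=random_state).fit(embed)
        blocks = [data.index[km.labels_ == b] for b in range(n_blocks)]
        logger.info("split %d probes into %d blocks", n, n_blocks)

    labels = pd.Series(UNASSIGNED, index=data.index, name="module", dtype=int)
    offset = 0
    for block in blocks:
        sub = data.loc[block]
        tom = topological_overlap(signed_adjacency(bicor_matrix(sub), soft_power))
        mod = detect_modules(
            tom,
            data=sub,
            min_module_size=min_module_size,
            merge_cut_height=merge_cut_height,
            cut_fraction=cut_fraction,
        )
        named = mod != UNASSIGNED
        labels.loc[block[named.to_numpy()]] = mod[named] + offset
        offset += int(mod.max())
    if len(blocks) > 1 and labels.max() > 1:
        labels[:] = _merge_modules(labels.to_numpy(), data, merge_cut_height)
        sizes = labels[labels != UNASSIGNED].value_counts()
        mapping = {old: new for new, old in enumerate(sizes.index, start=1)}
        labels[:] = [mapping.get(lab, UNASSIGNED) for lab in labels]

    eigs = {}
    for m in sorted(set(labels) - {UNASSIGNED}):
        eigs[f"M{m}"] = module_eigengene(data, labels.index[labels == m])
    eigengenes = pd.DataFrame(eigs, index=data.columns)
    return labels, eigengenes


# ---------------------------------------------------------------------------
# module-trait association
# ---------------------------------------------------------------------------

def module_trait_association(
    eigengenes: pd.DataFrame,
    phenotypes: pd.DataFrame,
    contrasts: tuple[tuple[str, str], ...] = (("iASD", "CTL"), ("dup15q", "CTL"), ("ASD", "CTL")),
    covariates: tuple[str, ...] = ("age", "sex", "region", "bank", "cets"),
    fdr_alpha: float = 0.05,
) -> pd.DataFrame:
    """Donor-random-intercept model of each eigengene on diagnosis.

    For every module and contrast a mixed model with the given fixed
    effects and a donor random intercept is fit on the samples of the two
    groups; p-values are Benjamini-Hochberg corrected across modules
    within each contrast.
    """
    if eigengenes.shape[1] == 0:
        return pd.DataFrame(columns=["module", "contrast", "effect", "se", "p_value", "fdr", "significant"])
    # eigengenes as a modules x samples "beta" matrix
    mat = eigengenes.T
    rows = []
    for case, control in contrasts:
        res = fit_lme(
            mat,
            phenotypes,
            case=case,
            control=control,
            regions=tuple(pd.unique(phenotypes.loc[mat.columns, "region"])),
            covariates=covariates,
        )
        pvals = res["p_value"].to_numpy()
        ok = ~np.isnan(pvals)
        fdr = np.full_like(pvals, np.nan)
        if ok.any():
            fdr[ok] = multipletests(pvals[ok], method="fdr_bh")[1]
        for module, (_, r), q in zip(res.index, res.iterrows(), fdr):
            rows.append(
                {
                    "module": module,
                    "contrast": f"{case}_vs_{control}",
                    "effect": r["effect"],
                    "se": r["se"],
                    "p_value": r["p_value"],
                    "fdr": q,
                    "significant": bool(q < fdr_alpha) if np.isfinite(q) else False,
                }
            )
    return pd.DataFrame(rows)
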