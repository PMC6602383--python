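"""Gene-ontology enrichment controlled for per-gene probe coverage.

Genes with many array probes are more likely to contain a significant
probe by chance, so a hypergeometric/Fisher test over genes is biased.
Instead, pathway membership is modelled by logistic regression over the
gene universe: ``in_pathway ~ intercept + in_test_list + log(probes+1)``;
the Wald test of the test-list coefficient measures enrichment with the
probe-count bias absorbed by the covariate. Pathways are filtered to
10-2000 genes (after intersecting with the universe), and the list of
significant pathways is refined by grouping: the most significant
pathway becomes a group head, every remaining significant pathway is
retested with head membership as an extra covariate, and pathways whose
test-list coefficient loses significance are assigned to the head's
group. The input GMT is assumed to have parent ontology terms already
propagated.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .ioformats import FormatError

logger = logging.getLogger(__name__)

__all__ = [
    "annotate_probes",
    "build_universe",
    "pathway_logistic_test",
    "run_enrichment",
    "group_pathways",
]

DEFAULT_SIZE_RANGE = (10, 2000)
TSS_WINDOW = 1500


def _probe_gene_pairs(manifest: pd.DataFrame, tss_window: int = TSS_WINDOW):
    """Yield (probe, gene) for annotations passing the TSS-window rule.

    ``tss_distance`` is signed (negative = upstream of the TSS): a gene
    counts when the probe overlaps it (non-negative distance) or lies at
    most ``tss_window`` bp upstream.
    """
    for probe, genes, tss in zip(manifest.index, manifest["genes"], manifest["tss_distance"]):
        gene_list = [g for g in str(genes).split(";") if g]
        if not gene_list:
            continue
        tss_list = [t for t in str(tss).split(";") if t]
        for k, gene in enumerate(gene_list):
            d = float(tss_list[k]) if k < len(tss_list) else 0.0
            if d >= -tss_window:
                yield probe, gene


def annotate_probes(
    probes: list[str] | pd.Index, manifest: pd.DataFrame, tss_window: int = TSS_WINDOW
) -> list[str]:
    """Genes annotated to a probe set; intergenic probes contribute nothing,
    multi-gene probes contribute every gene; duplicates collapse."""
    wanted = set(probes)
    sub = manifest.loc[manifest.index.isin(wanted)]
    return sorted({g for _, g in _probe_gene_pairs(sub, tss_window)})


def build_universe(
    manifest: pd.DataFrame,
    pathway_db: dict[str, tuple[str, frozenset[str]]],
    test_genes: list[str] | set[str],
    tss_window: int = TSS_WINDOW,
) -> pd.DataFrame:
    """The gene universe for the logistic test.

    A gene enters the universe when it has at least one (QC-passing)
    probe annotated and belongs to at least one pathway. Columns:
    ``n_probes`` (probes annotated to the gene) and ``in_test``.
    """
    counts: dict[str, int] = {}
    for _, gene in _probe_gene_pairs(manifest, tss_window):
        counts[gene] = counts.get(gene, 0) + 1
    pathway_genes = set().union(*(genes for _, genes in pathway_db.values())) if pathway_db else set()
    genes = sorted(set(counts) & pathway_genes)
    test = set(test_genes)
    return pd.DataFrame(
        {
            "n_probes": [counts[g] for g in genes],
            "in_test": [g in test for g in genes],
        },
        index=pd.Index(genes, name="gene"),
    )


def _firth_logit(y: np.ndarray, x: np.ndarray, max_iter: int = 50, tol: float = 1e-8):
    """Firth-penalised logistic regression (Jeffreys-prior score correction).

    Used as a fallback when plain maximum likelihood separates or fails;
    returns (coefficients, standard errors).
    """
    n, p = x.shape
    beta = np.zeros(p)
    for _ in range(max_iter):
        eta = np.clip(x @ beta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        xtw = x.T * w
        info = xtw @ x
        info_inv = np.linalg.pinv(info)
        # hat diagonal of W^1/2 X (X'WX)^-1 X' W^1/2
        h = np.einsum("ij,jk,ik->i", x * np.sqrt(w)[:, None], info_inv, x * np.sqrt(w)[:, None])
        score = x.T @ (y - mu + h * (0.5 - mu))
        step = info_inv @ score
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    eta = np.clip(x @ beta, -30, 30)
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = mu * (1.0 - mu)
    info_inv = np.linalg.pinv((x.T * w) @ x)
    return beta, np.sqrt(np.clip(np.diag(info_inv), 0.0, None))


def _logistic_wald(y: np.ndarray, x: np.ndarray, coef_index: int) -> tuple[float, float, float, str]:
    """(coefficient, se, two-sided Wald p, method) for one design column."""
    method = "ml"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.Logit(y, x).fit(disp=0, maxiter=200)
            coef, se = fit.params, fit.bse
            if not np.all(np.isfinite(se)) or np.max(np.abs(coef)) > 15:
                raise np.linalg.LinAlgError("unstable fit")
        except Exception:
            coef, se = _firth_logit(y, x)
            method = "firth"
    c, s = float(coef[coef_index]), float(se[coef_index])
    if s == 0 or not np.isfinite(s):
        return c, s, np.nan, method
    p = float(2.0 * stats.norm.sf(abs(c / s)))
    return c, s, p, method


def pathway_logistic_test(
    universe: pd.DataFrame,
    pathway_genes: frozenset[str] | set[str],
    size_range: tuple[int, int] = DEFAULT_SIZE_RANGE,
    log_counts: bool = True,
    extra_covariate: pd.Series | None = None,
) -> dict:
    """Probe-bias-controlled enrichment test of one pathway.

    Returns a dict with the pathway size (within the universe), the
    test-list coefficient, its standard error and two-sided Wald p, or a
    ``skipped`` reason when the size falls outside ``size_range``.
    ``extra_covariate`` (a 0/1 series over universe genes) supports the
    grouping procedure's conditional retests.
    """
    if not universe["in_test"].any():
        raise FormatError("the test gene list is empty within the universe")
    member = universe.index.isin(pathway_genes)
    size = int(member.sum())
    lo, hi = size_range
    if size < lo or size > hi:
        return {"size": size, "coef": np.nan, "se": np.nan, "p_value": np.nan,
                "skipped": f"size {size} outside [{lo}, {hi}]", "method": ""}
    counts = universe["n_probes"].to_numpy(dtype=float)
    count_col = np.log(counts + 1.0) if log_counts else counts
    cols = [np.ones(len(universe)), universe["in_test"].to_numpy(dtype=float), count_col]
    if extra_covariate is not None:
        cols.append(extra_covariate.reindex(universe.index).to_numpy(dtype=float))
    x = np.column_stack(cols)
    coef, se, p, method = _logistic_wald(member.astype(float), x, coef_index=1)
    return {"size": size, "coef": coef, "se": se, "p_value": p, "skipped": "", "method": method}


def run_enrichment(
    universe: pd.DataFrame,
    pathway_db: dict[str, tuple[str, frozenset[str]]],
    size_range: tuple[int, int] = DEFAULT_SIZE_RANGE,
    log_counts: bool = True,
) -> pd.DataFrame:
    """Test every pathway; deterministic order (sorted by pathway id)."""
    rows = []
    for pid in sorted(pathway_db):
        desc, genes = pathway_db[pid]
        res = pathway_logistic_test(universe, genes, size_range=size_range, log_counts=log_counts)
        rows.append({"pathway_id": pid, "description": desc, **res})
    return pd.DataFrame(rows).set_index("pathway_id")


def group_pathways(
    results: pd.DataFrame,
    universe: pd.DataFrame,
    pathway_db: dict[str, tuple[str, frozenset[str]]],
    alpha: float = 0.05,
    size_range: tuple[int, int] = DEFAULT_SIZE_RANGE,
    log_counts: bool = True,
) -> pd.DataFrame:
    """Group overlapping significant pathways under their best exemplar.

    Iteratively pops the most significant remaining pathway as a group
    head (p ties broken by pathway id) and retests every other remaining
    significant pathway with head membership as an extra covariate; a
    pathway whose test-list coefficient is no longer significant
    (p > ``alpha``) joins the head's group. Terminates in at most as many
    iterations as there are significant pathways; every pathway ends as
    a head or a group member.
    """
    sig = results[(results["p_value"] < alpha) & (results["skipped"] == "")].copy()
    # stable sort: p-value ascending, ties broken by pathway id
    sig = sig.sort_index(kind="stable").sort_values("p_value", kind="stable")
    remaining = list(sig.index)
    parent: dict[str, str] = {}
    order: list[str] = []
    while remaining:
        head = remaining.pop(0)
        parent[head] = head
        order.append(head)
        head_member = pd.Series(universe.index.isin(pathway_db[head][1]).astype(float), index=universe.index)
        still = []
        for pid in remaining:
            res = pathway_logistic_test(
                universe,
                pathway_db[pid][1],
                size_range=size_range,
                log_counts=log_counts,
                extra_covariate=head_member,
            )
            if not np.isfinite(res["p_value"]) or res["p_value"] > alpha:
                parent[pid] = head
            else:
                still.append(pid)
        remaining = still
    out = sig.copy()
    out["group_parent"] = [parent[p] for p in out.index]
    out["is_head"] = out.index == out["group_parent"]
    head_rank = {h: i for i, h in enumerate(order)}
    out["head_order"] = [head_rank[parent[p]] for p in out.index]
    return out.sort_values(["head_order", "p_value"], kind="stable").drop(columns="head_order")
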