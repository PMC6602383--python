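"""Spatially correlated DMR calling (comb-p style).

Nearby CpG probes have correlated methylation, so their association
p-values are correlated too. The procedure (i) estimates the
autocorrelation of p-value z-scores as a function of genomic distance,
(ii) sharpens each probe's p-value by a Stouffer-Liptak combination with
its neighbours within a maximum distance using that autocorrelation,
(iii) grows candidate regions from seed probes, (iv) scores each region
by a Stouffer-Liptak combination of its raw p-values with the
distance-derived correlation matrix, and (v) applies a Sidak correction
for the number of region-sized windows in the tested territory.

P-values are converted one-sidedly (z = Phi^-1(1 - p)), the comb-p
convention. A region whose probes all carry small p-values in opposite
effect directions therefore still combines — region calling is about
spatial clustering of significance, not sign.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .ioformats import FormatError

__all__ = [
    "AcfModel",
    "estimate_acf",
    "slk_adjust",
    "find_regions",
    "region_p",
    "sidak_correct",
    "call_dmrs",
]

_P_FLOOR = 1e-300
_P_CEIL = 1.0 - 1e-16


@dataclass(frozen=True)
class AcfModel:
    """Correlation of p-value z-scores per genomic distance bin.

    ``edges[i] < lag <= edges[i+1]`` maps to ``corr[i]``; lag 0 is 1 by
    definition. Lags beyond the last edge use the last bin's value.
    """

    edges: np.ndarray  # length n_bins + 1, starting at 0
    corr: np.ndarray  # length n_bins

    def __post_init__(self) -> None:
        if np.any(np.abs(self.corr) > 1.0):
            raise FormatError("ACF correlations must lie in [-1, 1]")

    def rho(self, dist: np.ndarray) -> np.ndarray:
        """Correlation for each (non-negative) pairwise distance."""
        dist = np.asarray(dist)
        if len(self.corr) == 0:
            return np.where(dist == 0, 1.0, 0.0)
        idx = np.clip(np.searchsorted(self.edges, dist, side="left") - 1, 0, len(self.corr) - 1)
        return np.where(dist == 0, 1.0, self.corr[idx])

    def rho_matrix(self, positions: np.ndarray) -> np.ndarray:
        pos = np.asarray(positions, dtype=np.int64)
        return self.rho(np.abs(pos[:, None] - pos[None, :]))

    @staticmethod
    def identity() -> "AcfModel":
        return AcfModel(edges=np.array([0.0]), corr=np.array([]))


def _zscores(p: np.ndarray) -> np.ndarray:
    return stats.norm.isf(np.clip(p, _P_FLOOR, _P_CEIL))


def _chrom_arrays(
    p_values: pd.Series, manifest: pd.DataFrame
) -> list[tuple[str, np.ndarray, np.ndarray, pd.Index]]:
    """(chrom, positions, z, probe index) per chromosome, position-sorted."""
    man = manifest.loc[p_values.index, ["chrom", "pos"]].copy()
    man["p"] = p_values
    man = man.dropna(subset=["p"]).sort_values(["chrom", "pos"], kind="stable")
    out = []
    for chrom, sub in man.groupby("chrom", sort=False):
        out.append(
            (str(chrom), sub["pos"].to_numpy(np.int64), _zscores(sub["p"].to_numpy(float)), sub.index)
        )
    return out


def estimate_acf(
    p_values: pd.Series,
    manifest: pd.DataFrame,
    max_lag: int = 300,
    bin_width: int = 50,
) -> AcfModel:
    """Estimate the distance-binned autocorrelation of p-value z-scores.

    For each distance bin the Pearson correlation is computed over all
    within-chromosome probe pairs whose separation falls in the bin;
    bins with fewer than 2 pairs inherit the nearest smaller-lag value
    (starting from 1 at lag 0). The ACF is estimated from the same
    p-value set being corrected, as comb-p does.
    """
    chrom_data = _chrom_arrays(p_values, manifest)
    if all(len(pos) < 2 for _, pos, _, _ in chrom_data):
        raise FormatError("ACF estimation needs >= 2 probes on some chromosome")
    n_bins = int(np.ceil(max_lag / bin_width))
    edges = np.arange(n_bins + 1, dtype=float) * bin_width
    edges[-1] = max_lag
    pairs_a: list[np.ndarray] = [[] for _ in range(n_bins)]
    pairs_b: list[np.ndarray] = [[] for _ in range(n_bins)]
    for _, pos, z, _ in chrom_data:
        hi = np.searchsorted(pos, pos + max_lag, side="right")
        for i in range(len(pos)):
            js = np.arange(i + 1, hi[i])
            if len(js) == 0:
                continue
            d = pos[js] - pos[i]
            bins = np.clip(np.searchsorted(edges, d, side="left") - 1, 0, n_bins - 1)
            for b in range(n_bins):
                sel = bins == b
                if sel.any():
                    pairs_a[b].append(np.full(sel.sum(), z[i]))
                    pairs_b[b].append(z[js[sel]])
    corr = np.empty(n_bins)
    prev = 1.0
    for b in range(n_bins):
        if pairs_a[b]:
            a = np.concatenate(pairs_a[b])
            c = np.concatenate(pairs_b[b])
        else:
            a = c = np.empty(0)
        if len(a) >= 2 and a.std() > 0 and c.std() > 0:
            prev = float(np.corrcoef(a, c)[0, 1])
        corr[b] = prev
    return AcfModel(edges=edges, corr=corr)


def _stouffer_liptak(z: np.ndarray, sigma: np.ndarray, repair: bool = True) -> float:
    """One-sided combined p of correlated z-scores with unit weights."""
    var = float(sigma.sum())
    if repair:
        w, v = np.linalg.eigh(sigma)
        if w.min() < 1e-8:  # nearest-PD repair: floor the eigenvalues
            w = np.clip(w, 1e-8, None)
            ones = np.ones(len(z))
            var = float(((v.T @ ones) ** 2 * w).sum())
    var = max(var, 1e-8)
    z_comb = float(z.sum()) / np.sqrt(var)
    return float(stats.norm.sf(z_comb))


def slk_adjust(
    p_values: pd.Series,
    manifest: pd.DataFrame,
    acf: AcfModel,
    max_lag: int = 300,
) -> pd.Series:
    """Stouffer-Liptak smoothing: each probe's p combined with neighbours.

    A probe with no neighbour within ``max_lag`` bp keeps its original p.
    """
    out = pd.Series(np.nan, index=p_values.index, dtype=float)
    for _, pos, z, idx in _chrom_arrays(p_values, manifest):
        lo = np.searchsorted(pos, pos - max_lag, side="left")
        hi = np.searchsorted(pos, pos + max_lag, side="right")
        vals = np.empty(len(pos))
        for i in range(len(pos)):
            window = slice(lo[i], hi[i])
            if hi[i] - lo[i] == 1:
                vals[i] = float(p_values.loc[idx[i]])
                continue
            sigma = acf.rho_matrix(pos[window])
            vals[i] = _stouffer_liptak(z[window], sigma, repair=False)
        out.loc[idx] = vals
    return out


def find_regions(
    adjusted_p: pd.Series,
    manifest: pd.DataFrame,
    seed_p: float = 1e-3,
    max_dist: int = 300,
    min_probes: int = 2,
) -> pd.DataFrame:
    """Grow candidate regions from seed probes.

    Seeds are probes with adjusted p below ``seed_p``; consecutive seeds
    whose gap is at most ``max_dist`` bp (inclusive boundary) join one
    region; regions with fewer than ``min_probes`` probes are discarded.
    """
    rows = []
    man = manifest.loc[adjusted_p.index]
    seeds = adjusted_p[adjusted_p < seed_p]
    sub = man.loc[seeds.index].sort_values(["chrom", "pos"], kind="stable")
    for chrom, grp in sub.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy(np.int64)
        breaks = np.flatnonzero(np.diff(pos) > max_dist)
        starts = np.concatenate([[0], breaks + 1])
        ends = np.concatenate([breaks, [len(pos) - 1]])
        for s, e in zip(starts, ends):
            if e - s + 1 < min_probes:
                continue
            probes = grp.index[s : e + 1]
            rows.append(
                {
                    "chrom": str(chrom),
                    "start": int(pos[s]),
                    "end": int(pos[e]),
                    "n_probes": int(e - s + 1),
                    "probe_ids": ";".join(probes),
                }
            )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "n_probes", "probe_ids"])


def region_p(
    probe_p: pd.Series,
    positions: pd.Series | np.ndarray,
    acf: AcfModel,
) -> float:
    """Stouffer-Liptak combination of a region's raw p-values.

    The correlation matrix comes from the ACF at the pairwise probe
    distances; if it is not positive definite its eigenvalues are floored
    at 1e-8 before the combined variance is computed. A single-probe
    region returns its raw p.
    """
    p = np.asarray(probe_p, dtype=float)
    if len(p) == 1:
        return float(p[0])
    z = _zscores(p)
    sigma = acf.rho_matrix(np.asarray(positions))
    return _stouffer_liptak(z, sigma, repair=True)


def sidak_correct(p: float, region_len_bp: float, territory_bp: float) -> float:
    """Sidak multiplicity correction over territory/region-length windows.

    Computed in log space (``1 - (1-p)^k = -expm1(k log1p(-p))``) so tiny
    region p-values survive; monotone increasing in both ``p`` and the
    territory-to-length ratio.
    """
    if not 0.0 <= p <= 1.0:
        raise FormatError("region p must lie in [0, 1]")
    if region_len_bp <= 0 or territory_bp <= 0:
        raise FormatError("lengths must be positive")
    k = max(territory_bp / region_len_bp, 1.0)
    if p == 0.0:
        return 0.0
    if p >= 1.0:
        return 1.0
    return float(-np.expm1(k * np.log1p(-p)))


def call_dmrs(
    p_values: pd.Series,
    manifest: pd.DataFrame,
    seed_p: float = 1e-3,
    max_dist: int = 300,
    min_probes: int = 2,
    sidak_alpha: float = 0.05,
    max_lag: int = 300,
    bin_width: int = 50,
) -> pd.DataFrame:
    """Full DMR pipeline: ACF -> smoothing -> regions -> region p -> Sidak.

    The Sidak territory is the total bp spanned by tested probes plus
    ``max_dist`` on each flank, summed over chromosomes; region length is
    ``end - start + 1`` floored at the median inter-probe spacing so a
    single-position region cannot have zero length.
    """
    acf = estimate_acf(p_values, manifest, max_lag=max_lag, bin_width=bin_width)
    adjusted = slk_adjust(p_values, manifest, acf, max_lag=max_lag)
    regions = find_regions(adjusted, manifest, seed_p=seed_p, max_dist=max_dist, min_probes=min_probes)

    man = manifest.loc[p_values.index]
    territory = 0.0
    spacings = []
    for _, grp in man.groupby("chrom", sort=False):
        pos = np.sort(grp["pos"].to_numpy(np.int64))
        territory += float(pos[-1] - pos[0] + 1 + 2 * max_dist)
        if len(pos) > 1:
            spacings.append(np.diff(pos))
    spacing_floor = float(np.median(np.concatenate(spacings))) if spacings else 1.0

    reg_p, sid_p = [], []
    for row in regions.itertuples(index=False):
        probes = row.probe_ids.split(";")
        rp = region_p(p_values.loc[probes], man.loc[probes, "pos"], acf)
        length = max(float(row.end - row.start + 1), spacing_floor)
        reg_p.append(rp)
        sid_p.append(sidak_correct(rp, length, territory))
    regions["region_p"] = reg_p
    regions["sidak_p"] = sid_p
    regions["significant"] = regions["sidak_p"] < sidak_alpha
    return regions
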