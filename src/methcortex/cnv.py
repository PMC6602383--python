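"""Copy-number detection from total array intensity.

On a methylation array the methylated plus unmethylated intensity at a
probe scales with local DNA copy number. For each test sample, the
quantile-normalised total intensity is compared against the median of a
control panel to give per-probe log2 ratios (a 3-copy gain sits near
log2(3/2) ~ 0.585); per-chromosome recursive binary segmentation finds
breakpoints, and segments above a gain threshold overlapping the
configured 15q11-13 interval call a sample duplication-positive.

The segmentation is a bespoke variance-reduction binary splitter (the
classic circular-binary-segmentation idea without the permutation test):
a split is accepted when it reduces the residual sum of squares by more
than ``penalty`` times the noise variance, with the noise level
estimated robustly from the median absolute deviation of first
differences.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ioformats import FormatError
from .preprocess import _quantile_normalize

logger = logging.getLogger(__name__)

__all__ = [
    "CnvSegment",
    "intensity_log2_ratio",
    "segment_ratios",
    "call_duplication",
    "dup15q_status",
    "DEFAULT_DUP15Q_LOCUS",
]

DEFAULT_DUP15Q_LOCUS = ("chr15", 23_000_000, 28_500_000)


@dataclass(frozen=True)
class CnvSegment:
    chrom: str
    start_probe: int  # index into the chromosome's sorted probes
    end_probe: int  # inclusive
    start_bp: int
    end_bp: int
    mean_log2_ratio: float
    n_probes: int
    call: str  # neutral / gain / loss


def intensity_log2_ratio(
    M: pd.DataFrame,
    U: pd.DataFrame,
    sample: str,
    controls: list[str],
) -> pd.Series:
    """Per-probe log2 ratio of a sample's total intensity vs control median.

    Total intensities (M + U) are quantile-normalised across all involved
    samples first, removing array-wide brightness differences; the ratio
    is then median-centred so a genome-wide scaling cannot mimic a gain.
    Probes whose control median is zero are masked (NaN).
    """
    if sample in controls:
        raise FormatError("the test sample cannot be part of its control set")
    cols = [sample] + list(controls)
    total = (M[cols].to_numpy(dtype=float) + U[cols].to_numpy(dtype=float))
    total = _quantile_normalize(total)
    test = total[:, 0]
    ctl_median = np.median(total[:, 1:], axis=1)
    ratio = np.full(len(test), np.nan)
    ok = ctl_median > 0
    with np.errstate(divide="ignore"):
        ratio[ok] = np.log2(test[ok] / ctl_median[ok])
    ratio[np.isinf(ratio)] = np.nan
    center = np.nanmedian(ratio)
    return pd.Series(ratio - center, index=M.index, name=sample)


def _mad_sigma(x: np.ndarray) -> float:
    """Robust noise SD from the MAD of first differences."""
    if len(x) < 3:
        return float(np.std(x)) or 1.0
    d = np.diff(x)
    mad = np.median(np.abs(d - np.median(d)))
    sigma = 1.4826 * mad / np.sqrt(2.0)
    return float(sigma) if sigma > 0 else (float(np.std(x)) or 1.0)


def _best_split(x: np.ndarray, min_seg: int) -> tuple[int | None, float]:
    """Split index maximising the reduction in residual sum of squares."""
    n = len(x)
    if n < 2 * min_seg:
        return None, 0.0
    csum = np.cumsum(x)
    total = csum[-1]
    k = np.arange(min_seg, n - min_seg + 1)  # left segment sizes
    left = csum[k - 1]
    right = total - left
    # RSS reduction of splitting at k: grand-mean SS minus two-segment SS
    gain = left**2 / k + right**2 / (n - k) - total**2 / n
    i = int(np.argmax(gain))
    return int(k[i]), float(gain[i])


def segment_ratios(
    log2_ratios: pd.Series,
    manifest: pd.DataFrame,
    min_seg: int = 10,
    penalty: float = 30.0,
) -> list[CnvSegment]:
    """Recursive binary segmentation of per-probe log2 ratios.

    Within each chromosome (probes position-sorted, NaNs dropped) the
    best split is accepted when its RSS reduction exceeds
    ``penalty * sigma^2`` and both sides keep at least ``min_seg``
    probes. Deterministic, and invariant to adding a constant to all
    ratios.
    """
    man = manifest.loc[log2_ratios.index]
    segments: list[CnvSegment] = []
    for chrom, grp in man.groupby("chrom", sort=False):
        sub = grp.sort_values("pos", kind="stable")
        vals = log2_ratios.loc[sub.index].to_numpy(dtype=float)
        ok = ~np.isnan(vals)
        vals = vals[ok]
        pos = sub["pos"].to_numpy(np.int64)[ok]
        if len(vals) == 0:
            continue
        sigma2 = _mad_sigma(vals) ** 2
        bounds: list[tuple[int, int]] = []

        def recurse(lo: int, hi: int) -> None:  # [lo, hi)
            split, gain = _best_split(vals[lo:hi], min_seg)
            if split is None or gain <= penalty * sigma2:
                bounds.append((lo, hi))
                return
            recurse(lo, lo + split)
            recurse(lo + split, hi)

        recurse(0, len(vals))
        for lo, hi in sorted(bounds):
            segments.append(
                CnvSegment(
                    chrom=str(chrom),
                    start_probe=lo,
                    end_probe=hi - 1,
                    start_bp=int(pos[lo]),
                    end_bp=int(pos[hi - 1]),
                    mean_log2_ratio=float(vals[lo:hi].mean()),
                    n_probes=hi - lo,
                    call="neutral",
                )
            )
    return segments


def call_duplication(
    segments: list[CnvSegment],
    gain_threshold: float = 0.3,
    loss_threshold: float = -0.3,
    min_probes: int = 20,
) -> list[CnvSegment]:
    """Label segments as gain/loss when their mean ratio passes the
    threshold with at least ``min_probes`` supporting probes."""
    out = []
    for seg in segments:
        call = "neutral"
        if seg.n_probes >= min_probes:
            if seg.mean_log2_ratio > gain_threshold:
                call = "gain"
            elif seg.mean_log2_ratio < loss_threshold:
                call = "loss"
        out.append(CnvSegment(**{**seg.__dict__, "call": call}))
    return out


def dup15q_status(
    segments: list[CnvSegment],
    locus: tuple[str, int, int] = DEFAULT_DUP15Q_LOCUS,
) -> bool:
    """True when a gain segment overlaps the 15q11-13 interval."""
    chrom, start, end = locus
    for seg in segments:
        if seg.call == "gain" and seg.chrom == chrom and seg.start_bp <= end and seg.end_bp >= start:
            return True
    return False


def segments_to_frame(segments: list[CnvSegment]) -> pd.DataFrame:
    return pd.DataFrame([s.__dict__ for s in segments])
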