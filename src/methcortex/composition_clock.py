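"""Cellular composition estimates and epigenetic-clock age analysis.

Bulk brain methylation is a mixture of neuronal and glial profiles, and
neuron/glia ratios differ between donors and regions; a two-component
least-squares deconvolution against reference profiles (the CETS-style
approach) estimates each sample's neuronal proportion so it can enter
the association models as a covariate. The estimate is not applied to
cerebellum, where most neurons are NeuN-negative and the cortical
reference does not transfer.

DNA-methylation age applies a linear clock (intercept + per-CpG
weights) followed by the standard inverse log-linear age transform; age
acceleration is the residual of methylation age regressed on
chronological age, compared between diagnostic groups with a t-test.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .ioformats import CellReference, ClockModel, FormatError

logger = logging.getLogger(__name__)

__all__ = [
    "estimate_neuronal_proportion",
    "estimate_neuronal_proportions",
    "dnam_age",
    "age_transform_inverse",
    "age_acceleration_test",
]

NO_DECONVOLUTION_REGIONS = ("CB",)


def estimate_neuronal_proportion(beta_sample: pd.Series, reference: CellReference) -> float:
    """Least-squares neuronal proportion of one bulk sample.

    Solves ``argmin_p sum_i (x_i - p n_i - (1-p) g_i)^2`` in closed form
    (the projection of ``x - g`` onto ``n - g``), clipped to [0, 1].
    Markers missing from the sample are dropped; at least 10 must remain.
    """
    x = beta_sample.reindex(reference.markers)
    ok = x.notna().to_numpy()
    if not ok.any():
        raise FormatError("all reference marker probes are missing from the sample")
    if ok.sum() < 10:
        raise FormatError(f"only {int(ok.sum())} marker probes present; need >= 10")
    xv = x.to_numpy(dtype=float)[ok]
    n = reference.neuron.to_numpy(dtype=float)[ok]
    g = reference.glia.to_numpy(dtype=float)[ok]
    d = n - g
    denom = float(d @ d)
    if denom == 0.0:
        raise FormatError("neuron and glia reference profiles are identical")
    p = float((xv - g) @ d / denom)
    return float(np.clip(p, 0.0, 1.0))


def estimate_neuronal_proportions(
    beta: pd.DataFrame,
    reference: CellReference,
    phenotypes: pd.DataFrame | None = None,
    skip_regions: tuple[str, ...] = NO_DECONVOLUTION_REGIONS,
) -> pd.Series:
    """Per-sample neuronal proportions; NaN for regions in ``skip_regions``."""
    out = pd.Series(np.nan, index=beta.columns, dtype=float, name="neuronal_proportion")
    for sample in beta.columns:
        if phenotypes is not None and phenotypes.loc[sample, "region"] in skip_regions:
            continue
        out[sample] = estimate_neuronal_proportion(beta[sample], reference)
    return out


def age_transform_inverse(raw: np.ndarray | float, adult_age: float = 20.0) -> np.ndarray | float:
    """Invert the log-linear age transform used to train clocks.

    ``raw < 0`` maps to ``(1 + adult) * exp(raw) - 1`` (childhood branch),
    otherwise to ``adult + raw * (1 + adult)``. Continuous and strictly
    increasing in ``raw``; the fixed point raw = 0 maps to ``adult_age``.
    """
    raw_arr = np.asarray(raw, dtype=float)
    out = np.where(
        raw_arr < 0,
        (1.0 + adult_age) * np.exp(raw_arr) - 1.0,
        adult_age + raw_arr * (1.0 + adult_age),
    )
    return float(out) if np.isscalar(raw) else out


def dnam_age(
    beta: pd.DataFrame | pd.Series, clock: ClockModel, max_missing_frac: float = 0.2
) -> pd.Series | float:
    """DNA-methylation age of each sample under a linear clock.

    Missing clock CpGs are mean-imputed from the cohort when at most
    ``max_missing_frac`` of them are absent; above that the clock is not
    applied and an error is raised.
    """
    single = isinstance(beta, pd.Series)
    mat = beta.to_frame() if single else beta
    cpgs = clock.coefficients.index
    sub = mat.reindex(cpgs)
    missing_rows = sub.isna().all(axis=1)
    frac_missing = float(missing_rows.mean())
    if frac_missing > max_missing_frac:
        raise FormatError(
            f"{frac_missing:.0%} of clock CpGs missing (> {max_missing_frac:.0%})"
        )
    if sub.isna().to_numpy().any():
        logger.warning("mean-imputing missing clock CpG values from the cohort")
        row_means = sub.mean(axis=1)
        row_means = row_means.fillna(clock.coefficients * 0 + 0.5)
        sub = sub.apply(lambda col: col.fillna(row_means))
    raw = clock.intercept + clock.coefficients.to_numpy() @ sub.to_numpy(dtype=float)
    ages = age_transform_inverse(raw, clock.adult_age)
    if single:
        return float(ages[0])
    return pd.Series(ages, index=mat.columns, name="dnam_age")


def age_acceleration_test(
    dnam_ages: pd.Series,
    phenotypes: pd.DataFrame,
    group_a: str,
    group_b: str = "CTL",
) -> pd.DataFrame:
    """Per-region clock calibration and group comparison of age acceleration.

    For each brain region: the Pearson correlation between methylation
    age and chronological age; age acceleration as the residual of an
    OLS of methylation age on chronological age (fit on all samples in
    the region); and a two-sided t-test of those residuals between the
    two diagnostic groups. When the residuals are identically zero the
    p-value is 1 by convention.
    """
    ph = phenotypes.loc[dnam_ages.index]
    rows = []
    for region, sub in ph.groupby("region", sort=False):
        y = dnam_ages.loc[sub.index].to_numpy(dtype=float)
        x = sub["age"].to_numpy(dtype=float)
        if len(x) < 3 or np.std(x) == 0:
            raise FormatError(f"region {region!r} has too few samples for the clock test")
        r = float(np.corrcoef(x, y)[0, 1]) if np.std(y) > 0 else np.nan
        slope, intercept = np.polyfit(x, y, 1)
        resid = y - (intercept + slope * x)
        a_mask = (sub["diagnosis"] == group_a).to_numpy()
        b_mask = (sub["diagnosis"] == group_b).to_numpy()
        if not a_mask.any() or not b_mask.any():
            raise FormatError(
                f"region {region!r} lacks samples in {group_a!r} or {group_b!r}"
            )
        ra, rb = resid[a_mask], resid[b_mask]
        shift = float(ra.mean() - rb.mean())
        if np.allclose(resid, 0.0):
            p = 1.0
        else:
            p = float(stats.ttest_ind(ra, rb, equal_var=False).pvalue)
        rows.append(
            {
                "region": region,
                "r_age": r,
                "accel_shift": shift,
                "p_value": p,
                "n_a": int(a_mask.sum()),
                "n_b": int(b_mask.sum()),
            }
        )
    return pd.DataFrame(rows).set_index("region")
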