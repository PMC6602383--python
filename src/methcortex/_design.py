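"""Shared construction of numeric covariate designs from phenotype tables.

Coding conventions used throughout the package: sex enters as a single
binary indicator (M = 1), every other categorical covariate as a dummy
set with the first (lexicographically sorted) level as reference, and
numeric covariates unchanged.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .ioformats import FormatError

__all__ = ["build_design", "diagnosis_indicator"]

_NUMERIC = {"age", "neuronal_proportion", "cets"}


def build_design(
    pheno: pd.DataFrame,
    covariates: list[str],
    add_intercept: bool = False,
) -> pd.DataFrame:
    """Numeric design matrix for the requested phenotype columns.

    ``cets`` is accepted as an alias for ``neuronal_proportion``.
    """
    cols: dict[str, np.ndarray] = {}
    if add_intercept:
        cols["intercept"] = np.ones(len(pheno))
    for name in covariates:
        key = "neuronal_proportion" if name == "cets" else name
        if key not in pheno.columns:
            raise FormatError(f"phenotype table has no column {key!r}")
        col = pheno[key]
        if key in _NUMERIC or pd.api.types.is_numeric_dtype(col):
            cols[key] = col.to_numpy(dtype=float)
        elif key == "sex":
            cols["sex[M]"] = (col == "M").to_numpy(dtype=float)
        else:
            levels = sorted(pd.unique(col.astype(str)))
            for lev in levels[1:]:  # first level is the reference
                cols[f"{key}[{lev}]"] = (col.astype(str) == lev).to_numpy(dtype=float)
    return pd.DataFrame(cols, index=pheno.index)


def diagnosis_indicator(
    pheno: pd.DataFrame, case: str, control: str = "CTL"
) -> tuple[pd.Series, pd.Index]:
    """0/1 case indicator and the index of samples in either group.

    ``case`` may be a single diagnosis or ``"ASD"`` for the combined
    iASD + dup15q group.
    """
    dx = pheno["diagnosis"]
    case_labels = {"ASD": {"iASD", "dup15q"}}.get(case, {case})
    in_case = dx.isin(case_labels)
    in_ctl = dx == control
    used = pheno.index[in_case | in_ctl]
    if not in_case.any() or not in_ctl.any():
        raise FormatError(f"need samples in both {case!r} and {control!r} groups")
    return in_case.astype(float).loc[used], used
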