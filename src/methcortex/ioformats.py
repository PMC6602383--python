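"""Readers and writers for the tabular formats the pipeline consumes and emits.

Conventions
-----------
* Matrices (beta values, methylated/unmethylated intensities, detection
  p-values) are tab-separated with probes in rows and samples in columns;
  the first column holds the probe ID.
* The probe manifest, phenotype table, clock coefficients, cell-type
  reference and differential-expression table are CSV.
* Pathways use the GMT format (``pathway_id <tab> description <tab> gene...``).
* Genomic coordinates are 1-based inclusive internally (array-manifest
  convention); BED export converts to 0-based half-open.
* Missing beta values may be written as an empty cell or ``NA``.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "ClockModel",
    "CellReference",
    "MANIFEST_COLUMNS",
    "read_beta",
    "write_beta",
    "read_manifest",
    "write_manifest",
    "validate_manifest",
    "read_phenotypes",
    "write_phenotypes",
    "validate_phenotypes",
    "read_gmt",
    "write_gmt",
    "read_clock",
    "write_clock",
    "read_cell_reference",
    "write_cell_reference",
    "read_de_table",
    "write_dmr_bed",
    "to_bed_interval",
    "from_bed_interval",
]


class FormatError(ValueError):
    """Raised when an input file violates its schema."""


MANIFEST_COLUMNS = [
    "probe_id",
    "chrom",
    "pos",
    "design_type",
    "genes",
    "tss_distance",
    "flag_snp_probe",
    "flag_cross_reactive",
    "flag_snp_within_10bp",
    "flag_sex_chrom",
]

_FLAG_COLUMNS = [c for c in MANIFEST_COLUMNS if c.startswith("flag_")]

PHENOTYPE_COLUMNS = [
    "sample_id",
    "donor_id",
    "region",
    "diagnosis",
    "age",
    "sex",
    "bank",
    "neuronal_proportion",
]

VALID_REGIONS = ("PFC", "TC", "CB")
VALID_DIAGNOSES = ("CTL", "iASD", "dup15q")


@dataclass(frozen=True)
class ClockModel:
    """An elastic-net style epigenetic clock: intercept + per-CpG weights.

    ``adult_age`` is the knot of the log-linear age transform used when
    training clocks on samples spanning development and adulthood.
    """

    intercept: float
    coefficients: pd.Series  # index: CpG probe IDs
    adult_age: float = 20.0

    def __post_init__(self) -> None:
        if self.coefficients.index.has_duplicates:
            raise FormatError("clock coefficient CpG IDs must be unique")


@dataclass(frozen=True)
class CellReference:
    """Two-component (neuron/glia) reference methylation profiles."""

    profiles: pd.DataFrame = field(repr=False)  # index: marker probe IDs

    def __post_init__(self) -> None:
        required = {"neuron", "glia"}
        if not required.issubset(self.profiles.columns):
            raise FormatError("cell reference needs 'neuron' and 'glia' columns")
        if len(self.profiles) < 10:
            raise FormatError("cell reference needs at least 10 marker probes")
        vals = self.profiles[["neuron", "glia"]].to_numpy(float)
        if np.nanmin(vals) < 0 or np.nanmax(vals) > 1:
            raise FormatError("reference profiles must lie in [0, 1]")

    @property
    def markers(self) -> pd.Index:
        return self.profiles.index

    @property
    def neuron(self) -> pd.Series:
        return self.profiles["neuron"]

    @property
    def glia(self) -> pd.Series:
        return self.profiles["glia"]


# ---------------------------------------------------------------------------
# beta / intensity matrices
# ---------------------------------------------------------------------------

def read_beta(path: str | Path, *, value_range: tuple[float, float] | None = (0.0, 1.0)) -> pd.DataFrame:
    """Read a probes x samples matrix from TSV, validating the value range.

    Values outside ``value_range`` raise :class:`FormatError` naming the
    offending probe and sample. Pass ``value_range=None`` for intensity
    matrices (only non-negativity is enforced then).
    """
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA", ""])
    df.index = df.index.astype(str)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise FormatError(f"duplicated probe ID {dup!r} in {path}")
    if df.columns.has_duplicates:
        dup = df.columns[df.columns.duplicated()][0]
        raise FormatError(f"duplicated sample ID {dup!r} in {path}")
    values = df.to_numpy(dtype=float, copy=False)
    lo, hi = value_range if value_range is not None else (0.0, np.inf)
    with np.errstate(invalid="ignore"):
        bad = (values < lo) | (values > hi)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise FormatError(
            f"value {values[i, j]!r} out of range [{lo}, {hi}] at probe "
            f"{df.index[i]!r}, sample {df.columns[j]!r} in {path}"
        )
    return df.astype(float)


def write_beta(beta: pd.DataFrame, path: str | Path) -> None:
    """Write a probes x samples matrix as TSV (probe ID first column)."""
    beta.to_csv(path, sep="\t", index_label="probe_id", na_rep="NA")


# ---------------------------------------------------------------------------
# probe manifest
# ---------------------------------------------------------------------------

def validate_manifest(manifest: pd.DataFrame) -> pd.DataFrame:
    """Validate (and lightly coerce) a probe manifest indexed by probe ID."""
    df = manifest.copy()
    if "probe_id" in df.columns:
        df = df.set_index("probe_id")
    df.index = df.index.astype(str)
    df.index.name = "probe_id"
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise FormatError(f"duplicate probe_id {dup!r} in manifest")
    missing = {"chrom", "pos", "design_type"} - set(df.columns)
    if missing:
        raise FormatError(f"manifest missing columns: {sorted(missing)}")
    df["pos"] = df["pos"].astype(np.int64)
    if (df["pos"] < 1).any():
        raise FormatError("manifest positions must be >= 1 (1-based)")
    bad_dt = set(df["design_type"].astype(str)) - {"I", "II"}
    if bad_dt:
        raise FormatError(f"invalid design_type values: {sorted(bad_dt)}")
    if "genes" not in df.columns:
        df["genes"] = ""
    df["genes"] = df["genes"].fillna("").astype(str)
    if "tss_distance" not in df.columns:
        df["tss_distance"] = ""
    df["tss_distance"] = df["tss_distance"].fillna("").astype(str)
    for col in _FLAG_COLUMNS:
        if col not in df.columns:
            df[col] = False
        df[col] = df[col].astype(bool)
    return df


def read_manifest(path: str | Path) -> pd.DataFrame:
    return validate_manifest(pd.read_csv(path, dtype={"probe_id": str, "chrom": str}))


def write_manifest(manifest: pd.DataFrame, path: str | Path) -> None:
    manifest.to_csv(path, index_label="probe_id")


def manifest_genes(manifest: pd.DataFrame) -> pd.Series:
    """Per-probe list of annotated gene symbols (empty list = intergenic)."""
    return manifest["genes"].map(lambda s: [g for g in str(s).split(";") if g])


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

def validate_phenotypes(pheno: pd.DataFrame) -> pd.DataFrame:
    df = pheno.copy()
    if "sample_id" in df.columns:
        df = df.set_index("sample_id")
    df.index = df.index.astype(str)
    df.index.name = "sample_id"
    if df.index.has_duplicates:
        raise FormatError("duplicate sample_id in phenotype table")
    required = {"donor_id", "region", "diagnosis", "age", "sex", "bank"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"phenotype table missing columns: {sorted(missing)}")
    if df.duplicated(subset=["donor_id", "region"]).any():
        raise FormatError("(donor_id, region) pairs must be unique")
    if (df["age"].astype(float) < 0).any():
        raise FormatError("age must be non-negative")
    bad_region = set(df["region"]) - set(VALID_REGIONS)
    if bad_region:
        raise FormatError(f"unknown brain region labels: {sorted(bad_region)}")
    bad_dx = set(df["diagnosis"]) - set(VALID_DIAGNOSES)
    if bad_dx:
        raise FormatError(f"unknown diagnosis labels: {sorted(bad_dx)}")
    if "neuronal_proportion" not in df.columns:
        df["neuronal_proportion"] = np.nan
    return df


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    return validate_phenotypes(pd.read_csv(path, dtype={"sample_id": str, "donor_id": str, "bank": str}))


def write_phenotypes(pheno: pd.DataFrame, path: str | Path) -> None:
    pheno.to_csv(path, index_label="sample_id")


# ---------------------------------------------------------------------------
# pathways (GMT)
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> dict[str, tuple[str, frozenset[str]]]:
    """Parse a GMT file into ``{pathway_id: (description, gene set)}``.

    Empty gene lists are retained (size 0), matching the convention that
    the size filter, not the parser, decides what is testable.
    """
    db: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise FormatError(f"{path}:{lineno}: GMT line needs id and description")
            pid, desc, *genes = parts
            if pid in db:
                raise FormatError(f"{path}:{lineno}: duplicate pathway id {pid!r}")
            db[pid] = (desc, frozenset(g for g in genes if g))
    return db


def write_gmt(db: dict[str, tuple[str, frozenset[str]]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for pid, (desc, genes) in db.items():
            fh.write("\t".join([pid, desc, *sorted(genes)]) + "\n")


# ---------------------------------------------------------------------------
# clock / cell reference / DE table
# ---------------------------------------------------------------------------

def read_clock(path: str | Path, *, adult_age: float = 20.0) -> ClockModel:
    """Read clock coefficients: columns ``cpg, coefficient``; one row with
    cpg = ``(Intercept)`` or ``intercept`` holds the intercept."""
    df = pd.read_csv(path, dtype={"cpg": str})
    if not {"cpg", "coefficient"}.issubset(df.columns):
        raise FormatError("clock CSV needs columns 'cpg' and 'coefficient'")
    is_icpt = df["cpg"].str.lower().isin(["(intercept)", "intercept"])
    if is_icpt.sum() != 1:
        raise FormatError("clock CSV needs exactly one intercept row")
    intercept = float(df.loc[is_icpt, "coefficient"].iloc[0])
    coef = df.loc[~is_icpt].set_index("cpg")["coefficient"].astype(float)
    return ClockModel(intercept=intercept, coefficients=coef, adult_age=adult_age)


def write_clock(clock: ClockModel, path: str | Path) -> None:
    rows = [("(Intercept)", clock.intercept)]
    rows += list(clock.coefficients.items())
    pd.DataFrame(rows, columns=["cpg", "coefficient"]).to_csv(path, index=False)


def read_cell_reference(path: str | Path) -> CellReference:
    df = pd.read_csv(path, dtype={"cpg": str})
    if not {"cpg", "neuron", "glia"}.issubset(df.columns):
        raise FormatError("cell reference CSV needs columns cpg, neuron, glia")
    return CellReference(profiles=df.set_index("cpg")[["neuron", "glia"]].astype(float))


def write_cell_reference(ref: CellReference, path: str | Path) -> None:
    ref.profiles.to_csv(path, index_label="cpg")


def read_de_table(path: str | Path) -> pd.DataFrame:
    """Differential-expression results: columns gene, log_fold_change, fdr."""
    df = pd.read_csv(path, dtype={"gene": str})
    missing = {"gene", "log_fold_change", "fdr"} - set(df.columns)
    if missing:
        raise FormatError(f"DE table missing columns: {sorted(missing)}")
    fdr = df["fdr"].astype(float)
    if ((fdr < 0) | (fdr > 1)).any():
        raise FormatError("DE table fdr values must lie in [0, 1]")
    return df


# ---------------------------------------------------------------------------
# BED export
# ---------------------------------------------------------------------------

def to_bed_interval(start: int, end: int) -> tuple[int, int]:
    """1-based inclusive -> 0-based half-open."""
    return start - 1, end


def from_bed_interval(start: int, end: int) -> tuple[int, int]:
    """0-based half-open -> 1-based inclusive."""
    return start + 1, end


def write_dmr_bed(regions: pd.DataFrame, path: str | Path) -> None:
    """Write DMRs as BED: chrom, start, end, name, sidak_p, sorted by locus.

    ``regions`` must have columns chrom, start, end (1-based inclusive)
    and sidak_p; an optional ``name`` column is used if present.
    """
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        if len(regions) == 0:
            return
        df = regions.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
        names = (
            df["name"].astype(str)
            if "name" in df.columns
            else pd.Series([f"dmr_{i + 1}" for i in range(len(df))])
        )
        for chrom, start, end, name, sidak in zip(
            df["chrom"], df["start"], df["end"], names, df["sidak_p"]
        ):
            start0, end0 = to_bed_interval(int(start), int(end))
            writer.writerow([chrom, start0, end0, name, f"{sidak:.6g}"])
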