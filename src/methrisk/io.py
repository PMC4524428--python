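"""Readers and writers for the tabular formats the pipeline touches.

In-memory conventions
---------------------
* A **β-value matrix** is a :class:`pandas.DataFrame` with probe IDs as the
  index and sample IDs as columns; entries are methylation fractions in
  ``[0, 1]`` with ``NaN`` for missing.  On disk it is a TSV with an ``NA``
  token for missing values.
* A **sample sheet** is a DataFrame indexed by ``sample_id`` with at least
  ``pair_id``, ``status`` (``case``/``control``), ``age_at_draw`` and
  ``followup`` (person-years); each ``pair_id`` appears exactly twice, once
  per status.
* A **WGBS pool** wraps a per-CpG table of read counts from one pooled
  bisulphite library, read from Bismark-style coverage files.  Coordinates
  are 1-based inclusive, matching Bismark output.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("methrisk")

MISSING_TOKEN = "NA"

REQUIRED_SHEET_COLUMNS = ("pair_id", "status", "age_at_draw", "followup")


class FormatError(ValueError):
    """Malformed input that the pipeline refuses to coerce."""


@dataclass
class WGBSPool:
    """Per-CpG methylated/total read counts for one pooled library.

    ``sites`` columns: ``chrom``, ``pos`` (1-based), ``meth_reads``,
    ``total_reads``.  Positions are unique per chromosome.
    """

    label: str
    sites: pd.DataFrame
    pathology_subgroup: str | None = None

    def __post_init__(self) -> None:
        s = self.sites
        required = ["chrom", "pos", "meth_reads", "total_reads"]
        missing = [c for c in required if c not in s.columns]
        if missing:
            raise FormatError(f"pool {self.label!r} missing columns {missing}")
        if len(s) and (s["meth_reads"] > s["total_reads"]).any():
            raise FormatError(f"pool {self.label!r}: methylated reads exceed total")
        if len(s) and s.duplicated(["chrom", "pos"]).any():
            raise FormatError(f"pool {self.label!r}: duplicate positions")

    @property
    def methylation(self) -> np.ndarray:
        """Per-site methylated-read fraction (NaN where coverage is zero)."""
        total = self.sites["total_reads"].to_numpy(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(total > 0, self.sites["meth_reads"].to_numpy(float) / total, np.nan)

    def __len__(self) -> int:
        return len(self.sites)


def log_stage(stage: str, **counts) -> None:
    """One structured log line per pipeline stage with in/out counts."""
    payload = " ".join(f"{k}={v}" for k, v in counts.items())
    logger.info("stage=%s %s", stage, payload)


# ---------------------------------------------------------------------------
# β-value matrices


def validate_beta_matrix(m: pd.DataFrame) -> None:
    """Raise :class:`FormatError` if *m* is not a valid β matrix."""
    values = m.to_numpy(float)
    bad = (values < 0) | (values > 1)
    if np.any(bad & ~np.isnan(values)):
        probe = m.index[np.where(bad & ~np.isnan(values))[0][0]]
        raise FormatError(f"β value outside [0, 1] at probe {probe!r}")
    if m.index.duplicated().any():
        raise FormatError("duplicate probe IDs")
    if m.columns.duplicated().any():
        raise FormatError("duplicate sample IDs")


def read_beta_matrix(path) -> pd.DataFrame:
    """Read a probe × sample β matrix from TSV (``NA`` = missing)."""
    m = pd.read_csv(path, sep="\t", index_col=0, na_values=[MISSING_TOKEN], keep_default_na=False)
    try:
        m = m.astype(float)
    except ValueError as exc:
        raise FormatError(f"non-numeric β value in {path}: {exc}") from exc
    validate_beta_matrix(m)
    log_stage("read_beta_matrix", probes=m.shape[0], samples=m.shape[1])
    return m


def write_beta_matrix(m: pd.DataFrame, path) -> None:
    validate_beta_matrix(m)
    m.to_csv(path, sep="\t", na_rep=MISSING_TOKEN, index_label="probe_id")


# ---------------------------------------------------------------------------
# Sample sheets


def validate_sample_sheet(sheet: pd.DataFrame) -> None:
    """Check pair integrity: each pair has exactly one case and one control."""
    missing = [c for c in REQUIRED_SHEET_COLUMNS if c not in sheet.columns]
    if missing:
        raise FormatError(f"sample sheet missing columns {missing}")
    if sheet["followup"].isna().any():
        bad = sheet.index[sheet["followup"].isna()][0]
        raise FormatError(f"missing follow-up time for sample {bad!r}")
    if (sheet["followup"] <= 0).any():
        bad = sheet.index[sheet["followup"] <= 0][0]
        raise FormatError(f"non-positive follow-up time for sample {bad!r}")
    bad_status = set(sheet["status"]) - {"case", "control"}
    if bad_status:
        raise FormatError(f"unknown status values {sorted(bad_status)}")
    for pair_id, grp in sheet.groupby("pair_id"):
        if len(grp) != 2:
            raise FormatError(f"pair {pair_id!r} has {len(grp)} members, expected 2")
        statuses = sorted(grp["status"])
        if statuses != ["case", "control"]:
            raise FormatError(f"pair {pair_id!r} is not one case + one control ({statuses})")


def read_sample_sheet(path) -> pd.DataFrame:
    sheet = pd.read_csv(path)
    if "sample_id" not in sheet.columns:
        raise FormatError("sample sheet needs a sample_id column")
    sheet = sheet.set_index("sample_id")
    validate_sample_sheet(sheet)
    log_stage("read_sample_sheet", samples=len(sheet), pairs=sheet["pair_id"].nunique())
    return sheet


def write_sample_sheet(sheet: pd.DataFrame, path) -> None:
    sheet.to_csv(path, index_label="sample_id")


# ---------------------------------------------------------------------------
# Bismark-style coverage files

COVERAGE_COLUMNS = ["chrom", "start", "end", "meth_pct", "meth_reads", "unmeth_reads"]


def read_coverage_file(path, label: str | None = None) -> WGBSPool:
    """Read a Bismark coverage-style TSV into a :class:`WGBSPool`.

    Columns: chrom, start, end (1-based inclusive), methylation %, methylated
    count, unmethylated count.  If the printed percentage disagrees with the
    counts by more than 0.1 a warning is issued and the counts win.
    """
    df = pd.read_csv(path, sep="\t", header=None, names=COVERAGE_COLUMNS)
    if df.empty:
        pool = WGBSPool(label or str(path), pd.DataFrame(columns=["chrom", "pos", "meth_reads", "total_reads"]))
        return pool
    for col in ("meth_reads", "unmeth_reads"):
        if (df[col] < 0).any():
            raise FormatError(f"negative count in column {col!r} of {path}")
        if not np.array_equal(df[col], df[col].astype(int)):
            raise FormatError(f"non-integer count in column {col!r} of {path}")
    total = df["meth_reads"] + df["unmeth_reads"]
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(total > 0, 100.0 * df["meth_reads"] / total, 0.0)
    if np.nanmax(np.abs(pct - df["meth_pct"].to_numpy(float)), initial=0.0) > 0.1:
        warnings.warn(f"{path}: methylation %% column inconsistent with counts; counts win", stacklevel=2)
    sites = pd.DataFrame(
        {
            "chrom": df["chrom"],
            "pos": df["start"].astype(int),
            "meth_reads": df["meth_reads"].astype(int),
            "total_reads": total.astype(int),
        }
    )
    return WGBSPool(label or str(path), sites)


def write_coverage_file(pool: WGBSPool, path) -> None:
    s = pool.sites
    total = s["total_reads"].to_numpy(int)
    meth = s["meth_reads"].to_numpy(int)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(total > 0, 100.0 * meth / total, 0.0)
    out = pd.DataFrame(
        {
            "chrom": s["chrom"],
            "start": s["pos"].astype(int),
            "end": s["pos"].astype(int),
            "meth_pct": np.round(pct, 6),
            "meth_reads": meth,
            "unmeth_reads": total - meth,
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# Run configuration


def load_run_config(path) -> dict:
    """Load a YAML run configuration (paths, thresholds, seed)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise FormatError("run config must be a YAML mapping")
    return cfg
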