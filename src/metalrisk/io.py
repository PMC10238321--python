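"""Readers and writers for concentration tables.

Two tidy-long schemas are supported, both CSV (UTF-8, period decimal):

* sample level — ``brand,tissue,metal,sample_id,concentration_ug_g``,
  one measured bird per row;
* group level  — ``brand,tissue,metal,n,mean_ug_g,se_ug_g``, one
  brand × tissue × metal summary per row.

The packaged study fixture (:func:`load_study_means`) is the published
216-group summary table (12 metals × 3 tissues × 6 brands, n = 20 each)
transcribed as printed; see ``data/fixture_notes.md`` for provenance and
the verbatim typographic oddities it preserves.
"""
from __future__ import annotations

import io as _io
import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterator, Union

import pandas as pd

log = logging.getLogger(__name__)

TISSUES = ("chest", "thigh", "liver")

SAMPLE_COLUMNS = ["brand", "tissue", "metal", "sample_id", "concentration_ug_g"]
GROUP_COLUMNS = ["brand", "tissue", "metal", "n", "mean_ug_g", "se_ug_g"]

__all__ = [
    "SampleRecord", "GroupSummary", "ConcentrationTable",
    "ConcentrationError", "read_concentrations", "write_concentrations",
    "load_study_means", "fixture_notes", "TISSUES",
]


class ConcentrationError(ValueError):
    """A concentration table violates its schema or invariants."""


@dataclass(frozen=True)
class SampleRecord:
    brand: str
    tissue: str
    metal: str
    concentration: float  # µg/g wet weight
    sample_id: str


@dataclass(frozen=True)
class GroupSummary:
    brand: str
    tissue: str
    metal: str
    n: int
    mean: float  # µg/g wet weight
    se: float    # µg/g wet weight


class ConcentrationTable:
    """A validated tidy table of concentrations at sample or group level."""

    def __init__(self, frame: pd.DataFrame, level: str):
        if level not in ("sample", "group"):
            raise ConcentrationError(f"level must be sample|group, got {level!r}")
        self.level = level
        self.frame = _validate(frame, level)

    def __len__(self) -> int:
        return len(self.frame)

    def __eq__(self, other) -> bool:
        if not isinstance(other, ConcentrationTable):
            return NotImplemented
        if self.level != other.level:
            return False
        a = self.frame.reset_index(drop=True)
        b = other.frame.reset_index(drop=True)
        return a.equals(b)

    def records(self) -> Iterator[Union[SampleRecord, GroupSummary]]:
        if self.level == "sample":
            for row in self.frame.itertuples(index=False):
                yield SampleRecord(row.brand, row.tissue, row.metal,
                                   row.concentration_ug_g, row.sample_id)
        else:
            for row in self.frame.itertuples(index=False):
                yield GroupSummary(row.brand, row.tissue, row.metal,
                                   int(row.n), row.mean_ug_g, row.se_ug_g)

    def group_keys(self) -> list[tuple[str, str]]:
        """Distinct (brand, tissue) pairs, in stable order."""
        seen = dict.fromkeys(
            zip(self.frame["brand"], self.frame["tissue"]))
        return list(seen)

    def subset(self, **where) -> "ConcentrationTable":
        frame = self.frame
        for col, val in where.items():
            frame = frame[frame[col] == val]
        return ConcentrationTable(frame.reset_index(drop=True), self.level)


def _validate(frame: pd.DataFrame, level: str) -> pd.DataFrame:
    required = SAMPLE_COLUMNS if level == "sample" else GROUP_COLUMNS
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ConcentrationError(
            f"{level}-level table is missing column(s) {missing}; "
            f"expected header {required}")
    frame = frame.loc[:, required].copy()
    for col in ("brand", "tissue", "metal"):
        frame[col] = frame[col].astype(str)
    if level == "sample":
        frame["sample_id"] = frame["sample_id"].astype(str)
        frame["concentration_ug_g"] = _numeric(frame, "concentration_ug_g")
        key_cols = ["brand", "tissue", "metal", "sample_id"]
    else:
        frame["n"] = _numeric(frame, "n").astype(int)
        frame["mean_ug_g"] = _numeric(frame, "mean_ug_g")
        frame["se_ug_g"] = _numeric(frame, "se_ug_g")
        key_cols = ["brand", "tissue", "metal"]

    for i, row in enumerate(frame.itertuples(index=False)):
        if row.tissue not in TISSUES:
            raise ConcentrationError(
                f"row {i}: field 'tissue' is {row.tissue!r}, "
                f"expected one of {TISSUES}")
        if level == "sample":
            if row.concentration_ug_g < 0:
                raise ConcentrationError(
                    f"row {i}: field 'concentration_ug_g' is negative "
                    f"({row.concentration_ug_g})")
        else:
            if row.n < 1:
                raise ConcentrationError(f"row {i}: field 'n' must be >= 1")
            if row.mean_ug_g < 0:
                raise ConcentrationError(
                    f"row {i}: field 'mean_ug_g' is negative ({row.mean_ug_g})")
            if row.se_ug_g < 0:
                raise ConcentrationError(
                    f"row {i}: field 'se_ug_g' is negative ({row.se_ug_g})")
            if row.n == 1 and row.se_ug_g != 0:
                raise ConcentrationError(
                    f"row {i}: field 'se_ug_g' must be 0 when n = 1")

    dup = frame.duplicated(subset=key_cols)
    if dup.any():
        i = int(dup.idxmax())
        raise ConcentrationError(
            f"row {i}: duplicate key "
            f"{tuple(frame.loc[i, c] for c in key_cols)}")
    return frame


def read_concentrations(source, level: str) -> ConcentrationTable:
    """Read a CSV (path, file-like or CSV string) into a validated table."""
    if isinstance(source, str) and "\n" in source:
        source = _io.StringIO(source)
    try:
        frame = pd.read_csv(source, dtype={"brand": str, "sample_id": str})
    except ValueError as exc:
        raise ConcentrationError(f"cannot parse CSV: {exc}") from exc
    return ConcentrationTable(frame, level)


def write_concentrations(table: ConcentrationTable, destination=None) -> str:
    """Write a table back to CSV; returns the text (and writes it if a
    path/file-like destination is given).  Round-trips exactly."""
    text = table.frame.to_csv(index=False)
    if destination is not None:
        if hasattr(destination, "write"):
            destination.write(text)
        else:
            Path(destination).write_text(text)
    return text


def _numeric(frame: pd.DataFrame, col: str) -> pd.Series:
    series = pd.to_numeric(frame[col], errors="coerce")
    if series.isna().any():
        i = int(series.isna().idxmax())
        raise ConcentrationError(
            f"row {i}: field {col!r} is not numeric ({frame[col][i]!r})")
    return series.astype(float)


def load_study_means() -> ConcentrationTable:
    """The packaged 216-group study fixture (published means ± SE)."""
    text = (resources.files("metalrisk.data") / "group_means.csv").read_text()
    return read_concentrations(text, level="group")


def load_published_table(name: str) -> pd.DataFrame:
    """A published derived table: 'edi', 'thq', 'hi' or 'tr'.

    Columns: brand, tissue[, metal], printed (string as printed), status
    (ok | recovered | anomaly — see data/fixture_notes.md).
    """
    fname = {"edi": "table3_edi.csv", "thq": "table4_thq.csv",
             "hi": "table5_hi.csv", "tr": "table6_tr.csv"}[name]
    text = (resources.files("metalrisk.data") / fname).read_text()
    return pd.read_csv(_io.StringIO(text), dtype={"brand": str, "printed": str})


def fixture_notes() -> str:
    return (resources.files("metalrisk.data") / "fixture_notes.md").read_text()
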