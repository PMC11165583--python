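"""Reading and writing protein quantification reports.

Handles long-format label-free quantification (LFQ) reports as produced by
gene-centric DIA search engines, sample metadata describing donors, time
points and injection replicates, and the bundled table of reference plasma
concentrations used to anchor the LFQ -> mg/dL calibration.

The minimal native dialect is a TSV with columns ``protein_group``, ``run``,
``quantity`` and (optionally) ``q_value``.  A mapping layer accommodates
DIA-NN-style column names.  Report-level quality filters are applied at read
time: records with q-value above 1% are dropped, and keratin / immunoglobulin
variable-region contaminant classes can be removed by id pattern.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("plasmatrace")

Q_VALUE_THRESHOLD = 0.01

#: Column names of the native report dialect.
NATIVE_DIALECT: dict[str, str] = {
    "protein_id": "protein_group",
    "run_id": "run",
    "quantity": "quantity",
    "q_value": "q_value",
}

#: Column mapping for DIA-NN gene-centric style reports.
DIANN_DIALECT: dict[str, str] = {
    "protein_id": "Genes",
    "run_id": "Run",
    "quantity": "PG.Quantity",
    "q_value": "PG.Q.Value",
}

DIALECTS: dict[str, dict[str, str]] = {
    "native": NATIVE_DIALECT,
    "diann": DIANN_DIALECT,
}

#: Default contaminant id predicates: keratins and immunoglobulin
#: variable regions (the hyper-variable CDR-covering entries).
DEFAULT_CONTAMINANT_PATTERNS: tuple[str, ...] = (
    r"^KRT\d+[A-Z]?$",
    r"^IG[HKL]V[\d/OR-]+.*$",
)

VALID_CONDITIONS = ("healthy", "pre_transplant", "post_transplant")


class ReportFormatError(ValueError):
    """A quantification report is structurally malformed."""


class ValidationError(ValueError):
    """A report parsed, but its values violate an invariant."""


@dataclass(frozen=True)
class QuantRecord:
    """One protein-group quantity in one LC-MS run."""

    protein_id: str
    run_id: str
    quantity: float
    q_value: float | None = None

    def __post_init__(self) -> None:
        if not self.protein_id:
            raise ValidationError("protein_id must be non-empty")
        if self.quantity < 0:
            raise ValidationError(
                f"negative quantity {self.quantity!r} for {self.protein_id}"
            )


@dataclass(frozen=True)
class SampleMetadata:
    """Provenance of one LC-MS run: donor, time point, condition."""

    run_id: str
    donor_id: str
    timepoint_index: int
    condition: str
    replicate_of: str | None = None

    def __post_init__(self) -> None:
        if self.timepoint_index < 0:
            raise ValidationError("timepoint_index must be >= 0")
        if self.condition not in VALID_CONDITIONS:
            raise ValidationError(
                f"condition {self.condition!r} not in {VALID_CONDITIONS}"
            )

    @property
    def sample_id(self) -> str:
        """Collapsed sample key: the replicate group if any, else the run."""
        return self.replicate_of or self.run_id


@dataclass
class QuantTable:
    """Long-format quantification table plus per-sample metadata.

    ``records`` has one row per (protein_id, run_id) with a ``quantity``
    column; after :func:`collapse_replicates` the run ids are sample ids and
    the pair is unique.
    """

    records: pd.DataFrame
    metadata: dict[str, SampleMetadata] = field(default_factory=dict)

    def __post_init__(self) -> None:
        required = {"protein_id", "run_id", "quantity"}
        missing = required - set(self.records.columns)
        if missing:
            raise ReportFormatError(f"records missing columns: {sorted(missing)}")

    @property
    def protein_ids(self) -> list[str]:
        return list(pd.unique(self.records["protein_id"]))

    @property
    def run_ids(self) -> list[str]:
        return list(pd.unique(self.records["run_id"]))

    def to_wide(self) -> pd.DataFrame:
        """Protein x run matrix of quantities (NaN where absent)."""
        return self.records.pivot_table(
            index="protein_id", columns="run_id", values="quantity", aggfunc="first"
        )

    def write(self, path: str | Path) -> None:
        cols = ["protein_id", "run_id", "quantity"]
        if "q_value" in self.records.columns:
            cols.append("q_value")
        out = self.records[cols].rename(
            columns={"protein_id": "protein_group", "run_id": "run"}
        )
        out.to_csv(path, sep="\t", index=False, float_format="%.17g")


@dataclass(frozen=True)
class ReferenceTable:
    """Reference plasma concentrations (mg/dL) for calibration anchors."""

    concentrations: Mapping[str, float]

    def __post_init__(self) -> None:
        if len(set(self.concentrations)) != len(self.concentrations):
            raise ValidationError("duplicate protein ids in reference table")
        for pid, conc in self.concentrations.items():
            if conc <= 0:
                raise ValidationError(f"non-positive reference value for {pid}")

    @property
    def protein_ids(self) -> list[str]:
        return list(self.concentrations)

    def __len__(self) -> int:
        return len(self.concentrations)


def load_reference_table(path: str | Path | None = None) -> ReferenceTable:
    """Load a reference-concentration TSV; defaults to the bundled 22-anchor panel."""
    if path is None:
        ref = resources.files("plasmatrace").joinpath(
            "data/reference_concentrations.tsv"
        )
        with resources.as_file(ref) as p:
            df = pd.read_csv(p, sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    for col in ("protein_id", "reference_concentration"):
        if col not in df.columns:
            raise ReportFormatError(f"reference table missing column {col!r}")
    return ReferenceTable(
        dict(zip(df["protein_id"].astype(str), df["reference_concentration"].astype(float)))
    )


def read_quant_report(
    path: str | Path, dialect: str | Mapping[str, str] = "native"
) -> list[QuantRecord]:
    """Read a long-format quantification report, filtering at 1% q-value.

    Records whose q-value exceeds :data:`Q_VALUE_THRESHOLD` are excluded when
    a q-value column is present (inclusive threshold, q <= 0.01 kept).  Row
    order is otherwise preserved.
    """
    colmap = DIALECTS[dialect] if isinstance(dialect, str) else dict(dialect)
    df = pd.read_csv(path, sep="\t")
    for key in ("protein_id", "run_id", "quantity"):
        if colmap[key] not in df.columns:
            raise ReportFormatError(f"report lacks mandatory column {colmap[key]!r}")
    has_q = colmap.get("q_value") in df.columns

    records: list[QuantRecord] = []
    for row in df.itertuples(index=False):
        row_d = dict(zip(df.columns, row))
        q = float(row_d[colmap["q_value"]]) if has_q else None
        if q is not None and q > Q_VALUE_THRESHOLD:
            continue
        records.append(
            QuantRecord(
                protein_id=str(row_d[colmap["protein_id"]]),
                run_id=str(row_d[colmap["run_id"]]),
                quantity=float(row_d[colmap["quantity"]]),
                q_value=q,
            )
        )
    return records


def read_metadata(path: str | Path) -> dict[str, SampleMetadata]:
    """Read sample metadata TSV (run, donor, timepoint, condition[, replicate_of])."""
    df = pd.read_csv(path, sep="\t")
    for col in ("run", "donor", "timepoint", "condition"):
        if col not in df.columns:
            raise ReportFormatError(f"metadata lacks mandatory column {col!r}")
    meta: dict[str, SampleMetadata] = {}
    for row in df.itertuples(index=False):
        rep = getattr(row, "replicate_of", None)
        if rep is not None and (pd.isna(rep) or rep == ""):
            rep = None
        meta[str(row.run)] = SampleMetadata(
            run_id=str(row.run),
            donor_id=str(row.donor),
            timepoint_index=int(row.timepoint),
            condition=str(row.condition),
            replicate_of=None if rep is None else str(rep),
        )
    return meta


def write_metadata(metadata: Mapping[str, SampleMetadata], path: str | Path) -> None:
    rows = [
        {
            "run": m.run_id,
            "donor": m.donor_id,
            "timepoint": m.timepoint_index,
            "condition": m.condition,
            "replicate_of": m.replicate_of or "",
        }
        for m in metadata.values()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def collapse_replicates(
    records: Iterable[QuantRecord],
    metadata: Mapping[str, SampleMetadata],
) -> QuantTable:
    """Collapse injection replicates to their per-protein median quantity.

    Runs sharing a ``replicate_of`` group key are merged into one sample whose
    quantity is the median over the replicate injections; runs without a group
    pass through unchanged.  The result is unique per (protein, sample).
    """
    rows = []
    for rec in records:
        meta = metadata.get(rec.run_id)
        sample = meta.sample_id if meta is not None else rec.run_id
        rows.append((rec.protein_id, sample, rec.quantity))
    if not rows:
        group_samples = {m.sample_id for m in metadata.values()}
        if metadata and not group_samples:
            raise ValidationError("replicate group with zero members")
        return QuantTable(
            records=pd.DataFrame(columns=["protein_id", "run_id", "quantity"]),
            metadata=_collapse_metadata(metadata),
        )
    df = pd.DataFrame(rows, columns=["protein_id", "run_id", "quantity"])
    # every declared replicate group must receive at least one record
    declared = {m.replicate_of for m in metadata.values() if m.replicate_of}
    observed = set(df["run_id"])
    empty = declared - observed
    if empty:
        raise ValidationError(f"replicate group(s) with zero members: {sorted(empty)}")
    collapsed = (
        df.groupby(["protein_id", "run_id"], sort=False, as_index=False)["quantity"]
        .median()
    )
    return QuantTable(records=collapsed, metadata=_collapse_metadata(metadata))


def _collapse_metadata(
    metadata: Mapping[str, SampleMetadata]
) -> dict[str, SampleMetadata]:
    """One metadata entry per collapsed sample id."""
    out: dict[str, SampleMetadata] = {}
    for m in metadata.values():
        sid = m.sample_id
        if sid not in out:
            out[sid] = SampleMetadata(
                run_id=sid,
                donor_id=m.donor_id,
                timepoint_index=m.timepoint_index,
                condition=m.condition,
                replicate_of=None,
            )
    return out


def filter_contaminant_classes(
    table: QuantTable,
    patterns: Sequence[str] = DEFAULT_CONTAMINANT_PATTERNS,
) -> QuantTable:
    """Remove contaminant protein classes by id pattern.

    Default patterns match keratin family ids and immunoglobulin
    variable-region ids.  Retained quantities are never altered.
    """
    if not patterns:
        return table
    compiled = [re.compile(p) for p in patterns]
    ids = table.records["protein_id"]
    mask = ids.map(lambda pid: any(c.match(pid) for c in compiled))
    removed = sorted(pd.unique(ids[mask]))
    if removed:
        logger.info("removed %d contaminant protein id(s): %s", len(removed), removed)
    return QuantTable(
        records=table.records.loc[~mask].reset_index(drop=True),
        metadata=table.metadata,
    )


def read_quant_table(
    report_path: str | Path,
    metadata_path: str | Path,
    dialect: str | Mapping[str, str] = "native",
) -> QuantTable:
    """Read report + metadata and collapse replicates in one step."""
    records = read_quant_report(report_path, dialect=dialect)
    metadata = read_metadata(metadata_path)
    return collapse_replicates(records, metadata)
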