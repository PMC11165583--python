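"""Label-free quantity -> absolute plasma concentration calibration.

Label-free quantification (LFQ) intensities are proportional to protein
abundance only up to an instrument- and workflow-dependent scale.  To place
them on an absolute mg/dL scale, a log10-log10 linear model

    log10(concentration mg/dL) = intercept + slope * log10(LFQ)

is fitted by ordinary least squares on a panel of anchor proteins whose
average plasma concentrations are known from the literature (the bundled
panel has 22 anchors).  Per anchor, the median over samples of the log10
quantity is regressed on the log10 reference concentration; the fitted map
then converts every (protein, sample) quantity to mg/dL.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .quant_io import QuantTable, ReferenceTable, SampleMetadata


class CalibrationError(ValueError):
    """Too few usable anchor proteins to fit a calibration."""


@dataclass(frozen=True)
class CalibrationModel:
    """Fitted log10-log10 map from LFQ intensity to mg/dL."""

    slope: float
    intercept: float
    r_squared: float
    n_anchors: int
    anchor_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.n_anchors < 3:
            raise CalibrationError("calibration needs >= 3 anchors")
        if not 0.0 <= self.r_squared <= 1.0 + 1e-12:
            raise ValueError(f"r_squared {self.r_squared} outside [0, 1]")

    def concentration(self, quantity: float | np.ndarray) -> float | np.ndarray:
        """mg/dL for an LFQ quantity (> 0)."""
        return 10.0 ** (self.intercept + self.slope * np.log10(quantity))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "slope": self.slope,
                    "intercept": self.intercept,
                    "r_squared": self.r_squared,
                    "n_anchors": self.n_anchors,
                    "anchor_ids": list(self.anchor_ids),
                },
                indent=1,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "CalibrationModel":
        d = json.loads(Path(path).read_text())
        return cls(
            slope=d["slope"],
            intercept=d["intercept"],
            r_squared=d["r_squared"],
            n_anchors=d["n_anchors"],
            anchor_ids=tuple(d["anchor_ids"]),
        )


@dataclass
class ConcentrationMatrix:
    """Protein x sample concentrations (mg/dL) with sample metadata."""

    values: pd.DataFrame  # proteins x samples
    metadata: dict[str, SampleMetadata] = field(default_factory=dict)

    @property
    def protein_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def donor_samples(self, donor_id: str) -> list[str]:
        """Sample ids of one donor, ordered by time point."""
        pairs = [
            (m.timepoint_index, sid)
            for sid, m in self.metadata.items()
            if m.donor_id == donor_id and sid in self.values.columns
        ]
        return [sid for _, sid in sorted(pairs)]

    @property
    def donor_ids(self) -> list[str]:
        seen: list[str] = []
        for sid in self.sample_ids:
            m = self.metadata.get(sid)
            if m is not None and m.donor_id not in seen:
                seen.append(m.donor_id)
        return seen

    def zscore(self, log10: bool = True) -> pd.DataFrame:
        """Per-protein standardization across all samples.

        Computed on log10 concentrations by default, so that z-scores are
        comparable across the ~5 orders of magnitude the plasma proteome
        spans.  Rows with zero variance come out as all-zero.
        """
        x = np.log10(self.values) if log10 else self.values.copy()
        mean = x.mean(axis=1)
        sd = x.std(axis=1, ddof=1)
        # constant rows (up to float jitter) carry no trajectory signal
        sd = sd.where(sd > 1e-10 * (1.0 + mean.abs()), np.nan)
        z = x.sub(mean, axis=0).div(sd, axis=0)
        return z.fillna(0.0)

    def write(self, path: str | Path) -> None:
        self.values.to_csv(path, sep="\t", float_format="%.12g", index_label="protein_id")


def fit_concentration_model(
    table: QuantTable, refs: ReferenceTable
) -> CalibrationModel:
    """Fit the LFQ -> mg/dL calibration on the reference anchor panel.

    For each anchor present in the table with a positive median quantity,
    the pair (median over samples of log10 quantity, log10 reference
    concentration) enters an ordinary least-squares fit.  Anchors absent
    from the table are skipped and reported; anchors with non-positive
    median quantity are excluded with a warning.
    """
    wide = table.to_wide()
    missing = [pid for pid in refs.protein_ids if pid not in wide.index]
    if missing:
        warnings.warn(
            f"{len(missing)} anchor(s) absent from table: {missing}", stacklevel=2
        )
    usable: list[tuple[str, float, float]] = []
    for pid in refs.protein_ids:
        if pid not in wide.index:
            continue
        med = float(wide.loc[pid].median(skipna=True))
        if not np.isfinite(med) or med <= 0:
            warnings.warn(
                f"anchor {pid} has non-positive median quantity; excluded",
                stacklevel=2,
            )
            continue
        usable.append((pid, np.log10(med), np.log10(refs.concentrations[pid])))
    if len(usable) < 3:
        raise CalibrationError(
            f"only {len(usable)} usable anchors (need >= 3); missing: {missing}"
        )
    ids, x, y = zip(*usable)
    x = np.asarray(x)
    y = np.asarray(y)
    if np.allclose(x, x[0]):
        raise CalibrationError("anchor quantities are degenerate (no spread)")
    fit = stats.linregress(x, y)
    return CalibrationModel(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=min(float(fit.rvalue**2), 1.0),
        n_anchors=len(ids),
        anchor_ids=tuple(ids),
    )


def lfq_to_concentration(
    model: CalibrationModel, table: QuantTable
) -> ConcentrationMatrix:
    """Convert every quantity in the table to mg/dL under the fitted model.

    Zero quantities become absent values (NaN), never zero concentrations:
    an LFQ of zero means 'not observed', not 'not present'.
    """
    wide = table.to_wide()
    with np.errstate(divide="ignore"):
        logq = np.log10(wide.where(wide > 0))
    conc = 10.0 ** (model.intercept + model.slope * logq)
    return ConcentrationMatrix(values=conc, metadata=dict(table.metadata))
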