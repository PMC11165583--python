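"""Acute-phase response detection and acute-phase protein classification.

The acute-phase response (APR) is located in time using the hallmark
inflammation markers CRP, SAA1 and SAA2: a time point is called an APR peak
when the donor's composite hallmark concentration exceeds a fold threshold
(default 5x) over that donor's hallmark baseline.  Against the resulting
peak/baseline split, every protein's trajectory is classified:

* **positive APP** — concentration at a peak at least 25% above the
  baseline median, and the trajectory tracks the hallmark composite;
* **negative APP** — at least 25% below baseline at a peak, with a
  mirror-image (anti-correlated) trajectory;
* **none** — everything else.

The 25% boundary is the defining criterion of acute-phase proteins; the
correlation condition encodes the mirror-image requirement as a testable
rule (|r| >= 0.6 against the mean hallmark z-trajectory).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calibration import ConcentrationMatrix

HALLMARK_IDS = ("CRP", "SAA1", "SAA2")
DEFAULT_PEAK_FOLD_THRESHOLD = 5.0
DEFAULT_APP_THRESHOLD = 0.25
DEFAULT_CORR_THRESHOLD = 0.6

APOA_IDS = ("APOA1", "APOA2", "APOA4")
SAA_IDS = ("SAA1", "SAA2")


class HallmarksMissingError(ValueError):
    """None of the hallmark markers are present in the matrix."""


@dataclass(frozen=True)
class APRCall:
    """APR episode localization for one donor."""

    donor_id: str
    peak_timepoints: frozenset[int]
    baseline_timepoints: frozenset[int]
    #: mean z-score of the hallmark log10 concentrations, per time point
    hallmark_composite: pd.Series

    def __post_init__(self) -> None:
        if self.peak_timepoints & self.baseline_timepoints:
            raise ValueError("peak and baseline time points overlap")


@dataclass(frozen=True)
class APPResult:
    """Classification of one protein trajectory during an APR."""

    protein_id: str
    fold_change_at_peak: float
    app_class: str
    hallmark_correlation: float


def detect_apr_peaks(
    matrix: ConcentrationMatrix,
    hallmark_ids: tuple[str, ...] = HALLMARK_IDS,
    fold_threshold: float = DEFAULT_PEAK_FOLD_THRESHOLD,
    exclude_t0: bool = True,
) -> dict[str, APRCall]:
    """Locate APR peaks per donor from the hallmark markers.

    Per hallmark, each time point's fold over the donor's median hallmark
    level is computed; the composite fold is the median across hallmarks,
    and a time point is a peak when it exceeds ``fold_threshold``.
    Baseline time points are those neither peaks nor adjacent to peaks;
    for patient donors T0 (the pre-transplant outlier sample) is
    additionally excluded when ``exclude_t0`` is set.
    """
    present = [h for h in hallmark_ids if h in matrix.values.index]
    if not present:
        raise HallmarksMissingError(
            f"no hallmark marker of {hallmark_ids} present in matrix"
        )
    calls: dict[str, APRCall] = {}
    for donor in matrix.donor_ids:
        samples = matrix.donor_samples(donor)
        if len(samples) < 3:
            raise ValueError(f"donor {donor}: need >= 3 time points")
        tps = [matrix.metadata[s].timepoint_index for s in samples]
        sub = matrix.values.loc[present, samples]
        folds = sub.div(sub.median(axis=1), axis=0)
        composite_fold = folds.median(axis=0)
        peaks = {
            t for t, f in zip(tps, composite_fold) if f > fold_threshold
        }
        near_peak = {t for p in peaks for t in (p - 1, p, p + 1)}
        is_patient = any(
            matrix.metadata[s].condition != "healthy" for s in samples
        )
        baseline = {
            t
            for t in tps
            if t not in near_peak and not (exclude_t0 and is_patient and t == 0)
        }
        logc = np.log10(sub)
        z = logc.sub(logc.mean(axis=1), axis=0).div(
            logc.std(axis=1, ddof=1).replace(0.0, np.nan), axis=0
        )
        composite = z.mean(axis=0).fillna(0.0)
        composite.index = tps
        calls[donor] = APRCall(
            donor_id=donor,
            peak_timepoints=frozenset(peaks),
            baseline_timepoints=frozenset(baseline),
            hallmark_composite=composite,
        )
    return calls


def classify_app(
    trajectory: pd.Series,
    apr_call: APRCall,
    threshold: float = DEFAULT_APP_THRESHOLD,
    corr_threshold: float = DEFAULT_CORR_THRESHOLD,
    protein_id: str = "",
) -> APPResult | None:
    """Classify one concentration trajectory as positive/negative APP or none.

    ``trajectory`` is indexed by time point.  The fold change is the peak
    concentration over the baseline median — maximized over peaks for the
    positive call and minimized for the negative call, so multi-episode
    donors are handled symmetrically.  Returns None (with a warning) when
    the baseline median is zero or undefined.
    """
    if not apr_call.peak_timepoints or not apr_call.baseline_timepoints:
        raise ValueError("APR call needs >= 1 peak and >= 1 baseline time point")
    base_vals = trajectory.reindex(sorted(apr_call.baseline_timepoints)).dropna()
    base = float(base_vals.median()) if len(base_vals) else np.nan
    if not np.isfinite(base) or base <= 0:
        warnings.warn(
            f"protein {protein_id or '<unnamed>'}: baseline median undefined; "
            "skipped",
            stacklevel=2,
        )
        return None
    peak_vals = trajectory.reindex(sorted(apr_call.peak_timepoints)).dropna()
    if peak_vals.empty:
        warnings.warn(
            f"protein {protein_id or '<unnamed>'}: no peak observations; skipped",
            stacklevel=2,
        )
        return None
    fold_up = float(peak_vals.max() / base)
    fold_down = float(peak_vals.min() / base)

    composite = apr_call.hallmark_composite
    shared = trajectory.index.intersection(composite.index)
    with np.errstate(divide="ignore", invalid="ignore"):
        logt = np.log10(trajectory.reindex(shared).astype(float))
    r = float(logt.corr(composite.reindex(shared)))
    if not np.isfinite(r):
        r = 0.0

    if fold_up >= 1.0 + threshold and r >= corr_threshold:
        return APPResult(protein_id, fold_up, "positive", r)
    if fold_down <= 1.0 - threshold and r <= -corr_threshold:
        return APPResult(protein_id, fold_down, "negative", r)
    return APPResult(protein_id, fold_up, "none", r)


def classify_all(
    matrix: ConcentrationMatrix,
    apr_call: APRCall,
    threshold: float = DEFAULT_APP_THRESHOLD,
    corr_threshold: float = DEFAULT_CORR_THRESHOLD,
) -> pd.DataFrame:
    """Classify every protein of one donor; returns a tidy result table."""
    samples = matrix.donor_samples(apr_call.donor_id)
    tps = [matrix.metadata[s].timepoint_index for s in samples]
    rows = []
    for pid in matrix.protein_ids:
        traj = pd.Series(matrix.values.loc[pid, samples].values, index=tps)
        res = classify_app(
            traj, apr_call, threshold=threshold, corr_threshold=corr_threshold,
            protein_id=pid,
        )
        if res is None:
            continue
        rows.append(
            {
                "protein_id": res.protein_id,
                "app_class": res.app_class,
                "fold_change_at_peak": res.fold_change_at_peak,
                "hallmark_correlation": res.hallmark_correlation,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "protein_id",
            "app_class",
            "fold_change_at_peak",
            "hallmark_correlation",
        ],
    )


def apoa_saa_ratio(
    matrix: ConcentrationMatrix,
    apoa_ids: tuple[str, ...] = APOA_IDS,
    saa_ids: tuple[str, ...] = SAA_IDS,
) -> pd.Series:
    """Per-sample (APOA1+APOA2+APOA4) / (SAA1+SAA2) concentration ratio.

    A sensitive inflammation marker: apolipoproteins A leave the HDL
    particle while serum amyloid A enters it, so the ratio drops sharply
    at APR peaks.  Missing proteins contribute 0 to the sums; samples with
    zero SAA are returned as NaN (ratio undefined).
    """
    apoa = [p for p in apoa_ids if p in matrix.values.index]
    saa = [p for p in saa_ids if p in matrix.values.index]
    if not apoa or not saa:
        raise ValueError("need at least one APOA and one SAA protein present")
    num = matrix.values.reindex(list(apoa_ids)).fillna(0.0).sum(axis=0)
    den = matrix.values.reindex(list(saa_ids)).fillna(0.0).sum(axis=0)
    undefined = den == 0
    if undefined.any():
        warnings.warn(
            f"APOA/SAA ratio undefined for {int(undefined.sum())} sample(s) "
            "(zero SAA)",
            stacklevel=2,
        )
    return (num / den.replace(0.0, np.nan)).rename("apoa_saa_ratio")
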