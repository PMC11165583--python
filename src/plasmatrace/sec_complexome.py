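"""SEC complexome profiling: MW calibration, elution peaks, coelution groups.

Size-exclusion chromatography separates native plasma proteins by
hydrodynamic size, larger species eluting earlier.  A log-linear calibration
fitted on gel-filtration standards,

    log10(MW kDa) = a + b * fraction_index,   b < 0,

converts a protein's elution position to an *apparent* molecular weight.
Apparent MW well above the monomer MW flags incorporation into a complex
(oligomer ratio = apparent / monomer).  Proteins whose per-fraction
intensity profiles correlate near-perfectly and elute at compatible MWs are
grouped into putative complexes (connected components of the coelution
graph), the signature by which stoichiometric assemblies such as fibrinogen
A2B2G2 or the inter-alpha-trypsin inhibitor (IaI) reveal themselves.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_MW_RANGE = (10.0, 3000.0)  # kDa
DEFAULT_PEAK_REL_HEIGHT = 0.1
DEFAULT_COELUTION_THRESHOLD = 0.9
DEFAULT_MW_TOLERANCE = 0.2  # relative
DEFAULT_OLIGOMER_FLAG_RATIO = 2.0
MIN_SHARED_FRACTIONS = 4


class SecCalibrationError(ValueError):
    """The MW calibration cannot be fitted from the given calibrants."""


@dataclass(frozen=True)
class Calibrant:
    """One gel-filtration standard: known MW and observed peak fraction."""

    standard_id: str
    mw_kda: float
    peak_fraction: float


@dataclass
class FractionTable:
    """Protein x SEC-fraction intensity matrix for one run.

    Columns are integer fraction indices.  ``excluded_fractions`` marks
    fractions removed for quality reasons; all analysis operations ignore
    them.  Calibrant channels carry a ``STD_`` id prefix and are listed in
    ``calibrants`` with their known MWs.
    """

    intensities: pd.DataFrame
    excluded_fractions: frozenset[int] = frozenset()
    calibrants: list[Calibrant] = field(default_factory=list)
    void_fraction: int | None = None
    run_id: str = ""

    def __post_init__(self) -> None:
        self.intensities.columns = [int(c) for c in self.intensities.columns]
        if (self.intensities.values < 0).any():
            raise ValueError("fraction intensities must be >= 0")

    @property
    def fraction_indices(self) -> list[int]:
        return list(self.intensities.columns)

    @property
    def retained_fractions(self) -> list[int]:
        return [f for f in self.fraction_indices if f not in self.excluded_fractions]

    @property
    def protein_ids(self) -> list[str]:
        return [p for p in self.intensities.index if not str(p).startswith("STD_")]

    def profile(self, protein_id: str) -> pd.Series:
        """Intensity over retained fractions for one protein."""
        return self.intensities.loc[protein_id, self.retained_fractions]

    def drop_excluded(self) -> "FractionTable":
        """A copy with excluded fraction columns physically removed."""
        return FractionTable(
            intensities=self.intensities[self.retained_fractions].copy(),
            excluded_fractions=self.excluded_fractions,
            calibrants=list(self.calibrants),
            void_fraction=self.void_fraction,
            run_id=self.run_id,
        )

    def write(self, path: str | Path) -> None:
        out = self.intensities.copy()
        out.columns = [f"fraction_{int(c):03d}" for c in out.columns]
        out.to_csv(path, sep="\t", float_format="%.12g", index_label="protein_id")

    @classmethod
    def read(
        cls,
        path: str | Path,
        excluded_fractions: Iterable[int] = (),
        calibrants: Sequence[Calibrant] = (),
        void_fraction: int | None = None,
    ) -> "FractionTable":
        df = pd.read_csv(path, sep="\t", index_col="protein_id")
        df.columns = [int(str(c).replace("fraction_", "")) for c in df.columns]
        return cls(
            intensities=df,
            excluded_fractions=frozenset(excluded_fractions),
            calibrants=list(calibrants),
            void_fraction=void_fraction,
        )


@dataclass(frozen=True)
class MWCalibration:
    """Fitted log-linear fraction -> MW map with residual diagnostics."""

    intercept: float
    slope: float  # negative
    mw_range: tuple[float, float] = DEFAULT_MW_RANGE
    residuals: dict[str, float] = field(default_factory=dict)  # log10 kDa

    def __post_init__(self) -> None:
        if self.slope >= 0:
            raise SecCalibrationError(
                "calibration slope must be negative (MW decreases with fraction)"
            )

    def mw_at(self, fraction: float) -> float:
        return float(10.0 ** (self.intercept + self.slope * fraction))

    def fraction_at(self, mw_kda: float) -> float:
        return float((np.log10(mw_kda) - self.intercept) / self.slope)

    def in_range(self, mw_kda: float) -> bool:
        low, high = self.mw_range
        return low <= mw_kda <= high

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "intercept": self.intercept,
                    "slope": self.slope,
                    "mw_range": list(self.mw_range),
                    "residuals": self.residuals,
                },
                indent=1,
            )
        )


@dataclass
class ElutionProfile:
    """One protein's elution profile and its apparent-MW summary."""

    protein_id: str
    intensities: pd.Series  # over retained fractions
    apparent_mw: float
    peak_window: tuple[int, ...]
    secondary_peaks: list[float] = field(default_factory=list)  # kDa
    monomer_mw: float | None = None
    out_of_range: bool = False

    @property
    def oligomer_ratio(self) -> float | None:
        if self.monomer_mw is None:
            return None
        return self.apparent_mw / self.monomer_mw


def fit_mw_calibration(
    calibrants: Sequence[Calibrant],
    mw_range: tuple[float, float] = DEFAULT_MW_RANGE,
) -> MWCalibration:
    """OLS fit of log10(MW) on peak fraction over the standards.

    The void-volume marker must not be among the calibrants (it elutes at
    the exclusion limit, off the linear range).  A positive slope raises an
    error — it indicates a wrong column orientation.  Non-monotone
    calibrant ordering only warns, with residuals reported for inspection.
    """
    if len(calibrants) < 2 or len({c.peak_fraction for c in calibrants}) < 2:
        raise SecCalibrationError("need >= 2 calibrants at distinct fractions")
    ordered = sorted(calibrants, key=lambda c: c.peak_fraction)
    mws = [c.mw_kda for c in ordered]
    if any(b >= a for a, b in zip(mws, mws[1:])):
        warnings.warn(
            "calibrant MWs are not strictly decreasing with fraction; "
            "check standards",
            stacklevel=2,
        )
    x = np.array([c.peak_fraction for c in calibrants])
    y = np.log10([c.mw_kda for c in calibrants])
    if len(calibrants) == 2:
        slope = (y[1] - y[0]) / (x[1] - x[0])
        intercept = y[0] - slope * x[0]
    else:
        fit = stats.linregress(x, y)
        slope, intercept = float(fit.slope), float(fit.intercept)
    if slope >= 0:
        raise SecCalibrationError(
            "fitted slope is non-negative; calibrants increase in MW with "
            "fraction (wrong column orientation?)"
        )
    residuals = {
        c.standard_id: float(np.log10(c.mw_kda) - (intercept + slope * c.peak_fraction))
        for c in calibrants
    }
    return MWCalibration(
        intercept=float(intercept),
        slope=float(slope),
        mw_range=mw_range,
        residuals=residuals,
    )


def _main_peak_window(
    profile: pd.Series, rel_height: float
) -> tuple[list[int], list[list[int]]]:
    """Contiguous fractions around the global maximum above rel_height * max.

    Also returns the remaining above-threshold runs (secondary peaks).
    Contiguity is in retained-fraction order, so gaps left by excluded
    fractions do not split a peak.
    """
    vals = profile.values.astype(float)
    fractions = list(profile.index)
    imax = int(np.argmax(vals))
    thresh = rel_height * vals[imax]
    above = vals >= thresh
    runs: list[list[int]] = []
    current: list[int] = []
    for i, ok in enumerate(above):
        if ok and vals[i] > 0:
            current.append(i)
        elif current:
            runs.append(current)
            current = []
    if current:
        runs.append(current)
    main = next(r for r in runs if imax in r)
    secondary = [r for r in runs if r is not main]
    return [fractions[i] for i in main], [[fractions[i] for i in r] for r in secondary]


def estimate_apparent_mw(
    profile: pd.Series,
    calibration: MWCalibration,
    rel_height: float = DEFAULT_PEAK_REL_HEIGHT,
    estimator: str = "centroid",
) -> tuple[float, tuple[int, ...], list[float]]:
    """Apparent MW from the main elution peak of a profile.

    The main peak is the contiguous run of fractions around the global
    maximum with intensity above ``rel_height`` of the maximum.  With the
    default ``centroid`` estimator, the calibration is applied to the
    intensity-weighted centroid fraction of that window; ``mode`` uses the
    argmax fraction instead.  Secondary above-threshold peaks are returned
    as a list of their own centroid MWs.

    Returns ``(apparent_mw_kda, peak_window, secondary_peak_mws)``.
    """
    profile = profile.astype(float)
    if profile.empty or not (profile > 0).any():
        raise ValueError("all-zero profile: apparent MW undefined")
    window, secondary_runs = _main_peak_window(profile, rel_height)

    def _centroid_mw(fracs: list[int]) -> float:
        w = profile.loc[fracs]
        if estimator == "mode":
            pos = float(w.idxmax())
        elif estimator == "centroid":
            pos = float(np.average(list(map(float, fracs)), weights=w.values))
        else:
            raise ValueError(f"unknown estimator {estimator!r}")
        return calibration.mw_at(pos)

    apparent = _centroid_mw(window)
    secondary = [_centroid_mw(r) for r in secondary_runs]
    return apparent, tuple(window), secondary


def build_elution_profiles(
    table: FractionTable,
    calibration: MWCalibration,
    monomer_mws: dict[str, float] | None = None,
    rel_height: float = DEFAULT_PEAK_REL_HEIGHT,
    estimator: str = "centroid",
) -> dict[str, ElutionProfile]:
    """Estimate apparent MW for every (non-calibrant) protein in a run."""
    monomer_mws = monomer_mws or {}
    out: dict[str, ElutionProfile] = {}
    for pid in table.protein_ids:
        prof = table.profile(pid)
        if not (prof > 0).any():
            continue
        mw, window, secondary = estimate_apparent_mw(
            prof, calibration, rel_height=rel_height, estimator=estimator
        )
        out[pid] = ElutionProfile(
            protein_id=pid,
            intensities=prof,
            apparent_mw=mw,
            peak_window=window,
            secondary_peaks=secondary,
            monomer_mw=monomer_mws.get(pid),
            out_of_range=not calibration.in_range(mw),
        )
    return out


def coelution_score(profile_p: pd.Series, profile_q: pd.Series) -> float:
    """Pearson correlation of two elution profiles over shared fractions.

    Raises when fewer than :data:`MIN_SHARED_FRACTIONS` retained fractions
    are shared (score undefined).
    """
    shared = profile_p.index.intersection(profile_q.index)
    if len(shared) < MIN_SHARED_FRACTIONS:
        raise ValueError(
            f"only {len(shared)} shared fractions "
            f"(need >= {MIN_SHARED_FRACTIONS})"
        )
    p = profile_p.loc[shared].astype(float)
    q = profile_q.loc[shared].astype(float)
    if p.std() == 0 or q.std() == 0:
        return 0.0
    return float(np.corrcoef(p.values, q.values)[0, 1])


@dataclass(frozen=True)
class CoelutionGroup:
    """A putative complex: coeluting proteins and their consensus MW."""

    members: tuple[str, ...]
    group_mw: float  # median member apparent MW, kDa


def detect_coelution_groups(
    profiles: dict[str, ElutionProfile],
    score_threshold: float = DEFAULT_COELUTION_THRESHOLD,
    mw_tolerance: float = DEFAULT_MW_TOLERANCE,
) -> list[CoelutionGroup]:
    """Group proteins into putative complexes by profile coelution.

    Two proteins are linked when their elution profiles correlate at or
    above ``score_threshold`` AND their apparent MWs agree within
    ``mw_tolerance`` (relative to the larger).  Groups are the connected
    components of this graph; the group MW is the median member apparent
    MW.  Singleton proteins form their own groups.
    """
    pids = sorted(profiles)
    parent = {p: p for p in pids}

    def find(p: str) -> str:
        while parent[p] != p:
            parent[p] = parent[parent[p]]
            p = parent[p]
        return p

    for i, p in enumerate(pids):
        for q in pids[i + 1:]:
            a, b = profiles[p], profiles[q]
            mw_gap = abs(a.apparent_mw - b.apparent_mw) / max(
                a.apparent_mw, b.apparent_mw
            )
            if mw_gap > mw_tolerance:
                continue
            try:
                score = coelution_score(a.intensities, b.intensities)
            except ValueError:
                continue
            if score >= score_threshold:
                parent[find(p)] = find(q)

    clusters: dict[str, list[str]] = {}
    for p in pids:
        clusters.setdefault(find(p), []).append(p)
    groups = [
        CoelutionGroup(
            members=tuple(sorted(members)),
            group_mw=float(np.median([profiles[m].apparent_mw for m in members])),
        )
        for members in clusters.values()
    ]
    return sorted(groups, key=lambda g: g.members)


def flag_complex_bound(
    profile: ElutionProfile,
    ratio_threshold: float = DEFAULT_OLIGOMER_FLAG_RATIO,
) -> tuple[bool, float]:
    """Flag a protein as complex-bound from its oligomer ratio.

    The oligomer ratio is apparent MW / monomer MW; a ratio at or above
    ``ratio_threshold`` (default 2, i.e. at least dimeric apparent size)
    flags the protein as part of a larger assembly.
    """
    if profile.monomer_mw is None:
        raise ValueError(f"{profile.protein_id}: monomer MW unknown")
    ratio = profile.apparent_mw / profile.monomer_mw
    return ratio >= ratio_threshold, float(ratio)


def groups_to_frame(groups: list[CoelutionGroup]) -> pd.DataFrame:
    """Flatten coelution groups to a tidy table for TSV export."""
    rows = [
        {
            "group_index": i,
            "group_mw_kda": g.group_mw,
            "n_members": len(g.members),
            "members": ";".join(g.members),
        }
        for i, g in enumerate(groups)
    ]
    return pd.DataFrame(
        rows, columns=["group_index", "group_mw_kda", "n_members", "members"]
    )
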