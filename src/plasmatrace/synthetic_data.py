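"""Synthetic longitudinal plasma cohorts and SEC runs with known ground truth.

The generator emulates the statistical structure of a small longitudinal
plasma-proteomics study: a handful of donors sampled at 3-10 time points,
protein concentrations spanning roughly 2000 mg/dL (albumin) down to
~0.02 mg/dL, acute-phase response (APR) episodes that multiply positive
acute-phase proteins (APPs) and depress negative ones, and size-exclusion
chromatography (SEC) runs in which monomers and stoichiometric complexes
elute as Gaussian peaks across 66 collected fractions.

Three presets mirror the study design:

``healthy_control``
    two healthy donors (C1, C2), three monthly time points, no APR.
``p1_apr``
    one transplant patient sampled at 10 time points with two APR
    episodes peaking at T1 and T8.
``p2_apr``
    one transplant patient sampled at 5 time points with a single strong
    APR peaking at T2 (hallmark peaks: CRP 50 mg/dL, SAA1 300 mg/dL,
    SAA2 100 mg/dL).
``study``
    the union of the three, a 21-sample cohort.

All randomness flows through :class:`numpy.random.Generator` seeded with
PCG64, so identical seeds reproduce identical tables on any platform.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .quant_io import QuantTable, SampleMetadata

# ---------------------------------------------------------------------------
# domain types

APP_CLASSES = ("positive", "negative", "none")


@dataclass(frozen=True)
class ProteinSpec:
    """Ground-truth parameters of one simulated plasma protein."""

    protein_id: str
    monomer_mw: float  # kDa
    baseline_conc: float  # mg/dL
    app_class: str = "none"
    response_fold: float = 1.0  # concentration multiplier at the APR peak

    def __post_init__(self) -> None:
        if self.monomer_mw <= 0 or self.baseline_conc <= 0:
            raise ValueError(f"{self.protein_id}: MW and baseline must be positive")
        if self.app_class not in APP_CLASSES:
            raise ValueError(f"unknown app_class {self.app_class!r}")
        if self.app_class == "positive" and self.response_fold <= 1:
            raise ValueError(f"{self.protein_id}: positive APP needs fold > 1")
        if self.app_class == "negative" and self.response_fold >= 1:
            raise ValueError(f"{self.protein_id}: negative APP needs fold < 1")
        if self.app_class == "none" and self.response_fold != 1:
            raise ValueError(f"{self.protein_id}: non-APP needs fold == 1")


@dataclass(frozen=True)
class ComplexSpec:
    """A stoichiometric protein assembly and its SEC elution mass.

    ``condition_composition`` optionally swaps the member list between the
    ``healthy`` and ``inflamed`` states — used for HDL-particle remodeling,
    where serum amyloid A displaces apolipoproteins at the APR peak.  An
    empty member list for a state means the species is absent then.
    """

    complex_id: str
    members: tuple[tuple[str, int], ...]
    assembled_mw: float  # kDa
    condition_composition: Mapping[str, tuple[tuple[str, int], ...]] | None = None

    def members_for(self, state: str) -> tuple[tuple[str, int], ...]:
        if self.condition_composition and state in self.condition_composition:
            return tuple(self.condition_composition[state])
        return self.members

    def validate(self, monomer_mws: Mapping[str, float]) -> None:
        for state in ("healthy", "inflamed"):
            for pid, stoich in self.members_for(state):
                if stoich < 1:
                    raise ValueError(f"{self.complex_id}: stoichiometry must be >= 1")
                if pid in monomer_mws and self.assembled_mw < monomer_mws[pid]:
                    raise ValueError(
                        f"{self.complex_id}: assembled MW below monomer of {pid}"
                    )


@dataclass(frozen=True)
class APREvent:
    """One acute-phase episode: a unimodal multiplier peaking at 1.

    The multiplier follows a triangular pulse of the given half-width in
    time-point units; with the default ``width=1`` only the peak time point
    itself is perturbed, matching abrupt infection-driven spikes.
    """

    peak_timepoint: int
    width: int = 1

    def __post_init__(self) -> None:
        if self.width < 1:
            raise ValueError("width must be >= 1 time point")

    def multiplier(self, timepoint: int) -> float:
        return max(0.0, 1.0 - abs(timepoint - self.peak_timepoint) / self.width)


@dataclass(frozen=True)
class DonorDesign:
    """Sampling design for one donor."""

    donor_id: str
    n_timepoints: int
    condition: str  # 'healthy' or 'patient'
    apr_events: tuple[APREvent, ...] = ()

    def condition_at(self, timepoint: int) -> str:
        if self.condition == "healthy":
            return "healthy"
        return "pre_transplant" if timepoint == 0 else "post_transplant"

    def apr_multiplier(self, timepoint: int) -> float:
        if not self.apr_events:
            return 0.0
        return max(ev.multiplier(timepoint) for ev in self.apr_events)

    def is_apr_peak(self, timepoint: int) -> bool:
        return any(ev.multiplier(timepoint) == 1.0 for ev in self.apr_events)

    @property
    def peak_timepoints(self) -> set[int]:
        return {t for t in range(self.n_timepoints) if self.is_apr_peak(t)}


@dataclass(frozen=True)
class SpeciesTruth:
    """One eluting species in a SEC run: a monomer or an assembled complex."""

    species_id: str
    assembled_mw: float
    members: tuple[tuple[str, int], ...]


@dataclass
class TruthRecord:
    """Generator ground truth accompanying an emitted table."""

    concentrations: pd.DataFrame  # proteins x samples, mg/dL
    app_class: dict[str, str]
    response_fold: dict[str, float]
    monomer_mw: dict[str, float]
    species: list[SpeciesTruth] = field(default_factory=list)
    apparent_mw: dict[str, float] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "concentrations": {
                p: {s: float(v) for s, v in row.items()}
                for p, row in self.concentrations.iterrows()
            },
            "app_class": self.app_class,
            "response_fold": self.response_fold,
            "monomer_mw": self.monomer_mw,
            "species": [
                {
                    "species_id": sp.species_id,
                    "assembled_mw": sp.assembled_mw,
                    "members": [list(m) for m in sp.members],
                }
                for sp in self.species
            ],
            "apparent_mw": self.apparent_mw,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


@dataclass(frozen=True)
class StudyDesign:
    """A full preset: protein panel, complexes, and per-donor sampling."""

    name: str
    proteins: tuple[ProteinSpec, ...]
    complexes: tuple[ComplexSpec, ...]
    donors: tuple[DonorDesign, ...]
    #: per-donor baseline overrides (mg/dL), e.g. patients' pre-APR CRP
    baseline_overrides: Mapping[str, Mapping[str, float]] = field(
        default_factory=dict
    )

    def baseline(self, donor_id: str, protein_id: str) -> float:
        override = self.baseline_overrides.get(donor_id, {})
        if protein_id in override:
            return override[protein_id]
        return self._by_id[protein_id].baseline_conc

    @property
    def _by_id(self) -> dict[str, ProteinSpec]:
        return {p.protein_id: p for p in self.proteins}

    def true_concentration(
        self, donor: DonorDesign, protein: ProteinSpec, timepoint: int
    ) -> float:
        base = self.baseline(donor.donor_id, protein.protein_id)
        m = donor.apr_multiplier(timepoint)
        return base * (1.0 + (protein.response_fold - 1.0) * m)


# ---------------------------------------------------------------------------
# protein panel: (id, monomer MW kDa, healthy baseline mg/dL, class, fold)
#
# Baselines for the 22 calibration-anchor proteins equal the bundled
# reference table; hallmark and APP baselines/peaks follow the reported
# longitudinal concentrations (CRP/SAA/LRG1/S100/serpins/fibrinogen/HDL).

_PANEL: tuple[tuple[str, float, float, str, float], ...] = (
    # calibration anchors
    ("A2M", 163.0, 200.0, "none", 1.0),
    ("B2M", 12.0, 0.2, "none", 1.0),
    ("C1R", 80.0, 5.0, "none", 1.0),
    ("C2", 83.0, 2.5, "none", 1.0),
    ("C6", 105.0, 4.5, "none", 1.0),
    ("C9", 63.0, 6.0, "none", 1.0),
    ("CFP", 51.0, 2.0, "none", 1.0),
    ("CP", 122.0, 30.0, "none", 1.0),
    ("F10", 55.0, 1.0, "none", 1.0),
    ("F12", 78.0, 3.0, "none", 1.0),
    ("F2", 70.0, 10.0, "none", 1.0),
    ("F7", 50.0, 0.05, "none", 1.0),
    ("F8", 267.0, 0.015, "none", 1.0),
    ("F9", 52.0, 0.5, "none", 1.0),
    ("HP", 45.0, 100.0, "positive", 2.5),
    ("KLKB1", 71.0, 4.0, "none", 1.0),
    ("MB", 17.0, 0.005, "none", 1.0),
    ("MBL2", 26.0, 0.15, "none", 1.0),
    ("SERPINA1", 47.0, 150.0, "positive", 2.5),
    ("TFRC", 85.0, 0.2, "none", 1.0),
    ("TTR", 14.0, 25.0, "negative", 0.5),
    ("VWF", 250.0, 1.0, "none", 1.0),
    # most abundant protein, tops the dynamic range
    ("ALB", 66.0, 2000.0, "none", 1.0),
    # hallmark positive APPs
    ("CRP", 24.0, 0.3, "positive", 50.0),
    ("SAA1", 12.0, 0.7, "positive", 200.0),
    ("SAA2", 12.0, 0.05, "positive", 200.0),
    # hallmark negative APPs
    ("TF", 77.0, 250.0, "negative", 0.5),
    # additional (presumed) positive APPs
    ("LRG1", 38.0, 7.0, "positive", 50.0 / 7.0),
    ("S100A8", 11.0, 0.1, "positive", 50.0),
    ("S100A9", 13.0, 0.1, "positive", 50.0),
    ("LBP", 60.0, 0.6, "positive", 6.0),
    ("CD14", 40.0, 0.2, "positive", 3.0),
    ("FGA", 66.0, 100.0, "positive", 4.0),
    ("FGB", 52.0, 100.0, "positive", 4.0),
    ("FGG", 46.0, 100.0, "positive", 4.0),
    ("SERPINA3", 48.0, 25.0, "positive", 4.8),
    # additional (presumed) negative APPs
    ("SERPIND1", 57.0, 8.0, "negative", 0.6),
    ("SERPINA4", 49.0, 10.0, "negative", 0.6),
    ("ITIH1", 101.0, 50.0, "negative", 0.6),
    ("ITIH2", 106.0, 40.0, "negative", 0.6),
    ("AMBP", 39.0, 2.0, "negative", 0.6),
)

#: Default displaced fraction of apolipoprotein A mass at the APR peak;
#: sets the APOA negative response fold to 1 - delta.
HDL_DISPLACEMENT = 0.5

#: Patient pre-APR baselines where they differ from healthy donors, chosen so
#: hallmark peak concentrations and fold changes are simultaneously the
#: reported ones (CRP: 50-fold to 50 mg/dL; SAA1: >100-fold to 300 mg/dL;
#: SAA2: >100-fold to 100 mg/dL).
_PATIENT_BASELINES: dict[str, float] = {"CRP": 1.0, "SAA1": 1.5, "SAA2": 0.5}


def _build_proteins(hdl_displacement: float) -> tuple[ProteinSpec, ...]:
    apoa_fold = 1.0 - hdl_displacement
    apoa = (
        ("APOA1", 28.0, 130.0, "negative", apoa_fold),
        ("APOA2", 9.0, 35.0, "negative", apoa_fold),
        ("APOA4", 45.0, 15.0, "negative", apoa_fold),
    )
    return tuple(ProteinSpec(*row) for row in _PANEL + apoa)


def _build_complexes() -> tuple[ComplexSpec, ...]:
    return (
        ComplexSpec(
            "fibrinogen_A2B2G2",
            (("FGA", 2), ("FGB", 2), ("FGG", 2)),
            375.0,
        ),
        ComplexSpec("HP1-1_dimer", (("HP", 2),), 150.0),
        ComplexSpec("CRP_pentamer", (("CRP", 5),), 120.0),
        ComplexSpec("calprotectin", (("S100A8", 1), ("S100A9", 1)), 24.0),
        ComplexSpec(
            "IaI", (("ITIH1", 1), ("ITIH2", 1), ("AMBP", 1)), 225.0
        ),
        ComplexSpec("TTR_tetramer", (("TTR", 4),), 55.0),
        ComplexSpec("A2M_tetramer", (("A2M", 4),), 720.0),
        # SAA1 circulates as a ~70 kDa hexamer when not HDL-bound
        ComplexSpec(
            "SAA1_hexamer",
            (("SAA1", 6),),
            70.0,
            condition_composition={"inflamed": ()},
        ),
        # HDL remodeling: the healthy particle carries the structural
        # apolipoproteins; at the APR peak SAA1/SAA2 displace APOA mass and
        # the SAA-loaded particle elutes at a higher apparent mass.
        ComplexSpec(
            "HDL",
            (("APOA1", 2), ("APOA2", 2), ("APOA4", 1)),
            200.0,
            condition_composition={"inflamed": ()},
        ),
        ComplexSpec(
            "HDL_inflamed",
            (),
            300.0,
            condition_composition={
                "inflamed": (
                    ("APOA1", 1),
                    ("APOA2", 1),
                    ("APOA4", 1),
                    ("SAA1", 8),
                    ("SAA2", 4),
                ),
            },
        ),
    )


def _donors(name: str) -> tuple[DonorDesign, ...]:
    c1 = DonorDesign("C1", 3, "healthy")
    c2 = DonorDesign("C2", 3, "healthy")
    p1 = DonorDesign("P1", 10, "patient", (APREvent(1), APREvent(8)))
    p2 = DonorDesign("P2", 5, "patient", (APREvent(2),))
    table = {
        "healthy_control": (c1, c2),
        "p1_apr": (p1,),
        "p2_apr": (p2,),
        "study": (c1, c2, p1, p2),
    }
    return table[name]


PRESET_NAMES = ("healthy_control", "p1_apr", "p2_apr", "study")


def preset(name: str, hdl_displacement: float = HDL_DISPLACEMENT) -> StudyDesign:
    """Build a named study design with its protein panel and complexes."""
    if name not in PRESET_NAMES:
        raise ValueError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")
    proteins = _build_proteins(hdl_displacement)
    complexes = _build_complexes()
    mws = {p.protein_id: p.monomer_mw for p in proteins}
    for c in complexes:
        c.validate(mws)
    donors = _donors(name)
    overrides = {
        d.donor_id: dict(_PATIENT_BASELINES)
        for d in donors
        if d.condition == "patient"
    }
    return StudyDesign(
        name=name,
        proteins=proteins,
        complexes=complexes,
        donors=donors,
        baseline_overrides=overrides,
    )


# ---------------------------------------------------------------------------
# quantification-table generation


def _lognormal_factors(
    rng: np.random.Generator, cv: float, size: int | tuple[int, ...]
) -> np.ndarray:
    """Multiplicative log-normal noise with unit mean and the given CV."""
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv**2))
    return np.exp(rng.normal(-0.5 * sigma**2, sigma, size))


def generate_quant_table(
    design: StudyDesign | str,
    noise_cv: float = 0.1,
    calibration_inverse: tuple[float, float] = (1.0, 0.0),
    seed: int = 0,
    n_replicates: int = 1,
) -> tuple[QuantTable, TruthRecord]:
    """Emit a long-format LFQ table for a study design, with ground truth.

    The true concentration trajectory is
    ``c(p, t) = baseline * (1 + (response_fold - 1) * apr_multiplier(t))``;
    LFQ values are obtained by inverting the configured log10-log10
    calibration map (``log10 conc = intercept + slope * log10 LFQ``) and
    multiplying by unit-mean log-normal noise of the given CV.

    Parameters
    ----------
    design
        A :class:`StudyDesign` or preset name.
    noise_cv
        Coefficient of variation of multiplicative measurement noise.
    calibration_inverse
        ``(slope, intercept)`` of the forward calibration to invert;
        the default identity makes LFQ numerically equal concentration.
    seed
        PCG64 seed; identical seeds give identical tables.
    n_replicates
        Injection replicates per sample (run ids suffixed ``_r<i>``).
    """
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    if isinstance(design, str):
        design = preset(design)
    slope, intercept = calibration_inverse
    rng = np.random.default_rng(seed)

    sample_ids: list[str] = []
    metadata: dict[str, SampleMetadata] = {}
    conc_cols: dict[str, np.ndarray] = {}
    pids = [p.protein_id for p in design.proteins]

    rows: list[tuple[str, str, float]] = []
    for donor in design.donors:
        for t in range(donor.n_timepoints):
            sid = f"{donor.donor_id}_T{t}"
            sample_ids.append(sid)
            conc = np.array(
                [design.true_concentration(donor, p, t) for p in design.proteins]
            )
            conc_cols[sid] = conc
            lfq_clean = 10.0 ** ((np.log10(conc) - intercept) / slope)
            for r in range(n_replicates):
                run_id = sid if n_replicates == 1 else f"{sid}_r{r + 1}"
                metadata[run_id] = SampleMetadata(
                    run_id=run_id,
                    donor_id=donor.donor_id,
                    timepoint_index=t,
                    condition=donor.condition_at(t),
                    replicate_of=sid if n_replicates > 1 else None,
                )
                noise = _lognormal_factors(rng, noise_cv, len(pids))
                lfq = lfq_clean * noise
                rows.extend(zip(pids, [run_id] * len(pids), lfq))

    records = pd.DataFrame(rows, columns=["protein_id", "run_id", "quantity"])
    table = QuantTable(records=records, metadata=metadata)
    truth = TruthRecord(
        concentrations=pd.DataFrame(conc_cols, index=pids),
        app_class={p.protein_id: p.app_class for p in design.proteins},
        response_fold={p.protein_id: p.response_fold for p in design.proteins},
        monomer_mw={p.protein_id: p.monomer_mw for p in design.proteins},
    )
    return table, truth


# ---------------------------------------------------------------------------
# SEC run generation

#: Gel-filtration standards (Sigma kit) and the void-volume marker.
SEC_STANDARDS: tuple[tuple[str, float], ...] = (
    ("Carbonic Anhydrase", 29.0),
    ("Albumin", 66.0),
    ("Alcohol Dehydrogenase", 150.0),
    ("beta-Amylase", 200.0),
    ("Apoferritin", 443.0),
    ("Thyroglobulin", 669.0),
)

VOID_MARKER_ID = "Blue Dextran"

#: Fraction indices removed from analysis in the emulated experiment.
DEFAULT_EXCLUDED_FRACTIONS = frozenset({18, 21, 22, 31, 32, 50})

DEFAULT_N_FRACTIONS = 66
DEFAULT_PEAK_SIGMA = 1.5  # fractions
MW_RANGE_KDA = (10.0, 3000.0)


@dataclass(frozen=True)
class SecMwMap:
    """Log-linear MW <-> fraction map: log10(MW kDa) = a + b * fraction."""

    intercept: float
    slope: float  # negative: larger species elute earlier

    @classmethod
    def spanning(
        cls,
        n_fractions: int = DEFAULT_N_FRACTIONS,
        mw_range: tuple[float, float] = MW_RANGE_KDA,
    ) -> "SecMwMap":
        low, high = mw_range
        b = (np.log10(low) - np.log10(high)) / (n_fractions - 1)
        a = np.log10(high) - b * 1.0
        return cls(intercept=a, slope=b)

    def fraction_at(self, mw_kda: float) -> float:
        return (np.log10(mw_kda) - self.intercept) / self.slope

    def mw_at(self, fraction: float) -> float:
        return 10.0 ** (self.intercept + self.slope * fraction)


def _species_for_state(
    design: StudyDesign, state: str
) -> list[SpeciesTruth]:
    """Resolve the eluting species list for a condition state.

    Every protein belongs entirely to the first complex listing it for the
    state; proteins in no complex elute as monomers at their monomer MW.
    """
    species: list[SpeciesTruth] = []
    assigned: set[str] = set()
    for cx in design.complexes:
        members = cx.members_for(state)
        members = tuple((pid, s) for pid, s in members if pid not in assigned)
        if not members:
            continue
        species.append(SpeciesTruth(cx.complex_id, cx.assembled_mw, members))
        assigned.update(pid for pid, _ in members)
    for p in design.proteins:
        if p.protein_id not in assigned:
            species.append(
                SpeciesTruth(f"{p.protein_id}_monomer", p.monomer_mw, ((p.protein_id, 1),))
            )
    return species


def subset_design(design: StudyDesign, protein_ids: Sequence[str]) -> StudyDesign:
    """Restrict a design to a protein subset (e.g. one complex plus standards).

    Complexes are kept with only their retained members; complexes losing
    all members disappear.  Useful for focused SEC simulations of a single
    assembly.
    """
    keep = set(protein_ids)
    proteins = tuple(p for p in design.proteins if p.protein_id in keep)
    missing = keep - {p.protein_id for p in proteins}
    if missing:
        raise ValueError(f"unknown protein ids: {sorted(missing)}")
    complexes = []
    for cx in design.complexes:
        states = dict(cx.condition_composition or {})
        new_members = tuple((p, s) for p, s in cx.members if p in keep)
        new_states = {
            state: tuple((p, s) for p, s in members if p in keep)
            for state, members in states.items()
        }
        if new_members or any(new_states.values()):
            complexes.append(
                ComplexSpec(
                    cx.complex_id,
                    new_members,
                    cx.assembled_mw,
                    condition_composition=new_states or None,
                )
            )
    return StudyDesign(
        name=f"{design.name}_subset",
        proteins=proteins,
        complexes=tuple(complexes),
        donors=design.donors,
        baseline_overrides={
            d: {p: v for p, v in ov.items() if p in keep}
            for d, ov in design.baseline_overrides.items()
        },
    )


def generate_sec_run(
    design: StudyDesign | str,
    timepoint: int,
    donor_id: str | None = None,
    n_fractions: int = DEFAULT_N_FRACTIONS,
    noise_cv: float = 0.0,
    seed: int = 0,
    peak_sigma: float = DEFAULT_PEAK_SIGMA,
    excluded_fractions: frozenset[int] | set[int] | None = None,
    drop_excluded: bool = False,
    mw_map: SecMwMap | None = None,
):
    """Emit one SEC fraction table (proteins x fractions) with ground truth.

    Each species present at the requested time point elutes as a Gaussian
    peak (sd ``peak_sigma`` fractions) centered at the fraction its
    assembled MW maps to under the log-linear MW calibration; each member
    protein's channel integrates to that protein's total concentration.
    The six gel-filtration standards and a void marker are emitted as
    annotated calibrant channels.

    ``excluded_fractions`` marks poor-quality fractions that downstream
    analysis must ignore (e.g. ``DEFAULT_EXCLUDED_FRACTIONS``); by default
    none are marked.  With ``drop_excluded`` the columns are physically
    removed as well.

    Returns ``(FractionTable, TruthRecord)``.
    """
    from .sec_complexome import Calibrant, FractionTable  # local: avoid cycle

    if isinstance(design, str):
        design = preset(design)
    if n_fractions < 10:
        raise ValueError("n_fractions must be >= 10")
    if donor_id is None:
        donor_id = design.donors[0].donor_id
    donors = {d.donor_id: d for d in design.donors}
    if donor_id not in donors:
        raise ValueError(f"donor {donor_id!r} not in design {design.name!r}")
    donor = donors[donor_id]
    if not 0 <= timepoint < donor.n_timepoints:
        raise ValueError(
            f"timepoint {timepoint} outside design for donor {donor_id} "
            f"(0..{donor.n_timepoints - 1})"
        )
    if mw_map is None:
        mw_map = SecMwMap.spanning(n_fractions)
    rng = np.random.default_rng(seed)

    state = "inflamed" if donor.is_apr_peak(timepoint) else "healthy"
    species = _species_for_state(design, state)
    conc = {
        p.protein_id: design.true_concentration(donor, p, timepoint)
        for p in design.proteins
    }

    fractions = np.arange(1, n_fractions + 1)
    profiles: dict[str, np.ndarray] = {
        p.protein_id: np.zeros(n_fractions) for p in design.proteins
    }
    apparent: dict[str, float] = {}
    for sp in species:
        center = mw_map.fraction_at(sp.assembled_mw)
        shape = np.exp(-0.5 * ((fractions - center) / peak_sigma) ** 2)
        shape /= shape.sum()
        for pid, _stoich in sp.members:
            profiles[pid] += conc[pid] * shape
            apparent[pid] = sp.assembled_mw

    matrix = pd.DataFrame(profiles, index=fractions).T
    if noise_cv > 0:
        matrix = matrix * _lognormal_factors(rng, noise_cv, matrix.shape)

    calibrants = [
        Calibrant(std_id, mw, float(mw_map.fraction_at(mw)))
        for std_id, mw in SEC_STANDARDS
    ]
    # calibrant channels emitted at fixed amplitude
    for cal in calibrants:
        shape = np.exp(-0.5 * ((fractions - cal.peak_fraction) / peak_sigma) ** 2)
        matrix.loc[f"STD_{cal.standard_id}"] = 100.0 * shape / shape.sum()
    void_fraction = 2
    matrix.loc[f"STD_{VOID_MARKER_ID}"] = 0.0
    matrix.loc[f"STD_{VOID_MARKER_ID}", void_fraction] = 100.0

    if excluded_fractions is None:
        excluded_fractions = frozenset()
    excluded = set(excluded_fractions) & set(fractions.tolist())
    table = FractionTable(
        intensities=matrix,
        excluded_fractions=frozenset(excluded),
        calibrants=calibrants,
        void_fraction=void_fraction,
        run_id=f"{donor_id}_T{timepoint}_SEC",
    )
    if drop_excluded:
        table = table.drop_excluded()

    truth = TruthRecord(
        concentrations=pd.DataFrame(
            {f"{donor_id}_T{timepoint}": pd.Series(conc)}
        ),
        app_class={p.protein_id: p.app_class for p in design.proteins},
        response_fold={p.protein_id: p.response_fold for p in design.proteins},
        monomer_mw={p.protein_id: p.monomer_mw for p in design.proteins},
        species=species,
        apparent_mw=apparent,
    )
    return table, truth
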