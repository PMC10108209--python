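"""Seeded synthetic data with the statistical structure the analyses assume.

Three generator families mirror the three input families of the pipeline:

* reflectance spectra — floral-part archetypes built as a baseline plus a
  sum of Gaussian reflectance peaks, with additive i.i.d. measurement noise
  clipped to [0, 1]; the defaults emulate the three distinctly colored
  regions of a caper flower (UV-absorbing white petals, a dimmer green
  nectary-access patch, and pink-magenta stamen filaments), seven flowers
  per part;
* emission matrices — per-compound mean emission rates with multiplicative
  floral-part effects, drawn from a mean-parameterized gamma (or lognormal)
  law with per-compound overdispersion; the default sampling design is the
  intrafloral one (calyx+gynoecium n=4, corolla n=5, nectar n=5, stamens
  n=6);
* visit logs — homogeneous Poisson event streams per (taxon, diel period)
  with given rates in visits per flower per hour, over overnight recording
  sessions.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, timedelta

import numpy as np
import pandas as pd

from .colorimetry import WORKING_GRID, Spectrum
from .visitation import (DEFAULT_PERIODS, ObservationSession, VisitEvent,
                         _period_windows)
from .volatilomics import EmissionMatrix, PeakTable

__all__ = [
    "PartArchetype",
    "SpectraDesign",
    "CompoundSpec",
    "EmissionDesign",
    "VisitDesign",
    "gen_reflectance_set",
    "gen_emission_matrix",
    "gen_peak_table",
    "gen_visit_log",
    "default_spectra_design",
    "default_emission_design",
    "default_visit_design",
]


# ---------------------------------------------------------------------------
# Reflectance spectra
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PartArchetype:
    """Mean reflectance curve of one floral part: baseline + Gaussian peaks."""

    label: str
    baseline: float
    peaks: tuple[tuple[float, float, float], ...] = ()  # (center nm, height, width nm)

    def curve(self, grid: np.ndarray) -> np.ndarray:
        r = np.full_like(grid, self.baseline, dtype=float)
        for center, height, width in self.peaks:
            r += height * np.exp(-((grid - center) ** 2) / (2.0 * width ** 2))
        return np.clip(r, 0.0, 1.0)


@dataclass
class SpectraDesign:
    part_archetypes: list[PartArchetype]
    n_flowers: int = 7
    noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_flowers < 1:
            raise ValueError("n_flowers must be >= 1")
        for a in self.part_archetypes:
            params = [a.baseline, *np.ravel([list(p) for p in a.peaks])] \
                if a.peaks else [a.baseline]
            if not np.all(np.isfinite(params)):
                raise ValueError(f"non-finite parameters in archetype {a.label!r}")


def default_spectra_design(seed: int = 0, noise_sd: float = 0.02,
                           n_flowers: int = 7) -> SpectraDesign:
    """Three-part caper-flower design: white petals, green nectary-access
    patch, pink-magenta stamens; all UV-absorbing."""
    archetypes = [
        # broad high plateau above ~400 nm: bright, weakly chromatic
        PartArchetype("white_petal", baseline=0.06,
                      peaks=((420.0, 0.30, 60.0), (540.0, 0.35, 90.0),
                             (660.0, 0.45, 90.0))),
        # narrow mid-wavelength band: dim but strongly chromatic
        PartArchetype("green_petal", baseline=0.02,
                      peaks=((555.0, 0.55, 45.0),)),
        # pink-magenta: blue plus long-wavelength reflectance
        PartArchetype("stamen", baseline=0.05,
                      peaks=((440.0, 0.30, 40.0), (670.0, 0.45, 60.0))),
    ]
    return SpectraDesign(archetypes, n_flowers=n_flowers, noise_sd=noise_sd,
                         seed=seed)


def gen_reflectance_set(design: SpectraDesign,
                        grid: np.ndarray = WORKING_GRID) -> list[Spectrum]:
    """One spectrum per flower x part archetype, with i.i.d. noise."""
    rng = np.random.default_rng(design.seed)
    out = []
    for i in range(design.n_flowers):
        for arch in design.part_archetypes:
            r = arch.curve(grid)
            if design.noise_sd > 0:
                r = r + rng.normal(0.0, design.noise_sd, size=grid.size)
            out.append(Spectrum(f"flower{i + 1}", arch.label, grid.copy(),
                                np.clip(r, 0.0, 1.0)))
    return out


# ---------------------------------------------------------------------------
# Emission matrices and peak tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CompoundSpec:
    name: str
    biosynthetic_class: str
    baseline_er: float  # ng per flower per hour

    def __post_init__(self) -> None:
        if self.baseline_er <= 0:
            raise ValueError(f"baseline ER of {self.name!r} must be > 0")


@dataclass
class EmissionDesign:
    compounds: list[CompoundSpec]
    n_per_part: dict[str, int]
    part_effects: dict[tuple[str, str], float] = field(default_factory=dict)
    dispersion: float | dict[str, float] = 0.3
    law: str = "gamma"  # or "lognormal"
    seed: int = 0

    def __post_init__(self) -> None:
        disp = (self.dispersion.values() if isinstance(self.dispersion, dict)
                else [self.dispersion])
        if any(d < 0 for d in disp):
            raise ValueError("dispersion must be >= 0")
        if self.law not in ("gamma", "lognormal"):
            raise ValueError(f"unknown law {self.law!r}")
        parts = set(self.n_per_part)
        for (comp, part) in self.part_effects:
            if part not in parts:
                raise ValueError(f"part effect references unknown part {part!r}")
            if comp not in {c.name for c in self.compounds}:
                raise ValueError(f"part effect references unknown compound "
                                 f"{comp!r}")

    def dispersion_of(self, compound: str) -> float:
        if isinstance(self.dispersion, dict):
            return self.dispersion[compound]
        return self.dispersion


#: Representative compounds of the caper floral headspace with
#: baseline emission rates (ng per flower per hour) of the right magnitude.
_DEFAULT_COMPOUNDS = [
    CompoundSpec("(E)-beta-Ocimene", "monoterpenes", 1200.0),
    CompoundSpec("Linalool", "monoterpenes", 500.0),
    CompoundSpec("Butyl aldoxime, 3-methyl-, syn-", "nitrogenous", 600.0),
    CompoundSpec("Butyl aldoxime, 2-methyl-, syn-", "nitrogenous", 450.0),
    CompoundSpec("Benzyl nitrile", "nitrogenous", 70.0),
    CompoundSpec("Methyl benzoate", "benzenoids", 250.0),
    CompoundSpec("Benzyl alcohol", "benzenoids", 80.0),
    CompoundSpec("Isoamyl acetate", "aliphatics", 75.0),
]

#: Intrafloral sampling design: calyx+gynoecium, corolla, nectar, stamens.
_DEFAULT_PARTS = {"calyx_gynoecium": 4, "corolla": 5, "nectar": 5, "stamens": 6}


def default_emission_design(seed: int = 0,
                            part_effects: dict[tuple[str, str], float] | None = None,
                            dispersion: float = 0.3) -> EmissionDesign:
    """Intrafloral design over representative caper-headspace compounds.

    Default part effects concentrate nitrogenous and monoterpene emissions
    in the corolla and stamens, mirroring the measured intrafloral pattern.
    """
    if part_effects is None:
        part_effects = {}
        for spec in _DEFAULT_COMPOUNDS:
            if spec.biosynthetic_class in ("nitrogenous", "monoterpenes"):
                part_effects[(spec.name, "calyx_gynoecium")] = 0.15
                part_effects[(spec.name, "nectar")] = 0.3
    return EmissionDesign(list(_DEFAULT_COMPOUNDS), dict(_DEFAULT_PARTS),
                          part_effects, dispersion=dispersion, seed=seed)


#: Below this dispersion the generator returns the mean exactly.
_DISPERSION_FLOOR = 1e-8


def gen_emission_matrix(design: EmissionDesign) -> EmissionMatrix:
    """Draw a samples x compounds ER matrix from the design's law.

    Gamma law: shape = 1/dispersion, scale = mean * dispersion, so the cell
    mean is baseline x part effect and the squared coefficient of variation
    equals the dispersion. Lognormal uses the same mean and variance.
    """
    rng = np.random.default_rng(design.seed)
    parts = []
    for part, n in design.n_per_part.items():
        parts += [part] * n
    names = [c.name for c in design.compounds]
    rows = []
    for i, part in enumerate(parts):
        row = []
        for spec in design.compounds:
            mean = spec.baseline_er * design.part_effects.get(
                (spec.name, part), 1.0)
            disp = design.dispersion_of(spec.name)
            if disp < _DISPERSION_FLOOR:
                row.append(mean)
            elif design.law == "gamma":
                row.append(rng.gamma(1.0 / disp, mean * disp))
            else:  # lognormal with matching mean and variance
                sigma2 = np.log1p(disp)
                mu = np.log(mean) - sigma2 / 2.0
                row.append(rng.lognormal(mu, np.sqrt(sigma2)))
        rows.append(row)
    index = pd.Index([f"s{i + 1:02d}" for i in range(len(parts))],
                     name="sample")
    values = pd.DataFrame(rows, index=index, columns=names)
    meta = pd.DataFrame({"part": parts}, index=index)
    cmeta = pd.DataFrame(
        {"biosynthetic_class": [c.biosynthetic_class for c in design.compounds]},
        index=pd.Index(names, name="compound"))
    return EmissionMatrix(values, "ng_fl_h", meta, cmeta)


def gen_peak_table(matrix: EmissionMatrix,
                   is_mass_ng: float = 1.0,
                   duration_h: float = 1.5,
                   is_area: float = 1.0e6) -> PeakTable:
    """Invert the emission-rate formula to raw peak areas (round-trip exact).

    area_compound = ER x duration x basis / IS mass x area_IS, so applying
    `emission_rate` to the result reproduces the input matrix.
    """
    if is_mass_ng <= 0 or duration_h <= 0:
        raise ValueError("is_mass_ng and duration_h must be > 0")
    if matrix.units != "ng_fl_h":
        raise ValueError("peak-table inversion expects per-flower units")
    areas = matrix.values * duration_h / is_mass_ng * is_area
    meta = matrix.sample_meta.copy()
    meta["is_area"] = is_area
    meta["is_mass_ng"] = is_mass_ng
    meta["duration_h"] = duration_h
    return PeakTable(areas, meta, matrix.compound_meta)


# ---------------------------------------------------------------------------
# Visit logs
# ---------------------------------------------------------------------------

@dataclass
class VisitDesign:
    rate_table: dict[tuple[str, str], float]  # (taxon, period) -> visits/fl/h
    sessions: list[ObservationSession]
    periods: dict = field(default_factory=lambda: dict(DEFAULT_PERIODS))
    seed: int = 0

    def __post_init__(self) -> None:
        if any(r < 0 for r in self.rate_table.values()):
            raise ValueError("rates must be >= 0")
        for (_, period) in self.rate_table:
            if period not in self.periods:
                raise ValueError(f"rate references unknown period {period!r}")


def default_visit_design(seed: int = 0,
                         n_sessions: int = 6,
                         n_flowers: int = 1,
                         first_night: datetime = datetime(2014, 7, 23, 20, 0),
                         ) -> VisitDesign:
    """Overnight camera sessions (20:00-10:00) at the recorded caper
    visitation rates: honeybees dominant at dusk and morning, carpenter
    bees in the morning, a hawkmoth at night."""
    rates = {
        ("Apis mellifera", "dusk"): 30.50,
        ("Apis mellifera", "morning"): 5.90,
        ("Xylocopa olivieri", "morning"): 0.33,
        ("Xylocopa violacea", "dusk"): 0.17,
        ("Xylocopa violacea", "morning"): 0.97,
        ("Theretra alecto", "night"): 0.17,
        ("Theretra alecto", "morning"): 0.03,
        ("Eupeodes corollae", "morning"): 0.03,
    }
    sessions = []
    for i in range(n_sessions):
        start = first_night + timedelta(days=2 * i)
        sessions.append(ObservationSession(
            f"night{i + 1}", start, start + timedelta(hours=14),
            n_flowers=n_flowers, plant_id=f"plant{i % 3 + 1}"))
    return VisitDesign(rates, sessions, seed=seed)


def gen_visit_log(design: VisitDesign) -> list[VisitEvent]:
    """Homogeneous Poisson visits per (taxon, period) within each session.

    Event counts per session x taxon x period are Poisson with mean
    rate x flower-hours; timestamps are uniform within the period window.
    """
    rng = np.random.default_rng(design.seed)
    events: list[VisitEvent] = []
    for s in design.sessions:
        for (taxon, period), rate in sorted(design.rate_table.items()):
            if rate == 0:
                continue
            for a, b in _period_windows(s, design.periods[period]):
                hours = (b - a).total_seconds() / 3600.0
                n = rng.poisson(rate * hours * s.n_flowers)
                if n == 0:
                    continue
                offsets = np.sort(rng.uniform(0.0, hours, size=n))
                flowers = rng.integers(1, s.n_flowers + 1, size=n)
                for off, fl in zip(offsets, flowers):
                    ts = a + timedelta(hours=float(off))
                    events.append(VisitEvent(ts, taxon,
                                             f"{s.session_id}_f{fl}",
                                             s.session_id))
    events.sort(key=lambda e: (e.session_id, e.timestamp, e.taxon))
    return events
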