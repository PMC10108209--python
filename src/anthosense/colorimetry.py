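"""Floral reflectance colorimetry for pollinator visual systems.

Models photoreceptor stimulation by reflected light for the visual systems
of four flower-visitor guilds (nocturnal and diurnal hawkmoths, bees, and
swallowtail butterflies), maps stimuli into the geometry appropriate to each
system (Maxwell triangle, bee color hexagon, tetrahedral space), and provides
the repeated-measures statistics used to compare floral parts.

The chain per stimulus is: quantum catch (reflectance x sensitivity x
illuminant, integrated over 300-700 nm) -> von Kries normalization against
the adapting background -> color-space coordinates -> saturation, defined as
the Euclidean distance of the locus from the achromatic center.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "WORKING_GRID",
    "Spectrum",
    "Illuminant",
    "VisualSystem",
    "ColorLocus",
    "PairedTestResult",
    "load_spectra",
    "mean_brightness",
    "brightness_test",
    "receptor_sensitivity",
    "quantum_catch",
    "to_color_locus",
    "saturation_test",
    "visual_system",
    "flat_illuminant",
    "flat_background",
]

#: 1-nm working grid covering the UV-visible range relevant to insect vision.
WORKING_GRID = np.arange(300.0, 701.0, 1.0)

# Reflectance slightly above 1 is tolerated (sensor artifacts) up to this cap.
_REFLECTANCE_CAP = 1.2
_NEGATIVE_TOL = 0.0


@dataclass
class Spectrum:
    """A single reflectance spectrum for one flower x floral part.

    Parameters
    ----------
    flower_id : str
        Identifier of the individual flower.
    part : str
        Floral-part label (e.g. ``white_petal``, ``green_petal``,
        ``stamen``, ``background``).
    wavelengths : ndarray
        Strictly increasing wavelength grid in nm, covering [300, 700].
    reflectance : ndarray
        Reflectance fraction per wavelength, in [0, 1.2].
    """

    flower_id: str
    part: str
    wavelengths: np.ndarray
    reflectance: np.ndarray

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.reflectance = np.asarray(self.reflectance, dtype=float)
        if self.wavelengths.size == 0:
            raise ValueError("empty wavelength grid")
        if self.wavelengths.size != self.reflectance.size:
            raise ValueError("wavelengths and reflectance differ in length")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelength grid must be strictly increasing")
        if self.wavelengths[0] > 300.0 or self.wavelengths[-1] < 700.0:
            raise ValueError(
                f"grid [{self.wavelengths[0]}, {self.wavelengths[-1]}] does not "
                "cover [300, 700] nm"
            )
        if np.any(~np.isfinite(self.reflectance)):
            raise ValueError("non-finite reflectance values")
        if np.any(self.reflectance < -_NEGATIVE_TOL):
            bad = np.where(self.reflectance < -_NEGATIVE_TOL)[0]
            raise ValueError(
                f"negative reflectance at wavelengths "
                f"{self.wavelengths[bad][:5].tolist()} (flower={self.flower_id}, "
                f"part={self.part})"
            )
        if np.any(self.reflectance > _REFLECTANCE_CAP):
            raise ValueError("reflectance exceeds tolerated cap of 1.2")
        if np.any(self.reflectance > 1.0):
            warnings.warn(
                f"reflectance > 1 in flower={self.flower_id} part={self.part}; "
                "tolerated as a sensor artifact",
                stacklevel=2,
            )

    def on_grid(self, grid: np.ndarray = WORKING_GRID) -> "Spectrum":
        """Linearly interpolate onto `grid` (values at original knots kept)."""
        if self.wavelengths.size == grid.size and np.allclose(self.wavelengths, grid):
            return self
        refl = np.interp(grid, self.wavelengths, self.reflectance)
        return Spectrum(self.flower_id, self.part, grid.copy(), refl)


@dataclass
class Illuminant:
    """Relative spectral photon flux of the adapting light."""

    name: str
    wavelengths: np.ndarray
    flux: np.ndarray

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.flux = np.asarray(self.flux, dtype=float)
        if np.any(self.flux < 0):
            raise ValueError("illuminant flux must be nonnegative")

    def on_grid(self, grid: np.ndarray = WORKING_GRID) -> np.ndarray:
        return np.interp(grid, self.wavelengths, self.flux)


def flat_illuminant(grid: np.ndarray = WORKING_GRID) -> Illuminant:
    """Equal-photon (flat) illuminant, the default adapting light."""
    return Illuminant("equal_photon", grid.copy(), np.ones_like(grid))


def flat_background(reflectance: float = 1.0,
                    grid: np.ndarray = WORKING_GRID) -> Spectrum:
    """Ideal achromatic background with constant reflectance."""
    return Spectrum("background", "background", grid.copy(),
                    np.full_like(grid, float(reflectance)))


# ---------------------------------------------------------------------------
# Receptor sensitivity template
# ---------------------------------------------------------------------------

def receptor_sensitivity(lambda_max: float,
                         grid: np.ndarray = WORKING_GRID,
                         beta_band: bool = False) -> np.ndarray:
    """Visual-pigment absorbance template for an A1 chromophore.

    Evaluates the rhodopsin alpha-band template of Govardovskii and
    colleagues (the standard nomogram used when only a receptor's peak
    wavelength is known) on `grid`, peak-normalized to 1. The weak
    beta-band (UV shoulder) can optionally be added before normalization.

    Parameters
    ----------
    lambda_max : float
        Wavelength of maximal sensitivity, nm; must lie in [300, 700].
    grid : ndarray
        Wavelengths (nm) at which to evaluate the curve.
    beta_band : bool
        Add the beta-band term (off by default).
    """
    if not 300.0 <= lambda_max <= 700.0:
        raise ValueError(f"lambda_max {lambda_max} outside [300, 700] nm")
    grid = np.asarray(grid, dtype=float)
    x = lambda_max / grid
    a = 0.8795 + 0.0459 * np.exp(-((lambda_max - 300.0) ** 2) / 11940.0)
    alpha = 1.0 / (
        np.exp(69.7 * (a - x))
        + np.exp(28.0 * (0.922 - x))
        + np.exp(-14.9 * (1.104 - x))
        + 0.674
    )
    s = alpha
    if beta_band:
        lmb = 189.0 + 0.315 * lambda_max
        b = -40.5 + 0.195 * lambda_max
        beta = 0.26 * np.exp(-(((grid - lmb) / b) ** 2))
        s = alpha + beta
    return s / s.max()


@dataclass
class VisualSystem:
    """A named receptor set with sensitivity curves and a space geometry."""

    name: str
    receptor_names: list[str]
    lambda_max: list[float]
    sensitivities: np.ndarray  # (n_receptors, len(grid)), peak-normalized
    geometry: str  # triangle | hexagon | tetrahedron
    grid: np.ndarray = field(default_factory=lambda: WORKING_GRID.copy())

    def __post_init__(self) -> None:
        n = len(self.lambda_max)
        if self.geometry in ("triangle", "hexagon") and n != 3:
            raise ValueError(f"{self.geometry} geometry requires 3 receptors, got {n}")
        if self.geometry == "tetrahedron" and n != 4:
            raise ValueError(f"tetrahedron geometry requires 4 receptors, got {n}")
        if self.geometry not in ("triangle", "hexagon", "tetrahedron"):
            raise ValueError(f"unknown geometry {self.geometry!r}")


#: Receptor peak wavelengths (nm) of the four built-in visual systems.
RECEPTOR_PEAKS: dict[str, dict[str, float]] = {
    # Tobacco hornworm hawkmoth (ventral retina, trichromatic)
    "manduca": {"uv": 357.0, "blue": 450.0, "green": 520.0},
    # Honeybee / conserved hymenopteran trichromacy
    "apis": {"uv": 344.0, "blue": 436.0, "green": 544.0},
    # Swallowtail butterfly (five spectral receptor classes)
    "papilio": {"uv": 360.0, "violet": 400.0, "blue": 460.0,
                "green": 520.0, "red": 600.0},
    # Hummingbird hawkmoth (diurnal, trichromatic)
    "macroglossum": {"uv": 349.0, "blue": 440.0, "green": 521.0},
}

_DEFAULT_GEOMETRY = {
    "manduca": "triangle",
    "apis": "hexagon",
    "papilio": "tetrahedron",
    "macroglossum": "triangle",
}

# Tetrachromatic subset used for the swallowtail tetrahedron; the violet
# receptor is excluded by default (configurable via `receptors=`).
_PAPILIO_TETRA = ["uv", "blue", "green", "red"]


def visual_system(name: str,
                  geometry: str | None = None,
                  receptors: list[str] | None = None,
                  grid: np.ndarray = WORKING_GRID,
                  beta_band: bool = False) -> VisualSystem:
    """Build one of the built-in visual systems from its receptor peaks."""
    key = name.lower()
    if key not in RECEPTOR_PEAKS:
        raise KeyError(f"unknown visual system {name!r}; "
                       f"available: {sorted(RECEPTOR_PEAKS)}")
    peaks = RECEPTOR_PEAKS[key]
    geometry = geometry or _DEFAULT_GEOMETRY[key]
    if receptors is None:
        receptors = _PAPILIO_TETRA if key == "papilio" else list(peaks)
    lmax = [peaks[r] for r in receptors]
    sens = np.vstack([receptor_sensitivity(l, grid, beta_band) for l in lmax])
    return VisualSystem(key, list(receptors), lmax, sens, geometry, grid.copy())


# ---------------------------------------------------------------------------
# Spectra I/O
# ---------------------------------------------------------------------------

def load_spectra(path, dialect: str = "long",
                 grid: np.ndarray = WORKING_GRID) -> list[Spectrum]:
    """Read reflectance spectra from CSV and resample to the 1-nm grid.

    Two dialects are supported:

    * ``long`` — columns ``flower_id, part, wavelength, reflectance``.
    * ``wide`` — a ``wavelength`` column plus one column per sample named
      ``<flower_id>__<part>``.

    Input grids are linearly interpolated to 1-nm steps; values at the
    original knots are preserved exactly.
    """
    df = pd.read_csv(path)
    if dialect == "long":
        required = {"flower_id", "part", "wavelength", "reflectance"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"long-dialect CSV missing columns {sorted(missing)}")
        dup = df.duplicated(subset=["flower_id", "part", "wavelength"])
        if dup.any():
            raise ValueError(
                f"duplicate (flower, part, wavelength) rows at indices "
                f"{df.index[dup][:5].tolist()}"
            )
        neg = df["reflectance"] < -_NEGATIVE_TOL
        if neg.any():
            raise ValueError(
                f"negative reflectance in rows {df.index[neg][:10].tolist()}"
            )
        out = []
        for (fid, part), sub in df.groupby(["flower_id", "part"], sort=False):
            sub = sub.sort_values("wavelength")
            s = Spectrum(str(fid), str(part),
                         sub["wavelength"].to_numpy(),
                         sub["reflectance"].to_numpy())
            out.append(s.on_grid(grid))
        return out
    if dialect == "wide":
        if "wavelength" not in df.columns:
            raise ValueError("wide-dialect CSV requires a 'wavelength' column")
        wl = df["wavelength"].to_numpy(dtype=float)
        out = []
        for col in df.columns:
            if col == "wavelength":
                continue
            if "__" not in col:
                raise ValueError(
                    f"wide-dialect column {col!r} must be named '<flower>__<part>'"
                )
            fid, part = col.split("__", 1)
            refl = df[col].to_numpy(dtype=float)
            if np.any(refl < -_NEGATIVE_TOL):
                bad = np.where(refl < -_NEGATIVE_TOL)[0]
                raise ValueError(
                    f"negative reflectance in column {col!r}, rows {bad[:10].tolist()}"
                )
            out.append(Spectrum(fid, part, wl, refl).on_grid(grid))
        return out
    raise ValueError(f"unknown dialect {dialect!r} (use 'wide' or 'long')")


def write_spectra(spectra: list[Spectrum], path) -> None:
    """Write spectra as long-dialect CSV (inverse of `load_spectra`)."""
    rows = []
    for s in spectra:
        rows.append(pd.DataFrame({
            "flower_id": s.flower_id, "part": s.part,
            "wavelength": s.wavelengths, "reflectance": s.reflectance,
        }))
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Brightness
# ---------------------------------------------------------------------------

def mean_brightness(s: Spectrum) -> float:
    """Mean relative reflectance over the whole 300-700 nm range."""
    if s.reflectance.size == 0:
        raise ValueError("empty spectrum")
    return float(np.mean(s.reflectance))


@dataclass
class PairedTestResult:
    """Outcome of a repeated-measures comparison across floral parts."""

    method: str
    statistic: float
    df: tuple
    pvalue: float
    posthoc: pd.DataFrame  # columns: part_a, part_b, statistic, p_raw, p_adj

    def significant_pairs(self, alpha: float = 0.05) -> list[tuple[str, str]]:
        sig = self.posthoc[self.posthoc["p_adj"] < alpha]
        return list(zip(sig["part_a"], sig["part_b"]))


def _blocks(values: pd.DataFrame) -> pd.DataFrame:
    """Validate a complete flower x part block design."""
    if values.isna().any().any():
        missing = values.index[values.isna().any(axis=1)].tolist()
        raise ValueError(f"incomplete blocks for flowers {missing}")
    if values.shape[1] < 2:
        raise ValueError("need at least 2 parts")
    return values


def brightness_test(spectra: list[Spectrum]) -> PairedTestResult:
    """Friedman test of mean brightness across floral parts, paired by flower.

    Post hoc: pairwise Wilcoxon signed-rank tests, Bonferroni-adjusted.
    """
    rows = [(s.flower_id, s.part, mean_brightness(s)) for s in spectra]
    df = pd.DataFrame(rows, columns=["flower_id", "part", "brightness"])
    pivot = _blocks(df.pivot(index="flower_id", columns="part", values="brightness"))
    return _friedman_with_wilcoxon(pivot, value_name="brightness")


def _friedman_with_wilcoxon(pivot: pd.DataFrame, value_name: str) -> PairedTestResult:
    parts = list(pivot.columns)
    k, n = len(parts), len(pivot)
    cols = [pivot[p].to_numpy() for p in parts]
    if np.allclose(np.ptp(np.vstack(cols), axis=0), 0.0):
        q, p = 0.0, 1.0
    else:
        q, p = stats.friedmanchisquare(*cols)
    m = k * (k - 1) // 2
    ph = []
    for i in range(k):
        for j in range(i + 1, k):
            d = cols[i] - cols[j]
            if np.allclose(d, 0.0):
                w, pw = 0.0, 1.0
            else:
                w, pw = stats.wilcoxon(cols[i], cols[j])
            ph.append((parts[i], parts[j], float(w), float(pw),
                       float(min(1.0, pw * m))))
    posthoc = pd.DataFrame(ph, columns=["part_a", "part_b", "statistic",
                                        "p_raw", "p_adj"])
    return PairedTestResult(f"friedman+wilcoxon_bonferroni[{value_name}]",
                            float(q), (k - 1,), float(p), posthoc)


# ---------------------------------------------------------------------------
# Quantum catches and color loci
# ---------------------------------------------------------------------------

@dataclass
class ColorLocus:
    """Receptor catches and the derived position in color space."""

    flower_id: str
    part: str
    system: str
    geometry: str
    catches: np.ndarray            # raw quantum catches Q_i
    von_kries: np.ndarray          # q_i = Q_i / Q_i(background)
    coordinates: np.ndarray | None = None
    saturation: float | None = None


def quantum_catch(s: Spectrum,
                  vs: VisualSystem,
                  illuminant: Illuminant | None = None,
                  background: Spectrum | None = None) -> ColorLocus:
    """Photoreceptor quantum catches with von Kries normalization.

    Q_i = integral of R(lambda) S_i(lambda) I(lambda) d(lambda) (trapezoidal
    on the working grid); q_i = Q_i / Q_i(background), so the adapting
    background maps to q = 1 in every receptor.
    """
    grid = vs.grid
    illum = (illuminant or flat_illuminant(grid)).on_grid(grid)
    bg = (background or flat_background(1.0, grid)).on_grid(grid)
    s = s.on_grid(grid)
    q_raw = np.trapezoid(s.reflectance * vs.sensitivities * illum, grid, axis=1)
    q_bg = np.trapezoid(bg.reflectance * vs.sensitivities * illum, grid, axis=1)
    if np.any(q_bg <= 0):
        raise ValueError("background yields zero quantum catch in some receptor")
    return ColorLocus(s.flower_id, s.part, vs.name, vs.geometry,
                      q_raw, q_raw / q_bg)


_TRIANGLE_ANGLES = np.deg2rad([90.0, 210.0, 330.0])
_TRIANGLE_VERTICES = np.column_stack([np.cos(_TRIANGLE_ANGLES),
                                      np.sin(_TRIANGLE_ANGLES)])
# Regular tetrahedron with unit circumradius, centroid at the origin.
_TETRA_VERTICES = np.array([[1.0, 1.0, 1.0],
                            [1.0, -1.0, -1.0],
                            [-1.0, 1.0, -1.0],
                            [-1.0, -1.0, 1.0]]) / np.sqrt(3.0)


def to_color_locus(locus: ColorLocus, geometry: str | None = None) -> ColorLocus:
    """Map von Kries catches to coordinates and saturation.

    * triangle / tetrahedron — relative catches q_i / sum(q) are barycentric
      weights on vertices at unit distance from the achromatic center, so
      only catch ratios matter and a pure single-receptor stimulus sits at a
      vertex (saturation 1).
    * hexagon — receptor excitations E = q / (q + 1) (UV, blue, green order),
      x = (sqrt(3)/2)(E_G - E_UV), y = E_B - (E_UV + E_G)/2.

    Saturation is the Euclidean distance from the achromatic center.
    """
    geometry = geometry or locus.geometry
    q = np.asarray(locus.von_kries, dtype=float)
    if np.all(q == 0):
        raise ValueError("all-zero catch vector has no defined color locus")
    if geometry in ("triangle", "tetrahedron"):
        verts = _TRIANGLE_VERTICES if geometry == "triangle" else _TETRA_VERTICES
        if q.size != verts.shape[0]:
            raise ValueError(
                f"{geometry} needs {verts.shape[0]} receptors, got {q.size}")
        rel = q / q.sum()
        coords = rel @ verts
    elif geometry == "hexagon":
        if q.size != 3:
            raise ValueError("hexagon needs 3 receptors (UV, blue, green)")
        e = q / (q + 1.0)
        e_uv, e_b, e_g = e
        coords = np.array([np.sqrt(3.0) / 2.0 * (e_g - e_uv),
                           e_b - (e_uv + e_g) / 2.0])
    else:
        raise ValueError(f"unknown geometry {geometry!r}")
    sat = float(np.linalg.norm(coords))
    return ColorLocus(locus.flower_id, locus.part, locus.system, geometry,
                      locus.catches, locus.von_kries, coords, sat)


def color_loci(spectra: list[Spectrum],
               vs: VisualSystem,
               illuminant: Illuminant | None = None,
               background: Spectrum | None = None) -> list[ColorLocus]:
    """Convenience: quantum catch + space mapping for a set of spectra."""
    return [to_color_locus(quantum_catch(s, vs, illuminant, background))
            for s in spectra]


# ---------------------------------------------------------------------------
# Saturation statistics
# ---------------------------------------------------------------------------

def saturation_test(loci: list[ColorLocus]) -> PairedTestResult:
    """One-way repeated-measures ANOVA on arcsine-transformed saturation.

    Saturation values (proportions in [0, 1]) are arcsine-square-root
    transformed; marginal excursions above 1 are clipped with a warning.
    Sphericity is assessed and the Greenhouse-Geisser-corrected p-value is
    used when Mauchly's test rejects. Post hoc: pairwise paired t-tests with
    Bonferroni adjustment.
    """
    import pingouin as pg

    rows = [(l.flower_id, l.part, l.saturation) for l in loci]
    df = pd.DataFrame(rows, columns=["flower_id", "part", "saturation"])
    pivot = _blocks(df.pivot(index="flower_id", columns="part",
                             values="saturation"))
    vals = pivot.to_numpy()
    if np.any(vals > 1.0):
        warnings.warn("saturation > 1 clipped to 1 before arcsine transform",
                      stacklevel=2)
        vals = np.clip(vals, 0.0, 1.0)
    if np.any(vals < 0):
        raise ValueError("negative saturation")
    trans = pd.DataFrame(np.arcsin(np.sqrt(vals)), index=pivot.index,
                         columns=pivot.columns)
    parts = list(trans.columns)
    k = len(parts)

    part_means = trans.to_numpy().mean(axis=0)
    if np.allclose(part_means, part_means[0]):
        # no between-part variation: F = 0 by convention (avoids 0/0)
        f_stat, p, dfs = 0.0, 1.0, (k - 1, (k - 1) * (len(trans) - 1))
    else:
        long = trans.reset_index().melt(id_vars="flower_id", var_name="part",
                                        value_name="y")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            aov = pg.rm_anova(data=long, dv="y", within="part",
                              subject="flower_id", correction=True)
        row = aov.iloc[0]
        f_stat = float(row["F"])
        dfs = (float(row["ddof1"]), float(row["ddof2"]))
        cols = set(aov.columns)
        spherical = bool(row["sphericity"]) if "sphericity" in cols else True
        if not spherical and "p_GG_corr" in cols:
            p = float(row["p_GG_corr"])
        else:
            p = float(row["p_unc"])

    m = k * (k - 1) // 2
    ph = []
    for i in range(k):
        for j in range(i + 1, k):
            a, b = trans[parts[i]].to_numpy(), trans[parts[j]].to_numpy()
            if np.allclose(a, b):
                t, pt = 0.0, 1.0
            else:
                t, pt = stats.ttest_rel(a, b)
            ph.append((parts[i], parts[j], float(t), float(pt),
                       float(min(1.0, pt * m))))
    posthoc = pd.DataFrame(ph, columns=["part_a", "part_b", "statistic",
                                        "p_raw", "p_adj"])
    return PairedTestResult("rm_anova+paired_t_bonferroni[arcsine_saturation]",
                            f_stat, dfs, p, posthoc)


def colorimetry_table(spectra: list[Spectrum],
                      systems: list[str] | None = None) -> pd.DataFrame:
    """Tidy results table: one row per flower x part x visual system."""
    systems = systems or list(RECEPTOR_PEAKS)
    rows = []
    for name in systems:
        vs = visual_system(name)
        for s in spectra:
            loc = to_color_locus(quantum_catch(s, vs))
            row = {
                "system": name, "geometry": vs.geometry,
                "flower_id": s.flower_id, "part": s.part,
                "brightness": mean_brightness(s),
                "saturation": loc.saturation,
            }
            for i, c in enumerate(loc.coordinates):
                row[f"coord_{i}"] = c
            rows.append(row)
    return pd.DataFrame(rows)
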