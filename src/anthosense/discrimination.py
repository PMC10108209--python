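"""Psychometric color-discrimination functions for pollinators.

Behavioral experiments show that the probability of an animal correctly
discriminating two colored stimuli is a sigmoidal function of the chromatic
distance V between their loci in the observer's color space. Two published
forms are implemented:

* a three-parameter logistic for the honeybee, calibrated on hexagon
  distances::

      h(V) = Mo * K / (Mo + (K - Mo) * exp(-r * V))

  with Mo = 0.492 (lower asymptote, chance-like performance), K = 1
  (upper asymptote) and r = 78.5 (increment rate per hexagon unit);

* a four-parameter logistic for the hummingbird hawkmoth, calibrated on
  Maxwell-triangle distances::

      h(V) = Mo + (K - Mo) / (1 + exp((xmid - V) / r))

  with Mo = 0.33, K = 1, r = 0.015 (distance-scale divisor) and
  xmid = 0.143 (inflection position).

Both are monotone nondecreasing in V with range [Mo, K).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .colorimetry import ColorLocus

__all__ = [
    "DiscriminationModel",
    "APIS_LOGISTIC3",
    "MACROGLOSSUM_LOGISTIC4",
    "MODEL_REGISTRY",
    "eval_logistic3",
    "eval_logistic4",
    "pairwise_discrimination",
    "discrimination_matrix",
    "fit_discrimination",
]


@dataclass(frozen=True)
class DiscriminationModel:
    """Parameters of a psychometric discrimination function.

    ``r`` is a rate constant per unit color distance for ``logistic3`` and a
    distance-scale divisor for ``logistic4``; ``xmid`` (logistic4 only) is
    the inflection position on the distance axis.
    """

    form: str               # "logistic3" | "logistic4"
    Mo: float               # lower asymptote (probability)
    K: float = 1.0          # upper asymptote (probability)
    r: float = 1.0
    xmid: float | None = None
    space: str | None = None  # color space the constants were calibrated in

    def __post_init__(self) -> None:
        if self.form not in ("logistic3", "logistic4"):
            raise ValueError(f"unknown form {self.form!r}")
        if not (0.0 <= self.Mo < self.K <= 1.0):
            raise ValueError("require 0 <= Mo < K <= 1")
        if self.r <= 0:
            raise ValueError("rate constant r must be > 0")
        if self.form == "logistic4":
            if self.xmid is None or self.xmid < 0:
                raise ValueError("logistic4 requires xmid >= 0")

    def __call__(self, v):
        if self.form == "logistic3":
            return eval_logistic3(self, v)
        return eval_logistic4(self, v)


def _check_v(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    if np.any(v < 0):
        raise ValueError("color distance V must be nonnegative")
    return v


def eval_logistic3(m: DiscriminationModel, v):
    """Three-parameter logistic: h = Mo K / (Mo + (K - Mo) exp(-r V))."""
    if m.form != "logistic3":
        raise ValueError("model form is not logistic3")
    v = _check_v(v)
    h = m.Mo * m.K / (m.Mo + (m.K - m.Mo) * np.exp(-m.r * v))
    return float(h) if h.ndim == 0 else h


def eval_logistic4(m: DiscriminationModel, v):
    """Four-parameter logistic: h = Mo + (K - Mo) / (1 + exp((xmid - V)/r))."""
    if m.form != "logistic4":
        raise ValueError("model form is not logistic4")
    v = _check_v(v)
    h = m.Mo + (m.K - m.Mo) / (1.0 + np.exp((m.xmid - v) / m.r))
    return float(h) if h.ndim == 0 else h


#: Honeybee model on hexagon distances.
APIS_LOGISTIC3 = DiscriminationModel("logistic3", Mo=0.492, K=1.0, r=78.5,
                                     space="hexagon")
#: Hummingbird-hawkmoth model on Maxwell-triangle distances.
MACROGLOSSUM_LOGISTIC4 = DiscriminationModel("logistic4", Mo=0.33, K=1.0,
                                             r=0.015, xmid=0.143,
                                             space="triangle")

MODEL_REGISTRY: dict[str, DiscriminationModel] = {
    "apis_logistic3": APIS_LOGISTIC3,
    "macroglossum_logistic4": MACROGLOSSUM_LOGISTIC4,
}


# ---------------------------------------------------------------------------
# Pairwise application to color loci
# ---------------------------------------------------------------------------

@dataclass
class DiscriminationCell:
    """Mean probability of correct discrimination over all cross pairings."""

    part_a: str
    part_b: str
    mean: float
    se: float
    n: int
    model: str
    space: str


def pairwise_discrimination(loci_a: list[ColorLocus],
                            loci_b: list[ColorLocus],
                            model: DiscriminationModel) -> DiscriminationCell:
    """Evaluate h over every cross pairing of two locus collections.

    Each of the nA x nB pairings contributes the Euclidean distance between
    the two loci in the model's calibration space; the cell reports the mean
    probability and its standard error over pairings (pairings treated as
    exchangeable; with 7 flowers per part this is the N = 49 design).
    """
    if not loci_a or not loci_b:
        raise ValueError("empty locus collection")
    spaces = {l.geometry for l in loci_a} | {l.geometry for l in loci_b}
    if len(spaces) > 1:
        raise ValueError(f"mixed color spaces in loci: {sorted(spaces)}")
    space = spaces.pop()
    if model.space is not None and space != model.space:
        raise ValueError(
            f"model calibrated in {model.space!r} but loci are in {space!r}")
    a = np.vstack([l.coordinates for l in loci_a])
    b = np.vstack([l.coordinates for l in loci_b])
    d = np.linalg.norm(a[:, None, :] - b[None, :, :], axis=-1).ravel()
    h = model(d)
    n = d.size
    se = float(np.std(h, ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    return DiscriminationCell(loci_a[0].part, loci_b[0].part,
                              float(np.mean(h)), se, n, model.form, space)


def discrimination_matrix(loci: list[ColorLocus],
                          model: DiscriminationModel) -> pd.DataFrame:
    """Symmetric part-by-part table of mean discrimination probabilities."""
    parts = sorted({l.part for l in loci})
    groups = {p: [l for l in loci if l.part == p] for p in parts}
    rows = []
    for i, pa in enumerate(parts):
        for pb in parts[i:]:
            cell = pairwise_discrimination(groups[pa], groups[pb], model)
            rows.append({"part_a": pa, "part_b": pb, "mean": cell.mean,
                         "se": cell.se, "n": cell.n, "model": cell.model,
                         "space": cell.space})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Fitting from binomial choice data
# ---------------------------------------------------------------------------

def fit_discrimination(choices: pd.DataFrame,
                       form: str,
                       fix_K: float | None = 1.0) -> DiscriminationModel:
    """Maximum-binomial-likelihood fit of a discrimination function.

    Parameters
    ----------
    choices : DataFrame
        Columns ``V`` (color distance), ``k`` (correct choices), ``n``
        (trials) — one row per tested distance level.
    form : str
        ``logistic3`` or ``logistic4``.
    fix_K : float or None
        Fix the upper asymptote (default 1.0); ``None`` frees it.
    """
    req = {"V", "k", "n"}
    if not req <= set(choices.columns):
        raise ValueError(f"choices table must have columns {sorted(req)}")
    v = choices["V"].to_numpy(dtype=float)
    k = choices["k"].to_numpy(dtype=float)
    n = choices["n"].to_numpy(dtype=float)
    if np.any((k < 0) | (k > n)):
        raise ValueError("require 0 <= k <= n")
    min_levels = 4 if form == "logistic4" else 3
    if np.unique(v).size < min_levels:
        raise ValueError(f"{form} needs >= {min_levels} distinct V levels")
    if np.all(k == n) or np.all(k == 0):
        raise ValueError(
            "degenerate choice data (all successes or all failures); "
            "the asymptotes are unidentifiable")

    eps = 1e-10

    def nll(theta):
        if form == "logistic3":
            mo, r = theta[0], theta[1]
            kk = fix_K if fix_K is not None else theta[2]
            h = mo * kk / (mo + (kk - mo) * np.exp(-r * v))
        else:
            mo, r, xm = theta[0], theta[1], theta[2]
            kk = fix_K if fix_K is not None else theta[3]
            z = np.clip((xm - v) / r, -700.0, 700.0)
            h = mo + (kk - mo) / (1.0 + np.exp(z))
        h = np.clip(h, eps, 1 - eps)
        return -np.sum(k * np.log(h) + (n - k) * np.log(1 - h))

    if form == "logistic3":
        x0 = [0.5, 10.0] + ([] if fix_K is not None else [0.99])
        bounds = [(0.01, 0.99), (1e-3, 1e4)] + \
                 ([] if fix_K is not None else [(0.5, 1.0)])
    elif form == "logistic4":
        x0 = [0.4, 0.05, float(np.median(v))] + \
             ([] if fix_K is not None else [0.99])
        bounds = [(0.01, 0.99), (1e-4, 10.0), (0.0, float(v.max()))] + \
                 ([] if fix_K is not None else [(0.5, 1.0)])
    else:
        raise ValueError(f"unknown form {form!r}")

    res = optimize.minimize(nll, x0, method="L-BFGS-B", bounds=bounds)
    if not res.success:
        raise RuntimeError(f"discrimination fit did not converge: {res.message}")
    if form == "logistic3":
        mo, r = res.x[0], res.x[1]
        kk = fix_K if fix_K is not None else res.x[2]
        return DiscriminationModel("logistic3", Mo=float(mo), K=float(kk),
                                   r=float(r))
    mo, r, xm = res.x[0], res.x[1], res.x[2]
    kk = fix_K if fix_K is not None else res.x[3]
    return DiscriminationModel("logistic4", Mo=float(mo), K=float(kk),
                               r=float(r), xmid=float(xm))


def simulate_choices(model: DiscriminationModel,
                     v_levels: np.ndarray,
                     n_per_level: int,
                     rng: np.random.Generator) -> pd.DataFrame:
    """Simulate binomial choice data from a discrimination model."""
    v = np.asarray(v_levels, dtype=float)
    p = np.asarray(model(v), dtype=float)
    k = rng.binomial(n_per_level, p)
    return pd.DataFrame({"V": v, "k": k, "n": n_per_level})
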