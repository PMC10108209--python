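"""Floral volatilome quantification and intrafloral statistics.

Starts from identified, integrated GC-MS peaks and provides:

* Kovats retention indices from an alkane ladder (non-isothermal, linear in
  retention time between bracketing n-alkanes);
* emission rates in internal-standard (toluene) equivalents, per flower or
  per gram fresh tissue per hour;
* composition shares by compound or biosynthetic class;
* Bray-Curtis NMDS ordination, Ward clustering of volatile profiles,
  and the Venn-style partition of compounds shared between floral parts;
* multivariate-abundance tests (sum of per-compound likelihood-ratio
  deviances, significance via PIT-trap residual resampling) with resampled
  univariate post hocs, and per-class one-way ANOVA with Tukey HSD.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist, squareform
from scipy.special import gammaln

__all__ = [
    "AlkaneLadder",
    "PeakTable",
    "EmissionMatrix",
    "MGLMResult",
    "BIOSYNTHETIC_CLASSES",
    "kovats_index",
    "emission_rate",
    "class_shares",
    "composition_shares",
    "nmds",
    "ward_cluster",
    "shared_compounds",
    "mglm_test",
    "class_er_anova",
]

BIOSYNTHETIC_CLASSES = (
    "aliphatics", "benzenoids", "irregular_terpenes",
    "monoterpenes", "nitrogenous", "sesquiterpenes",
)


# ---------------------------------------------------------------------------
# Kovats retention index
# ---------------------------------------------------------------------------

@dataclass
class AlkaneLadder:
    """Retention times (min) of consecutive n-alkanes C_n."""

    retention_times: dict[int, float]

    def __post_init__(self) -> None:
        ns = sorted(self.retention_times)
        rts = [self.retention_times[n] for n in ns]
        if len(ns) < 2:
            raise ValueError("alkane ladder needs at least two alkanes")
        if any(b - a != 1 for a, b in zip(ns, ns[1:])):
            raise ValueError("alkane carbon numbers must be consecutive")
        if any(b <= a for a, b in zip(rts, rts[1:])):
            raise ValueError("alkane retention times must be strictly increasing")
        self._ns = np.array(ns)
        self._rts = np.array(rts)


def kovats_index(rt: float, ladder: AlkaneLadder) -> float:
    """Kovats retention index, linear interpolation between bracketing alkanes.

    KRI = 100 n + 100 (rt - rt_n) / (rt_{n+1} - rt_n) for the alkanes C_n,
    C_{n+1} bracketing ``rt``. Invariant to affine rescaling of all
    retention times.
    """
    rts, ns = ladder._rts, ladder._ns
    if rt < rts[0] or rt > rts[-1]:
        raise ValueError(f"retention time {rt} outside ladder range "
                         f"[{rts[0]}, {rts[-1]}]")
    i = int(np.searchsorted(rts, rt, side="right") - 1)
    i = min(i, len(ns) - 2)
    n = ns[i]
    return float(100.0 * n + 100.0 * (rt - rts[i]) / (rts[i + 1] - rts[i]))


# ---------------------------------------------------------------------------
# Peak tables and emission matrices
# ---------------------------------------------------------------------------

@dataclass
class PeakTable:
    """Integrated peak areas per sample with internal-standard bookkeeping.

    ``areas`` is samples x compounds; ``sample_meta`` is indexed like
    ``areas`` and must carry ``is_area`` (internal-standard peak area),
    ``is_mass_ng`` (internal-standard mass added, ng) and ``duration_h``
    (sampling duration, h); ``fresh_mass_g`` is required only for
    per-fresh-mass normalization. Any further metadata columns (``part``,
    ``population``, ``time_point``, ``flower_id``) ride along.
    """

    areas: pd.DataFrame
    sample_meta: pd.DataFrame
    compound_meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if not self.areas.index.equals(self.sample_meta.index):
            raise ValueError("areas and sample_meta must share an index")
        req = {"is_area", "is_mass_ng", "duration_h"}
        missing = req - set(self.sample_meta.columns)
        if missing:
            raise ValueError(f"sample_meta missing columns {sorted(missing)}")
        if (self.areas.to_numpy() < 0).any():
            raise ValueError("negative peak areas")
        if (self.sample_meta["is_area"] <= 0).any():
            raise ValueError("internal-standard area must be > 0")
        if (self.sample_meta["duration_h"] <= 0).any():
            raise ValueError("sampling duration must be > 0")


@dataclass
class EmissionMatrix:
    """Samples x compounds emission rates with metadata.

    ``units`` is ``ng_fl_h`` (per flower) or ``ng_g_h`` (per g fresh mass).
    """

    values: pd.DataFrame
    units: str
    sample_meta: pd.DataFrame = field(default_factory=pd.DataFrame)
    compound_meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.units not in ("ng_fl_h", "ng_g_h"):
            raise ValueError(f"unknown units {self.units!r}")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("emission rates must be nonnegative")

    @property
    def compounds(self) -> list[str]:
        return list(self.values.columns)

    def part_means(self, by: str = "part") -> pd.DataFrame:
        """Mean ER per compound within each stratum of `by` (parts x compounds)."""
        return self.values.groupby(self.sample_meta[by]).mean()


def emission_rate(pt: PeakTable, normalize: str = "per_flower") -> EmissionMatrix:
    """Emission rates in internal-standard equivalents.

    ER = (area_compound / area_IS) x IS mass (ng) / (duration_h x basis),
    where the basis is one flower (``per_flower``) or the sample's fresh
    mass in g (``per_fresh_mass``).
    """
    meta = pt.sample_meta
    if normalize == "per_flower":
        basis = pd.Series(1.0, index=meta.index)
        units = "ng_fl_h"
    elif normalize == "per_fresh_mass":
        if "fresh_mass_g" not in meta.columns or meta["fresh_mass_g"].isna().any():
            raise ValueError("fresh_mass_g required for per_fresh_mass")
        if (meta["fresh_mass_g"] <= 0).any():
            raise ValueError("fresh mass must be > 0")
        basis = meta["fresh_mass_g"].astype(float)
        units = "ng_g_h"
    else:
        raise ValueError(f"unknown normalization {normalize!r}")
    factor = meta["is_mass_ng"] / (meta["is_area"] * meta["duration_h"] * basis)
    er = pt.areas.mul(factor, axis=0)
    return EmissionMatrix(er, units, meta.copy(), pt.compound_meta)


# ---------------------------------------------------------------------------
# Composition shares
# ---------------------------------------------------------------------------

def composition_shares(mean_er: pd.Series,
                       groups: dict[str, list[str]] | None = None) -> pd.Series:
    """Percent of total emissions per compound group.

    ``mean_er`` holds one mean ER per compound; each group's share is the
    summed group ER over the grand total, in percent. With ``groups=None``
    every compound is its own group (single-compound shares).
    """
    total = float(mean_er.sum())
    if total <= 0:
        raise ValueError("total emission is zero")
    if groups is None:
        return 100.0 * mean_er / total
    out = {}
    for name, members in groups.items():
        if not members:
            raise ValueError(f"empty group {name!r}")
        unknown = set(members) - set(mean_er.index)
        if unknown:
            raise ValueError(f"unknown compounds in group {name!r}: "
                             f"{sorted(unknown)}")
        out[name] = 100.0 * float(mean_er.loc[members].sum()) / total
    return pd.Series(out)


def class_shares(m: EmissionMatrix,
                 groups: dict[str, list[str]],
                 by: str | None = None) -> pd.DataFrame:
    """Group shares of total emissions, per stratum of the sample metadata."""
    if by is None:
        means = m.values.mean(axis=0)
        return composition_shares(means, groups).to_frame("share_pct").T
    strata = m.values.groupby(m.sample_meta[by]).mean()
    return pd.DataFrame({s: composition_shares(strata.loc[s], groups)
                         for s in strata.index}).T


# ---------------------------------------------------------------------------
# Ordination and clustering
# ---------------------------------------------------------------------------

@dataclass
class NMDSResult:
    coordinates: pd.DataFrame     # samples x k
    stress: float                 # Kruskal stress-1
    dissimilarity: str = "braycurtis"


def _stress1(embedding: np.ndarray, diss: np.ndarray) -> float:
    """Kruskal stress-1 of an embedding given target dissimilarities."""
    from sklearn.isotonic import IsotonicRegression

    d = pdist(embedding)
    order = np.argsort(diss, kind="stable")
    iso = IsotonicRegression()
    dhat = np.empty_like(d)
    dhat[order] = iso.fit_transform(diss[order], d[order])
    denom = float(np.sum(d ** 2))
    if denom == 0:
        return 0.0
    return float(np.sqrt(np.sum((d - dhat) ** 2) / denom))


def nmds(m: EmissionMatrix | pd.DataFrame,
         k: int = 2,
         seed: int | None = 0,
         n_restarts: int = 50,
         max_iter: int = 300) -> NMDSResult:
    """Non-metric multidimensional scaling on Bray-Curtis dissimilarities.

    Runs `n_restarts` random initializations of SMACOF-based non-metric MDS
    and keeps the configuration with the lowest Kruskal stress-1.
    """
    from sklearn.manifold import MDS

    values = m.values if isinstance(m, EmissionMatrix) else m
    x = values.to_numpy(dtype=float)
    if x.shape[0] < 3:
        raise ValueError("NMDS needs at least 3 samples")
    zero_rows = np.where(x.sum(axis=1) == 0)[0]
    if zero_rows.size:
        raise ValueError(
            f"all-zero samples (Bray-Curtis undefined): "
            f"{values.index[zero_rows].tolist()}")
    diss = pdist(x, metric="braycurtis")
    mds = MDS(n_components=k, metric_mds=False, metric="precomputed",
              init="random", n_init=n_restarts, max_iter=max_iter,
              random_state=seed, normalized_stress=True, eps=1e-9)
    emb = mds.fit_transform(squareform(diss))
    coords = pd.DataFrame(emb, index=values.index,
                          columns=[f"nmds{i + 1}" for i in range(k)])
    return NMDSResult(coords, _stress1(emb, diss))


@dataclass
class Dendrogram:
    labels: list[str]
    linkage_matrix: np.ndarray    # scipy linkage format

    @property
    def merge_heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2]

    def last_joined_singleton(self) -> str | None:
        """Label of the leaf merged in the final agglomeration, if single."""
        n = len(self.labels)
        a, b = int(self.linkage_matrix[-1, 0]), int(self.linkage_matrix[-1, 1])
        for idx in (a, b):
            if idx < n:
                return self.labels[idx]
        return None


def ward_cluster(m: EmissionMatrix | pd.DataFrame,
                 by: str | None = "part") -> Dendrogram:
    """Ward minimum-variance clustering on Euclidean distances.

    With ``by`` set, samples are first averaged within each stratum of the
    sample metadata (e.g. mean volatile profile per floral part); with
    ``by=None`` individual samples are clustered.
    """
    if isinstance(m, EmissionMatrix) and by is not None:
        profiles = m.part_means(by)
    else:
        profiles = m.values if isinstance(m, EmissionMatrix) else m
    if profiles.shape[0] < 2:
        raise ValueError("need at least 2 profiles to cluster")
    z = linkage(profiles.to_numpy(dtype=float), method="ward")
    return Dendrogram([str(i) for i in profiles.index], z)


def shared_compounds(m: EmissionMatrix,
                     by: str = "part",
                     threshold: float = 0.0) -> dict[frozenset, list[str]]:
    """Venn-style partition of compounds by presence across floral parts.

    A compound is present in a part if its mean ER there exceeds
    ``threshold``. Returns a mapping from each part-subset (frozenset) to
    the compounds present in exactly those parts; compounds absent
    everywhere are keyed by the empty frozenset.
    """
    means = m.part_means(by)
    if means.shape[0] < 2:
        raise ValueError("need at least 2 parts")
    presence = means > threshold
    out: dict[frozenset, list[str]] = {}
    for comp in means.columns:
        region = frozenset(presence.index[presence[comp]])
        out.setdefault(region, []).append(comp)
    return out


# ---------------------------------------------------------------------------
# Multivariate-abundance tests (PIT-trap resampling)
# ---------------------------------------------------------------------------

@dataclass
class MGLMResult:
    """Multivariate deviance test with resampled significance."""

    deviance: float
    df: tuple[int, int]            # (levels - 1, n - levels)
    pvalue: float
    n_boot: int
    family: str
    univariate: pd.DataFrame       # compound, deviance, p_raw, p_adj


def _nb_loglik(y: np.ndarray, mu: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """NB2 log-likelihood summed over axis 0; alpha broadcast per compound."""
    mu = np.maximum(mu, 1e-10)
    with np.errstate(divide="ignore", invalid="ignore"):
        ia = 1.0 / alpha
        ll = (gammaln(y + ia) - gammaln(ia) - gammaln(y + 1.0)
              + y * np.log(alpha * mu / (1.0 + alpha * mu))
              - ia * np.log1p(alpha * mu))
    return ll.sum(axis=0)


def _poisson_loglik(y: np.ndarray, mu: np.ndarray) -> np.ndarray:
    mu = np.maximum(mu, 1e-10)
    return (y * np.log(mu) - mu - gammaln(y + 1.0)).sum(axis=0)


def _group_means(y: np.ndarray, codes: np.ndarray, n_levels: int) -> np.ndarray:
    """Per-group column means, expanded back to observation shape."""
    out = np.empty_like(y, dtype=float)
    for g in range(n_levels):
        mask = codes == g
        out[mask] = y[mask].mean(axis=0)
    return out


def _deviances(y: np.ndarray, codes: np.ndarray, n_levels: int,
               family: str, alpha: np.ndarray) -> np.ndarray:
    """Per-compound LR deviances of the factor model vs the intercept model.

    For the one-factor design and the families used here, the maximum-
    likelihood fitted values are the group (or grand) means, so the
    likelihood-ratio statistic has closed form. For negbin the per-compound
    dispersion alpha is held fixed (moment estimate from the observed data),
    under which the group-mean MLE property still holds.
    """
    mu1 = _group_means(y, codes, n_levels)
    mu0 = np.broadcast_to(y.mean(axis=0), y.shape)
    if family == "negbin":
        ll1 = _nb_loglik(y, mu1, alpha)
        ll0 = _nb_loglik(y, mu0, alpha)
    elif family == "poisson":
        ll1 = _poisson_loglik(y, mu1)
        ll0 = _poisson_loglik(y, mu0)
    else:
        raise ValueError(f"unknown family {family!r}")
    return np.maximum(2.0 * (ll1 - ll0), 0.0)


def _nb_alpha_moment(y: np.ndarray, codes: np.ndarray, n_levels: int) -> np.ndarray:
    """Per-compound moment estimate of NB2 dispersion, given group means."""
    mu = _group_means(y, codes, n_levels)
    num = ((y - mu) ** 2 - mu).sum(axis=0)
    den = (mu ** 2).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = np.where(den > 0, num / den, 0.0)
    return np.clip(alpha, 1e-6, 1e3)


def _pit_upper_lower(y, mu, alpha, family):
    """CDF at y and at y-1 for the discrete families (for randomized PIT)."""
    if family == "negbin":
        n_param = 1.0 / alpha
        p_param = n_param / (n_param + np.maximum(mu, 1e-10))
        hi = stats.nbinom.cdf(y, n_param, p_param)
        lo = stats.nbinom.cdf(y - 1, n_param, p_param)
    else:
        hi = stats.poisson.cdf(y, np.maximum(mu, 1e-10))
        lo = stats.poisson.cdf(y - 1, np.maximum(mu, 1e-10))
    return lo, hi


def _pit_invert(u, mu, alpha, family):
    if family == "negbin":
        n_param = 1.0 / alpha
        p_param = n_param / (n_param + np.maximum(mu, 1e-10))
        return stats.nbinom.ppf(u, n_param, p_param)
    return stats.poisson.ppf(u, np.maximum(mu, 1e-10))


def mglm_test(m: EmissionMatrix,
              factor: str = "part",
              family: str = "negbin",
              B: int = 999,
              seed: int | None = 0,
              transform: str | None = None,
              scale: float = 1.0) -> MGLMResult:
    """Multivariate-abundance test of a categorical factor.

    Fits one GLM per compound (negative binomial by default, with a fixed
    per-compound moment dispersion estimate, or Poisson) under the null
    (intercept only) and the alternative (one mean per factor level); the
    multivariate statistic is the sum of per-compound likelihood-ratio
    deviances. Significance is assessed by PIT-trap residual resampling:
    randomized probability-integral-transform residuals of the null fit are
    resampled by row (preserving between-compound correlation) and inverted
    through the null quantile function, and p = (1 + #{Dev* >= Dev}) /
    (B + 1). Univariate per-compound p-values are adjusted by free
    step-down (Westfall-Young) resampling.

    Continuous emission rates are prepared for the count families by
    optional ``transform`` ("log1p") followed by scaling and rounding to
    integers.
    """
    if B < 99:
        raise ValueError("B must be >= 99 for a usable resolution floor")
    codes_ser = m.sample_meta[factor].astype("category")
    codes = codes_ser.cat.codes.to_numpy()
    n_levels = codes_ser.cat.categories.size
    if n_levels < 2:
        raise ValueError(f"factor {factor!r} has a single level")
    y = m.values.to_numpy(dtype=float) * scale
    if transform == "log1p":
        y = np.log1p(y)
    elif transform is not None:
        raise ValueError(f"unknown transform {transform!r}")
    y = np.round(y)
    n, p = y.shape
    rng = np.random.default_rng(seed)

    alpha = (_nb_alpha_moment(y, codes, n_levels) if family == "negbin"
             else np.ones(p))
    dev_uni = _deviances(y, codes, n_levels, family, alpha)
    dev_obs = float(dev_uni.sum())

    # Null-model fitted means and randomized PIT residuals
    mu0 = np.broadcast_to(y.mean(axis=0), y.shape)
    lo, hi = _pit_upper_lower(y, mu0, alpha, family)
    u = lo + rng.uniform(size=y.shape) * np.maximum(hi - lo, 0.0)
    u = np.clip(u, 1e-10, 1.0 - 1e-10)

    dev_boot = np.empty(B)
    dev_boot_uni = np.empty((B, p))
    for b in range(B):
        rows = rng.integers(0, n, size=n)
        ystar = _pit_invert(u[rows], mu0, alpha, family)
        d = _deviances(ystar, codes, n_levels, family, alpha)
        dev_boot_uni[b] = d
        dev_boot[b] = d.sum()
    pvalue = (1.0 + np.sum(dev_boot >= dev_obs - 1e-12)) / (B + 1.0)

    # Univariate raw p-values and free step-down (maxT) adjustment
    p_raw = (1.0 + (dev_boot_uni >= dev_uni[None, :] - 1e-12).sum(axis=0)) / (B + 1.0)
    order = np.argsort(-dev_uni)
    p_adj = np.empty(p)
    running_max = np.full(B, -np.inf)
    for rank in range(p - 1, -1, -1):
        j = order[rank]
        running_max = np.maximum(running_max, dev_boot_uni[:, j])
        p_adj[j] = (1.0 + np.sum(running_max >= dev_uni[j] - 1e-12)) / (B + 1.0)
    # enforce step-down monotonicity along decreasing observed deviance
    for rank in range(1, p):
        p_adj[order[rank]] = max(p_adj[order[rank]], p_adj[order[rank - 1]])

    uni = pd.DataFrame({
        "compound": m.values.columns,
        "deviance": dev_uni,
        "p_raw": p_raw,
        "p_adj": p_adj,
    })
    return MGLMResult(dev_obs, (n_levels - 1, n - n_levels), float(pvalue),
                      B, family, uni)


# ---------------------------------------------------------------------------
# Per-class ANOVA
# ---------------------------------------------------------------------------

@dataclass
class ClassAnovaResult:
    compound_class: str
    statistic: float
    df: tuple[int, int]
    pvalue: float
    tukey: pd.DataFrame            # group_a, group_b, meandiff, p_adj


def class_er_anova(m: EmissionMatrix,
                   compound_class: str | None = None,
                   factor: str = "part") -> ClassAnovaResult:
    """One-way ANOVA of per-sample class-total emission rates across parts.

    Post hoc: Tukey's HSD range test over all part pairs.
    """
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    if compound_class is not None:
        if m.compound_meta is None:
            raise ValueError("compound metadata required to select a class")
        members = m.compound_meta.index[
            m.compound_meta["biosynthetic_class"] == compound_class]
        if members.empty:
            raise ValueError(f"no compounds in class {compound_class!r}")
        totals = m.values[list(members)].sum(axis=1)
    else:
        totals = m.values.sum(axis=1)
    groups_ser = m.sample_meta[factor]
    levels = sorted(groups_ser.unique())
    if len(levels) < 2:
        raise ValueError("need at least 2 factor levels")
    samples = [totals[groups_ser == g].to_numpy() for g in levels]
    grand = np.concatenate(samples)
    df1 = len(levels) - 1
    df2 = grand.size - len(levels)
    if np.allclose(grand, grand[0]):
        f, p = 0.0, 1.0
    else:
        f, p = stats.f_oneway(*samples)
    with np.errstate(invalid="ignore"):  # degenerate zero-variance input
        res = pairwise_tukeyhsd(grand.astype(float),
                                np.concatenate([[g] * len(s) for g, s in
                                                zip(levels, samples)]))
    tukey = pd.DataFrame(res.summary().data[1:],
                         columns=[c.strip() for c in res.summary().data[0]])
    tukey = tukey.rename(columns={"group1": "group_a", "group2": "group_b",
                                  "p-adj": "p_adj"})
    return ClassAnovaResult(compound_class or "all", float(f), (df1, df2),
                            float(p), tukey)


# ---------------------------------------------------------------------------
# I/O helpers
# ---------------------------------------------------------------------------

def load_emission_matrix(values_csv, meta_csv=None, units="ng_fl_h",
                         compound_meta_csv=None) -> EmissionMatrix:
    """Read a wide samples x compounds ER CSV plus optional metadata CSVs."""
    values = pd.read_csv(values_csv, index_col=0)
    meta = (pd.read_csv(meta_csv, index_col=0) if meta_csv is not None
            else pd.DataFrame(index=values.index))
    cmeta = (pd.read_csv(compound_meta_csv, index_col=0)
             if compound_meta_csv is not None else None)
    return EmissionMatrix(values, units, meta, cmeta)
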