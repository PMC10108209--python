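"""Volatilomics: retention indices, emission rates, shares, ordination,
clustering, multivariate resampling tests, class ANOVA."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from anthosense import datasets
from anthosense.synthetic import (CompoundSpec, EmissionDesign,
                                  default_emission_design,
                                  gen_emission_matrix, gen_peak_table)
from anthosense.volatilomics import (AlkaneLadder, EmissionMatrix, PeakTable,
                                     class_er_anova, composition_shares,
                                     emission_rate, kovats_index, mglm_test,
                                     nmds, shared_compounds, ward_cluster)


# ---------------------------------------------------------------------------
# Kovats retention index
# ---------------------------------------------------------------------------

class TestKovats:
    LADDER = AlkaneLadder({10: 2.0, 11: 3.0, 12: 5.0, 13: 5.5})

    def test_alkane_itself(self):
        assert kovats_index(2.0, self.LADDER) == pytest.approx(1000.0)

    def test_linear_midpoint(self):
        assert kovats_index(2.5, self.LADDER) == pytest.approx(1050.0)

    def test_direct_formula_case(self):
        # C12 at 5.00 min, C13 at 5.50 min, rt = 5.25 -> 1250
        assert kovats_index(5.25, self.LADDER) == pytest.approx(1250.0)

    def test_outside_ladder_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            kovats_index(1.0, self.LADDER)

    def test_non_monotone_ladder_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            AlkaneLadder({10: 2.0, 11: 1.5})

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(scale=st.floats(0.1, 10.0), shift=st.floats(-1.0, 100.0),
           frac=st.floats(0.0, 1.0))
    def test_affine_invariance_of_retention_times(self, scale, shift, frac):
        rt = 5.0 + 0.5 * frac
        before = kovats_index(rt, self.LADDER)
        scaled = AlkaneLadder({n: scale * t + shift
                               for n, t in self.LADDER.retention_times.items()})
        after = kovats_index(scale * rt + shift, scaled)
        assert after == pytest.approx(before, abs=1e-6)


# ---------------------------------------------------------------------------
# Emission rates
# ---------------------------------------------------------------------------

def _peak_table(areas, is_area=100.0, is_mass=1.0, duration=1.5, mass_g=None):
    idx = pd.Index([f"s{i}" for i in range(len(areas))])
    meta = pd.DataFrame({"is_area": is_area, "is_mass_ng": is_mass,
                         "duration_h": duration}, index=idx)
    if mass_g is not None:
        meta["fresh_mass_g"] = mass_g
    return PeakTable(pd.DataFrame({"A": areas}, index=idx), meta)


class TestEmissionRate:
    def test_unit_case_90_minutes(self):
        pt = _peak_table([100.0], is_area=100.0, is_mass=1.0, duration=1.5)
        m = emission_rate(pt, "per_flower")
        assert m.values.iloc[0, 0] == pytest.approx(2.0 / 3.0)
        assert m.units == "ng_fl_h"

    def test_zero_area_gives_zero_er(self):
        m = emission_rate(_peak_table([0.0]))
        assert m.values.iloc[0, 0] == 0.0

    def test_per_fresh_mass_normalization(self):
        pt = _peak_table([100.0], mass_g=0.5)
        m = emission_rate(pt, "per_fresh_mass")
        assert m.values.iloc[0, 0] == pytest.approx((1.0 / 1.5) / 0.5)
        assert m.units == "ng_g_h"

    def test_missing_mass_rejected(self):
        with pytest.raises(ValueError, match="fresh_mass_g"):
            emission_rate(_peak_table([1.0]), "per_fresh_mass")

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(c=st.floats(0.1, 10.0), d=st.floats(0.1, 10.0))
    def test_homogeneity_in_area_and_duration(self, c, d):
        base = emission_rate(_peak_table([50.0], duration=1.0))
        scaled = emission_rate(_peak_table([50.0 * c], duration=d))
        assert scaled.values.iloc[0, 0] == pytest.approx(
            base.values.iloc[0, 0] * c / d)

    def test_round_trip_with_generator(self, emissions_default):
        pt = gen_peak_table(emissions_default, is_mass_ng=2.0, duration_h=0.75)
        back = emission_rate(pt)
        err = (back.values - emissions_default.values).abs().to_numpy().max()
        assert err < 1e-9


# ---------------------------------------------------------------------------
# Composition shares against the packaged survey table
# ---------------------------------------------------------------------------

class TestCompositionShares:
    def test_single_compound_occupies_everything(self):
        s = composition_shares(pd.Series({"A": 3.0}))
        assert s["A"] == pytest.approx(100.0)

    def test_aldoxime_share_koudouroudia(self):
        means = datasets.population_means(population="koudouroudia")
        s = composition_shares(means, {"aldoximes": datasets.ALDOXIMES})
        assert round(float(s["aldoximes"]), 1) == 41.6

    def test_linalool_share_thermi(self):
        means = datasets.population_means(population="thermi")
        s = composition_shares(means, {"linalool": ["Linalool"]})
        assert round(float(s["linalool"]), 1) == 23.1

    def test_unknown_compound_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            composition_shares(pd.Series({"A": 1.0}), {"g": ["B"]})

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            composition_shares(pd.Series({"A": 1.0}), {"g": []})


# ---------------------------------------------------------------------------
# NMDS
# ---------------------------------------------------------------------------

def _matrix(values, parts=None):
    idx = pd.Index([f"s{i}" for i in range(len(values))])
    meta = pd.DataFrame({"part": parts or ["p"] * len(values)}, index=idx)
    return EmissionMatrix(pd.DataFrame(values, index=idx), "ng_fl_h", meta)


class TestNMDS:
    def test_duplicated_samples_embed_with_zero_stress(self):
        m = _matrix([[1.0, 2.0, 3.0]] * 3 + [[5.0, 1.0, 0.5]] * 3)
        res = nmds(m, seed=0, n_restarts=8)
        assert res.stress < 1e-3

    def test_three_equidistant_samples_embed_exactly_in_2d(self):
        m = _matrix([[10.0, 0.0, 0.0], [0.0, 10.0, 0.0], [0.0, 0.0, 10.0]])
        res = nmds(m, seed=0, n_restarts=8)
        assert res.stress < 1e-3

    def test_separated_part_clusters_stay_separated(self):
        d = default_emission_design(seed=6, dispersion=0.1)
        m = gen_emission_matrix(d)
        res = nmds(m, seed=1, n_restarts=16)
        coords = res.coordinates.to_numpy()
        parts = m.sample_meta["part"].to_numpy()
        co = coords[parts == "corolla"]
        ca = coords[parts == "calyx_gynoecium"]
        within = np.linalg.norm(co - co.mean(axis=0), axis=1)
        between = np.linalg.norm(co.mean(axis=0) - ca.mean(axis=0))
        assert between > np.percentile(within, 95)

    def test_all_zero_sample_rejected(self):
        m = _matrix([[0.0, 0.0], [1.0, 2.0], [2.0, 1.0]])
        with pytest.raises(ValueError, match="all-zero"):
            nmds(m, seed=0)


# ---------------------------------------------------------------------------
# Ward clustering
# ---------------------------------------------------------------------------

def _brute_force_ward(points):
    """Greedy Ward agglomeration oracle using the Lance-Williams distance
    sqrt(2 |A||B| / (|A|+|B|)) * ||centroid_A - centroid_B||."""
    clusters = [(i, [p]) for i, p in enumerate(points)]
    merges = []
    next_id = len(points)
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                a, b = clusters[i][1], clusters[j][1]
                ca, cb = np.mean(a, axis=0), np.mean(b, axis=0)
                d = np.sqrt(2.0 * len(a) * len(b) / (len(a) + len(b))) \
                    * np.linalg.norm(ca - cb)
                if best is None or d < best[0]:
                    best = (d, i, j)
        d, i, j = best
        ida, pa = clusters[i]
        idb, pb = clusters[j]
        merges.append((min(ida, idb), max(ida, idb), d, len(pa) + len(pb)))
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
        clusters.append((next_id, pa + pb))
        next_id += 1
    return merges


class TestWardCluster:
    def test_identical_profiles_merge_at_zero_height(self):
        m = _matrix([[1.0, 2.0], [1.0, 2.0], [9.0, 9.0]])
        dend = ward_cluster(m, by=None)
        assert dend.merge_heights[0] == pytest.approx(0.0)

    def test_scaled_outlier_part_joins_last(self):
        profiles = pd.DataFrame(
            [[1.0, 2.0, 1.5], [1.2, 2.1, 1.4], [0.9, 1.8, 1.6],
             [10.0, 20.0, 15.0]],
            index=["calyx", "nectar", "stamens", "corolla"])
        dend = ward_cluster(profiles, by=None)
        assert dend.last_joined_singleton() == "corolla"

    def test_linkage_matches_brute_force_on_four_points(self):
        pts = np.array([[0.0, 0.0], [1.0, 0.2], [4.0, 4.0], [10.0, 0.0]])
        m = pd.DataFrame(pts, index=list("abcd"))
        dend = ward_cluster(m, by=None)
        oracle = _brute_force_ward(pts)
        for row, (ia, ib, d, size) in zip(dend.linkage_matrix, oracle):
            assert sorted(row[:2]) == [ia, ib]
            assert row[2] == pytest.approx(d)
            assert row[3] == size

    def test_merge_heights_monotone(self, emissions_default):
        dend = ward_cluster(emissions_default, by="part")
        assert np.all(np.diff(dend.merge_heights) >= -1e-12)

    def test_single_stratum_rejected(self):
        m = _matrix([[1.0, 2.0]])
        with pytest.raises(ValueError):
            ward_cluster(m, by=None)


# ---------------------------------------------------------------------------
# Shared-compound partition
# ---------------------------------------------------------------------------

class TestSharedCompounds:
    def _fixture(self):
        # 4 parts x 4 compounds with a known presence pattern
        parts = ["ca", "co", "ne", "st"]
        values = pd.DataFrame(
            {"everywhere": [1.0, 1.0, 1.0, 1.0],
             "corolla_only": [0.0, 5.0, 0.0, 0.0],
             "not_nectar": [2.0, 2.0, 0.0, 2.0],
             "absent": [0.0, 0.0, 0.0, 0.0]},
            index=pd.Index([f"s{i}" for i in range(4)]))
        meta = pd.DataFrame({"part": parts}, index=values.index)
        return EmissionMatrix(values, "ng_fl_h", meta)

    def test_partition_matches_set_algebra(self):
        venn = shared_compounds(self._fixture(), threshold=0.0)
        assert venn[frozenset({"ca", "co", "ne", "st"})] == ["everywhere"]
        assert venn[frozenset({"co"})] == ["corolla_only"]
        assert venn[frozenset({"ca", "co", "st"})] == ["not_nectar"]
        assert venn[frozenset()] == ["absent"]

    def test_threshold_above_max_empties_every_region(self):
        venn = shared_compounds(self._fixture(), threshold=100.0)
        assert set(venn) == {frozenset()}

    def test_all_compounds_everywhere(self, emissions_default):
        venn = shared_compounds(emissions_default, threshold=0.0)
        all_parts = frozenset(emissions_default.sample_meta["part"])
        assert sorted(venn[all_parts]) == sorted(emissions_default.compounds)


# ---------------------------------------------------------------------------
# Multivariate-abundance tests
# ---------------------------------------------------------------------------

class TestMGLM:
    def test_strong_part_effect_hits_resolution_floor(self, emissions_default):
        res = mglm_test(emissions_default, B=999, seed=0)
        assert res.pvalue == pytest.approx(1.0 / 1000.0)
        assert res.df == (3, 16)
        assert res.deviance > 0

    def test_single_compound_matrix_deviance_equals_univariate(self):
        d = EmissionDesign([CompoundSpec("A", "monoterpenes", 50.0)],
                           {"a": 5, "b": 5}, {("A", "b"): 4.0},
                           dispersion=0.2, seed=2)
        m = gen_emission_matrix(d)
        res = mglm_test(m, B=99, seed=0)
        assert res.deviance == pytest.approx(
            float(res.univariate["deviance"].iloc[0]))

    def test_type_one_error_near_nominal_under_null(self):
        # 200 null datasets, B = 199: rejection rate at alpha = 0.05
        comps = [CompoundSpec(f"c{i}", "monoterpenes", 100.0)
                 for i in range(4)]
        rej = 0
        n_data = 200
        for i in range(n_data):
            d = EmissionDesign(comps, {"a": 5, "b": 5, "c": 5, "d": 5}, {},
                               dispersion=0.3, seed=50_000 + i)
            m = gen_emission_matrix(d)
            res = mglm_test(m, B=199, seed=i)
            rej += res.pvalue <= 0.05
        assert 0.02 <= rej / n_data <= 0.09

    def test_univariate_adjusted_p_dominates_raw(self, emissions_default):
        res = mglm_test(emissions_default, B=199, seed=3)
        assert (res.univariate["p_adj"] >= res.univariate["p_raw"] - 1e-12).all()

    def test_pvalue_respects_floor(self, emissions_default):
        res = mglm_test(emissions_default, B=99, seed=1)
        assert res.pvalue >= 1.0 / 100.0

    def test_single_level_factor_rejected(self):
        d = EmissionDesign([CompoundSpec("A", "monoterpenes", 5.0)],
                           {"only": 6}, {}, seed=0)
        m = gen_emission_matrix(d)
        with pytest.raises(ValueError, match="single level"):
            mglm_test(m, B=99)

    def test_poisson_family_also_detects_strong_effect(self, emissions_default):
        res = mglm_test(emissions_default, family="poisson", B=199, seed=0)
        assert res.pvalue == pytest.approx(1.0 / 200.0)


# ---------------------------------------------------------------------------
# Class-total ANOVA
# ---------------------------------------------------------------------------

class TestClassAnova:
    def test_identical_totals_give_zero_F(self):
        m = _matrix([[1.0, 2.0]] * 8, parts=["a"] * 4 + ["b"] * 4)
        res = class_er_anova(m)
        assert res.statistic == 0.0
        assert res.pvalue == 1.0

    def test_two_groups_F_equals_squared_t(self, rng):
        vals = rng.gamma(2.0, 10.0, size=(12, 1))
        m = _matrix(vals.tolist(), parts=["a"] * 6 + ["b"] * 6)
        res = class_er_anova(m)
        from scipy import stats
        t, _ = stats.ttest_ind(vals[:6, 0], vals[6:, 0])
        assert res.statistic == pytest.approx(t ** 2)

    def test_F_matches_brute_force_sums_of_squares(self, rng):
        # unbalanced design like the intrafloral sampling: N = 4/5/5/6
        sizes = {"ca": 4, "co": 5, "ne": 5, "st": 6}
        parts, values = [], []
        for p, n in sizes.items():
            parts += [p] * n
            values += rng.gamma(3.0, 5.0, size=n).tolist()
        m = _matrix([[v] for v in values], parts=parts)
        res = class_er_anova(m)
        arr = np.array(values)
        grand = arr.mean()
        ss_between = sum(n * (arr[np.array(parts) == p].mean() - grand) ** 2
                         for p, n in sizes.items())
        ss_within = sum(((arr[np.array(parts) == p]
                          - arr[np.array(parts) == p].mean()) ** 2).sum()
                        for p in sizes)
        k, n_tot = len(sizes), len(values)
        f_brute = (ss_between / (k - 1)) / (ss_within / (n_tot - k))
        assert res.statistic == pytest.approx(f_brute)
        assert res.df == (3, 16)

    def test_class_selection_uses_compound_metadata(self, emissions_default):
        res = class_er_anova(emissions_default, "nitrogenous")
        assert res.compound_class == "nitrogenous"
        assert res.pvalue < 0.05  # default design concentrates N-compounds
        assert len(res.tukey) == 6  # all part pairs
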