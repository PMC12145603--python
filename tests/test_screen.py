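"""Univariate screening, donor-independent selection and Spearman maps."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from osteomet.library import (ENDO_SIGNATURE, EXCHANGE_DAYS, EXO_SIGNATURE,
                              build_default_library)
from osteomet.media import correct_table, corrected_wide
from osteomet.screen import (pair_group_means, percent_variation,
                             screen_table, select_donor_independent,
                             spearman_map, spearman_rho_p, wilcoxon_exact,
                             wilcoxon_stratified)
from osteomet.simulate import CohortConfig, simulate_tables


class TestWilcoxonExact:
    def test_disjoint_triplets(self):
        """{1,2,3} vs {4,5,6}: the most extreme of C(6,3)=20 splits, so the
        two-sided exact p is 2/20 = 0.1."""
        assert wilcoxon_exact([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_disjoint_quintets(self):
        assert wilcoxon_exact([1, 2, 3, 4, 5], [6, 7, 8, 9, 10]) == \
            pytest.approx(2 / 252)

    def test_identical_groups(self):
        assert wilcoxon_exact([5, 5, 5], [5, 5, 5]) == 1.0

    def test_triplicate_minimum_p_is_0_1(self):
        """With n=3 vs 3 the exact two-sided floor is 0.1, hence per-donor
        significance at alpha=0.05 is unattainable with triplicates."""
        rng = np.random.default_rng(0)
        ps = [wilcoxon_exact(rng.normal(size=3), rng.normal(10, 1, size=3))
              for _ in range(20)]
        assert min(ps) == pytest.approx(0.1)

    @pytest.mark.parametrize("n,m", [(n, m) for n in range(1, 7)
                                     for m in range(1, 7)])
    def test_matches_reference_enumeration(self, n, m):
        """Exact p agrees with the independent exact rank-sum reference for
        every group-size combination up to 6+6 (tie-free data)."""
        rng = np.random.default_rng(n * 10 + m)
        a = rng.permutation(np.arange(1.0, n + m + 1))[:n]
        b = np.setdiff1d(np.arange(1.0, n + m + 1), a)
        ours = wilcoxon_exact(a, b)
        ref = stats.mannwhitneyu(a, b, alternative="two-sided",
                                 method="exact").pvalue
        assert ours == pytest.approx(float(ref), abs=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_exact([], [1.0])


class TestWilcoxonStratified:
    def test_single_stratum_reduces_to_plain_exact(self):
        a, b = [1.0, 2.0, 5.0], [3.0, 4.0, 6.0]
        assert wilcoxon_stratified([(a, b)]) == pytest.approx(
            wilcoxon_exact(a, b))

    def test_consistent_shift_across_offset_strata_detected(self):
        """Three donor blocks with wildly different baselines but the same
        within-block shift: the stratified test sees it, a naive pooled
        rank-sum cannot."""
        strata = [([0.9, 1.0, 1.1], [1.4, 1.5, 1.6]),
                  ([10.9, 11.0, 11.1], [11.4, 11.5, 11.6]),
                  ([0.09, 0.10, 0.11], [0.14, 0.15, 0.16])]
        p_strat = wilcoxon_stratified(strata)
        pooled_a = np.concatenate([s[0] for s in strata])
        pooled_b = np.concatenate([s[1] for s in strata])
        p_naive = wilcoxon_exact(pooled_a, pooled_b)
        assert p_strat == pytest.approx(2 / 20 ** 3)
        assert p_naive > 0.05 > p_strat

    def test_null_is_uniformish(self):
        rng = np.random.default_rng(1)
        ps = []
        for _ in range(200):
            strata = [(rng.normal(size=3), rng.normal(size=3))
                      for _ in range(3)]
            ps.append(wilcoxon_stratified(strata))
        assert np.mean(np.asarray(ps) < 0.05) < 0.1

    def test_all_empty_strata_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_stratified([(np.empty(0), np.array([1.0]))])


class TestPercentVariation:
    def test_equal_means(self):
        assert percent_variation([2, 2], [2, 2]) == 0.0

    def test_arithmetic(self):
        assert percent_variation([2.0], [5.0]) == pytest.approx(150.0)

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            percent_variation([0.0], [1.0])

    def test_cohort_signature_increases_exceed_80pct(self, endo_table):
        """Planted osteogenic increases measured on the processed cohort at
        day 21 reach the design magnitude."""
        scr = screen_table(endo_table, mode="osteo")
        pooled = scr[(scr.donor == "pooled") & (scr.day == 21)]
        pooled = pooled.set_index("metabolite")
        for met in ("Cho", "Etn", "UDP-GlcNAc", "UDP-GalNAc", "U3.48"):
            assert pooled.loc[met, "pct_variation"] >= 80.0, met


class TestScreenTable:
    def test_small_groups_never_carry_p(self, exo_tables):
        _, wide = exo_tables
        scr = screen_table(wide, mode="osteo")
        small = scr[scr[["n_ref", "n_alt"]].min(axis=1) < 3]
        assert small["p_value"].isna().all()
        assert small["visual_only"].all()

    def test_proliferation_mode_contrasts_day0(self, endo_table):
        scr = screen_table(endo_table, mode="prolif")
        assert 0 not in scr["day"].unique()
        pooled = scr[(scr.donor == "pooled") & (scr.day == 21)]
        pooled = pooled.set_index("metabolite")
        for met in ("HTau", "MG", "GPC", "PEtn", "Ino"):
            assert pooled.loc[met, "pct_variation"] >= 85.0, met
        for met in ("ATP", "ADP"):
            assert pooled.loc[met, "pct_variation"] <= -55.0, met

    def test_bad_mode_rejected(self, endo_table):
        with pytest.raises(ValueError, match="mode"):
            screen_table(endo_table, mode="sideways")


def _table_cohort(seed, lib=None):
    lib = lib or build_default_library()
    tb = simulate_tables(lib, CohortConfig(seed=seed))
    wide = corrected_wide(correct_table(tb["media_long"], tb["blanks"],
                                        exchange_days=EXCHANGE_DAYS))
    return tb["cells"], wide


class TestSelection:
    def test_planted_sets_recovered_exactly(self):
        cells, media = _table_cohort(seed=1)
        endo_sel = select_donor_independent(screen_table(cells, mode="osteo"))
        exo_sel = select_donor_independent(screen_table(media, mode="osteo"))
        assert set(endo_sel) == set(ENDO_SIGNATURE)
        assert set(exo_sel) == set(EXO_SIGNATURE)

    def test_direction_flip_in_one_donor_excludes(self):
        rows = []
        for donor in (1, 2, 3):
            sign = -1 if donor == 3 else 1
            for day in (14, 21):
                rows.append({"metabolite": "X", "donor": donor, "day": day,
                             "n_ref": 3, "n_alt": 3,
                             "pct_variation": sign * 60.0, "p_value": 0.1,
                             "significant": False, "visual_only": False})
        for day in (14, 21):
            rows.append({"metabolite": "X", "donor": "pooled", "day": day,
                         "n_ref": 9, "n_alt": 9, "pct_variation": 40.0,
                         "p_value": 0.001, "significant": True,
                         "visual_only": False})
        assert select_donor_independent(pd.DataFrame(rows)) == []

    def test_magnitude_floor_excludes_weak_effects(self):
        rows = []
        for donor in (1, 2, 3):
            for day in (14, 21):
                rows.append({"metabolite": "X", "donor": donor, "day": day,
                             "n_ref": 3, "n_alt": 3, "pct_variation": 10.0,
                             "p_value": 0.1, "significant": False,
                             "visual_only": False})
        for day in (14, 21):
            rows.append({"metabolite": "X", "donor": "pooled", "day": day,
                         "n_ref": 9, "n_alt": 9, "pct_variation": 10.0,
                         "p_value": 0.001, "significant": True,
                         "visual_only": False})
        assert select_donor_independent(pd.DataFrame(rows)) == []

    def test_selection_monotone_in_effect_size(self):
        """Scaling every planted magnitude up never removes a selected
        metabolite (fixed seed and noise)."""
        import dataclasses
        lib = build_default_library()
        boosted = []
        for m in lib:
            prof = {}
            for key, bps in m.effect_profiles.items():
                prof[key] = [(d, 1.0 + 1.5 * (v - 1.0)) for d, v in bps]
            boosted.append(dataclasses.replace(m, effect_profiles=prof))
        from osteomet.library import MetaboliteLibrary
        cells_a, _ = _table_cohort(seed=4)
        cells_b, _ = _table_cohort(seed=4, lib=MetaboliteLibrary(boosted))
        sel_a = set(select_donor_independent(screen_table(cells_a)))
        sel_b = set(select_donor_independent(screen_table(cells_b)))
        assert sel_a <= sel_b

    def test_single_donor_rejected(self):
        rows = [{"metabolite": "X", "donor": 1, "day": 21, "n_ref": 3,
                 "n_alt": 3, "pct_variation": 50.0, "p_value": 0.1,
                 "significant": False, "visual_only": False}]
        with pytest.raises(ValueError, match="2 donors"):
            select_donor_independent(pd.DataFrame(rows))


class TestSpearman:
    def test_monotone_transform_gives_unit_rho(self):
        x = np.linspace(0, 3, 8)
        rho, p = spearman_rho_p(x, np.exp(x))
        assert rho == pytest.approx(1.0)
        assert p < 0.01

    def test_worked_five_point_example(self):
        """(1..5) vs (3,1,2,5,4): sum d^2 = 8 so rho = 1 - 48/120 = 0.6."""
        rho, p = spearman_rho_p([1, 2, 3, 4, 5], [3, 1, 2, 5, 4])
        assert rho == pytest.approx(0.6)
        assert 0 < p <= 1

    def test_exact_null_symmetry(self):
        """Under the exact permutation null the two-sided p of rho and -rho
        agree."""
        x = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        y = [2.0, 1.0, 4.0, 3.0, 6.0, 5.0]
        _, p_pos = spearman_rho_p(x, y)
        _, p_neg = spearman_rho_p(x, y[::-1])
        assert p_pos == pytest.approx(p_neg)

    def test_threshold_pair_retained_then_dropped(self):
        """A pair with 0.7 < rho < 0.8 and p < 0.001 passes the looser map
        threshold and fails the stricter one."""
        rng = np.random.default_rng(2)
        x = np.arange(40.0)
        y = x + rng.normal(0, 12, size=40)
        rho, p = spearman_rho_p(x, y)
        assert 0.7 < rho < 0.8 and p < 1e-3  # fixture sanity
        A = pd.DataFrame({"x": x, "y": y})
        loose = spearman_map(A, rho_min=0.7, p_max=1e-3)
        strict = spearman_map(A, rho_min=0.8, p_max=1e-3)
        assert len(loose) == 1
        assert len(strict) == 0

    def test_endo_exo_map_pairs_by_group_means(self, endo_table, exo_tables):
        _, exo_wide = exo_tables
        endo_means = pair_group_means(endo_table, ["UDP-GlcNAc",
                                                   "UDP-GalNAc", "Cho"])
        exo_means = pair_group_means(exo_wide, ["Lac", "Glc", "Orn"])
        pairs = spearman_map(endo_means, exo_means, rho_min=0.7, p_max=0.05)
        assert {"variable_a", "variable_b", "rho", "p_value"} <= set(
            pairs.columns)
        # planted: intracellular UDP species track extracellular Lac rise
        if len(pairs):
            assert (pairs["rho"].abs() > 0.7).all()

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            spearman_rho_p([1.0, 2.0], [2.0, 1.0])
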