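import math

import numpy as np
import pytest
from skbio.stats.distance import DistanceMatrix

import howlernet as hn
from howlernet.community_stats import arcsine_sqrt, ivi_table
from howlernet.io_model import Habitat, TransectRecord


def tr(site, transect, species, dbh, habitat=Habitat.continuous, x=0.0, y=0.0):
    return TransectRecord(site, habitat, transect, x, y, species, dbh)


class TestIVI:
    def test_single_species_scores_one(self):
        recs = [tr("s1", "t1", "Sp_A", 20), tr("s1", "t2", "Sp_A", 30)]
        (r,) = hn.compute_ivi(recs, "continuous")
        assert r.ivi == pytest.approx(1.0)

    def test_symmetric_species_split_evenly(self):
        recs = [
            tr("s1", "t1", "Sp_A", 25), tr("s1", "t1", "Sp_B", 25),
            tr("s1", "t2", "Sp_A", 25), tr("s1", "t2", "Sp_B", 25),
        ]
        for r in hn.compute_ivi(recs, "continuous"):
            assert r.ivi == pytest.approx(0.5)

    def test_hand_computed_three_species(self):
        # t1: A(20), B(10); t2: A(20)
        recs = [
            tr("s1", "t1", "Sp_A", 20),
            tr("s1", "t1", "Sp_B", 10),
            tr("s1", "t2", "Sp_A", 20),
        ]
        out = {r.species: r for r in hn.compute_ivi(recs, "continuous")}
        assert out["Sp_A"].relative_density == pytest.approx(2 / 3)
        assert out["Sp_A"].relative_frequency == pytest.approx(2 / 3)
        ba_a, ba_b = 2 * math.pi * 100, math.pi * 25
        assert out["Sp_A"].relative_dominance == pytest.approx(ba_a / (ba_a + ba_b))
        assert out["Sp_A"].ivi == pytest.approx(
            (2 / 3 + 2 / 3 + ba_a / (ba_a + ba_b)) / 3
        )

    def test_ivi_sums_to_one(self, study_scenario):
        for hab in ("continuous", "fragment"):
            total = sum(r.ivi for r in hn.compute_ivi(study_scenario.transects, hab))
            assert total == pytest.approx(1.0)

    def test_empty_habitat_errors(self):
        with pytest.raises(ValueError):
            hn.compute_ivi([tr("s1", "t1", "Sp_A", 20)], "fragment")


class TestJaccard:
    def test_identities(self):
        assert hn.jaccard({"a", "b"}, {"a", "b"}) == 1.0
        assert hn.jaccard({"a"}, {"b"}) == 0.0
        with pytest.raises(ValueError):
            hn.jaccard(set(), set())

    def test_diet_similarity_from_item_table(self, table3):
        from howlernet.io_model import species_items

        cont = {s for s, it in species_items(table3, "continuous").items() if it}
        frag = {s for s, it in species_items(table3, "fragment").items() if it}
        assert hn.jaccard(cont, frag) == pytest.approx(20 / 37)
        assert round(hn.jaccard(cont, frag), 2) == 0.54


def _random_distance(rng, n, ids):
    x = rng.random((n, 2)) * 10
    d = np.sqrt(((x[:, None, :] - x[None, :, :]) ** 2).sum(-1))
    return DistanceMatrix(d, ids)


class TestMantel:
    def test_identical_matrices_r_one(self):
        rng = np.random.default_rng(0)
        ids = list("abcdef")
        d = _random_distance(rng, 6, ids)
        res = hn.mantel_test(d, d, n_perm=99, seed=1)
        assert res.statistic == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1 / 100)

    def test_affine_transform_r_one(self):
        rng = np.random.default_rng(1)
        ids = list("abcde")
        d = _random_distance(rng, 5, ids)
        d2 = DistanceMatrix(2.5 * d.data, ids)
        res = hn.mantel_test(d, d2, n_perm=49, seed=1)
        assert res.statistic == pytest.approx(1.0)

    def test_agrees_with_skbio_statistic(self):
        from skbio.stats.distance import mantel as skbio_mantel

        rng = np.random.default_rng(2)
        ids = [f"t{i}" for i in range(7)]
        d1 = _random_distance(rng, 7, ids)
        d2 = _random_distance(rng, 7, ids)
        r_ref, _, _ = skbio_mantel(d1, d2, method="pearson", permutations=0)
        res = hn.mantel_test(d1, d2, n_perm=9, seed=0)
        assert res.statistic == pytest.approx(float(r_ref), abs=1e-12)

    def test_consistent_relabeling_preserves_p(self):
        rng = np.random.default_rng(3)
        ids = [f"t{i}" for i in range(6)]
        d1 = _random_distance(rng, 6, ids)
        d2 = _random_distance(rng, 6, ids)
        perm = rng.permutation(6)
        ids_p = [ids[i] for i in perm]
        d1p = DistanceMatrix(d1.data[np.ix_(perm, perm)], ids_p)
        d2p = DistanceMatrix(d2.data[np.ix_(perm, perm)], ids_p)
        r1 = hn.mantel_test(d1, d2, n_perm=199, seed=7)
        r2 = hn.mantel_test(d1p, d2p, n_perm=199, seed=7)
        assert r1.statistic == pytest.approx(r2.statistic)
        assert abs(r1.p_value - r2.p_value) <= 0.1

    def test_mismatched_labels_error(self):
        d1 = DistanceMatrix(np.array([[0.0, 1], [1, 0]]), ["a", "b"])
        d2 = DistanceMatrix(np.array([[0.0, 1], [1, 0]]), ["a", "c"])
        with pytest.raises(ValueError):
            hn.mantel_test(d1, d2)


class TestTransformedT:
    def test_identical_groups_t_zero(self):
        res = hn.transformed_t_test([1, 2, 3], [1, 2, 3], "log1p")
        assert res.statistic == pytest.approx(0.0)

    def test_df_convention(self):
        res = hn.transformed_t_test([1, 2, 3], [4, 5, 6, 7], "log1p")
        assert res.df == 5.0

    def test_matches_pooled_formula(self):
        x = np.log1p([3.0, 5.0, 9.0])
        y = np.log1p([2.0, 4.0, 4.5, 8.0])
        n1, n2 = len(x), len(y)
        sp2 = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / (n1 + n2 - 2)
        t_ref = (x.mean() - y.mean()) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
        res = hn.transformed_t_test([3, 5, 9], [2, 4, 4.5, 8], "log1p")
        assert res.statistic == pytest.approx(t_ref, abs=1e-12)

    def test_arcsine_bounds_enforced(self):
        with pytest.raises(ValueError):
            hn.transformed_t_test([0.5, 1.2], [0.1, 0.2], "arcsine_sqrt")


def test_arcsine_sqrt_monotone_and_endpoints():
    p = np.linspace(0, 1, 11)
    y = arcsine_sqrt(p)
    assert y[0] == 0.0 and y[-1] == pytest.approx(np.pi / 2)
    assert np.all(np.diff(y) > 0)


class TestItemFractions:
    def test_single_item_full_fraction(self, toy_records):
        only_mf = [r for r in toy_records if r.item is hn.Item.MF]
        table = hn.item_time_fractions(only_mf)
        assert table.loc["continuous", "MF"] == pytest.approx(1.0)

    def test_three_to_one_split(self, toy_records):
        table = hn.item_time_fractions(toy_records[:2])  # MF 5.0 vs IL 2.5
        assert table.loc["continuous", "MF"] == pytest.approx(2 / 3)
        assert table.loc["continuous", "IL"] == pytest.approx(1 / 3)

    def test_rows_sum_to_one(self, study_scenario):
        table = hn.item_time_fractions(study_scenario.records)
        assert table.sum(axis=1).values == pytest.approx(np.ones(len(table)))


class TestNestedAnova:
    def test_all_equal_values_give_zero_f(self):
        hab = ["c"] * 4 + ["f"] * 4
        item = ["MF", "MF", "IL", "IL"] * 2
        f_hab, f_item = hn.nested_anova([0.5] * 8, hab, item)
        assert f_hab.statistic == 0.0
        assert f_item.statistic == 0.0

    def test_balanced_toy_matches_hand_sums_of_squares(self):
        # 2 habitats x 2 items x 3 replicates, transform disabled via none
        values = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 2.0, 3.0, 4.0, 7.0, 8.0, 9.0]
        hab = ["A"] * 6 + ["B"] * 6
        item = ["x"] * 3 + ["y"] * 3 + ["x"] * 3 + ["y"] * 3
        y = np.array(values)
        grand = y.mean()
        means_h = {h: y[np.array(hab) == h].mean() for h in "AB"}
        ss_hab = sum(6 * (means_h[h] - grand) ** 2 for h in "AB")
        ss_item = 0.0
        ss_err = 0.0
        for h in "AB":
            for it in "xy":
                cell = y[(np.array(hab) == h) & (np.array(item) == it)]
                ss_item += 3 * (cell.mean() - means_h[h]) ** 2
                ss_err += ((cell - cell.mean()) ** 2).sum()
        f_hab_ref = (ss_hab / 1) / (ss_err / 8)
        f_item_ref = (ss_item / 2) / (ss_err / 8)
        f_hab, f_item = hn.nested_anova(values, hab, item, transform="none")
        assert f_hab.statistic == pytest.approx(f_hab_ref, abs=1e-10)
        assert f_item.statistic == pytest.approx(f_item_ref, abs=1e-10)
        assert f_hab.df == (1.0, 8.0)
        assert f_item.df == (2.0, 8.0)

    def test_agrees_with_statsmodels(self):
        import pandas as pd
        import statsmodels.api as sm
        from statsmodels.formula.api import ols

        rng = np.random.default_rng(0)
        rows = []
        for h in ("A", "B"):
            for it in ("x", "y", "z"):
                for _ in range(4):
                    rows.append({"h": h, "it": it, "v": rng.random() * 0.8 + 0.1})
        df = pd.DataFrame(rows)
        df["t"] = np.arcsin(np.sqrt(df["v"]))
        model = ols("t ~ C(h) + C(h):C(it)", data=df).fit()
        table = sm.stats.anova_lm(model, typ=1)
        f_hab, f_item = hn.nested_anova(df["v"], df["h"], df["it"])
        assert f_hab.statistic == pytest.approx(table.loc["C(h)", "F"], abs=1e-8)
        assert f_item.statistic == pytest.approx(table.loc["C(h):C(it)", "F"], abs=1e-8)

    def test_habitat_f_increases_with_effect_size(self):
        rng = np.random.default_rng(1)
        base = rng.random(12) * 0.3 + 0.2
        hab = ["A"] * 6 + ["B"] * 6
        item = ["x", "x", "x", "y", "y", "y"] * 2
        stats = []
        for effect in (0.0, 0.1, 0.2):
            values = base.copy()
            values[6:] += effect
            f_hab, _ = hn.nested_anova(values, hab, item, transform="none")
            stats.append(f_hab.statistic)
        assert stats[0] <= stats[1] <= stats[2]
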