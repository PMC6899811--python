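"""Sector grid, risk categories, targeting/avoiding split and chi-square tests."""

import numpy as np
import pandas as pd
import pytest

from mpabias.classification_stats import (
    RISK_LABELS,
    chi_square_uniform_sectors,
    quartile_sector_classify,
    risk_categories,
    strategy_split,
    transboundary_test,
)


def oracle_quartiles(values: np.ndarray) -> np.ndarray:
    """Independent quartile binning via explicit order-statistic interpolation."""
    srt = np.sort(values)
    n = len(srt)

    def q(p):  # linear interpolation between closest ranks
        h = (n - 1) * p
        lo = int(np.floor(h))
        hi = min(lo + 1, n - 1)
        return srt[lo] + (h - lo) * (srt[hi] - srt[lo])

    b1, b2, b3 = q(0.25), q(0.50), q(0.75)
    out = np.empty(n, dtype=int)
    for i, v in enumerate(values):
        if v <= b1:
            out[i] = 1
        elif v <= b2:
            out[i] = 2
        elif v <= b3:
            out[i] = 3
        else:
            out[i] = 4
    return out


def random_vectors(seed, n=232):
    """Protection/threat vectors with the heavy zero-protection ties of real data."""
    rng = np.random.default_rng(seed)
    protection = rng.beta(0.3, 4.0, size=n)
    protection[rng.random(n) < 0.45] = 0.0
    threat = rng.gamma(2.0, 0.2, size=n)
    idx = pd.Index([f"E{i:03d}" for i in range(n)], name="ecoregion_id")
    return pd.Series(protection, index=idx), pd.Series(threat, index=idx)


class TestSectorClassification:
    def test_eight_distinct_values_give_two_per_quartile(self):
        idx = pd.Index([f"E{i}" for i in range(8)])
        prot = pd.Series(np.arange(8.0), index=idx)
        threat = pd.Series(np.arange(8.0)[::-1], index=idx)
        out = quartile_sector_classify(prot, threat)
        assert out["protection_quartile"].value_counts().eq(2).all()
        assert out["threat_quartile"].value_counts().eq(2).all()

    def test_all_zero_protection_collapses_to_quartile_one(self):
        idx = pd.Index([f"E{i}" for i in range(8)])
        out = quartile_sector_classify(pd.Series(0.0, index=idx),
                                       pd.Series(np.arange(8.0), index=idx))
        assert (out["protection_quartile"] == 1).all()
        assert out["poorly_protected"].all()

    def test_sector_is_bijective_over_grid(self):
        idx = pd.Index([f"E{i}" for i in range(16)])
        rng = np.random.default_rng(0)
        out = quartile_sector_classify(
            pd.Series(rng.random(16), index=idx),
            pd.Series(rng.random(16), index=idx))
        recomputed = (out["protection_quartile"] - 1) * 4 + out["threat_quartile"]
        assert (out["sector"] == recomputed).all()
        assert out["sector"].between(1, 16).all()

    def test_fewer_than_four_ecoregions_rejected(self):
        idx = pd.Index(["E0", "E1", "E2"])
        with pytest.raises(ValueError, match="at least 4"):
            quartile_sector_classify(pd.Series([0.1, 0.2, 0.3], index=idx),
                                     pd.Series([1.0, 2.0, 3.0], index=idx))

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_sort_and_bin_oracle(self, seed):
        """232 ecoregions, heavy ties: equals an independent implementation."""
        prot, threat = random_vectors(seed)
        got = risk_categories(quartile_sector_classify(prot, threat))
        pq = oracle_quartiles(prot.to_numpy())
        tq = oracle_quartiles(threat.to_numpy())
        np.testing.assert_array_equal(got["protection_quartile"], pq)
        np.testing.assert_array_equal(got["threat_quartile"], tq)
        # oracle risk: poorly protected = at/below median, category by threat quartile
        med = np.median(prot.to_numpy())
        for eco, p, t in zip(prot.index, prot.to_numpy(), tq):
            if p <= med:
                assert got.loc[eco, "risk_category"] == RISK_LABELS[t]
            else:
                assert pd.isna(got.loc[eco, "risk_category"])

    def test_row_order_invariance(self):
        prot, threat = random_vectors(3)
        a = risk_categories(quartile_sector_classify(prot, threat))
        perm = np.random.default_rng(1).permutation(len(prot))
        b = risk_categories(quartile_sector_classify(prot.iloc[perm],
                                                     threat.iloc[perm]))
        pd.testing.assert_frame_equal(a.sort_index(), b.sort_index())

    def test_every_ecoregion_in_exactly_one_sector(self):
        prot, threat = random_vectors(5)
        out = quartile_sector_classify(prot, threat)
        assert out["sector"].notna().all()
        assert out["sector"].value_counts().sum() == len(prot)


class TestChiSquareSectors:
    def _classification(self, sectors):
        return pd.DataFrame({"sector": sectors})

    def test_uniform_counts_give_zero_statistic(self):
        res = chi_square_uniform_sectors(
            self._classification(list(range(1, 17)) * 3))
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)
        assert res.df == 15

    def test_fully_concentrated_counts_give_15n(self):
        n = 32
        res = chi_square_uniform_sectors(self._classification([7] * n))
        assert res.statistic == pytest.approx(15 * n)

    def test_expected_share_is_one_sixteenth(self):
        res = chi_square_uniform_sectors(self._classification([1, 2, 3, 4] * 8))
        assert (res.expected == 32 / 16).all()

    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(2)
        sectors = rng.integers(1, 17, size=100)
        res = chi_square_uniform_sectors(self._classification(list(sectors)))
        counts = np.bincount(sectors, minlength=17)[1:]
        expected = 100 / 16
        stat = ((counts - expected) ** 2 / expected).sum()
        assert res.statistic == pytest.approx(stat)

    def test_empty_classification_rejected(self):
        with pytest.raises(ValueError):
            chi_square_uniform_sectors(self._classification([]))


class TestStrategySplit:
    idx = pd.Index(["E0", "E1", "E2", "E3"], name="ecoregion_id")

    def _protection(self, protected):
        return pd.DataFrame({"protected_area_km2": protected,
                             "zone_area_km2": [100.0] * 4}, index=self.idx)

    def test_all_protection_in_low_threat_gives_zero_targeting_share(self):
        classes = pd.Series(["high", "high", "low", "low"], index=self.idx)
        out = strategy_split(self._protection([0, 0, 10, 10]), classes)
        s = out.set_index("threat_class")
        assert s.loc["high", "share_of_protection"] == 0.0
        assert s.loc["low", "share_of_protection"] == 1.0

    def test_equal_proportional_protection_ratio_one(self):
        classes = pd.Series(["high", "high", "low", "low"], index=self.idx)
        out = strategy_split(self._protection([5, 5, 5, 5]), classes).set_index(
            "threat_class")
        assert out.loc["low", "proportion_protected"] == pytest.approx(
            out.loc["high", "proportion_protected"])

    def test_avoiding_world_targeting_share_below_half(self):
        """Generator ground truth: bias away from threat -> targeting share < 0.5."""
        from mpabias.pipeline import stage_protect, stage_threat
        from tests.conftest import make_world

        world = make_world(seed=11, bias_beta=-2.0)
        threat = stage_threat(world)
        protect = stage_protect(world, seed=0)
        eco_threat = threat["eco_threat"][2013].set_index("ecoregion_id")[
            "mean_stoppable_threat"]
        classes = pd.Series(
            np.where(eco_threat > eco_threat.median(), "high", "low"),
            index=eco_threat.index)
        ep = protect["eco_summary"][("all", 2013)].set_index("ecoregion_id")
        out = strategy_split(ep[["protected_area_km2", "zone_area_km2"]],
                             classes).set_index("threat_class")
        assert out.loc["high", "share_of_protection"] < 0.5


class TestTransboundary:
    def _classified(self, risk, poorly=None):
        n = len(risk)
        df = pd.DataFrame({
            "sector": [1] * n,
            "threat_quartile": [1] * n,
            "poorly_protected": poorly if poorly is not None else [True] * n,
            "risk_category": risk,
        }, index=pd.Index([f"E{i}" for i in range(n)], name="ecoregion_id"))
        return df

    def test_uniform_classes_give_zero_statistic(self):
        labels = [RISK_LABELS[i] for i in (1, 2, 3, 4)]
        cls = self._classified(labels * 2)
        mult = pd.Series([1, 1, 1, 1, 2, 2, 2, 2], index=cls.index)
        res = transboundary_test(cls, mult)
        assert res.statistic == pytest.approx(0.0)
        assert res.df == 6

    def test_expected_share_is_quarter_per_category(self):
        labels = [RISK_LABELS[i] for i in (1, 2, 3, 4)]
        cls = self._classified(labels + ["crisis"] * 4)
        mult = pd.Series([1] * 4 + [2] * 4, index=cls.index)
        res = transboundary_test(cls, mult)
        np.testing.assert_allclose(res.expected.loc["single_country"], 1.0)
        np.testing.assert_allclose(res.expected.loc["transboundary"], 1.0)

    def test_contrived_table_matches_hand_computation(self):
        # single-country: 3/1/0/0, transboundary: 0/0/1/3
        risk = (["low_risk"] * 3 + ["moderate_risk"]
                + ["high_risk"] + ["crisis"] * 3)
        cls = self._classified(risk)
        mult = pd.Series([1, 1, 1, 1, 2, 2, 2, 2], index=cls.index)
        res = transboundary_test(cls, mult)
        stat = sum((o - 1.0) ** 2 / 1.0 for o in (3, 1, 0, 0, 0, 0, 1, 3))
        assert res.statistic == pytest.approx(stat)
        assert res.extras["transboundary_share"] == pytest.approx(0.5)

    def test_empty_border_class_skipped_with_warning(self, caplog):
        import logging
        risk = [RISK_LABELS[i] for i in (1, 2, 3, 4)]
        cls = self._classified(risk)
        mult = pd.Series([1, 1, 1, 1], index=cls.index)  # nothing transboundary
        with caplog.at_level(logging.WARNING):
            res = transboundary_test(cls, mult)
        assert res.df == 3
        assert res.extras["classes_tested"] == ["single_country"]

    def test_boosted_transboundary_threat_enriches_crisis(self):
        """Generator ground truth: extra threat on transboundary ecoregions."""
        from mpabias.pipeline import stage_protect, stage_threat
        from mpabias.classification_stats import quartile_sector_classify
        from tests.conftest import make_world

        crisis_share = {}
        for boost in (1.0, 4.0):
            counts = np.zeros(2)  # [single, trans] crisis counts
            for seed in range(5):
                world = make_world(seed=seed, n_ecoregions=32,
                                   transboundary_threat_boost=boost)
                threat = stage_threat(world)
                protect = stage_protect(world, seed=seed)
                eco_t = threat["eco_threat"][2013].set_index("ecoregion_id")[
                    "mean_stoppable_threat"]
                eco_p = protect["eco_summary"][("all", 2013)].set_index(
                    "ecoregion_id")["proportion_protected"]
                cls = risk_categories(quartile_sector_classify(eco_p, eco_t))
                mult = world.zones.groupby("ecoregion_id")["country_id"].nunique()
                crisis = cls["risk_category"] == "crisis"
                counts[0] += (crisis & (mult.reindex(cls.index) == 1)).sum()
                counts[1] += (crisis & (mult.reindex(cls.index) > 1)).sum()
            crisis_share[boost] = counts[1] / counts.sum()
        assert crisis_share[4.0] > crisis_share[1.0]
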