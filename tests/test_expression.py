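"""Normalization, per-region group comparison, brain-behavior correlation."""

import numpy as np
import pandas as pd
import pytest

import fosnet as f
from fosnet.expression import benjamini_hochberg, rank_transform
from fosnet.tables import BehaviorTable, CountTable


def _table(cond, arr, regions=None, prefix=None):
    arr = np.asarray(arr, dtype=float)
    regions = regions or [f"R{j}" for j in range(arr.shape[1])]
    subjects = [f"{prefix or cond}{i}" for i in range(arr.shape[0])]
    return CountTable(cond, pd.DataFrame(arr, index=subjects,
                                         columns=regions))


class TestNormalization:
    def test_constant_region_maps_to_100(self):
        a = _table("LI", [[7.0], [7.0], [7.0]])
        b = _table("HI", [[7.0], [7.0], [7.0]])
        na, nb = f.normalize_counts(a, b)
        assert (na.values() == 100.0).all() and (nb.values() == 100.0).all()

    def test_toy_two_value_example(self):
        # values 10 and 20, pooled mean 15 -> 66.67 and 133.33
        a = _table("LI", [[10.0]])
        b = _table("HI", [[20.0]])
        na, nb = f.normalize_counts(a, b)
        assert na.values()[0, 0] == pytest.approx(100 * 10 / 15)
        assert nb.values()[0, 0] == pytest.approx(100 * 20 / 15)

    def test_grand_mean_is_exactly_100_per_region(self):
        rng = np.random.default_rng(1)
        a = _table("LI", rng.lognormal(4, 0.5, (8, 5)))
        b = _table("HI", rng.lognormal(4.2, 0.5, (8, 5)))
        na, nb = f.normalize_counts(a, b)
        pooled = np.concatenate([na.values(), nb.values()])
        np.testing.assert_allclose(pooled.mean(axis=0), 100.0, rtol=1e-12)

    def test_zero_pooled_mean_rejected(self):
        a = _table("LI", [[0.0], [0.0], [0.0]])
        b = _table("HI", [[0.0], [0.0], [0.0]])
        with pytest.raises(ValueError, match="pooled mean 0"):
            f.normalize_counts(a, b)

    def test_region_mismatch_rejected(self):
        a = _table("LI", [[1.0], [2.0], [3.0]], regions=["X"])
        b = _table("HI", [[1.0], [2.0], [3.0]], regions=["Y"])
        with pytest.raises(ValueError, match="region sets differ"):
            f.normalize_counts(a, b)


class TestRegionComparison:
    def test_complete_separation_exact_p(self):
        a = _table("LI", [[1.0], [2.0], [3.0]])
        b = _table("HI", [[4.0], [5.0], [6.0]])
        (cmp,) = f.region_group_comparison(a, b)
        assert cmp.u_statistic == 0.0
        assert cmp.p_raw == pytest.approx(0.1)
        assert cmp.p_adjusted is None

    def test_identical_groups_p_one(self):
        a = _table("LI", [[1.0], [2.0], [3.0]])
        b = _table("HI", [[1.0], [2.0], [3.0]])
        (cmp,) = f.region_group_comparison(a, b)
        assert cmp.p_raw == pytest.approx(1.0)

    def test_bh_adjustment_monotone_and_bounded(self):
        rng = np.random.default_rng(2)
        a = _table("LI", rng.normal(100, 10, (8, 7)))
        b = _table("HI", rng.normal(105, 10, (8, 7)))
        rows = f.region_group_comparison(a, b, adjust="bh")
        for r in rows:
            assert r.p_adjusted >= r.p_raw - 1e-12
            assert r.p_adjusted <= 1.0
        raw = [r.p_raw for r in rows]
        np.testing.assert_allclose(
            benjamini_hochberg(raw), [r.p_adjusted for r in rows])

    def test_null_rejection_rate_calibrated(self, null_config):
        """Independent groups: exact MW rejects ~5% at alpha=0.05."""
        import fosnet.simulate as sim
        hits = 0
        trials = 0
        for k in range(300):
            cfg = sim.SimConfig(block_structure={"IND": ()}, rho_within=0.5,
                                rho_between=0.0, seed=k,
                                regions=("R0", "R1"))
            t = f.generate_condition_counts(cfg, "IND")
            a = _table("LI", t.values()[:, :1][:4], prefix="a")
            b = _table("HI", t.values()[:, :1][4:], prefix="b")
            (cmp,) = f.region_group_comparison(a, b)
            trials += 1
            hits += cmp.p_raw < 0.05
        # exact test is discrete: achieved level below but near 0.05
        assert hits / trials <= 0.08
        assert hits / trials >= 0.005


class TestNormalizationRankInvariance:
    def test_mw_and_spearman_unchanged_by_normalization(self):
        rng = np.random.default_rng(3)
        a = _table("LI", rng.lognormal(4, 0.4, (8, 4)))
        b = _table("HI", rng.lognormal(4, 0.4, (8, 4)))
        na, nb = f.normalize_counts(a, b)
        raw_cmp = f.region_group_comparison(a, b)
        norm_cmp = f.region_group_comparison(na, nb)
        for r1, r2 in zip(raw_cmp, norm_cmp):
            assert r1.u_statistic == pytest.approx(r2.u_statistic)
            assert r1.p_raw == pytest.approx(r2.p_raw)
        rho_raw, _ = f.spearman_matrix(a)
        rho_norm, _ = f.spearman_matrix(na)
        pd.testing.assert_frame_equal(rho_raw, rho_norm)

    def test_rank_transform_idempotent_for_network(self):
        rng = np.random.default_rng(4)
        a = _table("LI", rng.lognormal(4, 0.4, (8, 4)))
        net_raw = f.build_network(a)
        net_rank = f.build_network(rank_transform(a))
        pd.testing.assert_frame_equal(net_raw.rho, net_rank.rho)
        pd.testing.assert_frame_equal(net_raw.edges, net_rank.edges)


class TestBrainBehavior:
    @staticmethod
    def _beh(cond, d2_sorted):
        n = len(d2_sorted)
        t_total = np.full(n, 20.0)
        t_old = t_total * (1 + np.asarray(d2_sorted)) / 2
        return BehaviorTable.from_times(
            cond, [f"{cond}{i}" for i in range(n)], t_old, t_total - t_old)

    def test_monotone_counts_give_extreme_rho(self):
        beh = self._beh("LI", [0.1, 0.2, 0.3, 0.4, 0.5])
        up = _table("LI", np.arange(5)[:, None] + 1.0, regions=["R"])
        down = _table("LI", (5 - np.arange(5))[:, None] * 1.0, regions=["R"])
        r_up = f.brain_behavior_correlation(beh, up)
        r_down = f.brain_behavior_correlation(beh, down)
        assert r_up.loc["R", "rho"] == pytest.approx(1.0)
        assert r_down.loc["R", "rho"] == pytest.approx(-1.0)

    def test_constant_column_reported_missing(self):
        beh = self._beh("LI", [0.1, 0.2, 0.3, 0.4])
        t = _table("LI", np.column_stack([np.full(4, 3.0),
                                          np.arange(4.0)]),
                   regions=["FLAT", "VAR"])
        out = f.brain_behavior_correlation(beh, t)
        assert np.isnan(out.loc["FLAT", "rho"])
        assert np.isfinite(out.loc["VAR", "rho"])

    def test_subject_misalignment_rejected(self):
        beh = self._beh("LI", [0.1, 0.2, 0.3, 0.4])
        t = _table("LI", np.arange(4.0)[:, None], prefix="other")
        with pytest.raises(ValueError, match="different subjects"):
            f.brain_behavior_correlation(beh, t)
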