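"""Statistics: rising slopes, cluster permutation tests, ROI aggregation,
repeated-measures ANOVA."""

import numpy as np
import pandas as pd
import pytest

import neorhythm as nr
from neorhythm.stats import (
    anova_suite,
    rising_slope,
    rm_anova,
    roi_aggregate,
    spatial_cluster_test,
    temporal_cluster_test,
    tukey_kramer,
)

TIMES = np.arange(30) - 5.0  # 1 Hz bin labels, -5 .. 24 s


def _stack_from(traces_rc, traces_ac):
    """(n_part, 1 channel, 2 cond, T) stack from per-participant traces."""
    rc = np.asarray(traces_rc)[:, None, None, :]
    ac = np.asarray(traces_ac)[:, None, None, :]
    return np.concatenate([rc, ac], axis=2)


class TestRisingSlope:
    def test_linear_ramp(self):
        trace = np.zeros(30)
        trace[5:16] = np.linspace(0, 2, 11)  # 0 at t=0 to 2 z at t=10
        trace[16:] = 0.0
        stack = _stack_from([trace], [trace])
        res = rising_slope(stack, TIMES)
        assert res.slope[0, 0, 0] == pytest.approx(0.2)
        assert res.peak_time_s[0, 0, 0] == 10.0

    def test_equal_slopes_normalize_to_zero(self):
        trace = np.zeros(30)
        trace[5:] = np.linspace(0, 2, 25)
        res = rising_slope(_stack_from([trace], [trace]), TIMES)
        assert res.normalized[0, 0] == pytest.approx(0.0)

    def test_zero_arrhythmic_slope_normalizes_to_one(self):
        rc = np.zeros(30)
        rc[5:16] = np.linspace(0, 2, 11)
        ac = np.zeros(30)
        ac[6] = 1e-12  # peak > onset but essentially zero slope
        res = rising_slope(_stack_from([rc], [ac]), TIMES)
        assert res.normalized[0, 0] == pytest.approx(1.0)

    def test_antisymmetry_under_condition_swap(self):
        rng = np.random.default_rng(0)
        rc = np.abs(rng.normal(1, 0.3, (6, 30)))
        ac = np.abs(rng.normal(0.7, 0.3, (6, 30)))
        a = rising_slope(_stack_from(rc, ac), TIMES)
        b = rising_slope(_stack_from(ac, rc), TIMES)
        assert np.allclose(a.normalized, -b.normalized, equal_nan=True)

    def test_zero_denominator_warns_nan(self):
        flat = np.zeros(30)  # both slopes are exactly zero
        with pytest.warns(UserWarning, match="undefined"):
            res = rising_slope(_stack_from([flat], [flat]), TIMES)
        assert np.isnan(res.normalized[0, 0])


class TestTemporalCluster:
    def test_identical_series_no_clusters(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=(8, 25))
        res = temporal_cluster_test(a, a, nr.ClusterConfig(n_permutations=100))
        assert res.clusters == []

    def test_strong_effect_found(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=(10, 25))
        a[:, 8:14] += 2.0
        res = temporal_cluster_test(a, 0.0, nr.ClusterConfig(n_permutations=500), seed=0)
        sig = res.significant(0.05)
        assert sig, "expected a significant cluster"
        assert set(range(9, 13)) <= set(sig[0].members.tolist())

    def test_exhaustive_enumeration_small_n(self):
        rng = np.random.default_rng(2)
        a = rng.normal(size=(6, 20)) + 0.8
        res = temporal_cluster_test(a, 0.0, nr.ClusterConfig(n_permutations=500))
        assert res.exhaustive and res.n_permutations == 64
        for c in res.clusters:
            assert c.p_perm >= 1 / 64

    def test_sampled_agrees_with_exhaustive(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            a = rng.normal(size=(8, 25)) + 0.4
            ex = temporal_cluster_test(a, 0.0, nr.ClusterConfig(n_permutations=8000))
            sa = temporal_cluster_test(
                a, 0.0, nr.ClusterConfig(n_permutations=8000, exhaustive_max_n=0),
                seed=11,
            )
            assert ex.exhaustive and not sa.exhaustive
            for ce, cs in zip(ex.clusters, sa.clusters):
                assert abs(ce.p_perm - cs.p_perm) < 0.02

    def test_too_few_participants(self):
        with pytest.raises(ValueError):
            temporal_cluster_test(np.zeros((1, 10)), 0.0, nr.ClusterConfig())


class TestSpatialCluster:
    @staticmethod
    def _isolated_effect(montage):
        """Effect confined to channel 17; all other channels are exact zero
        differences, so no neighbor can be supra-threshold."""
        rng = np.random.default_rng(4)
        n_ch = montage.n_channels
        a = np.zeros((10, n_ch))
        a[:, 17] = 5.0 + rng.normal(0, 0.1, 10)
        return a, np.zeros_like(a)

    def test_singleton_cluster_allowed(self, montage):
        """An isolated supra-threshold channel forms a candidate cluster."""
        a, b = self._isolated_effect(montage)
        res = spatial_cluster_test(a, b, montage,
                                   nr.ClusterConfig(n_permutations=200), seed=0)
        assert any(c.members.tolist() == [17] for c in res.clusters)

    def test_min_cluster_size_switch(self, montage):
        a, b = self._isolated_effect(montage)
        res = spatial_cluster_test(
            a, b, montage,
            nr.ClusterConfig(n_permutations=50, min_cluster_size=2), seed=0,
        )
        assert not any(c.members.tolist() == [17] for c in res.clusters)

    def test_channel_relabeling_invariance(self, montage):
        """Permutation p-values do not depend on channel ordering."""
        rng = np.random.default_rng(5)
        n_ch = montage.n_channels
        a = rng.normal(size=(9, n_ch))
        a[:, [20, 21, 22]] += 1.5
        cfg = nr.ClusterConfig(n_permutations=300)
        res1 = spatial_cluster_test(a, np.zeros_like(a), montage, cfg, seed=7)
        perm = rng.permutation(n_ch)
        inv = np.argsort(perm)
        res2 = spatial_cluster_test(a[:, perm], np.zeros_like(a), montage, cfg,
                                    seed=7, channel_indices=perm)
        p1 = sorted(round(c.p_perm, 6) for c in res1.clusters)
        p2 = sorted(round(c.p_perm, 6) for c in res2.clusters)
        assert p1 == p2

    def test_clusters_are_connected(self, montage):
        rng = np.random.default_rng(6)
        a = rng.normal(size=(10, montage.n_channels)) * 2
        res = spatial_cluster_test(a, np.zeros_like(a), montage,
                                   nr.ClusterConfig(n_permutations=20), seed=0)
        radius = montage.default_neighbor_radius()
        adj = montage.adjacency(radius)
        for c in res.clusters:
            if c.members.size == 1:
                continue
            sub = adj[np.ix_(c.members, c.members)]
            # connectedness: BFS from the first member reaches all
            seen = {0}
            frontier = [0]
            while frontier:
                u = frontier.pop()
                for v in np.flatnonzero(sub[u]):
                    if v not in seen:
                        seen.add(v)
                        frontier.append(v)
            assert len(seen) == c.members.size


class TestRoiAggregate:
    def test_constant_window_mean(self, montage):
        n_ch = montage.n_channels
        stack = np.ones((3, n_ch, 2, 30))
        tab = roi_aggregate(stack, TIMES, montage)
        assert np.allclose(tab.hbo, 1.0)
        assert set(tab.roi) == {"auditory", "sensorimotor", "premotor"}
        assert len(tab) == 3 * 2 * 3 * 2

    def test_channel_averaging(self, montage):
        n_ch = montage.n_channels
        stack = np.zeros((1, n_ch, 2, 30))
        chans = [c.index for c in montage.channels_of("left", "auditory")][:2]
        other = [c.index for c in montage.channels_of("left", "auditory")][2:]
        stack[0, chans[0]] = 1.0
        stack[0, chans[1]] = 3.0
        retained = np.zeros(n_ch, dtype=bool)
        retained[chans] = True
        retained[[c.index for c in montage.channels_of()
                  if c.region in ("sensorimotor", "premotor")]] = True
        tab = roi_aggregate(stack, TIMES, montage, retained)
        val = tab[(tab.roi == "auditory") & (tab.hemisphere == "left")].hbo.iloc[0]
        assert val == pytest.approx(2.0)

    def test_window_is_8_to_12_inclusive(self, montage):
        n_ch = montage.n_channels
        stack = np.zeros((1, n_ch, 2, 30))
        sel = (TIMES >= 8) & (TIMES <= 12)
        assert sel.sum() == 5
        stack[..., sel] = 1.0
        tab = roi_aggregate(stack, TIMES, montage)
        assert np.allclose(tab.hbo, 1.0)


def _balanced_table(seed=0, n=8, effect=0.0):
    rng = np.random.default_rng(seed)
    rows = []
    for p in range(n):
        for c in ("rhythmic", "arrhythmic"):
            for roi in ("sensorimotor", "auditory", "premotor"):
                for h in ("left", "right"):
                    mu = 1.0 + effect * (c == "rhythmic") * (roi == "sensorimotor")
                    rows.append(dict(participant=p, condition=c, roi=roi,
                                     hemisphere=h, hbo=rng.normal(mu, 0.4)))
    return pd.DataFrame(rows)


class TestRmAnova:
    def test_zero_condition_difference(self):
        df = _balanced_table(seed=1)
        piv = df.pivot_table(index=["participant", "roi", "hemisphere"],
                             columns="condition", values="hbo").reset_index()
        piv["arrhythmic"] = piv["rhythmic"]  # force exact equality
        df2 = piv.melt(id_vars=["participant", "roi", "hemisphere"],
                       value_vars=["rhythmic", "arrhythmic"],
                       var_name="condition", value_name="hbo")
        res = rm_anova(df2)
        assert res["condition"].F == pytest.approx(0.0, abs=1e-20)
        assert res["condition"].p == pytest.approx(1.0)

    def test_matches_statsmodels(self):
        """Independent oracle: statsmodels AnovaRM on the same table."""
        from statsmodels.stats.anova import AnovaRM

        df = _balanced_table(seed=2, effect=0.5)
        mine = rm_anova(df)
        ref = AnovaRM(df, "hbo", "participant",
                      within=["condition", "roi", "hemisphere"]).fit().anova_table
        key_map = {
            "condition": "condition", "roi": "roi", "hemisphere": "hemisphere",
            "condition:roi": "condition x roi",
            "condition:hemisphere": "condition x hemisphere",
            "roi:hemisphere": "roi x hemisphere",
            "condition:roi:hemisphere": "condition x roi x hemisphere",
        }
        for sm_name, my_name in key_map.items():
            assert mine[my_name].F == pytest.approx(ref.loc[sm_name, "F Value"])
            assert mine[my_name].p == pytest.approx(ref.loc[sm_name, "Pr > F"])

    def test_matches_pingouin_gg(self):
        """Greenhouse-Geisser epsilon and corrected p vs pingouin."""
        import pingouin as pg

        df = _balanced_table(seed=3).groupby(
            ["participant", "roi"], as_index=False
        ).hbo.mean()
        mine = rm_anova(df, ["roi"])["roi"]
        ref = pg.rm_anova(data=df, dv="hbo", within="roi",
                          subject="participant", correction=True)
        assert mine.F == pytest.approx(float(ref["F"].iloc[0]))
        assert mine.gg_epsilon == pytest.approx(float(ref["eps"].iloc[0]), abs=1e-6)
        assert mine.p_gg == pytest.approx(float(ref["p_GG_corr"].iloc[0]), abs=1e-6)
        sph = pg.sphericity(df, dv="hbo", within="roi", subject="participant")
        assert mine.mauchly_p == pytest.approx(float(sph.pval), abs=1e-6)

    def test_partial_eta_squared_identity(self):
        df = _balanced_table(seed=4, effect=0.4)
        res = rm_anova(df)
        for e in res.effects.values():
            expect = e.F * e.df_num / (e.F * e.df_num + e.df_den)
            assert e.eta_p2 == pytest.approx(expect)

    def test_sum_of_squares_partition(self):
        """Effect + error partitions plus subject SS recover total SS."""
        df = _balanced_table(seed=5, effect=0.3)
        res = rm_anova(df)
        y = df.hbo.to_numpy()
        ss_total = float(((y - y.mean()) ** 2).sum())
        cells = len(df) // df.participant.nunique()
        subj = df.groupby("participant").hbo.mean().to_numpy()
        ss_subj = cells * float(((subj - y.mean()) ** 2).sum())
        parts = sum(e.ss_effect + e.ss_error for e in res.effects.values())
        assert ss_subj + parts == pytest.approx(ss_total)

    def test_missing_cells_error(self):
        df = _balanced_table(seed=6)
        df = df[~((df.participant == 0) & (df.roi == "premotor"))]
        with pytest.raises(ValueError, match="missing cells"):
            rm_anova(df)

    def test_suite_runs_all_followups(self):
        df = _balanced_table(seed=7, effect=0.6)
        suite = anova_suite(df)
        assert set(suite.by_condition) == {"rhythmic", "arrhythmic"}
        assert set(suite.by_roi) == {"sensorimotor", "auditory", "premotor"}
        assert len(suite.posthoc_roi) == 3
        assert ((suite.posthoc_roi.p_tukey >= 0) & (suite.posthoc_roi.p_tukey <= 1)).all()


class TestTukey:
    def test_detects_separated_level(self):
        rng = np.random.default_rng(8)
        rows = []
        for p in range(10):
            for roi, mu in (("sensorimotor", 0.0), ("auditory", 2.0), ("premotor", 0.1)):
                rows.append(dict(participant=p, roi=roi, hbo=rng.normal(mu, 0.3)))
        out = tukey_kramer(pd.DataFrame(rows), "roi")
        sep = out[(out.a == "auditory") | (out.b == "auditory")]
        same = out[(out.a != "auditory") & (out.b != "auditory")]
        assert (sep.p_tukey < 0.01).all()
        assert (same.p_tukey > 0.1).all()
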