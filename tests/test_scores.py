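"""Performance scoring against hand-computed and brute-force oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from switchddm import scores


def _trials(rows):
    return pd.DataFrame(rows)


class TestScoreCells:
    def test_speed_is_mean_of_reciprocals(self):
        t = _trials([
            dict(subject=0, block=1, s=0, i=0, accuracy=1, rt=0.5),
            dict(subject=0, block=1, s=0, i=0, accuracy=1, rt=1.0),
        ])
        c = scores.score_cells(t)
        assert c.speed.iloc[0] == pytest.approx(1.5)
        assert c.mean_rt.iloc[0] == pytest.approx(0.75)
        c2 = scores.score_cells(t, speed_of_mean=True)
        assert c2.speed.iloc[0] == pytest.approx(1 / 0.75)

    def test_probit_at_half(self):
        t = _trials([
            dict(subject=0, block=1, s=0, i=0, accuracy=a, rt=0.6)
            for a in (0, 1)
        ])
        c = scores.score_cells(t, probit_correction=False)
        assert c.probit_error.iloc[0] == pytest.approx(0.0)

    def test_probit_edge_correction(self):
        t = _trials([
            dict(subject=0, block=1, s=0, i=0, accuracy=1, rt=0.6)
            for _ in range(32)
        ])
        c = scores.score_cells(t)
        assert c.probit_error.iloc[0] == pytest.approx(stats.norm.ppf(0.5 / 33), abs=1e-9)
        assert np.isfinite(c.probit_error.iloc[0])

    def test_empty_correct_cell_flagged(self):
        t = _trials([
            dict(subject=0, block=1, s=0, i=0, accuracy=0, rt=0.6)
            for _ in range(4)
        ])
        c = scores.score_cells(t)
        assert c.empty_correct.iloc[0]
        assert np.isnan(c.speed.iloc[0])


class TestEffectScores:
    @staticmethod
    def _cells(vals):
        return pd.DataFrame([
            dict(subject=0, block=1, s=s, i=i, mean_rt=vals[(s, i)])
            for s in (0, 1) for i in (0, 1)
        ])

    def test_zero_when_cells_equal(self):
        e = scores.effect_scores(self._cells({(0, 0): .7, (0, 1): .7, (1, 0): .7, (1, 1): .7}))
        for col in ("global_switch", "specific_switch", "global_incon", "specific_incon"):
            assert e[col].iloc[0] == pytest.approx(0.0)

    def test_worked_example(self):
        # cell means near a typical first mixed block (ms: 700/720/825/886)
        e = scores.effect_scores(self._cells({(0, 0): .700, (0, 1): .720,
                                              (1, 0): .825, (1, 1): .886}))
        assert e.specific_switch.iloc[0] == pytest.approx(125.0)
        assert e.global_switch.iloc[0] == pytest.approx(145.5)
        assert e.specific_incon.iloc[0] == pytest.approx(20.0)

    def test_shift_invariance(self, rng):
        vals = {k: rng.uniform(0.5, 1.0) for k in itertools.product((0, 1), (0, 1))}
        shifted = {k: v + 0.123 for k, v in vals.items()}
        e1 = scores.effect_scores(self._cells(vals))
        e2 = scores.effect_scores(self._cells(shifted))
        for col in ("global_switch", "specific_switch", "global_incon", "specific_incon"):
            assert e1[col].iloc[0] == pytest.approx(e2[col].iloc[0], abs=1e-9)

    def test_global_equals_specific_without_interaction(self):
        e = scores.effect_scores(self._cells({(0, 0): .7, (0, 1): .75,
                                              (1, 0): .8, (1, 1): .85}))
        assert e.global_switch.iloc[0] == pytest.approx(e.specific_switch.iloc[0])
        assert e.global_incon.iloc[0] == pytest.approx(e.specific_incon.iloc[0])

    def test_missing_cell_raises(self):
        c = self._cells({(0, 0): .7, (0, 1): .72, (1, 0): .8, (1, 1): .85})
        with pytest.raises(ValueError, match="missing cell"):
            scores.effect_scores(c[~((c.s == 1) & (c.i == 1))])


def _brute_force_rm_anova(Y):
    """Independent sums-of-squares oracle for subject x A x B designs,
    written as explicit mean loops."""
    n, pa, pb = Y.shape
    gm = Y.mean()
    mA = Y.mean(axis=(0, 2))
    mB = Y.mean(axis=(0, 1))
    mS = Y.mean(axis=(1, 2))
    mAB = Y.mean(axis=0)
    mSA = Y.mean(axis=2)
    mSB = Y.mean(axis=1)
    ss = {}
    ss["A"] = n * pb * ((mA - gm) ** 2).sum()
    ss["B"] = n * pa * ((mB - gm) ** 2).sum()
    ss["AB"] = n * ((mAB - mA[:, None] - mB[None, :] + gm) ** 2).sum()
    ss["SA"] = pb * ((mSA - mS[:, None] - mA[None, :] + gm) ** 2).sum()
    ss["SB"] = pa * ((mSB - mS[:, None] - mB[None, :] + gm) ** 2).sum()
    resid = (Y - mAB[None] - mSA[:, :, None] - mSB[:, None, :]
             + mA[None, :, None] + mB[None, None, :] + mS[:, None, None] - gm)
    ss["SAB"] = (resid ** 2).sum()
    return ss


class TestRmAnova:
    def test_constant_data_gives_zero_f(self):
        rows = [dict(subject=s, b=b, c=c, y=3.0)
                for s in range(6) for b in range(3) for c in range(2)]
        res = scores.rm_anova(pd.DataFrame(rows), "y", ["b", "c"])
        assert (res.F == 0).all()

    def test_matches_brute_force_oracle(self, rng):
        n, pa, pb = 9, 3, 4
        Y = rng.normal(size=(n, pa, pb))
        rows = [dict(subject=s, A=a, B=b, y=Y[s, a, b])
                for s in range(n) for a in range(pa) for b in range(pb)]
        res = scores.rm_anova(pd.DataFrame(rows), "y", ["A", "B"]).set_index("term")
        ss = _brute_force_rm_anova(Y)
        assert res.loc["A", "ss"] == pytest.approx(ss["A"], abs=1e-8)
        assert res.loc["B", "ss"] == pytest.approx(ss["B"], abs=1e-8)
        assert res.loc["A x B", "ss"] == pytest.approx(ss["AB"], abs=1e-8)
        assert res.loc["A", "ss_error"] == pytest.approx(ss["SA"], abs=1e-8)
        assert res.loc["B", "ss_error"] == pytest.approx(ss["SB"], abs=1e-8)
        assert res.loc["A x B", "ss_error"] == pytest.approx(ss["SAB"], abs=1e-8)

    def test_matches_pingouin(self, rng):
        pg = pytest.importorskip("pingouin")
        rows = [dict(subject=s, b=b, c=c,
                     y=0.3 * b + 0.5 * c + rng.normal())
                for s in range(10) for b in range(3) for c in range(2)]
        df = pd.DataFrame(rows)
        ours = scores.rm_anova(df, "y", ["b", "c"]).set_index("term")
        theirs = pg.rm_anova(data=df, dv="y", within=["b", "c"],
                             subject="subject", detailed=True).set_index("Source")
        for ours_t, pg_t in (("b", "b"), ("c", "c"), ("b x c", "b * c")):
            assert ours.loc[ours_t, "F"] == pytest.approx(theirs.loc[pg_t, "F"], rel=1e-6)
            assert ours.loc[ours_t, "p"] == pytest.approx(theirs.loc[pg_t, "p_unc"], abs=1e-8)

    def test_injected_effect_detected(self, rng):
        rows = [dict(subject=s, sw=sw, inc=inc,
                     y=0.4 * sw + rng.normal(scale=0.5) + 0.1 * s % 2)
                for s in range(100) for sw in (0, 1) for inc in (0, 1)]
        res = scores.rm_anova(pd.DataFrame(rows), "y", ["sw", "inc"]).set_index("term")
        assert res.loc["sw", "p"] < 0.001
        assert res.loc["inc", "p"] > 0.01

    def test_block_df_with_101_subjects(self, rng):
        rows = [dict(subject=s, block=b, y=rng.normal())
                for s in range(101) for b in range(3)]
        res = scores.rm_anova(pd.DataFrame(rows), "y", ["block"])
        assert (int(res.df.iloc[0]), int(res.df_error.iloc[0])) == (2, 200)

    def test_incomplete_design_raises(self):
        rows = [dict(subject=s, b=b, y=1.0) for s in range(4) for b in range(3)]
        df = pd.DataFrame(rows).drop(index=0)
        with pytest.raises(ValueError, match="incomplete"):
            scores.rm_anova(df, "y", ["b"])


class TestRnbScoring:
    @staticmethod
    def _records(correct_fn):
        rows = []
        b = 0
        for load in (1, 2, 3, 4):
            for upd in (6, 9, 12):
                b += 1
                for t in range(upd):
                    rows.append(dict(subject=0, phase="test", block=b, load=load,
                                     n_updates=upd, trial_index=t,
                                     correct=correct_fn(load, upd, t)))
        for t in range(6):  # practice never counts
            rows.append(dict(subject=0, phase="practice", block=0, load=2,
                             n_updates=6, trial_index=t, correct=1))
        return pd.DataFrame(rows)

    def test_all_correct_gives_81(self):
        w = scores.score_rnb(self._records(lambda *a: 1))
        assert int(w.partial_credit_total.iloc[0]) == 81
        assert (w[["parcel_1", "parcel_2", "parcel_3"]].iloc[0] == 27).all()

    def test_load_one_excluded(self):
        all_right = scores.score_rnb(self._records(lambda l, u, t: 1))
        load1_wrong = scores.score_rnb(self._records(lambda l, u, t: 0 if l == 1 else 1))
        assert all_right.partial_credit_total.iloc[0] == load1_wrong.partial_credit_total.iloc[0]

    def test_total_is_brute_force_count(self, rng):
        flips = {}

        def f(l, u, t):
            flips[(l, u, t)] = int(rng.random() < 0.7)
            return flips[(l, u, t)]

        w = scores.score_rnb(self._records(f))
        manual = sum(v for (l, u, t), v in flips.items() if l >= 2)
        assert int(w.partial_credit_total.iloc[0]) == manual
        assert w.partial_credit_total.iloc[0] == (
            w.parcel_1 + w.parcel_2 + w.parcel_3).iloc[0]

    def test_parcels_are_latin_square(self):
        for blocks in scores.PARCEL_ASSIGNMENT.values():
            assert sorted(l for l, _u in blocks) == [2, 3, 4]
            assert sorted(u for _l, u in blocks) == [6, 9, 12]

    def test_missing_block_raises(self):
        bs = pd.DataFrame(dict(load=[2, 2, 2], n_updates=[6, 9, 12], correct=[5, 8, 10]))
        with pytest.raises(ValueError, match="missing"):
            scores.build_parcels(bs)


def test_speed_transform_reduces_skew(small_cohort):
    trials = small_cohort["trials"]
    sc = trials[(~trials.warmup) & (trials.accuracy == 1)]
    g = sc[(sc.switch_flag == 0) & (sc.incon_flag == 0)]
    rt_skew = stats.skew(g.rt)
    speed_skew = stats.skew(1.0 / g.rt)
    assert abs(speed_skew) < abs(rt_skew)
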