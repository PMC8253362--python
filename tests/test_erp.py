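"""ERP averaging, window amplitudes, behavioral filtering, and rm-ANOVA."""

import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from tmsnet import synthetic as syn
from tmsnet.containers import EpochSet
from tmsnet.erp import (
    ComponentWindow,
    average_erp,
    behavior_summary,
    filter_trials,
    rm_anova_gg,
    window_amplitude,
)


def make_epochs(data, fs=1000.0, channels=None, metadata=None, mask=None,
                t0_offset=0.0):
    n_trials, n_ch, n_t = data.shape
    channels = channels or [f"ch{i}" for i in range(n_ch)]
    times = np.arange(n_t) / fs + t0_offset
    return EpochSet(data=data, times=times, fs=fs, channels=channels,
                    align_label="TMS", metadata=metadata, mask=mask)


class TestAverageErp:
    def test_single_trial_average_is_identity(self):
        data = np.random.default_rng(0).standard_normal((1, 2, 50))
        avg = average_erp(make_epochs(data))
        np.testing.assert_array_equal(avg[("all",)], data[0])

    def test_opposite_waveforms_cancel(self):
        wave = np.random.default_rng(1).standard_normal((1, 2, 50))
        data = np.concatenate([wave, -wave])
        avg = average_erp(make_epochs(data))
        np.testing.assert_allclose(avg[("all",)], 0.0, atol=1e-12)

    def test_masked_samples_excluded_from_mean(self):
        data = np.ones((2, 1, 10))
        data[1, 0, 3] = 100.0
        mask = np.zeros((2, 10), bool)
        mask[1, 3] = True  # the outlier sample is flagged bad
        avg = average_erp(make_epochs(data, mask=mask))
        assert avg[("all",)][0, 3] == pytest.approx(1.0)

    def test_grouped_averages_by_metadata(self):
        data = np.zeros((4, 1, 5))
        data[2:] = 1.0
        md = pd.DataFrame({"condition": ["sham", "sham", "real", "real"]})
        avg = average_erp(make_epochs(data, metadata=md), ["condition"])
        assert avg[("sham",)][0, 0] == 0.0
        assert avg[("real",)][0, 0] == 1.0

    def test_planted_template_recovered_under_noise(self):
        # N270-like bump at -6 uV on white noise sigma=10: CLT bound 3*10/sqrt(200)
        rng = np.random.default_rng(2)
        n_trials, fs = 200, 1000.0
        t = np.arange(1000) / fs  # 0..1 s, S2 at 0.3 s
        bump = -6.0 * np.exp(-0.5 * ((t - 0.57) / 0.025) ** 2)
        data = bump[None, None, :] + 10.0 * rng.standard_normal((n_trials, 1, 1000))
        avg = average_erp(make_epochs(data, fs=fs))
        peak = avg[("all",)][0, 570]
        assert peak == pytest.approx(-6.0, abs=3 * 10 / np.sqrt(200))


class TestWindowAmplitude:
    def test_constant_waveform_any_window(self):
        wave = np.full((1, 1000), 3.0)
        cw = ComponentWindow("N270", (220, 320), ("ch0",))
        amp = window_amplitude(wave, np.arange(1000) / 1000.0, cw, ["ch0"],
                               s2_offset=0.3)
        assert amp["ch0"] == pytest.approx(3.0)

    def test_gaussian_bump_matches_analytic_window_mean(self):
        # mean over [220, 320) ms of a -6 uV, sigma 25 ms Gaussian at 270 ms:
        # -6 * sqrt(2*pi)*25/100 * (Phi(2) - Phi(-2)) = -3.5895 uV
        fs = 10000.0
        times = np.arange(int(1.0 * fs)) / fs
        lat = times - 0.3
        wave = (-6.0 * np.exp(-0.5 * ((lat - 0.27) / 0.025) ** 2))[None, :]
        cw = ComponentWindow("N270", (220, 320), ("C3",))
        amp = window_amplitude(wave, times, cw, ["C3"], s2_offset=0.3)
        expected = -6.0 * (np.sqrt(2 * np.pi) * 25 / 100) * (
            scipy.stats.norm.cdf(2) - scipy.stats.norm.cdf(-2))
        assert amp["C3"] == pytest.approx(expected, rel=0.01)

    def test_single_sample_window(self):
        wave = np.arange(100, dtype=float)[None, :]
        times = np.arange(100) / 1000.0
        cw = ComponentWindow("x", (10, 11), ("ch0",))
        amp = window_amplitude(wave, times, cw, ["ch0"], s2_offset=0.0)
        assert amp["ch0"] == 10.0

    def test_linearity(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal((1, 500))
        y = rng.standard_normal((1, 500))
        times = np.arange(500) / 1000.0
        cw = ComponentWindow("c", (50, 150), ("ch0",))

        def amp(w):
            return window_amplitude(w, times, cw, ["ch0"], s2_offset=0.0)["ch0"]

        assert amp(2.0 * x + 3.0 * y) == pytest.approx(2 * amp(x) + 3 * amp(y))

    def test_missing_electrode_rejected(self):
        wave = np.zeros((1, 100))
        cw = ComponentWindow("c", (10, 20), ("Pz",))
        with pytest.raises(ValueError, match="Pz"):
            window_amplitude(wave, np.arange(100) / 1000.0, cw, ["ch0"],
                             s2_offset=0.0)


class TestFilterTrials:
    def _table(self):
        rows = []
        for k in range(20):
            rows.append({"trial": k, "correct": True, "rt_ms": 500.0})
        rows[0]["correct"] = False
        rows[1]["rt_ms"] = 150.0
        rows[2]["rt_ms"] = 1600.0
        return pd.DataFrame(rows)

    def test_constructed_fixture_keeps_17(self):
        kept, log = filter_trials(self._table())
        assert len(kept) == 17
        assert log == {"incorrect": 1, "rt_too_fast": 1, "rt_too_slow": 1,
                       "kept": 17}

    def test_all_valid_is_identity(self):
        tt = pd.DataFrame({"correct": [True] * 5, "rt_ms": [300.0] * 5})
        kept, _ = filter_trials(tt)
        assert len(kept) == 5

    def test_boundary_rts_retained(self):
        tt = pd.DataFrame({"correct": [True, True], "rt_ms": [200.0, 1500.0]})
        kept, _ = filter_trials(tt)
        assert len(kept) == 2


class TestBehaviorSummary:
    def test_single_trial_cell(self):
        tt = pd.DataFrame([{"condition": "sham", "task": "color",
                            "stim_type": "match", "correct": True,
                            "rt_ms": 500.0}])
        s = behavior_summary(tt)
        assert s.rt_mean_ms.iloc[0] == 500.0
        assert s.correct_rate.iloc[0] == 1.0

    def test_two_trials_mean(self):
        tt = pd.DataFrame([
            {"condition": "sham", "task": "color", "stim_type": "match",
             "correct": True, "rt_ms": 400.0},
            {"condition": "sham", "task": "color", "stim_type": "match",
             "correct": True, "rt_ms": 600.0},
        ])
        assert behavior_summary(tt).rt_mean_ms.iloc[0] == 500.0

    def test_correct_rate_counts_all_trials(self):
        tt = pd.DataFrame([
            {"condition": "sham", "task": "color", "stim_type": "match",
             "correct": True, "rt_ms": 400.0},
            {"condition": "sham", "task": "color", "stim_type": "match",
             "correct": False, "rt_ms": 420.0},
        ])
        s = behavior_summary(tt)
        assert s.correct_rate.iloc[0] == 0.5
        assert s.rt_mean_ms.iloc[0] == 400.0  # incorrect trial excluded from RT

    def test_generator_cell_means_recovered(self):
        tt = syn.simulate_behavior(500, seed=4)
        s = behavior_summary(tt).set_index(["condition", "task", "stim_type"])
        assert s.loc[("sham", "color", "match"), "rt_mean_ms"] == pytest.approx(
            573.8, abs=7.0)
        assert s.loc[("real", "color", "match"), "rt_mean_ms"] == pytest.approx(
            527.4, abs=7.0)


def anova_oracle_oneway(y):
    """Direct sums-of-squares within-subject one-way ANOVA (n x k table)."""
    n, k = y.shape
    grand = y.mean()
    subj_means = y.mean(axis=1)
    cell_means = y.mean(axis=0)
    ss_treat = n * ((cell_means - grand) ** 2).sum()
    ss_subj = k * ((subj_means - grand) ** 2).sum()
    ss_total = ((y - grand) ** 2).sum()
    ss_err = ss_total - ss_treat - ss_subj
    df1, df2 = k - 1, (k - 1) * (n - 1)
    f = (ss_treat / df1) / (ss_err / df2)
    # GG epsilon from the double-centered covariance
    s = np.cov(y, rowvar=False, ddof=1)
    dc = s - s.mean(axis=0)[None, :] - s.mean(axis=1)[:, None] + s.mean()
    eps = np.trace(dc) ** 2 / ((k - 1) * (dc @ dc).trace())
    p = scipy.stats.f.sf(f, df1, df2)
    p_gg = scipy.stats.f.sf(f, df1 * eps, df2 * eps)
    return f, p, eps, p_gg


class TestRmAnovaGG:
    def _long(self, y, factor="A"):
        n, k = y.shape
        rows = []
        for s in range(n):
            for j in range(k):
                rows.append({"subj": s, factor: f"l{j}", "y": y[s, j]})
        return pd.DataFrame(rows)

    def test_two_level_factor_epsilon_exactly_one(self):
        rng = np.random.default_rng(5)
        df = self._long(rng.standard_normal((8, 2)))
        tab = rm_anova_gg(df, "y", "subj", ["A"]).effects
        assert tab.epsilon.iloc[0] == 1.0

    def test_identical_subjects_flagged_not_crash(self):
        y = np.tile([1.0, 1.0, 1.0], (5, 1))
        tab = rm_anova_gg(self._long(y), "y", "subj", ["A"]).effects
        assert tab.degenerate.iloc[0]
        assert np.isnan(tab.F.iloc[0])

    def test_three_level_eight_subject_oracle(self):
        rng = np.random.default_rng(6)
        y = rng.standard_normal((8, 3)) + np.array([0.0, 0.5, 0.2])
        f, p, eps, p_gg = anova_oracle_oneway(y)
        tab = rm_anova_gg(self._long(y), "y", "subj", ["A"]).effects
        assert tab.F.iloc[0] == pytest.approx(f, abs=1e-6)
        assert tab.p.iloc[0] == pytest.approx(p, abs=1e-6)
        assert tab.epsilon.iloc[0] == pytest.approx(eps, abs=1e-6)
        assert tab.p_gg.iloc[0] == pytest.approx(p_gg, abs=1e-6)

    def test_epsilon_bounds_hold(self):
        rng = np.random.default_rng(7)
        rows = []
        for s in range(6):
            for a, b in itertools.product(range(4), range(3)):
                rows.append({"subj": s, "A": a, "B": b, "y": rng.standard_normal()})
        df = pd.DataFrame(rows)
        tab = rm_anova_gg(df, "y", "subj", ["A", "B"]).effects
        for _, row in tab.iterrows():
            assert 1.0 / row.df1 - 1e-12 <= row.epsilon <= 1.0 + 1e-12

    def test_matches_pingouin_two_way(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(8)
        rows = []
        for s in range(10):
            for a in range(3):
                for b in range(4):
                    rows.append({"subj": s, "A": f"a{a}", "B": f"b{b}",
                                 "y": rng.normal() + 0.4 * (a == 1)})
        df = pd.DataFrame(rows)
        mine = rm_anova_gg(df, "y", "subj", ["A", "B"]).effects.set_index("effect")
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ref = pg.rm_anova(data=df, dv="y", subject="subj", within=["A", "B"],
                              correction=True, detailed=True).set_index("Source")
        for eff, src in [("A", "A"), ("B", "B"), ("A x B", "A * B")]:
            assert mine.loc[eff, "F"] == pytest.approx(ref.loc[src, "F"], abs=1e-8)
            assert mine.loc[eff, "p"] == pytest.approx(ref.loc[src, "p_unc"], abs=1e-8)
        for eff in ("A", "B"):  # main-effect epsilons share the definition
            assert mine.loc[eff, "epsilon"] == pytest.approx(
                ref.loc[eff, "eps"], abs=1e-8)

    def test_three_way_f_matches_statsmodels(self):
        from statsmodels.stats.anova import AnovaRM

        rng = np.random.default_rng(9)
        rows = []
        for s in range(8):
            for a in range(2):
                for b in range(3):
                    for d in range(2):
                        rows.append({"subj": s, "A": a, "B": b, "D": d,
                                     "y": rng.normal() + 0.3 * a * (b == 1)})
        df = pd.DataFrame(rows)
        mine = rm_anova_gg(df, "y", "subj", ["A", "B", "D"]).effects.set_index("effect")
        ref = AnovaRM(df, "y", "subj", within=["A", "B", "D"]).fit().anova_table
        pairs = {"A": "A", "B": "B", "D": "D", "A x B": "A:B", "A x D": "A:D",
                 "B x D": "B:D", "A x B x D": "A:B:D"}
        for eff, src in pairs.items():
            assert mine.loc[eff, "F"] == pytest.approx(
                ref.loc[src, "F Value"], abs=1e-8)

    def test_incomplete_design_rejected(self):
        df = self._long(np.random.default_rng(10).standard_normal((5, 3)))
        df = df.drop(index=0)
        with pytest.raises(ValueError, match="incomplete"):
            rm_anova_gg(df, "y", "subj", ["A"])

    def test_pairwise_bonferroni_capped(self):
        rng = np.random.default_rng(11)
        df = self._long(rng.standard_normal((8, 4)))
        tab = rm_anova_gg(df, "y", "subj", ["A"])
        assert tab.pairwise is not None
        assert (tab.pairwise.p_bonf <= 1.0 + 1e-12).all()
        assert len(tab.pairwise) == 6  # 4 choose 2


class TestEndToEndErpPattern:
    def test_real_condition_attenuates_n270_in_mismatch_only(self):
        from tmsnet.erp import DEFAULT_COMPONENTS, amplitude_table
        from tmsnet.preprocess import excise_tms_artifact, extract_epochs

        rec, trials = syn.simulate_session(5, fs=256.0, seed=21, noise_scale=3.0)
        ep = extract_epochs(rec, "TMS", (1.0, 1.0), baseline=(-0.9, -0.7),
                            metadata=trials)
        ep = excise_tms_artifact(ep, 0.0, 60.0)
        avgs = average_erp(ep, ["condition", "stim_type"])
        n270 = next(c for c in DEFAULT_COMPONENTS if c.name == "N270")
        amp = amplitude_table(avgs, ep.times, ep.channels, [n270],
                              group_names=["condition", "stim_type"])
        cell = amp.groupby(["condition", "stim_type"])["amplitude_uv"].mean()
        for st in ("task_relevant", "task_irrelevant", "conjunction"):
            assert cell[("real", st)] > cell[("sham", st)] + 0.5
        match_gap = abs(cell[("real", "match")] - cell[("sham", "match")])
        assert match_gap < 1.5
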