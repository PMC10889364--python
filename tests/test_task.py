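"""Contingencies, session designs, cohort generation, synthetic neural data."""

import numpy as np
import pandas as pd
import pytest

import statsmodels.api as sm

from sceptic import (AgentParams, CohortSpec, design_preset, generate_cohort,
                     generate_session, make_contingency, reversal_trials,
                     synth_neural)
from sceptic.io import read_table, write_table
from sceptic.task import draw_cohort_params


GRID = np.linspace(0.05, 3.95, 79)


class TestContingencies:
    @pytest.mark.parametrize("label", ["IEV", "DEV", "CEV", "CEVR"])
    def test_probability_and_magnitude_monotone(self, label):
        con = make_contingency(label)
        for fn in (con.p, con.m):
            d = np.diff(fn(GRID))
            assert np.all(d >= -1e-12) or np.all(d <= 1e-12)

    def test_cev_constant_expected_value(self):
        for label in ("CEV", "CEVR"):
            con = make_contingency(label)
            assert con.ev(0.5) / con.ev(3.5) == pytest.approx(1.0, abs=0.01)
            ev = con.ev(GRID)
            assert ev.max() / ev.min() < 1.01

    def test_iev_dev_learnable(self):
        iev, dev = make_contingency("IEV"), make_contingency("DEV")
        assert iev.ev(3.5) > iev.ev(0.5)
        assert np.all(np.diff(iev.ev(GRID)) > 0)
        assert np.all(np.diff(dev.ev(GRID)) < 0)

    def test_cevr_reverses_probability_trade_off(self):
        cev, cevr = make_contingency("CEV"), make_contingency("CEVR")
        d_cev = np.diff(cev.p(GRID))
        d_cevr = np.diff(cevr.p(GRID))
        assert np.all(np.sign(d_cev) == -np.sign(d_cevr))

    def test_invalid_ev_params_rejected(self):
        with pytest.raises(ValueError):
            make_contingency("CEV", ev_params={"ev": (200.0, 200.0)})

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            make_contingency("XEV")


class TestDesigns:
    def test_presets(self):
        f = design_preset("fmri_original")
        assert (f.n_runs, f.trials_per_run, f.trial_length) == (8, 50, 4.0)
        m = design_preset("meg_original")
        assert (m.n_runs, m.trials_per_run) == (8, 63)
        r = design_preset("replication")
        assert (r.n_trials, r.trial_length, r.reversal_every) == (240, 5.0, 40)
        assert r.basis_config().n_bins == 50

    def test_replication_reversal_schedule(self):
        r = design_preset("replication")
        assert reversal_trials(r) == [41, 81, 121, 161, 201]
        labels = r.run_schedule(0)
        # 6 blocks of 40 alternating IEV/DEV
        blocks = [labels[i * 40] for i in range(6)]
        assert blocks == ["IEV", "DEV", "IEV", "DEV", "IEV", "DEV"]
        assert all(len(set(labels[i * 40:(i + 1) * 40])) == 1 for i in range(6))

    def test_unknown_preset(self):
        with pytest.raises(ValueError):
            design_preset("nope")


class TestGenerateSession:
    def test_fixed_seed_byte_identical(self, tmp_path, default_agent):
        design = design_preset("replication")
        paths = []
        for i in range(2):
            log = generate_session(design, default_agent, seed=42)
            p = tmp_path / f"log{i}.tsv"
            write_table(log, p)
            paths.append(p)
        assert paths[0].read_bytes() == paths[1].read_bytes()

    def test_structure_and_onsets(self, default_agent):
        design = design_preset("replication")
        log = generate_session(design, default_agent, seed=1)
        assert len(log) == 240
        assert log["block"].nunique() == 6
        assert np.all(log["iti"] <= design.iti_max)
        assert np.all(np.diff(log["trial_onset"]) > 0)
        np.testing.assert_allclose(log["feedback_onset"],
                                   log["trial_onset"] + log["rt"])
        # contingency switches exactly at the reversal trials
        switches = np.flatnonzero(
            log["contingency"].to_numpy()[1:]
            != log["contingency"].to_numpy()[:-1]) + 2  # 1-based trial index
        assert list(switches) == reversal_trials(design)


class TestCohorts:
    def test_truth_table_and_reproducibility(self):
        from sceptic.task import SessionDesign
        design = SessionDesign("t", n_runs=1, trials_per_run=20)
        spec = CohortSpec(n_subjects=3, seed=5)
        logs1, truth1 = generate_cohort(spec, design)
        logs2, truth2 = generate_cohort(spec, design)
        assert len(truth1) == 3
        assert logs1.equals(logs2) and truth1.equals(truth2)
        assert set(logs1["subject"]) == set(truth1["subject"])

    def test_degenerate_sd_shares_parameters(self):
        spec = CohortSpec(n_subjects=4, sd={"alpha": 0.0, "beta": 0.0,
                                            "gamma": 0.0}, seed=1)
        truth = draw_cohort_params(spec)
        for c in ("alpha", "beta", "gamma"):
            assert truth[c].nunique() == 1

    def test_negative_sd_rejected(self):
        with pytest.raises(ValueError):
            CohortSpec(n_subjects=3, sd={"alpha": -0.1, "beta": 1, "gamma": 1})

    def test_single_subject_rejected(self):
        with pytest.raises(ValueError):
            CohortSpec(n_subjects=1)

    def test_truth_table_roundtrips_through_io(self, tmp_path):
        spec = CohortSpec(n_subjects=3, seed=9)
        truth = draw_cohort_params(spec)
        path = tmp_path / "truth.tsv"
        write_table(truth, path)
        back = read_table(path)
        np.testing.assert_allclose(back[["alpha", "beta", "gamma"]],
                                   truth[["alpha", "beta", "gamma"]],
                                   rtol=1e-9)

    def test_high_gamma_cohort_has_lower_late_entropy(self):
        from sceptic.task import SessionDesign
        design = SessionDesign("t", n_runs=1, trials_per_run=80,
                               contingencies=("IEV",))
        high = CohortSpec(n_subjects=6, mu={"alpha": -2.2, "beta": 1.6,
                                            "gamma": 1.5}, seed=3)
        low = CohortSpec(n_subjects=6, mu={"alpha": -2.2, "beta": 1.6,
                                           "gamma": -3.0}, seed=3)
        h = []
        for spec in (high, low):
            logs, _ = generate_cohort(spec, design)
            late = logs.groupby("subject").tail(10)
            h.append(late["entropy"].mean())
        assert h[0] < h[1]


class TestSynthNeural:
    def _small_log(self):
        from sceptic.task import SessionDesign
        design = SessionDesign("t", n_runs=1, trials_per_run=40)
        spec = CohortSpec(n_subjects=3, seed=2)
        logs, _ = generate_cohort(spec, design)
        return logs

    def test_noise_free_effect_recovered_exactly(self):
        logs = self._small_log()
        curve = lambda t: 2.5 * np.exp(-0.5 * (t - 1.0) ** 2)
        neural, truth = synth_neural(logs, {"entropy_change": curve},
                                     noise_sd=0.0, seed=0,
                                     subject_intercept_sd=0.0)
        at1 = neural[neural["time"] == 1.0].reset_index(drop=True)
        X = sm.add_constant(logs["entropy_change"].to_numpy())
        beta = sm.OLS(at1["response"], X).fit().params
        assert beta.iloc[1] == pytest.approx(2.5, abs=1e-8)

    def test_null_effect_map_centers_on_zero(self):
        logs = self._small_log()
        neural, _ = synth_neural(logs, {"entropy_change": lambda t: 0.0},
                                 noise_sd=0.3, seed=1,
                                 subject_intercept_sd=0.0)
        at1 = neural[neural["time"] == 1.0].reset_index(drop=True)
        X = sm.add_constant(logs["entropy_change"].to_numpy())
        fit = sm.OLS(at1["response"], X).fit()
        assert abs(fit.params.iloc[1]) < 2.5 * fit.bse.iloc[1] + 1e-9

    def test_effect_peak_recovered_under_noise(self):
        # regression per time point recovers the generating peak location
        logs = self._small_log()
        curve = lambda t: 3.0 * np.exp(-0.5 * ((t - 1.0) / 1.0) ** 2)
        neural, _ = synth_neural(logs, {"entropy_change": curve},
                                 noise_sd=0.5, seed=4)
        betas = {}
        for t, sub in neural.groupby("time"):
            sub = sub.reset_index(drop=True)
            X = sm.add_constant(logs["entropy_change"].to_numpy())
            betas[t] = sm.OLS(sub["response"], X).fit().params.iloc[1]
        times = sorted(betas)
        peak = times[int(np.argmax([betas[t] for t in times]))]
        assert abs(peak - 1.0) <= 1.0

    def test_missing_signal_column_rejected(self):
        logs = self._small_log().drop(columns=["entropy_change"])
        with pytest.raises(ValueError):
            synth_neural(logs, {"entropy_change": lambda t: t}, seed=0)
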