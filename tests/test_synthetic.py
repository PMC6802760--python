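"""Synthetic cohort generator: calibration, determinism, latent model."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

import visualspan as vs
from visualspan.synthetic import _DEFAULT_CELLS

#: calibration targets: group-mean span (characters) per age group x complexity
CALIBRATION_SPANS = {
    ("young", "low"): 7.2, ("young", "medium"): 6.5, ("young", "high"): 5.5,
    ("older", "low"): 7.1, ("older", "medium"): 6.4, ("older", "high"): 3.1,
}


class TestConfig:
    def test_invalid_fields_named(self):
        with pytest.raises(vs.ConfigError, match="n_per_group"):
            vs.synthetic.GeneratorConfig(n_per_group=0)
        bad_cells = dict(_DEFAULT_CELLS)
        bad_cells[("young", "low")] = dataclasses.replace(
            bad_cells[("young", "low")], middle_penalty=1.5)
        with pytest.raises(vs.ConfigError, match="middle_penalty"):
            vs.synthetic.GeneratorConfig(cells=bad_cells)

    def test_round_trips_through_dict(self):
        cfg = vs.default_config(n_per_group=3, seed=9)
        again = vs.config_from_dict(vs.config_to_dict(cfg))
        assert again == cfg
        assert vs.synthetic.config_hash(again) == vs.synthetic.config_hash(cfg)


class TestSampleParticipants:
    def test_zero_between_sd_gives_identical_participants(self):
        cells = {k: dataclasses.replace(v, between_participant_sd=0.0)
                 for k, v in _DEFAULT_CELLS.items()}
        cfg = vs.synthetic.GeneratorConfig(n_per_group=5, cells=cells)
        parts = vs.sample_participants(cfg, seed=1)
        young = [p for p in parts if p.age_group == "young"]
        for p in young[1:]:
            assert p.true_spans == young[0].true_spans
            assert p.cells == young[0].cells

    def test_same_seed_reproduces_cohort(self):
        cfg = vs.default_config(n_per_group=4)
        a = vs.sample_participants(cfg, seed=7)
        b = vs.sample_participants(cfg, seed=7)
        assert a == b

    def test_default_group_spans_match_calibration_targets(self):
        """Closed-form true spans of the default cells hit the calibration
        span means to within 0.5 characters."""
        cfg = vs.default_config()
        for key, target in CALIBRATION_SPANS.items():
            got = vs.cell_true_span(cfg.cells[key], cfg.set_size,
                                    cfg.criterion)
            assert got == pytest.approx(target, abs=0.5), key


@pytest.fixture(scope="module")
def participant():
    return vs.sample_participants(vs.default_config(n_per_group=1), seed=0)[0]


class TestLatentAccuracy:
    def test_peak_value_for_first_role(self, participant):
        cell = participant.cells["low"]
        p = vs.latent_accuracy(participant, "low", cell.peak_shift, "first")
        assert float(p) == pytest.approx(cell.peak, abs=1e-12)

    def test_far_eccentricity_approaches_chance(self, participant):
        p = vs.latent_accuracy(participant, "high", np.array([-60.0, 60.0]),
                               "first")
        assert np.allclose(p, 1 / 26, atol=1e-6)

    def test_middle_penalty_scales_above_chance_component(self, participant):
        first = float(vs.latent_accuracy(participant, "high", 0.0, "first"))
        middle = float(vs.latent_accuracy(participant, "high", 0.0, "middle"))
        pen = participant.cells["high"].middle_penalty
        chance = 1 / 26
        assert middle - chance == pytest.approx(pen * (first - chance),
                                                abs=1e-12)


class TestSimulateSession:
    def test_trial_count_and_schema(self, design):
        part = vs.sample_participants(vs.default_config(n_per_group=1),
                                      seed=3)[0]
        trials = vs.simulate_session(part, design, seed=11)
        assert len(trials) == 459
        counts = trials.groupby(["complexity", "block"])["center"] \
            .value_counts().unique()
        assert list(counts) == [3]  # every center 3x per block
        stim = trials[["stim1", "stim2", "stim3"]].to_numpy()
        assert (np.sort(stim, axis=1)[:, :-1]
                != np.sort(stim, axis=1)[:, 1:]).all()  # distinct characters

    def test_reproducible_given_seed(self, design):
        part = vs.sample_participants(vs.default_config(n_per_group=1),
                                      seed=3)[0]
        a = vs.simulate_session(part, design, seed=11)
        b = vs.simulate_session(part, design, seed=11)
        pd.testing.assert_frame_equal(a, b)

    def test_ceiling_configuration_all_correct(self, design):
        cells = {k: vs.CellParams(peak=1.0, sigma_left=1e6, sigma_right=1e6,
                                  peak_shift=0.0, middle_penalty=1.0,
                                  between_participant_sd=0.0)
                 for k in _DEFAULT_CELLS}
        cfg = vs.synthetic.GeneratorConfig(n_per_group=1, cells=cells)
        part = vs.sample_participants(cfg, seed=0)[0]
        trials = vs.simulate_session(part, design, seed=2)
        assert trials[["correct1", "correct2", "correct3"]].all().all()

    def test_empirical_accuracy_tracks_latent_probability(self, design):
        """Observed per-position accuracy stays within aggregate binomial
        error of the latent role-mixed curve."""
        cells = {k: dataclasses.replace(v, between_participant_sd=0.0)
                 for k, v in _DEFAULT_CELLS.items()}
        cfg = vs.synthetic.GeneratorConfig(n_per_group=6, cells=cells)
        parts, trials, _ = vs.simulate_experiment(cfg, seed=21)
        profiles = vs.build_profiles(trials, design)
        young = next(p for p in parts if p.age_group == "young")
        for comp in ("low", "high"):
            profs = [p for p in profiles
                     if p.age_group == "young" and p.complexity == comp]
            acc = np.mean([p.accuracy for p in profs], axis=0) / 100
            x = profs[0].positions.astype(float)
            expected = np.mean([np.asarray(
                vs.latent_accuracy(young, comp, x, role), float)
                for role in ("first", "middle", "last")], axis=0)
            n_total = 27 * len(profs)
            se = np.sqrt(expected * (1 - expected) / n_total)
            assert np.all(np.abs(acc - expected) < 5 * se + 1e-9)


class TestMiddlePenaltyEffect:
    def test_stronger_penalty_lowers_middle_cell_accuracy(self, design):
        """center_role_accuracy's middle cell decreases as the crowding
        penalty deepens (in expectation, checked with matched seeds)."""
        def middle_acc(penalty):
            cells = {k: dataclasses.replace(v, middle_penalty=penalty,
                                            between_participant_sd=0.0)
                     for k, v in _DEFAULT_CELLS.items()}
            cfg = vs.synthetic.GeneratorConfig(n_per_group=5, cells=cells)
            _, trials, _ = vs.simulate_experiment(cfg, seed=31)
            table = vs.center_role_accuracy(trials, design)
            cell = table[(table.age_group == "older")
                         & (table.complexity == "high")
                         & (table.role == "middle")]
            return float(cell["accuracy_pct"].iloc[0])

        accs = [middle_acc(p) for p in (1.0, 0.8, 0.5)]
        assert accs[0] > accs[1] > accs[2]

    def test_middle_role_deficit_detected(self, design, small_cohort):
        """With the default penalties, middle-role accuracy at fixation is
        below first/last-role accuracy for high-complexity older adults."""
        _, _, trials, _ = small_cohort
        table = vs.center_role_accuracy(trials, design).set_index(
            ["age_group", "complexity", "role"])
        mid = table.loc[("older", "high", "middle"), "accuracy_pct"]
        first = table.loc[("older", "high", "first"), "accuracy_pct"]
        last = table.loc[("older", "high", "last"), "accuracy_pct"]
        assert mid < first and mid < last


class TestEndToEndRecovery:
    def test_pipeline_spans_unbiased_for_closed_form_truth(self, design):
        """Full pipeline (simulate -> score -> fit -> span) recovers the
        closed-form true span of every age x complexity cell with mean bias
        within 0.3 characters."""
        cells = {k: dataclasses.replace(v, between_participant_sd=0.0)
                 for k, v in _DEFAULT_CELLS.items()}
        cfg = vs.synthetic.GeneratorConfig(n_per_group=40, cells=cells)
        _, trials, _ = vs.simulate_experiment(cfg, seed=2468)
        _, spans = vs.spans_from_trials(trials)
        means = spans.groupby(["age_group", "complexity"])["span_chars"].mean()
        for (group, comp), est in means.items():
            truth = vs.cell_true_span(cells[(group, comp)])
            assert abs(est - truth) <= 0.3, (group, comp, est, truth)


class TestExperimentDeterminism:
    def test_same_seed_byte_identical(self):
        cfg = vs.default_config(n_per_group=2)
        _, t1, r1 = vs.simulate_experiment(cfg, seed=99)
        _, t2, r2 = vs.simulate_experiment(cfg, seed=99)
        pd.testing.assert_frame_equal(t1, t2)
        pd.testing.assert_frame_equal(r1, r2)

    def test_row_counts(self, small_cohort):
        cfg, parts, trials, reading = small_cohort
        assert len(trials) == 2 * cfg.n_per_group * 459
        assert len(reading) == 2 * cfg.n_per_group * 20
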