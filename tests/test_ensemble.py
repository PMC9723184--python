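"""Learner registry, data splitting, gating, ensembling and classification."""

import numpy as np
import pytest

from mangrovesdm import synthetic as syn
from mangrovesdm.ensemble import (
    DEFAULT_CUTPOINTS,
    LEARNER_NAMES,
    LearnerSpec,
    NoQualifierError,
    SuitabilitySurface,
    UnknownLearnerError,
    classify_suitability,
    ensemble_weighted_mean,
    fit_learner,
    gate_learners,
    generate_pseudo_absences,
    run_all,
    split_data,
)
from mangrovesdm.grids import GridDefinition
from mangrovesdm.metrics import EvalScores, roc_auc


def toy_surface(grid, values, code="AR"):
    return SuitabilitySurface(grid=grid, species_code=code, values=np.asarray(values, float))


class TestPseudoAbsences:
    def test_zero_requested_gives_empty(self, grid10):
        assert len(generate_pseudo_absences(grid10, [1, 2], 0, seed=0)) == 0

    def test_all_unoccupied_gives_their_exact_set(self, grid10):
        occupied = np.arange(90)
        bg = generate_pseudo_absences(grid10, occupied, 10, seed=0)
        np.testing.assert_array_equal(bg, np.arange(90, 100))

    def test_deterministic(self, grid10):
        a = generate_pseudo_absences(grid10, [5, 6], 30, seed=4)
        b = generate_pseudo_absences(grid10, [5, 6], 30, seed=4)
        np.testing.assert_array_equal(a, b)

    def test_never_hits_occupied_cells(self, grid10):
        occupied = np.arange(0, 100, 2)
        bg = generate_pseudo_absences(grid10, occupied, 40, seed=1)
        assert not set(bg) & set(occupied)

    def test_oversampling_rejected(self, grid10):
        with pytest.raises(ValueError):
            generate_pseudo_absences(grid10, np.arange(95), 10, seed=0)


class TestSplitData:
    def test_partition_sizes(self):
        X = np.zeros((200, 2))
        y = np.repeat([1, 0], 100)
        train, intr, extr = split_data(X, y, seed=0)
        assert len(extr) == 40
        assert len(train) == 120
        assert len(intr) == 40

    def test_disjoint_and_exhaustive(self):
        y = np.tile([1, 0], 60)
        train, intr, extr = split_data(np.zeros((120, 1)), y, seed=3)
        all_idx = np.concatenate([train, intr, extr])
        assert len(all_idx) == 120
        assert len(np.unique(all_idx)) == 120

    def test_stratification_keeps_both_classes(self):
        y = np.array([1] * 10 + [0] * 90)
        for seed in range(5):
            for part in split_data(np.zeros((100, 1)), y, seed=seed):
                assert len(np.unique(y[part])) == 2

    def test_reproducible(self):
        y = np.tile([1, 0], 50)
        a = split_data(np.zeros((100, 1)), y, seed=11)
        b = split_data(np.zeros((100, 1)), y, seed=11)
        for pa, pb in zip(a, b):
            np.testing.assert_array_equal(pa, pb)

    def test_too_few_presences_rejected(self):
        y = np.array([1] * 7 + [0] * 50)
        with pytest.raises(ValueError):
            split_data(np.zeros((57, 1)), y, seed=0)


class TestLearners:
    def test_sre_envelope_definition(self):
        X = np.array([[2.0], [4.0], [6.0], [8.0]])
        y = np.ones(4, dtype=int)
        model = fit_learner(LearnerSpec("SRE", {"q": 0.0}), X, y)
        assert model.score_cells(np.array([[5.0]]))[0] == 1.0
        assert model.score_cells(np.array([[9.0]]))[0] == 0.0

    def test_glm_separable_auc_one(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(3, 0.3, (40, 1)), rng.normal(-3, 0.3, (40, 1))])
        y = np.repeat([1, 0], 40)
        model = fit_learner(LearnerSpec("GLM"), X, y)
        assert roc_auc(model.score_cells(X), y) == 1.0

    @pytest.mark.parametrize("name", LEARNER_NAMES)
    def test_every_learner_fits_and_scores_in_unit_interval(self, name):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(80, 4))
        y = (X[:, 0] + 0.5 * rng.normal(size=80) > 0).astype(int)
        model = fit_learner(LearnerSpec(name, seed=0), X, y)
        s = model.score_cells(rng.normal(size=(50, 4)))
        assert s.min() >= 0.0 and s.max() <= 1.0

    def test_unknown_learner_rejected(self):
        with pytest.raises(UnknownLearnerError):
            LearnerSpec("SVM")

    def test_single_class_rejected_except_sre(self):
        X = np.zeros((10, 2))
        with pytest.raises(ValueError):
            fit_learner(LearnerSpec("GLM"), X, np.ones(10, int))
        fit_learner(LearnerSpec("SRE"), X, np.ones(10, int))  # presence-only


class TestGating:
    def make(self, roc, tss, kappa):
        return EvalScores(roc=roc, tss=tss, kappa=kappa)

    def test_all_above_gate_qualifies(self):
        assert gate_learners({"GLM": self.make(0.8, 0.8, 0.8)}) == ["GLM"]

    def test_boundary_equal_is_excluded(self):
        """Strict > 0.75: a TSS of exactly 0.75 disqualifies."""
        assert gate_learners({"GLM": self.make(0.9, 0.75, 0.8)}) == []

    def test_empty_qualifiers_propagate_to_ensemble_error(self):
        with pytest.raises(NoQualifierError):
            ensemble_weighted_mean({}, {})

    def test_gating_monotone_in_scores(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            base = {f"L{i}": self.make(*rng.uniform(0.5, 1.0, 3)) for i in range(5)}
            q1 = set(gate_learners(base))
            name = rng.choice(list(base))
            s = base[name]
            raised = dict(base)
            raised[name] = self.make(min(s.roc + 0.1, 1), min(s.tss + 0.1, 1), min(s.kappa + 0.1, 1))
            q2 = set(gate_learners(raised))
            assert q1 - {name} <= q2


class TestEnsemble:
    def test_single_member_is_identity(self, grid10):
        s = toy_surface(grid10, np.linspace(0, 1, 100))
        out = ensemble_weighted_mean({"GLM": s}, {"GLM": 0.9})
        np.testing.assert_allclose(out.values, s.values)
        assert out.weights == (1.0,)

    def test_equal_weights_average(self, grid10):
        a = toy_surface(grid10, np.full(100, 0.2))
        b = toy_surface(grid10, np.full(100, 0.8))
        out = ensemble_weighted_mean({"a": a, "b": b}, {"a": 0.5, "b": 0.5})
        np.testing.assert_allclose(out.values, 0.5)

    def test_weight_normalization_arithmetic(self):
        grid = GridDefinition(1, 1)
        a = toy_surface(grid, [0.6])
        b = toy_surface(grid, [0.2])
        out = ensemble_weighted_mean({"a": a, "b": b}, {"a": 0.9, "b": 0.45})
        assert out.values[0] == pytest.approx((0.9 * 0.6 + 0.45 * 0.2) / 1.35)
        assert sum(out.weights) == pytest.approx(1.0)

    def test_bounded_by_member_envelope(self, grid10):
        rng = np.random.default_rng(5)
        members = {f"L{i}": toy_surface(grid10, rng.random(100)) for i in range(4)}
        out = ensemble_weighted_mean(members, {f"L{i}": rng.random() + 0.1 for i in range(4)})
        stackv = np.vstack([m.values for m in members.values()])
        assert np.all(out.values >= stackv.min(axis=0) - 1e-12)
        assert np.all(out.values <= stackv.max(axis=0) + 1e-12)


class TestClassify:
    def test_boundaries_left_closed_upgrade(self, grid10):
        s = toy_surface(grid10, np.full(100, 0.0))
        assert classify_suitability(s).classes[0] == 0  # not suitable
        s = toy_surface(grid10, np.full(100, 0.75))
        assert classify_suitability(s).classes[0] == 3  # highly, boundary up

    def test_uniform_surface_quarter_shares(self, grid10):
        rng = np.random.default_rng(9)
        n = 40000
        grid = GridDefinition(200, 200)
        s = toy_surface(grid, rng.random(n))
        cm = classify_suitability(s, DEFAULT_CUTPOINTS)
        shares = np.bincount(cm.classes, minlength=4) / n
        se = np.sqrt(0.25 * 0.75 / n)
        assert np.all(np.abs(shares - 0.25) < 3 * se + 1e-9)

    def test_bad_cutpoints_rejected(self, grid10):
        s = toy_surface(grid10, np.zeros(100))
        with pytest.raises(ValueError):
            classify_suitability(s, (0.5, 0.5, 0.75))


class TestRunAll:
    def _occurrences(self, stack, truths, codes, n=60, seed=0):
        import pandas as pd

        from mangrovesdm.occurrences import OccurrenceSet

        frames = [
            syn.sample_occurrences(stack, truths[c], n, seed=seed + i).records
            for i, c in enumerate(codes)
        ]
        return OccurrenceSet(pd.concat(frames, ignore_index=True), stack.grid)

    def test_fit_count_species_times_learners(self, small_stack, truths):
        occ = self._occurrences(small_stack, truths, ["AR", "AC"], n=40)
        learners = tuple(LearnerSpec(n) for n in ("GLM", "SRE", "CTA"))
        res = run_all(small_stack, occ, learners=learners, seed=0)
        assert res.n_fits == 6
        assert res.manifest["n_fits"] == 6

    def test_species_below_minimum_skipped_and_counted(self, small_stack, truths):
        occ = self._occurrences(small_stack, truths, ["AR", "AC", "AA"], n=40)
        few = syn.sample_occurrences(small_stack, truths["HF"], 5, seed=1)
        import pandas as pd

        from mangrovesdm.occurrences import OccurrenceSet

        occ = OccurrenceSet(
            pd.concat([occ.records, few.records], ignore_index=True), small_stack.grid
        )
        learners = tuple(LearnerSpec(n) for n in ("GLM", "SRE"))
        with pytest.warns(UserWarning, match="skipped"):
            res = run_all(small_stack, occ, learners=learners, seed=0)
        assert res.n_fits == 6  # 3 species x 2 learners, HF skipped
        assert res.manifest["skipped_species"] == ["HF"]

    def test_single_species_single_learner(self, small_stack, truths):
        occ = self._occurrences(small_stack, truths, ["AM"], n=50)
        res = run_all(small_stack, occ, learners=(LearnerSpec("GLM"),), seed=2)
        assert res.n_fits == 1
        assert "AM" in res.surfaces


def test_ensemble_recovers_strong_truths_across_seeds(small_config):
    """Extrinsic AUC > 0.75 for |coeff| >= 2 truths, n=200, in >= 9/10 seeds."""
    from mangrovesdm.ensemble import fit_species

    stack = syn.generate_env_stack(small_config)
    hits = 0
    for seed in range(10):
        truth = syn.SpeciesTruth(
            "AR",
            {"topographic_slope": 2.0, "environmental_ndvi": -2.0},
            prevalence=0.2,
        )
        occ = syn.sample_occurrences(stack, truth, 200, seed=seed)
        res, _ = fit_species(stack, occ, "AR", seed=seed)
        # fresh presence draw: genuinely out-of-sample evaluation
        fresh = syn.sample_occurrences(stack, truth, 200, seed=seed + 500)
        pres = fresh.records["cell_id"].to_numpy()
        bg = generate_pseudo_absences(stack.grid, pres, 200, seed=seed + 1000)
        scores = np.concatenate([res.surface.values[pres], res.surface.values[bg]])
        labels = np.concatenate([np.ones(len(pres), int), np.zeros(len(bg), int)])
        if roc_auc(scores, labels) > 0.75:
            hits += 1
    assert hits >= 9
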