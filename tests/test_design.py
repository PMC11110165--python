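"""Greedy diversity initializer and EI-based batch selection."""

import numpy as np
import pytest

from _oracles import expected_improvement_ref, gp_posterior
from conftest import COVERAGE_FIELDS, make_toy_space, toy_rules
from rxnopt import (
    AcquisitionConfig,
    DiversityConfig,
    FeatureEncoding,
    MeritGP,
    ParameterDef,
    ParameterSpace,
    build_grid,
    coverage_complete_after,
    expected_improvement,
    greedy_diverse_init,
    select_batch,
)
from test_surrogate import make_observations


class TestGreedyInit:
    def test_fully_crossed_two_field_toy_covered_in_two_picks(self):
        """Brute force over the four points: two picks must cover all levels."""
        space = ParameterSpace(
            [
                ParameterDef("solvent", "categorical", ("MeOH", "DMF")),
                ParameterDef("iodine_source", "categorical", ("KI", "NIS")),
            ]
        )
        grid = build_grid(space, [])
        for seed in range(5):
            cfg = DiversityConfig(
                n_init=2, coverage_fields=("solvent", "iodine_source"), seed=seed
            )
            picks = greedy_diverse_init(grid, cfg)
            # first pick covers 2 new levels; the second must cover the other 2
            assert picks[0]["solvent"] != picks[1]["solvent"]
            assert picks[0]["iodine_source"] != picks[1]["iodine_source"]
            assert coverage_complete_after(
                picks, grid, ["solvent", "iodine_source"]
            ) == 2

    def test_single_pick_has_maximal_novelty(self, toy_grid):
        cfg = DiversityConfig(n_init=1, coverage_fields=COVERAGE_FIELDS, seed=0)
        (pick,) = greedy_diverse_init(toy_grid, cfg)
        # any point exposes one unseen level per coverage field
        assert len({pick[f] for f in COVERAGE_FIELDS}) >= 1

    def test_covers_all_four_fields_in_eleven_on_default_grid(self, default_grid):
        for seed in (0, 1, 7):
            picks = greedy_diverse_init(
                default_grid, DiversityConfig(n_init=11, seed=seed)
            )
            assert len(picks) == len(set(picks)) == 11
            assert coverage_complete_after(picks, default_grid, COVERAGE_FIELDS) == 11
            assert len({p["solvent"] for p in picks}) == 11
            assert len({p["alkyne"] for p in picks}) == 4
            assert len({p["iodine_source"] for p in picks}) == 5
            assert len({p["catalyst"] for p in picks}) == 3

    def test_greedy_step_novelty_is_never_beaten(self, toy_grid):
        """Re-scan: no unchosen candidate offers more unseen levels."""
        cfg = DiversityConfig(n_init=6, coverage_fields=COVERAGE_FIELDS, seed=2)
        picks = greedy_diverse_init(toy_grid, cfg)
        seen: dict[str, set] = {f: set() for f in COVERAGE_FIELDS}
        chosen_keys = set()
        all_points = toy_grid.points()
        for pick in picks:
            def novelty(pt):
                return sum(pt[f] not in seen[f] for f in COVERAGE_FIELDS)

            best = max(
                novelty(pt) for pt in all_points if pt not in chosen_keys
            )
            assert novelty(pick) == best
            for f in COVERAGE_FIELDS:
                seen[f].add(pick[f])
            chosen_keys.add(pick)

    def test_deterministic_given_seed(self, toy_grid):
        cfg = DiversityConfig(n_init=5, seed=13)
        assert greedy_diverse_init(toy_grid, cfg) == greedy_diverse_init(toy_grid, cfg)

    def test_errors(self, toy_grid):
        with pytest.raises(ValueError):
            greedy_diverse_init(toy_grid, DiversityConfig(n_init=10**6))
        with pytest.raises(ValueError, match="coverage"):
            greedy_diverse_init(
                toy_grid, DiversityConfig(n_init=2, coverage_fields=("nope",))
            )


class TestExpectedImprovement:
    def test_no_improvement_without_uncertainty(self):
        assert expected_improvement(0.5, 0.0, 0.7, xi=0.0) == 0.0

    def test_at_best_with_unit_sd_equals_normal_density_at_zero(self):
        assert expected_improvement(0.5, 1.0, 0.5, xi=0.0) == pytest.approx(
            0.3989422804014327, abs=1e-12
        )

    def test_deterministic_limit(self):
        val = expected_improvement(0.9, 1e-12, 0.5, xi=0.0)
        assert val == pytest.approx(0.4, abs=1e-6)

    def test_nonnegative_and_matches_reference(self):
        rng = np.random.default_rng(0)
        mean = rng.uniform(0, 1, 200)
        sd = rng.uniform(0, 0.5, 200)
        ei = expected_improvement(mean, sd, best_seen=0.6, xi=0.01)
        assert np.all(ei >= 0)
        ref = [expected_improvement_ref(m, s, 0.6, 0.01) for m, s in zip(mean, sd)]
        assert np.allclose(ei, np.maximum(ref, 0.0), atol=1e-12)

    def test_strictly_increasing_in_sd_at_the_incumbent(self):
        sds = np.linspace(0.01, 1.0, 25)
        ei = expected_improvement(np.full(25, 0.5), sds, 0.5, xi=0.0)
        assert np.all(np.diff(ei) > 0)

    def test_negative_sd_rejected(self):
        with pytest.raises(ValueError):
            expected_improvement(0.5, -0.1, 0.5)


@pytest.fixture(scope="module")
def ten_point_problem():
    """A 10-point grid with a GP fitted on 4 observations."""
    space = ParameterSpace(
        [
            ParameterDef("alkyne", "categorical", ("s1", "s2")),
            ParameterDef("temperature", "ordinal-numeric", (25, 35, 45, 55, 65)),
        ]
    )
    grid = build_grid(space, [])
    enc = FeatureEncoding(space, grid)
    train_idx = [0, 3, 6, 9]
    merits = [0.2, 0.7, 0.4, 0.55]
    obs = make_observations(grid.points_at(train_idx), merits)
    model = MeritGP(enc, n_restarts=3, seed=4).fit(obs)
    return grid, enc, model, obs, train_idx


class TestSelectBatch:
    def test_batch_of_one_is_argmax_ei(self, ten_point_problem):
        grid, _, model, obs, train_idx = ten_point_problem
        candidates = [i for i in grid.indices if i not in train_idx]
        sel = select_batch(
            model, grid, candidates, obs, AcquisitionConfig(batch_size=1),
            rng=np.random.default_rng(0),
        )
        pred = model.predict(grid.points_at(candidates))
        best = max(o.merit for o in obs)
        ei = expected_improvement(pred.mean, pred.sd, best, 0.01)
        assert sel.indices == [candidates[int(np.argmax(ei))]]
        assert not sel.exhausted

    def test_batch_of_two_matches_brute_force_constant_liar(self, ten_point_problem):
        """Independent constant-liar enumeration with hand-rolled conditioning."""
        grid, enc, model, obs, train_idx = ten_point_problem
        candidates = [i for i in grid.indices if i not in train_idx]
        sel = select_batch(
            model, grid, candidates, obs, AcquisitionConfig(batch_size=2),
            rng=np.random.default_rng(0),
        )
        hp = model.hyperparameters
        best = max(o.merit for o in obs)
        Xtr = enc.encode([o.point for o in obs])
        ytr = np.array([o.merit for o in obs])

        def ei_over(cands, Xtr_, ytr_):
            Xte = enc.encode(grid.points_at(cands))
            mean, sd = gp_posterior(
                Xtr_, ytr_, Xte,
                hp["signal_variance"], hp["length_scales"], hp["noise_variance"],
            )
            return np.array(
                [max(expected_improvement_ref(m, s, best, 0.01), 0.0)
                 for m, s in zip(mean, sd)]
            )

        first = candidates[int(np.argmax(ei_over(candidates, Xtr, ytr)))]
        X1 = enc.encode(grid.points_at([first]))
        Xtr2 = np.vstack([Xtr, X1])
        ytr2 = np.append(ytr, best)  # the liar
        rest = [i for i in candidates if i != first]
        second = rest[int(np.argmax(ei_over(rest, Xtr2, ytr2)))]
        assert sel.indices == [first, second]

    def test_exhaustion_flag(self, ten_point_problem):
        grid, _, model, obs, _ = ten_point_problem
        sel = select_batch(
            model, grid, [0], obs, AcquisitionConfig(batch_size=2),
            rng=np.random.default_rng(0),
        )
        assert sel.indices == [0] and sel.exhausted
        empty = select_batch(
            model, grid, [], obs, AcquisitionConfig(batch_size=2),
            rng=np.random.default_rng(0),
        )
        assert empty.indices == [] and empty.exhausted

    def test_deterministic_given_rng_seed(self, ten_point_problem):
        grid, _, model, obs, train_idx = ten_point_problem
        candidates = [i for i in grid.indices if i not in train_idx]
        sel1 = select_batch(model, grid, candidates, obs,
                            AcquisitionConfig(batch_size=2),
                            rng=np.random.default_rng(8))
        sel2 = select_batch(model, grid, candidates, obs,
                            AcquisitionConfig(batch_size=2),
                            rng=np.random.default_rng(8))
        assert sel1.indices == sel2.indices
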