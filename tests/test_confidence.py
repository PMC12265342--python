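"""Confidence labeling, invariance, filtering, and classifier training."""

from dataclasses import replace

import numpy as np
import pytest

from metaldiff import nn
from metaldiff.confidence import (
    CandidateSet,
    ConfidenceConfig,
    _confidence_backward,
    confidence_forward,
    filter_by_confidence,
    generate_confidence_labels,
    init_confidence_params,
    score_candidates,
    train_confidence,
)
from metaldiff.errors import ContractError, DomainError, TrainingError
from metaldiff.graph import build_hetero_graph
from metaldiff.score_model import ScoreModelConfig, init_score_params
from metaldiff.synthetic import make_toy_complex

from conftest import random_rotation


class TestLabels:
    def test_threshold_examples(self):
        true = np.array([[0.0, 0, 0]])
        assert generate_confidence_labels(np.array([[4.0, 0, 0]]), true)[0] == 1
        assert generate_confidence_labels(np.array([[6.0, 0, 0]]), true)[0] == 0
        assert generate_confidence_labels(np.array([[0.0, 0, 0]]), true)[0] == 1

    def test_strict_below_at_boundary(self):
        true = np.array([[0.0, 0, 0]])
        assert generate_confidence_labels(np.array([[5.0, 0, 0]]), true)[0] == 0

    def test_empty_true_sites_rejected(self):
        with pytest.raises(DomainError):
            generate_confidence_labels(np.zeros((2, 3)), np.zeros((0, 3)))

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_nearest_distance(self, seed):
        rng = np.random.default_rng(seed)
        sampled = rng.uniform(0, 30, (25, 3))
        true = rng.uniform(0, 30, (4, 3))
        got = generate_confidence_labels(sampled, true, 5.0)
        want = [
            int(min(np.linalg.norm(s - t) for t in true) < 5.0) for s in sampled
        ]
        assert got.tolist() == want


@pytest.fixture(scope="module")
def conf_setup():
    cx = make_toy_complex(25, 2, 41)
    score_cfg = ScoreModelConfig()
    cfg = ConfidenceConfig()
    cp = init_confidence_params(cfg, score_cfg, np.random.default_rng(0))
    rng = np.random.default_rng(1)
    cands = cx.structure.metal_sites + rng.normal(0, 3.0, (2, 3))
    return cx.structure, cp, cands


def _probs(s, cands, cp):
    g = build_hetero_graph(
        s, cands, 0.0, cp.score_config.graph,
        sigma_t=cp.score_config.schedule.sigma_min,
    )
    return confidence_forward(g, cp)


class TestForward:
    @pytest.mark.parametrize("seed", range(5))
    def test_rigid_motion_invariance(self, conf_setup, seed):
        s, cp, cands = conf_setup
        rng = np.random.default_rng(200 + seed)
        rot, shift = random_rotation(rng), rng.uniform(-40, 40, 3)
        p1 = _probs(s, cands, cp)
        s2 = replace(
            s,
            residue_coords=s.residue_coords @ rot.T + shift,
            atom_coords=s.atom_coords @ rot.T + shift,
            metal_sites=s.metal_sites @ rot.T + shift,
        )
        p2 = _probs(s2, cands @ rot.T + shift, cp)
        assert np.abs(p1 - p2).max() < 1e-5

    def test_duplicate_candidates_equal_probs(self, conf_setup):
        s, cp, cands = conf_setup
        p = _probs(s, np.vstack([cands[0], cands[0]]), cp)
        assert p[0] == pytest.approx(p[1], abs=1e-12)

    @pytest.mark.parametrize("seed", range(20))
    def test_outputs_in_open_unit_interval_fuzz(self, seed):
        rng = np.random.default_rng(seed)
        cx = make_toy_complex(15, 1, seed)
        score_cfg = ScoreModelConfig()
        cp = init_confidence_params(ConfidenceConfig(), score_cfg, rng)
        for k in cp.params:  # random rescale to fuzz parameter space
            cp.params[k] = cp.params[k] * rng.uniform(0.2, 5.0)
        cands = rng.uniform(-10, 40, (5, 3))
        p = _probs(cx.structure, cands, cp)
        assert ((p > 0) & (p < 1)).all()

    def test_config_hash_mismatch_rejected(self, conf_setup):
        from metaldiff.graph import GraphConfig

        s, cp, cands = conf_setup
        g = build_hetero_graph(s, cands, 0.0, GraphConfig(r_atom=4.0))
        with pytest.raises(ContractError):
            confidence_forward(g, cp)


class TestFilter:
    def _cands(self):
        return CandidateSet(
            positions=np.array([[0.0, 0, 0], [1.0, 0, 0]]),
            probs=np.array([0.2, 0.8]),
        )

    def test_threshold_keeps_high(self):
        kept = filter_by_confidence(self._cands(), 0.5)
        assert kept.n == 1 and kept.probs[0] == 0.8

    def test_zero_threshold_is_identity(self):
        assert filter_by_confidence(self._cands(), 0.0).n == 2

    def test_threshold_one_generically_empty(self):
        assert filter_by_confidence(self._cands(), 1.0).n == 0

    def test_monotone_nested(self):
        rng = np.random.default_rng(0)
        cands = CandidateSet(
            positions=rng.uniform(0, 10, (50, 3)), probs=rng.uniform(0, 1, 50)
        )
        prev = set(range(50))
        for p in (0.1, 0.3, 0.5, 0.7, 0.9):
            kept = filter_by_confidence(cands, p)
            idx = {
                i for i in range(50) if cands.probs[i] >= p
            }
            assert kept.n == len(idx)
            assert idx <= prev
            prev = idx

    def test_missing_probs_rejected(self):
        with pytest.raises(ContractError):
            filter_by_confidence(CandidateSet(positions=np.zeros((2, 3))), 0.5)


class TestTraining:
    def test_empty_dataset_rejected(self):
        sp = init_score_params(ScoreModelConfig(), np.random.default_rng(0))
        with pytest.raises(TrainingError):
            train_confidence([], sp, ConfidenceConfig(), np.random.default_rng(0))

    def test_determinism_same_seed(self, trained_pipeline, synthetic_dataset):
        complexes, splits = synthetic_dataset
        data = [complexes[i].structure for i in splits["val"][:4]]
        sp = trained_pipeline["score"]
        cfg = ConfidenceConfig(epochs=3, candidates_per_complex=16, sample_steps=20)
        _, a = train_confidence(data, sp, cfg, np.random.default_rng(5))
        _, b = train_confidence(data, sp, cfg, np.random.default_rng(5))
        assert a == b

    def test_held_out_accuracy_above_080(
        self, trained_pipeline, synthetic_dataset
    ):
        from metaldiff.score_model import make_score_fn
        from metaldiff.sde import init_prior, reverse_sample

        sp = trained_pipeline["score"]
        cp = trained_pipeline["confidence"]
        complexes, splits = synthetic_dataset
        rng = np.random.default_rng(23)
        correct = total = 0
        for i in splits["test"]:
            s = complexes[i].structure
            fn = make_score_fn(s, sp)
            final = reverse_sample(
                fn, init_prior(s, 48, rng), 20, sp.config.schedule, rng
            )
            y = generate_confidence_labels(final, s.metal_sites)
            cs = score_candidates(s, CandidateSet(positions=final), cp)
            correct += int(((cs.probs >= 0.5).astype(int) == y).sum())
            total += y.size
        assert correct / total > 0.8

    def test_true_positive_confidence_exceeds_false_positive(
        self, trained_pipeline, synthetic_dataset
    ):
        from metaldiff.score_model import make_score_fn
        from metaldiff.sde import init_prior, reverse_sample

        sp = trained_pipeline["score"]
        cp = trained_pipeline["confidence"]
        complexes, splits = synthetic_dataset
        rng = np.random.default_rng(29)
        probs, labels = [], []
        for i in splits["test"]:
            s = complexes[i].structure
            fn = make_score_fn(s, sp)
            final = reverse_sample(
                fn, init_prior(s, 40, rng), 20, sp.config.schedule, rng
            )
            labels.append(generate_confidence_labels(final, s.metal_sites))
            cs = score_candidates(s, CandidateSet(positions=final), cp)
            probs.append(cs.probs)
        probs = np.concatenate(probs)
        labels = np.concatenate(labels)
        assert probs.size >= 200
        assert probs[labels == 1].mean() > probs[labels == 0].mean()

    def test_shuffled_label_control_near_chance(self, trained_pipeline,
                                                synthetic_dataset):
        """Training on permuted labels destroys the signal: accuracy on the
        held-out truth stays near 0.5."""
        from metaldiff.score_model import make_score_fn
        from metaldiff.sde import init_prior, reverse_sample

        sp = trained_pipeline["score"]
        complexes, splits = synthetic_dataset
        rng = np.random.default_rng(31)
        cfg = ConfidenceConfig(epochs=40, candidates_per_complex=24)
        cp = init_confidence_params(cfg, sp.config, rng)
        cached = []
        for i in splits["train"][:12]:
            s = complexes[i].structure
            fn = make_score_fn(s, sp)
            final = reverse_sample(
                fn, init_prior(s, 24, rng), 10, sp.config.schedule, rng
            )
            y = generate_confidence_labels(final, s.metal_sites).astype(float)
            g = build_hetero_graph(
                s, final, 0.0, sp.config.graph,
                sigma_t=sp.config.schedule.sigma_min,
            )
            cached.append((g, y))
        # balance then shuffle labels across the pool
        pool = np.concatenate([y for _, y in cached])
        rng.shuffle(pool)
        k = 0
        for j, (g, y) in enumerate(cached):
            cached[j] = (g, pool[k : k + y.size])
            k += y.size
        opt = nn.Adam(cp.params, lr=cfg.lr)
        for _ in range(cfg.epochs):
            for g, y in cached:
                loss, grads, _ = _confidence_backward(g, y, cp)
                opt.step(cp.params, grads)
        ys, ps = [], []
        for i in splits["test"]:
            s = complexes[i].structure
            fn = make_score_fn(s, sp)
            final = reverse_sample(
                fn, init_prior(s, 24, rng), 10, sp.config.schedule, rng
            )
            ys.append(generate_confidence_labels(final, s.metal_sites))
            ps.append(_probs(s, final, cp))
        y = np.concatenate(ys)
        pred = (np.concatenate(ps) >= 0.5).astype(int)
        # balanced accuracy is 0.5 in expectation for a signal-free model,
        # regardless of the label base rate
        acc_pos = (pred[y == 1] == 1).mean()
        acc_neg = (pred[y == 0] == 0).mean()
        assert abs((acc_pos + acc_neg) / 2 - 0.5) <= 0.12
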