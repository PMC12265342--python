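"""Reference benchmark runs used by the test suite and the acceptance script.

Everything here is recomputed from scratch at call time: datasets are
generated, both models trained, and the pipeline executed end to end.  A
single integer seed controls every source of randomness.

The case-study scenario reconstructions mirror the published two-protein
comparison (each protein holds two experimental zinc sites); the TP/FP/FN
count patterns below are the unique ones consistent with the printed
precision/coverage percentages, realized here as explicit coordinate
layouts and pushed through the full matching + metric code path.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import metrics as M
from .confidence import ConfidenceConfig, train_confidence
from .pipeline import predict_structure
from .score_model import ScoreModelConfig, train_score_model
from .sde import NoiseSchedule, forward_perturb, reverse_sample, analytic_mixture_score
from .synthetic import make_dataset, make_mixture_target

#: study conditions for the synthetic end-to-end benchmark
N_COMPLEXES = 40
N_RESIDUES = 30
N_POCKETS = 2

# training a seed costs minutes; within one process (e.g. a pytest session)
# identical (seed, config) requests reuse the result — rng streams are
# derived fresh from the seed, so caching cannot change any number
_MODEL_CACHE: dict = {}


def train_models(
    seed: int,
    n_complexes: int = N_COMPLEXES,
    score_cfg: ScoreModelConfig | None = None,
    conf_cfg: ConfidenceConfig | None = None,
):
    """Dataset + trained score and confidence models for a master seed."""
    score_cfg = score_cfg or ScoreModelConfig()
    conf_cfg = conf_cfg or ConfidenceConfig()
    key = (seed, n_complexes, repr(score_cfg), repr(conf_cfg))
    if key in _MODEL_CACHE:
        return _MODEL_CACHE[key]
    complexes, splits = make_dataset(
        n_complexes, rng=seed, n_residues=N_RESIDUES, n_pockets=N_POCKETS
    )
    train = [complexes[i].structure for i in splits["train"]]
    sp, losses = train_score_model(
        train, score_cfg, np.random.default_rng(seed + 1)
    )
    cp, trace = train_confidence(
        train, sp, conf_cfg, np.random.default_rng(seed + 2)
    )
    out = {
        "complexes": complexes,
        "splits": splits,
        "score": sp,
        "score_losses": losses,
        "confidence": cp,
        "confidence_trace": trace,
    }
    _MODEL_CACHE[key] = out
    return out


@dataclass(frozen=True)
class EndToEndResult:
    precision_pct: float | None
    coverage_pct: float
    mad_mean: float | None
    mad_median: float | None
    n_test: int
    score_losses: list[float]
    confidence_trace: list[dict]
    per_structure: list[dict]


def run_synthetic_end_to_end(
    seed: int,
    n_complexes: int = N_COMPLEXES,
    score_cfg: ScoreModelConfig | None = None,
    conf_cfg: ConfidenceConfig | None = None,
    confidence_cutoff: float = 0.5,
    cluster_eps: float = 5.0,
    cluster_min_samples: int = 2,
) -> EndToEndResult:
    """Train on the train split, predict the held-out test split, pool metrics.

    The master seed deterministically derives the dataset, training, and
    prediction streams.
    """
    models = train_models(seed, n_complexes, score_cfg, conf_cfg)
    complexes, splits = models["complexes"], models["splits"]
    test = [complexes[i].structure for i in splits["test"]]
    sp, losses = models["score"], models["score_losses"]
    cp, trace = models["confidence"], models["confidence_trace"]
    rng = np.random.default_rng(seed + 3)
    matchings = []
    per_structure = []
    for s in test:
        r = predict_structure(
            s, sp, cp, rng,
            confidence_cutoff=confidence_cutoff,
            cluster_eps=cluster_eps,
            cluster_min_samples=cluster_min_samples,
        )
        m = M.match_sites(r.sites, s.metal_sites, 5.0)
        matchings.append(m)
        per_structure.append(
            {"source": s.source_id, **r.counts, "tp": m.tp, "fp": m.fp, "fn": m.fn}
        )
    tp, fp, fn = M.pooled_eval(matchings)
    pairs = [p for m in matchings for p in m.tp_pairs]
    mm, md, _ = M.mad(pairs)
    return EndToEndResult(
        precision_pct=M.precision(tp, fp),
        coverage_pct=M.coverage(tp, fn),
        mad_mean=mm,
        mad_median=md,
        n_test=len(test),
        score_losses=losses,
        confidence_trace=trace,
        per_structure=per_structure,
    )


# ---------------------------------------------------------------------------
# case-study scenario reconstructions (two proteins, two zinc sites each)

_TRUE_SITES = np.array([[0.0, 0.0, 0.0], [30.0, 0.0, 0.0]])


def _scenario(n_tp: int, n_fp: int) -> np.ndarray:
    """Predicted sites hitting the first n_tp true sites plus n_fp decoys."""
    preds = [_TRUE_SITES[i] + np.array([1.2, 0.6, 0.0]) for i in range(n_tp)]
    preds += [np.array([60.0 + 12.0 * k, 40.0, 0.0]) for k in range(n_fp)]
    return np.array(preds) if preds else np.zeros((0, 3))


#: per protein, per method: (TP, FP) against the two true sites
CASE_STUDY_COUNTS = {
    "5in2": {
        "metal3d": (1, 2),
        "supermetal": (2, 0),
        "alphafold3_1ion": (1, 0),
        "alphafold3_2ion": (2, 0),
        "alphafold3_6ion": (2, 4),
    },
    "6btp": {
        "metal3d": (1, 0),
        "supermetal": (2, 0),
        "alphafold3_1ion": (1, 0),
        "alphafold3_2ion": (1, 1),
        "alphafold3_6ion": (1, 5),
    },
}


def case_study_metrics() -> dict[str, dict[str, int]]:
    """Integer precision/coverage for every case-study scenario.

    Each scenario is laid out geometrically and evaluated through
    match_sites -> precision/coverage -> report rounding.
    """
    out: dict[str, dict[str, int]] = {}
    for protein, methods in CASE_STUDY_COUNTS.items():
        for method, (n_tp, n_fp) in methods.items():
            m = M.match_sites(_scenario(n_tp, n_fp), _TRUE_SITES, 5.0)
            out[f"{protein}_{method}"] = {
                "precision": M.round_report(M.precision(m.tp, m.fp)),
                "coverage": M.round_report(M.coverage(m.tp, m.fn)),
            }
    return out


# ---------------------------------------------------------------------------
# analytic oracles


def oracle_sampling_occupancy(seed: int) -> dict[str, float]:
    """Reverse-sample 1000 candidates against a 3-mode closed-form score.

    Modes >= 15 A apart, base variance 0.25 A^2, schedule (0.1, 20),
    200 Euler-Maruyama steps.  Returns the percent of candidates within
    2 A of a mode and the smallest per-mode occupancy percent.
    """
    sch = NoiseSchedule(0.1, 20.0)
    target = make_mixture_target(3, 15.0, 0.25, seed)
    rng = np.random.default_rng(seed + 1)
    lo = target.means.min(axis=0) - 10.0
    hi = target.means.max(axis=0) + 10.0
    init = rng.uniform(lo, hi, size=(1000, 3))
    out = reverse_sample(
        lambda x, t: analytic_mixture_score(x, t, sch, target),
        init, 200, sch, rng,
    )
    d = np.linalg.norm(out[:, None, :] - target.means[None], axis=2)
    within = float((d.min(axis=1) < 2.0).mean() * 100.0)
    occ = np.bincount(d.argmin(axis=1), minlength=3) / out.shape[0]
    return {
        "frac_within_2A_pct": within,
        "min_mode_occupancy_pct": float(occ.min() * 100.0),
    }


def perturbation_kernel_std(seed: int, n_draws: int = 100_000) -> float:
    """Worst per-axis sample std of the forward kernel at sigma(t) = 2 A."""
    sch = NoiseSchedule(0.1, 20.0)
    t = float(np.log(2.0 / sch.sigma_min) / np.log(sch.sigma_max / sch.sigma_min))
    rng = np.random.default_rng(seed)
    rec = forward_perturb(np.zeros((n_draws, 3)), t, sch, rng)
    stds = rec.delta_r.std(axis=0)
    return float(stds[np.abs(stds - 2.0).argmax()])
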