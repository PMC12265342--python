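"""SE(3)-invariant confidence classifier over sampled candidate positions.

Each candidate is scored by the probability that it lies near a true metal
site.  The network reuses the score-model trunk shape: per-edge invariant
features (distance RBF, neighbor type, time embedding at t = 0) pass through
a small tanh MLP; the hidden representations are mean-pooled over each
candidate's edges (separately for the atom and residue branches), concatenated
with log edge counts, and read out through a fully connected head with a
sigmoid.  Every input is a rigid-motion invariant, so the probability is
exactly unchanged under rotations and translations.

Labels follow the per-candidate distance criterion: a candidate is positive
iff its distance to the nearest true site is below the cutoff (default 5 A,
strict ``<``).  Training minimizes binary cross-entropy on candidates drawn
from the trained diffusion sampler, mirroring how the classifier is used at
inference time.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from . import nn
from .errors import ContractError, DomainError, TrainingError
from .graph import GraphConfig, HeteroGraph, build_hetero_graph, graph_config_hash
from .score_model import (
    ScoreModelConfig,
    ScoreModelParams,
    _branch_inputs,
    make_score_fn,
)
from .sde import NoiseSchedule, init_prior, reverse_sample
from .structure import ProteinStructure

CONFIDENCE_CUTOFF_DEFAULT = 5.0  # A, labeling threshold


@dataclass(frozen=True)
class CandidateSet:
    """Sampled candidate positions, optionally with confidence probabilities."""

    positions: np.ndarray  # (n, 3) A
    probs: np.ndarray | None = None  # (n,) in [0, 1]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.probs is not None:
            p = np.asarray(self.probs, dtype=float)
            if p.shape[0] != self.positions.shape[0]:
                raise ContractError("probs and positions length mismatch")
            if p.size and (p.min() < 0 or p.max() > 1):
                raise ContractError("probabilities outside [0, 1]")

    @property
    def n(self) -> int:
        return int(self.positions.shape[0])


def generate_confidence_labels(
    sampled: np.ndarray,
    true_sites: np.ndarray,
    cutoff: float = CONFIDENCE_CUTOFF_DEFAULT,
) -> np.ndarray:
    """Binary labels: 1 iff nearest-true-site distance is strictly below cutoff."""
    true_sites = np.asarray(true_sites, dtype=float).reshape(-1, 3)
    if true_sites.shape[0] == 0:
        raise DomainError("true_sites must be non-empty for labeling")
    sampled = np.asarray(sampled, dtype=float).reshape(-1, 3)
    d = np.linalg.norm(
        sampled[:, None, :] - true_sites[None, :, :], axis=2
    ).min(axis=1)
    return (d < cutoff).astype(int)


@dataclass(frozen=True)
class ConfidenceConfig:
    """Hyperparameters of the confidence classifier and its training loop."""

    hidden: int = 64
    pooled: int = 32
    lr: float = 1e-3
    epochs: int = 400
    batch_complexes: int = 8
    candidates_per_complex: int = 128
    sample_steps: int = 20
    label_cutoff: float = CONFIDENCE_CUTOFF_DEFAULT
    # relative weight of negative (far-from-site) candidates in the
    # cross-entropy; >1 trades a little recall for specificity, which matters
    # because two surviving strays within eps already form a spurious site
    negative_weight: float = 3.0


@dataclass
class ConfidenceParams:
    """Classifier parameters tied to the score model's graph configuration."""

    params: nn.Params
    config: ConfidenceConfig
    score_config: ScoreModelConfig
    config_hash: str  # hash of the graph config, as for the score model

    def to_json(self) -> str:
        sc = self.score_config
        return json.dumps(
            {
                "kind": "confidence",
                "config_hash": self.config_hash,
                "config": asdict(self.config),
                "graph": asdict(sc.graph),
                "schedule": asdict(sc.schedule),
                "score_hidden": sc.hidden,
                "params": nn.params_to_jsonable(self.params),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "ConfidenceParams":
        blob = json.loads(text)
        sc = ScoreModelConfig(
            graph=GraphConfig(**blob["graph"]),
            schedule=NoiseSchedule(**blob["schedule"]),
            hidden=blob["score_hidden"],
        )
        return cls(
            params=nn.params_from_jsonable(blob["params"]),
            config=ConfidenceConfig(**blob["config"]),
            score_config=sc,
            config_hash=blob["config_hash"],
        )


def init_confidence_params(
    cfg: ConfidenceConfig, score_cfg: ScoreModelConfig, rng: np.random.Generator
) -> ConfidenceParams:
    params: nn.Params = {}
    params.update(
        nn.mlp_init([score_cfg.atom_feat_dim, cfg.hidden, cfg.pooled], rng, "catom_")
    )
    params.update(
        nn.mlp_init([score_cfg.res_feat_dim, cfg.hidden, cfg.pooled], rng, "cres_")
    )
    head_in = 2 * cfg.pooled + 2
    params.update(nn.mlp_init([head_in, cfg.hidden // 2, 1], rng, "head_"))
    return ConfidenceParams(
        params=params,
        config=cfg,
        score_config=score_cfg,
        config_hash=graph_config_hash(score_cfg.graph),
    )


_TRUNK_LAYERS = 2  # one tanh hidden layer + tanh pooled representation
_HEAD_LAYERS = 2


def _trunk_forward(x, params, prefix):
    h, cache = nn.mlp_forward(x, params, _TRUNK_LAYERS, prefix=prefix)
    h = np.tanh(h)  # keep pooled representation bounded
    cache.append(h)
    return h, cache


def _pooled_features(g: HeteroGraph, cp: ConfidenceParams, want_cache=False):
    """Mean-pooled scalar trunk representations per metal, plus edge counts."""
    branches = _branch_inputs(g, cp.score_config)
    n = g.n_metals
    pooled = {}
    caches = {}
    counts = {}
    for name, prefix in (("atom", "catom_"), ("res", "cres_")):
        b = branches[name]
        cnt = np.bincount(b["metal"], minlength=n).astype(float)
        counts[name] = cnt
        if b["feat"].shape[0] == 0:
            pooled[name] = np.zeros((n, cp.config.pooled))
            caches[name] = None
            continue
        h, cache = _trunk_forward(b["feat"], cp.params, prefix)
        acc = np.zeros((n, cp.config.pooled))
        np.add.at(acc, b["metal"], h)
        pooled[name] = acc / np.maximum(cnt, 1.0)[:, None]
        caches[name] = cache
    feats = np.concatenate(
        [
            pooled["atom"],
            pooled["res"],
            np.log1p(counts["atom"])[:, None],
            np.log1p(counts["res"])[:, None],
        ],
        axis=1,
    )
    if want_cache:
        return feats, branches, caches, counts
    return feats


def confidence_forward(g: HeteroGraph, cp: ConfidenceParams) -> np.ndarray:
    """Per-candidate probability in (0, 1); invariant under rigid motions."""
    if g.n_metals == 0:
        raise ContractError("graph contains no metal node")
    if graph_config_hash(g.config) != cp.config_hash:
        raise ContractError("graph config hash does not match confidence parameters")
    feats = _pooled_features(g, cp)
    logit, _ = nn.mlp_forward(feats, cp.params, _HEAD_LAYERS, prefix="head_")
    return 1.0 / (1.0 + np.exp(-logit[:, 0]))


def score_candidates(
    s: ProteinStructure, cands: CandidateSet, cp: ConfidenceParams
) -> CandidateSet:
    """Attach confidence probabilities to a candidate set (graph built at t=0)."""
    g = build_hetero_graph(
        s, cands.positions, 0.0, cp.score_config.graph,
        sigma_t=cp.score_config.schedule.sigma_min,
    )
    probs = confidence_forward(g, cp)
    return CandidateSet(
        positions=cands.positions, probs=probs, provenance=dict(cands.provenance)
    )


def filter_by_confidence(cands: CandidateSet, p: float) -> CandidateSet:
    """Keep candidates with probability >= p (order preserved)."""
    if cands.probs is None:
        raise ContractError("candidate set has no confidence probabilities")
    if not 0.0 <= p <= 1.0:
        raise DomainError(f"threshold p={p} outside [0, 1]")
    keep = np.asarray(cands.probs) >= p
    return CandidateSet(
        positions=cands.positions[keep],
        probs=np.asarray(cands.probs)[keep],
        provenance=dict(cands.provenance),
    )


# ---------------------------------------------------------------------------
# training


def _bce(p: np.ndarray, y: np.ndarray, neg_weight: float = 1.0) -> float:
    eps = 1e-12
    w = np.where(y > 0.5, 1.0, neg_weight)
    return float(
        -(w * (y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps))).mean()
    )


def train_confidence(
    dataset: list[ProteinStructure],
    score_params: ScoreModelParams,
    cfg: ConfidenceConfig | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[ConfidenceParams, list[dict]]:
    """Train the confidence classifier on candidates drawn from the sampler.

    For each training complex, candidates are generated with the trained
    diffusion model, labeled by the nearest-true-site criterion, and the
    classifier is fit with cross-entropy.  Returns the parameters and a
    per-epoch trace of loss and training accuracy.

    Raises
    ------
    TrainingError
        On an empty dataset or when all pooled labels fall in one class.
    """
    if not dataset:
        raise TrainingError("empty training dataset")
    cfg = cfg or ConfidenceConfig()
    rng = rng or np.random.default_rng()
    cp = init_confidence_params(cfg, score_params.config, rng)

    # draw and featurize candidates once; epochs then iterate over the cache
    cached = []
    all_labels = []
    for s in dataset:
        fn = make_score_fn(s, score_params)
        init = init_prior(s, n=cfg.candidates_per_complex, rng=rng)
        final = reverse_sample(
            fn, init, cfg.sample_steps, score_params.config.schedule, rng
        )
        labels = generate_confidence_labels(final, s.metal_sites, cfg.label_cutoff)
        g = build_hetero_graph(
            s, final, 0.0, score_params.config.graph,
            sigma_t=score_params.config.schedule.sigma_min,
        )
        cached.append((g, labels.astype(float)))
        all_labels.append(labels)
    pooled_labels = np.concatenate(all_labels)
    if pooled_labels.min() == pooled_labels.max():
        raise TrainingError(
            "degenerate labels: all candidates are "
            + ("positive" if pooled_labels[0] else "negative")
            + f" (n={pooled_labels.size}); cannot train a classifier"
        )

    opt = nn.Adam(cp.params, lr=cfg.lr)
    trace: list[dict] = []
    n = len(cached)
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        ep_loss, ep_correct, ep_count = 0.0, 0, 0
        for start in range(0, n, cfg.batch_complexes):
            batch = order[start : start + cfg.batch_complexes]
            grads: nn.Params = {}
            for idx in batch:
                g, y = cached[idx]
                loss, gr, correct = _confidence_backward(g, y, cp)
                nn.accumulate(grads, gr, weight=1.0 / len(batch))
                ep_loss += loss * y.size
                ep_correct += correct
                ep_count += y.size
            opt.step(cp.params, grads)
        if not np.isfinite(ep_loss):
            raise TrainingError(f"NaN/inf confidence loss at epoch {epoch}")
        trace.append(
            {"epoch": epoch, "loss": ep_loss / ep_count, "accuracy": ep_correct / ep_count}
        )
    return cp, trace


def _confidence_backward(g: HeteroGraph, y: np.ndarray, cp: ConfidenceParams):
    feats, branches, caches, counts = _pooled_features(g, cp, want_cache=True)
    logit, head_cache = nn.mlp_forward(feats, cp.params, _HEAD_LAYERS, prefix="head_")
    p = 1.0 / (1.0 + np.exp(-logit[:, 0]))
    nw = cp.config.negative_weight
    loss = _bce(p, y, nw)
    correct = int(((p >= 0.5).astype(int) == y.astype(int)).sum())
    m = y.size
    w = np.where(y > 0.5, 1.0, nw)
    grad_logit = (w * (p - y) / m)[:, None]  # weighted BCE through sigmoid
    grads, grad_feats = nn.mlp_backward(
        grad_logit, cp.params, head_cache, _HEAD_LAYERS, prefix="head_"
    )
    pooled = cp.config.pooled
    for k, (name, prefix) in enumerate((("atom", "catom_"), ("res", "cres_"))):
        b = branches[name]
        cache = caches[name]
        if cache is None:
            continue
        g_pool = grad_feats[:, k * pooled : (k + 1) * pooled]
        cnt = np.maximum(counts[name], 1.0)
        g_edge = g_pool[b["metal"]] / cnt[b["metal"], None]
        g_edge = g_edge * (1.0 - cache[-1] ** 2)  # through the bounding tanh
        br_grads, _ = nn.mlp_backward(
            g_edge, cp.params, cache[:-1], _TRUNK_LAYERS, prefix=prefix
        )
        nn.accumulate(grads, br_grads)
    return loss, grads, correct
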