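"""The trainable score model S_theta(x, y, t) and its denoising training loop.

Architecture (equivariant by construction)
------------------------------------------
For each candidate metal the model gathers its metal-atom and metal-residue
edges from the heterogeneous graph.  Each edge contributes an *invariant*
feature vector -- radial basis expansion of the distance, the neighbor's
type one-hot, the diffusion-time embedding, and the ratio d/sigma(t) --
which a small tanh MLP maps to two scalars: an attention logit and a radial
correction weight.  The model is a denoiser: soft attention over the
candidate's neighbors predicts where the clean metal position lies,

    x0_hat(m) = sum_e alpha_e a_e  +  sum_e beta_e u_e ,
    alpha = softmax over m's edges of the logits,

(a_e = neighbor position, u_e = unit vector from the metal to it; the beta
head lets the prediction leave the convex hull of the neighbors, e.g. for
3-coordinated sites).  The noise-normalized score is s_hat = (x0_hat - x) /
sigma(t) and the physical score is s_hat / sigma(t) -- the standard
denoiser/score identity for a Gaussian kernel.  Every scalar the network
computes is a rigid-motion invariant and the output is assembled from
positions and unit vectors, so the score is exactly translation-invariant
and rotation-equivariant.

Training samples t ~ U(0,1) per complex per step, perturbs the true metal
positions with the forward kernel, rebuilds the graph at the perturbed
positions, and regresses the model output onto the closed-form kernel score
by minibatch SGD (Adam).  The sigma(t)^2-weighted objective is the default
(all noise levels contribute comparably); the unweighted objective is
available via ``loss_weighting='none'``.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import numpy as np

from . import nn
from .errors import ContractError, TrainingError
from .graph import (
    ELEMENT_VOCAB,
    RESIDUE_VOCAB,
    GraphConfig,
    HeteroGraph,
    build_hetero_graph,
    graph_config_hash,
    rbf_expand,
)
from .sde import NoiseSchedule, sigma
from .structure import ProteinStructure

N_MLP_LAYERS = 3  # two tanh hidden layers + linear scalar readout


@dataclass(frozen=True)
class ScoreModelConfig:
    """Hyperparameters of the score model and its training loop."""

    graph: GraphConfig = field(default_factory=GraphConfig)
    schedule: NoiseSchedule = field(default_factory=NoiseSchedule)
    hidden: int = 64
    lr: float = 1e-3
    batch_size: int = 4
    epochs: int = 400  # matches the published training length; cheap at toy scale
    loss_weighting: str = "sigma2"  # or "none"
    grad_clip: float = 100.0  # global-norm clip; low-t draws have heavy tails

    @property
    def atom_feat_dim(self) -> int:
        return self.graph.n_rbf + len(ELEMENT_VOCAB) + self.graph.t_embed_dim + 4

    @property
    def res_feat_dim(self) -> int:
        return self.graph.n_rbf + len(RESIDUE_VOCAB) + self.graph.t_embed_dim + 4

    @property
    def r_far_max(self) -> float:
        return self.graph.r_far(self.schedule.sigma_max)


def config_hash(cfg: ScoreModelConfig) -> str:
    blob = json.dumps(
        {"graph": asdict(cfg.graph), "schedule": asdict(cfg.schedule),
         "hidden": cfg.hidden},
        sort_keys=True,
    ).encode()
    return hashlib.sha1(blob).hexdigest()[:16]


@dataclass
class ScoreModelParams:
    """Opaque parameter collection + the config it was trained under."""

    params: nn.Params
    config: ScoreModelConfig
    config_hash: str

    def to_json(self) -> str:
        return json.dumps(
            {
                "kind": "score",
                "config_hash": self.config_hash,
                "graph": asdict(self.config.graph),
                "schedule": asdict(self.config.schedule),
                "hidden": self.config.hidden,
                "lr": self.config.lr,
                "batch_size": self.config.batch_size,
                "epochs": self.config.epochs,
                "loss_weighting": self.config.loss_weighting,
                "grad_clip": self.config.grad_clip,
                "params": nn.params_to_jsonable(self.params),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "ScoreModelParams":
        blob = json.loads(text)
        cfg = ScoreModelConfig(
            graph=GraphConfig(**blob["graph"]),
            schedule=NoiseSchedule(**blob["schedule"]),
            hidden=blob["hidden"],
            lr=blob["lr"],
            batch_size=blob["batch_size"],
            epochs=blob["epochs"],
            loss_weighting=blob["loss_weighting"],
            grad_clip=blob.get("grad_clip", 100.0),
        )
        return cls(
            params=nn.params_from_jsonable(blob["params"]),
            config=cfg,
            config_hash=blob["config_hash"],
        )


def init_score_params(
    cfg: ScoreModelConfig, rng: np.random.Generator
) -> ScoreModelParams:
    h = cfg.hidden
    params: nn.Params = {}
    # two outputs per edge: attention logit, radial correction
    params.update(nn.mlp_init([cfg.atom_feat_dim, h, h, 2], rng, prefix="atom_"))
    params.update(nn.mlp_init([cfg.res_feat_dim, h, h, 2], rng, prefix="res_"))
    return ScoreModelParams(params=params, config=cfg, config_hash=config_hash(cfg))


# ---------------------------------------------------------------------------
# featurization


def _branch_inputs(
    g: HeteroGraph, cfg: ScoreModelConfig
) -> dict[str, dict[str, np.ndarray]]:
    """Per-branch edge features, unit vectors, and metal indices."""
    out = {}
    n = g.n_metals
    count_atom = np.bincount(g.metal_atom.src, minlength=n).astype(float)
    count_res = np.bincount(g.metal_res.src, minlength=n).astype(float)
    for name, edges, coords, onehot, cutoff in (
        ("atom", g.metal_atom, g.atom_coords, g.atom_onehot, cfg.graph.r_near),
        ("res", g.metal_res, g.residue_coords, g.residue_onehot, cfg.r_far_max),
    ):
        if edges.n_edges == 0:
            out[name] = {
                "feat": np.zeros((0, cfg.atom_feat_dim if name == "atom" else cfg.res_feat_dim)),
                "unit": np.zeros((0, 3)),
                "metal": np.zeros(0, dtype=int),
                "pos": np.zeros((0, 3)),
            }
            continue
        d = edges.dist
        vec = coords[edges.dst] - g.metal_coords[edges.src]
        unit = vec / np.maximum(d, 1e-9)[:, None]
        sig_t = sigma(g.t, cfg.schedule)
        # d/sigma is the natural scale of the normalized score target
        feat = np.concatenate(
            [
                rbf_expand(d, cutoff, cfg.graph.n_rbf),
                onehot[edges.dst],
                np.tile(g.t_embed, (d.shape[0], 1)),
                np.clip(d / sig_t, 0.0, 50.0)[:, None],
                (d / cutoff)[:, None],
                # neighborhood sizes disambiguate e.g. 3- vs 4-coordination
                np.log1p(count_atom[edges.src])[:, None],
                np.log1p(count_res[edges.src])[:, None],
            ],
            axis=1,
        )
        out[name] = {
            "feat": feat,
            "unit": unit,
            "metal": edges.src,
            "pos": coords[edges.dst],
        }
    return out


def _forward_denoiser(g: HeteroGraph, sp: ScoreModelParams):
    """Denoiser displacement x0_hat - x per metal, with full cache."""
    cfg = sp.config
    branches = _branch_inputs(g, cfg)
    n = g.n_metals
    caches = {}
    outs = {}
    for name, b in branches.items():
        if b["feat"].shape[0] == 0:
            caches[name] = None
            outs[name] = np.zeros((0, 2))
            continue
        o, cache = nn.mlp_forward(b["feat"], sp.params, N_MLP_LAYERS, prefix=f"{name}_")
        caches[name] = cache
        outs[name] = o
    # joint softmax over each metal's edges from both branches
    metal = np.concatenate([b["metal"] for b in branches.values()])
    pos = np.vstack([b["pos"] for b in branches.values()])
    unit = np.vstack([b["unit"] for b in branches.values()])
    logit = np.concatenate([o[:, 0] for o in outs.values()])
    beta = np.concatenate([o[:, 1] for o in outs.values()])
    has_edge = np.zeros(n, dtype=bool)
    has_edge[metal] = True
    mx = np.full(n, -np.inf)
    np.maximum.at(mx, metal, logit)
    ex = np.exp(logit - mx[metal])
    denom = np.zeros(n)
    np.add.at(denom, metal, ex)
    alpha = ex / denom[metal]
    disp = np.zeros((n, 3))
    np.add.at(disp, metal, alpha[:, None] * pos + beta[:, None] * unit)
    disp[has_edge] -= g.metal_coords[has_edge]
    cache = {
        "branches": branches,
        "caches": caches,
        "metal": metal,
        "pos": pos,
        "unit": unit,
        "alpha": alpha,
        "beta": beta,
        "has_edge": has_edge,
        "sizes": {k: b["feat"].shape[0] for k, b in branches.items()},
    }
    return disp, cache


def _forward_normalized(
    g: HeteroGraph, sp: ScoreModelParams, want_cache: bool = False
):
    """Noise-normalized model output s_hat = (x0_hat - x)/sigma(t) per metal."""
    disp, cache = _forward_denoiser(g, sp)
    out = disp / sigma(g.t, sp.config.schedule)
    if want_cache:
        return out, cache
    return out


def _backward_normalized(
    grad_out: np.ndarray, g: HeteroGraph, sp: ScoreModelParams, cache: dict
) -> nn.Params:
    """Gradients of a loss wrt parameters given d loss / d s_hat."""
    grad_disp = grad_out / sigma(g.t, sp.config.schedule)  # (n_metals, 3)
    metal, pos, unit = cache["metal"], cache["pos"], cache["unit"]
    alpha = cache["alpha"]
    gm = grad_disp[metal]  # (E, 3)
    grad_beta = (unit * gm).sum(axis=1)
    grad_alpha = (pos * gm).sum(axis=1)
    # softmax backward per metal: dl_e = alpha_e (da_e - sum_e' alpha_e' da_e')
    inner = np.zeros(grad_disp.shape[0])
    np.add.at(inner, metal, alpha * grad_alpha)
    grad_logit = alpha * (grad_alpha - inner[metal])
    grads: nn.Params = {}
    offset = 0
    for name in ("atom", "res"):
        e = cache["sizes"][name]
        c = cache["caches"][name]
        if c is None:
            continue
        go = np.stack(
            [grad_logit[offset : offset + e], grad_beta[offset : offset + e]],
            axis=1,
        )
        br_grads, _ = nn.mlp_backward(
            go, sp.params, c, N_MLP_LAYERS, prefix=f"{name}_"
        )
        nn.accumulate(grads, br_grads)
        offset += e
    return grads


def score_forward(g: HeteroGraph, sp: ScoreModelParams) -> np.ndarray:
    """Physical-scale score (A^-1), one 3-vector per candidate metal.

    Translation-invariant and rotation-equivariant by construction.

    Raises
    ------
    ContractError
        If the graph was built under a different graph configuration than the
        one the parameters were trained with.
    """
    if g.n_metals == 0:
        raise ContractError("graph contains no metal node")
    if graph_config_hash(g.config) != graph_config_hash(sp.config.graph):
        raise ContractError(
            "graph config hash does not match score-model parameters"
        )
    return _forward_normalized(g, sp) / sigma(g.t, sp.config.schedule)


def make_score_fn(s: ProteinStructure, sp: ScoreModelParams):
    """Bind a structure, producing the ``(positions, t) -> scores`` callable."""

    def fn(positions: np.ndarray, t: float) -> np.ndarray:
        sig = sigma(t, sp.config.schedule)
        g = build_hetero_graph(s, positions, t, sp.config.graph, sigma_t=sig)
        return score_forward(g, sp)

    return fn


# ---------------------------------------------------------------------------
# training


def _complex_loss_and_grads(
    s: ProteinStructure,
    sp: ScoreModelParams,
    rng: np.random.Generator,
) -> tuple[float, nn.Params]:
    """One denoising score-matching draw for a training complex."""
    cfg = sp.config
    t = float(rng.uniform(0.0, 1.0))
    sig = sigma(t, cfg.schedule)
    sites = s.metal_sites
    delta = rng.standard_normal(sites.shape) * sig
    metals = sites + delta
    g = build_hetero_graph(s, metals, t, cfg.graph, sigma_t=sig)
    target_norm = -delta / sig  # sigma(t) * kernel score
    out, cache = _forward_normalized(g, sp, want_cache=True)
    resid = out - target_norm
    m = max(g.n_metals, 1)
    # sigma^2-weighted objective compares normalized quantities with weight 1;
    # the plain objective rescales by 1/sigma^2.
    lam = 1.0 if cfg.loss_weighting == "sigma2" else 1.0 / (sig * sig)
    loss = lam * float((resid**2).sum() / m)
    grad_out = 2.0 * lam * resid / m  # (n_metals, 3)
    grads = _backward_normalized(grad_out, g, sp, cache)
    return loss, grads


def train_score_model(
    dataset: list[ProteinStructure],
    cfg: ScoreModelConfig | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[ScoreModelParams, list[float]]:
    """Train the score model by denoising score matching.

    Returns the trained parameters and the per-epoch mean loss trace.

    Raises
    ------
    TrainingError
        On an empty dataset, a complex without metal sites, or NaN loss.
    """
    if not dataset:
        raise TrainingError("empty training dataset")
    for s in dataset:
        if s.n_metal_sites == 0:
            raise TrainingError(f"{s.source_id}: no metal sites for training")
    cfg = cfg or ScoreModelConfig()
    rng = rng or np.random.default_rng()
    sp = init_score_params(cfg, rng)
    opt = nn.Adam(sp.params, lr=cfg.lr)
    losses: list[float] = []
    n = len(dataset)
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        epoch_losses: list[float] = []
        for start in range(0, n, cfg.batch_size):
            batch = order[start : start + cfg.batch_size]
            grads: nn.Params = {}
            batch_loss = 0.0
            for idx in batch:
                loss, g = _complex_loss_and_grads(dataset[idx], sp, rng)
                batch_loss += loss
                nn.accumulate(grads, g, weight=1.0 / len(batch))
            batch_loss /= len(batch)
            if not np.isfinite(batch_loss):
                raise TrainingError(
                    f"NaN/inf loss at epoch {epoch}, batch starting {start}"
                )
            epoch_losses.append(batch_loss)
            nn.clip_global_norm(grads, cfg.grad_clip)
            opt.step(sp.params, grads)
        losses.append(float(np.mean(epoch_losses)))
    return sp, losses
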