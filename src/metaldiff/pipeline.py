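"""End-to-end prediction: sample -> score -> filter -> cluster."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .confidence import (
    CandidateSet,
    ConfidenceParams,
    filter_by_confidence,
    score_candidates,
)
from .postprocess import ClusterResult, cluster_candidates
from .score_model import ScoreModelParams, make_score_fn
from .sde import init_prior, reverse_sample
from .structure import ProteinStructure


@dataclass(frozen=True)
class PredictionResult:
    """Final sites plus every intermediate stage, for accounting and curves."""

    candidates: CandidateSet  # all sampled candidates, with probabilities
    kept: CandidateSet  # after confidence filtering
    clusters: ClusterResult
    sites: np.ndarray  # (k, 3) final predicted positions
    site_probs: np.ndarray  # (k,) mean member confidence per site
    counts: dict  # stage counters: sampled / kept / clusters


def predict_structure(
    s: ProteinStructure,
    score_params: ScoreModelParams,
    conf_params: ConfidenceParams,
    rng: np.random.Generator,
    n_candidates: int = 100,
    n_steps: int = 20,
    confidence_cutoff: float = 0.5,
    cluster_eps: float = 5.0,
    cluster_min_samples: int = 2,
    denoise_last: bool = True,
) -> PredictionResult:
    """Run the full inference pipeline on one (cleaned) structure.

    Candidates are initialized uniformly in the padded bounding box, denoised
    by reverse diffusion under the trained score model, scored by the
    confidence classifier, thresholded, and consolidated by DBSCAN; each
    cluster contributes one predicted site at its centroid.
    """
    fn = make_score_fn(s, score_params)
    init = init_prior(s, n=n_candidates, rng=rng)
    final = reverse_sample(
        fn, init, n_steps, score_params.config.schedule, rng,
        denoise_last=denoise_last,
    )
    cands = score_candidates(
        s, CandidateSet(positions=final, provenance={"source": s.source_id}),
        conf_params,
    )
    kept = filter_by_confidence(cands, confidence_cutoff)
    clusters = cluster_candidates(
        kept.positions, eps=cluster_eps, min_samples=cluster_min_samples
    )
    site_probs = np.array(
        [np.mean([kept.probs[i] for i in mem]) for mem in clusters.members]
    ) if clusters.n_clusters else np.zeros(0)
    return PredictionResult(
        candidates=cands,
        kept=kept,
        clusters=clusters,
        sites=clusters.centroids,
        site_probs=site_probs,
        counts={
            "sampled": cands.n,
            "kept": kept.n,
            "clusters": clusters.n_clusters,
        },
    )
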