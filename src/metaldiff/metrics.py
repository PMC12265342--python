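"""Evaluation of predicted metal sites against experimental sites.

A predicted site is a true positive when it falls within the distance cutoff
(default 5 A, inclusive) of an experimental site.  Matching is one-to-one and
greedy by distance: all prediction-truth pairs are sorted ascending and a
pair is accepted iff both ends are still unmatched and the distance is within
the cutoff; this prevents one prediction from claiming two ions and vice
versa, with deterministic ties broken by (prediction index, truth index).

    precision = 100 * TP / (TP + FP)      (undefined when nothing predicted)
    coverage  = 100 * TP / (TP + FN)
    MAD       = mean ||x_i - x_hat_i|| over matched (true-positive) pairs

Integer rounding (half away from zero) is applied only at report level; raw
floats are retained internally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import ContractError, DomainError

MATCH_CUTOFF_DEFAULT = 5.0  # A


@dataclass(frozen=True)
class Matching:
    """One-to-one site assignment between predictions and truths."""

    tp_pairs: tuple[tuple[int, int, float], ...]  # (pred idx, true idx, distance)
    fp_indices: tuple[int, ...]
    fn_indices: tuple[int, ...]

    @property
    def tp(self) -> int:
        return len(self.tp_pairs)

    @property
    def fp(self) -> int:
        return len(self.fp_indices)

    @property
    def fn(self) -> int:
        return len(self.fn_indices)


@dataclass(frozen=True)
class EvalResult:
    """Counts, percentages, and positional-deviation statistics."""

    tp_pairs: tuple[tuple[int, int, float], ...]
    fp: int
    fn: int
    precision_pct: float | None  # None when no predictions were made
    coverage_pct: float
    mad_mean: float | None  # None (flagged undefined) with zero TP
    mad_median: float | None
    mad_std: float | None

    @property
    def tp(self) -> int:
        return len(self.tp_pairs)


def match_sites(
    pred: np.ndarray, true: np.ndarray, cutoff: float = MATCH_CUTOFF_DEFAULT,
    inclusive: bool = True,
) -> Matching:
    """Greedy nearest-first one-to-one matching within the distance cutoff."""
    if cutoff <= 0:
        raise DomainError(f"cutoff must be positive, got {cutoff}")
    pred = np.asarray(pred, dtype=float).reshape(-1, 3)
    true = np.asarray(true, dtype=float).reshape(-1, 3)
    np_, nt = pred.shape[0], true.shape[0]
    pairs = []
    for i in range(np_):
        for j in range(nt):
            d = float(np.linalg.norm(pred[i] - true[j]))
            ok = d <= cutoff if inclusive else d < cutoff
            if ok:
                pairs.append((d, i, j))
    pairs.sort()  # by distance, then pred idx, then true idx
    used_p: set[int] = set()
    used_t: set[int] = set()
    tp: list[tuple[int, int, float]] = []
    for d, i, j in pairs:
        if i in used_p or j in used_t:
            continue
        used_p.add(i)
        used_t.add(j)
        tp.append((i, j, d))
    return Matching(
        tp_pairs=tuple(tp),
        fp_indices=tuple(i for i in range(np_) if i not in used_p),
        fn_indices=tuple(j for j in range(nt) if j not in used_t),
    )


def precision(tp: int, fp: int) -> float | None:
    """Percent of predictions that are correct; None (undefined) if none made."""
    if tp < 0 or fp < 0:
        raise ContractError("counts must be non-negative")
    if tp + fp == 0:
        return None
    return 100.0 * tp / (tp + fp)


def coverage(tp: int, fn: int) -> float:
    """Percent of true sites recovered."""
    if tp < 0 or fn < 0:
        raise ContractError("counts must be non-negative")
    if tp + fn == 0:
        raise DomainError("coverage undefined: structure has no true sites")
    return 100.0 * tp / (tp + fn)


def mad(
    tp_pairs: tuple[tuple[int, int, float], ...] | list,
) -> tuple[float | None, float | None, float | None]:
    """Mean/median/std of matched-pair distances; (None,)*3 with no pairs."""
    d = np.array([p[2] for p in tp_pairs], dtype=float)
    if d.size == 0:
        return None, None, None
    return float(d.mean()), float(np.median(d)), float(d.std())


def round_report(x: float | None) -> int | None:
    """Integer rounding, half away from zero, for table-style reporting."""
    if x is None:
        return None
    return int(math.floor(abs(x) + 0.5) * (1 if x >= 0 else -1))


def evaluate_sites(
    pred: np.ndarray, true: np.ndarray, cutoff: float = MATCH_CUTOFF_DEFAULT
) -> EvalResult:
    """Match then compute precision, coverage, and MAD statistics."""
    m = match_sites(pred, true, cutoff)
    mm, md, ms = mad(m.tp_pairs)
    return EvalResult(
        tp_pairs=m.tp_pairs,
        fp=m.fp,
        fn=m.fn,
        precision_pct=precision(m.tp, m.fp),
        coverage_pct=coverage(m.tp, m.fn),
        mad_mean=mm,
        mad_median=md,
        mad_std=ms,
    )


def pooled_eval(results: list[Matching]) -> tuple[int, int, int]:
    """Micro-averaged TP/FP/FN totals across structures."""
    tp = sum(r.tp for r in results)
    fp = sum(r.fp for r in results)
    fn = sum(r.fn for r in results)
    return tp, fp, fn


def precision_coverage_curve(
    runs: list[tuple["np.ndarray", "np.ndarray", "np.ndarray"]],
    thresholds: list[float],
    eps: float = 5.0,
    min_samples: int = 2,
    cutoff: float = MATCH_CUTOFF_DEFAULT,
) -> list[tuple[float, float | None, float]]:
    """Pooled precision/coverage as the confidence threshold sweeps.

    Parameters
    ----------
    runs
        Per structure: (candidate positions (n,3), candidate probs (n,),
        true sites (m,3)).
    thresholds
        Confidence cutoffs in [0, 1]; output is sorted by threshold.

    For each threshold the full filter -> cluster -> match pipeline runs per
    structure and TP/FP/FN are pooled (micro-averaged) before computing the
    percentages.
    """
    from .postprocess import cluster_candidates

    for p in thresholds:
        if not 0.0 <= p <= 1.0:
            raise DomainError(f"threshold {p} outside [0, 1]")
    out = []
    for p in sorted(thresholds):
        matchings = []
        for positions, probs, true_sites in runs:
            keep = np.asarray(probs, dtype=float) >= p
            kept = np.asarray(positions, dtype=float).reshape(-1, 3)[keep]
            cl = cluster_candidates(kept, eps=eps, min_samples=min_samples)
            matchings.append(match_sites(cl.centroids, true_sites, cutoff))
        tp, fp, fn = pooled_eval(matchings)
        out.append((p, precision(tp, fp), coverage(tp, fn)))
    return out
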