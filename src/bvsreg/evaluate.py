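"""Replicate-averaged ranking, SNP calling and ROC/AUC evaluation.

Mirrors the GAW17-style analysis: fit one chain per phenotype replicate,
average each SNP's |posterior-mean coefficient| and PPA across replicates,
rank SNPs by each averaged score (1 = largest), and call a SNP associated
when it ranks within the estimated number of associated SNPs under both
scores.  With a truth table, score cutoffs are swept to trace TPR/FPR and
the area under the ROC summarises ranking performance, both on all SNPs
and on the rare subset (MAF < 1%).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datatypes import TruthTable
from .exceptions import AlignmentError, InvalidDataError, UndefinedRocError
from .model import PosteriorSummary

__all__ = [
    "ReplicateAverages",
    "CalledSet",
    "RocCurve",
    "average_over_replicates",
    "call_associated",
    "roc_curve",
    "rare_subset_roc",
]


@dataclass
class ReplicateAverages:
    """Across-replicate score averages and ranks per SNP."""

    snp_ids: np.ndarray
    mean_abs_coef: np.ndarray
    mean_ppa: np.ndarray
    rank_coef: np.ndarray
    rank_ppa: np.ndarray
    k_points: np.ndarray

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)


@dataclass
class CalledSet:
    """Associated-SNP calls under the k-range rule."""

    k_range: tuple[int, int]
    called: np.ndarray  # boolean mask
    snp_ids: np.ndarray

    @property
    def called_ids(self) -> np.ndarray:
        return self.snp_ids[self.called]


@dataclass
class RocCurve:
    """ROC points (cutoff sweep, descending) and trapezoidal AUC."""

    cutoffs: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float


def _ranks_descending(score: np.ndarray) -> np.ndarray:
    """Rank 1 = largest score; ties broken by ascending SNP index."""
    p = len(score)
    order = np.lexsort((np.arange(p), -np.asarray(score, dtype=float)))
    ranks = np.empty(p, dtype=np.int64)
    ranks[order] = np.arange(1, p + 1)
    return ranks


def average_over_replicates(
    summaries: list[PosteriorSummary],
) -> ReplicateAverages:
    """Average |coefficient| and PPA per SNP over replicate chains.

    All summaries must share the same SNP ids in the same order.  Ranks
    are assigned per averaged score in decreasing order, ties broken by
    SNP index.
    """
    if not summaries:
        raise InvalidDataError("no summaries to average")
    ids = np.asarray(summaries[0].snp_ids, dtype=object)
    for s in summaries[1:]:
        if len(s.snp_ids) != len(ids) or (np.asarray(s.snp_ids) != ids).any():
            raise AlignmentError("summaries do not share the same SNP set/order")
    abs_coef = np.mean([np.abs(s.alpha_mean) for s in summaries], axis=0)
    mean_ppa = np.mean([s.ppa for s in summaries], axis=0)
    return ReplicateAverages(
        snp_ids=ids,
        mean_abs_coef=abs_coef,
        mean_ppa=mean_ppa,
        rank_coef=_ranks_descending(abs_coef),
        rank_ppa=_ranks_descending(mean_ppa),
        k_points=np.array([s.k_point for s in summaries], dtype=np.int64),
    )


def call_associated(
    avgs: ReplicateAverages, score: str = "both"
) -> CalledSet:
    """Call SNPs whose rank falls within the estimated-k range maximum.

    The per-replicate point estimates of the associated-SNP count give a
    (min, max) range; a SNP is called when its rank is <= max under both
    the |coefficient| and PPA rankings (``score="coef"`` or ``"ppa"``
    relaxes to a single ranking).
    """
    if avgs.k_points.size == 0:
        raise InvalidDataError("no per-replicate k estimates available")
    k_range = (int(avgs.k_points.min()), int(avgs.k_points.max()))
    k_max = k_range[1]
    if score == "both":
        called = (avgs.rank_coef <= k_max) & (avgs.rank_ppa <= k_max)
    elif score == "coef":
        called = avgs.rank_coef <= k_max
    elif score == "ppa":
        called = avgs.rank_ppa <= k_max
    else:
        raise InvalidDataError(f"unknown score {score!r}")
    return CalledSet(k_range=k_range, called=called, snp_ids=avgs.snp_ids)


def roc_curve(scores: np.ndarray, is_causal: np.ndarray) -> RocCurve:
    """TPR/FPR series over every distinct score cutoff, plus trapezoidal AUC.

    A SNP is called at cutoff c when its score >= c; cutoffs are the
    distinct observed scores in decreasing order preceded by a sentinel
    above the maximum (the (0, 0) point).  The trapezoidal AUC equals the
    causal/non-causal concordance probability with ties counted 1/2.
    """
    scores = np.asarray(scores, dtype=float)
    is_causal = np.asarray(is_causal, dtype=bool)
    if scores.shape != is_causal.shape:
        raise InvalidDataError("scores and truth flags differ in length")
    n_pos = int(is_causal.sum())
    n_neg = int((~is_causal).sum())
    if n_pos == 0 or n_neg == 0:
        raise UndefinedRocError(
            "ROC undefined: need at least one causal and one non-causal SNP"
        )
    order = np.argsort(-scores, kind="stable")
    s_sorted = scores[order]
    pos_sorted = is_causal[order].astype(np.int64)
    tp_cum = np.cumsum(pos_sorted)
    fp_cum = np.cumsum(1 - pos_sorted)
    # last index of each run of equal scores = counts at that cutoff
    last_of_run = np.flatnonzero(np.diff(s_sorted, append=-np.inf) != 0)
    cutoffs = np.concatenate([[np.inf], s_sorted[last_of_run]])
    tpr = np.concatenate([[0.0], tp_cum[last_of_run] / n_pos])
    fpr = np.concatenate([[0.0], fp_cum[last_of_run] / n_neg])
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(cutoffs=cutoffs, tpr=tpr, fpr=fpr, auc=auc)


def rare_subset_roc(
    scores: np.ndarray,
    truth: TruthTable | np.ndarray,
    maf: np.ndarray,
    threshold: float = 0.01,
) -> RocCurve:
    """ROC restricted to SNPs with MAF below ``threshold`` (default 1%).

    Both the TPR and FPR denominators count within-subset SNPs only.
    """
    is_causal = truth.is_causal if isinstance(truth, TruthTable) else np.asarray(truth, dtype=bool)
    scores = np.asarray(scores, dtype=float)
    maf = np.asarray(maf, dtype=float)
    if not (len(scores) == len(is_causal) == len(maf)):
        raise InvalidDataError("scores, truth and MAF differ in length")
    keep = maf < threshold
    if not keep.any():
        raise UndefinedRocError(f"no SNPs with MAF < {threshold}")
    return roc_curve(scores[keep], is_causal[keep])
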