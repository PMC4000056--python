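"""Rank-based evaluation of DEG-calling methods against prior gene sets.

Given per-experiment ranked gene lists (from any method) and, for each
experiment, a prior set of genes expected to be differential (e.g. ChIP-seq
targets of the perturbed transcription factor), the scaled ranks of the
prior genes are pooled across experiments.  If the prior genes are neither
preferentially significant nor insignificant, the pooled ranks are uniform
and their cumulative distribution D satisfies D(r) = r; the deviation
D(r) - r is examined against the Kolmogorov-Smirnov-style fluctuation scale
phi = 1/sqrt(n).  Per-experiment AUCs summarize the same information one
experiment at a time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .containers import RankedList
from .errors import EmptyIntersectionWarning, InputError

__all__ = [
    "ExperimentRanking",
    "EvalCurve",
    "pooled_set_ranks",
    "cumulative_deviation",
    "fluctuation_scale",
    "set_auc",
    "evaluate_rankings",
]


@dataclass
class ExperimentRanking:
    """An ordered gene list (most to least significant) for one experiment."""

    experiment_id: str
    gene_ids: list[str]

    def __post_init__(self) -> None:
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise InputError(
                f"experiment {self.experiment_id!r} ranks a gene more than once"
            )
        if len(self.gene_ids) < 2:
            raise InputError("a ranking needs at least 2 genes")
        p = len(self.gene_ids)
        self.scaled_ranks = np.arange(p) / (p - 1)
        self._rank_of = {g: r for g, r in zip(self.gene_ids, self.scaled_ranks)}

    @classmethod
    def from_ranked_list(cls, experiment_id: str, ranked: RankedList):
        return cls(experiment_id, list(ranked.gene_ids))

    def scaled_rank_of(self, gene_id: str) -> float:
        return self._rank_of[gene_id]

    def member_ranks(self, gene_set) -> np.ndarray:
        """Scaled ranks of the set's genes present in this ranking."""
        return np.array(
            [self._rank_of[g] for g in set(gene_set) if g in self._rank_of]
        )


@dataclass
class EvalCurve:
    """Pooled deviation-from-uniform curve with its fluctuation scale."""

    pooled: np.ndarray  # the multiset A of pooled scaled ranks
    grid: np.ndarray  # sorted unique rank values
    deviation: np.ndarray  # D(r) - r at the grid (right-continuous D)
    sup_deviation: float  # sup over both jump sides of |D(r) - r|, signed
    phi: float
    aucs: dict[str, float] | None = None

    @property
    def scaled_deviation(self) -> np.ndarray:
        """(D(r) - r)/phi: values >> 1 indicate significant non-uniformity."""
        return self.deviation / self.phi


def pooled_set_ranks(
    rankings: "list[ExperimentRanking]",
    prior_sets: "dict[str, set[str] | list[str]]",
) -> np.ndarray:
    """Multiset union over experiments of the prior genes' scaled ranks.

    Each experiment's prior set is intersected with that experiment's gene
    universe; empty intersections are skipped with a warning.
    """
    pooled: list[np.ndarray] = []
    for ranking in rankings:
        try:
            members = prior_sets[ranking.experiment_id]
        except KeyError:
            raise InputError(
                f"no prior set for experiment {ranking.experiment_id!r}"
            ) from None
        ranks = ranking.member_ranks(members)
        if ranks.size == 0:
            warnings.warn(
                f"prior set for {ranking.experiment_id!r} shares no genes with "
                "the ranking; skipped",
                EmptyIntersectionWarning,
                stacklevel=2,
            )
            continue
        pooled.append(ranks)
    if not pooled:
        raise InputError("every prior set had an empty intersection")
    return np.concatenate(pooled)


def cumulative_deviation(A: np.ndarray) -> EvalCurve:
    """Deviation of the ECDF of pooled ranks from the uniform expectation.

    D is the right-continuous empirical CDF of A at its sorted unique
    values; the sup deviation is taken over both sides of every jump (the
    value attaining the largest magnitude is returned with its sign).
    Positive deviation means prior genes concentrated at small ranks.
    """
    A = np.asarray(A, dtype=float)
    if A.size == 0:
        raise InputError("empty rank multiset")
    n = A.size
    grid, counts = np.unique(A, return_counts=True)
    D_right = np.cumsum(counts) / n
    D_left = D_right - counts / n
    dev_right = D_right - grid
    dev_left = D_left - grid
    both = np.concatenate([dev_right, dev_left])
    sup = float(both[np.argmax(np.abs(both))])
    return EvalCurve(
        pooled=A,
        grid=grid,
        deviation=dev_right,
        sup_deviation=sup,
        phi=fluctuation_scale(n),
    )


def fluctuation_scale(n: int) -> float:
    """phi = 1/sqrt(n), the Kolmogorov-Smirnov fluctuation scale for |A| = n."""
    if n < 1:
        raise InputError("n must be >= 1")
    return 1.0 / np.sqrt(n)


def set_auc(ranking: ExperimentRanking, prior_set) -> float:
    """Area under the ECDF of the prior set's scaled ranks over [0, 1].

    Closed form: 1 - mean(scaled ranks of the set's measured members).
    0.5 under uniform placement; approaches 1 when the set ranks first.
    Returns nan (with a warning) when the intersection is empty.
    """
    ranks = ranking.member_ranks(prior_set)
    if ranks.size == 0:
        warnings.warn(
            f"prior set shares no genes with {ranking.experiment_id!r}",
            EmptyIntersectionWarning,
            stacklevel=2,
        )
        return float("nan")
    return float(1.0 - ranks.mean())


def evaluate_rankings(
    rankings: "list[ExperimentRanking]",
    prior_sets: "dict[str, set[str] | list[str]]",
) -> EvalCurve:
    """Pooled deviation curve plus per-experiment AUCs, in one call."""
    A = pooled_set_ranks(rankings, prior_sets)
    curve = cumulative_deviation(A)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", EmptyIntersectionWarning)
        curve.aucs = {
            r.experiment_id: set_auc(r, prior_sets[r.experiment_id])
            for r in rankings
        }
    return curve
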