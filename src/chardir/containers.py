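"""Core in-memory containers for two-class expression analysis.

An :class:`ExpressionMatrix` holds log-scale expression values as genes x
samples, the dominant convention of on-disk expression matrices.  All linear
algebra internally treats samples as points in gene (p-dimensional) space.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import DesignError, InputError, SmallClassWarning

__all__ = [
    "ExpressionMatrix",
    "TwoClassDesign",
    "ShrinkageSpec",
    "DirectionResult",
    "RankedList",
]


@dataclass
class ExpressionMatrix:
    """Genes x samples matrix of continuous (log-scale) expression values.

    Parameters
    ----------
    values
        Real matrix of shape (p genes, N samples); no missing or non-finite
        entries are allowed.  Values are assumed already normalized and
        log-transformed; no transformation is applied.
    gene_ids
        p unique, non-empty gene identifiers.
    sample_ids
        N unique sample identifiers.
    """

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.values.ndim != 2:
            raise InputError("expression values must be a 2-D matrix")
        p, n = self.values.shape
        if p != len(self.gene_ids):
            raise InputError(
                f"{len(self.gene_ids)} gene ids for {p} matrix rows"
            )
        if n != len(self.sample_ids):
            raise InputError(
                f"{len(self.sample_ids)} sample ids for {n} matrix columns"
            )
        if p < 2:
            raise InputError("need at least 2 genes")
        if n < 4:
            raise InputError("need at least 4 samples (two classes of >= 2)")
        if any(not g for g in self.gene_ids):
            raise InputError("empty gene id")
        dupes = _duplicates(self.gene_ids)
        if dupes:
            raise InputError(f"duplicate gene ids: {sorted(dupes)}")
        dupes = _duplicates(self.sample_ids)
        if dupes:
            raise InputError(f"duplicate sample ids: {sorted(dupes)}")
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise InputError(
                f"non-finite expression value at gene "
                f"{self.gene_ids[bad[0]]!r}, sample {self.sample_ids[bad[1]]!r}"
            )

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def column_index(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise InputError(f"unknown sample id: {sample_id!r}") from None


@dataclass
class TwoClassDesign:
    """Control vs. perturbed assignment of sample ids.

    Classes must be disjoint with at least two samples each.  A warning (not
    an error) is emitted when a class has fewer than three replicates, since
    at least three repeats are needed for practical applications.
    """

    control_ids: list[str]
    perturbed_ids: list[str]

    def __post_init__(self) -> None:
        self.control_ids = [str(s) for s in self.control_ids]
        self.perturbed_ids = [str(s) for s in self.perturbed_ids]
        if len(self.control_ids) < 2 or len(self.perturbed_ids) < 2:
            raise DesignError("each class needs at least 2 samples")
        if _duplicates(self.control_ids) or _duplicates(self.perturbed_ids):
            raise DesignError("duplicated sample id within a class")
        overlap = set(self.control_ids) & set(self.perturbed_ids)
        if overlap:
            raise DesignError(f"classes overlap: {sorted(overlap)}")

    def indices(self, matrix: ExpressionMatrix) -> tuple[np.ndarray, np.ndarray]:
        """Column indices of the two classes in *matrix* (control, perturbed)."""
        if min(len(self.control_ids), len(self.perturbed_ids)) < 3:
            warnings.warn(
                "a class has fewer than 3 replicates; at least three repeats "
                "are recommended for practical applications",
                SmallClassWarning,
                stacklevel=2,
            )
        ctrl = np.array([matrix.column_index(s) for s in self.control_ids])
        pert = np.array([matrix.column_index(s) for s in self.perturbed_ids])
        return ctrl, pert


@dataclass(frozen=True)
class ShrinkageSpec:
    """Covariance shrinkage towards the scalar-variance identity target.

    gamma = 1 keeps the raw pooled covariance, gamma = 0 replaces it with
    sigma^2 I.  sigma^2 is the mean of the diagonal of the pooled covariance
    (``mean_diagonal`` rule), i.e. the average per-gene pooled variance.
    """

    gamma: float = 1.0
    sigma2_rule: str = "mean_diagonal"

    def __post_init__(self) -> None:
        if not 0.0 <= self.gamma <= 1.0:
            raise InputError(f"gamma must be in [0, 1], got {self.gamma}")
        if self.sigma2_rule != "mean_diagonal":
            raise InputError(f"unknown sigma2 rule: {self.sigma2_rule!r}")


def as_shrinkage(shrinkage: "ShrinkageSpec | float") -> ShrinkageSpec:
    if isinstance(shrinkage, ShrinkageSpec):
        return shrinkage
    return ShrinkageSpec(gamma=float(shrinkage))


@dataclass
class DirectionResult:
    """The unit characteristic direction: the normal to the LDA separating
    hyperplane between the two classes.

    ``components`` are direction cosines; ``squared`` components sum to one
    and quantify each gene's relative share of the differential expression.
    The sign convention orients the vector so that positive components
    correspond to genes up-regulated in the perturbed class.
    """

    gene_ids: list[str]
    components: np.ndarray
    gamma: float
    subspace_dim: int
    squared: np.ndarray = field(default=None)  # type: ignore[assignment]
    sign_convention: str = "positive = up in perturbed class"

    def __post_init__(self) -> None:
        self.components = np.asarray(self.components, dtype=float)
        if self.squared is None:
            self.squared = self.components**2
        total = float(self.squared.sum())
        if abs(total - 1.0) > 1e-10:
            raise InputError(
                f"squared components must sum to 1, got {total!r}"
            )

    @property
    def n_genes(self) -> int:
        return self.components.size

    def as_series(self):
        import pandas as pd

        return pd.Series(self.components, index=self.gene_ids, name="component")


@dataclass
class RankedList:
    """Genes ordered by descending squared direction component.

    Scaled rank r = (rank - 1)/(p - 1): 0 for the most significant gene,
    1 for the least significant.  Ties are broken lexicographically by gene
    id so that repeated runs produce identical output.
    """

    gene_ids: list[str]
    squared: np.ndarray
    signs: np.ndarray
    ranks: np.ndarray
    scaled_ranks: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.squared) > 0):
            raise InputError("squared values must be non-increasing")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def scaled_rank_of(self, gene_id: str) -> float:
        return float(self.scaled_ranks[self.gene_ids.index(gene_id)])


def _duplicates(items: list[str]) -> set[str]:
    seen: set[str] = set()
    dup: set[str] = set()
    for x in items:
        if x in seen:
            dup.add(x)
        seen.add(x)
    return dup
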