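"""Synthetic two-class expression data with known DEGs.

The generator emulates two well-established properties of genome-wide
expression data: many genes with few samples, and strong gene-gene
dependence that concentrates the data in a subspace of dimension D << p.
Samples are drawn from a D-dimensional normal distribution expressed in a
random orthonormal basis of gene space; the subspace variances decay as
e^-(i-1) (1 for the first basis direction, e^-1 for the second, ...),
mimicking a principal-component spectrum.  Both classes share the
covariance; the control mean is zero and the perturbed mean is the known
unit DEG vector m-hat scaled by Delta.

m-hat seeds the Gram-Schmidt construction of the basis but is stored as
the LAST basis column, so the differential shift lies along the
lowest-variance direction e^-(D-1).  This is the regime the multivariate
method exists for: a shift along a direction with little natural
variability is nearly invisible gene-by-gene yet cleanly separable after
whitening by the within-class covariance.  (Placing the shift on the
dominant-variance axis instead makes whitening suppress it and inverts
every method comparison; see the methods note.)
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .containers import ExpressionMatrix, TwoClassDesign
from .errors import DegenerateDataError, InputError

__all__ = [
    "SyntheticSpec",
    "SyntheticDataset",
    "deg_direction_vector",
    "orthonormal_basis",
    "generate_two_class",
    "as_two_class",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic generator.

    p: genes on the array; n_d: true DEGs (0 allowed, for null data);
    D: subspace dimension; N: samples per class; delta: magnitude of the
    mean shift between classes (0.3 gives a realistically hard problem,
    3.0 a visually obvious one).
    """

    p: int
    n_d: int
    D: int
    N: int
    delta: float
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.n_d <= self.p:
            raise InputError(f"n_d must be in [0, p], got {self.n_d}")
        if not 1 <= self.D <= self.p:
            raise InputError(f"D must be in [1, p], got {self.D}")
        if self.N < 2:
            raise InputError("N (samples per class) must be >= 2")
        if self.delta < 0:
            raise InputError("delta must be >= 0")


@dataclass
class SyntheticDataset:
    """Generated control/perturbed matrices plus the generating truth."""

    control: np.ndarray  # p x N
    perturbed: np.ndarray  # p x N
    m_hat: np.ndarray  # unit p-vector, n_d nonzero entries (zero if n_d = 0)
    basis: np.ndarray  # p x D orthonormal columns in descending-variance
    # (principal) order; the last column spans m_hat
    spec: SyntheticSpec

    @property
    def true_degs(self) -> list[int]:
        """Indices of the genes carrying the mean shift (support of m_hat)."""
        return list(np.flatnonzero(self.m_hat))


def deg_direction_vector(
    p: int,
    n_d: int,
    seed: "int | np.random.Generator | None" = None,
    support: Sequence[int] | None = None,
) -> np.ndarray:
    """Random unit p-vector with exactly n_d nonzero components.

    Positions are chosen uniformly without replacement (or taken from
    *support* when given, e.g. to place the signal on specific genes);
    nonzero entries are standard normal before normalization, so up/down
    signs are symmetric.  n_d = 0 returns the zero vector (null data).
    """
    if n_d > p:
        raise InputError(f"n_d={n_d} exceeds p={p}")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    m = np.zeros(p)
    if n_d == 0:
        return m
    if support is not None:
        idx = np.asarray(list(support), dtype=int)
        if idx.size != n_d or np.unique(idx).size != n_d:
            raise InputError("support must list n_d distinct gene indices")
    else:
        idx = rng.choice(p, size=n_d, replace=False)
    vals = rng.standard_normal(n_d)
    while np.linalg.norm(vals) == 0.0:  # pragma: no cover - measure zero
        vals = rng.standard_normal(n_d)
    m[idx] = vals / np.linalg.norm(vals)
    return m


def orthonormal_basis(
    m_hat: np.ndarray,
    D: int,
    seed: "int | np.random.Generator | None" = None,
    max_retries: int = 100,
) -> np.ndarray:
    """Gram-Schmidt basis of an isotropic random D-subspace containing m_hat.

    The (normalized) DEG vector seeds the basis as its first vector; each
    subsequent vector is an isotropic standard-normal draw minus its
    projection onto the vectors already accepted, then normalized.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    p = m_hat.size
    if D < 1 or D > p:
        raise InputError(f"D must be in [1, p], got {D}")
    norm = np.linalg.norm(m_hat)
    if norm == 0.0:
        seed_vec = rng.standard_normal(p)
        seed_vec /= np.linalg.norm(seed_vec)
    else:
        seed_vec = m_hat / norm
    basis = [seed_vec]
    while len(basis) < D:
        for attempt in range(max_retries):
            b = rng.standard_normal(p)
            for prev in basis:  # subtract the part parallel to the accepted span
                b -= (b @ prev) * prev
            n = np.linalg.norm(b)
            if n > 1e-10:
                basis.append(b / n)
                break
        else:
            raise DegenerateDataError(
                f"could not draw an independent basis vector in {max_retries} tries"
            )
    return np.column_stack(basis)


def generate_two_class(spec: SyntheticSpec) -> SyntheticDataset:
    """Draw a control and a perturbed sample matrix under *spec*.

    Subspace coordinates are independent normals with variances
    e^0, e^-1, ..., e^-(D-1) along the basis columns; both classes share
    them.  The perturbed class mean is delta * m_hat in gene space (no
    shift when n_d = 0), i.e. the shift rides the last, lowest-variance
    basis direction.
    """
    rng = np.random.default_rng(spec.seed)
    m_hat = deg_direction_vector(spec.p, spec.n_d, rng)
    # Gram-Schmidt is seeded by m_hat; reversing the columns puts the basis
    # in principal (descending-variance) order with m_hat last.
    basis = orthonormal_basis(m_hat, spec.D, rng)[:, ::-1]
    std = np.exp(-0.5 * np.arange(spec.D))  # variance e^-(i-1), i = 1..D
    Zc = rng.standard_normal((spec.D, spec.N)) * std[:, None]
    Zp = rng.standard_normal((spec.D, spec.N)) * std[:, None]
    control = basis @ Zc
    perturbed = basis @ Zp + spec.delta * m_hat[:, None]
    return SyntheticDataset(
        control=control, perturbed=perturbed, m_hat=m_hat, basis=basis, spec=spec
    )


def as_two_class(
    dataset: SyntheticDataset,
) -> tuple[ExpressionMatrix, TwoClassDesign]:
    """Package a synthetic dataset as an ExpressionMatrix + design.

    Genes are named gene1..genep; samples control_1.. / perturbed_1.. .
    """
    p, n = dataset.control.shape
    gene_ids = [f"gene{i + 1}" for i in range(p)]
    ctrl_ids = [f"control_{j + 1}" for j in range(n)]
    pert_ids = [f"perturbed_{j + 1}" for j in range(dataset.perturbed.shape[1])]
    X = ExpressionMatrix(
        values=np.hstack([dataset.control, dataset.perturbed]),
        gene_ids=gene_ids,
        sample_ids=ctrl_ids + pert_ids,
    )
    return X, TwoClassDesign(control_ids=ctrl_ids, perturbed_ids=pert_ids)
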