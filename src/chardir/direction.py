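"""Estimation of the characteristic direction.

The characteristic direction is the normal to the separating hyperplane of
two-class linear discriminant analysis,

    b = Sigma_gamma^{-1} (mu_perturbed - mu_control),

normalized to unit length, with the pooled within-class covariance shrunk
towards the scalar variance,

    Sigma_gamma = gamma * Sigma_hat + (1 - gamma) * sigma^2 * I.

Because p >> N, the p x p system is never formed: b lies in the invariant
subspace V spanned by the within-class-centered samples together with the
mean difference (dimension q <= N - 1).  Sigma_gamma is block diagonal with
respect to V and its orthogonal complement (where it acts as the scalar
(1 - gamma) sigma^2), so

    b = V (V^T Sigma_gamma V)^{-1} V^T dmu

is exact, not an approximation.  At gamma = 1 the restricted covariance may
be singular and the Moore-Penrose pseudo-inverse is used.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import (
    DirectionResult,
    ExpressionMatrix,
    RankedList,
    ShrinkageSpec,
    TwoClassDesign,
    as_shrinkage,
)
from .errors import DegenerateDataError, ZeroDirectionError

__all__ = [
    "class_means",
    "pooled_within_covariance",
    "shrink_covariance",
    "characteristic_direction",
    "rank_genes",
    "CovarianceOperator",
    "ShrunkCovariance",
]

#: relative singular-value threshold below which subspace components are dropped
_SV_RTOL = 1e-12


def class_means(
    X: ExpressionMatrix, design: TwoClassDesign
) -> tuple[np.ndarray, np.ndarray]:
    """Arithmetic per-gene means of the control and perturbed sample columns."""
    idx_c, idx_p = design.indices(X)
    return X.values[:, idx_c].mean(axis=1), X.values[:, idx_p].mean(axis=1)


class CovarianceOperator:
    """Pooled within-class covariance Sigma_hat in implicit (factored) form.

    Stores the p x (N_c + N_p) matrix of within-class-centered samples C and
    exposes Sigma_hat v = C (C^T v) / (N - 2) without materializing p x p.
    """

    def __init__(self, centered: np.ndarray, ddof: int):
        self.centered = centered
        self.ddof = ddof

    @property
    def p(self) -> int:
        return self.centered.shape[0]

    def matvec(self, v: np.ndarray) -> np.ndarray:
        return self.centered @ (self.centered.T @ v) / self.ddof

    __matmul__ = matvec

    def diagonal_mean(self) -> float:
        """sigma^2 under the mean_diagonal rule: average per-gene pooled variance."""
        return float((self.centered**2).sum()) / (self.p * self.ddof)

    def dense(self) -> np.ndarray:
        """Materialize the full p x p matrix (small p only)."""
        return self.centered @ self.centered.T / self.ddof


class ShrunkCovariance:
    """Operator form of Sigma_gamma = gamma Sigma_hat + (1 - gamma) sigma^2 I."""

    def __init__(self, base: CovarianceOperator, gamma: float, sigma2: float):
        self.base = base
        self.gamma = gamma
        self.sigma2 = sigma2

    def matvec(self, v: np.ndarray) -> np.ndarray:
        out = (1.0 - self.gamma) * self.sigma2 * v
        if self.gamma > 0.0:
            out = out + self.gamma * self.base.matvec(v)
        return out

    __matmul__ = matvec

    def dense(self) -> np.ndarray:
        return self.gamma * self.base.dense() + (1.0 - self.gamma) * self.sigma2 * np.eye(
            self.base.p
        )


def pooled_within_covariance(
    X: ExpressionMatrix, design: TwoClassDesign
) -> CovarianceOperator:
    """Pooled within-class covariance (denominator N - 2, two classes)."""
    idx_c, idx_p = design.indices(X)
    C = _centered_columns(X.values, idx_c, idx_p)
    return CovarianceOperator(C, ddof=len(idx_c) + len(idx_p) - 2)


def shrink_covariance(
    Sigma_hat: CovarianceOperator, spec: ShrinkageSpec | float = ShrinkageSpec()
) -> ShrunkCovariance:
    """Shrink the pooled covariance towards the scalar-variance target."""
    spec = as_shrinkage(spec)
    sigma2 = Sigma_hat.diagonal_mean()
    if sigma2 == 0.0 and spec.gamma < 1.0:
        raise DegenerateDataError(
            "all genes have zero pooled variance; the scalar target is zero"
        )
    return ShrunkCovariance(Sigma_hat, spec.gamma, sigma2)


@dataclass
class _SubspaceFit:
    """Everything needed to apply Sigma_gamma^{-1} exactly at large p."""

    V: np.ndarray  # p x q orthonormal basis of span(centered samples, dmu)
    A: np.ndarray  # q x q restricted shrunk covariance V^T Sigma_gamma V
    A_pinv: np.ndarray  # pseudo-inverse of A (used for gamma = 1)
    sigma2: float
    gamma: float
    dmu: np.ndarray
    n_control: int
    n_perturbed: int

    @property
    def q(self) -> int:
        return self.V.shape[1]

    def solve(self, v: np.ndarray) -> np.ndarray:
        """Sigma_gamma^{-1} v for a p-vector v (pseudo-inverse at gamma = 1)."""
        z = self.V.T @ v
        if self.gamma == 1.0:
            return self.V @ (self.A_pinv @ z)
        y = np.linalg.solve(self.A, z)
        resid = v - self.V @ z
        return self.V @ y + resid / ((1.0 - self.gamma) * self.sigma2)


def _centered_columns(
    values: np.ndarray, idx_c: np.ndarray, idx_p: np.ndarray
) -> np.ndarray:
    Xc = values[:, idx_c]
    Xp = values[:, idx_p]
    return np.hstack(
        [Xc - Xc.mean(axis=1, keepdims=True), Xp - Xp.mean(axis=1, keepdims=True)]
    )


def _fit_subspace(
    X: ExpressionMatrix, design: TwoClassDesign, spec: ShrinkageSpec
) -> _SubspaceFit:
    idx_c, idx_p = design.indices(X)
    n_c, n_p = len(idx_c), len(idx_p)
    ddof = n_c + n_p - 2
    C = _centered_columns(X.values, idx_c, idx_p)
    dmu = X.values[:, idx_p].mean(axis=1) - X.values[:, idx_c].mean(axis=1)
    sigma2 = float((C**2).sum()) / (X.n_genes * ddof)
    if sigma2 == 0.0 and spec.gamma < 1.0:
        raise DegenerateDataError(
            "all genes have zero pooled variance; cannot shrink to a zero target"
        )

    M = np.hstack([C, dmu[:, None]])
    U, s, _ = np.linalg.svd(M, full_matrices=False)
    if s.size == 0 or s[0] == 0.0:
        raise DegenerateDataError("no variance and no mean difference in the data")
    V = U[:, s > _SV_RTOL * s[0]]

    G = V.T @ C  # q x m; exact since span(C) is inside span(V)
    A = spec.gamma * (G @ G.T) / ddof
    if spec.gamma < 1.0:
        A[np.diag_indices_from(A)] += (1.0 - spec.gamma) * sigma2
        A_pinv = None
    else:
        A_pinv = np.linalg.pinv(A, rcond=1e-12, hermitian=True)
    return _SubspaceFit(
        V=V,
        A=A,
        A_pinv=A_pinv,
        sigma2=sigma2,
        gamma=spec.gamma,
        dmu=dmu,
        n_control=n_c,
        n_perturbed=n_p,
    )


def characteristic_direction(
    X: ExpressionMatrix,
    design: TwoClassDesign,
    shrinkage: ShrinkageSpec | float = ShrinkageSpec(),
) -> DirectionResult:
    """Estimate the unit characteristic direction b-hat.

    Parameters
    ----------
    X
        Expression matrix (genes x samples, log scale).
    design
        Two-class sample assignment; each class needs >= 2 samples.
    shrinkage
        A :class:`ShrinkageSpec` or a plain gamma in [0, 1].  gamma = 0
        reduces b-hat to the normalized class-mean difference; gamma = 1
        (default) uses the unshrunk pooled covariance with a pseudo-inverse.

    Returns
    -------
    DirectionResult
        Unit vector whose squared components sum to one; positive components
        mark genes up in the perturbed class (the hyperplane normal is
        defined only up to sign, so the orientation b-hat . dmu >= 0 is
        fixed by convention).
    """
    spec = as_shrinkage(shrinkage)
    fit = _fit_subspace(X, design, spec)
    if not np.any(fit.dmu):
        raise ZeroDirectionError("class means are identical: no differential signal")
    b = fit.solve(fit.dmu)
    norm = np.linalg.norm(b)
    if norm == 0.0:
        raise DegenerateDataError(
            "the covariance pseudo-inverse annihilates the mean difference; "
            "use gamma < 1"
        )
    if b @ fit.dmu < 0:
        b = -b
    b = b / np.linalg.norm(b)
    return DirectionResult(
        gene_ids=list(X.gene_ids),
        components=b,
        gamma=spec.gamma,
        subspace_dim=fit.q,
    )


def rank_genes(direction: DirectionResult) -> RankedList:
    """Order genes by descending squared component (descending significance).

    Ties are broken by lexicographic gene id.  Scaled ranks run from 0 (most
    significant gene) to 1 (least significant gene).
    """
    sq = direction.squared
    ids = np.asarray(direction.gene_ids)
    order = np.lexsort((ids, -sq))
    p = sq.size
    ranks = np.arange(1, p + 1)
    return RankedList(
        gene_ids=[direction.gene_ids[i] for i in order],
        squared=sq[order],
        signs=np.sign(direction.components[order]).astype(int),
        ranks=ranks,
        scaled_ranks=(ranks - 1) / (p - 1),
    )
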