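"""Thresholding the characteristic direction: null curve, ratio, DEG calls.

The ranked squared components of the observed direction are compared with
the mean sorted squared components of directions computed from no-signal
mean differences.  Each null draw replaces the two class means with
multivariate-t variates (N_k - 1 degrees of freedom, scale Sigma_gamma/N_k;
the location cancels in the difference), pushes the difference through the
same regularized inverse as the observed direction, unit-normalizes, squares
and sorts.  The elementwise mean over repetitions is the null curve.

DEG calls come in two modes:

* ``conservative`` — accept every sorted position whose ratio
  b^2 / <b_null^2> exceeds one.
* ``s_peak`` — form the cumulative share of the ratio, measure its
  perpendicular distance s to the diagonal, and cut at the peak of s; the
  peak height (a fraction of unity) indicates whether there is any
  differential expression at all.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from .containers import (
    DirectionResult,
    ExpressionMatrix,
    ShrinkageSpec,
    TwoClassDesign,
    as_shrinkage,
)
from .direction import _fit_subspace, rank_genes
from .errors import InputError

__all__ = [
    "NullComponentCurve",
    "SignificanceResult",
    "null_component_curve",
    "ratio_curve",
    "call_degs",
]


@dataclass
class NullComponentCurve:
    """Mean sorted squared null direction components <b_null^2>."""

    curve: np.ndarray  # non-increasing, sums to 1
    reps: int
    seed: int | None
    gamma: float

    def __post_init__(self) -> None:
        self.curve = np.asarray(self.curve, dtype=float)
        if np.any(self.curve < 0) or np.any(np.diff(self.curve) > 1e-15):
            raise InputError("null curve must be non-negative and non-increasing")
        if abs(self.curve.sum() - 1.0) > 1e-10:
            raise InputError("null curve must sum to 1")


def _psd_sqrt(A: np.ndarray) -> np.ndarray:
    """Symmetric factor L with L L^T = A for a PSD matrix (eigenvalue clip)."""
    w, U = np.linalg.eigh(A)
    w = np.clip(w, 0.0, None)
    return U * np.sqrt(w)


def null_component_curve(
    X: ExpressionMatrix,
    design: TwoClassDesign,
    shrinkage: ShrinkageSpec | float = ShrinkageSpec(),
    reps: int = 100,
    seed: int | None = None,
) -> NullComponentCurve:
    """Simulate the null distribution of ranked squared components.

    Uses the same gamma, the same scalar variance and the same subspace
    machinery as :func:`chardir.characteristic_direction` on the observed
    data, so that the observed and null curves are directly comparable.
    The default of 100 repetitions matches the thresholding algorithm's
    stated repetition count.
    """
    if reps < 1:
        raise InputError("reps must be >= 1")
    spec = as_shrinkage(shrinkage)
    fit = _fit_subspace(X, design, spec)
    rng = np.random.default_rng(seed)
    p, q = X.n_genes, fit.q
    gamma, sigma2 = spec.gamma, fit.sigma2

    if gamma == 1.0:
        # Draws with scale Sigma_hat live inside the data subspace exactly.
        L = _psd_sqrt(fit.A)
        solve = lambda z: fit.A_pinv @ z  # noqa: E731
    else:
        A_chol = cho_factor(fit.A)
        # V^T Sigma_gamma V has sqrt factor L; the orthogonal complement is
        # isotropic with variance (1 - gamma) sigma2.
        L = _psd_sqrt(fit.A)
        solve = lambda z: cho_solve(A_chol, z)  # noqa: E731
    scalar = (1.0 - gamma) * sigma2

    def draw_mean(n: int) -> tuple[np.ndarray, np.ndarray]:
        """One multivariate-t class-mean draw, df = n - 1, scale Sigma_gamma/n.

        Returned split as (subspace coordinates, orthogonal p-space part).
        """
        t_scale = np.sqrt(rng.chisquare(n - 1) / (n - 1))
        z_q = L @ rng.standard_normal(q) / np.sqrt(n) / t_scale
        if scalar > 0.0:
            w = rng.standard_normal(p)
            w_perp = (w - fit.V @ (fit.V.T @ w)) * np.sqrt(scalar / n) / t_scale
        else:
            w_perp = None
        return z_q, w_perp

    acc = np.zeros(p)
    for _ in range(reps):
        z1, w1 = draw_mean(fit.n_control)
        z2, w2 = draw_mean(fit.n_perturbed)
        dz = z1 - z2
        b = fit.V @ solve(dz)
        if w1 is not None:
            b = b + (w1 - w2) / scalar
        norm = np.linalg.norm(b)
        if norm == 0.0:  # pragma: no cover - zero-probability event
            continue
        sq = (b / norm) ** 2
        sq.sort()
        acc += sq[::-1]
    curve = acc / reps
    curve /= curve.sum()  # remove rounding drift; each draw already sums to 1
    return NullComponentCurve(curve=curve, reps=reps, seed=seed, gamma=gamma)


def ratio_curve(
    direction: DirectionResult, null_curve: NullComponentCurve
) -> np.ndarray:
    """Elementwise ratio of sorted observed b^2 to the null curve.

    Positions where the null entry is zero map to +inf, flagged distinctly
    rather than raising.
    """
    sorted_sq = np.sort(direction.squared)[::-1]
    null = null_curve.curve
    if sorted_sq.size != null.size:
        raise InputError(
            f"direction has {sorted_sq.size} genes, null curve {null.size}"
        )
    with np.errstate(divide="ignore"):
        return np.where(null > 0.0, sorted_sq / np.where(null > 0, null, 1.0), np.inf)


@dataclass
class SignificanceResult:
    """Thresholding output: ratio/cumulative/s curves and the called DEG set."""

    ratio: np.ndarray
    cumulative: np.ndarray
    s: np.ndarray
    s_peak: float
    s_peak_index: int  # number of genes at/before the peak (1-based position)
    conservative_genes: list[str]
    s_peak_genes: list[str]
    significant: bool
    mode: str
    tau: float
    degs: list[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.degs is None:
            self.degs = (
                self.conservative_genes
                if self.mode == "conservative"
                else self.s_peak_genes
            )


def call_degs(
    direction: DirectionResult,
    null_curve: NullComponentCurve,
    mode: str = "s_peak",
    s_significance_tau: float = 0.1,
) -> SignificanceResult:
    """Call a discrete DEG set from the observed and null component curves.

    Parameters
    ----------
    mode
        ``"conservative"`` accepts genes at sorted positions with ratio > 1;
        ``"s_peak"`` cuts at the peak of the perpendicular distance between
        the cumulative ratio share and the diagonal.
    s_significance_tau
        Heuristic threshold on the s-peak height (a "significant fraction of
        unity") below which the dataset is flagged as having no credible
        differential expression.
    """
    if mode not in ("conservative", "s_peak"):
        raise InputError(f"unknown mode: {mode!r}")
    ranked = rank_genes(direction)
    ratio = ratio_curve(direction, null_curve)
    if not np.all(np.isfinite(ratio)):
        raise InputError("ratio curve contains non-finite entries")
    p = ratio.size
    cumulative = np.cumsum(ratio) / ratio.sum()
    x = np.arange(1, p + 1) / p
    s = (cumulative - x) / np.sqrt(2.0)
    peak = int(np.argmax(s))
    s_peak = float(s[peak])
    conservative = [g for g, r in zip(ranked.gene_ids, ratio) if r > 1.0]
    return SignificanceResult(
        ratio=ratio,
        cumulative=cumulative,
        s=s,
        s_peak=s_peak,
        s_peak_index=peak + 1,
        conservative_genes=conservative,
        s_peak_genes=ranked.gene_ids[: peak + 1],
        significant=s_peak >= s_significance_tau,
        mode=mode,
        tau=s_significance_tau,
    )
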