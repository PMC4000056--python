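"""Principal-angle gene-set enrichment and direction similarity.

A gene set spans a coordinate subspace of expression space.  The first
principal angle between the characteristic direction (a line) and that
subspace has cos^2(theta) equal to the squared norm of the direction's
projection onto the set's coordinates, i.e. the sum of the squared
components over the set's genes.  Under the isotropic null — the direction
uniform on the unit sphere in p dimensions — that projection follows an
exact Beta(k/2, (p-k)/2) law for a set of size k, which yields an analytic
upper-tail p-value; Benjamini-Hochberg controls the FDR across a library.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import beta as beta_dist
from statsmodels.stats.multitest import multipletests

from .containers import DirectionResult
from .direction import rank_genes
from .errors import EmptyIntersectionWarning, InputError

__all__ = [
    "GeneSetLibrary",
    "EnrichmentResult",
    "principal_angle",
    "enrichment_pvalue",
    "enrich_library",
    "direction_similarity",
]


@dataclass
class GeneSetLibrary:
    """Named gene sets (typically read from a GMT file)."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] | None = None

    def __post_init__(self) -> None:
        if self.descriptions is None:
            self.descriptions = {name: "" for name in self.sets}
        for name, members in self.sets.items():
            if not members:
                raise InputError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())


@dataclass
class EnrichmentResult:
    """Per-set principal-angle enrichment outcome."""

    name: str
    k: int  # members measured on the platform
    cos2: float  # squared cosine of the first principal angle
    angle: float  # radians, in [0, pi/2]
    p_value: float | None
    q_value: float | None  # Benjamini-Hochberg adjusted
    direction_score: float  # mean signed component over the set (up/down)
    mean_scaled_rank: float
    significant: bool = False


def principal_angle(
    direction: DirectionResult, gene_set: "set[str] | list[str]"
) -> tuple[float, float, int]:
    """First principal angle between the direction and a gene-set subspace.

    Returns (cos^2 theta, theta, k) where k is the size of the set's
    intersection with the direction's gene universe.  For a coordinate-axis
    subspace the first principal angle of a line reduces exactly to the
    projection norm: cos^2 = sum of squared components over the set.  An
    empty intersection returns (nan, nan, 0) with a warning.
    """
    members = set(gene_set)
    mask = np.fromiter(
        (g in members for g in direction.gene_ids), dtype=bool, count=direction.n_genes
    )
    k = int(mask.sum())
    if k == 0:
        warnings.warn(
            "gene set shares no genes with the measured universe",
            EmptyIntersectionWarning,
            stacklevel=2,
        )
        return math.nan, math.nan, 0
    cos2 = float(direction.squared[mask].sum())
    cos2 = min(max(cos2, 0.0), 1.0)
    return cos2, math.acos(math.sqrt(cos2)), k


def enrichment_pvalue(cos2: float, k: int, p: int) -> float:
    """Upper-tail probability of cos^2 theta under the isotropic null.

    For a direction uniform on the p-sphere, the squared projection onto a
    fixed k-dimensional coordinate subspace is Beta(k/2, (p-k)/2).
    """
    if k < 1:
        raise InputError("k must be >= 1 (empty sets have no p-value)")
    if k > p:
        raise InputError(f"k={k} exceeds p={p}")
    if k == p:
        return 1.0  # the angle is identically zero
    return float(beta_dist.sf(cos2, k / 2.0, (p - k) / 2.0))


def enrich_library(
    direction: DirectionResult,
    library: GeneSetLibrary,
    fdr: float = 0.10,
) -> list[EnrichmentResult]:
    """Principal-angle enrichment of every set in a library, BH-adjusted.

    Sets with no measured members are reported with k = 0 and no p-value
    and are excluded from the adjustment.  Results are sorted by p-value;
    each significant set carries an up/down label through the sign of its
    mean signed component (``direction_score``).
    """
    if len(library) == 0:
        raise InputError("gene-set library is empty")
    p = direction.n_genes
    ranked = rank_genes(direction)
    scaled = {g: r for g, r in zip(ranked.gene_ids, ranked.scaled_ranks)}
    comp = {g: c for g, c in zip(direction.gene_ids, direction.components)}

    results: list[EnrichmentResult] = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", EmptyIntersectionWarning)
        for name, members in library:
            cos2, angle, k = principal_angle(direction, members)
            if k == 0:
                results.append(
                    EnrichmentResult(name, 0, math.nan, math.nan, None, None,
                                     math.nan, math.nan)
                )
                continue
            measured = [g for g in set(members) if g in comp]
            results.append(
                EnrichmentResult(
                    name=name,
                    k=k,
                    cos2=cos2,
                    angle=angle,
                    p_value=enrichment_pvalue(cos2, k, p),
                    q_value=None,
                    direction_score=float(np.mean([comp[g] for g in measured])),
                    mean_scaled_rank=float(np.mean([scaled[g] for g in measured])),
                )
            )
    tested = [r for r in results if r.p_value is not None]
    if not tested:
        raise InputError("no gene set overlaps the measured gene universe")
    reject, qvals, _, _ = multipletests(
        [r.p_value for r in tested], alpha=fdr, method="fdr_bh"
    )
    for r, rej, q in zip(tested, reject, qvals):
        r.q_value = float(q)
        r.significant = bool(rej)
    results.sort(key=lambda r: (r.p_value is None, r.p_value))
    return results


def direction_similarity(
    d1: DirectionResult, d2: DirectionResult
) -> tuple[float, float]:
    """Cosine and angle between two characteristic directions.

    Both directions are restricted to the intersection of their gene
    universes and renormalized to unit length before the dot product.
    """
    c1 = dict(zip(d1.gene_ids, d1.components))
    c2 = dict(zip(d2.gene_ids, d2.components))
    common = [g for g in d1.gene_ids if g in c2]
    if len(common) < 2:
        raise InputError("gene universes share fewer than 2 genes")
    v1 = np.array([c1[g] for g in common])
    v2 = np.array([c2[g] for g in common])
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 == 0.0 or n2 == 0.0:
        raise InputError("a direction vanishes on the shared gene universe")
    cosine = float(np.clip(v1 @ v2 / (n1 * n2), -1.0, 1.0))
    return cosine, math.acos(cosine)
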