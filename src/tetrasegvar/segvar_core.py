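"""Closed-form additive segregation variance for autotetraploid crosses.

For a bi-parental cross P1 x P2 the additive genotypic variance among F1
progeny is the quadratic form

    sigma^2_{P1xP2} = beta' V beta,

where beta holds the additive marker effects and V is the progeny dosage
covariance matrix.  Under bivalent meiosis each element of V has a closed
form in the parental haplotypes:

  off-diagonal (loci A, B at recombination rate c):
    cov(xA, xB) = { 1/3 sum_h (A_h^P1 B_h^P1 + A_h^P2 B_h^P2)
                    - 1/12 (xA^P1 xB^P1 + xA^P2 xB^P2) } * (1 - 2c)

  diagonal:
    var(xA) = 1/3 (xA^P1 + xA^P2) - 1/12 ((xA^P1)^2 + (xA^P2)^2)

Loci on different chromosomes have c = 0.5 and contribute nothing, so V is
block-diagonal by chromosome and is never materialised in full.  Without
phased haplotypes the linkage terms are unavailable and V is taken diagonal
(dosages suffice).  A double-reduction variant replaces the attenuation
factor by (1 - 4c/3)(1 + 2 alpha_A) under complete quadrivalent pairing
with locus order centromere-A-B.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable

import numpy as np

from .data_model import (
    AlignedDataset,
    CrossPrediction,
    DosageGenotype,
    GeneticMap,
    MarkerEffects,
    PhasedParent,
)

__all__ = [
    "haldane",
    "haldane_inverse",
    "cov_phased",
    "var_locus",
    "cov_double_reduction",
    "ChromCovarianceBlock",
    "build_cov_blocks",
    "segregation_variance",
    "predict_cross",
    "MAX_ALPHA",
]

logger = logging.getLogger(__name__)

#: Theoretical maximum double-reduction rate under complete quadrivalents.
MAX_ALPHA = 1.0 / 6.0

# Round-off tolerance: negative quadratic-form results larger than this are
# treated as genuine errors rather than floating-point noise.
_NEG_TOL = 1e-9


def haldane(d):
    """Haldane map function: recombination rate c = 0.5 (1 - exp(-2 d)).

    ``d`` is a map distance in Morgan (scalar or array), assuming no
    crossover interference.
    """
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("map distance must be >= 0")
    c = 0.5 * (1.0 - np.exp(-2.0 * d))
    return float(c) if c.ndim == 0 else c


def haldane_inverse(c):
    """Map distance in Morgan for recombination rate c < 0.5."""
    c = np.asarray(c, dtype=float)
    if np.any(c < 0) or np.any(c >= 0.5):
        raise ValueError("recombination rate must be in [0, 0.5)")
    d = -0.5 * np.log(1.0 - 2.0 * c)
    return float(d) if d.ndim == 0 else d


def _check_c(c: float) -> None:
    if not 0.0 <= c <= 0.5:
        raise ValueError(f"recombination rate must be in [0, 0.5], got {c}")


def _bracket(p1: PhasedParent, p2: PhasedParent, locus_a: int, locus_b: int) -> float:
    """The linkage bracket: 1/3 sum_h(A_h B_h) per parent minus 1/12 xA xB."""
    total = 0.0
    for par in (p1, p2):
        a = par.haplotypes[:, locus_a].astype(float)
        b = par.haplotypes[:, locus_b].astype(float)
        total += (a * b).sum() / 3.0 - a.sum() * b.sum() / 12.0
    return total


def cov_phased(
    p1: PhasedParent, p2: PhasedParent, locus_a: int, locus_b: int, c: float
) -> float:
    """Closed-form progeny dosage covariance between two linked loci."""
    _check_c(c)
    return _bracket(p1, p2, locus_a, locus_b) * (1.0 - 2.0 * c)


def var_locus(x1: int, x2: int) -> float:
    """Progeny dosage variance at one locus from the parental dosages."""
    for x in (x1, x2):
        if not 0 <= x <= 4:
            raise ValueError(f"dosage must be in 0..4, got {x}")
    return (x1 + x2) / 3.0 - (x1**2 + x2**2) / 12.0


def cov_double_reduction(
    p1: PhasedParent,
    p2: PhasedParent,
    locus_a: int,
    locus_b: int,
    c: float,
    alpha_a: float,
) -> float:
    """Two-locus covariance allowing double reduction at locus A.

    Assumes complete quadrivalent pairing and locus order centromere-A-B;
    ``alpha_a`` is the double-reduction rate at the locus proximal to the
    centromere (bounded by 1/6, the complete-quadrivalent maximum).  Note
    that at alpha_a = 0 this does NOT reduce to the bivalent formula for
    c > 0: the pairing model differs, and so does the attenuation factor.
    """
    _check_c(c)
    if not 0.0 <= alpha_a <= MAX_ALPHA:
        raise ValueError(
            f"double-reduction rate must be in [0, {MAX_ALPHA:.4f}], got {alpha_a}"
        )
    factor = (1.0 - 4.0 * c / 3.0) * (1.0 + 2.0 * alpha_a)
    return _bracket(p1, p2, locus_a, locus_b) * factor


@dataclass
class ChromCovarianceBlock:
    """Progeny dosage covariance matrix of the markers on one chromosome."""

    chromosome: str
    matrix: np.ndarray  # (q, q) symmetric
    marker_index: np.ndarray  # map-order indices into the aligned dataset


def _phased_block(
    p1: PhasedParent, p2: PhasedParent, idx: np.ndarray, pos: np.ndarray
) -> np.ndarray:
    """Vectorised phased covariance block for one chromosome.

    The bracket term is additive over parents: for parent P with haplotype
    matrix H (4 x q), sum_h A_h B_h = (H'H)_{AB} and xA xB = outer(x, x),
    so the bracket matrix is (H1'H1 + H2'H2)/3 - (outer(x1,x1) +
    outer(x2,x2))/12.  The attenuation (1 - 2c) = exp(-2 |dA - dB|) under
    Haldane; its diagonal is 1, and the bracket diagonal equals the
    single-locus variance since A_h^2 = A_h.
    """
    bracket = np.zeros((len(idx), len(idx)))
    for par in (p1, p2):
        h = par.haplotypes[:, idx].astype(float)
        x = h.sum(axis=0)
        bracket += h.T @ h / 3.0 - np.outer(x, x) / 12.0
    atten = np.exp(-2.0 * np.abs(pos[:, None] - pos[None, :]))
    return bracket * atten


def build_cov_blocks(
    p1: PhasedParent | DosageGenotype,
    p2: PhasedParent | DosageGenotype,
    genetic_map: GeneticMap,
    mode: str = "phased",
    alpha: float | None = None,
) -> list[ChromCovarianceBlock]:
    """Per-chromosome progeny covariance blocks for one cross.

    ``mode`` is one of ``phased`` (linkage terms from haplotypes),
    ``unphased`` (diagonal blocks from dosages only) or
    ``double_reduction`` (phased brackets with the (1 - 4c/3)(1 + 2 alpha)
    attenuation; requires ``alpha``).  Loci on different chromosomes have
    recombination rate 0.5 and zero covariance, so only within-chromosome
    blocks exist.
    """
    if mode not in ("phased", "unphased", "double_reduction"):
        raise ValueError(f"unknown mode {mode!r}")
    phased_needed = mode in ("phased", "double_reduction")
    if phased_needed:
        for par in (p1, p2):
            if not isinstance(par, PhasedParent):
                raise TypeError(
                    f"mode {mode!r} requires phased parents, got dosage-only "
                    f"genotype for {par.parent_id!r}"
                )
    if mode == "double_reduction":
        if alpha is None:
            raise ValueError("double_reduction mode requires alpha")
        if not 0.0 <= alpha <= MAX_ALPHA:
            raise ValueError(
                f"double-reduction rate must be in [0, {MAX_ALPHA:.4f}]"
            )
        logger.warning(
            "double-reduction mode assumes complete quadrivalent pairing and "
            "centromere-A-B locus order; these assumptions are rarely met"
        )

    x1 = p1.dosages() if isinstance(p1, PhasedParent) else p1.dosages
    x2 = p2.dosages() if isinstance(p2, PhasedParent) else p2.dosages
    pos_all = genetic_map.positions
    blocks = []
    for chrom, idx in genetic_map.chrom_indices().items():
        pos = pos_all[idx]
        if mode == "unphased":
            diag = np.array(
                [var_locus(int(x1[i]), int(x2[i])) for i in idx]
            )
            mat = np.diag(diag)
        elif mode == "phased":
            mat = _phased_block(p1, p2, idx, pos)
        else:  # double_reduction
            bracket = np.zeros((len(idx), len(idx)))
            for par in (p1, p2):
                h = par.haplotypes[:, idx].astype(float)
                x = h.sum(axis=0)
                bracket += h.T @ h / 3.0 - np.outer(x, x) / 12.0
            c = 0.5 * (1.0 - np.exp(-2.0 * np.abs(pos[:, None] - pos[None, :])))
            factor = (1.0 - 4.0 * c / 3.0) * (1.0 + 2.0 * alpha)
            np.fill_diagonal(factor, 1.0)  # diagonal stays the locus variance
            mat = bracket * factor
        blocks.append(ChromCovarianceBlock(chrom, mat, idx))
    return blocks


def segregation_variance(
    blocks: Iterable[ChromCovarianceBlock], effects: MarkerEffects
) -> float:
    """Quadratic form beta' V beta summed over chromosome blocks.

    Small negative round-off results (> -1e-9) are clamped to 0; larger
    negatives indicate a corrupted covariance matrix and raise.
    """
    beta = effects.values
    total = 0.0
    for blk in blocks:
        b = beta[blk.marker_index]
        if len(b) != blk.matrix.shape[0]:
            raise ValueError(
                f"effects not aligned with block {blk.chromosome!r}"
            )
        total += float(b @ (blk.matrix @ b))
    if total < 0.0:
        if total < -_NEG_TOL:
            raise ValueError(
                f"segregation variance {total} is negative beyond round-off"
            )
        logger.warning("clamping %.3e round-off negative variance to 0", total)
        total = 0.0
    return total


def predict_cross(
    p1: PhasedParent | DosageGenotype,
    p2: PhasedParent | DosageGenotype,
    genetic_map: GeneticMap,
    effects: MarkerEffects,
    modes: Iterable[str] = ("phased", "unphased"),
    alpha: float | None = None,
) -> CrossPrediction:
    """Predict the segregation variance of one cross under selected modes."""
    pred = CrossPrediction(parent1=p1.parent_id, parent2=p2.parent_id)
    for mode in modes:
        blocks = build_cov_blocks(p1, p2, genetic_map, mode=mode, alpha=alpha)
        value = segregation_variance(blocks, effects)
        if mode == "phased":
            pred.sigma2_phased = value
        elif mode == "unphased":
            pred.sigma2_unphased = value
        else:
            pred.sigma2_dr = value
        pred.method_tags.add(mode)
    return pred


def predict_crosses(
    dataset: AlignedDataset,
    crosses: list[tuple[str, str]] | None = None,
    modes: Iterable[str] = ("phased", "unphased"),
    alpha: float | None = None,
) -> list[CrossPrediction]:
    """Predict all requested crosses (default: the full half-diallel)."""
    if crosses is None:
        crosses = list(combinations(sorted(dataset.parents), 2))
    out = []
    for a, b in crosses:
        out.append(
            predict_cross(
                dataset.parents[a],
                dataset.parents[b],
                dataset.genetic_map,
                dataset.effects,
                modes=modes,
                alpha=alpha,
            )
        )
    return out
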