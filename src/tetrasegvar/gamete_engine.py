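"""Exact two-locus gamete and progeny enumeration under bivalent meiosis.

With four homologs and purely bivalent pairing (no double reduction), a
tetraploid genotype A1B1/A2B2/A3B3/A4B4 produces 36 distinct two-locus
gametes: 6 fully parental (2P), 24 with one parental and one recombinant
chromatid (1P1R) and 6 fully recombinant (2R), with probabilities
(1-c)^2/6, c(1-c)/12 and c^2/6 respectively, where c is the recombination
rate between the loci.  Crossing two parents yields 36 x 36 = 1,296 progeny
genotype combinations under the product measure.  These tables provide the
brute-force covariance oracle against which the closed-form prediction is
verified.

Note on the 2R class: at the level of homolog labels, bivalent meiosis
produces 12 double-recombinant gametes (probability c^2/12 each); they
collapse pairwise into 6 rows with identical allele content — the unordered
set of homologs contributing to locus A determines the set contributing to
locus B — and the canonical table lists those 6 content classes at c^2/6.
Allele-count distributions, and hence all moments, are unaffected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import PhasedParent

__all__ = [
    "GAMETE_ROWS",
    "GameteDistribution",
    "ProgenyGenotypeTable",
    "gamete_probabilities",
    "enumerate_gametes",
    "enumerate_progeny",
    "cov_brute_force",
    "var_brute_force",
]

# The 36 canonical gamete rows: two chromatids, each (homolog at A, homolog
# at B), 1-based homolog labels, in canonical table order.
_2P = [((i, i), (j, j)) for i, j in
       [(1, 2), (1, 3), (1, 4), (2, 3), (2, 4), (3, 4)]]
_2R = [((1, 2), (3, 4)), ((1, 2), (4, 3)), ((2, 1), (3, 4)),
       ((2, 1), (4, 3)), ((3, 1), (4, 2)), ((1, 3), (2, 4))]
_1P1R = [
    ((1, 1), (3, 4)), ((1, 1), (4, 3)), ((2, 2), (3, 4)), ((2, 2), (4, 3)),
    ((3, 3), (1, 2)), ((4, 4), (1, 2)), ((3, 3), (2, 1)), ((4, 4), (2, 1)),
    ((1, 1), (2, 4)), ((1, 1), (4, 2)), ((3, 3), (2, 4)), ((3, 3), (4, 2)),
    ((2, 2), (1, 3)), ((4, 4), (1, 3)), ((2, 2), (3, 1)), ((4, 4), (3, 1)),
    ((1, 1), (2, 3)), ((1, 1), (3, 2)), ((4, 4), (2, 3)), ((4, 4), (3, 2)),
    ((2, 2), (1, 4)), ((3, 3), (1, 4)), ((2, 2), (4, 1)), ((3, 3), (4, 1)),
]

#: list of (chromatid1, chromatid2, type) in canonical order (2P, 2R, 1P1R).
GAMETE_ROWS: list[tuple[tuple[int, int], tuple[int, int], str]] = (
    [(c1, c2, "2P") for c1, c2 in _2P]
    + [(c1, c2, "2R") for c1, c2 in _2R]
    + [(c1, c2, "1P1R") for c1, c2 in _1P1R]
)

# 0-based homolog indices of the two chromatids at locus A and locus B.
_HOM_A = np.array([[c1[0] - 1, c2[0] - 1] for c1, c2, _ in GAMETE_ROWS])
_HOM_B = np.array([[c1[1] - 1, c2[1] - 1] for c1, c2, _ in GAMETE_ROWS])
_TYPES = np.array([t for _, _, t in GAMETE_ROWS])


def gamete_probabilities(c: float) -> np.ndarray:
    """Probabilities of the 36 canonical gametes at recombination rate c."""
    if not 0.0 <= c <= 0.5:
        raise ValueError(f"recombination rate must be in [0, 0.5], got {c}")
    p = np.empty(36)
    p[_TYPES == "2P"] = (1.0 - c) ** 2 / 6.0
    p[_TYPES == "2R"] = c**2 / 6.0
    p[_TYPES == "1P1R"] = c * (1.0 - c) / 12.0
    return p


def _gamete_label(c1: tuple[int, int], c2: tuple[int, int]) -> str:
    return f"A{c1[0]}B{c1[1]}/A{c2[0]}B{c2[1]}"


@dataclass
class GameteDistribution:
    """The 36 two-locus gametes of one parent with probabilities.

    ``allele_a``/``allele_b`` are the allele counts (0-2) contributed by the
    gamete's two chromatids at each locus, given the parent's phasing.
    """

    parent_id: str
    c: float
    probabilities: np.ndarray  # (36,)
    allele_a: np.ndarray  # (36,) int
    allele_b: np.ndarray  # (36,) int

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "index": np.arange(1, 37),
                "gamete": [_gamete_label(c1, c2) for c1, c2, _ in GAMETE_ROWS],
                "type": _TYPES,
                "probability": self.probabilities,
                "allele_count_A": self.allele_a,
                "allele_count_B": self.allele_b,
            }
        )


@dataclass
class ProgenyGenotypeTable:
    """All 1,296 progeny genotype combinations of a bi-parental cross."""

    probabilities: np.ndarray  # (1296,)
    x_a: np.ndarray  # (1296,) dosage at locus A, 0-4
    x_b: np.ndarray  # (1296,) dosage at locus B, 0-4
    gamete1_index: np.ndarray
    gamete2_index: np.ndarray


def enumerate_gametes(
    parent: PhasedParent, locus_a: int, locus_b: int, c: float
) -> GameteDistribution:
    """Enumerate the 36 two-locus gametes of ``parent``.

    ``locus_a``/``locus_b`` are marker column indices; ``c`` the
    recombination rate between them.
    """
    probs = gamete_probabilities(c)
    a = parent.haplotypes[:, locus_a].astype(int)
    b = parent.haplotypes[:, locus_b].astype(int)
    return GameteDistribution(
        parent_id=parent.parent_id,
        c=c,
        probabilities=probs,
        allele_a=a[_HOM_A].sum(axis=1),
        allele_b=b[_HOM_B].sum(axis=1),
    )


def enumerate_progeny(
    p1: PhasedParent,
    p2: PhasedParent,
    locus_a: int,
    locus_b: int,
    c1: float,
    c2: float | None = None,
) -> ProgenyGenotypeTable:
    """Cross-product of the parents' gamete distributions (1,296 rows).

    The same recombination rate applies to both parents unless ``c2`` is
    given (the two parents share one genetic map).
    """
    if c2 is None:
        c2 = c1
    g1 = enumerate_gametes(p1, locus_a, locus_b, c1)
    g2 = enumerate_gametes(p2, locus_a, locus_b, c2)
    i1, i2 = np.meshgrid(np.arange(36), np.arange(36), indexing="ij")
    i1, i2 = i1.ravel(), i2.ravel()
    return ProgenyGenotypeTable(
        probabilities=g1.probabilities[i1] * g2.probabilities[i2],
        x_a=g1.allele_a[i1] + g2.allele_a[i2],
        x_b=g1.allele_b[i1] + g2.allele_b[i2],
        gamete1_index=i1,
        gamete2_index=i2,
    )


def cov_brute_force(
    p1: PhasedParent,
    p2: PhasedParent,
    locus_a: int,
    locus_b: int,
    c: float,
) -> float:
    """Two-locus progeny dosage covariance by exhaustive enumeration.

    cov(xA, xB) = E[xA xB] - E[xA] E[xB] over the 1,296 progeny genotypes.
    """
    t = enumerate_progeny(p1, p2, locus_a, locus_b, c)
    p = t.probabilities
    return float(p @ (t.x_a * t.x_b) - (p @ t.x_a) * (p @ t.x_b))


def var_brute_force(p1: PhasedParent, p2: PhasedParent, locus: int) -> float:
    """Single-locus progeny dosage variance: the two-locus oracle at B = A,
    c = 0."""
    return cov_brute_force(p1, p2, locus, locus, 0.0)
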