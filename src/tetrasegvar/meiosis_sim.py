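"""Forward simulator of autotetraploid bivalent meiosis and F1 families.

Per chromosome the four parental homologs are partitioned uniformly at
random into two bivalents (three equiprobable pairings).  Each bivalent
transmits one chromatid: a mosaic of its two homologs produced by a
crossover process without interference.  Under the Haldane model the
homolog-switch points along the transmitted chromatid form a Poisson
process with rate 1 per Morgan, which gives a switch probability of
0.5 (1 - exp(-2 d)) between markers d Morgan apart — the per-interval
Markov walk and the Poisson construction are the same law; the latter is
used because it scales with the number of crossovers rather than the
number of markers.  A gamete carries one chromatid per bivalent (two
homologs total); no double reduction occurs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_model import GeneticMap, MarkerEffects, PhasedParent

__all__ = [
    "SimulatedFamily",
    "simulate_gamete_origins",
    "simulate_gamete",
    "simulate_family",
    "draw_qtl_effects",
]

# The three ways to split homologs {0,1,2,3} into two bivalents.
_PAIRINGS = np.array(
    [
        [[0, 1], [2, 3]],
        [[0, 2], [1, 3]],
        [[0, 3], [1, 2]],
    ],
    dtype=np.int8,
)


@dataclass
class SimulatedFamily:
    """Simulated F1 progeny of one cross.

    ``progeny_haplotypes`` (n x 4 x p) is retained only when requested;
    dosages and true genetic values g = X beta are always available.
    """

    parent1: str
    parent2: str
    progeny_dosages: np.ndarray  # (n, p) int8
    true_genetic_values: np.ndarray  # (n,)
    seed: int | None = None
    progeny_haplotypes: np.ndarray | None = None  # (n, 4, p) int8

    @property
    def n(self) -> int:
        return self.progeny_dosages.shape[0]

    @property
    def cross_id(self) -> str:
        return f"{self.parent1}x{self.parent2}"


def _chromatid_states(
    pos: np.ndarray, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Binary state (which member of the bivalent) of n transmitted
    chromatids at each of the q markers at positions ``pos`` (Morgan).

    Starting member uniform; switch points Poisson with rate 1/Morgan over
    the marker span.
    """
    q = len(pos)
    start = rng.integers(0, 2, size=n, dtype=np.int8)
    span = float(pos[-1] - pos[0]) if q > 1 else 0.0
    if span == 0.0:
        return np.broadcast_to(start[:, None], (n, q)).copy()
    k = rng.poisson(span, size=n)
    total = int(k.sum())
    flips_per_interval = np.zeros((n, q), dtype=np.int64)
    if total:
        rows = np.repeat(np.arange(n), k)
        fpos = pos[0] + rng.random(total) * span
        # a flip strictly before marker j (and at/after marker j-1) lands in
        # column j and toggles the state at markers j..q-1
        cols = np.searchsorted(pos, fpos, side="right")
        keep = cols < q  # flips at/after the last marker change nothing
        np.add.at(flips_per_interval, (rows[keep], cols[keep]), 1)
    parity = np.cumsum(flips_per_interval, axis=1) & 1
    return (start[:, None] ^ parity).astype(np.int8)


def simulate_gamete_origins(
    genetic_map: GeneticMap, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Homolog-of-origin indices (0-3) for n gametes, shape (n, 2, p).

    Axis 1 indexes the gamete's two chromatids (one per bivalent).  The
    result is parent-independent; gamete alleles follow by indexing a
    parent's haplotype matrix.
    """
    p = len(genetic_map)
    out = np.empty((n, 2, p), dtype=np.int8)
    pos_all = genetic_map.positions
    for chrom, idx in genetic_map.chrom_indices().items():
        pos = pos_all[idx]
        pairing = rng.integers(0, 3, size=n)
        rows = np.arange(n)[:, None]
        for b in (0, 1):
            states = _chromatid_states(pos, n, rng)
            homolog_pair = _PAIRINGS[pairing, b]  # (n, 2)
            out[:, b, idx] = homolog_pair[rows, states]
    return out


def simulate_gamete(
    parent: PhasedParent, genetic_map: GeneticMap, rng: np.random.Generator
) -> np.ndarray:
    """One gamete of ``parent``: a 2 x p binary array (two chromatids)."""
    origins = simulate_gamete_origins(genetic_map, 1, rng)[0]
    cols = np.arange(parent.n_markers)
    return parent.haplotypes[origins, cols[None, :]]


def _gamete_alleles(
    parent: PhasedParent, origins: np.ndarray
) -> np.ndarray:
    """(n, 2, p) gamete alleles from (n, 2, p) homolog origins."""
    cols = np.arange(parent.n_markers)
    return parent.haplotypes[origins, cols[None, None, :]]


def simulate_family(
    p1: PhasedParent,
    p2: PhasedParent,
    genetic_map: GeneticMap,
    effects: MarkerEffects,
    n: int,
    rng: np.random.Generator | int,
    keep_haplotypes: bool = False,
) -> SimulatedFamily:
    """Simulate n F1 progenies of p1 x p2 with true genetic values."""
    if n < 1:
        raise ValueError("family size must be >= 1")
    seed = None
    if isinstance(rng, (int, np.integer)):
        seed = int(rng)
        rng = np.random.default_rng(seed)
    g1 = _gamete_alleles(p1, simulate_gamete_origins(genetic_map, n, rng))
    g2 = _gamete_alleles(p2, simulate_gamete_origins(genetic_map, n, rng))
    dosages = (
        g1.sum(axis=1, dtype=np.int8) + g2.sum(axis=1, dtype=np.int8)
    )
    g = dosages.astype(float) @ effects.values
    haplos = None
    if keep_haplotypes:
        haplos = np.concatenate([g1, g2], axis=1)  # (n, 4, p)
    return SimulatedFamily(
        parent1=p1.parent_id,
        parent2=p2.parent_id,
        progeny_dosages=dosages,
        true_genetic_values=g,
        seed=seed,
        progeny_haplotypes=haplos,
    )


def draw_qtl_effects(
    n_qtl: int,
    n_markers: int,
    rng: np.random.Generator,
    shape: float = 2.0,
    scale: float = 0.2,
    random_sign: bool = False,
) -> tuple[MarkerEffects, np.ndarray]:
    """Gamma-distributed additive effects on a random marker subset.

    ``n_qtl`` markers are chosen uniformly without replacement from the
    ``n_markers`` available; their effects are gamma(shape, scale) draws
    (defaults k = 2, theta = 0.2, all positive); the remaining markers get
    effect 0.  Returns the full-length effect vector and the chosen QTL
    indices.  ``random_sign`` flips each effect's sign with probability 1/2
    (off by default).
    """
    if shape <= 0 or scale <= 0:
        raise ValueError("gamma shape and scale must be positive")
    if n_qtl > n_markers:
        raise ValueError("more QTL requested than markers available")
    qtl_idx = rng.choice(n_markers, size=n_qtl, replace=False)
    qtl_idx.sort()
    values = np.zeros(n_markers)
    draws = rng.gamma(shape, scale, size=n_qtl)
    if random_sign:
        draws *= rng.choice([-1.0, 1.0], size=n_qtl)
    values[qtl_idx] = draws
    return MarkerEffects(values), qtl_idx
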