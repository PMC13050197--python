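import numpy as np
import pytest

from tetrasegvar import GeneticMap, PhasedParent


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture
def duplex_coupling():
    """AB/AB/ab/ab: duplex at both loci, alleles in coupling phase."""
    return PhasedParent("dup", np.array([[1, 1], [1, 1], [0, 0], [0, 0]]))


@pytest.fixture
def nulliplex():
    return PhasedParent("nul", np.zeros((4, 2), dtype=np.int8))


@pytest.fixture
def balanced_duplex():
    """AB/Ab/aB/ab: duplex at both loci with bracket term exactly 0."""
    return PhasedParent("bal", np.array([[1, 1], [1, 0], [0, 1], [0, 0]]))


@pytest.fixture
def two_chrom_map():
    """Five markers on two chromosomes, positions in Morgan."""
    return GeneticMap(
        ["m1", "m2", "m3", "m4", "m5"],
        ["1", "1", "1", "2", "2"],
        [0.0, 0.1, 0.6, 0.0, 0.4],
    )


def random_parent(rng, pid="p", n_markers=2):
    return PhasedParent(pid, rng.integers(0, 2, size=(4, n_markers)))


def all_two_locus_phasings():
    """All 256 phasings of a 4 x 2 binary haplotype matrix."""
    out = []
    for code in range(256):
        bits = (code >> np.arange(8)) & 1
        out.append(bits.reshape(4, 2).astype(np.int8))
    return out


def gamete_row_lookup():
    """Map encoded chromatid pairs to canonical 36-row gamete indices.

    A chromatid with homolog a at locus A and b at locus B is encoded as
    a*4+b; an unordered chromatid pair as min*16+max.  Double-recombinant
    gametes are classified by allele content (the set of homologs feeding
    locus A), matching the canonical table's aggregation.
    """
    from tetrasegvar.gamete_engine import GAMETE_ROWS

    content2row, label2row = {}, {}
    for r, (c1, c2, t) in enumerate(GAMETE_ROWS):
        if t == "2R":
            content2row[frozenset((c1[0] - 1, c2[0] - 1))] = r
        else:
            label2row[
                frozenset(((c1[0] - 1, c1[1] - 1), (c2[0] - 1, c2[1] - 1)))
            ] = r
    lookup = -np.ones(256, dtype=int)
    for (p, q), (u, v) in (
        ((0, 1), (2, 3)), ((0, 2), (1, 3)), ((0, 3), (1, 2))
    ):
        for ch1 in ((p, p), (q, q), (p, q), (q, p)):
            for ch2 in ((u, u), (v, v), (u, v), (v, u)):
                if ch1[0] != ch1[1] and ch2[0] != ch2[1]:
                    r = content2row[frozenset((ch1[0], ch2[0]))]
                else:
                    r = label2row[frozenset((ch1, ch2))]
                k1, k2 = ch1[0] * 4 + ch1[1], ch2[0] * 4 + ch2[1]
                lookup[min(k1, k2) * 16 + max(k1, k2)] = r
    return lookup


def classify_gametes(origins):
    """Counts of simulated two-locus gametes in the 36 canonical rows."""
    lookup = gamete_row_lookup()
    k = origins[:, :, 0].astype(int) * 4 + origins[:, :, 1].astype(int)
    key = np.minimum(k[:, 0], k[:, 1]) * 16 + np.maximum(k[:, 0], k[:, 1])
    rows = lookup[key]
    assert np.all(rows >= 0), "simulated gamete outside the 36-row model"
    return np.bincount(rows, minlength=36)
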