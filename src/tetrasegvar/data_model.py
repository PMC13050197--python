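"""Domain types shared across the package.

Genotypes of an autotetraploid parent are represented either as phased
haplotypes (four binary homolog sequences per marker) or as unphased allele
dosages (0-4 per marker).  A genetic map places every marker on a chromosome
at a position in Morgan, and a vector of additive marker effects (trait units
per copy of the alternative allele) completes the inputs needed to predict
the segregation variance of a cross.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GeneticMap",
    "PhasedParent",
    "DosageGenotype",
    "MarkerEffects",
    "CrossPrediction",
    "ScenarioConfig",
    "EvaluationMetrics",
    "AlignedDataset",
    "align",
    "dosage_of",
]

PLOIDY = 4

#: Default factorial grid of the simulation study.
FAMILY_SIZES = (10, 20, 50, 100, 200, 500, 1000, 2000, 5000)
SIZE_DISTRIBUTIONS = ("uniform", "gamma")
N_CROSSES = (10, 50, 100, 250, 500)


class GeneticMap:
    """Per-marker chromosome assignment and map position in Morgan.

    Markers are stored sorted by (chromosome, position); positions within a
    chromosome are therefore non-decreasing.  Construction from centiMorgan
    input is supported via ``unit="cM"``.
    """

    def __init__(
        self,
        marker_ids: Sequence[str],
        chromosomes: Sequence[str],
        positions: Sequence[float],
        unit: str = "morgan",
    ):
        ids = list(marker_ids)
        if len(set(ids)) != len(ids):
            dup = pd.Index(ids)[pd.Index(ids).duplicated()].tolist()
            raise ValueError(f"duplicate marker ids in map: {dup[:5]}")
        pos = np.asarray(positions, dtype=float)
        if unit.lower() in ("cm", "centimorgan"):
            pos = pos / 100.0
        elif unit.lower() not in ("morgan", "m"):
            raise ValueError(f"unknown map unit {unit!r} (use 'morgan' or 'cM')")
        if np.any(pos < 0) or not np.all(np.isfinite(pos)):
            raise ValueError("map positions must be finite and >= 0 (Morgan)")
        df = pd.DataFrame(
            {"marker": ids, "chrom": [str(c) for c in chromosomes], "pos": pos}
        )
        df = df.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
        self._df = df
        self._index = {m: i for i, m in enumerate(df["marker"])}

    @classmethod
    def from_frame(cls, df: pd.DataFrame, unit: str = "morgan") -> "GeneticMap":
        return cls(df["marker"], df["chrom"], df["pos"], unit=unit)

    def __len__(self) -> int:
        return len(self._df)

    @property
    def marker_ids(self) -> list[str]:
        return self._df["marker"].tolist()

    @property
    def chrom(self) -> np.ndarray:
        return self._df["chrom"].to_numpy()

    @property
    def positions(self) -> np.ndarray:
        """Positions in Morgan, map order."""
        return self._df["pos"].to_numpy()

    @property
    def frame(self) -> pd.DataFrame:
        return self._df.copy()

    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self._df["chrom"]))

    def chrom_indices(self) -> dict[str, np.ndarray]:
        """Map-order integer indices of the markers on each chromosome."""
        groups = self._df.groupby("chrom", sort=False).indices
        return {c: np.asarray(ix, dtype=int) for c, ix in groups.items()}

    def subset(self, marker_ids: Iterable[str]) -> "GeneticMap":
        keep = set(marker_ids)
        sub = self._df[self._df["marker"].isin(keep)]
        return GeneticMap(sub["marker"], sub["chrom"], sub["pos"])

    def index_of(self, marker_id: str) -> int:
        return self._index[marker_id]


@dataclass
class PhasedParent:
    """One tetraploid parent as a 4 x p binary haplotype matrix.

    Row h, column m is the allele (0 reference / 1 alternative) carried by
    homolog h at marker m.
    """

    parent_id: str
    haplotypes: np.ndarray

    def __post_init__(self) -> None:
        h = np.asarray(self.haplotypes)
        if h.ndim != 2 or h.shape[0] != PLOIDY:
            raise ValueError(
                f"parent {self.parent_id!r}: haplotypes must be 4 x p, got {h.shape}"
            )
        if not np.isin(h, (0, 1)).all():
            raise ValueError(f"parent {self.parent_id!r}: haplotype entries must be 0/1")
        self.haplotypes = h.astype(np.int8)

    @property
    def n_markers(self) -> int:
        return self.haplotypes.shape[1]

    def dosages(self) -> np.ndarray:
        return self.haplotypes.sum(axis=0).astype(np.int8)

    def subset(self, idx: np.ndarray) -> "PhasedParent":
        return PhasedParent(self.parent_id, self.haplotypes[:, idx])


@dataclass
class DosageGenotype:
    """Unphased allele dosages (0-4) of one parent."""

    parent_id: str
    dosages: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.dosages)
        if d.ndim != 1:
            raise ValueError("dosages must be a 1-D vector")
        if not np.isin(d, (0, 1, 2, 3, 4)).all():
            raise ValueError(
                f"parent {self.parent_id!r}: dosages must be integers in 0..4"
            )
        self.dosages = d.astype(np.int8)

    @property
    def n_markers(self) -> int:
        return self.dosages.shape[0]

    def subset(self, idx: np.ndarray) -> "DosageGenotype":
        return DosageGenotype(self.parent_id, self.dosages[idx])


def dosage_of(parent: PhasedParent) -> DosageGenotype:
    """Collapse a phased parent to its dosage genotype (column sums)."""
    return DosageGenotype(parent.parent_id, parent.haplotypes.sum(axis=0))


@dataclass
class MarkerEffects:
    """Additive marker effects, optionally keyed by marker id.

    When ``marker_ids`` is None the vector is taken to be positionally
    aligned with whatever marker list it is used against.
    """

    values: np.ndarray
    marker_ids: list[str] | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1:
            raise ValueError("effects must be a 1-D vector")
        if not np.all(np.isfinite(v)):
            raise ValueError("effects must be finite")
        self.values = v
        if self.marker_ids is not None:
            self.marker_ids = list(self.marker_ids)
            if len(self.marker_ids) != len(v):
                raise ValueError("marker_ids and values length mismatch")
            if len(set(self.marker_ids)) != len(self.marker_ids):
                raise ValueError("duplicate marker ids in effects")

    def __len__(self) -> int:
        return len(self.values)

    def subset(self, idx: np.ndarray) -> "MarkerEffects":
        ids = [self.marker_ids[i] for i in idx] if self.marker_ids else None
        return MarkerEffects(self.values[idx], ids)


@dataclass
class CrossPrediction:
    """Predicted segregation variances for one bi-parental cross.

    ``sigma2_phased_finite`` is only populated once a finite progeny sample
    supplies ``cov_total``; the identity finite = phased + cov_total holds by
    construction.
    """

    parent1: str
    parent2: str
    sigma2_phased: float | None = None
    sigma2_unphased: float | None = None
    sigma2_dr: float | None = None
    cov_total: float | None = None
    sigma2_phased_finite: float | None = None
    method_tags: set = field(default_factory=set)


@dataclass
class ScenarioConfig:
    """One cell of the simulation-study grid."""

    n_cross: int
    family_size_mean: int
    size_distribution: str
    n_runs: int = 30
    n_qtl: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.size_distribution not in SIZE_DISTRIBUTIONS:
            raise ValueError(
                f"size_distribution must be one of {SIZE_DISTRIBUTIONS}"
            )
        for name in ("n_cross", "family_size_mean", "n_runs", "n_qtl"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class EvaluationMetrics:
    """PCC / RMSD pair, optionally scaled to CV[RMSD] = RMSD / ybar."""

    pcc: float
    rmsd: float
    cv_rmsd: float = float("nan")


@dataclass
class AlignedDataset:
    """Parents, map and effects restricted to a common marker set, map order."""

    parents: dict[str, PhasedParent | DosageGenotype]
    genetic_map: GeneticMap
    effects: MarkerEffects
    dropped_markers: list[str] = field(default_factory=list)

    @property
    def n_markers(self) -> int:
        return len(self.genetic_map)

    @property
    def phased(self) -> bool:
        return all(isinstance(p, PhasedParent) for p in self.parents.values())


def align(
    parents: Mapping[str, PhasedParent | DosageGenotype] | Sequence,
    genetic_map: GeneticMap,
    effects: MarkerEffects,
    parent_marker_ids: Sequence[str] | None = None,
) -> AlignedDataset:
    """Restrict parents, map and effects to their common marker set.

    Parent genotype columns are assumed to follow ``parent_marker_ids`` (or
    the map's marker order when omitted, which requires matching lengths).
    Effects with explicit ``marker_ids`` participate in the id intersection;
    id-less effects must positionally match the parent marker list.  The
    operation is idempotent.
    """
    if not isinstance(parents, Mapping):
        parents = {p.parent_id: p for p in parents}
    if parent_marker_ids is None:
        parent_marker_ids = genetic_map.marker_ids
    parent_marker_ids = list(parent_marker_ids)
    if len(set(parent_marker_ids)) != len(parent_marker_ids):
        raise ValueError("duplicate marker ids in parent genotypes")
    for pid, par in parents.items():
        if par.n_markers != len(parent_marker_ids):
            raise ValueError(
                f"parent {pid!r} has {par.n_markers} markers, expected "
                f"{len(parent_marker_ids)}"
            )
    if effects.marker_ids is None:
        if len(effects) != len(parent_marker_ids):
            raise ValueError(
                "id-less effects must match the parent marker count"
            )
        effect_ids = parent_marker_ids
    else:
        effect_ids = effects.marker_ids
    common = set(parent_marker_ids) & set(genetic_map.marker_ids) & set(effect_ids)
    if not common:
        raise ValueError("no markers shared between genotypes, map and effects")

    sub_map = genetic_map.subset(common)
    order = sub_map.marker_ids  # map order
    col_of = {m: i for i, m in enumerate(parent_marker_ids)}
    idx = np.array([col_of[m] for m in order], dtype=int)
    eff_col = {m: i for i, m in enumerate(effect_ids)}
    eff_idx = np.array([eff_col[m] for m in order], dtype=int)

    dropped = sorted(
        (set(parent_marker_ids) | set(genetic_map.marker_ids) | set(effect_ids))
        - common
    )
    return AlignedDataset(
        parents={pid: par.subset(idx) for pid, par in parents.items()},
        genetic_map=sub_map,
        effects=MarkerEffects(effects.values[eff_idx], order),
        dropped_markers=dropped,
    )
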