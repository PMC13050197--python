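"""Simulation-study harness: synthetic parents, scenario grid, runs.

The study crosses a panel of synthetic phased tetraploid founders in a
half-diallel, simulates F1 families under bivalent meiosis, and compares
progeny-based variance estimates (M1, M2) against the closed-form phased
and unphased predictions, reporting PCC and RMSD per comparison.  The full
factorial grid varies mean family size (10 ... 5,000), the family-size
distribution across crosses (uniform or gamma) and the number of crosses
(10 ... 500), giving 90 scenarios; each scenario is replicated over
independent runs (default 30) and medians are taken across runs.  QTL
positions are re-drawn every run while the multiset of effect sizes stays
fixed across the runs of a study.

Progeny are simulated at QTL markers only: non-QTL markers carry zero
effect, and restricting the crossover walk to a marker subset is an exact
marginalisation of the meiosis model, so neither the estimators nor the
closed forms are affected.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .data_model import (
    FAMILY_SIZES,
    N_CROSSES,
    SIZE_DISTRIBUTIONS,
    GeneticMap,
    MarkerEffects,
    PhasedParent,
    ScenarioConfig,
)
from .estimators import estimate_m1, estimate_m2, metrics
from .meiosis_sim import simulate_family
from .segvar_core import predict_cross

__all__ = [
    "COMPARISONS",
    "ScenarioResult",
    "build_grid",
    "draw_family_sizes",
    "synthesize_parents",
    "run_scenario",
    "half_diallel",
]

#: Comparisons evaluated in every run.
COMPARISONS = (
    "M1~phased",
    "M2~phased",
    "M1~unphased",
    "M2~unphased",
    "phased~unphased",
)

#: Gamma shape for the family-size distribution (scale follows the mean).
FAMILY_SIZE_GAMMA_SHAPE = 2.0


def build_grid(
    family_sizes=FAMILY_SIZES,
    distributions=SIZE_DISTRIBUTIONS,
    n_crosses=N_CROSSES,
    n_runs: int = 30,
    n_qtl: int = 2000,
    seed: int = 0,
) -> list[ScenarioConfig]:
    """Full factorial scenario grid (defaults: 9 x 2 x 5 = 90 scenarios)."""
    grid = []
    for size in family_sizes:
        for distr in distributions:
            for nc in n_crosses:
                grid.append(
                    ScenarioConfig(
                        n_cross=nc,
                        family_size_mean=size,
                        size_distribution=distr,
                        n_runs=n_runs,
                        n_qtl=n_qtl,
                        seed=seed,
                    )
                )
    return grid


def draw_family_sizes(
    config: ScenarioConfig, rng: np.random.Generator
) -> np.ndarray:
    """Family sizes for the scenario's crosses.

    ``uniform`` gives every family exactly the mean size; ``gamma`` draws
    i.i.d. gamma(shape=2) sizes rescaled to the target mean, rounded and
    floored at 2.
    """
    if config.family_size_mean < 2:
        raise ValueError("family_size_mean must be >= 2")
    if config.size_distribution == "uniform":
        return np.full(config.n_cross, config.family_size_mean, dtype=int)
    k = FAMILY_SIZE_GAMMA_SHAPE
    draws = rng.gamma(k, config.family_size_mean / k, size=config.n_cross)
    return np.maximum(np.rint(draws).astype(int), 2)


def synthesize_parents(
    n_parents: int = 100,
    n_chrom: int = 12,
    markers_per_chrom: int = 300,
    chrom_length_morgan: float = 1.0,
    allele_freq: float = 0.5,
    rng: np.random.Generator | int = 0,
) -> tuple[dict[str, PhasedParent], GeneticMap]:
    """Random phased tetraploid founders and their genetic map.

    Homolog alleles are i.i.d. Bernoulli(``allele_freq``); marker positions
    are uniform on [0, ``chrom_length_morgan``] per chromosome.
    """
    if min(n_parents, n_chrom, markers_per_chrom) <= 0:
        raise ValueError("dimensions must be positive")
    if not 0.0 <= allele_freq <= 1.0:
        raise ValueError("allele_freq must be in [0, 1]")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    ids, chroms, pos = [], [], []
    for c in range(n_chrom):
        p = np.sort(rng.random(markers_per_chrom)) * chrom_length_morgan
        for m, d in enumerate(p):
            ids.append(f"c{c + 1:02d}_m{m + 1:04d}")
            chroms.append(f"chr{c + 1:02d}")
            pos.append(d)
    gmap = GeneticMap(ids, chroms, pos)
    p_total = n_chrom * markers_per_chrom
    width = len(str(n_parents))
    parents = {}
    for i in range(n_parents):
        pid = f"P{i + 1:0{width}d}"
        hap = (rng.random((4, p_total)) < allele_freq).astype(np.int8)
        parents[pid] = PhasedParent(pid, hap)
    return parents, gmap


def half_diallel(parent_ids) -> list[tuple[str, str]]:
    """All unordered parent pairs, no selfs, no reciprocals."""
    return list(combinations(sorted(parent_ids), 2))


@dataclass
class ScenarioResult:
    """Per-run PCC/RMSD records and their medians for one scenario."""

    config: ScenarioConfig
    records: pd.DataFrame = field(repr=False)
    medians: pd.DataFrame = field(repr=False)


def _run_once(
    parents: dict[str, PhasedParent],
    genetic_map: GeneticMap,
    crosses: list[tuple[str, str]],
    family_sizes: np.ndarray,
    qtl_map: GeneticMap,
    qtl_effects: MarkerEffects,
    qtl_cols: np.ndarray,
    rng: np.random.Generator,
) -> dict[str, tuple[float, float]]:
    """One run: simulate every cross, return {comparison: (pcc, rmsd)}."""
    m1 = np.empty(len(crosses))
    m2 = np.empty(len(crosses))
    phased = np.empty(len(crosses))
    unphased = np.empty(len(crosses))
    for i, ((a, b), n) in enumerate(zip(crosses, family_sizes)):
        pa = parents[a].subset(qtl_cols)
        pb = parents[b].subset(qtl_cols)
        pred = predict_cross(pa, pb, qtl_map, qtl_effects)
        phased[i] = pred.sigma2_phased
        unphased[i] = pred.sigma2_unphased
        fam = simulate_family(pa, pb, qtl_map, qtl_effects, int(n), rng)
        m1[i] = estimate_m1(fam, qtl_effects, qtl_map)
        m2[i] = estimate_m2(fam, qtl_effects)
    out = {}
    for name, (x, y) in {
        "M1~phased": (m1, phased),
        "M2~phased": (m2, phased),
        "M1~unphased": (m1, unphased),
        "M2~unphased": (m2, unphased),
        "phased~unphased": (phased, unphased),
    }.items():
        m = metrics(x, y)
        out[name] = (m.pcc, m.rmsd)
    return out


def run_scenario(
    config: ScenarioConfig,
    parents: dict[str, PhasedParent],
    genetic_map: GeneticMap,
    effect_sizes: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> ScenarioResult:
    """Run one scenario: ``config.n_runs`` independent runs, medians across.

    ``effect_sizes`` is the study's fixed multiset of QTL effect sizes
    (length ``config.n_qtl``); when omitted it is drawn once from
    gamma(2, 0.2).  Each run re-draws the QTL positions, samples
    ``config.n_cross`` crosses from the half-diallel and the family sizes,
    simulates the families and evaluates all comparisons.
    """
    pool = half_diallel(parents)
    if config.n_cross > len(pool):
        raise ValueError(
            f"n_cross={config.n_cross} exceeds the {len(pool)}-cross "
            "half-diallel"
        )
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if effect_sizes is None:
        effect_sizes = rng.gamma(2.0, 0.2, size=config.n_qtl)
    effect_sizes = np.asarray(effect_sizes, dtype=float)
    if len(effect_sizes) != config.n_qtl:
        raise ValueError("effect_sizes length must equal n_qtl")

    marker_ids = np.array(genetic_map.marker_ids)
    rows = []
    for run in range(config.n_runs):
        qtl_cols = np.sort(
            rng.choice(len(genetic_map), size=config.n_qtl, replace=False)
        )
        qtl_map = genetic_map.subset(marker_ids[qtl_cols])
        qtl_effects = MarkerEffects(effect_sizes, None)
        pick = rng.choice(len(pool), size=config.n_cross, replace=False)
        crosses = [pool[i] for i in pick]
        sizes = draw_family_sizes(config, rng)
        result = _run_once(
            parents, genetic_map, crosses, sizes,
            qtl_map, qtl_effects, qtl_cols, rng,
        )
        for comp, (pcc, rmsd) in result.items():
            rows.append(
                {"run": run, "comparison": comp, "pcc": pcc, "rmsd": rmsd}
            )
    records = pd.DataFrame(rows)
    medians = (
        records.groupby("comparison", sort=False)[["pcc", "rmsd"]]
        .median()
        .reset_index()
    )
    return ScenarioResult(config=config, records=records, medians=medians)
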