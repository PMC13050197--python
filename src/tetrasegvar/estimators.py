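"""Progeny-based variance estimators and evaluation metrics.

Two estimators of the segregation variance from a simulated (or otherwise
genotyped) family:

  M1 — sum over chromosomes of the sample variance of per-chromosome
       genetic values, ignoring covariance between chromosomes;
  M2 — sample variance of the total genetic values, which includes the
       between-chromosome covariance present in a finite family.

The difference M2 - M1 equals cov_total, the effect-weighted sample
covariance between markers on different chromosomes.  In an infinite family
unlinked loci are uncorrelated and cov_total vanishes; in small families
drift-generated LD makes it substantial, and adding it to the closed-form
phased prediction yields the finite-family prediction.

All sample statistics use the n-1 divisor; m2 = m1 + cov_total is then an
exact algebraic identity on any family.
"""

from __future__ import annotations

import numpy as np

from .data_model import (
    CrossPrediction,
    EvaluationMetrics,
    GeneticMap,
    MarkerEffects,
)
from .meiosis_sim import SimulatedFamily

__all__ = [
    "chromosome_genetic_values",
    "estimate_m1",
    "estimate_m2",
    "cov_total",
    "cov_total_pairwise",
    "finite_prediction",
    "r2_unlinked",
    "metrics",
]


def chromosome_genetic_values(
    family: SimulatedFamily, effects: MarkerEffects, genetic_map: GeneticMap
) -> np.ndarray:
    """Per-chromosome genetic values g_chr = X_chr beta_chr, shape
    (n, n_chrom)."""
    beta = effects.values
    x = family.progeny_dosages.astype(float)
    cols = []
    for chrom, idx in genetic_map.chrom_indices().items():
        cols.append(x[:, idx] @ beta[idx])
    return np.column_stack(cols)


def estimate_m1(
    family: SimulatedFamily, effects: MarkerEffects, genetic_map: GeneticMap
) -> float:
    """M1: sum of per-chromosome sample variances of genetic values."""
    if family.n < 2:
        raise ValueError("M1 requires at least 2 progenies")
    g_chr = chromosome_genetic_values(family, effects, genetic_map)
    return float(g_chr.var(axis=0, ddof=1).sum())


def estimate_m2(family: SimulatedFamily, effects: MarkerEffects) -> float:
    """M2: sample variance of total genetic values."""
    if family.n < 2:
        raise ValueError("M2 requires at least 2 progenies")
    g = family.progeny_dosages.astype(float) @ effects.values
    return float(np.var(g, ddof=1))


def cov_total(
    family: SimulatedFamily, effects: MarkerEffects, genetic_map: GeneticMap
) -> float:
    """Effect-weighted sample covariance between markers on different
    chromosomes.

    Each unordered chromosome pair counts twice (both orders of the double
    sum), which makes m1 + cov_total = m2 exact.  Computed from the n x
    n_chrom matrix of per-chromosome genetic values rather than marker by
    marker; a single-chromosome genome returns 0 by definition.
    """
    if family.n < 2:
        raise ValueError("cov_total requires at least 2 progenies")
    g_chr = chromosome_genetic_values(family, effects, genetic_map)
    if g_chr.shape[1] < 2:
        return 0.0
    cov = np.cov(g_chr, rowvar=False, ddof=1)
    return float(cov.sum() - np.trace(cov))


def cov_total_pairwise(
    family: SimulatedFamily, effects: MarkerEffects, genetic_map: GeneticMap
) -> float:
    """Literal marker-pair double sum over distinct chromosomes (slow path,
    kept as the oracle for :func:`cov_total`)."""
    if family.n < 2:
        raise ValueError("cov_total requires at least 2 progenies")
    beta = effects.values
    x = family.progeny_dosages.astype(float)
    chrom_idx = list(genetic_map.chrom_indices().items())
    total = 0.0
    for ci, (_, idx_i) in enumerate(chrom_idx):
        for cj, (_, idx_j) in enumerate(chrom_idx):
            if ci == cj:
                continue
            xi = x[:, idx_i] - x[:, idx_i].mean(axis=0)
            xj = x[:, idx_j] - x[:, idx_j].mean(axis=0)
            cov_ij = xi.T @ xj / (family.n - 1)
            total += float(beta[idx_i] @ cov_ij @ beta[idx_j])
    return total


def finite_prediction(
    pred: CrossPrediction,
    family: SimulatedFamily,
    effects: MarkerEffects,
    genetic_map: GeneticMap,
) -> CrossPrediction:
    """Attach the finite-family correction to a phased prediction.

    Sets ``cov_total`` from the family sample and
    ``sigma2_phased_finite = sigma2_phased + cov_total``.
    """
    if pred.sigma2_phased is None:
        raise ValueError("finite correction requires sigma2_phased")
    ct = cov_total(family, effects, genetic_map)
    pred.cov_total = ct
    pred.sigma2_phased_finite = pred.sigma2_phased + ct
    pred.method_tags.add("finite")
    return pred


def r2_unlinked(
    family: SimulatedFamily,
    genetic_map: GeneticMap,
    n_pairs: int = 100_000,
    rng: np.random.Generator | int | None = 0,
) -> float:
    """Mean squared Pearson correlation of dosages over a random subsample
    of inter-chromosome marker pairs.

    Pairs where either marker has zero dosage variance in the family are
    skipped; returns NaN (with no polymorphic pairs) rather than raising.
    """
    if family.n < 3:
        raise ValueError("r2_unlinked requires at least 3 progenies")
    if isinstance(rng, (int, np.integer)) or rng is None:
        rng = np.random.default_rng(rng)
    chrom = genetic_map.chrom
    p = len(genetic_map)
    i = rng.integers(0, p, size=n_pairs)
    j = rng.integers(0, p, size=n_pairs)
    keep = chrom[i] != chrom[j]
    i, j = i[keep], j[keep]
    if len(i) == 0:
        return float("nan")
    x = family.progeny_dosages.astype(float)
    xc = x - x.mean(axis=0)
    ss = (xc**2).sum(axis=0)
    poly = (ss[i] > 0) & (ss[j] > 0)
    i, j = i[poly], j[poly]
    if len(i) == 0:
        return float("nan")
    num = (xc[:, i] * xc[:, j]).sum(axis=0)
    r2 = num**2 / (ss[i] * ss[j])
    return float(r2.mean())


def metrics(
    a: np.ndarray, b: np.ndarray, ybar: float | None = None
) -> EvaluationMetrics:
    """PCC, RMSD and (given a reference scale ybar) CV[RMSD] = RMSD / ybar.

    PCC is NaN when either vector is constant (correlation undefined).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("metrics requires two equal-length vectors, n >= 2")
    rmsd = float(np.sqrt(np.mean((a - b) ** 2)))
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        pcc = float("nan")
    else:
        pcc = float(np.corrcoef(a, b)[0, 1])
    cv = rmsd / ybar if ybar is not None else float("nan")
    return EvaluationMetrics(pcc=pcc, rmsd=rmsd, cv_rmsd=cv)
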