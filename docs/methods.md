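# Methods

## Scope and model

`tetrasegvar` predicts the additive genetic variance among the F1 progeny
of a single bi-parental cross in an autotetraploid with tetrasomic
inheritance. The prediction is the quadratic form σ² = βᵀVβ, where β is a
vector of additive marker effects (trait units per copy of the alternative
allele) and V the covariance matrix of progeny allele dosages. V is
derived exactly under these assumptions:

- **bi-allelic markers, ploidy 4**, complete genotype matrices (missing
  calls are an error, not imputed);
- **random bivalent pairing** at meiosis: the four homologs form two
  bivalents, all three pairings equally likely; no double reduction;
- **no crossover interference**: map distance converts to recombination
  rate by Haldane, c = ½(1 − e^(−2d));
- **additivity**: dominance and epistasis contribute nothing to the
  predicted variance (a real limitation for heterozygous potato material,
  where dominance is known to matter);
- a **single genetic map** shared by both parents (cross-specific
  recombination landscapes are ignored).

The two-locus covariance is
cov(x_A, x_B) = bracket(P1, P2) · (1 − 2c), with
bracket = ⅓ Σ_h (A_h^P1 B_h^P1 + A_h^P2 B_h^P2) − 1/12 (x_A^P1 x_B^P1 +
x_A^P2 x_B^P2). Setting B = A and c = 0 yields the diagonal
var(x_A) = ⅓(x_A^P1 + x_A^P2) − 1/12((x_A^P1)² + (x_A^P2)²), because
A_h² = A_h for binary indicators. At c = ½ the covariance is identically
zero, so V is block-diagonal by chromosome and the full p × p matrix is
never materialised; between-chromosome terms are structurally absent
rather than approximated.

Three prediction modes share this machinery:

- **phased** — full blocks from parental haplotypes;
- **unphased** — diagonal blocks only (linkage phase unknown, LD terms
  unavailable); equals Σ_m β_m² var(x_m);
- **double_reduction** — the bracket multiplied by (1 − 4c/3)(1 + 2α),
  valid under *complete quadrivalent pairing* with locus order
  centromere–A–B and double-reduction rate α at the proximal locus. α is
  a single genome-wide scalar bounded at 1/6 (the classical
  complete-quadrivalent maximum; the derivation itself does not state a
  bound, so the limit is a package convention, flagged at call time).
  Note the factor at α = 0 is (1 − 4c/3), not (1 − 2c): the two pairing
  models differ even without double reduction, and the mode logs a warning
  that its assumptions are rarely met in real material. Diagonal entries
  are kept at the bivalent var(x_A) so that only the linkage terms carry
  the quadrivalent attenuation.

## Exact oracle

The closed form is certified against exhaustive enumeration. Under
bivalent pairing a genotype A1B1/…/A4B4 yields 36 two-locus gametes: 6
fully parental (probability (1−c)²/6), 24 one-parental/one-recombinant
(c(1−c)/12) and 6 fully recombinant (c²/6). At homolog-label resolution
the fully recombinant class actually contains 12 outcomes at c²/12 each;
they merge pairwise into 6 allele-content classes (the canonical table's
rows), and since only allele content enters dosage moments the aggregation
is harmless. Crossing two parents gives 36² = 1,296 progeny rows under the
product measure; the covariance computed from those rows equals the closed
form to ≤ 1e−12 for **all** 2⁸ × 2⁸ two-locus parental phasings and
c ∈ {0, 0.05, …, 0.5}. The test exploits that gametes of the two parents
are independent, so the 1,296-row covariance decomposes into two 36-row
covariances; the literal enumeration is additionally checked against the
decomposition on a random subsample.

## Forward simulator

The validation simulator draws, per chromosome: a bivalent pairing
(uniform over the three), and per bivalent one transmitted chromatid as a
two-state mosaic of the paired homologs. The homolog-switch points along
a chromatid form a Poisson process with rate 1 per Morgan, which
reproduces the per-interval switch probability ½(1 − e^(−2Δd)) — the
Markov walk over marker intervals and the Poisson construction are the
same stochastic process, and the latter costs O(crossovers) instead of
O(markers) random draws. Correctness is certified statistically: 10⁶
simulated gametes reproduce every cell of the exact 36-gamete distribution
within three Monte-Carlo standard errors at c ∈ {0.05, 0.2, 0.4}.

Families are simulated only at markers that matter for the statistic at
hand (e.g. QTL positions): restricting the crossover walk to a marker
subset is an exact marginalisation of the process, not an approximation.

## Estimators and the finite-family correction

From a family of n progeny with true genetic values g = Xβ:

- **M1** = Σ_chr sample-var(g_chr), ignoring between-chromosome
  covariance;
- **M2** = sample-var(g), including it;
- **cov_total** = Σ_{chr ≠ chr′} β_i cov̂(x_i, x_j) β_j over ordered
  chromosome pairs, computed as the off-diagonal sum of the covariance of
  per-chromosome genetic values (O(n·#chr²) instead of O(p²); the literal
  marker-pair double sum is retained as a test oracle).

All sample statistics use the n − 1 divisor; the double sum counts each
unordered chromosome pair twice. Both choices are forced by requiring the
identity **M2 = M1 + cov_total** to hold exactly (the printed double-sum
notation is ambiguous on both points; this is the resolution under which
the decomposition is an identity, and tests guard it). The finite-family
prediction is σ²_finite = σ²_phased + cov_total: in small families genetic
drift generates LD between unlinked loci that the infinite-family closed
form deliberately omits, and adding the sampled between-chromosome term
restores it. The mean squared correlation of dosages across unlinked
marker pairs (`r2_unlinked`, subsampled, default 10⁵ pairs) quantifies the
same mechanism and decreases with family size.

## Synthetic study and its defaults

The scenario harness reproduces the simulation-study design: a factorial
grid of mean family size {10, 20, 50, 100, 200, 500, 1000, 2000, 5000} ×
size distribution {uniform, gamma} × number of crosses {10, 50, 100, 250,
500} (90 scenarios), each replicated over 30 independent runs by default.
Per run, crosses are drawn from the half-diallel of the founder panel,
2,000 QTL positions are re-drawn while the multiset of effect sizes —
gamma(k = 2, θ = 0.2), positive — stays fixed across a study's runs, and
M1/M2 are compared with the phased/unphased closed forms by Pearson
correlation (PCC) and root-mean-square deviation (RMSD), with medians
across runs.

Founders are synthetic: 100 parents by default, 12 chromosomes of ~1
Morgan with 300 uniformly placed markers each, homolog alleles i.i.d.
Bernoulli(0.5). This emulates the randomly-assigned-phase panel of the
original design at reduced marker density; it does **not** emulate real
LD structure among founders, realistic allele-frequency spectra,
relatedness, genotyping error or map error. Passing tests therefore
demonstrate the internal consistency of derivation, simulator and
estimators under the stated meiosis model — not robustness to real-data
phasing or map inaccuracies. The gamma family-size distribution's shape
is not specified anywhere; the package uses shape k = 2 (scale set by the
target mean, sizes rounded and floored at 2) as a convention, logged in
the module.

Problem sizes in the shipped tests and the acceptance script are chosen
as desk-scale defaults: the headline concordance check runs 50 crosses at
family size 5,000 with 2,000 QTL (closed form vs M1, PCC ≥ 0.99); the
grid-directionality checks run a 3 × 2 × 2 sub-grid at 10 runs on a
smaller panel (20 parents, 5 chromosomes), where the qualitative claims
(PCC rises with family size; M1 beats M2 in small families; uniform beats
gamma sizes; the number of crosses is irrelevant) are scale-free. The
uniform-vs-gamma comparison uses 30 runs because the median PCC at mean
size 10 is noisy with fewer.

## Numerical choices

- Enumeration and closed forms use plain double precision; the oracle
  tolerance is 1e−12, and c = ½ gives an exactly zero factor, so the
  unlinked covariance is 0 to the last bit.
- βᵀVβ can round off slightly negative for near-monomorphic crosses;
  values in (−1e−9, 0) are clamped to 0 with a logged warning, anything
  more negative raises (the true progeny covariance matrix is positive
  semidefinite, so a larger negative indicates corrupted input).
- Map positions are accepted in Morgan or centiMorgan and normalised to
  Morgan on input; co-located markers (d = 0, c = 0) are legal and are
  not merged.
- Per-run/per-study randomness derives from `numpy` `SeedSequence`
  spawning, so every CLI entry point and the acceptance script are
  bit-reproducible under a fixed seed.

## Known limitations

Additive effects only; a single shared map; no missing-data handling; the
double-reduction mode's assumptions (complete quadrivalents,
centromere-proximal locus order) are rarely satisfied in practice and the
mode has no simulator counterpart here (the forward simulator never
performs double reduction); marker-effect estimation (e.g. rrBLUP) is out
of scope — effects are consumed as input.
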