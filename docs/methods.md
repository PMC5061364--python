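# Methods

This note documents the models, estimators and numerical conventions
implemented in `ventpop`, the design choices made where several
reasonable conventions exist, and what the synthetic-data tests do and
do not demonstrate about real data.

## Data model and quality screen

Input is a codon-aligned set of protein-coding mtDNA sequences (mtCOI,
~600–675 bp) with per-specimen (species, region, site) metadata, either
embedded in FASTA headers as `key=value` tokens or supplied as a TSV
sample sheet.  Reading frame is configuration (`frame_offset` ∈
{0, 1, 2}) rather than auto-detected: automatic frame identification is
alignment-software territory and would make the screen nondeterministic.
The genetic code defaults to the invertebrate mitochondrial table
(NCBI table 5), taken from Biopython.

The QC screen rejects a sequence when (a) any internal gap run in the
aligned sequence has a length that is not a multiple of 3 (a
frame-shifting indel), or (b) its in-frame translation contains a stop
codon before the last called codon.  Both symptoms indicate a nuclear
mitochondrial insertion (NUMT) rather than the functional marker.
Codons containing gaps or ambiguity codes cannot be called and are
skipped; a stop in the final complete codon is treated as terminal and
allowed.

Per-population analyses use complete-case columns: a column is retained
only when every sequence of the population carries an unambiguous
A/C/G/T there.  Ambiguity codes are treated as missing rather than as
partial information; this is the "sites used / sites in alignment"
convention of standard diversity tables.  Populations with fewer than 4
specimens are carried through reporting (sequence and haplotype counts)
but excluded from estimation; their statistics print as "-".

Coordinates are 0-based internally; all user-facing reports are 1-based.

## Diversity statistics

* **Haplotype diversity** uses Nei's unbiased estimator
  Hd = n(1 − Σ p_i²)/(n − 1) over exact-match haplotype frequencies on
  the masked columns.
* **Nucleotide diversity** is the mean over all sequence pairs of the
  per-site difference proportion; under the Jukes–Cantor option each
  *pairwise* proportion p is corrected to d = −(3/4) ln(1 − 4p/3) before
  averaging (the standard corrected-π estimator; correcting the average
  instead would be the other convention).  p ≥ 3/4 makes the correction
  undefined and raises an error naming the pair.
* **π_a/π_s** follows the Nei–Gojobori (1986) method: per codon,
  synonymous site counts are the per-position fractions of single-base
  changes that preserve the amino acid (changes into stop codons count
  as nonsynonymous); per codon pair, differences are classified by
  averaging over all orderings of the differing positions, excluding
  pathways through stop codons (with an all-pathways fallback when every
  pathway is blocked).  Per-pair proportions are JC-corrected and then
  averaged.  The ratio reports as "-" when both components vanish, 0
  when only π_a vanishes, and infinity when only π_s vanishes.
* **p-distances** are uncorrected with pairwise deletion of non-ACGT
  positions.  The within-group standard error is the standard deviation
  of the group mean over site-resampling bootstrap replicates (500 by
  default) — columns, not specimens, are resampled, matching the
  convention of distance bootstrapping.

## Demography statistics and their null distributions

* **Tajima's D** = (k − S/a1)/√(e1·S + e2·S(S−1)) with the 1989
  constants; k is the mean pairwise difference count on masked sites.
* **Fu's Fs**: S′ = P(K ≥ K_obs | θ = k) under the Ewens sampling
  formula, Fs = ln(S′/(1 − S′)).  P(K = j) is computed exactly with
  unsigned Stirling numbers of the first kind (big-integer recurrence,
  log-space conversion), so no asymptotics enter even at n = 83.
  S′ is clamped to [10⁻⁴, 1 − 10⁻⁴] and flagged when it saturates, so
  Fs stays finite (a monomorphic-haplotype sample would otherwise give
  −∞).
* **R2** = √(Σ(U_i − k/2)²/n)/S, with U_i the number of minor-allele
  singletons carried by sequence i.  Without an outgroup there is no
  polarisation, so "singleton" means minor-allele count 1 at a column;
  every count-1 allele of a segregating column contributes.
* **Raggedness** is the sum of squared steps of the relative mismatch
  distribution *including both boundary steps* (from 0 into the first
  class and from the last class back to 0): a point-mass distribution
  scores 2 and {0.5, 0.5} scores 0.5.  This is a deliberate convention
  choice — the textbook Harpending index includes only the trailing
  boundary (point mass → 1).  Values on smooth unimodal distributions
  are nearly identical under both conventions because the boundary
  frequencies are then small.

**Significance** is empirical: `reps` (default 1000) neutral
constant-size coalescent samples without recombination are simulated at
a fitted θ, each statistic is recomputed, and P = (hits + 1)/(reps + 1).
The fitted θ is Watterson's S/a1 from the observed data; the
"population growth–decline" θ that older software fits internally is
not reproducible from published descriptions, so the documented,
config-exposed surrogate is used instead.  D, Fs and R2 are tested on
the lower tail (the expansion direction); raggedness on the
upper-or-equal tail.  Both orientations are available via the
`lower_tail` argument because the literature is inconsistent about the
direction for D/Fs.  Null replicates with S = 0 leave the statistic
undefined and are dropped from the denominator.

Power caveat: Tajima's D is a weak test.  In the package's own
simulations a majority of strongly-growing populations (growth rate 300
in coalescent units, θ = 30, n = 30) reach P < 0.05, but milder growth
regularly does not — which is consistent with how such tables look in
practice (many negative but "n.s." entries).

## Divergence

F_ST is the Weir–Cockerham (1984) variance-components θ adapted to
haploid data: sequences are single alleles, so the individuals-within-
populations layer drops out and, per haplotype allele,
a = (MSP − MSG)/n_c, b = MSG, with θ = Σa/Σ(a + b) summed over alleles.
Negative estimates are reported untruncated; the estimator's
small-sample floor for identical populations is −1/(n_c − 1).  A
distance-weighted Φ_ST (AMOVA on pairwise difference counts) is
available as `method="phi"`; the frequency-based θ is the default
because that is what the variance-components reference describes.
Significance comes from permuting sequences among populations with
sizes preserved, P = (hits + 1)/(reps + 1); "bootstrapping" in older
tables is this permutation procedure in the software that produced
them.

## Haplotype networks

The connection limit is probability-based: for j observed differences
over L sites, the Jukes–Cantor divergence d(j) at p = j/L implies
L·d(j) − j expected superimposed (hidden) changes; treating hidden
changes as Poisson, the probability that a j-step connection is free of
homoplasy is exp(−(L·d(j) − j)), and the limit is the largest j keeping
this at or above α (default 0.95), with a floor of one step.  This is
this package's own variant of the statistical-parsimony limit: it keeps
the defining properties (monotone in L, limit → 1 as α → 1) but is more
conservative than the classic TCS tables (7 steps at L = 657 versus
TCS's ~11); the exact published recursion is tied to unpublished
implementation details of the original program.

Construction is distance-ordered agglomeration: candidate haplotype
pairs within the limit are processed by increasing Hamming distance; a
pair is joined when its endpoints were in different components at the
start of its distance class, so equal-distance alternative bridges
between the same components are retained as reticulations (loops).
Multi-step joins insert d − 1 inferred intermediates (count 0) along a
deterministic path: sites are switched in ascending column order
starting from the higher-frequency endpoint (ties broken
lexicographically by node id).  Real TCS orders joins by cladogram
probabilities that are not reproducible; the frequency-then-lexicographic
rule imposes determinism and is order-invariant with respect to the
input.

Locality association is a chi-square statistic on the haplotype ×
locality table with a permutation null (locality labels permuted over
sequences).

## Synthetic data generator

The generator is a neutral Kingman coalescent (pairwise rate 1 in units
of 2N generations) with optional exponential growth — looking back, the
coalescence hazard scales as exp(g·t), so large g compresses internal
branches toward a star genealogy.  Mutations overlay as
Poisson(θ/2 × branch length), finite-sites Jukes–Cantor (uniform choice
among the three alternative bases), so the JC correction in the
diversity module is exercised nontrivially.  The codon constraint is
acceptance sampling: a candidate mutation that changes the amino acid is
kept with probability ω; with `suppress_stops` a mutation creating a
stop codon is always rejected, which guarantees that generated
alignments pass the ORF screen.  This emulates purifying selection well
enough to reproduce the π_a/π_s ≪ 1 regime (ω = 0.05 gives ratios
around 0.1) but it is not a codon substitution model: no
transition/transversion bias, no among-site rate variation, no CpG-type
context effects.  Consequently, passing tests demonstrate estimator
correctness and pipeline behaviour on data with the right *statistical
shape* (sample sizes 4–83, Hd 0.9–1, π ~0.003–0.015, singleton excess
under growth), not robustness to real mtDNA mutational idiosyncrasies.

Defaults mirror the study conditions: L = 657 sites, the invertebrate
mitochondrial code, and sample sizes in the 4–83 range for tests.
Seeds are mandatory; every run draws from a single seeded generator.

## Isolation-with-migration model and estimation

Two demes of constant diploid size N (default 10000 — an abundance-based
figure: 8 individuals per 64 cm² ≈ 1250/m² over an 8 m² vent field)
exchange migrants at backward per-generation rates m12/m21 (symmetric
model: both 10⁻⁴, so Nm = 1 migrant per generation; asymmetric: one
direction 0) and merge into an ancestral deme of size N_anc at T_div
generations (1000 or 100000 in the study design).  The ancestral size
defaults to N because sizes are held constant over time.  Datasets are
n_frag unlinked fragments of L = 600 bp at μ = 10⁻⁸/bp/generation;
within a fragment sites are completely linked (infinite-sites):
SFS-based estimation is insensitive to intra-fragment linkage, so
recombination is off by default and the `rec` field is carried only for
provenance.  Twenty diploid individuals per deme contribute 40 gene
copies each.

The simulator is an event-driven structured coalescent written in
scaled units (time in 2N generations, per-lineage migration rate
M = 2N·m).  Branch bookkeeping is by *lineage episodes* — a lineage's
descendant set is constant from its creation to its coalescence, so one
Poisson draw per episode places its mutations and one addition
accumulates its length into the joint-SFS cell (i, j) = (descendants in
deme 1, deme 2).  The test suite cross-checks the simulator against
msprime (marginal branch-length spectra) and against the closed-form
neutral expectations E[S] = θ·a1 and E[ℓ_i] = 2/i.

The observable is the folded joint SFS by default (no outgroup
polarises real data); folding pools cell (i, j) with its mirror
(2n−i, 2n−j) toward the smaller total count.  The expected SFS is
estimated by Monte Carlo over genealogies as expected branch length per
cell — no mutation sampling, which removes one layer of noise — with
zero cells floored at a small pseudo-count.

**Likelihood.**  `composite_loglik` is the multinomial composite
log-likelihood Σ obs·ln(expected proportion) over polymorphic cells.
SFS proportions, however, are invariant to the rescaling
(N, T, m) → (cN, cT, m/c), so the shape likelihood alone cannot identify
N once monomorphic cells are excluded.  `estimate_params` therefore
maximises the *Poisson* composite likelihood over absolute cell counts,
λ_ij = n_frag·μ·L·2N·E[ℓ_ij], which equals the multinomial term plus a
Poisson term on the total number of variable sites and identifies N
through the overall polymorphism level.  For fixed shape parameters
(τ = T/2N, M = 2Nm) the likelihood is concave in N with the closed-form
optimum N̂ = S_obs/(n_frag·μ·L·2·ΣE), so N is profiled out analytically
and the numeric search is two-dimensional: a coarse log-grid over
(τ, M) followed by Nelder–Mead on log coordinates.  Common random
numbers (one seed for all evaluations) make the Monte-Carlo surface
deterministic, and expected-SFS evaluations are cached by parameter
value, so a grid shared across pseudo-observed datasets is computed
once.  Search bounds: N ∈ [10², 10⁶], T ∈ [10², 10⁷], m ∈ [10⁻⁶, 10⁻²];
estimates clipped to a bound are flagged (`at_bound`).

Monte-Carlo budgets default to 150 genealogies per grid point and 400
per refinement step; these were chosen as the package's desk-scale
defaults and give median re-estimates within ~30 % of the truth for N
and ~20 % for m at 100 fragments (T_div is the weakly identified
parameter — with ongoing migration the sample's common ancestor can be
much younger than the split, and single-dataset T̂ scatters widely,
matching the known behaviour of SFS-based divergence-time estimation).

`run_performance_study` wraps the simulate-and-re-estimate loop over
models × divergence times × fragment counts × pseudo-datasets (the
published design uses fragment counts 10/100/1000/10000 with 20
pseudo-datasets per cell; the bundled acceptance run uses the
100-fragment symmetric cell with 5 pseudo-datasets, which completes in
about two minutes on one CPU) and records the per-dataset seeds.

## Geographic and abundance utilities

Inter-site distances are great-circle (haversine) on a sphere of radius
6371.0 km from degree-minute coordinates with hemisphere letters; comma
decimal separators are accepted.  Spherical distance reproduces the
published minute-precision distances to within ~1 km (TAG → Snake Pit:
306.1 vs 306.6 km printed); ellipsoidal geodesics are unnecessary at
that precision.  Note that the published ABE/Tu'i Malila distances are
mutually consistent only if the ABE longitude is 176°11'W rather than
the printed 177°11'W — the printed value appears to be a typo; the
package takes coordinates as given and does not silently "fix" inputs.
Abundance extrapolation scales a mean count per 64 cm² settlement
device by 10⁴/64 to individuals per m², times the vent-field area.

## Known limitations

* The mutation overlay has no transition/transversion bias; empirical
  mtDNA saturates faster at third positions than these simulations do.
* The TCS connection limit is a documented variant, conservative
  relative to the original program's tables.
* Fu's Fs P-values use the same empirical-tail convention as the other
  statistics; the conventional α = 0.02 significance cut-off for Fs is
  not applied automatically.
* T_div is weakly identified from folded joint SFS shape at these
  sample sizes; only N and m recovery is claimed.
* The pipeline assumes pre-aligned input; alignment itself (and
  automatic reading-frame detection) is out of scope.
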