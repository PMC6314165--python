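# Methods

This note documents the models, defaults and numerical choices behind
`epirilqtl`, and what the synthetic-data experiments do and do not show.

## Population model

The package targets epigenetic recombinant inbred lines (epiRILs): inbred
Arabidopsis lines from a Col-0 × *ddm1-2* cross segregating two parental
methylation epialleles at each DMR marker on a near-isogenic genome. The
population model is two-genotype (COL / DDM1) with no heterozygote class —
the lines are inbred. Epialleles are coded COL = 0, DDM1 = 1 for all
statistics.

### Epigenotype chain (simulator)

Along each chromosome epialleles follow a two-state Markov chain over the
ordered markers. For a gap of *d* cM the Haldane recombination fraction is
r = (1 − e^(−2d/100))/2, and the transition rates are

    T(COL -> DDM1) = 2 r p,      T(DDM1 -> COL) = 2 r (1 − p),

with *p* the stationary DDM1 frequency (default 0.3: the epiRIL backcross
design biases toward Col-0 epialleles). These rates are the unique choice
that (a) satisfies detailed balance with stationary (1−p, p), (b) reduces to
identity at r = 0, and (c) reduces to independent Bernoulli(p) draws at
r = 1/2. Adjacent-marker discordance is 4 r p (1 − p). The simulator models
marginal frequencies and linkage only, not the pedigree of backcross and
selfing generations.

### Genotype probabilities (scanner)

For Haley–Knott regression the scanner uses the *symmetric* two-state chain
(switch probability r in both directions), the standard inbred-line
approximation: P(DDM1) at a test position conditions on the nearest observed
flanking markers; one observed flank uses the single transition; no observed
flank falls back to the population DDM1 frequency at the nearest marker, so
probability columns are never missing. The mild mismatch between the
p-weighted simulation chain and the symmetric scanning chain is deliberate —
it mirrors the usual situation where the analysis model is an approximation
of the generating process — and does not bias the LOD calibration (verified
empirically by the permutation-calibration experiment). Kosambi's map
function is available as an alternative.

## QTL mapping

At each position the trait is regressed on intercept + P(DDM1) (+ cofactors)
and LOD = (n/2)·log₁₀(RSS₀/RSS₁), RSS₀ being the same fit without the
position term. With no cofactors this equals (n/2)·log₁₀(1/(1−r²)); the
permutation engine exploits that identity to compute all permuted-trait LOD
profiles as one matrix product after standardizing columns (cofactors are
projected out of both trait and genotype first). The per-position
least-squares route and the vectorized correlation route are cross-checked
in the test suite.

* **Significance**: empirical (1−α) quantile (`numpy` "higher" method) of the
  genome-wide max LOD over phenotype permutations; defaults 1000
  permutations, α = 0.05. Permutations shuffle trait values against intact
  epigenotype rows, preserving marker linkage structure.
* **Peaks**: greedy local maxima at or above threshold, separated by
  ≥ 10 cM and by a valley dropping ≥ 1.5 LOD below the smaller peak (without
  the valley rule every shoulder of a broad hill would be called).
* **Support intervals**: contiguous region with LOD within 1.5 of the peak,
  extended outward to the flanking observed markers.
* **Effects**: effect size is the fitted coefficient on the DDM1 coding at
  the peak; effect sign is sign(mean|COL − mean|DDM1), so negative means
  higher trait values in *ddm1*-derived epigenotypes.
* **Cofactors (MQM-style)**: candidates default to evenly cM-spaced markers;
  backward elimination removes the least significant candidate until all
  partial-F p-values ≤ 0.02. During a scan, cofactors within 10 cM of the
  test position, or correlated > 0.95 with it, are dropped at that position.
  The original cofactor choice this emulates is not reconstructable from
  available information, so evenly spaced candidates plus elimination is the
  package's documented scheme.
* **Missing data**: trait values are dropped pairwise per scan, never
  imputed; cofactor columns are mean-imputed (they are nuisance terms).
* **cM→bp projection**: linear interpolation between marker physical-interval
  midpoints, extended to cover the full physical intervals of markers inside
  the cM range (boundary markers belong to the QTL region); positions beyond
  the map clamp to the end markers, logged.

## Methylation scoring

ML = −post(U) + post(M) ∈ [−1, 1] per probe; [−1, −0.3) is hypomethylated
and [−0.3, 1] methylated — the −0.3 boundary belongs to the methylated side,
matching the quoted score ranges. Region scores are means over probes
overlapping a 0-based half-open interval. Methylation–trait association
regresses log₁₀ trait on continuous region ML (two-sided t-test on the
slope); a binary two-group Welch test is available, but the regression is
the default since the continuous score carries more information.
Cosegregation between region state and marker epiallele uses the 2×2
chi-square without continuity correction, switching to Fisher's exact test
when any expected count is below 5; a zero margin returns p = 1 with a
degenerate flag.

## cis funnel

Stages run in order with short-circuiting: interval membership → optional
pathway membership (local table; no live database access) → association
(P < 0.05 in any of promoter / gene body / 1 kb downstream; no
multiple-testing correction by default, matching raw-p reporting;
Benjamini–Hochberg can be applied downstream) → cosegregation of the most
significant region's state with the peak marker (P < 0.05) → ranking.
Rank weights are promoter 3, gene body 2, downstream 1 (the ordinal
preference made numeric), +1 for a TE within 1 kb, +1 for supplied
expression evidence. Promoter = 1000 bp upstream of the TSS, strand-aware,
clipped at chromosome bounds; the extent is configurable because no
canonical value exists.

## trans discovery

Five screening criteria per gene × QTL: promoter probes exist; their
methylation varies across the population; the parents are polymorphic at
those probes; at least two consecutive (genomically adjacent) promoter
probes correlate with the peak-marker coding at p < 0.05 with the same
sign; and the gene body lies outside the projected QTL interval. Promoters
of passing genes are searched for maximal exact matches (≥ 21 nt, forward
and reverse complement; N never matches) against the QTL interval sequence,
by seed-and-extend on 21-mers — any seed inside a maximal match extends to
the same match, so de-duplication by start coordinates is exact. Matches
decompose into all 21/22/23/24-nt windows on both strands
(Σₖ 2(L−k+1) candidates for a length-L segment; 21–24 nt spans the plant
sRNA size classes, 24 nt being the RdDM class).

The AGO-loading scorer is a pluggable interface. The default is an explicit
sequence-rule heuristic reflecting canonical AGO sorting preferences
(24 nt with 5' A → AGO4 0.9; 21–22 nt with 5' U → AGO4 0.1, AGO6/9 0.4;
otherwise 0.2 everywhere); any object with the same `score` method —
including a lookup of precomputed probabilities — can replace it. Library
matching is exact by default (≤ 2 mismatches supported by brute force),
sense or antisense, with palindromic candidates counted once. TE proximity
is strict: a gap of 999 bp counts as "within 1 kb", 1000 bp does not.
The final ranking orders genes by eQTL colocalization, then WT-library
support, then best AGO score; eQTL scans run on log₂ relative expression
from qPCR Ct values normalized against reference genes
(relative expression = efficiency^(mean Ct_refs − Ct_target), efficiency 2).

## Synthetic data: what it emulates, and what it does not

Defaults emulate the study design the package targets: 126 DMR markers on
five chromosomes (~4 cM spacing, 20 kb physical spacing), ~100 lines,
DDM1 frequency 0.3, probe posteriors coupled to the local epigenotype with
a 10% DDM1→WT reversion rate and Gaussian posterior noise (sd 0.05),
log-normal metabolite intensities (baseline log₁₀ ≈ 3 ± 0.3) with
per-(batch, metabolite) offsets (sd 0.05, four batches), block-correlated
noise (blocks of 10, sd 0.08) and iid noise (sd 0.1, giving CVs in the
20–30% range typical of untargeted profiling), planted fractional effects
in the 4–41% band, transgressive metabolites gated on a two-marker
DDM1/DDM1 combination, a detection floor at 1% of the per-metabolite
median, flowering time ~30 d with optional marker effects and
FT-proportional metabolites, promoter-embedded repeat segments for trans
targets with a nearby annotated TE, and WT/ddm1 24-nt libraries with
Poisson counts depleted 10× in *ddm1*. Gene promoters default to stable
methylation (the common non-DMR case); coupled and randomly varying
promoters are explicit options.

What passing tests show: the estimators recover what the generators plant,
at the stated sizes, under Gaussian noise and exact Markov linkage. What
they do not show: robustness to real MeDIP posterior miscalibration,
non-Gaussian intensity distributions, segregation distortion beyond the
stationary chain, genuine pedigree structure, or sRNA libraries with
sequencing error — none of which the generators model.

## Numerical choices and degenerate inputs

* r² is clipped to [0, 1−1e-15] before the log; constant traits give LOD 0
  everywhere; rank-deficient fits go through `lstsq`.
* Simulated probe posteriors are clipped to [0, 1]; posterior pairs must
  sum to 1 within 1e-6 on ingest.
* Readers reject malformed input (unknown call symbols name the offending
  cell; orphan markers are listed) rather than coercing.
* Output CSVs use a fixed `%.10g` float format and sorted table order, and
  each run writes a manifest with config hash and seed, so identical
  (config, seed) runs are byte-identical.
* Chi-square fixtures are asserted against hand-computed Σ(O−E)²/E values
  (e.g. table [[20,5],[4,21]] → 20.5128; a diagonal 2×2 table gives
  χ² = n).

## Problem sizes used in the verification experiments

The calibration experiment uses 500 null traits on one 100-line population
with 1000 permutations each (feasible because the permutation scan is a
single matrix product); interval-coverage uses 200 fresh populations of 100
lines with a planted effect explaining 25% of variance and 200 permutations
per threshold; effect-size recovery uses one 2000-line population;
the trans end-to-end run uses 300 lines, three planted targets with 30–41%
effects and 50 decoy genes; the exhaustive match-oracle comparison runs
1000 random sequence pairs up to 200 bp. These sizes were chosen so each
experiment's Monte-Carlo error is small relative to the property being
checked.

## Known limitations

* The cofactor-seeding scheme and the promoter extent are documented
  surrogates for choices that are not reconstructable or never defined.
* The default AGO scorer is a coarse heuristic; quantitative loading
  probabilities require an external model supplied through the scorer
  interface.
* The pleiotropy table reports a Pearson correlation t-test p-value for
  trait pairs sharing a region; it is labelled as such and is not a
  chi-square statistic.
* `eqtl_scan` and the pipeline treat expression like any other trait; no
  expression-specific normalization beyond reference-gene ΔCt is applied.
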