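# Methods

This note documents the models implemented in `insulome`, the choices
behind their defaults, and what the synthetic-data validation does and
does not establish.

## Scope and data model

The package analyses unphased diploid genotypes at common biallelic
autosomal SNPs — the kind of panel produced by genotype imputation of
low-coverage ancient genomes after filtering to MAF ≥ 5% and
missingness ≤ 2%. All genetic lengths are in centiMorgans, obtained by
linear interpolation of physical positions on a per-chromosome bp→cM
anchor table; positions outside the anchor span clamp to the terminal
anchor. Physical coordinates are 1-based (VCF convention) internally and
0-based half-open (BED convention) in segment files.

## ROH calling

`roh.call_roh` reproduces the PLINK `--homozyg` windowed heuristic with
the parameter set `--homozyg-window-het 0 --homozyg-snp 50 --homozyg-kb 1
--homozyg-density 5000 --homozyg-gap 5000`. Parameters not fixed by that
string (`window_missing_max = 5`, `window_hit_fraction = 0.05`) take
PLINK's documented defaults. The implementation is vectorised but its
semantics are pinned, case by case, to a deliberately literal brute-force
re-statement of the window rules (`tests/oracles.py`); the suite checks
exact equality of the two on hundreds of random genotype vectors.

F_ROH is the summed genetic length of reported segments divided by the
total map length of the analysed autosomes. The denominator is genetic
(cM) by default — physical and genetic denominators differ only through
map nonuniformity, and downstream consumers of F_ROH here (null-cloud
classification, Ne exclusion) use the cM convention consistently.
`min_report_cM` re-thresholds reported segments (0/5/10/15 cM
re-analyses are parameterisations, not separate code paths).

## Synthetic panels and ground truth

The simulator represents every haplotype as a mosaic of founder
haplotypes (per chromosome: breakpoints in cM plus founder ids). Meiosis
draws a Poisson(map length in Morgans) crossover count per chromosome
with uniform cM positions and no interference, and splices parental
mosaics exactly. Ancestry is therefore tracked without approximation:
ground-truth ROH and IBD segments are interval intersections of mosaics,
and the realised inbreeding coefficient of any simulated individual is a
deterministic function of its mosaics.

Founder haplotypes are mutually unrelated: allele frequencies are drawn
from a Beta distribution truncated to [0.05, 0.95] (inverse-CDF
sampling) and alleles are independent across sites and haplotypes. There
is no mutation model — over tens of generations, new mutations at common
SNPs are negligible — and founders carry no LD. Population simulation is
diploid Wright–Fisher with random mating (two distinct parents, no
selfing) per deme; migration moves each newborn with probability *m* by
randomly permuting deme labels within the migrant pool, which preserves
deme sizes exactly. Genotype error is modelled as independent per-allele
miscalls (each of the two alleles flips with rate ε) plus independent
genotype dropout.

What the synthetic panel does **not** emulate: linkage disequilibrium
among founders, imputation-correlated errors (real imputation errors
cluster in low-LD and low-coverage regions), reference-bias, allele
frequency drift between the analysed population and the frequency panel,
and non-equilibrium site-frequency spectra. Passing tests therefore
demonstrate correctness of the estimators under their own model
assumptions and calibrated behaviour on idealised common-SNP panels, not
robustness to imputation artefacts.

### SNP density and caller resolution

The ROH caller requires 50 SNPs per segment, so a panel with *d* SNPs/cM
cannot report segments shorter than ≈ 50/*d* cM. Calibration of
simulated F_ROH against analytic pedigree expectations (1/4 … 1/16) is
only meaningful when this floor sits well below the tract-length scale
of the deepest pedigree loop (first cousins: mean tract ≈ 17 cM, and
≈ 2% of tract mass below 3.3 cM). The calibration panels therefore use a
uniform 25 SNPs/cM (floor 2 cM, < 0.7% truncated mass); density is
uniform per cM rather than per chromosome so that resolution does not
vary with chromosome length.

## Pedigree nulls and consanguinity classification

Six pedigrees produce an inbred focal offspring from first-degree (full
sib, parent–offspring), second-degree (avuncular,
grandparent–grandchild) and third-degree (first cousins,
great-avuncular) parental pairs, with expected inbreeding
F = (1/2)^(degree+1). Each scenario is gene-dropped 400 times from
founders sampled without replacement, and every replicate is pushed
through the same ROH caller as the query genomes, so the null clouds in
(N_ROH, F_ROH) space absorb caller behaviour as well as genealogical
variance.

Classification makes the visual "inside / at the edge of / outside the
simulated distribution" judgement quantitative: the Mahalanobis distance
of the query to each cloud (covariance regularised by +1e-9 on the
diagonal; identity fallback for degenerate clouds) is converted to the
empirical quantile of that distance among the cloud's own points.
Verdicts are *inside* below quantile 0.90, *edge* in [0.90, 0.99],
*outside* above; nearest-cloud ties break toward the lower degree. Note
that a genome more extreme than a cloud (e.g. a sib-mating offspring
with additional background inbreeding) is correctly *outside* that
cloud while still having it nearest.

## Effective population size from the ROH spectrum

For a diploid genome the two copies of a locus coalesce *t* generations
back with geometric probability P(T=t) = (1/2Ne)(1 − 1/2Ne)^(t−1).
Conditional on *t*, recombination over the 2*t* meioses is Poisson with
rate 2*t* per Morgan, giving the expected density of ROH segments of
length *x* Morgans on a chromosome of *G* Morgans as
(2t)²(G − x)e^(−2tx) interior plus 2·(2t)e^(−2tx) edge terms.
Marginalising over *t* (truncated at t_max = 2000; the tail mass is
checked to be < 1e-6 at the lower search bound) and summing over
chromosomes yields λ(x); segments are treated as independent, giving a
composite Poisson likelihood over 1000 equal bins of [0.04, 0.5]
Morgans. λ is validated against a direct Monte-Carlo simulation of the
same generative story (draw T, drop breakpoints, tally pieces) at three
(Ne, map) settings.

Only bins whose midpoints lie within the segment-selection window
(default 4–20 cM) enter the likelihood: segments outside the window are
excluded from the counts, so including longer bins with forced-zero
counts would penalise every Ne that predicts long segments and bias the
estimate upward. The window's rationale: below 4 cM, detection and map
error dominate; above 20 cM, recent pedigree loops rather than
population size dominate. Individuals classified as products of close
consanguinity (inside/edge of a first- or second-degree cloud) are
excluded before pooling for the same reason.

The MLE maximises the likelihood over ln Ne (bounded scalar
minimisation, tolerance 1e-4 in ln Ne, search range [10, 1e6]); the 95%
CI is the profile-likelihood drop of 1.92 (χ²₁/2), found by bisection on
each side. Estimates or CI ends that hit a search bound are reported at
the bound with an explicit `at_boundary` flag. CI calibration is
verified by simulation: over model-simulated spectra at Ne = 500 the CI
covers the truth at the nominal rate.

A separate utility computes the harmonic mean of a supplied per-
generation size trajectory over generations 5–30 (inclusive), the
conventional scalar summary of a recent-trajectory estimate. Trajectory
*estimation* from IBD is out of scope; only the input-eligibility rule
(≥ 90 within-group segments ≥ 2 cM) and this summary are provided.

End-to-end validation fits the spectrum of ground-truth ROH segments
from forward-simulated Wright–Fisher populations (N = 500, 40
generations, 30 sampled genomes). Two known, documented gaps separate
this from perfection: (i) ground-truth rather than called segments are
used, because desk-scale SNP densities put the caller floor inside the
4–20 cM window (caller fidelity is established separately by the oracle
equivalence); (ii) a 40-generation simulation truncates coalescences
older than 40 generations — about 18% of the expected 4–20 cM mass at
Ne = 500 — which biases the estimate upward by roughly 20–30%. The
recovery check uses a factor-1.5 band that accommodates this.

## IBD detection and geography

Each site is scored with a log₁₀ likelihood ratio of an IBD1 model
(shared allele drawn at population frequency; each individual adds one
independent population allele) against a non-IBD model (independent
Hardy–Weinberg genotypes), both perturbed by per-allele miscalls at
ε = 0.005. Missing genotypes contribute zero. The score table is checked
to 1e-12 against an exhaustive enumeration of true alleles and flip
patterns. Per chromosome, maximal-scoring disjoint intervals of the
score sequence (recursive max-subarray splitting; the flanks of the best
interval are re-scanned) are reported when total LOD ≥ 3 and genetic
length ≥ 2 cM, with endpoints at the outermost contributing SNPs. Sites
are treated as independent given IBD state — defensible after MAF
filtering and LD pruning, and a stated limitation otherwise. The
detector is an independent implementation of the LOD-scan contract, not
a byte-compatible clone of any particular tool; it is validated by
planted-segment recovery (recall of true ≥ 4 cM sib-pair segments ≥ 90%
with FDR ≤ 5% under ε = 0.005 errors).

Relatedness is the robust kinship
φ̂ = (N_het,het − 2·N_opp,hom)/(N_het(i) + N_het(j)) over sites
non-missing in both individuals (≥ 100 required). Pairs with
φ̂ > 0.0442 — the conventional 3rd/4th-degree boundary, so third-degree
and closer relatives — are pruned greedily from the top down, removing
the member with more missing genotypes (tie: later panel id).

The pairwise IBD matrix holds total shared cM (and counts) per pair,
zero diagonal. Group summaries average per-pair *totals* within and
between groups with ≥ 2 members ("average IBD shared" admits a
per-segment reading; the per-pair-total reading is adopted for
consistency with the total-length matrix, and flagged here for users).
PCA treats matrix rows as feature vectors, mean-centres columns, and
decomposes by SVD; variance fractions are squared singular values over
their total.

## Pipeline and reproducibility

`insulome run --config run.cfg` executes: site filters (missingness
≤ 0.02, MAF ≥ 0.05, optional r² ≤ 0.5 LD pruning in 50-SNP windows
stepped by 2) → relative removal → ROH + F_ROH → pedigree nulls →
classification → per-group Ne → pairwise IBD → group summary + PCA,
writing a TSV/JSON bundle plus a run log with versions, seed and
parameters (no timestamps). A single global seed fans out to per-stage
seeds via `SeedSequence([seed, crc32(stage)])`; re-running a config
reproduces every output byte-for-byte. Any stage failure aborts with the
stage name and leaves a `FAILED` marker beside the partial outputs.

The bundled demo simulates a small "island" deme (N = 60) against a
larger "mainland" (N = 180) for 12 generations with one planted
sib-mating offspring, at a scale chosen to finish in seconds. At such
deme sizes background drift inbreeding is substantial, which is the
point of the island scenario — but it means several island genomes are
legitimately flagged by the consanguinity classifier, as happened with
real insular material.

## Numerical and degenerate-input choices

- ROH spectrum histogram bins are left-closed right-open; a segment on
  the last edge counts as remainder, never silently in-bin.
- Zero usable segments in an Ne fit return the upper search bound with a
  boundary flag and a warning rather than failing, so pipelines over
  many groups degrade gracefully.
- All-missing individuals yield an empty ROH list with a warning.
- F_ROH > 1 + 1e-9 is fatal (overlapping segments or a wrong
  denominator); smaller overshoot is clipped.
- LD pruning and relative filtering are deterministic given input order;
  pruning twice equals pruning once.
- Sizes used in the validation suite (6 × 150 cM or 22-autosome maps,
  15–25 SNPs/cM, populations of 120–1500 haplotypes) were chosen as the
  smallest at which the statistical checks are sharp; the methods are
  scale-free in the map and density parameters.
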