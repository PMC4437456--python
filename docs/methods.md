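# Methods

## Orthologue clustering

Proteins from all strains are compared all-vs-all. Two proteins are
*linked* when some similarity hit between them (in either direction)
passes three filters: e-value ≤ `evalue_max` (default 10⁻³), percent
identity ≥ the identity threshold, and alignment coverage ≥ the coverage
threshold on **both** sequences. Coverage is always recomputed as
alignment columns over sequence length; requiring the minimum of query
and subject coverage is the strictest symmetric reading and keeps the
hit graph undirected (a `require_both_directions` switch demands a
passing hit in each direction instead). Clusters are the connected
components of the link graph (single linkage); proteins with no
surviving link become singleton clusters.

The identity/coverage working point is not assumed: clustering is
repeated on the full 70–100 × 70–100 grid in steps of 2 and the pair
maximizing the number of core clusters is kept, ties broken towards the
stricter (larger) thresholds. The whole grid table is reported so the
choice is auditable.

For desk-scale panels the hits can be computed internally with a
Smith–Waterman aligner (BLOSUM62, gap open −11 / extend −1, identity =
matches over alignment columns). E-values for the internal aligner use
the Karlin–Altschul form E = K·m·n·e^(−λS) with fixed constants
λ = 0.267, K = 0.041 (gapped BLOSUM62 defaults). Ingesting external
tabular hits (the familiar 12-column dialect extended with query/subject
lengths) is the reference path for real panels.

## Pan-genome and profiles

The presence/absence matrix keeps per-cell copy counts, so paralogous
expansions remain visible even though association uses only 0/1. Core =
columns present in every strain; strain-specific = present in exactly
one. Before association, accessory columns are collapsed into unique
phylogenetic profiles. Clusters containing exactly one protein
(necessarily strain-specific singletons) are excluded by default — they
carry no linkage signal and inflate the profile count; a flag optionally
drops *all* single-strain clusters instead, since either reading of
"strain-specific exclusion" is defensible. Profile identifiers are a
SHA-1 prefix of the pattern string, so they are stable across runs and
strain-order permutations of the same panel are detectable.

## Strain phylogeny

The faithful path is a user-supplied rooted newick (e.g. from an
external maximum-likelihood tool); ML inference itself is out of scope
here. The self-contained fallback averages per-cluster pairwise
p-distances (mismatches over aligned non-gap columns of a global
alignment) across single-copy representatives of the core clusters —
clusters with paralogs contribute their longest member per strain —
then applies canonical neighbor joining. Negative NJ branch estimates
are clamped to zero with the deficit moved to the sibling branch so the
pair's total is preserved. The tree is rooted at the midpoint of the
longest leaf-to-leaf path.

The Brownian-motion covariance V has V_ij = shared root-to-MRCA branch
length and root-to-leaf depths on the diagonal. V is used
**unnormalized**: the Brownian rate is absorbed into the GLS residual
variance, to which the t-test is invariant (checked to 1e−9 under
rescaling).

## Association model

Traits scored on the 0–1 grid are recoded to 0/1. The default rule
counts any positive score as ability (the grid encodes *intensity*, not
certainty); a `strict` rule counting only full scores is available.
Strains with missing scores are dropped per trait; traits with fewer
than two positives or two negatives among the documented strains are
flagged untestable and skipped.

Each testable trait × profile pair gets two tests:

* **Fisher**: two-sided exact p from the 2×2 occurrence table. Fast and
  assumption-free, but blind to phylogeny: a trait and a profile that
  both follow one deep clade look associated even when the trait has no
  genetic cause in that profile.
* **Phylogenetic GLS**: y = b₀ + b₁x + ε with Cov(ε) = σ²V, solved in
  closed form via Cholesky whitening; σ̂² uses n − 2 degrees of freedom
  and the two-sided p comes from the t distribution. The binary
  response is modelled linearly (not logistically), matching standard
  comparative-method practice for this design; the GLS estimate is
  what an estimating-equation fit converges to under this covariance,
  and the closed form keeps the test exact and fast. When a profile
  matches the trait perfectly the residual is zero: the fit is reported
  as b₁ with an infinite statistic and p = 0 (exact fits are detected
  with a relative tolerance of 1e−12 so floating-point dust does not
  leak into the statistic).

If V is numerically singular (zero-length tips), 1e−8 × mean diagonal is
added once; failure after that raises an error naming the
indistinguishable tip pairs rather than silently degrading.

Significance in the scan report uses a stringent fixed threshold of
10⁻⁵ per method — a Bonferroni-style guard appropriate for several
hundred profiles — rather than an adaptive FDR, so the flag's meaning
does not drift with panel size.

### Calibration

Under continuous Brownian traits simulated on the scan tree, the GLS
p-values are exactly t-distributed and empirically uniform
(Kolmogorov–Smirnov over 1000 replicates). Binary traits obtained by
thresholding a Brownian character at its median violate the Gaussian
model, so exact calibration is not guaranteed; across independently
simulated accessory-gene profiles the 5%-level rejection rate sits near
0.05 (bounded in [0.03, 0.07] in the tests). For any *single* fixed
clade-shaped profile the rate can drift a few points either way — a
known property of binarized comparative tests, which is why the
calibration checks marginalize over profiles the way a real scan does.
Against clade-shaped profiles, thresholded-BM traits give systematically
smaller Fisher than GLS p-values, which is precisely the inflation the
phylogenetic correction exists to remove.

## Gene-decay screen

Coding sequences are translated codon-by-codon under NCBI genetic code
table 11. Internal stop codons are recorded as 1-based codon indices;
fragments are the amino-acid runs between stops with the terminal stop
excluded, so Σ fragments = full length − number of internal stops. No
re-initiation at internal start codons is modelled — fragment arithmetic
is kept purely positional (a 447-aa protein with a stop at codon 199
yields 198 + 248). A sequence whose length is not divisible by 3 is
flagged frameshift-suspect and scanned on the trimmed frame; true
frameshift detection from read alignments is out of scope.

Within a cluster, the reference length is the median full length of
members without internal stops (fallback: the maximum, with a warning).
A member is called a pseudogene if it has any internal stop or its
longest fragment is below 80% of the reference. The paper trail behind
the 80% default: observed decayed fragments sit at ≈55% of full length,
intact members at 100%, so 80% separates them with margin on both
sides; it is a parameter, not a constant.

## GC-island screen

Sliding-window GC (window ≥ 100 bp, stride ≤ window, N bases excluded
from every denominator) is compared with the sequence-wide GC; maximal
runs of windows at least `min_offset` points below it (default 5) that
span at least `min_span` bp (default 3 kb) are flagged with their mean
GC. Defaults suit a high-GC (~67%) genome carrying islands around 57% —
a 10-point contrast — while tolerating local fluctuation. Flags are
strand-symmetric by construction. Coordinates are 0-based half-open.

## Synthetic panels

The generator emulates the study conditions the pipeline targets, with
known truth for recovery scoring:

* **Tree**: pure-birth (Yule) with rate 1, stopped at n strains plus one
  final exponential epoch, so E[depth] = Σ_{k=2..n} 1/(k·λ). Default
  n = 22. Only relative shared-path structure matters to the GLS, so a
  birth–death model would add parameters without adding test power.
* **Gene content**: `n_core` columns present everywhere (default 100);
  accessory genes gained as a Poisson process (rate per unit branch
  length) and lost at a constant hazard below the gain point — or, for
  fixed-size studies, exactly `n_decoy_accessory` gains (default 200)
  placed proportionally to branch length, i.e. the same process
  conditioned on its total.
* **Causal island**: `island_size` (default 3) identical presence
  columns under one uniformly chosen internal branch whose clade leaves
  at least two strains outside, so the derived trait is always testable.
* **Phenotypes**: the binary trait is 1 iff every causal gene is present
  and un-decayed; the quantitative trait is functional causal genes /
  island size, quantized *down* to the 0.25 grid (mirroring conservative
  visual scoring — and documented so tests can be exact); a null trait
  thresholds an independent Brownian character at its median.
  Nonsense mutations (default fraction 0) are planted only in causal
  genes of island carriers, at a codon uniform in the central 80% of
  the gene — reproducing the "gene present but pseudogenized" situation.
* **Sequences**: each cluster gets a random ancestral protein
  (300–1500 codons); carrying strains receive copies independently
  mutated at per-site rate 1 − √(target/100), so expected pairwise
  identity ≈ the 85% default. Codons are drawn from a synonymous pool
  exponentially reweighted by codon GC, with the exponent solved by
  bisection to hit 67% GC for background genes and 57% for island
  genes — protein sequences are unaffected, so island detection must
  work from DNA alone. The ancestral amino-acid composition is biased
  towards Ala/Gly/Pro/Arg as in high-GC actinobacterial proteomes;
  without that bias a 67% target is unreachable by synonymous choice
  alone. Genomes concatenate each strain's CDS with random spacers, the
  island forming one contiguous block.

What the generator does **not** emulate: indels and recombination,
paralogous families (copy counts are 0/1 in simulation), transposase
flanks around islands, rate variation across genes, and assembly or
annotation error. Passing recovery tests therefore demonstrate the
statistical machinery under the model's assumptions, not robustness to
real-data artefacts.

## Problem sizes in the shipped checks

The test suite and `scripts/acceptance.py` run the clustering oracle on
200 random instances, the Fisher enumeration on 500 random tables, the
GLS calibration on 1000 null replicates, island recovery on 50 seeded
22-strain panels, and the sequence-level screens on 8-strain panels with
shortened genes (100–800 codons) — sizes chosen so each check carries
clear statistical power while the whole suite stays desk-scale.

## Known limitations

* Genome-scale counts from real 21-strain panels (10⁴ clusters from
  ~10⁵ proteins) require external all-vs-all search output; the internal
  aligner is for small panels and validation.
* The GLS treats the tree as known; uncertainty in tree inference is
  not propagated.
* Only the premature-stop decay mechanism is detected; frameshifts are
  flagged by length only.
* The grid search optimizes core-cluster count alone, as specified; it
  does not penalize over-merged accessory clusters.
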