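# Methods

This note documents the statistical conventions, default parameters,
and design choices behind `snpfinger`, and what the synthetic panels
used in testing do and do not establish about real data.

## Data model

Genotypes are unordered diploid allele pairs at biallelic SNPs,
canonicalised to alphabetical order ("G/A" ≡ "A/G"); phase is never
represented, since the intended panels are inbred lines where
heterozygosity is a purity signal rather than haplotype information.
Missing calls are whole-genotype (no half-calls).  Internally a panel
is a `(samples × markers × 2)` int8 array of nucleotide codes; because
every valid call draws from the marker's two reference alleles, a
minor-allele dosage encoding (0/1/2, −1 missing) is equivalent and is
used for all vectorised pairwise computation.

Input dialects: a **wide CSV** (row = sample; `sample_id, line_name,
replicate_id, subgroup, heterotic_group` then one `X/Y` column per
marker) and standard **HapMap text** (11 metadata columns, two-letter
genotypes).  Missing tokens `--`, `NN`, `NA` and empty cells are
normalised on input; `--` is written in the wide dialect and `NN` in
HapMap.  Read∘write is the identity on valid matrices in both
dialects.  Duplicate `(line, replicate)` pairs are an error, never a
silent overwrite.

## Marker statistics and the filter cascade

Per marker: MAF = minor-allele count / (2 × called samples), each
heterozygote contributing one copy of each allele; heterozygosity rate
over called samples (missing calls do not dilute the heterozygosity
signal — the denominator choice matters at high missingness); missing
rate over all samples; PIC by the biallelic Botstein form
`1 − (p² + q²) − 2p²q²`; and the mutation class collapsing strand
complements (A/G with T/C; A/C with G/T; A/T with C/G).

The filter retains a marker iff het ≤ 5 %, missing ≤ 10 % and
MAF ≥ 0.05 (defaults; all configurable).  Boundaries are inclusive by
default — exclusion criteria are phrased strictly ("greater than
5 %") — with a strict mode available.  The exclusion report names the
first failing criterion per marker (HET, then MISS, then MAF); a
fully-missing marker fails MISS at 100 % missingness.  The filter is
monotone: relaxing any threshold never shrinks the retained set.

## Purity and identity QC

**Purity** classifies each replicate by residual heterozygosity:
PURE < 1 %, BASIC 1–5 %, HETEROZYGOUS > 5 %; replicates above 3 % are
flagged for re-genotyping.  These are seed-lot quality levels: a
nominally inbred line whose sample is heterozygous was contaminated by
pollen or seed, or never fully fixed.

**Similarity rate** between two call vectors counts shared alleles
over mutually called markers: each marker contributes two alleles and
the shared count is the best pairing of the two allele multisets —
identical genotypes share 2, a homozygote and a heterozygote carrying
its allele share 1, disjoint genotypes 0.  Markers missing in either
vector are excluded from numerator and denominator (the only reading
consistent with "non-missing alleles").  At a strictly biallelic
marker two heterozygous calls are necessarily the same genotype, so
the question of how to score mismatched het–het pairs never arises and
no convention knob is exposed.

**Identity** classes per replicate pair: essentially identical
(> 99 %), identical with drift (95–99 %), issue (≤ 95 %).  Issue pairs
are diagnosed by combining the similarity level with replicate
heterozygosity: similarity > 85 % with a replicate above 5 % het →
impurity; ≤ 85 % with high het → likely impurity; ≤ 85 % between two
clean replicates → likely mislabelling during genotyping.  The 85 %/5 %
diagnostic thresholds are descriptive conventions, exposed in config;
the "likely" qualifier is deliberate — a definitive mislabel call
needs additional replicates.

The **cross-line screen** flags a line when its maximum within-line
replicate distance exceeds its minimum distance to any other line's
replicate — the signature of a swapped sample.  Line pairs at zero
distance within and between are reported separately as
indistinguishable (duplicated seed sources), not as mislabels.

## Consensus fingerprints

Replicates merge marker-wise under three rules: (1) all called
replicates agree → keep the call; (2) one homozygous genotype alongside
heterozygotes carrying its allele → keep the homozygote (residual
heterozygosity treated as a purity artefact); (3) conflicting
homozygotes, or a heterozygote sharing no allele → missing.  With more
than two replicates the rules generalise: unanimity; a single
homozygous genotype compatible with every het; otherwise missing.  The
merge is order-invariant.

A site called in some replicates and missing in others keeps the
observed call by default (`missing_policy="keep_call"`), treating
missingness as technical dropout; the literal alternative — any
disagreement including dropout yields missing — is available as
`"strict"`.  Consequence worth knowing: under keep-call with unequal
missingness patterns, the consensus heterozygosity *rate* can slightly
exceed a replicate's (denominator effect), even though merging can
never create a heterozygous call — a consensus het site is het in every
replicate called there, and under the strict policy the consensus
het-call count is bounded by every replicate's.

**Mislabel resolution** (lines with ≥ 3 replicates): a replicate is
excluded as a mislabel when the remaining replicates agree pairwise
above 95 % similarity while the candidate's mean similarity to them is
at or below 95 %.  When no consistent core exists (e.g. a 2-vs-3 split
of internally consistent but mutually distant replicate sets) the line
is UNRESOLVED and no consensus is emitted.  An NJ tree over all
examined replicates provides a cross-check: the candidate should fall
outside the smallest clade spanning its line's other replicates.  The
spanning clade may legitimately contain foreign leaves — in a swap, the
counterpart line's swapped-in replicate sits inside the cluster — so
exact clade membership is not required.  The check is advisory by
default (the similarity rule decides); strict mode requires both
signals.

**Reference assembly** per line: drop excluded replicates; if any
replicate is below 3 % heterozygosity, merge only those; restrict to
the retained marker set; lines with no usable replicate or UNRESOLVED
status are listed as missing from the reference rather than receiving
a fabricated consensus.  Identical inputs and configuration produce
byte-identical output.

## Diversity analyses

IBS distance is `1 − similarity`, i.e. one minus the allele-sharing
fraction over pairwise-complete markers — the same convention as the
identity QC, so QC and diversity numbers are directly comparable.
Only symmetry and range are guaranteed; IBS distances need not satisfy
the triangle inequality, and no metric property is assumed downstream.

* **Bins**: pair fractions over `[0, .05], (.05, .1], (.1, .3],
  (.3, .5], (.5, 1]` by default (half-open on the left to match
  "greater than" phrasing), summing to 100 %; exact-zero pairs and
  pairs under the 0.05 relatedness guard — the threshold below which a
  candidate line is considered too close to an existing line to
  release — are reported alongside.
* **Subgroup / heterotic-group distances**: within-group means over
  unordered distinct pairs, between-group over the full cross product;
  groups with fewer than two members get an undefined within-mean.
* **PCA**: minor-allele dosages, missing imputed to the marker mean,
  columns centred, no variance scaling, SVD.  Component signs are fixed
  (largest-magnitude loading positive) for determinism.  Explained
  variance fractions are relative to the total variance of the centred
  matrix.
* **NJ trees**: Saitou–Nei agglomeration on the Q-matrix.  Ties are
  broken by the lowest (row, column) index pair; negative branch-length
  estimates are clamped to zero with the length transferred to the
  sibling edge; node-to-new-node distances are floored at zero.  On
  additive matrices the generating topology is recovered exactly
  (property-tested against the generating tree and, at four leaves,
  an exhaustive least-squares fit of all three topologies).  Output is
  standard Newick; trees are also returned as dendropy objects.
* **Conversion tests**: IBS distance between a recurrent parent and a
  line converted from it (marker-assisted introgression of a target
  trait); pairs exceeding a closeness threshold (default 0.20) are
  flagged for review, since a conversion should stay near its parent.

## Synthetic panels

The generator emulates a germplasm-bank fingerprinting run and is the
basis of every end-to-end test.

* **Frequencies**: ancestral minor-allele frequencies uniform on
  [0.2, 0.5] in the preset; subgroup frequencies drift via
  Balding–Nichols Beta draws (variance `F·p(1−p)`).  A two-level pool
  hierarchy (tropical subgroups share a drifted pool ancestor;
  temperate drifts independently and harder) makes
  temperate–tropical distances exceed tropical–tropical ones.  Note a
  structural property of this model: drifted frequencies stay centred
  on the ancestral ones, so the *between*-group expected distance is
  invariant to F — divergence manifests as reduced within-group
  distance.  Real ascertained panels can show between-group distances
  above 0.5 (frequencies anti-correlated between pools); this model
  cannot, and no test asserts such magnitudes.
* **Ascertainment**: panel SNPs are chosen for high MAF, so drifted
  frequency draws whose panel-weighted MAF falls below 0.08 are redrawn
  for non-planted markers.  Planted low-MAF markers are exempt — their
  tail is the point.
* **Lines and replicates**: lines are sampled homozygous from their
  subgroup frequencies; per-line residual heterozygosity targets are
  Beta-distributed (preset mean 1.2 %, concentration 38, matched to a
  purity-level distribution with roughly 45 % of samples under 1 % and
  ~90 % under 5 % after noise).  Replicates copy the line genotype and
  add allele-call errors (0.3 %; 80 % of miscalls land heterozygous,
  20 % on the opposite homozygote, mimicking KASP cluster
  mis-assignment) and missingness (2 % baseline).
* **Planted structure**: a marker-quality tail (8 high-het, 16
  high-missing, 10 low-MAF markers with overlaps, leaving ~150 of 180
  retained); mislabels as replicate swaps between line pairs;
  contaminations as per-marker mixtures with another line (modelling
  pollen/seed admixture in a bulked leaf sample — each contaminated
  marker carries one allele from each source); half-sibling pairs
  sharing one simulated parent; conversions copying a parent with 5 %
  of markers introgressed from a donor.
* **Determinism**: a single seeded generator drives everything; the
  same config is byte-identical across runs.

Markers are simulated unlinked, which matches the sparse genome-wide
spacing of fingerprinting panels but means the generator cannot test
haplotype-aware methods.  Passing tests establish that the pipeline's
decision rules behave correctly under this generative model — allele
frequencies, drift, error and contamination of realistic magnitude —
not that the thresholds are optimal for any particular real panel,
where error modes (plate effects, assay-specific clustering failure)
are more structured than the independence assumptions here.

## Problem sizes and numerical choices

Tests and the acceptance script run a 0.2-scale panel (123 lines, 180
markers, two replicates; five replicates in mislabel-recovery runs) —
large enough that subgroup structure, the filter tail and planted
issues are all resolvable, small enough to iterate on quickly.
Mislabel-recovery operating characteristics are averaged over multiple
seeds; the conversion-distance check compares the simulated mean
against its analytic expectation `f · mean_m 2p_m(1−p_m)` at two
standard errors.  All rates are percentages in reports; distances and
MAF are fractions.  Undefined quantities (all-missing samples or
markers, pairs with no shared called marker) propagate as NaN with an
explicit flag or warning, never as silent zeros.

## Known limitations

* Mislabel resolution needs at least three replicates; with two, a
  swap is detectable (the cross-line screen flags it) but not
  attributable, and the merged fingerprint of a swapped pair can be
  artefactually close to its counterpart's — such lines should be
  re-genotyped before their fingerprints are trusted.
* The 85 %/5 % issue diagnosis is heuristic; it mirrors descriptive
  practice and is labelled "likely" accordingly.
* Consensus sites set missing by conflicting replicates are left
  missing; no imputation is attempted.
* IBS on a 150-marker panel cannot separate lines closer than roughly
  1/(2·markers); truly identical fingerprints are reported as
  indistinguishable pairs rather than forced apart.
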