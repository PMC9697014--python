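# snpfinger

Quality control and genetic-diversity analysis for **low-density SNP
fingerprinting of inbred-line panels**, as practised by germplasm banks
and breeding programs that genotype their line collections with small
KASP-style marker panels (tens to a few hundred SNPs) and several
biological replicates per line.

The package answers the questions such a fingerprinting run raises:

* **Which markers are usable?**  Per-marker minor allele frequency
  (MAF), heterozygosity, missing rate, PIC and mutation class, and a
  filter cascade that drops markers with heterozygosity > 5 %,
  missingness > 10 % or MAF < 0.05.
* **Are the seeds pure and the samples what their labels claim?**
  Per-replicate residual heterozygosity classifies seed purity
  (pure < 1 %, basic 1–5 %, heterozygous > 5 %, re-genotype above 3 %);
  the allele-sharing **similarity rate** between biological replicates
  classifies identity (essentially identical > 99 %, drift 95–99 %,
  issue ≤ 95 %) and diagnoses issues as impurity or likely mislabelling.
* **What is the line's reference fingerprint?**  Replicates are merged
  marker-wise (consistent calls kept; a homozygote overrides compatible
  heterozygotes; conflicting homozygotes become missing), after
  mislabelled replicates are excluded by a similarity rule
  cross-checked on a neighbor-joining tree.
* **How diverse is the collection?**  Identity-by-state (IBS) distances
  `d = 1 − (shared alleles) / (2 × markers compared)`, distance
  distributions with a 0.05 relatedness guard, subgroup and
  heterotic-group summaries, dosage-PCA, NJ trees (Newick), and
  parent–conversion distance tests.

A synthetic-panel generator (`snpfinger.simulate`) reproduces the
statistical structure this workflow assumes — subgroup allele-frequency
divergence under a Balding–Nichols drift model, residual
heterozygosity, call error and missingness, planted mislabels,
contaminations, siblings and trait conversions — with full ground
truth, so the whole pipeline is testable end to end without any
external dataset.

## Worked example

```sh
snpfinger all --preset standard --seed 3 --out out/
```

runs simulate → markerqc → sampleqc → reference → diversity on the
built-in preset (123 lines in four adaptation subgroups × 180 markers,
two replicates each, a planted marker-quality tail and a small issue
set) and prints:

```
markerqc: 153 of 180 markers retained
sampleqc: 246 samples, 3 replicate pair(s) with identity issues, 2 line(s) flagged
reference: 123 consensus fingerprints, mean het 1.39%, mean missing 0.73%, mean MAF 0.32
diversity: 123 lines, mean IBS distance 0.417, 4 pair(s) below the 0.05 relatedness guard
```

Reading the output: the filter cascade removed the planted tail of
high-het/high-missing/low-MAF markers (27 markers were planted bad);
the two flagged lines are the pair whose replicates were swapped — the
within-line replicate distance exceeds the distance to another line,
the signature of a mislabel; the consensus fingerprints have lower
heterozygosity and missingness than any single replicate because the
merge rules discard unconfirmed heterozygous calls and fill dropouts;
and the four pairs under the 0.05 relatedness guard are the three
planted conversions sitting 0.01–0.03 from their recurrent parents,
plus the swapped line pair itself — with only two replicates each, the
merge of one true and one swapped replicate turns the conflicting sites
missing and leaves two artefactually similar consensus fingerprints,
which is exactly why flagged lines are re-genotyped with further
replicates before their fingerprints are trusted.

All artifacts are plain text in `out/`: `marker_stats.csv`,
`purity.csv`, `identity.csv`, `flags.csv`, `reference.csv` (wide
genotype table), `provenance.csv`, `distances.csv`, `bins.csv`,
`subgroups.csv`, `pca_coords.csv`, `tree.nwk`, `conversions.csv`, and a
`run_log.jsonl` with config hashes and input checksums.

The same stages are available as library calls:

```python
from snpfinger import (simulate_panel, cml_panel_preset, compute_marker_stats,
                       filter_markers, classify_purity, build_reference,
                       distance_matrix)

matrix, truth = simulate_panel(cml_panel_preset(seed=3))
retained, excluded = filter_markers(compute_marker_stats(matrix))
reference = build_reference(matrix, retained_markers=retained)
dm = distance_matrix(reference)
```

Real data enters through `read_genotype_table(path, dialect="wide")`
(one row per sample, `X/Y` call columns) or `dialect="hapmap"`
(standard HapMap text); see `docs/methods.md` for format details.

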