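"""Per-marker statistics and the marker filter cascade.

Each panel SNP is summarised by minor allele frequency (MAF),
heterozygosity rate, missing rate, polymorphic information content (PIC,
biallelic Botstein form ``1 - (p^2 + q^2) - 2 p^2 q^2``) and its
mutation class (the three complementary substitution pairs A/G|T/C,
A/C|G/T, A/T|C/G).  The filter cascade retains a marker only when its
heterozygosity, missing rate and MAF all pass their thresholds; markers
failing the defaults (het <= 5%, missing <= 10%, MAF >= 0.05) are
excluded from the reference fingerprint set.

Rates are percentages; het rate is computed over non-missing calls so
that missingness does not dilute the heterozygosity signal, and MAF
counts each heterozygote as one copy of each allele.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import GenotypeMatrix, MarkerRecord

MUTATION_CLASSES = {
    frozenset("AG"): "A/G|T/C",
    frozenset("CT"): "A/G|T/C",
    frozenset("AC"): "A/C|G/T",
    frozenset("GT"): "A/C|G/T",
    frozenset("AT"): "A/T|C/G",
    frozenset("CG"): "A/T|C/G",
}


def mutation_class(ref_alleles: Sequence[str]) -> str:
    """Collapse a marker's allele pair onto its strand-complement class."""
    return MUTATION_CLASSES[frozenset(ref_alleles)]


@dataclass
class MarkerStats:
    marker_id: str
    maf: float  # NaN when no calls
    het_rate: float  # percent of non-missing calls; NaN when no calls
    missing_rate: float  # percent of samples
    pic: float  # NaN when no calls
    mutation_class: str
    n_called: int

    @property
    def defined(self) -> bool:
        return self.n_called > 0


@dataclass
class FilterThresholds:
    """Marker filter cascade thresholds (percent, percent, fraction).

    ``inclusive`` keeps markers sitting exactly on a boundary (the
    default: exclusions are phrased strictly, "greater than 5%" etc.).
    """

    max_het_pct: float = 5.0
    max_missing_pct: float = 10.0
    min_maf: float = 0.05
    inclusive: bool = True

    def __post_init__(self):
        if not (0 < self.max_het_pct <= 100):
            raise ValueError("max_het_pct must be in (0, 100]")
        if self.max_missing_pct <= 0 or self.min_maf < 0:
            raise ValueError("thresholds must be positive")


def pic_biallelic(maf: float) -> float:
    """Botstein PIC for a biallelic marker with minor allele frequency maf."""
    p, q = 1.0 - maf, maf
    return 1.0 - (p * p + q * q) - 2.0 * p * p * q * q


def compute_marker_stats(matrix: GenotypeMatrix) -> list[MarkerStats]:
    """Per-marker MAF, het rate, missing rate, PIC and mutation class.

    MAF = minor-allele count / (2 x non-missing calls), heterozygotes
    contributing one copy of each allele.  Markers with every call
    missing get NaN maf/het/pic and missing rate 100.
    """
    miss = matrix.missing_mask
    het = matrix.het_mask
    dosage = matrix.dosage().astype(np.int64)
    n_called = (~miss).sum(axis=0)
    alt_count = np.where(miss, 0, dosage).sum(axis=0)

    out = []
    for j, m in enumerate(matrix.markers):
        n = int(n_called[j])
        if n == 0:
            maf = het_rate = pic = math.nan
        else:
            p_alt = alt_count[j] / (2.0 * n)
            maf = min(p_alt, 1.0 - p_alt)
            het_rate = 100.0 * het[:, j].sum() / n
            pic = pic_biallelic(maf)
        out.append(
            MarkerStats(
                marker_id=m.marker_id,
                maf=maf,
                het_rate=het_rate,
                missing_rate=100.0 * miss[:, j].sum() / matrix.n_samples,
                pic=pic,
                mutation_class=mutation_class(m.ref_alleles),
                n_called=n,
            )
        )
    return out


def stats_table(stats: Sequence[MarkerStats]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "marker_id": [s.marker_id for s in stats],
            "maf": [s.maf for s in stats],
            "het_rate": [s.het_rate for s in stats],
            "missing_rate": [s.missing_rate for s in stats],
            "pic": [s.pic for s in stats],
            "mutation_class": [s.mutation_class for s in stats],
            "n_called": [s.n_called for s in stats],
        }
    )


def filter_markers(
    stats: Sequence[MarkerStats],
    thresholds: Optional[FilterThresholds] = None,
) -> tuple[list[str], pd.DataFrame]:
    """Apply the three-predicate filter cascade.

    Returns (retained marker ids, exclusion report).  The report has one
    row per excluded marker with the first failing criterion as its
    reason code: HET, then MISS, then MAF.  All-missing markers fail MISS
    (their missing rate is 100) and their undefined MAF never rescues
    them.
    """
    if not stats:
        raise ValueError("empty stats list")
    t = thresholds or FilterThresholds()
    retained: list[str] = []
    rows = []
    for s in stats:
        if t.inclusive:
            het_bad = s.het_rate > t.max_het_pct
            miss_bad = s.missing_rate > t.max_missing_pct
            maf_bad = s.maf < t.min_maf
        else:
            het_bad = s.het_rate >= t.max_het_pct
            miss_bad = s.missing_rate >= t.max_missing_pct
            maf_bad = s.maf <= t.min_maf
        # NaN comparisons are False; an all-missing marker is caught by MISS
        if not s.defined:
            het_bad, maf_bad = False, True
        if het_bad:
            rows.append((s.marker_id, "HET", s.het_rate))
        elif miss_bad:
            rows.append((s.marker_id, "MISS", s.missing_rate))
        elif maf_bad:
            rows.append((s.marker_id, "MAF", s.maf))
        else:
            retained.append(s.marker_id)
    report = pd.DataFrame(rows, columns=["marker_id", "reason", "value"])
    return retained, report


@dataclass
class ChromosomeSummary:
    """Per-chromosome marker summary plus panel-wide means."""

    table: pd.DataFrame  # index: chromosome label
    overall_means: dict[str, float]
    mean_markers_per_numbered_chromosome: float


def summarize_by_chromosome(
    stats: Sequence[MarkerStats], markers: Sequence[MarkerRecord]
) -> ChromosomeSummary:
    """Marker count and mean MAF/het/missing per chromosome.

    The mean markers-per-chromosome figure averages over the numbered
    chromosomes only (labels "1".."10"); contig-anchored markers
    (label "0" or a contig name) are summarised but not counted there.
    """
    chrom = {m.marker_id: m.chromosome for m in markers}
    missing_meta = [s.marker_id for s in stats if s.marker_id not in chrom]
    if missing_meta:
        raise ValueError(f"no MarkerRecord for marker(s) {missing_meta[:5]}")
    df = stats_table(stats)
    df["chromosome"] = [chrom[mid] for mid in df["marker_id"]]

    def chrom_key(label: str):
        return (0, int(label)) if label.isdigit() else (1, label)

    grouped = (
        df.groupby("chromosome")
        .agg(
            n_markers=("marker_id", "size"),
            mean_maf=("maf", "mean"),
            mean_het_rate=("het_rate", "mean"),
            mean_missing_rate=("missing_rate", "mean"),
        )
        .sort_index(key=lambda idx: idx.map(chrom_key))
    )
    overall = {
        "n_markers": int(len(df)),
        "mean_maf": float(df["maf"].mean()),
        "mean_het_rate": float(df["het_rate"].mean()),
        "mean_missing_rate": float(df["missing_rate"].mean()),
    }
    numbered = grouped.loc[[c for c in grouped.index if c.isdigit() and c != "0"]]
    mean_per_chrom = float(numbered["n_markers"].mean()) if len(numbered) else math.nan
    return ChromosomeSummary(grouped, overall, mean_per_chrom)
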