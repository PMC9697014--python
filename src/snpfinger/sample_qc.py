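"""Sample-level QC: purity, replicate identity, and cross-line screening.

Purity is the residual heterozygosity of a nominally inbred sample:
PURE below 1% heterozygous calls, BASIC between 1% and 5%, HETEROZYGOUS
above 5%.  Samples whose heterozygosity exceeds 3% are flagged for
re-genotyping.

Identity between two biological replicates is the allele-sharing
similarity rate: over markers called in both vectors, each marker
contributes two alleles and the shared count is the best pairing of the
two allele multisets (identical genotypes share 2, a homozygote and a
heterozygote carrying its allele share 1, disjoint genotypes share 0).
Replicate pairs above 99% similarity are essentially identical; between
95% and 99% identical with minor drift; at or below 95% the line has an
identity issue, diagnosed from the similarity level and the replicates'
heterozygosity (impure seed vs likely mislabelling).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import MISSING, GenotypeMatrix, shared_allele_count


@dataclass
class PurityThresholds:
    pure_max_pct: float = 1.0  # PURE below this
    basic_max_pct: float = 5.0  # BASIC up to this, HETEROZYGOUS above
    regenotype_pct: float = 3.0  # flag for re-genotyping above this


@dataclass
class IdentityThresholds:
    essential_min_pct: float = 99.0  # ESSENTIALLY_IDENTICAL above this
    drift_min_pct: float = 95.0  # IDENTICAL_WITH_DRIFT above this, ISSUE below
    diagnosis_similarity_pct: float = 85.0  # IMPURITY vs LIKELY_* split
    diagnosis_het_pct: float = 5.0  # "high heterozygosity" in the diagnosis


@dataclass
class PurityRecord:
    sample_id: str
    het_pct: float  # NaN for an all-missing sample
    missing_pct: float
    purity_level: str  # PURE | BASIC | HETEROZYGOUS | UNDEFINED
    regenotype_flag: bool
    needs_review: bool = False  # all-missing or otherwise uninterpretable


def classify_purity(
    matrix: GenotypeMatrix, thresholds: Optional[PurityThresholds] = None
) -> list[PurityRecord]:
    """Classify every sample's purity level from its heterozygosity."""
    if matrix.n_samples == 0:
        raise ValueError("empty matrix")
    t = thresholds or PurityThresholds()
    het = matrix.sample_het_pct()
    miss = matrix.sample_missing_pct()
    out = []
    for i, s in enumerate(matrix.samples):
        h = het[i]
        if np.isnan(h):
            level, flag, review = "UNDEFINED", False, True
        elif h < t.pure_max_pct:
            level, flag, review = "PURE", h > t.regenotype_pct, False
        elif h <= t.basic_max_pct:
            level, flag, review = "BASIC", h > t.regenotype_pct, False
        else:
            level, flag, review = "HETEROZYGOUS", h > t.regenotype_pct, False
        out.append(
            PurityRecord(
                sample_id=s.sample_id,
                het_pct=float(h),
                missing_pct=float(miss[i]),
                purity_level=level,
                regenotype_flag=bool(flag),
                needs_review=review,
            )
        )
    return out


def purity_table(records: Sequence[PurityRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records])


def similarity_rate(a: np.ndarray, b: np.ndarray) -> float:
    """Allele-sharing similarity between two genotype call vectors.

    Both are ``(m, 2)`` sorted allele-code arrays (missing ``(-1, -1)``).
    Markers missing in either vector are excluded from numerator and
    denominator (pairwise-complete).  Symmetric; 1.0 on identical
    vectors, 0.0 when no allele is shared anywhere.

    Raises ``ValueError`` when no marker is called in both vectors.
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError("vectors must cover the same markers in the same order")
    both = (a[:, 0] != MISSING) & (b[:, 0] != MISSING)
    n = int(both.sum())
    if n == 0:
        raise ValueError("no mutually non-missing marker; similarity undefined")
    shared = shared_allele_count(a[both], b[both]).sum()
    return float(shared) / (2.0 * n)


def _pairwise_similarity(matrix: GenotypeMatrix) -> np.ndarray:
    """Full sample x sample similarity matrix (NaN where undefined).

    Uses the dosage encoding: at a biallelic marker the shared-allele
    count between dosages ``u`` and ``v`` is ``2 - |u - v|``, which
    equals the multiset-pairing definition.
    """
    d = matrix.dosage().astype(np.float64)
    present = d >= 0
    d[~present] = np.nan
    n = matrix.n_samples
    sim = np.full((n, n), np.nan)
    np.fill_diagonal(sim, 1.0)
    for i in range(n):
        diff = np.abs(d[i + 1:] - d[i])  # NaN propagates through missing
        shared = 2.0 - diff
        cnt = np.sum(~np.isnan(diff), axis=1)
        tot = np.nansum(shared, axis=1)
        with np.errstate(invalid="ignore"):
            row = np.where(cnt > 0, tot / (2.0 * cnt), np.nan)
        sim[i, i + 1:] = row
        sim[i + 1:, i] = row
    return sim


@dataclass
class IdentityReport:
    line_name: str
    pair: tuple[str, str]  # sample ids
    similarity_pct: float
    identity_class: str  # ESSENTIALLY_IDENTICAL | IDENTICAL_WITH_DRIFT | ISSUE
    diagnosis: Optional[str] = None  # IMPURITY | LIKELY_IMPURITY | LIKELY_MISLABEL


def classify_identity(
    matrix: GenotypeMatrix,
    purity: Optional[Sequence[PurityRecord]] = None,
    thresholds: Optional[IdentityThresholds] = None,
) -> list[IdentityReport]:
    """Score all replicate pairs per line and classify their identity.

    Lines with a single replicate are skipped with a warning.  For ISSUE
    pairs the diagnosis combines the similarity level with the
    replicates' heterozygosity: high similarity (> 85%) with a
    heterozygous replicate points at impure seed; low similarity with a
    heterozygous replicate at likely impurity; low similarity between two
    clean replicates at likely mislabelling during genotyping.
    """
    t = thresholds or IdentityThresholds()
    if purity is None:
        purity = classify_purity(matrix)
    het_by_sample = {r.sample_id: r.het_pct for r in purity}
    sim = _pairwise_similarity(matrix)
    reports = []
    for line, idx in matrix.line_indices().items():
        if len(idx) < 2:
            warnings.warn(f"line {line}: single replicate, identity not assessed")
            continue
        for i, j in itertools.combinations(idx, 2):
            s_pct = sim[i, j] * 100.0
            sid_i = matrix.samples[i].sample_id
            sid_j = matrix.samples[j].sample_id
            if np.isnan(s_pct):
                warnings.warn(
                    f"line {line}: pair ({sid_i}, {sid_j}) has no mutually "
                    "non-missing marker"
                )
                continue
            if s_pct > t.essential_min_pct:
                cls, diag = "ESSENTIALLY_IDENTICAL", None
            elif s_pct > t.drift_min_pct:
                cls, diag = "IDENTICAL_WITH_DRIFT", None
            else:
                cls = "ISSUE"
                hets = [het_by_sample.get(sid_i, np.nan), het_by_sample.get(sid_j, np.nan)]
                high_het = any(h > t.diagnosis_het_pct for h in hets if not np.isnan(h))
                if s_pct > t.diagnosis_similarity_pct:
                    diag = "IMPURITY" if high_het else None
                elif high_het:
                    diag = "LIKELY_IMPURITY"
                else:
                    diag = "LIKELY_MISLABEL"
            reports.append(
                IdentityReport(
                    line_name=line,
                    pair=(sid_i, sid_j),
                    similarity_pct=float(s_pct),
                    identity_class=cls,
                    diagnosis=diag,
                )
            )
    return reports


def identity_table(reports: Sequence[IdentityReport]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "line_name": [r.line_name for r in reports],
            "sample_a": [r.pair[0] for r in reports],
            "sample_b": [r.pair[1] for r in reports],
            "similarity_pct": [r.similarity_pct for r in reports],
            "identity_class": [r.identity_class for r in reports],
            "diagnosis": [r.diagnosis or "" for r in reports],
        }
    )


@dataclass
class CrossLineScreen:
    """Result of the within- vs between-line distance screen.

    ``flagged`` lists lines whose replicates are further apart than the
    line is from its nearest other line (the signature of a swapped or
    mislabelled replicate).  ``duplicate_pairs`` lists line pairs that
    are mutually indistinguishable (zero distance within and between) —
    duplicated seed sources rather than mislabels.
    """

    flagged: pd.DataFrame
    duplicate_pairs: list[tuple[str, str]]


def cross_line_similarity_screen(
    matrix: GenotypeMatrix, zero_tol: float = 0.0
) -> CrossLineScreen:
    """Flag lines whose within-replicate distance exceeds the distance to
    another line."""
    lines = matrix.line_indices()
    if len(lines) < 2:
        raise ValueError("screen needs at least two lines")
    sim = _pairwise_similarity(matrix)
    dist = 1.0 - sim
    line_names = list(lines)
    rows = []
    dup_pairs: set[tuple[str, str]] = set()
    for line in line_names:
        idx = lines[line]
        if len(idx) < 2:
            continue
        within = max(
            dist[i, j] for i, j in itertools.combinations(idx, 2)
        )
        other_idx = [k for other, ks in lines.items() if other != line for k in ks]
        cross = np.nanmin(dist[np.ix_(idx, other_idx)])
        if within > cross:
            rows.append((line, float(within), float(cross)))
    for la, lb in itertools.combinations(line_names, 2):
        block = dist[np.ix_(lines[la], lines[lb])]
        if np.nanmax(block) <= zero_tol:
            dup_pairs.add((la, lb))
    flagged = pd.DataFrame(
        rows, columns=["line_name", "within_max_distance", "min_cross_distance"]
    )
    return CrossLineScreen(flagged=flagged, duplicate_pairs=sorted(dup_pairs))
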