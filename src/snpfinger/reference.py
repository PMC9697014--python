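"""Consensus fingerprint construction from biological replicates.

Replicates of a line are merged marker-by-marker under three rules:

1. all non-missing calls agree — keep that call;
2. a homozygote alongside heterozygotes carrying its allele — keep the
   homozygote (residual heterozygosity is treated as a purity artefact,
   not a true genotype);
3. any allele conflict between homozygotes, or a heterozygote sharing no
   allele with the homozygote — set the site missing.

A site called in some replicates and missing in others keeps the
observed call under the default ``missing_policy="keep_call"``
(missingness treated as technical dropout); ``"strict"`` sets it
missing instead.

Before merging, replicates that do not belong to their labelled line are
excluded: a replicate is a mislabel when the remaining replicates agree
with each other (pairwise similarity above the threshold) while the
candidate does not, optionally cross-checked against its placement on a
neighbor-joining tree of all flagged-line replicates.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .core import MISSING, GenotypeMatrix, SampleRecord
from .sample_qc import PurityRecord, _pairwise_similarity, classify_purity


def merge_replicates(calls: Sequence[Sequence[int]], missing_policy: str = "keep_call"):
    """Merge one marker's replicate calls into a consensus call.

    ``calls`` is a list of ``(allele1, allele2)`` sorted code pairs
    (missing ``(-1, -1)``).  Order-invariant.  Raises on empty input.
    """
    if len(calls) == 0:
        raise ValueError("merge needs at least one replicate call")
    arr = np.asarray(calls, dtype=np.int8).reshape(-1, 1, 2)
    merged = merge_replicate_stack(arr, missing_policy=missing_policy)
    return tuple(int(x) for x in merged[0])


def merge_replicate_stack(
    calls: np.ndarray, missing_policy: str = "keep_call"
) -> np.ndarray:
    """Vectorised merge of a ``(k, m, 2)`` replicate stack to ``(m, 2)``.

    Generalises the pairwise rules to any number of replicates:
    unanimity keeps the call; a single homozygous genotype compatible
    with every heterozygote keeps the homozygote; conflicting homozygotes
    or an incompatible heterozygote set the site missing.
    """
    if missing_policy not in ("keep_call", "strict"):
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    calls = np.asarray(calls, dtype=np.int8)
    k, m, _ = calls.shape
    miss = calls[..., 0] == MISSING  # (k, m)
    het = (~miss) & (calls[..., 0] != calls[..., 1])
    hom = (~miss) & ~het

    out = np.full((m, 2), MISSING, dtype=np.int8)
    n_present = (~miss).sum(axis=0)
    any_present = n_present > 0
    if missing_policy == "strict":
        considered_present = n_present == k  # a missing replicate breaks rule 1/2
    else:
        considered_present = any_present

    # distinct homozygous alleles per marker
    hom_allele = np.where(hom, calls[..., 0], MISSING)  # (k, m)
    hom_min = np.where(hom, calls[..., 0], 127).min(axis=0)
    hom_max = hom_allele.max(axis=0)
    has_hom = hom.any(axis=0)
    hom_conflict = has_hom & (hom_min != hom_max)

    # all non-missing genotypes identical?
    first_idx = np.argmax(~miss, axis=0)  # first non-missing replicate per marker
    first = calls[first_idx, np.arange(m)]  # (m, 2)
    same_as_first = miss | np.all(calls == first[None, :, :], axis=2)
    unanimous = same_as_first.all(axis=0)

    # heterozygotes all carry the (single) homozygous allele?
    het_has_allele = (
        (calls[..., 0] == hom_max[None, :]) | (calls[..., 1] == hom_max[None, :])
    )
    het_ok = np.where(het, het_has_allele, True).all(axis=0)

    take_unanimous = any_present & unanimous & considered_present
    out[take_unanimous] = first[take_unanimous]

    take_hom = (
        any_present
        & ~unanimous
        & considered_present
        & has_hom
        & ~hom_conflict
        & het_ok
    )
    out[take_hom, 0] = hom_max[take_hom]
    out[take_hom, 1] = hom_max[take_hom]
    return out


@dataclass
class ExclusionDecision:
    line_name: str
    sample_id: str
    decision: str  # KEEP | MISLABEL | UNRESOLVED
    mean_similarity_to_rest: float
    nj_agrees: Optional[bool] = None


def exclusions_table(decisions: Sequence[ExclusionDecision]) -> pd.DataFrame:
    return pd.DataFrame([d.__dict__ for d in decisions])


def resolve_mislabels(
    matrix: GenotypeMatrix,
    lines: Optional[Iterable[str]] = None,
    similarity_pct: float = 95.0,
    nj_check: str = "advisory",
) -> list[ExclusionDecision]:
    """Identify mislabelled replicates among a line's replicates.

    For each line (all lines with >= 3 replicates unless ``lines`` is
    given), a replicate is a MISLABEL when (a) the remaining replicates
    are mutually consistent — every pairwise similarity above
    ``similarity_pct`` — and (b) the candidate's mean similarity to them
    is at or below the threshold.  When no consistent core remains (for
    example a 2-vs-3 split of internally consistent but mutually distant
    replicates) every replicate of the line is marked UNRESOLVED and no
    consensus should be emitted.

    ``nj_check`` — "off", "advisory" (default; records whether the
    candidate falls outside its line's clade on a neighbor-joining tree
    of all examined replicates) or "strict" (both signals must agree for
    an exclusion).
    """
    if nj_check not in ("off", "advisory", "strict"):
        raise ValueError(f"unknown nj_check mode {nj_check!r}")
    line_idx = matrix.line_indices()
    if lines is None:
        lines = [ln for ln, idx in line_idx.items() if len(idx) >= 3]
    else:
        lines = list(lines)
    examined: list[str] = []
    for ln in lines:
        if ln not in line_idx:
            raise KeyError(f"line {ln} not in matrix")
        if len(line_idx[ln]) < 3:
            warnings.warn(
                f"line {ln}: mislabel resolution needs >= 3 replicates, skipped"
            )
            continue
        examined.append(ln)
    if not examined:
        return []

    all_idx = [i for ln in examined for i in line_idx[ln]]
    sub = matrix.subset(sample_idx=all_idx)
    sim = _pairwise_similarity(sub) * 100.0
    pos = {sid: i for i, sid in enumerate(sub.sample_ids)}

    nj_outside = {}
    if nj_check != "off" and len(examined) >= 2 and sub.n_samples >= 4:
        nj_outside = _nj_outlier_check(sub, examined)

    decisions: list[ExclusionDecision] = []
    for ln in examined:
        sids = [matrix.samples[i].sample_id for i in line_idx[ln]]
        k = [pos[s] for s in sids]
        line_dec: list[ExclusionDecision] = []
        for c, sid in zip(k, sids):
            rest = [j for j in k if j != c]
            rest_consistent = all(
                sim[i, j] > similarity_pct
                for i, j in itertools.combinations(rest, 2)
            )
            mean_sim = float(np.mean([sim[c, j] for j in rest]))
            is_outlier = rest_consistent and mean_sim <= similarity_pct
            nj_flag = nj_outside.get(sid)
            if is_outlier and nj_check == "strict" and nj_flag is False:
                is_outlier = False
            line_dec.append(
                ExclusionDecision(
                    line_name=ln,
                    sample_id=sid,
                    decision="MISLABEL" if is_outlier else "KEEP",
                    mean_similarity_to_rest=mean_sim,
                    nj_agrees=nj_flag,
                )
            )
        kept = [d for d in line_dec if d.decision == "KEEP"]
        kept_pos = [pos[d.sample_id] for d in kept]
        consistent = all(
            sim[i, j] > similarity_pct
            for i, j in itertools.combinations(kept_pos, 2)
        )
        if len(kept) < 1 or not consistent:
            for d in line_dec:
                d.decision = "UNRESOLVED"
        decisions.extend(line_dec)
    return decisions


def _nj_outlier_check(sub: GenotypeMatrix, lines: Sequence[str]) -> dict[str, bool]:
    """True when a replicate attaches outside its line's clade on the NJ
    tree of all examined replicates.

    A candidate is outside when it does not belong to the smallest clade
    (edge bipartition side) spanning the remaining replicates of its
    line.  The smallest spanning clade may legitimately contain foreign
    replicates (e.g. a swapped-in sample from another line), so exact
    clade membership is not required of the rest.
    """
    from .diversity import distance_matrix, nj_tree

    dm = distance_matrix(sub, labels=sub.sample_ids)
    tree = nj_tree(dm).tree
    ns = tree.taxon_namespace
    tree.encode_bipartitions()
    full = ns.all_taxa_bitmask()
    sides: list[tuple[int, int]] = []  # (popcount, bitmask)
    seen = set()
    for edge in tree.preorder_edge_iter():
        if edge.bipartition is None:
            continue
        for mask in (
            edge.bipartition.leafset_bitmask,
            edge.bipartition.leafset_bitmask ^ full,
        ):
            if mask not in seen:
                seen.add(mask)
                sides.append((bin(mask).count("1"), mask))
    sides.sort()
    bit = {t.label: ns.taxon_bitmask(t) for t in ns}
    by_line: dict[str, list[str]] = {}
    for s in sub.samples:
        by_line.setdefault(s.line_name, []).append(s.sample_id)
    out: dict[str, bool] = {}
    for ln in lines:
        sids = by_line[ln]
        for sid in sids:
            rest = [x for x in sids if x != sid]
            if len(rest) < 2:
                continue
            mask = 0
            for x in rest:
                mask |= bit[x]
            spanning = next(
                (m for _, m in sides if (m & mask) == mask), full
            )
            out[sid] = not (spanning & bit[sid])
    return out


@dataclass
class ConsensusFingerprint:
    line_name: str
    calls: np.ndarray  # (m, 2) int8
    n_replicates_used: int
    het_pct: float
    missing_pct: float
    provenance: list[tuple[str, str, str]]  # (sample_id, used|excluded, reason)


@dataclass
class ReferenceDataset:
    """Per-line consensus fingerprints over the retained marker set."""

    matrix: GenotypeMatrix  # one sample per line
    fingerprints: list[ConsensusFingerprint]
    summary: dict[str, float]  # mean het/missing over lines, mean MAF over markers
    missing_lines: list[str] = field(default_factory=list)

    @property
    def line_names(self) -> list[str]:
        return [f.line_name for f in self.fingerprints]


def build_reference(
    matrix: GenotypeMatrix,
    retained_markers: Optional[Sequence[str]] = None,
    purity: Optional[Sequence[PurityRecord]] = None,
    exclusions: Optional[Sequence[ExclusionDecision]] = None,
    het_max_pct: float = 3.0,
    het_boundary_inclusive: bool = False,
    missing_policy: str = "keep_call",
) -> ReferenceDataset:
    """Assemble the reference dataset of per-line consensus fingerprints.

    Per line: drop replicates excluded as mislabels; when any replicate
    has heterozygosity below ``het_max_pct`` restrict the merge to those
    low-het replicates; merge marker-wise; restrict to the retained
    marker set.  Lines whose replicates were UNRESOLVED, or with no
    usable replicate, are listed in ``missing_lines`` instead of
    receiving a consensus.
    """
    if retained_markers is not None:
        work = matrix.subset_markers_by_id(retained_markers)
    else:
        work = matrix
    if purity is None:
        purity = classify_purity(work)
    het_by_sample = {r.sample_id: r.het_pct for r in purity}
    status: dict[str, str] = {}
    if exclusions:
        for d in exclusions:
            status[d.sample_id] = d.decision

    fingerprints: list[ConsensusFingerprint] = []
    missing_lines: list[str] = []
    consensus_samples: list[SampleRecord] = []
    consensus_calls: list[np.ndarray] = []
    for line, idx in work.line_indices().items():
        if any(status.get(work.samples[i].sample_id) == "UNRESOLVED" for i in idx):
            missing_lines.append(line)
            continue
        provenance: list[tuple[str, str, str]] = []
        usable: list[int] = []
        for i in idx:
            sid = work.samples[i].sample_id
            if status.get(sid) == "MISLABEL":
                provenance.append((sid, "excluded", "MISLABEL"))
            else:
                usable.append(i)
        if not usable:
            missing_lines.append(line)
            continue

        def _het(i: int) -> float:
            return het_by_sample.get(work.samples[i].sample_id, np.nan)

        if het_boundary_inclusive:
            low_het = [i for i in usable if _het(i) <= het_max_pct]
        else:
            low_het = [i for i in usable if _het(i) < het_max_pct]
        chosen = low_het if low_het else usable
        for i in usable:
            sid = work.samples[i].sample_id
            if i in chosen:
                provenance.append((sid, "used", ""))
            else:
                provenance.append((sid, "excluded", "HIGH_HET"))

        merged = merge_replicate_stack(
            work.calls[chosen], missing_policy=missing_policy
        )
        m = merged.shape[0]
        miss = merged[:, 0] == MISSING
        n_called = int((~miss).sum())
        het = (~miss) & (merged[:, 0] != merged[:, 1])
        het_pct = 100.0 * het.sum() / n_called if n_called else float("nan")
        fingerprints.append(
            ConsensusFingerprint(
                line_name=line,
                calls=merged,
                n_replicates_used=len(chosen),
                het_pct=float(het_pct),
                missing_pct=100.0 * miss.sum() / m,
                provenance=provenance,
            )
        )
        rep0 = work.samples[idx[0]]
        consensus_samples.append(
            SampleRecord(
                sample_id=line,
                line_name=line,
                replicate_id="consensus",
                subgroup=rep0.subgroup,
                heterotic_group=rep0.heterotic_group,
            )
        )
        consensus_calls.append(merged)

    if not fingerprints:
        raise ValueError("no line produced a consensus fingerprint")
    cmatrix = GenotypeMatrix(
        consensus_samples,
        work.markers,
        np.stack(consensus_calls),
        validate=False,
    )
    from .marker_qc import compute_marker_stats

    stats = compute_marker_stats(cmatrix)
    mafs = [s.maf for s in stats if s.defined]
    summary = {
        "n_lines": float(len(fingerprints)),
        "n_markers": float(cmatrix.n_markers),
        "mean_het_pct": float(np.nanmean([f.het_pct for f in fingerprints])),
        "mean_missing_pct": float(np.mean([f.missing_pct for f in fingerprints])),
        "mean_maf": float(np.mean(mafs)) if mafs else float("nan"),
    }
    return ReferenceDataset(
        matrix=cmatrix,
        fingerprints=fingerprints,
        summary=summary,
        missing_lines=missing_lines,
    )


def provenance_table(reference: ReferenceDataset) -> pd.DataFrame:
    rows = []
    for f in reference.fingerprints:
        for sid, used, reason in f.provenance:
            rows.append((f.line_name, sid, used, reason))
    return pd.DataFrame(rows, columns=["line_name", "sample_id", "status", "reason"])
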