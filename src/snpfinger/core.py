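"""Core genotype containers for low-density SNP fingerprinting panels.

Diploid calls are stored as unordered allele pairs: a ``(n_samples,
n_markers, 2)`` int8 array of nucleotide codes (A=0, C=1, G=2, T=3),
sorted along the last axis, with missing calls encoded as ``(-1, -1)``.
Phase is never represented — the panels this package targets are inbred
lines where residual heterozygosity is a purity signal, not haplotype
information.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

ALLELES = "ACGT"
ALLELE_CODES: Mapping[str, int] = {a: i for i, a in enumerate(ALLELES)}
MISSING = -1

#: Missing-genotype tokens accepted on input; normalised at the boundary.
MISSING_TOKENS = frozenset({"--", "NN", "NA", "", "-", "N"})


class GenotypeError(ValueError):
    """Base class for genotype-data errors."""


class GenotypeParseError(GenotypeError):
    """Malformed file structure (bad header, ragged row, unknown token)."""


class GenotypeValidationError(GenotypeError):
    """Calls inconsistent with marker reference alleles or metadata.

    ``cells`` lists ``(sample_id, marker_id, observed_call)`` tuples for
    every offending cell, so a report can name them all at once.
    """

    def __init__(self, message: str, cells: Optional[list] = None):
        super().__init__(message)
        self.cells = cells or []


def parse_call(text: str) -> tuple[int, int]:
    """Parse a genotype token ("A/G", "AG", "--", "NN", ...) to sorted codes.

    Accepts one- or two-character and slash-separated forms; unordered, so
    "G/A" and "A/G" yield the same pair.
    """
    token = text.strip().upper()
    if token in MISSING_TOKENS:
        return (MISSING, MISSING)
    alleles = token.split("/") if "/" in token else list(token)
    if len(alleles) == 1:  # homozygous shorthand, e.g. "A"
        alleles = alleles * 2
    if len(alleles) != 2 or any(a not in ALLELE_CODES for a in alleles):
        raise GenotypeParseError(f"unrecognised genotype token {text!r}")
    a, b = sorted(ALLELE_CODES[x] for x in alleles)
    return (a, b)


def format_call(pair: Sequence[int], sep: str = "/", missing: str = "--") -> str:
    a, b = pair
    if a == MISSING or b == MISSING:
        return missing
    return f"{ALLELES[a]}{sep}{ALLELES[b]}"


def parse_allele_pair(text: str) -> tuple[str, str]:
    """Parse a marker's reference allele pair, e.g. "A/G" -> ("A", "G")."""
    token = text.strip().upper().replace("|", "/")
    alleles = token.split("/") if "/" in token else list(token)
    if len(alleles) != 2 or any(a not in ALLELE_CODES for a in alleles):
        raise GenotypeParseError(f"unrecognised allele pair {text!r}")
    a, b = sorted(alleles)
    if a == b:
        raise GenotypeParseError(f"allele pair must hold two distinct alleles: {text!r}")
    return (a, b)


@dataclass(frozen=True)
class MarkerRecord:
    """A panel SNP: id, genome anchor, reference allele pair, trait tag.

    ``chromosome`` is a label — "1".."10" for the numbered maize
    chromosomes, "0" or a contig name for unanchored markers.
    ``position_bp`` is 1-based. ``trait_tag`` marks breeder-ready markers
    (e.g. PVA, MSV, MLN, QPM, TSC) and is carried as metadata only.
    """

    marker_id: str
    chromosome: str = "0"
    position_bp: int = 1
    ref_alleles: tuple[str, str] = ("A", "G")
    trait_tag: Optional[str] = None

    def __post_init__(self):
        a, b = self.ref_alleles
        if a == b or a not in ALLELE_CODES or b not in ALLELE_CODES:
            raise GenotypeValidationError(
                f"marker {self.marker_id}: ref_alleles must be two distinct "
                f"nucleotides, got {self.ref_alleles}"
            )
        if tuple(sorted(self.ref_alleles)) != tuple(self.ref_alleles):
            object.__setattr__(self, "ref_alleles", tuple(sorted(self.ref_alleles)))
        if self.position_bp < 1:
            raise GenotypeValidationError(
                f"marker {self.marker_id}: position_bp must be >= 1"
            )

    @property
    def ref_codes(self) -> tuple[int, int]:
        return (ALLELE_CODES[self.ref_alleles[0]], ALLELE_CODES[self.ref_alleles[1]])


@dataclass(frozen=True)
class SampleRecord:
    """One genotyped sample: a biological replicate of a named line."""

    sample_id: str
    line_name: str
    replicate_id: str
    subgroup: Optional[str] = None
    heterotic_group: Optional[str] = None


class GenotypeMatrix:
    """Samples × markers grid of unordered diploid calls.

    Parameters
    ----------
    samples, markers
        Ordered metadata records; lengths must match ``calls``.
    calls
        ``(n_samples, n_markers, 2)`` int8 array, sorted along the last
        axis, missing = ``(-1, -1)``.
    validate
        Check call/ref-allele consistency and (line, replicate) uniqueness.
    """

    def __init__(
        self,
        samples: Sequence[SampleRecord],
        markers: Sequence[MarkerRecord],
        calls: np.ndarray,
        validate: bool = True,
    ):
        self.samples = list(samples)
        self.markers = list(markers)
        calls = np.asarray(calls, dtype=np.int8)
        if calls.shape != (len(self.samples), len(self.markers), 2):
            raise GenotypeValidationError(
                f"calls shape {calls.shape} does not match "
                f"{len(self.samples)} samples x {len(self.markers)} markers"
            )
        # canonical order within each call; missing half-calls are an error
        half = (calls == MISSING).sum(axis=2) == 1
        if half.any():
            i, j = np.argwhere(half)[0]
            raise GenotypeValidationError(
                f"half-call at sample {self.samples[i].sample_id}, "
                f"marker {self.markers[j].marker_id}: both alleles must be "
                "present or both missing"
            )
        self.calls = np.sort(calls, axis=2)
        if validate:
            self.validate()

    # -- validation ------------------------------------------------------

    def validate(self) -> None:
        seen: set[tuple[str, str]] = set()
        for s in self.samples:
            key = (s.line_name, s.replicate_id)
            if key in seen:
                raise GenotypeValidationError(
                    f"duplicate (line, replicate) pair {key}"
                )
            seen.add(key)
        ref = np.array([m.ref_codes for m in self.markers], dtype=np.int8)
        ok = self.calls == MISSING
        ok |= self.calls == ref[None, :, 0:1]
        ok |= self.calls == ref[None, :, 1:2]
        bad = ~ok.all(axis=2)
        if bad.any():
            cells = [
                (
                    self.samples[i].sample_id,
                    self.markers[j].marker_id,
                    format_call(self.calls[i, j]),
                )
                for i, j in np.argwhere(bad)[:50]
            ]
            listing = "; ".join(f"{s} @ {m}: {c}" for s, m, c in cells[:10])
            raise GenotypeValidationError(
                f"{bad.sum()} call(s) outside marker ref_alleles ({listing})",
                cells=cells,
            )

    # -- basic views -----------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    @property
    def marker_ids(self) -> list[str]:
        return [m.marker_id for m in self.markers]

    @property
    def missing_mask(self) -> np.ndarray:
        """(n, m) bool; True where the call is missing."""
        return self.calls[..., 0] == MISSING

    @property
    def het_mask(self) -> np.ndarray:
        """(n, m) bool; True where the call is heterozygous."""
        present = ~self.missing_mask
        return present & (self.calls[..., 0] != self.calls[..., 1])

    def sample_het_pct(self) -> np.ndarray:
        """Percent heterozygous calls per sample, over non-missing calls.

        NaN for all-missing samples.
        """
        nonmiss = (~self.missing_mask).sum(axis=1).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(
                nonmiss > 0, 100.0 * self.het_mask.sum(axis=1) / nonmiss, np.nan
            )

    def sample_missing_pct(self) -> np.ndarray:
        return 100.0 * self.missing_mask.sum(axis=1) / max(self.n_markers, 1)

    def dosage(self) -> np.ndarray:
        """(n, m) int8 count of each marker's alphabetically later ref
        allele; missing = -1.

        Valid because every non-missing call draws from the marker's two
        reference alleles, so the count of one of them determines the call.
        """
        hi = np.array([m.ref_codes[1] for m in self.markers], dtype=np.int8)
        d = (self.calls == hi[None, :, None]).sum(axis=2).astype(np.int8)
        d[self.missing_mask] = MISSING
        return d

    # -- structure -------------------------------------------------------

    def line_indices(self) -> dict[str, list[int]]:
        """Map line_name -> ordered sample indices (its replicates)."""
        out: dict[str, list[int]] = {}
        for i, s in enumerate(self.samples):
            out.setdefault(s.line_name, []).append(i)
        return out

    def subset(
        self,
        sample_idx: Optional[Sequence[int]] = None,
        marker_idx: Optional[Sequence[int]] = None,
    ) -> "GenotypeMatrix":
        si = np.arange(self.n_samples) if sample_idx is None else np.asarray(sample_idx)
        mi = np.arange(self.n_markers) if marker_idx is None else np.asarray(marker_idx)
        return GenotypeMatrix(
            [self.samples[i] for i in si],
            [self.markers[j] for j in mi],
            self.calls[np.ix_(si, mi)],
            validate=False,
        )

    def subset_markers_by_id(self, marker_ids: Iterable[str]) -> "GenotypeMatrix":
        wanted = set(marker_ids)
        idx = [j for j, m in enumerate(self.markers) if m.marker_id in wanted]
        return self.subset(marker_idx=idx)

    def __eq__(self, other) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.samples == other.samples
            and self.markers == other.markers
            and np.array_equal(self.calls, other.calls)
        )

    def __repr__(self) -> str:
        return f"GenotypeMatrix({self.n_samples} samples x {self.n_markers} markers)"


def shared_allele_count(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Per-marker count of shared alleles between two call vectors.

    The count is the size of the best pairing between the two allele
    multisets: identical genotypes share 2; a homozygote and a
    heterozygote carrying its allele share 1; disjoint genotypes share 0.
    Markers missing in either vector yield 0 here (callers mask them).

    Parameters are ``(m, 2)`` sorted code arrays.
    """
    a = np.asarray(a)
    b = np.asarray(b)
    shared = np.zeros(a.shape[0], dtype=np.int64)
    for code in range(len(ALLELES)):
        ca = (a == code).sum(axis=1)
        cb = (b == code).sum(axis=1)
        shared += np.minimum(ca, cb)
    return shared
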