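"""Readers and writers for genotype tables and marker metadata.

Two dialects are supported, because KASP-style exports come in both
orientations:

* ``wide`` — one row per sample, metadata columns (``sample_id``,
  ``line_name``, ``replicate_id``, ``subgroup``, ``heterotic_group``)
  followed by one "X/Y" call column per marker.  Missing is written
  ``--``.
* ``hapmap`` — standard HapMap text: 11 metadata columns then one
  two-letter genotype column per sample.  Missing is written ``NN``.

Missing tokens ``--``, ``NN``, ``NA`` and the empty string are accepted
on input in either dialect and normalised once at the boundary.
Round-trip ``read(write(m))`` is the identity for valid matrices.
"""

from __future__ import annotations

import csv
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import (
    ALLELES,
    MISSING,
    GenotypeMatrix,
    GenotypeParseError,
    MarkerRecord,
    SampleRecord,
    format_call,
    parse_allele_pair,
    parse_call,
)

SAMPLE_META_COLUMNS = [
    "sample_id",
    "line_name",
    "replicate_id",
    "subgroup",
    "heterotic_group",
]

HAPMAP_COLUMNS = [
    "rs#",
    "alleles",
    "chrom",
    "pos",
    "strand",
    "assembly#",
    "center",
    "protLSID",
    "assayLSID",
    "panelLSID",
    "QCcode",
]

#: separator between line name and replicate id inside a bare sample id
#: (used by the hapmap dialect, whose columns carry only the sample id).
SAMPLE_ID_SEP = ":"


def make_sample_id(line_name: str, replicate_id: str) -> str:
    return f"{line_name}{SAMPLE_ID_SEP}{replicate_id}"


def split_sample_id(sample_id: str) -> tuple[str, str]:
    """Recover (line_name, replicate_id) from a sample id.

    Falls back to replicate "1" when the id carries no separator.
    """
    if SAMPLE_ID_SEP in sample_id:
        line, rep = sample_id.rsplit(SAMPLE_ID_SEP, 1)
        return line, rep
    return sample_id, "1"


# ---------------------------------------------------------------------------
# marker metadata


def read_marker_table(path) -> list[MarkerRecord]:
    """Read marker metadata CSV: marker_id, chromosome, position_bp,
    alleles (e.g. "A/G"), trait_tag (optional)."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = {"marker_id", "chromosome", "position_bp", "alleles"}
    missing = required - set(df.columns)
    if missing:
        raise GenotypeParseError(
            f"{path}: marker table missing column(s) {sorted(missing)}"
        )
    records = []
    for _, row in df.iterrows():
        tag = row.get("trait_tag", "") or None
        records.append(
            MarkerRecord(
                marker_id=row["marker_id"],
                chromosome=str(row["chromosome"]),
                position_bp=int(row["position_bp"]),
                ref_alleles=parse_allele_pair(row["alleles"]),
                trait_tag=tag,
            )
        )
    return records


def write_marker_table(markers: Sequence[MarkerRecord], path) -> None:
    df = pd.DataFrame(
        {
            "marker_id": [m.marker_id for m in markers],
            "chromosome": [m.chromosome for m in markers],
            "position_bp": [m.position_bp for m in markers],
            "alleles": ["/".join(m.ref_alleles) for m in markers],
            "trait_tag": [m.trait_tag or "" for m in markers],
        }
    )
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# genotype tables


def read_genotype_table(
    path,
    dialect: str = "wide",
    markers: Optional[Sequence[MarkerRecord]] = None,
) -> GenotypeMatrix:
    """Read a genotype table and return a validated :class:`GenotypeMatrix`.

    Parameters
    ----------
    path
        Delimited text file.
    dialect
        ``"wide"`` (rows = samples) or ``"hapmap"`` (rows = markers).
    markers
        Optional marker metadata.  When given, calls are validated against
        each marker's reference alleles and a
        :class:`~snpfinger.core.GenotypeValidationError` names every
        offending cell.  When absent, reference alleles are inferred from
        the observed calls (hapmap carries its own ``alleles`` column).
    """
    if dialect == "wide":
        return _read_wide(path, markers)
    if dialect == "hapmap":
        return _read_hapmap(path, markers)
    raise ValueError(f"unknown dialect {dialect!r}")


def write_genotype_table(matrix: GenotypeMatrix, path, dialect: str = "wide") -> None:
    if dialect == "wide":
        _write_wide(matrix, path)
    elif dialect == "hapmap":
        _write_hapmap(matrix, path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def _infer_markers(
    marker_ids: Sequence[str], calls: np.ndarray
) -> list[MarkerRecord]:
    """Infer reference allele pairs from the observed calls.

    A marker showing one observed allele is paired with its Watson–Crick
    complement as a placeholder; more than two observed alleles is a
    parse-time error (the panel is biallelic).
    """
    complement = {"A": "T", "C": "G", "G": "C", "T": "A"}
    records = []
    for j, mid in enumerate(marker_ids):
        col = calls[:, j, :]
        observed = sorted({ALLELES[c] for c in col.ravel() if c != MISSING})
        if len(observed) > 2:
            raise GenotypeParseError(
                f"marker {mid}: {len(observed)} distinct alleles observed "
                f"({'/'.join(observed)}); panel markers are biallelic"
            )
        if len(observed) == 2:
            pair = (observed[0], observed[1])
        elif len(observed) == 1:
            pair = tuple(sorted((observed[0], complement[observed[0]])))
        else:  # all missing; placeholder pair
            pair = ("A", "G")
        records.append(MarkerRecord(marker_id=mid, ref_alleles=pair))
    return records


def _align_markers(
    marker_ids: Sequence[str], markers: Sequence[MarkerRecord]
) -> list[MarkerRecord]:
    by_id = {m.marker_id: m for m in markers}
    missing = [mid for mid in marker_ids if mid not in by_id]
    if missing:
        raise GenotypeParseError(
            f"{len(missing)} marker(s) absent from metadata, e.g. {missing[:5]}"
        )
    return [by_id[mid] for mid in marker_ids]


def _read_wide(path, markers) -> GenotypeMatrix:
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise GenotypeParseError(f"{path}: empty file (line 1)")
        if header[: len(SAMPLE_META_COLUMNS)] != SAMPLE_META_COLUMNS:
            raise GenotypeParseError(
                f"{path}: line 1: wide-dialect header must start with "
                f"{SAMPLE_META_COLUMNS}, got {header[:5]}"
            )
        marker_ids = header[len(SAMPLE_META_COLUMNS):]
        if not marker_ids:
            raise GenotypeParseError(f"{path}: line 1: no marker columns")
        samples: list[SampleRecord] = []
        rows: list[list[tuple[int, int]]] = []
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(header):
                raise GenotypeParseError(
                    f"{path}: line {lineno}: expected {len(header)} fields, "
                    f"got {len(row)}"
                )
            sid, line, rep, sub, het = row[:5]
            samples.append(
                SampleRecord(
                    sample_id=sid,
                    line_name=line,
                    replicate_id=rep,
                    subgroup=sub or None,
                    heterotic_group=het or None,
                )
            )
            try:
                rows.append([parse_call(tok) for tok in row[5:]])
            except GenotypeParseError as e:
                raise GenotypeParseError(f"{path}: line {lineno}: {e}") from e
    calls = np.array(rows, dtype=np.int8).reshape(len(samples), len(marker_ids), 2)
    recs = (
        _align_markers(marker_ids, markers)
        if markers is not None
        else _infer_markers(marker_ids, calls)
    )
    return GenotypeMatrix(samples, recs, calls)


def _write_wide(matrix: GenotypeMatrix, path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(SAMPLE_META_COLUMNS + matrix.marker_ids)
        for i, s in enumerate(matrix.samples):
            writer.writerow(
                [
                    s.sample_id,
                    s.line_name,
                    s.replicate_id,
                    s.subgroup or "",
                    s.heterotic_group or "",
                ]
                + [format_call(c) for c in matrix.calls[i]]
            )


def _read_hapmap(path, markers) -> GenotypeMatrix:
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise GenotypeParseError(f"{path}: empty file (line 1)")
        if [h.lower() for h in header[:2]] != ["rs#", "alleles"]:
            raise GenotypeParseError(
                f"{path}: line 1: hapmap header must start with 'rs#', "
                f"'alleles', got {header[:2]}"
            )
        sample_ids = header[len(HAPMAP_COLUMNS):]
        if not sample_ids:
            raise GenotypeParseError(f"{path}: line 1: no sample columns")
        marker_ids: list[str] = []
        inline_markers: list[MarkerRecord] = []
        cols: list[list[tuple[int, int]]] = []
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(header):
                raise GenotypeParseError(
                    f"{path}: line {lineno}: expected {len(header)} fields, "
                    f"got {len(row)}"
                )
            marker_ids.append(row[0])
            try:
                pair = parse_allele_pair(row[1])
                pos = int(row[3]) if row[3] else 1
                inline_markers.append(
                    MarkerRecord(
                        marker_id=row[0],
                        chromosome=row[2] or "0",
                        position_bp=pos,
                        ref_alleles=pair,
                        trait_tag=row[10] or None,
                    )
                )
                cols.append([parse_call(tok) for tok in row[len(HAPMAP_COLUMNS):]])
            except (GenotypeParseError, ValueError) as e:
                raise GenotypeParseError(f"{path}: line {lineno}: {e}") from e
    calls = np.array(cols, dtype=np.int8).transpose(1, 0, 2)
    samples = []
    for sid in sample_ids:
        line, rep = split_sample_id(sid)
        samples.append(SampleRecord(sample_id=sid, line_name=line, replicate_id=rep))
    recs = (
        _align_markers(marker_ids, markers) if markers is not None else inline_markers
    )
    return GenotypeMatrix(samples, recs, calls)


def _write_hapmap(matrix: GenotypeMatrix, path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(HAPMAP_COLUMNS + matrix.sample_ids)
        for j, m in enumerate(matrix.markers):
            meta = [
                m.marker_id,
                "/".join(m.ref_alleles),
                m.chromosome,
                str(m.position_bp),
                "+",
                "NA",
                "NA",
                "NA",
                "NA",
                "NA",
                m.trait_tag or "NA",
            ]
            writer.writerow(
                meta
                + [format_call(c, sep="", missing="NN") for c in matrix.calls[:, j]]
            )
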