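"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from snpfinger.core import (
    MISSING,
    ALLELE_CODES,
    GenotypeMatrix,
    MarkerRecord,
    SampleRecord,
    parse_call,
)
from snpfinger.simulate import cml_panel_preset, simulate_panel


def build_matrix(rows, ref_alleles=None, lines=None, subgroups=None):
    """Build a small GenotypeMatrix from genotype strings.

    ``rows`` is a list of per-sample call lists like ["A/A", "A/G", "--"].
    ``ref_alleles`` optionally gives each marker's allele pair as "A/G"
    strings; otherwise pairs are inferred from the observed calls.
    ``lines`` optionally maps samples to (line_name, replicate_id).
    """
    n = len(rows)
    m = len(rows[0])
    calls = np.full((n, m, 2), MISSING, dtype=np.int8)
    for i, row in enumerate(rows):
        for j, tok in enumerate(row):
            calls[i, j] = parse_call(tok)
    if ref_alleles is None:
        ref_alleles = []
        for j in range(m):
            obs = sorted(
                {c for i in range(n) for c in calls[i, j] if c != MISSING}
            )
            letters = "ACGT"
            if len(obs) == 2:
                ref_alleles.append(letters[obs[0]] + "/" + letters[obs[1]])
            elif len(obs) == 1:
                a = letters[obs[0]]
                comp = {"A": "T", "C": "G", "G": "C", "T": "A"}[a]
                ref_alleles.append("/".join(sorted((a, comp))))
            else:
                ref_alleles.append("A/G")
    markers = [
        MarkerRecord(
            marker_id=f"M{j+1:03d}",
            chromosome=str(1 + j % 10),
            position_bp=1000 * (j + 1),
            ref_alleles=tuple(sorted(ref_alleles[j].split("/"))),
        )
        for j in range(m)
    ]
    samples = []
    for i in range(n):
        if lines is not None:
            line, rep = lines[i]
        else:
            line, rep = f"S{i+1}", "R1"
        samples.append(
            SampleRecord(
                sample_id=f"{line}:{rep}",
                line_name=line,
                replicate_id=rep,
                subgroup=subgroups[i] if subgroups else None,
            )
        )
    return GenotypeMatrix(samples, markers, calls)


def similarity_oracle(a, b):
    """Brute-force allele-by-allele similarity: per marker, the best
    pairing between the two allele multisets, over mutually called
    markers."""
    shared = 0
    compared = 0
    for (a1, a2), (b1, b2) in zip(a, b):
        if MISSING in (a1, a2) or MISSING in (b1, b2):
            continue
        compared += 1
        best = 0
        for bb in itertools.permutations((b1, b2)):
            best = max(best, int(a1 == bb[0]) + int(a2 == bb[1]))
        shared += best
    if compared == 0:
        raise ValueError("no mutually non-missing marker")
    return shared / (2.0 * compared)


def merge_oracle(calls):
    """Independent statement of the three merge rules on a list of
    (a1, a2) code pairs."""
    present = [tuple(c) for c in calls if MISSING not in c]
    if not present:
        return (MISSING, MISSING)
    if len(set(present)) == 1:
        return present[0]
    homs = {c for c in present if c[0] == c[1]}
    hets = [c for c in present if c[0] != c[1]]
    if len(homs) > 1:
        return (MISSING, MISSING)
    if len(homs) == 1:
        h = next(iter(homs))
        if all(h[0] in het for het in hets):
            return h
        return (MISSING, MISSING)
    return (MISSING, MISSING)


def random_call_vector(rng, m, alleles="ACGT", p_missing=0.15, p_het=0.3):
    """Random genotype call vector as an (m, 2) sorted code array."""
    out = np.full((m, 2), MISSING, dtype=np.int8)
    codes = [ALLELE_CODES[x] for x in alleles]
    for j in range(m):
        if rng.random() < p_missing:
            continue
        if rng.random() < p_het:
            a, b = rng.choice(codes, size=2, replace=False)
        else:
            a = b = rng.choice(codes)
        out[j] = sorted((int(a), int(b)))
    return out


@pytest.fixture(scope="session")
def preset_panel():
    """One deterministic preset panel shared by the expensive tests."""
    return simulate_panel(cml_panel_preset(seed=1))
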