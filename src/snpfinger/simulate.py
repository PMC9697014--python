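"""Synthetic genotype panels with full ground truth.

The generator emulates a germplasm-bank fingerprinting panel: a few
hundred inbred lines from several adaptation subgroups genotyped at
~180 biallelic SNPs with 2-5 biological replicates per line.  Subgroup
allele frequencies diverge from a shared ancestral frequency under a
Balding–Nichols drift model (Beta distributed with variance
``F·p·(1-p)``), with a two-level pool hierarchy so that, e.g., the
tropical subgroups stay mutually closer than any of them is to the
temperate pool.  Lines are sampled homozygous from their subgroup
frequencies and then given a per-line residual-heterozygosity level;
replicates add allele-call errors and missingness.

Planted data-quality and identity issues, all recorded in the returned
:class:`Truth`:

* markers with inflated heterozygosity, inflated missingness, or low
  MAF (the filter-cascade tail);
* mislabels — a replicate swapped between two lines;
* contaminations — a replicate mixed per-marker with another line;
* sibling pairs sharing one simulated parent;
* conversions — a line copying a recurrent parent with a stated
  fraction of markers introgressed from a donor.

Markers are treated as unlinked, consistent with the sparse genome-wide
spacing such panels are designed for.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .core import ALLELE_CODES, MISSING, GenotypeMatrix, MarkerRecord, SampleRecord

SUBGROUPS = (
    "Lowland Tropical",
    "Subtropical/Mid-altitude",
    "Highland Tropical",
    "Temperate",
)

# complementary substitution classes with panel-like draw probabilities
_MUTATION_PAIRS = [
    (("A", "G"), ("C", "T")),
    (("A", "C"), ("G", "T")),
    (("A", "T"), ("C", "G")),
]
_MUTATION_PROBS = [0.599, 0.209, 0.192]


@dataclass
class SimulationConfig:
    """Generator parameters.  Rates are fractions in [0, 1].

    ``n_lines`` maps subgroup name to line count.  ``pools`` assigns each
    subgroup to a frequency pool; ``pool_F`` is the drift of each pool
    from the ancestral frequencies and ``divergence_F`` the further drift
    of each subgroup from its pool.  ``residual_het`` is the mean
    per-line heterozygosity target; with ``residual_het_concentration``
    set, per-line targets are Beta distributed around it (giving a
    realistic impure tail), otherwise constant.
    """

    n_markers: int = 180
    n_lines: dict = field(default_factory=lambda: {"Lowland Tropical": 40})
    pools: dict = field(default_factory=dict)  # subgroup -> pool name
    pool_F: dict = field(default_factory=dict)  # pool -> drift F
    divergence_F: dict = field(default_factory=dict)  # subgroup -> drift F
    maf_range: tuple = (0.15, 0.5)
    #: minimum panel-wide MAF enforced on non-planted markers by redrawing
    #: their drifted frequencies — emulates marker ascertainment (panel
    #: SNPs are picked for high MAF); 0 disables.
    ascertain_min_maf: float = 0.0
    residual_het: float = 0.02
    residual_het_concentration: Optional[float] = None
    n_replicates: int = 2
    call_error_rate: float = 0.005
    error_hom_to_het: float = 0.8  # miscalls landing het (vs opposite hom)
    missing_rate: float = 0.025
    # marker-quality tail
    n_high_het_markers: int = 0
    high_het_range: tuple = (0.08, 0.20)
    n_high_missing_markers: int = 0
    high_missing_range: tuple = (0.12, 0.30)
    n_low_maf_markers: int = 0
    low_maf_range: tuple = (0.0, 0.04)
    overlap_het_missing: int = 0
    overlap_missing_maf: int = 0
    # planted sample issues
    n_mislabels: int = 0  # swap events; each affects two lines
    n_contaminated: int = 0
    contamination_fraction: float = 0.2
    n_sibling_pairs: int = 0
    n_conversions: int = 0
    conversion_fraction: float = 0.05
    seed: int = 0

    @property
    def total_lines(self) -> int:
        return sum(self.n_lines.values())

    def validate(self) -> None:
        rates = {
            "residual_het": self.residual_het,
            "call_error_rate": self.call_error_rate,
            "error_hom_to_het": self.error_hom_to_het,
            "missing_rate": self.missing_rate,
            "contamination_fraction": self.contamination_fraction,
            "conversion_fraction": self.conversion_fraction,
        }
        for name, v in rates.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.residual_het > 0.2:
            raise ValueError("residual_het above 0.2 is not a credible inbred panel")
        for sub in self.n_lines:
            F = self.divergence_F.get(sub, 0.0)
            if not 0.0 <= F < 1.0:
                raise ValueError(f"divergence_F[{sub}] must be in [0, 1)")
        n_special = (
            2 * self.n_mislabels
            + self.n_contaminated
            + 2 * self.n_sibling_pairs
            + 2 * self.n_conversions
        )
        if n_special > self.total_lines:
            raise ValueError(
                f"{n_special} issue/relationship lines exceed panel size "
                f"{self.total_lines}"
            )
        n_bad = (
            self.n_high_het_markers
            + self.n_high_missing_markers
            + self.n_low_maf_markers
            - self.overlap_het_missing
            - self.overlap_missing_maf
        )
        if n_bad > self.n_markers:
            raise ValueError("planted bad markers exceed marker count")
        if self.overlap_het_missing > min(
            self.n_high_het_markers, self.n_high_missing_markers
        ) or self.overlap_missing_maf > min(
            self.n_high_missing_markers, self.n_low_maf_markers
        ):
            raise ValueError("marker-set overlaps exceed the sets themselves")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.n_mislabels and self.n_replicates < 2:
            raise ValueError("mislabel swaps need >= 2 replicates")


@dataclass
class Truth:
    """Ground truth for a simulated panel."""

    samples: pd.DataFrame  # sample_id, line_name, replicate_id, true_line, issue
    lines: pd.DataFrame  # line_name, subgroup, ... relationships
    markers: pd.DataFrame  # marker_id, p0, subgroup freqs, planted flags
    subgroup_freqs: dict  # subgroup -> (m,) allele frequency array


def _balding_nichols(rng, p: np.ndarray, F: float) -> np.ndarray:
    """Draw drifted frequencies around p with variance F·p·(1-p)."""
    if F <= 0.0:
        return p.copy()
    lam = (1.0 - F) / F
    out = p.copy()
    inner = (p > 0) & (p < 1)
    out[inner] = rng.beta(p[inner] * lam, (1.0 - p[inner]) * lam)
    return out


def simulate_panel(config: SimulationConfig) -> tuple[GenotypeMatrix, Truth]:
    """Generate a genotype panel and its ground truth.  Deterministic
    under a fixed config (the seed lives in the config)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    m = config.n_markers

    # ---- markers ------------------------------------------------------
    n_digits = max(3, len(str(m)))
    marker_ids = [f"M{j + 1:0{n_digits}d}" for j in range(m)]
    classes = rng.choice(3, size=m, p=np.asarray(_MUTATION_PROBS) / sum(_MUTATION_PROBS))
    strands = rng.integers(0, 2, size=m)
    pairs = [_MUTATION_PAIRS[c][s] for c, s in zip(classes, strands)]
    chroms = [str(1 + j % 10) for j in range(m)]
    positions = (1 + rng.integers(0, 3_000_000, size=m) + np.arange(m) * 1_000_000)
    markers = [
        MarkerRecord(
            marker_id=mid,
            chromosome=ch,
            position_bp=int(pos),
            ref_alleles=pair,
        )
        for mid, ch, pos, pair in zip(marker_ids, chroms, positions, pairs)
    ]

    # planted marker-quality tail, with overlaps between the tails
    perm = rng.permutation(m)
    nh, nm, nl = (
        config.n_high_het_markers,
        config.n_high_missing_markers,
        config.n_low_maf_markers,
    )
    high_het_idx = perm[:nh]
    miss_start = nh - config.overlap_het_missing
    high_missing_idx = perm[miss_start : miss_start + nm]
    maf_start = miss_start + nm - config.overlap_missing_maf
    low_maf_idx = perm[maf_start : maf_start + nl]

    p0 = rng.uniform(*config.maf_range, size=m)
    p0[low_maf_idx] = rng.uniform(*config.low_maf_range, size=nl)
    het_boost = np.zeros(m)
    het_boost[high_het_idx] = rng.uniform(*config.high_het_range, size=nh)
    miss_rate = np.full(m, config.missing_rate)
    miss_rate[high_missing_idx] = rng.uniform(*config.high_missing_range, size=nm)

    # ---- subgroup frequencies ----------------------------------------
    pool_of = {sub: config.pools.get(sub, sub) for sub in config.n_lines}

    def _draw_freqs() -> dict:
        pool_freqs = {
            pool: _balding_nichols(rng, p0, config.pool_F.get(pool, 0.0))
            for pool in dict.fromkeys(pool_of.values())
        }
        return {
            sub: _balding_nichols(
                rng, pool_freqs[pool_of[sub]], config.divergence_F.get(sub, 0.0)
            )
            for sub in config.n_lines
        }

    subgroup_freqs = _draw_freqs()
    if config.ascertain_min_maf > 0:
        # redraw drifted frequencies at markers whose panel-weighted MAF
        # fell below the ascertainment floor (planted low-MAF markers are
        # exempt: their tail is the point)
        weights = np.array([config.n_lines[s] for s in config.n_lines], dtype=float)
        weights /= weights.sum()
        exempt = np.zeros(m, dtype=bool)
        exempt[low_maf_idx] = True
        for _ in range(50):
            panel_p = sum(
                w * subgroup_freqs[s] for w, s in zip(weights, config.n_lines)
            )
            panel_maf = np.minimum(panel_p, 1.0 - panel_p)
            bad = (~exempt) & (panel_maf < config.ascertain_min_maf)
            if not bad.any():
                break
            redraw = _draw_freqs()
            for sub in subgroup_freqs:
                subgroup_freqs[sub][bad] = redraw[sub][bad]

    # ---- line metadata ------------------------------------------------
    line_names: list[str] = []
    line_subgroup: list[str] = []
    het_groups: list[str] = []
    counter = 0
    for sub, count in config.n_lines.items():
        for _ in range(count):
            counter += 1
            hg = "A" if rng.random() < 0.5 else "B"
            line_names.append(f"L{counter:04d}{hg}")
            line_subgroup.append(sub)
            het_groups.append(hg)
    n_lines = len(line_names)

    if config.residual_het_concentration:
        conc = config.residual_het_concentration
        a = max(config.residual_het * conc, 1e-6)
        b = max((1.0 - config.residual_het) * conc, 1e-6)
        het_targets = np.minimum(rng.beta(a, b, size=n_lines), 0.2)
    else:
        het_targets = np.full(n_lines, config.residual_het)

    # ---- designate special lines -------------------------------------
    special = rng.permutation(n_lines)
    cursor = 0

    def take(k: int) -> list[int]:
        nonlocal cursor
        out = special[cursor : cursor + k].tolist()
        cursor += k
        return out

    swap_pairs = [tuple(take(2)) for _ in range(config.n_mislabels)]
    contaminated_lines = take(config.n_contaminated)
    sibling_pairs = [tuple(take(2)) for _ in range(config.n_sibling_pairs)]
    conversion_lines = take(config.n_conversions)
    clean_pool = special[cursor:].tolist()  # parents/donors/contaminants

    # ---- base line genotypes (dosage of the later ref allele) ---------
    dosage = np.zeros((n_lines, m), dtype=np.int8)
    for i in range(n_lines):
        p = subgroup_freqs[line_subgroup[i]]
        dosage[i] = 2 * (rng.random(m) < p)

    sibling_group = [""] * n_lines
    for g, (i, j) in enumerate(sibling_pairs):
        # half-sibs: shared homozygous parent + each line's own second parent
        p = subgroup_freqs[line_subgroup[i]]
        shared = 2 * (rng.random(m) < p)
        for i_sib in (i, j):
            own = 2 * (rng.random(m) < subgroup_freqs[line_subgroup[i_sib]])
            from_shared = rng.random(m) < 0.5
            dosage[i_sib] = np.where(from_shared, shared, own).astype(np.int8)
            sibling_group[i_sib] = f"S{g + 1}"

    conversion_of = [""] * n_lines
    conversion_donor = [""] * n_lines
    conversion_frac = np.zeros(n_lines)
    for k, i in enumerate(conversion_lines):
        if len(clean_pool) < 2:
            raise ValueError("not enough clean lines to serve as parent and donor")
        parent = clean_pool[(2 * k) % len(clean_pool)]
        donor = clean_pool[(2 * k + 1) % len(clean_pool)]
        introgress = rng.random(m) < config.conversion_fraction
        dosage[i] = np.where(introgress, dosage[donor], dosage[parent]).astype(np.int8)
        conversion_of[i] = line_names[parent]
        conversion_donor[i] = line_names[donor]
        conversion_frac[i] = config.conversion_fraction
        line_subgroup[i] = line_subgroup[parent]

    # residual heterozygosity (skip conversions: they inherit the parent's
    # fixed genome plus introgression, and their own seed purity is clean)
    for i in range(n_lines):
        if conversion_of[i]:
            continue
        het_sites = rng.random(m) < het_targets[i]
        dosage[i, het_sites] = 1
    for i in conversion_lines:
        het_targets[i] = 0.0

    # ---- replicates ----------------------------------------------------
    k_rep = config.n_replicates
    rep_dosage = np.repeat(dosage[:, None, :], k_rep, axis=1).astype(np.int8)
    # per-marker heterozygosity inflation (assay artefact on planted markers)
    if het_boost.any():
        boost = rng.random(rep_dosage.shape) < het_boost[None, None, :]
        rep_dosage[boost] = 1
    # allele-call errors
    if config.call_error_rate > 0:
        err = rng.random(rep_dosage.shape) < config.call_error_rate
        to_het = rng.random(rep_dosage.shape) < config.error_hom_to_het
        flip_dir = rng.integers(0, 2, size=rep_dosage.shape)
        was_hom0 = rep_dosage == 0
        was_hom2 = rep_dosage == 2
        was_het = rep_dosage == 1
        rep_dosage[err & was_hom0 & to_het] = 1
        rep_dosage[err & was_hom0 & ~to_het] = 2
        rep_dosage[err & was_hom2 & to_het] = 1
        rep_dosage[err & was_hom2 & ~to_het] = 0
        rep_dosage[err & was_het] = (2 * flip_dir[err & was_het]).astype(np.int8)

    # contamination: one replicate mixed per-marker with another line
    issue = {}
    for k, i in enumerate(contaminated_lines):
        contaminant = clean_pool[rng.integers(len(clean_pool))]
        rep = int(rng.integers(k_rep))
        mix = rng.random(m) < config.contamination_fraction
        own_allele = _draw_allele(rng, rep_dosage[i, rep])
        other_allele = _draw_allele(rng, dosage[contaminant])
        mixed = (own_allele + other_allele).astype(np.int8)
        rep_dosage[i, rep, mix] = mixed[mix]
        issue[(i, rep)] = ("CONTAMINATED", line_names[i])

    # missingness (after contamination so the mixture can also drop out)
    miss = rng.random(rep_dosage.shape) < miss_rate[None, None, :]
    rep_dosage[miss] = MISSING

    # mislabels: swap the last replicate between the two lines
    for i, j in swap_pairs:
        r = k_rep - 1
        tmp = rep_dosage[i, r].copy()
        rep_dosage[i, r] = rep_dosage[j, r]
        rep_dosage[j, r] = tmp
        issue[(i, r)] = ("MISLABEL", line_names[j])
        issue[(j, r)] = ("MISLABEL", line_names[i])

    # ---- assemble matrix ----------------------------------------------
    lo = np.array([ALLELE_CODES[mk.ref_alleles[0]] for mk in markers], dtype=np.int8)
    hi = np.array([ALLELE_CODES[mk.ref_alleles[1]] for mk in markers], dtype=np.int8)
    samples: list[SampleRecord] = []
    truth_rows = []
    call_rows = []
    for i, line in enumerate(line_names):
        for r in range(k_rep):
            rep_id = f"R{r + 1}"
            sid = f"{line}:{rep_id}"
            samples.append(
                SampleRecord(
                    sample_id=sid,
                    line_name=line,
                    replicate_id=rep_id,
                    subgroup=line_subgroup[i],
                    heterotic_group=het_groups[i],
                )
            )
            kind, true_line = issue.get((i, r), ("NONE", line))
            truth_rows.append((sid, line, rep_id, true_line, kind))
            call_rows.append(_dosage_to_calls(rep_dosage[i, r], lo, hi))
    calls = np.stack(call_rows)
    matrix = GenotypeMatrix(samples, markers, calls, validate=False)

    lines_df = pd.DataFrame(
        {
            "line_name": line_names,
            "subgroup": line_subgroup,
            "heterotic_group": het_groups,
            "residual_het_target": het_targets,
            "sibling_group": sibling_group,
            "conversion_of": conversion_of,
            "conversion_donor": conversion_donor,
            "conversion_fraction": conversion_frac,
        }
    )
    markers_df = pd.DataFrame(
        {
            "marker_id": marker_ids,
            "p0": p0,
            "het_boost": het_boost,
            "missing_rate": miss_rate,
            "high_het": np.isin(np.arange(m), high_het_idx),
            "high_missing": np.isin(np.arange(m), high_missing_idx),
            "low_maf": np.isin(np.arange(m), low_maf_idx),
        }
    )
    samples_df = pd.DataFrame(
        truth_rows,
        columns=["sample_id", "line_name", "replicate_id", "true_line", "issue"],
    )
    truth = Truth(
        samples=samples_df,
        lines=lines_df,
        markers=markers_df,
        subgroup_freqs=subgroup_freqs,
    )
    return matrix, truth


def _draw_allele(rng, dosage_row: np.ndarray) -> np.ndarray:
    """Draw one allele (0 = earlier ref allele, 1 = later) per marker from
    a dosage vector; missing sites draw the earlier allele arbitrarily."""
    d = np.where(dosage_row < 0, 0, dosage_row)
    u = rng.random(d.shape)
    return np.where(d == 2, 1, np.where((d == 1) & (u < 0.5), 1, 0)).astype(np.int8)


def _dosage_to_calls(d: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    calls = np.empty((d.shape[0], 2), dtype=np.int8)
    calls[:, 0] = np.where(d <= 0, lo, np.where(d == 1, lo, hi))
    calls[:, 1] = np.where(d == 0, lo, hi)
    calls[d < 0] = MISSING
    return calls


def cml_panel_preset(seed: int = 101) -> SimulationConfig:
    """Preset emulating a CML-style germplasm-bank fingerprinting run.

    A 0.2-scale panel: 123 lines across the four adaptation subgroups
    (67 lowland tropical, 46 subtropical/mid-altitude, 7 highland
    tropical, 3 temperate), 180 markers with a planted quality tail
    (8 high-het, 16 high-missing, 10 low-MAF, overlapping), two
    replicates per line, and a small issue set: one replicate swap
    (two mislabelled samples), three contaminated samples, two sibling
    pairs, three trait conversions at 5% introgression.  Marginals land
    near mean missing ~3%, mean heterozygosity ~2%, mean MAF ~0.3.
    """
    return SimulationConfig(
        n_markers=180,
        n_lines={
            "Lowland Tropical": 67,
            "Subtropical/Mid-altitude": 46,
            "Highland Tropical": 7,
            "Temperate": 3,
        },
        pools={
            "Lowland Tropical": "tropical",
            "Subtropical/Mid-altitude": "tropical",
            "Highland Tropical": "tropical",
            "Temperate": "temperate",
        },
        pool_F={"tropical": 0.08, "temperate": 0.35},
        divergence_F={
            "Lowland Tropical": 0.02,
            "Subtropical/Mid-altitude": 0.02,
            "Highland Tropical": 0.08,
            "Temperate": 0.02,
        },
        maf_range=(0.2, 0.5),
        ascertain_min_maf=0.08,
        residual_het=0.012,
        residual_het_concentration=38.0,
        n_replicates=2,
        call_error_rate=0.003,
        missing_rate=0.02,
        n_high_het_markers=8,
        high_het_range=(0.06, 0.16),
        n_high_missing_markers=16,
        n_low_maf_markers=10,
        overlap_het_missing=3,
        overlap_missing_maf=4,
        n_mislabels=1,
        n_contaminated=3,
        contamination_fraction=0.2,
        n_sibling_pairs=2,
        n_conversions=3,
        conversion_fraction=0.05,
        seed=seed,
    )
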