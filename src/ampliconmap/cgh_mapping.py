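"""Copy-number calling, frequency maps, amplicon extraction and consensus regions.

The computational core of the aCGH analysis: per-clone log2 ratios are
thresholded into states (loss / neutral / gain / amp), summarized into
per-interval aberration frequencies, and focal high-level amplifications are
delineated per tumor and intersected across tumors into the minimal common
region that localizes candidate driver genes.

No segmentation or smoothing is applied before thresholding: calls are pure
per-clone ratio thresholds, with an optional merge of amplified runs across
small gaps for tiling data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import (
    CGHProfile,
    CloneMap,
    GeneRecord,
    ValidationError,
    read_gene_annotation,
)

STATES = ("loss", "neutral", "gain", "amp", "missing")


@dataclass(frozen=True)
class CallThresholds:
    """log2-ratio cutoffs for state calls.

    ``amp_min`` defaults to 1.0 (linear ratio 2); an alternate preset of 1.5
    is used for pangenomic screens. Loss/gain cutoffs of +/-0.25 are a
    conventional single-copy aCGH bound.
    """

    loss_max: float = -0.25
    gain_min: float = 0.25
    amp_min: float = 1.0

    def __post_init__(self) -> None:
        if not (self.loss_max < 0 < self.gain_min < self.amp_min):
            raise ValidationError(
                "thresholds must satisfy loss_max < 0 < gain_min < amp_min"
            )
        for v in (self.loss_max, self.gain_min, self.amp_min):
            if not np.isfinite(v):
                raise ValidationError("thresholds must be finite")


PANGENOMIC_THRESHOLDS = CallThresholds(amp_min=1.5)


@dataclass(frozen=True)
class AmpliconSegment:
    """A maximal run of amplified clones in one tumor."""

    tumor_id: str
    chrom: str
    start: int
    end: int
    n_clones: int
    peak_log2: float

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValidationError("amplicon start >= end")
        if self.n_clones < 1:
            raise ValidationError("amplicon must cover >= 1 clone")

    @property
    def width(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class ConsensusRegion:
    """Cross-tumor intersection of amplicons: the minimal common region."""

    chrom: str
    start: int
    end: int
    support: int
    supporting_tumor_ids: tuple[str, ...]

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def width_mb(self) -> float:
        return self.width / 1e6


@dataclass
class FrequencyMap:
    """Per-bin loss/gain frequencies across a cohort.

    ``table`` columns: chrom, start, end, n_informative, n_loss, n_gain,
    loss_freq, gain_freq. Bins where no tumor is informative carry NaN
    frequencies (missing, not zero). "Gain" counts states gain OR amp.
    """

    table: pd.DataFrame
    bin_size: int


def call_clone_states(profile: CGHProfile, thresholds: CallThresholds) -> np.ndarray:
    """Per-clone state calls: amp iff value > amp_min, gain iff
    gain_min < value <= amp_min, loss iff value <= loss_max, else neutral;
    masked clones are 'missing'."""
    v = profile.values
    states = np.full(v.shape, "neutral", dtype=object)
    states[v > thresholds.amp_min] = "amp"
    states[(v > thresholds.gain_min) & (v <= thresholds.amp_min)] = "gain"
    states[v <= thresholds.loss_max] = "loss"
    states[profile.mask] = "missing"
    return states


def _check_aligned(profiles: Sequence[CGHProfile], clone_map: CloneMap) -> None:
    for p in profiles:
        if len(p) != len(clone_map):
            raise ValidationError(
                f"profile {p.tumor_id!r} has {len(p)} values for a "
                f"{len(clone_map)}-clone map"
            )


def make_bins(clone_map: CloneMap, bin_size: int) -> pd.DataFrame:
    """Fixed-width genomic bins from 0 to the last clone end, per chromosome."""
    if bin_size <= 0:
        raise ValidationError("bin_size must be positive")
    rows = []
    for chrom in sorted({c.chrom for c in clone_map}):
        _, chrom_end = clone_map.chrom_span(chrom)
        for start in range(0, chrom_end, bin_size):
            rows.append((chrom, start, min(start + bin_size, chrom_end)))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def aberration_frequency(
    profiles: Sequence[CGHProfile],
    clone_map: CloneMap,
    bin_size: int = 2_000_000,
    thresholds: CallThresholds | None = None,
) -> FrequencyMap:
    """Tumor-level loss/gain frequency per fixed-width bin.

    For each bin and state: numerator = tumors with >= 1 clone in that state
    overlapping the bin; denominator = tumors with >= 1 informative clone in
    the bin. A clone counts in every bin it overlaps. An amplified clone also
    counts as gained.
    """
    if not profiles:
        raise ValidationError("need at least one profile")
    thresholds = thresholds or CallThresholds()
    _check_aligned(profiles, clone_map)
    bins = make_bins(clone_map, bin_size)

    state_mat = np.vstack([call_clone_states(p, thresholds) for p in profiles])
    clone_chrom = np.array([c.chrom for c in clone_map])
    clone_start = np.array([c.start for c in clone_map])
    clone_end = np.array([c.end for c in clone_map])

    n_inf, n_loss, n_gain = [], [], []
    for chrom, b_start, b_end in bins.itertuples(index=False):
        in_bin = (clone_chrom == chrom) & (clone_start < b_end) & (clone_end > b_start)
        if not in_bin.any():
            n_inf.append(0)
            n_loss.append(0)
            n_gain.append(0)
            continue
        sub = state_mat[:, in_bin]
        informative = (sub != "missing").any(axis=1)
        n_inf.append(int(informative.sum()))
        n_loss.append(int(((sub == "loss").any(axis=1) & informative).sum()))
        gained = ((sub == "gain") | (sub == "amp")).any(axis=1)
        n_gain.append(int((gained & informative).sum()))

    table = bins.assign(
        n_informative=n_inf,
        n_loss=n_loss,
        n_gain=n_gain,
    )
    denom = table["n_informative"].to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        table["loss_freq"] = np.where(denom > 0, table["n_loss"] / denom, np.nan)
        table["gain_freq"] = np.where(denom > 0, table["n_gain"] / denom, np.nan)
    return FrequencyMap(table=table, bin_size=bin_size)


def amplification_frequency(
    profiles: Sequence[CGHProfile],
    clone_map: CloneMap,
    thresholds: CallThresholds | None = None,
) -> pd.DataFrame:
    """Per-clone high-level amplification frequency across the cohort.

    Returns a table with columns clone_id, chrom, start, end, n_amp,
    n_informative, frequency (NaN where no tumor is informative).
    """
    if not profiles:
        raise ValidationError("need at least one profile")
    thresholds = thresholds or CallThresholds()
    _check_aligned(profiles, clone_map)
    values = np.vstack([p.values for p in profiles])
    mask = np.vstack([p.mask for p in profiles])
    amp = (values > thresholds.amp_min) & ~mask
    n_amp = amp.sum(axis=0)
    n_inf = (~mask).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(n_inf > 0, n_amp / n_inf, np.nan)
    out = clone_map.to_frame()
    out["n_amp"] = n_amp
    out["n_informative"] = n_inf
    out["frequency"] = freq
    return out


def extract_amplicons(
    profile: CGHProfile,
    clone_map: CloneMap,
    thresholds: CallThresholds | None = None,
    max_gap_clones: int = 0,
) -> list[AmpliconSegment]:
    """Maximal runs of consecutive amplified clones as genomic segments.

    Runs on the same chromosome separated by <= ``max_gap_clones`` non-amp
    clones are merged. Segment start/end are the first/last clone boundaries
    of the run. Returns an empty list when nothing is amplified.
    """
    thresholds = thresholds or CallThresholds()
    _check_aligned([profile], clone_map)
    states = call_clone_states(profile, thresholds)
    amp_idx = np.flatnonzero(states == "amp")
    if amp_idx.size == 0:
        return []
    clones = clone_map.entries

    # group amp clones into runs, merging across small same-chromosome gaps
    runs: list[list[int]] = [[int(amp_idx[0])]]
    for i in amp_idx[1:]:
        i = int(i)
        prev = runs[-1][-1]
        same_chrom = clones[i].chrom == clones[prev].chrom
        if same_chrom and (i - prev - 1) <= max_gap_clones:
            runs[-1].append(i)
        else:
            runs.append([i])

    segments = []
    for run in runs:
        first, last = run[0], run[-1]
        covered = list(range(first, last + 1))
        segments.append(
            AmpliconSegment(
                tumor_id=profile.tumor_id,
                chrom=clones[first].chrom,
                start=clones[first].start,
                end=clones[last].end,
                n_clones=len(covered),
                peak_log2=float(np.max(profile.values[run])),
            )
        )
    return segments


def _merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[list[int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def consensus_region(
    segments_by_tumor: Mapping[str, Sequence[AmpliconSegment]],
    min_support: int | None = None,
    chrom: str | None = None,
) -> ConsensusRegion:
    """Minimal common region: intersection over tumors of their amplicon unions.

    With the default ``min_support`` (all contributing tumors) the result is
    the strict cross-tumor intersection. If that intersection is empty (or a
    smaller ``min_support`` is given), the region of maximal support >= the
    requested level is returned, widest first, leftmost on ties. The returned
    region is contained in every supporting tumor's amplified footprint.
    """
    per_tumor: dict[str, list[tuple[int, int]]] = {}
    chroms = set()
    for tumor_id, segs in segments_by_tumor.items():
        segs = [s for s in segs if chrom is None or s.chrom == chrom]
        if not segs:
            continue
        chroms.update(s.chrom for s in segs)
        per_tumor[tumor_id] = _merge_intervals([(s.start, s.end) for s in segs])
    if not per_tumor:
        raise ValidationError("no amplicons to intersect")
    if len(chroms) > 1:
        raise ValidationError(
            f"segments span multiple chromosomes {sorted(chroms)}; pass chrom="
        )
    the_chrom = chroms.pop()
    target = len(per_tumor) if min_support is None else min_support

    # sweep over elementary intervals between breakpoints
    points = sorted({p for ivs in per_tumor.values() for iv in ivs for p in iv})
    pieces = []  # (start, end, frozenset of supporting tumors)
    for s, e in zip(points[:-1], points[1:]):
        support = frozenset(
            t for t, ivs in per_tumor.items()
            if any(a <= s and e <= b for a, b in ivs)
        )
        if support:
            pieces.append((s, e, support))

    best_level = max(len(p[2]) for p in pieces)
    level = min(target, best_level)
    # merge contiguous pieces with identical support sets at the chosen level
    candidates: list[tuple[int, int, frozenset]] = []
    for s, e, sup in pieces:
        if len(sup) < level:
            continue
        if candidates and candidates[-1][1] == s and candidates[-1][2] == sup:
            candidates[-1] = (candidates[-1][0], e, sup)
        else:
            candidates.append((s, e, sup))
    # highest support, then widest, then leftmost
    s, e, sup = max(candidates, key=lambda c: (len(c[2]), c[1] - c[0], -c[0]))
    return ConsensusRegion(
        chrom=the_chrom,
        start=s,
        end=e,
        support=len(sup),
        supporting_tumor_ids=tuple(sorted(sup)),
    )


def genes_in_region(
    region: ConsensusRegion | tuple[str, int, int],
    annotation: Sequence[GeneRecord],
    flank: int = 0,
) -> list[GeneRecord]:
    """Genes whose span overlaps [start - flank, end + flank), half-open,
    in stable start order. Any overlap counts."""
    if isinstance(region, ConsensusRegion):
        chrom, start, end = region.chrom, region.start, region.end
    else:
        chrom, start, end = region
    lo, hi = start - flank, end + flank
    hits = [
        g for g in annotation
        if g.chrom == chrom and g.start < hi and g.end > lo
    ]
    return sorted(hits, key=lambda g: (g.start, g.end, g.name))


_DATA_DIR = Path(__file__).parent / "data"

#: printed gene-listing interval of the 3q26.33 consensus amplicon (bp)
CONSENSUS_INTERVAL = ("chr3", 181_900_000, 184_600_000)


def packaged_gene_annotation() -> list[GeneRecord]:
    """The packaged 3q26.33 gene annotation (synthetic coordinates).

    Nine RefSeq genes fall inside the 181.9-184.6 Mb listing interval; the
    coordinates are synthetic approximations laid out in the documented
    genomic order, with flanking genes outside the interval for boundary
    tests.
    """
    return read_gene_annotation(_DATA_DIR / "chr3q26_genes.synthetic.bed")


def packaged_amplicon_fixture() -> dict[str, list[AmpliconSegment]]:
    """Five per-tumor 3q26.33 amplicon segments with differing outer limits.

    Synthetic stand-in for the five tiling-array amplicon profiles; their
    strict intersection is the 181.9-184.6 Mb consensus (2.7 Mb).
    """
    segs: dict[str, list[AmpliconSegment]] = {}
    for g in read_gene_annotation(_DATA_DIR / "amplicon_segments.synthetic.bed"):
        segs.setdefault(g.name, []).append(
            AmpliconSegment(
                tumor_id=g.name, chrom=g.chrom, start=g.start, end=g.end,
                n_clones=1, peak_log2=2.5,
            )
        )
    return segs


def packaged_candidate_mediators() -> list[str]:
    """Static literature-curated list of 16 cancer-related candidate mediator
    genes downstream of SOX2 (one composite two-gene probe annotation kept
    verbatim). Excluded from all statistics."""
    path = _DATA_DIR / "sox2_candidate_mediators.txt"
    return [
        line.strip() for line in path.read_text().splitlines()
        if line.strip() and not line.startswith("#")
    ]
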