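"""Seeded generators for every fixture the pipeline needs, with ground truth.

Each generator is a pure function of (parameters, seed) and returns the
generated data together with a truth object sufficient to compute every
downstream expected value. Noise is Gaussian on the log2 scale for both
aCGH and expression data. Defaults emulate the composition of the study
cohorts this pipeline was designed around: a 26-tumor chromosome-3 aCGH
cohort (5 focal 3q26.33 amplicon carriers, broad 3q gains, recurrent 3p
losses), a five-tumor 3q26.3-3q27 tiling cohort, tumor-vs-normal expression
matrices with an embedded stemness module and a SOX2-correlated target
block, a nine-gene qPCR fold-change table and a 51-case IHC score table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import (
    CGHProfile,
    CloneInterval,
    CloneMap,
    ExpressionMatrix,
    ValidationError,
)

DEFAULT_SEED = 17

#: consensus amplicon interval used by the default designs (bp)
AMPLICON_START = 181_900_000
AMPLICON_END = 184_600_000

#: nine candidate genes of the consensus interval, in genomic order
CANDIDATE_GENES = (
    "FXR1", "DNAJC19", "SOX2OT", "SOX2", "ATP11B",
    "DCUN1D1", "MCCC1", "LAMP3", "B3GNT5",
)


# ---------------------------------------------------------------------------
# chromosome-3 aCGH cohort
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SegmentSpec:
    """One embedded copy-number segment of the generating model."""

    chrom: str
    start: int
    end: int
    state: str  # loss | gain | amp
    mean_log2: float

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValidationError("segment start >= end")
        if self.state == "amp" and self.mean_log2 < 2.0:
            raise ValidationError("amp segments need mean log2 >= 2")
        if self.state == "gain" and not (0.3 < self.mean_log2 < 0.6):
            raise ValidationError("gain segments need mean log2 in (0.3, 0.6)")
        if self.state == "loss" and self.mean_log2 > -0.4:
            raise ValidationError("loss segments need mean log2 <= -0.4")
        if self.state not in ("loss", "gain", "amp"):
            raise ValidationError(f"unknown segment state {self.state!r}")


@dataclass
class CGHCohortTruth:
    """Ground truth of a simulated aCGH cohort."""

    segments_by_tumor: dict[str, list[SegmentSpec]]
    noise_sd: float
    seed: int

    def __post_init__(self) -> None:
        if self.noise_sd <= 0:
            raise ValidationError("noise_sd must be positive")

    def carriers(self, state: str) -> list[str]:
        return [
            t for t, segs in self.segments_by_tumor.items()
            if any(s.state == state for s in segs)
        ]

    @property
    def amplicon_carriers(self) -> list[str]:
        return self.carriers("amp")


def default_chr3_clone_map(n_clones: int = 214) -> CloneMap:
    """A chromosome-3 dedicated array: clones evenly tiled over 0-199 Mb.

    Clone width 150 kb; 214 clones emulate the density of a dedicated
    chromosome arm-scale BAC array.
    """
    chrom_len = 199_000_000
    starts = np.linspace(0, chrom_len - 150_000, n_clones).astype(int)
    entries = [
        CloneInterval(f"CHR3-{i:03d}", "chr3", int(s), int(s) + 150_000)
        for i, s in enumerate(starts)
    ]
    return CloneMap(entries)


def default_cgh_design(n_tumors: int = 26) -> dict[str, list[SegmentSpec]]:
    """The default 26-tumor chromosome-3 design.

    Five tumors carry a focal 3q26.33 amplicon containing the consensus
    interval (mean log2 >= 2) on top of a broad 3q26-qter gain; eleven
    further tumors carry the broad gain only; sixteen tumors carry a 3p
    loss over 8-10 Mb (~60% of the cohort).
    """
    tumor_ids = [f"T{i + 1:02d}" for i in range(n_tumors)]
    design: dict[str, list[SegmentSpec]] = {t: [] for t in tumor_ids}

    amp_bounds = [  # (start, end, mean log2), all containing the consensus
        (180_500_000, 185_500_000, 2.6),
        (181_000_000, 185_000_000, 2.2),
        (181_900_000, 184_600_000, 3.1),
        (181_500_000, 186_000_000, 2.4),
        (179_900_000, 185_900_000, 2.0),
    ]
    gain = SegmentSpec("chr3", 176_000_000, 196_000_000, "gain", 0.45)
    loss = SegmentSpec("chr3", 8_000_000, 10_000_000, "loss", -0.5)

    n_amp = min(5, n_tumors)
    n_gain_only = min(11, max(0, n_tumors - n_amp))
    for i in range(n_amp):
        s, e, m = amp_bounds[i]
        design[tumor_ids[i]].append(gain)
        design[tumor_ids[i]].append(SegmentSpec("chr3", s, e, "amp", m))
    for i in range(n_amp, n_amp + n_gain_only):
        design[tumor_ids[i]].append(gain)
    for i in range(min(16, n_tumors)):  # 16/26 ~ 60% 3p-loss carriers
        design[tumor_ids[i]].append(loss)
    return design


def _render_profiles(
    design: dict[str, list[SegmentSpec]],
    clone_map: CloneMap,
    noise_sd: float,
    rng: np.random.Generator,
) -> list[CGHProfile]:
    chrom = np.array([c.chrom for c in clone_map])
    start = np.array([c.start for c in clone_map])
    end = np.array([c.end for c in clone_map])
    spans = {c: clone_map.chrom_span(c) for c in set(chrom)}

    profiles = []
    for tumor_id, segs in design.items():
        mean = np.zeros(len(clone_map))
        for seg in segs:
            if seg.chrom not in spans:
                raise ValidationError(f"segment on {seg.chrom!r} not covered by map")
            lo, hi = spans[seg.chrom]
            if seg.start < lo or seg.end > hi:
                raise ValidationError(
                    f"segment {seg.chrom}:{seg.start}-{seg.end} outside clone map "
                    f"span {lo}-{hi}"
                )
            overlap = (chrom == seg.chrom) & (start < seg.end) & (end > seg.start)
            mean[overlap] += seg.mean_log2
        values = mean + rng.normal(0.0, noise_sd, size=len(clone_map))
        profiles.append(CGHProfile(tumor_id, values))
    return profiles


def make_cgh_cohort(
    n_tumors: int = 26,
    clone_map: CloneMap | None = None,
    design: dict[str, list[SegmentSpec]] | None = None,
    noise_sd: float = 0.1,
    seed: int = DEFAULT_SEED,
) -> tuple[list[CGHProfile], CGHCohortTruth, CloneMap]:
    """Simulate a chromosome-3 aCGH cohort.

    Each clone value is the sum of the overlapping embedded segment means
    plus N(0, noise_sd). Returns (profiles, truth, clone map); identical
    seeds give bit-identical output.
    """
    if n_tumors < 1:
        raise ValidationError("n_tumors must be >= 1")
    clone_map = clone_map or default_chr3_clone_map()
    if len(clone_map) == 0:
        raise ValidationError("clone map is empty")
    design = design if design is not None else default_cgh_design(n_tumors)
    rng = np.random.default_rng(seed)
    profiles = _render_profiles(design, clone_map, noise_sd, rng)
    truth = CGHCohortTruth(segments_by_tumor=design, noise_sd=noise_sd, seed=seed)
    return profiles, truth, clone_map


# ---------------------------------------------------------------------------
# tiling-array cohort
# ---------------------------------------------------------------------------

TILING_SPAN = (177_000_000, 186_000_000)  # 3q26.3-3q27 tiling window

DEFAULT_TILING_BOUNDARIES = {
    "T15": (179_900_000, 185_900_000),
    "T35": (181_900_000, 184_600_000),
    "T03": (181_000_000, 185_000_000),
    "T11": (181_500_000, 186_000_000),
    "T22": (180_500_000, 185_500_000),
}


@dataclass
class TilingTruth:
    """Ground truth for a simulated tiling-array cohort."""

    boundaries_by_tumor: dict[str, tuple[int, int]]
    amp_log2: float
    clone_spacing: int
    noise_sd: float
    seed: int

    @property
    def intersection(self) -> tuple[int, int]:
        starts = [s for s, _ in self.boundaries_by_tumor.values()]
        ends = [e for _, e in self.boundaries_by_tumor.values()]
        return max(starts), min(ends)


def tiling_clone_map(clone_spacing: int = 50_000) -> CloneMap:
    """Abutting tiling clones over the 177-186 Mb window."""
    if clone_spacing <= 0:
        raise ValidationError("clone_spacing must be positive")
    lo, hi = TILING_SPAN
    starts = np.arange(lo, hi, clone_spacing)
    entries = [
        CloneInterval(f"TIL-{i:04d}", "chr3", int(s), int(min(s + clone_spacing, hi)))
        for i, s in enumerate(starts)
    ]
    return CloneMap(entries)


def make_tiling_cohort(
    boundaries_by_tumor: dict[str, tuple[int, int]] | None = None,
    clone_spacing: int = 50_000,
    amp_log2: float = 2.5,
    noise_sd: float = 0.1,
    seed: int = DEFAULT_SEED,
) -> tuple[list[CGHProfile], TilingTruth, CloneMap]:
    """Simulate tiling-array profiles with known amplicon boundaries.

    Default: the five-tumor design whose amplicons all contain the
    181.9-184.6 Mb consensus with differing outer limits.
    """
    boundaries = dict(boundaries_by_tumor or DEFAULT_TILING_BOUNDARIES)
    lo, hi = TILING_SPAN
    for t, (s, e) in boundaries.items():
        if s >= e or s < lo or e > hi:
            raise ValidationError(
                f"tumor {t!r}: interval {s}-{e} outside tiling span {lo}-{hi}"
            )
    clone_map = tiling_clone_map(clone_spacing)
    design = {
        t: [SegmentSpec("chr3", s, e, "amp", amp_log2)]
        for t, (s, e) in boundaries.items()
    }
    rng = np.random.default_rng(seed)
    profiles = _render_profiles(design, clone_map, noise_sd, rng)
    truth = TilingTruth(
        boundaries_by_tumor=boundaries,
        amp_log2=amp_log2,
        clone_spacing=clone_spacing,
        noise_sd=noise_sd,
        seed=seed,
    )
    return profiles, truth, clone_map


# ---------------------------------------------------------------------------
# expression dataset
# ---------------------------------------------------------------------------

@dataclass
class ExpressionTruth:
    """Ground truth of a simulated tumor-vs-normal expression dataset."""

    de_up: list[str]
    de_down: list[str]
    module_genes: list[str]
    target_coefficients: dict[str, float]  # gene -> SOX2-coupling coefficient
    sox2_gene: str
    n_tumors: int
    n_normals: int
    de_effect: float
    module_effect: float
    target_noise_sd: float
    baseline_sd: float
    seed: int

    @property
    def de_genes(self) -> list[str]:
        return self.de_up + self.de_down

    @property
    def activated_targets(self) -> list[str]:
        return [g for g, c in self.target_coefficients.items() if c > 0]

    @property
    def repressed_targets(self) -> list[str]:
        return [g for g, c in self.target_coefficients.items() if c < 0]


def make_expression_dataset(
    n_genes: int = 2000,
    n_tumors: int = 20,
    n_normals: int = 20,
    n_de_up: int = 50,
    n_de_down: int = 50,
    n_module: int = 40,
    n_targets_activated: int = 40,
    n_targets_repressed: int = 20,
    de_effect: float = 2.0,
    module_effect: float = 1.5,
    target_coef: float = 0.8,
    target_noise_sd: float = 0.5,
    baseline_sd: float = 0.5,
    seed: int = DEFAULT_SEED,
) -> tuple[ExpressionMatrix, ExpressionTruth]:
    """Simulate a log2 tumor-vs-normal expression matrix.

    Per-gene baseline means are N(8, 1); differential genes get +/-de_effect
    in tumors, the stemness module +module_effect, and target-block genes
    track the SOX2 row with coefficient +/-target_coef plus N(0,
    target_noise_sd). Gene 1 is named SOX2 and is an up-regulated gene.
    """
    needed = 1 + n_de_up + n_de_down + n_module + n_targets_activated + n_targets_repressed
    if n_genes < needed:
        raise ValidationError(f"need >= {needed} genes for the requested truth lists")
    rng = np.random.default_rng(seed)

    sox2 = "SOX2"
    others = [f"G{i:04d}" for i in range(2, n_genes + 1)]
    genes = [sox2] + others
    cursor = 0
    if n_de_up > 0:
        de_up = [sox2] + others[cursor:cursor + n_de_up - 1]
        cursor += n_de_up - 1
    else:
        de_up = []
    de_down = others[cursor:cursor + n_de_down]
    cursor += n_de_down
    module_genes = others[cursor:cursor + n_module]
    cursor += n_module
    tgt_act = others[cursor:cursor + n_targets_activated]
    cursor += n_targets_activated
    tgt_rep = others[cursor:cursor + n_targets_repressed]

    samples = [f"SCC{i + 1:02d}" for i in range(n_tumors)] + [
        f"NL{i + 1:02d}" for i in range(n_normals)
    ]
    labels = {s: ("tumor" if s.startswith("SCC") else "normal") for s in samples}
    is_tumor = np.array([labels[s] == "tumor" for s in samples], dtype=float)
    n_samples = len(samples)

    baseline = rng.normal(8.0, 1.0, size=len(genes))
    values = (
        baseline[:, None]
        + rng.normal(0.0, baseline_sd, size=(len(genes), n_samples))
    )
    gidx = {g: i for i, g in enumerate(genes)}
    for g in de_up:
        values[gidx[g]] += de_effect * is_tumor
    for g in de_down:
        values[gidx[g]] -= de_effect * is_tumor
    for g in module_genes:
        values[gidx[g]] += module_effect * is_tumor

    sox2_profile = values[gidx[sox2]]
    centered = sox2_profile - sox2_profile.mean()
    coefficients: dict[str, float] = {}
    for g in tgt_act:
        coefficients[g] = target_coef
    for g in tgt_rep:
        coefficients[g] = -target_coef
    for g, c in coefficients.items():
        values[gidx[g]] = (
            baseline[gidx[g]]
            + c * centered
            + rng.normal(0.0, target_noise_sd, size=n_samples)
        )

    matrix = ExpressionMatrix(
        pd.DataFrame(values, index=genes, columns=samples), labels
    )
    truth = ExpressionTruth(
        de_up=de_up,
        de_down=de_down,
        module_genes=module_genes,
        target_coefficients=coefficients,
        sox2_gene=sox2,
        n_tumors=n_tumors,
        n_normals=n_normals,
        de_effect=de_effect,
        module_effect=module_effect,
        target_noise_sd=target_noise_sd,
        baseline_sd=baseline_sd,
        seed=seed,
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# qPCR fixture
# ---------------------------------------------------------------------------

QPCR_AMPLIFIED = ("AMP1", "AMP2", "AMP3", "AMP4", "AMP5")
QPCR_GAINED = ("GAIN1", "GAIN2")
QPCR_REFERENCE = ("REF1", "REF2")

# per-gene mean linear fold changes in the five amplified tumors
_QPCR_AMP_MEANS = {
    "FXR1": (3.2, 2.9, 4.1, 3.5, 3.0),
    "DNAJC19": (2.8, 3.3, 3.0, 3.6, 2.9),
    "SOX2OT": (20.0, 15.0, 9.0, 7.0, 8.0),
    "SOX2": (30.0, 60.0, 25.0, 12.0, 8.0),
    "ATP11B": (3.4, 2.9, 3.8, 3.1, 3.3),
    "DCUN1D1": (4.0, 3.4, 3.1, 4.2, 3.6),
    "MCCC1": (2.9, 3.1, 3.4, 2.8, 3.2),
    "LAMP3": (0.5, 0.6, 0.4, 0.55, 0.5),
    "B3GNT5": (3.0, 3.5, 2.9, 3.2, 3.7),
}
_QPCR_GAIN_MEANS = {
    "SOX2": (6.0, 7.5),
    "SOX2OT": (5.5, 5.0),
    "LAMP3": (0.6, 0.7),
}


def make_qpcr_fixture(
    seed: int = DEFAULT_SEED, noise_sd: float = 0.08
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Nine-gene x nine-tumor qPCR relative-quantity table with truth labels.

    Columns: five amplified tumors, two low-level-gain tumors, two reference
    tumors without copy-number change (raw quantities ~1). Multiplicative
    log-normal noise emulates technical replicate scatter. Truth labels per
    gene: 'strong' (SOX2, SOX2OT), 'recurrent' (six further candidates) or
    'none' (LAMP3).
    """
    rng = np.random.default_rng(seed)
    tumors = list(QPCR_AMPLIFIED + QPCR_GAINED + QPCR_REFERENCE)
    data = {}
    for gene in CANDIDATE_GENES:
        amp = np.asarray(_QPCR_AMP_MEANS[gene], dtype=float)
        gain = np.asarray(_QPCR_GAIN_MEANS.get(gene, (1.4, 1.6)), dtype=float)
        ref = np.ones(len(QPCR_REFERENCE))
        means = np.concatenate([amp, gain, ref])
        data[gene] = means * np.exp(rng.normal(0.0, noise_sd, size=means.size))
    table = pd.DataFrame(data, index=tumors).T
    labels = {g: "recurrent" for g in CANDIDATE_GENES}
    labels["SOX2"] = labels["SOX2OT"] = "strong"
    labels["LAMP3"] = "none"
    return table, labels


# ---------------------------------------------------------------------------
# IHC fixture
# ---------------------------------------------------------------------------

def make_ihc_fixture(
    seed: int = DEFAULT_SEED, n_cases: int = 51
) -> tuple[pd.DataFrame, dict[str, str]]:
    """A 51-case IHC score table with per-case truth labels.

    Composition (for the default 51 cases): 34 cases whose nuclear H-score
    exceeds the normal-lung reference of 90 (five of them the amplicon
    carriers, with near-uniform strong nuclear staining), 5 cases with
    strong exclusively-cytoplasmic staining, and 12 cases indistinguishable
    from or weaker than normal. Truth labels: 'activated',
    'cytoplasmic_only', 'other'.
    """
    rng = np.random.default_rng(seed)
    n_amp = 5
    n_activated = max(0, round(n_cases * 34 / 51))
    n_cyto = max(0, round(n_cases * 5 / 51))
    n_other = n_cases - n_activated - n_cyto

    rows: list[tuple[int, int, float, str]] = []
    # amplicon carriers: strong nuclear staining in nearly all cells
    for _ in range(min(n_amp, n_activated)):
        rows.append((3, rng.integers(0, 2), float(rng.integers(85, 96)), "activated"))
    # other activated cases: H-score strictly above 90
    for _ in range(n_activated - min(n_amp, n_activated)):
        if rng.random() < 0.5:
            rows.append((3, rng.integers(0, 3), float(rng.integers(40, 81)), "activated"))
        else:
            rows.append((2, rng.integers(0, 3), float(rng.integers(50, 91)), "activated"))
    # strong exclusively-cytoplasmic cases
    for _ in range(n_cyto):
        rows.append((0, 3, 0.0, "cytoplasmic_only"))
    # normal-like / weak cases: H-score <= 90
    normal_like = [(3, 30.0), (2, 40.0), (2, 30.0), (1, 60.0), (1, 40.0), (0, 0.0)]
    for i in range(n_other):
        ni, pct = normal_like[i % len(normal_like)]
        rows.append((ni, rng.integers(0, 2), pct, "other"))

    order = rng.permutation(len(rows))
    table = pd.DataFrame(
        [
            {
                "case_id": f"CASE{j + 1:02d}",
                "nuclear_intensity": int(rows[k][0]),
                "cytoplasmic_intensity": int(rows[k][1]),
                "pct_positive_nuclei": float(rows[k][2]),
            }
            for j, k in enumerate(order)
        ]
    )
    labels = {f"CASE{j + 1:02d}": rows[k][3] for j, k in enumerate(order)}
    return table, labels


# ---------------------------------------------------------------------------
# list-bookkeeping fixtures (target lists, correlated targets, consolidation)
# ---------------------------------------------------------------------------

def _symbols(prefix: str, n: int, start: int = 1) -> list[str]:
    return [f"{prefix}{i:04d}" for i in range(start, start + n)]


def make_target_components(
    n_activated: int = 242, n_repressed: int = 103, n_bound_extra: int = 150,
    n_diff_extra: int = 200,
) -> tuple[set[str], dict[str, str]]:
    """Component lists for curated target-list construction.

    Returns (bound promoters, directed differential dict gene->'up'|'down')
    whose intersection yields ``n_activated`` activated plus ``n_repressed``
    repressed targets (defaults: 242 + 103 = 345). Extra genes appear in
    only one component so the intersection is non-trivial.
    """
    act = _symbols("TGA", n_activated)
    rep = _symbols("TGR", n_repressed)
    bound = set(act) | set(rep) | set(_symbols("BND", n_bound_extra))
    differential = {g: "up" for g in act}
    differential.update({g: "down" for g in rep})
    for g in _symbols("DEX", n_diff_extra // 2):
        differential[g] = "up"
    for g in _symbols("DEY", n_diff_extra - n_diff_extra // 2):
        differential[g] = "down"
    return bound, differential


def make_correlated_expression_fixture(
    n_correlated_activated: int = 71,
    n_anticorrelated_repressed: int = 26,
    n_null_activated: int = 171,
    n_null_repressed: int = 77,
    n_background: int = 300,
    n_samples: int = 40,
    coef: float = 0.8,
    noise_sd: float = 0.5,
    seed: int = DEFAULT_SEED,
):
    """Expression matrix + 345-gene target list for correlated-target recovery.

    The coupled targets (71 activated, 26 repressed; 97 in total) track the
    SOX2 profile with coefficient +/-``coef``. The remaining 248 targets and
    the background genes are decorrelated from SOX2 by construction (their
    noise is residualized against the SOX2 profile), so the truth partition
    is unambiguous and the recovered count is deterministic.

    Returns (matrix, target_list-as-(activated, repressed) sets, truth dict).
    """
    from .enrichment import TargetList

    rng = np.random.default_rng(seed)
    act_hot = _symbols("CTA", n_correlated_activated)
    rep_hot = _symbols("CTR", n_anticorrelated_repressed)
    act_null = _symbols("NTA", n_null_activated)
    rep_null = _symbols("NTR", n_null_repressed)
    background = _symbols("BGX", n_background)

    samples = [f"SCC{i + 1:02d}" for i in range(n_samples)]
    sox2 = rng.normal(10.0, 1.5, size=n_samples)
    centered = sox2 - sox2.mean()
    unit = centered / np.linalg.norm(centered)

    def decorrelated_noise(n_rows: int) -> np.ndarray:
        eps = rng.normal(0.0, noise_sd, size=(n_rows, n_samples))
        return eps - np.outer(eps @ unit, unit)  # exact zero sample correlation

    rows, index = [], []
    index.append("SOX2")
    rows.append(sox2)
    for g in act_hot:
        rows.append(8.0 + coef * centered + rng.normal(0, noise_sd, n_samples))
        index.append(g)
    for g in rep_hot:
        rows.append(8.0 - coef * centered + rng.normal(0, noise_sd, n_samples))
        index.append(g)
    null_rows = decorrelated_noise(len(act_null) + len(rep_null) + len(background))
    for i, g in enumerate(act_null + rep_null + background):
        rows.append(8.0 + null_rows[i])
        index.append(g)

    matrix = ExpressionMatrix(
        pd.DataFrame(np.vstack(rows), index=index, columns=samples),
        {s: "tumor" for s in samples},
    )
    targets = TargetList(
        activated=frozenset(act_hot + act_null),
        repressed=frozenset(rep_hot + rep_null),
    )
    truth = {
        "correlated_activated": act_hot,
        "anticorrelated_repressed": rep_hot,
        "combined_size": len(act_hot) + len(rep_hot),
    }
    return matrix, targets, truth


def make_consolidation_fixture(
    n_consolidated: int = 142,
    n_sox2_total: int = 922,
    n_sig1_only: int = 80,
    n_sig2_only: int = 40,
):
    """SOX2-overexpression signature + two cohort signatures whose overlap
    consolidates to ``n_consolidated`` genes (default 142 of a 922-gene
    SOX2 signature).

    Returns (sox2_signature, [sig1, sig2]) as GeneSignature objects.
    """
    from .expression_drivers import GeneSignature

    n_both = n_consolidated - n_sig1_only - n_sig2_only
    if n_both < 0:
        raise ValidationError("n_consolidated smaller than the per-signature parts")
    shared = _symbols("CON", n_consolidated)
    sox2_only = _symbols("SSQ", n_sox2_total - n_consolidated)
    sig1_extra = _symbols("LS1", 120)
    sig2_extra = _symbols("LS2", 90)

    half = n_consolidated // 2
    sox2_sig = GeneSignature(
        up=sorted(shared[:half] + sox2_only[: len(sox2_only) // 2]),
        down=sorted(shared[half:] + sox2_only[len(sox2_only) // 2:]),
    )
    sig1_members = shared[:n_sig1_only] + shared[n_sig1_only + n_sig2_only:] + sig1_extra
    sig2_members = (
        shared[n_sig1_only:n_sig1_only + n_sig2_only]
        + shared[n_sig1_only + n_sig2_only:]
        + sig2_extra
    )
    sig1 = GeneSignature(up=sorted(sig1_members), down=[])
    sig2 = GeneSignature(up=sorted(sig2_members), down=[])
    return sox2_sig, [sig1, sig2]
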