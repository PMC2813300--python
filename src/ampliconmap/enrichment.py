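"""Gene-list overlap statistics and gene-set enrichment analysis.

Implements the exact hypergeometric overlap test, curated target-list
construction by directed intersection, phenotype-based gene ranking
(signal-to-noise for class labels, Pearson correlation for a continuous
profile such as SOX2 expression), the weighted Kolmogorov-Smirnov
enrichment statistic with permutation-based NES/p/FDR, leading-edge
extraction, correlated-target recovery and signature consolidation.

The enrichment statistic walks the ranked list accumulating
|score|^p / sum_hits |score|^p at set members and -1/(N - |S|) elsewhere;
the enrichment score (ES) is the signed maximum deviation from zero.
NES normalizes ES by the mean same-sign permutation |ES|; the FDR q-value
compares the pooled permutation NES distribution with the observed NES
values in the standard positive/negative-tail fashion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import ExpressionMatrix, GeneSet, ValidationError


# ---------------------------------------------------------------------------
# overlap statistics and target lists
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OverlapResult:
    """Exact hypergeometric overlap of two gene lists in an explicit universe."""

    n_universe: int
    n_A: int
    n_B: int
    n_overlap: int
    p_value: float
    fraction_of_A: float
    fraction_of_B: float


def hypergeometric_overlap(
    A: Iterable[str], B: Iterable[str], universe: Iterable[str]
) -> OverlapResult:
    """Upper-tail P(X >= |A & B|) for X hypergeometric; exact, no approximation.

    The universe is explicit and both lists must be contained in it.
    """
    U = {g.upper() for g in universe}
    sA = {g.upper() for g in A}
    sB = {g.upper() for g in B}
    for name, s in (("A", sA), ("B", sB)):
        stray = sorted(s - U)
        if stray:
            raise ValidationError(f"list {name} not in universe: {stray[:5]}")
    k = len(sA & sB)
    p = float(stats.hypergeom.sf(k - 1, len(U), len(sA), len(sB)))
    return OverlapResult(
        n_universe=len(U),
        n_A=len(sA),
        n_B=len(sB),
        n_overlap=k,
        p_value=min(p, 1.0),
        fraction_of_A=k / len(sA) if sA else 0.0,
        fraction_of_B=k / len(sB) if sB else 0.0,
    )


@dataclass(frozen=True)
class TargetList:
    """Direction-partitioned target genes (activated vs repressed)."""

    activated: frozenset[str]
    repressed: frozenset[str]

    def __post_init__(self) -> None:
        overlap = self.activated & self.repressed
        if overlap:
            raise ValidationError(
                f"targets in both partitions: {sorted(overlap)[:5]}"
            )

    def __len__(self) -> int:
        return len(self.activated) + len(self.repressed)

    @property
    def all_genes(self) -> frozenset[str]:
        return self.activated | self.repressed


def build_target_list(
    bound_promoters: Iterable[str],
    differential: Mapping[str, str],
) -> TargetList:
    """Intersect promoter-bound genes with a directed differential list.

    activated = bound & up-regulated; repressed = bound & down-regulated.
    ``differential`` maps gene symbol to 'up' or 'down'.
    """
    bound = {g.upper() for g in bound_promoters}
    up, down = set(), set()
    for g, direction in differential.items():
        g = g.upper()
        if direction == "up":
            up.add(g)
        elif direction == "down":
            down.add(g)
        else:
            raise ValidationError(f"gene {g!r}: direction must be 'up' or 'down'")
    return TargetList(
        activated=frozenset(bound & up), repressed=frozenset(bound & down)
    )


# ---------------------------------------------------------------------------
# phenotype ranking
# ---------------------------------------------------------------------------

def _signal_to_noise(
    values: np.ndarray, in_a: np.ndarray
) -> np.ndarray:
    a, b = values[:, in_a], values[:, ~in_a]
    mdiff = a.mean(axis=1) - b.mean(axis=1)
    denom = a.std(axis=1, ddof=1) + b.std(axis=1, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        s2n = np.where(denom > 0, mdiff / denom, 0.0)
    return s2n


def _pearson_scores(values: np.ndarray, profile: np.ndarray) -> np.ndarray:
    yc = profile - profile.mean()
    ynorm = np.linalg.norm(yc)
    if ynorm == 0:
        raise ValidationError("continuous phenotype has zero variance")
    vc = values - values.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(vc, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(norms > 0, (vc @ yc) / (norms * ynorm), 0.0)
    return np.clip(r, -1.0, 1.0)


def _order_descending(genes: Sequence[str], scores: np.ndarray) -> np.ndarray:
    """Indices sorting scores descending with stable lexicographic tie-break."""
    gene_rank = np.argsort(np.argsort(np.asarray(genes, dtype=object)))
    return np.lexsort((gene_rank, -scores))


def rank_genes_by_phenotype(
    matrix: ExpressionMatrix,
    phenotype: Mapping[str, str] | Sequence[float] | pd.Series | str,
    group_a: str = "tumor",
    group_b: str = "normal",
) -> pd.Series:
    """Rank all genes by association with a phenotype, descending.

    Class-label phenotypes use the signal-to-noise ratio
    (mean difference / sum of group standard deviations); a continuous
    phenotype (a sample-length profile, or the name of a gene in the matrix
    whose expression defines the phenotype) uses Pearson correlation.
    Zero-variance genes score 0. Ties are broken by gene id (stable).
    """
    values = matrix.values.to_numpy(dtype=float)
    genes = matrix.genes
    if isinstance(phenotype, str):
        gene = phenotype.upper()
        if gene not in matrix.values.index:
            raise ValidationError(f"phenotype gene {gene!r} absent from matrix")
        scores = _pearson_scores(values, matrix.values.loc[gene].to_numpy(float))
    elif isinstance(phenotype, Mapping):
        lab = [phenotype[s] for s in matrix.samples]
        in_a = np.array([l == group_a for l in lab])
        in_b = np.array([l == group_b for l in lab])
        if not (in_a.any() and in_b.any()):
            raise ValidationError("both phenotype classes must be present")
        if not (in_a | in_b).all():
            raise ValidationError("samples with labels outside the two classes")
        scores = _signal_to_noise(values, in_a)
    else:
        profile = np.asarray(phenotype, dtype=float)
        if profile.shape != (len(matrix.samples),):
            raise ValidationError("phenotype length must equal sample count")
        scores = _pearson_scores(values, profile)
    order = _order_descending(genes, scores)
    return pd.Series(scores[order], index=np.asarray(genes, dtype=object)[order])


# ---------------------------------------------------------------------------
# enrichment score
# ---------------------------------------------------------------------------

@dataclass
class ESCurve:
    """Enrichment score with its running sum over the ranked list."""

    es: float
    running: np.ndarray
    hits: np.ndarray  # boolean membership mask over the ranked list
    peak_index: int


def gsea_es(
    ranked: pd.Series, gene_set: GeneSet | Iterable[str], weight: float = 1.0
) -> ESCurve:
    """Weighted KS enrichment score of a gene set on a ranked, scored list.

    ``ranked`` maps gene -> score, ordered descending. The running sum
    increments |score|^weight / sum_hits |score|^weight at set members and
    decrements 1/(N - n_hits) elsewhere; ES is the signed maximal deviation
    from zero (positive preferred on exact magnitude ties).
    """
    members = gene_set.genes if isinstance(gene_set, GeneSet) else {
        g.upper() for g in gene_set
    }
    genes = np.asarray(ranked.index, dtype=object)
    scores = ranked.to_numpy(dtype=float)
    hits = np.isin(genes, list(members))
    n, nh = len(genes), int(hits.sum())
    if nh == 0:
        raise ValidationError("gene set has no overlap with the ranked list")
    w = np.abs(scores[hits]) ** weight
    total = w.sum()
    if total == 0:  # degenerate all-zero scores: fall back to equal weights
        w = np.ones(nh)
        total = float(nh)
    steps = np.full(n, (-1.0 / (n - nh)) if n > nh else 0.0)
    steps[hits] = w / total
    running = np.cumsum(steps)
    hi, lo = float(running.max()), float(running.min())
    if max(hi, 0.0) >= -min(lo, 0.0):
        es = max(hi, 0.0)
        peak = int(np.argmax(running)) if es > 0 else 0
    else:
        es = lo
        peak = int(np.argmin(running))
    return ESCurve(es=es, running=running, hits=hits, peak_index=peak)


def leading_edge(ranked: pd.Series, curve: ESCurve) -> list[str]:
    """Set members at or before the running-sum extremum (at or after it for
    negative ES): the subset that drives the enrichment."""
    genes = np.asarray(ranked.index, dtype=object)
    if curve.es >= 0:
        sel = curve.hits & (np.arange(len(genes)) <= curve.peak_index)
    else:
        sel = curve.hits & (np.arange(len(genes)) >= curve.peak_index)
    return list(genes[sel])


def _es_from_hit_ranks(
    abs_scores_pow: np.ndarray, hit_ranks: np.ndarray
) -> np.ndarray:
    """Vectorized ES for many same-size hit-position sets on one ranked list.

    ``hit_ranks`` is (n_sets, k), each row sorted ascending. Only the values
    of the running sum adjacent to hits can be extrema, so the full walk is
    never materialized.
    """
    n = abs_scores_pow.shape[0]
    hit_ranks = np.sort(hit_ranks, axis=1)
    k = hit_ranks.shape[1]
    w = abs_scores_pow[hit_ranks]
    totals = w.sum(axis=1, keepdims=True)
    equal = totals == 0
    if np.any(equal):  # all-zero scores: equal weights
        w = np.where(equal, 1.0, w)
        totals = np.where(equal, float(k), totals)
    cw = np.cumsum(w / totals, axis=1)
    miss = (1.0 / (n - k)) if n > k else 0.0
    i = np.arange(k)[None, :]
    after = cw - (hit_ranks - i) * miss
    before = after - w / totals
    hi = np.maximum(after.max(axis=1), 0.0)
    lo = np.minimum(before.min(axis=1), 0.0)
    return np.where(hi >= -lo, hi, lo)


# ---------------------------------------------------------------------------
# full enrichment with permutation statistics
# ---------------------------------------------------------------------------

@dataclass
class EnrichmentResult:
    """Permutation-calibrated enrichment of one gene set."""

    set_name: str
    es: float
    nes: float
    p_value: float
    fdr_q: float
    leading_edge: list[str]
    n_permutations: int
    permutation_scheme: str
    set_size: int


MIN_CLASS_FOR_PHENOTYPE_PERM = 7


def _resolve_scheme(scheme: str, phenotype, matrix: ExpressionMatrix,
                    group_a: str, group_b: str) -> str:
    if scheme != "auto":
        return scheme
    if isinstance(phenotype, Mapping):
        na = sum(1 for s in matrix.samples if phenotype[s] == group_a)
        nb = sum(1 for s in matrix.samples if phenotype[s] == group_b)
        ok = na >= MIN_CLASS_FOR_PHENOTYPE_PERM and nb >= MIN_CLASS_FOR_PHENOTYPE_PERM
    else:
        ok = len(matrix.samples) >= 2 * MIN_CLASS_FOR_PHENOTYPE_PERM
    return "phenotype" if ok else "gene_set"


def _permuted_rank_scores(
    matrix: ExpressionMatrix,
    phenotype,
    group_a: str,
    group_b: str,
    n_perm: int,
    rng: np.random.Generator,
):
    """Yield (scores, order) per phenotype permutation."""
    values = matrix.values.to_numpy(dtype=float)
    genes = matrix.genes
    gene_rank = np.argsort(np.argsort(np.asarray(genes, dtype=object)))
    if isinstance(phenotype, Mapping):
        lab = np.array([phenotype[s] for s in matrix.samples], dtype=object)
        in_a = lab == group_a
        if in_a.sum() < 2 or (~in_a).sum() < 2:
            raise ValidationError("phenotype permutation needs >= 2 samples per class")
        for _ in range(n_perm):
            perm = rng.permutation(in_a)
            scores = _signal_to_noise(values, perm)
            yield scores, np.lexsort((gene_rank, -scores))
    else:
        if isinstance(phenotype, str):
            profile = matrix.values.loc[phenotype.upper()].to_numpy(float)
        else:
            profile = np.asarray(phenotype, dtype=float)
        for _ in range(n_perm):
            perm = rng.permutation(profile)
            scores = _pearson_scores(values, perm)
            yield scores, np.lexsort((gene_rank, -scores))


def gsea_batch(
    matrix: ExpressionMatrix,
    phenotype,
    gene_sets: Sequence[GeneSet],
    n_perm: int = 1000,
    scheme: str = "auto",
    weight: float = 1.0,
    seed: int | None = None,
    group_a: str = "tumor",
    group_b: str = "normal",
) -> list[EnrichmentResult]:
    """Enrichment of several gene sets with a shared permutation null.

    ``scheme`` is 'phenotype' (permute sample phenotypes, preserving
    gene-gene correlation) when each class has at least 7 samples, else
    'gene_set' (random same-size sets on the observed ranking); 'auto'
    switches accordingly and the choice is recorded in every result.
    """
    if n_perm < 100:
        import warnings

        warnings.warn(f"n_perm={n_perm} < 100: permutation statistics are coarse",
                      stacklevel=2)
    scheme = _resolve_scheme(scheme, phenotype, matrix, group_a, group_b)
    rng = np.random.default_rng(seed)
    ranked = rank_genes_by_phenotype(matrix, phenotype, group_a, group_b)
    genes = np.asarray(ranked.index, dtype=object)
    n = len(genes)
    pos = {g: i for i, g in enumerate(genes)}

    curves, obs_es, sizes, hit_ranks_obs = [], [], [], []
    for s in gene_sets:
        curve = gsea_es(ranked, s, weight=weight)
        curves.append(curve)
        obs_es.append(curve.es)
        hr = np.flatnonzero(curve.hits)
        hit_ranks_obs.append(hr)
        sizes.append(hr.size)
    obs_es = np.asarray(obs_es)

    # permutation null: (n_sets, n_perm) ES values
    null_es = np.empty((len(gene_sets), n_perm))
    if scheme == "gene_set":
        abs_pow = np.abs(ranked.to_numpy(float)) ** weight
        for j, k in enumerate(sizes):
            if k >= n:
                draws = np.tile(np.arange(n), (n_perm, 1))
            else:
                draws = np.argpartition(rng.random((n_perm, n)), k, axis=1)[:, :k]
            null_es[j] = _es_from_hit_ranks(abs_pow, draws)
    elif scheme == "phenotype":
        set_idx = [
            np.array([pos[g] for g in (s.genes if isinstance(s, GeneSet) else s)
                      if g in pos])
            for s in gene_sets
        ]
        for pi, (scores, order) in enumerate(
            _permuted_rank_scores(matrix, phenotype, group_a, group_b, n_perm, rng)
        ):
            inv = np.empty(n, dtype=int)
            inv[order] = np.arange(n)
            abs_pow = np.abs(scores[order]) ** weight
            for j, idx in enumerate(set_idx):
                null_es[j, pi] = _es_from_hit_ranks(
                    abs_pow, np.sort(inv[idx])[None, :]
                )[0]
    else:
        raise ValidationError(f"unknown permutation scheme {scheme!r}")

    # NES: normalize by the mean same-sign |ES| of the null
    def _nes_one(es_val: float, null_row: np.ndarray) -> float:
        same = null_row[np.sign(null_row) == np.sign(es_val)] if es_val != 0 else null_row
        denom = np.abs(same).mean() if same.size else np.abs(null_row).mean()
        return float(es_val / denom) if denom > 0 else 0.0

    nes = np.array([_nes_one(e, null_es[j]) for j, e in enumerate(obs_es)])
    null_nes = np.vstack([
        null_es[j] / np.where(
            np.sign(null_es[j]) >= 0,
            max(null_es[j][null_es[j] > 0].mean(), 1e-12)
            if (null_es[j] > 0).any() else 1.0,
            max(-null_es[j][null_es[j] < 0].mean(), 1e-12)
            if (null_es[j] < 0).any() else 1.0,
        )
        for j in range(len(gene_sets))
    ])

    # nominal p: same-sign permutation tail
    pvals = np.empty(len(gene_sets))
    for j, e in enumerate(obs_es):
        row = null_es[j]
        same = row[row >= 0] if e >= 0 else row[row < 0]
        if same.size == 0:
            pvals[j] = 1.0 / n_perm
        else:
            pvals[j] = max((np.abs(same) >= abs(e)).sum() / same.size, 0.0)

    # FDR q per the positive/negative-tail pooled-null procedure
    pooled = null_nes.ravel()
    qvals = np.empty(len(gene_sets))
    for j, nv in enumerate(nes):
        if nv >= 0:
            null_tail = (pooled >= nv).sum()
            null_side = (pooled >= 0).sum()
            obs_tail = (nes >= nv).sum()
            obs_side = (nes >= 0).sum()
        else:
            null_tail = (pooled <= nv).sum()
            null_side = (pooled < 0).sum()
            obs_tail = (nes <= nv).sum()
            obs_side = (nes < 0).sum()
        num = null_tail / null_side if null_side else 0.0
        den = obs_tail / obs_side if obs_side else 1.0
        qvals[j] = min(1.0, num / den) if den > 0 else 1.0

    results = []
    for j, s in enumerate(gene_sets):
        name = s.name if isinstance(s, GeneSet) else f"set_{j}"
        results.append(
            EnrichmentResult(
                set_name=name,
                es=float(obs_es[j]),
                nes=float(nes[j]),
                p_value=float(pvals[j]),
                fdr_q=float(qvals[j]),
                leading_edge=leading_edge(ranked, curves[j]),
                n_permutations=n_perm,
                permutation_scheme=scheme,
                set_size=int(sizes[j]),
            )
        )
    return results


def gsea(
    matrix: ExpressionMatrix,
    phenotype,
    gene_set: GeneSet,
    n_perm: int = 1000,
    scheme: str = "auto",
    weight: float = 1.0,
    seed: int | None = None,
    group_a: str = "tumor",
    group_b: str = "normal",
) -> EnrichmentResult:
    """Single-set enrichment; see :func:`gsea_batch`."""
    return gsea_batch(
        matrix, phenotype, [gene_set], n_perm=n_perm, scheme=scheme,
        weight=weight, seed=seed, group_a=group_a, group_b=group_b,
    )[0]


# ---------------------------------------------------------------------------
# correlated targets and consolidation
# ---------------------------------------------------------------------------

@dataclass
class CorrelatedTargets:
    """Targets whose expression tracks the driver gene in the tumors."""

    correlated_activated: list[str]
    anticorrelated_repressed: list[str]
    table: pd.DataFrame

    @property
    def combined(self) -> list[str]:
        return sorted(self.correlated_activated + self.anticorrelated_repressed)

    def __len__(self) -> int:
        return len(self.correlated_activated) + len(self.anticorrelated_repressed)


def correlated_target_lists(
    matrix: ExpressionMatrix,
    sox2_gene: str,
    targets: TargetList,
    alpha: float = 0.05,
) -> CorrelatedTargets:
    """Per-gene Pearson correlation of known targets with the driver profile.

    Activated targets must correlate positively, repressed targets
    negatively, at BH-adjusted p < alpha (adjustment across all tested
    target genes present on the matrix).
    """
    from statsmodels.stats.multitest import multipletests

    sox2_gene = sox2_gene.upper()
    if sox2_gene not in matrix.values.index:
        raise ValidationError(f"driver gene {sox2_gene!r} absent from matrix")
    present = [g for g in sorted(targets.all_genes)
               if g in matrix.values.index and g != sox2_gene]
    if not present:
        return CorrelatedTargets([], [], pd.DataFrame(
            columns=["r", "p", "q", "partition"]))
    profile = matrix.values.loc[sox2_gene].to_numpy(float)
    values = matrix.values.loc[present].to_numpy(float)
    r = _pearson_scores(values, profile)
    n = len(matrix.samples)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r**2)
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.isnan(p), 1.0, np.where(np.abs(r) >= 1.0, 0.0, p))
    _, q, _, _ = multipletests(p, method="fdr_bh")
    partition = np.array(
        ["activated" if g in targets.activated else "repressed" for g in present]
    )
    table = pd.DataFrame({"r": r, "p": p, "q": q, "partition": partition},
                         index=present)
    sig = q < alpha
    act = sorted(np.array(present)[(partition == "activated") & sig & (r > 0)])
    rep = sorted(np.array(present)[(partition == "repressed") & sig & (r < 0)])
    return CorrelatedTargets(act, rep, table)


@dataclass
class ConsolidationResult:
    """Genes shared between the driver-overexpression signature and any
    cohort signature, with per-gene direction concordance."""

    genes: list[str]
    table: pd.DataFrame

    def __len__(self) -> int:
        return len(self.genes)


def consolidate_signatures(sox2_squamous, lung_sigs: Sequence) -> ConsolidationResult:
    """Genes present in the driver signature and in any cohort signature."""
    if not lung_sigs:
        raise ValidationError("need at least one cohort signature")
    sox2_dir = {g: "up" for g in sox2_squamous.up}
    sox2_dir.update({g: "down" for g in sox2_squamous.down})
    rows = []
    for g in sorted(sox2_dir):
        in_sigs, dirs = [], []
        for i, sig in enumerate(lung_sigs):
            if g in sig.members:
                in_sigs.append(i)
                dirs.append("up" if g in sig.up else "down")
        if in_sigs:
            rows.append(
                {
                    "gene": g,
                    "direction": sox2_dir[g],
                    "n_signatures": len(in_sigs),
                    "concordant": all(d == sox2_dir[g] for d in dirs),
                }
            )
    table = pd.DataFrame(rows, columns=["gene", "direction", "n_signatures",
                                        "concordant"])
    return ConsolidationResult(genes=list(table["gene"]), table=table)
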