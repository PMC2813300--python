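"""Fold-change computation, driver-gene nomination and signature definition.

Driver nomination follows two recurrence rules applied to RT-qPCR fold
changes of amplified tumors relative to reference tumors without the
copy-number change: recurrent over-expression (fold change > 2 in at least
4 of 5 tumors) and recurrent strong over-expression (fold change > 5 in at
least 4 of 5). Differential signatures use a Welch two-sample t statistic
with Benjamini-Hochberg adjustment and a log2 fold-change floor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import ExpressionMatrix, ValidationError


@dataclass
class FoldChangeTable:
    """Linear-scale fold changes of each gene in each tumor vs the reference
    average. Reference tumors' own fold changes are ~1 by construction."""

    fc: pd.DataFrame  # genes x tumors
    reference_ids: tuple[str, ...]
    reference_average: str = "geometric"

    def __post_init__(self) -> None:
        if (self.fc.to_numpy() <= 0).any():
            raise ValidationError("fold changes must be strictly positive")


@dataclass(frozen=True)
class DriverCall:
    """Recurrence-rule outcome for one candidate gene. The two rules are
    independent counts; 'strong' does not imply 'recurrent' by construction."""

    gene: str
    recurrent_over2: bool
    strong_over5: bool
    n_passing_over2: int
    n_passing_over5: int


@dataclass
class GeneSignature:
    """A directed differential gene list with optional per-gene statistics."""

    up: list[str]
    down: list[str]
    table: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.up = [g.upper() for g in self.up]
        self.down = [g.upper() for g in self.down]
        overlap = set(self.up) & set(self.down)
        if overlap:
            raise ValidationError(f"genes in both directions: {sorted(overlap)[:5]}")

    @property
    def members(self) -> set[str]:
        return set(self.up) | set(self.down)

    def __len__(self) -> int:
        return len(self.up) + len(self.down)


def relative_fold_changes(
    expr: pd.DataFrame,
    reference_ids: Sequence[str],
    average: str = "geometric",
) -> FoldChangeTable:
    """Per-gene fold change of every tumor vs the averaged reference tumors.

    ``expr`` holds linear-scale quantities (genes x tumors, all > 0). The
    reference average is geometric by default (fold changes are log-scale
    quantities); an arithmetic option is provided.
    """
    if not reference_ids:
        raise ValidationError("need at least one reference tumor")
    unknown = [r for r in reference_ids if r not in expr.columns]
    if unknown:
        raise ValidationError(f"unknown reference ids: {unknown}")
    vals = expr.to_numpy(dtype=float)
    if (vals <= 0).any() or not np.isfinite(vals).all():
        raise ValidationError("expression quantities must be positive and finite")
    ref = expr[list(reference_ids)].to_numpy(dtype=float)
    if average == "geometric":
        ref_avg = np.exp(np.log(ref).mean(axis=1))
    elif average == "arithmetic":
        ref_avg = ref.mean(axis=1)
    else:
        raise ValidationError(f"unknown reference average {average!r}")
    fc = expr.divide(ref_avg, axis=0)
    return FoldChangeTable(fc=fc, reference_ids=tuple(reference_ids),
                           reference_average=average)


def classify_driver_candidates(
    fc: FoldChangeTable,
    tumor_subset: Sequence[str],
    k: int = 4,
    n: int = 5,
    thr_recurrent: float = 2.0,
    thr_strong: float = 5.0,
) -> list[DriverCall]:
    """Apply the two recurrence rules over exactly ``n`` evaluated tumors."""
    if len(tumor_subset) != n:
        raise ValidationError(
            f"tumor subset has {len(tumor_subset)} tumors, expected {n}"
        )
    sub = fc.fc[list(tumor_subset)]
    calls = []
    for gene, row in sub.iterrows():
        n2 = int((row > thr_recurrent).sum())
        n5 = int((row > thr_strong).sum())
        calls.append(
            DriverCall(
                gene=gene,
                recurrent_over2=n2 >= k,
                strong_over5=n5 >= k,
                n_passing_over2=n2,
                n_passing_over5=n5,
            )
        )
    return calls


def _group_arrays(
    matrix: ExpressionMatrix, group_a: str, group_b: str
) -> tuple[np.ndarray, np.ndarray]:
    a_cols = matrix.samples_with_label(group_a)
    b_cols = matrix.samples_with_label(group_b)
    if len(a_cols) < 2 or len(b_cols) < 2:
        raise ValidationError("each group needs >= 2 samples")
    return (
        matrix.values[a_cols].to_numpy(dtype=float),
        matrix.values[b_cols].to_numpy(dtype=float),
    )


def differential_table(
    matrix: ExpressionMatrix, group_a: str = "tumor", group_b: str = "normal"
) -> pd.DataFrame:
    """Per-gene Welch t statistic, raw and BH-adjusted p, and log2 fold
    change (mean group_a minus mean group_b; data are log2)."""
    a, b = _group_arrays(matrix, group_a, group_b)
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
    lfc = a.mean(axis=1) - b.mean(axis=1)
    p = np.where(np.isnan(p), 1.0, p)
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return pd.DataFrame(
        {"statistic": t, "p": p, "q": q, "log2fc": lfc}, index=matrix.genes
    )


def define_signature(
    matrix: ExpressionMatrix,
    group_a: str = "tumor",
    group_b: str = "normal",
    alpha: float = 0.05,
    min_abs_lfc: float = 1.0,
) -> GeneSignature:
    """Directed differential signature: adjusted p < alpha AND
    |log2FC| >= min_abs_lfc; direction from the sign of the mean difference."""
    table = differential_table(matrix, group_a, group_b)
    selected = (table["q"] < alpha) & (table["log2fc"].abs() >= min_abs_lfc)
    up = sorted(table.index[selected & (table["log2fc"] > 0)])
    down = sorted(table.index[selected & (table["log2fc"] < 0)])
    return GeneSignature(up=up, down=down, table=table)


def top_markers(
    matrix: ExpressionMatrix,
    group_a: str = "tumor",
    group_b: str = "normal",
    n: int = 100,
) -> list[str]:
    """Genes ranked by |Welch t|, ties broken lexicographically; first n."""
    table = differential_table(matrix, group_a, group_b)
    if n > len(table):
        warnings.warn(
            f"requested {n} markers from {len(table)} genes; returning all",
            stacklevel=2,
        )
        n = len(table)
    order = sorted(
        table.index, key=lambda g: (-abs(table.at[g, "statistic"]), g)
    )
    return order[:n]


def detection_fraction(
    matrix: ExpressionMatrix,
    gene: str,
    group_a: str = "tumor",
    group_b: str = "normal",
    thr: float = 2.0,
) -> float:
    """Fraction of group_a samples where ``gene`` exceeds the group_b mean
    by more than ``thr``-fold (data are log2, so the cutoff is log2(thr))."""
    gene = gene.upper()
    if gene not in matrix.values.index:
        raise ValidationError(f"gene {gene!r} absent from matrix")
    a_cols = matrix.samples_with_label(group_a)
    b_cols = matrix.samples_with_label(group_b)
    row = matrix.values.loc[gene]
    baseline = row[b_cols].mean()
    return float((row[a_cols] > baseline + np.log2(thr)).mean())
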