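"""Immunohistochemistry H-score classification of SOX2 activation.

Each case is scored by nuclear staining intensity (0-3), cytoplasmic
intensity (0-3) and the percentage of positive nuclei. The nuclear H-score
(intensity x percent positive, range 0-300) operationalizes "stronger
nuclear staining in a higher proportion of cells"; a case is called
activated when its H-score strictly exceeds the normal bronchial epithelium
reference (intensity 3 in 30% of cells = 90), so a tumor indistinguishable
from normal is not called activated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .io_formats import ValidationError

#: normal bronchial epithelium: strong nuclear staining in 30% of cells
NORMAL_REFERENCE_H = 90.0


@dataclass(frozen=True)
class IHCRecord:
    """Per-case staining scores."""

    case_id: str
    nuclear_intensity: int
    cytoplasmic_intensity: int
    pct_positive_nuclei: float

    def __post_init__(self) -> None:
        if self.nuclear_intensity not in (0, 1, 2, 3):
            raise ValidationError(
                f"{self.case_id}: nuclear intensity {self.nuclear_intensity} "
                "not in 0..3"
            )
        if self.cytoplasmic_intensity not in (0, 1, 2, 3):
            raise ValidationError(
                f"{self.case_id}: cytoplasmic intensity "
                f"{self.cytoplasmic_intensity} not in 0..3"
            )
        if not 0.0 <= self.pct_positive_nuclei <= 100.0:
            raise ValidationError(
                f"{self.case_id}: percent positive {self.pct_positive_nuclei} "
                "not in 0..100"
            )


@dataclass(frozen=True)
class ActivationCall:
    """H-score and the binary activation classification for one case."""

    case_id: str
    h_score: float
    activated: bool
    cytoplasmic_only: bool


def score_case(record: IHCRecord, reference_h: float = NORMAL_REFERENCE_H) -> ActivationCall:
    """H-score = nuclear intensity x percent positive nuclei; activated iff
    strictly above the normal reference. 'Cytoplasmic only' flags strong
    cytoplasmic staining with no nuclear signal."""
    h = record.nuclear_intensity * record.pct_positive_nuclei
    return ActivationCall(
        case_id=record.case_id,
        h_score=h,
        activated=h > reference_h,
        cytoplasmic_only=(
            record.cytoplasmic_intensity == 3 and record.nuclear_intensity == 0
        ),
    )


def score_table(
    table: pd.DataFrame, reference_h: float = NORMAL_REFERENCE_H
) -> list[ActivationCall]:
    """Score every row of an IHC table (see io_formats.read_ihc_table)."""
    return [
        score_case(
            IHCRecord(
                case_id=str(row.case_id),
                nuclear_intensity=int(row.nuclear_intensity),
                cytoplasmic_intensity=int(row.cytoplasmic_intensity),
                pct_positive_nuclei=float(row.pct_positive_nuclei),
            ),
            reference_h,
        )
        for row in table.itertuples(index=False)
    ]


def summarize_cohort(calls: Sequence[ActivationCall]) -> dict:
    """Category counts and whole percentages over a scored cohort.

    Categories are mutually exclusive: activated, cytoplasmic_only
    (strong cytoplasmic staining without nuclear signal), other.
    """
    if not calls:
        raise ValidationError("cannot summarize an empty cohort")
    n = len(calls)
    n_act = sum(c.activated for c in calls)
    n_cyt = sum(c.cytoplasmic_only and not c.activated for c in calls)
    n_other = n - n_act - n_cyt
    return {
        "n_cases": n,
        "activated": {"count": n_act, "percent": round(100.0 * n_act / n)},
        "cytoplasmic_only": {"count": n_cyt, "percent": round(100.0 * n_cyt / n)},
        "other": {"count": n_other, "percent": round(100.0 * n_other / n)},
    }
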