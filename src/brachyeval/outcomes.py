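"""CTCAE outcome scoring and correlation with TCP/NTCP estimates.

Clinical follow-up after brachytherapy is graded on the CTCAE 1–5 adverse
event scale (1 mild … 5 death).  For quantitative comparison with model
estimates the grades are coded onto an evenly spaced 0–1 scale,
score = (grade − 1)/4, and the coded outcomes are correlated with the
predicted probabilities.  Because the coding is ordinal, the association
statistic is the Spearman rank correlation (mid-ranks for ties): NTCP
estimates pair with toxicity scores, TCP with tumour-control scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd
from scipy import stats

__all__ = [
    "GRADE_SCORES",
    "OutcomeRecord",
    "CorrelationReport",
    "grade_to_score",
    "correlate",
    "read_outcomes_csv",
    "write_correlation_csv",
]

#: numerical score per CTCAE grade: 1 mild → 0.00 … 5 death → 1.00
GRADE_SCORES: dict[int, float] = {1: 0.00, 2: 0.25, 3: 0.50, 4: 0.75, 5: 1.00}


def grade_to_score(grade: int) -> float:
    """Map a CTCAE grade (1–5) to its numerical score (grade − 1)/4."""
    if grade not in GRADE_SCORES:
        raise ValueError(f"CTCAE grade must be an integer in 1..5, got {grade!r}")
    return GRADE_SCORES[grade]


@dataclass(frozen=True)
class OutcomeRecord:
    """One patient's scored clinical outcome for one endpoint."""

    patient_id: str
    ctcae_grade: int
    endpoint_label: str = "acute toxicity"
    score: float = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "score", grade_to_score(self.ctcae_grade))


@dataclass(frozen=True)
class CorrelationReport:
    """Spearman rank correlation of model estimates with outcome scores.

    ``coefficient`` is None when the statistic is undefined (fewer than 3
    pairs, or a constant input column); ``note`` then says why.
    """

    coefficient: Optional[float]
    n: int
    pairs: pd.DataFrame
    note: Optional[str] = None


def correlate(
    estimates: Sequence[float], scores: Sequence[float]
) -> CorrelationReport:
    """Spearman rank correlation between estimates and coded outcomes.

    Ties are handled with mid-ranks.  Undefined cases are flagged in the
    report rather than returned as a silent zero.
    """
    if len(estimates) != len(scores):
        raise ValueError(
            f"length mismatch: {len(estimates)} estimates vs {len(scores)} scores"
        )
    pairs = pd.DataFrame({"estimate": list(estimates), "score": list(scores)})
    n = len(pairs)
    if n < 3:
        return CorrelationReport(
            coefficient=None, n=n, pairs=pairs,
            note=f"undefined: need at least 3 pairs, got {n}",
        )
    if pairs["estimate"].nunique() < 2 or pairs["score"].nunique() < 2:
        return CorrelationReport(
            coefficient=None, n=n, pairs=pairs,
            note="undefined: constant input column",
        )
    rho = stats.spearmanr(pairs["estimate"], pairs["score"]).statistic
    return CorrelationReport(coefficient=float(rho), n=n, pairs=pairs)


def read_outcomes_csv(path: str) -> list[OutcomeRecord]:
    """Read outcome records from a CSV with columns
    patient_id, endpoint_label, ctcae_grade."""
    df = pd.read_csv(path)
    required = {"patient_id", "endpoint_label", "ctcae_grade"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return [
        OutcomeRecord(
            patient_id=str(row.patient_id),
            ctcae_grade=int(row.ctcae_grade),
            endpoint_label=str(row.endpoint_label),
        )
        for row in df.itertuples()
    ]


def write_correlation_csv(report: CorrelationReport, path: str) -> None:
    """Write the paired (estimate, score) table plus the coefficient."""
    report.pairs.to_csv(path, index=False)
    with open(path, "a", encoding="utf-8") as fh:
        if report.coefficient is None:
            fh.write(f"# spearman_rho,undefined ({report.note})\n")
        else:
            fh.write(f"# spearman_rho,{report.coefficient:.6f}\n")
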