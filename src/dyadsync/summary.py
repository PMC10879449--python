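"""Cohort-level aggregation: analyzable Ns, percentage tables, cross-task kappa.

Per-dyad synchrony calls are aggregated into the study-level outputs: counts
of analyzable dyads per task and in both tasks, percentages of dyads showing
each direction-by-sign synchrony category (rounded half-away-from-zero to one
decimal), and Cohen's kappa for the cross-task agreement of each category's
binary present/absent indicator, with an approximate p-value from the
large-sample normal test of kappa = 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .dsem import SynchronyCall
from .errors import UndefinedKappaError

__all__ = [
    "AnalyzableCounts",
    "KappaResult",
    "AgreementTable",
    "analyzable_counts",
    "synchrony_percentages",
    "cohens_kappa",
    "build_agreement_table",
    "round_percentage",
]

CATEGORIES = (
    ("child_driven", "positive"),
    ("child_driven", "negative"),
    ("parent_driven", "positive"),
    ("parent_driven", "negative"),
)


def round_percentage(value: float, decimals: int = 1) -> float:
    """Round half-away-from-zero, matching conventional reporting (9/26 -> 34.6)."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class AnalyzableCounts:
    per_task: dict[str, int]
    n_both: int

    def as_tuple(self, task1: str, task2: str) -> tuple[int, int, int]:
        return self.per_task[task1], self.per_task[task2], self.n_both


def analyzable_counts(manifest: Iterable[Mapping] | pd.DataFrame) -> AnalyzableCounts:
    """Count usable dyads per task and in all tasks from a usability manifest.

    ``manifest`` rows need ``dyad_id``, ``task`` and ``usable``; a dyad absent
    from a task simply has no row for it.
    """
    df = pd.DataFrame(manifest)
    required = {"dyad_id", "task", "usable"}
    if not required.issubset(df.columns):
        raise ValueError(f"manifest must have columns {sorted(required)}")
    usable = df[df["usable"].astype(bool)]
    per_task = usable.groupby("task")["dyad_id"].nunique().to_dict()
    tasks = list(df["task"].unique())
    sets = [set(usable.loc[usable["task"] == t, "dyad_id"]) for t in tasks]
    n_both = len(set.intersection(*sets)) if sets else 0
    return AnalyzableCounts(per_task={t: int(per_task.get(t, 0)) for t in tasks}, n_both=n_both)


def synchrony_percentages(
    calls: Sequence[SynchronyCall], denominator: int
) -> pd.DataFrame:
    """Counts and one-decimal percentages per direction-by-sign category."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    if len(calls) > denominator:
        raise ValueError("denominator must be at least the number of calls")
    rows = []
    for direction in ("child_driven", "parent_driven"):
        for sign in ("positive", "negative", "null"):
            count = sum(1 for c in calls if getattr(c, direction) == sign)
            rows.append(
                {
                    "direction": direction,
                    "sign": sign,
                    "count": count,
                    "percentage": round_percentage(100.0 * count / denominator),
                }
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class KappaResult:
    kappa: float
    p_value: float
    n: int


def cohens_kappa(x: Sequence, y: Sequence) -> KappaResult:
    """Cohen's kappa for two paired binary vectors.

    ``kappa = (p_o - p_e) / (1 - p_e)`` with observed agreement ``p_o`` and
    chance agreement ``p_e`` from the marginals.  The approximate p-value uses
    the large-sample standard error of kappa under independence (kappa = 0).
    """
    x = np.asarray(x).astype(bool)
    y = np.asarray(y).astype(bool)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 paired observations")
    p_o = float(np.mean(x == y))
    px = np.array([np.mean(~x), np.mean(x)])
    py = np.array([np.mean(~y), np.mean(y)])
    p_e = float(px @ py)
    if p_e >= 1.0 - 1e-12:
        raise UndefinedKappaError("chance agreement is 1; kappa undefined")
    kappa = (p_o - p_e) / (1.0 - p_e)
    # Fleiss large-sample SE under H0: kappa = 0
    se0_num = p_e + p_e**2 - float(np.sum(px * py * (px + py)))
    se0 = math.sqrt(max(se0_num, 0.0)) / ((1.0 - p_e) * math.sqrt(n))
    if se0 > 0:
        p_value = float(2.0 * norm.sf(abs(kappa) / se0))
    else:
        p_value = 1.0
    return KappaResult(kappa=float(kappa), p_value=p_value, n=n)


@dataclass(frozen=True)
class AgreementTable:
    """Per-category task percentages and cross-task kappa (Table-style layout)."""

    task1: str
    task2: str
    n_task1: int
    n_task2: int
    n_both: int
    rows: pd.DataFrame  # direction, sign, pct_task1, pct_task2, kappa, p_value, kappa_defined

    def to_frame(self) -> pd.DataFrame:
        return self.rows.copy()


def build_agreement_table(
    calls_task1: Sequence[SynchronyCall],
    calls_task2: Sequence[SynchronyCall],
    task_labels: tuple[str, str] = ("conflict", "planning"),
) -> AgreementTable:
    """Cross-task agreement in synchrony categories.

    Percentages use each task's own analyzable denominator; kappa for each
    category is computed over the dyads present in both tasks from the binary
    indicator of showing that category.  An undefined kappa is flagged, not
    raised.
    """
    by1 = {c.dyad_id: c for c in calls_task1}
    by2 = {c.dyad_id: c for c in calls_task2}
    common = sorted(set(by1) & set(by2))
    if not common:
        raise ValueError("no dyads with calls in both tasks")
    rows = []
    for direction, sign in CATEGORIES:
        pct1 = round_percentage(
            100.0 * sum(getattr(c, direction) == sign for c in calls_task1) / len(by1)
        )
        pct2 = round_percentage(
            100.0 * sum(getattr(c, direction) == sign for c in calls_task2) / len(by2)
        )
        x = [getattr(by1[d], direction) == sign for d in common]
        y = [getattr(by2[d], direction) == sign for d in common]
        try:
            kr = cohens_kappa(x, y)
            kappa, p_value, defined = kr.kappa, kr.p_value, True
        except UndefinedKappaError:
            kappa, p_value, defined = float("nan"), float("nan"), False
        rows.append(
            {
                "direction": direction,
                "sign": sign,
                "pct_task1": pct1,
                "pct_task2": pct2,
                "kappa": kappa,
                "p_value": p_value,
                "kappa_defined": defined,
            }
        )
    return AgreementTable(
        task1=task_labels[0],
        task2=task_labels[1],
        n_task1=len(by1),
        n_task2=len(by2),
        n_both=len(common),
        rows=pd.DataFrame(rows),
    )
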