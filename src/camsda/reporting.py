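"""Evaluation metrics and benchmark-style summary tables.

Per-class accuracy is within-class recall: the fraction of samples of a
class that are predicted as that class, reported in percent.  Method
rows are summarised by their arithmetic mean, sample standard deviation
(n-1 denominator), and the difference of a reference method's mean over
each competitor's.  Paired two-sided t-tests over matched per-class (or
per-run) accuracies quantify whether a method's advantage is systematic.

The transcribed published comparison tables for the two chest X-ray
transfer scenarios ship with the package (``data/published_tables.csv``)
and drive the summary-arithmetic reproduction checks.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AccuracyTable",
    "PairedTestResult",
    "per_class_accuracy",
    "summarize",
    "paired_t_test",
    "render_report",
    "load_published_tables",
    "round_half_up",
]


def round_half_up(x: float, decimals: int = 2) -> float:
    """Round with ties away from zero, matching printed-table formatting."""
    quantum = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(quantum, rounding=ROUND_HALF_UP))


@dataclass
class AccuracyTable:
    """Methods x classes matrix of per-class accuracies in percent."""

    methods: List[str]
    classes: List[str]
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (len(self.methods), len(self.classes)):
            raise ValueError("values must be a methods x classes matrix")
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (finite.min() < 0 or finite.max() > 100):
            raise ValueError("accuracies must lie in [0, 100]")

    @property
    def avg(self) -> np.ndarray:
        return self.values.mean(axis=1)

    @property
    def sd(self) -> np.ndarray:
        if len(self.classes) < 2:
            raise ValueError("standard deviation needs at least two class columns")
        return self.values.std(axis=1, ddof=1)

    def row(self, method: str) -> np.ndarray:
        return self.values[self.methods.index(method)]


@dataclass
class PairedTestResult:
    t_statistic: float
    p_value: float
    df: int


def per_class_accuracy(
    true_labels: Sequence[int], predicted_labels: Sequence[int], n_classes: int
) -> np.ndarray:
    """Within-class recall per class, in percent; absent classes are NaN."""
    true = np.asarray(true_labels, dtype=np.intp)
    pred = np.asarray(predicted_labels, dtype=np.intp)
    if true.size == 0:
        raise ValueError("empty label vectors")
    if true.shape != pred.shape:
        raise ValueError("true and predicted labels must have equal length")
    if true.min() < 0 or true.max() >= n_classes or pred.min() < 0 or pred.max() >= n_classes:
        raise ValueError(f"labels must lie in [0, {n_classes})")
    out = np.full(n_classes, np.nan)
    for c in range(n_classes):
        mask = true == c
        if mask.any():
            out[c] = 100.0 * (pred[mask] == c).mean()
    return out


def summarize(table: AccuracyTable, reference: Optional[str] = None) -> pd.DataFrame:
    """Per-class columns plus Avg, SD and (optionally) Delta vs a reference.

    Delta is ``avg(reference) - avg(method)``.  Full precision is kept;
    callers round for display.
    """
    if not np.all(np.isfinite(table.values)):
        raise ValueError("summarize needs a complete accuracy matrix")
    frame = pd.DataFrame(table.values, index=table.methods, columns=table.classes)
    frame["Avg"] = table.avg
    frame["SD"] = table.sd
    if reference is not None:
        if reference not in table.methods:
            raise ValueError(f"reference method {reference!r} not in table")
        ref_avg = table.avg[table.methods.index(reference)]
        frame["Delta"] = ref_avg - frame["Avg"]
    return frame


def paired_t_test(a: Sequence[float], b: Sequence[float]) -> PairedTestResult:
    """Two-sided paired Student t-test on matched accuracy vectors."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("need two equal-length vectors of at least two pairs")
    d = a - b
    if np.allclose(d.std(ddof=1), 0.0):
        raise ValueError(
            "degenerate paired test: differences have zero variance"
            + (" (all differences are zero)" if np.allclose(d, 0) else " (infinite t)")
        )
    result = stats.ttest_rel(a, b)
    return PairedTestResult(
        t_statistic=float(result.statistic),
        p_value=float(result.pvalue),
        df=int(a.size - 1),
    )


def printed_delta(reference_avg: float, method_avg: float, decimals: int = 2) -> float:
    """Difference of two-decimal-rounded means, the printed-table convention.

    Published deltas are taken between the rounded Avg entries, so e.g.
    93.50 - 77.64 = 15.86 even when the full-precision difference rounds
    to 15.85.
    """
    return round(
        round_half_up(reference_avg, decimals) - round_half_up(method_avg, decimals), decimals
    )


def _format_cell(value: float, bold: bool) -> str:
    text = f"{round_half_up(value):.2f}"
    return f"**{text}**" if bold else text


def render_report(
    tables: Dict[str, AccuracyTable],
    tests: Optional[Dict[str, Dict[str, PairedTestResult]]] = None,
    reference: Optional[str] = None,
) -> str:
    """Markdown report with per-column maxima bolded (first index on ties)."""
    lines: List[str] = []
    for name, table in sorted(tables.items()):
        summary = summarize(table, reference=reference if reference in (table.methods or []) else None)
        columns = list(summary.columns)
        lines.append(f"## {name}")
        lines.append("")
        lines.append("| Method | " + " | ".join(columns) + " |")
        lines.append("|" + "---|" * (len(columns) + 1))
        bold_rows = {
            col: int(np.argmax(summary[col].to_numpy())) for col in columns if col != "Delta"
        }
        for r, method in enumerate(summary.index):
            cells = [
                _format_cell(summary.iloc[r][col], bold_rows.get(col, -1) == r) for col in columns
            ]
            lines.append(f"| {method} | " + " | ".join(cells) + " |")
        lines.append("")
    if tests:
        for name, methods in sorted(tests.items()):
            lines.append(f"## {name}: paired t-tests")
            lines.append("")
            lines.append("| Method | t-statistic | p-value | df |")
            lines.append("|---|---|---|---|")
            for method, res in methods.items():
                lines.append(
                    f"| {method} | {res.t_statistic:.4f} | {res.p_value:.4f} | {res.df} |"
                )
            lines.append("")
    return "\n".join(lines)


def load_published_tables() -> Dict[str, AccuracyTable]:
    """The transcribed published per-class accuracy tables, keyed by scenario."""
    with resources.files("camsda.data").joinpath("published_tables.csv").open("r") as fh:
        frame = pd.read_csv(fh)
    tables: Dict[str, AccuracyTable] = {}
    class_columns = ["AT", "CA", "EF", "CO", "ED", "PN"]
    for name, group in frame.groupby("table", sort=False):
        tables[name] = AccuracyTable(
            methods=list(group["method"]),
            classes=class_columns,
            values=group[class_columns].to_numpy(),
        )
    return tables


def load_published_averages() -> pd.DataFrame:
    """Printed Avg column next to each transcribed row, for reproduction checks."""
    with resources.files("camsda.data").joinpath("published_tables.csv").open("r") as fh:
        return pd.read_csv(fh)
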