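"""Result artifacts: summary tables, statistical comparisons, figures.

The summary table mirrors the study layout — mean (SD) of the
per-replication average outcome for each policy, per outcome and dataset,
with call success expressed as a percentage.  Group comparisons use a
chi-square test on 2x2 success/failure counts (no continuity correction by
default) and a two-sided Mann-Whitney U test with tie correction for the
ordinal scores, both on per-call observations pooled across replications.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import seaborn as sns

from .engine import ExperimentResult

__all__ = [
    "ComparisonResult",
    "summarize_table",
    "compare_success",
    "compare_scores",
    "compare_policies",
    "plot_distributions",
    "plot_regret",
]

POLICY_LABELS = {
    "cyclic": "Systematic allocation (baseline)",
    "single_best": "Single best",
    "oracle": "Optimal",
    "lin_ts": "Precision digital care (proposed)",
}


@dataclass(frozen=True)
class ComparisonResult:
    """One two-group statistical comparison."""

    test: str  # "chi_square" | "mann_whitney_u"
    statistic: float
    p_value: float
    groups: tuple[str, str]


# ---------------------------------------------------------------------------
# Summary table
# ---------------------------------------------------------------------------

def summarize_table(
    results: Mapping[tuple[str, str], ExperimentResult],
    policies: Sequence[str] = tuple(POLICY_LABELS),
) -> pd.DataFrame:
    """Mean (SD) per policy per outcome per dataset.

    Call success is reported as a percentage; PHQ-2 and SRH on their
    natural scales.  One row per (outcome, dataset), one ``mean``/``sd``
    column pair per policy.
    """
    rows = []
    for (ds, outcome), res in results.items():
        missing = [p for p in policies if p not in set(res.summary["policy"])]
        if missing:
            raise ValueError(
                f"missing policies for {outcome}/{ds}: {missing}"
            )
        agg = res.aggregate().set_index("policy")
        scale = 100.0 if outcome == "call_success" else 1.0
        row: dict[str, object] = {"outcome": outcome, "dataset": ds}
        for p in policies:
            row[f"{p}_mean"] = agg.loc[p, "mean"] * scale
            row[f"{p}_sd"] = agg.loc[p, "sd"] * scale
        rows.append(row)
    return pd.DataFrame(rows)


def render_table_text(table: pd.DataFrame, policies: Sequence[str] = tuple(POLICY_LABELS)) -> str:
    """Plain-text rendering of the summary table, mean (SD) cells."""
    lines = []
    header = ["outcome", "dataset"] + [POLICY_LABELS.get(p, p) for p in policies]
    lines.append("\t".join(header))
    for _, row in table.iterrows():
        cells = [str(row["outcome"]), str(row["dataset"])]
        for p in policies:
            cells.append(f"{row[f'{p}_mean']:.2f} ({row[f'{p}_sd']:.2f})")
        lines.append("\t".join(cells))
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# Statistical comparisons
# ---------------------------------------------------------------------------

def compare_success(
    counts_a: tuple[int, int],
    counts_b: tuple[int, int],
    groups: tuple[str, str] = ("a", "b"),
    correction: bool = False,
) -> ComparisonResult:
    """Chi-square test on a 2x2 (successes, failures) table.

    No Yates continuity correction by default (samples here are large).
    """
    table = np.asarray([counts_a, counts_b], dtype=float)
    if (table < 0).any() or table.sum(axis=1).min() <= 0:
        raise ValueError("counts must be nonnegative with nonempty groups")
    if table.sum(axis=0).min() == 0:
        # Degenerate margin: no variation in outcome, no association.
        return ComparisonResult("chi_square", 0.0, 1.0, groups)
    res = stats.chi2_contingency(table, correction=correction)
    return ComparisonResult(
        "chi_square", float(res.statistic), float(res.pvalue), groups
    )


def compare_scores(
    scores_a: Sequence[int] | np.ndarray,
    scores_b: Sequence[int] | np.ndarray,
    groups: tuple[str, str] = ("a", "b"),
) -> ComparisonResult:
    """Two-sided Mann-Whitney U with tie-corrected normal approximation."""
    a = np.asarray(scores_a)
    b = np.asarray(scores_b)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both score groups must be nonempty")
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return ComparisonResult(
        "mann_whitney_u", float(res.statistic), float(res.pvalue), groups
    )


def _counts_to_values(counts: Mapping[int, int]) -> np.ndarray:
    vals = sorted(counts)
    return np.repeat(vals, [counts[v] for v in vals])


def compare_policies(
    result: ExperimentResult,
    policy_a: str = "cyclic",
    policy_b: str = "lin_ts",
) -> ComparisonResult:
    """Compare two policies' pooled per-call outcomes for one scenario.

    Call success -> chi-square on success/failure counts; PHQ-2 / SRH ->
    Mann-Whitney U on the pooled integer scores.
    """
    ca, cb = result.value_counts[policy_a], result.value_counts[policy_b]
    if result.config.outcome == "call_success":
        a = (ca.get(1, 0), ca.get(0, 0))
        b = (cb.get(1, 0), cb.get(0, 0))
        return compare_success(a, b, groups=(policy_a, policy_b))
    return compare_scores(
        _counts_to_values(ca), _counts_to_values(cb), groups=(policy_a, policy_b)
    )


# ---------------------------------------------------------------------------
# Figures
# ---------------------------------------------------------------------------

_OUTCOME_LABEL = {
    "call_success": "Average call success rate",
    "phq2": "Average PHQ-2 score",
    "srh": "Average SRH score",
}


def plot_distributions(
    results: Mapping[tuple[str, str], ExperimentResult], out_dir: str | Path
) -> list[Path]:
    """One per-replication-mean distribution panel per dataset per outcome."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for (ds, outcome), res in results.items():
        if res.summary.empty:
            raise ValueError(f"no replications for {outcome}/{ds}")
        data = res.summary.copy()
        if outcome == "call_success":
            data["mean_outcome"] = data["mean_outcome"] * 100.0
        fig, ax = plt.subplots(figsize=(6, 4))
        sns.boxplot(
            data=data, x="policy", y="mean_outcome", hue="policy",
            order=list(res.config.policies), ax=ax, legend=False,
        )
        ax.set_xlabel("")
        ax.set_ylabel(_OUTCOME_LABEL[outcome])
        ax.set_title(f"{_OUTCOME_LABEL[outcome]} — {ds}")
        fig.tight_layout()
        path = out_dir / f"distribution_{outcome}_{ds}.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        paths.append(path)
    return paths


def plot_regret(
    results: Mapping[tuple[str, str], ExperimentResult], out_dir: str | Path
) -> list[Path]:
    """One cumulative-regret panel per dataset per outcome, all policies."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for (ds, outcome), res in results.items():
        trace = res.regret_trace
        if trace.empty:
            raise ValueError(f"empty regret trace for {outcome}/{ds}")
        fig, ax = plt.subplots(figsize=(6, 4))
        for policy in trace.columns:
            ax.plot(trace.index, trace[policy], label=POLICY_LABELS.get(policy, policy))
        ax.set_xlabel("Interaction step")
        ax.set_ylabel("Average cumulative regret")
        ax.set_title(f"Cumulative regret — {outcome} ({ds})")
        ax.legend(fontsize=8)
        fig.tight_layout()
        path = out_dir / f"regret_{outcome}_{ds}.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        paths.append(path)
    return paths
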