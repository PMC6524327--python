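"""Case/control comparison of per-gene score distributions.

Gene-score matrices are zero-inflated and far from normal, so group
comparisons use the Mann-Whitney U rank-sum test: midranks for ties with
the tie-corrected normal approximation (an exact null distribution is used
for very small, tie-free groups, where the approximation is poorest).

Two designs are supported:

* ``compare_gene`` — the full score distributions of the two groups;
* ``compare_tail`` — a one-tailed comparison restricted to the top ``q``
  fraction of each group, aimed at genes that explain disease in only a
  minority of cases (e.g. a causal gene mutated in ~3-5% of patients),
  where the full-distribution test is diluted by non-carriers.

``run_validation`` orchestrates a table of such tests over genes and
phenotype subgroups, with an optional Bonferroni column over the genes
tested.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .scoring import GeneScoreMatrix

__all__ = [
    "ComparisonResult",
    "StatsError",
    "compare_gene",
    "compare_tail",
    "run_validation",
]

_ALTERNATIVES = {"two_sided": "two-sided", "greater": "greater"}

#: largest per-group size for which the exact U null distribution is used
#: (only without ties; midranks + tie-corrected normal approximation otherwise)
EXACT_MAX_N = 8


class StatsError(ValueError):
    """Invalid comparison inputs."""


@dataclass(frozen=True)
class ComparisonResult:
    """Rank-sum comparison of one gene's scores between two groups."""

    gene: str
    metric: str
    n_case: int
    n_control: int
    u_statistic: float
    p_value: float
    alternative: str
    case_max: float
    case_mean: float
    control_max: float
    control_mean: float
    tail_fraction: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise StatsError(f"p-value {self.p_value} outside [0, 1]")
        if not 0.0 <= self.u_statistic <= self.n_case * self.n_control:
            raise StatsError(
                f"U={self.u_statistic} inconsistent with group sizes "
                f"{self.n_case}x{self.n_control}"
            )


def _as_group(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float).ravel()
    if arr.size == 0:
        raise StatsError(f"{name} group is empty")
    if not np.all(np.isfinite(arr)):
        raise StatsError(f"{name} group contains non-finite scores")
    return arr


def compare_gene(
    case_scores,
    control_scores,
    alternative: str = "two_sided",
    gene: str = "",
    metric: str = "",
) -> ComparisonResult:
    """Mann-Whitney U comparison of two unpaired score distributions.

    ``alternative="greater"`` tests whether case scores are stochastically
    larger than control scores.  When every value in both groups is tied the
    data carry no ordering information and ``p = 1`` is reported with the
    mid-value ``U = n1 * n2 / 2``.
    """
    if alternative not in _ALTERNATIVES:
        raise StatsError(
            f"alternative must be one of {sorted(_ALTERNATIVES)}, got {alternative!r}"
        )
    case = _as_group(case_scores, "case")
    control = _as_group(control_scores, "control")
    pooled = np.concatenate([case, control])
    if np.ptp(pooled) == 0.0:
        u, p = case.size * control.size / 2.0, 1.0
    else:
        has_ties = np.unique(pooled).size < pooled.size
        method = (
            "exact"
            if max(case.size, control.size) <= EXACT_MAX_N and not has_ties
            else "asymptotic"
        )
        res = sps.mannwhitneyu(
            case, control, alternative=_ALTERNATIVES[alternative], method=method
        )
        u, p = float(res.statistic), float(min(res.pvalue, 1.0))
    return ComparisonResult(
        gene=gene,
        metric=metric,
        n_case=case.size,
        n_control=control.size,
        u_statistic=u,
        p_value=p,
        alternative=alternative,
        case_max=float(case.max()),
        case_mean=float(case.mean()),
        control_max=float(control.max()),
        control_mean=float(control.mean()),
    )


def _top_fraction(values: np.ndarray, q: float) -> np.ndarray:
    """The top ``ceil(q * n)`` values; ties at the cut are all included."""
    k = math.ceil(q * values.size)
    threshold = np.sort(values)[::-1][k - 1]
    return values[values >= threshold]


def compare_tail(
    case_scores,
    control_scores,
    tail_fraction: float,
    gene: str = "",
    metric: str = "",
) -> ComparisonResult:
    """One-tailed (case > control) rank-sum test on the extreme score tails.

    The top ``ceil(q * n)`` scores are selected *within each group
    independently*; values tied with the cut-off are all retained rather
    than arbitrarily dropped.  With ``q = 1`` this reduces exactly to the
    one-tailed full-distribution test.
    """
    if not 0.0 < tail_fraction <= 1.0:
        raise StatsError(f"tail fraction must be in (0, 1], got {tail_fraction}")
    case = _as_group(case_scores, "case")
    control = _as_group(control_scores, "control")
    result = compare_gene(
        _top_fraction(case, tail_fraction),
        _top_fraction(control, tail_fraction),
        alternative="greater",
        gene=gene,
        metric=metric,
    )
    return ComparisonResult(
        **{**result.__dict__, "tail_fraction": tail_fraction}
    )


def run_validation(
    matrix: GeneScoreMatrix,
    phenotypes: Mapping[str, str],
    gene_list: Sequence[str] | None = None,
    tests: Sequence[tuple[str, float | None]] = (("two_sided", None),),
    control_group: str = "control",
    case_groups: Sequence[str] | None = None,
    bonferroni: bool = True,
) -> pd.DataFrame:
    """A table of rank-sum comparisons over genes, tests, and case subgroups.

    Parameters
    ----------
    phenotypes
        ``{sample_id: group label}``; must cover every matrix sample and
        contain no sample absent from the matrix.
    tests
        Sequence of ``(test_type, tail_fraction)`` with test_type in
        ``{"two_sided", "greater", "tail"}``; the tail fraction applies only
        to ``"tail"``.
    case_groups
        Phenotype labels compared against ``control_group``; default: every
        non-control label, in first-appearance order.
    bonferroni
        Add a ``p_bonferroni`` column correcting each p for the number of
        genes tested.
    """
    samples = set(matrix.sample_ids)
    unknown = sorted(set(phenotypes) - samples)
    if unknown:
        raise StatsError(f"phenotype file names unknown sample(s): {', '.join(unknown[:5])}")
    uncovered = sorted(samples - set(phenotypes))
    if uncovered:
        raise StatsError(f"samples without phenotype label: {', '.join(uncovered[:5])}")

    genes = list(gene_list) if gene_list is not None else matrix.gene_symbols
    missing = [g for g in genes if g not in matrix.values.columns]
    if missing:
        raise StatsError(f"genes not in matrix: {', '.join(missing)}")

    if case_groups is None:
        seen: list[str] = []
        for s in matrix.sample_ids:
            label = phenotypes[s]
            if label != control_group and label not in seen:
                seen.append(label)
        case_groups = seen
    control_ids = [s for s in matrix.sample_ids if phenotypes[s] == control_group]
    if not control_ids:
        raise StatsError(f"no samples labelled {control_group!r}")

    rows = []
    for group in case_groups:
        case_ids = [s for s in matrix.sample_ids if phenotypes[s] == group]
        if not case_ids:
            raise StatsError(f"no samples labelled {group!r}")
        for gene in genes:
            case = matrix.values.loc[case_ids, gene].to_numpy()
            control = matrix.values.loc[control_ids, gene].to_numpy()
            for test_type, q in tests:
                if test_type == "tail":
                    if q is None:
                        raise StatsError("tail test requires a tail fraction")
                    res = compare_tail(case, control, q, gene=gene, metric=matrix.metric_name)
                else:
                    res = compare_gene(
                        case, control, alternative=test_type,
                        gene=gene, metric=matrix.metric_name,
                    )
                rows.append(
                    {
                        "gene": gene,
                        "metric": matrix.metric_name,
                        "case_group": group,
                        "test": test_type,
                        "tail_fraction": res.tail_fraction,
                        "n_case": res.n_case,
                        "n_control": res.n_control,
                        "case_max": res.case_max,
                        "case_mean": res.case_mean,
                        "control_max": res.control_max,
                        "control_mean": res.control_mean,
                        "U": res.u_statistic,
                        "p": res.p_value,
                    }
                )
    table = pd.DataFrame(rows)
    if bonferroni and not table.empty:
        table["p_bonferroni"] = np.minimum(table["p"] * len(genes), 1.0)
    return table
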