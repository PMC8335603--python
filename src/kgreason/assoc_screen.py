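"""Exposure–outcome association screen on a survey cohort.

Given subject-level binary exposure and outcome responses (with
missingness), the screen builds a 2×2 contingency table per
exposure–outcome pair — at the level of individual chemicals and of
chemical classes — tests each with Pearson's chi-square or, for sparse
tables, Fisher's exact test, applies a single Benjamini–Hochberg false
discovery rate correction across the whole screen, and reports Wald
odds ratios with 95% confidence bounds. Missing values are handled by
pairwise deletion; no covariate adjustment is performed. Significant
hits can be turned directly into chemical–gene–disease question graphs
for mechanistic follow-up.

Conventions: no Yates continuity correction on the chi-square; Fisher
is triggered by Cochran's rule (any expected cell below 5) or a zero
margin; a subject is class-exposed if any member chemical is "yes",
class-missing only if no member is "yes" and at least one is missing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from kgreason.kg_store import Curie
from kgreason.question_engine import QEdge, QNode, QuestionGraph

__all__ = [
    "Cohort",
    "ContingencyTable",
    "AssociationResult",
    "build_contingency",
    "pearson_chi2",
    "fisher_exact_two_sided",
    "select_test",
    "wald_odds_ratio",
    "bh_adjust",
    "screen_associations",
    "questions_from_hits",
    "read_cohort",
    "results_to_frame",
]

Z_95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass
class Cohort:
    """Subject-level survey responses.

    ``responses`` holds one row per subject (index = subject_id) and one
    column per chemical and per condition, coded 1.0 (yes), 0.0 (no) or
    NaN (missing). ``chemical_classes`` maps a class name to its member
    chemicals; every member must be an exposure column.
    """

    responses: pd.DataFrame
    exposures: tuple[str, ...]
    outcomes: tuple[str, ...]
    chemical_classes: dict[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.responses.index.has_duplicates:
            raise ValueError("duplicate subject ids")
        missing_cols = (set(self.exposures) | set(self.outcomes)) - set(
            self.responses.columns
        )
        if missing_cols:
            raise ValueError(f"cohort table lacks columns: {sorted(missing_cols)}")
        for cls, members in self.chemical_classes.items():
            extra = members - set(self.exposures)
            if extra:
                raise ValueError(f"class {cls!r} has non-exposure members {sorted(extra)}")

    @property
    def n_subjects(self) -> int:
        return len(self.responses)

    def exposure_vector(self, exposure: str) -> pd.Series:
        """Per-subject exposure status (1/0/NaN) for a chemical or class."""
        if exposure in self.exposures:
            return self.responses[exposure]
        if exposure in self.chemical_classes:
            members = sorted(self.chemical_classes[exposure])
            block = self.responses[members]
            any_yes = (block == 1.0).any(axis=1)
            any_missing = block.isna().any(axis=1)
            out = pd.Series(0.0, index=self.responses.index)
            out[any_yes] = 1.0
            out[~any_yes & any_missing] = np.nan
            return out
        raise KeyError(f"unknown exposure label: {exposure!r}")


@dataclass(frozen=True)
class ContingencyTable:
    """2×2 counts: a=exposed case, b=exposed control, c=unexposed case,
    d=unexposed control."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("negative cell count")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def margins(self) -> tuple[int, int, int, int]:
        return (self.a + self.b, self.c + self.d, self.a + self.c, self.b + self.d)

    def expected(self) -> tuple[float, float, float, float]:
        r1, r2, c1, c2 = self.margins
        n = self.n
        return (r1 * c1 / n, r1 * c2 / n, r2 * c1 / n, r2 * c2 / n)

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])


def build_contingency(cohort: Cohort, exposure: str, outcome: str) -> ContingencyTable:
    """Cross-tabulate one exposure (chemical or class) against one outcome.

    Subjects missing either variable are excluded (pairwise deletion).
    """
    if outcome not in cohort.outcomes:
        raise KeyError(f"unknown outcome label: {outcome!r}")
    e = cohort.exposure_vector(exposure)
    o = cohort.responses[outcome]
    keep = e.notna() & o.notna()
    e, o = e[keep], o[keep]
    return ContingencyTable(
        a=int(((e == 1) & (o == 1)).sum()),
        b=int(((e == 1) & (o == 0)).sum()),
        c=int(((e == 0) & (o == 1)).sum()),
        d=int(((e == 0) & (o == 0)).sum()),
    )


def pearson_chi2(table: ContingencyTable) -> float:
    """Two-sided Pearson chi-square p-value (1 df, no continuity correction).

    Statistic: n(ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d)). Zero margins are an
    error — the caller should fall back to Fisher's exact test.
    """
    r1, r2, c1, c2 = table.margins
    if min(r1, r2, c1, c2) == 0:
        raise ValueError("chi-square undefined with a zero margin")
    stat = (
        table.n
        * (table.a * table.d - table.b * table.c) ** 2
        / (r1 * r2 * c1 * c2)
    )
    return float(stats.chi2.sf(stat, df=1))


def chi2_statistic(table: ContingencyTable) -> float:
    """The Pearson statistic itself (see :func:`pearson_chi2`)."""
    r1, r2, c1, c2 = table.margins
    if min(r1, r2, c1, c2) == 0:
        raise ValueError("chi-square undefined with a zero margin")
    return (
        table.n
        * (table.a * table.d - table.b * table.c) ** 2
        / (r1 * r2 * c1 * c2)
    )


def fisher_exact_two_sided(table: ContingencyTable) -> float:
    """Fisher's exact two-sided p: total hypergeometric mass of tables
    (same margins) no more probable than the observed one."""
    if table.n < 1:
        raise ValueError("empty table")
    return float(stats.fisher_exact(table.as_array(), alternative="two-sided")[1])


def select_test(table: ContingencyTable) -> str:
    """'fisher' if any expected cell < 5 (Cochran's rule) or any margin is
    zero; else 'chi_square'."""
    if min(table.margins) == 0:
        return "fisher"
    if min(table.expected()) < 5:
        return "fisher"
    return "chi_square"


def wald_odds_ratio(
    table: ContingencyTable,
) -> tuple[float, float, float] | None:
    """(OR, ci_low, ci_high) by the Wald convention, or None if any cell
    is zero (flagged undefined rather than raised).

    OR = ad/bc; CI = exp(ln OR ± 1.96 sqrt(1/a + 1/b + 1/c + 1/d)).
    """
    if min(table.a, table.b, table.c, table.d) == 0:
        return None
    odds_ratio = (table.a * table.d) / (table.b * table.c)
    se = math.sqrt(1 / table.a + 1 / table.b + 1 / table.c + 1 / table.d)
    log_or = math.log(odds_ratio)
    return (
        odds_ratio,
        math.exp(log_or - Z_95 * se),
        math.exp(log_or + Z_95 * se),
    )


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini–Hochberg step-up adjusted p-values, in input order."""
    if len(p_values) == 0:
        return []
    arr = np.asarray(p_values, dtype=float)
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return list(multipletests(arr, method="fdr_bh")[1])


@dataclass(frozen=True)
class AssociationResult:
    exposure: str
    outcome: str
    level: str  # 'chemical' or 'class'
    table: ContingencyTable
    test_used: str | None  # 'chi_square', 'fisher', or None for degenerate
    p_value: float
    p_fdr: float
    odds_ratio: float | None
    ci_low: float | None
    ci_high: float | None
    significant_05: bool
    significant_10: bool
    degenerate: bool = False


def _test_one(table: ContingencyTable) -> tuple[str, float]:
    test = select_test(table)
    if test == "chi_square":
        return test, pearson_chi2(table)
    return test, fisher_exact_two_sided(table)


def screen_associations(
    cohort: Cohort,
    outcomes: Sequence[str] | None = None,
) -> list[AssociationResult]:
    """Run the full screen: every chemical and every chemical class
    against every outcome, one BH family across all non-degenerate tests.

    Degenerate pairs (no complete observations after pairwise deletion)
    are reported with NaN p-values and excluded from the BH family.
    """
    outcomes = tuple(outcomes) if outcomes is not None else cohort.outcomes
    jobs: list[tuple[str, str, str]] = [
        (chem, out, "chemical") for chem in cohort.exposures for out in outcomes
    ] + [(cls, out, "class") for cls in sorted(cohort.chemical_classes) for out in outcomes]

    partial: list[dict] = []
    for exposure, outcome, level in jobs:
        table = build_contingency(cohort, exposure, outcome)
        if table.n == 0:
            partial.append(
                dict(
                    exposure=exposure,
                    outcome=outcome,
                    level=level,
                    table=table,
                    test_used=None,
                    p_value=float("nan"),
                    degenerate=True,
                )
            )
            continue
        test, p = _test_one(table)
        partial.append(
            dict(
                exposure=exposure,
                outcome=outcome,
                level=level,
                table=table,
                test_used=test,
                p_value=p,
                degenerate=False,
            )
        )

    testable = [rec for rec in partial if not rec["degenerate"]]
    adjusted = bh_adjust([rec["p_value"] for rec in testable])
    for rec, p_fdr in zip(testable, adjusted):
        rec["p_fdr"] = p_fdr
    results = []
    for rec in partial:
        p_fdr = rec.get("p_fdr", float("nan"))
        wald = wald_odds_ratio(rec["table"]) if not rec["degenerate"] else None
        odds_ratio, ci_low, ci_high = wald if wald is not None else (None, None, None)
        results.append(
            AssociationResult(
                exposure=rec["exposure"],
                outcome=rec["outcome"],
                level=rec["level"],
                table=rec["table"],
                test_used=rec["test_used"],
                p_value=rec["p_value"],
                p_fdr=p_fdr,
                odds_ratio=odds_ratio,
                ci_low=ci_low,
                ci_high=ci_high,
                significant_05=bool(p_fdr < 0.05),
                significant_10=bool(p_fdr < 0.10),
                degenerate=rec["degenerate"],
            )
        )
    return results


def questions_from_hits(
    results: Iterable[AssociationResult],
    curie_map: Mapping[str, Curie],
    alpha: float = 0.05,
) -> tuple[list[QuestionGraph], list[str]]:
    """Turn significant hits into chemical–gene–disease question graphs.

    For every result with adjusted p below *alpha* whose exposure and
    outcome labels both map to CURIEs, emit a three-node question:
    pinned chemical — type-constrained gene — pinned disease. Labels
    missing from the map are collected and reported, not fatal.
    """
    questions: list[QuestionGraph] = []
    unmapped: list[str] = []
    for res in results:
        if res.degenerate or not (res.p_fdr < alpha):
            continue
        missing = [lbl for lbl in (res.exposure, res.outcome) if lbl not in curie_map]
        if missing:
            unmapped.extend(missing)
            continue
        questions.append(
            QuestionGraph(
                qnodes=(
                    QNode(qid="chemical", binding=curie_map[res.exposure]),
                    QNode(qid="gene", category="gene"),
                    QNode(qid="disease", binding=curie_map[res.outcome]),
                ),
                qedges=(
                    QEdge(qeid="e0", source_qid="chemical", target_qid="gene"),
                    QEdge(qeid="e1", source_qid="gene", target_qid="disease"),
                ),
            )
        )
    return questions, sorted(set(unmapped))


# ---------------------------------------------------------------------------
# I/O

def read_cohort(
    cohort_table: str | Path,
    exposures: Sequence[str],
    outcomes: Sequence[str],
    classes_table: str | Path | None = None,
) -> Cohort:
    """Read a subject TSV (values 1/0/NA) and optional class TSV."""
    df = (
        pd.read_csv(cohort_table, sep="\t", na_values=["NA"])
        .set_index("subject_id")
        .astype(float)
    )
    classes: dict[str, frozenset[str]] = {}
    if classes_table is not None:
        cls_df = pd.read_csv(classes_table, sep="\t")
        if list(cls_df.columns) != ["class", "chemical"]:
            raise ValueError(f"{classes_table}: expected header 'class\\tchemical'")
        for cls, group in cls_df.groupby("class"):
            classes[str(cls)] = frozenset(group["chemical"])
    return Cohort(
        responses=df,
        exposures=tuple(exposures),
        outcomes=tuple(outcomes),
        chemical_classes=classes,
    )


def write_cohort(
    cohort: Cohort, cohort_table: str | Path, classes_table: str | Path | None = None
) -> None:
    df = cohort.responses.copy()
    out = df.map(lambda v: "NA" if pd.isna(v) else str(int(v)))
    out.index.name = "subject_id"
    out.to_csv(cohort_table, sep="\t")
    if classes_table is not None:
        rows = [
            {"class": cls, "chemical": chem}
            for cls in sorted(cohort.chemical_classes)
            for chem in sorted(cohort.chemical_classes[cls])
        ]
        pd.DataFrame(rows, columns=["class", "chemical"]).to_csv(
            classes_table, sep="\t", index=False
        )


def results_to_frame(results: Sequence[AssociationResult]) -> pd.DataFrame:
    """Flatten screen results for CSV export."""
    rows = []
    for r in results:
        rows.append(
            {
                "exposure": r.exposure,
                "outcome": r.outcome,
                "level": r.level,
                "a": r.table.a,
                "b": r.table.b,
                "c": r.table.c,
                "d": r.table.d,
                "test": r.test_used or "none",
                "p": r.p_value,
                "p_fdr": r.p_fdr,
                "or": r.odds_ratio,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "sig05": r.significant_05,
                "sig10": r.significant_10,
            }
        )
    return pd.DataFrame(rows)
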