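"""Diagnostic test accuracy and concordance.

2x2 confusion tables of an index test against a reference standard, the
standard accuracy metrics with Wald 95% confidence intervals, Cohen's
kappa, any-disorder aggregation, per-individual correctness, pooled
positive identification, prevalence/comorbidity tabulation and cutoff
sweeps.

Conventions
-----------
* Metrics are percentages; sensitivity = tp/(tp+fn), specificity =
  tn/(tn+fp), PPV = tp/(tp+fp), NPV = tn/(tn+fn), accuracy = (tp+tn)/n.
* Confidence intervals are Wald: p +/- 1.96*sqrt(p(1-p)/m) on the metric's
  own denominator m, clipped to [0, 100].  Wald intervals are known to
  undercover for extreme p and small m; this is the price of matching the
  conventional reporting and is documented rather than corrected.
* A metric whose denominator is zero is *undefined* and flagged as such —
  never silently 0 or 100.
* Rounding (percentages to 1 d.p., kappa to 2 d.p., half up) happens only
  at the reporting layer; stored values keep full precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .instruments import DISORDERS
from ._util import round_half_up

Z95 = 1.96


class DTAError(ValueError):
    """Invalid input to an accuracy computation."""


@dataclass(frozen=True)
class ConfusionTable:
    """2x2 table of index test (rows) against reference standard."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise DTAError("confusion cells must be non-negative")
        if self.n == 0:
            raise DTAError("empty confusion table")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def n_pos_index(self) -> int:
        """Respondents the index test calls positive."""
        return self.tp + self.fp

    @property
    def n_pos_ref(self) -> int:
        return self.tp + self.fn


def table_from_marginals(
    n: int, ref_positive: int, test_positive: int, concordant_positive: int
) -> ConfusionTable:
    """Reconstruct a 2x2 table from the counts a report typically prints:
    total N, reference positives, index-test positives, and true positives.
    """
    tp = concordant_positive
    fp = test_positive - tp
    fn = ref_positive - tp
    tn = n - tp - fp - fn
    return ConfusionTable(tp=tp, fp=fp, fn=fn, tn=tn)


@dataclass(frozen=True)
class Estimate:
    """A percentage metric with its 95% CI; undefined when denominator 0."""

    value: float | None
    ci: tuple[float, float] | None
    denominator: int
    defined: bool = True

    def rounded(self, ndigits: int = 1) -> float:
        if not self.defined or self.value is None:
            raise DTAError("metric is undefined (zero denominator)")
        return round_half_up(self.value, ndigits)


@dataclass(frozen=True)
class DTAReport:
    """Accuracy report for one disorder (one 2x2 table)."""

    table: ConfusionTable
    sensitivity: Estimate
    specificity: Estimate
    ppv: Estimate
    npv: Estimate
    accuracy: Estimate
    kappa: float | None

    @property
    def n_pos_index(self) -> int:
        return self.table.n_pos_index

    def to_dict(self) -> dict:
        def est(e: Estimate) -> dict:
            return {
                "value": e.value, "ci": list(e.ci) if e.ci else None,
                "denominator": e.denominator, "defined": e.defined,
            }
        return {
            "table": {"tp": self.table.tp, "fp": self.table.fp,
                      "fn": self.table.fn, "tn": self.table.tn},
            "n_pos_index": self.n_pos_index,
            "sensitivity": est(self.sensitivity),
            "specificity": est(self.specificity),
            "ppv": est(self.ppv), "npv": est(self.npv),
            "accuracy": est(self.accuracy),
            "kappa": self.kappa,
        }


def wald_ci(p: float, m: int, z: float = Z95) -> tuple[float, float]:
    """Wald interval for a proportion, on the percent scale, clipped."""
    if m <= 0:
        raise DTAError("Wald CI needs a positive denominator")
    half = z * math.sqrt(p * (1.0 - p) / m)
    return (max(0.0, (p - half) * 100.0), min(100.0, (p + half) * 100.0))


def _estimate(numer: int, denom: int) -> Estimate:
    if denom == 0:
        return Estimate(value=None, ci=None, denominator=0, defined=False)
    p = numer / denom
    return Estimate(value=p * 100.0, ci=wald_ci(p, denom), denominator=denom)


def cohen_kappa(table: ConfusionTable) -> float:
    """Chance-corrected agreement kappa = (po - pe) / (1 - pe).

    po is raw agreement; pe the agreement expected from the two marginal
    distributions.  Undefined (DTAError) when pe == 1, i.e. both raters
    are constant.
    """
    n = table.n
    po = (table.tp + table.tn) / n
    pe = ((table.tp + table.fp) * (table.tp + table.fn)
          + (table.fn + table.tn) * (table.fp + table.tn)) / (n * n)
    if pe == 1.0:
        raise DTAError("kappa undefined: expected agreement is 1")
    return (po - pe) / (1.0 - pe)


def metrics(table: ConfusionTable) -> DTAReport:
    """All accuracy metrics (with CIs) and kappa for one 2x2 table."""
    try:
        kappa = cohen_kappa(table)
    except DTAError:
        kappa = None
    return DTAReport(
        table=table,
        sensitivity=_estimate(table.tp, table.tp + table.fn),
        specificity=_estimate(table.tn, table.tn + table.fp),
        ppv=_estimate(table.tp, table.tp + table.fp),
        npv=_estimate(table.tn, table.tn + table.fn),
        accuracy=_estimate(table.tp + table.tn, table.n),
        kappa=kappa,
    )


# ---------------------------------------------------------------------------
# Cohort-level operations
# ---------------------------------------------------------------------------

def confusion(test_flags: pd.Series, labels: pd.Series) -> ConfusionTable:
    """2x2 table from aligned boolean series (index = respondent id)."""
    if len(test_flags) == 0:
        raise DTAError("empty input")
    if set(test_flags.index) != set(labels.index):
        raise DTAError("test flags and labels cover different respondents")
    labels = labels.loc[test_flags.index]
    t = test_flags.astype(bool)
    l = labels.astype(bool)
    return ConfusionTable(
        tp=int((t & l).sum()), fp=int((t & ~l).sum()),
        fn=int((~t & l).sum()), tn=int((~t & ~l).sum()),
    )


def any_disorder(flags: pd.DataFrame) -> pd.Series:
    """Row-wise OR over the four disorder columns."""
    missing = [d for d in DISORDERS if d not in flags.columns]
    if missing:
        raise DTAError(f"missing disorder columns: {missing}")
    return flags[list(DISORDERS)].astype(bool).any(axis=1)


@dataclass(frozen=True)
class CorrectnessHistogram:
    """Distribution of per-respondent correct calls over the 4 disorders."""

    counts: Mapping[int, int]          # k correct -> respondents
    n: int
    false_positive_failures: int       # discordant calls that were FPs
    false_negative_failures: int

    @property
    def share_fully_correct(self) -> float:
        return 100.0 * self.counts.get(len(DISORDERS), 0) / self.n

    @property
    def failure_fp_share(self) -> float:
        """Share of all failed calls that are false positives, percent."""
        failed = self.false_positive_failures + self.false_negative_failures
        if failed == 0:
            raise DTAError("no failed calls")
        return 100.0 * self.false_positive_failures / failed


def per_individual_correctness(
    flags: pd.DataFrame, labels: pd.DataFrame
) -> CorrectnessHistogram:
    """Count, per respondent, how many of the 4 disorder calls agree."""
    if set(flags.index) != set(labels.index):
        raise DTAError("flags and labels cover different respondents")
    labels = labels.loc[flags.index]
    f = flags[list(DISORDERS)].astype(bool)
    l = labels[list(DISORDERS)].astype(bool)
    agree = (f.values == l.values).sum(axis=1)
    counts = {k: int((agree == k).sum()) for k in range(len(DISORDERS) + 1)}
    fp = int((f.values & ~l.values).sum())
    fn = int((~f.values & l.values).sum())
    return CorrectnessHistogram(
        counts=counts, n=len(f),
        false_positive_failures=fp, false_negative_failures=fn,
    )


def pooled_positive_identification(
    tables: Iterable[ConfusionTable],
) -> float:
    """Pooled sensitivity across disorders: sum(tp) / sum(tp + fn), percent."""
    tables = list(tables)
    if not tables:
        raise DTAError("no tables to pool")
    tp = sum(t.tp for t in tables)
    pos = sum(t.tp + t.fn for t in tables)
    if pos == 0:
        raise DTAError("no reference positives to pool over")
    return 100.0 * tp / pos


def cutoff_sweep(
    scores: pd.Series,
    labels: pd.Series,
    cutoffs: Sequence[int],
) -> dict[int, DTAReport]:
    """Accuracy of ``score >= cutoff`` against labels, per candidate cutoff.

    This is the full-scale dichotomisation used when choosing a Tier-3
    cutoff (e.g. the insomnia scale's proposed 8 / 11 / 14), not the tiered
    procedure.
    """
    if len(cutoffs) == 0:
        raise DTAError("empty cutoff list")
    out: dict[int, DTAReport] = {}
    for c in sorted(set(int(c) for c in cutoffs)):
        flags = scores >= c
        out[c] = metrics(confusion(flags, labels))
    return out


@dataclass(frozen=True)
class PrevalenceReport:
    """Prevalence by index test and reference, plus label comorbidity."""

    n: int
    reference_counts: Mapping[str, int]
    test_counts: Mapping[str, int]
    reference_any: int
    test_any: int
    pairwise: pd.DataFrame               # symmetric co-diagnosis counts
    multimorbidity: Mapping[int, int]    # >=k diagnoses -> respondents

    def reference_percent(self, disorder: str) -> float:
        return 100.0 * self.reference_counts[disorder] / self.n

    def multimorbidity_percent(self, k: int) -> float:
        return 100.0 * self.multimorbidity.get(k, 0) / self.n


def prevalence_and_comorbidity(
    flags: pd.DataFrame, labels: pd.DataFrame
) -> PrevalenceReport:
    """Tabulate per-disorder prevalence and reference-label comorbidity."""
    if set(flags.index) != set(labels.index):
        raise DTAError("flags and labels cover different respondents")
    labels = labels.loc[flags.index]
    f = flags[list(DISORDERS)].astype(bool)
    l = labels[list(DISORDERS)].astype(bool)
    pairwise = pd.DataFrame(
        (l.values.astype(int).T @ l.values.astype(int)),
        index=list(DISORDERS), columns=list(DISORDERS),
    )
    per_person = l.sum(axis=1)
    multi = {k: int((per_person >= k).sum()) for k in range(1, len(DISORDERS) + 1)}
    return PrevalenceReport(
        n=len(f),
        reference_counts={d: int(l[d].sum()) for d in DISORDERS},
        test_counts={d: int(f[d].sum()) for d in DISORDERS},
        reference_any=int(l.any(axis=1).sum()),
        test_any=int(f.any(axis=1).sum()),
        pairwise=pairwise,
        multimorbidity=multi,
    )


def evaluate(
    flags: pd.DataFrame, labels: pd.DataFrame
) -> dict[str, DTAReport]:
    """Per-disorder and any-disorder accuracy reports for a cohort."""
    reports = {
        d: metrics(confusion(flags[d].astype(bool), labels[d].astype(bool)))
        for d in DISORDERS
    }
    reports["any"] = metrics(
        confusion(any_disorder(flags), any_disorder(labels))
    )
    return reports
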