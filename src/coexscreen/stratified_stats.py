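"""Seed-expression dichotomization and two-group marker testing.

Samples are split at the cohort median of seed expression (strictly
greater than the median -> "high"), then each marker gene is compared
between the two strata with a two-sample t-test (pooled "student"
variant by default, "welch" available).  Also houses the ordinal
score-vs-infiltration association test, Benjamini-Hochberg adjustment,
and the seed-sorted sub-matrix export used for external heatmaps.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from coexscreen.cohort_io import ExpressionCohort, write_expression_tsv

Stratum = Literal["low", "high"]
TestVariant = Literal["student", "welch"]

DIRECTION_UP = "up_in_high"
DIRECTION_DOWN = "down_in_high"
DIRECTION_FLAT = "flat"
STATUS_TESTED = "ok"
STATUS_NOT_TESTABLE = "not_testable"


class StratifyError(ValueError):
    """Raised when stratification or testing preconditions fail."""


@dataclass
class StratifiedResult:
    """Per-gene two-group test results between seed-low and seed-high strata.

    ``rows`` is indexed by gene with columns ``mean_low``, ``mean_high``,
    ``t``, ``p``, ``q`` (NaN unless BH requested), ``direction``, ``status``.
    """

    cohort_id: str
    seed_gene: str
    variant: TestVariant
    rows: pd.DataFrame

    def to_tsv(self, path: str | Path) -> None:
        out = self.rows.copy()
        out.index.name = "gene"
        out.to_csv(path, sep="\t", na_rep="NA", float_format="%.10g")


@dataclass
class MarkerAssociation:
    """Two-sample t of an ordinal 0-3 score between infiltration classes."""

    mean_positive: float
    mean_negative: float
    t: float
    p: float
    n_pos: int
    n_neg: int


def dichotomize_by_seed(
    cohort: ExpressionCohort,
    seed_gene: str,
    rule: Literal["median"] = "median",
) -> dict[str, Stratum]:
    """Label each sample low/high by seed expression.

    A sample is "high" iff its seed expression is strictly greater than
    the cohort median of the seed gene; otherwise "low".

    Raises
    ------
    StratifyError
        If the seed is absent or constant, fewer than 4 samples are
        available, or one stratum would be empty.
    """
    if rule != "median":
        raise StratifyError(f"unknown dichotomization rule: {rule!r}")
    if seed_gene not in cohort.data.index:
        raise StratifyError(f"seed gene {seed_gene!r} absent from cohort")
    seed = cohort.values_for(seed_gene)
    obs = ~np.isnan(seed)
    if obs.sum() < 4:
        raise StratifyError("need at least 4 samples with observed seed expression")
    vals = seed[obs]
    if np.all(vals == vals[0]):
        raise StratifyError(f"seed gene {seed_gene!r} is constant; cannot dichotomize")
    median = float(np.median(vals))
    labels: dict[str, Stratum] = {}
    for sample, value, ok in zip(cohort.sample_ids, seed, obs):
        if not ok:
            continue
        labels[sample] = "high" if value > median else "low"
    strata = set(labels.values())
    if strata != {"low", "high"}:
        raise StratifyError("dichotomization produced an empty stratum")
    return labels


def _two_sample_t(
    a: np.ndarray, b: np.ndarray, variant: TestVariant
) -> tuple[float, float]:
    """Two-sided two-sample t; returns (t, p). a = high, b = low."""
    if variant == "student":
        res = stats.ttest_ind(a, b, equal_var=True)
    elif variant == "welch":
        res = stats.ttest_ind(a, b, equal_var=False)
    else:
        raise StratifyError(f"unknown test variant: {variant!r}")
    t = float(res.statistic)
    p = float(res.pvalue)
    if np.isnan(t):  # zero pooled variance with equal means
        t, p = 0.0, 1.0
    return t, p


def two_group_test(
    cohort: ExpressionCohort,
    labels: Mapping[str, Stratum],
    genes: Sequence[str] | None = None,
    variant: TestVariant = "student",
    bh: bool = False,
) -> StratifiedResult:
    """Test each gene between the low and high strata.

    Genes with fewer than 2 usable values in either stratum are reported
    with status ``not_testable`` rather than raising.  With ``bh=True``
    the ``q`` column holds Benjamini-Hochberg adjusted p-values across
    the testable genes.
    """
    if genes is None:
        genes = cohort.feature_ids
    missing = [g for g in genes if g not in cohort.data.index]
    if missing:
        raise StratifyError(f"gene(s) absent from cohort: {missing}")
    low_samples = [s for s, lab in labels.items() if lab == "low"]
    high_samples = [s for s, lab in labels.items() if lab == "high"]
    if not low_samples or not high_samples:
        raise StratifyError("both strata must be nonempty")

    records = []
    for gene in genes:
        row = cohort.data.loc[gene]
        lo = row[low_samples].to_numpy(dtype=float)
        hi = row[high_samples].to_numpy(dtype=float)
        lo = lo[~np.isnan(lo)]
        hi = hi[~np.isnan(hi)]
        if lo.size < 2 or hi.size < 2:
            records.append(
                (gene, np.nan, np.nan, np.nan, np.nan, DIRECTION_FLAT, STATUS_NOT_TESTABLE)
            )
            continue
        t, p = _two_sample_t(hi, lo, variant)
        mean_low = float(lo.mean())
        mean_high = float(hi.mean())
        delta = mean_high - mean_low
        direction = (
            DIRECTION_UP if delta > 0 else DIRECTION_DOWN if delta < 0 else DIRECTION_FLAT
        )
        records.append((gene, mean_low, mean_high, t, p, direction, STATUS_TESTED))

    rows = pd.DataFrame(
        records,
        columns=["gene", "mean_low", "mean_high", "t", "p", "direction", "status"],
    ).set_index("gene")
    rows["q"] = np.nan
    if bh:
        testable = rows["status"] == STATUS_TESTED
        if testable.any():
            rows.loc[testable, "q"] = bh_adjust(list(rows.loc[testable, "p"]))
    rows = rows[["mean_low", "mean_high", "t", "p", "q", "direction", "status"]]
    return StratifiedResult(cohort.cohort_id, "", variant, rows)


def bh_adjust(pvals: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved.

    Raises
    ------
    StratifyError
        If any p lies outside [0, 1].
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise StratifyError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return list(out)


def score_infiltration_association(
    scores: Sequence[int],
    infiltrated: Sequence[bool],
) -> MarkerAssociation:
    """Two-sample t of an ordinal 0-3 score between infiltration classes.

    ``infiltrated`` marks samples whose infiltrating-cell percentage
    exceeds the positivity threshold.  Both classes need >= 2 samples.
    """
    scores_arr = np.asarray(scores, dtype=float)
    flags = np.asarray(infiltrated, dtype=bool)
    if scores_arr.shape != flags.shape:
        raise StratifyError("scores and infiltration flags must align")
    if not np.all(np.isin(scores_arr, [0, 1, 2, 3])):
        raise StratifyError("scores must be ordinal values in {0, 1, 2, 3}")
    pos = scores_arr[flags]
    neg = scores_arr[~flags]
    if pos.size < 2 or neg.size < 2:
        raise StratifyError("both infiltration classes need at least 2 samples")
    t, p = _two_sample_t(pos, neg, "student")
    return MarkerAssociation(
        mean_positive=float(pos.mean()),
        mean_negative=float(neg.mean()),
        t=t,
        p=p,
        n_pos=int(pos.size),
        n_neg=int(neg.size),
    )


def order_for_heatmap(
    cohort: ExpressionCohort,
    genes: Sequence[str],
    seed_gene: str,
    path: str | Path | None = None,
) -> tuple[list[str], ExpressionCohort]:
    """Order samples by ascending seed expression (ties by sample id).

    Returns the sample ordering and the gene-ordered, sample-ordered
    sub-matrix (seed gene first) for external plotting; writes it as TSV
    when ``path`` is given.
    """
    wanted = [seed_gene] + [g for g in genes if g != seed_gene]
    missing = [g for g in wanted if g not in cohort.data.index]
    if missing:
        raise StratifyError(f"gene(s) absent from cohort: {missing}")
    seed = cohort.data.loc[seed_gene]
    order = sorted(cohort.sample_ids, key=lambda s: (seed[s], s))
    sub = ExpressionCohort(
        cohort.cohort_id, cohort.group_id, cohort.data.loc[wanted, order].copy()
    )
    if path is not None:
        write_expression_tsv(sub, path)
    return order, sub
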