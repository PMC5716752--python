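"""Per-cohort seed-gene correlation and sign-split significant gene lists.

Every gene in a cohort is correlated with a single seed gene on
pairwise-complete samples.  Two-sided p-values come from the
t-transform ``t = r * sqrt((n - 2) / (1 - r^2))`` referred to a t
distribution with ``n - 2`` degrees of freedom.  Genes significant at
``alpha`` are split into a positive and a negative list by the sign of r.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats

from coexscreen.cohort_io import ExpressionCohort

#: Minimum pairwise-complete sample count to report a correlation.
MIN_N_USED = 5

STATUS_OK = "ok"
STATUS_CONSTANT = "excluded_constant"
STATUS_LOW_N = "excluded_low_n"

Method = Literal["pearson", "spearman"]


class ScreenError(ValueError):
    """Raised when the correlation screen is undefined for the input."""


@dataclass
class CorrelationTable:
    """Per-gene correlation with the seed gene in one cohort.

    ``rows`` is a DataFrame indexed by gene with columns ``r``, ``p``,
    ``n_used`` and ``status``; excluded genes carry NaN in ``r``/``p``.
    """

    cohort_id: str
    seed_gene: str
    method: Method
    rows: pd.DataFrame

    def __post_init__(self) -> None:
        ok = self.rows["status"] == STATUS_OK
        r = self.rows.loc[ok, "r"]
        if (r.abs() > 1 + 1e-12).any():
            raise ScreenError("correlation outside [-1, 1]")
        if self.seed_gene in self.rows.index:
            raise ScreenError("seed gene must not appear as a row")

    def to_tsv(self, path: str | Path) -> None:
        out = self.rows.copy()
        out.index.name = "gene"
        out.to_csv(path, sep="\t", na_rep="NA", float_format="%.10g")


@dataclass
class SignedGeneLists:
    """A cohort's positive and negative significant gene sets."""

    cohort_id: str
    positive: frozenset[str]
    negative: frozenset[str]
    alpha: float
    min_abs_r: float = 0.0

    def __post_init__(self) -> None:
        overlap = self.positive & self.negative
        if overlap:
            raise ScreenError(
                f"genes in both sign lists of {self.cohort_id!r}: {sorted(overlap)[:5]}"
            )


def _rank_with_nan(values: np.ndarray) -> np.ndarray:
    """Mid-rank transform, preserving NaN positions."""
    out = np.full_like(values, np.nan, dtype=float)
    mask = ~np.isnan(values)
    out[mask] = stats.rankdata(values[mask])
    return out


def correlate_with_seed(
    cohort: ExpressionCohort,
    seed_gene: str,
    method: Method = "pearson",
) -> CorrelationTable:
    """Correlate every non-seed gene with the seed gene.

    Missing values are handled pairwise: each gene uses only the samples
    where both it and the seed are observed, and that count is reported
    as ``n_used``.  Genes with zero variance on the usable samples are
    ``excluded_constant``; genes with fewer than 5 usable samples are
    ``excluded_low_n``.  Deterministic for fixed input.

    Raises
    ------
    ScreenError
        If the seed gene is absent, the cohort has fewer than 5 samples,
        or the seed gene is constant.
    """
    if seed_gene not in cohort.data.index:
        raise ScreenError(
            f"seed gene {seed_gene!r} absent from cohort {cohort.cohort_id!r}"
        )
    if cohort.n_samples < MIN_N_USED:
        raise ScreenError(
            f"cohort {cohort.cohort_id!r} has {cohort.n_samples} samples; "
            f"need at least {MIN_N_USED}"
        )
    if method not in {"pearson", "spearman"}:
        raise ScreenError(f"unknown correlation method: {method!r}")

    seed = cohort.values_for(seed_gene)
    seed_obs = seed[~np.isnan(seed)]
    if seed_obs.size == 0 or np.all(seed_obs == seed_obs[0]):
        raise ScreenError(
            f"seed gene {seed_gene!r} is constant in cohort {cohort.cohort_id!r}; "
            "screen undefined"
        )

    others = [g for g in cohort.feature_ids if g != seed_gene]
    matrix = cohort.data.loc[others].to_numpy(dtype=float)
    seed_row = seed[np.newaxis, :]

    if method == "spearman":
        # ranks must be recomputed per gene on the pairwise-complete subset
        r_arr = np.full(len(others), np.nan)
        n_arr = np.zeros(len(others), dtype=int)
        const = np.zeros(len(others), dtype=bool)
        for i in range(len(others)):
            pair = ~np.isnan(matrix[i]) & ~np.isnan(seed)
            n = int(pair.sum())
            n_arr[i] = n
            if n < MIN_N_USED:
                continue
            x = matrix[i, pair]
            y = seed[pair]
            if np.all(x == x[0]) or np.all(y == y[0]):
                const[i] = True
                continue
            r_arr[i] = _pearson_r(stats.rankdata(x), stats.rankdata(y))
    else:
        pair = ~np.isnan(matrix) & ~np.isnan(seed_row)
        n_arr = pair.sum(axis=1)
        xm = np.where(pair, matrix, 0.0)
        ym = np.where(pair, np.broadcast_to(seed_row, matrix.shape), 0.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            n_safe = np.where(n_arr > 0, n_arr, 1)
            mean_x = xm.sum(axis=1) / n_safe
            mean_y = ym.sum(axis=1) / n_safe
            dx = np.where(pair, matrix - mean_x[:, None], 0.0)
            dy = np.where(pair, seed_row - mean_y[:, None], 0.0)
            sxx = (dx * dx).sum(axis=1)
            syy = (dy * dy).sum(axis=1)
            sxy = (dx * dy).sum(axis=1)
            const = (sxx <= 0) | (syy <= 0)
            denom = np.sqrt(sxx * syy)
            r_arr = np.where(const | (n_arr < MIN_N_USED), np.nan, sxy / np.where(denom > 0, denom, 1.0))
        r_arr = np.clip(r_arr, -1.0, 1.0)

    status = np.full(len(others), STATUS_OK, dtype=object)
    status[n_arr < MIN_N_USED] = STATUS_LOW_N
    status[(n_arr >= MIN_N_USED) & const] = STATUS_CONSTANT
    ok = status == STATUS_OK

    p_arr = np.full(len(others), np.nan)
    r_ok = r_arr[ok]
    n_ok = n_arr[ok].astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r_ok * np.sqrt((n_ok - 2) / np.maximum(1 - r_ok**2, 0.0))
    p_ok = 2 * stats.t.sf(np.abs(t), n_ok - 2)
    p_ok[np.abs(r_ok) >= 1.0] = 0.0
    p_arr[ok] = np.minimum(p_ok, 1.0)
    r_arr[~ok] = np.nan

    rows = pd.DataFrame(
        {"r": r_arr, "p": p_arr, "n_used": n_arr, "status": status},
        index=pd.Index(others, name="gene"),
    )
    return CorrelationTable(cohort.cohort_id, seed_gene, method, rows)


def _pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    dx = x - x.mean()
    dy = y - y.mean()
    denom = np.sqrt((dx * dx).sum() * (dy * dy).sum())
    return float(np.clip((dx * dy).sum() / denom, -1.0, 1.0))


def split_by_sign(
    table: CorrelationTable,
    alpha: float = 0.05,
    min_abs_r: float = 0.0,
    bh: bool = False,
) -> SignedGeneLists:
    """Split significant genes into positive and negative lists.

    A gene is listed positive iff its status is ok, p < ``alpha``,
    r > 0 and |r| >= ``min_abs_r``; symmetric for negative.  With
    ``bh=True`` a Benjamini-Hochberg adjustment over the ok rows is
    applied before thresholding.
    """
    if not 0 < alpha < 1:
        raise ScreenError(f"alpha must be in (0, 1), got {alpha}")
    rows = table.rows
    ok = rows["status"] == STATUS_OK
    p = rows.loc[ok, "p"].to_numpy()
    if bh and p.size:
        from coexscreen.stratified_stats import bh_adjust

        p = np.asarray(bh_adjust(list(p)))
    r = rows.loc[ok, "r"].to_numpy()
    genes = rows.index[ok]
    keep = (p < alpha) & (np.abs(r) >= min_abs_r)
    positive = frozenset(genes[keep & (r > 0)])
    negative = frozenset(genes[keep & (r < 0)])
    return SignedGeneLists(table.cohort_id, positive, negative, alpha, min_abs_r)
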