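"""Multi-cohort synthetic expression data with planted seed-correlated modules.

Each cohort draws a per-sample latent factor f ~ N(0, 1).  The seed gene
is baseline + f + sigma*noise.  Positive-module genes load +beta on f,
negative-module genes load -beta, each gene being *active* in a given
cohort with probability pi (inactive module genes behave like
background).  Background genes are independent noise around the
baseline.  All randomness derives from a master seed via named
per-cohort substreams, so any cohort is reproducible in isolation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from coexscreen.cohort_io import ExpressionCohort
import pandas as pd


class SyntheticConfigError(ValueError):
    """Raised for an invalid generator configuration."""


SEED_GENE = "SEED"


@dataclass(frozen=True)
class GroupDesign:
    """One condition group: how many cohorts and their sample-size range."""

    group_id: str
    n_cohorts: int
    n_samples_range: tuple[int, int] = (100, 100)

    def __post_init__(self) -> None:
        lo, hi = self.n_samples_range
        if self.n_cohorts < 1 or lo < 5 or hi < lo:
            raise SyntheticConfigError(
                f"group {self.group_id!r}: invalid design "
                f"(n_cohorts={self.n_cohorts}, range={self.n_samples_range})"
            )


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the planted-module generator.

    Defaults mirror the screen's structure at a desk scale; the cohort
    counts of the full-size design (5 cervix, 6 lung, 19 breast,
    10 colon) can be requested via :func:`paper_scale_groups`.
    """

    groups: tuple[GroupDesign, ...] = (
        GroupDesign("g1", 3),
        GroupDesign("g2", 3),
        GroupDesign("g3", 3),
        GroupDesign("g4", 3),
    )
    genes_total: int = 2000
    module_size_pos: int = 50
    module_size_neg: int = 50
    beta: float = 0.8
    sigma: float = 1.0
    pi: float = 1.0
    baseline_mean: float = 7.0
    baseline_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.module_size_pos + self.module_size_neg + 1 > self.genes_total:
            raise SyntheticConfigError(
                "module sizes plus the seed gene exceed genes_total"
            )
        if not 0 < self.pi <= 1:
            raise SyntheticConfigError(f"pi must be in (0, 1], got {self.pi}")
        if self.sigma <= 0:
            raise SyntheticConfigError(f"sigma must be positive, got {self.sigma}")
        if self.beta < 0:
            raise SyntheticConfigError(f"beta must be >= 0, got {self.beta}")
        if self.module_size_pos < 0 or self.module_size_neg < 0:
            raise SyntheticConfigError("module sizes must be nonnegative")
        ids = [g.group_id for g in self.groups]
        if len(set(ids)) != len(ids):
            raise SyntheticConfigError("duplicate group ids")


def paper_scale_groups(
    n_samples_range: tuple[int, int] = (100, 100)
) -> tuple[GroupDesign, ...]:
    """The full-size design: 5 cervix, 6 lung, 19 breast, 10 colon cohorts."""
    return (
        GroupDesign("cervix", 5, n_samples_range),
        GroupDesign("lung", 6, n_samples_range),
        GroupDesign("breast", 19, n_samples_range),
        GroupDesign("colon", 10, n_samples_range),
    )


@dataclass
class SyntheticTruth:
    """Planted ground truth: module memberships and realized activity."""

    positive_module: frozenset[str]
    negative_module: frozenset[str]
    realized_membership: dict[str, dict[str, bool]]
    config: SyntheticConfig

    def __post_init__(self) -> None:
        if self.positive_module & self.negative_module:
            raise SyntheticConfigError("planted modules overlap")
        module = self.positive_module | self.negative_module
        for cohort_id, flags in self.realized_membership.items():
            extra = set(flags) - module
            if extra:
                raise SyntheticConfigError(
                    f"cohort {cohort_id!r}: activity flags for non-module genes"
                )

    def to_json(self, path: str | Path) -> None:
        payload = {
            "positive_module": sorted(self.positive_module),
            "negative_module": sorted(self.negative_module),
            "realized_membership": {
                c: {g: bool(v) for g, v in sorted(flags.items())}
                for c, flags in sorted(self.realized_membership.items())
            },
            "config": {
                "groups": [
                    {
                        "group_id": g.group_id,
                        "n_cohorts": g.n_cohorts,
                        "n_samples_range": list(g.n_samples_range),
                    }
                    for g in self.config.groups
                ],
                "genes_total": self.config.genes_total,
                "module_size_pos": self.config.module_size_pos,
                "module_size_neg": self.config.module_size_neg,
                "beta": self.config.beta,
                "sigma": self.config.sigma,
                "pi": self.config.pi,
                "baseline_mean": self.config.baseline_mean,
                "baseline_sd": self.config.baseline_sd,
                "seed": self.config.seed,
            },
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        payload = json.loads(Path(path).read_text())
        cfg = payload["config"]
        config = SyntheticConfig(
            groups=tuple(
                GroupDesign(
                    g["group_id"], g["n_cohorts"], tuple(g["n_samples_range"])
                )
                for g in cfg["groups"]
            ),
            genes_total=cfg["genes_total"],
            module_size_pos=cfg["module_size_pos"],
            module_size_neg=cfg["module_size_neg"],
            beta=cfg["beta"],
            sigma=cfg["sigma"],
            pi=cfg["pi"],
            baseline_mean=cfg["baseline_mean"],
            baseline_sd=cfg["baseline_sd"],
            seed=cfg["seed"],
        )
        return cls(
            positive_module=frozenset(payload["positive_module"]),
            negative_module=frozenset(payload["negative_module"]),
            realized_membership={
                c: dict(flags)
                for c, flags in payload["realized_membership"].items()
            },
            config=config,
        )


@dataclass
class RecoveryMetrics:
    """Precision/recall/F1 of a found gene set against a planted module."""

    precision: float
    recall: float
    f1: float
    degenerate: bool

    def __post_init__(self) -> None:
        for value in (self.precision, self.recall, self.f1):
            if not 0 <= value <= 1:
                raise SyntheticConfigError("recovery metrics must lie in [0, 1]")


def _gene_names(config: SyntheticConfig) -> tuple[list[str], list[str], list[str]]:
    pos = [f"POS{i:04d}" for i in range(config.module_size_pos)]
    neg = [f"NEG{i:04d}" for i in range(config.module_size_neg)]
    n_bg = config.genes_total - 1 - len(pos) - len(neg)
    bg = [f"BG{i:05d}" for i in range(n_bg)]
    return pos, neg, bg


def _cohort_rng(master_seed: int, cohort_id: str) -> np.random.Generator:
    # named substream: independent of generation order
    ss = np.random.SeedSequence(
        master_seed, spawn_key=tuple(cohort_id.encode())
    )
    return np.random.default_rng(ss)


def generate_cohorts(
    config: SyntheticConfig,
) -> tuple[list[ExpressionCohort], SyntheticTruth]:
    """Generate one cohort list plus the planted truth.

    Cohort ids are ``<group>_c<i>``.  Per cohort: sample count drawn
    uniformly from the group's range, latent factor per sample, seed
    gene = baseline + f + sigma*noise, active module genes =
    baseline +/- beta*f + sigma*noise, everything else independent
    noise.  Per-gene baselines are drawn once per cohort from
    N(baseline_mean, baseline_sd).  Bit-identical for a fixed config.
    """
    pos, neg, bg = _gene_names(config)
    genes = [SEED_GENE] + pos + neg + bg
    pos_set = frozenset(pos)
    neg_set = frozenset(neg)

    cohorts: list[ExpressionCohort] = []
    membership: dict[str, dict[str, bool]] = {}
    for group in config.groups:
        for i in range(group.n_cohorts):
            cohort_id = f"{group.group_id}_c{i + 1}"
            rng = _cohort_rng(config.seed, cohort_id)
            lo, hi = group.n_samples_range
            n = int(rng.integers(lo, hi + 1))
            f = rng.standard_normal(n)
            baselines = rng.normal(
                config.baseline_mean, config.baseline_sd, size=len(genes)
            )
            active = rng.random(len(pos) + len(neg)) < config.pi
            noise = rng.standard_normal((len(genes), n)) * config.sigma

            loadings = np.zeros(len(genes))
            loadings[0] = 1.0  # seed gene
            module_flags: dict[str, bool] = {}
            for j, gene in enumerate(pos + neg):
                module_flags[gene] = bool(active[j])
                if active[j]:
                    loadings[1 + j] = config.beta if gene in pos_set else -config.beta
            values = baselines[:, None] + loadings[:, None] * f[None, :] + noise

            frame = pd.DataFrame(
                values,
                index=pd.Index(genes, name="gene"),
                columns=[f"{cohort_id}_s{k + 1}" for k in range(n)],
            )
            cohorts.append(ExpressionCohort(cohort_id, group.group_id, frame))
            membership[cohort_id] = module_flags

    truth = SyntheticTruth(pos_set, neg_set, membership, config)
    return cohorts, truth


def _score(found: frozenset[str], planted: frozenset[str]) -> RecoveryMetrics:
    if not planted:
        return RecoveryMetrics(0.0, 0.0, 0.0, True)
    if not found:
        return RecoveryMetrics(0.0, 0.0, 0.0, True)
    hits = len(found & planted)
    precision = hits / len(found)
    recall = hits / len(planted)
    f1 = (
        0.0
        if precision + recall == 0
        else 2 * precision * recall / (precision + recall)
    )
    return RecoveryMetrics(precision, recall, f1, False)


def evaluate_recovery(
    consensus,
    truth: SyntheticTruth,
    min_groups: int,
) -> dict[str, RecoveryMetrics]:
    """Score consensus gene sets against the planted modules, per sign.

    ``consensus`` is a :class:`~coexscreen.consensus.ConsensusResult`.
    Precision and recall use plain set arithmetic; an empty found set is
    flagged degenerate with precision = recall = 0.
    """
    found_pos = consensus.consensus_at(min_groups, "positive")
    found_neg = consensus.consensus_at(min_groups, "negative")
    return {
        "positive": _score(found_pos, truth.positive_module),
        "negative": _score(found_neg, truth.negative_module),
    }
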