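"""End-to-end screen orchestration from a single run configuration.

``run_screen`` composes correlate -> split -> recurrence -> consensus
(plus optional enrichment and stratified testing), writing per-stage
TSVs, a machine-readable JSON summary, and a log.  Identical
configuration and inputs produce byte-identical summaries.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import yaml

import coexscreen
from coexscreen.cohort_io import (
    ExpressionCohort,
    read_expression_tsv,
    read_gmt,
    write_gene_list_tsv,
)
from coexscreen.consensus import (
    GroupRecurrenceSpec,
    RecurrentSets,
    consensus_intersect,
    recurrence_filter,
)
from coexscreen.correlation_screen import correlate_with_seed, split_by_sign
from coexscreen.enrichment import fold_enrichment, write_enrichment_tsv
from coexscreen.stratified_stats import dichotomize_by_seed, two_group_test

logger = logging.getLogger(__name__)


class PipelineError(ValueError):
    """Raised when a stage cannot run; names the stage and offender."""


@dataclass(frozen=True)
class CohortEntry:
    path: str
    cohort_id: str
    group_id: str


@dataclass
class RunConfig:
    """Everything needed for a deterministic end-to-end run."""

    cohorts: list[CohortEntry]
    seed_gene: str
    outdir: str
    method: str = "pearson"
    alpha: float = 0.05
    min_abs_r: float = 0.0
    bh: bool = False
    group_cutoffs: dict[str, int] = field(default_factory=dict)
    consensus_level: int = 0  # 0 = all groups
    stratify_genes: list[str] = field(default_factory=list)
    enrichment_gmt: str | None = None
    enrichment_sign: str = "positive"
    master_seed: int = 0

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        payload = (
            json.loads(text)
            if path.suffix.lower() == ".json"
            else yaml.safe_load(text)
        )
        return cls.from_dict(payload, base=path.parent)

    @classmethod
    def from_dict(cls, payload: Mapping, base: Path | None = None) -> "RunConfig":
        def resolve(p: str) -> str:
            candidate = Path(p)
            if base is not None and not candidate.is_absolute():
                candidate = base / candidate
            return str(candidate)

        cohorts = [
            CohortEntry(resolve(c["path"]), c["cohort_id"], c["group_id"])
            for c in payload["cohorts"]
        ]
        return cls(
            cohorts=cohorts,
            seed_gene=payload["seed_gene"],
            outdir=resolve(payload.get("outdir", "coexscreen_out")),
            method=payload.get("method", "pearson"),
            alpha=float(payload.get("alpha", 0.05)),
            min_abs_r=float(payload.get("min_abs_r", 0.0)),
            bh=bool(payload.get("bh", False)),
            group_cutoffs={
                str(k): int(v) for k, v in payload.get("group_cutoffs", {}).items()
            },
            consensus_level=int(payload.get("consensus_level", 0)),
            stratify_genes=list(payload.get("stratify_genes", [])),
            enrichment_gmt=(
                resolve(payload["enrichment_gmt"])
                if payload.get("enrichment_gmt")
                else None
            ),
            enrichment_sign=payload.get("enrichment_sign", "positive"),
            master_seed=int(payload.get("master_seed", 0)),
        )

    def validate(self) -> None:
        if not self.cohorts:
            raise PipelineError("config lists no cohorts")
        seen = set()
        for entry in self.cohorts:
            if entry.cohort_id in seen:
                raise PipelineError(f"duplicate cohort id {entry.cohort_id!r}")
            seen.add(entry.cohort_id)
            if not Path(entry.path).exists():
                raise PipelineError(
                    f"manifest references a missing file: {entry.path}"
                )
        groups = {e.group_id for e in self.cohorts}
        uncovered = groups - set(self.group_cutoffs)
        if uncovered:
            raise PipelineError(
                f"group cutoff(s) missing for group(s): {sorted(uncovered)}"
            )

    def content_hash(self) -> str:
        payload = {
            "cohorts": [
                (e.cohort_id, e.group_id, e.path) for e in self.cohorts
            ],
            "seed_gene": self.seed_gene,
            "method": self.method,
            "alpha": self.alpha,
            "min_abs_r": self.min_abs_r,
            "bh": self.bh,
            "group_cutoffs": sorted(self.group_cutoffs.items()),
            "consensus_level": self.consensus_level,
            "stratify_genes": self.stratify_genes,
            "enrichment_gmt": self.enrichment_gmt,
            "enrichment_sign": self.enrichment_sign,
            "master_seed": self.master_seed,
        }
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()


def parse_cutoff_string(text: str) -> dict[str, int]:
    """Parse a CLI cutoff string like ``"cervix:2/5,lung:3/6"``.

    The denominator, when given, is validated against the manifest later;
    only the numerator (the cutoff) is retained here.
    """
    out: dict[str, int] = {}
    for part in text.split(","):
        part = part.strip()
        if not part:
            continue
        try:
            group, value = part.split(":")
            cutoff = value.split("/")[0]
            out[group.strip()] = int(cutoff)
        except ValueError as exc:
            raise PipelineError(f"malformed cutoff spec {part!r}") from exc
    return out


def _load_cohorts(config: RunConfig) -> list[ExpressionCohort]:
    cohorts = []
    for entry in config.cohorts:
        try:
            cohorts.append(
                read_expression_tsv(
                    entry.path, cohort_id=entry.cohort_id, group_id=entry.group_id
                )
            )
        except Exception as exc:
            raise PipelineError(
                f"stage load: cohort {entry.cohort_id!r}: {exc}"
            ) from exc
    return cohorts


def run_screen(config: RunConfig) -> dict:
    """Run the full screen; returns the summary dict (also written to disk).

    Outputs under ``config.outdir``:

    - ``correlations/<cohort>.tsv`` — per-gene r, p, n_used, status
    - ``sign_lists/<cohort>.<sign>.tsv`` — significant gene lists
    - ``recurrent/<group>.<sign>.tsv`` — recurrent genes with cohort counts
    - ``consensus.<sign>.tsv`` — consensus genes with group counts
    - ``venn.<sign>.tsv`` — region counts (when <= 4 groups)
    - ``enrichment.tsv``, ``stratified/<cohort>.tsv`` — when configured
    - ``summary.json``, ``run.log``
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("coexscreen")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        logger.info("coexscreen version %s", coexscreen.__version__)
        logger.info("python %s", sys.version.split()[0])
        logger.info("config hash %s", config.content_hash())
        logger.info("master seed %d", config.master_seed)
        return _run_screen_inner(config, outdir)
    finally:
        root.removeHandler(handler)
        handler.close()


def _run_screen_inner(config: RunConfig, outdir: Path) -> dict:
    cohorts = _load_cohorts(config)

    (outdir / "correlations").mkdir(exist_ok=True)
    (outdir / "sign_lists").mkdir(exist_ok=True)
    sign_lists = {}
    for cohort in cohorts:
        try:
            table = correlate_with_seed(cohort, config.seed_gene, config.method)
        except Exception as exc:
            raise PipelineError(
                f"stage correlate: cohort {cohort.cohort_id!r}: {exc}"
            ) from exc
        table.to_tsv(outdir / "correlations" / f"{cohort.cohort_id}.tsv")
        lists = split_by_sign(table, config.alpha, config.min_abs_r, bh=config.bh)
        sign_lists[cohort.cohort_id] = lists
        for sign in ("positive", "negative"):
            write_gene_list_tsv(
                getattr(lists, sign),
                outdir / "sign_lists" / f"{cohort.cohort_id}.{sign}.tsv",
            )

    by_group: dict[str, list[str]] = {}
    for entry in config.cohorts:
        by_group.setdefault(entry.group_id, []).append(entry.cohort_id)

    (outdir / "recurrent").mkdir(exist_ok=True)
    recurrent: list[RecurrentSets] = []
    for group_id in sorted(by_group):
        spec = GroupRecurrenceSpec(
            group_id, tuple(by_group[group_id]), config.group_cutoffs[group_id]
        )
        try:
            rec = recurrence_filter(sign_lists, spec)
        except Exception as exc:
            raise PipelineError(f"stage recurrence: group {group_id!r}: {exc}") from exc
        recurrent.append(rec)
        for sign in ("positive", "negative"):
            write_gene_list_tsv(
                {
                    g: {"cohort_count": rec.counts[sign].get(g, 0)}
                    for g in rec.genes[sign]
                },
                outdir / "recurrent" / f"{group_id}.{sign}.tsv",
            )

    level = config.consensus_level or len(recurrent)
    try:
        result = consensus_intersect(recurrent, level)
    except Exception as exc:
        raise PipelineError(f"stage consensus: {exc}") from exc

    consensus_sizes = {}
    for sign in ("positive", "negative"):
        genes = result.consensus_at(level, sign)
        consensus_sizes[sign] = len(genes)
        write_gene_list_tsv(
            {g: {"group_count": result.group_count[sign][g]} for g in genes},
            outdir / f"consensus.{sign}.tsv",
        )
        if result.venn_regions is not None:
            with (outdir / f"venn.{sign}.tsv").open("w") as handle:
                handle.write("groups\tcount\n")
                for sig in sorted(
                    result.venn_regions[sign], key=lambda s: (len(s), sorted(s))
                ):
                    handle.write(
                        f"{'+'.join(sorted(sig))}\t{result.venn_regions[sign][sig]}\n"
                    )

    summary: dict = {
        "config_hash": config.content_hash(),
        "master_seed": config.master_seed,
        "seed_gene": config.seed_gene,
        "alpha": config.alpha,
        "method": config.method,
        "consensus_level": level,
        "per_cohort_list_sizes": {
            c: {
                "positive": len(sign_lists[c].positive),
                "negative": len(sign_lists[c].negative),
            }
            for c in sorted(sign_lists)
        },
        "per_group_recurrent_sizes": {
            r.group_id: {
                "cutoff": r.cutoff,
                "positive": len(r.genes["positive"]),
                "negative": len(r.genes["negative"]),
            }
            for r in recurrent
        },
        "consensus_sizes": consensus_sizes,
        "n_conflict_genes": len(result.conflict_genes),
    }

    if config.enrichment_gmt:
        try:
            collection = read_gmt(config.enrichment_gmt)
            background = set()
            for cohort in cohorts:
                background.update(cohort.feature_ids)
            background.discard(config.seed_gene)
            query = result.consensus_at(level, config.enrichment_sign)
            rows = fold_enrichment(query, collection, background, bh=True)
        except Exception as exc:
            raise PipelineError(f"stage enrichment: {exc}") from exc
        write_enrichment_tsv(rows, outdir / "enrichment.tsv")
        summary["enrichment_terms_scored"] = len(rows)

    if config.stratify_genes:
        (outdir / "stratified").mkdir(exist_ok=True)
        n_sig = {}
        for cohort in cohorts:
            try:
                labels = dichotomize_by_seed(cohort, config.seed_gene)
                genes = [
                    g for g in config.stratify_genes if g in cohort.data.index
                ]
                res = two_group_test(cohort, labels, genes, bh=config.bh)
            except Exception as exc:
                raise PipelineError(
                    f"stage stratify: cohort {cohort.cohort_id!r}: {exc}"
                ) from exc
            res.to_tsv(outdir / "stratified" / f"{cohort.cohort_id}.tsv")
            tested = res.rows[res.rows["status"] == "ok"]
            n_sig[cohort.cohort_id] = int((tested["p"] < config.alpha).sum())
        summary["stratified_significant"] = {
            c: n_sig[c] for c in sorted(n_sig)
        }

    (outdir / "summary.json").write_text(
        json.dumps(summary, indent=1, sort_keys=True) + "\n"
    )
    return summary
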