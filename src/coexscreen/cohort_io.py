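"""I/O and container types for expression cohorts, probe maps and gene sets.

Expression matrices are tab-separated text, features in rows by default:
the header row holds sample ids and the first column holds feature ids.
Missing values are written as ``NA`` and held as NaN in memory.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Values above this are taken as evidence the matrix is not log2-scale.
NON_LOG2_GUARD = 30.0

MISSING_TOKEN = "NA"

Orientation = Literal["features_in_rows", "samples_in_rows"]


class CohortIOError(ValueError):
    """Raised for malformed cohort, probe-map, gene-list or GMT input."""


@dataclass
class ExpressionCohort:
    """One cohort's log2 expression matrix with cohort and group identity.

    Parameters
    ----------
    cohort_id : str
        Identifier of the dataset.
    group_id : str
        Condition group the cohort belongs to (e.g. a tumor type).
    data : pandas.DataFrame
        Matrix of log2 expression, features in rows, samples in columns.
        Missing entries are NaN.
    """

    cohort_id: str
    group_id: str
    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.size == 0:
            raise CohortIOError(
                f"cohort {self.cohort_id!r}: empty expression matrix"
            )
        _check_unique(self.data.index, "feature")
        _check_unique(self.data.columns, "sample")
        values = self.data.to_numpy()
        if np.isinf(values).any():
            raise CohortIOError(
                f"cohort {self.cohort_id!r}: non-finite (infinite) values present"
            )

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_features(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def values_for(self, feature_id: str) -> np.ndarray:
        """Return one feature's values as a float array (NaN = missing)."""
        if feature_id not in self.data.index:
            raise KeyError(f"feature {feature_id!r} not in cohort {self.cohort_id!r}")
        return self.data.loc[feature_id].to_numpy(dtype=float)


@dataclass
class ProbeMap:
    """Mapping of probe ids to gene symbols."""

    entries: dict[str, str]

    def __post_init__(self) -> None:
        for probe, gene in self.entries.items():
            if not str(gene).strip():
                raise CohortIOError(f"probe {probe!r} maps to an empty gene symbol")

    def __contains__(self, probe_id: str) -> bool:
        return probe_id in self.entries

    def __getitem__(self, probe_id: str) -> str:
        return self.entries[probe_id]


@dataclass
class GeneSetCollection:
    """Named gene sets: term_id -> (description, member genes)."""

    sets: dict[str, tuple[str, frozenset[str]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for term, (_desc, members) in self.sets.items():
            if not members:
                raise CohortIOError(f"gene set {term!r} has no members")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())

    def members(self, term_id: str) -> frozenset[str]:
        return self.sets[term_id][1]

    def description(self, term_id: str) -> str:
        return self.sets[term_id][0]


def _check_unique(index: Iterable[str], kind: str) -> None:
    seen: set[str] = set()
    for ident in index:
        if ident in seen:
            raise CohortIOError(f"duplicate {kind} identifier: {ident!r}")
        seen.add(ident)


def read_expression_tsv(
    path: str | Path,
    cohort_id: str | None = None,
    group_id: str = "",
    orientation: Orientation = "features_in_rows",
) -> ExpressionCohort:
    """Read an expression cohort from a TSV file.

    The first row holds identifiers, as does the first column; which axis
    is features is controlled by ``orientation``.  Cells must be numeric
    or the missing token ``NA``.  A warning is logged when the matrix
    maximum exceeds 30, a sign that the input is probably not log2-scale.

    Raises
    ------
    CohortIOError
        On duplicate identifiers, non-numeric cells, or an empty matrix.
    """
    path = Path(path)
    if not path.exists():
        raise CohortIOError(f"expression file not found: {path}")
    raw = pd.read_csv(
        path, sep="\t", index_col=0, dtype=str, keep_default_na=False
    )
    if raw.size == 0:
        raise CohortIOError(f"{path}: empty expression matrix")
    _check_unique(raw.index.astype(str), "row")
    _check_unique(raw.columns.astype(str), "column")

    stripped = raw.map(lambda s: s.strip())
    numeric = stripped.apply(pd.to_numeric, errors="coerce")
    is_missing = stripped.isin([MISSING_TOKEN, ""])
    bad = numeric.isna() & ~is_missing
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise CohortIOError(
            f"{path}: non-numeric value {stripped.iat[i, j]!r} at row "
            f"{raw.index[i]!r}, column {raw.columns[j]!r}"
        )
    values = numeric.to_numpy(dtype=float)

    frame = pd.DataFrame(values, index=raw.index.astype(str), columns=raw.columns.astype(str))
    frame.index.name = None
    frame.columns.name = None
    if orientation == "samples_in_rows":
        frame = frame.T
    elif orientation != "features_in_rows":
        raise CohortIOError(f"unknown orientation: {orientation!r}")

    finite = frame.to_numpy()
    with np.errstate(invalid="ignore"):
        if np.nanmax(finite) > NON_LOG2_GUARD:
            logger.warning(
                "%s: maximum value %.3g exceeds %g; input may not be log2-scale",
                path,
                np.nanmax(finite),
                NON_LOG2_GUARD,
            )
    return ExpressionCohort(
        cohort_id=cohort_id if cohort_id is not None else path.stem,
        group_id=group_id,
        data=frame,
    )


def write_expression_tsv(cohort: ExpressionCohort, path: str | Path) -> None:
    """Write a cohort matrix as TSV (features in rows, ``NA`` for missing)."""
    out = cohort.data.copy()
    out.index.name = "feature_id"
    out.to_csv(path, sep="\t", na_rep=MISSING_TOKEN, float_format="%.10g")


def read_probe_map_tsv(path: str | Path) -> ProbeMap:
    """Read a two-column (probe_id, gene_symbol) TSV, header optional."""
    path = Path(path)
    entries: dict[str, str] = {}
    with path.open() as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise CohortIOError(
                    f"{path}:{lineno}: probe map line needs 2 tab-separated fields"
                )
            probe, gene = fields[0], fields[1]
            if lineno == 1 and probe.lower() in {"probe", "probe_id"}:
                continue
            if probe in entries:
                raise CohortIOError(f"{path}:{lineno}: duplicate probe id {probe!r}")
            entries[probe] = gene
    return ProbeMap(entries)


def collapse_probes(
    cohort: ExpressionCohort,
    probe_map: ProbeMap,
    method: Literal["named_probe", "max_mean"] = "max_mean",
    named_probes: Mapping[str, str] | None = None,
) -> ExpressionCohort:
    """Collapse probe-level features to gene level.

    Probes absent from ``probe_map`` are dropped (count is logged).  With
    ``max_mean``, each gene keeps the probe with the highest mean
    expression across samples.  With ``named_probe``, genes listed in
    ``named_probes`` (gene -> probe id) keep exactly that probe — a hard
    error if the designated probe is missing — and all other genes fall
    back to ``max_mean``.
    """
    mapped = [p for p in cohort.feature_ids if p in probe_map]
    dropped = cohort.n_features - len(mapped)
    if dropped:
        logger.info(
            "cohort %s: dropping %d unmapped probe(s)", cohort.cohort_id, dropped
        )
    if not mapped:
        raise CohortIOError(
            f"cohort {cohort.cohort_id!r}: no probes found in the probe map"
        )

    if method == "named_probe" and named_probes:
        for gene, probe in named_probes.items():
            if probe not in cohort.data.index:
                raise CohortIOError(
                    f"cohort {cohort.cohort_id!r}: designated probe {probe!r} "
                    f"for gene {gene!r} is absent"
                )
    elif method not in {"named_probe", "max_mean"}:
        raise CohortIOError(f"unknown collapse method: {method!r}")

    by_gene: dict[str, list[str]] = {}
    for probe in mapped:
        by_gene.setdefault(probe_map[probe], []).append(probe)

    chosen: dict[str, str] = {}
    for gene, probes in by_gene.items():
        if method == "named_probe" and named_probes and gene in named_probes:
            chosen[gene] = named_probes[gene]
        elif len(probes) == 1:
            chosen[gene] = probes[0]
        else:
            means = cohort.data.loc[probes].mean(axis=1, skipna=True)
            chosen[gene] = means.idxmax()

    genes = sorted(chosen)
    frame = cohort.data.loc[[chosen[g] for g in genes]].copy()
    frame.index = pd.Index(genes, name="gene")
    return ExpressionCohort(cohort.cohort_id, cohort.group_id, frame)


def write_gene_list_tsv(
    genes: Mapping[str, Mapping[str, object]] | Iterable[str],
    path: str | Path,
) -> None:
    """Write a gene list with optional per-gene annotation columns.

    ``genes`` may be a plain iterable of symbols or a mapping gene ->
    {column: value}.  The output has a header line starting with "gene".
    """
    path = Path(path)
    if isinstance(genes, Mapping):
        columns: list[str] = []
        for ann in genes.values():
            for key in ann:
                if key not in columns:
                    columns.append(key)
        with path.open("w") as handle:
            handle.write("\t".join(["gene", *columns]) + "\n")
            for gene in sorted(genes):
                ann = genes[gene]
                row = [gene] + [str(ann.get(c, "")) for c in columns]
                handle.write("\t".join(row) + "\n")
    else:
        with path.open("w") as handle:
            handle.write("gene\n")
            for gene in sorted(set(genes)):
                handle.write(f"{gene}\n")


def read_gene_list_tsv(path: str | Path) -> dict[str, dict[str, str]]:
    """Read a gene-list TSV written by :func:`write_gene_list_tsv`."""
    path = Path(path)
    out: dict[str, dict[str, str]] = {}
    with path.open() as handle:
        header = handle.readline().rstrip("\n").split("\t")
        if not header or header[0] != "gene":
            raise CohortIOError(f"{path}: gene-list header must start with 'gene'")
        columns = header[1:]
        for lineno, line in enumerate(handle, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            gene = fields[0]
            if gene in out:
                raise CohortIOError(f"{path}:{lineno}: duplicate gene {gene!r}")
            out[gene] = dict(zip(columns, fields[1:]))
    return out


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file: term_id <TAB> description <TAB> member genes."""
    path = Path(path)
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    with path.open() as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise CohortIOError(
                    f"{path}:{lineno}: GMT line needs at least 3 tab-separated fields"
                )
            term, desc = fields[0], fields[1]
            members = frozenset(f for f in fields[2:] if f)
            if term in sets:
                raise CohortIOError(f"{path}:{lineno}: duplicate term id {term!r}")
            if not members:
                raise CohortIOError(f"{path}:{lineno}: term {term!r} has no members")
            sets[term] = (desc, members)
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with Path(path).open("w") as handle:
        for term, (desc, members) in collection:
            handle.write("\t".join([term, desc, *sorted(members)]) + "\n")
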