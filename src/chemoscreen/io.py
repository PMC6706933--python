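"""Reading and writing screen count tables, gene sets, and gene-level results.

The input boundary is a tab-delimited read-count table with one row per
gRNA: a guide-identifier column, a gene-symbol column, and one integer
count column per sequenced sample.  Guide and gene identifiers are opaque
case-sensitive strings; no symbol normalization is performed.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._errors import ConfigurationError, ValidationError

#: Header written by :func:`write_gene_results`; the stable output contract.
RESULT_COLUMNS = [
    "GENE",
    "sumZ",
    "numObs",
    "normZ",
    "pval_synth",
    "rank_synth",
    "fdr_synth",
    "pval_supp",
    "rank_supp",
    "fdr_supp",
]


@dataclass
class ScreenCounts:
    """A guide x sample integer count table with guide->gene mapping.

    Parameters
    ----------
    counts
        DataFrame indexed by unique guide id, one column per sample,
        non-negative integer read counts.
    genes
        Series mapping guide id -> gene symbol, aligned to ``counts``.
    control_samples, treated_samples
        Ordered sample-role assignment.  In paired mode the i-th control
        and i-th treated column form replicate pair i.  May be left unset
        at read time and assigned later with :meth:`with_roles`.
    """

    counts: pd.DataFrame
    genes: pd.Series
    control_samples: list[str] = field(default_factory=list)
    treated_samples: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        idx = self.counts.index
        if idx.has_duplicates:
            dups = sorted(set(idx[idx.duplicated()]))
            raise ValidationError(f"duplicate guide_id values: {dups}")
        if not self.genes.index.equals(idx):
            raise ValidationError("genes index does not match counts index")
        vals = self.counts.to_numpy()
        if (vals < 0).any():
            rows = np.unique(np.nonzero((vals < 0).any(axis=1))[0])
            raise ValidationError(
                f"negative counts in rows {rows.tolist()} "
                f"(guides {idx[rows].tolist()})"
            )
        for arm in (self.control_samples, self.treated_samples):
            missing = [s for s in arm if s not in self.counts.columns]
            if missing:
                raise ConfigurationError(
                    f"sample columns not present: {missing}; "
                    f"available: {list(self.counts.columns)}"
                )

    @property
    def guide_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_names(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_guides(self) -> int:
        return len(self.counts)

    def with_roles(
        self, control_samples: list[str], treated_samples: list[str]
    ) -> "ScreenCounts":
        """Return a copy with sample roles assigned."""
        if not control_samples or not treated_samples:
            raise ConfigurationError(
                "at least one control and one treated sample are required"
            )
        return ScreenCounts(
            counts=self.counts,
            genes=self.genes,
            control_samples=list(control_samples),
            treated_samples=list(treated_samples),
        )


@dataclass(frozen=True)
class GeneSet:
    """A named set of gene symbols (e.g. an annotated DDR gene list)."""

    name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValidationError(f"gene set {self.name!r} is empty")

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, gene: str) -> bool:
        return gene in self.members


def read_count_table(
    path: str | os.PathLike,
    gene_column: str = "GENE",
    sample_columns: list[str] | None = None,
    guide_column: str | None = None,
) -> ScreenCounts:
    """Read and validate a tab-delimited read-count table.

    Parameters
    ----------
    path
        Tab-separated UTF-8 file with a header row.
    gene_column
        Name of the gene-symbol column.
    sample_columns
        Ordered count columns to load.  Defaults to every column other
        than the guide and gene columns; extra unnamed columns are
        ignored when an explicit list is given.
    guide_column
        Name of the guide-identifier column; defaults to the first column.

    Raises
    ------
    ConfigurationError
        A named column is absent from the file.
    ValidationError
        Duplicate guide ids, non-numeric counts, or negative counts.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if guide_column is None:
        guide_column = df.columns[0]
    for col in [guide_column, gene_column]:
        if col not in df.columns:
            raise ConfigurationError(
                f"column {col!r} not found in {path}; "
                f"available: {list(df.columns)}"
            )
    if sample_columns is None:
        sample_columns = [
            c for c in df.columns if c not in (guide_column, gene_column)
        ]
    missing = [c for c in sample_columns if c not in df.columns]
    if missing:
        raise ConfigurationError(
            f"sample columns not found: {missing}; "
            f"available: {list(df.columns)}"
        )
    if not sample_columns:
        raise ConfigurationError("no sample columns selected")

    raw = df[sample_columns]
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna().any(axis=1)
    if bad.any():
        rows = (np.nonzero(bad.to_numpy())[0] + 2).tolist()  # 1-based + header
        raise ValidationError(
            f"non-numeric counts at file line(s) {rows}"
        )
    neg = (numeric < 0).any(axis=1)
    if neg.any():
        rows = (np.nonzero(neg.to_numpy())[0] + 2).tolist()
        raise ValidationError(f"negative counts at file line(s) {rows}")

    counts = numeric.round().astype(np.int64)
    counts.index = pd.Index(df[guide_column], name=guide_column)
    genes = pd.Series(
        df[gene_column].to_numpy(), index=counts.index, name=gene_column
    )
    return ScreenCounts(counts=counts, genes=genes)


def read_gene_set(path: str | os.PathLike, name: str | None = None) -> GeneSet:
    """Read a gene-set file: one symbol per line, '#' comments ignored."""
    members: list[str] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            members.append(line)
    if name is None:
        name = os.path.splitext(os.path.basename(os.fspath(path)))[0]
    return GeneSet(name=name, members=frozenset(members))


def write_gene_results(results: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write gene-level results as a stable tab-delimited table.

    Rows are ordered by ascending normZ; floats carry six significant
    digits.  Raises :class:`ValidationError` on empty results before any
    file is created.
    """
    if results is None or len(results) == 0:
        raise ValidationError("no gene results to write")
    missing = [c for c in RESULT_COLUMNS if c not in results.columns]
    if missing:
        raise ValidationError(f"results missing columns: {missing}")
    out = results[RESULT_COLUMNS].sort_values(
        ["normZ", "GENE"], kind="mergesort"
    )
    out.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_gene_results(path: str | os.PathLike) -> pd.DataFrame:
    """Read a results table written by :func:`write_gene_results`."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in RESULT_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"result file missing columns: {missing}")
    return df
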