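"""Expression-matrix container and plain-text I/O.

The package works on genes-by-samples matrices of continuous expression
values (log-scale microarray intensities or variance-stabilised counts).
``ExpressionMatrix`` is a thin, validated wrapper over a numpy array with
gene and sample identifiers, plus an optional probe->gene map used when a
platform measures each gene with several probes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ExpressionMatrix", "read_expression_tsv", "read_probe_map", "read_gmt"]


@dataclass
class ExpressionMatrix:
    """Genes x samples continuous expression values.

    Parameters
    ----------
    values : ndarray, shape (n_genes, n_samples)
    gene_ids : sequence of unique str
    sample_ids : sequence of unique str
    probe_to_gene : optional mapping probe_id -> gene symbol, used by
        :func:`lpdstrat.preprocess.select_random_probe_per_gene` when
        ``gene_ids`` are really probe identifiers.
    """

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]
    probe_to_gene: dict[str, str] | None = field(default=None)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = list(map(str, self.gene_ids))
        self.sample_ids = list(map(str, self.sample_ids))
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (genes x samples)")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"shape {self.values.shape} inconsistent with "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("gene_ids are not unique")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("sample_ids are not unique")
        if not np.all(np.isfinite(self.values)):
            raise ValueError(
                "expression matrix contains missing or non-finite values; "
                "impute before constructing (see impute_gene_median)"
            )

    # -- basic introspection -------------------------------------------------
    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def gene_index(self, genes) -> np.ndarray:
        """Integer row positions of ``genes``; raises on absent genes."""
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in lookup]
        if missing:
            raise KeyError(f"{len(missing)} gene(s) absent from matrix, e.g. {missing[:3]}")
        return np.array([lookup[g] for g in genes], dtype=int)

    def subset_genes(self, genes) -> "ExpressionMatrix":
        idx = self.gene_index(genes)
        return ExpressionMatrix(
            self.values[idx], [self.gene_ids[i] for i in idx], list(self.sample_ids),
            probe_to_gene=self.probe_to_gene,
        )

    def subset_samples(self, samples) -> "ExpressionMatrix":
        lookup = {s: j for j, s in enumerate(self.sample_ids)}
        idx = np.array([lookup[s] for s in samples], dtype=int)
        return ExpressionMatrix(
            self.values[:, idx], list(self.gene_ids), [self.sample_ids[j] for j in idx],
            probe_to_gene=self.probe_to_gene,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, probe_to_gene=None) -> "ExpressionMatrix":
        return cls(df.to_numpy(dtype=float), list(df.index), list(df.columns),
                   probe_to_gene=probe_to_gene)

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values.copy(), list(self.gene_ids), list(self.sample_ids),
            probe_to_gene=dict(self.probe_to_gene) if self.probe_to_gene else None,
        )

    # -- I/O -----------------------------------------------------------------
    def to_tsv(self, path) -> None:
        df = self.to_frame()
        df.index.name = "gene_id"
        df.to_csv(path, sep="\t")


def read_expression_tsv(path, probe_map_path=None, impute_gene_median: bool = False) -> ExpressionMatrix:
    """Read a tab-separated expression matrix (first column gene IDs, header = samples).

    Missing values are rejected unless ``impute_gene_median`` is set, in which
    case they are replaced by the gene's median across samples (logged via a
    warning). The model itself has no missing-data mechanism.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.isna().to_numpy().any():
        if not impute_gene_median:
            raise ValueError(f"{path}: matrix contains missing values (use impute_gene_median=True)")
        n_missing = int(df.isna().to_numpy().sum())
        warnings.warn(f"{path}: imputed {n_missing} missing values with per-gene medians")
        med = df.median(axis=1)
        df = df.apply(lambda row: row.fillna(med[row.name]), axis=1)
    probe_map = read_probe_map(probe_map_path) if probe_map_path else None
    return ExpressionMatrix.from_frame(df, probe_to_gene=probe_map)


def read_probe_map(path) -> dict[str, str]:
    """Two-column TSV (probe_id <tab> gene) -> dict."""
    df = pd.read_csv(path, sep="\t", header=None, names=["probe", "gene"], dtype=str)
    return dict(zip(df["probe"], df["gene"]))


def read_gmt(path) -> dict[str, list[str]]:
    """Read a GMT gene-set file: set name, description, then member genes, tab-separated."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    if not sets:
        raise ValueError(f"{path}: empty GMT file")
    return sets
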