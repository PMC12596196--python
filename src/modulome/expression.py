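"""Expression-matrix I/O and normalization.

The pipeline consumes a genes × samples matrix of log10(TPM + 1) values
together with a sample metadata table assigning each sample to a project,
a condition and (optionally) a reference flag. Before decomposition the
matrix is batch-normalized by subtracting, within each project, the
per-gene mean of that project's reference samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

METADATA_COLUMNS = ("sample_id", "project_id", "condition", "is_reference", "replicate_group")


@dataclass
class ExpressionMatrix:
    """A genes × samples expression matrix.

    Parameters
    ----------
    data : pandas.DataFrame
        Genes in rows (index = locus tags), samples in columns. All
        entries must be finite; before centering all entries must be
        non-negative.
    is_centered : bool
        True once reference-condition centering has been applied.
    """

    data: pd.DataFrame
    is_centered: bool = False

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene id: {dups[:5]}")
        if self.data.columns.has_duplicates:
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample id: {dups[:5]}")
        values = self.data.to_numpy(dtype=float)
        if not np.isfinite(values).all():
            raise ValueError("expression matrix contains non-finite values")
        if not self.is_centered and values.size and values.min() < 0:
            raise ValueError("uncentered expression matrix contains negative entries")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


def read_expression(path, layout: str = "genes_by_samples") -> ExpressionMatrix:
    """Read a TSV/CSV expression table.

    ``layout`` is ``"genes_by_samples"`` (default: genes in rows) or
    ``"samples_by_genes"``, in which case the parsed table is transposed
    so the returned matrix is always genes × samples.
    """
    if layout not in ("genes_by_samples", "samples_by_genes"):
        raise ValueError(f"unknown layout {layout!r}")
    sep = "," if str(path).endswith(".csv") else "\t"
    table = pd.read_csv(path, sep=sep, index_col=0)
    try:
        table = table.astype(float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric cell in expression table {path}: {exc}") from None
    if layout == "samples_by_genes":
        table = table.T
    table.index = table.index.astype(str).rename(None)
    table.columns = table.columns.astype(str).rename(None)
    return ExpressionMatrix(table)


def read_metadata(path) -> pd.DataFrame:
    """Read the sample metadata CSV and validate its columns."""
    meta = pd.read_csv(path)
    missing = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"metadata missing columns: {missing}")
    if meta["sample_id"].duplicated().any():
        raise ValueError("duplicate sample_id in metadata")
    meta = meta.copy()
    if meta["is_reference"].dtype == object:
        meta["is_reference"] = (
            meta["is_reference"].astype(str).str.strip().str.lower().map({"true": True, "false": False})
        )
        if meta["is_reference"].isna().any():
            raise ValueError("is_reference must be true/false")
    meta["is_reference"] = meta["is_reference"].astype(bool)
    return meta


def validate_metadata(x: ExpressionMatrix, meta: pd.DataFrame) -> None:
    """Check that metadata covers every sample and every project has a reference."""
    meta_samples = set(meta["sample_id"])
    missing = [s for s in x.sample_ids if s not in meta_samples]
    if missing:
        raise ValueError(f"sample without metadata: {missing[:5]}")
    covered = meta[meta["sample_id"].isin(x.sample_ids)]
    for project, grp in covered.groupby("project_id"):
        if not grp["is_reference"].any():
            raise ValueError(f"project {project!r} has no reference sample")


def tpm_to_logtpm(x: ExpressionMatrix) -> ExpressionMatrix:
    """log10(TPM + 1) transform of a raw-TPM matrix."""
    values = x.values
    if values.size and values.min() < 0:
        raise ValueError("negative TPM entry")
    out = pd.DataFrame(np.log10(values + 1.0), index=x.data.index, columns=x.data.columns)
    return ExpressionMatrix(out)


def logtpm_to_tpm(x: ExpressionMatrix) -> ExpressionMatrix:
    """Inverse of :func:`tpm_to_logtpm`."""
    out = pd.DataFrame(
        np.power(10.0, x.values) - 1.0, index=x.data.index, columns=x.data.columns
    )
    return ExpressionMatrix(out)


def batch_center(x: ExpressionMatrix, meta: pd.DataFrame) -> ExpressionMatrix:
    """Center each project's samples on that project's reference-sample mean.

    For every project, the per-gene mean over that project's reference
    samples is subtracted from all of the project's samples. The result
    carries ``is_centered=True``. Centering the output again with the
    same metadata is a no-op (reference samples then average to zero).
    """
    validate_metadata(x, meta)
    centered = x.data.copy().astype(float)
    covered = meta[meta["sample_id"].isin(x.sample_ids)]
    for project, grp in covered.groupby("project_id"):
        samples = [s for s in x.sample_ids if s in set(grp["sample_id"])]
        refs = [s for s in samples if s in set(grp.loc[grp["is_reference"], "sample_id"])]
        ref_mean = x.data[refs].mean(axis=1)
        centered[samples] = x.data[samples].sub(ref_mean, axis=0)
    return ExpressionMatrix(centered, is_centered=True)


def _gene_profile(x: ExpressionMatrix, gene: str) -> np.ndarray:
    if gene not in x.data.index:
        raise KeyError(f"unknown gene {gene!r}")
    return x.data.loc[gene].to_numpy(dtype=float)


def gene_correlation(x: ExpressionMatrix, gene_a: str, gene_b: str) -> float:
    """Pearson correlation between two genes' expression profiles."""
    a = _gene_profile(x, gene_a)
    b = _gene_profile(x, gene_b)
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("zero-variance gene in correlation")
    return float(np.corrcoef(a, b)[0, 1])


def zero_variance_genes(x: ExpressionMatrix) -> list[str]:
    """Genes with identical expression in every sample (excluded from ICA)."""
    sd = x.data.std(axis=1, ddof=0)
    flagged = list(sd.index[sd == 0])
    if flagged:
        logger.warning("%d zero-variance genes excluded from analysis", len(flagged))
    return flagged


def log_fold_change(
    x: ExpressionMatrix,
    group_a: list[str],
    group_b: list[str],
    base: str = "log10",
) -> pd.Series:
    """Per-gene difference of group means on the log scale.

    Returns mean(group_a) − mean(group_b) for every gene. With
    ``base="log2"`` the log10-scale difference is converted to log2
    units (factor log2(10)); no count-based shrinkage or dispersion
    model is applied.
    """
    if not group_a or not group_b:
        raise ValueError("empty sample group")
    overlap = set(group_a) & set(group_b)
    if overlap:
        raise ValueError(f"overlapping sample groups: {sorted(overlap)[:5]}")
    for s in list(group_a) + list(group_b):
        if s not in x.data.columns:
            raise KeyError(f"unknown sample {s!r}")
    lfc = x.data[list(group_a)].mean(axis=1) - x.data[list(group_b)].mean(axis=1)
    if base == "log2":
        lfc = lfc * np.log2(10.0)
    elif base != "log10":
        raise ValueError(f"unknown base {base!r}")
    return lfc


def write_expression(x: ExpressionMatrix, path) -> None:
    sep = "," if str(path).endswith(".csv") else "\t"
    x.data.to_csv(path, sep=sep)
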