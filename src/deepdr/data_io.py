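"""Tabular I/O and preprocessing for expression, mutation and drug-response matrices.

All matrices are held as pandas DataFrames in gene-major (feature x sample)
orientation:

* expression  — genes x samples, log2(TPM+1) units, finite and non-negative;
* mutation    — genes x samples, binary {0, 1} nonsynonymous mutation status;
* response    — drugs x samples, log10 IC50 (uM); missing entries are NaN;
* annotation  — samples x columns, with a ``stratum`` column (e.g. cancer type).

On-disk formats are plain TSV/CSV with the feature id in the first column and
sample ids in the header; pandas handles gzip transparently by extension.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable

import numpy as np
import pandas as pd

from .exceptions import ValidationError

logger = logging.getLogger(__name__)

#: MAF variant classes counted as nonsynonymous: missense, nonsense and
#: frameshift insertions/deletions. User-extensible via the ``qualifying``
#: argument of :func:`maf_to_mutation_matrix`.
QUALIFYING_VARIANT_CLASSES = frozenset(
    {
        "Missense_Mutation",
        "Nonsense_Mutation",
        "Frame_Shift_Ins",
        "Frame_Shift_Del",
    }
)


def _check_unique(index: pd.Index, what: str) -> None:
    if index.has_duplicates:
        dupes = index[index.duplicated()].unique().tolist()[:5]
        raise ValidationError(f"duplicate {what} ids: {dupes}")


def read_matrix(path, sep: str = "\t", transpose: bool = False) -> pd.DataFrame:
    """Read a feature x sample table (first column = feature id, header = samples).

    Set ``transpose=True`` for sample-major files.
    """
    df = pd.read_csv(path, sep=sep, index_col=0)
    if transpose:
        df = df.T
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    _check_unique(df.index, "feature")
    _check_unique(df.columns, "sample")
    return df


def write_matrix(df: pd.DataFrame, path, sep: str = "\t") -> None:
    df.to_csv(path, sep=sep)


def read_annotation(path, sep: str = "\t") -> pd.DataFrame:
    """Read a sample annotation table (sample_id, stratum, optional flags)."""
    ann = pd.read_csv(path, sep=sep, index_col=0)
    ann.index = ann.index.astype(str)
    _check_unique(ann.index, "sample")
    if "stratum" not in ann.columns:
        raise ValidationError("annotation table must have a 'stratum' column")
    return ann


def validate_expression(E: pd.DataFrame) -> None:
    """Check the expression-matrix invariants: finite, non-negative, unique ids."""
    _check_unique(E.index, "gene")
    _check_unique(E.columns, "sample")
    values = E.to_numpy()
    bad = ~np.isfinite(values) | (values < 0)
    if bad.any():
        g, s = np.argwhere(bad)[0]
        raise ValidationError(
            f"expression value at gene {E.index[g]!r}, sample {E.columns[s]!r} "
            f"is {values[g, s]!r} (must be finite and >= 0)"
        )


def validate_mutation(M: pd.DataFrame) -> None:
    _check_unique(M.index, "gene")
    _check_unique(M.columns, "sample")
    values = M.to_numpy()
    if not np.isin(values, (0, 1)).all():
        g, s = np.argwhere(~np.isin(values, (0, 1)))[0]
        raise ValidationError(
            f"mutation value at gene {M.index[g]!r}, sample {M.columns[s]!r} "
            f"is {values[g, s]!r} (must be 0 or 1)"
        )


def log2_tpm_transform(tpm: pd.DataFrame) -> pd.DataFrame:
    """Transform a gene x sample TPM table to log2(TPM + 1).

    Raises :class:`ValidationError` naming the first offending (gene, sample)
    if any entry is negative or non-finite.
    """
    values = tpm.to_numpy(dtype=float)
    bad = ~np.isfinite(values) | (values < 0)
    if bad.any():
        g, s = np.argwhere(bad)[0]
        raise ValidationError(
            f"TPM value at gene {tpm.index[g]!r}, sample {tpm.columns[s]!r} "
            f"is {values[g, s]!r} (must be finite and >= 0)"
        )
    return pd.DataFrame(np.log2(values + 1.0), index=tpm.index, columns=tpm.columns)


def filter_low_information_genes(
    E: pd.DataFrame, mean_thr: float = 1.0, sd_thr: float = 0.5
) -> pd.DataFrame:
    """Drop genes with low information burden (mean < mean_thr or sd < sd_thr).

    Means and sample standard deviations (ddof=1) are taken per gene across
    samples on the matrix's own scale. Gene order is preserved.
    """
    if E.shape[1] < 2:
        raise ValidationError(
            "at least 2 samples are required (standard deviation undefined otherwise)"
        )
    means = E.mean(axis=1)
    sds = E.std(axis=1, ddof=1)
    keep = (means >= mean_thr) & (sds >= sd_thr)
    return E.loc[keep]


def maf_to_mutation_matrix(
    records,
    gene_ids: Iterable[str],
    sample_ids: Iterable[str],
    qualifying: frozenset[str] = QUALIFYING_VARIANT_CLASSES,
    on_unknown_sample: str = "warn",
) -> pd.DataFrame:
    """Collapse MAF-style records into a binary gene x sample mutation matrix.

    Parameters
    ----------
    records
        DataFrame with columns ``sample``, ``gene``, ``variant_classification``,
        or an iterable of (sample, gene, variant_classification) tuples.
    qualifying
        Variant classes that count as a mutation; everything else (Silent,
        intronic, ...) is ignored.
    on_unknown_sample
        ``"warn"`` skips records whose sample is not in ``sample_ids`` with a
        logged warning; ``"error"`` raises.
    """
    if on_unknown_sample not in ("warn", "error"):
        raise ValidationError("on_unknown_sample must be 'warn' or 'error'")
    if not isinstance(records, pd.DataFrame):
        records = pd.DataFrame(
            list(records), columns=["sample", "gene", "variant_classification"]
        )
    required = {"sample", "gene", "variant_classification"}
    if not required.issubset(records.columns):
        raise ValidationError(f"records need columns {sorted(required)}")

    gene_ids = pd.Index([str(g) for g in gene_ids])
    sample_ids = pd.Index([str(s) for s in sample_ids])
    _check_unique(gene_ids, "gene")
    _check_unique(sample_ids, "sample")

    M = pd.DataFrame(
        np.zeros((len(gene_ids), len(sample_ids)), dtype=np.int8),
        index=gene_ids,
        columns=sample_ids,
    )
    hits = records[records["variant_classification"].isin(qualifying)]
    unknown = ~hits["sample"].astype(str).isin(sample_ids)
    if unknown.any():
        examples = hits.loc[unknown, "sample"].unique().tolist()[:5]
        if on_unknown_sample == "error":
            raise ValidationError(f"records reference unknown samples: {examples}")
        logger.warning(
            "skipping %d records with unknown samples (e.g. %s)",
            int(unknown.sum()),
            examples,
        )
        hits = hits[~unknown]
    known_gene = hits["gene"].astype(str).isin(gene_ids)
    if (~known_gene).any():
        logger.debug("skipping %d records with unlisted genes", int((~known_gene).sum()))
        hits = hits[known_gene]
    gi = gene_ids.get_indexer(hits["gene"].astype(str))
    si = sample_ids.get_indexer(hits["sample"].astype(str))
    M.values[gi, si] = 1
    return M


def read_maf(
    path,
    sample_col: str = "Tumor_Sample_Barcode",
    gene_col: str = "Hugo_Symbol",
    class_col: str = "Variant_Classification",
    sep: str = "\t",
) -> pd.DataFrame:
    """Read a MAF-like TSV down to the three columns the pipeline uses."""
    maf = pd.read_csv(path, sep=sep, comment="#", dtype=str)
    missing = [c for c in (sample_col, gene_col, class_col) if c not in maf.columns]
    if missing:
        raise ValidationError(f"MAF file {path} lacks columns {missing}")
    out = maf[[sample_col, gene_col, class_col]].copy()
    out.columns = ["sample", "gene", "variant_classification"]
    return out


def drop_never_mutated_genes(
    M_a: pd.DataFrame, M_b: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove genes whose row sum is zero in *both* cohorts.

    Both matrices must cover the same gene universe; the retained gene set is
    identical in both outputs.
    """
    genes_a, genes_b = set(M_a.index), set(M_b.index)
    if genes_a != genes_b:
        if genes_a.isdisjoint(genes_b):
            raise ValidationError("gene universes are disjoint")
        raise ValidationError(
            f"gene universes differ ({len(genes_a ^ genes_b)} genes not shared)"
        )
    aligned_b = M_b.loc[M_a.index]
    carriers = (M_a.sum(axis=1) > 0) | (aligned_b.sum(axis=1) > 0)
    return M_a.loc[carriers], aligned_b.loc[carriers]


def intersect_gene_universe(
    A: pd.DataFrame, B: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Restrict two feature x sample matrices to their shared features, sorted."""
    common = sorted(set(A.index) & set(B.index))
    if not common:
        raise ValidationError("feature universes have empty intersection")
    return A.loc[common], B.loc[common]
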