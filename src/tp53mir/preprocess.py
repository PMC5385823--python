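"""Robustness re-analysis preprocessing.

Log2 harmonization (raw-intensity matrices are detected by a max > 50
signature and log2(x+1)-transformed), classic quantile normalization across
samples, k-means outlier removal on samples, dataset merging on the common
candidate genes, and per-gene Welch differential expression with
Benjamini-Hochberg adjustment.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from statsmodels.stats.multitest import multipletests

from .containers import ExpressionDataset, MergedMatrix
from .errors import DegenerateInputError, ParameterError
from .meta_microarray import welch_t

RAW_INTENSITY_MAX = 50.0  # log2 data essentially never exceeds this


def ensure_log2(matrix: pd.DataFrame) -> tuple[pd.DataFrame, bool]:
    """Return a log2-scale matrix, transforming when the raw signature fires."""
    values = matrix.to_numpy(float)
    if np.nanmax(values) <= RAW_INTENSITY_MAX:
        return matrix, False
    if (values < 0).any():
        raise ParameterError("ensure_log2: negative values under raw-intensity signature")
    return pd.DataFrame(np.log2(values + 1.0), index=matrix.index, columns=matrix.columns), True


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Classic quantile normalization: each column mapped onto the mean
    sorted profile; ties receive the mean of their would-be quantile values."""
    values = matrix.to_numpy(float)
    if np.isnan(values).any():
        raise ParameterError("quantile_normalize: missing values not supported")
    if values.shape[1] < 2:
        raise ParameterError("quantile_normalize: need >= 2 samples")
    n = values.shape[0]
    mean_sorted = np.sort(values, axis=0).mean(axis=1)
    ranks = stats.rankdata(values, axis=0)  # average ranks handle ties
    out = np.interp(ranks, np.arange(1, n + 1), mean_sorted)
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def kmeans_outlier_removal(
    matrix: pd.DataFrame,
    k: int = 2,
    min_cluster_frac: float = 0.1,
    seed: int = 0,
    classes: pd.Series | None = None,
) -> tuple[list[str], list[str], pd.Series]:
    """Cluster samples (columns) with k-means and drop small clusters.

    Clusters holding fewer than ``min_cluster_frac`` of the samples are
    declared outliers. Returns (kept, removed, cluster sizes). If ``classes``
    is given and removal empties a class, raises.
    """
    n_samples = matrix.shape[1]
    if n_samples <= k:
        raise ParameterError(f"kmeans_outlier_removal: need more than k={k} samples")
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    labels = km.fit_predict(matrix.to_numpy(float).T)
    sizes = pd.Series(labels).value_counts().sort_index()
    outlier_clusters = set(sizes.index[sizes < min_cluster_frac * n_samples])
    removed = [s for s, lab in zip(matrix.columns, labels) if lab in outlier_clusters]
    kept = [s for s in matrix.columns if s not in set(removed)]
    if classes is not None:
        kept_classes = set(classes.loc[kept])
        if set(classes.loc[list(matrix.columns)]) - kept_classes:
            raise DegenerateInputError(
                "kmeans_outlier_removal: removal emptied one sample class"
            )
    return kept, removed, sizes


def merge_datasets(
    datasets: list[ExpressionDataset], candidates: list[str]
) -> MergedMatrix:
    """Stack datasets column-wise on the candidate genes common to all."""
    if not datasets:
        raise ParameterError("merge_datasets: need >= 1 dataset")
    common = [g for g in candidates if all(g in ds.genes for ds in datasets)]
    if not common:
        raise ParameterError("merge_datasets: no candidate gene present in every dataset")
    blocks, samples, classes, origin = [], [], [], []
    for ds in datasets:
        idx = [ds.genes.index(g) for g in common]
        blocks.append(ds.values[idx, :])
        samples.extend(ds.samples)
        classes.extend(ds.classes)
        origin.extend([ds.name] * len(ds.samples))
    return MergedMatrix(
        genes=common,
        samples=samples,
        values=np.hstack(blocks),
        classes=np.asarray(classes, dtype=object),
        dataset_of_origin=np.asarray(origin, dtype=object),
    )


def differential_expression(merged: MergedMatrix) -> pd.DataFrame:
    """Per-gene Welch t, two-sided p and BH-adjusted p on the merged matrix.

    Degenerate genes (zero variance in both classes with differing means,
    etc.) yield NA rows carrying the reason instead of failing the run.
    """
    tumor = merged.values[:, merged.tumor_mask]
    normal = merged.values[:, ~merged.tumor_mask]
    if tumor.shape[1] < 2 or normal.shape[1] < 2:
        raise ParameterError("differential_expression: both classes need >= 2 samples")
    rows = []
    for i, gene in enumerate(merged.genes):
        try:
            t, df = welch_t(tumor[i], normal[i])
            p = 2.0 * stats.t.sf(abs(t), df)
            rows.append({"gene": gene, "t": t, "df": df, "p": p, "reason": ""})
        except DegenerateInputError as exc:
            rows.append(
                {"gene": gene, "t": np.nan, "df": np.nan, "p": np.nan, "reason": str(exc)}
            )
    table = pd.DataFrame(rows)
    ok = table.p.notna()
    table["p_adj"] = np.nan
    if ok.any():
        table.loc[ok, "p_adj"] = multipletests(table.loc[ok, "p"], method="fdr_bh")[1]
    return table[["gene", "t", "df", "p", "p_adj", "reason"]]


def preprocess_pipeline(
    datasets: list[ExpressionDataset],
    candidates: list[str],
    k: int = 2,
    min_cluster_frac: float = 0.1,
    seed: int = 0,
) -> tuple[MergedMatrix, pd.DataFrame, list[str]]:
    """log2-harmonize, merge, quantile-normalize, drop outliers, test.

    Returns the cleaned merged matrix, the DE table and the removed samples.
    """
    harmonized = []
    for ds in datasets:
        frame, flagged = ensure_log2(ds.to_frame())
        harmonized.append(
            ExpressionDataset(
                name=ds.name,
                genes=list(frame.index),
                samples=list(frame.columns),
                values=frame.to_numpy(float),
                classes=ds.classes,
                log2=True,
            )
        )
    merged = merge_datasets(harmonized, candidates)
    normalized = quantile_normalize(merged.to_frame())
    classes = pd.Series(merged.classes, index=merged.samples)
    kept, removed, _ = kmeans_outlier_removal(
        normalized, k=k, min_cluster_frac=min_cluster_frac, seed=seed, classes=classes
    )
    keep_mask = np.array([s in set(kept) for s in merged.samples])
    cleaned = MergedMatrix(
        genes=merged.genes,
        samples=[s for s in merged.samples if s in set(kept)],
        values=normalized.to_numpy()[:, keep_mask],
        classes=merged.classes[keep_mask],
        dataset_of_origin=merged.dataset_of_origin[keep_mask],
    )
    de = differential_expression(cleaned)
    return cleaned, de, removed
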