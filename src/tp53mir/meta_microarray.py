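"""Cross-dataset meta-analysis of two-class microarray statistics.

Per gene and dataset a Welch two-sample t (tumor minus normal) is computed,
mapped to a standard-normal z by the probability-integral transform
z = Phi^-1(F_t(t; df)), and combined across datasets with the unweighted
Stouffer statistic sum(z_i)/sqrt(k). Genes are ranked by |combined z| and
flagged against the two-sided 95% / 99% normal critical values (1.959964,
2.575829). Genes missing from a dataset contribute no term there (k counts
observed datasets only); a sample-size-weighted Stouffer variant is
available but off by default.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ExpressionDataset
from .errors import DegenerateInputError, ParameterError

CRITICAL = {0.95: stats.norm.ppf(0.975), 0.99: stats.norm.ppf(0.995)}


@dataclass
class MetaResult:
    """Per-gene meta-analysis table plus the genes skipped entirely."""

    table: pd.DataFrame  # gene, k_datasets, t_values, z_values, z_combined, rank, pass95, pass99
    skipped: list[str] = field(default_factory=list)


def welch_t(tumor_values, normal_values) -> tuple[float, float]:
    """Welch two-sample t (tumor - normal) with Welch-Satterthwaite df."""
    a = np.asarray(tumor_values, dtype=float)
    b = np.asarray(normal_values, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise DegenerateInputError("welch_t: each group needs >= 2 values")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise DegenerateInputError("welch_t: non-finite values")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            # identical constant groups: defined as no difference
            return 0.0, float(len(a) + len(b) - 2)
        raise DegenerateInputError("welch_t: zero variance in both groups")
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df)


def t_to_z(t: float, df: float) -> float:
    """Map a t statistic to the z with the same one-sided tail area."""
    if not np.isfinite(t):
        raise ParameterError("t_to_z: t must be finite")
    if df <= 0:
        raise ParameterError("t_to_z: df must be > 0")
    if t < 0:
        return -t_to_z(-t, df)
    # work in the upper tail for precision
    return float(stats.norm.isf(stats.t.sf(t, df)))


def combine_z(z_values) -> float:
    """Unweighted Stouffer combination sum(z)/sqrt(k)."""
    z = np.asarray(z_values, dtype=float)
    if z.size == 0:
        raise ParameterError("combine_z: empty z vector")
    if not np.isfinite(z).all():
        raise ParameterError("combine_z: non-finite z values")
    return float(z.sum() / np.sqrt(z.size))


def combine_z_weighted(z_values, weights) -> float:
    """Sample-size-weighted Stouffer: sum(w_i z_i)/sqrt(sum w_i^2)."""
    z = np.asarray(z_values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if z.size == 0 or w.size != z.size:
        raise ParameterError("combine_z_weighted: need matching non-empty z and weights")
    return float((w * z).sum() / np.sqrt((w**2).sum()))


def filter_ci(z_combined: float, level: float) -> bool:
    """Two-sided filter: |z| beyond the level's normal critical value."""
    if level not in CRITICAL:
        raise ParameterError(f"filter_ci: level must be one of {sorted(CRITICAL)}")
    return bool(abs(z_combined) > CRITICAL[level])


def meta_analyze(
    datasets: list[ExpressionDataset],
    candidates: list[str],
    weighted: bool = False,
    prescreen_per_dataset: bool = False,
) -> MetaResult:
    """Combine per-dataset Welch t -> z over every candidate gene.

    ``prescreen_per_dataset`` drops per-dataset z values inside the 95% band
    before combination (the stricter reading of a two-stage screen); off by
    default. Genes present in no dataset go to ``skipped``.
    """
    if not datasets:
        raise ParameterError("meta_analyze: need >= 1 dataset")
    rows = []
    skipped = []
    for gene in candidates:
        t_vals, z_vals, dfs, weights = [], [], [], []
        for ds in datasets:
            if gene not in ds.genes:
                continue
            gi = ds.genes.index(gene)
            tumor = ds.values[gi, ds.tumor_mask]
            normal = ds.values[gi, ~ds.tumor_mask]
            t, df = welch_t(tumor, normal)
            z = t_to_z(t, df)
            if prescreen_per_dataset and abs(z) <= CRITICAL[0.95]:
                continue
            t_vals.append(t)
            z_vals.append(z)
            dfs.append(df)
            weights.append(np.sqrt(len(tumor) + len(normal)))
        if not z_vals:
            skipped.append(gene)
            continue
        zc = combine_z_weighted(z_vals, weights) if weighted else combine_z(z_vals)
        rows.append(
            {
                "gene": gene,
                "k_datasets": len(z_vals),
                "t_values": ";".join(f"{t:.6g}" for t in t_vals),
                "z_values": ";".join(f"{z:.6g}" for z in z_vals),
                "z_combined": zc,
                "pass95": filter_ci(zc, 0.95),
                "pass99": filter_ci(zc, 0.99),
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "gene", "k_datasets", "t_values", "z_values", "z_combined", "pass95", "pass99",
        ],
    )
    if len(table):
        # rank by |combined z| descending, ties broken by gene id
        order = table.assign(absz=table.z_combined.abs()).sort_values(
            ["absz", "gene"], ascending=[False, True]
        ).index
        ranks = pd.Series(np.arange(1, len(table) + 1), index=order)
        table["rank"] = ranks.reindex(table.index).astype(int)
        table = table.sort_values("rank").reset_index(drop=True)
    else:
        table["rank"] = pd.Series(dtype=int)
    return MetaResult(table=table, skipped=skipped)
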