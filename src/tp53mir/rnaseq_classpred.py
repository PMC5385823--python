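"""RNA-seq two-class analysis: classifier composition table and NB test.

Counts are library-size normalized (counts per million). The classifier
composition table carries, per gene, a parametric p and t (Welch test on
log2(CPM + pseudocount)), the % of leave-one-out cross-validation folds in
which the gene entered the fold's classifier, per-class geometric means of
normalized intensities, and their ratio as the fold change (class 1 =
case/treated over class 2 = control/untreated), sorted ascending by t.

The negative binomial test models Var = mu + alpha * mu^2 with a per-gene
method-of-moments dispersion pooled across classes, and tests the log fold
change with a Wald statistic. P-values use a t reference with
df = n1 + n2 - 2 (a small-sample correction over the asymptotic normal);
q-values are Benjamini-Hochberg adjusted p.
"""
from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import CountDataset
from .errors import ParameterError

DISPERSION_FLOOR = 1e-8


def geometric_mean(values, pseudocount: float = 0.0) -> float:
    """exp(mean(log x)); a pseudocount option exists for counts with zeros."""
    x = np.asarray(values, dtype=float) + pseudocount
    if (x <= 0).any():
        raise ParameterError(
            "geometric_mean: non-positive values (use a pseudocount for zeros)"
        )
    return float(np.exp(np.mean(np.log(x))))


def fold_change(gm_class1: float, gm_class2: float) -> float:
    if gm_class2 <= 0:
        raise ParameterError("fold_change: class-2 geometric mean must be > 0")
    return gm_class1 / gm_class2


def _log_intensities(counts: CountDataset, pseudocount: float) -> np.ndarray:
    return np.log2(counts.cpm().to_numpy() + pseudocount)


def cv_support(
    counts: CountDataset,
    p_threshold: float = 0.001,
    pseudocount: float = 1.0,
) -> pd.Series:
    """% of LOO folds in which each gene passes the fold's selection test.

    Per fold (one sample held out) every gene gets a Welch test on the
    remaining samples' log2(CPM + pseudocount); selection = p < threshold.
    Folds that would empty a class are skipped with a warning.
    """
    case = counts.case_mask
    if case.sum() < 2 or (~case).sum() < 2:
        raise ParameterError("cv_support: both classes need >= 2 samples")
    log_x = _log_intensities(counts, pseudocount)
    n = len(counts.samples)
    selected = np.zeros(len(counts.genes), dtype=float)
    n_folds = 0
    for holdout in range(n):
        mask = np.ones(n, dtype=bool)
        mask[holdout] = False
        tr_case = case & mask
        tr_ctrl = (~case) & mask
        if tr_case.sum() < 2 or tr_ctrl.sum() < 2:
            warnings.warn(f"cv_support: fold {holdout} skipped (class too small)")
            continue
        with np.errstate(divide="ignore", invalid="ignore"):
            res = stats.ttest_ind(
                log_x[:, tr_case], log_x[:, tr_ctrl], axis=1, equal_var=False
            )
        p = np.where(np.isfinite(res.pvalue), res.pvalue, 1.0)
        selected += p < p_threshold
        n_folds += 1
    if n_folds == 0:
        raise ParameterError("cv_support: every fold emptied a class")
    return pd.Series(100.0 * selected / n_folds, index=counts.genes, name="cv_support")


def nb_test(counts: CountDataset) -> pd.DataFrame:
    """Per-gene NB Wald test on library-size-normalized counts.

    Returns gene, fold_change, statistic, p, q, significant (q < 0.05);
    all-zero genes give NA rows with a reason.
    """
    case = counts.case_mask
    n1, n2 = int(case.sum()), int((~case).sum())
    if n1 < 2 or n2 < 2:
        raise ParameterError("nb_test: both classes need >= 2 samples")
    norm = counts.cpm().to_numpy()
    x1, x2 = norm[:, case], norm[:, ~case]
    mu1, mu2 = x1.mean(axis=1), x2.mean(axis=1)
    v1, v2 = x1.var(axis=1, ddof=1), x2.var(axis=1, ddof=1)

    def mom_alpha(mu, v):
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(mu > 0, (v - mu) / mu**2, 0.0)

    # df-weighted pooling of the per-class moment estimates
    alpha = ((n1 - 1) * mom_alpha(mu1, v1) + (n2 - 1) * mom_alpha(mu2, v2)) / (
        n1 + n2 - 2
    )
    alpha = np.maximum(alpha, DISPERSION_FLOOR)

    rows = []
    df = n1 + n2 - 2
    for i, gene in enumerate(counts.genes):
        if mu1[i] <= 0 or mu2[i] <= 0:
            rows.append(
                {
                    "gene": gene, "fold_change": np.nan, "statistic": np.nan,
                    "p": np.nan, "reason": "zero mean in a class",
                }
            )
            continue
        lfc = np.log(mu1[i] / mu2[i])
        # delta method: Var(log mean_c) = (mu + alpha mu^2) / (n mu^2)
        var_lfc = (mu1[i] + alpha[i] * mu1[i] ** 2) / (n1 * mu1[i] ** 2) + (
            mu2[i] + alpha[i] * mu2[i] ** 2
        ) / (n2 * mu2[i] ** 2)
        w = lfc / np.sqrt(var_lfc)
        p = 2.0 * stats.t.sf(abs(w), df)
        rows.append(
            {
                "gene": gene,
                "fold_change": float(mu1[i] / mu2[i]),
                "statistic": float(w),
                "p": float(p),
                "reason": "",
            }
        )
    table = pd.DataFrame(rows)
    ok = table.p.notna()
    table["q"] = np.nan
    if ok.any():
        table.loc[ok, "q"] = multipletests(table.loc[ok, "p"], method="fdr_bh")[1]
    table["significant"] = table.q < 0.05
    return table[["gene", "fold_change", "statistic", "p", "q", "significant", "reason"]]


def _round_sig(x: float, sig: int = 2) -> float:
    if x == 0 or not np.isfinite(x):
        return x
    return float(np.round(x, -int(np.floor(np.log10(abs(x)))) + (sig - 1)))


def compose_table(
    counts: CountDataset,
    cv: pd.Series | None = None,
    pseudocount: float = 1.0,
    cv_threshold: float = 0.001,
) -> pd.DataFrame:
    """Assemble the classifier composition table, sorted ascending by t.

    Rounding follows the reporting convention: p to 2 significant figures,
    t to 3 decimals, geometric means and fold change to 2 decimals.
    """
    if cv is None:
        cv = cv_support(counts, p_threshold=cv_threshold, pseudocount=pseudocount)
    missing = set(counts.genes) ^ set(cv.index)
    if missing:
        raise ParameterError(
            f"compose_table: gene sets differ between counts and cv support: {sorted(missing)}"
        )
    norm = counts.cpm()
    case = counts.case_mask
    log_x = _log_intensities(counts, pseudocount)
    rows = []
    for i, gene in enumerate(counts.genes):
        x1 = norm.to_numpy()[i, case]
        x2 = norm.to_numpy()[i, ~case]
        pc = pseudocount if (min(x1.min(), x2.min()) <= 0) else 0.0
        gm1 = geometric_mean(x1, pseudocount=pc)
        gm2 = geometric_mean(x2, pseudocount=pc)
        res = stats.ttest_ind(log_x[i, case], log_x[i, ~case], equal_var=False)
        rows.append(
            {
                "gene": gene,
                "parametric_p": _round_sig(float(res.pvalue), 2),
                "t": round(float(res.statistic), 3),
                "cv_support": float(cv[gene]),
                "geomean_class1": round(gm1, 2),
                "geomean_class2": round(gm2, 2),
                "fold_change": round(fold_change(gm1, gm2), 2),
            }
        )
    table = pd.DataFrame(rows).sort_values(["t", "gene"]).reset_index(drop=True)
    return table
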