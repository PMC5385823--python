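"""Comparative threshold cycle (ddCt) relative quantification.

Livak assumptions: amplification efficiency 2 for target and reference.
dCt = Ct_target - Ct_reference per record; ddCt = dCt_sample -
dCt_calibrator; RQ = 2^(-ddCt). The calibrator is a pool of normal tissues
summarized by its mean dCt; per-gene summaries are geometric mean RQs.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ParameterError
from .rnaseq_classpred import geometric_mean


@dataclass(frozen=True)
class CtRecord:
    sample: str
    gene: str
    reference_gene: str
    ct_target: float
    ct_reference: float
    is_calibrator: bool = False

    def delta_ct(self) -> float:
        return self.ct_target - self.ct_reference


def delta_delta_ct(sample: CtRecord, calibrator: CtRecord) -> tuple[float, float]:
    """(ddCt, RQ) of a sample record against a calibrator record."""
    if sample.gene != calibrator.gene:
        raise ParameterError(
            f"delta_delta_ct: gene mismatch ({sample.gene!r} vs {calibrator.gene!r})"
        )
    if sample.reference_gene != calibrator.reference_gene:
        raise ParameterError("delta_delta_ct: reference gene mismatch")
    ddct = sample.delta_ct() - calibrator.delta_ct()
    return ddct, float(2.0 ** (-ddct))


def _records_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        df = pd.DataFrame([r.__dict__ for r in records])
    required = {"sample", "gene", "ct_target", "ct_reference", "is_calibrator"}
    missing = required - set(df.columns)
    if missing:
        raise ParameterError(f"qpcr records missing columns: {sorted(missing)}")
    if not np.isfinite(df[["ct_target", "ct_reference"]].to_numpy()).all():
        raise ParameterError("qpcr records: non-finite Ct values")
    df["delta_ct"] = df.ct_target - df.ct_reference
    return df


def summarize_relative_expression(records) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample RQ against the calibrator pool, plus a per-gene summary.

    The calibrator dCt is the mean dCt over the pool records of that gene;
    the per-gene summary is the geometric mean RQ over samples. Genes with
    no calibrator records are skipped with a warning.
    """
    df = _records_frame(records)
    pool = df[df.is_calibrator]
    if pool.empty:
        raise ParameterError("summarize_relative_expression: calibrator pool is empty")
    cal_dct = pool.groupby("gene")["delta_ct"].mean()
    per_sample_rows = []
    summary_rows = []
    for gene, sub in df[~df.is_calibrator].groupby("gene", sort=True):
        if gene not in cal_dct.index:
            warnings.warn(f"gene {gene!r} missing from calibrator pool; skipped")
            continue
        ddct = sub.delta_ct - cal_dct[gene]
        rq = 2.0 ** (-ddct)
        for (_, row), d, r in zip(sub.iterrows(), ddct, rq):
            per_sample_rows.append(
                {
                    "gene": gene, "sample": row["sample"], "delta_ct": row["delta_ct"],
                    "ddct": float(d), "rq": float(r),
                }
            )
        summary_rows.append({"gene": gene, "mean_rq": geometric_mean(rq), "n_samples": len(sub)})
    per_sample = pd.DataFrame(
        per_sample_rows, columns=["gene", "sample", "delta_ct", "ddct", "rq"]
    )
    summary = pd.DataFrame(summary_rows, columns=["gene", "mean_rq", "n_samples"])
    return per_sample, summary
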