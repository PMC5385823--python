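"""In-memory containers shared by the analysis stages.

Matrices are gene x sample throughout: rows are genes, columns are samples,
matching the on-disk TSV convention (first column = gene id, header = sample
ids).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ParameterError

TUMOR = "tumor"
NORMAL = "normal"
CASE = "case"
CONTROL = "control"


@dataclass
class ExpressionDataset:
    """One study's log2 intensity matrix with a two-class sample annotation."""

    name: str
    genes: list[str]
    samples: list[str]
    values: np.ndarray  # genes x samples, float
    classes: np.ndarray  # per sample, "tumor" / "normal"
    log2: bool = True

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.classes = np.asarray(self.classes, dtype=object)
        if self.values.shape != (len(self.genes), len(self.samples)):
            raise ParameterError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.genes)} genes x {len(self.samples)} samples"
            )
        if len(self.classes) != len(self.samples):
            raise ParameterError("classes: one label per sample required")
        bad = set(self.classes) - {TUMOR, NORMAL}
        if bad:
            raise ParameterError(f"classes: unknown labels {sorted(bad)}")
        if not ((self.classes == TUMOR).any() and (self.classes == NORMAL).any()):
            raise ParameterError("classes: both tumor and normal must be present")
        if len(set(self.genes)) != len(self.genes):
            raise ParameterError("genes: duplicate gene ids")

    @property
    def tumor_mask(self) -> np.ndarray:
        return self.classes == TUMOR

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genes, columns=self.samples)


@dataclass
class CountDataset:
    """Integer RNA-seq count matrix with a case/control annotation."""

    genes: list[str]
    samples: list[str]
    counts: np.ndarray  # genes x samples, non-negative int
    classes: np.ndarray  # per sample, "case" / "control"
    library_size: np.ndarray | None = None  # per sample; column sums if None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if not np.issubdtype(self.counts.dtype, np.integer):
            if np.any(self.counts != np.floor(self.counts)):
                raise ParameterError("counts: non-integral values")
            self.counts = self.counts.astype(np.int64)
        if (self.counts < 0).any():
            raise ParameterError("counts: negative values")
        if self.counts.shape != (len(self.genes), len(self.samples)):
            raise ParameterError("counts shape does not match gene/sample ids")
        self.classes = np.asarray(self.classes, dtype=object)
        bad = set(self.classes) - {CASE, CONTROL}
        if bad:
            raise ParameterError(f"classes: unknown labels {sorted(bad)}")
        if not ((self.classes == CASE).any() and (self.classes == CONTROL).any()):
            raise ParameterError("classes: both case and control must be present")
        if self.library_size is None:
            self.library_size = self.counts.sum(axis=0).astype(float)
        else:
            self.library_size = np.asarray(self.library_size, dtype=float)
            if len(self.library_size) != len(self.samples):
                raise ParameterError("library_size: one value per sample required")

    @property
    def case_mask(self) -> np.ndarray:
        return self.classes == CASE

    def cpm(self) -> pd.DataFrame:
        """Counts per million, using the stored library sizes."""
        lib = np.where(self.library_size > 0, self.library_size, 1.0)
        return pd.DataFrame(
            self.counts * (1e6 / lib), index=self.genes, columns=self.samples
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.genes, columns=self.samples)


@dataclass
class MergedMatrix:
    """Datasets merged on their common candidate genes, ready for re-analysis."""

    genes: list[str]
    samples: list[str]
    values: np.ndarray
    classes: np.ndarray
    dataset_of_origin: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.classes = np.asarray(self.classes, dtype=object)
        if self.dataset_of_origin is None:
            self.dataset_of_origin = np.asarray(["merged"] * len(self.samples), dtype=object)
        else:
            self.dataset_of_origin = np.asarray(self.dataset_of_origin, dtype=object)
        if self.values.shape != (len(self.genes), len(self.samples)):
            raise ParameterError("values shape does not match gene/sample ids")

    @property
    def tumor_mask(self) -> np.ndarray:
        return self.classes == TUMOR

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genes, columns=self.samples)
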