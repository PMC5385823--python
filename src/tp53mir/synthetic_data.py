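"""Synthetic inputs with the statistical structure the analyses assume.

Every generator is seeded and deterministic, and each returns its ground
truth alongside the data so downstream tests never have to re-derive it.

Microarray intensities are generated directly on the log2 scale: per gene a
baseline level shared across datasets plus a per-dataset batch shift, a
class effect for planted genes, and i.i.d. Gaussian noise. Counts follow a
negative binomial with Var = mu + alpha * mu^2 (alpha = ``dispersion``).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import CASE, CONTROL, NORMAL, TUMOR, CountDataset, ExpressionDataset
from .errors import ParameterError

#: The six genes the study flagged as novel in HNSCC; used as the default
#: planted set so an end-to-end run reads naturally.
NOVEL_GENES = ["MEIS1", "LDOC1", "AGTR1", "BAK1", "TYMS", "DTL"]

_DECAMER_CLASSES = {
    "R": "AG",
    "W": "AT",
    "Y": "CT",
    "C": "C",
    "G": "G",
}
P53_DECAMER = "RRRCWWGYYY"


def default_gene_universe(n_genes: int = 90) -> list[str]:
    """Candidate pool: the six novel genes plus numbered filler targets."""
    if n_genes < len(NOVEL_GENES):
        raise ParameterError(f"n_genes: need at least {len(NOVEL_GENES)}")
    filler = [f"G{i:03d}" for i in range(n_genes - len(NOVEL_GENES))]
    return NOVEL_GENES + filler


@dataclass
class PlantedDesign:
    """Design of a multi-dataset two-class microarray collection.

    ``effect_log2`` is the magnitude of the planted log2 tumor-vs-normal
    shift; genes in ``planted_up`` receive +effect, ``planted_down``
    receives -effect, identical in sign across all datasets. ``baseline_sd``
    spreads per-gene baseline levels; ``batch_sd`` adds an independent
    per-gene per-dataset shift so cross-dataset combination is genuinely
    exercised.
    """

    n_genes: int = 90
    planted_up: list[str] = field(default_factory=lambda: ["BAK1", "DTL"])
    planted_down: list[str] = field(
        default_factory=lambda: ["MEIS1", "LDOC1", "AGTR1", "TYMS"]
    )
    effect_log2: float = 2.0
    n_datasets: int = 6
    samples_per_class: list[tuple[int, int]] = field(
        default_factory=lambda: [(7, 7), (7, 7), (7, 7), (7, 7), (6, 6), (6, 6)]
    )
    noise_sd: float = 1.0
    baseline_mean: float = 8.0
    baseline_sd: float = 1.5
    batch_sd: float = 0.5
    seed: int = 0
    genes: list[str] | None = None

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ParameterError("n_genes: must be positive")
        if self.genes is None:
            self.genes = default_gene_universe(self.n_genes)
        if len(self.genes) != self.n_genes:
            raise ParameterError("genes: length must equal n_genes")
        universe = set(self.genes)
        overlap = set(self.planted_up) & set(self.planted_down)
        if overlap:
            raise ParameterError(f"planted_up/planted_down: overlap {sorted(overlap)}")
        unknown = (set(self.planted_up) | set(self.planted_down)) - universe
        if unknown:
            raise ParameterError(f"planted genes outside universe: {sorted(unknown)}")
        if self.n_datasets < 1:
            raise ParameterError("n_datasets: must be >= 1")
        if len(self.samples_per_class) != self.n_datasets:
            raise ParameterError("samples_per_class: one (n_tumor, n_normal) per dataset")
        for i, (nt, nn) in enumerate(self.samples_per_class):
            if nt < 2 or nn < 2:
                raise ParameterError(
                    f"samples_per_class[{i}]: both counts must be >= 2, got {(nt, nn)}"
                )
        if self.noise_sd < 0:
            raise ParameterError("noise_sd: must be non-negative")

    def effects(self) -> pd.Series:
        eff = pd.Series(0.0, index=self.genes)
        eff[list(self.planted_up)] = abs(self.effect_log2)
        eff[list(self.planted_down)] = -abs(self.effect_log2)
        return eff


@dataclass
class CountDesign:
    """Design of a two-class negative binomial count matrix.

    ``dispersion`` is alpha in Var = mu + alpha * mu^2; the alpha -> 0 limit
    (Poisson) is supported but alpha = 0 exactly is rejected to keep the
    overdispersed model honest. ``planted_fc`` is the true case/control
    fold-change per gene (scalar broadcasts).
    """

    n_genes: int = 90
    n_cases: int = 22
    n_controls: int = 4
    baseline_mean: float | np.ndarray = 500.0
    dispersion: float | np.ndarray = 0.05
    planted_fc: float | dict[str, float] | np.ndarray = 1.0
    seed: int = 0
    genes: list[str] | None = None

    def __post_init__(self) -> None:
        if self.genes is None:
            self.genes = default_gene_universe(self.n_genes)
        if len(self.genes) != self.n_genes:
            raise ParameterError("genes: length must equal n_genes")
        if self.n_cases < 2 or self.n_controls < 2:
            raise ParameterError("n_cases/n_controls: both must be >= 2")
        self.baseline_mean = np.broadcast_to(
            np.asarray(self.baseline_mean, dtype=float), (self.n_genes,)
        ).copy()
        self.dispersion = np.broadcast_to(
            np.asarray(self.dispersion, dtype=float), (self.n_genes,)
        ).copy()
        if isinstance(self.planted_fc, dict):
            fc = np.ones(self.n_genes)
            idx = {g: i for i, g in enumerate(self.genes)}
            for g, v in self.planted_fc.items():
                if g not in idx:
                    raise ParameterError(f"planted_fc: unknown gene {g!r}")
                fc[idx[g]] = v
            self.planted_fc = fc
        else:
            self.planted_fc = np.broadcast_to(
                np.asarray(self.planted_fc, dtype=float), (self.n_genes,)
            ).copy()
        if (self.baseline_mean <= 0).any():
            raise ParameterError("baseline_mean: must be > 0")
        if (self.dispersion <= 0).any():
            raise ParameterError("dispersion: must be > 0 (Poisson limit unsupported)")
        if (self.planted_fc <= 0).any():
            raise ParameterError("planted_fc: must be > 0")


def gen_microarray_collection(design: PlantedDesign) -> list[ExpressionDataset]:
    """Generate ``design.n_datasets`` independent two-class log2 datasets.

    Ground truth (the per-gene planted effect) is available from
    ``design.effects()``.
    """
    rng = np.random.default_rng(design.seed)
    effects = design.effects().to_numpy()
    gene_base = design.baseline_mean + design.baseline_sd * rng.standard_normal(
        design.n_genes
    )
    datasets = []
    for d, (n_tumor, n_normal) in enumerate(design.samples_per_class):
        n = n_tumor + n_normal
        classes = np.array([TUMOR] * n_tumor + [NORMAL] * n_normal, dtype=object)
        batch = design.batch_sd * rng.standard_normal(design.n_genes)
        base = (gene_base + batch)[:, None]
        effect = effects[:, None] * (classes == TUMOR)[None, :]
        noise = design.noise_sd * rng.standard_normal((design.n_genes, n))
        samples = [f"D{d}_S{j:02d}" for j in range(n)]
        datasets.append(
            ExpressionDataset(
                name=f"synthetic_{d}",
                genes=list(design.genes),
                samples=samples,
                values=base + effect + noise,
                classes=classes,
                log2=True,
            )
        )
    return datasets


def gen_count_matrix(design: CountDesign) -> tuple[CountDataset, pd.DataFrame]:
    """NB counts for ``n_cases`` cases and ``n_controls`` controls.

    Case-class mean is baseline * planted_fc; control mean is baseline.
    Returns the dataset and a ground-truth sidecar (baseline, dispersion,
    true fold-change per gene).
    """
    rng = np.random.default_rng(design.seed)
    n = design.n_cases + design.n_controls
    classes = np.array([CASE] * design.n_cases + [CONTROL] * design.n_controls, dtype=object)
    mu = np.where(
        (classes == CASE)[None, :],
        (design.baseline_mean * design.planted_fc)[:, None],
        design.baseline_mean[:, None],
    )
    alpha = design.dispersion[:, None]
    # numpy's NB(n, p): mean = n(1-p)/p -> n = 1/alpha, p = n/(n+mu)
    size = 1.0 / alpha
    p = size / (size + mu)
    counts = rng.negative_binomial(np.broadcast_to(size, mu.shape), p)
    samples = [f"T{j:02d}" for j in range(design.n_cases)] + [
        f"N{j:02d}" for j in range(design.n_controls)
    ]
    truth = pd.DataFrame(
        {
            "gene": design.genes,
            "baseline_mean": design.baseline_mean,
            "dispersion": design.dispersion,
            "true_fc": design.planted_fc,
        }
    )
    return (
        CountDataset(genes=list(design.genes), samples=samples, counts=counts, classes=classes),
        truth,
    )


def _random_decamer(rng: np.random.Generator) -> str:
    return "".join(rng.choice(list(_DECAMER_CLASSES[c])) for c in P53_DECAMER)


def gen_promoters(
    n: int,
    length: int,
    planted_sites: list[tuple[int, int]],
    seed: int = 0,
    background: str | None = None,
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Random promoter sequences with tandem p53 half-site pairs planted.

    ``planted_sites`` lists (position of first decamer, spacer length); each
    site is planted in every sequence. ``background`` optionally fixes the
    background composition to a single base (useful for hit-free controls).
    Returns FASTA-ready (id, seq) pairs and the ground-truth site table.
    """
    rng = np.random.default_rng(seed)
    for pos, spacer in planted_sites:
        if not 0 <= spacer <= 13:
            raise ParameterError(f"spacer_len: must be in [0, 13], got {spacer}")
        if pos < 0 or pos + 20 + spacer > length:
            raise ParameterError(
                f"planted site at {pos} with spacer {spacer} does not fit in length {length}"
            )
    records = []
    truth_rows = []
    for i in range(n):
        name = f"promoter_{i}"
        if background is not None:
            seq = list(background * length)
        else:
            seq = list(rng.choice(list("ACGT"), size=length))
        for pos, spacer in planted_sites:
            first = _random_decamer(rng)
            second = _random_decamer(rng)
            seq[pos : pos + 10] = first
            seq[pos + 10 + spacer : pos + 20 + spacer] = second
            truth_rows.append(
                {
                    "seq_id": name,
                    "first_start": pos,
                    "second_start": pos + 10 + spacer,
                    "spacer": spacer,
                }
            )
        records.append((name, "".join(seq)))
    truth = pd.DataFrame(truth_rows, columns=["seq_id", "first_start", "second_start", "spacer"])
    return records, truth


def gen_qpcr_table(
    genes: list[str],
    true_rq: dict[str, float] | float,
    ct_noise_sd: float = 0.0,
    seed: int = 0,
    n_samples: int = 3,
    n_calibrators: int = 3,
    reference_gene: str = "B2M",
) -> pd.DataFrame:
    """Ct table (sample, gene, ct_target, ct_reference, is_calibrator).

    Calibrator records mimic a pool of normal tissues; sample records carry
    a target Ct lowered by log2(true_rq) relative to the calibrator so the
    comparative-Ct estimate recovers true_rq up to ``ct_noise_sd`` noise.
    """
    if isinstance(true_rq, dict):
        rq_map = dict(true_rq)
    else:
        rq_map = {g: float(true_rq) for g in genes}
    for g in genes:
        if g not in rq_map:
            raise ParameterError(f"true_rq: missing gene {g!r}")
        if rq_map[g] <= 0:
            raise ParameterError(f"true_rq[{g!r}]: must be > 0")
    if ct_noise_sd < 0:
        raise ParameterError("ct_noise_sd: must be non-negative")
    rng = np.random.default_rng(seed)
    base_ct_target = 30.0
    base_ct_ref = 20.0
    rows = []
    for g in genes:
        for j in range(n_calibrators):
            rows.append(
                {
                    "sample": f"pool_{j}",
                    "gene": g,
                    "reference_gene": reference_gene,
                    "ct_target": base_ct_target + ct_noise_sd * rng.standard_normal(),
                    "ct_reference": base_ct_ref + ct_noise_sd * rng.standard_normal(),
                    "is_calibrator": True,
                }
            )
        for j in range(n_samples):
            rows.append(
                {
                    "sample": f"sample_{j}",
                    "gene": g,
                    "reference_gene": reference_gene,
                    "ct_target": base_ct_target
                    - np.log2(rq_map[g])
                    + ct_noise_sd * rng.standard_normal(),
                    "ct_reference": base_ct_ref + ct_noise_sd * rng.standard_normal(),
                    "is_calibrator": False,
                }
            )
    return pd.DataFrame(rows)


def default_design(seed: int = 42) -> PlantedDesign:
    """The default study-scale collection: 90 candidates, 6 planted genes at
    |log2 effect| = 2, noise sd 1, six datasets totalling 40 tumor + 40
    normal samples."""
    return PlantedDesign(seed=seed)
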