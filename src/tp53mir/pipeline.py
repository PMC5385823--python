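"""End-to-end orchestration of the discovery workflow.

Stage order: signed-network propagation -> input generation (or loading) ->
microarray meta-analysis -> preprocessing / merged differential expression ->
SVM-RFE stability selection -> RNA-seq class prediction + NB test -> qPCR
relative quantification -> cross-stage concordance for the novel gene set.
All randomness flows from the single config seed, every stage writes plain
TSV under its own subdirectory, and the report records resolved parameters
so a run is reproducible byte-for-byte.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io, meta_microarray, network_model, preprocess, qpcr, rnaseq_classpred
from . import stability_selection, synthetic_data
from .errors import ParameterError

DEFAULT_OVERRIDES = [
    ["miR-125b", "down", "AKT1 represses miR-125b when TP53 is lost"],
]


@dataclass
class RunConfig:
    seed: int = 42
    out_dir: str = "out"
    network_edges: str | None = None  # packaged curated network when None
    clamp: dict = field(default_factory=lambda: {"TP53": "down"})
    overrides: list = field(default_factory=lambda: [list(o) for o in DEFAULT_OVERRIDES])
    novel_genes: list = field(default_factory=lambda: list(synthetic_data.NOVEL_GENES))
    microarray: dict = field(default_factory=dict)  # PlantedDesign overrides
    counts: dict = field(default_factory=dict)  # CountDesign overrides
    qpcr_true_rq: dict = field(default_factory=dict)  # gene -> RQ; derived if empty
    qpcr_ct_noise_sd: float = 0.25
    meta_weighted: bool = False
    meta_prescreen: bool = False
    kmeans_k: int = 2
    min_cluster_frac: float = 0.1
    stability_enabled: bool = True
    n_repeats: int = 100
    n_features: int = 20
    train_frac: float = 1 / 3
    cv_threshold: float = 0.001
    pseudocount: float = 1.0
    q_threshold: float = 0.05

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ParameterError(f"config: unknown keys {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        if self.network_edges is not None and not Path(self.network_edges).exists():
            raise ParameterError(f"config: network_edges path {self.network_edges!r} missing")
        if not isinstance(self.seed, (int, np.integer)):
            raise ParameterError("config: seed must be an integer")
        if self.n_features < 1 or self.n_repeats < 1:
            raise ParameterError("config: n_features and n_repeats must be >= 1")


@dataclass
class RunReport:
    config: RunConfig
    node_states: dict
    meta_pass95: list[str]
    removed_samples: list[str]
    set_abundance: float | None
    accuracies: list[float]
    nb_significant: list[str]
    concordance: pd.DataFrame
    out_dir: str


def _direction_of(value: float, tol: float = 1e-12) -> str:
    if not np.isfinite(value):
        return "unknown"
    if value > tol:
        return "up"
    if value < -tol:
        return "down"
    return "unchanged"


def run_all(config: RunConfig) -> RunReport:
    config.validate()
    out = Path(config.out_dir)
    for sub in ["network", "inputs", "meta", "prep", "stabsel", "rnaseq", "qpcr", "report"]:
        (out / sub).mkdir(parents=True, exist_ok=True)

    # --- network stage ---------------------------------------------------
    if config.network_edges:
        net = network_model.load_edges(config.network_edges)
    else:
        net = network_model.bundled_network("tp53_normal")
    overrides = [tuple(o) for o in config.overrides]
    state = network_model.propagate(net, dict(config.clamp), overrides)
    pd.DataFrame(
        sorted(state.directions.items()), columns=["node", "direction"]
    ).to_csv(out / "network" / "node_states.tsv", sep="\t", index=False)

    # --- synthetic inputs -------------------------------------------------
    ma_design = synthetic_data.PlantedDesign(seed=config.seed, **config.microarray)
    datasets = synthetic_data.gen_microarray_collection(ma_design)
    effects = ma_design.effects()
    io.write_matrix(
        effects.rename("effect_log2").to_frame(), out / "inputs" / "ground_truth_microarray.tsv"
    )
    for ds in datasets:
        io.write_matrix(ds.to_frame(), out / "inputs" / f"{ds.name}.tsv")
        io.write_classes(ds.samples, ds.classes, out / "inputs" / f"{ds.name}_classes.tsv")

    counts_kwargs = dict(config.counts)
    if "planted_fc" not in counts_kwargs:
        fc = {g: 4.0 for g in ma_design.planted_up}
        fc.update({g: 0.25 for g in ma_design.planted_down})
        counts_kwargs["planted_fc"] = fc
    count_design = synthetic_data.CountDesign(seed=config.seed + 1, **counts_kwargs)
    counts, count_truth = synthetic_data.gen_count_matrix(count_design)
    io.write_matrix(counts.to_frame(), out / "inputs" / "counts.tsv")
    io.write_classes(counts.samples, counts.classes, out / "inputs" / "counts_classes.tsv")
    io.write_table(count_truth, out / "inputs" / "ground_truth_counts.tsv")

    rq = dict(config.qpcr_true_rq)
    if not rq:
        rq = {g: 4.0 for g in ma_design.planted_up}
        rq.update({g: 0.25 for g in ma_design.planted_down})
    qpcr_table = synthetic_data.gen_qpcr_table(
        genes=sorted(rq),
        true_rq=rq,
        ct_noise_sd=config.qpcr_ct_noise_sd,
        seed=config.seed + 2,
    )
    qpcr_table.to_csv(out / "inputs" / "qpcr_ct.csv", index=False, lineterminator="\n")

    # --- microarray meta-analysis ----------------------------------------
    candidates = list(ma_design.genes)
    meta = meta_microarray.meta_analyze(
        datasets, candidates,
        weighted=config.meta_weighted, prescreen_per_dataset=config.meta_prescreen,
    )
    io.write_table(meta.table, out / "meta" / "meta_result.tsv")
    pass95 = sorted(meta.table.gene[meta.table.pass95])

    # --- preprocessing + merged DE ----------------------------------------
    cleaned, de, removed = preprocess.preprocess_pipeline(
        datasets, candidates,
        k=config.kmeans_k, min_cluster_frac=config.min_cluster_frac, seed=config.seed,
    )
    io.write_matrix(cleaned.to_frame(), out / "prep" / "merged_normalized.tsv")
    io.write_table(de, out / "prep" / "differential_expression.tsv")
    io.write_table(
        pd.DataFrame({"sample": removed}), out / "prep" / "removed_samples.tsv"
    )

    # --- stability selection ----------------------------------------------
    run = None
    if config.stability_enabled:
        run = stability_selection.run_selection(
            cleaned,
            novel_set=config.novel_genes,
            n_repeats=config.n_repeats,
            n_features=config.n_features,
            train_frac=config.train_frac,
            base_seed=config.seed,
        )
        io.write_table(
            pd.DataFrame(
                {
                    "seed": [r.seed for r in run.repeats],
                    "accuracy": [r.accuracy for r in run.repeats],
                    "balanced_accuracy": [r.balanced_accuracy for r in run.repeats],
                    "selected": [";".join(r.selected) for r in run.repeats],
                    "failed": [r.failed for r in run.repeats],
                }
            ),
            out / "stabsel" / "repeats.tsv",
        )
        io.write_table(
            run.abundance.rename("abundance").rename_axis("gene").reset_index(),
            out / "stabsel" / "abundance.tsv",
        )

    # --- RNA-seq class prediction + NB test -------------------------------
    cv = rnaseq_classpred.cv_support(
        counts, p_threshold=config.cv_threshold, pseudocount=config.pseudocount
    )
    classifier = rnaseq_classpred.compose_table(counts, cv, pseudocount=config.pseudocount)
    nb = rnaseq_classpred.nb_test(counts)
    io.write_table(classifier, out / "rnaseq" / "classifier_table.tsv")
    io.write_table(nb, out / "rnaseq" / "nb_test.tsv")
    nb_sig = sorted(nb.gene[nb.q < config.q_threshold])

    # --- qPCR --------------------------------------------------------------
    per_sample, qpcr_summary = qpcr.summarize_relative_expression(qpcr_table)
    io.write_table(per_sample, out / "qpcr" / "per_sample_rq.tsv")
    io.write_table(qpcr_summary, out / "qpcr" / "summary.tsv")

    # --- concordance across evidence streams ------------------------------
    de_by_gene = de.set_index("gene")
    nb_by_gene = nb.set_index("gene")
    rq_by_gene = qpcr_summary.set_index("gene")
    rows = []
    for gene in config.novel_genes:
        d_micro = (
            _direction_of(de_by_gene.t.get(gene, np.nan)) if gene in de_by_gene.index else "unknown"
        )
        d_rna = (
            _direction_of(np.log(nb_by_gene.fold_change.get(gene, np.nan)))
            if gene in nb_by_gene.index else "unknown"
        )
        d_qpcr = (
            _direction_of(np.log(rq_by_gene.mean_rq.get(gene, np.nan)))
            if gene in rq_by_gene.index else "unknown"
        )
        known = [d for d in (d_micro, d_rna, d_qpcr) if d not in ("unknown", "unchanged")]
        concordant = len(set(known)) <= 1
        rows.append(
            {
                "gene": gene,
                "network": state.directions.get(gene, "unknown"),
                "microarray": d_micro,
                "rnaseq": d_rna,
                "qpcr": d_qpcr,
                "concordant": concordant,
            }
        )
    concordance = pd.DataFrame(
        rows, columns=["gene", "network", "microarray", "rnaseq", "qpcr", "concordant"]
    )
    io.write_table(concordance, out / "report" / "concordance.tsv")

    report = RunReport(
        config=config,
        node_states=dict(state.directions),
        meta_pass95=pass95,
        removed_samples=removed,
        set_abundance=(run.set_abundance if run is not None else None),
        accuracies=(list(run.accuracies) if run is not None else []),
        nb_significant=nb_sig,
        concordance=concordance,
        out_dir=str(out),
    )
    summary = {
        "seed": config.seed,
        "meta_pass95": pass95,
        "novel_in_pass95": sorted(set(config.novel_genes) & set(pass95)),
        "removed_samples": removed,
        "set_abundance": report.set_abundance,
        "min_accuracy": (float(min(report.accuracies)) if report.accuracies else None),
        "nb_significant": nb_sig,
        "n_discordant": int((~concordance.concordant).sum()),
        "parameters": {
            f.name: getattr(config, f.name)
            for f in dataclasses.fields(RunConfig)
            if f.name not in ("qpcr_true_rq", "out_dir")
        },
    }
    with open(out / "report" / "run_report.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    return report
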