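"""End-to-end pipeline orchestration and configuration.

A :class:`PipelineConfig` bundles every stage parameter (thresholds,
seeds, k, epsilon, ridge, file paths) and validates its domain;
:func:`run_all` executes simulate -> differential expression -> rank
aggregation -> enrichment -> network/hub selection -> hub validation ->
diagnostic classifier, writing every table as TSV under a run directory
together with a manifest (parameters, package version, output checksums).
Reruns with the same configuration reproduce byte-identical tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .diagnostic import evaluate, fit_logistic, split_train_validation
from .diffexpr import differential_expression, significant_degs
from .enrichment import GeneSetCollection, enrich, read_gmt, write_gmt
from .network import centrality_table, hub_genes, load_edges, rra_top_genes, write_edges
from .preprocess import ExpressionStudy, read_expression, write_expression
from .rra import run_meta
from .synthetic import SimConfig, simulate_multistudy, simulate_network

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_all", "validate_hubs", "HubValidation"]


@dataclass
class PipelineConfig:
    """All stage parameters of one pipeline run."""

    # global
    seed: int = 0
    simulate: bool = True
    # simulation (used when simulate=True); one validation study is
    # generated on top of n_studies aggregation studies
    n_genes: int = 2000
    n_studies: int = 4
    cases_per_study: int = 10
    controls_per_study: int = 10
    frac_de: float = 0.05
    effect_lfc: float = 2.0
    frac_up: float = 0.5
    attenuation: float = 0.8
    noise_sd: float = 0.5
    platform_coverage: float = 0.9
    # differential expression
    p_thresh: float = 0.05
    lfc_thresh: float = 1.0
    equal_var: bool = False
    # rank aggregation
    alpha_robust: float = 0.05
    alpha_ppi: float = 0.01
    adjust: str = "bonferroni"
    ppi_use_adjusted: bool = False
    # enrichment
    min_term: int = 5
    max_term: int = 2000
    gmt_path: str | None = None
    # network
    score_threshold: float = 0.7
    top_k: int = 100
    epsilon: float = 1.7
    keep_prob: float = 0.5
    epc_realizations: int = 1000
    edge_prob: float = 0.02
    hub_boost: float = 0.3
    n_planted_hubs: int = 20
    edges_path: str | None = None
    # hub validation + diagnostic
    validate_alpha: float = 0.05
    train_frac: float = 0.6
    split_seed: int = 1234
    ridge: float = 1e-4
    cutoff: float = 0.5
    # file inputs (used when simulate=False)
    study_paths: list[dict] = field(default_factory=list)
    validation_matrix: str | None = None
    validation_annotation: str | None = None

    def validate(self) -> None:
        unit = {
            "frac_de": self.frac_de, "frac_up": self.frac_up,
            "p_thresh": self.p_thresh, "alpha_robust": self.alpha_robust,
            "alpha_ppi": self.alpha_ppi, "keep_prob": self.keep_prob,
            "edge_prob": self.edge_prob, "hub_boost": self.hub_boost,
            "train_frac": self.train_frac, "cutoff": self.cutoff,
            "validate_alpha": self.validate_alpha, "score_threshold": self.score_threshold,
        }
        for name, v in unit.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}: must be in [0, 1], got {v}")
        if self.adjust not in ("bonferroni", "bh"):
            raise ValueError(f"adjust: must be 'bonferroni' or 'bh', got {self.adjust!r}")
        if self.top_k < 1:
            raise ValueError(f"top_k: must be >= 1, got {self.top_k}")
        if self.ridge < 0:
            raise ValueError(f"ridge: must be >= 0, got {self.ridge}")
        if self.epc_realizations < 1:
            raise ValueError("epc_realizations: must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class HubValidation:
    """Per-hub-gene check in an independent validation cohort."""

    table: pd.DataFrame  # index gene_id; columns log2fc, p_value, significant
    missing: list[str]   # hub genes absent from the validation universe

    @property
    def significant_genes(self) -> list[str]:
        return list(self.table.index[self.table["significant"]])

    def to_tsv(self, path) -> None:
        out = self.table.copy()
        out.index.name = "gene_id"
        out.to_csv(path, sep="\t")
        if self.missing:
            with open(str(path) + ".skipped", "w", encoding="utf-8") as fh:
                fh.write("\n".join(self.missing) + "\n")


def validate_hubs(
    hubs, validation_study: ExpressionStudy, alpha: float = 0.05, equal_var: bool = False
) -> HubValidation:
    """Re-test each hub gene in an independent cohort (same test as DE stage).

    Hub genes absent from the validation universe are reported in
    ``missing``, not fatal unless none remain.
    """
    hubs = list(hubs)
    present = [g for g in hubs if g in validation_study.universe]
    missing = [g for g in hubs if g not in validation_study.universe]
    if not present:
        raise ValueError("no hub gene is present in the validation universe")
    de = differential_expression(validation_study, equal_var=equal_var)
    table = de.table.loc[present].copy()
    table["significant"] = table["p_value"] < alpha
    return HubValidation(table=table, missing=missing)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _load_input_studies(config: PipelineConfig):
    studies = []
    for entry in config.study_paths:
        studies.append(
            read_expression(entry["matrix"], entry["annotation"], entry.get("study_id"))
        )
    if len(studies) < 2:
        raise ValueError("need at least 2 aggregation studies (study_paths)")
    validation = None
    if config.validation_matrix:
        validation = read_expression(
            config.validation_matrix, config.validation_annotation, "validation"
        )
    return studies, None, validation


def _simulate_studies(config: PipelineConfig):
    sim = SimConfig(
        n_genes=config.n_genes,
        n_studies=config.n_studies + 1,  # last study is the validation cohort
        cases_per_study=config.cases_per_study,
        controls_per_study=config.controls_per_study,
        frac_de=config.frac_de,
        effect_lfc=config.effect_lfc,
        frac_up=config.frac_up,
        attenuation=config.attenuation,
        noise_sd=config.noise_sd,
        platform_coverage=config.platform_coverage,
        seed=config.seed,
    )
    all_studies, truth = simulate_multistudy(sim)
    validation = all_studies[-1]
    validation.study_id = "validation"
    return all_studies[:-1], truth, validation


def _synthetic_gene_sets(universe, truth, rng_seed: int, n_random_terms: int = 20):
    """Small GMT-style collection: the planted signal plus random terms."""
    import numpy as np

    rng = np.random.default_rng(rng_seed)
    universe = sorted(universe)
    terms = {}
    de_in_universe = [g for g in truth.de_genes if g in set(universe)]
    if len(de_in_universe) >= 2:
        terms["PLANTED_SIGNAL"] = ("planted differential genes", frozenset(de_in_universe))
    for i in range(n_random_terms):
        size = int(rng.integers(10, 60))
        members = rng.choice(len(universe), size=size, replace=False)
        terms[f"RANDOM_{i + 1:02d}"] = (
            f"random term {i + 1}",
            frozenset(universe[j] for j in members),
        )
    return GeneSetCollection(terms=terms, source="synthetic")


def run_all(config: PipelineConfig, outdir) -> dict:
    """Run every stage, writing TSV outputs and a manifest under ``outdir``.

    Returns the manifest dictionary.  On a stage failure a FAILED marker
    naming the stage is left in the run directory and the error propagates.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage = "setup"
    try:
        if config.simulate:
            stage = "simulate"
            logger.info("[simulate] generating %d+1 studies", config.n_studies)
            studies, truth, validation = _simulate_studies(config)
            for s in studies + [validation]:
                write_expression(s, outdir / f"{s.study_id}_matrix.tsv",
                                 outdir / f"{s.study_id}_annotation.tsv")
            truth.to_tsv(outdir / "truth.tsv")
        else:
            stage = "load"
            studies, truth, validation = _load_input_studies(config)

        stage = "diffexpr"
        de_counts = {}
        for s in studies:
            de = differential_expression(s, equal_var=config.equal_var)
            de.to_tsv(outdir / f"de_{s.study_id}.tsv")
            up, down = significant_degs(de, config.p_thresh, config.lfc_thresh)
            de_counts[s.study_id] = {"up": len(up), "down": len(down)}
            logger.info("[diffexpr] %s: %d up / %d down significant DEGs",
                        s.study_id, len(up), len(down))

        stage = "rra"
        up_res, down_res = run_meta(studies, adjust=config.adjust,
                                    equal_var=config.equal_var)
        up_res.to_tsv(outdir / "rra_up.tsv")
        down_res.to_tsv(outdir / "rra_down.tsv")
        robust_up = up_res.robust_genes(config.alpha_robust)
        robust_down = down_res.robust_genes(config.alpha_robust)
        logger.info("[rra] robust DEGs: %d up, %d down", len(robust_up), len(robust_down))
        with open(outdir / "robust_degs.txt", "w", encoding="utf-8") as fh:
            for g in robust_up:
                fh.write(f"{g}\tup\n")
            for g in robust_down:
                fh.write(f"{g}\tdown\n")
        universe = list(up_res.table.index)

        stage = "enrichment"
        collection = None
        if config.gmt_path:
            collection = read_gmt(config.gmt_path)
        elif config.simulate and truth is not None:
            collection = _synthetic_gene_sets(universe, truth, config.seed + 1)
            write_gmt(collection, outdir / "gene_sets.gmt")
        if collection is not None and (robust_up or robust_down):
            table = enrich(set(robust_up) | set(robust_down), collection,
                           universe, config.min_term, config.max_term)
            table.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
            logger.info("[enrichment] %d terms tested", len(table))

        stage = "network"
        ppi_input = sorted(
            set(up_res.ppi_genes(config.alpha_ppi, config.ppi_use_adjusted))
            | set(down_res.ppi_genes(config.alpha_ppi, config.ppi_use_adjusted))
        )
        rra_top = rra_top_genes(up_res, down_res, config.top_k)
        hubs: list[str] = []
        if config.edges_path:
            graph = load_edges(config.edges_path, config.score_threshold)
        elif config.simulate and ppi_input:
            planted = [g for g in rra_top if g in set(ppi_input)][: config.n_planted_hubs]
            graph = simulate_network(
                n_nodes=len(ppi_input),
                edge_prob=config.edge_prob,
                hub_boost=config.hub_boost,
                seed=config.seed + 2,
                node_ids=ppi_input,
                hub_ids=planted,
            )
            write_edges(graph, outdir / "ppi_edges.tsv")
        else:
            graph = None
        if graph is not None and graph.number_of_nodes() > 0:
            cent = centrality_table(
                graph, epsilon=config.epsilon,
                n_realizations=config.epc_realizations,
                keep_prob=config.keep_prob, seed=config.seed + 3,
            )
            cent.to_csv(outdir / "centrality.tsv", sep="\t")
            hubs = hub_genes(cent, rra_top, config.top_k)
            logger.info("[network] %d nodes, %d edges, %d hub genes",
                        graph.number_of_nodes(), graph.number_of_edges(), len(hubs))
            with open(outdir / "hub_genes.txt", "w", encoding="utf-8") as fh:
                fh.write("\n".join(hubs) + ("\n" if hubs else ""))

        report = None
        if validation is not None and hubs:
            stage = "validate"
            hv = validate_hubs(hubs, validation, config.validate_alpha,
                               equal_var=config.equal_var)
            hv.to_tsv(outdir / "hub_validation.tsv")
            panel = hv.significant_genes
            logger.info("[validate] %d/%d hub genes significant in validation cohort",
                        len(panel), len(hubs))

            if panel:
                stage = "classify"
                samples = list(validation.matrix.columns)
                train, valid = split_train_validation(
                    samples, validation.groups, config.train_frac, config.split_seed
                )
                model = fit_logistic(
                    validation.matrix.loc[panel, train],
                    validation.groups, ridge=config.ridge,
                )
                model.to_json(outdir / "classifier.json")
                report = evaluate(
                    model, validation.matrix.loc[panel, valid],
                    validation.groups, cutoff=config.cutoff,
                )
                report.to_tsv(outdir / "classifier_report.tsv")
                logger.info("[classify] accuracy %.3f sensitivity %.3f "
                            "specificity %.3f AUC %.3f",
                            report.accuracy, report.sensitivity,
                            report.specificity, report.auc)

        stage = "manifest"
        outputs = sorted(
            p.name for p in outdir.iterdir()
            if p.is_file() and p.name not in ("manifest.json", "FAILED")
        )
        manifest = {
            "package": "rankmeta",
            "version": __version__,
            "config": config.to_dict(),
            "de_counts": de_counts,
            "n_robust_up": len(robust_up),
            "n_robust_down": len(robust_down),
            "n_hub_genes": len(hubs),
            "outputs": {name: _sha256(outdir / name) for name in outputs},
        }
        if report is not None:
            manifest["classifier"] = {
                "accuracy": report.accuracy,
                "sensitivity": report.sensitivity,
                "specificity": report.specificity,
                "auc": report.auc,
            }
        with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")
        failed = outdir / "FAILED"
        if failed.exists():
            failed.unlink()
        return manifest
    except Exception as err:
        (outdir / "FAILED").write_text(f"{stage}: {err}\n", encoding="utf-8")
        raise
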