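"""End-to-end orchestration: classify -> enrich per cohort -> label ->
contribution -> network -> report.

All randomness lives in the synthetic generator; the analysis stages are
seed-free and deterministic, so two runs on identical inputs write
byte-identical summaries.  Stage failures are re-raised as
:class:`~laminadiv.errors.PipelineError` naming the stage.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd

from . import contribution as contrib
from . import divergence, enrichment, laminaspec, network
from .errors import ConfigurationError, LaminadivError, PipelineError
from .io import (
    DEGTable,
    GeneAnnotation,
    GeneSetCollection,
    read_annotation,
    read_deg_table,
    read_edge_list,
    read_gmt,
    read_term_graph,
)
from .synthetic import (
    SyntheticConfig,
    SyntheticTruth,
    generate_annotation,
    generate_genesets,
    generate_network,
    generate_paired_tables,
    generate_term_graph,
)

logger = logging.getLogger(__name__)

DEFAULT_KEYWORD_MAP = {
    "synap": "activity",
    "ion transport": "neurotransmitter, ion and receptor",
    "receptor": "neurotransmitter, ion and receptor",
    "autophag": "autophagy",
    "metabol": "metabolism",
    "mitochondri": "metabolism",
    "rna": "RNA",
    "axon": "axonal and dendritic",
    "dendri": "axonal and dendritic",
    "immune": "immune",
    "cytoskelet": "development",
}


@dataclass
class RunConfig:
    """Inputs and fixed settings for one pipeline run.

    Either all five input paths are given, or ``synthetic`` is set and the
    inputs are generated in memory.  Defaults carry the study's fixed
    settings: gene-level alpha 0.05, LFC bin width 0.25, PPI confidence
    cutoff 0.4, top-39 hubs.
    """

    deg_a_path: str | None = None
    deg_b_path: str | None = None
    gmt_path: str | None = None
    annotation_path: str | None = None
    edge_list_path: str | None = None
    term_graph_path: str | None = None
    synthetic: SyntheticConfig | None = None

    alpha: float = 0.05
    pathway_significance: str = "raw"  # "raw" or "adjusted" (BH)
    lfc_bin_width: float = 0.25
    string_cutoff: float = 0.4
    hub_top_k: int | None = 39
    hub_min_degree: int | None = None
    keyword_map: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_KEYWORD_MAP))
    focus_chromosome: str = "21"
    strict_ls: bool = False
    out_dir: str | None = None

    def validate(self) -> None:
        if self.synthetic is None:
            required = {
                "deg_a_path": self.deg_a_path,
                "deg_b_path": self.deg_b_path,
                "gmt_path": self.gmt_path,
            }
            missing = [k for k, v in required.items() if v is None]
            if missing:
                raise ConfigurationError(
                    f"missing input path(s) {missing} and no synthetic config"
                )
            for key in (
                "deg_a_path",
                "deg_b_path",
                "gmt_path",
                "annotation_path",
                "edge_list_path",
                "term_graph_path",
            ):
                val = getattr(self, key)
                if val is not None and not Path(val).exists():
                    raise ConfigurationError(f"{key} does not exist: {val}")
        if not 0 < self.alpha < 1:
            raise ConfigurationError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.lfc_bin_width <= 0:
            raise ConfigurationError("lfc_bin_width must be > 0")
        if not 0 <= self.string_cutoff <= 1:
            raise ConfigurationError("string_cutoff must be in [0, 1]")


@dataclass
class PipelineInputs:
    table_a: DEGTable
    table_b: DEGTable
    sets: GeneSetCollection
    annotation: GeneAnnotation | None = None
    edges: nx.Graph | None = None
    term_graph: nx.DiGraph | None = None
    truth: SyntheticTruth | None = None


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except (LaminadivError, OSError) as err:
                raise PipelineError(name, err) from err

        return wrapper

    return deco


@_stage("ingest")
def load_inputs(config: RunConfig) -> PipelineInputs:
    if config.synthetic is not None:
        table_a, table_b, truth = generate_paired_tables(config.synthetic)
        sets = generate_genesets(config.synthetic, truth)
        return PipelineInputs(
            table_a=table_a,
            table_b=table_b,
            sets=sets,
            annotation=generate_annotation(config.synthetic, truth),
            edges=generate_network(config.synthetic, truth),
            term_graph=generate_term_graph(config.synthetic, sets),
            truth=truth,
        )
    return PipelineInputs(
        table_a=read_deg_table(config.deg_a_path, "A"),
        table_b=read_deg_table(config.deg_b_path, "B"),
        sets=read_gmt(config.gmt_path),
        annotation=(
            read_annotation(config.annotation_path) if config.annotation_path else None
        ),
        edges=(
            read_edge_list(config.edge_list_path) if config.edge_list_path else None
        ),
        term_graph=(
            read_term_graph(config.term_graph_path) if config.term_graph_path else None
        ),
    )


def cohort_queries(
    classified: pd.DataFrame, alpha: float
) -> dict[str, set[str]]:
    """The five gene cohorts: each lamina's uDEGs, each lamina's full DEG
    list, and the convergent genes."""
    return {
        "a_unique": divergence.udeg_set(classified, "a"),
        "b_unique": divergence.udeg_set(classified, "b"),
        "a_all": divergence.significant_set(classified, "a", alpha),
        "b_all": divergence.significant_set(classified, "b", alpha),
        "convergent": set(
            classified.loc[
                classified["category"].isin(
                    ["convergent_up", "convergent_down", "convergent_flat"]
                ),
                "gene_id",
            ]
        ),
    }


def _directions(classified: pd.DataFrame, lamina: str) -> dict[str, int]:
    col = f"lfc_{lamina}"
    sub = classified[["gene_id", col]].dropna()
    signs = sub[col].apply(lambda v: 1 if v > 0 else (-1 if v < 0 else 0))
    return {g: int(s) for g, s in zip(sub["gene_id"], signs) if s != 0}


@_stage("enrich")
def enrich_cohorts(
    classified: pd.DataFrame,
    inputs: PipelineInputs,
    config: RunConfig,
) -> dict[str, pd.DataFrame]:
    queries = cohort_queries(classified, config.alpha)
    genes_a, genes_b = inputs.table_a.genes, inputs.table_b.genes
    universes = {
        "a_unique": genes_a,
        "a_all": genes_a,
        "b_unique": genes_b,
        "b_all": genes_b,
        "convergent": genes_a | genes_b,
    }
    dir_a = _directions(classified, "a")
    dir_b = _directions(classified, "b")
    directions = {
        "a_unique": dir_a,
        "a_all": dir_a,
        "b_unique": dir_b,
        "b_all": dir_b,
        "convergent": dir_a,  # convergent genes share the sign in both laminae
    }
    return {
        cohort: enrichment.enrich_sets(
            queries[cohort],
            universes[cohort],
            inputs.sets,
            directions[cohort],
            alpha=config.alpha,
            cohort_label=cohort,
            significance="adjusted" if config.pathway_significance == "adjusted" else "raw",
        )
        for cohort in laminaspec.COHORTS
    }


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis and return the machine-readable report.

    With ``config.out_dir`` set, every stage's table is written as TSV and
    the report as ``summary.json`` (sorted keys, so reruns are
    byte-identical)."""
    config.validate()
    inputs = load_inputs(config)

    try:
        classified = divergence.classify_genes(
            inputs.table_a, inputs.table_b, alpha=config.alpha
        )
        bins_a = divergence.bin_by_lfc(classified, "a", config.lfc_bin_width)
        bins_b = divergence.bin_by_lfc(classified, "b", config.lfc_bin_width)
    except LaminadivError as err:
        raise PipelineError("classify", err) from err

    results = enrich_cohorts(classified, inputs, config)

    try:
        flag_matrix = laminaspec.build_flag_matrix(
            results,
            alpha=config.alpha,
            significance=config.pathway_significance,
        )
        labels = laminaspec.label_terms(flag_matrix, strict=config.strict_ls)
        categories = laminaspec.filter_terms_by_keyword(
            inputs.sets.names(), config.keyword_map
        )
    except LaminadivError as err:
        raise PipelineError("label", err) from err

    try:
        queries = cohort_queries(classified, config.alpha)
        contribution_out = {}
        for lamina in ("a", "b"):
            ls_terms = set(
                labels.loc[labels["label"] == f"{lamina}_layer_specific", "term_id"]
            )
            records = contrib.contribution_table(
                inputs.sets,
                queries[f"{lamina}_all"],
                queries[f"{lamina}_unique"],
                term_ids=ls_terms,
            )
            contribution_out[lamina] = {
                "records": records,
                "bins": contrib.summarize_bins(records) if len(records) else None,
                "categories": contrib.summarize_categories(records, categories)
                if len(records)
                else None,
            }
    except LaminadivError as err:
        raise PipelineError("contribute", err) from err

    network_out: dict[str, dict] = {}
    if inputs.edges is not None:
        try:
            for lamina in ("a", "b"):
                sub = network.induced_subnetwork(
                    inputs.edges, queries[f"{lamina}_unique"], config.string_cutoff
                )
                degrees = network.node_degrees(sub)
                hubs = network.select_hubs(
                    degrees,
                    top_k=config.hub_top_k,
                    min_degree=config.hub_min_degree,
                )
                network_out[lamina] = {
                    "degrees": degrees,
                    "hubs": hubs,
                    "n_edges": sub.number_of_edges(),
                    "n_nodes": sub.number_of_nodes(),
                }
        except LaminadivError as err:
            raise PipelineError("network", err) from err

    tally = None
    if inputs.annotation is not None:
        tally_a = divergence.subset_tally(
            queries["a_unique"], inputs.annotation, config.focus_chromosome
        )
        tally_b = divergence.subset_tally(
            queries["b_unique"], inputs.annotation, config.focus_chromosome
        )
        tally = {"a": tally_a, "b": tally_b}

    report = _build_report(
        classified, results, labels, contribution_out, network_out, tally, config
    )
    if config.out_dir:
        _write_outputs(
            Path(config.out_dir),
            classified,
            bins_a,
            bins_b,
            results,
            flag_matrix,
            labels,
            categories,
            contribution_out,
            network_out,
            report,
        )
    return report


def _build_report(classified, results, labels, contribution_out, network_out, tally, config):
    sig_terms = {
        cohort: int(df["significant"].sum()) for cohort, df in results.items()
    }
    label_counts = labels["label"].value_counts().to_dict()
    report = {
        "category_counts": divergence.category_counts(classified),
        "n_genes": int(len(classified)),
        "udeg_a": len(divergence.udeg_set(classified, "a")),
        "udeg_b": len(divergence.udeg_set(classified, "b")),
        "significant_terms_per_cohort": sig_terms,
        "label_counts": {k: int(v) for k, v in sorted(label_counts.items())},
        "contribution": {},
        "network": {},
        "settings": {
            "alpha": config.alpha,
            "pathway_significance": config.pathway_significance,
            "lfc_bin_width": config.lfc_bin_width,
            "string_cutoff": config.string_cutoff,
            "strict_ls": config.strict_ls,
        },
    }
    for lamina, out in contribution_out.items():
        entry = {"n_terms": int(len(out["records"]))}
        if out["bins"] is not None:
            entry["bin_shares_pct"] = {
                row["bin_label"]: round(row["share_pct"], 6)
                for _, row in out["bins"].iterrows()
            }
        report["contribution"][lamina] = entry
    for lamina, out in network_out.items():
        report["network"][lamina] = {
            "n_nodes": out["n_nodes"],
            "n_edges": out["n_edges"],
            "hubs": out["hubs"],
        }
    if tally is not None:
        report["focus_chromosome_tally"] = {
            lamina: {
                "n_total": t.n_total,
                "counts": t.counts,
                "fractions": t.fractions,
            }
            for lamina, t in tally.items()
        }
    return report


def _write_outputs(
    out_dir: Path,
    classified,
    bins_a,
    bins_b,
    results,
    flag_matrix,
    labels,
    categories,
    contribution_out,
    network_out,
    report,
) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    classified.to_csv(out_dir / "classified_genes.tsv", sep="\t", index=False)
    bins_a.to_csv(out_dir / "lfc_bins_a.tsv", sep="\t", index=False)
    bins_b.to_csv(out_dir / "lfc_bins_b.tsv", sep="\t", index=False)
    for cohort, df in results.items():
        df.to_csv(out_dir / f"enrichment_{cohort}.tsv", sep="\t", index=False)
    flag_matrix.to_csv(out_dir / "flag_matrix.tsv", sep="\t")
    labels.to_csv(out_dir / "term_labels.tsv", sep="\t", index=False)
    categories.to_csv(out_dir / "term_categories.tsv", sep="\t", index=False)
    for lamina, out in contribution_out.items():
        out["records"].to_csv(out_dir / f"contribution_{lamina}.tsv", sep="\t", index=False)
        if out["bins"] is not None:
            out["bins"].to_csv(out_dir / f"contribution_bins_{lamina}.tsv", sep="\t", index=False)
        if out["categories"] is not None:
            out["categories"].to_csv(
                out_dir / f"contribution_categories_{lamina}.tsv", sep="\t", index=False
            )
    for lamina, out in network_out.items():
        out["degrees"].to_csv(out_dir / f"degrees_{lamina}.tsv", sep="\t", index=False)
        pd.DataFrame({"gene_id": out["hubs"]}).to_csv(
            out_dir / f"hubs_{lamina}.tsv", sep="\t", index=False
        )
    with open(out_dir / "summary.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
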