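"""Synthetic paired-lamina DEG tables, gene sets, annotations and PPI
networks with known ground truth.

The generator emulates the downstream shape of a paired laser-capture
RNA-seq differential-expression study: two per-lamina DEG tables over a
shared tested-gene universe, where each gene is truly convergent (same
direction in both laminae), divergent (opposite directions), unique to one
lamina, or null.  Default class fractions mirror the motivating study's
proportions (roughly 16% of tested genes unique to lamina A, 11% unique to
B, 13% convergent, ~1% divergent) at a desk-scale universe of 2,000 genes.

P-values are drawn positionally rather than from a test statistic: the
pipeline consumes DE p-values, it does not produce them, so only their
position relative to alpha matters.  Truly significant genes draw
p ~ U(0, alpha * p_fraction) with p_fraction < 1; null calls draw
p ~ U(0, 1), so null genes cross alpha at about the alpha rate per lamina
and recovery tests bound rather than equate category counts.

Gene sets, a gene annotation (with a designated focus chromosome emulating
HSA21), a term DAG and an Erdős–Rényi PPI network with planted hubs are
generated against the same gene universe; all draws are keyed to the
mandatory integer seed and are reproducible across platforms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .io import (
    DEGTable,
    GeneAnnotation,
    GeneSet,
    GeneSetCollection,
    term_graph_from_edges,
    write_annotation,
    write_deg_table,
    write_edge_list,
    write_gmt,
    write_term_graph,
)

# stage constants mixed into the seed sequence so each generator stage has
# an independent, reproducible stream
_STAGE_TABLES, _STAGE_SETS, _STAGE_NETWORK, _STAGE_ANNOT, _STAGE_GRAPH = range(5)

TRUE_CLASSES = (
    "convergent_up",
    "convergent_down",
    "unique_a",
    "unique_b",
    "divergent",
    "null",
)

_SET_THEMES = (
    "synaptic transmission",
    "autophagosome assembly",
    "metabolic process",
    "rna processing",
    "ion transport",
    "immune response",
    "cytoskeleton organization",
    "mitochondrial respiration",
)


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic cohort.  ``seed`` is mandatory."""

    seed: int
    n_genes: int = 2000
    # true class fractions (must sum to 1)
    frac_convergent_up: float = 0.065
    frac_convergent_down: float = 0.065
    frac_unique_a: float = 0.16
    frac_unique_b: float = 0.11
    frac_divergent: float = 0.01
    frac_null: float = 0.59
    # p-value and LFC models
    alpha: float = 0.05
    p_fraction: float = 0.5
    lfc_mean: float = 0.7
    lfc_sd: float = 0.35
    null_lfc_sd: float = 0.15
    # gene sets
    n_background_sets: int = 200
    set_size_range: tuple[int, int] = (30, 80)
    n_planted_enriched: int = 5
    planted_set_size: int = 50
    planted_overlap_fraction: float = 0.6
    # PPI network
    net_n_nodes: int = 300
    net_edge_prob: float = 0.02
    n_planted_hubs: int = 5
    hub_degree_target: int = 60
    # annotation
    focus_chromosome: str = "21"
    n_focus_genes: int = 40

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ConfigurationError("seed is mandatory")
        fracs = self.fractions
        if any(f < 0 for f in fracs.values()):
            raise ConfigurationError("class fractions must be non-negative")
        total = sum(fracs.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ConfigurationError(f"class fractions sum to {total}, not 1")
        for name in ("n_genes", "n_background_sets", "net_n_nodes"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        lo, hi = self.set_size_range
        if not (0 < lo <= hi <= self.n_genes):
            raise ConfigurationError(f"invalid set_size_range {self.set_size_range}")
        if self.planted_set_size > self.n_genes:
            raise ConfigurationError("planted set size exceeds gene count")
        if self.hub_degree_target >= self.net_n_nodes:
            raise ConfigurationError("hub degree target must be < number of network nodes")
        if not 0 < self.alpha < 1 or not 0 < self.p_fraction < 1:
            raise ConfigurationError("alpha and p_fraction must be in (0, 1)")
        if not 0 <= self.planted_overlap_fraction <= 1:
            raise ConfigurationError("planted_overlap_fraction must be in [0, 1]")

    @property
    def fractions(self) -> dict[str, float]:
        return {
            "convergent_up": self.frac_convergent_up,
            "convergent_down": self.frac_convergent_down,
            "unique_a": self.frac_unique_a,
            "unique_b": self.frac_unique_b,
            "divergent": self.frac_divergent,
            "null": self.frac_null,
        }


@dataclass
class SyntheticTruth:
    """Planted ground truth the recovery tests assert against."""

    gene_class: pd.Series  # gene_id -> true class
    planted_set_ids: set[str] = field(default_factory=set)
    planted_hub_ids: set[str] = field(default_factory=set)

    def genes_of(self, *classes: str) -> set[str]:
        return set(self.gene_class.index[self.gene_class.isin(classes)])

    @property
    def udeg_a_true(self) -> set[str]:
        return self.genes_of("unique_a", "divergent")

    @property
    def udeg_b_true(self) -> set[str]:
        return self.genes_of("unique_b", "divergent")


def _rng(config: SyntheticConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([stage, config.seed])


def _sig_p(rng: np.random.Generator, config: SyntheticConfig, size: int) -> np.ndarray:
    # strictly positive, strictly below alpha * p_fraction
    return rng.uniform(1e-12, config.alpha * config.p_fraction, size)


def _magnitudes(rng: np.random.Generator, config: SyntheticConfig, size: int) -> np.ndarray:
    shape = (config.lfc_mean / config.lfc_sd) ** 2
    scale = config.lfc_sd**2 / config.lfc_mean
    return np.maximum(rng.gamma(shape, scale, size), 1e-6)


def generate_paired_tables(
    config: SyntheticConfig,
) -> tuple[DEGTable, DEGTable, SyntheticTruth]:
    """Draw the two per-lamina DEG tables and their ground truth.

    Deterministic given ``config.seed``; true classes are multinomial draws
    over the configured fractions, so realized marginals carry ordinary
    sampling error.
    """
    rng = _rng(config, _STAGE_TABLES)
    n = config.n_genes
    genes = np.array([f"G{i:06d}" for i in range(n)])
    fracs = config.fractions
    classes = rng.choice(TRUE_CLASSES, size=n, p=[fracs[c] for c in TRUE_CLASSES])

    lfc_a = rng.normal(0.0, config.null_lfc_sd, n)
    lfc_b = rng.normal(0.0, config.null_lfc_sd, n)
    p_a = rng.uniform(1e-12, 1.0, n)
    p_b = rng.uniform(1e-12, 1.0, n)

    def assign(mask: np.ndarray, lamina_sig_a: bool, lamina_sig_b: bool, sign_rule: str) -> None:
        m = int(mask.sum())
        if m == 0:
            return
        mag_a = _magnitudes(rng, config, m)
        mag_b = _magnitudes(rng, config, m)
        if sign_rule == "up":
            s_a = np.ones(m)
            s_b = np.ones(m)
        elif sign_rule == "down":
            s_a = -np.ones(m)
            s_b = -np.ones(m)
        elif sign_rule == "opposite":
            s_a = rng.choice([-1.0, 1.0], m)
            s_b = -s_a
        else:  # free: each lamina's sign independent
            s_a = rng.choice([-1.0, 1.0], m)
            s_b = rng.choice([-1.0, 1.0], m)
        if lamina_sig_a:
            lfc_a[mask] = s_a * mag_a
            p_a[mask] = _sig_p(rng, config, m)
        if lamina_sig_b:
            lfc_b[mask] = s_b * mag_b
            p_b[mask] = _sig_p(rng, config, m)

    assign(classes == "convergent_up", True, True, "up")
    assign(classes == "convergent_down", True, True, "down")
    assign(classes == "divergent", True, True, "opposite")
    assign(classes == "unique_a", True, False, "free")
    assign(classes == "unique_b", False, True, "free")

    table_a = DEGTable(
        lamina_label="A",
        data=pd.DataFrame({"gene_id": genes, "lfc": lfc_a, "p_value": p_a}),
    )
    table_b = DEGTable(
        lamina_label="B",
        data=pd.DataFrame({"gene_id": genes, "lfc": lfc_b, "p_value": p_b}),
    )
    truth = SyntheticTruth(gene_class=pd.Series(classes, index=genes, name="true_category"))
    return table_a, table_b, truth


def expected_classification_probs(config: SyntheticConfig) -> dict[str, float]:
    """Expected classified-category probabilities under the generator.

    Accounts for alpha-level misclassification: a truly unique or null gene
    crosses alpha in the other lamina with probability alpha, landing in
    divergent (opposite random sign, p 1/2) or a convergent class (p 1/4
    each).
    """
    a = config.alpha
    f = config.fractions
    probs = {
        "convergent_up": f["convergent_up"]
        + (f["unique_a"] + f["unique_b"]) * a * 0.25
        + f["null"] * a * a * 0.25,
        "convergent_down": f["convergent_down"]
        + (f["unique_a"] + f["unique_b"]) * a * 0.25
        + f["null"] * a * a * 0.25,
        "divergent": f["divergent"]
        + (f["unique_a"] + f["unique_b"]) * a * 0.5
        + f["null"] * a * a * 0.5,
        "unique_a": f["unique_a"] * (1 - a) + f["null"] * a * (1 - a),
        "unique_b": f["unique_b"] * (1 - a) + f["null"] * a * (1 - a),
        "not_significant": f["null"] * (1 - a) ** 2,
    }
    return probs


def generate_genesets(
    config: SyntheticConfig, truth: SyntheticTruth
) -> GeneSetCollection:
    """Background sets drawn uniformly plus planted sets biased into the
    lamina-A uDEG truth class by ``planted_overlap_fraction``."""
    rng = _rng(config, _STAGE_SETS)
    genes = np.array(sorted(truth.gene_class.index))
    pool = np.array(sorted(truth.udeg_a_true))
    others = np.array(sorted(set(genes) - set(pool)))
    coll = GeneSetCollection()
    for i in range(config.n_planted_enriched):
        n_from_pool = min(
            int(round(config.planted_set_size * config.planted_overlap_fraction)),
            len(pool),
        )
        n_rest = config.planted_set_size - n_from_pool
        members = np.concatenate(
            [
                rng.choice(pool, n_from_pool, replace=False),
                rng.choice(others, n_rest, replace=False),
            ]
        )
        theme = _SET_THEMES[i % len(_SET_THEMES)]
        set_id = f"PLANTED_{i + 1:02d}"
        coll.add(GeneSet(set_id=set_id, name=f"{theme} (planted {i + 1})", members=frozenset(members)))
        truth.planted_set_ids.add(set_id)
    lo, hi = config.set_size_range
    for i in range(config.n_background_sets):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(genes, size, replace=False)
        theme = _SET_THEMES[i % len(_SET_THEMES)]
        coll.add(
            GeneSet(
                set_id=f"BG_{i + 1:03d}",
                name=f"{theme} background {i + 1}",
                members=frozenset(members),
            )
        )
    return coll


def generate_network(config: SyntheticConfig, truth: SyntheticTruth) -> nx.Graph:
    """Erdős–Rényi background over uDEG-enriched nodes plus planted hubs
    wired up to the configured degree target.

    Hub edges carry confidence >= 0.6 so they survive the usual 0.4 STRING
    cutoff; background edges draw confidence ~ U(0.15, 1).
    """
    rng = _rng(config, _STAGE_NETWORK)
    pool = sorted(truth.udeg_a_true)
    if len(pool) < config.net_n_nodes:
        extra = sorted(set(truth.gene_class.index) - set(pool))
        pool = pool + extra[: config.net_n_nodes - len(pool)]
    nodes = [pool[i] for i in rng.choice(len(pool), config.net_n_nodes, replace=False)]

    graph = nx.Graph()
    graph.add_nodes_from(nodes)
    if config.net_edge_prob > 0:
        er = nx.fast_gnp_random_graph(
            config.net_n_nodes, config.net_edge_prob, seed=int(rng.integers(2**31))
        )
        for i, j in er.edges():
            graph.add_edge(nodes[i], nodes[j], confidence=float(rng.uniform(0.15, 1.0)))

    hubs = [nodes[i] for i in rng.choice(len(nodes), config.n_planted_hubs, replace=False)]
    for hub in hubs:
        truth.planted_hub_ids.add(hub)
        candidates = [n for n in nodes if n != hub and not graph.has_edge(hub, n)]
        need = config.hub_degree_target - graph.degree(hub)
        if need > 0:
            chosen = rng.choice(len(candidates), min(need, len(candidates)), replace=False)
            for idx in chosen:
                graph.add_edge(hub, candidates[idx], confidence=float(rng.uniform(0.6, 1.0)))
    return graph


def generate_annotation(config: SyntheticConfig, truth: SyntheticTruth) -> GeneAnnotation:
    """Chromosome and biotype assignments with a designated focus chromosome
    (emulating the triplicated chromosome) enriched for non-coding genes."""
    rng = _rng(config, _STAGE_ANNOT)
    genes = np.array(sorted(truth.gene_class.index))
    focus_idx = set(rng.choice(len(genes), min(config.n_focus_genes, len(genes)), replace=False).tolist())
    other_chroms = [str(c) for c in range(1, 23) if str(c) != config.focus_chromosome]
    biotypes = np.array(["protein_coding", "ncRNA", "rRNA", "other"])
    ann = GeneAnnotation()
    for i, g in enumerate(genes):
        if i in focus_idx:
            chrom = config.focus_chromosome
            bt = rng.choice(biotypes, p=[0.45, 0.40, 0.10, 0.05])
        else:
            chrom = other_chroms[int(rng.integers(len(other_chroms)))]
            bt = rng.choice(biotypes, p=[0.75, 0.17, 0.03, 0.05])
        ann.table[str(g)] = (chrom, str(bt))
    return ann


def generate_term_graph(config: SyntheticConfig, sets: GeneSetCollection) -> nx.DiGraph:
    """Random child -> parent DAG over the collection's term ids: each term
    may attach to one or two earlier terms, so edges always point from later
    to earlier ids and the graph is acyclic by construction."""
    rng = _rng(config, _STAGE_GRAPH)
    ids = [gs.set_id for gs in sets]
    edges: list[tuple[str, str]] = []
    graph_nodes = list(ids)
    for i in range(1, len(ids)):
        n_parents = int(rng.choice([0, 1, 2], p=[0.3, 0.5, 0.2]))
        if n_parents == 0:
            continue
        parents = rng.choice(i, min(n_parents, i), replace=False)
        for j in np.atleast_1d(parents):
            edges.append((ids[i], ids[int(j)]))
    graph = term_graph_from_edges(edges) if edges else nx.DiGraph()
    graph.add_nodes_from(graph_nodes)
    return graph


def write_fixtures(config: SyntheticConfig, out_dir: str | Path) -> dict[str, Path]:
    """Generate every fixture and write it in the formats the readers accept.

    Returns a name -> path map; also writes the ground truth (per-gene true
    class, planted set ids, planted hub ids) as plain text.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table_a, table_b, truth = generate_paired_tables(config)
    sets = generate_genesets(config, truth)
    graph = generate_network(config, truth)
    ann = generate_annotation(config, truth)
    terms = generate_term_graph(config, sets)

    paths = {
        "deg_a": out / "deg_a.tsv",
        "deg_b": out / "deg_b.tsv",
        "gene_sets": out / "gene_sets.gmt",
        "edges": out / "ppi_edges.tsv",
        "annotation": out / "annotation.tsv",
        "term_graph": out / "term_graph.tsv",
        "truth": out / "truth.tsv",
        "config": out / "synthetic_config.tsv",
    }
    write_deg_table(table_a, paths["deg_a"])
    write_deg_table(table_b, paths["deg_b"])
    write_gmt(sets, paths["gene_sets"])
    write_edge_list(graph, paths["edges"])
    write_annotation(ann, paths["annotation"])
    write_term_graph(terms, paths["term_graph"])

    truth_df = truth.gene_class.rename_axis("gene_id").reset_index()
    truth_df["planted_hub"] = truth_df["gene_id"].isin(truth.planted_hub_ids)
    truth_df.to_csv(paths["truth"], sep="\t", index=False)
    with open(out / "planted_sets.txt", "w") as fh:
        fh.write("\n".join(sorted(truth.planted_set_ids)) + "\n")
    paths["planted_sets"] = out / "planted_sets.txt"
    cfg_rows = pd.DataFrame(sorted(asdict(config).items()), columns=["key", "value"])
    cfg_rows.to_csv(paths["config"], sep="\t", index=False)
    return paths
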