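"""Five-cohort comparison of enrichment results and layer-specific labeling.

The study design compares pathway/process enrichment across five cohorts of
genes: each lamina's uDEGs (``a_unique``, ``b_unique``), each lamina's full
DEG list (``a_all``, ``b_all``), and the convergently dysregulated genes
(``convergent``).  For every term, a significance/direction flag is recorded
per cohort, and the flag vector is reduced to one label:

* ``a_layer_specific`` — significant for lamina A's uDEGs and its full DEG
  list while lamina B's full list is either not significant or significant
  in the opposite direction (mirror rule for B);
* ``a_unique_only`` / ``b_unique_only`` — significant only for that
  lamina's uDEGs;
* ``genotype_shared`` — significant in both full DEG lists without opposing
  directions (a genotype/disease effect common to both laminae);
* ``divergent_between_laminae`` — significant in both full lists with
  strictly opposite directions (and not attributable to a single lamina);
* ``unlabeled`` — any other combination.

The labeling function is total: every possible flag vector receives exactly
one label, and swapping the two laminae swaps the A/B labels while fixing
the shared ones.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

from .errors import ConfigurationError, ParameterError, ValidationError

logger = logging.getLogger(__name__)

COHORTS = ("a_unique", "b_unique", "a_all", "b_all", "convergent")

FLAGS = ("significant_up", "significant_down", "significant_nodir", "not_significant")

LABELS = (
    "a_layer_specific",
    "b_layer_specific",
    "a_unique_only",
    "b_unique_only",
    "genotype_shared",
    "divergent_between_laminae",
    "unlabeled",
)


def _flag(p_value: float, z: float, significant: bool) -> str:
    if not significant:
        return "not_significant"
    if pd.isna(z) or z == 0:
        return "significant_nodir"
    return "significant_up" if z > 0 else "significant_down"


def build_flag_matrix(
    results_by_cohort: Mapping[str, pd.DataFrame],
    alpha: float = 0.05,
    *,
    significance: str = "raw",
) -> pd.DataFrame:
    """Build the term x cohort significance-flag matrix.

    ``results_by_cohort`` must provide an enrichment frame (see
    :func:`laminadiv.enrichment.enrich_sets`) for each of the five
    :data:`COHORTS`.  One row per term appearing in any cohort; a term absent
    from a cohort's results is ``not_significant`` there.  Significance uses
    the raw pathway p-value by default (``significance="adjusted"`` switches
    to BH-adjusted); direction comes from the activation z.
    """
    missing = [c for c in COHORTS if c not in results_by_cohort]
    if missing:
        raise ConfigurationError(f"missing cohort(s): {missing}")
    if significance not in ("raw", "adjusted"):
        raise ParameterError(f"significance must be 'raw' or 'adjusted', got {significance!r}")
    pcol = "p_value" if significance == "raw" else "adj_p"
    terms: list[str] = []
    seen = set()
    for cohort in COHORTS:
        for t in results_by_cohort[cohort]["set_id"]:
            if t not in seen:
                seen.add(t)
                terms.append(t)
    matrix = pd.DataFrame("not_significant", index=sorted(terms), columns=list(COHORTS))
    matrix.index.name = "term_id"
    for cohort in COHORTS:
        df = results_by_cohort[cohort]
        for _, row in df.iterrows():
            sig = bool(row[pcol] < alpha)
            matrix.loc[row["set_id"], cohort] = _flag(row[pcol], row["activation_z"], sig)
    return matrix


def _sig(flag: str) -> bool:
    return flag != "not_significant"


def _opposite(flag_x: str, flag_y: str) -> bool:
    return {flag_x, flag_y} == {"significant_up", "significant_down"}


def label_flag_vector(flags: Mapping[str, str], *, strict: bool = False) -> str:
    """Label one term's five-cohort flag vector.

    ``strict=True`` drops the opposite-direction clause from the
    layer-specific rule, i.e. a term is layer specific for A only if B's
    full DEG list shows no significance at all.

    When both laminae satisfy the layer-specific rule simultaneously (only
    possible with both full-list cohorts significant in opposite
    directions), the term is labeled ``divergent_between_laminae``: the
    signal cannot be attributed to a single lamina, and the tie keeps the
    labeling mirror-symmetric.
    """
    for cohort in COHORTS:
        if cohort not in flags:
            raise ConfigurationError(f"flag vector missing cohort {cohort!r}")
        if flags[cohort] not in FLAGS:
            raise ValidationError(f"unknown flag {flags[cohort]!r} for cohort {cohort!r}")
    au, bu = flags["a_unique"], flags["b_unique"]
    aa, ba = flags["a_all"], flags["b_all"]

    def ls_eligible(u: str, own_all: str, other_all: str) -> bool:
        if not (_sig(u) and _sig(own_all)):
            return False
        if not _sig(other_all):
            return True
        return (not strict) and _opposite(own_all, other_all)

    a_ls = ls_eligible(au, aa, ba)
    b_ls = ls_eligible(bu, ba, aa)
    if a_ls and b_ls:
        return "divergent_between_laminae"
    if a_ls:
        return "a_layer_specific"
    if b_ls:
        return "b_layer_specific"
    if _sig(aa) and _sig(ba):
        if _opposite(aa, ba):
            return "divergent_between_laminae"
        return "genotype_shared"
    if _sig(au) and not _sig(aa) and not _sig(ba) and not _sig(bu):
        return "a_unique_only"
    if _sig(bu) and not _sig(ba) and not _sig(aa) and not _sig(au):
        return "b_unique_only"
    return "unlabeled"


def label_terms(flag_matrix: pd.DataFrame, *, strict: bool = False) -> pd.DataFrame:
    """Apply :func:`label_flag_vector` to every row of the flag matrix.

    Returns a DataFrame with columns ``term_id`` and ``label``.
    """
    rows = [
        {"term_id": term, "label": label_flag_vector(row.to_dict(), strict=strict)}
        for term, row in flag_matrix.iterrows()
    ]
    return pd.DataFrame(rows, columns=["term_id", "label"])


def label_ancestors(
    labels: pd.DataFrame,
    graph: nx.DiGraph,
    focus_terms: Iterable[str],
) -> pd.DataFrame:
    """List every ontology ancestor of each focus term with its own label.

    ``graph`` holds child -> parent edges; ancestors are all terms reachable
    by following them.  Ancestors carry their independently computed cohort
    label (``unlabeled`` if absent from ``labels``); nothing is propagated.
    Output rows are sorted by (focus term, ancestor) so the report is
    invariant to edge insertion order.
    """
    if not nx.is_directed_acyclic_graph(graph):
        raise ValidationError("term graph contains a cycle")
    label_of = dict(zip(labels["term_id"], labels["label"]))
    rows = []
    for focus in focus_terms:
        if focus not in graph:
            raise ValidationError(f"focus term {focus!r} not in term graph")
        for anc in sorted(nx.descendants(graph, focus)):
            rows.append(
                {
                    "focus_term": focus,
                    "ancestor": anc,
                    "label": label_of.get(anc, "unlabeled"),
                }
            )
    return pd.DataFrame(rows, columns=["focus_term", "ancestor", "label"])


def filter_terms_by_keyword(
    term_names: Mapping[str, str],
    keyword_map: Mapping[str, str],
) -> pd.DataFrame:
    """Tag terms with categories by case-insensitive keyword match on names.

    ``keyword_map`` maps keyword -> category in priority order (first match
    wins; multi-matches are logged).  Terms matching no keyword are
    excluded.  Returns columns ``term_id``, ``name``, ``category``.
    """
    if not keyword_map:
        raise ParameterError("keyword map must be non-empty")
    rows = []
    for term_id, name in term_names.items():
        lname = str(name).lower()
        matches = [cat for kw, cat in keyword_map.items() if kw.lower() in lname]
        if not matches:
            continue
        if len(set(matches)) > 1:
            logger.info(
                "term %r matches several categories %s; keeping %r",
                term_id, sorted(set(matches)), matches[0],
            )
        rows.append({"term_id": term_id, "name": name, "category": matches[0]})
    return pd.DataFrame(rows, columns=["term_id", "name", "category"])
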