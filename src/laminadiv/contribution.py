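"""Per-term uDEG contribution percentages, 10-point binning and category means.

For every layer-specific term, the contribution of a lamina's uDEGs is the
percentage of that term's differentially expressed members that are uDEGs:

    pct = 100 * |term ∩ uDEGs| / |term ∩ all DEGs|

Percentages are binned into one aggregate "<50" bin followed by half-open
10-point bins [50,60), [60,70), [70,80), [80,90) and a top bin [90,100]
closed at 100.  Terms with no differentially expressed member are skipped
(they cannot be a significantly dysregulated process).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, ValidationError
from .io import GeneSetCollection

logger = logging.getLogger(__name__)

BIN_LABELS = ("<50", "50-60", "60-70", "70-80", "80-90", "90-100")


def contribution_bin(pct: float) -> str:
    """Bin label for a contribution percentage in (0, 100]."""
    if not 0 <= pct <= 100:
        raise ValidationError(f"percentage {pct} outside [0, 100]")
    if pct < 50:
        return "<50"
    if pct >= 90:
        return "90-100"
    lo = int(pct // 10) * 10
    return f"{lo}-{lo + 10}"


@dataclass
class ContributionRecord:
    term_id: str
    n_all_degs_in_term: int
    n_udegs_in_term: int
    pct_udeg: float
    bin_label: str


def udeg_contribution(
    term_members: set[str], all_degs: set[str], udegs: set[str], term_id: str = ""
) -> ContributionRecord | None:
    """Contribution record for one term, or ``None`` if the term has no
    differentially expressed member.

    Requires ``udegs`` to be a subset of ``all_degs`` (uDEGs are DEGs).
    """
    if not udegs <= all_degs:
        stray = sorted(udegs - all_degs)
        raise ValidationError(f"uDEGs not a subset of all DEGs: {stray[:10]}")
    n_all = len(term_members & all_degs)
    if n_all == 0:
        logger.info("term %r has no DEG member; skipped", term_id)
        return None
    n_u = len(term_members & udegs)
    pct = 100.0 * n_u / n_all
    return ContributionRecord(
        term_id=term_id,
        n_all_degs_in_term=n_all,
        n_udegs_in_term=n_u,
        pct_udeg=pct,
        bin_label=contribution_bin(pct),
    )


def contribution_table(
    sets: GeneSetCollection,
    all_degs: set[str],
    udegs: set[str],
    term_ids: set[str] | None = None,
) -> pd.DataFrame:
    """Contribution records for every set (optionally restricted to
    ``term_ids``, e.g. the layer-specific terms), as a DataFrame."""
    rows = []
    n_skipped = 0
    for gs in sets:
        if term_ids is not None and gs.set_id not in term_ids:
            continue
        rec = udeg_contribution(gs.members, all_degs, udegs, term_id=gs.set_id)
        if rec is None:
            n_skipped += 1
            continue
        rows.append(vars(rec))
    if n_skipped:
        logger.info("skipped %d term(s) with no DEG overlap", n_skipped)
    return pd.DataFrame(
        rows,
        columns=["term_id", "n_all_degs_in_term", "n_udegs_in_term", "pct_udeg", "bin_label"],
    )


def summarize_bins(records: pd.DataFrame) -> pd.DataFrame:
    """Per-bin term counts, share of all terms (percent, summing to 100) and
    mean contribution over the bin's member terms.

    Empty bins appear with ``n_terms=0``, share 0 and NaN mean.
    """
    if len(records) == 0:
        raise InsufficientDataError("no contribution records to summarize")
    total = len(records)
    rows = []
    for label in BIN_LABELS:
        sub = records[records["bin_label"] == label]
        rows.append(
            {
                "bin_label": label,
                "n_terms": len(sub),
                "share_pct": 100.0 * len(sub) / total,
                "mean_pct_udeg": float(sub["pct_udeg"].mean()) if len(sub) else np.nan,
            }
        )
    return pd.DataFrame(rows, columns=["bin_label", "n_terms", "share_pct", "mean_pct_udeg"])


def summarize_categories(
    records: pd.DataFrame, categories: pd.DataFrame
) -> pd.DataFrame:
    """Average contribution per keyword category.

    ``categories`` is the output of
    :func:`laminadiv.laminaspec.filter_terms_by_keyword` (columns
    ``term_id``, ``category``); records for untagged terms are excluded.
    Returns per-category ``n_terms`` and ``mean_pct_udeg`` sorted by
    descending mean (category name breaks ties).
    """
    merged = records.merge(categories[["term_id", "category"]], on="term_id", how="inner")
    out = (
        merged.groupby("category")
        .agg(n_terms=("term_id", "size"), mean_pct_udeg=("pct_udeg", "mean"))
        .reset_index()
        .sort_values(
            ["mean_pct_udeg", "category"], ascending=[False, True], ignore_index=True
        )
    )
    return out[["category", "n_terms", "mean_pct_udeg"]]
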