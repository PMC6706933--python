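"""Hit-list benchmarking: hits at FDR thresholds and gene-set enrichment.

Given a gene-level result table, counts significant genes at a ladder of
FDR thresholds, intersects them with an annotated gene set (e.g. DNA
damage response genes in a PARP-inhibitor screen), and reports the
upper-tail hypergeometric over-representation p-value at each threshold.
The universe is the set of genes scored in the screen.
"""

from __future__ import annotations

from collections.abc import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._errors import ConfigurationError, ValidationError
from .io import GeneSet

_DIRECTION_COLS = {
    "synergy": ("fdr_synth", "rank_synth"),
    "suppressor": ("fdr_supp", "rank_supp"),
}


def hits_at_fdr(
    results: pd.DataFrame, direction: str, fdr_threshold: float
) -> list[str]:
    """Genes significant in one direction, ordered by that direction's rank."""
    if direction not in _DIRECTION_COLS:
        raise ConfigurationError(
            f"direction must be one of {sorted(_DIRECTION_COLS)}"
        )
    if not 0 < fdr_threshold <= 1:
        raise ConfigurationError("fdr_threshold must be in (0, 1]")
    fdr_col, rank_col = _DIRECTION_COLS[direction]
    hit = results[results[fdr_col] < fdr_threshold]
    return hit.sort_values(rank_col)["GENE"].tolist()


def hypergeom_enrichment(
    hits: Iterable[str], annotated: GeneSet, universe: Iterable[str]
) -> float:
    """Upper-tail hypergeometric p-value for gene-set over-representation.

    P[X >= k] where k = |hits ∩ annotated|, drawing |hits| genes without
    replacement from a universe containing |annotated ∩ universe|
    annotated members.  The observed overlap is included in the tail.
    """
    uni = set(universe)
    if not uni:
        raise ValidationError("universe is empty")
    hit_set = set(hits)
    stray = hit_set - uni
    if stray:
        raise ValidationError(
            f"hits outside the universe: {sorted(stray)[:5]}"
        )
    ann = annotated.members & uni
    k = len(hit_set & ann)
    if not hit_set:
        return 1.0
    # sf(k-1) = P[X >= k]
    return float(stats.hypergeom.sf(k - 1, len(uni), len(ann), len(hit_set)))


def enrichment_curve(
    results: pd.DataFrame,
    annotated: GeneSet,
    thresholds: Sequence[float],
    direction: str = "synergy",
) -> pd.DataFrame:
    """Enrichment report across an ascending ladder of FDR thresholds.

    One row per threshold: n_hits, n_hits_in_set, hypergeometric p-value,
    and -log10 p.  The universe is every gene in ``results``.
    """
    thresholds = list(thresholds)
    if thresholds != sorted(thresholds):
        raise ConfigurationError("thresholds must be sorted ascending")
    universe = set(results["GENE"])
    ann = annotated.members & universe
    rows = []
    for thr in thresholds:
        hit = hits_at_fdr(results, direction, thr)
        p = hypergeom_enrichment(hit, annotated, universe)
        rows.append(
            {
                "threshold": thr,
                "n_hits": len(hit),
                "n_hits_in_set": len(set(hit) & ann),
                "pval": p,
                "neg_log10_p": float(-np.log10(p)) if p > 0 else float("inf"),
            }
        )
    return pd.DataFrame(rows)
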