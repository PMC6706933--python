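"""The drugZ scoring algorithm for chemogenetic interaction screens.

Pipeline, in order: depth normalization of each sample to a fixed read
total; pseudocounted log2 fold change of treated vs. control per replicate;
an empirical-Bayes standard deviation for each fold change, borrowed from
the N guides with the most similar control read count; guide Z-scores;
gene-level aggregation to normZ = sumZ / sqrt(n); one-tailed p-values in
the synergy (depletion, negative normZ) and suppressor (enrichment,
positive normZ) directions, each Benjamini-Hochberg corrected across all
genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._errors import ConfigurationError, ValidationError
from .io import RESULT_COLUMNS, ScreenCounts

log = logging.getLogger(__name__)


@dataclass
class DrugzConfig:
    """Tunable parameters of the drugZ analysis.

    Attributes
    ----------
    pseudocount
        Added to normalized reads in both arms before the log ratio;
        keeps fold changes finite at zero counts.  Default 5.
    norm_target
        Total read count each sample is scaled to.  Default 1e7.
    window_size
        Number N of neighboring guides (ranked by control read count)
        whose fold changes estimate each guide's standard deviation.
        Default 1000.
    monotone_filter
        Enforce non-decreasing variance as control read count decreases
        (a running maximum down the abundance ranking).  Default on.
    paired
        Compare the i-th treated sample to the i-th control sample
        (paired design); off = mean of treated vs. mean of control arms.
    min_control_reads
        Guides with fewer raw control reads than this in a replicate are
        dropped from that replicate.  0 disables the filter (default; the
        method as published describes no count filter).
    remove_genes
        Gene symbols excluded from the result table before p-value/FDR
        computation (e.g. non-targeting controls).
    """

    pseudocount: float = 5.0
    norm_target: float = 1e7
    window_size: int = 1000
    monotone_filter: bool = True
    paired: bool = True
    min_control_reads: int = 0
    remove_genes: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.pseudocount <= 0:
            raise ConfigurationError("pseudocount must be > 0")
        if self.norm_target <= 0:
            raise ConfigurationError("norm_target must be > 0")
        if self.window_size < 2:
            raise ConfigurationError("window_size must be >= 2")
        if self.min_control_reads < 0:
            raise ConfigurationError("min_control_reads must be >= 0")
        self.remove_genes = frozenset(self.remove_genes)


def normalize_counts(
    counts: np.ndarray | pd.Series,
    norm_target: float = 1e7,
    sample: str = "",
) -> np.ndarray:
    """Scale one sample's read counts to sum to ``norm_target`` reads."""
    arr = np.asarray(counts, dtype=float)
    total = arr.sum()
    if total <= 0:
        name = f" {sample!r}" if sample else ""
        raise ValidationError(f"sample{name} has zero total reads")
    return arr * (norm_target / total)


def compute_fold_change(
    treated_norm: np.ndarray,
    control_norm: np.ndarray,
    pseudocount: float = 5.0,
) -> np.ndarray:
    """Pseudocounted log2 fold change of treated over control reads.

    fc_i = log2((treated_i + pc) / (control_i + pc)); always finite.
    """
    t = np.asarray(treated_norm, dtype=float)
    c = np.asarray(control_norm, dtype=float)
    if t.shape != c.shape:
        raise ValidationError(
            f"treated and control columns differ in length: "
            f"{t.shape} vs {c.shape}"
        )
    return np.log2((t + pseudocount) / (c + pseudocount))


def estimate_eb_std(
    fc: np.ndarray,
    control_norm: np.ndarray,
    window_size: int = 1000,
    monotone_filter: bool = True,
    guide_ids: np.ndarray | None = None,
) -> np.ndarray:
    """Empirical-Bayes standard deviation of each guide's fold change.

    Guides are ranked by control read count, descending (ties broken by
    guide id, ascending, for deterministic output).  Each guide's eb_std
    is the root-mean-square about zero — not about the window mean — of
    the fold changes of the ``window_size`` guides nearest in rank, the
    window clamped at both ends of the ranking.  With the monotone filter
    on, a running maximum down the ranking forces eb_std non-decreasing
    as read count decreases.  Returned in the original row order.
    """
    if window_size < 2:
        raise ConfigurationError("window_size must be >= 2")
    fc = np.asarray(fc, dtype=float)
    cn = np.asarray(control_norm, dtype=float)
    g = len(fc)
    if guide_ids is None:
        guide_ids = np.arange(g)
    # lexsort: last key is primary -> control descending, then guide id.
    order = np.lexsort((np.asarray(guide_ids), -cn))
    fc_sorted = fc[order]

    n = min(window_size, g)
    half = window_size // 2
    sq = np.concatenate(([0.0], np.cumsum(fc_sorted**2)))
    ranks = np.arange(g)
    starts = np.clip(ranks - half, 0, g - n)
    ends = starts + n
    eb_sorted = np.sqrt((sq[ends] - sq[starts]) / n)
    if monotone_filter:
        eb_sorted = np.maximum.accumulate(eb_sorted)

    out = np.empty(g)
    out[order] = eb_sorted
    return out


def guide_zscores(fc: np.ndarray, eb_std: np.ndarray) -> np.ndarray:
    """Z-score each fold change against its empirical-Bayes std."""
    fc = np.asarray(fc, dtype=float)
    eb = np.asarray(eb_std, dtype=float)
    if (eb <= 0).any():
        raise ValidationError(
            "eb_std must be positive everywhere; degenerate windows must "
            "be repaired before Z-scoring"
        )
    return fc / eb


def _repair_degenerate_eb(fc: np.ndarray, eb_std: np.ndarray) -> np.ndarray:
    """Z-scores with the degenerate eb_std = 0 case handled.

    Zero eb_std (a window of all-zero fold changes) is replaced by the
    smallest positive eb_std in the sample; in a wholly null screen with
    no positive value at all, the affected z are set to 0.
    """
    eb = np.asarray(eb_std, dtype=float)
    zero = eb <= 0
    if not zero.any():
        return fc / eb
    positive = eb[~zero]
    if positive.size == 0:
        return np.zeros_like(np.asarray(fc, dtype=float))
    eb = eb.copy()
    eb[zero] = positive.min()
    return fc / eb


def gene_normz(
    guide_z: np.ndarray, gene_map: np.ndarray | pd.Series
) -> pd.DataFrame:
    """Aggregate guide-replicate Z terms to gene-level scores.

    Per gene: sumZ = sum of its z terms, numObs = number of terms,
    normZ = sumZ / sqrt(numObs).
    """
    z = np.asarray(guide_z, dtype=float)
    genes = np.asarray(gene_map)
    if len(z) != len(genes):
        raise ValidationError("guide_z and gene_map differ in length")
    df = pd.DataFrame({"GENE": genes, "z": z})
    agg = df.groupby("GENE", sort=True)["z"].agg(["sum", "count"])
    agg.columns = ["sumZ", "numObs"]
    agg = agg[agg["numObs"] > 0]
    agg["normZ"] = agg["sumZ"] / np.sqrt(agg["numObs"])
    return agg.reset_index()


def pvalues_and_fdr(gene_table: pd.DataFrame) -> pd.DataFrame:
    """Two-directional p-values, ranks, and BH FDRs from normZ.

    Synergy (synthetic-lethal) direction: lower tail, pval = Phi(normZ).
    Suppressor direction: upper tail, pval = 1 - Phi(normZ).  Each
    direction is ranked (1 = most significant, ties broken by gene symbol
    so ranks are a permutation of 1..G) and BH step-up adjusted across
    all genes independently.
    """
    if len(gene_table) == 0:
        raise ValidationError("no genes to test")
    out = gene_table.copy()
    normz = out["normZ"].to_numpy()
    out["pval_synth"] = stats.norm.cdf(normz)
    out["pval_supp"] = stats.norm.sf(normz)
    genes = out["GENE"].to_numpy()
    g = len(out)
    for side in ("synth", "supp"):
        p = out[f"pval_{side}"].to_numpy()
        order = np.lexsort((genes, p))
        ranks = np.empty(g, dtype=np.int64)
        ranks[order] = np.arange(1, g + 1)
        out[f"rank_{side}"] = ranks
        out[f"fdr_{side}"] = multipletests(p, method="fdr_bh")[1]
    return out


def _normalized_arm(
    screen: ScreenCounts, samples: list[str], norm_target: float
) -> np.ndarray:
    cols = [
        normalize_counts(screen.counts[s].to_numpy(), norm_target, sample=s)
        for s in samples
    ]
    return np.column_stack(cols)


def _guide_level_z(
    screen: ScreenCounts, config: DrugzConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Run normalization -> fold change -> eb_std -> Z for every guide.

    Returns the flat array of guide-replicate Z terms and the parallel
    array of gene symbols (shared by drugZ aggregation and the Gibbs
    sampler).
    """
    ctrl = screen.control_samples
    trt = screen.treated_samples
    if not ctrl or not trt:
        raise ConfigurationError(
            "screen has no sample-role assignment; use "
            "ScreenCounts.with_roles(control_samples, treated_samples)"
        )
    if config.paired and len(ctrl) != len(trt):
        raise ConfigurationError(
            f"paired mode needs equal arm sizes (got {len(ctrl)} control, "
            f"{len(trt)} treated); consider unpaired mode"
        )

    genes = screen.genes.to_numpy()
    guide_ids = screen.guide_ids.to_numpy()
    ctrl_norm = _normalized_arm(screen, ctrl, config.norm_target)
    trt_norm = _normalized_arm(screen, trt, config.norm_target)
    ctrl_raw = screen.counts[ctrl].to_numpy()

    if config.paired:
        comparisons = [
            (trt_norm[:, r], ctrl_norm[:, r], ctrl_raw[:, r])
            for r in range(len(ctrl))
        ]
    else:
        comparisons = [
            (trt_norm.mean(axis=1), ctrl_norm.mean(axis=1),
             ctrl_raw.mean(axis=1))
        ]

    z_parts: list[np.ndarray] = []
    gene_parts: list[np.ndarray] = []
    for t_col, c_col, c_raw in comparisons:
        keep = c_raw >= config.min_control_reads
        if not keep.any():
            continue
        fc = compute_fold_change(t_col[keep], c_col[keep], config.pseudocount)
        eb = estimate_eb_std(
            fc,
            c_col[keep],
            window_size=config.window_size,
            monotone_filter=config.monotone_filter,
            guide_ids=guide_ids[keep],
        )
        z_parts.append(_repair_degenerate_eb(fc, eb))
        gene_parts.append(genes[keep])
    if not z_parts:
        raise ValidationError("no guides pass the min_control_reads filter")
    return np.concatenate(z_parts), np.concatenate(gene_parts)


def drugz(screen: ScreenCounts, config: DrugzConfig | None = None) -> pd.DataFrame:
    """Score a screen with drugZ; returns the gene-level result table.

    Columns follow the stable output contract: GENE, sumZ, numObs, normZ,
    and p-value / rank / FDR in the synergy and suppressor directions.
    Rows are ordered by ascending normZ (strongest synergy first).
    """
    if config is None:
        config = DrugzConfig()
    z, gene_terms = _guide_level_z(screen, config)
    table = gene_normz(z, gene_terms)
    if config.remove_genes:
        removed = table["GENE"].isin(config.remove_genes)
        if removed.any():
            log.info("excluding %d genes before FDR", int(removed.sum()))
        table = table[~removed].reset_index(drop=True)
    table = pvalues_and_fdr(table)
    return (
        table[RESULT_COLUMNS]
        .sort_values(["normZ", "GENE"], kind="mergesort")
        .reset_index(drop=True)
    )
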