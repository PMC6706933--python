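"""Synthetic chemogenetic screen generator with ground truth.

Emulates a paired-replicate pooled CRISPR drug-modifier screen: a library
of several guides per gene, log-normal latent guide abundances shared
between arms, negative-binomial sequencing noise, a minority of genes with
planted synergy (depletion under drug) or suppressor (enrichment under
drug) interactions, and a fraction of genes with drug-independent fitness
dropout applied to BOTH arms.  Every scoring stage is testable against the
emitted truth table without external data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._errors import ConfigurationError
from .io import ScreenCounts

LABELS = ("null", "synergy", "suppressor", "fitness_only")


@dataclass
class SimConfig:
    """Generative parameters of a synthetic screen.

    ``effect_size`` is the mean log2 shift applied to treated counts of
    interacting genes: synergy genes receive ``effect_size`` (negative =
    depletion), suppressor genes receive ``-effect_size``.  Per-guide
    effects are jittered ~ Normal(effect, |effect|/4) so guides of one
    gene are correlated but not identical.  ``fitness_effect`` is a log2
    shift applied to both arms of ``fitness_frac`` of the remaining
    genes (drug-independent dropout).  ``dispersion`` is the
    negative-binomial overdispersion (variance = m + dispersion * m^2);
    ``depth`` is the mean reads per guide.
    """

    n_genes: int
    guides_per_gene: int = 4
    n_replicates: int = 3
    frac_synergy: float = 0.05
    frac_suppressor: float = 0.05
    effect_size: float = -2.0
    fitness_frac: float = 0.1
    fitness_effect: float = -1.0
    dispersion: float = 0.1
    depth: float = 500.0
    abundance_sigma: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.guides_per_gene < 1:
            raise ConfigurationError("n_genes and guides_per_gene must be >= 1")
        if self.n_replicates < 1:
            raise ConfigurationError("n_replicates must be >= 1")
        if self.frac_synergy < 0 or self.frac_suppressor < 0:
            raise ConfigurationError("planted fractions must be >= 0")
        if self.frac_synergy + self.frac_suppressor > 0.5:
            raise ConfigurationError(
                "frac_synergy + frac_suppressor must be <= 0.5"
            )
        if self.depth <= 0:
            raise ConfigurationError("depth must be > 0")
        if self.dispersion < 0:
            raise ConfigurationError("dispersion must be >= 0")


@dataclass
class SimTruth:
    """Ground truth emitted alongside a simulated screen.

    ``gene_table`` has one row per gene: GENE, label (one of
    null/synergy/suppressor/fitness_only), effect (the gene-level planted
    log2 drug-interaction shift; 0 for null and fitness_only).
    ``guide_effects`` maps each guide id to its realized jittered shift.
    """

    gene_table: pd.DataFrame
    guide_effects: pd.Series

    def genes_with(self, label: str) -> list[str]:
        if label not in LABELS:
            raise ConfigurationError(f"unknown label {label!r}")
        t = self.gene_table
        return t.loc[t["label"] == label, "GENE"].tolist()


def _nb_draw(
    rng: np.random.Generator, mean: np.ndarray, dispersion: float
) -> np.ndarray:
    if dispersion == 0:
        return rng.poisson(mean)
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def simulate_screen(config: SimConfig) -> tuple[ScreenCounts, SimTruth]:
    """Draw one screen and its truth table; identical seed, identical output."""
    rng = np.random.default_rng(config.seed)
    g, k, r = config.n_genes, config.guides_per_gene, config.n_replicates

    genes = np.array([f"GENE{i:05d}" for i in range(g)])
    guide_genes = np.repeat(genes, k)
    guide_ids = np.array(
        [f"{gene}_g{j + 1}" for gene in genes for j in range(k)]
    )

    n_syn = int(round(config.frac_synergy * g))
    n_sup = int(round(config.frac_suppressor * g))
    n_fit = int(round(config.fitness_frac * (g - n_syn - n_sup)))
    perm = rng.permutation(g)
    labels = np.full(g, "null", dtype=object)
    labels[perm[:n_syn]] = "synergy"
    labels[perm[n_syn : n_syn + n_sup]] = "suppressor"
    labels[perm[n_syn + n_sup : n_syn + n_sup + n_fit]] = "fitness_only"

    gene_effect = np.zeros(g)
    gene_effect[labels == "synergy"] = config.effect_size
    gene_effect[labels == "suppressor"] = -config.effect_size

    jitter_sd = abs(config.effect_size) / 4.0
    per_guide = np.repeat(gene_effect, k)
    interacting = per_guide != 0
    if interacting.any() and jitter_sd > 0:
        per_guide = per_guide.astype(float)
        per_guide[interacting] = rng.normal(
            per_guide[interacting], jitter_sd
        )
    fitness = np.repeat(
        np.where(labels == "fitness_only", config.fitness_effect, 0.0), k
    )

    # latent abundance shared between arms; mean 1 so depth is the mean count
    sigma = config.abundance_sigma
    abundance = rng.lognormal(-(sigma**2) / 2.0, sigma, size=g * k)
    ctrl_mean = config.depth * abundance * 2.0**fitness
    trt_mean = ctrl_mean * 2.0**per_guide

    control_names = [f"CTRL_{i + 1}" for i in range(r)]
    treated_names = [f"DRUG_{i + 1}" for i in range(r)]
    data = {}
    for name in control_names:
        data[name] = _nb_draw(rng, ctrl_mean, config.dispersion)
    for name in treated_names:
        data[name] = _nb_draw(rng, trt_mean, config.dispersion)

    counts = pd.DataFrame(
        data, index=pd.Index(guide_ids, name="GUIDE"), dtype=np.int64
    )
    screen = ScreenCounts(
        counts=counts,
        genes=pd.Series(guide_genes, index=counts.index, name="GENE"),
        control_samples=control_names,
        treated_samples=treated_names,
    )
    truth = SimTruth(
        gene_table=pd.DataFrame(
            {"GENE": genes, "label": labels, "effect": gene_effect}
        ),
        guide_effects=pd.Series(
            per_guide, index=counts.index, name="effect"
        ),
    )
    return screen, truth


def write_screen(screen: ScreenCounts, path: str) -> None:
    """Write a screen in the tab-delimited count-table format."""
    out = screen.counts.copy()
    out.insert(0, "GENE", screen.genes)
    out.to_csv(path, sep="\t", index=True)


def write_truth(truth: SimTruth, path: str) -> None:
    """Write the per-gene truth sidecar table."""
    truth.gene_table.to_csv(path, sep="\t", index=False)
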