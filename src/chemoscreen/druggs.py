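"""The drugGS gene scorer: Gibbs sampling of a per-gene Normal model.

Each gene's guide Z-scores (across guides and replicates) are modeled as
draws from Normal(mu, 1/tau) with independent priors mu ~ Normal(mu_prior,
1/tau_prior) and tau ~ Gamma(a_prior, rate=b_prior).  A Gibbs chain
alternates

    mu  | tau, data ~ Normal((n*ybar*tau + mu_prior*tau_prior) /
                             (n*tau + tau_prior),
                             1 / (n*tau + tau_prior))
    tau | mu,  data ~ Gamma(a_prior + n/2,
                            rate = b_prior + 0.5 * sum((z_i - mu)^2))

and the gene score is the posterior mean of mu over the retained draws.
The conventional conjugate factor 1/2 on the residual sum is the default;
``strict_update=True`` drops it, reproducing the method's printed update
verbatim (at the cost of the conjugate-posterior identity).

Scores are standardized across genes (divided by their empirical standard
deviation) and pushed through the same two-directional p-value/FDR
machinery as drugZ.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._errors import ConfigurationError, ValidationError
from .core import DrugzConfig, _guide_level_z, pvalues_and_fdr
from .io import RESULT_COLUMNS, ScreenCounts

log = logging.getLogger(__name__)


@dataclass
class GibbsConfig:
    """Sampler settings and Normal-Gamma hyperparameters.

    ``n_samples`` draws are generated per gene; the first
    ``burn_frac`` fraction is discarded before averaging (set 0 to keep
    every draw).  Hyperparameter defaults are weakly informative:
    mu_prior 0, tau_prior 1e-3, a_prior = b_prior = 0.5.
    """

    n_samples: int = 1000
    mu_prior: float = 0.0
    tau_prior: float = 1e-3
    a_prior: float = 0.5
    b_prior: float = 0.5
    burn_frac: float = 0.1
    strict_update: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 100:
            raise ConfigurationError("n_samples must be >= 100")
        if min(self.tau_prior, self.a_prior, self.b_prior) <= 0:
            raise ConfigurationError(
                "tau_prior, a_prior, b_prior must all be > 0"
            )
        if not 0 <= self.burn_frac < 1:
            raise ConfigurationError("burn_frac must be in [0, 1)")


@dataclass
class GenePosterior:
    """Posterior draws and summary for one gene."""

    gene: str
    n: int
    mu_samples: np.ndarray
    tau_samples: np.ndarray
    score: float
    post_sd: float


def _gibbs_chains(
    n: np.ndarray,
    sum_z: np.ndarray,
    sum_z2: np.ndarray,
    config: GibbsConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Advance one Gibbs chain per gene in lock-step.

    ``n``, ``sum_z``, ``sum_z2`` are per-gene sufficient statistics
    (count, sum, sum of squares of the guide Z terms).  Returns the
    (S, G) arrays of mu and tau draws.
    """
    g = len(n)
    s = config.n_samples
    half = 1.0 if config.strict_update else 0.5
    a_upd = config.a_prior + n / 2.0
    ybar = sum_z / n

    mu_draws = np.empty((s, g))
    tau_draws = np.empty((s, g))
    tau = np.ones(g)  # chain initialized at unit precision, mu at ybar
    mu = ybar.copy()
    for k in range(s):
        prec = n * tau + config.tau_prior
        mean = (n * ybar * tau + config.mu_prior * config.tau_prior) / prec
        mu = rng.normal(mean, 1.0 / np.sqrt(prec))
        resid = sum_z2 - 2.0 * mu * sum_z + n * mu**2
        b_upd = config.b_prior + half * np.maximum(resid, 0.0)
        tau = rng.gamma(a_upd, 1.0 / b_upd)
        mu_draws[k] = mu
        tau_draws[k] = tau
    return mu_draws, tau_draws


def gibbs_gene(
    guide_z: np.ndarray,
    config: GibbsConfig | None = None,
    gene: str = "",
    rng: np.random.Generator | None = None,
) -> GenePosterior:
    """Sample the posterior of one gene's mean guide Z-score.

    Reproducible given ``config.seed`` (or an explicit generator).
    """
    if config is None:
        config = GibbsConfig()
    z = np.asarray(guide_z, dtype=float)
    if z.size == 0:
        raise ValidationError("gene has no guide Z terms")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = np.array([z.size], dtype=float)
    mu_draws, tau_draws = _gibbs_chains(
        n, np.array([z.sum()]), np.array([(z**2).sum()]), config, rng
    )
    burn = int(config.burn_frac * config.n_samples)
    kept = mu_draws[burn:, 0]
    return GenePosterior(
        gene=gene,
        n=int(z.size),
        mu_samples=mu_draws[:, 0],
        tau_samples=tau_draws[:, 0],
        score=float(kept.mean()),
        post_sd=float(kept.std(ddof=1)),
    )


def druggs(
    screen: ScreenCounts,
    drugz_config: DrugzConfig | None = None,
    gibbs_config: GibbsConfig | None = None,
) -> pd.DataFrame:
    """Score a screen with drugGS.

    Shares normalization, fold change, eb_std, and guide Z-scoring with
    drugZ; replaces the sumZ aggregation with a per-gene Gibbs posterior
    mean.  The returned table carries the drugZ column contract (normZ
    holds the cross-gene standardized posterior mean) plus the raw
    posterior mean (``score``) and posterior sd (``post_sd``).
    """
    if drugz_config is None:
        drugz_config = DrugzConfig()
    if gibbs_config is None:
        gibbs_config = GibbsConfig()
    z, gene_terms = _guide_level_z(screen, drugz_config)

    df = pd.DataFrame({"GENE": gene_terms, "z": z})
    agg = df.groupby("GENE", sort=True)["z"].agg(["count", "sum"])
    agg["sum2"] = df.assign(z2=df["z"] ** 2).groupby("GENE", sort=True)[
        "z2"
    ].sum()

    rng = np.random.default_rng(gibbs_config.seed)
    mu_draws, _ = _gibbs_chains(
        agg["count"].to_numpy(dtype=float),
        agg["sum"].to_numpy(),
        agg["sum2"].to_numpy(),
        gibbs_config,
        rng,
    )
    burn = int(gibbs_config.burn_frac * gibbs_config.n_samples)
    kept = mu_draws[burn:]
    scores = kept.mean(axis=0)
    post_sd = kept.std(axis=0, ddof=1)

    table = pd.DataFrame(
        {
            "GENE": agg.index.to_numpy(),
            "sumZ": agg["sum"].to_numpy(),
            "numObs": agg["count"].to_numpy(dtype=np.int64),
            "score": scores,
            "post_sd": post_sd,
        }
    )
    if drugz_config.remove_genes:
        table = table[~table["GENE"].isin(drugz_config.remove_genes)]
        table = table.reset_index(drop=True)
    sd = table["score"].std(ddof=1)
    if not np.isfinite(sd) or sd == 0:
        raise ValidationError("gene scores are degenerate; cannot standardize")
    table["normZ"] = table["score"] / sd
    table = pvalues_and_fdr(table)
    cols = RESULT_COLUMNS + ["score", "post_sd"]
    return (
        table[cols]
        .sort_values(["normZ", "GENE"], kind="mergesort")
        .reset_index(drop=True)
    )
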