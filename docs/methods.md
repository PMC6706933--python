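# Methods

## The scoring model

A pooled CRISPR drug-modifier screen measures, for every guide RNA, read
counts in drug-treated (T) and untreated control (C) populations across
replicates. The scientific question is which genes *modify* the drug's
effect — not which genes are essential. The statistic is therefore built on
the treated-vs-control contrast within the screen, so that drug-independent
fitness defects (which move both arms together) cancel.

### drugZ

1. **Normalization.** Each sample's counts are scaled to a fixed total of
   `norm_target` = 10⁷ reads, so fold changes are sequencing-depth
   invariant (a uniform doubling of raw counts is an exact no-op).
2. **Fold change.** Per replicate r,
   `fc_r = log2((norm(T_r) + pc) / (norm(C_r) + pc))` with pseudocount
   `pc` = 5 added *after* normalization. The pseudocount keeps fc finite at
   zero counts and shrinks ratios built on few reads.
3. **Empirical-Bayes standard deviation.** Low-abundance guides have
   noisier fold changes. Guides are ranked by control read count
   (descending; ties broken by guide id for platform-independent
   determinism), and each guide's sd is estimated from the `window_size`
   N = 1000 guides nearest in rank as the root-mean-square of their fold
   changes **about zero** — not about the window mean. Using μ = 0 is
   deliberate: most genes are non-interacting, so the null fc is centered
   at zero, and planted signal inflates the estimate only by its
   (minority) share of the window. Windows are centered on each guide's
   rank and clamped at both ends of the ranking, so the first and last
   ⌊N/2⌋ guides share the edge windows. With the **monotone filter** on
   (default), a running maximum down the ranking enforces that estimated
   variance never decreases as read count decreases; disabling it returns
   the raw windowed RMS.
4. **Guide Z-scores.** `z = fc / eb_std`. If a window's RMS is exactly
   zero (all-zero fold changes, e.g. treated ≡ control), the sd is
   replaced by the smallest positive eb_std in the sample; in a wholly
   degenerate screen the z's are set to 0 so null guides stay null.
5. **Gene score.** All guide-replicate z terms of a gene are summed
   (`sumZ`, over n = guides × replicates terms) and normalized:
   `normZ = sumZ / √n`. Under the null of independent standard-normal
   terms, normZ is itself standard normal — verified by simulation in the
   test suite (mean within ±0.05 of 0, sd within ±0.05 of 1 over 20 null
   screens).
6. **Inference.** Synergy p-value = Φ(normZ) (lower tail; depletion under
   drug drives normZ negative), suppressor p-value = 1 − Φ(normZ). Each
   direction is ranked and Benjamini–Hochberg adjusted across all genes
   *separately*, because synergistic and suppressor interactions are
   reported as separate ranked lists.

**Paired vs. unpaired.** In the paired default, the i-th treated sample is
compared with the i-th control sample and eb_std is estimated per replicate
against that replicate's own control reads. With `paired=False`, the mean
of the normalized treated columns is compared with the mean of the
normalized control columns, yielding a single fc column. The two modes are
nearly interchangeable in practice (Spearman ρ ≈ 0.99 on the default
simulated screen; the acceptance script recomputes this).

**Optional filters.** `min_control_reads` (default 0 = off) drops guides
whose raw control reads in a replicate fall below the threshold, from that
replicate only. `remove_genes` excludes listed genes (e.g. non-targeting
controls) from the gene table *after* aggregation and *before* p/FDR
computation, so the excluded genes still inform normalization totals and
variance windows but do not consume FDR budget.

### drugGS

The guide-level statistic is identical; only the gene aggregation differs.
Each gene's z terms are modeled as Normal(μ, 1/τ) with independent priors
μ ~ Normal(μ_prior, 1/τ_prior) and τ ~ Gamma(a_prior, rate b_prior). A
Gibbs chain alternates the full conditionals

    μ | τ ~ Normal((n·ȳ·τ + μ_prior·τ_prior)/(n·τ + τ_prior),
                   1/(n·τ + τ_prior))
    τ | μ ~ Gamma(a_prior + n/2, rate b_prior + ½·Σ(zᵢ − μ)²)

for `n_samples` S = 1000 iterations, initialized at μ = ȳ, τ = 1 (start at
the data; the choice washes out within the discarded burn-in). The first
10% of draws are discarded by default (`burn_frac`, settable to 0). The
gene score is the mean of the retained μ draws; its sd is reported as
`post_sd`.

Numerical choices worth stating:

- **The ½ on the residual sum.** The conventional conjugate Gamma update
  carries rate `b + ½Σ(z−μ)²`; a variant without the ½ is available as
  `strict_update=True`. The default keeps the ½ because only that form
  satisfies the analytic posterior identity the tests enforce (the Gibbs
  posterior mean is checked against a quadrature evaluation of the exact
  semi-conjugate posterior on 50 random genes, within 3 Monte-Carlo
  standard errors by batch means).
- **Hyperparameter defaults** are weakly informative — μ_prior = 0,
  τ_prior = 10⁻³, a = b = 0.5 — so with ≥ 1 observed term the data
  dominate; a gene with a single guide is visibly shrunk toward 0
  (|score| < |z|), which is the intended behavior for poorly measured
  genes.
- **Gamma parameterization** is shape/rate (mean a/b); the update
  a + n/2 is only coherent under the rate convention.
- **Cross-gene standardization.** Posterior means are divided by their
  empirical sd across genes before p-values are computed, so the
  downstream normal-tail inference is calibrated. This is one reasonable
  reading of "converted into a Z-score"; centering is deliberately *not*
  applied so a globally shifted screen is not forced to look null.
- The sampler is vectorized: one chain per gene advanced in lock-step from
  per-gene sufficient statistics (n, Σz, Σz²), which makes the S = 1000
  run on a 1000-gene screen take about a second.

## The simulator

`simulate_screen` emulates the structure of a paired-replicate knockout
screen with a genome-scale library: several guides per gene, log-normal
latent guide abundance (σ = 0.8, mean 1) shared between arms,
negative-binomial sequencing noise (variance m + φ·m², default φ = 0.1),
and mean depth 500 reads per guide — the regime of a well-covered screen
sequenced at a few hundred reads per guide. Defaults plant 5% synergy and
5% suppressor genes at a mean log2 effect of ±2 (a strong interaction, the
regime the method is designed to flag), with per-guide jitter
Normal(effect, |effect|/4) so a gene's guides are correlated but not
identical, and give 10% of the remaining genes a drug-independent fitness
dropout of −1 log2 applied to **both** arms. Replicates share all planted
effects and differ only in count noise; pairing is positional.

What a green test on this generator establishes — and what it does not:
the generator matches the method's own model family (independent NB noise,
symmetric arms, no guide-specific off-target structure, no copy-number
cutting toxicity, no time-course drift, equal library representation
across samples). Recovery and calibration results on it validate the
implementation and the statistic's internal logic, not the method's
performance on any particular real screen.

## The enrichment benchmark

`hits_at_fdr` returns genes below an FDR threshold in one direction,
ordered by rank. `hypergeom_enrichment` computes the upper-tail
hypergeometric probability P[X ≥ k] of the observed overlap k between hits
and an annotated set, drawing |hits| genes from the **universe of genes
scored in the screen** (not the whole genome) — the screen-relative
over-representation question. The observed overlap is included in the
tail, the standard convention. `enrichment_curve` repeats this over an
ascending FDR ladder. The test suite cross-checks the hypergeometric tail
against exhaustive enumeration of all draws on universes of ≤ 25 genes.

## Degenerate inputs and tie-breaks

- All-zero sample column → error naming the sample (normalization
  undefined).
- Paired analysis with unequal arm sizes → configuration error suggesting
  unpaired mode (which tolerates asymmetry by construction).
- Ties in control read count are broken by guide id so results are
  identical across runs and platforms; result rows are ordered by
  (normZ, gene) for the same reason.
- Genes with zero scored terms are dropped from the output rather than
  reported as NaN.

## Known limitations

- No copy-number correction: amplified loci can produce cutting-toxicity
  artifacts that masquerade as synergy.
- Each time point is an independent run; there is no joint time-course
  model.
- drugGS reports no convergence diagnostics beyond the S-doubling
  stability check in the tests (no multi-chain R-hat).
- The simulator does not emulate guide-efficiency heterogeneity beyond
  the per-guide effect jitter.
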