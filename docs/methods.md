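# Methods

This note documents the statistical models, the synthetic-data generator,
the numerical choices, and the known limitations of `keloidcerna`.

## Study design and data model

The pipeline targets a paired two-group wound-healing design: 8 keloid-prone
and 6 control individuals, each sampled at day 0 (before a standardized skin
injury) and day 42 (six weeks after). Gene expression arrives as an integer
RNA-seq count matrix (mRNAs and lncRNAs, distinguished by a user-supplied
biotype map) and miRNA expression as log2 array intensities on the same
samples. Gene identifiers are opaque strings; identifier translation is the
caller's responsibility. All tabular inputs are TSV (tab separator, `.`
decimal, no quoting); results are CSV, networks SIF/GraphML.

## Differential expression

### RNA-seq branch: negative-binomial Wald test

Counts for gene *g*, sample *s* are modelled as NB with mean μ and
dispersion α, Var = μ + αμ². The test is a deliberate approximation in the
DESeq2 family, not a reimplementation:

* **Size factors** — median-of-ratios: the per-gene reference is the
  geometric mean over samples (genes with any zero count drop out); each
  sample's factor is the median count/reference ratio.
* **Dispersion** — per-gene pooled method of moments over the two
  conditions, `α = (pooled excess variance) / (pooled squared mean)`,
  floored at 1e-8. No shrinkage across genes.
* **Wald statistic** — log2FC of normalized condition means with
  `SE² = [(1/μ₁ + α)/n₁ + (1/μ₂ + α)/n₂] / ln2²` (delta method on the NB
  mean), referred to a *t* distribution with n₁ + n₂ − 2 degrees of
  freedom. The *t* reference (rather than normal) compensates for the
  estimated dispersion at small n; on null NB simulations (8 vs 8,
  α = 0.05, 2000 genes) the raw-p rejection rate at nominal 0.05 averages
  ≈ 0.049 over replicates. Genes with all-zero counts get log2FC 0 and
  p 1; a zero mean in one condition only is offset by half a normalized
  count so the fold change stays finite.
* **Screen** — significant ⇔ `|log2FC| > 1` AND BH-adjusted `p < 0.05`,
  strict inequalities. The adjusted-p criterion is the default (a
  `use_adjusted_p` switch exposes the raw-p variant). Benjamini–Hochberg is
  the multiple-testing procedure throughout.
* Pairing by individual is **not** modelled in the count branch; the
  contrast is a plain two-condition comparison. This is a documented
  simplification — with a latent per-individual baseline the unpaired test
  loses power but stays valid.

Not implemented, by design: dispersion or LFC shrinkage, Cook's-distance
outlier handling, independent filtering, covariates beyond the contrast.

### miRNA array branch: moderated t

On log2 intensities the per-probe pooled variance s² (df d) is shrunk
toward a scaled-inverse-chi-square prior fitted across probes by the
standard moments method on log s² (digamma/trigamma inversion): posterior
`s̃² = (d₀s₀² + d s²)/(d₀ + d)`, t referred to d₀ + d df (normal when the
prior df is infinite). `paired=True` switches to per-individual day42−day0
differences with a one-sample moderated t. The screen is on the **linear**
fold change, `|FC| > 1.5` (i.e. |log2FC| > log2 1.5) with adjusted
`p < 0.05`; the published array criterion prints "P<0.5", which this
package treats as a typo for 0.05 (the 0.5 reading is reachable by setting
`mirna_alpha=0.5`).

## Keloid-specific subtraction

"Expressed only in the keloid-prone group" is operationalized as
*significantly DE in the keloid contrast and not in the control contrast*:
keloid-specific transcripts typically still show non-zero control
expression, so literal presence cannot be the rule. Direction concordance
is not required for exclusion. Applied per biotype (mRNA, lncRNA) and — in
the pipeline default — to miRNAs as well, consistent with the network's
keloid-specific intent (`mirna_keloid_specific=False` disables it).

## Quantification and co-expression

FPKM[g,s] = counts·1e9 / (length · library size), with library size the
column sum of the supplied count matrix (aligned-read totals are
unavailable once the analysis starts from counts). Correlations default to
log2(FPKM + 1) — the log stabilizes Pearson on skewed expression — over the
pooled keloid samples (both timepoints, 16 columns), because the network is
keloid-specific by construction; both choices are config keys
(`correlation_scale`, and the caller can pass any sample subset). Which
samples entered the published correlation screen is not stated anywhere, so
this is an explicit, logged assumption.

Screens are strict: lncRNA–mRNA pairs at `PCC > 0.95`; feature–miRNA pairs
at `PCC < 0` by default, with a stringent `−0.95` mode mirroring the
positive screen (`neg_threshold`). No correlation p-values — the screen is
on the coefficient alone. Correlations are clamped to [−1, 1] against
floating-point overshoot; constant features are skipped with a log line.

## Triads and network

A competitive triad requires: retained (lncRNA, mRNA) pair; both members
negatively correlated with the miRNA; both present as that miRNA's targets
in the interaction table; and (default `require_de_mirna=True`) the miRNA
in the DE-miRNA set. Expected ceRNA directionality (lncRNA and mRNA
co-directional, miRNA opposite) is annotated per triad but never used as a
filter. Output order is lexicographic everywhere, so triad and network
construction are fully deterministic. The network wires each triad as
lncRNA–miRNA and miRNA–mRNA edges — never a direct lncRNA–mRNA edge — and
carries molecule class and regulation direction as node attributes.

## Enrichment

One-sided (over-representation) Fisher's exact test per term — equal to the
hypergeometric upper tail, which the test suite verifies against exhaustive
enumeration — with BH adjustment across the terms of the supplied
collection and flagging at adjusted p < 0.05. The universe defaults to the
mRNA-biotype genes of the count matrix. GO/KEGG databases are not bundled;
any GMT works, and reproducing a specific annotation release's term list is
out of scope.

## qPCR

ΔCt = mean-over-replicates Ct(target) − mean Ct(reference); ΔΔCt subtracts
the calibrator group's mean ΔCt per gene; relative expression = 2^−ΔΔCt.
Replicates are averaged on the Ct scale before differencing (the
per-replicate geometric-mean alternative is available and identical on
balanced data). Group comparison uses a Welch t on per-sample ΔCt values —
the underlying wet-lab convention rarely names its test, so this is a
documented choice. No amplification-efficiency correction.

## Synthetic-data generator

The generator is the package's validation instrument; its defaults are the
study conditions, not tuning knobs.

* **Design** — 8 keloid / 6 control individuals × day0/day42; 2000 mRNAs,
  300 lncRNAs, 300 miRNAs (small enough that the full pipeline runs in
  seconds); per-sample depth factors lognormal with log2 sd 0.15 so size
  factors do real work.
* **Counts** — NB with per-gene baseline means 2^U(3,10) and dispersion
  0.05, the same parameterization the test models, so power analyses are
  interpretable. 30 keloid-only DE genes shift 2^±2 at day42 in keloid
  individuals only; 20 shared DE genes shift in both groups.
* **Planted triads** (3 by default) — one latent factor per triad, shared
  between count and array simulation: N(0,1) per sample plus a mean shift
  of 5 at keloid day42. Loadings apply to keloid samples only — the
  planted circuit operates in keloid-prone individuals, so the control
  contrast is a clean null for every triad member. The lncRNA and mRNA
  load with one sign, the miRNA with the other, so triad members are
  simultaneously keloid-specific DE (their differential expression *is*
  the factor shift) and strongly correlated. Loadings are closed-form calibrated,
  `b = σ·√(ρ/(1−ρ))/√Var(factor)` with ρ = 0.99 the target PCC and σ the
  member's own noise scale, which makes the realized member–member
  correlation ≈ ρ at any noise level (and the member–factor correlation
  √ρ). Two calibration constants were fixed by a priori power analysis:
  the factor shift of 5 keeps the triad members' Wald statistics clear of
  the BH threshold at the ~2300-gene scale, and the triad baseline of 2^11
  keeps the factor's low swing in a count-rich regime where the log-scale
  NB noise matches the σ used in the calibration. Realized triad PCCs land
  within ±0.05 of the target across seeds.
* **Target table** — all planted (miRNA, lncRNA) and (miRNA, mRNA) pairs
  plus `round(decoy_fraction × planted)` decoy pairs drawn among
  *non-planted* miRNAs and genes. Decoys model background interaction
  noise; because they never touch planted features, planted-triad recovery
  is exact whenever the correlation screens behave, which is the property
  the end-to-end tests assert.
* **Determinism** — all randomness flows through `numpy` Generators seeded
  from the config; fixed seed ⇒ byte-identical outputs.

### What the generator does not emulate

Real library-size heterogeneity beyond lognormal depth, batch effects,
GC/length biases, isoform structure, sex/age covariates, correlated gene
modules outside the planted triads, and array probe-affinity effects.
Passing tests therefore demonstrate that the pipeline's logic and
statistics behave as specified under the stated model — not that the
screens would reproduce a specific published gene list from raw public
data, which would require the original sequencing runs and annotation
release.

## Problem sizes used in tests and the acceptance script

Unit and property tests use a reduced budget (600 mRNA / 120 lncRNA /
120 miRNA) shared via a session fixture; the acceptance checks run the
full default budget once, 2000-gene null simulations for type-I error
(averaged over five replicates in the script, since size-factor estimation
noise is shared across genes and makes single-replicate rejection rates
overdispersed), a 500-probe array power simulation, and exhaustive oracle
enumerations (all 2×2 tables with universe ≤ 50 in the suite, ≤ 30 in the
script; all BH inputs of length ≤ 6 over a 7-point grid). The whole suite
runs in well under a minute on one CPU.

## Known limitations

* The NB Wald approximation will not numerically match DESeq2 (no
  shrinkage, different dispersion estimator); only screen-level behaviour
  is comparable.
* Pairing is ignored in the count branch (see above).
* The moderated-t prior fit uses the moments method on all probes with no
  robustification against variance outliers.
* The co-expression stage computes all pairwise correlations densely;
  it is intended for the post-subtraction feature sets (tens to hundreds
  of features), not genome-wide all-vs-all screening.
* The group-subtraction reading of "expressed only in the keloid group"
  is an interpretation; an interaction-term (group × time) model would be
  the rigorous alternative and is deliberately out of scope.
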