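# Methods

This note documents the models behind `degensim`, the defaults and why they
were chosen, the numerical decisions, and what the synthetic-data generators
do and do not capture about real degeneration experiments.

## Population model (popsim)

A culture is a set of **genotype classes**, each with a baseline relative
fitness, a frequency-dependence coefficient, a sporulation fraction, a
post-24 h hourly viability, solvent/acid yields, and a colony morphotype
(RD, DCOG, CIC, FW). One transfer cycle is:

1. **Germination** — transferred spores become vegetative founders
   (efficiency default 1.0; spores germinate readily in fresh medium).
   Without this step a 90%-sporulating wild type would need ~6.6 regrowth
   generations per 1:10 transfer; with it the cycle costs
   `g = log2(1/d) ≈ 3.32` generations, matching the ~16–17 generations a
   five-transfer series implies.
2. **Growth** — discrete Wright–Fisher generations double the population to
   carrying capacity `K` (the last step is partial). The realized
   per-generation fitness of class *i* is
   `w_i = baseline_fitness · (1 − freq_dependence · x_i)` with `x_i` the
   class's own current frequency; counts are multinomially resampled each
   generation.
3. **Mutation** — each generation, `Poisson(μ · daughters)` new one-cell
   lineages spawn, with `daughters = 2(N_next − N)` (two per division; a
   full doubling makes every cell a daughter). Parents are drawn
   proportional to class counts; each event picks a genomic region by the
   target weights, a substitution class by the spectrum, and founds a class
   whose parameters are the parent's patched by the region's effect
   template.
4. **Sporulation** — a binomial `sporulation_fraction` of each class's
   vegetative cells becomes spores (one-log vegetative drop for the wild
   type at the default 0.9).
5. **Post-24 h decay** — for transfer intervals beyond 24 h, vegetative
   cells of class *i* survive each extra hour with probability
   `post24h_viability_i` (spores are unaffected).
6. **Transfer** — binomial thinning at the dilution factor; in the
   heat-shock regime the transferred aliquot additionally loses all
   vegetative cells and its spores germinate.

Phenotype outputs (solvents, acids) are frequency-weighted class yields at
the end of growth; morphotype fractions and the allele-frequency truth table
are computed over the whole culture (vegetative + spores), mimicking plating
and pooled sequencing of a culture sample.

### Default parameters and calibration

| parameter | default | rationale |
|---|---|---|
| dilution factor | 0.1 | the 1:10 daily transfer protocol |
| transfer interval | 24 h (72 h variant) | study regimes |
| carrying capacity K | 10⁴ cells | scaled-down population; frequencies, not absolute CFU, are the object of study. Lineage tracking at the observed mutation-accumulation rate is tractable at this scale; per-operation APIs accept realistic K (10⁹) |
| mutation rate μ | 0.15 per daughter cell | calibrated so isolates sampled at transfer 5 carry on average ≈ 3.16 mutations (the observed accumulation over the ~20 lineage divisions from the starter colony). This is an *effective heritable-mutation rate* reproducing the observed load — far above per-bp biochemical rates, as the observed counts themselves are |
| substitution spectrum | 87% G:C>T:A, remainder uniform | the observed transversion bias |
| mutation kinds | SNP:del:ins = 211:12:2 | the observed catalogue composition |
| hotspot target weights | spo0A 0.0045, kinases 0.0035/0.0045, 0A-box 0.002 | calibrated jointly with the null-class fitness so the FW sweep follows the observed time course (≈ 8% at subculture 5, > 90% by 15) |
| WT class | fitness 1.0, sporulation 0.9, 7.2 g/L solvents, 2.0 g/L acids | one-log sporulation drop; peak productivity near 7.2 g/L with ~2 g/L acids |
| null-Spo0A template | fitness 1.14, freq-dependence 0.15, sporulation 0, solvents 0, viability 0.953/h past 24 h | no spores/solvents by definition; fitness and its decline put the competition crossover near 80% mutant share; viability gives ~90% loss between 24 h and 72 h, which is what stabilizes the 72 h regime |
| partial templates (kinase hits) | fitness 1.05–1.06, sporulation 0.30–0.35, reduced solvents | intermediate degenerates that still pass a heat shock |

Effect templates apply a "more degenerate wins" severity rule (WT < mild <
partial < null): a later hit in a milder region never reverts a null-Spo0A
lineage, while carrier (non-hotspot) hits copy the parent unchanged.

### What the simulator does not capture

* No within-transfer continuous-time dynamics, pH/metabolite feedback, or
  mechanistic acid-crash modeling — phenotypes are frequency-weighted
  yields only.
* Frequency dependence acts on each class's *own* frequency; several null
  lineages jointly exceed the single-mutant equilibrium, so terminal
  degeneration is more complete (solvents → ~0) than the observed ~80%
  decline.
* The transient dominance of the DCOG morphotype around subculture 5 is not
  reproduced; it would require phenotype plasticity or stronger
  kinase-mutant advantages than the endpoint data pin down.
* Fitness parameters for the mutant classes are illustrative calibrations
  to the qualitative trajectories, not fits to assay scatter.

Passing tests therefore demonstrate correctness of the bookkeeping,
statistics and filter logic under this generative model — not that the model
is a complete account of real cultures.

## Sequencing model (seqsim)

Per site: depth ~ negative binomial (mean 368, dispersion 26.8, giving
CV ≈ 0.2 like real coverage); reads split into "first-forward" /
"first-reverse" strata by a binomial at the orientation balance (0.5); alt
reads per stratum ~ `Binomial(n, af(1−ε) + (1−af)ε/3)` with ε = 0.001 per
base (a miscall hits one specific base a third of the time). Base qualities
are Normal(35, 3) floored at 20. Orientation strata are two abstract read
partitions; read-pair semantics, alignment and mapping quality are out of
scope. Indel sequencing errors are not simulated (the hotspot signal is
SNP-dominated).

## Filter cascade (varfilter)

External joint callers are not invoked; their consensus is re-specified as
two internal criteria on the same pileup:

* **Criterion A** — `qual = −10·log₁₀ P(X ≥ alt | Binomial(depth, ε/3))`,
  capped at 5000 (log-survival-function arithmetic avoids underflow);
  pass requires `qual ≥ 100` (non-strict, matching the rule's wording).
* **Criterion B** ("PASS" analogue) — Fisher-exact strand-bias screen
  (two-sided p ≥ 10⁻³), combined AF ≥ 0.01, depth ≥ 10.

Then the orientation rule (AF strictly > 0.04 in both strata, ≥ 4 reads per
stratum — the conservative per-stratum reading of the min-reads setting,
with a pooled-total alternative selectable — and mean base quality ≥ 20),
multiallelic splitting (per-alt counts preserved), and the trajectory rules:
AF > 0.08 (strict) in ≥ 3 subcultures of one replicate (non-consecutive by
default; a consecutive-run flag exists), exclusion intervals (rRNA, from
BED converted to 1-based inclusive), starter-culture AF ≤ 0.5 per replicate,
and a depth-artifact screen that generalizes a manual single-position
removal: Spearman |ρ(AF, depth)| ≥ 0.8 across ≥ 6 subcultures flags the
variant (disable with `depth_corr_threshold=None`). Sites failing
site-level rules enter trajectories as AF 0 (below detection). Labels
accumulate monotonically; a variant is kept iff its label set is empty, so
the cascade equals the conjunction of independently evaluated rules.

## Mutation statistics (mutstats)

Substitutions are collapsed to six base-pair classes (G→T and C→A both
report as G:C>T:A); transitions are G:C>A:T and A:T>G:C. Spectrum fractions
are over SNPs only. Every mutation is assigned to exactly one region — a
gene body (1-based inclusive; a hit at the start coordinate belongs to the
gene) or an intergenic region named by its flanking genes. Multi-hit
positions count once per record (per-isolate tabulation, no site
deduplication). The hotspot statistic is this package's definition: exact
upper-tail binomial test per region against the length-proportional null,
BH-corrected across all regions spanning the genome, enrichment at
q ≤ 0.05; a Poisson variant is available behind a flag. Binomial p-values
are discrete and therefore conservative: under a uniform null the
any-discovery rate stays below the nominal FDR.

## Fitness statistics (fitstats)

`w = [x₂(1 − x₁)]/[x₁(1 − x₂)]` requires interior proportions; boundary
values (a competitor below plating detection) return a flagged observation
rather than ±∞. Frequency dependence is declared negative iff the Spearman
correlation of w against x₁ is negative at α = 0.05 (Kendall's τ is
reported alongside as a pair-sign statistic); the w = 1 crossover is
estimated by monotone (running-minimum) interpolation of per-x₁ median w —
the data motivate "around 80%", not a parametric fit. Generations are
`n · log₂(1/d)`. Assay timepoints are recorded per observation and analyzed
stratified, not pooled. Series summaries measure the solvent change from the
series maximum to the final subculture (and the acid change from the same
reference subculture); morphotype dominance ties break in RD, DCOG, CIC, FW
order.

## Numerical and interface decisions

* Internal coordinates are 1-based inclusive everywhere; BED is converted
  at the boundary (half-open → inclusive) and merged.
* All randomness flows from one `numpy` Generator per run/series; identical
  seeds give bitwise-identical outputs (CLI runs echo a JSON manifest
  sufficient to reproduce them).
* Multinomial parent sampling during mutation spawning can, rarely, draw
  more events from a parent class than it has cells; counts are clipped at
  zero (a sub-cell-count correction at the default scales).
* Degenerate inputs: zero-depth sites are a scoring error; empty pileup
  tables produce empty outputs; zero-spore heat shocks and empty
  populations raise extinction errors; trajectory Spearman screens require
  ≥ 6 points and non-constant series.
* GFF3 parsing is a strict 9-column text parse with explicit line-numbered
  errors; VCF goes through pysam with a canonical text writer whose output
  is byte-stable under read/write round trips.

## Problem sizes

Tests and the acceptance script use the scaled-down study conditions
(K = 10⁴): 100 seeds per regime for the dominance/suppression checks, 200
simulated 30-observation fitness assays, 1,000 random pileup sites for
cascade/oracle parity, 10,000 sites per detection-limit point, and
400–1,000 uniform catalogues (225 mutations over a 6 Mb genome with 5,000
genes) for FDR calibration. Monte-Carlo standard errors at these sizes are
several-fold smaller than every asserted margin.
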