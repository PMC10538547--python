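# Methods

## Scope and data model

`heterosol` analyses label-free peptide-level intensity data from a
hybrid/allopolyploid design: two parental genotypes, one or more hybrid
genotypes, three subcellular fractions (whole-cell extract, soluble
supernatant, insoluble pellet), and biological replicates, one LC-MS run per
genotype × fraction × replicate. The quantification unit is the
**orthogroup**: the set of homoeologous/orthologous proteins across the two
parental proteomes. Raw spectra, database search, and FDR control are out of
scope; the pipeline starts from a peptide × run table of XIC peak areas
(missing observations are absent rows) plus parental FASTA proteomes and an
orthogroup membership table.

## Collapsed proteome and peptide assignment

Members of an orthogroup are concatenated in catalog order with a `KKK`
separator. Because trypsin cleaves after lysine, a fully tryptic peptide
with ≤2 missed cleavages cannot extend across the three separator lysines
into a second member, so orthogroup-collapsed entries behave as single
"proteins" during matching while retaining member coordinates (0-based,
half-open) for homoeolog-level work.

Digestion follows the standard trypsin convention: cleavage after K or R,
suppressed before proline (configurable), 0–2 missed cleavages, default
peptide length 6–50 residues. Assignment finds **every** occurrence of each
peptide in every collapsed sequence (k-mer-seeded exact substring search)
and derives:

- `unique_to_orthogroup` — all occurrences fall in one orthogroup;
- `subgenome_specific` — all overlapped members carry the same parent
  label (`parent1`/`parent2`), both parents (`shared`), or undetermined;
- `within_member` — at least one occurrence lies fully inside a member
  span. Peptides that touch separator lysines in *every* occurrence are
  collapse artifacts with no physical counterpart and are excluded from
  simulation and (by the uniqueness/quantification rules) play no role in
  abundance estimates. Separator-only lysine runs map to no member.

One caveat: a member whose sequence *begins* with proline would defeat the
separator (cleavage after the third K is suppressed, allowing a two-missed-
cleavage peptide to bridge members). Real proteins begin with methionine,
and the generator enforces this; the chimera-safety guarantee is stated for
Met-initial (more generally, non-Pro-initial) members.

I and L are treated as distinct residues by default (exact string match); an
`equate_il` mode collapses them, since mass spectrometry cannot tell them
apart.

## Quantification

Processing order is fixed: **filter → normalize → impute → TOP3**.

- *Filtering*: peptides observed in fewer than 3 runs are removed, then
  proteins left with a single peptide. The operation is idempotent.
- *Normalization*: each run's median log2 intensity is shifted to the global
  median of run medians (preserves overall scale; joint across fractions by
  default, per-fraction available).
- *Imputation*: a missing (peptide, run) cell is treated as left-censored at
  that run's minimum observed log2 intensity. Per protein, a Gaussian
  accelerated-failure (censored-normal) regression on log2 intensity with
  peptide and run covariates is fit by maximum likelihood (analytic
  gradient, L-BFGS-B, ridge 0.01 on non-intercept coefficients to keep
  levels observed only in censored cells finite). Censored cells are filled
  with the fitted truncated prediction E[y | y < bound], never above the
  bound; non-convergent fits fall back to the bound itself. Cells that are
  *structurally* absent — a subgenome-specific peptide of the other parent
  in a pure-parent run — are not imputed.
- *TOP3*: protein abundance per run is the mean log2 intensity of the three
  most intense peptides in that run (ties broken lexicographically for
  determinism; both peptides used when only two remain). Matrices are split
  by fraction. Whole-cell matrices are produced for QC; all downstream
  statistics run on the soluble/insoluble fractions.

## Statistical tests

**Nonadditive expression.** Per protein and fraction, a fixed-effects
group-means model on log2 abundance across the three genotypes (label-free
workflows conventionally fit a mixed model at feature level, as MSstats
does; with one TOP3 summary per run the fixed-effects model is equivalent). The MPV contrast
uses weights (1, −½, −½); the parent contrast (1, −1, 0). Standard errors
come from the pooled residual variance (df = N − 3); p-values are two-sided
t probabilities, deliberately uncorrected — with a fold-change gate
(|log2FC| ≥ 0.5 and p ≤ 0.05, thresholds inclusive) — because
Benjamini–Hochberg correction at this replicate level removes essentially
all calls; BH-adjusted p-values are available behind a flag. Proteins
require ≥2 measured replicates per genotype. The implementation is
closed-form and vectorized; tests verify exact agreement with an
independent OLS fit.

**Solubility.** Proteins must be quantified in every replicate of both
fractions for all three genotypes. The interaction test is a two-way ANOVA
on log2 abundance with fraction and genotype (both parents pooled as
"progenitors" vs hybrid); since the interaction is the highest-order term of
a 2×2 layout, its F test (df 1, N−4) is invariant to the sums-of-squares
type even though pooling makes cell sizes unequal. The solubility score
works on linear abundances: per replicate the soluble/insoluble ratio, per
genotype the **median** over replicates (the insoluble fraction is noisy),
`score = mean(parent medians) − hybrid median`. Classification at p ≤ 0.05
and |score| ≥ 0.5; the ±0.5 score threshold is a ratio difference whose
meaning depends on the abundance scale — the fixed ±0.5 value is retained
and should be interpreted with that caveat.

One consequence worth knowing: a pure solubility shift changes
soluble-fraction abundance by log2 of the share ratio without any change in
total abundance, so solubility-shifted proteins can legitimately appear
"nonadditive" in a single-fraction MPV contrast. This crosstalk is a
property of the design, not an artifact of the implementation.

**Homoeolog bias.** After discarding orthogroups whose subgenome-specific
peptides were observed in the wrong pure parent, observed specific-peptide
occurrences are counted per orthogroup per hybrid sample (presence-based;
an intensity-weighted mode exists behind a flag) and pooled per genotype.
A call requires a strictly >75% (>3:1) share; counts of zero are unbiased.
The pipeline counts over the soluble+insoluble runs only: the whole-cell
runs sit ~1 log2 unit above the fractionated runs, escape censoring almost
entirely, and therefore dilute the count asymmetry that carries the dose
signal (whole-cell matrices are QC-only throughout). The pooled per-genotype
call is the headline output; per-sample calls are retained. How per-sample
calls should aggregate to genotype level is genuinely open; pooling counts
before calling is this package's documented choice.

## Synthetic-data generator

The generator emulates a fractionated hybrid-proteomics design — 4 genotypes (two
parents, two reciprocal hybrids sharing truth; parent-of-origin effects are
not modeled) × 3 fractions × 3 replicates — with known injected effects.

Sequence level: per orthogroup one homoeolog pair (configurable), parent1
drawn uniformly over the 20 residues (Met-initial), parent2 derived by
independent substitutions at rate `aa_divergence` (default 0.05, a typical
congeneric protein divergence; it yields tens of subgenome-specific
peptides per orthogroup at default protein lengths of 150–400 aa).

Intensity level, per peptide j of orthogroup i in run r (log2):

    y = baseline_i + genotype effect + fraction split + bias term
        + offset_j + run effect_r + N(0, residual_sd)

- `baseline_i ~ N(22, 0.5)` log2 XIC units; peptide offsets N(0, 0.5); run
  effects N(0, 0.2); residual sd 0.3 — conventions, not estimates: replicate-level
  variance components are rarely reported for designs like this, so these
  were chosen once as plausible for well-behaved label-free data and kept.
- Parents sit at baseline; a hybrid deviates from the MPV by ±1 log2 unit
  for nonadditive orthogroups (15% of orthogroups by default).
- A soluble share s splits abundance: soluble runs add log2(s), insoluble
  log2(1−s); whole-cell runs are the linear sum (add 0). Parents have
  s = 0.5; solubility-shifted orthogroups (15%) move the hybrid to 0.73 (or
  0.27), i.e. a true score of ≈ ∓1.7.
- For biased orthogroups (15%), the favored subgenome's specific peptides
  are scaled by `bias_share` (0.9) and the disfavored by 0.1 in hybrid
  runs; shared peptides are untouched. Pure-parent runs contain only the
  peptides present in that parent's homoeolog.
- Missingness is left-censoring: an observation is dropped with probability
  logistic((19 − y) × 3). The threshold sits ~1 log2 unit below the typical
  fractionated-run intensity and ~2 units below the detectability band's
  center so that overall missingness is modest (~5–10%) while the −3.3 log2
  dose drop of a disfavored homoeolog pushes its peptides below the limit —
  the mechanism by which presence-based counting can see a 9:1 dose ratio
  at all. This geometry was chosen by design calculation before any
  recovery test was written. Censoring can be disabled with
  `censor_threshold = -inf`.

What the generator does **not** emulate: retention-time/charge structure,
ionization competition, peptide-level interference, contaminants (the
cross-match discard rule therefore fires only on constructed fixtures),
parental expression divergence, correlated replicate effects, and
non-Gaussian heavy tails. Passing recovery tests therefore demonstrates the
pipeline's logic and calibration under a faithful censored log-normal
model, not performance on any particular real dataset.

An abundance-level panel simulator (`simulate_abundance_panel`) provides
protein-level matrices with injected deltas or share shifts for the
calibration studies (type-I error on 10,000 null proteins, recovery on
1,000 effect proteins at n = 3); running sequence-level simulation at that
scale would add runtime but no information about the statistics under test.

## Numerical choices

- TOP3 ties broken by lexicographic peptide sequence; all pipeline stages
  byte-deterministic for a fixed seed (manifest records SHA-256 checksums).
- Zero residual variance in a contrast yields p = 1 when the estimate is 0
  and p = 0 otherwise (degenerate but deterministic).
- The ANOVA uses QR-projection residual quadratic forms shared across
  proteins (the design is identical per protein after the completeness
  rule); F is clipped at 0 against floating-point cancellation.
- Imputation ridge 0.01; σ parameterized as log σ; starting values from
  observed-cell moments.
- Coordinates are 0-based half-open everywhere.

## Known limitations

- The bias classifier's power depends on censoring geometry: orthogroups
  abundant enough that even a 10% dose survives detection show no count
  asymmetry (seen in practice for baselines ≳2 sd above the mean when
  whole-cell runs are included — one reason they are excluded from
  counting).
- The solubility score's ±0.5 threshold is scale-dependent (see above).
- Separate hybrid genotypes are tested independently against the same MPV;
  no joint modeling of reciprocal hybrids.
- The AFT imputation assumes the censoring bound equals the run's minimum
  observed intensity, which overstates the true detection limit slightly;
  imputed values are accordingly conservative (small negative bias,
  verified against ground truth in the tests).
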