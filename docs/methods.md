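# Methods

## Scope and data model

chemgenfit analyzes pooled competitive-growth screens of barcoded deletion
libraries. The in-memory containers are deliberately plain: a strain
catalog (`strain_id`, `gene`, `uptag`, one gene per strain), a design table
(`sample_id`, `compound`, `role` ∈ {treatment, control}, `pair_id`,
`batch`, `replicate`, and per-sample population doublings `generations`),
an integer count matrix (genes × samples, every catalog strain present even
when all-zero), and a long-format fitness table (gene × inhibitor:
`log2_effect`, `p_value`, `q_value`, `significant`, `direction`). All
on-disk formats are plain text (TSV, GMT, CDT, Newick, FASTQ).

Control samples carry the compound they serve (with `role = control`)
rather than a generic "control" label; this makes the treatment→control
mapping explicit and lets unpaired compounds (analyzed with an intercept +
treatment design instead of pair blocks) keep dedicated controls.

## Synthetic screens

The generator emulates the design of anaerobic chemical-genomics screens of
a drug-sensitized deletion library: ~4309 strains (any size works), a
compound panel with paired in-plate controls and biological triplicates,
and 6.5–10 total population doublings per plate (drawn uniformly per
replicate pair and enforced as an invariant).

**Effect model.** Genes are assigned to classes — neutral (default 70%),
beneficial-only (10%), deleterious-only (10%), antagonistic (10%) — by
largest-remainder allocation, so realized fractions match requested ones to
rounding. Compounds are partitioned into classes (default 2); a non-neutral
gene carries a class-level effect `|s| ~ U[0.1, 0.5]` (log2 per doubling)
in each affected compound class (each with probability 0.7, at least one;
antagonistic genes affect ≥ 2 classes with mixed signs, guaranteed). Every
compound in a class inherits the gene's class effect times a multiplicative
jitter `U[1−j, 1+j]` (default j = 0.15), which both preserves signs above
the floor `0.1·(1−j)` and enforces strongly correlated truth columns within
a compound class.

**Counts.** Expected frequencies propagate deterministically,
`p ∝ f₀ · 2^(G·s)` (controls `s = 0`), and all stochasticity enters at
sequencing: reads are gamma-Poisson (negative binomial) with per-gene
dispersion (default 0.05) around `p · depth` (default 2×10⁶; the demo
configs use smaller depths). This keeps closed-form expectations available
for oracle tests. Initial frequencies are log-normal (σ = 0.25) to mimic
uneven pool composition.

**Pairing.** Members of a replicate pair share a gene-wise log-normal batch
factor (σ default 0.3) and a common sequencing depth. The factor must be
gene-wise: a scalar per-pair factor would be absorbed into library-size
offsets and pairing would buy nothing. With σ ≥ 0.3 the paired model
demonstrably out-powers the unpaired one on identical data.

**What the generator does not emulate:** PCR jackpotting and chimeras,
index hopping, down-tag barcodes, plate-position gradients beyond the
scalar-per-gene batch term, strain-frequency drift between passages, and
dose–response structure. Passing tests therefore demonstrate correctness of
the inference machinery under a clean NB competition model, not robustness
to every artifact of real bar-seq data.

## Barcode counting

A read is assigned to the unique strain whose barcode matches the length-L
substring at a fixed offset within `max_mismatches` substitutions
(default 1); a read equidistant from two barcodes at the minimal distance
is ambiguous and discarded, and `assigned + ambiguous + unmatched +
too_short = total` holds per sample. Matching is exact-hash first, then a
precomputed 1-substitution neighborhood hash; `max_mismatches ≥ 2` falls
back to a vectorized Hamming scan. No quality filtering and no indel
alignment: barcodes are short, fixed-length, and at fixed position in the
synthetic dialect (an `offset` parameter covers other layouts).

## Differential fitness

**TMM.** Scaling factors are weighted trimmed means of M-values against a
reference sample (the one whose upper-quartile count proportion is closest
to the mean), trimming 30% by M and 5% by A symmetrically, weights from
the delta-method asymptotic variance, factors rescaled to geometric mean 1.
Genes with a zero in either sample are excluded from that pairwise factor.

**Dispersion.** For each contrast, the NB dispersion is profiled on a
19-point log grid (10⁻⁶ to 4) using the Cox–Reid adjusted profile
likelihood with all per-gene GLM fits batched across genes; grid maxima are
refined by quadratic interpolation in log φ. Three estimates are exposed:
per-gene maxima, an abundance-binned trend (the APL summed within bins of
≥ 50 genes, maximized per bin, interpolated across abundance), and a 60/40
gene/trend log-space blend (the shrinkage weight is configurable).

**Testing.** The fitted GLM uses the *trend* dispersion by default. At 2–3
residual degrees of freedom the per-gene APL maxima are strongly skewed
(many at the floor), and using them — or a blend dominated by them — in the
GLM makes the test anti-conservative. With the trended dispersion in the
GLM, gene-level dispersion variability is carried instead by the
quasi-likelihood dispersion `s² = deviance/df`, squeezed across genes by
empirical Bayes (scaled-F moment matching on log s²; the prior df may be
infinite when variances are less variable than chi-square noise). The
treatment coefficient is tested by `F = Δdeviance / s²_post` on
`F(1, df + df_prior)`. Measured on null screens (2000 genes, 6 compounds,
3 pairs, 20 seeds) this gives type-I error ≈ 0.046 at α = 0.05 and ≈ 0.010
at α = 0.01, with mean BH false-discovery proportion ≈ 0.03 — the
calibration the acceptance suite asserts. Deviance differences below 10⁻⁸
are treated as exact nulls (numerically perfect fits otherwise divide by a
floored variance).

`log2_effect` is the treatment coefficient of the same model refit with a
prior count of 0.5 added to every observation (stabilizing zeros), divided
by ln 2. Genes with zero counts across a contrast are untestable: NA
effect and p-value, excluded from the BH family. BH is applied within each
inhibitor by default (`global_fdr` pools instead), and significance is
`q < 0.05` strictly.

## Antagonism statistics

Per gene, `n_beneficial` and `n_deleterious` count inhibitors with a
significant effect of each sign; `prop_beneficial` divides by significant
conditions only; the gene class is antagonistic iff both counts are ≥ 1.
The pairwise antagonistic proportion of inhibitors (i, j) divides
antagonists by the union of significant deletions of the pair; the default
`both-significant` rule requires significance in both with opposite signs
(the stricter reading), while `union-signed` accepts significance in ≥ 1
with opposite-signed point estimates. Focal intersections follow UpSet
semantics: each gene in the union of opposite-sign sets `S_o` is counted
under exactly the membership pattern it matches, so exclusive sizes sum to
`|∪ S_o|`.

## Profiles and clustering

Inhibitor correlation uses Pearson r over pairwise-complete rows of the
log2-effect matrix restricted to the significant union (≥ 3 complete rows
per pair enforced; a constant column is an error naming the column),
followed by average-linkage clustering on `1 − r` with Newick export.
Cutting the dendrogram into named inhibitor classes is a human step; a
`cut` convenience is provided.

Gene clustering fits a k-component Gaussian mixture whose components share
one isotropic covariance σ²I ("EII": spherical, equal volume) by EM:
k-means++ initialization (best of `n_starts` by final log-likelihood),
log-sum-exp responsibilities, closed-form M-step with a single pooled σ²
(floor 10⁻⁸), convergence when the log-likelihood gain drops below `tol`.
A component emptied during EM is re-seeded at the worst-explained point;
the recorded trace restarts there, so the non-decreasing-trace invariant
refers to the final uninterrupted EM run. Missing log2 effects are imputed
as 0 (no fitness effect is the natural neutral value) and counted on the
result. Genes are ordered within clusters by average-linkage hierarchical
clustering on `1 − Pearson` (constant rows get distance 1), and the
cluster-ordered matrix is written as a CDT file that round-trips through
the package's own reader byte-identically.

## Enrichment

Hypergeometric upper tails are computed exactly. For each inhibitor the
significantly beneficial and significantly deleterious lists are tested
separately against each set; the universe defaults to genes *tested* for
that inhibitor (conditioning on testability; `all` and `union` modes
exposed). `p ≤ 1e-4` is enriched, deliberately without multiplicity
correction: functional categories overlap heavily and FDR methods
over-correct in that regime.

Diagnostic sets from a reference compendium (compound × gene z-scores with
compound → response-signature labels): gene g joins `Lee_Positive(S)` when
its compounds with z > 3.09 concentrate in S beyond chance — upper-tail
hypergeometric with population = all reference compounds, successes = |S|,
draws = g's significant compounds of that sign, association cutoff 10⁻³
(the z threshold is fixed by convention; the association cutoff is a free
parameter and exposed). Negative scores are treated symmetrically. The
per-gene compound-count formulation is implemented; a pooled-event
formulation (population = all significant (compound, gene) events) is a
documented alternative reading.

The signed matrix keeps category × inhibitor cells passing the cutoff on
either list as `sign · (−log10 p)` (beneficial positive, deleterious
negative; when both lists pass, the smaller p wins and an exact tie is
zeroed and flagged), then clusters rows and columns by average linkage on
Euclidean distance.

## Growth curves

AUC is the trapezoidal integral of OD600 over time (≥ 3 points, strictly
increasing time); relative growth is 100 × AUC(treated)/AUC(control). ICx
interpolates the dose giving (100 − x)% relative growth linearly in log10
dose after projecting the dose–response onto a non-increasing curve
(isotonic regression; any adjustment is flagged); an unbracketed level is
an error. Doubling time is ln 2 / slope of the best sliding window on
ln OD (default 10 points, R² ≥ 0.98, positive slope), NA with a reason
otherwise; mutant doubling times divide by the mean wild-type doubling
time of the same batch.

## Orchestration and determinism

`RunConfig` is a pydantic model with `extra="forbid"` at every level, so an
unknown YAML key fails before any stage runs. Every seed is explicit;
downstream stage seeds derive from the run seed by fixed offsets. All float
output goes through a fixed `%.6g` format, and the manifest records a
SHA-256 per output: rerunning an unchanged config reproduces every
non-log output byte-identically.

## Problem sizes used in verification

The test and acceptance runs use 250–2000 genes, 4–6 compounds, depths of
8×10⁴–2×10⁶ reads/sample, and 8–20 replicate simulations per property —
sizes chosen so the whole suite verifies every stage in about a minute
while keeping each check's statistical resolution (e.g. 96 000 null
p-values for calibration, ~1500–2000 strong planted effects for
sensitivity). The planted-recovery conditions (|s|·G ≥ 2, dispersion 0.05,
depth 2×10⁶, 3 pairs) delimit where ≥ 90% sensitivity is promised; weaker
effects, higher dispersion, or shallower sequencing degrade recovery
gracefully but are outside the guarantee.

## Known limitations

- The QL F-test's calibration is verified under the generator's NB model;
  real screens with UMI-free PCR duplicates or strain cross-contamination
  may be over-dispersed beyond NB.
- Dispersion trends assume enough genes per abundance bin (≥ 50); very
  small panels fall back to a common dispersion.
- The EII mixture fixes k; no BIC model selection, and other covariance
  families are out of scope.
- GO-style sets are flat (no ontology propagation).
- The ICx interpolation assumes a monotone dose response after isotonic
  projection; strongly hormetic curves are flagged but not modeled.
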