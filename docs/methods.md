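# Methods

This note records the models implemented, the synthetic cohort they are
exercised on, the numerical conventions, and the design choices made
where the procedure was genuinely open.

## Statistical conventions

Group comparisons are non-parametric throughout: two-sided Mann–Whitney U
for two groups, Kruskal–Wallis for three, Spearman rank correlation (tie
corrected) for associations, Benjamini–Hochberg step-up for multiplicity.
Degenerate inputs (constant vectors) return p = 1 for rank tests and NaN
("undefined") for correlations rather than raising.

## Variant cascade and burden score

A variant qualifies when it passes, in order: a two-sided Fisher exact
test on case/control **carrier** counts (p < 0.05), a protein-coding
region restriction (exonic; splicing behind a flag), a deleteriousness
rule — protein-truncating (frameshift / nonsense / stop-loss), or
missense with REVEL > 0.75 (strict) or at least two damaging calls among
SIFT, PolyPhen2-HDIV, PolyPhen2-HVAR, LRT, MutationTaster — and a gnomAD
allele frequency below 5%, with a missing frequency treated as 0 (novel
variants pass). Missing predictions never count as damaging. Non-frameshift
indels do not qualify by default (`include_inframe` admits them). Mode of
inheritance never filters; trio origin (de novo / maternal / paternal /
biparental / uncertain) is annotation only.

The burden score counts distinct qualifying variants carried (genotype
> 0) within the gene set; allele-dosage counting is behind a flag. The
median split puts ties in the LOW stratum — "high burden" is a strict
exceedance — and a constant score vector is reported as not-applicable
rather than tested. Carrier-count rather than allele-count Fisher testing
was chosen for robustness to genotype-quality noise; both are exposed.

Gene-set enrichment is a local one-sided hypergeometric
over-representation test against a GMT collection with BH adjustment
(no web-service dependence).

## Microbiome profiling

Shannon uses the natural logarithm; evenness is Pielou's H/ln S (0 when
S ≤ 1); Chao1 is always bias-corrected, S + F₁(F₁−1)/(2(F₂+1)), which is
defined even when F₂ = 0; ACE uses the standard rare/abundant split at
10 reads. Counts are never rarefied — depth differences are handled by
relative abundance, which also feeds ordination and biomarker discovery
(a flag switches to counts).

PCoA applies Gower double-centering and an eigendecomposition; negative
eigenvalues (Bray–Curtis is a semi-metric) are reported but excluded
from the proportion-explained denominator and carry zero coordinates.
PERMANOVA partitions squared distances, permutes labels freely (no
strata), and requires an explicit seed; p = (1 + #{F* ≥ F})/(1 + n_perm).

The LDA-effect-size biomarker procedure has two stages. Stage 1 filters
taxa by Kruskal–Wallis (Mann–Whitney for two classes) at α = 0.05.
Stage 2 rescales the surviving abundance submatrix to a common
[0, 10⁶] range and, over 30 bootstrap resamples, computes a regularized
Fisher discriminant (pooled covariance + small ridge) one-against-all
per class. The per-taxon effect is pinned as

    0.5 · ( |Δμᵢ| + |ŵᵢ · Δμᵢ| )

— the average of the raw rescaled between-class mean difference and the
component of the projected difference carried by the taxon, with ŵ the
unit-norm discriminant. On a one-feature problem ŵ = 1 and the effect is
exactly the rescaled mean difference. The reported score is
log₁₀(1 + effect), kept when it exceeds 2. The original tool
under-specifies its effect formula; this definition is frozen here, with
a brute-force oracle in the tests, and planted-biomarker recovery — not
equivalence with any particular implementation — is the correctness
criterion. No subclass (within-class Wilcoxon) stage exists because the
study design defines no subclasses.

## Co-occurrence networks and stability

Per-group networks use pairwise Spearman on prevalence-filtered
(≥ 20% of samples) proportions, BH across all pairs, keeping edges with
q < 0.05 **and** |ρ| ≥ 0.6; the source publication states no thresholds,
so these defaults are recorded in every output's metadata and are
CLI-configurable. Edge sign is sign(ρ). Natural connectivity is computed
on the unweighted 0/1 adjacency spectrum, ln((1/n) Σ e^{λᵢ}), via an
overflow-safe log-sum-exp; a weighted |ρ| variant is behind a flag.
Robustness curves remove nodes cumulatively (5% steps), either in seeded
random orders (mean ± sd over 20 repeats) or by descending degree with
ties broken by node identifier.

## Metabolite modules

Intensities are log(1+x)-transformed and the 1,000 most variable
metabolites retained. The soft threshold is the smallest power β ∈ 1..20
whose signed scale-free fit R² (log₁₀ binned frequency vs log₁₀
connectivity; negative when the slope is positive) reaches 0.85,
otherwise the argmax with a warning flag. Adjacency is unsigned,
|Pearson|^β on the log scale. TOM follows the standard shared-neighbor
formula; note TOMᵢⱼ ≥ aᵢⱼ does **not** hold in general and is not
asserted.

Tree cut: average-linkage clustering of 1 − TOM, cut at the merge height
that maximizes the number of clusters of size ≥ 30 (ties resolved toward
the **highest** such height, so sub-branches of one module are absorbed
before distinct modules merge), followed by a kME refinement — each
metabolite reassigned to the module whose eigenprofile it correlates
with most, metabolites with max |kME| < 0.5 and modules falling under
the minimum size dissolving into grey. This is a documented
simplification of adaptive branch cutting; planted-partition recovery is
its correctness criterion. Colors are assigned by decreasing size from
the conventional palette (turquoise, blue, brown, ...). Eigenprofiles are
the first principal component of the standardized member columns, unit
norm, oriented so the mean member correlation is non-negative.
Module–trait correlations are Spearman over the **case** samples, since
severity scores and GI flags are case phenotypes (the printed r/p pairs
are consistent with n = 25).

Volcano calls use Mann–Whitney q < 0.05 and |log₂FC| ≥ 1 on raw-scale
group means with pseudo-count 1; PLS-DA VIP (mean VIP² = 1 by
construction) is reported alongside, and the intersection rule is left
to the caller.

## Integration

NMDS minimizes Kruskal stress-1 by majorization (SMACOF) with monotone
regression, best of 10 seeded restarts. Procrustes uses the symmetric
statistic — both configurations centered and scaled to unit total
variance, M² = 1 − (Σ singular values)² ∈ [0, 1] — and PROTEST permutes
the rows of the second configuration (10,000 draws by default). The
metabolome ordination feeding Procrustes is Bray–Curtis on
min-max-scaled log intensities of the differential metabolites
(Bray–Curtis requires non-negativity). dbRDA regresses the positive
principal-coordinate axes on the constraints; the constrained proportion
is fitted variance over total positive-eigenvalue variance, monotone
under added constraints. Regression is per-outcome OLS with t-quantile
95% Wald intervals (small-n practice), rejecting singular designs by
name.

## The synthetic cohort

The generator emulates a 51 ASD / 51 TD cohort (25 + 25 metabolomics
subset). Its defaults are the study conditions; every planted quantity
is recorded in a ground-truth ledger. All randomness flows from one seed
through fixed per-stage streams, so identical configurations are
byte-identical on disk.

**Clinical.** Phenotype flags are Bernoulli at the published ASD
frequencies (constipation 36/51, diarrhea 18/51, insomnia 18/51,
hypersomnia 11/51, urinary symptoms 21/51, repetitive behaviors 42/51);
TD controls use typical background paediatric rates (10%, 8%, 10%, 5%,
5%, 2%). CARS = 35.5 + 3.47·diarrhea + N(0, 4²) for cases (TD ≈ 17.5),
clipped to [15, 60]; ABC = 55 + 14.82·insomnia + N(0, 18²), clipped to
[0, 158]. The noise scales give the planted betas detection power ≥ 0.8
at n = 51. The published scales' true distributions are unknown; these
are emulations, not fits.

**Variants.** Nine qualifying MUC-pathway variants (annotations modelled
on the published table: seven damaging missense, one frameshift, gnomAD
frequencies down to 0) plus ~190 decoys that each fail one cascade stage.
The per-subject true burden is Poisson with case/control rate ratio 3.5
(geometric-mean rate 1.87) coupled to CARS through a Gaussian copula
whose mixing coefficient is solved numerically (internal fixed-seed
Monte-Carlo bisection) so the realized cohort-level Spearman(burden,
CARS) hits the 0.32 target despite Poisson discretization and the group
asymmetry. The explicit case enrichment is needed because a rank
correlation of 0.32 alone cannot make individual variants detectable by
a 51-vs-51 carrier-count Fisher test; it is a separate planted effect,
zeroed in the null configuration. Trios are 11 de novo + 1 maternal.

**Microbiome.** 200 genera with log-normal base abundances (log-sd 2.0),
per-sample log-normal noise σ = 1.5, multinomial sampling at 20,000
reads. Ten differential taxa at fold 5 (five per direction, using named
genera such as Faecalibacterium and Bifidobacterium) plus one
diarrhea-subgroup biomarker (Megamonas, fold 5 in ASD_D samples only).
The Shannon deficit (default 0.2 nats) is realized by knocking out a
calibrated number of randomly chosen taxa in case samples, with the
count solved by bisection against a Monte-Carlo estimate of the expected
per-sample Shannon. Because the knockout removes mass, compositional
closure inflates the realized case-side fold changes slightly beyond the
planted value. Within-group correlation comes from blocks of 8 taxa at
latent correlation 0.75 with a signed member pattern; the fraction of
negatively-signed members is solved from the target negative-pair
fraction (ASD 0.25, TD 0.45). Group-level sign patterns are shared when
the targets are equal, keeping the groups exchangeable under the null.

**Metabolome.** 1,000 metabolites; nine planted factor modules (sizes
150…35, within-module correlation 0.7) whose trait couplings carry the
printed magnitudes (diarrhea −0.52, −0.49, +0.41; CARS +0.40), planted
**within the case samples only** — controls receive pure factor noise, so
trait-linked modules are not group-differential by construction. Twenty
up- and 68 down-shifted metabolites at |log₂FC| = 2 emulate the
differential tally. These 88 are mutually correlated through the case
indicator, so an unsigned co-expression analysis legitimately detects
them as **one additional module**; the truth ledger records this
(`group_module`), and pipeline runs typically report 10 modules — the 9
planted plus the disease-driven block.

**Cross-omics coupling.** A per-subject latent gut-axis score (standard
normal, its own stream) loads on 40 abundant non-planted taxa (±0.8 on
the log scale, random signs) and on the differential metabolites (0.5 ×
coupling, aligned with their shift direction). This shared continuous
variation is what Procrustes/PROTEST detects; without it the metabolite
ordination degenerates into two group blobs and no concordance exists to
find.

**Null configuration.** `SyntheticConfig.null()` zeroes every planted
effect (copula, case enrichment, clinical betas, Shannon shift,
differential taxa and metabolites, module–trait couplings, negative-edge
contrast, cross-omics coupling) for type-I-error calibration of the
downstream tests.

**What the generator does not emulate:** phylogenetic structure and real
taxonomies, compositional interactions beyond closure, batch and
depth-per-sample variation, metabolite annotation/identification,
linkage between variants, and measurement error in clinical scales.
Passing recovery tests therefore demonstrates the pipeline's
correctness and power under the planted statistical structure, not
performance on real sequencing data.

## Problem sizes used in tests and the acceptance script

Unit tests run on small constructed fixtures and oracle problems
(n ≤ 15 for brute-force enumerations). Study-scale checks use the
default cohort (51+51, 200 taxa, 1,000 metabolites): 50 replicate seeds
for the burden and biomarker power checks, 200 for regression CI
coverage and null calibrations (at reduced sizes: 10+10 samples, 40
taxa, 199 permutations), 10 for the module-recovery runs. The acceptance
script averages 8 replicate cohorts for stochastic summaries, 40
clinical replicates for the regression betas, and runs PERMANOVA with
999 and PROTEST with 10,000 permutations on one cohort.

## Known limitations

* The scale-free criterion rarely reaches R² ≥ 0.85 on block-factor
  data (it is not scale-free); the argmax power is then used with a
  warning, exactly as flagged in the result object.
* The printed network connectance/edge counts of the study are not
  reproducible from raw data (the edge-inclusion criteria are unstated);
  only the metric identities are checked on them.
* Procrustes M² on synthetic cohorts scatters around the printed value
  (≈0.66–0.90 across seeds) because concordance strength is an emergent
  property of the coupling, not a directly planted parameter.
* p-values (PERMANOVA, Shannon contrast, burden split) are reported as
  computed; under planted effects they match the published values only
  in order of magnitude.
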