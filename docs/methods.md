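# Methods

## Data model

A *sample* is one dated sediment layer: a site label, depth (cm), calibrated
age (years cal BP; present = 1950 CE, larger = older, negative = post-1950),
total organic carbon, and mean mapping coverage per organelle. Because each
layer pools DNA from many organisms, genotype calls are not meaningful; the
per-locus observation is the **alternate-read fraction** `alt / (ref + alt)`
from the VCF AD field. Cells with zero depth are *missing*, never zero — an
uncovered locus carries no frequency information. Variant records are
biallelic SNPs only, filtered at an inclusive quality threshold Q ≥ 30;
positions stay 1-based (VCF convention) and a locus is keyed by
`(replicon, position)`. Reads are consumed as called, with no deduplication
anywhere in the pipeline: for short, fragmented sedaDNA, duplicate removal
discards real molecules and the calls are taken as given.

## Damage authentication

Cytosine deamination in ancient DNA concentrates C→T substitutions at 5′ read
termini, and the per-sample rate

    d = n(C→T at 5′ position 1) / n(reference C at 5′ position 1)

rises with deposition age. Authentication rests on two Pearson correlations
across samples: `corr(age, d)` should be positive and significant;
`corr(coverage, d)` should not be. p-values use the exact two-sided *t*
reference, t = r√((n−2)/(1−r²)). Only the first 5′ position is scored; other
positions and the 3′ end are parsed and retained but not used. Whether the
two organelles should be combined before computing rates is not established;
rates here combine both replicons (the misincorporation table carries no
per-organelle split).

## Diversity

Nucleotide diversity is per-site expected heterozygosity from pooled
frequencies, π = (1/L) Σᵢ 2pᵢ(1−pᵢ) over non-missing loci, with L the
organelle genome length (127,202 nt chloroplast, 43,586 nt mitochondrion).
π and the distinct-variant (phased haplotype) count are divided by mean
mapping coverage so layers sequenced to different depths are comparable; this
normalization is linear and is reported alongside the raw values. Haplotype
evenness uses Shannon entropy in nats and the Gini–Simpson index 1 − Σpᵢ²
(stated explicitly in output headers because three Simpson conventions
circulate). Site comparisons first restrict both cores to their overlapping
age interval [max of per-site minimum ages, min of per-site maximum ages],
then apply Welch *t* tests (no equal-variance assumption, Satterthwaite df);
coverage-normalized π values from both organelles are pooled into one vector
per site. Degenerate inputs where both groups have zero variance are reported
with a flag (p = 1 for equal means, p = 0 otherwise) rather than crashing.

## Differentiation (FST)

For one locus with pooled site frequencies p₁, p₂ and p̄ = (p₁+p₂)/2, the
between-site variance component is (p₁−p₂)²/4 and the total is p̄(1−p̄);
multi-locus FST is the ratio of sums over loci, skipping loci that are
missing in either site or monomorphic across both. No sample-size correction
is applied: the number of organisms pooled into a layer is unknowable, so the
uncorrected pooled-frequency form is the honest estimator. The windowed
variant slides a half-open age window [a, a + w) (defaults w = 1000 y, step
250 y) from the oldest sample age downward; within a window each site's
frequency vector is the per-locus mean over its samples, and windows missing
either site are emitted as missing with the per-site sample counts. The
window grid is anchored at the oldest sample so the first emitted window
contains it; edge windows therefore hold few samples, which is inherent to
sliding windows and visible in the reported counts.

## Allelic composition (PCA, PERMANOVA)

PCA operates on the samples × loci frequency matrix: loci are mean-centered,
not scaled; missing cells are imputed with the locus mean and the affected
loci recorded; all-missing loci are dropped with a warning. Decomposition is
by SVD, with explained-variance ratios s²ₖ/Σs² and a deterministic sign
convention (each component's largest-magnitude loading is positive).

PERMANOVA asks how much of the Euclidean variation in a coordinate space
(default: the first two PCs) one covariate explains. With D the distance
matrix, G = −½·J·D²·J its Gower-centered form, X = [1, x] and hat matrix
H = X(XᵀX)⁻¹Xᵀ: SS_model = tr(HGH), SS_total = tr(G), R² = SS_model/SS_total,
pseudo-F = SS_model / ((SS_total − SS_model)/(n−2)). Significance permutes
the covariate rows (raw-data permutation), p = (1 + #{F_perm ≥ F_obs})/(B+1),
default B = 999, seeded. Because H is idempotent and G doubly centered,
tr(HGH) = xcᵀG xc / xcᵀxc with xc the centered covariate, so permutations
cost one quadratic form each; the permutation loop is vectorized on this
identity and the observed statistic is still computed from the full trace
form.

## Allele turnover and its trend

All layers from both sites are merged into one series sorted oldest to
youngest (treating the sites as one population, appropriate when between-site
FST is low; a per-site run is available for sensitivity analysis). Layers
with identical ages are averaged into one pseudo-layer. For each consecutive
pair, a locus "changes" when both frequencies are observed and |Δp| strictly
exceeds the threshold (default 0.01; the strict inequality carries a 1e-12
guard so a change of exactly the threshold expressed in binary floats is not
counted). Turnover = n_changes / n_loci_compared / generations by default;
per-locus normalization makes intervals with different missingness
comparable, and the raw count ratio is available by flag. Generations =
elapsed years × `gens_per_year`; no generation time is established for the
study system, so the default 1.0 makes turnover "per year" — callers with a
generation-time estimate should set this explicitly.

The temporal trend is a P-spline: cubic B-splines on equally spaced knots
(default basis dimension 10) with a second-order difference penalty on the
coefficients, fitted by penalized least squares. The smoothing parameter
comes from generalized cross-validation, GCV(λ) = n·RSS/(n − edf)², searched
on a deterministic logarithmic grid that includes λ = ∞. The penalty null
space is the straight line in age (equally spaced knots give exact polynomial
reproduction), so λ = ∞ is solved exactly as OLS on that null space. Two
numerical guards: RSS below a relative floor (Σy² × 1e-24) is clamped so
exact fits rank by effective degrees of freedom, and candidates are scanned
smoothest-first so GCV ties resolve to the smoother model. The era contrast
reports mean fitted turnover younger vs. older than a boundary age (default
1500 cal BP) and their ratio.

**Interval-length sensitivity.** A thresholded change count is not linear in
elapsed time: when read-sampling noise contributes to |Δp|, the expected
count per interval is roughly constant, so turnover per generation scales
like 1/Δt. Comparing eras is therefore only calibrated when layer spacing is
comparable across eras; the calibration tests run both simulated sites on one
uniform age grid for exactly this reason. On real cores with denser recent
sampling, an elevated recent turnover should be read jointly with the
interval lengths reported per row in the output table.

## Bait design

Probes of length 80 nt are tiled per contig at step = length / coverage
(80/4 = 20 nt), starts 0, 20, 40, … while the probe fits; if the regular grid
does not reach the contig end, one end-anchored probe at `contig − 80` is
appended so 3′ ends are never uncovered (the report flags how many probes are
end-anchored, since they raise local coverage to 5×). Probes with more than
35% lowercase (softmasked) bases are discarded — the boundary is inclusive,
so exactly 28/80 masked bases is retained. GC content is reported over non-N
bases. Tiling is single-strand and never spans contigs; contigs shorter than
one probe are skipped with a warning. Reproducing any specific published
probe count would require the identical reference and masker, which is out of
scope; the counts here are interpretable via the report.

## Synthetic-core generator

The generator emulates the downstream products of a two-core organellar
capture study, with defaults chosen as the study-like conditions:

- **Design:** two sites — a basin-like core spanning 8148 → −71 cal BP and a
  gulf-like core spanning 4300 → −71 — with 13 layers each (26 samples);
  500 biallelic loci by default, 85% on the chloroplast; mean depths 575.5×
  (chloroplast) and 78.77× (mitochondrion), reflecting the copy-number
  contrast of organellar capture data.
- **Trajectories:** baseline frequencies p₀ ~ Beta(2,2); between layers
  separated by g generations, a Gaussian diffusion approximation to
  Wright–Fisher drift, p′ = clip(p + N(0, √(p(1−p)·g/(2Nₑ))), ε, 1−ε) with
  ε = 1e-4 and Nₑ = 1e5 (large, as befits marine phytoplankton — drift is
  slow and long-term composition stable). Drift variance is multiplied by
  `accel_factor` (default 5) for layers younger than 1500 cal BP, emulating
  recent acceleration.
- **Events:** reversible excursions — within an event window, an affected
  fraction of loci receives an additive shift ~ N(0, shift_sd) that is
  removed after the window, so earlier compositions re-emerge. Defaults: a
  mid-Holocene window (7000–6000) and a medieval-era window (1100–700), each
  shifting 25% of loci with sd 0.12.
- **Sites:** both sites share the latent trajectory plus constant per-locus
  offsets ~ N(0, σ_site); the default σ_site = 0.172 was derived analytically
  to put the latent multi-locus FST near 0.08 (with E[p(1−p)] = 0.2 under
  Beta(2,2), FST ≈ (σ²/2)/(0.2 − σ²/2)), i.e. differentiated but clearly one
  interbreeding population.
- **Observation:** depth ~ Poisson(mean depth), alt reads ~ Binomial(depth,
  p); loci with ref C and alt T receive extra apparent alt reads at the
  age-dependent damage rate d(age) = d₀ + (d_max−d₀)(1−e^(−age/τ)) (defaults
  d₀ = 0.005, d_max = 0.05, τ = 2000 y), and the misincorporation table
  tallies first-position C→T counts at the same d(age). Variant qualities are
  Gamma(4, 20) (mean 80, ~9% below Q30) so the quality filter is exercised.
  Haplotype counts are multinomial draws from layer-specific Dirichlet
  mixtures over 20 latent haplotypes; TOC is drawn independently, i.e. a null
  covariate by construction.
- **Randomness:** one root seed; per-sample substreams are keyed by
  (seed, site, layer index) so adding layers never perturbs existing ones;
  reruns are byte-identical.

What the generator does **not** emulate: read-level sequences (no FASTQ, no
mapping artefacts), selection, spatial migration beyond the constant site
offset, age-model uncertainty, taphonomic loss, or reference bias. Passing
recovery tests therefore demonstrates that the estimators recover the
generative model's truth under realistic sampling noise — not that the
biological model is correct for any particular water body.

## Problem sizes and numerical conventions

Tests and the acceptance script run at desk scale: 200–400 loci, 26 layers,
20–50 simulation replicates per property (400–500 for null-calibration rates,
where the binomial standard error of the rate matters), 199–999 permutations.
The statistics converge well below these sizes; larger runs only tighten
Monte-Carlo error. Other conventions: duplicate loci are an error, not a
merge; PCA requires ≥ 2 samples and ≥ 2 loci; correlations require ≥ 3 paired
values and error on zero variance; FST returns missing (not 0) when every
locus is unusable; table round trips preserve floats to full repr precision.

## Known limitations

- Pooled alternate-read fractions conflate organism abundance with allele
  frequency; all downstream quantities inherit this (standard for sedaDNA).
- The variance FST has no sample-size or depth correction, so binomial read
  noise inflates it slightly at low depth; the recovery test quantifies this
  against latent truth.
- The turnover statistic's interval-length sensitivity (above).
- Locus-mean imputation before PCA shrinks missing-heavy loci toward zero
  contribution; imputed loci are listed in the result.
- The GAM is a single smooth of turnover against age with Gaussian errors; it
  is a trend summary, not a generative model of the change process.
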