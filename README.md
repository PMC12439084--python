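# sedapop

Temporal population genomics of organellar **sed**imentary **a**ncient DNA.

Dated sediment layers preserve degraded DNA of past plankton communities, so a
pair of sediment cores is a millennia-long time series of a species'
population-genetic state. `sedapop` implements the full downstream analysis
for pooled organellar (chloroplast + mitochondrial) sedaDNA from two sites:

- **Damage authentication.** The C→T substitution rate at the 5′-terminal read
  position, `d = n(C→T) / n(ref C)`, must increase with layer age (Pearson
  correlation with a two-sided *t* test) and be unrelated to mapping coverage
  — the standard argument that the signal is ancient, not artefactual.
- **Coverage-normalized diversity.** Nucleotide diversity from pooled allele
  frequencies, π = (1/L) Σᵢ 2pᵢ(1−pᵢ), and distinct-variant (haplotype)
  counts, both divided by mean mapping coverage; haplotype evenness via
  Shannon entropy H = −Σ pᵢ ln pᵢ and Gini–Simpson D = 1 − Σ pᵢ²; Welch
  *t* tests between sites restricted to their overlapping time window.
- **Differentiation through time.** Wright's variance FST on pooled
  frequencies: per locus, numerator (p₁−p₂)²/4 and denominator p̄(1−p̄),
  aggregated as a ratio of sums over loci, computed globally and in sliding
  age windows.
- **Allelic composition.** PCA of the loci × layers frequency matrix and a
  single-covariate PERMANOVA (McArdle–Anderson trace form, raw-data
  permutation) testing whether damage rate or total organic carbon explains
  PC-space variation.
- **Allele turnover.** Between consecutive dated layers, the fraction of loci
  whose frequency changed by strictly more than 1%, per generation; its
  temporal trend is a penalized cubic regression spline (P-spline, GCV-chosen
  smoothness) with a recent/ancient era contrast.
- **Capture-bait design.** 80-nt probes tiled at 4× (20-nt step) over a
  softmasked reference, discarding baits with more than 35% masked bases.
- **A synthetic-core generator** that emulates all of the above — drift with
  punctuated reversible event shifts, recent drift acceleration,
  age-increasing terminal damage, binomial read sampling on Poisson depths —
  and emits the exact input formats plus a ground-truth record, so every
  stage is testable without external data.

It is aimed at palaeogenomics / environmental-DNA researchers who have variant
calls (VCF), sample metadata, phased haplotype counts and mapDamage-style
misincorporation tables, and want a reproducible, tested path from those files
to the population-genetic time series.

## Worked example

Generate a synthetic two-core dataset (26 dated layers across two sites,
400 biallelic loci on two organelle replicons) and run every stage:

```bash
sedapop simulate --seed 11 --n-loci 400 --outdir core
sedapop all \
  --vcf core/variants.vcf --metadata core/metadata.tsv \
  --haplotypes core/haplotypes.tsv --misincorporation core/misincorporation.tsv \
  --outdir run --seed 11
```

which prints

```
done: 368/400 variants retained; outputs in run
```

(32 simulated variants fell below the inclusive Q ≥ 30 quality filter), and
writes `run/tables/` with the per-stage outputs and `run/manifest.json` with
the seed, config echo and SHA-256 checksums of all inputs and outputs.
Highlights from this run:

- `damage_correlations.json`: damage–age R = 0.84, p = 7.3e-08 — the
  simulated deamination curve is recovered as a strongly significant age
  signal across the 26 layers.
- `fst_windows.tsv`: sliding-window FST between the two sites; windows
  containing a single site are reported with an empty FST and the per-site
  sample counts, e.g. `(1, 0)` for the oldest basin-only windows.
- `era_contrast.json`: mean fitted turnover 0.00647 per generation younger
  than 1500 cal BP versus 0.00309 older — ratio 2.09, reflecting the
  generator's built-in recent drift acceleration.

The same stages are callable as a library (`sedapop.read_vcf`,
`sedapop.multilocus_fst`, `sedapop.turnover_series`, `sedapop.fit_gam`, …);
the subcommands `baits`, `damage`, `diversity`, `structure` and `turnover`
expose the individual stages.

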