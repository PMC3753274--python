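# Methods

## Problem setting and model assumptions

The package analyses single-end ChIP-seq of proteins that occupy the
mitochondrial genome. Two occupancy regimes are distinguished:

- **Coating (diffuse) binding**: occupancy probability is flat along the
  molecule, so the ChIP read profile is the input profile rescaled —
  including whatever smooth sequencing bias both libraries share. No
  position shows strand asymmetry.
- **Point-source binding**: protein bound at a fixed position is
  crosslinked to fragments whose midpoints cluster at the site. Since each
  fragment is sequenced from one 5′ end on a random strand, `+`-strand 5′
  ends pile up half a fragment upstream of the site and `−`-strand 5′ ends
  half a fragment downstream; the inter-strand offset equals the fragment
  length (~200 bp here).

The assumptions: fragments are ~200 ± 20 bp (size-selected), reads are
36 bp after trimming, mapping is exact (zero mismatches), and chrM is a
circular 16,569-bp molecule present at high copy number so that an input
library samples it in proportion to its mass fraction of total DNA.

## Synthetic reference bundle

`make_chrm_reference` draws a uniform-random A/C/G/T sequence of 16,569 bp
and attaches a fixed annotation using the public human mitochondrial gene
layout (13 protein-coding genes, 22 tRNAs, 2 rRNAs, D-loop wrapping the
origin, promoters with 22-bp footprint features, replication origins).
Random sequence avoids shipping a real genome while keeping every
coordinate-based statement meaningful; a user-supplied mitochondrial FASTA
can be substituted (`load_chrm_reference`). Two coordinates matter
downstream and are fixed by the layout: the putative binding site feature
is centred at 5175 (1-based) inside the ND2 ORF, and the light-strand
replication origin O_L starts at 5721, i.e. 546 bp downstream of the site
centre.

`make_nuclear_decoy` builds linear random contigs (default 5 Mb across
two contigs) and plants:

- **NUMTs** — copies of chrM intervals carrying exactly
  `round(divergence × length)` substitutions at distinct positions
  (default 3 NUMTs of 0.8/1.5/3 kb at 5% divergence). At 5% divergence a
  36-bp window is substitution-free with probability ≈ 0.16, so a small,
  quantifiable share of NUMT reads still maps perfectly to chrM — the
  ambiguity the two-pass partition is designed around. Divergence 0 makes
  a NUMT a guaranteed multiread source.
- **Repeats** — 500-bp blocks duplicated at a second locus. The registry
  records each core plus 300 bp of unique flank; the artifact read model
  piles symmetric signal onto these intervals.

A decoy drawn with `n_numts=0` is verified k-mer-disjoint from chrM
(hash-set intersection, redrawn in the astronomically unlikely collision
case), so "no read maps across genomes" is a construction guarantee, not
a hope. The decoy is deliberately desk-scale: the input chrM fraction is
an explicit mass-fraction parameter rather than an emergent property of
copy number, so full-genome statistics are reproduced at megabase scale.

## Library generation

All models share the fragment machinery: lengths are
`round(Normal(fragment_mean=200, fragment_sd=20))` clipped below at the
read length; each fragment emits one 36-bp read from the 5′ end of a
uniformly chosen strand; chrM fragments may wrap the origin. Identical
configuration (including seed) produces byte-identical FASTQ/BED output.
Sequencing errors are off by default — the zero-mismatch mapper would
silently drop erroneous reads; an `error_rate` knob exists to measure
exactly that loss.

- **input**: fragment origin is chrM with probability
  `mito_mass_fraction` (default 0.019), otherwise a nuclear contig chosen
  by length; positions follow the bias field (uniform when absent).
- **coating**: as input but with `chip_mito_fraction` (default 0.40) on
  chrM.
- **point_source_mix**: coating background plus planted fragments whose
  midpoints are `Normal(site_center, site_sd=30)`. The planted count per
  site is calibrated so the *peak midpoint density* equals
  `site_enrichment` × the background midpoint density on that contig:
  `n_site = (fold − 1) · (n_bg · p_contig / L_contig) · site_sd · √(2π)`.
  The 30-bp dispersion is a modelling choice for site occupancy width
  (the promoter footprint itself is 22 bp; occupancy spread is wider than
  the footprint). Total fragment count is conserved.
- **nuclear_artifact**: input-like background plus pileups on the repeat
  registry intervals. A 5′-end position is drawn
  `Normal(interval center, width/4)` first and the strand tossed
  independently, making the `+` and `−` 5′-end profiles identical in
  expectation — precisely the geometry a true binding site cannot
  produce. Reads falling in the duplicated cores become multireads and
  are removed downstream, recreating the "enriched site beside an
  unmappable repeat" pattern.
- **bias field** (`smooth_bias_field`): `exp(a · smoothed N(0,1))` with a
  500-bp correlation scale, shared between ChIP and input of one
  experiment. It emulates smooth sequencing/sonication bias — the reason
  a coating profile is non-uniform yet *tracks the input*.

What the generator does **not** emulate: paired ends, base-quality error
profiles, PCR duplicates, GC-dependent amplification bias (the bias field
is sequence-independent by construction, which is what makes the GC
null check meaningful), chromatin accessibility structure, and real
hg19-scale genome size. Passing tests therefore demonstrate correctness
of the *analysis logic* under the stated generative assumptions, not
robustness to every artifact of real libraries.

## Mapping

The aligner is an exhaustive exact-match k-mer index: every reference
window of 36 bp is hashed (64-bit polynomial rolling hash); queries are
binary-searched and every candidate verified base-by-base against the
reference, so hash collisions cannot create placements. Both strands are
queried (forward hash and reverse-complement hash). Circular contigs are
indexed as sequence + first 35 bp, yielding window starts 0..L−1 exactly,
i.e. wrapped placements at their mod-L coordinate with no duplicates.
A read is `unique` with one total placement, `multi` with more,
`unmapped` with none. On small references the mapper is tested for exact
agreement with a naive scan of every offset on both strands.

Partition follows the two-pass strategy: (1) map against chrM alone —
any read with a perfect chrM placement joins the chrM analysis set
(a read with several placements *all on chrM* is retained and assigned
one placement uniformly at random under a fixed seed, avoiding positional
dropout on the circle); (2) the remainder is mapped against the whole
bundle and only unique placements enter the nuclear set. The audit counts
satisfy `total = chrM + nuclear_unique + multi + unmapped` by
construction. Consequence of pass order: a nuclear-origin read that
happens to match chrM perfectly (undiverged NUMT window) is counted on
chrM — an accepted, quantified bias of the design (~+0.02 percentage
points on the input fraction at the default decoy).

## Site scanning and classification

Window scan as described in the README (window 200, step 50, q < 0.01,
fold ≥ 2; λ floor at the genome-wide mean; input scaled by library-total
ratio with pseudocount 1, evaluated at 1× and 5× window widths). Choices
worth recording:

- **Summit**: maximum of the Gaussian-smoothed (σ = 15 bp)
  fragment-extended coverage inside the merged region — 5′-end density is
  bimodal at a true site, extended coverage is unimodal at its centre.
- **Asymmetry**: profiles are smoothed (σ = 15 bp) in a ±2-fragment
  window around the summit; `d̂ = argmax_r shift ∈ [0, 2·fragment]`.
  Classification thresholds (`d̂` band 0.5–1.5 × fragment, gain > 0.2,
  artifact when unshifted r ≥ 0.5) are config-exposed; the underlying
  criterion in the literature is qualitative, so these are this package's
  operationalisation.
- **Degenerate windows**: zero-variance profile segments get r = 0; a
  merged region that intersects no grid window (cannot happen with step ≤
  window, guarded anyway) falls back to the nearest window's statistics.
- **Uniformity z-flagging** (|z| > 3 of windowed log2 ratios) is likewise
  an operationalisation of "no significant non-uniformity"; with
  proportional tracks the ratio vector is constant and its z-scores are
  defined as zero.

## Nuclear analysis

Cross-correlation is computed exactly (trimmed Pearson at every shift via
FFT cross-products and cumulative moments), combined across contigs by
read-count weighting. The read-length ± 5 bp "phantom" neighborhood is
masked for fragment-length estimation and flagged when it is the global
maximum. The peak caller reuses the shared scan and classifier per
contig; its fragment length comes from cross-correlation (clamped to
50–500 bp, falling back to the configured mean), and candidate regions
with fold enrichment in [2, 30] refine the estimate via the median of
their strand-shift offsets — the analogue of restricting model building
to moderately enriched sites in standard callers, repurposed because this
caller has no shift-model step. Called sites whose ±500-bp flanks are
> 30% non-unique (by the 36-mer mappability of the bundle) are annotated
`repeat-adjacent`; an enriched, strand-symmetric, repeat-adjacent site is
classified `artifact` — a codification of what is usually manual
inspection, and config-exposed like the rest.

## Problem sizes and determinism

Default desk-scale sizes: 10⁵–2×10⁵ fragments per library for profiling
runs and property tests, 10⁶ fragments for the enrichment-fraction
measurements, 0.3–2-Mb decoys in tests and 5 Mb for the enrichment runs.
Binomial/Poisson statistics at these depths give sub-0.1-percentage-point
standard errors on the fractions and ±few-bp summit recovery, so nothing
is lost relative to larger simulations. Every stochastic step takes an
explicit seed; the pipeline derives per-stage seeds from the run seed,
and reruns are byte-identical.

## Known limitations

- Zero-mismatch exact matching is the analysis contract, not a general
  aligner; real data with sequencing errors loses reads at a rate the
  `error_rate` knob can quantify, and mismatch-tolerant alignment is out
  of scope.
- The chrM multiread policy (random placement within chrM) slightly
  blurs positions inside perfect intra-chrM duplications; random
  sequence makes these essentially absent in the synthetic bundle.
- Interval fold enrichment in `locus_report` is computed on 5′-end
  counts, so it understates the peak *density* fold of a narrow site
  whose read ends straddle the queried window.
- The classifier's thresholds were chosen for 200-bp fragments and 36-bp
  reads; very different fragment-to-read ratios would need re-derived
  bands (all exposed in `ScanParams`).
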