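# mitochip

NUMT-aware analysis of ChIP-seq data for proteins that bind the
mitochondrial genome, built around the question: does a factor **coat** the
16.6-kb circular mitochondrial chromosome diffusely, or does it bind at
discrete **point sources** — and is there any credible binding on the
nuclear genome once mapping artifacts are accounted for?

The motivating case is TFAM, the mitochondrial transcription-factor /
packaging protein: a sequence-specific activator at the light- and
heavy-strand promoters (~22-bp footprints) that also packages mtDNA
nonspecifically. The package is aimed at anyone analysing ChIP-seq of
mitochondrial nucleoid proteins, where three things break the standard
nuclear-TF toolchain:

1. **chrM vs NUMTs.** Partial copies of the mitochondrial genome inside the
   nuclear genome (NUMTs) make many mtDNA-derived reads ambiguous. Reads
   are therefore trimmed to 36 bp and aligned with **zero mismatches**,
   once against chrM alone and once against the whole genome; nuclear
   analysis keeps only unique whole-genome alignments of reads with no
   chrM placement, and all multireads are discarded.
2. **Circularity.** chrM is circular; coverage, sliding windows, peak
   summits and feature distances all wrap through the origin.
3. **Coating vs point source.** A genuine localized binding site places
   `+`-strand read 5′ ends one fragment length upstream of `−`-strand 5′
   ends. A coating factor instead produces signal that tracks the input
   profile with identical strand profiles everywhere. The package scores
   every candidate site for this geometry and classifies it
   `point_source`, `artifact` (enriched but strand-symmetric, the
   signature of a mapping artifact) or `diffuse`.

## What's in the box

| module | role |
|---|---|
| `mitochip.genome` | synthetic 16,569-bp circular chrM (random sequence, realistic gene layout: 13 CDS, 22 tRNA, 2 rRNA, D-loop, promoters, replication origins), nuclear decoy with planted NUMTs/repeats |
| `mitochip.simulate` | ChIP/input FASTQ generator: mass-fraction input model, uniform-coating model, planted point sources, symmetric artifact pileups; ~200±20-bp fragments, 36-bp single-end reads, planted-truth BED |
| `mitochip.mapping` | exhaustive zero-mismatch 36-mer mapper (hash index, both strands, circular wrap), unique/multi/unmapped classification, two-pass chrM/nuclear partition |
| `mitochip.coverage` | strand-specific 5′-end and fragment-extended tracks |
| `mitochip.mito` | chrM enrichment fraction, uniformity vs input (windowed log-ratios, GC check), circular local-Poisson site scan with strand-asymmetry classification, feature distances, replicate correlation |
| `mitochip.nuclear` | strand cross-correlation QC, simplified local-Poisson peak caller vs matched input (Benjamini–Hochberg, q < 0.01), artifact triage with 36-mer mappability annotation |
| `mitochip.pipeline` / CLI | end-to-end presets, run manifests, reports |

## The statistics at the core

**Enrichment fraction.** For each library, the percentage of mapped reads
assigned to chrM: `100 · chrM_mapped / mapped`. An input library measures
the mtDNA mass fraction of the cell (order 1–2%); a strongly enriched ChIP
library reaches tens of percent.

**Local-Poisson site scan.** Windows of 200 bp every 50 bp (circular on
chrM). The window count of ChIP 5′ ends is tested against
`λ = max(genome-wide mean, scaled input at 1×, scaled input at 5× window)`,
input scaled by the ratio of library totals with a pseudocount;
p-values are Benjamini–Hochberg corrected across all windows (q < 0.01,
fold ≥ 2). Surviving windows are merged; the summit is the maximum of the
smoothed fragment-extended coverage.

**Strand-asymmetry classification.** Around each summit, the shift `d̂`
maximising the Pearson correlation between the smoothed `+` and shifted
`−` 5′-end profiles is found. A site is `point_source` when
`d̂ ∈ [0.5, 1.5] × fragment length` and the correlation gain over zero
shift exceeds 0.2; an enriched site whose unshifted strand profiles are
already near-identical is an `artifact`.

**Cross-correlation QC.** Pearson correlation of `+` vs `−` 5′-end density
tracks as a function of strand shift, read-count-weighted across contigs,
with the read-length "phantom" neighborhood masked when estimating the
fragment length. Genuine localized binding produces a fragment-length
peak; a signal-free library's profile is flat and indistinguishable from
input.

## Worked example

```python
from mitochip import RunConfig, run_pipeline

summary = run_pipeline(RunConfig(
    outdir="demo", seed=7, preset="planted-site",
    n_fragments=200_000, decoy_size=2_000_000))
```

This simulates a ChIP library (40% chrM fragments, one 10-fold point
source planted at the annotated putative site) and a matched input (1.9%
chrM mass fraction) over a 2-Mb NUMT-bearing decoy, maps and partitions
both, and profiles both genomes. The summary it prints:

```
ChIP_rep1  41.07 % of mapped reads on chrM
input       1.94 % of mapped reads on chrM
chrM sites: summit 5177, point_source, fold 2.45, 544 bp upstream of O_L
nuclear:    0 sites called (0 point_source)
```

Reading the numbers: the ChIP library is ~21-fold enriched for chrM over
input; the scan recovers the planted site within 2 bp of its true center
(1-based 5175) and reports it 544 bp upstream of the light-strand
replication origin O_L (annotation truth: 546 bp); nothing on the nuclear
decoy survives peak calling. The `coating` preset gives the same
enrichment but zero localized calls anywhere, and the `artifact` preset
produces nuclear calls that are all classified `artifact`, none
`point_source`.

The same run from the shell:

```sh
mitochip run --preset planted-site --seed 7 --n-fragments 200000 --out demo
mitochip report demo
```

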