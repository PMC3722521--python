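# prtdesign

Automated design of **paralogue ratio test (PRT)** assays for accurate,
cost-effective typing of genomic copy number variation.

A PRT is a quantitative PCR in which a *single* primer pair co-amplifies
two loci: a target amplicon inside a putative CNV and a fixed-copy
reference amplicon elsewhere in the genome. Because one primer pair drives
both amplifications, their kinetics match, and the ratio of the two
products (separated by size on electrophoresis, or by sequence) estimates
the integer copy number of the target. The catch is assay design: the
primer pair must anneal **perfectly at exactly two places** in the
reference genome, nowhere else, and the two products must be
distinguishable. Finding such pairs by hand takes hours per assay.

`prtdesign` automates this by brute force:

1. **Design** a large number of candidate primer pairs across the target
   interval (density `ppn` pairs per nucleotide, default 2), in
   overlapping 2 kb windows so candidates spread evenly; optimal design
   parameters are relaxed in decrements until each window's quota is met.
2. **Align** every primer to the genome with a k-mer-seeded,
   mismatch-tolerant in-silico PCR (tile 11 / stride 5 / perfect 3' 15 nt
   by default; an exhaustive *sensitive* mode finds every mispriming site)
   and enumerate all products either orientation could amplify.
3. **Select** pairs whose exact-match amplicons number exactly two — one
   inside the target region (the CNV amplicon), one outside (the
   reference).
4. **Filter** for PRT suitability: size difference between the amplicons
   (default ≥ 2 bp), reference ≥ 500 kb from the target or on another
   chromosome, bounded reference product size, and a low mispriming count
   (amplicons with match score > 900, i.e. ≲ 4 primer mismatches; default
   ≤ 2). Assays are annotated with CNV/indel-catalogue overlaps and SNP
   counts under each primer.

Primer placement can be masked against SNP, Alu/SINE and simple-tandem-
repeat tracks (BED), and a multi-target mode designs assays for CNVs whose
target sequence occurs 2–4 times per haploid reference genome.

## Worked example

Everything runs on synthetic genomes with planted structure — no
downloads. Build a 120 kb two-chromosome genome containing one engineered
paralogue pair (identical 60 bp primer-site flanks, diverged interiors
differing in length by exactly 20 bp), then design assays over the planted
locus:

```python
from prtdesign.synthetic import (
    SegmentCopy, SegmentFamily, SyntheticSpec, generate, write_fixture,
)

spec = SyntheticSpec(
    seed=7,
    chrom_lengths={"chr1": 60_000, "chr2": 60_000},
    families=(SegmentFamily("dupA", copies=(
        SegmentCopy("chr1", 30_000, 0),        # target copy
        SegmentCopy("chr2", 45_000, 20),       # paralogue, interior +20 bp
    )),),
)
write_fixture(generate(spec), "fixture")
```

```bash
prtdesign run --genome fixture/genome.fa --region "chr1:29,601-30,660" --out prt_out
# designed 2120 primer pairs, accepted 34 assays
# report: prt_out/report.tsv
```

The report prints each accepted assay on two lines — target first, then
reference — with 1-based inclusive coordinates:

```
ID           Chr   Start  End    Size  Misprime  DGV  Forward                 Reverse                SizeDiff  FSNP  RSNP
T0W0_000865  chr1  30006  30224  219   0         .    AGCCTGAGATACATCTGGCGCA  CTTACCTGACGCACAACGCCC  20        0     0
T0W0_000865  chr2  45006  45244  239   0         .    AGCCTGAGATACATCTGGCGCA  CTTACCTGACGCACAACGCCC  20        0     0
```

Read: primer pair `T0W0_000865` amplifies a 219 bp product at the planted
target locus on chr1 and a 239 bp product at the paralogous locus on chr2
— a 20 bp size difference, resolvable on a capillary sequencer — with zero
predicted mispriming products (`Misprime`), no overlap with a known
CNV/indel (`DGV`), and no SNPs under either primer (`FSNP`/`RSNP`). The
run directory also contains a BED6 browser track (`assays.bed`), a
machine-readable rejection audit, cluster/coverage statistics
(`stats.tsv`) and a reproducibility manifest.

Masking tracks, sensitivity mode, thresholds and the multi-target mode are
all flags (`prtdesign run --help`), and the same pipeline is callable as a
library via `prtdesign.RunConfig` / `prtdesign.run`.

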