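# icrscan

Genome-wide detection of **candidate imprinting control regions (ICRs)**
from clustered DNA motifs.

Genomic imprinting — parent-of-origin-specific monoallelic expression — is
controlled by ICRs: cis-acting, differentially methylated regions. ZFP57
binds the methylated hexamer TGC(mC)GC and protects ICR methylation, and in
known ICRs these binding sites occur in clusters, often as CpG-rich
composite elements in which the ZFP57 binding site (ZFBS, unmethylated word
`TGCCGC`) overlaps an MLL1/MLL2 CXXC-domain morpheme. `icrscan` turns that
observation into a predictor:

1. **Scan** chromosomal FASTA for two exact-word sets, on both strands:
   the ZFBS hexamer (`TGCCGC` / `GCGGCA`) and a set of composite
   "ZFBS-morph overlap" words, each carrying ≥ 2 CpG dinucleotides.
2. **Density**: count overlap-element occurrences in a sliding window of
   **850 bases**, discarding isolated occurrences (a lone element is
   background noise).
3. **Peaks**: chain nearby occurrences into clusters. Clusters of ≥ 3
   elements are **robust** candidate ICRs; clusters of exactly 2 are
   **weak** (possible false positives); singletons are discarded.
4. **Tracks**: write three UCSC-browser custom tracks (hexamer BED,
   overlap BED, density fixedStep WIG) plus a peak BED, and annotate peaks
   with genes in the vicinity — candidate imprinted genes.

A seeded synthetic-genome generator plants motif clusters in scrubbed
background with exact ground truth, so the whole pipeline is testable
without downloading an assembly.

## Worked example

Simulate a 120 kb chromosome with a 3-copy cluster, a 2-copy cluster and
one isolated site, then run the full pipeline on it:

```sh
icrscan simulate --out-dir demo --seed 42 --length 120000 \
    --clusters 3,2 --isolated 1 --motif-word TGCCGCGCG
printf 'OV4\tTGCCGCGCG\n' > demo/overlap.txt
icrscan all --genome demo/synthetic.fa --overlap-file demo/overlap.txt --out-dir demo
```

(Or pass a real chromosome FASTA as `--genome` and your composite-element
word list as `--overlap-file`.) The `scan` stage logs, per chromosome:

```
chrS: 29 hexamer hits, 6 overlap hits
```

— the short hexamer occurs by chance throughout the background, while the
CpG-rich composite word appears only where planted (6 = 3 + 2 + 1).
`call` then reports:

```
2 peaks (1 robust)
```

and `demo/peaks.bed` contains, after the track header:

```
chrS	53147	53997	weak:2	2
chrS	80198	81047	robust:3	3
```

The 3-copy cluster is a robust candidate ICR, the 2-copy cluster a weak
one, and the isolated site was suppressed — exactly the planted truth in
`demo/truth.bed`. `demo/manifest.txt` lists the three browser tracks, and
`icrscan annotate --genes genes.bed` adds nearby genes with signed
distances (0 = overlapping the peak).

The same stages are available as a library:

```python
import icrscan as ic

motif = ic.Motif(id="OV", word="TGCCGCGCG", origin="overlap")
chrom, truth = ic.simulate_genome(120_000, 0.42, [(3, 700), (2, 400)], 1, motif, seed=42)
ms = ic.expand_with_complements(ic.MotifSet(motifs=(motif,)))
hits = ic.dedupe_hits(ic.find_occurrences(chrom, ms))
peaks = ic.call_peaks(hits, window=850)   # -> one robust:3 peak, one weak:2 peak
```

## Motif word lists

The hexamer set is built in. The packaged composite-element list
(`src/icrscan/data/overlaps_synthetic.txt`) is a *synthetic stand-in*
generated by `icrscan.motifs.generate_overlap_motifs` from the hexamer and
a small CpG-rich morpheme set; replace it (or pass `--overlap-file` /
`--morpheme-file`) with a published list for real scans. Every overlap
word must carry ≥ 2 CpGs; `validate_overlap_set` audits this.

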