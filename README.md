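# pamscape

Tools for mapping the "editable genome": where CRISPR–Cas enzymes can
act, and whether those regions matter for complex traits.

Class-2 CRISPR nucleases only cut next to a protospacer-adjacent motif
(PAM) — NGG downstream of the target for SpCas9, TTTV upstream for
AsCas12a, and so on across a growing panel of natural orthologs and
engineered variants.  PAM density therefore determines which parts of a
genome each enzyme can reach.  `pamscape` quantifies this landscape and
its genetic consequences:

1. **Segment** a genome: concatenate chromosomes end to end and cut the
   sequence into a fixed number of equal segments (20,000 segments of
   144,052 bp for the GRCh37 autosomes), with N-adjusted GC content per
   segment.
2. **Count PAMs** per segment on both strands (NGG is counted as NGG
   plus CCN), with IUPAC-degenerate matching, and rank segments per Cas
   enzyme after deduplicating windows shared by its PAMs.  The top
   decile of segments forms that enzyme's *Cas-enriched regions*.
3. **Annotate SNPs**: mark each SNP of a panel 1/0 by membership in the
   enriched regions, with the standard LD-score-regression filters
   (MAF > 5%, MHC excluded, optional keep-list).
4. **Partition heritability** by stratified LD score regression.  Under
   the model E[χ²ⱼ] = 1 + N·Σ_c τ_c·ℓ(j,c), the per-annotation
   coefficients τ_c partition SNP heritability, and

       enrichment(c) = (share of h² in c) / (share of SNPs in c),

   with block-jackknife standard errors, Wald tests, and
   Benjamini–Hochberg FDR.
5. **Quantify overlap**: Fisher-exact odds-ratio matrices between Cas
   annotations and functional annotations, Fisher-Z-tested Pearson
   correlations (e.g. PAM GC content versus GC-rich-segment overlap),
   and matching of off-target cleavage sites to segments.

A synthetic-data module generates every input — genomes with structured
GC and N-runs, LD-block genotypes, model-faithful GWAS summary
statistics, GC-coupled functional annotations, off-target sites — so
the entire pipeline runs and is tested without any external download.
A curated registry of 21 Cas9/Cas12a enzymes ships as an editable TSV.

## Worked example

Synthetic 2 Mb genome with two GC-rich blocks; rank SpCas9 (NGG)
segments, annotate a simulated 8,000-SNP panel, and estimate the
heritability enrichment of a trait simulated with true enrichment 2.5:

```python
import numpy as np, pandas as pd
from pamscape import annotate as ann, heritability as h2
from pamscape import landscape as ls, segmentation as seg, simulate as sim

gspec = sim.GenomeSpec(chrom_lengths={"1": 2_000_000}, background_gc=0.41,
    gc_blocks=(("1", 200_000, 300_000, 0.65), ("1", 1_200_000, 1_300_000, 0.65)),
    seed=1)
sim.write_fasta(sim.generate_genome(gspec), "genome.fa")

concat = seg.concatenate_autosomes("genome.fa")
table = seg.segment_table("genome.fa", concat, 40)      # 50 kb segments
plan = table[["start", "end"]].to_numpy()
ngg = ls.count_pam_per_segment(seg.segment_sequences("genome.fa", concat, plan), "NGG")
regions = ls.top_k_segments(ngg, 4, ~table["all_n"].to_numpy(), label="SpCas9")
print("top SpCas9 (NGG) segments:", regions.indices)

X, panel = sim.generate_genotypes(sim.SimSpec(n=200, m=8000, block_size=25,
    rho=0.8, length=2_000_000, cm_per_mb=10.0, seed=2))
annots = pd.DataFrame({"base": np.ones(8000, dtype=np.int8),
                       "SpCas9": ann.annotate_snps(panel, regions, concat, plan)})
ldsc = h2.compute_ld_scores(X, panel["cm"].to_numpy(), annots, window_cm=1.0)
ss, _ = sim.simulate_sumstats(panel, annots, n_gwas=50_000,
    target_enrichment={"SpCas9": 2.5}, h2=0.5, mode="model", ldscores=ldsc, seed=3)
res = h2.enrichment_analysis(ss["Z"].to_numpy()**2, ldsc, annots, 50_000, n_blocks=100)
print(res[["snp_share", "enrichment", "enrichment_se", "enrichment_p"]].round(4))
```

Output:

```
top SpCas9 (NGG) segments: (4, 5, 24, 25)
        snp_share  enrichment  enrichment_se  enrichment_p
base       1.0000      1.0000         0.0000        1.0000
SpCas9     0.1035      2.5547         0.1367        0.0000
```

The four top-ranked segments are exactly those covering the two planted
GC-rich blocks (NGG is a 100%-GC PAM).  About 10% of SNPs land in the
enriched regions, and the estimated enrichment 2.55 ± 0.14 covers the
simulated truth of 2.5; the all-SNPs base annotation has enrichment 1
by construction.

## Command line

`pamscape` exposes the same stages as subcommands:
`pam-count`, `cas-rank`, `annotate`, `ldscore`, `h2-enrich`,
`overlap-or`, `offtarget-match`, and `simulate`.  Each reads and writes
plain TSV (LDSC-style `.annot`, `.l2.ldscore`, and `.sumstats` dialects
for the heritability stages).  See `pamscape --help`.

For a full-scale run on a locally available GRCh37 FASTA, use
`python scripts/full_scale.py --fasta GRCh37.fa --out landscape.tsv`,
which segments the 22 autosomes into 20,000 pieces, counts every
registry PAM, and reports the GC-concordance summary (expect hours on
one CPU).

## Documentation

`docs/methods.md` describes the model, the estimators, the synthetic
data generators and their limits, and the numerical conventions.
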