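# hml2quant

Locus-resolved quantification of HERV-K(HML-2) provirus expression from
enriched RNA-Seq.

## The problem

The HML-2 lineage is the youngest human endogenous retrovirus family:
~100 proviral copies, of which a few recently integrated loci still encode
a full-length Env protein — a candidate tumour antigen. Deciding *which*
locus is transcribed is hard because the young proviruses differ by only
~1.5% nt: a typical 100-nt read maps equally well to several of them, and
the choice of multi-mapping policy changes the answer by an order of
magnitude. This package implements the complete analysis:

* **Faux genome** — proviruses concatenated with N spacers as the mapping
  reference, with per-locus intervals and GTF export
  (`hml2quant.provirus_db`).
* **Multi-mapping policies** — per-locus counting under
  `random_multimap`, `unique_only`, `count_all` and `proportional`
  allocation, from external SAM/BAM or a built-in edit-distance aligner
  (`hml2quant.read_processing`). For a read tying loci with best-score set
  *S*: random allocation picks one of *S* uniformly; unique-only drops the
  read; count-all increments every locus in *S*; proportional splits it
  ∝ each candidate's unique-read count.
* **Diagnostic SNP k-mers** — alleles carried by exactly one provirus,
  verified by exact 31/17/11-nt window search against the whole set and
  counted as exact substrings in FASTQ; plus an 11-nt scanner for long
  reads carrying alleles of two different proviruses
  (`hml2quant.diagnostic_alleles`).
* **Bait design** — majority-rule consensus of the young subfamily's env
  alignment and ×10 probe tiling (`hml2quant.consensus_probe`).
* **Statistics** — RPKM (`count / (locus_kb × assigned_reads/1e6)`),
  Env-encoding fraction, enrichment fold, Spearman replicate concordance,
  cross-study relative-expression tables (`hml2quant.quantify_stats`).
* **Synthetic data** — a provirus-family and read simulator with truth
  labels (divergence-calibrated subfamilies, type-1 deletions, premature
  stops, hypermutation, insertional polymorphism, tandem duplication,
  shared and cryptic alleles, recombinant reads)
  (`hml2quant.synthetic_data`).

## Worked example

```python
from hml2quant.synthetic_data import SimConfig, end_to_end_recovery

rep = end_to_end_recovery(SimConfig(short_error_rate=0.0), seed=7)
t = rep["truth_young_share"]
for policy in ("random_multimap", "unique_only"):
    est = rep["policies"][policy]["young_share"]
    print(f"{policy:16s} young-subfamily share {est:.3f} (truth {t:.3f})")
```

prints

```
random_multimap  young-subfamily share 0.379 (truth 0.381)
unique_only      young-subfamily share 0.103 (truth 0.381)
```

Fifty thousand error-free reads were simulated from a 20-locus family whose
young subfamily (eight loci, mean pairwise divergence 1.5%) truly produced
38.1% of them. Randomly allocating multi-mappers recovers that share to
within 0.2 points; counting only uniquely mapping reads attributes barely a
quarter of it, because most reads from near-identical loci tie and are
discarded. The same report carries RPKM profiles, Env fractions, and the
discovered diagnostic alleles with their counts.

The numbered scripts under `analysis/` run the full study narrative —
family generation and divergence (01), bait design (02), policy comparison
(03), diagnostic-allele counting with a planted cryptic shared allele and
recombinant long reads (04), and summary statistics (05) — writing tables
under `results/` (bulky FASTA/FASTQ go to `scratch/`).

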