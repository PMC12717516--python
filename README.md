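# taxoskim

Desk-scale **taxogenomics** for genome-skimmed specimens: the computational
workflow for characterizing a single mixed-DNA specimen — e.g. a fungal
fruiting body sequenced on a portable long-read device in the field — without
PCR, reference downloads, or internet access.

A PCR-free skimming library carries three signals at once: the target
organism's genome (including its barcode loci ITS, LSU, SSU and *TEF*),
DNA of associated organisms (the specimen's microbiome, its host), and
incidental contamination. `taxoskim` implements every stage needed to work
such a library up and to decide whether the result can be trusted:

| stage | what it does |
|---|---|
| `qc` | mean-quality read filtering (probability-space Phred mean), end cropping, N50/quality summaries |
| `mine-loci` | extraction of reads matching barcode loci (≥200 bp, identity strictly >80%) with per-locus depth |
| `consensus` | pileup plurality consensus with deterministic tie rules |
| `place` | identity-ranking of a locus consensus against candidate relatives |
| `map-genome` | endogenous-genome mapping (Q10/300 bp pre-filter, E ≤ 0.001, length ≥ 300, identity ≥ 80) with chromosome- and gene-level coverage from unique hits |
| `classify` | best-hit taxon classification of every read against a labeled panel |
| `depth-benchmark` | simulated-read consensus error as a function of sequencing depth |

Alignment is an in-package seed-and-extend local aligner (exact 11-mer
seeding, banded affine-gap Smith–Waterman extension) with Karlin–Altschul
statistics, `E = K·m·n·e^(−λS)`, where λ solves
`Σᵢⱼ pᵢpⱼ e^{λ·sᵢⱼ} = 1`. On short inputs the reported optimum equals
exhaustive Smith–Waterman. A synthetic specimen generator emulates the
whole mixture — genome with embedded loci and annotated genes, labeled
contaminants, ONT-like reads at ~90% per-base accuracy — with exact truth
labels, so every stage is tested against ground truth.

The scientific core is the **depth–accuracy benchmark**: simulated long
reads at 10% per-base error (5% substitution, 2.5% insertion, 2.5%
deletion) are piled over a gene-sized reference padded with 100 bp of
donor-derived flanking sequence, and the plurality consensus is scored
against the truth as
`error % = 100 · (polymorphisms + uncovered positions) / reference length`.
It answers the field question: *how much coverage of a barcode locus do I
need before the consensus is trustworthy?*

## Worked example

```python
from taxoskim import ErrorModel, ReferenceSeq, run_depth_benchmark
from taxoskim.sample import random_bases
import numpy as np

rng = np.random.default_rng(7)
gene  = ReferenceSeq(id="LSU_like", bases=random_bases(1500, rng))
donor = ReferenceSeq(id="chr_donor", bases=random_bases(5000, rng))

df, summary = run_depth_benchmark(gene, donor, ErrorModel(),
                                  depths=(2, 5, 10, 25, 50, 75),
                                  replicates=3, seed=11)
for depth, row in sorted(summary.items()):
    print(f"{depth:5.0f}x  mean {row['mean_error_pct']:.2f}%  max {row['max_error_pct']:.2f}%")
```

prints

```
    2x  mean 2.87%  max 6.73%
    5x  mean 0.18%  max 0.27%
   10x  mean 0.00%  max 0.00%
   25x  mean 0.00%  max 0.00%
   50x  mean 0.00%  max 0.00%
   75x  mean 0.00%  max 0.00%
```

i.e. consensus error is severe at 2× coverage, drops sharply by 5×, and is
negligible (<1%) at 10× and above — the coverage floor a field worker
should demand before trusting a skimmed barcode sequence.

The same machinery is available from the shell:

```bash
taxoskim make-sample --outdir demo --seed 7          # synthetic specimen
taxoskim qc --reads demo/reads.fastq --out demo/qc.fastq --min-q 9 --crop 30
taxoskim mine-loci --reads demo/qc.fastq --panel demo/markers.fasta --out demo/loci.tsv
taxoskim run --config demo/config.json               # full pipeline + report.json
```

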