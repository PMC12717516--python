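# Methods

## The problem being modeled

A PCR-free genome-skimming library from one field specimen is a mixture:
a minority of bases from the target organism's nuclear genome (which
carries the high-copy barcode loci — ITS, LSU, SSU, *TEF* — used for
taxonomic placement), the rest from associated and incidental organisms.
Early-chemistry nanopore reads of such a library run near 90% per-base
accuracy, so single reads are unusable as barcode sequences; only a
pileup consensus at sufficient depth is. The package implements the
stages of that workup and, centrally, the simulation benchmark that
quantifies how consensus accuracy depends on sequencing depth.

## Synthetic specimen generator

`taxoskim.sample` fabricates the full study system: a genome with
embedded marker loci and annotated genes, independent contaminant
references, and a mixed read pool with exact per-read truth labels.

* **Composition.** References are i.i.d. uniform over {A,C,G,T}. This is
  deliberate: maximum-entropy sequence keeps chance cross-taxon alignment
  identity at the ~25% noise floor, so classification and mining errors in
  tests reflect the algorithms, not accidental homology. Real genomes have
  GC skew, repeats and low-complexity tracts that this generator does not
  emulate — passing tests therefore demonstrate correctness of the
  machinery under clean separability, not performance on repeat-rich or
  conserved-domain data.
* **Default mixture** (fraction of total bases): 20% target fungus, 55%
  split over two bacteria-like taxa, 18% a second fungus, 7% arthropod
  traces — a bacteria-dominated library with a minority endogenous
  fraction and trace host signal, the qualitative shape of a skimmed
  fruiting-body specimen. The exact numbers are package defaults, not
  measured values.
* **Marker locus lengths** default to typical fungal barcode fragments:
  ITS 600, LSU 900, SSU 1500, *TEF* 1000 bp, embedded disjointly in a
  50 kb genome (a deliberately scaled-down stand-in for a ~30 Mb fungal
  genome; all per-base statistics are length-invariant).
* **Relatives.** `mutate_relative` applies i.i.d. substitutions at a
  configured divergence (uniform alternative base), giving panels of
  "sister species" at known distances; indel divergence is not modeled.
* **Determinism.** Every output is a pure function of (config, seed);
  sub-seeds are derived by CRC-hashing stage/taxon tokens, so any source
  sequence can be regenerated in isolation.

## Read model

`taxoskim.read_model.ErrorModel` is a transparent parametric stand-in for
a learned nanopore error profile: i.i.d. per-base events — substitution
5%, insertion 2.5%, deletion 2.5% by default, totalling the ~10% error of
ONT v9-chemistry reads — plus a lognormal read-length distribution
(median ~1 kb, bounds 200 bp–20 kb) and two-level quality emission
(correct bases around Q13, erroneous around Q5, ±2 jitter). The split of
the 10% across event classes is a package choice; only the total is
anchored in what is known about the chemistry. Context effects
(homopolymer indels, k-mer-dependent miscalls) are intentionally absent:
they would change where consensus errors sit, not the depth at which
plurality voting suppresses them, and the i.i.d. form keeps every
expectation analytic (mean read identity ≈ (1−p_del−p_sub)/(1+p_ins) ≈
90.2%, tested at ±1 point).

Two devices support benchmarking gene-sized references:

* `add_flanks` pads the target with 100 bp copied from a related donor
  sequence per side; flanks exist only so simulated reads extend beyond
  the gene (coverage at its ends), and consensus scoring is restricted to
  the target interval.
* `min_len_quantile=0.95` floors sampled read lengths at the 95th
  quantile of the configured distribution. For a ~1.7 kb flanked
  reference that floor exceeds the reference length, so reads clamp to
  full length and cover the target uniformly — the intended behaviour
  when benchmarking a short gene with long-read simulation.

Coverage targets total simulated bases (depth × reference length), not
read counts.

`characterize` inverts the model from column-level alignments:
p_sub = mismatch columns / match+mismatch columns, p_ins = inserted query
bases / aligned subject bases, p_del = deleted subject bases / aligned
subject bases, and a log-moment lognormal fit to read lengths.
Characterization alignments use a dedicated scoring (match 2, mismatch
−4, gap open 1, extend 2): under the homology-search scoring a true
insertion/deletion pair a few bases apart is cheaper to trace as mismatch
columns, which deflates both indel rates by ~15–20% relative; the
gap-friendly scheme keeps the recovery bias under ~5% relative. A small
residual is irreducible — an insertion immediately followed by a deletion
is genuinely indistinguishable from a substitution.

## QC

Mean read quality is computed in probability space
(−10·log10 of the mean per-base error probability), the convention of the
standard nanopore filtering tools, so one bad stretch dominates as it
should. Filtering crops fixed head/tail lengths first (end bases are
systematically worst), then re-evaluates quality and length on the
cropped read; the quality threshold is boundary-inclusive. Cropping is
not idempotent by nature; the threshold filters are, and are tested as
such. Defaults: Q9 / crop 30 bp for locus mining, Q10 / 300 bp before
genome mapping.

## Alignment engine

Seed-and-extend local alignment: exact 11-mer seeding against a subject
k-mer index, seed diagonals clustered (gap ≤ band width), and a banded
affine-gap Smith–Waterman (Gotoh) extension over each cluster's diagonal
band (default half-width 50 — generous against indel drift, whose
standard deviation over a 2 kb read at 5% indel rate is ~10 diagonals).
Pairs with min length ≤ 64 bypass seeding and get the exhaustive DP, so
small-input optima equal full Smith–Waterman — verified against an
independent exhaustive-DP oracle. N never scores as a match. The
extension is not X-drop-terminated mid-band: at 10% read error, bursts of
consecutive errors are common enough that aggressive termination
truncates genuine alignments, and the banded DP is already cheap.

Scores default to blastn-style +2/−3 with gap open 5 / extend 2. λ is the
positive root of Σ pᵢpⱼ e^{λsᵢⱼ} = 1 for the ungapped substitution scores
(bracketed Brent root-finding, tolerance 1e-12); K defaults to 0.1.
E-values combine the ungapped (λ, K) with gapped raw scores — the
standard approximation; the package's contract is the behaviour of the
E ≤ 0.001 cutoff, not absolute E-value exactness. Identity is
identities / aligned columns with gap columns included (the convention of
the standard search tools).

**Locus mining** excludes reads under 200 bp before alignment and assigns
each remaining read to the locus of its best-scoring alignment with
identity strictly >80%. Two significance gates beyond those thresholds
are package additions: E ≤ 0.001 and ≥100 aligned columns. Without them
an identity-only filter is satisfied by any chance shared 11-mer (100%
identity, ~0.2 expected per read–locus pair); search tools apply
equivalent score cutoffs implicitly, and a 100-column floor at >80%
identity remains unreachable by chance between unrelated uniform
sequences.

**Genome mapping** pre-filters reads (mean quality ≥ Q10, length
≥ 300 bp), retains hits with E ≤ 0.001 then alignment length ≥ 300 and
identity ≥ 80, and caps reported subjects per read and alignments per
subject pair at 10. A read's **unique hit** is its single best-scoring
retained alignment, ties broken by higher identity, then lexicographic
subject id, then smaller subject start — deterministic and close to
common practice. Coverage (per-chromosome covered bases and mean depth;
per-gene covered flag, covered bases, mean depth) is computed from unique
hits only; a gene counts as hit when a unique hit overlaps it by ≥1 bp.

## Consensus and the depth benchmark

The pileup scores only columns inside the target interval. Consensus is a
plurality vote with fixed tie rules: base ties break A < C < G < T; a
deletion loses every tie; an insertion between columns is emitted only
when one inserted sequence is supported by more than half of the reads
spanning that junction; uncovered positions emit nothing and are tallied.
The rules never consult the truth sequence: in the benchmark the
reference is the truth, and a tie-to-reference rule (as polished GUI
consensus callers often default to) would deflate the error estimate
circularly, so it was rejected.

Polymorphisms against the truth are counted on a global end-to-end
alignment (match +1, mismatch −1, gap −2): each mismatch or gap column is
one polymorphism, so a 3 bp deletion counts as 3 — the unit had to be
fixed somewhere, and per-column counting is the conservative choice.
The benchmark error is
`100 · (polymorphisms + uncovered target positions) / truth length`;
counting uncovered positions as errors means a consensus that omits sites
can never score better than one that covers them. Below full coverage an
uncovered site is counted both as an alignment gap and in the uncovered
tally — conservative by construction and irrelevant at the depths where
the benchmark's claims live (full coverage).

The benchmark grid is depths (2, 5, 10, 25, 50, 75) in triplicate over a
~1.5 kb reference with 100 bp flanks, each trial seeded deterministically
from (seed, depth, replicate). With the default 90%-accuracy model the
expected behaviour, which the test suite and `scripts/acceptance.py`
verify, is: several percent error at 2×, a sharp drop by 5×, and mean
error below 1% at every depth ≥ 10× (with full coverage, typically
exactly 0 — at depth 10 a column needs ≥5 of 10 reads to agree on the
same wrong symbol, and errors split across symbols).

## Classification and placement

Classification assigns each read to the taxon of its best retained hit
(E ≤ 0.001, ≥200 aligned columns, identity ≥ 80) against a labeled panel,
with an explicit unassigned row so read counts are conserved exactly.
The 200-column floor (rather than the genome-mapping 300) is deliberate:
a 300 bp read at 10% error aligns over slightly fewer than 300 columns
after end clipping, and a 300-column floor would misdrop reads right at
the length cutoff. Best-hit-only, no lowest-common-ancestor logic — the
panel stands in for a database search whose result is read as "the
closest identifiable taxon".

Placement ranks panel members by global-alignment identity to a locus
consensus; with relatives generated at known divergence d, the top hit is
the closest relative with identity ≈ 100·(1−d) (binomial fluctuation ±1
point at 1.5 kb).

## Problem sizes and numerical choices

Test and benchmark problem sizes (20–50 kb genomes, 60–300 kb read pools,
1.5 kb benchmark references) are chosen so the full suite runs in a
couple of minutes while every statistical margin under test is wide
(classification agreement ~100% vs the 99% bound; benchmark error 0% vs
the 1% bound; rate recovery ~5% relative vs the 10% bound). All
per-base claims are scale-invariant, so nothing is learned by running
larger instances except tighter confidence on the same expectations.
Degenerate inputs fail loudly: empty sequences, empty panels, infeasible
locus packing, references shorter than the minimum read length (with a
pointer to `add_flanks`), traces inconsistent with their coordinates.

## Known limitations

* i.i.d. error and composition models — no context-dependent errors, no
  repeats, no GC structure; conclusions about repeat-induced mismapping
  or homopolymer consensus artefacts cannot be drawn from this package's
  synthetic data.
* Ungapped Karlin–Altschul statistics with gapped scores; no edge-effect
  correction. E-values are approximate by design.
* Seeding requires one exact 11-mer; alignments between sequences more
  than ~35% divergent are below the sensitivity floor (irrelevant for
  the >80%-identity regimes the package targets).
* No spliced alignment, protein-space search, quality-weighted or
  diploid/IUPAC consensus.
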