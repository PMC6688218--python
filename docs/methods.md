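# Methods

## The classification problem

A whole-genome shotgun assembly of a male contains contigs from the
autosomes, the X, and the Y. The Y is hard to isolate after the fact: it is
haploid (half the coverage of the autosomes), rich in repeats, and parts of
it are homologous to the X. `ycontig` classifies each contig as
Y-chromosomal or not using two k-mer statistics that can be computed without
any alignment:

* **proportion shared with female** — decompose the contig into all
  overlapping k-mers and look each one up in the set of k-mers of a female
  genome (reference or raw reads). Y-specific sequence shares almost
  nothing with a female; autosomal and X sequence shares almost everything.
* **male depth of coverage** — the median abundance of the contig's k-mers
  in the male reads used for the assembly. On a male, autosomes sit at
  twice the haploid depth, X and Y at once the haploid depth, and
  multi-copy (ampliconic) Y repeats at copy-number multiples of it.

A contig low on both axes is called Y. The median (not the mean) abundance
is used so that a contig spanning a repeat keeps a depth estimate driven by
its majority sequence class rather than by outlier k-mers.

## k-mer machinery

k-mers are canonical by default (the lexicographic minimum of a k-mer and
its reverse complement), because shotgun reads are strand-agnostic. The
default k = 25 is the standard choice for mammalian-scale k-mer coverage
work: long enough that random 25-mer collisions are negligible, short
enough that per-read error loss is manageable. Windows containing any
non-ACGT symbol are skipped entirely — substituting ambiguity codes would
invent phantom k-mers — and such windows are excluded from both the
numerator and the denominator of the shared proportion.

k-mers are packed two bits per base into 64-bit integers (so k ≤ 31), and
all per-window work is vectorized. Counting is exact: chunks of
concatenated records are k-merized, per-chunk counts from sorting are
merged, and k-mers with abundance below `min_abundance` (default 3) are
discarded as likely sequencing errors. The same floor is applied when the
female store is built from raw reads; it is *not* applied when it is built
from a reference, where even single-copy k-mers are trusted.

The female k-mer set is held in a Bloom filter (no false negatives;
false-positive rate configurable, default 0.001) so that a multi-gigabase
female fits in memory; bit positions come from splitmix64 double hashing of
the packed k-mer, which makes the serialized filter bit-exact across
platforms. The file format is self-describing (magic, k, canonical flag,
capacity, target FP rate, hash count, bit-array length, little-endian).
An exact hash-set backend with the same interface is available for small
inputs and testing; a one-sided consequence of the Bloom backend is that a
contig's measured shared proportion can only be biased *upward*, by at most
about the false-positive rate.

Absent k-mers contribute abundance 0 to the median depth: a contig made of
erroneous or foreign sequence honestly reports depth ~0 rather than being
dropped. Contigs with zero valid windows (shorter than k, or all N) have
undefined features; they are flagged and classified non-Y.

## Classification modes

* `female_only` — Y iff proportion < `p_thresh` (strictly). This is the
  classical female-subtraction genome scan; useful when the male reads are
  unavailable.
* `female_male` — Y iff proportion < `p_thresh` **and** depth < `c_thresh`.
  The depth ceiling rejects autosomal repeats that are under-represented in
  a draft female reference. Thresholds are strict: a contig exactly on a
  threshold is non-Y. There is deliberately no male-only mode: depth alone
  would discard multi-copy (ampliconic) Y regions.
* `best` — a linear separator learned from labeled contigs with a
  hinge-loss linear SVC (C = 1.0). Features are standardized to zero mean
  and unit variance on the training split before fitting, since the two
  features live on incommensurate scales; the standardization is stored
  inside the separator. Labeled contigs are randomly partitioned
  16% / 4% / 80% into train / test / validation — training on a small
  fraction guards against overfitting when the separator is to be carried
  to a related dataset — and accuracy is reported on all three. A contig
  exactly on the decision boundary is non-Y (conservative toward
  precision). The fit is deterministic given the seed, which is always
  logged.

## Truth labeling and evaluation

When an annotated reference exists, contigs are truth-labeled from their
alignments (PAF): alignments with mapping fraction (block length / query
length) below 0.5 are discarded; among survivors the single alignment with
the highest identity (matches / block length) wins, with ties broken by
larger block and then lexicographic target name; unaligned contigs are
`unplaced`. Y-mapped contigs get a region class (X-degenerate, ampliconic,
X-transposed, PAR) by maximal interval overlap with a BED annotation;
Y contigs overlapping no annotated interval are `Y_other`. PAF and BED
coordinates are 0-based half-open. On simulated data truth comes directly
from the simulator's manifest and no alignment is involved. One caveat:
with alignment-derived truth, PAR contigs usually map to the X and so
mostly vanish from the "true Y" set before evaluation ever sees them; the
simulator's manifest labels PAR honestly instead, so PAR recall here is a
property of the classifier, not of the alignment filter.

Precision and recall are **length-weighted**: with x the total length of
contigs both predicted Y and truly Y, precision = x / (length predicted Y)
and recall = x / (length truly Y). Per-region recall stratifies the true-Y
contigs by region class; regions with zero true length are omitted rather
than reported as 0/0, and overall recall is exactly the length-weighted
mean of the per-region recalls.

## The synthetic data generator

The generator emulates the structure that makes Y classification easy or
hard, at desk scale (defaults: ~5 Mb male genome):

| component | default | why |
|---|---|---|
| autosomes | 3.0 Mb in 2 chromosomes | diploid background, depth 2× haploid |
| X | 1.0 Mb | shared with the female, depth 1× in the male |
| Y X-degenerate | 650 kb | novel single-copy sequence, the easy core |
| Y ampliconic | 40 kb unit × 3 copies | multi-copy: low sharing but high depth |
| Y X-transposed | 50 kb | copy of an X segment mutated to share 60–90% of k-mers |
| Y PAR | 30 kb | exact copy of the X terminus, indistinguishable from female |
| GC | 0.41 | typical mammalian genome-wide GC |

The Y class proportions are a desk-scale caricature of a single-copy-
dominated euchromatic Y with the X-transposed block under 10% of the Y.
The X-transposed mutation rate r solves (1 − r)^k = s for the midpoint s
of the target sharing range — a k-mer survives only if all k bases escape
mutation — and the realized share is measured with the exact backend and
re-drawn if it misses the range by more than 0.05.

Reads are uniform substrings with uniform strand, substitution-only errors
(enough to exercise the abundance floor; no indels), constant quality, and
per-chromosome copy numbers (autosomes 2, X and Y 1 in a male; X 2 in a
female, the single reference X standing for both homologs). Everything is
deterministic given the seeds. Note that k-mer depth is lower than base
depth by the factor (L − k + 1)/L for read length L: at 30× haploid and
L = 150, k = 25, single-copy Y k-mer depth sits near 25, autosomes near 50.

What the generator does **not** model: heterochromatin and low-complexity
sequence, real repeat families shared across chromosomes, indels, read
pairs and insert sizes, assembly artifacts (contigs come from fragmenting
the genome, not from assembling the reads), or deletions private to the
female. Passing the simulated benchmark therefore demonstrates the
geometry of the method — which sequence classes are recoverable at which
thresholds — not its accuracy on real, repeat-rich genomes.

## The benchmark pipeline

`ycontig.workflow.run_simulated_benchmark` runs the whole chain through its
file interfaces: simulate → fragment into ~10 kb contigs (discarding
< 1 kb) → 30× haploid error-free reads → female Bloom store from the exact
reference → exact male counts → features → `female_male` classification at
p < 0.6, depth < 45 → length-weighted evaluation against the manifest.
With these settings single-copy Y is recovered nearly completely; the
ampliconic block (k-mer depth ≈ 3 × 25) is rejected by the 45× ceiling, and
a second pass with the ceiling raised to 1.5 × copies × haploid depth
recovers it — the trade-off the depth threshold controls. X-transposed and
PAR contigs are missed by construction (shared proportion ≥ 0.6), which is
exactly the known blind spot of female-subtraction methods. Problem sizes
(5 Mb genome, ~1.6 M reads) keep a full run in a few minutes on one CPU.

## Numerical and design notes

* Even-length median: mean of the two central values.
* Proportion counts k-mers per occurrence, not deduplicated.
* Bloom capacity defaults to 1.2 × total input length when not given;
  exceeding capacity is an error because the FP guarantee would silently
  void.
* `n_inserted` on the Bloom store is an upper bound on distinct insertions
  (deduplication is per-batch).
* Tie-breaks and strictness are all chosen toward precision: boundary
  points (thresholds, separator) are non-Y.
* The train/test/validation split uses rounded fractions of n; with n not
  a multiple of 25 the sizes are the nearest integers.
* A single CLI `--seed` drives every stochastic stage through derived
  per-stage streams, and each subcommand writes its resolved configuration
  to a JSON sidecar, so any two runs with the same config and inputs give
  byte-identical tables (plots are exempt from byte identity).
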