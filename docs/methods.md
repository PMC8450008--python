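# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `struoforge`. Everything stated here is computed by the test
suite or by `scripts/acceptance.py`; nothing is quoted from external runs.

## Taxonomy conversion

GTDB lineages are fixed 7-rank strings (`d__;p__;c__;o__;f__;g__;s__`).
Rank codes map onto the NCBI dump vocabulary (d→superkingdom, p→phylum, …,
s→species). A taxdump is one node per distinct root-anchored path prefix
plus a root (`taxid == parent == 1`, rank `no rank`). Because no public
convention fixes taxid values for a GTDB-derived dump, assignment had to be
chosen here: breadth-first from the root, siblings in lexicographic name
order, numbering consecutively from 2. This makes the assignment
deterministic and independent of input order, at the cost of being
**collection-relative**: adding a genome can renumber taxids. The pipeline
therefore treats the taxdump built from the current sample table as
authoritative and remaps each genome's taxid to its species node before the
Kraken2 export; taxids in the metadata table are carried as user input but
never trusted across collections.

Two lineages placing the same name at the same rank under different parents
are rejected rather than disambiguated: GTDB names are unique per rank, so
a collision indicates corrupt input.

NCBI↔GTDB name mapping is plurality voting over genomes that carry both
lineage strings: the target is the name at the same rank held by the most
linked genomes, `agreement` is that plurality fraction, and exact ties are
broken toward the lexicographically smallest target and flagged.

## Genome filtering

Assembly-quality filtering keeps genomes with completeness ≥ 50% and
contamination strictly < 5%, then selects one genome per species ranked by
highest completeness, then lowest contamination, then lexicographically
smallest accession (the final tie-break is this package's choice, made for
determinism). Both thresholds are arguments; the defaults reflect the
common MAG quality floor.

## Gene calling and dereplication

Gene calling is a deliberately simple ORF scanner, not a trained gene
finder: maximal ORFs from a start codon (ATG/GTG/TTG) to the next in-frame
stop, both strands, all frames, kept at nucleotide length ≥ 300 (stop
included). Within one stop/frame combination only the longest ORF is
reported. Coordinates are 0-based half-open on the forward strand;
minus-strand genes store the reverse-complement coding sequence. Amino-acid
sequences are the direct translation (bacterial table) with the stop
trimmed; alternative start codons are **not** rewritten to methionine, so
every stored nt/aa pair re-translates exactly — a property the tests
verify. This caller has none of a real gene finder's statistical models
(RBS scoring, GC-frame bias, overlap resolution) and is adequate only
because the synthetic genomes are built to be unambiguous for it.

Per-genome dereplication is greedy centroid selection on nucleotide
sequences, longest first (ties by gene id): a gene is discarded iff its
global-alignment identity to an already retained gene reaches 0.97.
Identity is matching columns over all alignment columns (gaps included)
under match +1 / mismatch −1 / gap open −2 / extend −1. The exact identity
definition varies between dereplication tools; this one is fixed and
documented so results are reproducible, and the test suite validates the
output against an all-pairs alignment oracle.

## Clustering and incremental update

Amino-acid clustering is greedy centroid clustering with exact global
alignments (BLOSUM62, gap open 11 / extend 1): candidates longest-first
(ties by gene id); a gene joins the first representative — in founding
order — with identity ≥ 0.9 **and** coverage ≥ 0.8 (mutually aligned
columns over the shorter sequence length), else it founds a cluster.
The thresholds are exposed configuration, not derived values. No k-mer
prefilter is applied: at the package's intended scale (thousands of genes)
exactness is worth more than speed.

Update never reassigns an existing gene or representative. New genes try
existing representatives first, then representatives founded during the
same update, in the same greedy order. When all new genes sort after all
existing ones in the candidate order (shorter, or lexicographically later
at equal length — which the genome naming convention of the fixtures
guarantees), incremental update is provably identical to a de-novo rebuild;
the suite asserts byte-identical cluster tables and annotation tables for a
10+5 genome split. For inputs that interleave with the existing catalog in
length order, update and rebuild may legitimately differ; this divergence
is inherent to greedy incremental clustering and is documented rather than
hidden.

## Annotation

Only cluster representatives are searched. The search is an exact
global-alignment best-hit scan over the whole reference set: accept hits
with identity ≥ 0.5 and coverage ≥ 0.8 (configurable), rank by alignment
score, break ties by higher identity then smaller reference id. Batch
splitting of the query set is a deterministic parallelism seam (contiguous
chunks, sizes differing by ≤ 1) and never changes results.

Annotations propagate verbatim from representative to members. UniRef90 ids
map to UniRef50 through a two-column index supplied as input; ids absent
from the index are counted and left unannotated at the 50% level. On
update, prior annotation rows are carried over byte-identical (their
`source` field is not rewritten), which is what makes the
update/de-novo equivalence exact; genes newly absorbed into old clusters
receive the representative's annotation with source `propagated`.

HUMAnN headers are `<uniref90_id>|<nt_length>|g__<genus>;s__<species>`,
with `|` as delimiter for downstream tool compatibility. Standalone genes
supplied without nucleotide sequences appear only in the amino-acid
export.

## Misassembly simulation

Three event types, all coordinates 0-based half-open, one seeded generator
threaded through every draw in a fixed order (per genome sorted by id: all
breakpoints, then rearrangements; then chimerisms per donor):

* breakpoint — split a uniformly chosen contig (length ≥ 2) at a position
  uniform on [1, len−1]; children named `<id>_1`, `<id>_2`.
* rearrangement — excise a fragment of length uniform on
  [1000, min(10000, len−1)] from a uniformly chosen eligible contig
  (length ≥ 1001, so excision can never empty a contig) at a uniform
  offset, insert at a uniform position (ends included) on a uniformly
  chosen contig of the same genome.
* chimerism — same draw, but the fragment moves from a donor genome to a
  uniformly chosen other genome. The fragment is removed from the donor
  (a relocation, not a copy), so donor length decreases by L and recipient
  grows by L.

Every event logs genome/contig ids, positions and fragment length, so the
log replays deterministically onto the input; the suite asserts replay
equality and conservation laws (concatenation identity for breakpoints,
per-genome base multisets for rearrangements, dataset-wide totals with
donor−L/recipient+L bookkeeping for chimerisms) over 100 random
configurations.

## Evaluation

Annotation recovery compares the annotation table of a perturbed build
against the unperturbed one: `pct_annotated` = 100 × annotated(test) /
annotated(truth); `pct_correct` additionally requires the paired truth
gene's UniRef90 id to match. Genes are paired by exact nucleotide sequence
first (preferring the same source genome), then by reciprocal best global
nucleotide identity ≥ 0.9 for sequence-disrupted genes. For genes whose
sequence survives an event intact, this is equivalent to coordinate
liftover through the event log while being much simpler; genes cut by an
event usually fail to be called at all and simply count as lost.
Correctness never exceeds the annotation rate by construction.

Bray–Curtis is computed over the taxon union; it is a dissimilarity, not a
metric, so only symmetry, range and identity of indiscernibles are
asserted. The Mantel statistic is the Pearson correlation of the
vectorized upper triangles; the p-value jointly permutes rows/columns of
the second matrix with p = (1 + #{ρ* ≥ ρ}) / (1 + n_perm) (never exactly
zero), 999 permutations by default, seeded. An exhaustive mode enumerates
all n! permutations for small n and is checked against a brute-force
oracle. OLS is the standard least-squares fit with R² = 1 − SS_res/SS_tot.

## Synthetic data

The generator plants shared gene families across genomes: each genome
carries one copy of each family, point-mutated at 2% per interior site
(start/stop codons preserved, stop codons never introduced), strand
randomized, placed with ≥ 50 bp margins in equal slots along the contig.
Intergenic background is sampled uniformly over A/C/G/T subject to never
forming a start codon on either strand (forbidden trigrams ATG/GTG/TTG and
their reverse complements CAT/CAC/CAA), so the ORF caller finds exactly the
planted genes; every contig is verified against the caller at generation
time and re-drawn (bounded retries) if a spurious ORF slipped through.
Reference proteins are one per family — the first planted copy's
translation, optionally mutated at a configurable amino-acid rate — with
families mapped 2:1 onto 50%-level identifiers, so the ground-truth
annotation of every planted gene is known exactly. Community profiles are
log-normal (base abundance lognormal(3, 1), per-sample noise
lognormal(0, 0.5)) with an optional two-group multiplicative shift on the
first fifth of taxa.

What the fixtures do **not** emulate: real base composition and codon
usage, gene density (real genomes are ~90% coding; these are mostly
background), pseudogenes, repeats, horizontal transfer, or read-level
noise. Passing tests therefore demonstrate correctness of the catalog,
clustering, annotation, simulation and evaluation logic — not caller
sensitivity or annotation accuracy on real assemblies.

## Problem sizes and numerics

Default test and acceptance sizes: 4–15 genomes, 1–2 contigs of 6–10 kb,
3–5 planted families of 600–900 bp; the misassembly sweep uses severities
b ∈ {0,2,4,8} with r = c = b/2 over several seeds. These sizes make every
stage exact (no heuristics, no prefilters) while keeping the full suite in
the low minutes on a single core. Alignment identities are exact rational
values of alignment counts; floating-point comparisons in tests use
explicit tolerances; the OLS oracle agrees to 1e-10. Manifest digests are
SHA-256 of file bytes, which is what the determinism guarantees are stated
over.

## Known limitations

* The ORF caller and the exact-alignment search are stand-ins for
  production gene callers and clustered-search engines; they are exact and
  deterministic but quadratic, and are not intended for GTDB-scale inputs.
* Update/de-novo equivalence holds under the documented candidate-order
  condition, not universally.
* Chimerism donors lose sequence; simulators that copy rather than
  relocate fragments will produce different contamination profiles.
* Taxids are collection-relative (see above); exported taxdumps should
  always travel with the library they were generated for.
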