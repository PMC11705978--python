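# Methods

This note records the models, estimators, parameter choices and numerical
conventions behind `taxani`, and what the synthetic test conditions do and
do not demonstrate about real data.

## Canonical k-mer hashing

A k-mer window is valid only if all k bases are in {A,C,G,T}; anything else
(N, IUPAC codes) invalidates every window covering it. The window and its
reverse complement are 2-bit packed (A=0 < C=1 < G=2 < T=3, first base in
the most significant bits, so integer order equals lexicographic string
order) and the smaller value is the canonical form. k must be odd: an even
k-mer can be its own reverse complement, which would make the canonical
choice ambiguous.

The canonical integer, XORed with a fixed seed (`0x5EED1E55`), is passed
through the 64-bit murmur3/splitmix64 finalizer (xor-shift 33, multiply,
xor-shift 33, multiply, xor-shift 33). The function is bijective on uint64
and implemented with NumPy's wrapping uint64 arithmetic, so hashes are
identical across runs, platforms and processes — a hard requirement, since
sketches are persisted and compared across invocations. The seed is part of
the database manifest; loading a database whose (k, s, seed) differ from
the pipeline configuration raises an error rather than silently producing
meaningless distances. No external hashing library is used; the finalizer
is ~10 lines and vectorizes cleanly, which keeps the on-disk format
self-describing and dependency-free.

## MinHash prescreen

* **k = 21, s = 10 000** by default — the customary choices for
  bacterial-scale genomes, giving k-mer specificity ≈ 4^21 ≫ genome size
  and Jaccard standard error ≈ sqrt(j(1−j)/s) ≲ 0.005. Both are
  configurable and recorded in the database manifest.
* Jaccard is estimated from the merged sketch: with M = the s smallest
  values of union(A, B), ĵ = |M ∩ A ∩ B| / |M|. The estimate is exact when
  both genomes have fewer than s distinct k-mers.
* Mash distance D = −(1/k)·ln(2j/(1+j)), clamped to [0, 1]; j = 0 is capped
  at D = 1 (the formula diverges; the cap keeps unrelated genomes sortable).
* Prescreen defaults **max_dist = 0.1, top_n = 20**: 0.1 corresponds to
  ≈ 90% identity, far outside the ~95% species boundary, so the true
  species comfortably survives to step 2 even for atypically diverged
  members; top_n bounds step-2 cost. Ties are broken by accession string
  ascending, everywhere, to keep output deterministic.

## Fragment ANI estimator

The ANI step plays the role a fragment-mapping ANI tool plays in the
published two-step workflows — comparable in role, not bit-identical in
output to any external tool. Design:

1. **Fragmentation**: non-overlapping 3 kb windows per contig, 0-based
   half-open; a terminal remainder shorter than half a fragment is dropped,
   longer remainders and short contigs are kept as short fragments. The
   default length trades mapping specificity against resolution on draft
   assemblies (a 3 kb fragment carries ~120 minimizers at w = 50).
2. **Reference index**: window minimizers (minimum hash of every window of
   w = 50 consecutive k-mer hashes, leftmost on ties, deduplicated by
   position), hash → [(contig, position)], plus the reference's full
   distinct k-mer set. Expected minimizer density is 2/(w+1) ≈ 3.9%.
3. **Mapping**: shared fragment/reference minimizers are binned by diagonal
   offset (ref_pos − frag_pos, bin width = fragment length, ties toward the
   smaller reference coordinate); the best bin must contain ≥ 5 shared
   minimizers covering ≥ 5% of the fragment's minimizers. This approximates
   a collinearity requirement without alignment.
4. **Identity**: containment c of the fragment's full distinct k-mer set in
   the reference's full k-mer set; identity = c^(1/k). Under a per-base
   substitution rate p, E[c] = (1−p)^k, so the estimator is unbiased for
   1−p up to O(1/n) Jensen terms. Identity is deliberately *not* computed
   from the shared-minimizer count: a k-mer that survives mutation need not
   be selected as a minimizer on both sides once its window neighbourhood
   differs, which empirically depresses minimizer containment by several
   percent and would bias ANI low by ~0.3–0.6 points at p = 0.03–0.05.
   Minimizers decide *whether/where* a fragment maps; full-set containment
   decides *how similar* it is. The cost is that containment ignores
   position, so exact repeats elsewhere in the reference can contribute;
   on real genomes with large repeat families this slightly inflates c,
   which is why mapping is still gated by the diagonal test.
5. **Genome ANI** = 100 × mean identity over mapped fragments, computed as
   an fsum over *sorted* identities so the value is bit-identical under
   contig/fragment reordering. ANI is undefined (and the reference yields
   no hit) when the aligned fraction < 0.15 — the gate that prevents a
   single conserved operon from producing a confident-looking ANI between
   unrelated genomes.

Self-comparison yields ANI exactly 100.0 (containment 1 for every
fragment). Indels shift diagonals smoothly (bin width 3 kb absorbs them)
but break the (1−p)^k calibration, so numeric recovery guarantees are
stated for the substitution-only model; the simulator supports indels for
qualitative tests.

## Reference database

* **Type-genome selection** is a pure row predicate: keep iff
  `relation_to_type_material` non-empty AND `excluded_from_refseq` empty
  AND taxonomy-check status ≠ `Failed`. "Misidentified type genome" is
  operationalized as status `Failed`; `Inconclusive` genomes are retained,
  since the upstream curator marks confirmed mislabels as Failed. The NCBI
  column vocabulary drifts over time, so column names are normalized
  through a documented alias map and the status vocabulary is validated at
  parse time.
* **Thresholds**: species-specific ANI thresholds (sanity-bounded to
  (75, 100)); lookup of an unlisted species returns the conventional 95%.
  GTDB mode carries no threshold table — a flat 95% applies to every
  species, matching how representative-genome assignment is defined.
* **Indistinguishable groups** require ≥ 2 members; a species may belong to
  at most one group.
* **Persistence**: a directory with `manifest.json` (format version, mode,
  k, s, hash seed, sketch digest), `sketches.json` (consolidated sketch
  file with the same header) and `refdb.sqlite` (catalog, thresholds,
  groups, schema v1). Manifest and sketch file are byte-deterministic in
  the inputs; the build timestamp lives only in SQLite so rebuilds are
  checksum-identical. Loading cross-checks manifest vs sketch header and
  catalog/sketch bijection.

## Classification

Acceptance uses **ANI ≥ threshold**. The source material for the status
semantics prints a strict ">" in one place and "≥" in another; ≥ was chosen
so a species-specific threshold exactly attained counts as accepted (the
strict variant would make the published threshold itself unreachable).
The four statuses are exhaustive and exclusive on any hit list:
no accepted hits → `no_hit`; one accepted species → `conclusive`; several
accepted species all mapping to a single indistinguishable group →
`indistinguishable`; otherwise `inconclusive`. A single accepted species
that merely *belongs* to a group is conclusive — group status describes
ambiguity actually observed, not potential ambiguity. For inconclusive and
indistinguishable results the top-ANI species is surfaced as a candidate,
clearly not an assignment. Sub-threshold near-misses are reported as
rejected hit rows only; they never affect the status.

The genome-size check compares assembly length to
[0.7 · min, 1.3 · max] over the species' reference lengths (one reference:
[0.7L, 1.3L]). The 0.7/1.3 factors are this package's defaults — generous
enough to tolerate draft incompleteness and plasmid variation — and the
range endpoints are reported so users can judge borderline cases; species
unknown or without references gives verdict `unknown`, never a hard
failure.

## Synthetic study conditions

The fixture generator models a genome as i.i.d. bases at a target GC and a
conspecific genome as a per-site substitution mutant (optional geometric
indels). Defaults: 20 species × 200 kb, queries 2% diverged from their
parents. One master seed fans out to per-genome 31-bit seeds through a
fixed NumPy generator, so a universe is a pure function of its spec.

What this does *not* emulate: real congeneric species share conserved genes
(independent random genomes share essentially no k-mers, a much stronger
separation), and real genomes carry repeats, rearrangements, HGT and
contamination. Passing the end-to-end recovery tests therefore shows the
pipeline's machinery and calibration are correct, not that real borderline
species pairs (the inconclusive/indistinguishable territory) are resolved —
those depend on the biological reference data, not on this code. Genome
sizes in the tests (50–200 kb rather than megabases) were chosen to keep
the suite and the acceptance script fast; all estimators scale in n only
through variance, which the tests' tolerances already account for.

## Numerical conventions

Coordinates are 0-based half-open internally. All sort orders have
documented deterministic tie-breaks (accession ascending; smaller reference
coordinate for diagonal bins). Reports contain no timestamps; identical
inputs and configuration reproduce reports byte-for-byte. Exit codes:
0 conclusive/indistinguishable, 1 inconclusive, 2 no hit.
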