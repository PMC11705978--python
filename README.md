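# taxani

Two-step species identification and quality control for prokaryotic genome
assemblies.

Mislabelled genomes in public databases propagate errors into every analysis
that reuses them. Before depositing (or reusing) a bacterial or archaeal
assembly, one wants a fast, local answer to: *which validly named species
does this genome actually belong to, and is its size plausible for that
species?* `taxani` answers this by comparing an assembly against type-strain
genomes (NCBI taxonomy) or representative genomes (GTDB taxonomy), for
people running genome projects who need to screen tens to thousands of
assemblies on an ordinary machine.

## Method

**Step 1 — genome-distance prescreen.** Each genome is reduced to a bottom-s
MinHash sketch: the s smallest 64-bit hashes of its canonical k-mer set
(k = 21, s = 10 000 by default). For a query/reference pair the Jaccard
similarity j is estimated from the merged sketch and converted to the Mash
distance

    D = -(1/k) · ln( 2j / (1+j) ),

an estimate of per-base divergence. References with D ≤ 0.1 (≈ 90% identity)
survive, at most 20 of them.

**Step 2 — fragment ANI.** The query is cut into 3 kb fragments. Each
fragment is located on a candidate reference via shared window minimizers
binned by diagonal offset; a fragment *maps* when its best diagonal holds
enough shared minimizers. Per-fragment identity comes from k-mer
containment: under substitution rate p a k-mer survives intact with
probability (1−p)^k, so with containment c the identity estimate is

    identity = c^(1/k),      ANI = 100 · mean identity over mapped fragments.

ANI is reported only when the aligned fraction (mapped/total fragments)
reaches 0.15, which suppresses spurious hits driven by a single conserved
region.

**Classification.** A hit is *accepted* when ANI ≥ the species' threshold —
a species-specific cutoff when NCBI publishes one, otherwise the
conventional 95% species boundary (GTDB mode always uses 95%). The outcome
is:

| status              | meaning                                                        |
|---------------------|----------------------------------------------------------------|
| `conclusive`        | accepted hits against exactly one species → assignment         |
| `indistinguishable` | several species, all in one known indistinguishable group (e.g. *E. coli*/*Shigella*) |
| `inconclusive`      | several unrelated species; the top-ANI species is a candidate  |
| `no_hit`            | no accepted hits                                               |

Finally the assembly length is checked against [0.7·min, 1.3·max] of the
species' reference genome lengths.

The reference database is built from NCBI-dialect metadata: assemblies are
retained iff they derive from type material, are not excluded from RefSeq,
and their taxonomy-check status is not `Failed`. Sketches are persisted in a
consolidated, versioned sketch file alongside a SQLite metadata store; both
are byte-deterministic functions of the inputs.

## Worked example

No downloads needed — the package ships a deterministic simulator that
writes a reference universe plus diverged query genomes:

```bash
taxani simulate --out universe --n-species 5 --length 50000 --seed 7
taxani build-db --genomes universe/genomes \
    --summary universe/assembly_summary.tsv \
    --ani-report universe/ani_report.tsv \
    --thresholds universe/thresholds.tsv \
    --groups universe/groups.tsv \
    --out refdb -s 1000
taxani check universe/queries/query_00.fna --db refdb --out-dir reports --format both
```

The check prints one line per query and exits 0 (conclusive or
indistinguishable), 1 (inconclusive) or 2 (no hit):

```
query_00.fna	conclusive	Simulatus species00	pass
```

and `reports/query_00.report.tsv` contains the per-reference evidence:

```
query_id	status	ref_accession	organism_name	species_taxid	ani	aligned_fraction	threshold	accepted
query_00	conclusive	GCA_SIM000000.1	Simulatus species00	100000	97.95	1.0000	95.00	True
```

The query was simulated 2% diverged from its parent, so its ANI of 97.95 is
right at the expected 100·(1−0.02) = 98; it clears the 95% threshold against
exactly one species, hence `conclusive`, and its length falls inside the
expected range for the species (`pass`). The JSON report additionally
carries assembly statistics, the size-check bounds and the full run
configuration for provenance.

The same `check`/`build-db` commands accept real assemblies and real NCBI
metadata files (`assembly_summary_genbank.txt`, `ANI_report_prokaryotes.txt`,
the species-threshold and indistinguishable-group tables); `--gtdb` switches
both commands to GTDB representative genomes and a flat 95% threshold.

## Scope

Species-level identification only: no phylogenetic placement above species
rank, no completeness/contamination estimation (the JSON report reserves
`completeness`/`contamination` fields for an external checker), and no
built-in downloading — reference genomes and metadata are local files.
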