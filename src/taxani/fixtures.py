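"""Deterministic synthetic genomes and metadata fixtures.

Every other module is testable without downloads: this module writes a
small "universe" — reference genomes, the four metadata TSVs in their
NCBI-style dialects, and labelled query genomes — as a pure function of a
:class:`SimSpec`.

Model and its limits
--------------------
Genomes are i.i.d. base sequences at a chosen GC content; distinct species
are *independent* draws, so their expected k-mer sharing is ~0 — a far
stronger separation than real congeneric species, which share conserved
operons.  Within-species queries are produced by per-site substitution (and
optionally geometric-length indels) at a known rate, so the expected ANI of
a query against its parent is 100·(1-p).  Rearrangements, HGT, plasmids and
contamination are not modelled.

Seeding: one master seed fans out to per-genome integer seeds drawn from a
``numpy`` generator initialised with the master (documented, stable rule),
so the universe is reproducible genome-by-genome.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .io_formats import SeqRecord, write_fasta

__all__ = ["SimSpec", "simulate_genome", "mutate_genome", "build_fixture_universe"]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SimSpec:
    """Study conditions for a synthetic universe.

    Defaults: 20 species of 200 kb at GC 0.5, queries diverged 2% from
    their parents by substitution only — comfortably inside the 95% ANI
    species boundary, while independent references sit effectively at
    ANI-undefined distance from each other.
    """

    n_species: int = 20
    genome_length: int = 200_000
    gc: float = 0.5
    within_species_divergence: float = 0.02
    between_species_min_divergence: float = 0.10
    indel_rate: float = 0.0
    seed: int = 7

    def __post_init__(self) -> None:
        if not (0.0 <= self.within_species_divergence <= 0.3):
            raise ValueError("within_species_divergence must be in [0, 0.3]")
        if not (0.0 <= self.indel_rate <= 0.3):
            raise ValueError("indel_rate must be in [0, 0.3]")
        if self.between_species_min_divergence <= self.within_species_divergence:
            raise ValueError(
                "between_species_min_divergence must exceed within_species_divergence"
            )


def simulate_genome(length: int, gc: float, seed: int, contig_id: str = "contig1") -> SeqRecord:
    """An i.i.d. random genome with P(G)+P(C) = gc; deterministic per seed."""
    if length < 1:
        raise ValueError("length must be >= 1")
    if not (0.0 < gc < 1.0):
        raise ValueError("gc must be in (0, 1)")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    codes = rng.choice(4, size=length, p=p)
    seq = _BASES[codes].tobytes().decode("ascii")
    return SeqRecord(id=contig_id, sequence=seq)


def mutate_genome(record: SeqRecord, subst_rate: float, indel_rate: float = 0.0,
                  seed: int = 0) -> SeqRecord:
    """Mutate per site: substitution to a uniformly chosen *different* base
    with probability ``subst_rate``; indel events at rate ``indel_rate``
    with geometric(0.5) lengths, insertion or deletion equally likely.
    Deterministic per seed.
    """
    for name, rate in (("subst_rate", subst_rate), ("indel_rate", indel_rate)):
        if not (0.0 <= rate <= 0.3):
            raise ValueError(f"{name} must be in [0, 0.3], got {rate}")
    rng = np.random.default_rng(seed)
    codes = np.searchsorted(_BASES, np.frombuffer(record.sequence.encode(), dtype=np.uint8))
    # substitutions: add 1..3 mod 4 so the base always changes
    mask = rng.random(codes.size) < subst_rate
    shift = rng.integers(1, 4, size=codes.size)
    codes = np.where(mask, (codes + shift) % 4, codes)
    if indel_rate > 0.0:
        events = np.flatnonzero(rng.random(codes.size) < indel_rate)
        pieces: list[np.ndarray] = []
        prev = 0
        for pos in events:
            if pos < prev:
                continue
            length = int(rng.geometric(0.5))
            if rng.random() < 0.5:  # deletion
                pieces.append(codes[prev:pos])
                prev = pos + length
            else:  # insertion
                pieces.append(codes[prev:pos])
                pieces.append(rng.integers(0, 4, size=length))
                prev = pos
        pieces.append(codes[prev:])
        codes = np.concatenate(pieces)
    seq = _BASES[codes].tobytes().decode("ascii")
    return SeqRecord(id=record.id, sequence=seq, description=record.description)


def _child_seeds(master: int, n: int) -> list[int]:
    """Fan a master seed out to n independent 31-bit child seeds."""
    rng = np.random.default_rng(master)
    return [int(x) for x in rng.integers(0, 2**31, size=n)]


def build_fixture_universe(spec: SimSpec, out_dir: str | Path,
                           *, thresholds: dict[int, float] | None = None,
                           group_pairs: list[tuple[int, int, str]] | None = None) -> dict:
    """Write a complete synthetic universe; returns the manifest dict.

    Layout under ``out_dir``::

        genomes/GCA_SIM{i}.1_genomic.fna   reference genomes (one/species)
        queries/query_{i}.fna              one query per species, mutated at
                                           within_species_divergence
        assembly_summary.tsv  ani_report.tsv  thresholds.tsv  groups.tsv
        manifest.json                      ground-truth labels

    References are independent simulations, hence mutually separated far
    beyond ``between_species_min_divergence`` in expectation.  All metadata
    rows mark the genomes as type material with taxonomy-check status OK.
    ``thresholds`` (taxid -> percent) and ``group_pairs`` (taxid, taxid,
    group id) optionally populate the two auxiliary tables.
    """
    out_dir = Path(out_dir)
    genome_dir = out_dir / "genomes"
    query_dir = out_dir / "queries"
    genome_dir.mkdir(parents=True, exist_ok=True)
    query_dir.mkdir(parents=True, exist_ok=True)

    n = spec.n_species
    seeds = _child_seeds(spec.seed, 2 * n)
    summary_rows: list[str] = []
    report_rows: list[str] = []
    labels: dict[str, dict] = {}

    for i in range(n):
        accession = f"GCA_SIM{i:06d}.1"
        taxid = 100_000 + i
        organism = f"Simulatus species{i:02d}"
        genome = simulate_genome(spec.genome_length, spec.gc, seeds[i],
                                 contig_id=f"{accession}_c1")
        write_fasta([genome], genome_dir / f"{accession}_genomic.fna")
        summary_rows.append("\t".join([
            accession, organism, str(taxid), "assembly from type material", "na",
        ]))
        report_rows.append("\t".join([accession, "OK"]))

        query = mutate_genome(genome, spec.within_species_divergence,
                              spec.indel_rate, seed=seeds[n + i])
        qname = f"query_{i:02d}.fna"
        write_fasta([SeqRecord(id=f"q{i:02d}", sequence=query.sequence)],
                    query_dir / qname)
        labels[qname] = {
            "parent_accession": accession,
            "species_taxid": taxid,
            "organism_name": organism,
            "divergence": spec.within_species_divergence,
        }

    (out_dir / "assembly_summary.tsv").write_text(
        "# Synthetic assembly summary\n"
        "# assembly_accession\torganism_name\tspecies_taxid\t"
        "relation_to_type_material\texcluded_from_refseq\n"
        + "\n".join(summary_rows) + "\n"
    )
    (out_dir / "ani_report.tsv").write_text(
        "# genbank_accession\ttaxonomy_check_status\n" + "\n".join(report_rows) + "\n"
    )
    thr_rows = [f"{t}\t{v}" for t, v in sorted((thresholds or {}).items())]
    (out_dir / "thresholds.tsv").write_text(
        "species_taxid\tani_threshold\n" + ("\n".join(thr_rows) + "\n" if thr_rows else "")
    )
    grp_rows: list[str] = []
    for a, b, gid in group_pairs or []:
        grp_rows += [f"{a}\t{gid}", f"{b}\t{gid}"]
    (out_dir / "groups.tsv").write_text(
        "species_taxid\tgroup_id\n" + ("\n".join(grp_rows) + "\n" if grp_rows else "")
    )

    manifest = {
        "spec": {
            "n_species": spec.n_species,
            "genome_length": spec.genome_length,
            "gc": spec.gc,
            "within_species_divergence": spec.within_species_divergence,
            "between_species_min_divergence": spec.between_species_min_divergence,
            "indel_rate": spec.indel_rate,
            "seed": spec.seed,
        },
        "queries": labels,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
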