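"""FASTA input, assembly statistics, and the TSV/JSON report writers.

A genome assembly is a multi-FASTA file (optionally gzip-compressed); all
contigs in one file are treated as one genome.  Sequences are stored
uppercase; bases outside A/C/G/T are kept in the sequence but ignored by
the k-mer machinery downstream.
"""

from __future__ import annotations

import gzip
import io
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

from .errors import FastaFormatError

__all__ = [
    "SeqRecord",
    "GenomeStats",
    "read_fasta",
    "write_fasta",
    "genome_stats",
    "write_report",
    "read_report",
]


@dataclass(frozen=True)
class SeqRecord:
    """One contig: ``id`` is the first whitespace-delimited header token."""

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise FastaFormatError("sequence record with empty id")
        if not self.sequence:
            raise FastaFormatError(f"record {self.id!r} has an empty sequence")


@dataclass(frozen=True)
class GenomeStats:
    """Basic assembly statistics.

    ``gc_fraction`` is computed over unambiguous (A/C/G/T) bases only;
    ``n_ambiguous`` counts everything else.  N50 is the largest length L
    such that contigs of length >= L sum to at least half the assembly.
    """

    total_length: int
    n_contigs: int
    n50: int
    gc_fraction: float
    n_ambiguous: int


def _open_text(path: str | Path) -> io.TextIOBase:
    """Open plain or gzipped text transparently (sniffs the gzip magic)."""
    path = Path(path)
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return io.TextIOWrapper(gzip.open(path, "rb"))
    return open(path, "rt")


def read_fasta(path: str | Path) -> list[SeqRecord]:
    """Read a (possibly gzipped) FASTA assembly into a list of records.

    Raises :class:`FastaFormatError` for an empty file, a file without a
    ``>`` header, or duplicate record ids.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with _open_text(path) as fh:
        head = fh.read(1)
        if not head:
            raise FastaFormatError(f"{path}: empty file")
        if head != ">":
            raise FastaFormatError(f"{path}: not FASTA (no '>' header on first line)")
        fh.seek(0)
        records: list[SeqRecord] = []
        seen: set[str] = set()
        for rec in SeqIO.parse(fh, "fasta"):
            if rec.id in seen:
                raise FastaFormatError(f"{path}: duplicate sequence id {rec.id!r}")
            seen.add(rec.id)
            seq = str(rec.seq).upper()
            if not seq:
                raise FastaFormatError(f"{path}: record {rec.id!r} has an empty sequence")
            records.append(SeqRecord(id=rec.id, sequence=seq, description=rec.description))
    if not records:
        raise FastaFormatError(f"{path}: no sequence records found")
    return records


def write_fasta(records: Iterable[SeqRecord], path: str | Path, width: int = 80) -> None:
    """Write records as plain FASTA, wrapping sequence lines at ``width``."""
    with open(path, "wt") as fh:
        for rec in records:
            header = rec.description if rec.description else rec.id
            fh.write(f">{header}\n")
            seq = rec.sequence
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


_GC = frozenset("GC")
_UNAMBIG = frozenset("ACGT")


def genome_stats(records: Sequence[SeqRecord]) -> GenomeStats:
    """Compute assembly statistics; invariant to contig order."""
    if not records:
        raise ValueError("genome_stats requires at least one record")
    lengths = sorted((len(r.sequence) for r in records), reverse=True)
    total = sum(lengths)
    half = total / 2
    cum = 0
    n50 = lengths[0]
    for length in lengths:
        cum += length
        if cum >= half:
            n50 = length
            break
    gc = 0
    unambig = 0
    for r in records:
        for base in r.sequence:
            if base in _UNAMBIG:
                unambig += 1
                if base in _GC:
                    gc += 1
    return GenomeStats(
        total_length=total,
        n_contigs=len(records),
        n50=n50,
        gc_fraction=(gc / unambig) if unambig else 0.0,
        n_ambiguous=total - unambig,
    )


# --------------------------------------------------------------------------
# Report output
# --------------------------------------------------------------------------

REPORT_COLUMNS = (
    "query_id",
    "status",
    "ref_accession",
    "organism_name",
    "species_taxid",
    "ani",
    "aligned_fraction",
    "threshold",
    "accepted",
)


def _hit_row(query_id: str, status: str, hit) -> list[str]:
    return [
        query_id,
        status,
        hit.ref_accession,
        hit.organism_name,
        str(hit.species_taxid),
        f"{hit.ani:.2f}" if hit.ani is not None else "",
        f"{hit.aligned_fraction:.4f}",
        f"{hit.threshold:.2f}",
        str(hit.accepted),
    ]


def report_to_dict(result, stats: GenomeStats | None = None, size_check=None,
                   config: dict | None = None) -> dict:
    """Assemble the nested JSON report structure.

    ``completeness``/``contamination`` are reserved fields (populated by an
    external completeness checker, not computed here) and are always null.
    """
    doc: dict = {
        "query_id": result.query_id,
        "status": str(result.status),
        "assigned_species": result.assigned_species,
        "group_id": result.group_id,
        "hits": [
            {
                "ref_accession": h.ref_accession,
                "organism_name": h.organism_name,
                "species_taxid": h.species_taxid,
                "ani": h.ani,
                "aligned_fraction": h.aligned_fraction,
                "threshold": h.threshold,
                "accepted": h.accepted,
            }
            for h in result.hits
        ],
        "genome_stats": None,
        "size_check": None,
        "completeness": None,
        "contamination": None,
    }
    if stats is not None:
        doc["genome_stats"] = {
            "total_length": stats.total_length,
            "n_contigs": stats.n_contigs,
            "n50": stats.n50,
            "gc_fraction": stats.gc_fraction,
            "n_ambiguous": stats.n_ambiguous,
        }
    if size_check is not None:
        doc["size_check"] = {
            "total_length": size_check.total_length,
            "expected_min": size_check.expected_min,
            "expected_max": size_check.expected_max,
            "verdict": str(size_check.verdict),
        }
    if config is not None:
        doc["config"] = config
    return doc


def write_report(result, path: str | Path, format: str = "tsv", *,
                 stats: GenomeStats | None = None, size_check=None,
                 config: dict | None = None) -> None:
    """Write a taxonomy-check report.

    TSV: one row per reference hit (all hits, sorted by ANI descending as
    carried by the result); a result with no hits yields a single row with
    the status and empty reference fields.  JSON: the nested structure of
    :func:`report_to_dict`.  Output is deterministic (no timestamps).
    """
    path = Path(path)
    if format == "tsv":
        lines = ["\t".join(REPORT_COLUMNS)]
        if result.hits:
            for h in result.hits:
                lines.append("\t".join(_hit_row(result.query_id, str(result.status), h)))
        else:
            lines.append(
                "\t".join([result.query_id, str(result.status), "", "", "", "", "", "", ""])
            )
        path.write_text("\n".join(lines) + "\n")
    elif format == "json":
        doc = report_to_dict(result, stats=stats, size_check=size_check, config=config)
        path.write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")
    else:
        raise ValueError(f"unknown report format {format!r} (expected 'tsv' or 'json')")


def read_report(path: str | Path) -> dict:
    """Load a JSON report back into its dict form (lossless round-trip)."""
    return json.loads(Path(path).read_text())
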