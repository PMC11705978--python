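"""Reference-database construction and loading.

The database integrates four inputs, all in NCBI-dialect TSV:

* an assembly summary (accession, organism, species taxid, whether the
  assembly derives from type material, RefSeq exclusion reason),
* a taxonomy-check ANI report (per-accession OK / Inconclusive / Failed),
* a species-specific ANI threshold table (default 95% when absent),
* indistinguishable species groups (e.g. *Escherichia coli* / *Shigella*),

plus one FASTA per retained reference genome.  Type-genome selection keeps
an assembly iff it derives from type material, is not excluded from
RefSeq, and its taxonomy-check status is not Failed (a confirmed mislabel);
Inconclusive genomes are retained.

On disk a database directory holds::

    manifest.json    # format version, mode, k, s, hash seed, sketch digest
    sketches.json    # consolidated sketch file (all reference sketches)
    refdb.sqlite     # catalog + thresholds + groups (schema v1)

``manifest.json`` and ``sketches.json`` are byte-deterministic functions of
the inputs and parameters, so a rebuild is checksum-identical; the build
timestamp lives only inside the SQLite store.  Loading verifies that the
requested (k, s, hash seed) match the manifest and fails loudly otherwise.

In GTDB mode the catalog carries GTDB species labels (``s__...``), the
threshold table is empty and a flat 95% applies to every species.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sqlite3
from dataclasses import dataclass, field, replace
from datetime import datetime, timezone
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .errors import RefDBError, SketchMismatchError, TableFormatError
from .io_formats import read_fasta
from .sketch import DEFAULT_HASH_SEED, DEFAULT_K, DEFAULT_SKETCH_SIZE, Sketch, minhash_sketch

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "RefGenomeMeta",
    "ThresholdTable",
    "IndistinguishableGroups",
    "RefDB",
    "parse_assembly_summary",
    "parse_ani_report",
    "select_type_genomes",
    "parse_threshold_table",
    "parse_groups",
    "build_reference_db",
    "build_gtdb_db",
    "load_refdb",
]

SCHEMA_VERSION = 1
DEFAULT_ANI_THRESHOLD = 95.0


@dataclass
class RefGenomeMeta:
    """Catalog entry for one reference assembly.

    ``relation_to_type_material`` empty means not type material;
    ``excluded_from_refseq`` empty means not excluded;
    ``taxonomy_check_status`` is one of OK / Inconclusive / Failed / "".
    ``species_label`` carries the GTDB species name in GTDB mode.
    """

    accession: str
    organism_name: str
    species_taxid: int
    relation_to_type_material: str = ""
    excluded_from_refseq: str = ""
    taxonomy_check_status: str = ""
    species_label: str = ""
    total_length: int = 0
    fasta_path: str = ""

    def species_key(self) -> int | str:
        """Key used to group hits into species (taxid, or GTDB label)."""
        return self.species_label if self.species_label else self.species_taxid


class ThresholdTable:
    """Species-specific ANI acceptance thresholds (percent).

    Lookup of an absent taxid yields the default (95%)."""

    def __init__(self, thresholds: Mapping[int, float] | None = None,
                 default: float = DEFAULT_ANI_THRESHOLD) -> None:
        self.thresholds: dict[int, float] = dict(thresholds or {})
        self.default = float(default)

    def get(self, species_taxid: int | str) -> float:
        if isinstance(species_taxid, int):
            return self.thresholds.get(species_taxid, self.default)
        return self.default

    def __len__(self) -> int:
        return len(self.thresholds)

    def __eq__(self, other) -> bool:
        return (isinstance(other, ThresholdTable)
                and self.thresholds == other.thresholds
                and self.default == other.default)


class IndistinguishableGroups:
    """Groups of species that ANI cannot tell apart."""

    def __init__(self, membership: Mapping[int | str, str] | None = None) -> None:
        self.membership: dict[int | str, str] = dict(membership or {})
        members: dict[str, list] = {}
        for taxid, gid in self.membership.items():
            members.setdefault(gid, []).append(taxid)
        self.members = members

    def group_of(self, species: int | str) -> str | None:
        return self.membership.get(species)

    def __len__(self) -> int:
        return len(self.members)

    def __eq__(self, other) -> bool:
        return (isinstance(other, IndistinguishableGroups)
                and self.membership == other.membership)


# --------------------------------------------------------------------------
# TSV parsing (NCBI dialect)
# --------------------------------------------------------------------------

def _norm_col(name: str) -> str:
    return name.strip().lstrip("#").strip().lower().replace("-", "_").replace(" ", "_")


#: Column-name drift observed across NCBI file revisions.
COLUMN_ALIASES = {
    "assembly_accession": "accession",
    "genbank_accession": "accession",
    "relation_to_type_material": "relation_to_type_material",
    "organism_name": "organism_name",
    "species_taxid": "species_taxid",
    "taxid": "taxid",
    "excluded_from_refseq": "excluded_from_refseq",
    "taxonomy_check_status": "taxonomy_check_status",
    "ani_threshold": "ani_threshold",
    "threshold": "ani_threshold",
    "group_id": "group_id",
    "group": "group_id",
    "gtdb_taxonomy": "gtdb_taxonomy",
    "species": "species_label",
    "gtdb_species": "species_label",
}


def _read_tsv_table(path: str | Path, required: Sequence[str]) -> tuple[list[dict[str, str]], list[int]]:
    """Read an NCBI-dialect TSV: '#'-comment lines, the last comment line
    (or the first line) is the header; 'na' is the null token.

    Returns (rows as dicts keyed by canonical column names, 1-based line
    numbers of the data rows).
    """
    path = Path(path)
    header: list[str] | None = None
    rows: list[dict[str, str]] = []
    lineno_of: list[int] = []
    with open(path, "rt") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                # NCBI convention: the last comment line is the header row
                candidate = [_norm_col(c) for c in line.lstrip("#").strip().split("\t")]
                if len(candidate) > 1 or candidate[0] in COLUMN_ALIASES:
                    header = [COLUMN_ALIASES.get(c, c) for c in candidate]
                continue
            if header is None:
                # plain dialect: first non-comment line is the header
                candidate = [_norm_col(c) for c in line.split("\t")]
                mapped = [COLUMN_ALIASES.get(c, c) for c in candidate]
                if not set(required) <= set(mapped):
                    raise TableFormatError(
                        f"{path}: no header found; expected columns {sorted(required)}"
                    )
                header = mapped
                continue
            fields = line.split("\t")
            if len(fields) > len(header):
                raise TableFormatError(
                    f"{path}, line {lineno}: {len(fields)} fields but header has {len(header)}"
                )
            row = {col: "" for col in header}
            for col, value in zip(header, fields):
                value = value.strip()
                row[col] = "" if value.lower() == "na" else value
            rows.append(row)
            lineno_of.append(lineno)
    if header is None:
        raise TableFormatError(f"{path}: empty table (no header line)")
    missing = set(required) - set(header)
    if missing:
        raise TableFormatError(f"{path}: missing required columns {sorted(missing)}")
    return rows, lineno_of


def parse_assembly_summary(path: str | Path) -> list[RefGenomeMeta]:
    """Parse an assembly summary into partial catalog entries.

    Required columns: accession, organism_name, species_taxid,
    relation_to_type_material; excluded_from_refseq is honoured when
    present.  Unknown extra columns are ignored.
    """
    required = ["accession", "organism_name", "species_taxid", "relation_to_type_material"]
    rows, linenos = _read_tsv_table(path, required)
    out: list[RefGenomeMeta] = []
    seen: set[str] = set()
    for row, lineno in zip(rows, linenos):
        acc = row["accession"]
        if not acc:
            raise TableFormatError(f"{path}, line {lineno}: empty accession")
        if acc in seen:
            raise TableFormatError(f"{path}, line {lineno}: duplicate accession {acc!r}")
        seen.add(acc)
        try:
            taxid = int(row["species_taxid"])
        except ValueError as exc:
            raise TableFormatError(
                f"{path}, line {lineno}: species_taxid {row['species_taxid']!r} is not an integer"
            ) from exc
        if taxid <= 0:
            raise TableFormatError(f"{path}, line {lineno}: species_taxid must be positive")
        out.append(RefGenomeMeta(
            accession=acc,
            organism_name=row["organism_name"],
            species_taxid=taxid,
            relation_to_type_material=row["relation_to_type_material"],
            excluded_from_refseq=row.get("excluded_from_refseq", ""),
        ))
    return out


_STATUS_MAP = {"ok": "OK", "inconclusive": "Inconclusive", "failed": "Failed", "": ""}


def parse_ani_report(path: str | Path) -> dict[str, str]:
    """Parse the taxonomy-check ANI report into accession -> status.

    Status values are normalized to {OK, Inconclusive, Failed, ""}; an
    accession absent from the mapping is treated as "".  Duplicate rows for
    one accession: the last wins, with a logged warning.
    """
    rows, linenos = _read_tsv_table(path, ["accession", "taxonomy_check_status"])
    out: dict[str, str] = {}
    for row, lineno in zip(rows, linenos):
        acc = row["accession"]
        if not acc:
            raise TableFormatError(f"{path}, line {lineno}: empty accession")
        raw = row["taxonomy_check_status"]
        key = raw.strip().lower()
        if key not in _STATUS_MAP:
            raise TableFormatError(
                f"{path}, line {lineno}: unknown taxonomy check status {raw!r} "
                f"(expected OK, Inconclusive, Failed or na)"
            )
        if acc in out:
            logger.warning("%s, line %d: duplicate ANI-report row for %s; last wins",
                           path, lineno, acc)
        out[acc] = _STATUS_MAP[key]
    return out


def select_type_genomes(catalog: Iterable[RefGenomeMeta],
                        ani_report: Mapping[str, str]) -> list[RefGenomeMeta]:
    """Apply the type-genome filtering predicate.

    Retained iff the assembly derives from type material, is not excluded
    from RefSeq, and its taxonomy-check status is not Failed.  Input order
    is preserved; the returned entries carry the resolved status.
    """
    kept: list[RefGenomeMeta] = []
    for meta in catalog:
        status = ani_report.get(meta.accession, "")
        meta = replace(meta, taxonomy_check_status=status)
        if not meta.relation_to_type_material:
            continue
        if meta.excluded_from_refseq:
            continue
        if status == "Failed":
            continue
        kept.append(meta)
    return kept


def parse_threshold_table(path: str | Path) -> ThresholdTable:
    """Parse the species-specific ANI threshold table (taxid, percent)."""
    rows, linenos = _read_tsv_table(path, ["species_taxid", "ani_threshold"])
    thresholds: dict[int, float] = {}
    for row, lineno in zip(rows, linenos):
        try:
            taxid = int(row["species_taxid"])
            value = float(row["ani_threshold"])
        except ValueError as exc:
            raise TableFormatError(f"{path}, line {lineno}: non-numeric row") from exc
        if taxid in thresholds:
            raise TableFormatError(f"{path}, line {lineno}: duplicate taxid {taxid}")
        if not (75.0 < value < 100.0):
            raise TableFormatError(
                f"{path}, line {lineno}: threshold {value} outside (75, 100)"
            )
        thresholds[taxid] = value
    return ThresholdTable(thresholds)


def parse_groups(path: str | Path) -> IndistinguishableGroups:
    """Parse indistinguishable-group membership (taxid, group id)."""
    rows, linenos = _read_tsv_table(path, ["species_taxid", "group_id"])
    membership: dict[int | str, str] = {}
    for row, lineno in zip(rows, linenos):
        try:
            taxid = int(row["species_taxid"])
        except ValueError as exc:
            raise TableFormatError(f"{path}, line {lineno}: non-integer taxid") from exc
        gid = row["group_id"]
        if not gid:
            raise TableFormatError(f"{path}, line {lineno}: empty group id")
        if taxid in membership:
            raise TableFormatError(
                f"{path}, line {lineno}: species {taxid} assigned to more than one group"
            )
        membership[taxid] = gid
    groups = IndistinguishableGroups(membership)
    singletons = sorted(g for g, ms in groups.members.items() if len(ms) < 2)
    if singletons:
        raise TableFormatError(
            f"{path}: indistinguishable groups must have >= 2 members; "
            f"singleton group(s) {singletons}"
        )
    return groups


# --------------------------------------------------------------------------
# Database build / load
# --------------------------------------------------------------------------

@dataclass
class RefDB:
    """Loaded reference database (catalog + sketches + thresholds + groups)."""

    catalog: dict[str, RefGenomeMeta]
    sketches: dict[str, Sketch]
    thresholds: ThresholdTable
    groups: IndistinguishableGroups
    mode: str  # "ncbi" | "gtdb"
    k: int
    s: int
    hash_seed: int
    db_dir: Path | None = None
    _ani_index_cache: dict = field(default_factory=dict, repr=False)

    def threshold_for(self, species_key: int | str) -> float:
        if self.mode == "gtdb":
            return DEFAULT_ANI_THRESHOLD
        return self.thresholds.get(species_key)

    def genome_records(self, accession: str):
        meta = self.catalog[accession]
        if not meta.fasta_path:
            raise RefDBError(f"no genome FASTA recorded for {accession}")
        return read_fasta(meta.fasta_path)

    def ani_index(self, accession: str, params):
        """Cached minimizer index of one reference genome."""
        from .ani import ReferenceIndex

        key = (accession, params.k, params.window, params.hash_seed)
        if key not in self._ani_index_cache:
            self._ani_index_cache[key] = ReferenceIndex(
                self.genome_records(accession), k=params.k,
                window=params.window, seed=params.hash_seed)
        return self._ani_index_cache[key]

    def species_lengths(self, species_key: int | str) -> list[int]:
        return [m.total_length for m in self.catalog.values()
                if m.species_key() == species_key and m.total_length > 0]


_FASTA_SUFFIXES = (".fna", ".fna.gz", ".fa", ".fa.gz", ".fasta", ".fasta.gz")


def _locate_genomes(genome_dir: str | Path, accessions: Sequence[str]) -> dict[str, Path]:
    genome_dir = Path(genome_dir)
    found: dict[str, Path] = {}
    missing: list[str] = []
    for acc in accessions:
        candidates = sorted(
            p for p in genome_dir.glob(f"{acc}*")
            if p.name.endswith(_FASTA_SUFFIXES)
        )
        if candidates:
            found[acc] = candidates[0]
        else:
            missing.append(acc)
    if missing:
        raise RefDBError(
            f"no genome FASTA found in {genome_dir} for accession(s): {', '.join(missing)}"
        )
    return found


def _write_sketch_file(path: Path, sketches: dict[str, Sketch], k: int, s: int,
                       hash_seed: int) -> str:
    """Write the consolidated sketch file; returns its sha256 hex digest."""
    doc = {
        "format_version": SCHEMA_VERSION,
        "k": k,
        "s": s,
        "hash_seed": hash_seed,
        "sketches": [
            {
                "source_id": acc,
                "genome_length": sk.genome_length,
                "hashes": [int(h) for h in sk.hashes],
            }
            for acc, sk in sorted(sketches.items())
        ],
    }
    payload = json.dumps(doc, sort_keys=True, separators=(",", ":")) + "\n"
    path.write_text(payload)
    return hashlib.sha256(payload.encode()).hexdigest()


def _build_db(catalog: Sequence[RefGenomeMeta], genome_dir: str | Path,
              thresholds: ThresholdTable, groups: IndistinguishableGroups,
              out_dir: str | Path, mode: str, k: int, s: int, hash_seed: int) -> RefDB:
    if not catalog:
        raise RefDBError("cannot build a reference database from an empty catalog")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = _locate_genomes(genome_dir, [m.accession for m in catalog])

    sketches: dict[str, Sketch] = {}
    cat: dict[str, RefGenomeMeta] = {}
    for meta in catalog:
        records = read_fasta(paths[meta.accession])
        sk = minhash_sketch(records, k=k, s=s, source_id=meta.accession, seed=hash_seed)
        sketches[meta.accession] = sk
        cat[meta.accession] = replace(
            meta, total_length=sk.genome_length, fasta_path=str(paths[meta.accession].resolve())
        )

    sketch_digest = _write_sketch_file(out_dir / "sketches.json", sketches, k, s, hash_seed)

    sqlite_path = out_dir / "refdb.sqlite"
    if sqlite_path.exists():
        sqlite_path.unlink()
    con = sqlite3.connect(sqlite_path)
    try:
        con.executescript(
            """
            CREATE TABLE meta (key TEXT PRIMARY KEY, value TEXT);
            CREATE TABLE genomes (
                accession TEXT PRIMARY KEY,
                organism_name TEXT,
                species_taxid INTEGER,
                relation_to_type_material TEXT,
                excluded_from_refseq TEXT,
                taxonomy_check_status TEXT,
                species_label TEXT,
                total_length INTEGER,
                fasta_path TEXT
            );
            CREATE TABLE thresholds (species_taxid INTEGER PRIMARY KEY, ani_threshold REAL);
            CREATE TABLE groups (species_taxid TEXT PRIMARY KEY, group_id TEXT);
            """
        )
        con.executemany(
            "INSERT INTO genomes VALUES (?,?,?,?,?,?,?,?,?)",
            [
                (m.accession, m.organism_name, m.species_taxid,
                 m.relation_to_type_material, m.excluded_from_refseq,
                 m.taxonomy_check_status, m.species_label, m.total_length, m.fasta_path)
                for m in sorted(cat.values(), key=lambda m: m.accession)
            ],
        )
        con.executemany("INSERT INTO thresholds VALUES (?,?)",
                        sorted(thresholds.thresholds.items()))
        con.executemany("INSERT INTO groups VALUES (?,?)",
                        sorted((str(t), g) for t, g in groups.membership.items()))
        con.executemany("INSERT INTO meta VALUES (?,?)", [
            ("schema_version", str(SCHEMA_VERSION)),
            ("mode", mode),
            ("k", str(k)),
            ("s", str(s)),
            ("hash_seed", str(hash_seed)),
            ("built_at", datetime.now(timezone.utc).isoformat()),
        ])
        con.commit()
    finally:
        con.close()

    manifest = {
        "format_version": SCHEMA_VERSION,
        "mode": mode,
        "k": k,
        "s": s,
        "hash_seed": hash_seed,
        "n_genomes": len(cat),
        "sketch_sha256": sketch_digest,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")

    return RefDB(catalog=cat, sketches=sketches, thresholds=thresholds, groups=groups,
                 mode=mode, k=k, s=s, hash_seed=hash_seed, db_dir=out_dir)


def build_reference_db(genome_dir: str | Path, catalog: Sequence[RefGenomeMeta],
                       thresholds: ThresholdTable, groups: IndistinguishableGroups,
                       out_dir: str | Path, *, k: int = DEFAULT_K,
                       s: int = DEFAULT_SKETCH_SIZE,
                       hash_seed: int = DEFAULT_HASH_SEED) -> RefDB:
    """Build and persist an NCBI-mode database from a (filtered) catalog."""
    return _build_db(catalog, genome_dir, thresholds, groups, out_dir,
                     mode="ncbi", k=k, s=s, hash_seed=hash_seed)


def _species_label_from_row(row: dict[str, str]) -> str:
    if row.get("species_label"):
        label = row["species_label"]
    elif row.get("gtdb_taxonomy"):
        parts = [p.strip() for p in row["gtdb_taxonomy"].split(";")]
        labels = [p for p in parts if p.startswith("s__")]
        label = labels[-1] if labels else ""
    else:
        label = ""
    return label


def build_gtdb_db(genome_dir: str | Path, metadata_tsv: str | Path,
                  out_dir: str | Path, *, k: int = DEFAULT_K,
                  s: int = DEFAULT_SKETCH_SIZE,
                  hash_seed: int = DEFAULT_HASH_SEED) -> RefDB:
    """Build a GTDB-mode database from representative genomes + metadata.

    The metadata TSV must map accession to a GTDB species label, either via
    a ``species`` column or a full ``gtdb_taxonomy`` string; labels are
    stored verbatim (``s__Genus species``).  No per-species thresholds: the
    flat 95% default applies.
    """
    rows, linenos = _read_tsv_table(metadata_tsv, ["accession"])
    catalog: list[RefGenomeMeta] = []
    for row, lineno in zip(rows, linenos):
        label = _species_label_from_row(row)
        if not label:
            raise TableFormatError(
                f"{metadata_tsv}, line {lineno}: no GTDB species label "
                f"(need a 'species' or 'gtdb_taxonomy' column value)"
            )
        catalog.append(RefGenomeMeta(
            accession=row["accession"],
            organism_name=label.removeprefix("s__"),
            species_taxid=0,
            species_label=label,
        ))
    return _build_db(catalog, genome_dir, ThresholdTable({}), IndistinguishableGroups({}),
                     out_dir, mode="gtdb", k=k, s=s, hash_seed=hash_seed)


def load_refdb(db_dir: str | Path, *, expect_k: int | None = None,
               expect_s: int | None = None,
               expect_hash_seed: int | None = None) -> RefDB:
    """Load a persisted database, verifying manifest/sketch consistency.

    ``expect_*`` let a caller assert the parameters its pipeline was
    configured with; a mismatch raises :class:`SketchMismatchError` with a
    pointer to rebuild rather than silently producing wrong distances.
    """
    db_dir = Path(db_dir)
    manifest_path = db_dir / "manifest.json"
    if not manifest_path.exists():
        raise RefDBError(f"{db_dir}: not a reference database (missing manifest.json)")
    manifest = json.loads(manifest_path.read_text())
    if manifest.get("format_version") != SCHEMA_VERSION:
        raise RefDBError(
            f"{db_dir}: unsupported database format version {manifest.get('format_version')}"
        )
    k, s, hash_seed = manifest["k"], manifest["s"], manifest["hash_seed"]
    for name, got, want in (("k", k, expect_k), ("s", s, expect_s),
                            ("hash seed", hash_seed, expect_hash_seed)):
        if want is not None and got != want:
            raise SketchMismatchError(
                f"{db_dir}: database built with {name}={got} but pipeline requests "
                f"{name}={want}; rebuild the database or adjust the configuration"
            )

    sketch_doc = json.loads((db_dir / "sketches.json").read_text())
    if (sketch_doc["k"], sketch_doc["s"], sketch_doc["hash_seed"]) != (k, s, hash_seed):
        raise SketchMismatchError(f"{db_dir}: sketch file header disagrees with manifest")
    sketches: dict[str, Sketch] = {}
    for entry in sketch_doc["sketches"]:
        hashes = np.array(entry["hashes"], dtype=np.uint64)
        sketches[entry["source_id"]] = Sketch(
            k=k, s=s, hash_seed=hash_seed, hashes=hashes,
            source_id=entry["source_id"], genome_length=entry["genome_length"])

    con = sqlite3.connect(db_dir / "refdb.sqlite")
    try:
        mode = dict(con.execute("SELECT key, value FROM meta"))["mode"]
        catalog: dict[str, RefGenomeMeta] = {}
        for row in con.execute(
            "SELECT accession, organism_name, species_taxid, relation_to_type_material, "
            "excluded_from_refseq, taxonomy_check_status, species_label, total_length, "
            "fasta_path FROM genomes"
        ):
            meta = RefGenomeMeta(*row)
            catalog[meta.accession] = meta
        thresholds = ThresholdTable(
            {int(t): float(v) for t, v in con.execute("SELECT species_taxid, ani_threshold FROM thresholds")}
        )
        membership: dict[int | str, str] = {}
        for t, g in con.execute("SELECT species_taxid, group_id FROM groups"):
            key: int | str = int(t) if str(t).lstrip("-").isdigit() else str(t)
            membership[key] = g
        groups = IndistinguishableGroups(membership)
    finally:
        con.close()

    if set(catalog) != set(sketches):
        raise RefDBError(
            f"{db_dir}: catalog/sketch mismatch "
            f"(catalog-only: {sorted(set(catalog) - set(sketches))}, "
            f"sketch-only: {sorted(set(sketches) - set(catalog))})"
        )
    return RefDB(catalog=catalog, sketches=sketches, thresholds=thresholds,
                 groups=groups, mode=mode, k=k, s=s, hash_seed=hash_seed, db_dir=db_dir)
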