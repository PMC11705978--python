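"""Shared fixtures: a small synthetic universe with a built reference DB.

All fixture data is generated at test time; nothing is downloaded or
stored in the repository.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pytest

from taxani.fixtures import SimSpec, build_fixture_universe
from taxani.refdb import (
    RefDB,
    build_reference_db,
    parse_ani_report,
    parse_assembly_summary,
    parse_groups,
    parse_threshold_table,
    select_type_genomes,
)

#: Small, fast study conditions for unit tests (acceptance tests build
#: their own universes at full size).
TINY_SPEC = SimSpec(n_species=5, genome_length=50_000, seed=7)
TINY_SKETCH_SIZE = 1000


@dataclass
class Universe:
    dir: Path
    manifest: dict
    db: RefDB


def build_db_from_universe(universe_dir: Path, out_dir: Path, *, k: int = 21,
                           s: int = 1000, hash_seed: int | None = None) -> RefDB:
    """Parse a fixture universe's metadata files and build a database."""
    from taxani.sketch import DEFAULT_HASH_SEED

    catalog = parse_assembly_summary(universe_dir / "assembly_summary.tsv")
    report = parse_ani_report(universe_dir / "ani_report.tsv")
    catalog = select_type_genomes(catalog, report)
    thresholds = parse_threshold_table(universe_dir / "thresholds.tsv")
    groups = parse_groups(universe_dir / "groups.tsv")
    return build_reference_db(
        universe_dir / "genomes", catalog, thresholds, groups, out_dir,
        k=k, s=s, hash_seed=DEFAULT_HASH_SEED if hash_seed is None else hash_seed)


@pytest.fixture(scope="session")
def tiny_universe(tmp_path_factory) -> Universe:
    """5 species x 50 kb, one 96% species threshold, one 2-species group."""
    root = tmp_path_factory.mktemp("tiny_universe")
    manifest = build_fixture_universe(
        TINY_SPEC, root,
        thresholds={100_001: 96.0},
        group_pairs=[(100_003, 100_004, "grpA")],
    )
    db = build_db_from_universe(root, root / "db", s=TINY_SKETCH_SIZE)
    return Universe(dir=root, manifest=manifest, db=db)
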