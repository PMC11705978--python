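"""Metadata parsing, type-genome filtering, database build/load."""

from __future__ import annotations

import hashlib
import json

import pytest
from hypothesis import given, settings, strategies as st

from taxani.errors import RefDBError, SketchMismatchError, TableFormatError
from taxani.fixtures import simulate_genome
from taxani.io_formats import write_fasta, SeqRecord
from taxani.refdb import (
    IndistinguishableGroups,
    RefGenomeMeta,
    ThresholdTable,
    build_gtdb_db,
    build_reference_db,
    load_refdb,
    parse_ani_report,
    parse_assembly_summary,
    parse_groups,
    parse_threshold_table,
    select_type_genomes,
)

SUMMARY = """\
#   Synthetic assembly summary for tests
# assembly_accession\torganism_name\tspecies_taxid\trelation_to_type_material\texcluded_from_refseq
GCA_000001.1\tEscherichia coli\t562\tassembly from type material\tna
GCA_000002.1\tBacillus subtilis\t1423\tna\tna
GCA_000003.1\tVibrio cholerae\t666\tassembly from type material\tderived from metagenome
"""


def test_parse_assembly_summary_fidelity(tmp_path):
    p = tmp_path / "summary.tsv"
    p.write_text(SUMMARY)
    catalog = parse_assembly_summary(p)
    assert len(catalog) == 3
    typed = [m for m in catalog if m.relation_to_type_material]
    assert [m.accession for m in typed] == ["GCA_000001.1", "GCA_000003.1"]
    assert catalog[0].species_taxid == 562
    assert catalog[1].relation_to_type_material == ""  # 'na' mapped to empty
    assert catalog[2].excluded_from_refseq == "derived from metagenome"


def test_parse_assembly_summary_column_alias(tmp_path):
    p = tmp_path / "summary.tsv"
    p.write_text(
        "# assembly_accession\torganism_name\tspecies_taxid\trelation-to-type-material\n"
        "GCA_1.1\tFoo bar\t5\tassembly from type material\n"
    )
    assert parse_assembly_summary(p)[0].relation_to_type_material != ""


@pytest.mark.parametrize(
    "content,match",
    [
        ("GCA_1.1\tFoo\t5\ttype\n", "no header"),
        ("# assembly_accession\torganism_name\n", "missing required"),
        ("# assembly_accession\torganism_name\tspecies_taxid\trelation_to_type_material\n"
         "GCA_1.1\tFoo\tnotanumber\tna\n", "line 2.*not an integer"),
        ("# assembly_accession\torganism_name\tspecies_taxid\trelation_to_type_material\n"
         "GCA_1.1\tFoo\t5\tna\nGCA_1.1\tFoo\t5\tna\n", "duplicate accession"),
    ],
)
def test_parse_assembly_summary_errors(tmp_path, content, match):
    p = tmp_path / "bad.tsv"
    p.write_text(content)
    with pytest.raises(TableFormatError, match=match):
        parse_assembly_summary(p)


def test_parse_ani_report_statuses(tmp_path):
    p = tmp_path / "ani.tsv"
    p.write_text(
        "# genbank_accession\ttaxonomy_check_status\n"
        "GCA_1.1\tOK\nGCA_2.1\tFailed\nGCA_3.1\tna\n"
    )
    report = parse_ani_report(p)
    assert report == {"GCA_1.1": "OK", "GCA_2.1": "Failed", "GCA_3.1": ""}
    assert report.get("GCA_absent.1", "") == ""


def test_parse_ani_report_duplicate_last_wins(tmp_path, caplog):
    p = tmp_path / "ani.tsv"
    p.write_text("# genbank_accession\ttaxonomy_check_status\nGCA_1.1\tOK\nGCA_1.1\tFailed\n")
    with caplog.at_level("WARNING"):
        report = parse_ani_report(p)
    assert report["GCA_1.1"] == "Failed"
    assert any("duplicate" in r.message for r in caplog.records)


def test_parse_ani_report_empty_and_unknown_status(tmp_path):
    p = tmp_path / "ani.tsv"
    p.write_text("# genbank_accession\ttaxonomy_check_status\n")
    assert parse_ani_report(p) == {}
    p.write_text("# genbank_accession\ttaxonomy_check_status\nGCA_1.1\tMaybe\n")
    with pytest.raises(TableFormatError, match="unknown taxonomy check status"):
        parse_ani_report(p)


# --------------------------------------------------------------------------
# Type-genome selection
# --------------------------------------------------------------------------

def _meta(acc, type_rel="assembly from type material", excluded=""):
    return RefGenomeMeta(accession=acc, organism_name="Org", species_taxid=1,
                         relation_to_type_material=type_rel,
                         excluded_from_refseq=excluded)


def five_row_catalog():
    """type+OK, type+Failed, non-type+OK, type+excluded, type+empty-status."""
    catalog = [
        _meta("A1"),
        _meta("A2"),
        _meta("A3", type_rel=""),
        _meta("A4", excluded="derived from metagenome"),
        _meta("A5"),
    ]
    report = {"A1": "OK", "A2": "Failed", "A3": "OK"}
    return catalog, report


def test_filter_rule_retains_exactly_rows_1_and_5():
    catalog, report = five_row_catalog()
    kept = select_type_genomes(catalog, report)
    assert [m.accession for m in kept] == ["A1", "A5"]


def test_filter_edge_cases():
    assert select_type_genomes([], {}) == []
    catalog = [_meta(f"B{i}") for i in range(4)]
    report = {m.accession: "OK" for m in catalog}
    assert len(select_type_genomes(catalog, report)) == 4
    # Inconclusive is retained (only a confirmed mislabel is excluded)
    kept = select_type_genomes([_meta("C1")], {"C1": "Inconclusive"})
    assert [m.accession for m in kept] == ["C1"]


@given(st.lists(st.tuples(st.booleans(), st.booleans(),
                          st.sampled_from(["OK", "Inconclusive", "Failed", ""])),
                max_size=20))
@settings(derandomize=True, max_examples=60, deadline=None)
def test_filter_is_a_pure_predicate(rows):
    """select(X + Y) == select(X) + select(Y): filtering is row-local."""
    catalog = [
        _meta(f"G{i}", type_rel="type" if is_type else "",
              excluded="excluded" if excl else "")
        for i, (is_type, excl, _) in enumerate(rows)
    ]
    report = {f"G{i}": status for i, (_, _, status) in enumerate(rows)}
    mid = len(catalog) // 2
    whole = [m.accession for m in select_type_genomes(catalog, report)]
    parts = [m.accession for m in select_type_genomes(catalog[:mid], report)]
    parts += [m.accession for m in select_type_genomes(catalog[mid:], report)]
    assert whole == parts


# --------------------------------------------------------------------------
# Thresholds & groups
# --------------------------------------------------------------------------

def test_threshold_table_lookup_and_default(tmp_path):
    p = tmp_path / "thr.tsv"
    p.write_text("species_taxid\tani_threshold\n562\t96.0\n")
    table = parse_threshold_table(p)
    assert table.get(562) == 96.0
    assert table.get(999) == 95.0  # default


@pytest.mark.parametrize(
    "rows,match",
    [
        ("562\t96.0\n562\t97.0\n", "duplicate taxid"),
        ("562\tveryhigh\n", "non-numeric"),
        ("562\t74.0\n", "outside"),
        ("562\t100.5\n", "outside"),
    ],
)
def test_threshold_table_errors(tmp_path, rows, match):
    p = tmp_path / "thr.tsv"
    p.write_text("species_taxid\tani_threshold\n" + rows)
    with pytest.raises(TableFormatError, match=match):
        parse_threshold_table(p)


def test_groups_parse_and_singleton_error(tmp_path):
    p = tmp_path / "groups.tsv"
    p.write_text("species_taxid\tgroup_id\n562\tgrpA\n620\tgrpA\n")
    groups = parse_groups(p)
    assert groups.group_of(562) == "grpA" == groups.group_of(620)
    assert groups.group_of(999) is None
    p.write_text("species_taxid\tgroup_id\n562\tgrpA\n")
    with pytest.raises(TableFormatError, match="singleton"):
        parse_groups(p)


def test_species_in_two_groups_rejected(tmp_path):
    p = tmp_path / "groups.tsv"
    p.write_text("species_taxid\tgroup_id\n562\tgrpA\n562\tgrpB\n620\tgrpA\n")
    with pytest.raises(TableFormatError, match="more than one group"):
        parse_groups(p)


# --------------------------------------------------------------------------
# Build / load
# --------------------------------------------------------------------------

def _write_genomes(tmp_path, n=5, length=5000):
    gdir = tmp_path / "genomes"
    gdir.mkdir()
    catalog = []
    for i in range(n):
        acc = f"GCA_{i:06d}.1"
        write_fasta([simulate_genome(length, 0.5, seed=i, contig_id=f"{acc}_c1")],
                    gdir / f"{acc}_genomic.fna")
        catalog.append(RefGenomeMeta(accession=acc, organism_name=f"Org {i}",
                                     species_taxid=100 + i,
                                     relation_to_type_material="type"))
    return gdir, catalog


def test_build_and_load_roundtrip(tmp_path):
    gdir, catalog = _write_genomes(tmp_path)
    thr = ThresholdTable({101: 96.5})
    grp = IndistinguishableGroups({102: "g1", 103: "g1"})
    db = build_reference_db(gdir, catalog, thr, grp, tmp_path / "db", k=21, s=200)
    loaded = load_refdb(tmp_path / "db")
    assert loaded.mode == "ncbi"
    assert (loaded.k, loaded.s) == (21, 200)
    assert set(loaded.catalog) == set(loaded.sketches) == {m.accession for m in catalog}
    assert loaded.thresholds == thr
    assert loaded.groups == grp
    assert loaded.sketches["GCA_000000.1"] == db.sketches["GCA_000000.1"]
    assert loaded.catalog["GCA_000000.1"].total_length == 5000


def test_rebuild_is_byte_identical(tmp_path):
    gdir, catalog = _write_genomes(tmp_path, n=3)
    thr, grp = ThresholdTable({}), IndistinguishableGroups({})
    build_reference_db(gdir, catalog, thr, grp, tmp_path / "db1", s=100)
    build_reference_db(gdir, catalog, thr, grp, tmp_path / "db2", s=100)
    d1 = hashlib.sha256((tmp_path / "db1" / "sketches.json").read_bytes()).hexdigest()
    d2 = hashlib.sha256((tmp_path / "db2" / "sketches.json").read_bytes()).hexdigest()
    assert d1 == d2
    m1 = (tmp_path / "db1" / "manifest.json").read_bytes()
    m2 = (tmp_path / "db2" / "manifest.json").read_bytes()
    assert m1 == m2


def test_missing_genome_fasta_named_in_error(tmp_path):
    gdir, catalog = _write_genomes(tmp_path, n=2)
    catalog.append(RefGenomeMeta(accession="GCA_999999.1", organism_name="Ghost",
                                 species_taxid=999, relation_to_type_material="type"))
    with pytest.raises(RefDBError, match="GCA_999999.1"):
        build_reference_db(gdir, catalog, ThresholdTable({}), IndistinguishableGroups({}),
                           tmp_path / "db", s=100)


def test_load_with_mismatched_params_fails_loudly(tmp_path):
    gdir, catalog = _write_genomes(tmp_path, n=2)
    build_reference_db(gdir, catalog, ThresholdTable({}), IndistinguishableGroups({}),
                       tmp_path / "db", k=21, s=100)
    with pytest.raises(SketchMismatchError, match="rebuild"):
        load_refdb(tmp_path / "db", expect_k=17)
    with pytest.raises(SketchMismatchError, match="rebuild"):
        load_refdb(tmp_path / "db", expect_s=500)


def test_load_rejects_non_database_dir(tmp_path):
    with pytest.raises(RefDBError, match="manifest"):
        load_refdb(tmp_path)


def test_gtdb_build(tmp_path):
    gdir, _ = _write_genomes(tmp_path, n=3)
    meta = tmp_path / "gtdb_metadata.tsv"
    meta.write_text(
        "accession\tgtdb_taxonomy\n"
        "GCA_000000.1\td__Bacteria;p__Pseudomonadota;s__Foo bar\n"
        "GCA_000001.1\td__Bacteria;s__Baz qux\n"
        "GCA_000002.1\td__Bacteria;s__Quux corge\n"
    )
    db = build_gtdb_db(gdir, meta, tmp_path / "gdb", s=100)
    assert db.mode == "gtdb"
    assert db.catalog["GCA_000000.1"].species_label == "s__Foo bar"  # stored verbatim
    assert len(db.thresholds) == 0
    assert db.threshold_for("s__Foo bar") == 95.0  # flat default for any species
    assert db.threshold_for(12345) == 95.0
    loaded = load_refdb(tmp_path / "gdb")
    assert loaded.mode == "gtdb"
    assert loaded.catalog["GCA_000001.1"].species_label == "s__Baz qux"
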