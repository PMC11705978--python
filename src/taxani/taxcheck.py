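"""The two-step taxonomy check, outcome classification and size check.

Classification of the accepted hits (ANI >= threshold, with the aligned
fraction already gated when ANI was computed):

* no accepted hits                      -> ``no_hit``
* one accepted species                  -> ``conclusive`` (that species)
* several species, all one indistinguishable group
                                        -> ``indistinguishable`` (the group;
                                           the top-ANI species is surfaced)
* several species, not one group        -> ``inconclusive`` (the top-ANI
                                           species is surfaced as a
                                           candidate, not an assignment)

The comparator is >= : a species-specific threshold exactly attained is
accepted.  A single accepted species is conclusive even if that species
belongs to an indistinguishable group — the group status only describes
ambiguity actually observed among accepted hits.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Sequence

from .ani import AniParams, compute_ani, profile_fragments
from .io_formats import GenomeStats, SeqRecord
from .refdb import IndistinguishableGroups, RefDB
from .sketch import minhash_sketch, prescreen

__all__ = [
    "Status",
    "SizeVerdict",
    "TaxHit",
    "TaxonomyResult",
    "SizeCheckResult",
    "classify_hits",
    "run_taxonomy_check",
    "genome_size_check",
    "run_full_check",
    "exit_code_for",
]


class Status(str, enum.Enum):
    CONCLUSIVE = "conclusive"
    INCONCLUSIVE = "inconclusive"
    INDISTINGUISHABLE = "indistinguishable"
    NO_HIT = "no_hit"

    def __str__(self) -> str:  # pragma: no cover - trivial
        return self.value


class SizeVerdict(str, enum.Enum):
    PASS = "pass"
    WARN = "warn"
    UNKNOWN = "unknown"

    def __str__(self) -> str:  # pragma: no cover - trivial
        return self.value


@dataclass(frozen=True)
class TaxHit:
    """One reference comparison carried into the report.

    ``species_taxid`` holds the NCBI species taxid, or the GTDB species
    label in GTDB mode.
    """

    ref_accession: str
    organism_name: str
    species_taxid: int | str
    ani: float
    aligned_fraction: float
    threshold: float
    accepted: bool


@dataclass(frozen=True)
class TaxonomyResult:
    query_id: str
    status: Status
    hits: tuple[TaxHit, ...]
    assigned_species: str = ""
    group_id: str = ""


@dataclass(frozen=True)
class SizeCheckResult:
    total_length: int
    expected_min: int | None
    expected_max: int | None
    verdict: SizeVerdict


def classify_hits(hits: Sequence[TaxHit],
                  groups: IndistinguishableGroups | None = None
                  ) -> tuple[Status, str, str]:
    """Classify a resolved hit list into (status, assigned species, group).

    Total on any hit list: exactly one status applies.  Acceptance is
    recomputed here from ``ani >= threshold`` so the function can be used
    on hit lists built elsewhere.
    """
    groups = groups or IndistinguishableGroups({})
    accepted = [h for h in hits if h.ani is not None and h.ani >= h.threshold]
    if not accepted:
        return Status.NO_HIT, "", ""
    top = max(accepted, key=lambda h: (h.ani, h.ref_accession))
    species = {h.species_taxid for h in accepted}
    if len(species) == 1:
        return Status.CONCLUSIVE, top.organism_name, ""
    gids = {groups.group_of(sp) for sp in species}
    if None not in gids and len(gids) == 1:
        return Status.INDISTINGUISHABLE, top.organism_name, gids.pop()
    return Status.INCONCLUSIVE, top.organism_name, ""


def run_taxonomy_check(records: Sequence[SeqRecord], refdb: RefDB, *,
                       max_dist: float = 0.1, top_n: int | None = 20,
                       ani_params: AniParams | None = None,
                       use_prescreen: bool = True,
                       query_id: str = "query") -> TaxonomyResult:
    """Run the two-step check: prescreen, per-candidate ANI, classification.

    With ``use_prescreen=False`` every reference genome is carried into the
    ANI step (slow but exhaustive).  An empty prescreen yields a ``no_hit``
    result, not an error.  Deterministic for identical inputs.
    """
    ani_params = ani_params or AniParams(k=refdb.k, hash_seed=refdb.hash_seed)
    if use_prescreen:
        query_sketch = minhash_sketch(records, k=refdb.k, s=refdb.s,
                                      source_id=query_id, seed=refdb.hash_seed)
        candidates = [h.ref_accession for h in prescreen(query_sketch, refdb,
                                                         max_dist=max_dist, top_n=top_n)]
    else:
        candidates = sorted(refdb.catalog)

    profiles = profile_fragments(records, ani_params) if candidates else []
    hits: list[TaxHit] = []
    for acc in candidates:
        meta = refdb.catalog[acc]
        index = refdb.ani_index(acc, ani_params)
        result = compute_ani(records, params=ani_params, index=index,
                             profiles=profiles, ref_accession=acc)
        if result.ani is None:
            continue  # aligned fraction below the reporting gate: no hit
        threshold = refdb.threshold_for(meta.species_key())
        hits.append(TaxHit(
            ref_accession=acc,
            organism_name=meta.organism_name,
            species_taxid=meta.species_key(),
            ani=result.ani,
            aligned_fraction=result.aligned_fraction,
            threshold=threshold,
            accepted=result.ani >= threshold,
        ))
    hits.sort(key=lambda h: (-h.ani, h.ref_accession))
    status, assigned, group_id = classify_hits(hits, refdb.groups)
    return TaxonomyResult(query_id=query_id, status=status, hits=tuple(hits),
                          assigned_species=assigned, group_id=group_id)


def genome_size_check(stats: GenomeStats, refdb: RefDB,
                      species_key: int | str | None,
                      *, lower_factor: float = 0.7,
                      upper_factor: float = 1.3) -> SizeCheckResult:
    """Check the assembly length against the species' reference lengths.

    Expected range is [lower_factor * min, upper_factor * max] over the
    catalog's assembly lengths for the species; with a single reference of
    length L the range is [0.7L, 1.3L].  Unknown species or no references
    -> verdict ``unknown``.
    """
    if species_key is None or species_key == "":
        return SizeCheckResult(stats.total_length, None, None, SizeVerdict.UNKNOWN)
    lengths = refdb.species_lengths(species_key)
    if not lengths:
        return SizeCheckResult(stats.total_length, None, None, SizeVerdict.UNKNOWN)
    lo = int(round(lower_factor * min(lengths)))
    hi = int(round(upper_factor * max(lengths)))
    verdict = SizeVerdict.PASS if lo <= stats.total_length <= hi else SizeVerdict.WARN
    return SizeCheckResult(stats.total_length, lo, hi, verdict)


def _top_accepted_species_key(result: TaxonomyResult) -> int | str | None:
    for h in result.hits:  # hits are ANI-descending
        if h.accepted:
            return h.species_taxid
    return None


def run_full_check(records: Sequence[SeqRecord], refdb: RefDB, *,
                   max_dist: float = 0.1, top_n: int | None = 20,
                   ani_params: AniParams | None = None,
                   use_prescreen: bool = True, query_id: str = "query"
                   ) -> tuple[TaxonomyResult, GenomeStats, SizeCheckResult]:
    """Taxonomy check plus assembly statistics and the genome-size check."""
    from .io_formats import genome_stats

    result = run_taxonomy_check(records, refdb, max_dist=max_dist, top_n=top_n,
                                ani_params=ani_params, use_prescreen=use_prescreen,
                                query_id=query_id)
    stats = genome_stats(records)
    size = genome_size_check(stats, refdb, _top_accepted_species_key(result))
    return result, stats, size


def exit_code_for(status: Status) -> int:
    """Pipeline-friendly exit codes: 0 assigned, 1 ambiguous, 2 no hit."""
    if status in (Status.CONCLUSIVE, Status.INDISTINGUISHABLE):
        return 0
    if status is Status.INCONCLUSIVE:
        return 1
    return 2
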