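"""Step-2 ANI estimation by fragment mapping with a minimizer index.

The query assembly is cut into non-overlapping fragments (default 3 kb).
The reference genome is indexed by open-syncmer-free window minimizers:
within every window of ``window`` consecutive canonical k-mer hashes the
minimum hash (leftmost on ties) is recorded with its position.  A fragment
is *mapped* when enough of its own minimizers co-locate on one diagonal of
the (reference, fragment) coordinate plane — a cheap stand-in for a
collinear alignment.

Per-fragment identity is derived from k-mer containment: a k-mer spanning
no mutated site is present in the reference, so under a per-base
substitution rate p the expected containment is (1-p)^k and identity is
estimated as c^(1/k).  Containment is measured over the fragment's full
distinct k-mer set against the reference's full k-mer set (minimizers
decide *where and whether* a fragment maps; containment decides *how
similar* it is).  Counting only shared minimizers would bias identity
downward, because a k-mer that survives mutation intact need not have been
selected as a minimizer on both sides once its neighbourhood differs.

Genome-level ANI is the mean identity over mapped fragments, reported only
when the aligned fraction (mapped/total fragments) reaches
``min_aligned_fraction`` — a guard against a single conserved region
producing a spurious, high ANI between unrelated genomes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .errors import ParameterError
from .io_formats import SeqRecord
from .sketch import DEFAULT_HASH_SEED, DEFAULT_K, SENTINEL, kmer_hash_array

__all__ = [
    "AniParams",
    "AniResult",
    "Fragment",
    "ReferenceIndex",
    "fragment_query",
    "index_reference",
    "map_fragment",
    "compute_ani",
]


@dataclass(frozen=True)
class AniParams:
    """Tunable knobs of the fragment-containment ANI estimator.

    fragment_len
        Query fragment length in bp.  3000 bp balances mapping specificity
        against resolution on draft assemblies with short contigs.
    window
        Minimizer window in k-mers; expected minimizer density is
        2/(window+1).
    min_shared / min_containment
        A fragment maps only if its best diagonal bin holds at least
        ``min_shared`` shared minimizers covering at least
        ``min_containment`` of the fragment's minimizers.
    min_aligned_fraction
        Minimum fraction of fragments that must map for the genome-level
        ANI to be reported at all.
    """

    k: int = DEFAULT_K
    fragment_len: int = 3000
    window: int = 50
    min_shared: int = 5
    min_containment: float = 0.05
    min_aligned_fraction: float = 0.15
    hash_seed: int = DEFAULT_HASH_SEED

    def __post_init__(self) -> None:
        if self.fragment_len < 10 * self.k:
            raise ParameterError(
                f"fragment_len ({self.fragment_len}) must be >= 10*k ({10 * self.k})"
            )
        if not (0.0 < self.min_containment < 1.0):
            raise ParameterError("min_containment must be in (0, 1)")
        if self.window < 1:
            raise ParameterError("window must be >= 1")


@dataclass(frozen=True)
class AniResult:
    """ANI between one query assembly and one reference genome.

    ``ani`` is a percent in [0, 100], or ``None`` when the aligned fraction
    fell below the reporting gate (the pair then yields no taxonomy hit).
    """

    ani: float | None
    aligned_fraction: float
    fragments_mapped: int
    fragments_total: int
    ref_accession: str = ""


@dataclass(frozen=True)
class Fragment:
    """One query fragment; coordinates are 0-based half-open on the contig."""

    contig_id: str
    start: int
    end: int
    sequence: str


def fragment_query(records: Sequence[SeqRecord], fragment_len: int) -> list[Fragment]:
    """Cut contigs into consecutive non-overlapping fragments.

    The terminal remainder of each contig is kept as a short fragment when
    it is at least half of ``fragment_len`` and dropped otherwise; a contig
    shorter than ``fragment_len`` is its own (possibly dropped) remainder.
    """
    if fragment_len < 1:
        raise ParameterError("fragment_len must be >= 1")
    out: list[Fragment] = []
    for rec in records:
        n = len(rec.sequence)
        nfull = n // fragment_len
        for i in range(nfull):
            start = i * fragment_len
            out.append(Fragment(rec.id, start, start + fragment_len,
                                rec.sequence[start : start + fragment_len]))
        rem = n - nfull * fragment_len
        if rem >= fragment_len / 2:
            start = nfull * fragment_len
            out.append(Fragment(rec.id, start, n, rec.sequence[start:]))
    return out


def _minimizer_positions(hashes: np.ndarray, window: int) -> np.ndarray:
    """Positions selected as window minimizers (leftmost minimum on ties).

    Invalid (sentinel) positions are never selected; a sequence with fewer
    k-mers than ``window`` is treated as a single window.
    """
    m = hashes.size
    if m == 0:
        return np.empty(0, dtype=np.intp)
    w = min(window, m)
    if w == 1:
        pos = np.arange(m)
    else:
        view = sliding_window_view(hashes, w)
        pos = np.unique(view.argmin(axis=1) + np.arange(view.shape[0]))
    return pos[hashes[pos] != SENTINEL]


class ReferenceIndex:
    """Minimizer index plus full k-mer set of one reference genome."""

    def __init__(self, records: Sequence[SeqRecord], k: int = DEFAULT_K,
                 window: int = 50, seed: int = DEFAULT_HASH_SEED) -> None:
        self.k = k
        self.window = window
        self.hash_seed = seed
        self.contig_ids = [r.id for r in records]
        minimizers: dict[int, list[tuple[int, int]]] = {}
        all_hashes: list[np.ndarray] = []
        n_minimizers = 0
        n_kmers = 0
        for ci, rec in enumerate(records):
            h = kmer_hash_array(rec.sequence, k, seed)
            valid = h[h != SENTINEL]
            n_kmers += valid.size
            all_hashes.append(valid)
            for p in _minimizer_positions(h, window):
                minimizers.setdefault(int(h[p]), []).append((ci, int(p)))
                n_minimizers += 1
        if n_kmers == 0:
            raise ParameterError("reference genome has no valid k-mers to index")
        self.minimizers = minimizers
        self.n_minimizers = n_minimizers
        self.kmer_set = np.unique(np.concatenate(all_hashes))

    def contains(self, hashes: np.ndarray) -> np.ndarray:
        """Membership of each hash in the reference's full k-mer set."""
        idx = np.searchsorted(self.kmer_set, hashes)
        idx = np.clip(idx, 0, self.kmer_set.size - 1)
        return self.kmer_set[idx] == hashes


def index_reference(records: Sequence[SeqRecord], k: int = DEFAULT_K,
                    window: int = 50, seed: int = DEFAULT_HASH_SEED) -> ReferenceIndex:
    """Build the minimizer index for a reference genome."""
    return ReferenceIndex(records, k=k, window=window, seed=seed)


@dataclass(frozen=True)
class _FragmentProfile:
    """Precomputed hash views of one fragment (reusable across references)."""

    fragment: Fragment
    minimizers: list[tuple[int, int]]  # (fragment k-mer position, hash)
    kmers: np.ndarray                  # distinct valid k-mer hashes


def _profile_fragment(frag: Fragment, params: AniParams) -> _FragmentProfile:
    h = kmer_hash_array(frag.sequence, params.k, params.hash_seed)
    pos = _minimizer_positions(h, params.window)
    mins = [(int(p), int(h[p])) for p in pos]
    valid = h[h != SENTINEL]
    return _FragmentProfile(fragment=frag, minimizers=mins, kmers=np.unique(valid))


def profile_fragments(records: Sequence[SeqRecord], params: AniParams) -> list[_FragmentProfile]:
    """Fragment the query and precompute per-fragment hash profiles."""
    return [_profile_fragment(f, params) for f in fragment_query(records, params.fragment_len)]


def _map_profile(prof: _FragmentProfile, index: ReferenceIndex,
                 params: AniParams) -> tuple[bool, float | None]:
    n = len(prof.minimizers)
    if n == 0 or prof.kmers.size == 0:
        return False, None
    # bin shared minimizers by diagonal offset; best bin wins, ties resolved
    # toward the smaller reference coordinate (smaller bin key)
    bins: dict[tuple[int, int], set[int]] = {}
    for fpos, h in prof.minimizers:
        for ci, rpos in index.minimizers.get(h, ()):
            key = (ci, (rpos - fpos) // params.fragment_len)
            bins.setdefault(key, set()).add(fpos)
    if not bins:
        return False, None
    best_key = min(bins, key=lambda kk: (-len(bins[kk]), kk))
    m = len(bins[best_key])
    if m < params.min_shared or m / n < params.min_containment:
        return False, None
    containment = float(index.contains(prof.kmers).mean())
    if containment <= 0.0:
        return False, None
    identity = min(containment ** (1.0 / params.k), 1.0)
    return True, identity


def map_fragment(fragment: Fragment, index: ReferenceIndex,
                 params: AniParams) -> tuple[bool, float | None]:
    """Map one fragment; returns (mapped, identity or None).

    A fragment shorter than k is unmapped with undefined identity.
    """
    if len(fragment.sequence) < params.k:
        return False, None
    return _map_profile(_profile_fragment(fragment, params), index, params)


def compute_ani(query: Sequence[SeqRecord], reference: Sequence[SeqRecord] | None = None,
                params: AniParams | None = None, *, index: ReferenceIndex | None = None,
                profiles: list[_FragmentProfile] | None = None,
                ref_accession: str = "") -> AniResult:
    """ANI between a query assembly and one reference genome.

    Either ``reference`` records or a prebuilt ``index`` must be given;
    passing a cached index (and/or precomputed query ``profiles``) avoids
    recomputation when one query is compared against many references.
    """
    params = params or AniParams()
    if index is None:
        if reference is None:
            raise ParameterError("compute_ani needs reference records or a prebuilt index")
        index = ReferenceIndex(reference, k=params.k, window=params.window,
                               seed=params.hash_seed)
    if index.k != params.k or index.window != params.window or index.hash_seed != params.hash_seed:
        raise ParameterError("reference index was built with different k/window/seed")
    if profiles is None:
        profiles = profile_fragments(query, params)
    if not profiles:
        return AniResult(ani=None, aligned_fraction=0.0, fragments_mapped=0,
                         fragments_total=0, ref_accession=ref_accession)
    identities: list[float] = []
    for prof in profiles:
        if len(prof.fragment.sequence) < params.k:
            continue
        mapped, ident = _map_profile(prof, index, params)
        if mapped:
            identities.append(ident)
    total = len(profiles)
    mapped_n = len(identities)
    af = mapped_n / total
    if af >= params.min_aligned_fraction and identities:
        # sorted fsum makes the value independent of fragment/contig order
        ani = 100.0 * math.fsum(sorted(identities)) / mapped_n
    else:
        ani = None
    return AniResult(ani=ani, aligned_fraction=af, fragments_mapped=mapped_n,
                     fragments_total=total, ref_accession=ref_accession)
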