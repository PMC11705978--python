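"""Canonical k-mer hashing, bottom-s MinHash sketches, Mash distance, and
the step-1 genome-distance prescreen.

Hashing
-------
Each window of k consecutive A/C/G/T bases is 2-bit packed (A=0, C=1, G=2,
T=3, most significant bits first, so integer order equals lexicographic
order) together with its reverse complement; the smaller of the two packed
values — the *canonical* k-mer — is passed through a fixed 64-bit mixing
function (the splitmix64/murmur3 finalizer) XORed with a documented seed.
The hash is therefore a pure function of the k-mer string and the seed:
identical across runs, platforms and processes.  Windows containing any
non-ACGT symbol contribute nothing.

Sketches
--------
A bottom-s sketch keeps the s smallest distinct hash values of a genome's
canonical k-mer set.  Jaccard similarity between two genomes is estimated
from the merged sketch (the s smallest values of the union), and converted
to the Mash distance D = -(1/k) * ln(2j / (1+j)), an estimate of per-base
divergence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import ParameterError, SketchMismatchError
from .io_formats import SeqRecord

__all__ = [
    "DEFAULT_K",
    "DEFAULT_SKETCH_SIZE",
    "DEFAULT_HASH_SEED",
    "Sketch",
    "ScreenHit",
    "canonical_kmers",
    "minhash_sketch",
    "sketch_jaccard",
    "mash_distance",
    "prescreen",
]

DEFAULT_K = 21
DEFAULT_SKETCH_SIZE = 10000
#: Fixed seed XORed into the packed canonical k-mer before mixing.  Part of
#: the on-disk sketch format: sketches built with different seeds are
#: incomparable and the database loader refuses to mix them.
DEFAULT_HASH_SEED = 0x5EED1E55

#: Hash slot marking a window that contains a non-ACGT base.
SENTINEL = np.uint64(0xFFFFFFFFFFFFFFFF)

_CODES = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODES[ord(_b)] = _i
    _CODES[ord(_b.lower())] = _i


def _encode(sequence: str) -> np.ndarray:
    """Map a sequence string to base codes (255 = non-ACGT)."""
    return _CODES[np.frombuffer(sequence.encode("ascii", "replace"), dtype=np.uint8)]


def _mix64(x: np.ndarray) -> np.ndarray:
    """Vectorized 64-bit finalizer (murmur3 fmix64); bijective on uint64."""
    x = x.copy()
    x ^= x >> np.uint64(33)
    x *= np.uint64(0xFF51AFD7ED558CCD)
    x ^= x >> np.uint64(33)
    x *= np.uint64(0xC4CEB9FE1A85EC53)
    x ^= x >> np.uint64(33)
    return x


def _check_k(k: int) -> None:
    if not (1 <= k <= 31):
        raise ParameterError(f"k must be in [1, 31], got {k}")
    if k % 2 == 0:
        raise ParameterError(
            f"k must be odd (k={k}): an even k-mer can equal its own reverse "
            "complement, making the canonical form ambiguous"
        )


def kmer_hash_array(sequence: str, k: int, seed: int = DEFAULT_HASH_SEED) -> np.ndarray:
    """Per-position canonical k-mer hashes for one contig.

    Returns a uint64 array of length ``len(sequence) - k + 1`` (empty if the
    contig is shorter than k).  Positions whose window contains a non-ACGT
    base hold :data:`SENTINEL`.
    """
    _check_k(k)
    codes = _encode(sequence)
    n = codes.size
    m = n - k + 1
    if m <= 0:
        return np.empty(0, dtype=np.uint64)
    invalid = codes >= 4
    codes4 = np.where(invalid, 0, codes).astype(np.uint64)
    fwd = np.zeros(m, dtype=np.uint64)
    rev = np.zeros(m, dtype=np.uint64)
    three = np.uint64(3)
    for j in range(k):
        fwd = (fwd << np.uint64(2)) | codes4[j : j + m]
        rev |= (three - codes4[j : j + m]) << np.uint64(2 * j)
    canon = np.minimum(fwd, rev)
    h = _mix64(canon ^ np.uint64(seed))
    # mask windows touching an ambiguous base
    cum = np.concatenate(([0], np.cumsum(invalid)))
    bad = (cum[k:] - cum[:-k]) > 0
    h[bad] = SENTINEL
    return h


def canonical_kmers(records: Sequence[SeqRecord], k: int,
                    seed: int = DEFAULT_HASH_SEED) -> np.ndarray:
    """The genome's canonical k-mer hash set, as a sorted unique uint64 array.

    Contigs are pooled: a multi-FASTA is one genome.
    """
    _check_k(k)
    parts = [kmer_hash_array(r.sequence, k, seed) for r in records]
    if parts:
        allh = np.concatenate(parts)
        allh = allh[allh != SENTINEL]
    else:
        allh = np.empty(0, dtype=np.uint64)
    return np.unique(allh)


@dataclass(frozen=True)
class Sketch:
    """Bottom-s MinHash sketch of one genome.

    ``hashes`` is strictly increasing with at most ``s`` entries; fewer only
    when the genome has fewer than s distinct valid k-mers.
    """

    k: int
    s: int
    hash_seed: int
    hashes: np.ndarray
    source_id: str
    genome_length: int

    def __post_init__(self) -> None:
        if self.hashes.size > self.s:
            raise ParameterError("sketch larger than its capacity s")

    def __eq__(self, other) -> bool:  # array field needs explicit comparison
        if not isinstance(other, Sketch):
            return NotImplemented
        return (
            self.k == other.k
            and self.s == other.s
            and self.hash_seed == other.hash_seed
            and self.source_id == other.source_id
            and self.genome_length == other.genome_length
            and np.array_equal(self.hashes, other.hashes)
        )


@dataclass(frozen=True)
class ScreenHit:
    """One reference surviving the genome-distance prescreen."""

    ref_accession: str
    mash_distance: float
    shared_hashes: int
    sketch_jaccard: float


def minhash_sketch(records: Sequence[SeqRecord], k: int = DEFAULT_K,
                   s: int = DEFAULT_SKETCH_SIZE, source_id: str = "",
                   seed: int = DEFAULT_HASH_SEED) -> Sketch:
    """Bottom-s sketch: the s smallest distinct canonical k-mer hashes."""
    if s < 1:
        raise ParameterError(f"sketch size s must be >= 1, got {s}")
    hashes = canonical_kmers(records, k, seed)
    if hashes.size == 0:
        raise ParameterError(
            f"no sketchable sequence in {source_id or 'input'}: "
            f"no window of {k} unambiguous bases"
        )
    total = sum(len(r.sequence) for r in records)
    return Sketch(k=k, s=s, hash_seed=seed, hashes=hashes[:s],
                  source_id=source_id, genome_length=total)


def _check_compatible(a: Sketch, b: Sketch) -> None:
    if a.k != b.k or a.s != b.s or a.hash_seed != b.hash_seed:
        raise SketchMismatchError(
            f"incompatible sketches: (k={a.k}, s={a.s}, seed={a.hash_seed:#x}) vs "
            f"(k={b.k}, s={b.s}, seed={b.hash_seed:#x})"
        )


def _merged_jaccard(a: Sketch, b: Sketch) -> tuple[float, int, int]:
    """Merged-sketch Jaccard estimate: (estimate, shared, merged size)."""
    union = np.union1d(a.hashes, b.hashes)
    merged = union[: a.s]
    in_a = np.isin(merged, a.hashes, assume_unique=True)
    in_b = np.isin(merged, b.hashes, assume_unique=True)
    shared = int(np.count_nonzero(in_a & in_b))
    return shared / merged.size, shared, merged.size


def sketch_jaccard(a: Sketch, b: Sketch) -> float:
    """Estimate Jaccard similarity from the merged bottom-s sketch.

    Exact whenever both genomes have fewer than s distinct k-mers (the
    sketches then *are* the full k-mer sets).
    """
    _check_compatible(a, b)
    j, _, _ = _merged_jaccard(a, b)
    return j


def mash_distance(j: float, k: int) -> float:
    """Mash distance D = -(1/k) * ln(2j / (1+j)), clamped to [0, 1].

    j = 1 gives 0; j = 0 is capped at 1.0 (the estimator diverges; the cap
    follows the Mash convention and keeps distances comparable).
    """
    if not (0.0 <= j <= 1.0):
        raise ParameterError(f"jaccard must be in [0, 1], got {j}")
    if j <= 0.0:
        return 1.0
    d = -(1.0 / k) * math.log(2.0 * j / (1.0 + j))
    return min(max(d, 0.0), 1.0)


def prescreen(query: Sketch, refdb, max_dist: float = 0.1,
              top_n: int | None = 20) -> list[ScreenHit]:
    """Step 1: rank references by Mash distance to the query sketch.

    Returns hits with distance <= ``max_dist``, sorted ascending by
    distance with ties broken by accession, truncated to ``top_n``
    (``None`` = unlimited).  The reference collection must have been built
    with the same (k, s, hash seed) as the query sketch.
    """
    sketches = refdb.sketches if hasattr(refdb, "sketches") else dict(refdb)
    if not sketches:
        raise SketchMismatchError("reference database contains no sketches")
    hits: list[ScreenHit] = []
    for acc in sorted(sketches):
        ref = sketches[acc]
        try:
            _check_compatible(query, ref)
        except SketchMismatchError as exc:
            raise SketchMismatchError(
                f"query sketch does not match reference database parameters "
                f"({exc}); rebuild the database or re-sketch the query"
            ) from exc
        j, shared, _ = _merged_jaccard(query, ref)
        d = mash_distance(j, query.k)
        if d <= max_dist:
            hits.append(ScreenHit(ref_accession=acc, mash_distance=d,
                                  shared_hashes=shared, sketch_jaccard=j))
    hits.sort(key=lambda h: (h.mash_distance, h.ref_accession))
    if top_n is not None:
        hits = hits[:top_n]
    return hits
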