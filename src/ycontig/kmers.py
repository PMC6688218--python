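"""Canonical k-merization and the two k-mer stores.

A male-assembly contig is compared against two structures built here:

* a *female k-mer set* — approximate (Bloom filter) or exact membership over
  the canonical k-mers of a female reference or of abundance-filtered female
  reads; and
* a *male k-mer abundance table* — exact canonical k-mer counts from the male
  reads used for assembly, with low-abundance (likely erroneous) k-mers
  removed.

k-mers are packed 2 bits per base into uint64 (so k <= 31 for the fast path;
k = 25 is the default throughout). A canonical k-mer is the lexicographic
minimum of the k-mer and its reverse complement, which for the A<C<G<T
encoding coincides with the numeric minimum of the packed values. Windows
containing any non-ACGT symbol are skipped entirely.
"""

from __future__ import annotations

import os
import struct
from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

import numpy as np

from .io import iter_sequences

__all__ = [
    "KmerParams",
    "kmerize",
    "encode_sequence",
    "kmer_codes",
    "decode_kmer",
    "reverse_complement",
    "ExactKmerSet",
    "BloomKmerSet",
    "MaleKmerCounts",
    "build_female_kmer_set",
    "count_male_kmers",
    "save_kmer_set",
    "load_kmer_set",
]

MAX_PACKED_K = 31

_BASE_TO_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_TO_CODE[_b] = _i
    _BASE_TO_CODE[_b + 32] = _i  # lower case
_CODE_TO_BASE = np.frombuffer(b"ACGT", dtype=np.uint8)

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class KmerParams:
    """k-merization parameters.

    Parameters
    ----------
    k : int
        k-mer length, default 25.
    min_abundance : int
        Abundance floor for read-derived k-mers; k-mers occurring fewer
        times than this are treated as erroneous and dropped. Default 3.
    canonical : bool
        Map every k-mer to min(kmer, revcomp(kmer)). Default True.
    """

    k: int = 25
    min_abundance: int = 3
    canonical: bool = True

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError(f"k must be >= 1, got {self.k}")
        if self.k > MAX_PACKED_K:
            raise ValueError(
                f"k must be <= {MAX_PACKED_K} for the packed representation, "
                f"got {self.k}")
        if self.min_abundance < 1:
            raise ValueError(
                f"min_abundance must be >= 1, got {self.min_abundance}")


def encode_sequence(seq: str | bytes) -> np.ndarray:
    """Encode a nucleotide string to uint8 codes (A=0 C=1 G=2 T=3, other=255)."""
    if isinstance(seq, str):
        seq = seq.encode("ascii")
    return _BASE_TO_CODE[np.frombuffer(seq, dtype=np.uint8)]


def kmer_codes(codes: np.ndarray, k: int, canonical: bool = True) -> np.ndarray:
    """Packed k-mers of every valid window of an encoded sequence.

    Windows containing a non-ACGT code are dropped; the result preserves the
    left-to-right order of the surviving windows.
    """
    n = codes.shape[0]
    m = n - k + 1
    if m <= 0:
        return np.empty(0, dtype=np.uint64)
    invalid = codes >= 4
    if invalid.any():
        bad = np.cumsum(invalid)
        # number of invalid symbols inside window [i, i+k)
        win_bad = bad[k - 1:].copy()
        win_bad[1:] -= bad[:m - 1]
        valid = win_bad == 0
        safe = np.where(invalid, 0, codes).astype(np.uint64)
    else:
        valid = None
        safe = codes.astype(np.uint64)

    fwd = np.zeros(m, dtype=np.uint64)
    for j in range(k):  # base at window offset j has weight 4^(k-1-j)
        fwd <<= np.uint64(2)
        fwd |= safe[j:j + m]
    if canonical:
        comp = np.uint64(3) - safe
        rev = np.zeros(m, dtype=np.uint64)
        for j in range(k):  # complement of offset j has weight 4^j in the revcomp
            rev |= comp[j:j + m] << np.uint64(2 * j)
        kmers = np.minimum(fwd, rev)
    else:
        kmers = fwd
    if valid is not None:
        kmers = kmers[valid]
    return kmers


def decode_kmer(packed: int, k: int) -> str:
    packed = int(packed)
    out = bytearray(k)
    for j in range(k - 1, -1, -1):
        out[j] = _CODE_TO_BASE[packed & 3]
        packed >>= 2
    return out.decode("ascii")


def kmerize(sequence: str, params: KmerParams | None = None, *,
            k: int | None = None, canonical: bool | None = None) -> list[str]:
    """All overlapping k-mers of ``sequence``, in order, as strings.

    Windows containing non-ACGT symbols are skipped; with fewer than k usable
    positions the result is empty. Convenience string API over
    :func:`kmer_codes`.
    """
    if params is None:
        params = KmerParams()
    kk = params.k if k is None else k
    canon = params.canonical if canonical is None else canonical
    packed = kmer_codes(encode_sequence(sequence), kk, canon)
    return [decode_kmer(x, kk) for x in packed]


# ---------------------------------------------------------------------------
# hashing (splitmix64 finalizer, vectorized on uint64)

_SM_C1 = np.uint64(0xBF58476D1CE4E5B9)
_SM_C2 = np.uint64(0x94D049BB133111EB)
_SM_INC = np.uint64(0x9E3779B97F4A7C15)


def _splitmix64(x: np.ndarray) -> np.ndarray:
    z = x + _SM_INC
    z = (z ^ (z >> np.uint64(30))) * _SM_C1
    z = (z ^ (z >> np.uint64(27))) * _SM_C2
    return z ^ (z >> np.uint64(31))


# ---------------------------------------------------------------------------
# female k-mer sets


class ExactKmerSet:
    """Exact membership set over packed canonical k-mers.

    Same interface as :class:`BloomKmerSet` with a false-positive rate of 0;
    intended for small inputs and as the ground-truth backend in tests.
    """

    backend = "exact"

    def __init__(self, k: int, canonical: bool = True):
        self.k = int(k)
        self.canonical = bool(canonical)
        self._chunks: list[np.ndarray] = []
        self._kmers = np.empty(0, dtype=np.uint64)

    @property
    def n_inserted(self) -> int:
        self._finalize()
        return int(self._kmers.shape[0])

    def add(self, kmers: np.ndarray) -> None:
        if kmers.size:
            self._chunks.append(np.unique(np.asarray(kmers, dtype=np.uint64)))

    def _finalize(self) -> None:
        if self._chunks:
            self._kmers = np.unique(np.concatenate([self._kmers, *self._chunks]))
            self._chunks = []

    def contains(self, kmers: np.ndarray) -> np.ndarray:
        self._finalize()
        kmers = np.asarray(kmers, dtype=np.uint64)
        idx = np.searchsorted(self._kmers, kmers)
        idx = np.minimum(idx, max(self._kmers.shape[0] - 1, 0))
        if self._kmers.shape[0] == 0:
            return np.zeros(kmers.shape[0], dtype=bool)
        return self._kmers[idx] == kmers

    def contains_kmer(self, kmer: str) -> bool:
        packed = kmer_codes(encode_sequence(kmer), self.k, self.canonical)
        if packed.size != 1:
            raise ValueError(f"expected a single {self.k}-mer, got {kmer!r}")
        return bool(self.contains(packed)[0])


class BloomKmerSet:
    """Bloom filter over packed canonical k-mers.

    No false negatives; false-positive probability approximately
    ``target_fp_rate`` as long as at most ``capacity`` distinct k-mers are
    inserted. Uses double hashing with two splitmix64-derived hash values.
    """

    backend = "bloom"

    def __init__(self, k: int, capacity: int, target_fp_rate: float = 0.001,
                 canonical: bool = True):
        if capacity < 1:
            raise ValueError(f"capacity must be >= 1, got {capacity}")
        if not 0.0 < target_fp_rate < 1.0:
            raise ValueError(
                f"target_fp_rate must be in (0, 1), got {target_fp_rate}")
        self.k = int(k)
        self.canonical = bool(canonical)
        self.capacity = int(capacity)
        self.target_fp_rate = float(target_fp_rate)
        ln2 = np.log(2.0)
        n_bits = int(np.ceil(-capacity * np.log(target_fp_rate) / (ln2 * ln2)))
        self.n_bits = max(n_bits, 64)
        self.n_hashes = max(1, int(round(self.n_bits / capacity * ln2)))
        self._bits = np.zeros((self.n_bits + 7) // 8, dtype=np.uint8)
        self.n_inserted = 0

    def _indices(self, kmers: np.ndarray, i: int) -> np.ndarray:
        h1 = _splitmix64(kmers)
        h2 = _splitmix64(kmers ^ np.uint64(0xA5A5A5A5A5A5A5A5)) | np.uint64(1)
        return (h1 + np.uint64(i) * h2) % np.uint64(self.n_bits)

    def add(self, kmers: np.ndarray) -> None:
        kmers = np.unique(np.asarray(kmers, dtype=np.uint64))
        if not kmers.size:
            return
        # n_inserted is an upper bound on distinct insertions (chunks are
        # deduplicated within, not across, calls)
        self.n_inserted += int(kmers.shape[0])
        if self.n_inserted > self.capacity:
            raise ValueError(
                f"Bloom filter capacity exceeded: {self.n_inserted} insertions "
                f"> capacity {self.capacity}; the false-positive guarantee "
                f"would be void")
        h1 = _splitmix64(kmers)
        h2 = _splitmix64(kmers ^ np.uint64(0xA5A5A5A5A5A5A5A5)) | np.uint64(1)
        nb = np.uint64(self.n_bits)
        for i in range(self.n_hashes):
            idx = (h1 + np.uint64(i) * h2) % nb
            np.bitwise_or.at(self._bits, (idx >> np.uint64(3)).astype(np.int64),
                             np.left_shift(np.uint8(1),
                                           (idx & np.uint64(7)).astype(np.uint8)))

    def contains(self, kmers: np.ndarray) -> np.ndarray:
        kmers = np.asarray(kmers, dtype=np.uint64)
        if not kmers.size:
            return np.zeros(0, dtype=bool)
        h1 = _splitmix64(kmers)
        h2 = _splitmix64(kmers ^ np.uint64(0xA5A5A5A5A5A5A5A5)) | np.uint64(1)
        nb = np.uint64(self.n_bits)
        out = np.ones(kmers.shape[0], dtype=bool)
        for i in range(self.n_hashes):
            idx = (h1 + np.uint64(i) * h2) % nb
            byte = self._bits[(idx >> np.uint64(3)).astype(np.int64)]
            bit = (byte >> (idx & np.uint64(7)).astype(np.uint8)) & np.uint8(1)
            out &= bit.astype(bool)
            if not out.any():
                break
        return out

    def contains_kmer(self, kmer: str) -> bool:
        packed = kmer_codes(encode_sequence(kmer), self.k, self.canonical)
        if packed.size != 1:
            raise ValueError(f"expected a single {self.k}-mer, got {kmer!r}")
        return bool(self.contains(packed)[0])


# ---------------------------------------------------------------------------
# male k-mer counts


class MaleKmerCounts:
    """Exact canonical k-mer abundances from male reads.

    Stores only k-mers with abundance >= ``min_abundance``; lookups of
    absent k-mers return 0.
    """

    def __init__(self, k: int, kmers: np.ndarray, counts: np.ndarray,
                 canonical: bool = True, min_abundance: int = 3):
        order = np.argsort(kmers, kind="stable")
        self.k = int(k)
        self.canonical = bool(canonical)
        self.min_abundance = int(min_abundance)
        self._kmers = np.asarray(kmers, dtype=np.uint64)[order]
        self._counts = np.asarray(counts, dtype=np.int64)[order]

    def __len__(self) -> int:
        return int(self._kmers.shape[0])

    def get(self, kmers: np.ndarray) -> np.ndarray:
        """Abundance of each packed k-mer; absent k-mers map to 0."""
        kmers = np.asarray(kmers, dtype=np.uint64)
        if self._kmers.shape[0] == 0:
            return np.zeros(kmers.shape[0], dtype=np.int64)
        idx = np.searchsorted(self._kmers, kmers)
        idx = np.minimum(idx, self._kmers.shape[0] - 1)
        hit = self._kmers[idx] == kmers
        return np.where(hit, self._counts[idx], 0)

    def get_kmer(self, kmer: str) -> int:
        packed = kmer_codes(encode_sequence(kmer), self.k, self.canonical)
        if packed.size != 1:
            raise ValueError(f"expected a single {self.k}-mer, got {kmer!r}")
        return int(self.get(packed)[0])

    def save(self, path: str | os.PathLike) -> None:
        np.savez(path, kmers=self._kmers, counts=self._counts,
                 k=self.k, canonical=self.canonical,
                 min_abundance=self.min_abundance)

    @classmethod
    def load(cls, path: str | os.PathLike,
             expected_k: int | None = None) -> "MaleKmerCounts":
        with np.load(path) as data:
            k = int(data["k"])
            if expected_k is not None and k != expected_k:
                raise ValueError(
                    f"k-mer count table at {path} was built with k={k}, "
                    f"expected k={expected_k}")
            return cls(k, data["kmers"], data["counts"],
                       canonical=bool(data["canonical"]),
                       min_abundance=int(data["min_abundance"]))


# ---------------------------------------------------------------------------
# builders

_CHUNK_BASES = 32 * 1024 * 1024  # ~32 Mb of sequence per processing chunk


def _check_readable(paths: Sequence[str | os.PathLike]) -> list[str]:
    paths = [os.fspath(p) for p in paths]
    if not paths:
        raise ValueError("no input sequence files given")
    for p in paths:
        if not os.path.exists(p):
            raise FileNotFoundError(f"sequence file not found: {p}")
        if os.path.getsize(p) == 0:
            raise ValueError(f"empty sequence file: {p}")
    return paths


def _iter_kmer_chunks(paths: Sequence[str], params: KmerParams,
                      chunk_bases: int = _CHUNK_BASES) -> Iterator[np.ndarray]:
    """Yield packed-k-mer arrays over all records of all files.

    Records are concatenated with an 'N' separator inside a chunk so no
    window spans a record boundary.
    """
    buf: list[str] = []
    size = 0

    def flush() -> np.ndarray:
        nonlocal buf, size
        joined = "N".join(buf)
        buf = []
        size = 0
        return kmer_codes(encode_sequence(joined), params.k, params.canonical)

    for path in paths:
        for _name, seq in iter_sequences(path):
            buf.append(seq)
            size += len(seq)
            if size >= chunk_bases:
                yield flush()
    if buf:
        yield flush()


def _count_kmers(paths: Sequence[str], params: KmerParams,
                 chunk_bases: int = _CHUNK_BASES) -> tuple[np.ndarray, np.ndarray]:
    """Exact (kmer, count) over all inputs, before any abundance filter."""
    uniq_chunks: list[np.ndarray] = []
    count_chunks: list[np.ndarray] = []
    for kmers in _iter_kmer_chunks(paths, params, chunk_bases):
        if not kmers.size:
            continue
        u, c = np.unique(kmers, return_counts=True)
        uniq_chunks.append(u)
        count_chunks.append(c.astype(np.int64))
    if not uniq_chunks:
        return np.empty(0, dtype=np.uint64), np.empty(0, dtype=np.int64)
    allk = np.concatenate(uniq_chunks)
    allc = np.concatenate(count_chunks)
    uniq, inverse = np.unique(allk, return_inverse=True)
    counts = np.bincount(inverse, weights=allc.astype(np.float64))
    return uniq, counts.astype(np.int64)


def count_male_kmers(inputs: Sequence[str | os.PathLike],
                     params: KmerParams | None = None) -> MaleKmerCounts:
    """Count canonical k-mers in male reads; drop abundances < min_abundance."""
    params = params or KmerParams()
    paths = _check_readable(inputs)
    kmers, counts = _count_kmers(paths, params)
    keep = counts >= params.min_abundance
    return MaleKmerCounts(params.k, kmers[keep], counts[keep],
                          canonical=params.canonical,
                          min_abundance=params.min_abundance)


def build_female_kmer_set(inputs: Sequence[str | os.PathLike],
                          params: KmerParams | None = None,
                          capacity: int | None = None,
                          target_fp_rate: float = 0.001,
                          input_kind: str = "reference",
                          backend: str = "bloom") -> "BloomKmerSet | ExactKmerSet":
    """Build the female k-mer membership set from reference or read files.

    With ``input_kind="reference"`` every canonical k-mer is inserted. With
    ``input_kind="reads"`` k-mers are counted first and only those with
    abundance >= ``params.min_abundance`` are inserted, removing likely
    sequencing errors.
    """
    params = params or KmerParams()
    if input_kind not in ("reference", "reads"):
        raise ValueError(f"input_kind must be 'reference' or 'reads', "
                         f"got {input_kind!r}")
    if backend not in ("bloom", "exact"):
        raise ValueError(f"backend must be 'bloom' or 'exact', got {backend!r}")
    paths = _check_readable(inputs)

    if backend == "exact":
        store: BloomKmerSet | ExactKmerSet = ExactKmerSet(
            params.k, canonical=params.canonical)
    else:
        if capacity is None:
            total = sum(os.path.getsize(p) for p in paths)
            # sequence bytes upper-bound the number of windows; gzip inputs
            # are handled by counting decompressed record lengths instead
            if any(p.endswith(".gz") for p in paths):
                total = sum(len(seq) for p in paths
                            for _n, seq in iter_sequences(p))
            capacity = max(64, int(1.2 * total))
        store = BloomKmerSet(params.k, capacity=capacity,
                             target_fp_rate=target_fp_rate,
                             canonical=params.canonical)

    if input_kind == "reference":
        for kmers in _iter_kmer_chunks(paths, params):
            store.add(kmers)
    else:
        kmers, counts = _count_kmers(paths, params)
        store.add(kmers[counts >= params.min_abundance])
    return store


# ---------------------------------------------------------------------------
# female-set serialization (self-describing, little-endian, bit-exact)

_BLOOM_MAGIC = b"YCBLOOM\x01"
_EXACT_MAGIC = b"YCEXACT\x01"
# k, canonical, capacity, n_inserted, n_hashes, n_bits, target_fp_rate
_BLOOM_HEADER = struct.Struct("<QQQQQQd")
# k, canonical, n_inserted
_EXACT_HEADER = struct.Struct("<QQQ")


def save_kmer_set(kmer_set: "BloomKmerSet | ExactKmerSet",
                  path: str | os.PathLike) -> None:
    """Serialize a female k-mer set; queries round-trip losslessly."""
    with open(path, "wb") as fh:
        if isinstance(kmer_set, BloomKmerSet):
            fh.write(_BLOOM_MAGIC)
            fh.write(_BLOOM_HEADER.pack(
                kmer_set.k, int(kmer_set.canonical), kmer_set.capacity,
                kmer_set.n_inserted, kmer_set.n_hashes, kmer_set.n_bits,
                kmer_set.target_fp_rate))
            fh.write(kmer_set._bits.tobytes())
        elif isinstance(kmer_set, ExactKmerSet):
            kmer_set._finalize()
            fh.write(_EXACT_MAGIC)
            fh.write(_EXACT_HEADER.pack(
                kmer_set.k, int(kmer_set.canonical), kmer_set.n_inserted))
            fh.write(kmer_set._kmers.astype("<u8").tobytes())
        else:
            raise TypeError(f"cannot serialize {type(kmer_set).__name__}")


def load_kmer_set(path: str | os.PathLike,
                  expected_k: int | None = None) -> "BloomKmerSet | ExactKmerSet":
    with open(path, "rb") as fh:
        data = fh.read()
    magic, body = data[:8], data[8:]
    if magic == _BLOOM_MAGIC:
        if len(body) < _BLOOM_HEADER.size:
            raise ValueError(f"truncated k-mer set file: {path}")
        (k, canonical, capacity, n_inserted, n_hashes, n_bits,
         fp_rate) = _BLOOM_HEADER.unpack_from(body)
        payload = body[_BLOOM_HEADER.size:]
        expected_bytes = (n_bits + 7) // 8
        if len(payload) != expected_bytes:
            raise ValueError(
                f"truncated or corrupt k-mer set file: {path} "
                f"(expected {expected_bytes} bit-array bytes, "
                f"found {len(payload)})")
        if expected_k is not None and k != expected_k:
            raise ValueError(f"k-mer set at {path} was built with k={k}, "
                             f"expected k={expected_k}")
        out = BloomKmerSet.__new__(BloomKmerSet)
        out.k = int(k)
        out.canonical = bool(canonical)
        out.capacity = int(capacity)
        out.target_fp_rate = float(fp_rate)
        out.n_hashes = int(n_hashes)
        out.n_bits = int(n_bits)
        out.n_inserted = int(n_inserted)
        out._bits = np.frombuffer(payload, dtype=np.uint8).copy()
        return out
    if magic == _EXACT_MAGIC:
        if len(body) < _EXACT_HEADER.size:
            raise ValueError(f"truncated k-mer set file: {path}")
        k, canonical, n_inserted = _EXACT_HEADER.unpack_from(body)
        payload = body[_EXACT_HEADER.size:]
        if len(payload) != 8 * n_inserted:
            raise ValueError(
                f"truncated or corrupt k-mer set file: {path} "
                f"(expected {8 * n_inserted} payload bytes, "
                f"found {len(payload)})")
        if expected_k is not None and k != expected_k:
            raise ValueError(f"k-mer set at {path} was built with k={k}, "
                             f"expected k={expected_k}")
        out = ExactKmerSet(int(k), canonical=bool(canonical))
        out._kmers = np.frombuffer(payload, dtype="<u8").astype(np.uint64)
        return out
    raise ValueError(f"not a k-mer set file (bad magic): {path}")
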