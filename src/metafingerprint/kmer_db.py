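"""Canonical k-mer databases: construction, filtering, merging, subtraction, I/O.

A class-level database is the "microbiome fingerprint" of one origin class
(e.g. a city): the set of canonical k-mers observed, at sufficient multiplicity,
in the reference samples of that class.  Databases are built per sample with
counts (``CountedKmerDB``), filtered against a minimum occurrence count ``ci``
to reject k-mers likely caused by sequencing errors, merged into per-class sets
(``KmerSet``), and finally host (human) k-mers are subtracted so that host DNA
carried by every sample cannot dominate the class signatures.

K-mers are stored 2-bit encoded (A=0, C=1, G=2, T=3) in sorted ``uint64``
arrays, which bounds supported k at 32; the default k is 24.  The 2-bit code
order coincides with lexicographic order on A<C<G<T, so sorted codes are
sorted k-mer strings.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

__all__ = [
    "MAX_K",
    "InvalidKmerError",
    "IncompatibleDatabaseError",
    "FormatError",
    "Provenance",
    "CountedKmerDB",
    "KmerSet",
    "canonical",
    "extract_kmers",
    "extract_kmer_codes",
    "encode_kmer",
    "decode_kmer",
    "revcomp_code",
    "build_counted_db",
    "filter_infrequent",
    "merge_to_class",
    "subtract",
    "save_db",
    "load_db",
]

MAX_K = 32

_BASES = "ACGT"
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(_BASES):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i


class InvalidKmerError(ValueError):
    """A k-mer has the wrong length or contains a non-ACGT symbol."""


class IncompatibleDatabaseError(ValueError):
    """Databases with different k cannot be combined."""


class FormatError(ValueError):
    """A database file is corrupt or inconsistent."""


# ---------------------------------------------------------------------------
# encoding primitives


def encode_kmer(seq: str) -> int:
    """2-bit encode an ACGT string (case-insensitive) into an integer."""
    v = 0
    for ch in seq.upper():
        c = _CODE[ord(ch)] if ord(ch) < 256 else 255
        if c > 3:
            raise InvalidKmerError(f"non-ACGT symbol {ch!r} in k-mer")
        v = (v << 2) | int(c)
    return v


def decode_kmer(code: int, k: int) -> str:
    """Inverse of :func:`encode_kmer`."""
    out = []
    for shift in range(2 * (k - 1), -1, -2):
        out.append(_BASES[(code >> shift) & 3])
    return "".join(out)


def revcomp_code(code: int, k: int) -> int:
    """Reverse complement of a 2-bit encoded k-mer."""
    rc = 0
    for _ in range(k):
        rc = (rc << 2) | (3 - (code & 3))
        code >>= 2
    return rc


def canonical(seq: str) -> str:
    """Return the canonical form of a k-mer: the lexicographically smaller of
    the k-mer and its reverse complement (order A<C<G<T).

    Raises :class:`InvalidKmerError` on any symbol outside ACGT (lowercase is
    accepted and uppercased).
    """
    if not seq:
        raise InvalidKmerError("empty k-mer")
    k = len(seq)
    if k > MAX_K:
        raise InvalidKmerError(f"k={k} exceeds supported maximum {MAX_K}")
    code = encode_kmer(seq)
    return decode_kmer(min(code, revcomp_code(code, k)), k)


def _encode_bases(seq: str) -> np.ndarray:
    """Map a sequence to base codes 0..3; anything else (incl. N) -> 255."""
    raw = np.frombuffer(seq.upper().encode("ascii", errors="replace"), dtype=np.uint8)
    return _CODE[raw]


def extract_kmer_codes(seq: str, k: int) -> tuple[np.ndarray, np.ndarray]:
    """All canonical k-mer codes of ``seq`` with their window start positions.

    Windows containing any symbol outside ACGT yield nothing.  Returns
    ``(codes, starts)`` as uint64 / int64 arrays ordered by window position.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > MAX_K:
        raise InvalidKmerError(f"k={k} exceeds supported maximum {MAX_K}")
    codes_b = _encode_bases(seq)
    n = codes_b.size - k + 1
    if n <= 0:
        return (np.empty(0, dtype=np.uint64), np.empty(0, dtype=np.int64))
    win = np.lib.stride_tricks.sliding_window_view(codes_b, k)
    valid = (win <= 3).all(axis=1)
    starts = np.nonzero(valid)[0].astype(np.int64)
    if starts.size == 0:
        return (np.empty(0, dtype=np.uint64), starts)
    w = win[valid].astype(np.uint64)
    shifts_f = np.arange(2 * (k - 1), -1, -2, dtype=np.uint64)
    fwd = (w << shifts_f).sum(axis=1, dtype=np.uint64)
    # reverse complement: complement codes, read right-to-left
    rc = ((np.uint64(3) - w)[:, ::-1] << shifts_f).sum(axis=1, dtype=np.uint64)
    return (np.minimum(fwd, rc), starts)


def extract_kmers(seq: str, k: int) -> list[str]:
    """Canonical k-mers of every all-ACGT window of ``seq``, in window order."""
    codes, _ = extract_kmer_codes(seq, k)
    return [decode_kmer(int(c), k) for c in codes]


# ---------------------------------------------------------------------------
# database containers


@dataclass(frozen=True)
class Provenance:
    """How a KmerSet was produced: source level, ci applied, host subtraction."""

    level: str = "sample"  # "sample" | "class"
    ci: int | None = None
    host_subtracted: bool = False


@dataclass
class CountedKmerDB:
    """Canonical k-mers with occurrence counts, pre-filtering (the D0_j DBs).

    ``codes`` is a sorted uint64 array of 2-bit encoded canonical k-mers and
    ``counts`` the parallel positive count array.
    """

    k: int
    codes: np.ndarray
    counts: np.ndarray
    label: str = ""
    level: str = "sample"

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.uint64)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.codes.shape != self.counts.shape:
            raise ValueError("codes and counts must be parallel arrays")
        if self.counts.size and self.counts.min() < 1:
            raise ValueError("all counts must be >= 1")
        if self.level not in ("sample", "class"):
            raise ValueError(f"unknown level {self.level!r}")

    @classmethod
    def from_mapping(
        cls, k: int, entries: Mapping[str, int], label: str = "", level: str = "sample"
    ) -> "CountedKmerDB":
        """Build from a {kmer-string: count} mapping (k-mers canonicalized)."""
        agg: dict[int, int] = {}
        for s, c in entries.items():
            if len(s) != k:
                raise InvalidKmerError(f"k-mer {s!r} has length {len(s)}, expected {k}")
            code = encode_kmer(s)
            code = min(code, revcomp_code(code, k))
            agg[code] = agg.get(code, 0) + int(c)
        codes = np.array(sorted(agg), dtype=np.uint64)
        counts = np.array([agg[int(c)] for c in codes], dtype=np.int64)
        return cls(k=k, codes=codes, counts=counts, label=label, level=level)

    def to_mapping(self) -> dict[str, int]:
        return {decode_kmer(int(c), self.k): int(n) for c, n in zip(self.codes, self.counts)}

    def __len__(self) -> int:
        return int(self.codes.size)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CountedKmerDB):
            return NotImplemented
        return (
            self.k == other.k
            and self.label == other.label
            and self.level == other.level
            and np.array_equal(self.codes, other.codes)
            and np.array_equal(self.counts, other.counts)
        )


@dataclass
class KmerSet:
    """A plain set of canonical k-mers (the D_j and D_H databases)."""

    k: int
    codes: np.ndarray
    label: str = ""
    provenance: Provenance = field(default_factory=Provenance)

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.uint64)

    @classmethod
    def from_strings(
        cls,
        k: int,
        members: Iterable[str],
        label: str = "",
        provenance: Provenance | None = None,
    ) -> "KmerSet":
        codes = set()
        for s in members:
            if len(s) != k:
                raise InvalidKmerError(f"k-mer {s!r} has length {len(s)}, expected {k}")
            code = encode_kmer(s)
            codes.add(min(code, revcomp_code(code, k)))
        return cls(
            k=k,
            codes=np.array(sorted(codes), dtype=np.uint64),
            label=label,
            provenance=provenance or Provenance(),
        )

    def to_strings(self) -> set[str]:
        return {decode_kmer(int(c), self.k) for c in self.codes}

    def contains_codes(self, codes: np.ndarray) -> np.ndarray:
        """Boolean membership mask for an array of canonical codes."""
        if self.codes.size == 0:
            return np.zeros(codes.shape, dtype=bool)
        idx = np.searchsorted(self.codes, codes)
        idx = np.minimum(idx, self.codes.size - 1)
        return self.codes[idx] == codes

    def __contains__(self, kmer: str) -> bool:
        code = encode_kmer(kmer)
        code = min(code, revcomp_code(code, self.k))
        i = int(np.searchsorted(self.codes, np.uint64(code)))
        return i < self.codes.size and int(self.codes[i]) == code

    def __len__(self) -> int:
        return int(self.codes.size)

    def __iter__(self) -> Iterator[str]:
        for c in self.codes:
            yield decode_kmer(int(c), self.k)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, KmerSet):
            return NotImplemented
        return (
            self.k == other.k
            and self.label == other.label
            and self.provenance == other.provenance
            and np.array_equal(self.codes, other.codes)
        )


# ---------------------------------------------------------------------------
# operations


def build_counted_db(
    reads: Iterable[str], k: int, label: str = "", level: str = "sample"
) -> CountedKmerDB:
    """Count canonical k-mers over all reads (multiset union of windows)."""
    chunks = []
    for read in reads:
        codes, _ = extract_kmer_codes(read, k)
        if codes.size:
            chunks.append(codes)
    if not chunks:
        return CountedKmerDB(
            k=k,
            codes=np.empty(0, dtype=np.uint64),
            counts=np.empty(0, dtype=np.int64),
            label=label,
            level=level,
        )
    codes, counts = np.unique(np.concatenate(chunks), return_counts=True)
    return CountedKmerDB(k=k, codes=codes, counts=counts.astype(np.int64), label=label, level=level)


def filter_infrequent(db: CountedKmerDB, ci: int) -> KmerSet:
    """Keep k-mers occurring at least ``ci`` times; drop counts.

    Infrequent k-mers are rejected because they likely stem from sequencing
    errors rather than genuine genomic content.
    """
    if ci < 1:
        raise ValueError("ci must be >= 1")
    mask = db.counts >= ci
    return KmerSet(
        k=db.k,
        codes=db.codes[mask].copy(),
        label=db.label,
        provenance=Provenance(level=db.level, ci=ci),
    )


def merge_to_class(
    dbs: Sequence[CountedKmerDB],
    ci: int,
    mode: str = "sample_level",
    label: str = "",
) -> KmerSet:
    """Combine per-sample counted databases into one class-level KmerSet.

    ``mode="sample_level"``: filter each sample at ci first, then take the set
    union (a k-mer survives if any single sample supports it ci times).
    ``mode="class_level"``: sum counts across samples, then filter the pooled
    counts at ci (spread-out support across samples can add up).
    """
    if not dbs:
        raise ValueError("need at least one database to merge")
    ks = {db.k for db in dbs}
    if len(ks) > 1:
        raise IncompatibleDatabaseError(f"mixed k values: {sorted(ks)}")
    k = ks.pop()
    if mode == "sample_level":
        parts = [filter_infrequent(db, ci).codes for db in dbs]
        codes = np.unique(np.concatenate(parts)) if parts else np.empty(0, dtype=np.uint64)
    elif mode == "class_level":
        all_codes = np.concatenate([db.codes for db in dbs])
        all_counts = np.concatenate([db.counts for db in dbs])
        uniq, inv = np.unique(all_codes, return_inverse=True)
        summed = np.zeros(uniq.size, dtype=np.int64)
        np.add.at(summed, inv, all_counts)
        codes = uniq[summed >= ci]
    else:
        raise ValueError(f"unknown merge mode {mode!r}")
    return KmerSet(
        k=k,
        codes=codes,
        label=label,
        provenance=Provenance(level="class", ci=ci),
    )


def subtract(db: KmerSet, host: KmerSet) -> KmerSet:
    """Set-difference ``db \\ host`` (host-DNA subtraction), flagged in provenance."""
    if db.k != host.k:
        raise IncompatibleDatabaseError(f"k mismatch: {db.k} vs {host.k}")
    keep = ~host.contains_codes(db.codes)
    return KmerSet(
        k=db.k,
        codes=db.codes[keep].copy(),
        label=db.label,
        provenance=replace(db.provenance, host_subtracted=True),
    )


# ---------------------------------------------------------------------------
# serialization: binary (MFKD) and text dialects

_MAGIC = b"MFKD"
_VERSION = 1
_FLAG_CLASS = 0x01
_FLAG_COUNTED = 0x02
_FLAG_HOST_SUB = 0x04


def _pack_codes(codes: np.ndarray, k: int) -> bytes:
    nbytes = (k + 3) // 4  # 2 bits per base, big-endian within the record
    out = bytearray()
    for c in codes:
        v = int(c) << (2 * (4 * nbytes - k))  # left-align to byte boundary
        out += v.to_bytes(nbytes, "big")
    return bytes(out)


def _unpack_codes(buf: bytes, k: int, n: int) -> np.ndarray:
    nbytes = (k + 3) // 4
    if len(buf) != n * nbytes:
        raise FormatError("truncated k-mer records")
    shift = 2 * (4 * nbytes - k)
    codes = np.empty(n, dtype=np.uint64)
    for i in range(n):
        v = int.from_bytes(buf[i * nbytes : (i + 1) * nbytes], "big") >> shift
        codes[i] = v
    return codes


def save_db(db: CountedKmerDB | KmerSet, path: str | Path, dialect: str = "binary") -> None:
    """Write a database to disk in the binary (MFKD) or text (TSV) dialect."""
    path = Path(path)
    if dialect == "binary":
        _save_binary(db, path)
    elif dialect == "text":
        _save_text(db, path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def _db_attrs(db: CountedKmerDB | KmerSet) -> tuple[str, int | None, bool, bool]:
    if isinstance(db, CountedKmerDB):
        return db.level, None, False, True
    return db.provenance.level, db.provenance.ci, db.provenance.host_subtracted, False


def _save_binary(db: CountedKmerDB | KmerSet, path: Path) -> None:
    level, ci, host_sub, counted = _db_attrs(db)
    flags = 0
    if level == "class":
        flags |= _FLAG_CLASS
    if counted:
        flags |= _FLAG_COUNTED
    if host_sub:
        flags |= _FLAG_HOST_SUB
    label = db.label.encode("utf-8")
    with open(path, "wb") as fh:
        fh.write(_MAGIC)
        fh.write(struct.pack("<BBB", _VERSION, db.k, flags))
        fh.write(struct.pack("<H", len(label)))
        fh.write(label)
        fh.write(struct.pack("<I", 0 if ci is None else ci))
        fh.write(struct.pack("<Q", len(db.codes)))
        fh.write(_pack_codes(db.codes, db.k))
        if counted:
            fh.write(np.asarray(db.counts, dtype="<u4").tobytes())


def _save_text(db: CountedKmerDB | KmerSet, path: Path) -> None:
    level, ci, host_sub, counted = _db_attrs(db)
    with open(path, "w") as fh:
        header = f"#k={db.k}\tlevel={level}\tlabel={db.label}"
        if ci is not None:
            header += f"\tci={ci}"
        if host_sub:
            header += "\thost_subtracted=1"
        fh.write(header + "\n")
        if counted:
            for c, n in zip(db.codes, db.counts):
                fh.write(f"{decode_kmer(int(c), db.k)}\t{int(n)}\n")
        else:
            for c in db.codes:
                fh.write(decode_kmer(int(c), db.k) + "\n")


def load_db(path: str | Path) -> CountedKmerDB | KmerSet:
    """Load either dialect, detected from the MFKD magic bytes."""
    path = Path(path)
    with open(path, "rb") as fh:
        magic = fh.read(4)
    if magic == _MAGIC:
        return _load_binary(path)
    return _load_text(path)


def _load_binary(path: Path) -> CountedKmerDB | KmerSet:
    data = Path(path).read_bytes()
    try:
        if data[:4] != _MAGIC:
            raise FormatError("bad magic")
        version, k, flags = struct.unpack_from("<BBB", data, 4)
        if version != _VERSION:
            raise FormatError(f"unsupported version {version}")
        if not (1 <= k <= MAX_K):
            raise FormatError(f"invalid k={k} in header")
        (label_len,) = struct.unpack_from("<H", data, 7)
        off = 9
        label = data[off : off + label_len].decode("utf-8")
        off += label_len
        (ci,) = struct.unpack_from("<I", data, off)
        off += 4
        (n,) = struct.unpack_from("<Q", data, off)
        off += 8
        nbytes = (k + 3) // 4
        codes = _unpack_codes(data[off : off + n * nbytes], k, n)
        off += n * nbytes
        level = "class" if flags & _FLAG_CLASS else "sample"
        if flags & _FLAG_COUNTED:
            buf = data[off : off + 4 * n]
            if len(buf) != 4 * n:
                raise FormatError("truncated count block")
            counts = np.frombuffer(buf, dtype="<u4")
            return CountedKmerDB(
                k=k, codes=codes, counts=counts.astype(np.int64), label=label, level=level
            )
        prov = Provenance(
            level=level,
            ci=ci if ci > 0 else None,
            host_subtracted=bool(flags & _FLAG_HOST_SUB),
        )
        return KmerSet(k=k, codes=codes, label=label, provenance=prov)
    except struct.error as exc:
        raise FormatError(f"truncated header: {exc}") from exc


def _load_text(path: Path) -> CountedKmerDB | KmerSet:
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if not header.startswith("#k="):
            raise FormatError("missing text header")
        fields = dict(
            item.split("=", 1) for item in header.lstrip("#").split("\t") if "=" in item
        )
        try:
            k = int(fields["k"])
        except (KeyError, ValueError) as exc:
            raise FormatError("bad k in text header") from exc
        level = fields.get("level", "sample")
        label = fields.get("label", "")
        ci = int(fields["ci"]) if "ci" in fields else None
        host_sub = fields.get("host_subtracted") == "1"
        kmers: list[int] = []
        counts: list[int] = []
        counted = None
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts[0]) != k:
                raise FormatError(f"record {parts[0]!r} does not match header k={k}")
            kmers.append(encode_kmer(parts[0]))
            if counted is None:
                counted = len(parts) == 2
            if counted:
                if len(parts) != 2:
                    raise FormatError("mixed counted/uncounted records")
                counts.append(int(parts[1]))
            elif len(parts) != 1:
                raise FormatError("mixed counted/uncounted records")
    codes = np.array(kmers, dtype=np.uint64)
    if counted:
        return CountedKmerDB(
            k=k, codes=codes, counts=np.array(counts, dtype=np.int64), label=label, level=level
        )
    return KmerSet(
        k=k,
        codes=codes,
        label=label,
        provenance=Provenance(level=level, ci=ci, host_subtracted=host_sub),
    )
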