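"""Sample loading, paired-end concatenation, and host-read removal.

Paired-end mates are fused into a single query unit: the forward read, a
single ``'N'`` separator, then the reverse complement of the mate.  The
separator can never occur inside a database k-mer (windows containing 'N'
are dropped at extraction), so no k-mer spans the junction and each pair
yields one score per class.

Host filtering discards any read in which at least one host-genome k-mer
appears; it operates on the concatenated unit, so a host k-mer in either
mate removes the whole pair.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

from Bio import SeqIO

from .kmer_db import KmerSet, extract_kmer_codes

__all__ = [
    "SEPARATOR",
    "InvalidSequenceError",
    "MateMismatchError",
    "ReadPair",
    "QuerySample",
    "reverse_complement",
    "concat_pair",
    "remove_host_reads",
    "load_sample",
    "ManifestRow",
    "load_manifest",
]

SEPARATOR = "N"

_COMPLEMENT = str.maketrans(
    "ACGTUNRYSWKMBDHVacgtunryswkmbdhv",
    "TGCAANYRSWMKVHDBtgcaanyrswmkvhdb",
)
_IUPAC = set("ACGTUNRYSWKMBDHVacgtunryswkmbdhv")


class InvalidSequenceError(ValueError):
    """A sequence contains a symbol outside the IUPAC nucleotide alphabet."""


class MateMismatchError(ValueError):
    """Paired FASTQ/FASTA files have different record counts."""


@dataclass
class ReadPair:
    """One sequencing fragment: forward read and optional reverse mate."""

    id: str
    fwd: str
    rev: str | None = None


@dataclass
class QuerySample:
    """A query sample of concatenated reads R_1..R_q."""

    id: str
    reads: list[str] = field(default_factory=list)

    @property
    def q(self) -> int:
        return len(self.reads)


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement; supports IUPAC ambiguity codes (N->N)."""
    bad = set(seq) - _IUPAC
    if bad:
        raise InvalidSequenceError(f"unknown symbols {sorted(bad)!r} in sequence")
    return seq.translate(_COMPLEMENT)[::-1]


def concat_pair(pair: ReadPair) -> str:
    """Fuse a read pair into one query string: fwd + 'N' + revcomp(rev).

    Single-end pairs are returned unchanged.
    """
    if pair.rev is None:
        return pair.fwd
    return pair.fwd + SEPARATOR + reverse_complement(pair.rev)


def remove_host_reads(sample: QuerySample, host: KmerSet) -> QuerySample:
    """Drop every read in which at least one host k-mer appears.

    Reads shorter than k carry no k-mers and are always retained.  Order of
    the surviving reads is preserved; the operation is idempotent.
    """
    if len(host) == 0:
        return QuerySample(id=sample.id, reads=list(sample.reads))
    kept = []
    for read in sample.reads:
        codes, _ = extract_kmer_codes(read, host.k)
        if codes.size == 0 or not host.contains_codes(codes).any():
            kept.append(read)
    return QuerySample(id=sample.id, reads=kept)


def _open_maybe_gzip(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def _sniff_format(path: str | Path) -> str:
    name = Path(path).name
    if name.endswith(".gz"):
        name = name[:-3]
    if name.endswith((".fq", ".fastq")):
        return "fastq"
    if name.endswith((".fa", ".fasta", ".fna")):
        return "fasta"
    # fall back to content sniffing
    with _open_maybe_gzip(path) as fh:
        first = fh.read(1)
    return "fastq" if first == "@" else "fasta"


def _iter_records(path: str | Path) -> Iterator:
    fmt = _sniff_format(path)
    with _open_maybe_gzip(path) as fh:
        yield from SeqIO.parse(fh, fmt)


def load_sample(
    paths: str | Path | Sequence[str | Path],
    paired: bool = True,
    sample_id: str | None = None,
) -> QuerySample:
    """Load a sample from FASTQ/FASTA files (gzip transparent).

    ``paired=True`` expects two files (R1, R2) with matched record order and
    concatenates each pair; ``paired=False`` expects one file of single-end
    reads.  A record-count mismatch between mates raises
    :class:`MateMismatchError`.
    """
    if isinstance(paths, (str, Path)):
        paths = [paths]
    paths = [Path(p) for p in paths]
    if sample_id is None:
        sample_id = paths[0].name.split(".")[0]
    if paired:
        if len(paths) != 2:
            raise ValueError("paired mode requires exactly two files (R1, R2)")
        reads = []
        it1, it2 = _iter_records(paths[0]), _iter_records(paths[1])
        _sentinel = object()
        while True:
            r1 = next(it1, _sentinel)
            r2 = next(it2, _sentinel)
            if r1 is _sentinel and r2 is _sentinel:
                break
            if r1 is _sentinel or r2 is _sentinel:
                raise MateMismatchError(
                    f"record count mismatch between {paths[0]} and {paths[1]}"
                )
            reads.append(concat_pair(ReadPair(id=r1.id, fwd=str(r1.seq), rev=str(r2.seq))))
        return QuerySample(id=sample_id, reads=reads)
    if len(paths) != 1:
        raise ValueError("single-end mode takes exactly one file")
    reads = [str(rec.seq) for rec in _iter_records(paths[0])]
    return QuerySample(id=sample_id, reads=reads)


@dataclass
class ManifestRow:
    """One row of a sample manifest: label and read file locations."""

    sample_id: str
    class_label: str
    path_R1: Path
    path_R2: Path | None = None

    def load(self) -> QuerySample:
        if self.path_R2 is None:
            return load_sample(self.path_R1, paired=False, sample_id=self.sample_id)
        return load_sample(
            [self.path_R1, self.path_R2], paired=True, sample_id=self.sample_id
        )


def load_manifest(path: str | Path) -> list[ManifestRow]:
    """Read a TSV manifest (sample_id, class_label, path_R1[, path_R2]).

    Relative read-file paths are resolved against the manifest's directory.
    """
    path = Path(path)
    base = path.parent
    rows: list[ManifestRow] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: i for i, name in enumerate(header)}
        for req in ("sample_id", "class_label", "path_R1"):
            if req not in idx:
                raise ValueError(f"manifest is missing required column {req!r}")
        for line in fh:
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            r2 = None
            if "path_R2" in idx and len(parts) > idx["path_R2"] and parts[idx["path_R2"]]:
                r2 = base / parts[idx["path_R2"]]
            rows.append(
                ManifestRow(
                    sample_id=parts[idx["sample_id"]],
                    class_label=parts[idx["class_label"]],
                    path_R1=base / parts[idx["path_R1"]],
                    path_R2=r2,
                )
            )
    return rows
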