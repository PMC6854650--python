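"""Deterministic synthetic multi-class metagenome datasets.

Emulates the structure of a multi-city environmental sequencing collection:
each class (origin) has its own reference genome, a tunable fraction of which
is shared across all classes; samples are sets of paired-end reads drawn
uniformly from their class genome with per-base substitution errors, and an
optional fraction of pairs is drawn from an independent host genome to mimic
host (human) DNA contamination.  Genomes are i.i.d. uniform over ACGT — enough
to exercise every pipeline stage with analyzable k-mer overlap statistics,
without claiming realistic community composition.

A single global seed fixes the full output byte-for-byte; per-sample seeds are
derived by stable hashing of sample ids, so any subset of samples regenerates
identically.
"""

from __future__ import annotations

import gzip
import hashlib
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .read_prep import ReadPair

__all__ = [
    "SimulationConfig",
    "SimulatedPair",
    "generate_class_genomes",
    "generate_sample",
    "generate_dataset",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic dataset generator.

    Defaults describe a small but non-trivial collection: 4 origin classes
    with disjoint 50 kb genomes, 3 samples per class of 2,000 pairs of 100 nt
    reads, 1% per-base substitution errors, and 10% of pairs drawn from a
    50 kb host genome.
    """

    n_classes: int = 4
    samples_per_class: int = 3
    genome_length: int = 50_000
    shared_fraction: float = 0.0
    read_length: int = 100
    insert_gap: int = 50
    pairs_per_sample: int = 2_000
    substitution_rate: float = 0.01
    host_genome_length: int = 50_000
    host_read_fraction: float = 0.1
    seed: int = 0
    k: int = 24  # used only for validation of minimum lengths

    def __post_init__(self) -> None:
        if self.n_classes < 1 or self.samples_per_class < 1 or self.pairs_per_sample < 1:
            raise ValueError("class, sample and pair counts must be >= 1")
        for name in ("genome_length", "read_length", "host_genome_length"):
            if getattr(self, name) < self.k:
                raise ValueError(f"{name} must be >= k={self.k}")
        for name in ("shared_fraction", "substitution_rate", "host_read_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.insert_gap < 0:
            raise ValueError("insert_gap must be >= 0")
        fragment = 2 * self.read_length + self.insert_gap
        if fragment > self.genome_length or fragment > self.host_genome_length:
            raise ValueError("fragment length exceeds genome length")

    @property
    def class_labels(self) -> list[str]:
        return [f"class_{i + 1}" for i in range(self.n_classes)]


@dataclass
class SimulatedPair:
    """One generated read pair plus its ground truth."""

    pair: ReadPair
    from_host: bool


def _rand_seq(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode("ascii")


def _sample_seed(global_seed: int, sample_id: str) -> list[int]:
    h = hashlib.blake2b(sample_id.encode(), digest_size=4).digest()
    return [int(global_seed) & 0x7FFFFFFF, int.from_bytes(h, "big") & 0x7FFFFFFF]


def generate_class_genomes(cfg: SimulationConfig) -> tuple[dict[str, str], str]:
    """Per-class genomes (with a shared prefix segment) and the host genome."""
    rng = np.random.default_rng(np.random.SeedSequence(_sample_seed(cfg.seed, "genomes")))
    shared_len = round(cfg.shared_fraction * cfg.genome_length)
    shared = _rand_seq(rng, shared_len)
    genomes = {
        label: shared + _rand_seq(rng, cfg.genome_length - shared_len)
        for label in cfg.class_labels
    }
    host = _rand_seq(rng, cfg.host_genome_length)
    return genomes, host


_REVCOMP_TABLE = bytes.maketrans(b"ACGT", b"TGCA")


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0.0:
        return seq
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    hit = np.nonzero(rng.random(arr.size) < rate)[0]
    if hit.size:
        # substitute with one of the three other bases
        codes = np.searchsorted(_BASES, arr[hit])
        arr[hit] = _BASES[(codes + rng.integers(1, 4, size=hit.size)) % 4]
    return arr.tobytes().decode("ascii")


def generate_sample(
    class_genome: str,
    host_genome: str,
    cfg: SimulationConfig,
    sample_seed: int | Sequence[int],
    sample_id: str = "sample",
) -> list[SimulatedPair]:
    """Draw error-bearing read pairs from a class genome, with host spike-in.

    Fragments of length 2*read_length + insert_gap are placed uniformly; the
    forward mate is the fragment's 5' end and the reverse mate is reported as
    the reverse complement of its 3' end (FR orientation).  Each pair
    independently originates from the host genome with probability
    ``host_read_fraction``.
    """
    rng = np.random.default_rng(np.random.SeedSequence(sample_seed))
    frag_len = 2 * cfg.read_length + cfg.insert_gap
    out = []
    for i in range(cfg.pairs_per_sample):
        from_host = bool(rng.random() < cfg.host_read_fraction)
        genome = host_genome if from_host else class_genome
        pos = int(rng.integers(0, len(genome) - frag_len + 1))
        fragment = genome[pos : pos + frag_len]
        fwd = _mutate(fragment[: cfg.read_length], cfg.substitution_rate, rng)
        rev_src = fragment[-cfg.read_length :]
        rev = _mutate(
            rev_src.encode("ascii").translate(_REVCOMP_TABLE)[::-1].decode("ascii"),
            cfg.substitution_rate,
            rng,
        )
        out.append(
            SimulatedPair(
                pair=ReadPair(id=f"{sample_id}_r{i + 1}", fwd=fwd, rev=rev),
                from_host=from_host,
            )
        )
    return out


def generate_dataset(
    cfg: SimulationConfig,
    out_dir: str | Path,
    gzip_fastq: bool = False,
) -> Path:
    """Write the full labeled collection: FASTQ pairs, host FASTA, manifest, truth.

    Produces per sample ``<id>_R1.fastq`` / ``<id>_R2.fastq`` (optionally
    gzipped), the host genome as ``host.fasta``, a ``manifest.tsv`` with
    columns sample_id, class_label, path_R1, path_R2, and a ``truth.tsv``
    recording the per-read host flag.  Returns the manifest path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    genomes, host_genome = generate_class_genomes(cfg)
    suffix = ".fastq.gz" if gzip_fastq else ".fastq"
    manifest_rows = []
    truth_rows = []
    for label in cfg.class_labels:
        for s in range(cfg.samples_per_class):
            sid = f"{label}_s{s + 1}"
            pairs = generate_sample(
                genomes[label], host_genome, cfg, _sample_seed(cfg.seed, sid), sample_id=sid
            )
            p1 = out_dir / f"{sid}_R1{suffix}"
            p2 = out_dir / f"{sid}_R2{suffix}"
            _write_fastq(p1, [(sp.pair.id, sp.pair.fwd) for sp in pairs], gzip_fastq)
            _write_fastq(p2, [(sp.pair.id, sp.pair.rev) for sp in pairs], gzip_fastq)
            manifest_rows.append((sid, label, p1.name, p2.name))
            truth_rows.extend(
                (sp.pair.id, sid, label, int(sp.from_host)) for sp in pairs
            )
    with open(out_dir / "host.fasta", "w") as fh:
        fh.write(">host\n")
        for i in range(0, len(host_genome), 80):
            fh.write(host_genome[i : i + 80] + "\n")
    manifest = out_dir / "manifest.tsv"
    with open(manifest, "w") as fh:
        fh.write("sample_id\tclass_label\tpath_R1\tpath_R2\n")
        for row in manifest_rows:
            fh.write("\t".join(row) + "\n")
    with open(out_dir / "truth.tsv", "w") as fh:
        fh.write("read_id\tsample_id\tclass_label\tfrom_host\n")
        for row in truth_rows:
            fh.write("\t".join(str(x) for x in row) + "\n")
    return manifest


def _write_fastq(path: Path, records: Sequence[tuple[str, str]], gz: bool) -> None:
    opener = gzip.open if gz else open
    with opener(path, "wt") as fh:
        for rid, seq in records:
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")
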