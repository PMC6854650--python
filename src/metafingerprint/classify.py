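"""Read-level match-rate scoring and sample classification.

Every read R_i of a query sample is scored against each of the N class
databases.  The match rate score Xi_ij is the percentage of the read's
nucleotides covered by at least one length-k window whose canonical k-mer is
present in class j's database; it therefore lies in [0, 100], with 100 meaning
every base of the read sits under some matching k-mer.

A read contributes points only if gating passes: let A = {j : Xi_ij >= T}.
The read is skipped when A is empty or when |A| > M (too promiscuous to be
informative).  Otherwise points are distributed to the classes in A under one
of three schemes:

* ``simple``     — every class in A gets 1 point;
* ``fractional`` — every class in A gets 1/|A| points;
* ``weighted``   — class j gets Xi_ij / sum over A of Xi_ia points.

Accumulated points are normalized by the total read count q (skipped reads
included) and expressed as percentages; the sample is assigned to the class of
the largest similarity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .kmer_db import IncompatibleDatabaseError, KmerSet, extract_kmer_codes
from .read_prep import QuerySample, SEPARATOR

__all__ = [
    "SKIPPED",
    "UNASSIGNED",
    "EmptySampleError",
    "MatchProfile",
    "ClassifierParams",
    "SimilarityVector",
    "match_rate_score",
    "score_read",
    "matched_classes",
    "accumulate_points",
    "classify_sample",
]

SCHEMES = ("simple", "fractional", "weighted")


class _Sentinel:
    def __init__(self, name: str) -> None:
        self._name = name

    def __repr__(self) -> str:
        return self._name


#: Returned by :func:`matched_classes` when a read is gated out.
SKIPPED = _Sentinel("SKIPPED")
#: Predicted class of a sample whose similarity vector is all zero.
UNASSIGNED = _Sentinel("UNASSIGNED")


class EmptySampleError(ValueError):
    """A query sample with zero reads cannot be classified."""


@dataclass
class MatchProfile:
    """Per-read vector of match-rate scores, one per class (percentages)."""

    read_index: int
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)


@dataclass
class ClassifierParams:
    """Tunable parameters of the classifier.

    ``T`` is the similarity threshold in percent a read must reach against a
    class to be considered matched to it; ``M`` caps how many classes a read
    may be matched to before it is discarded as uninformative (``None`` means
    M = N, i.e. no cap).  Defaults reflect the recommended operating point:
    k=24, ci=4, T=50, M=N, weighted sum, sample-level filtering.
    """

    T: float = 50.0
    M: int | None = None
    scheme: str = "weighted"
    k: int = 24
    ci: int = 4
    filter_mode: str = "sample_level"
    include_ns: bool = False  # count 'N' positions in the score denominator

    def __post_init__(self) -> None:
        if not 0.0 <= self.T <= 100.0:
            raise ValueError(f"T must be in [0, 100], got {self.T}")
        if self.M is not None and self.M < 1:
            raise ValueError(f"M must be >= 1, got {self.M}")
        if self.scheme not in SCHEMES:
            raise ValueError(f"scheme must be one of {SCHEMES}, got {self.scheme!r}")
        if self.filter_mode not in ("sample_level", "class_level"):
            raise ValueError(f"unknown filter_mode {self.filter_mode!r}")
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.ci < 1:
            raise ValueError("ci must be >= 1")

    def effective_M(self, n_classes: int) -> int:
        return n_classes if self.M is None else self.M


@dataclass
class SimilarityVector:
    """Per-class normalized similarity of one sample, with the predicted class."""

    sample_id: str
    class_labels: list[str]
    similarities: np.ndarray
    predicted_class: str | _Sentinel
    tie_flag: bool
    matched_read_count: int

    def __post_init__(self) -> None:
        self.similarities = np.asarray(self.similarities, dtype=float)

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.class_labels, self.similarities.tolist()))


def match_rate_score(read: str, db: KmerSet, include_ns: bool = False) -> float:
    """Match rate score Xi of one read against one class database, in percent.

    Xi = 100 * (number of read positions covered by at least one matching
    k-length window) / L.  L is the number of non-'N' nucleotides in the read
    (the artificial pair separator, and ambiguous calls which can never be
    covered, do not count against the read); ``include_ns=True`` uses the full
    read length instead.  Reads with no valid window score 0.
    """
    k = db.k
    if include_ns:
        L = len(read)
    else:
        L = len(read) - read.upper().count(SEPARATOR)
    if L == 0:
        return 0.0
    codes, starts = extract_kmer_codes(read, k)
    if codes.size == 0:
        return 0.0
    hit_starts = starts[db.contains_codes(codes)]
    if hit_starts.size == 0:
        return 0.0
    return 100.0 * _coverage_from_hits(len(read), hit_starts, k) / L


def _coverage_from_hits(read_len: int, hit_starts: np.ndarray, k: int) -> int:
    # union of covered intervals [s, s+k) via a difference array
    diff = np.zeros(read_len + 1, dtype=np.int64)
    np.add.at(diff, hit_starts, 1)
    np.add.at(diff, hit_starts + k, -1)
    return int(np.count_nonzero(np.cumsum(diff[:-1]) > 0))


def score_read(
    read: str,
    dbs: Sequence[KmerSet],
    read_index: int = 0,
    include_ns: bool = False,
) -> MatchProfile:
    """Score one read against all N class databases, in input order.

    K-mers are extracted once and membership is tested per database.
    """
    ks = {db.k for db in dbs}
    if len(ks) > 1:
        raise IncompatibleDatabaseError(f"mixed k values: {sorted(ks)}")
    k = ks.pop() if ks else 0
    L = len(read) if include_ns else len(read) - read.upper().count(SEPARATOR)
    scores = np.zeros(len(dbs), dtype=float)
    if L > 0 and k > 0:
        codes, starts = extract_kmer_codes(read, k)
        if codes.size:
            for j, db in enumerate(dbs):
                hit_starts = starts[db.contains_codes(codes)]
                if hit_starts.size:
                    scores[j] = 100.0 * _coverage_from_hits(len(read), hit_starts, k) / L
    return MatchProfile(read_index=read_index, scores=scores)


def matched_classes(
    profile: MatchProfile, T: float, M: int
) -> frozenset[int] | _Sentinel:
    """Gate a read: the set A of class indices with score >= T, or SKIPPED.

    A read is skipped when more than M classes pass the threshold (it is not
    specific enough to be informative) or when no class passes at all.  A zero
    score never counts as a match, so at T=0 only classes with some actual
    k-mer overlap enter A.  Returned indices are 0-based positions into the
    profile's score vector.
    """
    idx = np.nonzero((profile.scores >= T) & (profile.scores > 0))[0]
    if idx.size == 0 or idx.size > M:
        return SKIPPED
    return frozenset(int(i) for i in idx)


def accumulate_points(
    profiles: Sequence[MatchProfile], params: ClassifierParams, n_classes: int | None = None
) -> np.ndarray:
    """Accumulate per-class similarity points over all reads of a sample."""
    if n_classes is None:
        if not profiles:
            raise ValueError("cannot infer class count from zero profiles")
        n_classes = len(profiles[0].scores)
    M = params.effective_M(n_classes)
    points = np.zeros(n_classes, dtype=float)
    for prof in profiles:
        if len(prof.scores) != n_classes:
            raise ValueError("profile length does not match class count")
        A = matched_classes(prof, params.T, M)
        if A is SKIPPED:
            continue
        members = sorted(A)
        if params.scheme == "simple":
            for j in members:
                points[j] += 1.0
        elif params.scheme == "fractional":
            share = 1.0 / len(members)
            for j in members:
                points[j] += share
        else:  # weighted
            total = float(sum(prof.scores[j] for j in members))
            for j in members:
                points[j] += float(prof.scores[j]) / total
    return points


def _finalize(
    sample_id: str,
    labels: Sequence[str],
    points: np.ndarray,
    q: int,
    matched_reads: int,
) -> SimilarityVector:
    sims = 100.0 * points / q
    if not np.any(sims > 0):
        return SimilarityVector(
            sample_id=sample_id,
            class_labels=list(labels),
            similarities=sims,
            predicted_class=UNASSIGNED,
            tie_flag=False,
            matched_read_count=matched_reads,
        )
    top = sims.max()
    winners = [labels[j] for j in np.nonzero(sims == top)[0]]
    return SimilarityVector(
        sample_id=sample_id,
        class_labels=list(labels),
        similarities=sims,
        predicted_class=min(winners),
        tie_flag=len(winners) > 1,
        matched_read_count=matched_reads,
    )


def classify_sample(
    sample: QuerySample,
    dbs: Sequence[KmerSet],
    params: ClassifierParams,
    labels: Sequence[str] | None = None,
) -> SimilarityVector:
    """Classify a query sample against N class databases.

    Similarity to class j = 100 * points_j / q, where q counts every read of
    the sample including skipped ones.  The predicted class is the argmax;
    exact ties go to the lexicographically smallest label with ``tie_flag``
    set, and an all-zero vector yields ``UNASSIGNED``.
    """
    if sample.q == 0:
        raise EmptySampleError(f"sample {sample.id!r} has no reads")
    if labels is None:
        labels = [db.label or f"class_{j + 1}" for j, db in enumerate(dbs)]
    n = len(dbs)
    M = params.effective_M(n)
    points = np.zeros(n, dtype=float)
    matched = 0
    for i, read in enumerate(sample.reads):
        prof = score_read(read, dbs, read_index=i, include_ns=params.include_ns)
        A = matched_classes(prof, params.T, M)
        if A is SKIPPED:
            continue
        matched += 1
        points += accumulate_points([prof], params, n_classes=n)
    return _finalize(sample.id, labels, points, sample.q, matched)
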