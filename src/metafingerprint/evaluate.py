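"""Leave-one-out evaluation, confusion matrices, similarity matrices, clustering.

Leave-one-out cross-validation (LOO) holds out one labeled sample at a time,
rebuilds its own class's database from the class's remaining samples (other
class databases are unaffected), classifies the held-out sample, and tallies
the outcome into a confusion matrix.  From the matrix we derive per-class
recall TPR_i = TP_i / n_i, precision PPV_i = TP_i / (TP_i + FP_i), and overall
accuracy ACC = sum_i TP_i / N_s.

For unlabeled collections, each sample can instead be scored against the
single-sample database of every other sample, giving a (generally asymmetric)
mutual-similarity matrix; after row normalization (each row scaled so its
maximum is 100%) groups of mutually similar samples stand out and are
recovered as connected components above a similarity threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .classify import UNASSIGNED, ClassifierParams, classify_sample
from .kmer_db import (
    CountedKmerDB,
    KmerSet,
    Provenance,
    build_counted_db,
    filter_infrequent,
    merge_to_class,
    subtract,
)
from .read_prep import QuerySample, remove_host_reads

__all__ = [
    "EvaluationError",
    "LabeledSample",
    "ConfusionMatrix",
    "Metrics",
    "SimilarityMatrix",
    "build_class_databases",
    "loo_cross_validate",
    "compute_metrics",
    "mutual_similarity_matrix",
    "row_normalize",
    "cluster_samples",
]


class EvaluationError(ValueError):
    """The labeled collection cannot support the requested evaluation."""


@dataclass
class LabeledSample:
    """A query sample with its ground-truth class label."""

    sample: QuerySample
    class_label: str


@dataclass
class ConfusionMatrix:
    """Rows = true class, columns = predicted class; UNASSIGNED kept separate.

    UNASSIGNED predictions are not counted as false positives of any class;
    they appear only in the ``unassigned`` per-true-class vector.
    """

    labels: list[str]
    counts: np.ndarray
    unassigned: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        self.unassigned = np.asarray(self.unassigned, dtype=np.int64)

    @property
    def n_per_class(self) -> np.ndarray:
        """Samples per true class (row sums plus unassigned)."""
        return self.counts.sum(axis=1) + self.unassigned

    @property
    def n_samples(self) -> int:
        return int(self.n_per_class.sum())


@dataclass
class Metrics:
    """Per-class recall/precision and overall accuracy; undefined PPV is NaN."""

    labels: list[str]
    tpr: np.ndarray
    ppv: np.ndarray
    acc: float


@dataclass
class SimilarityMatrix:
    """Square sample-by-sample similarity matrix in percent; diagonal is NaN."""

    sample_ids: list[str]
    values: np.ndarray
    normalized: bool = False
    degenerate_rows: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)


# ---------------------------------------------------------------------------
# database assembly


def _sample_counted_dbs(samples: Sequence[LabeledSample], k: int) -> list[CountedKmerDB]:
    return [
        build_counted_db(ls.sample.reads, k, label=ls.sample.id, level="sample")
        for ls in samples
    ]


def build_class_databases(
    samples: Sequence[LabeledSample],
    params: ClassifierParams,
    host: KmerSet | None = None,
) -> tuple[list[str], list[KmerSet]]:
    """Build one filtered (and optionally host-subtracted) KmerSet per class."""
    labels = sorted({ls.class_label for ls in samples})
    counted = _sample_counted_dbs(samples, params.k)
    dbs = []
    for label in labels:
        members = [db for db, ls in zip(counted, samples) if ls.class_label == label]
        cls_db = merge_to_class(members, params.ci, mode=params.filter_mode, label=label)
        if host is not None:
            cls_db = subtract(cls_db, host)
        dbs.append(cls_db)
    return labels, dbs


def _union_codes(code_arrays: Sequence[np.ndarray]) -> np.ndarray:
    if not code_arrays:
        return np.empty(0, dtype=np.uint64)
    return np.unique(np.concatenate(code_arrays))


def _class_set(k: int, codes: np.ndarray, label: str, ci: int, host: KmerSet | None) -> KmerSet:
    ks = KmerSet(k=k, codes=codes, label=label, provenance=Provenance(level="class", ci=ci))
    return subtract(ks, host) if host is not None else ks


# ---------------------------------------------------------------------------
# leave-one-out


def loo_cross_validate(
    samples: Sequence[LabeledSample],
    params: ClassifierParams,
    host: KmerSet | None = None,
    naive: bool = False,
) -> ConfusionMatrix:
    """Leave-one-out cross-validation over a labeled sample collection.

    For each fold only the held-out sample's own class database is rebuilt
    from that class's remaining samples; the other classes' databases are
    shared across folds.  ``naive=True`` rebuilds every class database from
    scratch each fold instead (slow; used to validate the fast path).  A class
    with a single sample yields an empty own-class database for its fold, so
    that sample can at best be classified elsewhere or left UNASSIGNED.
    """
    labels = sorted({ls.class_label for ls in samples})
    if len(labels) < 2:
        raise EvaluationError("leave-one-out evaluation needs at least 2 classes")
    lab_idx = {c: j for j, c in enumerate(labels)}
    n = len(labels)
    counts = np.zeros((n, n), dtype=np.int64)
    unassigned = np.zeros(n, dtype=np.int64)

    if naive:
        for i, held in enumerate(samples):
            rest = [ls for j, ls in enumerate(samples) if j != i]
            fold_labels, dbs = build_class_databases(rest, params, host=host)
            db_by_label = dict(zip(fold_labels, dbs))
            fold_dbs = [
                db_by_label.get(
                    c, KmerSet(k=params.k, codes=np.empty(0, dtype=np.uint64), label=c)
                )
                for c in labels
            ]
            _tally(held, fold_dbs, labels, lab_idx, params, host, counts, unassigned)
        return ConfusionMatrix(labels=labels, counts=counts, unassigned=unassigned)

    counted = _sample_counted_dbs(samples, params.k)
    if params.filter_mode == "sample_level":
        per_sample = [filter_infrequent(db, params.ci).codes for db in counted]
        class_codes = {
            c: _union_codes(
                [per_sample[i] for i, ls in enumerate(samples) if ls.class_label == c]
            )
            for c in labels
        }
        full_dbs = {
            c: _class_set(params.k, class_codes[c], c, params.ci, host) for c in labels
        }
        for i, held in enumerate(samples):
            c = held.class_label
            rest = [
                per_sample[j]
                for j, ls in enumerate(samples)
                if ls.class_label == c and j != i
            ]
            own = _class_set(params.k, _union_codes(rest), c, params.ci, host)
            fold_dbs = [own if lbl == c else full_dbs[lbl] for lbl in labels]
            _tally(held, fold_dbs, labels, lab_idx, params, host, counts, unassigned)
    else:  # class_level: pooled counts minus the held-out sample, refiltered
        pooled: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for c in labels:
            members = [db for db, ls in zip(counted, samples) if ls.class_label == c]
            all_codes = np.concatenate([m.codes for m in members])
            all_counts = np.concatenate([m.counts for m in members])
            uniq, inv = np.unique(all_codes, return_inverse=True)
            summed = np.zeros(uniq.size, dtype=np.int64)
            np.add.at(summed, inv, all_counts)
            pooled[c] = (uniq, summed)
        full_dbs = {
            c: _class_set(
                params.k, pooled[c][0][pooled[c][1] >= params.ci], c, params.ci, host
            )
            for c in labels
        }
        for i, held in enumerate(samples):
            c = held.class_label
            uniq, summed = pooled[c]
            rem = summed.copy()
            pos = np.searchsorted(uniq, counted[i].codes)
            rem[pos] -= counted[i].counts
            own = _class_set(params.k, uniq[rem >= params.ci], c, params.ci, host)
            fold_dbs = [own if lbl == c else full_dbs[lbl] for lbl in labels]
            _tally(held, fold_dbs, labels, lab_idx, params, host, counts, unassigned)
    return ConfusionMatrix(labels=labels, counts=counts, unassigned=unassigned)


def _tally(
    held: LabeledSample,
    fold_dbs: Sequence[KmerSet],
    labels: Sequence[str],
    lab_idx: Mapping[str, int],
    params: ClassifierParams,
    host: KmerSet | None,
    counts: np.ndarray,
    unassigned: np.ndarray,
) -> None:
    query = held.sample
    if host is not None:
        query = remove_host_reads(query, host)
    row = lab_idx[held.class_label]
    if query.q == 0:
        unassigned[row] += 1
        return
    sv = classify_sample(query, fold_dbs, params, labels=list(labels))
    if sv.predicted_class is UNASSIGNED:
        unassigned[row] += 1
    else:
        counts[row, lab_idx[sv.predicted_class]] += 1


# ---------------------------------------------------------------------------
# metrics


def compute_metrics(cm: ConfusionMatrix) -> Metrics:
    """Recall, precision and accuracy from a confusion matrix.

    PPV of a class with zero predictions (TP + FP == 0) is undefined and
    reported as NaN.
    """
    n_s = cm.n_samples
    if n_s < 1:
        raise EvaluationError("empty confusion matrix")
    tp = np.diag(cm.counts).astype(float)
    n_i = cm.n_per_class.astype(float)
    col = cm.counts.sum(axis=0).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        tpr = np.where(n_i > 0, tp / n_i, np.nan)
        ppv = np.where(col > 0, tp / col, np.nan)
    acc = float(tp.sum() / n_s)
    return Metrics(labels=list(cm.labels), tpr=tpr, ppv=ppv, acc=acc)


# ---------------------------------------------------------------------------
# mutual similarity and clustering


def mutual_similarity_matrix(
    samples: Sequence[QuerySample],
    params: ClassifierParams,
    host: KmerSet | None = None,
) -> SimilarityMatrix:
    """Pairwise similarity of samples to each other's single-sample databases.

    Cell (r, c) holds the similarity of sample r classified against the
    database built from sample c alone (ci-filtered, host-subtracted).  The
    matrix is generally asymmetric; the diagonal (self-comparison) is NaN.
    """
    if len(samples) < 2:
        raise EvaluationError("mutual similarity needs at least 2 samples")
    ids = [s.id for s in samples]
    dbs = []
    for s in samples:
        db = filter_infrequent(build_counted_db(s.reads, params.k, label=s.id), params.ci)
        if host is not None:
            db = subtract(db, host)
        dbs.append(db)
    queries = [remove_host_reads(s, host) if host is not None else s for s in samples]
    n = len(samples)
    values = np.full((n, n), np.nan)
    for r in range(n):
        if queries[r].q == 0:
            values[r, [c for c in range(n) if c != r]] = 0.0
            continue
        for c in range(n):
            if c == r:
                continue
            sv = classify_sample(queries[r], [dbs[c]], params, labels=[ids[c]])
            values[r, c] = float(sv.similarities[0])
    return SimilarityMatrix(sample_ids=ids, values=values, normalized=False)


def row_normalize(m: SimilarityMatrix) -> SimilarityMatrix:
    """Scale each row so its maximum defined cell equals 100%.

    Rows with no positive defined cell are left unchanged and flagged in
    ``degenerate_rows``.  Idempotent on already-normalized matrices.
    """
    values = m.values.copy()
    degenerate = []
    for r in range(values.shape[0]):
        row = values[r]
        finite = row[np.isfinite(row)]
        if finite.size == 0 or finite.max() <= 0:
            degenerate.append(m.sample_ids[r])
            continue
        values[r] = row / finite.max() * 100.0
    return SimilarityMatrix(
        sample_ids=list(m.sample_ids),
        values=values,
        normalized=True,
        degenerate_rows=degenerate,
    )


def cluster_samples(m: SimilarityMatrix, threshold: float) -> list[list[str]]:
    """Partition samples into connected components of the similarity graph.

    Samples r and c are joined when max(value[r,c], value[c,r]) >= threshold
    (asymmetry is resolved optimistically).  Returns the partition as lists of
    sample ids, each sorted, ordered by first member; singletons allowed.
    """
    n = len(m.sample_ids)
    sym = np.fmax(m.values, m.values.T)  # fmax ignores NaN where possible
    adj = np.zeros((n, n), dtype=bool)
    with np.errstate(invalid="ignore"):
        adj[np.nan_to_num(sym, nan=-np.inf) >= threshold] = True
    np.fill_diagonal(adj, False)
    n_comp, comp = connected_components(csr_matrix(adj), directed=False)
    clusters: dict[int, list[str]] = {}
    for sid, c in zip(m.sample_ids, comp):
        clusters.setdefault(int(c), []).append(sid)
    parts = [sorted(v) for v in clusters.values()]
    return sorted(parts, key=lambda p: p[0])
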