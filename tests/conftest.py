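import numpy as np
import pytest

from metafingerprint.classify import MatchProfile

# --- brute-force oracles, independent of the package internals ---------------

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def oracle_revcomp(s: str) -> str:
    return "".join(_COMP[c] for c in reversed(s))


def oracle_canonical(s: str) -> str:
    return min(s, oracle_revcomp(s))


def oracle_extract(seq: str, k: int) -> list[str]:
    """Window scan: canonical k-mer per all-ACGT window, in position order."""
    seq = seq.upper()
    out = []
    for i in range(len(seq) - k + 1):
        w = seq[i : i + k]
        if all(c in "ACGT" for c in w):
            out.append(oracle_canonical(w))
    return out


def oracle_match_rate(read: str, members: set[str], k: int, include_ns: bool = False) -> float:
    """Position-coverage oracle: mark every position under a matching window."""
    read_u = read.upper()
    covered = [False] * len(read_u)
    for i in range(len(read_u) - k + 1):
        w = read_u[i : i + k]
        if all(c in "ACGT" for c in w) and oracle_canonical(w) in members:
            for p in range(i, i + k):
                covered[p] = True
    L = len(read_u) if include_ns else sum(1 for c in read_u if c != "N")
    return 100.0 * sum(covered) / L if L else 0.0


# --- shared fixtures ----------------------------------------------------------


@pytest.fixture
def worked_example_profiles() -> list[MatchProfile]:
    """The three illustrative per-read score lists over N=6 classes."""
    rows = [
        [30, 80, 85, 50, 90, 35],
        [20, 90, 0, 49, 0, 30],
        [20, 88, 90, 0, 0, 50],
    ]
    return [MatchProfile(read_index=i, scores=np.array(r, float)) for i, r in enumerate(rows)]
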