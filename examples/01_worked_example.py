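"""Gating and the three point-accumulation schemes on a hand-sized example.

Three reads scored against N=6 class databases; T=50, M=3.  Shows which reads
survive gating and how each scheme distributes credit.
"""

import numpy as np

from metafingerprint import ClassifierParams, MatchProfile, SKIPPED, accumulate_points, matched_classes

rows = [
    [30, 80, 85, 50, 90, 35],  # matches 4 classes at T=50 -> too promiscuous
    [20, 90, 0, 49, 0, 30],    # matches class 2 only
    [20, 88, 90, 0, 0, 50],    # matches classes 2, 3, 6
]
profiles = [MatchProfile(i, np.array(r, float)) for i, r in enumerate(rows)]

for p in profiles:
    A = matched_classes(p, T=50, M=3)
    label = "skipped" if A is SKIPPED else f"matched to classes {sorted(j + 1 for j in A)}"
    print(f"read {p.read_index + 1}: {label}")

q = len(profiles)
for scheme in ("simple", "fractional", "weighted"):
    pts = accumulate_points(profiles, ClassifierParams(T=50, M=3, scheme=scheme))
    sims = 100.0 * pts / q
    print(f"{scheme:>10}: points={np.round(pts, 2)}  similarity%={np.round(sims, 2)}")

print("\nThe sample is assigned to class 2 under every scheme (largest similarity).")
print("A read's credit always sums to 1 for fractional/weighted, so similarities")
print("sum to 100 x (matched reads)/q.")
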