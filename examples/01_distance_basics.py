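"""Distances between symptom profiles and standardized ratios.

Two respondents can both meet criteria for a major depressive episode while
endorsing very different symptoms. The package quantifies that disagreement
with the Hamming distance on binary (present/absent) profiles and the
Manhattan distance on ordinal severity profiles, each standardized to [0, 1]
by its maximum attainable value.
"""

import numpy as np

from symptomdist import (
    DistanceSpec,
    euclidean_distance,
    hamming_distance,
    manhattan_distance,
    standardized_ratio,
)

# Binary profiles over 16 symptom items: 1 = present, 0 = absent.
alice = np.array([1, 1, 0, 0, 1, 0, 0, 1, 0, 1, 1, 0, 1, 0, 0, 0])
bob   = np.array([1, 0, 1, 0, 1, 1, 0, 1, 0, 0, 1, 0, 1, 0, 1, 0])

d = hamming_distance(alice, bob)
spec = DistanceSpec("hamming", k=16)
print(f"Hamming distance:      {d} of a possible {spec.max_distance:.0f}")
print(f"Standardized ratio:    {standardized_ratio(d, spec):.4f}")

# Ordinal severity profiles (0-3 per item). Two items differ by the full
# range of 3; the remaining items agree.
x = np.array([3, 3, 0, 2, 1, 0])
y = np.array([0, 0, 0, 2, 1, 0])
spec_m = DistanceSpec("manhattan", k=6, v=3)
dm = manhattan_distance(x, y)
print(f"\nManhattan distance:    {dm} of a possible {spec_m.max_distance:.0f}")
print(f"Standardized ratio:    {standardized_ratio(dm, spec_m):.4f}")
print(f"Euclidean distance:    {euclidean_distance(x, y):.4f} "
      "(for comparison; emphasizes large per-item gaps)")

# On binary data the Manhattan and Hamming distances coincide.
assert manhattan_distance(alice, bob) == hamming_distance(alice, bob)
print("\nOn binary profiles Manhattan and Hamming distances are identical.")
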