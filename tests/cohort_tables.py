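"""Published cohort tables used as reference inputs by several suites."""

import numpy as np

# Per-participant medians of pairwise R^2 (rows = participants P1..P7,
# columns = speed, COPx, COPy).
COHORT_MEDIANS = np.array(
    [
        [0.307, 0.334, 0.141],
        [0.469, 0.226, 0.170],
        [0.463, 0.273, 0.013],
        [0.437, 0.287, 0.063],
        [0.499, 0.425, 0.235],
        [0.497, 0.406, 0.205],
        [0.490, 0.109, 0.194],
    ]
)

# Ranks of the medians within each column (rank 1 = smallest).
COHORT_RANKS = np.array(
    [
        [1, 5, 3],
        [4, 2, 4],
        [3, 3, 1],
        [2, 4, 2],
        [7, 7, 7],
        [6, 6, 6],
        [5, 1, 5],
    ]
)
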