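"""Published reference values from the original mouse cohort analysis.

The source study reports, for its real 72-mouse cohort, the 3-D PCA-space
coordinates of the six group centroids and the resulting pairwise Euclidean
distance matrix (to 2 decimals).  These printed values are treated as
*inputs* here -- the real cohort itself is not redistributed -- and drive
the centroid-distance and brain-age stages exactly as published.
"""

from __future__ import annotations

from typing import Dict, Tuple

#: Group centroid coordinates (x, y, z) in PCA space, as published.
REFERENCE_CENTROIDS: Dict[str, Tuple[float, float, float]] = {
    "6C": (-290.4239343, -351.278, 278.2895),
    "6RW": (-258.3819842, -188.679, 131.1928),
    "18C": (-480.2993301, -500.791, 166.7696),
    "18RW": (-439.3514277, -214.311, 326.1029),
    "24C": (-636.4445877, -261.612, 322.952),
    "24RW": (-221.3199115, -384.299, 412.169),
}

#: Published pairwise centroid distances (2 decimals), same group order as
#: REFERENCE_CENTROIDS.
REFERENCE_DISTANCES: Dict[str, Dict[str, float]] = {
    "6C":   {"6C": 0.00, "6RW": 221.59, "18C": 266.16, "18RW": 207.91, "24C": 360.23, "24RW": 154.24},
    "6RW":  {"6C": 221.59, "6RW": 0.00, "18C": 384.61, "18RW": 267.20, "24C": 430.14, "24RW": 344.37},
    "18C":  {"6C": 266.16, "6RW": 384.61, "18C": 0.00, "18RW": 330.36, "24C": 325.55, "24RW": 375.32},
    "18RW": {"6C": 207.91, "6RW": 267.20, "18C": 330.36, "18RW": 0.00, "24C": 202.71, "24RW": 289.55},
    "24C":  {"6C": 360.23, "6RW": 430.14, "18C": 325.55, "18RW": 202.71, "24C": 0.00, "24RW": 441.97},
    "24RW": {"6C": 154.24, "6RW": 344.37, "18C": 375.32, "18RW": 289.55, "24C": 441.97, "24RW": 0.00},
}
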