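"""Published remapping-frequency counts from the tilted shuttle-box study.

The recordings behind the study are not deposited, but its contingency
tables and activation counts are printed and serve as fixed inputs for
validating the count statistics in :mod:`slopecell.remapping`.

* :func:`elevation_half_counts` — remapping calls for 0-degree-active
  place cells between the flat and tilted conditions, split by whether
  the cell's main field sat in the top (most-elevated) or bottom half of
  the track.
* :func:`within_between_counts` — remapping calls across first-10/
  second-10 trial splits within a tilt condition versus across changes
  of tilt condition.
* ``ACTIVATION_COUNTS`` — number of place-cell-by-condition activations
  on downhill versus uphill runs.
"""

from __future__ import annotations

import numpy as np

from .remapping import REMAP_TYPES, ContingencyTable

__all__ = [
    "elevation_half_counts", "within_between_counts", "ACTIVATION_COUNTS",
    "pool_remap_vs_stable", "pool_complex_rate_stable",
]

_ELEVATION_HALF = {
    #            top  bottom
    "inactive":    (44, 45),
    "turn_on":     (17, 24),
    "turn_off":    (24, 11),
    "field_remap": (3, 2),
    "rate_remap":  (4, 7),
    "stable":      (6, 11),
}

_WITHIN_BETWEEN = {
    #            within between
    "inactive":    (379, 228),
    "turn_on":     (36, 60),
    "turn_off":    (55, 45),
    "field_remap": (4, 4),
    "rate_remap":  (13, 10),
    "stable":      (107, 49),
}

# place-cell-by-condition activations: downhill 125, uphill 87
ACTIVATION_COUNTS = {"downhill": 125, "uphill": 87}


def elevation_half_counts() -> ContingencyTable:
    counts = np.array([_ELEVATION_HALF[t] for t in REMAP_TYPES])
    return ContingencyTable(list(REMAP_TYPES), ["top", "bottom"], counts)


def within_between_counts() -> ContingencyTable:
    counts = np.array([_WITHIN_BETWEEN[t] for t in REMAP_TYPES])
    return ContingencyTable(list(REMAP_TYPES), ["within", "between"], counts)


def pool_remap_vs_stable(table: ContingencyTable) -> ContingencyTable:
    """Drop inactive, pool all remap types against stable (2 x k)."""
    return table.drop_row("inactive").pool_rows(
        {
            "remap": ["turn_on", "turn_off", "field_remap", "rate_remap"],
            "stable": ["stable"],
        }
    )


def pool_complex_rate_stable(table: ContingencyTable) -> ContingencyTable:
    """Drop inactive, pool complex remapping (on/off/field) vs rate vs stable."""
    return table.drop_row("inactive").pool_rows(
        {
            "complex": ["turn_on", "turn_off", "field_remap"],
            "rate_remap": ["rate_remap"],
            "stable": ["stable"],
        }
    )
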