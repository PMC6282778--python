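"""Remapping classification, shuffle-null correlations, and count statistics.

Across a pair of tilt conditions (shallower -> steeper, same slope
direction) a unit receives exactly one of six mutually exclusive calls:

* ``inactive``    — place-cell criteria met on neither condition,
* ``turn_on``     — criteria met only on the steeper tilt,
* ``turn_off``    — criteria met only on the shallower tilt,
* ``field_remap`` — active on both, 1D field peaks >= 20 cm apart,
* ``rate_remap``  — active on both, peaks < 20 cm apart, per-trial firing
  rates differ (two-sided Wilcoxon rank-sum, p < 0.05),
* ``stable``      — active on both, neither of the above.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "REMAP_TYPES", "RemapCall", "ContingencyTable", "CorrelationResult",
    "classify_remapping", "spatial_correlation", "shuffle_null",
    "sequence_matrix", "assign_half", "elevation_half_table",
    "chi_square_independence", "chi_square_gof", "wilcoxon_rank_sum",
    "FIELD_REMAP_SEPARATION_CM",
]

REMAP_TYPES = ("inactive", "turn_on", "turn_off", "field_remap", "rate_remap", "stable")
FIELD_REMAP_SEPARATION_CM = 20.0
RATE_REMAP_ALPHA = 0.05
MIN_COMMON_NONZERO_BINS = 3


@dataclass
class RemapCall:
    unit_id: str
    direction: str
    tilt_pair: tuple[int, int]       # (shallower, steeper)
    call: str
    peak_separation_cm: float        # NaN unless both conditions active
    rank_sum_p: float                # NaN unless the Wilcoxon stage ran


@dataclass
class ContingencyTable:
    row_labels: list[str]
    col_labels: list[str]
    counts: np.ndarray               # non-negative ints, rows x cols

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if (self.counts < 0).any():
            raise ValueError("contingency counts must be non-negative")

    def drop_row(self, label: str) -> "ContingencyTable":
        keep = [i for i, lab in enumerate(self.row_labels) if lab != label]
        return ContingencyTable(
            [self.row_labels[i] for i in keep], list(self.col_labels), self.counts[keep]
        )

    def pool_rows(self, groups: dict[str, list[str]]) -> "ContingencyTable":
        """Sum labelled rows into named groups (order of ``groups`` kept)."""
        idx = {lab: i for i, lab in enumerate(self.row_labels)}
        rows = [
            self.counts[[idx[lab] for lab in members]].sum(axis=0)
            for members in groups.values()
        ]
        return ContingencyTable(list(groups), list(self.col_labels), np.array(rows))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.row_labels, columns=self.col_labels)


@dataclass
class CorrelationResult:
    unit_id: str
    direction: str
    tilt_pair: tuple[int, int]
    r: float
    n_common_bins: int
    null_mean_r: float | None = None
    n_shuffles: int = 0
    seed: int | None = None
    skipped: bool = False
    skip_reason: str | None = None


def classify_remapping(
    unit_id: str,
    direction: str,
    tilt_pair: tuple[int, int],
    active_shallow: bool,
    active_steep: bool,
    peak_cm_shallow: float | None,
    peak_cm_steep: float | None,
    trial_rates_shallow: np.ndarray,
    trial_rates_steep: np.ndarray,
    alpha: float = RATE_REMAP_ALPHA,
    separation_cm: float = FIELD_REMAP_SEPARATION_CM,
) -> RemapCall:
    """One exhaustive, mutually exclusive call per (unit, condition pair).

    Peak locations are 1D place-field-map peaks in absolute cm; the
    boundary case (separation exactly 20 cm) counts as field remapping.
    """
    if not active_shallow and not active_steep:
        return RemapCall(unit_id, direction, tilt_pair, "inactive", float("nan"), float("nan"))
    if active_steep and not active_shallow:
        return RemapCall(unit_id, direction, tilt_pair, "turn_on", float("nan"), float("nan"))
    if active_shallow and not active_steep:
        return RemapCall(unit_id, direction, tilt_pair, "turn_off", float("nan"), float("nan"))
    sep = abs(float(peak_cm_steep) - float(peak_cm_shallow))
    if sep >= separation_cm:
        return RemapCall(unit_id, direction, tilt_pair, "field_remap", sep, float("nan"))
    _, p = wilcoxon_rank_sum(trial_rates_shallow, trial_rates_steep)
    call = "rate_remap" if p < alpha else "stable"
    return RemapCall(unit_id, direction, tilt_pair, call, sep, float(p))


# ---------------------------------------------------------------------------
# spatial correlations and the shuffle null


def spatial_correlation(
    unit_id: str,
    direction: str,
    tilt_pair: tuple[int, int],
    rate_a: np.ndarray,
    rate_b: np.ndarray,
    common_mask: np.ndarray,
) -> CorrelationResult:
    """Pearson r between two conditions' rates over common-occupied bins.

    ``common_mask`` marks bins occupied on *all three* tilts of the slope
    direction.  The pair is skipped unless each map has at least three
    non-zero common bins.
    """
    a = np.nan_to_num(rate_a)[common_mask]
    b = np.nan_to_num(rate_b)[common_mask]
    n = int(a.size)
    if (np.count_nonzero(a) < MIN_COMMON_NONZERO_BINS
            or np.count_nonzero(b) < MIN_COMMON_NONZERO_BINS):
        return CorrelationResult(unit_id, direction, tilt_pair, float("nan"), n,
                                 skipped=True, skip_reason="fewer than 3 common non-zero bins")
    if np.std(a) == 0 or np.std(b) == 0:
        return CorrelationResult(unit_id, direction, tilt_pair, float("nan"), n,
                                 skipped=True, skip_reason="zero variance")
    r = float(np.corrcoef(a, b)[0, 1])
    return CorrelationResult(unit_id, direction, tilt_pair, r, n)


def shuffle_null(
    rate_a: np.ndarray,
    rate_b: np.ndarray,
    common_mask: np.ndarray,
    n_shuffles: int = 10_000,
    rng: np.random.Generator | int | None = None,
) -> tuple[float, np.ndarray]:
    """Mean correlation under random permutation of one map's bin rates.

    Only the second map's rates are permuted over the common bins
    (permuting both is equivalent in distribution).  Returns the mean
    null r and the full vector of shuffle correlations.
    """
    rng = np.random.default_rng(rng)
    a = np.nan_to_num(rate_a)[common_mask].astype(float)
    b = np.nan_to_num(rate_b)[common_mask].astype(float)
    n = a.size
    a_std = (a - a.mean())
    sa = np.sqrt((a_std**2).sum())
    perms = np.argsort(rng.random((n_shuffles, n)), axis=1)
    B = b[perms]
    B_std = B - B.mean(axis=1, keepdims=True)
    sb = np.sqrt((B_std**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        rs = (B_std @ a_std) / (sa * sb)
    rs = rs[np.isfinite(rs)]
    return float(rs.mean()), rs


# ---------------------------------------------------------------------------
# sequence matrices and the elevation-half analysis


def sequence_matrix(
    vectors: dict[str, np.ndarray],
    baseline_peak_bin: dict[str, int],
) -> tuple[np.ndarray, list[str]]:
    """Stack per-cell 1D rate vectors ordered by baseline field position.

    Rows are min-max normalized to [0, 1]; callers normalize uphill and
    downhill ensembles separately by passing them separately.
    """
    from .ratemaps import normalize01

    order = sorted(vectors, key=lambda u: (baseline_peak_bin[u], u))
    mat = np.vstack([normalize01(np.nan_to_num(vectors[u])) for u in order])
    return mat, order


def assign_half(peak_cm: float, roi_mid_cm: float, elevated_end: str) -> str:
    """Top/bottom assignment of a 0-degree field peak; midpoint ties go bottom."""
    if peak_cm == roi_mid_cm:
        return "bottom"
    nearer_north = peak_cm > roi_mid_cm
    return "top" if nearer_north == (elevated_end == "north") else "bottom"


def elevation_half_table(
    calls: list[RemapCall],
    half_by_unit_direction: dict[tuple[str, str], str],
) -> ContingencyTable:
    """Tabulate remap calls for 0 -> tilted pairs by field half (top/bottom).

    ``half_by_unit_direction`` maps (unit, direction) -> "top"/"bottom"
    for units active on the flat condition; calls for units without an
    assignment are ignored.
    """
    counts = np.zeros((len(REMAP_TYPES), 2), dtype=int)
    for call in calls:
        if call.tilt_pair[0] != 0:
            continue
        half = half_by_unit_direction.get((call.unit_id, call.direction))
        if half is None:
            continue
        counts[REMAP_TYPES.index(call.call), 0 if half == "top" else 1] += 1
    return ContingencyTable(list(REMAP_TYPES), ["top", "bottom"], counts)


# ---------------------------------------------------------------------------
# count statistics


def chi_square_independence(table: ContingencyTable) -> tuple[float, int, float]:
    """Pearson chi-squared test of independence (no continuity correction)."""
    counts = table.counts
    if counts.shape[0] < 2 or counts.shape[1] < 2:
        raise ValueError("independence test needs at least 2 rows and 2 columns")
    row_sums = counts.sum(axis=1)
    col_sums = counts.sum(axis=0)
    if (row_sums == 0).any():
        lab = table.row_labels[int(np.argmin(row_sums))]
        raise ValueError(f"row {lab!r} has zero margin")
    if (col_sums == 0).any():
        lab = table.col_labels[int(np.argmin(col_sums))]
        raise ValueError(f"column {lab!r} has zero margin")
    stat, p, df, _ = stats.chi2_contingency(counts, correction=False)
    return float(stat), int(df), float(p)


def chi_square_gof(
    observed: np.ndarray, expected_proportions: np.ndarray | None = None
) -> tuple[float, int, float]:
    """Pearson goodness-of-fit; expected proportions default to equal."""
    obs = np.asarray(observed, dtype=float)
    total = obs.sum()
    if not total > 0:
        raise ValueError("observed counts sum to zero")
    if expected_proportions is None:
        props = np.full(obs.size, 1.0 / obs.size)
    else:
        props = np.asarray(expected_proportions, dtype=float)
        if not np.isclose(props.sum(), 1.0):
            raise ValueError("expected proportions must sum to 1")
    if (props <= 0).any():
        raise ValueError("expected proportions must be positive")
    stat, p = stats.chisquare(obs, f_exp=total * props)
    return float(stat), int(obs.size - 1), float(p)


def wilcoxon_rank_sum(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum with midrank ties.

    Exact p when the combined sample is small (n <= 20) and tie-free;
    normal approximation with tie correction otherwise.  The statistic is
    the rank sum of the first sample.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    combined = np.concatenate([a, b])
    has_ties = np.unique(combined).size < combined.size
    method = "exact" if (combined.size <= 20 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    w = float(res.statistic + a.size * (a.size + 1) / 2.0)
    return w, float(res.pvalue)
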