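"""Spatial information, sparsity, coherence, and the place-cell criteria.

All metrics are computed on the *unsmoothed* rate map.  A unit counts as
a place cell on a condition when it fired >= 100 ROI spikes, its ROI mean
rate is >= 0.1 Hz, its spatial information is >= 1 bit/spike, and its
spatial coherence (Fisher z) exceeds 0.5.

Spatial information (bits/spike):  I = sum_i p_i (l_i / L) log2(l_i / L)
Sparsity:                          S = (sum_i p_i l_i)^2 / sum_i p_i l_i^2

with p_i the occupancy probability of bin i, l_i its firing rate and
L = sum_i p_i l_i the overall mean rate.  Zero-rate bins contribute zero
to the information sum (x log x -> 0).  Coherence is the Fisher
z-transform of the Pearson correlation, over visited bins, between a
bin's rate and the mean rate of its visited 8-neighbors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .geometry import Condition
from .ratemaps import PlaceField, RateMap, field_mask

__all__ = [
    "MIN_SPIKES", "MIN_MEAN_RATE_HZ", "MIN_INFORMATION", "MIN_COHERENCE_Z",
    "CellConditionMetrics", "spatial_information", "sparsity",
    "spatial_coherence", "evaluate_place_cell",
]

MIN_SPIKES = 100
MIN_MEAN_RATE_HZ = 0.1
MIN_INFORMATION = 1.0
MIN_COHERENCE_Z = 0.5

_EIGHT = np.ones((3, 3))


def spatial_information(ratemap: RateMap) -> float:
    """Skaggs information in bits/spike; NaN when the cell never fired."""
    p = ratemap.occupancy.p[ratemap.visited]
    lam_i = np.nan_to_num(ratemap.rate[ratemap.visited])
    lam = float(np.sum(p * lam_i))
    if not lam > 0 or p.size < 2:
        return float("nan")
    ratio = lam_i / lam
    pos = ratio > 0
    return float(np.sum(p[pos] * ratio[pos] * np.log2(ratio[pos])))


def sparsity(ratemap: RateMap) -> float:
    """Skaggs sparsity in (0, 1]; 1 = uniform firing, NaN when silent."""
    p = ratemap.occupancy.p[ratemap.visited]
    lam_i = np.nan_to_num(ratemap.rate[ratemap.visited])
    num = float(np.sum(p * lam_i)) ** 2
    den = float(np.sum(p * lam_i**2))
    if not den > 0:
        return float("nan")
    return num / den


def spatial_coherence(ratemap: RateMap) -> float:
    """Fisher-z of the first-order spatial autocorrelation of the map.

    Each visited bin's rate is correlated with the mean rate of its
    visited 8-neighbors; bins without any visited neighbor are excluded.
    NaN when either vector has zero variance or fewer than 8 bins enter.
    """
    v = ratemap.visited
    filled = np.where(v, np.nan_to_num(ratemap.rate), 0.0)
    nbr_sum = ndimage.convolve(filled, _EIGHT, mode="constant", cval=0.0) - filled
    nbr_cnt = ndimage.convolve(v.astype(float), _EIGHT, mode="constant", cval=0.0) - v
    sel = v & (nbr_cnt > 0)
    if np.count_nonzero(sel) < 8:
        return float("nan")
    a = filled[sel]
    b = nbr_sum[sel] / nbr_cnt[sel]
    if np.std(a) == 0 or np.std(b) == 0:
        return float("nan")
    r = float(np.corrcoef(a, b)[0, 1])
    r = min(max(r, -0.999999999), 0.999999999)
    return float(np.arctanh(r))


@dataclass
class CellConditionMetrics:
    unit_id: str
    condition: Condition
    n_spikes: int              # ROI spikes within included trials
    mean_rate: float           # ROI spikes / summed included-trial time (Hz)
    peak_rate: float           # highest unsmoothed bin rate (Hz)
    information: float         # bits/spike (NaN when silent)
    sparsity: float
    coherence_z: float
    n_fields: int
    total_field_coverage: float  # field bins / visited bins
    main_field_coverage: float
    main_field_aspect: float
    infield_rate: float        # mean unsmoothed rate over field bins (Hz)
    outfield_rate: float       # mean over visited non-field bins (Hz)
    is_place_cell: bool


def evaluate_place_cell(unit_id: str, condition: Condition, ratemap: RateMap,
                        fields: list[PlaceField]) -> CellConditionMetrics:
    """Full metric battery for one unit on one condition.

    ``ratemap`` must be the unsmoothed map; ``fields`` come from the
    smoothed map.  The mean rate for the 0.1 Hz criterion is ROI spike
    count divided by summed included-trial time, matching the trial-based
    rate definition.
    """
    occ = ratemap.occupancy
    n_spikes = ratemap.n_spikes_roi
    mean_rate = n_spikes / occ.total_trial_time if occ.total_trial_time > 0 else 0.0
    info = spatial_information(ratemap)
    spars = sparsity(ratemap)
    coh = spatial_coherence(ratemap)

    v = ratemap.visited
    n_visited = int(np.count_nonzero(v))
    fmask = field_mask(fields, ratemap.rate.shape)
    main = next((f for f in fields if f.is_main), None)
    rates = np.nan_to_num(ratemap.rate)
    infield = float(rates[fmask & v].mean()) if (fmask & v).any() else float("nan")
    out_sel = v & ~fmask
    outfield = float(rates[out_sel].mean()) if out_sel.any() else float("nan")

    is_pc = (
        n_spikes >= MIN_SPIKES
        and mean_rate >= MIN_MEAN_RATE_HZ
        and np.isfinite(info) and info >= MIN_INFORMATION
        and np.isfinite(coh) and coh > MIN_COHERENCE_Z
    )
    return CellConditionMetrics(
        unit_id=unit_id,
        condition=condition,
        n_spikes=n_spikes,
        mean_rate=float(mean_rate),
        peak_rate=ratemap.peak_rate,
        information=info,
        sparsity=spars,
        coherence_z=coh,
        n_fields=len(fields),
        total_field_coverage=float(fmask.sum() / n_visited) if n_visited else 0.0,
        main_field_coverage=float(main.size / n_visited) if main and n_visited else 0.0,
        main_field_aspect=main.aspect_ratio if main else float("nan"),
        infield_rate=infield,
        outfield_rate=outfield,
        is_place_cell=bool(is_pc),
    )
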