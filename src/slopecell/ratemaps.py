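"""Occupancy and firing-rate maps, place-field detection, 1D collapse.

Maps live on the fine grid from :class:`~slopecell.geometry.TrackGeometry`
(nominal 2.5 cm squares over the running ROI; rows = short axis, cols =
long axis).  Bins visited for less than 100 ms are treated as unvisited.
Field detection runs on a Gaussian-smoothed copy of the map (sigma = one
bin); all scalar metrics are computed elsewhere on the unsmoothed map.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .behavior import Trial
from .geometry import TrackGeometry

__all__ = [
    "OccupancyMap",
    "RateMap",
    "PlaceField",
    "CoarseField",
    "build_occupancy_map",
    "build_rate_map",
    "smooth_rate_map",
    "detect_fields",
    "field_mask",
    "place_field_map_1d",
    "collapse_to_1d",
    "normalize01",
    "detect_fields_coarse",
]

MIN_DWELL_S = 0.1
FIELD_THRESHOLD_FRAC = 0.15
MIN_QUALIFYING_NEIGHBORS = 7
_EIGHT = np.ones((3, 3), dtype=int)


@dataclass
class OccupancyMap:
    dwell: np.ndarray          # seconds per bin, zeros where unvisited
    visited: np.ndarray        # bool mask: dwell >= 100 ms
    geometry: TrackGeometry
    total_trial_time: float    # summed duration of the included trials

    @property
    def p(self) -> np.ndarray:
        """Occupancy probability over visited bins (sums to 1)."""
        d = np.where(self.visited, self.dwell, 0.0)
        total = d.sum()
        return d / total if total > 0 else d

    @property
    def analyzable(self) -> bool:
        return bool(self.visited.any())


@dataclass
class RateMap:
    rate: np.ndarray           # Hz; NaN where unvisited
    occupancy: OccupancyMap
    n_spikes_in_map: int       # spikes landing in visited bins
    n_spikes_roi: int          # all ROI spikes in included trials (incl. removed bins)

    @property
    def visited(self) -> np.ndarray:
        return self.occupancy.visited

    @property
    def mean_rate(self) -> float:
        """Occupancy-weighted mean rate over visited bins."""
        return float(np.nansum(self.occupancy.p * np.nan_to_num(self.rate)))

    @property
    def peak_rate(self) -> float:
        return float(np.nanmax(self.rate)) if self.occupancy.analyzable else 0.0


@dataclass
class PlaceField:
    mask: np.ndarray
    size: int
    length_bins: int
    width_bins: int
    peak_rc: tuple[int, int]
    peak_rate: float
    is_main: bool = False

    @property
    def aspect_ratio(self) -> float:
        return self.length_bins / self.width_bins


def _sample_dt(t: np.ndarray) -> np.ndarray:
    """Duration attributed to each position sample (interval to the next)."""
    if t.size < 2:
        return np.zeros_like(t)
    dt = np.diff(t)
    return np.append(dt, np.median(dt))


def _in_trials(t: np.ndarray, trials: list[Trial]) -> np.ndarray:
    mask = np.zeros(t.size, dtype=bool)
    for tr in trials:
        mask |= (t >= tr.t_start) & (t < tr.t_end)
    return mask


def build_occupancy_map(t: np.ndarray, x: np.ndarray, y: np.ndarray,
                        trials: list[Trial], geometry: TrackGeometry) -> OccupancyMap:
    """Accumulate per-bin dwell time over the included trials, ROI only."""
    included = [tr for tr in trials if tr.included]
    dwell = np.zeros((geometry.n_bins_short, geometry.n_bins_long))
    total = float(sum(tr.duration for tr in included))
    if included and t.size:
        sel = _in_trials(t, included) & geometry.in_roi(x)
        if sel.any():
            dt = _sample_dt(t)[sel]
            row, col = geometry.bin_indices(x[sel], y[sel])
            np.add.at(dwell, (row, col), dt)
    visited = dwell >= MIN_DWELL_S
    return OccupancyMap(dwell=dwell, visited=visited, geometry=geometry,
                        total_trial_time=total)


def build_rate_map(spike_times: np.ndarray, t: np.ndarray, x: np.ndarray,
                   y: np.ndarray, trials: list[Trial],
                   occupancy: OccupancyMap) -> RateMap:
    """Element-wise spike-count / dwell on visited bins.

    Spike positions are linearly interpolated from the tracking stream.
    Spikes in sub-100 ms bins are dropped from the map but still counted
    in ``n_spikes_roi`` (the basis of the 100-spike criterion).
    """
    g = occupancy.geometry
    included = [tr for tr in trials if tr.included]
    rate = np.full_like(occupancy.dwell, np.nan)
    rate[occupancy.visited] = 0.0
    if not included or spike_times.size == 0 or t.size == 0:
        return RateMap(rate=rate, occupancy=occupancy, n_spikes_in_map=0, n_spikes_roi=0)
    sx = np.interp(spike_times, t, x)
    sy = np.interp(spike_times, t, y)
    sel = _in_trials(spike_times, included) & g.in_roi(sx)
    n_roi = int(np.count_nonzero(sel))
    counts = np.zeros_like(occupancy.dwell)
    if n_roi:
        row, col = g.bin_indices(sx[sel], sy[sel])
        np.add.at(counts, (row, col), 1.0)
    v = occupancy.visited
    rate[v] = counts[v] / occupancy.dwell[v]
    return RateMap(rate=rate, occupancy=occupancy,
                   n_spikes_in_map=int(counts[v].sum()), n_spikes_roi=n_roi)


def smooth_rate_map(ratemap: RateMap, sigma_bins: float = 1.0) -> RateMap:
    """Gaussian smoothing (sigma = one bin, truncated at 3 sigma).

    Unvisited bins are excluded from the kernel and the remaining weights
    renormalized, so edges and occupancy holes do not deflate rates.
    """
    v = ratemap.visited
    filled = np.where(v, np.nan_to_num(ratemap.rate), 0.0)
    kw = dict(sigma=sigma_bins, mode="constant", cval=0.0, truncate=3.0)
    num = ndimage.gaussian_filter(filled, **kw)
    den = ndimage.gaussian_filter(v.astype(float), **kw)
    sm = np.full_like(filled, np.nan)
    ok = v & (den > 0)
    sm[ok] = num[ok] / den[ok]
    return RateMap(rate=sm, occupancy=ratemap.occupancy,
                   n_spikes_in_map=ratemap.n_spikes_in_map,
                   n_spikes_roi=ratemap.n_spikes_roi)


def detect_fields(smoothed: RateMap,
                  threshold_frac: float = FIELD_THRESHOLD_FRAC,
                  min_neighbors: int = MIN_QUALIFYING_NEIGHBORS) -> list[PlaceField]:
    """Place fields: connected bins >= 15% of peak with 7+ qualifying neighbors.

    A bin survives when it meets the rate threshold and at least 7 of its
    8 neighbors do too (so edge bins, with at most 5 neighbors, never
    survive).  Surviving bins are grouped by 8-connectivity; the largest
    component is flagged as the main field.
    """
    if not smoothed.occupancy.analyzable:
        return []
    peak = smoothed.peak_rate
    if not peak > 0:
        return []
    qualify = smoothed.visited & (np.nan_to_num(smoothed.rate) >= threshold_frac * peak)
    nbrs = ndimage.convolve(qualify.astype(int), _EIGHT, mode="constant", cval=0)
    nbrs -= qualify.astype(int)  # the kernel counts the bin itself
    keep = qualify & (nbrs >= min_neighbors)
    labels, n = ndimage.label(keep, structure=_EIGHT)
    fields: list[PlaceField] = []
    for lab in range(1, n + 1):
        mask = labels == lab
        rows, cols = np.nonzero(mask)
        rates = np.where(mask, np.nan_to_num(smoothed.rate), -np.inf)
        pr, pc = np.unravel_index(np.argmax(rates), rates.shape)
        fields.append(
            PlaceField(
                mask=mask,
                size=int(mask.sum()),
                length_bins=int(cols.max() - cols.min() + 1),
                width_bins=int(rows.max() - rows.min() + 1),
                peak_rc=(int(pr), int(pc)),
                peak_rate=float(rates[pr, pc]),
            )
        )
    fields.sort(key=lambda f: (f.size, f.peak_rate), reverse=True)
    if fields:
        fields[0].is_main = True
    return fields


def field_mask(fields: list[PlaceField], shape: tuple[int, int]) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    for f in fields:
        mask |= f.mask
    return mask


def collapse_to_1d(rate: np.ndarray) -> np.ndarray:
    """Collapse the short axis by averaging visited bins in each column."""
    finite = np.isfinite(rate)
    counts = finite.sum(axis=0)
    sums = np.where(finite, rate, 0.0).sum(axis=0)
    with np.errstate(invalid="ignore"):
        return np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)


def normalize01(v: np.ndarray) -> np.ndarray:
    """Min-max normalize (used only for sequence plots)."""
    lo = np.nanmin(v)
    hi = np.nanmax(v)
    if not np.isfinite(hi - lo) or hi == lo:
        return np.zeros_like(v)
    return (v - lo) / (hi - lo)


def place_field_map_1d(smoothed: RateMap, fields: list[PlaceField]) -> np.ndarray:
    """1D place-field map: the longitudinal profile of field activity.

    Per long-axis column, the mean smoothed rate over field-member bins;
    columns outside every field are NaN.  The argmax of this vector is
    the 1D field peak used for remapping.
    """
    masked = np.where(field_mask(fields, smoothed.rate.shape),
                      np.nan_to_num(smoothed.rate), np.nan)
    return collapse_to_1d(masked)


# ---------------------------------------------------------------------------
# coarse field detection (phase precession)


@dataclass
class CoarseField:
    mask: np.ndarray           # (4, 20) bool
    col_min: int
    col_max: int
    size: int
    geometry: TrackGeometry

    @property
    def long_extent_cm(self) -> tuple[float, float]:
        """Absolute long-axis extent [entry edge, exit edge] of the field."""
        return (self.geometry.coarse_col_edge_cm(self.col_min),
                self.geometry.coarse_col_edge_cm(self.col_max + 1))

    def entry_exit_cm(self, direction_sign: int) -> tuple[float, float]:
        lo, hi = self.long_extent_cm
        return (lo, hi) if direction_sign > 0 else (hi, lo)


COARSE_MIN_DWELL_S = 0.5


def detect_fields_coarse(spike_times: np.ndarray, t: np.ndarray, x: np.ndarray,
                         y: np.ndarray, trials: list[Trial],
                         geometry: TrackGeometry,
                         min_neighbors: int = 2,
                         min_dwell_s: float = COARSE_MIN_DWELL_S) -> CoarseField | None:
    """Largest above-average firing cluster on the 4 x 20 grid over the ROI.

    Bins must fire above the map mean (over visited coarse bins) and have
    at least two 8-neighbors that also do; the largest surviving cluster
    is the phase-precession field.  Returns None when nothing qualifies.

    Coarse bins are ~13 cm^2, so the visited threshold is stricter than
    the fine grid's 100 ms: a bin needs ``min_dwell_s`` (default 0.5 s)
    of dwell before its rate estimate enters the mean or the clustering;
    shorter visits yield single-spike rates that inflate the cluster.
    """
    included = [tr for tr in trials if tr.included]
    if not included or t.size == 0:
        return None
    n_rows, n_cols = geometry.coarse_shape
    dwell = np.zeros((n_rows, n_cols))
    sel = _in_trials(t, included) & geometry.in_roi(x)
    if not sel.any():
        return None
    dt = _sample_dt(t)[sel]
    row, col = geometry.coarse_bin_indices(x[sel], y[sel])
    np.add.at(dwell, (row, col), dt)
    visited = dwell >= min_dwell_s
    if not visited.any():
        return None

    counts = np.zeros_like(dwell)
    if spike_times.size:
        sx = np.interp(spike_times, t, x)
        sy = np.interp(spike_times, t, y)
        ssel = _in_trials(spike_times, included) & geometry.in_roi(sx)
        if ssel.any():
            r, c = geometry.coarse_bin_indices(sx[ssel], sy[ssel])
            np.add.at(counts, (r, c), 1.0)
    rate = np.zeros_like(dwell)
    rate[visited] = counts[visited] / dwell[visited]
    mean_rate = rate[visited].mean()
    if not mean_rate > 0:
        return None
    qualify = visited & (rate > mean_rate)
    nbrs = ndimage.convolve(qualify.astype(int), _EIGHT, mode="constant", cval=0)
    nbrs -= qualify.astype(int)
    keep = qualify & (nbrs >= min_neighbors)
    labels, n = ndimage.label(keep, structure=_EIGHT)
    if n == 0:
        return None
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    lab = int(np.argmax(sizes)) + 1
    mask = labels == lab
    cols = np.nonzero(mask)[1]
    return CoarseField(mask=mask, col_min=int(cols.min()), col_max=int(cols.max()),
                       size=int(mask.sum()), geometry=geometry)
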