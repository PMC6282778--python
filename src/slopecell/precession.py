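"""Theta phase extraction and circular-linear phase-precession fits.

The LFP is band-pass filtered to the 7-9 Hz theta band (4th-order
Butterworth, forward-backward so the passband is zero-phase) and the
Hilbert transform yields instantaneous phase and amplitude envelope.
Phase is referenced so that 0 degrees falls at the trough of the
filtered signal.

In-field spikes from passes in the analysis direction, fired while the
theta envelope is above its mean, are mapped to (normalized field
position u in [0, 1], phase).  The precession slope a (degrees per field
traverse) maximizes the mean resultant length

    R(a) = | (1/n) sum_j exp(i (phi_j - a u_j)) |

over |a| <= 720 (two theta cycles per traverse), with the phase offset
phi0 the circular mean of phi_j - a u_j, and the circular-linear
correlation and p-value following Kempter et al.'s estimator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, signal, stats

from .behavior import Trial
from .circstats import circmean_deg
from .ratemaps import CoarseField

__all__ = [
    "ThetaPhaseSeries", "PrecessionFit", "theta_phase_series",
    "assign_spike_phases", "circular_linear_fit",
    "MIN_FIELD_SPIKES", "SLOPE_BOUND_DEG",
]

THETA_BAND_HZ = (7.0, 9.0)
MIN_FIELD_SPIKES = 50
SLOPE_BOUND_DEG = 720.0


@dataclass
class ThetaPhaseSeries:
    t: np.ndarray
    filtered: np.ndarray       # band-passed LFP (uV)
    phase_deg: np.ndarray      # [0, 360), 0 = filtered-signal trough
    envelope: np.ndarray       # analytic-signal magnitude (uV)
    fs_hz: float

    @property
    def mean_envelope(self) -> float:
        return float(self.envelope.mean())

    def phase_at(self, times: np.ndarray) -> np.ndarray:
        """Phase at arbitrary times by interpolating the unwrapped phase."""
        unwrapped = np.unwrap(np.deg2rad(self.phase_deg))
        return np.rad2deg(np.interp(times, self.t, unwrapped)) % 360.0

    def envelope_at(self, times: np.ndarray) -> np.ndarray:
        return np.interp(times, self.t, self.envelope)


@dataclass
class PrecessionFit:
    unit_id: str
    tilt: int
    n_spikes: int
    slope_deg_per_field: float
    phi0_deg: float
    rho: float
    p: float
    bounded: bool
    degenerate: bool = False

    @property
    def significant(self) -> bool:
        return np.isfinite(self.p) and self.p < 0.05


def theta_phase_series(t: np.ndarray, lfp_uv: np.ndarray, fs_hz: float,
                       band_hz: tuple[float, float] = THETA_BAND_HZ) -> ThetaPhaseSeries:
    """Band-pass the LFP and extract trough-referenced phase and envelope."""
    if t.size / fs_hz < 5.0:
        raise ValueError("LFP must be at least 5 s long for stable filtering")
    sos = signal.butter(4, band_hz, btype="bandpass", fs=fs_hz, output="sos")
    filt = signal.sosfiltfilt(sos, lfp_uv)
    analytic = signal.hilbert(filt)
    # analytic angle is 0 at the filtered-signal *peak*; shift 180 deg so
    # 0 lands on the trough in the negative portion
    phase = (np.rad2deg(np.angle(analytic)) + 180.0) % 360.0
    return ThetaPhaseSeries(t=t, filtered=filt, phase_deg=phase,
                            envelope=np.abs(analytic), fs_hz=fs_hz)


def assign_spike_phases(
    spike_times: np.ndarray,
    t_pos: np.ndarray,
    x: np.ndarray,
    theta: ThetaPhaseSeries,
    field: CoarseField,
    trials: list[Trial],
    envelope_threshold: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Map qualifying in-field spikes to (normalized position, phase).

    Spikes qualify when they fall inside an included trial of the
    analysis direction, inside the field's long-axis extent, and the
    theta envelope at spike time exceeds ``envelope_threshold``.
    Normalized position is 0 at the field edge first crossed (entry) and
    1 at the exit edge.
    """
    included = [tr for tr in trials if tr.included]
    if not included or spike_times.size == 0:
        return np.empty(0), np.empty(0)
    mask = np.zeros(spike_times.size, dtype=bool)
    for tr in included:
        in_tr = (spike_times >= tr.t_start) & (spike_times < tr.t_end)
        mask |= in_tr
    sx = np.interp(spike_times, t_pos, x)
    lo, hi = field.long_extent_cm
    mask &= (sx >= lo) & (sx <= hi)
    mask &= theta.envelope_at(spike_times) > envelope_threshold
    if not mask.any():
        return np.empty(0), np.empty(0)

    # travel direction sign per trial (x increasing or decreasing)
    u = np.full(spike_times.size, np.nan)
    for tr in included:
        x0 = float(np.interp(tr.t_start, t_pos, x))
        x1 = float(np.interp(tr.t_end, t_pos, x))
        entry, exit_ = (lo, hi) if x1 > x0 else (hi, lo)
        in_tr = mask & (spike_times >= tr.t_start) & (spike_times < tr.t_end)
        u[in_tr] = (sx[in_tr] - entry) / (exit_ - entry)
    ok = mask & np.isfinite(u)
    phases = theta.phase_at(spike_times[ok])
    return np.clip(u[ok], 0.0, 1.0), phases


def _resultant(a: np.ndarray, u: np.ndarray, phi_rad: np.ndarray) -> np.ndarray:
    """Mean resultant length R(a) for slope candidates ``a`` (deg/traverse)."""
    a = np.atleast_1d(np.asarray(a, dtype=float))
    z = np.exp(1j * (phi_rad[None, :] - np.deg2rad(a)[:, None] * u[None, :]))
    return np.abs(z.mean(axis=1))


def circular_linear_fit(
    u: np.ndarray,
    phase_deg: np.ndarray,
    unit_id: str = "",
    tilt: int = 0,
    slope_bound: float = SLOPE_BOUND_DEG,
    grid_step: float = 1.0,
) -> PrecessionFit:
    """Fit phase = phi0 + a * u on the circle.

    The slope maximizes R(a) on a 1 deg/traverse grid over [-720, 720]
    with local refinement; estimates pinned at the bound are flagged
    ``bounded``.  rho is the circular-circular correlation between the
    spike phases and the fitted phase (a u mod 360) with Kempter et al.'s
    normal-approximation p-value.
    """
    u = np.asarray(u, dtype=float)
    phi = np.deg2rad(np.asarray(phase_deg, dtype=float))
    n = u.size
    if np.allclose(phase_deg, phase_deg[0]):
        return PrecessionFit(unit_id, tilt, n, float("nan"), float(phase_deg[0]),
                             float("nan"), float("nan"), bounded=False, degenerate=True)

    grid = np.arange(-slope_bound, slope_bound + grid_step, grid_step)
    R = _resultant(grid, u, phi)
    best = int(np.argmax(R))
    lo = max(grid[best] - grid_step, -slope_bound)
    hi = min(grid[best] + grid_step, slope_bound)
    res = optimize.minimize_scalar(
        lambda a: -_resultant(a, u, phi)[0], bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-4},
    )
    a_hat = float(res.x)
    # prefer the exact bound when the optimum sits against it
    bounded = False
    for edge in (-slope_bound, slope_bound):
        if abs(a_hat - edge) <= grid_step and _resultant(edge, u, phi)[0] >= -res.fun - 1e-12:
            a_hat, bounded = edge, True

    phi0 = circmean_deg(np.rad2deg(phi) - a_hat * u)
    rho, p = _kempter_corr(u, phi, a_hat)
    return PrecessionFit(unit_id, tilt, n, a_hat, phi0, rho, p, bounded=bounded)


def _kempter_corr(u: np.ndarray, phi_rad: np.ndarray, a_deg: float) -> tuple[float, float]:
    """Circular-circular correlation between phases and the fitted ramp."""
    theta = np.deg2rad(a_deg) * u % (2 * np.pi)
    phi_bar = np.angle(np.exp(1j * phi_rad).mean())
    theta_bar = np.angle(np.exp(1j * theta).mean())
    sp = np.sin(phi_rad - phi_bar)
    st = np.sin(theta - theta_bar)
    den = np.sqrt((sp**2).sum() * (st**2).sum())
    if den == 0:
        return float("nan"), float("nan")
    rho = float((sp * st).sum() / den)
    n = u.size
    lam20 = (sp**2).mean()
    lam02 = (st**2).mean()
    lam22 = (sp**2 * st**2).mean()
    if lam22 <= 0:
        return rho, float("nan")
    z = rho * np.sqrt(n * lam20 * lam02 / lam22)
    p = 2.0 * stats.norm.sf(abs(z))
    return rho, float(p)
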