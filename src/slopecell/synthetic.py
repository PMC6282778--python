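"""Ground-truthed synthetic shuttle-box sessions.

The generator emulates the statistical structure the analysis assumes:
alternating end-to-end runs on a tiltable 120 x 24 cm box (constant
speed across the ROI, raised-cosine acceleration inside the endzones,
3 s reward dwells), theta-modulated Poisson place cells with Gaussian
spatial tuning and programmed condition-wise remapping, programmed
phase precession, and a sinusoid-plus-noise theta LFP.

Spikes are generated per theta cycle: each cycle contributes a Poisson
number of candidate spikes whose phases are von Mises-distributed around
the programmed phase ramp phi(x) = phi0 + slope * u(x) (u = normalized
position within the field span), and candidates are thinned by the
Gaussian spatial envelope evaluated at the actual candidate time.  This
keeps both the time-marginal rate equal to the programmed lambda(x) and,
at zero phase noise, spike phases exactly on the programmed ramp.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .geometry import DOWNHILL, NORTH, SOUTH, TILTS, UPHILL, Condition, TrackGeometry
from .session_io import ConditionBlock, Lfp, Session

__all__ = [
    "Tuning", "PrecessionSpec", "UnitSpec", "ScenarioConfig", "Run",
    "GroundTruth", "generate_trajectory", "generate_unit_spikes",
    "generate_session", "stable_ensemble", "remap_recovery_ensemble",
    "mixed_ensemble", "aligned_precession_unit", "remap_label",
    "STUDY_SPEEDS_CMS",
]

# mean running speeds (cm/s) by tilt x slope direction, as reported for
# the shuttle-box study
STUDY_SPEEDS_CMS: dict[tuple[int, str], float] = {
    (0, UPHILL): 32.7, (0, DOWNHILL): 33.4,
    (15, UPHILL): 33.4, (15, DOWNHILL): 31.5,
    (25, UPHILL): 30.0, (25, DOWNHILL): 26.6,
}


@dataclass(frozen=True)
class Tuning:
    """Gaussian spatial tuning on one condition (absolute cm, Hz)."""

    center_cm: float
    sigma_cm: float
    peak_hz: float

    def __post_init__(self) -> None:
        if self.sigma_cm <= 0:
            raise ValueError("sigma must be positive")
        if self.peak_hz < 0:
            raise ValueError("peak rate must be non-negative")


@dataclass(frozen=True)
class PrecessionSpec:
    """Programmed phase ramp across the field span.

    ``slope_deg_per_field`` is degrees of phase advance per full field
    traverse (negative = precession); ``kappa`` is the von Mises
    concentration of spike phases around the ramp (``inf`` = no noise).
    ``span_cm`` is the absolute (low, high) extent of the ramp; when
    omitted it defaults to center +/- 2 sigma of the condition's tuning.
    """

    phi0_deg: float = 180.0
    slope_deg_per_field: float = -360.0
    kappa: float = 4.0
    span_cm: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if abs(self.slope_deg_per_field) > 720.0 + 180.0:
            # programmed ramps a bit past the fit bound are allowed (the
            # analysis clips them), but wildly larger ones are a config bug
            raise ValueError("|slope| above 900 deg/field is not supported")


@dataclass(frozen=True)
class UnitSpec:
    """One synthetic unit: per-condition tuning plus baseline and precession."""

    unit_id: str
    tuning: dict[Condition, Tuning]
    baseline_hz: float = 0.3
    precession: PrecessionSpec | None = None

    def __post_init__(self) -> None:
        if self.baseline_hz < 0:
            raise ValueError("baseline must be non-negative")
        for tun in self.tuning.values():
            if tun is not None and tun.peak_hz < self.baseline_hz:
                raise ValueError("peak must be at least baseline")


@dataclass(frozen=True)
class ScenarioConfig:
    laps: int = 20
    tilts: tuple[int, ...] = TILTS
    elevated_end: str = NORTH
    speeds_cms: dict[tuple[int, str], float] = field(
        default_factory=lambda: dict(STUDY_SPEEDS_CMS)
    )
    speed_cv: float = 0.06
    dwell_s: float = 3.0
    position_fs_hz: float = 50.0
    theta_hz: float = 8.0
    lfp_fs_hz: float = 250.0
    lfp_amplitude_uv: float = 100.0
    lfp_noise_sd_uv: float = 20.0
    y_jitter_sd_cm: float = 3.0
    n_incomplete_per_block: int = 0
    n_slow_per_block: int = 0
    geometry: TrackGeometry = field(default_factory=TrackGeometry)

    def __post_init__(self) -> None:
        if self.laps < 1:
            raise ValueError("laps must be >= 1")
        if not 7.0 <= self.theta_hz <= 9.0:
            raise ValueError("theta frequency must lie in the 7-9 Hz band")

    def speed(self, tilt: int, direction: str) -> float:
        return self.speeds_cms.get((tilt, direction), 33.0)


@dataclass(frozen=True)
class Run:
    """One excursion out of an endzone (complete, slow, or incomplete)."""

    t_start: float
    t_end: float
    block_id: int
    tilt: int
    direction: str
    sign: int                # +1 travelling toward increasing x
    speed_cms: float
    kind: str = "normal"     # normal | slow | incomplete

    @property
    def condition(self) -> Condition:
        return Condition(self.tilt, self.direction)


@dataclass
class Trajectory:
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    blocks: list[ConditionBlock]
    runs: list[Run]


@dataclass
class GroundTruth:
    units: list[UnitSpec]
    runs: list[Run]
    remap_labels: dict[tuple[str, str, tuple[int, int]], str]
    config: ScenarioConfig


def remap_label(a: Tuning | None, b: Tuning | None,
                separation_cm: float = 20.0) -> str:
    """True remap type implied by a (shallower, steeper) tuning pair."""
    if a is None and b is None:
        return "inactive"
    if a is None:
        return "turn_on"
    if b is None:
        return "turn_off"
    if abs(b.center_cm - a.center_cm) >= separation_cm:
        return "field_remap"
    if not math.isclose(a.peak_hz, b.peak_hz):
        return "rate_remap"
    return "stable"


# ---------------------------------------------------------------------------
# trajectory


def _run_profile(v: float, d_end: float, roi_cm: float, fs: float) -> np.ndarray:
    """Distance-from-start samples for one run at constant ROI speed ``v``.

    Raised-cosine speed ramps cover the ``d_end`` centimetres between the
    reward well and the ROI boundary at each end, so the ROI crossing
    takes exactly ``roi_cm / v`` seconds.
    """
    tau = 2.0 * d_end / v
    t_const = roi_cm / v
    total = 2 * tau + t_const
    t = np.arange(1, int(total * fs) + 1) / fs
    s = np.empty_like(t)
    ramp = t < tau
    s[ramp] = 0.5 * v * (t[ramp] - (tau / np.pi) * np.sin(np.pi * t[ramp] / tau))
    mid = (~ramp) & (t < tau + t_const)
    s[mid] = d_end + v * (t[mid] - tau)
    dec = t >= tau + t_const
    td = np.minimum(t[dec] - tau - t_const, tau)
    s[dec] = d_end + roi_cm + 0.5 * v * (td + (tau / np.pi) * np.sin(np.pi * td / tau))
    return np.minimum(s, 2 * d_end + roi_cm)


def generate_trajectory(config: ScenarioConfig,
                        rng: np.random.Generator | int | None = None) -> Trajectory:
    """Shuttle-run position series for the configured condition schedule."""
    rng = np.random.default_rng(rng)
    g = config.geometry
    fs = config.position_fs_hz
    dt = 1.0 / fs
    well_offset = g.endzone_south_cm / 2.0      # reward well mid-endzone
    x_south = well_offset
    x_north = g.long_axis_cm - well_offset
    d_end = g.roi_start_cm - x_south            # ramp distance inside endzone

    xs: list[np.ndarray] = []
    runs: list[Run] = []
    blocks: list[ConditionBlock] = []
    n_total = 0
    ground = g.ground_end(config.elevated_end)
    at_south = ground == SOUTH                  # start at the ground end
    for block_id, tilt in enumerate(config.tilts):
        n_block_start = n_total
        n_runs = 2 * config.laps
        slow_idx = set(rng.choice(n_runs, size=min(config.n_slow_per_block, n_runs),
                                  replace=False).tolist()) if config.n_slow_per_block else set()
        incomplete_after = set(
            rng.choice(n_runs, size=min(config.n_incomplete_per_block, n_runs),
                       replace=False).tolist()) if config.n_incomplete_per_block else set()
        for i_run in range(n_runs):
            # reward dwell before each run
            dwell_n = int((config.dwell_s + rng.uniform(-0.5, 0.5)) * fs)
            x_here = x_south if at_south else x_north
            xs.append(x_here + rng.normal(0.0, 0.15, dwell_n).clip(-2, 2))
            n_total += dwell_n

            departing_ground = at_south == (ground == SOUTH)
            direction = UPHILL if departing_ground else DOWNHILL
            sign = 1 if at_south else -1

            if i_run in incomplete_after:
                # failed shuttle: run to mid-track and return, then dwell
                v = config.speed(tilt, direction)
                prof = _run_profile(v, d_end, (g.roi_long_cm / 2.0) - d_end, fs)
                out = x_here + sign * prof
                xs.append(np.concatenate([out, out[::-1]]))
                n_run = 2 * prof.size
                runs.append(Run((n_total) * dt, (n_total + n_run) * dt, block_id,
                                tilt, direction, sign, v, kind="incomplete"))
                n_total += n_run
                dwell_n = int(config.dwell_s * fs)
                xs.append(x_here + rng.normal(0.0, 0.15, dwell_n).clip(-2, 2))
                n_total += dwell_n

            mean_v = config.speed(tilt, direction)
            v = 12.0 if i_run in slow_idx else max(
                mean_v * (1.0 + config.speed_cv * rng.standard_normal()), 0.75 * mean_v
            )
            prof = _run_profile(v, d_end, g.roi_long_cm, fs)
            xs.append(x_here + sign * prof)
            runs.append(Run(n_total * dt, (n_total + prof.size) * dt, block_id,
                            tilt, direction, sign, v,
                            kind="slow" if i_run in slow_idx else "normal"))
            n_total += prof.size
            at_south = not at_south
        blocks.append(ConditionBlock(block_id=block_id, tilt=tilt,
                                     elevated_end=config.elevated_end,
                                     t_start=n_block_start * dt,
                                     t_end=n_total * dt))

    x = np.clip(np.concatenate(xs), 0.0, g.long_axis_cm)
    t = np.arange(x.size) * dt
    noise = gaussian_filter1d(rng.standard_normal(x.size), sigma=0.4 * fs)
    sd = noise.std()
    y = g.short_axis_cm / 2.0 + noise * (config.y_jitter_sd_cm / sd if sd > 0 else 0.0)
    y = np.clip(y, 0.5, g.short_axis_cm - 0.5)
    return Trajectory(t=t, x=x, y=y, blocks=blocks, runs=runs)


# ---------------------------------------------------------------------------
# spikes


def _phase_ramp(x: np.ndarray, spec: PrecessionSpec, span: tuple[float, float],
                sign: int) -> np.ndarray:
    lo, hi = span
    entry, exit_ = (lo, hi) if sign > 0 else (hi, lo)
    u = np.clip((x - entry) / (exit_ - entry), 0.0, 1.0)
    return spec.phi0_deg + spec.slope_deg_per_field * u


def generate_unit_spikes(traj: Trajectory, unit: UnitSpec, config: ScenarioConfig,
                         rng: np.random.Generator | int | None = None) -> np.ndarray:
    """Spike times for one unit across the whole trajectory."""
    rng = np.random.default_rng(rng)
    t, x = traj.t, traj.x
    f = config.theta_hz
    out: list[np.ndarray] = []

    t_end = float(t[-1])
    n_base = rng.poisson(unit.baseline_hz * t_end)
    if n_base:
        out.append(rng.uniform(0.0, t_end, n_base))

    for run in traj.runs:
        tun = unit.tuning.get(run.condition)
        if tun is None or tun.peak_hz <= 0:
            continue
        field_rate = tun.peak_hz - unit.baseline_hz
        if field_rate <= 0:
            continue
        k0 = int(np.ceil(run.t_start * f))
        k1 = int(np.floor(run.t_end * f))
        if k1 <= k0:
            continue
        cycles = np.arange(k0, k1) / f
        counts = rng.poisson(field_rate / f, size=cycles.size)
        if counts.sum() == 0:
            continue
        c_rep = np.repeat(cycles, counts)
        m = c_rep.size

        spec = unit.precession or PrecessionSpec(
            phi0_deg=float(rng.uniform(0, 360)), slope_deg_per_field=0.0, kappa=0.0
        )
        span = spec.span_cm or (tun.center_cm - 2 * tun.sigma_cm,
                                tun.center_cm + 2 * tun.sigma_cm)
        if np.isinf(spec.kappa):
            noise_deg = np.zeros(m)
        elif spec.kappa <= 0:
            noise_deg = rng.uniform(0.0, 360.0, m)
        else:
            noise_deg = np.rad2deg(rng.vonmises(0.0, spec.kappa, m))

        # solve theta(t) = phi(x(t)) + noise within each cycle: wrap-aware
        # fixed point t <- t + centered_phase_gap / omega, contraction for
        # ramps shallower than one cycle per theta period of travel
        ts = c_rep + 0.5 / f
        for _ in range(100):
            xx = np.interp(ts, t, x)
            target = _phase_ramp(xx, spec, span, run.sign) + noise_deg
            gap = (target - 360.0 * f * (ts - c_rep) + 180.0) % 360.0 - 180.0
            step = gap / (360.0 * f)
            ts = ts + step
            if np.max(np.abs(step)) < 1e-12:
                break

        xx = np.interp(ts, t, x)
        accept = rng.random(m) < np.exp(-((xx - tun.center_cm) ** 2)
                                        / (2.0 * tun.sigma_cm**2))
        accept &= (ts >= run.t_start) & (ts < run.t_end)
        if accept.any():
            out.append(ts[accept])

    if not out:
        return np.empty(0)
    spikes = np.sort(np.concatenate(out))
    return np.unique(spikes)


# ---------------------------------------------------------------------------
# sessions


def generate_session(config: ScenarioConfig, units: list[UnitSpec],
                     seed: int | np.random.SeedSequence = 0,
                     with_lfp: bool = True) -> tuple[Session, GroundTruth]:
    """Assemble trajectory, spike trains, LFP, and schedule; seeded."""
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(2 + len(units))
    traj = generate_trajectory(config, np.random.default_rng(children[0]))

    spike_trains = {
        unit.unit_id: generate_unit_spikes(traj, unit, config,
                                           np.random.default_rng(child))
        for unit, child in zip(units, children[2:])
    }

    lfp = None
    if with_lfp:
        lfp_rng = np.random.default_rng(children[1])
        t_lfp = np.arange(int(traj.t[-1] * config.lfp_fs_hz)) / config.lfp_fs_hz
        v = (-config.lfp_amplitude_uv * np.cos(2 * np.pi * config.theta_hz * t_lfp)
             + lfp_rng.normal(0.0, config.lfp_noise_sd_uv, t_lfp.size))
        lfp = Lfp(t=t_lfp, uv=v, fs_hz=config.lfp_fs_hz)

    session = Session(
        positions_t=traj.t, positions_x=traj.x, positions_y=traj.y,
        spike_trains=spike_trains, schedule=traj.blocks,
        geometry=config.geometry, lfp=lfp, position_fs_hz=config.position_fs_hz,
    )
    session.validate()

    labels: dict[tuple[str, str, tuple[int, int]], str] = {}
    tilts = sorted(config.tilts)
    for unit in units:
        for direction in (UPHILL, DOWNHILL):
            for i in range(len(tilts)):
                for j in range(i + 1, len(tilts)):
                    pair = (tilts[i], tilts[j])
                    labels[(unit.unit_id, direction, pair)] = remap_label(
                        unit.tuning.get(Condition(pair[0], direction)),
                        unit.tuning.get(Condition(pair[1], direction)),
                    )
    truth = GroundTruth(units=units, runs=traj.runs, remap_labels=labels, config=config)
    return session, truth


# ---------------------------------------------------------------------------
# ensembles


def _tuning_all(tilts, direction, center, sigma, peak) -> dict[Condition, Tuning]:
    return {Condition(t, direction): Tuning(center, sigma, peak) for t in tilts}


def stable_ensemble(n_units: int, rng: np.random.Generator | int | None = None,
                    tilts: tuple[int, ...] = TILTS, peak_hz: float = 15.0,
                    sigma_cm: float = 6.0, baseline_hz: float = 0.3) -> list[UnitSpec]:
    """Units with identical tuning on every tilt (programmed stable)."""
    rng = np.random.default_rng(rng)
    units = []
    for i in range(n_units):
        direction = UPHILL if i % 2 == 0 else DOWNHILL
        center = float(rng.uniform(25.0, 95.0))
        units.append(UnitSpec(
            unit_id=f"u{i:03d}",
            tuning=_tuning_all(tilts, direction, center, sigma_cm, peak_hz),
            baseline_hz=baseline_hz,
            precession=PrecessionSpec(phi0_deg=float(rng.uniform(0, 360)),
                                      slope_deg_per_field=-360.0, kappa=4.0),
        ))
    return units


_RECOVERY_TYPES = ("stable", "rate_remap", "field_remap", "turn_on", "turn_off")


def remap_recovery_ensemble(rng: np.random.Generator | int | None = None,
                            n_units: int = 30, pair: tuple[int, int] = (0, 15),
                            rate_factor: float = 2.0, shift_cm: float = 30.0,
                            peak_hz: float = 15.0, sigma_cm: float = 6.0,
                            ) -> tuple[list[UnitSpec], dict[str, str]]:
    """Uphill units programmed with known remap types on one tilt pair.

    Units fire at 10:1 peak:baseline signal-to-noise.  The steeper tilts
    (both members above the shallow one) share the transformed tuning.
    Returns the units and unit -> programmed type.
    """
    rng = np.random.default_rng(rng)
    shallow, steep = pair
    steeper_tilts = [t for t in TILTS if t >= steep]
    units, programmed = [], {}
    for i in range(n_units):
        typ = _RECOVERY_TYPES[i % len(_RECOVERY_TYPES)]
        center = float(rng.uniform(30.0, 65.0))
        base = Tuning(center, sigma_cm, peak_hz)
        tuning: dict[Condition, Tuning] = {}
        if typ != "turn_on":
            tuning[Condition(shallow, UPHILL)] = base
        if typ == "stable" or typ == "turn_on":
            after = base
        elif typ == "rate_remap":
            after = Tuning(center, sigma_cm, peak_hz * rate_factor)
        elif typ == "field_remap":
            after = Tuning(center + shift_cm, sigma_cm, peak_hz)
        else:  # turn_off
            after = None
        if after is not None:
            for t in steeper_tilts:
                tuning[Condition(t, UPHILL)] = after
        uid = f"u{i:03d}"
        programmed[uid] = typ
        units.append(UnitSpec(unit_id=uid, tuning=tuning, baseline_hz=peak_hz / 10.0))
    return units, programmed


def mixed_ensemble(n_units: int, rng: np.random.Generator | int | None = None
                   ) -> list[UnitSpec]:
    """A heterogeneous ensemble loosely matching the observed remap mix."""
    rng = np.random.default_rng(rng)
    units = []
    types = ("stable", "rate_remap", "field_remap", "turn_on", "turn_off", "inactive")
    probs = (0.30, 0.15, 0.05, 0.20, 0.20, 0.10)
    for i in range(n_units):
        typ = rng.choice(types, p=probs)
        direction = UPHILL if rng.random() < 0.41 else DOWNHILL
        center = float(rng.uniform(25.0, 80.0))
        peak = float(rng.uniform(10.0, 25.0))
        base = Tuning(center, 6.0, peak)
        tuning: dict[Condition, Tuning] = {}
        if typ == "inactive":
            pass
        elif typ == "turn_on":
            for t in (15, 25):
                tuning[Condition(t, direction)] = base
        elif typ == "turn_off":
            tuning[Condition(0, direction)] = base
        else:
            tuning[Condition(0, direction)] = base
            after = {
                "stable": base,
                "rate_remap": Tuning(center, 6.0, peak * 2.0),
                "field_remap": Tuning(center + 30.0, 6.0, peak),
            }[typ]
            for t in (15, 25):
                tuning[Condition(t, direction)] = after
        units.append(UnitSpec(
            unit_id=f"u{i:03d}", tuning=tuning, baseline_hz=0.3,
            precession=PrecessionSpec(phi0_deg=float(rng.uniform(90, 270)),
                                      slope_deg_per_field=float(rng.uniform(-420, -240)),
                                      kappa=4.0),
        ))
    return units


def aligned_precession_unit(slope_deg_per_field: float = -360.0, kappa: float = 4.0,
                            phi0_deg: float = 200.0,
                            geometry: TrackGeometry | None = None,
                            tilts: tuple[int, ...] = (0,),
                            peak_hz: float = 25.0) -> UnitSpec:
    """A unit whose field span coincides with whole coarse-grid columns.

    The programmed ramp spans coarse columns 7-11 (5 columns), so the
    coarse field detector recovers the same extent and slope estimates
    are comparable in degrees per field traverse.
    """
    g = geometry or TrackGeometry()
    lo = g.coarse_col_edge_cm(7)
    hi = g.coarse_col_edge_cm(12)
    center = 0.5 * (lo + hi)
    sigma = (hi - lo) / 4.0
    return UnitSpec(
        unit_id="prec0",
        tuning=_tuning_all(tilts, UPHILL, center, sigma, peak_hz),
        baseline_hz=0.3,
        precession=PrecessionSpec(phi0_deg=phi0_deg,
                                  slope_deg_per_field=slope_deg_per_field,
                                  kappa=kappa, span_cm=(lo, hi)),
    )
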