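"""End-to-end session analysis: behaviour -> maps -> remapping -> precession.

:func:`analyze_session` runs the full battery on one session and returns
a :class:`SessionResults` whose tables mirror the on-disk report format
(`trials.tsv`, `metrics.tsv`, `remap_calls.tsv`, `correlations.tsv`,
`contingency_tests.tsv`, `precession.tsv`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import behavior, ratemaps, remapping
from .geometry import DIRECTIONS, UPHILL, Condition
from .metrics import CellConditionMetrics, evaluate_place_cell
from .precession import (MIN_FIELD_SPIKES, PrecessionFit, assign_spike_phases,
                         circular_linear_fit, theta_phase_series)
from .ratemaps import RateMap, collapse_to_1d, place_field_map_1d
from .remapping import (ContingencyTable, CorrelationResult, RemapCall,
                        assign_half, classify_remapping, elevation_half_table,
                        sequence_matrix, shuffle_null, spatial_correlation)
from .session_io import Session, write_report

__all__ = ["UnitEval", "TrialSetEval", "SessionResults", "evaluate_trial_set",
           "analyze_session", "within_between_calls"]


@dataclass
class UnitEval:
    unit_id: str
    metrics: CellConditionMetrics
    ratemap: RateMap
    smoothed: RateMap
    fields: list
    peak_1d_cm: float          # 1D place-field-map peak (falls back to map peak)
    peak_1d_bin: int
    trial_rates: np.ndarray    # per included trial: spikes / duration (Hz)

    @property
    def active(self) -> bool:
        return self.metrics.is_place_cell


@dataclass
class TrialSetEval:
    condition: Condition
    trials: list
    occupancy: ratemaps.OccupancyMap
    units: dict[str, UnitEval]


@dataclass
class SessionResults:
    trials: list
    conditions: dict[Condition, TrialSetEval]
    remap_calls: list[RemapCall]
    correlations: list[CorrelationResult]
    sequence: dict[tuple[str, int], tuple[np.ndarray, list[str]]]
    elevation_table: ContingencyTable | None
    within_between_table: ContingencyTable | None
    precession: list[PrecessionFit]
    seed: int

    # ----- tabular views -----

    def trials_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "trial_id": tr.trial_id, "block_id": tr.block_id,
                    "tilt_deg": tr.tilt, "direction": tr.direction,
                    "t_start_s": tr.t_start, "t_end_s": tr.t_end,
                    "duration_s": tr.duration, "mean_speed_cms": tr.mean_speed,
                    "included": tr.included, "reason": tr.reason or "",
                }
                for tr in self.trials
            ]
        )

    def metrics_frame(self) -> pd.DataFrame:
        rows = []
        for cond, ev in self.conditions.items():
            for uid in sorted(ev.units):
                m = ev.units[uid].metrics
                rows.append({
                    "unit_id": uid, "tilt_deg": cond.tilt, "direction": cond.direction,
                    "n_spikes": m.n_spikes, "mean_rate_hz": m.mean_rate,
                    "peak_rate_hz": m.peak_rate, "information_bits": m.information,
                    "sparsity": m.sparsity, "coherence_z": m.coherence_z,
                    "n_fields": m.n_fields,
                    "total_field_coverage": m.total_field_coverage,
                    "main_field_coverage": m.main_field_coverage,
                    "main_field_aspect": m.main_field_aspect,
                    "infield_rate_hz": m.infield_rate,
                    "outfield_rate_hz": m.outfield_rate,
                    "is_place_cell": m.is_place_cell,
                })
        return pd.DataFrame(rows)

    def remap_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "unit_id": c.unit_id, "direction": c.direction,
                    "tilt_shallow": c.tilt_pair[0], "tilt_steep": c.tilt_pair[1],
                    "call": c.call, "peak_separation_cm": c.peak_separation_cm,
                    "rank_sum_p": c.rank_sum_p,
                }
                for c in self.remap_calls
            ]
        )

    def correlations_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "unit_id": c.unit_id, "direction": c.direction,
                    "tilt_a": c.tilt_pair[0], "tilt_b": c.tilt_pair[1],
                    "r": c.r, "n_common_bins": c.n_common_bins,
                    "null_mean_r": c.null_mean_r if c.null_mean_r is not None else float("nan"),
                    "n_shuffles": c.n_shuffles,
                    "skipped": c.skipped, "skip_reason": c.skip_reason or "",
                }
                for c in self.correlations
            ]
        )

    def precession_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "unit_id": f.unit_id, "tilt_deg": f.tilt, "n_spikes": f.n_spikes,
                    "slope_deg_per_field": f.slope_deg_per_field,
                    "offset_deg": f.phi0_deg, "rho": f.rho, "p": f.p,
                    "bounded": f.bounded, "significant": f.significant,
                }
                for f in self.precession
            ]
        )

    def place_cells(self) -> list[str]:
        """Units meeting the criteria on at least one condition."""
        out = set()
        for ev in self.conditions.values():
            out.update(u for u, ue in ev.units.items() if ue.active)
        return sorted(out)

    def write(self, path, summary_extra: dict | None = None) -> None:
        tables = {
            "trials": self.trials_frame(),
            "metrics": self.metrics_frame(),
            "remap_calls": self.remap_frame(),
            "correlations": self.correlations_frame(),
            "precession": self.precession_frame(),
        }
        summary = {
            "seed": self.seed,
            "n_trials": len(self.trials),
            "n_included_trials": sum(tr.included for tr in self.trials),
            "n_units": len(next(iter(self.conditions.values())).units)
            if self.conditions else 0,
            "n_place_cells": len(self.place_cells()),
            "remap_call_counts": self.remap_frame()["call"].value_counts().to_dict()
            if self.remap_calls else {},
        }
        if summary_extra:
            summary.update(summary_extra)
        write_report(tables, path, summary=summary)


# ---------------------------------------------------------------------------


def evaluate_trial_set(session: Session, trials: list, condition: Condition,
                       unit_ids: list[str] | None = None) -> TrialSetEval:
    """Maps, fields, and the metric battery for one set of included trials."""
    g = session.geometry
    t, x, y = session.positions_t, session.positions_x, session.positions_y
    occ = ratemaps.build_occupancy_map(t, x, y, trials, g)
    units: dict[str, UnitEval] = {}
    for uid in unit_ids or sorted(session.spike_trains):
        spikes = session.spike_trains[uid]
        raw = ratemaps.build_rate_map(spikes, t, x, y, trials, occ)
        sm = ratemaps.smooth_rate_map(raw)
        fields = ratemaps.detect_fields(sm)
        m = evaluate_place_cell(uid, condition, raw, fields)
        if fields:
            vec = place_field_map_1d(sm, fields)
        else:
            vec = collapse_to_1d(sm.rate)
        vec = np.nan_to_num(vec, nan=-np.inf)
        peak_bin = int(np.argmax(vec)) if np.isfinite(vec).any() else 0
        rates = np.array([
            np.count_nonzero((spikes >= tr.t_start) & (spikes < tr.t_end)) / tr.duration
            for tr in trials if tr.included
        ])
        units[uid] = UnitEval(
            unit_id=uid, metrics=m, ratemap=raw, smoothed=sm, fields=fields,
            peak_1d_cm=float(g.long_bin_center_cm(peak_bin)), peak_1d_bin=peak_bin,
            trial_rates=rates,
        )
    return TrialSetEval(condition=condition, trials=trials, occupancy=occ, units=units)


def _tilt_pairs(tilts: list[int]) -> list[tuple[int, int]]:
    tilts = sorted(set(tilts))
    return [(a, b) for i, a in enumerate(tilts) for b in tilts[i + 1:]]


def analyze_session(session: Session, n_shuffles: int = 10_000, seed: int = 0,
                    do_shuffles: bool = True, do_precession: bool = True,
                    do_within_between: bool = True) -> SessionResults:
    """Run the full analysis battery on one session."""
    g = session.geometry
    trials = behavior.apply_trial_filters(behavior.segment_trials(session))
    tilts = sorted({b.tilt for b in session.schedule})
    unit_ids = sorted(session.spike_trains)

    conditions: dict[Condition, TrialSetEval] = {}
    for direction in DIRECTIONS:
        for tilt in tilts:
            cond = Condition(tilt, direction)
            ctrials = behavior.trials_for_condition(trials, cond)
            conditions[cond] = evaluate_trial_set(session, ctrials, cond, unit_ids)

    place_cells = sorted({
        uid for ev in conditions.values() for uid, ue in ev.units.items() if ue.active
    })

    # --- remap calls (shallower -> steeper, per direction) ---
    calls: list[RemapCall] = []
    for direction in DIRECTIONS:
        for pair in _tilt_pairs(tilts):
            ev_a = conditions[Condition(pair[0], direction)]
            ev_b = conditions[Condition(pair[1], direction)]
            for uid in place_cells:
                ua, ub = ev_a.units[uid], ev_b.units[uid]
                calls.append(classify_remapping(
                    uid, direction, pair, ua.active, ub.active,
                    ua.peak_1d_cm, ub.peak_1d_cm, ua.trial_rates, ub.trial_rates,
                ))

    # --- spatial correlations + shuffle null ---
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    correlations: list[CorrelationResult] = []
    for direction in DIRECTIONS:
        occs = [conditions[Condition(t, direction)].occupancy for t in tilts]
        if not occs:
            continue
        common = np.logical_and.reduce([o.visited for o in occs])
        for pair in _tilt_pairs(tilts):
            ev_a = conditions[Condition(pair[0], direction)]
            ev_b = conditions[Condition(pair[1], direction)]
            for uid in place_cells:
                ra = ev_a.units[uid].ratemap.rate
                rb = ev_b.units[uid].ratemap.rate
                res = spatial_correlation(uid, direction, pair, ra, rb, common)
                if do_shuffles and not res.skipped:
                    mean_r, _ = shuffle_null(ra, rb, common, n_shuffles, rng)
                    res.null_mean_r = mean_r
                    res.n_shuffles = n_shuffles
                    res.seed = seed
                correlations.append(res)

    # --- sequence matrices (per direction x baseline tilt) ---
    sequence: dict[tuple[str, int], tuple[np.ndarray, list[str]]] = {}
    for direction in DIRECTIONS:
        active_any = [
            uid for uid in place_cells
            if any(conditions[Condition(t, direction)].units[uid].active for t in tilts)
        ]
        if not active_any:
            continue
        for baseline in tilts:
            ev = conditions[Condition(baseline, direction)]
            vectors = {
                uid: collapse_to_1d(ev.units[uid].ratemap.rate) for uid in active_any
            }
            peaks = {uid: ev.units[uid].peak_1d_bin for uid in active_any}
            sequence[(direction, baseline)] = sequence_matrix(vectors, peaks)

    # --- elevation-half contingency (0 deg -> tilted pairs) ---
    elevation = None
    if 0 in tilts and len(tilts) > 1:
        elevated_end = session.schedule[0].elevated_end
        halves: dict[tuple[str, str], str] = {}
        for direction in DIRECTIONS:
            ev0 = conditions[Condition(0, direction)]
            for uid in place_cells:
                if ev0.units[uid].active:
                    halves[(uid, direction)] = assign_half(
                        ev0.units[uid].peak_1d_cm, g.roi_mid_cm, elevated_end)
        if halves:
            elevation = elevation_half_table(calls, halves)

    # --- within/between trial-half comparison ---
    wb_table = None
    if do_within_between:
        wb_calls = within_between_calls(session, trials, unit_ids)
        if wb_calls:
            counts = np.zeros((len(remapping.REMAP_TYPES), 2), dtype=int)
            for kind, call in wb_calls:
                counts[remapping.REMAP_TYPES.index(call.call),
                       0 if kind == "within" else 1] += 1
            wb_table = ContingencyTable(list(remapping.REMAP_TYPES),
                                        ["within", "between"], counts)

    # --- phase precession (uphill and the equivalent flat direction) ---
    fits: list[PrecessionFit] = []
    if do_precession and session.lfp is not None:
        theta = theta_phase_series(session.lfp.t, session.lfp.uv, session.lfp.fs_hz)
        t, x, y = session.positions_t, session.positions_x, session.positions_y
        for tilt in tilts:
            ctrials = behavior.trials_for_condition(trials, Condition(tilt, UPHILL))
            if not ctrials:
                continue
            sel = np.zeros(t.size, dtype=bool)
            for tr in ctrials:
                sel |= (t >= tr.t_start) & (t < tr.t_end)
            sel &= g.in_roi(x)
            if not sel.any():
                continue
            threshold = float(theta.envelope_at(t[sel]).mean())
            for uid in unit_ids:
                spikes = session.spike_trains[uid]
                cf = ratemaps.detect_fields_coarse(spikes, t, x, y, ctrials, g)
                if cf is None:
                    continue
                u, phases = assign_spike_phases(spikes, t, x, theta, cf,
                                                ctrials, threshold)
                if u.size < MIN_FIELD_SPIKES:
                    continue
                fits.append(circular_linear_fit(u, phases, unit_id=uid, tilt=tilt))

    return SessionResults(
        trials=trials, conditions=conditions, remap_calls=calls,
        correlations=correlations, sequence=sequence, elevation_table=elevation,
        within_between_table=wb_table, precession=fits, seed=seed,
    )


def within_between_calls(session: Session, trials: list,
                         unit_ids: list[str] | None = None,
                         half_size: int = 10) -> list[tuple[str, RemapCall]]:
    """Remap calls across first/second trial halves within and between blocks.

    Within comparisons pit the first ``half_size`` included trials of a
    direction in the second and third blocks against the next
    ``half_size``; between comparisons pit the tail of one block against
    the head of the next.  Returns (kind, call) pairs.
    """
    unit_ids = unit_ids or sorted(session.spike_trains)
    blocks = sorted(session.schedule, key=lambda b: b.t_start)
    if len(blocks) < 2:
        return []

    def block_dir_trials(block, direction):
        return [tr for tr in trials
                if tr.included and tr.block_id == block.block_id
                and tr.direction == direction]

    out: list[tuple[str, RemapCall]] = []
    for direction in DIRECTIONS:
        comparisons: list[tuple[str, list, list, tuple[int, int]]] = []
        for block in blocks[1:]:
            bt = block_dir_trials(block, direction)
            if len(bt) >= 2 * half_size:
                comparisons.append(("within", bt[:half_size],
                                    bt[half_size:2 * half_size],
                                    (block.tilt, block.tilt)))
        for a, b in zip(blocks, blocks[1:]):
            ta = block_dir_trials(a, direction)
            tb = block_dir_trials(b, direction)
            if len(ta) >= half_size and len(tb) >= half_size:
                comparisons.append(("between", ta[-half_size:], tb[:half_size],
                                    (a.tilt, b.tilt)))
        for kind, trials_a, trials_b, pair in comparisons:
            cond = Condition(pair[0], direction)
            ev_a = evaluate_trial_set(session, trials_a, cond, unit_ids)
            ev_b = evaluate_trial_set(session, trials_b,
                                      Condition(pair[1], direction), unit_ids)
            for uid in unit_ids:
                ua, ub = ev_a.units[uid], ev_b.units[uid]
                out.append((kind, classify_remapping(
                    uid, direction, pair, ua.active, ub.active,
                    ua.peak_1d_cm, ub.peak_1d_cm, ua.trial_rates, ub.trial_rates,
                )))
    return out
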