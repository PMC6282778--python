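"""Map construction, smoothing, field detection, and the 1D collapse."""

import numpy as np
import pytest

from slopecell import behavior
from slopecell.geometry import Condition, TrackGeometry, UPHILL
from slopecell.pipeline import evaluate_trial_set
from slopecell.ratemaps import (OccupancyMap, RateMap, build_occupancy_map,
                                build_rate_map, collapse_to_1d, detect_fields,
                                detect_fields_coarse, normalize01,
                                smooth_rate_map)

GEOM = TrackGeometry()


def make_maps(rate: np.ndarray, dwell: np.ndarray | None = None,
              n_roi: int | None = None) -> RateMap:
    """Wrap a rate array (NaN = unvisited) into map objects for unit tests."""
    rate = np.asarray(rate, dtype=float)
    visited = np.isfinite(rate)
    if dwell is None:
        dwell = np.where(visited, 1.0, 0.0)
    occ = OccupancyMap(dwell=np.where(visited, dwell, 0.0), visited=visited,
                       geometry=GEOM, total_trial_time=float(dwell[visited].sum()))
    spikes = float(np.nansum(rate * occ.dwell))
    return RateMap(rate=rate, occupancy=occ,
                   n_spikes_in_map=int(round(spikes)),
                   n_spikes_roi=int(round(spikes)) if n_roi is None else n_roi)


# ---------------------------------------------------------------------------
# occupancy


def test_dwell_accumulates_and_short_visits_are_removed():
    t = np.arange(0, 4.0, 0.02)
    x = np.full(t.size, 30.0)      # one bin, 4 s
    x[:4] = 60.0                   # 80 ms in another bin -> removed
    y = np.full(t.size, 11.0)
    trial = behavior.Trial(0, 0, 0, UPHILL, 0.0, 4.0, 4.0, 25.0, True, None)
    occ = build_occupancy_map(t, x, y, [trial], GEOM)
    r, c = GEOM.bin_indices(np.array([30.0]), np.array([11.0]))
    assert occ.dwell[r[0], c[0]] == pytest.approx(4.0 - 0.08, abs=0.05)
    r2, c2 = GEOM.bin_indices(np.array([60.0]), np.array([11.0]))
    assert not occ.visited[r2[0], c2[0]]
    assert occ.dwell[occ.visited].sum() <= 4.0 + 1e-9


def test_occupancy_probability_sums_to_one(mixed_session):
    session, _ = mixed_session
    trials = behavior.apply_trial_filters(behavior.segment_trials(session))
    sel = behavior.trials_for_condition(trials, Condition(0, UPHILL))
    occ = build_occupancy_map(session.positions_t, session.positions_x,
                              session.positions_y, sel, session.geometry)
    assert occ.p.sum() == pytest.approx(1.0)
    assert occ.dwell[occ.visited].sum() <= occ.total_trial_time + 1e-6


# ---------------------------------------------------------------------------
# rate maps


def test_rate_is_spikes_over_dwell():
    t = np.arange(0, 2.0, 0.02)
    x = np.full(t.size, 30.0)
    y = np.full(t.size, 11.0)
    trial = behavior.Trial(0, 0, 0, UPHILL, 0.0, 2.0, 2.0, 50.0, True, None)
    occ = build_occupancy_map(t, x, y, [trial], GEOM)
    spikes = np.linspace(0.1, 1.9, 6)
    rm = build_rate_map(spikes, t, x, y, [trial], occ)
    r, c = GEOM.bin_indices(np.array([30.0]), np.array([11.0]))
    assert rm.rate[r[0], c[0]] == pytest.approx(6 / occ.dwell[r[0], c[0]])


def test_spike_count_conservation_on_generated_session(mixed_session):
    session, _ = mixed_session
    trials = behavior.apply_trial_filters(behavior.segment_trials(session))
    cond = Condition(0, UPHILL)
    ev = evaluate_trial_set(session, behavior.trials_for_condition(trials, cond), cond)
    for ue in ev.units.values():
        rm = ue.ratemap
        recon = np.nansum(rm.rate * rm.occupancy.dwell)
        assert recon == pytest.approx(rm.n_spikes_in_map, abs=1e-6)
        assert rm.n_spikes_in_map <= rm.n_spikes_roi


def test_silent_unit_yields_zero_map(mixed_session):
    session, _ = mixed_session
    trials = behavior.apply_trial_filters(behavior.segment_trials(session))
    cond = Condition(0, UPHILL)
    ev = evaluate_trial_set(session, behavior.trials_for_condition(trials, cond), cond)
    rm = ev.units["silent"].ratemap
    assert np.nansum(rm.rate) == 0.0
    assert rm.mean_rate == 0.0


# ---------------------------------------------------------------------------
# smoothing


def test_smoothing_is_identity_on_uniform_maps():
    rate = np.full((9, 41), 4.2)
    sm = smooth_rate_map(make_maps(rate))
    np.testing.assert_allclose(sm.rate, rate, atol=1e-9)


def test_smoothing_spreads_a_delta_symmetrically_and_preserves_mass():
    # tall enough that every bin receiving mass has a full 3-sigma kernel
    rate = np.zeros((21, 41))
    rate[10, 20] = 10.0
    sm = smooth_rate_map(make_maps(rate))
    assert sm.rate[10, 19] == pytest.approx(sm.rate[10, 21], abs=1e-12)
    assert sm.rate[9, 20] == pytest.approx(sm.rate[11, 20], abs=1e-12)
    assert sm.rate.sum() == pytest.approx(10.0, abs=1e-6)
    assert np.argmax(sm.rate) == np.ravel_multi_index((10, 20), sm.rate.shape)


def test_smoothed_peak_never_exceeds_raw_peak(mixed_session):
    session, _ = mixed_session
    trials = behavior.apply_trial_filters(behavior.segment_trials(session))
    cond = Condition(0, UPHILL)
    ev = evaluate_trial_set(session, behavior.trials_for_condition(trials, cond), cond)
    for ue in ev.units.values():
        if ue.ratemap.peak_rate > 0:
            assert ue.smoothed.peak_rate <= ue.ratemap.peak_rate + 1e-9


# ---------------------------------------------------------------------------
# field detection


def _gaussian_map(center_col=20, sigma_bins=2.4, peak=15.0, rows=slice(2, 7)):
    rate = np.full((9, 41), np.nan)
    cols = np.arange(41)
    profile = peak * np.exp(-((cols - center_col) ** 2) / (2 * sigma_bins**2))
    rate[rows, :] = profile[None, :]
    return rate


def test_planted_bump_yields_one_main_field_at_the_center():
    sm = smooth_rate_map(make_maps(_gaussian_map()))
    fields = detect_fields(sm)
    assert len(fields) == 1
    assert fields[0].is_main
    assert abs(fields[0].peak_rc[1] - 20) <= 1


def test_isolated_supra_threshold_bin_is_not_a_field():
    rate = np.full((9, 41), 0.1)
    rate[4, 20] = 10.0
    fields = detect_fields(make_maps(rate))  # unsmoothed on purpose
    assert fields == []


def test_two_bumps_give_two_fields_and_the_larger_is_main():
    rate = np.full((9, 41), np.nan)
    cols = np.arange(41)
    wide = 15.0 * np.exp(-((cols - 10) ** 2) / (2 * 3.2**2))
    narrow = 15.0 * np.exp(-((cols - 30) ** 2) / (2 * 1.8**2))
    rate[2:7, :] = (wide + narrow)[None, :]
    fields = detect_fields(smooth_rate_map(make_maps(rate)))
    assert len(fields) == 2
    main = next(f for f in fields if f.is_main)
    assert abs(main.peak_rc[1] - 10) <= 1
    assert main.size > min(f.size for f in fields)


def test_edge_bins_never_survive_the_neighbor_rule():
    rate = np.full((9, 41), 10.0)  # everything supra-threshold
    fields = detect_fields(make_maps(rate))
    mask = np.zeros((9, 41), bool)
    for f in fields:
        mask |= f.mask
    assert not mask[0, :].any() and not mask[-1, :].any()
    assert not mask[:, 0].any() and not mask[:, -1].any()


def test_zero_peak_map_has_no_fields():
    rate = np.zeros((9, 41))
    assert detect_fields(make_maps(rate)) == []


# ---------------------------------------------------------------------------
# 1D collapse


def test_collapse_matches_rows_when_constant_along_short_axis():
    rate = np.tile(np.linspace(0, 4, 41), (9, 1))
    np.testing.assert_allclose(collapse_to_1d(rate), rate[0])


def test_collapse_single_visited_row_equals_that_row():
    rate = np.full((9, 41), np.nan)
    rate[4] = np.linspace(0, 4, 41)
    np.testing.assert_allclose(collapse_to_1d(rate), rate[4])


def test_collapse_commutes_with_scaling():
    rng = np.random.default_rng(0)
    rate = rng.gamma(2.0, 2.0, (9, 41))
    np.testing.assert_allclose(collapse_to_1d(3.5 * rate),
                               3.5 * collapse_to_1d(rate), atol=1e-12)


def test_collapse_argmax_matches_2d_peak_for_planted_bump(mixed_session):
    session, _ = mixed_session
    trials = behavior.apply_trial_filters(behavior.segment_trials(session))
    cond = Condition(0, UPHILL)
    ev = evaluate_trial_set(session, behavior.trials_for_condition(trials, cond), cond)
    ue = ev.units["stable_up"]
    vec = collapse_to_1d(ue.smoothed.rate)
    assert abs(int(np.nanargmax(vec)) - ue.fields[0].peak_rc[1]) <= 1


def test_normalize01_bounds():
    v = np.array([2.0, 4.0, 10.0])
    n = normalize01(v)
    assert n.min() == 0.0 and n.max() == 1.0


# ---------------------------------------------------------------------------
# coarse detection


def test_coarse_field_overlaps_fine_grid_main_field(mixed_session):
    session, _ = mixed_session
    trials = behavior.apply_trial_filters(behavior.segment_trials(session))
    cond = Condition(0, UPHILL)
    sel = behavior.trials_for_condition(trials, cond)
    ev = evaluate_trial_set(session, sel, cond)
    ue = ev.units["stable_up"]
    cf = detect_fields_coarse(session.spike_trains["stable_up"],
                              session.positions_t, session.positions_x,
                              session.positions_y, sel, session.geometry)
    assert cf is not None
    lo, hi = cf.long_extent_cm
    peak_cm = ue.peak_1d_cm
    assert lo - 6.0 <= peak_cm <= hi + 6.0


def test_uniform_rate_gives_no_coarse_field():
    session_t = np.arange(0, 120.0, 0.02)
    x = np.linspace(10, 110, session_t.size)
    y = np.full(session_t.size, 12.0)
    trial = behavior.Trial(0, 0, 0, UPHILL, 0.0, 120.0, 120.0, 25.0, True, None)
    rng = np.random.default_rng(0)
    spikes = np.sort(rng.uniform(0, 120.0, 200))
    cf = detect_fields_coarse(spikes, session_t, x, y, [trial], GEOM)
    # rates hover at the mean; no coherent above-mean cluster of size > chance
    assert cf is None or cf.size <= 6
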