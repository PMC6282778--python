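"""Remapping calls, shuffle nulls, sequence order, and count statistics."""

import itertools

import numpy as np
import pytest

from slopecell.datasets import (ACTIVATION_COUNTS, elevation_half_counts,
                                pool_complex_rate_stable, pool_remap_vs_stable,
                                within_between_counts)
from slopecell.remapping import (ContingencyTable, assign_half,
                                 chi_square_gof, chi_square_independence,
                                 classify_remapping, sequence_matrix,
                                 shuffle_null, spatial_correlation,
                                 wilcoxon_rank_sum)

RNG = np.random.default_rng(99)


# ---------------------------------------------------------------------------
# classification


def _call(active_a, active_b, peak_a=30.0, peak_b=30.0,
          rates_a=None, rates_b=None):
    rates_a = np.array([2.0, 2.1, 1.9, 2.0, 2.2] * 4) if rates_a is None else rates_a
    rates_b = np.array([2.0, 2.1, 1.9, 2.0, 2.2] * 4) if rates_b is None else rates_b
    return classify_remapping("u", "uphill", (0, 15), active_a, active_b,
                              peak_a, peak_b, rates_a, rates_b)


def test_six_way_classification_is_exhaustive_and_exclusive():
    assert _call(False, False).call == "inactive"
    assert _call(False, True).call == "turn_on"
    assert _call(True, False).call == "turn_off"
    # peaks 30 and 55 cm apart -> field remap
    assert _call(True, True, peak_a=30.0, peak_b=55.0).call == "field_remap"
    # boundary: exactly 20 cm separation counts as field remap
    assert _call(True, True, peak_a=30.0, peak_b=50.0).call == "field_remap"
    # near peaks, doubled rates -> rate remap
    ra = RNG.gamma(8.0, 0.25, 20)
    call = _call(True, True, peak_a=30.0, peak_b=35.0, rates_a=ra, rates_b=2.5 * ra)
    assert call.call == "rate_remap" and call.rank_sum_p < 0.05
    # near peaks, same rates -> stable
    assert _call(True, True, peak_a=30.0, peak_b=35.0).call == "stable"


def test_programmed_remap_types_recovered_in_mixed_session(mixed_results, mixed_session):
    _, truth = mixed_session
    calls = {(c.unit_id, c.direction, c.tilt_pair): c.call
             for c in mixed_results.remap_calls}
    expected = {
        ("stable_up", "uphill", (0, 15)): "stable",
        ("rate_up", "uphill", (0, 15)): "rate_remap",
        ("field_down", "downhill", (0, 15)): "field_remap",
        ("on_up", "uphill", (0, 15)): "turn_on",
        ("off_down", "downhill", (0, 15)): "turn_off",
        ("stable_up", "downhill", (0, 15)): "inactive",
    }
    for key, want in expected.items():
        assert calls[key] == want, key
        assert truth.remap_labels[key] == want  # ground truth agrees


# ---------------------------------------------------------------------------
# spatial correlations and shuffles


def test_identical_maps_correlate_perfectly():
    a = RNG.gamma(2.0, 2.0, (9, 41))
    mask = np.ones((9, 41), bool)
    res = spatial_correlation("u", "uphill", (0, 15), a, a, mask)
    assert res.r == pytest.approx(1.0)


def test_too_few_common_nonzero_bins_is_skipped():
    a = np.zeros(40)
    b = np.zeros(40)
    a[:2] = [1.0, 2.0]
    b[:2] = [2.0, 1.0]
    res = spatial_correlation("u", "uphill", (0, 15), a, b, np.ones(40, bool))
    assert res.skipped and "common" in res.skip_reason


def test_independent_maps_correlate_near_zero_on_average():
    rs = []
    for seed in range(100):
        rng = np.random.default_rng(seed)
        a = rng.gamma(2.0, 2.0, 40)
        b = rng.gamma(2.0, 2.0, 40)
        rs.append(spatial_correlation("u", "uphill", (0, 15), a, b,
                                      np.ones(40, bool)).r)
    assert abs(np.mean(rs)) < 0.05


def test_shuffle_null_concentrates_near_zero_and_is_deterministic():
    a = RNG.gamma(2.0, 2.0, 40)
    b = a + RNG.normal(0, 0.5, 40)
    mask = np.ones(40, bool)
    m1, rs1 = shuffle_null(a, b, mask, 2000, np.random.default_rng(5))
    m2, _ = shuffle_null(a, b, mask, 2000, np.random.default_rng(5))
    assert m1 == m2
    assert abs(m1) < 3.0 / np.sqrt(40 * 2000)
    # the matching pair beats essentially every shuffle
    actual = spatial_correlation("u", "uphill", (0, 15), a, b, mask).r
    assert np.mean(rs1 >= actual) < 0.001


# ---------------------------------------------------------------------------
# sequence matrices


def test_sequence_matrix_self_ordering_is_diagonal():
    vectors = {}
    peaks = {}
    for i, col in enumerate([5, 12, 20, 28, 35]):
        v = np.exp(-((np.arange(41) - col) ** 2) / 8.0)
        vectors[f"u{i}"] = v
        peaks[f"u{i}"] = col
    mat, order = sequence_matrix(vectors, peaks)
    assert [peaks[u] for u in order] == sorted(peaks.values())
    assert np.all(np.argmax(mat, axis=1) == sorted(peaks.values()))
    assert mat.min() >= 0.0 and mat.max() <= 1.0


def test_stable_ensemble_keeps_sequence_order_across_tilts(mixed_results):
    # build rank correlation of 1D peaks between 0 and 15 deg for units
    # active on both (programmed stable) — order must be preserved
    from slopecell.geometry import Condition
    ev0 = mixed_results.conditions[Condition(0, "uphill")]
    ev15 = mixed_results.conditions[Condition(15, "uphill")]
    both = [u for u in ev0.units
            if ev0.units[u].active and ev15.units[u].active]
    if len(both) >= 2:
        p0 = [ev0.units[u].peak_1d_bin for u in both]
        p15 = [ev15.units[u].peak_1d_bin for u in both]
        assert np.all(np.diff([p15[i] for i in np.argsort(p0)]) >= -2)


# ---------------------------------------------------------------------------
# elevation halves


def test_half_assignment_follows_the_elevated_end():
    # ROI midpoint at 60 cm; north elevated means large x = top
    assert assign_half(80.0, 60.0, "north") == "top"
    assert assign_half(20.0, 60.0, "north") == "bottom"
    assert assign_half(20.0, 60.0, "south") == "top"
    # exact midpoint ties go to bottom
    assert assign_half(60.0, 60.0, "north") == "bottom"
    assert assign_half(60.0, 60.0, "south") == "bottom"


def test_elevation_table_under_positional_null_is_rarely_significant():
    """Remapping independent of field position: chi-squared mostly n.s.

    Uses one tilt pair per unit (calls across pairs from the same unit
    are correlated) and field centers balanced across the two halves.
    """
    from slopecell.pipeline import analyze_session
    from slopecell.remapping import elevation_half_table
    from slopecell.synthetic import (Condition, ScenarioConfig, Tuning,
                                     UnitSpec, generate_session)

    types = ["stable", "rate_remap", "field_remap", "turn_off", "turn_on"]
    n_sig = 0
    n_ok = 0
    for seed in range(8):
        rng = np.random.default_rng(seed + 600)
        units = []
        for i in range(30):
            typ = types[i % len(types)]
            center = float(rng.uniform(25.0, 65.0 if typ == "field_remap" else 95.0))
            base = Tuning(center, 6.0, 15.0)
            after = {"stable": base,
                     "rate_remap": Tuning(center, 6.0, 30.0),
                     "field_remap": Tuning(center + 30.0, 6.0, 15.0),
                     "turn_off": None, "turn_on": base}[typ]
            tuning = {}
            if typ != "turn_on":
                tuning[Condition(0, "uphill")] = base
            if after is not None and typ != "turn_on":
                tuning[Condition(15, "uphill")] = after
            if typ == "turn_on":
                tuning[Condition(15, "uphill")] = base
            units.append(UnitSpec(f"u{i:03d}", tuning, baseline_hz=1.5))
        sess, _ = generate_session(ScenarioConfig(tilts=(0, 15)), units,
                                   seed=seed + 600, with_lfp=False)
        res = analyze_session(sess, do_shuffles=False, do_precession=False,
                              do_within_between=False)
        if res.elevation_table is None:
            continue
        calls = [c for c in res.remap_calls if c.tilt_pair == (0, 15)]
        halves = {}
        ev0 = res.conditions[Condition(0, "uphill")]
        for uid, ue in ev0.units.items():
            if ue.active:
                halves[(uid, "uphill")] = assign_half(
                    ue.peak_1d_cm, sess.geometry.roi_mid_cm, "north")
        table = elevation_half_table(calls, halves)
        pooled = pool_remap_vs_stable(table)
        if (pooled.counts.sum(axis=1) == 0).any() or (pooled.counts.sum(axis=0) == 0).any():
            continue
        _, _, p = chi_square_independence(pooled)
        n_ok += 1
        n_sig += p < 0.05
    assert n_ok >= 5
    assert n_sig <= max(1, n_ok // 5)


# ---------------------------------------------------------------------------
# count statistics


def oracle_chi2_independence(counts):
    counts = np.asarray(counts, float)
    total = counts.sum()
    stat = 0.0
    for i in range(counts.shape[0]):
        for j in range(counts.shape[1]):
            e = counts[i].sum() * counts[:, j].sum() / total
            stat += (counts[i, j] - e) ** 2 / e
    return stat


def test_published_contingency_statistics_reproduce():
    table2 = elevation_half_counts()
    stat, df, p = chi_square_independence(pool_remap_vs_stable(table2))
    assert df == 1 and stat == pytest.approx(1.635, abs=5e-4)
    stat, df, _ = chi_square_independence(pool_complex_rate_stable(table2))
    assert df == 2 and stat == pytest.approx(2.89, abs=0.01)

    table3 = within_between_counts()
    stat, df, p = chi_square_independence(table3.drop_row("inactive"))
    assert df == 4 and stat == pytest.approx(23.5, abs=0.05)
    stat, df, _ = chi_square_independence(pool_remap_vs_stable(table3))
    assert df == 1 and stat == pytest.approx(16.6, abs=0.05)

    stat, df, p = chi_square_gof([ACTIVATION_COUNTS["downhill"],
                                  ACTIVATION_COUNTS["uphill"]])
    assert df == 1 and stat == pytest.approx(6.81, abs=5e-3) and p < 0.01


def test_chi_square_matches_brute_force_oracle_on_random_tables():
    rng = np.random.default_rng(11)
    for _ in range(200):
        shape = (int(rng.integers(2, 5)), int(rng.integers(2, 5)))
        counts = rng.integers(1, 60, shape)
        table = ContingencyTable([f"r{i}" for i in range(shape[0])],
                                 [f"c{j}" for j in range(shape[1])], counts)
        stat, df, _ = chi_square_independence(table)
        assert stat == pytest.approx(oracle_chi2_independence(counts), abs=1e-6)
        assert df == (shape[0] - 1) * (shape[1] - 1)


def test_chi_square_rejects_degenerate_margins():
    table = ContingencyTable(["a", "b"], ["x", "y"], [[0, 0], [3, 4]])
    with pytest.raises(ValueError, match="'a'"):
        chi_square_independence(table)


def test_gof_examples():
    assert chi_square_gof([10, 10], [0.5, 0.5])[0] == pytest.approx(0.0)
    assert chi_square_gof([60, 40])[0] == pytest.approx(4.0)
    with pytest.raises(ValueError):
        chi_square_gof([0, 0])


def test_wilcoxon_exact_and_symmetric_cases():
    # identical samples: two-sided exact p = 1
    w, p = wilcoxon_rank_sum([1.0, 2.0, 3.0], [1.5, 2.5, 0.5])
    assert 0 < p <= 1.0
    _, p_same = wilcoxon_rank_sum([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert p_same == pytest.approx(1.0)
    # complete separation of 3 vs 3: exact two-sided p = 2/20 = 0.1
    w, p = wilcoxon_rank_sum([1, 2, 3], [10, 11, 12])
    assert w == 6.0  # ranks 1+2+3
    assert p == pytest.approx(0.1)


def test_wilcoxon_enumeration_oracle_three_vs_three():
    """Exact tail probability by enumerating all rank assignments."""
    obs_w = 6.0
    ws = []
    for combo in itertools.combinations(range(1, 7), 3):
        ws.append(sum(combo))
    ws = np.array(ws)
    center = ws.mean()
    p_enum = np.mean(np.abs(ws - center) >= abs(obs_w - center))
    _, p = wilcoxon_rank_sum([1, 2, 3], [10, 11, 12])
    assert p == pytest.approx(p_enum)


def test_wilcoxon_detects_two_sigma_shifts():
    hits = 0
    for seed in range(40):
        rng = np.random.default_rng(seed)
        a = rng.normal(0.0, 1.0, 20)
        b = rng.normal(2.0, 1.0, 20)
        hits += wilcoxon_rank_sum(a, b)[1] < 0.05
    assert hits >= 38


# ---------------------------------------------------------------------------
# within/between protocol


def test_within_halves_are_more_stable_than_between_conditions():
    from slopecell.pipeline import within_between_calls
    from slopecell import behavior
    from slopecell.synthetic import (ScenarioConfig, remap_recovery_ensemble,
                                     generate_session)

    units, _ = remap_recovery_ensemble(np.random.default_rng(4), peak_hz=30.0)
    sess, _ = generate_session(ScenarioConfig(), units, seed=4, with_lfp=False)
    trials = behavior.apply_trial_filters(behavior.segment_trials(sess))
    calls = within_between_calls(sess, trials)
    assert calls
    def stable_rate(kind):
        sel = [c for k, c in calls if k == kind]
        return sum(c.call == "stable" for c in sel) / len(sel)
    assert stable_rate("within") > stable_rate("between")
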