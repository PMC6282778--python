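# Methods

## Setting and conventions

The apparatus is a 120 × 24 cm shuttle box with reward endzones at both
ends and a 103 cm running region of interest (ROI) in between; all
analysis is restricted to the ROI.  Coordinates are continuous cm with
the origin at the ground-level (pivot) corner: x along the long axis
(0–120), y across the width (0–24).  "North" is the x = 120 end,
"south" x = 0; each condition block records which end is elevated, and
0° blocks carry the same label so flat trials inherit the session's
uphill/downhill convention.  A trial is "uphill" when it departs the
endzone that stays on the ground.

The fine analysis grid is nominally 2.5 cm square.  103 and 24 cm are
not multiples of 2.5, so the grid has 41 × 9 bins and the last bin on
each axis absorbs the remainder (3.0 cm and 4.0 cm respectively); bins
are half-open.  The coarse grid used only for phase-precession field
detection is 4 × 20 over the ROI (bins ≈ 6.0 × 5.15 cm).

## Behaviour

Trial boundaries are half-open in time: the first position sample past
the origin endzone boundary opens the trial and the first sample past
the opposite boundary closes it.  Excursions returning to their origin
endzone are excluded ("incomplete").  The speed criterion uses
ROI length / duration, consistent with the equivalence of the 7 s limit
and 15 cm/s over 103 cm; completed trials longer than 7 s are excluded
("slow").  Filtering is idempotent and order-independent of direction
labelling.

## Rate maps and place fields

Occupancy accumulates each sample's interval to the next into the
sample's bin, over included trials only; bins under 100 ms of dwell are
treated as unvisited.  Rates are element-wise spike count / dwell.
Spikes landing in removed bins stay out of the map but still count
toward the 100-spike criterion.

Field detection runs on a smoothed copy (Gaussian, σ = 1 bin, truncated
at 3σ).  Unvisited bins are excluded from the kernel and the remaining
weights renormalized — zero-filling would deflate rates along the
occupancy edges of a narrow track.  A bin survives when it is at least
15% of the smoothed map peak and at least 7 of its 8 neighbours also
qualify; edge bins (≤ 5 neighbours) therefore never survive, an accepted
consequence of the rule.  Surviving bins are labelled by 8-connectivity;
the largest component is the main field; length and width are
bounding-box extents.

All scalar metrics (information, sparsity, coherence, peak rate,
infield/outfield rates) use the *unsmoothed* map.  The coherence
criterion (> 0.5) applies to the Fisher-z value: reported coherences in
this literature exceed 1, which is impossible for a raw correlation.
The mean rate for the 0.1 Hz criterion is ROI spike count divided by
summed included-trial time, and the 100-spike count is ROI-restricted,
matching the restriction of all analysis to the running ROI.  Terms
with λᵢ = 0 contribute zero to the information sum (x log x → 0);
silent maps report information and sparsity as not computable.

The 1D place-field map collapses the field-masked smoothed map by
averaging *field-member* bins per long-axis column (columns outside all
fields are NaN).  Averaging whole columns with non-field bins as zeros
makes the argmax sensitive to how many rows happen to be visited in
each column, shifting peaks by 2–3 bins on narrow-track data; the
field-restricted profile does not have that artifact.  Plain
whole-column averaging is still used for sequence plots, where rows are
min–max normalized per cell and uphill/downhill ensembles are
normalized separately.

## Remapping

Calls run from the shallower to the steeper tilt within a slope
direction.  "Active" means meeting all four place-cell criteria on that
condition.  Field remapping triggers at a 1D peak separation of
≥ 20 cm (the boundary value included).  Otherwise a two-sided Wilcoxon
rank-sum on per-trial firing rates (spikes in the trial window /
duration) decides rate remapping at p < 0.05; the test is exact for
combined n ≤ 20 without ties and a tie-corrected normal approximation
otherwise.

Spatial correlations use bins occupied on all three tilts of the
direction; a pair is skipped unless each map has ≥ 3 non-zero common
bins.  The shuffle null permutes one map's rates over the common bins
(permuting both is equivalent in distribution) 10,000 times with an
explicit seed recorded in the outputs.

The elevation-half analysis assigns 0°-active cells to the top or
bottom half by their 1D field peak relative to the ROI midpoint and the
elevated end; exact-midpoint ties go to bottom (deterministic,
measure-zero).  The within/between control splits each condition's
included trials per direction into first-10/second-10 halves and
classifies across the split with the same machinery.

Chi-squared tests are Pearson statistics without continuity correction;
this choice reproduces the statistics printed alongside the published
count tables (1.635, 2.89, 23.5, 16.6, 6.81) to their printed precision
(the three-way elevation statistic computes to 2.8848, i.e. the
published 2.89 is a rounding).  The df = 4 within/between test excludes
the inactive category, the only grouping consistent with its printed
degrees of freedom.

## Phase precession

The LFP is band-passed 7–9 Hz with a 4th-order Butterworth applied
forward–backward (zero phase distortion in the passband) and the
Hilbert transform gives instantaneous phase and envelope.  The analytic
angle is shifted 180° so 0° falls at the filtered-signal trough.

Fields for this analysis come from the coarse 4 × 20 grid: bins above
the map mean (over visited coarse bins) with ≥ 2 qualifying
8-neighbours, largest cluster wins.  Coarse bins use a 0.5 s minimum
dwell rather than the fine grid's 100 ms: at ~13 cm² per bin, shorter
visits produce single-spike rate estimates that randomly extend the
detected cluster.  Only uphill passes (and the equivalent flat
direction) are analysed.  Spikes qualify when in-field during an
included trial with the theta envelope above its mean over the
condition's in-ROI samples; position is normalized per traversal
(entry edge 0, exit edge 1).  Cells with fewer than 50 qualifying
spikes are skipped.

The slope maximizes the mean resultant length R(a) on a 1 deg/traverse
grid over ±720° (two theta cycles per traverse) with bounded local
refinement; estimates pinned at the bound are flagged rather than
rejected.  The phase offset is the circular mean of φⱼ − a·uⱼ, and ρ is
the circular–circular correlation between the spike phases and the
fitted ramp (a·u mod 360°) with the standard normal-approximation
p-value.  Because the slope is selected to maximize R before ρ is
computed, the null distribution of |ρ| is inflated above the naive
1/√n scale; the p-value remains approximately calibrated at the 5%
level, which is what the test suite asserts.

Circular statistics (Rayleigh uniformity test with the finite-sample
correction, Watson–Williams F with the concentration correction and a
low-concentration warning below pooled κ ≈ 1, Best–Fisher κ estimation)
are implemented in `slopecell.circstats` and calibrated against null
simulation in the tests.

## Synthetic sessions

The generator emulates the study conditions: three tilt blocks of 20
laps, per-condition mean speeds set to the reported group means
(32.7/33.4, 33.4/31.5, 30.0/26.6 cm/s for 0/15/25° up/down), 3 s reward
dwells, 50 Hz position sampling (a typical camera rate; the source does
not state one), lateral jitter of σ = 3 cm around the midline, and a
250 Hz LFP as an 8 Hz sinusoid (100 µV) plus white noise (20 µV).
Trajectories are constant-velocity across the ROI with raised-cosine
ramps inside the endzones, so realized mean trial speed equals the
programmed speed exactly up to per-run jitter (CV 6%).

Units have Gaussian spatial tuning per condition (center, σ, peak) over
a small baseline; remapping is programmed by transforming the tuning
between tilts (rate ×k, center shift, on/off).  Spikes are generated
per theta cycle: each cycle contributes a Poisson number of candidates
whose phases are von Mises-distributed (concentration κ) around the
programmed ramp φ(x) = φ₀ + s·u(x), candidate times are solved by a
wrap-aware fixed point so the spike's phase matches the ramp at its
actual position, and candidates are thinned by the Gaussian envelope
evaluated at that time.  This construction keeps the time-marginal rate
equal to the programmed λ(x) (so rate maps converge to the tuning
curve) and, at κ → ∞, puts spike phases exactly on the ramp.  Baseline
spikes are homogeneous Poisson with uniform phase.

What the generator does not emulate: broadband LFP structure (the
filtering stage sees only a tone plus white noise), tracking dropouts,
gait or speed–theta coupling, multi-field cells, and experience- or
time-dependent drift.  Passing tests therefore certify the estimators
against the generative model the analysis assumes, not against every
pathology of real recordings.

## Validation experiments and problem sizes

The acceptance suite (and `scripts/acceptance.py`) uses these sizes,
chosen to give stable Monte-Carlo estimates at interactive runtimes:

* Field recovery: 50 single-unit sessions (σ = 6 cm, 10:1 SNR, 20
  laps).  The absolute rate is not fixed by the ratio; peak 30 Hz /
  baseline 3 Hz matches the reported ~33 Hz peak rates.  Recovery is
  judged on the 1D place-field-map peak, the quantity remapping
  consumes.
* Remap recovery: 50 sessions × 30 units programmed with
  {stable, rate ×2, field +30 cm, turn on, turn off} at 10:1 SNR,
  scored on the (0°, 15°) uphill pair.
* Precession recovery: 50 end-to-end sessions at κ = 4 with the
  programmed span aligned to whole coarse columns (so degrees per
  programmed and per detected traverse are commensurate).  The
  residual ~3–6% steepening bias comes from occasional one-column span
  overestimates.  The zero-noise grid-resolution check runs on exactly
  generated (u, φ) pairs, where the fit's own contract applies; a
  one-column span error rescales a −900°/field ramp by a full theta
  cycle per traverse, which is unidentifiable modulo 360°, so the
  end-to-end clipping check requires ≥ 80% of seeds at the bound while
  the fit-level clip is asserted exactly.
* Shuffle null: 20 map pairs × 10,000 shuffles on 40-bin vectors.
* Oracles: Wilcoxon exact p against full enumeration of rank
  assignments; chi-squared against a literal-formula oracle on 1,000
  random tables.

## Known limitations

* The narrow track means fields often survive the 7-neighbour rule only
  as a one-row strip; field widths (and hence aspect ratios) are lower
  bounds on what a wider apparatus would yield.
* The within/between control needs ≥ 100 spikes inside a 10-trial
  half-block for a cell to count as active, so weakly firing cells
  default to inactive there.
* The coarse-grid "above average" threshold is taken over visited
  coarse bins (the map mean); the alternative reading (the unit's
  overall mean rate) was not adopted.
* With fewer than three tilts in a session the common-occupied bin mask
  is taken across the tilts present.
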