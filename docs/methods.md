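# Methods

## Error model and definitions

A fix is one GPS position solution: UTC time, latitude/longitude
(WGS-84 decimal degrees) and altitude above the WGS-84 ellipsoid.
All altitudes stay ellipsoidal; no geoid conversion is offered, because
calibration references surveyed the same datum.

**Horizontal accuracy** of a fix is the geodesic distance to the
surveyed reference point. The inverse and direct geodesic problems are
solved with Vincenty's iterative method on the WGS-84 ellipsoid
(a = 6378137 m, f = 1/298.257223563), vectorised over numpy arrays.
Convergence tolerance is 1e-15 rad on the iterated longitude/arc
variable; at that setting the solver agrees with independent reference
values to < 1 µm at sub-kilometre range and < 0.1 mm at thousands of
kilometres. Vincenty fails to converge only near antipodal pairs, which
cannot occur at calibration scales; the iteration cap (200) simply
returns the last iterate there. For displacements under 1 km the
geodesic agrees with a local planar east/north frame to < 0.1%
(property-tested), which is why the synthetic generator may draw errors
in a planar frame and place them by the direct geodesic.

**Vertical accuracy** is the signed difference
`reference_alt − fix_alt`: positive when the device under-reads the
true altitude. The *headline* vertical accuracy of a group is the mean
of |signed error|, with the signed mean reported separately as the
bias. A signed mean cannot serve as an accuracy magnitude — a device
with large symmetric vertical errors would score near zero — so the
magnitude/bias split keeps the accuracy number meaningful while still
exposing systematic under/over-estimation.

**Precision** is computed over all n(n−1)/2 unordered fix pairs:
horizontally the mean/SD of pairwise geodesic distances, vertically the
mean/SD of |altitude difference|. Pairs share fixes, so these values
are not independent; the SD across pairs is reported descriptively, as
is conventional, and p-values computed from per-pair samples should be
read the same way. Exact all-pairs evaluation is used up to 20,000
fixes; beyond that a seeded uniform random subsample of 2×10⁷ pairs is
drawn (pairs sampled with replacement; the duplicate probability is
negligible at that scale). At the package's own test scale (10⁵ fixes)
the subsample estimates the mean to well under 0.5% relative error.

**Error categories.** A fix is *inaccurate* when its error magnitude
strictly exceeds 10 m. Categories are half-open on the left:
accurate = [0, 10], 11–20 = (10, 20], 21–30 = (20, 30], >30 = (30, ∞).
The strict ">" reading of the 10 m threshold was chosen over "≥"
(both conventions circulate) and applied consistently; at float
precision the distinction only matters for fixes constructed exactly on
the boundary.

**Group comparisons** use the Kruskal–Wallis rank test (tie-corrected
H, chi-square p with df = k−1, via scipy). An optional Monte-Carlo
permutation p-value (label shuffles of the pooled ranks; default
10,000) is provided for small samples where the chi-square
approximation is rough; it is validated against exact enumeration of
all assignments at total n ≤ 10. When all pooled values are identical
the statistic is degenerate and returned as H = 0, p = 1 with a flag.
Sample (n−1) standard deviations are used throughout.

## Reference points

A surveyed reference may be a single point or the average of repeated
differential-GPS readings (typically three). Averaging is arithmetic in
degrees, which is valid because reading spreads are metres — far below
the ~1 km scale where degree-space averaging would distort; the
horizontal uncertainty attached to the average is the sample SD of each
reading's geodesic distance to the mean, the vertical uncertainty the
sample SD of the altitudes.

## Quantile screening by self-reported error

Given per-fix reported errors, `exclude_top_fraction` removes exactly
k = round(q·n) records with the largest reported error (round half away
from zero; floor/ceil configurable). Ties at the cutoff are broken by
removing later-timestamped records first, making re-runs deterministic.
The count-based reading ("remove q of the positions") was chosen over a
quantile-threshold reading, which would remove a data-dependent count.
Efficacy is reported per removal fraction and axis: counts and
proportions of inaccurate positions remaining among retained fixes,
per-category counts, and the share of originally inaccurate positions
eliminated (undefined — NaN — when nothing was inaccurate). A baseline
row at q = 0 is included. Efficacy is emitted per device and pooled.

The mechanism, and the reason screening works on intensive fix
schedules but not sparse ones, is purely the rank coupling between
reported and realised error: with perfect coupling the removed set *is*
the worst-q set (optimal among equal-size removals, verified by brute
force over all subsets at small n); with zero coupling removal is
random deletion and leaves the inaccurate proportion unchanged in
expectation.

## Deployment comparison

Post-deployment fixes are windowed to [t₀, t₀ + 7 days) — half-open, so
a fix exactly at the boundary is excluded; 7 days is the default
because nest-bound juveniles cannot have left the surveyed nest in that
window. Each metric (horizontal/vertical accuracy, horizontal/vertical
precision) is compared between phases with a two-group Kruskal–Wallis
test on the per-observation samples (per-pair samples for precision,
with the non-independence caveat above). Device inclusion is entirely
input-driven; nothing about device counts is hard-coded.

## Synthetic generator

`simulate_stationary` emulates the stationary calibration test with a
known ground truth returned alongside the fixes:

| parameter | meaning | default |
|---|---|---|
| `sigma_h` | per-axis horizontal noise SD (m); error magnitude is Rayleigh(σ_h) | 3.0 |
| `sigma_v` | vertical noise SD (m) | 5.0 |
| `v_bias` | mean signed vertical error (m); positive = altitude under-read | 0.0 |
| `device_offset_sd` | SD of the fixed per-device bias vector (m), drawn once per device | 0.0 |
| `outlier_prob`, `outlier_scale` | per-fix probability of multiplying the whole error vector (and vertical error) by the scale | 0.0 / 10 |
| `gpserror_reliability` | probability per fix that the reported error is rank-tied to the realised error | 1.0 |
| `dropout_prob` | per-scheduled-fix probability of no fix | 0.0 |
| `interval_minutes`, `span_hours` | schedule and duration; fixes per device = span/interval | 20 / 24 |

Horizontal errors are drawn in a local east/north frame
(bias + isotropic normal), optionally inflated by the outlier
multiplier — multiplying rather than re-drawing preserves direction and
produces the rare multi-hundred-metre tail real tests show — and placed
on the ellipsoid by the direct geodesic at the implied
distance/azimuth. Altitude is `reference_alt − v_err`, matching the
sign convention.

The reported error is emitted with a lognormal-shaped marginal
(log-SD 0.5) whose scale is σ_h times the Rayleigh 67th percentile
(≈1.489 σ_h), tying the typical report to the metric's definition as a
67%-probability displacement bound. With probability
`gpserror_reliability` the report is a strictly monotone transform of
the realised error magnitude (Rayleigh CDF → lognormal quantile; the
upper tail is computed from the log survival probability with
`ndtri_exp`, so the map never saturates in double precision and full
reliability means *exact* rank agreement); otherwise it is an
independent draw from the same marginal. An optional multiplicative
jitter exists but defaults to 0, precisely so the reliability dial has
clean endpoints. The Spearman correlation between reported and realised
error is monotone in the dial (property-tested at 0 / 0.5 / 1).

All randomness flows from one `numpy` Generator seeded by the config;
identical config + seed reproduces the dataset exactly.

**Presets.** The shipped per-interval presets (1 min: σ_h 2.7 m,
positive vertical bias, reliability 0.95; 20 min: σ_h 3.3 m,
reliability 0.5, device offsets 1 m; 60 min: σ_h 5 m, σ_v 12 m,
reliability 0.05, more/larger outliers) encode the qualitative pattern
of real devices — warm starts on intensive schedules give better fixes
and an informative error report; cold starts degrade both — but they
are data-free inventions for demos and tests, not fitted to any field
dataset.

**What the generator does not emulate:** temporal autocorrelation
between consecutive fixes, habitat/topography/antenna-orientation
effects, satellite geometry (DOP), battery/charging dynamics, and
animal movement. Passing tests therefore demonstrate the estimators and
the screening mechanism, not any particular device's field performance.

## Problem sizes and validation

The validation suite recovers the closed forms σ√(π/2), σ√π and
2σ_v/√π through the full pipeline at 10⁵ fixes (2% tolerance; the
pairwise stage uses the 2×10⁷-pair subsample), checks estimators
against brute-force double loops at n ≤ 50 and exact permutation
enumeration at n ≤ 10, verifies the screening contrast at
reliability 1 (exact set equality) and 0 (binomial-CI equivalence over
50 replicates of 1,000 fixes), and measures the phase comparison's
type-I error over 2,000 null replicates of 50 + 50 fixes.
`scripts/acceptance.py` recomputes the same quantities end-to-end from
a user-supplied seed.

## Known limitations

* Vincenty (not Karney) geodesics: unreliable near antipodal pairs;
  irrelevant at calibration scales but a caveat for reuse.
* Pairwise-sample tests (precision comparisons) inherit the
  non-independence of pairs; their p-values are descriptive.
* Fix-table ingestion supports delimited text and XLSX with plain,
  Movebank-style, or user-mapped columns; no live Movebank API or
  binary device logs.
* `fix_acquisition_rate` counts one expected fix per completed
  interval; schedules with day/night asymmetry need a custom expected
  count.
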