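# Methods

This note records the model choices, parameter defaults and numerical
conventions behind `ecobode`, and what the synthetic validation does and
does not establish about real data.

## Geometry model and its assumptions

The electrode array's in-plane trajectory is reconstructed from manually
selected landmarks on one (possibly overlaid) axial CT slice. The
reconstruction assumes:

* the slice plane is approximately aligned with the cochlea's basal turn,
  so a 2-D arc length is a usable proxy for the 3-D inserted length;
* the landmark chain `[round window, array points…]` is ordered
  basal→apical and includes the basal and apical contacts as its first
  and last array points;
* the array advances monotonically in angle about the cochlear center
  (true for an inserted array; the angle unwrapping adds 360° whenever
  the basal→apical sequence would otherwise decrease).

The spline interpolates x(t) and y(t) separately over the knot index
with not-a-knot boundary conditions and is evaluated at 10⁶ equally
spaced parameter values (`n_samples`, tunable); arc length is the
cumulative chord sum, which underestimates the true length and converges
monotonically from below as `n_samples` grows. At 10⁶ samples the
discretization error is far below the landmark-selection error. A
chord-length parameterization is available (`parameterization="chord"`)
for very unevenly spaced landmarks; the index parameterization is the
default because it reproduces the behavior of standard 1-D spline
interpolation routines.

Pixel coordinates are calibrated by a mandatory `scale_mm_per_px`
(from the CT metadata) before any arc-length computation.

**Rotation sense.** Whether insertion appears clockwise or
counter-clockwise in image coordinates depends on the ear side and the
raster orientation. The sense is inferred from the net signed rotation
of the array landmarks about the center (sum of wrapped successive
increments, plus the first knot's offset from the RW ray) rather than
from the first knots alone: the net sum is insensitive to noise on any
single knot and gives identical results on all tested geometries. This
makes all angle outputs invariant under rotation, translation and mirror
reflection of the landmark set.

**Apical-landmark consistency.** The apical contact's depth is read at
the trajectory sample nearest its landmark; a nearest-sample distance
above 0.1 mm indicates landmarks inconsistent with the fitted curve and
is treated as an error rather than silently accepted.

**Negative-depth correction.** Contact depths are an arithmetic sequence
anchored at the apical contact. When the basal contact would land at
negative depth (a basal contact at the RW plus a slight underestimate of
the arc), the axis is re-anchored to exactly `[array_length … 0]`,
keeping the spacing.

**Per-contact AIDs are a linear interpolation** between the basal and
apical contact angles. This is exact on a circle and degrades with
radial decay of the spiral: for an Archimedean spiral the deviation of
the true polar angle from the chord is ≈ b·Δs²/(8r³) (b the radius decay
per radian, Δs the contact span, r the local radius). For strongly
decaying spirals this approximation — not the trajectory fit — is the
dominant AID error. This is an inherent property of the two-endpoint
interpolation scheme, shared by the standardized (registry) route.

**Insertion-monitoring axis.** The surgeon's markers give the instants
at which each contact j passes the RW; at that instant the apical
recording electrode sits at depth `depth[1] − depth[j]` (the fixed arc
distance between the contacts, taken from the sweep axes). Between
markers, depth is linear in time; before the first marker it is linearly
extrapolated down to 0 mm and clamped there. AIDs follow the sweep axes'
linear depth↔angle map, extended to depth 0 and clamped at 0°. The
linear-in-time reading between markers is a modeling choice (constant
insertion speed between successive markers); it is isolated in
`monitoring_axis` so an alternative reading is a one-function change.
At least two markers are required, since extrapolation needs a slope.

## Tonotopy

Greenwood map in proportional-distance form, `F = A·(10^{a·x} − k)`,
`x = (L − d)/L`, with human constants A = 165.4 Hz, a = 2.1, k = 0.88 and
default duct length L = 36.2 mm. The proportional form is used so that an
individually measured L rescales the map without refitting constants;
with these values the map spans ≈ 19.85 Hz at the apex to ≈ 20 677 Hz at
the base. Depth is measured from the base (RW); the conversion to
apex-proportional distance happens in exactly one place, and strict
monotonicity is asserted in the tests to guard the classic base/apex
sign error. The inverse is closed-form. Constants and L are overridable
via YAML for non-human or individualized maps. Level-dependent tonotopic
shifts and otopathology corrections are out of scope.

## Array registry and standardized axes

When imaging is unavailable, axes come from the array's average
geometry: depths from the average apical insertion depth via the same
arithmetic-sequence rule, AIDs scaled linearly from the average AID at
the apical contact to 0° at depth 0 (the RW is the angle origin — a
convention, documented here, since average *basal* angles are not
published per array), and frequencies via Greenwood. The two routes
coincide exactly when imaging happens to measure the registry's average
geometry, which the tests assert.

The registry YAML ships nominal contact counts, active spans and average
insertion figures for common arrays, each with a provenance note; none
are vendor-certified, and entries whose averages are unknown are
explicit placeholders that refuse to produce axes rather than invent
geometry.

## Audiology

PTA is the arithmetic mean over 0.25, 0.5, 1, 2 kHz. No-response
frequencies enter as audiometer max + 5 dB; the substitution is enforced
at `Audiogram` construction so it cannot be skipped downstream.
`PTA_max` defaults to the mean of the per-frequency (max + 5) values
over the PTA frequencies, consistent with the substitution. HEARRING
bands: complete > 75%, partial 25–75% (boundaries inclusive), minimal
(0, 25), loss = 0%; HP is clamped to [0, 100], so postoperative
*improvement* reports as 100%.

## Insertion-pattern classifier

Only the two canonical shapes are modeled. Type A requires an
end-minus-start rise of at least `rise_min_db` (default 6 dB) with the
maximum in the final `end_window` fraction (default 0.2) of the course;
type C requires ends within `similar_tol_db` (default 3 dB) and a
maximum exceeding both ends by `rise_min_db` within the middle
`1 − 2·end_window` fraction (boundaries inclusive). Everything else —
including the further shapes of the wider typology (early peak, double
peak, flat) — is `other`. The thresholds quantify the qualitative
definitions ("overall increase", "similar amplitudes"); 6 dB is a
factor-2 amplitude change and 3 dB a factor-√2, natural units for dB-scale
similarity, and both are exposed parameters. Classification is invariant
under adding a constant to all amplitudes.

## Rendering

Shared log-frequency x-axis (low→high left→right, so insertion order
reads right to left), octave ticks; dB HL axis inverted per audiometric
convention; amplitude reference line at 0 dB re 1 µV (configurable). The
secondary AID axis is derived per tick by composing the Greenwood
inverse with the geometry's least-squares depth↔angle line, making the
two x-axes consistent by construction even though the AID axis is only
anchored at the end contacts. Phase unwrapping is available as a display
aid but off by default — recorded phases are plotted as-is. A series
whose amplitudes all lie at or below the 0 dB floor carries no
interpretable phase and is omitted from the phase panel. SVG output
fixes matplotlib's hash salt and strips the date metadata, so identical
inputs give byte-identical files.

## Synthetic validation: what it shows and what it does not

The validation cochlea is an Archimedean spiral `r(θ) = r0 − b·θ`,
chosen over a logarithmic spiral because its arc length has a closed
form — an exact, independent oracle for every depth. Defaults:
r0 = 1.72 mm, b = 0.004 mm/rad, apical contact at θ = 9.4 rad
(≈ 1.5 turns), giving ≈ 16 mm of arc for a 16-contact, 15 mm array and
17 landmarks — an insertion-depth/turn-count regime typical of a
mid-length array, with a decay gentle enough that the two-endpoint AID
interpolation is faithful (max deviation ≈ 1.3°; see the geometry
section for why stronger decay degrades it). Handedness exercises the
rotation-sense auto-detection. All randomness flows through explicitly
passed seeds; there is no global random state.

Synthetic measurements use a linear ramp (type A), a raised-cosine bump
(type C) and a flat control, with linear phase delay along the course;
synthetic audiograms are flat or high-frequency-sloping with the
no-response rule applied at the audiometer limit.

What passing does **not** show: robustness to real landmark-selection
error on real anatomy (the spiral is planar and noiseless by default; a
real cochlea is 3-D, and the slice overlay only approximates planarity),
correctness of any registry average, or the physiological validity of
the Greenwood constants for an individual ear. The geometry-recovery
tolerances (apical depth within 0.5%, AIDs within 2°) measure the
pipeline's numerical fidelity, not clinical accuracy.

## Problem sizes

The test suite and the acceptance script use the 10⁶-sample trajectory
(as in routine use), a 2001-point Greenwood round-trip grid, 1000 random
audiograms for the PTA oracle and 200 Monte-Carlo draws per classifier
class at 1 dB amplitude noise; the full suite runs in seconds.
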