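# Methods

This note documents the analysis conventions, the synthetic fiber model,
and the numerical choices behind `silkmech`.

## Coordinate conventions

All analysis runs on true stress–true strain curves referenced to the
maximum-supercontracted state of the fiber. Supercontraction conserves
volume, so the reference cross-section is `A0 = A_FS * L_FS / L0`
(forcibly-silked area and length, supercontracted gauge length). The
crosshead displacement stands in for the fiber extension: the fiber's
compliance dominates the metallic load train, so no extensometer or
machine-compliance correction is applied. Engineering magnitudes
`s = F/A0`, `e = dL/L0` map to true magnitudes `sigma = s(1+e)`,
`eps = ln(1+e)`; the inverse map is exact and is used by the generator to
emit machine records. Internal units: N, mm, s, µm² for areas, MPa for
stress; energy densities in MJ/m³ are numerically MPa·strain.

## Cycle segmentation

A cyclic test alternates slack take-up, loading, unloading, slack return
and a relaxation hold at the gauge position. Only the portions where the
fiber carries load belong to a cycle. Samples are classified against an
onset threshold `max(0.5 MPa, 1% of the global stress maximum)` — the
absolute floor guards low-stress tests, the relative term scales with the
specimen. Contiguous above-threshold runs become cycles; each run keeps
one at-or-below-threshold sample at either end so branches start and end
at (near-)zero load. Runs shorter than `min_points` (10) are noise;
runs separated by gaps shorter than `min_points` are merged *unless* the
later run reaches a new strain maximum, which distinguishes a
noise-fragmented unloading tail from a genuine next loading. The
loading/unloading split is the per-cycle stress maximum (later index on
ties); under stress noise the argmax can sit a sample past the strain
turning point, so each branch keeps its monotone strain subsequence
(noiseless data is untouched). A record whose stress never returns below
the threshold between cycles can instead be cut at time gaps ≥ 60 s
(`use_time_gaps`), matching the 20-min holds of the protocol.

The onset strain of a cycle is the strain of the last at-or-below-threshold
sample before the first sustained exceedance — the strain at which the
fiber starts to be subjected to load. On noiseless data this overestimates
the true onset by about `threshold / E` (≲ 2·10⁻³ strain); the bias enters
both the trend abscissae and the evaluation points, so fitted endpoint
values are affected only at the 0.1% level.

## Per-cycle metrics

**Elastic modulus.** Ordinary least squares (free intercept) over the
samples within a strain window of 0.01 starting at the first
above-threshold point. The window is small against the elastic extent
`sigma_y / E ≈ 0.012–0.04`, so the fit stays pre-knee; `r²` is reported and
flags fits that strayed across the knee.

**Yield stress (proportional limit).** The loading curve is intersected
with the straight line through `(eps_init, 0)` of slope `0.95 E`. The
anchor is the onset point, not the fitted intercept — the reproducible
reading of a construction defined by its slope alone. The curve leaves the
anchor above the line (its initial slope exceeds 95% of itself), so the
yield point is the first positive-to-nonpositive sign change of the stress
difference, linearly interpolated between samples. Requiring a strictly
positive difference before the crossing discards the trivial contact at
the anchor; a curve that never returns to the line (pure elasticity)
yields a no-yield result rather than an error. No minimum-strain exclusion
is applied: curves that bend immediately (e.g. saturating-exponential
knees) have their only crossing inside the modulus-fit window, and
excluding it would misreport them as elastic.

**Energies.** Absorbed energy is the trapezoidal integral of the loading
branch (negative stresses clipped to zero, so slack prefixes and noise
cannot produce negative energy). Dissipated energy is the shoelace area of
the polygon formed by the loading branch, the reversed unloading branch,
and vertical drops to zero stress at both ends; the closure therefore runs
along the strain axis. (Without the drops, threshold-trimmed branches
would close along a chord at threshold height whose area wobbles with the
sampling; with them, halving the sample step changes energies by well
under 0.1%.) Recovered energy between consecutive cycles is the area
enclosed between the previous unloading branch and the next reloading
branch on the union of their strain samples over
`[next onset, previous maximum]`, each branch extended with zero stress
beyond its own zero-stress end — closing the lens at the bottom. When the
two branches coincide within 10⁻³ of the cycle stress scale the loop
energy is fully recovered and the pair is flagged `concur`.

## Envelope, work to fracture, α*

The envelope interpolates `(eps_max, sigma_max)` of every complete cycle,
prepended with the origin, piecewise-linearly; queries beyond the last
knot are errors rather than extrapolations. Work to fracture is its
trapezoidal integral (exact for a polyline, hence invariant under knot
refinement).

α* registration translates the curve of interest toward smaller strain by
`delta ≥ 0` — a stiffer, strain-hardened curve registers onto the
compliant supercontracted reference at a positive shift; a signed search
is available behind a flag. "Concurrence" is operationalized as a sign
change (or exact zero) of the stress difference on the overlapping
support: a crossing rule is parameter-free, unlike a tolerance band.
Local slopes at the crossing come from a linear fit over ±0.01 strain —
point-to-point differences would amplify noise, and the window matches
the modulus-fit scale. The smallest admissible shift wins (deterministic
tie-break), scanned on a 10⁻⁴ grid and refined by bisection to 10⁻⁶.
The refinement treats admissibility as locally monotone between adjacent
grid points, which holds for smooth monotone curves.

## Trends

Modulus and yield stress are fitted against cycle onset strain by ordinary
least squares; endpoint values are read off the fitted lines at the first
and last cycles' onsets (not the raw per-cycle values). A zero-variance
response is fitted as a flat line with `r² = 0` by convention; degenerate
abscissae (all onsets equal) are an error. The yield trend is fitted even
though real fibers show large scatter in this parameter; interpretation is
left to the user.

## Synthetic fiber model

The generator emulates a displacement-controlled cyclic test of a single
maximum-supercontracted MAS fiber: 35 cycles of nominal true-strain
increment 0.025 at a true-strain rate of 0.5/min, 20-min holds at the
gauge position between cycles. It is phenomenological — no molecular or
microstructural state, no rate dependence (the emulated protocol uses a
single rate).

**Envelope (master curve).** `sigma_env = E1*eps` up to
`eps_y = sigma_y1/E1 = 0.04`, then `sigma_y1 + K*(eps-eps_y)^1.5`. The
hardening coefficient K is *derived* from the closed-form integral so that
the envelope's work to fracture at the calibration strain 0.875 equals
270 MJ/m³ (K ≈ 656.87 MPa for the defaults). Anchoring the calibration at
0.875 rather than at `n_cycles*d_eps` means a truncated test keeps the
same master curve, as a shorter test of the same fiber should.

**Schedules.** Cycle k loads from its residual strain `eps_r_k` with
modulus `E_k = E1 + (EN-E1) * eps_r_k / eps_r_N` — linear in onset strain,
which is the shape of the observed modulus trend — between E1 = 3 GPa and
EN = 12 GPa. The yield schedule is linear in cycle index from 120 to
140 MPa (the observed yield variation is mild and noisy; linearity is the
simplest monotone choice). Unloading follows
`sigma = sigma_max * ((eps-eps_u)/(eps_max-eps_u))^2` with
`eps_u = max(eps_r, eps_max - 1.2*sigma_max/E)` — steep initial unloading
and a concave return to zero, qualitatively like measured unloading
branches, whose exact functional form is not published. During the hold
the fiber recovers a fraction ρ = 0.3 of the strain accumulated in the
cycle: `eps_r' = eps_u - 0.3*(eps_u - eps_r)`. ρ, the unloading exponent
and the elastic-recovery factor are free model knobs, not measured
properties of any species. Because `eps_u` depends on `E_k` and `E_k` on
the residual strains, the schedule and the recursion are solved jointly by
fixed-point iteration (converges below 10⁻¹⁰ in a few passes); after
convergence the modulus-vs-onset relation is exactly linear, so the trend
fit recovers E1 and EN at the endpoints by construction.

**Reloading shape.** The loading branch must start at `(eps_r, 0)` with
slope `E_k`, show a proportional limit near the scheduled yield, and land
on the envelope at the previous maximum strain `eps_h` with matching value
and slope (this is what makes the response history-independent beyond
`eps_h`). A single cubic Hermite blend between the elastic-line tip and
the envelope cannot do this: for early/mid cycles the tiny stress gap with
a huge slope mismatch makes it non-monotone, and for late cycles its slope
stays near `E_k` so the 95%-modulus line would first cross far above the
scheduled yield. Instead the knee is S-shaped: elastic line to
`(eps_y_k, sigma_y_k)`, a low-slope plateau segment (slope
`min(envelope slope at eps_h, half the remaining secant)`, length 35% of
the remaining span), then a cubic Hermite stiffening segment to the
envelope. With those choices the Fritsch–Carlson bound `α²+β² ≤ 9` holds
by construction, so the cubic is monotone. When the elastic line meets the
envelope below the scheduled yield (early cycles, small residual strain)
the branch is simply `min(line, envelope)`; a virgin-like cycle (zero
residual, first-cycle modulus) retraces the envelope. Parameter
combinations that admit no monotone path raise a generation error naming
the cycle. Cycle 1 loads along the envelope and, reaching only 75 MPa,
never yields.

**Sampling and output.** The strain path is sampled at 2·10⁻⁴ strain per
point on active branches (≈37 k samples for the full test — the initial
slope window then holds ~50 points and trapezoidal energies are converged
to ≪0.1%) and ten times coarser on slack travel; time follows from the
constant true-strain rate with a 1 ms tick floor, and holds appear as
1200 s gaps at the gauge position. Optional Gaussian stress noise (seeded,
default off) perturbs the force channel only. Default geometry: 5 µm
forcibly-silked diameter, 25 mm → 20 mm supercontraction — plausible MAS
values, arbitrary but fixed. The same seed reproduces byte-identical
records.

**What the generator does not emulate.** Real records show drifting
strain targets (the nominal 0.025 increment "may be occasionally lower or
greater"), machine compliance, humidity/temperature variation, fiber
breakage, and cycle-to-cycle variability between specimens. Passing tests
on synthetic data therefore validate the *pipeline* — segmentation,
metric extraction, calibrated-parameter recovery — not any claim about a
particular spider.

## Numerical choices and degenerate inputs

- Duplicate time stamps keep the first occurrence; rows with non-finite
  entries are dropped with a count warning; fewer than 2 valid rows is an
  error.
- Results tables round-trip through CSV at 12 significant digits.
- A single monotone ramp segments into one cycle with an empty unloading
  branch, flagged incomplete; incomplete cycles get no loop metrics and
  are excluded from the envelope.
- A record with no sample above the onset threshold yields an empty cycle
  collection at the library level; the file-level pipeline treats it as a
  segmentation error.
- An all-equal response in a trend fit returns slope 0 with `r² = 0`;
  a single-cycle table reports raw values flagged degenerate.
- Anti-supercontraction geometry (`L0 > L_FS`) warns but computes.

## Known limitations

- The onset-threshold bias (~`threshold/E`) slightly shifts onset strains
  and, through the anchor, the measured proportional limits (≲1% for the
  calibrated model). Back-extrapolating the modulus fit to zero stress
  would remove it, at the cost of departing from the stated construction.
- α* refinement assumes local monotonicity of admissibility in the shift;
  pathological non-monotone curves may return a grid-resolution shift.
- The recovered-energy lens is a geometric construction; when the
  reloading path differs from the unloading path but no strain was
  recovered during the hold, it still reports the (small) enclosed area.
- No statistical inference on trends (no confidence intervals), no
  viscoelastic constitutive fitting, no breakage detection beyond the
  final incomplete-cycle flag.
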