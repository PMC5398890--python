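# Methods

## Scope

`glicgate` models and analyzes the gating of a proton-activated
pentameric channel as observed through three complementary readouts:
site-specific fluorescence quenching (conformation), voltage-clamp
currents (activity at steady stimulation) and thallium-flux quenching
in liposomes (activity milliseconds after stimulation).  The package
has two halves that are kept strictly separate: a synthetic-data
generator that encodes explicit study conditions, and an analysis
pipeline that never sees the generator's parameters.  Every pipeline
result reported by the tests or by `scripts/acceptance.py` is obtained
by fitting simulated observations, not by reading the generator.

## Kinetic model

Gating is a continuous-time Markov chain over four conformations in a
linear chain,

    R (resting) <=> P (pre-active) <=> O (open) <=> D (desensitized)

with proton-dependent forward rates following a Hill-type law
`k(H) = k_max * H^n / (H^n + K^n)` (H the proton concentration in
mol/L) and proton-independent backward rates.  The scheme treats the
pre-activation step as a conformational transition with instantaneous
proton equilibration; whether it is binding-limited is left open by the
data it emulates, and nothing downstream depends on that choice.
Occupancies are propagated with the matrix exponential of the
generator, which is exact for a time-homogeneous chain; a stiff ODE
integration serves as an independent oracle in the tests (agreement to
1e-6).

Default rates (units 1/s; pK in pH units):

| transition | k_max | pK   | n | reverse |
|------------|-------|------|---|---------|
| R -> P     | 12500 | 4.80 | 2 | 125     |
| P -> O     | 90    | 4.35 | 2 | 0.75    |
| O -> D     | 4.5   | 4.50 | 2 | 0.01    |

These defaults are a calibration, not a fit: they were chosen once so
that the scheme reproduces the study conditions the observables imply —
pre-activation relaxing in well under 1 ms at pH <= 5 with a
steady-state midpoint near pH 5.8; opening in the reconstituted-vesicle
regime relaxing in ~13 ms at pH 4, ~250 ms at pH 5 and ~1.3 s at pH 6,
with a quasi-steady open-occupancy midpoint near pH 5.3; and
desensitization entering with a >= 200 ms time constant, effectively
absorbing over a 30 s window.  Patch-clamp activation of this channel
in excised mammalian-cell patches is reported substantially slower
(tens to ~150 ms at pH 4); we calibrate opening to the faster
liposome/vesicle regime because the flux assay demonstrably reaches
maximal activity within the shortest 15 ms pre-mix delay, which is
incompatible with ~50 ms opening in the same preparation.  This is a
deliberate preparation-specific choice, documented here once.

A negative-control scheme (`build_concerted_scheme`) removes the
distinct pre-active step: the proton-dependent transition is fast at
every pH and highly cooperative (n = 4, as expected for a single
concerted switch coupling several protonation events), the P <-> O
isomerization is a rapid proton-independent equilibrium biased toward
O, and desensitization is switched off.  The last point matters: the
desensitized state is also compacted, so with a slow absorbing sink a
30 s fluorescence read and a 15 ms flux read would differ by a small
kinetic-window offset (~0.2 pH units) even without any intermediate;
removing the sink isolates the question the control is asked.

The `modulator_shift` field scales the forward pre-activation and
opening rates, giving a one-parameter hook for a negative allosteric
modulator (rightward midpoint shift); no binding model is implied.

## Fluorescence sensors

Each sensor is a (bimane position, quencher) pair with one brightness
per state, in denatured-reference units (fluorescence relative to the
fully denatured protein).  The pre-active state carries the compacted
extracellular-domain signature, so sensors reporting that compaction
assign nearly equal brightness to P, O and D and put most of their
amplitude into the dead-time step; the pore-level reporter at position
243 spreads amplitude across opening and desensitization instead.
Default brightness values were set from the steady-state intensity
levels and stopped-flow amplitude decompositions of the six retained
reporters (136-101, 135-72, 133-103, 33-160, 250-197, 243); they shape
amplitudes only, never time constants.

## Stopped-flow simulation and analysis

The acquisition protocol is a 30 s recording with a 2.1 ms mixing dead
time and three sampling regimes (100 us to 0.5 s, 1 ms to 1.5 s, 50 ms
to 30 s); the first 3 ms after the dead time are excluded from fits,
so analysis starts at 5.1 ms.  Simulated traces add Gaussian noise
(default sd 1% of full scale) and a multiplicative linear drift
(default 0.1%/s); neither value is reported by the emulated
experiments, so both are documented guesses chosen to look like
realistic instrument records.  Each test trace is paired with a pH-8
reference sharing the drift model; normalization divides by a robust
(soft-L1) linear fit of the reference, which removes shared
drift/bleaching and expresses the signal relative to the pH-8 level
(baseline 1.0).

Decays are fitted with `y(t) = F + F1 e^(-k1 t) + F2 e^(-k2 t) +
F3 e^(-k3 t)` by variable projection: rates are optimized by bounded
nonlinear least squares on log-rates while amplitudes are solved
exactly by linear least squares at each step.  Multi-start seeds are
log-spaced over 0.03-400 /s; the window spans 5.1 ms-30 s, i.e. rates
of 0.033-196 /s, and the upper end is kept above that so ~9 ms
components near the window edge are reachable.  The number of
components (1-3) is chosen by corrected Akaike information with a
conservative margin of 10, plus two degeneracy guards: models with
near-coincident rates (< 5% apart) or amplitudes within rounding of
zero are discarded.  Residuals may be weighted by the local sampling
interval (default on) so the 100 us regime does not dominate the
fit; the unweighted behavior is one switch away
(`weight_by_regime=False`).

Phase accounting evaluates the fitted model at the 5.1 ms window start:
the dead-time ("very fast") amplitude is that value minus the pH-8
baseline, each exponential contributes its remaining amplitude from the
window start, and the maximal variation is the sum of absolute phase
amplitudes (which collapses to |final - baseline| for unidirectional
traces).  Percentages therefore add to 100 by construction; traces
whose maximal variation is below 10% of baseline are flagged as showing
no variation and excluded from pooling.

## Phase clustering

Resolved time constants are pooled across sensors and pH and binned in
log10(tau) with width 0.4, anchored at the 5.1 ms analysis start so
everything faster falls into the very-fast phase by construction.
Components are pooled only if resolved within the 30 s window and with
absolute amplitude above 2.5x the fit residual sd (small spurious
components absorb noise and drift).  Clusters are runs of occupied
bins; bins holding at most 10% of the pooled counts do not interrupt a
gap (stray split components between dense clusters are gap noise), and
boundaries are drawn through gap middles.  When more than three runs
appear, only the widest gaps act as boundaries.  The cluster edges are
data-driven outputs, not constants: with the default calibration the
three clusters fall near 5-30 ms, 200-500 ms and 1.3-8 s, overlapping
the fast / intermediate / slow windows the stopped-flow literature
reports.

## Dose-response analysis

Hill fits are performed in proton-concentration space, `y = a x^nH /
(x^nH + EC50^nH)` with `x = 10^-pH`, matching the printed functional
form; pH50 = -log10(EC50) exactly.  Decreasing curves are fitted on
their mirror with a floating mirror level, so one functional form
serves both directions and recovery stays exact when the sampled top is
unsaturated; a floating-baseline option exists for shallow curves but
is off by default.  Non-monotonic curves are fitted on their dominant
limb with a warning, or rejected when no limb dominates (the
inverted-bell reporter is summarized descriptively, not Hill-fitted).
Peak-current curves can drop trailing low-pH points that fall below the
running maximum (desensitization droop) before fitting.

The intermediate-state comparison takes the fluorescence midpoint minus
the flux midpoint; a separation of at least 1.0 pH unit (one order of
magnitude in proton concentration, configurable) raises the flag.  In
seeded end-to-end runs the pre-active default scheme yields a
separation of ~1.2 with the flag raised, and the concerted control
~0.06 with the flag down.

## Flux assay simulation and analysis

Each simulated assay draws a liposome population (lognormal diameters,
mean 150 nm, log-sd 0.25; Poisson channel counts, mean 3) and exposes
it to 45 mM quencher (90 mM thallium nitrate buffer mixed 1:1).  ANTS
intensity relaxes pseudo-first-order toward the Stern-Volmer
equilibrium level `1/(1 + Ksv [Tl+])` (Ksv default 100 /M) with a
per-liposome rate `leak + r0 * channels * O(delay + t) / volume`; open
probability keeps evolving during the 1 s recording, which is what
makes rates decline at long pre-mix delays (activation is complete
before 15 ms, desensitization then erodes the open population).  The
ensemble trace is the volume-weighted average.  The single-channel
influx scale r0 = 47 /s (per open channel in a 150 nm liposome) and
Ksv are a joint calibration chosen so the default scheme gives ~80 /s
quench rates at pH 4.2 with the 15 ms delay; this is a calibration of
the readout scale, not channel physics.

Analysis fits the first 100 ms with the stretched exponential
`F(t) = F_inf + (F0 - F_inf) exp(-(t/tau0)^beta)` and reports the rate
at 2 ms, `k = (beta/tau0)(2 ms/tau0)^(beta-1)`.  beta is bounded in
(0, 1.2]: physically beta <= 1 for mixtures of exponential rates, and
the slack absorbs noise plus the brief sigmoid onset left by residual
activation.  F_inf is free, initialized from the 1 s tail; the no-Tl+
reference trace is used for quality control only.  Traces that drop
less than 5% of their initial intensity within the window are flagged
"no activity" and pinned at the leak rate instead of being fitted.
Rates are computed per repeat and averaged after fitting.  A bounded
trust-region solve is polished by an unconstrained
Levenberg-Marquardt pass when the optimum is interior, giving
machine-precision recovery on noiseless in-class data.

The homogeneous-limit check (beta -> 1) uses a monodisperse population
with a fixed channel count at a delay where open probability is
quasi-stationary (150 ms, desensitization-free scheme): with channels
still activating, even a homogeneous population decays
non-exponentially, which would test the wrong thing.

## Structural geometry

Coordinates are parsed from PDB files (gemmi; first model, altloc A).
Pair distances use Cb atoms (Ca for glycine) by default because the
deposited difference tables for this system are Cb-based; a Ca
selector is available since the quenching-radius literature quotes
Ca-Ca.  Quenching radii are 15 A (Trp) and 10 A (Tyr), boundary
inclusive — the radii are approximate, so the convention is fixed here
rather than pretending precision.  Superposition is a Kabsch
least-squares fit (SVD with reflection guard) on atoms matched by
(chain, residue, atom name).  The minimal fluorophore-quencher
distance is an exhaustive heavy-atom minimum, checked against a
brute-force oracle in the tests.  The fluorophore's hetero residue
name is resolved from the file at run time, not hard-coded.  The two
deposited-structure reference values (minimal bimane-W72 distance,
pentamer Calpha RMSD between the labeled and open-state models) can
only be recomputed when the coordinate files are present under
`data/structures/`; `analysis/06_structure_distances.py` documents how
to fetch them and falls back to a clearly-labeled synthetic toy
demonstration otherwise.

## What the generator does and does not emulate

Emulated: pH-dependent state occupancies; per-state sensor brightness;
stopped-flow dead time, triphasic sampling, noise and drift with a
matched reference; double-exponential activation currents scaled by
quasi-steady open occupancy; heterogeneous liposome populations with
Poisson loading, Stern-Volmer equilibria, leak, and a pore-blocker
control; seeded determinism throughout (one top-level seed, per-trace
derived streams).

Not emulated: photophysics beyond state-dependent brightness (no
spectra, no bleaching kinetics), proton-binding microsteps, single-
channel stochastics in the oocyte currents, day-to-day preparation
variability, and any structure-based rate prediction.  Passing tests
therefore demonstrate that the analysis pipeline recovers what this
model family can express — they do not certify the fitted mechanisms on
real recordings, where state brightness, noise structure and liposome
statistics are all richer.

## Numerical choices and degenerate inputs

Probability conservation is enforced to 1e-9 and verified per step;
occupancium round-off is clipped and renormalized.  All optimizers run
with tolerances at 1e-15 and explicit multi-starts; rate/time-constant
orderings are fixed (rates descending, activation taus ascending) with
ties broken by the sort.  Degenerate inputs fail loudly and early:
non-monotone grids, non-normalized initial occupancies, negative rates,
mismatched brightness vectors, non-positive references, all-zero
current tables ("non-functional"), flat rate profiles ("not
Hill-fittable") and empty atom selections raise with the offending
field named.  Problem sizes in the default test and acceptance runs
(six sensors x three pH stopped-flow fits, 300-liposome ensembles,
20-50 seed Monte-Carlo batches) were chosen as the smallest sets that
exercise every code path with stable statistics.

## Known limitations

The linear four-state chain cannot represent parallel desensitization
entry or multiple open states; the 243 reporter's multi-phase signal is
reproduced through per-state brightness without claiming which states
move.  The stretched-exponential rate at 2 ms is a convex readout of
underlying activity, so dose-response midpoints from flux rates carry a
small systematic offset relative to occupancy midpoints (visible in the
round-trip tests' 0.2 pH-unit tolerance).  The concerted control's
separation is not exactly zero for the same reason.  Cluster
identification assumes well-separated timescales; data with a
continuum of rates would need mixture modeling, which is out of scope.
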