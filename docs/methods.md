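# Methods

## The acquisition model

`ddasim` simulates a tandem mass spectrometer coupled to liquid
chromatography at the level that matters for scan scheduling: a clock, a
stream of MS1 survey scans, and a controller that turns each survey scan
into at most *N* MS2 fragmentation requests. Every scan advances the
clock by a fixed duration — 0.59 s for MS1 and 0.19 s for MS2, typical
averages for an Orbitrap-class instrument — so a full duty cycle at
N = 10 takes at most 2.49 s. An injection ends when the clock passes
`max_rt`. Ion physics below this level (AGC, ion accumulation, chimeric
isolation, fragment chemistry) is out of scope; MS2 spectra carry
deterministic placeholder fragments only so that emitted mzML is
well-formed.

Ground truth is a set of chemicals, each a single ionized species with a
fixed m/z and a chromatographic elution profile — Gaussian with apex
intensity `A`, apex time `t0` and width `σ` by default, or an empirical
interpolated profile when imported from a fullscan mzML. An MS1 scan at
time `t` reports every chemical's profile evaluated at `t` (a detection
floor, default 0, can suppress weak points). An MS2 scan executed at
time `t` records as its precursor intensity the most intense model point
inside the isolation window *at that moment*, so late fragmentation of a
fading peak is penalized the way it would be on an instrument; which
instant the real acquisition chain samples is not observable from the
outside, and using the MS2 clock time is what keeps intensity-based
exclusion meaningful.

## RoI tracking and exclusion state

Regions of Interest are built online with the centwave point-linking
rule: each scan point at or above the intensity threshold extends the
live RoI whose last m/z is nearest within tolerance (10 ppm by default;
ties go to the lower-m/z RoI, at most one point per RoI per scan) or
seeds a new RoI; an RoI unmatched for more than `max_missed` (3)
consecutive scans closes. An RoI's bounding box at query time spans the
points seen so far — it grows "to the right" in retention time as the
peak elutes.

Within-injection exclusion of a fragmented RoI supports three schemes:

* **plain** — hard exclusion for `rt_tol` (15 s) after the last
  fragmentation;
* **weighteddew** — weight 0 until `t0` (3 s), then a linear ramp back
  to 1 at `rt_tol`, trading strict exclusion for graded re-eligibility;
* **smartroi** — re-enabled by a state machine: when current intensity
  rises to `intensity_increase_factor` (10) times the minimum seen since
  fragmentation, when it falls below `drop_fraction` (0.1) of the
  intensity at fragmentation (the peak has decayed; the reference is
  reset), or `reset_length` (100 s) after the event.

Non-RoI strategies use exclusion boxes instead: each fragmentation event
creates a window spanning the event's m/z ± 0.01 Da and rt ± `rt_tol`.
The rt span is symmetric about the event. Within an injection this is
indistinguishable from a forward-only window (a scheduling decision
never precedes the event), but it is essential once windows are carried
across injections: with a forward-only span, a replayed injection
reaches each peak's scheduling decision just before the remembered
window starts and iterative exclusion would never exclude anything.

Between-injection memory is strategy-specific and lives in a registry
with two populations. *Within-injection* windows expire with their rt
span and are dropped (or, for the iterative-exclusion strategies,
promoted) at injection end; *carried* windows persist for the remainder
of the experiment and only accumulate. Carried windows are either
promoted DEW boxes or the final bounding boxes of fragmented RoIs, each
holding the precursor intensity of its fragmentation event (the maximum
over events for an RoI box). The lookup `φ` — the largest intensity of
any carried window containing a point — deliberately ignores
within-injection DEWs, and the within-injection indicator never consults
carried windows in the intensity strategies, so the two lifetimes play
the separate roles the scoring model assigns them.

When an RoI trace is treated as a rectangle (as the query of an area
score or as a carried box), it is padded by 0.01 Da in m/z and 1 s in
rt. The m/z pad reflects what an RoI box physically is — the tolerance
band around the trace, not the bare observed extent, which for a
noise-free trace is exactly zero wide (zero area would make every
dissection degenerate and disable the area strategies); the rt pad is
about one duty cycle, the sampling resolution of the trace. Both pads
are configurable.

## Area scoring

The dissection of a query rectangle against a set of overlapping boxes
is computed on the grid of all rt and m/z breakpoints clipped to the
query: each grid cell is fully inside or outside every clipped box, so
its owner set can be read off its centre. Pieces are interior-disjoint,
their areas sum exactly to the query area, and each carries the exact
subset of boxes covering it. Intervals are closed; rectangles touching
along an edge do not overlap (measure-zero sets cannot affect an area
integral). Zero-area owner combinations are excluded from the
region-intensity sum (they would otherwise contribute `λ^0 = 1`
spuriously), and non-positive modified intensities contribute 0, since a
negative base under a fractional exponent is undefined. A zero-area
query is flagged degenerate and treated as fully uncovered (`prop = 1`).
The intensity-non-overlap score clamps at 0 whenever the region sum is
at most 1, so candidates whose log would be non-positive are simply
ineligible.

Ranking is by descending score, then descending raw intensity, then
ascending m/z — a total order, so replays are deterministic.

## The synthetic cohorts

The generator emulates a multi-sample metabolomics batch at desk scale.
Chemicals draw m/z uniformly from 70–1000 (pairwise separated by at
least 1.4 Da, twice the 0.7 m/z isolation width, so ground truth is
unambiguous), apex times uniformly inside a 150 s gradient (kept 3σ_max
clear of the edges), apex intensities log-normally (median 5 × 10⁵
counts, σ_ln = 1.5), and chromatographic σ uniformly from 3–10 s. Shared
chemicals appear in every sample with an independent log-normal
intensity factor (σ_ln = 0.3) per sample; unique chemicals appear in
exactly one. The gradient length was chosen so that peak arrival is
comparable to the ~4 MS2/s duty-cycle capacity at N = 10 — the
oversubscribed regime in which scan prioritization matters at all; with
a much longer gradient every strategy trivially covers everything in one
injection.

The aligned truth-peak list contains one row per chemical and one box
per sample where it is present: rt apex ± 3σ (covering >99% of the
profile, mimicking picked-peak bounds), m/z ± 0.01 Da, and the
per-sample apex height. Alignment is by construction — the same chemical
id is the same row — standing in for peak-picking and alignment of real
data.

Two packaged designs are used throughout the tests and the acceptance
script: 300 chemicals injected 10 times (repeated single sample), and
six samples of 250 shared + 50 unique chemicals each injected four times
in the interleaved order S1-S2-S3-S4-S5-S6-S1-… so no sample leads
another by more than one repeat.

What the generator does **not** emulate: retention-time drift between
injections (off by default, available as seeded Gaussian jitter), m/z
measurement noise, isotope envelopes and adducts, co-eluting species
inside one isolation window, and detector saturation. Passing the
packaged benchmarks therefore shows that the strategies' *relative*
behavior (flat TopN, carryover coverage gains, continued
intensity-coverage gains of intensity-aware strategies) follows from the
scoring model itself, not that absolute coverage figures transfer to any
particular instrument or matrix.

## Evaluation metrics

Peak coverage after injection *k* is the fraction of aligned rows with
at least one fragmentation event, in any sample where the row has a box,
inside that box in injections ≤ *k*. Intensity coverage is the sum over
rows of the best matched precursor intensity so far — 0 if uncovered,
capped at the row's apex so the metric is bounded by 1 even if the
simulated intensity at the event instant exceeds the picked apex —
divided by the sum of row apexes (each row contributing its largest
per-sample apex). Both series are cumulative and non-decreasing by
construction. Exact matched-intensity conventions differ between
pipelines (e.g. whether the triggering MS1 point or the execution-time
intensity is used); these definitions are this package's canonical ones,
and any alternative can be computed from the same event logs behind the
same report type.

## Numerical and I/O choices

Natural logarithms throughout (ranking is base-invariant). Retention
time is stored in seconds everywhere; peak lists exported in minutes
(the MZMine convention) are converted at the CLI boundary via an
explicit unit flag. Event logs, registries, cohorts and reports are
plain CSV; configuration round-trips losslessly through YAML. mzML is
written and read by a minimal built-in codec (centroided spectra, 64-bit
little-endian arrays, optional zlib, scan times in seconds, precursor
isolation metadata on MS2 spectra) that resolves controlled-vocabulary
terms by accession.

## Known limitations

* SmartRoI semantics follow the three-trigger state machine described
  above; other implementations may differ in how the drop trigger resets
  its reference.
* Carried RoI boxes freeze at injection end; a strategy cannot benefit
  from a box created earlier in the *same* injection (within-injection
  repeats are governed by the RoI DEW instead).
* The evaluation assumes the truth boxes are mutually disjoint, which
  the generator guarantees by its m/z spacing rule; overlapping
  picked-peak lists from real data may attribute one event to several
  rows.
* Duty cycles are rigid (one MS1, then the granted MS2s); the simulator
  does not model vendor-specific scheduling overheads or dynamic scan
  times.
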