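# Methods

This note documents the models and numerical procedures implemented in
`channelgate`, the assumptions behind them, and what the synthetic
generators do and do not emulate.

## Pore profiling and the gating call

The pore radius profile follows the maximal-free-sphere construction:
in the channel frame (pore axis along z), the free radius at a point
`p` is `min over atoms (|p - x_i| - r_vdw,i)`, and the profile value at
axial position `z` is the maximum of the free radius over in-plane
centre positions `(x, y)`. Van der Waals radii default to the Bondi
set (C 1.70, N 1.55, O 1.52, S 1.80 Å, user-overridable); hydrogens are
ignored, consistent with heavy-atom models and a heavy-atom radius set.

Numerics: the z grid has a 0.25 Å step; at each slice the centre is
located by a 0.2 Å grid search followed by Nelder–Mead refinement
(`xatol` 10⁻³ Å). The in-plane step between adjacent slices is bounded
at 1 Å (3 Å for the first slice), which enforces a connected centre
path — with an unbounded step the probe can tunnel through a discrete
atom shell or escape through a pore mouth into bulk, where the free
radius is unbounded. Radii are capped at 10 Å; slices with no atoms
in reach are reported at the cap and flagged. For efficiency the atom
slab consulted per slice is trimmed adaptively to `r_prev + step +
0.5 Å` plus the largest vdW radius, with an automatic full-width retry
when the pore widens faster than that allowance. On the bundled
cylinder and hourglass fixtures the profiler is accurate to better
than 0.1 Å everywhere (the residual error comes from the discreteness
of the fixture's atom rings, not from the search).

The channel axis is estimated, by default, from C4 symmetry: for every
residue number present in all chains of the selection, the centroid of
the per-chain copies lies on the symmetry axis; the axis is the
principal direction through these centroids. A plain principal-axis
mode and an explicit point+vector override are available.

The gate is called **open** when the minimum radius strictly exceeds
the probe radius, default 1.4 Å — the radius of a water molecule. A
minimum exactly at the probe radius is closed; sub-angstrom minima
(≈0.4 Å in a closed gate) exclude even dehydrated ions, while minima
above ~2.3 Å pass hydrated cations.

## Structural state comparison

Superposition uses the Kabsch SVD solution with the determinant
correction, so the fitted rotation is always proper; RMSD is evaluated
over Cα pairs matched by (chain, residue number) intersection — no
sequence alignment, no gap handling. Alternate locations are resolved
before analysis (highest occupancy, ties toward altloc `A`).

Domain rotations are measured in two stages: both states are first
superposed on a selection assumed static (for TRP-channel work, the
S1–S4 Cα atoms of all subunits), then the rigid rotation mapping the
domain's Cα set from one state onto the other is fitted and its angle
taken from the trace identity `cos θ = (tr R − 1)/2`. The *in-plane*
mode projects the domain coordinates onto the plane orthogonal to the
membrane normal (the pore axis) and reports the optimal 2-D rotation
about that normal; it is the right reading for "rotation in the plane
of the membrane". Published rotation figures for flexible domains
depend on the frame convention, so agreement with them is expected to
be approximate (a few degrees).

Secondary structure is assigned from the backbone hydrogen-bond
pattern: residue *i* is **α** when its carbonyl O accepts from the
amide of *i+4*, **π** when bonded to *i+5* (π takes precedence when
both hold, which is what makes a π-bulge detectable inside an
α-helix), **3₁₀** when bonded to *i+3* only. The bond criterion is
O···N ≤ 3.5 Å with an O···H–N angle ≥ 120°; amide hydrogens, absent
from crystallographic and cryo-EM models, are reconstructed on the
external bisector of the C(prev)–N–CA angle at 1.01 Å. Prolines cannot
donate. Helix length changes are reported as helical-residue counts:
at 3.6 residues per turn, a two-turn change is ~7 residues.

## Trajectory analysis

Frames are aligned by translating the centre of mass of a reference
selection to the origin (for TRPM7, the four Y1085 Cα atoms); full
superposition is optional. Permeation counting is a per-particle
finite-state machine over the z series: *idle* → *armed* when the
particle crosses the entry plane toward the exit; an event fires on
the subsequent exit-plane crossing; re-crossing the entry plane first
disarms. Crossing detection is a sign change between consecutive
frames, without interpolation. Water passages use entry z = −2 Å and
exit z = −18 Å (downward); full-pore ion passages use −18 → +18 Å
(upward). With `direction="both"` the mirrored plane pair counts the
opposite direction. A z jump larger than half the box (or an explicit
`wrap_jump`) is treated as a periodic/recycling move: it resets the
machine and never counts. Counts are binned by event exit time into
60-ns blocks by default, with an optional initial discard window;
rates are per-block counts over block length, reported as mean ± SD
across blocks.

Conductance from ion counts under an applied voltage is
`I = N·e/T`, `g = |I/V|` (N crossings in simulated time T at membrane
voltage V); 37 crossings in 100 ns at 600 mV give 59.28 pA and
98.8 pS. The sign convention reports magnitude: crossings are counted
with the field, so a negative voltage driving downward events still
yields a positive conductance.

χ1 rotamer series (N–Cα–Cβ–Cγ, with the Cγ-equivalent taken per
residue type) are wrapped to (−180°, 180°] and summarised with
circular mean and SD. A residue is labelled *stable* when the circular
SD is ≤ 20° and *fluctuating* when the series visits both the −80°
and −180° rotamer wells (±25°) — the two-well criterion takes
precedence, since a bimodal series can have a misleadingly small
circular SD near the wrap point. Side-chain hydrogen bonds use
donor–acceptor ≤ 3.5 Å and donor–H–acceptor ≥ 150°, with hydrogens
rebuilt per frame: backbone amides from C(prev)/N/CA, and the sp²
amide pairs of Asn ND2 / Gln NE2 from the amide plane (both candidate
H positions are tried). Occupancy is the bonded-frame fraction.

## Single-channel analysis

All-points histograms bin every current sample with edges aligned to
multiples of the bin width. Current levels are located by a 1-D
Gaussian mixture (EM, components reported sorted by mean, convergence
flagged); at negative holding potentials the open level is the most
negative component. Idealization uses a half-amplitude threshold: the
state switches when the current crosses the midpoint of the closed and
open levels and stays there for at least 2 samples (shorter excursions
are absorbed into the enclosing dwell — an anti-noise rule, at the
cost of missing genuinely brief events). Dwell durations always
partition the trace exactly. Po per trace is open time over total
time; across traces the mean ± SEM (SD/√n, undefined and flagged for
n = 1) and the summed transition count are reported. Traces whose
amplitude exceeds 1.5× the unitary current for 4 or more consecutive
samples are rejected as multi-channel recordings. Voltage-ramp
analysis maps sample index linearly onto the −100 → +100 mV / 50 ms
ramp and reads currents at ±80 mV, normalised to cell capacitance as
pA/pF.

## Ca²⁺ flux calibration and dose–response

The aequorin calibration line is

```
p[Ca²⁺]ᵢ = 0.332588 · (−log k) + 5.5593
```

where k is the photoprotein consumption rate: the interval's counts/s
divided by the total counts of the run (`grand_total`, the default and
literal convention — the terminal lysis emission is part of the
total), or by the counts still unconsumed at that interval
(`remaining`, the classical fractional-rate convention). The log base
is taken as 10, the pCa convention; it is configurable, and the k = 1
anchor (pCa = 5.5593 exactly) is base-independent. Intervals with
k = 0 have undefined pCa and are flagged, not dropped. An optional
background series (an inactive-mutant control) is subtracted
interval-wise before calibration.

Dose–response data are fitted with the four-parameter logistic

```
E(c) = E_min + (E_max − E_min) / (1 + (c/IC50)^h)
```

for inhibition, with the concentration ratio inverted for activation.
A *literal* variant with numerator `(E_max + E_min)` is kept behind a
flag for exact replication of the published formula, which we read as
a sign typo: the corrected form is the one whose limits are E_max at
c → 0 and E_min at c → ∞ and whose midpoint at c = IC50 is
(E_max + E_min)/2. Fitting is nonlinear least squares (lmfit) with
data-driven starts (extreme-concentration means, geometric-midpoint
IC50, h = 1), IC50 > 0 and h ∈ (10⁻³, 20) bounds, and covariance-based
standard errors; flat data and non-convergence are flagged rather
than returning a spurious IC50.

## Synthetic generators: what they emulate

All generators draw from one numpy `default_rng` PRNG (PCG64,
platform-stable) with an explicit
integer seed, default 0; equal specs give byte-identical output.

* **Pore fixtures** place rings of pseudo-atoms with centre radius =
  target free radius + vdW radius, so the analytic profile is known by
  construction (hourglass profiles interpolate linearly in z between
  throat and mouths; rings every 0.5 Å, 48 atoms per ring). They test
  geometry only — no B-factors, no side-chain texture, no asymmetry.
* **Brownian pore trajectories** are overdamped random walks in a
  cylinder: diffusion 0.2 Å²/ps (bulk-water-like), optional axial
  drift standing in for the electrophoretic velocity under a membrane
  field, specular radial reflection, and recycling at the z bounds
  (periodic wrap with a fresh radial position). The snapshot stride is
  1 ps so the per-frame diffusive step (~0.6 Å) resolves plane
  crossings. The steady-state passage rate is n·|v|/L, which the
  counter must match within 3 SE over seeds once the startup transient
  (~1 ns: particles that begin inside the plane band never arm for
  their first passage) is discarded. The surrogate reproduces
  *counting statistics only*: no electrostatics, no single-file
  effects, no ion–ion correlations, no solvent structure — so
  agreement here validates the event counter, not any conductance
  physics.
* **Markov gating traces** are exact two-state continuous-time Markov
  chains (exponential dwells, stationary initial state) digitised at
  2 kHz over 200 s, with unitary current −5 pA, closed 0 pA, and
  Gaussian noise SD 0.5 pA (SNR 10). The closing rate 50 s⁻¹ (20 ms
  mean open time) with the opening rate set from the target Po spans
  the reported Po range 0.02–0.63 with hundreds to thousands of
  events per record. Real recordings add filtering artefacts, drift
  and subconductance states that the generator omits; Po recovery
  within ±0.02 here demonstrates the idealizer's correctness, not
  robustness to those artefacts.
* **Luminescence series** invert the calibration line per 1-s interval
  (counts = k·total), with the unconsumed remainder emitted as the
  terminal lysis bin; a pCa trajectory whose summed rates would exceed
  the total photoprotein is rejected. Optional Gaussian count noise.
* **Dose–response datasets** evaluate the corrected logistic on eight
  half-log-spaced concentrations (0.01–30 µM, bracketing the ~0.2 µM
  IC50 scale of potent channel inhibitors), six replicates, additive
  Gaussian noise with SD 5 on a 0–100 effect scale (5% of span).
  Under exactly these conditions the fitted IC50 has ~7% sampling SD,
  so accuracy statements are made on the mean absolute error across
  seeded datasets (measured ~5%), with per-dataset checks against the
  fit's own standard errors.

## Problem sizes

Defaults are desk-scale by design: pore profiles over ±18 Å at 0.25 Å
resolution run in ~1 s; Brownian ensembles of 50 particles × a few
thousand 1-ps frames give hundreds of passages; 200-s gating records
at 2 kHz are 4×10⁵ samples. These sizes make every statistical
tolerance in the test suite reachable while keeping the full suite in
tens of seconds.

## Known limitations

* The profiler reports a single connected centre path; bifurcated or
  strongly tilted pores need an explicit axis.
* Helix assignment requires a contiguous single-chain backbone span;
  chain breaks mark residues unassigned rather than bridging them.
* H-bond hydrogen reconstruction covers backbone amides and Asn/Gln
  side-chain amides; other donors require explicit hydrogens.
* The idealizer has no missed-event correction; at open/closed dwell
  times approaching the sampling interval, Po estimates bias toward
  the majority state.
* `remaining`-denominator calibration amplifies noise late in a run as
  the remaining-count denominator shrinks.
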