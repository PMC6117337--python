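# Methods

`microstim` models how the electric fields of simultaneously active
intraneural microelectrodes interact to recruit myelinated axons, and
quantifies the consequence for neural recruitment: the **volume ratio**
between tissue activated by synchronous two-electrode stimulation and the
union of the volumes each electrode activates alone.

## Tissue and field model

Electrodes are ideal point current sources in an infinite, homogeneous,
anisotropic volume conductor (return electrode at infinity).  The potential
at displacement (Δx, Δy, Δz) µm from a source carrying I µA is

    V(mV) = 10 √(ρx ρy ρz) I / (4π √(ρx Δx² + ρy Δy² + ρz Δz²)),

with resistivities in Ω·cm; the factor 10 makes the µm/µA/Ω·cm/mV unit
system consistent.  Defaults are ρz = 175 Ω·cm along the fiber axis and
ρx = ρy = 1211 Ω·cm transversely — dorsal-column–derived values commonly
used for peripheral nerve, and the subject of the sensitivity sweep.
Axes: x transverse, y depth, z longitudinal; axons run along z.  Fields of
multiple electrodes superpose linearly.  What is *nonlinear* is the axon's
spike initiation, which is the entire subject of the study.

Stimuli are charge-balanced biphasic pulses: a cathodic phase (default
200 µs) followed immediately by an anodic phase of half amplitude and twice
the duration.  Reported amplitudes are cathodic magnitudes, 1–30 µA by
default.  Asynchronous stimulation means non-overlapping pulses with no
residual membrane state between them, so it is modeled as independent
single-electrode simulations.

Not modeled (deliberately): finite electrode geometry, electrode–tissue
interface impedance, encapsulation, and the fascicular perineurium.  The
perineurium omission matters most: it would confine current within a
fascicle and is expected to *strengthen* interaction effects for
same-fascicle electrode pairs.

## Axon model

Fibers are McIntyre–Richardson–Grill (MRG) mammalian myelinated axons:
21 nodes of Ranvier and 20 internodes, each internode the sequence
MYSA–FLUT–6×STIN–FLUT–MYSA, with the published geometry table for the nine
diameters 5.7–16 µm (internodal length L runs 500–1500 µm).  Nodes carry
fast Na⁺ (m³h), persistent Na⁺ (p³), slow K⁺ (s) and linear leak channels
at 36 °C; internodal compartments are passive, wrapped by a myelin sheath
(0.1 µF/cm² and 0.001 S/cm² per lamella membrane) over a periaxonal space;
axoplasmic and periaxonal resistivity is 70 Ω·cm.  The published table
value of 1150 µm is used for the 10 µm fiber's internodal length (the
literature also quotes 1175 µm in one place; the table value is canonical).

The double-cable equations are integrated with backward Euler at a fixed
dt = 5 µs, gates advancing by an implicit substep at the pre-step membrane
potential (the standard staggered update of fixed-step compartmental
solvers).  Each step solves one pentadiagonal system in the interleaved
intracellular/periaxonal potentials.  Because only the 21 nodal
conductances change between steps — a symmetric rank-one block per node —
the constant part of the matrix is LU-factored once and each step applies
the Woodbury identity (one substitution plus a 21×21 solve).  This is
algebraically identical to refactoring every step; the test suite checks
the kernel against an independently coded dense-matrix solve of the same
equations (agreement ~1e-9 mV over full traces).

Initialization: the unstimulated fiber is relaxed to its numerical fixed
point once per diameter (50 ms settle, cached) and every simulation starts
from that state; the resting potential lands within 0.05 mV of −80 mV.
Ends are sealed.  Pulse widths must be multiples of dt so phase edges land
on step boundaries.

**Activation criterion**: a propagating action potential that drives the
*last* node of Ranvier above +10 mV at any time during the simulation,
which runs until 400 µs after the stimulus ends.  Simulations stop early
once the last node has crossed the criterion, or — for clearly
subthreshold runs — once every node is below −60 mV at least 120 µs after
the stimulus ends (a spike-bound trajectory always keeps some node
depolarized; this cannot misclassify a marginal case, only skip the
quiescent tail).

Integration error: thresholds at dt = 5 µs agree with dt = 1 µs within
0.2 µA (two accuracy quanta) in the tested configurations.

## Thresholds

The threshold at a center-node position is the smallest cathodic amplitude
eliciting a propagating spike, quantized to 0.1 µA and found by bisection
on the 0.1 µA lattice over 0–30 µA.  Defining the threshold as *the
smallest activating lattice multiple* makes the result independent of
bracket initialization, so warm starts (brackets predicted from
neighboring grid points, endpoints verified by simulation, full-range
fallback) are provably result-neutral.  Positions not recruited at 30 µA
store a not-recruited sentinel (NaN); amplitude-response monotonicity is
assumed by bisection and spot-checked by property tests.

Two exact accelerations:

* **Field-equivalence memoization.**  The extracellular profile along a
  fiber depends on each electrode only through q = ρx Δx² + ρy Δy² and Δz,
  so threshold searches with identical (q, Δz) multisets share one
  simulation.  With ρx = ρy this includes full rotational symmetry about
  any electrode's axis.  The z-reflected multiset is treated as equivalent
  too, relying on the fiber's mirror symmetry plus the fact that a
  propagating spike reaches both ends; a test compares grids with the
  reduction on and off.
* **Periodic longitudinal window.**  Away from the fiber ends the
  threshold as a function of center-node z is periodic with period L
  (shifting the fiber by one internode reproduces the geometry).  Large
  grids therefore sample z over exactly one period, with interpolation
  wrapping across the seam; the approximation error is the end effect of
  a 21-node fiber, measured at ≤ 0.2 µA.

Grid regions are sized per configuration: transverse/depth extents grow
outward until the synchronous threshold leaves the amplitude bracket, so
no activated voxel can touch the boundary (a warning guards the volume
stage regardless).  The grid z step is the integer divisor of L nearest
the requested step (e.g. 46 µm for the 10 µm fiber when 40 µm is
requested), keeping one period an integer number of cells.

## Volumes and the volume ratio

The VTA at amplitude a counts center-node positions with threshold ≤ a on
the threshold grid upsampled to a 1 µm lattice by trilinear interpolation,
restricted longitudinally to one internodal length: positions one period
apart along z are the same axon recruited at a different node and must not
be double counted.  The count is evaluated in closed form per coarse cell
(the interpolant is linear in z along each fine column), which is exactly
equal to materialized upsampling — verified by brute force on small fields
— without ever building the ~10⁹-point fine lattice.  Cells with a
not-recruited corner are excluded (conservative; the sized regions make
this immaterial).  Voxel membership uses the closed comparison
threshold ≤ a; with 0.1 µA-quantized thresholds the choice is material at
the voxel level and is absorbed by the study's tolerances.

The asynchronous condition is the pointwise minimum of the single-electrode
fields (each location is recruited by whichever electrode is cheaper), and
its VTA is automatically the union volume without double counting.  The
volume ratio is VTA_sync / VTA_async-union; 1 means functionally
independent electrodes.  Because the synchronous field is pointwise at or
below the asynchronous field for cathodic pairs, ratios are ≥ 1 up to
threshold-quantization noise.

For general fields spanning more than one period, `fold_longitudinal`
folds knot planes with the minimum rule before counting; the production
pipeline always builds one-period windows where folding is the identity.

## Populations and the neuron ratio

Populations place n identical fibers uniformly in a box centered on the
electrode pair (defaults: 2038 axons of 14 µm in 800 × 800 × 1400 µm — the
longitudinal extent is one internodal length, so each axon contributes one
center-node per period).  A neuron is recruited when the folded,
interpolated threshold field at its center-node position (z mod L) is at
or below the amplitude — the same field object the volume stage uses, so
neuron and volume ratios are directly comparable.  The neuron ratio is the
sync/async count ratio per population; across populations the mean tracks
the volume ratio until synchronous stimulation saturates the box, after
which the neuron ratio falls below it.  One top-level seed spawns
per-population child seeds, so any population is reproducible alone.
Statistical tests run 100–200 populations (the study-scale 10000 is a CLI
option, not a test default).

## Surrogate fields

A closed-form stand-in for the cable model exercises the geometry and
statistics stages exhaustively: single-electrode thresholds
t = offset + k·(anisotropy-weighted squared distance), so iso-threshold
surfaces are ellipsoids with analytic volumes; synchronous thresholds
combine reciprocally (1/t_sync = Σ 1/t_j), chosen purely for analytic
tractability — co-located pairs halve the threshold, giving an exact
volume-ratio formula ((2a − t0)/(a − t0))^{3/2} used as a parameter-recovery
oracle for the full pipeline and the Monte-Carlo stage.  The surrogate
carries no biophysical claim, and surrogate tests validate the *pipeline*,
not the axon model: real-tissue features (periodic nodal structure,
waveform dependence, anisotropic double-lobed synchronous fields) only
enter through the simulated grids.

## Study conditions and problem sizes

The default study conditions are: 200 µs cathodic
pulses, 1–30 µA, 0.1 µA threshold accuracy, 400 µm electrode pairs
(longitudinal and transverse), diameters spanning 5.7–15 µm, resistivity
perturbations of ±100 Ω·cm.  At full scale (20 µm grids, 10⁴ populations) these
analyses are cluster-sized; the package's shipped analyses run at
desk scale — 40 µm grids (20 µm for the lookup-accuracy check), one-period
longitudinal windows, and a few hundred populations — which the
threshold-reduction medians and ratio extrema tolerate by design.  The
`pair_study`/sweep APIs accept the full-scale settings unchanged.

## Known limitations

* The paper-scale 20 µm 3D sweeps are supported but slow on one core;
  grids cache to disk (`GridCache`) keyed by configuration hash.
* The periodic-window construction assumes end effects are negligible for
  the 21-node fiber; configurations probing recruitment near fiber ends
  need explicit long grids plus `fold_longitudinal`.
* Monotonicity of activation in amplitude is assumed by the bisection (a
  standard assumption; verified empirically at sampled points).
* The z-reflection equivalence could in principle mislabel a marginal case
  whose spike propagates in only one direction; none has been observed,
  and the reduction can be disabled per engine.
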