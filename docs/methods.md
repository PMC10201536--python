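# Methods

`tautopath` studies a single question at desk scale: can the
double-proton-transfer (DPT) tautomer A\*-T\* of an adenine–thymine base
pair become trapped while the DNA strands are pulled apart?  The package
couples a calibrated two-coordinate model of the transfer energetics to a
coarse-grained mechanical picture of the separating duplex.  Everything a
first-principles study would obtain from electronic-structure theory or an
all-atom force field is represented here by explicit, documented model
functions; the analysis machinery (constrained scans, nudged-elastic-band
path searches with a Gaussian-process surrogate, barrier extraction,
steered Langevin dynamics) is the same kind of machinery such a study
would use.

## The transfer surface

State: `(q1, q2, d)` — transfer progress of the proton in hydrogen bond
B1, progress of the proton in bond B2, and the strand-separation distance
d (Å).  `(0,0)` is the canonical pair, `(0,1)` the zwitterion A⁺-T⁻
(single proton transfer, SPT), `(1,1)` the tautomeric pair (DPT).  The
mechanism is asynchronous and stepwise: the B2 proton (thymine → adenine)
moves first, the B1 proton follows.

Each step is a tilted quartic
`S(q; h, Δ) = 16 h q² (1−q)² + Δ q`,
composed as

```
V(q1, q2; d) = S(q2; h₁(d), Δ₁(d))
             + s(q2) · S(q1; h₂(d), Δ₂(d))
             + (1 − s(q2)) · P · q1²,        s(q) = q²(3 − 2q)
```

with sequential penalty `P = 3 eV` forbidding B1 transfer before B2.
Coordinates live in `[−0.2, 1.2]` with cubic confinement walls outside
(C²-smooth) and a hard domain error beyond `[−0.5, 1.5]`.

The separation dependence enters through four calibration laws:

| law | form | default |
| --- | --- | --- |
| step-1 reverse barrier | `Er1(d) = b + A·d^p` | `b = 0.10 eV`, `A = 0.70 eV·Å⁻ᵖ`, `p = 1.894` (AT) / `1.783` (GC) |
| SPT asymmetry | `A_spt(d) = 0.55 + 0.25·d` eV | zwitterion above canonical |
| DPT asymmetry | `A_dpt(d) = 0.45 + 0.35·d` eV | tautomer above canonical |
| step-2 reverse barrier | `Er2(d) = 0.50·(d − 0.30)` eV | unbound when ≤ ε = 0.005 eV |

`Ef1 = A_spt + Er1` and `Ef2 = A_dpt + Er2 − A_spt`.  Below the onset
(`Er2 ≤ ε`, or `Ef2 ≤ 0`, which the linear laws produce in a narrow window
just above the onset) the step-2 term degenerates to the bare penalty and
the tautomeric corner holds no minimum at all.  The barrier-law magnitudes
are conventions of this package chosen to satisfy the qualitative
orderings a realistic landscape must have — zwitterion metastable at every
separation, no tautomeric well at the first two grid increments
(0.0, 0.222 Å) and a well from 0.444 Å on, second barrier far below the
first, quasi-linear asymmetries — because no quantitative barrier values
are established for this regime; the power-law exponents and the grid
landmarks are the quantitatively established inputs.

Per separation, `(h, Δ)` of each step are root-solved so that the
quartic's *own stationary analysis* reproduces the requested forward and
reverse barriers to 1e-8 eV (initialised at the first-order estimate
`h = (Ef+Er)/2`, `Δ = Ef−Er`).  The cross terms of the composition shift
the true 2-D stationary points from the 1-D calibration by ≲ 2e-3 eV,
which is the effective calibration tolerance of the full surface.

## Separation scan

The scan imposes `d_k = k · 0.222 Å`, `k = 0…12` (the 0.222 Å spacing is
inferred from the landmarks 0.22, 0.444 and 1.56-over-eight-increments,
all integer multiples), splitting each increment equally between the two
backbone pivots, and relaxes all unconstrained degrees of freedom with
L-BFGS to a gradient norm ≤ 0.01 eV/Å, continuing from the previous
increment's state.  Transition-state searches use the first 8 increments
(to 1.554 Å); analyses quoting the 0–2 Å range use the first 10.

The mechanical two-base model behind the scan treats each base as a rigid
body rotating about its backbone-attachment nitrogen: two Morse hydrogen
bonds (B1 deeper: 0.28 vs 0.22 eV, width 2 Å⁻¹, rest length 2.9 Å),
lever arm 4.5 Å between the B1/B2 sites, and a glycosidic rotation
restraint of 0.8 eV/rad² per base.  Because B1 resists stretching more,
relaxation rotates the bases to protect B1 at B2's expense: the opening
angle `θ = arcsin((ext_B2 − ext_B1)/w)` rises to ≈ +38° near d ≈ 1.3 Å
and reverts toward 0 by d ≈ 2 Å, where both Morse bonds are past the
reach of their wells and the rotation restraint wins.  In the tautomeric
form B1 is deeper still (×1.3) with a 0.1 Å shorter rest length, so the
tautomeric B1 bond first *shortens* under separation; below the onset
separation the tautomeric scan emits flagged zwitterion placeholders
(there is no tautomeric state to relax there).

## Path search

Plain NEB uses the improved-tangent projection with a climbing image on
the highest interior image, driven by FIRE, converged when the maximum
perpendicular true force (full force on the climber) is ≤ 0.01 eV/Å.
Convergence is measured with the same improved tangent used for the band
forces.

The surrogate-accelerated variant fits a squared-exponential Gaussian
process (per-dimension length scales, 1e-10 jitter, hyperparameters refit
by marginal likelihood every 5 acquisitions) to all true-model
evaluations, relaxes the band on the GP mean (analytic posterior-mean
gradients), and acquires a true evaluation at the interior image of
largest predicted standard deviation (ties toward higher mean).  The loop
stops when the maximum predicted uncertainty along the band is ≤ 0.02 eV
*and* the true projected forces are converged; the verification
evaluations are folded back into the training set.  Several stabilisers
are applied: the band is re-parameterised to uniform arc length between
surrogate cycles (string-method style); surrogate relaxation is confined
to a coordinate box 0.3 beyond the endpoints (an unconstrained GP mean
can launch images into unsampled territory); the spring constant is
raised to ~n·ΔE/L² on steep landscapes so the springs can keep images
ordered against the true forces; and if five verification rounds fail
(the energy-only surrogate cannot constrain gradients transverse to the
band), the band is finished on the true model from its surrogate-
converged state, which is still far cheaper than a cold start.  On the
packaged
surface the surrogate loop needs ~60–80 true evaluations where direct NEB
needs several thousand, with barriers agreeing to well within 0.02 eV.

Barriers are read off the converged profile via a cubic spline over the
normalised reaction coordinate: interior extrema with prominence ≥ ε
(default 0.005 eV, the unbound threshold), endpoints as boundary minima.
Admissible patterns are min–max–min (SPT only) and min–max–min–max–min
(both steps).  Stability: *unbound* if no third minimum or `Er2 ≤ ε`
(boundary closed on the unbound side), *metastable* up to 0.05 eV
(≈ 2 k_BT at 310 K — a shallower well is not a meaningful thermal trap),
*stable* beyond.  The onset is the smallest scanned d not classified
unbound; on the default grid and calibration the pipeline reports
0.444 Å, the third increment.

Power-law fits act on the barrier *increase* over the d = 0 baseline
(the reverse barrier has a nonzero offset at contact, and a pure power
law must vanish at 0); fitting `log y` on `log x` recovers the configured
exponents exactly on the noiseless series.  A fit variant without
baseline subtraction is available through the same function by passing
the raw series.

## Coarse-grained duplex and steered dynamics

Each nucleotide is three beads (150 amu each): a backbone bead and a
near-rigid triangle (springs of 30 eV/Å²) carrying the two bonding sites
separated by the lever arm 4.5 Å.  Pairs stack at a 3.4 Å rise; backbone
beads of a strand are joined by harmonic stacking springs (2.0 eV/Å²).
Hydrogen bonds are inter-strand Morse terms (B1 0.28 eV, B2 0.22 eV,
width 2 Å⁻¹, rest 2.9 Å).  Two modelling conventions shape the unzipping
statistics:

* **Fork orientation.**  The deeper hydrogen bond of each pair is placed
  on the fork-proximal side (toward the pulled terminal pair), as in A-T
  where the stronger N6–H···O4 bond faces the replication fork.  Because
  placement follows the depth ordering, swapping the two Morse depths
  relabels the duplex into its exact mirror image — the
  depth-swap/mirror symmetry of the angle statistics is a symmetry of
  construction.
* **Breakable base stacking.**  Vertically adjacent bonding sites of a
  strand interact through a finite Morse contact (0.10 eV, 1.5 Å⁻¹).
  These contacts anchor every site to the stack below it, so peeling must
  release contact after contact; the terminal pair's fork-proximal sites
  carry no such anchor, which is what lets unzipping start on the
  fork-proximal (deeper) bond despite its depth.  A harmonic tether here
  would make full unzipping mechanically impossible at the simulated
  forces.

Dynamics: BAOAB-splitting Langevin at 310 K, friction 1 ps⁻¹, 1 fs step;
with friction → 0 and no noise the scheme is exactly velocity Verlet,
which the energy-drift test exploits.  The steering force (quoted in
kJ mol⁻¹ nm⁻¹, converted via 1 kJ mol⁻¹ nm⁻¹ = 1.036427e-3 eV/Å) is
applied equally and oppositely to the terminal pair's backbone beads
along their instantaneous separation vector.  Replica seeds are spawned
from the protocol seed with `numpy.random.SeedSequence`; replicas share
the equilibrated starting state and differ in their noise streams.

Pair separation for the duplex is the *mean of the two bond extensions*:
in the quasi-static limit both bonds extend at the rate the strands
separate, so this tracks the scan's separation variable, and it is
invariant under rigid motion and insensitive to backbone flopping.
Opening angles use the same arcsine lever formula as the scan (NaN where
a fully broken bond pushes the extension difference past the lever arm).

Angle statistics: each replica is classified by which bond's extension
first exceeds 0.5 Å (ties toward B2-first).  The default histogram
samples θ at the first crossing of each level of a uniform separation
grid (0.02 Å) inside the 0–2 Å window, i.e. occurrences are collected
across the separation range; per-time-frame binning is available but
drowns the opening modes in closed-state thermal dwell.  Under default
parameters the B1-led (negative-angle) mode holds the global maximum near
−5…−10°, with a coexisting positive mode from B2-led openings — the
sign structure expected for fork-side peel entry at the stronger bond,
though the coarse-grained mode positions are not quantitative
predictions of modal angles.

Separation speed is the least-squares slope of separation versus time
between the first crossings of 0.2 and 2.0 Å, averaged over crossing
replicas with the standard error over replicas; non-crossing replicas
are excluded and counted.  At the weakest steering forces full crossings
are rare within the 200 ps production window, so speed estimates there
rest on few replicas.

## Problem sizes and defaults

The packaged test protocol uses 10 ps equilibration / 50 ps production;
ensemble-statistics checks (crossing fraction, speed ladder, angle
histograms) run at the 200 ps production default with 6–10 replicas, and
the standard-error scaling check uses a 4-pair duplex with 64 replicas.
The full stability pipeline (8 increments × surrogate path search) runs
in about a minute on one core.  These sizes are the package's default
desk-scale study conditions; the all-atom-scale protocol (500 ps / 200 ps,
14 bp, 49 replicas) remains one configuration edit away.

## What the synthetic models do and do not capture

The surface reproduces, by construction, the qualitative landscape
orderings and the printed scaling exponents; its absolute barrier heights
are conventions, so quantities derived from them (e.g. the temperature
equivalent of a reverse barrier at large separation) have the right order
of magnitude but are not predictions.  The duplex has no sequence
heterogeneity, helical twist, explicit solvent or electrostatics; its
bond-opening statistics demonstrate the analysis machinery and the
geometric mechanism (fork-side peel entry), not quantitative kinetics.
Passing tests therefore validate the pipeline's algorithms and the
stated invariants, not the underlying quantum chemistry of real DNA.

## Known limitations

* The tautomeric corner just above the onset has a forward step-2 barrier
  below 5 meV; optimisers started exactly on the ridge there can slide
  either way, which is why endpoint relaxation uses step-capped descent.
* GP hyperparameter refits are seeded and deterministic, but marginal
  likelihood optimisation with few points can pick short length scales;
  the acquisition loop recovers by sampling where uncertainty is
  overestimated (more evaluations, same converged path).
* Speed estimates at ≤ 50 kJ mol⁻¹ nm⁻¹ carry large standard errors at
  desk scale (few crossing replicas).
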