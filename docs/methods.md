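# Methods

This note documents the models and procedures implemented in `duplexmd`,
the parameter choices that matter, what the synthetic generators do and do
not emulate, and the numerical conventions a user relying on the outputs
should know.

## Trajectory model and I/O

A trajectory is a fixed topology plus a stack of coordinate frames (Å) at a
constant sampling interval `dt` (ps). Frames are timed `t0, t0+dt, …` with
`t0 = dt`, so a 50 ns run sampled every 10 ps contains exactly 5000 frames
(t = 10 … 50000 ps) and a 60 ns run 6000 — the convention is chosen so the
frame count equals duration/interval. `subsample` keeps frames at
`t0, t0+interval, …` and requires the interval to be an integer multiple of
`dt`; the first frame is always kept, so thinning commutes
(`subsample(subsample(T, a), b) = subsample(T, b)` when `b` is a multiple
of `a`).

Multi-model PDB is the only trajectory format. Parsing is delegated to
Biopython; a pre-scan validates coordinate fields so malformed records can
be reported with their line number. The writer emits fixed-width columns
with 3-decimal coordinates (round-trip error ≤ 10⁻³ Å); single-frame files
carry no MODEL records, multi-frame files are MODEL/ENDMDL blocks. Chains
are classified protein or RNA from residue-name vocabularies (20 standard
codes; A/U/G/C with R-prefixed and 5′/3′-terminal variants); an unknown
residue name is a hard error rather than a silent skip. Masses come from a
built-in element table; hydrogens are optional everywhere — no analysis
requires them.

## Superposition and descriptors

Rigid-body superposition is weighted least squares restricted to proper
rotations (reflections excluded), computed via
`scipy.spatial.transform.Rotation.align_vectors`; degenerate (collinear or
coincident) targets raise an explicit error. RMSD and RMSF are unweighted
over the selected atoms by default because the usual selections are a
single atom type (C5′ for the duplex, Cα for a domain); mass-weighting is a
flag. *R*g is mass-weighted, the standard convention. The superposition set
always equals the measurement set.

The average structure is the iterated superposition mean: all frames are
fitted to the running mean (seeded with the first frame) and the mean
recomputed until it moves < 10⁻⁶ Å, with a hard stop at 100 iterations.
Two consequences are documented deliberately: the result is defined only up
to a rigid motion of the seed frame's own orientation, and it matches naive
coordinate averages only to second order in the frame-to-frame displacement
(the tests assert exactly this). RMSF is the per-atom RMS deviation from
the time-averaged position after superposing every frame onto that mean —
fluctuation about the mean, not about the first frame, which is the
standard reading of per-residue "variation" profiles.

## Contact census

Three geometric contact classes are inventoried between every protein
residue and every nucleotide, per frame:

| class | criterion | default |
|---|---|---|
| hydrophobic | side-chain COM to base COM distance | < 6.5 Å |
| electrostatic | charged-group COM to backbone P distance | < 11 Å |
| hydrogen bond | donor–acceptor heavy-atom distance | ≤ 3.5 Å (+ angle ≥ 135° if H present) |

The 6.5 Å and 11 Å cutoffs are the field's values for side-chain contact
assignment and for charge–charge interactions that still contribute to
protein/RNA binding free energies. Hydrogen-bond criteria are a package
choice (3.5 Å / 135°) since no single convention dominates; the angle term
is applied only when hydrogens exist in the topology so that heavy-atom-only
structures (including all synthetic fixtures) remain analyzable.

Conventions that shape the numbers: the nucleotide "side chain" is the base
moiety (ring heavy atoms plus exocyclic N/O; no sugar, no phosphate); for
glycine the Cα stands in for the side chain. The charged residue set is
{Arg, Lys} with an opt-in His flag, and the charged-group COM uses the
terminal group (guanidinium nitrogens NE/NH1/NH2 for Arg, NZ for Lys) rather
than the whole residue — the charged moiety, not the backbone, is what the
phosphate sees. Nucleotides without a backbone P (5′ termini) are skipped by
the electrostatic census. Distance comparisons are strict (<) at the COM
cutoffs and inclusive (≤) for the donor–acceptor distance. A contact's
population is the exact fraction of frames in which its criterion holds;
the default filter keeps populations *strictly greater than* 0.5, matching
the usual "higher than 50%" phrasing, so a 25-of-50 contact is excluded.
An analysis window `[t_start, t_end]` can restrict the census to the
equilibrated part of a run; the default is the full trajectory.

## Base-pair geometry and opening

Pairing is declared explicitly as a `PairMap` (or inferred
antiparallel-by-position for two equal-length strands); pair indices count
from the declared terminus. Each pair's trace is the distance between the
two base-moiety mass centers per frame. The opening detector marks a pair
opened at the first frame where its distance exceeds `baseline + delta` for
at least `sustain` consecutive frames; defaults are delta = 3 Å over the
per-pair first-frame baseline and sustain = 50 frames (0.5 ns at 10 ps
sampling), both configurable, chosen so transient breathing does not
register. The ordering flag is true iff opening times are non-decreasing
with pair index and no unopened pair precedes an opened one — the
terminal-first signature. The detector is insensitive to appending
post-opening frames.

The distance-difference landscape compares two ensembles over one named
atom per nucleotide (C5′ by default): entry (i, j) is the difference of
time-mean pairwise distances, holo minus apo. It is symmetric, zero on the
diagonal, exactly zero for identical ensembles, antisymmetric under
swapping the ensembles, and invariant under global rigid motion.

## Energy landscapes

Two descriptor series are histogrammed on an equal-width 8×8 grid spanning
each axis's own data range (per-system ranges, matching how per-panel
landscapes are usually drawn); the probability *P* is the normalized count
and the pseudo-free energy is the Boltzmann inversion *G* = −ln(*P*/*P*ₘₐₓ)
in kT units — temperature never enters and only relative depths are
meaningful. Empty bins carry a +∞ sentinel (exported as `inf`). The basin
is the raw-histogram argmin of *G* (equivalently argmax of *P*); ties are
all reported. No smoothing or kernel density estimation is applied.

## Native-contact kinetics

Native contacts are the inter-strand heavy-atom pairs closer than 4.5 Å in
a reference frame (the first analysis frame by default); a native pair
counts as retained at time t while its distance is at most 1.2× its
reference distance. Both knobs are config values; the definition is the
common *Q* convention and a residue-level variant is available through the
contact census instead. *Q*b(t) is fitted by the single-exponential model
*A* e^(−t/τ) + *B* with `scipy.optimize.least_squares`, initialized from
the data shape (B₀ = mean of the last 10% of y, A₀ = y(0) − B₀, τ₀ = first
1/e crossing with a range/3 fallback) and bounded τ > 0. The fit never
returns an iterate worse than its initialization; a constant series is a
degenerate-fit error. τ is reported in the unit of the fitted time axis
(ns in the pipeline) together with t½ = τ ln 2, so both the
"time constant" and "half time" readings of an opening time are available.
Rescaling the time axis rescales τ exactly.

## Synthetic generators

The generators produce the *statistical* structure the analysis assumes,
not chemistry. `make_duplex` builds two antiparallel strands on a regular
helix with A-form-like defaults (rise 2.81 Å/bp, twist 32.7°/bp, 13 bp) and
paired base COMs exactly 5.5 Å apart — inside the 5–6 Å band a closed
miRNA:mRNA duplex shows. Each nucleotide carries only the atoms the
analysis touches — P (absent at 5′ termini), C5′, and five base heavy atoms
arranged so their mass-weighted COM realizes the pair geometry exactly —
with standard PDB names so selections behave as on real files.
`make_protein_patch` parks coarse residues (backbone plus correctly named
side-chain pseudo-atoms) so that the side-chain COM (or, for charged
residues anchored at a phosphate, the charged-group COM) lands exactly at
the stated offset, approaching from outside the helix; placements that come
within 1 Å of existing atoms are errors. `make_trajectory` adds isotropic,
uncorrelated Gaussian jitter (default σ = 0.3 Å), optional rigid drift, and
a programmed opening schedule: the strand-B nucleotide of each opening pair
moves along the pair axis by extra·(1 − e^(−t/τ)), saturating at the stated
extra separation. `make_qb_trace` samples the exponential decay model
directly. All generators are pure functions of (spec, seed) and reproduce
byte-identical output. The shipped `qb_decay_reference.json` carries the
decay parameters used throughout (τ = 4.96 ns is the literature-anchored
opening time scale of the modeled system; A = 0.6 and B = 0.4 are
repository choices, as no amplitude/offset is reported for it).

What the generators do **not** emulate — and hence what passing tests do
not show about real data: stereochemically valid sugar–phosphate backbones,
correlated (collective) motions, solvent and counter-ion effects, force-field
energetics, base-pair step parameters, and realistic contact-breaking
kinetics. On that last point: when the structural opening schedule is run
through the *Q*b pipeline, contacts break once the programmed displacement
exceeds their individual 1.2× tolerance, so *Q*b falls as a staircase whose
overall time scale is a fraction of the displacement τ — the exponential
fit then measures the contact-breaking time, not the displacement time
constant. Quantitative τ recovery is therefore validated on the exact
decay-model trace (noiseless recovery to 10⁻⁶ relative; mean over 200 noisy
replicates within 2%), while the structural route is validated on what it
actually guarantees: monotone decay, terminal-first opening order, and a
positive fitted time scale.

## Problem sizes and determinism

The test suite and acceptance script run on deliberately small problems:
13-bp duplexes (~180–230 atoms), 20–300-frame trajectories for structural
analyses, 5000-point decay traces, 10000–12000-frame 2-atom-per-residue
trajectories for the subsampling counts, and 200 replicates for the noisy
recovery study. These sizes were chosen as the smallest at which each
statistical claim is sharp (e.g. √n noise on a 200-replicate mean is ~0.1%
of τ, well inside the 2% band). Every stochastic step is seeded; TSV floats
are fixed to 6 significant digits, so identical configurations reproduce
identical bytes.

## Known limitations

- PDB only — no mmCIF, DCD/XTC or AMBER topology support, and no bond
  inference; selections are name/chain/resid/class predicates, not a query
  language.
- No π-stacking, cation–π or water-mediated contacts; no energy-based
  contact scoring; no MM-PBSA-style binding free energies.
- Landscapes are raw histograms: basin edges inherit bin-placement
  sensitivity, mitigated but not removed by the refinement-stability
  property test.
- The single-exponential kinetic model has no multi-exponential or
  stretched alternative and no bootstrap confidence interval on τ (the RSS
  is reported instead).
- Base pairing is positional or declared, never inferred from hydrogen
  bonding, so bulges and mismatches must be declared explicitly.
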