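# duplexmd

Trajectory analysis of protein–RNA duplex opening.

`duplexmd` is a small analysis toolkit for molecular-dynamics trajectories of
a miRNA:mRNA double-stranded RNA (dsRNA) bound by RNA-binding protein
domains — the motivating system is the miR369-3:TNFα-mRNA duplex engaged by
the Argonaute-2 PAZ domain and the FXR1 KH domain, where binding of both
domains is thought to pry the duplex open from its termini. The package is
aimed at structural-bioinformatics users who have a multi-model PDB
trajectory of such a complex and want the standard battery of stability and
opening diagnostics:

- **Superposition descriptors** — Kabsch least-squares fitting, per-frame
  RMSD relative to the iterated average structure, per-atom RMSF
  ("variation"), and the radius of gyration
  *R*g = √(Σᵢ mᵢ ‖rᵢ − r꜀ₒₘ‖² / Σᵢ mᵢ).
- **Three-class contact census** — per-frame presence and trajectory
  occupancy ("population") of hydrophobic contacts (side-chain COM to base
  COM < 6.5 Å), electrostatic contacts (Arg/Lys charged-group COM to
  backbone phosphate P < 11 Å) and hydrogen bonds (donor–acceptor heavy
  atoms ≤ 3.5 Å, with a D–H···A angle criterion when hydrogens are present),
  filtered to populations strictly above 50%.
- **Base-pair opening** — per-pair inter-strand base-COM distance traces, a
  sustained-excursion opening detector with a terminal-first ordering flag,
  residue-to-base distance series, and holo-vs-apo distance-difference
  matrices.
- **2D pseudo-free-energy landscapes** — 8×8 histograms over RMSD × *R*g
  inverted as *G* = −ln(*P*/*P*ₘₐₓ) (kT units), with basin extraction.
- **Native-contact kinetics** — the fraction of native inter-strand
  contacts *Q*b(*t*) and a statsmodels-style single-exponential model
  *Q*b(*t*) = *A* e^(−*t*/τ) + *B* whose fitted τ is the strand-opening time
  scale (t½ = τ ln 2 also reported).

Because MD trajectories of this system are rarely deposited, the package
ships seeded synthetic generators (`duplexmd.synthetic_data`) that build an
idealized A-form-like 13-bp duplex, park protein residues at controlled
distances, and animate Gaussian jitter plus programmed exponential
strand-opening schedules. These carry the statistical structure the
analysis assumes and back the entire test suite.

## Worked example

Generate a 3 ns opening trajectory (two terminal pairs opening with
τ = 0.2 and 0.5 ns), then run the landscape and kinetics stages:

```sh
$ duplexmd simulate trajectory --n-frames 300 --open-pair 1 12 0.2 \
      --open-pair 2 10 0.5 --seed 7 --out opening.pdb
wrote opening.pdb (300 frames)

$ duplexmd landscape opening.pdb --dt 10 --outdir out
basin: RMSD 0.42-0.68 Å, Rg 13.20-13.32 Å, P = 0.463

$ duplexmd qb opening.pdb --dt 10 --outdir out
41 native contacts; final Qb = 0.756
```

The basin line reports the most populated cell of the 8×8 RMSD × *R*g
histogram: the duplex spends 46% of the run in a compact, low-RMSD state
before the terminal pairs detach. `qb` finds 41 native inter-strand
heavy-atom contacts in the first frame and reports that 76% of them survive
to the end of the run — the signature of partial, terminal-first opening.

Fitting a noisy synthetic decay trace:

```sh
$ duplexmd simulate qb-trace --sigma 0.02 --seed 7 --out qb_trace.tsv
$ duplexmd fit qb_trace.tsv --outdir out
Single-exponential decay fit: y = A exp(-t/tau) + B
---------------------------------------------------
n observations              5000
A (amplitude)           0.595899
tau                      4.96689
t_half = tau ln 2        3.44278
B (offset)              0.399942
RSS                      1.97217
converged                   True
```

The fitted τ = 4.97 ns recovers the generating time constant (4.96 ns) to
0.1% despite 2% Gaussian noise on every sample.

The same stages are available as library calls
(`duplexmd.rmsd_series`, `duplexmd.hydrophobic_contacts`,
`duplexmd.energy_landscape`, `duplexmd.ExponentialDecayModel`, …) and as a
single config-driven run: `duplexmd run config.yaml` executes
descriptors → contacts → base pairs → landscape → kinetics and writes one
TSV per product plus a JSON manifest that fully determines reproduction.

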