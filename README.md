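# sbpconf

Conformational analysis of two-lobe substrate-binding proteins (SBPs) — the
periplasmic "Venus flytrap" receptors that capture a ligand between two lobes
and deliver it to a membrane transporter. The package quantifies the
open/closed equilibrium of such proteins (the sialic-acid binder SiaP is the
motivating case) from three complementary kinds of data:

1. **Structures and trajectories** — scalar order parameters of lobe closure:
   the *latch distance* (Cα–Cα gap of the surface pair, R50–N150 in
   HiSiaP-based numbering, that stacks shut on closure), the *hinge-helix kink
   angle* (three-Cα vertex angle, Q263–E225–E228), named atom-pair contacts
   (e.g. E186 OE2 – H209 NE2), pairwise Cα RMSD, and a DynDom-style
   two-rigid-body decomposition giving the inter-domain rotation angle
   θ = arccos((tr R − 1)/2).
2. **Solution X-ray scattering (SAXS)** — theoretical curves from coordinates
   via the Debye sum I(q) = Σᵢⱼ fᵢfⱼ sin(qrᵢⱼ)/(qrᵢⱼ); Guinier fits
   (Rg, I(0)); the pair-distance distribution P(r) and Dmax by regularized
   indirect Fourier transform; Porod volume V = 2π² I(0)/Q; and reduced-χ²
   ranking of candidate conformers against an experimental curve — the
   machinery behind "the liganded data are best fit by the closed model, the
   apo data by an open one".
3. **Binding and stability assays** — the exact 1:1 mass-action isotherm with
   ligand depletion, FB = ((P+L+Kd) − √((P+L+Kd)² − 4PL))/2P, fitted to
   MST-style titrations with residual-bootstrap confidence intervals;
   Boltzmann melt-curve fits for Tm/ΔTm (differential scanning fluorimetry);
   a hyperbolic apparent-K fit to Tm-vs-ligand thermal shifts; and the
   fluorescein labeling-ratio formula F/P = A495·C/(A280 − 0.35·A495).

A synthetic-data module generates every input with known ground truth — a
clamshell two-lobe pseudo-protein with a controllable hinge angle, conformer
ensembles with constant / Ornstein–Uhlenbeck / two-state hinge dynamics,
Poisson-noise scattering curves, 16-point serial-dilution titrations, and
sigmoidal melt curves — so the whole pipeline is testable end to end against
construction: hinge rotations are recovered exactly, Kd and Tm to their
stated tolerances, and conformer ranking against closed-form sphere oracles.

## Worked example

Generate a closed/open conformer pair from the same seed, recover the hinge
rotation, characterize the open state in solution, and fit a titration:

```console
$ sbpconf synth lobe --hinge 0  --seed 1 -o closed.pdb
wrote closed.pdb    latch_gap_A  32.47   latch  61,65   kink  62,63,64
$ sbpconf synth lobe --hinge 23 --seed 1 -o open.pdb
wrote open.pdb      latch_gap_A  41.07   latch  61,65   kink  62,63,64

$ sbpconf rotation --a closed.pdb --b open.pdb
angle_deg      23.00
axis           -0.0000,0.0000,1.0000
domain_sizes   63,62   hinge  0

$ sbpconf synth curve --pdb open.pdb --seed 2 -o open.dat
$ sbpconf saxs rank open.dat closed.pdb open.pdb
model        chi2       scale   rg_model
open.pdb     0.93       1.31    14.80
closed.pdb   525566.16  1.21    12.50

$ sbpconf synth titration --kd 4.3e-7 --seed 3 -o titration.csv
$ sbpconf binding fitkd titration.csv --ptot 7.5e-8
Kd_M   3.767e-07   CI95_M   2.455e-07-5.615e-07
```

Reading the output: the 23° hinge built into the open conformer is recovered
exactly by the two-rigid-body analysis (62/63 residues per lobe, no hinge
residues in this rigid toy); the noisy curve simulated from the open model is
fit by that model at reduced χ² ≈ 0.93 (χ² ≈ 1 means the model explains the
data to within its counting noise) while the closed model is rejected
outright; and a 5%-noise titration at 75 nM protein returns Kd = 377 nM with
a 95% bootstrap CI of 246–562 nM around the true 430 nM — ligand depletion
makes the quadratic isotherm essential here, since protein and Kd are within
an order of magnitude.

The same operations are available as a library (`sbpconf.conformation`,
`sbpconf.saxs`, `sbpconf.binding`, …); see `docs/methods.md` for the models,
defaults, and numerical choices.

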