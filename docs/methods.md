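# Methods

This note records the models implemented in `sbpconf`, their assumptions and
defaults, the numerical choices that matter, and what the synthetic-data
generator does and does not emulate.

## Coordinate model and numbering

Structures are parsed from fixed-column PDB text into an ordered
chain → residue → atom hierarchy keyed by *author* numbering
(chain, resseq, insertion code). Author numbers are never silently
renumbered: residue labels in the field's convention (HiSiaP-based numbers
such as R50, N150, E186) are reached only through `structio.map_numbering`,
which globally aligns a chain's one-letter sequence to a reference sequence
and returns an author→reference position map. This matters in practice
because recombinant constructs carry scars (e.g. an N-terminal Met-Asp
cloning remnant) that shift author numbering relative to the reference.

Alternate locations are resolved at read time — highest occupancy wins, ties
broken by the lexicographically smallest altloc — so every downstream
operation sees exactly one copy of each atom. Only the first MODEL is read by
`read_pdb`; trajectories/ensembles must go through `read_ensemble`, which
enforces a constant atom count across frames and names the first offending
frame otherwise. Hydrogens are parsed but excluded from all geometry (crystal
structures at typical resolution have none; simulation frames may).
Non-standard residues (ligands, acetate, waters) are retained as het groups
and excluded from sequence extraction and Cα pairing.

## Superposition, RMSD, surface areas

Rigid superposition is the closed-form Kabsch solution (SVD of the
cross-covariance with the determinant sign fix, so reflections are never
returned); point sets whose second singular value vanishes are rejected as
collinear. Rotation angles are extracted through the quaternion
representation rather than arccos((tr R − 1)/2) directly, which is the same
quantity but fully conditioned near 0° and 180°. Cα RMSD pairs residues on
shared keys (or shared reference positions when numbering maps are given) and
uses *all* pairs — no iterative outlier rejection, unlike some viewers'
`align`, so values can sit slightly above what such tools print.

Solvent-accessible surface area is Shrake–Rupley sampling on a Fibonacci
sphere lattice: radii C 1.70, N 1.55, O 1.52, S 1.80, P 1.80 Å; probe
1.4 Å; 960 points per atom by default (doubling the count moves totals by
<1% on the fixtures). Waters and hydrogens are excluded. Interface area
between chain sets A and B is (SASA(A) + SASA(B) − SASA(A∪B))/2, the
standard buried-area-per-side convention of PISA-style reports; because
published interface analyses do not document their exact radii/sampling,
agreement with them is expected at the ~10% level, not to the digit.

## Two-rigid-body partition and domain rotation

The lobe motion between two conformers is modeled as two rigid bodies plus a
hinge remainder, an intentionally simple stand-in for DynDom's published
window-based algorithm: globally superpose, split residues into two clusters
by displacement (1D two-means), refit each cluster by Kabsch, reassign every
residue to the cluster whose fit predicts it best, and iterate to a fixed
point (≤50 iterations). Residues whose best per-domain deviation exceeds
2.0 Å go to the hinge set; each domain must keep ≥20 residues
(`min_domain`).

Two degenerate regimes raise a single-rigid-body verdict rather than return
a meaningless split: (i) all residuals below 0.25 Å after global
superposition (the pair is one rigid body to within coordinate noise), and
(ii) converged domain fits differing by less than 2° of rotation — below
that, a two-body description of noisy coordinates carries no information.
Genuine small hinge motions (≥2–5°) partition exactly on synthetic ground
truth.

The inter-domain rotation superposes the pair on domain 1, then takes the
Kabsch rotation of domain 2 between the superposed structures; the angle is
reported in [0°, 180°] with the unit axis and the screw translation
component along it. On constructed hinge rotations of 5–60° the recovered
angle is exact to 1e-6°; residues exactly on the hinge axis (zero residual
under both fits) may tie-break into either domain, which is why partition
equality is only guaranteed up to a few hinge-adjacent residues.

## Descriptors, densities, state classification

Latch distance, kink angle, and named contacts are plain Euclidean/vertex
computations on mapped selections; the kink triplet default is vertex E225
with arms to Q263 and E228 (the operational definition used for trajectory
analysis of SiaP; an alternative triplet seen in figure legends can be set
via `DescriptorSpec` — the triplet is fully configurable precisely because
the literature is not unanimous). Probability densities use a Gaussian KDE
with Silverman bandwidth (histogram alternative: Freedman–Diaconis bins);
both are renormalized to integrate to 1 on their grid. State classification
thresholds a latch series against closed/open reference distances (intended
to come from the two crystal-form conformers) with a ±1.0 Å margin;
overlapping bands are an error rather than a silent reinterpretation.

## Scattering

`debye_intensity` evaluates the Debye double sum exactly for ≤5000 atoms and
through 0.1 Å pair-distance binning above (the two paths agree to <0.5% on
2000-atom fixtures). Form factors are either unit (`point`, for pseudo-atom
toys where closed-form oracles exist) or q-independent reduced scattering
lengths, element electron count minus 0.334 e/Å³ times the vdW sphere volume
(`reduced_atom`) — adequate for shape discrimination at q ≤ 0.5 Å⁻¹ without
Cromer–Mann tables. No hydration-shell term is modeled, so absolute χ²
against real, well-calibrated curves will differ from CRYSOL-class tools;
the tested contract is rank order across conformers, which survives the
missing shell. Model curves for ranking are evaluated directly on the
experimental q-grid (exact, so no interpolation error budget is needed);
`chi2_fit` still interpolates linearly when handed a pre-computed curve on a
different grid.

The Guinier fit is weighted linear regression of ln I on q², with the window
iterated until qmax·Rg ≤ 1.3 converges, then trimmed from the top while a
quadratic term in q² is statistically significant (>2 standard errors). The
trim removes the systematic high-Rg bias a full 1.3-window carries for
compact shapes (≈+2% for a uniform sphere) while leaving noisy data — where
the curvature is not resolvable — untouched. Fits with non-negative slope or
fewer than 10 usable points are errors, not numbers.

The P(r) inversion solves the linear system I(q) = 4π ∫ p(r) sinc(qr) dr on
a 101-point r-grid with p(0) = p(Dmax) = 0, a second-difference smoothness
penalty, and a soft non-negativity penalty (10× the smoothness weight on
offending nodes) so the solver stays linear. p is treated as piecewise
linear and the oscillatory kernel is integrated on a 4× finer grid, keeping
quadrature error below realistic noise across the full q-range. The
smoothness weight, when not supplied, comes from the L-curve corner guarded
by a discrepancy cap (candidates whose weighted residual exceeds twice the
best achievable are excluded before the corner search — this prevents the
corner from drifting into gross oversmoothing when the residual branch is
flat). `estimate_dmax` scans 21 candidates over [1.5, 4]·Rg and returns the
smallest whose fit χ² is within 5% of the scan minimum with near-nonnegative
p; on the analytic sphere this lands within one grid step of 2R.

Porod volume uses V = 2π² I(0)/Q with the invariant Q assembled from three
pieces: Guinier extrapolation below the first measured q, trapezoid
integration of q²(I − bg) over the data, and the analytic tail K/qmax, with
the constant background bg and Porod constant K from a weighted fit of
I = bg + K/q⁻⁴ over the top 20% of the q-range (bg clamped at zero when the
regression turns it negative — background-subtracted curves should not have
negative backgrounds). A warning is raised when q⁴(I − bg) does not plateau.
Sphere fixtures recover the volume within ~2–7% depending on the noise
model, inside the 10% the method is trusted to in practice.

## Binding and stability

`fraction_bound` is the exact depletion quadratic; the simple hyperbola
L/(L+Kd) agrees with it to 1% only when P ≤ Kd/100, which the motivating
experiments (75 nM labeled protein, sub-µM Kd) do not satisfy — hence the
depletion model is the default, not an option. `fit_kd` exploits that, at
fixed Kd, the affine signal parameters enter linearly: they are profiled out
in closed form and Kd is optimized on a 60-point log grid (±2 decades around
the measured ladder) with bounded golden-section refinement. This is
deterministic, immune to multistart luck, and fast enough that the residual
bootstrap (1000 resamples by default, fixed seed 20240930, percentile
2.5/97.5) and full coverage simulations are routine. The amplitude test
(|S_bound − S_free| < 3× residual SD → "no binding detected") prevents
confident nonsense on flat titrations; a Kd at the search bound warns.
Noiseless recovery is exact to <1e-6 relative across 1 nM–1 mM; at the
16-point, 5%-noise design the median of 100 replicate fits sits within a few
percent of truth and the 95% bootstrap CI covers truth ~90–95% of the time
(slight undercoverage is expected from residual bootstrap at n = 16).

Melt curves fit a Boltzmann sigmoid with sloped pre/post baselines,
F(T) = pre + (post − pre)/(1 + exp((Tm − T)/k)), initialized from the
smoothed-derivative peak; purely monotone traces with no interior transition
are an error. Tm is invariant under affine transforms of the fluorescence
axis. The thermal-shift fit Tm(L) = Tm0 + ΔTm·L/(L + K_app) reports an
*apparent* constant at the melting transition: it is not the isothermal Kd,
and the known MST/DSF discrepancy for sialic-acid binders (hundreds of nM vs
tens of µM) is expected behavior of the measurement, not a fit failure. The
rigorous unfolding-coupled (ΔH-dependent) model is out of scope and
documented as the likely source of that gap.

`fp_ratio` implements the fluorescein labeling formula verbatim:
C = (MW × E0.1%)/(389 × 195), F/P = A495·C/(A280 − 0.35·A495). The printed
arithmetic in common protocols is ambiguous about grouping; only
(MW × E0.1%)/(389 × 195) reproduces the standard worked value C = 0.3106 for
MW = 34 kDa, E0.1% = 0.693, so that grouping is implemented.

## Sequence utilities

Global alignment is affine-gap Needleman–Wunsch (BLOSUM62, open 10,
extend 0.5) via Biopython's PairwiseAligner; identity is counted over
columns where both positions are residues — the only convention that gives a
single percentage for unequal-length pairs. Scores match brute-force path
enumeration on short sequences. Molecular weight is the average-mass residue
sum plus one water (Biopython ProtParam); ε280 = 5500·nW + 1490·nY
(+125 per cystine when oxidized), and E0.1% = ε280/MW × 10 feeds `fp_ratio`.
Closely related pairs reproduce published identity percentages within
rounding; an HMM-based multiple aligner is not emulated.

## The synthetic generator: what it does and does not show

The structural toy is a clamshell: two uniform-ball lobes (default 60
pseudo-residues, radius 10 Å) on struts from a hinge pivot, closed at a
70° inter-strut angle with 1 Å of clearance, opened by rotating the lobe-2
block about the hinge axis. Latch markers sit at the lobe tips (gap strictly
increasing with hinge angle), kink markers on the connector (vertex angle =
closed angle + hinge angle). Uniform balls keep closed-form Rg/Dmax/P(r)
oracles available, and Cα-only unit form factors make the Debye sum exact to
sampling noise. Ensembles draw per-frame angles from constant, discrete-OU
(mean, relaxation time in frames, stationary SD), or two-state Markov
dynamics with stationary occupancies. Noise models: scattering σ(q) =
√(I/counts_scale) with Gaussian perturbation (SEC-SAXS-like counting
statistics); titration signal 1000 + 200·FB + N(0, 0.05·200) at the
16-point two-fold design from 100 µM (the study's ladder); melt curves on a
20–95 °C grid. Every generator is a pure function of its seed.

What passing these tests shows: the estimators recover their own forward
models at realistic designs and noise levels, exactly where closed forms
exist. What they do not show: robustness to real-data pathologies —
inter-particle interference and buffer-subtraction errors in SAXS,
aggregation tails, photobleaching drift in MST traces, non-two-state melting
— none of which the generators emulate. Real crystal-structure validation
targets (published inter-conformer RMSDs, the ~23° domain rotation, triad
and latch distances, interface areas) require the deposited coordinate files
as input; the operations that compute them are the ones exercised here on
synthetic ground truth.

## Problem sizes used in the automated checks

Chosen so the full suite exercises every claim at statistically meaningful
but desk-scale sizes: 100 replicate titrations per Kd recovery, 200
datasets × 200 bootstrap resamples for CI coverage, 20 seeds × 2 directions
for conformer ranking, 2000–5000-point sphere clouds for the Debye oracles,
and 300–600-frame ensembles for occupancy/mean recovery.
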