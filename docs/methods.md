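# Methods

This note documents the models implemented in `tandemww`, the conventions
and defaults behind them, and what the synthetic-data generators do and do
not emulate.

## Chemical shift perturbations

Titration peak lists are matched on `(residue, atom)` from assigned
spectra; no minimum-distance peak tracking is attempted, because severely
shifted peaks cannot be reassigned automatically anyway. The combined shift
distance is

    CSP = sqrt(0.5 * (Δδ_H² + w Δδ_X²)),   w = 0.14 (¹⁵N), 0.30 (¹³C),

applied identically to backbone amides, tryptophan side-chain Nε–Hε
correlations (same spin pair as an amide, hence the ¹⁵N weight) and methyl
¹H–¹³C correlations (¹³C weight; a residue's methyl CSP is the maximum over
its methyls, a conservative perturbation call). Unmatched peaks are flagged
`missing` with NaN, never imputed as zero: a missing bar and a zero bar
mean different things on a CSP chart.

Interface calling defaults to `mean + 1 SD` over measured entries. This is
a field convention, not a derived quantity; the threshold method and value
are exposed (`fixed_threshold`) because different systems warrant different
cutoffs.

## Relaxation

R₁/R₂ series are fit to `I(t) = I₀ exp(−R t)` by nonlinear least squares
(initialization: I₀ from the maximum intensity, R from the half-maximum
delay; two perturbed restarts). No baseline offset is fit by default —
intensities are assumed baseline-subtracted upstream. Intensity noise is
estimated from duplicate delays as `σ = |I_a − I_b| / √2`, pooled as the
RMS over all duplicate pairs across residues, and propagated through the
fit covariance (`absolute_sigma`).

The apparent rotational correlation time uses the standard closed form

    τ_c = sqrt(6 R₂/R₁ − 7) / (4π ν_N),    ν_N = 0.10136905 · ν_H,

valid for 6 R₂/R₁ > 7; out-of-range ratios raise rather than return a
complex number. Array input averages R₂/R₁ first (plain or trimmed mean,
both exposed, since reported values are typically averages over
well-ordered residues).

## RDC alignment tensors

Couplings follow `D = D_max uᵀ S u` with u the unit N–H vector and
`D_max = 21.7 kHz` (magnitude convention, r_NH = 1.02 Å, configurable).
The five independent Saupe elements are solved linearly by SVD; a design
matrix condition number above 1e8 (e.g. parallel bond vectors) raises.
Conventions: eigenvalues ordered `|S_zz| ≥ |S_yy| ≥ |S_xx|`; axis signs
fixed by putting each principal axis in the hemisphere of its largest
component and enforcing a right-handed frame; `D_a = D_max S_zz / 2` (so a
bond along the unique axis of an axial tensor gives D = 2 D_a) and
rhombicity `R = (2/3)(S_xx − S_yy)/S_zz ∈ [0, 2/3]`. The parameterization
round-trips exactly: `from_params(D_a, R, euler_zyz)` reconstructs the
Saupe matrix.

The quality factor is `Q = rms(D_obs − D_calc)/rms(D_obs)`; the alternative
normalization by `D_a sqrt(2 + 1.5 R²)` is available separately. Fits are
per single conformer — ensemble-averaged tensor fitting is deliberately out
of scope, because the package's use case is comparing per-domain tensors
fitted to rigid fragments (disagreeing tensors indicate interdomain
mobility; agreement indicates a rigid arrangement). Parameter uncertainties
come from seeded Monte-Carlo refits on `D_obs + N(0, σ_D)`.

Amide protons absent from the coordinates (common in minimal or
heavy-atom-only ensembles) are built geometrically: 1.02 Å from N along the
exterior bisector of the C(i−1)–N and CA–N directions, in plane.

## PRE back-calculation

The electron–proton PRE rate uses the transverse Solomon–Bloembergen
dipolar term

    Γ₂ = K r⁻⁶ (4 τ_c + 3 τ_c / (1 + ω_H² τ_c²)),

with `K = 1.23e16 Å⁶ s⁻²` (nitroxide–¹H) and the observable ratio

    I_para/I_dia = R₂dia exp(−Γ₂ t_INEPT) / (R₂dia + Γ₂).

Defaults are τ_c = 5 ns with R₂dia = 50 s⁻¹ for a free tandem and 8 ns /
55 s⁻¹ for the peptide-bound state, at 600 MHz; `t_INEPT = 10 ms` is a
standard HSQC transfer period (the comparisons this feeds are profile-level,
not tied to that constant). A single global R₂dia is used rather than
per-residue rates.

The label position is modeled as a point: at the Cβ of the labeled residue
(default, deterministic) or offset 6 Å from Cα along Cα→Cβ to mimic the
nitroxide arm. No rotamer ensemble of the label is modeled; profiles are
reported per residue with the mean and min/max envelope over conformers,
without smoothing. Observations falling below the envelope by more than
their error flag candidate transient contacts (a 1e-9 tolerance guards the
envelope edge against rounding).

## Ensemble geometry

Superposition is the Kabsch algorithm with a proper rotation enforced
(det = +1). Ensemble precision is reported in two conventions because the
literature rarely states which one a number comes from: `to_mean`
(superpose all conformers onto an iteratively refined mean, two refinement
passes, then average the per-conformer RMSD to the mean — the common
ensemble-statistics convention and our default) and `pairwise` (mean over
all ordered conformer pairs; always ≥ to_mean). The two-pass mean makes
`to_mean` very nearly, but not bitwise, independent of conformer order.
Backbone means N/CA/C/O; heavy means all non-hydrogen atoms; each atom
class uses its own superposition. Residue ranges use author numbering.

## ITC binding models

The perfusion bookkeeping per injection of volume dV into cell volume V0:
resident concentrations scale by (1 − dV/V0), then the syringe adds
`dV/V0 · c_syringe`. The same recursion is used in the forward and inverse
directions, which makes parameter-recovery results independent of the exact
instrument convention. The measured heat is

    q_i = 1e-3 · ΔH · V0 · (B_i − B_{i−1}(1 − dV_i/V0))   [µcal],

with B the bound-complex concentration from the identical-sites quadratic.
The fitted parameters are (N, Kd, ΔH) plus an optional constant
heat-of-dilution offset (fitted by default, since a blank subtraction
cannot be reconstructed from integrated heats). The first, small "priming"
injection is excluded from fitting by default. The Wiseman parameter
`c = N [cell]/Kd` is reported and warned on outside [1, 1000].

The fit always adopts the instrument convention that the cell species is
the macromolecule. When a multivalent construct sits in the syringe and a
single-site receptor in the cell, the algebra of the identical-sites model
maps the physical truth (s sites per syringe molecule, per-site Kd, ΔH)
exactly onto a cell-macromolecule fit with N = 1/s, Kd/s and s·ΔH; the
`tandems_per_peptide` interpretation layer inverts the role to recover the
stoichiometry of interest. This is why fitted N < 1 in such experiments
means "more than one receptor per construct".

Autoinhibition is the minimal two-state model consistent with the NMR
observation that a high-affinity ligand displaces the intramolecular
contacts: the receptor pre-equilibrates between an open state (binds
ligand, dissociation constant Kd) and a ligand-inaccessible closed state,
`k_closed = [closed]/[open]`. For this pre-equilibrium the apparent
constant seen by a one-site fit is exactly `Kd_app = Kd (1 + k_closed)`;
the package carries both the closed form and a bracketing numerical solver
for the three-species equilibrium, and tests require them to agree.
Because only the product Kd(1 + k_closed) is identifiable from a single
isotherm, fitting the autoinhibited variant requires pinning Kd or
k_closed; the intended route is to fit two isotherms (minimal and extended
receptor) one-site and infer `k_closed = Kd_app/Kd − 1`, which is what the
`autoinhibition` workflow does. Partial-displacement kinetics and
competitive displacement by a second free ligand are out of scope.

## Proline motif classes

Peptide classification is a deterministic operationalization of the
empirical affinity ordering of 16-mer proline peptides; thresholds are
config-exposed (run length ≥ 3, bridge gap ≤ 4 non-prolines, polyproline
run ≥ 4): (1) `pplp_bridge_polyP`, a PPLP motif bridged to a downstream
polyproline run — the bipartite architecture that engages both WW domains
and the highest-affinity class; (2) `two_stretches`, two runs of ≥ 3
prolines; (3) `broken_stretch`, one such run plus ≥ 2 scattered prolines;
(4) `spaced` otherwise. The classes are mutually exclusive by priority.
The `PPxP` motif kind matches both canonical orientations (`PP[^P]P` and
`P[^P][^P]PP`) so that motifs like PPVP and PALPP are both called.
Proline-rich regions are windows (default 16 residues, matching the
peptide-length grain) holding ≥ 8 prolines, merged when overlapping.

## Synthetic data: what it emulates and what it does not

The generators produce the *information content* of the real experiments,
not the raw spectra:

- Titrations are assigned peak lists, not lineshapes. Fast exchange is a
  single peak moving linearly in the bound fraction (taken as min(ratio, 1),
  the tight-binding limit appropriate for low-µM affinities at ~100 µM NMR
  concentrations); slow exchange is two co-existing peak lists with
  intensity weights (1 − f) and f. Exchange broadening, overlapped peaks
  and proline cis/trans effects are not modeled.
- Relaxation series are ideal mono-exponentials with 2% intensity noise and
  one duplicated delay; cross-correlated relaxation and offset effects are
  absent.
- Dumbbell ensembles are two internally rigid helical domains (torsions
  fixed, so per-domain rigidity holds exactly across conformers) joined by
  a linker whose φ/ψ are redrawn per conformer around an extended baseline
  (default dispersion 20°); residues are all-alanine with N/CA/C/O/CB.
  Conformers with any interdomain heavy-atom pair below 2 Å are resampled.
  These are geometric stand-ins, not force-field ensembles.
- RDC, PRE and ITC synthetic data come from the same forward models the
  fitters invert, plus Gaussian noise (defaults 0.5 Hz, 0.03 ratio units,
  0.1 µcal; titration shift noise 0.002 ppm in ¹H equivalents, with
  heteronucleus noise scaled by 1/√w so both dimensions contribute
  comparably). Zero-noise round trips therefore recover generating
  parameters to solver tolerance — this validates the estimators'
  correctness and conventions, not their robustness to real-data artifacts
  (baseline errors, aggregation heats, alignment-medium interactions).

Every generator takes a mandatory seed and is a pure function of its
arguments; regeneration is bit-identical.

## Problem sizes and numerical choices

Test and acceptance runs use desk-scale problems chosen to exercise every
code path: 10–20 conformer ensembles of ~32 residues, 26-injection
isotherms, 150-draw Monte-Carlo error estimates, and 1000-point brute-force
formula checks. ITC fits run three Kd-grid restarts of a
Levenberg–Marquardt minimization with ftol/xtol 1e-14; the equilibrium
solver brackets the bound concentration with brentq at 1e-14 tolerance;
exponential fits restart twice with perturbed initial rates. Degenerate
inputs (flat isotherms, all-equal intensities, parallel bond vectors,
empty peak intersections) raise informative errors instead of returning
spurious zeros.

## Known limitations

- No ensemble-averaged RDC fitting, model-free relaxation analysis, CPMG
  dispersion, lineshape/exchange-rate extraction, or SAXS prediction.
- The PRE label model ignores rotamer distributions; agreement scoring is
  profile-level.
- The ITC module starts from integrated heats; raw-thermogram baseline
  integration and vendor binary formats are out of scope.
- Peptide class labels are this package's operationalization of an
  empirical taxonomy; they are rule applications, not affinity predictions.
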