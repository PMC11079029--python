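# tandemww

Biophysical analysis of tandem WW domain recognition of proline-rich
ligands — the kind of system exemplified by the spliceosomal protein
PRPF40A, whose two WW domains bind bipartite proline motifs in SF1 and
SF3A1 and are autoinhibited by the protein's own N-terminal proline-rich
extension.

The package is for structural biologists and biophysicists who want a
scriptable, tested version of the quantitative analyses that usually live
in one-off spreadsheets and vendor software:

- **Chemical shift perturbation (CSP) mapping** of NMR titrations, with the
  weighted combined shift `CSP = sqrt(0.5 (Δδ_H² + w Δδ_X²))` (w = 0.14 for
  ¹⁵N, 0.30 for ¹³C) and interface calling (`tandemww.csp`).
- **¹⁵N relaxation**: mono-exponential R₁/R₂ fits with duplicate-delay error
  estimation, heteronuclear NOE ratios with error propagation, and the
  apparent correlation time `τ_c = sqrt(6 R₂/R₁ − 7) / (4π ν_N)`
  (`tandemww.relax`).
- **Residual dipolar couplings**: linear SVD fit of the 5-element Saupe
  tensor `D = D_max uᵀ S u`, Q-factors, Monte-Carlo errors, and per-domain
  tensor comparison to diagnose interdomain mobility (`tandemww.rdc`).
- **Paramagnetic relaxation enhancement**: Solomon–Bloembergen r⁻⁶
  back-calculation of para/diamagnetic intensity ratios from a spin-labeled
  conformer ensemble, with min/max envelopes and transient-contact flagging
  (`tandemww.pre`).
- **Ensemble geometry**: multi-MODEL PDB I/O, Kabsch superposition, and
  ensemble RMSD statistics in both to-mean and pairwise conventions
  (`tandemww.ensemble`).
- **ITC binding models**: forward simulation and nonlinear fitting of
  one-site isotherms, multivalent stoichiometry interpretation, and an
  autoinhibited (open/closed receptor) model with the closed form
  `Kd_app = Kd (1 + k_closed)` (`tandemww.itc`).
- **Proline motif classification**: maximal proline-run decomposition, the
  four affinity-ordered 16-mer peptide classes, and a proline-rich-region
  scanner (`tandemww.motifs`).
- **Synthetic data** for every input class, with known ground truth
  (`tandemww.synthetic`), and configuration-driven workflows
  (`tandemww.pipeline`).

## Worked example: autoinhibition weakens peptide binding

The N-terminal extension of the receptor competes intramolecularly with
external ligands. Simulating a 26-injection titration (peptide 30 µM in
cell, tandem 450 µM in syringe) for the minimal tandem at Kd = 1.4 µM and
for the extended construct with closed/open constant k_closed = 5.29, then
refitting both with the plain one-site model:

```python
from tandemww.itc import (BindingModel, default_schedule,
                          simulate_isotherm, fit_isotherm, kd_apparent)

sched = default_schedule()                      # 0.4 µL + 25 x 1.5 µL
free = simulate_isotherm(BindingModel("one_site", 1.0, 1.4, -8.0), sched)
auto = simulate_isotherm(
    BindingModel("autoinhibited", 1.0, 1.4, -8.0, k_closed=5.2857), sched)

print(fit_isotherm(free).model.kd)   # 1.3999999999995263
print(fit_isotherm(auto).model.kd)   # 8.799980000251107
print(kd_apparent(1.4, 5.2857))      # 8.79998
```

The one-site refit of the autoinhibited isotherm returns 8.8 µM — the
intrinsic 1.4 µM site diluted by the factor (1 + k_closed), i.e. the
extension makes a ~6-fold weaker apparent binder out of the same site.

The same machinery classifies the ligand peptides:

```python
from tandemww.motifs import classify_peptide
classify_peptide("PPLPPGAPPPPPPPPP").name   # 'pplp_bridge_polyP'
classify_peptide("MPPPPMGMMPPPPPPP").name   # 'two_stretches'
```

A command-line interface mirrors the library
(`tandemww simulate itc`, `tandemww itcfit`, `tandemww rdcfit`,
`tandemww pre`, `tandemww rmsd`, `tandemww motif`, `tandemww run --config`).

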