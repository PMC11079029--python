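"""Saupe tensor fitting, back-calculation and interdomain comparison."""

import math

import numpy as np
import pandas as pd
import pytest

from tandemww.ensemble import StructureEnsemble
from tandemww.rdc import (
    AlignmentTensor,
    back_calculate,
    compare_domain_tensors,
    mc_errors,
    nh_vectors,
    svd_fit,
)
from tandemww.synthetic import make_dumbbell_ensemble, make_rdc_set

TENSOR = AlignmentTensor.from_params(da=12.0, rhombicity=0.4, euler_zyz=(30.0, 50.0, 70.0))


class TestTensorConventions:
    def test_traceless_and_symmetric(self):
        assert np.trace(TENSOR.saupe) == pytest.approx(0.0, abs=1e-15)
        assert np.allclose(TENSOR.saupe, TENSOR.saupe.T)

    def test_eigenvalue_ordering(self):
        sxx, syy, szz = TENSOR.eigenvalues
        assert abs(szz) >= abs(syy) >= abs(sxx)

    def test_axial_vector_gives_two_da(self):
        axial = AlignmentTensor.from_params(da=8.0, rhombicity=0.0)
        u = np.array([0.0, 0.0, 1.0])
        d = axial.dmax * u @ axial.saupe @ u
        assert d == pytest.approx(2.0 * 8.0, rel=1e-12)

    def test_params_round_trip(self):
        rebuilt = AlignmentTensor.from_params(
            TENSOR.da, TENSOR.rhombicity, TENSOR.euler_zyz
        )
        assert np.allclose(rebuilt.saupe, TENSOR.saupe, atol=1e-14)

    def test_rhombicity_range(self):
        for r in (0.0, 0.2, 2.0 / 3.0):
            t = AlignmentTensor.from_params(10.0, r)
            assert t.rhombicity == pytest.approx(r, abs=1e-12)


class TestSVDFit:
    def test_noiseless_recovery_exact(self, dumbbell):
        ens, _ = dumbbell
        rdcs, _ = make_rdc_set(ens, 0, TENSOR, noise_sd=0.0, seed=1)
        fit = svd_fit(ens, 0, rdcs)
        assert np.allclose(fit.tensor.saupe, TENSOR.saupe, atol=1e-12)
        assert fit.q_factor < 1e-9
        assert fit.rmsd_hz < 1e-9

    def test_agrees_with_normal_equations_oracle(self, dumbbell):
        """SVD solution matches an independent dense normal-equations solve
        on noisy data, over 20 random tensors."""
        ens, _ = dumbbell
        rng = np.random.default_rng(42)
        resids, vecs = nh_vectors(ens, 0)
        for _ in range(20):
            t = AlignmentTensor.from_params(
                rng.uniform(5, 20),
                rng.uniform(0, 2 / 3),
                tuple(rng.uniform(0, 90, 3)),
            )
            rdcs, _ = make_rdc_set(
                ens, 0, t, noise_sd=1.0, seed=int(rng.integers(2**31))
            )
            fit = svd_fit(ens, 0, rdcs)
            # independent brute-force: explicit design matrix, solve A^T A s = A^T d
            obs = dict(zip(rdcs["residue"], rdcs["d_hz"]))
            a_rows, d = [], []
            for r, u in zip(resids, vecs):
                x, y, z = u
                a_rows.append(
                    [y * y - x * x, z * z - x * x, 2 * x * y, 2 * x * z, 2 * y * z]
                )
                d.append(obs[r] / t.dmax)
            a = np.array(a_rows)
            s = np.linalg.solve(a.T @ a, a.T @ np.array(d))
            syy, szz, sxy, sxz, syz = s
            saupe = np.array(
                [[-syy - szz, sxy, sxz], [sxy, syy, syz], [sxz, syz, szz]]
            )
            assert np.allclose(fit.tensor.saupe, saupe, atol=1e-10)

    def test_linearity_in_observed_couplings(self, dumbbell):
        ens, _ = dumbbell
        rdcs, _ = make_rdc_set(ens, 0, TENSOR, noise_sd=0.0, seed=1)
        doubled = rdcs.assign(d_hz=2.0 * rdcs["d_hz"])
        fit1 = svd_fit(ens, 0, rdcs)
        fit2 = svd_fit(ens, 0, doubled)
        assert fit2.tensor.da == pytest.approx(2.0 * fit1.tensor.da, rel=1e-9)
        assert fit2.tensor.rhombicity == pytest.approx(
            fit1.tensor.rhombicity, abs=1e-9
        )
        assert np.allclose(fit2.tensor.axes, fit1.tensor.axes, atol=1e-9)

    def test_parallel_vectors_rejected(self):
        # all N-H vectors along +z: rank-deficient design
        n_res = 8
        rows = []
        coords = []
        for i in range(1, n_res + 1):
            base = np.array([3.8 * i, 0.0, 0.0])
            for name, offset in [
                ("N", [0, 0, 0.0]),
                ("CA", [1.2, 0.9, 0.0]),
                ("C", [2.4, 0.0, 0.0]),
                ("H", [0.0, 0.0, 1.02]),
            ]:
                rows.append(("A", i, "ALA", name, name[0]))
                coords.append(base + np.array(offset))
        atoms = pd.DataFrame(
            rows, columns=["chain", "resid", "resname", "name", "element"]
        )
        ens = StructureEnsemble(atoms, np.asarray(coords)[None, :, :])
        rdcs = pd.DataFrame(
            {"residue": range(1, n_res + 1), "d_hz": 5.0, "err_hz": 0.5}
        )
        with pytest.raises(ValueError, match="degenerate|condition"):
            svd_fit(ens, 0, rdcs)


class TestBackCalculate:
    def test_zero_tensor_gives_zeros(self, dumbbell):
        ens, _ = dumbbell
        zero = AlignmentTensor(np.zeros((3, 3)))
        table = back_calculate(zero, ens, 0)
        assert np.allclose(table["d_hz"], 0.0)

    def test_fit_then_back_calculate_idempotent(self, dumbbell):
        ens, _ = dumbbell
        rdcs, _ = make_rdc_set(ens, 0, TENSOR, noise_sd=0.0, seed=1)
        fit = svd_fit(ens, 0, rdcs)
        recalc = back_calculate(fit.tensor, ens, 0)
        merged = rdcs.merge(recalc, on="residue", suffixes=("_in", "_out"))
        assert np.allclose(merged["d_hz_in"], merged["d_hz_out"], atol=1e-9)

    def test_joint_rotation_covariance(self, dumbbell):
        """Rotating structure and tensor together leaves couplings (and the
        refit Q-factor) unchanged."""
        ens, _ = dumbbell
        rdcs, _ = make_rdc_set(ens, 0, TENSOR, noise_sd=0.5, seed=9)
        fit = svd_fit(ens, 0, rdcs)
        from scipy.spatial.transform import Rotation

        rot = Rotation.from_euler("zyz", [20, 40, 60], degrees=True).as_matrix()
        ens_rot = StructureEnsemble(ens.atoms, ens.coords @ rot.T)
        d0 = back_calculate(TENSOR, ens, 0)["d_hz"]
        d1 = back_calculate(TENSOR.rotated(rot), ens_rot, 0)["d_hz"]
        assert np.allclose(d0, d1, atol=1e-9)
        fit_rot = svd_fit(ens_rot, 0, rdcs)
        assert fit_rot.q_factor == pytest.approx(fit.q_factor, rel=1e-9)


class TestDomainComparison:
    def test_identity(self, dumbbell):
        ens, _ = dumbbell
        rdcs, _ = make_rdc_set(ens, 0, TENSOR, noise_sd=0.0, seed=1)
        fit = svd_fit(ens, 0, rdcs)
        report = compare_domain_tensors(fit, fit)
        assert report["da_ratio"] == pytest.approx(1.0)
        assert report["rhombicity_diff"] == pytest.approx(0.0)
        assert np.allclose(report["axis_angles_deg"], 0.0, atol=1e-9)

    def test_rigid_conformer_per_domain_fits_agree(self, dumbbell):
        """A single global tensor fitted separately to the two rigid domains
        of one conformer returns consistent tensors (angles ~ 0)."""
        ens, truth = dumbbell
        rdcs, _ = make_rdc_set(ens, 0, TENSOR, noise_sd=0.0, seed=1)
        d1 = tuple(truth.parameters["domain1"])
        d2 = tuple(truth.parameters["domain2"])
        fit1 = svd_fit(ens, 0, rdcs, [d1])
        fit2 = svd_fit(ens, 0, rdcs, [d2])
        report = compare_domain_tensors(fit1, fit2)
        assert report["da_ratio"] == pytest.approx(1.0, abs=1e-6)
        assert max(report["axis_angles_deg"]) < 1e-3

    def test_mobile_ensemble_tensors_diverge(self, dumbbell):
        """Couplings averaged as if each conformer carried the same tensor in
        the frame of domain 1 make the per-domain fits disagree."""
        ens, truth = dumbbell
        d1 = tuple(truth.parameters["domain1"])
        d2 = tuple(truth.parameters["domain2"])
        tables = [
            make_rdc_set(ens, m, TENSOR, noise_sd=0.0, seed=1)[0]
            for m in range(ens.n_conformers)
        ]
        avg = tables[0].copy()
        avg["d_hz"] = np.mean([t["d_hz"].to_numpy() for t in tables], axis=0)
        fit1 = svd_fit(ens, 0, avg, [d1])
        fit2 = svd_fit(ens, 0, avg, [d2])
        report = compare_domain_tensors(fit1, fit2)
        assert max(report["axis_angles_deg"]) > 5.0 or abs(
            report["da_ratio"] - 1.0
        ) > 0.2


class TestMonteCarloErrors:
    def test_seeded_and_scaling(self, dumbbell):
        ens, _ = dumbbell
        rdcs, _ = make_rdc_set(ens, 0, TENSOR, noise_sd=0.5, seed=3)
        a = mc_errors(ens, 0, rdcs, n_draws=150, seed=11)
        b = mc_errors(ens, 0, rdcs, n_draws=150, seed=11)
        assert a["da_sd"] == b["da_sd"]
        # SDs scale ~ linearly with the stated measurement error
        small = rdcs.assign(err_hz=rdcs["err_hz"] * 0.1)
        c = mc_errors(ens, 0, small, n_draws=150, seed=11)
        assert c["da_sd"] == pytest.approx(0.1 * a["da_sd"], rel=0.3)
        tiny = rdcs.assign(err_hz=1e-9)
        d = mc_errors(ens, 0, tiny, n_draws=150, seed=11)
        assert d["da_sd"] < 1e-7
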