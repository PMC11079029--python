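"""Residual dipolar coupling analysis: SVD Saupe-tensor fits and diagnostics.

A backbone N-H RDC reports the orientation of its bond vector u relative to
the molecular alignment frame:

    D = Dmax * u^T S u

with S the traceless symmetric Saupe order matrix (5 independent elements)
and Dmax the static dipolar constant for the N-H spin pair at the assumed
1.02 A bond length.  Fitting S to >= 5 couplings on a rigid fragment is a
linear least-squares problem solved here by singular value decomposition.
Comparing tensors fitted independently to the two WW domains of a tandem
diagnoses interdomain mobility: a rigid tandem yields one common tensor,
mobile domains yield tensors differing in magnitude and orientation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .ensemble import StructureEnsemble, amide_positions

#: magnitude of the static N-H dipolar constant (Hz) at r_NH = 1.02 A
DMAX_NH = 21700.0

#: condition number above which the bond-vector geometry is declared degenerate
CONDITION_LIMIT = 1e8


@dataclass
class AlignmentTensor:
    """Saupe order matrix with derived axial/rhombic parameters.

    ``saupe`` is symmetric and traceless.  Eigenvalues are ordered
    |Szz| >= |Syy| >= |Sxx|; the axial magnitude is Da = Dmax*Szz/2 (Hz) and
    the rhombicity R = (2/3)(Sxx - Syy)/Szz lies in [0, 2/3].
    """

    saupe: np.ndarray
    dmax: float = DMAX_NH

    def __post_init__(self) -> None:
        self.saupe = np.asarray(self.saupe, dtype=float)
        if self.saupe.shape != (3, 3):
            raise ValueError("Saupe matrix must be 3x3")
        if not np.allclose(self.saupe, self.saupe.T, atol=1e-10):
            raise ValueError("Saupe matrix must be symmetric")
        if abs(np.trace(self.saupe)) > 1e-10 * max(1.0, np.abs(self.saupe).max()):
            raise ValueError("Saupe matrix must be traceless")

    # -- principal frame -------------------------------------------------
    def _principal(self) -> tuple[np.ndarray, np.ndarray]:
        """Eigenvalues (Sxx, Syy, Szz) and axes as rotation-matrix columns."""
        vals, vecs = np.linalg.eigh(self.saupe)
        order = np.argsort(np.abs(vals))  # ascending |.| : xx, yy, zz
        vals = vals[order]
        vecs = vecs[:, order]
        # deterministic axis signs: z axis into the hemisphere of its largest
        # absolute component, then x fixed to keep a right-handed frame
        for k in (2, 1):
            col = vecs[:, k]
            if col[np.argmax(np.abs(col))] < 0:
                vecs[:, k] = -col
        if np.linalg.det(vecs) < 0:
            vecs[:, 0] = -vecs[:, 0]
        return vals, vecs

    @property
    def eigenvalues(self) -> np.ndarray:
        return self._principal()[0]

    @property
    def axes(self) -> np.ndarray:
        """Principal axes as columns (x, y, z)."""
        return self._principal()[1]

    @property
    def da(self) -> float:
        """Axial magnitude in Hz (signed): Da = Dmax * Szz / 2."""
        return float(self.dmax * self.eigenvalues[2] / 2.0)

    @property
    def rhombicity(self) -> float:
        sxx, syy, szz = self.eigenvalues
        if szz == 0:
            return 0.0
        return float((2.0 / 3.0) * (sxx - syy) / szz)

    @property
    def euler_zyz(self) -> tuple[float, float, float]:
        """z-y-z Euler angles (degrees) rotating the lab frame onto the PAS."""
        r = self._principal()[1]
        beta = math.acos(min(1.0, max(-1.0, r[2, 2])))
        if abs(r[2, 2]) < 1.0 - 1e-12:
            alpha = math.atan2(r[1, 2], r[0, 2])
            gamma = math.atan2(r[2, 1], -r[2, 0])
        else:  # gimbal: fold everything into alpha
            alpha = math.atan2(r[1, 0], r[0, 0])
            gamma = 0.0
        return tuple(math.degrees(a) for a in (alpha, beta, gamma))

    @classmethod
    def from_params(
        cls,
        da: float,
        rhombicity: float,
        euler_zyz: tuple[float, float, float] = (0.0, 0.0, 0.0),
        dmax: float = DMAX_NH,
    ) -> "AlignmentTensor":
        """Build the Saupe matrix from (Da, R, orientation)."""
        szz = 2.0 * da / dmax
        sxx = szz * (1.5 * rhombicity - 1.0) / 2.0
        syy = -szz * (1.5 * rhombicity + 1.0) / 2.0
        rot = _rot_zyz(*euler_zyz)
        saupe = rot @ np.diag([sxx, syy, szz]) @ rot.T
        return cls(saupe, dmax=dmax)

    def rotated(self, rotation: np.ndarray) -> "AlignmentTensor":
        return AlignmentTensor(rotation @ self.saupe @ rotation.T, dmax=self.dmax)


def _rot_zyz(alpha: float, beta: float, gamma: float) -> np.ndarray:
    a, b, g = (math.radians(x) for x in (alpha, beta, gamma))

    def rz(t):
        return np.array(
            [[math.cos(t), -math.sin(t), 0], [math.sin(t), math.cos(t), 0], [0, 0, 1]]
        )

    def ry(t):
        return np.array(
            [[math.cos(t), 0, math.sin(t)], [0, 1, 0], [-math.sin(t), 0, math.cos(t)]]
        )

    return rz(a) @ ry(b) @ rz(g)


@dataclass
class TensorFit:
    tensor: AlignmentTensor
    q_factor: float
    rmsd_hz: float
    n_used: int
    condition_number: float
    residues: list[int] = field(default_factory=list)


# ---------------------------------------------------------------------------
# N-H bond vectors
# ---------------------------------------------------------------------------

def nh_vectors(
    ens: StructureEnsemble,
    conformer: int,
    chain: str = "A",
    selection: Sequence[tuple[int, int]] | None = None,
) -> tuple[list[int], np.ndarray]:
    """Unit N->H bond vectors for one conformer (H built when absent)."""
    resids, n_xyz, h_xyz = amide_positions(ens, chain)
    vec = h_xyz[conformer] - n_xyz[conformer]
    vec /= np.linalg.norm(vec, axis=1, keepdims=True)
    if selection is not None:
        keep = [
            i
            for i, r in enumerate(resids)
            if any(lo <= r <= hi for lo, hi in selection)
        ]
        resids = [resids[i] for i in keep]
        vec = vec[keep]
    return resids, vec


def _design_row(u: np.ndarray) -> np.ndarray:
    x, y, z = u
    return np.array([y * y - x * x, z * z - x * x, 2 * x * y, 2 * x * z, 2 * y * z])


def _saupe_from_elements(s: np.ndarray) -> np.ndarray:
    syy, szz, sxy, sxz, syz = s
    sxx = -syy - szz
    return np.array([[sxx, sxy, sxz], [sxy, syy, syz], [sxz, syz, szz]])


def svd_fit(
    ens: StructureEnsemble,
    conformer: int,
    rdcs: pd.DataFrame,
    selection: Sequence[tuple[int, int]] | None = None,
    chain: str = "A",
    dmax: float = DMAX_NH,
) -> TensorFit:
    """Fit the 5 Saupe elements to observed couplings by linear SVD.

    ``rdcs`` needs columns ``residue`` and ``d_hz`` (``err_hz`` optional).
    Only residues present both in the coupling table and with a resolvable
    N-H vector inside ``selection`` contribute.
    """
    resids, vecs = nh_vectors(ens, conformer, chain, selection)
    obs_map = dict(zip(rdcs["residue"].astype(int), rdcs["d_hz"].astype(float)))
    rows, d_obs, used = [], [], []
    for r, u in zip(resids, vecs):
        if r in obs_map:
            rows.append(_design_row(u))
            d_obs.append(obs_map[r])
            used.append(r)
    if len(used) < 5:
        raise ValueError(f"only {len(used)} usable RDCs — need at least 5")
    a = np.asarray(rows)
    d_obs = np.asarray(d_obs)
    u_, sv, vt = np.linalg.svd(a, full_matrices=False)
    cond = float(sv[0] / sv[-1]) if sv[-1] > 0 else math.inf
    if cond > CONDITION_LIMIT:
        raise ValueError(
            f"degenerate N-H vector geometry (condition number {cond:.3g})"
        )
    s = vt.T @ ((u_.T @ (d_obs / dmax)) / sv)
    tensor = AlignmentTensor(_saupe_from_elements(s), dmax=dmax)
    d_calc = dmax * (a @ s)
    resid_vec = d_obs - d_calc
    rms_obs = float(np.sqrt(np.mean(d_obs**2)))
    q = float(np.sqrt(np.mean(resid_vec**2)) / rms_obs) if rms_obs > 0 else 0.0
    return TensorFit(
        tensor=tensor,
        q_factor=q,
        rmsd_hz=float(np.sqrt(np.mean(resid_vec**2))),
        n_used=len(used),
        condition_number=cond,
        residues=used,
    )


def q_factor_da_normalized(fit: TensorFit) -> float:
    """Alternative Q normalization by Da*sqrt(2 + 1.5 R^2)."""
    da, r = fit.tensor.da, fit.tensor.rhombicity
    denom = abs(da) * math.sqrt(2.0 + 1.5 * r * r)
    return fit.rmsd_hz / denom if denom > 0 else math.inf


def back_calculate(
    tensor: AlignmentTensor,
    ens: StructureEnsemble,
    conformer: int,
    selection: Sequence[tuple[int, int]] | None = None,
    chain: str = "A",
) -> pd.DataFrame:
    """Forward dipolar equation: predicted couplings for each amide."""
    resids, vecs = nh_vectors(ens, conformer, chain, selection)
    d = tensor.dmax * np.einsum("ij,jk,ik->i", vecs, tensor.saupe, vecs)
    return pd.DataFrame({"residue": resids, "d_hz": d})


def compare_domain_tensors(fit_a: TensorFit, fit_b: TensorFit) -> dict:
    """Magnitude, rhombicity and orientation differences between two fits.

    Principal-axis angles are folded into [0, 90] degrees (tensor axes are
    sign-ambiguous).  Identical tensors give ratio 1, differences 0.
    """
    da_a, da_b = fit_a.tensor.da, fit_b.tensor.da
    axes_a, axes_b = fit_a.tensor.axes, fit_b.tensor.axes
    angles = []
    for k in range(3):
        c = abs(float(np.dot(axes_a[:, k], axes_b[:, k])))
        angles.append(math.degrees(math.acos(min(1.0, c))))
    return {
        "da_ratio": da_b / da_a,
        "rhombicity_diff": fit_b.tensor.rhombicity - fit_a.tensor.rhombicity,
        "axis_angles_deg": angles,
    }


def mc_errors(
    ens: StructureEnsemble,
    conformer: int,
    rdcs: pd.DataFrame,
    selection: Sequence[tuple[int, int]] | None = None,
    n_draws: int = 200,
    seed: int = 0,
    chain: str = "A",
    dmax: float = DMAX_NH,
) -> dict:
    """Monte-Carlo parameter SDs: refit on data perturbed by err_hz noise."""
    if n_draws < 100:
        raise ValueError("need at least 100 Monte-Carlo draws")
    if "err_hz" not in rdcs.columns:
        raise ValueError("RDC table needs an err_hz column for MC errors")
    rng = np.random.default_rng(seed)
    das, rhombs, elements = [], [], []
    failed = 0
    base = rdcs.reset_index(drop=True)
    for _ in range(n_draws):
        pert = base.copy()
        pert["d_hz"] = pert["d_hz"] + rng.normal(0.0, pert["err_hz"])
        try:
            fit = svd_fit(ens, conformer, pert, selection, chain, dmax)
        except ValueError:
            failed += 1
            continue
        das.append(fit.tensor.da)
        rhombs.append(fit.tensor.rhombicity)
        elements.append(fit.tensor.saupe[np.triu_indices(3)])
    return {
        "da_sd": float(np.std(das)),
        "rhombicity_sd": float(np.std(rhombs)),
        "saupe_sd": np.std(np.asarray(elements), axis=0),
        "n_failed": failed,
    }


# ---------------------------------------------------------------------------
# Tabular I/O
# ---------------------------------------------------------------------------

def read_rdcs(path: str) -> pd.DataFrame:
    """Read delimited couplings (columns residue, d_hz[, err_hz])."""
    df = pd.read_csv(path, sep=None, engine="python")
    if "err_hz" in df.columns and (df["err_hz"] <= 0).any():
        raise ValueError("RDC errors must be positive")
    if df["residue"].duplicated().any():
        raise ValueError("duplicate residues in RDC table")
    return df


def write_rdcs(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", index=False)
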