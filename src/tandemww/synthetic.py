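"""Synthetic data generators with known ground truth.

Every input class the analysis stages consume can be produced here: slow- and
fast-exchange titration shift trajectories, mono-exponential relaxation
series with a duplicate delay, two-rigid-domain ("dumbbell") conformer
ensembles joined by a flexible linker, RDC sets from a known Saupe tensor,
PRE ratio profiles from a labeled ensemble, and ITC isotherms for one-site,
multi-site and autoinhibited binding.  Generators are pure functions of
their parameters and a mandatory seed, and they share the forward-model code
paths that the fitting stages invert, so zero-noise round trips recover the
generating parameters to solver tolerance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from . import itc as itc_mod
from . import pre as pre_mod
from .csp import CSP_WEIGHTS, TitrationSeries
from .ensemble import LabelSite, StructureEnsemble
from .rdc import AlignmentTensor, back_calculate
from .relax import RelaxationSeries


@dataclass
class GroundTruth:
    """Parameters a generator used, for later comparison with fit output."""

    kind: Literal["titration", "relaxation", "ensemble", "rdc", "pre", "itc"]
    parameters: dict
    seed: int

    def write(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write(f"kind = {self.kind}\n")
            fh.write(f"seed = {self.seed}\n")
            for key, value in self.parameters.items():
                fh.write(f"{key} = {value}\n")


# ---------------------------------------------------------------------------
# Titrations
# ---------------------------------------------------------------------------

@dataclass
class TitrationPoint:
    """One synthetic titration point.

    Fast exchange: a single shifting peak list (``series``).  Slow exchange:
    two co-existing peak lists — the free-state peaks fading with intensity
    (1 - f) and the bound-state peaks growing with intensity f, where f is
    the bound fraction.
    """

    ratio: float
    series: TitrationSeries | None = None
    free_component: TitrationSeries | None = None
    bound_component: TitrationSeries | None = None

    @property
    def endpoint_peaks(self) -> TitrationSeries:
        return self.series if self.series is not None else self.bound_component


@dataclass
class TitrationSynthesis:
    free: TitrationSeries
    points: list[TitrationPoint]
    truth: GroundTruth


def make_titration(
    n_residues: int,
    interface: Sequence[int],
    max_csp: float,
    ratios: Sequence[float],
    regime: Literal["slow", "fast"] = "fast",
    noise_sd: float = 0.002,
    seed: int = 0,
) -> TitrationSynthesis:
    """Synthesize a ligand titration over amide peaks.

    Interface residues move toward an endpoint whose weighted CSP equals
    ``max_csp`` (ppm); non-interface residues feel only noise.  The bound
    fraction at ligand:protein ratio rho is min(rho, 1) — the tight-binding
    (stoichiometric) limit appropriate for low-micromolar affinities at NMR
    concentrations.  Heteronucleus noise is scaled by 1/sqrt(weight) so both
    dimensions contribute comparably to a noise-only CSP.
    """
    interface = sorted(set(int(r) for r in interface))
    if interface and (interface[0] < 1 or interface[-1] > n_residues):
        raise ValueError("interface must be a subset of 1..n_residues")
    if not interface and max_csp > 0:
        raise ValueError("non-zero max_csp with an empty interface")
    ratios = [float(r) for r in ratios]
    if any(r < 0 for r in ratios) or sorted(ratios) != ratios:
        raise ValueError("ratios must be non-negative and ascending")
    rng = np.random.default_rng(seed)
    residues = np.arange(1, n_residues + 1)
    w = CSP_WEIGHTS["N15"]
    x_noise = noise_sd / math.sqrt(w)

    shift_h0 = rng.uniform(7.5, 9.5, n_residues)
    shift_x0 = rng.uniform(105.0, 130.0, n_residues)
    delta_h = np.zeros(n_residues)
    delta_x = np.zeros(n_residues)
    for r in interface:
        phi = rng.uniform(0.0, 2.0 * math.pi)
        delta_h[r - 1] = max_csp * math.sqrt(2.0) * math.cos(phi)
        delta_x[r - 1] = max_csp * math.sqrt(2.0) * math.sin(phi) / math.sqrt(w)

    def peaklist(dh_frac: float, intensity: float) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "residue": residues,
                "atom": "HN",
                "shift_h": shift_h0
                + dh_frac * delta_h
                + rng.normal(0.0, noise_sd, n_residues),
                "shift_x": shift_x0
                + dh_frac * delta_x
                + rng.normal(0.0, x_noise, n_residues),
                "nucleus": "N15",
                "intensity": intensity,
            }
        )

    free = TitrationSeries(0.0, peaklist(0.0, 1.0), label="free")
    points = []
    for rho in ratios:
        f = min(rho, 1.0)
        if regime == "fast":
            points.append(
                TitrationPoint(rho, series=TitrationSeries(rho, peaklist(f, 1.0)))
            )
        else:
            points.append(
                TitrationPoint(
                    rho,
                    free_component=TitrationSeries(rho, peaklist(0.0, 1.0 - f)),
                    bound_component=TitrationSeries(rho, peaklist(1.0, f)),
                )
            )
    truth = GroundTruth(
        "titration",
        {
            "interface": interface,
            "max_csp": max_csp,
            "regime": regime,
            "noise_sd": noise_sd,
            "ratios": ratios,
        },
        seed,
    )
    return TitrationSynthesis(free, points, truth)


# ---------------------------------------------------------------------------
# Relaxation decays
# ---------------------------------------------------------------------------

def make_relaxation_series(
    rate: float,
    i0: float,
    delays: Sequence[float],
    duplicate_index: int = 0,
    noise_sd: float = 0.02,
    seed: int = 0,
    residue_id: int = 1,
    experiment: Literal["R1", "R2"] = "R1",
) -> RelaxationSeries:
    """Mono-exponential decay I0*exp(-rate*t) with one duplicated delay.

    ``noise_sd`` is a fraction of I0 (2% is typical peak-height noise); the
    duplicated delay gets an independent noise draw, which is what the
    duplicate-difference error estimate relies on.
    """
    if rate <= 0:
        raise ValueError("rate must be positive")
    delays = [float(d) for d in delays]
    if any(d < 0 for d in delays):
        raise ValueError("delays must be non-negative")
    rng = np.random.default_rng(seed)
    all_delays = delays + [delays[duplicate_index]]
    t = np.asarray(all_delays)
    y = i0 * np.exp(-rate * t) + rng.normal(0.0, noise_sd * i0, t.size)
    return RelaxationSeries(residue_id, t, y, experiment)


# ---------------------------------------------------------------------------
# Dumbbell ensembles (two rigid domains + flexible linker)
# ---------------------------------------------------------------------------

_BOND_N_CA, _BOND_CA_C, _BOND_C_N = 1.458, 1.525, 1.329
_ANG_N_CA_C, _ANG_CA_C_N, _ANG_C_N_CA = 111.2, 116.2, 121.7
_HELIX = (-60.0, -45.0)
_EXTENDED = (-120.0, 130.0)


def _nerf(a: np.ndarray, b: np.ndarray, c: np.ndarray, bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Place atom d from internal coordinates (angle at c, torsion a-b-c-d)."""
    angle = math.radians(angle_deg)
    torsion = math.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d2 = np.array(
        [
            -bond * math.cos(angle),
            bond * math.sin(angle) * math.cos(torsion),
            bond * math.sin(angle) * math.sin(torsion),
        ]
    )
    return c + d2[0] * bc + d2[1] * m + d2[2] * n


def _build_backbone(phis: np.ndarray, psis: np.ndarray) -> dict[str, np.ndarray]:
    """N/CA/C/O/CB coordinates for a chain with the given torsions."""
    n_res = len(phis)
    N = np.zeros((n_res, 3))
    CA = np.zeros((n_res, 3))
    C = np.zeros((n_res, 3))
    N[0] = [0.0, 0.0, 0.0]
    CA[0] = [_BOND_N_CA, 0.0, 0.0]
    ang = math.radians(_ANG_N_CA_C)
    C[0] = CA[0] + _BOND_CA_C * np.array([-math.cos(ang), math.sin(ang), 0.0])
    for i in range(1, n_res):
        N[i] = _nerf(N[i - 1], CA[i - 1], C[i - 1], _BOND_C_N, _ANG_CA_C_N, psis[i - 1])
        CA[i] = _nerf(CA[i - 1], C[i - 1], N[i], _BOND_N_CA, _ANG_C_N_CA, 180.0)
        C[i] = _nerf(C[i - 1], N[i], CA[i], _BOND_CA_C, _ANG_N_CA_C, phis[i])
    O = np.zeros((n_res, 3))
    for i in range(n_res - 1):
        d = (CA[i] - C[i]) / np.linalg.norm(CA[i] - C[i]) + (N[i + 1] - C[i]) / np.linalg.norm(N[i + 1] - C[i])
        O[i] = C[i] - 1.231 * d / np.linalg.norm(d)
    O[-1] = _nerf(N[-1], CA[-1], C[-1], 1.231, 120.5, psis[-1] + 180.0)
    CB = np.zeros((n_res, 3))
    for i in range(n_res):
        v1 = (N[i] - CA[i]) / np.linalg.norm(N[i] - CA[i])
        v2 = (C[i] - CA[i]) / np.linalg.norm(C[i] - CA[i])
        bis = (v1 + v2) / np.linalg.norm(v1 + v2)
        perp = np.cross(v2, v1)
        perp /= np.linalg.norm(perp)
        CB[i] = CA[i] + 1.521 * (-bis * 0.5905 + perp * 0.8070)
    return {"N": N, "CA": CA, "C": C, "O": O, "CB": CB}


def make_dumbbell_ensemble(
    n_conformers: int,
    domain_size: int = 15,
    linker_length: int = 8,
    linker_dispersion: float = 20.0,
    seed: int = 0,
    clash_distance: float = 2.0,
    max_retries: int = 200,
) -> tuple[StructureEnsemble, GroundTruth]:
    """Two rigid helical domains joined by a linker of variable torsions.

    Domain residues keep identical internal coordinates across conformers
    (their torsions are fixed); the linker's phi/psi are redrawn per
    conformer around an extended baseline with the given dispersion in
    degrees.  Conformers whose domains approach within ``clash_distance``
    (A, any heavy-atom pair) are resampled, a bounded number of times.
    """
    if n_conformers < 1:
        raise ValueError("need at least one conformer")
    rng = np.random.default_rng(seed)
    n_res = 2 * domain_size + linker_length
    phis = np.empty(n_res)
    psis = np.empty(n_res)
    d1 = slice(0, domain_size)
    lk = slice(domain_size, domain_size + linker_length)
    d2 = slice(domain_size + linker_length, n_res)
    phis[d1], psis[d1] = _HELIX
    phis[d2], psis[d2] = _HELIX
    atom_names = ["N", "CA", "C", "O", "CB"]
    coords = []
    dom1_atoms = slice(0, domain_size * 5)
    dom2_atoms = slice((domain_size + linker_length) * 5, n_res * 5)
    for _ in range(n_conformers):
        for attempt in range(max_retries):
            phis[lk] = _EXTENDED[0] + rng.normal(0.0, linker_dispersion, linker_length)
            psis[lk] = _EXTENDED[1] + rng.normal(0.0, linker_dispersion, linker_length)
            bb = _build_backbone(phis, psis)
            xyz = np.stack([bb[a] for a in atom_names], axis=1).reshape(-1, 3)
            a1, a2 = xyz[dom1_atoms], xyz[dom2_atoms]
            dmin = np.sqrt(
                np.min(np.sum((a1[:, None, :] - a2[None, :, :]) ** 2, axis=2))
            )
            if dmin >= clash_distance:
                coords.append(xyz)
                break
        else:
            raise RuntimeError(
                "could not place clash-free domains — linker too short or "
                "dispersion too high"
            )
    atoms = pd.DataFrame(
        {
            "chain": "A",
            "resid": np.repeat(np.arange(1, n_res + 1), len(atom_names)),
            "resname": "ALA",
            "name": atom_names * n_res,
            "element": [n[0] for n in atom_names] * n_res,
        }
    )
    ens = StructureEnsemble(atoms, np.stack(coords))
    truth = GroundTruth(
        "ensemble",
        {
            "domain_size": domain_size,
            "linker_length": linker_length,
            "linker_dispersion": linker_dispersion,
            "domain1": (1, domain_size),
            "domain2": (domain_size + linker_length + 1, n_res),
        },
        seed,
    )
    return ens, truth


# ---------------------------------------------------------------------------
# RDC / PRE / ITC
# ---------------------------------------------------------------------------

def make_rdc_set(
    ens: StructureEnsemble,
    conformer: int,
    tensor: AlignmentTensor,
    noise_sd: float = 0.5,
    seed: int = 0,
    selection: Sequence[tuple[int, int]] | None = None,
    chain: str = "A",
) -> tuple[pd.DataFrame, GroundTruth]:
    """Couplings from the dipolar forward model plus Gaussian noise (Hz)."""
    rng = np.random.default_rng(seed)
    table = back_calculate(tensor, ens, conformer, selection, chain)
    table = table.copy()
    table["d_hz"] = table["d_hz"] + rng.normal(0.0, noise_sd, len(table))
    table["err_hz"] = noise_sd if noise_sd > 0 else 1e-6
    truth = GroundTruth(
        "rdc",
        {
            "da": tensor.da,
            "rhombicity": tensor.rhombicity,
            "euler_zyz": tensor.euler_zyz,
            "noise_sd": noise_sd,
            "conformer": conformer,
        },
        seed,
    )
    return table, truth


def make_pre_set(
    ens: StructureEnsemble,
    site: LabelSite,
    params: pre_mod.PREParams,
    noise_sd: float = 0.03,
    seed: int = 0,
    target_chain: str = "A",
) -> tuple[pd.DataFrame, GroundTruth]:
    """Observed-style PRE ratios: ensemble-mean forward model plus noise."""
    rng = np.random.default_rng(seed)
    profile = pre_mod.predict_profile(ens, site, params, target_chain)
    obs = pd.DataFrame(
        {
            "residue": profile["residue"],
            "ratio": profile["ratio"] + rng.normal(0.0, noise_sd, len(profile)),
            "err": noise_sd if noise_sd > 0 else 1e-6,
        }
    )
    truth = GroundTruth(
        "pre",
        {
            "site": site.residue_id,
            "position_model": site.position_model,
            "tauc_ns": params.tauc_ns,
            "r2_dia": params.r2_dia,
            "noise_sd": noise_sd,
        },
        seed,
    )
    return obs, truth


def make_itc_isotherm(
    model: itc_mod.BindingModel,
    schedule: itc_mod.InjectionSchedule,
    noise_sd: float = 0.1,
    seed: int = 0,
) -> tuple[itc_mod.ITCExperiment, GroundTruth]:
    """Per-injection heats from the binding forward model plus noise (ucal)."""
    rng = np.random.default_rng(seed)
    exp = itc_mod.simulate_isotherm(model, schedule)
    exp.heats = exp.heats + rng.normal(0.0, noise_sd, exp.heats.size)
    truth = GroundTruth(
        "itc",
        {
            "variant": model.variant,
            "n_sites": model.n_sites,
            "kd_um": model.kd,
            "dh_kcal": model.dh,
            "k_closed": model.k_closed,
            "noise_sd": noise_sd,
            "macromolecule": schedule.macromolecule,
        },
        seed,
    )
    return exp, truth
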