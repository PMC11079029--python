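"""ITC binding models: one-site isotherms and autoinhibited receptors.

The forward model follows the standard perfusion-cell bookkeeping: each
injection of volume dV into a cell of volume V0 dilutes the resident
species by (1 - dV/V0) and adds dV/V0 of the syringe concentration; the
bound complex concentration then follows from the identical-sites binding
polynomial and the measured heat is the enthalpy released by the *change*
in bound complex,

    q_i = 1e-3 * dH * V0 * (B_i - B_{i-1} * (1 - dV_i/V0))   [ucal],

with dH in kcal/mol, V0 in uL and concentrations in uM.

Autoinhibition is modeled as a two-state receptor: an intramolecular
proline-rich extension occupies the WW tandem with equilibrium constant
k_closed = [closed]/[open], and external ligand binds only the open state.
For such a pre-equilibrium the apparent affinity seen by a one-site fit is

    Kd_app = Kd_intrinsic * (1 + k_closed),

which is how an N-terminal extension weakens peptide binding without
changing the intrinsic site.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import lmfit
import numpy as np
import pandas as pd
from scipy.optimize import brentq

Variant = Literal["one_site", "autoinhibited"]
Species = Literal["cell", "syringe"]


@dataclass
class InjectionSchedule:
    """Cell/syringe contents and the injection volume ladder.

    Concentrations in uM, volumes in uL.  ``macromolecule`` names the
    species that carries the N identical binding sites (usually the cell
    species; the syringe when a multivalent construct is titrated into a
    single-site receptor).
    """

    cell_volume: float = 200.0
    injection_volumes: Sequence[float] = field(default_factory=lambda: (0.4,) + (1.5,) * 25)
    spacing_s: float = 150.0
    cell_conc: float = 30.0
    syringe_conc: float = 450.0
    cell_species: str = "peptide"
    syringe_species: str = "tandem"
    macromolecule: Species = "cell"

    def __post_init__(self) -> None:
        self.injection_volumes = tuple(float(v) for v in self.injection_volumes)
        if self.cell_volume <= 0 or any(v <= 0 for v in self.injection_volumes):
            raise ValueError("volumes must be positive")
        if self.cell_conc <= 0 or self.syringe_conc <= 0:
            raise ValueError("concentrations must be positive")

    @property
    def n_injections(self) -> int:
        return len(self.injection_volumes)


def default_schedule(**kwargs) -> InjectionSchedule:
    """The 26-injection schedule (0.4 uL first, then 25 x 1.5 uL, 150 s)."""
    return InjectionSchedule(**kwargs)


@dataclass
class BindingModel:
    """Thermodynamic parameters of the binding reaction.

    ``n_sites`` is the number of identical sites per macromolecule,
    ``kd`` the per-site dissociation constant in uM, ``dh`` the molar
    enthalpy in kcal/mol, and ``k_closed`` the closed/open ratio of the
    autoinhibited receptor ([closed]/[open]; 0 means no autoinhibition).
    """

    variant: Variant = "one_site"
    n_sites: float = 1.0
    kd: float = 1.0
    dh: float = -8.0
    k_closed: float = 0.0

    def __post_init__(self) -> None:
        if self.kd <= 0 or self.n_sites <= 0:
            raise ValueError("kd and n_sites must be positive")
        if self.k_closed < 0:
            raise ValueError("k_closed must be >= 0")


@dataclass
class ITCExperiment:
    schedule: InjectionSchedule
    heats: np.ndarray  # ucal per injection
    blank_subtracted: bool = True

    def __post_init__(self) -> None:
        self.heats = np.asarray(self.heats, dtype=float)
        if len(self.heats) != self.schedule.n_injections:
            raise ValueError("one heat per injection required")

    def molar_ratios(self) -> np.ndarray:
        """Cumulative syringe:cell molar ratio after each injection."""
        mt, xt = _titration_totals(self.schedule)
        return xt / mt


# ---------------------------------------------------------------------------
# Equilibrium solvers
# ---------------------------------------------------------------------------

def _bound_quadratic(sites: float, ligand: float, kd: float) -> float:
    """Complex concentration for identical independent sites (uM)."""
    b = sites + ligand + kd
    disc = b * b - 4.0 * sites * ligand
    return 0.5 * (b - math.sqrt(max(disc, 0.0)))


def solve_equilibrium(
    receptor_total: float, ligand_total: float, kd: float, k_closed: float = 0.0
) -> dict:
    """Open/closed/bound/free concentrations for the autoinhibited receptor.

    The receptor interconverts between an open state that binds ligand with
    dissociation constant ``kd`` and a ligand-inaccessible closed state with
    [closed]/[open] = ``k_closed``.  Solved by bracketing the bound
    concentration; satisfies both equilibrium constants and mass balance to
    high precision.
    """
    if receptor_total < 0 or ligand_total < 0:
        raise ValueError("totals must be non-negative")
    if ligand_total == 0 or receptor_total == 0:
        open_c = receptor_total / (1.0 + k_closed)
        return {
            "open": open_c,
            "closed": receptor_total - open_c,
            "bound": 0.0,
            "free_ligand": ligand_total,
        }

    def f(b: float) -> float:
        return (receptor_total - b) * (ligand_total - b) / (1.0 + k_closed) - kd * b

    hi = min(receptor_total, ligand_total)
    bound = brentq(f, 0.0, hi, xtol=1e-14, rtol=1e-14)
    open_c = (receptor_total - bound) / (1.0 + k_closed)
    return {
        "open": open_c,
        "closed": k_closed * open_c,
        "bound": bound,
        "free_ligand": ligand_total - bound,
    }


def kd_apparent(kd_intrinsic: float, k_closed: float) -> float:
    """Apparent Kd of an autoinhibited receptor: Kd * (1 + k_closed)."""
    return kd_intrinsic * (1.0 + k_closed)


# ---------------------------------------------------------------------------
# Forward model
# ---------------------------------------------------------------------------

def _titration_totals(schedule: InjectionSchedule) -> tuple[np.ndarray, np.ndarray]:
    """Cell-resident total concentrations after each injection (uM)."""
    v0 = schedule.cell_volume
    mt, xt = schedule.cell_conc, 0.0
    mts, xts = [], []
    for dv in schedule.injection_volumes:
        f = 1.0 - dv / v0
        mt *= f
        xt = xt * f + schedule.syringe_conc * dv / v0
        mts.append(mt)
        xts.append(xt)
    return np.asarray(mts), np.asarray(xts)


def _bound_series(model: BindingModel, schedule: InjectionSchedule) -> np.ndarray:
    mts, xts = _titration_totals(schedule)
    if schedule.macromolecule == "cell":
        sites, ligand = model.n_sites * mts, xts
    else:
        sites, ligand = model.n_sites * xts, mts
    bound = np.empty_like(sites)
    for i, (s, l) in enumerate(zip(sites, ligand)):
        if model.variant == "autoinhibited":
            bound[i] = solve_equilibrium(s, l, model.kd, model.k_closed)["bound"]
        else:
            bound[i] = _bound_quadratic(s, l, model.kd)
    return bound


def simulate_isotherm(
    model: BindingModel, schedule: InjectionSchedule, offset: float = 0.0
) -> ITCExperiment:
    """Noise-free per-injection heats (ucal) for the given binding model.

    ``offset`` adds a constant heat of dilution per injection.
    """
    bound = _bound_series(model, schedule)
    v0 = schedule.cell_volume
    heats = np.empty_like(bound)
    prev = 0.0
    for i, dv in enumerate(schedule.injection_volumes):
        f = 1.0 - dv / v0
        heats[i] = 1e-3 * model.dh * v0 * (bound[i] - prev * f) + offset
        prev = bound[i]
    return ITCExperiment(schedule=schedule, heats=heats)


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

@dataclass
class IsothermFit:
    model: BindingModel
    offset: float
    errors: dict
    c_value: float
    rmsd_ucal: float
    n_points: int


def wiseman_c(model: BindingModel, schedule: InjectionSchedule) -> float:
    """Wiseman parameter c = N * [macromolecule in cell] / Kd."""
    conc = (
        schedule.cell_conc
        if schedule.macromolecule == "cell"
        else schedule.syringe_conc
    )
    return model.n_sites * conc / model.kd


def _initial_guesses(exp: ITCExperiment) -> tuple[float, float, float]:
    """(n, kd, dh) heuristics: plateau enthalpy, inflection ratio, slope."""
    sched = exp.schedule
    ratios = exp.molar_ratios()
    heats = exp.heats
    mts, _ = _titration_totals(sched)
    # steepest change in heat marks the equivalence point
    k = int(np.argmax(np.abs(np.diff(heats[1:])))) + 1
    n0 = min(max(float(ratios[k]), 1e-2), 50.0)
    total_heat = float(np.sum(heats))  # ucal
    moles_sites = n0 * mts[-1] * sched.cell_volume * 1e-12  # mol
    dh0 = total_heat * 1e-9 / moles_sites if moles_sites > 0 else -8.0
    kd0 = 0.1 * sched.cell_conc
    return n0, kd0, float(dh0)


def fit_isotherm(
    exp: ITCExperiment,
    variant: Variant = "one_site",
    fix: dict | None = None,
    exclude_first: bool = True,
    fit_offset: bool = True,
    noise_floor: float | None = None,
) -> IsothermFit:
    """Nonlinear least-squares fit of (N, Kd, dH[, offset]) to the heats.

    The fit always adopts the instrument convention that the cell species
    is the macromolecule carrying N sites — whatever forward model produced
    the data — so a multivalent syringe construct shows up as fitted N < 1
    (see :func:`tandems_per_peptide`).  The first (small-volume) injection
    is excluded from the residuals by default.  The autoinhibited variant is
    only identifiable with a pin on ``kd`` or ``k_closed`` via ``fix``
    (otherwise only their product Kd(1 + k_closed) is determined).
    Restarts over a Kd grid guard against a poor initialization.
    """
    fix = dict(fix or {})
    heats = exp.heats
    used = slice(1, None) if exclude_first else slice(None)
    if heats[used].size < 8:
        raise ValueError("need at least 8 informative injections")
    span = float(np.max(np.abs(heats[used])))
    if span == 0.0 or (noise_floor is not None and span < noise_floor):
        raise ValueError("flat isotherm — no binding heat to fit")
    if variant == "autoinhibited" and not ({"kd", "k_closed"} & set(fix)):
        raise ValueError(
            "autoinhibited fits need kd or k_closed pinned (only their "
            "product is identifiable from one isotherm)"
        )

    n0, kd0, dh0 = _initial_guesses(exp)
    sched_fit = replace(exp.schedule, macromolecule="cell")

    def residuals(params: lmfit.Parameters) -> np.ndarray:
        model = BindingModel(
            variant=variant,
            n_sites=params["n"].value,
            kd=math.exp(params["log_kd"].value),
            dh=params["dh"].value,
            k_closed=params["k_closed"].value,
        )
        sim = simulate_isotherm(model, sched_fit, offset=params["offset"].value)
        return (sim.heats - heats)[used]

    best = None
    for kd_try in (kd0, kd0 * 10.0, kd0 * 0.1):
        params = lmfit.Parameters()
        params.add("n", value=fix.get("n", n0), min=1e-3, max=100.0, vary="n" not in fix)
        params.add(
            "log_kd",
            value=math.log(fix.get("kd", kd_try)),
            min=math.log(1e-5),
            max=math.log(1e5),
            vary="kd" not in fix,
        )
        params.add("dh", value=fix.get("dh", dh0), vary="dh" not in fix)
        params.add(
            "k_closed",
            value=fix.get("k_closed", 0.0),
            min=0.0,
            vary=variant == "autoinhibited" and "k_closed" not in fix,
        )
        params.add("offset", value=0.0, vary=fit_offset and "offset" not in fix)
        try:
            res = lmfit.minimize(
                residuals, params, method="leastsq", xtol=1e-14, ftol=1e-14
            )
        except Exception:
            continue
        if best is None or res.chisqr < best.chisqr:
            best = res
        if best.chisqr < (1e-12 * span) ** 2 * heats[used].size:
            break
    if best is None:
        raise RuntimeError("isotherm fit failed to converge")

    p = best.params
    model = BindingModel(
        variant=variant,
        n_sites=p["n"].value,
        kd=math.exp(p["log_kd"].value),
        dh=p["dh"].value,
        k_closed=p["k_closed"].value,
    )
    errors = {}
    for name in ("n", "dh", "offset", "k_closed"):
        errors[name] = p[name].stderr if p[name].stderr is not None else float("nan")
    if p["log_kd"].stderr is not None:
        errors["kd"] = model.kd * p["log_kd"].stderr  # delta method
    else:
        errors["kd"] = float("nan")
    c = wiseman_c(model, sched_fit)
    if not (1.0 <= c <= 1000.0):
        warnings.warn(
            f"Wiseman c = {c:.3g} outside [1, 1000]; Kd is weakly constrained"
        )
    rmsd = float(np.sqrt(best.chisqr / heats[used].size))
    return IsothermFit(
        model=model,
        offset=p["offset"].value,
        errors=errors,
        c_value=c,
        rmsd_ucal=rmsd,
        n_points=int(heats[used].size),
    )


def tandems_per_peptide(n_fitted: float, peptide_in: Species) -> float:
    """Convert a fitted site number to WW tandems bound per peptide.

    With the peptide in the cell, N counts tandems per peptide directly;
    with the peptide in the syringe, the cell receptor's fitted N is
    peptides per tandem, so the stoichiometry of interest is 1/N.
    """
    if peptide_in == "cell":
        return float(n_fitted)
    return 1.0 / float(n_fitted)


# ---------------------------------------------------------------------------
# Tabular I/O: header block + injection rows
# ---------------------------------------------------------------------------

def read_itc(path: str) -> ITCExperiment:
    """Read the delimited ITC format written by :func:`write_itc`."""
    header: dict[str, str] = {}
    rows: list[tuple[float, float]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("injection_volume"):
                continue
            if line.startswith("#"):
                key, _, value = line[1:].strip().partition("=")
                header[key.strip()] = value.strip()
            else:
                vol, heat = line.split("\t")
                rows.append((float(vol), float(heat)))
    schedule = InjectionSchedule(
        cell_volume=float(header.get("cell_volume_ul", 200.0)),
        injection_volumes=[v for v, _ in rows],
        cell_conc=float(header["cell_conc_um"]),
        syringe_conc=float(header["syringe_conc_um"]),
        cell_species=header.get("cell_species", "cell"),
        syringe_species=header.get("syringe_species", "syringe"),
        macromolecule=header.get("macromolecule", "cell"),
    )
    return ITCExperiment(schedule=schedule, heats=[h for _, h in rows])


def write_itc(exp: ITCExperiment, path: str) -> None:
    s = exp.schedule
    with open(path, "w") as fh:
        fh.write(f"# cell_volume_ul = {s.cell_volume}\n")
        fh.write(f"# cell_conc_um = {s.cell_conc}\n")
        fh.write(f"# syringe_conc_um = {s.syringe_conc}\n")
        fh.write(f"# cell_species = {s.cell_species}\n")
        fh.write(f"# syringe_species = {s.syringe_species}\n")
        fh.write(f"# macromolecule = {s.macromolecule}\n")
        fh.write("injection_volume_uL\theat_ucal\n")
        for v, h in zip(s.injection_volumes, exp.heats):
            fh.write(f"{v}\t{float(h)!r}\n")
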