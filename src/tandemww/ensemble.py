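"""Multi-conformer structure handling: PDB ensembles, superposition, RMSD.

The structures this package cares about are NMR-style ensembles: an ordered
set of conformers sharing one atom inventory (e.g. the 20 lowest-energy
models of a tandem WW domain construct).  Coordinates are stored as a single
``(n_conformers, n_atoms, 3)`` array next to a flat atom table, which makes
selections, superpositions and distance extraction plain numpy operations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import gemmi
import numpy as np
import pandas as pd

BACKBONE_ATOMS = ("N", "CA", "C", "O")

AtomClass = Literal["backbone", "heavy", "all"]


@dataclass
class StructureEnsemble:
    """Ordered conformers over a shared atom inventory.

    Attributes
    ----------
    atoms:
        One row per atom with columns ``chain``, ``resid`` (author numbering),
        ``resname``, ``name`` and ``element``.
    coords:
        Array of shape ``(n_conformers, n_atoms, 3)`` in Angstrom.
    """

    atoms: pd.DataFrame
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_conformers, n_atoms, 3)")
        if self.coords.shape[1] != len(self.atoms):
            raise ValueError("coords second axis must match the atom table")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates in ensemble")

    @property
    def n_conformers(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def conformer(self, i: int) -> np.ndarray:
        """Coordinates of conformer ``i`` as an ``(n_atoms, 3)`` view."""
        return self.coords[i]

    def atom_index(self, chain: str, resid: int, name: str) -> int:
        hit = np.flatnonzero(
            (self.atoms["chain"].to_numpy() == chain)
            & (self.atoms["resid"].to_numpy() == resid)
            & (self.atoms["name"].to_numpy() == name)
        )
        if hit.size == 0:
            raise KeyError(f"atom {chain}:{resid}:{name} not in ensemble")
        return int(hit[0])

    def residues(self, chain: str | None = None) -> list[int]:
        tab = self.atoms if chain is None else self.atoms[self.atoms["chain"] == chain]
        return sorted(tab["resid"].unique().tolist())


@dataclass
class Selection:
    """Residue ranges plus an atom class, resolving to atom indices.

    ``ranges`` is a list of ``(chain, first_resid, last_resid)`` with
    inclusive author numbering, e.g. ``[("A", 146, 221), ("B", 575, 582)]``.
    """

    ranges: Sequence[tuple[str, int, int]]
    atoms: AtomClass = "backbone"

    def mask(self, ens: StructureEnsemble, atoms: AtomClass | None = None) -> np.ndarray:
        atom_class = self.atoms if atoms is None else atoms
        tab = ens.atoms
        in_range = np.zeros(len(tab), dtype=bool)
        chain = tab["chain"].to_numpy()
        resid = tab["resid"].to_numpy()
        for ch, lo, hi in self.ranges:
            in_range |= (chain == ch) & (resid >= lo) & (resid <= hi)
        if atom_class == "backbone":
            in_range &= tab["name"].isin(BACKBONE_ATOMS).to_numpy()
        elif atom_class == "heavy":
            in_range &= (tab["element"].to_numpy() != "H")
        elif atom_class != "all":
            raise ValueError(f"unknown atom class {atom_class!r}")
        return in_range

    def indices(self, ens: StructureEnsemble, atoms: AtomClass | None = None) -> np.ndarray:
        idx = np.flatnonzero(self.mask(ens, atoms))
        if idx.size < 3:
            raise ValueError("selection resolves to fewer than 3 atoms")
        return idx


def parse_selection(text: str, atoms: AtomClass = "backbone") -> Selection:
    """Parse ``A:146-221,B:575-582,B:586-590`` into a :class:`Selection`."""
    ranges = []
    for chunk in text.split(","):
        chunk = chunk.strip()
        if not chunk:
            continue
        if ":" in chunk:
            chain, span = chunk.split(":", 1)
        else:
            chain, span = "A", chunk
        lo, _, hi = span.partition("-")
        ranges.append((chain, int(lo), int(hi or lo)))
    return Selection(ranges, atoms)


# ---------------------------------------------------------------------------
# PDB I/O (gemmi)
# ---------------------------------------------------------------------------

def read_ensemble(path: str, strict: bool = True) -> StructureEnsemble:
    """Read a multi-MODEL PDB file into a :class:`StructureEnsemble`.

    Author residue numbering is preserved; altlocs other than blank/'A' are
    dropped with a warning; hydrogens are retained.  In strict mode an
    inconsistent atom inventory across MODELs is an error; in lenient mode
    the intersection of inventories is used.
    """
    st = gemmi.read_structure(path)
    if len(st) == 0:
        raise ValueError(f"no MODEL records in {path}")
    per_model: list[dict[tuple, np.ndarray]] = []
    dropped_altloc = False
    for model in st:
        atoms: dict[tuple, np.ndarray] = {}
        for chain in model:
            for res in chain:
                for atom in res:
                    if atom.altloc not in ("", "A", "\x00"):
                        dropped_altloc = True
                        continue
                    key = (chain.name, res.seqid.num, res.name, atom.name)
                    atoms[key] = np.array([atom.pos.x, atom.pos.y, atom.pos.z])
        per_model.append(atoms)
    if dropped_altloc:
        warnings.warn("dropped altloc conformations other than blank/'A'")
    keys = list(per_model[0])
    keyset = set(keys)
    for i, atoms in enumerate(per_model[1:], start=2):
        if set(atoms) != keyset:
            if strict:
                raise ValueError(
                    f"MODEL {i} atom inventory differs from MODEL 1 "
                    "(use strict=False to intersect)"
                )
            keyset &= set(atoms)
    if not strict:
        keys = [k for k in keys if k in keyset]
    table = pd.DataFrame(
        keys, columns=["chain", "resid", "resname", "name"]
    )
    table["element"] = [_element_of(n) for n in table["name"]]
    coords = np.stack(
        [np.array([m[k] for k in keys]) for m in per_model]
    )
    return StructureEnsemble(table, coords)


def _element_of(atom_name: str) -> str:
    name = atom_name.strip()
    if name[:1].isdigit():
        name = name.lstrip("0123456789")
    return "H" if name.startswith("H") else name[0]


def write_ensemble(ens: StructureEnsemble, path: str) -> None:
    """Write the ensemble as a multi-MODEL PDB file."""
    st = gemmi.Structure()
    st.name = "ensemble"
    for m in range(ens.n_conformers):
        model = gemmi.Model(m + 1)
        # gemmi copies on add_*, so assemble each chain bottom-up
        chain_order: list[str] = []
        residues: dict[str, list[gemmi.Residue]] = {}
        current: tuple[str, int] | None = None
        for row, xyz in zip(ens.atoms.itertuples(index=False), ens.coords[m]):
            if row.chain not in residues:
                residues[row.chain] = []
                chain_order.append(row.chain)
                current = None
            if current != (row.chain, row.resid):
                res = gemmi.Residue()
                res.name = row.resname
                res.seqid = gemmi.SeqId(int(row.resid), " ")
                residues[row.chain].append(res)
                current = (row.chain, row.resid)
            atom = gemmi.Atom()
            atom.name = row.name
            atom.element = gemmi.Element(row.element)
            atom.pos = gemmi.Position(*xyz)
            residues[row.chain][-1].add_atom(atom)
        for name in chain_order:
            chain = gemmi.Chain(name)
            for res in residues[name]:
                chain.add_residue(res)
            model.add_chain(chain)
        st.add_model(model)
    st.setup_entities()
    st.write_pdb(path)


# ---------------------------------------------------------------------------
# Superposition and RMSD
# ---------------------------------------------------------------------------

def kabsch(mobile: np.ndarray, reference: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal least-squares rigid superposition of paired coordinates.

    Returns ``(rotation, translation, rmsd)`` such that
    ``mobile @ rotation.T + translation`` best matches ``reference``.  A
    proper rotation (det = +1) is enforced.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("paired (n, 3) coordinate arrays required")
    if len(mobile) < 3:
        raise ValueError("at least 3 atoms required for superposition")
    mc = mobile.mean(axis=0)
    rc = reference.mean(axis=0)
    h = (mobile - mc).T @ (reference - rc)
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = rc - rot @ mc
    moved = mobile @ rot.T + trans
    rmsd = float(np.sqrt(np.mean(np.sum((moved - reference) ** 2, axis=1))))
    return rot, trans, rmsd


def kabsch_superpose(
    ens: StructureEnsemble,
    mobile: int,
    reference: int,
    sel: Selection,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Superpose conformer ``mobile`` onto ``reference`` over ``sel``."""
    idx = sel.indices(ens)
    return kabsch(ens.coords[mobile][idx], ens.coords[reference][idx])


def _rmsd_to_mean(coords: np.ndarray, n_iter: int = 2) -> float:
    """Mean per-conformer RMSD to the iteratively refined mean structure."""
    ref = coords[0]
    fitted = coords.copy()
    for _ in range(n_iter):
        for i in range(len(fitted)):
            rot, trans, _ = kabsch(fitted[i], ref)
            fitted[i] = fitted[i] @ rot.T + trans
        ref = fitted.mean(axis=0)
    per_conf = np.sqrt(np.mean(np.sum((fitted - ref) ** 2, axis=2), axis=1))
    return float(per_conf.mean())


def _rmsd_pairwise(coords: np.ndarray) -> float:
    vals = []
    n = len(coords)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            _, _, r = kabsch(coords[i], coords[j])
            vals.append(r)
    return float(np.mean(vals))


def ensemble_rmsd(
    ens: StructureEnsemble,
    sel: Selection,
    mode: Literal["to_mean", "pairwise"] = "to_mean",
) -> tuple[float, float]:
    """Ensemble precision over ``sel`` as ``(backbone_rmsd, heavy_rmsd)`` in A.

    ``to_mean`` superposes all conformers onto an iteratively refined mean
    structure (two refinement passes) and averages the per-conformer RMSD to
    that mean; ``pairwise`` averages the RMSD over all ordered conformer
    pairs after pairwise superposition.  Both atom classes use their own
    superposition.
    """
    if ens.n_conformers < 2:
        raise ValueError("ensemble RMSD needs at least 2 conformers")
    out = []
    for atom_class in ("backbone", "heavy"):
        idx = sel.indices(ens, atoms=atom_class)
        coords = ens.coords[:, idx, :]
        if mode == "to_mean":
            out.append(_rmsd_to_mean(coords))
        elif mode == "pairwise":
            out.append(_rmsd_pairwise(coords))
        else:
            raise ValueError(f"unknown mode {mode!r}")
    return out[0], out[1]


# ---------------------------------------------------------------------------
# Spin-label geometry (feeds the PRE forward model)
# ---------------------------------------------------------------------------

@dataclass
class LabelSite:
    """A paramagnetic label attachment point.

    ``CB_point`` places the unpaired electron at the Cbeta of the labeled
    residue; ``offset_point`` projects it ``offset`` Angstrom from the
    Calpha along the Calpha->Cbeta direction, mimicking the reach of a
    nitroxide arm.
    """

    residue_id: int
    chain: str = "A"
    position_model: Literal["CB_point", "offset_point"] = "CB_point"
    offset: float = 6.0

    def positions(self, ens: StructureEnsemble) -> np.ndarray:
        """Label position per conformer, shape ``(n_conformers, 3)``."""
        ca = ens.coords[:, ens.atom_index(self.chain, self.residue_id, "CA"), :]
        cb = ens.coords[:, ens.atom_index(self.chain, self.residue_id, "CB"), :]
        if self.position_model == "CB_point":
            return cb
        vec = cb - ca
        vec /= np.linalg.norm(vec, axis=1, keepdims=True)
        return ca + self.offset * vec


def amide_positions(
    ens: StructureEnsemble, chain: str = "A"
) -> tuple[list[int], np.ndarray, np.ndarray]:
    """Backbone amide N and H positions for every residue that has them.

    Returns ``(residue_ids, n_xyz, h_xyz)`` with coordinate arrays of shape
    ``(n_conformers, n_residues, 3)``.  Amide protons missing from the
    coordinates are built geometrically: in the Cprev-N-CA plane, 1.02 A
    from N along the exterior bisector.  The chain's first residue (no
    preceding carbonyl) and proline-like residues without an H are skipped
    only if the H cannot be built.
    """
    resids = ens.residues(chain)
    out_ids: list[int] = []
    n_list: list[np.ndarray] = []
    h_list: list[np.ndarray] = []
    for k, resid in enumerate(resids):
        try:
            i_n = ens.atom_index(chain, resid, "N")
            i_ca = ens.atom_index(chain, resid, "CA")
        except KeyError:
            continue
        n_xyz = ens.coords[:, i_n, :]
        try:
            h_xyz = ens.coords[:, ens.atom_index(chain, resid, "H"), :]
        except KeyError:
            if k == 0:
                continue
            try:
                i_cprev = ens.atom_index(chain, resids[k - 1], "C")
            except KeyError:
                continue
            h_xyz = build_amide_h(
                ens.coords[:, i_cprev, :], n_xyz, ens.coords[:, i_ca, :]
            )
        out_ids.append(resid)
        n_list.append(n_xyz)
        h_list.append(h_xyz)
    if not out_ids:
        raise ValueError(f"no resolvable amides on chain {chain!r}")
    return out_ids, np.stack(n_list, axis=1), np.stack(h_list, axis=1)


def build_amide_h(c_prev: np.ndarray, n: np.ndarray, ca: np.ndarray) -> np.ndarray:
    """Geometric amide proton: 1.02 A from N on the exterior bisector."""
    v1 = n - c_prev
    v2 = n - ca
    v1 = v1 / np.linalg.norm(v1, axis=-1, keepdims=True)
    v2 = v2 / np.linalg.norm(v2, axis=-1, keepdims=True)
    d = v1 + v2
    d = d / np.linalg.norm(d, axis=-1, keepdims=True)
    return n + 1.02 * d


def label_distances(
    ens: StructureEnsemble,
    site: LabelSite,
    target_chain: str = "A",
    target_atom: str | None = None,
) -> tuple[list[int], np.ndarray]:
    """Label-to-target distances, shape ``(n_conformers, n_residues)`` in A.

    By default the targets are the backbone amide protons (built
    geometrically when absent); passing ``target_atom`` measures to that
    named atom instead, skipping residues that lack it.
    """
    if target_atom is None:
        resids, _, t_xyz = amide_positions(ens, target_chain)
    else:
        resids, coords = [], []
        for resid in ens.residues(target_chain):
            try:
                idx = ens.atom_index(target_chain, resid, target_atom)
            except KeyError:
                continue
            resids.append(resid)
            coords.append(ens.coords[:, idx, :])
        if not resids:
            raise ValueError(f"no {target_atom!r} atoms on chain {target_chain!r}")
        t_xyz = np.stack(coords, axis=1)
    label = site.positions(ens)[:, None, :]
    dist = np.linalg.norm(t_xyz - label, axis=2)
    return resids, dist
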