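"""Chemical shift perturbation analysis for ligand titrations.

CSPs combine the proton and heteronucleus shift changes of one correlation
into a single weighted distance in ppm:

    CSP(HN) = sqrt(0.5 * (d_H^2 + 0.14 * d_N^2))      (1H-15N correlations)
    CSP(HC) = sqrt(0.5 * (d_H^2 + 0.30 * d_C^2))      (1H-13C correlations)

The heteronucleus weights compensate for the wider 15N/13C ppm ranges.
Tryptophan side-chain Neps-Heps correlations use the 15N weight; methyl
1H-13C correlations use the 13C weight, and a residue's methyl CSP is the
maximum over its methyls.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal

import numpy as np
import pandas as pd

#: heteronucleus weights for the combined shift distance
CSP_WEIGHTS = {"N15": 0.14, "C13": 0.3}

Nucleus = Literal["N15", "C13"]

PEAK_COLUMNS = ["residue", "atom", "shift_h", "shift_x", "nucleus", "intensity"]


@dataclass
class TitrationSeries:
    """One titration point: a peak list at a given ligand:protein ratio.

    ``peaks`` has columns ``residue`` (author numbering), ``atom`` (e.g. "HN",
    "HE1", "MD1"), ``shift_h`` and ``shift_x`` in ppm, ``nucleus`` ("N15" or
    "C13") and optionally ``intensity``.  Ratio 0 denotes the free state.
    """

    ratio: float
    peaks: pd.DataFrame
    label: str = ""

    def __post_init__(self) -> None:
        if self.ratio < 0:
            raise ValueError("ligand:protein ratio must be >= 0")
        missing = {"residue", "atom", "shift_h", "shift_x", "nucleus"} - set(
            self.peaks.columns
        )
        if missing:
            raise ValueError(f"peak list missing columns {sorted(missing)}")
        if not np.all(np.isfinite(self.peaks[["shift_h", "shift_x"]].to_numpy(float))):
            raise ValueError("non-finite chemical shifts in peak list")


def csp_value(delta_h: float, delta_x: float, nucleus_x: Nucleus = "N15") -> float:
    """Weighted chemical shift perturbation in ppm.

    Symmetric in the sign of both shift differences and zero only when both
    are zero.
    """
    if not (math.isfinite(delta_h) and math.isfinite(delta_x)):
        raise ValueError("non-finite shift difference (malformed peak matching?)")
    w = CSP_WEIGHTS[nucleus_x]
    return math.sqrt(0.5 * (delta_h**2 + w * delta_x**2))


def series_csp(reference: TitrationSeries, other: TitrationSeries) -> pd.DataFrame:
    """Per-peak CSP table between two titration points.

    Peaks are matched on ``(residue, atom)``.  The result has columns
    ``residue``, ``atom``, ``nucleus``, ``csp`` and ``flag`` where the flag is
    ``measured`` for matched pairs and ``missing`` for peaks present in only
    one list (their csp is NaN, never zero).  Works for free-vs-bound
    (reference ratio 0) and bound-vs-bound comparisons alike, and is
    symmetric in its arguments.
    """
    ref = reference.peaks.set_index(["residue", "atom"])
    oth = other.peaks.set_index(["residue", "atom"])
    common = ref.index.intersection(oth.index)
    if len(common) == 0:
        raise ValueError("no shared (residue, atom) peaks — mismatched assignments?")
    rows = []
    for key in ref.index.union(oth.index):
        if key in common:
            r, o = ref.loc[key], oth.loc[key]
            val = csp_value(
                float(o["shift_h"]) - float(r["shift_h"]),
                float(o["shift_x"]) - float(r["shift_x"]),
                str(r["nucleus"]),
            )
            rows.append((*key, r["nucleus"], val, "measured"))
        else:
            side = ref if key in ref.index else oth
            rows.append((*key, side.loc[key]["nucleus"], np.nan, "missing"))
    table = pd.DataFrame(rows, columns=["residue", "atom", "nucleus", "csp", "flag"])
    return table.sort_values(["residue", "atom"]).reset_index(drop=True)


def residue_csp(table: pd.DataFrame) -> pd.DataFrame:
    """Collapse a per-peak CSP table to one value per residue (max over peaks)."""
    measured = table[table["flag"] == "measured"]
    out = measured.groupby("residue", as_index=False)["csp"].max()
    return out


def interface_residues(
    table: pd.DataFrame,
    method: Literal["mean_plus_sd", "fixed_threshold"] = "mean_plus_sd",
    threshold: float | None = None,
) -> pd.DataFrame:
    """Call perturbed (interface) residues from a CSP table.

    ``mean_plus_sd`` flags residues whose CSP exceeds mean + 1 SD over all
    measured entries (the conventional cutoff when a paper states none);
    ``fixed_threshold`` uses the given ppm cutoff.  Returns the called
    residues with their margin above the cutoff.
    """
    per_res = residue_csp(table)
    values = table.loc[table["flag"] == "measured", "csp"].to_numpy(float)
    if values.size == 0:
        raise ValueError("all entries missing — empty CSP table")
    if values.size < 5:
        raise ValueError("need at least 5 measured entries to call an interface")
    if method == "mean_plus_sd":
        cut = float(values.mean() + values.std(ddof=1))
    elif method == "fixed_threshold":
        if threshold is None:
            raise ValueError("fixed_threshold requires a threshold in ppm")
        cut = float(threshold)
    else:
        raise ValueError(f"unknown method {method!r}")
    called = per_res[per_res["csp"] > cut].copy()
    called["margin"] = called["csp"] - cut
    called["cutoff"] = cut
    return called.reset_index(drop=True)


# ---------------------------------------------------------------------------
# Tabular I/O
# ---------------------------------------------------------------------------

def read_peaklist(path: str, ratio: float = 0.0, label: str = "") -> TitrationSeries:
    """Read a delimited peak list (columns residue, atom, shift_h, shift_x,
    nucleus[, intensity])."""
    peaks = pd.read_csv(path, sep=None, engine="python")
    return TitrationSeries(ratio=ratio, peaks=peaks, label=label)


def write_peaklist(series: TitrationSeries, path: str) -> None:
    cols = [c for c in PEAK_COLUMNS if c in series.peaks.columns]
    series.peaks.to_csv(path, sep="\t", index=False, columns=cols)


def write_csp_table(table: pd.DataFrame, path: str) -> None:
    table.to_csv(path, sep="\t", index=False)
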