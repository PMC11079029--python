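"""15N relaxation analysis: R1/R2 exponential fits, hetNOE, correlation time.

R1 and R2 series are mono-exponential decays I(t) = I0 exp(-R t) sampled at
a ladder of relaxation delays, with one delay usually acquired in duplicate
so that the spectral noise can be estimated from repeat differences.  The
apparent rotational correlation time is estimated from the R2/R1 ratio with
the standard closed form

    tau_c = (1 / (4 pi nu_N)) * sqrt(6 R2/R1 - 7)

valid outside the extreme-narrowing regime (6 R2/R1 > 7), where nu_N is the
15N Larmor frequency.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

#: |gamma_15N| / gamma_1H — converts a 1H field in MHz to the 15N frequency
N15_FREQUENCY_RATIO = 0.10136905


@dataclass
class RelaxationSeries:
    residue_id: int
    delays: np.ndarray  # s
    intensities: np.ndarray
    experiment: Literal["R1", "R2"] = "R1"

    def __post_init__(self) -> None:
        self.delays = np.asarray(self.delays, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.delays.shape != self.intensities.shape:
            raise ValueError("delays and intensities must align")
        if np.unique(self.delays).size < 4:
            raise ValueError("need at least 4 distinct delays")
        if np.any(self.delays < 0):
            raise ValueError("negative relaxation delay")

    def duplicate_pairs(self) -> list[tuple[float, float]]:
        """Intensity pairs measured at the same delay."""
        pairs = []
        for d in np.unique(self.delays):
            vals = self.intensities[self.delays == d]
            if len(vals) >= 2:
                pairs.append((float(vals[0]), float(vals[1])))
        return pairs


@dataclass
class RelaxationResult:
    residue_id: int
    rate: float  # s^-1
    rate_err: float
    i0: float


@dataclass
class HetNOEResult:
    residue_id: int
    noe: float
    noe_err: float


def duplicate_noise(series: Iterable[RelaxationSeries]) -> float:
    """Pooled intensity noise from duplicate delays: sigma = |Ia - Ib|/sqrt(2).

    Pooled as the RMS over all duplicate pairs across residues.
    """
    diffs = []
    for s in series:
        for a, b in s.duplicate_pairs():
            diffs.append((a - b) / math.sqrt(2.0))
    if not diffs:
        raise ValueError("no duplicate delays found for noise estimation")
    return float(np.sqrt(np.mean(np.square(diffs))))


def _decay(t: np.ndarray, i0: float, rate: float) -> np.ndarray:
    return i0 * np.exp(-rate * t)


def fit_exponential(
    series: RelaxationSeries, noise_sd: float | None = None
) -> RelaxationResult:
    """Nonlinear least-squares fit of I(t) = I0 exp(-R t).

    ``noise_sd`` (from :func:`duplicate_noise`) scales the rate uncertainty
    through the fit covariance; without it the covariance is scaled by the
    residual variance.  Restarts with perturbed initial values on failure.
    """
    t, y = series.delays, series.intensities
    if np.allclose(y, y[0]):
        raise ValueError("all intensities equal — cannot fit a decay")
    i0_init = float(np.max(np.abs(y)))
    # crude rate guess from the delay where intensity first halves
    below = np.flatnonzero(np.abs(y) <= 0.5 * i0_init)
    r_init = math.log(2.0) / float(t[below[0]]) if below.size and t[below[0]] > 0 else 1.0
    sigma = None if noise_sd is None else np.full_like(y, float(noise_sd))
    last_err: Exception | None = None
    for attempt, scale in enumerate((1.0, 0.3, 3.0)):
        try:
            popt, pcov = curve_fit(
                _decay,
                t,
                y,
                p0=(i0_init, r_init * scale),
                sigma=sigma,
                absolute_sigma=noise_sd is not None,
                maxfev=10000,
            )
            break
        except RuntimeError as err:  # pragma: no cover - pathological series
            last_err = err
    else:  # pragma: no cover
        raise RuntimeError(f"exponential fit failed after restarts: {last_err}")
    i0, rate = popt
    if rate <= 0:
        raise ValueError("fitted rate is non-positive — data do not decay")
    rate_err = float(np.sqrt(max(pcov[1, 1], 0.0)))
    return RelaxationResult(series.residue_id, float(rate), rate_err, float(i0))


def het_noe(
    saturated: float, unsaturated: float, noise_sd: float, residue_id: int = 0
) -> HetNOEResult:
    """Steady-state {1H}-15N NOE: saturated/unsaturated intensity ratio.

    The error propagates the common noise through both intensities:
    err = |noe| * sqrt((sigma/sat)^2 + (sigma/unsat)^2).  Negative ratios
    (flexible tails) are returned as-is.
    """
    if unsaturated == 0:
        raise ValueError("unsaturated reference intensity is zero")
    noe = saturated / unsaturated
    if saturated == 0:
        err = abs(noise_sd / unsaturated)
    else:
        err = abs(noe) * math.sqrt(
            (noise_sd / saturated) ** 2 + (noise_sd / unsaturated) ** 2
        )
    return HetNOEResult(residue_id, noe, err)


def estimate_tauc(
    r1: float, r2: float, field_1h: float, trim: float = 0.0
) -> float:
    """Apparent rotational correlation time in ns from the R2/R1 ratio.

    ``field_1h`` is the 1H spectrometer frequency in MHz.  ``r1``/``r2`` may
    be scalars (single amide) or arrays, in which case their (optionally
    trimmed) means are used, matching the practice of averaging R2/R1 over
    well-ordered residues before applying the closed form.
    """
    r1v = np.atleast_1d(np.asarray(r1, dtype=float))
    r2v = np.atleast_1d(np.asarray(r2, dtype=float))
    if trim > 0:
        from scipy.stats import trim_mean

        r1m, r2m = trim_mean(r1v, trim), trim_mean(r2v, trim)
    else:
        r1m, r2m = float(r1v.mean()), float(r2v.mean())
    ratio = r2m / r1m
    if 6.0 * ratio <= 7.0:
        raise ValueError("R2/R1 <= 7/6 — tau_c formula out of validity range")
    nu_n_hz = N15_FREQUENCY_RATIO * field_1h * 1e6
    tauc_s = math.sqrt(6.0 * ratio - 7.0) / (4.0 * math.pi * nu_n_hz)
    return tauc_s * 1e9


# ---------------------------------------------------------------------------
# Tabular I/O
# ---------------------------------------------------------------------------

def read_series(path: str, experiment: Literal["R1", "R2"] = "R1") -> list[RelaxationSeries]:
    """Read delimited series (columns residue, delay_s, intensity)."""
    df = pd.read_csv(path, sep=None, engine="python")
    out = []
    for resid, grp in df.groupby("residue"):
        out.append(
            RelaxationSeries(
                int(resid),
                grp["delay_s"].to_numpy(float),
                grp["intensity"].to_numpy(float),
                experiment,
            )
        )
    return out


def write_series(series: Sequence[RelaxationSeries], path: str) -> None:
    rows = []
    for s in series:
        for d, i in zip(s.delays, s.intensities):
            rows.append((s.residue_id, d, i))
    pd.DataFrame(rows, columns=["residue", "delay_s", "intensity"]).to_csv(
        path, sep="\t", index=False
    )
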