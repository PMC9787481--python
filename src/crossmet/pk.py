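"""One-compartment IP plasma simulation and non-compartmental analysis.

Model: first-order absorption into a single compartment,

    C(t) = (D * ka) / (V/F * (ka - ke)) * (exp(-ke t) - exp(-ka t))

with dose D per kg, absorption rate ka (1/min), elimination rate ke (1/min)
and apparent volume V/F (mL/kg).  Intraperitoneal dosing is extravascular,
so bioavailability F is inseparable and all volume/clearance estimates are
reported as /F quantities.

NCA: Cmax/Tmax by direct maximum; the terminal slope lambda_z by log-linear
least squares over the best (max adjusted R^2) suffix of >= ``min_terminal``
points strictly after Tmax; AUC by linear-up/log-down trapezoid; AUC_inf =
AUC_last + C_last/lambda_z; t1/2 = ln2/lambda_z; Vz/F = D/(lambda_z AUC_inf);
CL/F = D/AUC_inf.

When the first sample is drawn well after an effectively complete absorption
phase (rapid IP absorption), the pre-first-sample area is recovered by
back-extrapolating the terminal fit to t = 0 (bolus-like behaviour);
``c0_mode="zero"`` instead anchors the curve at C(0) = 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import stats

__all__ = ["ConcProfile", "NcaResult", "simulate_profile", "nca", "PAPER_SCHEDULE_MIN"]

#: The 6-point sampling schedule of the mouse study (minutes).
PAPER_SCHEDULE_MIN = (15.0, 30.0, 60.0, 120.0, 180.0, 240.0)


@dataclass(frozen=True)
class ConcProfile:
    times: Tuple[float, ...]  # minutes, strictly increasing
    concentrations: Tuple[float, ...]  # ug/mL
    dose_mg_per_kg: float
    route: str = "ip"

    def __post_init__(self) -> None:
        if len(self.times) != len(self.concentrations):
            raise ValueError("times and concentrations differ in length")
        t = np.asarray(self.times)
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if any(c < 0 for c in self.concentrations):
            raise ValueError("concentrations must be >= 0")


@dataclass(frozen=True)
class NcaResult:
    cmax: float
    tmax: float
    lambda_z: float
    t_half: float
    auc_last: float
    auc_inf: float
    vz_over_f: float  # mL/kg
    cl_over_f: float  # mL/min/kg
    n_terminal_points: int
    r_squared: float


def simulate_profile(
    ka: float,
    ke: float,
    v_over_f: float,
    dose_mg_per_kg: float,
    times: Sequence[float] = PAPER_SCHEDULE_MIN,
    noise_cv: float = 0.0,
    seed: Optional[int] = None,
) -> ConcProfile:
    """Closed-form one-compartment profile, optional lognormal noise.

    Noise is multiplicative lognormal with the given coefficient of
    variation and unit mean.  ``ka == ke`` is the degenerate flip-flop case;
    use a large ka (bolus limit) instead.
    """
    if ka <= 0 or ke <= 0:
        raise ValueError("rates must be > 0")
    if math.isclose(ka, ke, rel_tol=1e-12):
        raise ValueError(
            "ka == ke is degenerate; use ka >> ke to approximate the bolus limit"
        )
    if noise_cv > 0 and seed is None:
        raise ValueError("a seed is required when noise_cv > 0")
    t = np.asarray(times, dtype=float)
    dose_ug = dose_mg_per_kg * 1000.0
    a = dose_ug * ka / (v_over_f * (ka - ke))
    conc = a * (np.exp(-ke * t) - np.exp(-ka * t))
    conc = np.clip(conc, 0.0, None)
    if noise_cv > 0:
        rng = np.random.default_rng(seed)
        sigma = math.sqrt(math.log1p(noise_cv**2))
        mu = -0.5 * sigma**2  # unit-mean lognormal
        conc = conc * rng.lognormal(mean=mu, sigma=sigma, size=conc.shape)
    return ConcProfile(
        times=tuple(float(x) for x in t),
        concentrations=tuple(float(c) for c in conc),
        dose_mg_per_kg=dose_mg_per_kg,
    )


def _terminal_fit(
    t: np.ndarray, c: np.ndarray, tmax_idx: int, min_terminal: int
) -> Tuple[float, float, int, float]:
    """Best log-linear suffix fit after Tmax -> (lambda_z, intercept, n, r2)."""
    n = len(t)
    start_min = tmax_idx + 1
    best = None
    for start in range(start_min, n - min_terminal + 1):
        tt, cc = t[start:], c[start:]
        if np.any(cc <= 0):
            continue
        k = len(tt)
        if k < min_terminal:
            continue
        fit = stats.linregress(tt, np.log(cc))
        if fit.slope >= 0:
            continue
        r2 = fit.rvalue**2
        adj = 1.0 - (1.0 - r2) * (k - 1) / (k - 2) if k > 2 else r2
        key = (adj, k)  # ties -> more points
        if best is None or key > best[0]:
            best = (key, (-fit.slope, fit.intercept, k, r2))
    if best is None:
        raise ValueError(
            f"no valid terminal window of >= {min_terminal} positive, declining "
            "points after Tmax"
        )
    return best[1]


def nca(
    profile: ConcProfile,
    min_terminal: int = 3,
    c0_mode: str = "extrapolate",
    auc_method: str = "lin-up-log-down",
) -> NcaResult:
    """Non-compartmental parameter estimation from a concentration profile."""
    if c0_mode not in ("extrapolate", "zero"):
        raise ValueError("c0_mode must be 'extrapolate' or 'zero'")
    if auc_method not in ("lin-up-log-down", "linear"):
        raise ValueError("auc_method must be 'lin-up-log-down' or 'linear'")
    t = np.asarray(profile.times, dtype=float)
    c = np.asarray(profile.concentrations, dtype=float)
    if len(t) < min_terminal + 1:
        raise ValueError(f"need at least {min_terminal + 1} observations")
    if not np.any(c > 0):
        raise ValueError("need at least one positive concentration")

    tmax_idx = int(np.argmax(c))
    cmax = float(c[tmax_idx])
    tmax = float(t[tmax_idx])

    lambda_z, intercept, n_term, r2 = _terminal_fit(t, c, tmax_idx, min_terminal)

    # virtual C(0): terminal back-extrapolation if bolus-like, else baseline 0
    if t[0] > 0:
        if c0_mode == "extrapolate":
            c0 = float(np.exp(intercept))
            if c0 <= c[0]:  # visible absorption phase: extrapolation invalid
                c0 = 0.0
        else:
            c0 = 0.0
        t = np.concatenate([[0.0], t])
        c = np.concatenate([[c0], c])

    auc_last = 0.0
    for i in range(len(t) - 1):
        c1, c2 = c[i], c[i + 1]
        dt = t[i + 1] - t[i]
        if auc_method == "lin-up-log-down" and 0 < c2 < c1:
            auc_last += (c1 - c2) / math.log(c1 / c2) * dt
        else:
            auc_last += 0.5 * (c1 + c2) * dt

    positive = np.nonzero(c > 0)[0]
    c_last = float(c[positive[-1]])
    auc_inf = auc_last + c_last / lambda_z

    dose_ug = profile.dose_mg_per_kg * 1000.0
    return NcaResult(
        cmax=cmax,
        tmax=tmax,
        lambda_z=float(lambda_z),
        t_half=float(math.log(2) / lambda_z),
        auc_last=float(auc_last),
        auc_inf=float(auc_inf),
        vz_over_f=float(dose_ug / (lambda_z * auc_inf)),
        cl_over_f=float(dose_ug / auc_inf),
        n_terminal_points=int(n_term),
        r_squared=float(r2),
    )
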