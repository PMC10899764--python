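"""Michaelis-Menten analysis of methyl transfer.

Units are fixed throughout: concentrations in nM, time in minutes, assay
volume in microliters, radioactivity in Bq, methyl groups in pmol.  The
methyl donor (SAM) is assumed saturating and is not modeled.  Oligo
substrates are single-site, single-turnover-per-strand: the product ceiling
is the initial substrate concentration.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import optimize, stats


@dataclass(frozen=True)
class KineticParams:
    """KM (nM), kcat (1/min) and enzyme concentration E (nM)."""

    KM: float
    kcat: float
    E: float

    def __post_init__(self) -> None:
        if min(self.KM, self.kcat, self.E) <= 0:
            raise ValueError("KM, kcat and E must be strictly positive")

    @property
    def efficiency(self) -> float:
        """Catalytic efficiency kcat/KM (1/min/nM)."""
        return self.kcat / self.KM


@dataclass(frozen=True)
class AssayConditions:
    """Initial substrate S0 (nM), sampling times (min), label specific
    activity (Bq/pmol) and aliquot volume (ul)."""

    S0: float
    times: tuple
    specific_activity: float = 130.0
    volume: float = 30.0

    def __post_init__(self) -> None:
        times = tuple(float(t) for t in self.times)
        if any(t < 0 for t in times) or any(b <= a for a, b in zip(times, times[1:])) is True:
            raise ValueError("times must be non-negative and strictly increasing")
        object.__setattr__(self, "times", times)


def mm_rate(S: float, p: KineticParams) -> float:
    """Michaelis-Menten velocity v = kcat*E*S/(KM+S) in nM/min."""
    if S < 0:
        raise ValueError("substrate concentration must be >= 0")
    return p.kcat * p.E * S / (p.KM + S)


def product_to_pmol(product_nM: float, volume_ul: float) -> float:
    """Exact unit conversion: nM in a ul aliquot -> pmol (invertible)."""
    return product_nM * volume_ul * 1e-3


def pmol_to_product(pmol: float, volume_ul: float) -> float:
    return pmol / (volume_ul * 1e-3)


def _product_at(t: float, p: KineticParams, S0: float) -> float:
    """Solve the implicit integrated rate law
    kcat*E*t = P + KM*ln(S0/(S0-P)) for P(t)."""
    if t == 0:
        return 0.0
    vmax_t = p.kcat * p.E * t
    eps = S0 * 1e-12

    def g(P):
        return P + p.KM * np.log(S0 / (S0 - P)) - vmax_t

    hi = S0 - eps
    if g(hi) < 0:          # essentially complete conversion
        return S0
    return float(optimize.brentq(g, 0.0, hi, xtol=S0 * 1e-12, rtol=1e-14))


@dataclass(frozen=True)
class TimePoint:
    time: float
    product_nM: float
    incorporated_Bq: float


def simulate_timecourse(p: KineticParams, cond: AssayConditions,
                        noise_sd: float = 0.0,
                        seed: Optional[int] = None) -> list[TimePoint]:
    """Integrate product formation and account the incorporated label.

    Product is monotone non-decreasing and bounded by S0 (single turnover
    per methylatable strand); optional Gaussian noise applies to the Bq
    readout only.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed) if noise_sd > 0 else None
    out = []
    for t in cond.times:
        P = _product_at(t, p, cond.S0)
        bq = product_to_pmol(P, cond.volume) * cond.specific_activity
        if rng is not None:
            bq += rng.normal(0.0, noise_sd)
        out.append(TimePoint(t, P, bq))
    return out


def initial_rate(series: Sequence[TimePoint]) -> float:
    """Initial velocity (nM/min) from the earliest non-zero time point."""
    for tp in series:
        if tp.time > 0:
            return tp.product_nM / tp.time
    raise ValueError("series contains no positive time point")


@dataclass(frozen=True)
class FitResult:
    KM: float
    kcat: float
    KM_se: float
    kcat_se: float
    converged: bool
    message: str = ""

    def params(self, E: float) -> KineticParams:
        return KineticParams(self.KM, self.kcat, E)


def fit_mm(data: Iterable[tuple[float, float]], E: float) -> FitResult:
    """Nonlinear least squares on v = kcat*E*S/(KM+S).

    ``data`` is (S in nM, v in nM/min) pairs; initial values come from a
    double-reciprocal (Lineweaver-Burk) linear fit.  Non-convergence is
    reported, never silent.
    """
    pts = [(float(S), float(v)) for S, v in data]
    S = np.array([p[0] for p in pts])
    v = np.array([p[1] for p in pts])
    if len(np.unique(S)) < 4:
        raise ValueError("need >= 4 distinct substrate concentrations for identifiability")
    if np.all(v <= 0):
        raise ValueError("degenerate fit: all velocities are zero")

    mask = (S > 0) & (v > 0)
    lb = stats.linregress(1.0 / S[mask], 1.0 / v[mask])
    if lb.intercept > 0:
        vmax0 = 1.0 / lb.intercept
        km0 = max(lb.slope * vmax0, 1e-9)
    else:
        vmax0 = float(v.max())
        km0 = float(np.median(S))
    kcat0 = max(vmax0 / E, 1e-12)

    def model(S, KM, kcat):
        return kcat * E * S / (KM + S)

    try:
        popt, pcov = optimize.curve_fit(model, S, v, p0=[km0, kcat0], maxfev=20000)
    except RuntimeError as exc:
        return FitResult(np.nan, np.nan, np.nan, np.nan, False, str(exc))
    se = np.sqrt(np.diag(pcov))
    return FitResult(float(popt[0]), float(popt[1]), float(se[0]), float(se[1]),
                     True, "converged")


def efficiency_ratio(a: KineticParams, b: KineticParams) -> float:
    """Fold difference of catalytic efficiency, (a.kcat/a.KM)/(b.kcat/b.KM)."""
    return a.efficiency / b.efficiency
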