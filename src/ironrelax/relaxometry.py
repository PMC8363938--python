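"""Decay composition, R2/R2* fitting, and iron-extraction differencing.

Total GE/SE decays are products of the mechanism-specific decays: nanoscale
(exponential, identical for GE and SE), microscale (from the static-dephasing
or Monte Carlo simulators), and a non-iron rate.  Rates are recovered from
magnitude decays by either an ordinary log-linear fit or a nonlinear fit with
a Rician noise floor,

    S(TE) = sqrt((s0 exp(-rate TE))^2 + floor^2),

the quadrature form appropriate for magnitude images at moderate SNR.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .static_dephasing import SignalDecay

__all__ = [
    "RelaxFit",
    "RoiStats",
    "IronInducedRates",
    "compose_signal",
    "fit_relaxation",
    "normalize_at_first_echo",
    "iron_induced_rates",
    "roi_stats",
]


@dataclass(frozen=True)
class RelaxFit:
    """Fitted amplitude, relaxation rate (s^-1) and noise floor."""

    s0: float
    rate: float
    noise_floor: float
    rmse: float
    te_used: tuple
    model: str = "loglinear"
    converged: bool = True
    message: str = ""

    def __post_init__(self) -> None:
        if self.converged and (self.rate < 0 or self.noise_floor < 0):
            raise ValueError("rate and noise_floor must be >= 0")


@dataclass(frozen=True)
class RoiStats:
    """Mean/SD/SEM of a rate map over an ROI (population SD, ddof=0)."""

    mean: float
    sd: float
    sem: float
    n_voxels: int
    roi_name: str = "custom"

    def __post_init__(self) -> None:
        if self.n_voxels < 1:
            raise ValueError("n_voxels must be >= 1")


@dataclass(frozen=True)
class IronInducedRates:
    """Before-minus-after-extraction rates; SDs propagated in quadrature."""

    r2s_iron: float
    r2_iron: float
    reversible: float
    r2s_iron_sd: float = 0.0
    r2_iron_sd: float = 0.0
    reversible_sd: float = 0.0
    roi_name: str = "custom"


def compose_signal(
    nano_rate: float, micro: SignalDecay, other_rate: float, kind: str
) -> SignalDecay:
    """S(TE) = exp(-nano TE) * S_micro(TE) * exp(-other TE)."""
    if micro.kind != kind:
        raise ValueError(f"micro decay is {micro.kind}, requested {kind}")
    if nano_rate < 0 or other_rate < 0:
        raise ValueError("rates must be >= 0")
    env = np.exp(-(nano_rate + other_rate) * micro.te)
    meta = dict(micro.meta)
    meta.update({"nano_rate": nano_rate, "other_rate": other_rate})
    return SignalDecay(te=micro.te, signal=micro.signal * env, kind=kind, meta=meta)


def _loglinear(te: np.ndarray, signal: np.ndarray) -> tuple[float, float]:
    slope, intercept = np.polyfit(te, np.log(signal), 1)
    return float(np.exp(intercept)), float(-slope)


def fit_relaxation(decay: SignalDecay, model: str = "rician_floor") -> RelaxFit:
    """Fit a mono-exponential rate to a magnitude decay.

    ``loglinear`` fits log S by ordinary least squares (noise floor fixed at
    zero); ``rician_floor`` fits the quadrature model by nonlinear least
    squares, seeded from a log-linear fit on the early echoes.  A fit that
    fails to converge is returned flagged, never silently.
    """
    te = decay.te
    signal = decay.magnitude
    if te.size < 4:
        raise ValueError("need at least 4 echoes to fit")
    if np.any(signal <= 0):
        raise ValueError("signals must be positive for fitting")
    if model == "loglinear":
        s0, rate = _loglinear(te, signal)
        resid = signal - s0 * np.exp(-rate * te)
        return RelaxFit(
            s0=s0,
            rate=max(rate, 0.0),
            noise_floor=0.0,
            rmse=float(np.sqrt(np.mean(resid**2))),
            te_used=tuple(te),
            model="loglinear",
        )
    if model != "rician_floor":
        raise ValueError("model must be 'rician_floor' or 'loglinear'")

    def rician(t, s0, rate, floor):
        return np.sqrt((s0 * np.exp(-rate * t)) ** 2 + floor**2)

    n_early = max(4, te.size // 2)
    s0_0, rate_0 = _loglinear(te[:n_early], signal[:n_early])
    floor_0 = max(float(signal.min()) * 0.5, 1e-6 * s0_0)
    try:
        popt, _ = curve_fit(
            rician,
            te,
            signal,
            p0=[s0_0, max(rate_0, 1e-3), floor_0],
            bounds=([0.0, 0.0, 0.0], [np.inf, np.inf, np.inf]),
            maxfev=20_000,
        )
    except (RuntimeError, ValueError) as err:
        return RelaxFit(
            s0=s0_0,
            rate=max(rate_0, 0.0),
            noise_floor=0.0,
            rmse=float("nan"),
            te_used=tuple(te),
            model="rician_floor",
            converged=False,
            message=str(err),
        )
    resid = signal - rician(te, *popt)
    return RelaxFit(
        s0=float(popt[0]),
        rate=float(popt[1]),
        noise_floor=float(popt[2]),
        rmse=float(np.sqrt(np.mean(resid**2))),
        te_used=tuple(te),
        model="rician_floor",
    )


def normalize_at_first_echo(decay: SignalDecay) -> SignalDecay:
    """Divide the decay by its first-echo value (recorded in meta)."""
    first = decay.magnitude[0]
    if first == 0:
        raise ValueError("first-echo signal is zero; cannot normalize")
    meta = dict(decay.meta)
    meta["normalized_at_te_s"] = float(decay.te[0])
    return SignalDecay(te=decay.te, signal=decay.signal / first, kind=decay.kind, meta=meta)


def roi_stats(rate_map: np.ndarray, roi_mask: np.ndarray, roi_name: str = "custom") -> RoiStats:
    """Mean, population SD and SEM of a rate map over a mask."""
    mask = np.asarray(roi_mask, dtype=bool)
    values = np.asarray(rate_map)[mask]
    if values.size == 0:
        raise ValueError("empty ROI mask")
    sd = float(values.std(ddof=0))
    return RoiStats(
        mean=float(values.mean()),
        sd=sd,
        sem=sd / np.sqrt(values.size),
        n_voxels=int(values.size),
        roi_name=roi_name,
    )


def iron_induced_rates(
    r2s_before: RoiStats,
    r2_before: RoiStats,
    r2s_after: RoiStats,
    r2_after: RoiStats,
) -> IronInducedRates:
    """Iron-induced rates as before-minus-after-extraction differences.

    The reversible component is R2*_iron - R2_iron (equivalently the change
    in R2* - R2).  SDs propagate in quadrature and are labeled as propagated
    values, distinct from plain per-ROI SDs.
    """
    names = {s.roi_name for s in (r2s_before, r2_before, r2s_after, r2_after)}
    if len(names) != 1:
        raise ValueError(f"ROI mismatch between inputs: {sorted(names)}")
    r2s_iron = r2s_before.mean - r2s_after.mean
    r2_iron = r2_before.mean - r2_after.mean
    r2s_sd = float(np.hypot(r2s_before.sd, r2s_after.sd))
    r2_sd = float(np.hypot(r2_before.sd, r2_after.sd))
    return IronInducedRates(
        r2s_iron=r2s_iron,
        r2_iron=r2_iron,
        reversible=r2s_iron - r2_iron,
        r2s_iron_sd=r2s_sd,
        r2_iron_sd=r2_sd,
        reversible_sd=float(np.hypot(r2s_sd, r2_sd)),
        roi_name=names.pop(),
    )
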