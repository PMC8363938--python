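"""Random-walk water-diffusion dephasing simulator.

Protons start uniformly at random in the frequency map, take Gaussian steps
with per-axis SD sqrt(2 D dt), and accrue phase 2*pi*df(r(t))*dt along their
path (left-Riemann; df is piecewise constant over a step).  The GE signal is
the magnitude of the ensemble average of exp(-i phi(TE)); the SE signal
negates the phase accrued in the first half of the echo (refocusing pulse at
TE/2).  Positions wrap periodically; the map is assumed to tile space.

GE echoes may fall between step boundaries: the final partial step is
integrated exactly (frac * df at the step start), so standard multi-echo
protocols whose echo spacing is not a multiple of dt run unmodified.  SE
echoes require TE/2 on the step grid, because the refocusing is implemented
as an exact phase sign inversion at a step boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit

from .fieldsim import FrequencyMap
from .static_dephasing import SignalDecay

__all__ = [
    "McConfig",
    "McResult",
    "diffusion_time",
    "simulate_diffusion_decay",
    "convergence_report",
]


def diffusion_time(length_um: float, D_um2_per_ms: float) -> float:
    """Diffusion time tau_D = l^2 / D across a length scale, in seconds.

    Separates the relaxation regimes: distances diffused much faster than the
    echo time are motionally averaged (nanoscale), much slower ones are
    static (microscale).  E.g. 10 um at D = 1 um^2/ms gives 0.1 s.
    """
    if D_um2_per_ms <= 0:
        raise ValueError("D must be positive")
    return (length_um**2 / D_um2_per_ms) * 1e-3


@dataclass(frozen=True)
class McConfig:
    """Monte Carlo settings.

    dt is in ms, D in um^2/ms (post mortem tissue ~0.3, in vivo ~1.0),
    echo times in seconds.  ``init_box`` optionally confines starting
    positions to an axis-aligned box ((lo, hi) per axis, um), e.g. to keep
    walkers away from the boundary of a non-tiling field.
    """

    n_protons: int = 1_000_000
    dt: float = 0.1
    D: float = 0.3
    te: tuple = ()
    seed: int = 0
    interpolation: str = "trilinear"
    boundary: str = "periodic"
    compute_se: bool = True
    init_box: tuple | None = None

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive (ms)")
        if self.D < 0:
            raise ValueError("D must be >= 0 (um^2/ms)")
        if self.n_protons < 1_000:
            raise ValueError("n_protons must be >= 1000")
        if self.interpolation not in ("nearest", "trilinear"):
            raise ValueError("interpolation must be 'nearest' or 'trilinear'")
        if self.boundary != "periodic":
            raise ValueError("only periodic boundary conditions are supported")
        object.__setattr__(self, "te", tuple(float(t) for t in self.te))
        if any(t < 0 for t in self.te) or list(self.te) != sorted(set(self.te)):
            raise ValueError("echo times must be unique, increasing and >= 0")


@dataclass
class McResult:
    """GE (and optionally SE) decays plus run diagnostics."""

    ge: SignalDecay
    se: SignalDecay | None
    run_meta: dict = field(default_factory=dict)


@njit(cache=True, fastmath=True)
def _walk_kernel(
    df,
    sigma_vox,
    dt_s,
    n_protons,
    chk_step,
    chk_frac_s,
    idx_te,
    idx_half,
    use_se,
    trilinear,
    seed,
    lo,
    hi,
):  # pragma: no cover - exercised through simulate_diffusion_decay
    np.random.seed(seed)
    nx, ny, nz = df.shape
    n_chk = chk_step.shape[0]
    n_echo = idx_te.shape[0]
    ge_re = np.zeros(n_echo)
    ge_im = np.zeros(n_echo)
    se_re = np.zeros(n_echo)
    se_im = np.zeros(n_echo)
    phis = np.empty(n_chk)
    k_max = chk_step[n_chk - 1]
    two_pi = 2.0 * np.pi
    sx0 = hi[0] - lo[0]
    sx1 = hi[1] - lo[1]
    sx2 = hi[2] - lo[2]
    fnx = float(nx)
    fny = float(ny)
    fnz = float(nz)
    for _ in range(n_protons):
        x = lo[0] + np.random.random() * sx0
        y = lo[1] + np.random.random() * sx1
        z = lo[2] + np.random.random() * sx2
        phi = 0.0
        c = 0
        for k in range(k_max + 1):
            if trilinear:
                i0 = int(np.floor(x))
                j0 = int(np.floor(y))
                l0 = int(np.floor(z))
                wx = x - i0
                wy = y - j0
                wz = z - l0
                i1 = i0 + 1
                if i1 == nx:
                    i1 = 0
                j1 = j0 + 1
                if j1 == ny:
                    j1 = 0
                l1 = l0 + 1
                if l1 == nz:
                    l1 = 0
                f = (
                    (1.0 - wx)
                    * (
                        (1.0 - wy) * ((1.0 - wz) * df[i0, j0, l0] + wz * df[i0, j0, l1])
                        + wy * ((1.0 - wz) * df[i0, j1, l0] + wz * df[i0, j1, l1])
                    )
                    + wx
                    * (
                        (1.0 - wy) * ((1.0 - wz) * df[i1, j0, l0] + wz * df[i1, j0, l1])
                        + wy * ((1.0 - wz) * df[i1, j1, l0] + wz * df[i1, j1, l1])
                    )
                )
            else:
                i = int(x + 0.5)
                if i >= nx:
                    i -= nx
                j = int(y + 0.5)
                if j >= ny:
                    j -= ny
                l = int(z + 0.5)
                if l >= nz:
                    l -= nz
                f = df[i, j, l]
            while c < n_chk and chk_step[c] == k:
                phis[c] = phi + two_pi * f * chk_frac_s[c]
                c += 1
            phi += two_pi * f * dt_s
            if sigma_vox > 0.0:
                x += sigma_vox * np.random.normal()
                y += sigma_vox * np.random.normal()
                z += sigma_vox * np.random.normal()
                if x < 0.0 or x >= fnx:
                    x = x % fnx
                if y < 0.0 or y >= fny:
                    y = y % fny
                if z < 0.0 or z >= fnz:
                    z = z % fnz
        for e in range(n_echo):
            pte = phis[idx_te[e]]
            ge_re[e] += np.cos(pte)
            ge_im[e] -= np.sin(pte)
            if use_se:
                ps = pte - 2.0 * phis[idx_half[e]]
                se_re[e] += np.cos(ps)
                se_im[e] -= np.sin(ps)
    return ge_re, ge_im, se_re, se_im


def _checkpoints(te: np.ndarray, dt_s: float, compute_se: bool):
    """Map echo (and half-echo) times onto (step index, fractional remainder)."""
    times = list(te)
    if compute_se:
        bad = [t for t in te if abs(round(t / (2 * dt_s)) * 2 * dt_s - t) > 1e-9]
        if bad:
            raise ValueError(
                "SE refocusing needs TE as an even multiple of dt; offending TE (s): "
                f"{bad}"
            )
        times += [0.5 * t for t in te]
    steps = []
    fracs = []
    for t in times:
        m = int(np.floor(t / dt_s + 1e-9))
        frac = t - m * dt_s
        if frac < 1e-12:
            frac = 0.0
        steps.append(m)
        fracs.append(frac)
    steps = np.asarray(steps, dtype=np.int64)
    fracs = np.asarray(fracs, dtype=np.float64)
    order = np.lexsort((fracs, steps))
    rank = np.empty_like(order)
    rank[order] = np.arange(order.size)
    n_echo = te.size
    idx_te = rank[:n_echo].astype(np.int64)
    idx_half = (
        rank[n_echo:].astype(np.int64) if compute_se else np.zeros(n_echo, dtype=np.int64)
    )
    return steps[order], fracs[order], idx_te, idx_half


def simulate_diffusion_decay(f_map: FrequencyMap, cfg: McConfig) -> McResult:
    """Run the random-walk dephasing simulation on a frequency map."""
    df = np.ascontiguousarray(f_map.df, dtype=np.float64)
    if not np.all(np.isfinite(df)):
        raise ValueError("frequency map contains non-finite values")
    te = np.asarray(cfg.te, dtype=np.float64)
    if te.size == 0:
        raise ValueError("no echo times given")
    dt_s = cfg.dt * 1e-3
    chk_step, chk_frac, idx_te, idx_half = _checkpoints(te, dt_s, cfg.compute_se)
    sigma_vox = np.sqrt(2.0 * cfg.D * cfg.dt) / f_map.voxel_size
    shape = df.shape
    if cfg.init_box is None:
        lo = np.zeros(3)
        hi = np.asarray(shape, dtype=np.float64)
    else:
        lo = np.asarray([b[0] for b in cfg.init_box], dtype=np.float64) / f_map.voxel_size
        hi = np.asarray([b[1] for b in cfg.init_box], dtype=np.float64) / f_map.voxel_size
        if np.any(lo < 0) or np.any(hi > np.asarray(shape)) or np.any(hi <= lo):
            raise ValueError("init_box must be a nonempty box inside the grid (um)")
    ge_re, ge_im, se_re, se_im = _walk_kernel(
        df,
        float(sigma_vox),
        float(dt_s),
        int(cfg.n_protons),
        chk_step,
        chk_frac,
        idx_te,
        idx_half,
        bool(cfg.compute_se),
        cfg.interpolation == "trilinear",
        int(cfg.seed),
        lo,
        hi,
    )
    n = float(cfg.n_protons)
    ge_sig = np.hypot(ge_re, ge_im) / n
    meta = {
        "simulator": "mc",
        "seed": cfg.seed,
        "n_protons": cfg.n_protons,
        "dt_ms": cfg.dt,
        "D_um2_per_ms": cfg.D,
        "interpolation": cfg.interpolation,
    }
    ge = SignalDecay(te=te, signal=ge_sig, kind="GE", meta=dict(meta))
    se = None
    if cfg.compute_se:
        se_sig = np.hypot(se_re, se_im) / n
        se = SignalDecay(te=te, signal=se_sig, kind="SE", meta=dict(meta))
    return McResult(ge=ge, se=se, run_meta=meta)


def convergence_report(
    f_map: FrequencyMap, cfg: McConfig, n_runs: int = 3, upscale: int = 10
) -> dict:
    """Across-seed variability and upscaled-run agreement of the GE signal.

    Runs ``n_runs`` simulations at cfg.n_protons with consecutive seeds and
    one at ``upscale * n_protons``; reports the per-echo SD/mean across seeds
    and each run's maximal relative deviation from the upscaled run.
    """
    if n_runs < 2:
        raise ValueError("need at least 2 runs")
    signals = []
    for i in range(n_runs):
        res = simulate_diffusion_decay(f_map, replace(cfg, seed=cfg.seed + i, compute_se=False))
        signals.append(res.ge.magnitude)
    signals = np.asarray(signals)
    mean = signals.mean(axis=0)
    sd = signals.std(axis=0, ddof=1)
    sd_over_mean = sd / mean
    big_cfg = replace(
        cfg,
        n_protons=int(cfg.n_protons * upscale),
        seed=cfg.seed + n_runs,
        compute_se=False,
    )
    big = simulate_diffusion_decay(f_map, big_cfg).ge.magnitude
    rel_diff = np.abs(signals - big[None, :]) / big[None, :]
    return {
        "te_s": np.asarray(cfg.te).tolist(),
        "sd_over_mean": sd_over_mean.tolist(),
        "max_sd_over_mean": float(sd_over_mean.max()),
        "rel_diff_vs_upscaled": rel_diff.max(axis=1).tolist(),
        "max_rel_diff_vs_upscaled": float(rel_diff.max()),
        "n_protons": cfg.n_protons,
        "n_runs": n_runs,
        "upscale": upscale,
    }
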