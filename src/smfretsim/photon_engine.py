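"""Time-inhomogeneous photon sampling and burst assembly.

Each excitation event is a competing-risk race between homogeneous donor
decay (rate ``k_D``) and energy transfer with the time-dependent hazard
``k_ET(t) = k_D C kappa2(t) / r(t)^6`` evaluated along the simulated dye
and dipole paths. Transfer times are drawn by inverting the cumulative
trapezoid hazard (an independent Ogata-thinning sampler is provided for
cross-validation). Interphoton statistics are emergent: nothing here
assumes a homogeneous Poisson photon-arrival process.

Within a burst the translational state persists from one excitation to
the next; dipoles are re-initialized uniformly at each excitation and
evolve as spherical Brownian motion during the event (dynamic mode) or
are replaced by the isotropic average kappa^2 = 2/3 (static mode).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from numba import njit

from .dipole_dynamics import RotationalSpec
from .fret_core import PhysicalParams, RatePath
from .linker_models import PendulumSpec, SpringModelSpec, _pend_step

__all__ = [
    "ExcitationEvent",
    "BurstConfig",
    "ExperimentModel",
    "BurstSummary",
    "sample_transfer_time",
    "sample_transfer_times",
    "sample_transfer_times_thinning",
    "simulate_excitation",
    "simulate_excitations",
    "simulate_burst",
    "run_experiment",
    "BURST_COLUMNS",
    "PHOTON_COLUMNS",
]

BURST_COLUMNS = [
    "burst_id",
    "I_D",
    "I_A",
    "E_I",
    "tau_norm",
    "mean_kappa2",
    "n_excitations",
    "n_censored",
    "excluded",
]
PHOTON_COLUMNS = ["burst_id", "channel", "delay_ns", "detected"]


# ---------------------------------------------------------------------------
# transfer-time samplers on explicit rate paths
# ---------------------------------------------------------------------------


def sample_transfer_times(path: RatePath, n: int, seed=None) -> np.ndarray:
    """Draw ``n`` transfer times by integrated-hazard inversion.

    Returns ``np.inf`` for draws censored beyond the path horizon. The
    inversion solves ``Lambda(t*) = u`` with ``u ~ Exp(1)`` by monotone
    linear interpolation of the cumulative trapezoid integral.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    u = rng.exponential(size=n)
    t, lam = path.t_grid, path.Lambda
    out = np.full(n, np.inf)
    alive = u <= lam[-1]
    if np.any(alive):
        ua = u[alive]
        idx = np.clip(np.searchsorted(lam, ua, side="left") - 1, 0, len(t) - 2)
        dlam = lam[idx + 1] - lam[idx]
        frac = np.where(dlam > 0, (ua - lam[idx]) / np.where(dlam > 0, dlam, 1.0), 1.0)
        out[alive] = t[idx] + frac * (t[idx + 1] - t[idx])
    return out


def sample_transfer_time(path: RatePath, seed=None) -> float:
    """Single transfer time (``np.inf`` if censored)."""
    return float(sample_transfer_times(path, 1, seed)[0])


def sample_transfer_times_thinning(path: RatePath, n: int, seed=None) -> np.ndarray:
    """Independent Ogata-thinning sampler with bound ``max(k_ET)``.

    Used to cross-validate the hazard-inversion sampler; kept free of any
    shared machinery beyond linear interpolation of the hazard itself.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    t_grid, k = path.t_grid, path.k_ET
    kmax = float(np.max(k))
    t_max = float(t_grid[-1])
    out = np.full(n, np.inf)
    if kmax <= 0:
        return out
    t = np.zeros(n)
    undecided = np.ones(n, dtype=bool)
    while np.any(undecided):
        idx = np.flatnonzero(undecided)
        t[idx] += rng.exponential(scale=1.0 / kmax, size=len(idx))
        past = t[idx] > t_max
        undecided[idx[past]] = False  # censored, stays inf
        live = idx[~past]
        if len(live):
            accept = rng.random(len(live)) * kmax < np.interp(t[live], t_grid, k)
            acc = live[accept]
            out[acc] = t[acc]
            undecided[acc] = False
    return out


# ---------------------------------------------------------------------------
# single excitation events on explicit paths
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ExcitationEvent:
    """Outcome of one excitation cycle."""

    outcome: Literal["donor_photon", "acceptor_photon", "censored"]
    delay: float | None
    transfer_time: float | None


def simulate_excitations(
    t_grid,
    kappa2,
    r,
    params: PhysicalParams,
    n: int,
    seed=None,
    kappa2_mode: str = "dynamic",
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized competing-risk sampling of ``n`` events on one shared path.

    Returns ``(outcomes, delays)`` with outcome codes 0=donor, 1=acceptor,
    2=censored (delay ``nan`` when censored).
    """
    if kappa2_mode not in ("static", "dynamic"):
        raise ValueError("kappa2_mode must be 'static' or 'dynamic'")
    k2 = np.full_like(np.asarray(t_grid, float), 2.0 / 3.0) if kappa2_mode == "static" else kappa2
    path = RatePath.from_kappa_r(t_grid, k2, r, params)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    t_et = sample_transfer_times(path, n, rng)
    t_don = rng.exponential(scale=params.tau_D0, size=n)
    horizon = float(path.t_grid[-1])
    outcomes = np.full(n, 2, dtype=np.int64)
    delays = np.full(n, np.nan)
    donor_first = (t_don <= horizon) & (t_don < t_et)
    transfer_first = (t_et <= horizon) & ~donor_first
    outcomes[donor_first] = 0
    delays[donor_first] = t_don[donor_first]
    outcomes[transfer_first] = 1
    delays[transfer_first] = t_et[transfer_first] + rng.exponential(
        scale=1.0 / params.k_A, size=int(transfer_first.sum())
    )
    return outcomes, delays


def simulate_excitation(
    t_grid, kappa2, r, params: PhysicalParams, seed=None, kappa2_mode: str = "dynamic"
) -> ExcitationEvent:
    """One excitation event on explicit kappa^2(t) and r(t) paths."""
    if kappa2_mode not in ("static", "dynamic"):
        raise ValueError("kappa2_mode must be 'static' or 'dynamic'")
    t = np.asarray(t_grid, float)
    k2 = np.full_like(t, 2.0 / 3.0) if kappa2_mode == "static" else kappa2
    path = RatePath.from_kappa_r(t, k2, r, params)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    t_et = float(sample_transfer_times(path, 1, rng)[0])
    t_don = float(rng.exponential(scale=params.tau_D0))
    horizon = float(t[-1])
    if t_don <= horizon and t_don < t_et:
        return ExcitationEvent("donor_photon", t_don, None)
    if t_et <= horizon:
        delay = t_et + float(rng.exponential(scale=1.0 / params.k_A))
        return ExcitationEvent("acceptor_photon", delay, t_et)
    return ExcitationEvent("censored", None, None)


# ---------------------------------------------------------------------------
# burst configuration and experiment model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BurstConfig:
    """Per-burst excitation and detection settings.

    ``dt_factor`` sets the fine-grid step as ``tau_D0 / dt_factor``;
    ``horizon_factor`` sets the censoring horizon as a multiple of
    ``tau_D0``. Detection is independent Bernoulli thinning per photon.

    Excitation cycles repeat at the laser repetition period
    ``rep_period`` (ns): between the end of one event and the next
    excitation the translational state keeps evolving (exactly for OU
    springs, with a ``dead_dt_stride`` x coarser step for the pendulum),
    so within-burst mixing is set by physical time, not photon order.
    """

    n_excitations: int = 400
    eff_donor: float = 0.4
    eff_acceptor: float = 0.35
    min_photons: int = 10
    dt_factor: float = 200.0
    horizon_factor: float = 10.0
    rep_period: float = 25.0
    dead_dt_stride: int = 10

    def __post_init__(self) -> None:
        if self.n_excitations < 1:
            raise ValueError("n_excitations must be >= 1")
        for name in ("eff_donor", "eff_acceptor"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.min_photons < 0:
            raise ValueError("min_photons must be >= 0")
        if self.dt_factor <= 0 or self.horizon_factor <= 0:
            raise ValueError("dt_factor and horizon_factor must be > 0")
        if self.rep_period < 0:
            raise ValueError("rep_period must be >= 0")
        if self.dead_dt_stride < 1:
            raise ValueError("dead_dt_stride must be >= 1")

    def dt(self, params: PhysicalParams) -> float:
        return params.tau_D0 / self.dt_factor

    def max_steps(self, params: PhysicalParams) -> int:
        return int(round(self.horizon_factor * self.dt_factor))


_MODEL_KINDS = ("iso_spring", "aniso_spring", "pendulum")


@dataclass(frozen=True)
class ExperimentModel:
    """Translational + rotational model of the tethered dye pair.

    Spring models place each dye in an OU well centered on its attachment
    point; the pendulum model tethers each dye at its anchor with the
    polar axis pointing away from the other dye (``z_sign``).
    """

    kind: str
    attach_D: np.ndarray = field(default_factory=lambda: np.zeros(3))
    attach_A: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 5.0]))
    spring_D: SpringModelSpec | None = None
    spring_A: SpringModelSpec | None = None
    pend_D: PendulumSpec | None = None
    pend_A: PendulumSpec | None = None
    z_sign_D: float = -1.0
    z_sign_A: float = 1.0
    rot_D: RotationalSpec = field(default_factory=lambda: RotationalSpec(0.2))
    rot_A: RotationalSpec = field(default_factory=lambda: RotationalSpec(0.2))
    burn_in_time: float = 20.0  # ns, pendulum stationary-state burn-in

    def __post_init__(self) -> None:
        if self.kind not in _MODEL_KINDS:
            raise ValueError(f"kind must be one of {_MODEL_KINDS}, got {self.kind!r}")
        if self.kind in ("iso_spring", "aniso_spring"):
            if self.spring_D is None or self.spring_A is None:
                raise ValueError("spring models require spring_D and spring_A")
        else:
            if self.pend_D is None or self.pend_A is None:
                raise ValueError("pendulum model requires pend_D and pend_A")
        object.__setattr__(self, "attach_D", np.asarray(self.attach_D, float))
        object.__setattr__(self, "attach_A", np.asarray(self.attach_A, float))


@dataclass(frozen=True)
class BurstSummary:
    """Detected-photon summary of one burst."""

    burst_id: int
    I_D: int
    I_A: int
    E_I: float
    tau_norm: float
    mean_kappa2: float
    n_excitations: int
    n_censored: int
    excluded: bool


# ---------------------------------------------------------------------------
# numba kernel
# ---------------------------------------------------------------------------


@njit(cache=True)
def _uniform_unit():  # pragma: no cover
    while True:
        x = np.random.normal()
        y = np.random.normal()
        z = np.random.normal()
        n2 = x * x + y * y + z * z
        if n2 > 1e-12:
            inv = 1.0 / math.sqrt(n2)
            return x * inv, y * inv, z * inv


@njit(cache=True)
def _kappa2_scalar(mDx, mDy, mDz, mAx, mAy, mAz, dx, dy, dz, r2):  # pragma: no cover
    inv = 1.0 / math.sqrt(r2)
    rx = dx * inv
    ry = dy * inv
    rz = dz * inv
    dd = mDx * mAx + mDy * mAy + mDz * mAz
    d1 = rx * mDx + ry * mDy + rz * mDz
    d2 = rx * mAx + ry * mAy + rz * mAz
    kap = dd - 3.0 * d1 * d2
    return kap * kap


@njit(cache=True)
def _burst_kernel(
    model,
    dynamic,
    n_bursts,
    n_exc,
    dt,
    max_steps,
    k_D,
    k_A,
    CC,
    kappa_static,
    aD,
    bD,
    cD,
    sd0D,
    eqD,
    KD,
    aA,
    bA,
    cA,
    sd0A,
    eqA,
    KA,
    pdD,
    pdA,
    anchD,
    anchA,
    zsD,
    zsA,
    burn_steps,
    rep_period,
    dead_dt,
    D_rot_D,
    D_rot_A,
    eff_D,
    eff_A,
    seeds,
    record,
    ph_channel,
    ph_delay,
    ph_detected,
    ph_offsets,
    out_ID,
    out_IA,
    out_sumdel,
    out_ncens,
    out_k2mean,
):  # pragma: no cover
    amp_D = math.sqrt(2.0 * D_rot_D * dt)
    amp_A = math.sqrt(2.0 * D_rot_A * dt)
    for b in range(n_bursts):
        np.random.seed(seeds[b])
        # --- initial translational state ---
        xD = np.empty(3)
        xA = np.empty(3)
        rD = 0.0
        thD = 0.0
        phD = 0.0
        rA = 0.0
        thA = 0.0
        phA = 0.0
        if model == 0:
            for j in range(3):
                xD[j] = eqD[j] + sd0D[j] * np.random.normal()
                xA[j] = eqA[j] + sd0A[j] * np.random.normal()
        else:
            rD = pdD[1]
            thD = math.pi / 2.0
            phD = 2.0 * math.pi * np.random.random()
            rA = pdA[1]
            thA = math.pi / 2.0
            phA = 2.0 * math.pi * np.random.random()
            for _ in range(burn_steps):
                rD, thD, phD = _pend_step(
                    rD, thD, phD, pdD[0], pdD[1], pdD[2], pdD[3], pdD[4], pdD[5], dead_dt
                )
                rA, thA, phA = _pend_step(
                    rA, thA, phA, pdA[0], pdA[1], pdA[2], pdA[3], pdA[4], pdA[5], dead_dt
                )
        I_D = 0
        I_A = 0
        sumdel = 0.0
        ncens = 0
        k2sum_burst = 0.0
        nph = ph_offsets[b]
        for _e in range(n_exc):
            # fresh dipoles from the equilibrium (uniform) law
            mDx, mDy, mDz = _uniform_unit()
            mAx, mAy, mAz = _uniform_unit()
            u = -math.log(np.random.random())
            tdon = -math.log(np.random.random()) / k_D
            # hazard at event start
            if model == 0:
                dx = xA[0] - xD[0]
                dy = xA[1] - xD[1]
                dz = xA[2] - xD[2]
            else:
                sD = math.sin(thD)
                sA = math.sin(thA)
                pDx = anchD[0] + rD * sD * math.cos(phD)
                pDy = anchD[1] + rD * sD * math.sin(phD)
                pDz = anchD[2] + zsD * rD * math.cos(thD)
                pAx = anchA[0] + rA * sA * math.cos(phA)
                pAy = anchA[1] + rA * sA * math.sin(phA)
                pAz = anchA[2] + zsA * rA * math.cos(thA)
                dx = pAx - pDx
                dy = pAy - pDy
                dz = pAz - pDz
            r2 = dx * dx + dy * dy + dz * dz
            if dynamic == 1:
                k2 = _kappa2_scalar(mDx, mDy, mDz, mAx, mAy, mAz, dx, dy, dz, r2)
            else:
                k2 = kappa_static
            kprev = CC * k2 / (r2 * r2 * r2)
            k2sum = k2
            k2n = 1
            t = 0.0
            Lam = 0.0
            outcome = 2  # censored unless decided
            delay = 0.0
            tstop = max_steps * dt
            for _i in range(max_steps):
                # advance translational state
                if model == 0:
                    for j in range(3):
                        xD[j] = aD[j] * xD[j] + bD[j] + cD[j] * np.random.normal()
                        xA[j] = aA[j] * xA[j] + bA[j] + cA[j] * np.random.normal()
                    dx = xA[0] - xD[0]
                    dy = xA[1] - xD[1]
                    dz = xA[2] - xD[2]
                else:
                    rD, thD, phD = _pend_step(
                        rD, thD, phD, pdD[0], pdD[1], pdD[2], pdD[3], pdD[4], pdD[5], dt
                    )
                    rA, thA, phA = _pend_step(
                        rA, thA, phA, pdA[0], pdA[1], pdA[2], pdA[3], pdA[4], pdA[5], dt
                    )
                    sD = math.sin(thD)
                    sA = math.sin(thA)
                    pDx = anchD[0] + rD * sD * math.cos(phD)
                    pDy = anchD[1] + rD * sD * math.sin(phD)
                    pDz = anchD[2] + zsD * rD * math.cos(thD)
                    pAx = anchA[0] + rA * sA * math.cos(phA)
                    pAy = anchA[1] + rA * sA * math.sin(phA)
                    pAz = anchA[2] + zsA * rA * math.cos(thA)
                    dx = pAx - pDx
                    dy = pAy - pDy
                    dz = pAz - pDz
                if dynamic == 1:
                    # advance dipoles (tangent-plane increment + renormalize)
                    if amp_D > 0.0:
                        zx = np.random.normal()
                        zy = np.random.normal()
                        zz = np.random.normal()
                        d = zx * mDx + zy * mDy + zz * mDz
                        mDx += amp_D * (zx - d * mDx)
                        mDy += amp_D * (zy - d * mDy)
                        mDz += amp_D * (zz - d * mDz)
                        inv = 1.0 / math.sqrt(mDx * mDx + mDy * mDy + mDz * mDz)
                        mDx *= inv
                        mDy *= inv
                        mDz *= inv
                    if amp_A > 0.0:
                        zx = np.random.normal()
                        zy = np.random.normal()
                        zz = np.random.normal()
                        d = zx * mAx + zy * mAy + zz * mAz
                        mAx += amp_A * (zx - d * mAx)
                        mAy += amp_A * (zy - d * mAy)
                        mAz += amp_A * (zz - d * mAz)
                        inv = 1.0 / math.sqrt(mAx * mAx + mAy * mAy + mAz * mAz)
                        mAx *= inv
                        mAy *= inv
                        mAz *= inv
                r2 = dx * dx + dy * dy + dz * dz
                if dynamic == 1:
                    k2 = _kappa2_scalar(mDx, mDy, mDz, mAx, mAy, mAz, dx, dy, dz, r2)
                else:
                    k2 = kappa_static
                knew = CC * k2 / (r2 * r2 * r2)
                k2sum += k2
                k2n += 1
                tnext = t + dt
                Lamnext = Lam + 0.5 * dt * (kprev + knew)
                tstar = 1e300
                if Lamnext >= u and Lamnext > Lam:
                    tstar = t + dt * (u - Lam) / (Lamnext - Lam)
                if tdon <= tnext and tdon < tstar:
                    outcome = 0
                    delay = tdon
                    tstop = tdon
                    break
                if tstar <= tnext:
                    outcome = 1
                    delay = tstar - math.log(np.random.random()) / k_A
                    tstop = tstar
                    break
                t = tnext
                Lam = Lamnext
                kprev = knew
            if outcome == 2:
                ncens += 1
            else:
                if outcome == 0:
                    det = np.random.random() < eff_D
                    if det:
                        I_D += 1
                        sumdel += delay
                else:
                    det = np.random.random() < eff_A
                    if det:
                        I_A += 1
                if record == 1:
                    ph_channel[nph] = outcome
                    ph_delay[nph] = delay
                    ph_detected[nph] = 1 if det else 0
                    nph += 1
            k2sum_burst += k2sum / k2n
            # propagate translational state through the interpulse dead time
            dead = rep_period - tstop
            if dead > 0.0:
                if model == 0:
                    for j in range(3):
                        e = math.exp(-KD[j] * dead)
                        xD[j] = (
                            eqD[j]
                            + (xD[j] - eqD[j]) * e
                            + sd0D[j] * math.sqrt(1.0 - e * e) * np.random.normal()
                        )
                        e = math.exp(-KA[j] * dead)
                        xA[j] = (
                            eqA[j]
                            + (xA[j] - eqA[j]) * e
                            + sd0A[j] * math.sqrt(1.0 - e * e) * np.random.normal()
                        )
                else:
                    nstep = int(dead / dead_dt) + 1
                    hh = dead / nstep
                    for _ in range(nstep):
                        rD, thD, phD = _pend_step(
                            rD, thD, phD, pdD[0], pdD[1], pdD[2], pdD[3], pdD[4], pdD[5], hh
                        )
                        rA, thA, phA = _pend_step(
                            rA, thA, phA, pdA[0], pdA[1], pdA[2], pdA[3], pdA[4], pdA[5], hh
                        )
        out_ID[b] = I_D
        out_IA[b] = I_A
        out_sumdel[b] = sumdel
        out_ncens[b] = ncens
        out_k2mean[b] = k2sum_burst / n_exc
        ph_offsets[b + 1] = nph if record == 1 else 0


# ---------------------------------------------------------------------------
# python driver
# ---------------------------------------------------------------------------


def _spring_arrays(spec: SpringModelSpec, anchor: np.ndarray, dt: float):
    eq = anchor + spec.X_eq
    h = spec.K * dt
    a = 1.0 - h + 0.5 * h * h
    b = (1.0 - a) * eq
    c = spec.sigma * math.sqrt(dt) * (1.0 - 0.5 * h)
    sd0 = spec.stationary_std if spec.sigma > 0 else np.zeros(3)
    return a, b, np.asarray(c, float), np.asarray(sd0, float), eq


def _pend_array(spec: PendulumSpec) -> np.ndarray:
    return np.array(
        [spec.k_r, spec.r_eq, spec.sigma_r, spec.k_theta, spec.sigma_theta, spec.sigma_phi]
    )


def _burst_seeds(master_seed, n_bursts: int) -> np.ndarray:
    ss = np.random.SeedSequence(master_seed)
    return ss.generate_state(n_bursts, dtype=np.uint32).astype(np.int64)


def run_experiment(
    model: ExperimentModel,
    kappa2_mode: str,
    n_bursts: int,
    params: PhysicalParams,
    burst_cfg: BurstConfig | None = None,
    seed=0,
    collect_photons: bool = False,
) -> pd.DataFrame | tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate ``n_bursts`` bursts and return the burst table.

    The table has columns ``BURST_COLUMNS``; with ``collect_photons`` a
    photon-level table (``PHOTON_COLUMNS``) is returned as well. Fully
    deterministic given ``seed``: per-burst substreams are derived from a
    single master seed so any burst is reproducible in isolation.
    """
    if kappa2_mode not in ("static", "dynamic"):
        raise ValueError("kappa2_mode must be 'static' or 'dynamic'")
    if n_bursts < 1:
        raise ValueError("n_bursts must be >= 1")
    burst_cfg = burst_cfg or BurstConfig()
    dt = burst_cfg.dt(params)
    max_steps = burst_cfg.max_steps(params)
    n_exc = burst_cfg.n_excitations

    zero3 = np.zeros(3)
    if model.kind in ("iso_spring", "aniso_spring"):
        mcode = 0
        aD, bD, cD, sd0D, eqD = _spring_arrays(model.spring_D, model.attach_D, dt)
        aA, bA, cA, sd0A, eqA = _spring_arrays(model.spring_A, model.attach_A, dt)
        KD = np.asarray(model.spring_D.K, float)
        KA = np.asarray(model.spring_A.K, float)
        if dt * max(float(np.max(KD)), float(np.max(KA))) >= 0.1:
            raise ValueError("dt*max(K) >= 0.1: spring step too coarse for this grid")
        pdD = pdA = np.zeros(6)
        burn_steps = 0
    else:
        mcode = 1
        aD = bD = cD = sd0D = eqD = zero3
        aA = bA = cA = sd0A = eqA = zero3
        KD = KA = zero3
        pdD = _pend_array(model.pend_D)
        pdA = _pend_array(model.pend_A)
        burn_steps = int(round(model.burn_in_time / (dt * burst_cfg.dead_dt_stride)))

    dyn = 1 if kappa2_mode == "dynamic" else 0
    if dyn and dt * max(model.rot_D.D_rot, model.rot_A.D_rot) >= 0.1:
        raise ValueError("dt*D_rot >= 0.1: rotational step too coarse for this grid")

    seeds = _burst_seeds(seed, n_bursts)
    out_ID = np.zeros(n_bursts, dtype=np.int64)
    out_IA = np.zeros(n_bursts, dtype=np.int64)
    out_sumdel = np.zeros(n_bursts)
    out_ncens = np.zeros(n_bursts, dtype=np.int64)
    out_k2mean = np.zeros(n_bursts)

    record = 1 if collect_photons else 0
    cap = n_bursts * n_exc if collect_photons else 1
    ph_channel = np.zeros(cap, dtype=np.int8)
    ph_delay = np.zeros(cap)
    ph_detected = np.zeros(cap, dtype=np.int8)
    ph_offsets = np.zeros(n_bursts + 1, dtype=np.int64)

    _burst_kernel(
        mcode,
        dyn,
        n_bursts,
        n_exc,
        dt,
        max_steps,
        params.k_D,
        params.k_A,
        params.k_D * params.C,
        2.0 / 3.0,
        aD,
        bD,
        cD,
        sd0D,
        eqD,
        KD,
        aA,
        bA,
        cA,
        sd0A,
        eqA,
        KA,
        pdD,
        pdA,
        model.attach_D,
        model.attach_A,
        model.z_sign_D,
        model.z_sign_A,
        burn_steps,
        burst_cfg.rep_period,
        dt * burst_cfg.dead_dt_stride,
        model.rot_D.D_rot if dyn else 0.0,
        model.rot_A.D_rot if dyn else 0.0,
        burst_cfg.eff_donor,
        burst_cfg.eff_acceptor,
        seeds,
        record,
        ph_channel,
        ph_delay,
        ph_detected,
        ph_offsets,
        out_ID,
        out_IA,
        out_sumdel,
        out_ncens,
        out_k2mean,
    )

    total = out_ID + out_IA
    with np.errstate(invalid="ignore", divide="ignore"):
        E_I = np.where(total > 0, out_IA / np.where(total > 0, total, 1), np.nan)
        tau_norm = np.where(
            out_ID > 0, (out_sumdel / np.where(out_ID > 0, out_ID, 1)) / params.tau_D0, np.nan
        )
    excluded = (total < burst_cfg.min_photons) | (out_ID == 0)
    table = pd.DataFrame(
        {
            "burst_id": np.arange(n_bursts, dtype=np.int64),
            "I_D": out_ID,
            "I_A": out_IA,
            "E_I": E_I,
            "tau_norm": tau_norm,
            "mean_kappa2": out_k2mean,
            "n_excitations": np.full(n_bursts, n_exc, dtype=np.int64),
            "n_censored": out_ncens,
            "excluded": excluded,
        }
    )
    if not collect_photons:
        return table
    nph = int(ph_offsets[-1])
    burst_ids = np.repeat(np.arange(n_bursts), np.diff(ph_offsets))
    photons = pd.DataFrame(
        {
            "burst_id": burst_ids,
            "channel": np.where(ph_channel[:nph] == 0, "donor", "acceptor"),
            "delay_ns": ph_delay[:nph],
            "detected": ph_detected[:nph].astype(bool),
        }
    )
    return table, photons


def simulate_burst(
    model: ExperimentModel,
    params: PhysicalParams,
    burst_cfg: BurstConfig | None = None,
    seed=0,
    kappa2_mode: str = "dynamic",
) -> tuple[BurstSummary, pd.DataFrame]:
    """Simulate a single burst, returning its summary and photon records."""
    table, photons = run_experiment(
        model, kappa2_mode, 1, params, burst_cfg, seed=seed, collect_photons=True
    )
    row = table.iloc[0]
    summary = BurstSummary(
        burst_id=int(row.burst_id),
        I_D=int(row.I_D),
        I_A=int(row.I_A),
        E_I=float(row.E_I),
        tau_norm=float(row.tau_norm),
        mean_kappa2=float(row.mean_kappa2),
        n_excitations=int(row.n_excitations),
        n_censored=int(row.n_censored),
        excluded=bool(row.excluded),
    )
    return summary, photons
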