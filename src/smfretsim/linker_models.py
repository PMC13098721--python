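"""Translational dye-linker dynamics.

Two tethered-dye models:

* diagonal (isotropic or anisotropic) Ornstein-Uhlenbeck springs, with
  spring constants optionally derived from carbon-chain linker chemistry
  treated as springs in series;
* a stochastic elastic pendulum in spherical coordinates (radial spring,
  polar pendulum drift, azimuthal free diffusion).

All SDEs use the Stratonovich-consistent Euler-Heun scheme. For the OU
spring the noise is additive, so Ito and Stratonovich coincide.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy.signal import lfilter

__all__ = [
    "LinkerChemistry",
    "linker_from_chemistry",
    "SpringModelSpec",
    "PendulumSpec",
    "DyeTrajectory",
    "simulate_spring",
    "simulate_pendulum",
    "interdye_distance",
    "write_trajectory",
    "spherical_to_cartesian",
]


@dataclass(frozen=True)
class LinkerChemistry:
    """Effective spring constant and per-link length of a carbon-chain linker.

    A chain of ``N_links`` identical C-C springs in series has effective
    constant ``k_bond / N_links``. The effective per-link length follows
    from the law of cosines across a C-C-C angle:
    ``L_link = sqrt(2 l^2 - 2 l^2 cos(theta)) / 2``.
    """

    k_bond: float
    N_links: int
    l_bond: float  # nm
    theta_bond_deg: float
    k_eff: float = field(init=False)
    L_link: float = field(init=False)

    def __post_init__(self) -> None:
        if self.N_links < 1:
            raise ValueError(f"N_links must be >= 1, got {self.N_links}")
        if self.k_bond <= 0 or self.l_bond <= 0:
            raise ValueError("k_bond and l_bond must be > 0")
        theta = math.radians(self.theta_bond_deg)
        object.__setattr__(self, "k_eff", self.k_bond / self.N_links)
        object.__setattr__(
            self,
            "L_link",
            math.sqrt(2 * self.l_bond**2 - 2 * self.l_bond**2 * math.cos(theta)) / 2,
        )

    @property
    def contour_length(self) -> float:
        """Total effective linker length, N_links * L_link (nm)."""
        return self.N_links * self.L_link


def linker_from_chemistry(
    N_links: int,
    k_bond: float,
    l_bond: float = 0.154,
    theta_bond_deg: float = 109.5,
) -> LinkerChemistry:
    """Series-spring reduction of an ``N_links``-bond carbon chain.

    Defaults for bond length/angle mirror the packaged preset file
    (``presets.yaml`` key ``linker_defaults``).
    """
    return LinkerChemistry(
        k_bond=k_bond, N_links=N_links, l_bond=l_bond, theta_bond_deg=theta_bond_deg
    )


@dataclass(frozen=True)
class SpringModelSpec:
    """Diagonal OU spring in rate units (spring constant / friction).

    ``K`` is the (3,) diagonal of the spring matrix (1/ns); ``sigma`` is
    the standard noise amplitude so that the stationary per-axis variance
    is ``sigma**2 / (2 K)``. Use :meth:`from_paper_sigma` for the
    alternative convention where the printed variance formula is
    ``sigma_paper / k`` (i.e. ``sigma = sqrt(2 * sigma_paper)``).
    """

    K: np.ndarray
    X_eq: np.ndarray
    sigma: float
    anisotropy_p: float = 1.0

    def __post_init__(self) -> None:
        K = np.atleast_1d(np.asarray(self.K, dtype=float))
        if K.size == 1:
            K = np.full(3, K.item())
        if K.shape != (3,) or np.any(K <= 0):
            raise ValueError("K must be 3 positive diagonal entries")
        X_eq = np.asarray(self.X_eq, dtype=float)
        if X_eq.shape != (3,):
            raise ValueError("X_eq must be a 3-vector")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if not (0.0 <= self.anisotropy_p <= 1.0):
            raise ValueError("anisotropy_p must lie in [0, 1]")
        object.__setattr__(self, "K", K)
        object.__setattr__(self, "X_eq", X_eq)

    @classmethod
    def isotropic(cls, k: float, sigma: float, X_eq=(0.0, 0.0, 0.0)) -> "SpringModelSpec":
        return cls(K=np.full(3, float(k)), X_eq=np.asarray(X_eq, float), sigma=sigma)

    @classmethod
    def anisotropic(
        cls, k: float, p: float, sigma: float, X_eq=(0.0, 0.0, 0.0), stiff_axis: int = 2
    ) -> "SpringModelSpec":
        """Two soft entries ``p*k`` and one stiff entry ``k`` (on ``stiff_axis``)."""
        K = np.full(3, p * float(k))
        K[stiff_axis] = float(k)
        return cls(K=K, X_eq=np.asarray(X_eq, float), sigma=sigma, anisotropy_p=p)

    @classmethod
    def from_paper_sigma(
        cls, k, sigma_paper: float, X_eq=(0.0, 0.0, 0.0), anisotropy_p: float = 1.0
    ) -> "SpringModelSpec":
        """Convention where the stationary per-axis variance is sigma_paper/k."""
        return cls(
            K=np.asarray(k, float),
            X_eq=np.asarray(X_eq, float),
            sigma=math.sqrt(2.0 * sigma_paper),
            anisotropy_p=anisotropy_p,
        )

    @property
    def is_isotropic(self) -> bool:
        return bool(np.all(self.K == self.K[0]))

    @property
    def stationary_std(self) -> np.ndarray:
        """Per-axis stationary standard deviation sigma / sqrt(2 K)."""
        return self.sigma / np.sqrt(2.0 * self.K)


@dataclass(frozen=True)
class PendulumSpec:
    """Stochastic elastic pendulum in spherical coordinates.

    Radial OU spring toward ``r_eq`` with Bessel-type correction drift
    ``sigma_r**2 / r``; polar drift ``-k_theta * sin(theta)`` plus the
    curvature drift ``sigma_theta**2 * cos(theta) / (2 r^2 sin(theta))``
    (so ``k_theta = 0`` reduces to free diffusion on the sphere of radius
    r); azimuthal noise scaled by ``1 / (r sin(theta))``.
    """

    k_r: float
    r_eq: float
    sigma_r: float
    k_theta: float = 0.0
    sigma_theta: float = 0.0
    sigma_phi: float = 0.0

    def __post_init__(self) -> None:
        if self.k_r <= 0 or self.r_eq <= 0:
            raise ValueError("k_r and r_eq must be > 0")
        if min(self.sigma_r, self.sigma_theta, self.sigma_phi) < 0:
            raise ValueError("noise amplitudes must be >= 0")
        if self.k_theta < 0:
            raise ValueError("k_theta must be >= 0")


@dataclass(frozen=True)
class DyeTrajectory:
    """Joint donor/acceptor position path on a shared time grid."""

    t_grid: np.ndarray
    pos_D: np.ndarray
    pos_A: np.ndarray
    attach_D: np.ndarray
    attach_A: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.t_grid, dtype=float)
        if np.any(np.diff(t) <= 0):
            raise ValueError("t_grid must be strictly increasing")
        for name in ("pos_D", "pos_A"):
            p = np.asarray(getattr(self, name), dtype=float)
            if p.shape != (len(t), 3):
                raise ValueError(f"{name} must have shape (len(t_grid), 3)")
            if not np.all(np.isfinite(p)):
                raise ValueError(f"{name} contains non-finite values")
            object.__setattr__(self, name, p)
        object.__setattr__(self, "t_grid", t)


def _heun_coeffs(k: np.ndarray, dt: float, sigma: float):
    """AR(1) coefficients of the Euler-Heun step for linear drift -k(x-xeq)."""
    h = k * dt
    a = 1.0 - h + 0.5 * h * h
    c = sigma * math.sqrt(dt) * (1.0 - 0.5 * h)
    return a, c


def simulate_spring(
    spec: SpringModelSpec,
    t_grid,
    seed=None,
    x0=None,
    allow_unstable: bool = False,
) -> np.ndarray:
    """Sample one OU path on ``t_grid`` with the Euler-Heun scheme.

    Requires a uniform grid. The stationary per-axis variance is
    ``sigma**2 / (2 K)``; paths are exactly reproducible given ``seed``.
    """
    t = np.asarray(t_grid, dtype=float)
    dts = np.diff(t)
    if len(t) < 2 or np.any(dts <= 0):
        raise ValueError("t_grid must be strictly increasing with >= 2 points")
    if not np.allclose(dts, dts[0], rtol=1e-8):
        raise ValueError("simulate_spring requires a uniform time grid")
    dt = float(dts[0])
    if dt * float(np.max(spec.K)) >= 0.1:
        msg = f"dt*max(K) = {dt * float(np.max(spec.K)):.3g} >= 0.1: step too coarse"
        if not allow_unstable:
            raise ValueError(msg + " (pass allow_unstable=True to override)")
        warnings.warn(msg, stacklevel=2)

    rng = np.random.default_rng(seed)
    n = len(t)
    if x0 is None:
        x0 = spec.X_eq + spec.stationary_std * rng.standard_normal(3)
    x0 = np.asarray(x0, dtype=float)

    a, c = _heun_coeffs(spec.K, dt, spec.sigma)
    out = np.empty((n, 3))
    out[0] = x0
    noise = rng.standard_normal((n - 1, 3))
    for ax in range(3):
        # x_{i+1} = a x_i + (1-a) xeq + c xi_i  -> linear recursion via lfilter
        drive = (1.0 - a[ax]) * spec.X_eq[ax] + c[ax] * noise[:, ax]
        zi = np.array([a[ax] * x0[ax]])
        out[1:, ax], _ = lfilter([1.0], [1.0, -a[ax]], drive, zi=zi)
    return out


# ---------------------------------------------------------------------------
# elastic pendulum (numba kernels shared with the photon engine)
# ---------------------------------------------------------------------------

_SIN_EPS = 1e-6
_R_MIN = 1e-2


@njit(cache=True)
def _pend_substep(rr, tt, pp, kr, req, sr, kth, sth, sph, h):  # pragma: no cover
    """One Euler-Heun substep; returns (r, theta, phi, ok)."""
    s = math.sin(tt)
    if rr <= _R_MIN or abs(s) < _SIN_EPS:
        return rr, tt, pp, False
    z1 = np.random.normal()
    z2 = np.random.normal()
    z3 = np.random.normal()
    sh = math.sqrt(h)
    c = math.cos(tt)
    fr = -kr * (rr - req) + sr * sr / rr
    fth = -kth * s + sth * sth * c / (2.0 * rr * rr * s)
    gth = sth / rr
    gph = sph / (rr * s)
    # predictor
    r1 = rr + fr * h + sr * sh * z1
    t1 = tt + fth * h + gth * sh * z2
    s1 = math.sin(t1)
    if r1 <= _R_MIN or abs(s1) < _SIN_EPS:
        return rr, tt, pp, False
    c1 = math.cos(t1)
    fr1 = -kr * (r1 - req) + sr * sr / r1
    fth1 = -kth * s1 + sth * sth * c1 / (2.0 * r1 * r1 * s1)
    gth1 = sth / r1
    gph1 = sph / (r1 * s1)
    # corrector (averaged drift and diffusion, same Brownian increments)
    r2 = rr + 0.5 * h * (fr + fr1) + sr * sh * z1
    t2 = tt + 0.5 * h * (fth + fth1) + 0.5 * sh * z2 * (gth + gth1)
    p2 = pp + 0.5 * sh * z3 * (gph + gph1)
    if r2 <= _R_MIN:
        return rr, tt, pp, False
    return r2, t2, p2, True


@njit(cache=True)
def _pend_step(r0, t0, p0, kr, req, sr, kth, sth, sph, dt):  # pragma: no cover
    """One full step with pole/origin rejection and step halving."""
    if abs(math.sin(t0)) < _SIN_EPS:
        # nudge off the pole; phi is arbitrary there
        t0 = 1e-3 if t0 < math.pi / 2 else math.pi - 1e-3
    nsub = 1
    while nsub <= 256:
        rr, tt, pp = r0, t0, p0
        h = dt / nsub
        ok = True
        for _ in range(nsub):
            rr, tt, pp, okk = _pend_substep(rr, tt, pp, kr, req, sr, kth, sth, sph, h)
            if not okk:
                ok = False
                break
            # reflect theta into (0, pi)
            if tt < 0.0:
                tt = -tt
                pp += math.pi
            elif tt > math.pi:
                tt = 2.0 * math.pi - tt
                pp += math.pi
        if ok:
            return rr, tt, pp
        nsub *= 2
    # retry limit: clamp away from the singular set
    rr = max(r0, 2.0 * _R_MIN)
    tt = min(max(t0, 1e-3), math.pi - 1e-3)
    return rr, tt, pp


@njit(cache=True)
def _pendulum_path(
    n, dt, r0, t0, p0, kr, req, sr, kth, sth, sph, seed
):  # pragma: no cover
    np.random.seed(seed)
    out = np.empty((n, 3))
    rr, tt, pp = r0, t0, p0
    out[0, 0] = rr
    out[0, 1] = tt
    out[0, 2] = pp
    for i in range(1, n):
        rr, tt, pp = _pend_step(rr, tt, pp, kr, req, sr, kth, sth, sph, dt)
        out[i, 0] = rr
        out[i, 1] = tt
        out[i, 2] = pp
    return out


def spherical_to_cartesian(rtp: np.ndarray, z_sign: float = 1.0) -> np.ndarray:
    """(r, theta, phi) -> Cartesian; ``z_sign`` flips the polar axis."""
    r, th, ph = rtp[..., 0], rtp[..., 1], rtp[..., 2]
    st = np.sin(th)
    return np.stack(
        [r * st * np.cos(ph), r * st * np.sin(ph), z_sign * r * np.cos(th)], axis=-1
    )


def simulate_pendulum(
    spec: PendulumSpec,
    t_grid,
    seed=None,
    state0=None,
    return_spherical: bool = False,
) -> np.ndarray:
    """Integrate the elastic-pendulum Langevin system on a uniform grid.

    Steps that would cross the origin or a pole are rejected and halved
    (up to 256 subdivisions). Returns the Cartesian path relative to the
    attachment point, or the raw (r, theta, phi) states.
    """
    t = np.asarray(t_grid, dtype=float)
    dts = np.diff(t)
    if len(t) < 2 or np.any(dts <= 0):
        raise ValueError("t_grid must be strictly increasing with >= 2 points")
    if not np.allclose(dts, dts[0], rtol=1e-8):
        raise ValueError("simulate_pendulum requires a uniform time grid")
    dt = float(dts[0])
    if state0 is None:
        state0 = (spec.r_eq, math.pi / 2, 0.0)
    r0, th0, ph0 = map(float, state0)
    if r0 <= 0:
        raise ValueError("initial radius must be > 0")
    if not (0.0 <= th0 <= math.pi):
        raise ValueError("initial theta must lie in [0, pi]")
    seed32 = int(np.random.SeedSequence(seed).generate_state(1)[0])
    rtp = _pendulum_path(
        len(t),
        dt,
        r0,
        th0,
        ph0,
        spec.k_r,
        spec.r_eq,
        spec.sigma_r,
        spec.k_theta,
        spec.sigma_theta,
        spec.sigma_phi,
        seed32,
    )
    if return_spherical:
        return rtp
    return spherical_to_cartesian(rtp)


def interdye_distance(traj: DyeTrajectory) -> np.ndarray:
    """Elementwise Euclidean norm of pos_A - pos_D (nm)."""
    if traj.pos_D.shape != traj.pos_A.shape:
        raise ValueError("donor and acceptor paths must share the grid")
    return np.linalg.norm(traj.pos_A - traj.pos_D, axis=1)


def write_trajectory(traj: DyeTrajectory, path, header_lines=()) -> None:
    """Write a trajectory as tab-separated text: time, xD..zD, xA..zA."""
    cols = np.column_stack([traj.t_grid, traj.pos_D, traj.pos_A])
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("time_ns\txD\tyD\tzD\txA\tyA\tzA\n")
        np.savetxt(fh, cols, delimiter="\t", fmt="%.9g")
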