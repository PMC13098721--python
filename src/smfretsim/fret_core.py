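"""Closed-form FRET mathematics.

Orientation factor, transfer rates, static and path-dependent transfer
efficiencies, intensity/lifetime estimators, and the Jensen-inequality
relation between mixture lifetimes.

Unit conventions: time in ns, length in nm, rates in 1/ns. Conversions
happen at the configuration layer, never here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "UNIT_TOL",
    "PhysicalParams",
    "DipoleFrame",
    "RatePath",
    "kappa_squared",
    "kappa_squared_vec",
    "forster_rate",
    "efficiency_static",
    "efficiency_path",
    "efficiency_intensity",
    "efficiency_lifetime",
    "jensen_lifetimes",
    "EmptyBurstError",
]

#: tolerance for unit-vector validation
UNIT_TOL = 1e-9


class EmptyBurstError(ValueError):
    """Raised when an efficiency estimator receives zero photons."""


@dataclass(frozen=True)
class PhysicalParams:
    """Photophysical parameters of the donor/acceptor pair.

    Parameters
    ----------
    k_D : float
        Donor radiative decay rate (1/ns).
    k_A : float
        Acceptor radiative decay rate (1/ns).
    R0_iso : float
        Foerster radius under the isotropic kappa^2 = 2/3 convention (nm).

    The orientational coupling constant ``C`` is fixed to ``(3/2) R0_iso**6``
    so that the instantaneous sixth-power radius ``R0(t)**6 = C * kappa2(t)``
    recovers ``R0_iso`` when ``kappa2 = 2/3``.
    """

    k_D: float = 0.25
    k_A: float = 1.0
    R0_iso: float = 5.0

    def __post_init__(self) -> None:
        if self.k_D <= 0:
            raise ValueError(f"k_D must be > 0, got {self.k_D}")
        if self.k_A <= 0:
            raise ValueError(f"k_A must be > 0, got {self.k_A}")
        if self.R0_iso <= 0:
            raise ValueError(f"R0_iso must be > 0, got {self.R0_iso}")

    @property
    def C(self) -> float:
        """Orientational coupling constant (nm^6): C = 1.5 * R0_iso**6."""
        return 1.5 * self.R0_iso**6

    @property
    def tau_D0(self) -> float:
        """Donor-only lifetime (ns), 1/k_D."""
        return 1.0 / self.k_D


def _as_unit(v, name: str) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    if v.shape != (3,):
        raise ValueError(f"{name} must be a 3-vector, got shape {v.shape}")
    n = float(np.linalg.norm(v))
    if abs(n - 1.0) > 1e-6:
        raise ValueError(f"{name} must be a unit vector (norm={n!r})")
    return v


@dataclass(frozen=True)
class DipoleFrame:
    """Instantaneous geometry of the dipole pair.

    ``mu_D`` and ``mu_A`` are the donor/acceptor transition-dipole unit
    vectors; ``r_vec`` is the interdye displacement (nm).
    """

    mu_D: np.ndarray
    mu_A: np.ndarray
    r_vec: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "mu_D", _as_unit(self.mu_D, "mu_D"))
        object.__setattr__(self, "mu_A", _as_unit(self.mu_A, "mu_A"))
        r_vec = np.asarray(self.r_vec, dtype=float)
        if r_vec.shape != (3,):
            raise ValueError("r_vec must be a 3-vector")
        if float(np.linalg.norm(r_vec)) <= 0:
            raise ValueError("r_vec must have positive magnitude")
        object.__setattr__(self, "r_vec", r_vec)

    @property
    def r(self) -> float:
        return float(np.linalg.norm(self.r_vec))

    @property
    def r_hat(self) -> np.ndarray:
        return self.r_vec / self.r


def kappa_squared_vec(mu_D, mu_A, r_hat) -> np.ndarray:
    """Orientation factor kappa^2 for stacked unit vectors of shape (..., 3).

    No validation; used in hot paths. kappa = mu_D.mu_A - 3 (r.mu_D)(r.mu_A).
    """
    mu_D = np.asarray(mu_D, dtype=float)
    mu_A = np.asarray(mu_A, dtype=float)
    r_hat = np.asarray(r_hat, dtype=float)
    dd = np.sum(mu_D * mu_A, axis=-1)
    d1 = np.sum(r_hat * mu_D, axis=-1)
    d2 = np.sum(r_hat * mu_A, axis=-1)
    kappa = dd - 3.0 * d1 * d2
    return kappa * kappa


def kappa_squared(frame: DipoleFrame) -> float:
    """Orientation factor kappa^2 in [0, 4] for a validated frame."""
    k2 = float(kappa_squared_vec(frame.mu_D, frame.mu_A, frame.r_hat))
    # |kappa| <= 2 analytically; clip fp dust only
    return min(k2, 4.0)


def forster_rate(r: float, kappa2, params: PhysicalParams):
    """Energy-transfer rate k_ET = k_D * C * kappa^2 / r^6 (1/ns).

    With ``kappa2 = 2/3`` and ``r = R0_iso`` this returns exactly ``k_D``.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("r must be > 0")
    kappa2 = np.asarray(kappa2, dtype=float)
    if np.any(kappa2 < 0) or np.any(kappa2 > 4):
        raise ValueError("kappa2 must lie in [0, 4]")
    out = params.k_D * params.C * kappa2 / r**6
    return out if out.ndim else float(out)


def efficiency_static(r, params: PhysicalParams):
    """Static (time-homogeneous) efficiency 1 / ((r/R0)^6 + 1).

    Uses the isotropic kappa^2 = 2/3 convention; r = 0 maps to 1.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("r must be >= 0")
    out = 1.0 / ((r / params.R0_iso) ** 6 + 1.0)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class RatePath:
    """Transfer-hazard path for one excitation event.

    ``t_grid`` starts at 0 and is strictly increasing; ``Lambda`` is the
    cumulative trapezoid integral of ``k_ET`` (dimensionless).
    """

    t_grid: np.ndarray
    kappa2: np.ndarray
    k_ET: np.ndarray
    Lambda: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        t = np.asarray(self.t_grid, dtype=float)
        k2 = np.asarray(self.kappa2, dtype=float)
        k = np.asarray(self.k_ET, dtype=float)
        if t.ndim != 1 or len(t) < 2:
            raise ValueError("t_grid must be 1-D with at least two points")
        if t[0] != 0.0 or np.any(np.diff(t) <= 0):
            raise ValueError("t_grid must start at 0 and be strictly increasing")
        if k2.shape != t.shape or k.shape != t.shape:
            raise ValueError("kappa2 and k_ET must match t_grid in shape")
        if np.any(k2 < 0) or np.any(k2 > 4):
            raise ValueError("kappa2 values must lie in [0, 4]")
        if np.any(k < 0):
            raise ValueError("k_ET must be nonnegative")
        lam = np.concatenate(
            ([0.0], np.cumsum(0.5 * np.diff(t) * (k[1:] + k[:-1])))
        )
        object.__setattr__(self, "t_grid", t)
        object.__setattr__(self, "kappa2", k2)
        object.__setattr__(self, "k_ET", k)
        object.__setattr__(self, "Lambda", lam)

    @classmethod
    def from_kappa_r(cls, t_grid, kappa2, r, params: PhysicalParams) -> "RatePath":
        """Build a path from kappa^2(t) and interdye distance r(t)."""
        r = np.asarray(r, dtype=float)
        if np.any(r <= 0):
            raise ValueError("r path must be strictly positive")
        k = params.k_D * params.C * np.asarray(kappa2, dtype=float) / r**6
        return cls(t_grid=t_grid, kappa2=kappa2, k_ET=k)

    @classmethod
    def constant(cls, k_ET: float, t_max: float, n: int = 2) -> "RatePath":
        """Constant-hazard path on [0, t_max] (homogeneous limit)."""
        t = np.linspace(0.0, t_max, max(n, 2))
        kappa2 = np.full_like(t, 2.0 / 3.0)
        return cls(t_grid=t, kappa2=kappa2, k_ET=np.full_like(t, float(k_ET)))

    def cumulative_hazard(self, T) -> np.ndarray:
        """Lambda(T) with linear interpolation of k_ET off-grid."""
        T = np.asarray(T, dtype=float)
        t, k, lam = self.t_grid, self.k_ET, self.Lambda
        if np.any(T < 0) or np.any(T > t[-1]):
            raise ValueError("T outside the stored time grid")
        idx = np.clip(np.searchsorted(t, T, side="right") - 1, 0, len(t) - 2)
        k_T = np.interp(T, t, k)
        out = lam[idx] + 0.5 * (T - t[idx]) * (k[idx] + k_T)
        return out if out.ndim else float(out)


def efficiency_path(path: RatePath, T: float, params: PhysicalParams) -> float:
    """Path-dependent efficiency Lambda(T) / (Lambda(T) + k_D * T)."""
    if T <= 0 or T > path.t_grid[-1]:
        raise ValueError(f"T must lie in (0, {path.t_grid[-1]}], got {T}")
    lam = float(path.cumulative_hazard(T))
    return lam / (lam + params.k_D * T)


def efficiency_intensity(I_A: int, I_D: int) -> float:
    """Intensity estimator I_A / (I_A + I_D)."""
    if I_A < 0 or I_D < 0:
        raise ValueError("photon counts must be nonnegative")
    total = I_A + I_D
    if total < 1:
        raise EmptyBurstError("burst has zero photons; caller must filter")
    return I_A / total


def efficiency_lifetime(tau_DA: float, tau_D0: float) -> float:
    """Lifetime estimator 1 - tau_DA / tau_D0.

    Not clipped: noisy estimates may legitimately fall outside [0, 1].
    """
    if tau_D0 <= 0:
        raise ValueError("tau_D0 must be > 0")
    if tau_DA < 0:
        raise ValueError("tau_DA must be >= 0")
    return 1.0 - tau_DA / tau_D0


def jensen_lifetimes(rates, weights) -> tuple[float, float]:
    """Mixture lifetimes (tau_bar, tau_under).

    tau_bar = sum_i w_i / k_i is the average lifetime of the mixture;
    tau_under = 1 / sum_i w_i k_i is the lifetime of the average rate.
    By Jensen's inequality (1/x convex on (0, inf)), tau_under <= tau_bar.
    """
    rates = np.asarray(rates, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if rates.shape != weights.shape:
        raise ValueError("rates and weights must have the same shape")
    if np.any(rates <= 0):
        raise ValueError("rates must be > 0")
    if np.any(weights < 0) or not np.isclose(weights.sum(), 1.0, atol=1e-9):
        raise ValueError("weights must be nonnegative and sum to 1")
    tau_bar = float(np.sum(weights / rates))
    tau_under = float(1.0 / np.sum(weights * rates))
    return tau_bar, tau_under
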