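"""Transversal-force tilt model: Boltzmann reweighting of a tilt density.

A transversal force f pulling on a membrane-anchored receptor-ligand complex
of extension h adds the energy term -f*h*sin(tau) to the effective tilt
energy E0(tau) = -kB*T*ln(P0(tau)) obtained from the force-free tilt density
P0.  The tilted distribution follows by Boltzmann reweighting,

    Pf(tau) ~ P0(tau) * exp(f*h*sin(tau) / (kB*T)),

renormalized on [0, pi/2]; tilt beyond 90 degrees is geometrically excluded.
The mode shift of Pf with f quantifies the force-induced tilt, and
h*cos(tau) gives the membrane-surface separation spanned by the complex.

The 1D model assumes the complex rotates to align its tilt direction with
the force, so no azimuthal degree of freedom appears.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .constants import DEFAULT_EC_EXTENSION, DEFAULT_TEMPERATURE, KB

DEFAULT_GRID_STEP_DEG = 0.05


class ForceModelError(ValueError):
    pass


def _tau_grid(step_deg: float) -> np.ndarray:
    """Uniform radian grid on [0, pi/2] with the given step in degrees."""
    n = int(round(90.0 / step_deg)) + 1
    return np.deg2rad(np.linspace(0.0, 90.0, n))


def _normalize(tau: np.ndarray, p: np.ndarray) -> np.ndarray:
    z = np.trapezoid(p, tau)
    if z <= 0 or not np.isfinite(z):
        raise ForceModelError("density does not normalize")
    return p / z


@dataclass(frozen=True)
class ForceTiltModel:
    """Force-free tilt density on a radian grid plus (h, T)."""

    tau: np.ndarray  # radians, uniform on [0, pi/2]
    p0: np.ndarray  # normalized density (per radian)
    h: float = DEFAULT_EC_EXTENSION  # nm
    T: float = DEFAULT_TEMPERATURE  # K

    def __post_init__(self):
        if self.h <= 0 or self.T <= 0:
            raise ForceModelError("h and T must be positive")
        if (self.p0 < 0).any():
            raise ForceModelError("P0 must be non-negative")
        if abs(np.trapezoid(self.p0, self.tau) - 1.0) > 1e-9:
            raise ForceModelError("P0 must integrate to 1 on the grid")

    @property
    def kBT(self) -> float:
        return KB * self.T

    def energy(self, f: float = 0.0) -> np.ndarray:
        """Effective tilt energy Ef(tau) = -kBT ln P0 - f h sin(tau), pN*nm.

        Zero-density grid points get +inf energy.
        """
        with np.errstate(divide="ignore"):
            e0 = -self.kBT * np.log(self.p0)
        return e0 - f * self.h * np.sin(self.tau)


def empirical_p0(
    tilt_samples_deg: np.ndarray,
    grid_step_deg: float = DEFAULT_GRID_STEP_DEG,
    h: float = DEFAULT_EC_EXTENSION,
    T: float = DEFAULT_TEMPERATURE,
) -> ForceTiltModel:
    """KDE-based force-free tilt density from simulation tilt samples."""
    x = np.asarray(tilt_samples_deg, float)
    if x.size < 100:
        raise ForceModelError("need at least 100 tilt samples for a density")
    if (x < 0).any() or (x > 90).any():
        raise ForceModelError("tilt samples outside [0, 90] degrees")
    tau = _tau_grid(grid_step_deg)
    kde = stats.gaussian_kde(np.deg2rad(x), bw_method="silverman")
    p = _normalize(tau, np.clip(kde(tau), 0.0, None))
    return ForceTiltModel(tau=tau, p0=p, h=h, T=T)


def gaussian_surrogate(
    mean_deg: float,
    sd_deg: float,
    grid_step_deg: float = DEFAULT_GRID_STEP_DEG,
    h: float = DEFAULT_EC_EXTENSION,
    T: float = DEFAULT_TEMPERATURE,
) -> ForceTiltModel:
    """Truncated-Gaussian tilt density on [0, 90] degrees.

    A desk-scale stand-in for the empirical simulation density, built from
    its printed moments.
    """
    if sd_deg <= 0:
        raise ForceModelError("sd must be positive")
    tau = _tau_grid(grid_step_deg)
    mu, sigma = np.deg2rad(mean_deg), np.deg2rad(sd_deg)
    p = np.exp(-0.5 * ((tau - mu) / sigma) ** 2)
    return ForceTiltModel(tau=tau, p0=_normalize(tau, p), h=h, T=T)


def reweight(model: ForceTiltModel, f: float) -> np.ndarray:
    """Tilt density under transversal force f (pN), normalized on the grid.

    Computed in log space with the maximum exponent subtracted to guard
    against overflow at large f*h/kBT.
    """
    if f < 0:
        raise ForceModelError("force must be non-negative")
    with np.errstate(divide="ignore"):
        log_p = np.log(model.p0) + f * model.h * np.sin(model.tau) / model.kBT
    log_p -= log_p[np.isfinite(log_p)].max()
    return _normalize(model.tau, np.exp(log_p))


def mode_of(tau: np.ndarray, density: np.ndarray) -> float:
    """Mode of a gridded density in degrees, with quadratic refinement.

    The grid argmax is refined by fitting a parabola through the peak and
    its neighbours.  A flat density (or ties) triggers a warning and the
    smallest-tau maximum is reported.
    """
    density = np.asarray(density, float)
    if np.ptp(density) < 1e-300:
        warnings.warn("flat density: mode undefined, reporting smallest grid point")
        return float(np.degrees(tau[0]))
    i = int(np.argmax(density))  # ties resolve to the smallest tau
    if np.count_nonzero(density == density[i]) > 1:
        warnings.warn("multi-modal tie: reporting the smallest-tau maximum")
    if 0 < i < len(tau) - 1:
        y0, y1, y2 = density[i - 1], density[i], density[i + 1]
        denom = y0 - 2 * y1 + y2
        if denom != 0.0:
            delta = 0.5 * (y0 - y2) / denom
            step = tau[i + 1] - tau[i]
            return float(np.degrees(tau[i] + np.clip(delta, -1, 1) * step))
    return float(np.degrees(tau[i]))


def membrane_separation(h: float, tilt_deg: float) -> float:
    """Membrane-surface separation h*cos(tilt) spanned by the complex (nm)."""
    if h <= 0:
        raise ForceModelError("h must be positive")
    if not 0.0 <= tilt_deg <= 90.0:
        raise ForceModelError("tilt must lie in [0, 90] degrees")
    return h * float(np.cos(np.deg2rad(tilt_deg)))


def separation_change(h: float, tilt1_deg: float, tilt2_deg: float) -> float:
    """Decrease in membrane separation when tilt changes tilt1 -> tilt2 (nm)."""
    return membrane_separation(h, tilt1_deg) - membrane_separation(h, tilt2_deg)


def force_response_table(
    model: ForceTiltModel, forces: list[float]
) -> "pd.DataFrame":
    """Summary of mode and separation change across a list of forces."""
    import pandas as pd

    mode0 = mode_of(model.tau, model.p0)
    rows = []
    for f in forces:
        pf = reweight(model, f)
        mode_f = mode_of(model.tau, pf)
        rows.append(
            {
                "force_pN": f,
                "mode0_deg": mode0,
                "mode_f_deg": mode_f,
                "separation_change_nm": separation_change(model.h, mode0, mode_f),
            }
        )
    return pd.DataFrame(rows)
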