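"""Model fits for stalled-polymerase removal kinetics.

Two laws are fitted to per-condition mean lifetimes:

* a Bell/Boltzmann torque dependence of the dissociation rate,
  ``k(Gamma) = k(0) * exp(Gamma * theta / kB*T)``, fitted as ordinary least
  squares of ``ln k`` on torque; ``theta`` is the transcription-bubble
  rewinding angle at the transition state to dissociation;
* Michaelis-Menten saturation in [RapA] or [ATP],
  ``k(c) = kcat * c / (Km + c)``, fitted by nonlinear least squares on the
  mean lifetime ``<t>(c) = (Km + c)/(kcat*c)`` with starting values from the
  linearisation of ``<t>`` in ``1/c``.

Derived quantities: zero-torque extrapolated lifetimes, and the reduction of
the dissociation energy barrier produced by the enzyme,
``ddG = ln(t0_without / t0_with)`` in units of kB*T.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from scipy.optimize import curve_fit

from .mechanics import DEG_PER_BP, KBT_PN_NM, KBT_TO_KCAL_PER_MOL
from .survival import ExpFit


def _lifetime_and_se(point) -> tuple[float, float | None]:
    """Accept an ExpFit, a (lifetime, se) pair, or a bare lifetime."""
    if isinstance(point, ExpFit):
        return point.mean_lifetime, point.standard_error
    if isinstance(point, (tuple, list)):
        return float(point[0]), float(point[1])
    return float(point), None


@dataclass(frozen=True)
class BellFit:
    """Bell-law fit of ln(dissociation rate) versus torque.

    slope is theta/kB*T in rad per pN·nm; intercept is ln k at zero torque.
    theta is reported against the configured kB*T; its base-pair equivalent
    uses 34.3 degrees of helical rotation per bp.
    """

    slope: float
    intercept: float
    slope_se: float
    intercept_se: float
    n_points: int
    kbt: float = KBT_PN_NM

    @property
    def theta_rad(self) -> float:
        return self.slope * self.kbt

    @property
    def theta_deg(self) -> float:
        return math.degrees(self.theta_rad)

    @property
    def theta_bp(self) -> float:
        """Rewinding expressed in base pairs of helical rotation."""
        return self.theta_deg / DEG_PER_BP

    @property
    def k0(self) -> float:
        """Dissociation rate at zero torque, s^-1."""
        return math.exp(self.intercept)

    @property
    def zero_torque_lifetime(self) -> float:
        """Extrapolated residence time on torsionally relaxed DNA, s."""
        return 1.0 / self.k0

    def predict_rate(self, torque: float) -> float:
        """k(Gamma) = exp(intercept + slope*Gamma), s^-1."""
        return math.exp(self.intercept + self.slope * torque)

    def predict_lifetime(self, torque: float) -> float:
        return 1.0 / self.predict_rate(torque)


def fit_bell(
    points: Sequence[tuple[float, object]],
    weighted: bool = False,
    kbt: float = KBT_PN_NM,
) -> BellFit:
    """Fit ln(1/<t>) = intercept + slope * torque by least squares.

    Parameters
    ----------
    points : sequence of (torque pN·nm, lifetime)
        Each lifetime may be an :class:`~stallkin.survival.ExpFit`, a
        ``(lifetime, se)`` pair, or a bare mean lifetime in seconds.
    weighted : bool
        If True, weight each point by 1/sigma^2 with
        sigma_lnk = SE_t/<t> (requires SEs on every point).  Unweighted
        ordinary least squares is the default.
    kbt : float
        kB*T (pN·nm) used to convert the slope into the angle theta.
    """
    if len(points) < 2:
        raise ValueError(f"Bell fit needs >= 2 points, got {len(points)}")
    torques = np.array([float(t) for t, _ in points])
    if np.unique(torques).size < 2:
        raise ValueError("Bell fit needs >= 2 distinct torque values")
    lifes, ses = zip(*(_lifetime_and_se(p) for _, p in points))
    lifes = np.array(lifes)
    if np.any(lifes <= 0):
        raise ValueError("nonpositive lifetime in Bell fit input")
    lnk = np.log(1.0 / lifes)

    if not weighted:
        res = stats.linregress(torques, lnk)
        return BellFit(
            slope=float(res.slope),
            intercept=float(res.intercept),
            slope_se=float(res.stderr) if np.isfinite(res.stderr) else 0.0,
            intercept_se=float(res.intercept_stderr)
            if np.isfinite(res.intercept_stderr)
            else 0.0,
            n_points=len(points),
            kbt=kbt,
        )

    if any(s is None for s in ses):
        raise ValueError("weighted Bell fit requires a standard error on every point")
    sigma_lnk = np.array(ses) / lifes  # delta method: sd of ln(1/t)
    w = 1.0 / sigma_lnk**2
    X = np.column_stack([np.ones_like(torques), torques])
    WX = X * w[:, None]
    cov = np.linalg.inv(X.T @ WX)
    beta = cov @ (WX.T @ lnk)
    return BellFit(
        slope=float(beta[1]),
        intercept=float(beta[0]),
        slope_se=float(np.sqrt(cov[1, 1])),
        intercept_se=float(np.sqrt(cov[0, 0])),
        n_points=len(points),
        kbt=kbt,
    )


def extrapolate_zero_torque(fit: BellFit) -> float:
    """Residence time extrapolated to zero torque, 1/exp(intercept), s."""
    return fit.zero_torque_lifetime


@dataclass(frozen=True)
class BarrierReduction:
    """Enzyme-induced lowering of the dissociation barrier."""

    delta_kbt: float
    delta_kcal_per_mol: float


def barrier_reduction(
    fit_without: BellFit,
    fit_with: BellFit,
    kbt_to_kcal: float = KBT_TO_KCAL_PER_MOL,
) -> BarrierReduction:
    """ddG = ln(t0_without / t0_with) in kB*T, and in kcal/mol.

    The zero-torque lifetimes come from the two Bell fits; the kcal/mol
    conversion defaults to the reaction-temperature factor (0.610 at 307 K).
    """
    dd = math.log(fit_without.zero_torque_lifetime / fit_with.zero_torque_lifetime)
    return BarrierReduction(delta_kbt=dd, delta_kcal_per_mol=dd * kbt_to_kcal)


def negative_torque_report(fit: BellFit, torque: float = -12.0) -> dict[str, float]:
    """Naive extrapolation of a Bell fit to negative (underwinding) torque.

    Removal is in fact never observed on negatively supercoiled DNA, so this
    is a report of what the fitted law would predict — useful to show that
    the observed non-dissociation contradicts the naive extrapolation — not
    a fit.
    """
    return {
        "torque": torque,
        "predicted_rate": fit.predict_rate(torque),
        "predicted_lifetime": fit.predict_lifetime(torque),
    }


@dataclass(frozen=True)
class MMFit:
    """Michaelis-Menten fit: Km, kcat and the saturated lifetime 1/kcat."""

    Km: float
    kcat: float
    Km_se: float
    kcat_se: float
    substrate: str
    n_points: int

    @property
    def saturated_lifetime(self) -> float:
        return 1.0 / self.kcat

    def predict_lifetime(self, conc: float) -> float:
        return (self.Km + conc) / (self.kcat * conc)


def fit_mm(
    points: Sequence[tuple[float, object]],
    substrate: str = "RapA",
) -> MMFit:
    """Fit <t>(c) = (Km + c)/(kcat*c) to lifetime-versus-concentration data.

    Loss is on the lifetime (the measured quantity, with lifetime-scale
    errors), not on the rate.  Starting values come from the linearisation
    <t> = 1/kcat + (Km/kcat)*(1/c); the fit is then refined by nonlinear
    least squares.

    Parameters
    ----------
    points : sequence of (concentration, lifetime)
        Concentration in nM for RapA or uM for ATP; lifetime may be an
        ExpFit, a (lifetime, se) pair, or a bare mean lifetime.
    """
    if len(points) < 3:
        raise ValueError(f"Michaelis-Menten fit needs >= 3 points, got {len(points)}")
    concs = np.array([float(c) for c, _ in points])
    if np.any(concs <= 0):
        raise ValueError("nonpositive concentration in Michaelis-Menten fit input")
    lifes = np.array([_lifetime_and_se(p)[0] for _, p in points])
    if np.any(lifes <= 0):
        raise ValueError("nonpositive lifetime in Michaelis-Menten fit input")

    # linearisation: t = 1/kcat + (Km/kcat) * (1/c)
    lin = stats.linregress(1.0 / concs, lifes)
    kcat0 = 1.0 / max(lin.intercept, lifes.min() * 1e-3)
    km0 = max(lin.slope * kcat0, concs.min() * 1e-3)

    def model(c: np.ndarray, km: float, kcat: float) -> np.ndarray:
        return (km + c) / (kcat * c)

    popt, pcov = curve_fit(model, concs, lifes, p0=(km0, kcat0), maxfev=20000)
    km, kcat = (float(v) for v in popt)
    km_se, kcat_se = (float(v) for v in np.sqrt(np.diag(pcov)))
    if km <= 0 or kcat <= 0:
        raise RuntimeError("Michaelis-Menten fit converged to nonpositive parameters")
    return MMFit(
        Km=km,
        kcat=kcat,
        Km_se=km_se,
        kcat_se=kcat_se,
        substrate=substrate,
        n_points=len(points),
    )
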