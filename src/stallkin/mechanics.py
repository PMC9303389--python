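"""Mechanics of plectonemically supercoiled DNA in a magnetic trap.

A DNA molecule held at constant extending force ``F`` and twisted into the
plectonemic regime experiences a constant torque

    |Gamma| = sqrt(2 * xi * kB*T * F)

with ``xi`` the persistence length (``2*xi`` the Kuhn length).  The sign of
the torque follows the sign of the applied supercoiling (positive =
overwinding).

The product ``2*xi*kB*T`` is calibrated against the eight printed
(force, torque) operating points of the experiments this package models,
rather than taken from a textbook persistence length: the feasible interval
for the product is [444.08, 451.56) pN^2·nm^2 and the default is its
midpoint.  See :func:`calibrate_two_xi_kbt`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

#: Boltzmann constant in pN·nm per kelvin.
BOLTZMANN_PN_NM_PER_K = 1.380649e-2

#: Reaction temperature (34 C) used for thermodynamic conversions.
DEFAULT_TEMPERATURE_K = 307.15

#: kB*T at the reaction temperature, pN·nm.
KBT_PN_NM = BOLTZMANN_PN_NM_PER_K * DEFAULT_TEMPERATURE_K  # ~4.2587

#: kB*T -> kcal/mol at 307 K.  At 298 K the factor is 0.592; both are
#: supported, the reaction-temperature value is the default.
KBT_TO_KCAL_PER_MOL = 0.610
KBT_TO_KCAL_PER_MOL_298K = 0.592

#: Helical rotation per base pair of B-DNA, degrees (10.5 bp/turn).
DEG_PER_BP = 360.0 / 10.5

#: The eight (force pN, torque pN·nm) operating points used for calibration.
FORCE_TORQUE_PAIRS: tuple[tuple[float, int], ...] = (
    (0.3, 12),
    (0.7, 18),
    (1.1, 22),
    (1.6, 27),
    (2.0, 30),
    (3.0, 37),
    (4.0, 42),
    (6.0, 52),
)

#: Calibrated product 2*xi*kB*T, pN^2·nm^2 (midpoint of the feasible
#: interval; reproduced by ``calibrate_two_xi_kbt()``).
TWO_XI_KBT = 447.8

#: Persistence length implied by the calibrated product at 307.15 K, nm.
DEFAULT_PERSISTENCE_LENGTH_NM = TWO_XI_KBT / (2.0 * KBT_PN_NM)


def round_half_up(x: float) -> int:
    """Round to nearest integer with ties going away from zero-half up."""
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class TrapConditions:
    """Trap operating point: extending force plus thermal/elastic constants.

    Parameters
    ----------
    force : float
        Extending force on the bead, pN.  Must be >= 0.
    temperature : float
        Bath temperature, kelvin.
    persistence_length : float
        DNA bending persistence length xi, nm.
    """

    force: float
    temperature: float = DEFAULT_TEMPERATURE_K
    persistence_length: float = DEFAULT_PERSISTENCE_LENGTH_NM

    def __post_init__(self) -> None:
        if self.force < 0:
            raise ValueError(f"force must be >= 0 pN, got force={self.force}")
        if self.temperature <= 0:
            raise ValueError(
                f"temperature must be > 0 K, got temperature={self.temperature}"
            )
        if self.persistence_length <= 0:
            raise ValueError(
                "persistence_length must be > 0 nm, got "
                f"persistence_length={self.persistence_length}"
            )

    @property
    def thermal_energy(self) -> float:
        """kB*T in pN·nm."""
        return BOLTZMANN_PN_NM_PER_K * self.temperature


@dataclass(frozen=True)
class Torque:
    """Signed torque on supercoiled DNA, pN·nm (positive = overwinding)."""

    value: float

    @property
    def sign(self) -> int:
        return 0 if self.value == 0 else (1 if self.value > 0 else -1)


def torque_magnitude(force: float, two_xi_kbt: float = TWO_XI_KBT) -> float:
    """|Gamma| = sqrt(2*xi*kB*T*F) for a plectonemic molecule, pN·nm."""
    if force < 0:
        raise ValueError(f"force must be >= 0 pN, got force={force}")
    return math.sqrt(two_xi_kbt * force)


def torque_from_force(cond: TrapConditions, supercoil_sign: int) -> Torque:
    """Torque acting on plectonemic supercoiled DNA under force.

    The caller is responsible for the molecule actually being in the
    plectonemic (post-buckling) regime; the square-root law does not hold
    below buckling or once the duplex denatures.

    Parameters
    ----------
    cond : TrapConditions
    supercoil_sign : {-1, +1}
        Sign of the applied supercoiling.

    Returns
    -------
    Torque
        Signed torque, pN·nm.
    """
    if supercoil_sign not in (-1, 1):
        raise ValueError(f"supercoil_sign must be -1 or +1, got {supercoil_sign}")
    product = 2.0 * cond.persistence_length * cond.thermal_energy
    return Torque(supercoil_sign * math.sqrt(product * cond.force))


def calibrate_two_xi_kbt(
    pairs: tuple[tuple[float, int], ...] = FORCE_TORQUE_PAIRS,
    lo: float = 300.0,
    hi: float = 600.0,
    step: float = 0.01,
) -> float:
    """Grid-search calibration of the product 2*xi*kB*T.

    Scans candidate products and keeps those for which every (force, torque)
    operating point in ``pairs`` is reproduced by ``sqrt(product*F)`` after
    round-half-up to integer pN·nm.  Returns the midpoint of the passing
    interval.

    Raises
    ------
    ValueError
        If no candidate product reproduces all pairs.
    """
    candidates = np.arange(lo, hi, step)
    ok = np.ones(candidates.shape, dtype=bool)
    for force, torque in pairs:
        gamma = np.sqrt(candidates * force)
        ok &= np.floor(gamma + 0.5).astype(int) == torque
    if not ok.any():
        raise ValueError("no product in the scanned range reproduces all pairs")
    passing = candidates[ok]
    return float((passing.min() + passing.max()) / 2.0)
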