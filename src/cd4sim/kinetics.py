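"""Rate-law primitives: mass action and Hill kinetics.

Two elementary forms drive every reaction in the differentiation network:

* mass action      v = k * prod(level_i ** stoich_i)
* Hill activation  v = vmax * d^n / (km^n + d^n)
                       * prod( level_j / (ka_j + level_j) )   (co-activators)
                       * prod( ki_j / (ki_j + level_j) )      (inhibitors)

Levels are dimensionless arbitrary units (a.u.), time is in hours, so rates
are a.u./h.  The Hill term is evaluated through the ratio (d/km)^n so that
large Hill coefficients do not overflow.
"""

from __future__ import annotations

import math
from typing import Iterable, Sequence


def mass_action_rate(k: float, substrate_levels: Iterable[tuple[float, float]]) -> float:
    """Mass-action rate ``k * prod(level ** stoichiometry)``.

    Parameters
    ----------
    k : float
        Rate constant, must be > 0 (units 1/h times a.u. to the appropriate
        negative order).
    substrate_levels : iterable of (level, stoichiometry)
        Substrate concentrations in a.u. with their kinetic orders.

    Returns
    -------
    float
        Reaction rate in a.u./h, always >= 0 for valid inputs.
    """
    if k <= 0:
        raise ValueError(f"mass-action rate constant must be positive, got {k}")
    rate = k
    for level, stoich in substrate_levels:
        if level < 0:
            raise ValueError(f"negative substrate level {level}")
        if level == 0 and stoich > 0:
            return 0.0
        rate *= level ** stoich
    return rate


def _hill_fraction(driver_level: float, km: float, n: float) -> float:
    """Saturating fraction d^n / (km^n + d^n), overflow-safe for large n."""
    if driver_level == 0:
        return 0.0
    # work with the ratio so (d/km)^n never mixes huge and tiny magnitudes
    log_ratio = n * (math.log(driver_level) - math.log(km))
    if log_ratio > 700:          # exp would overflow; fraction is 1 to machine precision
        return 1.0
    if log_ratio < -700:
        return 0.0
    r = math.exp(log_ratio)
    return r / (1.0 + r)


def activation_factor(level: float, ka: float) -> float:
    """Saturating co-activator factor level / (ka + level) in [0, 1)."""
    if ka <= 0:
        raise ValueError(f"activation constant ka must be positive, got {ka}")
    if level < 0:
        raise ValueError(f"negative co-activator level {level}")
    return level / (ka + level)


def inhibition_factor(level: float, ki: float) -> float:
    """Saturating inhibition factor ki / (ki + level) in (0, 1]."""
    if ki <= 0:
        raise ValueError(f"inhibition constant ki must be positive, got {ki}")
    if level < 0:
        raise ValueError(f"negative inhibitor level {level}")
    return ki / (ki + level)


def hill_rate(
    vmax: float,
    km: float,
    n: float,
    driver_level: float,
    inhibitors: Sequence[tuple[float, float]] = (),
    coactivators: Sequence[tuple[float, float]] = (),
) -> float:
    """Hill-type production rate with multiplicative saturating modifiers.

    ``rate = vmax * d^n/(km^n + d^n) * prod(lvl/(ka+lvl)) * prod(ki/(ki+lvl))``

    The result is bounded in [0, vmax], monotone nondecreasing in the driver
    and every co-activator level, and monotone nonincreasing in every
    inhibitor level.

    Parameters
    ----------
    vmax : float
        Maximal rate (a.u./h), > 0.
    km : float
        Half-saturation level of the driver (a.u.), > 0.
    n : float
        Hill coefficient, >= 1.
    driver_level : float
        Level of the driving species (a.u.), >= 0.
    inhibitors : sequence of (level, ki)
        Inhibitor levels with their inhibition constants.
    coactivators : sequence of (level, ka)
        Co-activator levels with their half-saturation constants.
    """
    if vmax <= 0:
        raise ValueError(f"vmax must be positive, got {vmax}")
    if km <= 0:
        raise ValueError(f"km must be positive, got {km}")
    if n < 1:
        raise ValueError(f"Hill coefficient must be >= 1, got {n}")
    if driver_level < 0:
        raise ValueError(f"negative driver level {driver_level}")
    rate = vmax * _hill_fraction(driver_level, km, n)
    for level, ka in coactivators:
        rate *= activation_factor(level, ka)
    for level, ki in inhibitors:
        rate *= inhibition_factor(level, ki)
    return rate
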