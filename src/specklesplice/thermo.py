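"""Two-state Boltzmann model of competing splice-site usage.

A reporter carries two competing splice sites separated by a random region.
The system has two states: in one, the upstream site sits at the
speckle/nucleoplasm interface and the random region is inside the speckle;
in the other, the downstream site sits at the interface and the random
region is in the nucleoplasm.  Because the fixed flanks occupy the same
environment in both states, the free-energy difference between the states is
carried entirely by the random region and is approximated as the sum of
independent per-k-mer transfer energies:

    dG = sum_i dG_i     (i over all overlapping k-mers in the region)

The usage ratio (upstream / downstream) then follows the Boltzmann
distribution,

    ratio = exp(-dG / kT) = prod_i exp(-dG_i / kT),

which is the multiplicative law: the ratio is the product of per-word
Boltzmann factors.  Log space is the canonical internal representation; the
plain ratio is a presentation-layer conversion that may overflow for extreme
energies while the log ratio cannot.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .kmer import KmerEnergyTable, encode, window_codes

__all__ = [
    "ThermoConfig",
    "UsageOutcome",
    "delta_g",
    "usage_from_delta_g",
    "ratio_from_probabilities",
    "predict_ratio_multiplicative",
]


@dataclass(frozen=True)
class ThermoConfig:
    """Energy scale and word length of the model.

    ``kT`` is the thermal energy unit; all table energies are dimensionless
    multiples of it, so the default of 1.0 makes energies and log ratios
    numerically identical.
    """

    kT: float = 1.0
    k: int = 6

    def __post_init__(self) -> None:
        if not (self.kT > 0 and math.isfinite(self.kT)):
            raise ValueError(f"kT must be positive and finite, got {self.kT}")
        if not (1 <= self.k <= 8):
            raise ValueError(f"k must be in [1, 8], got {self.k}")


@dataclass(frozen=True)
class UsageOutcome:
    """Splice-site usage of a two-state reporter.

    ``log_ratio`` is the natural log of upstream/downstream usage and is the
    canonical representation; ``ratio`` is its exponential and may overflow
    to ``inf`` for very favorable regions.
    """

    log_ratio: float
    p_upstream: float
    p_downstream: float

    @property
    def ratio(self) -> float:
        with np.errstate(over="ignore"):
            return float(np.exp(self.log_ratio))


def delta_g(region: str, table: KmerEnergyTable) -> float:
    """Additive free energy of a region: sum of dG_i over all overlapping k-mers.

    Only windows fully inside the region contribute; a region of length L
    contributes L - k + 1 terms.  Raises ``ValueError`` if the region is
    shorter than ``table.k`` or contains an invalid character.
    """
    codes = window_codes(encode(region), table.k)
    return float(table.lookup(codes).sum())


def usage_from_delta_g(dG: float, config: ThermoConfig | None = None) -> UsageOutcome:
    """Boltzmann usage outcome for a two-state free-energy difference.

    ``dG`` is G(upstream-site-at-interface state) − G(downstream state), so
    ``log_ratio = -dG/kT`` and ``p_upstream = sigmoid(-dG/kT)``.
    """
    config = config or ThermoConfig()
    dG = float(dG)
    if not math.isfinite(dG):
        raise ValueError(f"dG must be finite, got {dG}")
    log_ratio = -dG / config.kT
    p_up = float(expit(log_ratio))
    p_down = float(expit(-log_ratio))
    return UsageOutcome(log_ratio=log_ratio, p_upstream=p_up, p_downstream=p_down)


def ratio_from_probabilities(
    p_upstream: float, p_downstream: float, tol: float = 1e-9
) -> float:
    """Usage ratio from the two usage probabilities, e.g. 75/25 = 3.0.

    Raises
    ------
    ValueError
        If either probability is negative, if they do not sum to 1 within
        ``tol``, or if ``p_downstream`` is zero (the ratio is undefined /
        infinite; use log-space accessors instead).
    """
    p_up, p_down = float(p_upstream), float(p_downstream)
    if p_up < 0 or p_down < 0:
        raise ValueError("probabilities must be non-negative")
    if abs(p_up + p_down - 1.0) > tol:
        raise ValueError(
            f"probabilities must sum to 1 within {tol}, got {p_up + p_down}"
        )
    if p_down == 0:
        raise ValueError(
            "p_downstream is 0: the usage ratio is infinite/undefined; "
            "work in log space instead"
        )
    return p_up / p_down


def predict_ratio_multiplicative(
    region: str, table: KmerEnergyTable, config: ThermoConfig | None = None
) -> float:
    """Usage ratio as the literal product of per-word Boltzmann factors.

    Computes ``prod_i exp(-dG_i/kT)`` over all overlapping k-mer occurrences
    in the region.  Algebraically identical to
    ``usage_from_delta_g(delta_g(region, table), config).ratio``; computing it
    as an explicit product exercises the multiplicative law directly.
    """
    config = config or ThermoConfig()
    codes = window_codes(encode(region), table.k)
    with np.errstate(over="ignore"):
        factors = np.exp(-table.lookup(codes) / config.kT)
        return float(np.prod(factors))
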