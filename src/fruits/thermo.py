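"""Reaction-direction feasibility from concentration ratios.

For a reaction whose quotient can be written as a product of
unimolecular concentration ratios (e.g. acetate kinase:
acetate + ATP → acetyl-P + ADP, with ratios [ADP]/[ATP] and
[acetyl-P]/[acetate]),

    ΔG = ΔG°' + RT·ln(10) · Σ log10(ratio)

so each ratio contributes one decade of RT·ln 10 ≈ 5.8 kJ mol⁻¹ at
303 K.  Working in ratios sidesteps the scarcity of absolute
intracellular concentration data; ΔG°' itself is a user-supplied input
(from any standard-condition calculator) and is never bundled here.
Net forward flux requires ΔG < 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Gas constant, kJ mol^-1 K^-1
R_KJ = 8.314462618e-3

#: Default cultivation temperature, K (30 °C)
DEFAULT_TEMPERATURE = 303.15


@dataclass(frozen=True)
class RatioThermoQuery:
    """A ΔG evaluation at given log10 concentration ratios.

    Each pair ``(label, log10_value)`` contributes +1 to the reaction
    quotient exponent, e.g. ``("adp_atp", 1.0)`` for a ten-fold ADP
    excess over ATP.
    """

    dg0_prime: float                      # kJ mol^-1
    log10_ratio_pairs: tuple[tuple[str, float], ...] = ()
    temperature: float = DEFAULT_TEMPERATURE

    def __post_init__(self):
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if any(not np.isfinite(v) for _, v in self.log10_ratio_pairs):
            raise ValueError("log10 ratios must be finite")


def rt_ln10(temperature: float = DEFAULT_TEMPERATURE) -> float:
    """RT·ln 10 in kJ mol^-1 — the ΔG increment per ratio decade."""
    return R_KJ * temperature * np.log(10.0)


def delta_g(query: RatioThermoQuery) -> float:
    """Transformed reaction energy at the queried concentration ratios.

    ΔG < 0 means net flux is feasible in the forward direction.
    """
    total_log = sum(v for _, v in query.log10_ratio_pairs)
    return query.dg0_prime + rt_ln10(query.temperature) * total_log


def min_substrate_excess(
    dg0_prime: float,
    fixed_log10_ratios: tuple[tuple[str, float], ...] = (),
    temperature: float = DEFAULT_TEMPERATURE,
) -> float:
    """Substrate fold-excess needed to pull ΔG to zero.

    Fixes all but one ratio, solves ``ΔG = 0`` for the free
    product:substrate log10 ratio, and returns ``10**(-log10 ratio)`` —
    the factor by which the substrate must exceed the product for net
    forward flux to become possible.  A value of ~100 for acetate
    kinase (at reported ATP:ADP ratios) is what justifies revising the
    reaction to irreversible in the model.
    """
    slope = rt_ln10(temperature)
    fixed_sum = sum(v for _, v in fixed_log10_ratios)
    free_log10 = -(dg0_prime / slope + fixed_sum)
    return float(10.0 ** (-free_log10))


def delta_g_grid(
    dg0_prime: float,
    ratio_a: tuple[str, np.ndarray],
    ratio_b: tuple[str, np.ndarray],
    temperature: float = DEFAULT_TEMPERATURE,
) -> np.ndarray:
    """ΔG over a grid of two log10 ratios (rows: a, columns: b)."""
    label_a, values_a = ratio_a
    label_b, values_b = ratio_b
    grid = np.empty((len(values_a), len(values_b)))
    for i, va in enumerate(values_a):
        for j, vb in enumerate(values_b):
            grid[i, j] = delta_g(
                RatioThermoQuery(
                    dg0_prime,
                    ((label_a, float(va)), (label_b, float(vb))),
                    temperature,
                )
            )
    return grid
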