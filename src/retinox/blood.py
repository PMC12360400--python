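"""Blood-side oxygen carriage: Hill saturation and convective transport.

The convective O2 transport rate along a vessel is
``f(P_b) = Q (H_D C0 S(P_b) + alpha_b P_b)`` with the oxyhemoglobin
saturation ``S`` given by a Hill curve; ``f`` is strictly increasing in
``P_b`` so blood PO2 can be recovered from a transport rate by monotone
inversion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["OxygenParams", "hill_saturation", "inverse_hill",
           "convective_o2_rate", "invert_convective_o2_rate"]


@dataclass
class OxygenParams:
    krogh_coeff: float = 6e-10  # D_diff*alpha, cm3 O2/cm/s/mmHg
    m0: float = 2.0  # tissue oxygen demand, cm3 O2/100 cm3/min
    p0: float = 10.0  # Michaelis-Menten half-max PO2, mmHg
    c0: float = 0.5  # O2 capacity of fully saturated RBCs, cm3 O2/cm3
    inflow_hematocrit: float = 0.4
    alpha_b: float = 3.1e-5  # O2 solubility in blood, cm3 O2/cm3/mmHg
    p50: float = 26.0  # Hill half-saturation, mmHg
    hill_n: float = 2.7
    inlet_saturation: float = 0.92

    def __post_init__(self):
        for name in ("krogh_coeff", "p0", "c0", "alpha_b", "p50", "hill_n"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.m0 < 0:
            raise ValueError("m0 must be non-negative")
        if not (0.0 < self.inlet_saturation < 1.0):
            raise ValueError("inlet_saturation must lie in (0, 1)")

    def inlet_blood_po2(self) -> float:
        return float(inverse_hill(self.inlet_saturation, self))


def hill_saturation(p_b, params: OxygenParams):
    """Oxyhemoglobin saturation S = P^n / (P^n + P50^n); S(P50) = 1/2."""
    p = np.maximum(np.asarray(p_b, dtype=float), 0.0)
    pn = p ** params.hill_n
    return pn / (pn + params.p50 ** params.hill_n)


def inverse_hill(s, params: OxygenParams):
    """Blood PO2 with saturation s (closed-form inverse of the Hill curve)."""
    s = np.asarray(s, dtype=float)
    if np.any((s < 0) | (s >= 1)):
        raise ValueError("saturation must lie in [0, 1)")
    return params.p50 * (s / (1.0 - s)) ** (1.0 / params.hill_n)


def convective_o2_rate(p_b, q_cgs, hematocrit, params: OxygenParams):
    """f(P_b) = Q (H_D C0 S + alpha_b P_b), cm3 O2/s; Q in cm3/s."""
    p = np.asarray(p_b, dtype=float)
    return q_cgs * (hematocrit * params.c0 * hill_saturation(p, params)
                    + params.alpha_b * p)


def invert_convective_o2_rate(f, q_cgs, hematocrit, params: OxygenParams,
                              p_guess=None):
    """Recover blood PO2 from a convective transport rate (vectorized).

    Uses safeguarded Newton iteration on the strictly increasing ``f``;
    non-positive rates return 0 (fully depleted blood).
    """
    f = np.atleast_1d(np.asarray(f, dtype=float))
    q = np.broadcast_to(np.asarray(q_cgs, dtype=float), f.shape)
    h = np.broadcast_to(np.asarray(hematocrit, dtype=float), f.shape)
    p = np.full(f.shape, 40.0) if p_guess is None else \
        np.array(np.broadcast_to(p_guess, f.shape), dtype=float)
    lo = np.zeros(f.shape)
    hi = np.full(f.shape, 500.0)
    # expand upper bracket where needed
    for _ in range(60):
        too_low = convective_o2_rate(hi, q, h, params) < f
        if not too_low.any():
            break
        hi[too_low] *= 2.0
    depleted = f <= 0.0
    n = params.hill_n
    for _ in range(100):
        val = convective_o2_rate(p, q, h, params) - f
        lo = np.where(val < 0, p, lo)
        hi = np.where(val > 0, p, hi)
        s = hill_saturation(p, params)
        with np.errstate(divide="ignore", invalid="ignore"):
            ds = np.where(p > 0, n * s * (1.0 - s) / p, 0.0)
        deriv = q * (h * params.c0 * ds + params.alpha_b)
        step = np.where(deriv > 0, val / np.maximum(deriv, 1e-300), 0.0)
        p_new = p - step
        bad = (p_new <= lo) | (p_new >= hi) | ~np.isfinite(p_new)
        p_new = np.where(bad, 0.5 * (lo + hi), p_new)
        if np.max(np.abs(p_new - p)) < 1e-12:
            p = p_new
            break
        p = p_new
    p = np.where(depleted, 0.0, np.maximum(p, 0.0))
    return p if p.shape != (1,) else float(p[0])
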