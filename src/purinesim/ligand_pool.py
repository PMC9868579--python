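"""Extracellular nucleotide pool under CD39 ectonucleotidase hydrolysis.

CD39 (NTPDase1) on the microglial surface degrades extracellular ATP in two
Michaelis-Menten steps, ATP -> ADP -> AMP.  The transient ADP pool produced
by the first step is the agonist for P2Y12, so the hydrolysis kinetics shape
both the decay of Ca2+ waveforms (by removing ATP) and the onset of
migration signaling (by producing ADP).  AMP is a terminal sink here: CD73
and adenosine receptors are outside the model.  UTP is carried in the pool
for P2Y2 selectivity protocols but is not a CD39 substrate.

Units: all concentrations in uM, time in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp


@dataclass
class NucleotidePool:
    """Extracellular nucleotide concentrations (uM)."""

    atp: float = 0.0
    adp: float = 0.0
    amp: float = 0.0
    utp: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array([self.atp, self.adp, self.amp, self.utp], float)

    @property
    def total_adenine(self) -> float:
        return self.atp + self.adp + self.amp


@dataclass
class CD39Params:
    """Two-step Michaelis-Menten hydrolysis constants.

    The chain runs in its effectively first-order regime (Km well above the
    millimolar doses used experimentally), with effective rate constants
    vmax/Km chosen so the ADP intermediate peaks near t = 4 min after a bolus
    and the ATP pool is depleted within a few minutes.  All four constants
    are refittable by the fitting module.

    vmax_* in uM/s, km_* in uM.  ``multiplier`` scales enzyme density
    (1 = wild type, 0 = CD39 knockout).
    """

    vmax_atp: float = 155.0
    km_atp: float = 10000.0
    vmax_adp: float = 4.2
    km_adp: float = 10000.0
    multiplier: float = 1.0

    def __post_init__(self) -> None:
        for name in ("vmax_atp", "km_atp", "vmax_adp", "km_adp", "multiplier"):
            if getattr(self, name) < 0:
                raise ValueError(f"CD39 parameter {name} must be >= 0")


def hydrolysis_rhs(pool: NucleotidePool | np.ndarray, params: CD39Params) -> np.ndarray:
    """Time derivatives (uM/s) of (atp, adp, amp, utp) under CD39 hydrolysis.

    Conserves total adenine exactly; UTP is untouched.  Rejects negative
    concentrations.
    """
    arr = pool.as_array() if isinstance(pool, NucleotidePool) else np.asarray(pool, float)
    if np.any(arr < 0):
        raise ValueError("nucleotide concentrations must be non-negative")
    atp, adp = arr[0], arr[1]
    e = params.multiplier
    v1 = e * params.vmax_atp * atp / (params.km_atp + atp)
    v2 = e * params.vmax_adp * adp / (params.km_adp + adp)
    return np.array([-v1, v1 - v2, v2, 0.0])


def simulate_pool(
    atp0: float,
    duration: float,
    params: CD39Params | None = None,
    dt_store: float = 1.0,
    utp0: float = 0.0,
):
    """Integrate the pool alone for ``duration`` seconds.

    Returns ``(t, y)`` with ``t`` the storage grid and ``y`` of shape
    (len(t), 4) holding (atp, adp, amp, utp) in uM.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if atp0 < 0:
        raise ValueError("atp0 must be non-negative")
    params = params or CD39Params()
    t = np.arange(0.0, duration + 0.5 * dt_store, dt_store)
    y0 = np.array([atp0, 0.0, 0.0, utp0])
    sol = solve_ivp(
        lambda _t, y: hydrolysis_rhs(np.maximum(y, 0.0), params),
        (0.0, t[-1]),
        y0,
        method="LSODA",
        t_eval=t,
        rtol=1e-8,
        atol=1e-10,
    )
    if not sol.success:  # pragma: no cover - solver failure is exceptional
        raise RuntimeError(f"pool integration failed: {sol.message}")
    return sol.t, sol.y.T


def first_order_rates(params: CD39Params) -> tuple[float, float]:
    """Effective first-order rate constants (1/s) in the substrate << Km limit."""
    e = params.multiplier
    return e * params.vmax_atp / params.km_atp, e * params.vmax_adp / params.km_adp


def adp_biexponential(t: np.ndarray, atp0: float, params: CD39Params) -> np.ndarray:
    """Closed-form ADP(t) for the first-order limit of the two-step chain.

    ADP(t) = k1 a0 (exp(-k1 t) - exp(-k2 t)) / (k2 - k1); used as the
    analytic oracle for the numerical solution when substrate << Km.
    """
    k1, k2 = first_order_rates(params)
    t = np.asarray(t, float)
    if np.isclose(k1, k2):
        return k1 * atp0 * t * np.exp(-k1 * t)
    return k1 * atp0 * (np.exp(-k1 * t) - np.exp(-k2 * t)) / (k2 - k1)
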