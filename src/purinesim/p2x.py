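"""Markov gating of the ionotropic P2X4 and P2X7 receptors.

P2X4 is the high-affinity isoform: micromolar ATP opens it quickly and it
desensitizes, producing a sharp, brief Ca2+ influx.  P2X7 needs
near-millimolar ATP, opens slowly and does not desensitize, producing the
prolonged plateau component of high-dose Ca2+ waveforms.  Each isoform is a
mass-conserving Markov scheme on its occupancy simplex:

    P2X4: closed <-> open -> desensitized -> closed   (3 states)
    P2X7: closed <-> open                             (2 states)

ATP dependence enters through a Hill occupancy term per isoform with
EC50(P2X4) << EC50(P2X7).  Channel Ca2+ flux is linear in the expression
multiplier rho, so rho = 0 silences an isoform exactly (knockout), and the
EGTA protocol zeroes the Ca2+ driving term while gating still evolves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class P2XParams:
    """Gating rates (1/s), Hill dose terms, and Ca2+ flux conductances.

    ``g_*`` convert open fraction into cytosolic Ca2+ influx (nM/s) at unit
    expression; they absorb channel conductance, the fraction of current
    carried by Ca2+, and the cell-volume/Faraday factor of the well-mixed
    compartment.
    """

    # P2X4 (closed/open/desensitized)
    ec50_x4: float = 10.0      # uM
    hill_x4: float = 1.5
    k_x4_open: float = 1.0
    k_x4_close: float = 0.5
    k_x4_desens: float = 0.05
    k_x4_recover: float = 0.01
    # P2X7 (closed/open)
    ec50_x7: float = 700.0     # uM
    hill_x7: float = 1.35
    k_x7_open: float = 0.15
    k_x7_close: float = 0.05
    # open-fraction -> Ca influx (nM/s) at rho = 1
    g_x4: float = 80.0
    g_x7: float = 300.0


def _hill(x: float, k: float, n: float) -> float:
    if x <= 0:
        return 0.0
    xn = (x / k) ** n
    return xn / (1.0 + xn)


def occupancy(atp: float, p: P2XParams) -> tuple[float, float]:
    """ATP occupancy (activation drive) of P2X4 and P2X7."""
    return _hill(atp, p.ec50_x4, p.hill_x4), _hill(atp, p.ec50_x7, p.hill_x7)


def p2x_rhs(gating: np.ndarray, atp: float, p: P2XParams) -> np.ndarray:
    """Derivatives of (x4_open, x4_desens, x7_open).

    Closed fractions are implicit (1 - open - desens per isoform), so the
    full per-isoform derivative vector sums to zero by construction.
    Rejects occupancies outside the simplex.
    """
    x4_o, x4_d, x7_o = np.asarray(gating, float)
    eps = 1e-8
    if min(x4_o, x4_d, x7_o) < -eps or x4_o + x4_d > 1 + eps or x7_o > 1 + eps:
        raise ValueError("P2X occupancies must lie on the probability simplex")
    a4, a7 = occupancy(atp, p)
    x4_c = 1.0 - x4_o - x4_d
    dx4_o = p.k_x4_open * a4 * x4_c - p.k_x4_close * x4_o - p.k_x4_desens * x4_o
    dx4_d = p.k_x4_desens * x4_o - p.k_x4_recover * x4_d
    dx7_o = p.k_x7_open * a7 * (1.0 - x7_o) - p.k_x7_close * x7_o
    return np.array([dx4_o, dx4_d, dx7_o])


def stationary_gating(atp: float, p: P2XParams) -> np.ndarray:
    """Fixed-point occupancies (x4_open, x4_desens, x7_open) at constant ATP.

    Solved from the transition-rate matrix null space; the ODE solution must
    relax to this (used as the linear-algebra oracle in tests).
    """
    a4, a7 = occupancy(atp, p)
    # P2X4 rate matrix over (closed, open, desens), columns sum to zero
    q4 = np.array(
        [
            [-p.k_x4_open * a4, p.k_x4_close, p.k_x4_recover],
            [p.k_x4_open * a4, -(p.k_x4_close + p.k_x4_desens), 0.0],
            [0.0, p.k_x4_desens, -p.k_x4_recover],
        ]
    )
    # null vector via the constrained linear system (replace last row by sum=1)
    a = q4.copy()
    a[-1, :] = 1.0
    b = np.array([0.0, 0.0, 1.0])
    pi4 = np.linalg.solve(a, b)
    x7_o = p.k_x7_open * a7 / (p.k_x7_open * a7 + p.k_x7_close)
    return np.array([pi4[1], pi4[2], x7_o])


def p2x_current(
    gating: np.ndarray,
    rho_p2x4: float,
    rho_p2x7: float,
    p: P2XParams,
    egta: bool = False,
) -> tuple[float, float, float]:
    """Per-isoform Ca2+ influx and total flux (nM/s into the cytosol).

    Returns ``(i_p2x4, i_p2x7, ca_influx)``.  Fluxes are linear in the
    expression multipliers; the EGTA flag zeroes the Ca2+ driving term only.
    """
    x4_o, _x4_d, x7_o = np.asarray(gating, float)
    drive = 0.0 if egta else 1.0
    i4 = p.g_x4 * rho_p2x4 * x4_o * drive
    i7 = p.g_x7 * rho_p2x7 * x7_o * drive
    return i4, i7, i4 + i7
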