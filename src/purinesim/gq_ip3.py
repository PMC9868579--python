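"""P2Y2 -> Gaq -> PLCbeta -> IP3/DAG signaling with PKC negative feedback.

This is the oscillator of the model, in the Cuthbertson-Chay lineage of
IP3-mediated Ca2+ oscillations: agonist-bound P2Y2 activates Gaq, Gaq
activates PLCbeta, PLCbeta cleaves PIP2 into IP3 and DAG, and DAG (with
Ca2+) activates PKC, which both inhibits PLCbeta and accelerates Gaq
deactivation.  The delayed negative feedback yields relaxation oscillations:
active Gaq climbs toward saturation (~80 of a 100 a.u. capacity under 1 mM
ATP), IP3/DAG rise with it, then PKC collapses the cycle.  Reducing the Gaq
activation rate ``k_g_cc`` below a bifurcation threshold converts the limit
cycle into a single-peak response; with CD39 hydrolysis active the agonist
decays and the cycles shrink from one to the next.

Gaq, PLC and PKC are in arbitrary units (Gaq capacity 100 a.u.); IP3 and
DAG are in nM.  P2Y2 responds to ATP and UTP; the ionotropic receptors do
not see UTP.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks


@dataclass
class GqState:
    g_active: float = 0.0
    plc_active: float = 0.0
    ip3: float = 0.0
    dag: float = 0.0
    pkc_active: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.g_active, self.plc_active, self.ip3, self.dag, self.pkc_active]
        )


@dataclass
class GqParams:
    """Rate constants for the Gaq/PLC/IP3/DAG/PKC loop.

    ``k_g_cc`` is the Gaq activation rate input (1/s at full receptor
    drive); scanning it moves the system across the oscillatory bifurcation
    and is how the waveform frequency/amplitude scans are realized.
    """

    g_total: float = 100.0     # a.u. Gaq capacity
    k_g_cc: float = 0.2        # 1/s, Gaq activation rate parameter
    k_y2: float = 200.0        # uM, hyperbolic agonist dose constant
    k_g_deact: float = 0.02    # 1/s, basal Gaq deactivation
    k_g_pkc: float = 0.5       # 1/s per PKC^2, feedback deactivation
    k_plc: float = 0.12        # PLC activation per Gaq a.u.
    k_pkc_plc: float = 1.2     # a.u., PKC level halving PLC activity
    d_plc: float = 0.1         # 1/s
    k_ip3: float = 1.0         # nM/s per PLC a.u.
    d_ip3: float = 0.1         # 1/s
    k_dag: float = 1.0         # nM/s per PLC a.u.
    d_dag: float = 0.1         # 1/s
    k_pkc: float = 0.2         # a.u./s at saturating DAG and Ca
    k_dag_pkc: float = 150.0   # nM, DAG half-activation of PKC (Hill n=4)
    k_ca_pkc: float = 200.0    # nM, Ca sensitivity of PKC activation
    d_pkc: float = 0.04        # a.u./s, max PKC deactivation (zero-order regime)
    k_m_pkc: float = 0.1       # a.u., Michaelis constant of PKC deactivation


def receptor_drive(atp: float, utp: float, rho_p2y2: float, p: GqParams) -> float:
    """Fractional P2Y2 receptor drive for a given agonist pool."""
    agonist = max(atp, 0.0) + max(utp, 0.0)
    return rho_p2y2 * agonist / (p.k_y2 + agonist)


def gq_rhs(
    state: np.ndarray,
    atp: float,
    utp: float,
    ca_cyt: float,
    p: GqParams,
    rho_p2y2: float = 1.0,
) -> np.ndarray:
    """Derivatives of (g_active, plc_active, ip3, dag, pkc_active).

    PKC inhibits PLCbeta (divisive) and accelerates Gaq deactivation; Ca2+
    promotes PKC activation, closing the DAG/Ca -> PKC -| PLC loop.
    """
    g, plc, ip3, dag, pkc = np.asarray(state, float)
    drive = receptor_drive(atp, utp, rho_p2y2, p)
    dg = p.k_g_cc * drive * (p.g_total - g) - (p.k_g_deact + p.k_g_pkc * pkc * pkc) * g
    plc_inh = 1.0 / (1.0 + (pkc / p.k_pkc_plc) ** 2)
    dplc = p.k_plc * g * plc_inh - p.d_plc * plc
    dip3 = p.k_ip3 * plc - p.d_ip3 * ip3
    ddag = p.k_dag * plc - p.d_dag * dag
    ca_fac = max(ca_cyt, 0.0) / (p.k_ca_pkc + max(ca_cyt, 0.0))
    d4 = (dag / p.k_dag_pkc) ** 4 if dag > 0 else 0.0
    dag_fac = d4 / (1.0 + d4)
    # zero-order deactivation makes PKC an ultrasensitive switch, which is
    # what sustains the relaxation limit cycle instead of damped ringing
    dpkc = p.k_pkc * dag_fac * ca_fac - p.d_pkc * pkc / (p.k_m_pkc + pkc)
    return np.array([dg, dplc, dip3, ddag, dpkc])


@dataclass
class WaveformClass:
    kind: str                  # "oscillatory" | "single_peak" | "flat"
    n_peaks: int
    period: float | None = None      # s, mean peak-to-peak interval
    frequency: float | None = None   # Hz
    amplitude: float | None = None   # mean peak-to-trough
    peak_times: np.ndarray = field(default_factory=lambda: np.array([]))


def classify_waveform(
    t: np.ndarray,
    x: np.ndarray,
    discard: float = 30.0,
    noise_frac: float = 0.05,
    max_period_cv: float = 0.5,
) -> WaveformClass:
    """Label a time series oscillatory / single_peak / flat.

    The first ``discard`` seconds (stimulus transient) are dropped; peaks
    must have prominence above ``noise_frac`` of the series range.
    Oscillatory requires >= 3 peaks with a bounded coefficient of variation
    of the peak intervals; 1-2 peaks are labeled single_peak (conservative
    tie-break); no peaks above the noise floor is flat.
    """
    t = np.asarray(t, float)
    x = np.asarray(x, float)
    if t.size != x.size:
        raise ValueError("t and x must have equal length")
    keep = t >= t[0] + discard
    if keep.sum() < 8:
        raise ValueError("series shorter than the classification window")
    ts, xs = t[keep], x[keep]
    rng = float(xs.max() - xs.min())
    if rng <= 0:
        return WaveformClass("flat", 0)
    prom = noise_frac * rng
    peaks, props = find_peaks(xs, prominence=prom)
    n = len(peaks)
    if n == 0:
        return WaveformClass("flat", 0)
    peak_times = ts[peaks]
    troughs = []
    for i, pk in enumerate(peaks):
        lo = peaks[i - 1] if i > 0 else 0
        hi = peaks[i + 1] if i < n - 1 else xs.size - 1
        troughs.append(min(xs[lo:pk].min() if pk > lo else xs[pk], xs[pk:hi + 1].min()))
    amplitude = float(np.mean(xs[peaks] - np.asarray(troughs)))
    if n < 3:
        return WaveformClass("single_peak", n, amplitude=amplitude, peak_times=peak_times)
    intervals = np.diff(peak_times)
    cv = float(intervals.std() / intervals.mean()) if intervals.mean() > 0 else np.inf
    if cv > max_period_cv:
        return WaveformClass("single_peak", n, amplitude=amplitude, peak_times=peak_times)
    period = float(intervals.mean())
    return WaveformClass(
        "oscillatory",
        n,
        period=period,
        frequency=1.0 / period,
        amplitude=amplitude,
        peak_times=peak_times,
    )
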