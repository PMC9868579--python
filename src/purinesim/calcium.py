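"""Two-compartment (cytosol/ER) Ca2+ dynamics.

Cytosolic Ca2+ is set by IP3R release from the ER, SERCA re-uptake, an ER
leak, P2X channel influx, NCX extrusion, a constitutive plasma-membrane
influx, and fast CaM buffering.  IP3R gating is deterministic, with IP3 and
cytosolic Ca2+ (CICR) cooperativity; store-operated entry is not modeled,
so SERCA acting on cytosolic Ca2+ is the only store-refill route.

The resting state is constructed to be an exact fixed point at
``ca_rest`` = 100 nM (the fluorescence normalization anchor): the ER load
is derived from the leak/SERCA balance and the constitutive membrane influx
from the NCX balance, so a zero-stimulus simulation holds 100 nM
indefinitely regardless of the other rate choices.

Units: cytosolic Ca2+ and CaM in nM, ER Ca2+ in uM, fluxes in nM/s
referred to cytosolic volume.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .gq_ip3 import classify_waveform


@dataclass
class CalciumState:
    ca_cyt: float = 100.0    # nM
    ca_er: float = 400.0     # uM
    cam_bound: float = 0.0   # nM CaM.Ca complex

    def as_array(self) -> np.ndarray:
        return np.array([self.ca_cyt, self.ca_er, self.cam_bound])


@dataclass
class CalciumParams:
    ca_rest: float = 100.0       # nM, resting cytosolic Ca2+
    v_ip3r: float = 3.12580e-4   # 1/s, max IP3R release rate per nM gradient
    k_ip3r_ip3: float = 400.0    # nM, IP3 sensitivity (Hill n=2)
    k_ip3r_ca: float = 150.0     # nM, CICR Ca activation (Hill n=2)
    v_serca: float = 200.0       # nM/s, SERCA Vmax (Hill n=2)
    k_serca: float = 200.0       # nM
    v_ncx: float = 150.0         # nM/s, NCX Vmax
    k_ncx: float = 300.0         # nM
    l_er: float = 1.0e-4         # 1/s, ER leak rate constant
    c_er: float = 0.18           # ER:cytosol effective volume ratio
    cam_total: float = 5000.0    # nM total CaM
    k_cam_on: float = 1.0e-3     # 1/nM/s
    k_cam_off: float = 1.0       # 1/s

    def serca_flux(self, ca: float) -> float:
        c = max(ca, 0.0)
        return self.v_serca * c * c / (c * c + self.k_serca**2)

    def ncx_flux(self, ca: float) -> float:
        c = max(ca, 0.0)
        return self.v_ncx * c / (c + self.k_ncx)

    @property
    def er_rest_nM(self) -> float:
        """ER load (nM) making rest an exact leak/SERCA balance."""
        if self.l_er == 0:
            if self.serca_flux(self.ca_rest) > 0:
                raise ValueError("zero ER leak cannot balance a nonzero SERCA flux")
            return self.ca_rest
        return self.ca_rest + self.serca_flux(self.ca_rest) / self.l_er

    @property
    def j_in(self) -> float:
        """Constitutive membrane influx balancing NCX at rest (nM/s)."""
        return self.ncx_flux(self.ca_rest)

    @property
    def cam_rest(self) -> float:
        on = self.k_cam_on * self.ca_rest
        if on + self.k_cam_off == 0:
            return 0.0
        return self.cam_total * on / (on + self.k_cam_off)

    def resting_state(self) -> CalciumState:
        return CalciumState(self.ca_rest, self.er_rest_nM * 1e-3, self.cam_rest)


def ip3r_open(ip3: float, ca: float, p: CalciumParams) -> float:
    """IP3R open fraction: cooperative in IP3 and in cytosolic Ca2+ (CICR)."""
    i = max(ip3, 0.0)
    c = max(ca, 0.0)
    f_ip3 = i * i / (i * i + p.k_ip3r_ip3**2)
    f_ca = c * c / (c * c + p.k_ip3r_ca**2)
    return f_ip3 * f_ca


def calcium_rhs(
    ca_state: np.ndarray,
    ip3: float,
    p2x_flux: float,
    p: CalciumParams,
    membrane_open: bool = True,
) -> np.ndarray:
    """Derivatives of (ca_cyt [nM], ca_er [uM], cam_bound [nM]).

    ``membrane_open=False`` closes every plasma-membrane flux (P2X, NCX and
    the constitutive influx), leaving a conservative cytosol/ER system used
    by the total-Ca conservation checks.
    """
    ca, er_uM, cam = np.asarray(ca_state, float)
    if ca < 0 or er_uM < 0:
        raise ValueError("Ca2+ concentrations must be non-negative")
    er = er_uM * 1e3
    j_rel = (p.v_ip3r * ip3r_open(ip3, ca, p) + p.l_er) * (er - ca)
    j_serca = p.serca_flux(ca)
    j_cam = p.k_cam_on * ca * (p.cam_total - cam) - p.k_cam_off * cam
    if membrane_open:
        j_mem = p2x_flux + p.j_in - p.ncx_flux(ca)
    else:
        j_mem = 0.0
    dca = j_rel - j_serca + j_mem - j_cam
    der = (j_serca - j_rel) / p.c_er * 1e-3
    return np.array([dca, der, j_cam])


def total_calcium(ca_state: np.ndarray, p: CalciumParams) -> float:
    """Cytosolic + CaM-bound + volume-weighted ER Ca2+ (nM cytosol-referred)."""
    ca, er_uM, cam = np.asarray(ca_state, float)
    return ca + cam + er_uM * 1e3 * p.c_er


def resting_flux_balance(p: CalciumParams) -> tuple[float, float]:
    """Residuals of the ER (leak vs SERCA) and membrane (influx vs NCX)
    balances at the constructed resting state; both should be ~0."""
    s = p.resting_state()
    er_res = p.l_er * (s.ca_er * 1e3 - s.ca_cyt) - p.serca_flux(s.ca_cyt)
    mem_res = p.j_in - p.ncx_flux(s.ca_cyt)
    return er_res, mem_res


def waveform_features(
    t: np.ndarray,
    ca: np.ndarray,
    onset: float,
    baseline: float | None = None,
) -> dict:
    """Summary features of a Ca2+ (or generic) transient.

    Requires the stimulus ``onset`` time (series without an onset marker are
    rejected).  Features are computed on the baseline-subtracted series:
    ``baseline`` defaults to the pre-onset mean (or the onset sample when
    the record starts at the onset).  ``duration`` is total time spent above
    baseline + 10% of the peak; ``decay_time`` is an exponential time
    constant fitted to the peak envelope (oscillatory traces) or to the
    post-peak decay (single transients).
    """
    t = np.asarray(t, float)
    ca = np.asarray(ca, float)
    if onset is None or onset < t[0] or onset > t[-1]:
        raise ValueError("stimulus onset must lie inside the record")
    pre = t < onset
    if baseline is None:
        baseline = float(ca[pre].mean()) if pre.any() else float(ca[t >= onset][0])
    post = t >= onset
    tp, xp = t[post], ca[post] - baseline
    ipk = int(np.argmax(xp))
    amp = float(xp[ipk])
    t_peak = float(tp[ipk] - onset)
    thr = 0.1 * amp
    above = xp > thr
    dt = np.median(np.diff(tp)) if tp.size > 1 else 0.0
    duration = float(above.sum() * dt)
    wf = classify_waveform(tp - tp[0], xp, discard=0.0) if tp.size >= 8 else None
    freq = wf.frequency if wf is not None and wf.kind == "oscillatory" else None
    decay = _fit_decay_time(tp, xp, ipk, amp, wf)
    return {
        "peak_amplitude": amp,
        "peak_value": amp + baseline,
        "time_to_peak": t_peak,
        "decay_time": decay,
        "duration": duration,
        "frequency": freq,
        "baseline": baseline,
    }


def _fit_decay_time(tp, xp, ipk, amp, wf) -> float | None:
    if wf is not None and wf.kind == "oscillatory" and len(wf.peak_times) >= 3:
        pk_t = wf.peak_times
        pk_x = np.interp(pk_t, tp - tp[0], xp)
        if np.all(pk_x > 0):
            slope = np.polyfit(pk_t, np.log(pk_x), 1)[0]
            return float(-1.0 / slope) if slope < 0 else None
        return None
    tail = slice(ipk, None)
    mask = xp[tail] > 0.05 * amp
    tt, xt = tp[tail][mask], xp[tail][mask]
    if tt.size < 3:
        return None
    slope = np.polyfit(tt, np.log(xt), 1)[0]
    return float(-1.0 / slope) if slope < 0 else None
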