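"""P2Y12/Gi -> PI3K -> pAkt signaling and pAkt-driven migration.

P2Y12 is activated by the ADP produced from ATP by CD39; through Gi/o it
agonizes PI3K and thereby Akt phosphorylation.  PI3K activation also has a
Ca2+-dependent component: Ca2+ entering through P2X channels (and released
from the ER) recruits PI3K to the plasma membrane.  Recruitment is modeled
as a slow state driven by a saturating Hill sensor of cytosolic Ca2+ above
baseline -- it builds during the Ca2+ transient and reverses over tens of
minutes, so a brief transient leaves a lasting boost of PI3K activity.
Recruited PI3K both amplifies the P2Y12/Gi-driven term and carries a small
P2Y12-independent basal activity.  At the reference protocol (50 uM ATP,
5 min, wild type) the P2Y12-dependent and Ca2+-dependent contributions to
peak pAkt partition approximately 90:10.

The migration rate is a saturating (Michaelis) function of normalized pAkt
multiplied by a CaM/MLCK efficiency that is neutral (1.0) at resting Ca2+.
The saturation means large pAkt transients are compressed while sustained
moderate pAkt keeps driving movement, which is what lets a 90% pAkt
knockdown (P2Y12-null) translate into the observed ~75% reduction in 1-h
migration distance rather than a 90% one.

pAkt is reported normalized to the peak of the 50 uM wild-type protocol;
distances are in um.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid


@dataclass
class MigrationParams:
    # ADP -> P2Y12 -> PI3K drive (Hill in ADP, uM; effectively a power law
    # over the micromolar operating range)
    k_adp: float = 7993.34
    n_adp: float = 0.480847
    w_p2y12: float = 1.0       # gain of the P2Y12 term (a.u.)
    beta_ca: float = 7.55742   # recruitment multiplier gain on the P2Y12 term
    w_ca: float = 0.0713658    # additive P2Y12-independent recruited-PI3K gain
    k_ca: float = 586.989      # nM above rest, Ca-sensor half-saturation
    n_ca: float = 1.247527     # Ca-sensor Hill exponent
    ca_rest: float = 100.0     # nM
    # Ca-dependent PI3K membrane recruitment (slow state)
    k_rec: float = 0.326232    # 1/s, recruitment rate at saturating Ca
    d_rec: float = 5.66603e-4  # 1/s, recruitment reversal (tau ~ 30 min)
    # pAkt kinetics
    k_akt: float = 1.0         # 1/s, activation gain
    d_akt: float = 0.0639258   # 1/s, dephosphorylation
    # pAkt -> migration
    pakt_ref: float = 8.80726  # absolute pAkt at the 50 uM WT peak (normalization)
    k_sat: float = 0.304337    # normalized-pAkt half-saturation of the rate
    rate_um_per_s: float = 0.0211474  # um/s at saturating pAkt, neutral MLCK
    e_mlck: float = 0.0        # CaM/MLCK efficiency gain (neutral default)


def ca_sensor(ca_cyt: float, p: MigrationParams) -> float:
    """Saturating Hill sensor of cytosolic Ca2+ elevation above rest, in [0, 1)."""
    d = max(ca_cyt - p.ca_rest, 0.0) ** p.n_ca
    return d / (p.k_ca**p.n_ca + d)


def recruitment_rhs(m: float, ca_cyt: float, p: MigrationParams,
                    clamp_ca: bool = False) -> float:
    """Slow Ca-dependent PI3K membrane-recruitment state, m in [0, 1)."""
    s = 0.0 if clamp_ca else ca_sensor(ca_cyt, p)
    m = min(max(m, 0.0), 1.0)
    return p.k_rec * s * (1.0 - m) - p.d_rec * m


def pi3k_drive(
    adp: float,
    ca_cyt: float,
    rho_p2y12: float,
    p: MigrationParams,
    recruitment: float | None = None,
    clamp_ca: bool = False,
) -> tuple[float, float, float]:
    """PI3K activation rate and its decomposition.

    Returns ``(total, p2y12_term, ca_term)``.  ``recruitment`` is the slow
    membrane-recruitment state; when None, the instantaneous Ca sensor is
    used in its place (quasi-static limit).  ``clamp_ca=True`` freezes the
    Ca2+ inputs at their resting value; the difference between a normal and
    a clamped run defines the Ca-conducted pAkt component used to quantify
    the EGTA effect.
    """
    if adp < 0:
        raise ValueError("adp must be non-negative")
    s = 0.0 if clamp_ca else ca_sensor(ca_cyt, p)
    m = s if recruitment is None else (0.0 if clamp_ca else recruitment)
    a = max(adp, 0.0) ** p.n_adp
    h = a / (a + p.k_adp**p.n_adp) if adp > 0 else 0.0
    y12 = p.w_p2y12 * rho_p2y12 * h * (1.0 + p.beta_ca * m)
    ca_term = p.w_ca * m
    return y12 + ca_term, y12, ca_term


def akt_rhs(p_akt: float, drive: float, p: MigrationParams) -> float:
    """First-order Akt phosphorylation toward the PI3K drive."""
    return p.k_akt * drive - p.d_akt * p_akt


def mlck_efficiency(cam_bound: float, cam_rest: float, p: MigrationParams) -> float:
    """CaM-dependent MLCK support of migration; 1.0 at resting CaM.Ca."""
    if cam_rest <= 0:
        return 1.0
    return 1.0 + p.e_mlck * max(cam_bound - cam_rest, 0.0) / cam_rest


def migration_rate(pakt_norm: float, mlck: float, p: MigrationParams) -> float:
    """Instantaneous migration rate (um/s); saturating in normalized pAkt."""
    x = max(pakt_norm, 0.0)
    return p.rate_um_per_s * x / (p.k_sat + x) * mlck


def migration_distance(
    t: np.ndarray,
    p_akt: np.ndarray,
    rate_constant: float,
    k_sat: float | None = None,
) -> np.ndarray:
    """Cumulative distance from a pAkt time course.

    With ``k_sat=None`` this is the plain quadrature
    ``distance(t) = rate_constant * integral(p_akt)`` (the closed-form
    testable case); with ``k_sat`` the saturating coupling used by the
    whole-cell engine is applied pointwise before integrating.
    """
    t = np.asarray(t, float)
    p_akt = np.asarray(p_akt, float)
    if np.any(p_akt < 0):
        raise ValueError("p_akt series must be non-negative")
    rate = p_akt if k_sat is None else p_akt / (k_sat + p_akt)
    d = cumulative_trapezoid(rate_constant * rate, t, initial=0.0)
    return d
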