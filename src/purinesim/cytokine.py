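"""Ca2+/CaM -> calcineurin -> NFAT -> TNFa transcription.

Sustained Ca2+ elevations activate calcineurin through CaM.Ca; calcineurin
dephosphorylates cytosolic NFAT, which then translocates to the nucleus on
a minutes timescale and drives TNFa mRNA transcription.  Because nuclear
accumulation is slow, short Ca2+ transients (< 2 min) induce negligible
transcription while prolonged or high-frequency waveforms do -- this is the
mechanism that separates migration-permissive from inflammatory waveforms.

NFAT is tracked as three conserved fractions: cytosolic phosphorylated
(inactive), cytosolic dephosphorylated (active), and nuclear.  TNFa mRNA,
intracellular protein, and exported protein are in arbitrary units with an
optional linear calibration to secreted pg-equivalents.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class CytokineParams:
    # calcineurin activation by CaM.Ca (Hill)
    cn_max: float = 1.0
    k_cn: float = 1500.0      # nM CaM.Ca
    n_cn: float = 3.0
    # NFAT cycling (1/s); nuclear accumulation time constant ~ minutes
    k_dephos: float = 0.01    # per unit calcineurin activity
    k_rephos: float = 0.01
    k_import: float = 0.005
    k_export: float = 0.002
    # TNFa
    k_tx: float = 0.02        # mRNA a.u./s per nuclear-NFAT fraction above basal
    k_tx0: float = 0.0        # basal transcription (above-basal units)
    d_mrna: float = 5.0e-4    # 1/s
    k_tl: float = 1.0e-3      # protein per mRNA a.u./s
    d_prot: float = 2.0e-4    # 1/s
    k_sec: float = 5.0e-4     # 1/s secretion


def calcineurin_activity(cam_bound: float, p: CytokineParams) -> float:
    c = max(cam_bound, 0.0)
    cn = c**p.n_cn / (c**p.n_cn + p.k_cn**p.n_cn)
    return p.cn_max * cn


def nfat_rhs(state: np.ndarray, cam_bound: float, p: CytokineParams) -> np.ndarray:
    """Derivatives of (nfat_active_cyt, nfat_nuclear) fractions.

    The phosphorylated cytosolic fraction is implicit (1 - active - nuclear)
    so total NFAT is conserved by construction.  Rejects states whose
    fractions leave [0, 1].
    """
    n_a, n_n = np.asarray(state, float)
    eps = 1e-6
    if min(n_a, n_n) < -eps or n_a + n_n > 1 + eps:
        raise ValueError("NFAT fractions must lie in [0,1] and sum to <= 1")
    cn = calcineurin_activity(cam_bound, p)
    n_c = 1.0 - n_a - n_n
    dn_a = p.k_dephos * cn * n_c - p.k_rephos * n_a - p.k_import * n_a
    dn_n = p.k_import * n_a - p.k_export * n_n
    return np.array([dn_a, dn_n])


def nfat_steady_state(cam_bound: float, p: CytokineParams) -> np.ndarray:
    """Closed-form stationary fractions at constant CaM.Ca (linear scheme)."""
    cn = calcineurin_activity(cam_bound, p)
    a = p.k_dephos * cn
    # solve: a(1 - n_a - n_n) = (k_rephos + k_import) n_a ; k_import n_a = k_export n_n
    r = p.k_import / p.k_export
    n_a = a / (a * (1.0 + r) + p.k_rephos + p.k_import)
    return np.array([n_a, r * n_a])


def tnfa_rhs(state: np.ndarray, nuclear_nfat: float, p: CytokineParams,
             nfat_basal: float = 0.0) -> np.ndarray:
    """Derivatives of (mRNA, intracellular protein, exported protein).

    Transcription is monotone in nuclear NFAT above its basal fraction;
    mRNA and protein degrade first-order; export is irreversible so the
    exported pool is non-decreasing.
    """
    mrna, prot, _exp = np.asarray(state, float)
    if mrna < 0 or prot < 0:
        raise ValueError("TNFa species must be non-negative")
    tx = p.k_tx0 + p.k_tx * max(nuclear_nfat - nfat_basal, 0.0)
    dm = tx - p.d_mrna * mrna
    dp = p.k_tl * mrna - (p.d_prot + p.k_sec) * prot
    de = p.k_sec * prot
    return np.array([dm, dp, de])
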