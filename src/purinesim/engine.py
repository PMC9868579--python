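"""Whole-cell assembly: one state vector, one stiff integrator, protocols.

The engine concatenates the module right-hand sides -- nucleotide pool,
P2X4/P2X7 gating, Gaq/IP3/DAG/PKC, cytosol/ER Ca2+, PI3K/pAkt/migration,
NFAT/TNFa -- into a 22-state ODE integrated with LSODA.  Shared couplings:
the pool feeds every receptor (ATP -> P2X4/P2X7/P2Y2, ADP -> P2Y12,
UTP -> P2Y2 only), IP3 gates the IP3R, and cytosolic Ca2+ feeds back onto
PKC, PI3K recruitment, CaM/MLCK and calcineurin/NFAT.

Protocols describe the stimulus (agonist species, dose, onset, optional
washout), the CD39 multiplier, the EGTA flag, and the receptor-expression
preset; knockouts are expression multipliers set to zero.  Runs are
deterministic; trajectories are stored on a uniform grid (default 1 s).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from . import calcium, cytokine, gq_ip3, ligand_pool, migration, p2x

STATE_NAMES = [
    "atp", "adp", "amp", "utp",
    "x4_open", "x4_desens", "x7_open",
    "g_active", "plc_active", "ip3", "dag", "pkc_active",
    "ca_cyt", "ca_er", "cam_bound",
    "pi3k_recruit", "p_akt", "distance",
    "nfat_active", "nfat_nuclear",
    "tnfa_mrna", "tnfa_protein", "tnfa_exported",
]
IDX = {n: i for i, n in enumerate(STATE_NAMES)}
N_STATES = len(STATE_NAMES)


@dataclass
class ReceptorExpression:
    """Multiplicative receptor-density scalings (1.0 = primary microglia)."""

    rho_p2x4: float = 1.0
    rho_p2x7: float = 1.0
    rho_p2y2: float = 1.0
    rho_p2y12: float = 1.0

    def __post_init__(self) -> None:
        for n in ("rho_p2x4", "rho_p2x7", "rho_p2y2", "rho_p2y12"):
            if getattr(self, n) < 0:
                raise ValueError(f"{n} must be >= 0")


# mRNA-derived expression presets (relative to primary cultured microglia)
EXPRESSION_PRESETS = {
    "primary": ReceptorExpression(1.0, 1.0, 1.0, 1.0),
    "bv2": ReceptorExpression(0.18, 0.65, 1.02, 0.030),
}


@dataclass
class ModelParams:
    cd39: ligand_pool.CD39Params = field(default_factory=ligand_pool.CD39Params)
    p2x: p2x.P2XParams = field(default_factory=p2x.P2XParams)
    gq: gq_ip3.GqParams = field(default_factory=gq_ip3.GqParams)
    ca: calcium.CalciumParams = field(default_factory=calcium.CalciumParams)
    mig: migration.MigrationParams = field(default_factory=migration.MigrationParams)
    cyt: cytokine.CytokineParams = field(default_factory=cytokine.CytokineParams)

    def resting_state(self) -> np.ndarray:
        """Full-state fixed point under zero agonist (used as y0)."""
        y = np.zeros(N_STATES)
        ca_rest = self.ca.resting_state()
        y[IDX["ca_cyt"]] = ca_rest.ca_cyt
        y[IDX["ca_er"]] = ca_rest.ca_er
        y[IDX["cam_bound"]] = ca_rest.cam_bound
        nfat = cytokine.nfat_steady_state(ca_rest.cam_bound, self.cyt)
        y[IDX["nfat_active"]], y[IDX["nfat_nuclear"]] = nfat
        return y

    @property
    def nfat_basal_nuclear(self) -> float:
        return float(cytokine.nfat_steady_state(self.ca.cam_rest, self.cyt)[1])


@dataclass
class Protocol:
    """Stimulus protocol: what is applied, when, and to which phenotype."""

    agonist: str = "ATP"           # "ATP" or "UTP"
    dose_uM: float = 0.0
    onset_s: float = 0.0
    duration_s: float | None = None   # analysis window; default = horizon
    horizon_s: float = 600.0
    cd39_multiplier: float = 1.0
    egta: bool = False
    expression: ReceptorExpression | str = "primary"
    dt_store: float = 1.0
    washout: bool = False          # remove the pool at onset + duration
    clamp_ca_drive: bool = False   # freeze Ca->PI3K inputs at rest (probe)

    def __post_init__(self) -> None:
        if self.dose_uM < 0:
            raise ValueError("dose must be >= 0")
        if self.duration_s is None:
            self.duration_s = self.horizon_s
        if self.horizon_s < self.duration_s:
            raise ValueError("horizon must cover the stimulus duration")
        if self.agonist.upper() not in ("ATP", "UTP"):
            raise ValueError("agonist must be ATP or UTP")

    @property
    def expr(self) -> ReceptorExpression:
        if isinstance(self.expression, ReceptorExpression):
            return self.expression
        return EXPRESSION_PRESETS[self.expression]


def _make_rhs(params: ModelParams, proto: Protocol):
    expr = proto.expr
    cd39 = replace(params.cd39, multiplier=params.cd39.multiplier * proto.cd39_multiplier)
    egta = proto.egta
    clamp = proto.clamp_ca_drive
    mp = params.mig
    nfat_basal = params.nfat_basal_nuclear
    cam_rest = params.ca.cam_rest

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        dy = np.empty(N_STATES)
        pool = np.maximum(y[0:4], 0.0)
        gating = np.clip(y[4:7], 0.0, 1.0)
        if gating[0] + gating[1] > 1.0:
            gating[:2] /= gating[0] + gating[1]
        gq_state = np.maximum(y[7:12], 0.0)
        ca_state = np.maximum(y[12:15], 1e-12)
        recruit = min(max(y[15], 0.0), 1.0)
        pakt = max(y[16], 0.0)
        nfat = np.clip(y[18:20], 0.0, 1.0)
        if nfat[0] + nfat[1] > 1.0:
            nfat /= nfat[0] + nfat[1]
        tnfa = np.maximum(y[20:23], 0.0)

        dy[0:4] = ligand_pool.hydrolysis_rhs(pool, cd39)
        atp, adp, utp = pool[0], pool[1], pool[3]
        dy[4:7] = p2x.p2x_rhs(gating, atp, params.p2x)
        _, _, ca_influx = p2x.p2x_current(
            gating, expr.rho_p2x4, expr.rho_p2x7, params.p2x, egta=egta
        )
        ca_cyt = ca_state[0]
        dy[7:12] = gq_ip3.gq_rhs(
            gq_state, atp, utp, ca_cyt, params.gq, rho_p2y2=expr.rho_p2y2
        )
        dy[12:15] = calcium.calcium_rhs(ca_state, gq_state[2], ca_influx, params.ca)
        dy[15] = migration.recruitment_rhs(recruit, ca_cyt, mp, clamp_ca=clamp)
        drive, _, _ = migration.pi3k_drive(
            adp, ca_cyt, expr.rho_p2y12, mp, recruitment=recruit, clamp_ca=clamp
        )
        dy[16] = migration.akt_rhs(pakt, drive, mp)
        cam = ca_state[2] if not clamp else cam_rest
        mlck = migration.mlck_efficiency(cam, cam_rest, mp)
        dy[17] = migration.migration_rate(pakt / mp.pakt_ref, mlck, mp)
        dy[18:20] = cytokine.nfat_rhs(nfat, ca_state[2], params.cyt)
        dy[20:23] = cytokine.tnfa_rhs(tnfa, nfat[1], params.cyt, nfat_basal=nfat_basal)
        return dy

    return rhs


def assemble_rhs(
    state: np.ndarray, t: float, protocol: Protocol, params: ModelParams
) -> np.ndarray:
    """Full derivative vector at one state (thin wrapper used by tests/tools)."""
    return _make_rhs(params, protocol)(t, np.asarray(state, float))


@dataclass
class Trajectory:
    """Uniformly stored run output with derived observables."""

    t: np.ndarray
    y: np.ndarray                  # (len(t), N_STATES)
    protocol: Protocol
    params: ModelParams

    def series(self, name: str) -> np.ndarray:
        return self.y[:, IDX[name]]

    @property
    def ca_cyt(self) -> np.ndarray:
        return self.series("ca_cyt")

    @property
    def pakt_norm(self) -> np.ndarray:
        return self.series("p_akt") / self.params.mig.pakt_ref

    @property
    def distance(self) -> np.ndarray:
        return self.series("distance")

    def currents(self) -> pd.DataFrame:
        """P2X per-isoform Ca2+ flux observables along the trajectory."""
        expr = self.protocol.expr
        rows = [
            p2x.p2x_current(
                np.clip(self.y[i, 4:7], 0.0, 1.0),
                expr.rho_p2x4,
                expr.rho_p2x7,
                self.params.p2x,
                egta=self.protocol.egta,
            )
            for i in range(len(self.t))
        ]
        return pd.DataFrame(rows, columns=["i_p2x4", "i_p2x7", "ca_influx"])

    def ca_features(self) -> dict:
        return calcium.waveform_features(
            self.t, self.ca_cyt, onset=self.protocol.onset_s,
            baseline=self.params.ca.ca_rest,
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.y, columns=STATE_NAMES)
        df.insert(0, "time_s", self.t)
        df["pakt_norm"] = self.pakt_norm
        return df


def run(
    protocol: Protocol,
    params: ModelParams | None = None,
    rtol: float = 1e-6,
    atol: float = 1e-9,
    max_step: float = np.inf,
    fine_step: bool = False,
) -> Trajectory:
    """Integrate a protocol with LSODA and store on the configured cadence.

    ``fine_step=True`` caps the internal step at 0.1 ms (the fixed-step
    regression regime; only sensible on short horizons).
    """
    params = params or ModelParams()
    if fine_step:
        max_step = min(max_step, 1e-4)
    y0 = params.resting_state()
    rhs = _make_rhs(params, protocol)
    segments: list[tuple[float, float]] = []
    events = sorted(
        {0.0, protocol.onset_s, protocol.horizon_s}
        | ({protocol.onset_s + protocol.duration_s} if protocol.washout else set())
    )
    events = [e for e in events if 0.0 <= e <= protocol.horizon_s]
    for a, b in zip(events[:-1], events[1:]):
        if b > a:
            segments.append((a, b))
    if not segments:
        segments = [(0.0, protocol.horizon_s)]

    ts_all, ys_all = [], []
    y = y0.copy()
    dose_key = "utp" if protocol.agonist.upper() == "UTP" else "atp"
    for a, b in segments:
        if np.isclose(a, protocol.onset_s):
            y[IDX[dose_key]] += protocol.dose_uM
        if protocol.washout and np.isclose(a, protocol.onset_s + protocol.duration_s):
            y[0:4] = 0.0
        t_eval = np.arange(a, b + 0.5 * protocol.dt_store, protocol.dt_store)
        t_eval = t_eval[(t_eval >= a) & (t_eval <= b)]
        sol = solve_ivp(
            rhs, (a, b), y, method="LSODA", t_eval=t_eval,
            rtol=rtol, atol=atol, max_step=max_step,
        )
        if not sol.success:
            raise RuntimeError(
                f"integration failed for protocol {protocol}: {sol.message}"
            )
        bad = ~np.isfinite(sol.y)
        if bad.any():
            name = STATE_NAMES[int(np.argwhere(bad.any(axis=1))[0])]
            raise RuntimeError(f"non-finite values in state '{name}' during run")
        ts_all.append(sol.t)
        ys_all.append(sol.y.T)
        y = sol.y[:, -1].copy()

    t = np.concatenate(ts_all)
    ys = np.vstack(ys_all)
    keep = np.concatenate(([True], np.diff(t) > 1e-9))
    return Trajectory(t[keep], ys[keep], protocol, params)


def scenario_matrix(
    base: Protocol,
    scenarios: dict[str, dict] | None = None,
    params: ModelParams | None = None,
) -> pd.DataFrame:
    """Run a control protocol plus named overrides; one feature row each.

    Overrides are Protocol field replacements (e.g. ``{"expression":
    ReceptorExpression(rho_p2x7=0)}``).  Returns waveform features, peak
    normalized pAkt, final migration distance and exported TNFa per row.
    """
    params = params or ModelParams()
    rows = []
    all_scen = {"control": {}}
    all_scen.update(scenarios or {})
    for name, over in all_scen.items():
        proto = replace(base, **over)
        traj = run(proto, params)
        feats = traj.ca_features()
        rows.append(
            {
                "scenario": name,
                "ca_peak_nM": feats["peak_value"],
                "ca_time_to_peak_s": feats["time_to_peak"],
                "ca_duration_s": feats["duration"],
                "ca_frequency_Hz": feats["frequency"],
                "peak_pakt_norm": float(traj.pakt_norm.max()),
                "distance_um": float(traj.distance[-1]),
                "tnfa_exported": float(traj.series("tnfa_exported")[-1]),
            }
        )
    return pd.DataFrame(rows)
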