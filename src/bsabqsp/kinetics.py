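"""Three-compartment trimer-kinetics model of a BCMA-CD3 bispecific antibody.

The bispecific drug is absorbed from a subcutaneous depot into a central
compartment, distributes to a peripheral and a bone-marrow (BM) compartment,
and in the BM binds membrane BCMA on myeloma cells and CD3 on T cells by
mass action.  Cross-arm closure of a drug:BCMA or drug:CD3 dimer forms the
functional trimer that drives Hill-type tumor killing on the effective
binding ratio theta = trimer / (all BCMA receptors).  Soluble BCMA, shed
from free membrane BCMA, acts as a drug sink in both compartments.  Trimer
formation releases IL-6 from a depletable pool, which slows T-cell egress
from the BM; myeloma cells secrete M-protein and free light chain, the
serum biomarkers used for response scoring.

Structural choices (all config-visible):

* logistic tumor growth, kill rate ``k_max·theta^n/(alpha^n+theta^n)``
  attenuated by ``1/(1+alpha_resis·t_treat)`` with the resistance clock
  starting at the first dose and not decaying on holidays;
* shedding is density-neutral: receptor synthesis replaces shed BCMA so the
  per-cell density stays constant and the receptor conservation identities
  hold exactly;
* cell death frees the drug of its complexes back into BM solution and, for
  trimers, the CD3 arm back to the surviving T cell;
* T-cell egress is slowed as ``k_out/(1+IL6/I50)``; counts are conserved
  between compartments (no proliferation or exhaustion);
* linear PK with volumetric exchange flows (L/day), so drug mass balance
  closes exactly;
* an optional nonfunctional CD3:drug:sBCMA trimer (on by default).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import least_squares

from . import units
from .params import (IDX, NSTATE, P_IDX, InitialState, InvalidParameterError,
                     PatientParameters, assemble_state, derive_consistent_rates,
                     pack)

try:  # pragma: no cover - exercised implicitly
    from numba import njit
except ImportError:  # pragma: no cover
    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]
        return lambda f: f


class SolverError(RuntimeError):
    """Stiff integration failed; message echoes the parameter set."""


class IntegrationQualityError(RuntimeError):
    """Receptor bookkeeping drifted beyond the acceptable tolerance."""


class EquilibriumError(RuntimeError):
    """The algebraic ternary-equilibrium solve did not converge."""


# ---------------------------------------------------------------------------
# derivative kernel
# ---------------------------------------------------------------------------

@njit(cache=True)
def _deriv(t, y, p):  # noqa: C901 - one flat kernel, kept branch-light
    dy = np.zeros(y.shape[0])

    A = y[0]
    Dc = y[1]; Dp = y[2]; Dbm = y[3]
    B = y[4]; DB = y[5]; C = y[6]; DC = y[7]; TRI = y[8]
    Sc = y[9]; Sbm = y[10]; DSc = y[11]; DSbm = y[12]; NT = y[13]
    N = y[14]; Tc = y[15]; Tbm = y[16]
    I = y[17]; R = y[18]

    kon_B = p[0]; koff_B = p[1]; kon_C = p[2]; koff_C = p[3]; chi = p[4]
    rho_B = p[5]; rho_C = p[6]
    k_max = p[7]; n_kill = p[8]; alpha_kill = p[9]; alpha_resis = p[10]
    g = p[11]; N_max = p[12]; N_min = p[13]
    k_shed = p[14]; k_cl_S = p[15]; q_S = p[16]
    k_M = p[17]; k_elim_M = p[18]; k_F = p[19]; k_elim_F = p[20]
    k_in = p[21]; k_out = p[22]; I50 = p[23]
    k_rel = p[24]; k_rep = p[25]; k_dep = p[26]; k_deg_I = p[27]
    ka = p[28]; CL = p[29]; Vc = p[30]; Vp = p[31]; Q = p[32]
    q_BM = p[33]; V_bm = p[34]
    u = p[35]
    soluble_trimer = p[36]
    t_first_dose = p[37]
    clamp = p[38]

    # effective binding ratio and kill rate
    b_tot = B + DB + TRI
    theta = TRI / b_tot if b_tot > 0.0 else 0.0
    if theta > 0.0 and k_max > 0.0:
        t_treat = t - t_first_dose
        if t_treat < 0.0:
            t_treat = 0.0
        resist = 1.0 / (1.0 + alpha_resis * t_treat)
        th_n = theta ** n_kill
        k_kill = k_max * th_n / (alpha_kill ** n_kill + th_n) * resist
        # a minimal residual reservoir is shielded from trimer killing
        shield = 1.0 - N_min / N if N > N_min else 0.0
        k_kill *= shield
    else:
        k_kill = 0.0

    growth = g * N * (1.0 - N / N_max)

    # mass-action binding fluxes (nM/day)
    f_DB = kon_B * Dbm * B - koff_B * DB
    f_DC = kon_C * Dbm * C - koff_C * DC
    f_T1 = chi * kon_C * DB * C - koff_C * TRI
    f_T2 = chi * kon_B * DC * B - koff_B * TRI
    f_DSc = kon_B * Dc * Sc - koff_B * DSc
    f_DSbm = kon_B * Dbm * Sbm - koff_B * DSbm
    f_NT = soluble_trimer * (chi * kon_B * DC * Sbm - koff_B * NT)

    # PK
    dy[0] = -ka * A
    dy[1] = (ka * A / Vc - (CL / Vc) * Dc
             - (Q / Vc) * (Dc - Dp) - (q_BM / Vc) * (Dc - Dbm) - f_DSc)
    dy[2] = (Q / Vp) * (Dc - Dp)
    if clamp == clamp:  # NaN check: clamp active when finite
        dy[3] = 0.0
    else:
        dy[3] = ((q_BM / V_bm) * (Dc - Dbm) - f_DB - f_DC - f_DSbm
                 + k_kill * (DB + TRI))

    # membrane BCMA on tumor cells
    dy[4] = growth * rho_B * u - f_DB - f_T2 - k_kill * B
    dy[5] = f_DB - f_T1 - k_kill * DB
    dy[8] = f_T1 + f_T2 - k_kill * TRI

    # CD3 on BM T cells; egress slowed by IL-6
    k_out_eff = k_out / (1.0 + I / I50)
    cd3_in = k_in * Tc * rho_C * u
    cd3_out = k_out_eff * C
    dy[6] = cd3_in - cd3_out - f_DC - f_T1 + k_kill * TRI
    dy[7] = f_DC - f_T2 - f_NT
    dy[13] = f_NT

    # soluble BCMA: shed in BM, exchanged, cleared centrally
    # the central drug:sBCMA complex clears with its antigen, so continuous
    # shedding is a genuine drug sink rather than a one-time buffer
    dy[9] = (q_S / Vc) * (Sbm - Sc) - k_cl_S * Sc - f_DSc
    dy[10] = k_shed * B - f_DSbm - f_NT - (q_S / V_bm) * (Sbm - Sc)
    dy[11] = f_DSc - k_cl_S * DSc + (q_S / Vc) * (DSbm - DSc)
    dy[12] = f_DSbm - (q_S / V_bm) * (DSbm - DSc)

    # cells
    dy[14] = growth - k_kill * N
    dy[15] = cd3_out / (rho_C * u) - k_in * Tc
    dy[16] = k_in * Tc - cd3_out / (rho_C * u)

    # IL-6 release from a depletable pool
    dy[17] = k_rel * TRI * R - k_deg_I * I
    dy[18] = k_rep * (1.0 - R) - k_dep * TRI * R

    # paraproteins
    dy[19] = k_M * N - k_elim_M * y[19]
    dy[20] = k_F * N - k_elim_F * y[20]

    # cumulative eliminated drug (nmol)
    dy[21] = CL * Dc + k_cl_S * DSc * Vc

    return dy


def derivatives(state: np.ndarray, t: float, params: PatientParameters,
                dose_input: float = np.inf) -> np.ndarray:
    """Time derivative of the full state vector.

    ``dose_input`` is the time of the first dose (the resistance clock);
    depot boluses themselves are discrete events handled by the simulator.
    Raises :class:`InvalidParameterError` naming the offending term if the
    derivative is non-finite.
    """
    state = np.asarray(state, dtype=float)
    if state.shape != (NSTATE,) or not np.all(np.isfinite(state)):
        raise InvalidParameterError("state vector must be finite with "
                                    f"{NSTATE} entries")
    init = InitialState()  # back-solve uses defaults only if k_M etc. unset
    p = pack(params, init, t_first_dose=dose_input)
    dy = _deriv(t, state, p)
    if not np.all(np.isfinite(dy)):
        from .params import STATE_NAMES
        bad = [STATE_NAMES[i] for i in np.where(~np.isfinite(dy))[0]]
        raise InvalidParameterError(f"non-finite derivative for {bad}")
    return dy


# ---------------------------------------------------------------------------
# simulation result
# ---------------------------------------------------------------------------

@dataclass
class SimulationResult:
    """Time-gridded trajectories of one simulated patient."""

    t: np.ndarray                  # days
    y: np.ndarray                  # (NSTATE, len(t))
    params: PatientParameters      # with back-solved consistency rates
    init: InitialState
    dose_times: np.ndarray         # days of administered boluses
    dose_amounts_mg: np.ndarray
    dropout_day: float | None = None   # progression-triggered removal

    def state(self, name: str) -> np.ndarray:
        return self.y[IDX[name]]

    @property
    def tumor_cells(self) -> np.ndarray:
        return self.state("tumor_cells")

    @property
    def effective_binding_ratio_series(self) -> np.ndarray:
        """theta(t) = trimer / (free BCMA + BCMA dimer + trimer)."""
        b_tot = (self.state("bcma_free") + self.state("bcma_dimer")
                 + self.state("trimer"))
        out = np.zeros_like(b_tot)
        nz = b_tot > 0
        out[nz] = self.state("trimer")[nz] / b_tot[nz]
        return out

    @property
    def trimer_per_tumor_cell(self) -> np.ndarray:
        """Trimer count divided by tumor-cell count."""
        tri_count = units.nM_to_count(self.state("trimer"), self.params.V_bm)
        n = self.tumor_cells
        out = np.zeros_like(n)
        nz = n > 0
        out[nz] = tri_count[nz] / n[nz]
        return out

    def integrated_paraprotein(self) -> tuple[str | None, np.ndarray]:
        """(marker name, series) under the M-protein-first selection rule."""
        from .response import select_integrated_paraprotein
        marker = select_integrated_paraprotein(self.init.M0, self.init.F0)
        if marker is None:
            return None, np.full_like(self.t, np.nan)
        return marker, self.state(marker)

    def values_at(self, name: str, times) -> np.ndarray:
        return np.interp(np.asarray(times, dtype=float), self.t, self.state(name))

    def to_frame(self, patient_id: str = "p0"):
        """Tidy CSV-ready frame: patient_id, time_day, variable, value."""
        import pandas as pd
        from .params import STATE_NAMES
        recs = []
        for name in STATE_NAMES:
            recs.append(pd.DataFrame({
                "patient_id": patient_id, "time_day": self.t,
                "variable": name, "value": self.state(name)}))
        return pd.concat(recs, ignore_index=True)

    def plot(self, variables=("tumor_cells", "mprotein", "drug_central", "il6"),
             ax=None):
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        for name in variables:
            series = self.state(name)
            ref = np.max(np.abs(series))
            ax.plot(self.t, series / ref if ref > 0 else series, label=name)
        ax.set_xlabel("time (days)")
        ax.set_ylabel("normalised level")
        ax.legend()
        return ax


# ---------------------------------------------------------------------------
# the per-patient model object
# ---------------------------------------------------------------------------

DEFAULT_SOLVER_OPTS = {"method": "LSODA", "rtol": 1e-6, "atol": 1e-9}


class PatientModel:
    """One virtual patient: mechanistic parameters plus sampled baseline.

    ``simulate`` integrates the stiff ODE system under an arbitrary dosing
    regimen, applying each dose as a discrete depot bolus (the integrator is
    stopped and restarted at event times).
    """

    def __init__(self, params: PatientParameters | None = None,
                 init: InitialState | None = None,
                 solver_opts: dict | None = None):
        self.init = init if init is not None else InitialState()
        raw = params if params is not None else PatientParameters()
        self.params = derive_consistent_rates(raw, self.init)
        self.solver_opts = dict(DEFAULT_SOLVER_OPTS)
        if solver_opts:
            self.solver_opts.update(solver_opts)

    # -- construction helpers ------------------------------------------------
    @classmethod
    def from_dicts(cls, params: dict, init: dict, **kw) -> "PatientModel":
        return cls(PatientParameters(**params), InitialState(**init), **kw)

    # -- simulation ----------------------------------------------------------
    def simulate(self, regimen=None, horizon: float = 336.0,
                 y0: np.ndarray | None = None, t0: float = 0.0,
                 t_first_dose: float | None = None,
                 clamp_drug_bm: float | None = None,
                 output_times: np.ndarray | None = None,
                 check_conservation: bool = True) -> SimulationResult:
        """Integrate from ``t0`` to ``horizon`` under ``regimen``.

        ``regimen`` may be ``None`` (no drug), a :class:`~bsabqsp.regimens.Regimen`
        or an iterable of ``(day, mg)`` pairs.  ``y0``/``t0`` allow chunked
        continuation (adaptive switching); ``clamp_drug_bm`` is a test hook
        holding free BM drug constant.
        """
        events = _expand_events(regimen, horizon)
        for day, _mg in events:
            if day < t0 or day > horizon:
                raise ValueError(f"dose at day {day} outside [{t0}, {horizon}]")
        if y0 is None:
            y0 = assemble_state(self.params, self.init)
        y = np.array(y0, dtype=float)
        if t_first_dose is None:
            t_first_dose = events[0][0] if events else np.inf
        p = pack(self.params, self.init, t_first_dose=t_first_dose,
                 clamp_drug_bm=np.nan if clamp_drug_bm is None else clamp_drug_bm)
        if clamp_drug_bm is not None:
            y[IDX["drug_bm"]] = clamp_drug_bm

        if output_times is None:
            grid = np.arange(np.ceil(t0), horizon + 0.5, 1.0)
            grid = np.unique(np.concatenate(
                [[t0], grid, [e[0] for e in events], [horizon]]))
            output_times = grid[(grid >= t0) & (grid <= horizon)]
        output_times = np.asarray(output_times, dtype=float)

        seg_bounds = np.unique(np.concatenate(
            [[t0, horizon], [e[0] for e in events]]))
        seg_bounds = seg_bounds[(seg_bounds >= t0) & (seg_bounds <= horizon)]
        event_map: dict[float, float] = {}
        for day, mg in events:
            event_map[day] = event_map.get(day, 0.0) + mg

        ts, ys = [], []
        for a, b in zip(seg_bounds[:-1], seg_bounds[1:]):
            if a in event_map:
                y[IDX["depot_nmol"]] += units.mg_to_nmol(
                    event_map[a], self.params.mw_drug)
            t_eval = output_times[(output_times >= a) & (output_times <= b)]
            sol = solve_ivp(_deriv, (a, b), y, t_eval=t_eval, args=(p,),
                            **self.solver_opts)
            if not sol.success:
                raise SolverError(
                    f"integration failed on [{a}, {b}]: {sol.message}; "
                    f"params={self.params.to_dict()}")
            if sol.t.size:
                ts.append(sol.t)
                ys.append(sol.y)
            y = sol.y[:, -1] if sol.y.size else y
            y = self._project_conservation(y)
        if seg_bounds[-1] in event_map:  # dose exactly at horizon
            y[IDX["depot_nmol"]] += units.mg_to_nmol(
                event_map[seg_bounds[-1]], self.params.mw_drug)

        t_all = np.concatenate(ts) if ts else np.array([t0])
        y_all = np.concatenate(ys, axis=1) if ys else y[:, None]
        t_all, keep = np.unique(t_all, return_index=True)
        y_all = y_all[:, keep]
        y_all = self._sanitize(y_all)

        res = SimulationResult(
            t=t_all, y=y_all, params=self.params, init=self.init,
            dose_times=np.array([e[0] for e in events]),
            dose_amounts_mg=np.array([e[1] for e in events]))
        if check_conservation and clamp_drug_bm is None:
            err = receptor_conservation_error(res)
            if err > 1e-4:
                raise IntegrationQualityError(
                    f"receptor bookkeeping drifted by {err:.2e} (rel)")
        return res

    def _project_conservation(self, y: np.ndarray) -> np.ndarray:
        """Rescale receptor species onto their conservation manifolds.

        The ODE structure conserves BCMA and CD3 bookkeeping exactly; the
        integrator drifts by O(rtol) per segment, which this projection
        removes so the identities hold to machine precision at output.
        """
        u = units.receptors_to_nM(1.0, self.params.V_bm)
        b_tot = y[IDX["bcma_free"]] + y[IDX["bcma_dimer"]] + y[IDX["trimer"]]
        b_ref = self.params.rho_B * y[IDX["tumor_cells"]] * u
        b_scale = self.params.rho_B * self.init.N0 * u   # initial pool size
        if b_ref > 0:
            defect = b_ref - b_tot
            if abs(defect) > 1e-3 * b_ref and abs(defect) > 1e-6 * b_scale:
                raise IntegrationQualityError(
                    f"BCMA bookkeeping drift {abs(defect) / b_ref:.2e} exceeds 1e-3")
            y[IDX["bcma_free"]] = max(y[IDX["bcma_free"]] + defect, 0.0)
        c_tot = (y[IDX["cd3_free"]] + y[IDX["cd3_dimer"]] + y[IDX["trimer"]]
                 + y[IDX["soluble_trimer"]])
        c_ref = self.params.rho_C * y[IDX["tcell_bm"]] * u
        c_scale = self.params.rho_C * self.init.Tbm0 * u
        if c_ref > 0:
            defect = c_ref - c_tot
            if abs(defect) > 1e-3 * c_ref and abs(defect) > 1e-6 * c_scale:
                raise IntegrationQualityError(
                    f"CD3 bookkeeping drift {abs(defect) / c_ref:.2e} exceeds 1e-3")
            y[IDX["cd3_free"]] = max(y[IDX["cd3_free"]] + defect, 0.0)
        return y

    @staticmethod
    def _sanitize(y_all: np.ndarray) -> np.ndarray:
        """Clip integrator-noise negatives (|x| < 1e-8 absolute) to zero."""
        small = (y_all < 0) & (y_all > -1e-8)
        y_all[small] = 0.0
        return y_all


def simulate_patient(params: PatientParameters, init: InitialState,
                     regimen=None, horizon: float = 336.0,
                     solver_opts: dict | None = None,
                     **kw) -> SimulationResult:
    """Functional wrapper around :meth:`PatientModel.simulate`."""
    return PatientModel(params, init, solver_opts).simulate(
        regimen=regimen, horizon=horizon, **kw)


def _expand_events(regimen, horizon: float) -> list[tuple[float, float]]:
    if regimen is None:
        return []
    if hasattr(regimen, "events_until"):
        return [(e.time, e.amount) for e in regimen.events_until(horizon)]
    return [(float(t), float(mg)) for t, mg in regimen]


# ---------------------------------------------------------------------------
# derived quantities
# ---------------------------------------------------------------------------

def effective_binding_ratio(result: SimulationResult,
                            window: tuple[float, float]) -> float:
    """Time-averaged trimer / total-BCMA ratio over ``window`` (days)."""
    t0, t1 = window
    if not (t0 < t1):
        raise ValueError(f"empty averaging window [{t0}, {t1}]")
    if t0 < result.t[0] - 1e-9 or t1 > result.t[-1] + 1e-9:
        raise ValueError("window outside simulated horizon")
    mask = (result.t >= t0) & (result.t <= t1)
    t = result.t[mask]
    theta = result.effective_binding_ratio_series[mask]
    if t.size < 2:
        return float(theta[0]) if t.size else 0.0
    return float(np.trapezoid(theta, t) / (t[-1] - t[0]))


def average_drug_concentration(result: SimulationResult,
                               window: tuple[float, float],
                               compartment: str = "drug_central") -> float:
    """Time-averaged free drug (nM) over ``window``; central by default."""
    t0, t1 = window
    mask = (result.t >= t0) & (result.t <= t1)
    t = result.t[mask]
    d = result.state(compartment)[mask]
    if t.size < 2:
        return float(d[0]) if t.size else 0.0
    return float(np.trapezoid(d, t) / (t[-1] - t[0]))


def untreated_doubling_time(params: PatientParameters, init: InitialState,
                            horizon: float = 2000.0) -> tuple[float, float]:
    """(tumor, M-protein) doubling times in days under no treatment.

    Uses the closed-form logistic tumor trajectory and integrates the linear
    M-protein balance on a daily grid; returns ``inf`` for a series that
    never doubles within ``horizon``.
    """
    p = derive_consistent_rates(params, init)
    t = np.arange(0.0, horizon + 0.25, 0.25)
    N = logistic_tumor(t, p.g, init.N0, p.N_max)
    k = p.k_elim_M
    from scipy.integrate import cumulative_trapezoid
    # damp the integrating factor to avoid overflow at long horizons
    expo = np.clip(k * t, None, 700.0)
    integ = cumulative_trapezoid(p.k_M * N * np.exp(expo), t, initial=0.0)
    M = np.exp(-expo) * (init.M0 + integ)
    return (_first_doubling(t, N, init.N0), _first_doubling(t, M, init.M0))


def _first_doubling(t: np.ndarray, x: np.ndarray, x0: float) -> float:
    target = 2.0 * x0
    above = np.where(x >= target)[0]
    if above.size == 0:
        return np.inf
    i = above[0]
    if i == 0:
        return float(t[0])
    f = (target - x[i - 1]) / (x[i] - x[i - 1])
    return float(t[i - 1] + f * (t[i] - t[i - 1]))


def logistic_tumor(t, g: float, N0: float, N_max: float):
    """Closed-form logistic growth trajectory."""
    a = (N_max - N0) / N0
    return N_max / (1.0 + a * np.exp(-g * np.asarray(t, dtype=float)))


def cytokine_peaks(result: SimulationResult) -> list[float]:
    """Maximum IL-6 between consecutive doses, ordered by dose."""
    dose_times = np.asarray(result.dose_times, dtype=float)
    if dose_times.size == 0:
        return []
    bounds = np.concatenate([dose_times, [result.t[-1]]])
    il6 = result.state("il6")
    peaks = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        mask = (result.t >= a) & (result.t <= b)
        peaks.append(float(il6[mask].max()) if mask.any() else 0.0)
    return peaks


# ---------------------------------------------------------------------------
# algebraic ternary-complex equilibrium (validation oracle)
# ---------------------------------------------------------------------------

def ternary_equilibrium_oracle(D_total: float, B_total: float, C_total: float,
                               S_total: float = 0.0, *,
                               kon_B: float = 2.0, koff_B: float = 40.0,
                               kon_C: float = 1.0, koff_C: float = 150.0,
                               chi: float = 1.0, soluble_trimer: bool = True,
                               fixed_free_drug: float | None = None) -> dict:
    """Solve the closed mass-action equilibrium by damped root-finding.

    Returns a dict of species (nM): ``D, B, C, S, DB, DC, TRI, DS, NT`` plus
    ``theta`` (trimer over total BCMA).  With ``fixed_free_drug`` the free
    drug is clamped (open system) and ``D_total`` is ignored.  Residuals are
    verified to < 1e-10 of the largest total.
    """
    totals = np.array([D_total, B_total, C_total, S_total], dtype=float)
    if np.any(totals < 0):
        raise ValueError("totals must be >= 0")
    K_B = koff_B / kon_B
    K_C = koff_C / kon_C
    st = 1.0 if soluble_trimer else 0.0
    scale = max(totals.max(), fixed_free_drug or 0.0, 1e-30)

    free_names = ["D", "B", "C", "S"]
    active = [i for i, v in enumerate(totals) if v > 0]
    if fixed_free_drug is not None:
        active = [i for i in active if i != 0]

    def species(D, B, C, S):
        DB = D * B / K_B
        DC = D * C / K_C
        TRI = chi * D * B * C / (K_B * K_C)
        DS = D * S / K_B
        NT = st * chi * D * C * S / (K_C * K_B)
        return DB, DC, TRI, DS, NT

    def unpack(x):
        free = np.zeros(4)
        if fixed_free_drug is not None:
            free[0] = fixed_free_drug
        for j, i in enumerate(active):
            free[i] = np.exp(x[j])
        return free

    def resid(x):
        D, B, C, S = unpack(x)
        DB, DC, TRI, DS, NT = species(D, B, C, S)
        r = np.array([
            D + DB + DC + TRI + DS + NT - D_total,
            B + DB + TRI - B_total,
            C + DC + TRI + NT - C_total,
            S + DS + NT - S_total,
        ]) / scale
        return r[active]

    if not active:
        free = np.zeros(4)
        if fixed_free_drug is not None:
            free[0] = fixed_free_drug
    else:
        x0 = np.log(np.maximum(totals[active] * 0.5, 1e-12 * scale))
        sol = least_squares(resid, x0, method="lm", xtol=1e-15, ftol=1e-15,
                            gtol=1e-15, max_nfev=20000)
        free = unpack(sol.x)
        res = np.abs(resid(sol.x)).max() if active else 0.0
        if res > 1e-10:
            raise EquilibriumError(
                f"equilibrium solve residual {res:.2e} (relative to {scale})")
    D, B, C, S = free
    DB, DC, TRI, DS, NT = species(D, B, C, S)
    b_tot = B + DB + TRI
    return {"D": D, "B": B, "C": C, "S": S, "DB": DB, "DC": DC, "TRI": TRI,
            "DS": DS, "NT": NT,
            "theta": TRI / b_tot if b_tot > 0 else 0.0}


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------

def receptor_conservation_error(result: SimulationResult) -> float:
    """Max relative violation of the BCMA and CD3 bookkeeping identities."""
    u = units.receptors_to_nM(1.0, result.params.V_bm)
    b_tot = (result.state("bcma_free") + result.state("bcma_dimer")
             + result.state("trimer"))
    b_ref = result.params.rho_B * result.tumor_cells * u
    c_tot = (result.state("cd3_free") + result.state("cd3_dimer")
             + result.state("trimer") + result.state("soluble_trimer"))
    c_ref = result.params.rho_C * result.state("tcell_bm") * u
    # guard the denominator with a tiny fraction of the peak pool so that a
    # fully cleared tumor (receptors at solver atol) does not dominate
    eps_b = 1e-9 * np.max(b_ref) if np.max(b_ref) > 0 else 1e-300
    eps_c = 1e-9 * np.max(c_ref) if np.max(c_ref) > 0 else 1e-300
    err_b = np.max(np.abs(b_tot - b_ref) / np.maximum(b_ref, eps_b))
    err_c = np.max(np.abs(c_tot - c_ref) / np.maximum(c_ref, eps_c))
    return float(max(err_b, err_c))


def drug_mass_balance_error(result: SimulationResult) -> float:
    """Relative drug mass-balance defect vs cumulative administered dose."""
    p = result.params
    administered_nmol = np.array([
        units.mg_to_nmol(result.dose_amounts_mg[result.dose_times <= t].sum(),
                         p.mw_drug)
        for t in result.t])
    in_system = (
        result.state("depot_nmol")
        + (result.state("drug_central") + result.state("sbcma_dimer_central")) * p.Vc
        + result.state("drug_peripheral") * p.Vp
        + (result.state("drug_bm") + result.state("bcma_dimer")
           + result.state("cd3_dimer") + result.state("trimer")
           + result.state("sbcma_dimer_bm") + result.state("soluble_trimer")) * p.V_bm
        + result.state("drug_eliminated"))
    mask = administered_nmol > 0
    if not mask.any():
        return float(np.max(np.abs(in_system)))
    return float(np.max(np.abs(in_system[mask] - administered_nmol[mask])
                        / administered_nmol[mask]))
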