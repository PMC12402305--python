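"""Patient-level parameterisation of the trimer-kinetics model.

:class:`PatientParameters` carries every mechanistic constant for one
simulated patient; :class:`InitialState` carries the sampled baseline and
back-solves the consistency quantities (paraprotein production rates,
soluble-BCMA clearance) that make the pre-treatment baseline a steady state.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field

import numpy as np

from . import units

# ---------------------------------------------------------------------------
# state-vector layout (nM unless noted)
# ---------------------------------------------------------------------------
STATE_NAMES = (
    "depot_nmol",       # 0  SC depot (nmol)
    "drug_central",     # 1  free drug, central
    "drug_peripheral",  # 2  free drug, peripheral
    "drug_bm",          # 3  free drug, bone marrow
    "bcma_free",        # 4  free membrane BCMA on tumor cells (BM)
    "bcma_dimer",       # 5  drug:BCMA dimer
    "cd3_free",         # 6  free CD3 on BM T cells
    "cd3_dimer",        # 7  drug:CD3 dimer
    "trimer",           # 8  functional CD3:drug:BCMA trimer
    "sbcma_central",    # 9  free soluble BCMA, central
    "sbcma_bm",         # 10 free soluble BCMA, BM
    "sbcma_dimer_central",  # 11 drug:sBCMA dimer, central
    "sbcma_dimer_bm",   # 12 drug:sBCMA dimer, BM
    "soluble_trimer",   # 13 nonfunctional CD3:drug:sBCMA trimer, BM
    "tumor_cells",      # 14 tumor cells (count)
    "tcell_central",    # 15 T cells, central (count)
    "tcell_bm",         # 16 T cells, BM (count)
    "il6",              # 17 IL-6 (pg/mL)
    "il6_pool",         # 18 releasable IL-6 pool (dimensionless)
    "mprotein",         # 19 serum M-protein (g/dL)
    "flc",              # 20 serum FLC (mg/L)
    "drug_eliminated",  # 21 cumulative eliminated drug (nmol)
)
NSTATE = len(STATE_NAMES)
IDX = {name: i for i, name in enumerate(STATE_NAMES)}


class InvalidParameterError(ValueError):
    """Raised when a parameter set violates its declared invariants."""


@dataclass(frozen=True)
class PatientParameters:
    """Mechanistic constants for one virtual patient.

    Units: association rates 1/(nM·day), other rates 1/day, volumes L,
    flows (CL, Q, q_BM) L/day, receptor densities receptors/cell.
    ``k_M``/``k_F``/``k_cl_S`` default to ``None`` meaning "back-solve at
    state assembly so the sampled baseline is a steady state".
    """

    # binding
    kon_B: float = 2.0        # drug–BCMA on-rate (also drug–sBCMA); Kd 20 nM
    koff_B: float = 40.0
    kon_C: float = 1.0        # drug–CD3 on-rate; deliberately weak arm, Kd 150 nM
    koff_C: float = 150.0
    chi: float = 1.0          # cross-arm avidity efficiency, (0, 1]
    # receptor densities
    rho_B: float = 3000.0     # BCMA per tumor cell
    rho_C: float = 60000.0    # CD3 per T cell
    # killing / resistance
    k_max: float = 2.0        # maximal trimer-driven kill rate, 1/day
    n_kill: float = 2.0
    alpha_kill: float = 1.5e-3  # half-maximal effective binding ratio, (0, 1)
    alpha_resis: float = 0.003  # resistance development rate, 1/day
    # tumor growth
    g: float = 0.005          # intrinsic growth rate, 1/day
    N_max: float = 5e12       # carrying capacity, cells
    N_min: float = 1e5        # minimal residual reservoir shielded from kill, cells
    # sBCMA
    k_shed: float = 10.0      # membrane-BCMA shedding, 1/day (fast turnover)
    k_cl_S: float | None = None   # central sBCMA clearance, 1/day (back-solved)
    q_S: float = 2.0          # BM<->central sBCMA exchange flow, L/day
    # paraproteins
    k_M: float | None = None  # M-protein production, g/dL per cell per day
    k_elim_M: float = 0.033   # IgG-scale elimination, 1/day (t1/2 ~ 21 d)
    k_F: float | None = None  # FLC production, mg/L per cell per day
    k_elim_F: float = 2.77    # FLC elimination, 1/day (t1/2 ~ 6 h)
    # T-cell trafficking / IL-6
    k_in: float = 0.1         # central -> BM entry, 1/day
    k_out: float = 0.2        # BM -> central egress, 1/day
    I50: float = 20.0         # IL-6 halving egress, pg/mL
    k_rel: float = 2.0e4      # IL-6 release per nM trimer per unit pool, pg/mL/day
    k_rep: float = 0.05       # releasable-pool replenishment, 1/day
    k_dep: float = 2.0e3      # releasable-pool depletion per nM trimer, 1/(nM·day)
    k_deg_I: float = 1.0      # IL-6 degradation, 1/day
    # PK
    ka: float = 0.25          # SC absorption, 1/day
    CL: float = 0.5           # clearance, L/day
    Vc: float = 4.0           # central volume, L
    Vp: float = 3.0           # peripheral volume, L
    Q: float = 0.6            # central<->peripheral flow, L/day
    q_BM: float = 0.35        # central<->BM drug exchange flow, L/day
    V_bm: float = 1.5         # bone-marrow (plasma-accessible) volume, L
    # molar masses
    mw_drug: float = units.MW_BSAB
    mw_sbcma: float = units.MW_SBCMA
    # structural switches
    soluble_trimer: bool = True   # nonfunctional CD3:drug:sBCMA complex

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        positive = (
            "kon_B koff_B kon_C koff_C rho_B rho_C k_max g N_max N_min k_shed q_S "
            "k_elim_M k_elim_F k_in k_out I50 k_rel k_rep k_dep k_deg_I "
            "ka CL Vc Vp Q q_BM V_bm mw_drug mw_sbcma"
        ).split()
        for name in positive:
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise InvalidParameterError(f"{name} must be finite and > 0, got {v!r}")
        if not 0 < self.chi <= 1:
            raise InvalidParameterError(f"chi must be in (0, 1], got {self.chi!r}")
        if not 0 < self.alpha_kill < 1:
            raise InvalidParameterError(
                f"alpha_kill must be in (0, 1), got {self.alpha_kill!r}")
        if self.n_kill < 1:
            raise InvalidParameterError(f"n_kill must be >= 1, got {self.n_kill!r}")
        if self.alpha_resis < 0:
            raise InvalidParameterError(
                f"alpha_resis must be >= 0, got {self.alpha_resis!r}")
        for name in ("k_M", "k_F", "k_cl_S"):
            v = getattr(self, name)
            if v is not None and not (math.isfinite(v) and v >= 0):
                raise InvalidParameterError(f"{name} must be >= 0 or None, got {v!r}")

    def replace(self, **kwargs) -> "PatientParameters":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "PatientParameters":
        with open(path) as fh:
            return cls(**json.load(fh))


@dataclass(frozen=True)
class InitialState:
    """Sampled baseline for one patient.

    ``sbcma0`` is the central free sBCMA in ng/mL; the BM level and the
    sBCMA clearance are back-solved at assembly so that, pre-treatment,
    shedding, exchange and clearance balance exactly.
    """

    N0: float = 2e11          # tumor cells
    M0: float = 2.5           # serum M-protein, g/dL
    F0: float = 300.0         # serum FLC, mg/L
    sbcma0: float = 60.0      # central free sBCMA, ng/mL
    Tc0: float = 2e10         # central T cells
    Tbm0: float = 3e10        # BM T cells
    sbcma_cutoff: float = 100.0   # ng/mL stratum boundary

    def __post_init__(self) -> None:
        for name in ("N0", "M0", "F0", "Tc0", "Tbm0"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise InvalidParameterError(f"{name} must be finite and > 0, got {v!r}")
        if self.sbcma0 < 0:
            raise InvalidParameterError("sbcma0 must be >= 0")

    @property
    def high_sbcma(self) -> bool:
        """Stratum flag: baseline sBCMA at or above the cutoff."""
        return self.sbcma0 >= self.sbcma_cutoff

    def replace(self, **kwargs) -> "InitialState":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def derive_consistent_rates(params: PatientParameters, init: InitialState) -> PatientParameters:
    """Back-solve ``k_M``, ``k_F``, ``k_cl_S`` (where unset) for a steady baseline.

    At t=0 with zero drug and growth ignored the paraprotein balances are
    ``k_M·N0 = k_elim_M·M0`` and ``k_F·N0 = k_elim_F·F0``; the sBCMA chain
    sheds ``k_shed·B_tot`` (nmol/day) in the BM, exports it through the
    exchange flow ``q_S`` and clears it centrally at ``k_cl_S``.
    """
    updates: dict = {}
    if params.k_M is None:
        updates["k_M"] = params.k_elim_M * init.M0 / init.N0
    if params.k_F is None:
        updates["k_F"] = params.k_elim_F * init.F0 / init.N0
    if params.k_cl_S is None:
        B_tot_nM = units.receptors_to_nM(params.rho_B * init.N0, params.V_bm)
        shed_nmol_day = params.k_shed * B_tot_nM * params.V_bm
        Sc_nM = units.ngml_to_nM(init.sbcma0, params.mw_sbcma)
        if Sc_nM > 0:
            updates["k_cl_S"] = shed_nmol_day / (Sc_nM * params.Vc)
        else:
            updates["k_cl_S"] = 1.0
    return params.replace(**updates) if updates else params


def baseline_sbcma_bm(params: PatientParameters, init: InitialState) -> float:
    """Steady-state BM free sBCMA (nM) implied by shedding and exchange."""
    B_tot_nM = units.receptors_to_nM(params.rho_B * init.N0, params.V_bm)
    Sc_nM = units.ngml_to_nM(init.sbcma0, params.mw_sbcma)
    return Sc_nM + params.k_shed * B_tot_nM * params.V_bm / params.q_S


def assemble_state(params: PatientParameters, init: InitialState) -> np.ndarray:
    """Build the t=0 state vector (drug-free)."""
    y0 = np.zeros(NSTATE)
    y0[IDX["bcma_free"]] = units.receptors_to_nM(params.rho_B * init.N0, params.V_bm)
    y0[IDX["cd3_free"]] = units.receptors_to_nM(params.rho_C * init.Tbm0, params.V_bm)
    y0[IDX["sbcma_central"]] = units.ngml_to_nM(init.sbcma0, params.mw_sbcma)
    y0[IDX["sbcma_bm"]] = baseline_sbcma_bm(params, init)
    y0[IDX["tumor_cells"]] = init.N0
    y0[IDX["tcell_central"]] = init.Tc0
    y0[IDX["tcell_bm"]] = init.Tbm0
    y0[IDX["il6_pool"]] = 1.0
    y0[IDX["mprotein"]] = init.M0
    y0[IDX["flc"]] = init.F0
    return y0


# order in which parameters are packed for the compiled derivative kernel
PACK_ORDER = (
    "kon_B", "koff_B", "kon_C", "koff_C", "chi",
    "rho_B", "rho_C",
    "k_max", "n_kill", "alpha_kill", "alpha_resis",
    "g", "N_max", "N_min",
    "k_shed", "k_cl_S", "q_S",
    "k_M", "k_elim_M", "k_F", "k_elim_F",
    "k_in", "k_out", "I50", "k_rel", "k_rep", "k_dep", "k_deg_I",
    "ka", "CL", "Vc", "Vp", "Q", "q_BM", "V_bm",
)
P_IDX = {name: i for i, name in enumerate(PACK_ORDER)}
# appended non-parameter slots: receptors/cell -> nM conversion, flags, clocks
P_EXTRA = ("u_bm", "soluble_trimer", "t_first_dose", "clamp_drug_bm")
NPACK = len(PACK_ORDER) + len(P_EXTRA)
for i, name in enumerate(P_EXTRA):
    P_IDX[name] = len(PACK_ORDER) + i


def pack(params: PatientParameters, init: InitialState,
         t_first_dose: float = np.inf, clamp_drug_bm: float = np.nan) -> np.ndarray:
    """Pack parameters into the flat array consumed by the derivative kernel."""
    p = derive_consistent_rates(params, init)
    arr = np.empty(NPACK)
    for name in PACK_ORDER:
        arr[P_IDX[name]] = getattr(p, name)
    arr[P_IDX["u_bm"]] = units.receptors_to_nM(1.0, p.V_bm)  # nM per receptor
    arr[P_IDX["soluble_trimer"]] = 1.0 if p.soluble_trimer else 0.0
    arr[P_IDX["t_first_dose"]] = t_first_dose
    arr[P_IDX["clamp_drug_bm"]] = clamp_drug_bm
    return arr
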