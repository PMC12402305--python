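"""Virtual-population workflow: sample, filter, and select by genetic algorithm.

The workflow mirrors standard QSP practice for calibrating mechanistic
models to cohort-level clinical summaries:

1. ``sample_trial_patients`` draws candidate parameterisations (the nine
   varied mechanistic parameters from uniform priors, baselines from the
   configured log-normal distributions);
2. ``plausibility_filter`` keeps candidates whose untreated tumor and
   M-protein doubling times fall within literature-scale bounds, then
   simulates every survivor once under every target regimen and caches
   assessment-time summaries (progression-triggered dropout applied);
3. ``genetic_select`` picks a fixed-size subset (a VPop) whose cohort
   summaries — stratified response rates, median percent-change trajectory,
   best-response deciles — best match the calibration targets.  Fitness is
   pure arithmetic on the caches, so selection never re-simulates.

:class:`VPopCalibration` wraps steps 2-3 as a model object whose ``fit``
returns a :class:`VPopCalibrationResults` with estimates, diagnostics and a
``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import regimens as rg
from . import response as resp
from . import synthetic
from .kinetics import PatientModel, untreated_doubling_time
from .params import InitialState, PatientParameters

#: objective penalty when a required sBCMA stratum has no members
EMPTY_STRATUM_PENALTY = 10.0
#: default untreated doubling-time plausibility bounds, days (stand-in for
#: the literature range)
DOUBLING_BOUNDS = (60.0, 600.0)

DEFAULT_GA_OPTS = {
    "population": 50,
    "generations": 100,
    "tournament": 3,
    "crossover_rate": 0.8,
    "mutation_swaps": 2,
    "elitism": 2,
}


def sample_trial_patients(n: int = 10_000,
                          priors: dict | None = None,
                          dists: synthetic.BaselineDistributions | None = None,
                          seed: int = 0) -> pd.DataFrame:
    """Candidate table: sampled baselines plus the nine varied parameters."""
    priors = priors if priors is not None else synthetic.parameter_priors()
    rng = np.random.default_rng(seed)
    df = synthetic.sample_baselines(n, dists, rng)
    for name, (lo, hi) in priors.items():
        df[name] = rng.uniform(lo, hi, size=n)
    return df


_VARIED = tuple(synthetic.PARAMETER_PRIORS)


def build_patient(row, base_params: PatientParameters | None = None
                  ) -> tuple[PatientParameters, InitialState]:
    """Materialise one candidate row into model inputs."""
    base = base_params if base_params is not None else PatientParameters()
    overrides = {k: float(row[k]) for k in _VARIED if k != "tbm0_mult"}
    params = base.replace(**overrides)
    init = InitialState(
        N0=float(row["N0"]), M0=float(row["M0"]), F0=float(row["F0"]),
        sbcma0=float(row["sbcma0"]), Tc0=float(row["Tc0"]),
        Tbm0=float(row["Tbm0"]) * float(row.get("tbm0_mult", 1.0)))
    return params, init


@dataclass
class RegimenCache:
    """Cached per-patient summaries under one regimen."""

    regimen_id: str
    assessment_days: np.ndarray
    pct_change: np.ndarray        # (n_patients, n_days), LOCF after dropout
    responder: np.ndarray         # bool
    bor: np.ndarray               # best % change
    persistent: np.ndarray        # confirmed response by cycle 7
    pd_day: np.ndarray            # nan if no progression
    high_sbcma: np.ndarray        # stratum flag


@dataclass
class PlausiblePool:
    """Plausibility-filtered candidates with per-regimen simulation caches."""

    candidates: pd.DataFrame              # one row per plausible patient
    doubling_times: pd.DataFrame          # tumor_dt, mprotein_dt (days)
    caches: dict[str, RegimenCache]
    base_params: PatientParameters
    bounds: tuple[float, float]

    def __len__(self) -> int:
        return len(self.candidates)

    def cache(self, regimen_id: str) -> RegimenCache:
        try:
            return self.caches[regimen_id]
        except KeyError:
            raise KeyError(f"no cached summaries for regimen {regimen_id!r}; "
                           f"cached: {sorted(self.caches)}") from None


def plausibility_filter(candidates: pd.DataFrame,
                        bounds: tuple[float, float] = DOUBLING_BOUNDS,
                        regimen_ids: tuple[str, ...] = (),
                        base_params: PatientParameters | None = None,
                        horizon: float | None = None,
                        solver_opts: dict | None = None) -> PlausiblePool:
    """Filter by untreated doubling times, then simulate-and-cache.

    A candidate is plausible when both its untreated tumor-cell and serum
    M-protein doubling times lie within ``bounds``.  Every survivor is then
    simulated under every regimen in ``regimen_ids`` (progression dropout
    applied; trajectories carried forward after dropout) and the summaries
    cached for selection.
    """
    lo, hi = bounds
    if not 0 < lo < hi:
        raise ValueError("need 0 < lo < hi doubling bounds")
    base = base_params if base_params is not None else PatientParameters()

    rows = []
    for idx, row in candidates.iterrows():
        params, init = build_patient(row, base)
        t_dt, m_dt = untreated_doubling_time(params, init)
        rows.append((idx, t_dt, m_dt, lo <= t_dt <= hi and lo <= m_dt <= hi))
    dt = pd.DataFrame(rows, columns=["patient", "tumor_dt", "mprotein_dt",
                                     "plausible"]).set_index("patient")
    keep = dt.index[dt["plausible"]]
    if len(keep) == 0:
        raise ValueError(
            "no candidate passed the doubling-time filter; widen the prior "
            f"on g or the bounds {bounds}")
    plausible = candidates.loc[keep]

    caches = {}
    for rid in regimen_ids:
        caches[rid] = simulate_cohort(plausible, rid, base_params=base,
                                      horizon=horizon, solver_opts=solver_opts)
    return PlausiblePool(candidates=plausible,
                         doubling_times=dt.loc[keep, ["tumor_dt", "mprotein_dt"]],
                         caches=caches, base_params=base, bounds=bounds)


def simulate_cohort(candidates: pd.DataFrame, regimen_id: str,
                    base_params: PatientParameters | None = None,
                    horizon: float | None = None,
                    solver_opts: dict | None = None,
                    regimen: rg.Regimen | None = None) -> RegimenCache:
    """Simulate every candidate under one regimen and summarise.

    ``regimen`` overrides the preset lookup (e.g. a flat dose with priming
    prepended).  Dropout: a patient leaving the trial at progression keeps
    their last observation carried forward in the trajectory summary.
    """
    if regimen is None:
        regimen = rg.preset_regimen(regimen_id)
    days = rg.assessment_days(regimen, horizon or 168.0)
    if horizon is None:
        horizon = float(days[-1])
    days = days[days <= horizon + 1e-9]

    n = len(candidates)
    pct = np.empty((n, days.size))
    responder = np.zeros(n, dtype=bool)
    persistent = np.zeros(n, dtype=bool)
    bor = np.empty(n)
    pd_day = np.full(n, np.nan)
    high = np.zeros(n, dtype=bool)

    for i, (idx, row) in enumerate(candidates.iterrows()):
        params, init = build_patient(row, base_params)
        model = PatientModel(params, init, solver_opts)
        res = model.simulate(regimen, horizon=horizon,
                             check_conservation=False)
        track = resp.track_from_simulation(res, days, patient_id=str(idx))
        call = resp.classify_response(track)
        p = track.pct_change.copy()
        if call.pd_day is not None:
            pd_day[i] = call.pd_day
            j = int(np.searchsorted(days, call.pd_day))
            p[j + 1:] = p[j]          # LOCF after removal
        pct[i] = p
        responder[i] = call.is_biochemical_responder
        persistent[i] = call.persistent_responder
        bor[i] = call.bor
        high[i] = init.high_sbcma
    return RegimenCache(regimen_id=regimen_id, assessment_days=days,
                        pct_change=pct, responder=responder, bor=bor,
                        persistent=persistent, pd_day=pd_day, high_sbcma=high)


# ---------------------------------------------------------------------------
# objective
# ---------------------------------------------------------------------------

def objective(member_pos: np.ndarray, targets: synthetic.CalibrationTargets,
              pool: PlausiblePool) -> tuple[float, dict]:
    """Weighted distance between a member set's summaries and the targets.

    ``member_pos`` holds positional indices into the pool.  Per cohort the
    three metrics — squared stratum-BRR error, mean squared median-trajectory
    error, mean squared best-response-decile error — are each normalised to
    unit scale (rates as fractions, percent changes divided by 100) before
    trial-size weighting.  An empty required stratum contributes a fixed
    penalty rather than raising.
    """
    member_pos = np.asarray(member_pos)
    breakdown = {}
    total = 0.0
    for cohort, w in zip(targets.cohorts, targets.weights):
        cache = pool.cache(cohort.regimen_id)
        high = cache.high_sbcma[member_pos]
        responder = cache.responder[member_pos]
        terms = {}

        brr_err = 0.0
        for name, flag, target in (("low", ~high, cohort.brr_low),
                                   ("high", high, cohort.brr_high)):
            if flag.sum() == 0:
                brr_err += EMPTY_STRATUM_PENALTY
            else:
                brr_err += (responder[flag].mean() - target) ** 2
        terms["brr"] = brr_err / 2.0

        sim_days = cache.assessment_days
        tgt_days = np.asarray(cohort.assessment_days, dtype=float)
        tgt_med = np.asarray(cohort.median_pct_change, dtype=float)
        sim_med = np.median(cache.pct_change[member_pos], axis=0)
        sim_at_tgt = np.interp(tgt_days, sim_days, sim_med)
        terms["trajectory"] = float(np.mean(((sim_at_tgt - tgt_med) / 100.0) ** 2))

        if cohort.bor_deciles is not None:
            sim_dec = resp.bor_deciles(cache.bor[member_pos])
            tgt_dec = np.asarray(cohort.bor_deciles, dtype=float)
            terms["deciles"] = float(np.mean(((sim_dec - tgt_dec) / 100.0) ** 2))

        cohort_total = sum(terms.values())
        breakdown[cohort.regimen_id] = {"weight": float(w), **terms,
                                        "total": cohort_total}
        total += w * cohort_total
    return float(total), breakdown


# ---------------------------------------------------------------------------
# genetic algorithm
# ---------------------------------------------------------------------------

@dataclass
class VPop:
    """One calibrated virtual population (members are pool positions)."""

    member_pos: np.ndarray
    member_ids: np.ndarray         # candidate-table index labels
    objective: float
    breakdown: dict
    seed: int
    history: np.ndarray            # best objective per generation

    @property
    def size(self) -> int:
        return self.member_pos.size


def genetic_select(pool: PlausiblePool, targets: synthetic.CalibrationTargets,
                   size: int = 120, ga_opts: dict | None = None,
                   seed: int = 0) -> VPop:
    """Fixed-cardinality subset selection by genetic algorithm.

    Tournament selection, uniform crossover with cardinality repair, random
    member-swap mutation and elitism; fitness reuses the simulation caches,
    so no ODE is solved here.  Deterministic given (pool, targets, seed).
    """
    n_pool = len(pool)
    if n_pool < size:
        raise ValueError(f"pool ({n_pool}) smaller than VPop size ({size})")
    opts = dict(DEFAULT_GA_OPTS)
    if ga_opts:
        opts.update(ga_opts)
    rng = np.random.default_rng(seed)

    if n_pool == size:
        members = np.arange(n_pool)
        obj, br = objective(members, targets, pool)
        return VPop(member_pos=members,
                    member_ids=pool.candidates.index.values[members],
                    objective=obj, breakdown=br, seed=seed,
                    history=np.array([obj]))

    def fitness(ind):
        return objective(ind, targets, pool)[0]

    popn = [np.sort(rng.choice(n_pool, size=size, replace=False))
            for _ in range(opts["population"])]
    fits = np.array([fitness(ind) for ind in popn])
    history = []

    for _gen in range(opts["generations"]):
        order = np.argsort(fits)
        history.append(fits[order[0]])
        elite = [popn[i].copy() for i in order[:opts["elitism"]]]
        children = list(elite)
        while len(children) < opts["population"]:
            a = _tournament(popn, fits, opts["tournament"], rng)
            b = _tournament(popn, fits, opts["tournament"], rng)
            if rng.random() < opts["crossover_rate"]:
                child = _crossover(a, b, size, rng)
            else:
                child = a.copy()
            _mutate(child, n_pool, opts["mutation_swaps"], rng)
            children.append(np.sort(child))
        popn = children
        fits = np.array([fitness(ind) for ind in popn])

    best = int(np.argmin(fits))
    history.append(fits[best])
    members = popn[best]
    obj, br = objective(members, targets, pool)
    return VPop(member_pos=members,
                member_ids=pool.candidates.index.values[members],
                objective=obj, breakdown=br, seed=seed,
                history=np.array(history))


def _tournament(popn, fits, k, rng):
    idx = rng.choice(len(popn), size=k, replace=False)
    return popn[idx[np.argmin(fits[idx])]]


def _crossover(a, b, size, rng):
    common = np.intersect1d(a, b)
    rest = np.setdiff1d(np.union1d(a, b), common)
    need = size - common.size
    pick = rng.choice(rest, size=need, replace=False) if need else rest[:0]
    return np.concatenate([common, pick])


def _mutate(child, n_pool, n_swaps, rng):
    member_set = set(child.tolist())
    for _ in range(n_swaps):
        out_pos = rng.integers(child.size)
        new = int(rng.integers(n_pool))
        while new in member_set:
            new = int(rng.integers(n_pool))
        member_set.discard(int(child[out_pos]))
        member_set.add(new)
        child[out_pos] = new


def calibrate_vpops(pool: PlausiblePool, targets: synthetic.CalibrationTargets,
                    k: int = 10, size: int = 120,
                    seeds=None, ga_opts: dict | None = None) -> list[VPop]:
    """Select ``k`` VPops with distinct GA seeds."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if seeds is None:
        seeds = range(k)
    seeds = list(seeds)
    if len(seeds) != k:
        raise ValueError("need one seed per VPop")
    return [genetic_select(pool, targets, size=size, ga_opts=ga_opts, seed=s)
            for s in seeds]


def membership_overlap(vpops: list[VPop]) -> np.ndarray:
    """Pairwise |intersection| / size matrix across VPops."""
    k = len(vpops)
    out = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            inter = np.intersect1d(vpops[i].member_ids, vpops[j].member_ids)
            out[i, j] = out[j, i] = inter.size / vpops[i].size
    return out


def ks_bias_table(pool: PlausiblePool, vpop: VPop) -> pd.DataFrame:
    """Kolmogorov-Smirnov distance pool-vs-VPop for each varied parameter.

    A small distance indicates selection did not distort the plausible
    parameter distributions.
    """
    rows = []
    sel = pool.candidates.iloc[vpop.member_pos]
    for name in _VARIED:
        ks = stats.ks_2samp(pool.candidates[name], sel[name])
        rows.append((name, float(ks.statistic), float(ks.pvalue)))
    return pd.DataFrame(rows, columns=["parameter", "ks_distance", "p_value"]
                        ).set_index("parameter")


# ---------------------------------------------------------------------------
# model/results wrappers
# ---------------------------------------------------------------------------

class VPopCalibration:
    """Calibration model: a plausible pool fitted to cohort-level targets."""

    def __init__(self, pool: PlausiblePool,
                 targets: synthetic.CalibrationTargets):
        self.pool = pool
        self.targets = targets

    @classmethod
    def from_sampling(cls, targets: synthetic.CalibrationTargets,
                      n_candidates: int = 10_000,
                      bounds: tuple[float, float] = DOUBLING_BOUNDS,
                      seed: int = 0, horizon: float | None = None,
                      base_params: PatientParameters | None = None,
                      solver_opts: dict | None = None) -> "VPopCalibration":
        cand = sample_trial_patients(n_candidates, seed=seed)
        pool = plausibility_filter(cand, bounds=bounds,
                                   regimen_ids=tuple(targets.regimen_ids),
                                   base_params=base_params, horizon=horizon,
                                   solver_opts=solver_opts)
        return cls(pool, targets)

    def fit(self, size: int = 120, n_vpops: int = 10, seed: int = 0,
            ga_opts: dict | None = None) -> "VPopCalibrationResults":
        seeds = [seed + i for i in range(n_vpops)]
        vpops = calibrate_vpops(self.pool, self.targets, k=n_vpops, size=size,
                                seeds=seeds, ga_opts=ga_opts)
        return VPopCalibrationResults(self, vpops)


class VPopCalibrationResults:
    """Selected VPops with their objectives and diagnostics."""

    def __init__(self, model: VPopCalibration, vpops: list[VPop]):
        self.model = model
        self.vpops = vpops

    @property
    def best(self) -> VPop:
        return min(self.vpops, key=lambda v: v.objective)

    def brr(self, regimen_id: str, stratum: str = "all",
            vpop: VPop | None = None) -> tuple[float, tuple[float, float], int]:
        """Stratified response rate of a selected VPop under a cached regimen."""
        pool = self.model.pool
        cache = pool.cache(regimen_id)
        members = (vpop or self.best).member_pos
        calls = [resp.ResponseCall(
            is_biochemical_responder=bool(cache.responder[i]),
            bor=float(cache.bor[i]), depth=[], pd_day=None,
            persistent_responder=bool(cache.persistent[i]),
            high_sbcma=bool(cache.high_sbcma[i])) for i in members]
        return resp.brr(calls, stratum=stratum)

    def overlap(self) -> np.ndarray:
        return membership_overlap(self.vpops)

    def bias_check(self, vpop: VPop | None = None) -> pd.DataFrame:
        return ks_bias_table(self.model.pool, vpop or self.best)

    def summary(self) -> str:
        lines = ["Virtual-population calibration",
                 "=" * 46,
                 f"plausible pool size: {len(self.model.pool)}",
                 f"doubling-time bounds: {self.model.pool.bounds} days",
                 f"VPops selected: {len(self.vpops)} "
                 f"(size {self.vpops[0].size})",
                 ""]
        for v in self.vpops:
            lines.append(f"  seed {v.seed:>4d}  objective {v.objective:.6f}")
        lines.append("")
        rid = self.model.targets.cohorts[0].regimen_id
        for stratum in ("low", "high", "all"):
            rate, (lo, hi), n = self.brr(rid, stratum)
            lines.append(f"best VPop BRR[{stratum:>4s}] @ {rid}: "
                         f"{100 * rate:5.1f}%  (95% CI {100 * lo:.1f}-"
                         f"{100 * hi:.1f}, n={n})")
        return "\n".join(lines)
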