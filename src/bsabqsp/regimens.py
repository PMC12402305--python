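"""Dosing schedules: presets, priming step-ups, and adaptive frequency switching.

Doses are subcutaneous boluses in mg.  A treatment cycle is 28 days; QW,
Q2W and Q4W denote 7-, 14- and 28-day dosing intervals.  The clinical
de-escalation rule switches a confirmed responder from QW to Q2W no earlier
than cycle 7 (week 25), optionally stepping down again to Q4W at cycle 13.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .params import InitialState, PatientParameters

CYCLE_DAYS = 28
#: reference body weight (kg) tying the fixed 76 mg dose to 1000 ug/kg
REFERENCE_WEIGHT_KG = 76.0


def ugkg_to_mg(dose_ugkg: float, ref_weight_kg: float = REFERENCE_WEIGHT_KG) -> float:
    """Weight-based to fixed-dose conversion (unrounded)."""
    if dose_ugkg <= 0 or ref_weight_kg <= 0:
        raise ValueError("dose and weight must be positive")
    return dose_ugkg * ref_weight_kg / 1000.0


@dataclass(frozen=True)
class DoseEvent:
    time: float          # day
    amount: float        # mg
    route: str = "subcutaneous"

    def __post_init__(self):
        if self.time < 0:
            raise ValueError("dose time must be >= 0")
        if self.amount <= 0:
            raise ValueError("dose amount must be > 0")


@dataclass(frozen=True)
class SwitchRule:
    """Adaptive de-escalation of dosing frequency after confirmed response."""

    earliest_cycle: int = 7          # first eligible cycle (week 25)
    depth: str = "PR"                # "PR" (>=50% decrease) or "VGPR" (>=90%)
    confirm_n: int = 2               # consecutive assessments required
    post_interval: int = 14          # days between doses after the switch
    second_switch_cycle: int | None = None   # e.g. 13 -> Q4W
    second_interval: int = 28

    def __post_init__(self):
        if self.depth not in ("PR", "VGPR"):
            raise ValueError("depth must be 'PR' or 'VGPR'")

    @property
    def depth_threshold(self) -> float:
        """Required percent change from baseline (negative)."""
        return -50.0 if self.depth == "PR" else -90.0

    @property
    def earliest_day(self) -> float:
        """First eligible day: cycle ``earliest_cycle`` day 1."""
        return (self.earliest_cycle - 1) * CYCLE_DAYS + 1

    @property
    def second_switch_day(self) -> float | None:
        if self.second_switch_cycle is None:
            return None
        return (self.second_switch_cycle - 1) * CYCLE_DAYS + 1


@dataclass(frozen=True)
class Regimen:
    """Priming step-ups followed by a fixed-interval maintenance schedule."""

    priming: tuple[DoseEvent, ...] = ()
    maintenance_dose: float = 76.0          # mg
    interval: int = 7                       # days: 7, 14 or 28
    maintenance_start: float = 1.0          # day of first maintenance dose
    switch_rule: SwitchRule | None = None
    name: str = ""

    def __post_init__(self):
        if self.interval not in (7, 14, 28):
            raise ValueError("interval must be 7, 14 or 28 days")
        times = [e.time for e in self.priming] + [self.maintenance_start]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("dose events must be strictly increasing in time")
        if self.maintenance_dose <= 0:
            raise ValueError("maintenance dose must be > 0")

    @property
    def fractionated(self) -> bool:
        """True when the regimen opens with priming step-up doses."""
        return len(self.priming) > 0

    def events_until(self, horizon: float) -> list[DoseEvent]:
        ev = [e for e in self.priming if e.time <= horizon]
        t = self.maintenance_start
        while t <= horizon:
            ev.append(DoseEvent(t, self.maintenance_dose))
            t += self.interval
        return ev

    def with_switch_rule(self, rule: SwitchRule | None) -> "Regimen":
        return replace(self, switch_rule=rule)


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

def _flat(dose_mg: float, interval: int, name: str) -> Regimen:
    return Regimen(maintenance_dose=dose_mg, interval=interval,
                   maintenance_start=1.0, name=name)


def two_step_priming(maintenance_dose: float = 76.0, interval: int = 7,
                     name: str = "two_step_priming_76qw") -> Regimen:
    """12 mg day 1, 32 mg day 4, maintenance from day 8."""
    return Regimen(priming=(DoseEvent(1, 12.0), DoseEvent(4, 32.0)),
                   maintenance_dose=maintenance_dose, interval=interval,
                   maintenance_start=8.0, name=name)


def _build_presets() -> dict:
    """Load the shipped preset table (data/regimen_presets.yaml)."""
    from importlib import resources

    import yaml

    text = resources.files("bsabqsp.data").joinpath(
        "regimen_presets.yaml").read_text()
    raw = yaml.safe_load(text)
    presets = {}
    for name, spec in raw.items():
        priming = tuple(DoseEvent(float(e["time"]), float(e["amount"]))
                        for e in spec.get("priming", []))
        presets[name] = Regimen(
            priming=priming,
            maintenance_dose=float(spec["maintenance_dose"]),
            interval=int(spec["interval"]),
            maintenance_start=float(spec["maintenance_start"]),
            name=name)
    return presets


PRESETS = _build_presets()


def preset_regimen(name: str) -> Regimen:
    """Look up a documented preset regimen by id."""
    try:
        return PRESETS[name]
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; available: "
                       f"{sorted(PRESETS)}") from None


def primed(dose_mg: float, interval: int = 7) -> Regimen:
    """Two-step priming followed by ``dose_mg`` every ``interval`` days."""
    return two_step_priming(maintenance_dose=dose_mg, interval=interval,
                            name=f"primed_{dose_mg:g}_q{interval}d")


def assessment_days(regimen: Regimen, horizon: float) -> np.ndarray:
    """Tumor-assessment schedule: every 4 weeks under fractionated
    (priming) regimens, every 3 weeks otherwise."""
    step = 28.0 if regimen.fractionated else 21.0
    return np.arange(step, horizon + 1e-9, step)


# ---------------------------------------------------------------------------
# adaptive simulation
# ---------------------------------------------------------------------------

def simulate_adaptive(params: PatientParameters, init: InitialState,
                      regimen: Regimen, horizon: float,
                      assessor=None, solver_opts: dict | None = None,
                      dropout_on_pd: bool = False):
    """Simulate in assessment-interval chunks with conditional switching.

    At each assessment from the rule's earliest cycle onward, the interim
    integrated-paraprotein track is scored (``assessor`` defaults to the
    percent-change-plus-confirmation logic of :mod:`bsabqsp.response`); once
    the required depth is confirmed at two consecutive assessments the
    dosing interval changes for all subsequent doses.  Deterministic.

    Returns ``(SimulationResult, switch_log)`` where ``switch_log`` is a
    list of ``(day, new_interval)``.  With ``dropout_on_pd`` the simulation
    stops at the first progression assessment and the result carries
    ``dropout_day``.
    """
    from .kinetics import PatientModel
    from .params import IDX, assemble_state
    from . import response as resp

    model = PatientModel(params, init, solver_opts)
    rule = regimen.switch_rule
    days = assessment_days(regimen, horizon)
    bounds = np.unique(np.concatenate([days, [horizon]]))

    marker = resp.select_integrated_paraprotein(init.M0, init.F0)
    if marker is None:
        raise ValueError("patient excluded: no measurable paraprotein")
    baseline = init.M0 if marker == "mprotein" else init.F0

    # expand the full no-switch schedule once, then retime on switch
    max_events = regimen.events_until(horizon)
    dose_times = [e.time for e in max_events]
    dose_amounts = [e.amount for e in max_events]
    t_first = dose_times[0] if dose_times else np.inf

    y = assemble_state(model.params, init)
    t_cur = 0.0
    chunks = []
    pct = []           # percent change at each past assessment
    assess_log = []
    switch_log: list[tuple[float, int]] = []
    interval = regimen.interval
    switched = False
    second_done = False
    dropout_day = None

    def _doses_in(a, b):
        return [(t, mg) for t, mg in zip(dose_times, dose_amounts)
                if a <= t < b]

    i_dose = 0  # index of first not-yet-given dose
    for b in bounds:
        seg_events = []
        while i_dose < len(dose_times) and dose_times[i_dose] < b:
            seg_events.append((dose_times[i_dose], dose_amounts[i_dose]))
            i_dose += 1
        res = model.simulate(seg_events, horizon=b, y0=y, t0=t_cur,
                             t_first_dose=t_first,
                             check_conservation=False)
        chunks.append(res)
        y = res.y[:, -1].copy()
        t_cur = b
        if b not in days:
            continue
        value = float(y[IDX[marker]])
        pct.append((value / baseline - 1.0) * 100.0)
        assess_log.append(b)

        if dropout_on_pd:
            values = baseline * (1.0 + np.asarray(pct) / 100.0)
            track = resp.ParaproteinTrack(
                patient_id="adaptive", baseline_M=init.M0, baseline_F=init.F0,
                baseline_sbcma=init.sbcma0, marker=marker, baseline=baseline,
                times=np.asarray(assess_log), values=values)
            pd_day = resp.detect_pd(track)
            if pd_day is not None:
                dropout_day = float(pd_day)
                break

        if rule is None:
            continue
        # second de-escalation step (Q2W -> Q4W) from its eligible day
        if (switched and not second_done and rule.second_switch_day is not None
                and b >= rule.second_switch_day):
            interval = rule.second_interval
            dose_times, dose_amounts = _retime(dose_times, dose_amounts,
                                               i_dose, interval)
            switch_log.append((b, interval))
            second_done = True
            continue
        if switched or b < rule.earliest_day:
            continue
        if len(pct) >= rule.confirm_n and all(
                p <= rule.depth_threshold for p in pct[-rule.confirm_n:]):
            interval = rule.post_interval
            dose_times, dose_amounts = _retime(dose_times, dose_amounts,
                                               i_dose, interval)
            switch_log.append((b, interval))
            switched = True

    result = _stitch(chunks, model, init,
                     dose_times[:i_dose], dose_amounts[:i_dose])
    result.dropout_day = dropout_day
    return result, switch_log


def _retime(dose_times, dose_amounts, i_next, interval):
    """Re-space all not-yet-given doses to the new interval."""
    if i_next >= len(dose_times):
        return dose_times, dose_amounts
    new_times = list(dose_times[:i_next])
    t = (new_times[-1] if i_next > 0 else dose_times[i_next] - interval)
    for _ in range(i_next, len(dose_times)):
        t += interval
        new_times.append(t)
    return new_times, list(dose_amounts)


def _stitch(chunks, model, init, dose_times, dose_amounts):
    from .kinetics import SimulationResult
    t = np.concatenate([c.t for c in chunks])
    y = np.concatenate([c.y for c in chunks], axis=1)
    t, keep = np.unique(t, return_index=True)
    return SimulationResult(
        t=t, y=y[:, keep], params=model.params, init=init,
        dose_times=np.asarray(dose_times, dtype=float),
        dose_amounts_mg=np.asarray(dose_amounts, dtype=float))
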