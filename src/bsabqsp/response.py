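"""IMWG-derived biochemical response scoring.

Response is scored on an "integrated paraprotein": serum M-protein when it
is measurable at baseline (>= 0.5 g/dL), otherwise serum free light chain
(FLC).  A biochemical responder shows a >=50% decrease from baseline
sustained over two consecutive assessments; VGPR depth is a >=90% decrease;
progressive disease (PD) is a >=25% increase from the running nadir
(baseline included).  The absolute-increase clause of the clinical PD
definition is deliberately omitted: simulated PD uses the relative rule
alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from statsmodels.stats.proportion import proportion_confint

#: minimum baseline M-protein (g/dL) for measurability
MPROTEIN_MEASURABLE = 0.5
#: minimum baseline FLC (mg/L) treated as measurable for synthetic patients
FLC_MEASURABLE = 10.0
#: assessment day by which a confirmed response counts as "persistent"
#: (first assessment at/after cycle 7 day 1 under 28-day cadence)
PERSISTENT_BY_DAY = 196.0


class InsufficientDataError(ValueError):
    pass


def select_integrated_paraprotein(baseline_M: float, baseline_FLC: float,
                                  flc_measurable: bool | None = None
                                  ) -> str | None:
    """Marker choice: ``"mprotein"``, ``"flc"``, or ``None`` (excluded)."""
    if baseline_M < 0 or baseline_FLC < 0:
        raise ValueError("baselines must be non-negative")
    if baseline_M >= MPROTEIN_MEASURABLE:
        return "mprotein"
    if flc_measurable is None:
        flc_measurable = baseline_FLC >= FLC_MEASURABLE
    return "flc" if flc_measurable else None


@dataclass
class ParaproteinTrack:
    """Assessment-time integrated-paraprotein series for one patient."""

    patient_id: str
    baseline_M: float            # g/dL
    baseline_F: float            # mg/L
    baseline_sbcma: float        # ng/mL
    marker: str                  # "mprotein" or "flc"
    baseline: float              # baseline value of the chosen marker
    times: np.ndarray            # assessment days, strictly increasing
    values: np.ndarray           # marker values at assessments
    dropout_day: float | None = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.size != self.values.size:
            raise ValueError("times and values must align")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("assessments must be strictly increasing")
        if self.baseline <= 0:
            raise ValueError("baseline of the chosen marker must be > 0")

    @property
    def pct_change(self) -> np.ndarray:
        return (self.values / self.baseline - 1.0) * 100.0


@dataclass
class ResponseCall:
    is_biochemical_responder: bool
    bor: float                      # best % change from baseline (negative = shrinkage)
    depth: list[str]                # per-assessment: "VGPR", "PR" or "none"
    pd_day: float | None
    persistent_responder: bool
    confirmation_day: float | None = None
    high_sbcma: bool | None = None


def classify_response(track: ParaproteinTrack,
                      persistent_by_day: float = PERSISTENT_BY_DAY
                      ) -> ResponseCall:
    """Score a track: responder / BOR / per-assessment depth / persistence."""
    if track.times.size < 2:
        raise InsufficientDataError("need >= 2 assessments to classify")
    pct = track.pct_change
    depth = ["VGPR" if p <= -90.0 else ("PR" if p <= -50.0 else "none")
             for p in pct]
    confirmation_day = None
    for i in range(1, pct.size):
        if pct[i] <= -50.0 and pct[i - 1] <= -50.0:
            confirmation_day = float(track.times[i])
            break
    responder = confirmation_day is not None
    return ResponseCall(
        is_biochemical_responder=responder,
        bor=float(pct.min()),
        depth=depth,
        pd_day=detect_pd(track),
        persistent_responder=responder and confirmation_day <= persistent_by_day,
        confirmation_day=confirmation_day,
        high_sbcma=None,
    )


def detect_pd(track: ParaproteinTrack) -> float | None:
    """First assessment with a >=25% increase from the running nadir.

    The nadir runs over the baseline and all strictly earlier assessments;
    the boundary (exactly 1.25x nadir) is inclusive.
    """
    if track.times.size < 1:
        raise InsufficientDataError("need >= 1 assessment")
    nadir = track.baseline
    for t, v in zip(track.times, track.values):
        if v >= 1.25 * nadir:
            return float(t)
        nadir = min(nadir, v)
    return None


def brr(calls: list[ResponseCall], stratum: str = "all",
        alpha: float = 0.05) -> tuple[float, tuple[float, float], int]:
    """Biochemical response rate with a Wilson binomial interval.

    ``stratum`` filters on each call's ``high_sbcma`` flag: "all", "low"
    or "high".  Returns ``(rate, (lo, hi), n)``.
    """
    if stratum == "low":
        calls = [c for c in calls if c.high_sbcma is False]
    elif stratum == "high":
        calls = [c for c in calls if c.high_sbcma is True]
    elif stratum != "all":
        raise ValueError("stratum must be 'all', 'low' or 'high'")
    if not calls:
        raise ValueError(f"empty cohort for stratum {stratum!r}")
    k = sum(c.is_biochemical_responder for c in calls)
    n = len(calls)
    lo, hi = proportion_confint(k, n, alpha=alpha, method="wilson")
    return k / n, (float(lo), float(hi)), n


def bor_deciles(bors) -> np.ndarray:
    """Medians of 10 contiguous groups of BORs ranked in decreasing order.

    Accepts an array of BOR percent changes or a list of
    :class:`ResponseCall`; requires a cohort of at least 10.
    """
    arr = np.asarray([b.bor if isinstance(b, ResponseCall) else b
                      for b in bors], dtype=float)
    if arr.size < 10:
        raise ValueError("need >= 10 patients for decile profile")
    ranked = np.sort(arr)[::-1]
    return np.array([np.median(g) for g in np.array_split(ranked, 10)])


def track_from_simulation(result, assessment_times, patient_id: str = "p0",
                          dropout_day: float | None = None) -> ParaproteinTrack:
    """Build an assessment-time track from a simulated trajectory."""
    marker = select_integrated_paraprotein(result.init.M0, result.init.F0)
    if marker is None:
        raise ValueError("patient excluded: no measurable paraprotein")
    baseline = result.init.M0 if marker == "mprotein" else result.init.F0
    times = np.asarray(assessment_times, dtype=float)
    if dropout_day is not None:
        times = times[times <= dropout_day]
    return ParaproteinTrack(
        patient_id=patient_id, baseline_M=result.init.M0,
        baseline_F=result.init.F0, baseline_sbcma=result.init.sbcma0,
        marker=marker, baseline=baseline, times=times,
        values=result.values_at(marker, times), dropout_day=dropout_day)
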