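# bsabqsp

Quantitative systems pharmacology (QSP) of a BCMA-CD3 bispecific T-cell
engager (elranatamab-like) in relapsed/refractory multiple myeloma: a
mechanistic trimer-formation / tumor-kill ODE model, a virtual-population
calibration workflow, IMWG-derived biochemical response scoring, and the
virtual-trial analyses built on them — dose-response stratified by baseline
soluble BCMA (sBCMA), binding-ratio curve-shape taxonomy, dose-frequency
de-escalation after response, and biomarker-cutoff selection.

It is written for pharmacometricians and systems pharmacologists who want a
tested, reproducible reference implementation of the virtual-population
approach to bispecific-antibody dose/regimen questions, with every input
synthesized from documented distributions (no proprietary trial data).

## The model in brief

A bispecific antibody D binds membrane BCMA (B) on myeloma cells and CD3
(C) on T cells in the bone marrow by mass action,

    D + B <-> DB,   D + C <-> DC,   DB + C <-> T,   DC + B <-> T,

the trimer T forming with a cross-arm avidity efficiency chi. Soluble BCMA
competes for the BCMA arm in both plasma and marrow and clears with the
drug bound — a continuous drug sink. The efficacy driver is the
*effective binding ratio*

    theta = T / (B + DB + T),

trimers per BCMA receptor, and tumor cells die at

    k_max * theta^n / (alpha_kill^n + theta^n) * 1 / (1 + alpha_resis * t),

on top of logistic growth. theta is bell-shaped in exposure: scarce drug
forms few trimers, excess drug saturates both receptors into inactive
dimers. Myeloma cells secrete M-protein and free light chain — the serum
markers used to score partial response (>= 50% decline, confirmed), VGPR
(>= 90%), and progression (>= 25% rise from nadir). Trimer formation
releases IL-6 from a depletable pool, slowing T-cell egress from the
marrow.

Calibration selects virtual populations (VPops): sample ~10,000 candidate
parameterizations from uniform priors over nine varied parameters, keep
those with clinically sensible untreated doubling times, simulate each
survivor once per target regimen, then pick 120-member subsets by genetic
algorithm so cohort summaries (stratified biochemical response rates,
median paraprotein trajectory, best-response deciles) match the synthetic
calibration targets. See `docs/methods.md` for the full account.

## Worked example

```python
import numpy as np
from bsabqsp import PatientModel, two_step_priming, effective_binding_ratio
from bsabqsp.regimens import assessment_days
from bsabqsp.response import track_from_simulation, classify_response

model = PatientModel()                  # default virtual patient
regimen = two_step_priming()            # 12 mg d1, 32 mg d4, 76 mg QW from d8
result = model.simulate(regimen, horizon=168.0)

track = track_from_simulation(result, assessment_days(regimen, 168.0))
call = classify_response(track)
print(np.round(track.pct_change, 1))
print(call.is_biochemical_responder, call.bor, call.persistent_responder)
print(round(effective_binding_ratio(result, (0, 84)), 4))
```

prints

```
[-53.9 -81.7 -92.7 -97.1 -98.9 -99.5]
True -99.5 True
0.0044
```

— the default patient's M-protein falls 54% by the day-28 assessment and
more than 90% by day ~100 (a confirmed, persistent VGPR-depth responder;
BOR is the deepest change), and trimers occupy on average 0.44% of BCMA
receptors over the first three cycles. Cohort-level workflows follow the
same pattern around `VPopCalibration` (see `bsabqsp.vpop`), and a thin CLI
(`bsabqsp simulate | calibrate | threshold-scan | run-all`) wraps the
common entry points.

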