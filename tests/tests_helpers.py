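"""Small builders shared across test modules."""

import numpy as np

from bsabqsp.response import ParaproteinTrack


def make_track(values, baseline=100.0, step=28.0, **kw):
    values = np.asarray(values, dtype=float)
    fields = dict(patient_id="t", baseline_M=baseline, baseline_F=500.0,
                  baseline_sbcma=50.0, marker="mprotein", baseline=baseline,
                  times=step * np.arange(1, values.size + 1), values=values)
    fields.update(kw)
    return ParaproteinTrack(**fields)
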