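"""Published summary statistics used as worked-example inputs.

These are the printed group-level numbers from a large (N = 273) study of
timing performance, spatial suppression and psychometric intelligence in
young adults: inter-composite correlations of the intelligence test,
the correlation matrix of the four timing tasks, and the correlations of
the four motion-direction duration thresholds.  Raw individual-level data
for that study were never deposited, so these matrices are the only
re-analysable quantities; the rest of the package works on simulated
populations calibrated to the same effect sizes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: Sample size behind all printed correlation matrices.
N_SUBJECTS = 273

#: Timing-task labels: duration discrimination with empty / filled
#: intervals, temporal generalization (inverted dispersion index), rhythm
#: perception.
TIMING_TASKS = ["DDE", "DDF", "TG", "RP"]

#: Pearson correlations among the four timing tasks.
TIMING_CORR = pd.DataFrame(
    [[1.00, 0.36, 0.25, 0.26],
     [0.36, 1.00, 0.34, 0.17],
     [0.25, 0.34, 1.00, 0.16],
     [0.26, 0.17, 0.16, 1.00]],
    index=TIMING_TASKS, columns=TIMING_TASKS)

#: Intelligence-test composite labels (Berlin Intelligence Structure short
#: form): capacity, speed, memory.
BIS_COMPOSITES = ["capacity", "speed", "memory"]

#: Pearson correlations among the three intelligence composites
#: (capacity-speed .51, capacity-memory .46, memory-speed .39).
BIS_CORR = pd.DataFrame(
    [[1.00, 0.51, 0.46],
     [0.51, 1.00, 0.39],
     [0.46, 0.39, 1.00]],
    index=BIS_COMPOSITES, columns=BIS_COMPOSITES)

#: Stimulus sizes (degrees visual angle) of the motion task.
STIMULUS_SIZES = [1.8, 3.6, 5.4, 7.2]
THRESHOLD_VARS = [f"thr_{s:g}" for s in STIMULUS_SIZES]

#: Pearson correlations among the four duration thresholds.
THRESHOLD_CORR = pd.DataFrame(
    [[1.00, 0.83, 0.69, 0.63],
     [0.83, 1.00, 0.84, 0.76],
     [0.69, 0.84, 1.00, 0.88],
     [0.63, 0.76, 0.88, 1.00]],
    index=THRESHOLD_VARS, columns=THRESHOLD_VARS)

#: Correlations of the g-factor scores with thresholds, suppression index
#: and timing tasks (one row, same study).
G_CORR = pd.Series(
    {"thr_1.8": -0.17, "thr_3.6": -0.24, "thr_5.4": -0.23, "thr_7.2": -0.26,
     "SI": -0.17, "DDE": -0.24, "DDF": -0.20, "TG": -0.34, "RP": -0.24})

#: Small-sample correlations from an earlier three-size study (N = 47)
#: used in the confidence-interval reanalysis: g with the threshold for a
#: small (0.7 deg) and a large (6 deg) stimulus.
SMALL_SAMPLE_N = 47
SMALL_SAMPLE_R = {"small_stimulus": -0.213, "large_stimulus": 0.255}


def timing_corr() -> np.ndarray:
    return TIMING_CORR.to_numpy(dtype=float)


def bis_corr() -> np.ndarray:
    return BIS_CORR.to_numpy(dtype=float)


def threshold_corr() -> np.ndarray:
    return THRESHOLD_CORR.to_numpy(dtype=float)
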