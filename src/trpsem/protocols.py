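"""Complete task sessions and their reduction to per-subject measures.

Session layouts:

* motion task: 3 blocks x 4 stimulus sizes x 2 Bayesian-adaptive runs of
  22 trials each (6 threshold estimates per size); per size the highest and
  lowest estimates are discarded and the remaining four averaged; the
  suppression index is the largest-size minus smallest-size log threshold;
* duration discrimination (empty / filled variants): two interleaved
  32-trial weighted up-down series (comparison above / below the 50-ms
  standard) -> x.75 and x.25; difference limen DL = (x.75 - x.25)/2;
* temporal generalization: 8 blocks, standard (75 ms) twice per block and
  each of six alternatives once; the response-dispersion index is the
  relative "yes" frequency to the standard over the summed relative "yes"
  frequencies of all seven durations (inverted for analysis);
* rhythm perception: two interleaved 32-trial weighted up-down series on
  the deviant increment x (start 20 ms, -4 ms after correct / +12 ms after
  incorrect, equilibrium 75%); thresholds from the last 20 trials of each
  series, then averaged;
* intelligence test: 18 subtest raw scores are z-standardized and averaged
  into capacity / speed / memory composites (six subtests each).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from . import observers as obsmod
from .adaptive import Quest, QuestConfig, Staircase, interleave_series
from .observers import ObserverParams, TG_DURATIONS, TG_STANDARD

__all__ = ["run_spatial_suppression", "aggregate_estimates",
           "spatial_suppression_index", "run_duration_discrimination",
           "dispersion_index", "run_temporal_generalization",
           "run_rhythm_perception",
           "score_bis", "outlier_filter", "run_session", "run_battery",
           "MEASURE_COLUMNS", "OUTLIER_SCREEN_VARS"]

#: stable column order of the subject-by-measure table
MEASURE_COLUMNS = ["subject", "thr_1.8", "thr_3.6", "thr_5.4", "thr_7.2",
                   "si", "dl_empty", "dl_filled", "tg_raw", "tg_inverted",
                   "rp_threshold", "bis_capacity", "bis_speed", "bis_memory"]

#: variables screened by the 3-SD outlier rule (timing measures and the
#: smallest-size threshold; on all of them high = poor)
OUTLIER_SCREEN_VARS = ["dl_empty", "dl_filled", "tg_inverted",
                       "rp_threshold", "thr_1.8"]


# ---------------------------------------------------------------------------
# motion task
# ---------------------------------------------------------------------------

def aggregate_estimates(estimates) -> float:
    """Drop the single highest and lowest of six estimates, average the rest."""
    est = np.sort(np.asarray(estimates, dtype=float))
    if est.size < 6:
        raise ValueError(f"need at least 6 estimates, got {est.size}")
    return float(est[1:-1].mean())


def run_spatial_suppression(obs: ObserverParams, rng, *, n_blocks: int = 3,
                            estimates_per_block: int = 2,
                            trials_per_estimate: int = 22,
                            quest_config: QuestConfig | None = None) -> dict:
    """Full adaptive motion session; returns per-size thresholds (log10 ms).

    ``estimates[s]`` holds all n_blocks * estimates_per_block raw estimates
    for size s; ``thresholds`` the drop-min/max averages.
    """
    cfg = quest_config or QuestConfig()
    n_sizes = len(obs.mdd_log_threshold)
    estimates = [[] for _ in range(n_sizes)]
    trials = []
    for block in range(n_blocks):
        for size in range(n_sizes):
            for run in range(estimates_per_block):
                q = Quest(cfg)
                series_id = f"b{block + 1}s{size}r{run + 1}"
                for t in range(trials_per_estimate):
                    level = q.next_level()
                    correct = obsmod.respond_motion(obs, size, level, rng)
                    q.update(level, correct)
                    trials.append({"task": "motion", "series_id": series_id,
                                   "trial_index": t + 1, "level": level,
                                   "response_correct": correct})
                estimates[size].append(q.estimate())
    thresholds = np.array([aggregate_estimates(e) for e in estimates])
    return {"thresholds": thresholds, "estimates": estimates,
            "si": spatial_suppression_index(thresholds), "trials": trials}


def spatial_suppression_index(thresholds) -> float:
    """Largest-size minus smallest-size log10 threshold."""
    thr = np.asarray(thresholds, dtype=float)
    if thr.size != 4:
        raise ValueError("expected four per-size thresholds")
    return float(thr[-1] - thr[0])


# ---------------------------------------------------------------------------
# duration discrimination
# ---------------------------------------------------------------------------

def run_duration_discrimination(obs: ObserverParams, variant: str, rng, *,
                                standard_ms: float = 50.0,
                                initial_delta: float = 30.0) -> dict:
    """Two interleaved weighted up-down series -> (x.25, x.75, DL)."""
    if variant not in ("empty", "filled"):
        raise ValueError("variant must be 'empty' or 'filled'")
    # the shorter series keeps the comparison at least 1 ms long
    stair = {"longer": Staircase(initial_delta),
             "shorter": Staircase(initial_delta, ceiling=standard_ms - 1.0)}
    schedule = interleave_series(32, 32, rng)
    label = {"A": "longer", "B": "shorter"}
    trials = []
    for entry in schedule:
        series = label[entry["series"]]
        sc = stair[series]
        delta = sc.level
        comparison = standard_ms + delta if series == "longer" else standard_ms - delta
        correct = obsmod.respond_duration_discrimination(
            obs, comparison, rng, standard_ms=standard_ms, variant=variant)
        sc.record(correct)
        trials.append({"task": f"dd_{variant}", "series_id": series,
                       "trial_index": entry["series_trial"], "level": delta,
                       "response_correct": correct})
    x75 = standard_ms + stair["longer"].threshold()
    x25 = standard_ms - stair["shorter"].threshold()
    flags = [f"{s}_series_at_floor" for s, sc in stair.items()
             if any(lv <= sc.floor for lv, _ in sc.history[-20:])]
    return {"x25": x25, "x75": x75, "dl": (x75 - x25) / 2.0,
            "flags": flags, "trials": trials}


# ---------------------------------------------------------------------------
# temporal generalization
# ---------------------------------------------------------------------------

def dispersion_index(rel_freqs: dict[float, float],
                     standard: float = TG_STANDARD) -> float:
    """Relative "yes" frequency to the standard over the summed relative
    "yes" frequencies across all durations.  NaN when no "yes" at all."""
    total = float(sum(rel_freqs.values()))
    if total == 0.0:
        return float("nan")
    return float(rel_freqs[standard] / total)


def run_temporal_generalization(obs: ObserverParams, rng, *,
                                n_blocks: int = 8) -> dict:
    """Yes/no generalization session -> response-dispersion index.

    The standard is shown twice per block, every alternative once; relative
    "yes" frequencies are computed per duration over its own presentation
    count.  With no "yes" response at all the index is undefined and is set
    to 1/7, the value of a completely insensitive observer, and flagged.
    """
    durations, yes = [], []
    for _ in range(n_blocks):
        block = [TG_STANDARD] * 2 + [d for d in TG_DURATIONS if d != TG_STANDARD]
        rng.shuffle(block)
        for d in block:
            durations.append(d)
            yes.append(obsmod.respond_generalization(obs, d, rng))
    df = pd.DataFrame({"duration": durations, "yes": yes})
    rel = df.groupby("duration")["yes"].mean()
    raw = dispersion_index(rel.to_dict())
    flags = []
    if np.isnan(raw):
        flags.append("no_yes_responses")
        raw = 1.0 / 7.0  # value of a completely insensitive observer

    return {"tg_raw": raw, "tg_inverted": 1.0 - raw, "flags": flags,
            "trials": df}


# ---------------------------------------------------------------------------
# rhythm perception
# ---------------------------------------------------------------------------

def run_rhythm_perception(obs: ObserverParams, rng, *, initial_x: float = 20.0,
                          step_up: float = 12.0, step_down: float = 4.0) -> dict:
    """Two interleaved 32-trial series on the deviant increment x."""
    stair = {"third": Staircase(initial_x, steps=((step_up, step_down),),
                                phase_switch=(), floor=0.0),
             "fourth": Staircase(initial_x, steps=((step_up, step_down),),
                                 phase_switch=(), floor=0.0)}
    schedule = interleave_series(32, 32, rng)
    label = {"A": "third", "B": "fourth"}
    trials = []
    for entry in schedule:
        series = label[entry["series"]]
        sc = stair[series]
        x = sc.level
        correct = obsmod.respond_rhythm(obs, x, rng)
        sc.record(correct)
        trials.append({"task": "rp", "series_id": series,
                       "trial_index": entry["series_trial"], "level": x,
                       "response_correct": correct})
    per_series = {s: sc.threshold() for s, sc in stair.items()}
    return {"rp_threshold": float(np.mean(list(per_series.values()))),
            "series_thresholds": per_series, "trials": trials}


# ---------------------------------------------------------------------------
# intelligence scoring
# ---------------------------------------------------------------------------

def score_bis(subtests: pd.DataFrame, mapping: dict[str, list[str]]
              ) -> pd.DataFrame:
    """z-standardize 18 subtests columnwise, average each 6-subtest bundle."""
    out = {}
    for comp, cols in mapping.items():
        if len(cols) != 6:
            raise ValueError(f"composite {comp!r} needs 6 subtests, got {len(cols)}")
        zs = []
        for c in cols:
            x = subtests[c].to_numpy(dtype=float)
            sd = x.std(ddof=1)
            if sd == 0:
                raise ValueError(f"subtest {c!r} has zero variance; "
                                 "z-standardization undefined")
            zs.append((x - x.mean()) / sd)
        out[f"bis_{comp}"] = np.mean(zs, axis=0)
    df = pd.DataFrame(out)
    if "subject" in subtests:
        df.insert(0, "subject", subtests["subject"].to_numpy())
    return df


# ---------------------------------------------------------------------------
# outlier screening
# ---------------------------------------------------------------------------

def outlier_filter(measures: pd.DataFrame, variables=None, *,
                   sd_limit: float = 3.0, two_sided: bool = False
                   ) -> tuple[pd.DataFrame, list[dict]]:
    """One-pass 3-SD rule: drop subjects exceeding mean + 3 SD (one-sided,
    high = poor) on any screened variable; mean/SD from the pre-filter
    sample.  Returns (filtered table, removal log)."""
    variables = OUTLIER_SCREEN_VARS if variables is None else variables
    if len(measures) < 3:
        warnings.warn("fewer than 3 subjects: outlier filter skipped",
                      stacklevel=2)
        return measures.copy(), []
    log, drop = [], np.zeros(len(measures), dtype=bool)
    for var in variables:
        x = measures[var].to_numpy(dtype=float)
        mu, sd = x.mean(), x.std(ddof=1)
        hi = x > mu + sd_limit * sd
        lo = x < mu - sd_limit * sd if two_sided else np.zeros_like(hi)
        for idx in np.flatnonzero(hi | lo):
            log.append({"subject": int(measures.iloc[idx]["subject"]),
                        "variable": var, "value": float(x[idx]),
                        "mean": float(mu), "sd": float(sd)})
        drop |= hi | lo
    return measures.loc[~drop].reset_index(drop=True), log


# ---------------------------------------------------------------------------
# full battery
# ---------------------------------------------------------------------------

def run_session(obs: ObserverParams, rng, *, quest_config=None,
                collect_trials: bool = False) -> dict:
    """All experimental tasks for one observer -> measure dict."""
    ss = run_spatial_suppression(obs, rng, quest_config=quest_config)
    dde = run_duration_discrimination(obs, "empty", rng)
    ddf = run_duration_discrimination(obs, "filled", rng)
    tg = run_temporal_generalization(obs, rng)
    rp = run_rhythm_perception(obs, rng)
    row = {"thr_1.8": ss["thresholds"][0], "thr_3.6": ss["thresholds"][1],
           "thr_5.4": ss["thresholds"][2], "thr_7.2": ss["thresholds"][3],
           "si": ss["si"], "dl_empty": dde["dl"], "dl_filled": ddf["dl"],
           "tg_raw": tg["tg_raw"], "tg_inverted": tg["tg_inverted"],
           "rp_threshold": rp["rp_threshold"]}
    flags = dde["flags"] + ddf["flags"] + tg["flags"]
    out = {"measures": row, "flags": flags}
    if collect_trials:
        rows = ss["trials"] + dde["trials"] + ddf["trials"] + rp["trials"]
        out["trials"] = rows
    return out


def run_battery(observers, spec, latents: pd.DataFrame, seed: int, *,
                quest_config=None, collect_trials: bool = False
                ) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Run every observer through all tasks plus the intelligence test.

    Returns (measures table in MEASURE_COLUMNS order, trial log or None).
    Each subject gets an independent child RNG stream, so results are
    reproducible given (observers, seed) regardless of ordering.
    """
    root = np.random.SeedSequence(seed)
    streams = root.spawn(len(observers) + 1)
    rows, all_trials = [], []
    for obs, ss_stream in zip(observers, streams[:-1]):
        rng = np.random.default_rng(ss_stream)
        res = run_session(obs, rng, quest_config=quest_config,
                          collect_trials=collect_trials)
        row = {"subject": obs.subject, **res["measures"]}
        rows.append(row)
        if collect_trials:
            for tr in res["trials"]:
                all_trials.append({"subject_id": obs.subject, **tr})
    measures = pd.DataFrame(rows)
    bis_rng = np.random.default_rng(streams[-1])
    subtests, mapping = obsmod.generate_bis_subtests(spec, latents, bis_rng)
    composites = score_bis(subtests, mapping)
    measures = measures.merge(composites, on="subject")
    measures = measures[MEASURE_COLUMNS]
    trials = pd.DataFrame(all_trials) if collect_trials else None
    return measures, trials
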