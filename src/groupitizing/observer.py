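"""Synthetic observers for the numerosity-estimation dual-task design.

The generator emits trial tables with the statistical structure the
analysis pipeline assumes:

* scalar variability — verbal numerosity estimates are integers whose
  standard deviation grows proportionally with numerosity (constant Weber
  fraction), with condition-specific Weber fractions for the single task
  and each dual task;
* a small proportional estimation bias shared across conditions;
* log-normal between-participant spread of Weber fractions, plus a
  per-participant susceptibility to each dual-task type (shared by the
  grouped and ungrouped session halves of that task);
* rare lapse trials carrying a wild response and an out-of-range response
  time, so the 3-SD outlier filter has something to find;
* Bernoulli concurrent-task correctness on dual-task trials.

The full design per participant: a single-task session (4 grouped +
4 ungrouped blocks of 36 trials), a single task with ignored distractors
(grouped only, 4 blocks of 36), and three dual-task sessions (auditory,
visuo-spatial, arithmetic; 8 blocks of 36 each) — 1296 trials in total.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri

from .stimuli import configuration_table

__all__ = [
    "SimParams",
    "default_params",
    "simulate_response",
    "simulate_experiment",
    "TASKS",
    "SINGLE_TASKS",
    "DUAL_TASKS",
    "ARRANGEMENTS",
]

SINGLE_TASKS = ("single", "single_distractor")
DUAL_TASKS = ("aud_dt", "vsp_dt", "arithm_dt")
TASKS = SINGLE_TASKS + DUAL_TASKS
ARRANGEMENTS = ("grouped", "ungrouped")

# Variance added by rounding a continuous estimate to the integer lattice.
_ROUNDING_VAR = 1.0 / 12.0


class SimParamError(ValueError):
    """Invalid simulator parameter."""


@dataclass(frozen=True)
class SimParams:
    """Generating parameters of the synthetic observer population.

    Weber fractions and fold increases default to the group means the
    analysis is expected to recover: single-task Wf 0.09 (grouped) and
    0.11 (ungrouped); dual-task Wfs are the single-task values times the
    per-task fold increase (grouped 1.6/2.3/2.0, ungrouped 1.3/1.5/1.3 for
    the auditory, visuo-spatial and arithmetic tasks respectively).

    ``bias`` is the proportional over-estimation of the mean response
    (+7% puts mean perceived numerosity over 5-8 near 6.96).
    ``lapse_rate`` is the probability of a wild trial (uniform response in
    1..3N with an out-of-range response time).

    Between-participant heterogeneity: each participant draws one mean-one
    log-normal precision factor per *task family* (single tasks, and each
    dual task) with log-scale SD ``between_participant_sd``; the factors
    correlate ``participant_corr`` across families (a shared-ability
    component plus a family-specific susceptibility). A factor applies to
    both arrangements of its family, and the two single-task sessions share
    one factor. Mean-one log-normals preserve the condition means, and the
    family-specific part keeps the visuo-spatial and arithmetic dual tasks
    only partially correlated — the covariance structure the two-component
    interference analysis probes.

    Response times are log-normal (log-ms location/scale)
    truncated at ``rt_truncation`` SDs — a paced experiment produces no
    extreme RTs except on lapse trials, which are shifted by
    ``lapse_rt_shift`` log units.
    """

    wf_single_grouped: float = 0.09
    wf_single_ungrouped: float = 0.11
    fold_increase: dict = field(default_factory=lambda: {
        ("grouped", "aud_dt"): 1.6,
        ("grouped", "vsp_dt"): 2.3,
        ("grouped", "arithm_dt"): 2.0,
        ("ungrouped", "aud_dt"): 1.3,
        ("ungrouped", "vsp_dt"): 1.5,
        ("ungrouped", "arithm_dt"): 1.3,
    })
    bias: float = 0.07
    lapse_rate: float = 0.006
    between_participant_sd: float = 0.3
    participant_corr: float = 0.5
    concurrent_accuracy: dict = field(default_factory=lambda: {
        "aud_dt": 0.82, "vsp_dt": 0.94, "arithm_dt": 0.96,
    })
    rt_location: float = 6.6   # log ms, exp(6.6) ~ 735 ms
    rt_scale: float = 0.15
    rt_truncation: float = 2.3
    lapse_rt_shift: float = 1.2
    blocks_per_arrangement: int = 4
    trials_per_block: int = 36

    def __post_init__(self) -> None:
        if self.wf_single_grouped <= 0 or self.wf_single_ungrouped <= 0:
            raise SimParamError("single-task Weber fractions must be > 0")
        if any(v <= 0 for v in self.fold_increase.values()):
            raise SimParamError("fold increases must be > 0")
        if not 0 <= self.lapse_rate < 0.05:
            raise SimParamError("lapse_rate must be in [0, 0.05)")
        if not all(0 <= v <= 1 for v in self.concurrent_accuracy.values()):
            raise SimParamError("concurrent accuracies must be probabilities")
        if self.between_participant_sd < 0:
            raise SimParamError("between_participant_sd must be >= 0")
        if not 0 <= self.participant_corr <= 1:
            raise SimParamError("participant_corr must be in [0, 1]")
        if self.blocks_per_arrangement < 1 or self.trials_per_block < 1:
            raise SimParamError("design sizes must be >= 1")

    def generating_wf(self, task: str, arrangement: str) -> float:
        """Condition-mean Weber fraction for a task x arrangement cell."""
        base = (self.wf_single_grouped if arrangement == "grouped"
                else self.wf_single_ungrouped)
        if task in SINGLE_TASKS:
            return base
        if task in DUAL_TASKS:
            return base * self.fold_increase[(arrangement, task)]
        raise SimParamError(f"unknown task {task!r}")


def default_params() -> SimParams:
    """The calibrated defaults (see :class:`SimParams`)."""
    return SimParams()


def simulate_response(N, wf, bias: float = 0.0, lapse_rate: float = 0.0,
                      rng: np.random.Generator | None = None):
    """Draw integer numerosity estimates under scalar variability.

    The continuous internal estimate is ``N * (1 + bias) + eps`` with
    ``eps ~ Normal(0, sigma)``; the verbal response is that estimate rounded
    to the nearest integer and clamped at 1. ``sigma`` is chosen as
    ``sqrt((wf * N)^2 - 1/12)`` so that, after integer rounding, the sample
    SD of responses equals ``wf * N`` (rounding adds ~1/12 variance); when
    ``wf * N`` is below the rounding floor sigma collapses to 0.  With
    probability ``lapse_rate`` the response is instead uniform on 1..3N.

    ``N`` and ``wf`` may be scalars or equal-shaped arrays.
    """
    if np.any(np.asarray(wf) < 0):
        raise SimParamError("wf must be >= 0")
    if not 0 <= lapse_rate < 1:
        raise SimParamError("lapse_rate must be in [0, 1)")
    if rng is None:
        rng = np.random.default_rng()
    N = np.asarray(N)
    if np.any(N < 1):
        raise SimParamError("N must be >= 1")
    scalar = N.ndim == 0
    N = np.atleast_1d(N).astype(float)
    wf = np.broadcast_to(np.asarray(wf, dtype=float), N.shape)
    sigma = np.sqrt(np.maximum((wf * N) ** 2 - _ROUNDING_VAR, 0.0))
    est = N * (1.0 + bias) + rng.normal(0.0, 1.0, size=N.shape) * sigma
    resp = np.maximum(np.rint(est), 1).astype(int)
    if lapse_rate > 0:
        lapse = rng.random(N.shape) < lapse_rate
        wild = rng.integers(1, (3 * N).astype(int) + 1)
        resp = np.where(lapse, wild, resp)
    return int(resp[0]) if scalar else resp


def _session_blocks(params: SimParams) -> list[tuple[str, str]]:
    """(task, arrangement) per block, in session order."""
    b = params.blocks_per_arrangement
    blocks: list[tuple[str, str]] = []
    blocks += [("single", "grouped")] * b + [("single", "ungrouped")] * b
    blocks += [("single_distractor", "grouped")] * b
    for task in DUAL_TASKS:
        blocks += [(task, "grouped")] * b + [(task, "ungrouped")] * b
    return blocks


def _truncated_normal(rng: np.random.Generator, size: int, bound: float) -> np.ndarray:
    lo, hi = ndtr(-bound), ndtr(bound)
    return ndtri(rng.uniform(lo, hi, size=size))


def simulate_experiment(params: SimParams | None = None,
                        n_participants: int = 28,
                        seed: int = 0) -> pd.DataFrame:
    """Simulate the full trial table for ``n_participants`` observers.

    Returns a tidy table with one row per trial and columns
    participant, session, task, arrangement, numerosity, configuration,
    response, rt_ms, concurrent_correct. Fully reproducible per ``seed``
    (independent sub-streams per participant).
    """
    if params is None:
        params = default_params()
    if n_participants < 1:
        raise SimParamError("n_participants must be >= 1")

    configs = configuration_table()
    tpb = params.trials_per_block
    conf_labels = np.array([configs[i % len(configs)].label for i in range(tpb)])
    conf_ns = np.array([configs[i % len(configs)].numerosity for i in range(tpb)])
    blocks = _session_blocks(params)

    streams = np.random.SeedSequence(seed).spawn(n_participants)
    frames = []
    for pi, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        pid = f"P{pi + 1:02d}"
        # correlated mean-one log-normal precision factors per task family
        sd, rho = params.between_participant_sd, params.participant_corr
        shared = rng.normal()
        families = ("single",) + DUAL_TASKS
        factor = {fam: np.exp(sd * (math.sqrt(rho) * shared
                                    + math.sqrt(1 - rho) * rng.normal())
                              - sd ** 2 / 2)
                  for fam in families}

        task_col, arr_col, sess_col, num_col, cfg_col = [], [], [], [], []
        block_index: dict[str, int] = {}
        for task, arrangement in blocks:
            bi = block_index.get(task, 0)
            block_index[task] = bi + 1
            order = rng.permutation(tpb)
            nums = conf_ns[order]
            cfgs = conf_labels[order] if arrangement == "grouped" else np.array([""] * tpb)
            task_col += [task] * tpb
            arr_col += [arrangement] * tpb
            sess_col += [f"{task}.b{bi + 1}"] * tpb
            num_col.append(nums)
            cfg_col.append(cfgs)
        nums = np.concatenate(num_col)
        n_trials = len(nums)
        tasks = np.array(task_col)
        arrs = np.array(arr_col)

        wf = np.array([params.generating_wf(t, a) for t, a in zip(tasks, arrs)])
        fam_of = {t: (t if t in DUAL_TASKS else "single") for t in TASKS}
        wf *= np.array([factor[fam_of[t]] for t in tasks])

        resp = simulate_response(nums, wf, bias=params.bias, lapse_rate=0.0, rng=rng)
        z = _truncated_normal(rng, n_trials, params.rt_truncation)
        rt = np.exp(params.rt_location + params.rt_scale * z)
        if params.lapse_rate > 0:
            lapse = rng.random(n_trials) < params.lapse_rate
            wild = rng.integers(1, 3 * nums + 1)
            resp = np.where(lapse, wild, resp)
            rt = np.where(lapse, rt * np.exp(params.lapse_rt_shift), rt)

        is_dual = np.isin(tasks, DUAL_TASKS)
        acc = np.array([params.concurrent_accuracy.get(t, np.nan) for t in tasks])
        correct = rng.random(n_trials) < acc
        conc = np.where(is_dual, np.where(correct, "true", "false"), "na")

        frames.append(pd.DataFrame({
            "participant": pid,
            "session": sess_col,
            "task": tasks,
            "arrangement": arrs,
            "numerosity": nums.astype(int),
            "configuration": np.concatenate(cfg_col),
            "response": resp.astype(int),
            "rt_ms": np.round(rt, 1),
            "concurrent_correct": conc,
        }))
    return pd.concat(frames, ignore_index=True)
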