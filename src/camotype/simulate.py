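"""Synthetic detection outcomes for the field and search experiments.

The field generator draws a latent bird-predation time for each pinned
target from an exponential distribution whose log-hazard is linear in the
target's standardized distances from the colour and texture centroids,
their product, and normal random effects for block and target pattern.  A
competing exponential censoring process stands in for non-bird outcomes
(other predators, lost targets); what is recorded is the first inspection
time after the earlier latent event, or censoring at the final check.

The search generator draws log10 reaction times from a normal model linear
in the same distances with target and background random effects, truncated
at the trial timeout, plus an independent miss mechanism whose probability
falls with distance but never below an asymptotic floor.

Default effect sizes encode the structure the statistics module is meant to
recover: detection hazard rises with both distances, with a negative
colour x texture interaction sized so the texture effect vanishes for
colour-atypical targets; search slopes default to typical psychophysics
magnitudes on the log10-seconds and logit scales.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["DetectionModel", "simulate_field", "simulate_search", "CHECK_TIMES"]

# survival inspection schedule, hours after placement
CHECK_TIMES = (7.0, 24.0, 31.0, 48.0, 55.0, 72.0)


@dataclass(frozen=True)
class DetectionModel:
    """Generating parameters linking typicality distances to detectability.

    Field side: ``log hazard = baseline_log_hazard + beta_colour*d_c +
    beta_texture*d_t + beta_interaction*d_c*d_t + block RE + target RE``
    (hazard per hour).  ``beta_interaction`` defaults negative, sized so the
    texture slope ``beta_texture + beta_interaction*d_c`` is ~0 at the
    colour distance typical of colour-rare stimuli selected from the default
    synthetic population (d_c ~ 3.5 standardized units).

    Search side: ``log10 RT = rt_baseline + rt_slopes . (d_c, d_t) + target
    RE + background RE + noise`` seconds; hit probability is logistic in the
    distances with ceiling ``1 - hit_floor``.
    """

    baseline_log_hazard: float = -5.0
    beta_colour: float = 0.5
    beta_texture: float = 0.5
    beta_interaction: float = -0.14
    block_sd: float = 0.25
    target_sd: float = 0.25
    censor_rate: float = 0.003
    check_times: tuple[float, ...] = CHECK_TIMES

    rt_baseline: float = 0.75  # log10 seconds (~5.6 s median search)
    rt_slopes: tuple[float, float] = (-0.058, -0.039)
    rt_noise_sd: float = 0.25
    rt_target_sd: float = 0.05
    rt_background_sd: float = 0.05
    timeout: float = 30.0
    hit_baseline_logit: float = 1.2
    hit_slopes: tuple[float, float] = (0.404, 0.280)
    hit_floor: float = 0.02

    def __post_init__(self) -> None:
        ct = tuple(float(t) for t in self.check_times)
        if len(ct) < 1 or np.any(np.diff(ct) <= 0):
            raise ValueError("check_times must be strictly increasing")
        if self.timeout < 0:
            raise ValueError("timeout must be >= 0")
        if self.censor_rate < 0 or not 0 <= self.hit_floor < 1:
            raise ValueError("censor_rate must be >= 0 and hit_floor in [0, 1)")
        object.__setattr__(self, "check_times", ct)


def _interval_censor(t: float, checks: tuple[float, ...]) -> float | None:
    """First inspection time at or after t, or None if t exceeds the last."""
    for c in checks:
        if t <= c:
            return c
    return None


def simulate_field(
    schedule: pd.DataFrame,
    distances: pd.DataFrame,
    model: DetectionModel,
    seed: int = 0,
) -> pd.DataFrame:
    """Survival records for a field placement schedule.

    ``schedule`` comes from :func:`camotype.design.build_field_schedule`;
    ``distances`` must map (tree_id, patch_id) to d_colour/d_texture (as in
    :func:`camotype.typicality.ranks_to_frame`).  Returns one row per
    placement with the recorded time (hours at an inspection) and event
    flag (1 = bird predation, 0 = censored).
    """
    rng = np.random.default_rng(seed)
    merged = schedule.merge(distances[["tree_id", "patch_id", "d_colour", "d_texture"]],
                            on=["tree_id", "patch_id"], how="left", validate="m:1")
    if merged[["d_colour", "d_texture"]].isna().any().any():
        missing = merged.loc[merged["d_colour"].isna(), ["tree_id", "patch_id"]]
        raise ValueError(f"distances missing for targets:\n{missing.drop_duplicates()}")

    blocks = merged["block"].to_numpy()
    tkey = merged["tree_id"].astype(str) + "/" + merged["patch_id"].astype(str)
    target_codes, _ = pd.factorize(tkey, sort=True)
    block_codes, _ = pd.factorize(blocks, sort=True)
    block_re = rng.normal(0.0, model.block_sd, block_codes.max() + 1)
    target_re = rng.normal(0.0, model.target_sd, target_codes.max() + 1)

    dc = merged["d_colour"].to_numpy()
    dt = merged["d_texture"].to_numpy()
    log_hazard = (
        model.baseline_log_hazard
        + model.beta_colour * dc
        + model.beta_texture * dt
        + model.beta_interaction * dc * dt
        + block_re[block_codes]
        + target_re[target_codes]
    )
    hazard = np.exp(log_hazard)
    bird_t = np.where(
        hazard > 0, rng.standard_exponential(len(merged)) / np.maximum(hazard, 1e-300), np.inf
    )
    if model.censor_rate > 0:
        cens_t = rng.standard_exponential(len(merged)) / model.censor_rate
    else:
        cens_t = np.full(len(merged), np.inf)

    times, events = [], []
    last = model.check_times[-1]
    for bt, ct in zip(bird_t, cens_t):
        first = min(bt, ct)
        rec = _interval_censor(first, model.check_times)
        if rec is None:
            times.append(last)
            events.append(0)
        else:
            times.append(rec)
            events.append(int(bt <= ct))
    out = merged[["block", "tree_id", "patch_id", "treatment", "d_colour", "d_texture"]].copy()
    out["time"] = times
    out["event"] = events
    return out


def simulate_search(
    schedule: pd.DataFrame,
    distances: pd.DataFrame,
    model: DetectionModel,
    seed: int = 0,
) -> pd.DataFrame:
    """Trial records (reaction time, hit/miss/timeout) for a search schedule.

    ``schedule`` comes from :func:`camotype.design.build_search_schedule`;
    ``distances`` maps the 0-based ``target`` id to d_colour/d_texture.
    Practice trials are carried through flagged but receive outcomes too.
    """
    rng = np.random.default_rng(seed)
    dist = distances.set_index("target")[["d_colour", "d_texture"]]
    if not set(schedule["target"]) <= set(dist.index):
        raise ValueError("distances missing for some scheduled targets")
    # slopes are per z-scored distance (the scale search analyses report),
    # so standardize over the target set before applying them
    zdist = (dist - dist.mean()) / dist.std(ddof=0).replace(0.0, 1.0)
    dc = zdist["d_colour"].reindex(schedule["target"]).to_numpy()
    dt = zdist["d_texture"].reindex(schedule["target"]).to_numpy()

    n_targets = int(schedule["target"].max()) + 1
    n_bg = int(schedule["background"].max()) + 1
    target_re = rng.normal(0.0, model.rt_target_sd, n_targets)
    bg_re = rng.normal(0.0, model.rt_background_sd, n_bg)

    mu = (
        model.rt_baseline
        + model.rt_slopes[0] * dc
        + model.rt_slopes[1] * dt
        + target_re[schedule["target"].to_numpy()]
        + bg_re[schedule["background"].to_numpy()]
    )
    log_rt = rng.normal(mu, model.rt_noise_sd)
    rt = 10.0 ** log_rt
    timed_out = rt > model.timeout

    logit = (
        model.hit_baseline_logit
        + model.hit_slopes[0] * dc
        + model.hit_slopes[1] * dt
    )
    p_hit = (1.0 - model.hit_floor) / (1.0 + np.exp(-logit))
    hit = (rng.uniform(size=len(schedule)) < p_hit) & ~timed_out

    out = schedule.copy()
    out["d_colour"] = dist["d_colour"].reindex(schedule["target"]).to_numpy()
    out["d_texture"] = dist["d_texture"].reindex(schedule["target"]).to_numpy()
    out["rt"] = np.where(timed_out, model.timeout, rt)
    out["timed_out"] = timed_out
    out["hit"] = hit.astype(int)
    return out
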