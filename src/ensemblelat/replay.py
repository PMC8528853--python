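"""Bayesian replay decoding, sequence scoring and per-cell contribution.

Candidate events are SWRs of 50-300 ms in which at least five place cells
fire. Each event is cut into non-overlapping 20 ms bins and the spike counts
are decoded against the exploration firing-rate templates with a memoryless
Poisson observation model,

    Pr(pos | spikes) ~ (prod_i f_i(pos)^{sp_i}) * exp(-tau * sum_i f_i(pos)),

column-normalised over positions (computed in log space). Sequence structure
is the position-time correlation weighted by the posterior; its null
distribution comes from circularly shifting every cell's template by an
independent uniform number of spatial bins and re-decoding. The sequence
score rZ is |r_observed| z-scored against that null, and the Monte Carlo
P-value is (n_exceed + 1) / (n_shuffles + 1). Per-cell contribution (PCC)
shuffles only one cell's template: PCC = (rZ_observed - mean single-cell
shuffled rZ) x number of participating cells (cells with more than one spike
in the event).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.stats import ranksums

from .types import (DecodingTemplate, PosteriorMatrix, ReplayEvent, RippleEvent,
                    UnitSpikeTrain)

__all__ = [
    "Candidate",
    "select_candidate_events",
    "bayesian_decode",
    "weighted_correlation",
    "sequence_score_rz",
    "monte_carlo_p",
    "pick_direction_and_significance",
    "replay_kinematics",
    "per_cell_contribution",
    "pcc_from_delta",
    "score_candidate",
    "lateralized_replay_comparisons",
]

_SHUFFLE_CHUNK = 250  # shuffles decoded per vectorised block


@dataclass
class Candidate:
    """One candidate replay window: a qualifying ripple plus active cells."""

    ripple: RippleEvent
    active_unit_ids: tuple

    @property
    def window(self) -> Tuple[float, float]:
        return (self.ripple.t_start, self.ripple.t_stop)


def select_candidate_events(ripple_events: Sequence[RippleEvent],
                            units: Sequence[UnitSpikeTrain], *,
                            min_cells: int = 5, min_ms: float = 50.0,
                            max_ms: float = 300.0) -> List[Candidate]:
    """Ripples of qualifying duration with >= ``min_cells`` active place cells."""
    out = []
    for ev in ripple_events:
        if not (min_ms <= ev.duration_ms <= max_ms):
            continue
        active = tuple(u.unit_id for u in units if u.count_in(ev.t_start, ev.t_stop) >= 1)
        if len(active) >= min_cells:
            out.append(Candidate(ripple=ev, active_unit_ids=active))
    return out


def _bin_counts(window: Tuple[float, float], units: Sequence[UnitSpikeTrain],
                template: DecodingTemplate) -> Tuple[np.ndarray, np.ndarray]:
    """Spike counts (M temporal bins x C cells) over non-overlapping tau bins.

    The final partial bin is dropped so every decoded bin has width tau.
    """
    t0, t1 = window
    m = int(np.floor((t1 - t0) / template.tau))
    if m < 1:
        raise ValueError("window shorter than one decoding bin")
    edges = t0 + template.tau * np.arange(m + 1)
    by_id = {u.unit_id: u for u in units}
    counts = np.zeros((m, template.unit_ids.size))
    for c, uid in enumerate(template.unit_ids):
        u = by_id.get(int(uid))
        if u is not None:
            counts[:, c] = np.histogram(u.spike_times, bins=edges)[0]
    centers = 0.5 * (edges[:-1] + edges[1:])
    return counts, centers


def _posterior_batch(counts: np.ndarray, f_batch: np.ndarray, tau: float) -> np.ndarray:
    """Column-normalised posteriors for a batch of templates.

    counts: (M, C); f_batch: (S, C, P) floored rates. Returns (S, M, P).
    Log-space with per-column max subtraction keeps the computation stable
    for any realistic spike count.
    """
    logf = np.log(f_batch)
    loglik = np.einsum("mc,scp->smp", counts, logf) - tau * f_batch.sum(axis=1)[:, None, :]
    loglik -= loglik.max(axis=2, keepdims=True)
    pr = np.exp(loglik)
    pr /= pr.sum(axis=2, keepdims=True)
    return pr


def _weighted_r_batch(pr: np.ndarray, pos: np.ndarray) -> np.ndarray:
    """Posterior-weighted position-time correlation for a batch (S,) of events."""
    s, m, p = pr.shape
    bins = np.arange(m, dtype=float)
    tot = pr.sum(axis=(1, 2))
    mpos = np.einsum("smp,p->s", pr, pos) / tot
    mbin = np.einsum("smp,m->s", pr, bins) / tot
    dpos = pos[None, None, :] - mpos[:, None, None]
    dbin = bins[None, :, None] - mbin[:, None, None]
    cov_pb = np.einsum("smp,smp,smp->s", pr, dpos, dbin) / tot
    cov_pp = np.einsum("smp,smp,smp->s", pr, dpos, dpos) / tot
    cov_bb = np.einsum("smp,smp,smp->s", pr, dbin, dbin) / tot
    denom = np.sqrt(cov_pp * cov_bb)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, cov_pb / denom, np.nan)
    return r


def bayesian_decode(window: Tuple[float, float], units: Sequence[UnitSpikeTrain],
                    template: DecodingTemplate, event_id: int = -1) -> PosteriorMatrix:
    """Decode one event window against a direction template."""
    counts, centers = _bin_counts(window, units, template)
    pr = _posterior_batch(counts, template.floored_rates()[None], template.tau)[0]
    return PosteriorMatrix(Pr=pr.T, bin_times=centers,
                           bin_centers_cm=template.bin_centers, event_id=event_id)


def weighted_correlation(posterior: PosteriorMatrix) -> float:
    """Weighted position-time correlation of a decoded event (in [-1, 1]).

    NaN if the posterior carries no variance in position or time (flagged
    undefined by the caller).
    """
    if posterior.n_time < 2:
        raise ValueError("need at least 2 temporal bins")
    pr = posterior.Pr.T[None]  # (1, M, P)
    return float(_weighted_r_batch(pr, np.asarray(posterior.bin_centers_cm, float))[0])


def _shuffled_rates(base: np.ndarray, shifts: np.ndarray) -> np.ndarray:
    """Circularly shift each cell's rate curve by its own number of bins.

    base: (C, P); shifts: (S, C) integers. Returns (S, C, P).
    """
    c, p = base.shape
    cols = (np.arange(p)[None, None, :] - shifts[:, :, None]) % p
    return base[np.arange(c)[None, :, None], cols]


def monte_carlo_p(n_exceed: int, n_shuffles: int = 1000) -> float:
    """Monte Carlo P-value (n_exceed + 1) / (n_shuffles + 1)."""
    if not (0 <= n_exceed <= n_shuffles):
        raise ValueError("need 0 <= n_exceed <= n_shuffles")
    return (n_exceed + 1) / (n_shuffles + 1)


def sequence_score_rz(window: Tuple[float, float], units: Sequence[UnitSpikeTrain],
                      template: DecodingTemplate, *, n_shuffles: int = 1000,
                      seed: int = 0) -> dict:
    """Observed weighted correlation, circular-shuffle null, rZ and P.

    Every shuffle shifts EVERY cell's template by an independent uniform
    number of spatial bins and re-decodes the event. Exceedances are counted
    two-sided (|r_null| > |r_observed|), matching the |r|-based score.
    """
    counts, centers = _bin_counts(window, units, template)
    rates = template.floored_rates()
    pos = np.asarray(template.bin_centers, float)
    r_obs = float(_weighted_r_batch(
        _posterior_batch(counts, rates[None], template.tau), pos)[0])
    rng = np.random.default_rng([seed, 23])
    shifts = rng.integers(0, template.n_pos, size=(n_shuffles, rates.shape[0]))
    null = np.empty(n_shuffles)
    for a in range(0, n_shuffles, _SHUFFLE_CHUNK):
        b = min(a + _SHUFFLE_CHUNK, n_shuffles)
        fb = _shuffled_rates(rates, shifts[a:b])
        null[a:b] = _weighted_r_batch(_posterior_batch(counts, fb, template.tau), pos)
    abs_null = np.abs(null)
    mu, sd = float(np.nanmean(abs_null)), float(np.nanstd(abs_null))
    rz = (abs(r_obs) - mu) / sd if sd > 0 else float("nan")
    n_exceed = int(np.nansum(abs_null > abs(r_obs)))
    return dict(r=r_obs, rz=rz, null_abs_mean=mu, null_abs_sd=sd,
                null_r=null, n_exceed=n_exceed,
                p_mc=monte_carlo_p(n_exceed, n_shuffles),
                bin_times=centers)


def pick_direction_and_significance(scores: Sequence[dict], *,
                                    alpha: float = 0.05) -> Tuple[dict, bool]:
    """Keep the direction with the smaller Monte Carlo P.

    Ties go to the larger |r|, then to the first listed direction (fixed
    order). The kept direction is significant iff its P < alpha.
    """
    best = min(range(len(scores)),
               key=lambda i: (scores[i]["p_mc"], -abs(scores[i]["r"]), i))
    chosen = scores[best]
    return chosen, bool(chosen["p_mc"] < alpha)


def replay_kinematics(posterior: PosteriorMatrix, tau: float = 0.020) -> dict:
    """Trajectory summaries from per-bin peak decoded positions.

    distance = max - min of peak positions (cm); mean_jump = mean |step|
    between adjacent bins; speed = distance over the decoded extent (M*tau),
    in m/s. Argmax ties resolve to the lowest spatial bin.
    """
    if posterior.n_time < 2:
        raise ValueError("need at least 2 temporal bins")
    peaks = np.asarray(posterior.bin_centers_cm, float)[np.argmax(posterior.Pr, axis=0)]
    distance = float(peaks.max() - peaks.min())
    mean_jump = float(np.mean(np.abs(np.diff(peaks))))
    duration = posterior.n_time * tau
    return dict(distance_cm=distance, mean_jump_cm=mean_jump,
                speed_m_s=distance / 100.0 / duration, peak_positions=peaks)


def pcc_from_delta(delta_rz: float, n_participants: int) -> float:
    """Per-cell contribution: score drop times the number of participants."""
    return delta_rz * n_participants


def per_cell_contribution(window: Tuple[float, float], units: Sequence[UnitSpikeTrain],
                          template: DecodingTemplate, observed: dict, *,
                          n_shuffles: int = 1000, seed: int = 0) -> dict:
    """PCC of every participating cell in one significant event.

    Participants are cells with more than one spike in the window. For each,
    only that cell's template is circularly shuffled ``n_shuffles`` times and
    the event re-decoded; each shuffled |r| is scored against the event's
    all-cell null (same mean/SD as the observed rZ), and the mean shuffled
    score is subtracted from the observed rZ and scaled by the number of
    participants.
    """
    counts, _ = _bin_counts(window, units, template)
    rates = template.floored_rates()
    pos = np.asarray(template.bin_centers, float)
    mu, sd = observed["null_abs_mean"], observed["null_abs_sd"]
    rz_obs = observed["rz"]
    total = counts.sum(axis=0)
    participants = np.flatnonzero(total > 1)
    n_part = participants.size
    rng = np.random.default_rng([seed, 29])
    pcc: Dict[int, float] = {}
    for c in participants:
        shifts = np.zeros((n_shuffles, rates.shape[0]), dtype=int)
        shifts[:, c] = rng.integers(0, template.n_pos, size=n_shuffles)
        rs = np.empty(n_shuffles)
        for a in range(0, n_shuffles, _SHUFFLE_CHUNK):
            b = min(a + _SHUFFLE_CHUNK, n_shuffles)
            fb = _shuffled_rates(rates, shifts[a:b])
            rs[a:b] = _weighted_r_batch(_posterior_batch(counts, fb, template.tau), pos)
        rz_shuf = float(np.nanmean((np.abs(rs) - mu) / sd))
        pcc[int(template.unit_ids[c])] = pcc_from_delta(rz_obs - rz_shuf, n_part)
    return dict(pcc=pcc, n_participants=int(n_part),
                participant_ids=[int(template.unit_ids[c]) for c in participants])


def score_candidate(candidate: Candidate, units: Sequence[UnitSpikeTrain],
                    templates: Dict[int, DecodingTemplate], *, n_shuffles: int = 1000,
                    seed: int = 0, alpha: float = 0.05, event_id: int = -1,
                    compute_pcc: bool = False) -> ReplayEvent:
    """Score one candidate under both direction templates and keep the best.

    The two per-direction decodings use independent seeded shuffle sets.
    """
    window = candidate.window
    scores = []
    for j, d in enumerate(sorted(templates.keys(), reverse=True)):  # fixed order: +1, -1
        s = sequence_score_rz(window, units, templates[d], n_shuffles=n_shuffles,
                              seed=seed * 1009 + event_id * 7 + j)
        s["direction"] = d
        s["template"] = templates[d]
        scores.append(s)
    chosen, significant = pick_direction_and_significance(scores, alpha=alpha)
    template = chosen["template"]
    posterior = bayesian_decode(window, units, template, event_id=event_id)
    kin = replay_kinematics(posterior, tau=template.tau)
    counts, _ = _bin_counts(window, units, template)
    n_participants = int(np.sum(counts.sum(axis=0) > 1))
    pcc = None
    if compute_pcc and significant:
        pcc = per_cell_contribution(window, units, template, chosen,
                                    n_shuffles=n_shuffles, seed=seed * 1013 + event_id)
    return ReplayEvent(event_id=event_id, ripple_hemisphere=candidate.ripple.hemisphere,
                       t_start=window[0], t_stop=window[1], direction=chosen["direction"],
                       r=chosen["r"], rz=chosen["rz"], p_mc=chosen["p_mc"],
                       significant=significant, distance_cm=kin["distance_cm"],
                       speed_m_s=kin["speed_m_s"], mean_jump_cm=kin["mean_jump_cm"],
                       n_participants=n_participants,
                       participants=tuple(candidate.active_unit_ids),
                       posterior=posterior, pcc=pcc["pcc"] if pcc else None)


def _subset_templates(templates: Dict[int, DecodingTemplate],
                      keep_ids: set) -> Optional[Dict[int, DecodingTemplate]]:
    out = {}
    for d, t in templates.items():
        sel = np.array([int(u) in keep_ids for u in t.unit_ids])
        if sel.sum() == 0:
            return None
        out[d] = DecodingTemplate(unit_ids=t.unit_ids[sel], rates=t.rates[sel],
                                  bin_centers=t.bin_centers, direction=d, tau=t.tau,
                                  rate_floor=t.rate_floor)
    return out


def lateralized_replay_comparisons(ripple_events: Sequence[RippleEvent],
                                   units: Sequence[UnitSpikeTrain],
                                   templates: Dict[int, DecodingTemplate], *,
                                   min_cells: int = 5, n_shuffles: int = 200,
                                   seed: int = 0, alpha: float = 0.05,
                                   compute_pcc: bool = True) -> dict:
    """Hemisphere-conditioned replay quality.

    For every candidate SWR the event is re-decoded twice through the full
    pipeline (same inclusion gates): once with only cells ipsilateral to the
    detecting hemisphere and once with only contralateral cells; the rZ of
    the winning direction is collected per arm and the arms compared with a
    two-sided rank-sum test. Additionally, PCC values from the full bilateral
    decoding of significant events are grouped by whether the cell lies in
    the same or the opposite hemisphere as the source ripple.
    """
    hemi = {u.unit_id: u.hemisphere for u in units}
    rz_same: List[float] = []
    rz_opp: List[float] = []
    pcc_same: List[float] = []
    pcc_opp: List[float] = []
    dropped = {"same": 0, "opposite": 0}
    candidates = select_candidate_events(ripple_events, units, min_cells=min_cells)
    for k, cand in enumerate(candidates):
        rip_h = cand.ripple.hemisphere
        ev = score_candidate(cand, units, templates, n_shuffles=n_shuffles,
                             seed=seed, event_id=k, alpha=alpha, compute_pcc=compute_pcc)
        if ev.significant and ev.pcc:
            for uid, val in ev.pcc.items():
                (pcc_same if hemi[uid] == rip_h else pcc_opp).append(val)
        for arm, want_same in (("same", True), ("opposite", False)):
            keep = {u for u, h in hemi.items() if (h == rip_h) == want_same}
            sub_units = [u for u in units if u.unit_id in keep]
            sub_t = _subset_templates(templates, keep)
            n_active = sum(1 for u in sub_units
                           if u.count_in(cand.ripple.t_start, cand.ripple.t_stop) >= 1)
            if sub_t is None or n_active < min_cells:
                dropped[arm] += 1
                continue
            sub_ev = score_candidate(cand, sub_units, sub_t, n_shuffles=n_shuffles,
                                     seed=seed + 5000, event_id=k, alpha=alpha)
            (rz_same if want_same else rz_opp).append(sub_ev.rz)
    report = dict(rz_same=np.array(rz_same), rz_opposite=np.array(rz_opp),
                  pcc_same=np.array(pcc_same), pcc_opposite=np.array(pcc_opp),
                  n_dropped=dropped,
                  opposite_arm_empty=len(rz_opp) == 0)
    if len(rz_same) >= 2 and len(rz_opp) >= 2:
        stat, p = ranksums(rz_same, rz_opp)
        report["rz_ranksum_stat"], report["rz_ranksum_p"] = float(stat), float(p)
    return report
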