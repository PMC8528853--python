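"""PCA/ICA cell-assembly detection, laterality, and activation tracking.

Spike trains are binned into 25 ms windows and z-scored per unit. The number
of genuine co-activation patterns N_A is the number of eigenvalues of the
unit-correlation matrix above the Marcenko-Pastur bound

    lambda_max = (1 + sqrt(n_units / n_bins))^2,

the analytic upper edge for an n x B matrix of independent rows. The z-scored
matrix is projected onto the N_A significant principal components and
fastICA unmixes the projection; assembly weight vectors are the PCA-space
back-projection of the unmixing rows, unit-normalised and sign-fixed so the
largest-magnitude weight is positive. Members are units whose weight exceeds
the population mean by more than 2 SD.

Activation strength of pattern k at bin t is the quadratic form
R_k(t) = z(t)^T P_k z(t) with P_k the outer product of the weight vector with
zero diagonal (so a single active unit scores 0), evaluated on
Gaussian-smoothed z-scores.
"""

from __future__ import annotations

import warnings
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.stats import kurtosis
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

from .types import (ActivationTrace, AssemblyPattern, BinnedSpikeMatrix,
                    PositionTrace, RippleEvent, UnitSpikeTrain)

__all__ = [
    "bin_and_zscore",
    "marcenko_pastur_lambda_max",
    "detect_assembly_patterns",
    "assign_members",
    "classify_laterality",
    "unilateral_fraction_null",
    "smooth_zscores",
    "activation_strength",
    "reactivation_in_ripples",
]


def bin_and_zscore(units: Sequence[UnitSpikeTrain], window: Tuple[float, float], *,
                   bin_ms: float = 25.0, position: Optional[PositionTrace] = None,
                   direction: Optional[int] = None) -> BinnedSpikeMatrix:
    """Bin spike counts into ``bin_ms`` windows and z-score per unit.

    If ``position`` and ``direction`` are given, only bins whose centre falls
    in a sample moving in that direction are kept (direction-separated
    activity). Units with zero count variance are dropped and recorded in
    ``dropped_unit_ids``.
    """
    t0, t1 = window
    if t1 <= t0:
        raise ValueError("empty window")
    dt = bin_ms * 1e-3
    n_bins = int(np.floor((t1 - t0) / dt))
    if n_bins < 1:
        raise ValueError("window shorter than one bin")
    if n_bins < 100:
        warnings.warn("fewer than 100 bins: eigenvalue bound will be loose", stacklevel=2)
    edges = t0 + dt * np.arange(n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    counts = np.array([np.histogram(u.spike_times, bins=edges)[0] for u in units],
                      dtype=float)
    keep_bins = np.ones(n_bins, dtype=bool)
    if direction is not None:
        if position is None:
            raise ValueError("direction selection requires a position trace")
        d = np.interp(centers, position.times, position.direction.astype(float))
        keep_bins = np.sign(d) == direction
        counts = counts[:, keep_bins]
        centers = centers[keep_bins]
    mean = counts.mean(axis=1, keepdims=True)
    sd = counts.std(axis=1, keepdims=True)
    ok = sd[:, 0] > 0
    unit_ids = np.array([u.unit_id for u in units], dtype=int)
    dropped = unit_ids[~ok]
    Z = (counts[ok] - mean[ok]) / sd[ok]
    return BinnedSpikeMatrix(Z=Z, bin_times=centers, unit_ids=unit_ids[ok],
                             direction=direction, dropped_unit_ids=dropped, bin_ms=bin_ms)


def marcenko_pastur_lambda_max(n_units: int, n_bins: int) -> float:
    """Upper Marcenko-Pastur eigenvalue bound (1 + sqrt(n/B))^2."""
    if n_units < 2 or n_bins < 2:
        raise ValueError("need n_units >= 2 and n_bins >= 2")
    return float((1.0 + np.sqrt(n_units / n_bins)) ** 2)


def _sign_fix(v: np.ndarray) -> np.ndarray:
    """Flip so the largest-|weight| entry is positive (reporting convention)."""
    return v * np.sign(v[np.argmax(np.abs(v))]) if v.size else v


def detect_assembly_patterns(Z: BinnedSpikeMatrix, *, seed: int = 0,
                             n_restarts: int = 20,
                             max_iter: int = 1000) -> Tuple[List[AssemblyPattern], dict]:
    """Detect co-activation patterns in a z-scored binned spike matrix.

    ICA is randomised, so it is restarted ``n_restarts`` times from seeded
    initial conditions and the run whose sources are most non-Gaussian
    (largest summed |excess kurtosis|) is kept. Returns the patterns plus a
    diagnostics record (eigenvalue spectrum, bound, N_A, ICA seed/restarts).
    """
    n, B = Z.n_units, Z.n_bins
    corr = Z.Z @ Z.Z.T / B
    eigvals, eigvecs = np.linalg.eigh(corr)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    lam_max = marcenko_pastur_lambda_max(n, B)
    n_sig = int(np.sum(eigvals > lam_max))
    diagnostics = dict(eigenvalues=eigvals, lambda_max=lam_max, n_significant=n_sig,
                       ica_seed=seed, ica_restarts=n_restarts)
    if n_sig == 0:
        return [], diagnostics
    p_sign = eigvecs[:, :n_sig]                      # n x N_A
    z_proj = p_sign.T @ Z.Z                          # N_A x B

    best_V, best_score = None, -np.inf
    ss = np.random.SeedSequence([seed, 13])
    for child in ss.spawn(n_restarts):
        state = int(child.generate_state(1)[0] % (2 ** 31))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            ica = FastICA(n_components=n_sig, random_state=state, max_iter=max_iter,
                          whiten="unit-variance")
            sources = ica.fit_transform(z_proj.T)    # B x N_A
        score = float(np.sum(np.abs(kurtosis(sources, axis=0))))
        if score > best_score:
            best_score = score
            best_V = p_sign @ ica.components_.T      # n x N_A weight vectors
    diagnostics["ica_nongaussianity"] = best_score

    patterns: List[AssemblyPattern] = []
    for k in range(n_sig):
        v = best_V[:, k]
        v = v / np.linalg.norm(v)
        v = _sign_fix(v)
        members = assign_members(v, Z.unit_ids)
        patterns.append(AssemblyPattern(assembly_id=k, unit_ids=Z.unit_ids.copy(),
                                        weights=v, members=members,
                                        direction=Z.direction))
    return patterns, diagnostics


def assign_members(weights: np.ndarray, unit_ids: Optional[np.ndarray] = None) -> frozenset:
    """Units whose weight strictly exceeds mean + 2 SD of all weights.

    Degenerate case: zero weight SD (all weights equal) yields no members.
    Membership is invariant to a global sign flip of an already sign-fixed
    vector because the rule is applied after sign fixing.
    """
    w = np.asarray(weights, dtype=float)
    if w.size < 3:
        raise ValueError("need at least 3 weights")
    ids = np.arange(w.size) if unit_ids is None else np.asarray(unit_ids)
    sd = w.std()
    if sd == 0:
        return frozenset()
    thr = w.mean() + 2.0 * sd
    return frozenset(int(i) for i in ids[w > thr])


def classify_laterality(members: frozenset, hemisphere_map: dict) -> Tuple[str, str]:
    """(laterality, dominant_side) of a member set.

    Unilateral iff all members share a hemisphere; the dominant side is the
    majority hemisphere, "tied" on equal counts; empty set -> "undefined".
    """
    if not members:
        return "undefined", "tied"
    sides = [hemisphere_map[m] for m in members]
    n_l, n_r = sides.count("L"), sides.count("R")
    if n_r == 0:
        return "unilateral-L", "L"
    if n_l == 0:
        return "unilateral-R", "R"
    dom = "L" if n_l > n_r else ("R" if n_r > n_l else "tied")
    return "bilateral", dom


def unilateral_fraction_null(assemblies: Sequence[frozenset], hemisphere_map: dict, *,
                             n_shuffles: int = 1000, seed: int = 0) -> dict:
    """Member-shuffle null for the fraction of unilateral assemblies.

    Each shuffle reconstitutes every assembly with a same-size random draw of
    units, without replacement within the assembly, from the session's
    recorded pool; the unilateral fraction is recomputed per shuffle.
    Returns observed fraction, the null vector and the observed value's
    empirical percentile.
    """
    pool = np.array(sorted(hemisphere_map.keys()))
    sizes = [len(a) for a in assemblies]
    if not sizes:
        raise ValueError("no assemblies")
    if max(sizes) > pool.size:
        raise ValueError("unit pool smaller than the largest assembly")
    is_uni = [classify_laterality(a, hemisphere_map)[0].startswith("unilateral")
              for a in assemblies]
    observed = float(np.mean(is_uni))
    rng = np.random.default_rng([seed, 17])
    sides = np.array([hemisphere_map[u] == "L" for u in pool])
    null = np.empty(n_shuffles)
    for s in range(n_shuffles):
        uni = 0
        for size in sizes:
            draw = rng.choice(pool.size, size=size, replace=False)
            n_l = int(sides[draw].sum())
            uni += (n_l == 0) or (n_l == size)
        null[s] = uni / len(sizes)
    percentile = float(np.mean(null < observed) * 100.0)
    return dict(observed_fraction=observed, null_fractions=null, percentile=percentile)


def smooth_zscores(Z: BinnedSpikeMatrix, sd_bins: float = 1.0,
                   truncate: float = 4.0) -> BinnedSpikeMatrix:
    """Gaussian-smooth each unit's z-score series (SD in bins, truncated)."""
    Zs = gaussian_filter1d(Z.Z, sd_bins, axis=1, mode="nearest", truncate=truncate)
    return BinnedSpikeMatrix(Z=Zs, bin_times=Z.bin_times, unit_ids=Z.unit_ids,
                             direction=Z.direction, dropped_unit_ids=Z.dropped_unit_ids,
                             bin_ms=Z.bin_ms)


def _strict_peaks(r: np.ndarray, threshold: float) -> np.ndarray:
    """Indices of strict local maxima above threshold; plateaus take the first bin."""
    peaks = []
    i, n = 1, r.size
    while i < n - 1:
        if r[i] > r[i - 1]:
            j = i
            while j + 1 < n and r[j + 1] == r[j]:
                j += 1
            if j + 1 < n and r[j + 1] < r[j] and r[i] > threshold:
                peaks.append(i)
            i = j + 1
        else:
            i += 1
    return np.array(peaks, dtype=int)


def activation_strength(pattern: AssemblyPattern, Z_smooth: BinnedSpikeMatrix, *,
                        threshold: float = 5.0) -> ActivationTrace:
    """Activation strength R_k(t) of one pattern on smoothed z-scores.

    Computed as (v.z)^2 - sum_i v_i^2 z_i^2, the quadratic form of the
    zero-diagonal projection matrix. Every unit of the pattern must be present
    in the matrix; missing units raise an error listing them.
    """
    idx_of = {int(u): i for i, u in enumerate(Z_smooth.unit_ids)}
    missing = [int(u) for u in pattern.unit_ids if int(u) not in idx_of]
    if missing:
        raise ValueError(f"pattern units missing from matrix: {missing}")
    rows = np.array([idx_of[int(u)] for u in pattern.unit_ids])
    Zm = Z_smooth.Z[rows]
    v = pattern.weights
    r = (v @ Zm) ** 2 - (v ** 2) @ (Zm ** 2)
    ipk = _strict_peaks(r, threshold)
    return ActivationTrace(assembly_id=pattern.assembly_id, times=Z_smooth.bin_times,
                           strength=r, peak_times=Z_smooth.bin_times[ipk],
                           peak_strengths=r[ipk], threshold=threshold)


def reactivation_in_ripples(trace: ActivationTrace, ripple_events: Sequence[RippleEvent], *,
                            min_rate: float = 0.01) -> dict:
    """Reactivation rate and strength of one assembly within SWRs.

    Rate is the number of supra-threshold activation peaks inside a ripple
    interval divided by the total ripple duration; strength is the mean of
    those peaks. Assemblies whose overall reactivation rate (peaks per second
    of trace) falls below ``min_rate`` are flagged for exclusion from group
    statistics.
    """
    if len(ripple_events) == 0:
        raise ValueError("no ripple events")
    total = float(sum(e.t_stop - e.t_start for e in ripple_events))
    starts = np.array([e.t_start for e in ripple_events])
    stops = np.array([e.t_stop for e in ripple_events])
    order = np.argsort(starts)
    starts, stops = starts[order], stops[order]
    in_ripple = np.zeros(trace.peak_times.size, dtype=bool)
    for i, t in enumerate(trace.peak_times):
        j = np.searchsorted(starts, t, side="right") - 1
        in_ripple[i] = j >= 0 and t <= stops[j]
    n_in = int(in_ripple.sum())
    rate = n_in / total if total > 0 else 0.0
    strength = float(trace.peak_strengths[in_ripple].mean()) if n_in else float("nan")
    span = trace.times[-1] - trace.times[0] if trace.times.size > 1 else 0.0
    overall_rate = trace.peak_times.size / span if span > 0 else 0.0
    return dict(rate_hz=rate, strength=strength, n_peaks_in_ripples=n_in,
                overall_rate_hz=overall_rate, excluded=overall_rate < min_rate)
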