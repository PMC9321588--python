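"""Post-processing: mixing times, lifeline regimes, population statistics.

Mixing is quantified two ways.  The *probe* mixing time ``tau95`` is the
last time the normalized single-point signal leaves the +/-5 % band
around the tank mean (it stays in-band afterwards).  The *coefficient of
mixing* (CoM) is the volume-weighted coefficient of variation of the
concentration field,

    CoM(t) = sqrt( sum_i ((Cs_i - Cs_mean)/Cs_mean)^2 dV_i / sum_i dV_i ),

with the volumetric mixing time registered when CoM first drops below
0.0283 (the 95 %-homogeneity threshold) and stays below.

Lifelines — per-parcel traces of the uptake saturation ``qs/qs_max`` —
are classified into (E)xcess (> 0.95), (S)tarvation (< 0.05) and
(L)imitation (in between).  Before computing regime statistics two
filters remove short, low-amplitude transitions: a centered moving
average over a 0.36 s window, and a "fuzzy boundary" of +/-0.01 around
each threshold implemented as hysteresis (entering Excess requires
crossing 0.96, leaving it crossing 0.94; mirrored for Starvation).
Residence-time statistics are keyed by *transition pattern* — the regime
visited plus its flanking regimes (LEL, LSL, ELE, ELS, SLE, SLS) — and
visits truncated by the ends of the series are discarded.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import numpy as np

__all__ = [
    "COM_THRESHOLD",
    "REGIME_THRESHOLDS",
    "com_value",
    "com_curve",
    "com_tau95",
    "probe_tau95",
    "classify_regimes",
    "moving_average",
    "hysteresis_labels",
    "filter_lifeline",
    "residence_time_stats",
    "regime_fractions",
    "pool_histograms",
]

#: CoM value corresponding to 95 % homogeneity
COM_THRESHOLD = 0.0283

#: saturation-ratio thresholds: Excess above, Starvation below
REGIME_THRESHOLDS = {"excess": 0.95, "starvation": 0.05}

#: fuzzy-boundary half width applied around each threshold
FUZZY_HALF_WIDTH = 0.01

#: moving-average window (s)
SMOOTHING_WINDOW_S = 0.36

STANDARD_PATTERNS = ("LEL", "LSL", "ELE", "ELS", "SLE", "SLS")


class AnalysisError(ValueError):
    pass


# ---------------------------------------------------------------------------
# mixing metrics
# ---------------------------------------------------------------------------

def com_value(concentration: np.ndarray, volumes: np.ndarray) -> float:
    """Volume-weighted coefficient of variation of one concentration field."""
    c = np.asarray(concentration, dtype=float)
    v = np.asarray(volumes, dtype=float)
    mean = float((c * v).sum() / v.sum())
    if mean == 0.0:
        raise AnalysisError("zero tank mean: coefficient of mixing undefined")
    dev2 = ((c - mean) / mean) ** 2
    return float(np.sqrt((dev2 * v).sum() / v.sum()))


def com_curve(concentrations: np.ndarray, volumes: np.ndarray) -> np.ndarray:
    """CoM series for a (nt, nc) stack of concentration fields."""
    c = np.atleast_2d(np.asarray(concentrations, dtype=float))
    v = np.asarray(volumes, dtype=float)
    mean = (c * v).sum(axis=1) / v.sum()
    if np.any(mean == 0.0):
        raise AnalysisError("zero tank mean: coefficient of mixing undefined")
    dev2 = ((c - mean[:, None]) / mean[:, None]) ** 2
    return np.sqrt((dev2 * v).sum(axis=1) / v.sum())


def com_tau95(times: np.ndarray, com: np.ndarray,
              threshold: float = COM_THRESHOLD) -> tuple[float, bool]:
    """First time the CoM drops below ``threshold`` and stays below.

    Returns ``(tau95, reached)``; ``(nan, False)`` if the series never
    settles below the threshold.
    """
    times = np.asarray(times, dtype=float)
    com = np.asarray(com, dtype=float)
    above = com >= threshold
    if above[-1]:
        return float("nan"), False
    if not above.any():
        return float(times[0]), True
    last_above = int(np.flatnonzero(above)[-1])
    # linear interpolation of the final downward crossing
    t0, t1 = times[last_above], times[last_above + 1]
    c0, c1 = com[last_above], com[last_above + 1]
    frac = (c0 - threshold) / (c0 - c1) if c0 != c1 else 1.0
    return float(t0 + frac * (t1 - t0)), True


def probe_tau95(times: np.ndarray, probe_normalized: np.ndarray,
                band: tuple[float, float] = (0.95, 1.05)) -> tuple[float, bool]:
    """Last exit of the normalized probe signal from the homogeneity band.

    ``probe_normalized`` is probe concentration divided by the tank mean.
    Returns ``(tau95, settled)``: the interpolated time of the final band
    crossing, or 0 if the signal never leaves the band, or ``(nan,
    False)`` if it is out of band at the series end.
    """
    times = np.asarray(times, dtype=float)
    s = np.asarray(probe_normalized, dtype=float)
    lo, hi = band
    out = (s < lo) | (s > hi)
    if out[-1]:
        return float("nan"), False
    if not out.any():
        return 0.0, True
    k = int(np.flatnonzero(out)[-1])
    # interpolate the crossing of whichever edge was violated at sample k
    edge = lo if s[k] < lo else hi
    t0, t1 = times[k], times[k + 1]
    s0, s1 = s[k], s[k + 1]
    frac = (edge - s0) / (s1 - s0) if s1 != s0 else 1.0
    return float(t0 + frac * (t1 - t0)), True


# ---------------------------------------------------------------------------
# regime classification and filtering
# ---------------------------------------------------------------------------

def classify_regimes(ratio: np.ndarray,
                     excess: float = REGIME_THRESHOLDS["excess"],
                     starvation: float = REGIME_THRESHOLDS["starvation"]) -> np.ndarray:
    """Label each sample E / L / S by strict threshold comparison."""
    r = np.asarray(ratio, dtype=float)
    labels = np.full(r.shape, "L", dtype="U1")
    labels[r > excess] = "E"
    labels[r < starvation] = "S"
    return labels


def moving_average(ratio: np.ndarray, dt_sample: float,
                   window_s: float = SMOOTHING_WINDOW_S) -> np.ndarray:
    """Centered moving average; edges use shrinking windows.

    The window is the odd sample count spanning ``window_s`` (7 points at
    the default 0.06 s sampling).
    """
    r = np.asarray(ratio, dtype=float)
    half = int(round(window_s / dt_sample / 2.0))
    n = 2 * half + 1
    if n > r.size:
        raise AnalysisError(
            f"smoothing window of {n} samples exceeds series length {r.size}"
        )
    if half == 0:
        return r.copy()
    csum = np.concatenate([[0.0], np.cumsum(r)])
    idx = np.arange(r.size)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half, r.size - 1)
    return (csum[hi + 1] - csum[lo]) / (hi - lo + 1)


def hysteresis_labels(ratio: np.ndarray,
                      excess: float = REGIME_THRESHOLDS["excess"],
                      starvation: float = REGIME_THRESHOLDS["starvation"],
                      half_width: float = FUZZY_HALF_WIDTH) -> np.ndarray:
    """Fuzzy-boundary regime labelling with hysteresis.

    A transition into Excess requires the ratio to exceed
    ``excess + half_width``; leaving Excess requires dropping below
    ``excess - half_width`` (mirrored for Starvation).  The first sample
    is labelled by the plain thresholds.
    """
    r = np.asarray(ratio, dtype=float)
    labels = np.empty(r.shape, dtype="U1")
    state = classify_regimes(r[:1], excess, starvation)[0]
    e_in, e_out = excess + half_width, excess - half_width
    s_in, s_out = starvation - half_width, starvation + half_width
    for k, x in enumerate(r):
        if state == "E":
            if x < e_out:
                state = "S" if x < s_in else "L"
        elif state == "S":
            if x > s_out:
                state = "E" if x > e_in else "L"
        else:
            if x > e_in:
                state = "E"
            elif x < s_in:
                state = "S"
        labels[k] = state
    return labels


def filter_lifeline(ratio: np.ndarray, dt_sample: float,
                    window_s: float = SMOOTHING_WINDOW_S,
                    half_width: float = FUZZY_HALF_WIDTH) -> tuple[np.ndarray, np.ndarray]:
    """Smooth a ratio trace and label it with the hysteresis filter.

    Returns ``(smoothed_ratio, labels)``.
    """
    smooth = moving_average(ratio, dt_sample, window_s)
    return smooth, hysteresis_labels(smooth, half_width=half_width)


# ---------------------------------------------------------------------------
# residence-time and fraction statistics
# ---------------------------------------------------------------------------

def _runs(labels: np.ndarray) -> list[tuple[str, int, int]]:
    """Maximal runs as ``(label, start, length)``."""
    labels = np.asarray(labels)
    if labels.size == 0:
        return []
    change = np.flatnonzero(labels[1:] != labels[:-1]) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [labels.size]])
    return [(str(labels[s]), int(s), int(e - s)) for s, e in zip(starts, ends)]


@dataclass
class RegimeStats:
    """Per-pattern residence-time statistics from a set of lifelines."""

    durations: dict  # pattern -> np.ndarray of visit durations (s)

    def mean(self, pattern: str) -> float:
        d = self.durations.get(pattern)
        return float(np.mean(d)) if d is not None and len(d) else float("nan")

    def count(self, pattern: str) -> int:
        d = self.durations.get(pattern)
        return len(d) if d is not None else 0

    def summary(self) -> dict:
        return {
            p: {"mean_s": self.mean(p), "count": self.count(p)}
            for p in sorted(self.durations)
        }


def residence_time_stats(label_sequences, dt_sample: float) -> RegimeStats:
    """Visit durations keyed by transition pattern (flank-regime-flank).

    Each maximal run whose previous and next regimes are both known
    contributes ``length * dt_sample`` seconds to pattern
    ``prev + regime + next``; runs touching either series end are
    discarded as truncated.
    """
    if isinstance(label_sequences, np.ndarray) and label_sequences.ndim == 1:
        label_sequences = [label_sequences]
    acc: dict[str, list[float]] = defaultdict(list)
    for labels in label_sequences:
        runs = _runs(np.asarray(labels))
        for k in range(1, len(runs) - 1):
            prev_lab = runs[k - 1][0]
            lab, _, length = runs[k]
            next_lab = runs[k + 1][0]
            acc[prev_lab + lab + next_lab].append(length * dt_sample)
    return RegimeStats(durations={p: np.asarray(v) for p, v in acc.items()})


def regime_fractions(label_sequences, dt_sample: float,
                     window_s: float = 1800.0) -> dict:
    """Time fraction (%) spent in E / L / S, with a 2-SD window margin.

    The pooled label stream is cut into consecutive windows of
    ``window_s`` seconds (per lifeline), fractions are computed per
    window, and the spread across windows gives the reported margin.
    Windows shorter than half the nominal length are dropped; if the
    series is shorter than one window the whole series is one window.
    """
    if isinstance(label_sequences, np.ndarray) and label_sequences.ndim == 1:
        label_sequences = [label_sequences]
    win = max(1, int(round(window_s / dt_sample)))
    per_window = {"E": [], "L": [], "S": []}
    for labels in label_sequences:
        labels = np.asarray(labels)
        n = labels.size
        if n == 0:
            continue
        starts = range(0, n, win)
        for s in starts:
            chunk = labels[s:s + win]
            if chunk.size < win // 2 and n > win:
                continue
            for reg in per_window:
                per_window[reg].append(100.0 * np.mean(chunk == reg))
    out = {}
    for reg, vals in per_window.items():
        arr = np.asarray(vals)
        mean = float(arr.mean()) if arr.size else float("nan")
        sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
        out[reg] = {"percent": mean, "margin_2sd": 2.0 * sd, "n_windows": int(arr.size)}
    return out


def pool_histograms(pools: np.ndarray, pool_names=None, selection=None,
                    bins: int = 30) -> dict:
    """Across-parcel distribution summaries of intracellular pools.

    ``pools`` is the (Np, Npool) snapshot at one time; the standard
    deviation across parcels is the population-heterogeneity metric.
    """
    pools = np.atleast_2d(np.asarray(pools, dtype=float))
    if pools.shape[0] < 2:
        raise AnalysisError("population statistics require at least two parcels")
    npool = pools.shape[1]
    if pool_names is None:
        pool_names = [f"pool_{k}" for k in range(npool)]
    if selection is None:
        selection = range(npool)
    out = {}
    for k in selection:
        vals = pools[:, k]
        counts, edges = np.histogram(vals, bins=bins)
        out[pool_names[k]] = {
            "mean": float(vals.mean()),
            "sd": float(vals.std()),
            "counts": counts,
            "bin_edges": edges,
        }
    return out
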