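"""Per-residue disorder and low-complexity signals, and their 34-number summary.

The predictor is alignment-free, so both signals come from fast built-in
estimators: a windowed hydropathy/charge score for intrinsic disorder
(charge-hydropathy phase-plane logic: low mean hydropathy combined with high
net charge marks disorder-prone segments) and a sliding-window Shannon
entropy mask for low-complexity regions. Externally computed per-residue
scores can be injected from a 2-column text file and are used verbatim.

Each signal is condensed into the same fixed 34-statistic summary, giving
the 68-feature disorder/complexity block.
"""

from __future__ import annotations

import numpy as np

from .composition import encode
from .scales import window_means
from .tables import AA_INDEX, load_residue_scales

DISORDER_WINDOW = 21
LC_WINDOW = 12
LC_ENTROPY_THRESHOLD = 2.2  # bits
_SIGMOID_SLOPE = 6.0
# FoldIndex-style fold/unfold boundary in the charge-hydropathy plane
_FOLD_A, _FOLD_B = 2.785, 1.151


def _centered_window_means(values: np.ndarray, w: int) -> np.ndarray:
    """Mean of values over a centered window of nominal width w (clipped at ends)."""
    n = values.size
    half = w // 2
    cs = np.concatenate([[0.0], np.cumsum(values)])
    idx = np.arange(n)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half + 1, n)
    return (cs[hi] - cs[lo]) / (hi - lo)


def disorder_profile(sequence: str, window: int = DISORDER_WINDOW) -> np.ndarray:
    """Per-residue disorder propensity in [0, 1]; higher = more disordered."""
    codes = encode(sequence)
    kd = load_residue_scales()[0]
    assert kd.name == "KYTE_DOOLITTLE"
    hydropathy = (kd.as_array()[codes] + 4.5) / 9.0  # rescaled to [0, 1]
    charge = np.zeros(20)
    charge[[AA_INDEX["K"], AA_INDEX["R"]]] = 1.0
    charge[[AA_INDEX["D"], AA_INDEX["E"]]] = -1.0
    q = charge[codes]
    mean_h = _centered_window_means(hydropathy, window)
    mean_q = _centered_window_means(q, window)
    fold = _FOLD_A * mean_h - np.abs(mean_q) - _FOLD_B  # >0: predicted folded
    return 1.0 / (1.0 + np.exp(_SIGMOID_SLOPE * fold))


def low_complexity_mask(
    sequence: str,
    window: int = LC_WINDOW,
    entropy_threshold: float = LC_ENTROPY_THRESHOLD,
) -> np.ndarray:
    """0/1 mask: residue covered by any window with entropy below threshold."""
    codes = encode(sequence)
    n = codes.size
    w = min(window, n)
    mask = np.zeros(n, dtype=np.int8)
    counts = np.bincount(codes[:w], minlength=20).astype(float)
    for start in range(n - w + 1):
        if start > 0:
            counts[codes[start - 1]] -= 1
            counts[codes[start + w - 1]] += 1
        p = counts[counts > 0] / w
        entropy = -np.sum(p * np.log2(p))
        if entropy < entropy_threshold:
            mask[start : start + w] = 1
    return mask


def read_score_file(path, length: int) -> np.ndarray:
    """Load an external per-residue score (2 columns: position, score).

    The score replaces the built-in disorder/complexity signal; values are
    clipped to [0, 1]. Raises ValueError if the file length does not match
    the sequence.
    """
    data = np.loadtxt(path, ndmin=2)
    if data.shape[0] != length:
        raise ValueError(
            f"score file has {data.shape[0]} rows for a sequence of "
            f"length {length}"
        )
    return np.clip(data[:, -1], 0.0, 1.0)


_RUN_THRESHOLDS = (1, 4, 10)
_EDGE = 30  # residues averaged at each terminus

PROFILE_STAT_NAMES = tuple(
    ["mean", "median", "std", "min", "max"]
    + [f"{m}{w}" for w in (5, 15, 31) for m in ("wmin", "wmax")]
    + ["frac_above"]
    + [
        f"{stat}_minrun{t}"
        for t in _RUN_THRESHOLDS
        for stat in ("run_count", "longest_run", "mean_run", "coverage")
    ]
    + ["pos_first", "pos_q25", "pos_q50", "pos_q75", "pos_last"]
    + ["crossings", "mean_first30", "mean_last30", "mean_above", "mean_below"]
)
assert len(PROFILE_STAT_NAMES) == 34


def profile_summary34(signal: np.ndarray, length: int) -> np.ndarray:
    """Condense a per-residue signal in [0, 1] into 34 fixed statistics."""
    signal = np.asarray(signal, dtype=float)
    if signal.size != length or length < 1:
        raise ValueError("signal length must equal the sequence length (>= 1)")
    out: list[float] = [
        float(signal.mean()),
        float(np.median(signal)),
        float(signal.std()),
        float(signal.min()),
        float(signal.max()),
    ]
    for w in (5, 15, 31):
        wm = window_means(signal, w)
        out += [float(wm.min()), float(wm.max())]
    above = signal > 0.5
    out.append(above.mean())

    # run statistics of the thresholded signal at minimum run lengths 1/4/10
    padded = np.concatenate(([False], above, [False]))
    edges = np.flatnonzero(padded[1:] != padded[:-1])
    run_lengths = edges[1::2] - edges[0::2]
    for t in _RUN_THRESHOLDS:
        runs = run_lengths[run_lengths >= t]
        if runs.size:
            out += [
                runs.size / length,
                runs.max() / length,
                runs.mean() / length,
                runs.sum() / length,
            ]
        else:
            out += [0.0, 0.0, 0.0, 0.0]

    positions = np.flatnonzero(above)
    if positions.size:
        n = positions.size
        for frac in (0.0, 0.25, 0.5, 0.75, 1.0):
            k = max(1, int(np.ceil(frac * n)))
            out.append((positions[k - 1] + 1) / length)
    else:
        out += [0.0] * 5

    out.append(np.count_nonzero(above[1:] != above[:-1]) / length)
    edge = min(_EDGE, length)
    out.append(float(signal[:edge].mean()))
    out.append(float(signal[-edge:].mean()))
    out.append(float(signal[above].mean()) if above.any() else 0.0)
    out.append(float(signal[~above].mean()) if (~above).any() else 0.0)
    result = np.asarray(out, dtype=float)
    assert result.size == 34
    return result
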