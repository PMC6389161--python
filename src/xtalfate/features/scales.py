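"""Per-residue numeric-scale features (448 = 64 scales x 7 statistics).

For each bundled residue scale the sequence is mapped to a numeric profile;
the features are the whole-sequence mean plus the minimum and maximum of the
sliding-window means for window lengths 5, 15 and 31 (windows longer than
the sequence are clipped to a single full-length window).
"""

from __future__ import annotations

from functools import lru_cache
from typing import Sequence

import numpy as np

from .composition import encode
from .tables import ResidueIndexTable, load_residue_scales

WINDOWS = (5, 15, 31)


def window_means(profile: np.ndarray, w: int) -> np.ndarray:
    """Means of all contiguous windows of length min(w, len(profile))."""
    n = profile.shape[-1]
    w = min(w, n)
    cs = np.concatenate(
        [np.zeros(profile.shape[:-1] + (1,)), np.cumsum(profile, axis=-1)], axis=-1
    )
    return (cs[..., w:] - cs[..., :-w]) / w


def aaindex_features(
    sequence: str, scales: Sequence[ResidueIndexTable] | None = None
) -> np.ndarray:
    if scales is None:
        scales = load_residue_scales()
    codes = encode(sequence)
    matrix = np.stack([s.as_array() for s in scales])  # (n_scales, 20)
    profiles = matrix[:, codes]  # (n_scales, L)
    cols = [profiles.mean(axis=1)]
    for w in WINDOWS:
        wm = window_means(profiles, w)
        cols.append(wm.min(axis=1))
        cols.append(wm.max(axis=1))
    # scale-major order: (mean, min5, max5, min15, max15, min31, max31) per scale
    return np.stack(cols, axis=1).ravel()


@lru_cache(maxsize=1)
def scale_feature_names() -> tuple[str, ...]:
    stats = ["mean"] + [f"{m}{w}" for w in WINDOWS for m in ("min", "max")]
    return tuple(
        f"IDX_{scale.name}_{stat}"
        for scale in load_residue_scales()
        for stat in stats
    )
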