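"""Two-sample comparison of distance distributions and selection of
representative configurations.

The default comparison is the two-sided Mann-Whitney U rank test on
pooled per-configuration Cu-Cu distances (a Kolmogorov-Smirnov
alternative is selectable); significance is flagged at p < 0.05.
Representative configurations are those falling in the maximally
populated bin of a 2-D histogram of two structural quantities
(typically intra-dimer Cu-Cu distance and radius of gyration),
optionally intersected with a distance window around a distribution
maximum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "ComparisonResult",
    "compare_distance_samples",
    "select_representatives",
    "SIGNIFICANCE_LEVEL",
]

SIGNIFICANCE_LEVEL = 0.05

_METHODS = ("mannwhitney", "ks")


@dataclass(frozen=True)
class ComparisonResult:
    p_value: float
    test_name: str
    n1: int
    n2: int
    effect: float  # difference of means, nm
    significant: bool


def compare_distance_samples(
    d1: np.ndarray,
    d2: np.ndarray,
    method: str = "mannwhitney",
    subsample_stride: int = 1,
) -> ComparisonResult:
    """Rank-based two-sample comparison of pooled distance samples.

    ``subsample_stride`` > 1 keeps every k-th observation, a cheap
    mitigation of serial correlation between successive configurations
    of a trajectory-like ensemble.
    """
    if method not in _METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {_METHODS}")
    d1 = np.asarray(d1, dtype=float)[::subsample_stride]
    d2 = np.asarray(d2, dtype=float)[::subsample_stride]
    if d1.size < 10 or d2.size < 10:
        raise ValueError("each sample must have at least 10 values")
    if method == "mannwhitney":
        stat = sps.mannwhitneyu(d1, d2, alternative="two-sided")
    else:
        stat = sps.ks_2samp(d1, d2)
    p = float(min(stat.pvalue, 1.0))
    return ComparisonResult(
        p_value=p,
        test_name=method,
        n1=int(d1.size),
        n2=int(d2.size),
        effect=float(d1.mean() - d2.mean()),
        significant=p < SIGNIFICANCE_LEVEL,
    )


def select_representatives(
    x: np.ndarray,
    y: np.ndarray,
    bins: int | tuple[int, int] = 20,
    window_values: np.ndarray | None = None,
    window: tuple[float, float] | None = None,
) -> np.ndarray:
    """Indices of configurations in the modal bin of the 2-D histogram
    of (x, y); modal-bin ties break to the lowest flat bin index.

    If ``window`` is given, the selection is intersected with
    ``window[0] <= window_values <= window[1]`` (e.g. a Cu-Cu distance
    window around the maximum of a distance distribution); an empty
    intersection returns an empty array.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or x.shape != y.shape:
        raise ValueError("x and y must be nonempty arrays of equal length")
    counts, xe, ye = np.histogram2d(x, y, bins=bins)
    flat_mode = int(np.argmax(counts))  # argmax takes the lowest tied index
    ix, iy = np.unravel_index(flat_mode, counts.shape)
    # histogram2d membership: right edge of the last bin inclusive
    def _in_bin(v, edges, i):
        hi = v <= edges[i + 1] if i + 1 == edges.size - 1 else v < edges[i + 1]
        return (v >= edges[i]) & hi

    sel = _in_bin(x, xe, ix) & _in_bin(y, ye, iy)
    if window is not None:
        if window_values is None:
            raise ValueError("window given without window_values")
        wv = np.asarray(window_values, dtype=float)
        sel &= (wv >= window[0]) & (wv <= window[1])
    return np.flatnonzero(sel)
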