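"""Ordinal-pattern encoding and permutation entropy.

Each window of D samples (spaced ``lag`` apart) is mapped to the
permutation describing the rank order of its values: the window
{0, 5, 10, 13} becomes the pattern "0123", {0, 13, 5, 10} becomes "0312".
A pattern is stored as the lexicographic rank of its rank-string (the
Lehmer code), giving a fixed feature position in [0, D!) for every
permutation — the contract the downstream regressor relies on.

The relative frequencies of the D! patterns over all maximally overlapping
windows define the ordinal distribution; its Shannon entropy (natural log)
is the permutation entropy S, normalized by ln D! to S-bar in [0, 1].
Ordinal statistics depend only on rank order, so they are invariant under
any strictly increasing transform of the amplitudes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.stats import entropy as _shannon_entropy

__all__ = [
    "OrdinalConfig",
    "OrdinalDistribution",
    "encode_pattern",
    "pattern_codes",
    "pattern_distribution",
    "permutation_entropy",
    "normalized_pe",
]


@dataclass(frozen=True)
class OrdinalConfig:
    """Pattern length D (default 6, i.e. 720 patterns) and sample lag (default 1)."""

    D: int = 6
    lag: int = 1

    def __post_init__(self) -> None:
        if not 2 <= self.D <= 8:
            raise ValueError("D must be in [2, 8]")
        if self.lag < 1:
            raise ValueError("lag must be >= 1")

    @property
    def n_patterns(self) -> int:
        return math.factorial(self.D)

    def min_length(self) -> int:
        return (self.D - 1) * self.lag + 1


@dataclass(frozen=True)
class OrdinalDistribution:
    """Relative frequencies of the D! ordinal patterns over n_windows windows."""

    probs: np.ndarray
    n_windows: int
    config: OrdinalConfig = OrdinalConfig()

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        if p.ndim != 1 or p.size != self.config.n_patterns:
            raise ValueError(
                f"expected {self.config.n_patterns} probabilities for D={self.config.D}, got {p.size}"
            )
        if np.any(p < 0.0) or np.any(p > 1.0) or abs(p.sum() - 1.0) > 1e-12:
            raise ValueError("probabilities must lie in [0,1] and sum to 1")
        object.__setattr__(self, "probs", p)


def _lehmer_codes(windows: np.ndarray, D: int) -> np.ndarray:
    """Lexicographic rank of each window's rank-string.

    The rank-string entry of sample i is its rank within the window, ties
    broken by temporal order (earlier sample ranks lower).  Its
    lexicographic rank among all permutations is the Lehmer code
    sum_i l_i * (D-1-i)!, where l_i counts later samples strictly smaller
    than sample i — the only pairwise relation needed, so no sort is run.
    """
    codes = np.zeros(windows.shape[0], dtype=np.int64)
    for i in range(D - 1):
        l_i = (windows[:, i + 1 :] < windows[:, i, None]).sum(axis=1)
        codes += l_i * math.factorial(D - 1 - i)
    return codes


def encode_pattern(window) -> int:
    """Ordinal-pattern index of a single window of D values.

    Returns the lexicographic rank of the window's rank-string, in
    [0, D!).  The identity pattern (increasing window) has index 0; any
    strictly decreasing window has index D!-1.
    """
    w = np.asarray(window, dtype=float)
    if w.ndim != 1 or w.size < 2:
        raise ValueError("window must be 1-D with at least 2 values")
    if not np.all(np.isfinite(w)):
        raise ValueError("window contains non-finite values")
    return int(_lehmer_codes(w[None, :], w.size)[0])


def pattern_codes(x, cfg: OrdinalConfig = OrdinalConfig()) -> np.ndarray:
    """Pattern index of every (maximally overlapping) window of a series."""
    values = np.asarray(getattr(x, "values", x), dtype=float)
    if values.size < cfg.min_length():
        raise ValueError(
            f"series of length {values.size} is shorter than the minimum "
            f"{cfg.min_length()} for D={cfg.D}, lag={cfg.lag}"
        )
    if not np.all(np.isfinite(values)):
        raise ValueError("series contains non-finite values")
    windows = sliding_window_view(values, (cfg.D - 1) * cfg.lag + 1)[:, :: cfg.lag]
    return _lehmer_codes(windows, cfg.D)


def pattern_distribution(x, cfg: OrdinalConfig = OrdinalConfig()) -> OrdinalDistribution:
    """Relative frequencies of the D! ordinal patterns (window step 1)."""
    codes = pattern_codes(x, cfg)
    counts = np.bincount(codes, minlength=cfg.n_patterns)
    return OrdinalDistribution(counts / codes.size, int(codes.size), cfg)


def permutation_entropy(dist: OrdinalDistribution) -> float:
    """Shannon entropy of the ordinal distribution, in nats (0*ln 0 = 0)."""
    return float(_shannon_entropy(dist.probs))


def normalized_pe(dist: OrdinalDistribution) -> float:
    """Permutation entropy divided by its maximum ln D!, in [0, 1]."""
    return permutation_entropy(dist) / math.log(dist.config.n_patterns)
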