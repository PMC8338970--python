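"""The flicker-noise reference entropy curve S-bar_fn(alpha).

For each alpha on a grid spanning the training range [-1, 3], an ensemble
of seeded flicker-noise realizations is generated and the mean and
standard deviation of their normalized permutation entropy recorded.  The
curve peaks at alpha=0 (white noise, all patterns equally likely,
S-bar = 1) and falls off as |alpha| grows and temporal correlations bias
the pattern frequencies.

Because normalized PE at D=6 is length-dependent for short series
(only n-5 windows populate 720 patterns), the calibration length is a
first-class parameter: compare a series against a curve calibrated at a
matching (or much larger, for long series both converged) length.
Queries interpolate linearly between grid points, with alpha clamped to
the calibrated range.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .ordinal import OrdinalConfig, normalized_pe, pattern_distribution
from .synth_signals import generate_flicker

__all__ = ["FNCurve", "calibrate_curve", "lookup_sbar"]


@dataclass(frozen=True)
class FNCurve:
    """Tabulated mean (and sd) normalized PE of flicker noise per alpha."""

    alpha_grid: np.ndarray
    sbar_mean: np.ndarray
    sbar_sd: np.ndarray
    realizations: int
    series_length: int

    def __post_init__(self) -> None:
        grid = np.asarray(self.alpha_grid, dtype=float)
        mean = np.asarray(self.sbar_mean, dtype=float)
        sd = np.asarray(self.sbar_sd, dtype=float)
        if grid.size == 0:
            raise ValueError("empty curve")
        if grid.size != mean.size or grid.size != sd.size:
            raise ValueError("grid/mean/sd length mismatch")
        if np.any(np.diff(grid) <= 0):
            raise ValueError("alpha grid must be strictly increasing")
        if np.any(mean <= 0.0) or np.any(mean > 1.0 + 1e-12):
            raise ValueError("sbar_mean must lie in (0, 1]")
        object.__setattr__(self, "alpha_grid", grid)
        object.__setattr__(self, "sbar_mean", mean)
        object.__setattr__(self, "sbar_sd", sd)

    # -- persistence (CSV + JSON sidecar of settings) ----------------------

    def save(self, path) -> None:
        path = Path(path)
        header = "alpha,sbar_mean,sbar_sd"
        rows = np.column_stack([self.alpha_grid, self.sbar_mean, self.sbar_sd])
        np.savetxt(path, rows, delimiter=",", header=header, comments="", fmt="%.12g")
        sidecar = path.with_suffix(path.suffix + ".json")
        sidecar.write_text(
            json.dumps({"realizations": self.realizations, "series_length": self.series_length})
        )

    @classmethod
    def load(cls, path) -> "FNCurve":
        path = Path(path)
        rows = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
        sidecar = path.with_suffix(path.suffix + ".json")
        settings = json.loads(sidecar.read_text()) if sidecar.exists() else {}
        return cls(
            alpha_grid=rows[:, 0],
            sbar_mean=rows[:, 1],
            sbar_sd=rows[:, 2],
            realizations=int(settings.get("realizations", 0)),
            series_length=int(settings.get("series_length", 0)),
        )


def calibrate_curve(
    alpha_min: float = -1.0,
    alpha_max: float = 3.0,
    step: float = 0.05,
    realizations: int = 100,
    series_length: int = 2**17,
    seed: int = 0,
    config: OrdinalConfig = OrdinalConfig(),
) -> FNCurve:
    """Monte-Carlo calibration of S-bar_fn(alpha) on a regular alpha grid.

    Defaults: grid step 0.05 over [-1, 3], 100 realizations of 2^17
    samples per grid point.  Grid points outside [-1, 3] are rejected —
    the regressor is uncalibrated there.
    """
    if alpha_min < -1.0 or alpha_max > 3.0 or alpha_min >= alpha_max:
        raise ValueError("calibration grid must lie within [-1, 3]")
    if step > 0.1:
        raise ValueError("grid step must be <= 0.1")
    if realizations < 20:
        raise ValueError("need at least 20 realizations per grid point")
    n_pts = int(round((alpha_max - alpha_min) / step)) + 1
    grid = alpha_min + step * np.arange(n_pts)
    ss = np.random.SeedSequence(seed)
    means = np.empty(n_pts)
    sds = np.empty(n_pts)
    for j, alpha in enumerate(grid):
        children = ss.spawn(realizations)
        sbars = np.empty(realizations)
        for k, child in enumerate(children):
            x = generate_flicker(alpha, series_length, child)
            sbars[k] = normalized_pe(pattern_distribution(x.values, config))
        means[j] = sbars.mean()
        sds[j] = sbars.std(ddof=1)
    return FNCurve(grid, means, sds, realizations, series_length)


def lookup_sbar(curve: FNCurve, alpha_e: float) -> float:
    """Reference entropy S-bar_fn at alpha_e (linear interpolation, clamped)."""
    return float(np.interp(alpha_e, curve.alpha_grid, curve.sbar_mean))
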