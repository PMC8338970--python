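"""Seeded generators for the stochastic and chaotic benchmark signals.

Stochastic families
-------------------
* flicker (colored) noise with power spectrum P(f) ~ 1/f^alpha, synthesized
  in the frequency domain with Gaussian random Fourier coefficients scaled
  by f^(-alpha/2);
* fractional Gaussian noise (fGn) and fractional Brownian motion (fBm),
  sampled exactly by Davies-Harte circulant embedding of the fGn
  autocovariance (fBm is the cumulative sum of fGn increments);
* iid draws from uniform, Gaussian and Cauchy distributions.

Deterministic families
----------------------
* one-dimensional chaotic maps (beta-x / generalized Bernoulli, logistic,
  Schuster intermittency map, skew tent);
* successive maxima of the Lorenz x variable (fixed-step RK4 integration).

Transforms: noise contamination Z = (1-eta)X + eta*Y, sums of m independent
orbits, and value-preserving shuffling.

Every generator is a pure function of (parameters, n, seed): the same call
returns a bit-identical series.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any, Mapping

import numpy as np
from numba import njit

__all__ = [
    "TimeSeries",
    "NoiseSpec",
    "MapSpec",
    "LorenzSpec",
    "DegenerateOrbitError",
    "LorenzShortfallError",
    "generate_flicker",
    "generate_fractional",
    "generate_iid",
    "iterate_map",
    "lorenz_maxima",
    "mix_signals",
    "sum_of_maps",
    "shuffle_series",
    "standardize",
]

# --------------------------------------------------------------------------
# container and spec types
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class TimeSeries:
    """An ordered, finite, real-valued sample sequence plus provenance.

    ``meta`` records the generator id, its parameters and the seed, so the
    series can be regenerated exactly.
    """

    values: np.ndarray
    meta: Mapping[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size < 2:
            raise ValueError("a time series needs at least 2 samples in 1-D")
        if not np.all(np.isfinite(v)):
            raise ValueError("time series contains non-finite values")
        object.__setattr__(self, "values", v)

    @property
    def n(self) -> int:
        return int(self.values.size)

    def __len__(self) -> int:  # pragma: no cover - convenience
        return self.n


_MAP_IDS = {"betax": 0, "logistic": 1, "schuster": 2, "skewtent": 3}
_MAP_PARAM_NAMES = {"betax": "beta", "logistic": "r", "schuster": "z", "skewtent": "omega"}
_MAP_DEFAULTS = {"betax": 2.0, "logistic": 4.0, "schuster": 1.5, "skewtent": 0.1847}


@dataclass(frozen=True)
class NoiseSpec:
    """Stochastic family selector.

    ``alpha`` applies to flicker noise only (spectral exponent, training
    range [-1, 3]); ``hurst`` applies to fbm/fgn only, H in (0, 1).  The
    spectral-exponent correspondence is alpha = 2H+1 for fBm and
    alpha = 2H-1 for fGn.
    """

    family: str
    alpha: float | None = None
    hurst: float | None = None

    def __post_init__(self) -> None:
        if self.family not in {"flicker", "fbm", "fgn", "uniform", "gaussian", "cauchy"}:
            raise ValueError(f"unknown noise family {self.family!r}")
        if self.family == "flicker":
            if self.alpha is None:
                raise ValueError("flicker requires alpha")
        if self.family in {"fbm", "fgn"}:
            if self.hurst is None or not 0.0 < self.hurst < 1.0:
                raise ValueError("fbm/fgn require a Hurst index in (0, 1)")

    @property
    def equivalent_alpha(self) -> float:
        """Spectral exponent implied by the spec (alpha = 2H±1 for fBm/fGn)."""
        if self.family == "flicker":
            return float(self.alpha)
        if self.family == "fbm":
            return 2.0 * self.hurst + 1.0
        if self.family == "fgn":
            return 2.0 * self.hurst - 1.0
        return 0.0  # iid families are white


@dataclass(frozen=True)
class MapSpec:
    """One-dimensional chaotic map: id, control parameter, initial condition.

    ``x0=None`` draws the initial condition uniformly from (0.01, 0.99)
    under the generator seed.  ``transient`` iterations are discarded.
    Reference parameter values: beta=2, r=4, omega=0.1847; the Schuster
    intermittency exponent z defaults to 1.5 (z must exceed 1 for the
    1/f^z intermittent regime; z=0.5 remains runnable).
    """

    map_id: str
    parameter: float | None = None
    x0: float | None = None
    transient: int = 1000

    def __post_init__(self) -> None:
        if self.map_id not in _MAP_IDS:
            raise ValueError(f"unknown map {self.map_id!r}")
        if self.parameter is None:
            object.__setattr__(self, "parameter", _MAP_DEFAULTS[self.map_id])
        if self.x0 is not None and not 0.0 < self.x0 < 1.0:
            raise ValueError("x0 must lie in the open unit interval")
        if self.transient < 0:
            raise ValueError("transient must be >= 0")


@dataclass(frozen=True)
class LorenzSpec:
    """Lorenz flow parameters and maxima-extraction settings.

    Defaults are the chaotic regime sigma=16, R=45.92, b=4; the returned
    series is the sequence of successive local maxima of x(t) after
    ``transient_time`` time units, located by parabolic refinement of the
    discrete maximum.  ``dt`` is guarded by a self-convergence test.
    """

    sigma: float = 16.0
    R: float = 45.92
    b: float = 4.0
    dt: float = 0.005
    transient_time: float = 100.0
    n_maxima: int = 1000


class DegenerateOrbitError(RuntimeError):
    """The orbit reached an exact fixed point (e.g. x=0) and carries no signal."""


class LorenzShortfallError(RuntimeError):
    """Fewer Lorenz maxima than requested (trajectory settled or cap hit)."""


# --------------------------------------------------------------------------
# helpers
# --------------------------------------------------------------------------


def standardize(x: np.ndarray) -> np.ndarray:
    """Return ``x`` shifted to zero mean and scaled to unit variance."""
    x = np.asarray(x, dtype=float)
    sd = x.std()
    if sd == 0.0:
        raise ValueError("cannot standardize a constant series")
    return (x - x.mean()) / sd


def _as_seed_sequence(seed) -> np.random.SeedSequence:
    if isinstance(seed, np.random.SeedSequence):
        return seed
    return np.random.SeedSequence(seed)


# --------------------------------------------------------------------------
# stochastic generators
# --------------------------------------------------------------------------


def generate_flicker(alpha: float, n: int, seed) -> TimeSeries:
    """Flicker (colored) noise with power spectrum P(f) ~ 1/f^alpha.

    Frequency-domain synthesis: independent Gaussian real/imaginary Fourier
    coefficients at each positive frequency, scaled by f^(-alpha/2); the DC
    component is zero (zero-mean output) and no low-frequency cutoff is
    applied beyond the fundamental 1/n.  The output is standardized to unit
    variance (ordinal statistics are amplitude-invariant).

    alpha=0 is white noise, alpha=2 Brownian-like; the regressor training
    range is [-1, 3], and values outside [-2, 4] are rejected.
    """
    if not -2.0 <= alpha <= 4.0:
        raise ValueError(f"alpha={alpha} outside the sane range [-2, 4]")
    n = int(n)
    if n < 2:
        raise ValueError("n must be >= 2")
    rng = np.random.default_rng(_as_seed_sequence(seed))
    f = np.fft.rfftfreq(n)
    amp = np.zeros_like(f)
    amp[1:] = f[1:] ** (-alpha / 2.0)
    re = rng.standard_normal(f.size) * amp
    im = rng.standard_normal(f.size) * amp
    im[0] = 0.0
    if n % 2 == 0:
        im[-1] = 0.0  # Nyquist coefficient of a real signal is real
    x = np.fft.irfft(re + 1j * im, n=n)
    x = standardize(x)
    return TimeSeries(x, {"generator": "flicker", "alpha": float(alpha), "n": n, "seed": seed})


def _fgn_davies_harte(hurst: float, n: int, rng: np.random.Generator) -> np.ndarray:
    """Exact fGn sample via circulant embedding of the autocovariance."""
    k = np.arange(n + 1, dtype=float)
    h2 = 2.0 * hurst
    gamma = 0.5 * ((k + 1.0) ** h2 - 2.0 * k**h2 + np.abs(k - 1.0) ** h2)
    # symmetric circulant first row of size 2n: gamma(0..n) then gamma(n-1..1)
    row = np.concatenate([gamma, gamma[-2:0:-1]])
    lam = np.fft.fft(row).real
    # the embedding is nonnegative definite for fGn; clip fp dust
    lam = np.clip(lam, 0.0, None)
    g = rng.standard_normal(row.size)
    x = np.fft.ifft(np.sqrt(lam) * np.fft.fft(g)).real[:n]
    return x


def generate_fractional(spec: NoiseSpec, n: int, seed) -> TimeSeries:
    """Fractional Gaussian noise or fractional Brownian motion.

    fGn is sampled exactly (Davies-Harte); fBm is the running sum of fGn
    increments, so H=0.5 gives classical Brownian motion with independent
    increments and fGn at H=0.5 is white noise.
    """
    if spec.family not in {"fbm", "fgn"}:
        raise ValueError("generate_fractional expects an fbm or fgn NoiseSpec")
    n = int(n)
    if n < 2:
        raise ValueError("n must be >= 2")
    rng = np.random.default_rng(_as_seed_sequence(seed))
    incr = _fgn_davies_harte(spec.hurst, n, rng)
    x = np.cumsum(incr) if spec.family == "fbm" else incr
    meta = {"generator": spec.family, "hurst": spec.hurst, "n": n, "seed": seed}
    return TimeSeries(x, meta)


def generate_iid(dist: str, n: int, seed) -> TimeSeries:
    """Independent identically distributed draws: uniform(0,1), standard
    normal, or standard Cauchy."""
    n = int(n)
    if n < 2:
        raise ValueError("n must be >= 2")
    rng = np.random.default_rng(_as_seed_sequence(seed))
    if dist == "uniform":
        x = rng.uniform(0.0, 1.0, n)
    elif dist == "gaussian":
        x = rng.standard_normal(n)
    elif dist == "cauchy":
        x = rng.standard_cauchy(n)
    else:
        raise ValueError(f"unknown iid distribution {dist!r}")
    return TimeSeries(x, {"generator": f"iid_{dist}", "n": n, "seed": seed})


# --------------------------------------------------------------------------
# chaotic maps
# --------------------------------------------------------------------------


@njit(cache=False)
def _iterate_kernel(map_id: int, p: float, x0: float, n: int, transient: int):
    out = np.empty(n)
    x = x0
    for t in range(transient + n):
        if map_id == 0:  # beta-x: x -> beta*x mod 1
            xn = (p * x) % 1.0
        elif map_id == 1:  # logistic: x -> r x (1-x)
            xn = p * x * (1.0 - x)
        elif map_id == 2:  # Schuster: x -> x + x^z mod 1
            xn = (x + x**p) % 1.0
        else:  # skew tent
            xn = x / p if x <= p else (1.0 - x) / (1.0 - p)
        if xn == x or xn == 0.0:
            return out, t  # degenerate orbit at step t
        x = xn
        if t >= transient:
            out[t - transient] = x
    return out, -1


@njit(cache=False)
def _betax_digits_kernel(digits, beta: float, K: int, n: int, transient: int):
    out = np.empty(n)
    for t in range(n):
        x = 0.0
        base = t + transient
        for j in range(K - 1, -1, -1):
            x = (x + digits[base + j]) / beta
        out[t] = x
    return out


def _iterate_betax_exact(beta: int, n: int, transient: int, rng: np.random.Generator):
    """Exact beta-x orbit for integer beta via its symbolic digit stream.

    In base beta the map x -> beta*x mod 1 is a digit shift, so a double
    orbit of the beta=2 map collapses to exactly 0 within ~1100 iterations
    (each step discards one mantissa bit).  Drawing an iid base-beta digit
    stream and reading x_t as the first K digits from position t gives the
    true orbit of a uniformly drawn infinite-precision initial condition,
    truncated to full double precision.
    """
    K = int(math.ceil(53.0 / math.log2(beta)))
    digits = rng.integers(0, beta, size=transient + n + K).astype(np.float64)
    return _betax_digits_kernel(digits, float(beta), K, n, transient)


def iterate_map(spec: MapSpec, n: int, seed=None) -> TimeSeries:
    """Iterate a chaotic interval map, discarding the transient.

    The initial condition is ``spec.x0`` when given, otherwise drawn
    uniformly from (0.01, 0.99) under ``seed``.  Orbits that reach an exact
    fixed point (including 0) raise :class:`DegenerateOrbitError`.

    The beta-x map with integer beta and a seed-drawn initial condition is
    iterated exactly through its base-beta digit representation (see
    :func:`_iterate_betax_exact`); floating-point iteration of that map is
    a bit shift and always collapses to the degenerate orbit at 0.
    """
    n = int(n)
    if n < 2:
        raise ValueError("n must be >= 2")
    x0 = spec.x0
    if x0 is None:
        if seed is None:
            raise ValueError("either spec.x0 or a seed is required")
        rng = np.random.default_rng(_as_seed_sequence(seed))
        if spec.map_id == "betax" and float(spec.parameter).is_integer() and spec.parameter >= 2:
            out = _iterate_betax_exact(int(spec.parameter), n, spec.transient, rng)
            meta = {
                "generator": "betax",
                "beta": spec.parameter,
                "x0": "digit-stream",
                "transient": spec.transient,
                "n": n,
                "seed": seed,
            }
            return TimeSeries(out, meta)
        x0 = rng.uniform(0.01, 0.99)
    out, bad = _iterate_kernel(_MAP_IDS[spec.map_id], float(spec.parameter), float(x0), n, spec.transient)
    if bad >= 0:
        raise DegenerateOrbitError(
            f"{spec.map_id} orbit from x0={x0!r} reached a fixed point at iteration {bad}"
        )
    meta = {
        "generator": spec.map_id,
        _MAP_PARAM_NAMES[spec.map_id]: spec.parameter,
        "x0": float(x0),
        "transient": spec.transient,
        "n": n,
        "seed": seed,
    }
    return TimeSeries(out, meta)


# --------------------------------------------------------------------------
# Lorenz flow
# --------------------------------------------------------------------------


@njit(cache=False)
def _lorenz_maxima_kernel(
    sigma: float,
    R: float,
    b: float,
    dt: float,
    transient_steps: int,
    n_maxima: int,
    max_steps: int,
    x: float,
    y: float,
    z: float,
):
    maxima = np.empty(n_maxima)
    count = 0
    xm2 = x
    xm1 = x
    steps = 0
    settled = 0
    while count < n_maxima and steps < max_steps:
        # classical RK4 step of the Lorenz field
        k1x = sigma * (y - x)
        k1y = x * (R - z) - y
        k1z = x * y - b * z
        x2, y2, z2 = x + 0.5 * dt * k1x, y + 0.5 * dt * k1y, z + 0.5 * dt * k1z
        k2x = sigma * (y2 - x2)
        k2y = x2 * (R - z2) - y2
        k2z = x2 * y2 - b * z2
        x3, y3, z3 = x + 0.5 * dt * k2x, y + 0.5 * dt * k2y, z + 0.5 * dt * k2z
        k3x = sigma * (y3 - x3)
        k3y = x3 * (R - z3) - y3
        k3z = x3 * y3 - b * z3
        x4, y4, z4 = x + dt * k3x, y + dt * k3y, z + dt * k3z
        k4x = sigma * (y4 - x4)
        k4y = x4 * (R - z4) - y4
        k4z = x4 * y4 - b * z4
        x = x + dt * (k1x + 2.0 * k2x + 2.0 * k3x + k4x) / 6.0
        y = y + dt * (k1y + 2.0 * k2y + 2.0 * k3y + k4y) / 6.0
        z = z + dt * (k1z + 2.0 * k2z + 2.0 * k3z + k4z) / 6.0
        steps += 1
        if steps > transient_steps + 2:
            if xm1 > xm2 and xm1 > x:
                # parabolic refinement of the vertex through three samples
                denom = xm2 - 2.0 * xm1 + x
                if denom < 0.0:
                    peak = xm1 - 0.125 * (xm2 - x) * (xm2 - x) / denom
                else:
                    peak = xm1
                maxima[count] = peak
                count += 1
                # a settling trajectory emits near-identical maxima
                if count >= 2 and abs(maxima[count - 1] - maxima[count - 2]) < 1e-10:
                    settled += 1
                    if settled >= 5:
                        return maxima, count, 1
                else:
                    settled = 0
        xm2 = xm1
        xm1 = x
    status = 0 if count == n_maxima else 2
    return maxima, count, status


def lorenz_maxima(spec: LorenzSpec, seed) -> TimeSeries:
    """Successive local maxima of the Lorenz x variable.

    Integrates the flow with fixed-step RK4, discards ``transient_time``,
    and records each local maximum of x (discrete maximum refined by a
    parabola through its three neighbouring samples).  Raises
    :class:`LorenzShortfallError` when the trajectory settles onto a fixed
    point or the integration cap is reached before ``n_maxima`` maxima.
    """
    rng = np.random.default_rng(_as_seed_sequence(seed))
    x0, y0, z0 = rng.uniform(1.0, 10.0, 3)
    transient_steps = int(round(spec.transient_time / spec.dt))
    # chaotic maxima arrive every ~0.5-1 time units; generous cap
    max_steps = transient_steps + int(2000.0 / spec.dt) + spec.n_maxima * int(5.0 / spec.dt)
    maxima, count, status = _lorenz_maxima_kernel(
        spec.sigma, spec.R, spec.b, spec.dt, transient_steps, spec.n_maxima, max_steps, x0, y0, z0
    )
    if status != 0:
        reason = "trajectory settled onto a fixed point" if status == 1 else "integration cap reached"
        raise LorenzShortfallError(
            f"found {count} of {spec.n_maxima} requested Lorenz maxima ({reason}); "
            f"parameters sigma={spec.sigma}, R={spec.R}, b={spec.b} may not be chaotic"
        )
    meta = {
        "generator": "lorenz_maxima",
        "sigma": spec.sigma,
        "R": spec.R,
        "b": spec.b,
        "dt": spec.dt,
        "transient_time": spec.transient_time,
        "seed": seed,
        "x0": (float(x0), float(y0), float(z0)),
    }
    return TimeSeries(maxima, meta)


# --------------------------------------------------------------------------
# transforms
# --------------------------------------------------------------------------


def mix_signals(x: TimeSeries, y: TimeSeries, eta: float, standardize_inputs: bool = True) -> TimeSeries:
    """Noise contamination Z_t = (1-eta) X_t + eta Y_t.

    By default both inputs are standardized to zero mean / unit variance
    first, so eta is a comparable amplitude fraction: eta=0 returns X
    (standardized), eta=1 returns Y.  ``standardize_inputs=False`` applies
    the mixing rule to the raw amplitudes.
    """
    if not 0.0 <= eta <= 1.0:
        raise ValueError("eta must lie in [0, 1]")
    if standardize_inputs:
        xv, yv = standardize(x.values), standardize(y.values)
    else:
        xv, yv = x.values, y.values
    if xv.size != yv.size:
        raise ValueError("mix_signals requires equal-length series")
    z = (1.0 - eta) * xv + eta * yv
    return TimeSeries(z, {"generator": "mix", "eta": float(eta), "x": dict(x.meta), "y": dict(y.meta)})


def sum_of_maps(spec: MapSpec, m: int, n: int, seed) -> TimeSeries:
    """Pointwise sum of ``m`` independent orbits of the same map, standardized.

    Each replicate draws its own initial condition from a child seed; by the
    central limit theorem the sample distribution approaches a Gaussian as m
    grows, washing out the deterministic structure.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    children = _as_seed_sequence(seed).spawn(m)
    total = np.zeros(n)
    for child in children:
        total += iterate_map(spec, n, child).values
    return TimeSeries(
        standardize(total),
        {"generator": f"sum_{spec.map_id}", "m": m, "n": n, "seed": seed,
         _MAP_PARAM_NAMES[spec.map_id]: spec.parameter},
    )


def shuffle_series(x, seed):
    """Uniformly random permutation of the samples (exact multiset preserved).

    Accepts a :class:`TimeSeries` or a plain array; a length-1 input is
    returned unchanged.
    """
    if isinstance(x, TimeSeries):
        rng = np.random.default_rng(_as_seed_sequence(seed))
        shuffled = rng.permutation(x.values)
        return TimeSeries(shuffled, {"generator": "shuffle", "seed": seed, "source": dict(x.meta)})
    arr = np.asarray(x, dtype=float)
    if arr.size <= 1:
        return arr
    rng = np.random.default_rng(_as_seed_sequence(seed))
    return rng.permutation(arr)
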