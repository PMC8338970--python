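"""Seeded reproductions of the benchmark experiments.

Covers the standard validation battery: the ten-system summary table
(five stochastic, five chaotic generators), the noise-contamination sweep
over eta, the aggregation sweep over m summed maps, the series-length
robustness sweep, and the regression-error-vs-length grid.  Every output
is a DataFrame writable as CSV with a '#'-prefixed metadata header
(spec, seed, model/curve hashes) so results are fully regenerable.

Desk-scale defaults (100 replicates of 2^17 samples; 20 Lorenz replicates
of 2^15 maxima) stand in for the reference 1000 x 2^20 ensembles: the
ordinal probabilities and entropy statistics are converged well below
those sizes, so only the ensemble standard errors differ.
"""

from __future__ import annotations

import hashlib
import itertools
import math
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .alpha_regressor import RegressorModel
from .classifier import analyze
from .fn_reference import FNCurve, calibrate_curve
from .ordinal import OrdinalConfig, pattern_distribution
from .synth_signals import (
    LorenzSpec,
    MapSpec,
    NoiseSpec,
    TimeSeries,
    generate_flicker,
    generate_fractional,
    generate_iid,
    iterate_map,
    lorenz_maxima,
    mix_signals,
    shuffle_series,
    sum_of_maps,
)

__all__ = [
    "ExperimentSpec",
    "STOCHASTIC_SYSTEMS",
    "CHAOTIC_SYSTEMS",
    "generate_system",
    "run_benchmark_table",
    "run_eta_sweep",
    "run_m_sweep",
    "run_length_sweep",
    "run_mae_vs_length",
    "make_fixtures",
    "write_csv",
]

# system name -> callable(n, seed) -> TimeSeries
STOCHASTIC_SYSTEMS = {
    "fn_alpha0": lambda n, seed: generate_flicker(0.0, n, seed),
    "fbm_h0.5": lambda n, seed: generate_fractional(NoiseSpec("fbm", hurst=0.5), n, seed),
    "fgn_h0.5": lambda n, seed: generate_fractional(NoiseSpec("fgn", hurst=0.5), n, seed),
    "cauchy": lambda n, seed: generate_iid("cauchy", n, seed),
    "uniform": lambda n, seed: generate_iid("uniform", n, seed),
}

CHAOTIC_SYSTEMS = {
    "betax": lambda n, seed: iterate_map(MapSpec("betax"), n, seed),
    "logistic": lambda n, seed: iterate_map(MapSpec("logistic"), n, seed),
    "schuster": lambda n, seed: iterate_map(MapSpec("schuster"), n, seed),
    "skewtent": lambda n, seed: iterate_map(MapSpec("skewtent"), n, seed),
    "lorenz": lambda n, seed: lorenz_maxima(LorenzSpec(n_maxima=n), seed),
}

ALL_SYSTEMS = {**STOCHASTIC_SYSTEMS, **CHAOTIC_SYSTEMS}


def generate_system(name: str, n: int, seed) -> TimeSeries:
    """Generate one series of a named benchmark system."""
    try:
        return ALL_SYSTEMS[name](n, seed)
    except KeyError:
        raise ValueError(f"unknown system {name!r}; choose from {sorted(ALL_SYSTEMS)}") from None


@dataclass(frozen=True)
class ExperimentSpec:
    """Ensemble sizes and seed for one scripted experiment.

    ``lorenz_replicates``/``lorenz_maxima`` bound the flow integration,
    which dominates runtime (each maximum costs ~70 RK4 steps).
    """

    replicates: int = 100
    series_length: int = 2**17
    lorenz_replicates: int = 20
    lorenz_n_maxima: int = 2**15
    seed: int = 7

    def __post_init__(self) -> None:
        if self.replicates < 1 or self.lorenz_replicates < 1:
            raise ValueError("replicates must be >= 1")


def _model_hash(model: RegressorModel) -> str:
    h = hashlib.sha256()
    for arr in (model.W1, model.b1, model.W2, model.b2):
        h.update(np.ascontiguousarray(arr).tobytes())
    return h.hexdigest()[:12]


def _curve_hash(curve: FNCurve) -> str:
    h = hashlib.sha256()
    h.update(curve.alpha_grid.tobytes())
    h.update(curve.sbar_mean.tobytes())
    return h.hexdigest()[:12]


def write_csv(df: pd.DataFrame, path, meta: dict) -> None:
    """Write a DataFrame as CSV preceded by '#'-prefixed metadata lines."""
    path = Path(path)
    with path.open("w") as fh:
        for key, value in meta.items():
            fh.write(f"# {key}: {value}\n")
        df.to_csv(fh, index=False)


def _ensemble(spec: ExperimentSpec, system: str, model, curve, n=None, replicates=None):
    """alpha_e and Omega for a seeded ensemble of one system."""
    if n is None:
        n = spec.lorenz_n_maxima if system == "lorenz" else spec.series_length
    if replicates is None:
        replicates = spec.lorenz_replicates if system == "lorenz" else spec.replicates
    children = np.random.SeedSequence([spec.seed, _SYSTEM_TAGS[system]]).spawn(replicates)
    alphas = np.empty(replicates)
    omegas = np.empty(replicates)
    for k, child in enumerate(children):
        x = generate_system(system, n, child)
        res = analyze(x, model, curve)
        alphas[k] = res.alpha_e_raw
        omegas[k] = res.omega
    return alphas, omegas


_SYSTEM_TAGS = {name: i for i, name in enumerate(ALL_SYSTEMS)}


def run_benchmark_table(spec: ExperimentSpec, model: RegressorModel, curve: FNCurve) -> pd.DataFrame:
    """Mean and sd of alpha_e and Omega for the ten benchmark systems."""
    _require(model, curve)
    rows = []
    for kind, names in (("stochastic", STOCHASTIC_SYSTEMS), ("chaotic", CHAOTIC_SYSTEMS)):
        for name in names:
            alphas, omegas = _ensemble(spec, name, model, curve)
            if alphas.size == 1:
                warnings.warn(f"{name}: single replicate, sd reported as 0", stacklevel=2)
            rows.append(
                {
                    "system": name,
                    "kind": kind,
                    "alpha_e_mean": alphas.mean(),
                    "alpha_e_sd": alphas.std(ddof=1) if alphas.size > 1 else 0.0,
                    "omega_mean": omegas.mean(),
                    "omega_sd": omegas.std(ddof=1) if omegas.size > 1 else 0.0,
                    "replicates": alphas.size,
                }
            )
    return pd.DataFrame(rows)


def run_eta_sweep(
    spec: ExperimentSpec,
    system: str,
    model: RegressorModel,
    curve: FNCurve,
    etas=tuple(np.round(np.arange(0.0, 1.01, 0.1), 10)),
) -> pd.DataFrame:
    """Omega vs. noise fraction eta for Z = (1-eta)X + eta*Y.

    X is a chaotic series, Y uniform white noise (both standardized before
    mixing); a shuffled-X control column accompanies each eta.  Reports
    median and IQR because Omega is bounded below by 0.
    """
    _require(model, curve)
    if system not in CHAOTIC_SYSTEMS:
        raise ValueError(f"eta sweep expects a chaotic system, got {system!r}")
    n = spec.lorenz_n_maxima if system == "lorenz" else spec.series_length
    replicates = spec.lorenz_replicates if system == "lorenz" else spec.replicates
    children = np.random.SeedSequence([spec.seed, 101, _SYSTEM_TAGS[system]]).spawn(replicates)
    rows = []
    for eta in etas:
        omegas = np.empty(replicates)
        shuffled = np.empty(replicates)
        for k, child in enumerate(children):
            sx, sy, ssh = child.spawn(3)
            x = generate_system(system, n, sx)
            y = generate_iid("uniform", x.n, sy)
            omegas[k] = analyze(mix_signals(x, y, float(eta)), model, curve).omega
            shuffled[k] = analyze(
                mix_signals(shuffle_series(x, ssh), y, float(eta)), model, curve
            ).omega
        q25, q50, q75 = np.percentile(omegas, [25, 50, 75])
        rows.append(
            {
                "eta": float(eta),
                "omega_median": q50,
                "omega_q25": q25,
                "omega_q75": q75,
                "omega_mean": omegas.mean(),
                "omega_shuffled_median": float(np.median(shuffled)),
            }
        )
    return pd.DataFrame(rows)


def run_m_sweep(
    spec: ExperimentSpec,
    model: RegressorModel,
    curve: FNCurve,
    ms=(1, 2, 5, 10, 50),
    map_spec: MapSpec = MapSpec("logistic"),
) -> pd.DataFrame:
    """Omega vs. the number m of independent summed map orbits."""
    _require(model, curve)
    rows = []
    for m in ms:
        children = np.random.SeedSequence([spec.seed, 202, m]).spawn(spec.replicates)
        omegas = np.array(
            [
                analyze(sum_of_maps(map_spec, m, spec.series_length, child), model, curve).omega
                for child in children
            ]
        )
        q25, q50, q75 = np.percentile(omegas, [25, 50, 75])
        rows.append(
            {
                "m": m,
                "omega_median": q50,
                "omega_q25": q25,
                "omega_q75": q75,
                "omega_mean": omegas.mean(),
            }
        )
    return pd.DataFrame(rows)


def run_length_sweep(
    spec: ExperimentSpec,
    model: RegressorModel,
    lengths=(64, 128, 256, 512, 1024, 2048, 4096),
    systems=None,
    curve_step: float = 0.1,
    curve_realizations: int = 100,
) -> pd.DataFrame:
    """Omega vs. series length N for every benchmark system.

    Short-series entropies are compared against a reference curve
    calibrated at the *same* length N, since normalized PE at D=6 is
    strongly length-dependent when N is not much larger than 720.
    """
    if systems is None:
        systems = list(ALL_SYSTEMS)
    rows = []
    for n in lengths:
        curve_n = calibrate_curve(
            step=curve_step,
            realizations=curve_realizations,
            series_length=n,
            seed=spec.seed + 1,
        )
        for name in systems:
            replicates = spec.lorenz_replicates if name == "lorenz" else spec.replicates
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # short-series reliability warning
                alphas, omegas = _ensemble(
                    spec, name, model, curve_n, n=n, replicates=replicates
                )
            rows.append(
                {
                    "N": n,
                    "system": name,
                    "kind": "chaotic" if name in CHAOTIC_SYSTEMS else "stochastic",
                    "omega_mean": omegas.mean(),
                    "omega_sd": omegas.std(ddof=1) if omegas.size > 1 else 0.0,
                    "alpha_e_mean": alphas.mean(),
                    "replicates": replicates,
                }
            )
    return pd.DataFrame(rows)


def run_mae_vs_length(
    spec: ExperimentSpec,
    model: RegressorModel,
    lengths=(2**8, 2**10, 2**12, 2**14, 2**16),
    alphas=tuple(np.round(np.arange(-1.0, 3.01, 0.5), 10)),
) -> pd.DataFrame:
    """Mean absolute error of alpha_e over an (alpha, N) grid of flicker noise."""
    rows = []
    for n, alpha in itertools.product(lengths, alphas):
        children = np.random.SeedSequence(
            [spec.seed, 303, n, int(round((alpha + 1) * 100))]
        ).spawn(spec.replicates)
        errs = np.empty(spec.replicates)
        for k, child in enumerate(children):
            x = generate_flicker(float(alpha), n, child)
            probs = pattern_distribution(x.values).probs
            errs[k] = abs(float(model.predict(probs)[0]) - alpha)
        rows.append({"N": n, "alpha": float(alpha), "mae": errs.mean()})
    return pd.DataFrame(rows)


def _require(model, curve) -> None:
    if model is None:
        raise ValueError("no trained model: run the training stage first (chaostoch train)")
    if curve is None:
        raise ValueError("no reference curve: run the calibration first (chaostoch calibrate)")


# --------------------------------------------------------------------------
# deterministic test fixtures
# --------------------------------------------------------------------------


def _oracle_distribution(values: np.ndarray, D: int = 6) -> np.ndarray:
    """Naive per-window argsort oracle for the ordinal distribution."""
    perms = {p: i for i, p in enumerate(itertools.permutations(range(D)))}
    counts = np.zeros(math.factorial(D))
    for start in range(values.size - D + 1):
        w = values[start : start + D]
        order = np.argsort(w, kind="stable")
        ranks = np.empty(D, dtype=int)
        ranks[order] = np.arange(D)
        counts[perms[tuple(ranks)]] += 1
    return counts / counts.sum()


def make_fixtures(seed: int, outdir) -> list[Path]:
    """Write one small deterministic series per system plus its oracle
    ordinal distribution, for use as regression-test fixtures."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    n = 4096
    for i, name in enumerate(ALL_SYSTEMS):
        x = generate_system(name, n, np.random.SeedSequence([seed, i]))
        series_path = outdir / f"{name}.txt"
        np.savetxt(series_path, x.values, fmt="%.17g")
        dist = _oracle_distribution(x.values)
        dist_path = outdir / f"{name}_ordinal.csv"
        np.savetxt(
            dist_path,
            np.column_stack([np.arange(dist.size), dist]),
            delimiter=",",
            header="pattern_index,probability",
            comments="",
            fmt=["%d", "%.17g"],
        )
        written.extend([series_path, dist_path])
    return written
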