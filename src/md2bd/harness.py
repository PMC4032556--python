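"""Run configuration, trajectory containers/IO and statistical estimators.

Everything here is model-agnostic plumbing: the trajectory-ensemble
container shared by all engines, the mean-squared-displacement estimator,
the distribution comparison helpers (Kolmogorov–Smirnov against a
continuous CDF, chi-square against a binned density), and lossless CSV /
JSON round-tripping of trajectories and run configurations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, ParameterError

__all__ = [
    "TrajectoryEnsemble",
    "estimate_msd",
    "compare_distribution",
    "write_trajectory_csv",
    "read_trajectory_csv",
    "load_config",
]


@dataclass
class TrajectoryEnsemble:
    """Per-realization, per-timepoint heavy-particle states.

    Attributes
    ----------
    times : numpy.ndarray, shape (nt,)
        Common, strictly increasing time grid.
    X : numpy.ndarray, shape (n_real, nt, dim)
        Positions (dim = 1 or 3).
    V : numpy.ndarray or None
        Velocities on the same grid, when the integrator tracks them.
    regime : numpy.ndarray or None, shape (n_real, nt)
        Integer regime flag per record (application runs).
    bound : numpy.ndarray or None, shape (n_real,)
        Binding time per realization (NaN when unbound).
    meta : dict
        Run parameters and audit counters.
    """

    times: np.ndarray
    X: np.ndarray
    V: np.ndarray | None = None
    regime: np.ndarray | None = None
    bound: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 3 or self.X.shape[1] != self.times.size:
            raise ParameterError("X must have shape (n_real, nt, dim)")
        if np.any(np.diff(self.times) < 0):
            raise ParameterError("time grid must be monotone")

    @property
    def n_realizations(self) -> int:
        return self.X.shape[0]

    @property
    def dim(self) -> int:
        return self.X.shape[2]


def estimate_msd(ensemble: TrajectoryEnsemble) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Ensemble mean squared displacement with standard errors.

    Returns ``(times, msd, se)`` where ``msd[k] = E[|X(t_k) - X(0)|^2]``
    (summed over components) and ``se`` is the sample standard deviation of
    the squared displacement divided by ``sqrt(n_real)``.

    Raises
    ------
    ParameterError
        For ensembles with fewer than 2 realizations.
    """
    if ensemble.n_realizations < 2:
        raise ParameterError("MSD needs at least 2 realizations")
    disp2 = np.sum((ensemble.X - ensemble.X[:, :1, :]) ** 2, axis=2)
    msd = disp2.mean(axis=0)
    se = disp2.std(axis=0, ddof=1) / np.sqrt(ensemble.n_realizations)
    return ensemble.times.copy(), msd, se


def compare_distribution(samples, reference, alpha: float = 0.01,
                         bins: int | np.ndarray = 30) -> dict:
    """Goodness-of-fit of samples against a reference law.

    Parameters
    ----------
    samples : array_like
        At least 100 one-dimensional observations.
    reference : callable or tuple
        Either a vectorised CDF (Kolmogorov–Smirnov test) or a tuple
        ``(bin_edges, expected_probabilities)`` for a chi-square test.
    alpha : float
        Significance level of the pass/fail verdict.
    bins : int or array
        Binning used only when a chi-square test is requested with an
        integer bin count.

    Returns
    -------
    dict with keys ``test``, ``statistic``, ``pvalue``, ``passed``.
    """
    samples = np.asarray(samples, dtype=float).ravel()
    if samples.size < 100:
        raise ParameterError("need at least 100 samples")
    if np.ptp(samples) == 0:
        raise ParameterError("degenerate (constant) sample")
    if callable(reference):
        res = stats.kstest(samples, reference)
        return {"test": "ks", "statistic": float(res.statistic),
                "pvalue": float(res.pvalue), "passed": bool(res.pvalue > alpha)}
    edges, probs = reference
    edges = np.asarray(edges, dtype=float)
    probs = np.asarray(probs, dtype=float)
    obs, _ = np.histogram(samples, bins=edges)
    inside = obs.sum()
    exp = probs / probs.sum() * inside
    keep = exp > 5  # merge ultra-sparse bins into the test implicitly
    res = stats.chisquare(obs[keep], exp[keep] * obs[keep].sum() / exp[keep].sum())
    return {"test": "chi2", "statistic": float(res.statistic),
            "pvalue": float(res.pvalue), "passed": bool(res.pvalue > alpha)}


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

def write_trajectory_csv(path, ensemble: TrajectoryEnsemble) -> None:
    """Write an ensemble to CSV in long format at full float precision.

    Columns: ``realization, t, X1..Xd[, V1..Vd][, regime]``.
    """
    n_real, nt, dim = ensemble.X.shape
    cols = {"realization": np.repeat(np.arange(n_real), nt),
            "t": np.tile(ensemble.times, n_real)}
    for d in range(dim):
        cols[f"X{d + 1}"] = ensemble.X[:, :, d].ravel()
    if ensemble.V is not None:
        for d in range(dim):
            cols[f"V{d + 1}"] = ensemble.V[:, :, d].ravel()
    if ensemble.regime is not None:
        cols["regime"] = ensemble.regime.ravel()
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.17g")


def read_trajectory_csv(path) -> TrajectoryEnsemble:
    """Read an ensemble written by :func:`write_trajectory_csv`."""
    df = pd.read_csv(path, float_precision="round_trip")
    reals = np.unique(df["realization"].to_numpy())
    n_real = reals.size
    times = df.loc[df["realization"] == reals[0], "t"].to_numpy()
    nt = times.size
    xcols = sorted(c for c in df.columns if c.startswith("X"))
    vcols = sorted(c for c in df.columns if c.startswith("V"))
    X = df[xcols].to_numpy().reshape(n_real, nt, len(xcols))
    V = df[vcols].to_numpy().reshape(n_real, nt, len(vcols)) if vcols else None
    regime = (df["regime"].to_numpy().reshape(n_real, nt)
              if "regime" in df.columns else None)
    return TrajectoryEnsemble(times=times, X=X, V=V, regime=regime)


_SCHEMAS = {
    "bath": {"model": str, "mu": (int, float), "gamma": (int, float),
             "D": (int, float)},
}


def _require(cfg: dict, key: str, types, path: str) -> None:
    if key not in cfg:
        raise ConfigurationError(f"missing required field '{path}{key}'")
    if not isinstance(cfg[key], types):
        raise ConfigurationError(
            f"field '{path}{key}' has type {type(cfg[key]).__name__}, "
            f"expected {types}")


def load_config(path, required: dict | None = None) -> dict:
    """Load a JSON run configuration and validate required fields.

    Parameters
    ----------
    path : str or Path
    required : dict, optional
        Mapping ``field -> type or tuple of types``; nested fields use
        dotted paths (one level, e.g. ``"bath.mu"``).

    Raises
    ------
    ConfigurationError
        Naming the missing/mistyped field.
    """
    with open(path) as fh:
        cfg = json.load(fh)
    if not isinstance(cfg, dict):
        raise ConfigurationError("configuration root must be a JSON object")
    for key, types in (required or {}).items():
        if "." in key:
            head, tail = key.split(".", 1)
            _require(cfg, head, dict, "")
            _require(cfg[head], tail, types, head + ".")
        else:
            _require(cfg, key, types, "")
    return cfg
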