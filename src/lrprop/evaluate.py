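"""Benchmarking proportionality against correlation on data with known truth.

The study design: simulate absolute counts (so the true pairwise association
is knowable), close them into relative abundances, then score five measures
of dependence against the *absolute correlation* — the Pearson correlation of
the log absolute counts, which no purely relative method can observe:

1. ``corr_relative``     — Pearson r of the log relative data
2. ``corr_clr``          — Pearson r of the clr-transformed relative data
3. ``rho``               — proportionality rho on clr-transformed relative data
4. ``phi_transformed``   — f(phi), phi mapped into [-1, 1]
5. ``phi_s_transformed`` — f(phi_s); identical to rho by construction

where ``f(x) = 1 - 2 * logistic(ln x) = (1 - x) / (1 + x)`` maps the
dissimilarity range [0, inf) onto the correlation range, with
``rho = f(phi_s)`` exactly.

A *spurious event* is a pair a measure calls strongly associated
(|measure| >= theta) while the absolute correlation is negligible
(|absolute r| <= theta0).  The report tabulates, per measure, the mean
squared error against absolute correlation, the spurious-event count, and
the MSE over the spurious pairs alone.
"""

from __future__ import annotations

import warnings
from typing import Optional

import numpy as np
import pandas as pd

from .io import CountMatrix
from .metrics import phi, phi_s, rho
from .simulate import SimulationResult, SimulationSpec, close_to_relative, simulate_absolute
from .transforms import clr, replace_zeros

__all__ = [
    "MEASURES",
    "comparability_transform",
    "measure_battery",
    "evaluation_report",
    "run_evaluation",
]

MEASURES = ["corr_relative", "corr_clr", "rho", "phi_transformed", "phi_s_transformed"]


def comparability_transform(x):
    """Map a dissimilarity in [0, inf) onto the correlation scale [-1, 1].

    ``f(x) = 1 - 2 * logistic(ln x)``, which simplifies to
    ``(1 - x) / (1 + x)``: strictly decreasing with ``f(0) = 1``, ``f(1) = 0``
    and ``f(x) -> -1`` as ``x -> inf``.  Chosen so that ``f(phi_s) = rho``
    identically.  NaN propagates; negative input is a domain error.
    """
    arr = np.asarray(x, dtype=float)
    with np.errstate(invalid="ignore"):
        if np.any(arr < 0):
            raise ValueError("comparability transform is defined on [0, inf)")
        out = (1.0 - arr) / (1.0 + arr)
    return out if arr.ndim else float(out)


def _log_corr(values: np.ndarray) -> np.ndarray:
    return np.corrcoef(np.log(values), rowvar=False)


def measure_battery(
    absolute: CountMatrix,
    relative: Optional[pd.DataFrame] = None,
    sample_size: int = 10_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Score the five dependence measures on randomly sampled feature pairs.

    ``absolute`` must be strictly positive (replace zeros first); ``relative``
    defaults to its closure.  All correlations operate on the log scale, the
    scale every competing measure shares.  Returns one row per sampled
    unordered pair (i < j; phi's value is read in that orientation) with the
    reference ``corr_absolute`` column and the five measure columns.
    """
    if np.any(absolute.values <= 0):
        raise ValueError("absolute counts must be strictly positive; replace zeros first")
    if relative is None:
        relative = close_to_relative(absolute)
    rel = CountMatrix.unchecked(
        relative.to_numpy(dtype=float), tuple(relative.index), tuple(relative.columns)
    )
    if rel.values.shape != absolute.values.shape:
        raise ValueError("absolute and relative matrices must share dimensions")
    if np.any(rel.values <= 0):
        raise ValueError("relative matrix must be strictly positive")

    d = absolute.n_features
    n_pairs = d * (d - 1) // 2
    if sample_size > n_pairs:
        warnings.warn(
            f"sample_size {sample_size} exceeds the {n_pairs} available pairs; using all",
            UserWarning, stacklevel=2,
        )
        sample_size = n_pairs
    rng = np.random.default_rng(seed)
    iu, ju = np.triu_indices(d, k=1)
    pick = rng.choice(n_pairs, size=sample_size, replace=False)
    iu, ju = iu[pick], ju[pick]

    corr_abs = _log_corr(absolute.values)
    corr_rel = _log_corr(rel.values)
    A = clr(rel)
    corr_clr = np.corrcoef(A.values, rowvar=False)
    rho_m = rho(A).matrix.to_numpy()
    phi_m = phi(A).matrix.to_numpy()
    phi_s_m = phi_s(A).matrix.to_numpy()

    ids = list(absolute.feature_ids)
    return pd.DataFrame(
        {
            "feature_i": [ids[i] for i in iu],
            "feature_j": [ids[j] for j in ju],
            "corr_absolute": corr_abs[iu, ju],
            "corr_relative": corr_rel[iu, ju],
            "corr_clr": corr_clr[iu, ju],
            "rho": rho_m[iu, ju],
            "phi_transformed": comparability_transform(phi_m[iu, ju]),
            "phi_s_transformed": comparability_transform(phi_s_m[iu, ju]),
        }
    )


def evaluation_report(
    battery: pd.DataFrame,
    assoc_threshold: float = 0.7,
    null_threshold: float = 0.3,
) -> pd.DataFrame:
    """Tabulate each measure against the absolute correlation.

    A pair is a spurious event for a measure when |measure| >= the
    association threshold while |absolute correlation| <= the null threshold.
    Returns one row per measure with ``mse``, ``n_spurious`` and
    ``spurious_mse`` (MSE over the spurious pairs only; NaN when there are
    none).
    """
    if not assoc_threshold > null_threshold >= 0:
        raise ValueError("need assoc_threshold > null_threshold >= 0")
    ref = battery["corr_absolute"].to_numpy()
    rows = []
    for measure in MEASURES:
        m = battery[measure].to_numpy()
        ok = ~np.isnan(m) & ~np.isnan(ref)
        err = (m[ok] - ref[ok]) ** 2
        spurious = ok & (np.abs(m) >= assoc_threshold) & (np.abs(ref) <= null_threshold)
        rows.append(
            {
                "measure": measure,
                "mse": float(err.mean()) if err.size else np.nan,
                "n_spurious": int(spurious.sum()),
                "spurious_mse": float(((m[spurious] - ref[spurious]) ** 2).mean())
                if spurious.any()
                else np.nan,
            }
        )
    return pd.DataFrame(rows)


def run_evaluation(
    spec: Optional[SimulationSpec] = None,
    sample_size: int = 10_000,
    assoc_threshold: float = 0.7,
    null_threshold: float = 0.3,
    seed: Optional[int] = None,
):
    """Simulate, close, score, tabulate — the full benchmark in one call.

    Returns ``(simulation, battery, report)``.  ``seed`` overrides the
    spec's seed and also seeds the pair sampling, so a single integer
    reproduces the whole study.
    """
    spec = spec or SimulationSpec()
    if seed is not None:
        spec = SimulationSpec(**{**spec.__dict__, "seed": int(seed)})
    sim: SimulationResult = simulate_absolute(spec)
    positive = replace_zeros(sim.counts, 1.0)
    relative = close_to_relative(positive)
    battery = measure_battery(positive, relative, sample_size=sample_size, seed=spec.seed)
    report = evaluation_report(battery, assoc_threshold, null_threshold)
    return sim, battery, report
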