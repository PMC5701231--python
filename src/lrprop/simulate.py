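"""Synthetic count data with known absolute abundances.

The generator produces the study conditions under which proportionality can
be benchmarked against correlation: a matrix of negative-binomial "absolute"
transcript counts whose closure (division by the per-sample total) yields the
relative data a sequencer would report.  Three kinds of structure can be
planted, each recorded as ground truth:

* independent background features, NB with feature-specific means drawn
  log-uniformly and feature-specific dispersions;
* exactly or noisily proportional feature pairs (feature j tracks c times
  feature i);
* one *non-random* feature whose expected abundance ramps monotonically
  across samples from a minor to a dominant fraction of the library (0.1x to
  10x the summed background means by default, a 100-fold swing such as a
  hyper-induced transcript over a time course).  Because this feature comes
  to dominate the per-sample total, closure divides every other feature by a
  systematically varying denominator — the classic mechanism by which
  independent absolute abundances acquire spurious relative correlations.

The negative binomial is parameterised by mean ``m`` and dispersion ``alpha``
(variance ``m + alpha * m**2``), the convention used for RNA-Seq counts, and
sampled as a gamma-Poisson mixture.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .io import CountMatrix

__all__ = [
    "SimulationSpec",
    "SimulationResult",
    "simulate_absolute",
    "simulate_modules",
    "close_to_relative",
]


@dataclass(frozen=True)
class SimulationSpec:
    """Parameters of the synthetic absolute-count generator.

    Defaults reproduce the benchmark conditions: 1,000 random NB features
    plus one non-random trending feature, with a handful of proportional
    pairs planted among the random features so recovery can be scored.
    """

    n_features: int = 1000
    n_samples: int = 30
    mean_range: tuple = (10.0, 1000.0)  # log-uniform draw of NB means
    dispersion_range: tuple = (0.1, 0.5)  # alpha; var = m + alpha m^2
    n_proportional_pairs: int = 10
    pair_factor_range: tuple = (2.0, 5.0)  # proportionality constant c
    pair_noise_sd: float = 0.05  # lognormal sd around exact proportionality
    nonrandom_feature: bool = True
    nonrandom_trend: tuple = (0.1, 10.0)  # feature mean as multiple of library, ramped
    depth_sigma: float = 0.0  # optional lognormal per-sample depth variation
    seed: int = 0

    def __post_init__(self):
        if self.n_features < 2 or self.n_samples < 2:
            raise ValueError("need at least 2 features and 2 samples")
        if not (0 < self.mean_range[0] <= self.mean_range[1]):
            raise ValueError("mean_range must be positive and ordered")
        if not (0 < self.dispersion_range[0] <= self.dispersion_range[1]):
            raise ValueError("dispersion_range must be positive and ordered")
        if self.n_proportional_pairs < 0 or 2 * self.n_proportional_pairs > self.n_features:
            raise ValueError("too many proportional pairs for n_features")
        if self.pair_noise_sd < 0 or self.depth_sigma < 0:
            raise ValueError("noise parameters must be non-negative")


@dataclass(frozen=True)
class SimulationResult:
    """Absolute counts plus the planted ground truth."""

    counts: CountMatrix
    proportional_pairs: tuple  # tuples of (feature_i, feature_j, factor)
    nonrandom_feature: Optional[str]
    spec: SimulationSpec = field(repr=False)


def _nb_draw(rng: np.random.Generator, mean, alpha, size) -> np.ndarray:
    """Gamma-Poisson draw of NB(mean, dispersion alpha); alpha -> 0 is Poisson."""
    shape = 1.0 / np.maximum(alpha, 1e-12)
    lam = rng.gamma(shape, np.asarray(mean) / shape, size=size)
    return rng.poisson(lam).astype(float)


def simulate_absolute(spec: SimulationSpec) -> SimulationResult:
    """Draw a seeded absolute count matrix with planted structure.

    Feature layout: background NB features first, then the planted
    proportional partners (named ``P<i>a`` / ``P<i>b``), then the optional
    trending feature ``NONRANDOM`` as the final column.
    """
    rng = np.random.default_rng(spec.seed)
    n, d = spec.n_samples, spec.n_features
    n_pair_features = 2 * spec.n_proportional_pairs
    n_background = d - n_pair_features - (1 if spec.nonrandom_feature else 0)
    if n_background < 0:
        raise ValueError("n_features too small for the requested planted structure")

    means = np.exp(
        rng.uniform(np.log(spec.mean_range[0]), np.log(spec.mean_range[1]), d)
    )
    alphas = rng.uniform(*spec.dispersion_range, d)

    columns, names = [], []
    for i in range(n_background):
        columns.append(_nb_draw(rng, means[i], alphas[i], n))
        names.append(f"G{i + 1}")

    pairs = []
    for p in range(spec.n_proportional_pairs):
        i = n_background + 2 * p
        base = _nb_draw(rng, means[i], alphas[i], n)
        base = np.maximum(base, 1.0)  # partner of an all-zero draw is meaningless
        factor = rng.uniform(*spec.pair_factor_range)
        noise = rng.lognormal(0.0, spec.pair_noise_sd, n) if spec.pair_noise_sd else 1.0
        partner = np.round(base * factor * noise)
        a, b = f"P{p + 1}a", f"P{p + 1}b"
        columns += [base, partner]
        names += [a, b]
        pairs.append((a, b, float(factor)))

    nonrandom_name = None
    if spec.nonrandom_feature:
        library = float(means[: d - 1].sum())
        ramp = np.linspace(spec.nonrandom_trend[0], spec.nonrandom_trend[1], n)
        columns.append(rng.poisson(library * ramp).astype(float))
        nonrandom_name = "NONRANDOM"
        names.append(nonrandom_name)

    values = np.column_stack(columns)
    if spec.depth_sigma:
        depth = rng.lognormal(0.0, spec.depth_sigma, n)
        values = np.round(values * depth[:, None])

    counts = CountMatrix(values, None, tuple(names))
    return SimulationResult(counts, tuple(pairs), nonrandom_name, spec)


def simulate_modules(
    module_sizes=(5, 5),
    module_log_sd=(1.5, 0.5),
    n_noise: int = 10,
    n_samples: int = 20,
    base_mean: float = 200.0,
    noise_sd: float = 0.05,
    seed: int = 0,
):
    """Counts with planted proportional modules of controlled loudness.

    Module ``m`` shares one latent log-abundance trajectory with standard
    deviation ``module_log_sd[m]`` across samples; each member feature is the
    latent series times a feature-specific constant, jittered by lognormal
    noise of spread ``noise_sd`` — so within-module pairs are nearly exactly
    proportional, and a module's VLS scales with its latent loudness.
    ``n_noise`` independent NB features form the background.

    Returns ``(counts, membership)`` where ``membership`` maps module index
    (1-based) to its member feature ids; noise features are not listed.
    """
    rng = np.random.default_rng(seed)
    columns, names, membership = [], [], {}
    for m, (size, sd) in enumerate(zip(module_sizes, module_log_sd), start=1):
        latent = rng.normal(np.log(base_mean), sd, n_samples)
        members = []
        for f in range(size):
            scale = rng.uniform(-1.0, 1.0)  # log feature-specific constant
            eps = rng.normal(0.0, noise_sd, n_samples)
            col = np.maximum(np.round(np.exp(latent + scale + eps)), 1.0)
            name = f"M{m}_{f + 1}"
            columns.append(col)
            names.append(name)
            members.append(name)
        membership[m] = members
    for f in range(n_noise):
        col = np.maximum(_nb_draw(rng, base_mean, 0.3, n_samples), 1.0)
        columns.append(col)
        names.append(f"N{f + 1}")
    counts = CountMatrix(np.column_stack(columns), None, tuple(names))
    return counts, membership


def close_to_relative(absolute: CountMatrix) -> pd.DataFrame:
    """Closure: divide each sample (row) by its total so rows sum to 1.

    The per-sample total is the library size; dividing it out is exactly what
    makes sequencing data relative.  Idempotent on already-closed data.
    Zero rows are rejected (no information to normalise).
    """
    values = np.asarray(absolute.values, dtype=float)
    totals = values.sum(axis=1)
    if np.any(totals <= 0):
        bad = int(np.flatnonzero(totals <= 0)[0])
        raise ValueError(f"sample row {bad} sums to zero; closure undefined")
    rel = values / totals[:, None]
    return pd.DataFrame(
        rel, index=list(absolute.sample_ids), columns=list(absolute.feature_ids)
    )
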