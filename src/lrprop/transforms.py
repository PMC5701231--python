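"""Zero replacement and the clr / alr log-ratio transformations.

Count data carry only relative information, so before measuring association
each sample vector ``x`` is mapped out of the simplex with a log-ratio
transform:

* centred log-ratio:  ``clr(x)_i = ln(x_i / g(x))`` with ``g`` the geometric
  mean of the sample over all features;
* additive log-ratio: ``alr(x)_i = ln(x_i / x_ref)`` against a designated
  reference feature (or the geometric mean of a reference set).

Both are scale invariant: multiplying a sample by any positive constant (a
library-size change) leaves the output untouched, which is the property that
makes downstream proportionality metrics identical on absolute counts and
their closed (row-normalised) counterparts.

Logs are natural logs throughout.  Zeros must be replaced first; the default
strategy substitutes 1 for every zero count (multiplicative replacement).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io import CountMatrix

__all__ = ["LogRatioMatrix", "replace_zeros", "clr", "clr_subset", "alr"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class LogRatioMatrix:
    """An N x M matrix of log-ratio transformed abundances.

    ``M == D`` for clr; ``M == D - len(reference)`` for alr (the reference
    column(s), identically zero self-ratios, are dropped).  Carries enough
    provenance (transform name, reference, zero replacement used) for results
    built on it to be reproducible.
    """

    values: np.ndarray
    feature_ids: tuple
    sample_ids: tuple
    transform: str  # "clr" or "alr"
    reference_ids: tuple = ()
    zero_replacement: float = 1.0

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def select_features(self, keep) -> "LogRatioMatrix":
        idx = [self.feature_ids.index(str(f)) for f in keep]
        return LogRatioMatrix(
            self.values[:, idx],
            tuple(self.feature_ids[i] for i in idx),
            self.sample_ids,
            self.transform,
            self.reference_ids,
            self.zero_replacement,
        )

    def column(self, feature_id) -> np.ndarray:
        return self.values[:, self.feature_ids.index(str(feature_id))]


def replace_zeros(counts: CountMatrix, replacement: float = 1.0) -> CountMatrix:
    """Replace every zero count with ``replacement`` (default 1).

    Non-zero entries are untouched.  The number of replaced cells is logged so
    analysts can audit how much the zero strategy touches their data.
    """
    if not replacement > 0:
        raise ValueError(f"zero replacement must be positive, got {replacement}")
    values = counts.values.copy()
    mask = values == 0
    n_replaced = int(mask.sum())
    values[mask] = replacement
    logger.info("replaced %d zero entries with %g", n_replaced, replacement)
    # unchecked: a fractional replacement value is legitimate
    return CountMatrix.unchecked(values, counts.sample_ids, counts.feature_ids)


def _check_positive(values: np.ndarray) -> None:
    if np.any(values <= 0):
        raise ValueError(
            "log-ratio transforms need strictly positive entries; "
            "run replace_zeros first"
        )


def clr(counts: CountMatrix, zero_replacement: float = 1.0) -> LogRatioMatrix:
    """Centred log-ratio transform of every sample.

    Row ``n`` maps to ``ln(x_n / g(x_n))`` where ``g`` is the geometric mean
    of the row, computed as ``exp(mean(ln x))`` so large counts cannot
    overflow.  Every output row sums to zero.
    """
    _check_positive(counts.values)
    logx = np.log(counts.values)
    out = logx - logx.mean(axis=1, keepdims=True)
    return LogRatioMatrix(
        out, counts.feature_ids, counts.sample_ids, "clr", (), zero_replacement
    )


def clr_subset(counts: CountMatrix, keep, zero_replacement: float = 1.0) -> LogRatioMatrix:
    """clr over all features, then retain only the columns in ``keep``.

    The geometric mean is always taken over the full feature set, so dropping
    features *after* the transform (e.g. a low-count filter) leaves the
    retained log-ratios — and any metric built on them — bit-identical to
    subsetting the full result.  This is the trick that lets filtering and
    proportionality be computed simultaneously without altering the result.
    """
    keep = [str(f) for f in keep]
    if not keep:
        raise ValueError("keep must name at least one feature")
    missing = set(keep) - set(counts.feature_ids)
    if missing:
        raise KeyError(f"unknown feature(s): {sorted(missing)}")
    return clr(counts, zero_replacement).select_features(keep)


def alr(counts: CountMatrix, reference, zero_replacement: float = 1.0) -> LogRatioMatrix:
    """Additive log-ratio transform against a reference feature (or set).

    With a single reference the denominator is that feature's count; with
    several, the geometric mean of the named subset.  Reference columns are
    self-ratios (identically zero) and are dropped from the output.  When the
    reference has truly fixed absolute abundance, alr back-calculates absolute
    abundances from relative data up to a constant.
    """
    refs = [reference] if isinstance(reference, str) else list(reference)
    refs = [str(r) for r in refs]
    if not refs:
        raise ValueError("at least one reference feature is required")
    missing = set(refs) - set(counts.feature_ids)
    if missing:
        raise KeyError(f"reference feature(s) not found: {sorted(missing)}")
    _check_positive(counts.values)
    logx = np.log(counts.values)
    ref_idx = [counts.feature_ids.index(r) for r in refs]
    denom = logx[:, ref_idx].mean(axis=1, keepdims=True)
    keep_idx = [i for i in range(counts.n_features) if i not in set(ref_idx)]
    out = logx[:, keep_idx] - denom
    return LogRatioMatrix(
        out,
        tuple(counts.feature_ids[i] for i in keep_idx),
        counts.sample_ids,
        "alr",
        tuple(refs),
        zero_replacement,
    )
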