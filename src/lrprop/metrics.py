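"""Proportionality metrics on log-ratio transformed data.

Given the transformed matrix ``A`` (samples x features), association between
two feature columns is measured through the *log-ratio variance*

    vlr(i, j) = var(A_i - A_j)

which is zero exactly when the two features are proportional across samples
and — crucially — identical whether computed on absolute counts or their
closed, relative counterpart.  The VLR has no intrinsic scale, so three
scalings of it are provided:

    phi(i, j)   = vlr(i, j) / var(A_i)                    in [0, inf), asymmetric
    rho(i, j)   = 1 - vlr(i, j) / (var(A_i) + var(A_j))   in [-1, 1], symmetric
    phi_s(i, j) = vlr(i, j) / var(A_i + A_j)              in [0, inf), symmetric

``rho`` and ``phi_s`` are linked by the monotone map
``rho = (1 - phi_s) / (1 + phi_s)``.

All variances use the unbiased N-1 denominator.  The pairwise pass is blocked
over feature columns so peak scratch memory stays at O(M * block) beyond the
M x M result itself.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .io import CountMatrix, PAIR_COLUMNS
from .transforms import LogRatioMatrix, alr, clr_subset, replace_zeros

__all__ = [
    "ProportionalityResult",
    "filter_features",
    "feature_variances",
    "vlr_matrix",
    "phi",
    "rho",
    "phi_s",
    "proportionality",
    "extract_pairs",
]

#: Relative noise floor for the cancellation-prone quantity v_i + v_j ± 2 cov.
#: A VLR below this fraction of the pair's summed variances is numerically
#: indistinguishable from exact proportionality and is snapped to zero; the
#: same floor flags the phi_s denominator var(A_i + A_j) as degenerate.
_CANCEL_TOL = 1e-12

_DEFAULT_BLOCK = 512


def feature_variances(A: LogRatioMatrix) -> np.ndarray:
    """Per-feature sample variance (ddof=1) of the log-ratio columns."""
    if A.n_samples < 2:
        raise ValueError("variance needs at least 2 samples")
    return A.values.var(axis=0, ddof=1)


def _centered(A: LogRatioMatrix) -> np.ndarray:
    # C-order enforced: einsum's summation order (and hence bit-level
    # reproducibility under subsetting) depends on the memory layout
    return np.ascontiguousarray(A.values - A.values.mean(axis=0, keepdims=True))


def vlr_matrix(A: LogRatioMatrix, block_size: Optional[int] = None) -> np.ndarray:
    """The M x M log-ratio variance matrix ``var(A_i - A_j)``.

    Computed from one covariance pass as ``var_i + var_j - 2 cov_ij``,
    streamed in column blocks.  Symmetric with a zero diagonal; entries below
    the cancellation noise floor are reported as exactly 0.
    """
    n, m = A.values.shape
    if n < 2:
        raise ValueError("VLR needs at least 2 samples")
    if block_size is None or block_size <= 0:
        block_size = m
    xc = _centered(A)
    v = (xc * xc).sum(axis=0) / (n - 1)
    out = np.empty((m, m))
    for start in range(0, m, block_size):
        stop = min(start + block_size, m)
        # einsum (not BLAS gemm): per-entry summation order is fixed, so the
        # result is bit-identical under column blocking and feature subsetting
        cov = np.einsum("ni,nj->ij", xc, xc[:, start:stop]) / (n - 1)
        block = v[:, None] + v[None, start:stop] - 2.0 * cov
        np.maximum(block, 0.0, out=block)
        block[block <= _CANCEL_TOL * (v[:, None] + v[None, start:stop])] = 0.0
        out[:, start:stop] = block
    np.fill_diagonal(out, 0.0)
    return out


def _vlp_matrix(A: LogRatioMatrix, block_size: Optional[int] = None) -> np.ndarray:
    """var(A_i + A_j), the phi_s denominator (variance of the log product)."""
    n, m = A.values.shape
    if block_size is None or block_size <= 0:
        block_size = m
    xc = _centered(A)
    v = (xc * xc).sum(axis=0) / (n - 1)
    out = np.empty((m, m))
    for start in range(0, m, block_size):
        stop = min(start + block_size, m)
        cov = np.einsum("ni,nj->ij", xc, xc[:, start:stop]) / (n - 1)
        block = v[:, None] + v[None, start:stop] + 2.0 * cov
        np.maximum(block, 0.0, out=block)
        block[block <= _CANCEL_TOL * (v[:, None] + v[None, start:stop])] = 0.0
        out[:, start:stop] = block
    return out


@dataclass
class ProportionalityResult:
    """A fitted feature x feature proportionality matrix with provenance.

    Attributes
    ----------
    matrix : DataFrame, M x M
        Metric values; symmetric for ``rho`` / ``phi_s``, asymmetric for
        ``phi`` (row feature supplies the denominator variance).
    metric : {"phi", "rho", "phi_s"}
    logratios : LogRatioMatrix
        The transformed data the matrix was computed from; kept so pair
        extraction and plotting can recover per-pair VLR / VLS.
    filter_spec : (min_count, min_samples) or None
    """

    matrix: pd.DataFrame
    metric: str
    logratios: LogRatioMatrix
    filter_spec: Optional[tuple] = None
    zero_replacement: float = 1.0
    n_zeros_replaced: int = 0
    _vlr: np.ndarray = field(default=None, repr=False)

    @property
    def transform(self) -> str:
        return self.logratios.transform

    @property
    def feature_ids(self) -> tuple:
        return tuple(self.matrix.columns)

    @property
    def n_features(self) -> int:
        return self.matrix.shape[1]

    def vlr(self) -> np.ndarray:
        if self._vlr is None:
            self._vlr = vlr_matrix(self.logratios)
        return self._vlr

    # -- downstream conveniences (thin wrappers over the module functions) --
    def pairs(self, cutoff: float, direction: str = "greater") -> pd.DataFrame:
        return extract_pairs(self, self.logratios, cutoff, direction)

    def distance(self) -> pd.DataFrame:
        from .cluster import proportionality_distance

        return proportionality_distance(self)

    def cocluster(self, k: Optional[int] = None, height: Optional[float] = None,
                  linkage: str = "complete"):
        from .cluster import cocluster

        return cocluster(self.distance(), linkage=linkage, k=k, height=height)

    def summary(self) -> str:
        """Plain-text summary in the spirit of a model-results table."""
        m = self.matrix.to_numpy()
        off = m[~np.eye(len(m), dtype=bool)]
        lines = [
            "Proportionality results",
            "=" * 47,
            f"metric:            {self.metric}",
            f"transform:         {self.transform}"
            + (f" (reference: {', '.join(self.logratios.reference_ids)})"
               if self.logratios.reference_ids else ""),
            f"samples:           {self.logratios.n_samples}",
            f"features:          {self.n_features}",
            f"filter:            {self.filter_spec if self.filter_spec else 'none'}",
            f"zeros replaced:    {self.n_zeros_replaced} (with {self.zero_replacement:g})",
            f"off-diagonal min:  {np.nanmin(off): .4f}",
            f"off-diagonal max:  {np.nanmax(off): .4f}",
            f"off-diagonal mean: {np.nanmean(off): .4f}",
            "=" * 47,
        ]
        return "\n".join(lines)


def filter_features(counts: CountMatrix, min_count: int = 10, min_samples: int = 10):
    """Features with at least ``min_count`` counts in at least ``min_samples`` samples.

    Returns the surviving feature ids in their original order.  Thresholds are
    inclusive ("at least").  The default (10, 10) targets lowly expressed
    transcripts in bulk RNA-Seq.
    """
    if min_count < 0:
        raise ValueError("min_count must be non-negative")
    if min_samples < 1:
        raise ValueError("min_samples must be at least 1")
    if min_samples > counts.n_samples:
        warnings.warn(
            f"min_samples={min_samples} exceeds the {counts.n_samples} available "
            "samples; no feature can pass", UserWarning, stacklevel=2,
        )
    n_passing = (counts.values >= min_count).sum(axis=0)
    return [f for f, n in zip(counts.feature_ids, n_passing) if n >= min_samples]


def _check_nonconstant(v: np.ndarray, feature_ids) -> None:
    bad = np.flatnonzero(v <= 0)
    if bad.size:
        names = [feature_ids[i] for i in bad[:10]]
        raise ValueError(
            f"zero-variance (constant) log-ratio feature(s): {names}"
            + (" ..." if bad.size > 10 else "")
        )


def _wrap(values: np.ndarray, A: LogRatioMatrix, metric: str, vlr: np.ndarray,
          **kw) -> ProportionalityResult:
    ids = list(A.feature_ids)
    df = pd.DataFrame(values, index=ids, columns=ids)
    return ProportionalityResult(df, metric, A, _vlr=vlr, **kw)


def phi(A: LogRatioMatrix, block_size: Optional[int] = None, **kw) -> ProportionalityResult:
    """phi = vlr(i, j) / var(A_i): a dissimilarity in [0, inf).

    Asymmetric: the row feature's variance is the denominator, so
    ``phi[i, j] * var_i == phi[j, i] * var_j == vlr[i, j]``.
    """
    v = feature_variances(A)
    _check_nonconstant(v, A.feature_ids)
    vlr = vlr_matrix(A, block_size)
    return _wrap(vlr / v[:, None], A, "phi", vlr, **kw)


def rho(A: LogRatioMatrix, block_size: Optional[int] = None, **kw) -> ProportionalityResult:
    """rho = 1 - vlr / (var_i + var_j): a correlation analogue in [-1, 1].

    Symmetric with unit diagonal; 1 means exact proportionality, -1 exact
    anti-proportionality (log-ratios mirror each other).
    """
    n, m = A.values.shape
    v = feature_variances(A)
    _check_nonconstant(v, A.feature_ids)
    vlr = vlr_matrix(A, block_size)
    bs = block_size if block_size and block_size > 0 else m
    out = np.empty((m, m))
    for start in range(0, m, bs):
        stop = min(start + bs, m)
        vls = v[:, None] + v[None, start:stop]
        out[:, start:stop] = 1.0 - vlr[:, start:stop] / vls
    np.clip(out, -1.0, 1.0, out=out)
    np.fill_diagonal(out, 1.0)
    return _wrap(out, A, "rho", vlr, **kw)


def phi_s(A: LogRatioMatrix, block_size: Optional[int] = None, **kw) -> ProportionalityResult:
    """phi_s = vlr / var(A_i + A_j): the symmetric variant of phi.

    Pairs whose denominator (the variance of the log product) vanishes —
    exact anti-proportionality — are reported as NaN rather than infinity so
    downstream clustering cannot silently absorb them.
    """
    v = feature_variances(A)
    _check_nonconstant(v, A.feature_ids)
    vlr = vlr_matrix(A, block_size)
    vlp = _vlp_matrix(A, block_size)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(vlp > 0, vlr / np.where(vlp > 0, vlp, 1.0), np.nan)
    np.fill_diagonal(out, 0.0)
    return _wrap(out, A, "phi_s", vlr, **kw)


_METRICS = {"phi": phi, "rho": rho, "phi_s": phi_s}


def proportionality(
    counts: CountMatrix,
    metric: str = "rho",
    transform: str = "clr",
    reference=None,
    filter: Optional[tuple] = None,
    zero_replacement: float = 1.0,
    block_size: Optional[int] = None,
) -> ProportionalityResult:
    """End-to-end pipeline: zero replacement, optional filter, transform, metric.

    The low-count filter is evaluated on the raw counts and applied *after*
    the clr geometric means are taken over all features, so filtering never
    alters the retained entries of the result — it only subsets them.  For
    alr the transform depends only on the reference, which must itself pass
    the filter (an error otherwise, since silently dropping the denominator
    would change the analysis).

    Parameters
    ----------
    metric : {"rho", "phi", "phi_s"}
    transform : {"clr", "alr"}; ``reference`` is required for alr
    filter : optional (min_count, min_samples)
    """
    if metric not in _METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {sorted(_METRICS)}")
    if transform not in ("clr", "alr"):
        raise ValueError(f"unknown transform {transform!r}")
    if transform == "alr" and reference is None:
        raise ValueError("alr requires a reference feature")
    if transform == "clr" and reference is not None:
        raise ValueError("reference is only meaningful with transform='alr'")

    replaced = replace_zeros(counts, zero_replacement)
    n_zeros = int((counts.values == 0).sum())

    keep = list(counts.feature_ids)
    if filter is not None:
        keep = filter_features(counts, *filter)

    if transform == "clr":
        if not keep:
            raise ValueError("filter removed every feature")
        A = clr_subset(replaced, keep, zero_replacement)
    else:
        refs = [reference] if isinstance(reference, str) else list(reference)
        if filter is not None:
            missing = set(map(str, refs)) - set(keep)
            if missing:
                raise ValueError(
                    f"alr reference(s) {sorted(missing)} fail the count filter; "
                    "refusing to drop the denominator of the transform"
                )
        A = alr(replaced, refs, zero_replacement)
        keep = [f for f in keep if f in A.feature_ids]
        A = A.select_features(keep)

    return _METRICS[metric](
        A,
        block_size=block_size,
        filter_spec=tuple(filter) if filter is not None else None,
        zero_replacement=zero_replacement,
        n_zeros_replaced=n_zeros,
    )


def extract_pairs(
    result: ProportionalityResult,
    A: Optional[LogRatioMatrix] = None,
    cutoff: float = 0.95,
    direction: str = "greater",
) -> pd.DataFrame:
    """Long-form table of unordered feature pairs passing a metric cutoff.

    Each row carries the pair's VLR (``var(A_i - A_j)``) and VLS (the sum of
    the two features' variances, which for rho satisfies
    ``vlr / vls == 1 - rho``).  For the asymmetric phi a pair passes if either
    orientation passes and the smaller of the two values is reported.  NaN
    (degenerate) entries never pass.

    ``direction`` is one of ``greater`` (metric > cutoff, the natural choice
    for rho), ``less`` (metric < cutoff, for the dissimilarities phi and
    phi_s) or ``abs_greater`` (|metric| > cutoff).
    """
    if direction not in ("greater", "less", "abs_greater"):
        raise ValueError(f"unknown direction {direction!r}")
    if A is None:
        A = result.logratios
    ids = list(result.matrix.columns)
    if list(A.feature_ids) != ids:
        raise ValueError("log-ratio matrix does not match the result's features")

    m = result.matrix.to_numpy()
    if result.metric == "phi":
        value = np.fmin(m, m.T)  # fmin: either orientation may pass; report smaller
        test_m = value
    else:
        value = m
        test_m = m
    with np.errstate(invalid="ignore"):
        if direction == "greater":
            passing = test_m > cutoff
        elif direction == "less":
            passing = test_m < cutoff
        else:
            passing = np.abs(test_m) > cutoff
    passing &= ~np.isnan(test_m)

    iu, ju = np.triu_indices(len(ids), k=1)
    mask = passing[iu, ju]
    iu, ju = iu[mask], ju[mask]

    vlr = result.vlr()[iu, ju]
    v = feature_variances(A)
    vls = v[iu] + v[ju]
    table = pd.DataFrame(
        {
            "feature_i": [ids[i] for i in iu],
            "feature_j": [ids[j] for j in ju],
            "metric_name": result.metric,
            "metric_value": value[iu, ju],
            "vlr": vlr,
            "vls": vls,
            "cluster_i": pd.array([pd.NA] * len(iu), dtype="Int64"),
            "cluster_j": pd.array([pd.NA] * len(iu), dtype="Int64"),
        }
    )
    return table[PAIR_COLUMNS]
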