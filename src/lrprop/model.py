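"""Model-style front end: build from a count table, ``fit()`` to a result.

:class:`Proportionality` holds the data and the analysis choices (metric,
transform, reference, filter, zero replacement); :meth:`Proportionality.fit`
runs the pipeline and returns a :class:`~lrprop.metrics.ProportionalityResult`
carrying the metric matrix, its provenance, and the downstream methods
(``pairs``, ``distance``, ``cocluster``, ``summary``).

    >>> model = Proportionality.from_dataframe(df, metric="rho")
    >>> result = model.fit()
    >>> print(result.summary())
    >>> hits = result.pairs(cutoff=0.95)
"""

from __future__ import annotations

from typing import Optional

import pandas as pd

from .io import CountMatrix, read_counts
from .metrics import ProportionalityResult, proportionality

__all__ = ["Proportionality"]


class Proportionality:
    """Proportionality analysis of a samples x features count matrix.

    Parameters
    ----------
    counts : CountMatrix
        Non-negative integral counts, samples as rows.
    metric : {"rho", "phi", "phi_s"}
        rho behaves like a correlation (range [-1, 1]); phi and phi_s are
        dissimilarities (range [0, inf), 0 = perfectly proportional).
    transform : {"clr", "alr"}
        clr scales each sample by its geometric mean; alr divides by a
        designated ``reference`` feature (or the geometric mean of several).
    filter : optional (min_count, min_samples)
        Drop features lacking ``min_count`` counts in ``min_samples``
        samples.  Applied after the clr geometric means are taken, so the
        retained entries equal the unfiltered result's.
    zero_replacement : positive float
        Value substituted for zero counts before taking logs (default 1).
    """

    def __init__(
        self,
        counts: CountMatrix,
        metric: str = "rho",
        transform: str = "clr",
        reference=None,
        filter: Optional[tuple] = None,
        zero_replacement: float = 1.0,
    ):
        self.counts = counts
        self.metric = metric
        self.transform = transform
        self.reference = reference
        self.filter = filter
        self.zero_replacement = zero_replacement

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "Proportionality":
        """Build from a samples-as-rows DataFrame with labelled axes."""
        return cls(CountMatrix.from_dataframe(df), **kwargs)

    @classmethod
    def from_file(
        cls, path, delimiter: str = "\t", orientation: str = "samples_as_rows", **kwargs
    ) -> "Proportionality":
        """Build from a delimited count table on disk."""
        return cls(read_counts(path, delimiter, orientation), **kwargs)

    def fit(self, block_size: Optional[int] = None) -> ProportionalityResult:
        """Run zero replacement, filtering, the transform and the metric.

        ``block_size`` streams the pairwise pass over feature-column blocks
        (identical output; bounds scratch memory for wide matrices).
        """
        return proportionality(
            self.counts,
            metric=self.metric,
            transform=self.transform,
            reference=self.reference,
            filter=self.filter,
            zero_replacement=self.zero_replacement,
            block_size=block_size,
        )

    def __repr__(self) -> str:
        return (
            f"Proportionality(n_samples={self.counts.n_samples}, "
            f"n_features={self.counts.n_features}, metric={self.metric!r}, "
            f"transform={self.transform!r})"
        )
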