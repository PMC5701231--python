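"""Reading, validating and writing the tables that proportionality analysis consumes.

The canonical in-memory container for raw data is :class:`CountMatrix`, a thin
labelled wrapper around a dense numpy array with samples as rows and features
as columns.  Everything downstream (log-ratio transforms, metric matrices,
pair tables) speaks pandas, so the readers and writers here are deliberately
small shims over :func:`pandas.read_csv` / :meth:`pandas.DataFrame.to_csv`
that add the validation the analysis relies on: non-negative integral counts,
unique labels, and a fixed orientation.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CountMatrix",
    "read_counts",
    "read_annotations",
    "write_pairs",
    "read_pairs",
    "write_matrix",
    "write_clusters",
    "PAIR_COLUMNS",
]

#: Column schema of a pair table, in on-disk order.  ``cluster_i``/``cluster_j``
#: are nullable integers; unset clusters are written as the string ``NA``.
PAIR_COLUMNS = [
    "feature_i",
    "feature_j",
    "metric_name",
    "metric_value",
    "vlr",
    "vls",
    "cluster_i",
    "cluster_j",
]


class ValidationError(ValueError):
    """Raised when an input table violates a structural invariant."""


@dataclass(frozen=True)
class CountMatrix:
    """A labelled N x D table of non-negative integral counts.

    Samples are rows, features are columns.  Values are stored as floats so
    that downstream arithmetic (zero replacement, log-ratios) is uniform, but
    construction verifies that every entry is a non-negative integer.

    Parameters
    ----------
    values : ndarray of shape (n_samples, n_features)
    sample_ids, feature_ids : sequences of unique string labels
    """

    values: np.ndarray
    sample_ids: tuple = field(default=None)
    feature_ids: tuple = field(default=None)

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise ValidationError("count matrix must be two-dimensional")
        n, d = values.shape
        if n < 2 or d < 2:
            raise ValidationError(
                f"need at least 2 samples and 2 features, got {n} x {d}: "
                "variances across samples and ratios across features are "
                "otherwise undefined"
            )
        if not np.all(np.isfinite(values)):
            bad = np.argwhere(~np.isfinite(values))[0]
            raise ValidationError(f"non-finite entry at row {bad[0]}, column {bad[1]}")
        if np.any(values < 0):
            bad = np.argwhere(values < 0)[0]
            raise ValidationError(
                f"negative count at row {bad[0]} ({self._label(self.sample_ids, bad[0])}), "
                f"column {bad[1]} ({self._label(self.feature_ids, bad[1])})"
            )
        if np.any(values != np.round(values)):
            bad = np.argwhere(values != np.round(values))[0]
            raise ValidationError(
                f"non-integral count at row {bad[0]}, column {bad[1]}"
            )
        sample_ids = self._make_ids(self.sample_ids, n, "S")
        feature_ids = self._make_ids(self.feature_ids, d, "F")
        if len(set(sample_ids)) != n:
            raise ValidationError("duplicate sample labels")
        if len(set(feature_ids)) != d:
            raise ValidationError("duplicate feature labels")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "sample_ids", sample_ids)
        object.__setattr__(self, "feature_ids", feature_ids)

    @staticmethod
    def _make_ids(ids, n, prefix):
        if ids is None:
            return tuple(f"{prefix}{i + 1}" for i in range(n))
        return tuple(str(x) for x in ids)

    @staticmethod
    def _label(ids, idx):
        return ids[idx] if ids is not None and idx < len(ids) else "?"

    # -- conveniences -------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "CountMatrix":
        """Build from a samples-as-rows DataFrame with labelled axes."""
        return cls(df.to_numpy(dtype=float), tuple(map(str, df.index)), tuple(map(str, df.columns)))

    @classmethod
    def unchecked(cls, values, sample_ids, feature_ids) -> "CountMatrix":
        """Wrap positive real-valued data (e.g. closed relative abundances).

        Skips the integral-count validation — log-ratio machinery is defined
        on any strictly positive composition, not only on raw counts — but
        still requires a 2-D finite non-negative array and unique labels.
        """
        values = np.asarray(values, dtype=float)
        if values.ndim != 2:
            raise ValidationError("matrix must be two-dimensional")
        if not np.all(np.isfinite(values)) or np.any(values < 0):
            raise ValidationError("entries must be finite and non-negative")
        out = cls.__new__(cls)
        object.__setattr__(out, "values", values)
        object.__setattr__(
            out, "sample_ids", cls._make_ids(sample_ids, values.shape[0], "S")
        )
        object.__setattr__(
            out, "feature_ids", cls._make_ids(feature_ids, values.shape[1], "F")
        )
        if len(set(out.sample_ids)) != values.shape[0]:
            raise ValidationError("duplicate sample labels")
        if len(set(out.feature_ids)) != values.shape[1]:
            raise ValidationError("duplicate feature labels")
        return out

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values.copy(), index=list(self.sample_ids), columns=list(self.feature_ids)
        )

    def select_features(self, keep) -> "CountMatrix":
        """Column subset by feature label, preserving the given order."""
        idx = [self.feature_ids.index(str(f)) for f in keep]
        return CountMatrix(
            self.values[:, idx], self.sample_ids, tuple(self.feature_ids[i] for i in idx)
        )

    def __eq__(self, other):
        if not isinstance(other, CountMatrix):
            return NotImplemented
        return (
            self.sample_ids == other.sample_ids
            and self.feature_ids == other.feature_ids
            and np.array_equal(self.values, other.values)
        )


def read_counts(
    path, delimiter: str = "\t", orientation: str = "samples_as_rows"
) -> CountMatrix:
    """Read a labelled delimited count table into canonical orientation.

    Parameters
    ----------
    path : str or path-like
    delimiter : field separator, tab by default
    orientation : ``"samples_as_rows"`` (canonical) or ``"features_as_rows"``
        (the common genomics convention); the latter is transposed on read.
    """
    if orientation not in ("samples_as_rows", "features_as_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    try:
        df = pd.read_csv(path, sep=delimiter, index_col=0)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise ValidationError(f"cannot parse {path}: {exc}") from exc
    non_numeric = df.columns[[not pd.api.types.is_numeric_dtype(t) for t in df.dtypes]]
    if len(non_numeric):
        raise ValidationError(
            f"non-numeric entries in column(s) {list(map(str, non_numeric))} of {path}"
        )
    if orientation == "features_as_rows":
        df = df.T
    return CountMatrix.from_dataframe(df)


def read_annotations(path, delimiter: str = "\t") -> pd.DataFrame:
    """Read a feature annotation table with columns ``feature_id``, ``direction``.

    ``direction`` must be one of ``increased`` / ``decreased`` / ``none``; it
    typically records the sign of differential expression from an external
    tool and is used only to colour network nodes.
    """
    df = pd.read_csv(path, sep=delimiter, dtype=str)
    required = {"feature_id", "direction"}
    if not required.issubset(df.columns):
        raise ValidationError(f"annotation table needs columns {sorted(required)}")
    df = df[["feature_id", "direction"]]
    bad = set(df["direction"]) - {"increased", "decreased", "none"}
    if bad:
        raise ValidationError(f"unknown direction value(s): {sorted(bad)}")
    if df["feature_id"].duplicated().any():
        raise ValidationError("duplicate feature_id in annotation table")
    return df


def _coerce_pairs(pairs: pd.DataFrame) -> pd.DataFrame:
    out = pairs.copy()
    for col in PAIR_COLUMNS:
        if col not in out.columns:
            out[col] = pd.NA if col.startswith("cluster") else np.nan
    out = out[PAIR_COLUMNS]
    out["cluster_i"] = out["cluster_i"].astype("Int64")
    out["cluster_j"] = out["cluster_j"].astype("Int64")
    return out


def write_pairs(pairs: pd.DataFrame, path) -> None:
    """Write a pair table as TSV; unset clusters become the sentinel ``NA``."""
    _coerce_pairs(pairs).to_csv(path, sep="\t", index=False, na_rep="NA")


def read_pairs(path) -> pd.DataFrame:
    """Read back a pair table written by :func:`write_pairs`."""
    df = pd.read_csv(
        path,
        sep="\t",
        na_values=["NA"],
        dtype={"feature_i": str, "feature_j": str, "metric_name": str},
    )
    return _coerce_pairs(df)


def write_matrix(matrix: pd.DataFrame, path) -> None:
    """Write a labelled feature x feature metric matrix as TSV."""
    matrix.to_csv(path, sep="\t")


def write_clusters(assignment, path) -> None:
    """Write a cluster assignment as a two-column TSV (feature_id, cluster)."""
    pd.DataFrame(
        {
            "feature_id": list(assignment.feature_ids),
            "cluster": [assignment.labels[f] for f in assignment.feature_ids],
        }
    ).to_csv(path, sep="\t", index=False)


def ensure_dir(path) -> None:
    os.makedirs(path, exist_ok=True)
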