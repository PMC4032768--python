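"""Expression-matrix container, delimited-text I/O, imputation and normalization.

The central container is :class:`ExpressionDataset`: an instances-by-features
real matrix of expression intensities with optional true class labels and a
nominal chip-type tag.  Missing cells are stored as ``NaN`` in ``values`` and
mirrored in a boolean ``missing_mask``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Dialect",
    "ExpressionDataset",
    "ParseError",
    "load_expression",
    "write_expression",
    "impute_missing",
    "normalize",
    "NORMALIZATION_METHODS",
]


class ParseError(ValueError):
    """Raised when a delimited expression file cannot be parsed."""


@dataclass(frozen=True)
class Dialect:
    """Options controlling how a delimited expression file is interpreted.

    Parameters
    ----------
    delimiter:
        Field separator; ``None`` infers ``,`` for ``.csv`` and tab otherwise.
    orientation:
        ``"instances_in_rows"`` (default) or ``"features_in_rows"`` for
        gene-per-row files, which are transposed on load.
    missing_tokens:
        Cell contents treated as unobserved (default: empty field or ``NA``).
    label_column, chip_column:
        Sidecar column names (after orientation normalization) carrying the
        true class label and the chip-type tag.
    """

    delimiter: str | None = None
    orientation: str = "instances_in_rows"
    missing_tokens: tuple[str, ...] = ("", "NA")
    label_column: str = "label"
    chip_column: str = "chip"

    def sep_for(self, path: Path) -> str:
        if self.delimiter is not None:
            return self.delimiter
        return "," if path.suffix.lower() == ".csv" else "\t"


@dataclass
class ExpressionDataset:
    """An instances x features expression matrix with optional labels.

    ``values`` holds ``NaN`` at unobserved cells; ``missing_mask`` mirrors
    those positions and is derived automatically when not supplied.
    """

    values: np.ndarray
    instance_ids: list[str]
    feature_ids: list[str]
    true_labels: np.ndarray | None = None
    chip_type: str = "unknown"
    missing_mask: np.ndarray = field(default=None)  # type: ignore[assignment]
    name: str = "dataset"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        n, d = self.values.shape
        if n < 2:
            raise ValueError(f"need at least 2 instances, got {n}")
        if d < 1:
            raise ValueError("need at least 1 feature")
        if len(self.instance_ids) != n:
            raise ValueError("instance_ids length does not match matrix rows")
        if len(self.feature_ids) != d:
            raise ValueError("feature_ids length does not match matrix columns")
        if self.missing_mask is None:
            self.missing_mask = np.isnan(self.values)
        else:
            self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
            if self.missing_mask.shape != self.values.shape:
                raise ValueError("missing_mask shape does not match values")
            if not np.array_equal(self.missing_mask, np.isnan(self.values)):
                raise ValueError("missing_mask inconsistent with NaN cells in values")
        if self.true_labels is not None:
            self.true_labels = np.asarray(self.true_labels)
            if len(self.true_labels) != n:
                raise ValueError("true_labels length does not match matrix rows")
            if len(set(self.true_labels.tolist())) < 2:
                logger.warning(
                    "dataset %r has fewer than 2 distinct true labels; "
                    "external validation against it is not meaningful",
                    self.name,
                )

    @property
    def n_instances(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def n_classes(self) -> int | None:
        if self.true_labels is None:
            return None
        return len(set(self.true_labels.tolist()))

    def with_values(self, values: np.ndarray) -> "ExpressionDataset":
        """Copy of this dataset with a new value matrix (mask re-derived)."""
        return replace(self, values=np.asarray(values, dtype=float), missing_mask=None)


def load_expression(path, dialect: Dialect | None = None) -> ExpressionDataset:
    """Read a delimited expression matrix (header row + id column).

    Sidecar ``label`` / ``chip`` columns, when present after orientation
    normalization, populate ``true_labels`` and ``chip_type``.
    """
    dialect = dialect or Dialect()
    path = Path(path)
    sep = dialect.sep_for(path)
    try:
        frame = pd.read_csv(path, sep=sep, index_col=0, dtype=str, keep_default_na=False)
    except pd.errors.ParserError as exc:  # ragged rows etc.; pandas names the line
        raise ParseError(f"{path}: {exc}") from exc
    if frame.shape[0] == 0:
        raise ParseError(f"{path}: no data rows")

    if dialect.orientation == "features_in_rows":
        frame = frame.T
    elif dialect.orientation != "instances_in_rows":
        raise ValueError(f"unknown orientation: {dialect.orientation!r}")

    true_labels = None
    chip_type = "unknown"
    if dialect.label_column in frame.columns:
        true_labels = frame.pop(dialect.label_column).to_numpy()
    if dialect.chip_column in frame.columns:
        chip = frame.pop(dialect.chip_column)
        chip_type = str(chip.iloc[0])

    raw = frame.to_numpy(dtype=object)
    missing = np.isin(raw.astype(str), dialect.missing_tokens) | (raw == None)  # noqa: E711
    numeric = pd.DataFrame(raw).apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    bad = np.isnan(numeric) & ~missing
    if bad.any():
        i, j = map(int, np.argwhere(bad)[0])
        raise ParseError(
            f"{path}: non-numeric cell {raw[i, j]!r} at instance "
            f"{frame.index[i]!r}, feature {frame.columns[j]!r}"
        )
    numeric[missing] = np.nan
    return ExpressionDataset(
        values=numeric,
        instance_ids=[str(i) for i in frame.index],
        feature_ids=[str(c) for c in frame.columns],
        true_labels=true_labels,
        chip_type=chip_type,
        name=path.stem,
    )


def write_expression(ds: ExpressionDataset, path, dialect: Dialect | None = None) -> None:
    """Write a dataset in the dialect :func:`load_expression` reads back.

    Floats are written with 17 significant digits so a round trip is exact.
    """
    dialect = dialect or Dialect()
    path = Path(path)
    frame = pd.DataFrame(ds.values, index=ds.instance_ids, columns=ds.feature_ids)
    if ds.true_labels is not None:
        frame[dialect.label_column] = ds.true_labels
    if ds.chip_type != "unknown":
        frame[dialect.chip_column] = ds.chip_type
    frame.to_csv(
        path,
        sep=dialect.sep_for(path),
        index_label="id",
        na_rep=dialect.missing_tokens[0],
        float_format="%.17g",
    )


def impute_missing(ds: ExpressionDataset, strategy: str = "feature_mean") -> ExpressionDataset:
    """Replace unobserved cells with the mean of observed values per feature."""
    if strategy != "feature_mean":
        raise ValueError(f"unknown imputation strategy: {strategy!r}")
    if not ds.missing_mask.any():
        return ds
    all_missing = ds.missing_mask.all(axis=0)
    if all_missing.any():
        j = int(np.argmax(all_missing))
        raise ValueError(f"feature {ds.feature_ids[j]!r} has no observed values")
    values = ds.values.copy()
    col_means = np.nanmean(values, axis=0)
    rows, cols = np.nonzero(ds.missing_mask)
    values[rows, cols] = col_means[cols]
    return ds.with_values(values)


def _norm_none(x: np.ndarray) -> np.ndarray:
    return x.copy()


def _norm_zscore(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=0)
    sd = x.std(axis=0)  # population sd
    out = np.zeros_like(x)
    ok = sd > 0
    out[:, ok] = (x[:, ok] - mu[ok]) / sd[ok]
    return out


def _norm_minmax(x: np.ndarray) -> np.ndarray:
    lo = x.min(axis=0)
    rng = x.max(axis=0) - lo
    out = np.full_like(x, 0.5)
    ok = rng > 0
    out[:, ok] = (x[:, ok] - lo[ok]) / rng[ok]
    return out


def _norm_rank(x: np.ndarray) -> np.ndarray:
    from scipy.stats import rankdata

    n = x.shape[0]
    ranks = rankdata(x, axis=0, method="average")
    return (ranks - 1.0) / (n - 1.0)


#: Registry of per-feature normalization methods; extensible by assignment.
NORMALIZATION_METHODS: dict[str, callable] = {
    "none": _norm_none,
    "zscore_feature": _norm_zscore,
    "minmax_feature": _norm_minmax,
    "rank_feature": _norm_rank,
}


def normalize(ds: ExpressionDataset, method: str) -> ExpressionDataset:
    """Apply a per-feature normalization from :data:`NORMALIZATION_METHODS`."""
    if method not in NORMALIZATION_METHODS:
        raise ValueError(
            f"unknown normalization method: {method!r} "
            f"(known: {sorted(NORMALIZATION_METHODS)})"
        )
    if ds.missing_mask.any():
        raise ValueError("normalize requires a fully observed matrix; impute first")
    if method == "none":
        return ds
    return ds.with_values(NORMALIZATION_METHODS[method](ds.values))
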