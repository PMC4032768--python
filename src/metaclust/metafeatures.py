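"""Dataset and algorithm meta-attributes.

A metaexample row has exactly 24 meta-attributes: 13 dataset descriptors,
5 nominal algorithm descriptors (the four RC tokens plus the normalization
tag), and the 6 internal validity measures, followed by the AMI performance
label and the (dataset_id, algorithm_name) keys.

The 13-descriptor set covers dimension, missingness, moment, outlier,
multivariate-normality, redundancy, class-structure and chip-type
characteristics of the kind used in microarray metalearning studies.  It is
implemented as a declarative registry so an alternative descriptor set can be
substituted; the registry size is pinned to 13 to preserve the 24-attribute
contract.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import stats

__all__ = [
    "DATASET_DESCRIPTOR_NAMES",
    "ALGORITHM_DESCRIPTOR_NAMES",
    "INTERNAL_MEASURE_COLUMNS",
    "INTERNAL_MEASURE_TOKENS",
    "META_ATTRIBUTE_COLUMNS",
    "NOMINAL_META_ATTRIBUTES",
    "extract_metafeatures",
    "describe_algorithm",
    "assemble_meta_attributes",
    "split_meta_attributes",
]

#: Instances farther from the centroid than mean + this many sd of centroid
#: distances are counted as outliers.
OUTLIER_SD_FACTOR = 2.0
#: Features with variance below this fraction of the median feature variance
#: are counted as low-variance (near-redundant).
LOW_VARIANCE_FRACTION = 0.10


def _imputed(values: np.ndarray) -> np.ndarray:
    """Feature-mean-imputed copy used by descriptors needing full rows."""
    if not np.isnan(values).any():
        return values
    out = values.copy()
    means = np.nanmean(out, axis=0)
    idx = np.nonzero(np.isnan(out))
    out[idx] = np.take(means, idx[1])
    return out


def _mean_skewness(ds):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sk = stats.skew(ds.values, axis=0, nan_policy="omit")
    return float(np.nanmean(np.asarray(sk, dtype=float)))


def _mean_kurtosis(ds):
    # Fisher (excess) kurtosis: 0 for a normal feature
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ku = stats.kurtosis(ds.values, axis=0, nan_policy="omit")
    return float(np.nanmean(np.asarray(ku, dtype=float)))


def _pct_outliers(ds):
    x = _imputed(ds.values)
    d = np.linalg.norm(x - x.mean(axis=0), axis=1)
    thr = d.mean() + OUTLIER_SD_FACTOR * d.std()
    return float(100.0 * (d > thr).mean())


def _mardia_skewness(ds):
    """Mardia's multivariate skewness b_{1,d} via the Gram/SVD identity.

    With S the (possibly singular) sample covariance, the Mahalanobis Gram
    matrix G_ij = (x_i - xbar)' S^+ (x_j - xbar) equals n * U_r U_r' on the
    non-null singular subspace, so b1 = mean_ij G_ij^3 is computed without
    ever forming the d x d covariance.
    """
    x = _imputed(ds.values)
    n = x.shape[0]
    xc = x - x.mean(axis=0)
    u, s, _ = np.linalg.svd(xc, full_matrices=False)
    r = s > s.max() * 1e-10 if s.size and s.max() > 0 else np.zeros_like(s, dtype=bool)
    g = n * (u[:, r] @ u[:, r].T)
    return float((g**3).sum() / n**2)


def _mean_abs_feature_correlation(ds):
    x = _imputed(ds.values)
    sd = x.std(axis=0)
    x = x[:, sd > 0]
    d = x.shape[1]
    if d < 2:
        return 0.0
    c = np.corrcoef(x, rowvar=False)
    off = np.abs(c[np.triu_indices(d, k=1)])
    return float(np.nanmean(off))


def _pct_low_variance(ds):
    var = np.nanvar(ds.values, axis=0)
    med = float(np.median(var))
    return float(100.0 * (var < LOW_VARIANCE_FRACTION * med).mean())


def _n_true_classes(ds):
    return float(ds.n_classes) if ds.true_labels is not None else float("nan")


def _class_balance_entropy(ds):
    if ds.true_labels is None:
        return float("nan")
    _, counts = np.unique(ds.true_labels, return_counts=True)
    if len(counts) < 2:
        return 0.0
    p = counts / counts.sum()
    return float(-(p * np.log(p)).sum() / np.log(len(counts)))


#: Declarative registry of the 13 dataset descriptors (order is the schema).
DATASET_DESCRIPTORS = {
    "log2_n_instances": lambda ds: float(np.log2(ds.n_instances)),
    "log2_n_features": lambda ds: float(np.log2(ds.n_features)),
    "instance_feature_ratio": lambda ds: ds.n_instances / ds.n_features,
    "pct_missing": lambda ds: float(100.0 * ds.missing_mask.mean()),
    "mean_skewness": _mean_skewness,
    "mean_kurtosis": _mean_kurtosis,
    "pct_outliers": _pct_outliers,
    "multivariate_normality_stat": _mardia_skewness,
    "mean_abs_feature_correlation": _mean_abs_feature_correlation,
    "pct_low_variance_features": _pct_low_variance,
    "n_true_classes": _n_true_classes,
    "class_balance_entropy": _class_balance_entropy,
    "chip_type": lambda ds: ds.chip_type,
}

DATASET_DESCRIPTOR_NAMES = tuple(DATASET_DESCRIPTORS)
assert len(DATASET_DESCRIPTOR_NAMES) == 13, "descriptor registry must stay at 13"

ALGORITHM_DESCRIPTOR_NAMES = ("init", "distance", "update", "evaluate", "normalization")

#: Internal-measure columns in the order the measures are usually listed
#: (compactness, silhouette, AIC, BIC, Xie-Beni, connectivity).
INTERNAL_MEASURE_COLUMNS = ("compact", "silhou", "aic", "bic", "xb", "conn")
INTERNAL_MEASURE_TOKENS = ("COMPACT", "SILHOU", "AIC", "BIC", "XB", "CONN")

META_ATTRIBUTE_COLUMNS = (
    DATASET_DESCRIPTOR_NAMES + ALGORITHM_DESCRIPTOR_NAMES + INTERNAL_MEASURE_COLUMNS
)
assert len(META_ATTRIBUTE_COLUMNS) == 24

NOMINAL_META_ATTRIBUTES = ("chip_type",) + ALGORITHM_DESCRIPTOR_NAMES


def extract_metafeatures(ds) -> dict:
    """The 13 dataset descriptors, computed on the raw (unnormalized) matrix.

    Missing values are permitted (``pct_missing`` is measured before any
    imputation); descriptors needing complete rows use an internal
    feature-mean-imputed copy.  Deterministic and invariant to instance and
    feature order.
    """
    if ds.n_instances < 3:
        raise ValueError("metafeature extraction needs at least 3 instances")
    return {name: fn(ds) for name, fn in DATASET_DESCRIPTORS.items()}


def describe_algorithm(spec) -> dict:
    """The 5 nominal algorithm descriptors of a spec."""
    return {
        "init": spec.init,
        "distance": spec.distance,
        "update": spec.update,
        "evaluate": spec.evaluate,
        "normalization": spec.normalization,
    }


def assemble_meta_attributes(mf, algo, internal, ami_label, dataset_id, algorithm_name) -> dict:
    """Assemble one metaexample row in the fixed 24-column order.

    ``internal`` may be a dict keyed by the lowercase column names or by the
    RC tokens, or a sequence of 6 values in column order.
    """
    if set(mf) != set(DATASET_DESCRIPTOR_NAMES):
        raise ValueError("dataset descriptor block must have exactly the 13 descriptors")
    if set(algo) != set(ALGORITHM_DESCRIPTOR_NAMES):
        raise ValueError("algorithm descriptor block must have exactly 5 descriptors")
    if isinstance(internal, dict):
        key_map = dict(zip(INTERNAL_MEASURE_TOKENS, INTERNAL_MEASURE_COLUMNS))
        internal = {key_map.get(k, k): v for k, v in internal.items()}
        if set(internal) != set(INTERNAL_MEASURE_COLUMNS):
            raise ValueError("internal measure block must have exactly 6 measures")
        internal_values = [internal[c] for c in INTERNAL_MEASURE_COLUMNS]
    else:
        internal_values = list(internal)
        if len(internal_values) != 6:
            raise ValueError("internal measure block must have exactly 6 measures")
    row = {name: mf[name] for name in DATASET_DESCRIPTOR_NAMES}
    row.update({name: algo[name] for name in ALGORITHM_DESCRIPTOR_NAMES})
    row.update(dict(zip(INTERNAL_MEASURE_COLUMNS, internal_values)))
    row["AMI"] = ami_label
    row["dataset_id"] = dataset_id
    row["algorithm_name"] = algorithm_name
    return row


def split_meta_attributes(row: dict):
    """Inverse of :func:`assemble_meta_attributes` (blocks + label)."""
    mf = {k: row[k] for k in DATASET_DESCRIPTOR_NAMES}
    algo = {k: row[k] for k in ALGORITHM_DESCRIPTOR_NAMES}
    internal = {k: row[k] for k in INTERNAL_MEASURE_COLUMNS}
    return mf, algo, internal, row["AMI"]
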