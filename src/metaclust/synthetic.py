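"""Synthetic expression-like datasets and metalearning benchmarks.

`generate_expression` emulates a clustered expression matrix: instances drawn
from ``k_true`` spherical Gaussians whose centers sit on a scaled simplex so
every pair of centers is exactly ``separation`` within-cluster standard
deviations apart.  Optional knobs add missing cells, outlier instances, a
shared latent factor inducing feature-feature correlation, and heavy-tailed
(Student-t) noise for stress-testing robust components.

`generate_meta_benchmark` builds a metaexample repository over a population
of such datasets, either by actually running clustering algorithms
("clustered" mode) or by synthesizing AMI labels directly from a declared
function of the meta-attributes ("oracle" mode, for fast metalearning tests
with a known planted effect).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dataset import ExpressionDataset, impute_missing
from .engine import run_experiment_grid
from .metafeatures import (
    INTERNAL_MEASURE_COLUMNS,
    assemble_meta_attributes,
    describe_algorithm,
    extract_metafeatures,
)
from .metalearning import MetaTable

__all__ = [
    "SyntheticConfig",
    "generate_expression",
    "generate_meta_benchmark",
    "planted_component_effect",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one synthetic expression dataset.

    ``separation`` is the between-center distance in units of the
    within-cluster standard deviation (sigma = 1): 0 means unclusterable,
    ~6 is well separated, >= 20 is trivially separable.
    """

    n_instances: int = 60
    n_features: int = 20
    k_true: int = 3
    separation: float = 6.0
    missing_rate: float = 0.0
    outlier_rate: float = 0.0
    feature_correlation: float = 0.0
    heavy_tails: bool = False
    chip_type: str = "Affy"
    seed: int = 0

    def __post_init__(self):
        if self.k_true < 1 or self.k_true > self.n_instances:
            raise ValueError("k_true must be in [1, n_instances]")
        if self.n_features < self.k_true:
            raise ValueError("need n_features >= k_true to embed separated centers")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        if not 0.0 <= self.outlier_rate < 1.0:
            raise ValueError("outlier_rate must be in [0, 1)")
        if not 0.0 <= self.feature_correlation < 1.0:
            raise ValueError("feature_correlation must be in [0, 1)")
        if self.separation < 0:
            raise ValueError("separation must be >= 0")


def generate_expression(cfg: SyntheticConfig) -> ExpressionDataset:
    """Draw one clustered expression-like dataset, fully determined by seed."""
    rng = np.random.default_rng(cfg.seed)
    n, d, k = cfg.n_instances, cfg.n_features, cfg.k_true

    # centers on a scaled simplex: |e_i - e_j| = sqrt(2), so scale by sep/sqrt(2)
    centers = np.zeros((k, d))
    centers[:, :k] = np.eye(k) * (cfg.separation / np.sqrt(2.0))

    sizes = np.full(k, n // k)
    sizes[: n % k] += 1
    labels = np.repeat([f"c{i}" for i in range(k)], sizes)

    if cfg.heavy_tails:
        noise = rng.standard_t(df=3, size=(n, d)) / np.sqrt(3.0)  # unit variance
    else:
        noise = rng.standard_normal((n, d))
    rho = cfg.feature_correlation
    if rho > 0:
        latent = rng.standard_normal((n, 1))
        noise = np.sqrt(rho) * latent + np.sqrt(1.0 - rho) * noise
    values = centers[np.repeat(np.arange(k), sizes)] + noise

    n_out = int(round(cfg.outlier_rate * n))
    if n_out:
        lo = values.min(axis=0)
        hi = values.max(axis=0)
        span = np.maximum(hi - lo, 1.0)
        out_idx = rng.choice(n, size=n_out, replace=False)
        values[out_idx] = rng.uniform(lo - span, hi + span, size=(n_out, d))

    if cfg.missing_rate > 0:
        mask = rng.random((n, d)) < cfg.missing_rate
        # never blank out a whole feature: keep at least one observed value
        full_cols = mask.all(axis=0)
        mask[0, full_cols] = False
        values = values.copy()
        values[mask] = np.nan

    return ExpressionDataset(
        values=values,
        instance_ids=[f"s{i}" for i in range(n)],
        feature_ids=[f"g{j}" for j in range(d)],
        true_labels=labels,
        chip_type=cfg.chip_type,
        name=f"synth-{cfg.seed}",
    )


def planted_component_effect(
    base: float = 0.2,
    component: str = "distance",
    level: str = "CORREL",
    boost: float = 0.3,
    noise_sd: float = 0.02,
    condition: tuple[str, float] | None = None,
):
    """Oracle-label function: AMI = base + boost*[component == level] + noise.

    With ``condition=(metafeature_name, threshold)`` the boost applies only on
    datasets where that metafeature exceeds the threshold — a planted
    metafeature x component interaction.  Labels are clipped to [0, 1].
    """

    def effect(mf: dict, spec, rng: np.random.Generator) -> float:
        label = base + rng.normal(0.0, noise_sd)
        active = getattr(spec, component) == level
        if condition is not None:
            name, threshold = condition
            active = active and float(mf[name]) > threshold
        if active:
            label += boost
        return float(np.clip(label, 0.0, 1.0))

    return effect


def default_config_sampler(rng: np.random.Generator) -> SyntheticConfig:
    """Spread of dataset sizes/separations/missingness emulating a benchmark
    collection of small expression matrices."""
    return SyntheticConfig(
        n_instances=int(rng.integers(40, 121)),
        n_features=int(rng.integers(10, 41)),
        k_true=int(rng.integers(2, 6)),
        separation=float(rng.uniform(1.0, 8.0)),
        missing_rate=float(rng.uniform(0.0, 0.05)),
        feature_correlation=float(rng.choice([0.05, 0.7])),
        chip_type=str(rng.choice(["cDNA", "Affy"])),
        seed=int(rng.integers(0, 2**31 - 1)),
    )


def generate_meta_benchmark(
    n_datasets: int,
    specs,
    seed: int = 0,
    effect=None,
    mode: str = "oracle",
    config_sampler=default_config_sampler,
):
    """Build (datasets, MetaTable) for metalearning tests.

    ``mode="clustered"`` runs every spec on every dataset (real internal
    measures and AMI).  ``mode="oracle"`` skips clustering: labels come from
    ``effect(metafeatures, spec, rng)`` and the internal-measure slots are
    filled with uninformative standard-normal draws.
    """
    if n_datasets < 20:
        raise ValueError("a meta benchmark needs at least 20 datasets")
    specs = list(specs)
    rng = np.random.default_rng(seed)
    datasets = [generate_expression(config_sampler(rng)) for _ in range(n_datasets)]
    for i, ds in enumerate(datasets):
        ds.name = f"bench-{seed}-{i}"

    if mode == "clustered":
        frame = run_experiment_grid(datasets, specs, seed=seed)
        return datasets, MetaTable(frame, provenance={ds.name: "synthetic" for ds in datasets})
    if mode != "oracle":
        raise ValueError(f"unknown benchmark mode: {mode!r}")
    if effect is None:
        effect = planted_component_effect()

    rows = []
    for ds in datasets:
        mf = extract_metafeatures(impute_missing(ds))
        mf["pct_missing"] = float(100.0 * ds.missing_mask.mean())
        for spec in specs:
            internal = {c: float(rng.standard_normal()) for c in INTERNAL_MEASURE_COLUMNS}
            label = effect(mf, spec, rng)
            rows.append(
                assemble_meta_attributes(
                    mf, describe_algorithm(spec), internal,
                    ami_label=label, dataset_id=ds.name, algorithm_name=spec.full_name,
                )
            )
    table = MetaTable.from_rows(rows, provenance={ds.name: "synthetic-oracle" for ds in datasets})
    return datasets, table
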