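"""Synthetic expression datasets with controllable class structure.

The generator emulates multi-subclass microarray / protein-array benchmark
data: a handful to a few dozen samples per subclass, thousands of noisy
features, and a small informative subset whose mean shifts differ between
subclasses.  Each class's shift is applied to its own disjoint block of the
informative features — the analogue of subtype-specific differentially
expressed genes — so every class is identifiable in principle.

Values are generated on a linear scale with additive Gaussian noise by
default (POC is amplitude-free, so no log transform or scaling is applied);
Student-t noise (df=3) is available to exercise the rank test's robustness
to heavy tails.  Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dataset import ExpressionDataset

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "generate",
    "generate_worked_fixture",
    "from_preset",
    "srbct_like_config",
    "PRESETS",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of one synthetic dataset.

    ``effect_size`` is the informative-feature mean shift in units of
    ``noise_sd``; 0 informative features (or effect 0) gives pure null data
    with no class signal.
    """

    n_classes: int
    samples_per_class: tuple[int, ...]
    n_features: int
    n_informative: int = 200
    effect_size: float = 2.0
    noise_sd: float = 1.0
    baseline_mean: float = 7.0
    noise: str = "gaussian"  # or "student_t" (df=3, scaled to sd=noise_sd)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")
        if len(self.samples_per_class) != self.n_classes:
            raise ValueError("samples_per_class must list one count per class")
        if any(c < 1 for c in self.samples_per_class):
            raise ValueError("every class needs at least 1 sample")
        if self.n_features < 1:
            raise ValueError("need at least 1 feature")
        if not 0 <= self.n_informative <= self.n_features:
            raise ValueError("n_informative must be in [0, n_features]")
        if self.noise_sd < 0 or self.effect_size < 0:
            raise ValueError("noise_sd and effect_size must be >= 0")
        if self.noise not in ("gaussian", "student_t"):
            raise ValueError(f"unknown noise model {self.noise!r}")


@dataclass(frozen=True)
class GroundTruth:
    """What the generator actually planted, for recovery tests."""

    informative_indices: np.ndarray
    #: K x N matrix of true per-class feature means.
    class_means: np.ndarray
    #: Informative-feature block assigned to each class label.
    class_blocks: dict[str, np.ndarray] = field(default_factory=dict)


def _class_labels(k: int) -> list[str]:
    width = len(str(k))
    return [f"c{i + 1:0{width}d}" for i in range(k)]  # zero-padded: lexicographic == numeric order


def generate(config: SyntheticConfig) -> tuple[ExpressionDataset, GroundTruth]:
    """Draw one dataset from ``config``; returns (dataset, ground truth)."""
    rng = np.random.default_rng(config.seed)
    k, n = config.n_classes, config.n_features
    m = int(sum(config.samples_per_class))
    labels_by_class = _class_labels(k)

    informative = np.sort(rng.choice(n, size=config.n_informative, replace=False))
    blocks = np.array_split(informative, k)
    class_means = np.full((k, n), config.baseline_mean)
    shift = config.effect_size * config.noise_sd
    for ci, block in enumerate(blocks):
        class_means[ci, block] += shift

    codes = np.repeat(np.arange(k), config.samples_per_class)
    if config.noise == "gaussian":
        noise = rng.standard_normal((m, n))
    else:
        df = 3.0
        noise = rng.standard_t(df, size=(m, n)) / np.sqrt(df / (df - 2.0))
    values = class_means[codes] + config.noise_sd * noise

    ds = ExpressionDataset(
        values=values,
        sample_ids=tuple(f"s{i + 1:03d}" for i in range(m)),
        feature_ids=tuple(f"f{j + 1:05d}" for j in range(n)),
        labels=tuple(labels_by_class[c] for c in codes),
    )
    truth = GroundTruth(
        informative_indices=informative,
        class_means=class_means,
        class_blocks={labels_by_class[ci]: blk for ci, blk in enumerate(blocks)},
    )
    return ds, truth


def generate_worked_fixture() -> ExpressionDataset:
    """A hard-coded 8-sample x 9-feature, 2-class dataset for worked examples.

    Feature f1 separates the classes cleanly ({1,2,3,4} vs {6,7,8,9}); with
    no ties its Kruskal-Wallis H is 12/(8*9) * [4*(2.5-4.5)^2 +
    4*(6.5-4.5)^2] = 16/3.  Feature f2 is constant (no information, p = 1).
    The remaining features are fixed arbitrary values.  Class templates are
    hand-checkable means, e.g. template(a)[f1] = (1+2+3+4)/4 = 2.5.
    """
    values = np.array(
        [
            # f1 f2 f3 f4 f5 f6 f7 f8 f9
            [1, 5, 2, 7, 1, 4, 9, 3, 6],
            [2, 5, 3, 6, 2, 5, 8, 2, 7],
            [3, 5, 1, 8, 1, 4, 9, 4, 5],
            [4, 5, 2, 7, 2, 3, 7, 3, 6],
            [6, 5, 8, 2, 9, 5, 1, 4, 2],
            [7, 5, 9, 1, 8, 6, 2, 3, 3],
            [8, 5, 7, 3, 9, 5, 1, 5, 1],
            [9, 5, 8, 2, 8, 4, 3, 4, 2],
        ],
        dtype=float,
    )
    return ExpressionDataset(
        values=values,
        sample_ids=tuple(f"s{i}" for i in range(1, 9)),
        feature_ids=tuple(f"f{j}" for j in range(1, 10)),
        labels=("a", "a", "a", "a", "b", "b", "b", "b"),
    )


def _near_even(total: int, k: int) -> tuple[int, ...]:
    base, rem = divmod(total, k)
    return tuple(base + 1 if i < rem else base for i in range(k))


#: Shapes (samples per class, feature count) mirroring well-known complex
#: disease benchmarks.  Per-class counts are the published ones where known
#: (gse29676, srbct, colon), otherwise near-even splits of the total.
#: gse5281's published total (161) exceeds the stated 87+71 per-group
#: counts; the total is kept and split 87/74.
PRESETS: dict[str, SyntheticConfig] = {
    "leukemia1": SyntheticConfig(3, _near_even(72, 3), 12582),
    "gse29676": SyntheticConfig(3, (50, 29, 40), 9480),
    "leukemia2": SyntheticConfig(3, _near_even(72, 3), 7129),
    "srbct": SyntheticConfig(4, (29, 11, 18, 25), 2308),
    "gse5281": SyntheticConfig(2, (87, 74), 54675),
    "colon": SyntheticConfig(2, (40, 22), 2000),
    "gcm": SyntheticConfig(14, _near_even(190, 14), 16063),
}


def from_preset(name: str, seed: int = 0, **overrides) -> tuple[ExpressionDataset, GroundTruth]:
    """Generate a dataset shaped like a named benchmark (see ``PRESETS``)."""
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(PRESETS)}")
    base = PRESETS[name]
    cfg = SyntheticConfig(
        n_classes=base.n_classes,
        samples_per_class=base.samples_per_class,
        n_features=base.n_features,
        n_informative=overrides.pop("n_informative", base.n_informative),
        effect_size=overrides.pop("effect_size", base.effect_size),
        noise_sd=overrides.pop("noise_sd", base.noise_sd),
        baseline_mean=overrides.pop("baseline_mean", base.baseline_mean),
        noise=overrides.pop("noise", base.noise),
        seed=seed,
    )
    if overrides:
        raise TypeError(f"unknown overrides: {sorted(overrides)}")
    return generate(cfg)


def srbct_like_config(effect_size: float = 2.0, seed: int = 0) -> SyntheticConfig:
    """4 classes, 83 samples, 2304 = 48^2 features (square, so 2-D POC applies
    without further selection), 200 informative."""
    return SyntheticConfig(
        n_classes=4,
        samples_per_class=(29, 11, 18, 25),
        n_features=2304,
        n_informative=200,
        effect_size=effect_size,
        seed=seed,
    )
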