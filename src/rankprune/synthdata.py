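"""Seeded synthetic tabular datasets with known informative features.

Four archetypes of clinical tabular data are emulated:

``numeric``
    low-dimensional numeric binary-outcome data (glucose/BMI-style panels);
``categorical_mixed``
    numeric plus 3-level categorical columns (cholesterol/ECG-style mixes);
``signal``
    numeric features passed through a bounded sinusoidal mixture, mimicking
    frequency/amplitude summaries of a recorded signal;
``highdim``
    p >> n omics-style data with correlated redundant blocks and class
    imbalance.

The generative model is Gaussian class-conditional: each informative
feature has unit within-class standard deviation and a between-class mean
gap equal to ``effect``, so the standardized separation is the effect size
itself and analytic expectations are available for tests. Noise features
are class-independent N(0,1); redundant features are a parent informative
feature plus N(0, noise_sd) noise, giving parent correlation
1/sqrt(1+noise_sd^2) (>= 0.8 for noise_sd <= 0.75).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_io import Dataset, FeatureMeta
from .exceptions import ConfigurationError

ARCHETYPES = ("numeric", "categorical_mixed", "signal", "highdim")


@dataclass(frozen=True)
class GeneratorSpec:
    """Parameters of the synthetic generator.

    ``effect`` is the standardized class-mean separation of informative
    features; ``imbalance`` the minority-class fraction in (0, 0.5];
    ``redundant_blocks`` the number of correlated copies per informative
    feature; ``n_categorical`` (mixed archetype) how many columns are
    quantile-binned into 3-level codes.
    """

    archetype: str = "numeric"
    n: int = 300
    p: int = 50
    p_informative: int = 5
    effect: float = 1.5
    imbalance: float = 0.5
    redundant_blocks: int = 0
    noise_sd: float = 0.5
    n_categorical: int = 0
    seed: int = 0

    def __post_init__(self):
        if self.archetype not in ARCHETYPES:
            raise ConfigurationError(f"unknown archetype {self.archetype!r}")
        if self.n < 2 or self.p < 1:
            raise ConfigurationError("need n >= 2 and p >= 1")
        if self.p_informative > self.p:
            raise ConfigurationError(
                f"p_informative={self.p_informative} exceeds p={self.p}"
            )
        if not (0.0 < self.imbalance <= 0.5):
            raise ConfigurationError("imbalance must lie in (0, 0.5]")
        if self.effect <= 0:
            raise ConfigurationError("effect must be positive")
        if self.noise_sd <= 0:
            raise ConfigurationError("noise_sd must be positive")
        if self.redundant_blocks < 0 or self.n_categorical < 0:
            raise ConfigurationError("counts must be nonnegative")
        n_derived = self.p_informative * (1 + self.redundant_blocks)
        if n_derived > self.p:
            raise ConfigurationError(
                "p too small for p_informative * (1 + redundant_blocks)"
            )
        if self.n_categorical > self.p:
            raise ConfigurationError("n_categorical exceeds p")
        if self.archetype == "highdim" and self.p < 5 * self.n:
            raise ConfigurationError("highdim archetype requires p >= 5 n")


def generate(spec: GeneratorSpec) -> Dataset:
    """Draw one dataset from the generator; bitwise-reproducible by seed."""
    rng = np.random.default_rng(spec.seed)
    n, p = spec.n, spec.p

    n_minority = int(round(spec.imbalance * n))
    y = np.zeros(n, dtype=int)
    y[:n_minority] = 1
    rng.shuffle(y)

    n_inf = spec.p_informative
    n_red = n_inf * spec.redundant_blocks
    n_noise = p - n_inf - n_red

    # informative: within-class sd 1, between-class mean gap = effect
    informative = rng.normal(0.0, 1.0, size=(n, n_inf))
    informative[y == 1] += spec.effect

    blocks = [informative]
    kinds = ["informative"] * n_inf
    parents = list(range(n_inf))
    for parent in range(n_inf):
        for _ in range(spec.redundant_blocks):
            blocks.append(
                (informative[:, parent]
                 + rng.normal(0.0, spec.noise_sd, size=n))[:, None]
            )
            kinds.append("redundant")
            parents.append(parent)
    if n_noise:
        blocks.append(rng.normal(0.0, 1.0, size=(n, n_noise)))
        kinds.extend(["noise"] * n_noise)
        parents.extend([-1] * n_noise)

    X = np.concatenate(blocks, axis=1)
    mask = np.asarray([k == "informative" for k in kinds], dtype=bool)

    order = rng.permutation(p)
    X = X[:, order]
    mask = mask[order]
    roles = [kinds[j] for j in order]
    parent_of = [parents[j] for j in order]

    feature_kind = {"numeric": "numeric", "categorical_mixed": "numeric",
                    "signal": "signal", "highdim": "omics"}[spec.archetype]

    if spec.archetype == "signal":
        # bounded sinusoid plus a linear amplitude term; breaks linearity
        # while preserving a monotone trend so class signal survives
        X = np.sin(X) + 0.3 * X

    meta: list[FeatureMeta] = []
    columns: list[np.ndarray] = []
    cat_cols: set[int] = set()
    if spec.archetype == "categorical_mixed" and spec.n_categorical > 0:
        cat_cols = set(
            rng.choice(p, size=spec.n_categorical, replace=False).tolist()
        )

    level_names = np.asarray(["low", "mid", "high"], dtype=object)
    width = len(str(p))
    for j in range(p):
        name = f"f{j + 1:0{width}d}"
        if j in cat_cols:
            # 3-level quantile binning keeps the class signal as an ordered code
            q1, q2 = np.quantile(X[:, j], [1 / 3, 2 / 3])
            codes = np.digitize(X[:, j], [q1, q2])
            columns.append(level_names[codes])
            meta.append(FeatureMeta(name=name, kind="categorical"))
        else:
            columns.append(X[:, j].astype(float))
            meta.append(FeatureMeta(name=name, kind=feature_kind))

    out = np.column_stack(columns) if cat_cols else X.astype(float)
    ds = Dataset(X=out, y=y, feature_meta=meta, informative_mask=mask)
    ds.roles = roles  # per-column role: informative / redundant / noise
    ds.parent_of = parent_of
    return ds


def fixture_suite() -> dict[str, Dataset]:
    """Four canonical seeded datasets mirroring familiar dataset shapes.

    Shapes follow well-known public benchmarks (768 x 8 diabetes panel,
    195 x 22 vocal-feature table, a 13-column mixed cardiology table, and a
    100 x 2000 imbalanced omics block); only the shapes are mirrored, no
    distributional fidelity is claimed.
    """
    specs = {
        "numeric": GeneratorSpec(archetype="numeric", n=768, p=8,
                                 p_informative=4, seed=11),
        "categorical_mixed": GeneratorSpec(archetype="categorical_mixed",
                                           n=300, p=13, p_informative=4,
                                           n_categorical=5, seed=13),
        "signal": GeneratorSpec(archetype="signal", n=195, p=22,
                                p_informative=5, seed=17),
        "highdim": GeneratorSpec(archetype="highdim", n=100, p=2000,
                                 p_informative=20, imbalance=0.3, seed=19),
    }
    return {name: generate(s) for name, s in specs.items()}
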