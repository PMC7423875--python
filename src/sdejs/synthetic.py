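"""Synthetic data with known ground truth.

Two generators back the test surface of the package:

* :func:`make_sparse_classification` — labeled Gaussian data in which only
  a known subset of features carries class information, so selector
  recall against the planted support is measurable exactly.
* :func:`make_surrogate_eeg` — directories of plain-ASCII single-channel
  signal segments (one amplitude per line, 4097 lines by default, one
  subdirectory per group) in the layout of the Bonn epilepsy corpus, so
  the loaders and the end-to-end pipeline run without any download.  The
  segments are stationary AR(2) processes with class-specific spectra —
  deliberately simple surrogates, with no claim of physiological realism.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .ejs import FeatureMatrix, LabelMatrix


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for a sparse-signal classification dataset.

    Informative features get a class-conditional mean offset of
    ``effect_size * noise_sd`` (each informative feature is elevated in
    exactly one class, assigned round-robin); nuisance features are
    zero-mean with pairwise equicorrelation ``correlation`` induced by a
    shared per-sample latent factor.
    """

    n_samples: int = 200
    n_features: int = 100
    n_informative: int = 10
    n_classes: int = 3
    effect_size: float = 1.5
    noise_sd: float = 1.0
    correlation: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_informative > self.n_features:
            raise ValueError("n_informative cannot exceed n_features")
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")
        if self.n_samples < 2 * self.n_classes:
            raise ValueError("each class needs at least 2 samples")
        if not self.noise_sd > 0:
            raise ValueError("noise_sd must be positive")
        if self.effect_size < 0:
            raise ValueError("effect_size must be nonnegative")
        if not 0 <= self.correlation < 1:
            raise ValueError("correlation must lie in [0, 1)")


def make_sparse_classification(
    spec: SyntheticSpec,
) -> tuple[FeatureMatrix, np.ndarray, set]:
    """Generate ``(X, labels, true_support)`` fully determined by the seed.

    ``X`` is ``n_features x n_samples``; ``true_support`` holds the
    indices of the ``n_informative`` discriminative features.
    """
    rng = np.random.default_rng(spec.seed)
    n, d, k, c = spec.n_samples, spec.n_features, spec.n_informative, spec.n_classes

    # Balanced labels, then shuffled so class blocks are not contiguous.
    labels = rng.permutation(np.arange(n) % c)

    support = rng.choice(d, size=k, replace=False)
    X = np.empty((d, n))

    # Equicorrelated nuisance block via a shared latent factor.
    rho = spec.correlation
    latent = rng.standard_normal(n)
    noise = rng.standard_normal((d, n))
    X[:] = spec.noise_sd * (
        np.sqrt(rho) * latent[None, :] + np.sqrt(1.0 - rho) * noise
    )

    # Informative features: independent noise plus a one-class mean bump.
    for j, feat in enumerate(support):
        target_class = j % c
        mean = np.where(labels == target_class, spec.effect_size * spec.noise_sd, 0.0)
        X[feat] = mean + spec.noise_sd * rng.standard_normal(n)

    fm = FeatureMatrix(X)
    return fm, labels, set(int(i) for i in support)


def one_hot(labels, n_classes: int) -> LabelMatrix:
    """Encode integer class labels as an ``n x c`` one-hot matrix."""
    labels = np.asarray(labels, dtype=int)
    if labels.ndim != 1:
        raise ValueError("labels must be a 1-D sequence")
    if labels.size and (labels.min() < 0 or labels.max() >= n_classes):
        raise ValueError(
            f"labels must lie in 0..{n_classes - 1}, got range "
            f"[{labels.min()}, {labels.max()}]"
        )
    Y = np.zeros((labels.size, n_classes))
    Y[np.arange(labels.size), labels] = 1.0
    return LabelMatrix(Y)


@dataclass(frozen=True)
class ArClass:
    """A surrogate signal class: an AR(2) process ``x_t = a1 x_{t-1} +
    a2 x_{t-2} + e_t`` scaled to an amplitude range."""

    name: str
    a1: float
    a2: float
    scale: float = 50.0

    def __post_init__(self) -> None:
        # Stationarity triangle for AR(2): roots of 1 - a1 z - a2 z^2
        # outside the unit circle.
        if not (
            abs(self.a2) < 1
            and self.a1 + self.a2 < 1
            and self.a2 - self.a1 < 1
        ):
            raise ValueError(
                f"AR coefficients ({self.a1}, {self.a2}) for class "
                f"{self.name!r} are not stationary"
            )


# Five groups with distinct spectra and amplitude ranges, echoing the
# healthy (A, B) vs interictal (C, D) vs ictal (E) contrast: the ictal
# surrogate is a large-amplitude, strongly resonant process.
DEFAULT_EEG_CLASSES = (
    ArClass("A", 1.3, -0.40, scale=40.0),
    ArClass("B", 1.0, -0.30, scale=40.0),
    ArClass("C", 0.6, -0.20, scale=60.0),
    ArClass("D", 1.5, -0.70, scale=80.0),
    ArClass("E", 1.7, -0.90, scale=300.0),
)


@dataclass(frozen=True)
class SurrogateEegSpec:
    """Layout and process parameters for surrogate segment emission."""

    segments_per_class: int = 100
    segment_length: int = 4097
    classes: tuple = DEFAULT_EEG_CLASSES
    seed: int = 0

    def __post_init__(self) -> None:
        if self.segment_length < 16:
            raise ValueError("segment_length must be >= 16")
        if self.segments_per_class < 1:
            raise ValueError("segments_per_class must be >= 1")


def _simulate_ar2(
    cls: ArClass, length: int, rng: np.random.Generator, burn_in: int = 500
) -> np.ndarray:
    e = rng.standard_normal(length + burn_in)
    x = np.zeros(length + burn_in)
    for t in range(2, length + burn_in):
        x[t] = cls.a1 * x[t - 1] + cls.a2 * x[t - 2] + e[t]
    x = x[burn_in:]
    sd = x.std()
    if sd > 0:
        x = x / sd
    return cls.scale * x


def make_surrogate_eeg(spec: SurrogateEegSpec, out_dir) -> Path:
    """Write one ASCII file per segment plus a ``manifest.csv``.

    Layout: ``out_dir/<group>/<group><idx>.txt``, each file exactly
    ``segment_length`` lines, one integer amplitude per line — the
    dialect the Bonn loader consumes.  Byte-for-byte deterministic under
    the spec's seed.
    """
    out_dir = Path(out_dir)
    rng = np.random.default_rng(spec.seed)
    manifest_rows = []
    for label, cls in enumerate(spec.classes):
        group_dir = out_dir / cls.name
        group_dir.mkdir(parents=True, exist_ok=True)
        for i in range(spec.segments_per_class):
            x = _simulate_ar2(cls, spec.segment_length, rng)
            fname = f"{cls.name}{i + 1:03d}.txt"
            body = "\n".join(str(int(round(v))) for v in x) + "\n"
            (group_dir / fname).write_text(body)
            manifest_rows.append((f"{cls.name}/{fname}", cls.name, label))
    with open(out_dir / "manifest.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["filename", "group", "label"])
        writer.writerows(manifest_rows)
    return out_dir
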