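"""Synthetic reference profiles and mixtures with known ground truth.

The generator emulates the structure the deconvolution pipeline assumes:
each cell type shares a common baseline transcriptome but elevates a small
disjoint set of marker genes; replicate arrays are the class profile times
multiplicative measurement noise; bulk mixtures are proportion-weighted sums
of the class profiles (the linear mixing model M = S F) plus noise, with the
mixing proportions drawn from a Dirichlet and returned as ground truth.

Baseline intensities are log-normal (log2-normal with mean 6, sd 2), so
values are positive and right-skewed like microarray intensities.  The noise
model is multiplicative log-normal by default (sd on the log2 scale);
additive Gaussian with sd proportional to the expected intensity is
available via ``noise_model="additive"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .io_formats import ExpressionMatrix, PhenotypeAnnotation

__all__ = [
    "GeneratorSpec",
    "MixtureTruth",
    "planted_markers",
    "generate_references",
    "generate_mixtures",
    "plant_outlier",
]

_BASE_LOG2_MEAN = 6.0
_BASE_LOG2_SD = 2.0


@dataclass
class GeneratorSpec:
    """All knobs of the generator; ``seed`` fixes every random draw.

    marker_effect is the fold elevation of a marker gene in its own class;
    noise_sd is the replicate noise level (log2-scale sd for the log-normal
    model, relative sd for the additive model); dirichlet_alpha is the
    symmetric concentration of the mixing proportions.
    """

    n_classes: int = 8
    n_genes: int = 1000
    markers_per_class: int = 5
    replicates_per_class: int = 3
    marker_effect: float = 8.0
    noise_sd: float = 0.01
    noise_model: str = "lognormal"
    dirichlet_alpha: float = 1.0
    n_mixtures: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_classes", "n_genes", "markers_per_class",
                     "replicates_per_class", "n_mixtures"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.markers_per_class * self.n_classes > self.n_genes:
            raise ValueError("more planted markers than genes")
        if self.noise_model not in ("lognormal", "additive"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")
        if self.marker_effect <= 0 or self.dirichlet_alpha <= 0:
            raise ValueError("marker_effect and dirichlet_alpha must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    @property
    def class_labels(self) -> list[str]:
        return [f"class_{k + 1:02d}" for k in range(self.n_classes)]

    @property
    def gene_ids(self) -> list[str]:
        return [f"G{i + 1:04d}" for i in range(self.n_genes)]


@dataclass
class MixtureTruth:
    """Ground-truth mixing proportions plus an echo of the generator spec."""

    f_true: pd.DataFrame  # mixtures x classes, rows sum to 1
    spec: GeneratorSpec

    def __post_init__(self) -> None:
        values = self.f_true.to_numpy()
        if (values < 0).any():
            raise ValueError("ground-truth proportions must be non-negative")
        if not np.allclose(values.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("ground-truth proportions must sum to 1 per mixture")

    def spec_echo(self) -> dict:
        return asdict(self.spec)


def planted_markers(spec: GeneratorSpec) -> dict[str, list[str]]:
    """Which genes are markers of which class (assigned deterministically:
    the first ``markers_per_class * n_classes`` genes, in class blocks)."""
    genes = spec.gene_ids
    m = spec.markers_per_class
    return {
        label: genes[k * m : (k + 1) * m]
        for k, label in enumerate(spec.class_labels)
    }


def _rng_for(spec: GeneratorSpec, stream: int) -> np.random.Generator:
    # independent streams so references and mixtures do not share draws
    return np.random.default_rng(np.random.SeedSequence(spec.seed).spawn(stream + 1)[stream])


def _class_profiles(spec: GeneratorSpec) -> pd.DataFrame:
    """Noise-free per-class expected profiles (genes x classes)."""
    rng = _rng_for(spec, 0)
    base = np.exp2(rng.normal(_BASE_LOG2_MEAN, _BASE_LOG2_SD, size=spec.n_genes))
    profiles = np.tile(base[:, None], (1, spec.n_classes))
    m = spec.markers_per_class
    for k in range(spec.n_classes):
        profiles[k * m : (k + 1) * m, k] *= spec.marker_effect
    return pd.DataFrame(profiles, index=spec.gene_ids, columns=spec.class_labels)


def _apply_noise(
    expected: np.ndarray, spec: GeneratorSpec, rng: np.random.Generator
) -> np.ndarray:
    if spec.noise_sd == 0:
        return expected.copy()
    if spec.noise_model == "lognormal":
        return expected * np.exp2(rng.normal(0.0, spec.noise_sd, size=expected.shape))
    noisy = expected + rng.normal(0.0, spec.noise_sd * expected, size=expected.shape)
    return np.clip(noisy, 0.0, None)


def generate_references(
    spec: GeneratorSpec,
) -> tuple[ExpressionMatrix, PhenotypeAnnotation]:
    """Replicated reference arrays: per class, ``replicates_per_class`` noisy
    copies of the class profile."""
    profiles = _class_profiles(spec)
    rng = _rng_for(spec, 1)
    columns: dict[str, np.ndarray] = {}
    assignments: dict[str, str] = {}
    for label in spec.class_labels:
        expected = profiles[label].to_numpy()
        for rep in range(spec.replicates_per_class):
            sample = f"{label}_rep{rep + 1}"
            columns[sample] = _apply_noise(expected, spec, rng)
            assignments[sample] = label
    matrix = ExpressionMatrix(pd.DataFrame(columns, index=spec.gene_ids))
    return matrix, PhenotypeAnnotation(assignments)


def generate_mixtures(
    references: ExpressionMatrix,
    annotation: PhenotypeAnnotation,
    spec: GeneratorSpec,
) -> tuple[ExpressionMatrix, MixtureTruth]:
    """Bulk mixtures M = S F (class means of the references, Dirichlet F)
    plus measurement noise; the true F is returned alongside."""
    annotation.validate_against(references)
    classes = annotation.classes
    s_true = np.column_stack(
        [references.data[annotation.samples_of(c)].mean(axis=1).to_numpy() for c in classes]
    )
    rng = _rng_for(spec, 2)
    f_true = rng.dirichlet([spec.dirichlet_alpha] * len(classes), size=spec.n_mixtures)
    expected = s_true @ f_true.T  # genes x mixtures
    noisy = _apply_noise(expected, spec, rng)
    mixture_ids = [f"mix_{j + 1:03d}" for j in range(spec.n_mixtures)]
    mixtures = ExpressionMatrix(
        pd.DataFrame(noisy, index=references.gene_ids, columns=mixture_ids)
    )
    truth = MixtureTruth(
        pd.DataFrame(f_true, index=mixture_ids, columns=classes), spec
    )
    return mixtures, truth


def plant_outlier(
    references: ExpressionMatrix,
    annotation: PhenotypeAnnotation,
    sample_id: str,
    donor_class: str,
    spec: GeneratorSpec,
) -> ExpressionMatrix:
    """Replace one reference column with a noisy copy of another class's
    profile, producing an array whose label disagrees with its expression."""
    if sample_id not in references.data.columns:
        raise KeyError(f"unknown sample {sample_id!r}")
    if donor_class not in annotation.classes:
        raise KeyError(f"unknown class {donor_class!r}")
    profiles = _class_profiles(spec)
    rng = _rng_for(spec, 3)
    planted = _apply_noise(profiles[donor_class].to_numpy(), spec, rng)
    frame = references.data.copy()
    frame[sample_id] = planted
    return ExpressionMatrix(frame)
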