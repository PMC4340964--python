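"""Low-level stimulus similarity: pairwise pixel correlations within and
between image sets, compared with Welch two-tailed t-tests."""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from PIL import Image

from .errors import ConfigurationError
from .stats import TestResult, welch_t


@dataclass
class ImageSet:
    """A labelled stack of same-shape grayscale images (float intensities)."""

    label: str
    images: np.ndarray  # (n, h, w)

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images, dtype=float)
        if self.images.ndim != 3:
            raise ConfigurationError("images must be a (n, h, w) stack")
        if len(self.images) < 2:
            raise ConfigurationError("an image set needs at least 2 images")

    def __len__(self) -> int:
        return len(self.images)

    @classmethod
    def from_files(cls, label: str, paths: Sequence[str | Path]) -> "ImageSet":
        """Load PNG/TIFF/JPEG images; colour is converted by luminance."""
        arrays = [np.asarray(Image.open(p).convert("L"), dtype=float) for p in paths]
        shapes = {a.shape for a in arrays}
        if len(shapes) > 1:
            raise ConfigurationError(f"images differ in size: {sorted(shapes)}")
        return cls(label=label, images=np.stack(arrays))


def pixel_correlation(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation over flattened pixel intensities.

    Returns NaN (with a warning) when either image is constant, since the
    correlation is then undefined.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ConfigurationError("images must have identical dimensions")
    da = a - a.mean()
    db = b - b.mean()
    denom = np.sqrt((da @ da) * (db @ db))
    if denom == 0:
        warnings.warn("constant image: pixel correlation undefined", RuntimeWarning, stacklevel=2)
        return float("nan")
    return float((da @ db) / denom)


@dataclass
class SimilarityReport:
    """Within/between-set pixel-correlation lists and their Welch tests."""

    within: dict[str, np.ndarray]  # label -> n(n-1)/2 correlations
    between: np.ndarray  # n1*n2 correlations
    means: dict[str, float]
    sems: dict[str, float]
    tests: dict[str, TestResult]

    def to_dict(self) -> dict:
        return {
            "within": {k: v.tolist() for k, v in self.within.items()},
            "between": self.between.tolist(),
            "means": self.means,
            "sems": self.sems,
            "tests": {
                k: {
                    "t": r.statistic,
                    "df": round(r.df, 2),
                    "p": r.p,
                    "tail": r.tail,
                }
                for k, r in self.tests.items()
            },
        }


def _sem(x: np.ndarray) -> float:
    x = x[~np.isnan(x)]
    return float(x.std(ddof=1) / np.sqrt(len(x))) if len(x) > 1 else float("nan")


def compare_sets(s1: ImageSet, s2: ImageSet) -> SimilarityReport:
    """All pairwise pixel correlations within each set and between sets.

    For sets of n images there are n(n-1)/2 within-set pairs per set and
    n1*n2 between-set pairs.  Three Welch two-tailed tests compare
    within-set-1 vs between, within-set-2 vs between, and the two within
    lists against each other.
    """
    if s1.images.shape[1:] != s2.images.shape[1:]:
        raise ConfigurationError("the two sets must share image dimensions")

    def within(s: ImageSet) -> np.ndarray:
        return np.array(
            [pixel_correlation(s.images[i], s.images[j])
             for i, j in itertools.combinations(range(len(s)), 2)]
        )

    w1 = within(s1)
    w2 = within(s2)
    between = np.array(
        [pixel_correlation(a, b) for a in s1.images for b in s2.images]
    )

    def clean(x: np.ndarray) -> np.ndarray:
        return x[~np.isnan(x)]

    comparisons = {
        f"within_{s1.label}_vs_between": (clean(w1), clean(between)),
        f"within_{s2.label}_vs_between": (clean(w2), clean(between)),
        f"within_{s1.label}_vs_within_{s2.label}": (clean(w1), clean(w2)),
    }
    # a set of 2 images yields a single within-pair; the test is then undefined
    tests = {
        key: welch_t(a, b, "two")
        for key, (a, b) in comparisons.items()
        if len(a) >= 2 and len(b) >= 2
    }
    return SimilarityReport(
        within={s1.label: w1, s2.label: w2},
        between=between,
        means={
            f"within_{s1.label}": float(np.nanmean(w1)),
            f"within_{s2.label}": float(np.nanmean(w2)),
            "between": float(np.nanmean(between)),
        },
        sems={
            f"within_{s1.label}": _sem(w1),
            f"within_{s2.label}": _sem(w2),
            "between": _sem(between),
        },
        tests=tests,
    )


def synthetic_image_set(
    label: str,
    n_images: int = 8,
    shape: tuple[int, int] = (64, 64),
    seed: int = 0,
    base_contrast: float = 1.0,
    variation: float = 0.3,
) -> ImageSet:
    """Seeded stand-in stimuli: a shared smooth base pattern per set plus
    per-image perturbations, so within-set correlations are high but < 1."""
    rng = np.random.default_rng(seed)

    def smooth(field: np.ndarray) -> np.ndarray:
        # cheap separable blur to make images spatially correlated
        k = np.ones(7) / 7.0
        out = np.apply_along_axis(lambda r: np.convolve(r, k, mode="same"), 0, field)
        return np.apply_along_axis(lambda r: np.convolve(r, k, mode="same"), 1, out)

    base = smooth(rng.normal(0, base_contrast, shape))
    images = np.stack(
        [base + smooth(rng.normal(0, variation, shape)) for _ in range(n_images)]
    )
    return ImageSet(label=label, images=images)
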