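"""Core domain types shared across the package.

The unit of data is a 2-D slice: a single-channel image in [0, 1] plus an
integer per-pixel class map. Slices carry a provenance flag distinguishing
trusted ("strong") labels from inaccurate automatically-generated ("weak")
ones; the refinement pipeline rewrites weak label maps but never promotes a
sample to strong provenance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = ["ClassScheme", "SliceSample", "CANONICAL_SCHEME", "Provenance"]

#: Allowed provenance values. ``truth`` is used only by evaluation manifests.
Provenance = str
_PROVENANCES = ("strong", "weak", "truth")


@dataclass(frozen=True)
class ClassScheme:
    """Ordered catalogue of segmentation classes.

    Index 0 is always the background; foreground classes follow in fixed
    order. The canonical abdominal scheme is background, muscle,
    subcutaneous adipose tissue (SAT), visceral adipose tissue (VAT).
    """

    names: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.names) < 2:
            raise ValueError("a class scheme needs at least background + 1 class")
        if len(set(self.names)) != len(self.names):
            raise ValueError(f"class names must be unique, got {self.names}")
        if self.names[0] != "background":
            raise ValueError("class index 0 must be 'background'")

    @property
    def count(self) -> int:
        return len(self.names)

    @property
    def foreground(self) -> tuple[int, ...]:
        """Indices of the non-background classes, in scheme order."""
        return tuple(range(1, self.count))

    def validate_labels(self, labels: np.ndarray, context: str = "label map") -> None:
        """Raise ``ValueError`` if any value is not a valid class index."""
        labels = np.asarray(labels)
        if labels.ndim != 2:
            raise ValueError(f"{context}: expected a 2-D array, got shape {labels.shape}")
        bad = labels[(labels < 0) | (labels >= self.count)]
        if bad.size:
            raise ValueError(
                f"{context}: invalid class value {int(bad.flat[0])}; "
                f"valid indices are 0..{self.count - 1}"
            )


#: Background, muscle, subcutaneous and visceral adipose tissue.
CANONICAL_SCHEME = ClassScheme(
    ("background", "muscle", "subcutaneous_adipose", "visceral_adipose")
)


@dataclass(frozen=True)
class SliceSample:
    """One 2-D image with its per-pixel class labels.

    ``provenance`` is fixed at construction: refined labels always produce a
    new *weak* revision, never a strong sample. Arrays are defensively
    read-only so revisions cannot mutate shared data.
    """

    image: np.ndarray
    labels: np.ndarray
    provenance: Provenance
    sample_id: str
    scheme: ClassScheme = field(default=CANONICAL_SCHEME, repr=False)

    def __post_init__(self) -> None:
        image = np.ascontiguousarray(np.asarray(self.image, dtype=np.float64))
        labels = np.ascontiguousarray(np.asarray(self.labels, dtype=np.int64))
        if image.ndim != 2:
            raise ValueError(f"image must be 2-D, got shape {image.shape}")
        if image.shape != labels.shape:
            raise ValueError(
                f"image shape {image.shape} != label shape {labels.shape}"
            )
        if self.provenance not in _PROVENANCES:
            raise ValueError(
                f"provenance must be one of {_PROVENANCES}, got {self.provenance!r}"
            )
        self.scheme.validate_labels(labels, context=f"sample {self.sample_id}")
        image.setflags(write=False)
        labels.setflags(write=False)
        object.__setattr__(self, "image", image)
        object.__setattr__(self, "labels", labels)

    @property
    def shape(self) -> tuple[int, int]:
        return self.image.shape  # type: ignore[return-value]

    def with_labels(self, labels: np.ndarray, sample_id: str | None = None) -> "SliceSample":
        """Return a new *weak* revision carrying ``labels`` over the same image."""
        return SliceSample(
            image=self.image,
            labels=labels,
            provenance="weak",
            sample_id=self.sample_id if sample_id is None else sample_id,
            scheme=self.scheme,
        )


def as_sample_list(samples: Sequence[SliceSample]) -> list[SliceSample]:
    if not samples:
        raise ValueError("sample set must be non-empty")
    return list(samples)
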