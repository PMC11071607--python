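"""Synthetic abdominal-slice phantoms and weak-label corruption.

Real abdominal CT with body-composition annotations is not publicly
redistributable, so the pipeline is exercised on a geometric stand-in that
keeps the spatial structure the refinement method must exploit: a concentric
"abdomen" with a thick subcutaneous fat band wrapped around a muscle ring
that encloses a visceral fat interior, plus a few isolated muscle patches
inside the interior (the analogue of pelvis muscle).

Weak labels are produced by parametric corruption of the ground truth,
emulating the two failure modes of automated body-composition segmenters:
whole muscle components go missing, and the innermost part of the
subcutaneous band is mislabeled as visceral fat. A seeded morphological
jitter can additionally perturb class boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure, morphology

from .core import CANONICAL_SCHEME, ClassScheme, SliceSample

__all__ = ["CorruptionSpec", "generate_phantom", "corrupt_labels"]

# Class indices in the canonical scheme.
BG, MUSCLE, SAT, VAT = 0, 1, 2, 3

# Mean intensity per class (unitless, image already normalized to [0, 1]).
# Muscle is bright against both fat compartments; SAT and VAT differ by a
# smaller margin, as on soft-tissue windows.
_CLASS_MEANS = {BG: 0.05, MUSCLE: 0.60, SAT: 0.25, VAT: 0.38}
_NOISE_SD = 0.03
_BIAS_AMPLITUDE = 0.04


@dataclass(frozen=True)
class CorruptionSpec:
    """Parameters of the weak-label corruption operator.

    muscle_miss_fraction
        Fraction of muscle connected components deleted to background,
        in [0, 1]. Selection is a seeded draw biased toward small
        components (isolated patches are missed far more often than the
        main muscle wall); 1.0 deletes every component.
    sat_to_vat_band
        Width in pixels of the innermost subcutaneous strip that is
        relabeled as visceral adipose tissue.
    boundary_jitter
        Maximum radius in pixels of a per-class seeded erosion/dilation.
    seed
        Fully determines the corruption.
    """

    muscle_miss_fraction: float = 0.5
    sat_to_vat_band: int = 3
    boundary_jitter: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.muscle_miss_fraction <= 1.0:
            raise ValueError(
                f"muscle_miss_fraction must be in [0, 1], got {self.muscle_miss_fraction}"
            )
        if self.sat_to_vat_band < 0:
            raise ValueError(f"sat_to_vat_band must be >= 0, got {self.sat_to_vat_band}")
        if self.boundary_jitter < 0:
            raise ValueError(f"boundary_jitter must be >= 0, got {self.boundary_jitter}")


def _ellipse_mask(h: int, w: int, cy: float, cx: float, ry: float, rx: float) -> np.ndarray:
    yy, xx = np.mgrid[0:h, 0:w]
    return ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0


def generate_phantom(
    seed: int,
    height: int,
    width: int,
    scheme: ClassScheme = CANONICAL_SCHEME,
) -> SliceSample:
    """Generate one ground-truth phantom slice.

    The label map is concentric — background / SAT band / muscle ring /
    VAT interior with scattered muscle patches — with seeded jitter of the
    centre, radii and patch placement. The image is a per-class mean plus a
    smooth multiplicative-style bias field and Gaussian noise, clipped to
    [0, 1]. Identical seeds give bit-identical samples.
    """
    if height < 32 or width < 32:
        raise ValueError(f"height and width must be >= 32, got {height}x{width}")
    if scheme.count != 4 or scheme != CANONICAL_SCHEME:
        raise ValueError("generate_phantom requires the canonical 4-class scheme")

    rng = np.random.default_rng(seed)
    half_h, half_w = height / 2.0, width / 2.0
    half = min(half_h, half_w)

    cy = half_h * (1.0 + rng.uniform(-0.04, 0.04))
    cx = half_w * (1.0 + rng.uniform(-0.04, 0.04))
    ry_out = half_h * rng.uniform(0.84, 0.92)
    rx_out = half_w * rng.uniform(0.84, 0.92)
    t_sat = half * rng.uniform(0.30, 0.36)  # thick subcutaneous band
    t_mus = half * rng.uniform(0.12, 0.16)  # muscle wall

    body = _ellipse_mask(height, width, cy, cx, ry_out, rx_out)
    inner1 = _ellipse_mask(height, width, cy, cx, ry_out - t_sat, rx_out - t_sat)
    inner2 = _ellipse_mask(
        height, width, cy, cx, ry_out - t_sat - t_mus, rx_out - t_sat - t_mus
    )

    labels = np.zeros((height, width), dtype=np.int64)
    labels[body] = SAT
    labels[inner1] = MUSCLE
    labels[inner2] = VAT

    # Isolated muscle patches inside the visceral interior (pelvis-muscle
    # analogue). Centres are kept well inside so patches stay disconnected
    # from the ring.
    n_patches = int(rng.integers(3, 5))
    ry_vat = ry_out - t_sat - t_mus
    rx_vat = rx_out - t_sat - t_mus
    for _ in range(n_patches):
        ang = rng.uniform(0, 2 * np.pi)
        rad = rng.uniform(0.15, 0.55)
        py = cy + rad * ry_vat * np.sin(ang)
        px = cx + rad * rx_vat * np.cos(ang)
        pr = half * rng.uniform(0.10, 0.15)
        patch = _ellipse_mask(height, width, py, px, pr, pr)
        labels[patch & inner2] = MUSCLE

    image = np.empty((height, width), dtype=np.float64)
    for cls, mean in _CLASS_MEANS.items():
        image[labels == cls] = mean

    # Smooth bias field: two low-frequency cosine modes with seeded phase.
    yy, xx = np.mgrid[0:height, 0:width]
    ph1, ph2 = rng.uniform(0, 2 * np.pi, size=2)
    bias = _BIAS_AMPLITUDE * (
        0.6 * np.cos(2 * np.pi * yy / height + ph1)
        + 0.4 * np.cos(2 * np.pi * xx / width + ph2)
    )
    image += bias + rng.normal(0.0, _NOISE_SD, size=image.shape)
    np.clip(image, 0.0, 1.0, out=image)

    sample = SliceSample(
        image=image,
        labels=labels,
        provenance="strong",
        sample_id=f"phantom-{seed:08d}",
        scheme=scheme,
    )
    _check_fractions(sample)
    return sample


def _check_fractions(sample: SliceSample) -> None:
    n = sample.labels.size
    for cls in sample.scheme.foreground:
        frac = np.count_nonzero(sample.labels == cls) / n
        if not 0.01 <= frac <= 0.60:
            raise RuntimeError(
                f"phantom geometry degenerate: class {cls} occupies {frac:.3f} of pixels"
            )


def _fill_from_nearest(labels: np.ndarray, holes: np.ndarray) -> np.ndarray:
    """Fill ``holes`` with the label of the nearest non-hole pixel."""
    if not holes.any():
        return labels
    _, (iy, ix) = ndimage.distance_transform_edt(holes, return_indices=True)
    out = labels.copy()
    out[holes] = labels[iy[holes], ix[holes]]
    return out


def corrupt_labels(truth: SliceSample, spec: CorruptionSpec) -> SliceSample:
    """Corrupt a ground-truth label map into a weak-provenance revision.

    The image channel is untouched and ``truth`` is never mutated.
    Corruption order: muscle-component deletion, SAT-to-VAT inner band,
    boundary jitter. The geometry driving the SAT band relabeling is taken
    from the *truth* map, so the three operators compose deterministically.
    """
    rng = np.random.default_rng(spec.seed)
    scheme = truth.scheme
    labels = truth.labels.copy()

    # 1) Delete a fraction of muscle connected components to background.
    if spec.muscle_miss_fraction > 0:
        comps = measure.label(truth.labels == MUSCLE, connectivity=2)
        n_comp = int(comps.max())
        if n_comp:
            sizes = np.bincount(comps.ravel())[1:].astype(np.float64)
            k = int(round(spec.muscle_miss_fraction * n_comp))
            if spec.muscle_miss_fraction >= 1.0:
                k = n_comp
            # Weighted random order without replacement (weights ~ 1/size):
            # small patches are missed far more readily than the main wall.
            # A single order per seed makes deletion nested in the fraction.
            keys = rng.random(n_comp) ** (sizes / sizes.min())
            order = np.argsort(-keys, kind="stable") + 1  # largest key deleted first
            for comp_id in order[:k]:
                labels[comps == comp_id] = BG

    # 2) Relabel the innermost SAT strip as VAT. The "inside" is everything
    # the subcutaneous band wraps (muscle ring + visceral interior).
    if spec.sat_to_vat_band > 0:
        interior = ndimage.binary_fill_holes(
            (truth.labels == MUSCLE) | (truth.labels == VAT)
        )
        grown = ndimage.binary_dilation(
            interior, structure=morphology.footprint_rectangle((3, 3)),
            iterations=spec.sat_to_vat_band,
        )
        labels[(truth.labels == SAT) & grown] = VAT

    # 3) Seeded per-class boundary jitter.
    if spec.boundary_jitter > 0:
        classes = list(scheme.foreground)
        rng.shuffle(classes)
        for cls in classes:
            radius = int(rng.integers(1, spec.boundary_jitter + 1))
            footprint = morphology.disk(radius)
            mask = labels == cls
            if not mask.any():
                continue
            if rng.random() < 0.5:
                new_mask = ndimage.binary_dilation(mask, structure=footprint)
                labels[new_mask] = cls
            else:
                new_mask = ndimage.binary_erosion(mask, structure=footprint)
                removed = mask & ~new_mask
                labels = _fill_from_nearest(np.where(removed, -1, labels), removed)

    return SliceSample(
        image=truth.image,
        labels=labels,
        provenance="weak",
        sample_id=f"{truth.sample_id}-weak",
        scheme=scheme,
    )
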