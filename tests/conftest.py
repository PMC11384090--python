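"""Shared fixtures: small phantoms with known analytic ground truth."""

from __future__ import annotations

import numpy as np
import pytest

from vertemap import (FieldSpec, PhantomSpec, VertebraSpec,
                      extract_vertebra_roi, generate_phantom)


def make_roi(
    *,
    a=15.0, b=11.0, height=28.0, exponent=2.0, tilt=0.0,
    field=None, spacing=(1.2, 1.2, 3.0), noise=0.0, seed=0,
):
    """One-vertebra phantom cropped to its ROI; returns (roi, spec)."""
    vert = VertebraSpec(
        semi_axis_a_mm=a, semi_axis_b_mm=b, height_mm=height,
        superellipse_exponent=exponent, inclination_deg=tilt,
        field=field or FieldSpec(40.0),
    )
    spec = PhantomSpec(vertebrae=(vert,), spacing_mm=spacing,
                       noise_sd_percent=noise, rng_seed=seed)
    scalar, labels = generate_phantom(spec)
    return extract_vertebra_roi(scalar, labels, 1), spec


@pytest.fixture
def uniform_roi():
    """Untilted elliptical vertebra filled with exactly 40 % PDFF."""
    roi, _ = make_roi()
    return roi


def dice_aligned(mask_a, mask_b, com_a, com_b, search=1):
    """Dice of two masks in a common frame anchored at the centers of mass.

    A ±`search`-voxel shift search absorbs the rounding of the float com
    anchor, so the score measures interpolation loss, not frame alignment.
    """
    pad = 8
    shape = tuple(max(sa, sb) + 2 * pad
                  for sa, sb in zip(mask_a.shape, mask_b.shape))

    def embed(mask, com):
        out = np.zeros(shape, dtype=bool)
        center = np.array(shape) // 2
        off = center - np.round(com).astype(int)
        idx = np.nonzero(mask)
        out[tuple(i + o for i, o in zip(idx, off))] = True
        return out

    A = embed(mask_a, com_a)
    B0 = embed(mask_b, com_b)
    best = 0.0
    rng = range(-search, search + 1)
    for dz in rng:
        for dy in rng:
            for dx in rng:
                B = np.roll(B0, (dz, dy, dx), axis=(0, 1, 2))
                best = max(best, 2 * np.count_nonzero(A & B)
                           / (np.count_nonzero(A) + np.count_nonzero(B)))
    return best
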