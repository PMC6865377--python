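"""MP2RAGE uniform-image ("MP2") reconstruction.

The two inversion images are combined voxelwise as

    MP2 = INV1 * INV2 / (INV1**2 + INV2**2)

which is bounded in [-0.5, 0.5] and invariant to any common multiplicative
factor — a shared receive-field bias cancels exactly, which is why such
images are called self-bias-corrected. The denominator is floored by a small
epsilon: air/background voxels with negligible signal map to 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._util import as_volume

__all__ = ["Mp2Params", "reconstruct_mp2", "verify_bias_cancellation"]

#: fixed output interval of the combination formula
CLIP_RANGE = (-0.5, 0.5)


@dataclass(frozen=True)
class Mp2Params:
    background_epsilon: float = 1e-12  # intensity^2 floor for the denominator

    def __post_init__(self) -> None:
        if self.background_epsilon < 0:
            raise ValueError("background_epsilon must be >= 0")


def reconstruct_mp2(inv1, inv2, params: Mp2Params | None = None) -> np.ndarray:
    """Combine the two inversion images into the uniform MP2 image.

    Signed inputs are allowed; the output is clipped (numerically a no-op
    away from the epsilon floor) to [-0.5, 0.5] and is exactly 0 wherever
    INV1**2 + INV2**2 <= background_epsilon.
    """
    params = params or Mp2Params()
    a = np.asarray(inv1, dtype=float)
    b = np.asarray(inv2, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"INV1/INV2 grids differ: {a.shape} vs {b.shape}")
    denom = a * a + b * b
    background = denom <= params.background_epsilon
    out = np.where(background, 0.0, a * b / np.where(background, 1.0, denom))
    return np.clip(out, *CLIP_RANGE)


def verify_bias_cancellation(inv1, inv2, bias_field, params: Mp2Params | None = None,
                             mask=None) -> float:
    """Max |MP2(b*INV1, b*INV2) - MP2(INV1, INV2)| over the (optional) mask.

    For any strictly positive bias field the deviation is zero up to floating
    point, because the common factor b**2 cancels between numerator and
    denominator. Nonpositive bias values are rejected.
    """
    a = as_volume(inv1, "inv1") if np.ndim(inv1) == 3 else np.asarray(inv1, dtype=float)
    b = np.asarray(inv2, dtype=float)
    field = np.asarray(bias_field, dtype=float)
    if np.any(field <= 0):
        raise ValueError("bias field must be strictly positive")
    base = reconstruct_mp2(a, b, params)
    biased = reconstruct_mp2(field * a, field * b, params)
    dev = np.abs(biased - base)
    if mask is not None:
        dev = dev[np.asarray(mask, dtype=bool)]
    return float(dev.max())
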