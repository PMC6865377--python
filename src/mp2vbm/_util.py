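"""Small shared helpers."""

from __future__ import annotations

import numpy as np

_FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))  # 2.35482...


def round_half_away(x: float, ndigits: int = 1) -> float:
    """Round half away from zero (table-style rounding, not banker's)."""
    factor = 10.0**ndigits
    scaled = x * factor
    # nudge by a relative epsilon so values that are exact halves after a
    # clean decimal computation (e.g. 62.45) do not fall on the wrong side
    # of the representable-float boundary
    nudged = scaled + np.copysign(1e-9 * max(1.0, abs(scaled)), scaled)
    return float(np.copysign(np.floor(abs(nudged) + 0.5), scaled) / factor)


def as_volume(x, name: str = "volume") -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 3:
        raise ValueError(f"{name} must be a 3-D array, got shape {arr.shape}")
    return arr


def check_same_grid(a: np.ndarray, b: np.ndarray, what: str = "volumes") -> None:
    if a.shape != b.shape:
        raise ValueError(f"{what} must share one grid: {a.shape} vs {b.shape}")
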