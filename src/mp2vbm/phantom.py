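"""Seeded synthetic multispectral brain phantom.

Generates cohorts of healthy controls and focal-epilepsy-like patients on a
common grid: an ellipsoidal brain with an eight-lobe label atlas, soft-boundary
GM/WM/CSF probability maps, a thin dura/vessel confounder shell just outside
the brain, multispectral channel intensities (T1-like, the two MP2RAGE
inversion images INV1/INV2, FLAIR-like) with a smooth multiplicative bias
field shared between the two inversion images, additive Gaussian noise, and
focal gray-matter concentration lesions of configurable radius and amplitude
planted in a known lobe.

The phantom is deliberately geometric rather than anatomical: downstream
evaluation only needs a labeled partition of a brain-shaped mask, probability
fields that sum to one, a confounder that mimics dura (GM-like on T1/INV
channels, separable on FLAIR), and lesions with known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
from scipy import ndimage

__all__ = [
    "PhantomConfig",
    "MultiContrastVolume",
    "TissueProbabilityMaps",
    "LobarAtlas",
    "GroundTruth",
    "Subject",
    "LOBE_NAMES",
    "DEFAULT_CHANNEL_MEANS",
    "make_atlas",
    "make_tissue_maps",
    "synth_contrasts",
    "insert_lesion",
    "make_cohort",
]

#: lobe label -> name; left/right x frontal/parietal/temporal/occipital
LOBE_NAMES = {
    1: "left-frontal",
    2: "left-parietal",
    3: "left-temporal",
    4: "left-occipital",
    5: "right-frontal",
    6: "right-parietal",
    7: "right-temporal",
    8: "right-occipital",
}

#: mean intensity per (channel, compartment). INV1 is signed (short inversion
#: time: CSF not yet recovered), which is what gives the combined MP2 image
#: its tissue contrast. Dura is deliberately close to GM on T1/INV1/INV2 and
#: well separated on FLAIR.
DEFAULT_CHANNEL_MEANS: dict[str, dict[str, float]] = {
    "T1": {"csf": 25.0, "gm": 65.0, "wm": 95.0, "dura": 55.0},
    "INV1": {"csf": -30.0, "gm": 10.0, "wm": 60.0, "dura": -8.0},
    "INV2": {"csf": 70.0, "gm": 75.0, "wm": 80.0, "dura": 72.0},
    "FLAIR": {"csf": 15.0, "gm": 75.0, "wm": 55.0, "dura": 25.0},
}

# radial positions (fraction of the ellipsoid radius) of the ventricle/WM and
# WM/GM soft boundaries, and their logistic widths
_R_VENTRICLE = 0.42
_R_GM = 0.80
_W_VENTRICLE = 0.02
_W_GM = 0.03
_SEMI_AXIS_FRACTION = 0.44  # ellipsoid semi-axes as a fraction of grid extent


@dataclass(frozen=True)
class PhantomConfig:
    """Study conditions for one synthetic cohort.

    Defaults describe the reference phantom used throughout: a 48x56x48 grid
    at 2 mm isotropic (large enough for eight non-empty lobes and 16 mm
    smoothing, small enough for seconds-scale runs), 12 controls and 8
    patients carrying lobar-scale 14 mm malformations that add or remove up
    to 0.3 of GM probability (sized to remain detectable across the 4-16 mm
    smoothing range).
    """

    grid_shape: tuple[int, int, int] = (48, 56, 48)
    voxel_size: float = 2.0  # mm, isotropic
    n_controls: int = 12
    n_patients: int = 8
    lesion_radius: float = 14.0  # mm
    lesion_amplitude: float = 0.3  # GM-probability delta in (0, 1]
    lesion_sign: str = "both"  # {increase, decrease, both}
    noise_sd: float = 4.0  # intensity units, per channel
    bias_amplitude: float = 0.2  # multiplicative field in [1-a, 1+a]
    dura_thickness: int = 1  # voxels
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.grid_shape) != 3 or any(int(s) < 16 for s in self.grid_shape):
            raise ValueError("grid_shape must be 3 integers, each >= 16")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")
        if self.n_controls < 2:
            raise ValueError("need at least 2 controls (group statistics undefined)")
        if self.n_patients < 0:
            raise ValueError("n_patients must be >= 0")
        if not (0.0 < self.lesion_amplitude <= 1.0):
            raise ValueError("lesion_amplitude must be in (0, 1]")
        if self.lesion_radius <= 0:
            raise ValueError("lesion_radius must be positive")
        if self.lesion_sign not in ("increase", "decrease", "both"):
            raise ValueError("lesion_sign must be 'increase', 'decrease' or 'both'")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.bias_amplitude < 0:
            raise ValueError("bias_amplitude must be >= 0")
        if self.dura_thickness < 1:
            raise ValueError("dura_thickness must be >= 1 voxel")


@dataclass
class MultiContrastVolume:
    """Co-registered per-subject channel images on one grid."""

    channels: dict[str, np.ndarray]
    voxel_size: float
    bias_fields: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        shapes = {c: v.shape for c, v in self.channels.items()}
        if len(set(shapes.values())) > 1:
            raise ValueError(f"channel grids differ: {shapes}")

    @property
    def grid_shape(self) -> tuple[int, ...]:
        return next(iter(self.channels.values())).shape


@dataclass
class TissueProbabilityMaps:
    """GM/WM/CSF probability volumes in [0, 1]; in-mask sum is 1."""

    gm: np.ndarray
    wm: np.ndarray
    csf: np.ndarray
    mask: np.ndarray  # brain mask (bool)
    voxel_size: float

    def copy(self) -> "TissueProbabilityMaps":
        return TissueProbabilityMaps(
            self.gm.copy(), self.wm.copy(), self.csf.copy(), self.mask.copy(), self.voxel_size
        )

    def validate(self, atol: float = 1e-9) -> None:
        total = self.gm + self.wm + self.csf
        if not np.allclose(total[self.mask], 1.0, atol=atol):
            raise ValueError("in-mask tissue probabilities do not sum to 1")
        for name, vol in (("gm", self.gm), ("wm", self.wm), ("csf", self.csf)):
            if vol.min() < -atol or vol.max() > 1 + atol:
                raise ValueError(f"{name} probabilities outside [0, 1]")


@dataclass
class LobarAtlas:
    """Integer lobe labels (1..8) inside an ellipsoidal brain mask, 0 outside."""

    labels: np.ndarray  # int
    mask: np.ndarray  # bool, == labels > 0
    voxel_size: float
    center: np.ndarray  # voxel coordinates of the ellipsoid center
    semi_axes: np.ndarray  # voxel units

    @property
    def lobe_labels(self) -> tuple[int, ...]:
        return tuple(sorted(int(v) for v in np.unique(self.labels) if v != 0))


@dataclass
class GroundTruth:
    center: tuple[int, int, int]
    lobe: int
    mask: np.ndarray  # bool lesion mask (empty for controls)
    hypothesis_lobes: frozenset[int]
    sign: str = "increase"


@dataclass
class Subject:
    subject_id: str
    group: str  # "control" | "patient"
    tissues: TissueProbabilityMaps
    channels: MultiContrastVolume
    dura_mask: np.ndarray
    ground_truth: GroundTruth | None
    seed: int


def _radial_coordinate(shape, center, semi_axes) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    r2 = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, semi_axes))
    return np.sqrt(r2)


def _smooth_random_field(shape, rng: np.random.Generator, n_components: int = 6,
                         normalize: str = "rms") -> np.ndarray:
    """Sum of low-frequency 3-D cosines.

    With several components the voxelwise distribution across realizations is
    close to Gaussian. ``normalize='rms'`` scales to unit root-mean-square
    (amplitudes then mean RMS amplitudes); ``'peak'`` scales to unit maximum
    (used for bias fields, which are specified by their range).
    """
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    out = np.zeros(shape, dtype=float)
    for _ in range(n_components):
        freqs = rng.integers(1, 5, size=3)  # 1..4 cycles across the grid
        phases = rng.uniform(0, 2 * np.pi, size=3)
        amp = rng.uniform(0.5, 1.0)
        comp = amp * np.ones(shape)
        for g, s, f, p in zip(grids, shape, freqs, phases):
            comp = comp * np.cos(2 * np.pi * f * g / s + p)
        out += comp
    if normalize == "peak":
        scale = np.abs(out).max()
    else:
        scale = np.sqrt(np.mean(out**2))
    return out / scale if scale > 0 else out


def make_atlas(
    grid_shape: Iterable[int], voxel_size: float = 2.0, seed: int = 0
) -> LobarAtlas:
    """Build the ellipsoidal brain mask and its eight-lobe partition.

    One mid-sagittal plane splits hemispheres; one coronal and one axial plane
    through the centroid split each hemisphere into frontal, parietal,
    temporal and occipital quadrants. ``seed`` is accepted for interface
    symmetry with the other generators; the atlas geometry is deterministic.

    Raises ``ValueError`` if the grid cannot contain an ellipsoid with all
    eight lobes non-empty.
    """
    shape = tuple(int(s) for s in grid_shape)
    if len(shape) != 3 or any(s < 16 for s in shape):
        raise ValueError("grid_shape must be 3 integers, each >= 16 voxels")
    center = (np.asarray(shape, dtype=float) - 1.0) / 2.0
    semi_axes = _SEMI_AXIS_FRACTION * np.asarray(shape, dtype=float)
    r = _radial_coordinate(shape, center, semi_axes)
    mask = r <= 1.0
    if not mask.any():
        raise ValueError("grid too small: empty brain mask")

    ii, jj, kk = np.meshgrid(*(np.arange(s) for s in shape), indexing="ij")
    right = ii >= center[0]  # sagittal cut
    anterior = jj >= center[1]  # coronal cut
    superior = kk >= center[2]  # axial cut
    # region offsets: frontal 0, parietal 1, temporal 2, occipital 3
    region = np.where(
        anterior & superior, 0, np.where(~anterior & superior, 1, np.where(anterior, 2, 3))
    )
    labels = np.where(mask, 1 + region + 4 * right.astype(int), 0).astype(np.int16)

    counts = np.bincount(labels.ravel(), minlength=9)[1:9]
    if np.any(counts == 0):
        empty = [LOBE_NAMES[i + 1] for i in range(8) if counts[i] == 0]
        raise ValueError(f"grid too small: empty lobes {empty}")
    return LobarAtlas(labels=labels, mask=mask, voxel_size=float(voxel_size),
                      center=center, semi_axes=semi_axes)


def make_tissue_maps(
    atlas: LobarAtlas,
    dura_thickness: int = 1,
    seed: int = 0,
    boundary_jitter: float = 0.004,
    tissue_noise: float = 0.015,
) -> tuple[TissueProbabilityMaps, np.ndarray]:
    """Soft-boundary tissue probabilities plus a dura shell outside the brain.

    The brain is layered radially: a central ventricle of CSF, a WM core and
    an outer GM shell, with logistic transitions between compartments. The
    seeded jitter perturbs the internal boundaries per subject (a smooth
    near-Gaussian low-frequency field plus small global offsets), emulating
    the sub-voxel residual anatomical misalignment left after spatial
    normalization to a common space; the bulk of the cohort's map-level
    variance then comes from channel noise through segmentation, which is
    the regime in which voxelwise group statistics are well behaved. The
    dura shell is a ``dura_thickness``-voxel dilation ring immediately
    outside the brain mask and is excluded from the tissue maps.
    """
    if dura_thickness < 1:
        raise ValueError("dura_thickness must be >= 1 voxel")
    if dura_thickness >= atlas.semi_axes.min():
        raise ValueError("dura_thickness must be smaller than the brain radius")
    rng = np.random.default_rng(seed)
    shape = atlas.labels.shape
    r = _radial_coordinate(shape, atlas.center, atlas.semi_axes)
    r = r + boundary_jitter * _smooth_random_field(shape, rng)
    r_v = _R_VENTRICLE + rng.normal(0.0, boundary_jitter)
    r_g = _R_GM + rng.normal(0.0, boundary_jitter)

    def sigmoid(x):
        return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))

    csf = sigmoid((r_v - r) / _W_VENTRICLE)
    gm = (1.0 - csf) * sigmoid((r - r_g) / _W_GM)
    wm = 1.0 - csf - gm
    if tissue_noise > 0:
        # per-subject smooth density exchanges concentrated at each internal
        # interface (envelope 4*p*q peaks where two tissues mix): coherent,
        # near-Gaussian biological variability at every soft boundary, so
        # between-subject variance is honest wherever tissue composition can
        # differ and segmentation speckle never dominates group statistics
        ex_gw = tissue_noise * _smooth_random_field(shape, rng) * 4.0 * gm * wm
        gm = gm + ex_gw
        wm = wm - ex_gw
        ex_cw = tissue_noise * _smooth_random_field(shape, rng) * 4.0 * csf * wm
        csf = csf + ex_cw
        wm = wm - ex_cw
        # subarachnoid partial volume at the cortical surface: a baseline
        # ~0.1 of GM cedes to CSF toward the brain edge, with per-subject
        # smooth variation around it, clipped to keep all maps feasible
        rim = np.clip((r - 0.94) / 0.06, 0.0, 1.0)
        ex_rim = (0.1 + tissue_noise * _smooth_random_field(shape, rng)) * rim * gm
        ex_rim = np.clip(ex_rim, np.maximum(gm - 1.0, -csf),
                         np.minimum(gm, 1.0 - csf))
        gm = gm - ex_rim
        csf = csf + ex_rim
    for vol in (csf, gm, wm):
        vol[~atlas.mask] = 0.0
        np.clip(vol, 0.0, 1.0, out=vol)

    dura = ndimage.binary_dilation(atlas.mask, iterations=int(dura_thickness)) & ~atlas.mask
    tpm = TissueProbabilityMaps(gm=gm, wm=wm, csf=csf, mask=atlas.mask.copy(),
                                voxel_size=atlas.voxel_size)
    tpm.validate()
    return tpm, dura


def synth_contrasts(
    tissues: TissueProbabilityMaps,
    dura_mask: np.ndarray,
    channel_means: Mapping[str, Mapping[str, float]] | None = None,
    noise_sd: float = 4.0,
    bias_amplitude: float = 0.2,
    seed: int = 0,
    dura_sd: float = 1.0,
) -> MultiContrastVolume:
    """Synthesize T1/INV1/INV2/FLAIR channel images from tissue maps.

    Each channel is the tissue-probability-weighted mixture of per-tissue
    means (plus the dura mean on the dura shell), multiplied by a smooth
    random bias field scaled to [1-bias_amplitude, 1+bias_amplitude], plus
    additive Gaussian noise. INV1 and INV2 share one bias-field realization —
    the physical premise that lets their combined uniform image cancel the
    receive field — while T1 and FLAIR each get their own. Bias fields are
    exposed on ``MultiContrastVolume.bias_fields``.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if bias_amplitude < 0:
        raise ValueError("bias_amplitude must be >= 0")
    means = channel_means if channel_means is not None else DEFAULT_CHANNEL_MEANS
    for ch, tissue_means in means.items():
        missing = {"csf", "gm", "wm", "dura"} - set(tissue_means)
        if missing:
            raise ValueError(f"channel {ch!r} is missing means for {sorted(missing)}")

    rng = np.random.default_rng(seed)
    shape = tissues.gm.shape
    if dura_mask.shape != shape:
        raise ValueError("dura mask grid does not match tissue maps")

    def bias(amplitude):
        if amplitude == 0:
            return np.ones(shape)
        return 1.0 + amplitude * _smooth_random_field(shape, rng, n_components=3,
                                                      normalize="peak")

    # fixed draw order keeps the seeding contract stable
    bias_fields = {"T1": bias(bias_amplitude)}
    b_inv = bias(bias_amplitude)
    bias_fields["INV1"] = b_inv
    bias_fields["INV2"] = b_inv
    bias_fields["FLAIR"] = bias(bias_amplitude)

    # smooth per-subject variation of the dura signal (variable meningeal
    # thickness / partial volume): keeps the confounder shell from being
    # bit-identical across subjects
    dura_field = _smooth_random_field(shape, rng) if dura_sd > 0 else np.zeros(shape)

    channels: dict[str, np.ndarray] = {}
    for ch in ("T1", "INV1", "INV2", "FLAIR"):
        if ch not in means:
            continue
        m = means[ch]
        signal = m["csf"] * tissues.csf + m["gm"] * tissues.gm + m["wm"] * tissues.wm
        signal = np.where(dura_mask, m["dura"] + dura_sd * dura_field, signal)
        vol = signal * bias_fields[ch]
        if noise_sd > 0:
            vol = vol + rng.normal(0.0, noise_sd, size=shape)
        channels[ch] = vol
    return MultiContrastVolume(channels=channels, voxel_size=tissues.voxel_size,
                               bias_fields={c: bias_fields[c] for c in channels})


def _lesion_candidates(
    tissues: TissueProbabilityMaps, atlas: LobarAtlas, lobe: int, radius_mm: float
) -> np.ndarray:
    """In-lobe GM/WM interface voxels at least one radius from other lobes."""
    in_lobe = atlas.labels == lobe
    interface = in_lobe & (tissues.gm >= 0.3) & (tissues.wm >= 0.3)
    other_lobes = atlas.mask & ~in_lobe
    dist_mm = ndimage.distance_transform_edt(~other_lobes, sampling=atlas.voxel_size)
    return np.argwhere(interface & (dist_mm >= radius_mm))


def insert_lesion(
    tissues: TissueProbabilityMaps,
    atlas: LobarAtlas,
    lobe: int,
    radius: float = 14.0,
    amplitude: float = 0.3,
    sign: str = "increase",
    seed: int = 0,
) -> tuple[TissueProbabilityMaps, GroundTruth]:
    """Plant a spherical, cosine-tapered GM-concentration lesion in ``lobe``.

    The perturbation exchanges probability between GM and the other
    compartments (an increase draws proportionally on WM and CSF, a decrease
    cedes to them), bounded by what is locally available, so per-voxel sums
    stay 1 and all maps stay in [0, 1]. The center is drawn from in-lobe GM/WM
    interface voxels with at least one lesion radius of clearance from brain
    tissue of any other lobe; a lobe with no such voxel is rejected.
    """
    if lobe not in LOBE_NAMES or lobe not in atlas.lobe_labels:
        raise ValueError(f"unknown lobe label {lobe}")
    if radius <= 0:
        raise ValueError("radius must be positive")
    if not (0.0 <= amplitude <= 1.0):
        raise ValueError("amplitude must be in [0, 1]")
    if sign not in ("increase", "decrease"):
        raise ValueError("sign must be 'increase' or 'decrease'")

    rng = np.random.default_rng(seed)
    candidates = _lesion_candidates(tissues, atlas, lobe, radius)
    if len(candidates) == 0:
        raise ValueError(
            f"lobe {LOBE_NAMES[lobe]} has no GM/WM interface voxel with room "
            f"for a {radius} mm lesion"
        )
    center = tuple(int(v) for v in candidates[rng.integers(len(candidates))])

    shape = tissues.gm.shape
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    d_mm = np.sqrt(sum((g - c) ** 2 for g, c in zip(grids, center))) * tissues.voxel_size
    taper = np.where(d_mm <= radius, 0.5 * (1.0 + np.cos(np.pi * np.minimum(d_mm, radius) / radius)), 0.0)
    delta = amplitude * taper
    delta[~tissues.mask] = 0.0

    out = tissues.copy()
    if sign == "increase":
        # GM grows at the expense of whatever else is present, split
        # proportionally between WM and CSF
        donor = out.wm + out.csf
        transfer = np.minimum(delta, donor)
        with np.errstate(invalid="ignore", divide="ignore"):
            frac_wm = np.where(donor > 0, out.wm / np.where(donor > 0, donor, 1.0), 0.0)
        out.gm += transfer
        out.wm -= transfer * frac_wm
        out.csf -= transfer * (1.0 - frac_wm)
    else:
        transfer = np.minimum(delta, out.gm)
        recipient = out.wm + out.csf
        with np.errstate(invalid="ignore", divide="ignore"):
            frac_wm = np.where(recipient > 0, out.wm / np.where(recipient > 0, recipient, 1.0), 1.0)
        out.gm -= transfer
        out.wm += transfer * frac_wm
        out.csf += transfer * (1.0 - frac_wm)
    out.validate()

    lesion_mask = (d_mm <= radius) & tissues.mask
    gt = GroundTruth(center=center, lobe=int(lobe), mask=lesion_mask,
                     hypothesis_lobes=frozenset({int(lobe)}), sign=sign)
    return out, gt


def population_priors(
    atlas: LobarAtlas,
    dura_mask: np.ndarray,
    smooth_fwhm: float = 6.0,
    floor: float = 0.05,
) -> list[np.ndarray]:
    """Soft CSF/GM/WM spatial priors for segmentation in the common space.

    The analog of standard tissue probability maps: the unjittered template
    anatomy, smoothed and floored so no class is impossible anywhere.
    Dura-shell voxels get an uninformative CSF/GM-leaning prior — the prior
    must not decide the confounder's class, the channel likelihood should.
    Returns [csf, gm, wm] volumes normalized over the segmentation mask
    (brain plus dura shell).
    """
    from scipy.ndimage import gaussian_filter

    template, _ = make_tissue_maps(atlas, dura_thickness=1, seed=0, boundary_jitter=0.0)
    seg_mask = atlas.mask | dura_mask
    sigma = smooth_fwhm / (atlas.voxel_size * 2.0 * np.sqrt(2.0 * np.log(2.0)))
    priors = []
    for vol, dura_weight in ((template.csf, 0.4), (template.gm, 0.4), (template.wm, 0.2)):
        p = vol.copy()
        p[dura_mask] = dura_weight
        priors.append(gaussian_filter(p, sigma, mode="nearest") + floor)
    total = priors[0] + priors[1] + priors[2]
    out = []
    for p in priors:
        q = np.where(seg_mask, p / total, 0.0)
        out.append(q)
    return out


def _subject_seeds(config: PhantomConfig, n: int) -> np.ndarray:
    # stable non-negative 31-bit seeds derived from the cohort seed
    state = np.random.SeedSequence(config.seed).generate_state(n, dtype=np.uint32)
    return (state & np.uint32(0x7FFFFFFF)).astype(np.int64)


def make_cohort(config: PhantomConfig) -> tuple[list[Subject], LobarAtlas]:
    """Generate the full cohort: lesion-free controls then lesioned patients.

    Per-subject seeds (tissue jitter, lesion placement, noise/bias) are
    derived deterministically from ``config.seed``, so an identical config
    regenerates bit-identical volumes. Patient lesion lobes cycle through the
    eight atlas labels; with ``lesion_sign='both'`` the sign alternates
    increase/decrease across patients.
    """
    atlas = make_atlas(config.grid_shape, config.voxel_size, seed=config.seed)
    n_total = config.n_controls + config.n_patients
    seeds = _subject_seeds(config, 3 * n_total).reshape(n_total, 3)

    subjects: list[Subject] = []
    lobes = list(LOBE_NAMES)
    for i in range(config.n_controls):
        s_tissue, s_contrast, _ = (int(v) for v in seeds[i])
        tpm, dura = make_tissue_maps(atlas, config.dura_thickness, seed=s_tissue)
        mcv = synth_contrasts(tpm, dura, noise_sd=config.noise_sd,
                              bias_amplitude=config.bias_amplitude, seed=s_contrast)
        gt = GroundTruth(center=(0, 0, 0), lobe=0,
                         mask=np.zeros(atlas.labels.shape, dtype=bool),
                         hypothesis_lobes=frozenset(), sign="none")
        subjects.append(Subject(f"control_{i:02d}", "control", tpm, mcv, dura, gt, s_tissue))

    for j in range(config.n_patients):
        s_tissue, s_contrast, s_lesion = (int(v) for v in seeds[config.n_controls + j])
        tpm, dura = make_tissue_maps(atlas, config.dura_thickness, seed=s_tissue)
        lobe = lobes[j % len(lobes)]
        if config.lesion_sign == "both":
            sign = "increase" if j % 2 == 0 else "decrease"
        else:
            sign = config.lesion_sign
        tpm, gt = insert_lesion(tpm, atlas, lobe, radius=config.lesion_radius,
                                amplitude=config.lesion_amplitude, sign=sign, seed=s_lesion)
        mcv = synth_contrasts(tpm, dura, noise_sd=config.noise_sd,
                              bias_amplitude=config.bias_amplitude, seed=s_contrast)
        subjects.append(Subject(f"patient_{j:02d}", "patient", tpm, mcv, dura, gt, s_tissue))
    return subjects, atlas
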