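"""Clusters, the one-third overlap rules, and cohort performance rates.

Thresholded t-maps are reduced to connected supra-threshold components;
clusters with less than one third of their voxels inside the brain count as
no finding; a patient is concordant (discordant) when at least one surviving
cluster has at least one third of its voxels in the union of hypothesis
(non-hypothesis) lobes. Controls carry an empty hypothesis, so every lobe is
discordant for them and specificity is the share of controls with no
surviving finding at all. All one-third comparisons are inclusive (>=) and
computed on integer voxel counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage

from ._util import round_half_away
from .phantom import LobarAtlas
from .vbmcore import TMap

__all__ = [
    "Cluster",
    "FindingRecord",
    "extract_clusters",
    "apply_brain_rule",
    "classify_findings",
    "concordant_rate",
    "discordant_rate",
    "specificity",
    "corrected_specificity",
    "lobe_concordance_census",
    "concordant_discordant_ratio",
]

_CONNECTIVITY_RANK = {6: 1, 18: 2, 26: 3}


@dataclass
class Cluster:
    indices: np.ndarray  # (size, 3) voxel coordinates
    size: int
    peak_t: float
    direction: str
    in_brain_fraction: float | None = None
    lobe_fractions: dict[int, float] = field(default_factory=dict)
    out_of_atlas_fraction: float | None = None


@dataclass
class FindingRecord:
    subject_id: str
    concordant: bool
    discordant: bool
    any_finding: bool
    clusters: list[Cluster] = field(default_factory=list)


def extract_clusters(tmap, threshold: float, connectivity: int = 26,
                     direction: str | None = None) -> list[Cluster]:
    """Connected components of {t >= threshold} within the analysis mask.

    ``tmap`` may be a :class:`~mp2vbm.vbmcore.TMap` or a raw 3-D array (then
    all voxels are eligible and ``direction`` defaults to "increase").
    Connectivity is 6, 18 or 26 (default 26, the usual convention for
    cluster-level reporting in statistical parametric maps).
    """
    if connectivity not in _CONNECTIVITY_RANK:
        raise ValueError(f"connectivity must be one of {sorted(_CONNECTIVITY_RANK)}")
    if isinstance(tmap, TMap):
        t = tmap.t
        eligible = tmap.mask
        direction = direction or tmap.direction
    else:
        t = np.asarray(tmap, dtype=float)
        eligible = np.ones(t.shape, dtype=bool)
        direction = direction or "increase"
    structure = ndimage.generate_binary_structure(3, _CONNECTIVITY_RANK[connectivity])
    supra = (t >= threshold) & eligible
    labeled, n = ndimage.label(supra, structure=structure)
    clusters: list[Cluster] = []
    for obj_slice, lab in zip(ndimage.find_objects(labeled), range(1, n + 1)):
        local = labeled[obj_slice] == lab
        coords = np.argwhere(local) + [s.start for s in obj_slice]
        peak = float(t[obj_slice][local].max())
        clusters.append(Cluster(indices=coords, size=int(local.sum()), peak_t=peak,
                                direction=direction))
    return clusters


def apply_brain_rule(clusters: Sequence[Cluster], brain_mask) -> list[Cluster]:
    """Keep clusters with >= 1/3 of their voxels inside the brain mask."""
    brain = np.asarray(brain_mask, dtype=bool)
    kept = []
    for cl in clusters:
        inside = int(brain[tuple(cl.indices.T)].sum())
        cl.in_brain_fraction = inside / cl.size
        if 3 * inside >= cl.size:
            kept.append(cl)
    return kept


def _annotate_lobe_fractions(cluster: Cluster, atlas: LobarAtlas) -> None:
    labels_at = atlas.labels[tuple(cluster.indices.T)]
    counts = np.bincount(labels_at, minlength=9)
    cluster.lobe_fractions = {lab: counts[lab] / cluster.size for lab in atlas.lobe_labels}
    cluster.out_of_atlas_fraction = counts[0] / cluster.size


def classify_findings(clusters: Sequence[Cluster], atlas: LobarAtlas,
                      hypothesis_lobes: Iterable[int],
                      subject_id: str = "") -> FindingRecord:
    """Apply the one-third lobar overlap rules to surviving clusters.

    ``hypothesis_lobes`` may be empty (controls): no cluster can then be
    concordant and any cluster with >= 1/3 of voxels in the atlas is
    discordant. Overlap is computed against the union of hypothesis lobes and
    the union of the remaining lobes; a single cluster may satisfy both
    rules. Voxels outside the atlas (label 0) count toward neither.
    """
    hyp = frozenset(int(l) for l in hypothesis_lobes)
    unknown = hyp - set(atlas.lobe_labels)
    if unknown:
        raise ValueError(f"unknown lobe labels in hypothesis: {sorted(unknown)}")
    non_hyp = set(atlas.lobe_labels) - hyp
    concordant = discordant = False
    for cl in clusters:
        labels_at = atlas.labels[tuple(cl.indices.T)]
        n_hyp = int(np.isin(labels_at, list(hyp)).sum()) if hyp else 0
        n_non = int(np.isin(labels_at, list(non_hyp)).sum()) if non_hyp else 0
        _annotate_lobe_fractions(cl, atlas)
        if hyp and 3 * n_hyp >= cl.size:
            concordant = True
        if non_hyp and 3 * n_non >= cl.size:
            discordant = True
    return FindingRecord(subject_id=subject_id, concordant=concordant,
                         discordant=discordant, any_finding=len(clusters) > 0,
                         clusters=list(clusters))


def _rate(flag_count: int, total: int) -> float:
    return round_half_away(100.0 * flag_count / total, 1)


def concordant_rate(records: Sequence[FindingRecord]) -> float:
    """Percent of patients with a concordant finding, one decimal."""
    if not records:
        raise ValueError("no patient records")
    return _rate(sum(r.concordant for r in records), len(records))


def discordant_rate(records: Sequence[FindingRecord]) -> float:
    if not records:
        raise ValueError("no patient records")
    return _rate(sum(r.discordant for r in records), len(records))


def specificity(records: Sequence[FindingRecord]) -> float:
    """Percent of controls with no surviving VBM finding, one decimal."""
    if not records:
        raise ValueError("no control records")
    return _rate(sum(not r.any_finding for r in records), len(records))


def corrected_specificity(unclear_percent: float) -> float:
    """100 minus the unclear-findings percentage (post-visual-review bound)."""
    if not (0.0 <= unclear_percent <= 100.0):
        raise ValueError("unclear percentage must be in [0, 100]")
    return round_half_away(100.0 - unclear_percent, 1)


def concordant_discordant_ratio(n_concordant: int, n_discordant: int) -> float:
    if n_discordant <= 0:
        raise ValueError("discordant lobe count must be positive")
    return round_half_away(n_concordant / n_discordant, 2)


def lobe_concordance_census(hypotheses: Sequence[Iterable[int]],
                            atlas: LobarAtlas | None = None,
                            n_lobes: int = 8) -> tuple[int, int, float]:
    """Cumulative concordant and discordant lobe counts over a cohort.

    Each patient contributes their hypothesis lobes to the concordant count
    and the remaining lobes (out of ``n_lobes``) to the discordant count.
    Returns ``(n_concordant, n_discordant, ratio)`` with the ratio at two
    decimals.
    """
    valid = set(atlas.lobe_labels) if atlas is not None else set(range(1, n_lobes + 1))
    n_con = n_disc = 0
    for hyp in hypotheses:
        hyp = set(int(l) for l in hyp)
        unknown = hyp - valid
        if unknown:
            raise ValueError(f"hypothesis lobe(s) not in atlas: {sorted(unknown)}")
        n_con += len(hyp)
        n_disc += len(valid) - len(hyp)
    return n_con, n_disc, concordant_discordant_ratio(n_con, n_disc)
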