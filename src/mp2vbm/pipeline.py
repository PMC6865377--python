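"""End-to-end orchestration: phantom -> recon -> segment -> smooth -> t-maps
-> lobar findings -> operating-point sweep -> reports."""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import asdict, dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .lobar import (FindingRecord, apply_brain_rule, classify_findings,
                    concordant_rate, discordant_rate, extract_clusters, specificity)
from .phantom import LobarAtlas, PhantomConfig, Subject, make_cohort
from .recon import reconstruct_mp2
from .tune import (DEFAULT_THRESHOLD_GRID, OperatingChoice, RocCurve,
                   choose_operating_point, sweep_grid)
from .vbmcore import (DEFAULT_FWHM_GRID, SmoothingSpec, TMap, analysis_mask,
                      compute_tiv, individual_tmap, smooth_volume, tissue_volume)

__all__ = ["RunConfig", "PipelineResult", "CohortEvaluator", "MODEL_CHANNELS",
           "add_mp2_channel", "segment_cohort", "run_pipeline"]

#: the seven model presets: named channel sets used for segmentation
MODEL_CHANNELS: dict[str, tuple[str, ...]] = {
    "T1": ("T1",),
    "MP2": ("MP2",),
    "T1+FLAIR": ("T1", "FLAIR"),
    "MP2+INV1": ("MP2", "INV1"),
    "MP2+INV2": ("MP2", "INV2"),
    "MP2+FLAIR": ("MP2", "FLAIR"),
    "INV1+INV2": ("INV1", "INV2"),
}


@dataclass(frozen=True)
class RunConfig:
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    model: str = "MP2+INV1"
    fwhm_grid: tuple[float, ...] = DEFAULT_FWHM_GRID
    threshold_grid: tuple[float, ...] = DEFAULT_THRESHOLD_GRID
    connectivity: int = 26
    direction: str = "both"  # {increase, decrease, both}
    mask_threshold: float = 0.2
    seg_max_iter: int = 200
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if self.model not in MODEL_CHANNELS:
            raise ValueError(
                f"unknown model {self.model!r}; choose from {sorted(MODEL_CHANNELS)}"
            )
        if self.direction not in ("increase", "decrease", "both"):
            raise ValueError("direction must be 'increase', 'decrease' or 'both'")
        if not self.fwhm_grid or not self.threshold_grid:
            raise ValueError("fwhm and threshold grids must be nonempty")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        phantom_raw = raw.pop("phantom", {})
        if "grid_shape" in phantom_raw:
            phantom_raw["grid_shape"] = tuple(phantom_raw["grid_shape"])
        for key in ("fwhm_grid", "threshold_grid"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(phantom=PhantomConfig(**phantom_raw), **raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        return d


@dataclass
class PipelineResult:
    config: RunConfig
    performance: pd.DataFrame
    curves: list[RocCurve]
    operating_point: OperatingChoice
    findings: list[FindingRecord]
    volumes: pd.DataFrame
    manifest: dict


def add_mp2_channel(subjects: Sequence[Subject]) -> None:
    """Reconstruct the uniform MP2 image from INV1/INV2 for every subject."""
    for s in subjects:
        ch = s.channels.channels
        if "MP2" not in ch:
            ch["MP2"] = reconstruct_mp2(ch["INV1"], ch["INV2"])


def segment_cohort(subjects: Sequence[Subject], atlas: LobarAtlas, model: str,
                   max_iter: int = 200) -> dict[str, np.ndarray]:
    """Per-subject GM posterior maps for one channel-set model.

    Segmentation runs on the brain mask plus the dura shell, so the
    confounder competes for a tissue class exactly as meninges do in real
    segmentations, and uses the population template priors (the common-space
    analog of standard tissue probability maps), which pins class identity
    across subjects.
    """
    from .phantom import population_priors
    from .segment import MultispectralSegmenter

    channels = MODEL_CHANNELS[model]
    controls = [s for s in subjects if s.group == "control"]
    if not controls:
        raise ValueError("cohort has no controls to build the normative model")
    seg_mask = atlas.mask | controls[0].dura_mask
    priors = population_priors(atlas, controls[0].dura_mask)
    prior_mat = np.column_stack([p[seg_mask] for p in priors])

    def voxel_matrix(subject):
        return np.column_stack([subject.channels.channels[c][seg_mask]
                                for c in channels])

    # normative intensity model: one mixture fit on a control subsample so
    # that pathology cannot bias the class parameters it is judged against
    rng = np.random.default_rng(controls[0].seed)
    per_control = max(1, 60_000 // len(controls))
    xs, ps = [], []
    for s in controls:
        X = voxel_matrix(s)
        idx = rng.choice(X.shape[0], size=min(per_control, X.shape[0]), replace=False)
        xs.append(X[idx])
        ps.append(prior_mat[idx])
    seg = MultispectralSegmenter(max_iter=max_iter, random_state=int(controls[0].seed))
    seg.fit(np.concatenate(xs), priors=np.concatenate(ps))

    gm_maps: dict[str, np.ndarray] = {}
    gm_col = seg.class_names_.index("gm")
    for s in subjects:
        resp = seg.predict_proba(voxel_matrix(s), priors=prior_mat)
        gm = np.zeros(atlas.labels.shape)
        gm[seg_mask] = resp[:, gm_col]
        gm_maps[s.subject_id] = gm
    return gm_maps


class CohortEvaluator:
    """Findings engine over the (smoothing x threshold) grid.

    Caches per-smoothing t-maps (patients vs all controls; each control vs
    the rest, leave-one-out) so a grid sweep only pays the smoothing and
    statistics once per FWHM.
    """

    def __init__(self, gm_maps: Mapping[str, np.ndarray], groups: Mapping[str, str],
                 hypotheses: Mapping[str, frozenset], atlas: LobarAtlas,
                 connectivity: int = 26, direction: str = "both",
                 mask_threshold: float = 0.2):
        self.gm_maps = dict(gm_maps)
        self.groups = dict(groups)
        self.hypotheses = dict(hypotheses)
        self.atlas = atlas
        self.connectivity = connectivity
        self.direction = direction
        self.mask_threshold = mask_threshold
        self.controls = [sid for sid, g in self.groups.items() if g == "control"]
        self.patients = [sid for sid, g in self.groups.items() if g == "patient"]
        if len(self.controls) < 2:
            raise ValueError("need at least 2 controls")
        self._cached_fwhm: float | None = None
        self._tmaps: dict[str, TMap] = {}

    def _prepare(self, fwhm: float) -> None:
        if self._cached_fwhm == fwhm:
            return
        spec = SmoothingSpec(fwhm=fwhm, voxel_size=self.atlas.voxel_size)
        smoothed = {sid: smooth_volume(vol, spec) for sid, vol in self.gm_maps.items()}
        tmaps: dict[str, TMap] = {}
        all_controls = [smoothed[c] for c in self.controls]
        patient_mask = analysis_mask(all_controls, self.mask_threshold)
        for sid in self.patients:
            tmaps[sid] = individual_tmap(smoothed[sid], all_controls, patient_mask)
        for sid in self.controls:
            rest = [smoothed[c] for c in self.controls if c != sid]
            mask = analysis_mask(rest, self.mask_threshold)
            tmaps[sid] = individual_tmap(smoothed[sid], rest, mask)
        self._tmaps = tmaps
        self._cached_fwhm = fwhm

    def _subject_clusters(self, sid: str, threshold: float):
        tmap = self._tmaps[sid]
        clusters = []
        if self.direction in ("increase", "both"):
            clusters += extract_clusters(tmap, threshold, self.connectivity)
        if self.direction in ("decrease", "both"):
            neg = TMap(t=-tmap.t, df=tmap.df, mask=tmap.mask, direction="decrease")
            clusters += extract_clusters(neg, threshold, self.connectivity)
        return apply_brain_rule(clusters, self.atlas.mask)

    def findings(self, fwhm: float, threshold: float) -> list[FindingRecord]:
        self._prepare(fwhm)
        records = []
        for sid in self.patients + self.controls:
            clusters = self._subject_clusters(sid, threshold)
            hyp = self.hypotheses.get(sid, frozenset()) if self.groups[sid] == "patient" \
                else frozenset()
            records.append(classify_findings(clusters, self.atlas, hyp, subject_id=sid))
        return records

    def rates(self, fwhm: float, threshold: float) -> tuple[float, float, float]:
        records = self.findings(fwhm, threshold)
        by_id = {r.subject_id: r for r in records}
        patient_records = [by_id[s] for s in self.patients]
        control_records = [by_id[s] for s in self.controls]
        return (concordant_rate(patient_records), discordant_rate(patient_records),
                specificity(control_records))


def _volume_table(subjects: Sequence[Subject]) -> pd.DataFrame:
    rows = []
    for s in subjects:
        vs = s.tissues.voxel_size
        report = compute_tiv(tissue_volume(s.tissues.gm, vs),
                             tissue_volume(s.tissues.wm, vs),
                             tissue_volume(s.tissues.csf, vs))
        rows.append({"subject_id": s.subject_id, "group": s.group,
                     "gm_ml": report.gm_ml, "wm_ml": report.wm_ml,
                     "csf_ml": report.csf_ml, "tiv_ml": report.tiv_ml})
    return pd.DataFrame(rows)


def _manifest(config: RunConfig) -> dict:
    blob = json.dumps(config.to_dict(), sort_keys=True, default=str)
    return {
        "config": config.to_dict(),
        "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
        "mp2vbm_version": __version__,
        "numpy_version": np.__version__,
    }


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute the whole analysis on a generated phantom cohort.

    Deterministic given the config: rerunning an identical config reproduces
    identical tables. When ``config.out_dir`` is set, the performance table,
    per-smoothing ROC points and AUCs, the operating-point report, findings
    at the operating point, per-subject absolute volumes and a manifest are
    written there as CSV / text.
    """
    subjects, atlas = make_cohort(config.phantom)
    add_mp2_channel(subjects)
    gm_maps = segment_cohort(subjects, atlas, config.model, max_iter=config.seg_max_iter)
    groups = {s.subject_id: s.group for s in subjects}
    hypotheses = {s.subject_id: s.ground_truth.hypothesis_lobes for s in subjects
                  if s.ground_truth is not None}
    evaluator = CohortEvaluator(gm_maps, groups, hypotheses, atlas,
                                connectivity=config.connectivity,
                                direction=config.direction,
                                mask_threshold=config.mask_threshold)
    performance = sweep_grid(evaluator.rates, config.fwhm_grid, config.threshold_grid)
    choice, curves = choose_operating_point(performance)
    findings = evaluator.findings(choice.fwhm, choice.threshold)
    volumes = _volume_table(subjects)
    result = PipelineResult(config=config, performance=performance, curves=curves,
                            operating_point=choice, findings=findings,
                            volumes=volumes, manifest=_manifest(config))
    if config.out_dir:
        _write_reports(result, config.out_dir)
    return result


def _write_reports(result: PipelineResult, out_dir: str) -> None:
    os.makedirs(out_dir, exist_ok=True)
    result.performance.to_csv(os.path.join(out_dir, "performance.csv"), index=False)
    roc_rows = [{"fwhm": c.fwhm, "fpr": p[0], "c_r": p[1]}
                for c in result.curves for p in c.points]
    pd.DataFrame(roc_rows).to_csv(os.path.join(out_dir, "roc_points.csv"), index=False)
    pd.DataFrame([{"fwhm": c.fwhm, "auc": c.auc} for c in result.curves]) \
        .to_csv(os.path.join(out_dir, "auc_summary.csv"), index=False)
    op = result.operating_point
    pd.DataFrame([asdict(op)]).to_csv(os.path.join(out_dir, "operating_point.csv"),
                                      index=False)
    find_rows = [{
        "subject_id": r.subject_id, "n_clusters": len(r.clusters),
        "peak_t": max((c.peak_t for c in r.clusters), default=float("nan")),
        "concordant": r.concordant, "discordant": r.discordant,
        "any_finding": r.any_finding,
    } for r in result.findings]
    pd.DataFrame(find_rows).to_csv(os.path.join(out_dir, "findings.csv"), index=False)
    result.volumes.to_csv(os.path.join(out_dir, "volumes.csv"), index=False)
    with open(os.path.join(out_dir, "manifest.txt"), "w") as fh:
        for key, value in result.manifest.items():
            fh.write(f"{key}: {value}\n")
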