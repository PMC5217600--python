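"""End-to-end orchestration: simulate a two-group stroke-imaging study, then
analyze it (contrast → alignment → flow → perfusion areas → volumetry → NSS →
group statistics) into a machine-readable report.

The simulation defaults emulate the study conditions of a conscious-vs-
anesthetized photothrombotic experiment: 11 rats per group, a hypoperfused
territory growing to a group-specific target area by 15 min of illumination
(19.5 mm² conscious, 12.4 mm² anesthetized), CBF recorded up to 25 min
post-onset, T2-like lesion stacks (1-mm slices) and TTC-like stacks (3-mm
slices) with group-specific planted volumes, and 0–18 NSS cohorts scored by
3 examiners over 3 trials.  Per-animal spread is set from the reported SEMs
(sd = SEM·√11).  Image geometry defaults are scaled down from 640² to 128² so
a full synthetic study runs in minutes; pitch scales inversely so areas stay
in mm².
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as sfio
from .contrast import spatial_contrast
from .flow import contrast_to_flow
from .perfusion import (
    AreaSeries,
    area_time_series,
    normalize_to_baseline,
    occlusion_success,
)
from .registration import align_stack
from .stats import (
    compare_groups,
    group_summary,
    nss_total,
    percent_difference,
    timepoint_comparison,
)
from .synthetic import (
    ScenarioConfig,
    _disc_mask,
    inject_motion,
    make_lesion_volume,
    make_nss_cohort,
    render_sequence,
)
from .lesion import infarct_volume, lesion_volume

logger = logging.getLogger("speckleflow")

__all__ = ["GroupSpec", "RunConfig", "run_simulation", "run_analysis"]


@dataclass
class GroupSpec:
    """Planted ground truth for one experimental group."""

    n_rats: int = 11
    cbf50_mean_mm2: float = 19.5
    cbf50_sd_mm2: float = 1.4 * np.sqrt(11)
    lesion_mean_mm3: float = 63.7
    lesion_sd_mm3: float = 11.2 * np.sqrt(11)
    infarct_mean_mm3: float = 47.0
    infarct_sd_mm3: float = 15.0 * np.sqrt(11)
    nss_mean: float = 5.9
    nss_sd: float = 1.0 * np.sqrt(11)


def _default_groups() -> dict:
    return {
        "conscious": GroupSpec(),
        "anesthetic": GroupSpec(
            cbf50_mean_mm2=12.4,
            cbf50_sd_mm2=1.5 * np.sqrt(11),
            lesion_mean_mm3=40.1,
            lesion_sd_mm3=6.2 * np.sqrt(11),
            infarct_mean_mm3=32.0,
            infarct_sd_mm3=12.0 * np.sqrt(11),
            nss_mean=4.6,
            nss_sd=1.0 * np.sqrt(11),
        ),
    }


@dataclass
class RunConfig:
    """All knobs of a simulated study and its analysis."""

    seed: int = 0
    groups: dict = field(default_factory=_default_groups)
    # imaging geometry (scaled down from the 640-px acquisition by default)
    image_px: int = 128
    pixel_pitch_mm: float = 0.08
    exposure_s: float = 5e-3
    frame_rate_hz: float = 50.0
    beta: float = 1.0
    n_substeps: int = 64
    baseline_tau_s: float = 1e-3
    occlusion_flow_fraction: float = 0.3
    # static reflectance structure; required (>0) when simulating motion
    anatomy_contrast: float = 0.0
    anatomy_corr_px: float = 4.0
    # acquisition plan: analysis bins (minutes post illumination onset),
    # recording capped at 25 min post occlusion
    bin_times_min: list = field(default_factory=lambda: [1.0, 5.0, 8.0, 12.0, 15.0, 20.0, 25.0])
    frames_per_bin: int = 8
    motion_jitter_px: float = 0.0
    # analysis
    window_px: int = 7
    enhancement_threshold: float = 1.2
    occlusion_criterion: float = 0.85
    align: bool = False
    alpha: float = 0.05
    equal_var: bool = False
    bonferroni: bool = False
    # lesion phantoms
    mri_slices: int = 20
    mri_thickness_mm: float = 1.0
    ttc_slices: int = 6
    ttc_thickness_mm: float = 3.0
    lesion_pitch_mm: float = 0.1
    lesion_slice_px: int = 128

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        groups = raw.pop("groups", None)
        cfg = cls(**raw)
        if groups:
            cfg.groups = {name: GroupSpec(**spec) for name, spec in groups.items()}
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["groups"] = {k: dataclasses.asdict(v) for k, v in self.groups.items()}
        return d

    def scenario(self, target_area_mm2: float, seed: int) -> ScenarioConfig:
        return ScenarioConfig(
            target_area_15min_mm2=target_area_mm2,
            baseline_tau_s=self.baseline_tau_s,
            occlusion_flow_fraction=self.occlusion_flow_fraction,
            image_shape=(self.image_px, self.image_px),
            pixel_pitch_mm=self.pixel_pitch_mm,
            exposure_s=self.exposure_s,
            frame_rate_hz=self.frame_rate_hz,
            beta=self.beta,
            n_substeps=self.n_substeps,
            anatomy_contrast=self.anatomy_contrast,
            anatomy_corr_px=self.anatomy_corr_px,
            seed=seed,
        )


def _bin_duration_min(cfg: RunConfig) -> float:
    return cfg.frames_per_bin / cfg.frame_rate_hz / 60.0


def run_simulation(cfg: RunConfig, out_dir: str | Path) -> Path:
    """Write a complete synthetic dataset: per-rat speckle stacks per analysis
    bin, lesion volumes, TTC stacks, NSS tables, and ground-truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, g in cfg.groups.items():
        if g.n_rats < 1:
            raise ValueError(f"group {name!r} needs at least one rat")
    if cfg.motion_jitter_px > 0 and cfg.anatomy_contrast <= 0:
        raise ValueError(
            "motion simulation requires anatomy_contrast > 0: registration needs "
            "persistent structure to lock onto"
        )
    root_ss = np.random.SeedSequence(cfg.seed)
    meta = {
        "config": cfg.to_dict(),
        "bin_times_min": list(cfg.bin_times_min),
        "groups": {},
    }
    dur = _bin_duration_min(cfg)
    for gi, (name, g) in enumerate(sorted(cfg.groups.items())):
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1000 + gi]))
        nss_records = make_nss_cohort(
            g.nss_mean, g.nss_sd, g.n_rats, seed=int(rng.integers(2**31)), id_prefix=f"{name}_rat"
        )
        rat_ids = []
        for r in range(g.n_rats):
            rat_id = f"{name}_rat{r:02d}"
            rat_ids.append(rat_id)
            rat_dir = out / name / rat_id
            rat_dir.mkdir(parents=True, exist_ok=True)
            target = float(np.clip(rng.normal(g.cbf50_mean_mm2, g.cbf50_sd_mm2), 1.0, None))
            scen = cfg.scenario(target, seed=int(rng.integers(2**31)))
            stacks = {"baseline": render_sequence(scen, -dur, 0.0)}
            for t in cfg.bin_times_min:
                stacks[f"bin_{t:g}"] = render_sequence(scen, t, t + dur)
            if cfg.motion_jitter_px > 0:
                for key, st in stacks.items():
                    sched = rng.normal(0.0, cfg.motion_jitter_px, size=(len(st), 2))
                    sched[0] = 0.0
                    stacks[key] = inject_motion(st, sched)
            for key, st in stacks.items():
                sfio.write_stack(st, rat_dir / f"{key}.tif")
            lesion_true = float(np.clip(rng.normal(g.lesion_mean_mm3, g.lesion_sd_mm3), 2.0, None))
            infarct_true = float(np.clip(rng.normal(g.infarct_mean_mm3, g.infarct_sd_mm3), 2.0, None))
            mri = make_lesion_volume(
                lesion_true,
                cfg.mri_slices,
                cfg.mri_thickness_mm,
                cfg.lesion_pitch_mm,
                seed=int(rng.integers(2**31)),
                slice_shape=(cfg.lesion_slice_px, cfg.lesion_slice_px),
            )
            ttc = make_lesion_volume(
                infarct_true,
                cfg.ttc_slices,
                cfg.ttc_thickness_mm,
                cfg.lesion_pitch_mm,
                seed=int(rng.integers(2**31)),
                slice_shape=(cfg.lesion_slice_px, cfg.lesion_slice_px),
                modality="TTC-like",
            )
            sfio.write_volume_nifti(mri, rat_dir / "mri.nii")
            sfio.write_volume_tiff(ttc, rat_dir / "ttc.tif")
            sfio.write_nss_csv([rec for rec in nss_records if rec.rat_id == rat_id], rat_dir / "nss.csv")
            truth = {
                "cbf50_target_mm2": target,
                "lesion_volume_mm3": mri.true_volume_mm3,
                "infarct_volume_mm3": ttc.true_volume_mm3,
                "occlusion_center_px": list(scen.occlusion_center_px),
            }
            (rat_dir / "truth.json").write_text(json.dumps(truth))
        meta["groups"][name] = {"rat_ids": rat_ids, "spec": dataclasses.asdict(g)}
    (out / "meta.json").write_text(json.dumps(meta, indent=1, sort_keys=True))
    return out


def _analyze_rat(cfg: RunConfig, rat_dir: Path, meta: dict) -> dict:
    bin_times = meta["bin_times_min"]
    baseline_stack = sfio.read_stack(rat_dir / "baseline.tif")
    reference = baseline_stack.frames.mean(axis=0) if cfg.align else None

    def to_flow(stack, t):
        if cfg.align:
            stack, _ = align_stack(stack, reference=reference)
        cmap = spatial_contrast(stack, window=cfg.window_px, bin_time_min=t)
        return contrast_to_flow(cmap, T=stack.exposure_s, beta=cfg.beta)

    baseline_flow = to_flow(baseline_stack, 0.0)
    flow_maps = []
    for t in bin_times:
        flow_maps.append(to_flow(sfio.read_stack(rat_dir / f"bin_{t:g}.tif"), t))

    h = w = cfg.image_px
    hemisphere = np.zeros((h, w), dtype=bool)
    hemisphere[:, : w // 2] = True
    cbf50, cbfplus = area_time_series(
        flow_maps, baseline_flow, hemisphere, enhancement_threshold=cfg.enhancement_threshold
    )

    truth = json.loads((rat_dir / "truth.json").read_text())
    cy, cx = truth["occlusion_center_px"]
    roi = _disc_mask((h, w), (cy, cx), max(h / 32.0, 3.0))
    endpoint_idx = int(np.argmin(np.abs(np.asarray(bin_times) - 15.0)))
    nmap_end = normalize_to_baseline(flow_maps[endpoint_idx], baseline_flow)
    occluded = occlusion_success(nmap_end, roi, cfg.occlusion_criterion)

    mri = sfio.read_volume_nifti(rat_dir / "mri.nii")
    ttc = sfio.read_volume_tiff(rat_dir / "ttc.tif")
    nss = nss_total(sfio.read_nss_csv(rat_dir / "nss.csv"))
    return {
        "rat_id": rat_dir.name,
        "occlusion_success": bool(occluded),
        "cbf50_mm2": cbf50.areas_mm2.tolist(),
        "cbfplus_mm2": cbfplus.areas_mm2.tolist(),
        "cbf50_at_15min_mm2": cbf50.primary_endpoint_mm2,
        "lesion_volume_mm3": lesion_volume(mri).total_volume_mm3,
        "infarct_volume_mm3": infarct_volume(ttc).total_volume_mm3,
        "nss": nss,
        "_series": (cbf50, cbfplus),
    }


def run_analysis(cfg: RunConfig, dataset_dir: str | Path) -> dict:
    """Analyze a simulated (or equivalently formatted) dataset into the group
    report: per-rat endpoints, group means ± SEM, per-timepoint t-tests and the
    three headline percent differences.  Rats failing the occlusion-success
    criterion are excluded with a logged reason.  The analysis path is fully
    deterministic given the dataset."""
    dataset = Path(dataset_dir)
    meta_path = dataset / "meta.json"
    if not meta_path.exists():
        raise FileNotFoundError(f"dataset incomplete: {meta_path} missing")
    meta = json.loads(meta_path.read_text())
    report: dict = {
        "parameters": {
            "window_px": cfg.window_px,
            "exposure_s": cfg.exposure_s,
            "beta": cfg.beta,
            "reduction_threshold": 0.5,
            "enhancement_threshold": cfg.enhancement_threshold,
            "occlusion_criterion": cfg.occlusion_criterion,
            "alpha": cfg.alpha,
            "equal_var": cfg.equal_var,
            "bonferroni": cfg.bonferroni,
            "align": cfg.align,
        },
        "groups": {},
        "excluded": [],
    }
    series_by_group: dict[str, list[AreaSeries]] = {}
    metrics_by_group: dict[str, dict[str, list[float]]] = {}
    for name, ginfo in sorted(meta["groups"].items()):
        rats = []
        series_by_group[name] = []
        metrics = {"cbf50_at_15min_mm2": [], "lesion_volume_mm3": [], "infarct_volume_mm3": [], "nss": []}
        for rat_id in ginfo["rat_ids"]:
            res = _analyze_rat(cfg, dataset / name / rat_id, meta)
            cbf50, _ = res.pop("_series")
            if not res["occlusion_success"]:
                logger.warning("excluding %s: occlusion-success criterion not met", rat_id)
                report["excluded"].append({"rat_id": rat_id, "reason": "occlusion not successful"})
                continue
            rats.append(res)
            series_by_group[name].append(cbf50)
            for key in metrics:
                metrics[key].append(res[key])
        if not rats:
            raise ValueError(f"group {name!r} has no analyzable rats")
        gsum = {}
        for key, vals in metrics.items():
            if len(vals) >= 2:
                m, sem = group_summary(vals)
                gsum[key] = {"mean": m, "sem": sem, "n": len(vals)}
        report["groups"][name] = {"rats": rats, "summary": gsum}
        metrics_by_group[name] = metrics

    names = sorted(meta["groups"])
    if len(names) == 2:
        a, b = "conscious", "anesthetic"
        if a not in names or b not in names:
            a, b = names
        comp = {}
        for key, label in [
            ("lesion_volume_mm3", "mri_lesion"),
            ("nss", "nss"),
            ("infarct_volume_mm3", "ttc_infarct"),
            ("cbf50_at_15min_mm2", "cbf50_15min"),
        ]:
            va, vb = metrics_by_group[a][key], metrics_by_group[b][key]
            if len(va) >= 2 and len(vb) >= 2:
                gc = compare_groups(va, vb, equal_var=cfg.equal_var, alpha=cfg.alpha)
                comp[label] = dataclasses.asdict(gc)
        times, pvals = timepoint_comparison(
            series_by_group[a], series_by_group[b], equal_var=cfg.equal_var, bonferroni=cfg.bonferroni
        )
        report["comparison"] = {
            "group_a": a,
            "group_b": b,
            "metrics": comp,
            "cbf50_timepoints_min": times.tolist(),
            "cbf50_p_values": pvals.tolist(),
            "percent_differences": {
                lbl: comp[lbl]["percent_diff"] for lbl in ("mri_lesion", "nss", "ttc_infarct") if lbl in comp
            },
        }
    return report


def write_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=1, sort_keys=True))
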