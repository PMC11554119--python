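"""End-to-end pipeline runner on fully synthetic subjects.

``run_pipeline`` simulates N subjects (design, features, main-task and
localizer BOLD, behavior), runs the full analysis chain (GLM with parametric
modulators, single-trial estimation, localizer searchlight decoding for ROI
voxel selection, surprise-scaling regression, behavioral statistics) and
writes a manifest recording the configuration, seeds and content hashes of
every output, so any result can be regenerated bit-identically.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as pio
from .behavior import condition_split, filter_trials, posthoc, rm_anova
from .decode import accuracy_map
from .design import build_tpm, generate_run, generate_localizer, run_duration
from .features import correlation_rdm, trial_surprise
from .glm import build_design, fit_glm, vif
from .lss import lss
from .rsa import make_searchlights
from .scaling import build_rois, scaling_regression
from .stimuli import default_stimulus_set
from .synth import (default_ground_truth, synth_behavior, synth_bold,
                    synth_feature_hierarchy, synth_localizer_bold)

REQUIRED_SEEDS = ("design", "features", "bold", "behavior", "analysis")


@dataclass
class PipelineConfig:
    """All knobs of the synthetic end-to-end run, with explicit seeds."""

    out_dir: str = "pescale_out"
    n_subjects: int = 2
    n_runs: int = 1
    grid: tuple[int, int, int] = (12, 10, 8)
    tr: float = 1.0
    voxel_mm: float = 2.0
    smoothing_fwhm_mm: float = 5.0
    highpass_cutoff_s: float = 128.0
    searchlight_radius_mm: float = 6.0
    roi_rule: str = "top_k_decoding"
    roi_k: int = 100
    models: tuple[str, ...] = ("layer2", "layer8")
    noise_sd: float = 1.0
    planted_high_slope: float = 1.0
    formation_z: float = 3.29
    rsa_display_z: float = 3.1
    liberal_z: float = 1.96
    n_permutations: int = 200
    seeds: dict = field(default_factory=lambda: {
        "design": 11, "features": 23, "bold": 37, "behavior": 53, "analysis": 71,
    })

    def validate(self) -> None:
        missing = [s for s in REQUIRED_SEEDS if s not in self.seeds]
        if missing:
            raise ValueError(f"missing seed(s): {missing}")
        for name in ("formation_z", "rsa_display_z", "liberal_z"):
            if getattr(self, name) <= 0:
                raise ValueError(f"threshold {name} must be positive")
        if self.n_subjects < 1 or self.n_runs < 1:
            raise ValueError("need at least one subject and one run")


def _stage_seed(config: PipelineConfig, stage: str, *key: int) -> int:
    base = int(config.seeds[stage])
    ss = np.random.SeedSequence([base, *key])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_subject(config: PipelineConfig, subject: int, out: Path) -> dict:
    """Simulate and analyze a single synthetic subject; returns summaries."""
    stimuli = default_stimulus_set(rng_seed=_stage_seed(config, "design", subject, 0))
    tpm = build_tpm(stimuli)
    truth = default_ground_truth(grid=config.grid,
                                 high_slope=config.planted_high_slope,
                                 rng_seed=_stage_seed(config, "bold", subject, 99))

    layers = synth_feature_hierarchy(
        n_stimuli=8, stimulus_ids=stimuli.stimulus_ids,
        rng_seed=_stage_seed(config, "features", subject))
    rdms = {fs.layer_id: correlation_rdm(fs) for fs in layers}
    model_rdms = {m: rdms[m] for m in config.models}

    run_records = []
    behavior_tables = []
    all_stacks, all_surprise = [], []

    for run_idx in range(config.n_runs):
        events = generate_run(tpm, rng_seed=_stage_seed(config, "design",
                                                        subject, run_idx + 1))
        surprise = {m: trial_surprise(r, events, stimuli, model_id=m)
                    for m, r in model_rdms.items()}
        bold = synth_bold(events, surprise, truth, noise_sd=config.noise_sd,
                          tr=config.tr,
                          rng_seed=_stage_seed(config, "bold", subject, run_idx))
        n_scans = bold.n_scans
        design = build_design(events, list(surprise.values()), n_scans,
                              tr=config.tr)
        fit = fit_glm(bold.timeseries(), design)
        run_vif = vif(design)
        stack = lss(bold, events)
        unexpected = stack.restrict("unexpected")
        stack.trials["run"] = run_idx
        all_stacks.append(unexpected)
        all_surprise.append({m: surprise[m].z for m in config.models})
        run_records.append({"run": run_idx, "max_vif": float(run_vif.max()),
                            "n_scans": n_scans,
                            "n_trials": len(events)})
        behavior_tables.append(
            synth_behavior(events, stimuli,
                           rng_seed=_stage_seed(config, "behavior",
                                                subject, run_idx))
            .assign(run=run_idx))

    # localizer: searchlight decoding informs ROI voxel selection
    loc_events = generate_localizer(
        stimuli, rng_seed=_stage_seed(config, "design", subject, 900))
    loc_bold = synth_localizer_bold(
        loc_events, truth, noise_sd=config.noise_sd, tr=config.tr,
        rng_seed=_stage_seed(config, "bold", subject, 900))
    loc_stack = lss(loc_bold, loc_events[loc_events["condition"] == "intact"])
    mask = np.ones(config.grid, dtype=bool)
    searchlights = make_searchlights(mask, config.searchlight_radius_mm,
                                     config.voxel_mm)
    acc = accuracy_map(loc_stack, searchlights, config.grid,
                       random_state=_stage_seed(config, "analysis", subject))
    acc = np.nan_to_num(acc, nan=0.0)

    # one ROI per planted voxel population (early/late visual stand-ins),
    # informative voxels selected from localizer decoding only
    anatomical = {
        pop: (truth.population == pop).reshape(config.grid)
        for pop in ("high_scaling", "low_scaling", "null")
    }
    rois = build_rois(anatomical, acc, rule=config.roi_rule,
                      k=config.roi_k, dilation_fwhm_mm=0.0,
                      voxel_mm=config.voxel_mm)

    roi_slopes = {roi.name: {} for roi in rois}
    for roi in rois:
        for m in config.models:
            res_m = scaling_regression(
                all_stacks, [s[m] for s in all_surprise],
                roi_voxels=roi.selected, scope="roi")
            # mean over this subject's runs
            roi_slopes[roi.name][m] = float(np.mean(res_m["slopes"]))

    behavior = pd.concat(behavior_tables, ignore_index=True)
    behavior["subject"] = subject

    subj_dir = out / f"sub-{subject:02d}"
    subj_dir.mkdir(parents=True, exist_ok=True)
    files = {
        "events": pio.write_events(events, subj_dir / "task_events.tsv"),
        "localizer_events": pio.write_events(loc_events,
                                             subj_dir / "localizer_events.tsv"),
        "behavior": pio.write_events(behavior, subj_dir / "behavior.tsv"),
        "rdm_layer8": pio.write_rdm(model_rdms[config.models[-1]],
                                    subj_dir / "rdm_high.tsv"),
    }
    return {"subject": subject, "roi_slopes": roi_slopes,
            "runs": run_records, "behavior": behavior,
            "files": {k: str(v) for k, v in files.items()}}


def run_pipeline(config: PipelineConfig) -> dict:
    """Simulate and analyze ``config.n_subjects`` subjects, write a manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    subjects = [run_subject(config, s, out) for s in range(config.n_subjects)]

    group: dict = {"roi_scaling": {}}
    roi_names = list(subjects[0]["roi_slopes"])
    for roi_name in roi_names:
        group["roi_scaling"][roi_name] = {}
        for m in config.models:
            slopes = np.array([s["roi_slopes"][roi_name][m] for s in subjects])
            entry = {"mean_slope": float(slopes.mean()), "n": len(slopes)}
            if len(slopes) >= 3 and slopes.std(ddof=1) > 0:
                from scipy import stats as sstats
                res = sstats.ttest_1samp(slopes, 0.0)
                entry.update(t=float(res.statistic), p=float(res.pvalue))
            group["roi_scaling"][roi_name][m] = entry

    behavior = pd.concat([s["behavior"] for s in subjects], ignore_index=True)
    filtered, report = filter_trials(behavior)
    summary = condition_split(filtered)
    group["behavior_filter"] = report
    if behavior["subject"].nunique() >= 3:
        group["behavior_anova"] = rm_anova(summary)
        group["behavior_posthoc"] = posthoc(summary).to_dict("records")

    config_path = pio.write_config(
        {**{k: v for k, v in asdict(config).items() if k != "grid"},
         "grid": list(config.grid), "models": list(config.models)},
        out / "config.yaml")
    result_path = pio.write_json(group, out / "group_results.json")

    manifest = {
        "config": str(config_path),
        "seeds": config.seeds,
        "files": {},
    }
    for s in subjects:
        for name, path in s["files"].items():
            manifest["files"][f"sub-{s['subject']:02d}/{name}"] = _sha256(Path(path))
    manifest["files"]["group_results.json"] = _sha256(result_path)
    manifest_path = pio.write_json(manifest, out / "manifest.json")
    return {"group": group, "subjects": subjects,
            "manifest": json.loads(Path(manifest_path).read_text())}
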