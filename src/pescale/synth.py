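"""Synthetic data with planted ground truth.

Everything the pipeline consumes can be generated here: a layered feature
hierarchy whose RDMs are partially correlated across layers (mimicking the
layers of a visual network), 4-D BOLD runs whose unexpected-trial responses
scale linearly with a chosen model's surprise in designated voxel
populations, localizer runs with stimulus-selective patterns, word-embedding
stand-ins, and behavioral response tables.  Ground truth (baselines, slopes,
population labels, stimulus patterns) is recorded alongside each run so that
every downstream estimate can be checked by parameter recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import glm
from .design import run_duration
from .features import FeatureSpace, SurpriseVector
from .stimuli import StimulusSet

DEFAULT_GRID = (20, 20, 10)
DEFAULT_TR = 1.0
DEFAULT_VOXEL_MM = 2.0

POPULATIONS = ("high_scaling", "low_scaling", "null", "non_selective")


@dataclass
class GroundTruth:
    """Planted per-voxel generative parameters for a synthetic brain."""

    grid: tuple[int, int, int]
    baseline: np.ndarray                    # voxels (flat)
    slopes: dict[str, np.ndarray]           # model -> per-voxel slope
    population: np.ndarray                  # voxels, labels from POPULATIONS
    stimulus_patterns: np.ndarray | None = None   # stimuli x voxels
    scrambled_gain: float = 0.4             # scrambled vs intact amplitude

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.grid))

    def voxels_in(self, label: str) -> np.ndarray:
        return np.where(self.population == label)[0]


@dataclass
class BoldRun:
    """A 4-D BOLD run with its repetition time, mask and provenance."""

    data: np.ndarray                 # x, y, z, time
    tr: float
    mask: np.ndarray                 # x, y, z boolean
    voxel_mm: float = DEFAULT_VOXEL_MM
    truth: GroundTruth | None = None

    def __post_init__(self) -> None:
        if self.data.ndim != 4:
            raise ValueError("BOLD data must be 4-D (x, y, z, time)")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("BOLD data must be finite")

    @property
    def n_scans(self) -> int:
        return self.data.shape[3]

    def timeseries(self) -> np.ndarray:
        """(time x voxels) view over the full grid (flattened C-order)."""
        nx, ny, nz, nt = self.data.shape
        return self.data.reshape(nx * ny * nz, nt).T


def default_ground_truth(grid: tuple[int, int, int] = DEFAULT_GRID,
                         n_stimuli: int = 8, high_slope: float = 1.0,
                         low_slope: float = 0.0, baseline: float = 10.0,
                         pattern_sd: float = 1.0, rng_seed: int = 0,
                         high_model: str = "layer8",
                         low_model: str = "layer2") -> GroundTruth:
    """Partition the grid along x into four equal voxel populations.

    The ``high_scaling`` population's unexpected-trial amplitude rises by
    ``high_slope`` per z-unit of high-model surprise; ``low_scaling``
    analogously for the low model; ``null`` responds to stimuli but carries
    no surprise scaling; ``non_selective`` has no stimulus patterns either.
    """
    rng = np.random.default_rng(rng_seed)
    n_vox = int(np.prod(grid))
    x_index = np.repeat(np.arange(grid[0]), grid[1] * grid[2])
    bounds = np.linspace(0, grid[0], 5)
    population = np.empty(n_vox, dtype=object)
    for k, label in enumerate(POPULATIONS):
        population[(x_index >= bounds[k]) & (x_index < bounds[k + 1])] = label

    slopes = {
        high_model: np.where(population == "high_scaling", high_slope, 0.0),
        low_model: np.where(population == "low_scaling", low_slope, 0.0),
    }
    patterns = rng.normal(0.0, pattern_sd, size=(n_stimuli, n_vox))
    patterns[:, population == "non_selective"] = 0.0
    return GroundTruth(grid=grid, baseline=np.full(n_vox, float(baseline)),
                       slopes=slopes, population=population,
                       stimulus_patterns=patterns)


# ---------------------------------------------------------------------------
# layered feature hierarchy


def synth_feature_hierarchy(n_stimuli: int = 8, n_layers: int = 8,
                            mixing_schedule: np.ndarray | None = None,
                            latent_dim: int = 6, feature_dim: int = 50,
                            noise_sd: float = 0.1, instance_id: int = 0,
                            rng_seed: int = 0,
                            stimulus_ids: tuple[str, ...] | None = None,
                            ) -> list[FeatureSpace]:
    """Layered feature spaces interpolating two independent latent factors.

    Two latent stimulus factor matrices ("low" and "high") are drawn once
    from the stimulus seed; layer ``l`` features are
    ``(1 - w_l) * low @ P_low,l + w_l * high @ P_high,l`` plus feature noise,
    with a monotone non-decreasing mixing schedule ``w_l`` running from
    low-dominated early layers to high-dominated late layers.  Different
    ``instance_id`` values redraw only the projections and noise, emulating
    independently initialized network instances that share representational
    geometry.
    """
    if mixing_schedule is None:
        mixing_schedule = np.linspace(0.0, 1.0, n_layers)
    w = np.asarray(mixing_schedule, dtype=float)
    if len(w) != n_layers:
        raise ValueError("mixing schedule length must equal n_layers")
    if np.any(np.diff(w) < 0):
        raise ValueError("mixing schedule must be monotone non-decreasing")
    if stimulus_ids is None:
        stimulus_ids = tuple(f"stim{i:03d}" for i in range(n_stimuli))

    latent_rng = np.random.default_rng(rng_seed)
    low = latent_rng.normal(size=(n_stimuli, latent_dim))
    high = latent_rng.normal(size=(n_stimuli, latent_dim))

    inst_rng = np.random.default_rng(np.random.SeedSequence((rng_seed, 1000 + instance_id)))
    layers = []
    for l in range(n_layers):
        p_low = inst_rng.normal(size=(latent_dim, feature_dim)) / np.sqrt(latent_dim)
        p_high = inst_rng.normal(size=(latent_dim, feature_dim)) / np.sqrt(latent_dim)
        feats = (1.0 - w[l]) * (low @ p_low) + w[l] * (high @ p_high)
        feats = feats + inst_rng.normal(0.0, noise_sd, size=feats.shape)
        layers.append(FeatureSpace(layer_id=f"layer{l + 1}", matrix=feats,
                                   stimulus_ids=stimulus_ids,
                                   instance_id=instance_id))
    return layers


def synth_word_embeddings(stimuli: StimulusSet, dim: int = 50,
                          animacy_weight: float = 0.2,
                          rng_seed: int = 0) -> dict[str, np.ndarray]:
    """Synthetic word-embedding stand-ins for the category words.

    Embeddings share an animacy-aligned component (semantically related words
    cluster) plus dominant word-specific structure, so the derived semantic
    RDM is moderately — not perfectly — correlated with the animacy split,
    as real distributional embeddings are (semantic similarity varies widely
    within an animacy class).
    """
    rng = np.random.default_rng(rng_seed)
    animate_axis = rng.normal(size=dim)
    out = {}
    for word, animate in zip(stimuli.category_words, stimuli.animacy):
        sign = 1.0 if animate else -1.0
        out[word] = (animacy_weight * sign * animate_axis
                     + rng.normal(size=dim))
    return out


# ---------------------------------------------------------------------------
# BOLD synthesis


def _trial_regressors(trials: pd.DataFrame, n_scans: int, tr: float) -> np.ndarray:
    """(scans x trials) HRF-convolved unit boxcars, one column per trial."""
    cols = [glm._convolve_events(np.array([row["onset"]]),
                                 np.array([row["duration"]]),
                                 np.array([1.0]), n_scans, tr)
            for _, row in trials.iterrows()]
    return np.column_stack(cols)


def _drift(n_scans: int, tr: float, amplitude: float,
           rng: np.random.Generator, cutoff_s: float = 128.0) -> np.ndarray:
    """Low-frequency drift: random combination of cosines below the
    high-pass cutoff (so filtering should remove it)."""
    basis = glm.dct_highpass_basis(n_scans, tr, cutoff_s)
    if basis.shape[1] == 0 or amplitude == 0:
        return np.zeros(n_scans)
    weights = rng.normal(0.0, amplitude, size=basis.shape[1])
    return basis @ weights


def synth_bold(trials: pd.DataFrame, surprise: dict[str, SurpriseVector],
               truth: GroundTruth, noise_sd: float = 1.0,
               drift_amplitude: float = 0.0, tr: float = DEFAULT_TR,
               rng_seed: int = 0, ar1_rho: float = 0.0) -> BoldRun:
    """Main-task BOLD run with planted linear surprise scaling.

    Each trial evokes, in voxel v, an HRF-convolved 500 ms response of
    amplitude ``baseline_v + sum_m slope_vm * z_m(trial)`` (the z term only
    on unexpected trials covered by that model's surprise vector), plus
    low-frequency drift and Gaussian noise (optionally AR(1)).
    """
    rng = np.random.default_rng(rng_seed)
    n_vox = truth.n_voxels
    n_scans = int(np.ceil(run_duration(trials) / tr))

    x_trials = _trial_regressors(trials, n_scans, tr)      # scans x trials
    amp = np.tile(truth.baseline, (len(trials), 1))        # trials x voxels
    pos = {idx: k for k, idx in enumerate(trials.index)}
    for model, sv in surprise.items():
        slope = truth.slopes.get(model)
        if slope is None:
            continue
        for trial_idx, z in zip(sv.trial_index, sv.z):
            amp[pos[trial_idx]] += slope * z

    unexpected_idx = set(trials.index[trials["condition"] == "unexpected"])
    covered = set()
    for sv in surprise.values():
        covered.update(sv.trial_index.tolist())
    if not unexpected_idx <= covered and surprise:
        raise ValueError("surprise vectors do not cover all unexpected trials")

    signal = x_trials @ amp                                 # scans x voxels
    signal += _drift(n_scans, tr, drift_amplitude, rng)[:, None]
    if noise_sd > 0:
        noise = rng.normal(0.0, noise_sd, size=signal.shape)
        if ar1_rho:
            for t in range(1, n_scans):
                noise[t] += ar1_rho * noise[t - 1]
        signal = signal + noise

    data = signal.T.reshape(*truth.grid, n_scans)
    mask = np.ones(truth.grid, dtype=bool)
    return BoldRun(data=data, tr=tr, mask=mask, truth=truth)


def synth_localizer_bold(localizer_trials: pd.DataFrame, truth: GroundTruth,
                         noise_sd: float = 1.0, tr: float = DEFAULT_TR,
                         block_gain: float = 1.0, rng_seed: int = 0) -> BoldRun:
    """Localizer BOLD run carrying stimulus-specific additive patterns.

    Selective voxels respond to each miniblock with baseline plus the
    stimulus's planted pattern; scrambled miniblocks evoke the baseline
    scaled by ``truth.scrambled_gain`` and no stimulus pattern, so the
    intact-minus-scrambled contrast isolates object-selective voxels.
    """
    rng = np.random.default_rng(rng_seed)
    if truth.stimulus_patterns is None:
        raise ValueError("ground truth lacks stimulus patterns")
    stim_ids = sorted({s for s in localizer_trials["stim_id"]
                       if not s.startswith("scr_")})
    stim_pos = {s: k for k, s in enumerate(stim_ids)}
    n_scans = int(np.ceil(run_duration(localizer_trials) / tr))

    x_blocks = _trial_regressors(localizer_trials, n_scans, tr)
    amp = np.zeros((len(localizer_trials), truth.n_voxels))
    for k, (_, row) in enumerate(localizer_trials.iterrows()):
        if row["condition"] == "scrambled":
            amp[k] = truth.baseline * truth.scrambled_gain
        else:
            amp[k] = truth.baseline + block_gain * truth.stimulus_patterns[stim_pos[row["stim_id"]]]
    amp[:, truth.population == "non_selective"] = 0.0

    signal = x_blocks @ amp
    if noise_sd > 0:
        signal = signal + rng.normal(0.0, noise_sd, size=signal.shape)
    data = signal.T.reshape(*truth.grid, n_scans)
    return BoldRun(data=data, tr=tr, mask=np.ones(truth.grid, dtype=bool),
                   truth=truth)


# ---------------------------------------------------------------------------
# reduced generator for statistical simulations


def synth_trial_betas(surprise_z: np.ndarray, slope: float, noise_sd: float,
                      n_voxels: int = 1, baseline: float = 0.0,
                      rng: np.random.Generator | None = None,
                      rng_seed: int = 0) -> np.ndarray:
    """Single-trial response amplitudes generated directly at the beta level.

    Emulates what the per-trial estimation stage recovers from a run whose
    unexpected-trial amplitude scales linearly with surprise: one amplitude
    per (trial, voxel), ``baseline + slope * z + noise``.  Used for group
    power/type-I simulations where synthesizing and refitting full volumes
    for every replicate adds nothing but runtime.
    """
    if rng is None:
        rng = np.random.default_rng(rng_seed)
    z = np.asarray(surprise_z, dtype=float)[:, None]
    return baseline + slope * z + rng.normal(0.0, noise_sd, size=(len(z), n_voxels))


NUISANCE_COLUMNS = ("trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z",
                    "fd", "csf", "wm")


def synth_nuisance(n_scans: int, rng_seed: int = 0,
                   ar: float = 0.95, sd: float = 0.05) -> pd.DataFrame:
    """Synthetic nuisance time series: 6 motion parameters, framewise
    displacement, CSF and WM signals, each a slow AR(1) process."""
    rng = np.random.default_rng(rng_seed)
    out = {}
    for name in NUISANCE_COLUMNS:
        x = np.empty(n_scans)
        x[0] = rng.normal(0, sd)
        innov = rng.normal(0, sd, size=n_scans)
        for t in range(1, n_scans):
            x[t] = ar * x[t - 1] + innov[t]
        if name == "fd":
            x = np.abs(x)
        out[name] = x
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# behavior


DEFAULT_RT_MEANS = {"expected": 501.0, "unexpected_same": 509.0,
                    "unexpected_diff": 524.0}
DEFAULT_ERROR_RATES = {"expected": 0.02, "unexpected_same": 0.03,
                       "unexpected_diff": 0.06}


def synth_behavior(trials: pd.DataFrame, stimuli: StimulusSet,
                   rt_means: dict[str, float] | None = None,
                   rt_sd: float = 90.0,
                   error_rates: dict[str, float] | None = None,
                   false_alarm_rate: float = 0.03,
                   rng_seed: int = 0) -> pd.DataFrame:
    """Simulated responses: condition-dependent Gaussian RTs (ms, truncated
    at 0 by resampling) and Bernoulli errors; no-go trials respond only on
    false alarms.

    The three RT conditions follow the planted ordering
    expected < unexpected-same < unexpected-different, the behavioral
    facilitation signature of statistical learning.
    """
    rt_means = dict(DEFAULT_RT_MEANS if rt_means is None else rt_means)
    error_rates = dict(DEFAULT_ERROR_RATES if error_rates is None else error_rates)
    rng = np.random.default_rng(rng_seed)

    rows = []
    for idx, row in trials.iterrows():
        cond = row["condition"]
        if cond == "nogo":
            responded = rng.random() < false_alarm_rate
            rows.append({"trial": idx, "condition3": "nogo",
                         "responded": responded, "correct": not responded,
                         "rt_ms": np.nan, **row[["condition", "cue", "stim_id"]]})
            continue
        if cond == "expected":
            cond3 = "expected"
        else:
            expected_img = stimuli.stimulus_for_cue(row["cue"])
            same = stimuli.animacy_of(expected_img) == stimuli.animacy_of(row["stim_id"])
            cond3 = "unexpected_same" if same else "unexpected_diff"
        rt = rng.normal(rt_means[cond3], rt_sd)
        while rt <= 0:
            rt = rng.normal(rt_means[cond3], rt_sd)
        correct = rng.random() >= error_rates[cond3]
        rows.append({"trial": idx, "condition3": cond3, "responded": True,
                     "correct": bool(correct), "rt_ms": float(rt),
                     **row[["condition", "cue", "stim_id"]]})
    return pd.DataFrame(rows)
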