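"""Least-squares-separate (LSS) single-trial estimation.

One GLM is fit per trial: the design contains a regressor for the trial of
interest, one regressor per image identity collecting that image's remaining
trials, a no-go regressor, and nuisance columns.  The beta at the
trial-of-interest column is that trial's estimate.  No-go trials themselves
are never trials of interest.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .glm import _convolve_events
from .synth import BoldRun


@dataclass
class TrialBetaStack:
    """One beta map per go trial plus the trial metadata."""

    betas: np.ndarray            # trials x voxels
    trials: pd.DataFrame         # go trials, aligned with rows of betas

    def __len__(self) -> int:
        return len(self.trials)

    def restrict(self, condition: str) -> "TrialBetaStack":
        keep = (self.trials["condition"] == condition).to_numpy()
        return TrialBetaStack(betas=self.betas[keep],
                              trials=self.trials[keep])

    def select_voxels(self, voxel_idx: np.ndarray) -> np.ndarray:
        return self.betas[:, voxel_idx]


def lss(run: BoldRun | np.ndarray, trials: pd.DataFrame,
        nuisance: pd.DataFrame | None = None,
        tr: float | None = None) -> TrialBetaStack:
    """Least-squares-separate single-trial betas for all go trials.

    ``run`` may be a :class:`BoldRun` or a (time x voxels) array (then
    ``tr`` is required).
    """
    if isinstance(run, BoldRun):
        y = run.timeseries()
        tr = run.tr
    else:
        y = np.asarray(run, dtype=float)
        if tr is None:
            raise ValueError("tr required when passing a raw time series")
    n_scans = y.shape[0]

    go = trials[trials["condition"] != "nogo"]
    nogo = trials[trials["condition"] == "nogo"]

    def conv(subset: pd.DataFrame, amplitudes=None) -> np.ndarray:
        if amplitudes is None:
            amplitudes = np.ones(len(subset))
        return _convolve_events(subset["onset"].to_numpy(),
                                subset["duration"].to_numpy(),
                                amplitudes, n_scans, tr)

    # precompute: single-trial regressors and full per-image regressors
    trial_cols = {idx: conv(go.loc[[idx]]) for idx in go.index}
    images = sorted(go["stim_id"].unique())
    image_full = {img: conv(go[go["stim_id"] == img]) for img in images}
    nogo_col = conv(nogo) if len(nogo) else None
    nuis = (nuisance.to_numpy(dtype=float)
            if nuisance is not None else np.empty((n_scans, 0)))
    const = np.ones((n_scans, 1))

    betas = np.empty((len(go), y.shape[1]))
    for k, idx in enumerate(go.index):
        img = go.loc[idx, "stim_id"]
        cols = [trial_cols[idx]]
        for other in images:
            col = image_full[other] - (trial_cols[idx] if other == img else 0.0)
            if np.allclose(col, 0.0):
                continue        # the trial of interest was that image's only trial
            cols.append(col)
        if nogo_col is not None:
            cols.append(nogo_col)
        x = np.column_stack([np.column_stack(cols), nuis, const])
        if np.linalg.matrix_rank(x) < x.shape[1]:
            raise ValueError(f"rank-deficient LSS design at trial {idx}")
        beta, *_ = np.linalg.lstsq(x, y, rcond=None)
        betas[k] = beta[0]
    return TrialBetaStack(betas=betas, trials=go.reset_index())


def lsa(run: BoldRun | np.ndarray, trials: pd.DataFrame,
        nuisance: pd.DataFrame | None = None,
        tr: float | None = None) -> TrialBetaStack:
    """Least-squares-all oracle: one regressor per go trial, one joint GLM.

    Used as an independent cross-check for LSS on well-spaced designs; not a
    pipeline stage.
    """
    if isinstance(run, BoldRun):
        y = run.timeseries()
        tr = run.tr
    else:
        y = np.asarray(run, dtype=float)
    n_scans = y.shape[0]
    go = trials[trials["condition"] != "nogo"]
    nogo = trials[trials["condition"] == "nogo"]

    cols = [_convolve_events(np.array([row["onset"]]), np.array([row["duration"]]),
                             np.array([1.0]), n_scans, tr)
            for _, row in go.iterrows()]
    extra = []
    if len(nogo):
        extra.append(_convolve_events(nogo["onset"].to_numpy(),
                                      nogo["duration"].to_numpy(),
                                      np.ones(len(nogo)), n_scans, tr))
    if nuisance is not None:
        extra.extend(nuisance[c].to_numpy(dtype=float) for c in nuisance.columns)
    extra.append(np.ones(n_scans))
    x = np.column_stack(cols + extra)
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    return TrialBetaStack(betas=beta[:len(go)], trials=go.reset_index())
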