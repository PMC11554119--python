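"""Surprise-scaling analysis: the headline question of the pipeline.

Single-trial response estimates on unexpected trials are regressed onto
z-scored feature-model surprise, per voxel or per ROI and per subject; the
per-subject slopes are then tested against zero across subjects.  Per-voxel
"preferred layer" maps assign each voxel the layer whose surprise explains
the most variance of its prediction-error response.  ROI construction
(dilation, overlap arbitration, informativeness-based voxel selection) and
the modulator test battery (one-sample and pairwise tests, FDR, Bayes
factors for null results) live here too.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import ndimage, stats
from statsmodels.stats.multitest import multipletests

from .glm import GlmFit, cohens_dz, rank_biserial, smooth, t_to_z
from .lss import TrialBetaStack


@dataclass
class RoiSpec:
    """A named ROI: anatomical voxel set plus the selected analysis subset."""

    name: str
    anatomical: np.ndarray       # flat voxel indices
    selected: np.ndarray         # flat voxel indices, subset of anatomical
    rule: str
    k: int

    def __post_init__(self) -> None:
        if not set(self.selected.tolist()) <= set(self.anatomical.tolist()):
            raise ValueError("selected voxels must lie inside the anatomical mask")


def dilate_mask(mask: np.ndarray, fwhm_mm: float = 3.0,
                voxel_mm: float = 2.0, threshold: float = 0.5) -> np.ndarray:
    """Gaussian dilation of a binary mask (smooth then re-threshold)."""
    sm = smooth(mask.astype(float), fwhm_mm, voxel_mm)
    return (sm >= threshold * sm.max()) | mask.astype(bool)


def arbitrate_overlap(masks: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    """Assign voxels shared between ROI masks to the smaller mask."""
    names = list(masks)
    sizes = {n: int(masks[n].sum()) for n in names}
    order = sorted(names, key=lambda n: sizes[n])   # smallest first keeps the voxel
    out = {n: masks[n].astype(bool).copy() for n in names}
    claimed = np.zeros_like(next(iter(out.values())), dtype=bool)
    for n in order:
        out[n] &= ~claimed
        claimed |= out[n]
    return out


def build_rois(anatomical_masks: dict[str, np.ndarray],
               informativeness: np.ndarray, rule: str = "top_k_decoding",
               k: int = 200, dilation_fwhm_mm: float = 3.0,
               voxel_mm: float = 2.0,
               stimulus_driven_z: float = 3.1) -> list[RoiSpec]:
    """Dilate, arbitrate overlap, then select analysis voxels per ROI.

    ``informativeness`` is a flat per-voxel map: localizer decoding accuracy
    for the ``top_k_decoding`` / ``bottom_k_decoding`` rules, or a localizer
    activation z map for the ``stimulus_driven`` rule.
    """
    shape = next(iter(anatomical_masks.values())).shape
    dilated = {n: dilate_mask(m, dilation_fwhm_mm, voxel_mm)
               for n, m in anatomical_masks.items()}
    arbitrated = arbitrate_overlap(dilated)

    info = np.asarray(informativeness, dtype=float).ravel()
    rois = []
    for name, mask in arbitrated.items():
        anatomical = np.where(mask.ravel())[0]
        if anatomical.size == 0:
            raise ValueError(f"ROI {name} is empty after overlap arbitration")
        scores = info[anatomical]
        if rule == "top_k_decoding":
            kk = min(k, anatomical.size)
            selected = anatomical[np.argsort(scores)[::-1][:kk]]
        elif rule == "bottom_k_decoding":
            kk = min(k, anatomical.size)
            selected = anatomical[np.argsort(scores)[:kk]]
        elif rule == "stimulus_driven":
            selected = anatomical[scores >= stimulus_driven_z]
        else:
            raise ValueError(f"unknown selection rule: {rule}")
        if selected.size == 0:
            raise ValueError(f"ROI {name} has no voxels after selection")
        rois.append(RoiSpec(name=name, anatomical=anatomical,
                            selected=np.sort(selected), rule=rule, k=k))
    return rois


# ---------------------------------------------------------------------------
# regression of single-trial responses onto surprise


def _slope_r(y: np.ndarray, z: np.ndarray) -> tuple[float, float]:
    """OLS slope of y on z (with intercept) and the Pearson r."""
    zc = z - z.mean()
    denom = float(zc @ zc)
    slope = float(zc @ (y - y.mean()) / denom)
    sy = y.std()
    r = float(np.corrcoef(y, z)[0, 1]) if sy > 0 else 0.0
    return slope, r


def scaling_regression(subject_betas: list[TrialBetaStack],
                       subject_surprise: list[np.ndarray],
                       roi_voxels: np.ndarray | None = None,
                       scope: str = "roi") -> dict:
    """Per-subject regression of unexpected-trial responses on surprise.

    Each subject contributes a :class:`TrialBetaStack` already restricted to
    unexpected trials (rows aligned with that subject's z-scored surprise
    vector).  For ``scope='roi'`` the ROI-mean beta per trial is regressed on
    surprise; for ``scope='voxel'`` a slope per voxel is estimated.  Group
    inference is a one-sample t across the subject slopes.
    """
    slopes, rs = [], []
    for stack, z in zip(subject_betas, subject_surprise):
        if len(stack) < 8:
            raise ValueError("need >= 8 unexpected trials per subject")
        if z.std() == 0:
            raise ValueError("degenerate surprise variance")
        betas = stack.betas if roi_voxels is None else stack.select_voxels(roi_voxels)
        if scope == "roi":
            y = betas.mean(axis=1)
            slope, r = _slope_r(y, z)
            slopes.append(slope)
            rs.append(r)
        elif scope == "voxel":
            zc = z - z.mean()
            denom = float(zc @ zc)
            slopes.append(zc @ (betas - betas.mean(axis=0)) / denom)
        else:
            raise ValueError("scope must be 'roi' or 'voxel'")
    slopes_arr = np.asarray(slopes)
    if scope == "roi":
        out = {"slopes": slopes_arr, "mean_slope": float(slopes_arr.mean()),
               "mean_r": float(np.mean(rs)), "dof": len(slopes_arr) - 1}
        if len(slopes_arr) >= 2:
            res = stats.ttest_1samp(slopes_arr, 0.0)
            out.update(t=float(res.statistic), p=float(res.pvalue),
                       dz=cohens_dz(slopes_arr))
        else:
            out.update(t=np.nan, p=np.nan, dz=np.nan)
        return out
    mean = slopes_arr.mean(axis=0)
    if len(slopes_arr) < 2:
        return {"slopes": slopes_arr, "mean_slope": mean,
                "dof": len(slopes_arr) - 1}
    sd = slopes_arr.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(sd > 0, mean / (sd / np.sqrt(len(slopes_arr))), 0.0)
    return {"slopes": slopes_arr, "mean_slope": mean, "t": t,
            "z": t_to_z(t, len(slopes_arr) - 1), "dof": len(slopes_arr) - 1}


def best_layer_effect_map(subject_betas: list[TrialBetaStack],
                          subject_surprise: list[dict[str, np.ndarray]],
                          layer_order: list[str], grid: tuple[int, int, int],
                          mask: np.ndarray | None = None,
                          threshold_z: float = 1.96,
                          extra_smooth_fwhm: float = 3.0,
                          voxel_mm: float = 2.0) -> tuple[np.ndarray, np.ndarray]:
    """Per-voxel preferred layer of the prediction-error scaling.

    For each subject, voxel and layer, a single-layer regression of
    unexpected-trial betas on that layer's z-scored surprise yields an R^2
    and a slope (maps optionally receive additional spatial smoothing before
    group aggregation).  Per voxel, the layer with the largest
    subject-mean R^2 wins (ties to the earlier layer); voxels whose winning
    layer's group slope z falls below ``threshold_z`` are unlabeled (-1).

    Returns (labels, group_z) as flat arrays over the grid.
    """
    n_sub = len(subject_betas)
    n_vox = int(np.prod(grid))
    n_layers = len(layer_order)
    r2 = np.zeros((n_sub, n_layers, n_vox))
    slope = np.zeros((n_sub, n_layers, n_vox))

    for s, (stack, surprise) in enumerate(zip(subject_betas, subject_surprise)):
        betas = stack.betas
        bc = betas - betas.mean(axis=0)
        tss = (bc ** 2).sum(axis=0)
        tss = np.where(tss == 0, np.inf, tss)
        for l, layer in enumerate(layer_order):
            z = surprise[layer]
            zc = z - z.mean()
            denom = float(zc @ zc)
            b = zc @ bc / denom
            ess = denom * b ** 2
            if extra_smooth_fwhm > 0:
                b = smooth(b.reshape(grid), extra_smooth_fwhm, voxel_mm,
                           mask=mask).ravel()
                ess_map = smooth((ess / tss).reshape(grid), extra_smooth_fwhm,
                                 voxel_mm, mask=mask).ravel()
                r2[s, l] = ess_map
            else:
                r2[s, l] = ess / tss
            slope[s, l] = b

    mean_r2 = r2.mean(axis=0)
    best = np.argmax(mean_r2, axis=0)           # first max -> earlier layer on ties
    labels = best.astype(int)
    group_z = np.zeros(n_vox)
    sel = slope[:, best, np.arange(n_vox)]      # subjects x voxels at best layer
    mean = sel.mean(axis=0)
    sd = sel.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(sd > 0, mean / (sd / np.sqrt(n_sub)), 0.0)
    group_z = t_to_z(t, n_sub - 1)
    labels[np.abs(group_z) < threshold_z] = -1
    if mask is not None:
        labels[~mask.ravel()] = -1
    return labels, group_z


def joint_scaling_regression(subject_betas: list[np.ndarray],
                             subject_surprise: list[np.ndarray],
                             model_names: list[str]) -> dict:
    """Joint multi-modulator regression of ROI-mean responses on surprise.

    Per subject, ``betas`` (per-trial ROI-mean responses) are regressed on
    all surprise models simultaneously (plus an intercept), so variance
    shared between models is discarded rather than attributed to either —
    the partial slope per model is tested against zero across subjects.

    ``subject_surprise`` entries are (n_trials x n_models) z-scored columns
    aligned with ``model_names``.
    """
    n_models = len(model_names)
    slopes = np.empty((len(subject_betas), n_models))
    for s, (y, z) in enumerate(zip(subject_betas, subject_surprise)):
        z = np.asarray(z, dtype=float)
        if z.ndim != 2 or z.shape[1] != n_models:
            raise ValueError("surprise must be (trials x models)")
        x = np.column_stack([z, np.ones(len(y))])
        beta, *_ = np.linalg.lstsq(x, np.asarray(y, dtype=float), rcond=None)
        slopes[s] = beta[:n_models]
    out = {}
    for m, name in enumerate(model_names):
        v = slopes[:, m]
        res = stats.ttest_1samp(v, 0.0)
        sem = v.std(ddof=1) / np.sqrt(len(v))
        tcrit = stats.t.ppf(0.975, len(v) - 1)
        out[name] = {"slopes": v, "mean_slope": float(v.mean()),
                     "t": float(res.statistic), "p": float(res.pvalue),
                     "dz": cohens_dz(v),
                     "ci95": (float(v.mean() - tcrit * sem),
                              float(v.mean() + tcrit * sem))}
    return out


# ---------------------------------------------------------------------------
# ROI modulator test battery


def bayes_factor_onesample(t: float, n: int, cauchy_scale: float = 0.707) -> float:
    """Default-prior (JZS, Cauchy 0.707) one-sample Bayes factor BF10."""
    return float(pg.bayesfactor_ttest(t, nx=n, paired=True, r=cauchy_scale))


def roi_modulator_tests(estimates: dict[str, dict[str, np.ndarray]],
                        alpha: float = 0.05,
                        bf_threshold_p: float = 0.05) -> pd.DataFrame:
    """Test each modulator against zero and modulators pairwise, per ROI.

    ``estimates[roi][modulator]`` is the vector of subject-level contrast
    estimates.  One-sample t tests per (ROI, modulator), paired t tests for
    each modulator pair within each ROI, Benjamini-Hochberg correction
    across all tests, Cohen's dz, and a default-prior Bayes factor for
    nonsignificant one-sample results.
    """
    rows = []
    for roi, mods in estimates.items():
        names = list(mods)
        for m in names:
            v = np.asarray(mods[m], dtype=float)
            if np.allclose(v, 0.0):
                rows.append({"roi": roi, "test": "vs_zero", "a": m, "b": "",
                             "statistic": 0.0, "p": 1.0, "dz": 0.0, "n": len(v)})
                continue
            res = stats.ttest_1samp(v, 0.0)
            rows.append({"roi": roi, "test": "vs_zero", "a": m, "b": "",
                         "statistic": float(res.statistic), "p": float(res.pvalue),
                         "dz": cohens_dz(v), "n": len(v)})
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                diff = np.asarray(mods[names[i]]) - np.asarray(mods[names[j]])
                if np.allclose(diff, 0.0):
                    rows.append({"roi": roi, "test": "paired", "a": names[i],
                                 "b": names[j], "statistic": 0.0, "p": 1.0,
                                 "dz": 0.0, "n": len(diff)})
                    continue
                res = stats.ttest_1samp(diff, 0.0)
                rows.append({"roi": roi, "test": "paired", "a": names[i],
                             "b": names[j], "statistic": float(res.statistic),
                             "p": float(res.pvalue), "dz": cohens_dz(diff),
                             "n": len(diff)})
    table = pd.DataFrame(rows)
    _, p_adj, _, _ = multipletests(table["p"].fillna(1.0), alpha=alpha,
                                   method="fdr_bh")
    table["p_fdr"] = p_adj
    table["bf10"] = np.nan
    nonsig = (table["test"] == "vs_zero") & (table["p_fdr"] >= bf_threshold_p)
    for idx in table.index[nonsig]:
        table.loc[idx, "bf10"] = bayes_factor_onesample(
            table.loc[idx, "statistic"], int(table.loc[idx, "n"]))
    return table


def expectation_suppression_contrast(fit: GlmFit) -> tuple[np.ndarray, np.ndarray]:
    """The unexpected-minus-expected contrast (generic prediction error)."""
    return fit.contrast({"unexpected": 1.0, "expected": -1.0})
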