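"""First-level GLM machinery: HRF, design matrices, filtering, fitting,
run combination, collinearity diagnostics and group tests.

Design matrices model each image presentation as a 500 ms event convolved
with a double-gamma hemodynamic response function.  Expected, unexpected and
no-go trials get separate condition regressors; each z-scored surprise model
adds a parametric modulator built from the unexpected-trial events weighted
by that trial's z value.  Temporal derivatives and nuisance time series can
be appended.  Estimation is ordinary least squares per voxel (with an
optional AR(1) Cochrane-Orcutt pass), runs are combined by inverse-variance
fixed effects, and group inference is a one-sample t or Wilcoxon signed-rank
test across subjects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

OVERSAMPLING = 16

COLUMN_CLASSES = ("condition", "modulator", "derivative", "nuisance", "constant")


def hrf_double_gamma(time_grid: np.ndarray, peak_delay: float = 6.0,
                     undershoot_delay: float = 16.0, peak_disp: float = 1.0,
                     undershoot_disp: float = 1.0, ratio: float = 6.0) -> np.ndarray:
    """Canonical double-gamma HRF sampled on ``time_grid`` (seconds).

    Positive response peaking near ``peak_delay`` s minus an undershoot
    peaking near ``undershoot_delay`` s scaled by 1/``ratio``; the kernel is
    normalized to unit peak and is exactly zero at t = 0.
    """
    t = np.asarray(time_grid, dtype=float)
    if np.any(t < 0):
        raise ValueError("HRF time grid must be non-negative")
    peak = stats.gamma.pdf(t, peak_delay / peak_disp, scale=peak_disp)
    under = stats.gamma.pdf(t, undershoot_delay / undershoot_disp,
                            scale=undershoot_disp)
    h = peak - under / ratio
    m = h.max()
    if m > 0:
        h = h / m
    return h


def _convolve_events(onsets: np.ndarray, durations: np.ndarray,
                     amplitudes: np.ndarray, n_scans: int, tr: float,
                     kernel: np.ndarray | None = None,
                     derivative: bool = False) -> np.ndarray:
    """HRF-convolve weighted boxcar events on an oversampled grid, sample at TR."""
    dt = tr / OVERSAMPLING
    n_fine = n_scans * OVERSAMPLING
    neural = np.zeros(n_fine)
    for onset, dur, amp in zip(onsets, durations, amplitudes):
        a = int(round(onset / dt))
        b = int(round((onset + dur) / dt))
        if b > n_fine:
            raise ValueError(f"event at {onset:.2f}s extends past the run end")
        neural[a:b] += amp
    if kernel is None:
        t_kernel = np.arange(0, 32.0 + dt, dt)
        kernel = hrf_double_gamma(t_kernel)
        if derivative:
            kernel = np.gradient(kernel, dt)
    conv = np.convolve(neural, kernel)[:n_fine]
    return conv[::OVERSAMPLING]


@dataclass
class DesignMatrix:
    """Named regressors by timepoint, with per-column classes and the TR."""

    frame: pd.DataFrame
    column_classes: dict[str, str]
    tr: float

    @property
    def matrix(self) -> np.ndarray:
        return self.frame.to_numpy(dtype=float)

    @property
    def names(self) -> list[str]:
        return list(self.frame.columns)

    def columns_of_class(self, cls: str) -> list[str]:
        return [c for c, k in self.column_classes.items() if k == cls]

    def contrast_vector(self, weights: dict[str, float]) -> np.ndarray:
        c = np.zeros(len(self.frame.columns))
        for name, w in weights.items():
            c[self.names.index(name)] = w
        return c


def build_design(trials: pd.DataFrame, surprise: list, n_scans: int,
                 tr: float = 1.0, nuisance: pd.DataFrame | None = None,
                 add_derivatives: bool = True,
                 rank_check: bool = True) -> DesignMatrix:
    """First-level design: condition regressors, z-scored parametric
    modulators on the unexpected trials, optional derivatives and nuisance.

    ``surprise`` is a list of :class:`~pescale.features.SurpriseVector`
    whose ``trial_index`` values refer to rows of ``trials``.
    """
    columns: dict[str, np.ndarray] = {}
    classes: dict[str, str] = {}

    for cond in ("expected", "unexpected", "nogo"):
        sel = trials[trials["condition"] == cond]
        if len(sel) == 0:
            continue
        col = _convolve_events(sel["onset"].to_numpy(), sel["duration"].to_numpy(),
                               np.ones(len(sel)), n_scans, tr)
        columns[cond] = col
        classes[cond] = "condition"

    unexpected = trials[trials["condition"] == "unexpected"]
    if len(unexpected) == 0 and surprise:
        import warnings
        warnings.warn("no unexpected trials: modulator columns omitted")
        surprise = []
    for sv in surprise:
        sel = trials.loc[sv.trial_index]
        col = _convolve_events(sel["onset"].to_numpy(), sel["duration"].to_numpy(),
                               sv.z, n_scans, tr)
        name = f"mod_{sv.model_id}"
        columns[name] = col
        classes[name] = "modulator"

    if add_derivatives:
        for name in list(columns):
            if classes[name] == "condition":
                sel = trials[trials["condition"] == name]
                amp = np.ones(len(sel))
            else:
                sv = next(s for s in surprise if f"mod_{s.model_id}" == name)
                sel = trials.loc[sv.trial_index]
                amp = sv.z
            dcol = _convolve_events(sel["onset"].to_numpy(),
                                    sel["duration"].to_numpy(), amp,
                                    n_scans, tr, derivative=True)
            columns[f"d_{name}"] = dcol
            classes[f"d_{name}"] = "derivative"

    if nuisance is not None:
        for name in nuisance.columns:
            columns[f"nuis_{name}"] = nuisance[name].to_numpy(dtype=float)
            classes[f"nuis_{name}"] = "nuisance"

    columns["constant"] = np.ones(n_scans)
    classes["constant"] = "constant"

    frame = pd.DataFrame(columns)
    bad = [c for c in frame.columns if np.allclose(frame[c], 0)]
    if bad:
        raise ValueError(f"all-zero design column(s): {bad}")
    x = frame.to_numpy(dtype=float)
    if rank_check and np.linalg.matrix_rank(x) < x.shape[1]:
        collinear = _collinear_columns(frame)
        raise ValueError(f"design matrix is rank deficient; collinear columns: {collinear}")
    return DesignMatrix(frame=frame, column_classes=classes, tr=tr)


def _collinear_columns(frame: pd.DataFrame) -> list[str]:
    x = frame.to_numpy(dtype=float)
    _, r = np.linalg.qr(x)
    diag = np.abs(np.diag(r))
    tol = diag.max() * 1e-10
    return [frame.columns[i] for i in np.where(diag < tol)[0]]


# ---------------------------------------------------------------------------
# temporal / spatial preprocessing


def dct_highpass_basis(n_scans: int, tr: float, cutoff_s: float = 128.0) -> np.ndarray:
    """Discrete-cosine basis spanning fluctuations slower than the cutoff
    (mean column excluded)."""
    order = int(np.floor(2 * n_scans * tr / cutoff_s))
    t = np.arange(n_scans)
    basis = [np.cos(np.pi * k * (2 * t + 1) / (2 * n_scans)) for k in range(1, order + 1)]
    if not basis:
        return np.empty((n_scans, 0))
    return np.column_stack(basis)


def highpass(ts: np.ndarray, tr: float = 1.0, cutoff_s: float = 128.0) -> np.ndarray:
    """Remove slow drifts by projecting out a DCT basis (mean removed too).

    Accepts a 1-D series or a 2-D (time x voxels) array.
    """
    y = np.asarray(ts, dtype=float)
    squeeze = y.ndim == 1
    if squeeze:
        y = y[:, None]
    n = y.shape[0]
    basis = np.column_stack([np.ones(n), dct_highpass_basis(n, tr, cutoff_s)])
    beta, *_ = np.linalg.lstsq(basis, y, rcond=None)
    out = y - basis @ beta
    return out[:, 0] if squeeze else out


def smooth(volume: np.ndarray, fwhm_mm: float, voxel_mm: float = 2.0,
           mask: np.ndarray | None = None) -> np.ndarray:
    """Gaussian spatial smoothing with mask-aware edge renormalization.

    Sigma per axis is fwhm / (2 * sqrt(2 * ln 2)) in voxel units.  Within a
    mask, the kernel is renormalized so that flat signal stays flat at the
    mask boundary.
    """
    if fwhm_mm <= 0:
        return volume.copy()
    sigma = fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / voxel_mm
    if mask is None:
        mask = np.ones(volume.shape[:3], dtype=bool)
    m = mask.astype(float)

    def _sm(vol3d: np.ndarray) -> np.ndarray:
        num = ndimage.gaussian_filter(vol3d * m, sigma)
        den = ndimage.gaussian_filter(m, sigma)
        out = np.zeros_like(vol3d)
        ok = den > 1e-12
        out[ok] = num[ok] / den[ok]
        return out * mask

    if volume.ndim == 3:
        return _sm(volume)
    out = np.empty_like(volume, dtype=float)
    for t in range(volume.shape[3]):
        out[..., t] = _sm(volume[..., t])
    return out


# ---------------------------------------------------------------------------
# estimation


@dataclass
class GlmFit:
    """OLS fit of one run: betas, residual variance and (X'X)^-1 for contrasts."""

    design: DesignMatrix
    beta: np.ndarray            # regressors x voxels
    sigma2: np.ndarray          # voxels
    dof: int
    xtx_inv: np.ndarray

    def contrast(self, weights: dict[str, float]) -> tuple[np.ndarray, np.ndarray]:
        """Contrast estimate and variance per voxel."""
        c = self.design.contrast_vector(weights)
        est = c @ self.beta
        var = self.sigma2 * float(c @ self.xtx_inv @ c)
        return est, var

    def contrast_t(self, weights: dict[str, float]) -> np.ndarray:
        est, var = self.contrast(weights)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(var > 0, est / np.sqrt(var), 0.0)
        return t


def fit_glm(y: np.ndarray, design: DesignMatrix, ar1: bool = False) -> GlmFit:
    """Per-voxel ordinary least squares; optional AR(1) Cochrane-Orcutt pass.

    ``y`` is (time x voxels); time length must match the design.
    """
    y = np.asarray(y, dtype=float)
    if y.ndim == 1:
        y = y[:, None]
    x = design.matrix
    if y.shape[0] != x.shape[0]:
        raise ValueError("time axis of data and design differ")
    dof = x.shape[0] - np.linalg.matrix_rank(x)
    if dof <= 0:
        raise ValueError("non-positive residual degrees of freedom")

    if ar1:
        beta0, *_ = np.linalg.lstsq(x, y, rcond=None)
        resid = y - x @ beta0
        num = np.sum(resid[1:] * resid[:-1])
        den = np.sum(resid[:-1] ** 2)
        rho = float(num / den) if den > 0 else 0.0
        rho = np.clip(rho, -0.97, 0.97)
        y = y[1:] - rho * y[:-1]
        x = x[1:] - rho * x[:-1]
        dof = x.shape[0] - np.linalg.matrix_rank(x)

    xtx_inv = np.linalg.pinv(x.T @ x)
    beta = xtx_inv @ x.T @ y
    resid = y - x @ beta
    sigma2 = (resid ** 2).sum(axis=0) / dof
    return GlmFit(design=design, beta=beta, sigma2=sigma2, dof=dof,
                  xtx_inv=xtx_inv)


def t_to_z(t: np.ndarray, dof: int) -> np.ndarray:
    """Map t statistics to standard-normal z preserving tail probability."""
    t = np.asarray(t, dtype=float)
    p = stats.t.sf(np.abs(t), dof)
    z = stats.norm.isf(np.clip(p, 1e-300, 1.0))
    return np.sign(t) * z


def fixed_effects(estimates: list[np.ndarray],
                  variances: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Inverse-variance weighted combination of run-level contrast estimates."""
    est = np.asarray(estimates, dtype=float)
    var = np.asarray(variances, dtype=float)
    if np.any(var <= 0):
        raise ValueError("contrast variances must be positive for fixed effects")
    w = 1.0 / var
    combined_var = 1.0 / w.sum(axis=0)
    combined = (w * est).sum(axis=0) * combined_var
    return combined, combined_var


def vif(design: DesignMatrix, column_class: str | None = None) -> pd.Series:
    """Variance inflation factor per regressor (constant excluded).

    VIF_j = 1 / (1 - R^2_j) from regressing mean-centered column j on all
    other mean-centered columns; perfect collinearity reports ``inf``.
    """
    names = [c for c in design.names if design.column_classes[c] != "constant"]
    x = design.frame[names].to_numpy(dtype=float)
    x = x - x.mean(axis=0)
    out = {}
    for j, name in enumerate(names):
        others = np.delete(x, j, axis=1)
        yj = x[:, j]
        tss = float(yj @ yj)
        if tss == 0:
            out[name] = np.inf
            continue
        beta, *_ = np.linalg.lstsq(others, yj, rcond=None)
        rss = float(np.sum((yj - others @ beta) ** 2))
        r2 = 1.0 - rss / tss
        out[name] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    s = pd.Series(out, name="vif")
    if column_class is not None:
        keep = [c for c in s.index if design.column_classes[c] == column_class]
        s = s.loc[keep]
    return s


# ---------------------------------------------------------------------------
# group-level inference


def cohens_dz(values: np.ndarray) -> float:
    v = np.asarray(values, dtype=float)
    sd = v.std(ddof=1)
    if sd == 0:
        return np.nan
    return float(v.mean() / sd)


def rank_biserial(values: np.ndarray) -> float:
    """Matched-pairs rank-biserial correlation for a one-sample/paired design."""
    v = np.asarray(values, dtype=float)
    v = v[v != 0]
    if len(v) == 0:
        return 0.0
    ranks = stats.rankdata(np.abs(v))
    w_plus = ranks[v > 0].sum()
    total = ranks.sum()
    return float(2.0 * w_plus / total - 1.0)


def group_test(values: np.ndarray, test: str = "t") -> dict:
    """One-sample test of subject-level estimates against zero.

    Returns statistic, two-sided p and the effect size appropriate for the
    test (Cohen's dz for t, matched-pairs rank-biserial r for Wilcoxon).
    """
    v = np.asarray(values, dtype=float)
    if test == "t":
        if v.std(ddof=1) == 0:
            return {"test": "t", "statistic": np.nan, "p": np.nan,
                    "effect_size": np.nan, "flag": "zero variance: dz undefined",
                    "dof": len(v) - 1}
        res = stats.ttest_1samp(v, 0.0)
        dz = cohens_dz(v)
        return {"test": "t", "statistic": float(res.statistic),
                "p": float(res.pvalue), "effect_size": dz, "dof": len(v) - 1}
    if test == "wilcoxon":
        nonzero = v[v != 0]
        if len(nonzero) == 0:
            return {"test": "wilcoxon", "statistic": 0.0, "p": 1.0,
                    "effect_size": 0.0}
        res = stats.wilcoxon(nonzero)
        return {"test": "wilcoxon", "statistic": float(res.statistic),
                "p": float(res.pvalue), "effect_size": rank_biserial(v)}
    raise ValueError(f"unknown test: {test}")


def cluster_inference(subject_maps: np.ndarray, mask: np.ndarray,
                      formation_z: float = 3.29, n_permutations: int = 1000,
                      rng_seed: int = 0) -> pd.DataFrame:
    """Cluster-level FWE inference by sign-flip permutation.

    ``subject_maps`` is (subjects, x, y, z).  The observed group t map is
    converted to z, thresholded at |z| >= ``formation_z``, and 26-connected
    cluster extents are compared against the max-cluster-extent null obtained
    by randomly flipping subject signs.
    """
    maps = np.asarray(subject_maps, dtype=float)
    n_sub = maps.shape[0]
    mask = mask.astype(bool)
    structure = np.ones((3, 3, 3), dtype=bool)   # 26-connectivity

    def _group_z(data: np.ndarray) -> np.ndarray:
        mean = data.mean(axis=0)
        sd = data.std(axis=0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(sd > 0, mean / (sd / np.sqrt(n_sub)), 0.0)
        return t_to_z(t, n_sub - 1)

    def _max_extent(zmap: np.ndarray) -> int:
        supra = (np.abs(zmap) >= formation_z) & mask
        if not supra.any():
            return 0
        labels, n = ndimage.label(supra, structure=structure)
        return int(np.max(ndimage.sum_labels(supra, labels, range(1, n + 1))))

    z_obs = _group_z(maps)
    supra = (np.abs(z_obs) >= formation_z) & mask
    labels, n_clusters = ndimage.label(supra, structure=structure)
    if n_clusters == 0:
        return pd.DataFrame(columns=["cluster_id", "size", "peak_z", "p_fwe"])

    rng = np.random.default_rng(rng_seed)
    null_max = np.empty(n_permutations)
    for k in range(n_permutations):
        flips = rng.choice([-1.0, 1.0], size=n_sub)[:, None, None, None]
        null_max[k] = _max_extent(_group_z(maps * flips))

    rows = []
    for cid in range(1, n_clusters + 1):
        voxels = labels == cid
        size = int(voxels.sum())
        peak = float(np.max(np.abs(z_obs[voxels])))
        p = float((1 + np.sum(null_max >= size)) / (n_permutations + 1))
        rows.append({"cluster_id": cid, "size": size, "peak_z": peak, "p_fwe": p})
    return pd.DataFrame(rows).sort_values("size", ascending=False).reset_index(drop=True)
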