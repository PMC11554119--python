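"""Searchlight representational similarity analysis.

Neural RDMs are built from per-stimulus response patterns (z-scored per
voxel across stimuli, then pairwise cosine distance) inside searchlight
spheres or ROIs, and compared to candidate model RDMs by Kendall tau-a on
the lower-triangle vectors.  Per-voxel best-model ("best layer") maps
summarize which feature level explains local representational geometry.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .features import RDM
from .glm import t_to_z


@dataclass(frozen=True)
class Searchlight:
    center: tuple[int, int, int]
    members: np.ndarray          # flat voxel indices into the grid


def sphere_offsets(radius_mm: float, voxel_mm: float) -> np.ndarray:
    """Integer voxel offsets within a Euclidean radius (mm) of the center."""
    r_vox = radius_mm / voxel_mm
    k = int(np.floor(r_vox))
    axis = np.arange(-k, k + 1)
    dx, dy, dz = np.meshgrid(axis, axis, axis, indexing="ij")
    keep = dx ** 2 + dy ** 2 + dz ** 2 <= r_vox ** 2 + 1e-9
    return np.column_stack([dx[keep], dy[keep], dz[keep]])


def make_searchlights(mask: np.ndarray, radius_mm: float = 6.0,
                      voxel_mm: float = 2.0) -> list[Searchlight]:
    """One sphere per in-mask voxel, members clipped to the mask."""
    mask = np.asarray(mask, dtype=bool)
    offsets = sphere_offsets(radius_mm, voxel_mm)
    shape = mask.shape
    flat = np.ravel_multi_index
    out = []
    centers = np.argwhere(mask)
    for cx, cy, cz in centers:
        pts = offsets + np.array([cx, cy, cz])
        ok = np.all((pts >= 0) & (pts < np.array(shape)), axis=1)
        pts = pts[ok]
        inmask = mask[pts[:, 0], pts[:, 1], pts[:, 2]]
        pts = pts[inmask]
        members = flat((pts[:, 0], pts[:, 1], pts[:, 2]), shape)
        out.append(Searchlight(center=(int(cx), int(cy), int(cz)),
                               members=members))
    return out


def zscore_patterns(betas: np.ndarray) -> np.ndarray:
    """Z-score per voxel across stimuli (rows = stimuli, cols = voxels)."""
    b = np.asarray(betas, dtype=float)
    sd = b.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    return (b - b.mean(axis=0)) / sd


def neural_rdm(patterns: np.ndarray, labels: tuple[str, ...],
               prescaled: bool = False) -> RDM:
    """Cosine-distance RDM over per-voxel z-scored stimulus patterns.

    ``patterns`` is (stimuli x voxels) with at least 2 voxels and 3 stimuli.
    """
    p = np.asarray(patterns, dtype=float)
    if p.shape[0] < 3 or p.shape[1] < 2:
        raise ValueError("need >= 3 stimuli and >= 2 voxels")
    if not prescaled:
        p = zscore_patterns(p)
    norms = np.linalg.norm(p, axis=1)
    if np.any(norms == 0):
        raise ValueError("zero-norm pattern after z-scoring")
    unit = p / norms[:, None]
    values = 1.0 - unit @ unit.T
    np.fill_diagonal(values, 0.0)
    values = (values + values.T) / 2.0
    return RDM(labels=tuple(labels), values=values)


def kendall_tau_a(x: np.ndarray, y: np.ndarray) -> float:
    """Kendall tau-a: (concordant - discordant) / C(n, 2), ties count zero."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 2:
        raise ValueError("need at least two values")
    sx = np.sign(x[:, None] - x[None, :])
    sy = np.sign(y[:, None] - y[None, :])
    iu = np.triu_indices(n, k=1)
    return float(np.sum(sx[iu] * sy[iu]) / (n * (n - 1) / 2))


def rsa_tau(neural: RDM, model: RDM, variant: str = "a") -> tuple[float, float]:
    """Rank correlation between lower triangles, with its Fisher z.

    Returns (tau, atanh(tau)); |tau| = 1 is clamped just inside +-1 before
    the Fisher transform.
    """
    nv = neural.lower_triangle()
    mv = model.lower_triangle()
    if np.all(mv == mv[0]):
        raise ValueError("model RDM lower triangle is constant; tau undefined")
    if variant == "a":
        tau = kendall_tau_a(nv, mv)
    elif variant == "b":
        tau = float(stats.kendalltau(nv, mv).statistic)
    else:
        raise ValueError("variant must be 'a' or 'b'")
    clamped = np.clip(tau, -1 + 1e-12, 1 - 1e-12)
    return tau, float(np.arctanh(clamped))


def searchlight_rsa(stimulus_betas: np.ndarray, labels: tuple[str, ...],
                    searchlights: list[Searchlight],
                    models: dict[str, RDM]) -> dict[str, np.ndarray]:
    """Fisher-z RSA value per searchlight center for each model RDM.

    ``stimulus_betas`` is (stimuli x voxels) over the full flattened grid.
    Returns model -> array over searchlights (NaN where a sphere is too
    small or degenerate).
    """
    z = zscore_patterns(stimulus_betas)
    n = len(labels)
    denom_pairs = None

    # model sign matrices over lower-triangle vectors
    model_signs = {}
    for name, rdm in models.items():
        mv = rdm.lower_triangle()
        model_signs[name] = np.sign(mv[:, None] - mv[None, :])
        m = len(mv)
        denom_pairs = m * (m - 1) / 2

    out = {name: np.full(len(searchlights), np.nan) for name in models}
    li, lj = np.tril_indices(n, k=-1)
    for s_idx, sl in enumerate(searchlights):
        if len(sl.members) < 2:
            continue
        p = z[:, sl.members]
        norms = np.linalg.norm(p, axis=1)
        if np.any(norms == 0):
            continue
        unit = p / norms[:, None]
        dist = 1.0 - unit @ unit.T
        nv = dist[li, lj]
        ns = np.sign(nv[:, None] - nv[None, :])
        pair_iu = np.triu_indices(len(nv), k=1)
        ns_vec = ns[pair_iu]
        for name, ms in model_signs.items():
            tau = np.sum(ns_vec * ms[pair_iu]) / denom_pairs
            out[name][s_idx] = np.arctanh(np.clip(tau, -1 + 1e-12, 1 - 1e-12))
    return out


def best_layer_map(subject_rsa: list[dict[str, np.ndarray]],
                   layer_order: list[str],
                   threshold_z: float = 3.1) -> tuple[np.ndarray, np.ndarray]:
    """Per-searchlight best model label from group-level RSA.

    ``subject_rsa`` holds one Fisher-z dict per subject (aligned searchlight
    order).  For each searchlight, the group mean Fisher-z is maximized over
    layers (ties broken toward the earlier layer); centers whose best layer
    fails the group one-sample t (converted to z) against zero at
    ``threshold_z`` get label -1.

    Returns (labels, group_z_of_best_layer); labels index into
    ``layer_order`` (0-based), -1 = unlabeled.
    """
    n_sub = len(subject_rsa)
    n_sl = len(subject_rsa[0][layer_order[0]])
    stack = np.stack([
        np.stack([s[layer] for layer in layer_order], axis=0)
        for s in subject_rsa
    ])  # subjects x layers x searchlights

    mean = np.nanmean(stack, axis=0)
    best = np.argmax(mean, axis=0)            # argmax returns first max: earlier layer wins ties
    labels = best.copy()
    zbest = np.full(n_sl, np.nan)
    for k in range(n_sl):
        vals = stack[:, best[k], k]
        vals = vals[~np.isnan(vals)]
        if len(vals) < 2 or vals.std(ddof=1) == 0:
            labels[k] = -1
            continue
        t = vals.mean() / (vals.std(ddof=1) / np.sqrt(len(vals)))
        zk = float(t_to_z(np.array([t]), len(vals) - 1)[0])
        zbest[k] = zk
        if zk < threshold_z:
            labels[k] = -1
    return labels, zbest
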