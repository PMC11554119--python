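"""Feature-model RDMs and trial-wise surprise scoring.

A feature model assigns each stimulus a feature vector (e.g. one layer of a
visual network, a word embedding, or a binary animacy code).  The model's
representational dissimilarity matrix (RDM) holds pairwise correlation
distances (1 - Pearson r) between stimulus feature vectors.  Trial-wise
surprise on an unexpected trial is the model dissimilarity between the image
the cue predicted and the image actually seen, z-scored within subject.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .stimuli import StimulusSet


@dataclass(frozen=True)
class FeatureSpace:
    """Per-stimulus feature matrix for one model layer/instance."""

    layer_id: str
    matrix: np.ndarray                  # stimuli x features
    stimulus_ids: tuple[str, ...]
    instance_id: int = 0

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix)
        if m.ndim != 2 or m.shape[1] < 2:
            raise ValueError("feature matrix must be 2-D with >= 2 features")
        if m.shape[0] != len(self.stimulus_ids):
            raise ValueError("one feature row per stimulus required")
        if not np.all(np.isfinite(m)):
            raise ValueError("feature values must be finite")


@dataclass(frozen=True)
class RDM:
    """Symmetric stimulus-by-stimulus dissimilarity matrix."""

    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        n = len(self.labels)
        if v.shape != (n, n):
            raise ValueError("RDM must be square with one row per label")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("RDM must be symmetric")
        if not np.allclose(np.diag(v), 0, atol=1e-10):
            raise ValueError("RDM diagonal must be zero")

    def lookup(self, a: str, b: str) -> float:
        return float(self.values[self.labels.index(a), self.labels.index(b)])

    def lower_triangle(self) -> np.ndarray:
        i, j = np.tril_indices(len(self.labels), k=-1)
        return self.values[i, j]


@dataclass(frozen=True)
class SurpriseVector:
    """Per-unexpected-trial dissimilarity under one feature model."""

    model_id: str
    trial_index: np.ndarray     # row indices into the source events table
    raw: np.ndarray
    z: np.ndarray

    def __len__(self) -> int:
        return len(self.raw)


def correlation_rdm(fs: FeatureSpace) -> RDM:
    """Correlation-distance RDM (1 - Pearson r between feature rows)."""
    m = np.asarray(fs.matrix, dtype=float)
    sd = m.std(axis=1)
    dead = np.where(sd == 0)[0]
    if dead.size:
        names = ", ".join(fs.stimulus_ids[i] for i in dead)
        raise ValueError(f"zero-variance feature row(s) for stimuli: {names}")
    r = np.corrcoef(m)
    values = 1.0 - r
    np.fill_diagonal(values, 0.0)
    values = (values + values.T) / 2.0
    return RDM(labels=tuple(fs.stimulus_ids), values=values)


def average_rdms(rdms: list[RDM]) -> RDM:
    """Element-wise mean of RDMs sharing one label set (instance averaging)."""
    if not rdms:
        raise ValueError("need at least one RDM")
    labels = rdms[0].labels
    for r in rdms[1:]:
        if r.labels != labels:
            raise ValueError("RDM label sets/order do not match")
    return RDM(labels=labels, values=np.mean([r.values for r in rdms], axis=0))


def animacy_rdm(stimuli: StimulusSet) -> RDM:
    """Binary RDM: 0 for same animacy category, 1 for different."""
    a = np.asarray(stimuli.animacy, dtype=int)
    values = (a[:, None] != a[None, :]).astype(float)
    return RDM(labels=tuple(stimuli.stimulus_ids), values=values)


def semantic_rdm(embeddings: dict[str, np.ndarray],
                 words: tuple[str, ...]) -> RDM:
    """Correlation-distance RDM over word-embedding vectors.

    ``embeddings`` maps category words to vectors (supplied externally,
    e.g. precomputed word2vec vectors or a synthetic stand-in).
    """
    missing = [w for w in words if w not in embeddings]
    if missing:
        raise KeyError(f"no embedding for word(s): {missing}")
    matrix = np.vstack([np.asarray(embeddings[w], dtype=float) for w in words])
    fs = FeatureSpace(layer_id="semantic", matrix=matrix, stimulus_ids=words)
    return correlation_rdm(fs)


def trial_surprise(rdm: RDM, trials: pd.DataFrame, stimuli: StimulusSet,
                   model_id: str | None = None) -> SurpriseVector:
    """Dissimilarity of seen vs. cue-predicted image on unexpected trials.

    Raw values are ``rdm[expected_image, seen_image]``; expected and no-go
    trials are excluded.  Values are z-scored across the subject's
    unexpected trials (population SD), matching the convention for
    parametric modulators entered into a design matrix.
    """
    unexpected = trials[trials["condition"] == "unexpected"]
    raw = np.empty(len(unexpected))
    for k, (_, row) in enumerate(unexpected.iterrows()):
        expected_img = stimuli.stimulus_for_cue(row["cue"])
        if expected_img == row["stim_id"]:
            raise ValueError(
                f"trial {row.name}: seen image equals the cue-predicted image "
                "but is flagged unexpected"
            )
        raw[k] = rdm.lookup(expected_img, row["stim_id"])
    sd = raw.std()
    if len(raw) and sd == 0:
        raise ValueError(
            f"feature model {model_id or rdm.labels}: surprise is constant "
            "across unexpected trials and cannot be z-scored"
        )
    z = (raw - raw.mean()) / sd if len(raw) else raw
    return SurpriseVector(model_id=model_id or "model",
                          trial_index=unexpected.index.to_numpy(),
                          raw=raw, z=z)


# ---------------------------------------------------------------------------
# stimulus-set optimization and outlier screening over a larger image pool


def _subset_score(low: np.ndarray, high: np.ndarray) -> tuple[float, float, float, float]:
    i, j = np.tril_indices(low.shape[0], k=-1)
    lv, hv = low[i, j], high[i, j]
    var_low = float(np.var(lv))
    var_high = float(np.var(hv))
    r = float(np.corrcoef(lv, hv)[0, 1])
    return var_low + var_high - abs(r), var_low, var_high, r


def select_stimulus_set(pool_low: FeatureSpace, pool_high: FeatureSpace,
                        pool_animacy: dict[str, bool], n_candidates: int = 1000,
                        rng_seed: int = 0) -> tuple[list[str], dict]:
    """Pick 8 stimuli (4 animate + 4 inanimate) maximizing RDM detectability.

    Among ``n_candidates`` random admissible subsets, returns the one with the
    largest score = var(low-layer RDM triangle) + var(high-layer RDM triangle)
    - |Pearson r between the two triangles|, i.e. maximal within-layer RDM
    variance with minimal across-layer RDM correlation.
    """
    if pool_low.stimulus_ids != pool_high.stimulus_ids:
        raise ValueError("low/high feature spaces must cover the same pool")
    ids = list(pool_low.stimulus_ids)
    animate = [s for s in ids if pool_animacy[s]]
    inanimate = [s for s in ids if not pool_animacy[s]]
    if len(animate) < 4 or len(inanimate) < 4:
        raise ValueError("pool must contain >= 4 stimuli per animacy class")

    rdm_low = correlation_rdm(pool_low).values
    rdm_high = correlation_rdm(pool_high).values
    idx = {s: k for k, s in enumerate(ids)}

    rng = np.random.default_rng(rng_seed)
    single = len(animate) == 4 and len(inanimate) == 4
    best, best_sel, best_diag = -np.inf, None, None
    for _ in range(1 if single else n_candidates):
        sel = (list(rng.choice(animate, 4, replace=False))
               + list(rng.choice(inanimate, 4, replace=False)))
        rows = [idx[s] for s in sel]
        sub_low = rdm_low[np.ix_(rows, rows)]
        sub_high = rdm_high[np.ix_(rows, rows)]
        score, vl, vh, r = _subset_score(sub_low, sub_high)
        if score > best:
            best, best_sel = score, sel
            best_diag = {"score": score, "var_low": vl, "var_high": vh,
                         "cross_layer_r": r}
    return best_sel, best_diag


def flag_outliers(features_high: FeatureSpace,
                  category_labels: dict[str, str]) -> list[str]:
    """Flag category outliers by agglomerative clustering of high-layer features.

    Stimuli are clustered (average linkage, correlation distance, cut at
    k = number of categories); a stimulus is flagged when it is the sole
    exemplar of its category assigned outside that category's modal cluster.
    Categories with fewer than 2 exemplars are skipped.
    """
    ids = list(features_high.stimulus_ids)
    cats = [category_labels[s] for s in ids]
    unique_cats = sorted(set(cats))
    m = np.asarray(features_high.matrix, dtype=float)
    # correlation distance condensed matrix
    dist = 1.0 - np.corrcoef(m)
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    z = linkage(squareform(dist, checks=False), method="average")
    assignment = fcluster(z, t=len(unique_cats), criterion="maxclust")

    flagged: list[str] = []
    for cat in unique_cats:
        members = [k for k, c in enumerate(cats) if c == cat]
        if len(members) < 2:
            continue
        clusters = assignment[members]
        vals, counts = np.unique(clusters, return_counts=True)
        modal = vals[np.argmax(counts)]
        outside = [ids[members[k]] for k in range(len(members))
                   if clusters[k] != modal]
        if len(outside) == 1:
            flagged.extend(outside)
    return flagged
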