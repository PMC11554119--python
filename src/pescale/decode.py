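"""Linear multiclass decoding of stimulus identity.

A linear SVM (C = 1) decodes the 8 image identities from single-trial
response patterns.  Searchlight decoding of the localizer runs provides the
per-voxel informativeness map used for ROI voxel selection; class
probabilities on main-task unexpected trials (from a calibrated decoder
trained on the prediction-free localizer) are regressed onto high-level
surprise; and per-run condition averages support expected-vs-unexpected
identity decoding.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .glm import cohens_dz
from .lss import TrialBetaStack
from .rsa import Searchlight


# pairwise-coupled Platt calibration is the documented probability method;
# newer sklearn flags the constructor argument for future removal
warnings.filterwarnings("ignore", message=".*probability.*deprecated.*",
                        category=FutureWarning, module="sklearn")


def _svm(probability: bool = False, random_state: int = 0) -> SVC:
    # Platt-calibrated pairwise coupling when probability=True
    kwargs = {"probability": True} if probability else {}
    return SVC(kernel="linear", C=1.0, random_state=random_state,
               decision_function_shape="ovo", **kwargs)


def cross_validated_accuracy(x: np.ndarray, labels: np.ndarray,
                             folds: int = 4, random_state: int = 0) -> float:
    """Mean held-out accuracy of a linear SVM under stratified k-fold CV."""
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if np.any(counts < folds):
        raise ValueError("every class needs at least one sample per fold")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=random_state)
    accs = []
    for train, test in skf.split(x, labels):
        clf = _svm(random_state=random_state)
        clf.fit(x[train], labels[train])
        accs.append(float(np.mean(clf.predict(x[test]) == labels[test])))
    return float(np.mean(accs))


def searchlight_decode(stack: TrialBetaStack, searchlights: list[Searchlight],
                       folds: int = 4, random_state: int = 0,
                       label_column: str = "stim_id") -> np.ndarray:
    """Cross-validated decoding accuracy per searchlight sphere."""
    labels = stack.trials[label_column].to_numpy()
    out = np.full(len(searchlights), np.nan)
    for k, sl in enumerate(searchlights):
        if len(sl.members) < 2:
            continue
        out[k] = cross_validated_accuracy(stack.betas[:, sl.members], labels,
                                          folds=folds, random_state=random_state)
    return out


def accuracy_map(stack: TrialBetaStack, searchlights: list[Searchlight],
                 grid: tuple[int, int, int], folds: int = 4,
                 random_state: int = 0) -> np.ndarray:
    """Flat per-voxel accuracy map (centers carry their sphere's accuracy)."""
    acc = searchlight_decode(stack, searchlights, folds, random_state)
    out = np.full(int(np.prod(grid)), np.nan)
    for sl, a in zip(searchlights, acc):
        flat = np.ravel_multi_index(sl.center, grid)
        out[flat] = a
    return out


def true_class_probability_slope(proba: np.ndarray, classes: np.ndarray,
                                 labels: np.ndarray,
                                 z: np.ndarray) -> tuple[float, np.ndarray]:
    """Slope of the decoder's true-class probability on z-scored surprise.

    ``proba`` is (trials x classes) predicted class probabilities; the
    true-class probability of each trial is regressed on ``z`` by OLS with
    intercept.  A decoder emitting uniform probabilities yields a true-class
    probability of exactly 1/n_classes on every trial and a slope of 0.
    """
    class_index = {c: k for k, c in enumerate(classes)}
    true_p = np.array([proba[i, class_index[s]] for i, s in enumerate(labels)])
    zc = z - z.mean()
    slope = float(zc @ (true_p - true_p.mean()) / (zc @ zc))
    return slope, true_p


def probability_vs_surprise(localizer_stacks: list[TrialBetaStack],
                            test_stacks: list[TrialBetaStack],
                            surprise: list[np.ndarray],
                            roi_voxels: np.ndarray,
                            random_state: int = 0) -> dict:
    """Regress decoded true-class probability onto high-level surprise.

    Per subject: a probability-calibrated linear SVM is trained on the
    localizer single-trial patterns (ROI voxels), the true-class probability
    is extracted for each unexpected main-task trial, and its OLS slope on
    the subject's z-scored surprise recorded.  Group inference: one-sample t
    on the slopes.  A decoder with uniform probabilities yields true-class
    probability 1/8 = 0.125 on every trial and slope 0.
    """
    slopes, mean_probs = [], []
    for loc, test, z in zip(localizer_stacks, test_stacks, surprise):
        if loc.betas.shape[1] != test.betas.shape[1]:
            raise ValueError("train/test voxel sets differ")
        x_train = loc.select_voxels(roi_voxels)
        x_test = test.select_voxels(roi_voxels)
        clf = _svm(probability=True, random_state=random_state)
        clf.fit(x_train, loc.trials["stim_id"].to_numpy())
        proba = clf.predict_proba(x_test)
        slope, true_p = true_class_probability_slope(
            proba, clf.classes_, test.trials["stim_id"].to_numpy(), z)
        slopes.append(slope)
        mean_probs.append(float(true_p.mean()))
    slopes_arr = np.asarray(slopes)
    res = stats.ttest_1samp(slopes_arr, 0.0)
    return {"slopes": slopes_arr, "t": float(res.statistic),
            "p": float(res.pvalue), "dz": cohens_dz(slopes_arr),
            "mean_true_class_probability": float(np.mean(mean_probs)),
            "chance": 1.0 / 8.0}


def expectation_decoding(localizer_stack: TrialBetaStack,
                         main_stack: TrialBetaStack,
                         roi_voxels: np.ndarray,
                         run_column: str = "run",
                         random_state: int = 0) -> dict[str, float]:
    """Identity decoding accuracy for expected vs. unexpected trials.

    Trains on localizer patterns and tests on main-task patterns averaged
    per (object, expectation condition, run); returns the mean accuracy per
    condition for one subject.
    """
    clf = _svm(random_state=random_state)
    clf.fit(localizer_stack.select_voxels(roi_voxels),
            localizer_stack.trials["stim_id"].to_numpy())

    trials = main_stack.trials.copy()
    betas = main_stack.select_voxels(roi_voxels)
    if run_column not in trials.columns:
        trials[run_column] = 0
    out = {}
    for cond in ("expected", "unexpected"):
        feats, labels = [], []
        sel = trials["condition"] == cond
        positions = np.where(sel.to_numpy())[0]
        sub = trials.iloc[positions]
        for (run, stim), idx in sub.groupby([run_column, "stim_id"]).indices.items():
            feats.append(betas[positions[idx]].mean(axis=0))
            labels.append(stim)
        acc = float(np.mean(clf.predict(np.vstack(feats)) == np.array(labels)))
        out[cond] = acc
    return out
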