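"""Experimental design generation: transition matrix, runs, blocks, localizer.

The paradigm is a statistical-learning design: on each trial a letter cue
(500 ms) is followed by an object image (500 ms).  Each of the 8 consonant
cues predicts one image, which is 7 times more likely than each of the 7
other images given that cue, i.e. a 50% conditional probability.  Vowel
cues mark no-go trials and carry no predictive association.

Trial sequences are returned as BIDS-style events tables (one row per trial,
``onset``/``duration`` in seconds).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .stimuli import StimulusSet

EVENT_COLUMNS = [
    "onset", "duration", "trial_type", "cue", "stim_id", "condition", "iti",
]

#: seconds between image offset and the next trial's cue onset is the ITI;
#: the cue occupies 0.5 s before each image.
CUE_DURATION = 0.5
IMAGE_DURATION = 0.5


@dataclass(frozen=True)
class ItiSpec:
    """Truncated-exponential intertrial-interval distribution (seconds)."""

    mean: float = 5.0
    minimum: float = 3.0
    maximum: float = 12.0

    def __post_init__(self) -> None:
        if not (self.minimum < self.mean < self.maximum):
            raise ValueError("ITI mean must lie strictly within (min, max)")

    def scale(self) -> float:
        """Exponential scale whose [0, max-min]-truncated mean hits target.

        For Y ~ Exp(s) conditioned on Y <= U the mean is
        s - U / (exp(U/s) - 1); we solve for s so that min + E[Y|Y<=U]
        equals the requested mean.
        """
        u = self.maximum - self.minimum
        target = self.mean - self.minimum

        def trunc_mean(s: float) -> float:
            with np.errstate(over="ignore"):
                return s - u / np.expm1(u / s)

        # truncated mean is increasing in s, bounded above by u/2
        if target >= u / 2:
            raise ValueError("requested mean unattainable for a truncated exponential")
        return brentq(lambda s: trunc_mean(s) - target, 1e-6, 1e4)

    def draw(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw n ITIs by rejection sampling (out-of-range draws redrawn)."""
        s = self.scale()
        out = np.empty(n)
        filled = 0
        while filled < n:
            y = rng.exponential(s, size=2 * (n - filled) + 16)
            y = y[y <= self.maximum - self.minimum]
            take = min(len(y), n - filled)
            out[filled:filled + take] = self.minimum + y[:take]
            filled += take
        return out


MAIN_ITI = ItiSpec(mean=5.0, minimum=3.0, maximum=12.0)
BLOCK_ITI = ItiSpec(mean=2.5, minimum=1.5, maximum=7.5)


@dataclass(frozen=True)
class TransitionMatrix:
    """Cue-by-image trial counts for one run, plus the no-go trial count."""

    stimuli: StimulusSet
    counts: np.ndarray          # 8x8, rows = cues (by stimulus order), cols = images
    nogo_count: int

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.shape != (8, 8):
            raise ValueError("transition matrix must be 8x8")
        if np.any(c < 1):
            raise ValueError("every cue-image cell must occur at least once")

    @property
    def n_go(self) -> int:
        return int(self.counts.sum())

    def conditional_probability(self, cue_idx: int, image_idx: int) -> float:
        row = self.counts[cue_idx]
        return float(row[image_idx] / row.sum())


def build_tpm(stimuli: StimulusSet, expected_reps: int = 7,
              nogo_count: int = 16) -> TransitionMatrix:
    """Transition matrix with the paired image `expected_reps` times per run
    and each of the 7 unexpected images once."""
    if len(set(stimuli.cue_letters)) != 8:
        raise ValueError("stimulus set must define 8 unique cue-image pairings")
    counts = np.ones((8, 8), dtype=int)
    np.fill_diagonal(counts, expected_reps)
    return TransitionMatrix(stimuli=stimuli, counts=counts, nogo_count=nogo_count)


def _order_without_adjacent_repeats(pairs: list[tuple], rng: np.random.Generator,
                                    max_attempts: int = 10_000) -> list[tuple]:
    """Random order with no two consecutive identical entries.

    Shuffles, then repairs any adjacent duplicate by swapping its second
    element with a random position where the swap creates no new duplicate;
    retries with a fresh shuffle if repair stalls.
    """
    pairs = list(pairs)
    n = len(pairs)

    def _ok_at(seq: list, i: int) -> bool:
        if i > 0 and seq[i] == seq[i - 1]:
            return False
        if i < n - 1 and seq[i] == seq[i + 1]:
            return False
        return True

    for _ in range(100):
        perm = rng.permutation(n)
        seq = [pairs[i] for i in perm]
        for _ in range(max_attempts):
            bad = [i for i in range(n - 1) if seq[i] == seq[i + 1]]
            if not bad:
                return seq
            i = bad[0] + 1
            for j in rng.permutation(n):
                if j == i:
                    continue
                seq[i], seq[j] = seq[j], seq[i]
                if _ok_at(seq, i) and _ok_at(seq, j):
                    break
                seq[i], seq[j] = seq[j], seq[i]
            else:
                break   # no repairing swap found; reshuffle
    raise RuntimeError(
        f"could not order {n} trials without adjacent repeats; try another seed"
    )


def _assemble_events(trials: list[dict], itis: np.ndarray,
                     lead_in: float) -> pd.DataFrame:
    onset = lead_in
    rows = []
    for trial, iti in zip(trials, itis):
        rows.append({**trial, "onset": round(onset, 6),
                     "duration": IMAGE_DURATION, "iti": float(iti)})
        # next image onset: this image + ITI + next trial's cue
        onset += IMAGE_DURATION + iti + CUE_DURATION
    return pd.DataFrame(rows)[EVENT_COLUMNS]


def generate_run(tpm: TransitionMatrix, nogo_count: int | None = None,
                 iti_spec: ItiSpec = MAIN_ITI, rng_seed: int = 0,
                 lead_in: float = 10.0) -> pd.DataFrame:
    """One main-task run: the TPM realized exactly, plus no-go trials.

    Returns an events table whose onsets are image onsets (the cue occupies
    the 500 ms before each image and is not modeled as a separate event).
    """
    rng = np.random.default_rng(rng_seed)
    stim = tpm.stimuli
    if nogo_count is None:
        nogo_count = tpm.nogo_count

    pairs: list[tuple[str, str, str]] = []   # (cue, stim_id, condition)
    for i, cue in enumerate(stim.cue_letters):
        for j, image in enumerate(stim.stimulus_ids):
            condition = "expected" if i == j else "unexpected"
            pairs.extend([(cue, image, condition)] * int(tpm.counts[i, j]))
    vowels = list("aeiou")
    for _ in range(nogo_count):
        cue = vowels[rng.integers(len(vowels))]
        image = stim.stimulus_ids[rng.integers(stim.n)]
        pairs.append((cue, image, "nogo"))

    ordered = _order_without_adjacent_repeats(pairs, rng)
    itis = iti_spec.draw(len(ordered), rng)
    trials = [
        {"trial_type": cond, "cue": cue, "stim_id": image, "condition": cond}
        for cue, image, cond in ordered
    ]
    return _assemble_events(trials, itis, lead_in)


def generate_behavioral_block(tpm: TransitionMatrix, rng_seed: int = 0,
                              lead_in: float = 5.0) -> pd.DataFrame:
    """One behavioral block: expected pairs tripled (21 repetitions), twice
    the no-go trials, shorter ITIs; 256 trials in total."""
    boosted = tpm.counts.copy()
    diag = np.diag_indices(8)
    boosted[diag] = boosted[diag] * 3
    block_tpm = TransitionMatrix(stimuli=tpm.stimuli, counts=boosted,
                                 nogo_count=tpm.nogo_count * 2)
    return generate_run(block_tpm, iti_spec=BLOCK_ITI, rng_seed=rng_seed,
                        lead_in=lead_in)


# ---------------------------------------------------------------------------
# functional localizer

MINIBLOCK_DURATION = 12.0     # seconds
CYCLE_DURATION = 0.8          # 500 ms on, 300 ms off
N_CYCLES = int(MINIBLOCK_DURATION / CYCLE_DURATION)   # 15
INTACT_REPEATS = 4
SCRAMBLED_REPEATS = 2


def generate_localizer(stimuli: StimulusSet, scrambled_ids: list[str] | None = None,
                       rng_seed: int = 0, inter_block_interval: float = 4.0,
                       lead_in: float = 10.0) -> pd.DataFrame:
    """Localizer miniblock sequence: each intact image 4 miniblocks, each
    scrambled image 2, no immediate repetition of the same stimulus.

    Each 12 s miniblock flashes one stimulus for 15 cycles (500 ms on,
    300 ms off); one brightness-target cycle per miniblock is drawn
    uniformly from cycles 4-13 (1-based), excluding the first 3 and last 2.
    """
    rng = np.random.default_rng(rng_seed)
    if scrambled_ids is None:
        scrambled_ids = [f"scr_{s}" for s in stimuli.stimulus_ids]
    if len(scrambled_ids) != 8:
        raise ValueError("expected 8 scrambled stimuli")

    blocks = ([(s, "intact")] * INTACT_REPEATS for s in stimuli.stimulus_ids)
    pool = [b for group in blocks for b in group]
    pool += [(s, "scrambled") for s in scrambled_ids for _ in range(SCRAMBLED_REPEATS)]
    ordered = _order_without_adjacent_repeats(pool, rng)

    rows = []
    onset = lead_in
    for stim_id, kind in ordered:
        target_cycle = int(rng.integers(4, N_CYCLES - 1))  # 1-based in {4..13}
        rows.append({
            "onset": round(onset, 6), "duration": MINIBLOCK_DURATION,
            "trial_type": kind, "cue": "", "stim_id": stim_id,
            "condition": kind, "iti": inter_block_interval,
            "target_cycle": target_cycle,
        })
        onset += MINIBLOCK_DURATION + inter_block_interval
    return pd.DataFrame(rows)


def run_duration(events: pd.DataFrame, tail: float = 20.0) -> float:
    """Total run length in seconds, with a post-stimulus tail for the HRF."""
    last = events.iloc[-1]
    return float(last["onset"] + last["duration"] + tail)
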