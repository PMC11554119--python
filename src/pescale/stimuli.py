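"""Stimulus sets for the probabilistic cue-image paradigm.

A stimulus set is 8 full-colour object images (4 animate, 4 inanimate), each
paired one-to-one with a consonant letter cue.  Vowels are reserved as no-go
cues and are never paired with a stimulus.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

VOWELS = frozenset("aeiou")

#: category words available in the image pool, with their animacy
CATEGORY_ANIMACY = {
    "dog": True, "dolphin": True, "elephant": True, "foot": True,
    "hand": True, "woman": True, "man": True, "face": True,
    "swan": True, "tiger": True,
    "car": False, "airplane": False, "church": False, "guitar": False,
    "hammer": False, "house": False, "spoon": False,
}


@dataclass(frozen=True)
class StimulusSet:
    """Eight stimuli, their animacy labels, category words and cue letters."""

    stimulus_ids: tuple[str, ...]
    animacy: tuple[bool, ...]          # True = animate
    category_words: tuple[str, ...]
    cue_letters: tuple[str, ...]

    def __post_init__(self) -> None:
        n = len(self.stimulus_ids)
        if n != 8:
            raise ValueError(f"expected exactly 8 stimuli, got {n}")
        if len(set(self.stimulus_ids)) != n:
            raise ValueError("stimulus ids must be unique")
        if sum(self.animacy) != 4:
            raise ValueError("expected exactly 4 animate and 4 inanimate stimuli")
        if len(set(self.cue_letters)) != n:
            raise ValueError("cue letters must map one-to-one onto stimuli")
        bad = [c for c in self.cue_letters if c.lower() in VOWELS or not c.isalpha()]
        if bad:
            raise ValueError(f"cue letters must be consonants, got {bad}")

    @property
    def n(self) -> int:
        return len(self.stimulus_ids)

    def index(self, stimulus_id: str) -> int:
        return self.stimulus_ids.index(stimulus_id)

    def animacy_of(self, stimulus_id: str) -> bool:
        return self.animacy[self.index(stimulus_id)]

    def cue_for(self, stimulus_id: str) -> str:
        return self.cue_letters[self.index(stimulus_id)]

    def stimulus_for_cue(self, cue: str) -> str:
        return self.stimulus_ids[self.cue_letters.index(cue)]


def default_stimulus_set(rng_seed: int | None = None) -> StimulusSet:
    """A canonical 4+4 stimulus set with fixed or randomized cue pairing.

    With ``rng_seed=None`` a fixed deterministic pairing is returned;
    otherwise cue letters are shuffled against stimuli (each participant
    learns a different letter-image mapping).
    """
    words = ("dog", "tiger", "swan", "face", "car", "guitar", "hammer", "house")
    animacy = tuple(CATEGORY_ANIMACY[w] for w in words)
    letters = ["b", "c", "d", "f", "g", "h", "k", "l"]
    if rng_seed is not None:
        rng = np.random.default_rng(rng_seed)
        letters = list(rng.permutation(letters))
    return StimulusSet(
        stimulus_ids=words,
        animacy=animacy,
        category_words=words,
        cue_letters=tuple(letters),
    )
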