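"""Trial-stream builders for the location-based CSPC experiments.

Two locations (up/down) act as contexts.  In the *simple CSPC* design every
item is biased: in the mostly congruent (MC) location each word appears in
its own color 9 times per block and once in each other color (75%
congruent), while in the mostly incongruent (MI) location every word-color
cell occurs 3 times (75% incongruent).  In the *inducer/diagnostic* design
two words ("red", "green") are inducers — 100% congruent in one location and
100% incongruent (reciprocally: red<->green) in the other — while "blue" and
"yellow" are contingency-unbiased diagnostic items, 50% congruent in both
locations.  Each block has 96 trials, 48 per location; a session is 4
blocks (384 trials), shuffled within block.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional

import numpy as np
import pandas as pd

from .model_core import WORDS, COLORS, LOCATIONS

N_BLOCKS = 4
BLOCK_SIZE = 96

MC = "MC"
MI = "MI"

CONGRUENT = "congruent"
INCONGRUENT = "incongruent"


@dataclass
class TrialSpec:
    """One planned trial: stimuli plus condition labels."""

    word: int
    color: int
    location: int
    block: int = 0
    trial: int = 0
    congruency: str = ""
    context: str = ""
    item_type: str = "unbiased"
    contingency: Optional[str] = None  # high/low, for contingency streams

    @property
    def word_name(self) -> str:
        return WORDS[self.word]

    @property
    def color_name(self) -> str:
        return COLORS[self.color]

    @property
    def location_name(self) -> str:
        return LOCATIONS[self.location]


@dataclass(frozen=True)
class DesignTable:
    """Per-context word x color count matrices for one block."""

    counts: np.ndarray  # (n_locations, 4 words, 4 colors)
    item_type: np.ndarray  # (4, 4) of str labels
    context_of_location: tuple  # e.g. ("MC", "MI")

    def block_total(self) -> int:
        return int(self.counts.sum())


def _sim1_table(mc_location: int) -> DesignTable:
    counts = np.zeros((2, 4, 4), dtype=int)
    counts[mc_location] = np.full((4, 4), 1)
    np.fill_diagonal(counts[mc_location], 9)
    counts[1 - mc_location] = np.full((4, 4), 3)
    ctx = [None, None]
    ctx[mc_location], ctx[1 - mc_location] = MC, MI
    return DesignTable(counts, np.full((4, 4), "unbiased", dtype=object), tuple(ctx))


def _sim2_table(mc_location: int) -> DesignTable:
    counts = np.zeros((2, 4, 4), dtype=int)
    # inducers: red (0) and green (1); 100% congruent in the MC location,
    # reciprocally incongruent (red<->green) in the MI location
    counts[mc_location, 0, 0] = 12
    counts[mc_location, 1, 1] = 12
    counts[1 - mc_location, 0, 1] = 12
    counts[1 - mc_location, 1, 0] = 12
    # diagnostics: blue (2) and yellow (3); 50% congruent everywhere
    for loc in (0, 1):
        for w in (2, 3):
            for c in (2, 3):
                counts[loc, w, c] = 6
    item_type = np.full((4, 4), "diagnostic", dtype=object)
    item_type[:2, :] = "inducer"
    ctx = [None, None]
    ctx[mc_location], ctx[1 - mc_location] = MC, MI
    return DesignTable(counts, item_type, tuple(ctx))


def _expand(table: DesignTable, rng: np.random.Generator) -> List[TrialSpec]:
    trials: List[TrialSpec] = []
    for block in range(N_BLOCKS):
        block_trials = []
        for loc in range(table.counts.shape[0]):
            for w in range(4):
                for c in range(4):
                    for _ in range(int(table.counts[loc, w, c])):
                        block_trials.append(TrialSpec(
                            word=w, color=c, location=loc, block=block,
                            item_type=str(table.item_type[w, c])))
        order = rng.permutation(len(block_trials))
        for i in order:
            block_trials[i].trial = len(trials)
            trials.append(block_trials[i])
    return assign_conditions(trials, table.context_of_location)


def assign_conditions(trials: List[TrialSpec],
                      context_of_location=(MC, MI)) -> List[TrialSpec]:
    """Fill in congruency and context labels from the stimuli themselves."""
    for t in trials:
        if not 0 <= t.word < 4 or not 0 <= t.color < 4:
            raise ValueError(f"unknown word/color id in {t}")
        t.congruency = CONGRUENT if t.word == t.color else INCONGRUENT
        t.context = context_of_location[t.location]
    return trials


def build_simulation1_design(rng: np.random.Generator,
                             mc_location: int = 0) -> List[TrialSpec]:
    """The simple CSPC design: 4 blocks x 96 trials, all items biased.

    ``mc_location`` selects which location is mostly congruent (0 = up, the
    published layout; counterbalancing flips it).
    """
    return _expand(_sim1_table(mc_location), rng)


def build_simulation2_design(rng: np.random.Generator,
                             mc_location: int = 0) -> List[TrialSpec]:
    """The inducer/diagnostic CSPC design: 4 blocks x 96 trials."""
    return _expand(_sim2_table(mc_location), rng)


def build_contingency_design(rng: np.random.Generator,
                             contingency_level: float = 0.75) -> List[TrialSpec]:
    """A plain color-word contingency-learning stream (single location).

    Each word is paired with one *incongruent* color on 9 of its 12
    presentations per block (75%, the classic high-contingency level) and
    with each remaining color once.  Pairings follow a fixed derangement
    (word i -> color (i+1) mod 4) so no word predicts its congruent color;
    trials are labelled high/low contingency, letting the contingency
    benefit be measured among incongruent trials only, uncontaminated by
    congruency.
    """
    if not np.isclose(contingency_level, 0.75):
        raise ValueError("only the 9/12 (75%) schedule is supported")
    trials: List[TrialSpec] = []
    for block in range(N_BLOCKS):
        block_trials = []
        for w in range(4):
            high_c = (w + 1) % 4
            for c in range(4):
                n = 9 if c == high_c else 1
                for _ in range(n):
                    block_trials.append(TrialSpec(
                        word=w, color=c, location=0, block=block,
                        contingency="high" if c == high_c else "low"))
        order = rng.permutation(len(block_trials))
        for i in order:
            block_trials[i].trial = len(trials)
            trials.append(block_trials[i])
    return assign_conditions(trials, (MC, MI))


def design_table(name: str, mc_location: int = 0) -> DesignTable:
    """The per-block count matrices behind a named design."""
    if name == "sim1":
        return _sim1_table(mc_location)
    if name == "sim2":
        return _sim2_table(mc_location)
    raise ValueError(f"unknown design {name!r}")


def build_design(name: str, rng: np.random.Generator,
                 mc_location: int = 0) -> List[TrialSpec]:
    if name == "sim1":
        return build_simulation1_design(rng, mc_location)
    if name == "sim2":
        return build_simulation2_design(rng, mc_location)
    if name == "contingency":
        return build_contingency_design(rng)
    raise ValueError(f"unknown design {name!r}")


def design_to_dataframe(trials: List[TrialSpec]) -> pd.DataFrame:
    return pd.DataFrame({
        "block": [t.block for t in trials],
        "trial": [t.trial for t in trials],
        "word": [t.word_name for t in trials],
        "color": [t.color_name for t in trials],
        "location": [t.location_name for t in trials],
        "congruency": [t.congruency for t in trials],
        "context": [t.context for t in trials],
        "item_type": [t.item_type for t in trials],
    })
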