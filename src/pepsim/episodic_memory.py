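"""Episode storage, retrieval, and the two learning mechanisms.

One episode is laid down per completed trial, coding the word, color and
location presented, the response made, and the trial's RT.  On later trials
episodes are retrieved in parallel, each in proportion to its feature
overlap with what is currently on screen (a MINERVA-2-style echo: full
matches strongest, partial matches weaker, unrelated episodes weakest).

Retrieved episodes do two things:

* **Contingency learning** — each episode pushes the response it encodes,
  proportional to its activation and its response weight.  Stimuli that
  reliably predict a response therefore come to facilitate it, including
  conjunctively (word + location), which is all that context-specific
  contingency learning requires.
* **Temporal learning** — the *pace* (expected time to respond) is pulled
  toward the RTs encoded in the retrieved episodes, weighted by activation
  and time weight, and the response threshold dips when the elapsed time
  nears the pace.  Because retrieval generalises across partial matches,
  a location context acquires its own rhythm, which is what transfers the
  proportion-congruency bias to contingency-unbiased diagnostic items.

Both weights of an episode are weakened multiplicatively each time it is
retrieved, so recent events dominate both predictions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from . import _engine as eng
from .model_core import ModelParameters, TrialStimulus

_INITIAL_WEIGHT = 1.0


@dataclass(frozen=True)
class Episode:
    """One stored trial instance."""

    word: int
    color: int
    location: int
    response: int
    encoded_rt: int
    response_weight: float
    time_weight: float
    trial_index: int


@dataclass(frozen=True)
class Pace:
    """Expected time to respond, in cycles from target onset."""

    expected_rt: float
    provenance: str = "start_of_trial"  # or "within_trial"

    def __float__(self):
        return self.expected_rt


class EpisodeStore:
    """Growable columnar store of episodes for one simulated participant.

    Also carries the participant's pace chain (previous trial's end-of-trial
    pace and RT), since both are episodic quantities that persist across
    trials.
    """

    def __init__(self, capacity: int = 512):
        capacity = max(int(capacity), 8)
        self._word = np.zeros(capacity, dtype=np.int64)
        self._color = np.zeros(capacity, dtype=np.int64)
        self._loc = np.zeros(capacity, dtype=np.int64)
        self._resp = np.zeros(capacity, dtype=np.int64)
        self._rt = np.zeros(capacity, dtype=np.float64)
        self._rw = np.zeros(capacity, dtype=np.float64)
        self._tw = np.zeros(capacity, dtype=np.float64)
        self._n = 0
        self._last_acts: Optional[np.ndarray] = None
        self.previous_pace: Optional[float] = None
        self.previous_rt: Optional[float] = None

    def __len__(self) -> int:
        return self._n

    def _grow(self):
        for name in ("_word", "_color", "_loc", "_resp", "_rt", "_rw", "_tw"):
            old = getattr(self, name)
            new = np.zeros(old.size * 2, dtype=old.dtype)
            new[: old.size] = old
            setattr(self, name, new)

    def encode_episode(self, word: int, color: int, location: int,
                       response: int, rt: int) -> Episode:
        """Append one episode with both weights at their maximum."""
        if self._n == self._word.size:
            self._grow()
        i = self._n
        self._word[i] = word
        self._color[i] = color
        self._loc[i] = location
        self._resp[i] = response
        self._rt[i] = rt
        self._rw[i] = _INITIAL_WEIGHT
        self._tw[i] = _INITIAL_WEIGHT
        self._n += 1
        return self.episode(i)

    def episode(self, i: int) -> Episode:
        if not 0 <= i < self._n:
            raise IndexError(i)
        return Episode(int(self._word[i]), int(self._color[i]),
                       int(self._loc[i]), int(self._resp[i]),
                       int(self._rt[i]), float(self._rw[i]),
                       float(self._tw[i]), i)

    @property
    def time_weights(self) -> np.ndarray:
        return self._tw[: self._n].copy()

    @property
    def response_weights(self) -> np.ndarray:
        return self._rw[: self._n].copy()

    def start_of_trial_pace(self, params: ModelParameters) -> float:
        """Blend of the previous trial's pace and RT; the configured prior
        on a participant's very first trial (the model has no history and,
        at this point, no knowledge of the upcoming context)."""
        if self.previous_pace is None or self.previous_rt is None:
            return float(params.initial_pace)
        return float(start_of_trial_pace(self.previous_pace,
                                         self.previous_rt, params).expected_rt)

    def finish_trial(self, pace_end: float, rt: float):
        self.previous_pace = float(pace_end)
        self.previous_rt = float(rt)

    def to_dataframe(self) -> pd.DataFrame:
        """Episode ledger (debugging/export)."""
        n = self._n
        return pd.DataFrame({
            "trial_index": np.arange(n),
            "word": self._word[:n], "color": self._color[:n],
            "location": self._loc[:n], "response": self._resp[:n],
            "rt": self._rt[:n], "response_weight": self._rw[:n],
            "time_weight": self._tw[:n],
        })


# -- retrieval and its two consequences --------------------------------------

def retrieve_activations(store: EpisodeStore, input_activations: np.ndarray,
                         stim: TrialStimulus, params: ModelParameters) -> np.ndarray:
    """Per-episode activation given the current input activations.

    Each feature of an episode contributes the current activation of the
    input node it encodes; the summed activation is then scaled by
    ``match_mismatch_ratio`` once for every bank in which the encoded
    feature differs from a currently presented one, so episodes are gated
    conjunctively by how well they match the whole display.  Empty store
    returns an empty array.
    """
    acts = np.zeros(max(len(store), 1))
    w, c, l = stim._codes()
    eng.episode_activations(acts, store._word, store._color, store._loc,
                            len(store), input_activations, w, c, l,
                            params.match_mismatch_ratio)
    return acts[: len(store)]


def response_facilitation(activations: np.ndarray, store: EpisodeStore,
                          params: ModelParameters) -> np.ndarray:
    """Additive per-response boost: gain x sum of activation x response
    weight over the episodes encoding each response."""
    boost = np.zeros(eng.N_COLORS)
    acts = np.ascontiguousarray(activations, dtype=np.float64)
    eng.response_facilitation(boost, acts, store._resp, store._rw,
                              min(len(store), acts.size), params.facilitation_gain)
    return boost


def start_of_trial_pace(previous_pace: float, previous_rt: float,
                        params: ModelParameters) -> Pace:
    """pace = blend x previous pace + (1 - blend) x previous RT."""
    b = params.pace_blend
    return Pace(b * float(previous_pace) + (1.0 - b) * float(previous_rt),
                "start_of_trial")


def adjust_pace(pace, activations: np.ndarray, store: EpisodeStore,
                params: ModelParameters) -> Pace:
    """One within-trial pace update toward the weighted mean of the RTs
    encoded in the activated episodes; a no-op when nothing is active."""
    acts = np.ascontiguousarray(activations, dtype=np.float64)
    new = eng.adjust_pace(float(pace), acts, store._tw, store._rt,
                          min(len(store), acts.size), params.pace_update_rate)
    return Pace(float(new), "within_trial")


def threshold_modulation(pace, cycle_from_onset: float,
                         params: ModelParameters, lesioned: bool = False) -> float:
    """Threshold with a Gaussian dip of depth ``dip_depth`` centred on the
    pace; constant at baseline when the temporal mechanism is lesioned."""
    return float(eng.threshold_value(float(pace), float(cycle_from_onset),
                                     params.as_array(), lesioned))


def weaken_on_retrieval(store: EpisodeStore, activations: np.ndarray,
                        params: ModelParameters) -> None:
    """End-of-trial decay of both weights of every stored episode,
    multiplicative in that episode's activation this trial."""
    acts = np.ascontiguousarray(activations, dtype=np.float64)
    eng.weaken_on_retrieval(acts, store._rw, store._tw,
                            min(len(store), acts.size), params.time_weight_decay)
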