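"""Cycle-level network dynamics of the PEP model.

The model is a small interactive-activation network.  Input nodes (4 color
words, 4 colors, 2 screen locations) are driven toward a signal level while
their stimulus is on screen and decay toward a noise floor otherwise.  Word
and color inputs feed four color-concept identity nodes (locations do not —
location is task-irrelevant for color naming), which compete through lateral
inhibition; that competition is the source of the Stroop congruency effect.
Identity nodes feed matching response accumulators, which additionally
receive episodic facilitation (see :mod:`pepsim.episodic_memory`).  The
model responds when a response accumulator crosses the current threshold,
and the number of cycles from target (color) onset to that crossing is the
simulated response time, one cycle standing in for roughly one millisecond.

A trial presents the word alone at fixation for ``word_lead_cycles``, then
removes it and shows the color patch at one of two locations until a
response or ``max_trial_cycles`` elapse.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from typing import Optional

import numpy as np

from . import _engine as eng

WORDS = ("red", "green", "blue", "yellow")
COLORS = WORDS
LOCATIONS = ("up", "down")

N_WORDS = eng.N_WORDS
N_COLORS = eng.N_COLORS
N_LOCATIONS = eng.N_LOCATIONS


class RandomStream:
    """A self-contained PCG32 stream.

    Every simulated participant owns one of these, so runs are reproducible
    and independent of execution order.  ``seq`` selects an independent
    substream for the same seed.
    """

    def __init__(self, seed: int, seq: int = 0):
        self.seed = int(seed)
        self.seq = int(seq)
        self.state = eng.seed_rng(np.uint64(seed), np.uint64(seq))

    def normal(self) -> float:
        return float(eng.rand_normal(self.state))

    def uniform(self) -> float:
        return float(eng.rand_u01(self.state))

    def copy(self) -> "RandomStream":
        other = RandomStream.__new__(RandomStream)
        other.seed, other.seq = self.seed, self.seq
        other.state = self.state.copy()
        return other


@dataclass(frozen=True)
class ModelParameters:
    """The single fixed parameterization shared by every simulation.

    Defaults are the package's one-time calibration, chosen to put overall
    correct RTs in the 700-900 cycle range with a congruency effect of
    standard Stroop magnitude; they are not refit per experiment.

    input_noise_sd
        SD of the Gaussian noise added to every node on every cycle
        (activation units/cycle).
    input_signal_gain
        Asymptotic activation of an input node whose stimulus is on screen.
    input_growth_rate
        Leaky-integration rate of input and identity nodes, per cycle.
    lateral_inhibition
        Subtractive inhibition between identity nodes, per unit of
        competitor activation per cycle.
    identity_to_response_gain
        Evidence fed per cycle from an identity node to its response
        accumulator, per unit of identity activation.
    facilitation_gain
        Scale of the episodic response boost (contingency learning).
    baseline_threshold
        Response threshold in activation units, absent any temporal dip.
    dip_depth, dip_width
        Depth (activation units) and width (cycles) of the Gaussian
        threshold dip centred on the expected time to respond.
    pace_blend
        Start-of-trial mix of previous pace vs. previous RT (1 = all pace).
    pace_update_rate
        Per-cycle rate at which the pace moves toward the retrieved RTs.
    time_weight_decay
        Retrieval-proportional multiplicative decay of episode weights.
    match_mismatch_ratio
        Multiplicative retrieval penalty applied to an episode's whole
        activation per non-matching feature bank (1 = feature identity
        ignored, 0 = strict conjunction).
    word_lead_cycles
        Duration of the word-alone preview at fixation.
    max_trial_cycles
        Response deadline, in cycles from target onset.
    initial_pace
        Expected RT assumed on a participant's very first trial.
    base_seed
        Default seed for runs that do not specify one.
    """

    input_noise_sd: float = 0.006
    input_signal_gain: float = 1.0
    input_growth_rate: float = 0.01
    lateral_inhibition: float = 0.10
    identity_to_response_gain: float = 0.0007
    facilitation_gain: float = 8e-5
    baseline_threshold: float = 1.12
    dip_depth: float = 0.42
    dip_width: float = 90.0
    pace_blend: float = 0.5
    pace_update_rate: float = 0.06
    time_weight_decay: float = 0.05
    match_mismatch_ratio: float = 0.50
    word_lead_cycles: int = 100
    max_trial_cycles: int = 2000
    initial_pace: float = 800.0
    base_seed: int = 0

    def __post_init__(self):
        if self.input_noise_sd < 0:
            raise ValueError("input_noise_sd must be non-negative")
        if self.input_signal_gain < 0:
            raise ValueError("input_signal_gain must be non-negative")
        if not 0 < self.input_growth_rate <= 1:
            raise ValueError("input_growth_rate must be in (0, 1]")
        for name in ("lateral_inhibition", "identity_to_response_gain",
                     "facilitation_gain", "dip_depth"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.baseline_threshold <= 0:
            raise ValueError("baseline_threshold must be positive")
        if self.dip_depth >= self.baseline_threshold:
            raise ValueError("dip_depth must be smaller than baseline_threshold")
        if self.dip_width <= 0:
            raise ValueError("dip_width must be positive")
        for name in ("pace_blend", "pace_update_rate", "time_weight_decay",
                     "match_mismatch_ratio"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.word_lead_cycles < 0:
            raise ValueError("word_lead_cycles must be non-negative")
        if self.max_trial_cycles <= 0:
            raise ValueError("max_trial_cycles must be positive")
        if self.word_lead_cycles >= self.max_trial_cycles:
            raise ValueError("word_lead_cycles must be below max_trial_cycles")
        if not 0 < self.initial_pace <= self.max_trial_cycles:
            raise ValueError("initial_pace must be in (0, max_trial_cycles]")

    def as_array(self) -> np.ndarray:
        """Pack into the flat vector the compiled kernels consume."""
        p = np.empty(eng.N_PARAMS)
        p[eng.P_NOISE_SD] = self.input_noise_sd
        p[eng.P_SIGNAL_GAIN] = self.input_signal_gain
        p[eng.P_GROWTH] = self.input_growth_rate
        p[eng.P_INHIBITION] = self.lateral_inhibition
        p[eng.P_ID_TO_RESP] = self.identity_to_response_gain
        p[eng.P_FACILITATION] = self.facilitation_gain
        p[eng.P_THRESHOLD] = self.baseline_threshold
        p[eng.P_DIP_DEPTH] = self.dip_depth
        p[eng.P_DIP_WIDTH] = self.dip_width
        p[eng.P_PACE_BLEND] = self.pace_blend
        p[eng.P_PACE_RATE] = self.pace_update_rate
        p[eng.P_TW_DECAY] = self.time_weight_decay
        p[eng.P_MISMATCH] = self.match_mismatch_ratio
        p[eng.P_WORD_LEAD] = self.word_lead_cycles
        p[eng.P_MAX_CYCLES] = self.max_trial_cycles
        p[eng.P_INITIAL_PACE] = self.initial_pace
        return p

    def replace(self, **kwargs) -> "ModelParameters":
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


#: The repository's fixed parameterization; every reported simulation uses it.
DEFAULT_PARAMETERS = ModelParameters()


@dataclass
class TrialStimulus:
    """What is on screen at one moment: ids (or None) per stimulus bank."""

    word: Optional[int] = None
    color: Optional[int] = None
    location: Optional[int] = None

    def _codes(self):
        w = -1 if self.word is None else int(self.word)
        c = -1 if self.color is None else int(self.color)
        l = -1 if self.location is None else int(self.location)
        return np.int64(w), np.int64(c), np.int64(l)


@dataclass
class NetworkState:
    """Per-cycle snapshot of the network."""

    input_activations: np.ndarray
    identity_activations: np.ndarray
    response_activations: np.ndarray
    current_threshold: float
    current_pace: float
    cycle: int = 0

    def input_activation(self, bank: str, idx: int) -> float:
        offset = {"word": 0, "color": eng.COLOR_OFFSET, "location": eng.LOC_OFFSET}[bank]
        return float(self.input_activations[offset + idx])


def initialize_trial(params: ModelParameters, rng: RandomStream,
                     pace: Optional[float] = None) -> NetworkState:
    """Fresh network state at cycle 0.

    Input nodes start with small random biases (clamped non-negative noise),
    identity and response nodes at zero, the threshold at baseline and the
    pace at the supplied start-of-trial value (default: the first-trial
    prior).
    """
    if rng is None:
        raise TypeError("initialize_trial requires an explicit RandomStream")
    p = params.as_array()
    in_act = np.zeros(eng.N_INPUTS)
    eng.init_inputs(in_act, p, rng.state)
    return NetworkState(
        input_activations=in_act,
        identity_activations=np.zeros(eng.N_COLORS),
        response_activations=np.zeros(eng.N_COLORS),
        current_threshold=params.baseline_threshold,
        current_pace=params.initial_pace if pace is None else float(pace),
        cycle=0,
    )


def step_cycle(state: NetworkState, stim: TrialStimulus, params: ModelParameters,
               memory=None, rng: RandomStream = None,
               lesion_temporal: bool = False) -> NetworkState:
    """Advance the network by one cycle in place (and return it).

    ``memory`` is an :class:`~pepsim.episodic_memory.EpisodeStore` (or None
    for an episode-free network).  This is the same compiled kernel the full
    trial loop uses, exposed one cycle at a time.
    """
    if rng is None:
        raise TypeError("step_cycle requires an explicit RandomStream")
    if state.cycle >= params.word_lead_cycles + params.max_trial_cycles:
        raise RuntimeError("trial already exhausted max_trial_cycles")
    from .episodic_memory import EpisodeStore  # local import: avoid cycle
    store = memory if memory is not None else EpisodeStore()
    w, c, l = stim._codes()
    p = params.as_array()
    acts = np.zeros(max(len(store), 1))
    pace, threshold = eng.step_cycle(
        state.input_activations, state.identity_activations,
        state.response_activations, acts,
        store._word, store._color, store._loc, store._resp,
        store._rt, store._rw, store._tw, len(store),
        w, c, l, state.cycle, state.current_pace, p,
        lesion_temporal, rng.state)
    if not np.all(np.isfinite(state.response_activations)):
        raise FloatingPointError("non-finite activation: model dynamics diverged")
    state.current_pace = float(pace)
    state.current_threshold = float(threshold)
    state.cycle += 1
    store._last_acts = acts
    return state


def run_trial(trial, params: ModelParameters, memory, rng: RandomStream,
              lesion_temporal: bool = False, record_trace: bool = False):
    """Run one full trial and encode its episode.

    ``trial`` is anything with ``word``, ``color`` and ``location`` ids (a
    :class:`~pepsim.experiment_designs.TrialSpec` or a
    :class:`TrialStimulus` with all fields set).  The word is presented
    alone for the lead period, then replaced by the color patch at its
    location.  Returns ``(response, rt, timeout)`` — RT in cycles from
    target onset — plus the threshold trace when ``record_trace`` is set.

    Side effects: the trial's episode is appended to ``memory`` (existing
    episode weights are weakened by retrieval first) and the memory's pace
    chain is advanced.
    """
    if trial.word is None or trial.color is None or trial.location is None:
        raise ValueError("run_trial needs word, color and location all set")
    p = params.as_array()
    pace_start = memory.start_of_trial_pace(params)
    total = params.word_lead_cycles + params.max_trial_cycles
    trace = np.zeros(total if record_trace else 1)
    response, rt, timeout, pace_end = eng.run_trial_kernel(
        np.int64(trial.word), np.int64(trial.color), np.int64(trial.location),
        p, memory._word, memory._color, memory._loc, memory._resp,
        memory._rt, memory._rw, memory._tw, len(memory),
        pace_start, lesion_temporal, rng.state, trace, record_trace)
    response, rt, timeout = int(response), int(rt), bool(timeout)
    if not np.isfinite(pace_end):
        raise FloatingPointError("non-finite pace: model dynamics diverged")
    memory.encode_episode(trial.word, trial.color, trial.location,
                          response, params.max_trial_cycles if timeout else rt)
    memory.finish_trial(pace_end, rt if not timeout else params.max_trial_cycles)
    if record_trace:
        n = rt + params.word_lead_cycles if not timeout else total
        return response, rt, timeout, trace[:n]
    return response, rt, timeout
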