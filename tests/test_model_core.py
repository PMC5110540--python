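"""Unit tests for the cycle-level network core."""

import numpy as np
import pytest

from pepsim import (DEFAULT_PARAMETERS, ModelParameters, RandomStream,
                    TrialStimulus, initialize_trial, run_trial, step_cycle)
from pepsim.episodic_memory import EpisodeStore


def test_default_parameters_valid_and_frozen():
    p = DEFAULT_PARAMETERS
    assert p.dip_depth < p.baseline_threshold
    assert p.word_lead_cycles < p.max_trial_cycles
    with pytest.raises(AttributeError):
        p.dip_depth = 0.5


@pytest.mark.parametrize("kwargs", [
    {"input_noise_sd": -0.1},
    {"input_signal_gain": -1.0},
    {"input_growth_rate": 0.0},
    {"input_growth_rate": 1.5},
    {"lateral_inhibition": -0.1},
    {"facilitation_gain": -1e-6},
    {"baseline_threshold": 0.0},
    {"baseline_threshold": 0.3, "dip_depth": 0.3},
    {"dip_width": 0.0},
    {"pace_blend": 1.5},
    {"pace_update_rate": -0.1},
    {"time_weight_decay": 2.0},
    {"match_mismatch_ratio": -0.5},
    {"word_lead_cycles": -1},
    {"max_trial_cycles": 0},
    {"word_lead_cycles": 2000, "max_trial_cycles": 2000},
    {"initial_pace": 0.0},
])
def test_parameter_validation_rejects_out_of_range(kwargs):
    with pytest.raises(ValueError):
        DEFAULT_PARAMETERS.replace(**kwargs)


def test_replace_returns_new_instance():
    p = DEFAULT_PARAMETERS.replace(dip_depth=0.2)
    assert p.dip_depth == 0.2
    assert DEFAULT_PARAMETERS.dip_depth != 0.2
    assert p.baseline_threshold == DEFAULT_PARAMETERS.baseline_threshold


def test_as_array_roundtrip():
    arr = DEFAULT_PARAMETERS.as_array()
    d = DEFAULT_PARAMETERS.to_dict()
    assert arr.size == len(d) - 1  # every field except base_seed
    p2 = DEFAULT_PARAMETERS.replace(dip_width=55.0)
    assert 55.0 in p2.as_array()
    assert 55.0 not in arr


def test_random_stream_reproducible_and_substreams_differ():
    a = [RandomStream(42, 1).normal() for _ in range(3)]
    b = [RandomStream(42, 1).normal() for _ in range(3)]
    assert a == b
    r1, r2 = RandomStream(42, 1), RandomStream(42, 2)
    assert [r1.normal() for _ in range(5)] != [r2.normal() for _ in range(5)]
    u = RandomStream(7).uniform()
    assert 0.0 <= u < 1.0


def test_random_stream_copy_is_independent():
    r = RandomStream(3)
    c = r.copy()
    assert r.normal() == c.normal()
    r.normal()
    assert r.normal() != c.normal()  # streams have diverged by one draw


def test_trial_stimulus_codes():
    assert TrialStimulus()._codes() == (-1, -1, -1)
    assert TrialStimulus(word=2, color=0, location=1)._codes() == (2, 0, 1)


def test_initialize_trial_state():
    state = initialize_trial(DEFAULT_PARAMETERS, RandomStream(0))
    assert state.cycle == 0
    assert state.current_threshold == DEFAULT_PARAMETERS.baseline_threshold
    assert state.current_pace == DEFAULT_PARAMETERS.initial_pace
    assert np.all(state.input_activations >= 0)
    assert np.all(state.identity_activations == 0)
    assert np.all(state.response_activations == 0)
    with pytest.raises(TypeError):
        initialize_trial(DEFAULT_PARAMETERS, None)


def test_step_cycle_word_lead_drives_word_not_color():
    params = DEFAULT_PARAMETERS
    rng = RandomStream(1)
    state = initialize_trial(params, rng)
    stim = TrialStimulus(word=0, location=0)
    for _ in range(60):
        step_cycle(state, stim, params, None, rng)
    assert state.cycle == 60
    word_act = state.input_activation("word", 0)
    color_acts = [state.input_activation("color", c) for c in range(4)]
    assert word_act > max(color_acts) + 0.1
    assert params.baseline_threshold - params.dip_depth \
        <= state.current_threshold <= params.baseline_threshold


def test_word_input_decays_after_removal():
    """The word is off screen after target onset and its input decays."""
    params = DEFAULT_PARAMETERS
    rng = RandomStream(2)
    state = initialize_trial(params, rng)
    for _ in range(100):
        step_cycle(state, TrialStimulus(word=1, location=0), params, None, rng)
    at_onset = state.input_activation("word", 1)
    for _ in range(400):
        step_cycle(state, TrialStimulus(color=2, location=0), params, None, rng)
    after = state.input_activation("word", 1)
    assert after < at_onset / 2
    assert state.input_activation("color", 2) > after


def test_step_cycle_exhaustion_raises():
    params = DEFAULT_PARAMETERS.replace(word_lead_cycles=1, max_trial_cycles=3,
                                        initial_pace=2.0)
    rng = RandomStream(0)
    state = initialize_trial(params, rng)
    stim = TrialStimulus(word=0, color=0, location=0)
    for _ in range(4):
        step_cycle(state, stim, params, None, rng)
    with pytest.raises(RuntimeError):
        step_cycle(state, stim, params, None, rng)


def test_run_trial_requires_full_stimulus():
    with pytest.raises(ValueError):
        run_trial(TrialStimulus(word=0, color=None, location=0),
                  DEFAULT_PARAMETERS, EpisodeStore(), RandomStream(0))


def test_run_trial_encodes_exactly_one_episode_with_exact_rt():
    mem = EpisodeStore()
    rng = RandomStream(5)
    resp, rt, timeout = run_trial(TrialStimulus(word=0, color=0, location=0),
                                  DEFAULT_PARAMETERS, mem, rng)
    assert len(mem) == 1
    ep = mem.episode(0)
    assert (ep.word, ep.color, ep.location) == (0, 0, 0)
    assert ep.response == resp
    assert ep.encoded_rt == rt if not timeout \
        else ep.encoded_rt == DEFAULT_PARAMETERS.max_trial_cycles
    assert 0 < rt <= DEFAULT_PARAMETERS.max_trial_cycles
    run_trial(TrialStimulus(word=1, color=2, location=1),
              DEFAULT_PARAMETERS, mem, rng)
    assert len(mem) == 2


def test_run_trial_deterministic():
    def once():
        mem = EpisodeStore()
        rng = RandomStream(9)
        out = []
        for w, c in [(0, 0), (1, 3), (2, 2), (0, 1)]:
            out.append(run_trial(TrialStimulus(word=w, color=c, location=0),
                                 DEFAULT_PARAMETERS, mem, rng))
        return out
    assert once() == once()


def test_lesioned_threshold_trace_constant():
    mem = EpisodeStore()
    rng = RandomStream(4)
    # a couple of trials of history so the pace mechanism would dip if on
    for _ in range(3):
        run_trial(TrialStimulus(word=0, color=0, location=0),
                  DEFAULT_PARAMETERS, mem, rng)
    *_, trace = run_trial(TrialStimulus(word=0, color=0, location=0),
                          DEFAULT_PARAMETERS, mem, rng,
                          lesion_temporal=True, record_trace=True)
    assert np.all(trace == DEFAULT_PARAMETERS.baseline_threshold)


def test_normal_threshold_trace_dips_within_bounds():
    mem = EpisodeStore()
    rng = RandomStream(4)
    for _ in range(3):
        run_trial(TrialStimulus(word=0, color=0, location=0),
                  DEFAULT_PARAMETERS, mem, rng)
    *_, trace = run_trial(TrialStimulus(word=0, color=0, location=0),
                          DEFAULT_PARAMETERS, mem, rng, record_trace=True)
    lo = DEFAULT_PARAMETERS.baseline_threshold - DEFAULT_PARAMETERS.dip_depth
    assert np.all(trace >= lo - 1e-12)
    assert np.all(trace <= DEFAULT_PARAMETERS.baseline_threshold + 1e-12)
    assert trace.min() < DEFAULT_PARAMETERS.baseline_threshold  # it does dip
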