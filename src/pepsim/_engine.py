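"""Compiled inner loop of the PEP simulator.

Everything that runs once per cycle lives here as numba ``@njit`` kernels so
that a 384-trial participant (a few hundred thousand cycles, each touching the
whole episode store) simulates in about a second.  The public modules
(`model_core`, `episodic_memory`) call these same kernels for their
step-level operations, so there is exactly one implementation of the
dynamics.

Randomness uses an explicit PCG32 stream (state passed in as a ``uint64[2]``
array) rather than a global RNG: every participant owns an independent,
reproducible stream, and step-level calls from Python share the same draws as
the fused trial loop.

Node layout (fixed by the task): input nodes 0-3 = words red/green/blue/
yellow, 4-7 = colors, 8-9 = locations up/down; identity nodes 0-3 and
response nodes 0-3 follow the color order.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# -- indices into the packed parameter vector ---------------------------------
P_NOISE_SD = 0
P_SIGNAL_GAIN = 1
P_GROWTH = 2
P_INHIBITION = 3
P_ID_TO_RESP = 4
P_FACILITATION = 5
P_THRESHOLD = 6
P_DIP_DEPTH = 7
P_DIP_WIDTH = 8
P_PACE_BLEND = 9
P_PACE_RATE = 10
P_TW_DECAY = 11
P_MISMATCH = 12
P_WORD_LEAD = 13
P_MAX_CYCLES = 14
P_INITIAL_PACE = 15
N_PARAMS = 16

N_WORDS = 4
N_COLORS = 4
N_LOCATIONS = 2
N_INPUTS = N_WORDS + N_COLORS + N_LOCATIONS
COLOR_OFFSET = N_WORDS
LOC_OFFSET = N_WORDS + N_COLORS

_PCG_MULT = np.uint64(6364136223846793005)


# -- PCG32 stream -------------------------------------------------------------

@njit(cache=True)
def _pcg32(rng):
    old = rng[0]
    rng[0] = old * _PCG_MULT + rng[1]
    xorshifted = np.uint32((((old >> np.uint64(18)) ^ old) >> np.uint64(27)))
    rot = np.uint32(old >> np.uint64(59))
    return np.uint32((xorshifted >> rot) | (xorshifted << ((np.uint32(0) - rot) & np.uint32(31))))


@njit(cache=True)
def seed_rng(seed, seq):
    """Initialise a PCG32 state array from (seed, stream) integers."""
    rng = np.zeros(2, dtype=np.uint64)
    rng[1] = (np.uint64(seq) << np.uint64(1)) | np.uint64(1)
    rng[0] = np.uint64(0)
    _pcg32(rng)
    rng[0] = rng[0] + np.uint64(seed)
    _pcg32(rng)
    return rng


@njit(cache=True)
def rand_u01(rng):
    # strictly inside (0, 1) so Box-Muller never sees log(0)
    return (np.float64(_pcg32(rng)) + 0.5) * (1.0 / 4294967296.0)


@njit(cache=True)
def rand_normal(rng):
    u1 = rand_u01(rng)
    u2 = rand_u01(rng)
    return np.sqrt(-2.0 * np.log(u1)) * np.cos(2.0 * np.pi * u2)


# -- per-cycle dynamics -------------------------------------------------------

@njit(cache=True)
def update_inputs(in_act, word, color, loc, params, rng):
    """Leaky growth toward the signal for presented nodes, decay plus noise
    elsewhere; activations clamped at zero.  ``word``/``color``/``loc`` are
    node ids within their bank, or -1 when that stimulus is absent."""
    gain = params[P_SIGNAL_GAIN]
    rate = params[P_GROWTH]
    sd = params[P_NOISE_SD]
    for i in range(N_INPUTS):
        if i < COLOR_OFFSET:
            presented = i == word
        elif i < LOC_OFFSET:
            presented = (color >= 0) and (i == COLOR_OFFSET + color)
        else:
            presented = (loc >= 0) and (i == LOC_OFFSET + loc)
        drive = gain if presented else 0.0
        a = in_act[i] + rate * (drive - in_act[i]) + sd * rand_normal(rng)
        in_act[i] = a if a > 0.0 else 0.0


@njit(cache=True)
def update_identities(id_act, in_act, params, rng):
    """Word and color inputs drive the matching color-concept node; location
    inputs do not project here.  Lateral inhibition is subtractive in the
    summed activation of the competitors."""
    rate = params[P_GROWTH]
    inh = params[P_INHIBITION]
    sd = params[P_NOISE_SD]
    total = 0.0
    for c in range(N_COLORS):
        total += id_act[c]
    for c in range(N_COLORS):
        drive = in_act[c] + in_act[COLOR_OFFSET + c]
        others = total - id_act[c]
        a = id_act[c] + rate * (drive - id_act[c]) - inh * others + sd * rand_normal(rng)
        id_act[c] = a if a > 0.0 else 0.0


@njit(cache=True)
def episode_activations(acts, ep_word, ep_color, ep_loc, n_ep,
                        in_act, word, color, loc, mismatch_ratio):
    """Similarity-driven parallel retrieval.

    Each stored episode is activated by the current input activation of the
    nodes it encodes, summed over its three feature banks; the whole
    episode activation is then scaled by ``mismatch_ratio`` once per bank
    in which the encoded feature differs from a currently presented one
    (conjunctive gating: an episode from the other location is retrieved
    only faintly even when its word matches).  When nothing is presented
    in a bank (id -1, e.g. the word after target onset) no penalty applies
    and the encoded feature is driven by whatever residual activation its
    node retains.  Full matches therefore dominate, partial matches
    (shared word, color, or location) are retrieved more weakly, and
    zero-overlap episodes weakest of all."""
    for e in range(n_ep):
        w = ep_word[e]
        c = ep_color[e]
        l = ep_loc[e]
        a = in_act[w] + in_act[COLOR_OFFSET + c] + in_act[LOC_OFFSET + l]
        if word >= 0 and w != word:
            a *= mismatch_ratio
        if color >= 0 and c != color:
            a *= mismatch_ratio
        if loc >= 0 and l != loc:
            a *= mismatch_ratio
        acts[e] = a


@njit(cache=True)
def response_facilitation(boost, acts, ep_resp, ep_rw, n_ep, gain):
    """Contingency mechanism: each episode pushes the response it encodes,
    proportional to its activation and its (decaying) response weight."""
    for r in range(N_COLORS):
        boost[r] = 0.0
    for e in range(n_ep):
        boost[ep_resp[e]] += acts[e] * ep_rw[e]
    for r in range(N_COLORS):
        boost[r] *= gain


@njit(cache=True)
def update_responses(resp_act, id_act, boost, params, rng):
    """Responses accumulate identity evidence plus episodic facilitation;
    no leak, clamped at zero."""
    g = params[P_ID_TO_RESP]
    sd = params[P_NOISE_SD]
    for r in range(N_COLORS):
        a = resp_act[r] + g * id_act[r] + boost[r] + sd * rand_normal(rng)
        resp_act[r] = a if a > 0.0 else 0.0


@njit(cache=True)
def adjust_pace(pace, acts, ep_tw, ep_rt, n_ep, rate):
    """Move the pace toward the activation- and time-weight-weighted mean of
    the RTs encoded in the retrieved episodes; inert when nothing is
    retrieved."""
    num = 0.0
    den = 0.0
    for e in range(n_ep):
        w = acts[e] * ep_tw[e]
        num += w * ep_rt[e]
        den += w
    if den <= 1e-12:
        return pace
    return pace + rate * (num / den - pace)


@njit(cache=True)
def threshold_value(pace, t_from_onset, params, lesioned):
    """Gaussian dip in the response threshold centred on the expected time to
    respond; a lesioned (fixed-threshold) model stays at baseline."""
    base = params[P_THRESHOLD]
    if lesioned:
        return base
    z = (t_from_onset - pace) / params[P_DIP_WIDTH]
    return base - params[P_DIP_DEPTH] * np.exp(-0.5 * z * z)


@njit(cache=True)
def step_cycle(in_act, id_act, resp_act, acts,
               ep_word, ep_color, ep_loc, ep_resp, ep_rt, ep_rw, ep_tw, n_ep,
               word, color, loc, cycle, pace, params, lesioned, rng):
    """One full cycle of the network given the currently presented stimuli.

    Mutates the activation arrays in place and returns the updated
    ``(pace, threshold)``.  ``cycle`` counts from trial start; the pace is
    only adjusted, and the threshold dip only referenced, relative to target
    onset (= end of the word-lead period)."""
    word_lead = np.int64(params[P_WORD_LEAD])
    update_inputs(in_act, word, color, loc, params, rng)
    update_identities(id_act, in_act, params, rng)
    episode_activations(acts, ep_word, ep_color, ep_loc, n_ep,
                        in_act, word, color, loc, params[P_MISMATCH])
    boost = np.empty(N_COLORS)
    response_facilitation(boost, acts, ep_resp, ep_rw, n_ep, params[P_FACILITATION])
    update_responses(resp_act, id_act, boost, params, rng)
    t_from_onset = np.float64(cycle - word_lead)
    if cycle >= word_lead:
        pace = adjust_pace(pace, acts, ep_tw, ep_rt, n_ep, params[P_PACE_RATE])
    threshold = threshold_value(pace, t_from_onset, params, lesioned)
    return pace, threshold


@njit(cache=True)
def weaken_on_retrieval(acts, ep_rw, ep_tw, n_ep, decay):
    """End-of-trial weight decay: both the response and the time weight of an
    episode shrink multiplicatively in proportion to how strongly it was
    retrieved this trial, floored at zero."""
    for e in range(n_ep):
        f = 1.0 - decay * acts[e]
        if f < 0.0:
            f = 0.0
        ep_rw[e] *= f
        ep_tw[e] *= f


@njit(cache=True)
def init_inputs(in_act, params, rng):
    """Start-of-trial random input biases (half-normal, scale = noise sd)."""
    sd = params[P_NOISE_SD]
    for i in range(N_INPUTS):
        a = sd * rand_normal(rng)
        in_act[i] = a if a > 0.0 else 0.0


@njit(cache=True)
def run_trial_kernel(word, color, loc, params,
                     ep_word, ep_color, ep_loc, ep_resp, ep_rt, ep_rw, ep_tw,
                     n_ep, pace_start, lesioned, rng, thr_trace, record_trace):
    """Simulate one trial: word alone for the lead period, then the color
    patch at its location until a response node crosses the (possibly
    dipping) threshold or the trial times out.

    Returns ``(response, rt, timeout, pace_end)`` with the RT in cycles from
    target onset.  Encoding of the new episode and weight weakening are done
    by the caller so that the episode store stays a plain growable structure
    on the Python side."""
    word_lead = np.int64(params[P_WORD_LEAD])
    max_cycles = np.int64(params[P_MAX_CYCLES])
    in_act = np.zeros(N_INPUTS)
    id_act = np.zeros(N_COLORS)
    resp_act = np.zeros(N_COLORS)
    acts = np.zeros(max(n_ep, 1))
    init_inputs(in_act, params, rng)
    pace = pace_start
    response = np.int64(-1)
    rt = np.int64(max_cycles)
    timeout = True
    total = word_lead + max_cycles
    for cycle in range(total):
        # the location is visible throughout: the word appears at it, then
        # the color patch replaces the word there
        if cycle < word_lead:
            w, c, l = word, np.int64(-1), loc
        else:
            w, c, l = np.int64(-1), color, loc
        pace, threshold = step_cycle(
            in_act, id_act, resp_act, acts,
            ep_word, ep_color, ep_loc, ep_resp, ep_rt, ep_rw, ep_tw, n_ep,
            w, c, l, cycle, pace, params, lesioned, rng)
        if record_trace:
            thr_trace[cycle] = threshold
        if cycle >= word_lead:
            best = 0
            for r in range(1, N_COLORS):
                if resp_act[r] > resp_act[best]:
                    best = r
            if resp_act[best] >= threshold:
                # exact ties broken at random among the tied maxima
                n_tied = 0
                for r in range(N_COLORS):
                    if resp_act[r] == resp_act[best]:
                        n_tied += 1
                if n_tied > 1:
                    k = np.int64(rand_u01(rng) * n_tied)
                    if k >= n_tied:
                        k = n_tied - 1
                    for r in range(N_COLORS):
                        if resp_act[r] == resp_act[best]:
                            if k == 0:
                                best = r
                                break
                            k -= 1
                response = np.int64(best)
                rt = np.int64(cycle - word_lead + 1)
                timeout = False
                break
    if timeout:
        # no threshold crossing: report the most active response, flagged
        best = 0
        for r in range(1, N_COLORS):
            if resp_act[r] > resp_act[best]:
                best = r
        response = np.int64(best)
    if n_ep > 0:
        weaken_on_retrieval(acts, ep_rw, ep_tw, n_ep, params[P_TW_DECAY])
    return response, rt, timeout, pace
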