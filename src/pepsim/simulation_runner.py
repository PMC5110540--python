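"""Batch execution of simulated participants.

Every participant shares the one fixed parameterization but owns an
independent noise stream and a freshly shuffled trial order, so results
differ across participants while any (design, parameters, seed) triple is
bit-reproducible.  The temporal-learning lesion is a single switch that
holds the response threshold at baseline; nothing else changes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional

import numpy as np
import pandas as pd

from . import model_core
from .episodic_memory import EpisodeStore
from .experiment_designs import TrialSpec, build_design
from .model_core import DEFAULT_PARAMETERS, ModelParameters, RandomStream

logger = logging.getLogger("pepsim")

#: columns of the trial-level results table, in output order
RESULT_COLUMNS = ["participant", "block", "trial", "word", "color", "location",
                  "context", "item_type", "congruency", "response",
                  "rt_cycles", "accuracy", "timeout"]

# substream tags so design shuffling and network noise never share draws
_DESIGN_STREAM = 7
_ENGINE_STREAM = 11


@dataclass
class TrialResult:
    """One simulated trial's outcome joined with its condition labels."""

    participant: int
    spec: TrialSpec
    response: int
    rt_cycles: int
    accuracy: bool
    timeout: bool

    def as_row(self) -> dict:
        s = self.spec
        return {
            "participant": self.participant, "block": s.block, "trial": s.trial,
            "word": s.word_name, "color": s.color_name,
            "location": s.location_name, "context": s.context,
            "item_type": s.item_type, "congruency": s.congruency,
            "response": model_core.COLORS[self.response] if self.response >= 0 else "none",
            "rt_cycles": self.rt_cycles, "accuracy": self.accuracy,
            "timeout": self.timeout,
            **({"contingency": s.contingency} if s.contingency else {}),
        }


@dataclass
class RunConfig:
    """Everything needed to reproduce a batch run."""

    design: str = "sim1"
    n_participants: int = 500
    lesion_temporal: bool = False
    base_seed: int = 0
    output: Optional[str] = None
    mc_location: int = 0
    params: ModelParameters = field(default_factory=lambda: DEFAULT_PARAMETERS)
    allow_param_override: bool = False

    def __post_init__(self):
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        if self.params != DEFAULT_PARAMETERS and not self.allow_param_override:
            raise ValueError(
                "non-default ModelParameters: all reported simulations share "
                "one fixed parameterization; pass allow_param_override=True "
                "to run an exploratory parameterization")


def run_participant(design: List[TrialSpec], params: ModelParameters,
                    seed: int, lesion_temporal: bool = False,
                    participant: int = 0) -> List[TrialResult]:
    """Run one participant through an already-ordered trial list.

    A fresh episode store is created; trials run in the given order; the
    outcome stream is fully determined by ``seed``.
    """
    rng = RandomStream(seed, _ENGINE_STREAM)
    memory = EpisodeStore(capacity=len(design))
    results = []
    for spec in design:
        response, rt, timeout = model_core.run_trial(
            spec, params, memory, rng, lesion_temporal=lesion_temporal)
        results.append(TrialResult(
            participant=participant, spec=spec, response=response,
            rt_cycles=rt, accuracy=(response == spec.color) and not timeout,
            timeout=timeout))
    return results


def run_batch(config: RunConfig) -> pd.DataFrame:
    """Run ``n_participants`` simulated participants and return (and
    optionally write) the concatenated trial-level results.

    Participant *i* uses seed ``base_seed + i`` for both their trial-order
    shuffle and their network noise, so batches are reproducible and
    independent of execution order.
    """
    out_path = None
    if config.output is not None:
        out_path = Path(config.output)
        parent = out_path.parent
        if not parent.exists():
            raise FileNotFoundError(f"output directory does not exist: {parent}")
    rows = []
    for i in range(config.n_participants):
        seed = config.base_seed + i
        design_rng = np.random.default_rng([seed, _DESIGN_STREAM])
        design = build_design(config.design, design_rng, config.mc_location)
        results = run_participant(design, config.params, seed,
                                  config.lesion_temporal, participant=i)
        rts = [r.rt_cycles for r in results if r.accuracy and not r.timeout]
        err = 100.0 * (1.0 - sum(r.accuracy for r in results) / len(results))
        logger.info("participant %d/%d: mean correct RT %.0f cycles, %.1f%% errors",
                    i + 1, config.n_participants,
                    float(np.mean(rts)) if rts else float("nan"), err)
        rows.extend(r.as_row() for r in results)
    df = pd.DataFrame(rows)
    ordered = [c for c in RESULT_COLUMNS if c in df.columns]
    extra = [c for c in df.columns if c not in ordered]
    df = df[ordered + extra]
    if out_path is not None:
        df.to_csv(out_path, index=False)
    return df
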