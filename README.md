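# pepsim

A trial-level simulator of the **Parallel Episodic Processing (PEP)**
model of Stroop performance, built to reproduce **context-specific
proportion congruent (CSPC)** effects — the finding that the Stroop
congruency effect is larger in a screen location where most trials are
congruent than in a location where most trials are incongruent, even
though participants cannot know a trial's location in advance.

The model explains this without a conflict monitor or attentional control
system. It stores one **episode** per trial (word, color, location,
response, response time) and retrieves past episodes in parallel, in
proportion to their overlap with the current display. Retrieval does two
things:

* **Contingency learning** — each retrieved episode facilitates the
  response it encodes, so stimulus compounds (e.g., a word at a location)
  that reliably predict a response come to speed it.
* **Temporal learning** — retrieved episodes carry their RTs, which set
  the **pace**: the expected time to respond. The response threshold dips
  transiently around the pace, so the model responds fastest when the
  current trial's timing matches the local rhythm. Each location acquires
  its own rhythm, which transfers the proportion-congruency bias even to
  contingency-unbiased items.

Lesioning the temporal mechanism (fixing the threshold at baseline)
leaves only contingency learning, which shrinks — but does not abolish —
the CSPC effect. That dissociation, and its transfer to unbiased
diagnostic items, are the headline simulation results this package
reproduces.

## Worked example

Simulate 20 participants in the Simulation 1 design (two locations: one
75% congruent, one 75% incongruent) and measure the CSPC effect:

```python
import pepsim as pp

df = pp.run_batch(pp.RunConfig(design="sim1", n_participants=20, base_seed=0))
print(pp.summarize(df).to_string(index=False))
eff = pp.cspc_effect(df)
print(f"CSPC effect: {eff.cspc_effect:.1f} cycles "
      f"(t({eff.n_participants - 1}) = {eff.t_statistic:.2f}, "
      f"p = {eff.p_value:.2g})")
```

Output (exact, reproducible — every batch is fully seeded):

```
context  congruency item_type    mean_rt  error_pct    n
     MC   congruent       all 633.472608   0.034722 2876
     MC incongruent       all 781.166135   0.208333  956
     MI   congruent       all 661.592996   0.104167  959
     MI incongruent       all 772.513579   0.348193 2873
CSPC effect: 36.8 cycles (t(19) = 4.22, p = 0.00046)
```

Reading the table: RT is in cycles (~ms) from color onset, on correct
non-timeout trials, averaged within participant first. The congruency
effect is 781 − 633 ≈ 148 cycles in the mostly congruent (MC) location
but only 773 − 662 ≈ 111 cycles in the mostly incongruent (MI) location:
a CSPC effect of ~37 cycles, significant across 20 simulated
participants. Errors are rare but follow the same pattern (more errors on
incongruent trials) — no speed-accuracy trade-off.

The same run from the command line:

```bash
pep-sim run --design sim1 --participants 20 --seed 0 --out results.csv
pep-sim report --in results.csv --out summary.csv --plot cells.png
```

Other designs and switches:

```bash
# temporal lesion: contingency learning only
pep-sim run --design sim1 --participants 100 --seed 0 --lesion-temporal --out lesion.csv

# inducer/diagnostic design; analyse unbiased items only
pep-sim run --design sim2 --participants 100 --seed 0 --out sim2.csv
pep-sim report --in sim2.csv --out diag.csv --item-type diagnostic

# single-location 75% contingency stream
pep-sim run --design contingency --participants 100 --seed 0 --lesion-temporal --out cont.csv
```

All reported simulations share one fixed parameterization
(`pepsim.DEFAULT_PARAMETERS`); `run_batch` refuses other parameterizations
unless an explicit exploratory override is set. See
[docs/methods.md](docs/methods.md) for the full model description,
parameter table and calibration rationale.

## Package layout

| module | contents |
| --- | --- |
| `pepsim.model_core` | parameters, network state, cycle-level dynamics, trial loop |
| `pepsim.episodic_memory` | episode store, parallel retrieval, facilitation, pace/threshold |
| `pepsim.experiment_designs` | trial-stream builders for the CSPC and contingency designs |
| `pepsim.simulation_runner` | seeded batch execution, lesion switch, CSV persistence |
| `pepsim.analysis_reporting` | condition summaries, congruency/CSPC/contingency effects, figures |
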