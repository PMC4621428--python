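# eventmodels

Online event segmentation into discrete episodic markers, an
activation-based episodic store, retrospective construction of event
partonomies, and mental-model temporal reasoning — in one pipeline.

The engine consumes timestamped symbolic observation streams over four
channels (`goal`, `location`, `person`, `object`). Each instant at which at
least one change is detected yields one *episodic marker* — a punctate
chunk recording all simultaneous changes, chained to its predecessor and
tagged with the active goal. Markers live in an episodic store with
base-level activation decay, retrieval spikes, and one-step spreading to
associates. From retrieved markers the engine reconstructs *event models*:
durational/punctate events bounded by marker pairs, arranged at ordinal
(non-metric) timeline positions and nested into a bounded part-whole
hierarchy. Reconstruction is either *veridical* (every marker pair becomes
an event) or *prioritized* (goal > location > person > object; lower-priority
events are committed only within the bounds of committed higher-priority
events). Temporal queries (`before`, `after`, `while`, `when`, `during`)
are answered by scanning models; premise-based problems enumerate all
consistent ordinal arrangements and classify relations as **necessary**,
**possible**, or **impossible**. Models can be revised counterfactually by
repositioning events.

## CLI

All commands are under a single entry point:

```bash
# generate a stream: a canned fixture or a seeded random scenario
eventmodels simulate --fixture patrol --out patrol.jsonl
eventmodels simulate --seed 7 --channels 3 --duration 60 --rate 0.2 --out random.jsonl

# encode episodic markers
eventmodels segment --stream patrol.jsonl --out markers.jsonl

# reconstruct an event model (ASCII rendering with --show)
eventmodels reconstruct --markers markers.jsonl --mode veridical --out model.json --show
eventmodels reconstruct --markers markers.jsonl --mode prioritized \
    --priority goal,location,person,object --out model.json

# query a stored model
eventmodels query --model model.json --assert "Bob during patrol"

# premise-based inference (one premise per line: "<label> <relation> <label>")
eventmodels infer --premises premises.txt --assert "shower before breakfast" --show

# end-to-end pipeline with a deterministic JSON report
eventmodels run --stream patrol.jsonl --query "Bob during patrol" --out report.json
```

Pipeline parameters (memory decay, spreading, priority order, mode,
depth/model bounds, strictness, seed) go in a YAML config passed via
`--config`; unknown keys are rejected.

Stream dialect (JSONL, one observation per line):

```json
{"t": 1.0, "ch": "goal", "entity": "patrol", "pol": "onset"}
```

## Layout

- `src/eventmodels/scenario.py` — fixtures, seeded random streams, JSONL/YAML I/O
- `src/eventmodels/segmentation.py` — change detection and marker encoding
- `src/eventmodels/memory.py` — activation decay, retrieval, spreading
- `src/eventmodels/event_model.py` — veridical/prioritized reconstruction, ordinals, partonomy, rendering
- `src/eventmodels/reasoning.py` — premise models, verdicts, counterfactual revision, exhaustive oracle
- `src/eventmodels/cli.py` — command-line surface and pipeline config
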