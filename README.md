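# cycleont

Attributes of cyclic physiological processes — rate, rhythm and
duration patterns of heart beating — computed from cycle-event series
and emitted as RDF instance graphs realising an ontology design pattern.

## The problem

Clinical language constantly qualifies *processes*: a heart beats
*fast*, *regularly*, *with paroxysmal atrial fibrillation*. Realist
upper ontologies (BFO and kin) have no "process quality" category —
qualities inhere in continuants, while processes *are* changes — so
such attributes must be defined through what a process is made of: its
repeated sub-processes (cycles), their durations, and how they compose
the whole. `cycleont` makes that design pattern executable for anyone
building or testing biomedical knowledge representations: given a
series of timestamped heart cycles (RR intervals, with optional cycle
typing), it computes fiat measurement windows, classifies the process
attributes, and materialises the result as RDF that the pattern's class
definitions can be evaluated against.

## The model

A beating process `q` is a contiguous sequence of cycles
`P = {p_1 … p_n}` (each `p_{k}` *follows* `p_{k-1}`; every process has
exactly one duration; a beating process has ≥ 2 cycles as granular
parts). On top of this structure:

- **Rate** — a fiat 60-second measuring window contains
  `N = |{p_k fully inside the window}|` grains; the process is *normal*
  for `60 ≤ N ≤ 100` (adult band), *slow* below, *fast* strictly above
  100. Bounds rescale linearly for other window durations.
- **Rhythm** — over ≥ 3 cycles, regular iff the coefficient of
  variation of durations `CV = s/d̄ ≤ 0.10` (configurable).
- **Patterns** — ideal accelerating / decelerating / even processes
  satisfy `dur(p_k) < dur(p_{k-1})` / `>` / `=` for every adjacent
  pair; tolerant variants allow a bounded fraction of violating pairs.
  The distance of a duration sequence to each ideal is the summed
  magnitude of violating increments:
  `accel = Σ max(0, d_k − d_{k−1})`, `decel = Σ max(0, d_{k−1} − d_k)`,
  `even = accel + decel`.
- **Bigeminy** — alternating short/long pairing with
  `short < 0.8 × long` over ≥ 3 consecutive pairs.
- **Atrial fibrillation** — from maximal typed runs: all-AF cycles ⇒
  chronic AF; ≥ 2 AF episodes (runs of ≥ 2 cycles) separated by ≥ 1
  sinus episode ⇒ paroxysmal AF.
- **Sudden onset** — a boundary instant where steady normal-rate
  beating is immediately followed by a tolerantly accelerating segment.

The RDF layer emits each classified sequence in two encodings — grain
counts as per-cycle `hasGranularPart` statements (*cardinality*) or as
one `hasNumberOfGrains` integer literal (*data_property*) — evaluates
the clinical class definitions (bradycardiac patient, tachycardic drug
effect, chronic/paroxysmal AF attributes, rate bands) by forward
chaining to fixpoint, and answers the competency question "which
diseases co-occur with some arrhythmia" in SPARQL.

## Worked example

Classify a simulated paroxysmal-AF recording (two AF episodes inside
sinus beating, ~71 s) and inspect the report:

```sh
$ cycleont classify --preset paroxysmal_af --seed 1 --out-report paf.json
3 attributes (IRREGULAR_RHYTHM, NORMAL_RATE, PAROXYSMAL_AF) -> paf.json
```

The report (abridged) shows one complete 60-second window holding 77
full cycles — inside the 60–100 normal band — whose durations vary too
much for a regular rhythm, and the whole-sequence AF episode structure:

```json
{
 "n_cycles": 90,
 "total_duration_s": 70.706,
 "windows": [{"index": 0, "start_s": 0.0, "duration_s": 60.0, "grain_count": 77}],
 "attributes": [
  {"label": "NORMAL_RATE",      "target": "window[0]@0s"},
  {"label": "IRREGULAR_RHYTHM", "target": "window[0]@0s"},
  {"label": "PAROXYSMAL_AF",    "target": "sequence"}
 ]
}
```

So: a normally *fast-enough* but *irregular* beating process whose run
structure qualifies as paroxysmal atrial fibrillation. Emit the same
recording as RDF and query it:

```sh
cycleont emit --preset paroxysmal_af --seed 1 --encoding data-property --out-ttl paf.ttl
cycleont query --ttl paf.ttl --sparql my_query.rq
```

The library surface mirrors the pipeline (`build_sequence`,
`tile_windows`, `attribute_profile`, `emit_graph`,
`classify_individuals`, `competency_query`); see the docstrings and
`docs/methods.md`.

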