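# Methods

## Model and assumptions

`cycleont` treats a beating process as a contiguous, onset-ordered
sequence of cycles that tile time: each cycle starts exactly where its
predecessor ends (tolerance 1e-9 s), carries exactly one positive
duration, and the *follows* relation is adjacency in this ordering.
Gaps in a recording are not representable implicitly; they must be
modelled as `OTHER`-typed filler cycles. This mirrors the view of the
beating process as homomereous, with cycles as its exhaustive grains.
A sequence qualifies as a beating process only with at least two
cycles; classification of shorter inputs is a validation error.

Time is seconds throughout. Abstract unitless duration lists (such as
the worked 16-cycle example) are accepted as abstract seconds; nothing
downstream depends on the unit label except the per-60-s rate band.

Cycle types (`SA_NODE`, `ATRIAL_FIBRILLATION`, `VENTRICULAR_ECTOPIC`,
`OTHER`) are input metadata. Deriving them from ECG waveforms is out of
scope by design.

## Fiat windows and grain counting

Measuring windows are half-open intervals `[start, start+d)`; a cycle
counts iff it lies wholly inside (full cycles only). Half-openness
makes abutting tumbling windows disjoint, so no cycle is counted
twice; a cycle straddling a boundary belongs to neither window.
Trailing spans shorter than the window duration produce no window: the
sixty-second beating process is defined by its exact duration, and a
45-second tail is not one. Containment and tiling comparisons tolerate
1e-9 s so that `k` cycles of `60/k` s survive float accumulation.
Sliding mode (step default 1 s) exists for boundary scanning; tumbling
is the default everywhere.

## Classifiers and their parameters

| parameter | default | unit | provenance |
|---|---|---|---|
| `normal_low` / `normal_high` | 60 / 100 | cycles per 60 s | adult clinical convention; band closed on both ends, fast starts at 101 |
| `even_tolerance` | 0 | relative | ideal evenness is exact equality |
| `rhythm_cv_threshold` | 0.10 | – | extrinsic; "similar intervals" is not quantified clinically |
| `violation_fraction` | 0.1 | – | extrinsic; tolerant patterns allow "a certain amount of exceptions" |
| `bigeminy_ratio` | 0.8 | – | extrinsic; short/long contrast |
| `bigeminy_min_pairs` | 3 | pairs | extrinsic |
| `min_rhythm_cycles` | 3 | cycles | rhythm is defined over three or more subsequent cycles |
| `af_min_run` | 2 | cycles | an episode (typed sub-beating) needs more than one grain |
| `onset_segment_s` | 10 | s | extrinsic; sudden-onset analysis granularity |

Rate thresholds rescale linearly with window duration (they are counts
per 60 s); only adult defaults ship, age stratification being a config
extension point. Rhythm CV uses the sample standard deviation
(ddof=1). Ties between adjacent durations falsify both strict ideals
while contributing zero to every distance — consistent with the strict
inequalities that define the ideals.

**Pattern distances.** The continuum between accelerating, even and
decelerating beating has to be divided by fiat. We use summed violation
*magnitudes* over adjacent pairs rather than violation *counts*:
magnitudes yield a strict closeness ordering on sequences (such as the
worked 16-cycle example, where counting ties) and give the metric the
exact identity `even = accel + decel`, reversal symmetry (reversing the
sequence swaps `accel` and `decel`), and linear scale equivariance —
all of which are property-tested.

**Bigeminy** scans both pair parities and both orientations for a
streak of ≥ `bigeminy_min_pairs` non-overlapping pairs with
`short < ratio × long`. At the permissive defaults, grossly irregular
(AF-like) duration series can occasionally satisfy the test by chance;
the AF classifiers, not bigeminy, are the discriminating signal for
such inputs.

**Sudden onset.** The defining configuration is steady normal-rate
beating whose end instant coincides with the start of an accelerating
segment. The literal reading — any NORMAL-rate segment followed by an
accelerating one — would also fire at every internal boundary of a
long acceleration ramp still inside the normal band, which contradicts
the intended "onset" (a transition, located at one instant). We
therefore additionally require the preceding segment *not* to be
tolerantly accelerating. Analysis segments are tumbling
`onset_segment_s` windows; rate thresholds rescale accordingly.

**AF patterns** operate on maximal same-type runs: all-AF ⇒ chronic;
≥ 2 AF episodes (`≥ af_min_run` cycles each) plus ≥ 1 sinus episode ⇒
paroxysmal. AF cycles present without qualifying episode structure
yield no attribute; `attribute_profile` records an "isolated ectopy"
note instead, because a bare `None` cannot carry parameters.

All classifiers are deterministic; randomness lives exclusively in the
simulator.

## RDF realisation

Instance graphs are emitted in a project namespace
(`https://w3id.org/cycleont/pattern#`); alignment of `hasGranularPart`
(collective→grain), `isAbout` (information artifact→subject) and the
clinical class names with upper-level ontologies is nominal, by label,
to avoid importing and re-serialising upstream ontologies.
`hasGranularPart` and `hasPart` are computed as the same parthood; both
are emitted (grain links in the cardinality encoding, plain parthood
structure always), since the pattern uses both for cycle⊑beating
parthood without distinguishing their extensions.

Both encodings emit: the sequence node, every cycle (typed by its cycle
class), multi-cycle typed runs, the measuring windows, exactly one
`hasDuration` decimal per process node, and attribute nodes linked by
the mutually inverse `hasProcessAttribute` / `isProcessAttributeOf`.
The encodings differ only in how grain counts are represented:
per-cycle `hasGranularPart` statements versus one `hasNumberOfGrains`
integer literal per cycle-bearing process node. Node IRIs are derived
from a content hash of the sequence, so emission is byte-stable across
runs. Length-1 runs stay plain cycles — a single cycle is not a beating
process.

**Rule inference.** Full OWL-DL classification over cardinality
restrictions is impractically slow at realistic cycle counts, so the
clinical class definitions are evaluated as a fixed forward-chaining
rule set over the instance graph: rate bands from grain counts
(reading the literal when present, else counting grain statements),
bradycardiac patient, tachycardic drug effect, typed sub-beatings
(all-one-type, > 1 grain), paroxysmal and chronic AF attributes. Rules
only add `rdf:type` statements, so chaining is monotone, idempotent,
insertion-order independent, and reaches fixpoint in at most
rules × nodes iterations. The rules use existential ("some") semantics
for the attribute linkage; the class definitions vary between "some"
and "only" at that position, and "some" is the reading under which
instance-level evaluation is well-defined. A consequence of the
chronic-AF equivalence ("an attribute of a beating process having only
AF cycles as parts") is that *every* attribute of an all-AF process —
including its rate attribute — is inferred to be a chronic-AF
attribute; this is the definition applied faithfully, not a bug.
Emitted graphs are plain RDF and can be handed to external OWL tooling
unchanged.

The competency query (diseases co-occurring with arrhythmia) ships as
a SPARQL resource; an explicit `rdfs:subClassOf Disease` constraint
pins the returned variable to disease classes. Clinical-finding
statements reuse `isAbout`, targeting either a process node (history
of tachyarrhythmia, normal conduction) or an attribute node (chronic
AF diagnosis).

## Synthetic data

The simulator generates the conditions each classifier assumes:

- steady sinus rhythm at 70 (normal), 45 (brady) and 120 (tachy)
  cycles/min over 120 s with 5 % lognormal duration CV — resting-scale
  variability;
- a constant 70/min minute (ideal evenness);
- a linear shortening trend 1.0 → 0.5 s over 20 cycles, 1 % CV
  (acceleration);
- bigeminal 0.5 s/1.0 s pairs (ectopic/sinus typed), 40 pairs, 2 % CV;
- all-AF beating at 90/min with 30 % CV (chronic AF, gross
  irregularity);
- sinus–AF–sinus–AF–sinus runs of 20/15/20/15/20 cycles (paroxysmal
  AF), 5 %/30 % CV per type;
- a decelerate-then-accelerate manoeuvre (Valsalva-style) for
  variability probing.

Jitter is lognormal multiplicative (durations stay positive; empirical
CV tracks the requested CV within sampling error). Counts are
`round(rate·T/60)`. Zero-noise variants zero every CV.

What passing recovery tests shows: each classifier recovers the label
its preset was constructed to exhibit, under idealised noise. What it
does not show: performance on real RR series, whose non-stationarity,
respiratory modulation, artefacts and beat-detection errors the
generator does not emulate, and whose cycle types would come from an
upstream annotator rather than ground truth.

## Problem sizes

The default test and acceptance runs use sequences of 20–300 cycles,
boundary sweeps over 0–200 cycles per window, 50 seeds per preset at
zero noise and 200 at stated noise, and toy graphs of tens of nodes —
sizes at which every check, including the brute-force oracles, is
exact and the whole suite completes in seconds.

## Known limitations

- Thresholds flagged *extrinsic* above are engineering defaults, not
  clinically validated cut-offs; the config file records provenance for
  every value used.
- No heart-rate-variability measures (SDNN, RMSSD, spectral indices);
  rhythm regularity is CV-only.
- The rule engine implements exactly the shipped class definitions; it
  is not a general OWL reasoner, and cardinality semantics beyond grain
  counting (e.g. qualified maximums) are not interpreted.
- Bigeminy detection at default thresholds is sensitive under gross
  irregularity (see above).
- CSV input is trusted for typing; no morphology-based verification.
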