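"""RDF realisation of the process-attribute design pattern.

Emits instance graphs for classified cycle sequences in the two
encodings the pattern supports — per-grain parthood statements
(*cardinality*) versus an integer grain-count literal (*data_property*)
— evaluates the clinical class definitions as forward-chaining rules
over the graph, and answers the competency query for diseases
co-occurring with arrhythmia.

Full description-logic reasoning is deliberately replaced by a fixed
rule set implementing exactly the existential path patterns the class
definitions use: counting grains through OWL cardinality restrictions is
known to be impractically slow for realistic cycle counts, while the
rule evaluation here is linear in the graph.  The emitted graphs remain
plain RDF and can be exported to external OWL tooling unchanged.

Class and property IRIs are minted in a project namespace; alignment
with upper-level ontologies (the grain parthood of collectives, the
information-artifact "is about" relation) is nominal, by label.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from importlib import resources
from typing import Callable, Iterable, Optional, Sequence

from rdflib import Graph, Literal, Namespace, RDF, RDFS, OWL, URIRef, XSD

from .attributes import AttributeLabel, ProcessAttribute
from .model import CycleSequence, CycleType, RunSegment, ValidationError, segment_runs
from .windows import MeasuringWindow

DEFAULT_NAMESPACE = "https://w3id.org/cycleont/pattern#"
DEFAULT_INSTANCE_NAMESPACE = "https://w3id.org/cycleont/instance/"

#: Ontology class name per classified attribute label.
ATTRIBUTE_CLASSES: dict[AttributeLabel, str] = {
    AttributeLabel.SLOW_RATE: "SlowHeartRate",
    AttributeLabel.NORMAL_RATE: "NormalHeartRate",
    AttributeLabel.FAST_RATE: "FastHeartRate",
    AttributeLabel.REGULAR_RHYTHM: "InvariantHeartCyclePeriod",
    AttributeLabel.IRREGULAR_RHYTHM: "ArrhythmicHeartRate",
    AttributeLabel.IDEAL_ACCELERATING: "IdealAcceleratingHeartBeating",
    AttributeLabel.IDEAL_DECELERATING: "IdealDeceleratingHeartBeating",
    AttributeLabel.IDEAL_EVEN: "IdealEvenHeartBeating",
    AttributeLabel.TOLERANT_ACCELERATING: "AcceleratingHeartBeating",
    AttributeLabel.TOLERANT_DECELERATING: "DeceleratingHeartBeating",
    AttributeLabel.BIGEMINAL: "BigeminalRhythm",
    AttributeLabel.CHRONIC_AF: "ChronicAtrialFibrillationAttribute",
    AttributeLabel.PAROXYSMAL_AF: "IntermittentAtrialFibrillationAttribute",
    AttributeLabel.SUDDEN_ONSET: "SuddenOnsetAttribute",
}

#: Rate labels additionally typed as frequency attributes.
_FREQUENCY_LABELS = {
    AttributeLabel.SLOW_RATE,
    AttributeLabel.NORMAL_RATE,
    AttributeLabel.FAST_RATE,
}

CYCLE_CLASSES: dict[CycleType, str] = {
    CycleType.SA_NODE: "SANodeStartedHeartCycle",
    CycleType.ATRIAL_FIBRILLATION: "AtrialFibrillationCycle",
    CycleType.VENTRICULAR_ECTOPIC: "VentricularEctopicCycle",
    CycleType.OTHER: "OtherHeartCycle",
}

_CLASS_NAMES = (
    "HeartBeatingProcess",
    "HeartCycle",
    "SixtySecondTemporalInterval",
    "SixtySecondHeartBeatingProcess",
    "HeartCycleFrequencyAttribute",
    "ProcessAttribute",
    "Human",
    "Heart",
    "Disease",
    "Drug",
    "DrugFunction",
    "TherapeuticMedicationAdministration",
    "ClinicalFinding",
    "AtrialFibrillationHeartBeating",
    "SANodeHeartBeating",
    "BradycardiacPatient",
    "TachycardicEffect",
) + tuple(ATTRIBUTE_CLASSES.values()) + tuple(CYCLE_CLASSES.values())

_OBJECT_PROPERTIES = (
    "hasGranularPart",
    "hasPart",
    "hasProcessAttribute",
    "isProcessAttributeOf",
    "participatesIn",
    "inheresIn",
    "precedes",
    "isAbout",
)

_DATA_PROPERTIES = ("hasDuration", "hasNumberOfGrains")


@dataclass(frozen=True)
class PatternVocabulary:
    """The minted terms of the pattern: one namespace, fixed names."""

    namespace: str = DEFAULT_NAMESPACE
    instance_namespace: str = DEFAULT_INSTANCE_NAMESPACE

    @property
    def ns(self) -> Namespace:
        return Namespace(self.namespace)

    @property
    def inst(self) -> Namespace:
        return Namespace(self.instance_namespace)

    def term(self, name: str) -> URIRef:
        if name not in _CLASS_NAMES + _OBJECT_PROPERTIES + _DATA_PROPERTIES:
            raise ValidationError(f"term {name!r} is not declared in the vocabulary")
        return self.ns[name]

    def declare(self, graph: Graph) -> None:
        """Declare every class/property and the attribute-link inverse pair."""
        for name in _CLASS_NAMES:
            graph.add((self.ns[name], RDF.type, OWL.Class))
        for name in _OBJECT_PROPERTIES:
            graph.add((self.ns[name], RDF.type, OWL.ObjectProperty))
        for name in _DATA_PROPERTIES:
            graph.add((self.ns[name], RDF.type, OWL.DatatypeProperty))
        graph.add(
            (self.ns["hasProcessAttribute"], OWL.inverseOf, self.ns["isProcessAttributeOf"])
        )
        graph.add(
            (self.ns["isProcessAttributeOf"], OWL.inverseOf, self.ns["hasProcessAttribute"])
        )


DEFAULT_VOCAB = PatternVocabulary()

ENCODINGS = ("cardinality", "data_property")


def _sequence_id(seq: CycleSequence) -> str:
    h = hashlib.sha1()
    h.update(f"{seq.start:.9f}".encode())
    for ev in seq.events:
        h.update(f"|{ev.duration:.9f}:{ev.cycle_type.value}".encode())
    return h.hexdigest()[:12]


def _new_graph(vocab: PatternVocabulary) -> Graph:
    g = Graph()
    g.bind("cp", vocab.ns)
    g.bind("inst", vocab.inst)
    g.bind("owl", OWL)
    return g


def _attr_target_node(
    attr: ProcessAttribute,
    seq_node: URIRef,
    window_nodes: Sequence[URIRef],
) -> URIRef:
    target = attr.target
    if target.startswith("window["):
        idx = int(target[len("window[") : target.index("]")])
        try:
            return window_nodes[idx]
        except IndexError:
            raise ValidationError(f"attribute targets unknown window: {target}")
    return seq_node  # sequence-level and boundary attributes describe the whole


def emit_graph(
    seq: CycleSequence,
    windows: Sequence[MeasuringWindow],
    attributes: Sequence[ProcessAttribute],
    encoding: str = "data_property",
    vocab: PatternVocabulary = DEFAULT_VOCAB,
) -> Graph:
    """Emit the instance graph realising the pattern for *seq*.

    Both encodings emit the full part structure (sequence, typed runs,
    windows, cycles, all linked by ``hasPart``) and exactly one
    ``hasDuration`` literal per process node.  The *cardinality* encoding
    additionally mirrors every process-to-cycle link as
    ``hasGranularPart``; the *data_property* encoding instead attaches a
    single ``hasNumberOfGrains`` integer literal to each cycle-bearing
    process node.  Node IRIs are content-derived, so emission is
    byte-stable across runs.
    """
    if encoding not in ENCODINGS:
        raise ValidationError(f"unknown encoding {encoding!r}; choose from {ENCODINGS}")
    for attr in attributes:
        if attr.label not in ATTRIBUTE_CLASSES:
            raise ValidationError(f"unknown attribute label {attr.label!r}")

    cp, inst = vocab.ns, vocab.inst
    g = _new_graph(vocab)
    vocab.declare(g)
    sid = _sequence_id(seq)

    seq_node = inst[f"seq-{sid}"]
    g.add((seq_node, RDF.type, cp.HeartBeatingProcess))
    g.add((seq_node, cp.hasDuration, Literal(round(seq.total_duration, 9), datatype=XSD.decimal)))

    cycle_nodes: list[URIRef] = []
    for k, ev in enumerate(seq.events):
        c = inst[f"seq-{sid}-cycle-{k}"]
        cycle_nodes.append(c)
        g.add((c, RDF.type, cp.HeartCycle))
        g.add((c, RDF.type, cp[CYCLE_CLASSES[ev.cycle_type]]))
        g.add((c, cp.hasDuration, Literal(round(ev.duration, 9), datatype=XSD.decimal)))
        g.add((seq_node, cp.hasPart, c))

    def emit_grains(node: URIRef, members: Iterable[int]) -> None:
        members = list(members)
        if encoding == "cardinality":
            for k in members:
                g.add((node, cp.hasGranularPart, cycle_nodes[k]))
        else:
            g.add(
                (node, cp.hasNumberOfGrains, Literal(len(members), datatype=XSD.integer))
            )

    emit_grains(seq_node, range(len(seq)))

    # Typed runs: sub-beating episodes.  A single cycle is not a beating
    # process, so length-1 runs stay plain cycles.
    if len(seq) > 0:
        for run in segment_runs(seq):
            if run.length < 2:
                continue
            r = inst[f"seq-{sid}-run-{run.start_index}"]
            members = range(run.start_index, run.start_index + run.length)
            run_dur = sum(seq.events[k].duration for k in members)
            g.add((r, RDF.type, cp.HeartBeatingProcess))
            g.add((r, cp.hasDuration, Literal(round(run_dur, 9), datatype=XSD.decimal)))
            g.add((seq_node, cp.hasPart, r))
            for k in members:
                g.add((r, cp.hasPart, cycle_nodes[k]))
            emit_grains(r, members)

    window_nodes: list[URIRef] = []
    for w in windows:
        wn = inst[f"seq-{sid}-window-{w.start:g}"]
        window_nodes.append(wn)
        g.add((wn, RDF.type, cp.HeartBeatingProcess))
        if w.duration == 60.0:
            g.add((wn, RDF.type, cp.SixtySecondHeartBeatingProcess))
        g.add((wn, cp.hasDuration, Literal(round(w.duration, 9), datatype=XSD.decimal)))
        g.add((seq_node, cp.hasPart, wn))
        for k in w.contained_cycle_indices:
            g.add((wn, cp.hasPart, cycle_nodes[k]))
        emit_grains(wn, w.contained_cycle_indices)

    for i, attr in enumerate(attributes):
        target = _attr_target_node(attr, seq_node, window_nodes)
        a = inst[f"seq-{sid}-attr-{i}-{attr.label.value.lower()}"]
        g.add((a, RDF.type, cp.ProcessAttribute))
        g.add((a, RDF.type, cp[ATTRIBUTE_CLASSES[attr.label]]))
        if attr.label in _FREQUENCY_LABELS:
            g.add((a, RDF.type, cp.HeartCycleFrequencyAttribute))
        if attr.label is AttributeLabel.IDEAL_ACCELERATING:
            g.add((a, RDF.type, cp.AcceleratingHeartBeating))
        if attr.label is AttributeLabel.IDEAL_DECELERATING:
            g.add((a, RDF.type, cp.DeceleratingHeartBeating))
        g.add((target, cp.hasProcessAttribute, a))
        g.add((a, cp.isProcessAttributeOf, target))
    return g


def write_turtle(graph: Graph, path) -> None:
    graph.serialize(destination=str(path), format="turtle")


def read_turtle(path) -> Graph:
    """Parse a Turtle file; parse failures surface with line information."""
    g = Graph()
    try:
        g.parse(str(path), format="turtle")
    except Exception as exc:  # rdflib BadSyntax carries the line number
        raise ValidationError(f"Turtle parse error in {path}: {exc}") from exc
    return g


# ---------------------------------------------------------------------------
# Forward-chaining rules for the clinical class definitions
# ---------------------------------------------------------------------------


def _grain_count(g: Graph, vocab: PatternVocabulary, node) -> Optional[int]:
    """Grain count of a process node under either encoding."""
    for lit in g.objects(node, vocab.ns.hasNumberOfGrains):
        return int(lit)
    grains = set(g.objects(node, vocab.ns.hasGranularPart))
    if grains:
        return len(grains)
    cycles = [
        o
        for o in g.objects(node, vocab.ns.hasPart)
        if (o, RDF.type, vocab.ns.HeartCycle) in g
    ]
    return len(cycles) if cycles else None


def _cycle_parts(g: Graph, vocab: PatternVocabulary, node) -> list:
    cp = vocab.ns
    parts = set(g.objects(node, cp.hasPart)) | set(g.objects(node, cp.hasGranularPart))
    return [o for o in parts if (o, RDF.type, cp.HeartCycle) in g]


def _rule_rate_bands(g: Graph, vocab: PatternVocabulary):
    """Frequency attributes of sixty-second windows: normal on the
    60..100 grain band, fast strictly above 100."""
    cp = vocab.ns
    out = []
    for attr in g.subjects(RDF.type, cp.HeartCycleFrequencyAttribute):
        for proc in g.objects(attr, cp.isProcessAttributeOf):
            if (proc, RDF.type, cp.SixtySecondHeartBeatingProcess) not in g:
                continue
            n = _grain_count(g, vocab, proc)
            if n is None:
                continue
            if 60 <= n <= 100:
                out.append((attr, RDF.type, cp.NormalHeartRate))
            elif n > 100:
                out.append((attr, RDF.type, cp.FastHeartRate))
    return out


def _rule_bradycardiac_patient(g: Graph, vocab: PatternVocabulary):
    """Human with a heart participating in a beating process bearing a
    slow-rate attribute."""
    cp = vocab.ns
    out = []
    for human in g.subjects(RDF.type, cp.Human):
        for heart in g.objects(human, cp.hasPart):
            if (heart, RDF.type, cp.Heart) not in g:
                continue
            for beating in g.objects(heart, cp.participatesIn):
                if (beating, RDF.type, cp.HeartBeatingProcess) not in g:
                    continue
                for attr in g.objects(beating, cp.hasProcessAttribute):
                    if (attr, RDF.type, cp.SlowHeartRate) in g:
                        out.append((human, RDF.type, cp.BradycardiacPatient))
    return out


def _rule_tachycardic_effect(g: Graph, vocab: PatternVocabulary):
    """Drug function whose drug participates in an administration that
    precedes an accelerating beating process."""
    cp = vocab.ns
    out = []
    for fn in g.subjects(RDF.type, cp.DrugFunction):
        for drug in g.objects(fn, cp.inheresIn):
            if (drug, RDF.type, cp.Drug) not in g:
                continue
            for adm in g.objects(drug, cp.participatesIn):
                if (adm, RDF.type, cp.TherapeuticMedicationAdministration) not in g:
                    continue
                for beating in g.objects(adm, cp.precedes):
                    if (beating, RDF.type, cp.HeartBeatingProcess) not in g:
                        continue
                    for attr in g.objects(beating, cp.hasProcessAttribute):
                        if (attr, RDF.type, cp.AcceleratingHeartBeating) in g:
                            out.append((fn, RDF.type, cp.TachycardicEffect))
    return out


def _typed_beating_rule(cycle_class: str, beating_class: str):
    """Beating process whose cycle parts are all of one type (and more
    than one grain) is a typed sub-beating."""

    def rule(g: Graph, vocab: PatternVocabulary):
        cp = vocab.ns
        out = []
        for proc in g.subjects(RDF.type, cp.HeartBeatingProcess):
            cycles = _cycle_parts(g, vocab, proc)
            if not cycles:
                continue
            if not all((c, RDF.type, cp[cycle_class]) in g for c in cycles):
                continue
            n = _grain_count(g, vocab, proc)
            if n is not None and n > 1:
                out.append((proc, RDF.type, cp[beating_class]))
        return out

    return rule


def _rule_paroxysmal_af(g: Graph, vocab: PatternVocabulary):
    """Attribute of a process with >= 2 AF sub-beatings and >= 1 sinus
    sub-beating as parts."""
    cp = vocab.ns
    out = []
    for attr, proc in g.subject_objects(cp.isProcessAttributeOf):
        parts = set(g.objects(proc, cp.hasPart))
        n_af = sum(
            1 for p in parts if (p, RDF.type, cp.AtrialFibrillationHeartBeating) in g
        )
        n_sa = sum(1 for p in parts if (p, RDF.type, cp.SANodeHeartBeating) in g)
        if n_af >= 2 and n_sa >= 1:
            out.append((attr, RDF.type, cp.IntermittentAtrialFibrillationAttribute))
    return out


def _rule_chronic_af(g: Graph, vocab: PatternVocabulary):
    """Attribute of a beating process whose parts are only AF cycles."""
    cp = vocab.ns
    out = []
    for attr, proc in g.subject_objects(cp.isProcessAttributeOf):
        if (proc, RDF.type, cp.HeartBeatingProcess) not in g:
            continue
        cycles = _cycle_parts(g, vocab, proc)
        if not cycles:
            continue
        if all((c, RDF.type, cp.AtrialFibrillationCycle) in g for c in cycles):
            out.append((attr, RDF.type, cp.ChronicAtrialFibrillationAttribute))
    return out


DEFAULT_RULES: tuple[tuple[str, Callable], ...] = (
    ("rate_bands", _rule_rate_bands),
    ("bradycardiac_patient", _rule_bradycardiac_patient),
    ("tachycardic_effect", _rule_tachycardic_effect),
    (
        "af_beating",
        _typed_beating_rule("AtrialFibrillationCycle", "AtrialFibrillationHeartBeating"),
    ),
    (
        "sa_beating",
        _typed_beating_rule("SANodeStartedHeartCycle", "SANodeHeartBeating"),
    ),
    ("paroxysmal_af", _rule_paroxysmal_af),
    ("chronic_af", _rule_chronic_af),
)


def classify_individuals(
    graph: Graph,
    rule_set: Sequence[tuple[str, Callable]] = DEFAULT_RULES,
    vocab: PatternVocabulary = DEFAULT_VOCAB,
) -> Graph:
    """Forward-chain the rule set to fixpoint over a copy of *graph*.

    Rules only ever add ``rdf:type`` statements, so inference is monotone
    and idempotent; the fixpoint is reached in at most rules x nodes
    iterations and is independent of statement insertion order.
    """
    g = _new_graph(vocab)
    for triple in graph:
        g.add(triple)
    changed = True
    while changed:
        changed = False
        for _name, rule in rule_set:
            for triple in rule(g, vocab):
                if triple not in g:
                    g.add(triple)
                    changed = True
    return g


# ---------------------------------------------------------------------------
# Competency query and findings
# ---------------------------------------------------------------------------

_QUERY_IDS = ("2c",)


def competency_query_text(
    question_id: str = "2c", vocab: PatternVocabulary = DEFAULT_VOCAB
) -> str:
    """SPARQL text for a competency question, in the vocab's namespace."""
    if question_id not in _QUERY_IDS:
        raise ValidationError(
            f"unknown competency question {question_id!r}; known: {_QUERY_IDS}"
        )
    text = (
        resources.files("cycleont.queries")
        .joinpath("diseases_with_arrhythmia.rq")
        .read_text()
    )
    return text.replace(DEFAULT_NAMESPACE, vocab.namespace)


def competency_query(
    graph: Graph,
    question_id: str = "2c",
    vocab: PatternVocabulary = DEFAULT_VOCAB,
) -> list[tuple]:
    """Run a competency question; for ``"2c"``, the distinct disease
    classes whose instances inhere in a human whose heart participates in
    a beating process bearing an arrhythmic attribute."""
    result = graph.query(competency_query_text(question_id, vocab))
    return sorted(tuple(row) for row in result)


def emit_finding(
    graph: Graph,
    about,
    finding_label: str,
    vocab: PatternVocabulary = DEFAULT_VOCAB,
) -> URIRef:
    """Add a clinical-finding node linked to *about* via ``isAbout``.

    *about* may be a process node or an attribute node (a chronic-AF
    diagnosis is about the attribute itself).  The target must already
    occur in the graph.
    """
    about = URIRef(about) if not isinstance(about, URIRef) else about
    present = any(True for _ in graph.predicate_objects(about)) or any(
        True for _ in graph.subject_predicates(about)
    )
    if not present:
        raise ValidationError(f"finding target {about} is not in the graph")
    digest = hashlib.sha1(f"{about}|{finding_label}".encode()).hexdigest()[:12]
    node = vocab.inst[f"finding-{digest}"]
    graph.add((node, RDF.type, vocab.ns.ClinicalFinding))
    graph.add((node, RDFS.label, Literal(finding_label)))
    graph.add((node, vocab.ns.isAbout, about))
    return node


# ---------------------------------------------------------------------------
# Toy clinical fixtures (synthetic, hand-wired; used in tests and demos)
# ---------------------------------------------------------------------------


def fixture_bradycardia(
    slow: bool = True, vocab: PatternVocabulary = DEFAULT_VOCAB
) -> Graph:
    """Synthetic patient fixture: human -> heart -> beating process; the
    beating carries a slow-rate attribute iff *slow*."""
    cp, inst = vocab.ns, vocab.inst
    g = _new_graph(vocab)
    g.add((inst["pat-1"], RDF.type, cp.Human))
    g.add((inst["pat-1"], cp.hasPart, inst["heart-1"]))
    g.add((inst["heart-1"], RDF.type, cp.Heart))
    g.add((inst["heart-1"], cp.participatesIn, inst["beating-1"]))
    g.add((inst["beating-1"], RDF.type, cp.HeartBeatingProcess))
    if slow:
        g.add((inst["beating-1"], cp.hasProcessAttribute, inst["attr-slow"]))
        g.add((inst["attr-slow"], cp.isProcessAttributeOf, inst["beating-1"]))
        g.add((inst["attr-slow"], RDF.type, cp.SlowHeartRate))
    return g


def fixture_drug_effect(
    accelerating: bool = True, vocab: PatternVocabulary = DEFAULT_VOCAB
) -> Graph:
    """Synthetic drug fixture: drug function -> drug -> administration
    preceding a beating process, accelerating iff requested."""
    cp, inst = vocab.ns, vocab.inst
    g = _new_graph(vocab)
    g.add((inst["fn-1"], RDF.type, cp.DrugFunction))
    g.add((inst["fn-1"], cp.inheresIn, inst["drug-1"]))
    g.add((inst["drug-1"], RDF.type, cp.Drug))
    g.add((inst["drug-1"], cp.participatesIn, inst["adm-1"]))
    g.add((inst["adm-1"], RDF.type, cp.TherapeuticMedicationAdministration))
    g.add((inst["adm-1"], cp.precedes, inst["beating-2"]))
    g.add((inst["beating-2"], RDF.type, cp.HeartBeatingProcess))
    g.add((inst["beating-2"], cp.hasProcessAttribute, inst["attr-accel"]))
    g.add((inst["attr-accel"], cp.isProcessAttributeOf, inst["beating-2"]))
    if accelerating:
        g.add((inst["attr-accel"], RDF.type, cp.AcceleratingHeartBeating))
    return g


def fixture_disease_query(
    arrhythmic: bool = True, vocab: PatternVocabulary = DEFAULT_VOCAB
) -> Graph:
    """Synthetic two-patient fixture for the disease/arrhythmia query.

    Two disease instances of two disease classes; only the first patient's
    beating process carries an arrhythmic attribute (when *arrhythmic*),
    so the query must return exactly that one disease class.
    """
    cp, inst = vocab.ns, vocab.inst
    g = _new_graph(vocab)
    g.add((cp.AtrialFibrillationDx, RDFS.subClassOf, cp.Disease))
    g.add((cp.HypertensionDx, RDFS.subClassOf, cp.Disease))

    g.add((inst["dx-1"], RDF.type, cp.AtrialFibrillationDx))
    g.add((inst["dx-1"], cp.inheresIn, inst["human-1"]))
    g.add((inst["human-1"], RDF.type, cp.Human))
    g.add((inst["human-1"], cp.hasPart, inst["heart-a"]))
    g.add((inst["heart-a"], RDF.type, cp.Heart))
    g.add((inst["heart-a"], cp.participatesIn, inst["beating-a"]))
    g.add((inst["beating-a"], RDF.type, cp.HeartBeatingProcess))
    g.add((inst["beating-a"], cp.hasProcessAttribute, inst["attr-a"]))
    g.add((inst["attr-a"], cp.isProcessAttributeOf, inst["beating-a"]))
    if arrhythmic:
        g.add((inst["attr-a"], RDF.type, cp.ArrhythmicHeartRate))
    else:
        g.add((inst["attr-a"], RDF.type, cp.InvariantHeartCyclePeriod))

    g.add((inst["dx-2"], RDF.type, cp.HypertensionDx))
    g.add((inst["dx-2"], cp.inheresIn, inst["human-2"]))
    g.add((inst["human-2"], RDF.type, cp.Human))
    g.add((inst["human-2"], cp.hasPart, inst["heart-b"]))
    g.add((inst["heart-b"], RDF.type, cp.Heart))
    g.add((inst["heart-b"], cp.participatesIn, inst["beating-b"]))
    g.add((inst["beating-b"], RDF.type, cp.HeartBeatingProcess))
    g.add((inst["beating-b"], cp.hasProcessAttribute, inst["attr-b"]))
    g.add((inst["attr-b"], cp.isProcessAttributeOf, inst["beating-b"]))
    g.add((inst["attr-b"], RDF.type, cp.InvariantHeartCyclePeriod))
    return g
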