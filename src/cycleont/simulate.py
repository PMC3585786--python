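"""Seeded synthetic cycle-sequence generator.

Emulates RR-interval series with the statistical structure each
classifier assumes: steady rates with multiplicative jitter, monotone
duration trends (acceleration/deceleration), alternating short/long
bigeminal pairing, high-variability atrial-fibrillation cycles, typed
episode runs, and a decelerate-then-accelerate variability manoeuvre
(Valsalva-style).

Jitter is lognormal (multiplicative) so durations stay strictly
positive; the lognormal shape parameter is chosen so the multiplier has
unit mean and the requested coefficient of variation.  Cycle counts are
``round(rate x T / 60)``; residual time beyond the last whole cycle is
simply not generated, consistent with the fiat-window policy of dropping
incomplete trailing spans.

All generation is driven by :func:`numpy.random.default_rng` under the
preset's seed: identical seed and parameters give identical sequences.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Mapping

import numpy as np

from .attributes import AttributeLabel, AttributeProfile
from .model import CycleSequence, CycleType, build_sequence

KINDS = (
    "constant",
    "jittered",
    "trend",
    "bigeminal",
    "chronic_af",
    "intermittent_af",
    "valsalva",
)


@dataclass(frozen=True)
class SimPreset:
    """A named generator configuration: kind, parameters and seed."""

    name: str
    kind: str
    params: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown simulator kind {self.kind!r}")


def _lognormal_jitter(rng: np.random.Generator, cv: float, n: int) -> np.ndarray:
    """Unit-mean multiplicative jitter with coefficient of variation *cv*."""
    if cv < 0:
        raise ValueError(f"jitter cv must be >= 0, got {cv}")
    if cv == 0 or n == 0:
        return np.ones(n)
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(mean=-(sigma**2) / 2.0, sigma=sigma, size=n)


def _n_cycles(rate_bpm: float, total_s: float) -> int:
    if rate_bpm <= 0:
        raise ValueError(f"rate must be positive, got {rate_bpm}")
    if total_s <= 0:
        raise ValueError(f"total duration must be positive, got {total_s}")
    return int(round(rate_bpm * total_s / 60.0))


def _gen_constant(rng, p):
    n = _n_cycles(p["rate_bpm"], p["total_s"])
    base = 60.0 / p["rate_bpm"]
    return [base] * n, None


def _gen_jittered(rng, p):
    n = _n_cycles(p["rate_bpm"], p["total_s"])
    base = 60.0 / p["rate_bpm"]
    durs = base * _lognormal_jitter(rng, p.get("cv", 0.0), n)
    ct = CycleType(p.get("cycle_type", "SA_NODE"))
    return list(durs), [ct] * n


def _gen_trend(rng, p):
    n = int(p["n"])
    if n < 2:
        raise ValueError("trend needs at least 2 cycles")
    base = np.linspace(p["start_dur"], p["end_dur"], n)
    if np.any(base <= 0):
        raise ValueError("trend durations must stay positive")
    durs = base * _lognormal_jitter(rng, p.get("cv", 0.0), n)
    return list(durs), None


def _gen_bigeminal(rng, p):
    n_pairs = int(p["n_pairs"])
    short, long = float(p["short_s"]), float(p["long_s"])
    if not 0 < short < long:
        raise ValueError("bigeminal needs 0 < short_s < long_s")
    base = np.array([short, long] * n_pairs)
    types = [CycleType.VENTRICULAR_ECTOPIC, CycleType.SA_NODE] * n_pairs
    durs = base * _lognormal_jitter(rng, p.get("cv", 0.0), 2 * n_pairs)
    return list(durs), types


def _gen_chronic_af(rng, p):
    durs, _ = _gen_jittered(rng, {**p, "cycle_type": "SA_NODE"})
    return durs, [CycleType.ATRIAL_FIBRILLATION] * len(durs)


def _gen_intermittent_af(rng, p):
    durs: list[float] = []
    types: list[CycleType] = []
    for type_name, length in p["run_spec"]:
        ct = CycleType(type_name)
        if ct is CycleType.ATRIAL_FIBRILLATION:
            base, cv = 60.0 / p.get("af_rate_bpm", 90.0), p.get("af_cv", 0.0)
        else:
            base, cv = 60.0 / p.get("sa_rate_bpm", 70.0), p.get("sa_cv", 0.0)
        durs.extend(base * _lognormal_jitter(rng, cv, int(length)))
        types.extend([ct] * int(length))
    return durs, types


def _gen_valsalva(rng, p):
    """Deceleration phase (durations lengthen) then acceleration back."""
    base, peak = float(p["base_dur"]), float(p["base_dur"]) * float(p["peak_factor"])
    n_down, n_up = int(p["n_down"]), int(p["n_up"])
    up_phase = np.linspace(base, peak, n_down)          # slowing: durations grow
    down_phase = np.linspace(peak, base, n_up + 1)[1:]  # speeding back up
    seq = np.concatenate([up_phase, down_phase])
    durs = seq * _lognormal_jitter(rng, p.get("cv", 0.0), len(seq))
    return list(durs), None


_GENERATORS: Mapping[str, Callable] = {
    "constant": _gen_constant,
    "jittered": _gen_jittered,
    "trend": _gen_trend,
    "bigeminal": _gen_bigeminal,
    "chronic_af": _gen_chronic_af,
    "intermittent_af": _gen_intermittent_af,
    "valsalva": _gen_valsalva,
}


def simulate(preset: SimPreset, start: float = 0.0) -> CycleSequence:
    """Generate the cycle sequence a preset describes (deterministically)."""
    rng = np.random.default_rng(preset.seed)
    durs, types = _GENERATORS[preset.kind](rng, preset.params)
    return build_sequence(durs, types=types, start=start)


# ---------------------------------------------------------------------------
# Named presets: the study conditions each classifier is exercised under.
# ---------------------------------------------------------------------------

#: Parameter templates by preset name.  Noise levels are the stated study
#: conditions: 5% duration CV for steady sinus rhythm (normal resting HRV
#: scale), 30% for atrial fibrillation (grossly irregular), 1-2% on
#: structured patterns where the structure itself is the signal.
PRESET_TEMPLATES: dict[str, tuple[str, dict]] = {
    "normal": ("jittered", {"rate_bpm": 70, "total_s": 120, "cv": 0.05}),
    "brady": ("jittered", {"rate_bpm": 45, "total_s": 120, "cv": 0.05}),
    "tachy": ("jittered", {"rate_bpm": 120, "total_s": 120, "cv": 0.05}),
    "even": ("constant", {"rate_bpm": 70, "total_s": 60}),
    "accelerating": ("trend", {"start_dur": 1.0, "end_dur": 0.5, "n": 20, "cv": 0.01}),
    "bigeminal": ("bigeminal", {"short_s": 0.5, "long_s": 1.0, "n_pairs": 40, "cv": 0.02}),
    "chronic_af": ("chronic_af", {"rate_bpm": 90, "total_s": 120, "cv": 0.30}),
    "paroxysmal_af": (
        "intermittent_af",
        {
            "run_spec": [
                ("SA_NODE", 20),
                ("ATRIAL_FIBRILLATION", 15),
                ("SA_NODE", 20),
                ("ATRIAL_FIBRILLATION", 15),
                ("SA_NODE", 20),
            ],
            "sa_rate_bpm": 70,
            "af_rate_bpm": 90,
            "sa_cv": 0.05,
            "af_cv": 0.30,
        },
    ),
    "valsalva": (
        "valsalva",
        {"base_dur": 60 / 70, "peak_factor": 1.4, "n_down": 15, "n_up": 15, "cv": 0.0},
    ),
}

_NOISE_KEYS = ("cv", "sa_cv", "af_cv")


def preset(name: str, seed: int = 0, noise: bool = True) -> SimPreset:
    """Build a named preset; ``noise=False`` zeroes every jitter CV."""
    if name not in PRESET_TEMPLATES:
        raise ValueError(
            f"unknown preset {name!r}; choose from {sorted(PRESET_TEMPLATES)}"
        )
    kind, params = PRESET_TEMPLATES[name]
    params = dict(params)
    if not noise:
        for key in _NOISE_KEYS:
            if key in params:
                params[key] = 0.0
    return SimPreset(name=name, kind=kind, params=params, seed=seed)


#: The attribute each preset is constructed to exhibit; recovery means the
#: profile contains one of these labels (and, for rate presets, no
#: contradictory rate label in any window).
_RATE_LABELS = {
    AttributeLabel.SLOW_RATE,
    AttributeLabel.NORMAL_RATE,
    AttributeLabel.FAST_RATE,
}

INTENDED_LABELS: dict[str, set[AttributeLabel]] = {
    "normal": {AttributeLabel.NORMAL_RATE},
    "brady": {AttributeLabel.SLOW_RATE},
    "tachy": {AttributeLabel.FAST_RATE},
    "even": {AttributeLabel.IDEAL_EVEN},
    "accelerating": {
        AttributeLabel.IDEAL_ACCELERATING,
        AttributeLabel.TOLERANT_ACCELERATING,
    },
    "bigeminal": {AttributeLabel.BIGEMINAL},
    "chronic_af": {AttributeLabel.CHRONIC_AF},
    "paroxysmal_af": {AttributeLabel.PAROXYSMAL_AF},
}


def intended_recovered(name: str, profile: AttributeProfile) -> bool:
    """Did the attribute profile recover the preset's intended label?

    For the rate presets the recovered rate must also be unanimous across
    windows (a single contradictory window counts as a miss).
    """
    intended = INTENDED_LABELS[name]
    labels = {a.label for a in profile.attributes}
    if not intended & labels:
        return False
    if intended & _RATE_LABELS:
        stray = (labels & _RATE_LABELS) - intended
        return not stray
    return True
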