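"""Core PAD arithmetic: scoring, typing, proximity, preference, effect size.

The instrument is a 12-item semantic differential on a 9-point bipolar
scale (−4 … +4).  Each PAD dimension is scored from four items, two keyed
positively and two negatively, and divided by 4, so every component lives
on the same −4 … +4 scale as the items.

Two distinct label vocabularies are deliberately kept apart:

* **octant labels** — one of eight names determined purely by the sign
  pattern of (P, A, D); includes ``Mild`` and ``Anxiety``;
* **normative emotion labels** — names attached to fixed reference points
  in PAD space (:data:`DEFAULT_NORMS`); includes ``Surprise`` and
  ``Fear``.

No mapping between the two is attempted; preference is defined as minimum
Euclidean distance to a normative point, octant typing as the sign lookup.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

__all__ = [
    "RatingRecord",
    "PADVector",
    "EmotionNorm",
    "OctantLabel",
    "PreferenceResult",
    "DEFAULT_NORMS",
    "OCTANT_TABLE",
    "GROUPS",
    "score_pad",
    "classify_octant",
    "proximity",
    "nearest_emotion",
    "smd",
    "classify_pleasure_band",
    "aggregate_group",
    "run_pad_pipeline",
]

#: Recognised group labels.  ``young-man`` and ``young-woman`` are subsets
#: of ``young``; a record labelled with either also counts toward ``young``.
GROUPS = ("young", "young-man", "young-woman", "elderly")

ITEM_MIN = -4.0
ITEM_MAX = 4.0
N_ITEMS = 12


class ValidationError(ValueError):
    """Raised when an input record violates the instrument's contract."""


class ConfigurationError(ValueError):
    """Raised for invalid analysis configuration (e.g. empty norm table)."""


class UndefinedEffectError(ZeroDivisionError):
    """Raised when the standardized mean difference has a zero denominator."""


@dataclass(frozen=True)
class PADVector:
    """A point in Pleasure/Arousal/Dominance space on the item scale."""

    P: float
    A: float
    D: float

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.P, self.A, self.D)

    def __iter__(self):
        return iter(self.as_tuple())


@dataclass(frozen=True)
class RatingRecord:
    """One participant's 12 item scores for one stimulus.

    Items are validated eagerly: exactly 12 values, each finite and within
    [−4, +4].  Missing values are rejected, never imputed.
    """

    participant_id: str
    group: str
    stimulus_id: str
    items: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValidationError(
                f"unknown group {self.group!r}; expected one of {GROUPS}"
            )
        items = tuple(float(v) for v in self.items)
        if len(items) != N_ITEMS:
            raise ValidationError(
                f"expected {N_ITEMS} item scores, got {len(items)}"
            )
        for i, v in enumerate(items):
            if not math.isfinite(v) or not (ITEM_MIN <= v <= ITEM_MAX):
                raise ValidationError(
                    f"item V{i + 1} = {v!r} outside [{ITEM_MIN:g}, {ITEM_MAX:g}]"
                )
        object.__setattr__(self, "items", items)

    @property
    def pad(self) -> PADVector:
        return score_pad(self.items)

    def in_group(self, group: str) -> bool:
        """Group membership with young-man/young-woman nested under young."""
        if group == "young":
            return self.group in ("young", "young-man", "young-woman")
        return self.group == group


@dataclass(frozen=True)
class EmotionNorm:
    """A labelled normative (PN, AN, DN) reference point in PAD space."""

    label: str
    PN: float
    AN: float
    DN: float

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.PN, self.AN, self.DN)


#: Built-in normative inventory, in canonical table order.  Distances are
#: computed against these points; the minimum defines the preferred emotion.
DEFAULT_NORMS: tuple[EmotionNorm, ...] = (
    EmotionNorm("Joyful", 2.77, 1.21, 1.42),
    EmotionNorm("Relaxed", 2.19, -0.66, 1.05),
    EmotionNorm("Surprise", 1.72, 1.71, 0.22),
    EmotionNorm("Dependent", 0.39, -0.81, -1.48),
    EmotionNorm("Boring", -0.53, -1.25, -0.84),
    EmotionNorm("Fear", -0.95, 0.32, -0.63),
    EmotionNorm("Contempt", -1.58, 0.32, 1.02),
    EmotionNorm("Disgust", -1.80, 0.40, 0.67),
)

#: Sign-triple → octant name.  True means the component is positive.
OCTANT_TABLE: Mapping[tuple[bool, bool, bool], str] = {
    (True, True, True): "Joyful",
    (True, True, False): "Dependent",
    (True, False, True): "Relaxed",
    (True, False, False): "Mild",
    (False, False, False): "Boring",
    (False, False, True): "Contempt",
    (False, True, False): "Anxiety",
    (False, True, True): "Disgust",
}


@dataclass(frozen=True)
class OctantLabel:
    """Octant emotion type: a pure function of the signs of (P, A, D).

    ``zero_flag`` is set when any component is exactly zero, in which case
    the label depends on the configured zero policy.
    """

    label: str
    signs: tuple[int, int, int]
    zero_flag: bool


@dataclass(frozen=True)
class PreferenceResult:
    """Per stimulus × group outcome of the preference pipeline."""

    stimulus_id: str
    group: str
    pad: PADVector
    octant: OctantLabel
    proximities: Mapping[str, float]
    nearest_emotion: str
    nearest_distance: float
    pleasure_band: str
    tie_flag: bool
    n_records: int = 0


def score_pad(items: Sequence[float]) -> PADVector:
    """Score a 12-item semantic-differential response into a PAD vector.

    P = (V1 − V4 + V7 − V10) / 4
    A = (−V2 + V5 − V8 + V11) / 4
    D = (V3 − V6 + V9 − V12) / 4

    Raises :class:`ValidationError` naming the offending item index on a
    wrong-length or out-of-range input.
    """
    vals = [float(v) for v in items]
    if len(vals) != N_ITEMS:
        raise ValidationError(f"expected {N_ITEMS} item scores, got {len(vals)}")
    for i, v in enumerate(vals):
        if not math.isfinite(v) or not (ITEM_MIN <= v <= ITEM_MAX):
            raise ValidationError(
                f"item V{i + 1} = {v!r} outside [{ITEM_MIN:g}, {ITEM_MAX:g}]"
            )
    v1, v2, v3, v4, v5, v6, v7, v8, v9, v10, v11, v12 = vals
    return PADVector(
        P=(v1 - v4 + v7 - v10) / 4.0,
        A=(-v2 + v5 - v8 + v11) / 4.0,
        D=(v3 - v6 + v9 - v12) / 4.0,
    )


def classify_octant(
    pad: PADVector, zero_policy: Literal["negative", "positive"] = "negative"
) -> OctantLabel:
    """Map the sign triple of a PAD vector to its octant emotion name.

    An exactly-zero component carries no sign; under the default policy it
    counts as negative and ``zero_flag`` is raised so downstream consumers
    can see the call was policy-determined.
    """
    comps = pad.as_tuple()
    for c in comps:
        if not math.isfinite(c):
            raise ValidationError(f"non-finite PAD component {c!r}")
    zero_flag = any(c == 0.0 for c in comps)
    if zero_policy == "negative":
        key = tuple(c > 0 for c in comps)
    elif zero_policy == "positive":
        key = tuple(c >= 0 for c in comps)
    else:  # pragma: no cover - guarded by Literal in typed callers
        raise ConfigurationError(f"unknown zero_policy {zero_policy!r}")
    signs = tuple(1 if k else -1 for k in key)
    return OctantLabel(label=OCTANT_TABLE[key], signs=signs, zero_flag=zero_flag)


def proximity(pad: PADVector, norm: EmotionNorm | PADVector) -> float:
    """Euclidean distance between a measured PAD point and a reference point.

    √((P−PN)² + (A−AN)² + (D−DN)²); reported at 4 decimals in tabular
    output, computed here at full precision.
    """
    if isinstance(norm, EmotionNorm):
        ref = norm.as_tuple()
    else:
        ref = norm.as_tuple()
    return math.dist(pad.as_tuple(), ref)


def nearest_emotion(
    pad: PADVector, norms: Sequence[EmotionNorm] = DEFAULT_NORMS
) -> tuple[str, float, bool]:
    """Pick the normative emotion at minimum Euclidean proximity.

    Exact ties are broken by norm-table order (first listed wins) and
    reported through the returned ``tie_flag``.
    """
    norms = tuple(norms)
    if not norms:
        raise ConfigurationError("norm inventory is empty")
    labels = [n.label for n in norms]
    if len(set(labels)) != len(labels):
        raise ConfigurationError("norm labels are not unique")
    distances = [proximity(pad, n) for n in norms]
    best = min(distances)
    idx = distances.index(best)
    tie = distances.count(best) > 1
    return norms[idx].label, best, tie


def smd(m1: float, m2: float) -> float:
    """Variance-free standardized mean difference: (m1 − m2)/(|m1| + |m2|).

    Bounded in [−1, 1]; |smd| = 1 exactly when the two means have opposite
    signs or one of them is zero.  Undefined when both means are zero.
    """
    denom = abs(m1) + abs(m2)
    if denom == 0.0:
        raise UndefinedEffectError("SMD undefined: both means are zero")
    return (m1 - m2) / denom


#: Band node sequences, inner → outer, per scheme.  Bands between
#: consecutive nodes are Unpleased / General / Pleased.
_BAND_NODES = {
    "painting": (-1.25, -0.25, 0.25, 1.25),
    "interior": (-1.5, -0.2, 0.5, 1.5),
}
_BAND_NAMES = ("Unpleased", "General", "Pleased")


def classify_pleasure_band(
    p: float, scheme: Literal["painting", "interior"] = "painting"
) -> str:
    """Assign a Pleasure mean to its Unpleased / General / Pleased band.

    Band edges are shared nodes; a value landing exactly on a shared node
    goes to the band farther from zero.  Values outside the outer nodes
    are assigned to the nearest band.
    """
    try:
        lo, a, b, hi = _BAND_NODES[scheme]
    except KeyError:
        raise ConfigurationError(
            f"unknown band scheme {scheme!r}; expected one of {sorted(_BAND_NODES)}"
        ) from None
    if p <= a:
        return "Unpleased"
    if p < b:
        return "General"
    return "Pleased"


def band_in_range(p: float, scheme: Literal["painting", "interior"] = "painting") -> bool:
    """True when ``p`` lies within the scheme's outer band nodes."""
    nodes = _BAND_NODES[scheme]
    return nodes[0] <= p <= nodes[-1]


def aggregate_group(
    records: Iterable[RatingRecord],
    group: str,
    stimulus_map: Mapping[str, str] | None = None,
) -> dict[str, PADVector]:
    """Unweighted mean PAD per stimulus over the records of one group.

    ``stimulus_map`` optionally relabels stimulus ids before averaging
    (e.g. pooling several images of one style into a single style cell).
    Empty cells are simply absent from the result — never reported as zero.
    """
    if group not in GROUPS:
        raise ConfigurationError(f"unknown group {group!r}; expected one of {GROUPS}")
    sums: dict[str, list[float]] = {}
    counts: dict[str, int] = {}
    for rec in records:
        if not rec.in_group(group):
            continue
        stim = rec.stimulus_id
        if stimulus_map is not None:
            stim = stimulus_map.get(stim, stim)
        pad = rec.pad
        acc = sums.setdefault(stim, [0.0, 0.0, 0.0])
        acc[0] += pad.P
        acc[1] += pad.A
        acc[2] += pad.D
        counts[stim] = counts.get(stim, 0) + 1
    return {
        stim: PADVector(s[0] / counts[stim], s[1] / counts[stim], s[2] / counts[stim])
        for stim, s in sums.items()
    }


def _group_sizes(
    records: Iterable[RatingRecord],
    group: str,
    stimulus_map: Mapping[str, str] | None,
) -> dict[str, int]:
    counts: dict[str, int] = {}
    for rec in records:
        if not rec.in_group(group):
            continue
        stim = rec.stimulus_id
        if stimulus_map is not None:
            stim = stimulus_map.get(stim, stim)
        counts[stim] = counts.get(stim, 0) + 1
    return counts


def preference_for_pad(
    pad: PADVector,
    *,
    stimulus_id: str = "",
    group: str = "young",
    norms: Sequence[EmotionNorm] = DEFAULT_NORMS,
    scheme: Literal["painting", "interior"] = "painting",
    n_records: int = 0,
) -> PreferenceResult:
    """Full preference evaluation of a single (already aggregated) PAD point."""
    octant = classify_octant(pad)
    prox = {n.label: proximity(pad, n) for n in norms}
    label, dist, tie = nearest_emotion(pad, norms)
    band = classify_pleasure_band(pad.P, scheme)
    return PreferenceResult(
        stimulus_id=stimulus_id,
        group=group,
        pad=pad,
        octant=octant,
        proximities=prox,
        nearest_emotion=label,
        nearest_distance=dist,
        pleasure_band=band,
        tie_flag=tie,
        n_records=n_records,
    )


def run_pad_pipeline(
    records: Sequence[RatingRecord],
    norms: Sequence[EmotionNorm] = DEFAULT_NORMS,
    scheme: Literal["painting", "interior"] = "painting",
    groups: Sequence[str] = GROUPS,
    stimulus_map: Mapping[str, str] | None = None,
) -> list[PreferenceResult]:
    """Aggregate, type, and rank every group × stimulus cell.

    Deterministic given inputs: results are ordered by the ``groups``
    argument and, within a group, by first appearance of the stimulus in
    ``records``.
    """
    records = list(records)
    results: list[PreferenceResult] = []
    for group in groups:
        if group not in GROUPS:
            raise ConfigurationError(
                f"unknown group {group!r}; expected one of {GROUPS}"
            )
        means = aggregate_group(records, group, stimulus_map)
        sizes = _group_sizes(records, group, stimulus_map)
        order: list[str] = []
        for rec in records:
            stim = rec.stimulus_id
            if stimulus_map is not None:
                stim = stimulus_map.get(stim, stim)
            if stim in means and stim not in order:
                order.append(stim)
        for stim in order:
            results.append(
                preference_for_pad(
                    means[stim],
                    stimulus_id=stim,
                    group=group,
                    norms=norms,
                    scheme=scheme,
                    n_records=sizes[stim],
                )
            )
    return results
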