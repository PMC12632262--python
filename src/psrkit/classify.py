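"""Receiver vs. pseudo-receiver classification.

A domain recognized as a receiver but lacking any one of the five conserved
active-site residues (DD1, DD2, D, T, K) is called a pseudo-receiver (PsR);
the subset lacking the Asp phosphorylation site (D) is the aspartate-less
receiver (ALR) class.  Classification is binary and per-sequence: a landmark
is *missing* when its column holds a residue outside the landmark's allowed
residue class, and a gap always counts as missing (a domain that fails to
align a landmark cannot present the catalytic residue).

Default residue classes: DD1, DD2 ∈ {D, E} (the metal-binding pair is 100%
acidic in true receivers), D ∈ {D} only (Glu at D is the hallmark ALR
substitution and must count as missing), T ∈ {S, T}, K ∈ {K}.  All classes
are overridable, e.g. a single-landmark rule with allowed = {H} counts
missing His phosphorylation sites in HisKA / HisKA_3 / Hpt alignments.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import pandas as pd

from .align_io import (
    AMINO_ACIDS,
    GAP,
    LANDMARKS,
    AlignedDomainSet,
    LandmarkMap,
    PositionLabel,
)

__all__ = [
    "ResidueClassRule",
    "DomainCall",
    "PresenceSummary",
    "default_rules",
    "classify_domain",
    "classify_set",
    "partition_set",
    "landmark_presence_fraction",
    "calls_table",
    "summarize_calls",
    "write_calls_tsv",
    "write_summary_json",
]

#: Default conserved-residue classes per landmark.
DEFAULT_CONSERVED_CLASSES: Mapping[str, str] = {
    "DD1": "DE",
    "DD2": "DE",
    "D": "D",
    "T": "ST",
    "K": "K",
}

RECEIVER = "receiver"
PSEUDO_RECEIVER = "pseudo_receiver"


@dataclasses.dataclass(frozen=True)
class ResidueClassRule:
    """An allowed residue class at a (possibly landmark-relative) position."""

    label: PositionLabel
    allowed: frozenset[str]

    def __post_init__(self) -> None:
        allowed = frozenset(str(a).upper() for a in self.allowed)
        object.__setattr__(self, "allowed", allowed)
        if not allowed:
            raise ValueError("allowed residue class must be non-empty")
        bad = allowed - set(AMINO_ACIDS)
        if bad:
            raise ValueError(
                f"allowed residue class contains non-amino-acid symbols: {sorted(bad)}"
            )


def default_rules(
    overrides: Mapping[str, Iterable[str]] | None = None,
) -> dict[str, ResidueClassRule]:
    """The five landmark rules, optionally overriding allowed classes."""
    classes = dict(DEFAULT_CONSERVED_CLASSES)
    if overrides:
        for name, allowed in overrides.items():
            if name not in LANDMARKS:
                raise ValueError(f"unknown landmark {name!r}")
            classes[name] = "".join(allowed)
    return {
        name: ResidueClassRule(PositionLabel(name, 0), frozenset(classes[name]))
        for name in LANDMARKS
    }


def _check_rules(rules: Mapping[str, ResidueClassRule]) -> None:
    if set(rules) != set(LANDMARKS):
        raise ValueError(
            f"rules must cover exactly the landmarks {LANDMARKS}, got {sorted(rules)}"
        )


@dataclasses.dataclass(frozen=True)
class DomainCall:
    """Classification of one aligned domain sequence."""

    sequence_id: str
    call: str
    missing_landmarks: frozenset[str]
    is_alr: bool

    def __post_init__(self) -> None:
        if (self.call == RECEIVER) != (not self.missing_landmarks):
            raise ValueError("call must be receiver iff no landmark is missing")
        if self.is_alr and ("D" not in self.missing_landmarks):
            raise ValueError("ALR requires the D landmark to be missing")


class PresenceSummary(NamedTuple):
    missing_count: int
    total: int
    fraction_missing: float


def classify_domain(
    sequence_id: str,
    residues: str,
    landmark_map: LandmarkMap,
    rules: Mapping[str, ResidueClassRule] | None = None,
) -> DomainCall:
    """Classify one aligned row as receiver or pseudo-receiver.

    Deterministic, and independent of any other row: only the five landmark
    columns of this row are inspected.
    """
    if rules is None:
        rules = default_rules()
    _check_rules(rules)
    missing: set[str] = set()
    for name in LANDMARKS:
        rule = rules[name]
        col = landmark_map.column_of(rule.label)
        if col >= len(residues):
            raise ValueError("malformed alignment row")
        if residues[col] not in rule.allowed:  # gap never allowed -> missing
            missing.add(name)
    call = RECEIVER if not missing else PSEUDO_RECEIVER
    return DomainCall(
        sequence_id=sequence_id,
        call=call,
        missing_landmarks=frozenset(missing),
        is_alr=("D" in missing),
    )


def classify_set(
    alignment: AlignedDomainSet,
    landmark_map: LandmarkMap,
    rules: Mapping[str, ResidueClassRule] | None = None,
) -> list[DomainCall]:
    if rules is None:
        rules = default_rules()
    return [
        classify_domain(sid, res, landmark_map, rules)
        for sid, res in alignment.sequences
    ]


def partition_set(
    alignment: AlignedDomainSet,
    landmark_map: LandmarkMap,
    rules: Mapping[str, ResidueClassRule] | None = None,
) -> tuple[AlignedDomainSet, AlignedDomainSet, list[DomainCall]]:
    """Split an alignment into (receivers, PsRs, calls).

    Exhaustive and exclusive: every sequence lands in exactly one output set.
    """
    if alignment.n_sequences == 0:
        raise ValueError("no sequences")
    calls = classify_set(alignment, landmark_map, rules)
    rec_idx = [i for i, c in enumerate(calls) if c.call == RECEIVER]
    psr_idx = [i for i, c in enumerate(calls) if c.call == PSEUDO_RECEIVER]
    receivers = alignment.subset(rec_idx, group_label=RECEIVER)
    psrs = alignment.subset(psr_idx, group_label=PSEUDO_RECEIVER)
    return receivers, psrs, calls


def landmark_presence_fraction(
    alignment: AlignedDomainSet,
    rule: ResidueClassRule,
    landmark_map: LandmarkMap | None = None,
    column: int | None = None,
) -> PresenceSummary:
    """Count rows missing one conserved position.

    The position is either ``rule.label`` resolved through ``landmark_map``,
    or an explicit ``column`` (used e.g. for the conserved His of
    HisKA/HisKA_3/Hpt alignments, which have no receiver landmarks).
    """
    if alignment.n_sequences == 0:
        raise ValueError("no sequences")
    if column is None:
        if landmark_map is None:
            raise ValueError("either landmark_map or column is required")
        column = landmark_map.column_of(rule.label)
    missing = 0
    for sid, res in alignment.sequences:
        if column >= len(res):
            raise ValueError("malformed alignment row")
        if res[column] not in rule.allowed:
            missing += 1
    total = alignment.n_sequences
    return PresenceSummary(missing, total, missing / total)


def calls_table(calls: Sequence[DomainCall]) -> pd.DataFrame:
    """Tabulate calls: sequence_id, call, missing landmarks, ALR flag."""
    return pd.DataFrame(
        {
            "sequence_id": [c.sequence_id for c in calls],
            "call": [c.call for c in calls],
            "missing_landmarks": [
                ",".join(sorted(c.missing_landmarks, key=LANDMARKS.index))
                for c in calls
            ],
            "is_ALR": [c.is_alr for c in calls],
        }
    )


def summarize_calls(calls: Sequence[DomainCall]) -> dict:
    n = len(calls)
    n_psr = sum(c.call == PSEUDO_RECEIVER for c in calls)
    n_alr = sum(c.is_alr for c in calls)
    per_landmark = {
        name: sum(name in c.missing_landmarks for c in calls) for name in LANDMARKS
    }
    return {
        "n_sequences": n,
        "n_receiver": n - n_psr,
        "n_pseudo_receiver": n_psr,
        "n_alr": n_alr,
        "fraction_pseudo_receiver": (n_psr / n) if n else 0.0,
        "fraction_alr": (n_alr / n) if n else 0.0,
        "missing_counts_per_landmark": per_landmark,
    }


def write_calls_tsv(calls: Sequence[DomainCall], path: str | Path) -> None:
    calls_table(calls).to_csv(path, sep="\t", index=False)


def write_summary_json(calls: Sequence[DomainCall], path: str | Path) -> None:
    Path(path).write_text(json.dumps(summarize_calls(calls), indent=2) + "\n")
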