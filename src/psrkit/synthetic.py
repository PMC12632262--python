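"""Synthetic alignment generator with known planted structure.

Generates reference-anchored alignments whose statistical structure is known
by construction, so every downstream stage — classification, composition
profiling, covariation, networks, rank shift — can be validated without any
external data.  Three kinds of structure can be planted:

* **Landmark conservation.**  Each of the five active-site landmarks draws
  its conserved residue class with a tunable probability; a failed draw
  samples a substitute class instead (default: the complement of the
  conserved class, uniformly), so the planted missing rate is exact.
* **Composition biases.**  Any column's background categorical distribution
  over the 20 amino acids can be overridden, e.g. to plant Ala+Gly abundance
  at T+1 or the Phe vs. Ala/Ile/Leu/Val balance at K+2.
* **Coupled pairs / blocks.**  With probability ``coupling`` a row draws all
  columns of a block jointly from one of two designated residue
  combinations (chosen 50/50); otherwise the columns are drawn
  independently from the background.  This two-component mixture has a
  simple, analytically tractable mutual information that grows
  monotonically with the coupling strength.

Gaps are injected independently per cell after the residue draws.  A
generation is a pure function of ``(spec, seed)``: one PRNG is seeded per
call and every draw derives from it, so the same spec reproduces a
byte-identical alignment.  The companion truth record states, per row, which
landmarks were planted missing (by substitution or gap) and hence the true
receiver / pseudo-receiver / ALR call, plus the planted couplings, which is
sufficient to score recovery.

The :func:`receiver_like_spec` and :func:`psr_like_spec` presets emulate
curated receiver and PsR sequence sets: their planted marginals are the
published composition values for those groups (e.g. DD1/DD2 100% acidic,
T+1 Ala+Gly at 74% in receivers vs. 43% in PsRs, K−3 aromatics at 86% vs.
65%, K+2 Phe vs. A/I/L/V at 40/39 vs. 20/55).  Sites are drawn
independently, so planted *joint* quantities are products of marginals.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .align_io import (
    AMINO_ACIDS,
    GAP_CODE,
    LANDMARKS,
    AlignedDomainSet,
    LandmarkMap,
    write_alignment,
)

__all__ = [
    "LandmarkSiteSpec",
    "CoupledBlockSpec",
    "coupled_pair",
    "SyntheticSpec",
    "TruthRecord",
    "generate_alignment",
    "landmark_map_for",
    "default_landmark_columns",
    "make_two_group_fixture",
    "TwoGroupFixture",
    "receiver_like_spec",
    "psr_like_spec",
    "representative_set_spec",
    "spec_to_yaml",
    "spec_from_yaml",
    "write_fixture",
]

_AA_SET = set(AMINO_ACIDS)
_CODE_OF = {aa: i for i, aa in enumerate(AMINO_ACIDS)}


def _check_prob(p: float, what: str) -> None:
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"{what} must be in [0, 1], got {p}")


@dataclasses.dataclass(frozen=True)
class LandmarkSiteSpec:
    """One landmark column: conserved class, conservation probability, and
    the substitute class drawn when conservation fails (default: uniform
    over the complement of the conserved class)."""

    column: int
    conserved: frozenset[str]
    p_conserved: float
    substitute: frozenset[str] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "conserved", frozenset(self.conserved))
        if self.substitute is not None:
            object.__setattr__(self, "substitute", frozenset(self.substitute))
        _check_prob(self.p_conserved, "p_conserved")
        if not self.conserved or self.conserved - _AA_SET:
            raise ValueError("conserved class must be a non-empty set of amino acids")
        sub = self.substitute
        if sub is not None:
            if not sub or sub - _AA_SET:
                raise ValueError(
                    "substitute class must be a non-empty set of amino acids"
                )
            if sub & self.conserved:
                raise ValueError("substitute class overlaps conserved class")

    @property
    def effective_substitute(self) -> frozenset[str]:
        if self.substitute is not None:
            return self.substitute
        return frozenset(_AA_SET - self.conserved)


@dataclasses.dataclass(frozen=True)
class CoupledBlockSpec:
    """A planted covarying block: with probability ``coupling`` a row draws
    all block columns jointly from one of two residue-state tuples."""

    columns: tuple[int, ...]
    coupling: float
    states: tuple[tuple[str, ...], tuple[str, ...]]

    def __post_init__(self) -> None:
        cols = tuple(int(c) for c in self.columns)
        object.__setattr__(self, "columns", cols)
        states = tuple(tuple(str(x).upper() for x in s) for s in self.states)
        object.__setattr__(self, "states", states)
        _check_prob(self.coupling, "coupling")
        if len(cols) < 2 or len(set(cols)) != len(cols):
            raise ValueError("a coupled block needs >= 2 distinct columns")
        if len(states) != 2:
            raise ValueError("exactly two residue states are required")
        for s in states:
            if len(s) != len(cols):
                raise ValueError("each state must name one residue per column")
            if set(s) - _AA_SET:
                raise ValueError(f"state letters outside the amino-acid alphabet: {s}")
        if states[0] == states[1]:
            raise ValueError("the two states must differ")


def coupled_pair(
    col_i: int,
    col_j: int,
    coupling: float,
    combos: tuple[tuple[str, str], tuple[str, str]] = (("A", "V"), ("V", "A")),
) -> CoupledBlockSpec:
    """Convenience: a two-column coupled block (the common case)."""
    return CoupledBlockSpec((col_i, col_j), coupling, combos)


@dataclasses.dataclass(frozen=True)
class SyntheticSpec:
    """Full recipe for one synthetic aligned domain set.

    ``background`` maps column index → {amino acid: probability} overriding
    the uniform default at that column; ``gap_rate`` is a global per-cell
    probability or a per-column mapping.
    """

    n_sequences: int
    n_columns: int
    seed: int = 0
    group_label: str = "synthetic"
    background: Mapping[int, Mapping[str, float]] | None = None
    landmark_sites: Mapping[str, LandmarkSiteSpec] | None = None
    coupled_blocks: tuple[CoupledBlockSpec, ...] = ()
    gap_rate: float | Mapping[int, float] = 0.0

    def __post_init__(self) -> None:
        if self.n_sequences < 1 or self.n_columns < 1:
            raise ValueError("n_sequences and n_columns must be >= 1")
        sites = dict(self.landmark_sites or {})
        object.__setattr__(self, "landmark_sites", sites)
        object.__setattr__(
            self, "coupled_blocks", tuple(self.coupled_blocks)
        )
        bg = {int(c): dict(d) for c, d in (self.background or {}).items()}
        object.__setattr__(self, "background", bg)
        for name, site in sites.items():
            if name not in LANDMARKS:
                raise ValueError(f"unknown landmark {name!r}")
            if not 0 <= site.column < self.n_columns:
                raise ValueError(f"landmark {name} column out of range")
        landmark_cols = {s.column for s in sites.values()}
        if len(landmark_cols) != len(sites):
            raise ValueError("landmark columns must be distinct")
        for block in self.coupled_blocks:
            for c in block.columns:
                if not 0 <= c < self.n_columns:
                    raise ValueError("coupled block column out of range")
                if c in landmark_cols:
                    raise ValueError(
                        "coupled block columns may not overlap landmark columns"
                    )
        for c, dist in bg.items():
            if not 0 <= c < self.n_columns:
                raise ValueError("background override column out of range")
            if set(dist) - _AA_SET:
                raise ValueError("background distribution has non-amino-acid keys")
            total = sum(dist.values())
            if any(p < 0 for p in dist.values()) or total > 1 + 1e-9:
                raise ValueError(
                    "background override probabilities must be >= 0 and sum to <= 1"
                )
        if isinstance(self.gap_rate, Mapping):
            for c, g in self.gap_rate.items():
                _check_prob(g, f"gap_rate[{c}]")
        else:
            _check_prob(float(self.gap_rate), "gap_rate")


@dataclasses.dataclass(frozen=True)
class TruthRecord:
    """Planted ground truth for one generated alignment."""

    missing_landmarks: tuple[frozenset[str], ...]
    calls: tuple[str, ...]
    is_alr: tuple[bool, ...]
    coupled_blocks: tuple[CoupledBlockSpec, ...]
    landmark_columns: dict[str, int]

    @property
    def n_receiver(self) -> int:
        return sum(c == "receiver" for c in self.calls)

    @property
    def n_pseudo_receiver(self) -> int:
        return sum(c == "pseudo_receiver" for c in self.calls)

    @property
    def n_alr(self) -> int:
        return sum(self.is_alr)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "calls": list(self.calls),
            "missing_landmarks": [sorted(m) for m in self.missing_landmarks],
            "is_alr": list(self.is_alr),
            "landmark_columns": self.landmark_columns,
            "coupled_blocks": [
                {
                    "columns": list(b.columns),
                    "coupling": b.coupling,
                    "states": [list(s) for s in b.states],
                }
                for b in self.coupled_blocks
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def _column_probs(spec: SyntheticSpec) -> np.ndarray:
    probs = np.full((spec.n_columns, 20), 1.0 / 20.0)
    for c, dist in spec.background.items():
        row = np.zeros(20)
        for aa, p in dist.items():
            row[_CODE_OF[aa]] = p
        rest = 1.0 - row.sum()
        free = row == 0
        if free.any() and rest > 0:
            row[free] = rest / free.sum()
        row = row / row.sum()
        probs[c] = row
    return probs


def generate_alignment(
    spec: SyntheticSpec, seed: int | None = None
) -> tuple[AlignedDomainSet, TruthRecord]:
    """Draw one alignment from a spec.  Deterministic for a given seed
    (``spec.seed`` unless overridden); returns the alignment plus the truth
    record of planted calls and couplings."""
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    n, L = spec.n_sequences, spec.n_columns
    probs = _column_probs(spec)
    codes = np.empty((n, L), dtype=np.int16)
    for c in range(L):
        codes[:, c] = rng.choice(20, size=n, p=probs[c])

    for block in spec.coupled_blocks:
        hit = rng.random(n) < block.coupling
        pick = rng.integers(0, 2, size=n)
        for k, col in enumerate(block.columns):
            state_codes = np.array(
                [_CODE_OF[block.states[0][k]], _CODE_OF[block.states[1][k]]]
            )
            codes[hit, col] = state_codes[pick[hit]]

    missing: list[set[str]] = [set() for _ in range(n)]
    for name in LANDMARKS:  # fixed order keeps generation reproducible
        site = spec.landmark_sites.get(name)
        if site is None:
            continue
        conserved_codes = np.array(sorted(_CODE_OF[a] for a in site.conserved))
        sub_codes = np.array(
            sorted(_CODE_OF[a] for a in site.effective_substitute)
        )
        keep = rng.random(n) < site.p_conserved
        draw_cons = conserved_codes[rng.integers(0, len(conserved_codes), size=n)]
        draw_sub = sub_codes[rng.integers(0, len(sub_codes), size=n)]
        codes[:, site.column] = np.where(keep, draw_cons, draw_sub)
        for r in np.flatnonzero(~keep):
            missing[r].add(name)

    if isinstance(spec.gap_rate, Mapping):
        gap_p = np.zeros(L)
        for c, g in spec.gap_rate.items():
            gap_p[int(c)] = g
    else:
        gap_p = np.full(L, float(spec.gap_rate))
    if gap_p.any():
        gaps = rng.random((n, L)) < gap_p[None, :]
        codes[gaps] = GAP_CODE
        for name, site in spec.landmark_sites.items():
            for r in np.flatnonzero(gaps[:, site.column]):
                missing[r].add(name)

    width = max(5, len(str(n)))
    ids = [f"{spec.group_label}_{i:0{width}d}" for i in range(n)]
    alignment = AlignedDomainSet.from_codes(spec.group_label, ids, codes)
    frozen = tuple(frozenset(m) for m in missing)
    calls = tuple(
        "receiver" if not m else "pseudo_receiver" for m in frozen
    )
    truth = TruthRecord(
        missing_landmarks=frozen,
        calls=calls,
        is_alr=tuple("D" in m for m in frozen),
        coupled_blocks=spec.coupled_blocks,
        landmark_columns={
            name: site.column for name, site in spec.landmark_sites.items()
        },
    )
    return alignment, truth


def default_landmark_columns(n_columns: int) -> dict[str, int]:
    """Landmark columns at CheY-proportional positions (12/13/57/87/109 of
    129), scaled to the alignment width."""
    if n_columns < 12:
        raise ValueError("need at least 12 columns to place five landmarks")
    frac = {"DD1": 12 / 129, "DD2": 13 / 129, "D": 57 / 129, "T": 87 / 129, "K": 109 / 129}
    cols = {k: int(round(f * (n_columns - 1))) for k, f in frac.items()}
    cols["DD2"] = max(cols["DD2"], cols["DD1"] + 1)  # keep strict order
    return cols


def landmark_map_for(spec: SyntheticSpec) -> LandmarkMap:
    """Gapless identity map (column *i* ↔ residue *i + 1*) whose landmark
    columns come from the spec's landmark sites, or from CheY-proportional
    defaults when the spec plants fewer than five landmarks."""
    sites = spec.landmark_sites
    if set(sites) == set(LANDMARKS):
        cols = {name: sites[name].column for name in LANDMARKS}
    else:
        cols = default_landmark_columns(spec.n_columns)
        for name, site in sites.items():
            cols[name] = site.column
    return LandmarkMap.identity(cols, spec.n_columns, reference_id="synthetic")


@dataclasses.dataclass(frozen=True)
class TwoGroupFixture:
    """Two alignments over a shared column map, ready for rank-shift."""

    receiver: AlignedDomainSet
    psr: AlignedDomainSet
    truth_receiver: TruthRecord
    truth_psr: TruthRecord
    landmark_map: LandmarkMap


def make_two_group_fixture(
    spec_receiver: SyntheticSpec, spec_psr: SyntheticSpec
) -> TwoGroupFixture:
    """Generate two groups sharing one column map.

    Requires equal widths and identical landmark placement so covariation
    results from the two groups are directly comparable pair-by-pair.
    """
    if spec_receiver.n_columns != spec_psr.n_columns:
        raise ValueError("group specs must have equal n_columns")
    map_a = landmark_map_for(spec_receiver)
    map_b = landmark_map_for(spec_psr)
    if map_a.landmark_columns != map_b.landmark_columns:
        raise ValueError("group specs must place landmarks identically")
    aln_a, truth_a = generate_alignment(spec_receiver)
    aln_b, truth_b = generate_alignment(spec_psr)
    return TwoGroupFixture(aln_a, aln_b, truth_a, truth_b, map_a)


# ---------------------------------------------------------------------------
# Presets emulating curated receiver / PsR sequence sets.  The planted
# marginals are the published group compositions; joint statistics follow as
# products because sites are drawn independently.

_CHEY_LIKE_COLUMNS = 125  # CheY-length layout, landmarks at 12/13/57/87/109


def _chey_like_landmarks(
    rates: Mapping[str, float], d_substitute: frozenset[str] | None
) -> dict[str, LandmarkSiteSpec]:
    cols = {"DD1": 11, "DD2": 12, "D": 56, "T": 86, "K": 108}
    classes = {"DD1": "DE", "DD2": "DE", "D": "D", "T": "ST", "K": "K"}
    sites = {}
    for name in LANDMARKS:
        sites[name] = LandmarkSiteSpec(
            column=cols[name],
            conserved=frozenset(classes[name]),
            p_conserved=rates[name],
            substitute=d_substitute if name == "D" else None,
        )
    return sites


def receiver_like_spec(
    n_sequences: int = 9153, seed: int = 0, group_label: str = "receiver"
) -> SyntheticSpec:
    """A receiver-domain-like group: all five landmarks fully conserved,
    with receiver-typical composition at key variable positions — Ala+Gly
    74% at T+1, Phe/Tyr 86% at K−3, Phe 40% vs. Ala/Ile/Leu/Val 39% at
    K+2, Pro 71% at D+4 and Gly 71% at D+8."""
    background = {
        87: {"A": 0.37, "G": 0.37},                      # T+1 (ref 88)
        105: {"F": 0.43, "Y": 0.43},                     # K−3 (ref 106)
        110: {"F": 0.40, "A": 0.0975, "I": 0.0975,
              "L": 0.0975, "V": 0.0975},                 # K+2 (ref 111)
        60: {"P": 0.71},                                 # D+4 (ref 61)
        64: {"G": 0.71},                                 # D+8 (ref 65)
    }
    rates = {name: 1.0 for name in LANDMARKS}
    return SyntheticSpec(
        n_sequences=n_sequences,
        n_columns=_CHEY_LIKE_COLUMNS,
        seed=seed,
        group_label=group_label,
        background=background,
        landmark_sites=_chey_like_landmarks(rates, None),
    )


def psr_like_spec(
    n_sequences: int = 9153, seed: int = 1, group_label: str = "PsR"
) -> SyntheticSpec:
    """A pseudo-receiver-like group: landmark conservation degraded to the
    published PsR marginals (DD1 80% acidic, DD2 20% acidic, D 65% with Glu
    as the substitute, T 70% Ser/Thr, K 65% Lys) and PsR-typical composition
    at key variable positions — Ala+Gly 43% at T+1, Phe/Tyr 65% at K−3, Phe
    20% vs. Ala/Ile/Leu/Val 55% at K+2, with the D+4 Pro and D+8 Gly
    preferences relaxed to 30%."""
    background = {
        87: {"A": 0.215, "G": 0.215},                    # T+1 (ref 88)
        105: {"F": 0.325, "Y": 0.325},                   # K−3 (ref 106)
        110: {"F": 0.20, "A": 0.1375, "I": 0.1375,
              "L": 0.1375, "V": 0.1375},                 # K+2 (ref 111)
        60: {"P": 0.30},                                 # D+4 (ref 61)
        64: {"G": 0.30},                                 # D+8 (ref 65)
    }
    rates = {"DD1": 0.80, "DD2": 0.20, "D": 0.65, "T": 0.70, "K": 0.65}
    return SyntheticSpec(
        n_sequences=n_sequences,
        n_columns=_CHEY_LIKE_COLUMNS,
        seed=seed,
        group_label=group_label,
        background=background,
        landmark_sites=_chey_like_landmarks(rates, frozenset("E")),
    )


def representative_set_spec(
    n_sequences: int = 20000, seed: int = 2, group_label: str = "representative"
) -> SyntheticSpec:
    """A representative mixed receiver/PsR database: per-landmark missing
    rates chosen so ~2% of rows lack the Asp phosphorylation site and ~6%
    lack at least one of the five conserved residues."""
    rates = {"DD1": 0.995, "DD2": 0.98, "D": 0.98, "T": 0.99, "K": 0.995}
    return SyntheticSpec(
        n_sequences=n_sequences,
        n_columns=_CHEY_LIKE_COLUMNS,
        seed=seed,
        group_label=group_label,
        landmark_sites=_chey_like_landmarks(rates, frozenset("E")),
    )


# ---------------------------------------------------------------------------
# Spec serialization (YAML) and fixture emission (FASTA + truth JSON).

def spec_to_yaml(spec: SyntheticSpec, path: str | Path) -> None:
    payload = {
        "n_sequences": spec.n_sequences,
        "n_columns": spec.n_columns,
        "seed": spec.seed,
        "group_label": spec.group_label,
        "background": {c: dict(d) for c, d in spec.background.items()},
        "landmark_sites": {
            name: {
                "column": s.column,
                "conserved": "".join(sorted(s.conserved)),
                "p_conserved": s.p_conserved,
                "substitute": (
                    "".join(sorted(s.substitute)) if s.substitute else None
                ),
            }
            for name, s in spec.landmark_sites.items()
        },
        "coupled_blocks": [
            {
                "columns": list(b.columns),
                "coupling": b.coupling,
                "states": ["".join(s) for s in b.states],
            }
            for b in spec.coupled_blocks
        ],
        "gap_rate": (
            dict(spec.gap_rate)
            if isinstance(spec.gap_rate, Mapping)
            else spec.gap_rate
        ),
    }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def spec_from_yaml(path: str | Path) -> SyntheticSpec:
    data = yaml.safe_load(Path(path).read_text())
    sites = {
        name: LandmarkSiteSpec(
            column=d["column"],
            conserved=frozenset(d["conserved"]),
            p_conserved=d["p_conserved"],
            substitute=frozenset(d["substitute"]) if d.get("substitute") else None,
        )
        for name, d in (data.get("landmark_sites") or {}).items()
    }
    blocks = tuple(
        CoupledBlockSpec(
            columns=tuple(b["columns"]),
            coupling=b["coupling"],
            states=tuple(tuple(s) for s in b["states"]),
        )
        for b in data.get("coupled_blocks") or ()
    )
    return SyntheticSpec(
        n_sequences=data["n_sequences"],
        n_columns=data["n_columns"],
        seed=data.get("seed", 0),
        group_label=data.get("group_label", "synthetic"),
        background=data.get("background") or None,
        landmark_sites=sites or None,
        coupled_blocks=blocks,
        gap_rate=data.get("gap_rate", 0.0),
    )


def write_fixture(
    spec: SyntheticSpec, out_dir: str | Path, stem: str | None = None
) -> tuple[Path, Path]:
    """Emit one generated alignment as aligned FASTA plus a truth-record
    JSON; returns the two paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stem = stem or spec.group_label
    alignment, truth = generate_alignment(spec)
    fasta = out_dir / f"{stem}.afa"
    truth_path = out_dir / f"{stem}.truth.json"
    write_alignment(alignment, fasta, "fasta")
    truth.to_json(truth_path)
    return fasta, truth_path
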