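"""Alignment I/O and reference-anchored position arithmetic.

Receiver-domain analyses are position-centric: every statistic is reported
against the residue numbering of a reference sequence (by default *E. coli*
CheY, the model receiver domain), and variable positions are named relative
to the five conserved active-site landmarks — the acidic metal-binding pair
(``DD1``, ``DD2``), the Asp phosphorylation site (``D``), the conserved
Ser/Thr (``T``) and the conserved Lys (``K``).  Labels such as ``T+1`` or
``K-3`` count *reference residues* from a landmark, so alignment columns that
are insertions relative to the reference are skipped.

This module reads and writes aligned FASTA / Stockholm files (via
:mod:`Bio.AlignIO`), validates the 20-letter + gap alphabet, builds the
column ↔ reference-number map from a reference row, and resolves
landmark-relative labels to alignment columns.  Column indices are 0-based
internally; reference residue numbers are 1-based in all user-facing output.
"""

from __future__ import annotations

import dataclasses
import re
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml
from Bio import AlignIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "AMINO_ACIDS",
    "GAP",
    "GAP_CODE",
    "LANDMARKS",
    "AlignedDomainSet",
    "PositionLabel",
    "LandmarkMap",
    "read_alignment",
    "write_alignment",
    "build_landmark_map",
    "resolve_position",
    "load_landmark_fixture",
    "chey_reference",
    "henikoff_weights",
]

#: The 20 standard amino acids, alphabetical; composition and MI alphabets
#: are exactly these letters plus the gap.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"
GAP_CODE = 20
LANDMARKS = ("DD1", "DD2", "D", "T", "K")

_CODE_OF = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
_CODE_OF[GAP] = GAP_CODE
_LETTER_OF = np.array(list(AMINO_ACIDS + GAP))

# ASCII lookup table: residue letter -> integer code, -1 for anything illegal.
_ASCII_CODES = np.full(128, -1, dtype=np.int8)
for _ch, _code in _CODE_OF.items():
    _ASCII_CODES[ord(_ch)] = _code

_FORMAT_ALIASES = {
    "fasta": "fasta",
    "aligned-fasta": "fasta",
    "afa": "fasta",
    "stockholm": "stockholm",
    "sto": "stockholm",
}


def _canonical_format(fmt: str) -> str:
    try:
        return _FORMAT_ALIASES[fmt.lower()]
    except KeyError:
        raise ValueError(
            f"unsupported alignment format {fmt!r}; use aligned-FASTA or Stockholm"
        ) from None


@dataclasses.dataclass(frozen=True)
class AlignedDomainSet:
    """A labeled group of equal-length aligned domain sequences.

    Parameters
    ----------
    group_label
        Free-text label of the group (e.g. ``"receiver"`` or ``"PsR"``).
    sequences
        Tuple of ``(id, residues)`` pairs; residues over the 20 amino acids
        plus ``'-'``, all the same length.
    n_columns
        Alignment width; inferred from the first sequence when omitted, but
        required for an empty set (partitions may produce empty groups).
    """

    group_label: str
    sequences: tuple[tuple[str, str], ...]
    n_columns: int | None = None

    def __post_init__(self) -> None:
        seqs = tuple((str(i), str(s)) for i, s in self.sequences)
        object.__setattr__(self, "sequences", seqs)
        if self.n_columns is None:
            if not seqs:
                raise ValueError("empty alignment requires explicit n_columns")
            object.__setattr__(self, "n_columns", len(seqs[0][1]))
        if self.n_columns < 1:
            raise ValueError("n_columns must be >= 1")
        seen: set[str] = set()
        for sid, res in seqs:
            if sid in seen:
                raise ValueError(f"duplicate sequence id {sid!r}")
            seen.add(sid)
            if len(res) != self.n_columns:
                raise ValueError("unequal sequence lengths")
            for ch in res:
                if ch not in _CODE_OF:
                    raise ValueError(
                        f"unknown residue code {ch!r} in sequence {sid!r}"
                    )

    @classmethod
    def from_records(
        cls,
        group_label: str,
        records: Iterable[tuple[str, str]],
        n_columns: int | None = None,
    ) -> "AlignedDomainSet":
        """Build a set from raw records, uppercasing and mapping ``.`` to ``-``."""
        norm = tuple(
            (sid, str(res).upper().replace(".", GAP)) for sid, res in records
        )
        return cls(group_label, norm, n_columns)

    @property
    def n_sequences(self) -> int:
        return len(self.sequences)

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(sid for sid, _ in self.sequences)

    def row(self, sequence_id: str) -> str:
        for sid, res in self.sequences:
            if sid == sequence_id:
                return res
        raise KeyError(sequence_id)

    def to_codes(self) -> np.ndarray:
        """Integer-encode the alignment: shape (n_sequences, n_columns),
        codes 0..19 for amino acids (alphabetical) and 20 for the gap."""
        if not self.sequences:
            return np.empty((0, self.n_columns), dtype=np.int8)
        flat = "".join(res for _, res in self.sequences)
        arr = np.frombuffer(flat.encode("ascii"), dtype=np.uint8)
        return _ASCII_CODES[arr].reshape(self.n_sequences, self.n_columns)

    @classmethod
    def from_codes(
        cls,
        group_label: str,
        ids: Sequence[str],
        codes: np.ndarray,
    ) -> "AlignedDomainSet":
        letters = _LETTER_OF[codes]
        seqs = tuple(
            (str(sid), "".join(row)) for sid, row in zip(ids, letters)
        )
        return cls(group_label, seqs, n_columns=int(codes.shape[1]))

    def subset(
        self, indices: Sequence[int], group_label: str | None = None
    ) -> "AlignedDomainSet":
        label = self.group_label if group_label is None else group_label
        return AlignedDomainSet(
            label,
            tuple(self.sequences[i] for i in indices),
            n_columns=self.n_columns,
        )


def read_alignment(
    path: str | Path, format: str = "fasta", group_label: str | None = None
) -> AlignedDomainSet:
    """Read an aligned FASTA or Stockholm file into an :class:`AlignedDomainSet`.

    Residues are uppercased and ``.`` gaps normalized to ``-``.  Ragged input
    raises ``unequal sequence lengths``; characters outside the 20-letter +
    gap alphabet (including ambiguity codes X/B/Z/U/O) raise
    ``unknown residue code`` — the composition and MI alphabets must be
    exactly 20 amino acids plus gap, so ambiguous residues have to be removed
    upstream.
    """
    path = Path(path)
    fmt = _canonical_format(format)
    try:
        msa = AlignIO.read(str(path), fmt)
    except ValueError as exc:
        if "same length" in str(exc):
            raise ValueError("unequal sequence lengths") from exc
        raise
    label = group_label if group_label is not None else path.stem
    return AlignedDomainSet.from_records(
        label, ((rec.id, str(rec.seq)) for rec in msa)
    )


def write_alignment(
    alignment: AlignedDomainSet, path: str | Path, format: str = "fasta"
) -> None:
    """Write an alignment as aligned FASTA or Stockholm (round-trip exact)."""
    fmt = _canonical_format(format)
    msa = MultipleSeqAlignment(
        SeqRecord(Seq(res), id=sid, description="")
        for sid, res in alignment.sequences
    )
    AlignIO.write(msa, str(path), fmt)


_LABEL_RE = re.compile(r"^(DD1|DD2|DD|D|T|K)\s*([+\-−]\s*\d+)?$")


@dataclasses.dataclass(frozen=True)
class PositionLabel:
    """A landmark-relative position, e.g. ``T+1`` → ``(T, +1)``.

    ``DD±k`` labels are anchored at DD1: the two acidic residues are not
    guaranteed to be adjacent in every receiver family, and usage of labels
    like ``DD+5`` (α1, paired with β2 positions) is consistent with an
    α1-proximal anchor.  Offsets count reference residues, not raw columns.
    """

    landmark: str
    offset: int = 0

    def __post_init__(self) -> None:
        if self.landmark not in LANDMARKS:
            raise ValueError(f"unknown landmark {self.landmark!r}")
        if abs(self.offset) > 30:
            raise ValueError(
                f"offset {self.offset} out of range for a ~125-residue domain"
            )

    @classmethod
    def parse(cls, text: str) -> "PositionLabel":
        m = _LABEL_RE.match(text.strip())
        if m is None:
            raise ValueError(f"cannot parse position label {text!r}")
        landmark = m.group(1)
        if landmark == "DD":  # bare DD and DD±k anchor at DD1
            landmark = "DD1"
        off = m.group(2)
        offset = 0
        if off is not None:
            off = off.replace("−", "-").replace(" ", "")
            offset = int(off)
        return cls(landmark, offset)

    def __str__(self) -> str:
        if self.offset == 0:
            return self.landmark
        return f"{self.landmark}{self.offset:+d}"


def _as_label(label: "PositionLabel | str") -> PositionLabel:
    return label if isinstance(label, PositionLabel) else PositionLabel.parse(label)


@dataclasses.dataclass(frozen=True)
class LandmarkMap:
    """Mapping between alignment columns, reference residue numbers, and the
    five active-site landmarks.

    ``reference_numbering`` maps alignment column index (0-based) to the
    reference residue number (1-based); columns that are insertions relative
    to the reference are absent from it.
    """

    landmark_columns: Mapping[str, int]
    reference_numbering: Mapping[int, int]
    reference_id: str

    def __post_init__(self) -> None:
        lm = dict(self.landmark_columns)
        num = dict(self.reference_numbering)
        object.__setattr__(self, "landmark_columns", lm)
        object.__setattr__(self, "reference_numbering", num)
        missing = [k for k in LANDMARKS if k not in lm]
        if missing:
            raise ValueError(f"landmark outside reference: {', '.join(missing)}")
        cols = [lm[k] for k in LANDMARKS]
        if len(set(cols)) != 5:
            raise ValueError("landmark columns must be distinct")
        if not all(a < b for a, b in zip(cols, cols[1:])):
            raise ValueError(
                "landmark column order must be DD1 < DD2 < D < T < K"
            )
        for name, col in lm.items():
            if col not in num:
                raise ValueError(
                    f"landmark {name} column {col} has no reference number"
                )
        ordered = sorted(num.items())
        nums = [n for _, n in ordered]
        if not all(a < b for a, b in zip(nums, nums[1:])):
            raise ValueError("reference numbering must be strictly increasing")
        object.__setattr__(
            self, "_column_of_number", {n: c for c, n in num.items()}
        )

    @classmethod
    def identity(
        cls,
        landmark_columns: Mapping[str, int],
        n_columns: int,
        reference_id: str = "synthetic",
    ) -> "LandmarkMap":
        """A gapless map: column *i* ↔ reference residue *i + 1*."""
        return cls(
            dict(landmark_columns),
            {c: c + 1 for c in range(n_columns)},
            reference_id,
        )

    @property
    def mapped_columns(self) -> tuple[int, ...]:
        return tuple(sorted(self.reference_numbering))

    def reference_number(self, column: int) -> int:
        try:
            return self.reference_numbering[column]
        except KeyError:
            raise ValueError(
                f"column {column} is an insertion relative to {self.reference_id}"
            ) from None

    def column_of_number(self, number: int) -> int:
        try:
            return self._column_of_number[number]
        except KeyError:
            raise ValueError("position outside reference span") from None

    def column_of(self, label: "PositionLabel | str") -> int:
        label = _as_label(label)
        anchor_col = self.landmark_columns[label.landmark]
        target = self.reference_numbering[anchor_col] + label.offset
        return self.column_of_number(target)


def build_landmark_map(
    alignment: AlignedDomainSet,
    reference_id: str,
    reference_landmarks: Mapping[str, int],
) -> LandmarkMap:
    """Anchor alignment columns to reference numbering via a reference row.

    Walks the named row, assigning increasing residue numbers to its non-gap
    columns; each landmark's column is the one holding the stated reference
    residue number.
    """
    try:
        row = alignment.row(reference_id)
    except KeyError:
        raise ValueError("reference not in alignment") from None
    numbering: dict[int, int] = {}
    n = 0
    for col, ch in enumerate(row):
        if ch != GAP:
            n += 1
            numbering[col] = n
    col_of = {num: col for col, num in numbering.items()}
    landmark_columns: dict[str, int] = {}
    for name in LANDMARKS:
        if name not in reference_landmarks:
            raise ValueError(f"landmark outside reference: {name}")
        resnum = reference_landmarks[name]
        if resnum not in col_of:
            raise ValueError(f"landmark outside reference: {name}")
        landmark_columns[name] = col_of[resnum]
    return LandmarkMap(landmark_columns, numbering, reference_id)


def resolve_position(
    label: "PositionLabel | str", landmark_map: LandmarkMap
) -> int:
    """Alignment column for a landmark-relative label (reference-residue
    offsets; insertion columns are skipped)."""
    return landmark_map.column_of(label)


def load_landmark_fixture(path: str | Path | None = None) -> dict:
    """Load a landmark fixture file (reference id, sequence, and the five
    landmark residue numbers).  Defaults to the packaged *E. coli* CheY file."""
    if path is None:
        text = (
            resources.files("psrkit.data")
            .joinpath("chey_landmarks.yaml")
            .read_text()
        )
    else:
        text = Path(path).read_text()
    data = yaml.safe_load(text)
    data["sequence"] = "".join(str(data["sequence"]).split())
    data["landmarks"] = {k: int(v) for k, v in data["landmarks"].items()}
    return data


def chey_reference() -> tuple[str, str, dict[str, int]]:
    """(reference_id, sequence, landmark residue numbers) for E. coli CheY."""
    fx = load_landmark_fixture()
    return fx["reference_id"], fx["sequence"], fx["landmarks"]


def henikoff_weights(alignment: AlignedDomainSet) -> np.ndarray:
    """Henikoff & Henikoff position-based sequence weights, normalized to
    mean 1.  Gap cells contribute nothing at their column.  Offered for
    sensitivity analysis; the default everywhere is uniform weighting, on the
    assumption that input sets are already redundancy-reduced."""
    codes = alignment.to_codes()
    n, L = codes.shape
    if n == 0:
        return np.zeros(0)
    w = np.zeros(n)
    for c in range(L):
        col = codes[:, c]
        residues = col[col != GAP_CODE]
        if residues.size == 0:
            continue
        counts = np.bincount(residues, minlength=20)
        r = int((counts > 0).sum())
        contrib = np.zeros(n)
        mask = col != GAP_CODE
        contrib[mask] = 1.0 / (r * counts[col[mask]])
        w += contrib
    w /= L
    mean = w.mean()
    if mean > 0:
        w = w / mean
    return w
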