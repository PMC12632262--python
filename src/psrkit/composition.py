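"""Position-wise amino-acid composition profiles and group differences.

Percent abundance at a column is computed over non-gap residues (the gap
fraction is reported separately), so a statement like "the metal-binding
pair is 100% acidic in receivers" is reproducible even when some rows gap
the column.  Differences between a receiver profile and a PsR profile form
the composition-difference heatmap: receiver minus PsR per (position, amino
acid), clipped for display at ±20 percentage points by default, with raw
values always retained.

Named-position statistics use landmark-relative labels (``T+1``, ``K-3``,
…); :func:`paired_retention` evaluates conjunctions such as Y-T coupling
competence (Ser/Thr at T *and* an aromatic at K−3) per sequence.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .align_io import (
    AMINO_ACIDS,
    GAP_CODE,
    AlignedDomainSet,
    LandmarkMap,
    PositionLabel,
)

__all__ = [
    "CompositionProfile",
    "CompositionDiff",
    "DEFAULT_YT_PAIRS",
    "composition_profile",
    "composition_difference",
    "class_abundance",
    "paired_retention",
    "plot_difference_heatmap",
]

#: Default Y-T coupling retention criteria: Ser/Thr at the conserved T and an
#: aromatic (Phe/Tyr) at K−3.
DEFAULT_YT_PAIRS: tuple[tuple[PositionLabel, frozenset[str]], ...] = (
    (PositionLabel("T", 0), frozenset("ST")),
    (PositionLabel("K", -3), frozenset("FY")),
)


@dataclasses.dataclass(frozen=True)
class CompositionProfile:
    """Per-position percent-abundance matrix for one sequence group.

    ``abundance`` is a 20 × n_positions DataFrame (rows = amino acids,
    columns = reference residue numbers, values = percent of non-gap
    residues).  Columns that are entirely gapped in the group are excluded
    from ``abundance`` and listed in ``excluded_columns``.
    """

    group_label: str
    abundance: pd.DataFrame
    gap_fraction: pd.Series
    landmarks: LandmarkMap
    n_sequences: int
    excluded_columns: tuple[int, ...] = ()

    @property
    def columns(self) -> tuple[int, ...]:
        return tuple(int(c) for c in self.abundance.columns)

    def to_tsv(self, path: str | Path) -> None:
        self.abundance.to_csv(path, sep="\t", index_label="amino_acid")


@dataclasses.dataclass(frozen=True)
class CompositionDiff:
    """Signed percent differences, receiver minus PsR, per (position, aa)."""

    diff: pd.DataFrame
    clip_limit: float = 20.0
    receiver_label: str = "receiver"
    psr_label: str = "pseudo_receiver"

    @property
    def columns(self) -> tuple[int, ...]:
        return tuple(int(c) for c in self.diff.columns)

    @property
    def clipped(self) -> pd.DataFrame:
        """Display copy, clipped to ±clip_limit; raw values stay in ``diff``."""
        return self.diff.clip(-self.clip_limit, self.clip_limit)

    def to_tsv(self, path: str | Path) -> None:
        self.diff.to_csv(path, sep="\t", index_label="amino_acid")


def composition_profile(
    alignment: AlignedDomainSet,
    landmark_map: LandmarkMap,
    weights: np.ndarray | None = None,
) -> CompositionProfile:
    """Percent abundance of each amino acid at every reference-mapped column.

    abundance[c][a] = 100 · count(a at c) / count(non-gap at c).  Uniform
    sequence weights by default; pass Henikoff weights for sensitivity
    analysis.
    """
    if alignment.n_sequences == 0:
        raise ValueError("no sequences")
    codes = alignment.to_codes()
    n = alignment.n_sequences
    if weights is None:
        weights = np.ones(n)
    weights = np.asarray(weights, dtype=float)
    if weights.shape != (n,):
        raise ValueError("weights must have one entry per sequence")

    cols = list(landmark_map.mapped_columns)
    cols = [c for c in cols if c < alignment.n_columns]
    abundance: dict[int, np.ndarray] = {}
    gap_fraction: dict[int, float] = {}
    excluded: list[int] = []
    wtot = weights.sum()
    for c in cols:
        refnum = landmark_map.reference_number(c)
        col = codes[:, c]
        nongap = col != GAP_CODE
        gap_fraction[refnum] = float(weights[~nongap].sum() / wtot)
        denom = weights[nongap].sum()
        if denom == 0:
            excluded.append(refnum)
            continue
        counts = np.bincount(col[nongap], weights=weights[nongap], minlength=20)[:20]
        abundance[refnum] = 100.0 * counts / denom
    ab = pd.DataFrame(abundance, index=list(AMINO_ACIDS))
    gf = pd.Series(gap_fraction, name="gap_fraction")
    return CompositionProfile(
        group_label=alignment.group_label,
        abundance=ab,
        gap_fraction=gf,
        landmarks=landmark_map,
        n_sequences=n,
        excluded_columns=tuple(excluded),
    )


def composition_difference(
    receiver_profile: CompositionProfile,
    psr_profile: CompositionProfile,
    clip_limit: float = 20.0,
) -> CompositionDiff:
    """Receiver minus PsR percent abundance per (position, amino acid)."""
    a, b = receiver_profile.abundance, psr_profile.abundance
    if list(a.columns) != list(b.columns):
        raise ValueError("profiles not comparable")
    return CompositionDiff(
        diff=a - b,
        clip_limit=clip_limit,
        receiver_label=receiver_profile.group_label,
        psr_label=psr_profile.group_label,
    )


def class_abundance(
    profile: CompositionProfile,
    label: PositionLabel | str,
    residue_class: Iterable[str],
) -> float:
    """Summed percent abundance of a residue class at a named position."""
    col = profile.landmarks.column_of(label)
    refnum = profile.landmarks.reference_number(col)
    if refnum not in profile.abundance.columns:
        raise ValueError(
            f"position {label} (reference residue {refnum}) is entirely gapped"
        )
    members = [str(a).upper() for a in residue_class]
    bad = set(members) - set(AMINO_ACIDS)
    if bad:
        raise ValueError(f"residue class contains non-amino-acid symbols: {sorted(bad)}")
    return float(profile.abundance.loc[members, refnum].sum())


def paired_retention(
    alignment: AlignedDomainSet,
    landmark_map: LandmarkMap,
    pairs: Sequence[tuple[PositionLabel | str, Iterable[str]]] = DEFAULT_YT_PAIRS,
) -> float:
    """Proportion of sequences satisfying *all* (position, residue class)
    criteria; a gap fails its criterion.  Default criteria are the Y-T
    coupling requirements (Ser/Thr at T, Phe/Tyr at K−3)."""
    if alignment.n_sequences == 0:
        raise ValueError("no sequences")
    pairs = list(pairs)
    if not pairs:
        raise ValueError("no criteria")
    resolved = [
        (landmark_map.column_of(label), frozenset(str(a).upper() for a in cls))
        for label, cls in pairs
    ]
    ok = 0
    for _, res in alignment.sequences:
        if all(res[col] in cls for col, cls in resolved):
            ok += 1
    return ok / alignment.n_sequences


def plot_difference_heatmap(
    diff: CompositionDiff,
    ax=None,
    cmap: str = "PiYG",
):
    """Render the clipped difference matrix as a diverging heatmap.

    Green marks amino acids more abundant in receivers, magenta/pink those
    more abundant in PsRs.  Returns the matplotlib Axes.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(
            figsize=(max(6.0, 0.09 * len(diff.columns)), 5.0)
        )
    data = diff.clipped
    lim = diff.clip_limit
    im = ax.imshow(
        data.to_numpy(),
        aspect="auto",
        cmap=cmap,
        vmin=-lim,
        vmax=lim,
        interpolation="nearest",
    )
    ax.set_yticks(range(len(data.index)), list(data.index), fontsize=7)
    step = max(1, len(data.columns) // 25)
    ax.set_xticks(
        range(0, len(data.columns), step),
        [str(c) for c in data.columns[::step]],
        rotation=90,
        fontsize=7,
    )
    ax.set_xlabel(f"position ({diff.receiver_label} reference numbering)")
    ax.set_ylabel("amino acid")
    cbar = ax.figure.colorbar(im, ax=ax)
    cbar.set_label(
        f"{diff.receiver_label} − {diff.psr_label} abundance (%, clipped ±{lim:g})"
    )
    return ax
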