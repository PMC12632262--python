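"""Corrected mutual-information covariation within and between alignments.

For every pair of alignment columns the raw mutual information

    MI(i, j) = Σ_ab p(a, b) · log2[ p(a, b) / (p(a) p(b)) ]

is computed over residue pairs observed at the two columns (units: bits).
Raw MI carries a background component driven by per-column entropy and
shared phylogeny; the average-product correction (APC) removes it:

    APC(i, j) = MI(i, ·) · MI(·, j) / ⟨MI⟩,    corrected = MI − APC,

where MI(i, ·) is the mean off-diagonal MI of column *i* and ⟨MI⟩ the mean
over all off-diagonal pairs.  Significance is a global z-score of the
corrected score across all off-diagonal pairs (default threshold z ≥ 6.5),
and percentile ranks (0–100, higher score → higher rank) support top-x%
selections and the between-group rank-shift comparison: for two groups
analysed over the identical column set, shift = rank_receiver − rank_PsR,
so positive shifts mark interactions that are relatively stronger in
receivers and negative ones those stronger in PsRs.

Gap handling is pairwise deletion by default (rows gapped at either column
are dropped for that pair); a gap-as-21st-symbol mode and an additive
pseudocount are available for sensitivity analysis.  Columns gapped in more
than ``max_gap_fraction`` of sequences are excluded from the analysis.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .align_io import (
    GAP_CODE,
    AlignedDomainSet,
    LandmarkMap,
    _ASCII_CODES,
)

__all__ = [
    "CovariationResult",
    "RankShiftTable",
    "column_mi",
    "mi_matrix",
    "product_correction",
    "significance",
    "rank_pairs",
    "top_fraction_indices",
    "covariation_analysis",
    "rank_shift",
    "DegenerateScoreDistribution",
]

DEFAULT_Z_THRESHOLD = 6.5


class DegenerateScoreDistribution(UserWarning):
    """All corrected scores equal: no z-scores, no significant pairs."""


def _encode(column: Iterable) -> np.ndarray:
    if isinstance(column, str):
        column = list(column)
    arr = np.asarray(column)
    if arr.dtype.kind in "iu":
        return arr.astype(np.int16)
    if arr.dtype.kind in "US" or arr.dtype == object:
        flat = "".join(str(x) for x in arr)
        raw = np.frombuffer(flat.encode("ascii"), dtype=np.uint8)
        codes = _ASCII_CODES[raw].astype(np.int16)
        if (codes < 0).any():
            bad = flat[int(np.argmax(codes < 0))]
            raise ValueError(f"unknown residue code {bad!r}")
        return codes
    raise TypeError("column must be residue letters or integer codes")


def _mi_bits(counts: np.ndarray) -> float:
    """MI in bits from a joint count (or weight) table."""
    total = counts.sum()
    p = counts / total
    pi = p.sum(axis=1)
    pj = p.sum(axis=0)
    nz = p > 0
    outer = np.outer(pi, pj)
    return float((p[nz] * np.log2(p[nz] / outer[nz])).sum())


def column_mi(
    col_i: Iterable,
    col_j: Iterable,
    pseudocount: float = 0.0,
    weights: np.ndarray | None = None,
    gap_as_symbol: bool = False,
) -> float:
    """Mutual information (bits) between two aligned columns.

    Rows gapped at either column are dropped pairwise unless
    ``gap_as_symbol`` treats the gap as a 21st letter.  ``pseudocount`` adds
    a uniform weight to every cell of the full joint table.  Raises
    ``insufficient coverage`` when fewer than two usable rows remain.
    """
    a = _encode(col_i)
    b = _encode(col_j)
    if a.shape != b.shape:
        raise ValueError("columns must have equal length")
    if weights is None:
        w = np.ones(a.shape[0])
    else:
        w = np.asarray(weights, dtype=float)
    k = 21 if gap_as_symbol else 20
    if not gap_as_symbol:
        mask = (a != GAP_CODE) & (b != GAP_CODE)
        a, b, w = a[mask], b[mask], w[mask]
    if a.size < 2:
        raise ValueError("insufficient coverage")
    counts = np.zeros((k, k))
    np.add.at(counts, (a, b), w)
    if pseudocount:
        counts = counts + pseudocount
    return _mi_bits(counts)


def mi_matrix(
    codes: np.ndarray,
    pseudocount: float = 0.0,
    weights: np.ndarray | None = None,
    gap_as_symbol: bool = False,
) -> np.ndarray:
    """Symmetric raw-MI matrix over the columns of an encoded alignment.

    Pairs with insufficient pairwise coverage are flagged NaN and excluded
    from all downstream statistics.  Diagonal is NaN (self-pairs carry no
    covariation information).
    """
    n, p = codes.shape
    if weights is None:
        weights = np.ones(n)
    out = np.full((p, p), np.nan)
    gap = codes == GAP_CODE
    k = 21 if gap_as_symbol else 20
    for i in range(p):
        ai = codes[:, i]
        for j in range(i + 1, p):
            aj = codes[:, j]
            if gap_as_symbol:
                a, b, w = ai, aj, weights
            else:
                mask = ~(gap[:, i] | gap[:, j])
                a, b, w = ai[mask], aj[mask], weights[mask]
            if a.size < 2:
                continue  # insufficient coverage: leave NaN
            counts = np.zeros((k, k))
            np.add.at(counts, (a, b), w)
            if pseudocount:
                counts = counts + pseudocount
            out[i, j] = out[j, i] = _mi_bits(counts)
    return out


def product_correction(raw_mi: np.ndarray) -> np.ndarray:
    """Average-product correction: corrected = MI − MI(i,·)·MI(·,j)/⟨MI⟩.

    Row means and the overall mean are taken over off-diagonal finite
    entries.  A constant off-diagonal matrix corrects to exactly zero; an
    all-zero matrix is defined to correct to all zeros.  The corrected
    matrix may be negative; the diagonal is zero.
    """
    M = np.asarray(raw_mi, dtype=float).copy()
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError("raw_mi must be a square matrix")
    np.fill_diagonal(M, np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows
        row_mean = np.nanmean(M, axis=1)
        overall = np.nanmean(M)
    corrected = np.zeros_like(M)
    if np.isfinite(overall) and overall != 0:
        apc = np.outer(row_mean, row_mean) / overall
        corrected = M - apc
    else:
        corrected = np.zeros_like(M)
        corrected[np.isnan(M)] = np.nan
    np.fill_diagonal(corrected, 0.0)
    return corrected


def _offdiag_upper(p: int) -> tuple[np.ndarray, np.ndarray]:
    return np.triu_indices(p, k=1)


def significance(
    corrected: np.ndarray,
    threshold: float = DEFAULT_Z_THRESHOLD,
) -> tuple[np.ndarray, np.ndarray]:
    """Global z-scores of corrected MI and the significant-pair mask.

    z(i,j) = (corrected(i,j) − mean) / sd over all finite off-diagonal
    pairs (sample sd).  A pair is significant iff z ≥ threshold.  With zero
    spread a ``DegenerateScoreDistribution`` warning is emitted and no pair
    is significant.
    """
    p = corrected.shape[0]
    iu, ju = _offdiag_upper(p)
    vals = corrected[iu, ju]
    finite = np.isfinite(vals)
    z = np.full_like(corrected, np.nan, dtype=float)
    if finite.sum() < 2:
        warnings.warn(
            "degenerate score distribution", DegenerateScoreDistribution
        )
        return z, np.zeros_like(corrected, dtype=bool)
    mean = vals[finite].mean()
    sd = vals[finite].std(ddof=1)
    if sd == 0:
        warnings.warn(
            "degenerate score distribution", DegenerateScoreDistribution
        )
        return z, np.zeros_like(corrected, dtype=bool)
    zvals = (corrected - mean) / sd
    off = ~np.eye(p, dtype=bool)
    z[off] = zvals[off]
    sig = np.zeros_like(corrected, dtype=bool)
    with np.errstate(invalid="ignore"):
        sig[off] = z[off] >= threshold
    return z, sig


def rank_pairs(corrected: np.ndarray) -> np.ndarray:
    """Percentile ranks (0–100] of off-diagonal pairs by corrected score.

    Higher score → higher percentile; tied scores share their mean rank, so
    three distinct scores land at 33.3/66.7/100 and an all-tied matrix puts
    every pair at the single shared rank.  NaN (excluded) pairs stay NaN.
    """
    p = corrected.shape[0]
    iu, ju = _offdiag_upper(p)
    vals = corrected[iu, ju]
    finite = np.isfinite(vals)
    out = np.full_like(corrected, np.nan, dtype=float)
    if finite.sum() == 0:
        return out
    ranks = rankdata(vals[finite], method="average")
    pct = 100.0 * ranks / finite.sum()
    full = np.full(vals.shape, np.nan)
    full[finite] = pct
    out[iu, ju] = full
    out[ju, iu] = full
    return out


def top_fraction_indices(
    scores: np.ndarray, fraction: float
) -> np.ndarray:
    """Indices of the top ``ceil(fraction · n)`` scores, descending, with all
    boundary ties included.  NaN scores never qualify."""
    scores = np.asarray(scores, dtype=float)
    finite = np.isfinite(scores)
    m = int(finite.sum())
    if m == 0 or fraction <= 0:
        return np.empty(0, dtype=int)
    k = min(m, math.ceil(fraction * m))
    order = np.argsort(np.where(finite, scores, -np.inf))[::-1]
    cutoff = scores[order[k - 1]]
    sel = finite & (scores >= cutoff)
    return np.flatnonzero(sel)[np.argsort(-scores[sel], kind="stable")]


@dataclasses.dataclass(frozen=True)
class CovariationResult:
    """Pairwise covariation statistics for one alignment.

    All matrices are symmetric with the diagonal excluded; matrix axis *k*
    corresponds to reference residue number ``columns[k]``.
    """

    group_label: str
    columns: np.ndarray
    raw_mi: np.ndarray
    corrected_mi: np.ndarray
    zscores: np.ndarray
    percentile_rank: np.ndarray
    significant: np.ndarray
    significance_threshold: float = DEFAULT_Z_THRESHOLD
    units: str = "bits"
    n_sequences: int = 0

    @property
    def n_positions(self) -> int:
        return len(self.columns)

    def pair_table(self) -> pd.DataFrame:
        """Long-form table of off-diagonal pairs (reference-numbered)."""
        iu, ju = _offdiag_upper(self.n_positions)
        return pd.DataFrame(
            {
                "pos_i": self.columns[iu],
                "pos_j": self.columns[ju],
                "raw_mi": self.raw_mi[iu, ju],
                "corrected_mi": self.corrected_mi[iu, ju],
                "z": self.zscores[iu, ju],
                "percentile": self.percentile_rank[iu, ju],
                "significant": self.significant[iu, ju],
            }
        )

    def significant_pairs(self) -> pd.DataFrame:
        t = self.pair_table()
        return t[t["significant"]].reset_index(drop=True)

    def significant_fraction(self) -> float:
        """Fraction of analysable pairs that reach the z threshold."""
        t = self.pair_table()
        finite = np.isfinite(t["corrected_mi"])
        if finite.sum() == 0:
            return 0.0
        return float(t.loc[finite, "significant"].mean())

    def matrix_to_tsv(self, which: str, path: str | Path) -> None:
        mat = getattr(self, which)
        pd.DataFrame(mat, index=self.columns, columns=self.columns).to_csv(
            path, sep="\t", index_label="position"
        )

    def pairs_to_tsv(self, path: str | Path) -> None:
        self.pair_table().to_csv(path, sep="\t", index=False)


def covariation_analysis(
    alignment: AlignedDomainSet,
    landmark_map: LandmarkMap,
    threshold: float = DEFAULT_Z_THRESHOLD,
    max_gap_fraction: float = 0.5,
    pseudocount: float = 0.0,
    gap_as_symbol: bool = False,
    weights: np.ndarray | None = None,
) -> CovariationResult:
    """Full covariation pipeline for one alignment.

    Restricts to reference-mapped columns with gap fraction ≤
    ``max_gap_fraction``, computes raw MI, applies the average-product
    correction, and derives z-scores and percentile ranks.
    """
    if alignment.n_sequences < 2:
        raise ValueError("insufficient coverage")
    codes = alignment.to_codes()
    cols = [c for c in landmark_map.mapped_columns if c < alignment.n_columns]
    gapfrac = (codes[:, cols] == GAP_CODE).mean(axis=0)
    kept = [c for c, g in zip(cols, gapfrac) if g <= max_gap_fraction]
    if len(kept) < 2:
        raise ValueError("fewer than two analysable columns")
    sub = codes[:, kept]
    raw = mi_matrix(
        sub,
        pseudocount=pseudocount,
        weights=weights,
        gap_as_symbol=gap_as_symbol,
    )
    corrected = product_correction(raw)
    z, sig = significance(corrected, threshold)
    pct = rank_pairs(corrected)
    refnums = np.array([landmark_map.reference_number(c) for c in kept])
    return CovariationResult(
        group_label=alignment.group_label,
        columns=refnums,
        raw_mi=raw,
        corrected_mi=corrected,
        zscores=z,
        percentile_rank=pct,
        significant=sig,
        significance_threshold=threshold,
        n_sequences=alignment.n_sequences,
    )


@dataclasses.dataclass(frozen=True)
class RankShiftTable:
    """Between-group rank-shift comparison over a shared column set.

    ``table`` holds the selected pairs (top ``top_fraction`` of significant
    pairs by |shift|, zero shifts excluded); ``all_significant`` holds every
    pair significant in at least one group.  shift = receiver percentile −
    PsR percentile: positive means relatively stronger covariation in
    receivers.
    """

    table: pd.DataFrame
    all_significant: pd.DataFrame
    top_fraction: float
    receiver_label: str
    psr_label: str

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(
                "# shift = percentile rank in "
                f"{self.receiver_label} minus percentile rank in {self.psr_label}; "
                "positive = stronger in the first group\n"
            )
            self.table.to_csv(fh, sep="\t", index=False)


def rank_shift(
    cov_receiver: CovariationResult,
    cov_psr: CovariationResult,
    top_fraction: float = 0.02,
) -> RankShiftTable:
    """Rank-shift table between two covariation results.

    Both results must cover the identical reference column set (the PsR
    alignment is built on receiver-anchored columns precisely so pairs are
    directly comparable).  Pairs significant (z ≥ threshold) in at least one
    group are ranked by |shift| and the top ``top_fraction`` retained,
    boundary ties included; pairs whose shift is exactly zero are never
    selected.
    """
    a, b = cov_receiver, cov_psr
    if a.n_positions != b.n_positions or not np.array_equal(a.columns, b.columns):
        raise ValueError("alignments not comparable")
    iu, ju = _offdiag_upper(a.n_positions)
    df = pd.DataFrame(
        {
            "pos_i": a.columns[iu],
            "pos_j": a.columns[ju],
            "rank_receiver": a.percentile_rank[iu, ju],
            "rank_psr": b.percentile_rank[iu, ju],
            "sig_receiver": a.significant[iu, ju],
            "sig_psr": b.significant[iu, ju],
        }
    )
    df["shift"] = df["rank_receiver"] - df["rank_psr"]
    df["significant_in"] = [
        ",".join(
            g
            for g, s in (("receiver", sr), ("psr", sp))
            if s
        )
        for sr, sp in zip(df["sig_receiver"], df["sig_psr"])
    ]
    sig = df[(df["sig_receiver"] | df["sig_psr"])].copy()
    sig = sig[np.isfinite(sig["shift"])]
    candidates = sig[sig["shift"] != 0]
    if len(candidates):
        idx = top_fraction_indices(
            candidates["shift"].abs().to_numpy(), top_fraction
        )
        selected = candidates.iloc[idx].copy()
    else:
        selected = candidates.copy()
    keep = [
        "pos_i",
        "pos_j",
        "rank_receiver",
        "rank_psr",
        "shift",
        "significant_in",
    ]
    return RankShiftTable(
        table=selected[keep].reset_index(drop=True),
        all_significant=sig[keep].reset_index(drop=True),
        top_fraction=top_fraction,
        receiver_label=a.group_label,
        psr_label=b.group_label,
    )
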