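"""Per-column conservation and bootstrap divergence statistics.

Conservation of a region of the alignment is summarized two ways:

* a per-column profile (residue counts and information content in bits,
  the quantity a sequence logo draws), and
* a bootstrap divergence distribution: resample the region's columns with
  replacement, and for each replicate take the mean over all unordered
  sequence pairs of the pairwise p-distance (mismatch proportion with
  pairwise gap deletion) restricted to the resampled columns.  Low values
  mean high conservation; box plots of these distributions are the standard
  region-vs-region comparison, tested nonparametrically (Mann-Whitney U for
  two regions, Kruskal-Wallis for several).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError
from .seq_io import AA_ALPHABET, GAP, AlignedSet

_GAP_CODE = ord(GAP)


@dataclass
class DivergenceProfile:
    """Bootstrap distribution of mean pairwise p-distance for one region."""

    region_label: str
    replicates: np.ndarray
    n_replicates: int
    seed: int

    @property
    def median(self) -> float:
        return float(np.median(self.replicates))

    @property
    def q1(self) -> float:
        return float(np.percentile(self.replicates, 25))

    @property
    def q3(self) -> float:
        return float(np.percentile(self.replicates, 75))


def pairwise_p_distance(
    a: str, b: str, columns: Sequence[int] | None = None
) -> float:
    """Mismatch proportion between two gapped sequences over given columns.

    Columns where either sequence has a gap are excluded from both numerator
    and denominator (pairwise deletion).  Returns NaN when no column is
    comparable.  ``columns`` are 1-based alignment columns; default all.
    """
    if len(a) != len(b):
        raise InputError(f"sequence lengths differ: {len(a)} vs {len(b)}")
    cols = range(1, len(a) + 1) if columns is None else columns
    compared = mismatches = 0
    for c in cols:
        x, y = a[c - 1], b[c - 1]
        if x == GAP or y == GAP:
            continue
        compared += 1
        if x != y:
            mismatches += 1
    return mismatches / compared if compared else float("nan")


def _encode(aln: AlignedSet, columns: Sequence[int]) -> np.ndarray:
    return np.array(
        [[ord(rec.sequence[c - 1]) for c in columns] for rec in aln.records],
        dtype=np.int16,
    )


def bootstrap_divergence(
    aln: AlignedSet,
    columns: Sequence[int],
    n_replicates: int = 1000,
    seed: int = 0,
    region_label: str = "",
) -> DivergenceProfile:
    """Bootstrap the mean pairwise p-distance over a column set.

    Each replicate draws ``len(columns)`` columns with replacement from
    ``columns``, computes every unordered pair's p-distance on the resampled
    columns (pairwise gap deletion), and averages over pairs with at least
    one comparable column.  Deterministic for a fixed seed.
    """
    if aln.n_sequences < 2:
        raise InputError("bootstrap_divergence needs at least 2 sequences")
    columns = list(columns)
    if not columns:
        raise InputError("bootstrap_divergence needs at least 1 column")
    bad = [c for c in columns if not 1 <= c <= aln.n_columns]
    if bad:
        raise InputError(f"columns outside alignment 1..{aln.n_columns}: {bad[:5]}")

    mat = _encode(aln, columns)  # (n_seq, n_col)
    ii, jj = np.triu_indices(aln.n_sequences, k=1)
    nongap = mat != _GAP_CODE
    comparable = nongap[ii] & nongap[jj]  # (n_pair, n_col)
    mismatch = (mat[ii] != mat[jj]) & comparable

    rng = np.random.default_rng(seed)
    n_col = len(columns)
    reps = np.empty(n_replicates, dtype=float)
    for r in range(n_replicates):
        idx = rng.integers(0, n_col, size=n_col)
        num = mismatch[:, idx].sum(axis=1)
        den = comparable[:, idx].sum(axis=1)
        with np.errstate(invalid="ignore"):
            per_pair = np.where(den > 0, num / np.maximum(den, 1), np.nan)
        reps[r] = float(np.nanmean(per_pair)) if np.any(den > 0) else float("nan")
    return DivergenceProfile(
        region_label=region_label, replicates=reps, n_replicates=n_replicates, seed=seed
    )


def column_profiles(aln: AlignedSet) -> pd.DataFrame:
    """Residue counts, gap count and information content per alignment column.

    The returned frame (one row per column, 1-based ``column`` index) is the
    logo matrix: counts for the 20 canonical residues, ``gap_count``, and
    ``information_content`` = log2(20) − Shannon entropy of the column's
    residue distribution, gaps excluded, no small-sample correction.
    All-gap columns get NaN information content.
    """
    rows = []
    for c in range(1, aln.n_columns + 1):
        col = [rec.sequence[c - 1] for rec in aln.records]
        counts = {aa: 0 for aa in AA_ALPHABET}
        gaps = 0
        for ch in col:
            if ch == GAP:
                gaps += 1
            elif ch in counts:
                counts[ch] += 1
        rows.append({"column": c, **counts, "gap_count": gaps,
                     "information_content": information_content(counts)})
    return pd.DataFrame(rows)


def information_content(counts) -> float:
    """log2(20) minus the Shannon entropy of a column's residue counts.

    ``counts`` is a mapping or sequence of per-residue counts (gaps already
    excluded).  A fully conserved column scores log2(20) ≈ 4.32 bits, a
    uniform column 0; an empty column returns NaN.
    """
    vals = np.asarray(
        list(counts.values()) if hasattr(counts, "values") else counts, dtype=float
    )
    total = vals.sum()
    if total <= 0:
        return float("nan")
    p = vals[vals > 0] / total
    entropy = float(-(p * np.log2(p)).sum())
    return math.log2(len(AA_ALPHABET)) - entropy


@dataclass(frozen=True)
class MannWhitneyResult:
    U: float
    p: float
    method: str


@dataclass(frozen=True)
class KruskalResult:
    H: float
    p: float


def mann_whitney_u(
    x: Sequence[float], y: Sequence[float], alternative: str = "two-sided"
) -> MannWhitneyResult:
    """Mann-Whitney U test of two independent samples.

    The p-value is computed by exact enumeration of the U distribution when
    the combined sample size is ≤ 12 and no ties are present, and by the
    normal approximation with tie and continuity corrections otherwise.
    ``U`` is the U statistic of the first sample.
    """
    x, y = list(x), list(y)
    if not x or not y:
        raise InputError("mann_whitney_u requires non-empty samples")
    has_ties = len(set(x) | set(y)) < len(x) + len(y)
    method = "exact" if (len(x) + len(y) <= 12 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative=alternative, method=method)
    return MannWhitneyResult(U=float(res.statistic), p=float(res.pvalue), method=method)


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> KruskalResult:
    """Kruskal-Wallis rank test (tie-corrected H, chi-square p-value)."""
    if len(groups) < 2:
        raise InputError("kruskal_wallis requires at least 2 groups")
    if any(len(g) == 0 for g in groups):
        raise InputError("kruskal_wallis requires every group to be non-empty")
    flat = {v for g in groups for v in g}
    if len(flat) == 1:
        # all observations identical: no rank variation at all
        return KruskalResult(H=0.0, p=1.0)
    res = stats.kruskal(*groups)
    return KruskalResult(H=float(res.statistic), p=float(res.pvalue))


def divergence_table(profiles: Sequence[DivergenceProfile]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "region": [p.region_label for p in profiles],
            "median": [p.median for p in profiles],
            "q1": [p.q1 for p in profiles],
            "q3": [p.q3 for p in profiles],
            "n_replicates": [p.n_replicates for p in profiles],
            "seed": [p.seed for p in profiles],
        }
    )
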