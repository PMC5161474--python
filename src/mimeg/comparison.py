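"""Accuracy tables and the statistics comparing feature-extraction methods.

An :class:`AccuracyTable` holds per-session (rows) x per-method (columns)
accuracies in percent.  On top of it:

* :func:`friedman_test` — the rank-based test for differences among the
  methods over matched sessions.  With ``replicates=1`` each row is ranked
  separately (classic Friedman).  With ``replicates=2`` the two sessions of
  each subject form one block whose ``2k`` observations are ranked
  *jointly* and the statistic generalizes to

      chi2 = 12 * sum_j (R_j - E)^2 / (n m^2 k (m k + 1)),

  with ``n`` blocks, ``m`` replicates, ``k`` methods, ``R_j`` the rank sum
  of method ``j`` and ``E = n m (m k + 1) / 2`` — which reduces to the
  classic statistic at ``m = 1``.  Ties get mean ranks; by default no
  tie-correction divisor is applied (matching the common software lineage),
  and ``tie_correction=True`` exposes the corrected variant.
* :func:`bonferroni_posthoc` — pairwise mean-rank z-tests with Bonferroni
  adjustment.
* :func:`paired_onesided_ttests` — the one-sided paired t-test matrix over
  matched per-fold accuracies ("method a better than method b").
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats

__all__ = ["AccuracyTable", "StatsResult", "aggregate_results",
           "friedman_test", "bonferroni_posthoc", "paired_onesided_ttests",
           "replicate_pairs"]


@dataclass
class AccuracyTable:
    """Session-by-method accuracies in percent, plus optional replicate
    grouping (pairs of rows belonging to the same subject)."""

    values: pd.DataFrame
    replicate_groups: list[tuple[str, ...]] | None = None

    def __post_init__(self) -> None:
        arr = self.values.to_numpy(float)
        if np.any(~np.isfinite(arr)):
            raise ValueError("accuracy table has missing cells")
        if np.any((arr < 0) | (arr > 100)):
            raise ValueError("accuracies must lie in [0, 100] percent")

    @property
    def methods(self) -> list[str]:
        return list(self.values.columns)

    @property
    def sessions(self) -> list[str]:
        return list(self.values.index)

    def column_means(self) -> pd.Series:
        return self.values.mean(axis=0)

    def row_means(self) -> pd.Series:
        return self.values.mean(axis=1)

    def grand_mean(self) -> float:
        return float(self.values.to_numpy().mean())

    # -- TSV round trip ---------------------------------------------------
    @classmethod
    def from_tsv(cls, path_or_buffer) -> "AccuracyTable":
        """Read a TSV with sessions as the first column; decimal commas and
        points are both accepted."""
        if isinstance(path_or_buffer, str) and "\t" in path_or_buffer:
            path_or_buffer = io.StringIO(path_or_buffer)
        df = pd.read_csv(path_or_buffer, sep="\t", index_col=0, dtype=str,
                         comment="#")
        df = df.map(lambda v: float(re.sub(",", ".", str(v).strip())))
        return cls(values=df)

    def to_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t", float_format="%.1f")


def aggregate_results(records) -> AccuracyTable:
    """Build an AccuracyTable (percent) from CVResult-like records; every
    session must report the same method set."""
    cells: dict[str, dict[str, float]] = {}
    for r in records:
        cells.setdefault(r.session_id, {})[r.method] = 100 * r.mean_accuracy
    df = pd.DataFrame(cells).T
    if df.isna().any().any():
        raise ValueError("ragged input: sessions report different methods")
    return AccuracyTable(values=df)


def replicate_pairs(table: AccuracyTable,
                    subject_of=lambda s: str(s)[:-1]) -> AccuracyTable:
    """Group rows into two-session subject blocks (rows like '4A'/'4B'),
    dropping subjects with a single session; row order is preserved."""
    from collections import defaultdict
    groups = defaultdict(list)
    for s in table.sessions:
        groups[subject_of(s)].append(s)
    pairs = [tuple(v) for v in groups.values() if len(v) == 2]
    keep = [s for pair in pairs for s in pair]
    return AccuracyTable(values=table.values.loc[keep],
                         replicate_groups=pairs)


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------

@dataclass
class StatsResult:
    friedman_chi2: float
    df: int
    p: float
    mean_ranks: pd.Series
    n_blocks: int
    replicates: int
    tie_correction: bool
    posthoc_p: pd.DataFrame | None = None
    ttest_p: pd.DataFrame | None = None


def _block_ranks(X: np.ndarray, replicates: int):
    """Rank sums per method with joint within-block ranking.

    ``X`` rows are ordered block-major (the ``replicates`` rows of a block
    are consecutive).  Returns (rank sums R_j, tie term sum(t^3 - t))."""
    n_rows, k = X.shape
    Rj = np.zeros(k)
    tie_term = 0.0
    for b in range(n_rows // replicates):
        block = X[b * replicates:(b + 1) * replicates]
        ranks = sstats.rankdata(block.ravel()).reshape(replicates, k)
        Rj += ranks.sum(axis=0)
        _, counts = np.unique(block.ravel(), return_counts=True)
        tie_term += float(np.sum(counts ** 3 - counts))
    return Rj, tie_term


def friedman_test(table: AccuracyTable, replicates: int = 1,
                  tie_correction: bool = False) -> StatsResult:
    """Friedman test over the table, optionally with two observations per
    subject-method cell (see module docstring for the statistic)."""
    X = table.values.to_numpy(float)
    n_rows, k = X.shape
    if replicates not in (1, 2):
        raise ValueError("replicates must be 1 or 2")
    if replicates > 1:
        if table.replicate_groups is not None:
            order = [s for pair in table.replicate_groups for s in pair]
            X = table.values.loc[order].to_numpy(float)
            n_rows = X.shape[0]
        if n_rows % replicates:
            raise ValueError("row count is not a multiple of replicates; "
                             "provide replicate_groups or drop odd rows")
    m = replicates
    n = n_rows // m
    Rj, tie_term = _block_ranks(X, m)
    q = m * k                       # items ranked per block
    E = n * m * (q + 1) / 2.0
    chi2 = 12.0 * np.sum((Rj - E) ** 2) / (n * m ** 2 * k * (q + 1))
    if tie_correction:
        denom = 1.0 - tie_term / (n * q * (q ** 2 - 1))
        if denom <= 0:
            raise ValueError("degenerate table: all values tied")
        chi2 /= denom
    df = k - 1
    return StatsResult(friedman_chi2=float(chi2), df=df,
                       p=float(sstats.chi2.sf(chi2, df)),
                       mean_ranks=pd.Series(Rj / (n * m),
                                            index=table.methods),
                       n_blocks=n, replicates=m,
                       tie_correction=tie_correction)


def bonferroni_posthoc(stats: StatsResult) -> pd.DataFrame:
    """Pairwise mean-rank comparisons after a Friedman test.

    Normal approximation of the mean-rank difference with
    ``SE = sqrt(k (m k + 1) / (6 n))``; two-sided p multiplied by the
    number of pairs, capped at 1.
    """
    ranks = stats.mean_ranks
    k, n, m = len(ranks), stats.n_blocks, stats.replicates
    se = np.sqrt(k * (m * k + 1) / (6.0 * n))
    n_pairs = k * (k - 1) // 2
    methods = list(ranks.index)
    out = pd.DataFrame(np.ones((k, k)), index=methods, columns=methods)
    for i in range(k):
        for j in range(i + 1, k):
            z = abs(ranks.iloc[i] - ranks.iloc[j]) / se
            p = min(1.0, 2.0 * sstats.norm.sf(z) * n_pairs)
            out.iloc[i, j] = out.iloc[j, i] = p
    stats.posthoc_p = out
    return out


def paired_onesided_ttests(fold_accuracies: dict[str, np.ndarray]
                           ) -> pd.DataFrame:
    """One-sided paired t-tests over matched fold accuracies.

    Entry (a, b) is the p-value for the alternative "method a yields better
    results than method b", from the upper tail of the paired t statistic
    on the differences a - b.  Zero-variance, zero-mean differences give
    p = 0.5 (t = 0); zero-variance nonzero differences are degenerate and
    map to p of 0 or 1 with a warning.
    """
    import warnings

    methods = list(fold_accuracies)
    vecs = {m: np.asarray(v, float) for m, v in fold_accuracies.items()}
    n = len(next(iter(vecs.values())))
    if any(len(v) != n for v in vecs.values()):
        raise ValueError("fold vectors must be matched in length")
    out = pd.DataFrame(np.nan, index=methods, columns=methods)
    for a in methods:
        for b in methods:
            if a == b:
                continue
            d = vecs[a] - vecs[b]
            sd = d.std(ddof=1)
            if sd == 0:
                if np.mean(d) == 0:
                    p = 0.5
                else:
                    warnings.warn(f"degenerate zero-variance difference "
                                  f"({a} vs {b})", RuntimeWarning)
                    p = 0.0 if np.mean(d) > 0 else 1.0
            else:
                t = np.mean(d) / (sd / np.sqrt(n))
                p = float(sstats.t.sf(t, n - 1))
            out.loc[a, b] = p
    return out
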