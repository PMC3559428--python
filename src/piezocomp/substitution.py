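"""Directional amino-acid substitution counting and asymmetry testing.

Over the ungapped columns of a set of aligned ortholog pairs, the directed
substitution matrix M counts, for every ordered residue pair (a, b), the
columns where the reference organism (matrix rows) carries a and the
comparison organism (columns) carries b; the diagonal holds conserved
positions. For each unordered pair {a, b} the two directed counts
x = M[a][b] and y = M[b][a] are tested against the 50:50 ratio expected in
the absence of directional pressure with the one-degree-of-freedom
goodness-of-fit statistic chi2 = (x - y)^2 / (x + y). An exact binomial
alternative (mid-p by default, whose large-sample limit is the uncorrected
chi-square) is available both as an option and as a test oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .alphabet import AA_INDEX, AA_ORDER, GAP, encode
from .orthology import OrthologSet

DEFAULT_ALPHA = 0.0005


@dataclass
class DirectedSubstitutionMatrix:
    """20x20 residue-state count table over ungapped alignment columns.

    ``counts[i, j]`` is the number of columns with row-organism state
    ``AA_ORDER[i]`` and column-organism state ``AA_ORDER[j]``.
    """

    counts: np.ndarray
    row_organism: str = "A"
    col_organism: str = "B"

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (20, 20):
            raise ValueError("counts must be a 20x20 table")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        """Grand total = number of ungapped columns analysed."""
        return int(self.counts.sum())

    def count(self, a: str, b: str) -> int:
        """Directed count of row-state ``a`` against column-state ``b``."""
        return int(self.counts[AA_INDEX[a], AA_INDEX[b]])

    def transpose(self) -> "DirectedSubstitutionMatrix":
        return DirectedSubstitutionMatrix(
            self.counts.T.copy(), self.col_organism, self.row_organism
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=list(AA_ORDER), columns=list(AA_ORDER)
        )

    @classmethod
    def from_frame(
        cls, frame: pd.DataFrame, row_organism: str = "A", col_organism: str = "B"
    ) -> "DirectedSubstitutionMatrix":
        missing = set(AA_ORDER) - set(frame.index) | set(AA_ORDER) - set(frame.columns)
        if missing:
            raise ValueError(f"matrix table missing residues {sorted(missing)}")
        ordered = frame.loc[list(AA_ORDER), list(AA_ORDER)]
        return cls(ordered.to_numpy(dtype=np.int64), row_organism, col_organism)


def count_substitutions(
    orthologs: OrthologSet,
    row_organism: str = "A",
    col_organism: str = "B",
) -> DirectedSubstitutionMatrix:
    """Build the directed substitution matrix from aligned ortholog pairs.

    Only columns without a gap in either row are counted; columns containing
    any non-canonical letter (e.g. the ambiguity letter X of lenient mode)
    are likewise excluded, so the grand total is the number of fully
    canonical ungapped columns. An empty ortholog set yields the all-zero
    matrix.
    """
    counts = np.zeros((20, 20), dtype=np.int64)
    for pair in orthologs.pairs:
        a = encode(pair.aligned_a)
        b = encode(pair.aligned_b)
        keep = (a >= 0) & (b >= 0)  # gaps and non-canonical letters map to -1
        if keep.any():
            flat = np.bincount(
                a[keep].astype(np.int64) * 20 + b[keep].astype(np.int64),
                minlength=400,
            )
            counts += flat.reshape(20, 20)
    return DirectedSubstitutionMatrix(counts, row_organism, col_organism)


@dataclass(frozen=True)
class AsymmetryTestResult:
    """Outcome of one binary-exchange asymmetry test.

    ``x`` is the directed count a→b (row-organism state a, column-organism
    state b), ``y`` the reverse. ``direction`` names the residue gaining net
    counts in the comparison organism (None for x == y or x + y == 0).
    """

    a: str
    b: str
    x: int
    y: int
    chi2: float
    p_value: float
    significant: bool
    direction: str | None


def chi_square_asymmetry(
    x: int,
    y: int,
    a: str = "a",
    b: str = "b",
    alpha: float = DEFAULT_ALPHA,
    method: str = "chi2",
) -> AsymmetryTestResult:
    """Test the directed counts of one residue pair against a 50:50 ratio.

    ``method='chi2'`` uses chi2 = (x-y)^2/(x+y) with the 1-df upper tail and
    no continuity correction. ``method='binomial-midp'`` is the exact
    two-sided mid-p binomial test (half weight on the observed outcome),
    whose large-sample limit is the uncorrected chi-square;
    ``method='binomial'`` is the conventional minimum-likelihood exact test.
    x + y = 0 leaves the test undefined and is reported as p = 1.
    """
    if x < 0 or y < 0:
        raise ValueError("counts must be non-negative")
    if int(x) != x or int(y) != y:
        raise ValueError("counts must be integers")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    x, y = int(x), int(y)
    n = x + y
    if n == 0:
        return AsymmetryTestResult(a, b, x, y, 0.0, 1.0, False, None)
    chi2 = (x - y) ** 2 / n
    if method == "chi2":
        p = float(stats.chi2.sf(chi2, df=1))
    elif method == "binomial-midp":
        p = _binomial_midp(x, n)
    elif method == "binomial":
        p = float(stats.binomtest(x, n, 0.5).pvalue)
    else:
        raise ValueError(f"unknown method {method!r}")
    direction = b if x > y else (a if y > x else None)
    return AsymmetryTestResult(a, b, x, y, float(chi2), p, p < alpha, direction)


def _binomial_midp(x: int, n: int) -> float:
    """Two-sided mid-p exact binomial p-value at p0 = 0.5."""
    lo = stats.binom.cdf(x, n, 0.5) - 0.5 * stats.binom.pmf(x, n, 0.5)
    hi = stats.binom.sf(x - 1, n, 0.5) - 0.5 * stats.binom.pmf(x, n, 0.5)
    return float(min(1.0, 2.0 * min(lo, hi)))


def test_all_pairs(
    m: DirectedSubstitutionMatrix,
    alpha: float = DEFAULT_ALPHA,
    method: str = "chi2",
    correction: str | None = None,
) -> list[AsymmetryTestResult]:
    """Asymmetry tests for all 190 unordered residue pairs.

    By default no multiple-testing correction is applied, i.e. the raw
    per-pair threshold ``alpha`` is used; ``correction`` may be
    ``'bonferroni'`` or ``'fdr_bh'``. Results are sorted by ascending
    p-value, ties broken by residue-pair order for determinism.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    results = []
    for i, a in enumerate(AA_ORDER):
        for b in AA_ORDER[i + 1 :]:
            results.append(
                chi_square_asymmetry(
                    m.count(a, b), m.count(b, a), a=a, b=b, alpha=alpha, method=method
                )
            )
    if correction is not None:
        from statsmodels.stats.multitest import multipletests

        reject, p_adj, _, _ = multipletests(
            [r.p_value for r in results], alpha=alpha, method=correction
        )
        results = [
            AsymmetryTestResult(
                r.a, r.b, r.x, r.y, r.chi2, float(p), bool(rej), r.direction
            )
            for r, p, rej in zip(results, p_adj, reject)
        ]
    return sorted(results, key=lambda r: (r.p_value, r.a, r.b))


def results_to_frame(results: list[AsymmetryTestResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "a": [r.a for r in results],
            "b": [r.b for r in results],
            "x": [r.x for r in results],
            "y": [r.y for r in results],
            "chi2": [r.chi2 for r in results],
            "p": [r.p_value for r in results],
            "significant": [r.significant for r in results],
            "direction": [r.direction if r.direction else "" for r in results],
        }
    )


@dataclass
class ReplacementSummary:
    """Per-residue replacement bookkeeping derived from the matrix.

    ``table`` has one row per residue with columns: ``replaced`` (row
    off-diagonal total: columns where the reference state was this residue
    and the comparison organism differs), ``gained`` (column off-diagonal
    total), ``net_excess`` (replaced - gained) and ``net_excess_pct``
    (100 * net_excess / full row total, conserved positions included).
    ``preferred_acceptors`` lists residues that are the significant gaining
    direction in at least ``min_pairs`` exchange pairs.
    """

    table: pd.DataFrame
    preferred_acceptors: list[str] = field(default_factory=list)


def replacement_summary(
    m: DirectedSubstitutionMatrix,
    results: list[AsymmetryTestResult],
    min_pairs: int = 3,
) -> ReplacementSummary:
    """Summarise which residues are preferentially lost or gained."""
    c = m.counts.astype(float)
    diag = np.diag(c)
    row_off = c.sum(axis=1) - diag
    col_off = c.sum(axis=0) - diag
    row_total = c.sum(axis=1)
    net = row_off - col_off
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = np.where(row_total > 0, 100.0 * net / row_total, np.nan)
    table = pd.DataFrame(
        {
            "replaced": row_off.astype(int),
            "gained": col_off.astype(int),
            "net_excess": net.astype(int),
            "net_excess_pct": pct,
        },
        index=list(AA_ORDER),
    )
    acceptor_hits: dict[str, int] = {}
    for r in results:
        if r.significant and r.direction is not None:
            acceptor_hits[r.direction] = acceptor_hits.get(r.direction, 0) + 1
    acceptors = sorted(aa for aa, k in acceptor_hits.items() if k >= min_pairs)
    return ReplacementSummary(table=table, preferred_acceptors=acceptors)
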