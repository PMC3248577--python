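"""Differential expression, peak-to-gene linking and enrichment tests.

The DE caller is a vectorized per-gene Welch two-sample t-test on log2
expression with Benjamini-Hochberg adjustment; it stands in for a
moderated-t pipeline, and externally produced gene lists can be supplied
instead wherever a gene set is consumed. A cell line's *candidate DE
genes* are those DE against both other lines but not DE between those two.
Genes are linked to peaks through a fixed window (default 20 kb) on either
side of the TSS; enrichment of DE genes among peak-proximal genes uses
Fisher's exact test, and proximity fractions of two peak classes are
compared with a 1-df chi-squared test without continuity correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .annotate import GeneModel
from .intervals import PeakSet

DEFAULT_TSS_WINDOW = 20_000
DEFAULT_ALPHA = 0.01


@dataclass
class ExpressionTable:
    """Genes x samples log2 expression with a sample -> (line, replicate) map."""

    values: pd.DataFrame  # index: gene_id, columns: sample_id
    sample_lines: dict[str, str]
    sample_reps: dict[str, int]

    def __post_init__(self):
        if self.values.isna().any().any():
            raise ValueError("expression table contains missing values")
        missing = set(self.values.columns) - set(self.sample_lines)
        if missing:
            raise ValueError(f"samples without a cell-line mapping: {missing}")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    def line_columns(self, line: str) -> list[str]:
        return [s for s in self.values.columns if self.sample_lines[s] == line]


def read_expression(path) -> ExpressionTable:
    """Read a TSV with gene rows and ``<line>_rep<k>`` sample columns."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    lines: dict[str, str] = {}
    reps: dict[str, int] = {}
    for col in df.columns:
        if "_rep" not in col:
            raise ValueError(
                f"sample column {col!r} not of the form <line>_rep<k>"
            )
        line, rep = col.rsplit("_rep", 1)
        lines[col] = line
        reps[col] = int(rep)
    return ExpressionTable(values=df.astype(float), sample_lines=lines, sample_reps=reps)


@dataclass
class DEResult:
    gene_id: str
    p_value: float
    adjusted_p: float
    direction: str  # up/down for lineA relative to lineB
    mean_diff: float


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def de_test(expr: ExpressionTable, line_a: str, line_b: str) -> list[DEResult]:
    """Per-gene Welch t-test of line_a vs line_b, BH-adjusted, two-sided.

    Direction is the sign of mean(line_a) - mean(line_b). Genes with zero
    variance in both groups and equal means get p = 1.
    """
    cols_a = expr.line_columns(line_a)
    cols_b = expr.line_columns(line_b)
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError("need at least 2 replicates per cell line")
    a = expr.values[cols_a].to_numpy()
    b = expr.values[cols_b].to_numpy()
    t, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
    diff = a.mean(axis=1) - b.mean(axis=1)
    # degenerate rows (no variance): identical means -> no evidence
    bad = ~np.isfinite(p)
    p = np.where(bad & (diff == 0), 1.0, p)
    if np.any(~np.isfinite(p)):
        # zero variance but unequal means: as extreme as it gets
        p = np.where(~np.isfinite(p), 0.0, p)
    adj = bh_adjust(p)
    return [
        DEResult(
            gene_id=g,
            p_value=float(pv),
            adjusted_p=float(av),
            direction="up" if d >= 0 else "down",
            mean_diff=float(d),
        )
        for g, pv, av, d in zip(expr.genes, p, adj, diff)
    ]


def candidate_de_genes(
    de_l_a: Sequence[DEResult],
    de_l_b: Sequence[DEResult],
    de_a_b: Sequence[DEResult],
    alpha: float = DEFAULT_ALPHA,
    use_adjusted: bool = True,
) -> set[str]:
    """Genes DE in line L against both other lines but not between those two."""
    universes = [frozenset(r.gene_id for r in de) for de in (de_l_a, de_l_b, de_a_b)]
    if not (universes[0] == universes[1] == universes[2]):
        raise ValueError("the three contrasts must cover the same gene universe")

    def sig(de: Sequence[DEResult]) -> set[str]:
        key = (lambda r: r.adjusted_p) if use_adjusted else (lambda r: r.p_value)
        return {r.gene_id for r in de if key(r) < alpha}

    return (sig(de_l_a) & sig(de_l_b)) - sig(de_a_b)


def genes_near_peaks(
    peaks: PeakSet,
    genes: Sequence[GeneModel],
    window: int = DEFAULT_TSS_WINDOW,
) -> set[str]:
    """Genes whose ±window TSS neighbourhood a peak intersects by >=1 bp.

    The neighbourhood is ``[tss - window, tss + window)``.
    """
    by_chrom = peaks.by_chrom()
    out: set[str] = set()
    for g in genes:
        arrs = by_chrom.get(g.chrom)
        if arrs is None:
            continue
        starts, ends = arrs
        lo, hi = g.tss - window, g.tss + window
        if np.any((starts < hi) & (ends > lo)):
            out.add(g.gene_id)
    return out


@dataclass
class EnrichmentResult:
    contingency: np.ndarray  # [[de&near, de&far], [notde&near, notde&far]]
    odds_ratio: float
    p_value: float
    continuity_added: bool
    alternative: str


def fisher_enrichment(
    de_genes: set[str],
    near_genes: set[str],
    universe: set[str],
    alternative: str = "two-sided",
) -> EnrichmentResult:
    """Fisher's exact test for association of DE status with peak proximity.

    Two-sided by default (summing hypergeometric probabilities no larger
    than the observed table's, the R convention); ``alternative="greater"``
    gives the one-sided enrichment test. The odds ratio is the sample
    (ad)/(bc), with 0.5 added to every cell only when some cell is zero
    (flagged in the result).
    """
    if not universe:
        raise ValueError("empty gene universe")
    if not de_genes <= universe or not near_genes <= universe:
        raise ValueError("de_genes and near_genes must be subsets of universe")
    a = len(de_genes & near_genes)
    b = len(de_genes - near_genes)
    c = len(near_genes - de_genes)
    d = len(universe) - a - b - c
    table = np.array([[a, b], [c, d]], dtype=np.int64)
    _stat, p = stats.fisher_exact(table, alternative=alternative)
    continuity = (table == 0).any()
    if continuity:
        a2, b2, c2, d2 = (x + 0.5 for x in (a, b, c, d))
    else:
        a2, b2, c2, d2 = a, b, c, d
    return EnrichmentResult(
        contingency=table,
        odds_ratio=float(a2 * d2 / (b2 * c2)),
        p_value=float(p),
        continuity_added=bool(continuity),
        alternative=alternative,
    )


def peak_proximity_fraction(
    peaks: PeakSet,
    gene_set: set[str],
    genes: Sequence[GeneModel],
    window: int = DEFAULT_TSS_WINDOW,
) -> float:
    """Percent of peaks within ±window of the TSS of >=1 gene in the set."""
    if len(peaks) == 0:
        raise ValueError("peak set is empty")
    wanted = [g for g in genes if g.gene_id in gene_set]
    if not wanted:
        return 0.0
    windows = PeakSet(
        _tss_window_peaks(wanted, window), label="tss_windows"
    )
    return 100.0 * peaks.overlap_mask(windows).sum() / len(peaks)


def _tss_window_peaks(genes: Sequence[GeneModel], window: int):
    from .intervals import Peak

    for g in genes:
        lo = max(0, g.tss - window)
        yield Peak(g.chrom, lo, g.tss + window, name=g.gene_id)


def compare_proportions(k1: int, n1: int, k2: int, n2: int) -> tuple[float, float]:
    """1-df chi-squared test of two proportions, no continuity correction.

    Returns (statistic, two-sided p). Raises when any expected cell is 0
    (use Fisher's exact test instead).
    """
    if not (0 <= k1 <= n1 and 0 <= k2 <= n2) or n1 == 0 or n2 == 0:
        raise ValueError("need 0 <= k <= n with n > 0")
    table = np.array([[k1, n1 - k1], [k2, n2 - k2]], dtype=float)
    expected = stats.contingency.expected_freq(table)
    if np.any(expected == 0):
        raise ValueError(
            "an expected cell is 0; use fisher_enrichment instead"
        )
    chi2, p, _dof, _exp = stats.chi2_contingency(table, correction=False)
    return float(chi2), float(p)


def table1_enrichment(
    candidate_sets: Mapping[str, set[str]],
    near_sets: Mapping[str, set[str]],
    universe: set[str],
    alternative: str = "greater",
) -> pd.DataFrame:
    """All-pairs Fisher enrichment of per-line candidate DE genes among
    genes near per-line-specific peaks (rows: DE line, columns: peak line).

    One-sided enrichment by default, matching the question "are DE genes
    over-represented near this line's unique peaks".
    """
    rows = []
    for de_line, de_set in candidate_sets.items():
        for peak_line, near in near_sets.items():
            res = fisher_enrichment(de_set, near, universe, alternative=alternative)
            rows.append(
                {
                    "de_line": de_line,
                    "peak_line": peak_line,
                    "overlap": int(res.contingency[0, 0]),
                    "n_de": len(de_set),
                    "n_near": len(near),
                    "odds_ratio": res.odds_ratio,
                    "p_value": res.p_value,
                }
            )
    return pd.DataFrame(rows)
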