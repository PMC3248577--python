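import math

import numpy as np
import pandas as pd
import pytest

from cobindkit.annotate import GeneModel
from cobindkit.expression import (
    ExpressionTable,
    bh_adjust,
    candidate_de_genes,
    compare_proportions,
    de_test,
    fisher_enrichment,
    genes_near_peaks,
    peak_proximity_fraction,
    read_expression,
)
from cobindkit.intervals import Peak, PeakSet


def make_table(values: np.ndarray, lines=("A", "B"), reps=3):
    cols = {}
    k = 0
    for line in lines:
        for r in range(1, reps + 1):
            cols[f"{line}_rep{r}"] = values[:, k]
            k += 1
    df = pd.DataFrame(cols, index=[f"g{i}" for i in range(values.shape[0])])
    return ExpressionTable(
        values=df,
        sample_lines={c: c.rsplit("_rep", 1)[0] for c in df.columns},
        sample_reps={c: int(c.rsplit("_rep", 1)[1]) for c in df.columns},
    )


class TestExpressionIO:
    def test_read_and_sample_mapping(self, tmp_path):
        p = tmp_path / "e.tsv"
        p.write_text(
            "gene_id\tMCF7_rep1\tMCF7_rep2\tZR751_rep1\tZR751_rep2\n"
            "g1\t1.0\t1.1\t2.0\t2.1\n"
        )
        t = read_expression(p)
        assert t.line_columns("MCF7") == ["MCF7_rep1", "MCF7_rep2"]
        assert t.values.loc["g1", "ZR751_rep2"] == 2.1

    def test_bad_column_name(self, tmp_path):
        p = tmp_path / "e.tsv"
        p.write_text("gene_id\tsampleX\ng1\t1.0\n")
        with pytest.raises(ValueError, match="sampleX"):
            read_expression(p)

    def test_missing_values_rejected(self):
        df = pd.DataFrame({"A_rep1": [1.0, np.nan], "A_rep2": [1.0, 2.0]})
        with pytest.raises(ValueError, match="missing"):
            ExpressionTable(df, {c: "A" for c in df.columns}, {c: 1 for c in df.columns})


class TestDeTest:
    def test_identical_groups_not_significant(self, rng):
        base = rng.normal(8, 1, size=(50, 3))
        values = np.hstack([base, base])
        res = de_test(make_table(values), "A", "B")
        assert all(r.p_value > 0.99 for r in res)

    def test_welch_closed_form_single_gene(self):
        a = np.array([8.1, 8.4, 7.9])
        b = np.array([6.0, 6.3, 6.2])
        values = np.concatenate([a, b])[None, :]
        res = de_test(make_table(values), "A", "B")[0]
        va, vb = a.var(ddof=1), b.var(ddof=1)
        se = math.sqrt(va / 3 + vb / 3)
        t = (a.mean() - b.mean()) / se
        df = (va / 3 + vb / 3) ** 2 / (
            (va / 3) ** 2 / 2 + (vb / 3) ** 2 / 2
        )
        from scipy.stats import t as tdist

        expected_p = 2 * tdist.sf(abs(t), df)
        assert res.p_value == pytest.approx(expected_p, rel=1e-10)
        assert res.direction == "up"

    def test_direction_sign(self):
        values = np.array([[1.0, 1.1, 0.9, 5.0, 5.1, 4.9]])
        res = de_test(make_table(values), "A", "B")[0]
        assert res.direction == "down"

    def test_requires_two_replicates(self):
        df = pd.DataFrame({"A_rep1": [1.0], "B_rep1": [2.0], "B_rep2": [2.1]})
        t = ExpressionTable(
            df, {c: c.rsplit("_rep", 1)[0] for c in df.columns}, {c: 1 for c in df.columns}
        )
        with pytest.raises(ValueError, match="replicates"):
            de_test(t, "A", "B")

    def test_power_on_planted_shifts(self):
        """A 4-fold shift at sigma 0.25, n=3 is recovered by the raw p<0.01
        cut in >=90 of 100 planted genes with <=1% false positives (median
        over 20 seeded simulations)."""
        recalls, fps = [], []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = 2000
            planted = rng.choice(n, 100, replace=False)
            base = rng.normal(8, 1, n)
            shift = np.zeros(n)
            shift[planted] = 2.0 * np.where(rng.random(100) < 0.5, 1, -1)
            cols = []
            for line_shift in (shift, np.zeros(n)):
                for _ in range(3):
                    cols.append(base + line_shift + rng.normal(0, 0.25, n))
            res = de_test(make_table(np.column_stack(cols)), "A", "B")
            p = np.array([r.p_value for r in res])
            mask = np.zeros(n, bool)
            mask[planted] = True
            recalls.append((p[mask] < 0.01).sum())
            fps.append((p[~mask] < 0.01).mean())
        assert np.median(recalls) >= 90
        assert np.median(fps) <= 0.01


class TestBhAdjust:
    def test_stepup_hand_example(self):
        p = [0.01, 0.02, 0.03, 0.04, 0.05]
        np.testing.assert_allclose(bh_adjust(p), [0.05] * 5)

    def test_single_and_equal(self):
        assert bh_adjust([0.3])[0] == pytest.approx(0.3)
        np.testing.assert_allclose(bh_adjust([0.2, 0.2, 0.2]), [0.2, 0.2, 0.2])

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    def test_permutation_invariance(self, rng):
        p = rng.random(50)
        adj = bh_adjust(p)
        perm = rng.permutation(50)
        np.testing.assert_allclose(bh_adjust(p[perm]), adj[perm])

    def test_adjusted_at_least_raw(self, rng):
        p = rng.random(30)
        assert np.all(bh_adjust(p) >= p - 1e-12)


class TestCandidates:
    def _de(self, mapping):
        from cobindkit.expression import DEResult

        return [
            DEResult(g, p, p, "up", 1.0) for g, p in mapping.items()
        ]

    def test_definition_cases(self):
        genes = {"g1": 0.001, "g2": 0.5, "g3": 0.001}
        la = self._de(genes)
        lb = self._de({"g1": 0.001, "g2": 0.001, "g3": 0.001})
        ab = self._de({"g1": 0.5, "g2": 0.5, "g3": 0.001})
        out = candidate_de_genes(la, lb, ab)
        assert out == {"g1"}  # g2 fails L contrasts; g3 fails the A-vs-B condition

    def test_mismatched_universe_rejected(self):
        la = self._de({"g1": 0.1})
        lb = self._de({"g2": 0.1})
        with pytest.raises(ValueError, match="universe"):
            candidate_de_genes(la, lb, la)

    def test_matches_bruteforce_on_random_p(self, rng):
        genes = [f"g{i}" for i in range(200)]
        tables = [dict(zip(genes, rng.random(200) * 0.05)) for _ in range(3)]
        out = candidate_de_genes(
            self._de(tables[0]), self._de(tables[1]), self._de(tables[2]), alpha=0.02
        )
        expected = {
            g
            for g in genes
            if tables[0][g] < 0.02 and tables[1][g] < 0.02 and tables[2][g] >= 0.02
        }
        assert out == expected


class TestGenesNearPeaks:
    GENES = [GeneModel("g1", "chr1", "+", 100_000, 120_000)]

    def test_boundary_one_bp_reach(self):
        # peak ending exactly at tss-20000+1 reaches the window by 1 bp
        peaks = PeakSet([Peak("chr1", 79_000, 80_001)])
        assert genes_near_peaks(peaks, self.GENES) == {"g1"}
        peaks = PeakSet([Peak("chr1", 79_000, 80_000)])
        assert genes_near_peaks(peaks, self.GENES) == set()

    def test_no_peaks(self):
        assert genes_near_peaks(PeakSet([]), self.GENES) == set()

    def test_matches_bruteforce(self, rng):
        genes = [
            GeneModel(f"g{i}", "chr1", "+", int(s), int(s) + 5000)
            for i, s in enumerate(rng.integers(0, 900_000, size=40))
        ]
        peaks = PeakSet(
            [
                Peak("chr1", int(s), int(s) + 400)
                for s in rng.integers(0, 950_000, size=60)
            ]
        )
        expected = {
            g.gene_id
            for g in genes
            if any(p.start < g.tss + 20_000 and p.end > g.tss - 20_000 for p in peaks)
        }
        assert genes_near_peaks(peaks, genes) == expected


def hypergeom_enumeration_p(table):
    """Two-sided Fisher p by exhaustive fixed-margin enumeration."""
    a, b = table[0]
    c, d = table[1]
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def logfact(k):
        return math.lgamma(k + 1)

    def prob(x):
        # P(X = x) for the hypergeometric with these margins
        if x < max(0, c1 - r2) or x > min(r1, c1):
            return 0.0
        return math.exp(
            logfact(r1)
            + logfact(r2)
            + logfact(c1)
            + logfact(n - c1)
            - logfact(n)
            - logfact(x)
            - logfact(r1 - x)
            - logfact(c1 - x)
            - logfact(r2 - c1 + x)
        )

    p_obs = prob(a)
    total = 0.0
    for x in range(0, min(r1, c1) + 1):
        px = prob(x)
        if px <= p_obs * (1 + 1e-9):
            total += px
    return min(total, 1.0)


class TestFisher:
    def test_no_association(self):
        res = fisher_enrichment(
            {f"g{i}" for i in range(20)},
            {f"g{i}" for i in range(10, 30)},
            {f"g{i}" for i in range(40)},
        )
        assert np.array_equal(res.contingency, [[10, 10], [10, 10]])
        assert res.odds_ratio == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "table",
        [
            [[8, 2], [2, 8]],
            [[1, 9], [5, 5]],
            [[0, 10], [10, 0]],
            [[12, 3], [4, 11]],
        ],
    )
    def test_matches_enumeration(self, table):
        (a, b), (c, d) = table
        de = {f"d{i}" for i in range(a)} | {f"b{i}" for i in range(b)}
        near = {f"d{i}" for i in range(a)} | {f"c{i}" for i in range(c)}
        universe = de | near | {f"x{i}" for i in range(d)}
        res = fisher_enrichment(de, near, universe)
        assert res.p_value == pytest.approx(hypergeom_enumeration_p(table), rel=1e-9)

    def test_degenerate_margins(self):
        u = {f"g{i}" for i in range(10)}
        res = fisher_enrichment(u, u, u)
        assert res.p_value == pytest.approx(1.0)
        assert res.continuity_added  # zero cells -> 0.5 added for the OR

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            fisher_enrichment(set(), set(), set())

    def test_one_sided_enrichment_direction(self):
        de = {f"d{i}" for i in range(8)} | {"b0", "b1"}
        near = {f"d{i}" for i in range(8)} | {"c0", "c1"}
        universe = de | near | {f"x{i}" for i in range(8)}
        two = fisher_enrichment(de, near, universe)
        greater = fisher_enrichment(de, near, universe, alternative="greater")
        assert greater.alternative == "greater"
        assert greater.p_value <= two.p_value + 1e-12


class TestCompareProportions:
    def test_equal_rates(self):
        chi2, p = compare_proportions(30, 100, 30, 100)
        assert chi2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_hand_computed_statistic(self):
        # (30/100 vs 10/100): expected cells 20/80, chi2 = sum (O-E)^2/E
        chi2, p = compare_proportions(30, 100, 10, 100)
        expected = (
            (30 - 20) ** 2 / 20
            + (70 - 80) ** 2 / 80
            + (10 - 20) ** 2 / 20
            + (90 - 80) ** 2 / 80
        )
        assert chi2 == pytest.approx(expected)

    def test_symmetry(self):
        assert compare_proportions(30, 100, 10, 100)[1] == pytest.approx(
            compare_proportions(10, 100, 30, 100)[1]
        )

    def test_zero_expected_rejected(self):
        with pytest.raises(ValueError, match="[Ff]isher"):
            compare_proportions(0, 10, 0, 10)


class TestProximityFraction:
    GENES = [
        GeneModel("g1", "chr1", "+", 100_000, 120_000),
        GeneModel("g2", "chr1", "+", 500_000, 520_000),
    ]

    def test_empty_gene_set(self):
        peaks = PeakSet([Peak("chr1", 100_000, 100_400)])
        assert peak_proximity_fraction(peaks, set(), self.GENES) == 0.0

    def test_all_peaks_on_tss(self):
        peaks = PeakSet([Peak("chr1", 99_900, 100_100) for _ in range(3)])
        assert peak_proximity_fraction(peaks, {"g1"}, self.GENES) == 100.0

    def test_counts_fraction(self):
        peaks = PeakSet(
            [Peak("chr1", 99_900, 100_100), Peak("chr1", 700_000, 700_400)]
        )
        assert peak_proximity_fraction(peaks, {"g1", "g2"}, self.GENES) == 50.0

    def test_empty_peaks_rejected(self):
        with pytest.raises(ValueError):
            peak_proximity_fraction(PeakSet([]), {"g1"}, self.GENES)
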