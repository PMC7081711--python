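"""Promoter assignment, correlation, closest-gene mapping, enrichment and
cohort expression comparison.

Statistical results are checked against oracles that do not share code
with the implementation: first-principles formulas, hypergeometric
enumeration for the Fisher test, and exhaustive rank-permutation
enumeration for the Wilcoxon test.
"""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from methylcoom.integration import (
    assign_mirna_promoters,
    closest_gene,
    compare_target_expression,
    correlate,
    promoter_windows,
    region_enrichment,
    simplify_segments,
)
from methylcoom.io import BetaMatrix, ExpressionMatrix, GenomicRegionSet, ProbeAnnotation


def _annotation(positions, chrom="chr1"):
    return ProbeAnnotation(
        pd.DataFrame(
            {
                "chrom": chrom,
                "pos": positions,
                "snp": False,
                "sex_chrom": False,
            },
            index=pd.Index([f"cg{i}" for i in range(len(positions))], name="probe_id"),
        )
    )


def _genes(rows):
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "tss", "strand"])


class TestPromoterWindows:
    def test_plus_strand_window_span(self):
        out = promoter_windows(_genes([("g", "chr1", 100_000, "+")]))
        row = out.iloc[0]
        # 1-based inclusive span 97,500..100,500
        assert (row["start"], row["end"]) == (97_499, 100_500)

    def test_minus_strand_mirrors_window(self):
        out = promoter_windows(_genes([("g", "chr1", 100_000, "-")]))
        row = out.iloc[0]
        # 1-based inclusive span 99,500..102,500
        assert (row["start"], row["end"]) == (99_499, 102_500)

    def test_unknown_strand_rejected(self):
        with pytest.raises(ValueError, match="strand"):
            promoter_windows(_genes([("g", "chr1", 500, ".")]))

    def test_probe_assignment_matches_bruteforce_scan(self):
        rng = np.random.default_rng(6)
        pos = np.sort(rng.choice(np.arange(1, 500_000), 400, replace=False))
        ann = _annotation(pos)
        genes = _genes(
            [
                (f"g{i}", "chr1", int(t), s)
                for i, (t, s) in enumerate(
                    zip(rng.integers(5_000, 495_000, 30), rng.choice(["+", "-"], 30))
                )
            ]
        )
        out = promoter_windows(genes, ann).set_index("gene_id")
        for g in out.index:
            row = out.loc[g]
            expected = sorted(
                f"cg{i}" for i, p in enumerate(pos)
                if row["start"] <= p - 1 < row["end"]
            )
            assert row["probes"] == expected


class TestMirnaPromoters:
    def _sources(self, segments):
        df = pd.DataFrame(segments, columns=["chrom", "start", "end"])
        return [GenomicRegionSet("s1", df), GenomicRegionSet("s2", df.copy())]

    def test_segment_within_upstream_window_assigned(self):
        tss = 200_000
        segs = self._sources([("chr1", tss - 60_000, tss - 59_000)])
        mirnas = pd.DataFrame(
            [("mir1", "chr1", tss, "+")], columns=["mirna_id", "chrom", "tss", "strand"]
        )
        out = assign_mirna_promoters(segs, mirnas)
        assert list(out["mirna_id"]) == ["mir1"]

    def test_segment_beyond_window_not_assigned(self):
        tss = 200_000
        segs = self._sources([("chr1", tss - 121_000, tss - 120_000)])
        mirnas = pd.DataFrame(
            [("mir1", "chr1", tss, "+")], columns=["mirna_id", "chrom", "tss", "strand"]
        )
        out = assign_mirna_promoters(segs, mirnas)
        assert len(out) == 0

    def test_simplify_intersects_sources(self):
        a = GenomicRegionSet(
            "a", pd.DataFrame([("chr1", 100, 300)], columns=["chrom", "start", "end"])
        )
        b = GenomicRegionSet(
            "b", pd.DataFrame([("chr1", 200, 400)], columns=["chrom", "start", "end"])
        )
        merged = simplify_segments([a, b])
        assert merged.iloc[0].tolist() == ["chr1", 200, 300]
        union = simplify_segments([a, b], combine="union")
        assert union.iloc[0].tolist() == ["chr1", 100, 400]

    def test_random_layout_matches_bruteforce_distance_scan(self):
        rng = np.random.default_rng(7)
        segs = []
        for _ in range(40):
            s = int(rng.integers(0, 2_000_000))
            segs.append(("chr1", s, s + int(rng.integers(200, 2_000))))
        sources = self._sources(segs)
        merged = simplify_segments(sources)
        mirnas = pd.DataFrame(
            [
                (f"mir{i}", "chr1", int(t), s)
                for i, (t, s) in enumerate(
                    zip(rng.integers(1, 2_000_000, 15), rng.choice(["+", "-"], 15))
                )
            ],
            columns=["mirna_id", "chrom", "tss", "strand"],
        )
        out = assign_mirna_promoters(sources, mirnas)
        got = set(map(tuple, out[["mirna_id", "start", "end"]].to_numpy()))
        expected = set()
        for m in mirnas.itertuples(index=False):
            t0 = m.tss - 1
            for seg in merged.itertuples(index=False):
                if seg.start <= t0 < seg.end:
                    expected.add((m.mirna_id, seg.start, seg.end))
                elif m.strand == "+" and seg.end <= t0 and t0 - (seg.end - 1) <= 100_000:
                    expected.add((m.mirna_id, seg.start, seg.end))
                elif m.strand == "-" and seg.start > t0 and seg.start - t0 <= 100_000:
                    expected.add((m.mirna_id, seg.start, seg.end))
        assert got == expected

    def test_empty_sources_rejected(self):
        with pytest.raises(ValueError):
            simplify_segments([])


def _pearson_oracle(x, y):
    x, y = np.asarray(x, float), np.asarray(y, float)
    n = len(x)
    xm, ym = x - x.mean(), y - y.mean()
    r = (xm * ym).sum() / math.sqrt((xm**2).sum() * (ym**2).sum())
    t = r * math.sqrt((n - 2) / (1 - r**2))
    p = 2 * stats.t.sf(abs(t), n - 2)
    return r, p


def _spearman_oracle(x, y):
    rx = pd.Series(x).rank().to_numpy()
    ry = pd.Series(y).rank().to_numpy()
    return _pearson_oracle(rx, ry)


class TestCorrelate:
    def _inputs(self, x, y):
        samples = [f"s{i}" for i in range(len(x))]
        meth = BetaMatrix(pd.DataFrame([x], index=["cg0"], columns=samples))
        expr = ExpressionMatrix(pd.DataFrame([y], index=["g0"], columns=samples))
        pairs = pd.DataFrame({"feature_id": ["g0"], "probe_id": ["cg0"]})
        return meth, expr, pairs

    def test_perfect_anticorrelation_passes(self):
        x = [0.1, 0.3, 0.5, 0.7, 0.9]
        y = [5.0 - 4.0 * v for v in x]
        meth, expr, pairs = self._inputs(x, y)
        out = correlate(meth, expr, pairs)
        assert out.iloc[0]["r"] == pytest.approx(-1.0)
        assert out.iloc[0]["passes"]

    def test_constant_expression_excluded(self):
        meth, expr, pairs = self._inputs([0.1, 0.4, 0.6, 0.8], [2.0] * 4)
        out = correlate(meth, expr, pairs)
        assert out.iloc[0]["excluded"]
        assert not out.iloc[0]["passes"]

    def test_fewer_than_four_shared_samples_rejected(self):
        meth, expr, pairs = self._inputs([0.1, 0.2, 0.3], [1, 2, 3])
        with pytest.raises(ValueError, match="shared"):
            correlate(meth, expr, pairs)

    @pytest.mark.parametrize("method,oracle", [
        ("pearson", _pearson_oracle),
        ("spearman", _spearman_oracle),
    ])
    def test_matches_first_principles_oracle(self, method, oracle):
        rng = np.random.default_rng(8)
        for _ in range(25):
            n = int(rng.integers(5, 30))
            x = rng.random(n)
            y = 2.0 - x + rng.normal(0, 0.5, n)
            meth, expr, pairs = self._inputs(x, y)
            out = correlate(meth, expr, pairs, method=method).iloc[0]
            r, p = oracle(x, y)
            assert out["r"] == pytest.approx(r, abs=1e-9)
            assert out["p_value"] == pytest.approx(p, abs=1e-6)


class TestClosestGene:
    def test_overlapping_tss_distance_zero(self):
        regions = GenomicRegionSet(
            "r", pd.DataFrame([("chr1", 100, 200)], columns=["chrom", "start", "end"])
        )
        genes = _genes([("g1", "chr1", 150, "+"), ("g2", "chr1", 5_000, "+")])
        out = closest_gene(regions, genes)
        assert out.iloc[0]["gene_id"] == "g1"
        assert out.iloc[0]["distance"] == 0

    def test_tie_broken_by_smaller_coordinate(self):
        regions = GenomicRegionSet(
            "r", pd.DataFrame([("chr1", 1_000, 1_001)], columns=["chrom", "start", "end"])
        )
        genes = _genes([("gB", "chr1", 901, "+"), ("gA", "chr1", 1_101, "+")])
        out = closest_gene(regions, genes)
        assert out.iloc[0]["gene_id"] == "gB"

    def test_chromosome_without_genes_flagged(self):
        regions = GenomicRegionSet(
            "r", pd.DataFrame([("chr9", 10, 20)], columns=["chrom", "start", "end"])
        )
        genes = _genes([("g1", "chr1", 100, "+")])
        out = closest_gene(regions, genes)
        assert bool(out.iloc[0]["unassigned"])

    def test_random_layout_matches_all_pairs_scan(self):
        rng = np.random.default_rng(10)
        regions = GenomicRegionSet(
            "r",
            pd.DataFrame(
                [
                    ("chr1", int(s), int(s) + 500)
                    for s in rng.integers(0, 1_000_000, 25)
                ],
                columns=["chrom", "start", "end"],
            ),
        )
        genes = _genes(
            [
                (f"g{i}", "chr1", int(t), "+")
                for i, t in enumerate(rng.integers(1, 1_000_000, 40))
            ]
        )
        out = closest_gene(regions, genes)
        for _, row in out.iterrows():
            best = None
            for g in genes.itertuples(index=False):
                t0 = g.tss - 1
                d = max(0, row["start"] - t0, t0 - (row["end"] - 1))
                key = (d, t0, g.gene_id)
                if best is None or key < best:
                    best = key
            assert row["gene_id"] == best[2]


def _fisher_oracle(a, b, c, d):
    """Two-sided Fisher p by hypergeometric enumeration."""
    n = a + b + c + d
    row1, col1 = a + b, a + c
    rv = stats.hypergeom(n, row1, col1)
    p_obs = rv.pmf(a)
    ks = np.arange(max(0, col1 - (n - row1)), min(row1, col1) + 1)
    probs = rv.pmf(ks)
    return probs[probs <= p_obs * (1 + 1e-9)].sum()


class TestEnrichment:
    def _setup(self, n_bg=1_000, n_fg=60, in_set_fg=20, in_set_bg=100, seed=0):
        rng = np.random.default_rng(seed)
        pos = 1_000 * (np.arange(n_bg) + 1)
        ann = _annotation(pos)
        classes = np.array(["none"] * n_bg, dtype=object)
        classes[:n_fg] = "A"
        calls = pd.DataFrame(
            {"class": classes}, index=[f"cg{i}" for i in range(n_bg)]
        )
        members = list(rng.choice(n_fg, in_set_fg, replace=False)) + list(
            rng.choice(np.arange(n_fg, n_bg), in_set_bg - in_set_fg, replace=False)
        )
        regions = GenomicRegionSet(
            "set",
            pd.DataFrame(
                [("chr1", int(pos[i]) - 10, int(pos[i]) + 10) for i in sorted(members)],
                columns=["chrom", "start", "end"],
            ),
        )
        return calls, ann, regions

    def test_fold_change_arithmetic(self):
        calls, ann, regions = self._setup(
            n_bg=10_000, n_fg=100, in_set_fg=30, in_set_bg=1_000
        )
        out = region_enrichment(calls, ann, [regions], classes=("A",)).iloc[0]
        assert out["fold_change"] == pytest.approx(3.0)
        expected_p = _fisher_oracle(30, 70, 970, 8_930)
        assert out["fisher_p"] == pytest.approx(expected_p, rel=1e-6)

    def test_null_case_fold_change_one(self):
        calls, ann, regions = self._setup(
            n_bg=10_000, n_fg=1_000, in_set_fg=100, in_set_bg=1_000, seed=3
        )
        out = region_enrichment(calls, ann, [regions], classes=("A",)).iloc[0]
        assert out["fold_change"] == pytest.approx(1.0)
        assert out["fisher_p"] >= 0.9

    def test_zero_foreground_hits(self):
        calls, ann, regions = self._setup(in_set_fg=0, in_set_bg=50, seed=4)
        out = region_enrichment(calls, ann, [regions], classes=("A",)).iloc[0]
        assert out["fold_change"] == 0.0

    def test_empty_foreground_class_rejected(self):
        calls, ann, regions = self._setup()
        with pytest.raises(ValueError, match="foreground"):
            region_enrichment(calls, ann, [regions], classes=("B",))

    @pytest.mark.parametrize("seed", range(6))
    def test_fisher_p_matches_hypergeometric_oracle(self, seed):
        rng = np.random.default_rng(seed + 100)
        calls, ann, regions = self._setup(
            n_bg=400,
            n_fg=int(rng.integers(10, 80)),
            in_set_fg=int(rng.integers(0, 10)),
            in_set_bg=int(rng.integers(20, 80)),
            seed=seed,
        )
        out = region_enrichment(calls, ann, [regions], classes=("A",)).iloc[0]
        expected = _fisher_oracle(
            out["fg_hits"],
            out["fg_total"] - out["fg_hits"],
            out["bg_hits"] - out["fg_hits"],
            (out["bg_total"] - out["fg_total"]) - (out["bg_hits"] - out["fg_hits"]),
        )
        assert out["fisher_p"] == pytest.approx(expected, abs=1e-6)


def _wilcoxon_exact_oracle(x, y):
    """Two-sided rank-sum p by exhaustive enumeration (no ties)."""
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    rx = ranks[: len(x)].sum()
    n = len(pooled)
    stats_all = [
        sum(combo) for combo in itertools.combinations(ranks, len(x))
    ]
    mean = np.mean(stats_all)
    p = sum(1 for s in stats_all if abs(s - mean) >= abs(rx - mean) - 1e-9) / len(stats_all)
    return min(1.0, p)


class TestTargetExpression:
    def _expr(self, rows, samples):
        return ExpressionMatrix(
            pd.DataFrame(rows, index=[f"g{i}" for i in range(len(rows))], columns=samples)
        )

    def test_exact_small_sample_p(self):
        expr = self._expr([[1, 2, 3, 10, 11, 12]], list("abcdef"))
        out = compare_target_expression(expr, ["g0"], list("abc"), list("def"))
        assert out.iloc[0]["p_value"] == pytest.approx(0.1)
        assert out.iloc[0]["direction"] == -1

    def test_identical_groups_p_one(self):
        expr = self._expr([[2.0] * 6], list("abcdef"))
        out = compare_target_expression(expr, ["g0"], list("abc"), list("def"))
        assert out.iloc[0]["p_value"] == 1.0

    def test_groups_smaller_than_three_rejected(self):
        expr = self._expr([[1, 2, 3, 4]], list("abcd"))
        with pytest.raises(ValueError):
            compare_target_expression(expr, ["g0"], list("ab"), list("cd"))

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        nx, ny = int(rng.integers(3, 6)), int(rng.integers(3, 6))
        x = rng.random(nx) * 10
        y = rng.random(ny) * 10 + rng.uniform(0, 3)
        samples = [f"s{i}" for i in range(nx + ny)]
        expr = self._expr([np.concatenate([x, y])], samples)
        out = compare_target_expression(expr, ["g0"], samples[:nx], samples[nx:])
        assert out.iloc[0]["p_value"] == pytest.approx(
            _wilcoxon_exact_oracle(x, y), abs=1e-9
        )
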