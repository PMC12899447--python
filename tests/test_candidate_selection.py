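import numpy as np
import pytest
from scipy import stats

from ssrscout.candidate_selection import (
    build_final_panel,
    classify_region,
    filter_to_hotspots,
    locus_distance,
    panel_summaries,
    rank_candidates,
    structural_filter,
)
from ssrscout.genome_io import LocusAnnotation
from ssrscout.hotspot_stats import HotspotRegion
from ssrscout.oracles import min_interval_distance_naive
from ssrscout.ssr_mining import SSRRecord


def _ssr(start, end=None, k=2, repeats=8, contig="c1", motif="AC", locus="L1", dist=0):
    if end is None:
        end = start + k * repeats - 1
    return SSRRecord(contig, start, end, motif, k, repeats,
                     ssr_id=f"s{start}", locus_id=locus, distance_to_locus=dist)


def _gene(start=1000, end=2000, strand="+", exons=(), contig="c1"):
    return LocusAnnotation("L1", "X", contig, start, end, strand, list(exons))


def _hs(start, end, level=99, contig="c1"):
    return HotspotRegion("L1", contig, start, end, 1, 3.0, level)


class TestLocusDistance:
    def test_overlap_is_zero(self):
        assert locus_distance(_ssr(1500), _gene()) == 0

    def test_gap_right_of_gene(self):
        assert locus_distance(_ssr(2001, 2016), _gene(1, 1000)) == 1001

    def test_different_contig_is_error(self):
        with pytest.raises(ValueError):
            locus_distance(_ssr(10, contig="c2"), _gene())

    def test_randomized_against_per_base_oracle(self, rng):
        for _ in range(50):
            a = sorted(rng.integers(1, 300, size=2))
            b = sorted(rng.integers(1, 300, size=2))
            ssr = _ssr(a[0], a[0] + 15)
            gene = _gene(b[0], b[1] + 16)
            got = locus_distance(ssr, gene)
            want = min_interval_distance_naive((ssr.start, ssr.end), (gene.start, gene.end))
            # oracle counts adjacent intervals as distance 1; overlap as 0
            if got == 0:
                assert want == 0
            else:
                assert got == want


class TestFilterToHotspots:
    def test_ssr_inside_99_region_kept(self):
        kept = filter_to_hotspots([_ssr(1200)], [_hs(1000, 2000, 99)], [])
        assert len(kept) == 1 and kept[0][1].level == 99

    def test_fallback_to_95_when_99_empty(self):
        kept = filter_to_hotspots([_ssr(1200)], [], [_hs(1000, 2000, 95)])
        assert len(kept) == 1 and kept[0][1].level == 95

    def test_no_overlap_at_either_level_dropped(self):
        assert filter_to_hotspots([_ssr(5000)], [_hs(1, 100, 99)], [_hs(200, 300, 95)]) == []

    def test_99_candidates_suppress_95_fallback(self):
        kept = filter_to_hotspots(
            [_ssr(1200), _ssr(4000)], [_hs(1000, 2000, 99)], [_hs(3900, 4100, 95)]
        )
        assert [(s.start, h.level) for s, h in kept] == [(1200, 99)]


class TestRanking:
    def test_repeats_then_distance_order(self):
        cands = [
            _ssr(100, 100 + 19, k=2, repeats=10, dist=500),
            _ssr(300, 300 + 19, k=2, repeats=10, dist=100),
            _ssr(500, 500 + 15, k=2, repeats=8, dist=0),
        ]
        ranked = rank_candidates(cands)
        assert [c.ssr.start for c in ranked] == [300, 100, 500]

    def test_cap_at_100(self):
        cands = [_ssr(i * 100, dist=i) for i in range(1, 151)]
        assert len(rank_candidates(cands)) == 100

    def test_matches_full_sort_oracle(self, rng):
        cands = []
        for i in range(60):
            reps = int(rng.integers(3, 12))
            cands.append(_ssr(int(rng.integers(1, 10_000)) , None, k=2, repeats=reps,
                              dist=int(rng.integers(0, 5000))))
        ranked = rank_candidates(cands, cap=1000)
        oracle = sorted(cands, key=lambda s: (-s.repeats, s.distance_to_locus, s.start))
        assert [c.ssr.key() for c in ranked] == [s.key() for s in oracle]

    def test_ranking_is_deterministic_total_order(self, rng):
        cands = [_ssr(int(s)) for s in rng.choice(np.arange(1, 5000, 16), 30, replace=False)]
        a = [c.ssr.key() for c in rank_candidates(cands)]
        b = [c.ssr.key() for c in rank_candidates(list(reversed(cands)))]
        assert a == b


class TestStructuralFilter:
    @pytest.mark.parametrize(
        "k,repeats,kept",
        [
            (2, 8, True), (2, 7, False),
            (3, 7, False), (3, 8, True),
            (4, 8, True), (4, 7, False),
            (5, 4, True), (5, 3, False),
            (6, 4, True), (6, 3, False),
        ],
    )
    def test_motif_length_dependent_minimums(self, k, repeats, kept):
        motif = "ACGTAG"[:k]
        ssrs = [_ssr(100, 100 + k * repeats - 1, k=k, repeats=repeats, motif=motif)]
        assert (structural_filter(ssrs) == ssrs) is kept


class TestPanel:
    def test_panel_capped_at_five(self):
        ranked = rank_candidates([_ssr(i * 50) for i in range(1, 13)], cap=100)
        panel = build_final_panel({"L1": ranked})
        assert len(panel["L1"]) == 5
        assert all(c.selected for c in panel["L1"])

    def test_small_locus_keeps_all(self):
        ranked = rank_candidates([_ssr(100), _ssr(400)])
        panel = build_final_panel({"L1": ranked})
        assert len(panel["L1"]) == 2


class TestClassifyRegion:
    def _gene_with_exons(self, strand="+"):
        return _gene(1000, 2000, strand, exons=[(1000, 1200), (1800, 2000)])

    def test_between_exons_is_intronic(self):
        assert classify_region(_ssr(1400), self._gene_with_exons()) == "intronic"

    def test_exon_overlap_is_exonic(self):
        assert classify_region(_ssr(1150), self._gene_with_exons()) == "exonic"

    def test_upstream_is_strand_aware(self):
        # 300 bp genomically right of a minus-strand gene's end = its 5' side
        ssr = _ssr(2300)
        assert classify_region(ssr, self._gene_with_exons("-")) == "promoter_upstream"
        assert classify_region(ssr, self._gene_with_exons("+")) == "downstream"

    def test_beyond_flank_is_distal(self):
        gene = self._gene_with_exons()
        assert classify_region(_ssr(6900), gene, flank=5000) == "downstream"
        assert classify_region(_ssr(7200), gene, flank=5000) == "distal_intergenic"

    def test_labels_partition_random_placements(self, rng):
        """Per-base oracle: exactly one label per placement, consistent
        with direct interval membership."""
        gene = self._gene_with_exons("+")
        for _ in range(200):
            start = int(rng.integers(1, 9000))
            ssr = _ssr(start, start + 15)
            label = classify_region(ssr, gene, flank=5000)
            span = set(range(ssr.start, ssr.end + 1))
            in_exon = any(span & set(range(es, ee + 1)) for es, ee in gene.exons)
            in_gene = bool(span & set(range(gene.start, gene.end + 1)))
            if in_exon:
                want = "exonic"
            elif in_gene:
                want = "intronic"
            else:
                d = min_interval_distance_naive((ssr.start, ssr.end), (gene.start, gene.end))
                if d > 5000:
                    want = "distal_intergenic"
                elif ssr.end < gene.start:
                    want = "promoter_upstream"
                else:
                    want = "downstream"
            assert label == want


class TestPanelSummaries:
    def _panel_df(self, repeats, max_z):
        import pandas as pd

        n = len(repeats)
        return pd.DataFrame(
            {
                "ssr_id": [f"s{i}" for i in range(n)],
                "gene_label": ["g"] * n,
                "k": [2] * n,
                "repeats": repeats,
                "strand": ["+"] * n,
                "distance": list(range(n)),
                "region_class": ["intronic"] * n,
                "max_z": max_z,
            }
        )

    def test_constant_repeats_gives_nan_correlation(self):
        out = panel_summaries(self._panel_df([8, 8, 8], [1.0, 2.0, 3.0]))
        assert np.isnan(out["correlations"]["pearson"])

    def test_perfect_monotone_pair(self):
        out = panel_summaries(self._panel_df([1, 2, 3], [2.0, 4.0, 6.0]))
        assert out["correlations"]["pearson"] == pytest.approx(1.0)
        assert out["correlations"]["spearman"] == pytest.approx(1.0)

    def test_matches_textbook_formulas(self, rng):
        x = rng.integers(3, 15, size=40).astype(float)
        y = rng.normal(size=40)
        out = panel_summaries(self._panel_df(x, y))
        # independent recomputation from the definitions
        px = (x - x.mean()) / x.std()
        py = (y - y.mean()) / y.std()
        pearson = float((px * py).mean())
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        spearman = float(np.corrcoef(rx, ry)[0, 1])
        assert out["correlations"]["pearson"] == pytest.approx(pearson, abs=1e-12)
        assert out["correlations"]["spearman"] == pytest.approx(spearman, abs=1e-12)

    def test_distance_stats(self):
        out = panel_summaries(self._panel_df([4, 5, 6], [1.0, 2.0, 3.0]))
        assert out["distance_stats"]["mean"] == pytest.approx(1.0)
        assert out["distance_stats"]["median"] == pytest.approx(1.0)
        assert out["distance_stats"]["min"] == 0
        assert out["distance_stats"]["max"] == 2
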