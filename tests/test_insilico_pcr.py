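import math

import numpy as np
import pytest

from ssrscout.genome_io import ContigSet, reverse_complement
from ssrscout.insilico_pcr import (
    enumerate_amplicons,
    find_sites,
    multigenome_summary,
    pic,
    virtual_gel,
)
from ssrscout.oracles import enumerate_amplicons_naive, find_sites_naive
from ssrscout.primer_design import PrimerPair


def _pair(forward, reverse, primer_id="P1"):
    return PrimerPair(primer_id, forward, reverse, 60.0, 60.0, 50.0, 50.0, 0)


def _random_genome(rng, n=3000, contigs=2):
    return ContigSet(
        {f"c{i}": "".join(rng.choice(list("ACGT"), size=n)) for i in range(contigs)}
    )


class TestFindSites:
    def test_forward_and_revcomp_occurrences(self):
        probe = "AAACCCGGGTTTAAACCCGG"
        assert probe != reverse_complement(probe)
        seq = "T" * 50 + probe + "T" * 50 + reverse_complement(probe) + "T" * 50
        sites = find_sites(ContigSet({"c1": seq}), probe)
        assert {(s, strand) for _, s, strand in sites} == {(51, "+"), (121, "-")}

    def test_probe_with_n_never_matches(self):
        sites = find_sites(ContigSet({"c1": "ACGTNACGT" * 10}), "ACGTN")
        assert sites == []

    def test_overlapping_occurrences_found(self):
        sites = find_sites(ContigSet({"c1": "ATATATAT"}), "ATAT")
        plus = [s for _, s, strand in sites if strand == "+"]
        assert plus == [1, 3, 5]

    def test_matches_naive_scan_oracle(self, rng):
        genome = _random_genome(rng, n=1500)
        for _ in range(10):
            probe = "".join(rng.choice(list("ACGT"), size=int(rng.integers(4, 8))))
            assert sorted(find_sites(genome, probe)) == sorted(
                find_sites_naive(genome, probe)
            )

    def test_strand_symmetry_under_genome_reversal(self, rng):
        genome = _random_genome(rng, n=800, contigs=1)
        probe = genome["c0"][100:118]
        rc_genome = ContigSet({"c0": reverse_complement(genome["c0"])})
        n = len(genome["c0"])
        fwd = {(s, strand) for _, s, strand in find_sites(genome, probe)}
        mirrored = {
            (n - (s + len(probe) - 1) + 1, "+" if strand == "-" else "-")
            for _, s, strand in find_sites(rc_genome, probe)
        }
        assert fwd == mirrored


class TestEnumerateAmplicons:
    def test_single_product_arithmetic(self):
        rng = np.random.default_rng(0)
        f = "".join(rng.choice(list("ACGT"), 20))
        r = "".join(rng.choice(list("ACGT"), 20))
        filler = "".join(rng.choice(list("ACGT"), 80))
        tail = "".join(rng.choice(list("ACGT"), 50))
        # F at 101; rc(R) ends at 300
        seq = "".join(rng.choice(list("ACGT"), 100)) + f + filler + reverse_complement(r) + tail
        genome = ContigSet({"c1": seq})
        hits = [h for h in enumerate_amplicons(genome, _pair(f, r)) if h.orientation == "F/rc(R)"]
        assert len(hits) == 1
        assert (hits[0].start, hits[0].end, hits[0].length) == (101, 220, 120)

    def test_products_beyond_cap_excluded(self):
        rng = np.random.default_rng(1)
        f = "".join(rng.choice(list("ACGT"), 20))
        r = "".join(rng.choice(list("ACGT"), 20))
        seq = f + "".join(rng.choice(list("ACGT"), 1200)) + reverse_complement(r)
        genome = ContigSet({"c1": seq})
        assert enumerate_amplicons(genome, _pair(f, r), max_len=1000) == []

    def test_multi_site_genomes_match_exhaustive_oracle(self, rng):
        for trial in range(5):
            f = "".join(rng.choice(list("ACGT"), 12))
            r = "".join(rng.choice(list("ACGT"), 12))
            pieces = []
            for _ in range(6):
                pieces.append("".join(rng.choice(list("ACGT"), int(rng.integers(30, 300)))))
                pieces.append(
                    rng.choice([f, r, reverse_complement(f), reverse_complement(r)])
                )
            genome = ContigSet({"c1": "".join(pieces)})
            got = {
                (h.contig_id, h.start, h.end, h.orientation)
                for h in enumerate_amplicons(genome, _pair(f, r))
            }
            want = enumerate_amplicons_naive(genome, f, r, max_len=1000)
            assert got == want

    def test_round_trip_on_design_genome(self, rng):
        """Designed primers recover their own template product."""
        from ssrscout.primer_design import design_for_ssrs
        from ssrscout.ssr_mining import SSRRecord

        seq = "".join(rng.choice(list("ACGT"), size=4000))
        seq = seq[:1500] + "AC" * 10 + seq[1520:]
        genome = ContigSet({"c1": seq})
        ssr = SSRRecord("c1", 1501, 1520, "AC", 2, 10, ssr_id="s1")
        pairs = design_for_ssrs(genome, [ssr])
        assert pairs, "design failed on a balanced random template"
        for pair in pairs:
            hits = enumerate_amplicons(genome, pair, genome_label="ref")
            assert any(h.length == pair.expected_product for h in hits)


class TestPIC:
    def test_single_allele_is_zero(self):
        assert pic([242]) == 0.0
        assert pic([300, 300, 300]) == 0.0

    def test_two_allele_hand_computation(self):
        # p = (2/3, 1/3): 1 - 5/9 - 8/81 = 28/81
        assert pic([334, 334, 332]) == pytest.approx(28 / 81, abs=1e-12)

    def test_three_equifrequent_alleles(self):
        assert pic([1, 2, 3, 1, 2, 3]) == pytest.approx(0.5926, abs=5e-4)
        assert pic([1, 2, 3, 1, 2, 3]) > 0.5

    def test_empty_multiset_is_nan(self):
        assert math.isnan(pic([]))

    def test_invariant_to_relabeling(self, rng):
        sizes = rng.integers(100, 400, size=30).tolist()
        shift = [s + 1000 for s in sizes]
        assert pic(sizes) == pytest.approx(pic(shift), abs=1e-12)

    def test_maximal_at_equifrequency(self, rng):
        balanced = pic([1, 2, 3, 4] * 5)
        for _ in range(20):
            counts = rng.multinomial(20, [0.25] * 4)
            skewed = [a for a, c in zip((1, 2, 3, 4), counts) for _ in range(c)]
            if not skewed:
                continue
            assert pic(skewed) <= balanced + 1e-12

    def test_bounded_below_one(self, rng):
        for _ in range(20):
            sizes = rng.integers(100, 110, size=int(rng.integers(1, 25))).tolist()
            v = pic(sizes)
            assert 0.0 <= v < 1.0


class TestSummaries:
    def _hit(self, primer, genome, length, start=100):
        from ssrscout.insilico_pcr import AmpliconHit

        return AmpliconHit(primer, genome, "c1", start, start + length - 1, "F/rc(R)")

    def test_single_genome_single_product_monomorphic(self):
        summary = multigenome_summary({"ref": [self._hit("P1", "ref", 242)]})
        row = summary.iloc[0]
        assert row.pic == 0.0 and not row.multi_product
        assert row.n_genomes_amplified == 1

    def test_multi_product_flag(self):
        hits = {
            "g1": [self._hit("P1", "g1", 185), self._hit("P1", "g1", 217, 500),
                   self._hit("P1", "g1", 260, 900)],
            "g2": [self._hit("P1", "g2", 242)],
        }
        row = multigenome_summary(hits).iloc[0]
        assert row.multi_product
        assert row.n_genomes_amplified == 2
        assert row.allele_sizes == [185, 217, 242, 260]

    def test_unamplified_primer_reported_nan(self):
        summary = multigenome_summary({"ref": []}, primer_ids=["P9"])
        assert math.isnan(summary.iloc[0].pic)
        assert summary.iloc[0].n_amplicons == 0

    def test_virtual_gel_bands(self):
        hits = {
            "g1": [self._hit("P1", "g1", 200), self._hit("P1", "g1", 200, 700),
                   self._hit("P1", "g1", 350, 1400)],
        }
        gel = virtual_gel(hits)
        assert len(gel) == 2  # co-migrating 200-bp bands collapse
        assert gel[gel["size"] == 200].iloc[0].multiplicity == 2

    def test_virtual_gel_empty(self):
        assert virtual_gel({}).empty

    def test_cultivar_jitter_truth(self, study, rng):
        """Planted repeat jitter makes primers polymorphic; frozen
        cultivars give PIC > 0 exactly when allele lengths differ."""
        from ssrscout.insilico_pcr import enumerate_amplicons
        from ssrscout.primer_design import design_for_ssrs
        from ssrscout.ssr_mining import SSRRecord
        from ssrscout.synthetic_data import derive_cultivar

        contigs, genes, truth = study
        planted = truth.ssrs.head(6)
        ssrs = [
            SSRRecord(r.contig, r.start, r.end, r.motif, r.k, r.repeats, ssr_id=r.ssr_id)
            for r in planted.itertuples(index=False)
        ]
        pairs = design_for_ssrs(contigs, ssrs)
        assert pairs
        genomes = {"ref": contigs}
        deltas = {}
        for i in range(2):
            cult, delta = derive_cultivar(contigs, truth, seed=500 + i)
            genomes[f"cv{i}"] = cult
            deltas[f"cv{i}"] = delta.set_index("ssr_id")
        hits = {
            label: [h for p in pairs for h in enumerate_amplicons(g, p, genome_label=label)]
            for label, g in genomes.items()
        }
        summary = multigenome_summary(hits, [p.primer_id for p in pairs]).set_index("primer_id")
        planted_by_id = truth.ssrs.set_index("ssr_id")
        for pair in pairs:
            target = planted_by_id.loc[pair.target_ssr_id]
            # reference product interval in genome coordinates
            t_start = target.start - 200  # templates here are never trimmed
            prod_lo = t_start + pair.forward_start - 1
            prod_hi = t_start + pair.reverse_end - 1
            inside = truth.ssrs[
                (truth.ssrs.contig == target.contig)
                & (truth.ssrs.start >= prod_lo)
                & (truth.ssrs.end <= prod_hi)
            ]
            expected_sizes = {pair.expected_product}
            for c in deltas:
                shift = sum(
                    int(deltas[c].loc[r.ssr_id].delta) * r.k
                    for r in inside.itertuples(index=False)
                )
                expected_sizes.add(pair.expected_product + shift)
            row = summary.loc[pair.primer_id]
            if row.n_genomes_amplified == 3 and row.n_amplicons == 3:
                # clean one-product-per-genome case: allele sizes and PIC
                # must track the planted jitter exactly
                assert set(row.allele_sizes) == expected_sizes
                assert (row.pic > 0) == (len(expected_sizes) > 1)
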