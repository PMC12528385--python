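import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from sortmave.library_design import (
    AMINO_ACIDS,
    STOP,
    InvalidRegionError,
    Region,
    VariantSpec,
    classify_variant,
    enumerate_possible_variants,
    filter_barcode_collisions,
    nns_codon_outcomes,
    plan_mutagenesis_pools,
    region_codon_count,
)
from sortmave.synthetic_data import random_protein_sequence


class TestRegion:
    @pytest.mark.parametrize(
        "start,end,expected", [(28, 955, 928), (5, 5, 1), (28, 47, 20)]
    )
    def test_codon_count(self, start, end, expected):
        assert region_codon_count(Region(start, end)) == expected

    def test_inverted_region_rejected(self):
        with pytest.raises(InvalidRegionError):
            Region(10, 9)


class TestEnumeration:
    def test_ectodomain_variant_count(self):
        """19 missense + 1 stop per codon: 18,560 over the 928-codon region."""
        region = Region(28, 955)
        seq = random_protein_sequence(len(region), seed=0)
        variants = enumerate_possible_variants(region, seq)
        assert len(variants) == 18_560
        missense = [v for v in variants if v.klass == "missense"]
        assert len(missense) == 17_632  # 928 x 19, brute-force checked below

    def test_single_position(self):
        variants = enumerate_possible_variants(Region(1, 1), "M")
        assert len(variants) == 20
        assert sum(v.klass == "nonsense" for v in variants) == 1

    @given(st.integers(1, 40), st.integers(0, 30))
    def test_count_matches_nested_loop_oracle(self, start, length):
        """|variants| == 20 x |region| for any region (explicit enumeration)."""
        region = Region(start, start + length)
        seq = random_protein_sequence(len(region), seed=1)
        variants = enumerate_possible_variants(region, seq)
        brute = {
            (pos, alt)
            for pos, wt in zip(region.positions, seq)
            for alt in list(AMINO_ACIDS) + [STOP]
            if alt != wt
        }
        assert len(variants) == 20 * region_codon_count(region)
        assert {(v.position, v.alt) for v in variants} == brute


class TestNNSCodons:
    def test_full_amino_acid_coverage_single_stop(self):
        outcomes = nns_codon_outcomes()
        assert len(outcomes) == 32
        aas = set(outcomes.values()) - {STOP}
        assert aas == set(AMINO_ACIDS)
        assert [c for c, aa in outcomes.items() if aa == STOP] == ["TAG"]

    def test_third_base_is_strong(self):
        assert all(c[2] in "GC" for c in nns_codon_outcomes())
        assert "TAA" not in nns_codon_outcomes()
        assert "TGA" not in nns_codon_outcomes()

    def test_agrees_with_standard_genetic_code(self):
        from Bio.Seq import Seq

        for codon, aa in nns_codon_outcomes().items():
            translated = str(Seq(codon).translate())
            assert aa == (STOP if translated == "*" else translated)


class TestPools:
    @pytest.mark.parametrize(
        "start,end,block,expected",
        [(28, 955, 20, 47), (28, 47, 20, 1), (28, 48, 20, 2)],
    )
    def test_pool_counts(self, start, end, block, expected):
        pools = plan_mutagenesis_pools(Region(start, end), block)
        assert len(pools) == expected

    def test_pools_tile_region_without_overlap(self):
        region = Region(28, 955)
        pools = plan_mutagenesis_pools(region)
        covered = list(itertools.chain.from_iterable(p.positions for p in pools))
        assert covered == list(region.positions)

    def test_block_size_validation(self):
        with pytest.raises(ValueError):
            plan_mutagenesis_pools(Region(1, 10), 0)


def _map(rows):
    return pd.DataFrame(
        rows, columns=["barcode", "position", "wt_aa", "alt_aa", "support_reads"]
    )


class TestCollisionFilter:
    base = "ACGT" * 5  # 20-mer barcodes for compactness

    def _mutate(self, s, k):
        flip = {"A": "C", "C": "A", "G": "T", "T": "G"}
        return "".join(flip[c] if i < k else c for i, c in enumerate(s))

    def test_conflicting_pair_keeps_higher_support(self):
        rows = [
            (self.base, 100, "G", "Q", 5),
            (self._mutate(self.base, 2), 200, "W", "L", 1),
        ]
        kept = filter_barcode_collisions(_map(rows))
        assert kept["barcode"].tolist() == [self.base]

    def test_same_variant_pair_untouched(self):
        rows = [
            (self.base, 100, "G", "Q", 5),
            (self._mutate(self.base, 2), 100, "G", "Q", 1),
        ]
        assert len(filter_barcode_collisions(_map(rows))) == 2

    def test_distance_above_threshold_kept(self):
        rows = [
            (self.base, 100, "G", "Q", 5),
            (self._mutate(self.base, 3), 200, "W", "L", 1),
        ]
        assert len(filter_barcode_collisions(_map(rows))) == 2

    def test_tied_support_drops_both(self):
        rows = [
            (self.base, 100, "G", "Q", 3),
            (self._mutate(self.base, 1), 200, "W", "L", 3),
        ]
        assert filter_barcode_collisions(_map(rows)).empty

    def test_matches_all_pairs_oracle_and_is_idempotent(self):
        rng = np.random.default_rng(7)
        letters = np.array(list("ACGT"))
        n = 40
        barcodes = ["".join(letters[rng.integers(0, 2, 12)]) for _ in range(n)]
        rows = [
            (bc, int(rng.integers(1, 4)) * 100, "G", "Q" if rng.random() < 0.5 else "L",
             int(rng.integers(1, 6)))
            for bc in set(barcodes)
        ]
        bvmap = _map(rows)
        kept = filter_barcode_collisions(bvmap)
        # oracle: drop any barcode that has a conflicting neighbour with >= support
        def ham(a, b):
            return sum(x != y for x, y in zip(a, b))

        expect_drop = set()
        recs = bvmap.to_dict("records")
        for a, b in itertools.combinations(recs, 2):
            if ham(a["barcode"], b["barcode"]) <= 2 and (
                (a["position"], a["alt_aa"]) != (b["position"], b["alt_aa"])
            ):
                if a["support_reads"] <= b["support_reads"]:
                    expect_drop.add(a["barcode"])
                if b["support_reads"] <= a["support_reads"]:
                    expect_drop.add(b["barcode"])
        assert set(kept["barcode"]) == set(bvmap["barcode"]) - expect_drop
        again = filter_barcode_collisions(kept)
        pd.testing.assert_frame_equal(again.reset_index(drop=True),
                                      kept.reset_index(drop=True))
        assert len(kept) <= len(bvmap)

    def test_unequal_lengths_rejected(self):
        rows = [("ACGT", 1, "G", "Q", 1), ("ACGTA", 2, "W", "L", 1)]
        with pytest.raises(ValueError):
            filter_barcode_collisions(_map(rows))


class TestClassification:
    @pytest.mark.parametrize(
        "wt,alt,expected",
        [("G", "G", "synonymous"), ("G", "*", "nonsense"), ("G", "Q", "missense"),
         ("G", "=", "synonymous")],
    )
    def test_klass(self, wt, alt, expected):
        assert classify_variant(wt, alt) == expected

    def test_unknown_symbols_rejected(self):
        with pytest.raises(ValueError):
            classify_variant("B", "Q")
        with pytest.raises(ValueError):
            classify_variant("G", "J")

    def test_variant_spec_id_roundtrip(self):
        v = VariantSpec(333, "G", "Q")
        assert v.id == "G333Q"
        assert v.klass == "missense"
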