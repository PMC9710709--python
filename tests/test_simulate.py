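import numpy as np
import pytest

from sfstools.alphabet import reverse_complement
from sfstools.search import SfsEmission
from sfstools.simulate import (
    CHILD_HAPLOTYPES,
    PARENT_HAPLOTYPES,
    generate_genome,
    lift_read_interval,
    make_trio,
    reads_frame,
    simulate_reads,
    truth_frame,
    variant_overlap,
)


@pytest.fixture(scope="module")
def genome():
    return generate_genome(30_000, seed=11)


@pytest.fixture(scope="module")
def trio(genome):
    return make_trio(genome, n_inherited=8, n_denovo=9,
                     sv_size_range=(50, 200), seed=5,
                     edge_margin=500, min_gap=50)


class TestGenerateGenome:
    def test_seeded_determinism(self):
        assert generate_genome(5000, seed=1) == generate_genome(5000, seed=1)

    def test_different_seeds_differ(self):
        assert generate_genome(5000, seed=1) != generate_genome(5000, seed=2)

    def test_base_composition(self):
        g = generate_genome(100_000, seed=3)
        for base in "ACGT":
            assert abs(g.count(base) / len(g) - 0.25) < 0.02

    def test_too_short_errors(self):
        with pytest.raises(ValueError, match="length"):
            generate_genome(999, seed=1)


class TestMakeTrio:
    def test_denovo_split_evenly(self, genome):
        trio = make_trio(genome, n_inherited=0, n_denovo=21, seed=2,
                         sv_size_range=(50, 100), edge_margin=500)
        kinds = [v.kind for v in trio.de_novo_variants]
        assert kinds.count("insertion") == 7
        assert kinds.count("deletion") == 7
        assert kinds.count("inversion") == 7

    def test_denovo_near_equal_split(self, genome):
        trio = make_trio(genome, n_inherited=0, n_denovo=20, seed=2,
                         sv_size_range=(50, 100), edge_margin=500)
        counts = {k: sum(v.kind == k for v in trio.de_novo_variants)
                  for k in ("insertion", "deletion", "inversion")}
        assert sum(counts.values()) == 20
        assert max(counts.values()) - min(counts.values()) <= 1

    def test_no_recombination_child_copies_parent(self, genome):
        trio = make_trio(genome, n_inherited=6, n_denovo=0, seed=3,
                         edge_margin=500)
        for child_id in CHILD_HAPLOTYPES:
            child = trio.haplotypes[child_id]
            assert child.sequence == trio.haplotypes[child.source].sequence

    def test_length_conservation(self, trio, genome):
        for hap_id, hap in trio.haplotypes.items():
            delta = 0
            for p in hap.placements:
                v = p.variant
                if v.kind == "insertion":
                    delta += v.length
                elif v.kind == "deletion":
                    delta -= v.length
            assert len(hap.sequence) == len(genome) + delta

    def test_inversion_content(self, genome):
        trio = make_trio(genome, n_inherited=0, n_denovo=3, seed=7,
                         sv_size_range=(60, 60), edge_margin=500)
        for hap_id in CHILD_HAPLOTYPES:
            hap = trio.haplotypes[hap_id]
            for p in hap.placements:
                if p.variant.kind != "inversion":
                    continue
                segment = hap.sequence[p.hap_begin:p.hap_end]
                anc = genome[p.variant.ref_pos:p.variant.ref_pos + 60]
                assert segment == reverse_complement(anc)

    def test_denovo_absent_from_parents(self, trio):
        for hap_id in PARENT_HAPLOTYPES:
            for p in trio.haplotypes[hap_id].placements:
                assert p.variant.origin == "inherited"

    def test_truth_disjoint_on_each_haplotype(self, trio):
        for hap in trio.haplotypes.values():
            spans = sorted((p.hap_begin, max(p.hap_end, p.hap_begin + 1))
                           for p in hap.placements)
            for (b1, e1), (b2, e2) in zip(spans, spans[1:]):
                assert e1 <= b2

    def test_inherited_on_at_least_two_parent_haplotypes(self, trio):
        carriers = {v.vid: 0 for v in trio.variants if v.origin == "inherited"}
        for hap_id in PARENT_HAPLOTYPES:
            for p in trio.haplotypes[hap_id].placements:
                carriers[p.variant.vid] += 1
        assert all(n >= 2 for n in carriers.values())

    def test_impossible_placement_errors(self, genome):
        with pytest.raises(ValueError, match="place"):
            make_trio(genome, n_inherited=0, n_denovo=200,
                      sv_size_range=(400, 500), seed=1, edge_margin=500)

    def test_liftover_roundtrip(self, trio, genome, rnd):
        for hap in trio.haplotypes.values():
            hits = 0
            while hits < 250:
                pos = rnd.randrange(len(hap.sequence))
                anc = hap.hap_to_anc(pos)
                if anc is None:
                    continue  # inside variant-derived sequence
                hits += 1
                assert hap.anc_to_hap(anc) == pos
                assert hap.sequence[pos] == genome[anc]


class TestSimulateReads:
    def test_error_free_reads_are_slices(self, trio):
        haps = {h: trio.haplotypes[h].sequence for h in CHILD_HAPLOTYPES}
        reads = simulate_reads(haps, 3.0, (2000, 400, 500), 0.0, seed=1)
        for r in reads:
            chunk = trio.haplotypes[r.haplotype_id].sequence[r.hap_begin:r.hap_end]
            if r.strand == "-":
                chunk = reverse_complement(chunk)
            assert r.sequence == chunk
            assert r.errors_injected == 0

    def test_realized_coverage(self):
        g = generate_genome(100_000, seed=9)
        reads = simulate_reads({"h": g}, 20.0, (10_000, 2_000, 1_000), 0.0, seed=4)
        total = sum(r.hap_end - r.hap_begin for r in reads)
        assert abs(total / len(g) - 20.0) / 20.0 < 0.05

    def test_seeded_determinism(self, trio):
        haps = {h: trio.haplotypes[h].sequence for h in CHILD_HAPLOTYPES}
        a = simulate_reads(haps, 2.0, (2000, 400, 500), 0.001, seed=8)
        b = simulate_reads(haps, 2.0, (2000, 400, 500), 0.001, seed=8)
        assert a == b

    def test_error_injection_counts(self, trio):
        haps = {CHILD_HAPLOTYPES[0]: trio.haplotypes[CHILD_HAPLOTYPES[0]].sequence}
        reads = simulate_reads(haps, 5.0, (2000, 400, 500), 0.005, seed=3)
        total_bases = sum(r.hap_end - r.hap_begin for r in reads)
        total_errors = sum(r.errors_injected for r in reads)
        assert 0 < total_errors / total_bases < 0.02

    def test_invalid_parameters(self, trio):
        haps = {"h": trio.haplotypes["child_1"].sequence}
        with pytest.raises(ValueError, match="coverage"):
            simulate_reads(haps, 0, error_rate=0.0, seed=1)
        with pytest.raises(ValueError, match="error_rate"):
            simulate_reads(haps, 1.0, error_rate=0.5, seed=1)

    def test_read_length_clipped_to_haplotype(self):
        g = generate_genome(2000, seed=5)
        reads = simulate_reads({"h": g}, 2.0, (10_000, 2_000, 1_000), 0.0, seed=6)
        assert all(len(r.sequence) <= len(g) for r in reads)


class TestVariantOverlap:
    def _read_over(self, trio, hap_id, begin, end, strand="+"):
        from sfstools.simulate import SimulatedRead
        seq = trio.haplotypes[hap_id].sequence[begin:end]
        if strand == "-":
            seq = reverse_complement(seq)
        return SimulatedRead(f"{hap_id}:x", seq, hap_id, begin, end, strand, 0)

    def test_emission_inside_unvaried_region(self, trio):
        hap = trio.haplotypes["child_1"]
        # find a gap with no placement
        pos = 0
        spans = sorted((p.hap_begin, p.hap_end) for p in hap.placements)
        for b, e in spans:
            if b - pos > 300:
                break
            pos = max(pos, e, b + 1)
        read = self._read_over(trio, "child_1", pos + 10, pos + 200)
        em = SfsEmission(read.sequence[5:50], read.read_id, 5, 50)
        assert variant_overlap(em, read, trio) == []

    def test_emission_spanning_insertion(self, trio):
        for hap_id in CHILD_HAPLOTYPES:
            hap = trio.haplotypes[hap_id]
            ins = [p for p in hap.placements if p.variant.kind == "insertion"]
            if not ins:
                continue
            p = ins[0]
            read = self._read_over(trio, hap_id, p.hap_begin - 50, p.hap_end + 50)
            em = SfsEmission(read.sequence[40:70], read.read_id, 40, 70)
            assert p.variant in variant_overlap(em, read, trio)
            return
        pytest.skip("no insertion placed on a child haplotype")

    def test_deletion_requires_spanning_junction(self, trio):
        for hap_id in CHILD_HAPLOTYPES:
            hap = trio.haplotypes[hap_id]
            dels = [p for p in hap.placements if p.variant.kind == "deletion"]
            if not dels:
                continue
            p = dels[0]
            read = self._read_over(trio, hap_id, p.hap_begin - 100, p.hap_begin + 100)
            spanning = SfsEmission(read.sequence[90:110], read.read_id, 90, 110)
            assert p.variant in variant_overlap(spanning, read, trio)
            touching = SfsEmission(read.sequence[50:100], read.read_id, 50, 100)
            assert p.variant not in variant_overlap(touching, read, trio)
            return
        pytest.skip("no deletion placed on a child haplotype")

    def test_minus_strand_liftover(self, trio):
        hap_id = "child_1"
        read = self._read_over(trio, hap_id, 1000, 1400, strand="-")
        hb, he = lift_read_interval(read, 0, 50)
        assert (hb, he) == (1350, 1400)

    def test_mismatched_read_errors(self, trio):
        read = self._read_over(trio, "child_1", 100, 400)
        em = SfsEmission("ACGT", "some_other_read", 0, 4)
        with pytest.raises(ValueError, match="does not match"):
            variant_overlap(em, read, trio)


class TestFrames:
    def test_truth_frame_columns(self, trio):
        df = truth_frame(trio)
        assert {"variant_id", "kind", "origin", "haplotype_id",
                "hap_begin", "hap_end"} <= set(df.columns)
        assert (df["origin"].isin(["inherited", "de_novo"])).all()

    def test_reads_frame(self, trio):
        haps = {h: trio.haplotypes[h].sequence for h in CHILD_HAPLOTYPES}
        reads = simulate_reads(haps, 1.0, (2000, 400, 500), 0.0, seed=2)
        df = reads_frame(reads)
        assert len(df) == len(reads)
        assert df["read_id"].is_unique
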