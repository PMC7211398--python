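import itertools

import pytest
from Bio.Restriction import AgeI as BioAgeI
from Bio.Seq import Seq

from donorforge.assembly import (
    LOXP,
    AssemblyError,
    AssemblyProduct,
    Fragment,
    HazardReport,
    canonical_rotation,
    circular_equal,
    detect_hazards,
    digest,
    gibson_assemble,
    insert_flanking_sites,
    make_sgrna_site,
    plan_assembly,
    verify_construct,
)
from donorforge.enzymes import DEFAULT_ENZYMES
from conftest import rand_dna

AgeI = DEFAULT_ENZYMES["AgeI"]
XhoI = DEFAULT_ENZYMES["XhoI"]


class TestCircularHelpers:
    def test_canonical_rotation_matches_naive(self, rng):
        for _ in range(50):
            s = rand_dna(rng, int(rng.integers(1, 30)))
            assert canonical_rotation(s) == min(s[i:] + s[:i] for i in range(len(s)))

    def test_circular_equality(self):
        assert circular_equal("ACGTT", "GTTAC")
        assert not circular_equal("ACGTT", "ACGTA")


class TestDigest:
    def test_single_site_circular(self):
        frags = digest("ACCGGTAAAATTTT", AgeI, circular=True)
        assert len(frags) == 1
        f = frags[0]
        assert f.seq == "CCGGTAAAATTTTA"
        assert f.end5.kind == f.end3.kind == "5p"
        assert f.end5.seq == f.end3.seq == "CCGG"

    def test_two_sites_conserve_length(self, rng):
        plasmid = "ACCGGT" + rand_dna(rng, 400) + "ACCGGT" + rand_dna(rng, 900)
        frags = digest(plasmid, AgeI, circular=True)
        assert len(frags) == 2
        assert sum(len(f.seq) for f in frags) == len(plasmid)

    def test_multi_cut_conservation_and_positions_match_biopython(self, rng):
        for _ in range(10):
            parts = [rand_dna(rng, int(rng.integers(50, 200))) for _ in range(4)]
            plasmid = "ACCGGT".join(parts) + "ACCGGT"
            frags = digest(plasmid, AgeI, circular=True)
            assert sum(len(f.seq) for f in frags) == len(plasmid)
            ours = sorted(
                (len(plasmid) - sum(len(f.seq) for f in frags[:i])) % len(plasmid)
                for i in range(len(frags))
            )
            bio = sorted((p - 1) % len(plasmid) for p in BioAgeI.search(Seq(plasmid), linear=False))
            starts = sorted(
                (plasmid + plasmid).find(f.seq, 0, 2 * len(plasmid)) for f in frags
            )
            assert len(frags) == len(bio)
            # every fragment starts at a Biopython-reported top-strand cut
            for f in frags:
                assert any(
                    (plasmid + plasmid)[b : b + len(f.seq)] == f.seq for b in bio
                )

    def test_uncut_circular_is_error(self, rng):
        with pytest.raises(AssemblyError, match="site not found"):
            digest(rand_dna(rng, 60).replace("ACCGGT", "ACCGGA"), AgeI, circular=True)

    def test_linear_digest_keeps_outer_ends_blunt(self, rng):
        lin = rand_dna(rng, 100) + "ACCGGT" + rand_dna(rng, 100)
        frags = digest(lin, AgeI, circular=False)
        assert len(frags) == 2
        assert frags[0].end5.kind == "blunt" and frags[1].end3.kind == "blunt"
        assert frags[0].end3.ligatable(frags[1].end5)

    def test_blunt_cutter(self, rng):
        ecorv = DEFAULT_ENZYMES["EcoRV"]
        plasmid = "GATATC" + rand_dna(rng, 300)
        frags = digest(plasmid, ecorv, circular=True)
        assert frags[0].end5.kind == "blunt"


class TestGibson:
    def test_digest_then_assemble_restores_plasmid(self, rng):
        """Single-site digestion followed by assembly re-circularises."""
        for seed_len in (200, 801, 1500):
            body = rand_dna(rng, seed_len)
            while "ACCGGT" in body:
                body = rand_dna(rng, seed_len)
            plasmid = "ACCGGT" + body
            frags = digest(plasmid, AgeI, circular=True)
            product = gibson_assemble(frags)
            assert isinstance(product, AssemblyProduct)
            assert circular_equal(product.seq, plasmid)

    def test_single_fragment_homology_circularisation(self, rng):
        overlap = rand_dna(rng, 30)
        core = rand_dna(rng, 300)
        product = gibson_assemble([Fragment(overlap + core + overlap, label="v")])
        # seamless: the terminal repeat appears once in the circle
        assert len(product.seq) == 330
        assert circular_equal(product.seq, overlap + core)

    def test_three_fragments_unique_overlaps(self, rng):
        o = [rand_dna(rng, 30) for _ in range(3)]
        frags = [
            Fragment(o[0] + rand_dna(rng, 150) + o[1], label="A"),
            Fragment(o[1] + rand_dna(rng, 120) + o[2], label="B"),
            Fragment(o[2] + rand_dna(rng, 90) + o[0], label="C"),
        ]
        expect_len = sum(len(f.seq) for f in frags) - 90
        products = []
        for perm in itertools.permutations(frags):
            product = gibson_assemble(list(perm))
            assert isinstance(product, AssemblyProduct)
            assert len(product.seq) == expect_len
            products.append(product.canonical)
        assert len(set(products)) == 1  # order-independent

    def test_repeated_loxp_overlaps_are_ambiguous(self, rng):
        frags = [
            Fragment(LOXP + rand_dna(rng, 100) + LOXP, label="x"),
            Fragment(LOXP + rand_dna(rng, 80) + LOXP, label="y"),
            Fragment(LOXP + rand_dna(rng, 60) + LOXP, label="z"),
        ]
        report = gibson_assemble(frags)
        assert isinstance(report, HazardReport)
        assert not report.is_empty
        assert report.alternative_products >= 2

    def test_short_overlap_incompatible(self, rng):
        o = rand_dna(rng, 10)
        frags = [
            Fragment(o + rand_dna(rng, 100) + o, label="A"),
            Fragment(o + rand_dna(rng, 100) + o, label="B"),
        ]
        with pytest.raises(AssemblyError, match="incompatible ends"):
            gibson_assemble(frags, min_overlap=20)

    def test_min_overlap_floor(self, rng):
        with pytest.raises(ValueError):
            gibson_assemble([Fragment(rand_dna(rng, 50))], min_overlap=10)


class TestDetectHazards:
    def _loxp_fragments(self, rng):
        o1, o2, o3 = (rand_dna(rng, 30) for _ in range(3))
        # declared order: arm -> IF -> vector; the arm carries one LoxP on its
        # far (5') end, the IF carries the marker-flanking pair just inside
        # its linker overlaps -- three LoxP copies total, as in a removable-SM
        # donor with a LoxP-bearing homology arm.
        arm = LOXP + rand_dna(rng, 150) + o1
        insert = o1 + LOXP + rand_dna(rng, 200) + LOXP + o2
        vector = o2 + rand_dna(rng, 300) + o3
        return [
            Fragment(arm, label="arm"),
            Fragment(insert, label="IF"),
            Fragment(vector, label="vector"),
        ]

    def test_three_loxp_sites_three_pairings(self, rng):
        frags = self._loxp_fragments(rng)
        report = detect_hazards(frags, k=15, window=64)
        loxp_hits = [
            j for j in report.ambiguous_junctions if LOXP in j["shared_terminal_sequence"]
        ]
        assert len(loxp_hits) == 3
        assert all(j["length"] >= 34 for j in loxp_hits)

    def test_unique_termini_clean(self, rng):
        o = [rand_dna(rng, 30) for _ in range(3)]
        frags = [
            Fragment(o[0] + rand_dna(rng, 100) + o[1], label="A"),
            Fragment(o[1] + rand_dna(rng, 100) + o[2], label="B"),
            Fragment(o[2] + rand_dna(rng, 100) + o[0], label="C"),
        ]
        assert detect_hazards(frags, k=15).is_empty

    def test_symmetric_in_fragment_order(self, rng):
        frags = self._loxp_fragments(rng)
        fwd = detect_hazards(frags, k=15, window=64, intended_order=False)
        rev = detect_hazards(list(reversed(frags)), k=15, window=64, intended_order=False)
        key = lambda j: (tuple(sorted(j["fragments"])), j["length"])
        assert sorted(map(key, fwd.ambiguous_junctions)) == sorted(
            map(key, rev.ambiguous_junctions)
        )

    def test_scan_consistent_with_full_assembly(self, rng):
        """A nonempty quick scan implies assembly cannot give a unique product."""
        frags = [
            Fragment(LOXP + rand_dna(rng, 100) + LOXP, label="x"),
            Fragment(LOXP + rand_dna(rng, 80) + LOXP, label="y"),
        ]
        assert not detect_hazards(frags, k=15).is_empty
        result = gibson_assemble(frags)
        assert isinstance(result, HazardReport)


class TestPlanAssembly:
    def test_snai1_case_triggers_everything(self):
        plan = plan_assembly(72.8, 60.5, if_has_loxp_sm=True)
        assert plan.mode == "two_step"
        assert plan.rationale == ["arm5_gc", "arm3_gc", "loxp_sm"]
        digests = [s.enzyme for s in plan.steps if s.op == "digest"]
        assert digests == ["AgeI", "XhoI"]  # 5' arm round before 3' arm round

    def test_balanced_one_step(self):
        plan = plan_assembly(50.0, 50.0, if_has_loxp_sm=False)
        assert plan.mode == "one_step" and plan.rationale == []

    def test_single_arm_trigger(self):
        plan = plan_assembly(50.0, 65.0, if_has_loxp_sm=False)
        assert plan.mode == "two_step" and plan.rationale == ["arm3_gc"]

    def test_domain_check(self):
        with pytest.raises(ValueError):
            plan_assembly(-5.0, 50.0, False)


class TestSgrnaSite:
    def test_cdh1_worked_example(self):
        assert (
            make_sgrna_site("AAGCTGGCTGACATGTACGG", "AGG")
            == "AAGCTGGCTGACATGTACGGAGG"
        )

    def test_pam_pattern(self):
        with pytest.raises(ValueError):
            make_sgrna_site("AAGCTGGCTGACATGTACGG", "ATT")
        with pytest.raises(ValueError):
            make_sgrna_site("AAGCTGGCTGACATGTACG", "AGG")

    def test_length_contract(self, rng):
        assert len(make_sgrna_site(rand_dna(rng, 20), "TGG")) == 23


class TestInsertFlankingSites:
    @staticmethod
    def _rand_site_free(rng, n):
        while True:
            s = rand_dna(rng, n)
            if "ACCGGT" not in s and "CTCGAG" not in s:
                return s

    def _donor(self, rng):
        r = self._rand_site_free
        return (
            "ACCGGT" + r(rng, 40)          # linker a region
            + r(rng, 700)                  # IF
            + r(rng, 40) + "CTCGAG"        # linker b region
            + r(rng, 1200)                 # backbone
        )

    def test_length_bookkeeping_and_res_preserved(self, rng):
        donor = self._donor(rng)
        site = make_sgrna_site("AAGCTGGCTGACATGTACGG", "AGG")
        product = insert_flanking_sites(donor, site, AgeI, XhoI)
        assert len(product) == len(donor) + 2 * 23
        assert product.count(site) == 2
        assert product.count("ACCGGT") == 1 and product.count("CTCGAG") == 1

    def test_duplicate_site_rejected(self, rng):
        donor = self._donor(rng) + "ACCGGT" + self._rand_site_free(rng, 50)
        with pytest.raises(ValueError, match="AgeI"):
            insert_flanking_sites(donor, "AAA", AgeI, XhoI)

    def test_empty_insert_is_identity(self, rng):
        donor = self._donor(rng)
        assert circular_equal(insert_flanking_sites(donor, "", AgeI, XhoI), donor)


class TestVerifyConstruct:
    def test_correct_circular_order(self, rng):
        parts = [rand_dna(rng, 80) for _ in range(3)]
        construct = parts[1] + parts[2] + parts[0]  # a rotation of the order
        ok, violation = verify_construct(construct, parts)
        assert ok and violation is None

    def test_swapped_order_detected(self, rng):
        parts = [rand_dna(rng, 80) for _ in range(3)]
        ok, violation = verify_construct(parts[0] + parts[2] + parts[1], parts)
        assert not ok and "order" in violation

    def test_duplicate_element_detected(self, rng):
        a, b = rand_dna(rng, 60), rand_dna(rng, 60)
        ok, violation = verify_construct(a + b + a, [a, b])
        assert not ok and "2 times" in violation
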