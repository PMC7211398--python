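import pytest

from donorforge.enzymes import DEFAULT_ENZYMES
from donorforge.genome_screen import build_index
from donorforge.linkers import (
    LinkerLayout,
    LinkerPair,
    default_layout,
    design_primers,
    enumerate_candidates,
    rank_pairs,
    run_pipeline,
    screen_pair,
)
from donorforge.seq_metrics import FilterThresholds, revcomp
from conftest import rand_dna

E = DEFAULT_ENZYMES


def small_layout() -> LinkerLayout:
    """A 26-bp layout with a 4-base total spacer budget, small enough for
    exhaustive enumeration in tests."""
    return LinkerLayout(
        enzymes_a=(E["AgeI"], E["NheI"], E["SalI"], E["BamHI"]),
        enzymes_b=(E["SpeI"], E["MluI"], E["EcoRV"], E["XhoI"]),
        gaps_a=(1, 1, 0, 0),
        gaps_b=(0, 0, 1, 1),
        linker_len=26,
    )


class TestLayout:
    def test_default_geometry(self):
        lay = default_layout()
        assert lay.linker_len == 30
        assert lay.enzymes_a[0].name == "AgeI"
        assert lay.enzymes_b[-1].name == "XhoI"
        assert len(lay.enzymes) == 8
        assert lay.spacer_budget == 12

    def test_bad_budget_rejected(self):
        with pytest.raises(ValueError):
            LinkerLayout(
                enzymes_a=(E["AgeI"],),
                enzymes_b=(E["XhoI"],),
                gaps_a=(1,),
                gaps_b=(1,),
                linker_len=30,
            )

    def test_anchoring(self):
        lay = default_layout()
        a = lay.build_linker_a("AT" * 3)
        b = lay.build_linker_b("AT" * 3)
        assert a.startswith("ACCGGT") and len(a) == 30
        assert b.endswith("CTCGAG") and len(b) == 30


class TestEnumeration:
    def test_exhaustive_count_matches_closed_form(self):
        lay = small_layout()
        stats = {}
        pairs = list(enumerate_candidates(lay, mode="exhaustive", stats=stats))
        assert stats["generated"] == 4**lay.spacer_budget == 256
        assert stats["emitted"] + stats["discarded"] == stats["generated"]
        assert len(pairs) == stats["emitted"]

    def test_zero_budget_single_candidate(self):
        lay = LinkerLayout(
            enzymes_a=(E["AgeI"], E["NheI"], E["SalI"], E["BamHI"]),
            enzymes_b=(E["SpeI"], E["MluI"], E["EcoRV"], E["XhoI"]),
            gaps_a=(0, 0, 0, 0),
            gaps_b=(0, 0, 0, 0),
            linker_len=24,
        )
        pairs = list(enumerate_candidates(lay, mode="exhaustive"))
        assert len(pairs) == 1

    def test_site_uniqueness_invariant(self):
        lay = small_layout()
        for pair in enumerate_candidates(lay, mode="exhaustive"):
            for enzymes, own, other in (
                (lay.enzymes_a, pair.linker_a, pair.linker_b),
                (lay.enzymes_b, pair.linker_b, pair.linker_a),
            ):
                for enz in enzymes:
                    assert own.count(enz.site) == 1
                    assert other.count(enz.site) == 0

    def test_sampled_determinism(self):
        lay = default_layout()
        a = [(p.linker_a, p.linker_b)
             for p in enumerate_candidates(lay, "sampled", seed=7, max_candidates=50)]
        b = [(p.linker_a, p.linker_b)
             for p in enumerate_candidates(lay, "sampled", seed=7, max_candidates=50)]
        assert a == b and 0 < len(a) <= 50  # draws are fixed; a few fail uniqueness

    def test_auto_switch_to_sampling(self, caplog):
        lay = default_layout()  # 4^12 assignments
        with caplog.at_level("WARNING"):
            pairs = list(enumerate_candidates(lay, "exhaustive", seed=1, max_candidates=20))
        assert len(pairs) <= 20
        assert any("switching to seeded sampling" in r.message for r in caplog.records)


class TestScreenPair:
    def test_repeat_failure_named(self):
        lay = default_layout()
        pair = LinkerPair("ACGTAAAAAAAAGATCGATGCAGTCATGCA", "ACTAGTACACGCGTAGGATATCTTCTCGAG", lay)
        screen_pair(pair)
        assert "repeats" in pair.report_a.failed_filters()
        assert not pair.passed

    def test_revcomp_pair_fails_cross_dimer(self):
        lay = default_layout()
        a = "ACCGGTAGGCTAGCAAGTCGACCTGGATCC"
        pair = screen_pair(LinkerPair(a, revcomp(a), lay))
        assert "cross_dimer" in pair.report_cross.failed_filters()

    def test_passing_pair_has_empty_reports(self):
        lay = default_layout()
        pair = screen_pair(
            LinkerPair("ACCGGTAGGCTAGCAAGTCGACCTGGATCC", "ACTAGTACACGCGTAGGATATCTTCTCGAG", lay)
        )
        assert pair.passed
        assert pair.report_a.failures == pair.report_b.failures == []


class TestRanking:
    def _passing_pairs(self, n=6, seed=11):
        lay = default_layout()
        out = []
        for cand in enumerate_candidates(lay, "sampled", seed=seed, max_candidates=5000):
            if screen_pair(cand).passed:
                out.append(cand)
                if len(out) == n:
                    break
        assert len(out) == n
        return out

    def test_orders_by_identity_and_assigns_ranks(self, rng):
        genome = rand_dna(rng, 50000)
        idx = build_index([("c", genome)], k=8)
        pairs = self._passing_pairs()
        ranked = rank_pairs(pairs, idx)
        scores = [p.identity.longest_shared_substring for p in ranked]
        assert scores == sorted(scores)
        assert [p.rank for p in ranked] == list(range(1, len(ranked) + 1))

    def test_planted_genome_copy_ranked_last(self, rng):
        pairs = self._passing_pairs()
        genome = rand_dna(rng, 20000) + pairs[0].linker_a + rand_dna(rng, 20000)
        idx = build_index([("c", genome)], k=8)
        ranked = rank_pairs(pairs, idx)
        assert ranked[-1] is pairs[0]
        assert ranked[-1].identity.longest_shared_substring == 30

    def test_stable_under_input_permutation(self, rng):
        genome = rand_dna(rng, 30000)
        idx = build_index([("c", genome)], k=8)
        pairs = self._passing_pairs()
        order1 = [(p.linker_a, p.linker_b) for p in rank_pairs(list(pairs), idx)]
        for p in pairs:
            p.identity = p.rank = None
        order2 = [(p.linker_a, p.linker_b) for p in rank_pairs(list(reversed(pairs)), idx)]
        assert order1 == order2

    def test_unscreened_pair_rejected(self, rng):
        idx = build_index([("c", rand_dna(rng, 2000))], k=8)
        with pytest.raises(ValueError):
            rank_pairs([LinkerPair("A" * 30, "C" * 30, default_layout())], idx)


class TestPrimers:
    def test_60bp_contract(self, rng):
        arm = rand_dna(rng, 30)
        linker = "ACCGGTAGGCTAGCAAGTCGACCTGGATCC"
        p5 = design_primers(arm, linker, "5p")
        p3 = design_primers(arm, linker, "3p")
        assert len(p5) == len(p3) == 60
        assert p5 == linker + arm
        assert p5[-30:] == arm
        assert p3 == revcomp(linker) + arm

    def test_length_preconditions(self, rng):
        with pytest.raises(ValueError):
            design_primers(rand_dna(rng, 30), "", "5p")
        with pytest.raises(ValueError):
            design_primers(rand_dna(rng, 29), "A" * 30, "5p")
        with pytest.raises(ValueError):
            design_primers(rand_dna(rng, 30), "A" * 30, "sideways")


class TestPipeline:
    def test_pure_function_of_inputs(self, rng):
        genome = rand_dna(rng, 40000)
        idx = build_index([("c", genome)], k=8)
        kwargs = dict(mode="sampled", seed=5, max_candidates=800, top=5)
        r1 = run_pipeline(idx, **kwargs)
        r2 = run_pipeline(idx, **kwargs)
        assert [(p.linker_a, p.linker_b, p.rank) for p in r1.pairs] == [
            (p.linker_a, p.linker_b, p.rank) for p in r2.pairs
        ]
        assert len(r1.pairs) > 0
        assert r1.stats["thresholds"] == FilterThresholds().to_dict()

    def test_survivors_satisfy_anchor_invariant(self, rng):
        idx = build_index([("c", rand_dna(rng, 20000))], k=8)
        result = run_pipeline(idx, mode="sampled", seed=2, max_candidates=600)
        assert result.pairs
        for p in result.pairs:
            assert p.linker_a.startswith("ACCGGT")
            assert p.linker_b.endswith("CTCGAG")
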