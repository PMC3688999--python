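import math

import numpy as np
import pytest

from plastocomp import genome_model as gm
from plastocomp import intergenic as ig
from plastocomp import structure as st
from plastocomp import synthetic_data as syn
from _oracles import kimura2p


@pytest.fixture(scope="module")
def spacer_setup(planted_pair):
    ga, gb, truth, ptruth = planted_pair
    quad = st.partition_quadripartite(ga.seq, st.find_ir(ga.seq, 1000))
    spa = ig.extract_unique_spacers(ga, quad=quad)
    spb = ig.extract_unique_spacers(gb, quad=quad)
    return ga, gb, ptruth, spa, spb


class TestExtraction:
    def test_two_genes_give_two_spacers(self):
        seq = gm.Sequence("ACGT" * 250)
        g = gm.AnnotatedGenome("t", seq, (
            gm.Feature("a", "CDS", "+", ((100, 300),)),
            gm.Feature("b", "CDS", "-", ((500, 800),))))
        spacers = ig.extract_unique_spacers(g)
        assert len(spacers) == 2
        assert {sp.name for sp in spacers} == {"a-b", "b-a"}

    def test_matches_generator_truth(self, spacer_setup):
        ga, gb, ptruth, spa, _ = spacer_setup
        got = {sp.name: sp.interval for sp in spa}
        for name, iv in ptruth.spacer_intervals_a.items():
            assert got[name] == iv

    def test_ira_spacers_collapsed(self, spacer_setup):
        ga, *_ = spacer_setup
        quad = st.partition_quadripartite(ga.seq, st.find_ir(ga.seq, 1000))
        a0, a1 = quad.ira
        for sp in ig.extract_unique_spacers(ga, quad=quad):
            s, e = sp.interval
            assert not (a0 <= s and e <= a1)

    def test_zero_length_gaps_skipped(self):
        seq = gm.Sequence("ACGT" * 100)
        g = gm.AnnotatedGenome("t", seq, (
            gm.Feature("a", "CDS", "+", ((0, 100),)),
            gm.Feature("b", "CDS", "+", ((100, 250),))))
        assert len(ig.extract_unique_spacers(g)) == 1  # only b..a around the circle


class TestExclusions:
    def test_excluded_gene_spacers_removed(self, spacer_setup):
        *_, spa, _ = spacer_setup
        victim = spa[0].name.split("-", 1)[0]
        expected_drop = sum(victim in sp.name.split("-", 1) for sp in spa)
        kept, warnings = ig.apply_exclusions(spa, [victim])
        assert len(spa) - len(kept) == expected_drop
        assert warnings == []

    def test_empty_exclusion_is_identity(self, spacer_setup):
        *_, spa, _ = spacer_setup
        kept, _ = ig.apply_exclusions(spa, [])
        assert kept == spa

    def test_unknown_gene_warns_and_noops(self, spacer_setup):
        *_, spa, _ = spacer_setup
        kept, warnings = ig.apply_exclusions(spa, ["nosuchgene"],
                                             known_genes={"a", "b"})
        assert kept == spa
        assert len(warnings) == 1


class TestPairing:
    def test_identical_annotations_all_matched(self, spacer_setup):
        *_, spa, spb = spacer_setup
        pairs, un_a, un_b = ig.pair_spacers(spa, spb)
        assert len(pairs) == len(spa) == len(spb)
        assert un_a == un_b == []

    def test_missing_gene_leaves_unmatched(self, spacer_setup):
        *_, spa, spb = spacer_setup
        victim = spa[3].name.split("-", 1)[0]
        spb_cut = [sp for sp in spb if victim not in sp.name.split("-", 1)]
        pairs, un_a, un_b = ig.pair_spacers(spa, spb_cut)
        assert all(victim in sp.name.split("-", 1) for sp in un_a)
        assert len(un_a) >= 1


class TestDivergence:
    def test_identical_sequences_zero_under_all_models(self):
        sp = ig.Spacer("x", (0, 400), "ACGT" * 100)
        for model in ("p", "JC", "F84"):
            d = ig.divergence(sp, sp, model=model)
            assert d.defined and d.distance == pytest.approx(0.0, abs=1e-12)

    def test_closed_forms_on_100_in_1000_substitutions(self):
        rng = np.random.default_rng(2)
        bases = np.array(list("ACGT"))
        a = "".join(bases[rng.integers(0, 4, 1000)])
        arr = list(a)
        for p in rng.choice(1000, 100, replace=False):
            arr[p] = [c for c in "ACGT" if c != arr[p]][int(rng.integers(3))]
        sa, sb = ig.Spacer("x", (0, 1000), a), ig.Spacer("x", (0, 1000), "".join(arr))
        assert ig.divergence(sa, sb, model="p").distance == pytest.approx(0.100, abs=1e-12)
        jc = ig.divergence(sa, sb, model="JC").distance
        assert jc == pytest.approx(-0.75 * math.log(1 - 0.4 / 3), abs=1e-9)

    def test_f84_equals_independent_closed_form_at_equal_frequencies(self):
        # equal base frequencies, composition-preserving substitutions:
        # 30 A->G plus 30 G->A transitions (P=0.06), 10 A->C plus 10 C->A
        # transversions (Q=0.02); F84 must reduce to the two-parameter form
        # exactly 250 of each base (shuffled, so no periodicity), mutated by
        # composition-preserving swaps at scattered positions: frequencies
        # stay exactly 1/4 each and the optimal alignment is the identity
        rng = np.random.default_rng(8)
        a = "".join(rng.permutation(list("ACGT" * 250)))
        arr = list(a)
        a_pos = [i for i, c in enumerate(a) if c == "A"]
        g_pos = [i for i, c in enumerate(a) if c == "G"]
        c_pos = [i for i, c in enumerate(a) if c == "C"]
        for i in a_pos[::8][:30]:
            arr[i] = "G"
        for i in g_pos[::8][:30]:
            arr[i] = "A"
        for i in a_pos[4::8][:10]:
            arr[i] = "C"
        for i in c_pos[4::8][:10]:
            arr[i] = "A"
        sa = ig.Spacer("x", (0, 1000), a)
        sb = ig.Spacer("x", (0, 1000), "".join(arr))
        d = ig.divergence(sa, sb, model="F84")
        assert d.aligned_length == 1000
        assert d.p_distance == pytest.approx(0.08, abs=1e-12)
        assert d.distance == pytest.approx(kimura2p(0.06, 0.02), abs=1e-9)

    def test_model_ordering_strict(self, spacer_setup):
        ga, gb, ptruth, spa, spb = spacer_setup
        pairs, *_ = ig.pair_spacers(spa, spb)
        for a, b in pairs:
            dp = ig.divergence(a, b, model="p")
            dj = ig.divergence(a, b, model="JC")
            df = ig.divergence(a, b, model="F84")
            if not (dp.defined and dj.defined and df.defined):
                continue
            assert df.distance >= dj.distance - 1e-12
            assert dj.distance >= dp.distance - 1e-12
            if dp.distance > 0:
                assert dj.distance > dp.distance

    def test_symmetry(self, spacer_setup):
        ga, gb, ptruth, spa, spb = spacer_setup
        pairs, *_ = ig.pair_spacers(spa, spb)
        for a, b in pairs[:10]:
            d1 = ig.divergence(a, b, model="F84")
            d2 = ig.divergence(b, a, model="F84")
            assert d1.distance == pytest.approx(d2.distance, abs=1e-12)

    def test_planted_p_distance_exact(self, mid_plastome):
        # substitution-only pair (no planted SSR runs): measured p equals
        # the constructed per-spacer substitution proportion exactly
        g, truth = mid_plastome
        ga, gb, ptruth = syn.make_genome_pair(
            g, truth, syn.DivergenceSpec(default_rate=0.02), seed=13)
        checked = 0
        for name, (s, e) in ptruth.spacer_intervals_a.items():
            a = ig.Spacer(name, (s, e), ga.seq.residues[s:e])
            b = ig.Spacer(name, (s, e), gb.seq.residues[s:e])
            d = ig.divergence(a, b, model="p")
            assert d.distance == pytest.approx(ptruth.spacer_true_p[name], abs=1e-12)
            checked += 1
        assert checked >= 20


class TestSummaryAndSelection:
    def _mk(self, name, dist, length=600):
        return ig.SpacerDivergence(name, ("A", "B"), length, dist, dist, "p")

    def test_mean_sd_hand_arithmetic(self):
        divs = [self._mk("a", 0.1), self._mk("b", 0.2), self._mk("c", 0.3)]
        mean, sd, ranked = ig.summarize_comparison(divs)
        assert mean == pytest.approx(0.2)
        assert sd == pytest.approx(0.1)
        assert [d.spacer for d in ranked] == ["c", "b", "a"]
        assert [d.rank for d in ranked] == [1, 2, 3]

    def test_single_distance_sd_zero(self):
        mean, sd, _ = ig.summarize_comparison([self._mk("a", 0.25)])
        assert (mean, sd) == (0.25, 0.0)

    def test_tie_break_by_aligned_length_then_name(self):
        divs = [self._mk("bb", 0.2, 500), self._mk("aa", 0.2, 500),
                self._mk("cc", 0.2, 900)]
        _, _, ranked = ig.summarize_comparison(divs)
        assert [d.spacer for d in ranked] == ["cc", "aa", "bb"]

    def test_select_markers_top_k_and_length_filter(self):
        focal = ([ig.Spacer(f"s{i:02d}-x", (0, 700), "A" * 700) for i in range(8)]
                 + [ig.Spacer(f"s{i:02d}-x", (0, 300), "A" * 300) for i in range(8, 16)])
        comparisons = {}
        for comp in ("c1", "c2", "c3"):
            divs = [self._mk(sp.name, 0.3 if sp.name in
                             ("s00-x", "s01-x", "s08-x") else 0.01, len(sp))
                    for sp in focal]
            comparisons[comp] = ig.summarize_comparison(divs)[2]
        sel = ig.select_markers(comparisons, focal, k=3, min_len=500)
        assert {m.spacer for m in sel} == {"s00-x", "s01-x"}
        for m in sel:
            assert all(r <= 3 for r in m.ranks.values())

    def test_adding_comparison_never_grows_selection(self):
        focal = [ig.Spacer(f"s{i}-x", (0, 700), "A" * 700) for i in range(10)]
        rng = np.random.default_rng(0)
        tables = {}
        for comp in ("c1", "c2", "c3"):
            divs = [self._mk(sp.name, float(rng.random()), 700) for sp in focal]
            tables[comp] = ig.summarize_comparison(divs)[2]
        sel2 = ig.select_markers({k: tables[k] for k in ("c1", "c2")}, focal, k=4, min_len=0)
        sel3 = ig.select_markers(tables, focal, k=4, min_len=0)
        assert {m.spacer for m in sel3} <= {m.spacer for m in sel2}

    def test_k_clamped_to_table_size(self):
        focal = [ig.Spacer("a-b", (0, 700), "A" * 700)]
        table = ig.summarize_comparison([self._mk("a-b", 0.2)])[2]
        sel = ig.select_markers({"c1": table}, focal, k=100, min_len=0)
        assert [m.spacer for m in sel] == ["a-b"]
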