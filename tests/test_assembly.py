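import numpy as np
import pytest

from plastocomp import assembly as asm
from plastocomp import genome_model as gm
from plastocomp import synthetic_data as syn
from plastocomp.genome_model import reverse_complement


BASES = np.array(list("ACGT"))


def _random_seq(n, rng):
    return "".join(BASES[rng.integers(0, 4, n)])


def _tiling_reads(seq, read_len=100, step=5, prefix="t"):
    """Error-free reads tiling a linear sequence."""
    return [asm.Read(f"{prefix}{i}", seq[i:i + read_len])
            for i in range(0, len(seq) - read_len + 1, step)]


@pytest.fixture(scope="module")
def small_assembly_setup():
    """21-kb plastome with 2.5-kb IR plus PE + spanning MP libraries."""
    spec = syn.PlastomeSpec(lsc_len=12_000, ssc_len=4_000, ir_len=2_500,
                            n_genes=16, n_trna=4, intron_genes=2, ir_genes=1,
                            seed=3)
    g, truth = syn.make_plastome(spec)
    pe = syn.ReadLibSpec(read_len=100, insert_mean=250, insert_sd=25,
                         coverage=40, seed=11)
    mp = syn.ReadLibSpec(read_len=100, insert_mean=3_500, insert_sd=300,
                         coverage=20, mate_pair=True, seed=12)
    r1, r2, _ = syn.simulate_reads(g, pe, "pe")
    m1, m2, _ = syn.simulate_reads(g, mp, "mp")
    libs = [asm.ReadLibrary(asm.pair_reads(r1, r2, "paired_end", 250, 25),
                            250, 25, "paired_end"),
            asm.ReadLibrary(asm.pair_reads(m1, m2, "mate_pair", 3_500, 300),
                            3_500, 300, "mate_pair")]
    return g, truth, libs


class TestRecruit:
    def test_verbatim_read_recruited(self):
        rng = np.random.default_rng(1)
        ref = _random_seq(2_000, rng)
        read = asm.Read("r", ref[500:600])
        assert asm.recruit_reads([read], [ref]) == [read]
        rc_read = asm.Read("r2", reverse_complement(ref[500:600]))
        assert asm.recruit_reads([rc_read], [ref]) == [rc_read]

    def test_contaminants_rejected_plastome_recalled(self):
        g, _ = syn.make_plastome(syn.PlastomeSpec(
            8_000, 3_000, 1_500, n_genes=10, n_trna=2, seed=6))
        lib = syn.ReadLibSpec(coverage=3, contaminant_fraction=0.3, seed=8)
        r1, r2, truth = syn.simulate_reads(g, lib)
        reads = [asm.Read(rid, s) for rid, s, _ in r1]
        recruited = {r.id for r in asm.recruit_reads(reads, [g.seq.residues])}
        for rid, s, _ in r1:
            stem = rid.rsplit("/", 1)[0]
            is_contam = truth.origins[stem][3]
            if is_contam:
                assert rid not in recruited      # 0% contaminant recruitment
            else:
                assert rid in recruited          # 100% recall

    def test_threshold_above_kmer_count_empty(self):
        rng = np.random.default_rng(2)
        ref = _random_seq(1_000, rng)
        read = asm.Read("r", ref[100:160])       # 30 k-mers at k=31
        assert asm.recruit_reads([read], [ref], k=31, t=31) == []

    def test_empty_reference_set_errors(self):
        with pytest.raises(ValueError):
            asm.recruit_reads([asm.Read("r", "ACGT" * 30)], [])


class TestInitialAssemble:
    def test_single_contig_from_repeat_free_sequence(self):
        rng = np.random.default_rng(4)
        seq = _random_seq(1_000, rng)
        contigs = asm.initial_assemble(_tiling_reads(seq), k=31,
                                       min_contig_len=500)
        assert len(contigs) == 1
        got = contigs[0].residues
        assert got == seq or got == reverse_complement(seq)

    def test_ir_breaks_assembly_but_contigs_are_exact(self, small_assembly_setup):
        g, truth, libs = small_assembly_setup
        reads = [r for lib in libs for r in lib.reads()]
        contigs = asm.initial_assemble(reads, k=31, min_contig_len=500)
        assert len(contigs) > 1                  # broken at the IR
        doubled = g.seq.residues * 2
        for c in contigs:
            assert c.residues in doubled or reverse_complement(c.residues) in doubled

    def test_min_contig_len_zero_never_loses_bases(self, small_assembly_setup):
        g, truth, libs = small_assembly_setup
        reads = [r for lib in libs for r in lib.reads()]
        kept = asm.initial_assemble(reads, k=31, min_contig_len=500)
        everything = asm.initial_assemble(reads, k=31, min_contig_len=0)
        assert (sum(len(c) for c in everything)
                >= sum(len(c) for c in kept))

    def test_no_reads_empty_result(self):
        assert asm.initial_assemble([], k=31) == []

    def test_even_k_rejected(self):
        with pytest.raises(ValueError):
            asm.initial_assemble([asm.Read("r", "ACGT" * 20)], k=30)


class TestIterateImprove:
    def test_complete_circle_one_contig_converges(self):
        rng = np.random.default_rng(9)
        genome = _random_seq(6_000, rng)
        g = gm.AnnotatedGenome("c", gm.Sequence(genome, True))
        lib = syn.ReadLibSpec(read_len=100, insert_mean=300, insert_sd=30,
                              coverage=30, seed=5)
        r1, r2, _ = syn.simulate_reads(g, lib)
        pairs = asm.pair_reads(r1, r2, "paired_end", 300, 30)
        libs = [asm.ReadLibrary(pairs, 300, 30, "paired_end")]
        contigs = asm.initial_assemble([r for p in pairs for r in (p.r1, p.r2)],
                                       k=31, min_contig_len=500)
        assert len(contigs) == 1 and contigs[0].circular
        final, report = asm.iterate_improve(contigs, libs)
        assert report.circularized
        assert asm.circular_equivalent(final.contigs[0].residues, genome)

    def test_end_to_end_recovers_planted_plastome(self, small_assembly_setup):
        g, truth, libs = small_assembly_setup
        reads = [r for lib in libs for r in lib.reads()]
        contigs = asm.initial_assemble(reads, k=31, min_contig_len=500)
        final, report = asm.iterate_improve(contigs, libs)
        assert report.circularized
        assert len(final.contigs[0]) == len(g)
        assert asm.circular_equivalent(final.contigs[0].residues, g.seq.residues)
        assert report.anomalies == []

    def test_scaffold_count_never_increases(self, small_assembly_setup):
        g, truth, libs = small_assembly_setup
        reads = [r for lib in libs for r in lib.reads()]
        contigs = asm.initial_assemble(reads, k=31, min_contig_len=500)
        final, report = asm.iterate_improve(contigs, libs)
        assert report.n_scaffolds <= report.n_input_contigs

    def test_deterministic(self, small_assembly_setup):
        g, truth, libs = small_assembly_setup
        reads = [r for lib in libs for r in lib.reads()]
        out = []
        for _ in range(2):
            contigs = asm.initial_assemble(reads, k=31, min_contig_len=500)
            final, _ = asm.iterate_improve(contigs, libs)
            out.append(tuple(c.residues for c in final.contigs))
        assert out[0] == out[1]

    def test_misjoin_appears_in_anomaly_list(self):
        rng = np.random.default_rng(14)
        genome = _random_seq(12_000, rng)
        g = gm.AnnotatedGenome("m", gm.Sequence(genome, True))
        lib = syn.ReadLibSpec(read_len=100, insert_mean=400, insert_sd=40,
                              coverage=30, seed=15)
        r1, r2, _ = syn.simulate_reads(g, lib)
        pairs = asm.pair_reads(r1, r2, "paired_end", 400, 40)
        libs = [asm.ReadLibrary(pairs, 400, 40, "paired_end")]
        # deliberately misjoin: swap two 3-kb blocks -> breakpoints at
        # 3000, 6000 and 9000
        mis = genome[:3_000] + genome[6_000:9_000] + genome[3_000:6_000] + genome[9_000:]
        anomalies = asm.detect_anomalies(mis, True, libs)
        for breakpoint in (3_000, 6_000, 9_000):
            assert any(s <= breakpoint <= e for s, e in anomalies)

    def test_clean_assembly_has_no_anomalies(self):
        rng = np.random.default_rng(16)
        genome = _random_seq(8_000, rng)
        g = gm.AnnotatedGenome("ok", gm.Sequence(genome, True))
        lib = syn.ReadLibSpec(read_len=100, insert_mean=400, insert_sd=40,
                              coverage=30, seed=17)
        r1, r2, _ = syn.simulate_reads(g, lib)
        libs = [asm.ReadLibrary(asm.pair_reads(r1, r2, "paired_end", 400, 40),
                                400, 40, "paired_end")]
        assert asm.detect_anomalies(genome, True, libs) == []


class TestMapAndCoverage:
    def test_mean_depth_matches_simulated_coverage(self):
        g, _ = syn.make_plastome(syn.PlastomeSpec(
            8_000, 3_000, 1_500, n_genes=10, n_trna=2, seed=20))
        lib = syn.ReadLibSpec(coverage=30, insert_mean=300, insert_sd=30, seed=21)
        r1, r2, _ = syn.simulate_reads(g, lib)
        reads = [asm.Read(rid, s) for rid, s, _ in r1 + r2]
        assembly = asm.Assembly([asm.Contig(g.seq.residues, np.ones(1), True)])
        tracks, unplaced = asm.map_and_coverage(assembly, reads)
        assert unplaced == 0
        assert abs(tracks[0].mean() - 30) <= 0.05 * 30

    def test_empty_read_set_zero_track(self):
        assembly = asm.Assembly([asm.Contig("ACGT" * 100, np.ones(1), True)])
        tracks, unplaced = asm.map_and_coverage(assembly, [])
        assert tracks[0].sum() == 0 and unplaced == 0

    def test_ir_collapsed_reference_doubles_depth(self):
        g, truth = syn.make_plastome(syn.PlastomeSpec(
            8_000, 3_000, 1_500, n_genes=10, n_trna=2, ir_genes=1, seed=22))
        lib = syn.ReadLibSpec(coverage=30, insert_mean=300, insert_sd=30, seed=23)
        r1, r2, _ = syn.simulate_reads(g, lib)
        reads = [asm.Read(rid, s) for rid, s, _ in r1 + r2]
        # single-IR-collapsed reference: LSC + IRb + SSC (IRa removed)
        L, I, S = 8_000, 1_500, 3_000
        collapsed = g.seq.residues[:L + I + S]
        assembly = asm.Assembly([asm.Contig(collapsed, np.ones(1), True)])
        tracks, _ = asm.map_and_coverage(assembly, reads)
        sc_depth = tracks[0][1_000:7_000].mean()
        ir_depth = tracks[0][L + 200:L + I - 200].mean()
        assert ir_depth == pytest.approx(2 * sc_depth, rel=0.15)
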