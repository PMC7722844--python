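import numpy as np
import pandas as pd
import pytest

from silentscan import synthetic_data as sd
from silentscan._seq import revcomp
from silentscan.synthetic_data import (
    CountSimConfig,
    ReadSimConfig,
    TruthInsertion,
)


class TestSimulateGenome:
    def test_length_and_alphabet(self):
        seq = sd.simulate_genome(1000, 0.5, seed=1)
        assert len(seq) == 1000
        assert set(seq) <= set("ACGT")

    def test_deterministic(self):
        assert sd.simulate_genome(1000, 0.5, seed=1) == sd.simulate_genome(1000, 0.5, seed=1)

    def test_gc_concentration(self):
        # binomial sd at n=1e5, p=0.64 is ~0.0015; +-0.01 is ~6.6 sd
        seq = sd.simulate_genome(100_000, 0.64, seed=7)
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert abs(gc - 0.64) <= 0.01

    @pytest.mark.parametrize("length,gc", [(0, 0.5), (-5, 0.5), (100, 0.0), (100, 1.0)])
    def test_invalid_args(self, length, gc):
        with pytest.raises(ValueError):
            sd.simulate_genome(length, gc, seed=0)


def _lift_bruteforce(chrom, position, strain, design, te_library):
    """Independent coordinate-lifting oracle: insert elements one at a time
    into an explicit marker list and track where `position` lands."""
    carried = sorted(
        (i for i in design if i.chrom == chrom and strain in i.strain_set),
        key=lambda i: i.position,
    )
    offset = 0
    for ins in carried:
        if ins.position < position:
            offset += len(te_library[ins.te_name])
    return position + offset


class TestPlantInsertions:
    def test_length_conservation(self, te_library):
        backbone = {"chr1": sd.simulate_genome(10_000, 0.5, seed=3)}
        strains = frozenset(["s1", "s2", "s3", "s4"])
        design = [TruthInsertion("TEalpha", strains, "chr1", 5000, 1000)]
        genomes, truth = sd.plant_te_insertions(backbone, te_library, design)
        assert truth == design
        for strain in strains:
            assert len(genomes[strain]["chr1"]) == 11_000

    def test_mrc1_pattern_row_sums(self):
        # 154 shared + 3/3/4/7 singletons + 7 triple = 178 insertions total
        strains = ("cw15arg", "Elow47", "UVM4", "UVM11")
        design = []
        pos = 100
        def add(n, carriers):
            nonlocal pos
            for _ in range(n):
                design.append(TruthInsertion("MRC1like", frozenset(carriers), "chr1", pos, 10))
                pos += 50
        add(154, strains)
        for strain, n in zip(strains, (3, 3, 4, 7)):
            add(n, [strain])
        add(7, strains[1:])
        assert len(design) == 178
        per_strain = {s: sum(1 for i in design if s in i.strain_set) for s in strains}
        assert per_strain == {"cw15arg": 157, "Elow47": 164, "UVM4": 165, "UVM11": 168}

    def test_inserted_sequence_recovered(self, te_library):
        backbone = {"chr1": sd.simulate_genome(8000, 0.5, seed=4)}
        design = [
            TruthInsertion("TEalpha", frozenset(["s1"]), "chr1", 1000, 1000),
            TruthInsertion("TEbeta", frozenset(["s1", "s2"]), "chr1", 4000, 800),
        ]
        genomes, _ = sd.plant_te_insertions(backbone, te_library, design)
        for ins in design:
            for strain in ins.strain_set:
                lifted = sd.lift_position(ins.chrom, ins.position, strain, design)
                assert lifted == _lift_bruteforce(ins.chrom, ins.position, strain, design, te_library)
                got = genomes[strain][ins.chrom][lifted:lifted + ins.te_length]
                assert got == te_library[ins.te_name]

    def test_overlapping_positions_rejected(self, te_library):
        backbone = {"chr1": "ACGT" * 1000}
        design = [
            TruthInsertion("TEalpha", frozenset(["s1"]), "chr1", 100, 1000),
            TruthInsertion("TEbeta", frozenset(["s2"]), "chr1", 100, 800),
        ]
        with pytest.raises(ValueError, match="overlapping"):
            sd.plant_te_insertions(backbone, te_library, design)

    def test_unknown_te_rejected(self, te_library):
        backbone = {"chr1": "ACGT" * 1000}
        design = [TruthInsertion("nope", frozenset(["s1"]), "chr1", 100, 5)]
        with pytest.raises(ValueError, match="unknown TE"):
            sd.plant_te_insertions(backbone, te_library, design)


class TestSimulatePairedReads:
    def test_zero_error_reads_are_substrings(self, small_genome):
        cfg = ReadSimConfig(coverage=2, error_rate=0.0, seed=5)
        pairs = sd.simulate_paired_reads({"chr1": small_genome}, cfg)
        haystack = small_genome + "#" + revcomp(small_genome)
        assert all(p.seq1 in haystack and p.seq2 in haystack for p in pairs)

    def test_pair_count_formula(self):
        genome = {"chr1": sd.simulate_genome(200_000, 0.5, seed=6)}
        cfg = ReadSimConfig(coverage=30, error_rate=0.0, seed=6)
        pairs = sd.simulate_paired_reads(genome, cfg)
        assert abs(len(pairs) - 30_000) <= 0.05 * 30_000

    def test_mate2_is_far_end_revcomp(self, small_genome):
        cfg = ReadSimConfig(coverage=0.5, error_rate=0.0, seed=8)
        for p in sd.simulate_paired_reads({"chr1": small_genome}, cfg):
            frag = small_genome[p.fragment_start:p.fragment_end]
            assert p.seq1 == frag[:100]
            assert p.seq2 == revcomp(frag[-100:])

    def test_fastq_deterministic(self, small_genome, tmp_path):
        cfg = ReadSimConfig(coverage=1, error_rate=0.01, seed=9)
        for run in ("a", "b"):
            pairs = sd.simulate_paired_reads({"chr1": small_genome}, cfg)
            sd.write_fastq_pair(pairs, tmp_path / f"{run}_1.fq", tmp_path / f"{run}_2.fq")
        assert (tmp_path / "a_1.fq").read_bytes() == (tmp_path / "b_1.fq").read_bytes()
        assert (tmp_path / "a_2.fq").read_bytes() == (tmp_path / "b_2.fq").read_bytes()

    def test_genome_too_short(self):
        cfg = ReadSimConfig(insert_mean=300, insert_sd=30, coverage=1, seed=0)
        with pytest.raises(ValueError, match="shorter"):
            sd.simulate_paired_reads({"chr1": "ACGT" * 50}, cfg)

    def test_invalid_config(self):
        with pytest.raises(ValueError):
            ReadSimConfig(read_length=10)
        with pytest.raises(ValueError):
            ReadSimConfig(insert_mean=150.0)
        with pytest.raises(ValueError):
            ReadSimConfig(error_rate=0.5)


class TestSimulateCounts:
    def test_null_mean_ratio(self):
        cfg = CountSimConfig(n_genes=300, n_replicates=200, baseline_mean=200,
                             dispersion=0.05, seed=10)
        counts, truth = sd.simulate_counts(cfg)
        assert truth.empty
        a = counts.iloc[:, :200].mean(axis=1)
        b = counts.iloc[:, 200:].mean(axis=1)
        ratio = b / a
        assert (np.abs(ratio - 1) <= 0.10).mean() >= 0.95

    def test_poisson_limit(self):
        cfg = CountSimConfig(n_genes=5, n_replicates=4000, baseline_mean=100,
                             baseline_log2_sd=0.0, dispersion=1e-8, seed=11)
        counts, _ = sd.simulate_counts(cfg)
        values = counts.to_numpy()
        ratio = values.var(axis=1) / values.mean(axis=1)
        assert np.allclose(ratio, 1.0, atol=0.15)

    def test_planted_fold_change_realized(self):
        cfg = CountSimConfig(n_genes=50, n_replicates=300, baseline_mean=100,
                             dispersion=0.05, planted_de=((0, 2.0), (1, -2.0)), seed=12)
        counts, truth = sd.simulate_counts(cfg)
        a = counts.iloc[:, :300].mean(axis=1)
        b = counts.iloc[:, 300:].mean(axis=1)
        assert abs(np.log2(b.iloc[0] / a.iloc[0]) - 2.0) < 0.2
        assert abs(np.log2(b.iloc[1] / a.iloc[1]) + 2.0) < 0.2
        assert list(truth["direction"]) == ["up", "down"]

    def test_deterministic(self):
        cfg = CountSimConfig(n_genes=20, n_replicates=3, seed=13)
        m1, _ = sd.simulate_counts(cfg)
        m2, _ = sd.simulate_counts(cfg)
        pd.testing.assert_frame_equal(m1, m2)

    def test_invalid_config(self):
        with pytest.raises(ValueError):
            CountSimConfig(dispersion=0.0)
        with pytest.raises(ValueError):
            CountSimConfig(n_genes=10, planted_de=((3, 1.0), (3, 2.0)))
        with pytest.raises(ValueError):
            CountSimConfig(n_genes=10, planted_de=((99, 1.0),))


class TestSimulateGenotypes:
    def test_rf_zero_absolute_linkage(self):
        table, _ = sd.simulate_genotypes(60, {"X1": 0.0}, seed=14)
        assert (table["X1"] == sd.ALLELE_MUTANT).all()

    def test_rf_half_is_unlinked(self):
        table, _ = sd.simulate_genotypes(4000, {"far": 0.5}, seed=15)
        freq = (table["far"] == sd.ALLELE_MUTANT).mean()
        assert abs(freq - 0.5) < 0.03

    def test_rf_recovery(self):
        table, _ = sd.simulate_genotypes(1000, {"m": 0.10}, seed=16)
        est = 100 * (table["m"] == sd.ALLELE_POLYMORPHIC).mean()
        assert abs(est - 10) <= 3

    def test_rf_out_of_range(self):
        with pytest.raises(ValueError):
            sd.simulate_genotypes(10, {"m": 0.6}, seed=0)


class TestSimulateCq:
    def test_noise_free_round_trip(self):
        from silentscan.chip_norm import QpcrMeasurement, percent_input

        truth = {("s", "H3ac", "CYC6"): 10.0, ("s", "H3ac", "YFP"): 2.5}
        table = sd.simulate_cq(truth, n_replicates=2, seed=17, noise_sd=0.0)
        for _, row in table.iterrows():
            m = QpcrMeasurement(row["region"], row["mark"], row["strain"],
                                row["cq_ip"], row["cq_input"])
            assert percent_input(m) == pytest.approx(truth[("s", "H3ac", row["region"])])


class TestSimulateVariants:
    def test_patterns_respected(self):
        from silentscan.variant_triage import GT_ALT, GT_MISSING, GT_REF

        strains = ["p", "m1", "m2"]
        specs = [
            {"gene": "g1", "effect": "missense_variant", "carriers": {"m1"}},
            {"gene": "g2", "effect": "synonymous_variant", "carriers": {"m2"}, "missing": {"p"}},
        ]
        records = sd.simulate_variants(strains, specs, seed=18)
        assert records[0].genotypes == {"p": GT_REF, "m1": GT_ALT, "m2": GT_REF}
        assert records[1].genotypes == {"p": GT_MISSING, "m1": GT_REF, "m2": GT_ALT}
        assert records[0].ref != records[0].alt
        assert records[1].pos > records[0].pos

    def test_unknown_strain(self):
        with pytest.raises(ValueError, match="unknown strains"):
            sd.simulate_variants(["a"], [{"gene": "g", "carriers": {"zzz"}}])


class TestProteinAlignment:
    def test_shape_and_determinism(self):
        names, seqs, splits = sd.simulate_protein_alignment(6, 200, seed=19)
        assert len(names) == 6 and len(seqs) == 6
        assert {len(s) for s in seqs} == {200}
        again = sd.simulate_protein_alignment(6, 200, seed=19)
        assert again == (names, seqs, splits)
        assert all(2 <= len(s) <= 4 for s in splits)

    def test_too_few_taxa(self):
        with pytest.raises(ValueError):
            sd.simulate_protein_alignment(3, 100)
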