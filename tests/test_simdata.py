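"""Synthetic-data generator: genome layout, read generators, library emission."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rdrnascan.ioutils import write_fasta, write_gff3, write_reads_fasta
from rdrnascan.simdata import (
    SimConfig,
    emit_libraries,
    generate_genome,
    simulate_exsirna_reads,
    simulate_rdrna_reads,
)

TINY = dict(
    genome_length=100_000,
    n_contigs=2,
    n_exon_features=8,
    n_transposon_features=2,
    n_rdrna_loci={"rdrp1": 1, "rdrp2": 1, "both": 1},
    n_exsirna_loci={"I": 1, "II": 1, "III": 1, "IV": 0},
    n_background_loci=5,
    library_depth=5_000,
    rng_seed=11,
)


class TestGenerateGenome:
    def test_empty_locus_plan_still_emits_annotation(self):
        cfg = SimConfig(
            **{**TINY, "n_rdrna_loci": {}, "n_exsirna_loci": {}, "n_background_loci": 0}
        )
        ds = generate_genome(cfg)
        assert len(ds.truth) == 0
        assert len(ds.features) == cfg.n_exon_features + cfg.n_transposon_features

    def test_determinism_byte_identical_outputs(self, tmp_path):
        files = []
        for run in (1, 2):
            ds = generate_genome(SimConfig(**TINY))
            fa = tmp_path / f"g{run}.fa"
            gff = tmp_path / f"a{run}.gff3"
            write_fasta(ds.genome, fa)
            write_gff3(ds.features, gff)
            files.append((fa.read_bytes(), gff.read_bytes()))
        assert files[0] == files[1]

    def test_features_disjoint_and_in_bounds(self):
        """Oracle: all-pairs overlap scan over the emitted features."""
        cfg = SimConfig(
            genome_length=50_000,
            n_contigs=1,
            n_exon_features=10,
            n_transposon_features=0,
            n_rdrna_loci={},
            n_exsirna_loci={},
            n_background_loci=0,
            rng_seed=3,
        )
        ds = generate_genome(cfg)
        feats = ds.features
        assert len(feats) == 10
        assert (feats["start"] >= 0).all()
        assert (feats["end"] <= 50_000).all()
        rows = list(feats.itertuples(index=False))
        for i in range(len(rows)):
            for j in range(i + 1, len(rows)):
                a, b = rows[i], rows[j]
                if a.contig != b.contig:
                    continue
                assert min(a.end, b.end) <= max(a.start, b.start), (a, b)

    def test_each_locus_inside_exactly_one_feature_or_intergenic(self):
        ds = generate_genome(SimConfig(**TINY))
        for row in ds.truth.itertuples(index=False):
            hosts = ds.features[
                (ds.features["contig"] == row.contig)
                & (ds.features["start"] <= row.start)
                & (ds.features["end"] >= row.end)
            ]
            if row.class_label == "background":
                assert len(hosts) == 0
            else:
                assert len(hosts) == 1
                assert hosts.iloc[0]["category"] == "exon"

    def test_capacity_error_names_limiting_parameter(self):
        cfg_kwargs = {**TINY, "genome_length": 5_000, "n_contigs": 1}
        with pytest.raises(ValueError, match="genome_length"):
            generate_genome(SimConfig(**cfg_kwargs))

    def test_multiplier_invariants(self):
        ds = generate_genome(SimConfig(**TINY))
        t = ds.truth
        assert (t["mult_WT"] == 1.0).all()
        # dependent genotypes at <= 1/4; unaffected within the [1/2, 2] band
        for row in t.itertuples(index=False):
            if row.class_label.startswith("rdRNA-rdrp1"):
                assert row.mult_rdrp1 <= 0.25
                assert 0.5 <= row.mult_dcl1 <= 2.0
            if row.class_label == "background":
                for g in ("dcl1", "dcl2", "rdrp1", "rdrp2", "r3b2"):
                    assert 0.5 <= getattr(row, f"mult_{g}") <= 2.0


class TestSimulateRdrnaReads:
    def test_full_efficiency_forces_penultimate_u(self):
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list("ACGT"), size=2000))
        reads = simulate_rdrna_reads(seq, 1.0, (18, 24), 1000, seed=1)
        for r in reads.itertuples(index=False):
            assert r.sequence[-2] == "T"
            assert r.strand == "+"

    def test_no_uracil_returns_empty(self):
        reads = simulate_rdrna_reads("ACG" * 100, 1.0, (18, 24), 100, seed=1)
        assert len(reads) == 0

    def test_hand_enumerated_single_fragment(self):
        seq = "TA" + "A" * 18 + "TAA"
        reads = simulate_rdrna_reads(seq, 1.0, (18, 24), 50, seed=2)
        assert len(reads) == 1
        r = reads.iloc[0]
        assert (r["start"], r["end"]) == (2, 22)
        assert r["count"] == 50
        assert r["sequence"] == seq[2:22]
        assert r["sequence"][18] == "T"

    def test_length_spectrum_matches_exhaustive_enumeration(self):
        """Empirical lengths vs the transcript's inter-U distance spectrum."""
        rng = np.random.default_rng(5)
        seq = "".join(rng.choice(list("ACGT"), size=10_000))
        reads = simulate_rdrna_reads(seq, 1.0, (18, 24), 10_000, seed=6)
        emp = {}
        total = reads["count"].sum()
        for r in reads.itertuples(index=False):
            L = r.end - r.start
            emp[L] = emp.get(L, 0) + r.count
        # oracle: exhaustive enumeration of consecutive inter-U distances
        t_idx = [i for i, b in enumerate(seq) if b == "T" and i + 2 <= len(seq)]
        gaps = [b - a for a, b in zip(t_idx, t_idx[1:]) if 18 <= b - a <= 24]
        exact = {}
        for g in gaps:
            exact[g] = exact.get(g, 0) + 1
        n_frag = sum(exact.values())
        tv = 0.5 * sum(
            abs(emp.get(L, 0) / total - exact.get(L, 0) / n_frag)
            for L in range(18, 25)
        )
        assert tv < 0.05


class TestSimulateExsirnaReads:
    def test_sizes_respect_distribution_support(self):
        seq = "".join(np.random.default_rng(1).choice(list("ACGT"), size=500))
        reads = simulate_exsirna_reads(seq, {23: 0.5, 24: 0.5}, 0.5, 0.5, 10_000, seed=2)
        lens = (reads["end"] - reads["start"]).unique()
        assert set(lens) <= {23, 24}

    def test_strand_mix_within_binomial_bounds(self):
        seq = "".join(np.random.default_rng(2).choice(list("ACGT"), size=500))
        reads = simulate_exsirna_reads(seq, {23: 1.0}, 0.5, 0.0, 10_000, seed=3)
        sense = reads.loc[reads["strand"] == "+", "count"].sum()
        assert 0.47 <= sense / reads["count"].sum() <= 0.53

    def test_five_prime_u_forced(self):
        seq = "".join(np.random.default_rng(3).choice(list("ACGT"), size=500))
        reads = simulate_exsirna_reads(seq, {23: 1.0}, 0.5, 1.0, 5_000, seed=4)
        assert all(r.sequence[0] == "T" for r in reads.itertuples(index=False))

    def test_locus_shorter_than_read_errors(self):
        with pytest.raises(ValueError, match="shorter"):
            simulate_exsirna_reads("ACGTACGT", {23: 1.0}, 0.5, 0.5, 10, seed=5)

    def test_reads_stay_inside_locus(self):
        seq = "".join(np.random.default_rng(4).choice(list("ACGT"), size=100))
        reads = simulate_exsirna_reads(seq, {23: 0.5, 24: 0.5}, 0.5, 1.0, 2_000, seed=6)
        assert (reads["start"] >= 0).all()
        assert (reads["end"] <= 100).all()


class TestEmitLibraries:
    def test_multinomial_closure(self, small_libraries):
        libs, _ = small_libraries
        for g, lib in libs.items():
            assert lib["count"].sum() == 50_000, g

    def test_depleted_genotype_counts_within_poisson_bounds(self, small_dataset, small_libraries):
        """Realized depleted counts agree with weight x multiplier expectations."""
        libs, expected_rpm = small_libraries
        depth = small_dataset.config.library_depth
        truth = small_dataset.truth
        for g in ("rdrp1", "r3b2"):
            lib = libs[g]
            for row in truth.itertuples(index=False):
                mult = getattr(row, f"mult_{g}")
                exp = expected_rpm.loc[row.locus_id, g] * depth / 1e6
                if exp < 50:
                    continue
                got = lib[
                    (lib["contig"] == row.contig)
                    & (lib["start"] >= row.start - 30)
                    & (lib["end"] <= row.end + 30)
                ]["count"].sum()
                lo, hi = stats.poisson.ppf([0.0005, 0.9995], exp)
                assert lo <= got <= hi, (row.locus_id, g, exp, got)

    def test_zero_depth_gives_empty_valid_files(self, small_dataset, tmp_path):
        libs, _ = emit_libraries(small_dataset, depth=0)
        for g, lib in libs.items():
            assert lib["count"].sum() == 0
            path = tmp_path / f"{g}.fa"
            write_reads_fasta(
                list(lib.groupby("sequence")["count"].sum().items()), path
            )
            assert path.exists()

    def test_same_seed_identical_libraries(self, small_dataset):
        libs1, _ = emit_libraries(small_dataset, seed=42)
        libs2, _ = emit_libraries(small_dataset, seed=42)
        for g in libs1:
            pd.testing.assert_frame_equal(libs1[g], libs2[g])

    def test_rdrna_reads_sense_only(self):
        # noise-free libraries so every placement traces to a planted locus
        ds = generate_genome(SimConfig(**{**TINY, "uniform_noise_frac": 0.0}))
        libs, _ = emit_libraries(ds)
        lib = libs["WT"]
        for row in ds.truth.itertuples(index=False):
            if not row.class_label.startswith("rdRNA"):
                continue
            sub = lib[
                (lib["contig"] == row.contig)
                & (lib["start"] >= row.start)
                & (lib["end"] <= row.end)
            ]
            assert (sub["strand"] == row.strand).all()
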