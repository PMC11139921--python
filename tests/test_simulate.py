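"""Synthetic-data generators: determinism, ground-truth fidelity, degenerate
inputs."""

import numpy as np
import pytest

import pollenpipe as pp
from pollenpipe import io, simulate


class TestSimulateGenome:
    def test_same_seed_gives_byte_identical_annotation(self, tmp_path):
        paths = []
        for i in range(2):
            g = pp.simulate_genome(seed=7, chrom_length=20_000, n_genes=4, n_tes=8)
            p = tmp_path / f"ann{i}.bed"
            io.write_annotation_bed(g.features, p)
            paths.append(p.read_bytes())
        assert paths[0] == paths[1]

    def test_features_fit_and_do_not_overlap(self, genome):
        by_chrom: dict[str, list] = {}
        for f in genome.features:
            assert 0 <= f.start < f.end <= genome.chrom_lengths[f.chrom]
            by_chrom.setdefault(f.chrom, []).append(f)
        for feats in by_chrom.values():
            feats.sort(key=lambda f: f.start)
            for a, b in zip(feats, feats[1:]):
                assert a.end <= b.start

    def test_cytosine_contexts_and_bounds(self, genome):
        assert set(genome.cytosines["context"]) <= {"CG", "CHG", "CHH"}
        for chrom, sub in genome.cytosines.groupby("chrom"):
            assert sub["pos"].between(0, genome.chrom_lengths[chrom] - 1).all()

    def test_no_tes_leaves_empty_te_universe(self):
        g = pp.simulate_genome(seed=1, n_genes=3, n_tes=0, chrom_length=20_000)
        assert g.features_of_class("TE") == []
        assert g.te_copies_by_family() == {}

    def test_overfull_genome_is_an_error(self):
        with pytest.raises(ValueError, match="cannot fit"):
            pp.simulate_genome(seed=1, n_chrom=1, chrom_length=2_000, n_genes=5, n_tes=5)

    def test_te_family_copies_share_length(self, genome):
        for fam, copies in genome.te_copies_by_family().items():
            assert len({len(c) for c in copies}) == 1


class TestSimulateMethylome:
    def test_null_levels_match_baseline_within_3_se(self, genome):
        # binomial sampling theory: SE of the pooled mean level is
        # sqrt(p (1 - p) / total coverage)
        truth = pp.MethylationTruth(coverage_mean=20.0)
        reps = pp.simulate_methylome(genome, truth, n_replicates=1, seed=3)
        for (cond, _rep), table in reps.items():
            for ctx, sub in table.groupby("context"):
                assert len(sub) >= 1000
                cov = (sub["meth"] + sub["unmeth"]).sum()
                level = sub["meth"].sum() / cov
                p = truth.baseline_level[ctx]
                se = np.sqrt(p * (1 - p) / cov)
                assert abs(level - p) < 3 * se, (cond, ctx)

    def test_zero_coverage_handled_gracefully_downstream(self, genome):
        truth = pp.MethylationTruth(coverage_mean=0.0)
        reps = pp.simulate_methylome(genome, truth, n_replicates=1, seed=3)
        a, b = reps[("test", 1)], reps[("reference", 1)]
        assert (a["meth"] + a["unmeth"]).eq(0).all()
        assert pp.call_dmrs([a], [b]) == []

    def test_planted_delta_recovered_empirically(self, genome, planted_truth):
        reps = pp.simulate_methylome(genome, planted_truth, n_replicates=1, seed=4)
        a, b = reps[("test", 1)], reps[("reference", 1)]
        region = planted_truth.planted_regions[0]
        for df in (a, b):
            df["in_region"] = (
                (df["chrom"] == region.interval.chrom)
                & (df["pos"] >= region.interval.start)
                & (df["pos"] < region.interval.end)
                & (df["context"] == "CHH")
            )
        lev_a = a.loc[a.in_region, "meth"].sum() / (
            a.loc[a.in_region, ["meth", "unmeth"]].sum().sum()
        )
        lev_b = b.loc[b.in_region, "meth"].sum() / (
            b.loc[b.in_region, ["meth", "unmeth"]].sum().sum()
        )
        assert lev_a - lev_b == pytest.approx(-0.3, abs=0.05)

    def test_impossible_level_rejected_at_validation(self, genome):
        te = genome.features_of_class("TE")[0]
        truth = pp.MethylationTruth(
            planted_regions=[pp.PlantedRegion(te, "CHH", delta=-0.3)]  # baseline 0.10
        )
        with pytest.raises(ValueError, match="outside"):
            pp.simulate_methylome(genome, truth, seed=1)

    def test_reports_round_trip_through_io(self, genome, tmp_path):
        truth = pp.MethylationTruth(coverage_mean=5.0)
        reps = pp.simulate_methylome(genome, truth, n_replicates=1, seed=5)
        table = reps[("test", 1)]
        path = tmp_path / "m.cx.tsv"
        io.write_cytosine_report(table, path)
        back = io.read_cytosine_table(path)
        assert back.equals(table[back.columns])


@pytest.fixture()
def expression(genome):
    fams = sorted(genome.te_copies_by_family())
    mean = {"gene:0": 300.0, f"TE:{fams[0]}": 2000.0, f"TE:{fams[1]}": 300.0}
    return pp.ExpressionTruth(mean=mean, group_log2fc={f"TE:{fams[0]}": -5.0})


class TestSimulateSmallRna:

    def test_hit_count_matches_emitted_placements(self, genome, expression):
        reads = pp.simulate_smallrna_reads(genome, expression, seed=6)
        assert reads
        for r in reads:
            assert r.n_hits == len(r.placements)

    def test_contaminant_lengths_planted_then_filtered(self, genome, expression):
        reads = pp.simulate_smallrna_reads(genome, expression, seed=6)
        assert any(r.length < 18 or r.length > 30 for r in reads)
        kept = pp.filter_reads(reads)
        assert all(18 <= r.length <= 30 for r in kept)

    def test_group_log2fc_reflected_in_weighted_totals(self, genome, expression):
        fams = sorted(genome.te_copies_by_family())
        target = f"TE:{fams[0]}"

        def weighted_total(condition):
            reads = pp.filter_reads(
                pp.simulate_smallrna_reads(
                    genome, expression, seed=6, condition=condition, imperfect_rate=0.0
                )
            )
            return sum(r.count for r in reads if target in r.read_id)

        ratio = weighted_total("B") / weighted_total("A")
        assert ratio == pytest.approx(2.0**-5, rel=0.5)

    def test_single_hit_reads_weighted_equals_raw(self, genome):
        expr = pp.ExpressionTruth(mean={"gene:0": 200.0})
        reads = pp.simulate_smallrna_reads(
            genome, expr, seed=7, contaminant_rate=0.0, imperfect_rate=0.0
        )
        assert all(r.n_hits == 1 for r in reads)
        placements = pp.weight_multimappers(reads)
        assert placements["weight"].sum() == sum(r.count for r in reads)

    def test_empty_length_distribution_is_an_error(self, genome):
        expr = pp.ExpressionTruth(mean={"gene:0": 10.0})
        with pytest.raises(ValueError, match="length distribution"):
            pp.simulate_smallrna_reads(genome, expr, seed=1, gene_length_dist={})

    def test_alignment_files_pass_reader_unchanged(self, genome, expression, tmp_path):
        reads = pp.simulate_smallrna_reads(genome, expression, seed=8)
        path = tmp_path / "aln.tsv"
        io.write_alignments_tsv(reads, path)
        back = io.read_alignments(path)
        assert {r.read_id for r in back} == {r.read_id for r in reads}
        assert sum(r.count for r in back) == sum(r.count for r in reads)


class TestSimulateSeedCounts:
    def test_mean_collapse_fraction_within_3_se(self):
        # binomial: SE of the mean over 20 plants x 300 seeds
        p = 0.35
        table = pp.simulate_seed_counts({"jas-3": p}, n_plants=20, seeds_per_plant=300, seed=9)
        frac = table["collapsed"].sum() / (table["collapsed"] + table["normal"]).sum()
        se = np.sqrt(p * (1 - p) / (20 * 300))
        assert abs(frac - p) < 3 * se

    def test_zero_probability_means_zero_collapsed(self):
        table = pp.simulate_seed_counts({"wt": 0.0}, n_plants=5, seed=9)
        assert (table["collapsed"] == 0).all()

    def test_same_seed_identical_table(self):
        t1 = pp.simulate_seed_counts({"a": 0.3, "b": 0.1}, seed=10)
        t2 = pp.simulate_seed_counts({"a": 0.3, "b": 0.1}, seed=10)
        assert t1.equals(t2)

    def test_overdispersion_inflates_between_plant_variance(self):
        tight = pp.simulate_seed_counts({"g": 0.3}, n_plants=200, rho=0.0, seed=11)
        wide = pp.simulate_seed_counts({"g": 0.3}, n_plants=200, rho=0.2, seed=11)
        assert wide["collapsed"].var() > 2 * tight["collapsed"].var()

    def test_invalid_rho_rejected(self):
        with pytest.raises(ValueError, match="rho"):
            pp.simulate_seed_counts({"g": 0.3}, rho=1.5)
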