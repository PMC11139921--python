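"""DMR caller: per-cytosine criteria, bin thresholds, merging, annotation,
and brute-force oracle equivalence."""

import numpy as np
import pandas as pd
import pytest

import pollenpipe as pp
from pollenpipe import dmr as dmr_mod
from pollenpipe.config import DmrConfig
from pollenpipe.core import CytosineRecord, GenomicInterval

from _oracles import brute_force_dmrs


class TestPoolReplicates:
    def test_counts_sum_across_replicates(self, make_cytosine_table):
        r1 = make_cytosine_table([("Chr1", 10, "+", "CHH", 3, 17)])
        r2 = make_cytosine_table([("Chr1", 10, "+", "CHH", 1, 19)])
        pooled = pp.pool_replicates([r1, r2])
        assert pooled.loc[0, ["meth", "unmeth"]].tolist() == [4, 36]

    def test_single_replicate_is_identity(self, make_cytosine_table):
        r1 = make_cytosine_table([("Chr1", 10, "+", "CHH", 3, 17)])
        assert pp.pool_replicates([r1]).equals(r1)

    def test_cytosine_missing_from_one_replicate_kept(self, make_cytosine_table):
        r1 = make_cytosine_table([("Chr1", 10, "+", "CHH", 3, 17)])
        r2 = make_cytosine_table(
            [("Chr1", 10, "+", "CHH", 1, 19), ("Chr1", 55, "-", "CG", 9, 1)]
        )
        pooled = pp.pool_replicates([r1, r2])
        assert len(pooled) == 2
        assert pooled.set_index("pos").loc[55, "meth"] == 9


class TestPerCytosineDiff:
    def rec(self, meth, unmeth, context="CHH"):
        return CytosineRecord("Chr1", 100, "+", context, meth, unmeth)

    def test_chh_difference_at_threshold_is_hypo(self):
        assert pp.per_cytosine_diff(self.rec(1, 19), self.rec(3, 17)) == "hypo"

    def test_cg_difference_below_threshold_not_differential(self):
        # CG needs |diff| >= 0.4; 0.35 is not enough
        a = self.rec(0, 20, "CG")
        b = self.rec(7, 13, "CG")
        assert pp.per_cytosine_diff(a, b) == "not_differential"

    def test_low_coverage_is_insufficient(self):
        assert pp.per_cytosine_diff(self.rec(1, 2), self.rec(10, 10)) == "insufficient"

    def test_hyper_when_test_exceeds_reference(self):
        assert pp.per_cytosine_diff(self.rec(10, 10), self.rec(2, 18)) == "hyper"

    def test_context_mismatch_is_an_error(self):
        with pytest.raises(ValueError):
            pp.per_cytosine_diff(self.rec(1, 19, "CHH"), self.rec(3, 17, "CG"))


def _bin_tables(make_table, n_cyt, context, level_a, level_b, start=0, cov=20):
    """n_cyt cytosines evenly spaced in [start, start+100) with fixed levels."""
    rows_a, rows_b = [], []
    for i in range(n_cyt):
        pos = start + i * (100 // n_cyt)
        rows_a.append(("Chr1", pos, "+", context, round(level_a * cov), cov - round(level_a * cov)))
        rows_b.append(("Chr1", pos, "+", context, round(level_b * cov), cov - round(level_b * cov)))
    return make_table(rows_a), make_table(rows_b)


class TestBinScan:
    def test_six_chh_hypo_cytosines_make_a_candidate(self, make_cytosine_table):
        a, b = _bin_tables(make_cytosine_table, 6, "CHH", 0.1, 0.4)
        bins = pp.bin_scan(a, b)
        assert len(bins) == 1
        assert bins.iloc[0]["direction"] == "hypo"
        assert bins.iloc[0]["n_support"] == 6

    def test_five_chh_cytosines_are_not_enough(self, make_cytosine_table):
        a, b = _bin_tables(make_cytosine_table, 5, "CHH", 0.1, 0.4)
        assert len(pp.bin_scan(a, b)) == 0

    def test_four_cg_hyper_cytosines_make_a_candidate(self, make_cytosine_table):
        a, b = _bin_tables(make_cytosine_table, 4, "CG", 0.9, 0.2)
        bins = pp.bin_scan(a, b)
        assert len(bins) == 1
        assert (bins.iloc[0]["context"], bins.iloc[0]["direction"]) == ("CG", "hyper")


class TestMergeBins:
    def _candidates(self, starts):
        return pd.DataFrame(
            [
                ("Chr1", s, s + 100, "CHH", "hypo", 6, 0.1, 0.4)
                for s in starts
            ],
            columns=dmr_mod.BIN_COLUMNS,
        )

    def test_gap_150_merges(self):
        dmrs = pp.merge_bins(self._candidates([1000, 1250]))
        assert len(dmrs) == 1
        assert (dmrs[0].start, dmrs[0].end) == (1000, 1350)
        assert dmrs[0].n_supporting_cytosines == 12

    def test_gap_300_stays_separate(self):
        dmrs = pp.merge_bins(self._candidates([1000, 1400]))
        assert len(dmrs) == 2

    def test_gap_exactly_200_merges_inclusive(self):
        dmrs = pp.merge_bins(self._candidates([1000, 1300]))
        assert len(dmrs) == 1

    def test_chain_merges_transitively(self):
        dmrs = pp.merge_bins(self._candidates([0, 300, 600, 900]))
        assert len(dmrs) == 1
        assert dmrs[0].source_bins == ((0, 100), (300, 400), (600, 700), (900, 1000))


class TestAnnotateDmrs:
    ann = [
        GenomicInterval("Chr1", 0, 500, feature_class="TE", family="ATGP1", superfamily="LTR/Gypsy"),
        GenomicInterval("Chr1", 400, 900, feature_class="gene"),
    ]

    def _dmr(self, start, end):
        return pp.Dmr("Chr1", start, end, "CHH", "hypo", 6, 0.1, 0.4, ())

    def test_te_label_with_family(self):
        (d,) = pp.annotate_dmrs([self._dmr(100, 200)], self.ann)
        assert (d.feature_class, d.family, d.superfamily) == ("TE", "ATGP1", "LTR/Gypsy")

    def test_te_priority_over_gene(self):
        (d,) = pp.annotate_dmrs([self._dmr(450, 480)], self.ann)
        assert d.feature_class == "TE"

    def test_unannotated_space_is_intergenic(self):
        (d,) = pp.annotate_dmrs([self._dmr(2000, 2100)], self.ann)
        assert d.feature_class == "intergenic"

    def test_gene_only_overlap(self):
        (d,) = pp.annotate_dmrs([self._dmr(600, 700)], self.ann)
        assert d.feature_class == "gene"


def _simulated_pair(seed, planted=True):
    genome = pp.simulate_genome(
        seed=seed, n_chrom=1, chrom_length=20_000, n_genes=2, n_tes=6
    )
    regions = []
    if planted:
        regions = [
            pp.PlantedRegion(te, "CHH", delta=-0.3, ref_level=0.4)
            for te in genome.features_of_class("TE")[:2]
        ]
    truth = pp.MethylationTruth(planted_regions=regions, coverage_mean=15.0)
    reps = pp.simulate_methylome(genome, truth, n_replicates=1, seed=seed + 1000)
    return reps[("test", 1)], reps[("reference", 1)]


class TestProperties:
    def test_matches_brute_force_oracle(self):
        for seed in range(3):
            a, b = _simulated_pair(seed)
            dmrs = pp.call_dmrs([a], [b])
            got = {
                (d.chrom, d.start, d.end, str(d.context), d.direction, d.n_supporting_cytosines)
                for d in dmrs
            }
            assert got == brute_force_dmrs(a, b)

    def test_swapping_conditions_exchanges_directions(self):
        a, b = _simulated_pair(7)
        fwd = pp.call_dmrs([a], [b])
        rev = pp.call_dmrs([b], [a])
        flip = {"hypo": "hyper", "hyper": "hypo"}
        key = lambda ds: sorted(  # noqa: E731
            (d.chrom, d.start, d.end, str(d.context), d.direction) for d in ds
        )
        flipped = sorted(
            (d.chrom, d.start, d.end, str(d.context), flip[d.direction]) for d in rev
        )
        assert key(fwd) == flipped

    @pytest.mark.parametrize("param", ["min_abs_diff", "min_diff_cytosines"])
    def test_raising_thresholds_never_adds_dmrs(self, param):
        a, b = _simulated_pair(9)
        base = len(pp.call_dmrs([a], [b]))
        cfg = DmrConfig()
        if param == "min_abs_diff":
            cfg.min_abs_diff = {k: min(1.0, v * 2) for k, v in cfg.min_abs_diff.items()}
        else:
            cfg.min_diff_cytosines = {k: v + 2 for k, v in cfg.min_diff_cytosines.items()}
        assert len(pp.call_dmrs([a], [b], cfg)) <= base

    def test_fisher_criterion_is_stricter_than_level_only(self):
        a, b = _simulated_pair(6)
        level_only = {(d.chrom, d.start, d.end, d.direction) for d in pp.call_dmrs([a], [b])}
        fisher_cfg = DmrConfig(diff_method="fisher")
        fisher = {
            (d.chrom, d.start, d.end, d.direction)
            for d in pp.call_dmrs([a], [b], fisher_cfg)
        }
        assert len(fisher) <= len(level_only)
        # a well-powered comparison stays differential under either criterion
        rec_a = CytosineRecord("Chr1", 100, "+", "CHH", 0, 30)
        rec_b = CytosineRecord("Chr1", 100, "+", "CHH", 15, 15)
        assert pp.per_cytosine_diff(rec_a, rec_b, fisher_cfg) == "hypo"
        # a marginal level difference at low coverage fails the Fisher gate
        rec_a2 = CytosineRecord("Chr1", 100, "+", "CHH", 0, 5)
        rec_b2 = CytosineRecord("Chr1", 100, "+", "CHH", 1, 4)
        assert pp.per_cytosine_diff(rec_a2, rec_b2, fisher_cfg) == "not_differential"

    def test_stricter_bin_mean_flag_is_a_subset(self):
        a, b = _simulated_pair(5)
        default = {(d.chrom, d.start, d.end) for d in pp.call_dmrs([a], [b])}
        strict_cfg = DmrConfig(require_bin_mean_diff=True)
        strict = {(d.chrom, d.start, d.end) for d in pp.call_dmrs([a], [b], strict_cfg)}
        assert len(strict) <= len(default)
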