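"""Retention scoring, homoeology, analyzer selection and progenitor calls."""

import numpy as np
import pandas as pd
import pytest

from polydart.filters import species_presence, select_species_specific
from polydart.progenitor import (
    EmptyAnalyzerSetError,
    call_progenitors,
    chromosome_profile,
    cross_genome_monomorphism,
    homoeology_table,
    polyploid_specific_markers,
    retention,
    retention_table,
    select_analyzers,
)
from polydart.simulate import (
    PolyploidEvent,
    SimConfig,
    Simulator,
    simulate_panel,
    triticeae_like_config,
)

from conftest import make_markers, make_panel, make_snps


def two_parent_config(seed, loss_rate, gain=400, pool=4000, missing_rate=0.0,
                      chrom_loss=None):
    """Minimal two-diploid + one-tetraploid simulation for retention checks."""
    return SimConfig(
        seed=seed,
        species_tree="(P1:1,P2:1);",
        ancestral_pool_size=pool,
        branch_loss_rate=0.0,
        branch_gain=gain,
        polyploids=(PolyploidEvent("T", ("P1", "P2"), loss_rate=loss_rate,
                                   gain=0, chrom_loss=chrom_loss),),
        missing_rate=missing_rate,
        snp_count=50,
    )


class TestRetention:
    def test_basic_proportion(self):
        assert retention({"m1", "m2", "m3", "m4"}, {"m1", "m2"}) == 0.5

    def test_superset_target_is_one_disjoint_is_zero(self):
        assert retention({"a", "b"}, {"a", "b", "c"}) == 1.0
        assert retention({"a", "b"}, {"x"}) == 0.0

    def test_empty_analyzer_set_is_an_error_not_zero(self):
        with pytest.raises(EmptyAnalyzerSetError):
            retention(set(), {"m1"})

    def test_noiseless_union_retains_each_parent_specific_set_fully(self):
        result = simulate_panel(two_parent_config(seed=7, loss_rate=0.0))
        table = retention_table(result.markers, result.panel, ["P1", "P2"], ["T"])
        assert table.values.loc["P1", "T"] == 1.0
        assert table.values.loc["P2", "T"] == 1.0

    def test_loss_rate_recovered_as_binomial_mean_over_replicates(self):
        """Post-merger loss 0.2 => mean parent-specific retention 0.8 +- 3 s.e."""
        lam, gain, n_rep = 0.2, 400, 100
        values = []
        for seed in range(n_rep):
            result = simulate_panel(two_parent_config(seed, loss_rate=lam,
                                                      gain=gain, pool=500))
            table = retention_table(result.markers, result.panel, ["P1", "P2"], ["T"])
            values.extend(table.values["T"])
        se = np.sqrt(lam * (1 - lam) / gain / len(values))
        assert abs(np.mean(values) - (1 - lam)) < 3 * se

    def test_empty_analyzer_cell_flagged_not_silently_zero(self, three_sample_panel):
        # spA and spB identical => both specific sets empty
        m = make_markers({"m1": [1, 1, 0], "m2": [0, 0, 1]}, ["s1", "s2", "s3"])
        table = retention_table(m, three_sample_panel, ["spA", "spB"], ["spC"])
        assert np.isnan(table.values.loc["spA", "spC"])
        assert ("spA", "spC") in table.undefined_cells


class TestHomoeology:
    @pytest.fixture
    def reference_setup(self):
        panel = make_panel([
            ("d1", "dipA", 2, "A", "diploid_analyzer"),
            ("d2", "dipB", 2, "B", "diploid_analyzer"),
            ("ref", "wheat", 6, "ABD", "reference"),
        ])
        chrom = {"m1": "1A", "m2": "2A", "m3": "1B", "m4": "5B", "m5": "3D",
                 "m6": "6D", "m7": "unassigned"}
        m = make_markers({
            # dipA on A chromosomes, shared m1 with dipB
            "m1": [1, 1, 1], "m2": [1, 0, 1],
            "m3": [0, 1, 1], "m4": [1, 1, 1],
            "m5": [0, 1, 1], "m6": [0, 0, 1],
            "m7": [1, 1, 1],
        }, ["d1", "d2", "ref"], chromosome=chrom)
        return m, panel

    def test_counts_split_and_percentage(self, reference_setup):
        m, panel = reference_setup
        table = homoeology_table(m, panel, ["dipA", "dipB"], "wheat")
        # dipA on A: m1 (shared with dipB), m2 (specific) => 1+1=2; ref A total 2
        assert table.counts.loc["dipA", ("A", "shared")] == 1
        assert table.counts.loc["dipA", ("A", "specific")] == 1
        assert table.counts.loc["dipA", ("A", "total")] == 2
        assert table.percentages.loc["dipA", "A"] == 100.0
        # dipA on B: m4 only, shared; ref B total 2 => 50.0
        assert table.percentages.loc["dipA", "B"] == 50.0
        # dipA absent from D entirely
        assert table.counts.loc["dipA", ("D", "total")] == 0
        assert table.percentages.loc["dipA", "D"] == 0.0

    def test_unassigned_markers_excluded(self, reference_setup):
        m, panel = reference_setup
        table = homoeology_table(m, panel, ["dipA", "dipB"], "wheat")
        total_counted = int(table.counts.loc[:, (slice(None), "total")].to_numpy().sum())
        assert total_counted == 7  # m7 (unassigned, present in both) never counted

    def test_reference_without_subgenome_markers_is_an_error(self):
        panel = make_panel([("d1", "dipA", 2, "A", "diploid_analyzer"),
                            ("ref", "wheat", 6, "ABD", "reference")])
        m = make_markers({"m1": [1, 1]}, ["d1", "ref"], chromosome={"m1": "1A"})
        with pytest.raises(ValueError, match="subgenome"):
            homoeology_table(m, panel, ["dipA"], "wheat")


class TestSelectAnalyzers:
    def test_inclusive_threshold_and_union(self):
        pct = pd.DataFrame({"A": [10.0, 9.9], "B": [5.0, 45.0], "D": [2.0, 1.0]},
                           index=["sp1", "sp2"])
        sel = select_analyzers(pct, 10.0)
        assert sel.per_subgenome["A"] == ["sp1"]
        assert sel.per_subgenome["B"] == ["sp2"]
        assert sel.union == ["sp1", "sp2"]

    def test_threshold_100_requires_full_reference_match(self):
        pct = pd.DataFrame({"A": [100.0, 99.9], "B": [0.0, 0.0], "D": [0.0, 0.0]},
                           index=["full", "near"])
        assert select_analyzers(pct, 100.0).union == ["full"]

    def test_monotone_in_threshold_and_matches_bruteforce(self, rng):
        pct = pd.DataFrame(rng.uniform(0, 50, size=(12, 3)),
                           columns=["A", "B", "D"],
                           index=[f"sp{i}" for i in range(12)])
        previous = None
        for threshold in (5.0, 10.0, 20.0, 40.0):
            sel = select_analyzers(pct, threshold)
            brute = [s for s in pct.index
                     if any(pct.loc[s, g] >= threshold for g in "ABD")]
            assert sel.union == brute
            if previous is not None:
                assert set(sel.union) <= set(previous)
            previous = sel.union


class TestPolyploidSpecific:
    def test_recovers_planted_private_marker_counts(self):
        cfg = triticeae_like_config(seed=11, missing_rate=0.0)
        result = simulate_panel(cfg)
        polys = result.panel.species_with_role("polyploid_target")
        report = polyploid_specific_markers(result.markers, result.panel, polys)
        truth = result.truth
        for species in polys:
            mine = truth.species_markers[species]
            others = set().union(*(truth.species_markers[o] for o in polys
                                   if o != species))
            assert report.loc[species, "specific"] == len(mine - others)

    def test_identical_marker_sets_give_zero_specific(self):
        panel = make_panel([("p1", "polyA", 4, "XY", "polyploid_target"),
                            ("p2", "polyB", 4, "XY", "polyploid_target")])
        m = make_markers({"m1": [1, 1], "m2": [0, 0], "m3": [1, 1]}, ["p1", "p2"])
        report = polyploid_specific_markers(m, panel, ["polyA", "polyB"])
        assert (report["specific"] == 0).all()


class TestChromosomeProfile:
    def _profiled(self, chrom_loss=None, seed=5):
        cfg = two_parent_config(seed, loss_rate=0.15, gain=1400, pool=2000,
                                chrom_loss=chrom_loss)
        result = simulate_panel(cfg)
        specific = select_species_specific(result.markers, result.panel, "P1", ["P2"])
        letter_counts = result.markers.chromosome.reindex(specific.markers)
        letter = letter_counts.str[-1].mode()[0]
        return chromosome_profile(result.markers, result.panel, specific, "T", letter)

    def test_uniform_loss_gives_flat_profile(self):
        prof = self._profiled()
        values = prof.retention.dropna()
        # every bucket estimates the same 1-lambda; spread bounded by binomial noise
        assert values.max() - values.min() < 0.25
        assert ((values - 0.85).abs() < 0.15).all()

    def test_planted_chromosome_segment_loss_is_detected(self):
        prof = self._profiled(chrom_loss={"3A": 0.8, "3B": 0.8, "3D": 0.8})
        others = prof.retention.drop(3).dropna()
        assert prof.retention[3] < others.min() - 0.3

    def test_low_support_buckets_flagged(self, three_sample_panel):
        m = make_markers({"m1": [1, 0, 1], "m2": [1, 0, 0]}, ["s1", "s2", "s3"],
                         chromosome={"m1": "2B", "m2": "5B"})
        specific = select_species_specific(m, three_sample_panel, "spA", ["spB"])
        prof = chromosome_profile(m, three_sample_panel, specific, "spC", "B",
                                  n_min=20)
        assert prof.low_support.all()
        assert prof.retention[2] == 1.0 and prof.retention[5] == 0.0

    def test_no_markers_on_subgenome_is_an_error(self, three_sample_panel):
        m = make_markers({"m1": [1, 0, 0]}, ["s1", "s2", "s3"],
                         chromosome={"m1": "unassigned"})
        specific = select_species_specific(m, three_sample_panel, "spA", ["spB"])
        with pytest.raises(ValueError, match="subgenome"):
            chromosome_profile(m, three_sample_panel, specific, "spC", "A")


class TestCallProgenitors:
    def test_constructed_tie_yields_unresolved_last_slot(self):
        column = pd.Series({"best": 0.9, "tie1": 0.85, "tie2": 0.85,
                            "far1": 0.2, "far2": 0.15})
        call = call_progenitors(column, ploidy=4, margin=0.1)
        assert call.selected == ["best"]
        assert call.unresolved == [["tie1", "tie2"]]

    def test_margin_zero_is_pure_argmax_fill(self, rng):
        for _ in range(20):
            column = pd.Series(rng.uniform(0, 1, 8),
                               index=[f"a{i}" for i in range(8)])
            call = call_progenitors(column, ploidy=6, margin=0.0)
            expected = list(column.sort_values(ascending=False).index[:3])
            assert call.selected == expected
            assert not call.unresolved

    def test_near_tied_parents_filling_all_slots_are_both_selected(self):
        column = pd.Series({"P1": 0.81, "P2": 0.79, "o1": 0.02, "o2": 0.01})
        call = call_progenitors(column, ploidy=4, margin=0.1)
        assert call.selected == ["P1", "P2"]

    def test_parameter_recovery_on_noisy_tetraploids(self):
        """True parents called in >= 95/100 replicates at loss 0.2."""
        hits = 0
        for seed in range(100):
            result = simulate_panel(two_parent_config(seed, loss_rate=0.2,
                                                      gain=400, pool=1500,
                                                      missing_rate=0.01))
            table = retention_table(result.markers, result.panel,
                                    ["P1", "P2"], ["T"])
            call = call_progenitors(table.column("T"), ploidy=4, margin=0.1)
            hits += set(call.selected) == {"P1", "P2"}
        assert hits >= 95

    def test_slot_count_is_half_the_ploidy(self):
        column = pd.Series({"a": 0.9, "b": 0.8, "c": 0.7, "d": 0.1})
        call = call_progenitors(column, ploidy=6, margin=0.0)
        assert len(call.slots) == 3

    def test_fewer_analyzers_than_slots_is_an_error(self):
        with pytest.raises(ValueError, match="slots"):
            call_progenitors(pd.Series({"a": 0.9}), ploidy=4)

    def test_incomplete_retention_column_is_an_error(self):
        column = pd.Series({"a": 0.9, "b": np.nan, "c": 0.5})
        with pytest.raises(ValueError, match="incomplete"):
            call_progenitors(column, ploidy=4)


class TestCrossGenomeMonomorphism:
    def test_identical_samples_are_fully_monomorphic(self):
        m = make_snps({"m1": [0, 0], "m2": [2, 2], "m3": [1, 1]}, ["x", "y"])
        out = cross_genome_monomorphism(m, {"all": ["m1", "m2", "m3"]},
                                        {"pair": ["x", "y"]})
        assert out.loc[("pair", "all"), "monomorphic_pct"] == 100.0

    def test_k_of_n_differences(self):
        rows = {f"m{i}": [0, 0] for i in range(8)}
        rows.update({"d1": [0, 1], "d2": [2, 0]})  # k=2 of n=10
        m = make_snps(rows, ["x", "y"])
        out = cross_genome_monomorphism(m, {"all": list(rows)}, {"pair": ["x", "y"]})
        assert out.loc[("pair", "all"), "monomorphic_pct"] == pytest.approx(80.0)

    def test_markers_with_missing_calls_excluded_from_denominator(self):
        m = make_snps({"m1": [0, 0], "m2": [None, 1], "m3": [1, 2]}, ["x", "y"])
        out = cross_genome_monomorphism(m, {"all": ["m1", "m2", "m3"]},
                                        {"pair": ["x", "y"]})
        row = out.loc[("pair", "all")]
        assert row["n_markers"] == 2
        assert row["monomorphic_pct"] == pytest.approx(50.0)

    def test_collapse_het_merges_alt_and_heterozygote(self):
        m = make_snps({"m1": [1, 2], "m2": [0, 2]}, ["x", "y"])
        raw = cross_genome_monomorphism(m, {"all": ["m1", "m2"]},
                                        {"pair": ["x", "y"]})
        collapsed = cross_genome_monomorphism(m, {"all": ["m1", "m2"]},
                                              {"pair": ["x", "y"]},
                                              collapse_het=True)
        assert raw.loc[("pair", "all"), "monomorphic_pct"] == 0.0
        assert collapsed.loc[("pair", "all"), "monomorphic_pct"] == 50.0

    def test_shared_ancestry_raises_group_monomorphism(self, rng):
        """Samples derived from one common vector stay more monomorphic than
        samples drawn independently, at matched divergence rates."""
        n = 2000
        ancestor = rng.integers(0, 2, n).astype(float)
        def derive(vec):
            out = vec.copy()
            flips = rng.random(n) < 0.05
            out[flips] = 1 - out[flips]
            return out
        trio = {f"h{i}": derive(ancestor) for i in range(3)}
        indep = {f"t{i}": derive(rng.integers(0, 2, n).astype(float))
                 for i in range(3)}
        rows = {f"m{j}": [trio[f"h{i}"][j] for i in range(3)]
                        + [indep[f"t{i}"][j] for i in range(3)]
                for j in range(n)}
        m = make_snps(rows, ["h0", "h1", "h2", "t0", "t1", "t2"])
        out = cross_genome_monomorphism(
            m, {"all": list(rows)},
            {"shared": ["h0", "h1", "h2"], "independent": ["t0", "t1", "t2"]})
        assert (out.loc[("shared", "all"), "monomorphic_pct"]
                > out.loc[("independent", "all"), "monomorphic_pct"] + 20)

    def test_empty_partition_is_an_error(self):
        m = make_snps({"m1": [0, 1]}, ["x", "y"])
        with pytest.raises(ValueError, match="empty"):
            cross_genome_monomorphism(m, {"none": []}, {"pair": ["x", "y"]})
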