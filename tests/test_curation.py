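"""Training-set curation pipeline: filters, ranking, simulation, assembly."""

import numpy as np
import pytest

from pafa.curation import (
    CurationConfig,
    build_training_sets,
    label_recurrent,
    rank_inverse_controls,
    resolve_conflicts,
    select_control_candidates,
    select_csnps,
    simulate_adjacent_variants,
)
from pafa.features import FeatureMatrix, FeatureRegistry
from pafa.popdiff import PopulationFrequencyTable
from pafa.variant_io import AnnotationTrack, GenomicInterval, VariantRecord


def V(pos, chrom="1", ref="A", alt="T", **kw):
    return VariantRecord(chrom=chrom, pos=pos, ref=ref, alt=alt, **kw)


def freq_table(fst_level):
    """A 2-population table with roughly the requested differentiation."""
    if fst_level == "low":
        p = np.array([0.5, 0.5])
    else:
        p = np.array([0.05, 0.95])
    return PopulationFrequencyTable(["P1", "P2"], p, np.array([100.0, 100.0]))


class TestResolveConflicts:
    def test_conflicts_stay_functional(self):
        a, b, c = V(1), V(2), V(3)
        functional, control = resolve_conflicts([a, b], [b, c])
        assert [v.key() for v in functional] == [a.key(), b.key()]
        assert [v.key() for v in control] == [c.key()]

    def test_disjoint_unchanged(self):
        functional, control = resolve_conflicts([V(1)], [V(2)])
        assert len(functional) == 1 and len(control) == 1

    def test_duplicates_collapsed(self):
        functional, control = resolve_conflicts([V(1), V(1)], [V(2), V(2)])
        assert len(functional) == 1 and len(control) == 1


class TestSelectCsnps:
    def make_track(self, *spans):
        t = AnnotationTrack("elem")
        for s, e in spans:
            t.add(GenomicInterval("1", s, e))
        return t

    def test_threshold_and_overlap_jointly_required(self):
        # five cSNPs; the 1e-7 one and one significant one overlap nothing
        track = self.make_track((0, 50), (99, 150))
        vs = [
            V(10, pvalue=1e-9),   # in [0,50)        -> keep
            V(100, pvalue=1e-9),  # in [99,150)      -> keep
            V(120, pvalue=1e-7),  # overlaps but p too big -> drop
            V(130, pvalue=1e-10), # in [99,150)      -> keep
            V(500, pvalue=1e-9),  # no overlap       -> drop
        ]
        kept = select_csnps(vs, [track])
        assert [v.pos for v in kept] == [10, 100, 130]

    def test_no_op_thresholds_keep_all(self):
        track = self.make_track((0, 10_000))
        vs = [V(p, pvalue=0.5) for p in (5, 6, 7)]
        assert select_csnps(vs, [track], alpha=1.0) == vs

    def test_empty_tracks_drop_everything(self):
        assert select_csnps([V(5, pvalue=1e-9)], []) == []

    def test_missing_pvalue_names_record(self):
        with pytest.raises(ValueError, match="1:5"):
            select_csnps([V(5)], [self.make_track((0, 10))])


class TestSelectControlCandidates:
    def test_small_pool_returned_whole(self):
        vs = [V(i) for i in range(1, 11)]
        tables = {v.key(): freq_table("low") for v in vs}
        out = select_control_candidates(vs, tables, exclusions=set(), k=100_000, seed=0)
        assert {v.key() for v in out} == {v.key() for v in vs}

    def test_high_fst_never_selected(self):
        hi, lo = V(1), V(2)
        tables = {hi.key(): freq_table("high"), lo.key(): freq_table("low")}
        out = select_control_candidates([hi, lo], tables, exclusions=set(), seed=0)
        assert [v.key() for v in out] == [lo.key()]

    def test_exclusions_and_missing_tables_skipped(self):
        a, b, c = V(1), V(2), V(3)
        tables = {a.key(): freq_table("low"), b.key(): freq_table("low")}
        out = select_control_candidates([a, b, c], tables, exclusions={a.key()}, seed=0)
        assert [v.key() for v in out] == [b.key()]

    def test_seeded_sampling_deterministic(self):
        vs = [V(i) for i in range(1, 101)]
        tables = {v.key(): freq_table("low") for v in vs}
        s1 = select_control_candidates(vs, tables, exclusions=set(), k=10, seed=4)
        s2 = select_control_candidates(vs, tables, exclusions=set(), k=10, seed=4)
        s3 = select_control_candidates(vs, tables, exclusions=set(), k=10, seed=5)
        assert [v.key() for v in s1] == [v.key() for v in s2]
        assert [v.key() for v in s1] != [v.key() for v in s3]


def planted_matrices(n_pos=50, n_anti=50, n_like=50):
    """cSNPs carry feature 1; anti-pattern candidates carry feature 2;
    cSNP-like candidates carry feature 1 as well."""
    reg = FeatureRegistry()
    f_csnp = reg.get_or_register("csnp_pattern", "annotation")
    f_anti = reg.get_or_register("anti_pattern", "annotation")
    csnp_rows = [{f_csnp: 1.0} for _ in range(n_pos)]
    cand_rows = [{f_anti: 1.0} for _ in range(n_anti)] + [{f_csnp: 1.0} for _ in range(n_like)]
    csnps = [V(1000 + i, chrom="9") for i in range(n_pos)]
    candidates = [V(2000 + i, chrom="9") for i in range(n_anti + n_like)]
    return (
        candidates,
        FeatureMatrix(csnp_rows, reg),
        FeatureMatrix(cand_rows, reg),
    )


class TestRankInverseControls:
    def test_planted_anti_pattern_selected(self):
        candidates, csnp_m, cand_m = planted_matrices()
        res = rank_inverse_controls(candidates, csnp_m, cand_m, m=50, seed=0)
        assert res.shortfall == 0
        selected = {v.key() for v in res.selected}
        assert selected == {v.key() for v in candidates[:50]}  # the anti-pattern half
        assert all(res.decisions[k] < 0 for k in selected)

    def test_shortfall_reported(self):
        # positives dominate the shared pattern, so the 15 cSNP-like
        # candidates score positive; only the 5 anti-pattern ones qualify
        candidates, csnp_m, cand_m = planted_matrices(n_pos=95, n_anti=5, n_like=15)
        res = rank_inverse_controls(candidates, csnp_m, cand_m, m=10, seed=0)
        assert len(res.selected) + res.shortfall == 10
        assert res.shortfall > 0
        assert {v.key() for v in res.selected} <= {v.key() for v in candidates[:5]}

    def test_deterministic_rerun(self):
        candidates, csnp_m, cand_m = planted_matrices()
        r1 = rank_inverse_controls(candidates, csnp_m, cand_m, m=30, seed=2)
        r2 = rank_inverse_controls(candidates, csnp_m, cand_m, m=30, seed=2)
        assert [v.key() for v in r1.selected] == [v.key() for v in r2.selected]

    def test_registry_mismatch_rejected(self):
        candidates, csnp_m, _ = planted_matrices()
        other_reg = FeatureRegistry()
        other_reg.get_or_register("different", "annotation")
        bad = FeatureMatrix([{} for _ in candidates], other_reg)
        with pytest.raises(ValueError, match="registr"):
            rank_inverse_controls(candidates, csnp_m, bad, m=10)


class TestSimulateAdjacent:
    def test_positions_within_window_and_not_anchor(self):
        anchor = V(1000)
        out = simulate_adjacent_variants([anchor], window=50, per_anchor=30, seed=0)
        for v in out:
            assert 950 <= v.pos <= 1050 and v.pos != 1000
            assert v.chrom == anchor.chrom

    def test_dedup_bounds_output(self):
        anchors = [V(100 * i, chrom="2") for i in range(1, 101)]
        out = simulate_adjacent_variants(anchors, window=50, per_anchor=10, seed=1)
        assert len(out) <= 1000
        assert len({v.key() for v in out}) == len(out)

    def test_seeded_rerun_identical(self):
        anchors = [V(500), V(900)]
        a = simulate_adjacent_variants(anchors, per_anchor=5, seed=3)
        b = simulate_adjacent_variants(anchors, per_anchor=5, seed=3)
        assert [v.key() for v in a] == [v.key() for v in b]

    def test_clipped_at_chromosome_start(self):
        out = simulate_adjacent_variants([V(3)], window=50, per_anchor=20, seed=0)
        assert all(v.pos >= 1 for v in out)


class TestLabelRecurrent:
    def test_distinct_donor_counting(self):
        flags = label_recurrent(
            {
                ("1", 10, "A", "T"): ["D1", "D2"],
                ("1", 20, "A", "T"): ["D1", "D1"],
                ("1", 30, "A", "T"): [],
            }
        )
        assert flags[("1", 10, "A", "T")] is True
        assert flags[("1", 20, "A", "T")] is False
        assert flags[("1", 30, "A", "T")] is False


def toy_curation_config(simulate_per_anchor=0, seed=0):
    """Hand-countable fixture: 12 pathogenic, 4 benign with 2 conflicts,
    10 cSNPs of which 6 pass both filters, 40 candidates of which 20 carry
    the anti-cSNP pattern."""
    pathogenic = [V(i, chrom="1") for i in range(1, 13)]
    benign = [V(1, chrom="1"), V(2, chrom="1"), V(101, chrom="1"), V(102, chrom="1")]

    element = AnnotationTrack("elem")
    element.add(GenomicInterval("2", 0, 1000))
    gwas = []
    for i in range(10):
        pos = 10 + i  # 0-based 9+i; first 8 inside [0,1000)... all inside
        # make 2 fail the p filter and 2 fail the overlap filter
        if i < 2:
            gwas.append(V(pos, chrom="2", pvalue=1e-6))
        elif i < 4:
            gwas.append(V(5000 + pos, chrom="2", pvalue=1e-9))
        else:
            gwas.append(V(pos, chrom="2", pvalue=1e-9))
    # 10 cSNPs: 2 fail p, 2 fail overlap -> 6 survivors

    kg = [V(100 + i, chrom="3") for i in range(40)]
    tables = {v.key(): freq_table("low") for v in kg}

    reg = FeatureRegistry()
    f_csnp = reg.get_or_register("csnp_pattern", "annotation")
    f_anti = reg.get_or_register("anti_pattern", "annotation")
    anti_keys = {v.key() for v in kg[:20]}

    def featurize(vs):
        rows = []
        for v in vs:
            if v.chrom == "2":
                rows.append({f_csnp: 1.0})
            elif v.key() in anti_keys:
                rows.append({f_anti: 1.0})
            else:
                rows.append({f_csnp: 1.0})
        return FeatureMatrix(rows, reg)

    return CurationConfig(
        pathogenic=pathogenic,
        benign=benign,
        gwas_variants=gwas,
        element_tracks=[element],
        kg_variants=kg,
        kg_freq_tables=tables,
        featurize=featurize,
        m=20,
        simulate_per_anchor=simulate_per_anchor,
        seed=seed,
    )


class TestBuildTrainingSets:
    def test_hand_counted_fixture(self):
        sets = build_training_sets(toy_curation_config())
        prov = sets.provenance_counts
        assert prov["pathogenic_after_conflicts"] == 12
        assert prov["benign_after_conflicts"] == 2
        assert prov["csnps_selected"] == 6
        assert prov["functional_before_balance"] == 18
        assert prov["control_candidates"] == 40
        assert prov["inverse_controls"] == 20
        assert prov["control_before_balance"] == 22
        assert len(sets.functional) == 18 and len(sets.control) == 18

    def test_disjointness_after_balancing(self):
        sets = build_training_sets(toy_curation_config(simulate_per_anchor=1))
        fk = {v.key() for v in sets.functional}
        ck = {v.key() for v in sets.control}
        assert not fk & ck
        assert all(v.label == "functional" for v in sets.functional)
        assert all(v.label == "control" for v in sets.control)

    def test_provenance_consistent_with_inputs(self):
        sets = build_training_sets(toy_curation_config())
        prov = sets.provenance_counts
        assert prov["input_pathogenic"] == 12
        assert prov["input_benign"] == 4
        assert prov["input_gwas"] == 10
        assert prov["input_kg"] == 40
        # every filter is monotone: survivors never exceed inputs
        assert prov["csnps_selected"] <= prov["input_gwas"]
        assert prov["control_candidates"] <= prov["input_kg"]
        assert prov["inverse_controls"] <= prov["control_candidates"]

    def test_pipeline_deterministic_under_seed(self):
        s1 = build_training_sets(toy_curation_config(simulate_per_anchor=1, seed=9))
        s2 = build_training_sets(toy_curation_config(simulate_per_anchor=1, seed=9))
        assert [v.key() for v in s1.functional] == [v.key() for v in s2.functional]
        assert [v.key() for v in s1.control] == [v.key() for v in s2.control]
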