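import numpy as np
import pytest

from chipregulon.annotation import (
    PeakRecord,
    assign_divergent_targets,
    filter_far_upstream,
    flanking_genes,
    subtract_control,
    summit_per_transcription_unit,
    veto_control_peaks,
)
from chipregulon.genome_io import GeneModel


def _rec(position=100, **kw):
    return PeakRecord(position=position, **kw)


class TestFlankingGenes:
    def test_upstream_of_forward_gene(self):
        genes = [GeneModel("g", 1000, 2000, "+")]
        left, right, dl, dr = flanking_genes(842, genes)
        assert (left, right) == (None, "g")
        assert dr == 158  # promoter distance, position upstream of start

    def test_inside_forward_gene_negative_distance(self):
        genes = [GeneModel("g", 1000, 2000, "+")]
        left, right, dl, dr = flanking_genes(1065, genes)
        assert left == "g" and right is None
        assert dl == -65  # downstream of the start codon, inside the gene

    def test_divergent_pair_two_distances(self):
        # '-' gene heads rightward toward the gap, '+' gene heads leftward
        genes = [GeneModel("a", 100, 500, "-"), GeneModel("b", 1000, 1500, "+")]
        left, right, dl, dr = flanking_genes(703, genes)
        assert (left, right) == ("a", "b")
        assert dl == 203 and dr == 297  # both promoter-proximal

    def test_tail_facing_gene_gets_no_distance(self):
        # '+' left gene presents its 3' end; '-' right gene its 3' end too
        genes = [GeneModel("a", 100, 500, "+"), GeneModel("b", 1000, 1500, "-")]
        left, right, dl, dr = flanking_genes(703, genes)
        assert (left, right) == ("a", "b")
        assert dl is None and dr is None  # convergent pair: no promoters

    def test_upstream_of_reverse_gene(self):
        genes = [GeneModel("g", 100, 500, "-")]
        _, _, dl, _ = flanking_genes(565, genes)
        assert dl == 65

    def test_distance_sign_flips_at_start_codon(self):
        genes = [GeneModel("g", 1000, 2000, "+")]
        before = flanking_genes(999, genes)[3]
        after = flanking_genes(1001, genes)[2]
        assert before == 1 and after == -1

    def test_empty_annotation_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            flanking_genes(10, [])


class TestFarUpstreamFilter:
    def test_promoter_proximal_kept(self):
        kept, removed = filter_far_upstream([_rec(distance_right=158)])
        assert len(kept) == 1 and not removed

    def test_both_far_removed(self):
        kept, removed = filter_far_upstream(
            [_rec(distance_left=447, distance_right=520)])
        assert not kept and len(removed) == 1
        assert removed[0].excluded_reason == "upstream_gt_300"

    def test_one_side_near_kept(self):
        kept, removed = filter_far_upstream(
            [_rec(distance_left=649, distance_right=130)])
        assert len(kept) == 1 and not removed

    def test_intragenic_negative_distance_always_kept(self):
        kept, removed = filter_far_upstream([_rec(distance_left=-65)])
        assert len(kept) == 1

    def test_no_promoter_distance_removed(self):
        kept, removed = filter_far_upstream([_rec()])
        assert not kept and len(removed) == 1

    def test_partition_is_exact(self, rng):
        records = [
            _rec(position=i,
                 distance_left=int(rng.integers(-200, 900)),
                 distance_right=int(rng.integers(-200, 900)))
            for i in range(50)
        ]
        kept, removed = filter_far_upstream(records)
        assert len(kept) + len(removed) == 50
        assert not ({id(r) for r in kept} & {id(r) for r in removed})


class TestControlSubtraction:
    def test_control_significant_excluded(self):
        rec = _rec(p_adj={"C": 1e-5}, significant={"C": True})
        kept, excluded = subtract_control([rec], "C")
        assert not kept and excluded[0].excluded_reason == "control_significant"

    def test_control_insignificant_kept(self):
        rec = _rec(p_adj={"C": 0.3}, significant={"C": False})
        kept, excluded = subtract_control([rec], "C")
        assert len(kept) == 1 and not excluded

    def test_run_aware_veto_removes_shared_peak_tail(self):
        # one physical peak spanning grid positions 100..175 (step 25); the
        # control is significant everywhere except the borderline tail at
        # 175, which belongs to a different unit — the whole run is vetoed
        run = [
            _rec(position=p, significant={"F": True, "C": True})
            for p in (100, 125, 150)
        ]
        tail = _rec(position=175, significant={"F": True, "C": False})
        summits = [run[1], tail]
        kept, excluded = veto_control_peaks(summits, run + [tail], "C", step=25)
        assert kept == []
        assert {r.position for r in excluded} == {125, 175}

    def test_run_aware_veto_keeps_isolated_ip_only_call(self):
        # an IP-only call far from any control signal is not vetoed
        shared = [_rec(position=p, significant={"F": True, "C": True})
                  for p in (100, 125)]
        lone = _rec(position=1000, significant={"F": True, "C": False})
        kept, excluded = veto_control_peaks([lone], shared + [lone], "C",
                                            step=25)
        assert kept == [lone] and not excluded


class TestDivergentAssignment:
    def _divergent(self):
        return _rec(left_gene="a", right_gene="b",
                    distance_left=100, distance_right=120)

    def test_single_responding_gene_assigned(self):
        (rec,) = assign_divergent_targets(
            [self._divergent()],
            {"a": "unchanged", "b": "activated_by_regulator"})
        assert rec.assigned_targets == ["b"] and not rec.ambiguous

    def test_both_unchanged_keeps_both_flagged(self):
        (rec,) = assign_divergent_targets(
            [self._divergent()], {"a": "unchanged", "b": "unchanged"})
        assert rec.assigned_targets == ["a", "b"] and rec.ambiguous

    def test_both_responding_keeps_both_flagged(self):
        (rec,) = assign_divergent_targets(
            [self._divergent()],
            {"a": "repressed_by_regulator", "b": "activated_by_regulator"})
        assert rec.assigned_targets == ["a", "b"] and rec.ambiguous

    def test_missing_gene_treated_as_unchanged_with_warning(self):
        with pytest.warns(UserWarning, match="absent"):
            (rec,) = assign_divergent_targets(
                [self._divergent()], {"b": "activated_by_regulator"})
        assert rec.assigned_targets == ["b"]

    def test_single_candidate_assigned_directly(self):
        (rec,) = assign_divergent_targets(
            [_rec(left_gene="a", right_gene="b", distance_right=50)], {})
        assert rec.assigned_targets == ["b"]


class TestSummitSelection:
    def test_most_significant_kept(self):
        a = _rec(position=100, p_adj={"F": 1e-6}, d={"F": 0.3},
                 assigned_targets=["g"])
        b = _rec(position=200, p_adj={"F": 1e-5}, d={"F": 0.3},
                 assigned_targets=["g"])
        assert summit_per_transcription_unit([a, b]) == [a]

    def test_tie_broken_by_larger_difference(self):
        a = _rec(position=100, p_adj={"F": 1e-6}, d={"F": 0.2},
                 assigned_targets=["g"])
        b = _rec(position=200, p_adj={"F": 1e-6}, d={"F": 0.4},
                 assigned_targets=["g"])
        assert summit_per_transcription_unit([a, b]) == [b]

    def test_full_tie_broken_by_position(self):
        a = _rec(position=200, p_adj={"F": 1e-6}, d={"F": 0.4},
                 assigned_targets=["g"])
        b = _rec(position=100, p_adj={"F": 1e-6}, d={"F": 0.4},
                 assigned_targets=["g"])
        assert summit_per_transcription_unit([a, b]) == [b]

    def test_control_ignored_in_ranking(self):
        a = _rec(position=100, p_adj={"F": 1e-6, "C": 1e-9}, d={"F": 0.3},
                 assigned_targets=["g"])
        b = _rec(position=200, p_adj={"F": 1e-8, "C": 0.9}, d={"F": 0.3},
                 assigned_targets=["g"])
        out = summit_per_transcription_unit([a, b], control_condition="C")
        assert out == [b]

    def test_operon_grouping_collapses_members(self):
        a = _rec(position=100, p_adj={"F": 1e-6}, d={"F": 0.3},
                 assigned_targets=["g1"])
        b = _rec(position=5000, p_adj={"F": 1e-9}, d={"F": 0.3},
                 assigned_targets=["g2"])
        operons = {"g1": "op1", "g2": "op1"}
        assert summit_per_transcription_unit([a, b], operons=operons) == [b]

    def test_output_count_bounded_by_units(self, rng):
        records = [
            _rec(position=int(p),
                 p_adj={"F": float(rng.uniform())}, d={"F": 0.1},
                 assigned_targets=[f"g{int(rng.integers(5))}"])
            for p in rng.choice(100_000, size=40, replace=False)
        ]
        out = summit_per_transcription_unit(records)
        units = {g for r in records for g in r.assigned_targets}
        assert len(out) <= len(units)
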