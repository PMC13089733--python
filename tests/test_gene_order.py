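"""Signed circular gene-order comparison: canonicalization, breakpoint
distance, arrangement grouping and single-event classification."""

import itertools

import numpy as np
import pytest

from mitostruct.architecture import extract_gene_order
from mitostruct.errors import ValidationError
from mitostruct.gene_order import (GeneOrderSignature, adjacency_set,
                                   breakpoint_distance, canonicalize,
                                   classify_events, compare,
                                   group_arrangements, harmonize_name,
                                   linear_diagram, replay_event)


def _flip(x):
    return (x[0], "-" if x[1] == "+" else "+")


def sig(label, order, circular=True):
    return GeneOrderSignature(label, order, circular)


TOY = sig("toy", [("cox1", "+"), ("g2", "+"), ("g3", "-"),
                  ("g4", "+"), ("g5", "-")])


class TestCanonicalize:
    def test_reference_order_anchors_at_cox1(self, reference_record):
        c = canonicalize(extract_gene_order(reference_record))
        assert c.order[:2] == (("cox1", "+"), ("trnR", "+"))

    def test_idempotent(self):
        rotated = sig("r", TOY.order[3:] + TOY.order[:3])
        once = canonicalize(rotated)
        assert canonicalize(once).order == once.order == TOY.order

    def test_minus_anchor_mirrors_the_circle(self):
        # hand-flipped 5-gene construction
        mirrored = sig("m", [_flip(x) for x in reversed(TOY.order)])
        assert canonicalize(mirrored).order == TOY.order

    def test_missing_or_duplicated_anchor_rejected(self):
        with pytest.raises(ValidationError):
            canonicalize(sig("x", [("g2", "+"), ("g3", "+")]))
        with pytest.raises(ValidationError):
            canonicalize(sig("x", [("cox1", "+"), ("cox1", "+")]))

    def test_alternative_anchor_flag(self):
        s = sig("x", [("g2", "+"), ("g3", "+")])
        assert canonicalize(s, anchor="g3").order[0] == ("g3", "+")


class TestBreakpointDistance:
    def test_identical_orders(self):
        assert breakpoint_distance(TOY, sig("b", TOY.order)) == 0

    def test_reversed_circle_is_the_same_arrangement(self):
        rev = sig("rev", [_flip(x) for x in reversed(TOY.order)])
        assert breakpoint_distance(TOY, rev) == 0

    def test_toy_swap_against_exhaustive_adjacency_oracle(self):
        a = sig("a", [(g, "+") for g in ["cox1", "g2", "g3", "g4", "g5"]])
        b = sig("b", [(g, "+") for g in ["cox1", "g3", "g2", "g4", "g5"]])
        got = breakpoint_distance(a, b)

        # oracle: enumerate signed circular adjacencies by hand, where an
        # adjacency x->y equals its reverse complement flip(y)->flip(x)
        def adj(order):
            pairs = set()
            for x, y in zip(order, order[1:] + order[:1]):
                pairs.add(min((x, y), (_flip(y), _flip(x))))
            return pairs
        oa = adj([(g, "+") for g in ["cox1", "g2", "g3", "g4", "g5"]])
        ob = adj([(g, "+") for g in ["cox1", "g3", "g2", "g4", "g5"]])
        assert got == len(oa - ob) == 3

    def test_disjoint_gene_sets_rejected(self):
        with pytest.raises(ValidationError):
            breakpoint_distance(TOY, sig("z", [("x1", "+"), ("x2", "+")]))

    def test_content_mismatch_restricts_to_shared_with_warning(self):
        extra = sig("e", TOY.order + (("novel", "+"),))
        with pytest.warns(UserWarning, match="shared genes"):
            assert breakpoint_distance(TOY, extra) == 0

    def test_metric_axioms_exhaustive_five_genes(self):
        genes = ["g2", "g3", "g4", "g5"]
        sets = []
        for perm in itertools.permutations(genes):
            for signs in itertools.product("+-", repeat=4):
                s = sig("x", [("cox1", "+")] + list(zip(perm, signs)))
                sets.append(adjacency_set(s))
        n = len(sets)
        D = np.zeros((n, n), dtype=np.int16)
        for i in range(n):
            for j in range(i + 1, n):
                d = len(sets[i] - sets[j])
                assert len(sets[j] - sets[i]) == d       # symmetry
                D[i, j] = D[j, i] = d
        assert (np.diag(D) == 0).all()                   # identity
        for m in range(n):                               # triangle
            assert not (D > D[:, m, None] + D[None, m, :]).any()


class TestGrouping:
    def test_identical_orders_one_class(self, reference_record):
        a = extract_gene_order(reference_record)
        b = GeneOrderSignature("copy", a.order)
        assert len(group_arrangements([a, b])) == 1

    def test_moved_trnm_makes_second_class(self, reference_record):
        a = extract_gene_order(reference_record)
        order = [x for x in a.order if x[0] != "trnM"]
        order.insert(3, ("trnM", "+"))
        b = GeneOrderSignature("moved", order)
        assert len(group_arrangements([a, b])) == 2


class TestEvents:
    def test_identical_orders_no_events(self):
        assert classify_events(TOY, sig("b", TOY.order)) == []

    def test_trnm_translocation_detected_and_sound(self, reference_record):
        a = extract_gene_order(reference_record)
        order = [x for x in a.order if x[0] != "trnM"]
        order.insert(3, ("trnM", "+"))
        b = GeneOrderSignature("moved", order)
        events = classify_events(a, b)
        assert [e.kind for e in events] == ["single_gene_translocation"]
        assert events[0].genes == ("trnM",)
        replayed = replay_event(a, events[0])
        assert canonicalize(replayed).order == canonicalize(b).order

    def test_all_but_anchor_inversion_detected_and_sound(self):
        inverted = sig("inv", (TOY.order[0],)
                       + tuple(_flip(x) for x in reversed(TOY.order[1:])))
        events = classify_events(TOY, inverted)
        assert events[0].kind == "inversion"
        assert events[0].genes == ("g2", "g3", "g4", "g5")
        replayed = replay_event(TOY, events[0])
        assert canonicalize(replayed).order == canonicalize(inverted).order

    def test_block_shift_detected_and_sound(self):
        base = sig("a", [(g, "+") for g in
                         ["cox1", "g2", "g3", "g4", "g5", "g6", "g7"]])
        shifted = sig("b", [(g, "+") for g in
                            ["cox1", "g4", "g5", "g2", "g3", "g6", "g7"]])
        events = classify_events(base, shifted)
        assert events[0].kind == "multi_gene_shift"
        replayed = replay_event(base, events[0])
        assert canonicalize(replayed).order == canonicalize(shifted).order

    def test_composite_history_reports_unclassified(self):
        scrambled = sig("s", [("cox1", "+"), ("g4", "-"), ("g2", "+"),
                              ("g5", "+"), ("g3", "-")])
        events = classify_events(TOY, scrambled)
        assert events[0].kind == "unclassified"
        assert events[0].detail["breakpoints"] > 0

    def test_unequal_content_rejected(self):
        with pytest.raises(ValidationError):
            classify_events(TOY, sig("b", TOY.order[:-1]))

    @pytest.mark.parametrize("seed", range(8))
    def test_soundness_on_random_single_events(self, seed):
        """Apply a random planned event; whatever event the classifier
        emits must replay a into b."""
        rng = np.random.default_rng(seed)
        genes = [f"g{i}" for i in range(2, 12)]
        order = [("cox1", "+")] + [
            (g, "+-"[rng.integers(2)]) for g in genes]
        a = sig("a", order)
        kind = ["transloc", "invert", "shift"][seed % 3]
        b_order = list(order)
        if kind == "transloc":
            i = int(rng.integers(1, len(b_order)))
            item = b_order.pop(i)
            j = int(rng.integers(1, len(b_order) + 1))
            b_order.insert(j, item)
        elif kind == "invert":
            i = int(rng.integers(1, len(b_order) - 1))
            j = int(rng.integers(i, len(b_order)))
            b_order[i:j + 1] = [_flip(x) for x in reversed(b_order[i:j + 1])]
        else:
            i = int(rng.integers(1, len(b_order) - 2))
            j = int(rng.integers(i + 1, len(b_order)))
            block = b_order[i:j + 1]
            del b_order[i:j + 1]
            k = int(rng.integers(1, len(b_order) + 1))
            b_order[k:k] = block
        b = sig("b", b_order)
        events = classify_events(a, b)
        if events and events[0].kind != "unclassified":
            replayed = replay_event(a, events[0])
            assert canonicalize(replayed).order == canonicalize(b).order


class TestReportAndNames:
    def test_compare_report_fields(self, reference_record):
        a = extract_gene_order(reference_record)
        b = GeneOrderSignature("copy", a.order)
        rep = compare(a, b)
        assert rep.breakpoints == 0 and rep.events == []
        assert rep.shared_adjacencies == len(a.order)

    def test_name_harmonization(self):
        assert harmonize_name("trnL(uag)") == "trnL1"
        assert harmonize_name("trnS(GCU)") == "trnS1"
        assert harmonize_name("cox1") == "cox1"

    def test_linear_diagram_marks_minus_strand(self):
        text = linear_diagram(TOY)
        assert text.startswith("cox1 g2 (g3) g4 (g5)")
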