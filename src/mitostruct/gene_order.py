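"""Comparison of mitochondrial gene orders across species.

A gene order is modelled as a signed circular sequence of (gene,
orientation) pairs.  Orders are canonicalized by rotating cox1 — the one
gene whose position is conserved across holothurian mitogenomes — to the
front, mirroring the whole circle if cox1 lies on the minus strand, so a
circular order and its reverse-complement reading are one arrangement.

Dissimilarity is the breakpoint distance: the number of signed adjacencies
of one order absent from the other (an adjacency and its reverse
complement are identified).  On equal gene content this count is symmetric
and satisfies the triangle inequality.  A single-event heuristic labels
pairs as a single-gene translocation, a segment inversion, or a
multi-gene (block) shift; anything needing more than one event is
reported unclassified rather than guessed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

from .errors import ValidationError

Oriented = tuple[str, str]              # (gene name, '+' | '-')
Adjacency = tuple[Oriented, Oriented]

#: cross-database tRNA naming harmonization (MITOS-style labels -> the
#: controlled vocabulary used here); editable by callers.
NAME_HARMONIZATION: dict[str, str] = {
    "trnl(uag)": "trnL1", "trnl(uaa)": "trnL2",
    "trns(uga)": "trnS2", "trns(gcu)": "trnS1",
    "trnl(tag)": "trnL1", "trnl(taa)": "trnL2",
    "trns(tga)": "trnS2", "trns(gct)": "trnS1",
    "16s": "rrnL", "12s": "rrnS", "rrn16": "rrnL", "rrn12": "rrnS",
}


def harmonize_name(name: str) -> str:
    return NAME_HARMONIZATION.get(name.lower(), name)


def _flip(item: Oriented) -> Oriented:
    return (item[0], "-" if item[1] == "+" else "+")


@dataclass(frozen=True)
class GeneOrderSignature:
    label: str
    order: tuple[Oriented, ...]
    circular: bool = True

    def __init__(self, label: str, order, circular: bool = True):
        object.__setattr__(self, "label", label)
        object.__setattr__(self, "order",
                           tuple((harmonize_name(g), s) for g, s in order))
        object.__setattr__(self, "circular", circular)

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(g for g, _ in self.order)


def canonicalize(sig: GeneOrderSignature,
                 anchor: str = "cox1") -> GeneOrderSignature:
    """Rotate the anchor gene to the front, reading the circle in the
    direction that puts the anchor on '+'.  Idempotent."""
    positions = [i for i, (g, _) in enumerate(sig.order) if g == anchor]
    if len(positions) != 1:
        raise ValidationError(
            f"{sig.label}: anchor {anchor!r} occurs {len(positions)} times; "
            "pass a different anchor gene"
        )
    i = positions[0]
    order = list(sig.order)
    if order[i][1] == "-":
        order = [_flip(x) for x in reversed(order)]
        i = len(order) - 1 - i
    if sig.circular:
        order = order[i:] + order[:i]
    elif i != 0:
        warnings.warn(
            f"{sig.label}: linear order cannot be rotated; anchor left at "
            f"position {i}", stacklevel=2,
        )
    return replace(sig, order=tuple(order))


def _canonical_adjacency(a: Oriented, b: Oriented) -> Adjacency:
    forward = (a, b)
    reverse = (_flip(b), _flip(a))
    return min(forward, reverse)


def adjacency_set(sig: GeneOrderSignature) -> frozenset[Adjacency]:
    """Signed adjacencies (wrap included when circular), identified with
    their reverse complements."""
    order = sig.order
    pairs = list(zip(order, order[1:]))
    if sig.circular and len(order) > 1:
        pairs.append((order[-1], order[0]))
    return frozenset(_canonical_adjacency(a, b) for a, b in pairs)


def _restrict(sig: GeneOrderSignature,
              genes: frozenset[str]) -> GeneOrderSignature:
    return replace(sig, order=tuple(x for x in sig.order if x[0] in genes))


def breakpoint_distance(a: GeneOrderSignature, b: GeneOrderSignature,
                        anchor: str = "cox1") -> int:
    """Number of adjacencies of ``a`` absent from ``b``.

    With unequal gene content both orders are first restricted to the
    shared genes (with a warning); disjoint sets are an error.
    """
    shared = a.genes & b.genes
    if not shared:
        raise ValidationError("gene orders share no genes")
    if shared != a.genes or shared != b.genes:
        warnings.warn(
            f"gene content differs; comparing the {len(shared)} shared genes",
            stacklevel=2,
        )
        a, b = _restrict(a, shared), _restrict(b, shared)
    a, b = canonicalize(a, anchor), canonicalize(b, anchor)
    return len(adjacency_set(a) - adjacency_set(b))


def group_arrangements(sigs: list[GeneOrderSignature],
                       anchor: str = "cox1") -> list[list[GeneOrderSignature]]:
    """Equivalence classes under identical canonical signed order."""
    classes: dict[tuple, list[GeneOrderSignature]] = {}
    for sig in sigs:
        key = canonicalize(sig, anchor).order
        classes.setdefault(key, []).append(sig)
    return list(classes.values())


# ---------------------------------------------------------------------------
# single-event classification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RearrangementEvent:
    kind: str                       # single_gene_translocation | inversion |
                                    # multi_gene_shift | unclassified
    genes: tuple[str, ...]
    detail: dict | None = None


@dataclass
class RearrangementReport:
    pair: tuple[str, str]
    shared_adjacencies: int
    breakpoints: int
    events: list[RearrangementEvent]


def _find_translocation(a: list[Oriented], b: list[Oriented]
                        ) -> RearrangementEvent | None:
    genes_a = [g for g, _ in a]
    for idx, (gene, _) in enumerate(a):
        rest_a = a[:idx] + a[idx + 1:]
        pos_b = [i for i, (g, _) in enumerate(b) if g == gene]
        if len(pos_b) != 1:
            continue
        j = pos_b[0]
        rest_b = b[:j] + b[j + 1:]
        if rest_a == rest_b and a != b:
            return RearrangementEvent(
                kind="single_gene_translocation", genes=(gene,),
                detail={"to_index": j, "orientation": b[j][1]},
            )
    return None


def _find_inversion(a: list[Oriented], b: list[Oriented]
                    ) -> RearrangementEvent | None:
    if len(a) != len(b):
        return None
    diffs = [i for i, (x, y) in enumerate(zip(a, b)) if x != y]
    if not diffs:
        return None
    i, j = diffs[0], diffs[-1]
    segment = [_flip(x) for x in reversed(a[i:j + 1])]
    if a[:i] + segment + a[j + 1:] == b:
        return RearrangementEvent(
            kind="inversion", genes=tuple(g for g, _ in a[i:j + 1]),
            detail={"from_index": i, "to_index": j},
        )
    return None


def _find_block_shift(a: list[Oriented], b: list[Oriented]
                      ) -> RearrangementEvent | None:
    n = len(a)
    if n != len(b):
        return None
    for i in range(n):
        for j in range(i, n):
            block = a[i:j + 1]
            rest = a[:i] + a[j + 1:]
            for k in range(len(rest) + 1):
                if k == i:
                    continue
                if rest[:k] + block + rest[k:] == b:
                    return RearrangementEvent(
                        kind="multi_gene_shift",
                        genes=tuple(g for g, _ in block),
                        detail={"from_index": i, "to_index": k},
                    )
    return None


def classify_events(a: GeneOrderSignature, b: GeneOrderSignature,
                    anchor: str = "cox1") -> list[RearrangementEvent]:
    """Single-event heuristic, tried in order: translocation, inversion,
    block shift; otherwise one ``unclassified`` event carrying the
    breakpoint count.  Identical canonical orders yield an empty list."""
    if a.genes != b.genes:
        raise ValidationError("event classification requires equal gene content")
    ca = list(canonicalize(a, anchor).order)
    cb = list(canonicalize(b, anchor).order)
    if ca == cb:
        return []
    for finder in (_find_translocation, _find_inversion, _find_block_shift):
        event = finder(ca, cb)
        if event is not None:
            return [event]
    return [RearrangementEvent(
        kind="unclassified", genes=(),
        detail={"breakpoints": breakpoint_distance(a, b, anchor)},
    )]


def replay_event(a: GeneOrderSignature, event: RearrangementEvent,
                 anchor: str = "cox1") -> GeneOrderSignature:
    """Apply a classified event to ``a``; used to verify soundness
    (replaying the event must reproduce the other order)."""
    order = list(canonicalize(a, anchor).order)
    if event.kind == "single_gene_translocation":
        (gene,) = event.genes
        idx = next(i for i, (g, _) in enumerate(order) if g == gene)
        del order[idx]
        order.insert(event.detail["to_index"],
                     (gene, event.detail["orientation"]))
    elif event.kind == "inversion":
        i, j = event.detail["from_index"], event.detail["to_index"]
        order[i:j + 1] = [_flip(x) for x in reversed(order[i:j + 1])]
    elif event.kind == "multi_gene_shift":
        i, k = event.detail["from_index"], event.detail["to_index"]
        size = len(event.genes)
        block = order[i:i + size]
        del order[i:i + size]
        order[k:k] = block
    else:
        raise ValidationError(f"cannot replay event kind {event.kind!r}")
    return replace(a, order=tuple(order))


def compare(a: GeneOrderSignature, b: GeneOrderSignature,
            anchor: str = "cox1") -> RearrangementReport:
    """Pairwise report: shared adjacencies, breakpoints, classified events."""
    shared_genes = a.genes & b.genes
    ra, rb = _restrict(a, shared_genes), _restrict(b, shared_genes)
    ra, rb = canonicalize(ra, anchor), canonicalize(rb, anchor)
    sa, sb = adjacency_set(ra), adjacency_set(rb)
    events = classify_events(ra, rb, anchor)
    return RearrangementReport(
        pair=(a.label, b.label),
        shared_adjacencies=len(sa & sb),
        breakpoints=len(sa - sb),
        events=events,
    )


def linear_diagram(sig: GeneOrderSignature, anchor: str = "cox1") -> str:
    """Plain-text one-line diagram of a canonical order; minus-strand genes
    are parenthesized."""
    order = canonicalize(sig, anchor).order
    return " ".join(g if s == "+" else f"({g})" for g, s in order)
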