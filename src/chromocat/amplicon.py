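"""Double-minute reconstruction from a breakpoint graph over amplified
fragments.

Each amplified CN segment becomes a graph node with two ports (its left and
right genomic ends).  A rearrangement joins two ports when each breakend
falls within +/- 30 kb of a fragment end whose side is consistent with the
breakend orientation: a ``head`` breakend (retained sequence on the lower-
coordinate side) attaches to a fragment's right end, a ``tail`` breakend to
a fragment's left end.  A candidate double minute is a simple cycle that
traverses every visited fragment through opposite ports; cycle search is
exhaustive up to a fragment-count cap, which is exact at the scale such
amplicons occur (a handful of fragments).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from .model import HEAD, TAIL, SVCall

log = logging.getLogger(__name__)

LEFT = "left"
RIGHT = "right"


@dataclass(frozen=True)
class AmpliconFragment:
    """One amplified genomic fragment (a graph node)."""

    node_id: int
    chrom: str
    start: int
    end: int
    total_cn: int

    @property
    def length(self):
        return self.end - self.start


@dataclass(frozen=True)
class GraphEdge:
    edge_id: int
    sv: SVCall
    port1: Tuple[int, str]  # (node_id, side)
    port2: Tuple[int, str]


@dataclass
class BreakpointGraph:
    fragments: List[AmpliconFragment] = field(default_factory=list)
    edges: List[GraphEdge] = field(default_factory=list)
    n_unmatched_svs: int = 0

    def adjacency(self) -> Dict[Tuple[int, str], List[GraphEdge]]:
        adj: Dict[Tuple[int, str], List[GraphEdge]] = {}
        for e in self.edges:
            adj.setdefault(e.port1, []).append(e)
            adj.setdefault(e.port2, []).append(e)
        return adj


@dataclass
class AmpliconCycle:
    """A closed, oriented chain of amplified fragments — a candidate DM.

    ``orientations[i]`` is '+' when fragment i is traversed left-to-right.
    """

    fragments: List[AmpliconFragment]
    orientations: List[str]
    svs: List[SVCall]
    total_length_bp: int = 0
    mean_cn: float = 0.0
    chromosomes: Tuple[str, ...] = ()

    def __post_init__(self):
        self.total_length_bp = sum(f.length for f in self.fragments)
        total = sum(f.length * f.total_cn for f in self.fragments)
        self.mean_cn = total / self.total_length_bp if self.total_length_bp else 0.0
        self.chromosomes = tuple(sorted({f.chrom for f in self.fragments}))


def _other_side(side):
    return RIGHT if side == LEFT else LEFT


def _match_port(bnd, fragments, window):
    """Fragment port for one breakend, or None.

    head -> right end (pos ~ fragment.end), tail -> left end (pos ~ start);
    nearest matching fragment wins.
    """
    best = None
    for frag in fragments:
        if frag.chrom != bnd.chrom:
            continue
        anchor = frag.end if bnd.orient == HEAD else frag.start
        d = abs(bnd.pos - anchor)
        if d <= window and (best is None or d < best[0]):
            best = (d, (frag.node_id, RIGHT if bnd.orient == HEAD else LEFT))
    return best[1] if best else None


def build_breakpoint_graph(amplified_segments: Sequence, svs: Sequence[SVCall],
                           window: int = 30_000) -> BreakpointGraph:
    """Graph over amplified fragments; SVs whose breakends both match a
    fragment port become edges, the rest are ignored (counted)."""
    fragments = [
        AmpliconFragment(i, seg.chrom, seg.start, seg.end, seg.total_cn)
        for i, seg in enumerate(amplified_segments)
    ]
    graph = BreakpointGraph(fragments=fragments)
    for sv in svs:
        p1 = _match_port(sv.bnd1, fragments, window)
        p2 = _match_port(sv.bnd2, fragments, window)
        if p1 is None or p2 is None:
            graph.n_unmatched_svs += 1
            continue
        graph.edges.append(GraphEdge(len(graph.edges), sv, p1, p2))
    if graph.n_unmatched_svs:
        log.info("breakpoint graph: %d SV(s) matched no fragment end", graph.n_unmatched_svs)
    return graph


def _edge_other_port(edge, port):
    return edge.port2 if edge.port1 == port else edge.port1


def find_circular_amplicons(graph: BreakpointGraph,
                            max_cycle_fragments: int = 12) -> List[AmpliconCycle]:
    """All simple port-consistent cycles, each reported once.

    Every fragment in a cycle is entered at one port and exited at the
    other; consecutive fragments are linked by one SV edge.  A cycle is
    identified by its edge set (which fixes the cyclic order), so rotations
    and reflections collapse to one report.  Results are sorted by total
    length descending.
    """
    adj = graph.adjacency()
    frag_by_id = {f.node_id: f for f in graph.fragments}
    found: Dict[frozenset, List[GraphEdge]] = {}

    def close_or_extend(target_port, current, entry_side, used, visited):
        exit_port = (current, _other_side(entry_side))
        for edge in adj.get(exit_port, []):
            if edge.edge_id in used:
                continue
            nxt, nxt_side = _edge_other_port(edge, exit_port)
            if (nxt, nxt_side) == exit_port:
                continue  # degenerate self-edge on one port
            if (nxt, nxt_side) == target_port:
                key = frozenset(used | {edge.edge_id})
                found.setdefault(key, [graph.edges[i] for i in sorted(used | {edge.edge_id})])
            elif nxt not in visited and len(visited) < max_cycle_fragments:
                close_or_extend(target_port, nxt, nxt_side,
                                used | {edge.edge_id}, visited | {nxt})

    for e0 in graph.edges:
        (fa, sa), (fb, sb) = e0.port1, e0.port2
        if fa == fb:
            # single-fragment cycle: the edge must join the two ports
            if sa != sb:
                found.setdefault(frozenset({e0.edge_id}), [e0])
            continue
        # the cycle must re-enter the start fragment at its unused port
        close_or_extend((fa, _other_side(sa)), fb, sb, {e0.edge_id}, {fa, fb})

    cycles = [_assemble_cycle(edges, frag_by_id) for edges in found.values()]
    cycles.sort(key=lambda c: (-c.total_length_bp, [f.node_id for f in c.fragments]))
    return cycles


def _assemble_cycle(edges: List[GraphEdge], frag_by_id) -> AmpliconCycle:
    """Order a validated edge set into a canonical fragment walk
    (start at the smallest fragment id, direction toward the smaller
    neighbouring fragment id)."""
    by_port: Dict[Tuple[int, str], GraphEdge] = {}
    for e in edges:
        by_port[e.port1] = e
        by_port[e.port2] = e
    frag_ids = sorted({p[0] for e in edges for p in (e.port1, e.port2)})
    start = frag_ids[0]

    def walk(first_exit_side):
        order, orients, used_edges = [], [], []
        current, entry = start, _other_side(first_exit_side)
        while True:
            order.append(frag_by_id[current])
            orients.append("+" if entry == LEFT else "-")
            exit_port = (current, _other_side(entry))
            edge = by_port[exit_port]
            used_edges.append(edge)
            nxt, nxt_side = _edge_other_port(edge, exit_port)
            if nxt == start:
                return order, orients, used_edges
            current, entry = nxt, nxt_side

    if len(frag_ids) == 1:
        order, orients, used = walk(RIGHT)
    else:
        a = walk(RIGHT)
        b = walk(LEFT)
        # choose the direction whose second fragment id is smaller
        order, orients, used = a if a[0][1].node_id <= b[0][1].node_id else b
    return AmpliconCycle(fragments=order, orientations=orients,
                         svs=[e.sv for e in used])


def score_amplicon(cycle: AmpliconCycle) -> dict:
    """Summary statistics of a reconstructed cycle."""
    return {
        "n_fragments": len(cycle.fragments),
        "total_length_bp": cycle.total_length_bp,
        "mean_cn": cycle.mean_cn,
        "min_cn": min(f.total_cn for f in cycle.fragments),
        "n_chromosomes": len(cycle.chromosomes),
        "chromosomes": list(cycle.chromosomes),
    }
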