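"""Signed TP53-miRNA-target network and p53 response-element scanning.

The network is a set of typed nodes (TF / miRNA / gene) with signed edges:
+1 for transcriptional activation, -1 for repression. Expression direction
is propagated breadth-first from clamped nodes: a child's direction is the
parent's direction multiplied by the edge sign (a repressed activator sends
"down" through +1 edges and "up" through -1 edges). Feedback (the
AKT1/MDM2 loop that keeps miR-125b down when TP53 is lost) is expressed as
an override annotation, not a dynamical fixed point.

The p53 response element is a tandem pair of RRRCWWGYYY decamers (R =
purine, W = A/T, Y = pyrimidine) separated by a 0-13 nt spacer. Coordinates
are 0-based half-open in the API; BED output follows the same convention.
"""
from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from importlib import resources

import pandas as pd

from .errors import ConflictError, FormatError, LookupError_, ParameterError

UP = "up"
DOWN = "down"
UNCHANGED = "unchanged"
UNKNOWN = "unknown"

NODE_KINDS = {"TF", "miRNA", "gene"}

_SIGN_TOKENS = {
    "+1": 1, "1": 1, "+": 1, "activation": 1,
    "-1": -1, "-": -1, "repression": -1,
}

_IUPAC = {
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "W": frozenset("AT"),
    "C": frozenset("C"),
    "G": frozenset("G"),
}
P53_DECAMER = "RRRCWWGYYY"
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass(frozen=True)
class Edge:
    source: str
    target: str
    sign: int
    context: str = ""


@dataclass
class SignedNetwork:
    """Nodes with kinds and signed regulation edges."""

    nodes: dict[str, str] = field(default_factory=dict)  # id -> kind
    edges: list[Edge] = field(default_factory=list)

    def add_node(self, node_id: str, kind: str) -> None:
        if kind not in NODE_KINDS:
            raise ParameterError(f"node kind must be one of {sorted(NODE_KINDS)}, got {kind!r}")
        existing = self.nodes.get(node_id)
        if existing is not None and existing != kind:
            raise ParameterError(f"node {node_id!r} declared with conflicting kinds")
        self.nodes[node_id] = kind

    def add_edge(self, source: str, target: str, sign: int, context: str = "") -> None:
        if source == target:
            raise ParameterError(f"self-loop on {source!r} not allowed")
        if sign not in (1, -1):
            raise ParameterError(f"sign must be +1 or -1, got {sign!r}")
        for endpoint in (source, target):
            if endpoint not in self.nodes:
                raise ParameterError(f"edge endpoint {endpoint!r} not declared as a node")
        if any(e.source == source and e.target == target for e in self.edges):
            raise ParameterError(f"duplicate edge {source!r} -> {target!r}")
        self.edges.append(Edge(source, target, sign, context))

    def out_edges(self, source: str) -> list[Edge]:
        if source not in self.nodes:
            raise LookupError_(f"unknown node {source!r}")
        return [e for e in self.edges if e.source == source]

    def __len__(self) -> int:
        return len(self.edges)


@dataclass
class NodeState:
    """Per-node expression direction after propagation."""

    directions: dict[str, str]
    override_reasons: dict[str, str] = field(default_factory=dict)

    def __getitem__(self, node: str) -> str:
        return self.directions[node]


@dataclass(frozen=True)
class MotifHit:
    """One tandem decamer pair; starts are 0-based."""

    seq_id: str
    first_start: int
    second_start: int
    spacer: int
    matched: str  # the two decamers, '+'-joined
    strand: str = "+"


def load_edges(path) -> SignedNetwork:
    """Read a TSV edge list (source, source_kind, target, target_kind, sign[, context])."""
    net = SignedNetwork()
    with open(path) as fh:
        header = fh.readline()
        if header and not header.startswith("source\t"):
            raise FormatError(f"{path}:1: expected header starting with 'source'")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 5:
                raise FormatError(f"{path}:{lineno}: expected >= 5 columns, got {len(parts)}")
            source, source_kind, target, target_kind, sign_token = parts[:5]
            context = parts[5] if len(parts) > 5 else ""
            if sign_token not in _SIGN_TOKENS:
                raise FormatError(f"{path}:{lineno}: unknown sign token {sign_token!r}")
            try:
                net.add_node(source, source_kind)
                net.add_node(target, target_kind)
                net.add_edge(source, target, _SIGN_TOKENS[sign_token], context)
            except ParameterError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return net


def bundled_network(name: str = "tp53_normal") -> SignedNetwork:
    """Load one of the packaged curated networks (tp53_normal, tp53_feedback)."""
    ref = resources.files("tp53mir.data").joinpath(f"{name}.tsv")
    with resources.as_file(ref) as path:
        return load_edges(path)


def count_edges_by_sign(net: SignedNetwork, source: str) -> tuple[int, int]:
    """(n_activation, n_repression) over the out-edges of ``source``."""
    edges = net.out_edges(source)
    return (sum(e.sign == 1 for e in edges), sum(e.sign == -1 for e in edges))


def _combine(direction: str, sign: int) -> str:
    if direction == UNCHANGED:
        return UNCHANGED
    if direction == UP:
        return UP if sign == 1 else DOWN
    if direction == DOWN:
        return DOWN if sign == 1 else UP
    return UNKNOWN


def propagate(
    net: SignedNetwork,
    clamped: dict[str, str],
    overrides: list[tuple[str, str, str]] | None = None,
) -> NodeState:
    """Breadth-first signed propagation from clamped nodes.

    ``clamped`` maps node -> direction; ``overrides`` force (node, direction,
    reason) regardless of incoming signals (they propagate downstream like
    clamps). In-edges of clamped/overridden nodes are ignored, so feedback
    cycles through them are broken. A node receiving contradictory
    un-overridden signals raises :class:`ConflictError` listing both paths.
    """
    overrides = overrides or []
    for node in list(clamped) + [o[0] for o in overrides]:
        if node not in net.nodes:
            raise LookupError_(f"unknown node {node!r}")
    for direction in list(clamped.values()) + [o[1] for o in overrides]:
        if direction not in (UP, DOWN, UNCHANGED):
            raise ParameterError(f"direction must be up/down/unchanged, got {direction!r}")

    fixed: dict[str, str] = dict(clamped)
    reasons: dict[str, str] = {}
    for node, direction, reason in overrides:
        fixed[node] = direction
        reasons[node] = reason

    directions: dict[str, str] = {n: UNKNOWN for n in net.nodes}
    directions.update(fixed)
    paths: dict[str, str] = {n: n for n in fixed}  # representative path text

    # cycle check on the graph with fixed nodes' in-edges removed
    active = [e for e in net.edges if e.target not in fixed]
    indeg = {n: 0 for n in net.nodes}
    for e in active:
        indeg[e.target] += 1
    queue_t = deque(n for n, d in indeg.items() if d == 0)
    seen = 0
    indeg_work = dict(indeg)
    while queue_t:
        n = queue_t.popleft()
        seen += 1
        for e in active:
            if e.source == n:
                indeg_work[e.target] -= 1
                if indeg_work[e.target] == 0:
                    queue_t.append(e.target)
    if seen != len(net.nodes):
        raise ParameterError(
            "network is cyclic after removing clamped/overridden nodes' in-edges; "
            "clamp or override a node on each feedback loop"
        )

    queue = deque(fixed)
    while queue:
        node = queue.popleft()
        for e in net.out_edges(node):
            if e.target in fixed:
                continue
            implied = _combine(directions[node], e.sign)
            if implied == UNKNOWN:
                continue
            path = f"{paths.get(node, node)} -{'+' if e.sign == 1 else '-'}-> {e.target}"
            current = directions[e.target]
            if current == UNKNOWN:
                directions[e.target] = implied
                paths[e.target] = path
                queue.append(e.target)
            elif current != implied:
                raise ConflictError(
                    f"node {e.target!r} receives {current!r} via [{paths[e.target]}] "
                    f"but {implied!r} via [{path}]"
                )
    return NodeState(directions=directions, override_reasons=reasons)


def _match_decamer(seq: str, start: int) -> bool:
    if start + 10 > len(seq):
        return False
    return all(seq[start + i] in _IUPAC[c] for i, c in enumerate(P53_DECAMER))


def _validate_sequence(seq: str) -> str:
    seq = seq.upper()
    for offset, ch in enumerate(seq):
        if ch not in "ACGTN":
            raise FormatError(f"non-nucleotide character {ch!r} at offset {offset}")
    return seq


def _scan_forward(seq: str, seq_id: str, max_spacer: int, strand: str) -> list[MotifHit]:
    starts = [i for i in range(len(seq) - 9) if _match_decamer(seq, i)]
    hits = []
    start_set = set(starts)
    for i in starts:
        for spacer in range(max_spacer + 1):
            j = i + 10 + spacer
            if j + 10 > len(seq):
                break
            if j in start_set:
                hits.append(
                    MotifHit(
                        seq_id=seq_id,
                        first_start=i,
                        second_start=j,
                        spacer=spacer,
                        matched=f"{seq[i:i + 10]}+{seq[j:j + 10]}",
                        strand=strand,
                    )
                )
    return hits


def scan_p53_re(
    seq: str,
    max_spacer: int = 13,
    seq_id: str = "seq",
    both_strands: bool = False,
) -> list[MotifHit]:
    """All tandem RRRCWWGYYY decamer pairs with spacer in [0, max_spacer].

    Overlapping pairings (one decamer shared by two pairs) are all reported.
    N never matches. With ``both_strands`` the reverse complement is also
    scanned and hits mapped back to forward-strand coordinates (start of the
    leftmost decamer in original coordinates), flagged strand "-".
    """
    if max_spacer < 0:
        raise ParameterError("max_spacer: must be >= 0")
    seq = _validate_sequence(seq)
    hits = _scan_forward(seq, seq_id, max_spacer, "+")
    if both_strands:
        rc = seq.translate(_COMPLEMENT)[::-1]
        n = len(seq)
        for h in _scan_forward(rc, seq_id, max_spacer, "-"):
            # leftmost decamer in original coords comes from the rc second decamer
            first = n - (h.second_start + 10)
            second = n - (h.first_start + 10)
            hits.append(
                MotifHit(
                    seq_id=seq_id,
                    first_start=first,
                    second_start=second,
                    spacer=h.spacer,
                    matched=h.matched,
                    strand="-",
                )
            )
    return sorted(hits, key=lambda h: (h.first_start, h.second_start, h.strand))


def hits_to_frame(hits: list[MotifHit]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "seq_id": h.seq_id,
                "first_start": h.first_start,
                "second_start": h.second_start,
                "spacer": h.spacer,
                "matched": h.matched,
                "strand": h.strand,
            }
            for h in hits
        ],
        columns=["seq_id", "first_start", "second_start", "spacer", "matched", "strand"],
    )


def hits_to_bed(hits: list[MotifHit]) -> pd.DataFrame:
    """BED6: full tandem element span, name = spacer length."""
    return pd.DataFrame(
        [
            {
                "chrom": h.seq_id,
                "start": h.first_start,
                "end": h.second_start + 10,
                "name": str(h.spacer),
                "score": 0,
                "strand": h.strand,
            }
            for h in hits
        ],
        columns=["chrom", "start", "end", "name", "score", "strand"],
    )
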