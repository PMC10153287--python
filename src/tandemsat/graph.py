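"""Greedy reconstruction of repeat units from the bidirected de Bruijn graph.

The graph is never built explicitly: a thresholded :class:`~tandemsat.kmers.
KmerTable` implies it. Nodes are canonical k-mers visited in one of two
orientations; two oriented k-mers are adjacent when they overlap by k-1 bases
in their traversal orientation.

A satellite array ``BBBB...`` with near-identical monomers yields a cycle of
highly abundant k-mers. Reconstruction starts from the most abundant k-mer
and, at every bifurcation, greedily follows the highest-count successor until
the walk closes on its start (a repeat unit) or fails (deadend or revisit).
Failed walks are discarded but their k-mers are still marked used, so each
k-mer neighbourhood is traversed at most once and reported units never share
k-mers.

Determinism: count ties at bifurcations break by extension base in the fixed
order A < C < G < T; start k-mers are taken in descending count order with
lexicographic tie-break; the reported unit sequence is normalised to the
lexicographically smallest rotation over both strands. Identical inputs
therefore give byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, Iterator, List, Optional, Set, Tuple

from .kmers import KmerTable, canonical, revcomp

WALK_CYCLE = "cycle"
WALK_DEADEND = "deadend"
WALK_REVISIT = "revisit"

_BASES = "ACGT"


@dataclass(frozen=True)
class OrientedKmer:
    """A canonical k-mer plus the orientation it is traversed in."""

    canon: str
    flipped: bool

    @property
    def seq(self) -> str:
        """The k-mer as spelled in traversal orientation."""
        return revcomp(self.canon) if self.flipped else self.canon


@dataclass
class Walk:
    """One greedy traversal; ``steps`` starts with the start node."""

    start: OrientedKmer
    steps: List[OrientedKmer]
    outcome: str  # cycle | deadend | revisit


@dataclass
class RepeatUnit:
    """A circular consensus repeat unit spelled by one greedy cycle.

    ``seq`` is one base per cycle node, normalised to the canonical
    rotation/strand; every circular k-window of it canonicalises into the
    source table. min/max/mean summarise the cycle's k-mer counts.
    """

    id: str
    seq: str
    k: int
    min_count: int
    max_count: int
    mean_count: float

    def __len__(self) -> int:
        return len(self.seq)


def successors(node: OrientedKmer, table: KmerTable) -> List[Tuple[str, OrientedKmer, int]]:
    """The <= 4 graph successors of *node* present in *table*.

    Each candidate is the (k-1)-suffix of the oriented k-mer extended by one
    base, canonicalised; returned as ``(base, oriented_kmer, count)`` in
    A < C < G < T order.
    """
    suffix = node.seq[1:]
    out: List[Tuple[str, OrientedKmer, int]] = []
    for b in _BASES:
        cand = suffix + b
        canon, flipped = canonical(cand)
        cnt = table.counts.get(canon)
        if cnt is not None:
            out.append((b, OrientedKmer(canon, flipped), cnt))
    return out


def greedy_walk(
    start: OrientedKmer,
    table: KmerTable,
    globally_visited: Iterable[str] = (),
) -> Walk:
    """Greedy highest-count traversal from *start*.

    At each step the successor of maximal count is chosen (ties by extension
    base, A first). The walk ends with outcome:

    - ``cycle``   — the chosen successor is the start node in the same
      orientation (a repeat unit);
    - ``deadend`` — no successor exists in the table;
    - ``revisit`` — the chosen successor was already used: seen earlier in
      this walk, consumed by a previous walk, or the start in the flipped
      orientation (a palindromic pseudo-cycle). Such walks are discarded.
    """
    if not isinstance(globally_visited, (set, frozenset)):
        globally_visited = set(globally_visited)
    cur = start
    steps = [start]
    in_walk: Set[str] = {start.canon}
    for _ in range(len(table) + 1):
        succ = successors(cur, table)
        if not succ:
            return Walk(start, steps, WALK_DEADEND)
        best = succ[0]
        for cand in succ[1:]:
            if cand[2] > best[2]:
                best = cand
        nxt = best[1]
        if nxt == start:
            return Walk(start, steps, WALK_CYCLE)
        if nxt.canon in in_walk or nxt.canon in globally_visited:
            return Walk(start, steps, WALK_REVISIT)
        steps.append(nxt)
        in_walk.add(nxt.canon)
        cur = nxt
    # unreachable unless the table mutates mid-walk; treat as failed
    return Walk(start, steps, WALK_REVISIT)


def canonical_form(seq: str) -> str:
    """Lexicographically smallest rotation of *seq* or of its reverse
    complement — the stable representative of a circular, strand-free unit."""
    def best_rotation(s: str) -> str:
        n = len(s)
        d = s + s
        return min(d[i : i + n] for i in range(n))

    return min(best_rotation(seq), best_rotation(revcomp(seq)))


def walk_to_unit(walk: Walk, table: KmerTable, unit_id: str = "unit") -> RepeatUnit:
    """Spell the repeat unit of a closed walk (one base per cycle node)."""
    if walk.outcome != WALK_CYCLE:
        raise ValueError(f"cannot build a unit from a {walk.outcome!r} walk")
    seq = "".join(step.seq[-1] for step in walk.steps)
    counts = [table.counts[step.canon] for step in walk.steps]
    return RepeatUnit(
        id=unit_id,
        seq=canonical_form(seq),
        k=table.k,
        min_count=min(counts),
        max_count=max(counts),
        mean_count=sum(counts) / len(counts),
    )


def unit_kmers(unit: RepeatUnit) -> Set[str]:
    """Canonical k-mers of the unit read circularly (for validation)."""
    k = unit.k
    d = unit.seq + unit.seq
    return {canonical(d[i : i + k])[0] for i in range(len(unit.seq))}


def find_repeat_units(
    table: KmerTable,
    *,
    stop_count: Optional[int] = None,
    min_unit_len: int = 1,
) -> List[RepeatUnit]:
    """Reconstruct all repeat units of a thresholded table.

    Repeatedly: take the highest-count k-mer not yet used, walk greedily, and
    emit a unit when the walk closes. All k-mers touched by a walk — closed
    or failed — are marked used. Stops when every k-mer is used or the best
    remaining count falls below *stop_count* (default: no extra stop beyond
    the table's own threshold). Units are numbered in discovery order.
    """
    order = sorted(table.counts.items(), key=lambda kv: (-kv[1], kv[0]))
    visited: Set[str] = set()
    units: List[RepeatUnit] = []
    floor = stop_count if stop_count is not None else 1
    for kmer, cnt in order:
        if cnt < floor:
            break
        if kmer in visited:
            continue
        walk = greedy_walk(OrientedKmer(kmer, False), table, visited)
        visited.update(step.canon for step in walk.steps)
        if walk.outcome == WALK_CYCLE and len(walk.steps) >= min_unit_len:
            unit = walk_to_unit(walk, table, unit_id=f"unit-{len(units) + 1:04d}")
            units.append(unit)
    return units


# ---------------------------------------------------------------------------
# Unit FASTA I/O


def write_units_fasta(units: Iterable[RepeatUnit], path: str) -> None:
    with open(path, "wt") as fh:
        for u in units:
            fh.write(
                f">{u.id} k={u.k} len={len(u.seq)} "
                f"min={u.min_count} max={u.max_count} mean={u.mean_count:.2f}\n"
            )
            for i in range(0, len(u.seq), 80):
                fh.write(u.seq[i : i + 80] + "\n")


def read_units_fasta(path: str) -> List[RepeatUnit]:
    """Read units written by :func:`write_units_fasta`.

    Header attributes are optional so plain FASTA of repeat motifs (e.g. from
    another tool) can be annotated too; missing stats default to 0.
    """
    units: List[RepeatUnit] = []
    name = None
    attrs: Dict[str, str] = {}
    chunks: List[str] = []

    def flush() -> None:
        if name is None:
            return
        seq = "".join(chunks).upper()
        units.append(
            RepeatUnit(
                id=name,
                seq=seq,
                k=int(attrs.get("k", 0)),
                min_count=int(attrs.get("min", 0)),
                max_count=int(attrs.get("max", 0)),
                mean_count=float(attrs.get("mean", 0.0)),
            )
        )

    with open(path, "rt") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                flush()
                parts = line[1:].split()
                name = parts[0] if parts else "unit"
                attrs = dict(p.split("=", 1) for p in parts[1:] if "=" in p)
                chunks = []
            elif line:
                chunks.append(line.strip())
        flush()
    return units
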