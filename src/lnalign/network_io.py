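"""Readers and writers for the file formats the pipeline touches.

Two network dialects are supported:

``edgelist``
    Tab-separated ``idA<TAB>idB[<TAB>confidence]``. Lines starting with ``#``
    are comments. Optional ``!node<TAB>id[<TAB>color]`` lines declare colored
    or isolated nodes explicitly.

``string_tsv``
    A STRING-style export with columns ``protein1``, ``protein2``,
    ``combined_score`` (header tolerated). Scores may be integers on the
    0-999 scale or reals in [0, 1]; the scale is auto-detected and
    normalized to [0, 1] (any score > 1 is divided by 1000).

Seed pairs arrive as ``idA<TAB>idB[<TAB>similarity]`` with a default
similarity of 1.0. Protein identifiers are opaque, case-sensitive strings;
no identifier mapping is attempted — the seed file is the only bridge
between the two species' namespaces.
"""

from __future__ import annotations

import json
import hashlib
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx

logger = logging.getLogger(__name__)

#: color assigned when an input carries no node-color information
DEFAULT_COLOR = "c0"


class ParseError(ValueError):
    """A line of an input file violated its column contract."""

    def __init__(self, path, lineno: int, message: str):
        super().__init__(f"{path}:{lineno}: {message}")
        self.path = str(path)
        self.lineno = lineno


@dataclass
class PPINetwork:
    """Undirected protein-protein interaction network.

    Wraps a :class:`networkx.Graph` whose nodes carry a ``color`` attribute
    and whose edges carry a ``confidence`` attribute in [0, 1].
    """

    name: str
    graph: nx.Graph = field(default_factory=nx.Graph)

    @property
    def nodes(self):
        return self.graph.nodes

    @property
    def edges(self):
        return self.graph.edges

    def color(self, node: str) -> str:
        return self.graph.nodes[node].get("color", DEFAULT_COLOR)

    def add_node(self, node: str, color: str = DEFAULT_COLOR) -> None:
        self.graph.add_node(node, color=color)

    def add_edge(self, u: str, v: str, confidence: float = 1.0) -> None:
        if u == v:
            raise ValueError(f"self-loop on {u!r} not allowed")
        for n in (u, v):
            if n not in self.graph:
                self.graph.add_node(n, color=DEFAULT_COLOR)
        self.graph.add_edge(u, v, confidence=confidence)

    def number_of_nodes(self) -> int:
        return self.graph.number_of_nodes()

    def number_of_edges(self) -> int:
        return self.graph.number_of_edges()

    def validate(self) -> None:
        loops = list(nx.selfloop_edges(self.graph))
        if loops:
            raise ValueError(f"network {self.name!r} contains self-loops: {loops[:3]}")


@dataclass
class SeedPairMap:
    """Scored cross-species protein pairs seeding the alignment graph.

    ``pairs`` preserves file order; duplicates are removed on construction
    and a duplicate with a conflicting similarity raises.
    """

    pairs: list[tuple[str, str, float]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        return iter(self.pairs)

    def as_dict(self) -> dict[tuple[str, str], float]:
        return {(a, b): s for a, b, s in self.pairs}


def _split_line(raw: str) -> list[str]:
    # tolerate space-separated files, but TSV is the documented contract
    return raw.rstrip("\n").split("\t") if "\t" in raw else raw.split()


def _parse_confidence(token: str, path, lineno: int) -> float:
    try:
        return float(token)
    except ValueError:
        raise ParseError(path, lineno, f"confidence {token!r} is not a number") from None


def read_network(
    path,
    fmt: str = "edgelist",
    min_confidence: float = 0.0,
    name: str | None = None,
) -> PPINetwork:
    """Read a PPI network, keeping only edges with confidence >= *min_confidence*.

    Plain edge lists without a score column treat every edge as confidence
    1.0. Self-loops are dropped with a warning. Isolated nodes survive the
    confidence filter only when declared with ``!node`` lines.

    Raises :class:`ParseError` naming the offending line on malformed input
    and :class:`ValueError` if no edge survives the filter.
    """
    path = Path(path)
    if fmt not in ("edgelist", "string_tsv"):
        raise ValueError(f"unknown network format {fmt!r}")
    if not 0.0 <= min_confidence <= 1.0:
        raise ValueError("min_confidence must be in [0, 1]")
    net = PPINetwork(name=name or path.stem)

    rows: list[tuple[str, str, float]] = []
    declared: list[tuple[str, str]] = []
    with open(path) as fh:
        lines = fh.readlines()
    max_score = 0.0
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = _split_line(line)
        if fields[0] == "!node":
            if fmt != "edgelist":
                raise ParseError(path, lineno, "!node lines only allowed in edgelist format")
            if len(fields) < 2:
                raise ParseError(path, lineno, "!node line needs an identifier")
            declared.append((fields[1], fields[2] if len(fields) > 2 else DEFAULT_COLOR))
            continue
        if fmt == "string_tsv" and lineno == 1 and not _is_score(fields[-1]):
            continue  # header
        if len(fields) < 2:
            raise ParseError(path, lineno, f"expected at least 2 columns, got {len(fields)}")
        a, b = fields[0], fields[1]
        conf = 1.0
        if len(fields) >= 3 and fields[2] != "":
            conf = _parse_confidence(fields[2], path, lineno)
        if a == b:
            warnings.warn(f"{path}:{lineno}: self-loop {a!r} dropped", stacklevel=2)
            continue
        max_score = max(max_score, conf)
        rows.append((a, b, conf))

    # STRING exports score on 0-999; normalize once the full range is known
    if max_score > 1.0:
        rows = [(a, b, c / 1000.0) for a, b, c in rows]

    for node, color in declared:
        net.add_node(node, color)
    kept = 0
    for a, b, conf in rows:
        if conf >= min_confidence:
            net.add_edge(a, b, confidence=conf)
            kept += 1
    if kept == 0:
        raise ValueError(f"{path}: no edges survive filter (min_confidence={min_confidence})")
    logger.info(
        "read %s: %d nodes, %d edges (of %d parsed) at min_confidence=%g",
        path, net.number_of_nodes(), kept, len(rows), min_confidence,
    )
    return net


def _is_score(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


def write_network(net: PPINetwork, path) -> None:
    """Write a network in edgelist format, declaring every node's color."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# network {net.name}\n")
        for node in sorted(net.graph.nodes):
            fh.write(f"!node\t{node}\t{net.color(node)}\n")
        for u, v, data in sorted(net.graph.edges(data=True)):
            fh.write(f"{u}\t{v}\t{data.get('confidence', 1.0):.17g}\n")


def read_seed_pairs(path) -> SeedPairMap:
    """Read a seed-pair TSV; missing similarity column defaults to 1.0.

    Exact duplicate rows are removed (first occurrence kept); a duplicate
    (A, B) pair with a conflicting similarity raises.
    """
    path = Path(path)
    seen: dict[tuple[str, str], float] = {}
    pairs: list[tuple[str, str, float]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = _split_line(line)
            if len(fields) < 2:
                raise ParseError(path, lineno, f"expected >=2 columns, got {len(fields)}")
            a, b = fields[0], fields[1]
            sim = 1.0
            if len(fields) >= 3 and fields[2] != "":
                try:
                    sim = float(fields[2])
                except ValueError:
                    raise ParseError(path, lineno, f"similarity {fields[2]!r} is not a number") from None
            if not sim == sim or sim == float("inf"):
                raise ParseError(path, lineno, f"similarity {sim} not finite")
            key = (a, b)
            if key in seen:
                if seen[key] != sim:
                    raise ParseError(
                        path, lineno,
                        f"duplicate pair ({a}, {b}) with conflicting similarity {sim} != {seen[key]}",
                    )
                continue
            seen[key] = sim
            pairs.append((a, b, sim))
    return SeedPairMap(pairs=pairs)


def write_seed_pairs(seeds: SeedPairMap, path) -> None:
    with open(path, "w") as fh:
        for a, b, s in seeds:
            fh.write(f"{a}\t{b}\t{s:.17g}\n")


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_module_report(modules: Sequence, scores, path, provenance: dict | None = None) -> None:
    """Write a TSV of modules plus a JSON sidecar with provenance.

    One row per module: index, size, per-species member lists, and one
    column per similarity measure present in *scores* (a mapping
    ``(module_index, measure) -> float`` or None). Missing scores leave the
    cell empty.
    """
    if not modules:
        raise ValueError("modules must be non-empty")
    path = Path(path)
    measures: list[str] = []
    if scores:
        measures = sorted({m for (_, m) in scores})
    with open(path, "w") as fh:
        header = ["module", "size", "species1_members", "species2_members"] + measures
        fh.write("\t".join(header) + "\n")
        for mod in modules:
            row = [
                str(mod.index),
                str(mod.size),
                ",".join(mod.project(1)),
                ",".join(mod.project(2)),
            ]
            for meas in measures:
                val = scores.get((mod.index, meas)) if scores else None
                row.append("" if val is None else f"{val:.6g}")
            fh.write("\t".join(row) + "\n")
    sidecar = path.with_suffix(path.suffix + ".json")
    with open(sidecar, "w") as fh:
        json.dump(provenance or {}, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")


def read_module_report(path) -> list[dict]:
    """Re-read a module report TSV into a list of dicts (round-trip check)."""
    out = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for raw in fh:
            fields = raw.rstrip("\n").split("\t")
            rec = dict(zip(header, fields))
            rec["module"] = int(rec["module"])
            rec["size"] = int(rec["size"])
            rec["species1_members"] = rec["species1_members"].split(",") if rec["species1_members"] else []
            rec["species2_members"] = rec["species2_members"].split(",") if rec["species2_members"] else []
            out.append(rec)
    return out
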