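"""Graph, gene-set and drug-profile containers plus readers/writers.

Gene identifiers are opaque, case-sensitive strings throughout: no
symbol-to-ID normalization is attempted, so inputs must already share a
namespace.

Edge-list dialect: whitespace- or tab-separated columns ``source target
[sign]``, ``#`` comments, blank lines ignored.  The optional third column
accepts ``+1, -1, 1, activate, inhibit`` (and the unicode minus ``−1``);
a missing sign column means every edge is activating.  Duplicate edges are
an error rather than silently merged, to surface data problems early.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx

_POSITIVE_TOKENS = {"+1", "1", "+", "activate", "activation", "pos"}
_NEGATIVE_TOKENS = {"-1", "−1", "-", "inhibit", "inhibition", "neg"}

UNKNOWN_SIGN = 0  #: sentinel for drug targets whose direction is unstated


class GraphParseError(ValueError):
    """Malformed edge-list or GMT content; carries the offending line number."""


@dataclass
class SignedDiGraph:
    """Directed graph whose edges carry activation (+1) / inhibition (-1) signs.

    Backed by a :class:`networkx.DiGraph` with a ``sign`` attribute per edge;
    the stand-in for a human signaling network.
    """

    graph: nx.DiGraph = field(default_factory=nx.DiGraph)

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str, int]],
        nodes: Iterable[str] = (),
        allow_self_loops: bool = False,
    ) -> "SignedDiGraph":
        g = nx.DiGraph()
        g.add_nodes_from(nodes)
        for u, v, s in edges:
            if s not in (1, -1):
                raise ValueError(f"edge ({u}, {v}) has sign {s!r}; expected +1 or -1")
            if u == v and not allow_self_loops:
                raise ValueError(f"self-loop on node {u!r} not allowed")
            if g.has_edge(u, v):
                raise ValueError(f"duplicate directed edge ({u}, {v})")
            g.add_edge(u, v, sign=s)
        return cls(g)

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> list[tuple[str, str, int]]:
        return [(u, v, d["sign"]) for u, v, d in self.graph.edges(data=True)]

    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def negative_fraction(self) -> float:
        m = self.n_edges()
        if m == 0:
            return 0.0
        neg = sum(1 for _, _, s in self.edges if s == -1)
        return neg / m

    def unsigned(self) -> "SignedDiGraph":
        """Copy with every edge sign forced to +1 (sign-blind view)."""
        return SignedDiGraph.from_edges(
            [(u, v, 1) for u, v, _ in self.edges], nodes=self.nodes
        )


@dataclass
class Interactome:
    """Undirected protein-protein interaction network (background interactome)."""

    graph: nx.Graph = field(default_factory=nx.Graph)

    @classmethod
    def from_edges(
        cls, edges: Iterable[tuple[str, str]], nodes: Iterable[str] = ()
    ) -> "Interactome":
        g = nx.Graph()
        g.add_nodes_from(nodes)
        for u, v in edges:
            if u == v:
                raise ValueError(f"self-loop on node {u!r} not allowed")
            if g.has_edge(u, v):
                raise ValueError(f"duplicate undirected pair {{{u}, {v}}}")
            g.add_edge(u, v)
        return cls(g)

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[frozenset[str]]:
        return {frozenset((u, v)) for u, v in self.graph.edges}


@dataclass(frozen=True)
class GeneSet:
    """A named set of gene identifiers (disease genes, drug targets, ...)."""

    name: str
    members: frozenset[str]

    def __init__(self, name: str, members: Iterable[str]):
        object.__setattr__(self, "name", name)
        object.__setattr__(self, "members", frozenset(members))

    def __len__(self) -> int:
        return len(self.members)

    def intersect(self, universe: Iterable[str]) -> "GeneSet":
        return GeneSet(self.name, self.members & set(universe))


@dataclass
class DrugProfile:
    """A drug: identifier, optional SMILES, and signed target list.

    ``targets`` maps gene -> sign in {+1, -1, UNKNOWN_SIGN}; the unknown
    sentinel is permitted only where the source data leaves direction
    unstated.
    """

    drug_id: str
    smiles: str | None = None
    targets: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for gene, sign in self.targets.items():
            if sign not in (1, -1, UNKNOWN_SIGN):
                raise ValueError(
                    f"drug {self.drug_id!r} target {gene!r} has sign {sign!r}"
                )

    def target_set(self) -> GeneSet:
        return GeneSet(self.drug_id, self.targets)


#: gene identifier -> set of opaque function-term identifiers (e.g. GO BP terms)
AnnotationMap = dict


def _parse_sign(token: str, lineno: int) -> int:
    t = token.strip().lower()
    if t in _POSITIVE_TOKENS:
        return 1
    if t in _NEGATIVE_TOKENS:
        return -1
    raise GraphParseError(f"line {lineno}: unknown sign token {token!r}")


def read_signed_edgelist(
    path: str | Path, directed: bool = True
) -> SignedDiGraph | Interactome:
    """Parse an edge-list file into a signed digraph or an interactome.

    Directed mode returns :class:`SignedDiGraph`; undirected mode ignores any
    sign column and returns :class:`Interactome`.  A header line starting with
    ``#nodes:`` may enumerate isolated nodes.  Duplicate (source, target)
    lines raise :class:`GraphParseError` identifying the line number.
    """
    path = Path(path)
    nodes: list[str] = []
    dedges: list[tuple[str, str, int]] = []
    uedges: list[tuple[str, str]] = []
    seen_d: set[tuple[str, str]] = set()
    seen_u: set[frozenset[str]] = set()
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                if line.startswith("#nodes:"):
                    nodes.extend(line[len("#nodes:") :].split())
                continue
            parts = line.split()
            if len(parts) < 2:
                raise GraphParseError(
                    f"line {lineno}: expected at least 2 columns, got {len(parts)}"
                )
            u, v = parts[0], parts[1]
            sign = _parse_sign(parts[2], lineno) if len(parts) >= 3 else 1
            if directed:
                if (u, v) in seen_d:
                    raise GraphParseError(f"line {lineno}: duplicate edge ({u}, {v})")
                seen_d.add((u, v))
                dedges.append((u, v, sign))
            else:
                pair = frozenset((u, v))
                if pair in seen_u:
                    raise GraphParseError(
                        f"line {lineno}: duplicate undirected pair ({u}, {v})"
                    )
                seen_u.add(pair)
                uedges.append((u, v))
    if directed:
        return SignedDiGraph.from_edges(dedges, nodes=nodes)
    return Interactome.from_edges(uedges, nodes=nodes)


def write_signed_edgelist(
    graph: SignedDiGraph | Interactome, path: str | Path
) -> None:
    """Write an edge list deterministically (edges sorted by source, target).

    Isolated nodes are preserved in a ``#nodes:`` header so that
    :func:`read_signed_edgelist` inverts this function exactly.
    """
    path = Path(path)
    lines: list[str] = []
    if isinstance(graph, SignedDiGraph):
        rows = sorted(graph.edges)
        touched = {u for u, _, _ in rows} | {v for _, v, _ in rows}
        isolated = sorted(graph.nodes - touched)
        if isolated:
            lines.append("#nodes: " + " ".join(isolated))
        for u, v, s in rows:
            lines.append(f"{u}\t{v}\t{'+1' if s == 1 else '-1'}")
    else:
        pairs = sorted(tuple(sorted(p)) for p in graph.edges)
        touched = {n for p in pairs for n in p}
        isolated = sorted(graph.nodes - touched)
        if isolated:
            lines.append("#nodes: " + " ".join(isolated))
        for u, v in pairs:
            lines.append(f"{u}\t{v}")
    path.write_text("\n".join(lines) + ("\n" if lines else ""))


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Read gene sets in GMT format: ``name<TAB>description<TAB>gene...``.

    The description field is discarded; duplicate members collapse.
    """
    sets: list[GeneSet] = []
    with Path(path).open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GraphParseError(
                    f"line {lineno}: GMT line needs >=3 tab-separated fields"
                )
            sets.append(GeneSet(fields[0], fields[2:]))
    return sets


def write_gmt(sets: Iterable[GeneSet], path: str | Path) -> None:
    lines = [
        "\t".join([s.name, "na"] + sorted(s.members)) for s in sets
    ]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_drug_table(path: str | Path) -> list[DrugProfile]:
    """Read a drug CSV/TSV with columns ``drug_id, smiles, targets``.

    ``targets`` is a semicolon-joined list of ``gene`` or ``gene:sign``
    tokens (sign in +1/-1/?); a bare gene or ``?`` sign means direction
    unknown.
    """
    path = Path(path)
    delim = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    drugs: list[DrugProfile] = []
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh, delimiter=delim)
        if reader.fieldnames is None or "drug_id" not in reader.fieldnames:
            raise GraphParseError("drug table needs a 'drug_id' column")
        for row in reader:
            targets: dict[str, int] = {}
            for token in (row.get("targets") or "").split(";"):
                token = token.strip()
                if not token:
                    continue
                if ":" in token:
                    gene, sig = token.rsplit(":", 1)
                    sign = UNKNOWN_SIGN if sig.strip() == "?" else _parse_sign(sig, 0)
                else:
                    gene, sign = token, UNKNOWN_SIGN
                if gene in targets:
                    raise GraphParseError(
                        f"drug {row['drug_id']!r}: duplicate target {gene!r}"
                    )
                targets[gene] = sign
            smiles = (row.get("smiles") or "").strip() or None
            drugs.append(DrugProfile(row["drug_id"], smiles, targets))
    return drugs


def write_drug_table(drugs: Iterable[DrugProfile], path: str | Path) -> None:
    def fmt_sign(s: int) -> str:
        return {1: "+1", -1: "-1", UNKNOWN_SIGN: "?"}[s]

    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["drug_id", "smiles", "targets"])
        for d in drugs:
            toks = ";".join(
                f"{g}:{fmt_sign(s)}" for g, s in sorted(d.targets.items())
            )
            writer.writerow([d.drug_id, d.smiles or "", toks])


def read_annotations(path: str | Path) -> AnnotationMap:
    """Read gene-to-function-term annotations as 2-column TSV ``gene<TAB>term``."""
    ann: AnnotationMap = {}
    with Path(path).open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise GraphParseError(f"line {lineno}: expected gene<TAB>term")
            ann.setdefault(parts[0], set()).add(parts[1])
    return ann


def write_annotations(ann: Mapping[str, set], path: str | Path) -> None:
    lines = [
        f"{gene}\t{term}"
        for gene in sorted(ann)
        for term in sorted(ann[gene])
    ]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def giant_strongly_connected(graph: SignedDiGraph) -> SignedDiGraph:
    """Induced subgraph on the largest strongly connected component (GSC).

    Ties between equal-sized components are broken toward the component
    containing the lexicographically smallest node.
    """
    if graph.n_nodes() == 0:
        raise ValueError("cannot take the GSC of an empty graph")
    comps = [set(c) for c in nx.strongly_connected_components(graph.graph)]
    best = min(comps, key=lambda c: (-len(c), min(c)))
    sub = graph.graph.subgraph(best)
    return SignedDiGraph.from_edges(
        [(u, v, d["sign"]) for u, v, d in sub.edges(data=True)], nodes=best
    )
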