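"""Diagnosis-code handling: normalization and in-system hierarchies.

ICD-10 codes ("E27.1"), ICD-9 codes ("255.4") and ORPHA identifiers
("ORPHA:85138") each live in their own coding system with their own
parent/child hierarchy.  Internally codes are stored in a normalized
form (uppercase, dot separator removed); ICD codes are re-dotted on
output after the third character, which is where the category/subcode
boundary sits in both ICD revisions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Iterator

import networkx as nx


class System(str, Enum):
    ICD10 = "ICD10"
    ICD9 = "ICD9"
    ORPHA = "ORPHA"


def normalize_code(code: str) -> str:
    """Uppercase a code and strip dots and whitespace.

    ``"e27.1" -> "E271"``, ``"orpha:389 " -> "ORPHA:389"``.
    """
    return code.strip().upper().replace(".", "").replace(" ", "")


def format_icd(code: str) -> str:
    """Restore the display dot of a normalized ICD code: ``E271 -> E27.1``."""
    code = normalize_code(code)
    if len(code) > 3:
        return code[:3] + "." + code[3:]
    return code


@dataclass
class CodeNode:
    """One code in one coding system, with links to its parents."""

    system: System
    code: str
    label: str = ""
    parents: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.code = normalize_code(self.code)
        self.parents = [normalize_code(p) for p in self.parents]


class CodeHierarchy:
    """An acyclic is-a hierarchy over the codes of a single system.

    Edges run parent -> child.  Codes referenced only as parents are
    materialized as label-less nodes so partial hierarchies still answer
    ancestor queries.
    """

    def __init__(self, system: System, nodes: Iterable[CodeNode] = ()) -> None:
        self.system = system
        self._graph = nx.DiGraph()
        for node in nodes:
            self.add(node)

    def add(self, node: CodeNode) -> None:
        if node.system != self.system:
            raise ValueError(f"node {node.code} belongs to {node.system}, not {self.system}")
        if node.code in self._graph and self._graph.nodes[node.code].get("label"):
            raise ValueError(f"duplicate code {node.code!r} in {self.system.value} hierarchy")
        self._graph.add_node(node.code, label=node.label)
        for parent in node.parents:
            self._graph.add_edge(parent, node.code)
        if not nx.is_directed_acyclic_graph(self._graph):
            raise ValueError(f"parent links of {node.code!r} introduce a cycle")

    def __contains__(self, code: str) -> bool:
        return normalize_code(code) in self._graph

    def __iter__(self) -> Iterator[str]:
        return iter(self._graph.nodes)

    def __len__(self) -> int:
        return len(self._graph)

    def label(self, code: str) -> str:
        return self._graph.nodes[normalize_code(code)].get("label", "")

    def ancestors(self, code: str) -> set[str]:
        """All strict ancestors (parents, grandparents, ...) of ``code``."""
        return nx.ancestors(self._graph, normalize_code(code))

    def descendants(self, code: str) -> set[str]:
        return nx.descendants(self._graph, normalize_code(code))

    def is_ancestor(self, a: str, b: str) -> bool:
        """True when ``a`` is a strict ancestor of ``b``."""
        a, b = normalize_code(a), normalize_code(b)
        if a not in self._graph or b not in self._graph or a == b:
            return False
        return a in nx.ancestors(self._graph, b)

    @classmethod
    def from_parent_table(
        cls, system: System, rows: Iterable[tuple[str, str, str]]
    ) -> "CodeHierarchy":
        """Build from ``(code, label, parent-or-empty)`` rows (TSV-shaped)."""
        nodes: dict[str, CodeNode] = {}
        for code, label, parent in rows:
            code = normalize_code(code)
            node = nodes.setdefault(code, CodeNode(system, code, label))
            node.label = node.label or label
            if parent:
                node.parents.append(normalize_code(parent))
        return cls(system, nodes.values())
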