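"""Treatment-tree discovery (CareFlow-Miner-style prefix tree).

The discovery algorithm takes the event log and builds a tree with a common
starting point (the *recruitment* root holding every patient).  The root
branches to all observed first-line labels; each node recursively branches
to the next-line labels observed in its sub-cohort.  A patient belongs to a
node exactly when the first ``depth`` labels of their sequence equal the
node's path, so sibling patient sets partition the parent's "continuing"
patients and every non-root node's patients are a subset of its parent's.

Nodes below a minimum patient count can be pruned (whole subtrees are
removed) to keep the display compact; child ordering is deterministic
(descending patient count, then lexicographic label).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterator, Sequence

from .event_log import ADJUVANT, EventLog
from .exceptions import ContractError, ValidationError

ROOT_LABEL = "recruitment"


def label_str(label: tuple[str, str] | None) -> str:
    """Render a (type, setting) label; adjuvant labels get an ``adj:`` prefix."""
    if label is None:
        return ROOT_LABEL
    ttype, setting = label
    return f"adj:{ttype}" if setting == ADJUVANT else ttype


def parse_label(text: str) -> tuple[str, str]:
    text = text.strip()
    if text.startswith("adj:"):
        return (text[4:], ADJUVANT)
    return (text, "advanced")


@dataclass
class TreatmentNode:
    node_id: int
    label: tuple[str, str] | None  # None marks the root
    depth: int
    patient_ids: set[str]
    parent: "TreatmentNode | None" = field(default=None, repr=False)
    children: list["TreatmentNode"] = field(default_factory=list, repr=False)
    #: patient -> start date of this node's treatment line for that patient
    anchor_dates: dict = field(default_factory=dict, repr=False)
    #: patient -> the (original) line index anchoring this node
    anchor_lines: dict = field(default_factory=dict, repr=False)

    @property
    def is_root(self) -> bool:
        return self.label is None

    @property
    def n_patients(self) -> int:
        return len(self.patient_ids)

    @property
    def setting(self) -> str | None:
        return None if self.label is None else self.label[1]

    def __repr__(self) -> str:  # compact, cycle-free
        return f"TreatmentNode({label_str(self.label)!r}, n={self.n_patients})"


@dataclass
class TreatmentTree:
    root: TreatmentNode
    min_patients: int
    node_index: dict[int, TreatmentNode]

    def nodes(self) -> Iterator[TreatmentNode]:
        """Breadth-first traversal (deterministic)."""
        queue = [self.root]
        while queue:
            node = queue.pop(0)
            yield node
            queue.extend(node.children)

    @property
    def n_nodes(self) -> int:
        return len(self.node_index)

    def find(self, path: Sequence[tuple[str, str] | str]) -> TreatmentNode:
        """Resolve a label path (root-relative) to its node."""
        node = self.root
        for raw in path:
            want = parse_label(raw) if isinstance(raw, str) else tuple(raw)
            for child in node.children:
                if child.label == want:
                    node = child
                    break
            else:
                raise KeyError(
                    f"no node with path {[label_str(l if not isinstance(l, str) else parse_label(l)) for l in path]}"
                )
        return node

    def path_counts(self) -> dict[tuple, int]:
        """(label-path tuple) -> patient count, for every node."""
        return {tuple(node_path(n)): n.n_patients for n in self.nodes()}

    # -- export ------------------------------------------------------------

    def to_json(self, log: EventLog | None = None, include_patient_ids: bool = False,
                indent: int | None = 2) -> str:
        """Serialise the tree as JSON (nodes + edges with branch fractions).

        With ``log`` given, each non-root node carries its best-overall
        response (or recurrence) counts and a compact OS summary.  Patient
        identifiers are withheld unless explicitly requested.
        """
        from . import node_stats  # local import: node_stats consumes nodes

        nodes = []
        edges = []
        for node in self.nodes():
            entry = {
                "id": node.node_id,
                "label": ROOT_LABEL if node.is_root else node.label[0],
                "setting": node.setting,
                "depth": node.depth,
                "parent": None if node.parent is None else node.parent.node_id,
                "n_patients": node.n_patients,
            }
            if include_patient_ids:
                entry["patient_ids"] = sorted(node.patient_ids)
            if log is not None and not node.is_root:
                bor = node_stats.node_bor(node, log)
                entry["bor"] = dict(sorted(bor.counts.items()))
                if node.n_patients:
                    curve = node_stats.node_os_curve(node, log)
                    entry["os_summary"] = {
                        "t_months": [round(t / 30.44, 2) for t in curve.times],
                        "s": [round(s, 4) for s in curve.survival],
                    }
            nodes.append(entry)
            for child in node.children:
                edges.append(
                    {
                        "parent": node.node_id,
                        "child": child.node_id,
                        "fraction": round(branch_fraction(child), 6),
                    }
                )
        return json.dumps({"nodes": nodes, "edges": edges}, indent=indent,
                          sort_keys=False)

    def to_dot(self) -> str:
        """Graphviz DOT text: edge width tracks the branch fraction, adjuvant
        nodes are filled yellow (matching the usual tree rendering)."""
        lines = ["digraph treatment_tree {", "  rankdir=TB;",
                 '  node [shape=box, style=filled, fillcolor=white];']
        for node in self.nodes():
            name = f"n{node.node_id}"
            text = f"{label_str(node.label)}\\nn={node.n_patients}"
            style = ', fillcolor="khaki"' if node.setting == ADJUVANT else ""
            lines.append(f'  {name} [label="{text}"{style}];')
        for node in self.nodes():
            for child in node.children:
                w = 1.0 + 6.0 * branch_fraction(child)
                lines.append(
                    f"  n{node.node_id} -> n{child.node_id} [penwidth={w:.2f}];"
                )
        lines.append("}")
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# discovery / pruning
# ---------------------------------------------------------------------------


def discover_tree(log: EventLog, min_patients: int = 0) -> TreatmentTree:
    """Grow the prefix tree of treatment-line label sequences.

    A node exists for every observed label-sequence prefix shared by at
    least ``min_patients`` patients.  Children are ordered by descending
    patient count, ties broken lexicographically, so identical logs always
    yield identical trees.
    """
    if min_patients < 0:
        raise ValidationError("min_patients must be >= 0")
    sequences = {pid: log.sequence(pid) for pid in log.events}
    root = TreatmentNode(node_id=0, label=None, depth=0,
                         patient_ids=set(sequences))

    def grow(node: TreatmentNode) -> None:
        groups: dict[tuple[str, str], list[str]] = {}
        for pid in node.patient_ids:
            seq = sequences[pid]
            if len(seq) > node.depth:
                groups.setdefault(seq[node.depth], []).append(pid)
        ordered = sorted(
            groups.items(), key=lambda kv: (-len(kv[1]), label_str(kv[0]))
        )
        for label, pids in ordered:
            if len(pids) < min_patients:
                continue
            child = TreatmentNode(
                node_id=-1,
                label=label,
                depth=node.depth + 1,
                patient_ids=set(pids),
                parent=node,
            )
            for pid in pids:
                ev = log.events[pid][node.depth]
                child.anchor_dates[pid] = ev.start_date
                child.anchor_lines[pid] = ev.line
            node.children.append(child)
            grow(child)

    grow(root)
    return _index(root, min_patients)


def _index(root: TreatmentNode, min_patients: int) -> TreatmentTree:
    """Assign breadth-first node ids and build the index."""
    index: dict[int, TreatmentNode] = {}
    queue = [root]
    next_id = 0
    while queue:
        node = queue.pop(0)
        node.node_id = next_id
        index[next_id] = node
        next_id += 1
        queue.extend(node.children)
    return TreatmentTree(root=root, min_patients=min_patients, node_index=index)


def prune_tree(tree: TreatmentTree, min_patients: int) -> TreatmentTree:
    """Raise the pruning threshold: drop whole subtrees below ``min_patients``.

    Pruning only removes nodes; asking for a threshold below the tree's
    current one is a contract error (rebuild from the log instead).  The
    result is identical to discovering the tree at the new threshold.
    """
    if min_patients < tree.min_patients:
        raise ContractError(
            f"cannot prune to {min_patients} < current threshold "
            f"{tree.min_patients}; rebuild with discover_tree"
        )

    def copy(node: TreatmentNode, parent: TreatmentNode | None) -> TreatmentNode:
        clone = TreatmentNode(
            node_id=-1,
            label=node.label,
            depth=node.depth,
            patient_ids=set(node.patient_ids),
            parent=parent,
            anchor_dates=dict(node.anchor_dates),
            anchor_lines=dict(node.anchor_lines),
        )
        clone.children = [
            copy(c, clone) for c in node.children if c.n_patients >= min_patients
        ]
        return clone

    return _index(copy(tree.root, None), min_patients)


def branch_fraction(node: TreatmentNode) -> float:
    """Fraction of the parent's patients continuing into this node.

    Drives the branch thickness in tree renderings.  Undefined for the root.
    """
    if node.parent is None:
        raise ContractError("branch_fraction is undefined for the root node")
    if node.parent.n_patients == 0:
        return 0.0
    return node.n_patients / node.parent.n_patients


def node_path(node: TreatmentNode) -> list[tuple[str, str]]:
    """Labels from the first line down to ``node`` (empty for the root)."""
    path = []
    while node.parent is not None:
        path.append(node.label)
        node = node.parent
    return list(reversed(path))
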