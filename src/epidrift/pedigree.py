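"""Mutation-accumulation pedigrees.

A pedigree is a rooted tree: one ancestor, directed edges parent -> child,
each edge annotated with its length in mitoses.  By default an edge from a
node at transfer u to a child at transfer v spans (v - u) *
``mitoses_per_transfer`` mitoses (25 per the study design); explicit edge
lengths override this.  The quantity the downstream model consumes is the
pair divergence time: for samples i and j, the branch lengths t_i and t_j
from each sample back to their most recent common ancestor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_MITOSES_PER_TRANSFER = 25


@dataclass
class PedigreeNode:
    node_id: str
    line_id: str
    transfer: int
    parent_id: str | None
    edge_mitoses: float  # length of the edge from the parent; 0 for the root
    sampled: bool = True


@dataclass
class Pedigree:
    """Rooted MA lineage tree with edge lengths in mitoses."""

    nodes: dict[str, PedigreeNode] = field(default_factory=dict)
    mitoses_per_transfer: float = DEFAULT_MITOSES_PER_TRANSFER

    def add_node(
        self,
        node_id,
        line_id="",
        transfer=0,
        parent_id=None,
        edge_mitoses=None,
        sampled=True,
    ):
        if node_id in self.nodes:
            raise ValueError(f"duplicate node id {node_id!r}")
        if node_id == parent_id:
            raise ValueError(f"node {node_id!r} is its own parent")
        if edge_mitoses is None:
            if parent_id is None:
                edge_mitoses = 0.0
            else:
                parent = self.nodes.get(parent_id)
                if parent is None:
                    raise ValueError(f"parent {parent_id!r} of {node_id!r} not defined before use")
                edge_mitoses = (transfer - parent.transfer) * self.mitoses_per_transfer
        if edge_mitoses < 0:
            raise ValueError(f"negative edge length for node {node_id!r}")
        self.nodes[node_id] = PedigreeNode(
            str(node_id), str(line_id), int(transfer), parent_id, float(edge_mitoses), sampled
        )
        return self

    @property
    def root(self) -> str:
        roots = [n.node_id for n in self.nodes.values() if n.parent_id is None]
        if len(roots) != 1:
            raise ValueError(f"pedigree must have exactly one root, found {len(roots)}")
        return roots[0]

    def validate(self) -> "Pedigree":
        root = self.root  # raises on 0 or >1 roots
        for node in self.nodes.values():
            if node.parent_id is not None and node.parent_id not in self.nodes:
                raise ValueError(f"node {node.node_id!r} references missing parent {node.parent_id!r}")
        for node in self.nodes.values():  # cycle check: every chain must end at the root
            seen = set()
            cur = node
            while cur.parent_id is not None:
                if cur.node_id in seen:
                    raise ValueError(f"cycle detected at node {cur.node_id!r}")
                seen.add(cur.node_id)
                cur = self.nodes[cur.parent_id]
            if cur.node_id != root:
                raise ValueError(f"node {node.node_id!r} not reachable from the root")
        return self

    def samples(self) -> list[str]:
        return [n.node_id for n in self.nodes.values() if n.sampled]

    def _path_to_root(self, node_id) -> dict[str, float]:
        """Cumulative mitoses from ``node_id`` to each of its ancestors (incl. itself at 0)."""
        if node_id not in self.nodes:
            raise KeyError(f"unknown node {node_id!r}")
        out = {node_id: 0.0}
        cur = self.nodes[node_id]
        total = 0.0
        while cur.parent_id is not None:
            total += cur.edge_mitoses
            cur = self.nodes[cur.parent_id]
            out[cur.node_id] = total
        return out

    def time_to_root(self, node_id) -> float:
        return max(self._path_to_root(node_id).values())

    def divergence_time(self, i, j) -> tuple[float, float]:
        """Branch lengths (t_i, t_j) from samples i and j to their MRCA."""
        pi = self._path_to_root(i)
        pj = self._path_to_root(j)
        common = set(pi) & set(pj)
        if not common:
            raise ValueError(f"{i!r} and {j!r} share no ancestor (different pedigrees?)")
        mrca = min(common, key=lambda a: pi[a])
        return pi[mrca], pj[mrca]

    def delta_t(self, i, j) -> float:
        ti, tj = self.divergence_time(i, j)
        return ti + tj

    def topological_order(self) -> list[str]:
        """Node ids, parents before children."""
        order, seen = [], set()

        def visit(nid):
            node = self.nodes[nid]
            if node.parent_id is not None and node.parent_id not in seen:
                visit(node.parent_id)
            if nid not in seen:
                seen.add(nid)
                order.append(nid)

        for nid in self.nodes:
            visit(nid)
        return order

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "sample_id": n.node_id,
                "line_id": n.line_id,
                "transfer": n.transfer,
                "parent_id": "" if n.parent_id is None else n.parent_id,
                "edge_mitoses": n.edge_mitoses,
                "sampled": int(n.sampled),
            }
            for n in self.nodes.values()
        ]
        return pd.DataFrame(rows)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, mitoses_per_transfer=DEFAULT_MITOSES_PER_TRANSFER) -> "Pedigree":
        ped = cls(mitoses_per_transfer=mitoses_per_transfer)
        df = df.copy()
        # parents must exist before children; sort by dependency via repeated passes
        pending = list(df.index)
        added: set[str] = set()
        while pending:
            progressed = False
            rest = []
            for idx in pending:
                row = df.loc[idx]
                parent = row.get("parent_id", None)
                if parent is None or (isinstance(parent, float) and np.isnan(parent)) or parent == "":
                    parent = None
                else:
                    parent = str(parent)
                if parent is not None and parent not in added:
                    rest.append(idx)
                    continue
                edge = row.get("edge_mitoses", None)
                if edge is not None and (isinstance(edge, float) and np.isnan(edge)):
                    edge = None
                ped.add_node(
                    str(row["sample_id"]),
                    line_id=str(row.get("line_id", "")),
                    transfer=int(row.get("transfer", 0)),
                    parent_id=parent,
                    edge_mitoses=None if edge is None else float(edge),
                    sampled=bool(int(row["sampled"])) if "sampled" in row else True,
                )
                added.add(str(row["sample_id"]))
                progressed = True
            if not progressed:
                missing = {str(df.loc[i]["parent_id"]) for i in rest} - added - set(df["sample_id"].astype(str))
                if missing:
                    raise ValueError(f"missing parent node(s): {sorted(missing)}")
                raise ValueError("pedigree contains a cycle")
            pending = rest
        return ped.validate()
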