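"""Directed network container with per-link metadata.

Links carry whatever the producing stage attaches: transfer entropy,
reconstructed interaction delay and p-value at the subject level;
support counts and binomial tail probabilities at the group level;
provenance flags after a union.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

__all__ = ["DirectedNetwork"]


@dataclass
class DirectedNetwork:
    """Node labels plus directed links with attribute dicts."""

    nodes: list[str]
    links: dict[tuple[str, str], dict] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.nodes)) != len(self.nodes):
            raise ValueError("node labels must be unique")
        for (s, t) in self.links:
            self._check_link(s, t)

    def _check_link(self, s: str, t: str) -> None:
        if s == t:
            raise ValueError(f"self-link {s}->{t} not allowed")
        if s not in self.nodes or t not in self.nodes:
            raise ValueError(f"link {s}->{t} references unknown node")

    def add_link(self, source: str, target: str, **attrs) -> None:
        self._check_link(source, target)
        self.links[(source, target)] = dict(attrs)

    def has_link(self, source: str, target: str) -> bool:
        return (source, target) in self.links

    @property
    def n_links(self) -> int:
        return len(self.links)

    def copy(self) -> "DirectedNetwork":
        return DirectedNetwork(
            nodes=list(self.nodes),
            links={k: dict(v) for k, v in self.links.items()},
        )

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for (s, t), attrs in sorted(self.links.items()):
            rows.append({"source": s, "target": t, **attrs})
        cols = ["source", "target"]
        return pd.DataFrame(rows, columns=cols if not rows else None)

    def to_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, nodes: list[str] | None = None) -> "DirectedNetwork":
        df = pd.read_csv(path, sep="\t")
        df["source"] = df["source"].astype(str)
        df["target"] = df["target"].astype(str)
        if nodes is None:
            nodes = sorted(set(df["source"]) | set(df["target"]))
        net = cls(nodes=list(nodes))
        for _, row in df.iterrows():
            attrs = {k: row[k] for k in df.columns if k not in ("source", "target")}
            net.add_link(str(row["source"]), str(row["target"]), **attrs)
        return net

    def to_graphml(self, path) -> None:
        import networkx as nx

        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for (s, t), attrs in self.links.items():
            clean = {k: v for k, v in attrs.items() if v is not None}
            g.add_edge(s, t, **clean)
        nx.write_graphml(g, Path(path))
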