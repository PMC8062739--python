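"""Candidate model spaces for the three-step effective-connectivity analysis.

Step 1 starts from the union TE network and emits the full model, every
single-link deletion, and the PPI-only / PPNI-only variants.  Step 2
prunes simple cascade and common-drive artifacts: in every transitive
(acyclic) triangle X->Y, Y->Z, X->Z the link X->Z may be spurious due to
a two-step cascade through Y, or Y->Z may be spurious due to the common
driver X — but not both, because the two explanations are mutually
exclusive.  The step-2 space therefore enumerates all subsets of
removable links that delete at most one of the two candidates of every
triangle.  Step 3 fixes the winning structure (A-matrix) and varies
which links are modulated by the illusory percept (B-matrix).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .network import DirectedNetwork

__all__ = [
    "ModelSpec", "Triangle", "TriangleCatalog",
    "full_space_size", "network_to_model", "step1_models",
    "find_acyclic_triangles", "enumerate_pruned_models",
    "step3_modulation_models",
]

Link = tuple[str, str]


@dataclass
class ModelSpec:
    """One candidate model: link presence (A) and modulation (B) matrices.

    ``A[i, j]`` is True when the directed link ``nodes[i] -> nodes[j]``
    is present; ``B`` flags which present links are modulated by the
    percept.  ``family`` tags the coupling-sign family.  ``delays``
    optionally carries per-link transmission delays in samples (from the
    TE delay reconstruction) used by the spectral fit.
    """

    nodes: list[str]
    A: np.ndarray
    B: np.ndarray | None = None
    family: str = "excitatory"
    provenance: str = "full"
    delays: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = len(self.nodes)
        self.A = np.asarray(self.A, dtype=bool)
        if self.A.shape != (n, n):
            raise ValueError("A must be (n_nodes, n_nodes)")
        if self.A.diagonal().any():
            raise ValueError("no self-links allowed in A")
        if self.B is None:
            self.B = self.A.copy()
        self.B = np.asarray(self.B, dtype=bool)
        if (self.B & ~self.A).any():
            raise ValueError("B must be a subset of A")
        if self.family not in ("excitatory", "inhibitory", "mixed"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.delays is not None:
            self.delays = np.asarray(self.delays, dtype=int)
            if self.delays.shape != (n, n):
                raise ValueError("delays must be (n_nodes, n_nodes)")

    @property
    def n_links(self) -> int:
        return int(self.A.sum())

    def links(self) -> list[Link]:
        return [(self.nodes[i], self.nodes[j])
                for i, j in zip(*np.nonzero(self.A))]

    def index(self, link: Link) -> tuple[int, int]:
        return self.nodes.index(link[0]), self.nodes.index(link[1])

    def without_links(self, removed, provenance: str) -> "ModelSpec":
        A = self.A.copy()
        B = self.B.copy()
        for link in removed:
            i, j = self.index(link)
            A[i, j] = False
            B[i, j] = False
        return ModelSpec(nodes=list(self.nodes), A=A, B=B, family=self.family,
                         provenance=provenance, delays=self.delays)

    def to_dict(self) -> dict:
        return {
            "nodes": self.nodes,
            "A": self.A.astype(int).tolist(),
            "B": self.B.astype(int).tolist(),
            "family": self.family,
            "provenance": self.provenance,
            "delays": None if self.delays is None else self.delays.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        return cls(nodes=d["nodes"], A=np.array(d["A"]), B=np.array(d["B"]),
                   family=d["family"], provenance=d["provenance"],
                   delays=None if d.get("delays") is None else np.array(d["delays"]))


@dataclass(frozen=True)
class Triangle:
    """Transitive triangle X->Y, Y->Z, X->Z with its two spurious candidates."""

    x: str
    y: str
    z: str

    @property
    def cascade_candidate(self) -> Link:
        """X->Z: spurious if the transfer is a two-step cascade via Y."""
        return (self.x, self.z)

    @property
    def common_drive_candidate(self) -> Link:
        """Y->Z: spurious if X commonly drives both Y and Z."""
        return (self.y, self.z)

    @property
    def candidates(self) -> tuple[Link, Link]:
        return (self.cascade_candidate, self.common_drive_candidate)


@dataclass
class TriangleCatalog:
    triangles: list[Triangle] = field(default_factory=list)

    @property
    def removable_links(self) -> list[Link]:
        """Union of all candidate links, in deterministic order."""
        seen: dict[Link, None] = {}
        for tri in self.triangles:
            for link in tri.candidates:
                seen.setdefault(link)
        return list(seen)

    def __len__(self) -> int:
        return len(self.triangles)


def full_space_size(n_nodes: int) -> int:
    """Number of presence/absence patterns over undirected node pairs.

    2^(n(n-1)/2) structural models per coupling-sign family; for the
    eight sources of the illusion network this is 2^28 = 268,435,456 —
    the intractable space that motivates TE-guided pruning.
    """
    if n_nodes < 2:
        raise ValueError("need >= 2 nodes")
    return 2 ** (n_nodes * (n_nodes - 1) // 2)


def network_to_model(net: DirectedNetwork, family: str = "excitatory",
                     provenance: str = "full",
                     default_delay: int = 1) -> ModelSpec:
    """ModelSpec with A set to a network's links (B = A, delays attached)."""
    n = len(net.nodes)
    A = np.zeros((n, n), dtype=bool)
    delays = np.full((n, n), default_delay, dtype=int)
    idx = {name: i for i, name in enumerate(net.nodes)}
    for (s, t), attrs in net.links.items():
        A[idx[s], idx[t]] = True
        d = attrs.get("delay")
        if d is not None and np.isfinite(d):
            delays[idx[s], idx[t]] = int(d)
    return ModelSpec(nodes=list(net.nodes), A=A, family=family,
                     provenance=provenance, delays=delays)


def step1_models(union: DirectedNetwork, ppi: DirectedNetwork,
                 ppni: DirectedNetwork, family: str = "excitatory") -> list[ModelSpec]:
    """Step-1 model set: full, every single-link deletion, PPI- and PPNI-only.

    Count = n_links + 3.  PPI/PPNI links must be subsets of the union.
    """
    if union.n_links == 0:
        raise ValueError("union network has no links")
    for name, sub in (("ppi", ppi), ("ppni", ppni)):
        if not set(sub.links) <= set(union.links):
            raise ValueError(f"{name} network is not a subset of the union")
    full = network_to_model(union, family=family, provenance="full")
    models = [full]
    for link in sorted(union.links):
        models.append(full.without_links([link],
                                         provenance=f"single-deletion({link[0]}->{link[1]})"))
    for name, sub in (("ppi-only", ppi), ("ppni-only", ppni)):
        removed = sorted(set(union.links) - set(sub.links))
        models.append(full.without_links(removed, provenance=name))
    return models


def find_acyclic_triangles(net: DirectedNetwork | ModelSpec) -> TriangleCatalog:
    """Enumerate transitive triangles X->Y, Y->Z, X->Z.

    Cyclic triangles (X->Y, Y->Z, Z->X) do not match the pattern and are
    naturally excluded.
    """
    if isinstance(net, ModelSpec):
        links = set(net.links())
        nodes = net.nodes
    else:
        links = set(net.links)
        nodes = net.nodes
    out = []
    for x in nodes:
        for y in nodes:
            if y == x or (x, y) not in links:
                continue
            for z in nodes:
                if z in (x, y):
                    continue
                if (y, z) in links and (x, z) in links:
                    out.append(Triangle(x, y, z))
    return TriangleCatalog(triangles=out)


def enumerate_pruned_models(base: ModelSpec,
                            catalog: TriangleCatalog,
                            removed_already=()) -> list[ModelSpec]:
    """Step-2 model set: constrained simultaneous link removals.

    Emits one model per subset S of the removable links (union of all
    triangle candidates, including the empty set) such that no triangle
    has both of its candidates in S; models are deduplicated by the
    resulting A-matrix.  Enumeration is a depth-first scan over the
    removable links with early constraint pruning, feasible for the
    network sizes the TE stage produces (tens of links).

    ``removed_already`` lists links that an earlier pruning step removed
    from the network the catalog was computed on (so they are absent
    from ``base``): they still count against each triangle's
    one-candidate budget, keeping the mutual-exclusivity constraint
    consistent across steps.
    """
    base_links = set(base.links())
    removed_already = set(removed_already)
    known = base_links | removed_already
    for tri in catalog.triangles:
        for link in ((tri.x, tri.y),) + tri.candidates:
            if link not in known:
                raise ValueError(f"catalog link {link} absent from base model")
    removable = [link for link in catalog.removable_links
                 if link in base_links]
    # per removable link, the triangles it belongs to
    link_tris: dict[Link, list[int]] = {link: [] for link in removable}
    for ti, tri in enumerate(catalog.triangles):
        for link in tri.candidates:
            if link in link_tris:
                link_tris[link].append(ti)
    tri_candidates = [set(t.candidates) for t in catalog.triangles]

    models: list[ModelSpec] = []
    seen: set[bytes] = set()
    chosen: list[Link] = []

    def emit() -> None:
        removed = sorted(chosen)
        spec = base.without_links(
            removed, provenance=f"triangle-pruned({removed!r})")
        key = np.packbits(spec.A).tobytes()
        if key not in seen:
            seen.add(key)
            models.append(spec)

    def feasible(link: Link) -> bool:
        removed = set(chosen) | removed_already
        for ti in link_tris[link]:
            other = tri_candidates[ti] - {link}
            if other & removed:
                return False
        return True

    def rec(i: int) -> None:
        if i == len(removable):
            emit()
            return
        rec(i + 1)                      # keep link
        if feasible(removable[i]):      # remove link
            chosen.append(removable[i])
            rec(i + 1)
            chosen.pop()

    rec(0)
    return models


def step3_modulation_models(winning: ModelSpec) -> list[ModelSpec]:
    """Step-3 model set: fixed structure, varying percept modulation.

    The all-modulated model (B = A) plus, for every present link, one
    model with only that link's modulation removed.  Count = n_links + 1.
    """
    if winning.n_links < 1:
        raise ValueError("winning model has no links")
    full_B = ModelSpec(nodes=list(winning.nodes), A=winning.A.copy(),
                       B=winning.A.copy(), family=winning.family,
                       provenance="modulation-variant(all)",
                       delays=winning.delays)
    models = [full_B]
    for link in sorted(winning.links()):
        B = winning.A.copy()
        i, j = winning.index(link)
        B[i, j] = False
        models.append(ModelSpec(
            nodes=list(winning.nodes), A=winning.A.copy(), B=B,
            family=winning.family,
            provenance=f"modulation-variant(-{link[0]}->{link[1]})",
            delays=winning.delays))
    return models
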