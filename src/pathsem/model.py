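"""From shortest-path modules to identified observed-variable path models.

This layer turns a fused pathway module plus gene classifications and
superfamily membership into an initial SEM specification: one free path
coefficient per directed edge, free error variances, and error covariances
fixed at zero.  Non-DEG connector genes that share a protein superfamily
are summarized by a first-principal-component composite before the model
is assembled.  Two identifiability conditions are enforced:

* bow-free — no variable pair has both a free directed edge and a free
  error covariance;
* block-recursive — feedback/reciprocal relations are confined to blocks
  (strongly connected components) of at most two equations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

from .errors import IdentificationError
from .graph import PathwayGraph, ShortestPathModule

__all__ = [
    "GeneClassification",
    "CompositeVariable",
    "PathModel",
    "classify_genes",
    "build_composites",
    "collapse_graph",
    "check_bow_free",
    "check_block_recursive",
    "build_initial_model",
]


@dataclass(frozen=True)
class GeneClassification:
    """Partition of the measured genes into DEG and non-DEG sets."""

    all_genes: frozenset
    degs: frozenset
    ndegs: frozenset


def classify_genes(graph_nodes: Iterable[str], deg_list: Iterable[str]) -> GeneClassification:
    """Partition graph nodes into DEGs and NDEGs; strays are warned and dropped."""
    nodes = frozenset(str(n) for n in graph_nodes)
    degs_in = {str(d) for d in deg_list}
    if not degs_in:
        raise ValueError("empty DEG list")
    strays = sorted(degs_in - nodes)
    if strays:
        warnings.warn(f"{len(strays)} DEG(s) not in the graph were dropped: {strays}")
    degs = frozenset(degs_in & nodes)
    return GeneClassification(all_genes=nodes, degs=degs, ndegs=nodes - degs)


@dataclass
class CompositeVariable:
    """A superfamily summarized by first-principal-component scores.

    ``loadings`` has unit Euclidean norm with the largest-magnitude entry
    positive; ``variance_explained`` is the PC1 eigenvalue share in [0, 1];
    ``scores`` are the per-sample PC1 scores used as the composite's data.
    """

    id: str
    members: tuple
    loadings: np.ndarray
    variance_explained: float
    scores: np.ndarray


def _pc1(X: np.ndarray, use_correlation: bool) -> tuple[np.ndarray, float, np.ndarray]:
    """First principal axis of an n x m member matrix."""
    Xc = X - X.mean(axis=0)
    if use_correlation:
        sd = X.std(axis=0, ddof=1)
        Xc = Xc / sd
        C = np.corrcoef(X, rowvar=False)
    else:
        C = np.cov(X, rowvar=False)
    evals, evecs = np.linalg.eigh(C)
    loadings = evecs[:, -1]
    k = int(np.argmax(np.abs(loadings)))
    if loadings[k] < 0:
        loadings = -loadings
    share = float(evals[-1] / evals.sum())
    scores = Xc @ loadings
    return loadings, share, scores


def build_composites(
    module: ShortestPathModule,
    sfmap: Mapping[str, str],
    expr: pd.DataFrame,
    min_variance: float = 0.5,
    use_correlation: bool = True,
) -> list[CompositeVariable]:
    """Build PC1 composites for superfamilies with >= 2 members in the module.

    ``expr`` is a samples x genes data frame.  A family is accepted when its
    PC1 explains at least ``min_variance`` of the member (standardized, by
    default) variance; rejected families leave their members as individual
    nodes.  Constant member genes are an error: they cannot be standardized.
    """
    nodes = module.subgraph.nodes
    families: dict[str, list[str]] = {}
    for gene, fam in sfmap.items():
        gene, fam = str(gene), str(fam)
        if gene in nodes and gene in expr.columns:
            families.setdefault(fam, []).append(gene)
    out = []
    for fam in sorted(families):
        members = sorted(families[fam])
        if len(members) < 2:
            continue
        X = expr[members].to_numpy(float)
        sds = X.std(axis=0, ddof=1)
        for gene, sd in zip(members, sds):
            if sd == 0:
                raise ValueError(f"gene {gene!r} has zero variance; cannot standardize")
        loadings, share, scores = _pc1(X, use_correlation)
        if share >= min_variance:
            out.append(
                CompositeVariable(
                    id=fam,
                    members=tuple(members),
                    loadings=loadings,
                    variance_explained=share,
                    scores=scores,
                )
            )
        else:
            warnings.warn(
                f"superfamily {fam}: PC1 explains {share:.0%} < {min_variance:.0%};"
                " members kept as individual nodes"
            )
    return out


def collapse_graph(module: ShortestPathModule, composites: list[CompositeVariable]) -> PathwayGraph:
    """Replace composite members by their composite node and merge edges.

    Edges re-targeted onto the same collapsed pair are merged keeping the
    interaction type of the lexicographically first original edge;
    self-loops created by merging are dropped.
    """
    g = module.subgraph
    mapping: dict[str, str] = {}
    for comp in composites:
        if comp.id in g.nodes:
            raise ValueError(f"composite ID {comp.id!r} collides with a gene ID")
        for m in comp.members:
            mapping[m] = comp.id
    out = PathwayGraph()
    for node in sorted(g.nodes):
        out.add_node(mapping.get(node, node))
    for u, v, kind in g.directed_edges:  # sorted, so dedup keeps lex-first type
        cu, cv = mapping.get(u, u), mapping.get(v, v)
        if cu != cv:
            out.add_edge(cu, cv, interaction=kind)
    return out


class PathModel:
    """An observed-variable SEM specification over an ordered variable list.

    ``beta_free[i, j]`` marks the path coefficient of edge variable_j ->
    variable_i as free; ``psi_free`` is the symmetric error-covariance
    pattern (diagonal always free).  ``provenance`` records, per free edge,
    where it came from: ``kegg:<type>``, ``string``, ``directed_path`` or
    ``mi_added``.
    """

    def __init__(
        self,
        variables: Iterable[str],
        mean_structure: bool = False,
    ) -> None:
        self.variables: tuple = tuple(str(v) for v in variables)
        if len(set(self.variables)) != len(self.variables):
            raise ValueError("duplicate variable names")
        p = len(self.variables)
        self.beta_free = np.zeros((p, p), dtype=bool)
        self.psi_free = np.eye(p, dtype=bool)
        self.beta_provenance: dict[tuple, str] = {}
        self.psi_provenance: dict[tuple, str] = {}
        self.mean_structure = bool(mean_structure)
        self._index = {v: i for i, v in enumerate(self.variables)}

    # -- construction --------------------------------------------------
    def index(self, name: str) -> int:
        return self._index[str(name)]

    def add_beta(self, target: str, source: str, provenance: str = "mi_added") -> None:
        i, j = self.index(target), self.index(source)
        if i == j:
            raise ValueError("self-loop path coefficients are fixed at zero")
        self.beta_free[i, j] = True
        self.beta_provenance[(self.variables[i], self.variables[j])] = provenance

    def remove_beta(self, target: str, source: str) -> None:
        i, j = self.index(target), self.index(source)
        self.beta_free[i, j] = False
        self.beta_provenance.pop((self.variables[i], self.variables[j]), None)

    def add_psi(self, a: str, b: str, provenance: str = "mi_added") -> None:
        i, j = self.index(a), self.index(b)
        if i == j:
            raise ValueError("error variances are always free; nothing to add")
        self.psi_free[i, j] = self.psi_free[j, i] = True
        self.psi_provenance[tuple(sorted((str(a), str(b))))] = provenance

    def remove_psi(self, a: str, b: str) -> None:
        i, j = self.index(a), self.index(b)
        self.psi_free[i, j] = self.psi_free[j, i] = False
        self.psi_provenance.pop(tuple(sorted((str(a), str(b)))), None)

    def copy(self) -> "PathModel":
        out = PathModel(self.variables, self.mean_structure)
        out.beta_free = self.beta_free.copy()
        out.psi_free = self.psi_free.copy()
        out.beta_provenance = dict(self.beta_provenance)
        out.psi_provenance = dict(self.psi_provenance)
        return out

    # -- queries --------------------------------------------------------
    @property
    def p(self) -> int:
        return len(self.variables)

    @property
    def n_free_beta(self) -> int:
        return int(self.beta_free.sum())

    @property
    def n_free_psi(self) -> int:
        return self.p + int(self.psi_free[np.triu_indices(self.p, 1)].sum())

    @property
    def t(self) -> int:
        """Free covariance-structure parameter count (+ means if enabled)."""
        t = self.n_free_beta + self.n_free_psi
        if self.mean_structure:
            t += self.p
        return t

    def edges(self) -> list:
        """Free directed edges as (target, source, provenance) triples."""
        out = []
        for i, j in zip(*np.nonzero(self.beta_free)):
            tgt, src = self.variables[i], self.variables[j]
            out.append((tgt, src, self.beta_provenance.get((tgt, src), "")))
        return out

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (
            f"PathModel(p={self.p}, beta={self.n_free_beta}, "
            f"psi={self.n_free_psi}, mean_structure={self.mean_structure})"
        )


def check_bow_free(m: PathModel) -> list:
    """Pairs with both a free directed edge and a free error covariance."""
    bad = []
    p = m.p
    for i in range(p):
        for j in range(i + 1, p):
            if m.psi_free[i, j] and (m.beta_free[i, j] or m.beta_free[j, i]):
                bad.append((m.variables[i], m.variables[j]))
    return bad


def check_block_recursive(m: PathModel) -> tuple[bool, list]:
    """Strongly connected components of the directed part; pass iff all <= 2."""
    G = nx.DiGraph()
    G.add_nodes_from(range(m.p))
    for i, j in zip(*np.nonzero(m.beta_free)):
        G.add_edge(j, i)  # source -> target
    blocks = [
        {m.variables[i] for i in comp} for comp in nx.strongly_connected_components(G)
    ]
    blocks.sort(key=lambda s: sorted(s))
    ok = all(len(b) <= 2 for b in blocks)
    return ok, blocks


def build_initial_model(g: PathwayGraph, mean_structure: bool = False) -> PathModel:
    """One free path coefficient per directed edge; diagonal-only error covariance.

    Self-loop edges are dropped with a warning, as are bi-directed pathway
    edges (error covariances enter only later, through evidence-gated
    refinement).  Raises :class:`IdentificationError` if the resulting model
    violates the block-recursive criterion or is over-parameterized.
    """
    model = PathModel(sorted(g.nodes), mean_structure=mean_structure)
    for u, v, kind in g.directed_edges:
        if u == v:
            warnings.warn(f"dropping self-loop edge on {u!r}")
            continue
        model.add_beta(v, u, provenance=f"kegg:{kind}")
    if g.bidirected_edges:
        warnings.warn(
            f"ignoring {len(g.bidirected_edges)} bi-directed pathway edge(s); "
            "error covariances are fixed at zero in the initial model"
        )
    bows = check_bow_free(model)
    ok, blocks = check_block_recursive(model)
    if bows or not ok:
        oversized = [b for b in blocks if len(b) > 2]
        raise IdentificationError(
            f"initial model not identified: bow violations {bows}, "
            f"feedback blocks with >2 equations {oversized}"
        )
    max_t = model.p * (model.p + 1) // 2
    if model.n_free_beta + model.n_free_psi > max_t:
        raise IdentificationError(
            f"over-parameterized: t={model.n_free_beta + model.n_free_psi} "
            f"exceeds p(p+1)/2={max_t}"
        )
    return model
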