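"""Synthetic networks and degree sequences with known structure.

Used to calibrate and validate the evaluation pipeline end to end: iid
draws from the discrete tail distributions; Erdős–Rényi graphs (no
scale-free structure); directed preferential attachment and directed vertex
copying (heavy-tailed in-degrees); and a temporal power-law random graph
whose snapshots target iid power-law expected degrees.

Every generator is a pure function of its parameters and the seed: a master
seed spawns independent substreams, so the same spec always reproduces the
same data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .distributions import FAMILIES, sample_alternative, sample_powerlaw
from .simplify import Edge, NetworkDataset, SimpleGraph
from .simplify import DegreeSequence

__all__ = [
    "GeneratorSpec",
    "generate",
    "sample_discrete",
    "gen_erdos_renyi",
    "gen_directed_pa",
    "gen_vertex_copy",
    "gen_temporal_pl",
]

DISCRETE_MODELS = ("powerlaw_iid", "lognormal_iid", "exponential_iid", "cutoff_iid")
GRAPH_MODELS = ("erdos_renyi", "directed_pa", "vertex_copy", "temporal_pl")


@dataclass(frozen=True)
class GeneratorSpec:
    model: str
    n: int
    params: dict = field(default_factory=dict)
    seed: int | None = None

    def __post_init__(self):
        if self.model not in DISCRETE_MODELS + GRAPH_MODELS:
            raise ValueError(f"unknown model {self.model!r}")


def generate(spec: GeneratorSpec):
    """Dispatch a :class:`GeneratorSpec` to the matching generator."""
    p = dict(spec.params)
    if spec.model in DISCRETE_MODELS:
        return sample_discrete(spec.model, p, spec.n, spec.seed)
    fn = {
        "erdos_renyi": gen_erdos_renyi,
        "directed_pa": gen_directed_pa,
        "vertex_copy": gen_vertex_copy,
        "temporal_pl": gen_temporal_pl,
    }[spec.model]
    return fn(spec.n, seed=spec.seed, **p)


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def sample_discrete(model: str, params: dict, n: int, seed=None) -> DegreeSequence:
    """``n`` iid draws from one of the discrete tail distributions."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = _rng(seed)
    params = dict(params)
    k_min = int(params.pop("k_min", 1))
    if model == "powerlaw_iid":
        draws = sample_powerlaw(n, params["alpha"], k_min, rng)
    elif model == "cutoff_iid" and params.get("lam", params.get("lambda", 0.0)) == 0.0:
        draws = sample_powerlaw(n, params["alpha"], k_min, rng)
    else:
        family, p = {
            "lognormal_iid": ("lognormal", ("mu", "sigma")),
            "exponential_iid": ("exponential", ("lam",)),
            "cutoff_iid": ("powerlaw_cutoff", ("alpha", "lam")),
        }[model]
        vals = tuple(params[name] for name in p)
        draws = sample_alternative(n, family, vals, k_min, rng)
    label = ", ".join(f"{k}={v}" for k, v in sorted(params.items()))
    return DegreeSequence(draws, provenance=f"{model}({label}, k_min={k_min}, n={n})")


def gen_erdos_renyi(n: int, p: float, seed=None) -> SimpleGraph:
    """G(n, p): each unordered pair is an edge independently with prob p."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    rng = _rng(seed)
    nodes = frozenset(range(n))
    if p == 0.0 or n < 2:
        return SimpleGraph(nodes, frozenset(), f"erdos_renyi(n={n}, p={p})")
    iu, ju = np.triu_indices(n, k=1)
    keep = rng.random(iu.size) < p
    edges = frozenset(
        frozenset((int(a), int(b))) for a, b in zip(iu[keep], ju[keep])
    )
    return SimpleGraph(nodes, edges, f"erdos_renyi(n={n}, p={p})")


def gen_directed_pa(
    n: int, out_edges_per_node: int = 2, offset: float = 1.0, seed=None
) -> NetworkDataset:
    """Directed preferential attachment.

    Nodes arrive one at a time; each emits ``m = out_edges_per_node``
    directed edges whose targets are picked with probability proportional to
    in-degree plus an additive ``offset`` a.  The asymptotic in-degree
    exponent is ``alpha = 2 + a/m`` (2.5 at the defaults m = 2, a = 1).
    """
    m = int(out_edges_per_node)
    if not n > m >= 1:
        raise ValueError("need n > out_edges_per_node >= 1")
    if offset <= 0:
        raise ValueError("offset must be positive")
    rng = _rng(seed)
    n0 = m + 1
    edges: list[Edge] = []
    # seed clique among the first n0 nodes (directed i -> j, i > j)
    targets: list[int] = []  # one entry per incoming edge: preferential pool
    for i in range(1, n0):
        for j in range(i):
            edges.append(Edge(i, j))
            targets.append(j)
    for v in range(n0, n):
        total_in = len(targets)
        chosen: set[int] = set()
        while len(chosen) < m:
            if rng.random() < total_in / (total_in + offset * v):
                t = targets[rng.integers(len(targets))]
            else:
                t = int(rng.integers(v))
            chosen.add(t)
        for t in sorted(chosen):
            edges.append(Edge(v, t))
            targets.append(t)
    return NetworkDataset(
        f"directed_pa(n={n}, m={m}, offset={offset})",
        edges,
        flags={"directed"},
        nodes=set(range(n)),
    )


def gen_vertex_copy(n: int, copy_prob: float = 0.6, out_degree: int = 2,
                    seed=None) -> NetworkDataset:
    """Directed vertex-copy model.

    Each new node picks an existing prototype uniformly at random and copies
    each of its out-links with probability ``copy_prob``; non-copied links
    are rewired to uniformly random existing nodes.  Copying concentrates
    in-links on already-popular nodes, producing heavy-tailed in-degrees.
    """
    if not 0.0 < copy_prob < 1.0:
        raise ValueError("copy_prob must lie in (0, 1)")
    m = int(out_degree)
    if not n > m >= 1:
        raise ValueError("need n > out_degree >= 1")
    rng = _rng(seed)
    n0 = m + 1
    out_links: list[list[int]] = []
    for i in range(n0):
        out_links.append([j for j in range(n0) if j != i][:m])
    for v in range(n0, n):
        proto = int(rng.integers(v))
        links = []
        for t in out_links[proto]:
            if rng.random() < copy_prob:
                links.append(t)
            else:
                links.append(int(rng.integers(v)))
        out_links.append(links)
    edges = [Edge(u, t) for u, links in enumerate(out_links) for t in links]
    return NetworkDataset(
        f"vertex_copy(n={n}, q={copy_prob}, m={m})",
        edges,
        flags={"directed"},
        nodes=set(range(n)),
    )


def gen_temporal_pl(n: int, snapshots: int = 3, alpha: float = 2.5,
                    k_min: int = 1, seed=None) -> NetworkDataset:
    """Temporal power-law random graph.

    Each snapshot is an independent Chung–Lu-style random graph whose
    expected degrees are iid draws from the discrete power law, so every
    time slice carries a power-law degree sequence; edges are timestamped
    with the snapshot index.
    """
    if snapshots < 2:
        raise ValueError("need at least 2 snapshots")
    if alpha <= 2.0:
        raise ValueError("alpha must exceed 2 for a finite mean")
    rng = _rng(seed)
    edges: list[Edge] = []
    for t in range(snapshots):
        w = sample_powerlaw(n, alpha, k_min, rng).astype(float)
        # cap expected degrees so edge probabilities stay <= 1
        s = w.sum()
        w = np.minimum(w, np.sqrt(s))
        iu, ju = np.triu_indices(n, k=1)
        prob = w[iu] * w[ju] / s
        keep = rng.random(prob.size) < prob
        for a, b in zip(iu[keep], ju[keep]):
            edges.append(Edge(int(a), int(b), timestamp=float(t)))
    return NetworkDataset(
        f"temporal_pl(n={n}, snapshots={snapshots}, alpha={alpha})",
        edges,
        flags={"temporal"},
        nodes=set(range(n)),
    )
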