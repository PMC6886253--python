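"""Undirected PPI network container and metapath (random-walk) generation.

Walks are the training corpus for the CBOW embedder: ``neighbor_size``
bounded uniform random walks are started from every node, each up to
``length`` nodes. Walks over a 1-node component stop immediately (logged).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)


class EdgeListParseError(ValueError):
    """Malformed edge-list line; carries the 1-based line number."""

    def __init__(self, path, lineno: int, line: str):
        super().__init__(f"{path}:{lineno}: expected two IDs, got {line!r}")
        self.lineno = lineno


@dataclass
class PPINetwork:
    """Simple undirected graph: opaque string node IDs, no self-loops."""

    adjacency: dict[str, list[str]] = field(default_factory=dict)

    @property
    def nodes(self) -> list[str]:
        return list(self.adjacency)

    @property
    def edges(self) -> set[frozenset[str]]:
        return {
            frozenset((u, v)) for u, nbrs in self.adjacency.items() for v in nbrs
        }

    def __len__(self) -> int:
        return len(self.adjacency)

    def add_node(self, u: str) -> None:
        self.adjacency.setdefault(u, [])

    def add_edge(self, u: str, v: str) -> bool:
        """Add an undirected edge; returns False for self-loops/duplicates."""
        if u == v:
            return False
        self.add_node(u)
        self.add_node(v)
        if v in self.adjacency[u]:
            return False
        self.adjacency[u].append(v)
        self.adjacency[v].append(u)
        return True

    def neighbors(self, u: str) -> list[str]:
        return self.adjacency[u]

    def degree(self, u: str) -> int:
        return len(self.adjacency[u])

    @classmethod
    def from_pairs(cls, pairs) -> "PPINetwork":
        net = cls()
        for u, v in pairs:
            net.add_edge(u, v)
        return net


def load_edge_list(path) -> tuple[PPINetwork, dict[str, int]]:
    """Parse a two-column TSV/whitespace edge list.

    Self-interactions are removed and duplicate edges collapsed; the
    returned stats dict reports ``self_loops_removed`` and
    ``duplicates_removed`` counts for logging.
    """
    net = PPINetwork()
    stats = {"self_loops_removed": 0, "duplicates_removed": 0, "edges": 0}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise EdgeListParseError(path, lineno, raw.rstrip("\n"))
            u, v = parts
            if u == v:
                stats["self_loops_removed"] += 1
            elif not net.add_edge(u, v):
                stats["duplicates_removed"] += 1
            else:
                stats["edges"] += 1
    if not net.adjacency:
        logger.warning("edge list %s produced an empty network", path)
    return net, stats


@dataclass(frozen=True)
class MetapathConfig:
    """Walk generation parameters (length counts nodes, not edges)."""

    length: int = 10
    neighbor_size: int = 4
    seed: int = 0
    sample_step_candidates: bool = False

    def __post_init__(self) -> None:
        if self.length < 2:
            raise ValueError("walk length must be >= 2")
        if self.neighbor_size < 1:
            raise ValueError("neighbor_size must be >= 1")


def generate_metapaths(net: PPINetwork, cfg: MetapathConfig) -> list[list[str]]:
    """Emit ``neighbor_size`` uniform random walks from every node.

    With ``sample_step_candidates`` (alternative reading of the fanout
    parameter) each step first restricts the candidate neighbours to a
    random subset of size ``neighbor_size`` before choosing uniformly;
    the default treats ``neighbor_size`` purely as walks-per-start-node.
    """
    if not net.adjacency:
        raise ValueError("cannot generate walks over an empty network")
    rng = np.random.default_rng(cfg.seed)
    walks: list[list[str]] = []
    isolated = 0
    for start in net.nodes:
        if net.degree(start) == 0:
            isolated += 1
        for _ in range(cfg.neighbor_size):
            walk = [start]
            while len(walk) < cfg.length:
                nbrs = net.neighbors(walk[-1])
                if not nbrs:
                    break
                if cfg.sample_step_candidates and len(nbrs) > cfg.neighbor_size:
                    idx = rng.choice(len(nbrs), size=cfg.neighbor_size, replace=False)
                    nbrs = [nbrs[i] for i in idx]
                walk.append(nbrs[rng.integers(len(nbrs))])
            walks.append(walk)
    if isolated:
        logger.warning("%d isolated node(s): emitted length-1 walks", isolated)
    return walks


def context_pairs(
    paths: list[list[str]], window: int = 1
) -> list[tuple[str, list[str]]]:
    """(center, context-nodes) records for CBOW training, clipped at path ends."""
    if window < 1:
        raise ValueError("window must be >= 1")
    out: list[tuple[str, list[str]]] = []
    for path in paths:
        if len(path) < 2:
            continue
        for c, center in enumerate(path):
            ctx = path[max(0, c - window): c] + path[c + 1: c + 1 + window]
            out.append((center, ctx))
    return out


def write_walks(path, walks: list[list[str]]) -> None:
    """One walk per line, space-separated node IDs (word2vec corpus dialect)."""
    with open(path, "w") as fh:
        for walk in walks:
            fh.write(" ".join(walk) + "\n")


def read_walks(path) -> list[list[str]]:
    with open(path) as fh:
        return [line.split() for line in fh if line.strip()]
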