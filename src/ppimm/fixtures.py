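"""Synthetic inputs for exercising the whole pipeline offline.

Generates random protein sequences with per-family residue-composition
bias, planted-partition interaction graphs whose blocks double as family
and (disjoint) location labels, and a bundled end-to-end fixture whose
positives are the sampled edges. Community membership therefore carries
both the interaction signal and the family signal, so the supervised
heads have learnable structure without any real data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .dataset import LocationTable
from .fusion import FamilyExample, PairExample, write_families, write_pairs
from .ppi_graph import PPINetwork
from .seq_features import ALPHABET, ProteinRecord


@dataclass(frozen=True)
class FixtureSpec:
    n_proteins: int = 120
    length_range: tuple[int, int] = (60, 200)
    n_blocks: int = 2
    p_in: float = 0.3
    p_out: float = 0.02
    n_families: int | None = None  # defaults to n_blocks
    composition_shift: float = 0.1
    n_locations: int | None = None  # defaults to n_blocks
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.p_out < self.p_in <= 1:
            raise ValueError("need 0 <= p_out < p_in <= 1")
        if self.length_range[0] < 31:
            raise ValueError("minimum length must be >= 31 (QSO nlag precondition)")
        if self.n_proteins < 2 * self.n_blocks:
            raise ValueError("need at least 2 proteins per block")


def _block_of(spec: FixtureSpec, i: int) -> int:
    # contiguous blocks of (almost) equal size
    per = spec.n_proteins // spec.n_blocks
    return min(i // per, spec.n_blocks - 1)


def protein_ids(spec: FixtureSpec) -> list[str]:
    width = len(str(spec.n_proteins - 1))
    return [f"P{i:0{width}d}" for i in range(spec.n_proteins)]


def family_of(spec: FixtureSpec, i: int) -> str:
    n_fam = spec.n_families or spec.n_blocks
    if n_fam == spec.n_blocks:
        return f"FAM{_block_of(spec, i)}"
    # refinement: split each block into n_families // n_blocks subfamilies
    per_block = max(1, n_fam // spec.n_blocks)
    return f"FAM{_block_of(spec, i)}.{i % per_block}"


def make_sequences(spec: FixtureSpec) -> list[ProteinRecord]:
    """Random sequences, residue frequencies biased per family."""
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    ids = protein_ids(spec)
    families = sorted({family_of(spec, i) for i in range(spec.n_proteins)})
    fam_freqs: dict[str, np.ndarray] = {}
    for k, fam in enumerate(families):
        freqs = np.full(20, 1.0 / 20)
        if spec.composition_shift > 0:
            # boost a family-specific residue subset, then renormalize
            boosted = rng.permutation(20)[:5]
            freqs[boosted] += spec.composition_shift
            freqs /= freqs.sum()
        fam_freqs[fam] = freqs
    lo, hi = spec.length_range
    records = []
    letters = np.array(list(ALPHABET))
    for i, pid in enumerate(ids):
        length = int(rng.integers(lo, hi + 1))
        seq = "".join(rng.choice(letters, size=length, p=fam_freqs[family_of(spec, i)]))
        records.append(ProteinRecord(pid, seq))
    return records


def make_network(
    spec: FixtureSpec,
) -> tuple[PPINetwork, LocationTable, list[FamilyExample]]:
    """Planted-partition graph + block-disjoint locations + family labels."""
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 2]))
    ids = protein_ids(spec)
    blocks = [_block_of(spec, i) for i in range(spec.n_proteins)]
    net = PPINetwork()
    for pid in ids:
        net.add_node(pid)
    for i in range(spec.n_proteins):
        for j in range(i + 1, spec.n_proteins):
            p = spec.p_in if blocks[i] == blocks[j] else spec.p_out
            if p > 0 and rng.random() < p:
                net.add_edge(ids[i], ids[j])
    n_loc = spec.n_locations or spec.n_blocks
    locs = LocationTable(
        {ids[i]: {f"LOC{blocks[i] % n_loc}"} for i in range(spec.n_proteins)}
    )
    families = [FamilyExample(ids[i], family_of(spec, i)) for i in range(spec.n_proteins)]
    return net, locs, families


@dataclass
class FixtureBundle:
    spec: FixtureSpec
    records: list[ProteinRecord]
    network: PPINetwork
    locations: LocationTable
    families: list[FamilyExample]
    positives: list[PairExample] = field(default_factory=list)

    def block_of(self, pid: str) -> int:
        return _block_of(self.spec, protein_ids(self.spec).index(pid))

    def write(self, out_dir) -> dict[str, Path]:
        """Write every artifact in the dialects the pipeline reads."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": out / "proteins.fasta",
            "edges": out / "edges.tsv",
            "locations": out / "locations.tsv",
            "families": out / "families.tsv",
            "positives": out / "positive_pairs.tsv",
        }
        with open(paths["fasta"], "w") as fh:
            for rec in self.records:
                fh.write(f">{rec.id}\n")
                for lo in range(0, len(rec.sequence), 60):
                    fh.write(rec.sequence[lo: lo + 60] + "\n")
        with open(paths["edges"], "w") as fh:
            for edge in sorted(tuple(sorted(e)) for e in self.network.edges):
                fh.write(f"{edge[0]}\t{edge[1]}\n")
        self.locations.write(paths["locations"])
        write_families(paths["families"], self.families)
        write_pairs(paths["positives"], self.positives)
        return paths


def make_end_to_end_fixture(spec: FixtureSpec | None = None) -> FixtureBundle:
    """Compose sequences + network; positives are the sampled edges."""
    spec = spec or FixtureSpec()
    records = make_sequences(spec)
    net, locs, families = make_network(spec)
    positives = [
        PairExample(a, b, 1)
        for a, b in sorted(tuple(sorted(e)) for e in net.edges)
    ]
    return FixtureBundle(spec, records, net, locs, families, positives)
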