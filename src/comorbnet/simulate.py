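"""Synthetic interactomes, disease gene sets, and pathway collections.

The generator emulates the statistical structure the pipeline assumes:
an undirected simple background interactome, two partially overlapping
disease gene sets, "candidate" genes wired to a controlled number of
shared genes (so guilt-by-association recovery has a constructive ground
truth), and pathway collections whose planted members are drawn
preferentially from a disease set at a controlled enrichment fraction.

Everything is reproducible from a single integer seed driving one numpy
Generator; written files are byte-identical across runs.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import networkx as nx
import numpy as np

from .enrichment import Pathway, PathwayCollection, write_gmt
from .genesets import GeneRecord, GeneSet, write_gene_list
from .network import Interactome, write_edge_list


class InfeasibleConfigError(Exception):
    """The requested configuration cannot be generated."""


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one synthetic dataset.

    Defaults match the benchmark conditions used throughout the test
    suite: a 5,000-gene universe with a sparse background interactome
    (mean degree 6), two disease sets of 100 genes sharing 30, 20 planted
    candidate genes each wired to 8 shared genes, and a 50-pathway
    collection with 4 pathways per disease drawing 80% of their members
    from that disease's gene set.
    """

    seed: int = 0
    n_genes: int = 5000
    edge_model: str = "erdos_renyi"  # or "preferential_attachment"
    mean_degree: float = 6.0  # erdos_renyi: expected degree
    pa_attach: int = 3  # preferential_attachment: edges per new node
    n_a: int = 100
    n_b: int = 100
    n_shared: int = 30
    n_candidates: int = 20
    candidate_wiring: int = 8
    n_pathways: int = 50
    pathway_size_range: tuple[int, int] = (10, 60)
    n_enriched_per_disease: int = 4
    enrichment_fraction: float = 0.8

    def validate(self) -> None:
        if self.n_genes < 2:
            raise InfeasibleConfigError("need at least two genes")
        if self.edge_model not in ("erdos_renyi", "preferential_attachment"):
            raise InfeasibleConfigError(f"unknown edge model {self.edge_model!r}")
        if self.n_shared > min(self.n_a, self.n_b):
            raise InfeasibleConfigError("n_shared exceeds a disease-set size")
        if self.candidate_wiring > self.n_shared:
            raise InfeasibleConfigError("candidate_wiring exceeds n_shared")
        if self.n_a + self.n_b - self.n_shared + self.n_candidates > self.n_genes:
            raise InfeasibleConfigError("disease sets plus candidates exceed the universe")
        lo, hi = self.pathway_size_range
        if not (1 <= lo <= hi <= self.n_genes):
            raise InfeasibleConfigError("pathway sizes must fit inside the gene universe")
        if not (0.0 < self.enrichment_fraction <= 1.0):
            raise InfeasibleConfigError("enrichment_fraction must lie in (0, 1]")
        if 2 * self.n_enriched_per_disease > self.n_pathways:
            raise InfeasibleConfigError("more planted than total pathways")


@dataclass
class SyntheticTruth:
    planted_candidates: frozenset[int] = frozenset()
    planted_enriched_a: frozenset[str] = frozenset()
    planted_enriched_b: frozenset[str] = frozenset()


@dataclass
class SyntheticDataset:
    config: SyntheticConfig
    interactome: Interactome
    genes_a: GeneSet
    genes_b: GeneSet
    collection: PathwayCollection
    truth: SyntheticTruth = field(default_factory=SyntheticTruth)

    @property
    def shared_gene_ids(self) -> frozenset[int]:
        return self.genes_a.gene_ids & self.genes_b.gene_ids


def _background_edges(config: SyntheticConfig, rng: np.random.Generator) -> set[tuple[int, int]]:
    n = config.n_genes
    if config.edge_model == "preferential_attachment":
        nx_seed = int(rng.integers(0, 2**31 - 1))
        graph = nx.barabasi_albert_graph(n, config.pa_attach, seed=nx_seed)
        return {(min(u, v) + 1, max(u, v) + 1) for u, v in graph.edges()}
    # Erdos-Renyi G(n, m) with m = mean_degree * n / 2, sampled directly
    m = int(round(config.mean_degree * n / 2.0))
    m = min(m, n * (n - 1) // 2)
    edges: set[tuple[int, int]] = set()
    while len(edges) < m:
        need = m - len(edges)
        us = rng.integers(1, n + 1, size=2 * need + 8)
        vs = rng.integers(1, n + 1, size=2 * need + 8)
        for u, v in zip(us, vs):
            if u == v:
                continue
            edges.add((min(u, v), max(u, v)))
            if len(edges) == m:
                break
    return {(int(u), int(v)) for u, v in edges}


def _gene_set(label: str, ids, source: str) -> GeneSet:
    return GeneSet(
        label,
        [
            GeneRecord(int(g), symbol=f"G{int(g):05d}", sources=frozenset({source}))
            for g in ids
        ],
    )


def generate(config: SyntheticConfig) -> SyntheticDataset:
    """Generate a full dataset with planted ground truth.

    Construction order (one RNG stream, so fully seed-reproducible):
    background graph; shared genes sampled first, then disease-exclusive
    genes, then candidate genes from the remainder; candidate->shared
    wiring edges added on top of the background; planted then null
    pathways.  The planted-candidate guarantee is constructive: each
    candidate receives exactly ``candidate_wiring`` distinct shared-gene
    neighbors, and candidates are never disease genes.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    edges = _background_edges(config, rng)

    universe = np.arange(1, config.n_genes + 1)
    perm = rng.permutation(universe)
    pos = 0
    shared = sorted(int(g) for g in perm[pos : pos + config.n_shared]); pos += config.n_shared
    a_only = sorted(int(g) for g in perm[pos : pos + config.n_a - config.n_shared]); pos += config.n_a - config.n_shared
    b_only = sorted(int(g) for g in perm[pos : pos + config.n_b - config.n_shared]); pos += config.n_b - config.n_shared
    candidates = sorted(int(g) for g in perm[pos : pos + config.n_candidates]); pos += config.n_candidates

    shared_arr = np.array(shared)
    for cand in candidates:
        targets = rng.choice(shared_arr, size=config.candidate_wiring, replace=False)
        for t in targets:
            t = int(t)
            edges.add((min(cand, t), max(cand, t)))

    genes_a = _gene_set("disease_a", sorted(a_only + shared), "synthetic")
    genes_b = _gene_set("disease_b", sorted(b_only + shared), "synthetic")

    set_a = np.array(sorted(a_only + shared))
    set_b = np.array(sorted(b_only + shared))
    lo, hi = config.pathway_size_range
    pathways: list[Pathway] = []
    planted_a: list[str] = []
    planted_b: list[str] = []
    n_planted = config.n_enriched_per_disease
    for idx in range(config.n_pathways):
        size = int(rng.integers(lo, hi + 1))
        pid = f"PW{idx:04d}"
        if idx < n_planted or n_planted <= idx < 2 * n_planted:
            disease_pool = set_a if idx < n_planted else set_b
            n_from_disease = min(math.ceil(config.enrichment_fraction * size),
                                 len(disease_pool), size)
            members = set(
                int(g) for g in rng.choice(disease_pool, size=n_from_disease, replace=False)
            )
            rest_pool = np.setdiff1d(universe, np.fromiter(members, dtype=int))
            n_rest = size - len(members)
            if n_rest > 0:
                members |= {
                    int(g) for g in rng.choice(rest_pool, size=n_rest, replace=False)
                }
            (planted_a if idx < n_planted else planted_b).append(pid)
            name = f"planted_{'a' if idx < n_planted else 'b'}_{idx:04d}"
        else:
            members = {int(g) for g in rng.choice(universe, size=size, replace=False)}
            name = f"null_{idx:04d}"
        pathways.append(Pathway(pid, name, frozenset(members)))

    collection = PathwayCollection(pathways, frozenset(int(g) for g in universe))
    return SyntheticDataset(
        config=config,
        interactome=Interactome.from_edges(edges),
        genes_a=genes_a,
        genes_b=genes_b,
        collection=collection,
        truth=SyntheticTruth(
            planted_candidates=frozenset(candidates),
            planted_enriched_a=frozenset(planted_a),
            planted_enriched_b=frozenset(planted_b),
        ),
    )


def rewire(net: Interactome, rate: float, seed: int) -> Interactome:
    """Replace ``round(rate * |edges|)`` edges with random new pairs.

    Removed edges are chosen uniformly; replacements are random
    non-self, non-duplicate pairs over the node set, so the edge count is
    conserved exactly.  The degree sequence is NOT preserved — this is a
    crude noise model, not a degree-preserving shuffle.
    """
    if not (0.0 <= rate <= 1.0):
        raise ValueError(f"rate must lie in [0, 1], got {rate}")
    if rate == 0.0 or not net.edges:
        return net
    rng = np.random.default_rng(seed)
    edges = sorted(net.edges)
    nodes = sorted(net.nodes)
    n_replace = int(round(rate * len(edges)))
    if n_replace == 0:
        return net
    drop_idx = set(rng.choice(len(edges), size=n_replace, replace=False).tolist())
    kept = {e for i, e in enumerate(edges) if i not in drop_idx}
    node_arr = np.array(nodes)
    target = len(edges)
    while len(kept) < target:
        need = target - len(kept)
        us = node_arr[rng.integers(0, len(node_arr), size=2 * need + 8)]
        vs = node_arr[rng.integers(0, len(node_arr), size=2 * need + 8)]
        for u, v in zip(us, vs):
            if u == v:
                continue
            kept.add((int(min(u, v)), int(max(u, v))))
            if len(kept) == target:
                break
    return Interactome(frozenset(kept))


def write_dataset(dataset: SyntheticDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write the dataset in the formats the real pipeline reads.

    Produces ``genes_a.tsv``, ``genes_b.tsv``, ``pathways.gmt``,
    ``ppin.tsv``, and ``truth.json`` (planted labels + config echo).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "genes_a": out / "genes_a.tsv",
        "genes_b": out / "genes_b.tsv",
        "gmt": out / "pathways.gmt",
        "ppin": out / "ppin.tsv",
        "truth": out / "truth.json",
    }
    write_gene_list(dataset.genes_a, paths["genes_a"])
    write_gene_list(dataset.genes_b, paths["genes_b"])
    write_gmt(dataset.collection, paths["gmt"])
    write_edge_list(dataset.interactome, paths["ppin"])
    truth = {
        "planted_candidates": sorted(dataset.truth.planted_candidates),
        "planted_enriched_a": sorted(dataset.truth.planted_enriched_a),
        "planted_enriched_b": sorted(dataset.truth.planted_enriched_b),
        "config": asdict(dataset.config),
    }
    paths["truth"].write_text(json.dumps(truth, indent=2, sort_keys=True) + "\n")
    return paths


def load_truth(path: str | Path) -> SyntheticTruth:
    data = json.loads(Path(path).read_text())
    return SyntheticTruth(
        planted_candidates=frozenset(data["planted_candidates"]),
        planted_enriched_a=frozenset(data["planted_enriched_a"]),
        planted_enriched_b=frozenset(data["planted_enriched_b"]),
    )
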