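"""Over-representation analysis (ORA) against a pathway collection.

The statistic is the classical one-sided hypergeometric tail: with a
background universe of ``N`` genes, a pathway of ``K`` members, and a
query of ``n`` genes of which ``k`` fall in the pathway, the p-value is
``P(X >= k)`` for ``X ~ Hypergeometric(N, K, n)``.  p-values are adjusted
across the collection with the Benjamini–Hochberg step-up procedure and a
pathway is called significant when its FDR falls below ``alpha``
(0.05 by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .genesets import GeneSet

DEFAULT_ALPHA = 0.05


class GMTError(Exception):
    """Malformed or empty GMT file."""


class EmptyQueryError(Exception):
    """No query gene remains after restriction to the background."""


class MismatchedCollectionsError(Exception):
    """The two result lists were not computed on the same collection."""


@dataclass(frozen=True)
class Pathway:
    pathway_id: str
    name: str
    members: frozenset[int]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"pathway {self.pathway_id!r} has no members")
        object.__setattr__(self, "members", frozenset(self.members))


@dataclass
class PathwayCollection:
    """Named gene sets plus the background universe they live in.

    The background defaults to the union of all members when not given
    explicitly.
    """

    pathways: list[Pathway] = field(default_factory=list)
    background: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        ids = [p.pathway_id for p in self.pathways]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate pathway_id in collection")
        if not self.background:
            universe: set[int] = set()
            for p in self.pathways:
                universe |= p.members
            self.background = frozenset(universe)
        else:
            self.background = frozenset(self.background)
        for p in self.pathways:
            if not p.members <= self.background:
                raise ValueError(
                    f"pathway {p.pathway_id!r} has members outside the background"
                )

    def __len__(self) -> int:
        return len(self.pathways)

    def __iter__(self):
        return iter(self.pathways)

    def get(self, pathway_id: str) -> Pathway | None:
        for p in self.pathways:
            if p.pathway_id == pathway_id:
                return p
        return None


@dataclass(frozen=True)
class EnrichmentResult:
    """Per-pathway overlap counts, raw p-value, BH-FDR, significance call."""

    pathway_id: str
    name: str
    k: int  # query genes in pathway
    K: int  # pathway size
    n: int  # query size (restricted to background)
    N: int  # background size
    p_value: float
    fdr: float
    significant: bool


@dataclass(frozen=True)
class PathwayClassification:
    """Pathways significant in both diseases vs in exactly one."""

    shared: frozenset[str]
    a_specific: frozenset[str]
    b_specific: frozenset[str]


def read_gmt(path: str | Path, background: Iterable[int] | None = None) -> PathwayCollection:
    """Parse a Broad-dialect GMT file: name, description, then members.

    Duplicate members within a line are collapsed; a line with fewer than
    three non-empty fields raises :class:`GMTError`.
    """
    path = Path(path)
    pathways = []
    try:
        lines = path.read_text().splitlines()
    except OSError as exc:
        raise GMTError(f"cannot read GMT file {path}: {exc}") from exc
    for lineno, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        members = [f for f in fields[2:] if f.strip()]
        if len(fields) < 3 or not members:
            raise GMTError(f"{path}:{lineno}: GMT line needs name, description, members")
        try:
            member_ids = frozenset(int(m) for m in members)
        except ValueError as exc:
            raise GMTError(f"{path}:{lineno}: non-integer gene member") from exc
        pathways.append(Pathway(fields[0], fields[1], member_ids))
    if not pathways:
        raise GMTError(f"GMT file {path} contains no gene sets")
    return PathwayCollection(pathways, frozenset(background or ()))


def write_gmt(collection: PathwayCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in collection.pathways:
            members = "\t".join(str(g) for g in sorted(p.members))
            fh.write(f"{p.pathway_id}\t{p.name}\t{members}\n")


def hypergeom_pvalue(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail hypergeometric probability ``P(X >= k)``.

    Over-representation only: the probability of drawing at least ``k``
    pathway members in ``n`` draws without replacement from a universe of
    ``N`` genes containing ``K`` members.  ``k = 0`` returns exactly 1.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"need 0 <= K, n <= N; got K={K}, n={n}, N={N}")
    if not (0 <= k <= min(K, n)):
        raise ValueError(f"need 0 <= k <= min(K, n); got k={k}, K={K}, n={n}")
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini–Hochberg step-up adjusted values, in the input order.

    Each adjusted value is ``min_{j >= rank}(m * p_(j) / j)`` capped at 1.
    """
    ps = list(p_values)
    if not ps:
        return []
    for p in ps:
        if not (0.0 < p <= 1.0):
            raise ValueError(f"p-values must lie in (0, 1], got {p}")
    _, adjusted, _, _ = multipletests(ps, method="fdr_bh")
    return [float(q) for q in adjusted]


def run_enrichment(
    query: GeneSet | Iterable[int],
    collection: PathwayCollection,
    alpha: float = DEFAULT_ALPHA,
) -> list[EnrichmentResult]:
    """ORA of a query gene set against every pathway in the collection.

    Query genes outside the background are dropped before testing; BH
    adjustment runs across the whole collection.  Results are sorted by
    (fdr, pathway_id).
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    query_ids = query.gene_ids if isinstance(query, GeneSet) else frozenset(query)
    restricted = query_ids & collection.background
    if not restricted:
        raise EmptyQueryError("no query gene lies in the collection background")
    N = len(collection.background)
    n = len(restricted)
    raw = []
    for p in collection.pathways:
        k = len(restricted & p.members)
        raw.append((p, k, hypergeom_pvalue(k, len(p.members), n, N)))
    fdrs = bh_adjust([pv for _, _, pv in raw])
    results = [
        EnrichmentResult(
            pathway_id=p.pathway_id,
            name=p.name,
            k=k,
            K=len(p.members),
            n=n,
            N=N,
            p_value=pv,
            fdr=q,
            significant=q < alpha,
        )
        for (p, k, pv), q in zip(raw, fdrs)
    ]
    return sorted(results, key=lambda r: (r.fdr, r.pathway_id))


def classify_pathways(
    results_a: Sequence[EnrichmentResult],
    results_b: Sequence[EnrichmentResult],
    alpha: float = DEFAULT_ALPHA,
) -> PathwayClassification:
    """Split pathways into shared vs disease-specific significance.

    ``shared`` holds pathways significant in both diseases at the given
    FDR; the *-specific sets those significant in exactly one.
    """
    ids_a = {r.pathway_id for r in results_a}
    ids_b = {r.pathway_id for r in results_b}
    if ids_a != ids_b:
        raise MismatchedCollectionsError(
            "result lists cover different pathway collections"
        )
    sig_a = {r.pathway_id for r in results_a if r.fdr < alpha}
    sig_b = {r.pathway_id for r in results_b if r.fdr < alpha}
    return PathwayClassification(
        shared=frozenset(sig_a & sig_b),
        a_specific=frozenset(sig_a - sig_b),
        b_specific=frozenset(sig_b - sig_a),
    )


def results_to_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "pathway_id": r.pathway_id,
                "name": r.name,
                "k": r.k,
                "K": r.K,
                "n": r.n,
                "N": r.N,
                "p_value": r.p_value,
                "fdr": r.fdr,
                "significant": r.significant,
            }
            for r in results
        ],
        columns=["pathway_id", "name", "k", "K", "n", "N", "p_value", "fdr", "significant"],
    )


def write_enrichment(results: Sequence[EnrichmentResult], path: str | Path) -> None:
    results_to_frame(results).to_csv(path, sep="\t", index=False)
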