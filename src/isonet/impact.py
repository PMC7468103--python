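"""Pathogenic-impact scoring of cancer-specific transcript switches.

Four complementary read-outs:

* **Disruption mapping** — every physical interaction the switched
  isoform loses, per sample, plus the percentage of the canonical
  protein's interactions that are lost.
* **Network density score (NDS)** — the degree of a protein plus the
  depth-decayed, score-weighted degrees of its neighbourhood up to three
  hops; ranked over all proteins to a relative position in [0, 1].
* **Census proximity** — breadth-first-search hop distance from a
  protein to the nearest cancer-census gene, with a matched random
  control (expressed, multi-isoform proteins) and a rank-sum comparison.
* **Enrichment** — hypergeometric gene-set enrichment of the connected
  components of each sample's disrupted-edge subgraph, against the
  isoform-network proteins as the background universe.
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from isonet.io import ExpressionMatrix, InteractionEdge
from isonet.dominance import CmdtCall
from isonet.network import IsoformInteractionNetwork

logger = logging.getLogger(__name__)

UNREACHABLE = -1  # sentinel hop distance for proteins with no path to the census


@dataclass(frozen=True)
class DisruptionRecord:
    """One interaction lost in one sample, attributed to one cMDT."""

    sample_id: str
    transcript_id: str
    gene_id: str
    partner_protein: str
    combined_score: float


@dataclass(frozen=True)
class NdsEntry:
    protein_id: str
    nds: float
    relative_rank: float


@dataclass(frozen=True)
class ProximityRecord:
    protein_id: str
    nearest_census_gene: str | None
    distance: int


@dataclass(frozen=True)
class EnrichmentResult:
    sample_id: str
    component_id: int
    term_id: str
    overlap: int
    component_size: int
    term_size: int
    universe_size: int
    p_value: float
    q_value: float


# ---------------------------------------------------------------------------
# disruption mapping
# ---------------------------------------------------------------------------


def map_disruptions(
    calls: list[CmdtCall],
    network: IsoformInteractionNetwork,
    transcript_to_protein: dict[str, str],
) -> tuple[list[DisruptionRecord], pd.DataFrame]:
    """Attribute lost interactions to cMDT calls, per sample.

    Returns one record per (sample, cMDT, lost edge) and a per-call
    summary with the percentage of the canonical protein's physical
    interactions lost; calls whose gene has no physical edge in the
    network are summarised as ``no PPI data`` (percent lost is NA).
    """
    by_isoform: dict[str, list] = {}
    for status in network.statuses:
        by_isoform.setdefault(status.isoform_id, []).append(status)

    records: list[DisruptionRecord] = []
    summary_rows = []
    for call in calls:
        isoform = transcript_to_protein.get(call.transcript_id)
        statuses = by_isoform.get(isoform, []) if isoform else []
        if not statuses:
            summary_rows.append(
                {
                    "sample_id": call.sample_id,
                    "transcript_id": call.transcript_id,
                    "gene_id": call.gene_id,
                    "n_lost": 0,
                    "n_persists": 0,
                    "percent_lost": np.nan,
                    "ppi_data": False,
                }
            )
            continue
        lost = [s for s in statuses if s.status == "lost"]
        for status in lost:
            records.append(
                DisruptionRecord(
                    sample_id=call.sample_id,
                    transcript_id=call.transcript_id,
                    gene_id=call.gene_id,
                    partner_protein=status.partner_protein,
                    combined_score=status.combined_score,
                )
            )
        summary_rows.append(
            {
                "sample_id": call.sample_id,
                "transcript_id": call.transcript_id,
                "gene_id": call.gene_id,
                "n_lost": len(lost),
                "n_persists": len(statuses) - len(lost),
                "percent_lost": 100.0 * len(lost) / len(statuses),
                "ppi_data": True,
            }
        )
    summary = pd.DataFrame(
        summary_rows,
        columns=[
            "sample_id",
            "transcript_id",
            "gene_id",
            "n_lost",
            "n_persists",
            "percent_lost",
            "ppi_data",
        ],
    )
    return records, summary


def disruption_summary(
    per_sample_counts: pd.Series | dict[str, int], cohort_size: int | None = None
) -> dict[str, float]:
    """Cohort-level disruption totals and mean per sample.

    ``per_sample_counts`` maps sample id -> number of disrupted
    interactions; samples without disruptions may be absent, in which
    case ``cohort_size`` supplies the true denominator.
    """
    counts = pd.Series(per_sample_counts, dtype=float)
    n = int(cohort_size) if cohort_size is not None else int(len(counts))
    if n <= 0:
        raise ValueError("cohort size must be positive")
    total = float(counts.sum())
    return {
        "total_disrupted": total,
        "n_samples": n,
        "mean_per_sample": total / n,
    }


# ---------------------------------------------------------------------------
# network density score
# ---------------------------------------------------------------------------


def interaction_graph(edges: list[InteractionEdge]) -> nx.Graph:
    """Undirected scored graph over all (not only physical) edges."""
    graph = nx.Graph()
    for edge in edges:
        graph.add_edge(edge.protein_a, edge.protein_b, score=edge.combined_score)
    return graph


def network_density_score(
    graph: nx.Graph, protein_id: str, max_depth: int = 3, decay_base: float = 2.0
) -> float:
    """Degree of a protein plus decayed, score-weighted neighbourhood degrees.

    A breadth-first traversal visits every node once, at its shortest
    depth ``s`` (up to ``max_depth``). A node ``b`` found at depth ``s``
    through BFS parent ``p`` contributes ``decay_base**-s * degree(b) *
    score(b, p)``; when several parents offer the same depth the
    lexicographically smallest parent id is used, making the score
    deterministic. Isolated proteins score 0.
    """
    if protein_id not in graph:
        raise KeyError(f"unknown protein {protein_id!r}")
    total = float(graph.degree(protein_id))
    visited = {protein_id}
    frontier = [protein_id]
    for depth in range(1, max_depth + 1):
        # collect each next-layer node with its smallest eligible parent
        parents: dict[str, str] = {}
        for node in frontier:
            for neighbor in graph.neighbors(node):
                if neighbor in visited:
                    continue
                if neighbor not in parents or node < parents[neighbor]:
                    parents[neighbor] = node
        if not parents:
            break
        weight = decay_base ** (-depth)
        for node, parent in parents.items():
            total += weight * graph.degree(node) * graph[node][parent]["score"]
        visited.update(parents)
        frontier = list(parents)
    return total


def rank_nds(nds_values: dict[str, float]) -> list[NdsEntry]:
    """Rank proteins by NDS to relative positions in [0, 1].

    Ascending order; position ``i`` of ``N`` maps to ``i / (N - 1)``;
    tied scores share the mean of their positions.
    """
    if len(nds_values) < 2:
        raise ValueError("need at least two proteins to rank")
    proteins = sorted(nds_values)
    values = np.array([nds_values[p] for p in proteins], dtype=float)
    ranks = (stats.rankdata(values, method="average") - 1.0) / (len(values) - 1.0)
    return [
        NdsEntry(protein_id=p, nds=float(v), relative_rank=float(r))
        for p, v, r in zip(proteins, values, ranks)
    ]


# ---------------------------------------------------------------------------
# census proximity
# ---------------------------------------------------------------------------


def census_proximity(
    graph: nx.Graph, queries, census: set[str]
) -> list[ProximityRecord]:
    """Hop distance from each query protein to the nearest census protein.

    Multi-source BFS from all census proteins present in the graph;
    queries in the census have distance 0, queries with no path (or
    absent from the graph when they are not census members) get the
    ``UNREACHABLE`` sentinel. The nearest census protein reached first
    (ties broken by BFS order from sorted sources) is reported.
    """
    if not census:
        raise ValueError("empty census set")
    sources = sorted(c for c in census if c in graph)
    dist: dict[str, int] = {}
    origin: dict[str, str] = {}
    queue: deque[str] = deque()
    for s in sources:
        dist[s] = 0
        origin[s] = s
        queue.append(s)
    while queue:
        node = queue.popleft()
        for neighbor in graph.neighbors(node):
            if neighbor not in dist:
                dist[neighbor] = dist[node] + 1
                origin[neighbor] = origin[node]
                queue.append(neighbor)
    records = []
    for query in queries:
        if query in census:
            records.append(ProximityRecord(query, query, 0))
        elif query in dist:
            records.append(ProximityRecord(query, origin[query], dist[query]))
        else:
            records.append(ProximityRecord(query, None, UNREACHABLE))
    return records


def proximity_control(
    matrix: ExpressionMatrix,
    graph: nx.Graph,
    census: set[str],
    query_proteins,
    n_draws: int,
    seed: int,
    min_tpm: float = 2.0,
) -> dict:
    """Compare query-to-census distances against an expression-matched control.

    Controls are drawn uniformly (with replacement) among proteins that
    are expressed at >= ``min_tpm`` TPM in at least one sample of the
    cohort matrix and whose gene has at least two annotated isoforms.
    Unreachable proteins are excluded from both distributions before the
    two-sided rank-sum comparison.
    """
    if n_draws <= 0:
        raise ValueError("n_draws must be positive")
    # eligibility: protein product of a multi-isoform gene with expression
    protein_to_transcript = {
        p: t for t, p in matrix.transcript_to_protein.items()
    }
    eligible = []
    for protein, transcript in sorted(protein_to_transcript.items()):
        if protein not in graph:
            continue
        gene = matrix.transcript_to_gene[transcript]
        if len(matrix.transcripts_of(gene)) < 2:
            continue
        if float(matrix.tpm.loc[transcript].max()) >= min_tpm:
            eligible.append(protein)
    if not eligible:
        raise ValueError("no eligible control proteins")
    rng = np.random.default_rng(seed)
    controls = [eligible[i] for i in rng.integers(0, len(eligible), size=n_draws)]

    query_dist = [
        r.distance for r in census_proximity(graph, query_proteins, census)
        if r.distance != UNREACHABLE
    ]
    control_dist = [
        r.distance for r in census_proximity(graph, controls, census)
        if r.distance != UNREACHABLE
    ]
    if query_dist and control_dist:
        p = float(
            stats.mannwhitneyu(query_dist, control_dist, alternative="two-sided").pvalue
        )
    else:
        p = float("nan")
    return {
        "query_distances": query_dist,
        "control_distances": control_dist,
        "p_value": p,
        "n_eligible": len(eligible),
    }


# ---------------------------------------------------------------------------
# enrichment
# ---------------------------------------------------------------------------


def enrich_components(
    records: list[DisruptionRecord],
    gene_sets: dict[str, set[str]],
    universe: set[str],
    transcript_to_protein: dict[str, str],
) -> list[EnrichmentResult]:
    """Hypergeometric term enrichment per disrupted-edge component.

    The disrupted edges of one sample form a graph whose connected
    components are the tested subnetworks. For each component and term,
    the upper-tail hypergeometric p-value uses the isoform-network
    proteins as the universe; q-values are Benjamini-Hochberg within the
    component, and only the most significant term per component is kept
    (ties resolved to the lexicographically smallest term id).
    """
    if not records:
        raise ValueError("no disruption records")
    samples = sorted({r.sample_id for r in records})
    universe = set(universe)
    m_universe = len(universe)
    term_members = {
        term: members & universe for term, members in gene_sets.items()
    }

    results: list[EnrichmentResult] = []
    for sample_id in samples:
        graph = nx.Graph()
        for r in records:
            if r.sample_id != sample_id:
                continue
            own = transcript_to_protein.get(r.transcript_id, r.transcript_id)
            graph.add_edge(own, r.partner_protein)
        for component_id, component in enumerate(
            sorted(nx.connected_components(graph), key=lambda c: sorted(c)[0])
        ):
            annotated = component & universe
            if not annotated:
                logger.info(
                    "component %d of sample %s has no annotated protein; skipped",
                    component_id,
                    sample_id,
                )
                continue
            n_draws = len(annotated)
            term_rows = []
            for term in sorted(term_members):
                members = term_members[term]
                if not members:
                    continue
                overlap = len(annotated & members)
                p = float(
                    stats.hypergeom.sf(overlap - 1, m_universe, len(members), n_draws)
                )
                term_rows.append((term, overlap, len(members), p))
            if not term_rows:
                continue
            qvalues = multipletests([t[3] for t in term_rows], method="fdr_bh")[1]
            best = min(
                zip(term_rows, qvalues), key=lambda item: (item[1], item[0][0])
            )
            (term, overlap, term_size, p), q = best
            results.append(
                EnrichmentResult(
                    sample_id=sample_id,
                    component_id=component_id,
                    term_id=term,
                    overlap=overlap,
                    component_size=n_draws,
                    term_size=term_size,
                    universe_size=m_universe,
                    p_value=p,
                    q_value=float(q),
                )
            )
    return results
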