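"""Construction of the isoform-specific protein-protein interaction network.

A functional interaction between two canonical proteins is considered
physical when the two endpoints carry domain instances whose families are
known to interact in solved structures. For every alternative isoform of a
gene we then ask, for each physical edge of the gene's canonical protein,
whether the canonical interacting-domain sequence is still present verbatim
in the isoform: if at least one supporting domain instance survives, the
interaction persists; otherwise it is lost.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from isonet.io import DomainInstance, InteractionEdge

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class IsoformInteractionStatus:
    """Persist/lost call for one isoform on one physical edge of its gene."""

    isoform_id: str
    gene_id: str
    partner_protein: str
    status: str  # "persists" | "lost"
    supporting_domains: frozenset[str]
    matched_domains: frozenset[str]
    edge_key: tuple[str, str]
    combined_score: float

    def __post_init__(self) -> None:
        if self.status not in ("persists", "lost"):
            raise ValueError(f"invalid status {self.status!r}")
        if not self.supporting_domains:
            raise ValueError("status without supporting domain evidence")
        if (self.status == "persists") != bool(self.matched_domains):
            raise ValueError("status inconsistent with matched_domains")
        if not self.matched_domains <= self.supporting_domains:
            raise ValueError("matched_domains not a subset of supporting_domains")


@dataclass
class IsoformInteractionNetwork:
    """The assembled isoform-resolved interaction database.

    ``edges`` is the full canonical edge list (physical subset flagged),
    ``statuses`` one row per (isoform, physical edge of its gene) and
    ``canonical_of`` the gene -> canonical protein mapping used.
    """

    edges: list[InteractionEdge]
    statuses: list[IsoformInteractionStatus]
    canonical_of: dict[str, str]
    skipped_genes: list[str] = field(default_factory=list)

    def statuses_of(self, isoform_id: str) -> list[IsoformInteractionStatus]:
        return [s for s in self.statuses if s.isoform_id == isoform_id]

    def proteins(self) -> set[str]:
        out: set[str] = set()
        for edge in self.edges:
            out.add(edge.protein_a)
            out.add(edge.protein_b)
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "isoform_id": s.isoform_id,
                "gene_id": s.gene_id,
                "partner_protein": s.partner_protein,
                "status": s.status,
                "supporting_domains": ";".join(sorted(s.supporting_domains)),
                "matched_domains": ";".join(sorted(s.matched_domains)),
                "combined_score": s.combined_score,
            }
            for s in self.statuses
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "isoform_id",
                "gene_id",
                "partner_protein",
                "status",
                "supporting_domains",
                "matched_domains",
                "combined_score",
            ],
        )

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def verify_sequence_identity(
    network_fasta: dict[str, str], annotation_fasta: dict[str, str]
) -> set[str]:
    """Return the protein ids whose sequences agree byte-for-byte.

    Proteins present in only one source, or whose sequences differ at any
    residue, are discarded (and counted in the log) — downstream domain
    coordinates are only trustworthy for identical sequences.
    """
    retained = {
        pid
        for pid, seq in network_fasta.items()
        if annotation_fasta.get(pid) == seq
    }
    n_discarded = len(network_fasta) - len(retained)
    if n_discarded:
        logger.info("discarded %d proteins with non-identical sequences", n_discarded)
    return retained


def annotate_physical_edges(
    edges: list[InteractionEdge],
    domains: list[DomainInstance],
    ddi: set[frozenset[str]],
) -> list[InteractionEdge]:
    """Flag edges as physical and attach their supporting domain-instance pairs.

    For each edge, every pair of instances (one per endpoint) whose domain
    families form a known interacting pair — in either orientation —
    becomes a supporting pair. Edges with no such pair stay non-physical.
    """
    by_protein: dict[str, list[DomainInstance]] = {}
    for inst in domains:
        by_protein.setdefault(inst.protein_id, []).append(inst)

    annotated = []
    for edge in edges:
        pairs = set()
        for inst_a in by_protein.get(edge.protein_a, []):
            for inst_b in by_protein.get(edge.protein_b, []):
                if frozenset((inst_a.domain_id, inst_b.domain_id)) in ddi:
                    pairs.add((inst_a.instance_id, inst_b.instance_id))
        annotated.append(
            InteractionEdge(
                edge.protein_a,
                edge.protein_b,
                edge.combined_score,
                physical=bool(pairs),
                domain_pairs=frozenset(pairs),
            )
        )
    return annotated


def assess_isoform_interaction(
    isoform_id: str,
    isoform_sequence: str,
    gene_id: str,
    edge: InteractionEdge,
    side: str,
    domain_index: dict[str, DomainInstance],
) -> IsoformInteractionStatus:
    """Decide whether one isoform keeps one physical interaction.

    ``side`` is the canonical protein id of the isoform's gene on this
    edge. Each supporting domain instance on that side is tested for
    exact substring presence of its canonical sequence in
    ``isoform_sequence``; the interaction persists iff at least one
    instance matches.
    """
    if not edge.physical:
        raise ValueError(f"no domain evidence on edge {edge.key}")
    if side == edge.protein_a:
        own = {pair[0] for pair in edge.domain_pairs}
    elif side == edge.protein_b:
        own = {pair[1] for pair in edge.domain_pairs}
    else:
        raise KeyError(f"{side} is not an endpoint of {edge.key}")
    matched = {
        inst_id
        for inst_id in own
        if domain_index[inst_id].sequence in isoform_sequence
    }
    return IsoformInteractionStatus(
        isoform_id=isoform_id,
        gene_id=gene_id,
        partner_protein=edge.partner_of(side),
        status="persists" if matched else "lost",
        supporting_domains=frozenset(own),
        matched_domains=frozenset(matched),
        edge_key=edge.key,
        combined_score=edge.combined_score,
    )


def build_isoform_network(
    retained: set[str],
    edges: list[InteractionEdge],
    domains: list[DomainInstance],
    ddi: set[frozenset[str]],
    isoforms: dict[str, dict[str, str]],
    canonical_of: dict[str, str],
) -> IsoformInteractionNetwork:
    """Assemble the full isoform-resolved network.

    Parameters
    ----------
    retained
        Protein ids that passed sequence-identity verification; edges
        touching discarded proteins are excluded.
    isoforms
        Mapping gene id -> {isoform protein id: sequence}, including the
        canonical isoform.
    canonical_of
        Mapping gene id -> canonical protein id.

    Every alternative isoform is assessed against every physical edge of
    its gene's canonical protein; canonical isoforms are recorded as
    persisting on all their edges. Genes whose canonical protein is not
    retained are skipped and counted.
    """
    kept_edges = [
        e for e in edges if e.protein_a in retained and e.protein_b in retained
    ]
    kept_domains = [d for d in domains if d.protein_id in retained]
    annotated = annotate_physical_edges(kept_edges, kept_domains, ddi)
    domain_index = {d.instance_id: d for d in kept_domains}

    physical_by_protein: dict[str, list[InteractionEdge]] = {}
    for edge in annotated:
        if edge.physical:
            physical_by_protein.setdefault(edge.protein_a, []).append(edge)
            physical_by_protein.setdefault(edge.protein_b, []).append(edge)

    statuses: list[IsoformInteractionStatus] = []
    skipped: list[str] = []
    for gene_id in sorted(isoforms):
        canonical = canonical_of.get(gene_id)
        if canonical is None or canonical not in retained:
            skipped.append(gene_id)
            continue
        gene_edges = physical_by_protein.get(canonical, [])
        for isoform_id in sorted(isoforms[gene_id]):
            sequence = isoforms[gene_id][isoform_id]
            for edge in gene_edges:
                status = assess_isoform_interaction(
                    isoform_id, sequence, gene_id, edge, canonical, domain_index
                )
                if isoform_id == canonical and status.status != "persists":
                    raise AssertionError(
                        f"canonical isoform {canonical} lost its own edge {edge.key}"
                    )
                statuses.append(status)
    if skipped:
        logger.info("skipped %d genes without a retained canonical protein", len(skipped))
    return IsoformInteractionNetwork(
        edges=annotated,
        statuses=statuses,
        canonical_of=dict(canonical_of),
        skipped_genes=skipped,
    )
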