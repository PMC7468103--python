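"""Self-contained toy worlds with planted ground truth.

The generator emulates, at toy scale, every input the pipeline consumes:
a proteome with canonical and alternative isoforms, residue-level domain
annotations, physically interacting domain-family pairs, a scored
interaction network, tumor/normal expression cohorts with planted
cancer-specific dominance switches, and a mutation table with planted
cis-expression associations. Every random draw flows from one seed, and
truth tables record each planted switch, lost interaction and mutated
association so downstream detection can be scored exactly.

Construction guarantees
-----------------------
* Alternative isoform sequences are the canonical sequence with whole
  domain instances deleted, so interaction persistence is known by
  construction: an edge is lost for an isoform exactly when its
  supporting domain on the isoform's side was deleted.
* Domain sequences are unique random amino-acid strings (regenerated on
  the rare collision), so substring tests cannot match accidentally.
* Planted switch genes express the alternative transcript at relative
  expression ``0.5 + rel_expr_gap / 2`` in tumors and
  ``0.5 - rel_expr_gap / 2`` in normals, with multiplicative lognormal
  noise on isoform proportions (renormalized per sample) and lognormal
  gene-level totals, keeping TPM semantics intact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from isonet.io import (
    CohortPair,
    DomainInstance,
    ExpressionMatrix,
    InteractionEdge,
    MutationRecord,
    match_variants_to_regions,
    write_expression_matrix,
    write_gmt,
)

AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

# genomic layout of the toy chromosome: one functional block per gene
_GENE_SPACING = 10_000
_REGION_LAYOUT = [  # (offset_start, offset_end, region_class), BED half-open
    (0, 200, "promoter_core"),
    (200, 400, "promoter_domain"),
    (400, 500, "utr5"),
    (500, 1500, "cds"),
    (1500, 1520, "splice_site"),
    (1520, 1700, "utr3"),
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions of the toy world.

    ``rel_expr_gap`` is the separation between the planted alternative
    transcript's relative expression in tumors versus normals;
    ``noise_sd`` the standard deviation of the lognormal proportion
    noise. A gap below 1/3 cannot satisfy the 2x dominance rule on both
    sides for two-transcript genes and is rejected, as is noise large
    enough to routinely cross the gap.
    """

    n_genes: int = 50
    isoforms_per_gene: tuple[int, int] = (2, 4)
    n_tumor: int = 10
    n_normal: int = 20
    switch_fraction: float = 0.2
    rel_expr_gap: float = 0.6
    noise_sd: float = 0.25
    edge_density: float = 0.15
    nonphysical_edge_fraction: float = 0.2
    domain_length: tuple[int, int] = (8, 15)
    domains_per_protein: tuple[int, int] = (1, 3)
    mean_gene_tpm: float = 50.0
    gene_tpm_log_sd: float = 0.5
    census_fraction: float = 0.1
    n_gene_sets: int = 5
    n_assoc_genes: int = 3
    assoc_fold: float = 10.0
    n_background_variants: int = 30
    cancer_type: str = "SynthCancer"
    normal_tissue: str = "SynthTissue"
    seed: int = 0

    def validate(self) -> None:
        for name in ("switch_fraction", "rel_expr_gap", "edge_density", "census_fraction"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {value}")
        if self.n_tumor < 1 or self.n_normal < 1:
            raise ValueError("cohort sizes must be >= 1")
        if self.n_genes < 1:
            raise ValueError("need at least one gene")
        if self.switch_fraction > 0 and self.rel_expr_gap < 1.0 / 3.0:
            raise ValueError(
                "rel_expr_gap below 1/3 cannot produce dominant switches in "
                "two-transcript genes (2x rule fails on one side)"
            )
        if self.switch_fraction > 0 and self.noise_sd > self.rel_expr_gap / 2.0:
            raise ValueError("noise_sd too large for the requested rel_expr_gap")
        lo, hi = self.isoforms_per_gene
        if not 1 <= lo <= hi:
            raise ValueError("invalid isoforms_per_gene range")
        if self.domain_length[0] < 4:
            raise ValueError("domains shorter than 4 residues are not unique enough")


@dataclass
class SyntheticWorld:
    """All inputs of one toy study plus its ground truth."""

    config: SyntheticConfig
    canonical_fasta: dict[str, str]
    proteome_fasta: dict[str, str]
    domains: list[DomainInstance]
    ddi: set[frozenset[str]]
    edges: list[InteractionEdge]
    isoforms: dict[str, dict[str, str]]
    canonical_of: dict[str, str]
    transcript_of_protein: dict[str, str]
    census: set[str]
    gene_sets: dict[str, set[str]]
    tumor_matrix: ExpressionMatrix
    normal_matrix: ExpressionMatrix
    cohort: CohortPair
    variants: pd.DataFrame
    regions: pd.DataFrame
    truth_cmdt: pd.DataFrame
    truth_lost_edges: pd.DataFrame
    truth_associations: pd.DataFrame
    variant_counts: dict[str, int] = field(default_factory=dict)

    def mutation_records(self) -> list[MutationRecord]:
        return match_variants_to_regions(self.variants, self.regions)

    def write(self, outdir) -> None:
        """Emit every input as its standard on-disk format."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "truth").mkdir(exist_ok=True)

        def fasta(path, sequences: dict[str, str]) -> None:
            with open(path, "w") as handle:
                for name in sorted(sequences):
                    handle.write(f">{name}\n{sequences[name]}\n")

        fasta(out / "canonical.fasta", self.canonical_fasta)
        fasta(out / "proteome.fasta", self.proteome_fasta)
        pd.DataFrame(
            [
                {
                    "protein_id": d.protein_id,
                    "domain_id": d.domain_id,
                    "start": d.start,
                    "end": d.end,
                }
                for d in self.domains
            ]
        ).to_csv(out / "domains.tsv", sep="\t", index=False)
        pd.DataFrame(
            sorted(tuple(sorted(p)) for p in self.ddi),
            columns=["domain_a", "domain_b"],
        ).to_csv(out / "ddi.tsv", sep="\t", index=False)
        pd.DataFrame(
            [
                {
                    "protein_a": e.protein_a,
                    "protein_b": e.protein_b,
                    "combined_score": e.combined_score,
                }
                for e in self.edges
            ]
        ).to_csv(out / "edges.tsv", sep="\t", index=False)
        write_gmt({"cancer_census": self.census}, out / "census.gmt")
        write_gmt(self.gene_sets, out / "gene_sets.gmt")
        write_expression_matrix(
            self.tumor_matrix, out / "expression_tumor.tsv", out / "id_map.tsv"
        )
        write_expression_matrix(self.normal_matrix, out / "expression_normal.tsv")
        self.variants.to_csv(out / "mutations.tsv", sep="\t", index=False)
        self.regions.to_csv(out / "regions.bed", sep="\t", index=False, header=False)
        with open(out / "cohort.yaml", "w") as handle:
            yaml.safe_dump(
                {
                    "cancer_type": self.cohort.cancer_type,
                    "normal_tissue": self.cohort.normal_tissue,
                    "tumor_samples": sorted(self.cohort.tumor_samples),
                    "normal_samples": sorted(self.cohort.normal_samples),
                },
                handle,
            )
        self.truth_cmdt.to_csv(out / "truth" / "cmdt.tsv", sep="\t", index=False)
        self.truth_lost_edges.to_csv(
            out / "truth" / "lost_edges.tsv", sep="\t", index=False
        )
        self.truth_associations.to_csv(
            out / "truth" / "associations.tsv", sep="\t", index=False
        )
        pd.DataFrame(
            sorted(self.variant_counts.items()), columns=["sample_id", "n_variants"]
        ).to_csv(out / "truth" / "variant_counts.tsv", sep="\t", index=False)


def _random_peptide(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(AMINO_ACIDS, size=length))


def generate_world(config: SyntheticConfig | None = None) -> SyntheticWorld:
    """Build one toy world; identical configs yield identical worlds."""
    config = config or SyntheticConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)

    n = config.n_genes
    genes = [f"G{i:04d}" for i in range(1, n + 1)]
    lo, hi = config.isoforms_per_gene
    n_isoforms = rng.integers(lo, hi + 1, size=n)

    # --- canonical proteins with embedded, globally unique domains -------
    canonical_fasta: dict[str, str] = {}
    proteome_fasta: dict[str, str] = {}
    domains: list[DomainInstance] = []
    domain_seqs: set[str] = set()
    canonical_of: dict[str, str] = {}
    isoforms: dict[str, dict[str, str]] = {}
    transcript_of_protein: dict[str, str] = {}
    gene_domains: dict[str, list[DomainInstance]] = {}
    domain_family = 0

    id_rows = []
    for gene, k in zip(genes, n_isoforms):
        n_dom = int(
            rng.integers(config.domains_per_protein[0], config.domains_per_protein[1] + 1)
        )
        pieces = [_random_peptide(rng, int(rng.integers(10, 21)))]
        spans = []
        for _ in range(n_dom):
            length = int(rng.integers(config.domain_length[0], config.domain_length[1] + 1))
            seq = _random_peptide(rng, length)
            while seq in domain_seqs:  # vanishing probability, but be exact
                seq = _random_peptide(rng, length)
            domain_seqs.add(seq)
            start = sum(len(p) for p in pieces) + 1
            pieces.append(seq)
            spans.append((start, start + length - 1, seq))
            pieces.append(_random_peptide(rng, int(rng.integers(10, 21))))
        canonical_seq = "".join(pieces)

        canonical = f"{gene}P1"
        canonical_of[gene] = canonical
        canonical_fasta[canonical] = canonical_seq
        gene_domains[gene] = []
        for start, end, seq in spans:
            domain_family += 1
            inst = DomainInstance(canonical, f"PF{domain_family:05d}", start, end, seq)
            domains.append(inst)
            gene_domains[gene].append(inst)

        # isoforms: canonical plus alternatives with whole-domain deletions
        gene_isoforms = {canonical: canonical_seq}
        transcript_of_protein[canonical] = f"{gene}T1"
        id_rows.append((f"{gene}T1", gene, canonical))
        for j in range(2, int(k) + 1):
            n_delete = int(rng.integers(1, n_dom + 1))
            delete_idx = sorted(
                rng.choice(n_dom, size=n_delete, replace=False).tolist()
            )
            kept = canonical_seq
            for idx in reversed(delete_idx):
                start, end, _ = spans[idx]
                kept = kept[: start - 1] + kept[end:]
            protein = f"{gene}P{j}"
            gene_isoforms[protein] = kept
            transcript_of_protein[protein] = f"{gene}T{j}"
            id_rows.append((f"{gene}T{j}", gene, protein))
        isoforms[gene] = gene_isoforms
        proteome_fasta.update(gene_isoforms)

    # --- interaction network and DDI support -----------------------------
    ddi: set[frozenset[str]] = set()
    edges: list[InteractionEdge] = []
    edge_support: dict[tuple[str, str], dict[str, DomainInstance]] = {}
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() >= config.edge_density:
                continue
            ga, gb = genes[i], genes[j]
            pa, pb = canonical_of[ga], canonical_of[gb]
            score = round(float(rng.uniform(0.9, 0.999)), 3)
            key = (pa, pb) if pa < pb else (pb, pa)
            if rng.random() < config.nonphysical_edge_fraction:
                edges.append(InteractionEdge(*key, score))
                continue
            inst_a = gene_domains[ga][int(rng.integers(len(gene_domains[ga])))]
            inst_b = gene_domains[gb][int(rng.integers(len(gene_domains[gb])))]
            ddi.add(frozenset((inst_a.domain_id, inst_b.domain_id)))
            edges.append(InteractionEdge(*key, score))
            edge_support[key] = {pa: inst_a, pb: inst_b}
    edges.sort(key=lambda e: e.key)

    # ground-truth lost edges: an alternative isoform loses a supported
    # edge exactly when the supporting domain on its own side was deleted
    lost_rows = []
    for gene in genes:
        canonical = canonical_of[gene]
        own_edges = [
            (key, support) for key, support in edge_support.items() if canonical in support
        ]
        for protein, seq in isoforms[gene].items():
            if protein == canonical:
                continue
            for key, support in own_edges:
                partner = key[0] if key[1] == canonical else key[1]
                if support[canonical].sequence not in seq:
                    lost_rows.append(
                        {
                            "isoform_id": protein,
                            "gene_id": gene,
                            "partner_protein": partner,
                        }
                    )
    truth_lost_edges = pd.DataFrame(
        lost_rows, columns=["isoform_id", "gene_id", "partner_protein"]
    ).sort_values(["isoform_id", "partner_protein"]).reset_index(drop=True)

    # --- census and gene sets --------------------------------------------
    n_census = max(1, round(config.census_fraction * n))
    census_genes = sorted(
        rng.choice(genes, size=n_census, replace=False).tolist()
    )
    census = {canonical_of[g] for g in census_genes}
    gene_sets: dict[str, set[str]] = {}
    shuffled = list(genes)
    rng.shuffle(shuffled)
    for s in range(config.n_gene_sets):
        members = shuffled[s :: config.n_gene_sets]
        gene_sets[f"GS{s + 1:02d}"] = {canonical_of[g] for g in members}

    # --- expression cohorts with planted switches ------------------------
    tumor_samples = [f"TUM{i:03d}" for i in range(1, config.n_tumor + 1)]
    normal_samples = [f"NOR{i:03d}" for i in range(1, config.n_normal + 1)]
    multi_isoform = [g for g, k in zip(genes, n_isoforms) if int(k) >= 2]
    n_switch = min(round(config.switch_fraction * n), len(multi_isoform))
    switch_genes = sorted(rng.choice(multi_isoform, size=n_switch, replace=False).tolist())

    alt_high = 0.5 + config.rel_expr_gap / 2.0
    alt_low = 0.5 - config.rel_expr_gap / 2.0

    transcript_ids = [row[0] for row in id_rows]
    t2g = {row[0]: row[1] for row in id_rows}
    t2p = {row[0]: row[2] for row in id_rows}

    def proportions(gene: str, k: int, switched: bool, role: str) -> np.ndarray:
        """Base isoform proportions for one gene (canonical first)."""
        props = np.zeros(k)
        if switched and k >= 2:
            alt = alt_high if role == "tumor" else alt_low
            minor = 0.05 * max(k - 2, 0)
            props[1] = alt
            props[0] = 1.0 - alt - minor
            props[2:] = 0.05
        else:
            props[0] = 0.75 if k > 1 else 1.0
            if k > 1:
                props[1:] = 0.25 / (k - 1)
        return props

    def cohort_tpm(samples: list[str], role: str) -> pd.DataFrame:
        data = np.zeros((len(transcript_ids), len(samples)))
        row = 0
        for gene, k in zip(genes, n_isoforms):
            k = int(k)
            base = proportions(gene, k, gene in switch_genes, role)
            totals = np.exp(
                rng.normal(np.log(config.mean_gene_tpm), config.gene_tpm_log_sd, len(samples))
            )
            noise = np.exp(rng.normal(0.0, config.noise_sd, size=(k, len(samples))))
            noisy = base[:, None] * noise
            noisy /= noisy.sum(axis=0, keepdims=True)
            data[row : row + k, :] = noisy * totals[None, :]
            row += k
        return pd.DataFrame(np.round(data, 6), index=transcript_ids, columns=samples)

    tumor_tpm = cohort_tpm(tumor_samples, "tumor")
    normal_tpm = cohort_tpm(normal_samples, "normal")

    # --- planted cis-mutation associations and the variant table ---------
    assoc_pool = [g for g in genes if g not in switch_genes and int(n_isoforms[genes.index(g)]) >= 1]
    n_assoc = min(config.n_assoc_genes, len(assoc_pool))
    assoc_genes = sorted(rng.choice(assoc_pool, size=n_assoc, replace=False).tolist())
    n_mutated = max(5, config.n_tumor // 2)
    if n_mutated > config.n_tumor:
        assoc_genes = []

    gene_base = {g: (i + 1) * _GENE_SPACING for i, g in enumerate(genes)}
    region_rows = []
    for gene in genes:
        base = gene_base[gene]
        for off_start, off_end, region_class in _REGION_LAYOUT:
            region_rows.append(
                {
                    "chrom": "chr1",
                    "start": base + off_start,
                    "end": base + off_end,
                    "gene_id": gene,
                    "region_class": region_class,
                }
            )
    regions = pd.DataFrame(region_rows)

    variant_rows = []
    assoc_rows = []
    for gene in assoc_genes:
        mutated = sorted(rng.choice(tumor_samples, size=n_mutated, replace=False).tolist())
        base = gene_base[gene]
        for sample in mutated:
            pos = int(base + 500 + rng.integers(0, 1000))  # inside the cds block
            ref, alt = rng.choice(["A", "C", "G", "T"], size=2, replace=False)
            variant_rows.append(
                {"sample_id": sample, "chrom": "chr1", "pos": pos, "ref": ref, "alt": alt}
            )
        # shift the whole gene's expression in mutated samples; proportions
        # (and hence dominance calls) are unchanged
        gene_transcripts = [t for t in transcript_ids if t2g[t] == gene]
        tumor_tpm.loc[gene_transcripts, mutated] = np.round(
            tumor_tpm.loc[gene_transcripts, mutated] * config.assoc_fold, 6
        )
        for transcript in gene_transcripts:
            assoc_rows.append(
                {
                    "gene_id": gene,
                    "transcript_id": transcript,
                    "n_mutated": len(mutated),
                    "mutated_samples": ";".join(mutated),
                }
            )
    for _ in range(config.n_background_variants):
        sample = tumor_samples[int(rng.integers(len(tumor_samples)))]
        pos = int(rng.integers(_GENE_SPACING, (n + 1) * _GENE_SPACING))
        ref, alt = rng.choice(["A", "C", "G", "T"], size=2, replace=False)
        variant_rows.append(
            {"sample_id": sample, "chrom": "chr1", "pos": pos, "ref": ref, "alt": alt}
        )
    variants = pd.DataFrame(
        variant_rows, columns=["sample_id", "chrom", "pos", "ref", "alt"]
    ).sort_values(["sample_id", "chrom", "pos"]).reset_index(drop=True)
    variant_counts = variants.groupby("sample_id").size().to_dict()
    for sample in tumor_samples:
        variant_counts.setdefault(sample, 0)

    # --- truth: every tumor sample of every switch gene is a planted cMDT
    cmdt_rows = [
        {"sample_id": sample, "gene_id": gene, "transcript_id": f"{gene}T2"}
        for gene in switch_genes
        for sample in tumor_samples
    ]
    truth_cmdt = pd.DataFrame(
        cmdt_rows, columns=["sample_id", "gene_id", "transcript_id"]
    )

    id_map = {t: g for t, g, _ in id_rows}
    protein_map = {t: p for t, _, p in id_rows}
    tumor_matrix = ExpressionMatrix(tumor_tpm, id_map, protein_map)
    normal_matrix = ExpressionMatrix(normal_tpm, id_map, protein_map)
    cohort = CohortPair(
        cancer_type=config.cancer_type,
        tumor_samples=frozenset(tumor_samples),
        normal_tissue=config.normal_tissue,
        normal_samples=frozenset(normal_samples),
    )

    return SyntheticWorld(
        config=config,
        canonical_fasta=canonical_fasta,
        proteome_fasta=proteome_fasta,
        domains=domains,
        ddi=ddi,
        edges=edges,
        isoforms=isoforms,
        canonical_of=canonical_of,
        transcript_of_protein=transcript_of_protein,
        census=census,
        gene_sets=gene_sets,
        tumor_matrix=tumor_matrix,
        normal_matrix=normal_matrix,
        cohort=cohort,
        variants=variants,
        regions=regions,
        truth_cmdt=truth_cmdt,
        truth_lost_edges=truth_lost_edges,
        truth_associations=pd.DataFrame(
            assoc_rows,
            columns=["gene_id", "transcript_id", "n_mutated", "mutated_samples"],
        ),
        variant_counts=variant_counts,
    )
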