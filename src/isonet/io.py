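"""Readers, writers and the in-memory data model for all external formats.

Everything downstream operates on the types defined here: a dense
transcripts x samples TPM matrix with id mappings, canonicalized scored
interaction edges, residue-level domain instances, functional-region
mutation records and tumor/normal cohort definitions.

Conventions
-----------
* Expression tables are TSV with a header of sample ids and one row per
  transcript; missing/NA cells are coerced to TPM 0.
* Interaction edge lists accept either real scores in [0, 1] or
  STRING-style integer scores in 0-999 (auto-detected; integers are
  divided by 1000).
* Functional-region files follow the BED convention (0-based, half-open);
  variant positions are 1-based. The conversion happens once, at load.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

#: Functional region classes in which a variant counts as a cis mutation.
REGION_CLASSES = frozenset(
    {"promoter_core", "promoter_domain", "utr5", "cds", "splice_site", "utr3"}
)

VARIANT_CLASSES = frozenset({"snv", "mnv", "indel"})


class FormatError(ValueError):
    """Raised when an input file violates a hard invariant."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class InteractionEdge:
    """A scored, canonically ordered protein-protein interaction.

    ``physical`` is true exactly when at least one pair of domain
    instances on the two endpoints belongs to a known physically
    interacting domain-family pair; those instance pairs are stored in
    ``domain_pairs`` as ``(instance_on_a, instance_on_b)`` id tuples.
    """

    protein_a: str
    protein_b: str
    combined_score: float
    physical: bool = False
    domain_pairs: frozenset[tuple[str, str]] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.protein_a == self.protein_b:
            raise FormatError(f"self-interaction for {self.protein_a}")
        if self.protein_a > self.protein_b:
            raise FormatError(
                f"edge not canonically ordered: {self.protein_a} > {self.protein_b}"
            )
        if not 0.0 <= self.combined_score <= 1.0:
            raise FormatError(f"combined score {self.combined_score} outside [0, 1]")
        if self.physical != bool(self.domain_pairs):
            raise FormatError("physical flag inconsistent with domain_pairs")

    @property
    def key(self) -> tuple[str, str]:
        return (self.protein_a, self.protein_b)

    def partner_of(self, protein: str) -> str:
        if protein == self.protein_a:
            return self.protein_b
        if protein == self.protein_b:
            return self.protein_a
        raise KeyError(f"{protein} is not an endpoint of {self.key}")


@dataclass(frozen=True)
class DomainInstance:
    """One domain occurrence on a protein, with its residue-level sequence.

    ``start``/``end`` are 1-based inclusive positions into the protein
    sequence, and ``sequence`` must equal that substring.
    """

    protein_id: str
    domain_id: str
    start: int
    end: int
    sequence: str

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise FormatError(
                f"invalid span {self.start}-{self.end} on {self.protein_id}"
            )
        if len(self.sequence) != self.end - self.start + 1:
            raise FormatError(
                f"sequence length {len(self.sequence)} does not match span "
                f"{self.start}-{self.end} on {self.protein_id}"
            )

    @property
    def instance_id(self) -> str:
        return f"{self.protein_id}:{self.domain_id}:{self.start}-{self.end}"


@dataclass(frozen=True)
class MutationRecord:
    """One variant falling inside one functional region of a gene."""

    sample_id: str
    gene_id: str
    region_class: str
    variant_class: str

    def __post_init__(self) -> None:
        if self.region_class not in REGION_CLASSES:
            raise FormatError(f"unknown region class {self.region_class!r}")
        if self.variant_class not in VARIANT_CLASSES:
            raise FormatError(f"unknown variant class {self.variant_class!r}")


@dataclass(frozen=True)
class CohortPair:
    """A tumor cohort and its matched normal-tissue cohort."""

    cancer_type: str
    tumor_samples: frozenset[str]
    normal_tissue: str
    normal_samples: frozenset[str]

    def __post_init__(self) -> None:
        if not self.tumor_samples or not self.normal_samples:
            raise FormatError("tumor and normal sample sets must be non-empty")
        if self.tumor_samples & self.normal_samples:
            raise FormatError("tumor and normal sample sets overlap")


class ExpressionMatrix:
    """Dense transcripts x samples TPM matrix with transcript id mappings.

    Parameters
    ----------
    tpm
        DataFrame indexed by transcript id with sample-id columns. Values
        must be finite and non-negative after NA coercion.
    transcript_to_gene
        Total mapping transcript id -> gene id.
    transcript_to_protein
        Partial mapping transcript id -> protein (isoform) id.
    """

    def __init__(
        self,
        tpm: pd.DataFrame,
        transcript_to_gene: dict[str, str],
        transcript_to_protein: dict[str, str] | None = None,
    ) -> None:
        if tpm.index.duplicated().any():
            dup = tpm.index[tpm.index.duplicated()][0]
            raise FormatError(f"duplicate transcript id {dup!r}")
        if tpm.columns.duplicated().any():
            dup = tpm.columns[tpm.columns.duplicated()][0]
            raise FormatError(f"duplicate sample id {dup!r}")
        if len(tpm.index) == 0:
            raise FormatError("no transcripts")
        values = tpm.to_numpy(dtype=float)
        if not np.isfinite(values).all():
            raise FormatError("non-finite TPM values after NA coercion")
        if (values < 0).any():
            raise FormatError("negative TPM values")
        missing = [t for t in tpm.index if t not in transcript_to_gene]
        if missing:
            raise FormatError(f"transcripts without gene mapping: {missing[:5]}")
        self.tpm = tpm.astype(float)
        self.transcript_to_gene = dict(transcript_to_gene)
        self.transcript_to_protein = dict(transcript_to_protein or {})
        self._gene_transcripts: dict[str, list[str]] = {}
        for t in self.tpm.index:
            self._gene_transcripts.setdefault(self.transcript_to_gene[t], []).append(t)

    @property
    def transcript_ids(self) -> list[str]:
        return list(self.tpm.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.tpm.columns)

    @property
    def genes(self) -> list[str]:
        return list(self._gene_transcripts)

    def transcripts_of(self, gene_id: str) -> list[str]:
        return list(self._gene_transcripts.get(gene_id, []))

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        keep = [s for s in self.tpm.columns if s in set(sample_ids)]
        return ExpressionMatrix(
            self.tpm[keep], self.transcript_to_gene, self.transcript_to_protein
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"ExpressionMatrix({len(self.tpm.index)} transcripts x "
            f"{len(self.tpm.columns)} samples, {len(self._gene_transcripts)} genes)"
        )


# ---------------------------------------------------------------------------
# expression I/O
# ---------------------------------------------------------------------------


def read_id_map(path) -> tuple[dict[str, str], dict[str, str]]:
    """Read a transcript/gene/protein mapping TSV.

    Expects columns ``transcript_id``, ``gene_id`` and optionally
    ``protein_id`` (empty cells mean no protein product).
    """
    table = pd.read_csv(path, sep="\t", dtype=str)
    if "transcript_id" not in table.columns or "gene_id" not in table.columns:
        raise FormatError("id map needs transcript_id and gene_id columns")
    if table["transcript_id"].duplicated().any():
        dup = table.loc[table["transcript_id"].duplicated(), "transcript_id"].iloc[0]
        raise FormatError(f"duplicate transcript id {dup!r} in id map")
    t2g = dict(zip(table["transcript_id"], table["gene_id"]))
    t2p: dict[str, str] = {}
    if "protein_id" in table.columns:
        for t, p in zip(table["transcript_id"], table["protein_id"]):
            if isinstance(p, str) and p:
                t2p[t] = p
    return t2g, t2p


def read_expression_matrix(path, id_maps, strict: bool = True) -> ExpressionMatrix:
    """Load a TPM TSV (rows = transcripts, columns = samples).

    NA/empty cells become 0 TPM. In strict mode a transcript missing from
    the id map is a hard error; in lenient mode it is dropped with a
    logged count.
    """
    table = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if table.index.duplicated().any():
        dup = table.index[table.index.duplicated()][0]
        raise FormatError(f"duplicate transcript id {dup!r}")
    if len(table.index) == 0:
        raise FormatError("no transcripts")
    try:
        tpm = table.apply(pd.to_numeric, errors="raise")
    except (ValueError, TypeError) as exc:
        raise FormatError(f"non-numeric TPM cell: {exc}") from exc
    if (tpm.to_numpy() < 0).any():
        raise FormatError("negative TPM values")
    tpm = tpm.fillna(0.0)
    t2g, t2p = read_id_map(id_maps)
    unmapped = [t for t in tpm.index if t not in t2g]
    if unmapped:
        if strict:
            raise FormatError(f"unmapped transcripts: {unmapped[:5]}")
        logger.warning("dropping %d unmapped transcripts", len(unmapped))
        tpm = tpm.drop(index=unmapped)
        if len(tpm.index) == 0:
            raise FormatError("no transcripts")
    return ExpressionMatrix(tpm, t2g, t2p)


def write_expression_matrix(matrix: ExpressionMatrix, path, id_maps=None) -> None:
    """Write the matrix (and optionally its id map) back to TSV.

    Values are serialized with ``repr`` precision so that a write/read
    round trip reproduces them bit for bit.
    """
    frame = matrix.tpm.copy()
    frame.index.name = "transcript_id"
    frame.to_csv(path, sep="\t", float_format=None)
    if id_maps is not None:
        rows = []
        for t in matrix.transcript_ids:
            rows.append(
                {
                    "transcript_id": t,
                    "gene_id": matrix.transcript_to_gene[t],
                    "protein_id": matrix.transcript_to_protein.get(t, ""),
                }
            )
        pd.DataFrame(rows).to_csv(id_maps, sep="\t", index=False)


# ---------------------------------------------------------------------------
# interaction edges
# ---------------------------------------------------------------------------


def read_interaction_edges(path, min_score: float = 0.9) -> list[InteractionEdge]:
    """Read a scored protein-pair TSV and return canonical, filtered edges.

    Score dialect is auto-detected: any score > 1 means the whole file is
    in 0-999 integer units and every score is divided by 1000. Duplicate
    pairs (in either orientation) collapse to one edge keeping the
    maximum score; self-loop rows are dropped with a counted warning.
    """
    table = pd.read_csv(path, sep="\t", dtype={0: str, 1: str})
    if table.shape[1] < 3:
        raise FormatError("edge list needs protein_a, protein_b, score columns")
    a = table.iloc[:, 0].astype(str)
    b = table.iloc[:, 1].astype(str)
    try:
        scores = pd.to_numeric(table.iloc[:, 2], errors="raise").astype(float)
    except (ValueError, TypeError) as exc:
        raise FormatError(f"malformed score: {exc}") from exc
    if scores.isna().any() or not np.isfinite(scores.to_numpy()).all():
        raise FormatError("malformed score: NA or non-finite")
    if (scores > 1).any():
        if (scores < 0).any() or (scores > 999).any():
            raise FormatError("integer-dialect scores must lie in 0-999")
        scores = scores / 1000.0
    elif (scores < 0).any():
        raise FormatError("scores must be non-negative")

    best: dict[tuple[str, str], float] = {}
    n_self = 0
    for pa, pb, sc in zip(a, b, scores):
        if pa == pb:
            n_self += 1
            continue
        key = (pa, pb) if pa < pb else (pb, pa)
        if sc >= min_score and sc > best.get(key, -1.0):
            best[key] = sc
    if n_self:
        logger.warning("dropped %d self-loop rows", n_self)
    return [
        InteractionEdge(pa, pb, sc) for (pa, pb), sc in sorted(best.items())
    ]


# ---------------------------------------------------------------------------
# sequences, domains, DDI, gene sets
# ---------------------------------------------------------------------------


def read_fasta(path) -> dict[str, str]:
    """Read protein sequences keyed by record id."""
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in sequences:
            raise FormatError(f"duplicate FASTA id {record.id!r}")
        sequences[record.id] = str(record.seq)
    return sequences


def read_domain_table(path, sequences: dict[str, str]) -> list[DomainInstance]:
    """Read domain annotations (protein_id, domain_id, start, end).

    Coordinates are 1-based inclusive; each instance's sequence is
    extracted from ``sequences`` and validated against the span. Proteins
    absent from ``sequences`` are skipped (they carry no usable evidence).
    """
    table = pd.read_csv(path, sep="\t", dtype={"protein_id": str, "domain_id": str})
    required = {"protein_id", "domain_id", "start", "end"}
    if not required.issubset(table.columns):
        raise FormatError(f"domain table needs columns {sorted(required)}")
    instances = []
    for row in table.itertuples(index=False):
        seq = sequences.get(row.protein_id)
        if seq is None:
            continue
        start, end = int(row.start), int(row.end)
        if not 1 <= start <= end <= len(seq):
            raise FormatError(
                f"domain span {start}-{end} outside {row.protein_id} "
                f"(length {len(seq)})"
            )
        instances.append(
            DomainInstance(row.protein_id, row.domain_id, start, end, seq[start - 1 : end])
        )
    return instances


def read_ddi_pairs(path) -> set[frozenset[str]]:
    """Read unordered physically interacting domain-family pairs."""
    table = pd.read_csv(path, sep="\t", dtype=str)
    if table.shape[1] < 2:
        raise FormatError("DDI table needs two domain columns")
    return {
        frozenset((da, db))
        for da, db in zip(table.iloc[:, 0], table.iloc[:, 1])
    }


def read_gmt(path) -> dict[str, set[str]]:
    """Read gene sets in GMT format (name, description, members...)."""
    sets: dict[str, set[str]] = {}
    with open(path) as handle:
        for line in handle:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3 or not fields[0]:
                continue
            sets[fields[0]] = {g for g in fields[2:] if g}
    return sets


def write_gmt(sets: dict[str, set[str]], path, description: str = "na") -> None:
    with open(path, "w") as handle:
        for name in sorted(sets):
            members = "\t".join(sorted(sets[name]))
            handle.write(f"{name}\t{description}\t{members}\n")


# ---------------------------------------------------------------------------
# mutations
# ---------------------------------------------------------------------------


def _merge_adjacent_snvs(variants: pd.DataFrame) -> list[dict]:
    """Join maximal runs of adjacent same-sample SNVs into MNVs.

    Indels (ref/alt of unequal or multi-base length) never merge. Returns
    one dict per merged variant with 1-based inclusive [pos, end].
    """
    is_snv = (variants["ref"].str.len() == 1) & (variants["alt"].str.len() == 1)
    merged: list[dict] = []
    snvs = variants[is_snv].sort_values(["sample_id", "chrom", "pos"])
    for (sample, chrom), group in snvs.groupby(["sample_id", "chrom"], sort=True):
        run_start = None
        prev = None
        for pos in group["pos"]:
            if run_start is None:
                run_start, prev = pos, pos
            elif pos == prev + 1:
                prev = pos
            elif pos == prev:  # duplicate position, keep one
                continue
            else:
                merged.append(
                    {
                        "sample_id": sample,
                        "chrom": chrom,
                        "pos": run_start,
                        "end": prev,
                        "variant_class": "snv" if run_start == prev else "mnv",
                    }
                )
                run_start, prev = pos, pos
        if run_start is not None:
            merged.append(
                {
                    "sample_id": sample,
                    "chrom": chrom,
                    "pos": run_start,
                    "end": prev,
                    "variant_class": "snv" if run_start == prev else "mnv",
                }
            )
    for row in variants[~is_snv].itertuples(index=False):
        span = max(len(row.ref), 1)
        merged.append(
            {
                "sample_id": row.sample_id,
                "chrom": row.chrom,
                "pos": int(row.pos),
                "end": int(row.pos) + span - 1,
                "variant_class": "indel",
            }
        )
    return merged


def match_variants_to_regions(
    variants: pd.DataFrame, regions: pd.DataFrame
) -> list[MutationRecord]:
    """Intersect variants with functional regions after MNV joining.

    ``variants`` has columns sample_id, chrom, pos, ref, alt (pos
    1-based); ``regions`` has columns chrom, start, end, gene_id,
    region_class in BED convention (0-based half-open). Adjacent
    same-sample SNVs are first joined into MNVs; each (variant, region)
    overlap then yields one record, and variants hitting no functional
    region are discarded.
    """
    required = {"sample_id", "chrom", "pos", "ref", "alt"}
    if not required.issubset(variants.columns):
        raise FormatError(f"variant table needs columns {sorted(required)}")
    variants = variants.assign(pos=variants["pos"].astype(int))

    bad = set(regions["region_class"]) - REGION_CLASSES
    if bad:
        raise FormatError(f"unknown region class {sorted(bad)[0]!r}")
    sorted_ok = (
        regions.groupby("chrom")["start"].apply(lambda s: s.is_monotonic_increasing).all()
    )
    if not sorted_ok:
        logger.warning("region file not sorted; sorting internally")
    regions = regions.sort_values(["chrom", "start", "end"]).reset_index(drop=True)

    # BED half-open [start, end) -> 1-based inclusive [start + 1, end]
    by_chrom: dict[str, list[tuple[int, int, str, str]]] = {}
    for row in regions.itertuples(index=False):
        by_chrom.setdefault(row.chrom, []).append(
            (int(row.start) + 1, int(row.end), row.gene_id, row.region_class)
        )

    records: list[MutationRecord] = []
    for var in _merge_adjacent_snvs(variants):
        for r_start, r_end, gene, region_class in by_chrom.get(var["chrom"], []):
            if var["pos"] <= r_end and var["end"] >= r_start:
                records.append(
                    MutationRecord(
                        var["sample_id"], gene, region_class, var["variant_class"]
                    )
                )
    return records


def read_mutation_table(path, regions) -> list[MutationRecord]:
    """Load per-sample variants and intersect them with functional regions.

    ``path`` is a variant TSV with a header (sample_id, chrom, pos, ref,
    alt); ``regions`` is a header-less BED-like TSV (chrom, start, end,
    gene_id, region_class). See :func:`match_variants_to_regions` for
    the overlap semantics.
    """
    variants = pd.read_csv(
        path, sep="\t", dtype={"sample_id": str, "chrom": str, "ref": str, "alt": str}
    )
    reg = pd.read_csv(
        regions,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "gene_id", "region_class"],
        dtype={"chrom": str, "gene_id": str, "region_class": str},
    )
    return match_variants_to_regions(variants, reg)


# ---------------------------------------------------------------------------
# edge annotation helper shared with isonet_build
# ---------------------------------------------------------------------------


def canonical_edge_key(protein_a: str, protein_b: str) -> tuple[str, str]:
    """Order an unordered protein pair lexicographically."""
    return (protein_a, protein_b) if protein_a < protein_b else (protein_b, protein_a)
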