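"""End-to-end orchestration: network build, switch calling, impact, association.

The pipeline is a pure function of its input files, thresholds and seed:
running it twice on the same configuration yields byte-identical outputs.
Configuration is a YAML document naming every input path and threshold::

    inputs:
      expression_tumor: .../expression_tumor.tsv
      expression_normal: .../expression_normal.tsv
      id_map: .../id_map.tsv
      canonical_fasta: .../canonical.fasta
      proteome_fasta: .../proteome.fasta
      domains: .../domains.tsv
      ddi: .../ddi.tsv
      edges: .../edges.tsv
      census_gmt: .../census.gmt
      gene_sets_gmt: .../gene_sets.gmt
      mutations: .../mutations.tsv
      regions: .../regions.bed
      cohort: .../cohort.yaml
    thresholds:
      min_score: 0.9
      min_tpm_tumor: 2.0
      min_tpm_normal: 0.2
      dominance_fold: 2.0
      q_cmdt: 0.01
      q_assoc: 0.01
      min_mutated: 5
      nds_depth: 3
    n_control_draws: 1000
    seed: 0
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from isonet import dominance, impact, io, mutation, network

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLDS = {
    "min_score": 0.9,
    "min_tpm_tumor": 2.0,
    "min_tpm_normal": 0.2,
    "dominance_fold": 2.0,
    "q_cmdt": 0.01,
    "q_assoc": 0.01,
    "min_mutated": 5,
    "nds_depth": 3,
}

REQUIRED_INPUTS = [
    "expression_tumor",
    "expression_normal",
    "id_map",
    "canonical_fasta",
    "proteome_fasta",
    "domains",
    "ddi",
    "edges",
    "census_gmt",
    "gene_sets_gmt",
    "mutations",
    "regions",
    "cohort",
]


def load_config(path) -> dict:
    with open(path) as handle:
        config = yaml.safe_load(handle)
    validate_config(config)
    return config


def validate_config(config: dict) -> None:
    inputs = config.get("inputs", {})
    missing = [k for k in REQUIRED_INPUTS if k not in inputs]
    if missing:
        raise ValueError(f"config missing input paths: {missing}")
    absent = [k for k in REQUIRED_INPUTS if not Path(inputs[k]).exists()]
    if absent:
        raise FileNotFoundError(
            f"input files do not exist: {[str(inputs[k]) for k in absent]}"
        )
    thresholds = {**DEFAULT_THRESHOLDS, **config.get("thresholds", {})}
    for key, value in thresholds.items():
        if value <= 0:
            raise ValueError(f"threshold {key} must be positive, got {value}")


def _read_cohort(path) -> io.CohortPair:
    with open(path) as handle:
        raw = yaml.safe_load(handle)
    return io.CohortPair(
        cancer_type=raw["cancer_type"],
        tumor_samples=frozenset(raw["tumor_samples"]),
        normal_tissue=raw["normal_tissue"],
        normal_samples=frozenset(raw["normal_samples"]),
    )


class InputBundle:
    """All loaded inputs of one pipeline run."""

    def __init__(self, config: dict) -> None:
        inputs = config["inputs"]
        thresholds = {**DEFAULT_THRESHOLDS, **config.get("thresholds", {})}
        self.thresholds = thresholds
        self.seed = int(config.get("seed", 0))
        self.n_control_draws = int(config.get("n_control_draws", 1000))
        self.cohort = _read_cohort(inputs["cohort"])
        self.tumor_matrix = io.read_expression_matrix(
            inputs["expression_tumor"], inputs["id_map"]
        )
        self.normal_matrix = io.read_expression_matrix(
            inputs["expression_normal"], inputs["id_map"]
        )
        self.canonical_fasta = io.read_fasta(inputs["canonical_fasta"])
        self.proteome = io.read_fasta(inputs["proteome_fasta"])
        self.edges = io.read_interaction_edges(inputs["edges"], thresholds["min_score"])
        self.domains = io.read_domain_table(inputs["domains"], self.canonical_fasta)
        self.ddi = io.read_ddi_pairs(inputs["ddi"])
        self.census = set().union(*io.read_gmt(inputs["census_gmt"]).values())
        self.gene_sets = io.read_gmt(inputs["gene_sets_gmt"])
        self.mutations = io.read_mutation_table(inputs["mutations"], inputs["regions"])

    def isoform_map(self) -> tuple[dict[str, dict[str, str]], dict[str, str]]:
        """Gene -> isoform sequences and gene -> canonical protein maps."""
        isoforms: dict[str, dict[str, str]] = {}
        canonical_of: dict[str, str] = {}
        for transcript, protein in self.tumor_matrix.transcript_to_protein.items():
            gene = self.tumor_matrix.transcript_to_gene[transcript]
            if protein in self.proteome:
                isoforms.setdefault(gene, {})[protein] = self.proteome[protein]
            if protein in self.canonical_fasta:
                canonical_of[gene] = protein
        return isoforms, canonical_of

    def build_network(self) -> network.IsoformInteractionNetwork:
        retained = network.verify_sequence_identity(self.canonical_fasta, self.proteome)
        isoforms, canonical_of = self.isoform_map()
        return network.build_isoform_network(
            retained, self.edges, self.domains, self.ddi, isoforms, canonical_of
        )


def load_inputs(config: dict) -> InputBundle:
    validate_config(config)
    return InputBundle(config)


def run_pipeline(config: dict, outdir) -> dict:
    """Run every stage and write a report directory; returns the summary."""
    validate_config(config)
    thresholds = {**DEFAULT_THRESHOLDS, **config.get("thresholds", {})}
    seed = int(config.get("seed", 0))
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)

    def stage(name):
        logger.info("stage: %s", name)

    try:
        stage("load")
        bundle = InputBundle(config)
        cohort = bundle.cohort
        tumor_matrix = bundle.tumor_matrix
        normal_matrix = bundle.normal_matrix
        census = bundle.census
        gene_sets = bundle.gene_sets
        mutations = bundle.mutations
    except Exception as exc:
        raise RuntimeError(f"stage 'load' failed: {exc}") from exc

    try:
        stage("build-network")
        _, canonical_of = bundle.isoform_map()
        isonet = bundle.build_network()
        isonet.write(out / "network.tsv")
    except Exception as exc:
        raise RuntimeError(f"stage 'build-network' failed: {exc}") from exc

    try:
        stage("call-mdt")
        tumor_mdts = dominance.identify_mdt_cohort(
            tumor_matrix,
            sorted(cohort.tumor_samples),
            "tumor",
            thresholds["dominance_fold"],
            thresholds["min_tpm_tumor"],
        )
        normal_mdts = dominance.identify_mdt_cohort(
            normal_matrix,
            sorted(cohort.normal_samples),
            "normal",
            thresholds["dominance_fold"],
            thresholds["min_tpm_normal"],
        )
        dominance.mdt_frame(tumor_mdts).to_csv(out / "mdt_tumor.tsv", sep="\t", index=False)
        dominance.mdt_frame(normal_mdts).to_csv(out / "mdt_normal.tsv", sep="\t", index=False)
    except Exception as exc:
        raise RuntimeError(f"stage 'call-mdt' failed: {exc}") from exc

    try:
        stage("call-cmdt")
        cmdt_calls = dominance.call_cmdt(
            tumor_mdts,
            normal_mdts,
            tumor_matrix,
            normal_matrix,
            cohort,
            q_threshold=thresholds["q_cmdt"],
        )
        dominance.cmdt_frame(cmdt_calls).to_csv(out / "cmdt.tsv", sep="\t", index=False)
        recurrence = dominance.recurrent_cmdt(cmdt_calls, cohort)
        recurrence.to_csv(out / "recurrence.tsv", sep="\t", index=False)
    except Exception as exc:
        raise RuntimeError(f"stage 'call-cmdt' failed: {exc}") from exc

    try:
        stage("impact")
        records, disruption = impact.map_disruptions(
            cmdt_calls, isonet, tumor_matrix.transcript_to_protein
        )
        disruption.to_csv(out / "disruptions.tsv", sep="\t", index=False)
        per_sample = (
            pd.DataFrame([vars(r) for r in records])
            .groupby("sample_id")
            .size()
            .to_dict()
            if records
            else {}
        )
        summary_stats = impact.disruption_summary(per_sample, len(cohort.tumor_samples))

        graph = impact.interaction_graph(isonet.edges)
        nds_values = {
            p: impact.network_density_score(graph, p, thresholds["nds_depth"])
            for p in sorted(graph.nodes)
        }
        if len(nds_values) >= 2:
            nds_entries = impact.rank_nds(nds_values)
            pd.DataFrame([vars(e) for e in nds_entries]).to_csv(
                out / "nds.tsv", sep="\t", index=False
            )
        cmdt_canonicals = sorted(
            {canonical_of[c.gene_id] for c in cmdt_calls if c.gene_id in canonical_of}
        )
        proximity = impact.census_proximity(graph, cmdt_canonicals, census)
        pd.DataFrame([vars(p) for p in proximity]).to_csv(
            out / "proximity.tsv", sep="\t", index=False
        )
        control = None
        if cmdt_canonicals:
            control = impact.proximity_control(
                tumor_matrix,
                graph,
                census,
                cmdt_canonicals,
                n_draws=int(config.get("n_control_draws", 1000)),
                seed=seed,
            )
    except Exception as exc:
        raise RuntimeError(f"stage 'impact' failed: {exc}") from exc

    try:
        stage("enrich")
        if records:
            enrichment = impact.enrich_components(
                records, gene_sets, isonet.proteins(), tumor_matrix.transcript_to_protein
            )
            pd.DataFrame([vars(e) for e in enrichment]).to_csv(
                out / "enrichment.tsv", sep="\t", index=False
            )
    except Exception as exc:
        raise RuntimeError(f"stage 'enrich' failed: {exc}") from exc

    try:
        stage("mut-assoc")
        groups = mutation.assign_groups(tumor_matrix, mutations, cohort.tumor_samples)
        associations = mutation.test_association(
            groups,
            tumor_matrix,
            cohort.cancer_type,
            q_threshold=thresholds["q_assoc"],
            min_mutated=int(thresholds["min_mutated"]),
        )
        pd.DataFrame([vars(a) for a in associations]).to_csv(
            out / "associations.tsv", sep="\t", index=False
        )
        cmdt_load = {s: 0 for s in cohort.tumor_samples}
        for call in cmdt_calls:
            cmdt_load[call.sample_id] += 1
        variant_load: dict[str, int] = {s: 0 for s in cohort.tumor_samples}
        for record in mutations:
            if record.sample_id in variant_load:
                variant_load[record.sample_id] += 1
        try:
            rho = mutation.load_correlation(cmdt_load, variant_load)
        except ValueError:
            rho = float("nan")
    except Exception as exc:
        raise RuntimeError(f"stage 'mut-assoc' failed: {exc}") from exc

    n_samples = len(cohort.tumor_samples)
    loads = sorted(cmdt_load.values())
    summary = {
        "cancer_type": cohort.cancer_type,
        "n_tumor_samples": n_samples,
        "n_normal_samples": len(cohort.normal_samples),
        "n_tumor_mdt": len(tumor_mdts),
        "n_cmdt_calls": len(cmdt_calls),
        "n_unique_cmdt": len({c.transcript_id for c in cmdt_calls}),
        "median_cmdt_per_sample": float(np.median(loads)) if loads else 0.0,
        "total_disrupted_ppi": summary_stats["total_disrupted"],
        "mean_disrupted_ppi_per_sample": summary_stats["mean_per_sample"],
        "n_associations_significant": sum(a.significant for a in associations),
        "cmdt_variant_load_spearman": rho,
        "proximity_control_p": control["p_value"] if control else float("nan"),
    }
    with open(out / "summary.json", "w") as handle:
        json.dump(summary, handle, indent=2, sort_keys=True)
        handle.write("\n")
    return summary
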