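"""Most-dominant-transcript (MDT) calling and cancer-specific switch detection.

Per sample and gene, the transcript with the highest TPM is the MDT when it
is expressed at least ``dominance_fold`` (default 2x) above the runner-up
and clears a role-specific noise floor (tumor 2.0 TPM, normal 0.2 TPM; the
tumor floor corresponds to the background expression ceiling of tissue-
restricted genes, the normal floor is relaxed to still detect matched
low-expression dominance).

A tumor MDT becomes a cancer-specific MDT (cMDT) when four criteria hold:

1. the transcript is never an MDT in any normal sample (scope
   configurable: whole normal compendium or matched cohort only);
2. its gene has an MDT (of any transcript identity) in at least half of
   the matched normal samples;
3. its relative expression differs significantly from the matched normal
   cohort — a sign test over per-normal-sample comparisons feeding an
   exact two-sided binomial, Benjamini-Hochberg corrected per cancer
   type, q below threshold (default 0.01);
4. its relative expression exceeds the transcript's median relative
   expression across the matched normal cohort.

Relative expression of a transcript is its TPM divided by the summed TPM
of all transcripts of its gene in the same sample (undefined when the gene
is silent).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from isonet.io import CohortPair, ExpressionMatrix

MIN_TPM_TUMOR = 2.0
MIN_TPM_NORMAL = 0.2
DOMINANCE_FOLD = 2.0


@dataclass(frozen=True)
class MdtCall:
    """One gene's most dominant transcript in one sample."""

    sample_id: str
    gene_id: str
    transcript_id: str
    tpm: float
    second_tpm: float
    cohort_role: str  # "tumor" | "normal"


@dataclass(frozen=True)
class RelativeExpression:
    transcript_id: str
    sample_id: str
    value: float
    defined: bool


@dataclass(frozen=True)
class CmdtCall:
    """A cancer-specific MDT with its cohort statistics."""

    sample_id: str
    gene_id: str
    transcript_id: str
    rel_expr: float
    n_higher: int
    n_lower: int
    p_value: float
    q_value: float
    normal_median_rel_expr: float


def _min_tpm(cohort_role: str) -> float:
    if cohort_role == "tumor":
        return MIN_TPM_TUMOR
    if cohort_role == "normal":
        return MIN_TPM_NORMAL
    raise ValueError(f"unknown cohort role {cohort_role!r}")


def identify_mdt(
    matrix: ExpressionMatrix,
    sample_id: str,
    cohort_role: str,
    dominance_fold: float = DOMINANCE_FOLD,
    min_tpm: float | None = None,
) -> list[MdtCall]:
    """Call at most one MDT per gene in one sample.

    A single-transcript gene yields an MDT iff its TPM clears the floor
    (the runner-up TPM is then 0). Equal top-two TPMs never qualify: the
    fold rule requires top >= fold x second with fold > 1.
    """
    if sample_id not in matrix.tpm.columns:
        raise KeyError(f"unknown sample {sample_id!r}")
    floor = _min_tpm(cohort_role) if min_tpm is None else min_tpm
    column = matrix.tpm[sample_id]
    calls: list[MdtCall] = []
    for gene_id in matrix.genes:
        transcripts = matrix.transcripts_of(gene_id)
        values = column.loc[transcripts].to_numpy()
        order = np.argsort(values, kind="stable")[::-1]
        top = float(values[order[0]])
        second = float(values[order[1]]) if len(values) > 1 else 0.0
        if top < floor:
            continue
        if second > 0 and top < dominance_fold * second:
            continue
        if len(values) > 1 and top == second:
            continue  # ties: no dominant transcript
        calls.append(
            MdtCall(
                sample_id=sample_id,
                gene_id=gene_id,
                transcript_id=transcripts[int(order[0])],
                tpm=top,
                second_tpm=second,
                cohort_role=cohort_role,
            )
        )
    return calls


def identify_mdt_cohort(
    matrix: ExpressionMatrix,
    sample_ids,
    cohort_role: str,
    dominance_fold: float = DOMINANCE_FOLD,
    min_tpm: float | None = None,
) -> list[MdtCall]:
    """Vectorized MDT calling over many samples at once."""
    floor = _min_tpm(cohort_role) if min_tpm is None else min_tpm
    sample_ids = list(sample_ids)
    missing = [s for s in sample_ids if s not in matrix.tpm.columns]
    if missing:
        raise KeyError(f"unknown samples {missing[:5]}")
    calls: list[MdtCall] = []
    sub = matrix.tpm[sample_ids]
    for gene_id in matrix.genes:
        transcripts = matrix.transcripts_of(gene_id)
        block = sub.loc[transcripts].to_numpy()  # transcripts x samples
        if block.shape[0] == 1:
            top_idx = np.zeros(block.shape[1], dtype=int)
            top = block[0]
            second = np.zeros_like(top)
        else:
            order = np.argsort(block, axis=0, kind="stable")
            top_idx = order[-1]
            cols = np.arange(block.shape[1])
            top = block[top_idx, cols]
            second = block[order[-2], cols]
        ok = (top >= floor) & ((second == 0) | (top >= dominance_fold * second))
        if block.shape[0] > 1:
            ok &= top != second
        for j in np.nonzero(ok)[0]:
            calls.append(
                MdtCall(
                    sample_id=sample_ids[j],
                    gene_id=gene_id,
                    transcript_id=transcripts[int(top_idx[j])],
                    tpm=float(top[j]),
                    second_tpm=float(second[j]),
                    cohort_role=cohort_role,
                )
            )
    return calls


def compute_relative_expression(
    matrix: ExpressionMatrix, transcript_id: str, sample_id: str
) -> RelativeExpression:
    """Transcript TPM over the summed TPM of its gene in the same sample."""
    if transcript_id not in matrix.transcript_to_gene:
        raise KeyError(f"unknown transcript {transcript_id!r}")
    gene_id = matrix.transcript_to_gene[transcript_id]
    transcripts = matrix.transcripts_of(gene_id)
    total = float(matrix.tpm.loc[transcripts, sample_id].sum())
    if total == 0.0:
        return RelativeExpression(transcript_id, sample_id, 0.0, defined=False)
    value = float(matrix.tpm.at[transcript_id, sample_id]) / total
    return RelativeExpression(transcript_id, sample_id, value, defined=True)


def relative_expression_profile(
    matrix: ExpressionMatrix, transcript_id: str, sample_ids
) -> list[RelativeExpression]:
    gene_id = matrix.transcript_to_gene[transcript_id]
    transcripts = matrix.transcripts_of(gene_id)
    block = matrix.tpm.loc[transcripts, list(sample_ids)]
    totals = block.sum(axis=0)
    row = block.loc[transcript_id]
    out = []
    for sample_id in sample_ids:
        total = float(totals[sample_id])
        if total == 0.0:
            out.append(RelativeExpression(transcript_id, sample_id, 0.0, False))
        else:
            out.append(
                RelativeExpression(
                    transcript_id, sample_id, float(row[sample_id]) / total, True
                )
            )
    return out


def sign_test_mdt(
    cancer_rel: float, normal_rels, two_sided: str = "minlike"
) -> tuple[int, int, float]:
    """Sign test of one tumor relative expression against a normal cohort.

    Counts how many normal-sample values lie strictly below
    (``n_higher``) and strictly above (``n_lower``) the tumor value; ties
    are excluded from both counts. The counts feed an exact two-sided
    binomial test with success probability 0.5; zero informative
    comparisons give p = 1.

    ``two_sided`` selects the two-sided p-value construction:
    ``"minlike"`` (sum of outcome probabilities no larger than the
    observed one; the standard exact binomial convention) or
    ``"double"`` (twice the smaller tail, capped at 1).
    """
    if len(normal_rels) == 0:
        raise ValueError("empty normal cohort")
    values = np.asarray(list(normal_rels), dtype=float)
    n_higher = int((values < cancer_rel).sum())
    n_lower = int((values > cancer_rel).sum())
    n = n_higher + n_lower
    if n == 0:
        return 0, 0, 1.0
    if two_sided == "minlike":
        p = float(stats.binomtest(n_higher, n, 0.5, alternative="two-sided").pvalue)
    elif two_sided == "double":
        tail = stats.binom.cdf(min(n_higher, n_lower), n, 0.5)
        p = float(min(1.0, 2.0 * tail))
    else:
        raise ValueError(f"unknown two-sided method {two_sided!r}")
    return n_higher, n_lower, min(p, 1.0)


def call_cmdt(
    tumor_mdts: list[MdtCall],
    normal_mdts: list[MdtCall],
    tumor_matrix: ExpressionMatrix,
    normal_matrix: ExpressionMatrix,
    cohort: CohortPair,
    q_threshold: float = 0.01,
    uniqueness_scope: str = "all_normals",
    two_sided: str = "minlike",
) -> list[CmdtCall]:
    """Promote tumor MDTs to cancer-specific MDTs.

    Sign-test p-values are computed for every tumor MDT of the cancer
    type and Benjamini-Hochberg adjusted as one family; the four
    specificity criteria and the q threshold are then applied.

    ``uniqueness_scope`` controls criterion 1: ``"all_normals"`` rejects a
    transcript that is an MDT anywhere in ``normal_mdts`` (the whole
    normal compendium passed in), ``"matched"`` only within the matched
    cohort's samples.
    """
    if uniqueness_scope not in ("all_normals", "matched"):
        raise ValueError(f"unknown uniqueness scope {uniqueness_scope!r}")
    matched_normals = sorted(cohort.normal_samples)
    if not matched_normals:
        raise ValueError("cohort has no normal samples")

    if uniqueness_scope == "matched":
        normal_mdt_transcripts = {
            m.transcript_id for m in normal_mdts if m.sample_id in cohort.normal_samples
        }
    else:
        normal_mdt_transcripts = {m.transcript_id for m in normal_mdts}
    # criterion 2: fraction of matched normals in which the gene has an MDT
    gene_mdt_samples: dict[str, set[str]] = {}
    for m in normal_mdts:
        if m.sample_id in cohort.normal_samples:
            gene_mdt_samples.setdefault(m.gene_id, set()).add(m.sample_id)

    tumor_mdts = [m for m in tumor_mdts if m.sample_id in cohort.tumor_samples]

    # sign test for every tumor MDT; normal relative expressions are cached
    # per transcript since all tumor samples share the matched cohort
    normal_rel_cache: dict[str, tuple[np.ndarray, float]] = {}

    def normal_rels(transcript_id: str) -> tuple[np.ndarray, float]:
        if transcript_id not in normal_rel_cache:
            profile = relative_expression_profile(
                normal_matrix, transcript_id, matched_normals
            )
            values = np.array([r.value for r in profile if r.defined])
            median = float(np.median(values)) if values.size else float("nan")
            normal_rel_cache[transcript_id] = (values, median)
        return normal_rel_cache[transcript_id]

    tested: list[tuple[MdtCall, float, int, int, float, float]] = []
    for mdt in tumor_mdts:
        if mdt.transcript_id not in normal_matrix.transcript_to_gene:
            continue
        rel = compute_relative_expression(tumor_matrix, mdt.transcript_id, mdt.sample_id)
        values, median = normal_rels(mdt.transcript_id)
        if values.size == 0:
            continue
        n_higher, n_lower, p = sign_test_mdt(rel.value, values, two_sided=two_sided)
        tested.append((mdt, rel.value, n_higher, n_lower, p, median))

    if not tested:
        return []
    pvalues = np.array([t[4] for t in tested])
    qvalues = multipletests(pvalues, method="fdr_bh")[1]

    calls: list[CmdtCall] = []
    n_matched = len(matched_normals)
    for (mdt, rel_value, n_higher, n_lower, p, median), q in zip(tested, qvalues):
        if mdt.transcript_id in normal_mdt_transcripts:
            continue  # criterion 1: unique to the tumor cohort
        if len(gene_mdt_samples.get(mdt.gene_id, ())) < 0.5 * n_matched:
            continue  # criterion 2: gene has stable MDT behaviour in normals
        if q >= q_threshold:
            continue  # criterion 3: significant shift in relative expression
        if not rel_value > median:
            continue  # criterion 4: elevated relative expression
        calls.append(
            CmdtCall(
                sample_id=mdt.sample_id,
                gene_id=mdt.gene_id,
                transcript_id=mdt.transcript_id,
                rel_expr=rel_value,
                n_higher=n_higher,
                n_lower=n_lower,
                p_value=float(p),
                q_value=float(q),
                normal_median_rel_expr=median,
            )
        )
    return calls


def recurrent_cmdt(
    calls: list[CmdtCall],
    cohort: CohortPair,
    other_cohorts: dict[str, list[CmdtCall]] | None = None,
) -> pd.DataFrame:
    """Per-transcript recurrence table for one cancer type.

    Frequency is the percentage of the tumor cohort carrying the call.
    With ``other_cohorts`` given (cancer type -> calls), transcripts seen
    in no other cohort are flagged cancer-type specific.
    """
    n = len(cohort.tumor_samples)
    counts: dict[tuple[str, str], set[str]] = {}
    for call in calls:
        counts.setdefault((call.gene_id, call.transcript_id), set()).add(call.sample_id)
    elsewhere: set[str] = set()
    if other_cohorts:
        for calls_other in other_cohorts.values():
            elsewhere.update(c.transcript_id for c in calls_other)
    rows = []
    for (gene_id, transcript_id), samples in sorted(counts.items()):
        freq = 100.0 * len(samples) / n
        rows.append(
            {
                "gene_id": gene_id,
                "transcript_id": transcript_id,
                "n_samples": len(samples),
                "frequency_pct": freq,
                "in_all_samples": len(samples) == n,
                "cancer_type_specific": (
                    transcript_id not in elsewhere if other_cohorts is not None else pd.NA
                ),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "transcript_id",
            "n_samples",
            "frequency_pct",
            "in_all_samples",
            "cancer_type_specific",
        ],
    )


def mdt_frame(calls: list[MdtCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [vars(c) for c in calls],
        columns=["sample_id", "gene_id", "transcript_id", "tpm", "second_tpm", "cohort_role"],
    )


def cmdt_frame(calls: list[CmdtCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [vars(c) for c in calls],
        columns=[
            "sample_id",
            "gene_id",
            "transcript_id",
            "rel_expr",
            "n_higher",
            "n_lower",
            "p_value",
            "q_value",
            "normal_median_rel_expr",
        ],
    )
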