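"""Cis-mutation association with transcript expression.

Within one cancer type, each transcript's samples are split into a
*Mutated* group (the transcript's gene carries at least one variant in a
cis functional region — promoter core/domain, 5'UTR, coding sequence,
splice site, 3'UTR — in that sample) and a *Wildtype* group. Expression
differences are tested with a two-sided Wilcoxon rank-sum test (exact
permutation enumeration for small groups, tie-corrected normal
approximation otherwise), Benjamini-Hochberg corrected per cancer type.
A transcript is only tested when at least five samples are mutated.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from isonet.io import REGION_CLASSES, ExpressionMatrix, MutationRecord

CIS_REGIONS = REGION_CLASSES  # all six functional classes count as cis
MIN_MUTATED = 5
EXACT_MAX_N = 8  # largest group size for which the exact permutation law is used


@dataclass(frozen=True)
class AssociationRecord:
    cancer_type: str
    transcript_id: str
    n_mutated: int
    n_wildtype: int
    statistic: float
    p_value: float
    q_value: float
    direction: int  # sign of median(mutated) - median(wildtype)
    significant: bool


def assign_groups(
    matrix: ExpressionMatrix,
    mutations: list[MutationRecord],
    cohort_samples,
) -> dict[str, tuple[frozenset[str], frozenset[str]]]:
    """Split the cohort into mutated/wildtype sample sets per transcript.

    A sample is *Mutated* for transcript ``t`` iff its gene carries at
    least one cis-region mutation in that sample; every other cohort
    sample is *Wildtype*. The result is independent of mutation record
    order and of repeated records.
    """
    cohort = frozenset(cohort_samples)
    mutated_by_gene: dict[str, set[str]] = {}
    for record in mutations:
        if record.sample_id in cohort and record.region_class in CIS_REGIONS:
            mutated_by_gene.setdefault(record.gene_id, set()).add(record.sample_id)
    groups: dict[str, tuple[frozenset[str], frozenset[str]]] = {}
    for transcript in matrix.transcript_ids:
        gene = matrix.transcript_to_gene[transcript]
        mutated = frozenset(mutated_by_gene.get(gene, set()))
        groups[transcript] = (mutated, cohort - mutated)
    return groups


def _exact_rank_sum_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided rank-sum p by full enumeration of group assignments.

    Valid with ties; enumerates all C(n1+n2, n1) labelings of the pooled
    values and counts those whose rank sum is at least as extreme (in
    absolute deviation from its mean) as the observed one.
    """
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    n1 = len(x)
    observed = float(ranks[:n1].sum())
    mean = ranks.sum() * n1 / len(pooled)
    observed_dev = abs(observed - mean)
    count = 0
    total = comb(len(pooled), n1)
    for subset in combinations(range(len(pooled)), n1):
        if abs(float(ranks[list(subset)].sum()) - mean) >= observed_dev - 1e-12:
            count += 1
    return observed, count / total


def rank_sum_test(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test.

    Exact permutation enumeration when both groups have at most
    ``EXACT_MAX_N`` observations, tie-corrected normal approximation
    (with continuity correction) otherwise. Returns (rank-sum statistic
    of the first group, p-value).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    if max(len(x), len(y)) <= EXACT_MAX_N:
        return _exact_rank_sum_p(x, y)
    result = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    rank_sum = float(result.statistic) + len(x) * (len(x) + 1) / 2.0
    return rank_sum, float(result.pvalue)


def test_association(
    groups: dict[str, tuple[frozenset[str], frozenset[str]]],
    matrix: ExpressionMatrix,
    cancer_type: str,
    q_threshold: float = 0.01,
    min_mutated: int = MIN_MUTATED,
) -> list[AssociationRecord]:
    """Rank-sum association tests over all eligible transcripts.

    Eligibility: at least ``min_mutated`` mutated samples, a non-empty
    wildtype group, at least one non-zero expression value in each
    group, and non-constant pooled expression. BH correction is applied
    over all tested transcripts of the cancer type.
    """
    tested: list[tuple[str, int, int, float, float, int]] = []
    for transcript in matrix.transcript_ids:
        mutated, wildtype = groups.get(transcript, (frozenset(), frozenset()))
        if len(mutated) < min_mutated or not wildtype:
            continue
        x = matrix.tpm.loc[transcript, sorted(mutated)].to_numpy(dtype=float)
        y = matrix.tpm.loc[transcript, sorted(wildtype)].to_numpy(dtype=float)
        if not (x > 0).any() or not (y > 0).any():
            continue
        if np.ptp(np.concatenate([x, y])) == 0:
            continue  # constant expression: statistic undefined
        statistic, p = rank_sum_test(x, y)
        direction = int(np.sign(np.median(x) - np.median(y)))
        tested.append((transcript, len(x), len(y), statistic, p, direction))
    if not tested:
        return []
    qvalues = multipletests([t[4] for t in tested], method="fdr_bh")[1]
    return [
        AssociationRecord(
            cancer_type=cancer_type,
            transcript_id=transcript,
            n_mutated=n1,
            n_wildtype=n2,
            statistic=statistic,
            p_value=p,
            q_value=float(q),
            direction=direction,
            significant=bool(q <= q_threshold),
        )
        for (transcript, n1, n2, statistic, p, direction), q in zip(tested, qvalues)
    ]


def load_correlation(cmdt_counts: dict[str, int], variant_counts: dict[str, int]) -> float:
    """Spearman rank correlation between per-sample switch and variant load.

    Counts are aligned by sample id (intersection); ties receive average
    ranks. Requires at least three shared samples.
    """
    shared = sorted(set(cmdt_counts) & set(variant_counts))
    if len(shared) < 3:
        raise ValueError("need at least 3 samples with both counts")
    x = np.asarray([cmdt_counts[s] for s in shared], dtype=float)
    y = np.asarray([variant_counts[s] for s in shared], dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")  # constant load: rank correlation undefined
    rho = stats.spearmanr(x, y).statistic
    return float(rho)
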