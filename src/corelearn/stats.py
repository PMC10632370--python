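"""External-validation statistics for candidate gene sets.

Candidate sets produced by the ensemble are validated against independent
gene-level resources: membership gene sets (mouse-knockout phenotype
orthologs, differentially expressed genes, drug targets, druggable genes)
via Fisher's exact test with odds ratios per consensus-score bin; continuous
constraint scores (LoF / missense intolerance Z) via Tukey's honestly
significant difference across the positive / candidate / non-candidate
grouping; drug-targeting degree via pairwise Wilcoxon rank-sum tests and the
fold change of medians; and candidate-vs-benchmark validation rates via a
pooled two-proportion z-test.  All p-value families are Benjamini-Hochberg
adjusted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd
from statsmodels.stats.multitest import multipletests

from .ensemble import ConsensusResult

logger = logging.getLogger("corelearn")


@dataclass
class GeneSetAnnotation:
    """A membership gene set over a background universe."""

    membership: set[int]
    background: set[int]
    name: str = "annotation"

    def __post_init__(self):
        self.membership = set(self.membership) & set(self.background)


@dataclass
class EnrichmentResult:
    a: int  # test & member
    b: int  # test & non-member
    c: int  # background-only & member
    d: int  # background-only & non-member
    odds_ratio: float
    p_value: float
    fdr: float | None = None
    bin_label: str = ""
    haldane: bool = False


@dataclass
class GroupComparison:
    groups: list[str]
    means: dict[str, float]
    comparisons: list[dict]  # group1, group2, diff, ci_low, ci_high, p_adj


def _sample_or(a: int, b: int, c: int, d: int) -> tuple[float, bool]:
    """Cross-product odds ratio with Haldane 0.5 correction on zero cells."""
    if min(a, b, c, d) == 0:
        a2, b2, c2, d2 = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        return (a2 * d2) / (b2 * c2), True
    return (a * d) / (b * c), False


def fisher_enrichment(
    test_set: set[int],
    annotation: GeneSetAnnotation,
    exclusions: set[int] | None = None,
    bin_label: str = "",
) -> EnrichmentResult:
    """Two-sided Fisher's exact test of annotation membership in the test set.

    ``exclusions`` (e.g. the known positives) are removed from the test set
    and from the background before the 2x2 table is formed.
    """
    exclusions = exclusions or set()
    background = set(annotation.background) - exclusions
    test = (set(test_set) & background) - exclusions
    if not test:
        raise ValueError("test set is empty after exclusions")
    member = annotation.membership & background
    rest = background - test
    a = len(test & member)
    b = len(test - member)
    c = len(rest & member)
    d = len(rest - member)
    odds, haldane = _sample_or(a, b, c, d)
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return EnrichmentResult(a=a, b=b, c=c, d=d, odds_ratio=odds,
                            p_value=float(p), bin_label=bin_label, haldane=haldane)


def enrichment_by_cs_bin(
    consensus: ConsensusResult,
    annotation: GeneSetAnnotation,
    known_positives: set[int],
    fdr_level: float = 0.05,
) -> list[EnrichmentResult]:
    """Cumulative enrichment per consensus-score bin k = 1..m.

    For bin k the test set is the non-positive genes with CS >= k and the
    comparison background is the non-positive genes with CS < k; BH-FDR is
    applied across the m bins.  Bins whose test set is empty are skipped.
    """
    cs = consensus.cs
    results: list[EnrichmentResult] = []
    for k in range(1, consensus.m + 1):
        test = {g for g in np.nonzero(cs >= k)[0] if g not in known_positives}
        if not test:
            logger.warning("CS bin >= %d is empty; skipped", k)
            continue
        background = {int(g) for g in np.nonzero(~np.isnan(cs))[0]} & set(
            annotation.background)
        ann = GeneSetAnnotation(annotation.membership, background, annotation.name)
        res = fisher_enrichment(test, ann, exclusions=set(known_positives),
                                bin_label=f"CS>={k}")
        results.append(res)
    if results:
        adj = multipletests([r.p_value for r in results], method="fdr_bh")[1]
        for r, q in zip(results, adj):
            r.fdr = float(q)
            if q >= fdr_level:
                r.bin_label += " (ns)"
    return results


def tukey_groups(values: dict[str, np.ndarray]) -> GroupComparison:
    """All pairwise group comparisons with studentized-range adjustment.

    Simultaneous 95% confidence intervals per Tukey's honestly significant
    difference; requires at least two groups of at least two values each.
    """
    names = list(values)
    if len(names) < 2 or any(len(values[g]) < 2 for g in names):
        raise ValueError("need >=2 groups with >=2 values each")
    data = {g: np.asarray(values[g], dtype=np.float64) for g in names}
    means = {g: float(v.mean()) for g, v in data.items()}
    endog = np.concatenate([data[g] for g in names])
    labels = np.concatenate([[g] * len(data[g]) for g in names])
    res = pairwise_tukeyhsd(endog, labels, alpha=0.05)
    comparisons = []
    for row in range(len(res.meandiffs)):
        g1 = str(res._multicomp.groupsunique[res._multicomp.pairindices[0][row]])
        g2 = str(res._multicomp.groupsunique[res._multicomp.pairindices[1][row]])
        comparisons.append({
            "group1": g1, "group2": g2,
            "diff": float(res.meandiffs[row]),
            "ci_low": float(res.confint[row, 0]),
            "ci_high": float(res.confint[row, 1]),
            "p_adj": float(res.pvalues[row]),
        })
    return GroupComparison(groups=names, means=means, comparisons=comparisons)


def drug_degree_ranksum(
    counts: dict[str, np.ndarray], fdr_level: float = 0.05
) -> list[dict]:
    """Pairwise rank-sum tests on drug-interaction counts plus median ratios.

    Only genes with at least one drug interaction belong in ``counts``.
    xDC (the median fold change) is reported relative to the second group of
    each pair; groups without eligible genes are skipped with a warning.
    """
    names = [g for g in counts if len(counts[g]) > 0]
    for g in counts:
        if len(counts[g]) == 0:
            logger.warning("group %r has no genes with drug interactions; skipped", g)
    results = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            g1, g2 = names[i], names[j]
            x, y = np.asarray(counts[g1], float), np.asarray(counts[g2], float)
            stat, p = stats.mannwhitneyu(x, y, alternative="two-sided")
            med2 = np.median(y)
            xdc = float(np.median(x) / med2) if med2 > 0 else np.inf
            results.append({"group1": g1, "group2": g2, "xdc": xdc,
                            "p_value": float(p), "u_stat": float(stat)})
    if results:
        adj = multipletests([r["p_value"] for r in results], method="fdr_bh")[1]
        for r, q in zip(results, adj):
            r["fdr"] = float(q)
            r["significant"] = bool(q < fdr_level)
    return results


def druggable_excluding_targets(
    druggable: set[int],
    targets: set[int],
    test_set: set[int],
    background: set[int],
) -> EnrichmentResult:
    """Enrichment of druggable-but-untargeted genes (the Dr- analysis).

    Known drug targets are removed from the test set and background before
    testing the remaining genes for druggable-membership enrichment.
    """
    test = set(test_set) - set(targets)
    bg = set(background) - set(targets)
    if not test:
        raise ValueError("test set is empty after removing drug targets")
    ann = GeneSetAnnotation(set(druggable) & bg, bg, name="druggable-untargeted")
    return fisher_enrichment(test, ann, bin_label="Dr-")


def compare_rates_ztest(k1: int, n1: int, k2: int, n2: int) -> tuple[float, float]:
    """Two-proportion z-test with pooled variance; returns (z, two-sided p)."""
    if n1 <= 0 or n2 <= 0:
        raise ValueError("trial counts must be positive")
    p1, p2 = k1 / n1, k2 / n2
    pooled = (k1 + k2) / (n1 + n2)
    se = np.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    if se == 0:
        return 0.0, 1.0
    z = (p1 - p2) / se
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(min(p, 1.0))


def adjust_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, capped at 1."""
    p = np.asarray(p_values, dtype=np.float64)
    if p.ndim != 1 or len(p) == 0:
        raise ValueError("expected a non-empty 1-D array of p-values")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
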