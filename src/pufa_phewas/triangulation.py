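"""Triangulation of level- and PGS-mode associations, and disease-group
relative-risk enrichment.

A metabolite-disease link is called *suggestive* when the direct (level)
and genetic (PGS) associations are both significant at the Bonferroni
threshold and point the same way (OR > 1 risk, OR < 1 protective).
Enrichment of suggestive hits in a disease group is quantified by the
relative risk

    RR = (n_sig_in_group / n_sig_total) / (n_group / n_total)

tested with a two-sided Fisher's exact test on the 2x2 count table
[[sig & group, sig & not-group], [nonsig & group, nonsig & not-group]],
with group-level significance at 0.05 / (number of groups holding at least
one significant disease).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd
from scipy.stats import fisher_exact

from .association import AssociationResult

logger = logging.getLogger(__name__)

__all__ = ["TriangulatedAssociation", "EnrichmentResult", "bonferroni_threshold",
           "triangulate", "enrichment", "overlap_counts"]


@dataclass
class TriangulatedAssociation:
    metabolite: str
    disease: str
    direction: str  # {"protective", "risk"}
    level_result: AssociationResult | None
    pgs_result: AssociationResult | None
    passes: bool
    reason: str = ""


@dataclass
class EnrichmentResult:
    group: str
    n_sig_in_group: int
    n_sig_total: int
    n_group: int
    n_total: int
    rr: float
    fisher_p: float
    significant: bool


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Family-wise threshold alpha / n_tests."""
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0,1), got {alpha}")
    if n_tests < 1:
        raise ValueError(f"n_tests must be >= 1, got {n_tests}")
    return alpha / n_tests


def triangulate(level_results: list[AssociationResult],
                pgs_results: list[AssociationResult],
                threshold: float) -> list[TriangulatedAssociation]:
    """Pair level/PGS results by (metabolite, disease) and apply the rule:
    passes iff both p <= threshold and directions concordant."""
    level = {(r.metabolite, r.disease): r for r in level_results}
    pgs = {(r.metabolite, r.disease): r for r in pgs_results}
    out = []
    for key in sorted(set(level) | set(pgs)):
        lr, pr = level.get(key), pgs.get(key)
        if lr is None or pr is None:
            missing = "level" if lr is None else "pgs"
            logger.info("pair %s missing %s-mode result", key, missing)
            some = lr or pr
            out.append(TriangulatedAssociation(
                metabolite=key[0], disease=key[1], direction=some.direction,
                level_result=lr, pgs_result=pr, passes=False,
                reason=f"missing {missing} result"))
            continue
        both_sig = lr.p <= threshold and pr.p <= threshold
        concordant = (lr.or_ > 1.0) == (pr.or_ > 1.0)
        passes = both_sig and concordant
        reason = "" if passes else ("discordant direction" if both_sig else "not significant")
        out.append(TriangulatedAssociation(
            metabolite=key[0], disease=key[1], direction=lr.direction,
            level_result=lr, pgs_result=pr, passes=passes, reason=reason))
    return out


def enrichment(significant_diseases: set[str], group_map: dict[str, str],
               alpha: float = 0.05) -> list[EnrichmentResult]:
    """Disease-group RR enrichment over the tested disease universe.

    ``group_map`` maps every tested phecode to its group (the universe);
    ``significant_diseases`` is the subset with a suggestive association.
    Significance threshold: alpha / (groups with >= 1 significant disease).
    """
    unknown = significant_diseases - set(group_map)
    if unknown:
        raise KeyError(f"significant diseases without a group: {sorted(unknown)[:5]}")
    n_total = len(group_map)
    n_sig_total = len(significant_diseases)
    groups = sorted(set(group_map.values()))
    per_group_sig = {g: sum(1 for d in significant_diseases if group_map[d] == g)
                     for g in groups}
    n_groups_with_sig = sum(1 for g in groups if per_group_sig[g] > 0)
    threshold = alpha / max(n_groups_with_sig, 1)

    out = []
    for g in groups:
        n_group = sum(1 for v in group_map.values() if v == g)
        if n_group == 0:
            raise ValueError(f"group {g!r} has zero diseases")
        a = per_group_sig[g]
        b = n_sig_total - a
        c = n_group - a
        d = (n_total - n_sig_total) - c
        if n_sig_total == 0 or n_group == 0:
            rr = float("nan")
        else:
            rr = (a / n_sig_total) / (n_group / n_total)
        _, p = fisher_exact([[a, b], [c, d]], alternative="two-sided")
        out.append(EnrichmentResult(
            group=g, n_sig_in_group=a, n_sig_total=n_sig_total,
            n_group=n_group, n_total=n_total, rr=rr, fisher_p=float(p),
            significant=bool(p <= threshold)))
    return out


def overlap_counts(triangulated: list[TriangulatedAssociation]) -> pd.DataFrame:
    """Per-disease pattern of which metabolites pass (Venn-style summary)."""
    passing = [t for t in triangulated if t.passes]
    if not passing:
        return pd.DataFrame(columns=["metabolites", "n_diseases"])
    by_disease: dict[str, set[str]] = {}
    for t in passing:
        by_disease.setdefault(t.disease, set()).add(t.metabolite)
    patterns: dict[str, int] = {}
    for mets in by_disease.values():
        key = "+".join(sorted(mets))
        patterns[key] = patterns.get(key, 0) + 1
    return (pd.DataFrame({"metabolites": list(patterns), "n_diseases": list(patterns.values())})
            .sort_values("metabolites").reset_index(drop=True))
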