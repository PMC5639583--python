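"""Sample-identity assertion and swap detection.

A sample's claimed identity is confirmed when its matched-pair concordance
across platforms sits well above the background distribution of deliberately
mismatched pairs; a swapped sample's "self" concordance falls into the
background band instead.  The separation between the self-hit and mismatch
concordance distributions is quantified with the two-sample
Kolmogorov–Smirnov statistic, overall and per relatedness stratum
(mismatches against a parent or sibling sit closer to self-hits than
mismatches against unrelated individuals).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as _stats

from .concord import PairConcordance

DEFAULT_MIN_INFORMATIVE = 200
THRESHOLD_CLAMP = (0.80, 0.99)


@dataclass
class SeparationStat:
    group_a_label: str
    group_b_label: str
    ks_statistic: float
    p_value: float
    n_a: int
    n_b: int


@dataclass
class IdentityDecision:
    sample: str
    claimed_match_concordance: float
    background_min: float
    background_median: float
    background_max: float
    threshold: float
    verdict: str  # confirmed | swap_suspected | undetermined
    n_common: int = 0


def ks_two_sample(values_a, values_b) -> SeparationStat:
    """Exact two-sample KS statistic D = sup_x |F_a(x) - F_b(x)|.

    D is computed exactly from the sorted arrays; the reported p-value is
    the asymptotic Kolmogorov approximation (auxiliary output only).
    """
    a = np.sort(np.asarray(values_a, dtype=float))
    b = np.sort(np.asarray(values_b, dtype=float))
    if a.size == 0 or b.size == 0:
        raise ValueError("ks_two_sample requires non-empty samples")
    pooled = np.concatenate([a, b])
    cdf_a = np.searchsorted(a, pooled, side="right") / a.size
    cdf_b = np.searchsorted(b, pooled, side="right") / b.size
    d = float(np.max(np.abs(cdf_a - cdf_b)))
    en = math.sqrt(a.size * b.size / (a.size + b.size))
    p = float(_stats.kstwobign.sf(en * d))
    return SeparationStat("a", "b", d, min(1.0, p), a.size, b.size)


def swap_scan(
    concordance_pairs: list[PairConcordance],
    claimed_identities: list[str] | None = None,
    min_informative: int = DEFAULT_MIN_INFORMATIVE,
    threshold: float | None = None,
    clamp: tuple[float, float] = THRESHOLD_CLAMP,
    pedigree: list[tuple[str, str, str]] | None = None,
) -> tuple[list[IdentityDecision], list[SeparationStat]]:
    """Scan full cross-product concordances for suspected sample swaps.

    For each claimed identity, the self-pair concordance is compared against
    the cohort-wide decision threshold: by default the midpoint between the
    maximum mismatched-pair concordance and the minimum matched-pair
    concordance observed, clamped into ``clamp``.  Samples whose self
    concordance falls below it are ``swap_suspected``; samples without an
    informative self pair are ``undetermined``.  When a pedigree is given,
    KS separation of self-hits from each relatedness stratum of mismatches
    is reported as well.
    """
    self_pairs: dict[str, PairConcordance] = {}
    mismatches: dict[str, list[float]] = {}
    all_self, all_mis = [], []
    for p in concordance_pairs:
        if not p.defined:
            continue
        if p.sample_a == p.sample_b:
            self_pairs.setdefault(p.sample_a, p)
            all_self.append(p.concordance)
        else:
            mismatches.setdefault(p.sample_a, []).append(p.concordance)
            mismatches.setdefault(p.sample_b, []).append(p.concordance)
            all_mis.append(p.concordance)
    if claimed_identities is None:
        claimed_identities = sorted(set(self_pairs) | set(mismatches))
    if threshold is None:
        if all_self and all_mis:
            mid = 0.5 * (max(all_mis) + min(all_self))
        elif all_self:
            mid = min(all_self) - 0.01
        else:
            mid = clamp[0]
        threshold = float(np.clip(mid, *clamp))
    decisions = []
    for s in claimed_identities:
        bg = mismatches.get(s, [])
        bg_min = min(bg) if bg else float("nan")
        bg_med = float(np.median(bg)) if bg else float("nan")
        bg_max = max(bg) if bg else float("nan")
        p = self_pairs.get(s)
        if p is None or p.n_common < min_informative:
            decisions.append(
                IdentityDecision(s, float("nan"), bg_min, bg_med, bg_max, threshold, "undetermined")
            )
            continue
        verdict = "confirmed" if p.concordance >= threshold else "swap_suspected"
        decisions.append(
            IdentityDecision(s, p.concordance, bg_min, bg_med, bg_max, threshold, verdict, p.n_common)
        )
    strata = _stratum_separation(concordance_pairs, all_self, pedigree)
    return decisions, strata


def _relatedness_strata(pedigree) -> dict[frozenset, str]:
    """Classify sample pairs from a (child, father, mother) pedigree into
    parent_child / siblings / second_order strata."""
    parents = {c: {f, m} for c, f, m in pedigree}
    strata: dict[frozenset, str] = {}
    kids = list(parents)
    for c, ps in parents.items():
        for p in ps:
            strata[frozenset((c, p))] = "parent_child"
    for i, a in enumerate(kids):
        for b in kids[i + 1 :]:
            shared = parents[a] & parents[b]
            if len(shared) == 2:
                strata[frozenset((a, b))] = "siblings"
            elif len(shared) == 1:
                strata[frozenset((a, b))] = "second_order"
    # grandparent / avuncular second-order links via a connecting parent
    for c, ps in parents.items():
        for p in ps:
            for gp in parents.get(p, ()):  # grandparents
                strata.setdefault(frozenset((c, gp)), "second_order")
    return strata


def _stratum_separation(pairs, self_values, pedigree) -> list[SeparationStat]:
    if not self_values:
        return []
    strata_map = _relatedness_strata(pedigree) if pedigree else {}
    groups: dict[str, list[float]] = {}
    for p in pairs:
        if p.sample_a == p.sample_b or not p.defined:
            continue
        stratum = strata_map.get(frozenset((p.sample_a, p.sample_b)), "unrelated")
        groups.setdefault(stratum, []).append(p.concordance)
    out = []
    for stratum in ("parent_child", "siblings", "second_order", "unrelated"):
        vals = groups.get(stratum)
        if not vals:
            continue
        stat = ks_two_sample(self_values, vals)
        stat.group_a_label = "self_hits"
        stat.group_b_label = stratum
        out.append(stat)
    return out
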