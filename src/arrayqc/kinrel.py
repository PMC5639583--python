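"""KING-robust kinship, IBS sharing, and rule-based relationship calls.

The between-family KING-robust estimator infers the kinship coefficient phi
of a sample pair from heterozygote and opposite-homozygote counts alone,

    phi_hat = (N_AaAa - 2 N_AAaa) / (2 min(N_Aa^i, N_Aa^j))
              - (N_Aa^i + N_Aa^j) / (4 min(N_Aa^i, N_Aa^j)) + 1/2,

which is unbiased for unrelated pairs under arbitrary population structure
(its expectation cancels allele-frequency terms).  Expected values: 0.5 for
duplicates/MZ twins, 0.25 for first-degree pairs, 0.125 for second-degree,
0 for unrelated.  Kinship alone cannot separate parent-offspring from full
siblings; the IBS0 proportion (opposite homozygotes) resolves them, since a
parent-offspring pair shares at least one allele at every marker in the
absence of genotyping error (IBS0 = 0), while full siblings show IBS0 of
roughly p^2 q^2 / 2 per marker.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .genio import MISSING, GenotypeMatrix, MarkerManifest

DEFAULT_MIN_MARKERS = 100
#: powers-of-two midpoint kinship cutoffs (KING's standard degree bands)
DUP_CUTOFF = 2 ** -1.5       # 0.3536
FIRST_CUTOFF = 2 ** -2.5     # 0.1768
SECOND_CUTOFF = 2 ** -3.5    # 0.0884
UNRELATED_CUTOFF = 2 ** -4.5 # 0.0442
DEFAULT_IBS0_PO_THRESHOLD = 0.012
DEFAULT_IBS0_SIB_MAX = 0.04


@dataclass
class KinshipResult:
    sample_a: str
    sample_b: str
    n_used: int
    n_het_a: int
    n_het_b: int
    n_both_het: int
    n_opp_hom: int
    ibs0: float
    ibs1: float
    ibs2: float
    kinship: float
    relationship_call: str = ""


def king_robust(
    matrix: GenotypeMatrix,
    sample_a: str,
    sample_b: str,
    min_markers: int = DEFAULT_MIN_MARKERS,
) -> KinshipResult:
    """KING-robust kinship for one pair on an (autosomal, bi-allelic,
    blacklist-filtered) matrix.  Pairs with too few jointly observed markers
    or no heterozygotes in either sample come back ``undetermined``."""
    a = matrix.row(sample_a)
    b = matrix.row(sample_b)
    return _king_from_rows(sample_a, sample_b, a, b, min_markers)


def _king_from_rows(sa, sb, a, b, min_markers) -> KinshipResult:
    both = (a != MISSING) & (b != MISSING)
    n_used = int(both.sum())
    av, bv = a[both], b[both]
    het_a = int((av == 1).sum())
    het_b = int((bv == 1).sum())
    both_het = int(((av == 1) & (bv == 1)).sum())
    opp_hom = int((np.abs(av.astype(np.int16) - bv.astype(np.int16)) == 2).sum())
    ibs2_n = int((av == bv).sum())
    if n_used == 0:
        return KinshipResult(sa, sb, 0, 0, 0, 0, 0, float("nan"), float("nan"), float("nan"), float("nan"), "undetermined")
    ibs0 = opp_hom / n_used
    ibs2 = ibs2_n / n_used
    ibs1 = 1.0 - ibs0 - ibs2
    min_het = min(het_a, het_b)
    if n_used < min_markers or min_het == 0:
        return KinshipResult(sa, sb, n_used, het_a, het_b, both_het, opp_hom, ibs0, ibs1, ibs2, float("nan"), "undetermined")
    phi = (
        (both_het - 2.0 * opp_hom) / (2.0 * min_het)
        - (het_a + het_b) / (4.0 * min_het)
        + 0.5
    )
    return KinshipResult(sa, sb, n_used, het_a, het_b, both_het, opp_hom, ibs0, ibs1, ibs2, phi)


def classify_relationship(
    result: KinshipResult,
    ibs0_po_threshold: float = DEFAULT_IBS0_PO_THRESHOLD,
    ibs0_sib_max: float = DEFAULT_IBS0_SIB_MAX,
) -> str:
    """Map a kinship estimate to a relationship call.

    Degree bands are the standard powers-of-two midpoints on phi; within the
    first-degree band IBS0 separates parent-child (IBS0 below the threshold;
    exactly 0 without genotyping error) from siblings, with an upper guard
    above which the pair is flagged ``first_degree_ambiguous``.
    """
    phi = result.kinship
    if not np.isfinite(phi):
        return "undetermined"
    if phi > DUP_CUTOFF:
        call = "duplicate_or_MZ"
    elif phi > FIRST_CUTOFF:
        if result.ibs0 < ibs0_po_threshold:
            call = "parent_child"
        elif result.ibs0 > ibs0_sib_max:
            call = "first_degree_ambiguous"
        else:
            call = "siblings"
    elif phi > SECOND_CUTOFF:
        call = "second_order"
    elif phi > UNRELATED_CUTOFF:
        call = "third_order"
    else:
        call = "unrelated"
    return call


def kinship_matrix(
    matrix: GenotypeMatrix,
    pairs: list[tuple[str, str]] | None = None,
    pedigree: list[tuple[str, str, str]] | None = None,
    min_markers: int = DEFAULT_MIN_MARKERS,
) -> tuple[list[KinshipResult], list[dict]]:
    """Kinship for all sample pairs (or a provided pair list), with
    relationship calls filled in.  When a pedigree is supplied, pairs whose
    call disagrees with the pedigree expectation are returned as a
    discrepancy list (the classic route to uncovering mislabeled relatives).
    """
    if pairs is None:
        pairs = list(combinations(matrix.sample_ids, 2))
    idx = {s: i for i, s in enumerate(matrix.sample_ids)}
    results = []
    for sa, sb in pairs:
        r = _king_from_rows(sa, sb, matrix.calls[idx[sa]], matrix.calls[idx[sb]], min_markers)
        if r.relationship_call != "undetermined":
            r.relationship_call = classify_relationship(r)
        results.append(r)
    discrepancies = []
    if pedigree is not None:
        expected = _pedigree_expectations(pedigree)
        for r in results:
            key = frozenset((r.sample_a, r.sample_b))
            exp = expected.get(key)
            if exp is None:
                continue
            ok = r.relationship_call == exp or (
                exp in ("parent_child", "siblings")
                and r.relationship_call in ("first_degree_ambiguous",)
            )
            if not ok:
                discrepancies.append(
                    {
                        "sample_a": r.sample_a,
                        "sample_b": r.sample_b,
                        "pedigree_relationship": exp,
                        "called_relationship": r.relationship_call,
                        "kinship": r.kinship,
                        "ibs0": r.ibs0,
                    }
                )
    return results, discrepancies


def _pedigree_expectations(pedigree) -> dict[frozenset, str]:
    parents = {c: {f, m} for c, f, m in pedigree}
    out: dict[frozenset, str] = {}
    for c, ps in parents.items():
        for p in ps:
            out[frozenset((c, p))] = "parent_child"
    kids = list(parents)
    for i, a in enumerate(kids):
        for b in kids[i + 1 :]:
            shared = parents[a] & parents[b]
            if len(shared) == 2:
                out[frozenset((a, b))] = "siblings"
            elif len(shared) == 1:
                out[frozenset((a, b))] = "second_order"
    return out


def results_to_frame(results: list[KinshipResult]) -> pd.DataFrame:
    """KING-style table: ID1, ID2, N_SNP, HetHet, IBS0, Kinship, InfType."""
    return pd.DataFrame(
        [
            (r.sample_a, r.sample_b, r.n_used, r.n_both_het, r.ibs0, r.kinship, r.relationship_call)
            for r in results
        ],
        columns=["ID1", "ID2", "N_SNP", "HetHet", "IBS0", "Kinship", "InfType"],
    )


def autosomal_matrix(matrix: GenotypeMatrix, manifest: MarkerManifest) -> GenotypeMatrix:
    """Restrict a matrix to autosomal (non-PAR) markers for kinship use."""
    keep = [m for m in matrix.marker_ids if m in set(manifest.autosomal_ids())]
    return matrix.subset_markers(keep)
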