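"""Sex inference from X/Y marker behaviour and a minimal mitochondrial
haplogroup matcher for sparse marker panels.

Sex calls rest on two signals that are near-binary in clean data: X
heterozygosity (males are hemizygous, so het calls on non-PAR X markers come
only from genotyping error) and Y call rate (female Y assays fail to
genotype).  A wide ambiguous band between the male and female thresholds
avoids silent errors on noisy samples.

Haplogroup matching scores each node of a phylogenetic tree by the fraction
of its root-to-node defining variants that are both observable on the panel
and matched by the sample, breaking ties toward the more general (shallower)
branch.  On a panel of only a few dozen mitochondrial SNPs this reproduces
the characteristic behaviour of sparse-panel classifiers: calls are correct
but truncated to an ancestral branch of the true fine-grained haplogroup.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genio import MISSING, GenotypeMatrix, MarkerManifest


@dataclass
class SexInference:
    sample: str
    x_heterozygosity: float
    y_callrate: float
    inferred: str  # male | female | ambiguous
    self_reported: str | None = None
    mismatch_flag: bool = False
    reason: str = ""


@dataclass
class HaplogroupNode:
    name: str
    parent: str | None
    defining_variants: list[tuple[int, str]]  # (MT position, derived allele)


@dataclass
class HaplogroupCall:
    node: str
    score: float
    specificity_depth: int
    n_matched: int
    n_observable: int
    low_confidence: bool


def infer_sex(
    matrix: GenotypeMatrix,
    manifest: MarkerManifest,
    self_reported: dict[str, str] | None = None,
    x_het_male_max: float = 0.05,
    x_het_female_min: float = 0.15,
    y_call_male_min: float = 0.8,
    y_call_female_max: float = 0.2,
    min_x_markers: int = 20,
    min_y_markers: int = 10,
) -> list[SexInference]:
    """Call genetic sex per sample from X heterozygosity and Y call rate.

    PAR markers are excluded from both statistics (they behave autosomally
    in both sexes).  Samples with too few informative markers, or with a
    signal pattern between the male and female bands, are ``ambiguous``.
    """
    x_ids = [m for m in manifest.ids_in_category("X") if m in set(matrix.marker_ids)]
    y_ids = [m for m in manifest.ids_in_category("Y") if m in set(matrix.marker_ids)]
    xm = matrix.subset_markers(x_ids).calls if x_ids else np.empty((matrix.n_samples, 0), np.int8)
    ym = matrix.subset_markers(y_ids).calls if y_ids else np.empty((matrix.n_samples, 0), np.int8)
    out = []
    for i, s in enumerate(matrix.sample_ids):
        x_obs = xm[i] != MISSING
        n_x = int(x_obs.sum())
        x_het = float((xm[i][x_obs] == 1).mean()) if n_x else float("nan")
        y_call = float((ym[i] != MISSING).mean()) if ym.shape[1] else float("nan")
        reason = ""
        if n_x < min_x_markers or ym.shape[1] < min_y_markers:
            inferred = "ambiguous"
            reason = f"insufficient markers (X non-missing {n_x}, Y assayed {ym.shape[1]})"
        elif x_het <= x_het_male_max and y_call >= y_call_male_min:
            inferred = "male"
        elif x_het >= x_het_female_min and y_call <= y_call_female_max:
            inferred = "female"
        else:
            inferred = "ambiguous"
            reason = f"signals inconsistent (x_het={x_het:.3f}, y_callrate={y_call:.3f})"
        reported = (self_reported or {}).get(s)
        mismatch = inferred != "ambiguous" and reported is not None and reported != inferred
        out.append(SexInference(s, x_het, y_call, inferred, reported, mismatch, reason))
    return out


# ---------------------------------------------------------------------------
# haplogroup tree


def toy_phylotree() -> list[HaplogroupNode]:
    """A small synthetic mtDNA phylogeny for tests and simulation.

    Covers the major branches seen on sparse array panels (L/M/N backbone,
    C, D, A, W, R, HV, H, B, T, K) with a few fine-grained leaves whose
    deeper defining variants are deliberately off typical panels, so that
    sparse-panel truncation behaviour is exercised.  Positions and alleles
    are synthetic, not real PhyloTree variants.
    """
    n = HaplogroupNode
    return [
        n("L", None, []),
        n("L2", "L", [(146, "C")]),
        n("L2a1c", "L2", [(2789, "T"), (7175, "C")]),
        n("L3", "L", [(769, "A"), (1018, "A")]),
        n("M", "L3", [(489, "C"), (10400, "T")]),
        n("C", "M", [(3552, "A"), (9545, "G")]),
        n("C1", "C", [(6026, "A")]),
        n("C1d", "C1", [(7697, "A"), (16051, "G")]),
        n("D", "M", [(4883, "T"), (5178, "A")]),
        n("D4", "D", [(3010, "A")]),
        n("D4j", "D4", [(11696, "A")]),
        n("M7", "M", [(6455, "T"), (9824, "C")]),
        n("N", "L3", [(8701, "G"), (9540, "C")]),
        n("A", "N", [(1736, "G"), (4824, "G")]),
        n("W", "N", [(1243, "C"), (5460, "A")]),
        n("R", "N", [(12705, "C"), (16223, "C")]),
        n("HV", "R", [(14766, "C")]),
        n("H", "HV", [(2706, "A"), (7028, "C")]),
        n("H5", "H", [(456, "T")]),
        n("H5a3b", "H5", [(4336, "C"), (15833, "T")]),
        n("B", "R", [(8281, "d"), (16189, "C")]),
        n("B2", "B", [(4977, "C"), (11177, "T")]),
        n("B4", "B", [(16217, "C")]),
        n("T", "R", [(709, "A"), (4917, "G")]),
        n("T2b", "T", [(5147, "A")]),
        n("K", "R", [(3480, "G"), (9055, "A"), (11299, "C")]),
    ]


def _index(tree: list[HaplogroupNode]) -> dict[str, HaplogroupNode]:
    idx = {n.name: n for n in tree}
    roots = [n for n in tree if n.parent is None]
    if len(roots) != 1:
        raise ValueError(f"tree must have exactly one root, found {len(roots)}")
    for n in tree:
        if n.parent is not None and n.parent not in idx:
            raise ValueError(f"node {n.name} has unknown parent {n.parent}")
    return idx


def path_to_root(node: str, tree: list[HaplogroupNode]) -> list[HaplogroupNode]:
    """Nodes from the root down to ``node`` (inclusive)."""
    idx = _index(tree)
    path = []
    cur: str | None = node
    seen = set()
    while cur is not None:
        if cur in seen:
            raise ValueError(f"cycle in haplogroup tree at {cur}")
        seen.add(cur)
        path.append(idx[cur])
        cur = idx[cur].parent
    return path[::-1]


def path_variants(node: str, tree: list[HaplogroupNode]) -> list[tuple[int, str]]:
    """Cumulative defining variants from the root down to ``node``."""
    out = []
    for n in path_to_root(node, tree):
        out.extend(n.defining_variants)
    return out


def assign_haplogroup(
    mt_calls: dict[int, str],
    tree: list[HaplogroupNode],
    low_confidence_score: float = 0.8,
) -> HaplogroupCall:
    """Match sparse mitochondrial calls to the best-supported tree node.

    ``mt_calls`` maps MT position to the called allele.  Each node is scored
    as (matched defining variants on its root path) / (defining variants on
    that path observable among the called positions); nodes with no
    observable path variants score 0.  Nodes are ranked by score, then by
    matched-variant count, with remaining ties broken toward the shallower
    (more general) node.  A node whose own defining variants are all off the
    panel therefore never beats its deepest observable ancestor: calls
    truncate to the most general branch the panel can support, and a sample
    contradicting every branch falls back to the root, flagged.
    """
    if not tree:
        raise ValueError("empty haplogroup tree")
    if not mt_calls:
        raise ValueError("no mitochondrial calls supplied")
    _index(tree)  # validates
    best = None  # (score, n_matched, -depth, name, n_observable)
    for node in tree:
        path = path_to_root(node.name, tree)
        depth = len(path) - 1
        variants = [v for n in path for v in n.defining_variants]
        observable = [(p, a) for p, a in variants if p in mt_calls]
        matched = sum(1 for p, a in observable if mt_calls[p] == a)
        score = matched / len(observable) if observable else 0.0
        key = (score, matched, -depth, node.name, len(observable))
        if best is None or key[:3] > best[:3]:
            best = key
    score, matched, negdepth, name, observable = best
    return HaplogroupCall(
        node=name,
        score=score,
        specificity_depth=-negdepth,
        n_matched=matched,
        n_observable=observable,
        low_confidence=score < low_confidence_score or matched == 0,
    )


def mt_calls_from_matrix(
    matrix: GenotypeMatrix, manifest: MarkerManifest, sample: str
) -> dict[int, str]:
    """Extract one sample's non-missing mitochondrial calls as position ->
    allele (manifest alt when the haploid dosage is >=1, else ref)."""
    mt_ids = [m for m in manifest.ids_in_category("mitochondrial") if m in set(matrix.marker_ids)]
    row = matrix.subset_markers(mt_ids).row(sample)
    tab = manifest.table
    out = {}
    for m, g in zip(mt_ids, row):
        if g == MISSING:
            continue
        out[int(tab.loc[m, "pos"])] = str(tab.loc[m, "alt"] if g >= 1 else tab.loc[m, "ref"])
    return out


def haplogroup_calls(
    node: str, tree: list[HaplogroupNode], panel_positions: list[int]
) -> dict[int, str]:
    """Ideal panel calls for an individual of haplogroup ``node``: the derived
    allele at every on-path defining position present on the panel, and the
    ancestral placeholder 'r' elsewhere."""
    derived = dict(path_variants(node, tree))
    return {p: derived.get(p, "r") for p in panel_positions}
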