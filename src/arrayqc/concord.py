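"""Pairwise genotype concordance, per-marker discordance profiling, and the
under-performing-marker blacklist.

Concordance between two call sets for a pair of samples is the fraction of
marker positions, non-missing in both, at which the genotype codes match
exactly ("number of concordant positions" / "number of common positions").
Y-chromosome markers are analysed separately from the autosomal+X core
because Y call behaviour differs systematically between sexes.  Markers that
disagree between platforms for at least 10% of matched samples — and, by
default, all extended-MHC markers, whose array calls are unreliable — are
blacklisted from downstream analyses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genio import MISSING, GenotypeMatrix, MarkerManifest

DEFAULT_BLACKLIST_THRESHOLD = 0.10


@dataclass
class PairConcordance:
    sample_a: str
    sample_b: str
    n_common: int
    n_concordant: int
    concordance: float  # NaN when n_common == 0
    platform_a: str = ""
    platform_b: str = ""
    scope: str = "autosomal+X"

    @property
    def defined(self) -> bool:
        return self.n_common > 0


@dataclass
class MarkerDiscordance:
    marker_id: str
    n_samples_compared: int
    n_samples_discordant: int

    @property
    def discordant_fraction(self) -> float:
        if self.n_samples_compared == 0:
            return float("nan")
        return self.n_samples_discordant / self.n_samples_compared


def filter_for_concordance(
    matrix: GenotypeMatrix,
    manifest: MarkerManifest,
    blacklist: set[str] | None = None,
    exclude_mhc: bool = True,
) -> tuple[GenotypeMatrix, GenotypeMatrix]:
    """Split a call set into the concordance core and a separate Y matrix.

    Multi-allelic-flagged markers are removed outright; Y-category markers
    go to their own matrix; blacklisted and (by default) extended-MHC
    markers are removed from the core.
    """
    tab = manifest.table
    black = blacklist or set()
    core_ids, y_ids = [], []
    for m in matrix.marker_ids:
        if m in matrix.multiallelic:
            continue
        cat = tab.loc[m, "category"] if m in manifest else None
        if cat == "Y":
            y_ids.append(m)
            continue
        if m in black or (exclude_mhc and cat == "extended_MHC"):
            continue
        core_ids.append(m)
    return matrix.subset_markers(core_ids), matrix.subset_markers(y_ids)


def _pair_counts(row_a: np.ndarray, row_b: np.ndarray) -> tuple[int, int]:
    both = (row_a != MISSING) & (row_b != MISSING)
    n_common = int(both.sum())
    n_conc = int((row_a[both] == row_b[both]).sum())
    return n_common, n_conc


def pair_concordance(
    matrix_a: GenotypeMatrix,
    matrix_b: GenotypeMatrix,
    sample_a: str,
    sample_b: str,
    platform_a: str = "",
    platform_b: str = "",
) -> PairConcordance:
    """Concordance between one sample in each of two aligned call sets."""
    if matrix_a.marker_ids != matrix_b.marker_ids:
        raise ValueError("matrices are not aligned on the same markers")
    n_common, n_conc = _pair_counts(matrix_a.row(sample_a), matrix_b.row(sample_b))
    conc = n_conc / n_common if n_common else float("nan")
    return PairConcordance(sample_a, sample_b, n_common, n_conc, conc, platform_a, platform_b)


def concordance_matrix(
    matrix_a: GenotypeMatrix,
    matrix_b: GenotypeMatrix,
    mode: str = "matched",
    platform_a: str = "",
    platform_b: str = "",
) -> list[PairConcordance]:
    """Concordance for sample pairs across two aligned call sets.

    ``mode='matched'`` compares each shared sample id with itself;
    ``mode='cross'`` computes the full cross-product (used for mix-up
    simulation and swap scanning).
    """
    if matrix_a.marker_ids != matrix_b.marker_ids:
        raise ValueError("matrices are not aligned on the same markers")
    a_obs = matrix_a.calls != MISSING
    b_obs = matrix_b.calls != MISSING
    out = []
    if mode == "matched":
        shared = [s for s in matrix_a.sample_ids if s in set(matrix_b.sample_ids)]
        for s in shared:
            out.append(pair_concordance(matrix_a, matrix_b, s, s, platform_a, platform_b))
        return out
    if mode != "cross":
        raise ValueError(f"unknown mode: {mode}")
    # vectorized cross-product: for each a-row, compare against all b-rows
    for i, sa in enumerate(matrix_a.sample_ids):
        both = a_obs[i][None, :] & b_obs  # n_b x M
        eq = (matrix_a.calls[i][None, :] == matrix_b.calls) & both
        n_common = both.sum(axis=1)
        n_conc = eq.sum(axis=1)
        for j, sb in enumerate(matrix_b.sample_ids):
            conc = n_conc[j] / n_common[j] if n_common[j] else float("nan")
            out.append(
                PairConcordance(sa, sb, int(n_common[j]), int(n_conc[j]), conc, platform_a, platform_b)
            )
    return out


def marker_discordance_profile(
    matrix_a: GenotypeMatrix, matrix_b: GenotypeMatrix
) -> list[MarkerDiscordance]:
    """Per-marker fraction of matched samples whose two platform calls
    disagree (samples missing on either platform at that marker are excluded
    from its denominator)."""
    if matrix_a.marker_ids != matrix_b.marker_ids:
        raise ValueError("matrices are not aligned on the same markers")
    shared = [s for s in matrix_a.sample_ids if s in set(matrix_b.sample_ids)]
    ia = [matrix_a.sample_index(s) for s in shared]
    ib = [matrix_b.sample_index(s) for s in shared]
    a = matrix_a.calls[ia]
    b = matrix_b.calls[ib]
    both = (a != MISSING) & (b != MISSING)
    disc = (a != b) & both
    n_cmp = both.sum(axis=0)
    n_disc = disc.sum(axis=0)
    return [
        MarkerDiscordance(m, int(n_cmp[j]), int(n_disc[j]))
        for j, m in enumerate(matrix_a.marker_ids)
    ]


def build_blacklist(
    profiles: list[MarkerDiscordance], threshold: float = DEFAULT_BLACKLIST_THRESHOLD
) -> set[str]:
    """Markers discordant across *at least* ``threshold`` of compared samples
    (inclusive >=); markers never compared are not blacklisted."""
    out = set()
    for p in profiles:
        f = p.discordant_fraction
        if not math.isnan(f) and f >= threshold:
            out.add(p.marker_id)
    return out


def write_blacklist(blacklist: set[str], path) -> None:
    with open(path, "w") as fh:
        for m in sorted(blacklist):
            fh.write(m + "\n")


def pairs_to_frame(pairs: list[PairConcordance]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (p.sample_a, p.sample_b, p.platform_a, p.platform_b, p.n_common, p.n_concordant, p.concordance)
            for p in pairs
        ],
        columns=["sample_a", "sample_b", "platform_a", "platform_b", "n_common", "n_concordant", "concordance"],
    )
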