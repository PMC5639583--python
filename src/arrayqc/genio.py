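"""Genotype I/O: marker manifests, genotype matrices, VCF / PLINK-text readers,
allele harmonization and alignment of call sets on shared positions.

Genotypes are stored as alt-allele dosage codes in a dense ``int8`` array:
``0/1/2`` for diploid calls, ``0/1`` for haploid contexts (male Y, MT), and
``-1`` for missing.  Dosage always counts the *manifest* alt allele so that
call sets from different platforms are directly comparable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam

log = logging.getLogger(__name__)

MISSING: int = -1

#: closed category vocabulary of the marker manifest
CATEGORIES = (
    "ADME",
    "AIM",
    "blood_group",
    "fingerprint",
    "linkage",
    "extended_MHC",
    "mitochondrial",
    "X",
    "Y",
    "PAR",
)

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

MANIFEST_COLUMNS = ["marker_id", "chrom", "pos", "ref", "alt", "category", "strand"]


class FormatError(ValueError):
    """Malformed input file (names the offending record where possible)."""


class EmptyOverlapError(ValueError):
    """Two call sets share no marker positions."""


@dataclass
class MarkerManifest:
    """Per-marker coordinates, alleles, category and strand.

    Backed by a DataFrame indexed by ``marker_id`` with columns
    ``chrom, pos, ref, alt, category, strand``.  Positions are 1-based
    (VCF convention); PAR markers carry their X coordinate.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if self.table.index.name != "marker_id":
            if "marker_id" in self.table.columns:
                self.table = self.table.set_index("marker_id")
            else:
                raise FormatError("manifest lacks a marker_id column")
        if self.table.index.duplicated().any():
            dup = self.table.index[self.table.index.duplicated()][0]
            raise FormatError(f"duplicate marker_id in manifest: {dup}")
        bad = set(self.table["category"]) - set(CATEGORIES)
        if bad:
            raise FormatError(f"unknown manifest categories: {sorted(bad)}")
        self.table["chrom"] = self.table["chrom"].astype(str)

    # -- constructors -------------------------------------------------

    @classmethod
    def from_tsv(cls, path) -> "MarkerManifest":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        missing = set(MANIFEST_COLUMNS) - set(df.columns)
        if missing:
            raise FormatError(f"manifest {path} lacks columns {sorted(missing)}")
        return cls(df)

    def to_tsv(self, path) -> None:
        self.table.reset_index()[MANIFEST_COLUMNS].to_csv(path, sep="\t", index=False)

    # -- lookups ------------------------------------------------------

    def __len__(self) -> int:
        return len(self.table)

    def __contains__(self, marker_id: str) -> bool:
        return marker_id in self.table.index

    @property
    def marker_ids(self) -> list[str]:
        return list(self.table.index)

    def position_index(self) -> dict[tuple[str, int], str]:
        """Map (chrom, pos) -> marker_id. Duplicated positions map to the
        first record; callers treat extra records as multi-allelic splits."""
        out: dict[tuple[str, int], str] = {}
        for mid, row in zip(self.table.index, self.table.itertuples()):
            out.setdefault((row.chrom, int(row.pos)), mid)
        return out

    def ids_in_category(self, *categories: str) -> list[str]:
        mask = self.table["category"].isin(categories)
        return list(self.table.index[mask])

    def autosomal_ids(self) -> list[str]:
        auto = {str(c) for c in range(1, 23)}
        mask = self.table["chrom"].isin(auto) & (self.table["category"] != "PAR")
        return list(self.table.index[mask])

    def haploid_mask(self, sex: str) -> np.ndarray:
        """Boolean mask (manifest order) of markers haploid for a given sex.

        MT is haploid for everyone; Y is haploid for males (and absent in
        females); male non-PAR X is hemizygous but reported as a homozygous
        diploid call by array software, so it is *not* flagged haploid here.
        """
        cat = self.table["category"].to_numpy()
        mt = cat == "mitochondrial"
        if sex == "male":
            return mt | (cat == "Y")
        return mt


@dataclass
class GenotypeMatrix:
    """samples x markers dosage matrix, the common currency of all modules.

    ``calls[i, j]`` is the alt-allele dosage of sample ``sample_ids[i]`` at
    marker ``marker_ids[j]``; ``-1`` marks a missing call.  ``alleles`` holds
    the (ref, alt) pair observed in the source file per marker (used by
    :func:`harmonize_alleles`); ``multiallelic`` flags markers seen with more
    than one alt allele, which downstream concordance filtering removes.
    """

    sample_ids: list[str]
    marker_ids: list[str]
    calls: np.ndarray
    alleles: dict[str, tuple[str, str]] = field(default_factory=dict)
    multiallelic: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.sample_ids), len(self.marker_ids)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.marker_ids)} markers"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        if len(set(self.marker_ids)) != len(self.marker_ids):
            raise ValueError("duplicate marker ids")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise KeyError(f"unknown sample id: {sample_id}") from None

    def row(self, sample_id: str) -> np.ndarray:
        return self.calls[self.sample_index(sample_id)]

    def subset_markers(self, marker_ids) -> "GenotypeMatrix":
        marker_ids = list(marker_ids)
        pos = {m: j for j, m in enumerate(self.marker_ids)}
        idx = [pos[m] for m in marker_ids]
        return GenotypeMatrix(
            list(self.sample_ids),
            marker_ids,
            self.calls[:, idx].copy(),
            {m: self.alleles[m] for m in marker_ids if m in self.alleles},
            self.multiallelic & set(marker_ids),
        )

    def subset_samples(self, sample_ids) -> "GenotypeMatrix":
        sample_ids = list(sample_ids)
        idx = [self.sample_index(s) for s in sample_ids]
        return GenotypeMatrix(
            sample_ids,
            list(self.marker_ids),
            self.calls[idx].copy(),
            dict(self.alleles),
            set(self.multiallelic),
        )

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            list(self.sample_ids),
            list(self.marker_ids),
            self.calls.copy(),
            dict(self.alleles),
            set(self.multiallelic),
        )


# ---------------------------------------------------------------------------
# readers


def read_vcf(path, manifest: MarkerManifest) -> GenotypeMatrix:
    """Read a VCF with a GT field into a :class:`GenotypeMatrix`.

    Bi-allelic SNVs are mapped to alt-allele dosage; any GT containing a
    missing allele ('.') becomes MISSING; records at positions absent from
    the manifest, indel records, and "chromosome 0" control records are
    dropped (a count is logged).  Positions seen with more than one alt
    allele are flagged multi-allelic for downstream exclusion.
    """
    posmap = manifest.position_index()
    vf = pysam.VariantFile(str(path))
    samples = list(vf.header.samples)
    if not samples:
        raise FormatError(f"{path}: VCF has no sample columns / GT field")
    rows: dict[str, np.ndarray] = {}
    alleles: dict[str, tuple[str, str]] = {}
    multi: set[str] = set()
    n_dropped = 0
    for rec in vf:
        chrom = rec.chrom.removeprefix("chr")
        if chrom == "0":
            n_dropped += 1
            continue
        alts = rec.alts or ()
        if len(rec.ref) != 1 or any(len(a) != 1 for a in alts if a != "."):
            n_dropped += 1  # indel
            continue
        mid = posmap.get((chrom, rec.pos))
        if mid is None:
            n_dropped += 1
            continue
        if len(alts) > 1:
            multi.add(mid)
        alt = alts[0] if alts else manifest.table.loc[mid, "alt"]
        alleles[mid] = (rec.ref, alt)
        calls = np.full(len(samples), MISSING, dtype=np.int8)
        for i, s in enumerate(samples):
            gt = rec.samples[s].get("GT")
            if gt is None or any(a is None for a in gt):
                continue
            if any(a > 1 for a in gt):  # call uses a 2nd alt: multi-allelic use
                multi.add(mid)
                continue
            calls[i] = sum(gt)
        rows[mid] = calls
    if n_dropped:
        log.info("read_vcf(%s): dropped %d off-manifest/indel/control records", path, n_dropped)
    marker_ids = [m for m in manifest.marker_ids if m in rows]
    if not marker_ids:
        raise FormatError(f"{path}: no manifest-resolvable biallelic SNV records")
    mat = np.stack([rows[m] for m in marker_ids], axis=1) if marker_ids else np.empty((len(samples), 0), np.int8)
    return GenotypeMatrix(samples, marker_ids, mat, alleles, multi)


def write_vcf(matrix: GenotypeMatrix, manifest: MarkerManifest, path, sexes: dict[str, str] | None = None) -> None:
    """Write a minimal VCF 4.2. Haploid codes are written as haploid GTs
    ('0'/'1') for male Y and all MT calls; female Y rows come out './.'."""
    tab = manifest.table
    chrom_order = {c: i for i, c in enumerate(dict.fromkeys(tab["chrom"]))}
    order = sorted(
        range(len(matrix.marker_ids)),
        key=lambda j: (chrom_order[tab.loc[matrix.marker_ids[j], "chrom"]], int(tab.loc[matrix.marker_ids[j], "pos"])),
    )
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in dict.fromkeys(tab["chrom"]):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(matrix.sample_ids) + "\n")
        for j in order:
            mid = matrix.marker_ids[j]
            row = tab.loc[mid]
            haploid_all = row["category"] == "mitochondrial"
            haploid_male = row["category"] == "Y"
            gts = []
            for i, s in enumerate(matrix.sample_ids):
                g = int(matrix.calls[i, j])
                sex = (sexes or {}).get(s)
                if haploid_all or (haploid_male and sex != "female"):
                    gts.append("." if g == MISSING else str(g))
                elif haploid_male:  # female Y
                    gts.append("./.")
                else:
                    gts.append({0: "0/0", 1: "0/1", 2: "1/1"}.get(g, "./."))
            fh.write(
                f"{row['chrom']}\t{int(row['pos'])}\t{mid}\t{row['ref']}\t{row['alt']}\t.\t.\t.\tGT\t" + "\t".join(gts) + "\n"
            )


def read_plink_text(ped_path, map_path, manifest: MarkerManifest) -> GenotypeMatrix:
    """Read whitespace-delimited PLINK text PED + MAP into dosage codes.

    Allele pairs are coded against the manifest ref/alt ('0 0' is missing,
    per PLINK convention).  An allele letter matching neither manifest allele
    leaves the call missing and flags the marker in the returned matrix's
    ``multiallelic`` set.
    """
    map_rows = []
    with open(map_path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) < 4:
                raise FormatError(f"{map_path}:{ln}: expected 4 MAP columns")
            map_rows.append((parts[0].removeprefix("chr"), parts[1], int(parts[3])))
    posmap = manifest.position_index()
    marker_ids = []
    keep = []
    for k, (chrom, name, pos) in enumerate(map_rows):
        mid = posmap.get((chrom, pos), None)
        if mid is None and name in manifest:
            mid = name
        if mid is not None:
            marker_ids.append(mid)
            keep.append(k)
    samples: list[str] = []
    rows = []
    multi: set[str] = set()
    ref = manifest.table.loc[marker_ids, "ref"].to_numpy() if marker_ids else np.array([])
    alt = manifest.table.loc[marker_ids, "alt"].to_numpy() if marker_ids else np.array([])
    with open(ped_path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * len(map_rows):
                raise FormatError(
                    f"{ped_path}:{ln}: expected {6 + 2 * len(map_rows)} columns, found {len(parts)}"
                )
            samples.append(parts[1])
            calls = np.full(len(marker_ids), MISSING, dtype=np.int8)
            for out_j, k in enumerate(keep):
                a1, a2 = parts[6 + 2 * k], parts[7 + 2 * k]
                if a1 == "0" or a2 == "0":
                    continue
                dose = 0
                ok = True
                for a in (a1, a2):
                    if a == alt[out_j]:
                        dose += 1
                    elif a != ref[out_j]:
                        ok = False
                if ok:
                    calls[out_j] = dose
                else:
                    multi.add(marker_ids[out_j])
            rows.append(calls)
    alleles = {m: (r, a) for m, r, a in zip(marker_ids, ref, alt)}
    mat = np.stack(rows) if rows else np.empty((0, len(marker_ids)), np.int8)
    return GenotypeMatrix(samples, marker_ids, mat, alleles, multi)


# ---------------------------------------------------------------------------
# harmonization and alignment


@dataclass
class HarmonizeReport:
    n_flipped: int
    n_ambiguous_excluded: int
    n_irreconcilable: int
    flipped: list[str]
    excluded: list[str]
    reasons: dict[str, str]


def _is_ambiguous(ref: str, alt: str) -> bool:
    return {ref, alt} in ({"A", "T"}, {"C", "G"})


def harmonize_alleles(
    matrix: GenotypeMatrix, manifest: MarkerManifest, keep_ambiguous: bool = False
) -> tuple[GenotypeMatrix, HarmonizeReport]:
    """Reconcile each marker's stored alleles with the manifest.

    Markers whose stored (ref, alt) is the reverse complement of the
    manifest's are flipped (dosage codes are unchanged: complementing both
    alleles preserves which one is alt).  Strand-ambiguous A/T and C/G
    markers cannot be resolved without a strand report and are excluded by
    default.  Markers irreconcilable even after complementing are excluded.
    A stored pair equal to the manifest's but swapped (ref<->alt) has its
    dosages recoded ``d -> 2 - d``.
    """
    flipped, excluded, reasons = [], [], {}
    out = matrix.copy()
    want = manifest.table
    for j, mid in enumerate(matrix.marker_ids):
        stored = matrix.alleles.get(mid)
        if stored is None or mid not in manifest:
            continue
        m_ref, m_alt = want.loc[mid, "ref"], want.loc[mid, "alt"]
        if _is_ambiguous(m_ref, m_alt) and not keep_ambiguous:
            excluded.append(mid)
            reasons[mid] = "strand-ambiguous A/T or C/G"
            continue
        s_ref, s_alt = stored
        if (s_ref, s_alt) == (m_ref, m_alt):
            continue
        comp = (_COMPLEMENT.get(s_ref, "?"), _COMPLEMENT.get(s_alt, "?"))
        if comp == (m_ref, m_alt):
            flipped.append(mid)
            out.alleles[mid] = (m_ref, m_alt)
        elif (s_ref, s_alt) == (m_alt, m_ref) or comp == (m_alt, m_ref):
            # swapped orientation: recode dosage 0<->2
            col = out.calls[:, j]
            nz = col != MISSING
            col[nz] = 2 - col[nz]
            flipped.append(mid)
            out.alleles[mid] = (m_ref, m_alt)
        else:
            excluded.append(mid)
            reasons[mid] = f"alleles {s_ref}/{s_alt} irreconcilable with manifest {m_ref}/{m_alt}"
    if excluded:
        keep = [m for m in out.marker_ids if m not in set(excluded)]
        out = out.subset_markers(keep)
    report = HarmonizeReport(
        n_flipped=len(flipped),
        n_ambiguous_excluded=sum(1 for m in excluded if reasons[m].startswith("strand")),
        n_irreconcilable=sum(1 for m in excluded if not reasons[m].startswith("strand")),
        flipped=flipped,
        excluded=excluded,
        reasons=reasons,
    )
    return out, report


def align_on_shared(
    matrix_a: GenotypeMatrix,
    matrix_b: GenotypeMatrix,
    intersect_samples: bool = False,
) -> tuple[GenotypeMatrix, GenotypeMatrix]:
    """Restrict two matrices to their shared markers (and optionally shared
    samples), in identical order.  Raises :class:`EmptyOverlapError` when no
    markers are shared."""
    shared = [m for m in matrix_a.marker_ids if m in set(matrix_b.marker_ids)]
    if not shared:
        raise EmptyOverlapError("call sets share no marker positions")
    a = matrix_a.subset_markers(shared)
    b = matrix_b.subset_markers(shared)
    if intersect_samples:
        samples = [s for s in a.sample_ids if s in set(b.sample_ids)]
        if not samples:
            raise EmptyOverlapError("call sets share no sample ids")
        a = a.subset_samples(samples)
        b = b.subset_samples(samples)
    return a, b
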