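"""Synthetic multi-population cohort simulator with full ground truth.

The generative model is deliberately the one the downstream analyses assume:

* Population structure follows the Balding–Nichols model — each ancestral
  component k draws its allele frequency at marker m from a Beta
  distribution centred on an ancestral frequency p_m with variance
  F_k p_m (1 - p_m), where F_k is the component's fixation index (Fst).
* Individuals carry an admixture vector q on the K-simplex; autosomal
  genotypes are Binomial(2, sum_k q_k f_km) — Hardy–Weinberg within the
  mixed individual.
* Families obey Mendelian transmission; X is hemizygous in males (reported
  as a homozygous diploid call, as array software does), Y is paternal and
  male-only, mtDNA is maternal.
* Each "platform" is an independent noisy, partially missing copy of the
  truth genotypes.

Markers are unlinked (no LD) and there is no mutation; the simulator's
purpose is to provide cohorts whose concordance, kinship, sex, ancestry and
haplogroup structure is known exactly, not to emulate genome biology.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genio import MISSING, GenotypeMatrix, MarkerManifest
from . import sexmito

#: the nine ancestral components used throughout, with a representative
#: reference population (name, latitude, longitude, super-region) each
COMPONENT_NAMES = (
    "North East Asian",
    "Mediterranean",
    "South African",
    "South West Asian",
    "Native American",
    "Oceanian",
    "South East Asian",
    "Northern European",
    "Sub-Saharan African",
)

_DEFAULT_POPS = [
    ("Yakut", 62.0, 129.7, "NORTH ASIA"),
    ("Sardinian", 40.1, 9.0, "EUROPE"),
    ("Khomani", -28.5, 21.0, "AFRICA"),
    ("Gujarati", 22.3, 72.6, "INDIA"),
    ("Peruvian", -9.2, -75.0, "NATIVE AMERICAN"),
    ("Vanuatan", -15.4, 166.9, "OCEANIA"),
    ("Vietnamese", 16.0, 107.8, "EAST ASIA"),
    ("Norwegian", 60.5, 8.5, "EUROPE"),
    ("Yoruba", 7.4, 3.9, "AFRICA"),
]

#: fine-grained haplogroups assigned to founders, cycled per population;
#: leaves whose deepest defining variants are off the default panel exercise
#: the sparse-panel truncation behaviour
_FOUNDER_HAPLOGROUPS = (
    "H5a3b", "C1d", "D4j", "L2a1c", "B2", "T2b", "K", "A", "W", "M7", "B4", "H",
)


class ValidationError(ValueError):
    pass


@dataclass
class AncestralComponent:
    """One of K ancestral components: a name, an Fst, and (once simulated)
    per-autosomal-marker allele frequencies."""

    name: str
    fst: float
    allele_freqs: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not 0 < self.fst < 1:
            raise ValidationError(f"fst must be in (0,1), got {self.fst}")


@dataclass
class ReferencePopulation:
    name: str
    mean_admixture: np.ndarray
    latitude: float
    longitude: float
    region: str

    def __post_init__(self) -> None:
        q = np.asarray(self.mean_admixture, dtype=float)
        if (q < 0).any() or abs(q.sum() - 1.0) > 1e-9:
            raise ValidationError(f"mean_admixture of {self.name} is not on the simplex")
        self.mean_admixture = q


@dataclass
class SyntheticCohort:
    """Genotypes plus complete ground truth for every downstream check."""

    manifest: MarkerManifest
    components: list[AncestralComponent]
    truth: GenotypeMatrix  # error-free truth calls
    truth_sex: dict[str, str]
    truth_admixture: dict[str, np.ndarray]
    truth_population: dict[str, str]
    truth_haplogroup: dict[str, str]
    pedigree: list[tuple[str, str, str]] = field(default_factory=list)  # (child, father, mother)
    genotypes_by_platform: dict[str, GenotypeMatrix] = field(default_factory=dict)
    planted_swaps: list[tuple[str, str, str]] = field(default_factory=list)
    x_freqs: np.ndarray | None = None  # K x n_X component frequencies
    y_freqs: np.ndarray | None = None  # n_Y shared frequencies

    @property
    def sample_ids(self) -> list[str]:
        return list(self.truth.sample_ids)


# ---------------------------------------------------------------------------
# manifest


def default_manifest(
    n_autosomal: int = 5000,
    n_x: int = 200,
    n_y: int = 100,
    n_mt: int = 50,
    n_par: int = 10,
    aim_fraction: float = 0.4,
) -> MarkerManifest:
    """Build a synthetic marker manifest at roughly one-third array scale.

    Autosomal markers are split across the array's autosomal categories with
    AIMs the largest block; X/Y/MT/PAR counts default to the same scaled-down
    proportions.  Mitochondrial markers are placed at the toy phylotree's
    defining positions first so haplogroup structure is observable.
    """
    if n_autosomal < 0 or n_x < 0 or n_y < 0 or n_mt < 0:
        raise ValidationError("marker counts must be non-negative")
    rows = []
    bases = ("A", "C", "G", "T")
    n_aim = int(round(aim_fraction * n_autosomal))
    n_mhc = min(max(n_autosomal // 40, 0), n_autosomal - n_aim)
    rest = n_autosomal - n_aim - n_mhc
    cats = ["AIM"] * n_aim + ["extended_MHC"] * n_mhc
    fill = ["linkage", "fingerprint", "ADME", "blood_group"]
    cats += [fill[i % 4] for i in range(rest)]
    for i in range(n_autosomal):
        chrom = str(i % 22 + 1)
        ref, alt = bases[i % 4], bases[(i + 1) % 4]
        rows.append((f"auto{i:05d}", chrom, 10_000 + (i // 22) * 1000, ref, alt, cats[i], "forward"))
    for i in range(n_x):
        rows.append((f"x{i:04d}", "X", 3_000_000 + i * 1000, bases[i % 4], bases[(i + 1) % 4], "X", "forward"))
    for i in range(n_par):
        rows.append((f"par{i:03d}", "X", 100_000 + i * 1000, bases[i % 4], bases[(i + 1) % 4], "PAR", "forward"))
    for i in range(n_y):
        rows.append((f"y{i:04d}", "Y", 2_700_000 + i * 1000, bases[i % 4], bases[(i + 1) % 4], "Y", "forward"))
    tree = sexmito.toy_phylotree()
    off_panel = {"H5", "H5a3b", "C1d", "D4j", "T2b", "L2a1c"}
    panel_vars: dict[int, str] = {}
    for node in tree:
        if node.name in off_panel:
            continue
        for pos, allele in node.defining_variants:
            panel_vars.setdefault(pos, allele)
    mt_positions = sorted(panel_vars)[:n_mt]
    filler = 0
    while len(mt_positions) < n_mt:
        p = 200 + filler * 97  # synthetic non-defining positions
        if p not in panel_vars:
            mt_positions.append(p)
        filler += 1
    for i, pos in enumerate(sorted(mt_positions)):
        derived = panel_vars.get(pos, "T")
        ref = "A" if derived != "A" else "G"
        rows.append((f"mt{i:03d}", "MT", pos, ref, derived, "mitochondrial", "forward"))
    df = pd.DataFrame(rows, columns=["marker_id", "chrom", "pos", "ref", "alt", "category", "strand"])
    return MarkerManifest(df)


# ---------------------------------------------------------------------------
# frequencies and founders


def default_components(k: int = 9, fst: float = 0.15) -> list[AncestralComponent]:
    names = COMPONENT_NAMES if k == 9 else [f"component{j}" for j in range(k)]
    return [AncestralComponent(name, fst) for name in names]


def default_populations(components: list[AncestralComponent], own_weight: float = 0.9) -> list[ReferencePopulation]:
    """One reference population per component: ``own_weight`` of its own
    component, the remainder spread evenly over the others."""
    k = len(components)
    pops = []
    for j, comp in enumerate(components):
        q = np.full(k, (1 - own_weight) / (k - 1)) if k > 1 else np.array([1.0])
        if k > 1:
            q[j] = own_weight
        name, lat, lon, region = _DEFAULT_POPS[j] if k == 9 else (f"pop{j}", -60 + 15 * j, -170 + 38 * j, f"region{j}")
        pops.append(ReferencePopulation(name, q, lat, lon, region))
    return pops


def simulate_frequencies(
    n_markers: int,
    components: list[AncestralComponent],
    seed: int,
) -> list[AncestralComponent]:
    """Draw Balding–Nichols component allele frequencies for each component.

    For each marker an ancestral frequency p ~ U[0.05, 0.95]; component k
    then draws Beta(p(1-F)/F, (1-p)(1-F)/F) — mean p, variance F p (1-p) —
    clipped to [0.001, 0.999].  Deterministic given the seed.
    """
    if n_markers < 1:
        raise ValidationError(f"n_markers must be >= 1, got {n_markers}")
    rng = np.random.default_rng(seed)
    p = rng.uniform(0.05, 0.95, size=n_markers)
    out = []
    for comp in components:
        f = comp.fst
        a = p * (1 - f) / f
        b = (1 - p) * (1 - f) / f
        freqs = np.clip(rng.beta(a, b), 0.001, 0.999)
        out.append(AncestralComponent(comp.name, f, freqs))
    return out


def _simulate_mt_row(haplogroup: str, manifest: MarkerManifest, tree) -> np.ndarray:
    mt_ids = manifest.ids_in_category("mitochondrial")
    derived = dict(sexmito.path_variants(haplogroup, tree))
    tab = manifest.table
    row = np.zeros(len(mt_ids), dtype=np.int8)
    for j, mid in enumerate(mt_ids):
        pos = int(tab.loc[mid, "pos"])
        if pos in derived and derived[pos] == tab.loc[mid, "alt"]:
            row[j] = 1
    return row


def simulate_individuals(
    components: list[AncestralComponent],
    populations: list[ReferencePopulation],
    n_per_pop: int,
    seed: int,
    manifest: MarkerManifest | None = None,
    dirichlet_concentration: float | None = None,
) -> SyntheticCohort:
    """Simulate unrelated founders, ``n_per_pop`` per reference population.

    Each founder's admixture vector is its population's mean (optionally
    Dirichlet-jittered around it with the given concentration); autosomal
    genotypes are Binomial(2, q . f_m); sexes alternate male/female; X is
    hemizygous-as-homozygous in males; Y is male-only haploid; mtDNA
    haplogroups are cycled from the simulator's founder list.
    """
    if not components or components[0].allele_freqs is None:
        raise ValidationError("components must carry simulated allele_freqs")
    k = len(components)
    for pop in populations:
        if len(pop.mean_admixture) != k:
            raise ValidationError(
                f"population {pop.name} has K={len(pop.mean_admixture)}, components have K={k}"
            )
    freqs = np.stack([c.allele_freqs for c in components])  # K x M_auto
    if manifest is None:
        manifest = default_manifest(n_autosomal=freqs.shape[1])
    auto_ids = manifest.autosomal_ids()
    if freqs.shape[1] != len(auto_ids):
        raise ValidationError(
            f"components carry {freqs.shape[1]} autosomal frequencies but the manifest has {len(auto_ids)}"
        )
    rng = np.random.default_rng(seed)
    x_ids = manifest.ids_in_category("X")
    par_ids = manifest.ids_in_category("PAR")
    y_ids = manifest.ids_in_category("Y")
    mt_ids = manifest.ids_in_category("mitochondrial")
    # component frequencies for X and PAR (Balding-Nichols again), shared Y freqs
    x_freqs = _chrom_freqs(rng, k, len(x_ids), [c.fst for c in components])
    par_freqs = _chrom_freqs(rng, k, len(par_ids), [c.fst for c in components])
    y_freqs = rng.uniform(0.05, 0.95, size=len(y_ids))
    tree = sexmito.toy_phylotree()

    marker_ids = auto_ids + x_ids + par_ids + y_ids + mt_ids
    sample_ids, sexes, admixture, population, haplogroup = [], {}, {}, {}, {}
    rows = []
    hap_cycle = 0
    for pop in populations:
        for i in range(n_per_pop):
            sid = f"{pop.name}_{i:04d}"
            sample_ids.append(sid)
            sex = "male" if i % 2 == 0 else "female"
            sexes[sid] = sex
            if dirichlet_concentration is None:
                q = pop.mean_admixture.copy()
            else:
                q = rng.dirichlet(pop.mean_admixture * dirichlet_concentration)
            admixture[sid] = q
            population[sid] = pop.name
            hg = _FOUNDER_HAPLOGROUPS[hap_cycle % len(_FOUNDER_HAPLOGROUPS)]
            hap_cycle += 1
            haplogroup[sid] = hg
            p_auto = q @ freqs
            auto = rng.binomial(2, p_auto).astype(np.int8)
            p_x = q @ x_freqs if len(x_ids) else np.empty(0)
            if sex == "female":
                x = rng.binomial(2, p_x).astype(np.int8)
                y = np.full(len(y_ids), MISSING, dtype=np.int8)
            else:
                x = (2 * rng.binomial(1, p_x)).astype(np.int8)  # hemizygous, reported homozygous
                y = rng.binomial(1, y_freqs).astype(np.int8)
            par = rng.binomial(2, q @ par_freqs).astype(np.int8) if len(par_ids) else np.empty(0, np.int8)
            mt = _simulate_mt_row(hg, manifest, tree)
            rows.append(np.concatenate([auto, x, par, y, mt]))
    calls = np.stack(rows) if rows else np.empty((0, len(marker_ids)), np.int8)
    truth = GenotypeMatrix(sample_ids, marker_ids, calls)
    return SyntheticCohort(
        manifest=manifest,
        components=components,
        truth=truth,
        truth_sex=sexes,
        truth_admixture=admixture,
        truth_population=population,
        truth_haplogroup=haplogroup,
        x_freqs=x_freqs,
        y_freqs=y_freqs,
    )


def _chrom_freqs(rng, k, m, fsts):
    if m == 0:
        return np.empty((k, 0))
    p = rng.uniform(0.05, 0.95, size=m)
    out = np.empty((k, m))
    for j, f in enumerate(fsts):
        out[j] = np.clip(rng.beta(p * (1 - f) / f, (1 - p) * (1 - f) / f), 0.001, 0.999)
    return out


# ---------------------------------------------------------------------------
# families


def add_family(
    cohort: SyntheticCohort,
    father: str,
    mother: str,
    n_children: int,
    seed: int,
    child_prefix: str | None = None,
) -> SyntheticCohort:
    """Append Mendelian children of an existing couple to the cohort.

    Autosomes: one allele drawn from each parent (a het parent transmits
    either allele with probability 1/2).  X: sons receive one maternal X
    allele (reported homozygous) plus the paternal Y; daughters one X allele
    from each parent.  Y: sons copy the father.  mtDNA: copied from the
    mother, haplogroup included.  Children alternate male/female.
    """
    if father == mother:
        raise ValidationError("father and mother must differ")
    for pid, want in ((father, "male"), (mother, "female")):
        if pid not in cohort.truth_sex:
            raise ValidationError(f"unknown parent id: {pid}")
        if cohort.truth_sex[pid] != want:
            raise ValidationError(f"{pid} is not {want}")
    if cohort.genotypes_by_platform:
        raise ValidationError("add families before genotyping platforms")
    rng = np.random.default_rng(seed)
    manifest = cohort.manifest
    mids = cohort.truth.marker_ids
    cat = manifest.table.loc[mids, "category"].to_numpy()
    is_auto = ~np.isin(cat, ["X", "Y", "mitochondrial"])  # PAR transmits autosomally
    is_x = cat == "X"
    is_y = cat == "Y"
    is_mt = cat == "mitochondrial"
    f_row = cohort.truth.row(father)
    m_row = cohort.truth.row(mother)
    prefix = child_prefix or f"{father}x{mother}"
    new_rows, new_ids = [], []
    n_existing = sum(1 for c, f, m in cohort.pedigree if f == father and m == mother)
    for c in range(n_children):
        cid = f"{prefix}_c{n_existing + c:03d}"
        sex = "male" if c % 2 == 0 else "female"
        row = np.full(len(mids), MISSING, dtype=np.int8)
        pat = rng.binomial(1, np.clip(f_row[is_auto] / 2.0, 0, 1)).astype(np.int8)
        mat = rng.binomial(1, np.clip(m_row[is_auto] / 2.0, 0, 1)).astype(np.int8)
        row[is_auto] = pat + mat
        mat_x = rng.binomial(1, np.clip(m_row[is_x] / 2.0, 0, 1)).astype(np.int8)
        if sex == "male":
            row[is_x] = 2 * mat_x
            row[is_y] = f_row[is_y]
        else:
            pat_x = (f_row[is_x] // 2).astype(np.int8)  # father hemizygous: 0 or 2 -> allele
            row[is_x] = mat_x + pat_x
            # daughters: no Y, stays MISSING
        row[is_mt] = m_row[is_mt]
        new_rows.append(row)
        new_ids.append(cid)
        cohort.truth_sex[cid] = sex
        cohort.truth_admixture[cid] = 0.5 * (
            cohort.truth_admixture[father] + cohort.truth_admixture[mother]
        )
        cohort.truth_population[cid] = cohort.truth_population[mother]
        cohort.truth_haplogroup[cid] = cohort.truth_haplogroup[mother]
        cohort.pedigree.append((cid, father, mother))
    cohort.truth = GenotypeMatrix(
        cohort.truth.sample_ids + new_ids,
        mids,
        np.vstack([cohort.truth.calls, np.stack(new_rows)]) if new_rows else cohort.truth.calls,
    )
    return cohort


# ---------------------------------------------------------------------------
# platforms and swaps


def genotype_on_platform(
    cohort: SyntheticCohort,
    platform: str,
    error_rate: float = 0.002,
    missing_rate: float = 0.01,
    seed: int = 0,
) -> SyntheticCohort:
    """Add an independent noisy platform copy of the truth genotypes.

    Each call is set missing with probability ``missing_rate``; otherwise,
    with probability ``error_rate`` a diploid code is replaced by one of the
    two other codes uniformly and a haploid code flips.  Errors are
    independent across platforms.
    """
    if not 0 <= error_rate <= 1 or not 0 <= missing_rate <= 1:
        raise ValidationError("error_rate and missing_rate must be in [0,1]")
    rng = np.random.default_rng(seed)
    calls = cohort.truth.calls.copy()
    mids = cohort.truth.marker_ids
    cat = cohort.manifest.table.loc[mids, "category"].to_numpy()
    haploid_cols = np.isin(cat, ["Y", "mitochondrial"])
    n_s, n_m = calls.shape
    observed = calls != MISSING
    err = (rng.random(calls.shape) < error_rate) & observed
    # haploid flip
    hap = err & haploid_cols[None, :]
    calls[hap] = 1 - calls[hap]
    # diploid: shift by 1 or 2 mod 3 picks one of the two other codes uniformly
    dip = err & ~haploid_cols[None, :]
    shift = rng.integers(1, 3, size=calls.shape).astype(np.int8)
    calls[dip] = (calls[dip] + shift[dip]) % 3
    miss = (rng.random(calls.shape) < missing_rate) & observed
    calls[miss] = MISSING
    cohort.genotypes_by_platform[platform] = GenotypeMatrix(
        list(cohort.truth.sample_ids), list(mids), calls
    )
    return cohort


def plant_swap(cohort: SyntheticCohort, platform: str, sample_a: str, sample_b: str) -> SyntheticCohort:
    """Exchange two samples' genotype rows on one platform, recording the
    truth in ``planted_swaps``.  Swapping a sample with itself is rejected."""
    if platform not in cohort.genotypes_by_platform:
        raise ValidationError(f"unknown platform: {platform}")
    if sample_a == sample_b:
        raise ValidationError("cannot swap a sample with itself")
    mat = cohort.genotypes_by_platform[platform]
    ia, ib = mat.sample_index(sample_a), mat.sample_index(sample_b)
    mat.calls[[ia, ib]] = mat.calls[[ib, ia]]
    pair = (platform, sample_a, sample_b)
    if pair in cohort.planted_swaps:
        cohort.planted_swaps.remove(pair)  # swapping back undoes the record
    else:
        cohort.planted_swaps.append(pair)
    return cohort


# ---------------------------------------------------------------------------
# export


def write_cohort(cohort: SyntheticCohort, outdir) -> None:
    """Write one VCF per platform, the manifest TSV, a PLINK-style pedigree
    file and a truth JSON into ``outdir``."""
    import json
    from pathlib import Path

    from .genio import write_vcf

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    cohort.manifest.to_tsv(out / "manifest.tsv")
    for platform, mat in cohort.genotypes_by_platform.items():
        write_vcf(mat, cohort.manifest, out / f"{platform}.vcf", sexes=cohort.truth_sex)
    parents = {c: (f, m) for c, f, m in cohort.pedigree}
    with open(out / "pedigree.ped", "w") as fh:
        for sid in cohort.sample_ids:
            f, m = parents.get(sid, ("0", "0"))
            sexcode = 1 if cohort.truth_sex[sid] == "male" else 2
            fh.write(f"FAM1 {sid} {f} {m} {sexcode} -9\n")
    truth = {
        "sex": cohort.truth_sex,
        "population": cohort.truth_population,
        "haplogroup": cohort.truth_haplogroup,
        "admixture": {s: list(map(float, q)) for s, q in cohort.truth_admixture.items()},
        "pedigree": cohort.pedigree,
        "planted_swaps": cohort.planted_swaps,
    }
    with open(out / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1)
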