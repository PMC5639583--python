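"""Pipeline orchestration and the consolidated per-cohort QC report.

The report answers the questions a diagnostic lab asks of every batch:
are the samples who we think they are (identity/swap scan), is the recorded
sex right, do recorded family relationships hold up (kinship vs pedigree),
is the self-reported ancestry plausible, and which markers should be
excluded (blacklist)?  Any swap suspicion, sex mismatch or pedigree
discrepancy makes the run "failing" (nonzero exit status from the CLI).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import ancestry, concord, identity, kinrel, sexmito
from .genio import GenotypeMatrix, MarkerManifest, align_on_shared, read_vcf


@dataclass
class QCConfig:
    """Declarative pipeline configuration.

    Inputs may be given as file paths (``manifest_path`` + ``platform_vcfs``)
    or as in-memory objects (``manifest`` + ``platforms``); in-memory wins.
    All stage thresholds carry the pipeline defaults.
    """

    manifest_path: str | None = None
    platform_vcfs: dict[str, str] = field(default_factory=dict)
    manifest: MarkerManifest | None = None
    platforms: dict[str, GenotypeMatrix] = field(default_factory=dict)
    panel: ancestry.ReferencePanel | None = None
    panel_pop_path: str | None = None
    panel_freq_path: str | None = None
    pedigree: list[tuple[str, str, str]] | None = None
    metadata: dict[str, dict] | None = None  # sample -> {"sex":..., "region":...}
    haplogroup_tree: list | None = None
    outdir: str | None = None
    blacklist_threshold: float = concord.DEFAULT_BLACKLIST_THRESHOLD
    exclude_mhc: bool = True
    min_informative: int = identity.DEFAULT_MIN_INFORMATIVE
    run_identity: bool = True
    run_kinship: bool = True
    run_sex: bool = True
    run_ancestry: bool = True
    run_haplogroups: bool = True


@dataclass
class QCReport:
    n_samples: int
    n_markers: int
    platforms: list[str]
    blacklist: dict[str, str]
    mean_matched_concordance: float
    identity_decisions: list
    swap_suspected: list[str]
    sex_inferences: list
    sex_mismatches: list[str]
    kinship_results: list
    pedigree_discrepancies: list[dict]
    provenance: list
    metadata_discrepancies: list[dict]
    ks_strata: list
    config_used: dict

    @property
    def has_findings(self) -> bool:
        return bool(self.swap_suspected or self.sex_mismatches or self.pedigree_discrepancies)

    @property
    def exit_code(self) -> int:
        return 1 if self.has_findings else 0

    def to_json(self) -> str:
        def enc(o):
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            if isinstance(o, np.ndarray):
                return [float(x) for x in o]
            if isinstance(o, (np.floating, np.integer)):
                return o.item()
            raise TypeError(f"unserializable: {type(o)}")

        return json.dumps(dataclasses.asdict(self), default=enc, indent=1, allow_nan=True)

    def summary_text(self) -> str:
        lines = [
            f"samples: {self.n_samples}   markers: {self.n_markers}   platforms: {', '.join(self.platforms)}",
            f"blacklisted markers: {len(self.blacklist)}",
            f"mean matched-sample cross-platform concordance: {self.mean_matched_concordance:.4f}",
            f"swap suspected: {sorted(self.swap_suspected) or 'none'}",
            f"sex mismatches: {sorted(self.sex_mismatches) or 'none'}",
            f"pedigree discrepancies: {len(self.pedigree_discrepancies)}",
            f"metadata discrepancies: {len(self.metadata_discrepancies)}",
            f"status: {'FINDINGS' if self.has_findings else 'clean'}",
        ]
        return "\n".join(lines)


def run_pipeline(config: QCConfig) -> QCReport:
    """Execute the QC stages in order: I/O -> concordance/blacklist ->
    identity -> kinship -> sex -> ancestry/haplogroups -> report."""
    manifest = config.manifest or MarkerManifest.from_tsv(config.manifest_path)
    platforms = dict(config.platforms)
    for label, path in config.platform_vcfs.items():
        platforms.setdefault(label, read_vcf(path, manifest))
    if not platforms:
        raise ValueError("no platform call sets configured")
    labels = list(platforms)
    panel = config.panel
    if panel is None and config.panel_pop_path:
        panel = ancestry.ReferencePanel.from_tsv(config.panel_pop_path, config.panel_freq_path)

    # --- concordance + blacklist (first two platforms) -------------------
    blacklist: dict[str, str] = {}
    mean_conc = float("nan")
    decisions, strata, swap_suspected = [], [], []
    if len(labels) >= 2 and config.run_identity:
        a_raw, b_raw = align_on_shared(platforms[labels[0]], platforms[labels[1]])
        core_a, _ = concord.filter_for_concordance(a_raw, manifest, exclude_mhc=config.exclude_mhc)
        core_b, _ = concord.filter_for_concordance(b_raw, manifest, exclude_mhc=config.exclude_mhc)
        core_a, core_b = align_on_shared(core_a, core_b)
        profile = concord.marker_discordance_profile(core_a, core_b)
        from_profile = concord.build_blacklist(profile, config.blacklist_threshold)
        for m in from_profile:
            blacklist[m] = f"discordant in >= {config.blacklist_threshold:.0%} of matched samples"
        if config.exclude_mhc:
            for m in manifest.ids_in_category("extended_MHC"):
                blacklist.setdefault(m, "extended MHC region")
        keep = [m for m in core_a.marker_ids if m not in from_profile]
        core_a, core_b = core_a.subset_markers(keep), core_b.subset_markers(keep)
        matched = concord.concordance_matrix(core_a, core_b, mode="matched",
                                            platform_a=labels[0], platform_b=labels[1])
        defined = [p.concordance for p in matched if p.defined]
        mean_conc = float(np.mean(defined)) if defined else float("nan")
        cross = concord.concordance_matrix(core_a, core_b, mode="cross",
                                           platform_a=labels[0], platform_b=labels[1])
        decisions, strata = identity.swap_scan(
            cross, min_informative=config.min_informative, pedigree=config.pedigree
        )
        swap_suspected = [d.sample for d in decisions if d.verdict == "swap_suspected"]

    primary = platforms[labels[0]]

    # --- kinship ---------------------------------------------------------
    kin_results, ped_disc = [], []
    if config.run_kinship:
        auto = kinrel.autosomal_matrix(primary, manifest)
        auto = auto.subset_markers([m for m in auto.marker_ids if m not in blacklist])
        kin_results, ped_disc = kinrel.kinship_matrix(auto, pedigree=config.pedigree)

    # --- sex -------------------------------------------------------------
    sex_inf, sex_mis = [], []
    if config.run_sex:
        reported = {
            s: meta.get("sex")
            for s, meta in (config.metadata or {}).items()
            if meta.get("sex")
        }
        sex_inf = sexmito.infer_sex(primary, manifest, self_reported=reported)
        sex_mis = [r.sample for r in sex_inf if r.mismatch_flag]

    # --- ancestry + haplogroups -----------------------------------------
    prov: list = []
    if config.run_ancestry and panel is not None:
        shared = [m for m in panel.marker_ids if m in set(primary.marker_ids)]
        sub = primary.subset_markers(shared)
        cols = [panel.marker_ids.index(m) for m in shared]
        sub_panel = ancestry.ReferencePanel(
            list(panel.components), panel.component_freqs[:, cols], shared, panel.populations
        )
        for s in primary.sample_ids:
            prov.append(ancestry.provenance(s, sub.row(s).astype(float), sub_panel))
    haplogroups = {}
    if config.run_haplogroups:
        tree = config.haplogroup_tree or sexmito.toy_phylotree()
        for s in primary.sample_ids:
            calls = sexmito.mt_calls_from_matrix(primary, manifest, s)
            if calls:
                haplogroups[s] = sexmito.assign_haplogroup(calls, tree)

    report = QCReport(
        n_samples=primary.n_samples,
        n_markers=primary.n_markers,
        platforms=labels,
        blacklist=blacklist,
        mean_matched_concordance=mean_conc,
        identity_decisions=decisions,
        swap_suspected=swap_suspected,
        sex_inferences=sex_inf,
        sex_mismatches=sex_mis,
        kinship_results=kin_results,
        pedigree_discrepancies=ped_disc,
        provenance=prov,
        metadata_discrepancies=[],
        ks_strata=strata,
        config_used={
            "blacklist_threshold": config.blacklist_threshold,
            "exclude_mhc": config.exclude_mhc,
            "min_informative": config.min_informative,
        },
    )
    if config.metadata:
        report.metadata_discrepancies = cross_check_metadata(report, config.metadata)
    if config.outdir:
        out = Path(config.outdir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(report.to_json())
        (out / "report.txt").write_text(report.summary_text() + "\n")
        kinrel.results_to_frame(kin_results).to_csv(out / "kinship.tsv", sep="\t", index=False)
        concord.write_blacklist(set(blacklist), out / "blacklist.txt")
    return report


def cross_check_metadata(report: QCReport, metadata: dict[str, dict]) -> list[dict]:
    """Compare self-reported sex and region against inferred values; one
    discrepancy record per conflict, with severity (sex conflicts are
    high-severity: they usually mean a sample or metadata mix-up)."""
    inferred_sex = {r.sample: r.inferred for r in report.sex_inferences}
    predicted_region = {p.sample: p.nearest_region for p in report.provenance}
    known = set(inferred_sex) | set(predicted_region)
    out = []
    for s, meta in metadata.items():
        if s not in known:
            out.append({"sample": s, "field": "sample", "severity": "warning",
                        "detail": "metadata refers to a sample absent from the cohort"})
            continue
        want_sex = meta.get("sex")
        got_sex = inferred_sex.get(s)
        if want_sex and got_sex and got_sex != "ambiguous" and want_sex != got_sex:
            out.append({"sample": s, "field": "sex", "severity": "high",
                        "detail": f"self-reported {want_sex}, inferred {got_sex}"})
        want_region = meta.get("region")
        got_region = predicted_region.get(s)
        if want_region and got_region and want_region != got_region:
            out.append({"sample": s, "field": "region", "severity": "moderate",
                        "detail": f"self-reported {want_region}, predicted {got_region}"})
    return out
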