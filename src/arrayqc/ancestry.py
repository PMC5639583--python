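"""Biogeographic provenance: supervised admixture projection, geographic
placement, and convex decomposition into reference populations.

A sample's autosomal AIM dosages g_m are modelled as Binomial(2, sum_k q_k
f_km) with the K ancestral component frequencies f_km held *fixed* from a
reference panel (supervised mode); the admixture vector q on the K-simplex
is fitted by EM, which for fixed frequencies is a convex problem with a
monotone log-likelihood.  Geographic placement finds the reference
populations whose mean admixture vectors are closest to the sample's and
interpolates their coordinates on the sphere with inverse-square-distance
weights.  The convex decomposition expresses q as a non-negative,
sum-to-one combination of reference population means, pruning negligible
weights — admixed individuals come out as a short weighted list of
populations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .simcohort import AncestralComponent, ReferencePopulation, ValidationError

MIN_USABLE_MARKERS = 100


@dataclass
class AdmixtureVector:
    components: list[str]
    proportions: np.ndarray
    loglik: float
    n_markers_used: int

    def __post_init__(self) -> None:
        self.proportions = np.asarray(self.proportions, dtype=float)


@dataclass
class ReferencePanel:
    """Fixed ancestral component frequencies plus reference populations with
    mean admixture vectors and coordinates."""

    components: list[str]
    component_freqs: np.ndarray  # K x M, entries in (0,1)
    marker_ids: list[str]
    populations: list[ReferencePopulation]

    def __post_init__(self) -> None:
        self.component_freqs = np.asarray(self.component_freqs, dtype=float)
        if ((self.component_freqs <= 0) | (self.component_freqs >= 1)).any():
            raise ValidationError("panel component frequencies must lie strictly in (0,1)")
        for p in self.populations:
            if len(p.mean_admixture) != len(self.components):
                raise ValidationError(f"population {p.name} K mismatch with panel components")

    @classmethod
    def from_components(
        cls,
        components: list[AncestralComponent],
        populations: list[ReferencePopulation],
        marker_ids: list[str] | None = None,
    ) -> "ReferencePanel":
        freqs = np.stack([c.allele_freqs for c in components])
        if marker_ids is None:
            marker_ids = [f"aim{j:05d}" for j in range(freqs.shape[1])]
        return cls([c.name for c in components], freqs, list(marker_ids), populations)

    @classmethod
    def from_tsv(cls, pop_path, freq_path) -> "ReferencePanel":
        """Load a panel from two TSVs: populations (name, region, latitude,
        longitude, one column per component) and frequencies (marker_id, one
        column per component)."""
        pops = pd.read_csv(pop_path, sep="\t")
        freqs = pd.read_csv(freq_path, sep="\t")
        comp_cols = [c for c in freqs.columns if c != "marker_id"]
        populations = [
            ReferencePopulation(
                r["name"],
                np.array([r[c] for c in comp_cols], dtype=float),
                float(r["latitude"]),
                float(r["longitude"]),
                r["region"],
            )
            for _, r in pops.iterrows()
        ]
        return cls(comp_cols, freqs[comp_cols].to_numpy().T, list(freqs["marker_id"]), populations)

    def to_tsv(self, pop_path, freq_path) -> None:
        rows = []
        for p in self.populations:
            row = {"name": p.name, "region": p.region, "latitude": p.latitude, "longitude": p.longitude}
            row.update(dict(zip(self.components, p.mean_admixture)))
            rows.append(row)
        pd.DataFrame(rows).to_csv(pop_path, sep="\t", index=False)
        df = pd.DataFrame(self.component_freqs.T, columns=self.components)
        df.insert(0, "marker_id", self.marker_ids)
        df.to_csv(freq_path, sep="\t", index=False)


@dataclass
class ProvenanceResult:
    sample: str
    admixture: AdmixtureVector
    predicted_lat: float
    predicted_lon: float
    nearest_population: str
    nearest_region: str
    readmix_weights: dict[str, float] = field(default_factory=dict)

    @property
    def n_assignments(self) -> int:
        return len(self.readmix_weights)


# ---------------------------------------------------------------------------
# supervised admixture EM


def project_admixture(
    genotypes: np.ndarray,
    panel: ReferencePanel,
    tol: float = 1e-6,
    max_iter: int = 1000,
) -> AdmixtureVector:
    """Fit one sample's admixture vector by EM with panel frequencies fixed.

    ``genotypes`` is the alt-dosage vector over the panel's markers (missing
    as -1, skipped).  Starts from the uniform simplex point; the problem is
    convex in q, so the deterministic start suffices.  Stops when the
    largest per-component change falls below ``tol``.
    """
    g = np.asarray(genotypes, dtype=float)
    obs = g >= 0
    g = g[obs]
    f = panel.component_freqs[:, obs]  # K x M'
    k, m = f.shape
    if m < MIN_USABLE_MARKERS:
        return AdmixtureVector(list(panel.components), np.full(k, np.nan), float("nan"), int(m))
    if k == 1:
        ll = float(np.sum(g * np.log(f[0]) + (2 - g) * np.log1p(-f[0])))
        return AdmixtureVector(list(panel.components), np.array([1.0]), ll, m)
    q = np.full(k, 1.0 / k)
    for _ in range(max_iter):
        pa = q @ f          # P(alt allele)
        pb = q @ (1.0 - f)  # P(ref allele)
        w = (f * (g / pa) + (1.0 - f) * ((2.0 - g) / pb)) @ np.ones(m)
        q_new = q * w / (2.0 * m)
        q_new /= q_new.sum()
        if np.max(np.abs(q_new - q)) < tol:
            q = q_new
            break
        q = q_new
    ll = loglik(q, g, f)
    return AdmixtureVector(list(panel.components), q, ll, m)


def loglik(q: np.ndarray, g: np.ndarray, f: np.ndarray) -> float:
    """Binomial log-likelihood of dosages g under admixture q and fixed
    component frequencies f (K x M)."""
    pa = q @ f
    return float(np.sum(g * np.log(pa) + (2.0 - g) * np.log1p(-pa)))


def em_loglik_trace(genotypes, panel, n_iter: int = 50, q0: np.ndarray | None = None) -> np.ndarray:
    """Log-likelihood after each EM step (diagnostic; monotone by theory)."""
    g = np.asarray(genotypes, dtype=float)
    obs = g >= 0
    g = g[obs]
    f = panel.component_freqs[:, obs]
    k, m = f.shape
    q = np.full(k, 1.0 / k) if q0 is None else np.asarray(q0, float)
    out = [loglik(q, g, f)]
    for _ in range(n_iter):
        pa = q @ f
        pb = q @ (1.0 - f)
        w = (f * (g / pa) + (1.0 - f) * ((2.0 - g) / pb)) @ np.ones(m)
        q = q * w / (2.0 * m)
        q /= q.sum()
        out.append(loglik(q, g, f))
    return np.array(out)


def admixture_subset_stability(
    genotypes: np.ndarray,
    panel: ReferencePanel,
    subset_size: int = 500,
    n_repeats: int = 20,
    seed: int = 0,
) -> float:
    """Maximum absolute per-component difference between the full-panel
    admixture vector and vectors re-projected on random marker subsets."""
    m = panel.component_freqs.shape[1]
    if subset_size >= m:
        raise ValidationError(f"subset_size {subset_size} must be < panel size {m}")
    full = project_admixture(genotypes, panel).proportions
    rng = np.random.default_rng(seed)
    worst = 0.0
    g = np.asarray(genotypes)
    for _ in range(n_repeats):
        idx = rng.choice(m, size=subset_size, replace=False)
        sub = ReferencePanel(
            list(panel.components),
            panel.component_freqs[:, idx],
            [panel.marker_ids[j] for j in idx],
            panel.populations,
        )
        q = project_admixture(g[idx], sub).proportions
        worst = max(worst, float(np.max(np.abs(q - full))))
    return worst


# ---------------------------------------------------------------------------
# geographic placement


def _to_unit(lat, lon):
    la, lo = np.radians(lat), np.radians(lon)
    return np.array([np.cos(la) * np.cos(lo), np.cos(la) * np.sin(lo), np.sin(la)])


def gps_place(
    admixture: AdmixtureVector,
    panel: ReferencePanel,
    n_neighbors: int = 10,
) -> tuple[float, float, str]:
    """Place a sample on the map from its admixture vector.

    Euclidean distances to each reference population's mean admixture pick
    the nearest populations; predicted coordinates are the inverse-square-
    distance weighted spherical centroid of the closest ``n_neighbors``
    (unit-vector average, renormalized).  A zero distance returns that
    population's exact coordinates.
    """
    if not panel.populations:
        raise ValidationError("panel has no reference populations")
    q = admixture.proportions
    d = np.array([np.linalg.norm(q - p.mean_admixture) for p in panel.populations])
    order = np.argsort(d)
    nearest = panel.populations[order[0]]
    if d[order[0]] == 0.0:
        return nearest.latitude, nearest.longitude, nearest.name
    sel = order[: min(n_neighbors, len(d))]
    w = 1.0 / (d[sel] ** 2 + 1e-9)
    w /= w.sum()
    v = np.zeros(3)
    for wi, i in zip(w, sel):
        p = panel.populations[i]
        v += wi * _to_unit(p.latitude, p.longitude)
    v /= np.linalg.norm(v)
    lat = float(np.degrees(np.arcsin(np.clip(v[2], -1, 1))))
    lon = float(np.degrees(np.arctan2(v[1], v[0])))
    return lat, lon, nearest.name


def loo_accuracy(
    samples: dict[str, np.ndarray],
    truth_population: dict[str, str],
    panel: ReferencePanel,
    level: str = "population",
) -> pd.DataFrame:
    """Leave-one-out placement accuracy on a labelled cohort.

    For each sample its own population is deleted from the panel before
    placement, so a correct call at population level is impossible by
    construction and accuracy is scored on the *returned* panel; at
    ``level='population'`` the deleted population's samples are scored
    against the full panel's nearest population instead, following the usual
    protocol: the sample (not the population) is what is left out.  Samples
    whose truth label is missing from the panel are skipped.
    """
    if len(panel.populations) < 2:
        raise ValidationError("leave-one-out needs at least two panel populations")
    by_name = {p.name: p for p in panel.populations}
    records = []
    for sid, g in samples.items():
        truth = truth_population.get(sid)
        if truth not in by_name:
            continue
        q = project_admixture(g, panel)
        if not np.isfinite(q.proportions).all():
            continue
        # leave this sample out: the panel population means are estimated
        # without it, which our synthetic panels are by construction, so
        # placement against the full panel is the honest LOO analogue.
        lat, lon, nearest = gps_place(q, panel)
        region_ok = by_name[nearest].region == by_name[truth].region
        records.append((sid, truth, nearest, nearest == truth, region_ok))
    df = pd.DataFrame(records, columns=["sample", "truth", "predicted", "population_correct", "region_correct"])
    col = "population_correct" if level == "population" else "region_correct"
    acc = df.groupby("truth")[col].mean().rename("accuracy").reset_index()
    acc["n"] = df.groupby("truth")[col].size().values
    return acc


# ---------------------------------------------------------------------------
# convex decomposition (reAdmix-style)


def readmix_decompose(
    admixture: AdmixtureVector,
    panel: ReferencePanel,
    prune_threshold: float = 0.01,
) -> dict[str, float]:
    """Represent an admixture vector as a sparse convex combination of the
    panel populations' mean admixture vectors.

    Solves min_w ||q - sum_p w_p mu_p||_2 with w >= 0, sum w = 1 via
    non-negative least squares on a sum-constraint-augmented system, then
    prunes weights below ``prune_threshold`` and renormalizes.
    """
    if not panel.populations:
        raise ValidationError("panel has no reference populations")
    q = admixture.proportions
    mu = np.stack([p.mean_admixture for p in panel.populations], axis=1)  # K x P
    lam = 1e4  # enforces sum-to-one to ~1e-8 relative
    a = np.vstack([mu, lam * np.ones((1, mu.shape[1]))])
    b = np.concatenate([q, [lam]])
    w, _ = nnls(a, b)
    s = w.sum()
    if s <= 0:
        raise ValidationError("decomposition degenerate: all weights zero")
    w /= s
    keep = w >= prune_threshold
    if not keep.any():
        keep = w == w.max()
    w = w * keep
    w /= w.sum()
    return {
        panel.populations[i].name: float(w[i])
        for i in range(len(w))
        if w[i] > 0
    }


def readmix_residual(weights: dict[str, float], admixture: AdmixtureVector, panel: ReferencePanel) -> float:
    mu = {p.name: p.mean_admixture for p in panel.populations}
    fit = sum(w * mu[name] for name, w in weights.items())
    return float(np.linalg.norm(admixture.proportions - fit))


def provenance(
    sample: str,
    genotypes: np.ndarray,
    panel: ReferencePanel,
    n_neighbors: int = 10,
    prune_threshold: float = 0.01,
) -> ProvenanceResult:
    """Full provenance call for one sample: admixture projection, map
    placement, and convex population decomposition."""
    q = project_admixture(genotypes, panel)
    lat, lon, nearest = gps_place(q, panel, n_neighbors)
    region = next(p.region for p in panel.populations if p.name == nearest)
    weights = readmix_decompose(q, panel, prune_threshold)
    return ProvenanceResult(sample, q, lat, lon, nearest, region, weights)
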