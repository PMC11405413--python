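"""Synthetic study-condition generators with known ground truth.

Everything the pipeline consumes can be generated here: parcel geometry
(centroids on two offset spherical caps standing in for the hemispheres),
spatially autocorrelated marker maps (Gaussian-process draws with an
exponential covariance, the same family the variogram-matched surrogates
assume), modeled-CT age trajectories whose windowed relative change is a
known linear mixture of selected atlases plus autocorrelated noise,
developmental gene-expression datasets (peaked vs. flat genes over a large
"non-brain" null pool), and a two-session longitudinal cohort with
subject- and site-level variation.  All generators are deterministic given
their seed.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

from .ct_change_windows import PERCENTILES, SEXES, CTTrajectorySet
from .parcel_core import AtlasSet, ParcelMap, zscore_map

__all__ = [
    "ParcelGeometry",
    "GroundTruth",
    "ExpressionDataset",
    "CohortData",
    "make_parcel_geometry",
    "sample_gp_map",
    "make_atlas_library",
    "make_library_from_latents",
    "make_ct_trajectories",
    "make_expression_dataset",
    "make_cohort",
]


@dataclasses.dataclass(frozen=True)
class ParcelGeometry:
    """Parcel centroids in 3D (arbitrary units) with hemisphere tags."""

    parcel_ids: tuple[str, ...]
    centroid_coords: np.ndarray  # (n, 3)
    hemisphere: tuple[str, ...]

    def __post_init__(self) -> None:
        xyz = np.asarray(self.centroid_coords, float)
        object.__setattr__(self, "centroid_coords", xyz)
        if xyz.shape != (len(self.parcel_ids), 3):
            raise ValueError("need one 3D centroid per parcel")
        left = xyz[[h == "L" for h in self.hemisphere], 0]
        right = xyz[[h == "R" for h in self.hemisphere], 0]
        if left.size and right.size and left.max() >= right.min():
            raise ValueError("hemispheres must occupy disjoint half-spaces")

    @property
    def n_parcels(self) -> int:
        return len(self.parcel_ids)


def make_parcel_geometry(n_per_hemisphere: int = 74,
                         seed: int = 0) -> ParcelGeometry:
    """Quasi-uniform centroids on two offset spherical caps (radius 40,
    hemisphere centers at x = -50 / +50), via a jittered Fibonacci lattice.
    """
    if n_per_hemisphere < 4:
        raise ValueError("need at least 4 parcels per hemisphere")
    rng = np.random.default_rng(seed)
    n = n_per_hemisphere
    golden = (1 + 5 ** 0.5) / 2
    i = np.arange(n)
    # Fibonacci lattice on the outward-facing half sphere
    phi = 2 * np.pi * i / golden
    cosb = 1 - (i + 0.5) / n          # polar angle from outward axis, cap
    sinb = np.sqrt(1 - cosb ** 2)
    radius = 40.0
    jitter = rng.normal(scale=0.5, size=(2, n, 3))
    coords = []
    hemis = []
    for h, (sign, jit) in enumerate(zip((-1.0, 1.0), jitter)):
        x = sign * (50.0 + radius * cosb)
        y = radius * sinb * np.cos(phi)
        z = radius * sinb * np.sin(phi)
        xyz = np.column_stack([x, y, z]) + jit
        # keep hemispheres strictly separated despite jitter
        xyz[:, 0] = sign * np.maximum(sign * xyz[:, 0], 45.0)
        coords.append(xyz)
        hemis += ["L" if sign < 0 else "R"] * n
    ids = tuple(f"L_p{k:03d}" for k in range(n)) + tuple(
        f"R_p{k:03d}" for k in range(n))
    return ParcelGeometry(ids, np.vstack(coords), tuple(hemis))


def _gp_draws(geometry: ParcelGeometry, length_scale: float,
              n_draws: int, rng: np.random.Generator) -> np.ndarray:
    """(n_draws, n_parcels) zero-mean GP draws, exponential covariance."""
    if length_scale <= 0:
        raise ValueError("length_scale must be positive")
    xyz = geometry.centroid_coords
    d = np.sqrt(((xyz[:, None] - xyz[None]) ** 2).sum(-1))
    cov = np.exp(-d / length_scale)
    cov[np.diag_indices_from(cov)] += 1e-8
    chol = np.linalg.cholesky(cov)
    return rng.standard_normal((n_draws, geometry.n_parcels)) @ chol.T


def sample_gp_map(geometry: ParcelGeometry, length_scale: float,
                  seed: int, name: str = "gp_map") -> ParcelMap:
    """One z-scored draw from a GP with covariance exp(-d/length_scale)."""
    rng = np.random.default_rng(seed)
    vals = _gp_draws(geometry, length_scale, 1, rng)[0]
    return zscore_map(ParcelMap(geometry.parcel_ids, vals, name,
                                geometry.hemisphere))


def make_atlas_library(geometry: ParcelGeometry, n_maps: int,
                       length_scale: float = 25.0,
                       cross_correlation: float = 0.0,
                       seed: int = 0, prefix: str = "atlas",
                       modality: str = "ni") -> AtlasSet:
    """Library of z-scored GP maps with controllable pairwise correlation.

    Maps are built as sqrt(r)*shared + sqrt(1-r)*independent GP fields so
    every pair correlates at ~``cross_correlation`` (which must lie in
    [0, 1): a common negative equicorrelation is infeasible for >2 maps).
    """
    if n_maps < 1:
        raise ValueError("need at least one map")
    if not 0 <= cross_correlation < 1:
        raise ValueError("cross_correlation must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    shared = _gp_draws(geometry, length_scale, 1, rng)[0]
    indep = _gp_draws(geometry, length_scale, n_maps, rng)
    r = cross_correlation
    maps = []
    for k in range(n_maps):
        vals = np.sqrt(r) * shared + np.sqrt(1 - r) * indep[k]
        maps.append(zscore_map(ParcelMap(geometry.parcel_ids, vals,
                                         f"{prefix}{k + 1}",
                                         geometry.hemisphere)))
    return AtlasSet(maps, modality={m.name: modality for m in maps})


def make_library_from_latents(geometry: ParcelGeometry, n_maps: int = 10,
                              n_latents: int = 3, loading: float = 0.9,
                              length_scale: float | None = 25.0,
                              seed: int = 0, exact_structure: bool = False,
                              ) -> tuple[AtlasSet, np.ndarray]:
    """Maps as noisy copies of a few latent maps (for factor recovery).

    Map k is ``loading * latent_{k mod n_latents} + sqrt(1-loading^2) *
    noise_k``.  ``length_scale=None`` draws white-noise latents and noise
    instead of GP fields.  With ``exact_structure`` the latents and noise
    vectors are orthogonalized across parcels, so the sample correlation
    matrix satisfies the k-factor model exactly (useful for testing
    retention rules, which otherwise count borderline sampling factors).
    Returns the set and the true (n_maps, n_latents) loading matrix.
    """
    rng = np.random.default_rng(seed)
    if length_scale is None:
        draw = lambda m: rng.standard_normal((m, geometry.n_parcels))
    else:
        draw = lambda m: _gp_draws(geometry, length_scale, m, rng)
    lat = draw(n_latents)
    noise = draw(n_maps)
    if exact_structure:
        if geometry.n_parcels <= n_maps + n_latents:
            raise ValueError("exact_structure needs more parcels than "
                             "maps + latents")
        stack = np.vstack([lat, noise])
        stack = stack - stack.mean(1, keepdims=True)
        Q, _ = np.linalg.qr(stack.T)          # orthonormal columns
        stack = Q.T * np.sqrt(geometry.n_parcels)
        lat, noise = stack[:n_latents], stack[n_latents:]
    lat = (lat - lat.mean(1, keepdims=True)) / lat.std(1, keepdims=True)
    noise = (noise - noise.mean(1, keepdims=True)) / noise.std(1, keepdims=True)
    true_loadings = np.zeros((n_maps, n_latents))
    maps = []
    for k in range(n_maps):
        j = k % n_latents
        true_loadings[k, j] = loading
        vals = loading * lat[j] + np.sqrt(1 - loading ** 2) * noise[k]
        maps.append(zscore_map(ParcelMap(geometry.parcel_ids, vals,
                                         f"map{k + 1}", geometry.hemisphere)))
    return AtlasSet(maps), true_loadings


@dataclasses.dataclass
class GroundTruth:
    """Construction record for a synthetic CT-change mixture.

    ``mixture_weights`` are per-atlas weights on z-scored atlases; exactly
    one of ``noise_sd`` (SD of the autocorrelated noise component, in units
    of the mixture map) or ``construction_r2`` (target variance fraction
    explained by the atlases on the realized map) is specified up front;
    the generator fills in the other realized value.
    """

    mixture_weights: np.ndarray
    noise_sd: float | None = None
    construction_r2: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        self.mixture_weights = np.asarray(self.mixture_weights, float)
        if (self.noise_sd is None) == (self.construction_r2 is None):
            raise ValueError(
                "specify exactly one of noise_sd and construction_r2")
        if self.construction_r2 is not None:
            if not 0 < self.construction_r2 <= 1:
                raise ValueError("construction_r2 must lie in (0, 1]")
            if not np.any(self.mixture_weights != 0):
                raise ValueError(
                    "cannot target a positive R2 with all-zero weights")


def make_ct_trajectories(geometry: ParcelGeometry, atlas_truth: AtlasSet,
                         truth: GroundTruth,
                         age_grid: np.ndarray | None = None,
                         target_window: tuple[float, float] = (10.0, 15.0),
                         noise_length_scale: float = 25.0,
                         modulation: float = 0.03,
                         age_drift: float = 0.0,
                         ) -> tuple[CTTrajectorySet, GroundTruth]:
    """Smooth positive CT trajectories whose relative change over
    ``target_window`` is an affine image of ``weights . atlases + noise``.

    CT(p, a) = B(p) * g(a)^(1 + age_drift * D(p)) * (1 + modulation *
    M(p) * ramp(a)) with a GP baseline map B > 0, a smooth declining age
    factor g, a smoothstep ramp rising from 0 at window start to 1 at
    window end, and the z-scored mixture M.  Percentile and sex structure
    is multiplicative, so the relative-change map is identical across
    slices.  The noise component is a GP draw orthogonalized against the
    atlas columns, so the realized regression R2 of the change map on the
    atlases equals the construction value exactly.  ``age_drift`` adds a
    small atlas-independent GP modulation D of the aging rate so that
    change maps outside the target window also vary across parcels
    (default 0: change is spatially uniform wherever the mixture is
    silent).  Returns the trajectory set and the realized truth.
    """
    if age_grid is None:
        age_grid = np.arange(5.0, 90.0 + 1e-9, 0.5)
    age_grid = np.asarray(age_grid, float)
    if np.any(np.diff(age_grid) <= 0):
        raise ValueError("age grid must be strictly increasing")
    w = truth.mixture_weights
    if w.size != len(atlas_truth):
        raise ValueError(
            f"{w.size} weights for {len(atlas_truth)} atlases")
    rng = np.random.default_rng(truth.seed)
    npar = geometry.n_parcels

    A = atlas_truth.zscored().matrix()
    signal = A @ w
    noise_raw = _gp_draws(geometry, noise_length_scale, 1, rng)[0]
    # orthogonalize the noise against the atlas span so the construction R2
    # is exact under OLS on the true atlases
    Q, _ = np.linalg.qr(np.column_stack([np.ones(npar), A]))
    noise_orth = noise_raw - Q @ (Q.T @ noise_raw)
    sd_noise = noise_orth.std()
    sd_signal = signal.std()
    if truth.construction_r2 is not None:
        r2 = truth.construction_r2
        scale = (sd_signal / sd_noise) * np.sqrt((1 - r2) / r2) \
            if sd_noise > 0 else 0.0
        noise = scale * noise_orth
        noise_sd = float(noise.std())
    else:
        noise = (truth.noise_sd / sd_noise) * noise_orth \
            if truth.noise_sd > 0 and sd_noise > 0 else np.zeros(npar)
        noise_sd = float(truth.noise_sd)
    M = signal + noise
    tot = M.std()
    r2_realized = float((sd_signal ** 2) / (tot ** 2)) if tot > 0 else 0.0
    Mn = M / tot if tot > 0 else M  # unit SD keeps CT positive at any w

    base = 2.5 + 0.25 * _gp_draws(geometry, 30.0, 1, rng)[0]
    base = np.maximum(base, 1.0)
    g_age = 0.85 + 0.30 * np.exp(-age_grid / 25.0)  # smooth lifespan decline
    drift = _gp_draws(geometry, noise_length_scale, 1, rng)[0]
    drift = np.clip(drift / max(drift.std(), 1e-12), -3.0, 3.0)
    exponent = 1.0 + age_drift * drift
    i, j = target_window
    t = np.clip((age_grid - i) / (j - i), 0.0, 1.0)
    ramp = t * t * (3 - 2 * t)  # smoothstep: 0 before i, 1 after j

    ct_pa = (base[:, None] * g_age[None, :] ** exponent[:, None]
             * (1.0 + modulation * Mn[:, None] * ramp[None, :]))
    pct_off = np.array([-0.12, -0.08, -0.03, 0.0, 0.03, 0.08, 0.12])
    sex_off = np.array([0.02, -0.02])  # female slightly thicker baseline
    ct = (ct_pa[:, :, None, None]
          * (1 + pct_off)[None, None, :, None]
          * (1 + sex_off)[None, None, None, :])
    traj = CTTrajectorySet(geometry.parcel_ids, age_grid, ct,
                           PERCENTILES, SEXES, geometry.hemisphere)
    realized = GroundTruth(w.copy(), noise_sd=noise_sd, seed=truth.seed)
    realized.construction_r2 = r2_realized
    return traj, realized


@dataclasses.dataclass
class ExpressionDataset:
    """Postnatal developmental expression: subjects x genes with ages.

    ``expression`` holds normalized log2 values (n_subjects, n_genes);
    ``gene_sets`` maps marker names to gene lists; ``nonbrain_pool`` is the
    null gene pool and must be disjoint from every brain gene set.
    """

    subject_ids: tuple[str, ...]
    ages: np.ndarray
    genes: tuple[str, ...]
    expression: np.ndarray
    gene_sets: dict[str, list[str]]
    nonbrain_pool: list[str]
    peak_period: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.ages = np.asarray(self.ages, float)
        self.expression = np.asarray(self.expression, float)
        if np.any(self.ages <= 0):
            raise ValueError("ages must be postnatal (> 0 years)")
        if self.expression.shape != (len(self.subject_ids), len(self.genes)):
            raise ValueError("expression must be (n_subjects, n_genes)")
        known = set(self.genes)
        for name, members in self.gene_sets.items():
            missing = [g for g in members if g not in known]
            if missing:
                raise ValueError(f"gene set '{name}': unknown {missing[:3]}")
        brain = {g for s in self.gene_sets.values() for g in s}
        overlap = brain & set(self.nonbrain_pool)
        if overlap:
            raise ValueError(f"non-brain pool overlaps brain sets: "
                             f"{sorted(overlap)[:3]}")

    def gene_index(self, names) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(self.genes)}
        missing = [g for g in names if g not in lookup]
        if missing:
            raise KeyError(f"unknown gene(s): {missing[:5]}")
        return np.array([lookup[g] for g in names], dtype=int)

    def write(self, matrix_csv: str | Path, subjects_tsv: str | Path) -> None:
        pd.DataFrame(self.expression.T, index=list(self.genes),
                     columns=list(self.subject_ids)).to_csv(matrix_csv)
        pd.DataFrame({"subject": self.subject_ids, "age": self.ages}
                     ).to_csv(subjects_tsv, sep="\t", index=False)


def make_expression_dataset(n_subjects: int = 33,
                            ages: tuple[float, float] = (0.33, 82.05),
                            n_signal_genes: int = 50,
                            n_flat_genes: int = 50,
                            n_nonbrain_pool: int = 2154,
                            peak_period: tuple[float, float] = (5.0, 30.0),
                            effect_size: float = 2.0,
                            genes_per_set: int = 5,
                            seed: int = 0) -> ExpressionDataset:
    """Synthetic developmental expression with peaked vs. flat genes.

    Subject ages are log-spaced (postnatal sampling is dense at young
    ages) with the range endpoints pinned.  Every gene is baseline + iid
    noise (within-gene SD 0.5 log2 units); signal genes add a raised-cosine
    bump inside ``peak_period`` with amplitude ``effect_size`` within-gene
    SDs.  Signal and flat genes are grouped into marker gene sets of
    ``genes_per_set``; the non-brain pool genes are flat.
    """
    if n_nonbrain_pool < 1:
        raise ValueError("non-brain pool must be non-empty")
    lo, hi = ages
    if not (lo < peak_period[0] < peak_period[1] < hi):
        raise ValueError("peak_period must lie strictly inside the age range")
    rng = np.random.default_rng(seed)
    age = np.sort(np.exp(rng.uniform(np.log(lo), np.log(hi), n_subjects)))
    age[0], age[-1] = lo, hi

    sig = [f"sig{k:04d}" for k in range(n_signal_genes)]
    flat = [f"flat{k:04d}" for k in range(n_flat_genes)]
    pool = [f"nb{k:04d}" for k in range(n_nonbrain_pool)]
    genes = tuple(sig + flat + pool)
    n_genes = len(genes)

    noise_sd = 0.5
    baseline = rng.normal(6.0, 1.0, n_genes)
    expr = baseline[None, :] + rng.normal(0, noise_sd, (n_subjects, n_genes))
    p0, p1 = peak_period
    inside = (age >= p0) & (age <= p1)
    t = (age[inside] - p0) / (p1 - p0)
    bump = 0.5 * (1 - np.cos(2 * np.pi * t))  # 0 at edges, 1 mid-period
    expr[np.ix_(inside, np.arange(n_signal_genes))] += (
        effect_size * noise_sd * bump[:, None])

    def group(names, tag):
        return {f"{tag}{i + 1}": names[i * genes_per_set:(i + 1) * genes_per_set]
                for i in range(len(names) // genes_per_set)}

    gene_sets = {**group(sig, "marker_sig"), **group(flat, "marker_flat")}
    subjects = tuple(f"S{k:03d}" for k in range(n_subjects))
    return ExpressionDataset(subjects, age, genes, expr, gene_sets, pool,
                             peak_period)


@dataclasses.dataclass
class CohortData:
    """Two(+)-session longitudinal cohort: CT per subject x session x parcel."""

    subject_ids: tuple[str, ...]
    sex: tuple[str, ...]
    site: tuple[str, ...]
    session_labels: tuple[str, ...]
    ages: np.ndarray        # (n_subjects, n_sessions); NaN = missing session
    ct: np.ndarray          # (n_subjects, n_sessions, n_parcels)
    parcel_ids: tuple[str, ...]
    hemisphere: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.ages = np.asarray(self.ages, float)
        self.ct = np.asarray(self.ct, float)
        ns, nt = self.ages.shape
        if self.ct.shape != (ns, nt, len(self.parcel_ids)):
            raise ValueError("ct must be (subjects, sessions, parcels)")
        present = ~np.isnan(self.ages)
        if np.any(np.nansum(present, axis=1) < 1):
            raise ValueError("each subject needs at least one session")
        if np.any(self.ct[present] <= 0):
            raise ValueError("CT must be strictly positive where observed")

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    def to_long_frame(self) -> pd.DataFrame:
        rows = []
        for s, sid in enumerate(self.subject_ids):
            for t, lab in enumerate(self.session_labels):
                if np.isnan(self.ages[s, t]):
                    continue
                rows.append(pd.DataFrame({
                    "subject": sid, "session": lab,
                    "age": self.ages[s, t], "sex": self.sex[s],
                    "site": self.site[s], "parcel": list(self.parcel_ids),
                    "ct": self.ct[s, t]}))
        return pd.concat(rows, ignore_index=True)

    def write_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        self.to_long_frame().to_csv(path, sep="\t", index=False,
                                    float_format="%.17g")
        return path

    @classmethod
    def from_long_frame(cls, df: pd.DataFrame) -> "CohortData":
        parcels = tuple(dict.fromkeys(df["parcel"].astype(str)))
        subjects = tuple(dict.fromkeys(df["subject"].astype(str)))
        sessions = tuple(dict.fromkeys(df["session"].astype(str)))
        ns, nt, npar = len(subjects), len(sessions), len(parcels)
        ages = np.full((ns, nt), np.nan)
        ct = np.full((ns, nt, npar), np.nan)
        sex, site = {}, {}
        pidx = {p: i for i, p in enumerate(parcels)}
        sidx = {s: i for i, s in enumerate(subjects)}
        tidx = {t: i for i, t in enumerate(sessions)}
        for (subj, sess), grp in df.groupby(["subject", "session"],
                                            sort=False):
            s, t = sidx[str(subj)], tidx[str(sess)]
            ages[s, t] = grp["age"].iloc[0]
            sex[s] = str(grp["sex"].iloc[0])
            site[s] = str(grp["site"].iloc[0])
            rows = [pidx[str(p)] for p in grp["parcel"]]
            ct[s, t, rows] = grp["ct"].to_numpy()
        # placeholder positive CT for missing sessions (masked via ages NaN)
        ct[np.isnan(ct)] = 1.0
        return cls(subjects, tuple(sex[i] for i in range(ns)),
                   tuple(site[i] for i in range(ns)), sessions, ages, ct,
                   parcels)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "CohortData":
        return cls.from_long_frame(
            pd.read_csv(path, sep="\t", float_precision="round_trip"))


def make_cohort(geometry: ParcelGeometry, trajectories: CTTrajectorySet,
                n_subjects: int = 100, n_sites: int = 20,
                subject_sd: float = 0.05, site_sd: float = 0.02,
                noise_sd: float = 0.02,
                session_ages: tuple[float, ...] = (10.0, 12.0),
                seed: int = 0) -> CohortData:
    """Two-session cohort: population CT + subject/site maps + noise.

    Per subject, CT at a session is the population trajectory (median
    percentile, sex-average) at the session age, plus a subject random
    intercept map (GP, SD ``subject_sd`` mm), a site offset map (GP, SD
    ``site_sd`` mm) shared within site, and iid measurement noise.  Sites
    are assigned round-robin (balanced within one subject).  Data are
    emitted already harmonized (no site-by-scale interactions).
    """
    if n_sites < 1:
        raise ValueError("need at least one site")
    if len(session_ages) < 2:
        raise ValueError("need at least two session ages")
    rng = np.random.default_rng(seed)
    npar = geometry.n_parcels
    pop = np.column_stack([
        trajectories.slice_map(a, 50, "average").values
        for a in session_ages])                      # (npar, nsess)
    subj_maps = (subject_sd * _gp_draws(geometry, 25.0, n_subjects, rng)
                 if subject_sd > 0 else np.zeros((n_subjects, npar)))
    site_maps = (site_sd * _gp_draws(geometry, 25.0, n_sites, rng)
                 if site_sd > 0 else np.zeros((n_sites, npar)))
    nsess = len(session_ages)
    noise = (noise_sd * rng.standard_normal((n_subjects, nsess, npar))
             if noise_sd > 0 else np.zeros((n_subjects, nsess, npar)))
    sites = np.arange(n_subjects) % n_sites
    ct = (pop.T[None] + subj_maps[:, None, :]
          + site_maps[sites][:, None, :] + noise)
    ct = np.maximum(ct, 0.05)
    ages = np.tile(np.asarray(session_ages, float), (n_subjects, 1))
    return CohortData(
        tuple(f"sub{k:04d}" for k in range(n_subjects)),
        tuple("female" if k % 2 else "male" for k in range(n_subjects)),
        tuple(f"site{sites[k]:02d}" for k in range(n_subjects)),
        tuple(f"T{t}" for t in range(nsess)),
        ages, ct, geometry.parcel_ids, geometry.hemisphere)
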