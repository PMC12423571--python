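"""Synthetic ground-truth data: path-model samples and full landscape bundles.

Two levels of synthesis are provided.

* :func:`simulate_sem_table` draws assemblage tables directly from a known
  linear-Gaussian path model — the ground truth for estimator checks.
* :func:`simulate_landscape` builds a full input bundle (trait tables,
  occurrence points, range discs, environmental / footprint / land-mask
  rasters, and imputation replicates) on an abstract island so the entire
  pipeline from rasterization to spatial checks can run without any
  external download.

The landscape embeds a known causal cascade at the assemblage level:
human footprint downsizes extant frugivores, large extant frugivores pull
large-seeded plants, footprint weakly repels large-seeded plants directly,
and mega-seeded plants (seed width above the swallowing limit of extant
frugivores) track the distribution of large extinct megafrugivores only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from shapely.geometry import Point

from .model import PathModel, default_downsizing_model
from .rasters import Raster

__all__ = [
    "SimConfig",
    "LandscapeBundle",
    "default_true_parameters",
    "theta_from_maps",
    "simulate_sem_table",
    "emulate_imputations",
    "simulate_landscape",
]

#: true standardized-scale path coefficients used by the default generator;
#: signs follow the downsizing / legacy hypotheses
DEFAULT_PATHS = {
    ("seed", "footprint"): -0.15,
    ("seed", "mass_extant"): 0.40,
    ("seed", "mass_extinct"): 0.20,
    ("seed", "pc1"): 0.20,
    ("seed", "pc2"): 0.25,
    ("mass_extant", "footprint"): -0.50,
    ("mass_extant", "pc1"): 0.10,
    ("mass_extant", "pc2"): 0.35,
    ("mass_extinct", "pc1"): 0.40,
    ("mass_extinct", "pc2"): 0.30,
    ("footprint", "pc1"): -0.30,
    ("footprint", "pc2"): 0.30,
}
DEFAULT_RESID = {
    "seed": 0.60,
    "mass_extant": 0.60,
    "mass_extinct": 0.70,
    "footprint": 0.80,
    "pc1": 1.0,
    "pc2": 1.0,
}
DEFAULT_COVS = {
    ("footprint", "mass_extinct"): 0.10,
    ("mass_extant", "mass_extinct"): 0.10,
    ("pc1", "pc2"): 0.0,
}


def theta_from_maps(
    model: PathModel,
    paths: dict[tuple[str, str], float],
    resid: dict[str, float],
    covs: dict[tuple[str, str], float] | None = None,
) -> np.ndarray:
    """Assemble a free-parameter vector from edge/variance maps."""
    covs = covs or {}
    theta = np.zeros(model.n_free)
    for k, edge in enumerate(model.regressions):
        theta[k] = paths.get(edge, 0.0)
    v = model.variables
    for k, (i, j) in enumerate(model.free_psi_pairs(), start=len(model.regressions)):
        if i == j:
            theta[k] = resid[v[i]]
        else:
            theta[k] = covs.get((v[i], v[j]), covs.get((v[j], v[i]), 0.0))
    return theta


def default_true_parameters() -> tuple[PathModel, np.ndarray]:
    model = default_downsizing_model()
    return model, theta_from_maps(model, DEFAULT_PATHS, DEFAULT_RESID, DEFAULT_COVS)


def simulate_sem_table(
    model: PathModel,
    theta: np.ndarray,
    n: int,
    seed: int,
) -> pd.DataFrame:
    """Draw ``n`` rows from the linear-Gaussian system y = By + zeta.

    Columns follow the model's variable order; all randomness flows from
    ``seed``.
    """
    B, Psi = model.build_matrices(theta)
    if np.any(np.diag(Psi) <= 0):
        raise ValueError("residual variances must be positive")
    p = model.n_vars
    if n < p:
        raise ValueError("n must be at least the number of variables")
    rng = np.random.default_rng(seed)
    # zeta via Cholesky of Psi (Psi must be PSD with positive diagonal)
    try:
        L = np.linalg.cholesky(Psi)
    except np.linalg.LinAlgError as exc:
        raise ValueError("Psi is not positive definite") from exc
    zeta = rng.standard_normal((n, p)) @ L.T
    y = np.linalg.solve(np.eye(p) - B, zeta.T).T
    return pd.DataFrame(y, columns=list(model.variables))


def emulate_imputations(
    traits: pd.DataFrame,
    fraction: float,
    m: int,
    noise_sd: float,
    seed: int,
    width_col: str = "seed_width_mm",
    eligible: np.ndarray | None = None,
) -> list[pd.DataFrame]:
    """Emulate multiple-imputation replicates of a seed-width table.

    A random subset of ``round(fraction * n)`` species is flagged imputed;
    in each of the ``m`` replicates the flagged widths are independently
    perturbed on the log scale with standard deviation ``noise_sd``
    (imputation noise on positive widths), while unflagged widths are
    identical across replicates.  The flag is returned in column
    ``imputed``.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    if m < 1:
        raise ValueError("m must be at least 1")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    n = len(traits)
    if eligible is None:
        eligible = np.ones(n, dtype=bool)
    pool = np.flatnonzero(np.asarray(eligible, dtype=bool))
    k = min(int(round(fraction * n)), len(pool))
    flagged = np.zeros(n, dtype=bool)
    if k > 0:
        flagged[rng.choice(pool, size=k, replace=False)] = True
    reps = []
    base = traits[width_col].to_numpy(dtype=float)
    for _ in range(m):
        t = traits.copy()
        w = base.copy()
        if k > 0 and noise_sd > 0:
            w[flagged] = np.exp(np.log(w[flagged]) + rng.normal(0, noise_sd, size=k))
        t[width_col] = w
        t["imputed"] = flagged
        reps.append(t)
    return reps


# ---------------------------------------------------------------------------
# landscape bundle
# ---------------------------------------------------------------------------
@dataclass
class SimConfig:
    """Parameters of the synthetic landscape.

    Defaults mirror the study conditions at a desk-scale extent: a
    30 km assemblage grid, 20 imputation replicates covering 57.7% of
    plant species, a mega-seed threshold of 24.6 mm, and a causal cascade
    footprint -| extant mass -> seed width with a direct footprint -| seed
    path and an extinct-mass legacy confined to mega-seeded species.
    """

    extent_km: tuple[float, float] = (420.0, 600.0)  # (width, height)
    cell_size_m: float = 30_000.0
    pixel_size_m: float = 6_000.0
    n_plants: int = 750
    n_frugivores_extant: int = 80
    n_frugivores_extinct: int = 20
    imputed_fraction: float = 0.577
    m_imputations: int = 20
    imputation_noise_sd: float = 0.15
    mega_threshold_mm: float = 24.6
    seed_width_log_mean: float = float(np.log(5.0))
    seed_width_log_sd: float = 0.75
    #: mega-seeded relicts: count, range restriction and width spread above
    #: the swallowing threshold (bulk species are gape-limited below it)
    n_mega_species: int = 15
    mega_range_radius_m: float = 20_000.0
    mega_width_log_sd: float = 0.65
    #: sd of the quantile jitter in trait-rank placement (0 = perfect
    #: sorting of species along their suitability gradient)
    placement_jitter: float = 0.05
    direct_footprint_effect: float = 1.0
    mean_occurrences: float = 7.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.imputed_fraction <= 1.0:
            raise ValueError("imputed_fraction must be in [0, 1]")
        if self.n_plants <= 0 or self.n_frugivores_extant <= 0:
            raise ValueError("species counts must be positive")
        if self.cell_size_m <= 0 or self.pixel_size_m <= 0:
            raise ValueError("sizes must be positive")
        nx = self.extent_km[0] * 1000 / self.cell_size_m
        ny = self.extent_km[1] * 1000 / self.cell_size_m
        if nx < 1 or ny < 1:
            raise ValueError("extent smaller than one grid cell")

    @property
    def n_cells(self) -> int:
        nx = int(round(self.extent_km[0] * 1000 / self.cell_size_m))
        ny = int(round(self.extent_km[1] * 1000 / self.cell_size_m))
        return nx * ny


@dataclass
class LandscapeBundle:
    """Everything the pipeline ingests, generated with known ground truth."""

    plants: pd.DataFrame  # species, seed_width_mm, imputed
    frugivores: pd.DataFrame  # species, body_mass_g, status
    occurrences: pd.DataFrame  # species, x, y
    ranges: dict[str, object]  # species -> shapely geometry (discs)
    env_rasters: dict[str, Raster]
    footprint: Raster
    landmask: Raster
    imputations: list[pd.DataFrame]
    config: SimConfig | None = None


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int], sigma: float) -> np.ndarray:
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=sigma, mode="nearest")
    return (f - f.mean()) / (f.std() + 1e-12)


def _zscore(x: np.ndarray) -> np.ndarray:
    return (x - x.mean()) / (x.std() + 1e-12)


def simulate_landscape(config: SimConfig | None = None) -> LandscapeBundle:
    """Generate a full landscape bundle on an abstract island.

    Environmental structure: a north–south moisture gradient (``env_dry``),
    a radial highland dome (``env_elev``) and an east–west mixture layer
    (``env_mix``), each with smooth spatial noise.  Footprint concentrates
    in the highlands and the drier part of the island.  Species are placed
    as discs (frugivores, megafauna) or Poisson point clouds inside discs
    (plants) whose centers prefer cells matching their trait value, which
    induces the assemblage-level cascade documented in the module
    docstring.
    """
    cfg = config or SimConfig()
    rng = np.random.default_rng(cfg.rng_seed)

    w_m = cfg.extent_km[0] * 1000.0
    h_m = cfg.extent_km[1] * 1000.0
    ncol = int(round(w_m / cfg.pixel_size_m))
    nrow = int(round(h_m / cfg.pixel_size_m))

    # --- island land mask: inscribed ellipse --------------------------------
    jj, ii = np.meshgrid(np.arange(ncol), np.arange(nrow))
    cx, cy = (ncol - 1) / 2.0, (nrow - 1) / 2.0
    ell = ((jj - cx) / (0.52 * ncol)) ** 2 + ((ii - cy) / (0.52 * nrow)) ** 2
    land = (ell <= 1.0).astype(float)

    # --- environmental fields (pixel scale) ---------------------------------
    lat = _zscore(-(ii.astype(float)))  # increases northwards
    dome = _zscore(-ell)  # high in the island center
    # two latent axes (seasonal drought; highland-lowland) drive all three
    # observed layers, so the first two principal components recover them
    env_dry = _zscore(0.9 * lat + 0.3 * _smooth_field(rng, (nrow, ncol), 6))
    env_elev = _zscore(0.9 * dome + 0.3 * _smooth_field(rng, (nrow, ncol), 6))
    env_mix = _zscore(0.6 * env_dry - 0.6 * env_elev + 0.15 * _smooth_field(rng, (nrow, ncol), 6))

    foot_raw = _zscore(
        0.4 * env_elev - 0.3 * env_dry + 0.85 * _smooth_field(rng, (nrow, ncol), 9)
    )
    footprint_vals = 25.0 + 10.0 * foot_raw  # unitless index, roughly 0..50
    footprint_vals = np.clip(footprint_vals, 0.0, 50.0)

    def mk(vals: np.ndarray) -> Raster:
        v = np.where(land > 0, vals, np.nan)
        return Raster(v, 0.0, 0.0, cfg.pixel_size_m)

    env_rasters = {
        "env_dry": mk(env_dry),
        "env_elev": mk(env_elev),
        "env_mix": mk(env_mix),
    }
    footprint = mk(footprint_vals)
    landmask = Raster(land, 0.0, 0.0, cfg.pixel_size_m)

    # --- latent cell-level targets ------------------------------------------
    ncx = int(round(w_m / cfg.cell_size_m))
    ncy = int(round(h_m / cfg.cell_size_m))
    px_per_cell = int(round(cfg.cell_size_m / cfg.pixel_size_m))

    def cell_mean(a: np.ndarray) -> np.ndarray:
        # mean over land pixels of each cell; rows of `a` start at the top
        out = np.full((ncy, ncx), np.nan)
        for r in range(ncy):
            for c in range(ncx):
                blk = a[r * px_per_cell : (r + 1) * px_per_cell,
                        c * px_per_cell : (c + 1) * px_per_cell]
                msk = land[r * px_per_cell : (r + 1) * px_per_cell,
                           c * px_per_cell : (c + 1) * px_per_cell] > 0
                if msk.any():
                    out[r, c] = blk[msk].mean()
        return out

    F_c = cell_mean(footprint_vals)
    dry_c = cell_mean(env_dry)
    elev_c = cell_mean(env_elev)
    ok = ~np.isnan(F_c)

    def cz(a: np.ndarray) -> np.ndarray:
        z = np.full_like(a, 0.0)
        z[ok] = _zscore(a[ok])
        return z

    Fz, dryz, elevz = cz(F_c), cz(dry_c), cz(elev_c)
    def noise() -> np.ndarray:
        # spatially smooth guild-specific field: correlated over ~1.5 cells
        # so it survives range-disc smoothing and reaches the trait metrics
        f = ndimage.gaussian_filter(
            rng.standard_normal(F_c.shape), sigma=1.5, mode="nearest"
        )
        return cz(np.where(ok, f, 0.0))
    extant_target = _masked_z(-0.7 * Fz - 0.3 * elevz + 0.6 * noise(), ok)

    # cell centers (x, y) for placing disc centers
    xs_c = (np.arange(ncx) + 0.5) * cfg.cell_size_m
    ys_c = h_m - (np.arange(ncy) + 0.5) * cfg.cell_size_m
    cxg, cyg = np.meshgrid(xs_c, ys_c)

    def place_by_quantile(
        trait_z: np.ndarray,
        field: np.ndarray,
        q_range: tuple[float, float] = (0.0, 1.0),
    ) -> np.ndarray:
        """Centers for a guild: trait rank maps to the field's quantile.

        Species are sorted by trait and placed at the matching quantile of
        the suitability field (plus jitter), so larger-trait species sit in
        higher-suitability cells — a smooth, low-variance trait-matching
        coupling.  Returns an (n, 2) array of center coordinates.
        """
        n_sp = trait_z.size
        ranks = np.argsort(np.argsort(trait_z))
        q = (ranks + 0.5) / n_sp
        q = np.clip(q + rng.normal(0.0, cfg.placement_jitter, n_sp), 0.0, 1.0)
        q = q_range[0] + q * (q_range[1] - q_range[0])
        vals = field[ok]
        order = np.argsort(vals)
        xs = cxg[ok][order]
        ys = cyg[ok][order]
        idx = np.minimum((q * (vals.size - 1)).round().astype(int), vals.size - 1)
        jit = (rng.random((n_sp, 2)) - 0.5) * cfg.cell_size_m
        return np.column_stack([xs[idx] + jit[:, 0], ys[idx] + jit[:, 1]])

    # --- frugivores -----------------------------------------------------------
    frug_rows = []
    ranges: dict[str, object] = {}
    ext_masses = np.exp(rng.normal(np.log(1500.0), 1.1, size=cfg.n_frugivores_extant))
    ext_centers = place_by_quantile(np.log(ext_masses), extant_target)
    ext_radii = np.exp(rng.normal(np.log(45_000.0), 0.2, size=cfg.n_frugivores_extant))
    for s in range(cfg.n_frugivores_extant):
        name = f"frug_extant_{s:03d}"
        ranges[name] = Point(*ext_centers[s]).buffer(ext_radii[s], quad_segs=24)
        frug_rows.append((name, float(ext_masses[s]), "extant"))

    # realized trait surfaces: 95th-percentile mass of the species whose
    # range disc covers each cell center, per guild
    cell_xy = np.column_stack([cxg[ok], cyg[ok]])

    def realized_surface(centers_g, radii_g, traits_g):
        # mimic the any-overlap rasterization rule: a disc reaches a cell
        # if it comes within half a cell diagonal of the cell center
        reach = radii_g[None, :] + 0.5 * np.sqrt(2.0) * cfg.cell_size_m
        present = (
            np.linalg.norm(cell_xy[:, None, :] - centers_g[None, :, :], axis=2)
            <= reach
        )
        surf = np.full(cell_xy.shape[0], np.nan)
        for c in range(cell_xy.shape[0]):
            if present[c].any():
                surf[c] = np.percentile(traits_g[present[c]], 95)
        return np.where(np.isnan(surf), np.nanmin(surf), surf)

    e95 = realized_surface(ext_centers, ext_radii, ext_masses)
    ze95 = np.zeros_like(Fz)
    ze95[ok] = _zscore(np.log(e95))

    # extinct suitability: its guild-specific component is orthogonalized
    # against footprint, environment and the realized extant surface, so
    # by construction the megafrugivore legacy carries no signal for the
    # gape-limited (non-mega) flora
    nu_raw = noise()
    X_orth = np.column_stack(
        [np.ones(ok.sum()), Fz[ok], dryz[ok], elevz[ok], ze95[ok]]
    )
    beta_o, *_ = np.linalg.lstsq(X_orth, nu_raw[ok], rcond=None)
    nu_x = np.zeros_like(Fz)
    nu_x[ok] = _zscore(nu_raw[ok] - X_orth @ beta_o)
    extinct_target = _masked_z(0.45 * dryz + 0.35 * elevz + 0.55 * nu_x, ok)

    mega_masses = np.exp(rng.normal(np.log(60_000.0), 0.9, size=cfg.n_frugivores_extinct))
    mega_centers = place_by_quantile(np.log(mega_masses), extinct_target)
    mega_radii = np.exp(rng.normal(np.log(60_000.0), 0.45, size=cfg.n_frugivores_extinct))
    for s in range(cfg.n_frugivores_extinct):
        name = f"frug_extinct_{s:03d}"
        ranges[name] = Point(*mega_centers[s]).buffer(mega_radii[s], quad_segs=24)
        frug_rows.append((name, float(mega_masses[s]), "extinct"))
    frugivores = pd.DataFrame(frug_rows, columns=["species", "body_mass_g", "status"])

    # --- plants ---------------------------------------------------------------
    # bulk endozoochorous species are gape-limited: widths drawn from a
    # lognormal truncated at the swallowing threshold of extant frugivores
    n_bulk = cfg.n_plants - cfg.n_mega_species
    if n_bulk <= 0:
        raise ValueError("n_plants must exceed n_mega_species")
    mu, sd, thr = cfg.seed_width_log_mean, cfg.seed_width_log_sd, cfg.mega_threshold_mm
    u = rng.random(n_bulk)
    from scipy import stats as _stats

    cap = _stats.norm.cdf((np.log(thr) - mu) / sd)
    bulk = np.exp(mu + sd * _stats.norm.ppf(u * cap))

    x95 = realized_surface(mega_centers, mega_radii, mega_masses)

    # anachronistic relicts persist in the upper reaches of the legacy
    # gradient; each relict's seed width matches the mass of the largest
    # megafrugivores that historically occurred at its home cell
    n_rel = cfg.n_mega_species
    order_cells = np.argsort(x95)
    top = order_cells[int(0.5 * len(order_cells)):]
    pick = np.linspace(0, len(top) - 1, n_rel).round().astype(int)
    home = top[pick]
    # width follows the home cell's legacy *value* (not its rank): the x95
    # surface is lumpy, so ranks would scramble the trait matching
    lx = np.log(x95[home])
    zx = (lx - lx.mean()) / (lx.std() + 1e-12)
    u_val = (zx - zx.min()) / (zx.max() - zx.min() + 1e-12)
    relict = thr * np.exp(
        np.clip(
            0.04 + 2.0 * cfg.mega_width_log_sd * u_val
            + rng.normal(0.0, 0.04, n_rel),
            0.02,
            None,
        )
    )
    widths = np.concatenate([bulk, relict])
    is_mega = np.concatenate(
        [np.zeros(n_bulk, dtype=bool), np.ones(n_rel, dtype=bool)]
    )

    # bulk placement field: trait matching with the *realized* extant
    # frugivore size surface plus the direct repulsion of large-seeded
    # plants from high-footprint cells
    e95_field = np.zeros_like(Fz)
    e95_field[ok] = (np.log(e95) - np.log(e95).mean()) / (np.log(e95).std() + 1e-12)
    bulk_field = _masked_z(
        e95_field - cfg.direct_footprint_effect * 0.3 * Fz, ok
    )
    centers = np.empty((cfg.n_plants, 2))
    centers[~is_mega] = place_by_quantile(np.log(widths[~is_mega]), bulk_field)
    centers[is_mega] = cell_xy[home] + (rng.random((n_rel, 2)) - 0.5) * cfg.cell_size_m
    occ_rows = []
    for s in range(cfg.n_plants):
        name = f"plant_{s:04d}"
        if is_mega[s]:
            # relicts are conspicuous large trees with more records
            radius = np.exp(rng.normal(np.log(cfg.mega_range_radius_m), 0.3))
            n_pts = rng.poisson(1.0 * cfg.mean_occurrences) + 2
        else:
            radius = np.exp(rng.normal(np.log(25_000.0), 0.2))
            n_pts = rng.poisson(cfg.mean_occurrences) + 2
        ang = rng.random(n_pts) * 2 * np.pi
        rad = radius * np.sqrt(rng.random(n_pts))
        px = np.clip(centers[s, 0] + rad * np.cos(ang), 0, w_m - 1.0)
        py = np.clip(centers[s, 1] + rad * np.sin(ang), 0, h_m - 1.0)
        for x, y in zip(px, py):
            occ_rows.append((name, float(x), float(y)))
    plants = pd.DataFrame(
        {"species": [f"plant_{s:04d}" for s in range(cfg.n_plants)],
         "seed_width_mm": widths}
    )
    occurrences = pd.DataFrame(occ_rows, columns=["species", "x", "y"])

    # --- imputation replicates (mega species never imputed, as in the data) --
    imps = emulate_imputations(
        plants,
        cfg.imputed_fraction,
        cfg.m_imputations,
        cfg.imputation_noise_sd,
        seed=int(rng.integers(2**31 - 1)),
        eligible=~is_mega,
    )
    plants = imps[0][["species", "seed_width_mm", "imputed"]].copy()
    plants["seed_width_mm"] = widths  # replicate 1 noise stays in imps only

    return LandscapeBundle(
        plants=plants,
        frugivores=frugivores,
        occurrences=occurrences,
        ranges=ranges,
        env_rasters=env_rasters,
        footprint=footprint,
        landmask=landmask,
        imputations=imps,
        config=cfg,
    )


def _masked_z(a: np.ndarray, ok: np.ndarray) -> np.ndarray:
    z = np.zeros_like(a)
    z[ok] = _zscore(a[ok])
    return z
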