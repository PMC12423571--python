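"""Grid-cell assemblages: rasterization, upper-percentile traits, filters.

An assemblage is the set of plant and frugivore species co-occurring in one
grid cell of a projected metric grid (30 km cells by default).  Cell trait
metrics use the 95th-percentile "maximum" — the upper tail of the trait
distribution with extreme outliers damped — and cells are filtered to those
with enough species and land area for the trait-matching hypotheses to be
meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from shapely import STRtree
from shapely.geometry import box

from .rasters import Raster

__all__ = [
    "Grid",
    "PresenceMatrix",
    "FilterRules",
    "load_mega_seeded_table",
    "MEGA_SEED_THRESHOLD_MM",
    "build_grid",
    "rasterize_points",
    "rasterize_ranges",
    "upper_percentile",
    "classify_mega_seeded",
    "assemblage_metrics",
    "filter_assemblages",
    "split_by_mega",
]

#: width (mm) of the largest seed recorded to be dispersed by an extant
#: Malagasy frugivore; seeds strictly wider are "mega-seeded"/anachronistic
MEGA_SEED_THRESHOLD_MM = 24.6


def load_mega_seeded_table() -> pd.DataFrame:
    """The 15 mega-seeded endozoochorous species with printed seed widths."""
    with resources.files("seedpath.data").joinpath("mega_seeded_species.csv").open() as fh:
        return pd.read_csv(fh)


# ---------------------------------------------------------------------------
# grid
# ---------------------------------------------------------------------------
@dataclass
class Grid:
    """Regular projected grid; cell ids are row-major from the top-left."""

    x0: float
    y0: float  # lower-left corner
    cell_size: float
    n_rows: int
    n_cols: int
    land_fraction: np.ndarray  # flat, length n_rows * n_cols
    crs: str = "local-metric"

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        self.land_fraction = np.asarray(self.land_fraction, dtype=float)
        if self.land_fraction.shape != (self.n_rows * self.n_cols,):
            raise ValueError("land_fraction length must equal cell count")
        if np.nanmin(self.land_fraction) < -1e-9 or np.nanmax(self.land_fraction) > 1 + 1e-9:
            raise ValueError("land fractions must lie in [0, 1]")

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def y_top(self) -> float:
        return self.y0 + self.n_rows * self.cell_size

    def cell_of(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Row-major cell id for points; -1 for points outside the grid.

        Membership uses half-open intervals [x0, x0 + s) horizontally and
        (y_top - s, y_top] handled analogously so each point belongs to
        exactly one cell.
        """
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        col = np.floor((x - self.x0) / self.cell_size).astype(int)
        row = np.floor((self.y_top - y) / self.cell_size).astype(int)
        # points exactly on the top edge belong to row 0
        row = np.where(np.isclose(y, self.y_top), 0, row)
        inside = (col >= 0) & (col < self.n_cols) & (row >= 0) & (row < self.n_rows)
        return np.where(inside, row * self.n_cols + col, -1)

    def cell_box(self, cell_id: int):
        row, col = divmod(cell_id, self.n_cols)
        x0 = self.x0 + col * self.cell_size
        y1 = self.y_top - row * self.cell_size
        return box(x0, y1 - self.cell_size, x0 + self.cell_size, y1)

    def centroids(self) -> np.ndarray:
        """(n_cells, 2) array of cell center coordinates."""
        cols = np.arange(self.n_cols)
        rows = np.arange(self.n_rows)
        cxs = self.x0 + (cols + 0.5) * self.cell_size
        cys = self.y_top - (rows + 0.5) * self.cell_size
        gx, gy = np.meshgrid(cxs, cys)
        return np.column_stack([gx.ravel(), gy.ravel()])


def build_grid(
    extent: tuple[float, float, float, float],
    cell_size: float,
    landmask: Raster | None = None,
) -> Grid:
    """Lay a regular grid over ``extent`` = (xmin, ymin, xmax, ymax).

    Land fraction per cell is the mean of the land-mask pixels whose
    centers fall in the cell (1.0 everywhere when no mask is given).
    """
    xmin, ymin, xmax, ymax = extent
    if xmax <= xmin or ymax <= ymin:
        raise ValueError("degenerate extent")
    if cell_size <= 0:
        raise ValueError("cell_size must be positive")
    n_cols = int(np.ceil((xmax - xmin) / cell_size - 1e-9))
    n_rows = int(np.ceil((ymax - ymin) / cell_size - 1e-9))
    if n_cols < 1 or n_rows < 1:
        raise ValueError("extent smaller than one cell")
    grid = Grid(xmin, ymin, cell_size, n_rows, n_cols,
                np.ones(n_rows * n_cols))
    if landmask is not None:
        gx, gy = landmask.pixel_centers()
        vals = landmask.values
        cells = grid.cell_of(gx.ravel(), gy.ravel())
        frac = np.zeros(grid.n_cells)
        v = vals.ravel()
        for cid in range(grid.n_cells):
            sel = cells == cid
            if sel.any():
                frac[cid] = np.nanmean(np.nan_to_num(v[sel], nan=0.0))
        grid = Grid(xmin, ymin, cell_size, n_rows, n_cols, frac)
    return grid


# ---------------------------------------------------------------------------
# presence matrices
# ---------------------------------------------------------------------------
@dataclass
class PresenceMatrix:
    """Boolean cells-by-species matrix for one guild."""

    matrix: np.ndarray
    species: tuple[str, ...]
    guild: str = "plant"

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=bool)
        if self.matrix.shape[1] != len(self.species):
            raise ValueError("matrix width must equal species count")

    @property
    def n_cells(self) -> int:
        return self.matrix.shape[0]

    def richness(self) -> np.ndarray:
        return self.matrix.sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix.astype(int), columns=list(self.species))


def rasterize_points(
    occurrences: pd.DataFrame,
    grid: Grid,
    species: list[str] | None = None,
    guild: str = "plant",
    x_col: str = "x",
    y_col: str = "y",
) -> PresenceMatrix:
    """Presence where at least one occurrence point falls in a cell.

    Duplicate points and row order do not matter; species without points
    keep an all-false row.
    """
    for col in ("species", x_col, y_col):
        if col not in occurrences.columns:
            raise ValueError(f"occurrence table lacks column {col!r}")
    if species is None:
        species = sorted(occurrences["species"].unique())
    sp_index = {s: k for k, s in enumerate(species)}
    unknown = set(occurrences["species"]) - set(species)
    if unknown:
        raise ValueError(f"occurrences for unknown species: {sorted(unknown)[:5]}")
    M = np.zeros((grid.n_cells, len(species)), dtype=bool)
    cells = grid.cell_of(occurrences[x_col].to_numpy(), occurrences[y_col].to_numpy())
    for cid, sp in zip(cells, occurrences["species"]):
        if cid >= 0:
            M[cid, sp_index[sp]] = True
    return PresenceMatrix(M, tuple(species), guild)


def rasterize_ranges(
    ranges: dict[str, object],
    grid: Grid,
    guild: str = "frugivore",
    rule: str = "any",
) -> PresenceMatrix:
    """Presence where a range polygon overlaps a cell.

    ``rule='any'`` marks presence for any positive-area intersection
    (touching an edge does not count); ``rule='centroid'`` requires the
    cell centroid to be covered.
    """
    species = tuple(sorted(ranges))
    M = np.zeros((grid.n_cells, len(species)), dtype=bool)
    boxes = [grid.cell_box(cid) for cid in range(grid.n_cells)]
    tree = STRtree(boxes)
    cents = grid.centroids()
    for k, sp in enumerate(species):
        geom = ranges[sp]
        if geom is None or getattr(geom, "is_empty", True):
            raise ValueError(f"empty geometry for species {sp!r}")
        if not geom.is_valid:
            raise ValueError(f"invalid geometry for species {sp!r}")
        if rule == "any":
            for idx in tree.query(geom):
                inter = geom.intersection(boxes[idx])
                if not inter.is_empty and inter.area > 0:
                    M[idx, k] = True
        elif rule == "centroid":
            from shapely.geometry import Point

            for cid in range(grid.n_cells):
                if geom.covers(Point(*cents[cid])):
                    M[cid, k] = True
        else:
            raise ValueError("rule must be 'any' or 'centroid'")
    return PresenceMatrix(M, species, guild)


# ---------------------------------------------------------------------------
# trait metrics
# ---------------------------------------------------------------------------
def upper_percentile(values: np.ndarray, level: float = 95.0) -> float:
    """Linear-interpolation percentile at index h = (level/100)(n-1)."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty input")
    if not 0 < level <= 100:
        raise ValueError("level must be in (0, 100]")
    return float(np.percentile(values, level, method="linear"))


def classify_mega_seeded(
    traits: pd.DataFrame,
    threshold: float = MEGA_SEED_THRESHOLD_MM,
    width_col: str = "seed_width_mm",
) -> pd.Series:
    """Flag species whose seed is strictly wider than the threshold."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    widths = traits[width_col]
    if widths.isna().any():
        bad = traits.loc[widths.isna(), "species"].tolist()
        raise ValueError(f"missing seed widths for: {bad}")
    return (widths > threshold).rename("mega")


def assemblage_metrics(
    grid: Grid,
    plant_presence: PresenceMatrix,
    plant_traits: pd.DataFrame,
    extant_presence: PresenceMatrix,
    extinct_presence: PresenceMatrix,
    frugivore_traits: pd.DataFrame,
    level: float = 95.0,
    width_col: str = "seed_width_mm",
) -> pd.DataFrame:
    """Per-cell 95th-percentile trait metrics and species counts.

    Uses the trait table handed in, so imputation replicates simply call
    this once per replicate-specific width column.
    """
    widths = plant_traits.set_index("species")[width_col]
    masses = frugivore_traits.set_index("species")["body_mass_g"]
    pw = widths.reindex(plant_presence.species).to_numpy(dtype=float)
    me = masses.reindex(extant_presence.species).to_numpy(dtype=float)
    mx = masses.reindex(extinct_presence.species).to_numpy(dtype=float)
    cents = grid.centroids()
    rows = []
    for cid in range(grid.n_cells):
        psel = plant_presence.matrix[cid]
        esel = extant_presence.matrix[cid]
        xsel = extinct_presence.matrix[cid]
        rows.append(
            {
                "cell_id": cid,
                "x": cents[cid, 0],
                "y": cents[cid, 1],
                "land_fraction": grid.land_fraction[cid],
                "n_plants": int(psel.sum()),
                "n_extant": int(esel.sum()),
                "n_extinct": int(xsel.sum()),
                "seed": upper_percentile(pw[psel], level) if psel.any() else np.nan,
                "mass_extant": upper_percentile(me[esel], level) if esel.any() else np.nan,
                "mass_extinct": upper_percentile(mx[xsel], level) if xsel.any() else np.nan,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# filters and the mega split
# ---------------------------------------------------------------------------
@dataclass(frozen=True)
class FilterRules:
    """Inclusion rules for assemblages entering the models."""

    min_land_fraction: float = 0.5
    min_plants: int = 3
    min_extant: int = 3
    min_extinct: int = 1


def filter_assemblages(
    table: pd.DataFrame,
    rules: FilterRules = FilterRules(),
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Drop cells failing any inclusion rule; return the per-rule log.

    Rules: at least half the cell on land, at least three plant species,
    at least three extant frugivores, at least one extinct frugivore.
    The log counts removals per rule (a cell can fail several rules).
    """
    log = {
        "land": int((table["land_fraction"] < rules.min_land_fraction).sum()),
        "plants": int((table["n_plants"] < rules.min_plants).sum()),
        "extant": int((table["n_extant"] < rules.min_extant).sum()),
        "extinct": int((table["n_extinct"] < rules.min_extinct).sum()),
    }
    keep = (
        (table["land_fraction"] >= rules.min_land_fraction)
        & (table["n_plants"] >= rules.min_plants)
        & (table["n_extant"] >= rules.min_extant)
        & (table["n_extinct"] >= rules.min_extinct)
    )
    out = table.loc[keep].reset_index(drop=True)
    if out.empty:
        import warnings

        warnings.warn("all assemblages removed by filters", stacklevel=2)
    return out, log


def split_by_mega(
    table: pd.DataFrame,
    plant_presence: PresenceMatrix,
    mega_flags: pd.Series,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition cells into those with and without mega-seeded plants."""
    flags = mega_flags.reindex(plant_presence.species).to_numpy(dtype=bool)
    has_mega_all = plant_presence.matrix[:, flags].any(axis=1)
    has_mega = has_mega_all[table["cell_id"].to_numpy()]
    mega = table.loc[has_mega].reset_index(drop=True)
    nonmega = table.loc[~has_mega].reset_index(drop=True)
    return mega, nonmega
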