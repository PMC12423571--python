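"""Reading and writing landscape bundles on disk.

Layout written by :func:`write_bundle` (all plain text):

    traits.csv              species, seed_width_mm, imputed
    frugivores.csv          species, body_mass_g, status
    occurrences.csv         species, x, y
    ranges.geojson          FeatureCollection, one polygon per species
    env_<name>.asc          environmental layers (ESRI ASCII grid)
    footprint.asc           human-footprint layer
    landmask.asc            land mask (1 = land)
    imputations/rep_01.csv  ... rep_m.csv
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from shapely.geometry import mapping, shape

from .rasters import read_ascii_grid, write_ascii_grid
from .synthetic import LandscapeBundle

__all__ = ["write_bundle", "read_bundle"]


def write_bundle(bundle: LandscapeBundle, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle.plants.to_csv(outdir / "traits.csv", index=False)
    bundle.frugivores.to_csv(outdir / "frugivores.csv", index=False)
    bundle.occurrences.to_csv(outdir / "occurrences.csv", index=False)
    features = [
        {
            "type": "Feature",
            "properties": {"species": sp},
            "geometry": mapping(geom),
        }
        for sp, geom in sorted(bundle.ranges.items())
    ]
    with open(outdir / "ranges.geojson", "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)
    for name, r in bundle.env_rasters.items():
        write_ascii_grid(r, outdir / f"env_{name}.asc")
    write_ascii_grid(bundle.footprint, outdir / "footprint.asc")
    write_ascii_grid(bundle.landmask, outdir / "landmask.asc")
    imp = outdir / "imputations"
    imp.mkdir(exist_ok=True)
    for k, rep in enumerate(bundle.imputations, start=1):
        rep.to_csv(imp / f"rep_{k:02d}.csv", index=False)


def read_bundle(indir: str | Path) -> LandscapeBundle:
    indir = Path(indir)
    with open(indir / "ranges.geojson") as fh:
        fc = json.load(fh)
    ranges = {
        f["properties"]["species"]: shape(f["geometry"]) for f in fc["features"]
    }
    env = {
        p.stem.removeprefix("env_"): read_ascii_grid(p)
        for p in sorted(indir.glob("env_*.asc"))
    }
    reps = [
        pd.read_csv(p) for p in sorted((indir / "imputations").glob("rep_*.csv"))
    ]
    return LandscapeBundle(
        plants=pd.read_csv(indir / "traits.csv"),
        frugivores=pd.read_csv(indir / "frugivores.csv"),
        occurrences=pd.read_csv(indir / "occurrences.csv"),
        ranges=ranges,
        env_rasters=env,
        footprint=read_ascii_grid(indir / "footprint.asc"),
        landmask=read_ascii_grid(indir / "landmask.asc"),
        imputations=reps,
    )
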