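"""Global frequency heatmaps for HLA alleles, amino-acid motifs and haplotypes.

The pipeline has three stages, composed by :func:`palm` (Population Allele
Locating Mapmaker):

1. :func:`select_variant` joins a variant specifier against a population
   frequency table, yielding one point value per population.  An allele
   specifier picks that allele's frequency (0 where the population is typed
   but the allele absent); a motif specifier sums the frequencies of every
   allele in the table that carries the motif in the locus' protein
   alignment; a haplotype specifier sums haplotype-record frequencies whose
   alleles - extracted from possibly longer multi-gene haplotypes and
   truncated to the requested field depth - equal the spec.
2. :func:`grid_frequencies` interpolates the point values onto a global
   latitude x longitude grid by inverse-distance weighting on great-circle
   distance, masking sea cells (coarse coastline polygons) and cells
   farther than a cutoff from every population.
3. :func:`render_map` draws the grid in colour (blue low -> red high) or
   greyscale (white low -> black high), with one white dot per population
   and a colour bar from 0 to the grid maximum.

Populations flagged migrant/admixed can be filtered out, and maps for
variants whose frequency is everywhere below 1e-4 are refused unless
explicitly requested - mirroring the conventions under which the published
global allele-frequency map collections were generated.
"""

from __future__ import annotations

import importlib.resources
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .imgt_io import AlignmentTable
from .names import AlleleName, MotifSpec
from .seqquery import motif_match

LOW_FREQUENCY_THRESHOLD = 1e-4
EARTH_RADIUS_KM = 6371.0

#: values of the Solberg "complex" column treated as migrant/admixed
MIGRANT_CODES = frozenset({"mig", "migrant", "adm", "admixed", "1", "yes", "true"})

FREQUENCY_COLUMNS = [
    "popname", "latit", "longit", "locus", "allele",
    "frequency", "sample_size", "complex",
]
HAPLOTYPE_COLUMNS = [
    "population", "haplotype", "frequency", "sample_size", "latit", "longit",
]


class FrequencyDataError(ValueError):
    pass


class NotObservedError(FrequencyDataError):
    """The variant occurs in no population of the dataset."""


class LowFrequencyError(FrequencyDataError):
    """Every point value is below the low-frequency threshold and
    low-frequency maps were not requested."""


# ---------------------------------------------------------------------------
# table I/O


def read_frequency_table(source) -> pd.DataFrame:
    """Read a Solberg-dialect allele frequency TSV and validate it.

    Adds a boolean ``migrant`` column derived from the ``complex`` codes.
    """
    df = pd.read_csv(source, sep="\t", dtype={"complex": str}, keep_default_na=False,
                     na_values=[""])
    missing = [c for c in FREQUENCY_COLUMNS if c not in df.columns]
    if missing:
        raise FrequencyDataError(f"frequency table missing columns: {missing}")
    df = df.copy()
    df["complex"] = df["complex"].fillna("").astype(str)
    df["migrant"] = df["complex"].str.strip().str.lower().isin(MIGRANT_CODES)
    validate_frequency_table(df)
    return df


def validate_frequency_table(df: pd.DataFrame) -> None:
    if ((df["frequency"] < 0) | (df["frequency"] > 1)).any():
        raise FrequencyDataError("frequencies must lie in [0, 1]")
    if ((df["latit"] < -90) | (df["latit"] > 90)).any():
        raise FrequencyDataError("latitudes must lie in [-90, 90]")
    if ((df["longit"] <= -180) | (df["longit"] > 180)).any():
        raise FrequencyDataError("longitudes must lie in (-180, 180]")
    sums = df.groupby(["popname", "locus"])["frequency"].sum()
    bad = sums[sums > 1 + 1e-6]
    if not bad.empty:
        pop, locus = bad.index[0]
        raise FrequencyDataError(
            f"frequencies for {pop}/{locus} sum to {bad.iloc[0]:.6f} > 1"
        )


def read_haplotype_table(source) -> pd.DataFrame:
    """Read an AFND-dialect haplotype frequency TSV and validate it."""
    df = pd.read_csv(source, sep="\t", keep_default_na=False, na_values=[""])
    missing = [c for c in HAPLOTYPE_COLUMNS if c not in df.columns]
    if missing:
        raise FrequencyDataError(f"haplotype table missing columns: {missing}")
    if ((df["frequency"] < 0) | (df["frequency"] > 1)).any():
        raise FrequencyDataError("frequencies must lie in [0, 1]")
    for pop, group in df.groupby("population"):
        locus_sets = {
            tuple(sorted(AlleleName.parse(a).locus for a in hap.split("~")))
            for hap in group["haplotype"]
        }
        if len(locus_sets) > 1:
            raise FrequencyDataError(
                f"population {pop} mixes haplotypes over different locus sets"
            )
    return df


# ---------------------------------------------------------------------------
# stage 1: variant -> per-population point values


def select_variant(
    spec,
    freq: pd.DataFrame,
    kind: str,
    prot_table: AlignmentTable | None = None,
    filter_migrant: bool = True,
    generate_low_freq: bool = False,
) -> tuple[pd.DataFrame, dict]:
    """Per-population point values for an allele, motif or haplotype spec.

    Returns ``(points, audit)`` where points has columns population,
    latitude, longitude, value.
    """
    audit: dict = {"kind": kind, "spec": str(spec)}
    if kind == "allele":
        points = _allele_points(spec, freq, filter_migrant, audit)
    elif kind == "motif":
        if prot_table is None:
            raise FrequencyDataError(
                "motif maps need the locus protein alignment (prot_table)"
            )
        points = _motif_points(spec, freq, prot_table, filter_migrant, audit)
    elif kind == "haplotype":
        points = _haplotype_points(spec, freq, audit)
    else:
        raise ValueError("kind must be 'allele', 'motif' or 'haplotype'")
    if points.empty:
        raise NotObservedError(
            f"no population in the dataset supports {audit['spec']!r}"
            + (" after migrant filtering" if filter_migrant else "")
        )
    vmax = points["value"].max()
    if vmax < LOW_FREQUENCY_THRESHOLD and not generate_low_freq:
        raise LowFrequencyError(
            f"{audit['spec']} has frequency < {LOW_FREQUENCY_THRESHOLD} in every "
            "population; pass generate_low_freq=True to map it anyway"
        )
    audit["n_populations"] = len(points)
    audit["max_point_value"] = float(vmax)
    return points.reset_index(drop=True), audit


def _drop_migrant(sub: pd.DataFrame, filter_migrant: bool, audit: dict) -> pd.DataFrame:
    if not filter_migrant:
        audit["populations_dropped_migrant"] = []
        return sub
    dropped = sorted(sub.loc[sub["migrant"], "popname"].unique())
    audit["populations_dropped_migrant"] = dropped
    return sub[~sub["migrant"]]


def _allele_points(spec, freq, filter_migrant, audit) -> pd.DataFrame:
    allele = AlleleName.parse(spec) if isinstance(spec, str) else spec
    sub = _drop_migrant(freq[freq["locus"] == allele.locus], filter_migrant, audit)
    if sub.empty:
        return pd.DataFrame(columns=["population", "latitude", "longitude", "value"])

    def matches(name: str) -> bool:
        depth = AlleleName.parse(name).n_fields
        return allele.truncate(depth).without_prefix().raw == name

    hit = sub["allele"].map(matches)
    if not hit.any():
        raise NotObservedError(
            f"{allele.raw} is not observed in any "
            + ("non-migrant " if filter_migrant else "")
            + "population of the dataset"
        )
    audit["matched_alleles"] = sorted(sub.loc[hit, "allele"].unique())
    per_pop = sub.assign(value=np.where(hit, sub["frequency"], 0.0)).groupby(
        ["popname", "latit", "longit"], as_index=False
    )["value"].sum()
    return per_pop.rename(
        columns={"popname": "population", "latit": "latitude", "longit": "longitude"}
    )


def _motif_points(spec, freq, prot_table, filter_migrant, audit) -> pd.DataFrame:
    motif = MotifSpec.parse(spec) if isinstance(spec, str) else spec
    sub = _drop_migrant(freq[freq["locus"] == motif.locus], filter_migrant, audit)
    if sub.empty:
        return pd.DataFrame(columns=["population", "latitude", "longitude", "value"])
    full_hits = motif_match(motif, prot_table)
    by_depth: dict[int, set[str]] = {}

    def matches(name: str) -> bool:
        depth = AlleleName.parse(name).n_fields
        if depth not in by_depth:
            by_depth[depth] = {
                AlleleName.parse(h).truncate(depth).raw for h in full_hits
            }
        return name in by_depth[depth]

    hit = sub["allele"].map(matches)
    audit["matched_alleles"] = sorted(sub.loc[hit, "allele"].unique())
    audit["n_alignment_matches"] = len(full_hits)
    per_pop = sub.assign(value=np.where(hit, sub["frequency"], 0.0)).groupby(
        ["popname", "latit", "longit"], as_index=False
    )["value"].sum()
    return per_pop.rename(
        columns={"popname": "population", "latit": "latitude", "longit": "longitude"}
    )


def _haplotype_points(spec, freq, audit) -> pd.DataFrame:
    terms = [AlleleName.parse(t) for t in str(spec).split("~")]
    want = {t.locus: t for t in terms}
    if len(want) != len(terms):
        raise FrequencyDataError("haplotype spec repeats a locus")
    records = []
    audit["matched_rows"] = 0
    for (pop, lat, lon), group in freq.groupby(["population", "latit", "longit"]):
        row_loci = {
            AlleleName.parse(a).locus for a in group["haplotype"].iloc[0].split("~")
        }
        if not set(want) <= row_loci:
            continue
        depths_ok = True
        value = 0.0
        for hap, f in zip(group["haplotype"], group["frequency"]):
            parts = {
                (p := AlleleName.parse(a)).locus: p for a in hap.split("~")
            }
            if any(parts[l].n_fields < want[l].n_fields for l in want):
                depths_ok = False
                break
            if all(
                parts[l].truncate(want[l].n_fields).raw == want[l].without_prefix().raw
                for l in want
            ):
                value += f
                audit["matched_rows"] += 1
        if depths_ok:
            records.append(
                {"population": pop, "latitude": lat, "longitude": lon, "value": value}
            )
    return pd.DataFrame(records, columns=["population", "latitude", "longitude", "value"])


# ---------------------------------------------------------------------------
# stage 2: gridding

_LAND = None


def load_land_polygons():
    """Shapely MultiPolygon of the packaged coarse land outlines (cached)."""
    global _LAND
    if _LAND is None:
        from shapely.geometry import MultiPolygon, Polygon

        payload = json.loads(
            (importlib.resources.files("hlakit.data") / "land_coarse.json").read_text()
        )
        _LAND = MultiPolygon(
            [Polygon(coords) for coords in payload["polygons"].values()]
        )
    return _LAND


def haversine_km(lat1, lon1, lat2, lon2):
    """Great-circle distance in km; accepts scalars or broadcastable arrays."""
    lat1, lon1, lat2, lon2 = map(np.radians, (lat1, lon1, lat2, lon2))
    a = (
        np.sin((lat2 - lat1) / 2) ** 2
        + np.cos(lat1) * np.cos(lat2) * np.sin((lon2 - lon1) / 2) ** 2
    )
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0, 1)))


@dataclass
class HeatGrid:
    """A gridded global frequency surface with land/distance masking."""

    lats: np.ndarray  # cell-centre latitudes, ascending
    lons: np.ndarray  # cell-centre longitudes, ascending
    values: np.ma.MaskedArray  # shape (n_lat, n_lon)
    vmax: float
    scale_mode: str  # data_max | unit
    resolution: float
    points: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def value_at(self, latitude: float, longitude: float) -> float:
        i = int(np.argmin(np.abs(self.lats - latitude)))
        j = int(np.argmin(np.abs(self.lons - longitude)))
        if self.values.mask is not np.ma.nomask and self.values.mask[i, j]:
            return float("nan")
        return float(self.values[i, j])


def grid_frequencies(
    points: pd.DataFrame,
    resolution: float = 1.0,
    power: float = 2.0,
    cutoff_km: float = 2000.0,
    scale_mode: str = "data_max",
    mask_sea: bool = True,
) -> HeatGrid:
    """Inverse-distance-weighted interpolation onto an r-degree global grid.

    IDW with great-circle distances is bounded by the min/max point value
    (no overshoot, unlike spline gridding).  Cells farther than
    ``cutoff_km`` from every population are masked, so regions without
    nearby data stay blank; sea cells are masked by the coarse coastline
    polygons.  The cell nearest each population is forced to that
    population's exact value and never masked.
    """
    if points.empty:
        raise FrequencyDataError("cannot grid zero points")
    if scale_mode not in ("data_max", "unit"):
        raise ValueError("scale_mode must be 'data_max' or 'unit'")
    lats = np.arange(-90 + resolution / 2, 90, resolution)
    lons = np.arange(-180 + resolution / 2, 180, resolution)
    glat, glon = np.meshgrid(lats, lons, indexing="ij")
    plat = points["latitude"].to_numpy(float)
    plon = points["longitude"].to_numpy(float)
    pval = points["value"].to_numpy(float)

    d = haversine_km(
        glat[..., None], glon[..., None], plat[None, None, :], plon[None, None, :]
    )  # (n_lat, n_lon, n_points)
    with np.errstate(divide="ignore"):
        w = 1.0 / np.maximum(d, 1e-9) ** power
    values = (w * pval).sum(axis=-1) / w.sum(axis=-1)

    mask = d.min(axis=-1) > cutoff_km
    if mask_sea:
        from shapely import contains_xy
        from shapely.prepared import prep  # noqa: F401  (prep not needed w/ vectorised)

        land = load_land_polygons()
        on_land = contains_xy(land, glon.ravel(), glat.ravel()).reshape(glat.shape)
        mask |= ~on_land

    # snap each population's own cell to its exact value, unmasked
    for lat, lon, val in zip(plat, plon, pval):
        i = int(np.argmin(np.abs(lats - lat)))
        j = int(np.argmin(np.abs(lons - lon)))
        values[i, j] = val
        mask[i, j] = False
    # populations sharing one cell: use their mean
    cell_groups: dict[tuple[int, int], list[float]] = {}
    for lat, lon, val in zip(plat, plon, pval):
        key = (int(np.argmin(np.abs(lats - lat))), int(np.argmin(np.abs(lons - lon))))
        cell_groups.setdefault(key, []).append(val)
    for (i, j), vals in cell_groups.items():
        if len(vals) > 1:
            values[i, j] = float(np.mean(vals))

    vmax = 1.0 if scale_mode == "unit" else float(pval.max())
    return HeatGrid(
        lats=lats,
        lons=lons,
        values=np.ma.masked_array(values, mask=mask),
        vmax=vmax,
        scale_mode=scale_mode,
        resolution=resolution,
        points=points.copy(),
        meta={"power": power, "cutoff_km": cutoff_km, "mask_sea": mask_sea},
    )


# ---------------------------------------------------------------------------
# stage 3: rendering


def render_map(
    grid: HeatGrid,
    out_path: str | Path,
    color_mode: str = "color",
    title: str | None = None,
) -> Path:
    """Draw the grid to PNG/SVG/PDF (chosen by file suffix).

    Colour maps run blue (lowest) to red (highest); greyscale runs white to
    black.  Population support points are drawn as white dots and the
    colour bar is labelled 0 to vmax.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if color_mode not in ("color", "greyscale"):
        raise ValueError("color_mode must be 'color' or 'greyscale'")
    out_path = Path(out_path)
    if not out_path.parent.exists():
        raise FileNotFoundError(f"output directory {out_path.parent} does not exist")
    cmap = plt.get_cmap("turbo" if color_mode == "color" else "Greys").copy()
    fig, ax = plt.subplots(figsize=(10, 5.2), constrained_layout=True)
    half = grid.resolution / 2
    mesh = ax.pcolormesh(
        np.concatenate([grid.lons - half, [grid.lons[-1] + half]]),
        np.concatenate([grid.lats - half, [grid.lats[-1] + half]]),
        grid.values,
        cmap=cmap,
        vmin=0.0,
        vmax=grid.vmax,
        shading="flat",
        rasterized=True,
    )
    for poly in load_land_polygons().geoms:
        x, y = poly.exterior.xy
        ax.plot(x, y, color="0.3", linewidth=0.5)
    ax.scatter(
        grid.points["longitude"],
        grid.points["latitude"],
        s=12,
        facecolor="white",
        edgecolor="black",
        linewidth=0.4,
        zorder=3,
    )
    ax.set_xlim(-180, 180)
    ax.set_ylim(-90, 90)
    ax.set_xlabel("longitude")
    ax.set_ylabel("latitude")
    if title:
        ax.set_title(title)
    fig.colorbar(mesh, ax=ax, shrink=0.8, label="frequency")
    metadata = (
        {"Date": None} if out_path.suffix == ".svg" else {"Software": "hlakit"}
    )
    fig.savefig(out_path, dpi=150, metadata=metadata)
    plt.close(fig)
    return out_path


# ---------------------------------------------------------------------------
# composition


class AlignmentCache:
    """Per-locus protein-alignment cache for motif maps.

    Building a locus alignment dominates the cost of the first map for that
    locus; subsequent maps reuse the cached table.
    """

    def __init__(self, loader: Callable[[str], AlignmentTable]):
        self._loader = loader
        self._tables: dict[str, AlignmentTable] = {}
        self.n_builds = 0

    def get(self, locus: str) -> AlignmentTable:
        if locus not in self._tables:
            self._tables[locus] = self._loader(locus)
            self.n_builds += 1
        return self._tables[locus]


@dataclass
class PalmResult:
    points: pd.DataFrame
    grid: HeatGrid
    image_path: Path | None
    audit: dict


def palm(
    spec,
    freq: pd.DataFrame,
    kind: str = "allele",
    alignments: AlignmentCache | Mapping[str, AlignmentTable] | None = None,
    out_path: str | Path | None = None,
    filter_migrant: bool = True,
    generate_low_freq: bool = False,
    map_scale: bool = True,
    color_mode: str = "color",
    resolution: float = 1.0,
    power: float = 2.0,
    cutoff_km: float = 2000.0,
    mask_sea: bool = True,
) -> PalmResult:
    """Variant spec + frequency table -> heatmap (select, grid, render).

    ``map_scale=True`` scales colours to the data maximum; ``False`` fixes
    the scale at 1.0 so maps of complementary variants share one colour
    bar.  With ``out_path=None`` no image is written.
    """
    prot_table = None
    if kind == "motif":
        motif = MotifSpec.parse(spec) if isinstance(spec, str) else spec
        if alignments is None:
            raise FrequencyDataError("motif maps need alignments")
        if isinstance(alignments, AlignmentCache):
            prot_table = alignments.get(motif.locus)
        else:
            prot_table = alignments[motif.locus]
    points, audit = select_variant(
        spec,
        freq,
        kind=kind,
        prot_table=prot_table,
        filter_migrant=filter_migrant,
        generate_low_freq=generate_low_freq,
    )
    grid = grid_frequencies(
        points,
        resolution=resolution,
        power=power,
        cutoff_km=cutoff_km,
        scale_mode="data_max" if map_scale else "unit",
        mask_sea=mask_sea,
    )
    audit["vmax"] = grid.vmax
    image_path = None
    if out_path is not None:
        image_path = render_map(grid, out_path, color_mode=color_mode, title=str(spec))
    return PalmResult(points=points, grid=grid, image_path=image_path, audit=audit)


def genotype_frequencies(f: float, g: float | None = None) -> dict[str, float]:
    """Random-mating genotype estimates: hom = f^2, het = 2 f g.

    These are Hardy-Weinberg estimates from allele/motif frequencies, not
    observed genotype counts.
    """
    out = {"hom": f * f}
    if g is not None:
        out["het"] = 2 * f * g
        out["hom_other"] = g * g
    return out
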