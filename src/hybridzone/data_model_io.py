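"""Domain containers and file I/O for hybrid-zone analyses.

The central objects are:

* :class:`GenotypePanel` — individuals x diagnostic markers, dosage coded as
  the number of *O. ophryticus* alleles (0/1/2, missing allowed), so a hybrid
  index of 1 means pure *O. ophryticus*.
* :class:`LocalityFrame` — sampling localities with WGS84 coordinates and
  per-locality summaries (sample sizes, hybrid index, mtDNA frequency).
* :class:`MtdnaCalls`, :class:`OccurrenceSet`, :class:`RasterStack` — inputs
  for the mitochondrial and niche-overlap arms.

All coordinates are WGS84 decimal degrees throughout the package; no
projected CRS is used anywhere and all distances are computed on the sphere.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

MISSING = -1  # sentinel for a missing dosage inside the integer matrix


class LifeStage(str, Enum):
    PRE_METAMORPHIC = "pre_metamorphic"
    POST_METAMORPHIC = "post_metamorphic"
    UNKNOWN = "unknown"


class SpeciesLabel(str, Enum):
    NESTEROVI = "nesterovi"
    OPHRYTICUS = "ophryticus"
    ADMIXED = "admixed"


@dataclass
class GenotypePanel:
    """Diploid dosage matrix over species-diagnostic markers.

    ``dosage[i, l]`` counts *O. ophryticus* alleles for individual ``i`` at
    marker ``l`` (0, 1, 2); missing cells hold :data:`MISSING` and are flagged
    in :attr:`missing`.
    """

    individual_ids: list[str]
    locality_codes: list[str]
    marker_ids: list[str]
    dosage: np.ndarray  # (n_individuals, n_markers) int8
    life_stages: list[LifeStage] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        n, L = self.dosage.shape
        if len(self.individual_ids) != n or len(self.locality_codes) != n:
            raise ValueError("individual/locality lists must match dosage rows")
        if len(self.marker_ids) != L:
            raise ValueError("marker_ids must match dosage columns")
        if L < 1:
            raise ValueError("panel needs at least one marker")
        if len(set(self.marker_ids)) != L:
            raise ValueError("marker ids must be unique")
        if len(set(self.individual_ids)) != n:
            raise ValueError("duplicate individual id in panel")
        valid = np.isin(self.dosage, (0, 1, 2, MISSING))
        if not valid.all():
            i, l = np.argwhere(~valid)[0]
            raise ValueError(
                f"invalid dosage {self.dosage[i, l]} for individual "
                f"{self.individual_ids[i]!r}, marker {self.marker_ids[l]!r}"
            )
        if not self.life_stages:
            self.life_stages = [LifeStage.UNKNOWN] * n

    @property
    def missing(self) -> np.ndarray:
        return self.dosage == MISSING

    @property
    def n_individuals(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosage.shape[1]

    def localities(self) -> list[str]:
        """Unique locality codes in order of first appearance."""
        return list(dict.fromkeys(self.locality_codes))

    def subset_individuals(self, mask: np.ndarray) -> "GenotypePanel":
        idx = np.flatnonzero(np.asarray(mask))
        return GenotypePanel(
            [self.individual_ids[i] for i in idx],
            [self.locality_codes[i] for i in idx],
            list(self.marker_ids),
            self.dosage[idx],
            [self.life_stages[i] for i in idx],
        )

    def locality_mask(self, code: str) -> np.ndarray:
        return np.array([c == code for c in self.locality_codes])

    def drop_markers(self, marker_ids: Sequence[str]) -> "GenotypePanel":
        drop = set(marker_ids)
        keep = [j for j, m in enumerate(self.marker_ids) if m not in drop]
        return GenotypePanel(
            list(self.individual_ids),
            list(self.locality_codes),
            [self.marker_ids[j] for j in keep],
            self.dosage[:, keep],
            list(self.life_stages),
        )


@dataclass
class LocalityFrame:
    """Per-locality table mirroring the published sampling summary."""

    frame: pd.DataFrame  # columns: code, latitude, longitude, species, n_kasp, hybrid_index, n_mtdna, mtdna_freq

    REQUIRED = ("code", "latitude", "longitude", "species", "n_kasp",
                "hybrid_index", "n_mtdna", "mtdna_freq")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.frame.columns]
        if missing:
            raise ValueError(f"locality table lacks columns: {missing}")
        f = self.frame
        if (f["latitude"].abs() > 90).any() or (f["longitude"].abs() > 180).any():
            bad = f.loc[(f["latitude"].abs() > 90) | (f["longitude"].abs() > 180), "code"]
            raise ValueError(f"coordinates out of WGS84 range at locality {list(bad)}")
        for col in ("hybrid_index", "mtdna_freq"):
            vals = f[col].dropna()
            if ((vals < 0) | (vals > 1)).any():
                raise ValueError(f"{col} outside [0, 1]")
        for col in ("n_kasp", "n_mtdna"):
            if (f[col] < 0).any():
                raise ValueError(f"{col} negative")

    def __len__(self) -> int:
        return len(self.frame)

    def natural_range(self) -> "LocalityFrame":
        """Rows from the natural range (drops introduced populations, code 'I')."""
        return LocalityFrame(self.frame[self.frame["code"] != "I"].reset_index(drop=True))

    def row(self, code: str) -> pd.Series:
        hit = self.frame[self.frame["code"].astype(str) == str(code)]
        if hit.empty:
            raise KeyError(f"no locality with code {code!r}")
        return hit.iloc[0]


@dataclass
class MtdnaCalls:
    individual_ids: list[str]
    species_calls: list[SpeciesLabel]

    def validate_against(self, panel: GenotypePanel) -> None:
        known = set(panel.individual_ids)
        orphans = [i for i in self.individual_ids if i not in known]
        if orphans:
            raise ValueError(f"mtDNA calls for unknown individuals: {orphans[:5]}")


@dataclass
class OccurrenceSet:
    species: str
    latitudes: np.ndarray
    longitudes: np.ndarray

    def __post_init__(self) -> None:
        self.latitudes = np.asarray(self.latitudes, dtype=float)
        self.longitudes = np.asarray(self.longitudes, dtype=float)
        if self.latitudes.size == 0:
            raise ValueError(f"no occurrence records for {self.species}")
        if (np.abs(self.latitudes) > 90).any() or (np.abs(self.longitudes) > 180).any():
            raise ValueError("occurrence coordinates out of WGS84 range")


@dataclass
class RasterStack:
    """Aligned environmental layers on a regular lat/lon grid.

    ``values[k]`` is layer ``k`` as a (nrows, ncols) array with NaN for
    nodata; row 0 is the northernmost row. All layers share the grid, and the
    nodata mask is unified across layers on construction.
    """

    names: list[str]
    values: np.ndarray          # (n_layers, nrows, ncols) float
    lat: np.ndarray             # (nrows,) cell-centre latitudes, descending
    lon: np.ndarray             # (ncols,) cell-centre longitudes, ascending

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3 or self.values.shape[0] != len(self.names):
            raise ValueError("values must be (n_layers, nrows, ncols)")
        # unify nodata across layers
        bad = np.isnan(self.values).any(axis=0)
        self.values[:, bad] = np.nan

    @property
    def valid_mask(self) -> np.ndarray:
        return ~np.isnan(self.values[0])

    def table(self) -> pd.DataFrame:
        """Valid cells as a DataFrame (one row per cell, one column per layer)."""
        m = self.valid_mask
        data = {name: self.values[k][m] for k, name in enumerate(self.names)}
        rr, cc = np.nonzero(m)
        data["latitude"] = self.lat[rr]
        data["longitude"] = self.lon[cc]
        return pd.DataFrame(data)

    def subset(self, names: Sequence[str]) -> "RasterStack":
        idx = [self.names.index(n) for n in names]
        return RasterStack(list(names), self.values[idx].copy(), self.lat, self.lon)


# ---------------------------------------------------------------------------
# readers / writers


def read_genotype_table(path: str | Path) -> GenotypePanel:
    """Read a delimited genotype table into a :class:`GenotypePanel`.

    Expected columns: ``individual``, ``locality``, optionally ``life_stage``,
    then one column per marker holding 0/1/2 or NA. Raises a located error for
    non-integer or out-of-range dosages and for duplicated individual ids.
    """
    path = Path(path)
    sep = "\t" if path.suffix in (".tsv", ".txt") else ","
    df = pd.read_csv(path, sep=sep, dtype=str)
    for col in ("individual", "locality"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    dupes = df["individual"][df["individual"].duplicated()]
    if not dupes.empty:
        raise ValueError(f"{path}: duplicate individual id {dupes.iloc[0]!r}")
    meta = {"individual", "locality", "life_stage"}
    markers = [c for c in df.columns if c not in meta]
    if not markers:
        raise ValueError(f"{path}: no marker columns found")
    n = len(df)
    dosage = np.full((n, len(markers)), MISSING, dtype=np.int8)
    for j, m in enumerate(markers):
        for i, raw in enumerate(df[m]):
            if raw is None or (isinstance(raw, float) and np.isnan(raw)) or str(raw).strip() in ("", "NA", "nan"):
                continue
            try:
                v = int(str(raw).strip())
            except ValueError:
                raise ValueError(
                    f"{path}: non-integer dosage {raw!r} at individual "
                    f"{df['individual'].iloc[i]!r}, marker {m!r}"
                ) from None
            if v not in (0, 1, 2):
                raise ValueError(
                    f"{path}: dosage {v} out of range at individual "
                    f"{df['individual'].iloc[i]!r}, marker {m!r}"
                )
            dosage[i, j] = v
    stages = (
        [LifeStage(s) for s in df["life_stage"]]
        if "life_stage" in df.columns
        else [LifeStage.UNKNOWN] * n
    )
    return GenotypePanel(
        list(df["individual"]), list(df["locality"]), markers, dosage, stages
    )


def write_genotype_table(panel: GenotypePanel, path: str | Path) -> None:
    """Inverse of :func:`read_genotype_table` (round-trip safe)."""
    path = Path(path)
    df = pd.DataFrame(
        {"individual": panel.individual_ids, "locality": panel.locality_codes,
         "life_stage": [s.value for s in panel.life_stages]}
    )
    for j, m in enumerate(panel.marker_ids):
        col = panel.dosage[:, j].astype(object)
        col[panel.dosage[:, j] == MISSING] = "NA"
        df[m] = col
    sep = "\t" if path.suffix in (".tsv", ".txt") else ","
    df.to_csv(path, sep=sep, index=False)


def read_locality_table(path: str | Path) -> LocalityFrame:
    df = pd.read_csv(path, dtype={"code": str})
    return LocalityFrame(df)


def load_table1_fixture() -> LocalityFrame:
    """The published 43-locality sampling table (42 natural + Spain row 'I').

    Columns: code, locality, latitude, longitude, species, n_kasp,
    hybrid_index (proportion of *O. ophryticus* alleles), n_mtdna,
    mtdna_freq (*O. ophryticus* haplotype frequency).
    """
    with resources.files("hybridzone.data").joinpath("table1_localities.csv").open() as fh:
        df = pd.read_csv(fh, dtype={"code": str})
    return LocalityFrame(df)


def export_genepop(panel: GenotypePanel, path: str | Path, title: str = "hybridzone export") -> None:
    """Write a Genepop-format file: two-digit alleles, missing as 0000.

    Dosage 0 -> ``0101``, 1 -> ``0102``, 2 -> ``0202`` (allele 02 is the
    *O. ophryticus* allele). One ``Pop`` block per locality.
    """
    if panel.n_individuals == 0:
        raise ValueError("cannot export an empty panel")
    code = {0: "0101", 1: "0102", 2: "0202", MISSING: "0000"}
    lines = [title]
    lines.extend(panel.marker_ids)
    for loc in panel.localities():
        lines.append("Pop")
        for i in np.flatnonzero(panel.locality_mask(loc)):
            geno = " ".join(code[int(g)] for g in panel.dosage[i])
            lines.append(f"{panel.individual_ids[i]} ,  {geno}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_genepop(path: str | Path) -> GenotypePanel:
    """Parse a diploid two-digit Genepop file back into a panel.

    Only the dosage convention written by :func:`export_genepop` is decoded
    (alleles 01/02); used for round-trip checks and interoperability.
    """
    lines = Path(path).read_text().splitlines()
    if len(lines) < 3:
        raise ValueError("not a Genepop file")
    body = lines[1:]
    markers: list[str] = []
    i = 0
    while i < len(body) and body[i].strip().lower() != "pop":
        # marker names may be one per line or comma-separated
        markers.extend(m.strip() for m in body[i].split(",") if m.strip())
        i += 1
    ids: list[str] = []
    locs: list[str] = []
    rows: list[list[int]] = []
    pop_idx = 0
    decode = {"0101": 0, "0102": 1, "0201": 1, "0202": 2, "0000": MISSING}
    while i < len(body):
        if body[i].strip().lower() == "pop":
            pop_idx += 1
            i += 1
            continue
        name, _, geno = body[i].partition(",")
        alleles = geno.split()
        if len(alleles) != len(markers):
            raise ValueError(f"line {i + 2}: expected {len(markers)} genotypes")
        ids.append(name.strip())
        locs.append(f"pop{pop_idx}")
        rows.append([decode[a] for a in alleles])
        i += 1
    return GenotypePanel(ids, locs, markers, np.array(rows, dtype=np.int8))


# ---------------------------------------------------------------------------
# ESRI ASCII grid I/O for RasterStack (text-only raster format)


def write_ascii_grid(stack: RasterStack, directory: str | Path, nodata: float = -9999.0) -> list[Path]:
    """Write each layer as an ESRI ASCII grid ``<name>.asc``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    ncols = stack.lon.size
    nrows = stack.lat.size
    cell = float(np.abs(np.diff(stack.lon)).mean())
    xll = float(stack.lon.min() - cell / 2)
    yll = float(stack.lat.min() - cell / 2)
    paths = []
    for k, name in enumerate(stack.names):
        vals = np.where(np.isnan(stack.values[k]), nodata, stack.values[k])
        header = (
            f"ncols {ncols}\nnrows {nrows}\nxllcorner {xll}\nyllcorner {yll}\n"
            f"cellsize {cell}\nNODATA_value {nodata}\n"
        )
        p = directory / f"{name}.asc"
        with p.open("w") as fh:
            fh.write(header)
            np.savetxt(fh, vals, fmt="%.6g")
        paths.append(p)
    return paths


def read_ascii_grids(paths: Sequence[str | Path]) -> RasterStack:
    """Read aligned ESRI ASCII grids into a :class:`RasterStack`."""
    names, layers = [], []
    ref = None
    for p in paths:
        p = Path(p)
        with p.open() as fh:
            header = {}
            for _ in range(6):
                key, val = fh.readline().split()
                header[key.lower()] = float(val)
            vals = np.loadtxt(fh)
        vals = np.atleast_2d(vals)
        vals[vals == header["nodata_value"]] = np.nan
        geo = (header["ncols"], header["nrows"], header["xllcorner"],
               header["yllcorner"], header["cellsize"])
        if ref is None:
            ref = geo
        elif not np.allclose(geo, ref):
            raise ValueError(f"{p}: grid does not align with first layer")
        names.append(p.stem)
        layers.append(vals)
    ncols, nrows, xll, yll, cell = ref
    lon = xll + cell / 2 + cell * np.arange(int(ncols))
    lat = yll + cell / 2 + cell * np.arange(int(nrows))[::-1]
    return RasterStack(names, np.array(layers), lat, lon)
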