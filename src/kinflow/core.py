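"""Data model and I/O for georeferenced multilocus genotype tables.

The central container is :class:`IndividualTable`: one row per individual
tree carrying an ID, a site label, planar (x, y in meters) or geographic
(lon, lat in decimal degrees) coordinates, diameter at breast height (DBH,
cm), an optional altitude, a diploid nuclear genotype at L microsatellite
loci, and a haploid plastid haplotype.  All downstream stages (diversity,
spatial genetic structure, parentage, dispersal) consume this container.

Genotypes are stored order-normalized (allele a <= allele b as strings) so
genotype equality is well defined; a single sentinel (``None`` internally,
``"NA"`` on disk) marks missing data.  A locus with any missing allele is
treated as wholly missing for that individual, the usual convention for
SSR panels where a half-called genotype is not trusted.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

#: Earth mean radius used for great-circle distances, meters.
EARTH_RADIUS_M = 6_371_008.8

#: Tokens recognized as missing alleles / haplotypes on input.
MISSING_TOKENS = {"", "NA", "na", "NaN", "nan", ".", "?", "-"}

#: Canonical missing sentinel written on output.
MISSING_SENTINEL = "NA"


class DataError(ValueError):
    """Raised for malformed or inconsistent input tables."""


def _is_missing(tok) -> bool:
    if tok is None:
        return True
    if isinstance(tok, float) and math.isnan(tok):
        return True
    return str(tok).strip() in MISSING_TOKENS


def _norm_pair(a, b):
    """Order-normalize an allele pair; any missing allele voids the locus."""
    if _is_missing(a) or _is_missing(b):
        return (None, None)
    a, b = str(a).strip(), str(b).strip()
    return (a, b) if a <= b else (b, a)


@dataclass
class IndividualTable:
    """Georeferenced individuals with nuclear genotypes and plastid haplotypes.

    Parameters
    ----------
    ids : array of unique individual identifiers.
    site : array of site labels.
    coords : (n, 2) float array; meaning depends on ``coord_mode``.
    coord_mode : ``"planar"`` (x, y meters) or ``"lonlat"`` (degrees).
    dbh : (n,) float array, cm; NaN = missing.
    loci : ordered locus names, shared by all individuals.
    genotypes : (n, L, 2) object array of allele labels, ``None`` = missing;
        pairs are order-normalized.
    haplotypes : (n,) object array of plastid haplotype labels, ``None`` = missing.
    altitude : optional (n,) float array, meters.
    """

    ids: np.ndarray
    site: np.ndarray
    coords: np.ndarray
    coord_mode: str
    dbh: np.ndarray
    loci: list[str]
    genotypes: np.ndarray
    haplotypes: np.ndarray
    altitude: np.ndarray | None = None

    def __post_init__(self):
        self.ids = np.asarray(self.ids, dtype=object)
        self.site = np.asarray(self.site, dtype=object)
        self.coords = np.asarray(self.coords, dtype=float)
        self.dbh = np.asarray(self.dbh, dtype=float)
        self.genotypes = np.asarray(self.genotypes, dtype=object)
        self.haplotypes = np.asarray(self.haplotypes, dtype=object)
        n = len(self.ids)
        if len(set(self.ids.tolist())) != n:
            seen, dup = set(), None
            for i in self.ids:
                if i in seen:
                    dup = i
                    break
                seen.add(i)
            raise DataError(f"duplicate individual_id: {dup!r}")
        if self.coord_mode not in ("planar", "lonlat"):
            raise DataError(f"unknown coord_mode: {self.coord_mode!r}")
        if self.coords.shape != (n, 2):
            raise DataError("coords must be (n, 2)")
        if self.genotypes.shape != (n, len(self.loci), 2):
            raise DataError("genotypes must be (n, L, 2)")

    # ------------------------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def index_of(self, individual_id) -> int:
        hits = np.nonzero(self.ids == individual_id)[0]
        if len(hits) == 0:
            raise KeyError(individual_id)
        return int(hits[0])

    def subset(self, mask_or_indices) -> "IndividualTable":
        idx = np.asarray(mask_or_indices)
        return IndividualTable(
            ids=self.ids[idx],
            site=self.site[idx],
            coords=self.coords[idx],
            coord_mode=self.coord_mode,
            dbh=self.dbh[idx],
            loci=list(self.loci),
            genotypes=self.genotypes[idx],
            haplotypes=self.haplotypes[idx],
            altitude=None if self.altitude is None else self.altitude[idx],
        )

    def by_site(self) -> dict[str, "IndividualTable"]:
        return {s: self.subset(self.site == s) for s in pd.unique(self.site)}

    def missing_mask(self) -> np.ndarray:
        """(n, L) boolean mask: True where the locus is untyped."""
        return np.equal(self.genotypes[:, :, 0], None)

    # ------------------------------------------------------------------
    def to_dataframe(self) -> pd.DataFrame:
        cols = {"id": self.ids, "site": self.site}
        if self.coord_mode == "planar":
            cols["x"], cols["y"] = self.coords[:, 0], self.coords[:, 1]
        else:
            cols["lon"], cols["lat"] = self.coords[:, 0], self.coords[:, 1]
        cols["dbh"] = self.dbh
        if self.altitude is not None:
            cols["altitude"] = self.altitude
        cols["hap"] = [h if h is not None else MISSING_SENTINEL for h in self.haplotypes]
        for l, locus in enumerate(self.loci):
            cols[f"{locus}_a"] = [
                g if g is not None else MISSING_SENTINEL for g in self.genotypes[:, l, 0]
            ]
            cols[f"{locus}_b"] = [
                g if g is not None else MISSING_SENTINEL for g in self.genotypes[:, l, 1]
            ]
        return pd.DataFrame(cols)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def to_genepop(self, path, title: str = "kinflow export") -> None:
        """Write nuclear genotypes in GenePop format (3-digit allele codes).

        Alleles are recoded per locus in sorted label order starting at 001;
        000 is the missing code.  One POP block per site.
        """
        codes = []
        for l in range(self.n_loci):
            alleles = sorted(
                {a for a in self.genotypes[:, l, :].ravel() if a is not None}
            )
            if len(alleles) > 999:
                raise DataError(f"locus {self.loci[l]} has >999 alleles")
            codes.append({a: f"{i + 1:03d}" for i, a in enumerate(alleles)})
        buf = io.StringIO()
        buf.write(title + "\n")
        for locus in self.loci:
            buf.write(locus + "\n")
        for s, sub in self.by_site().items():
            buf.write("POP\n")
            for i in range(sub.n):
                toks = []
                for l in range(sub.n_loci):
                    a, b = sub.genotypes[i, l]
                    if a is None:
                        toks.append("000000")
                    else:
                        toks.append(codes[l][a] + codes[l][b])
                buf.write(f"{sub.ids[i]} ,  " + " ".join(toks) + "\n")
        with open(path, "w") as fh:
            fh.write(buf.getvalue())

    # ------------------------------------------------------------------
    def to_planar(self) -> "IndividualTable":
        """Project lon/lat to a local tangent plane (equirectangular about the
        centroid), returning a planar-mode copy.  A no-op for planar tables."""
        if self.coord_mode == "planar":
            return self
        lon, lat = self.coords[:, 0], self.coords[:, 1]
        lon0, lat0 = lon.mean(), lat.mean()
        x = np.radians(lon - lon0) * EARTH_RADIUS_M * np.cos(np.radians(lat0))
        y = np.radians(lat - lat0) * EARTH_RADIUS_M
        out = replace(self)
        out.coords = np.column_stack([x, y])
        out.coord_mode = "planar"
        return out


@dataclass
class SizeClassPartition:
    """Split of a table at a DBH threshold: SSS (< threshold) vs ADL (>=)."""

    sss: IndividualTable
    adl: IndividualTable
    threshold: float


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix in meters."""

    values: np.ndarray
    mode: str  # "planar" | "geodesic"
    ids: np.ndarray | None = None

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if not np.allclose(v, v.T):
            raise DataError("distance matrix not symmetric")
        if np.any(np.diag(v) != 0):
            raise DataError("distance matrix diagonal not zero")
        if np.any(v < 0):
            raise DataError("negative distance")
        self.values = v


# ----------------------------------------------------------------------
# loading


def _detect_loci(columns, explicit=None):
    if explicit is not None:
        return list(explicit)
    loci = []
    for c in columns:
        if c.endswith("_a") and c[:-2] + "_b" in columns:
            loci.append(c[:-2])
    return loci


def load_individuals(path_or_buf, schema: dict | None = None) -> IndividualTable:
    """Load an :class:`IndividualTable` from a delimited text table.

    ``schema`` optionally maps field names (``id``, ``site``, ``x``, ``y``,
    ``lon``, ``lat``, ``dbh``, ``altitude``, ``hap``, ``loci``) to column
    names; by default the native column names are used and loci are
    auto-detected from paired ``<locus>_a`` / ``<locus>_b`` columns or
    single ``<locus>`` columns holding ``a/b`` tokens.
    """
    schema = dict(schema or {})
    df = pd.read_csv(path_or_buf, dtype=str, keep_default_na=False)
    cols = set(df.columns)

    def col(name, default=None):
        return schema.get(name, default if default is not None else name)

    id_col = col("id")
    if id_col not in cols:
        raise DataError(f"missing id column {id_col!r}")
    ids = df[id_col].astype(str).to_numpy(dtype=object)
    if df[id_col].duplicated().any():
        dup = df[id_col][df[id_col].duplicated()].iloc[0]
        raise DataError(f"duplicate individual_id: {dup!r}")

    site = (
        df[col("site")].astype(str).to_numpy(dtype=object)
        if col("site") in cols
        else np.array(["site1"] * len(df), dtype=object)
    )

    has_xy = col("x") in cols and col("y") in cols
    has_ll = col("lon") in cols and col("lat") in cols
    if has_xy and has_ll:
        raise DataError("mixed coordinate modes: both x/y and lon/lat present")
    if has_xy:
        coord_mode = "planar"
        cx, cy = col("x"), col("y")
    elif has_ll:
        coord_mode = "lonlat"
        cx, cy = col("lon"), col("lat")
    else:
        raise DataError("no coordinate columns found (x/y or lon/lat)")
    def numeric(series):
        return pd.to_numeric(series.where(~series.isin(list(MISSING_TOKENS)))).to_numpy()

    try:
        coords = np.column_stack([numeric(df[cx]), numeric(df[cy])])
    except ValueError as e:
        raise DataError(f"unparseable coordinate: {e}") from e

    if col("dbh") in cols:
        dbh = numeric(df[col("dbh")])
    else:
        dbh = np.full(len(df), np.nan)
    altitude = None
    if col("altitude") in cols:
        altitude = numeric(df[col("altitude")])

    hap_col = col("hap")
    if hap_col in cols:
        haplotypes = np.array(
            [None if _is_missing(h) else str(h).strip() for h in df[hap_col]], dtype=object
        )
    else:
        haplotypes = np.array([None] * len(df), dtype=object)

    loci = _detect_loci(cols, schema.get("loci"))
    if not loci:
        # fall back to single-column "a/b" dialect: any unclaimed column
        # whose values all look like allele pairs
        claimed = {id_col, col("site"), cx, cy, col("dbh"), col("altitude"), hap_col}
        loci = [c for c in df.columns if c not in claimed]
    loci = sorted(loci)
    n, L = len(df), len(loci)
    genotypes = np.empty((n, L, 2), dtype=object)
    for l, locus in enumerate(loci):
        if f"{locus}_a" in cols and f"{locus}_b" in cols:
            a_ser, b_ser = df[f"{locus}_a"], df[f"{locus}_b"]
            for i in range(n):
                genotypes[i, l] = _norm_pair(a_ser.iat[i], b_ser.iat[i])
        elif locus in cols:
            for i in range(n):
                tok = str(df[locus].iat[i]).strip()
                if _is_missing(tok):
                    genotypes[i, l] = (None, None)
                    continue
                parts = tok.split("/")
                if len(parts) != 2:
                    raise DataError(
                        f"unparseable allele token {tok!r} at row {i} locus {locus}"
                    )
                genotypes[i, l] = _norm_pair(*parts)
        else:
            raise DataError(f"locus {locus!r} columns not found")

    return IndividualTable(
        ids=ids,
        site=site,
        coords=coords,
        coord_mode=coord_mode,
        dbh=dbh,
        loci=loci,
        genotypes=genotypes,
        haplotypes=haplotypes,
        altitude=altitude,
    )


# ----------------------------------------------------------------------
# size classes


def split_size_classes(table: IndividualTable, threshold: float = 30.0) -> SizeClassPartition:
    """Partition individuals at a DBH threshold (cm).

    Individuals with DBH exactly at the threshold are adults (ADL),
    matching the ">= 30 cm" definition of potentially reproductive trees;
    individuals with missing DBH are excluded from both classes.
    """
    if threshold <= 0:
        raise DataError("threshold must be positive")
    typed = ~np.isnan(table.dbh)
    if not typed.any():
        raise DataError("all DBH missing; cannot partition size classes")
    sss = table.subset(typed & (table.dbh < threshold))
    adl = table.subset(typed & (table.dbh >= threshold))
    return SizeClassPartition(sss=sss, adl=adl, threshold=threshold)


# ----------------------------------------------------------------------
# distances


def encode_genotypes(table: IndividualTable):
    """Integer-encode nuclear genotypes for fast numeric work.

    Returns ``(codes, alleles)`` where ``codes`` is an (n, L, 2) int array
    (-1 = missing) and ``alleles[l]`` is the sorted allele-label list of
    locus ``l`` (code = position in that list).
    """
    n, L = table.n, table.n_loci
    codes = np.full((n, L, 2), -1, dtype=np.int32)
    alleles = []
    for l in range(L):
        labs = sorted({a for a in table.genotypes[:, l, :].ravel() if a is not None})
        lut = {a: k for k, a in enumerate(labs)}
        alleles.append(labs)
        for i in range(n):
            a, b = table.genotypes[i, l]
            if a is not None:
                codes[i, l, 0] = lut[a]
                codes[i, l, 1] = lut[b]
    return codes, alleles


def haversine_m(lon1, lat1, lon2, lat2) -> float:
    """Great-circle distance in meters between two lon/lat points (degrees)."""
    lam1, phi1, lam2, phi2 = map(math.radians, (lon1, lat1, lon2, lat2))
    a = (
        math.sin((phi2 - phi1) / 2) ** 2
        + math.cos(phi1) * math.cos(phi2) * math.sin((lam2 - lam1) / 2) ** 2
    )
    return 2 * EARTH_RADIUS_M * math.asin(min(1.0, math.sqrt(a)))


def pairwise_distances(table: IndividualTable, mode: str | None = None) -> DistanceMatrix:
    """Pairwise distances in meters.

    Planar tables use Euclidean distance; lon/lat tables use great-circle
    (haversine) distance by default, or the tangent-plane projection if
    ``mode="planar"`` is forced.
    """
    if np.isnan(table.coords).any():
        bad = table.ids[np.isnan(table.coords).any(axis=1)][0]
        raise DataError(f"missing coordinates for individual {bad!r}")
    if mode is None:
        mode = "planar" if table.coord_mode == "planar" else "geodesic"
    if mode == "planar":
        t = table.to_planar()
        d = squareform(pdist(t.coords))
        return DistanceMatrix(values=d, mode="planar", ids=table.ids)
    if mode == "geodesic":
        if table.coord_mode != "lonlat":
            raise DataError("geodesic distances require lon/lat coordinates")
        lon = np.radians(table.coords[:, 0])
        lat = np.radians(table.coords[:, 1])
        dlat = lat[:, None] - lat[None, :]
        dlon = lon[:, None] - lon[None, :]
        a = np.sin(dlat / 2) ** 2 + np.cos(lat)[:, None] * np.cos(lat)[None, :] * np.sin(dlon / 2) ** 2
        d = 2 * EARTH_RADIUS_M * np.arcsin(np.minimum(1.0, np.sqrt(a)))
        np.fill_diagonal(d, 0.0)
        d = (d + d.T) / 2
        return DistanceMatrix(values=d, mode="geodesic", ids=table.ids)
    raise DataError(f"unknown distance mode {mode!r}")
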