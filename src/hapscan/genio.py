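"""Readers and writers for map, genotype, phenotype and group tables.

The on-disk dialect is tab-separated text with one header line.  A
genotype cell is an unordered allele pair ``a1/a2`` (positive integer
allele codes) or ``.`` for missing.  Phase is never represented in
genotype files: the analysis consumes unphased data, and the two allele
codes of every genotype are stored canonically with ``a1 <= a2``.

A PLINK-style ``.ped``/``.map`` import is provided for interoperability
with microsatellite panels typed elsewhere (``0`` = missing allele;
half-missing genotypes collapse to fully missing, since the two-locus EM
needs both alleles or neither).

All readers are strict: malformed cells, duplicated identifiers and
markers absent from the map raise ``GenioError``; every collapsed cell
is counted and logged.
"""

from __future__ import annotations

import logging
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("hapscan")

MISSING = -1


class GenioError(ValueError):
    """Raised on malformed input files or inconsistent containers."""


class GeneticMap:
    """Ordered marker positions (cM) per chromosome.

    Parameters
    ----------
    table : pandas.DataFrame
        Columns ``marker``, ``chromosome``, ``position_cm``.  Within a
        chromosome the rows must be in non-decreasing position order;
        marker names must be unique genome-wide.
    """

    def __init__(self, table: pd.DataFrame):
        required = {"marker", "chromosome", "position_cm"}
        missing = required - set(table.columns)
        if missing:
            raise GenioError(f"map table lacks columns: {sorted(missing)}")
        table = table.loc[:, ["marker", "chromosome", "position_cm"]].copy()
        table["marker"] = table["marker"].astype(str)
        table["chromosome"] = table["chromosome"].astype(str)
        table["position_cm"] = table["position_cm"].astype(float)
        if table["marker"].duplicated().any():
            dup = table.loc[table["marker"].duplicated(), "marker"].iloc[0]
            raise GenioError(f"duplicated marker name in map: {dup!r}")
        if (table["position_cm"] < 0).any():
            bad = table.loc[table["position_cm"] < 0, "marker"].iloc[0]
            raise GenioError(f"negative map position at marker {bad!r}")
        for chrom, sub in table.groupby("chromosome", sort=False):
            pos = sub["position_cm"].to_numpy()
            drop = np.flatnonzero(np.diff(pos) < 0)
            if drop.size:
                bad = sub["marker"].iloc[drop[0] + 1]
                raise GenioError(
                    f"map positions decrease on chromosome {chrom} at marker {bad!r}"
                )
        self._table = table.reset_index(drop=True)
        self._pos = dict(zip(table["marker"], table["position_cm"]))
        self._chrom = dict(zip(table["marker"], table["chromosome"]))

    @property
    def table(self) -> pd.DataFrame:
        return self._table.copy()

    @property
    def markers(self) -> list[str]:
        return list(self._table["marker"])

    @property
    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self._table["chromosome"]))

    def __len__(self) -> int:
        return len(self._table)

    def __contains__(self, marker: str) -> bool:
        return marker in self._pos

    def position(self, marker: str) -> float:
        return self._pos[marker]

    def chromosome_of(self, marker: str) -> str:
        return self._chrom[marker]

    def chromosome_markers(self, chrom: str) -> tuple[list[str], np.ndarray]:
        sub = self._table[self._table["chromosome"] == chrom]
        return list(sub["marker"]), sub["position_cm"].to_numpy()

    def consecutive_pairs(self) -> Iterator[tuple[str, str, str, float]]:
        """Yield ``(chromosome, marker_a, marker_b, distance_cm)`` for every
        adjacent marker pair in map order."""
        for chrom in self.chromosomes:
            names, pos = self.chromosome_markers(chrom)
            for i in range(len(names) - 1):
                yield chrom, names[i], names[i + 1], float(pos[i + 1] - pos[i])

    def window_pairs(
        self, window_cm: float = 15.0, chromosomes: Sequence[str] | None = None
    ) -> Iterator[tuple[str, str, str, float]]:
        """Yield all within-chromosome marker pairs at distance <= window_cm."""
        for chrom in chromosomes if chromosomes is not None else self.chromosomes:
            names, pos = self.chromosome_markers(chrom)
            for i in range(len(names)):
                for j in range(i + 1, len(names)):
                    d = float(pos[j] - pos[i])
                    if d > window_cm:
                        break
                    yield chrom, names[i], names[j], d


class GenotypeMatrix:
    """Individuals x markers of unordered multiallelic allele pairs.

    Storage is an integer array of shape ``(n_individuals, n_markers, 2)``
    with allele codes sorted ascending per genotype and ``-1/-1`` for
    missing.  Half-missing input collapses to fully missing.
    """

    def __init__(
        self,
        ids: Sequence[str],
        markers: Sequence[str],
        alleles: np.ndarray,
    ):
        ids = [str(i) for i in ids]
        markers = [str(m) for m in markers]
        if len(set(ids)) != len(ids):
            raise GenioError("duplicated individual ids")
        if len(set(markers)) != len(markers):
            raise GenioError("duplicated marker names")
        a = np.array(alleles, dtype=np.int32, copy=True)
        if a.shape != (len(ids), len(markers), 2):
            raise GenioError(
                f"allele array shape {a.shape} does not match "
                f"({len(ids)}, {len(markers)}, 2)"
            )
        half = (a < 0).any(axis=2) & ~(a < 0).all(axis=2)
        if half.any():
            logger.info("collapsing %d half-missing genotypes to missing", half.sum())
        a.sort(axis=2)
        a[(a < 0).any(axis=2)] = MISSING
        self._alleles = a
        self.ids = ids
        self.markers = markers
        self._midx = {m: k for k, m in enumerate(markers)}

    @property
    def n_individuals(self) -> int:
        return len(self.ids)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def alleles(self) -> np.ndarray:
        """Read-only view of the (n, m, 2) allele-code array."""
        v = self._alleles.view()
        v.flags.writeable = False
        return v

    def pair(self, marker: str) -> np.ndarray:
        """Return the (n, 2) genotype column of one marker."""
        return self._alleles[:, self._midx[marker], :]

    def subset_individuals(self, ids: Sequence[str]) -> "GenotypeMatrix":
        pos = {i: k for k, i in enumerate(self.ids)}
        try:
            rows = [pos[str(i)] for i in ids]
        except KeyError as exc:
            raise GenioError(f"unknown individual id {exc.args[0]!r}") from None
        return GenotypeMatrix(list(ids), self.markers, self._alleles[rows])

    def rename_markers(self, mapping: Mapping[str, str]) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.ids, [mapping.get(m, m) for m in self.markers], self._alleles
        )

    def to_frame(self) -> pd.DataFrame:
        """Genotypes as an id-indexed frame of ``a1/a2`` strings."""
        cells = np.where(
            self._alleles[:, :, 0] < 0,
            ".",
            np.char.add(
                np.char.add(self._alleles[:, :, 0].astype(str), "/"),
                self._alleles[:, :, 1].astype(str),
            ),
        )
        return pd.DataFrame(cells, index=pd.Index(self.ids, name="individual"),
                            columns=self.markers)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.ids == other.ids
            and self.markers == other.markers
            and np.array_equal(self._alleles, other._alleles)
        )


# ---------------------------------------------------------------------------
# TSV dialect
# ---------------------------------------------------------------------------

def read_map(path) -> GeneticMap:
    table = pd.read_csv(path, sep="\t", dtype={"marker": str, "chromosome": str})
    return GeneticMap(table)


def write_map(gmap: GeneticMap, path) -> None:
    gmap.table.to_csv(path, sep="\t", index=False)


def _parse_genotype_cell(cell: str, marker: str, individual: str) -> tuple[int, int]:
    cell = cell.strip()
    if cell == ".":
        return (MISSING, MISSING)
    parts = cell.split("/")
    if len(parts) != 2:
        raise GenioError(
            f"malformed genotype {cell!r} for individual {individual!r} "
            f"at marker {marker!r}"
        )
    try:
        a1, a2 = int(parts[0]), int(parts[1])
    except ValueError:
        raise GenioError(
            f"non-integer allele in genotype {cell!r} for individual "
            f"{individual!r} at marker {marker!r}"
        ) from None
    if a1 <= 0 or a2 <= 0:
        raise GenioError(
            f"allele codes must be positive integers, got {cell!r} for "
            f"individual {individual!r} at marker {marker!r}"
        )
    return (a1, a2)


def read_genotypes(path, gmap: GeneticMap) -> GenotypeMatrix:
    frame = pd.read_csv(path, sep="\t", dtype=str)
    if frame.columns[0] != "individual":
        raise GenioError("genotype table must start with an 'individual' column")
    ids = list(frame["individual"])
    if len(set(ids)) != len(ids):
        raise GenioError("duplicated individual ids in genotype table")
    markers = list(frame.columns[1:])
    for m in markers:
        if m not in gmap:
            raise GenioError(f"genotype column {m!r} references an unmapped marker")
    a = np.empty((len(ids), len(markers), 2), dtype=np.int32)
    for j, m in enumerate(markers):
        col = frame[m]
        for i, cell in enumerate(col):
            a[i, j] = _parse_genotype_cell(str(cell), m, ids[i])
    gm = GenotypeMatrix(ids, markers, a)
    n_missing = int((gm.alleles[:, :, 0] < 0).sum())
    logger.info(
        "read %d individuals x %d markers (%d missing genotypes)",
        gm.n_individuals, gm.n_markers, n_missing,
    )
    return gm


def write_genotypes(gm: GenotypeMatrix, path) -> None:
    gm.to_frame().to_csv(path, sep="\t")


def _read_two_column(path, value_name: str, numeric: bool) -> pd.Series:
    frame = pd.read_csv(path, sep="\t", dtype=str)
    if frame.shape[1] < 2:
        raise GenioError(f"{value_name} table needs two columns")
    ids = frame.iloc[:, 0].astype(str)
    if ids.duplicated().any():
        raise GenioError(f"duplicated individual ids in {value_name} table")
    values = frame.iloc[:, 1]
    if numeric:
        values = pd.to_numeric(values, errors="raise").astype(float)
        if not np.isfinite(values).all():
            raise GenioError(f"non-finite value in {value_name} table")
    ser = pd.Series(values.to_numpy(), index=pd.Index(ids, name="individual"),
                    name=value_name)
    return ser


def read_phenotypes(path) -> pd.Series:
    """Individual id -> quantitative phenotype (finite, unique ids)."""
    return _read_two_column(path, "phenotype", numeric=True)


def write_phenotypes(phenotypes: pd.Series, path) -> None:
    phenotypes.rename("phenotype").rename_axis("individual").to_csv(path, sep="\t")


def read_sires(path) -> pd.Series:
    return _read_two_column(path, "sire", numeric=False)


def write_sires(sires: pd.Series, path) -> None:
    sires.rename("sire").rename_axis("individual").to_csv(path, sep="\t")


def read_groups(path) -> pd.Series:
    groups = _read_two_column(path, "group", numeric=False)
    bad = set(groups.unique()) - {"high", "low", "unselected"}
    if bad:
        raise GenioError(f"unknown group labels: {sorted(bad)}")
    return groups


def write_groups(groups: pd.Series, path) -> None:
    groups.rename("group").rename_axis("individual").to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# PLINK-style ped/map import
# ---------------------------------------------------------------------------

def read_ped_map(ped_path, map_path, with_phenotypes: bool = False):
    """Import a whitespace-separated ``.ped``/``.map`` pair.

    The map file carries ``chromosome  marker  position_cm`` (a fourth,
    base-pair column is ignored if present).  The ped file carries
    family, individual, father, mother, sex and phenotype columns
    followed by two allele columns per marker; ``0`` is a missing
    allele and a half-missing genotype collapses to fully missing.

    Returns the map, the genotype matrix and per-individual sire labels
    (the father column; ``0`` becomes missing/NA).  The ped phenotype
    column is ignored unless ``with_phenotypes`` is set, in which case a
    fourth element (a float Series; ``-9`` kept verbatim) is returned.
    """
    rows = []
    with open(map_path) as fh:
        for line in fh:
            fields = line.split()
            if not fields:
                continue
            if len(fields) not in (3, 4):
                raise GenioError(f"map line needs 3 or 4 fields: {line.strip()!r}")
            rows.append((fields[1], fields[0], float(fields[2])))
    gmap = GeneticMap(pd.DataFrame(rows, columns=["marker", "chromosome", "position_cm"]))
    m = len(gmap)

    ids: list[str] = []
    sires: list[str | None] = []
    phenos: list[float] = []
    genos: list[np.ndarray] = []
    n_collapsed = 0
    with open(ped_path) as fh:
        for ln, line in enumerate(fh, 1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) < 6 or (len(fields) - 6) % 2 != 0:
                raise GenioError(f"ped line {ln}: odd number of allele columns")
            n_alleles = len(fields) - 6
            if n_alleles != 2 * m:
                raise GenioError(
                    f"ped line {ln}: {n_alleles} allele columns for {m} mapped markers"
                )
            try:
                codes = np.array([int(x) for x in fields[6:]], dtype=np.int32)
            except ValueError:
                raise GenioError(f"ped line {ln}: non-integer allele code") from None
            if (codes < 0).any():
                raise GenioError(f"ped line {ln}: negative allele code")
            g = codes.reshape(m, 2)
            half = (g == 0).any(axis=1) & ~(g == 0).all(axis=1)
            n_collapsed += int(half.sum())
            g[(g == 0).any(axis=1)] = 0
            g = np.where(g == 0, MISSING, g)
            ids.append(fields[1])
            sires.append(None if fields[2] == "0" else fields[2])
            try:
                phenos.append(float(fields[5]))
            except ValueError:
                phenos.append(float("nan"))
            genos.append(g)
    if n_collapsed:
        logger.info("ped import: %d half-missing genotypes collapsed", n_collapsed)
    gm = GenotypeMatrix(ids, gmap.markers, np.stack(genos))
    sire_ser = pd.Series(sires, index=pd.Index(ids, name="individual"), name="sire")
    if with_phenotypes:
        pheno_ser = pd.Series(phenos, index=pd.Index(ids, name="individual"),
                              name="phenotype")
        return gmap, gm, sire_ser, pheno_ser
    return gmap, gm, sire_ser


def read_config(path) -> dict[str, str]:
    """Plain key=value configuration file; ``#`` starts a comment."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise GenioError(f"config line {ln} is not key=value: {line!r}")
            key, value = line.split("=", 1)
            out[key.strip()] = value.strip()
    return out
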