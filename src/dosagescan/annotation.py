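"""Gene annotations, chromosome region partitions and paired expression tables.

Coordinates are stored 1-based inclusive (GFF3 convention) throughout; BED
input is converted from 0-based half-open on read and converted back on
write, so a BED round-trip is lossless.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "AnnotationParseError",
    "GeneModel",
    "GeneCatalog",
    "Region",
    "RegionPartition",
    "ExpressionPair",
    "load_gene_annotation",
    "load_expression_pair",
    "assign_regions",
]


class AnnotationParseError(ValueError):
    """Raised for malformed annotation or expression input, naming the line."""


@dataclass(frozen=True)
class GeneModel:
    """One gene locus: identifier, chromosome and 1-based inclusive span."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "unknown"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"gene {self.gene_id}: start {self.start} > end {self.end}"
            )
        if self.strand not in {"+", "-", "unknown"}:
            raise ValueError(f"gene {self.gene_id}: bad strand {self.strand!r}")


@dataclass
class GeneCatalog:
    """An ordered gene set; the spatial backbone for windows and regions.

    Genes are kept sorted by (chrom, start, gene_id) — a total, deterministic
    order — and gene ids are unique.
    """

    genes: list[GeneModel] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.genes = sorted(
            self.genes, key=lambda g: (g.chrom, g.start, g.gene_id)
        )
        seen: set[str] = set()
        for g in self.genes:
            if g.gene_id in seen:
                raise ValueError(f"duplicate gene_id {g.gene_id!r} in catalog")
            seen.add(g.gene_id)

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self) -> Iterator[GeneModel]:
        return iter(self.genes)

    @property
    def gene_ids(self) -> list[str]:
        return [g.gene_id for g in self.genes]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": [g.gene_id for g in self.genes],
                "chrom": [g.chrom for g in self.genes],
                "start": [g.start for g in self.genes],
                "end": [g.end for g in self.genes],
                "strand": [g.strand for g in self.genes],
            }
        )

    def to_bed(self, path: str | Path) -> None:
        """Write BED6 (0-based half-open), preserving ids and strand."""
        with open(path, "w") as fh:
            for g in self.genes:
                strand = g.strand if g.strand in {"+", "-"} else "."
                fh.write(
                    f"{g.chrom}\t{g.start - 1}\t{g.end}\t{g.gene_id}\t0\t{strand}\n"
                )

    def to_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class Region:
    region_id: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"region {self.region_id}: start > end")


@dataclass
class RegionPartition:
    """Named chromosome intervals partitioning genes into analysis regions.

    Genes not covered by any listed region fall back to their own chromosome
    name as the region id. Regions on the same chromosome must not overlap.
    """

    regions: list[Region] = field(default_factory=list)

    def __post_init__(self) -> None:
        by_chrom: dict[str, list[Region]] = {}
        for r in self.regions:
            by_chrom.setdefault(r.chrom, []).append(r)
        for chrom, regs in by_chrom.items():
            regs = sorted(regs, key=lambda r: r.start)
            for a, b in zip(regs, regs[1:]):
                if b.start <= a.end:
                    raise ValueError(
                        f"overlapping regions on {chrom}: "
                        f"{a.region_id} and {b.region_id}"
                    )

    def region_of(self, gene: GeneModel) -> str:
        """Region id of a gene: the interval containing its start coordinate,
        else the gene's chromosome name (default rule)."""
        for r in self.regions:
            if r.chrom == gene.chrom and r.start <= gene.start <= r.end:
                return r.region_id
        return gene.chrom

    @classmethod
    def from_tsv(cls, path: str | Path) -> "RegionPartition":
        df = pd.read_csv(
            path, sep="\t", names=["region_id", "chrom", "start", "end"],
            comment="#",
        )
        # tolerate a header row
        if df.iloc[0]["region_id"] == "region_id":
            df = df.iloc[1:]
        return cls(
            [
                Region(str(r.region_id), str(r.chrom), int(r.start), int(r.end))
                for r in df.itertuples()
            ]
        )

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("region_id\tchrom\tstart\tend\n")
            for r in self.regions:
                fh.write(f"{r.region_id}\t{r.chrom}\t{r.start}\t{r.end}\n")


def assign_regions(
    catalog: GeneCatalog, partition: RegionPartition
) -> dict[str, str]:
    """Total map gene_id -> region_id (partition: every gene to exactly one)."""
    return {g.gene_id: partition.region_of(g) for g in catalog}


# ---------------------------------------------------------------------------
# annotation readers


def _parse_gff3_attributes(attr: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for piece in attr.strip().split(";"):
        piece = piece.strip()
        if not piece or "=" not in piece:
            continue
        k, v = piece.split("=", 1)
        out[k] = v
    return out


def load_gene_annotation(
    path: str | Path,
    feature_filter: str = "gene",
    id_attribute: str = "ID",
) -> GeneCatalog:
    """Read a GFF3 (keeping `feature_filter` features) or BED6 file.

    The format is chosen by extension (.bed -> BED6, otherwise GFF3). BED
    coordinates are converted from 0-based half-open to 1-based inclusive.
    Malformed lines raise :class:`AnnotationParseError` with the line number.
    """
    path = Path(path)
    if path.suffix.lower() == ".bed":
        return _load_bed6(path)
    return _load_gff3(path, feature_filter, id_attribute)


def _load_bed6(path: Path) -> GeneCatalog:
    genes: list[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise AnnotationParseError(
                    f"{path}:{lineno}: BED line has {len(fields)} fields, need >= 4"
                )
            try:
                start0, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise AnnotationParseError(
                    f"{path}:{lineno}: non-integer BED coordinates"
                ) from exc
            strand = fields[5] if len(fields) >= 6 else "unknown"
            if strand not in {"+", "-"}:
                strand = "unknown"
            genes.append(
                GeneModel(
                    gene_id=fields[3],
                    chrom=fields[0],
                    start=start0 + 1,
                    end=end,
                    strand=strand,
                )
            )
    try:
        return GeneCatalog(genes)
    except ValueError as exc:
        raise AnnotationParseError(f"{path}: {exc}") from exc


def _load_gff3(path: Path, feature_filter: str, id_attribute: str) -> GeneCatalog:
    genes: list[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise AnnotationParseError(
                    f"{path}:{lineno}: GFF3 line has {len(fields)} fields, need 9"
                )
            if fields[2] != feature_filter:
                continue
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError as exc:
                raise AnnotationParseError(
                    f"{path}:{lineno}: non-integer GFF3 coordinates"
                ) from exc
            attrs = _parse_gff3_attributes(fields[8])
            if id_attribute not in attrs:
                raise AnnotationParseError(
                    f"{path}:{lineno}: missing attribute {id_attribute!r}"
                )
            strand = fields[6] if fields[6] in {"+", "-"} else "unknown"
            genes.append(
                GeneModel(
                    gene_id=attrs[id_attribute],
                    chrom=fields[0],
                    start=start,
                    end=end,
                    strand=strand,
                )
            )
    try:
        return GeneCatalog(genes)
    except ValueError as exc:
        raise AnnotationParseError(f"{path}: {exc}") from exc


# ---------------------------------------------------------------------------
# expression tables


@dataclass
class ExpressionPair:
    """Matched control/variant per-gene expression values (FPKM semantics).

    ``data`` is indexed by gene_id with float columns ``control`` and
    ``variant`` (the inner join of the two input tables); genes present in
    only one input are counted in ``n_control_only`` / ``n_variant_only``.
    """

    data: pd.DataFrame
    n_control_only: int = 0
    n_variant_only: int = 0

    def __post_init__(self) -> None:
        if list(self.data.columns) != ["control", "variant"]:
            raise ValueError("ExpressionPair needs columns [control, variant]")
        if (self.data["control"] < 0).any() or (self.data["variant"] < 0).any():
            raise ValueError("expression values must be non-negative")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def gene_ids(self) -> pd.Index:
        return self.data.index

    def restrict_to(self, catalog: GeneCatalog) -> "ExpressionPair":
        """Keep genes present in the catalog (preserving catalog order)."""
        ids = [g for g in catalog.gene_ids if g in self.data.index]
        return ExpressionPair(
            self.data.loc[ids], self.n_control_only, self.n_variant_only
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ExpressionPair":
        return cls(df[["control", "variant"]].astype(float))


def _try_float(v) -> float:
    try:
        return float(v)
    except (TypeError, ValueError):
        return float("nan")


def _read_expression_tsv(path: str | Path) -> pd.Series:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise AnnotationParseError(f"{path}: expected 2 tab-separated columns")
    df = df.iloc[:, :2]
    df.columns = ["gene_id", "value"]
    # python float() is correctly rounded (pd.to_numeric is not)
    parsed = [_try_float(v) for v in df["value"]]
    values = pd.Series(parsed, index=df.index, dtype=float)
    # optional header: tolerated only as a lone leading non-numeric row
    # followed by numeric data, so a bad value is never mistaken for one
    if values.iloc[0] != values.iloc[0] and len(df) > 1 and values.iloc[1:].notna().all():
        df = df.iloc[1:]
        values = values.iloc[1:]
    if values.isna().any():
        bad = df.loc[values.isna()].index[0] + 1
        raise AnnotationParseError(f"{path}:{bad}: non-numeric expression value")
    if (values < 0).any():
        bad = df.loc[values < 0].index[0] + 1
        raise AnnotationParseError(f"{path}:{bad}: negative expression value")
    s = pd.Series(values.to_numpy(float), index=df["gene_id"].to_numpy())
    if s.index.duplicated().any():
        dup = s.index[s.index.duplicated()][0]
        raise AnnotationParseError(f"{path}: duplicate gene_id {dup!r}")
    return s


def load_expression_pair(
    control_path: str | Path, variant_path: str | Path
) -> ExpressionPair:
    """Inner-join two (gene_id, value) TSVs into an :class:`ExpressionPair`.

    Genes found in only one file are excluded and the exclusion counts are
    logged and kept on the returned object.
    """
    control = _read_expression_tsv(control_path)
    variant = _read_expression_tsv(variant_path)
    shared = control.index.intersection(variant.index)
    n_control_only = len(control.index.difference(variant.index))
    n_variant_only = len(variant.index.difference(control.index))
    if n_control_only or n_variant_only:
        logger.info(
            "expression join: %d genes only in control, %d only in variant "
            "(excluded); %d shared",
            n_control_only, n_variant_only, len(shared),
        )
    df = pd.DataFrame(
        {"control": control.loc[shared], "variant": variant.loc[shared]}
    )
    return ExpressionPair(df, n_control_only, n_variant_only)


def write_expression_tsv(
    values: Mapping[str, float] | pd.Series, path: str | Path,
    header: bool = False,
) -> None:
    s = pd.Series(values)
    with open(path, "w") as fh:
        if header:
            fh.write("gene_id\tfpkm\n")
        for gid, v in s.items():
            # shortest round-trippable decimal, so reloading is lossless
            fh.write(f"{gid}\t{float(v)!r}\n")
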