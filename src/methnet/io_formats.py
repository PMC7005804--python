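"""Readers and writers for the external formats used by the pipeline.

All genomic coordinates are 0-based, half-open internally.  The only
exception is WIG output, which is 1-based per the WIG standard; the shift
is applied at the file boundary.

Supported formats
-----------------
- methylation count tables (TSV; per-cytosine methylated/total read counts)
- BED3+ region files
- GMT pathway gene-set files
- PPI edge tables (TSV with confidence and co-expression scores)
- expression (DEG) tables (TSV)
- variableStep WIG tracks
- a bedGraph-style (fraction, coverage) adapter mapped to counts
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

VALID_GROUPS = ("reference", "control", "treatment")
VALID_KINDS = ("gene", "enhancer", "other")

_METH_COLUMNS = ["chrom", "pos", "strand", "context", "n_meth", "n_total"]


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class MethylomeSample:
    """Per-cytosine methylation counts for one individual.

    ``sites`` is a DataFrame with columns chrom, pos, strand, context,
    n_meth, n_total, sorted by (chrom, pos), with (chrom, pos, strand)
    unique and ``n_meth <= n_total`` everywhere.
    """

    sample_id: str
    group: str
    sites: pd.DataFrame

    def __post_init__(self) -> None:
        if self.group not in VALID_GROUPS:
            raise ValueError(f"unknown group {self.group!r}; expected one of {VALID_GROUPS}")
        df = self.sites.reset_index(drop=True).copy()
        missing = [c for c in _METH_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"sites table missing columns: {missing}")
        df = df[_METH_COLUMNS]
        df["pos"] = df["pos"].astype(np.int64)
        df["n_meth"] = df["n_meth"].astype(np.int64)
        df["n_total"] = df["n_total"].astype(np.int64)
        if (df["pos"] < 0).any():
            raise ValueError("negative position in sites table")
        if (df["n_total"] < 1).any():
            raise ValueError("n_total < 1 in sites table")
        bad = df["n_meth"] > df["n_total"]
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(f"n_meth > n_total at row {i} ({df.iloc[i]['chrom']}:{df.iloc[i]['pos']})")
        if df.duplicated(subset=["chrom", "pos", "strand"]).any():
            raise ValueError("duplicate (chrom, pos, strand) in sites table")
        df = df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
        self.sites = df

    @property
    def n_sites(self) -> int:
        return len(self.sites)


@dataclass
class RegionSet:
    """A set of genomic regions (0-based, half-open)."""

    regions: pd.DataFrame  # chrom, start, end, name, strand, kind

    def __post_init__(self) -> None:
        df = self.regions.reset_index(drop=True).copy()
        for col, default in (("strand", "."), ("kind", "other")):
            if col not in df.columns:
                df[col] = default
        df = df[["chrom", "start", "end", "name", "strand", "kind"]]
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        if (df["start"] >= df["end"]).any():
            raise ValueError("region with start >= end")
        for kind, sub in df.groupby("kind"):
            if sub["name"].duplicated().any():
                raise ValueError(f"duplicate region names within kind {kind!r}")
        self.regions = df

    def __len__(self) -> int:
        return len(self.regions)

    def subset(self, names: Iterable[str]) -> "RegionSet":
        names = set(names)
        return RegionSet(self.regions[self.regions["name"].isin(names)].copy())

    def lengths(self) -> pd.Series:
        df = self.regions
        return pd.Series((df["end"] - df["start"]).to_numpy(), index=df["name"].to_numpy())


@dataclass
class ExpressionTable:
    """Differential-expression results, one row per gene."""

    rows: pd.DataFrame  # gene, log2fc, p_value, deg_flag

    def __post_init__(self) -> None:
        df = self.rows.reset_index(drop=True).copy()
        df = df[["gene", "log2fc", "p_value", "deg_flag"]]
        if df["gene"].duplicated().any():
            raise ValueError("duplicate gene in expression table")
        if ((df["p_value"] < 0) | (df["p_value"] > 1)).any():
            raise ValueError("p_value outside [0, 1]")
        df["deg_flag"] = df["deg_flag"].astype(bool)
        self.rows = df

    def degs(self) -> set[str]:
        return set(self.rows.loc[self.rows["deg_flag"], "gene"])


@dataclass
class PathwayDB:
    """Mapping pathway id -> (description, gene set)."""

    sets: dict[str, set[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for pid, genes in self.sets.items():
            if not genes:
                raise ValueError(f"empty gene set for pathway {pid!r}")
        for pid in self.sets:
            self.descriptions.setdefault(pid, "")

    def __len__(self) -> int:
        return len(self.sets)

    def universe(self) -> set[str]:
        out: set[str] = set()
        for genes in self.sets.values():
            out |= genes
        return out


@dataclass
class PPIEdgeTable:
    """Undirected weighted gene-gene edges."""

    edges: pd.DataFrame  # gene_a, gene_b, combined_score, coexpression

    def __post_init__(self) -> None:
        df = self.edges.reset_index(drop=True).copy()
        df = df[["gene_a", "gene_b", "combined_score", "coexpression"]]
        if (df["gene_a"] == df["gene_b"]).any():
            raise ValueError("self-loop in PPI edge table")
        for col in ("combined_score", "coexpression"):
            if ((df[col] < 0) | (df[col] > 1)).any():
                raise ValueError(f"{col} outside [0, 1]")
        # canonical unordered orientation, dedup keeping max combined_score
        a = df[["gene_a", "gene_b"]].min(axis=1)
        b = df[["gene_a", "gene_b"]].max(axis=1)
        df["gene_a"], df["gene_b"] = a, b
        df = (
            df.sort_values("combined_score", kind="mergesort")
            .drop_duplicates(subset=["gene_a", "gene_b"], keep="last")
            .sort_values(["gene_a", "gene_b"], kind="mergesort")
            .reset_index(drop=True)
        )
        self.edges = df

    def __len__(self) -> int:
        return len(self.edges)

    def genes(self) -> set[str]:
        return set(self.edges["gene_a"]) | set(self.edges["gene_b"])


# ---------------------------------------------------------------------------
# methylation count tables
# ---------------------------------------------------------------------------


def read_methylation_table(path, sample_id: str, group: str) -> MethylomeSample:
    """Read a per-cytosine count TSV into a :class:`MethylomeSample`.

    Required header: chrom, pos, strand, context, n_meth, n_total.  A
    leading pragma line ``## coords=1-based`` converts positions to the
    internal 0-based convention.
    """
    one_based = False
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("##"):
            if "coords=1-based" in first:
                one_based = True
            header_line = fh.readline()
            offset = 2
        else:
            header_line = first
            offset = 1
        header = header_line.rstrip("\n").split("\t")
        if header != _METH_COLUMNS:
            raise FormatError(f"{path}: bad header {header}; expected {_METH_COLUMNS}")
        rows = []
        for lineno, line in enumerate(fh, start=offset + 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 6:
                raise FormatError(f"{path}:{lineno}: expected 6 fields, got {len(parts)}")
            try:
                pos = int(parts[1])
                n_meth = int(parts[4])
                n_total = int(parts[5])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
            if n_meth > n_total:
                raise FormatError(f"{path}:{lineno}: n_meth ({n_meth}) > n_total ({n_total})")
            rows.append((parts[0], pos - 1 if one_based else pos, parts[2], parts[3], n_meth, n_total))
    df = pd.DataFrame(rows, columns=_METH_COLUMNS)
    return MethylomeSample(sample_id=sample_id, group=group, sites=df)


def write_methylation_table(sample: MethylomeSample, path) -> None:
    sample.sites.to_csv(path, sep="\t", index=False)


def read_bedgraph_counts(path, sample_id: str, group: str, context: str = "CpG") -> MethylomeSample:
    """Adapter for bedGraph-like files carrying (fraction, coverage) pairs.

    Columns: chrom, start, end, fraction, coverage.  Methylated counts are
    recovered by rounding ``fraction * coverage``.
    """
    df = pd.read_csv(path, sep="\t", comment="#", header=None,
                     names=["chrom", "start", "end", "fraction", "coverage"])
    n_total = df["coverage"].astype(np.int64)
    n_meth = np.rint(df["fraction"].to_numpy() * n_total.to_numpy()).astype(np.int64)
    sites = pd.DataFrame({
        "chrom": df["chrom"],
        "pos": df["start"].astype(np.int64),
        "strand": ".",
        "context": context,
        "n_meth": n_meth,
        "n_total": n_total,
    })
    return MethylomeSample(sample_id=sample_id, group=group, sites=sites)


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------


def read_bed(path, kind: str = "other") -> RegionSet:
    """Read a BED3+ file (0-based half-open, preserved verbatim)."""
    if kind not in VALID_KINDS:
        raise ValueError(f"unknown kind {kind!r}")
    rows = []
    with open(path) as fh:
        n = 0
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: BED line with <3 fields")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
            if start >= end:
                raise FormatError(f"{path}:{lineno}: start >= end")
            n += 1
            name = parts[3] if len(parts) > 3 and parts[3] not in ("", ".") else f"region_{n}"
            strand = parts[5] if len(parts) > 5 else "."
            rows.append((parts[0], start, end, name, strand, kind))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "strand", "kind"])
    return RegionSet(df)


def write_bed(region_set: RegionSet, path) -> None:
    df = region_set.regions
    with open(path, "w") as fh:
        for row in df.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{row.name}\t0\t{row.strand}\n")


# ---------------------------------------------------------------------------
# GMT
# ---------------------------------------------------------------------------


def read_gmt(path) -> PathwayDB:
    sets: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line with <3 fields")
            pid, desc, genes = parts[0], parts[1], [g for g in parts[2:] if g]
            sets[pid] = set(genes)
            descriptions[pid] = desc
    return PathwayDB(sets=sets, descriptions=descriptions)


def write_gmt(db: PathwayDB, path) -> None:
    with open(path, "w") as fh:
        for pid in sorted(db.sets):
            genes = "\t".join(sorted(db.sets[pid]))
            fh.write(f"{pid}\t{db.descriptions.get(pid, '')}\t{genes}\n")


# ---------------------------------------------------------------------------
# PPI edge tables
# ---------------------------------------------------------------------------


def read_ppi_table(path) -> PPIEdgeTable:
    df = pd.read_csv(path, sep="\t")
    expected = ["gene_a", "gene_b", "combined_score", "coexpression"]
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    return PPIEdgeTable(df[expected])


def write_ppi_table(table: PPIEdgeTable, path) -> None:
    # fixed float format keeps write -> read -> write byte-stable
    table.edges.to_csv(path, sep="\t", index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# expression tables
# ---------------------------------------------------------------------------


def read_expression_table(path) -> ExpressionTable:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ("gene", "log2fc", "p_value") if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    if "deg_flag" not in df.columns:
        df["deg_flag"] = (df["p_value"] <= 0.05) & (df["log2fc"].abs() > 1)
    else:
        df["deg_flag"] = df["deg_flag"].astype(str).str.lower().isin(("true", "1", "yes"))
    return ExpressionTable(df[["gene", "log2fc", "p_value", "deg_flag"]])


def write_expression_table(table: ExpressionTable, path) -> None:
    df = table.rows.copy()
    df["deg_flag"] = np.where(df["deg_flag"], "True", "False")
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# WIG
# ---------------------------------------------------------------------------


def write_wig(track_name: str, per_site_values: Mapping[tuple[str, int], float], path) -> None:
    """Write variableStep WIG; internal 0-based positions become 1-based."""
    with open(path, "w") as fh:
        fh.write(f'track type=wiggle_0 name="{track_name}"\n')
        by_chrom: dict[str, list[tuple[int, float]]] = {}
        for (chrom, pos), value in per_site_values.items():
            by_chrom.setdefault(chrom, []).append((pos, value))
        for chrom in sorted(by_chrom):
            fh.write(f"variableStep chrom={chrom}\n")
            for pos, value in sorted(by_chrom[chrom]):
                fh.write(f"{pos + 1}\t{value:.6g}\n")


def read_wig(path) -> tuple[str, dict[tuple[str, int], float]]:
    """Parse a variableStep WIG written by :func:`write_wig` (positions back to 0-based)."""
    values: dict[tuple[str, int], float] = {}
    track_name = ""
    chrom = None
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("track"):
                if 'name="' in line:
                    track_name = line.split('name="', 1)[1].rsplit('"', 1)[0]
                continue
            if line.startswith("variableStep"):
                chrom = dict(kv.split("=") for kv in line.split()[1:])["chrom"]
                continue
            if not line:
                continue
            pos_s, val_s = line.split("\t")
            if chrom is None:
                raise FormatError(f"{path}: data line before variableStep declaration")
            values[(chrom, int(pos_s) - 1)] = float(val_s)
    return track_name, values
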