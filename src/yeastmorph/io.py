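"""Readers and writers for the pipeline's external formats.

Three tabular inputs drive the analysis:

* a **trait table** — replicate-level values of the morphological traits, one
  row per (strain, replicate), with a medium column and the number of cells
  imaged per culture;
* a **lineage edge list** — parent→child breeding events annotated with the
  breeding type (spontaneous isolate, mutagen-induced isolate, cross, or
  mutagenized cross);
* an optional **genotype matrix** — biallelic diploid calls coded as 0/1/2
  alternate-allele counts, from a plain TSV or a minimal VCF (GT field only).

All formats are uncompressed UTF-8 text; the trait-table delimiter (tab or
comma) is sniffed from the header line.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .catalog import TraitCatalog, _sniff_sep

log = logging.getLogger(__name__)

META_COLUMNS = ["strain", "replicate", "medium", "cell_count"]

BREEDING_TYPES = ("spontaneous", "mutagen", "cross", "cross_mutagen")

#: a record missing more than this fraction of traits is rejected outright
MAX_MISSING_FRACTION = 0.10


class FormatError(ValueError):
    """Malformed input file (missing columns, bad tokens)."""


class DomainError(ValueError):
    """A trait value outside its family's value domain."""


class LineageError(ValueError):
    """Inconsistent breeding graph (cycles, bad parent counts)."""


# ---------------------------------------------------------------------------
# trait table
# ---------------------------------------------------------------------------

@dataclass
class TraitTable:
    """Replicate-level trait observations plus the catalog they follow.

    ``data`` has the metadata columns ``strain, replicate, medium,
    cell_count`` followed by one column per catalog trait (NaN = missing,
    tolerated up to :data:`MAX_MISSING_FRACTION` per record).
    """

    data: pd.DataFrame = field(repr=False)
    catalog: TraitCatalog = field(repr=False)

    def __post_init__(self) -> None:
        df = self.data
        missing_meta = [c for c in META_COLUMNS if c not in df.columns]
        if missing_meta:
            raise FormatError(f"trait table missing columns: {missing_meta}")
        missing_traits = [t for t in self.catalog.trait_ids if t not in df.columns]
        if missing_traits:
            raise FormatError(
                f"trait table missing {len(missing_traits)} catalog traits, "
                f"e.g. {missing_traits[:3]}"
            )
        keys = df[["strain", "replicate"]].astype(str)
        if keys.duplicated().any():
            dup = keys[keys.duplicated()].iloc[0].tolist()
            raise FormatError(f"duplicate (strain, replicate) pair: {dup}")
        if (df["cell_count"] <= 0).any():
            raise DomainError("cell_count must be a positive integer")
        self._check_domains(df)
        frac_missing = df[self.catalog.trait_ids].isna().mean(axis=1)
        bad = frac_missing > MAX_MISSING_FRACTION
        if bad.any():
            rows = df.loc[bad, ["strain", "replicate"]].astype(str).agg(
                "/".join, axis=1
            )
            raise FormatError(
                f"records missing >{MAX_MISSING_FRACTION:.0%} of traits: "
                f"{rows.tolist()[:5]}"
            )

    def _check_domains(self, df: pd.DataFrame) -> None:
        fams = self.catalog.families()
        for trait in fams.index[fams == "proportion"]:
            col = df[trait]
            bad = col.notna() & ((col < 0) | (col > 1))
            if bad.any():
                i = int(np.flatnonzero(bad.to_numpy())[0])
                raise DomainError(
                    f"proportion trait {trait!r} value {col.iloc[i]} outside "
                    f"[0, 1] at row {i} (strain {df['strain'].iloc[i]!r})"
                )
        for trait in fams.index[fams == "positive"]:
            col = df[trait]
            bad = col.notna() & (col <= 0)
            if bad.any():
                i = int(np.flatnonzero(bad.to_numpy())[0])
                raise DomainError(
                    f"positive trait {trait!r} value {col.iloc[i]} <= 0 at "
                    f"row {i} (strain {df['strain'].iloc[i]!r})"
                )

    # -- accessors ---------------------------------------------------------
    @property
    def strains(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.data["strain"].astype(str):
            seen.setdefault(s, None)
        return list(seen)

    @property
    def n_records(self) -> int:
        return len(self.data)

    def trait_values(self, trait_id: str) -> pd.Series:
        return self.data[trait_id]

    def subset_strains(self, strains) -> "TraitTable":
        keep = self.data["strain"].isin(list(strains))
        return TraitTable(self.data.loc[keep].reset_index(drop=True), self.catalog)


def read_trait_table(path, catalog: TraitCatalog) -> TraitTable:
    """Read and validate a delimited trait table against ``catalog``."""
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep)
    for col in META_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"trait table at {path} lacks column {col!r}")
    df["strain"] = df["strain"].astype(str)
    df["replicate"] = df["replicate"].astype(str)
    df["medium"] = df["medium"].astype(str)
    return TraitTable(df, catalog)


def write_trait_table(table: TraitTable, path, sep: str = "\t") -> None:
    cols = META_COLUMNS + table.catalog.trait_ids
    table.data[cols].to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# lineage graph
# ---------------------------------------------------------------------------

@dataclass
class LineageGraph:
    """Breeding pedigree: parent→child edges annotated by breeding type."""

    graph: nx.DiGraph = field(repr=False)

    def __post_init__(self) -> None:
        for child, info in self.events().items():
            btype = info["breeding_type"]
            if btype not in BREEDING_TYPES:
                raise LineageError(f"unknown breeding type {btype!r} for {child}")
            n_par = len(info["parents"])
            want_two = btype in ("cross", "cross_mutagen")
            if want_two and n_par != 2:
                raise LineageError(
                    f"cross child {child!r} needs exactly two parents, got {n_par}"
                )
            if not want_two and n_par != 1:
                raise LineageError(
                    f"{btype} child {child!r} needs exactly one parent, got {n_par}"
                )
        if not nx.is_directed_acyclic_graph(self.graph):
            cyc = nx.find_cycle(self.graph)
            raise LineageError(f"lineage contains a cycle: {cyc}")

    @property
    def strains(self) -> list[str]:
        return list(self.graph.nodes)

    def events(self) -> dict[str, dict]:
        """Map child strain → {'parents': [...], 'breeding_type': str}."""
        out: dict[str, dict] = {}
        for parent, child, attrs in self.graph.edges(data=True):
            rec = out.setdefault(
                child, {"parents": [], "breeding_type": attrs["breeding_type"]}
            )
            rec["parents"].append(parent)
            if rec["breeding_type"] != attrs["breeding_type"]:
                raise LineageError(
                    f"child {child!r} has edges of conflicting breeding types"
                )
        return out

    def parents_of(self, child: str) -> list[str]:
        return sorted(self.graph.predecessors(child))

    def breeding_type_of(self, child: str) -> str:
        return self.events()[child]["breeding_type"]


def read_lineage(path) -> LineageGraph:
    """Read a whitespace-delimited edge list.

    One breeding event per line: ``child breeding_type parent1 [parent2]``.
    Blank lines and ``#`` comments are ignored.
    """
    g = nx.DiGraph()
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) < 3:
                raise FormatError(
                    f"{path}:{lineno}: expected 'child type parent [parent2]'"
                )
            child, btype, *parents = parts
            if btype in ("cross", "cross_mutagen") and len(parents) != 2:
                raise FormatError(
                    f"{path}:{lineno}: cross event needs two parents"
                )
            if btype not in BREEDING_TYPES:
                raise FormatError(f"{path}:{lineno}: unknown breeding type {btype!r}")
            for p in parents:
                g.add_edge(p, child, breeding_type=btype)
    return LineageGraph(g)


def write_lineage(lineage: LineageGraph, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for child, info in lineage.events().items():
            fh.write(
                f"{child} {info['breeding_type']} {' '.join(info['parents'])}\n"
            )


# ---------------------------------------------------------------------------
# genotype matrix
# ---------------------------------------------------------------------------

@dataclass
class GenotypeMatrix:
    """Diploid genotypes coded 0/1/2 (alternate-allele counts), NaN = missing.

    ``calls`` is a strains × sites DataFrame.
    """

    calls: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        vals = self.calls.to_numpy(dtype=float)
        ok = np.isnan(vals) | np.isin(vals, (0.0, 1.0, 2.0))
        if not ok.all():
            i, j = np.argwhere(~ok)[0]
            raise FormatError(
                f"genotype call {vals[i, j]} at strain "
                f"{self.calls.index[i]!r}, site {self.calls.columns[j]!r} "
                "is not in {0, 1, 2, missing}"
            )

    @property
    def strains(self) -> list[str]:
        return list(self.calls.index)

    @property
    def sites(self) -> list[str]:
        return list(self.calls.columns)


def read_genotypes(path) -> GenotypeMatrix:
    """Read genotypes from a sites × strains TSV or a minimal VCF.

    VCF handling is deliberately minimal: only the GT subfield is used,
    sites with more than one ALT allele (multiallelic) are dropped with a
    log message, and phasing is ignored.
    """
    with open(path, encoding="utf-8") as fh:
        first = fh.readline()
    if first.startswith("##fileformat=VCF") or first.startswith("#CHROM"):
        return _read_vcf(path)
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA", ".", ""])
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()]
            raise FormatError(
                f"non-numeric genotype token {bad.iloc[0]!r} in column {col!r}"
            )
    # file is sites × strains; internal layout is strains × sites
    return GenotypeMatrix(df.T.astype(float))


def _read_vcf(path) -> GenotypeMatrix:
    samples: list[str] = []
    sites: list[str] = []
    rows: list[list[float]] = []
    n_dropped = 0
    with open(path, encoding="utf-8") as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if line.startswith("##") or not line:
                continue
            if line.startswith("#CHROM"):
                samples = line.split("\t")[9:]
                continue
            fields = line.split("\t")
            if len(fields) < 10:
                raise FormatError("VCF data line has no sample columns")
            chrom, pos, _, _, alt = fields[0], fields[1], fields[2], fields[3], fields[4]
            if "," in alt:  # multiallelic → not biallelic, drop
                n_dropped += 1
                continue
            fmt = fields[8].split(":")
            try:
                gt_idx = fmt.index("GT")
            except ValueError as exc:
                raise FormatError("VCF FORMAT lacks GT") from exc
            calls = []
            for sample_field in fields[9:]:
                gt = sample_field.split(":")[gt_idx].replace("|", "/")
                alleles = gt.split("/")
                if "." in alleles:
                    calls.append(np.nan)
                else:
                    try:
                        calls.append(float(sum(int(a) for a in alleles)))
                    except ValueError as exc:
                        raise FormatError(f"bad GT token {gt!r}") from exc
            sites.append(f"{chrom}:{pos}")
            rows.append(calls)
    if n_dropped:
        log.info("dropped %d multiallelic VCF site(s)", n_dropped)
    df = pd.DataFrame(rows, index=sites, columns=samples)
    return GenotypeMatrix(df.T)


def write_genotypes(geno: GenotypeMatrix, path) -> None:
    out = geno.calls.T
    out.index.name = "site"
    out.to_csv(path, sep="\t", na_rep="NA")
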