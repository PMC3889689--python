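"""Readers and writers for every external format the pipeline touches.

Formats: GFF3 and BED12 gene models, ENCODE narrowPeak and plain-TSV peak
lists, counts TSV, ortholog-map TSV, weighted edge-list TSV, GMT gene-set
collections, and a two-column scaffold-length TSV.  All coordinates are
normalized to 0-based half-open on read; GFF3 (1-based closed) is converted
only here.  Writers sort records by primary key so identical in-memory
objects always produce byte-identical files.
"""

from __future__ import annotations

import math
from typing import Iterable, Optional

import gffutils
import pandas as pd

from .models import (
    CountMatrix,
    GeneModel,
    GeneSetCollection,
    OrthologMap,
    Peak,
    ScaffoldSet,
    WeightedNetwork,
)

__all__ = [
    "ParseError",
    "read_scaffolds",
    "write_scaffolds",
    "filter_scaffolds",
    "read_gene_models",
    "write_gene_models",
    "read_peaks",
    "write_peaks",
    "read_counts",
    "write_counts",
    "read_ortholog_map",
    "write_ortholog_map",
    "read_network",
    "write_network",
    "read_gene_sets",
    "write_gene_sets",
]


class ParseError(ValueError):
    """A malformed record in an input file; carries the 1-based line number."""

    def __init__(self, path, line_number: Optional[int], message: str):
        self.path = str(path)
        self.line_number = line_number
        where = f"{path}" if line_number is None else f"{path}:{line_number}"
        super().__init__(f"{where}: {message}")


# ---------------------------------------------------------------------------
# scaffolds


def read_scaffolds(path) -> ScaffoldSet:
    df = pd.read_csv(path, sep="\t", dtype={"scaffold_id": str})
    if list(df.columns) != ["scaffold_id", "length"]:
        raise ParseError(path, 1, f"expected columns scaffold_id, length; got {list(df.columns)}")
    if df["scaffold_id"].duplicated().any():
        dup = df.loc[df["scaffold_id"].duplicated(), "scaffold_id"].iloc[0]
        raise ParseError(path, None, f"duplicate scaffold_id {dup!r}")
    return ScaffoldSet(dict(zip(df["scaffold_id"], df["length"].astype(int))))


def write_scaffolds(scaffolds: ScaffoldSet, path) -> None:
    rows = sorted(scaffolds.lengths.items())
    with open(path, "w") as fh:
        fh.write("scaffold_id\tlength\n")
        for sid, length in rows:
            fh.write(f"{sid}\t{length}\n")


def filter_scaffolds(scaffolds: ScaffoldSet, min_length: int = 10_000) -> ScaffoldSet:
    """Scaffolds strictly longer than ``min_length`` bases (default 10 kb)."""
    return scaffolds.filter(min_length)


# ---------------------------------------------------------------------------
# gene models


def _validate_gff3_lines(path) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(path, lineno, f"expected 9 tab-separated fields, got {len(fields)}")
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError:
                raise ParseError(path, lineno, f"non-integer coordinates {fields[3]!r}, {fields[4]!r}")
            if start < 1 or end < start:
                raise ParseError(path, lineno, f"invalid 1-based closed interval [{start}, {end}]")


def _read_gene_models_gff3(path) -> list[GeneModel]:
    _validate_gff3_lines(path)
    try:
        db = gffutils.create_db(
            str(path),
            dbfn=":memory:",
            keep_order=True,
            merge_strategy="error",
        )
    except Exception as exc:  # gffutils raises several exception types
        raise ParseError(path, None, f"GFF3 parse failed: {exc}") from exc

    genes: list[GeneModel] = []
    seen: set[str] = set()
    for gene in db.features_of_type("gene", order_by=("seqid", "start")):
        gene_id = gene.id
        if gene_id in seen:
            raise ParseError(path, None, f"duplicate gene_id {gene_id!r}")
        seen.add(gene_id)
        ortholog = gene.attributes.get("ortholog", [None])[0]
        transcripts = list(db.children(gene, featuretype="mRNA"))
        best: Optional[tuple[int, int, int]] = None  # (exonic_length, start0, end0)
        if transcripts:
            for tx in transcripts:
                exons = list(db.children(tx, featuretype="exon"))
                if exons:
                    exonic = sum(e.end - e.start + 1 for e in exons)
                    lo = min(e.start for e in exons) - 1
                    hi = max(e.end for e in exons)
                else:
                    exonic = tx.end - tx.start + 1
                    lo, hi = tx.start - 1, tx.end
                cand = (exonic, lo, hi)
                if best is None or cand[0] > best[0]:
                    best = cand
        else:
            best = (gene.end - gene.start + 1, gene.start - 1, gene.end)
        exonic, lo, hi = best
        genes.append(
            GeneModel(
                gene_id=gene_id,
                scaffold_id=gene.seqid,
                start=lo,
                end=hi,
                strand=gene.strand if gene.strand in "+-" else "+",
                transcript_length=exonic,
                human_ortholog=ortholog,
            )
        )
    return genes


_BED12_COLUMNS = [
    "chrom", "chromStart", "chromEnd", "name", "score", "strand",
    "thickStart", "thickEnd", "itemRgb", "blockCount", "blockSizes", "blockStarts",
]


def _read_gene_models_bed12(path) -> list[GeneModel]:
    try:
        df = pd.read_csv(path, sep="\t", header=None, names=_BED12_COLUMNS, dtype=str)
    except pd.errors.EmptyDataError:
        return []
    per_gene: dict[str, tuple[int, GeneModel]] = {}
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            start, end = int(row.chromStart), int(row.chromEnd)
            n_blocks = int(row.blockCount)
            sizes = [int(x) for x in str(row.blockSizes).rstrip(",").split(",")]
        except (TypeError, ValueError) as exc:
            raise ParseError(path, i, f"malformed BED12 record: {exc}") from exc
        if len(sizes) != n_blocks:
            raise ParseError(path, i, f"blockCount {n_blocks} != {len(sizes)} blockSizes")
        exonic = sum(sizes)
        model = GeneModel(
            gene_id=str(row.name),
            scaffold_id=str(row.chrom),
            start=start,
            end=end,
            strand=row.strand if row.strand in "+-" else "+",
            transcript_length=exonic,
        )
        prev = per_gene.get(model.gene_id)
        # several BED lines with one name = alternative transcripts; keep the longest
        if prev is None or exonic > prev[0]:
            per_gene[model.gene_id] = (exonic, model)
    return [m for _, m in per_gene.values()]


def read_gene_models(path, format: str, scaffolds: ScaffoldSet) -> list[GeneModel]:
    """Read gene models, one per gene = its longest transcript.

    ``transcript_length`` is the summed exon length of the longest
    transcript (GFF3: over mRNA children; BED12: over blocks of the longest
    line sharing a name).  Genes on scaffolds absent from ``scaffolds``, or
    extending past the scaffold end, are rejected.
    """
    if format == "gff3":
        genes = _read_gene_models_gff3(path)
    elif format == "bed12":
        genes = _read_gene_models_bed12(path)
    else:
        raise ValueError(f"unknown gene-model format {format!r}")
    for gene in genes:
        if gene.scaffold_id not in scaffolds:
            raise ParseError(path, None, f"gene {gene.gene_id!r} on unknown scaffold {gene.scaffold_id!r}")
        if gene.end > scaffolds.length_of(gene.scaffold_id):
            raise ParseError(
                path, None,
                f"gene {gene.gene_id!r} extends past the end of scaffold {gene.scaffold_id!r}",
            )
    return sorted(genes, key=lambda g: (g.scaffold_id, g.start, g.gene_id))


def _exon_blocks(gene: GeneModel) -> list[tuple[int, int]]:
    """Exon intervals (0-based half-open) spanning [start, end) with total
    exonic length == transcript_length; one block when intron-free."""
    span = gene.end - gene.start
    tl = gene.transcript_length
    if tl == span:
        return [(gene.start, gene.end)]
    if tl < 2:
        raise ValueError(
            f"gene {gene.gene_id!r}: cannot represent transcript_length {tl} < 2 with introns"
        )
    a = max(1, tl // 2)
    b = tl - a
    return [(gene.start, gene.start + a), (gene.end - b, gene.end)]


def write_gene_models(genes: Iterable[GeneModel], path, format: str) -> None:
    genes = sorted(genes, key=lambda g: (g.scaffold_id, g.start, g.gene_id))
    if format == "gff3":
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for g in genes:
                attrs = f"ID={g.gene_id}"
                if g.human_ortholog:
                    attrs += f";ortholog={g.human_ortholog}"
                fh.write(
                    f"{g.scaffold_id}\ttfdirect\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
                )
                tx_id = f"{g.gene_id}.t1"
                fh.write(
                    f"{g.scaffold_id}\ttfdirect\tmRNA\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t"
                    f"ID={tx_id};Parent={g.gene_id}\n"
                )
                for k, (lo, hi) in enumerate(_exon_blocks(g), start=1):
                    fh.write(
                        f"{g.scaffold_id}\ttfdirect\texon\t{lo + 1}\t{hi}\t.\t{g.strand}\t.\t"
                        f"ID={tx_id}.exon{k};Parent={tx_id}\n"
                    )
    elif format == "bed12":
        with open(path, "w") as fh:
            for g in genes:
                blocks = _exon_blocks(g)
                sizes = ",".join(str(hi - lo) for lo, hi in blocks)
                starts = ",".join(str(lo - g.start) for lo, hi in blocks)
                fh.write(
                    f"{g.scaffold_id}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\t"
                    f"{g.start}\t{g.end}\t0\t{len(blocks)}\t{sizes}\t{starts}\n"
                )
    else:
        raise ValueError(f"unknown gene-model format {format!r}")


# ---------------------------------------------------------------------------
# peaks

_NARROWPEAK_COLUMNS = [
    "chrom", "chromStart", "chromEnd", "name", "score", "strand",
    "signalValue", "pValue", "qValue", "peak",
]


def _fdr_from_dialect(value: float, dialect: str, path, lineno: int) -> float:
    if dialect == "fraction":
        if not (0.0 <= value <= 1.0):
            raise ParseError(path, lineno, f"FDR fraction {value} outside [0, 1]")
        return float(value)
    if dialect == "neglog10":
        if value < 0:
            raise ParseError(path, lineno, f"-log10 FDR {value} is negative")
        return float(10.0 ** (-value))
    raise ValueError(f"unknown FDR dialect {dialect!r}")


def read_peaks(path, format: str, fdr_dialect: str = "fraction") -> list[Peak]:
    """Read a peak list; ``fdr_dialect`` says whether the FDR column holds a
    fraction or a -log10 value (ENCODE narrowPeak convention)."""
    if format == "narrowpeak":
        try:
            df = pd.read_csv(path, sep="\t", header=None, names=_NARROWPEAK_COLUMNS, dtype=str)
        except pd.errors.EmptyDataError:
            return []
        peaks = []
        for i, row in enumerate(df.itertuples(index=False), start=1):
            try:
                start, end = int(row.chromStart), int(row.chromEnd)
                fold = float(row.signalValue)
                q = float(row.qValue)
            except (TypeError, ValueError) as exc:
                raise ParseError(path, i, f"malformed narrowPeak record: {exc}") from exc
            if start >= end:
                raise ParseError(path, i, f"start {start} >= end {end}")
            if fold < 0:
                raise ParseError(path, i, f"negative fold-enrichment {fold}")
            name = str(row.name)
            peak_id = name if name not in (".", "nan", "") else f"peak_{i:05d}"
            peaks.append(
                Peak(
                    peak_id=peak_id,
                    scaffold_id=str(row.chrom),
                    start=start,
                    end=end,
                    fdr=_fdr_from_dialect(q, fdr_dialect, path, i),
                    fold_enrichment=fold,
                )
            )
        return peaks
    if format == "tsv":
        try:
            df = pd.read_csv(path, sep="\t", dtype={"scaffold_id": str, "peak_id": str})
        except pd.errors.EmptyDataError:
            return []
        if df.empty:
            return []
        required = {"scaffold_id", "start", "end", "fdr", "fold_enrichment"}
        if not required <= set(df.columns):
            raise ParseError(path, 1, f"missing columns {sorted(required - set(df.columns))}")
        peaks = []
        for i, row in enumerate(df.itertuples(index=False), start=2):
            start, end = int(row.start), int(row.end)
            fold = float(row.fold_enrichment)
            if start >= end:
                raise ParseError(path, i, f"start {start} >= end {end}")
            if fold < 0:
                raise ParseError(path, i, f"negative fold-enrichment {fold}")
            peak_id = getattr(row, "peak_id", None) or f"peak_{i - 1:05d}"
            peaks.append(
                Peak(
                    peak_id=str(peak_id),
                    scaffold_id=str(row.scaffold_id),
                    start=start,
                    end=end,
                    fdr=_fdr_from_dialect(float(row.fdr), fdr_dialect, path, i),
                    fold_enrichment=fold,
                )
            )
        return peaks
    raise ValueError(f"unknown peak format {format!r}")


def write_peaks(peaks: Iterable[Peak], path, format: str, fdr_dialect: str = "fraction") -> None:
    peaks = sorted(peaks, key=lambda p: (p.scaffold_id, p.start, p.peak_id))
    if format == "narrowpeak":
        with open(path, "w") as fh:
            for p in peaks:
                if fdr_dialect == "fraction":
                    q = repr(p.fdr)
                elif fdr_dialect == "neglog10":
                    q = repr(-math.log10(p.fdr)) if p.fdr > 0 else "999.0"
                else:
                    raise ValueError(f"unknown FDR dialect {fdr_dialect!r}")
                fh.write(
                    f"{p.scaffold_id}\t{p.start}\t{p.end}\t{p.peak_id}\t0\t.\t"
                    f"{p.fold_enrichment!r}\t-1\t{q}\t-1\n"
                )
    elif format == "tsv":
        with open(path, "w") as fh:
            fh.write("peak_id\tscaffold_id\tstart\tend\tfdr\tfold_enrichment\n")
            for p in peaks:
                fh.write(
                    f"{p.peak_id}\t{p.scaffold_id}\t{p.start}\t{p.end}\t{p.fdr!r}\t{p.fold_enrichment!r}\n"
                )
    else:
        raise ValueError(f"unknown peak format {format!r}")


# ---------------------------------------------------------------------------
# counts


def read_counts(path, group: dict[str, str]) -> CountMatrix:
    df = pd.read_csv(path, sep="\t", index_col="gene_id")
    return CountMatrix(df, group)


def write_counts(counts: CountMatrix, path) -> None:
    df = counts.counts.sort_index()
    df.to_csv(path, sep="\t", index_label="gene_id")


# ---------------------------------------------------------------------------
# ortholog map


def read_ortholog_map(path) -> OrthologMap:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns) != ["frog_gene_id", "human_gene_id"]:
        raise ParseError(path, 1, f"expected columns frog_gene_id, human_gene_id; got {list(df.columns)}")
    if df["frog_gene_id"].duplicated().any():
        dup = df.loc[df["frog_gene_id"].duplicated(), "frog_gene_id"].iloc[0]
        raise ParseError(path, None, f"frog gene {dup!r} maps to more than one human gene")
    return OrthologMap(dict(zip(df["frog_gene_id"], df["human_gene_id"])))


def write_ortholog_map(orthologs: OrthologMap, path) -> None:
    with open(path, "w") as fh:
        fh.write("frog_gene_id\thuman_gene_id\n")
        for frog, human in sorted(orthologs.items()):
            fh.write(f"{frog}\t{human}\n")


# ---------------------------------------------------------------------------
# weighted network


def read_network(path) -> WeightedNetwork:
    try:
        df = pd.read_csv(path, sep="\t", dtype={"gene_a": str, "gene_b": str})
    except pd.errors.EmptyDataError:
        return WeightedNetwork()
    if list(df.columns) != ["gene_a", "gene_b", "weight"]:
        raise ParseError(path, 1, f"expected columns gene_a, gene_b, weight; got {list(df.columns)}")
    return WeightedNetwork(
        (row.gene_a, row.gene_b, float(row.weight)) for row in df.itertuples(index=False)
    )


def write_network(network: WeightedNetwork, path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_a\tgene_b\tweight\n")
        for a, b, w in network.edges():
            fh.write(f"{a}\t{b}\t{w!r}\n")


# ---------------------------------------------------------------------------
# GMT gene sets


def read_gene_sets(path) -> GeneSetCollection:
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(path, lineno, "GMT line needs name, description and >= 1 member")
            name, desc, members = fields[0], fields[1], fields[2:]
            if name in sets:
                raise ParseError(path, lineno, f"duplicate gene-set name {name!r}")
            if len(members) != len(set(members)):
                raise ParseError(path, lineno, f"duplicate members in set {name!r}")
            sets[name] = members
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gene_sets(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name in sorted(collection):
            members = "\t".join(sorted(collection[name]))
            fh.write(f"{name}\t{collection.description(name)}\t{members}\n")
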