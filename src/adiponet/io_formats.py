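"""Readers and writers for every on-disk artifact the pipeline touches.

All genomic intervals are 0-based half-open (BED convention); the annotation
TSS is a single 0-based coordinate.  Readers reject invalid records rather
than coercing them, and error messages name the offending record.  Writers
emit a stable row ordering so that ``write . read`` round-trips are
byte-identical on valid files.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_BIOTYPES = ("mRNA", "lncRNA")
VALID_STRANDS = ("+", "-")
META_COLUMNS = ("depot", "condition", "replicate")


class FormatError(ValueError):
    """A file violated the expected on-disk format."""


class ConsistencyError(ValueError):
    """Two related inputs disagree (e.g. expression columns vs. metadata)."""


# ---------------------------------------------------------------------------
# Expression matrices
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Nonnegative gene x sample abundance table (FPKM) plus sample metadata.

    ``values`` is a genes-by-samples DataFrame; ``meta`` is indexed by sample
    id with columns depot / condition / replicate.
    """

    values: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        v = self.values
        if v.index.duplicated().any():
            dups = v.index[v.index.duplicated()].unique().tolist()
            raise ConsistencyError(f"duplicate gene ids: {dups}")
        if v.columns.duplicated().any():
            dups = v.columns[v.columns.duplicated()].unique().tolist()
            raise ConsistencyError(f"duplicate sample ids: {dups}")
        arr = v.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise FormatError("expression matrix contains non-numeric cells")
        bad = ~np.isfinite(arr)
        if bad.any():
            g, s = np.argwhere(bad)[0]
            raise FormatError(
                f"non-finite expression at gene {v.index[g]!r}, sample {v.columns[s]!r}"
            )
        neg = arr < 0
        if neg.any():
            g, s = np.argwhere(neg)[0]
            raise FormatError(
                f"negative expression {arr[g, s]} at gene {v.index[g]!r}, "
                f"sample {v.columns[s]!r}"
            )
        missing = [c for c in META_COLUMNS if c not in self.meta.columns]
        if missing:
            raise FormatError(f"metadata missing columns: {missing}")
        if list(self.meta.index) != list(v.columns):
            only_meta = sorted(set(self.meta.index) - set(v.columns))
            only_expr = sorted(set(v.columns) - set(self.meta.index))
            raise ConsistencyError(
                "sample metadata does not match expression columns "
                f"(meta-only: {only_meta}, expression-only: {only_expr})"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def subset_genes(self, genes: Iterable[str]) -> "ExpressionMatrix":
        genes = [g for g in self.gene_ids if g in set(genes)]
        return ExpressionMatrix(self.values.loc[genes].copy(), self.meta.copy())

    def subset_samples(self, samples: Iterable[str]) -> "ExpressionMatrix":
        samples = list(samples)
        return ExpressionMatrix(
            self.values[samples].copy(), self.meta.loc[samples].copy()
        )


def read_expression(matrix_path, meta_path) -> ExpressionMatrix:
    """Read a dense TSV expression matrix plus its sample-metadata TSV."""
    raw = pd.read_csv(matrix_path, sep="\t", index_col=0, dtype=str)
    values = pd.DataFrame(index=raw.index.astype(str))
    for col in raw.columns:
        cells = raw[col].tolist()
        parsed = np.empty(len(cells))
        for i, cell in enumerate(cells):  # float() is correctly rounded
            try:
                parsed[i] = float(cell)
            except (TypeError, ValueError):
                raise FormatError(
                    f"non-numeric cell {cell!r} at gene {raw.index[i]!r}, "
                    f"sample {col!r}"
                ) from None
        if np.isnan(parsed).any():
            gene = raw.index[int(np.isnan(parsed).nonzero()[0][0])]
            raise FormatError(f"missing cell at gene {gene!r}, sample {col!r}")
        values[col] = parsed
    meta = pd.read_csv(meta_path, sep="\t", index_col=0, dtype=str)
    meta.index = meta.index.astype(str)
    if "replicate" in meta.columns:
        meta["replicate"] = meta["replicate"].astype(int)
    return ExpressionMatrix(values, meta)


def write_expression(em: ExpressionMatrix, matrix_path, meta_path) -> None:
    em.values.to_csv(matrix_path, sep="\t", index_label="gene_id")
    em.meta.to_csv(meta_path, sep="\t", index_label="sample_id")


# ---------------------------------------------------------------------------
# Gene annotation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneRecord:
    gene_id: str
    biotype: str
    chrom: str
    strand: str
    tss: int
    utr3: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.biotype not in VALID_BIOTYPES:
            raise FormatError(
                f"gene {self.gene_id!r}: unknown biotype {self.biotype!r}"
            )
        if self.strand not in VALID_STRANDS:
            raise FormatError(
                f"gene {self.gene_id!r}: unknown strand {self.strand!r}"
            )
        if self.tss < 0:
            raise FormatError(f"gene {self.gene_id!r}: negative TSS {self.tss}")
        if self.utr3 is not None and not self.utr3[0] < self.utr3[1]:
            raise FormatError(
                f"gene {self.gene_id!r}: 3'UTR end {self.utr3[1]} <= start "
                f"{self.utr3[0]}"
            )


ANNOTATION_COLUMNS = (
    "gene_id", "biotype", "chrom", "strand", "tss", "utr3_start", "utr3_end"
)


def read_annotation(path) -> dict[str, GeneRecord]:
    """Read a gene annotation from TSV or GTF-lite, keyed by gene id.

    The format is sniffed from the first line: a header starting with
    ``gene_id`` means TSV, otherwise GTF-lite (9 tab-separated columns with
    ``gene_id "x"; biotype "mRNA";`` attributes; ``gene`` rows define the
    record and optional ``three_prime_utr`` rows attach the UTR interval).
    """
    text = Path(path).read_text()
    first = text.splitlines()[0] if text.strip() else ""
    if first.startswith("gene_id"):
        return _read_annotation_tsv(text)
    return _read_annotation_gtf(text)


def _read_annotation_tsv(text: str) -> dict[str, GeneRecord]:
    df = pd.read_csv(io.StringIO(text), sep="\t", dtype=str)
    missing = [c for c in ANNOTATION_COLUMNS[:5] if c not in df.columns]
    if missing:
        raise FormatError(f"annotation missing columns: {missing}")
    records: dict[str, GeneRecord] = {}
    for _, row in df.iterrows():
        gid = str(row["gene_id"])
        if gid in records:
            raise FormatError(f"duplicate gene_id {gid!r} in annotation")
        utr3 = None
        us, ue = row.get("utr3_start"), row.get("utr3_end")
        if pd.notna(us) and str(us) != "":
            utr3 = (int(float(us)), int(float(ue)))
        records[gid] = GeneRecord(
            gene_id=gid,
            biotype=str(row["biotype"]),
            chrom=str(row["chrom"]),
            strand=str(row["strand"]),
            tss=int(float(row["tss"])),
            utr3=utr3,
        )
    return records


def _parse_gtf_attributes(attrs: str) -> dict[str, str]:
    out = {}
    for chunk in attrs.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        key, _, value = chunk.partition(" ")
        out[key] = value.strip().strip('"')
    return out


def _read_annotation_gtf(text: str) -> dict[str, GeneRecord]:
    genes: dict[str, dict] = {}
    for ln, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 9:
            raise FormatError(f"GTF-lite line {ln}: expected 9 columns")
        chrom, _src, feature, start, end, _score, strand, _frame, attrs = fields
        a = _parse_gtf_attributes(attrs)
        if "gene_id" not in a:
            raise FormatError(f"GTF-lite line {ln}: missing gene_id attribute")
        gid = a["gene_id"]
        start0, end0 = int(start) - 1, int(end)  # GTF is 1-based inclusive
        if feature == "gene":
            if gid in genes and "tss" in genes[gid]:
                raise FormatError(f"duplicate gene_id {gid!r} in annotation")
            tss = start0 if strand == "+" else end0 - 1
            genes.setdefault(gid, {})
            genes[gid].update(
                biotype=a.get("biotype", ""), chrom=chrom, strand=strand, tss=tss
            )
        elif feature == "three_prime_utr":
            genes.setdefault(gid, {})["utr3"] = (start0, end0)
    records: dict[str, GeneRecord] = {}
    for gid, g in genes.items():
        if "tss" not in g:
            raise FormatError(f"gene {gid!r}: three_prime_utr without gene row")
        records[gid] = GeneRecord(
            gene_id=gid,
            biotype=g["biotype"],
            chrom=g["chrom"],
            strand=g["strand"],
            tss=g["tss"],
            utr3=g.get("utr3"),
        )
    return records


def write_annotation(records: Mapping[str, GeneRecord], path) -> None:
    rows = []
    for gid, rec in records.items():
        utr = rec.utr3
        rows.append(
            {
                "gene_id": gid,
                "biotype": rec.biotype,
                "chrom": rec.chrom,
                "strand": rec.strand,
                "tss": rec.tss,
                "utr3_start": "" if utr is None else utr[0],
                "utr3_end": "" if utr is None else utr[1],
            }
        )
    pd.DataFrame(rows, columns=list(ANNOTATION_COLUMNS)).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# BED peaks
# ---------------------------------------------------------------------------

@dataclass
class PeakSet:
    """ChIP peaks as 0-based half-open intervals, sorted by (chrom, start)."""

    source: str
    records: list[tuple[str, int, int, float | None]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for chrom, start, end, _score in self.records:
            if start >= end:
                raise FormatError(
                    f"peak {chrom}:{start}-{end}: start >= end"
                )
        self.records = sorted(
            self.records, key=lambda r: (r[0], r[1], r[2])
        )

    def __len__(self) -> int:
        return len(self.records)


def read_bed(path, source: str | None = None) -> PeakSet:
    records = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split()
        if len(fields) < 3:
            raise FormatError(f"BED line {ln}: fewer than 3 columns")
        chrom, start, end = fields[0], int(fields[1]), int(fields[2])
        if start >= end:
            raise FormatError(f"BED line {ln}: start {start} >= end {end}")
        score = float(fields[4]) if len(fields) >= 5 else None
        records.append((chrom, start, end, score))
    return PeakSet(source=source or Path(path).stem, records=records)


def write_bed(peaks: PeakSet, path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, score in peaks.records:
            if score is None:
                fh.write(f"{chrom}\t{start}\t{end}\n")
            else:
                fh.write(f"{chrom}\t{start}\t{end}\t.\t{score:g}\n")


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------

@dataclass
class GeneSetCollection:
    sets: dict[str, tuple[str, ...]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if len(members) == 0:
                raise FormatError(f"gene set {name!r} is empty")

    def __iter__(self):
        return iter(self.sets.items())

    def __len__(self) -> int:
        return len(self.sets)


def read_gmt(path) -> GeneSetCollection:
    sets: dict[str, tuple[str, ...]] = {}
    descriptions: dict[str, str] = {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise FormatError(f"GMT line {ln}: needs name, description, >=1 gene")
        name, desc, genes = fields[0], fields[1], [g for g in fields[2:] if g]
        if name in sets:
            raise FormatError(f"GMT line {ln}: duplicate set name {name!r}")
        if not genes:
            raise FormatError(f"GMT line {ln}: set {name!r} is empty")
        sets[name] = tuple(genes)
        descriptions[name] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, members in collection.sets.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *members]) + "\n")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path, rna: bool = False) -> dict[str, str]:
    """Read FASTA into an id -> uppercased sequence map.

    With ``rna=True`` the DNA alphabet is normalized to RNA (T -> U) so that
    downstream UTR scans match the literal "UGU".
    """
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise FormatError(f"duplicate FASTA id {rec.id!r}")
        seq = str(rec.seq).upper()
        if rna:
            seq = seq.replace("T", "U")
        seqs[rec.id] = seq
    return seqs


def write_fasta(seqs: Mapping[str, str], path, width: int = 60) -> None:
    records = [
        SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# Network output
# ---------------------------------------------------------------------------

def write_network(graph, partition, path_edges, path_nodes,
                  path_graphml=None) -> None:
    """Write the edge and node tables for a finalized partial-correlation graph.

    Edge rows carry (gene_a, gene_b, pcor, fdr) with gene_a < gene_b
    lexicographically and rows sorted; node rows carry (gene, biotype,
    cluster).
    """
    import networkx as nx

    rows = []
    for u, v, data in graph.edges(data=True):
        a, b = sorted((u, v))
        if a == b:
            raise AssertionError(f"self-loop on {a!r} must be impossible upstream")
        rows.append((a, b, data["pcor"], data["fdr"]))
    rows.sort(key=lambda r: (r[0], r[1]))
    edges = pd.DataFrame(rows, columns=["gene_a", "gene_b", "pcor", "fdr"])
    edges.to_csv(path_edges, sep="\t", index=False)

    assignment = partition.assignment if partition is not None else {}
    node_rows = [
        (n, graph.nodes[n].get("biotype", ""), assignment.get(n, ""))
        for n in sorted(graph.nodes)
    ]
    nodes = pd.DataFrame(node_rows, columns=["gene", "biotype", "cluster"])
    nodes.to_csv(path_nodes, sep="\t", index=False)

    if path_graphml is not None:
        mirror = graph.copy()
        for n in mirror.nodes:
            if n in assignment:
                mirror.nodes[n]["cluster"] = int(assignment[n])
        nx.write_graphml(mirror, path_graphml)


def read_network_edges(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"gene_a": str, "gene_b": str})
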