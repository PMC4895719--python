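"""Shared domain types and readers/writers for the standard text formats.

Sequence I/O goes through Biopython; tabular formats through pandas.
Coordinates are 0-based half-open in memory and 1-based inclusive in GFF3.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


@dataclass
class GeneRecord:
    """One annotated gene: location, strand, CDS sequence, optional label."""

    id: str
    species: str
    chrom: str
    start: int  # 0-based
    end: int  # half-open
    strand: str = "+"
    seq: str = ""
    label: str | None = None
    scaffold: str | None = None
    exons: list[tuple[int, int]] = field(default_factory=list)  # genome coords

    def __post_init__(self) -> None:
        if self.scaffold is None:
            self.scaffold = self.chrom
        if self.strand not in "+-.":
            raise ValueError(f"bad strand {self.strand!r} for gene {self.id}")

    @property
    def length(self) -> int:
        return self.end - self.start


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# GFF3 (genes + exons, 1-based inclusive on disk)

def write_gff3(genes: Iterable[GeneRecord], path: str | Path) -> None:
    lines = ["##gff-version 3"]
    for g in genes:
        attrs = f"ID={g.id}"
        if g.label:
            attrs += f";Name={g.label}"
        attrs += f";scaffold={g.scaffold}"
        lines.append(
            "\t".join(
                [g.chrom, "subtracta", "gene", str(g.start + 1), str(g.end),
                 ".", g.strand, ".", attrs]
            )
        )
        for i, (es, ee) in enumerate(g.exons, start=1):
            lines.append(
                "\t".join(
                    [g.chrom, "subtracta", "exon", str(es + 1), str(ee),
                     ".", g.strand, ".", f"ID={g.id}.exon{i};Parent={g.id}"]
                )
            )
    Path(path).write_text("\n".join(lines) + "\n")


def _parse_attrs(s: str) -> dict[str, str]:
    out = {}
    for part in s.strip().split(";"):
        if "=" in part:
            k, v = part.split("=", 1)
            out[k] = v
    return out


def read_gff3(path: str | Path, species: str = "") -> list[GeneRecord]:
    genes: dict[str, GeneRecord] = {}
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        chrom, _src, ftype, start, end, _score, strand, _frame, attrs = line.split("\t")
        a = _parse_attrs(attrs)
        if ftype == "gene":
            g = GeneRecord(
                id=a["ID"], species=species, chrom=chrom,
                start=int(start) - 1, end=int(end), strand=strand,
                label=a.get("Name"), scaffold=a.get("scaffold", chrom),
            )
            genes[g.id] = g
        elif ftype == "exon":
            parent = a["Parent"]
            genes[parent].exons.append((int(start) - 1, int(end)))
    return list(genes.values())


# ---------------------------------------------------------------------------
# Tabular

def read_counts_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_tsv(df: pd.DataFrame, path: str | Path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index)


def load_gene_list(path: str | Path, column: str | int = 0) -> list[str]:
    """Load a one-gene-per-row list (TSV with optional header) for set algebra.

    Used to count and intersect externally deposited gene lists.
    """
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    col = df.columns[column] if isinstance(column, int) else column
    vals = [v for v in df[col].dropna().tolist()]
    # tolerate a header row of non-gene text
    return vals


def gene_list_cardinality(path: str | Path) -> int:
    return len(load_gene_list(path))


def intersect_gene_lists(a: Iterable[str], b: Iterable[str]) -> set[str]:
    fold = lambda xs: {str(x).strip().casefold() for x in xs}
    return fold(a) & fold(b)


# ---------------------------------------------------------------------------
# Minimal VCF-like SNP table (VCFv4.2 subset; also accepts plain TSV)

VCF_COLUMNS = ["chrom", "pos", "id", "ref", "alt", "qual", "filter", "info"]


def read_snp_table(path: str | Path) -> pd.DataFrame:
    """Read a minimal VCF (or headered TSV) into a SNP record frame.

    Returns columns: chrom, pos, ref, alt, base_quality, mapping_quality,
    maf, depth.  VCF INFO keys used: BQ, MQ, AF, DP.
    """
    text = Path(path).read_text().splitlines()
    body = [l for l in text if l and not l.startswith("##")]
    if body and body[0].startswith("#CHROM"):
        rows = []
        for i, line in enumerate(body[1:], start=2):
            f = line.split("\t")
            if len(f) < 8:
                raise ValueError(f"malformed VCF record at line {i}: {line!r}")
            info = dict(kv.split("=") for kv in f[7].split(";") if "=" in kv)
            try:
                rows.append(
                    dict(chrom=f[0], pos=int(f[1]), ref=f[3], alt=f[4],
                         base_quality=float(info["BQ"]),
                         mapping_quality=float(info["MQ"]),
                         maf=float(info["AF"]), depth=int(info["DP"]))
                )
            except (KeyError, ValueError) as exc:
                raise ValueError(f"malformed VCF record at line {i}: {exc}") from exc
        return pd.DataFrame(rows)
    df = pd.read_csv(path, sep="\t")
    df.columns = [c.lower() for c in df.columns]
    return df


def write_snp_vcf(df: pd.DataFrame, path: str | Path) -> None:
    lines = ["##fileformat=VCFv4.2",
             "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO"]
    for r in df.itertuples(index=False):
        info = (f"BQ={r.base_quality:g};MQ={r.mapping_quality:g};"
                f"AF={r.maf:g};DP={int(r.depth)}")
        lines.append(f"{r.chrom}\t{int(r.pos)}\t.\t{r.ref}\t{r.alt}\t.\tPASS\t{info}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# JSON helpers for dataclass payloads

class _SetEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, (set, frozenset)):
            return sorted(o)
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return dataclasses.asdict(o)
        return super().default(o)


def dump_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True, cls=_SetEncoder))


def load_json(path: str | Path):
    return json.loads(Path(path).read_text())
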