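"""Readers/writers for the plain-text formats the pipeline exchanges.

Conventions: FASTA via Biopython; GFF3 coordinates are 1-based inclusive on
disk and 0-based half-open in memory; tables are tab-separated with a header
row; ground truth travels as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


def read_fasta(path) -> Dict[str, str]:
    """Read a FASTA file into an ordered ``{id: sequence}`` dict."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: Dict[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_tsv(df: pd.DataFrame, path, header_comment: str | None = None) -> None:
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, sep="\t", index=False)


GFF_COLUMNS = [
    "seqid", "source", "type", "start", "end", "score", "strand", "phase", "attributes",
]


def write_gff3_orfs(orfs: pd.DataFrame, path) -> None:
    """Write an ORF table as GFF3.

    Expects columns ``orf_id, contig_id, contig_start, contig_end`` (0-based
    half-open) plus optional annotation columns (``genome, kind, marker_id,
    heme_count``) that are carried in the attribute string.
    """
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for row in orfs.itertuples(index=False):
            attrs = [f"ID={row.orf_id}"]
            for key in ("genome", "kind", "marker_id", "heme_count"):
                val = getattr(row, key, None)
                if val is not None and not (isinstance(val, float) and pd.isna(val)):
                    attrs.append(f"{key}={val}")
            fields = [
                row.contig_id, "simcom", "CDS",
                str(int(row.contig_start) + 1), str(int(row.contig_end)),
                ".", "+", "0", ";".join(attrs),
            ]
            fh.write("\t".join(fields) + "\n")


def read_gff3_orfs(path) -> pd.DataFrame:
    """Read ORFs from GFF3 into a 0-based half-open table."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            attrs = dict(kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv)
            rows.append(
                {
                    "orf_id": attrs.get("ID"),
                    "contig_id": parts[0],
                    "contig_start": int(parts[3]) - 1,
                    "contig_end": int(parts[4]),
                    "genome": attrs.get("genome"),
                    "kind": attrs.get("kind", "generic"),
                    "marker_id": attrs.get("marker_id"),
                    "heme_count": int(attrs["heme_count"]) if "heme_count" in attrs else 0,
                }
            )
    return pd.DataFrame(rows)


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True)


def read_json(path):
    with open(path) as fh:
        return json.load(fh)


class Fixture:
    """Lazy view over an emitted simulated-community directory."""

    def __init__(self, path):
        self.path = Path(path)

    @property
    def contigs(self) -> Dict[str, str]:
        return read_fasta(self.path / "contigs.fasta")

    @property
    def proteins(self) -> Dict[str, str]:
        return read_fasta(self.path / "proteins.faa")

    @property
    def orfs(self) -> pd.DataFrame:
        return read_gff3_orfs(self.path / "orfs.gff3")

    @property
    def dna_counts(self) -> pd.DataFrame:
        return read_tsv(self.path / "dna_counts.tsv")

    @property
    def mrna_counts(self) -> pd.DataFrame:
        return read_tsv(self.path / "mrna_counts.tsv")

    @property
    def contig_dna_counts(self) -> pd.DataFrame:
        return read_tsv(self.path / "contig_dna_counts.tsv")

    @property
    def linkage(self) -> pd.DataFrame:
        return read_tsv(self.path / "linkage.tsv")

    @property
    def marker_hits(self) -> pd.DataFrame:
        return read_tsv(self.path / "marker_hits.tsv")

    @property
    def design(self) -> pd.DataFrame:
        return read_tsv(self.path / "design.tsv")

    @property
    def comparisons(self) -> pd.DataFrame:
        return read_tsv(self.path / "comparisons.tsv")

    @property
    def truth(self) -> dict:
        return read_json(self.path / "truth.json")
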