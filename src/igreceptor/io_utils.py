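"""Plain-text readers/writers: FASTA, FASTQ, GFF3, TSV, JSON.

All writers are byte-stable (fixed ordering, fixed float formats) so that
identical runs produce identical files; reading of FASTA/FASTQ goes
through Biopython.  Coordinates are 0-based half-open in memory and
1-based inclusive in GFF3 on disk.
"""

from __future__ import annotations

import json
from pathlib import Path

from Bio import SeqIO


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def read_fastq(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fastq")}


def write_fasta(records: dict[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rid, seq in records.items():
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_fastq(reads: list[tuple[str, str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rid, seq, qual in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")


def write_gff3(features: list[tuple], path: str | Path, source: str = "igreceptor") -> None:
    """Write (seqid, type, start0, end0, strand, attrs) tuples as GFF3."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for seqid, ftype, start, end, strand, attrs in features:
            attr_s = ";".join(f"{k}={v}" for k, v in attrs.items())
            fh.write(
                f"{seqid}\t{source}\t{ftype}\t{start + 1}\t{end}\t.\t{strand}\t.\t{attr_s}\n"
            )


def read_gff3(path: str | Path) -> list[tuple]:
    """Read GFF3 lines back to (seqid, type, start0, end0, strand, attrs)."""
    out = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            attrs = dict(kv.split("=", 1) for kv in f[8].split(";") if kv)
            out.append((f[0], f[2], int(f[3]) - 1, int(f[4]), f[6], attrs))
    return out


def write_tsv(rows: list[dict], path: str | Path, columns: list[str]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(columns) + "\n")
        for row in rows:
            fh.write("\t".join(_fmt(row.get(c, "")) for c in columns) + "\n")


def _fmt(v) -> str:
    if isinstance(v, float):
        return f"{v:.4f}"
    if isinstance(v, bool):
        return str(v).lower()
    return str(v)


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
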