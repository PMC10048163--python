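"""Readers and writers: FASTA, BED6, TSV reports, coordinate labels.

Coordinates are BED-convention 0-based half-open everywhere inside the
package; 1-based "chr:start-end" genome-browser labels are converted at
this boundary only.
"""

from __future__ import annotations

import re
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .detect import G4Region

__all__ = [
    "read_fasta",
    "write_fasta",
    "write_bed",
    "read_bed",
    "parse_coordinate_label",
    "format_coordinate_label",
    "write_match_tsv",
    "write_classification_tsv",
]


def read_fasta(path: str | Path) -> dict[str, str]:
    """FASTA records as an ordered id -> uppercase sequence mapping.

    Gapped (aligned) FASTA is preserved verbatim apart from case.
    """
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ValueError(f"duplicate FASTA id {rec.id!r}")
        records[rec.id] = str(rec.seq).upper()
    return records


def write_fasta(records: dict[str, str], path: str | Path, wrap: int = 60) -> None:
    recs = [
        SeqRecord(Seq(seq), id=sid, description="") for sid, seq in records.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=wrap)
        writer.write_file(recs)


def write_bed(regions: list[G4Region], path: str | Path) -> None:
    """BED6: chrom, start, end, region id, score = tract count, strand."""
    rows = sorted(regions, key=lambda r: (r.contig, r.start, r.end, r.strand))
    with open(path, "w") as fh:
        for r in rows:
            fh.write(
                f"{r.contig}\t{r.start}\t{r.end}\t{r.region_id}\t"
                f"{r.n_tracts}\t{r.strand}\n"
            )


def read_bed(path: str | Path) -> list[tuple[str, int, int, str, int, str]]:
    out = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{ln}: BED line needs >= 3 fields")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if end < start:
                raise ValueError(f"{path}:{ln}: inverted interval {start}-{end}")
            name = parts[3] if len(parts) > 3 else "."
            score = int(parts[4]) if len(parts) > 4 else 0
            strand = parts[5] if len(parts) > 5 else "."
            out.append((chrom, start, end, name, score, strand))
    return out


_LABEL_RE = re.compile(r"^([^:]+):([\d,]+)-([\d,]+)$")


def parse_coordinate_label(label: str) -> tuple[str, int, int]:
    """1-based inclusive "chr:start-end" -> (chrom, 0-based start, end)."""
    m = _LABEL_RE.match(label.strip())
    if not m:
        raise ValueError(f"cannot parse coordinate label {label!r}")
    chrom = m.group(1)
    start1 = int(m.group(2).replace(",", ""))
    end1 = int(m.group(3).replace(",", ""))
    if start1 < 1 or end1 < start1:
        raise ValueError(f"invalid 1-based interval in {label!r}")
    return chrom, start1 - 1, end1


def format_coordinate_label(chrom: str, start: int, end: int) -> str:
    """0-based half-open -> 1-based inclusive browser label."""
    return f"{chrom}:{start + 1}-{end}"


def write_match_tsv(rows: list[dict], path: str | Path) -> None:
    """Detection matches: one row per 4-tract placement."""
    cols = ["contig", "region_start", "region_end", "strand", "match_start",
            "match_end", "tract_indices", "loops", "sequence"]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for row in rows:
            fh.write("\t".join(str(row.get(c, "")) for c in cols) + "\n")


def write_classification_tsv(results: list, path: str | Path) -> None:
    """Classification report with the family-assignment columns
    (location, sequence, log odds, Akaike weight, strand, gene id, family)."""
    cols = ["location", "sequence", "log_odds", "akaike_weight", "strand",
            "gene_id", "family"]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for r in results:
            fh.write("\t".join(str(r.get(c, "")) for c in cols) + "\n")
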