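"""Readers and writers for the plain-text formats the pipeline exchanges:
FASTA, FASTQ, GFF3 (1-based inclusive on disk, 0-based half-open in
memory), BED, and the tag/truth/count TSV tables."""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .aligner import AlignmentHit
from .blocks import Block
from .synthgen import Feature, TruthLocus, TruthTable


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fastq(reads: list[str], path: str | Path, prefix: str = "read") -> None:
    with open(path, "w") as fh:
        for i, seq in enumerate(reads):
            fh.write(f"@{prefix}_{i}\n{seq}\n+\n{'I' * len(seq)}\n")


def read_fastq(path: str | Path) -> list[str]:
    return [str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fastq")]


def write_gff3(features: list[Feature], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            fh.write(
                f"{f.chrom}\tsrnablocks\t{f.ftype}\t{f.start + 1}\t{f.end}\t.\t"
                f"{f.strand}\t.\tID={f.feature_id}\n"
            )


def read_gff3(path: str | Path) -> list[Feature]:
    features = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            chrom, _src, ftype, start, end, _score, strand, _frame, attrs = (
                line.rstrip("\n").split("\t")
            )
            fid = ""
            for item in attrs.split(";"):
                if item.startswith("ID="):
                    fid = item[3:]
            features.append(Feature(chrom, int(start) - 1, int(end), strand, ftype, fid))
    return features


def write_tags(tag_abundance: dict[str, dict[str, int]], path: str | Path) -> None:
    rows = []
    for lib in sorted(tag_abundance):
        for seq in sorted(tag_abundance[lib]):
            rows.append(
                {"sequence": seq, "length": len(seq),
                 "abundance": tag_abundance[lib][seq], "library_id": lib}
            )
    pd.DataFrame(rows, columns=["sequence", "length", "abundance", "library_id"]).to_csv(
        path, sep="\t", index=False
    )


def read_tags(path: str | Path) -> dict[str, dict[str, int]]:
    df = pd.read_csv(path, sep="\t")
    out: dict[str, dict[str, int]] = {}
    for row in df.itertuples():
        out.setdefault(row.library_id, {})[row.sequence] = int(row.abundance)
    return out


def write_hits(hits: dict[str, list[AlignmentHit]], path: str | Path) -> None:
    """BED6-compatible TSV with a mismatch column."""
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tname\tscore\tstrand\tmismatches\n")
        for seq in sorted(hits):
            for h in hits[seq]:
                fh.write(
                    f"{h.chrom}\t{h.start}\t{h.end}\t{h.tag_sequence}\t0\t"
                    f"{h.strand}\t{h.mismatches}\n"
                )


def read_hits(path: str | Path) -> dict[str, list[AlignmentHit]]:
    out: dict[str, list[AlignmentHit]] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            chrom, start, end, name, _score, strand, mm = line.rstrip("\n").split("\t")
            out.setdefault(name, []).append(
                AlignmentHit(name, chrom, int(start), int(end), strand, int(mm))
            )
    return out


def write_blocks_bed(blocks: list[Block], path: str | Path) -> None:
    with open(path, "w") as fh:
        for b in blocks:
            fh.write(f"{b.chrom}\t{b.start}\t{b.end}\t{b.block_id}\n")


def read_blocks_bed(path: str | Path) -> list[Block]:
    out = []
    with open(path) as fh:
        for line in fh:
            chrom, start, end, bid = line.rstrip("\n").split("\t")
            out.append(Block(bid, chrom, int(start), int(end)))
    return out


_TRUTH_FIXED = ["locus_id", "class", "chrom", "start", "end", "strand",
                "mature", "base_weight"]


def write_truth(truth: TruthTable, path: str | Path) -> None:
    libs = sorted({lib for l in truth.loci for lib in l.expected})
    cols = _TRUTH_FIXED + [f"expected_{lib}" for lib in libs] + ["folds"]
    rows = []
    for l in truth.loci:
        row = {
            "locus_id": l.locus_id, "class": l.locus_class, "chrom": l.chrom,
            "start": l.start, "end": l.end, "strand": l.strand,
            "mature": l.mature or ".", "base_weight": repr(l.base_weight),
            "folds": json.dumps(l.folds, sort_keys=True),
        }
        for lib in libs:
            row[f"expected_{lib}"] = repr(l.expected.get(lib, 0.0))
        rows.append(row)
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def read_truth(path: str | Path) -> TruthTable:
    df = pd.read_csv(path, sep="\t", dtype=str)
    lib_cols = [c for c in df.columns if c.startswith("expected_")]
    loci = []
    for row in df.itertuples():
        locus = TruthLocus(
            locus_id=row.locus_id, locus_class=getattr(row, "_2"),
            chrom=row.chrom, start=int(row.start), end=int(row.end),
            strand=row.strand,
            mature=None if row.mature == "." else row.mature,
            base_weight=float(row.base_weight),
            folds=json.loads(row.folds),
        )
        for col in lib_cols:
            locus.expected[col[len("expected_"):]] = float(getattr(row, col))
        loci.append(locus)
    return TruthTable(loci=loci)
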