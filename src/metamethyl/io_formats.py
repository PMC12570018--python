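"""Readers and writers for every external format the pipeline touches.

All coordinates are 0-based half-open internally, regardless of the source
dialect; conversion happens only here, at the parsers and writers.  Reports
are TSV with a header line, UTF-8, LF line endings.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

#: bedMethyl modified-base codes -> modification type.
MOD_CODE_MAP = {"m": "5mC", "a": "6mA", "21839": "4mC"}
MOD_TYPE_CODE = {v: k for k, v in MOD_CODE_MAP.items()}

RECORD_COLUMNS = [
    "sample", "contig", "pos", "strand", "mod_type",
    "valid_cov", "n_mod", "fraction",
]


@dataclass(frozen=True)
class MethylRecord:
    """One strand-specific per-site modified-base pileup row."""

    contig: str
    pos: int          # 0-based reference position of the modified base
    strand: str       # '+' or '-'
    mod_type: str     # 5mC / 6mA / 4mC
    valid_cov: int
    n_mod: int

    @property
    def fraction(self) -> float:
        """Modified fraction n_mod / valid_cov; NaN at zero coverage."""
        if self.valid_cov == 0:
            return float("nan")
        return self.n_mod / self.valid_cov


@dataclass(frozen=True)
class GeneRecord:
    """A gene/CDS interval, 0-based half-open, strand required."""

    contig: str
    start: int
    end: int
    strand: str
    gene_id: str
    annotation: str = ""

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(
                f"gene {self.gene_id}: start {self.start} >= end {self.end}")
        if self.strand not in "+-":
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")


RM_SYSTEM_TYPES = ("I", "II", "III", "IV")
RM_ROLES = ("MTase", "REase", "S", "combined")


@dataclass(frozen=True)
class RMGene:
    """A restriction-modification gene from the upstream homology table."""

    contig: str
    gene_id: str
    system_type: str
    role: str
    recognition_motif: str | None = None
    methylated_offset: int | None = None
    homolog_identity: float | None = None
    start: int | None = None
    end: int | None = None
    genome: str | None = None   # MAG/bin id when known

    def __post_init__(self):
        if self.system_type not in RM_SYSTEM_TYPES:
            raise ValueError(f"unknown RM system type {self.system_type!r}")
        if self.role not in RM_ROLES:
            raise ValueError(f"unknown RM role {self.role!r}")
        # Type IV systems cleave modified DNA and carry no methylase.
        if self.system_type == "IV" and self.role in ("MTase", "combined"):
            raise ValueError(
                f"gene {self.gene_id}: Type IV systems lack methylase activity")


@dataclass(frozen=True)
class Region:
    """A labelled half-open interval on a contig (e.g. prophage vs host)."""

    contig: str
    start: int
    end: int
    label: str

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(
                f"region {self.label}@{self.contig}: start >= end")

    def __len__(self) -> int:
        return self.end - self.start


class BedMethylParseError(ValueError):
    pass


def _parse_bedmethyl_line(line: str, lineno: int) -> MethylRecord | None:
    fields = line.rstrip("\n").split("\t")
    # Two accepted dialects, detected by column count: the full 18-column
    # pileup layout (BED9 + 9 count columns: valid_cov at col 10, n_mod at
    # col 12) and a minimal 11-column layout (BED9 + valid_cov + n_mod).
    if len(fields) >= 18:
        cov_idx, mod_idx = 9, 11
    elif len(fields) == 11:
        cov_idx, mod_idx = 9, 10
    else:
        raise BedMethylParseError(
            f"line {lineno}: expected 11 or >=18 tab-separated columns, "
            f"got {len(fields)}")
    contig, start, code, strand = fields[0], fields[1], fields[3], fields[5]
    try:
        pos = int(start)
        valid_cov = int(fields[cov_idx])
        n_mod = int(fields[mod_idx])
    except ValueError as exc:
        raise BedMethylParseError(f"line {lineno}: non-integer field: {exc}")
    if strand not in "+-":
        raise BedMethylParseError(f"line {lineno}: bad strand {strand!r}")
    if valid_cov < 0 or n_mod < 0 or n_mod > valid_cov:
        raise BedMethylParseError(
            f"line {lineno}: invalid counts n_mod={n_mod} "
            f"valid_cov={valid_cov}")
    if code not in MOD_CODE_MAP:
        return None  # unknown modified-base code: skipped, counted by caller
    return MethylRecord(contig, pos, strand, MOD_CODE_MAP[code],
                        valid_cov, n_mod)


def read_bedmethyl(path: str | Path, sample_id: str = "") -> Iterator[MethylRecord]:
    """Stream MethylRecords from a bedMethyl pileup file.

    Rows with an unknown modified-base code are skipped; the skip count is
    logged once at the end.  Malformed rows raise BedMethylParseError naming
    the line number.
    """
    skipped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("track", "#")):
                continue
            rec = _parse_bedmethyl_line(line, lineno)
            if rec is None:
                skipped += 1
                continue
            yield rec
    if skipped:
        logger.warning("%s: skipped %d rows with unknown modified-base codes",
                       sample_id or path, skipped)


def load_bedmethyl(path: str | Path, sample_id: str) -> pd.DataFrame:
    """Read a bedMethyl file into the standard records DataFrame."""
    rows = [(sample_id, r.contig, r.pos, r.strand, r.mod_type,
             r.valid_cov, r.n_mod) for r in read_bedmethyl(path, sample_id)]
    df = pd.DataFrame(rows, columns=RECORD_COLUMNS[:-1])
    df["fraction"] = df["n_mod"] / df["valid_cov"].where(df["valid_cov"] > 0)
    return df


def load_samples(paths_by_sample: dict[str, str | Path]) -> pd.DataFrame:
    """Load several samples' bedMethyl files into one records DataFrame."""
    frames = [load_bedmethyl(p, s) for s, p in paths_by_sample.items()]
    if not frames:
        return pd.DataFrame(columns=RECORD_COLUMNS)
    return pd.concat(frames, ignore_index=True)


def read_fasta(path: str | Path) -> dict[str, str]:
    """Contig id -> uppercase sequence; ids are the first whitespace token."""
    contigs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in contigs:
            raise ValueError(f"duplicate contig id {rec.id!r} in {path}")
        seq = str(rec.seq).upper()
        for off, ch in enumerate(seq):
            if ch not in "ACGTN":
                raise ValueError(
                    f"contig {rec.id!r}: non-nucleotide character {ch!r} "
                    f"at offset {off}")
        contigs[rec.id] = seq
    return contigs


def write_fasta(contigs: dict[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w", newline="\n") as fh:
        for cid, seq in contigs.items():
            fh.write(f">{cid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_gff(path: str | Path,
             feature_types: tuple[str, ...] = ("CDS", "gene")) -> list[GeneRecord]:
    """GFF3 genes/CDS as GeneRecords (1-based inclusive -> 0-based half-open)."""
    from gffutils.iterators import DataIterator

    genes: list[GeneRecord] = []
    for feat in DataIterator(str(path)):
        if feat.featuretype not in feature_types:
            continue
        if feat.start > feat.end:
            raise ValueError(
                f"{path}: feature with start {feat.start} > end {feat.end}")
        gene_id = (feat.attributes.get("ID") or
                   feat.attributes.get("gene_id") or
                   [f"{feat.seqid}:{feat.start}-{feat.end}"])[0]
        ann = (feat.attributes.get("product") or
               feat.attributes.get("Name") or [""])[0]
        genes.append(GeneRecord(feat.seqid, feat.start - 1, feat.end,
                                feat.strand, gene_id, ann))
    return genes


def write_gff(genes: list[GeneRecord], path: str | Path,
              feature_type: str = "CDS") -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = f"ID={g.gene_id}"
            if g.annotation:
                attrs += f";product={g.annotation}"
            fh.write("\t".join([
                g.contig, "metamethyl", feature_type,
                str(g.start + 1), str(g.end), ".", g.strand, ".", attrs,
            ]) + "\n")


_RM_COLUMNS = ["contig", "gene_id", "system_type", "role", "recognition_motif",
               "methylated_offset", "homolog_identity"]


def read_rm_table(path: str | Path) -> list[RMGene]:
    """Restriction-modification gene table (TSV with header).

    Required columns: contig, gene_id, system_type, role; optional:
    recognition_motif, methylated_offset, homolog_identity, start, end,
    genome.  Empty cells, '.', 'NA' and 'None' mean unknown.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = [c for c in _RM_COLUMNS[:4] if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing RM table column(s) {missing}")

    def opt(val, cast):
        val = str(val).strip()
        if val in ("", ".", "NA", "None", "nan"):
            return None
        return cast(val)

    genes = []
    for _, row in df.iterrows():
        genes.append(RMGene(
            contig=row["contig"],
            gene_id=row["gene_id"],
            system_type=row["system_type"].strip(),
            role=row["role"].strip(),
            recognition_motif=opt(row.get("recognition_motif", ""), str),
            methylated_offset=opt(row.get("methylated_offset", ""), int),
            homolog_identity=opt(row.get("homolog_identity", ""), float),
            start=opt(row.get("start", ""), int),
            end=opt(row.get("end", ""), int),
            genome=opt(row.get("genome", ""), str),
        ))
    return genes


def write_rm_table(genes: list[RMGene], path: str | Path) -> None:
    rows = [{
        "contig": g.contig, "gene_id": g.gene_id,
        "system_type": g.system_type, "role": g.role,
        "recognition_motif": g.recognition_motif if g.recognition_motif else ".",
        "methylated_offset": g.methylated_offset
        if g.methylated_offset is not None else ".",
        "homolog_identity": g.homolog_identity
        if g.homolog_identity is not None else ".",
        "start": g.start if g.start is not None else ".",
        "end": g.end if g.end is not None else ".",
        "genome": g.genome if g.genome else ".",
    } for g in genes]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_regions(path: str | Path) -> list[Region]:
    """BED (0-based half-open) with the label in column 4."""
    regions: list[Region] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("track", "#")):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 4:
                raise ValueError(
                    f"{path} line {lineno}: BED needs >=4 columns")
            regions.append(Region(fields[0], int(fields[1]), int(fields[2]),
                                  fields[3]))
    _check_region_overlaps(regions)
    return regions


def _check_region_overlaps(regions: list[Region]) -> None:
    by_key: dict[tuple[str, str], list[Region]] = {}
    for r in regions:
        by_key.setdefault((r.contig, r.label), []).append(r)
    for (contig, label), group in by_key.items():
        group = sorted(group, key=lambda r: r.start)
        for a, b in zip(group, group[1:]):
            if b.start < a.end:
                raise ValueError(
                    f"overlapping {label!r} regions on {contig}: "
                    f"[{a.start},{a.end}) and [{b.start},{b.end})")


def write_regions(regions: list[Region], path: str | Path) -> None:
    with open(path, "w", newline="\n") as fh:
        for r in regions:
            fh.write(f"{r.contig}\t{r.start}\t{r.end}\t{r.label}\n")


def write_report(table: pd.DataFrame, path: str | Path) -> None:
    """Write a report table as TSV with a header and stable column order."""
    table.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_report(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
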