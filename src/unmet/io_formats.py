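"""Readers and writers for the genomic formats the pipeline touches.

One coordinate convention is used everywhere inside the package: 0-based,
half-open intervals and 0-based positions. The only conversions happen at
the VCF boundary (VCF is 1-based), applied exactly once on read and once
on write.

Formats handled: FASTA (reference genome), VCF v4.x with a FILTER column
(variant catalog), BED3/BED4 (interval annotations), bedGraph (per-base
tracks), and a GFF3 convenience reader that extracts CDS lines.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("unmet")

# Nucleotide byte codes used by every per-base computation: A C G T N -> 0..4.
_ALPHABET = "ACGTN"
_CODE_OF = {b: i for i, b in enumerate(_ALPHABET)}
N_CODE = 4
_ENCODE_TABLE = np.full(256, N_CODE, dtype=np.uint8)
for _b, _i in _CODE_OF.items():
    _ENCODE_TABLE[ord(_b)] = _i
_COMPLEMENT = np.array([3, 2, 1, 0, 4], dtype=np.uint8)  # A<->T, C<->G, N->N

_NON_ACGTN = re.compile(r"[^ACGTN]")


def encode_sequence(seq: str) -> np.ndarray:
    """Encode an uppercase nucleotide string as uint8 codes (A=0..T=3, N=4)."""
    return _ENCODE_TABLE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def reverse_complement_codes(codes: np.ndarray) -> np.ndarray:
    return _COMPLEMENT[codes[::-1]]


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


# ---------------------------------------------------------------------------
# Genome sequence
# ---------------------------------------------------------------------------


@dataclass
class GenomeSequence:
    """Reference genome: chromosome name -> uppercase string over {A,C,G,T,N}."""

    sequences: dict[str, str]
    _codes: dict[str, np.ndarray] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        for name, seq in self.sequences.items():
            if _NON_ACGTN.search(seq):
                raise ValueError(f"chromosome {name!r} contains symbols outside ACGTN")

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.sequences.items()}

    @property
    def chromosomes(self) -> list[str]:
        return list(self.sequences)

    def codes(self, chrom: str) -> np.ndarray:
        """Cached uint8 encoding of one chromosome."""
        if chrom not in self._codes:
            self._codes[chrom] = encode_sequence(self.sequences[chrom])
        return self._codes[chrom]

    def reverse_complemented(self) -> "GenomeSequence":
        return GenomeSequence(
            {name: reverse_complement(seq) for name, seq in self.sequences.items()}
        )


def read_fasta(path: str | Path) -> GenomeSequence:
    """Read a FASTA file into a :class:`GenomeSequence`.

    Sequences are uppercased; IUPAC ambiguity codes and any other
    non-ACGTN symbols are mapped to ``N`` with a logged warning.
    """
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            if not line.startswith(">"):
                raise ValueError(
                    f"{path}: line {lineno}: expected FASTA header '>', got {line[:20]!r}"
                )
            break
        else:
            raise ValueError(f"{path}: empty FASTA file (no records)")

    sequences: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in sequences:
            raise ValueError(f"{path}: duplicate chromosome name {rec.id!r}")
        seq = str(rec.seq).upper()
        n_bad = len(_NON_ACGTN.findall(seq))
        if n_bad:
            logger.warning(
                "%s: chromosome %s: %d non-ACGTN symbols mapped to N", path, rec.id, n_bad
            )
            seq = _NON_ACGTN.sub("N", seq)
        sequences[rec.id] = seq
    if not sequences:
        raise ValueError(f"{path}: empty FASTA file (no records)")
    return GenomeSequence(sequences)


def write_fasta(genome: GenomeSequence, path: str | Path, width: int = 60) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.sequences.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# Interval sets (BED)
# ---------------------------------------------------------------------------

_BED_COLUMNS = ["chrom", "start", "end", "name"]


@dataclass(frozen=True)
class Interval:
    chrom: str
    start: int
    end: int
    name: str = ""


class IntervalSet:
    """Sorted set of 0-based half-open genomic intervals with optional labels."""

    def __init__(self, df: pd.DataFrame):
        df = df.copy()
        if "name" not in df.columns:
            df["name"] = ""
        df = df[_BED_COLUMNS]
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        df["name"] = df["name"].fillna("").astype(str)
        if (df["start"] >= df["end"]).any():
            bad = df[df["start"] >= df["end"]].iloc[0]
            raise ValueError(
                f"interval start must be < end: {bad.chrom}:{bad.start}-{bad.end}"
            )
        if (df["start"] < 0).any():
            raise ValueError("negative interval coordinates")
        df = df.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)
        self.df = df

    @classmethod
    def from_records(cls, records: Iterable[tuple]) -> "IntervalSet":
        rows = []
        for rec in records:
            if len(rec) == 3:
                chrom, start, end = rec
                name = ""
            else:
                chrom, start, end, name = rec[:4]
            rows.append((str(chrom), int(start), int(end), str(name)))
        return cls(pd.DataFrame(rows, columns=_BED_COLUMNS))

    @classmethod
    def empty(cls) -> "IntervalSet":
        return cls(pd.DataFrame(columns=_BED_COLUMNS))

    def __len__(self) -> int:
        return len(self.df)

    def __iter__(self) -> Iterator[Interval]:
        for row in self.df.itertuples(index=False):
            yield Interval(row.chrom, int(row.start), int(row.end), row.name)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        return self.df.equals(other.df)

    def subset(self, name: str) -> "IntervalSet":
        return IntervalSet(self.df[self.df["name"] == name])

    def merged(self, by_name: bool = False) -> "IntervalSet":
        """Union of overlapping/adjacent intervals (within a label if by_name)."""
        if len(self.df) == 0:
            return IntervalSet.empty()
        keys = ["name", "chrom"] if by_name else ["chrom"]
        out = []
        for key, grp in self.df.groupby(keys, sort=True):
            if not isinstance(key, tuple):
                key = (key,)
            name = key[0] if by_name else ""
            chrom = key[-1]
            cur_s = cur_e = None
            for s, e in zip(grp["start"], grp["end"]):
                if cur_s is None:
                    cur_s, cur_e = s, e
                elif s <= cur_e:
                    cur_e = max(cur_e, e)
                else:
                    out.append((chrom, cur_s, cur_e, name))
                    cur_s, cur_e = s, e
            out.append((chrom, cur_s, cur_e, name))
        return IntervalSet.from_records(out)

    def extended(self, flank: int, lengths: Mapping[str, int] | None = None) -> "IntervalSet":
        """Extend every interval by ``flank`` on both sides, clipped at bounds."""
        df = self.df.copy()
        df["start"] = (df["start"] - flank).clip(lower=0)
        if lengths is not None:
            df["end"] = [
                min(e + flank, lengths[c]) for c, e in zip(df["chrom"], df["end"])
            ]
        else:
            df["end"] = df["end"] + flank
        return IntervalSet(df)

    def contains(self, chrom: str, positions: np.ndarray | Sequence[int]) -> np.ndarray:
        """Boolean membership of 0-based positions in the union of intervals."""
        positions = np.asarray(positions, dtype=np.int64)
        sub = self.merged().df
        sub = sub[sub["chrom"] == chrom]
        if len(sub) == 0:
            return np.zeros(positions.shape, dtype=bool)
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        idx = np.searchsorted(starts, positions, side="right") - 1
        ok = idx >= 0
        ok[ok] &= positions[ok] < ends[idx[ok]]
        return ok

    def total_length(self) -> int:
        m = self.merged().df
        return int((m["end"] - m["start"]).sum())

    def to_mask(
        self, lengths: Mapping[str, int], flank: int = 0
    ) -> dict[str, np.ndarray]:
        """Rasterize (optionally flank-extended) intervals onto per-base 0/1 arrays."""
        masks = {chrom: np.zeros(n, dtype=np.uint8) for chrom, n in lengths.items()}
        for iv in self:
            if iv.chrom not in masks:
                continue
            n = lengths[iv.chrom]
            s = max(0, iv.start - flank)
            e = min(n, iv.end + flank)
            if s < e:
                masks[iv.chrom][s:e] = 1
        return masks


def read_bed(path: str | Path) -> IntervalSet:
    """Read BED3/BED4 (0-based half-open); track/browser/comment lines skipped."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 3:
                raise ValueError(f"{path}: line {lineno}: fewer than 3 BED fields")
            name = fields[3] if len(fields) > 3 else ""
            rows.append((fields[0], int(fields[1]), int(fields[2]), name))
    return IntervalSet(pd.DataFrame(rows, columns=_BED_COLUMNS))


def write_bed(intervals: IntervalSet, path: str | Path) -> None:
    df = intervals.df
    cols = _BED_COLUMNS if (df["name"] != "").any() else _BED_COLUMNS[:3]
    df[cols].to_csv(path, sep="\t", header=False, index=False)


def read_gff_cds(path: str | Path) -> IntervalSet:
    """Convenience reader: extract CDS lines of a GFF3 file as an IntervalSet.

    GFF is 1-based closed; converted to 0-based half-open on read.
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) >= 5 and fields[2] == "CDS":
                rows.append((fields[0], int(fields[3]) - 1, int(fields[4]), "CDS"))
    return IntervalSet(pd.DataFrame(rows, columns=_BED_COLUMNS))


# ---------------------------------------------------------------------------
# Variant catalog (VCF)
# ---------------------------------------------------------------------------

PASSED = "passed"
FILTERED = "filtered"
SNV = "snv"
INDEL = "indel"


@dataclass(frozen=True)
class VariantSite:
    """One observed variant allele.

    ``pos`` is 0-based internally (1-based in VCF). ``status`` collapses the
    VCF FILTER column to a binary flag: PASS (or missing ".") -> passed, any
    named filter -> filtered.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    var_class: str
    status: str

    def __post_init__(self) -> None:
        is_snv = len(self.ref) == 1 and len(self.alt) == 1
        if (self.var_class == SNV) != is_snv:
            raise ValueError(
                f"variant class {self.var_class!r} inconsistent with alleles "
                f"{self.ref}>{self.alt}"
            )
        if self.var_class not in (SNV, INDEL):
            raise ValueError(f"unknown variant class {self.var_class!r}")
        if self.status not in (PASSED, FILTERED):
            raise ValueError(f"unknown filter status {self.status!r}")


def make_variant_site(chrom: str, pos: int, ref: str, alt: str, status: str) -> VariantSite:
    """Build a VariantSite, deriving the SNV/indel class from allele lengths."""
    var_class = SNV if len(ref) == 1 and len(alt) == 1 else INDEL
    return VariantSite(chrom, int(pos), ref, alt, var_class, status)


def read_vcf_sites(
    path: str | Path, region_set: IntervalSet | None = None
) -> list[VariantSite]:
    """Read a VCF into per-alt-allele :class:`VariantSite` records.

    Multi-allelic records are split into one site per alternate allele.
    FILTER "PASS" or "." maps to passed; any other value to filtered. VCF
    1-based positions are converted to internal 0-based exactly here.
    Symbolic alleles (``<...>``, ``*``) are skipped with a warning.
    """
    sites: list[VariantSite] = []
    n_symbolic = 0
    with pysam.VariantFile(str(path)) as vf:
        contig_lengths = {
            name: ctg.length for name, ctg in vf.header.contigs.items() if ctg.length
        }
        for rec in vf:
            keys = list(rec.filter.keys())
            status = PASSED if not keys or keys == ["PASS"] else FILTERED
            pos = rec.start  # pysam already exposes 0-based start
            length = contig_lengths.get(rec.chrom)
            if length is not None and pos >= length:
                raise ValueError(
                    f"{path}: variant at {rec.chrom}:{rec.pos} beyond contig length {length}"
                )
            if region_set is not None and not bool(region_set.contains(rec.chrom, [pos])[0]):
                continue
            for alt in rec.alts or ():
                if alt == "*" or alt.startswith("<"):
                    n_symbolic += 1
                    continue
                sites.append(make_variant_site(rec.chrom, pos, rec.ref, alt, status))
    if n_symbolic:
        logger.warning("%s: skipped %d symbolic alt alleles", path, n_symbolic)
    sites.sort(key=lambda s: (s.chrom, s.pos, s.ref, s.alt))
    return sites


def write_vcf(
    sites: Sequence[VariantSite], genome: GenomeSequence, path: str | Path
) -> None:
    """Write sites as an uncompressed VCF with a binary PASS/FAIL FILTER column."""
    header = pysam.VariantHeader()
    header.add_line('##FILTER=<ID=FAIL,Description="Failed variant quality filters">')
    for name, length in genome.lengths.items():
        header.contigs.add(name, length=length)
    ordered = sorted(sites, key=lambda s: (s.chrom, s.pos, s.ref, s.alt))
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for site in ordered:
            rec = vf.new_record(
                contig=site.chrom,
                start=site.pos,
                alleles=(site.ref, site.alt),
                filter="PASS" if site.status == PASSED else "FAIL",
            )
            vf.write(rec)


# ---------------------------------------------------------------------------
# Coverage tracks (bedGraph)
# ---------------------------------------------------------------------------


@dataclass
class CoverageTrack:
    """Per-base read depth; positions absent from the input are NaN, not zero."""

    depth: dict[str, np.ndarray]

    @property
    def lengths(self) -> dict[str, int]:
        return {chrom: len(v) for chrom, v in self.depth.items()}


def read_coverage(
    path: str | Path, lengths: Mapping[str, int] | None = None
) -> CoverageTrack:
    """Read a bedGraph coverage track into per-base vectors.

    Lines must be sorted and non-overlapping within each chromosome.
    If ``lengths`` is not given, each chromosome's vector length is the
    maximum end coordinate seen for it.
    """
    df = pd.read_csv(
        path,
        sep=r"\s+",
        header=None,
        names=["chrom", "start", "end", "value"],
        comment="#",
        dtype={"chrom": str},
    )
    if len(df) and ((df["start"] < 0).any() or (df["start"] >= df["end"]).any()):
        raise ValueError(f"{path}: invalid bedGraph interval (start >= end or negative)")
    depth: dict[str, np.ndarray] = {}
    for chrom, grp in df.groupby("chrom", sort=True):
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        if not (np.diff(starts) > 0).all() or (starts[1:] < ends[:-1]).any():
            raise ValueError(f"{path}: bedGraph lines for {chrom} unsorted or overlapping")
        n = int(lengths[chrom]) if lengths is not None else int(ends.max())
        if ends.max() > n:
            raise ValueError(f"{path}: {chrom} coverage extends beyond length {n}")
        vec = np.full(n, np.nan)
        for s, e, v in zip(starts, ends, grp["value"]):
            vec[s:e] = v
        depth[chrom] = vec
    if lengths is not None:
        for chrom, n in lengths.items():
            depth.setdefault(chrom, np.full(int(n), np.nan))
    return CoverageTrack(depth)


def _track_values(track) -> Mapping[str, np.ndarray]:
    for attr in ("depth", "values", "data"):
        if hasattr(track, attr) and isinstance(getattr(track, attr), Mapping):
            return getattr(track, attr)
    if isinstance(track, Mapping):
        return track
    raise TypeError(f"cannot extract per-chromosome vectors from {type(track)!r}")


def write_bedgraph(track, path: str | Path, precision: int = 6) -> None:
    """Write per-base values as bedGraph, run-length encoding equal values.

    NaN positions (undefined) are omitted. Accepts a CoverageTrack, any
    per-base track object, or a plain mapping chrom -> vector.
    """
    values = _track_values(track)
    with open(path, "w") as fh:
        for chrom in sorted(values):
            vec = np.asarray(values[chrom], dtype=float)
            defined = ~np.isnan(vec)
            if not defined.any():
                continue
            # run boundaries: value change or defined-status change
            change = np.empty(len(vec), dtype=bool)
            change[0] = True
            same = (vec[1:] == vec[:-1]) | (~defined[1:] & ~defined[:-1])
            change[1:] = ~same
            starts = np.flatnonzero(change)
            ends = np.append(starts[1:], len(vec))
            for s, e in zip(starts, ends):
                if defined[s]:
                    v = vec[s]
                    text = f"{v:.{precision}g}"
                    fh.write(f"{chrom}\t{s}\t{e}\t{text}\n")
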