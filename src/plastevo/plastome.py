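"""Annotated plastome I/O and the coding / non-coding size partition.

A plastome is modelled as a circular nucleotide sequence plus a flat list of
typed gene features. Coordinates are 0-based half-open internally; conversion
to and from GenBank's 1-based closed convention happens only at file
boundaries. Features that span the circular origin are stored as two
intervals.

"Coding" throughout this package means protein-coding CDS only: tRNA, rRNA,
introns, intergenic spacers and pseudogenes all fall in the non-coding
bucket, so ``total_bp == coding_bp + noncoding_bp`` always holds.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

FEATURE_KINDS = ("protein_cds", "trna", "rrna", "pseudogene", "intron", "igs")

_ALPHABET = frozenset("ACGTN")


class PlastomeError(ValueError):
    """Raised for malformed or unsupported plastome inputs."""


@dataclass
class GeneFeature:
    """A typed gene feature with one or more 0-based half-open intervals."""

    name: str
    kind: str
    strand: str
    intervals: list[tuple[int, int]]

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise PlastomeError(f"unknown feature kind {self.kind!r}")
        if self.strand not in ("+", "-"):
            raise PlastomeError(f"strand must be '+' or '-', got {self.strand!r}")
        for start, end in self.intervals:
            if not (0 <= start < end):
                raise PlastomeError(
                    f"feature {self.name}: bad interval [{start},{end})"
                )

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.intervals)

    @property
    def span(self) -> tuple[int, int]:
        """Leftmost start and rightmost end over all intervals."""
        return min(s for s, _ in self.intervals), max(e for _, e in self.intervals)


@dataclass
class AnnotatedPlastome:
    """Circular plastome sequence with gene annotation."""

    id: str
    sequence: str
    features: list[GeneFeature] = field(default_factory=list)

    def __post_init__(self) -> None:
        bad = set(self.sequence) - _ALPHABET
        if bad:
            raise PlastomeError(
                f"{self.id}: sequence contains non-ACGTN characters: {sorted(bad)}"
            )
        n = len(self.sequence)
        for f in self.features:
            for s, e in f.intervals:
                if e > n:
                    raise PlastomeError(
                        f"{self.id}: feature {f.name} interval [{s},{e}) "
                        f"exceeds genome length {n}"
                    )

    @property
    def length(self) -> int:
        return len(self.sequence)

    def rotated(self, offset: int) -> "AnnotatedPlastome":
        """Return the plastome with the circular origin moved to ``offset``.

        Position ``offset`` in the old frame becomes position 0. Feature
        intervals are remapped; an interval that comes to span the new
        origin is split in two.
        """
        n = self.length
        offset %= n
        seq = self.sequence[offset:] + self.sequence[:offset]
        feats = []
        for f in self.features:
            ivs: list[tuple[int, int]] = []
            for s, e in f.intervals:
                s2, e2 = (s - offset) % n, (e - offset) % n or n
                if s2 < e2:
                    ivs.append((s2, e2))
                else:  # wraps the new origin
                    ivs.append((s2, n))
                    ivs.append((0, e2))
            feats.append(GeneFeature(f.name, f.kind, f.strand, ivs))
        return AnnotatedPlastome(self.id, seq, feats)


@dataclass
class SizeRecord:
    """One row of the genome-size table: total, protein-coding, non-coding bp."""

    species: str
    clade: str
    total_bp: int
    coding_bp: int
    noncoding_bp: int

    def __post_init__(self) -> None:
        if self.total_bp != self.coding_bp + self.noncoding_bp:
            raise PlastomeError(
                f"{self.species}: total {self.total_bp} != coding "
                f"{self.coding_bp} + noncoding {self.noncoding_bp}"
            )
        if min(self.total_bp, self.coding_bp, self.noncoding_bp) < 0:
            raise PlastomeError(f"{self.species}: negative size field")


# ---------------------------------------------------------------------------
# GenBank I/O

_GB_TYPE_MAP = {"CDS": "protein_cds", "tRNA": "trna", "rRNA": "rrna"}


def _location_to_intervals(loc) -> list[tuple[int, int]]:
    parts = loc.parts if isinstance(loc, CompoundLocation) else [loc]
    return [(int(p.start), int(p.end)) for p in parts]


def read_genbank(path: str | Path | io.TextIOBase) -> AnnotatedPlastome:
    """Read a single-record GenBank flat file into an :class:`AnnotatedPlastome`.

    Gene/CDS/tRNA/rRNA features are captured; a CDS or gene carrying a
    ``pseudo``/``pseudogene`` qualifier becomes a ``pseudogene`` feature.
    Plain ``gene`` features that duplicate a captured CDS/tRNA/rRNA of the
    same name are dropped. Coordinates arrive 0-based half-open from
    Biopython; origin-spanning joins come through as two intervals.
    """
    records = list(SeqIO.parse(path, "genbank"))
    if len(records) != 1:
        raise PlastomeError(
            f"expected exactly one GenBank record, found {len(records)}"
        )
    rec = records[0]
    seq = str(rec.seq).upper()

    feats: list[GeneFeature] = []
    seen: set[tuple[str, str]] = set()
    plain_genes: list[GeneFeature] = []
    for f in rec.features:
        if f.type not in ("CDS", "tRNA", "rRNA", "gene"):
            continue
        name = (
            f.qualifiers.get("gene", [None])[0]
            or f.qualifiers.get("locus_tag", ["?"])[0]
        )
        pseudo = "pseudo" in f.qualifiers or "pseudogene" in f.qualifiers
        if f.type == "gene" and not pseudo:
            kind = None  # resolved after the typed features are collected
        else:
            kind = "pseudogene" if pseudo else _GB_TYPE_MAP[f.type]
        strand = "-" if f.location.strand == -1 else "+"
        gf_intervals = _location_to_intervals(f.location)
        if kind is None:
            plain_genes.append(GeneFeature(name, "igs", strand, gf_intervals))
            continue
        feats.append(GeneFeature(name, kind, strand, gf_intervals))
        seen.add((name, kind))
    # keep gene features only when no typed feature of the same name exists
    typed_names = {n for n, _ in seen}
    for g in plain_genes:
        if g.name not in typed_names:
            feats.append(GeneFeature(g.name, "igs", g.strand, g.intervals))

    return AnnotatedPlastome(rec.id or rec.name, seq, feats)


def write_genbank(p: AnnotatedPlastome, path: str | Path) -> None:
    """Write a plastome as a circular single-record GenBank flat file."""
    rec = SeqRecord(Seq(p.sequence), id=p.id, name=p.id[:16], description="")
    rec.annotations["molecule_type"] = "DNA"
    rec.annotations["topology"] = "circular"
    for f in p.features:
        strand = -1 if f.strand == "-" else 1
        locs = [SimpleLocation(s, e, strand=strand) for s, e in f.intervals]
        loc = locs[0] if len(locs) == 1 else CompoundLocation(locs)
        ftype = {"protein_cds": "CDS", "trna": "tRNA", "rrna": "rRNA"}.get(
            f.kind, "gene"
        )
        qualifiers = {"gene": [f.name]}
        if f.kind == "pseudogene":
            qualifiers["pseudo"] = [""]
        rec.features.append(SeqFeature(loc, type=ftype, qualifiers=qualifiers))
    SeqIO.write([rec], str(path), "genbank")


def write_fasta(p: AnnotatedPlastome, path: str | Path) -> None:
    SeqIO.write(
        [SeqRecord(Seq(p.sequence), id=p.id, description="")], str(path), "fasta"
    )


# ---------------------------------------------------------------------------
# Size partition

def coding_union(p: AnnotatedPlastome) -> int:
    """Number of genomic positions covered by >= 1 protein_cds interval.

    Positions are counted once even when CDS intervals overlap; pseudogenes
    never contribute.
    """
    ivs = sorted(
        iv for f in p.features if f.kind == "protein_cds" for iv in f.intervals
    )
    covered = 0
    cur_s, cur_e = None, None
    for s, e in ivs:
        if cur_e is None or s > cur_e:
            if cur_e is not None:
                covered += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    if cur_e is not None:
        covered += cur_e - cur_s
    return covered


def size_partition(p: AnnotatedPlastome, clade: str = "") -> SizeRecord:
    """Partition the genome length into protein-coding and non-coding bp."""
    coding = coding_union(p)
    return SizeRecord(
        species=p.id,
        clade=clade,
        total_bp=p.length,
        coding_bp=coding,
        noncoding_bp=p.length - coding,
    )


# ---------------------------------------------------------------------------
# Size table I/O

_SIZE_HEADER = ["species", "clade", "total_bp", "coding_bp", "noncoding_bp"]


def write_size_table(records: Sequence[SizeRecord], path: str | Path) -> None:
    """Write size records as TSV, preserving input order."""
    if not records:
        raise PlastomeError("write_size_table: empty record list")
    with open(path, "w") as fh:
        fh.write("\t".join(_SIZE_HEADER) + "\n")
        for r in records:
            fh.write(
                f"{r.species}\t{r.clade}\t{r.total_bp}\t{r.coding_bp}\t"
                f"{r.noncoding_bp}\n"
            )


def read_size_table(path: str | Path) -> list[SizeRecord]:
    records = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _SIZE_HEADER:
            raise PlastomeError(f"unexpected size-table header: {header}")
        for line in fh:
            sp, clade, tot, cod, non = line.rstrip("\n").split("\t")
            records.append(SizeRecord(sp, clade, int(tot), int(cod), int(non)))
    return records
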