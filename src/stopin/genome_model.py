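"""Genome and gene-model containers with strand-aware coordinate arithmetic.

All internal coordinates are 0-based half-open on the plus strand; GFF3's
1-based inclusive convention is converted at the I/O boundary and nowhere
else. A ``GeneModel`` stores per-isoform CDS intervals in transcription order
(descending genomic coordinate for minus-strand genes), and ``spliced_cds``
returns both the spliced coding sequence and a bijective coordinate map
between genomic and CDS space.
"""

from __future__ import annotations

import tempfile
import warnings
from dataclasses import dataclass, field

import gffutils
from Bio import SeqIO

from stopin.errors import AlphabetError, CoordinateError, FormatError, LookupError_

_ALPHABET = set("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string over A/C/G/T/N.

    Involution: ``reverse_complement(reverse_complement(s)) == s``.
    """
    bad = set(seq) - _ALPHABET
    if bad:
        raise AlphabetError(f"non-DNA characters in sequence: {sorted(bad)}")
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Interval:
    """A 0-based half-open genomic interval on one strand."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise CoordinateError(
                f"invalid interval [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in "+-":
            raise CoordinateError(f"strand must be + or -, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def contains_point(self, pos: int) -> bool:
        """True when an insertion point ``pos`` (between bases) falls strictly
        inside the interval, i.e. both neighbours are interval bases."""
        return self.start < pos < self.end


class Genome:
    """Uppercase A/C/G/T/N sequences keyed by chromosome name."""

    def __init__(self, sequences: dict[str, str]):
        for name, seq in sequences.items():
            if not seq:
                raise FormatError(f"empty sequence for record {name!r}")
            bad = set(seq) - _ALPHABET
            if bad:
                raise AlphabetError(
                    f"record {name!r} contains non-DNA characters: {sorted(bad)}"
                )
        self.sequences = dict(sequences)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sequences

    def length(self, chrom: str) -> int:
        try:
            return len(self.sequences[chrom])
        except KeyError:
            raise LookupError_(f"unknown chromosome {chrom!r}") from None

    def fetch(self, chrom: str, start: int, end: int, strand: str = "+") -> str:
        """Sequence of ``[start, end)`` on ``strand``; minus strand returns the
        reverse complement of the plus-strand slice."""
        if chrom not in self.sequences:
            raise LookupError_(f"unknown chromosome {chrom!r}")
        n = len(self.sequences[chrom])
        if not 0 <= start <= end <= n:
            raise CoordinateError(
                f"[{start}, {end}) out of bounds for {chrom} (length {n})"
            )
        s = self.sequences[chrom][start:end]
        return s if strand == "+" else reverse_complement(s)

    def fetch_interval(self, iv: Interval) -> str:
        return self.fetch(iv.chrom, iv.start, iv.end, iv.strand)


@dataclass
class GeneModel:
    """A gene with one or more isoforms, each an ordered list of CDS intervals.

    ``isoforms`` maps isoform id to CDS intervals in transcription order;
    ``exons`` holds the exon intervals the same way. The annotated stop codon
    is part of the CDS whenever the annotation includes it; nothing is
    appended or trimmed.
    """

    gene_id: str
    chrom: str
    strand: str
    isoforms: dict[str, list[Interval]]
    exons: dict[str, list[Interval]] = field(default_factory=dict)
    name: str | None = None

    def isoform_ids(self) -> list[str]:
        return list(self.isoforms)

    def cds_intervals(self, isoform_id: str) -> list[Interval]:
        try:
            return self.isoforms[isoform_id]
        except KeyError:
            raise LookupError_(
                f"unknown isoform {isoform_id!r} of gene {self.gene_id!r}"
            ) from None

    def cds_length(self, isoform_id: str) -> int:
        return sum(len(iv) for iv in self.cds_intervals(isoform_id))

    def span(self) -> Interval:
        starts = [iv.start for ivs in self.isoforms.values() for iv in ivs]
        ends = [iv.end for ivs in self.isoforms.values() for iv in ivs]
        return Interval(self.chrom, min(starts), max(ends), self.strand)


def load_genome(fasta_path: str) -> Genome:
    """Read a FASTA file into a :class:`Genome`, uppercasing sequence.

    Raises :class:`FormatError` on malformed input (naming the offending
    line) and on duplicate record names; :class:`AlphabetError` on characters
    outside A/C/G/T/N (e.g. RNA "U").
    """
    with open(fasta_path) as fh:
        lines = fh.read().splitlines()
    seen_header = False
    for i, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        if line.startswith(">"):
            seen_header = True
            continue
        if not seen_header:
            raise FormatError(f"{fasta_path}:{i}: sequence before first FASTA header")
        bad = set(line.strip().upper()) - _ALPHABET
        if bad:
            raise AlphabetError(
                f"{fasta_path}:{i}: non-DNA characters {sorted(bad)}"
            )
    if not seen_header:
        raise FormatError(f"{fasta_path}: no FASTA records found")

    sequences: dict[str, str] = {}
    for record in SeqIO.parse(fasta_path, "fasta"):
        if record.id in sequences:
            raise FormatError(f"duplicate FASTA record name {record.id!r}")
        sequences[record.id] = str(record.seq).upper()
    return Genome(sequences)


def _transcription_sort(intervals: list[Interval], strand: str) -> list[Interval]:
    return sorted(intervals, key=lambda iv: iv.start, reverse=(strand == "-"))


def load_annotation(gff3_path: str, genome: Genome) -> list[GeneModel]:
    """Parse a GFF3 (gene → mRNA → exon/CDS with Parent links) into gene models.

    Coordinates become 0-based half-open. CDS phase fields are ignored: frame
    is always recomputed from structure. mRNAs without CDS features are
    skipped with a warning; features on unknown chromosomes are an error.
    """
    with tempfile.NamedTemporaryFile(suffix=".db") as tmp:
        db = gffutils.create_db(
            gff3_path,
            dbfn=tmp.name,
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
        )
        genes: list[GeneModel] = []
        for g in db.features_of_type("gene"):
            isoforms: dict[str, list[Interval]] = {}
            exons: dict[str, list[Interval]] = {}
            for mrna in db.children(g, featuretype="mRNA"):
                cds_list = []
                exon_list = []
                for feat in db.children(mrna, featuretype=("CDS", "exon")):
                    if feat.seqid not in genome:
                        raise LookupError_(
                            f"feature {feat.id or mrna.id} references unknown "
                            f"chromosome {feat.seqid!r}"
                        )
                    if feat.end > genome.length(feat.seqid):
                        raise CoordinateError(
                            f"feature on {feat.seqid} ends at {feat.end}, past "
                            f"chromosome length {genome.length(feat.seqid)}"
                        )
                    iv = Interval(feat.seqid, feat.start - 1, feat.end, feat.strand)
                    (cds_list if feat.featuretype == "CDS" else exon_list).append(iv)
                if not cds_list:
                    warnings.warn(
                        f"mRNA {mrna.id!r} of gene {g.id!r} has no CDS; skipped",
                        stacklevel=2,
                    )
                    continue
                isoforms[mrna.id] = _transcription_sort(cds_list, g.strand)
                exons[mrna.id] = _transcription_sort(exon_list, g.strand)
            if not isoforms:
                continue
            name = g.attributes.get("Name", [None])[0]
            genes.append(
                GeneModel(
                    gene_id=g.id,
                    chrom=g.seqid,
                    strand=g.strand,
                    isoforms=isoforms,
                    exons=exons,
                    name=name,
                )
            )
        return genes


class CoordinateMap:
    """Bijection between genomic positions and spliced-CDS offsets.

    CDS offset ``i`` names the i-th base of the spliced coding sequence in
    transcription order; on minus-strand genes that base is the complement of
    the plus-strand base at the mapped genomic position.
    """

    def __init__(self, genomic_positions: list[int]):
        self._g = genomic_positions
        self._inv = {g: i for i, g in enumerate(genomic_positions)}

    def __len__(self) -> int:
        return len(self._g)

    def to_genome(self, cds_offset: int) -> int:
        return self._g[cds_offset]

    def to_cds(self, genomic_pos: int) -> int:
        try:
            return self._inv[genomic_pos]
        except KeyError:
            raise CoordinateError(f"position {genomic_pos} is not a CDS base") from None

    def covers(self, genomic_pos: int) -> bool:
        return genomic_pos in self._inv


def spliced_cds(
    gene: GeneModel, isoform_id: str, genome: Genome
) -> tuple[str, CoordinateMap]:
    """Spliced coding sequence of one isoform plus its genome↔CDS map."""
    intervals = gene.cds_intervals(isoform_id)
    parts: list[str] = []
    positions: list[int] = []
    for iv in intervals:
        parts.append(genome.fetch_interval(iv))
        if gene.strand == "+":
            positions.extend(range(iv.start, iv.end))
        else:
            positions.extend(range(iv.end - 1, iv.start - 1, -1))
    return "".join(parts), CoordinateMap(positions)


def cds_insertion_offset(
    gene: GeneModel, isoform_id: str, cut: int
) -> int | None:
    """Offset ``o`` in the spliced CDS such that inserting at genomic point
    ``cut`` yields ``cds[:o] + payload + cds[o:]`` on the sense strand.

    Returns None when the insertion point is not strictly inside any CDS
    interval of the isoform (that isoform is unaffected by the edit).
    """
    intervals = gene.cds_intervals(isoform_id)
    if not any(iv.contains_point(cut) for iv in intervals):
        return None
    offset = 0
    for iv in intervals:
        if iv.contains_point(cut):
            offset += (cut - iv.start) if gene.strand == "+" else (iv.end - cut)
            return offset
        offset += len(iv)
    return None  # pragma: no cover - guarded above
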