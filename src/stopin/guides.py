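"""Cas9 guide-site scanning, cut-site geometry, and candidate ranking.

A guide site is a 20-nt protospacer immediately followed by an NGG PAM
(S. pyogenes Cas9), on either chromosome strand. Cas9 cuts bluntly 3 bp
5' of the PAM, i.e. between protospacer bases 17 and 18; the cut point is
where the STOP-IN cassette will be inserted, so only sites whose cut falls
strictly inside coding sequence are candidates. Ranking prefers cuts early
in the spliced CDS of exons shared by all isoforms, the configuration most
likely to yield a true null.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from stopin.errors import DesignError
from stopin.genome_model import (
    GeneModel,
    Genome,
    Interval,
    cds_insertion_offset,
    reverse_complement,
)

GUIDE_LEN = 20
PAM_LEN = 3
SITE_LEN = GUIDE_LEN + PAM_LEN


@dataclass
class GuideSite:
    """One protospacer+PAM occurrence.

    ``protospacer`` and ``pam`` are written on the PAM strand; ``span`` is
    the plus-strand genomic interval covering both; ``cut_position`` is the
    plus-strand insertion point (between two bases) 3 bp 5' of the PAM on
    the PAM strand.
    """

    protospacer: str
    pam: str
    pam_strand: str
    span: Interval
    cut_position: int
    cds_fraction: float | None = None
    isoform_coverage: list[str] = field(default_factory=list)
    genome_match_count: int | None = None

    @property
    def site_sequence(self) -> str:
        """Protospacer + PAM on the PAM strand (the crRNA design sequence + NGG)."""
        return self.protospacer + self.pam


@dataclass
class GuideQuery:
    """Filter and ranking options for :func:`find_guides`."""

    require_all_isoforms: bool = True
    max_cds_fraction: float = 0.5
    require_unique: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.max_cds_fraction <= 1:
            raise DesignError("max_cds_fraction must be in (0, 1]")


def _cut_coordinate(span_start: int, pam_strand: str) -> int:
    """Plus-strand insertion coordinate of the blunt Cas9 cut.

    For a plus-strand PAM the 23-nt site occupies ``[s, s+23)`` with the PAM
    at ``[s+20, s+23)``; the cut falls between protospacer bases 17 and 18,
    3 bp 5' of the PAM, i.e. at coordinate ``s+17``. On the minus strand the
    geometry mirrors: PAM at ``[s, s+3)``, cut at ``s+6``.
    """
    return span_start + (17 if pam_strand == "+" else 6)


def cut_site(guide: GuideSite) -> int:
    """Blunt-cut insertion point of a guide, as a plus-strand coordinate."""
    return _cut_coordinate(guide.span.start, guide.pam_strand)


def iter_guide_windows(seq: str, chrom: str):
    """Yield every N20-NGG site on both strands of ``seq`` as a GuideSite
    without CDS annotation. Windows containing N are skipped."""
    n = len(seq)
    for i in range(n - SITE_LEN + 1):
        window = seq[i : i + SITE_LEN]
        if "N" in window:
            continue
        if window[21:23] == "GG":
            yield GuideSite(
                protospacer=window[:GUIDE_LEN],
                pam=window[GUIDE_LEN:],
                pam_strand="+",
                span=Interval(chrom, i, i + SITE_LEN),
                cut_position=_cut_coordinate(i, "+"),
            )
        if window[0:2] == "CC":
            rc = reverse_complement(window)
            yield GuideSite(
                protospacer=rc[:GUIDE_LEN],
                pam=rc[GUIDE_LEN:],
                pam_strand="-",
                span=Interval(chrom, i, i + SITE_LEN),
                cut_position=_cut_coordinate(i, "-"),
            )


def genome_match_count(site_sequence: str, genome: Genome) -> int:
    """Exact occurrences of a 23-nt protospacer+PAM on both strands genome-wide."""
    if len(site_sequence) != SITE_LEN:
        raise DesignError(f"site sequence must be {SITE_LEN} nt")
    rc = reverse_complement(site_sequence)
    total = 0
    for seq in genome.sequences.values():
        for query in (site_sequence, rc):
            start = 0
            while True:
                idx = seq.find(query, start)
                if idx < 0:
                    break
                total += 1
                start = idx + 1
    return total


def _annotate_cds(guide: GuideSite, gene: GeneModel, genome: Genome) -> bool:
    """Fill isoform coverage and cds_fraction; True if cut is in some CDS."""
    coverage = []
    fractions: dict[str, tuple[int, float]] = {}
    for iso in gene.isoform_ids():
        offset = cds_insertion_offset(gene, iso, guide.cut_position)
        if offset is None:
            continue
        coverage.append(iso)
        length = gene.cds_length(iso)
        fractions[iso] = (length, offset / length)
    if not coverage:
        return False
    guide.isoform_coverage = coverage
    # fraction within the shortest covered CDS: positions early in the most
    # compact isoform are conservatively "early" for every isoform
    shortest = min(fractions, key=lambda iso: fractions[iso][0])
    guide.cds_fraction = fractions[shortest][1]
    return True


def find_guides(gene: GeneModel, genome: Genome, query: GuideQuery | None = None) -> list[GuideSite]:
    """All candidate guide sites of a gene, filtered and ranked.

    Scans both strands over the gene span (padded by one site length so that
    protospacers may overhang exon boundaries), keeps sites whose cut point
    is strictly inside CDS, then applies the query filters. Ranking is by
    ascending cds_fraction, then genomic coordinate, then + before -.
    """
    if query is None:
        query = GuideQuery()
    if not gene.isoforms or all(gene.cds_length(i) == 0 for i in gene.isoform_ids()):
        import warnings

        warnings.warn(f"gene {gene.gene_id!r} has no CDS; no guides", stacklevel=2)
        return []
    span = gene.span()
    lo = max(0, span.start - SITE_LEN)
    hi = min(genome.length(gene.chrom), span.end + SITE_LEN)
    region = genome.fetch(gene.chrom, lo, hi)

    results: list[GuideSite] = []
    for g in iter_guide_windows(region, gene.chrom):
        g.span = Interval(gene.chrom, g.span.start + lo, g.span.end + lo)
        g.cut_position += lo
        if not _annotate_cds(g, gene, genome):
            continue
        if query.require_all_isoforms and set(g.isoform_coverage) != set(
            gene.isoform_ids()
        ):
            continue
        if g.cds_fraction is not None and g.cds_fraction > query.max_cds_fraction:
            continue
        g.genome_match_count = genome_match_count(g.site_sequence, genome)
        if query.require_unique and g.genome_match_count != 1:
            continue
        results.append(g)

    results.sort(
        key=lambda g: (
            g.cds_fraction if g.cds_fraction is not None else 1.0,
            g.span.start,
            0 if g.pam_strand == "+" else 1,
        )
    )
    return results
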