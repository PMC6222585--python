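"""Repair-oligo construction and in-silico HDR.

Knock-in oligos follow two efficiency rules: the homology arms (default
35 nt each) sit immediately against the Cas9 cut, and the single-stranded
oligo is synthesized on the same chromosome strand as the PAM. The payload
orientation is chosen so that after repair the gene's *sense* strand carries
the canonical cassette verbatim, whatever the PAM or gene strand — that is
what makes the null design frame- and strand-independent. Reversion oligos
are plain wild-type sequence (default 71 nt, 35 bases 5' and 36 bases 3' of
the junction on the sense strand) used together with a crRNA against the
cassette's exogenous Cas9 site.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from stopin.cassette import CASSETTE_SEQUENCE, canonical_cassette
from stopin.errors import CoordinateError, DesignError, StateError
from stopin.genome_model import (
    GeneModel,
    Genome,
    Interval,
    cds_insertion_offset,
    reverse_complement,
)
from stopin.guides import GuideSite


@dataclass
class RepairOligo:
    """A single-stranded repair template, written 5'→3' in synthesis order."""

    arm5: str
    payload: str
    arm3: str
    synthesis_strand: str
    chrom: str
    insertion_point: int
    target_gene: str
    notes: dict = field(default_factory=dict)

    @property
    def full_sequence(self) -> str:
        return self.arm5 + self.payload + self.arm3

    def __len__(self) -> int:
        return len(self.full_sequence)


@dataclass
class EditPlan:
    """A concrete genome edit: replace ``[replace_start, replace_end)`` of
    ``chrom`` with ``replacement_plus`` (given on the plus strand).

    Knock-ins have a zero-length replace span (pure insertion at the cut);
    reversions excise the 43-nt cassette. ``expected_sense_local`` is the
    post-edit sequence around the junction on the gene's sense strand, for
    eyeballing and for exact tests.
    """

    chrom: str
    replace_start: int
    replace_end: int
    replacement_plus: str
    gene_strand: str
    oligo: RepairOligo | None = None
    guide: GuideSite | None = None
    expected_sense_local: str = ""

    @property
    def length_delta(self) -> int:
        return len(self.replacement_plus) - (self.replace_end - self.replace_start)


def _check_guide_in_gene(guide: GuideSite, gene: GeneModel) -> None:
    if guide.span.chrom != gene.chrom:
        raise DesignError(
            f"guide on {guide.span.chrom} does not belong to gene {gene.gene_id} "
            f"on {gene.chrom}"
        )
    if all(
        cds_insertion_offset(gene, iso, guide.cut_position) is None
        for iso in gene.isoform_ids()
    ):
        raise DesignError(
            f"cut site {guide.cut_position} is not inside any CDS of {gene.gene_id}"
        )


def design_knockin_oligo(
    guide: GuideSite,
    gene: GeneModel,
    genome: Genome,
    arm_len: int = 35,
    arm_len_3: int | None = None,
) -> RepairOligo:
    """Knock-in ssODN for one guide: arm5 + cassette payload + arm3.

    The oligo is written on the PAM strand. When the PAM strand equals the
    gene's sense strand the payload is the cassette as written; otherwise it
    is the reverse complement, so that the repaired sense strand always
    reads the canonical cassette.
    """
    _check_guide_in_gene(guide, gene)
    if arm_len_3 is None:
        arm_len_3 = arm_len
    cut = guide.cut_position
    chrom_len = genome.length(gene.chrom)
    if cut - arm_len < 0 or cut + arm_len_3 > chrom_len:
        raise CoordinateError(
            f"cut at {cut} is closer than an arm length to the end of {gene.chrom}"
        )
    # plus-strand picture of the repaired junction
    plus_insert = (
        CASSETTE_SEQUENCE if gene.strand == "+" else reverse_complement(CASSETTE_SEQUENCE)
    )
    left = genome.fetch(gene.chrom, cut - arm_len, cut)
    right = genome.fetch(gene.chrom, cut, cut + arm_len_3)
    if guide.pam_strand == "+":
        arm5, payload, arm3 = left, plus_insert, right
    else:
        arm5 = reverse_complement(right)
        payload = reverse_complement(plus_insert)
        arm3 = reverse_complement(left)
    return RepairOligo(
        arm5=arm5,
        payload=payload,
        arm3=arm3,
        synthesis_strand=guide.pam_strand,
        chrom=gene.chrom,
        insertion_point=cut,
        target_gene=gene.gene_id,
        notes={"arm_len_5": len(arm5), "arm_len_3": len(arm3)},
    )


def plan_knockin(
    guide: GuideSite,
    gene: GeneModel,
    genome: Genome,
    arm_len: int = 35,
) -> EditPlan:
    """Bundle a knock-in oligo with its simulated-edit description."""
    oligo = design_knockin_oligo(guide, gene, genome, arm_len=arm_len)
    cut = guide.cut_position
    plus_insert = (
        CASSETTE_SEQUENCE if gene.strand == "+" else reverse_complement(CASSETTE_SEQUENCE)
    )
    flank = 35
    left = genome.fetch(gene.chrom, max(0, cut - flank), cut)
    right = genome.fetch(gene.chrom, cut, min(genome.length(gene.chrom), cut + flank))
    local_plus = left + plus_insert + right
    expected = local_plus if gene.strand == "+" else reverse_complement(local_plus)
    return EditPlan(
        chrom=gene.chrom,
        replace_start=cut,
        replace_end=cut,
        replacement_plus=plus_insert,
        gene_strand=gene.strand,
        oligo=oligo,
        guide=guide,
        expected_sense_local=expected,
    )


def simulate_hdr(genome: Genome, plan: EditPlan) -> Genome:
    """Apply a perfect HDR edit, returning a new genome.

    Pre-checks that the genome is in the state the plan assumes: for a
    knock-in, the guide's protospacer+PAM must still span the cut (a second
    application therefore fails); for a reversion, the excised span must be
    the cassette in the expected orientation.
    """
    seq = genome.sequences.get(plan.chrom)
    if seq is None:
        raise CoordinateError(f"unknown chromosome {plan.chrom!r}")
    if not 0 <= plan.replace_start <= plan.replace_end <= len(seq):
        raise CoordinateError(
            f"edit span [{plan.replace_start}, {plan.replace_end}) outside {plan.chrom}"
        )
    if plan.guide is not None and plan.replace_start == plan.replace_end:
        site = plan.guide.site_sequence
        if plan.guide.pam_strand == "-":
            site = reverse_complement(site)
        s, e = plan.guide.span.start, plan.guide.span.end
        if seq[s:e] != site:
            raise StateError(
                "guide site no longer present at its span; genome already edited?"
            )
    if plan.replace_end > plan.replace_start:
        excised = seq[plan.replace_start : plan.replace_end]
        if excised != (
            CASSETTE_SEQUENCE
            if plan.gene_strand == "+"
            else reverse_complement(CASSETTE_SEQUENCE)
        ):
            raise StateError(
                "excision span does not contain the cassette in the expected "
                "orientation"
            )
    edited = seq[: plan.replace_start] + plan.replacement_plus + seq[plan.replace_end :]
    sequences = dict(genome.sequences)
    sequences[plan.chrom] = edited
    return Genome(sequences)


@dataclass
class ReversionDesign:
    """Reversion reagents: wild-type ssODN plus the companion crRNA that
    targets the cassette's exogenous Cas9 site."""

    oligo: RepairOligo
    crrna: str
    plan: EditPlan


def design_reversion_oligo(
    edited_genome: Genome,
    chrom: str,
    insertion_point: int,
    gene_strand: str,
    total_len: int = 71,
    target_gene: str = "",
) -> ReversionDesign:
    """Wild-type reversion ssODN for a cassette-bearing locus.

    The locus must carry the cassette exactly at ``insertion_point`` in the
    gene's sense orientation. The oligo is contiguous wild-type sequence on
    the sense strand spanning the original insertion junction, split
    ``total_len // 2`` bases 5' and the remainder 3' (35 + 36 by default);
    the split is recorded in the oligo notes. The companion crRNA is the
    cassette's 20-nt exogenous protospacer.
    """
    seq = edited_genome.sequences.get(chrom)
    if seq is None:
        raise CoordinateError(f"unknown chromosome {chrom!r}")
    sense_cassette = (
        CASSETTE_SEQUENCE if gene_strand == "+" else reverse_complement(CASSETTE_SEQUENCE)
    )
    ins = insertion_point
    if seq[ins : ins + 43] != sense_cassette:
        raise StateError(
            f"cassette not found at {chrom}:{ins} in the gene's sense orientation"
        )
    # count occurrences near the locus to catch tandem insertions
    window = seq[max(0, ins - 200) : ins + 243]
    if window.count(sense_cassette) != 1:
        raise StateError("cassette present more than once at the locus")
    five_len = total_len // 2
    three_len = total_len - five_len
    if gene_strand == "+":
        upstream = seq[ins - five_len : ins]
        downstream = seq[ins + 43 : ins + 43 + three_len]
        oligo_seq5, oligo_seq3 = upstream, downstream
    else:
        # sense strand runs right-to-left on plus coordinates
        oligo_seq5 = reverse_complement(seq[ins + 43 : ins + 43 + five_len])
        oligo_seq3 = reverse_complement(seq[ins - three_len : ins])
    if len(oligo_seq5) != five_len or len(oligo_seq3) != three_len:
        raise CoordinateError("reversion oligo would run past a chromosome end")
    oligo = RepairOligo(
        arm5=oligo_seq5,
        payload="",
        arm3=oligo_seq3,
        synthesis_strand=gene_strand,
        chrom=chrom,
        insertion_point=ins,
        target_gene=target_gene,
        notes={"split": f"{five_len}+{three_len}", "kind": "reversion"},
    )
    crrna = canonical_cassette().protospacer
    plan = EditPlan(
        chrom=chrom,
        replace_start=ins,
        replace_end=ins + 43,
        replacement_plus="",
        gene_strand=gene_strand,
        oligo=oligo,
        expected_sense_local=oligo.full_sequence,
    )
    return ReversionDesign(oligo=oligo, crrna=crrna, plan=plan)


def lift_gene_model(gene: GeneModel, plan: EditPlan) -> GeneModel:
    """Gene model with coordinates shifted to match a simulated edit.

    Intervals downstream of the edit shift by the length delta; an interval
    containing the edit span stretches. Used to re-extract spliced CDS from
    an edited genome.
    """
    delta = plan.length_delta

    def lift(iv: Interval) -> Interval:
        if iv.chrom != plan.chrom or iv.end <= plan.replace_start:
            return iv
        if iv.start >= plan.replace_end:
            return Interval(iv.chrom, iv.start + delta, iv.end + delta, iv.strand)
        return Interval(iv.chrom, iv.start, iv.end + delta, iv.strand)

    return GeneModel(
        gene_id=gene.gene_id,
        chrom=gene.chrom,
        strand=gene.strand,
        isoforms={iso: [lift(iv) for iv in ivs] for iso, ivs in gene.isoforms.items()},
        exons={iso: [lift(iv) for iv in ivs] for iso, ivs in gene.exons.items()},
        name=gene.name,
    )
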