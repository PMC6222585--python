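"""In-silico proof that a planned insertion is a putative null.

For every isoform the edited transcript is rebuilt from the edited genome
and checked for (a) a premature stop codon at or shortly after the insertion
— the cassette carries one in every reading phase — and (b) a downstream
frameshift (payload length = 1 mod 3), the independent safeguard should a
single stop read through. The locus itself is checked for destruction of the
original Cas9 site (the insertion splits the protospacer between bases 17
and 18) and installation of the exogenous re-editable site.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from Bio.Seq import Seq

from stopin.cassette import STOP_CODONS, canonical_cassette
from stopin.errors import StopinError
from stopin.genome_model import (
    GeneModel,
    Genome,
    cds_insertion_offset,
    reverse_complement,
    spliced_cds,
)
from stopin.repair import EditPlan, lift_gene_model, simulate_hdr


def translate(cds: str) -> str:
    """Translate with the standard nuclear code, stopping at the first stop.

    A trailing partial codon is ignored; codons containing non-ACGT bases
    translate to X.
    """
    if len(cds) < 3:
        raise StopinError("translate requires at least one codon")
    trimmed = cds[: len(cds) - len(cds) % 3]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return str(Seq(trimmed).translate(to_stop=True))


@dataclass
class IsoformReport:
    """Per-isoform consequence of the insertion."""

    isoform_id: str
    affected: bool
    insertion_offset: int | None = None
    phase: int | None = None
    first_stop_offset: int | None = None
    truncation_fraction: float | None = None
    frameshift: bool = False


@dataclass
class VerificationReport:
    """Null-design verification: per-isoform transcript checks plus locus checks."""

    gene_id: str
    isoforms: dict[str, IsoformReport] = field(default_factory=dict)
    original_site_destroyed: bool = False
    exogenous_site_installed: bool = False
    nhei_unique_in_amplicon: bool | None = None
    putative_null: bool = False

    @property
    def affected_isoforms(self) -> list[str]:
        return [i for i, r in self.isoforms.items() if r.affected]


def _first_stop_at_or_after(cds: str, insertion_offset: int) -> int | None:
    """Offset of the first in-frame stop codon at/after the codon containing
    the insertion, scanning frame 0 of the (edited) CDS."""
    start = (insertion_offset // 3) * 3
    for i in range(start, len(cds) - 2, 3):
        if cds[i : i + 3] in STOP_CODONS:
            return i
    return None


def verify_knockin(
    gene: GeneModel,
    plan: EditPlan,
    reference: Genome,
    max_cds_fraction: float = 0.5,
) -> VerificationReport:
    """Rebuild every isoform's transcript after the edit and verify nullness.

    Isoforms whose CDS does not contain the insertion point are reported as
    unaffected (supporting deliberate isoform-specific designs) rather than
    raising.
    """
    edited = simulate_hdr(reference, plan)
    lifted = lift_gene_model(gene, plan)
    cut = plan.replace_start
    payload_len = plan.length_delta
    report = VerificationReport(gene_id=gene.gene_id)

    null_ok: list[bool] = []
    for iso in gene.isoform_ids():
        offset = cds_insertion_offset(gene, iso, cut)
        if offset is None:
            report.isoforms[iso] = IsoformReport(isoform_id=iso, affected=False)
            continue
        wt_cds, _ = spliced_cds(gene, iso, reference)
        edited_cds, _ = spliced_cds(lifted, iso, edited)
        stop_offset = _first_stop_at_or_after(edited_cds, offset)
        wt_protein_len = len(translate(wt_cds))
        retained = offset // 3
        truncation = 1.0 - retained / wt_protein_len if wt_protein_len else 1.0
        report.isoforms[iso] = IsoformReport(
            isoform_id=iso,
            affected=True,
            insertion_offset=offset,
            phase=offset % 3,
            first_stop_offset=stop_offset,
            truncation_fraction=truncation,
            frameshift=payload_len % 3 != 0,
        )
        null_ok.append(
            stop_offset is not None
            and offset / len(wt_cds) <= max_cds_fraction
        )

    # locus checks by exact substring search around the edit
    chrom_seq = edited.sequences[plan.chrom]
    lo = max(0, plan.replace_start - 60)
    hi = min(len(chrom_seq), plan.replace_start + len(plan.replacement_plus) + 60)
    local = chrom_seq[lo:hi]
    if plan.guide is not None:
        site_plus = plan.guide.site_sequence
        if plan.guide.pam_strand == "-":
            site_plus = reverse_complement(site_plus)
        report.original_site_destroyed = (
            site_plus not in local and reverse_complement(site_plus) not in local
        )
    exo = canonical_cassette().exogenous_site
    sense_exo = exo if plan.gene_strand == "+" else reverse_complement(exo)
    report.exogenous_site_installed = local.count(sense_exo) == 1
    report.putative_null = bool(null_ok) and all(null_ok)
    return report
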