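"""Repair-oligo construction, simulated HDR, and reversion round-trips."""

import pytest

from stopin.cassette import CASSETTE_SEQUENCE
from stopin.errors import CoordinateError, DesignError, StateError
from stopin.fixtures import (
    coverage_spec,
    guide_site_from_manifest,
    load_fixture,
)
from stopin.genome_model import reverse_complement
from stopin.repair import (
    design_knockin_oligo,
    design_reversion_oligo,
    plan_knockin,
    simulate_hdr,
)


@pytest.fixture(scope="module")
def fixture():
    genome, genes, manifest = load_fixture(coverage_spec())
    return genome, {g.gene_id: g for g in genes}, manifest


def _each_guide(fixture):
    genome, genes, manifest = fixture
    for mg in manifest["guides"]:
        gene = genes[mg["gene_id"]]
        yield mg, gene, guide_site_from_manifest(mg, gene, genome)


class TestKnockinOligo:
    def test_default_length_113(self, fixture):
        genome, genes, manifest = fixture
        for mg, gene, guide in _each_guide(fixture):
            oligo = design_knockin_oligo(guide, gene, genome)
            assert len(oligo) == 113  # 35 + 43 + 35
            assert oligo.full_sequence == oligo.arm5 + oligo.payload + oligo.arm3

    def test_payload_orientation_per_strand_combination(self, fixture):
        """PAM strand == sense strand -> cassette verbatim in the oligo;
        otherwise the oligo carries the reverse complement, but the repaired
        sense strand always gains the cassette verbatim."""
        genome, genes, manifest = fixture
        seen = set()
        for mg, gene, guide in _each_guide(fixture):
            oligo = design_knockin_oligo(guide, gene, genome)
            assert oligo.synthesis_strand == guide.pam_strand
            if guide.pam_strand == gene.strand:
                assert oligo.payload == CASSETTE_SEQUENCE
            else:
                assert oligo.payload == reverse_complement(CASSETTE_SEQUENCE)
            plan = plan_knockin(guide, gene, genome)
            edited = simulate_hdr(genome, plan)
            sense = edited.fetch(
                gene.chrom, 0, edited.length(gene.chrom), gene.strand
            )
            assert CASSETTE_SEQUENCE in sense
            seen.add((gene.strand, guide.pam_strand))
        assert seen == {("+", "+"), ("+", "-"), ("-", "+"), ("-", "-")}

    def test_arms_flank_cut_on_synthesis_strand(self, fixture):
        genome, genes, manifest = fixture
        for mg, gene, guide in _each_guide(fixture):
            oligo = design_knockin_oligo(guide, gene, genome)
            cut = guide.cut_position
            left = genome.fetch(gene.chrom, cut - 35, cut)
            right = genome.fetch(gene.chrom, cut, cut + 35)
            if guide.pam_strand == "+":
                assert (oligo.arm5, oligo.arm3) == (left, right)
            else:
                assert oligo.arm5 == reverse_complement(right)
                assert oligo.arm3 == reverse_complement(left)

    def test_arms_rederived_from_edited_genome(self, fixture):
        """After the edit, the oligo arms flank the inserted payload exactly
        (no off-by-one at either junction)."""
        genome, genes, manifest = fixture
        for mg, gene, guide in _each_guide(fixture):
            plan = plan_knockin(guide, gene, genome)
            edited = simulate_hdr(genome, plan)
            oligo = plan.oligo
            if guide.pam_strand == "+":
                local = edited.fetch(gene.chrom, plan.replace_start - 35,
                                     plan.replace_start + 43 + 35)
            else:
                local = edited.fetch(gene.chrom, plan.replace_start - 35,
                                     plan.replace_start + 43 + 35, "-")
            assert local == oligo.full_sequence

    def test_boundary_error_near_chromosome_end(self):
        """A gene starting 12 bp into the chromosome puts the cut closer
        than one arm length to the end."""
        from stopin.fixtures import FixtureSpec, GeneSpec, PlantSpec

        spec = FixtureSpec(
            seed=2,
            gene_start=12,
            genes=[
                GeneSpec(
                    gene_id="edge",
                    exon_cds_lengths=(90, 90),
                    guides=[PlantSpec("ACGACGCAGACGACAGCAGC", "CGG", "+", 0, offset=3)],
                )
            ],
            chrom_length=2000,
        )
        genome, genes, manifest = load_fixture(spec)
        guide = guide_site_from_manifest(manifest["guides"][0], genes[0], genome)
        assert guide.cut_position < 35
        with pytest.raises(CoordinateError):
            design_knockin_oligo(guide, genes[0], genome)

    def test_guide_outside_gene_rejected(self, fixture):
        genome, genes, manifest = fixture
        mg, gene, guide = next(iter(_each_guide(fixture)))
        other = next(g for g in genes.values() if g.gene_id != gene.gene_id)
        with pytest.raises(DesignError):
            design_knockin_oligo(guide, other, genome)


class TestSimulateHdr:
    def test_insertion_adds_43_bases(self, fixture):
        genome, genes, manifest = fixture
        mg, gene, guide = next(iter(_each_guide(fixture)))
        plan = plan_knockin(guide, gene, genome)
        edited = simulate_hdr(genome, plan)
        assert edited.length(gene.chrom) == genome.length(gene.chrom) + 43

    def test_original_site_destroyed(self, fixture):
        """The insertion splits the protospacer between bases 17 and 18, so
        the original 23-mer disappears from both strands (verified by
        search, not assumed)."""
        genome, genes, manifest = fixture
        for mg, gene, guide in _each_guide(fixture):
            plan = plan_knockin(guide, gene, genome)
            edited = simulate_hdr(genome, plan)
            site_plus = (
                guide.site_sequence
                if guide.pam_strand == "+"
                else reverse_complement(guide.site_sequence)
            )
            lo = max(0, guide.span.start - 30)
            window = edited.sequences[gene.chrom][lo : guide.span.end + 73]
            assert site_plus not in window
            assert reverse_complement(site_plus) not in window

    def test_second_application_fails(self, fixture):
        genome, genes, manifest = fixture
        mg, gene, guide = next(iter(_each_guide(fixture)))
        plan = plan_knockin(guide, gene, genome)
        edited = simulate_hdr(genome, plan)
        with pytest.raises(StateError, match="guide site"):
            simulate_hdr(edited, plan)


class TestReversion:
    def test_oligo_is_71nt_and_crrna_is_cassette_prefix(self, fixture):
        genome, genes, manifest = fixture
        mg, gene, guide = next(iter(_each_guide(fixture)))
        plan = plan_knockin(guide, gene, genome)
        edited = simulate_hdr(genome, plan)
        design = design_reversion_oligo(edited, gene.chrom, plan.replace_start, gene.strand)
        assert len(design.oligo) == 71
        assert design.oligo.notes["split"] == "35+36"
        assert design.crrna == "GGGAAGTTTGTCCAGAGCAG"
        assert design.crrna == CASSETTE_SEQUENCE[:20]

    def test_round_trip_restores_reference_exactly(self, fixture):
        """knock-in then reversion returns the chromosome byte-for-byte."""
        genome, genes, manifest = fixture
        for mg, gene, guide in _each_guide(fixture):
            plan = plan_knockin(guide, gene, genome)
            edited = simulate_hdr(genome, plan)
            design = design_reversion_oligo(
                edited, gene.chrom, plan.replace_start, gene.strand
            )
            restored = simulate_hdr(edited, design.plan)
            assert restored.sequences[gene.chrom] == genome.sequences[gene.chrom]

    def test_reversion_oligo_matches_wildtype_sense_sequence(self, fixture):
        genome, genes, manifest = fixture
        mg, gene, guide = next(iter(_each_guide(fixture)))
        plan = plan_knockin(guide, gene, genome)
        edited = simulate_hdr(genome, plan)
        design = design_reversion_oligo(edited, gene.chrom, plan.replace_start, gene.strand)
        cut = plan.replace_start
        if gene.strand == "+":
            expected = genome.fetch(gene.chrom, cut - 35, cut + 36)
        else:
            expected = genome.fetch(gene.chrom, cut - 36, cut + 35, "-")
        assert design.oligo.full_sequence == expected

    def test_cassette_absent_raises_state_error(self, fixture):
        genome, genes, manifest = fixture
        mg, gene, guide = next(iter(_each_guide(fixture)))
        with pytest.raises(StateError):
            design_reversion_oligo(genome, gene.chrom, guide.cut_position, gene.strand)
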