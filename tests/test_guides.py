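"""Guide scanning: recovery of planted sites, cut geometry, oracle equality."""

import pytest

from stopin.fixtures import (
    FixtureSpec,
    GeneSpec,
    coverage_spec,
    load_fixture,
)
from stopin.genome_model import Genome, GeneModel, Interval, reverse_complement
from stopin.guides import (
    GuideQuery,
    GuideSite,
    SITE_LEN,
    cut_site,
    find_guides,
    genome_match_count,
    iter_guide_windows,
)


def _scan_query():
    return GuideQuery(require_all_isoforms=False, max_cds_fraction=1.0, require_unique=False)


class TestCutGeometry:
    def test_plus_strand_cut_three_bp_from_pam(self):
        # protospacer at [100,120), PAM at [120,123): cut between 116 and 117
        g = GuideSite("A" * 20, "AGG", "+", Interval("c", 100, 123), 0)
        g.cut_position = cut_site(g)
        assert g.cut_position == 117
        assert 120 - g.cut_position == 3  # 3 bp 5' of the PAM

    def test_minus_strand_cut_mirrors(self):
        # PAM at [100,103) on plus coordinates: cut between 105 and 106
        g = GuideSite("A" * 20, "AGG", "-", Interval("c", 100, 123), 0)
        assert cut_site(g) == 106
        assert cut_site(g) - 103 == 3  # 3 bp 5' of PAM on the minus strand

    def test_cut_to_pam_distance_on_all_fixture_guides(self, coverage_fixture):
        _, _, manifest = coverage_fixture
        assert manifest["guides"], "fixture must plant guides"
        for mg in manifest["guides"]:
            pam_start = (
                mg["span_end"] - 3 if mg["pam_strand"] == "+" else mg["span_start"] + 3
            )
            assert abs(mg["cut"] - pam_start) == 3

    def test_span_length_is_23(self, coverage_fixture):
        genome, genes, manifest = coverage_fixture
        for mg in manifest["guides"]:
            assert mg["span_end"] - mg["span_start"] == SITE_LEN


class TestFindGuides:
    def test_recovers_every_planted_guide(self, coverage_fixture):
        """Each planted site is found at its manifest coordinates with the
        right strand, protospacer, cut position, and isoform coverage."""
        genome, genes, manifest = coverage_fixture
        for mg in manifest["guides"]:
            gene = genes[mg["gene_id"]]
            found = [
                g
                for g in find_guides(gene, genome, _scan_query())
                if g.span.start == mg["span_start"] and g.pam_strand == mg["pam_strand"]
            ]
            assert len(found) == 1, mg
            g = found[0]
            assert g.protospacer == mg["protospacer"]
            assert g.pam == mg["pam"]
            assert g.cut_position == mg["cut"]
            assert set(g.isoform_coverage) == set(mg["isoform_coverage"])

    def test_aex2_guide_recovered_verbatim(self, aex2_fixture):
        genome, gene, manifest = aex2_fixture
        guides = find_guides(gene, genome)
        assert any(g.protospacer == "ATTACTGCAGCGACATGGGG" for g in guides)

    def test_unshared_exon_guide_excluded_when_all_isoforms_required(
        self, coverage_fixture
    ):
        genome, genes, manifest = coverage_fixture
        gene = genes["iso2"]
        shared = find_guides(
            gene, genome, GuideQuery(require_all_isoforms=True, max_cds_fraction=1.0)
        )
        any_iso = find_guides(
            gene, genome, GuideQuery(require_all_isoforms=False, max_cds_fraction=1.0)
        )
        planted = [
            mg for mg in manifest["guides"] if mg["gene_id"] == "iso2"
        ]
        partial = [
            mg for mg in planted if set(mg["isoform_coverage"]) != set(gene.isoform_ids())
        ]
        assert partial, "fixture must plant a guide in an unshared exon"
        partial_starts = {mg["span_start"] for mg in partial}
        assert partial_starts.isdisjoint({g.span.start for g in shared})
        assert partial_starts <= {g.span.start for g in any_iso}

    def test_intron_only_guides_yield_empty_list(self):
        """A gene whose only NGG windows cut inside introns gives no guides."""
        spec = FixtureSpec(
            seed=3,
            genes=[GeneSpec(gene_id="bare", exon_cds_lengths=(90, 90), intron_length=80)],
            chrom_length=3000,
        )
        genome, genes, _ = load_fixture(spec)
        gene = genes[0]
        # plant a site mid-intron by hand: cut lands outside all CDS
        iv0, iv1 = gene.isoforms[gene.isoform_ids()[0]]
        intron_mid = iv0.end + 30
        seq = genome.sequences["chrS"]
        site = "ACGACGCAGACGACAGCAGCCGG"
        edited = Genome(
            {"chrS": seq[:intron_mid] + site + seq[intron_mid + 23 :]}
        )
        assert find_guides(gene, edited, _scan_query()) == []

    def test_ranking_prefers_early_cuts(self, coverage_fixture):
        genome, genes, _ = coverage_fixture
        guides = find_guides(genes["gpp"], genome, _scan_query())
        fractions = [g.cds_fraction for g in guides]
        assert fractions == sorted(fractions)

    def test_completeness_equals_brute_force_scan(self, coverage_fixture):
        """find_guides with filters off equals an independent exhaustive
        enumeration of N20-NGG windows whose cut lies in CDS."""
        genome, genes, _ = coverage_fixture
        seq = genome.sequences["chrS"]
        for gene in genes.values():
            expected = set()
            for i in range(len(seq) - 22):
                window = seq[i : i + 23]
                if "N" in window:
                    continue
                for strand, is_pam in (("+", window[21:23] == "GG"), ("-", window[0:2] == "CC")):
                    if not is_pam:
                        continue
                    cut = i + (17 if strand == "+" else 6)
                    in_cds = any(
                        iv.start < cut < iv.end
                        for iso in gene.isoform_ids()
                        for iv in gene.cds_intervals(iso)
                    )
                    if in_cds:
                        expected.add((i, strand))
            got = {(g.span.start, g.pam_strand) for g in find_guides(gene, genome, _scan_query())}
            assert got == expected

    def test_strand_symmetry(self, coverage_fixture):
        """Reverse-complementing the chromosome and mirroring annotations
        yields the same guides with strands flipped and coordinates mirrored."""
        genome, genes, _ = coverage_fixture
        n = genome.length("chrS")
        flipped_genome = Genome({"chrS": reverse_complement(genome.sequences["chrS"])})

        def mirror(iv):
            return Interval(iv.chrom, n - iv.end, n - iv.start, "-" if iv.strand == "+" else "+")

        for gene in genes.values():
            flipped = GeneModel(
                gene_id=gene.gene_id,
                chrom=gene.chrom,
                strand="-" if gene.strand == "+" else "+",
                isoforms={iso: [mirror(iv) for iv in ivs] for iso, ivs in gene.isoforms.items()},
            )
            orig = {
                (g.span.start, g.pam_strand)
                for g in find_guides(gene, genome, _scan_query())
            }
            mirrored = {
                (n - g.span.end, "+" if g.pam_strand == "-" else "-")
                for g in find_guides(flipped, flipped_genome, _scan_query())
            }
            assert orig == mirrored


class TestGenomeMatchCount:
    def test_planted_guides_unique(self, coverage_fixture):
        genome, _, manifest = coverage_fixture
        for mg in manifest["guides"]:
            site = mg["protospacer"] + mg["pam"]
            assert genome_match_count(site, genome) == 1

    def test_site_planted_twice_counts_two(self):
        site = "ACGACGCAGACGACAGCAGCCGG"
        filler = "ATATATATAT" * 10
        seq = filler + site + filler + reverse_complement(site) + filler
        assert genome_match_count(site, Genome({"c": seq})) == 2

    def test_equals_naive_sliding_window(self, coverage_fixture):
        genome, _, manifest = coverage_fixture
        seq = genome.sequences["chrS"]
        for mg in manifest["guides"][:4]:
            site = mg["protospacer"] + mg["pam"]
            rc = reverse_complement(site)
            naive = sum(
                1
                for i in range(len(seq) - 22)
                if seq[i : i + 23] in (site, rc)
            )
            assert genome_match_count(site, genome) == naive
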