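"""Deterministic synthetic genomes and annotations for end-to-end testing.

The generator emulates the design-relevant features of real loci — genes on
either chromosome strand, multi-exon/multi-isoform structures, guide sites
with the PAM on either strand and any insertion phase, guides overhanging
exon/intron boundaries — while keeping ground truth exact: background
sequence is sampled with rejection so that it never contains a GG or CC
dinucleotide, hence never an NGG PAM, and every planted protospacer+PAM is
the only guide-producing sequence outside the immediate neighbourhood of a
planting. A manifest records each planted guide's expected coordinates, cut
site, strand, and isoform coverage; tests treat the manifest as the single
source of truth.

Exon CDS lengths are multiples of three and isoforms differ only by skipping
internal exons, so every isoform starts ATG, ends with a shared stop codon,
and is internally stop-free — which is what lets verification tests assert
"no premature stop in wild type" exactly.
"""

from __future__ import annotations

import random
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

from stopin.cassette import STOP_CODONS
from stopin.errors import DesignError
from stopin.genome_model import (
    GeneModel,
    Genome,
    load_annotation,
    load_genome,
    reverse_complement,
)
from stopin.guides import GuideQuery, find_guides
from stopin.repair import EditPlan, plan_knockin, simulate_hdr


@dataclass
class PlantSpec:
    """A guide to embed in a gene.

    ``pam_strand`` is relative to the gene's sense strand; ``offset`` (bases
    from the start of the exon's CDS, sense orientation) may be given
    explicitly — including values that make the site overhang the exon — or
    left None to search for a stop-free placement, optionally constrained to
    a given insertion ``phase`` (cut offset mod 3 in the spliced CDS).
    """

    protospacer: str
    pam: str = "CGG"
    pam_strand: str = "+"
    exon_index: int = 0
    offset: int | None = None
    phase: int | None = None
    expect_unique: bool = True

    def __post_init__(self) -> None:
        if len(self.protospacer) != 20:
            raise DesignError("protospacer must be 20 nt")
        if len(self.pam) != 3 or not self.pam.endswith("GG"):
            raise DesignError("PAM must be 3 nt ending in GG")

    @property
    def site(self) -> str:
        return self.protospacer + self.pam


@dataclass
class GeneSpec:
    """Structure of one synthetic gene (CDS-only model)."""

    gene_id: str
    strand: str = "+"
    exon_cds_lengths: tuple[int, ...] = (90, 120, 90)
    intron_length: int = 60
    isoforms: dict[str, tuple[int, ...]] | None = None
    guides: list[PlantSpec] = field(default_factory=list)

    def __post_init__(self) -> None:
        for ln in self.exon_cds_lengths:
            if ln % 3 or ln < 9:
                raise DesignError("exon CDS lengths must be multiples of 3, >= 9")
        n = len(self.exon_cds_lengths)
        if self.isoforms is None:
            self.isoforms = {f"{self.gene_id}.a": tuple(range(n))}
        for iso, exons in self.isoforms.items():
            if exons[0] != 0 or exons[-1] != n - 1:
                raise DesignError(
                    f"isoform {iso}: first and last exons must be included "
                    "(they carry the start and stop codons)"
                )
            if list(exons) != sorted(set(exons)):
                raise DesignError(f"isoform {iso}: exon list must be ascending")


@dataclass
class FixtureSpec:
    """A deterministic toy genome: identical seed+spec gives identical text."""

    seed: int
    genes: list[GeneSpec]
    chrom: str = "chrS"
    chrom_length: int = 12000
    gene_start: int = 500
    gene_spacing: int = 400


_BASES = "ACGT"


def _next_base(rng: random.Random, prev: str, exclude: set[str] = frozenset()) -> str:
    """Sample a base that never forms GG or CC with its predecessor."""
    choices = [
        b
        for b in _BASES
        if b not in exclude and not (prev == "G" and b == "G") and not (prev == "C" and b == "C")
    ]
    return rng.choice(choices)


def _background(rng: random.Random, length: int, prev: str = "A") -> str:
    out = []
    for _ in range(length):
        prev = _next_base(rng, prev)
        out.append(prev)
    return "".join(out)


def _exon_cds(rng: random.Random, length: int, prev: str, first: bool, last: bool) -> str:
    """Stop-free frame-0 CDS chunk; optionally starts ATG / ends TAA."""
    out: list[str] = []
    if first:
        out.extend("ATG")
        prev = "G"
    body_len = length - (3 if first else 0) - (3 if last else 0)
    for i in range(body_len):
        codon_pos = (len(out)) % 3
        exclude: set[str] = set()
        if codon_pos == 2:
            two = "".join(out[-2:])
            exclude = {b for b in _BASES if two + b in STOP_CODONS}
        prev = _next_base(rng, prev, exclude)
        out.append(prev)
    if last:
        if prev == "T":
            # avoid TT..A ambiguity? TAA after T is fine; GG/CC rule only
            pass
        out.extend("TAA")
    return "".join(out)


class _GeneBuild:
    """Assembled sense-strand gene with exon bookkeeping."""

    def __init__(self, spec: GeneSpec, rng: random.Random):
        self.spec = spec
        parts: list[str] = []
        self.exon_spans: list[tuple[int, int]] = []  # gene coords, sense
        prev = "A"
        n = len(spec.exon_cds_lengths)
        pos = 0
        for i, ln in enumerate(spec.exon_cds_lengths):
            exon = _exon_cds(rng, ln, prev, first=(i == 0), last=(i == n - 1))
            parts.append(exon)
            self.exon_spans.append((pos, pos + ln))
            pos += ln
            prev = exon[-1]
            if i < n - 1:
                intron = _background(rng, spec.intron_length, prev)
                parts.append(intron)
                pos += spec.intron_length
                prev = intron[-1]
        self.sequence = "".join(parts)
        self.planted: list[dict] = []

    def _isoform_cds(self, exon_indices: tuple[int, ...], seq: str) -> str:
        return "".join(
            seq[self.exon_spans[i][0] : self.exon_spans[i][1]] for i in exon_indices
        )

    def _internal_stop_free(self, seq: str) -> bool:
        for exons in self.spec.isoforms.values():
            cds = self._isoform_cds(exons, seq)
            for i in range(0, len(cds) - 3, 3):  # exclude the terminal codon
                if cds[i : i + 3] in STOP_CODONS:
                    return False
        return True

    def plant(self, plant: PlantSpec) -> None:
        ex_start, ex_end = self.exon_spans[plant.exon_index]
        site_sense = (
            plant.site if plant.pam_strand == "+" else reverse_complement(plant.site)
        )
        cut_delta = 17 if plant.pam_strand == "+" else 6

        def try_offset(offset: int) -> dict | None:
            p = ex_start + offset
            if p < 0 or p + 23 > len(self.sequence):
                return None
            cut_gene = p + cut_delta
            if not ex_start < cut_gene < ex_end:
                return None  # insertion must land inside this exon's CDS
            # keep start/stop codons intact
            if plant.exon_index == 0 and p < ex_start + 3:
                return None
            if plant.exon_index == len(self.exon_spans) - 1 and p + 23 > ex_end - 3:
                return None
            for other in self.planted:
                if not (p + 23 <= other["gene_pos"] or other["gene_pos"] + 23 <= p):
                    return None
            candidate = self.sequence[:p] + site_sense + self.sequence[p + 23 :]
            if not self._internal_stop_free(candidate):
                return None
            if plant.phase is not None and (offset + cut_delta) % 3 != plant.phase:
                return None
            return {"gene_pos": p, "cut_gene": cut_gene, "sequence": candidate}

        if plant.offset is not None:
            result = try_offset(plant.offset)
            if result is None:
                raise DesignError(
                    f"{self.spec.gene_id}: cannot plant guide at exon "
                    f"{plant.exon_index} offset {plant.offset} (conflict or "
                    "in-frame stop)"
                )
        else:
            result = None
            for offset in range(0, ex_end - ex_start):
                result = try_offset(offset)
                if result is not None:
                    break
            if result is None:
                raise DesignError(
                    f"{self.spec.gene_id}: no stop-free placement for guide in "
                    f"exon {plant.exon_index}"
                    + (f" at phase {plant.phase}" if plant.phase is not None else "")
                )
        self.sequence = result["sequence"]
        coverage = [
            iso
            for iso, exons in self.spec.isoforms.items()
            if plant.exon_index in exons
        ]
        self.planted.append(
            {
                "spec": plant,
                "gene_pos": result["gene_pos"],
                "cut_gene": result["cut_gene"],
                "isoform_coverage": coverage,
            }
        )


def _wrap_fasta(name: str, seq: str, width: int = 60) -> str:
    lines = [f">{name}"]
    lines.extend(seq[i : i + width] for i in range(0, len(seq), width))
    return "\n".join(lines) + "\n"


def make_fixture(spec: FixtureSpec) -> tuple[str, str, dict]:
    """Build (FASTA text, GFF3 text, manifest) for a fixture spec.

    The manifest lists every planted guide's genomic span, chromosome PAM
    strand, cut coordinate, and isoform coverage, plus per-gene placement.
    Raises :class:`DesignError` when the spec cannot be realized (genes do
    not fit, a guide has no stop-free placement, or a planted site fails its
    uniqueness guarantee after several background re-draws).
    """
    last_error: Exception | None = None
    for attempt in range(6):
        rng = random.Random(spec.seed + 7919 * attempt)
        try:
            return _make_fixture_once(spec, rng)
        except DesignError as exc:
            if "uniqueness guarantee" not in str(exc):
                raise
            last_error = exc
    raise DesignError(f"fixture generation failed repeatedly: {last_error}")


def _make_fixture_once(spec: FixtureSpec, rng: random.Random) -> tuple[str, str, dict]:
    builds: list[tuple[int, _GeneBuild]] = []
    cursor = spec.gene_start
    for gene_spec in spec.genes:
        build = _GeneBuild(gene_spec, rng)
        for plant in gene_spec.guides:
            build.plant(plant)
        glen = len(build.sequence)
        if cursor + glen + spec.gene_spacing > spec.chrom_length:
            raise DesignError(
                f"gene {gene_spec.gene_id} does not fit on a chromosome of "
                f"length {spec.chrom_length}"
            )
        builds.append((cursor, build))
        cursor += glen + spec.gene_spacing

    background = _background(rng, spec.chrom_length)
    chrom = list(background)
    for g0, build in builds:
        gene_seq = (
            build.sequence
            if build.spec.strand == "+"
            else reverse_complement(build.sequence)
        )
        chrom[g0 : g0 + len(gene_seq)] = gene_seq
    chrom_seq = "".join(chrom)

    manifest: dict = {
        "chrom": spec.chrom,
        "chrom_length": spec.chrom_length,
        "seed": spec.seed,
        "genes": [],
        "guides": [],
    }
    gff_lines = ["##gff-version 3"]
    for g0, build in builds:
        gspec = build.spec
        glen = len(build.sequence)

        def to_genomic(a: int, b: int) -> tuple[int, int]:
            if gspec.strand == "+":
                return g0 + a, g0 + b
            return g0 + glen - b, g0 + glen - a

        span_lo, span_hi = to_genomic(0, glen)
        gff_lines.append(
            f"{spec.chrom}\tstopin\tgene\t{span_lo + 1}\t{span_hi}\t.\t"
            f"{gspec.strand}\t.\tID={gspec.gene_id};Name={gspec.gene_id}"
        )
        iso_manifest = {}
        for iso, exon_indices in gspec.isoforms.items():
            gff_lines.append(
                f"{spec.chrom}\tstopin\tmRNA\t{span_lo + 1}\t{span_hi}\t.\t"
                f"{gspec.strand}\t.\tID={iso};Parent={gspec.gene_id}"
            )
            cum = 0
            intervals = []
            for i in exon_indices:
                a, b = build.exon_spans[i]
                lo, hi = to_genomic(a, b)
                intervals.append((lo, hi))
                phase = (3 - cum % 3) % 3
                cum += b - a
                for feat in ("exon", "CDS"):
                    gff_lines.append(
                        f"{spec.chrom}\tstopin\t{feat}\t{lo + 1}\t{hi}\t.\t"
                        f"{gspec.strand}\t{phase if feat == 'CDS' else '.'}\t"
                        f"ID={iso}.{feat}{i};Parent={iso}"
                    )
            iso_manifest[iso] = intervals
        manifest["genes"].append(
            {
                "gene_id": gspec.gene_id,
                "strand": gspec.strand,
                "gene_start": g0,
                "gene_length": glen,
                "isoform_cds": iso_manifest,
            }
        )
        for planted in build.planted:
            plant: PlantSpec = planted["spec"]
            p = planted["gene_pos"]
            s_lo, s_hi = to_genomic(p, p + 23)
            chrom_pam_strand = (
                plant.pam_strand if gspec.strand == "+" else
                ("-" if plant.pam_strand == "+" else "+")
            )
            cut_lo, cut_hi = to_genomic(planted["cut_gene"], planted["cut_gene"])
            manifest["guides"].append(
                {
                    "gene_id": gspec.gene_id,
                    "protospacer": plant.protospacer,
                    "pam": plant.pam,
                    "pam_strand": chrom_pam_strand,
                    "span_start": s_lo,
                    "span_end": s_hi,
                    "cut": cut_lo,
                    "isoform_coverage": planted["isoform_coverage"],
                    "expect_unique": plant.expect_unique,
                }
            )

    # uniqueness guarantee for planted sites
    for g in manifest["guides"]:
        site = g["protospacer"] + g["pam"]
        plus = site if g["pam_strand"] == "+" else reverse_complement(site)
        count = chrom_seq.count(plus) + chrom_seq.count(reverse_complement(plus))
        if g["expect_unique"] and count != 1:
            raise DesignError(
                f"planted guide {site} violates its uniqueness guarantee "
                f"(found {count} occurrences)"
            )
        g["genome_match_count"] = count

    fasta = _wrap_fasta(spec.chrom, chrom_seq)
    gff3 = "\n".join(gff_lines) + "\n"
    return fasta, gff3, manifest


def load_fixture(spec: FixtureSpec) -> tuple[Genome, list[GeneModel], dict]:
    """Generate a fixture and round-trip it through the FASTA/GFF3 loaders."""
    fasta, gff3, manifest = make_fixture(spec)
    with tempfile.TemporaryDirectory() as tmp:
        fa = Path(tmp) / "fixture.fa"
        gff = Path(tmp) / "fixture.gff3"
        fa.write_text(fasta)
        gff.write_text(gff3)
        genome = load_genome(str(fa))
        genes = load_annotation(str(gff), genome)
    return genome, genes, manifest


def guide_site_from_manifest(
    manifest_guide: dict, gene: GeneModel, genome: Genome
):
    """Locate the planted guide among a gene's scanned sites."""
    all_sites = find_guides(
        gene,
        genome,
        GuideQuery(require_all_isoforms=False, max_cds_fraction=1.0, require_unique=False),
    )
    for site in all_sites:
        if (
            site.span.start == manifest_guide["span_start"]
            and site.pam_strand == manifest_guide["pam_strand"]
        ):
            return site
    raise DesignError("planted guide not recovered by the scanner")


@dataclass
class EditedPair:
    """Matched wild-type/knock-in genomes with the plan that relates them."""

    wildtype: Genome
    knockin: Genome
    plan: EditPlan
    gene: GeneModel
    manifest: dict


def make_edited_pair(spec: FixtureSpec, guide_index: int = 0) -> EditedPair:
    """Convenience wrapper: fixture → guide → knock-in oligo → simulated HDR."""
    genome, genes, manifest = load_fixture(spec)
    if not manifest["guides"]:
        raise DesignError("spec contains no planted guides")
    mg = manifest["guides"][guide_index]
    gene = next(g for g in genes if g.gene_id == mg["gene_id"])
    site = guide_site_from_manifest(mg, gene, genome)
    plan = plan_knockin(site, gene, genome)
    edited = simulate_hdr(genome, plan)
    return EditedPair(
        wildtype=genome, knockin=edited, plan=plan, gene=gene, manifest=manifest
    )


# ---------------------------------------------------------------------------
# Ready-made specs used by the test suite and the CLI `fixtures` command.

AEX2_GUIDE = "ATTACTGCAGCGACATGGGG"


def aex2_like_spec(seed: int = 7) -> FixtureSpec:
    """A six-exon plus-strand gene carrying the aex-2 guide in exon 3."""
    gene = GeneSpec(
        gene_id="aex-2-like",
        strand="+",
        exon_cds_lengths=(60, 90, 120, 90, 90, 60),
        intron_length=50,
        guides=[PlantSpec(protospacer=AEX2_GUIDE, pam="CGG", exon_index=2)],
    )
    return FixtureSpec(seed=seed, genes=[gene], chrom_length=8000)


def coverage_spec(seed: int = 11) -> FixtureSpec:
    """Genes covering strand x PAM-strand x insertion-phase combinations,
    plus a two-isoform gene with a shared and an unshared exon."""
    genes: list[GeneSpec] = []
    # T-free protospacers cannot form a stop codon in either orientation,
    # so they plant cleanly at any forced insertion phase
    guide_pool = [
        "ACGACGGACAGCAAGCA",
        "CAGCACGAAGCAGACGA",
        "GACAGGCAACGAAGCAG",
        "AGCAACGGAGACAGCAA",
    ]
    idx = 0
    for strand in "+-":
        for pam_strand in "+-":
            plants = [
                PlantSpec(
                    protospacer=guide_pool[idx % len(guide_pool)] + _phase_tag(ph),
                    pam="CGG",
                    pam_strand=pam_strand,
                    exon_index=ex,
                    phase=ph,
                )
                for ph, ex in zip((0, 1, 2), (0, 1, 2))
            ]
            genes.append(
                GeneSpec(
                    gene_id=f"g{strand}{pam_strand}".replace("+", "p").replace("-", "m"),
                    strand=strand,
                    exon_cds_lengths=(120, 120, 120),
                    intron_length=55,
                    guides=plants,
                )
            )
            idx += 1
    genes.append(
        GeneSpec(
            gene_id="iso2",
            strand="+",
            exon_cds_lengths=(90, 90, 90, 90),
            intron_length=50,
            isoforms={"iso2.a": (0, 1, 2, 3), "iso2.b": (0, 2, 3)},
            guides=[
                PlantSpec("AGCAGACGGAACAGCAGCAA", "AGG", "+", exon_index=1),
                PlantSpec("CAAGACGGCAGCAAGACGCA", "AGG", "+", exon_index=2),
            ],
        )
    )
    return FixtureSpec(seed=seed, genes=genes, chrom_length=16000)


def _phase_tag(phase: int) -> str:
    # distinct T-free 3-nt tails so sibling guides in one gene never collide
    return {0: "ACA", 1: "CAA", 2: "AGA"}[phase]
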