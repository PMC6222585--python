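"""PCR/RFLP genotyping-assay design and simulation.

The screen uses two reactions per animal: gene-specific outer primers (P1,
P3) flanking the insertion give a 43-bp band shift between wild-type and
knock-in alleles (the amplicon is kept under 500 bp so the shift resolves on
an agarose gel), and the universal inner primer (P2, binding inside the
cassette) with P1 reports presence of the cassette at all. NheI digestion of
the outer amplicon is an orthogonal RFLP check. Primer binding is modeled as
exact match only — the goal is a deterministic in-silico gel, not
thermodynamic realism.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.SeqUtils import MeltingTemp, gc_fraction

from stopin.cassette import CASSETTE_SEQUENCE, NHEI_SITE
from stopin.errors import DesignError
from stopin.genome_model import GeneModel, Genome, reverse_complement

UNIVERSAL_INNER_PRIMER = "GCTTATCACTTAGTCACCTCTGCTC"


def universal_inner_primer() -> str:
    """The common reverse inner primer; binds only cassette-bearing templates."""
    return UNIVERSAL_INNER_PRIMER


@dataclass
class Primer:
    sequence: str
    chrom: str
    start: int  # plus-strand footprint, half-open
    end: int
    strand: str  # strand the primer sequence is written on
    tm: float
    gc: float


@dataclass
class PrimerPair:
    """Outer primer pair plus the predicted product sizes of both reactions."""

    p1_forward: Primer
    p3_reverse: Primer
    wt_product_size: int
    ki_product_size: int
    p2: str = UNIVERSAL_INNER_PRIMER
    inner_product_size: int | None = None


@dataclass
class PrimerConstraints:
    """Primer-design constraints; Tm is a nearest-neighbor estimate computed
    at 50 mM Na+ and 250 nM primer (defaults of the estimator used)."""

    length_min: int = 18
    length_max: int = 25
    gc_min: float = 0.40
    gc_max: float = 0.60
    tm_min: float = 52.0
    tm_max: float = 62.0
    product_cap: int = 500
    uniqueness_window: int = 5000
    search_margin: int = 20  # closest primer 3' end to the insertion point


def _find_all(haystack: str, needle: str) -> list[int]:
    out, start = [], 0
    while True:
        idx = haystack.find(needle, start)
        if idx < 0:
            return out
        out.append(idx)
        start = idx + 1


def simulate_pcr(
    template: Genome | str,
    forward: str,
    reverse: str,
    max_product: int = 5000,
) -> list[int]:
    """Exact-match PCR: product sizes for every convergent primer placement.

    Each primer may bind either strand; a product requires the two primers on
    opposite strands pointing toward each other. Size is measured 5' end of
    one footprint to 5' end of the other, inclusive of both. No binding
    yields an empty list.
    """
    if len(forward) < 15 or len(reverse) < 15:
        raise DesignError("primers must be at least 15 nt")
    seqs = template.sequences.values() if isinstance(template, Genome) else [template]
    sizes: list[int] = []
    for seq in seqs:
        for plus, minus in ((forward, reverse), (reverse, forward)):
            plus_hits = _find_all(seq, plus)
            minus_hits = _find_all(seq, reverse_complement(minus))
            for i in plus_hits:
                for j in minus_hits:
                    size = j + len(minus) - i
                    if j >= i and max(len(plus), len(minus)) <= size <= max_product:
                        sizes.append(size)
    return sorted(set(sizes))


def nhei_digest(amplicon: str) -> list[int]:
    """Fragment sizes after cutting every GCTAGC between site bases 1 and 2
    (G^CTAGC). Fragments always sum to the amplicon length."""
    cuts = [pos + 1 for pos in _find_all(amplicon, NHEI_SITE)]
    bounds = [0] + cuts + [len(amplicon)]
    return [b - a for a, b in zip(bounds, bounds[1:]) if b > a]


def _count_in_window(seq: str, primer: str) -> int:
    return len(_find_all(seq, primer)) + len(_find_all(seq, reverse_complement(primer)))


def _candidates(
    seq: str,
    lo: int,
    hi: int,
    strand: str,
    chrom: str,
    constraints: PrimerConstraints,
    window_seq: str,
) -> tuple[list[Primer], dict[str, int]]:
    """Enumerate primers with footprints inside [lo, hi); track why
    candidates were rejected for failure reporting."""
    rejected = {"gc_content": 0, "melting_temperature": 0, "uniqueness": 0}
    out: list[Primer] = []
    for length in range(constraints.length_min, constraints.length_max + 1):
        for start in range(lo, hi - length + 1):
            footprint = seq[start : start + length]
            if "N" in footprint:
                continue
            gc = gc_fraction(footprint)
            if not constraints.gc_min <= gc <= constraints.gc_max:
                rejected["gc_content"] += 1
                continue
            primer_seq = footprint if strand == "+" else reverse_complement(footprint)
            tm = MeltingTemp.Tm_NN(primer_seq)
            if not constraints.tm_min <= tm <= constraints.tm_max:
                rejected["melting_temperature"] += 1
                continue
            if _count_in_window(window_seq, primer_seq) != 1:
                rejected["uniqueness"] += 1
                continue
            out.append(
                Primer(primer_seq, chrom, start, start + length, strand, tm, gc)
            )
    return out, rejected


def pick_outer_primers(
    gene: GeneModel,
    insertion_point: int,
    genome: Genome,
    constraints: PrimerConstraints | None = None,
) -> PrimerPair:
    """Choose gene-specific outer primers bracketing the insertion point.

    Deterministic: candidates within the length/GC/Tm bounds and unique in a
    ±``uniqueness_window`` region are scored by distance from a 57 °C target
    Tm, ties broken by smaller product then coordinates. The wild-type
    product is kept under ``product_cap``; the knock-in product is 43 bp
    larger. On failure a :class:`DesignError` names the violated constraint.
    """
    if constraints is None:
        constraints = PrimerConstraints()
    seq = genome.sequences[gene.chrom]
    ins = insertion_point
    half = constraints.product_cap // 2
    if ins < 200 or ins + 200 > len(seq):
        raise DesignError("need at least 200 bp of reference on each side")

    wlo = max(0, ins - constraints.uniqueness_window)
    whi = min(len(seq), ins + constraints.uniqueness_window)
    window_seq = seq[wlo:whi]

    f_lo = max(0, ins - half)
    f_hi = ins - constraints.search_margin
    r_lo = ins + constraints.search_margin
    r_hi = min(len(seq), ins + half)
    fwd, rej_f = _candidates(seq, f_lo, f_hi, "+", gene.chrom, constraints, window_seq)
    rev, rej_r = _candidates(seq, r_lo, r_hi, "-", gene.chrom, constraints, window_seq)

    def fail(rejections: dict[str, int], side: str) -> DesignError:
        worst = max(rejections, key=rejections.get)
        return DesignError(
            f"no {side} primer satisfies the constraints; most candidates "
            f"violated: {worst} ({rejections})"
        )

    if not fwd:
        raise fail(rej_f, "forward")
    if not rev:
        raise fail(rej_r, "reverse")

    best: tuple | None = None
    for f in fwd:
        for r in rev:
            product = r.end - f.start
            if product >= constraints.product_cap:
                continue
            score = abs(f.tm - 57.0) + abs(r.tm - 57.0) + abs(f.tm - r.tm)
            key = (score, product, f.start, r.end)
            if best is None or key < best[0]:
                best = (key, f, r)
    if best is None:
        raise DesignError(
            f"no primer pair yields a wild-type product under "
            f"{constraints.product_cap} bp (product_size constraint)"
        )
    _, f, r = best
    wt_size = r.end - f.start
    pair = PrimerPair(
        p1_forward=f,
        p3_reverse=r,
        wt_product_size=wt_size,
        ki_product_size=wt_size + 43,
    )
    # inner-reaction product on the knock-in template: P2 pairs with
    # whichever outer primer sits 5' of the cassette on the gene's sense strand
    insert_plus = (
        CASSETTE_SEQUENCE if gene.strand == "+" else reverse_complement(CASSETTE_SEQUENCE)
    )
    local_lo = max(0, f.start - 10)
    ki_local = (
        seq[local_lo:ins] + insert_plus + seq[ins : min(len(seq), r.end + 10)]
    )
    outer = f.sequence if gene.strand == "+" else r.sequence
    inner_sizes = simulate_pcr(ki_local, outer, UNIVERSAL_INNER_PRIMER)
    pair.inner_product_size = inner_sizes[0] if inner_sizes else None
    return pair


@dataclass
class BandPattern:
    """Band sizes per reaction for one (possibly diploid) animal."""

    outer: list[int] = field(default_factory=list)
    inner: list[int] = field(default_factory=list)


def diploid_band_pattern(
    pair: PrimerPair, allele_templates: list[Genome | str], max_product: int = 5000
) -> BandPattern:
    """Simulate both genotyping reactions over a set of allele templates;
    the pattern is the union of per-allele bands (as on a gel)."""
    outer: set[int] = set()
    inner: set[int] = set()
    for template in allele_templates:
        outer.update(
            simulate_pcr(template, pair.p1_forward.sequence, pair.p3_reverse.sequence, max_product)
        )
        for outer_primer in (pair.p1_forward.sequence, pair.p3_reverse.sequence):
            inner.update(simulate_pcr(template, outer_primer, pair.p2, max_product))
    return BandPattern(outer=sorted(outer), inner=sorted(inner))


@dataclass(frozen=True)
class GenotypeCall:
    call: str  # wild-type | heterozygous | homozygous-candidate | ambiguous
    confirm_next_generation: bool = False


def classify_f1(
    outer_bands: BandPattern | list[int],
    inner_bands: BandPattern | list[int],
    wt_size: int,
    ki_size: int,
) -> GenotypeCall:
    """Genotype call from the two screening reactions.

    Inner product + both outer bands → heterozygous; inner product + only
    the larger band → homozygous candidate (flagged for confirmation in the
    next generation, since a deletion allele can mask the wild-type band);
    no inner product + wild-type band → wild type; anything else ambiguous.
    """
    outer = set(outer_bands.outer if isinstance(outer_bands, BandPattern) else outer_bands)
    inner = set(inner_bands.inner if isinstance(inner_bands, BandPattern) else inner_bands)
    inner_present = bool(inner)
    if inner_present and outer == {wt_size, ki_size}:
        return GenotypeCall("heterozygous")
    if inner_present and outer == {ki_size}:
        return GenotypeCall("homozygous-candidate", confirm_next_generation=True)
    if not inner_present and outer == {wt_size}:
        return GenotypeCall("wild-type")
    return GenotypeCall("ambiguous")
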