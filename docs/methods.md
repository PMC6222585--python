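# Methods

## The editing model

The toolkit models S. pyogenes Cas9 knock-in by homology-directed repair
(HDR) from a single-stranded oligo donor. Cas9 recognizes a 20-nt
protospacer followed by an NGG PAM and cuts bluntly 3 bp 5' of the PAM,
i.e. between protospacer bases 17 and 18. All design arithmetic flows from
that single coordinate: the insertion point of the cassette, the homology
arms, the primer placements, and the post-edit transcript models.

Repair is modeled as *perfect*: the cassette (or, for reversion, nothing)
replaces exactly the planned span with zero junction errors. Error-prone
NHEJ outcomes, partial repair (gel bands slightly smaller than predicted),
and two-allele F1 mosaics are real screening phenomena but are intentionally
out of scope; the screen's genotype caller flags apparent homozygotes for
next-generation confirmation precisely because the model cannot exclude a
masking deletion allele.

### Why the cassette makes nulls regardless of frame

The 43-nt cassette carries stop codons in all three reading frames (two in
frames 1 and 2, one in frame 3), so whatever the phase of the insertion
point, the first in-frame stop appears within at most 45 nt of the
junction. Independently, 43 ≡ 1 (mod 3) guarantees a frameshift of every
downstream codon, a second kill switch that survives stop-codon
readthrough. The verification module checks both properties per isoform by
rebuilding spliced transcripts from the edited genome rather than by
trusting the arithmetic — insertions that miss an isoform's CDS are
reported as "unaffected", supporting deliberate isoform-specific designs.

### Strand logic

The ssODN is synthesized on the same chromosome strand as the PAM (the
empirically more efficient donor orientation when inserting at the cut).
The payload orientation is then forced by one invariant: *after repair the
gene's sense strand must read the canonical cassette 5'→3'*. When the PAM
strand equals the sense strand the oligo carries the cassette as written;
otherwise it carries the reverse complement. The test suite asserts the
sense-strand invariant for all four gene-strand × PAM-strand combinations.

## Coordinates and conventions

* Internal coordinates are 0-based half-open on the plus strand everywhere;
  GFF3's 1-based inclusive convention is converted only at the I/O
  boundary. Insertion points are "between-base" coordinates.
* Spliced CDS is the concatenation of CDS features in transcription order
  (reverse-complemented for minus-strand genes); the annotated stop codon is
  included iff the annotation includes it. CDS phase fields in GFF3 are
  ignored and frame is recomputed from structure.
* Stop codons are TAA/TAG/TGA (standard nuclear code); frames are numbered
  1–3 in reports, 0–2 internally. `N` bases are preserved but match nothing
  during guide scanning and translate to X.
* "Early exon" is operationalized as a cut within the first half of the
  spliced CDS (`max_cds_fraction = 0.5`, configurable). The fraction is
  evaluated in the shortest isoform containing the cut, the conservative
  choice when isoform lengths differ.
* Ranking ties break by genomic coordinate, then + before −, so CLI output
  is reproducible.
* Off-target assessment is exact-match counting of the 23-mer on both
  strands (`genome_match_count`), a uniqueness proxy rather than a
  mismatch-tolerant specificity score; users wanting Doench/CRISPOR-style
  scoring should use a dedicated scorer and feed the chosen guide back in.

## Tunable parameters

| Parameter | Default | Meaning |
|---|---|---|
| `arm_len` | 35 nt | homology arm on each side of the cut (oligo = 2·35+43 = 113 nt) |
| reversion `total_len` | 71 nt | wild-type oligo, split 35 nt 5' / 36 nt 3' of the junction on the sense strand (the split is a recorded design choice; only the total is canonical) |
| `max_cds_fraction` | 0.5 | "early exon" cutoff for ranking/filtering |
| primer length / GC / Tm | 18–25 nt, 40–60%, 52–62 °C | outer-primer constraints; Tm is a nearest-neighbor estimate at the estimator's default 50 mM Na+, 250 nM primer |
| `product_cap` | 500 bp | cap on the wild-type outer amplicon so the 43-bp shift resolves on 2.5% agarose; the knock-in product (cap+43) is reported but not capped |
| uniqueness window | ±5 kb | region in which each outer primer must bind once |

Primer binding in the PCR simulator is exact-match with convergent
orientation; product size spans both primer footprints (the gel-observable
length). NheI cuts G^CTAGC; fragment sizes always sum to the amplicon
length.

## Screen statistics

Per-experiment efficiency is `n_ki / n_genotyped` expressed as an integer
percent, rounded half away from zero — the only rule consistent with every
published per-gene value (87.5 → 88, 62.5 → 63) — computed with exact
rational arithmetic. Pooled efficiency sums counts before dividing (never
averages row percents); over the packaged 22-experiment table this yields
322/694 = 46%. The lethal vs non-lethal comparison is an uncorrected
Pearson chi-square on the 2×2 knock-in-by-group table (Yates correction
available by flag; with these counts both versions are significant far
below 10⁻⁴). The packaged table stores counts only; percentages are always
recomputed. No correction is attempted for the known ascertainment bias
against lethal genes (F1 animals with two loss-of-function alleles are not
recovered); the caveat is attached to the injection-mix report as text.

## Synthetic fixtures

The generator emulates what the designs care about — genes on both strands,
multi-exon and multi-isoform structures, guides with either PAM orientation
and any insertion phase, guides overhanging exon/intron boundaries, loci
embedding real screen guides verbatim — and nothing else. It does not
mimic real chromosome composition, codon usage, repeats, splice-site
motifs, or UTRs.

Two constructions keep ground truth exact. First, all background sequence
(and wild-type CDS) is sampled base-by-base rejecting any GG or CC
dinucleotide, so it can contain no NGG PAM on either strand; planted sites
are therefore the only guide-producing sequences apart from windows
overlapping a planting. Second, exon CDS lengths are multiples of three and
isoforms differ only by skipping internal exons, so every isoform is ATG-
initiated, internally stop-free, and shares the terminal stop — letting
tests assert "wild type translates cleanly" and "the edit creates the first
premature stop" with equality rather than tolerance. Planted guides are
placed by a deterministic search for a stop-free, phase-correct offset, and
every planted 23-mer is verified unique genome-wide (with bounded
background re-draws on collision). A JSON manifest of planted truths is the
single source of coordinates for the oracle tests.

Consequently, passing tests demonstrate correctness of the design
arithmetic and simulators on structurally faithful loci; they say nothing
about wet-lab efficiency, chromatin context, or guide activity on real
genomes.

## Problem sizes and determinism

Fixture chromosomes are 8–16 kb with 5–6 genes and 14–15 planted guides —
large enough to exercise every combination (gene strand × PAM strand ×
three insertion phases × shared/unshared exons) while keeping brute-force
oracle scans (every 23-nt window of the chromosome) exact and fast. The
null-guarantee sweep draws 1,000 random insertion positions across fixture
transcripts. All randomness flows through explicitly seeded generators;
identical seeds give byte-identical FASTA/GFF3 output.

## Known limitations

* No NHEJ modeling, no partial-repair artifacts, no crRNA chemistry or
  on-target activity scores.
* Exact-match primer binding: no mismatch tolerance, 3'-end rules,
  primer-dimer or secondary-structure checks.
* CDS-only gene models: no UTRs, trans-splicing, or operons.
* "Putative null" is a structural label (premature stop early in the CDS of
  all required isoforms); phenotypic nullness requires genetics.
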