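"""The universal 43-nt STOP-IN cassette and its reading-frame anatomy.

The cassette is a fixed insert that renders any coding sequence a putative
null regardless of the reading frame at the insertion point:

* stop codons in all three frames (two in frames 1 and 2, one in frame 3),
* length 43 = 1 mod 3, so readthrough still frameshifts everything downstream,
* a 23-nt exogenous Cas9 target (protospacer + AGG PAM) for later re-editing,
* an NheI site (GCTAGC) for RFLP genotyping,
* the reverse complement of the universal inner genotyping primer.
"""

from __future__ import annotations

from dataclasses import dataclass

from stopin.errors import StopinError
from stopin.genome_model import reverse_complement

CASSETTE_SEQUENCE = "GGGAAGTTTGTCCAGAGCAGAGGTGACTAAGTGATAAGCTAGC"

#: Reverse inner genotyping primer (oHP013r); binds only cassette-bearing templates.
_UNIVERSAL_INNER_PRIMER = "GCTTATCACTTAGTCACCTCTGCTC"

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

NHEI_SITE = "GCTAGC"


@dataclass(frozen=True)
class FrameReport:
    """Stop-codon content of a sequence read in all three frames.

    ``stop_counts[f]`` and ``first_stop_offset[f]`` are keyed by frame offset
    0/1/2 (reported to users as frames 1/2/3); offsets are 0-based positions
    of the first base of the stop codon. ``net_frameshift`` is length mod 3.
    """

    stop_counts: dict[int, int]
    first_stop_offset: dict[int, int | None]
    net_frameshift: int

    def as_frame_numbers(self) -> dict[int, int]:
        """Stop counts keyed by 1-based frame number, for display."""
        return {f + 1: self.stop_counts[f] for f in range(3)}


def frame_report(seq: str) -> FrameReport:
    """Scan non-overlapping codons at offsets 0, 1, 2 and count stops."""
    if len(seq) < 3:
        raise StopinError("frame_report requires a sequence of length >= 3")
    counts: dict[int, int] = {}
    firsts: dict[int, int | None] = {}
    for f in range(3):
        stops = [
            i for i in range(f, len(seq) - 2, 3) if seq[i : i + 3] in STOP_CODONS
        ]
        counts[f] = len(stops)
        firsts[f] = stops[0] if stops else None
    return FrameReport(counts, firsts, len(seq) % 3)


@dataclass(frozen=True)
class Cassette:
    """A stop cassette with its annotated sub-features (half-open spans)."""

    sequence: str
    exogenous_target: tuple[int, int]  # protospacer + PAM
    pam: tuple[int, int]
    nhei_span: tuple[int, int]
    universal_primer_site: tuple[int, int]

    @property
    def protospacer(self) -> str:
        start, _ = self.exogenous_target
        return self.sequence[start : self.pam[0]]

    @property
    def pam_sequence(self) -> str:
        return self.sequence[self.pam[0] : self.pam[1]]

    @property
    def exogenous_site(self) -> str:
        """Protospacer + PAM, the crRNA target used for reversion edits."""
        return self.sequence[self.exogenous_target[0] : self.exogenous_target[1]]

    def frames(self) -> FrameReport:
        return frame_report(self.sequence)


def canonical_cassette() -> Cassette:
    """The 43-nt STOP-IN constant with all sub-features located.

    The exogenous Cas9 target is the first 23 nt (protospacer = first 20,
    PAM = AGG at positions 20-23); the NheI site is the terminal 6 nt; the
    inner-primer site is located by searching for the reverse complement of
    the universal primer.
    """
    seq = CASSETTE_SEQUENCE
    primer_rc = reverse_complement(_UNIVERSAL_INNER_PRIMER)
    site = seq.find(primer_rc)
    if site < 0:  # pragma: no cover - constant property
        raise StopinError("universal primer site missing from cassette constant")
    return Cassette(
        sequence=seq,
        exogenous_target=(0, 23),
        pam=(20, 23),
        nhei_span=(seq.rindex(NHEI_SITE), seq.rindex(NHEI_SITE) + 6),
        universal_primer_site=(site, site + len(primer_rc)),
    )


@dataclass
class IntegrityReport:
    """Outcome of :func:`verify_cassette_integrity`: named checks with results."""

    checks: dict[str, bool]
    details: dict[str, str]

    @property
    def passed(self) -> bool:
        return all(self.checks.values())

    @property
    def failures(self) -> list[str]:
        return [name for name, ok in self.checks.items() if not ok]


def _count_occurrences(haystack: str, needle: str) -> int:
    count = start = 0
    while True:
        idx = haystack.find(needle, start)
        if idx < 0:
            return count
        count += 1
        start = idx + 1


def verify_cassette_integrity(cassette: Cassette) -> IntegrityReport:
    """Check a cassette against its design-critical properties.

    The canonical cassette must pass every check. A user-supplied variant
    (anything whose sequence differs from the canonical constant) is held
    only to the modification-tolerant core: at least one stop per frame, a
    net frameshift, an exogenous target ending in GG, and a unique
    restriction site.
    """
    seq = cassette.sequence
    checks: dict[str, bool] = {}
    details: dict[str, str] = {}
    report = frame_report(seq) if len(seq) >= 3 else None

    checks["stops_in_all_frames"] = bool(report) and all(
        report.stop_counts[f] >= 1 for f in range(3)
    )
    checks["frameshift"] = len(seq) % 3 != 0
    details["frameshift"] = f"length {len(seq)} mod 3 = {len(seq) % 3}"
    target = seq[cassette.exogenous_target[0] : cassette.exogenous_target[1]]
    checks["exogenous_target_pam"] = target.endswith("GG") and len(target) == 23
    nhei = seq[cassette.nhei_span[0] : cassette.nhei_span[1]]
    checks["restriction_site"] = (
        nhei == NHEI_SITE and _count_occurrences(seq, NHEI_SITE) == 1
    )

    if seq == CASSETTE_SEQUENCE:
        checks["canonical_sequence"] = True
        checks["length_43"] = len(seq) == 43
        checks["stop_counts_2_2_1"] = bool(report) and [
            report.stop_counts[f] for f in range(3)
        ] == [2, 2, 1]
        primer_rc = reverse_complement(_UNIVERSAL_INNER_PRIMER)
        checks["universal_primer_site"] = _count_occurrences(seq, primer_rc) == 1
        checks["nhei_at_3_prime_end"] = seq.endswith(NHEI_SITE)
    return IntegrityReport(checks, details)
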