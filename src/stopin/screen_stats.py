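"""Screen-efficiency accounting for STOP-IN knock-in experiments.

The unit of observation is one genome-editing experiment for one gene: the
number of co-converted F1 plates genotyped and the number carrying the
knock-in. Per-gene efficiency is n_ki / n_genotyped rounded half away from
zero to an integer percent (the convention that reproduces every published
per-gene value, e.g. 21/24 = 87.5 → 88). Pooling sums counts before taking
the percent; it is never the mean of row percents. Lethal-candidate genes
(those that could not be homozygosed) are compared to the rest with an
uncorrected Pearson chi-square on the 2x2 knock-in-by-group table. The
packaged screen table stores counts, not percentages — percentages are
always recomputed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from fractions import Fraction
from importlib import resources
from typing import Callable, Iterable

import pandas as pd
from scipy import stats as sps

from stopin.errors import StopinError

MARKERS = ("dpy-10", "unc-58")


@dataclass(frozen=True)
class ScreenRecord:
    """One experiment row: gene, allele names, guide, screen counts."""

    gene: str
    alleles: str
    guide: str
    n_genotyped: int
    n_ki: int
    lethal: bool
    marker: str

    def __post_init__(self) -> None:
        if self.n_ki > self.n_genotyped:
            raise StopinError(
                f"{self.gene}: n_ki ({self.n_ki}) exceeds n_genotyped "
                f"({self.n_genotyped})"
            )
        if self.n_genotyped < 0 or self.n_ki < 0:
            raise StopinError(f"{self.gene}: negative counts")


def load_screen_table(path) -> list[ScreenRecord]:
    """Read a TSV with columns gene, alleles, guide, n_genotyped, n_ki,
    lethal (yes/no), marker."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"gene", "alleles", "guide", "n_genotyped", "n_ki", "lethal", "marker"}
    missing = required - set(df.columns)
    if missing:
        raise StopinError(f"screen table missing columns: {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        records.append(
            ScreenRecord(
                gene=row.gene,
                alleles=row.alleles,
                guide=row.guide,
                n_genotyped=int(row.n_genotyped),
                n_ki=int(row.n_ki),
                lethal=str(row.lethal).strip().lower() in ("yes", "true", "1"),
                marker=row.marker,
            )
        )
    return records


def packaged_screen_table() -> list[ScreenRecord]:
    """The bundled 22-experiment knock-in screen table."""
    with resources.files("stopin").joinpath("data/knockin_screen.tsv").open() as fh:
        return load_screen_table(fh)


def _percent(n_ki: int, n_genotyped: int) -> int:
    """Integer percent, rounded half away from zero (87.5 → 88, 62.5 → 63).

    Exact rational arithmetic avoids binary-float half-point surprises.
    """
    value = Fraction(100 * n_ki, n_genotyped)
    whole = value.numerator // value.denominator
    return whole + (1 if value - whole >= Fraction(1, 2) else 0)


def ki_percent(record: ScreenRecord) -> int:
    """Per-experiment knock-in efficiency as an integer percent."""
    if record.n_genotyped == 0:
        raise StopinError(f"{record.gene}: rate undefined for n_genotyped = 0")
    return _percent(record.n_ki, record.n_genotyped)


@dataclass(frozen=True)
class PooledEfficiency:
    percent: int
    n_total: int
    n_ki: int


def pooled_efficiency(
    records: Iterable[ScreenRecord],
    predicate: Callable[[ScreenRecord], bool] | None = None,
) -> PooledEfficiency:
    """Knock-in efficiency over pooled counts (sum first, then percent)."""
    selected = [r for r in records if predicate is None or predicate(r)]
    if not selected:
        raise StopinError("no records selected")
    n_total = sum(r.n_genotyped for r in selected)
    n_ki = sum(r.n_ki for r in selected)
    return PooledEfficiency(_percent(n_ki, n_total), n_total, n_ki)


@dataclass
class GroupComparison:
    """Pearson chi-square comparison of knock-in rates between two groups."""

    table: list[list[int]]  # rows: groups; cols: (ki, non-ki)
    chi_square_statistic: float
    p_value: float
    rates: dict[str, PooledEfficiency]
    yates_correction: bool


def compare_groups(
    records: Iterable[ScreenRecord],
    grouping: Callable[[ScreenRecord], bool] | None = None,
    labels: tuple[str, str] = ("lethal", "non-lethal"),
    yates_correction: bool = False,
) -> GroupComparison:
    """2x2 chi-square of (knock-in vs not) by group; default grouping is the
    lethal flag, default test is uncorrected Pearson with 1 df."""
    if grouping is None:
        grouping = lambda r: r.lethal  # noqa: E731
    records = list(records)
    group_a = [r for r in records if grouping(r)]
    group_b = [r for r in records if not grouping(r)]
    if not group_a or not group_b:
        raise StopinError("both groups must be non-empty")
    eff_a = pooled_efficiency(group_a)
    eff_b = pooled_efficiency(group_b)
    table = [
        [eff_a.n_ki, eff_a.n_total - eff_a.n_ki],
        [eff_b.n_ki, eff_b.n_total - eff_b.n_ki],
    ]
    result = sps.chi2_contingency(table, correction=yates_correction)
    if (result.expected_freq < 1).any():
        warnings.warn(
            "an expected cell count is below 1; consider an exact test",
            stacklevel=2,
        )
    return GroupComparison(
        table=table,
        chi_square_statistic=float(result.statistic),
        p_value=float(result.pvalue),
        rates={labels[0]: eff_a, labels[1]: eff_b},
        yates_correction=yates_correction,
    )


@dataclass(frozen=True)
class MixComponent:
    name: str
    amount: float
    units: str


@dataclass
class InjectionMix:
    """Ribonucleoprotein injection-mix recipe for one co-conversion marker."""

    marker: str
    components: list[MixComponent]
    annealing: list[MixComponent]
    caveat: str = (
        "knock-in efficiency for lethal genes may be underestimated: F1 "
        "animals carrying two loss-of-function alleles are not recovered"
    )


def injection_mix(marker: str) -> InjectionMix:
    """Injection-solution and crRNA-annealing recipe for dpy-10 or unc-58
    co-conversion."""
    if marker not in MARKERS:
        raise StopinError(f"unknown marker {marker!r}; supported: {MARKERS}")
    components = [
        MixComponent("Cas9 protein", 3.4, "ug/uL"),
        MixComponent("annealed guide RNA mixture", 45.9, "uM"),
        MixComponent("target-gene repair oligo", 0.51, "uM"),
        MixComponent(
            f"{marker} repair oligo", 0.25 if marker == "dpy-10" else 0.51, "uM"
        ),
    ]
    if marker == "dpy-10":
        annealing = [
            MixComponent("tracrRNA (100 uM)", 2.5, "uL"),
            MixComponent("dpy-10 crRNA (100 uM)", 0.5, "uL"),
            MixComponent("target-gene crRNA (100 uM)", 2.0, "uL"),
        ]
    else:
        annealing = [
            MixComponent("tracrRNA (100 uM)", 2.5, "uL"),
            MixComponent("unc-58 crRNA (100 uM)", 1.0, "uL"),
            MixComponent("target-gene crRNA (100 uM)", 1.5, "uL"),
        ]
    return InjectionMix(marker=marker, components=components, annealing=annealing)
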