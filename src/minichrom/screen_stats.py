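"""Kernel-screen fate tallies and derived frequencies.

The breakage screen follows kernels showing mosaic loss of the 9S
anthocyanin marker (a sign of 9-Bic-1 breakage) and records the fate of
the broken chromosome: fragment lost, translocated, recovered as an
isochromosome, or recovered as a heritable mini chromosome.  Percentages
are reported against the number of kernels with breakage signs; rates
against the total kernels screened are reported only when that denominator
is explicit.  Exact fractions are retained alongside two-decimal half-up
percentages.
"""
from __future__ import annotations

import csv
from dataclasses import dataclass, field
from fractions import Fraction
from importlib import resources

from ._util import round_half_up

FATES = ("lost", "translocation", "isochromosome", "mini_chromosome", "other")


@dataclass
class ScreenTally:
    kernels_screened: int
    kernels_with_breakage_signs: int
    fates: dict[str, int]
    b_derived_minis: int = 0

    def validate(self) -> None:
        if any(v < 0 for v in self.fates.values()) or self.b_derived_minis < 0 \
                or self.kernels_screened < 0 or self.kernels_with_breakage_signs < 0:
            raise ValueError("negative count")
        unknown = set(self.fates) - set(FATES)
        if unknown:
            raise ValueError(f"unknown fate categories: {sorted(unknown)}")
        total = sum(self.fates.values())
        if total != self.kernels_with_breakage_signs:
            raise ValueError(
                f"sum of fates ({total}) != kernels_with_breakage_signs "
                f"({self.kernels_with_breakage_signs})"
            )
        if self.b_derived_minis > self.fates.get("mini_chromosome", 0):
            raise ValueError("b_derived_minis exceeds fates[mini_chromosome]")


@dataclass
class ScreenReport:
    fate_fractions: dict[str, Fraction] = field(default_factory=dict)
    fate_percent: dict[str, float] = field(default_factory=dict)
    b_breakage_fraction: Fraction | None = None
    b_breakage_percent: float | None = None
    counts: dict[str, int] = field(default_factory=dict)
    b_derived_minis: int = 0
    denominator: int = 0  # kernels with breakage signs


def summarize_screen(tally: ScreenTally) -> ScreenReport:
    """Per-fate percentages and the B-breakage rate (two decimals, half-up)."""
    tally.validate()
    report = ScreenReport()
    denom = tally.kernels_with_breakage_signs
    if denom == 0:
        return report  # nothing screened positive; no division
    report.denominator = denom
    report.b_derived_minis = tally.b_derived_minis
    for fate, count in tally.fates.items():
        frac = Fraction(count, denom)
        report.counts[fate] = count
        report.fate_fractions[fate] = frac
        report.fate_percent[fate] = round_half_up(100.0 * float(frac), 2)
    report.b_breakage_fraction = Fraction(tally.b_derived_minis, denom)
    report.b_breakage_percent = round_half_up(100.0 * float(report.b_breakage_fraction), 2)
    return report


# ---------------------------------------------------------------------------
# TSV in/out
# ---------------------------------------------------------------------------


def read_tally_tsv(path_or_file) -> ScreenTally:
    if hasattr(path_or_file, "read"):
        rows = list(csv.reader(path_or_file, delimiter="\t"))
    else:
        with open(path_or_file) as fh:
            rows = list(csv.reader(fh, delimiter="\t"))
    values: dict[str, int] = {}
    for row in rows:
        if not row or row[0].startswith("#"):
            continue
        key, val = row[0].strip(), int(row[1])
        values[key] = val
    fates = {f: values.pop(f, 0) for f in FATES}
    return ScreenTally(
        kernels_screened=values.pop("kernels_screened", 0),
        kernels_with_breakage_signs=values.pop("kernels_with_breakage_signs", 0),
        fates=fates,
        b_derived_minis=values.pop("b_derived_minis", 0),
    )


def write_report_tsv(report: ScreenReport, path, header: list[str] | None = None) -> None:
    with open(path, "w") as fh:
        for line in header or []:
            fh.write(line + "\n")
        fh.write("quantity\tfraction\tpercent\n")
        for fate in report.fate_fractions:
            fh.write(f"{fate}\t{report.counts[fate]}/{report.denominator}"
                     f"\t{report.fate_percent[fate]:.2f}\n")
        if report.b_breakage_fraction is not None:
            fh.write(f"b_breakage\t{report.b_derived_minis}/{report.denominator}"
                     f"\t{report.b_breakage_percent:.2f}\n")


def study_screen_tally() -> ScreenTally:
    """The packaged screen tallies of the study lines."""
    with resources.files("minichrom").joinpath("data/screen_tally.tsv").open() as fh:
        return read_tally_tsv(fh)
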