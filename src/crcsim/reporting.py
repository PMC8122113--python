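"""Comparison reports: the scenario outcome table, percentage
reductions, unit scaling, and per-year series for plotting.

The headline table reports totals for individuals aged 40-100 over
2018-2050 in units of x10,000 persons/events, rounded half-up to two
decimals; percentage-reduction rows are computed from the table's own
(rounded) count rows, so the printed table is self-consistent by
construction.  Reductions are rendered at two decimals with trailing
zeros trimmed.  False positives are reported as a count and as a
percentage of positive tests (that definition is printed in the
report).  Total colonoscopy volume sums primary screening
colonoscopies, diagnostic follow-up colonoscopies and (flagged)
surveillance colonoscopies.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .params import ModelParams
from .scenario_engine import AnnualOutcomes

__all__ = [
    "compute_reduction",
    "round_half_up",
    "scale_units",
    "format_count",
    "OutcomeTable",
    "annual_series",
]

WINDOW_YEARS = (2018, 2050)
WIDE_AGES = (40, 100)
CORE_AGES = (50, 74)


def round_half_up(x: float, decimals: int = 2) -> float:
    """Decimal round-half-up (so 0.125 -> 0.13 at 2 dp), as rendered in
    the outcome table."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def compute_reduction(reference_count: float, scenario_count: float, decimals: int | None = None) -> float:
    """Percent reduction of a scenario count versus the no-screening
    reference: 100 x (reference - scenario) / reference.

    Undefined for a zero reference (the table renders such cells "-").
    """
    if reference_count <= 0:
        raise ValueError("reduction undefined for a nonpositive reference count")
    pct = 100.0 * (reference_count - scenario_count) / reference_count
    return pct if decimals is None else round_half_up(pct, decimals)


def scale_units(count_in_10k: float) -> int:
    """Convert a x10,000 table value to an absolute count."""
    if count_in_10k < 0:
        raise ValueError("counts cannot be negative")
    return int(round_half_up(count_in_10k * 10_000.0, 0))


def format_count(count: int) -> str:
    """Absolute count with thousands separators (482,700)."""
    return f"{int(count):,}"


def _fmt2(x: float) -> str:
    return f"{round_half_up(x, 2):.2f}"


def _fmt_reduction(x: float) -> str:
    s = f"{round_half_up(x, 2):.2f}".rstrip("0").rstrip(".")
    return s if s else "0"


@dataclass
class OutcomeTable:
    """The scenario-comparison table (rows x scenario columns).

    Count rows hold floats in x10,000 units (already rounded to 2 dp);
    reduction rows are recomputed from those rounded counts.  Rendering
    is deterministic: regenerating from the same outcomes is
    byte-identical.
    """

    frame: pd.DataFrame  # formatted strings, index = row labels
    values: pd.DataFrame  # numeric x10,000 count rows (NaN where "-")

    @classmethod
    def from_outcomes(
        cls,
        outcomes: dict,
        params: ModelParams,
        scenarios: list,
        reference_label: str | None = None,
        include_surveillance: bool = True,
    ) -> "OutcomeTable":
        labels = [sc.label for sc in scenarios]
        by_label = {sc.label: sc for sc in scenarios}
        if reference_label is None:
            refs = [sc.label for sc in scenarios if sc.design is None]
            if not refs:
                raise ValueError("a comparison set must include a no-screening scenario")
            reference_label = refs[0]

        y0, y1 = WINDOW_YEARS
        pop40 = float(params.pyramid.count[params.pyramid.age >= WIDE_AGES[0]].sum())
        rows: dict = {}
        vals: dict = {}

        def count_row(name, fn, render=None):
            vals[name] = {}
            rows[name] = {}
            for lab in labels:
                v = fn(outcomes[lab], by_label[lab])
                if v is None:
                    rows[name][lab] = "-"
                    vals[name][lab] = np.nan
                else:
                    v = round_half_up(v / 1e4, 2)
                    vals[name][lab] = v
                    rows[name][lab] = _fmt2(v) if render is None else render(v)

        def reduction_row(name, count_name):
            rows[name] = {}
            ref = vals[count_name][reference_label]
            for lab in labels:
                if lab == reference_label or not np.isfinite(vals[count_name][lab]) or ref <= 0:
                    rows[name][lab] = "-"
                else:
                    rows[name][lab] = _fmt_reduction(compute_reduction(ref, vals[count_name][lab]))

        count_row(f"Population aged {WIDE_AGES[0]}+ in {params.base_year}", lambda o, sc: pop40)
        count_row(
            f"Person-years, {y0}-{y1}",
            lambda o, sc: float(o.person_years_per_year(*WIDE_AGES).sum()) if o.person_years is not None else None,
        )
        a0, a1 = WIDE_AGES
        count_row(
            f"Colorectal cancer cases (age {a0}-{a1})",
            lambda o, sc: o.total("crc_cases", a0, a1, years=WINDOW_YEARS),
        )
        reduction_row(
            f"Colorectal cancer incidence reduction (%, {a0}-{a1}) vs no screening",
            f"Colorectal cancer cases (age {a0}-{a1})",
        )
        count_row(
            f"Colorectal cancer deaths (age {a0}-{a1})",
            lambda o, sc: o.total("crc_deaths", a0, a1, years=WINDOW_YEARS),
        )
        reduction_row(
            f"Colorectal cancer mortality reduction (%, {a0}-{a1}) vs no screening",
            f"Colorectal cancer deaths (age {a0}-{a1})",
        )
        c0, c1 = CORE_AGES
        count_row(
            f"Colorectal cancer cases (age {c0}-{c1})",
            lambda o, sc: o.total("crc_cases", c0, c1, years=WINDOW_YEARS),
        )
        reduction_row(
            f"Colorectal cancer incidence reduction (%, {c0}-{c1}) vs no screening",
            f"Colorectal cancer cases (age {c0}-{c1})",
        )
        count_row(
            f"Colorectal cancer deaths (age {c0}-{c1})",
            lambda o, sc: o.total("crc_deaths", c0, c1, years=WINDOW_YEARS),
        )
        reduction_row(
            f"Colorectal cancer mortality reduction (%, {c0}-{c1}) vs no screening",
            f"Colorectal cancer deaths (age {c0}-{c1})",
        )

        for test in ("gFOBT", "FIT", "FS", "colonoscopy"):
            count_row(
                f"Primary screening tests: {test}",
                lambda o, sc, test=test: o.total(f"tests_{test}", years=WINDOW_YEARS),
            )
        count_row("Positive screening tests", lambda o, sc: o.total("positives", years=WINDOW_YEARS))

        def followups(o, sc):
            if sc.design is not None and params.tests[sc.design.test_name].is_direct_visualization:
                return None  # the positive result is already the colonoscopy
            return o.total("followup_colonoscopies", years=WINDOW_YEARS)

        count_row("Diagnostic follow-up colonoscopies performed", followups)
        count_row("False-positive tests", lambda o, sc: o.total("false_positives", years=WINDOW_YEARS))

        rows["False positives (% of positive tests)"] = {}
        for lab in labels:
            pos = vals["Positive screening tests"][lab]
            fp = vals["False-positive tests"][lab]
            if pos and pos > 0:
                rows["False positives (% of positive tests)"][lab] = _fmt_reduction(100.0 * fp / pos)
            else:
                rows["False positives (% of positive tests)"][lab] = "0" if by_label[lab].design is not None else "-"

        def complications(o, sc):
            return sum(
                o.total(f"complications_{c}", years=WINDOW_YEARS)
                for c in ("serious", "cardiovascular", "other")
            )

        count_row("Colonoscopy complications", complications)
        if include_surveillance:
            count_row(
                "Surveillance colonoscopies performed (not in Diagnostic follow-up row)",
                lambda o, sc: o.total("surveillance_colonoscopies", years=WINDOW_YEARS),
            )
        count_row("Adenomas detected", lambda o, sc: o.total("adenomas_detected", years=WINDOW_YEARS))
        count_row("Colorectal cancers detected (screen-detected)", lambda o, sc: o.total("cancers_detected", years=WINDOW_YEARS))

        frame = pd.DataFrame(rows).T[labels]
        values = pd.DataFrame(vals).T.reindex(frame.index)[labels]
        return cls(frame=frame, values=values)

    def to_markdown(self) -> str:
        lines = [
            f"Screening outcomes (x10,000) per simulated scenario, ages {WIDE_AGES[0]}-{WIDE_AGES[1]} "
            f"unless stated, {WINDOW_YEARS[0]}-{WINDOW_YEARS[1]}.",
            "",
        ]
        header = ["Outcome"] + list(self.frame.columns)
        lines.append("| " + " | ".join(header) + " |")
        lines.append("|" + "|".join(["---"] * len(header)) + "|")
        for name, row in self.frame.iterrows():
            lines.append("| " + " | ".join([str(name)] + [str(v) for v in row]) + " |")
        lines.append("")
        lines.append(
            "False positives are reported as a count and as a percentage of "
            "positive tests. Direct-visualization screening reports no separate "
            "diagnostic follow-up colonoscopies."
        )
        return "\n".join(lines) + "\n"

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index_label="outcome", lineterminator="\n")


def annual_series(
    outcomes: AnnualOutcomes,
    include_surveillance: bool = True,
    ages: tuple = WIDE_AGES,
) -> pd.DataFrame:
    """Per-calendar-year incidence and mortality rates (per 100,000
    demographic person-years, ages ``ages``) and total colonoscopies
    (primary + diagnostic follow-up, plus surveillance when flagged)."""
    py = outcomes.person_years_per_year(*ages)
    cases = outcomes.per_year("crc_cases", *ages)
    deaths = outcomes.per_year("crc_deaths", *ages)
    colos = outcomes.per_year("tests_colonoscopy") + outcomes.per_year("followup_colonoscopies")
    if include_surveillance:
        colos = colos + outcomes.per_year("surveillance_colonoscopies")
    with np.errstate(divide="ignore", invalid="ignore"):
        inc_rate = np.where(py > 0, cases / py * 1e5, 0.0)
        mort_rate = np.where(py > 0, deaths / py * 1e5, 0.0)
    return pd.DataFrame(
        {
            "year": outcomes.years,
            "crc_cases": cases,
            "crc_deaths": deaths,
            "person_years": py,
            "incidence_rate_per_100k": inc_rate,
            "mortality_rate_per_100k": mort_rate,
            "total_colonoscopies": colos,
        }
    )
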