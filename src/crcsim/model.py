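"""High-level modelling interface.

``ScreeningModel`` binds a country data template to a regional
benchmark; ``fit()`` runs the quality checks and calibrates the onset
hazard to the country's age-specific incidence, returning a
``CalibrationResults`` that carries the calibrated parameter set,
per-band onset multipliers and fit diagnostics.  Scenario simulation
hangs off the results object: ``CalibrationResults.simulate`` returns a
``ComparisonResults`` with scaled per-calendar-year outcomes, the
headline comparison table, per-year series, and plotting helpers.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .country_template import (
    BenchmarkModel,
    CalibrationInfo,
    CountryTemplate,
    QualityCheckReport,
    TemplateError,
    adjust_benchmark,
    get_benchmark,
    read_template,
    run_quality_checks,
)
from .params import ModelParams, ProgrammeDesign
from .reporting import OutcomeTable, annual_series
from .scenario_engine import (
    ScalingFactors,
    Scenario,
    person_years_projection,
    run_comparison,
    scale_to_population,
)

__all__ = ["ScreeningModel", "CalibrationResults", "ComparisonResults", "default_scenarios"]


def default_scenarios(params: ModelParams, colonoscopy_interval: int = 5) -> list:
    """No screening, the current programme continued, and primary
    colonoscopy screening from the switch year."""
    current = Scenario.current_programme(params, "Current programme")
    colo = Scenario(
        "Colonoscopy screening",
        ProgrammeDesign(
            test_name="colonoscopy",
            start_age=current.design.start_age,
            stop_age=current.design.stop_age,
            interval=colonoscopy_interval,
            participation=current.design.participation,
            invitation_coverage=current.design.invitation_coverage,
            followup_adherence=current.design.followup_adherence,
            start_year=current.switch_year,
        ),
    )
    return [Scenario.no_screening(), current, colo]


class ScreeningModel:
    """CRC screening evaluation model for one country.

    Parameters
    ----------
    template : CountryTemplate
        The uploaded country dataset (demography, epidemiology,
        screening programme).
    benchmark : str or BenchmarkModel or ModelParams
        Regional benchmark used as the starting parameter set
        ("western", "eastern", "northern" or "southern").
    """

    def __init__(self, template: CountryTemplate, benchmark="western"):
        self.template = template
        if isinstance(benchmark, str):
            benchmark = get_benchmark(benchmark)
        self.benchmark = benchmark
        self.quality_report: QualityCheckReport = run_quality_checks(template)

    @classmethod
    def from_template(cls, path, benchmark="western") -> "ScreeningModel":
        """Build the model from a template directory or XLSX workbook."""
        return cls(read_template(path), benchmark=benchmark)

    def fit(self, tol: float = 0.02, max_iter: int = 10, dt: float = 0.02) -> "CalibrationResults":
        """Quality-check the template and calibrate the benchmark to it."""
        if not self.quality_report.ok:
            msgs = "; ".join(c.message for c in self.quality_report.errors)
            raise TemplateError(f"template failed quality checks: {msgs}")
        params, info = adjust_benchmark(self.benchmark, self.template, tol=tol, max_iter=max_iter, dt=dt)
        return CalibrationResults(model=self, params=params, info=info)


@dataclass
class CalibrationResults:
    """Calibrated parameter set plus fit diagnostics."""

    model: ScreeningModel
    params: ModelParams
    info: CalibrationInfo

    def summary(self) -> str:
        """Human-readable calibration summary table."""
        bench = self.model.benchmark
        region = bench.region if isinstance(bench, BenchmarkModel) else "custom"
        lines = [
            "Country calibration against regional benchmark",
            "=" * 62,
            f"Benchmark region:        {region}",
            f"Quality checks:          {len(self.model.quality_report.errors)} errors, "
            f"{len(self.model.quality_report.warnings)} warnings",
            f"Converged:               {self.info.converged}",
            f"Polish iterations:       {self.info.n_iter}",
            f"Max rel. incidence error: {100 * self.info.max_rel_error:.3f}%",
            "",
            "Age band   target/100k   fitted/100k   onset multiplier",
            "-" * 62,
        ]
        for (lo, hi), t, a, m in zip(
            self.info.bands, self.info.target, self.info.achieved, self.info.multipliers
        ):
            lines.append(f"{lo:>3}-{hi - 1:<5} {t:>11.2f} {a:>13.2f} {m:>15.3f}")
        return "\n".join(lines) + "\n"

    def multipliers_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "age_low": [b[0] for b in self.info.bands],
                "age_high": [b[1] - 1 for b in self.info.bands],
                "target_per_100k": self.info.target,
                "fitted_per_100k": self.info.achieved,
                "onset_multiplier": self.info.multipliers,
            }
        )

    def simulate(
        self,
        scenarios: list | None = None,
        n_sim: int = 100_000,
        seed: int = 0,
        years: tuple = (2018, 2050),
        progress: bool = False,
    ) -> "ComparisonResults":
        """Run a scenario comparison over a shared simulated population."""
        if scenarios is None:
            scenarios = default_scenarios(self.params)
        raws, factors = run_comparison(
            self.params, scenarios, n_sim=n_sim, master_seed=seed, years=years, progress=progress
        )
        py = person_years_projection(
            self.params.pyramid, self.params.life_table, years=years
        )
        outcomes = {
            lab: scale_to_population(raw, factors, person_years=py) for lab, raw in raws.items()
        }
        return ComparisonResults(
            calibration=self,
            scenarios=scenarios,
            raw=raws,
            factors=factors,
            outcomes=outcomes,
            n_sim=n_sim,
            seed=seed,
        )


@dataclass
class ComparisonResults:
    """Scenario-comparison outcomes, scaled to the country population."""

    calibration: CalibrationResults
    scenarios: list
    raw: dict  # label -> RawOutcomes (per-cohort, unscaled)
    factors: ScalingFactors
    outcomes: dict  # label -> AnnualOutcomes (population scale)
    n_sim: int
    seed: int

    def outcome_table(self, include_surveillance: bool = True) -> OutcomeTable:
        return OutcomeTable.from_outcomes(
            self.outcomes,
            self.calibration.params,
            self.scenarios,
            include_surveillance=include_surveillance,
        )

    def summary(self) -> str:
        head = (
            f"Scenario comparison ({self.n_sim:,} simulated persons, seed {self.seed})\n"
        )
        return head + "\n" + self.outcome_table().to_markdown()

    def annual_series(self, label: str, include_surveillance: bool = True) -> pd.DataFrame:
        return annual_series(self.outcomes[label], include_surveillance=include_surveillance)

    def to_csv(self, out_dir) -> None:
        """Write one long-format outcome CSV per scenario plus the table."""
        import pathlib

        out = pathlib.Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for lab, o in self.outcomes.items():
            slug = lab.lower().replace(" ", "_")
            o.to_frame().to_csv(out / f"outcomes_{slug}.csv", index=False, lineterminator="\n")
            self.annual_series(lab).to_csv(out / f"annual_{slug}.csv", index=False, lineterminator="\n")
        self.outcome_table().to_csv(out / "outcome_table.csv")
        with open(out / "report.md", "w") as fh:
            fh.write(self.summary())

    def plot_annual_series(self, metrics=("incidence_rate_per_100k", "mortality_rate_per_100k", "total_colonoscopies")):
        """Per-year incidence/mortality rates and colonoscopy volume,
        one panel per metric, one line per scenario."""
        import matplotlib.pyplot as plt

        fig, axes = plt.subplots(1, len(metrics), figsize=(5 * len(metrics), 4), squeeze=False)
        for ax, metric in zip(axes[0], metrics):
            for sc in self.scenarios:
                s = self.annual_series(sc.label)
                ax.plot(s["year"], s[metric], label=sc.label)
            ax.set_xlabel("calendar year")
            ax.set_title(metric.replace("_", " "))
        axes[0][0].legend(frameon=False, fontsize=8)
        fig.tight_layout()
        return fig
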