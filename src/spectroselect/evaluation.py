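"""Derived comparisons and the printed-table verifier.

Using predictions instead of measured traits shrinks variability; the
quantities here summarize that loss and its consequences for breeding:

* ``Δσ²_p = 1 − σ²_p(pred)/σ²_p(meas)`` — proportional decrease in
  phenotypic variance of a prediction relative to its measured trait, and
  the analogous ``Δσ²_a`` for additive-genetic variance;
* the OLS R² of external-validation R² on Δσ²_p (resp. Δσ²_a) across
  traits — how tightly variance loss tracks prediction quality;
* means of the additive-genetic (r_a) and residual (r_e) correlations
  between measured traits and their predictions;
* relative efficiency of indirect selection,
  ``CR/R = r_a·h_indicator/h_target``.

The package ships the published summary tables for a population of 1,327
Piemontese young bulls as a fixture; :func:`verify_printed_aggregates`
recomputes every aggregate statistic from those per-trait values and checks
them against the printed aggregate sentences within rounding tolerance.
"""

from __future__ import annotations

import importlib.resources as resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PrintedTables",
    "load_reference_tables",
    "variance_decrease",
    "regression_r2",
    "summarize_correlations",
    "selection_efficiency",
    "verify_printed_aggregates",
    "reference_aggregates",
]

TRAITS = ["L*", "a*", "b*", "C*", "h*", "pH", "PL", "CL", "WBSF"]
SOURCES = ["lab", "vis", "micro"]


@dataclass
class PrintedTables:
    """The published per-trait estimates in tidy form (9 traits × 3 sources)."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if self.table.empty:
            raise ValueError("reference table fixture is empty")
        missing = set(TRAITS) - set(self.table["trait"])
        if missing:
            raise ValueError(f"reference table missing traits: {sorted(missing)}")

    def column(self, col: str, source: str, traits=TRAITS) -> np.ndarray:
        sub = self.table[self.table["source"] == source].set_index("trait")
        return sub.loc[traits, col].to_numpy(dtype=float)


def load_reference_tables() -> PrintedTables:
    """Load the bundled published summary tables."""
    with resources.files("spectroselect.data").joinpath("reference_tables.csv").open() as fh:
        df = pd.read_csv(fh, comment="#")
    return PrintedTables(table=df)


def variance_decrease(var_measured: float, var_predicted: float) -> float:
    """Proportional variance decrease ``1 − σ²(pred)/σ²(meas)``."""
    if var_measured <= 0:
        raise ValueError("measured variance must be > 0")
    return 1.0 - var_predicted / var_measured


def regression_r2(x, y) -> float:
    """R² of the ordinary least-squares line of y on x (squared Pearson r).

    A constant ``y`` is defined to give 0 (flagged by convention rather than
    raising, since an all-equal column can legitimately occur).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.std(x) == 0:
        raise ValueError("x is constant; regression undefined")
    if np.std(y) == 0:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1] ** 2)


def summarize_correlations(tables: PrintedTables | pd.DataFrame) -> dict:
    """Arithmetic means of r_a and r_e across traits, per instrument and
    overall (the overall mean pools the 9 traits × 2 instruments)."""
    if isinstance(tables, pd.DataFrame):
        tables = PrintedTables(table=tables)
    out = {}
    for what in ("r_a", "r_e"):
        per = {}
        for src in ("vis", "micro"):
            vals = tables.column(what, src)
            if np.any(~np.isfinite(vals)):
                raise ValueError(f"incomplete {what} grid for {src}")
            per[src] = float(vals.mean())
        out[f"mean_{what}_vis"] = per["vis"]
        out[f"mean_{what}_micro"] = per["micro"]
        out[f"mean_{what}"] = float(
            np.mean(np.concatenate([tables.column(what, s) for s in ("vis", "micro")]))
        )
    return out


def selection_efficiency(r_a: float, h2_indicator: float, h2_target: float) -> float:
    """Relative efficiency of indirect selection, ``CR/R = r_a·h_i/h_t``.

    ``h`` is the square root of heritability; the ratio compares the
    correlated response in the target trait when selecting on the indicator
    against direct selection at equal intensity.
    """
    if not (0 < h2_indicator <= 1 and 0 < h2_target <= 1):
        raise ValueError("heritabilities must be in (0, 1]")
    return r_a * np.sqrt(h2_indicator) / np.sqrt(h2_target)


@dataclass
class AggregateCheck:
    name: str
    computed: float
    printed: float
    tolerance: float
    passed: bool = field(init=False)

    def __post_init__(self) -> None:
        self.passed = abs(self.computed - self.printed) <= self.tolerance


def reference_aggregates(tables: PrintedTables | None = None) -> dict:
    """Every aggregate statistic recomputable from the per-trait tables."""
    t = tables or load_reference_tables()
    out: dict = {}
    var_lab = t.column("phen_var", "lab")
    add_lab = t.column("ratio_additive", "lab") * var_lab
    for src in ("vis", "micro"):
        var_p = t.column("phen_var", src)
        dvp = 1.0 - var_p / var_lab
        out[f"dvp_{src}"] = dvp
        out[f"mean_dvp_{src}"] = float(dvp.mean())
        out[f"fig1_r2_{src}"] = regression_r2(dvp, t.column("r2_ext", src))
        add_p = t.column("ratio_additive", src) * var_p
        dva = 1.0 - add_p / add_lab
        out[f"dva_{src}"] = dva
        out[f"mean_dva_{src}"] = float(dva.mean())
        out[f"fig2_r2_{src}"] = regression_r2(dva, t.column("r2_ext", src))
        out[f"fig3_r2_{src}"] = regression_r2(
            t.column("r2_ext", src), t.column("r_a", src)
        )
        sd_red = 1.0 - t.column("sd", src) / t.column("sd", "lab")
        out[f"sd_reduction_{src}"] = sd_red
        out[f"mean_sd_reduction_{src}"] = float(sd_red.mean())
    out["mean_dva_overall"] = float(
        np.mean(np.concatenate([out["dva_vis"], out["dva_micro"]]))
    )
    water_idx = [TRAITS.index(n) for n in ("PL", "CL", "WBSF")]
    out["max_sd_reduction_losses"] = float(
        max(out["sd_reduction_vis"][water_idx].max(), out["sd_reduction_micro"][water_idx].max())
    )
    out.update(summarize_correlations(t))
    return out


#: printed aggregate sentences: name -> (printed value, absolute tolerance);
#: correlations and R² carry ±0.015 for rounding, percentages ±1.5 points
PRINTED_AGGREGATES = {
    "fig1_r2_vis": (0.96, 0.015),
    "fig1_r2_micro": (0.98, 0.015),
    "mean_dvp_vis": (0.50, 0.015),
    "mean_dvp_micro": (0.60, 0.015),
    "mean_dva_overall": (0.70, 0.015),
    "mean_sd_reduction_vis": (0.30, 0.015),
    "mean_sd_reduction_micro": (0.40, 0.015),
    "max_sd_reduction_losses": (0.78, 0.015),
    "mean_r_a": (0.81, 0.015),
}


def verify_printed_aggregates(tables: PrintedTables | None = None) -> pd.DataFrame:
    """Recompute the printed aggregates from the per-trait fixture and check
    each against its published value; returns a machine-readable ledger."""
    agg = reference_aggregates(tables)
    checks = [
        AggregateCheck(name, float(agg[name]), printed, tol)
        for name, (printed, tol) in PRINTED_AGGREGATES.items()
    ]
    return pd.DataFrame(
        {
            "check": [c.name for c in checks],
            "computed": [c.computed for c in checks],
            "printed": [c.printed for c in checks],
            "tolerance": [c.tolerance for c in checks],
            "passed": [c.passed for c in checks],
        }
    )
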