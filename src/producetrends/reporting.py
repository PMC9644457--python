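"""Figure rendering and the end-to-end pipeline driver.

Figures mirror the study's displays: monthly weighted means with 95% CI
bars under the fitted seasonal curve and a grand-mean reference line, and
a point-and-interval chart of annual rates of change by age x income
cell.  ``run_pipeline`` chains simulate -> preprocess -> aggregate -> fit
-> describe -> figures, writing a manifest with per-stage row counts so a
rerun with the same seed is verifiably identical.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import asdict, dataclass

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from . import county_data
from .aggregation import build_panel, grand_mean, weighted_monthly_series
from .gee import (
    ContrastResult,
    FitResult,
    ModelSpec,
    annual_change_contrast,
    baseline_percent,
    build_design,
    fit_gee,
    fitted_percent_curve,
)
from .labels import AGE_LABELS, CELLS, INCOME_LABELS
from .preprocessing import ExclusionRules, apply_exclusions, classify_items, prepare_cohort
from .representativeness import MarginalTable, chi_square_comparison, table_percentages
from .synthetic import GeneratorConfig, generate_households, generate_transactions

__all__ = ["FigureSpec", "seasonal_figure", "rate_of_change_figure", "run_pipeline"]


@dataclass(frozen=True)
class FigureSpec:
    """Options for a seasonal-trend figure."""

    grouping: str  # "age" or "income"
    output_path: str
    show_fit: bool = True
    show_grand_mean: bool = True
    image_format: str = "png"

    def __post_init__(self) -> None:
        if self.grouping not in ("age", "income"):
            raise ValueError("figure grouping must be 'age' or 'income'")


def seasonal_figure(
    series: pd.DataFrame,
    fit: FitResult | None,
    spec: FigureSpec,
    grand_mean_value: float | None = None,
) -> str:
    """Render per-group monthly weighted means, fitted curve, grand mean."""
    group_col = f"{spec.grouping}_group"
    if group_col not in series.columns:
        raise ValueError(
            f"series lacks {group_col}; was it built with grouping={spec.grouping!r}?"
        )
    if spec.show_fit:
        if fit is None or fit.spec.grouping != spec.grouping:
            raise ValueError("fit grouping does not match the figure grouping")
    labels = AGE_LABELS if spec.grouping == "age" else INCOME_LABELS
    fig, axes = plt.subplots(
        len(labels), 1, figsize=(7, 2.1 * len(labels)), sharex=True, sharey=True
    )
    for ax, lab in zip(np.atleast_1d(axes), labels):
        g = series[series[group_col] == lab]
        ax.errorbar(
            g["month"],
            100 * g["weighted_mean"],
            yerr=[
                100 * (g["weighted_mean"] - g["ci_low"]),
                100 * (g["ci_high"] - g["weighted_mean"]),
            ],
            fmt="o",
            ms=3,
            lw=1,
            color="0.3",
            label="monthly weighted mean",
        )
        if spec.show_fit:
            curve = fitted_percent_curve(fit, lab)
            ax.plot(curve["month"], curve["fitted_percent"], color="C0", label="fitted")
        if spec.show_grand_mean and grand_mean_value is not None:
            ax.axhline(100 * grand_mean_value, color="C3", ls="--", lw=1, label="grand mean")
        ax.set_ylabel("% produce")
        ax.set_title(f"{spec.grouping} {lab}", fontsize=9)
    np.atleast_1d(axes)[-1].set_xlabel("study month")
    fig.tight_layout()
    fig.savefig(spec.output_path, format=spec.image_format, dpi=120)
    plt.close(fig)
    return spec.output_path


def rate_of_change_figure(
    contrasts: list[ContrastResult], output_path: str
) -> str:
    """Point-and-interval chart of annual change, one point per cell."""
    have = {c.label for c in contrasts}
    want = {f"{a} x {i}" for a, i in CELLS}
    missing = sorted(want - have)
    if missing:
        raise ValueError(f"missing annual-change contrasts for cells: {missing}")
    by_label = {c.label: c for c in contrasts}
    fig, ax = plt.subplots(figsize=(9, 4.5))
    xticks, xlabels = [], []
    for ai, a in enumerate(AGE_LABELS):
        for ii, i in enumerate(INCOME_LABELS):
            c = by_label[f"{a} x {i}"]
            x = ai * (len(INCOME_LABELS) + 1) + ii
            ax.errorbar(
                x,
                c.estimate,
                yerr=[[c.estimate - c.ci_low], [c.ci_high - c.estimate]],
                fmt="o",
                ms=4,
                color=f"C{ii}",
            )
            xticks.append(x)
            xlabels.append(i if ai == 0 else "")
        ax.text(
            ai * (len(INCOME_LABELS) + 1) + 2.5, ax.get_ylim()[0], a,
            ha="center", va="bottom", fontsize=8,
        )
    ax.axhline(0, color="0.5", lw=0.8)
    ax.set_ylabel("annual change in % produce purchased")
    ax.set_xticks(xticks)
    ax.set_xticklabels(xlabels, rotation=90, fontsize=7)
    fig.tight_layout()
    fig.savefig(output_path, dpi=120)
    plt.close(fig)
    return output_path


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def _config_hash(config: GeneratorConfig) -> str:
    # dataclass repr is deterministic and covers nested model truth
    return hashlib.sha256(repr(config).encode()).hexdigest()[:12]


def run_pipeline(
    config: GeneratorConfig,
    out_dir,
    rules: ExclusionRules | None = None,
    fit_groupings: tuple[str, ...] = ("age", "income", "age_by_income"),
) -> "pathlib.Path":
    """Run simulate -> preprocess -> aggregate -> fit -> describe -> figures.

    Each stage writes its CSV outputs under ``out_dir``; a
    ``manifest.json`` records per-stage row counts, the config hash and
    seed.  The age-by-income fit is skipped (and noted in the manifest)
    when some cell has no cohort household, which can happen at small
    simulated sizes.
    """
    import pathlib

    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rules = rules or ExclusionRules()
    manifest: dict = {
        "seed": config.seed,
        "config_hash": _config_hash(config),
        "python": platform.python_version(),
        "stages": {},
    }

    def _stage(name):
        def deco(fn):
            try:
                info = fn()
            except Exception as e:  # noqa: BLE001 - abort with stage name
                raise PipelineError(name, e) from e
            manifest["stages"][name] = info
            return info

        return deco

    state: dict = {}

    @_stage("simulate")
    def _():
        hh = generate_households(config)
        tx = generate_transactions(hh, config)
        hh.to_csv(out / "households.csv", index=False)
        tx.to_csv(out / "transactions.csv", index=False)
        state.update(hh=hh, tx=tx)
        return {"households": len(hh), "transaction_items": len(tx)}

    @_stage("preprocess")
    def _():
        items, log = apply_exclusions(state["tx"], state["hh"], rules)
        items = classify_items(items)
        cohort = prepare_cohort(state["hh"], rules)
        cohort.to_csv(out / "cohort.csv", index=False)
        items.to_csv(out / "items_clean.csv", index=False)
        pd.Series(log, name="removed").rename_axis("rule").to_csv(out / "removal_log.csv")
        state.update(items=items, cohort=cohort)
        return {
            "items_in": len(state["tx"]),
            "items_retained": len(items),
            "removed": log,
            "cohort_households": len(cohort),
        }

    @_stage("aggregate")
    def _():
        panel = build_panel(
            state["items"], state["cohort"], config.start_month, config.study_months
        )
        panel.to_csv(out / "panel.csv", index=False)
        gm = grand_mean(panel)
        for grouping in ("none", "age", "income"):
            weighted_monthly_series(panel, grouping).to_csv(
                out / f"series_{grouping}.csv", index=False
            )
        state.update(panel=panel, gm=gm)
        return {"panel_rows": len(panel), "grand_mean_percent": round(100 * gm, 3)}

    @_stage("fit")
    def _():
        info = {}
        fits = {}
        for grouping in fit_groupings:
            if grouping == "age_by_income":
                present = set(
                    zip(state["panel"]["age_group"], state["panel"]["income_group"])
                )
                if len(present) < len(CELLS):
                    info[grouping] = "skipped: empty age x income cells"
                    continue
            spec = ModelSpec(grouping=grouping)
            fit = fit_gee(build_design(state["panel"], spec))
            fits[grouping] = fit
            fit.summary_frame().to_csv(out / f"fit_{grouping}.csv")
            cells = (
                AGE_LABELS
                if grouping == "age"
                else INCOME_LABELS if grouping == "income" else CELLS
            )
            rows = []
            for cell in cells:
                for fn in (baseline_percent, annual_change_contrast):
                    c = fn(fit, cell)
                    rows.append(
                        {
                            "cell": c.label,
                            "quantity": c.quantity,
                            "estimate": c.estimate,
                            "ci_low": c.ci_low,
                            "ci_high": c.ci_high,
                        }
                    )
            pd.DataFrame(rows).to_csv(out / f"contrasts_{grouping}.csv", index=False)
            info[grouping] = {
                "converged": fit.converged,
                "iterations": fit.iterations,
                "n_params": len(fit.params),
            }
        state["fits"] = fits
        return info

    @_stage("describe")
    def _():
        table_percentages(county_data.AGE_INCOME_COUNTS, axis="column").to_csv(
            out / "table1.csv"
        )
        table_percentages(county_data.AGE_FAMILY_COUNTS, axis="row").to_csv(
            out / "table2.csv"
        )
        loy = MarginalTable(
            tuple(county_data.COUNTY_INCOME_COUNTS.index),
            tuple(county_data.COUNTY_INCOME_COUNTS["loyalty"]),
            "internal",
        )
        acs = MarginalTable(
            tuple(county_data.COUNTY_INCOME_COUNTS.index),
            tuple(county_data.COUNTY_INCOME_COUNTS["acs"]),
            "external",
        )
        comparison = chi_square_comparison(loy, acs)
        (out / "comparison.json").write_text(json.dumps(comparison, indent=2))
        return {"chi_square_p": comparison["p_value"]}

    @_stage("figures")
    def _():
        written = []
        for grouping in ("age", "income"):
            series = pd.read_csv(out / f"series_{grouping}.csv")
            fit = state["fits"].get(grouping)
            path = seasonal_figure(
                series,
                fit,
                FigureSpec(
                    grouping=grouping,
                    output_path=str(out / f"seasonal_{grouping}.png"),
                    show_fit=fit is not None,
                ),
                grand_mean_value=state["gm"],
            )
            written.append(path)
        if "age_by_income" in state["fits"]:
            contrasts = [
                annual_change_contrast(state["fits"]["age_by_income"], cell)
                for cell in CELLS
            ]
            written.append(
                rate_of_change_figure(contrasts, str(out / "rate_of_change.png"))
            )
        return {"files": [str(p) for p in written]}

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return out
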