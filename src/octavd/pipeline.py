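"""End-to-end reproducible runs: configuration, orchestration, report I/O.

:func:`run_reproduce` simulates the reference BCR/control cohort, runs
the whole statistical workflow (group comparisons, acuity correlations,
univariable screen feeding multivariable clustered models, and the
clustered longitudinal test on a simulated two-year subgroup), and
returns a structured report embedding the seed and configuration so that
every number is reproducible from (config, seed).

A single master seed is split into independent per-stage streams with
``numpy.random.SeedSequence``, so stages can be re-run in isolation
without perturbing each other.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .stats import (TestResult, chi_squared_2xk, clustered_wilcoxon_signed_rank,
                    mann_whitney_u, multivariable_fit, pearson_r,
                    univariable_screen)
from .synthetic import (METRICS, generate_cohort, generate_longitudinal_deltas,
                        reference_cohort_spec, reference_covariate_effects,
                        reference_longitudinal_spec)

__all__ = ["RunConfig", "run_reproduce", "stage_seeds",
           "read_cohort_csv", "write_cohort_csv", "write_report"]

log = logging.getLogger(__name__)

COHORT_COLUMNS = ["patient_id", "eye", "group", "age", "sex", "logmar",
                  "cst_um", "duration_months", "treatment", "active",
                  "plexus", "whole_vd", "extrafaz_vd", "faz_area_pct"]

SCREEN_CANDIDATES = ["age", "sex", "cst_um", "duration_months",
                     "treatment", "active"]


@dataclass(frozen=True)
class RunConfig:
    """Serializable knobs of a reproduction run."""

    seed: int = 0
    rho: float = 0.5
    alpha_screen: float = 0.10
    alpha: float = 0.05
    bootstrap_replicates: int = 2000
    with_covariate_effects: bool = True
    make_figures: bool = False

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        return cls(**json.loads(text))


def stage_seeds(master: int, n: int = 8) -> list[int]:
    """Split a master seed into independent sub-31-bit stage seeds."""
    children = np.random.SeedSequence(master).spawn(n)
    return [int(c.generate_state(1)[0] % (2 ** 31)) for c in children]


def run_reproduce(config: RunConfig = RunConfig(),
                  out_dir: str | Path | None = None,
                  cohort_spec=None) -> dict:
    """Simulate the reference cohort and rerun the full analysis on it.

    ``cohort_spec`` overrides the generated cohort's recipe (e.g. a
    global-null configuration for calibration runs); by default the
    reference BCR/control recipe is used.

    Returns a report dict with sections ``group_comparisons``,
    ``demographics``, ``acuity_correlations``, ``models`` and
    ``longitudinal``; stage failures are caught and listed under
    ``failures`` so a partial report is still produced.  If ``out_dir``
    is given the report, cohort table, and screen/model tables are
    written there.
    """
    seeds = stage_seeds(config.seed)
    if cohort_spec is None:
        effects = (reference_covariate_effects()
                   if config.with_covariate_effects else {})
        spec = reference_cohort_spec(covariate_effects=effects,
                                     rho=config.rho)
    else:
        spec = cohort_spec
    report: dict = {
        "config": dataclasses.asdict(config),
        "package_version": __version__,
        "stage_seeds": seeds,
        "failures": [],
    }

    cohort = generate_cohort(spec, seed=seeds[0])
    report["n"] = {
        g.name: {"patients": g.n_patients, "eyes": g.n_eyes}
        for g in spec.groups}

    def run_stage(name, fn):
        try:
            report[name] = fn()
        except Exception as exc:  # noqa: BLE001 — partial-report contract
            log.warning("stage %s failed: %s", name, exc)
            report["failures"].append({"stage": name, "error": str(exc)})

    def _tr(t: TestResult) -> dict:
        return {"method": t.method, "statistic": t.statistic, "p": t.p,
                "n": list(t.n), "notes": t.notes}

    def group_comparisons():
        out = {}
        for plexus in ("SCP", "DCP"):
            sub = cohort[cohort["plexus"] == plexus]
            bcr = sub[sub["group"] == "BCR"]
            ctl = sub[sub["group"] == "control"]
            for metric in METRICS:
                res = mann_whitney_u(bcr[metric], ctl[metric])
                entry = _tr(res)
                entry["mean_bcr"] = float(bcr[metric].mean())
                entry["mean_control"] = float(ctl[metric].mean())
                out[f"{plexus}_{metric}"] = entry
        return out

    def demographics():
        pat = cohort.drop_duplicates("patient_id")
        counts = pd.crosstab(pat["group"], pat["sex"])
        return {"sex_by_group": _tr(chi_squared_2xk(counts.to_numpy()))}

    def acuity_correlations():
        out = {}
        bcr = cohort[cohort["group"] == "BCR"]
        for plexus in ("SCP", "DCP"):
            sub = bcr[bcr["plexus"] == plexus]
            for metric in METRICS:
                res = pearson_r(sub["logmar"], sub[metric],
                                cluster_ids=sub["patient_id"],
                                n_boot=config.bootstrap_replicates,
                                seed=seeds[1])
                out[f"{plexus}_{metric}"] = _tr(res)
        return out

    screens: dict[str, pd.DataFrame] = {}
    model_tables: dict[str, pd.DataFrame] = {}

    def models():
        out = {}
        bcr = cohort[cohort["group"] == "BCR"]
        for plexus in ("SCP", "DCP"):
            sub = bcr[bcr["plexus"] == plexus]
            for metric in METRICS:
                key = f"{plexus}_{metric}"
                retained, screen = univariable_screen(
                    sub, metric, SCREEN_CANDIDATES,
                    alpha=config.alpha_screen)
                screens[key] = screen
                if not retained:
                    out[key] = {"retained": [],
                                "note": "no covariate screened in; "
                                        "multivariable stage skipped"}
                    continue
                fit = multivariable_fit(sub, metric, retained)
                model_tables[key] = fit.table
                out[key] = {
                    "retained": retained,
                    "n_eyes": fit.n_eyes, "n_patients": fit.n_patients,
                    "coefficients": {
                        name: {"estimate": float(row["estimate"]),
                               "se": float(row["se"]), "p": float(row["p"])}
                        for name, row in fit.table.iterrows()},
                }
        return out

    def longitudinal():
        deltas = generate_longitudinal_deltas(
            reference_longitudinal_spec(), seed=seeds[2])
        out = {}
        for plexus in ("SCP", "DCP"):
            sub = deltas[deltas["plexus"] == plexus]
            for metric in METRICS:
                res = clustered_wilcoxon_signed_rank(
                    sub[f"delta_{metric}"], sub["patient_id"])
                rec = _tr(res)
                rec["mean_delta"] = float(sub[f"delta_{metric}"].mean())
                out[f"{plexus}_{metric}"] = rec
        return out

    run_stage("group_comparisons", group_comparisons)
    run_stage("demographics", demographics)
    run_stage("acuity_correlations", acuity_correlations)
    run_stage("models", models)
    run_stage("longitudinal", longitudinal)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_cohort_csv(cohort, out_dir / "cohort.csv")
        for key, screen in screens.items():
            screen.to_csv(out_dir / f"screen_{key}.csv", index=False)
        for key, table in model_tables.items():
            table.to_csv(out_dir / f"model_{key}.csv")
        write_report(report, out_dir / "report.json")
        if config.make_figures:
            _boxplot_figure(cohort, out_dir / "group_boxplots.png")
    return report


def _boxplot_figure(cohort: pd.DataFrame, path: Path) -> None:
    """Cosmetic six-panel group boxplot (not asserted anywhere)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(2, 3, figsize=(11, 6), sharex=True)
    for i, plexus in enumerate(("SCP", "DCP")):
        sub = cohort[cohort["plexus"] == plexus]
        for j, metric in enumerate(METRICS):
            ax = axes[i][j]
            data = [sub.loc[sub["group"] == g, metric] for g in
                    ("BCR", "control")]
            ax.boxplot(data, tick_labels=["BCR", "control"])
            ax.set_title(f"{plexus} {metric}", fontsize=9)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


# ---------------------------------------------------------------------------
# Table I/O with schema validation
# ---------------------------------------------------------------------------

def write_cohort_csv(cohort: pd.DataFrame, path: str | Path) -> None:
    """Write an eye-level cohort table with the documented column order."""
    missing = [c for c in COHORT_COLUMNS if c not in cohort.columns]
    if missing:
        raise ValueError(f"cohort table missing columns: {missing}")
    cohort[COHORT_COLUMNS].to_csv(path, index=False)


def read_cohort_csv(path: str | Path) -> pd.DataFrame:
    """Read and validate an eye-level cohort CSV.

    Raises ``ValueError`` naming the missing column or the offending row
    on schema violations (bad plexus label, non-numeric outcome).
    """
    df = pd.read_csv(path)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    bad_plexus = ~df["plexus"].isin(["SCP", "DCP"])
    if bad_plexus.any():
        raise ValueError(
            f"{path}: invalid plexus at row(s) "
            f"{df.index[bad_plexus].tolist()[:5]}")
    for col in ("whole_vd", "extrafaz_vd", "faz_area_pct", "age",
                "cst_um", "duration_months", "logmar"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any() and not df[col].isna().any():
            row = int(df.index[vals.isna()][0])
            raise ValueError(f"{path}: non-numeric '{col}' at row {row}")
        df[col] = vals
    return df


def write_report(report: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=float)
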