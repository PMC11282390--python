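"""End-to-end runner: cohort CSV (real or synthetic) to the full result set.

The pipeline reads or generates a person-level cohort, applies the standard
exclusion rules (records with missing pain/SES/sociodemographics first, then
age < 45) with per-rule counts, and produces the complete analysis bundle:
descriptive table, concentration index and curve, decomposition table,
Kaplan-Meier curves with the log-rank test, adjusted and stratified Cox
fits, and the per-site / per-severity analyses.  Every run writes a manifest
echoing the configuration, the package version, per-stage record counts and
output checksums, so any output can be regenerated from the manifest alone.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import SITE_COLUMNS, GeneratorParams, generate_cohort
from .concentration import ConcentrationIndex
from .decomposition import ConcentrationDecomposition
from .stats import (
    descriptive_table,
    pain_correlates_logistic,
    site_severity_inequality,
    site_severity_mortality,
    weighted_prevalence,
)
from .survival import adjusted_pain_hr, forest_frame, km_estimator, logrank_test, stratified_fits

__all__ = ["AnalysisConfig", "read_cohort", "run_full_analysis"]

REQUIRED_COLUMNS = (
    "age", "gender", "education", "marital", "smoking", "drinking",
    "bmi_class", "location", "pce", "pain", "dead", "time",
)
NUMERIC_COLUMNS = ("age", "pce", "weight", "pain", "dead", "time")


@dataclass
class AnalysisConfig:
    """Configuration of a full analysis run."""

    input: str | None = None          # cohort CSV path; mutually exclusive with generate
    generate: bool = False            # synthesise the cohort instead of reading one
    seed: int = 0
    params: GeneratorParams | None = None
    weighted: bool = False
    ties: str = "breslow"
    model: str = "lpm"                # decomposition regression mode
    min_stratum_records: int = 100
    min_stratum_events: int = 5
    min_age: float = 45.0
    outdir: str = "results"
    figures: bool = False

    def __post_init__(self):
        if (self.input is None) == (not self.generate):
            raise ValueError("exactly one of `input` or `generate` must be set")
        if self.ties not in ("breslow", "efron"):
            raise ValueError("ties must be 'breslow' or 'efron'")
        if self.model not in ("lpm", "margeff"):
            raise ValueError("model must be 'lpm' or 'margeff'")

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if k != "params"}
        d["params"] = self.params.to_dict() if self.params is not None else None
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        d = dict(d)
        if d.get("params"):
            d["params"] = GeneratorParams.from_dict(d["params"])
        return cls(**d)


def read_cohort(path, min_age: float = 45.0) -> tuple[pd.DataFrame, dict]:
    """Read and validate a cohort CSV, applying the exclusion rules in order.

    Exclusions: (1) records missing pain, the SES measure or any
    sociodemographic covariate; (2) records below the age threshold.
    Returns (cohort, exclusion counts).  Rows with pain = 1 but a missing
    severity grade are retained with severity left missing.
    """
    df = pd.read_csv(path)
    unknown = set(df.columns) - set(REQUIRED_COLUMNS) - {
        "id", "weight", "severity", "age_group", "econ", "ses_rank", *SITE_COLUMNS}
    if unknown:
        raise ValueError(f"unknown columns in {path}: {sorted(unknown)}")
    missing = set(REQUIRED_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"missing required columns: {sorted(missing)}")
    if "id" in df.columns and df["id"].duplicated().any():
        dup_rows = (df.index[df["id"].duplicated()] + 2).tolist()
        raise ValueError(f"duplicate ids at rows {dup_rows}")
    if "id" not in df.columns:
        df["id"] = np.arange(len(df))
    if "weight" not in df.columns:
        df["weight"] = 1.0
    for col in NUMERIC_COLUMNS:
        raw = df[col]
        converted = pd.to_numeric(raw, errors="coerce")
        bad = converted.isna() & raw.notna()
        if bad.any():
            row = int(bad.idxmax()) + 2  # header is line 1
            raise ValueError(f"malformed number in column {col!r} at row {row}: {raw[bad.idxmax()]!r}")
        df[col] = converted

    counts = {"input": len(df)}
    core = ["pain", "pce"] + [c for c in REQUIRED_COLUMNS if c not in ("pain", "pce", "dead", "time")]
    complete = df[core].notna().all(axis=1)
    df = df[complete]
    counts["excluded_missing"] = counts["input"] - len(df)
    kept = df["age"] >= min_age
    counts["excluded_age"] = int((~kept).sum())
    df = df[kept].reset_index(drop=True)
    counts["analysed"] = len(df)
    if len(df) == 0:
        raise ValueError("no records remain after exclusions")
    if (df["pce"] <= 0).any() or (df["time"] <= 0).any():
        raise ValueError("pce and time must be positive")
    return df, counts


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_full_analysis(config: AnalysisConfig) -> dict:
    """Run the complete analysis and write the result bundle to ``outdir``.

    Re-running with an identical configuration is bit-identical.  Returns a
    dict of in-memory results, including the manifest.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": config.to_dict(), "version": __version__, "stages": {}}
    t_all = time.time()

    def stage(name, fn):
        t0 = time.time()
        out = fn()
        manifest["stages"][name] = {"seconds": round(time.time() - t0, 3)}
        return out

    if config.generate:
        params = (config.params or GeneratorParams()).replace(seed=config.seed)
        cohort = stage("generate", lambda: generate_cohort(params))
        counts = {"input": len(cohort), "excluded_missing": 0, "excluded_age": 0,
                  "analysed": len(cohort)}
    else:
        cohort, counts = stage("read", lambda: read_cohort(config.input, config.min_age))
    manifest["record_counts"] = counts
    weights = cohort["weight"].to_numpy(float) if config.weighted else None

    results: dict = {"cohort": cohort, "manifest": manifest}

    desc = stage("descriptive", lambda: descriptive_table(cohort))
    desc.to_csv(outdir / "descriptive_table.csv")
    results["descriptive"] = desc

    prev, prev_se, prev_ci = weighted_prevalence(
        cohort["pain"].to_numpy(float), cohort["weight"].to_numpy(float))
    results["weighted_prevalence"] = {"estimate": prev, "se": prev_se,
                                      "ci_low": prev_ci[0], "ci_high": prev_ci[1]}

    conc = stage("concentration", lambda: ConcentrationIndex.from_dataframe(
        cohort, "pain", weights="weight" if config.weighted else None).fit())
    conc.to_frame().to_csv(outdir / "concentration_index.csv", index=False)
    conc.curve.to_csv(outdir / "concentration_curve.csv", index=False)
    results["concentration"] = conc

    decomp = stage("decomposition", lambda: ConcentrationDecomposition.from_dataframe(
        cohort, weights="weight" if config.weighted else None, model=config.model).fit())
    decomp.to_csv(outdir / "decomposition_table.csv")
    results["decomposition"] = decomp

    def _km():
        curves = km_estimator(cohort["time"], cohort["dead"], group=cohort["pain"])
        lr = logrank_test(cohort["time"], cohort["dead"], cohort["pain"])
        return curves, lr

    curves, lr = stage("kaplan_meier", _km)
    km_frames = []
    for label, curve in curves.items():
        f = curve.to_frame()
        f.insert(0, "pain", label)
        km_frames.append(f)
    pd.concat(km_frames).to_csv(outdir / "km_curves.csv", index=False)
    (outdir / "logrank.json").write_text(json.dumps(
        {"chi2": lr.statistic, "df": lr.df, "pvalue": lr.pvalue}, indent=2))
    results["km"] = curves
    results["logrank"] = lr

    cox = stage("cox_adjusted", lambda: adjusted_pain_hr(cohort, ties=config.ties))
    cox_out = pd.concat([cox.params, cox.bse, cox.hazard_ratios, cox.conf_int(),
                         cox.pvalues.rename("pvalue")], axis=1)
    cox_out.to_csv(outdir / "cox_adjusted.csv")
    results["cox"] = cox

    def _strata():
        frames, skipped_all = [], {}
        for var in ("age_group", "gender", "education", "marital", "smoking",
                    "drinking", "bmi_class", "location"):
            fits, skipped = stratified_fits(
                cohort, var, min_records=config.min_stratum_records,
                min_events=config.min_stratum_events, ties=config.ties)
            f = forest_frame(fits)
            f.insert(0, "variable", var)
            frames.append(f)
            skipped_all.update({f"{var}:{k}": v for k, v in skipped.items()})
        return pd.concat(frames, ignore_index=True), skipped_all

    forest, skipped = stage("stratified", _strata)
    forest.to_csv(outdir / "stratified_forest.csv", index=False)
    manifest["skipped_strata"] = skipped
    results["forest"] = forest

    correlates = stage("logistic", lambda: pain_correlates_logistic(cohort, weights))
    correlates.to_csv(outdir / "pain_correlates.csv")
    results["correlates"] = correlates

    ineq = stage("site_severity_inequality", lambda: site_severity_inequality(cohort, weights))
    ineq.to_csv(outdir / "site_severity_inequality.csv")
    results["site_inequality"] = ineq

    def _site_mort():
        fits, skip = site_severity_mortality(cohort, ties=config.ties)
        rows = []
        for name, res in fits.items():
            ci = res.conf_int().loc["exposure"]
            rows.append({"outcome": name, "hr": float(np.exp(res.params["exposure"])),
                         "hr_low": float(ci["hr_low"]), "hr_high": float(ci["hr_high"]),
                         "n": res.nobs, "events": res.nevents})
        return pd.DataFrame(rows), skip

    site_mort, skipped_sites = stage("site_severity_mortality", _site_mort)
    site_mort.to_csv(outdir / "site_severity_mortality.csv", index=False)
    manifest["skipped_site_fits"] = skipped_sites
    results["site_mortality"] = site_mort

    if config.figures:
        stage("figures", lambda: _write_figures(results, outdir))

    manifest["wall_seconds"] = round(time.time() - t_all, 3)
    manifest["outputs"] = {p.name: _sha256(p) for p in sorted(outdir.glob("*.csv"))}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return results


def _write_figures(results: dict, outdir: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ax = results["concentration"].plot()
    ax.figure.savefig(outdir / "concentration_curve.png", dpi=150, bbox_inches="tight")
    plt.close(ax.figure)

    fig, ax = plt.subplots()
    for label, curve in results["km"].items():
        t = np.r_[0.0, curve.times]
        risk = 1.0 - np.r_[1.0, curve.survival]
        ax.step(t, risk, where="post", label=f"pain={label}")
    ax.set_xlabel("years of follow-up")
    ax.set_ylabel("cumulative mortality risk")
    ax.legend(frameon=False)
    fig.savefig(outdir / "km_curves.png", dpi=150, bbox_inches="tight")
    plt.close(fig)

    forest = results["forest"]
    fig, ax = plt.subplots(figsize=(6, 0.3 * len(forest) + 1))
    ypos = np.arange(len(forest))[::-1]
    ax.errorbar(forest["hr"], ypos,
                xerr=[forest["hr"] - forest["hr_low"], forest["hr_high"] - forest["hr"]],
                fmt="o", ms=3, capsize=2)
    ax.axvline(1.0, color="grey", lw=0.8)
    ax.set_yticks(ypos)
    ax.set_yticklabels(forest["variable"] + ": " + forest["stratum"])
    ax.set_xlabel("adjusted hazard ratio for pain")
    fig.savefig(outdir / "forest.png", dpi=150, bbox_inches="tight")
    plt.close(fig)
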