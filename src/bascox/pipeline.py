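"""Pipeline orchestration: configuration, cohort CSV schema, run reports.

One :func:`run_pipeline` call executes simulate -> preprocess -> univariate
screen -> tune -> stability loop -> score -> association for one outcome and
returns a :class:`RunReport` whose every number is recomputable from the
config; rendering to JSON, Markdown or a CSV bundle is lossless.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .preprocess import preprocess
from .screen import screen_metabolites
from .simulate import BA_NAMES, CohortSpec, CohortTable, simulate_cohort
from .stability import BileAcidScorePipeline, BileAcidScoreResults

log = logging.getLogger(__name__)

#: cohort CSV column order (one row per subject); bile acids follow
SCHEMA_COLUMNS = [
    "subject_id", "time_mace", "event_mace", "time_death", "event_death",
    "age", "sex", "bmi", "smoking", "hypertension", "dyslipidemia", "t2d",
    "dx_ua", "dx_stemi", "dx_nstemi", "statin", "beta_blocker", "aspirin",
    "diuretic", "oad", "insulin", "egfr",
]


def write_cohort_csv(table: CohortTable, path, truth_path=None) -> None:
    """Write the cohort schema; missing cells become empty strings."""
    cols = [c for c in SCHEMA_COLUMNS if c in table.data.columns]
    cols += [c for c in table.data.columns if c not in cols]
    table.data[cols].to_csv(path, index=False, na_rep="")
    if truth_path is not None and table.truth is not None:
        table.truth.to_csv(truth_path, index=False)


def read_cohort_csv(path, truth_path=None, provenance: str = "real") -> CohortTable:
    """Read a cohort CSV (empty strings decode as missing)."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in SCHEMA_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort CSV lacks required column(s): {missing}")
    truth = None
    if truth_path is not None and Path(truth_path).exists():
        truth = pd.read_csv(truth_path)
        provenance = "synthetic"
    return CohortTable(data=df, truth=truth, provenance=provenance)


@dataclass
class PipelineConfig:
    """Every stage default plus per-stage seeds; YAML round-trippable."""

    seed: int = 0
    outcome: str = "mace"
    # input: either a CSV path or a synthetic draw
    cohort_csv: str | None = None
    n_subjects: int = 309
    # preprocessing
    missing_threshold: float = 0.20
    imputation_max_iter: int = 10
    imputation_learner: str = "bridge"
    int_offset: str = "blom"
    # tuning
    alpha_start: float = 0.10
    alpha_stop: float = 1.00
    alpha_step: float = 0.05
    n_folds: int = 10
    n_lambda: int = 30
    lambda_ratio: float = 0.01
    lambda_override: float | None = None
    alpha_override: float | None = None
    # stability loop
    n_iter: int = 100
    train_fraction: float = 0.8
    ties: str = "efron"

    def alpha_grid(self) -> np.ndarray:
        n = int(round((self.alpha_stop - self.alpha_start) / self.alpha_step)) + 1
        return np.round(self.alpha_start + self.alpha_step * np.arange(n), 4)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


@dataclass
class RunReport:
    """Everything one pipeline run produced, as plain serializable data."""

    config: dict
    preprocessing: dict
    screen: list
    tune: dict
    stability: dict
    score: dict | None
    association: dict | None
    status: str = "ok"
    timings: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "config": self.config,
            "preprocessing": self.preprocessing,
            "screen": self.screen,
            "tune": self.tune,
            "stability": self.stability,
            "score": self.score,
            "association": self.association,
            "status": self.status,
        }

    def fingerprint(self) -> str:
        """SHA-256 over the canonical JSON; timings excluded."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


def _association_block(results: BileAcidScoreResults) -> dict | None:
    if results.crude is None:
        return None
    block = {}
    for label, fit in (("crude", results.crude), ("adjusted", results.adjusted)):
        ci = fit.conf_int()
        block[label] = {
            "hr_per_sd": float(fit.hazard_ratios[0]),
            "ci_low": float(ci[0, 0]),
            "ci_high": float(ci[0, 1]),
            "p": float(fit.pvalues[0]),
            "converged": bool(fit.converged),
        }
    return block


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute the full analysis for one outcome under one config."""
    timings = {}
    t0 = time.perf_counter()
    if config.cohort_csv:
        table = read_cohort_csv(config.cohort_csv)
    else:
        table = simulate_cohort(CohortSpec(n_subjects=config.n_subjects,
                                           seed=config.seed))
    timings["input"] = time.perf_counter() - t0
    log.info("input stage done (n=%d, seed=%d)", len(table.data), config.seed)

    t0 = time.perf_counter()
    prepped, prep_report = preprocess(
        table,
        threshold=config.missing_threshold,
        max_iter=config.imputation_max_iter,
        seed=config.seed,
        int_offset=config.int_offset,
        learner=config.imputation_learner,
    )
    timings["preprocess"] = time.perf_counter() - t0
    log.info("preprocess done: removed %s", list(prep_report.removed_metabolites))

    t0 = time.perf_counter()
    screen_df = screen_metabolites(prepped, config.outcome, ties=config.ties)
    timings["screen"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    pipe = BileAcidScorePipeline(
        prepped,
        outcome=config.outcome,
        alpha_grid=config.alpha_grid(),
        n_folds=config.n_folds,
        n_lambda=config.n_lambda,
        lambda_ratio=config.lambda_ratio,
        n_iter=config.n_iter,
        fraction=config.train_fraction,
    )
    if config.alpha_override is not None or config.lambda_override is not None:
        results = _fit_with_overrides(pipe, config)
    else:
        results = pipe.fit(seed=config.seed)
    timings["model"] = time.perf_counter() - t0
    log.info("model stage done: alpha*=%.2f lambda*=%.6g, %d consistent",
             results.tune.alpha_star, results.tune.lambda_star,
             len(results.members))

    stab = results.stability
    return RunReport(
        config=asdict(config),
        preprocessing=prep_report.to_dict(),
        screen=json.loads(screen_df.to_json(orient="records")),
        tune=results.tune.to_dict(),
        stability={
            "names": stab.names,
            "counts": stab.counts.tolist(),
            "alpha_star": stab.alpha_star,
            "lambda_star": stab.lambda_star,
            "n_iter": stab.n_iter,
        },
        score=None if results.score_model is None else results.score_model.to_dict(),
        association=_association_block(results),
        status=results.status,
        timings=timings,
    )


def _fit_with_overrides(pipe: BileAcidScorePipeline,
                        config: PipelineConfig) -> BileAcidScoreResults:
    """Bypass tuning with fixed (alpha, lambda) — mainly for diagnostics."""
    from .stability import (TuneResult, associate_score, build_score_model,
                            consistent_set, split_train_test, stability_loop,
                            tune_alpha_lambda)

    seed = config.seed
    train, test = split_train_test(pipe.table, pipe.fraction, seed)
    alpha = config.alpha_override if config.alpha_override is not None else 0.5
    lam = config.lambda_override
    if lam is None:
        tuned = tune_alpha_lambda(train, test, outcome=pipe.outcome,
                                  alpha_grid=np.array([alpha]),
                                  n_folds=pipe.n_folds, n_lambda=pipe.n_lambda,
                                  lambda_ratio=pipe.lambda_ratio, seed=seed + 1)
        lam = tuned.lambda_star
    tune = TuneResult(
        alpha_grid=np.array([alpha]), lambda_per_alpha=np.array([lam]),
        cv_deviance=[], test_cindex=np.array([np.nan]),
        alpha_star=float(alpha), lambda_star=float(lam),
        split_seed=seed, outcome=pipe.outcome)
    stab = stability_loop(pipe.table, float(alpha), float(lam),
                          outcome=pipe.outcome, n_iter=pipe.n_iter,
                          fraction=pipe.fraction, base_seed=seed + 10_000)
    members = consistent_set(stab)
    if not members:
        return BileAcidScoreResults(
            outcome=pipe.outcome, tune=tune, stability=stab, members=[],
            score_model=None, crude=None, adjusted=None,
            status="no score constructed")
    score = build_score_model(pipe.table, stab, members)
    crude, adjusted = associate_score(pipe.table, score, pipe.outcome)
    return BileAcidScoreResults(outcome=pipe.outcome, tune=tune, stability=stab,
                                members=members, score_model=score,
                                crude=crude, adjusted=adjusted)


# --------------------------------------------------------------------------
# rendering
# --------------------------------------------------------------------------

def render_report(report: RunReport, fmt: str, out_dir) -> list[str]:
    """Write the report as 'json', 'markdown' or 'csv-bundle'; returns the
    list of files written."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if fmt == "json":
        path = out / "report.json"
        with open(path, "w") as fh:
            json.dump(report.to_dict(), fh, indent=2, sort_keys=True)
        return [str(path)]
    if fmt == "markdown":
        path = out / "report.md"
        path.write_text(_render_markdown(report))
        return [str(path)]
    if fmt == "csv-bundle":
        written = []
        screen = pd.DataFrame(report.screen)
        p = out / "screen.csv"
        screen.to_csv(p, index=False)
        written.append(str(p))
        counts = pd.DataFrame({
            "metabolite": report.stability["names"],
            "selection_count": report.stability["counts"],
        })
        p = out / "stability_counts.csv"
        counts.to_csv(p, index=False)
        written.append(str(p))
        if report.score is not None:
            weights = pd.DataFrame({
                "metabolite": report.score["members"],
                "weight": report.score["weights"],
                "ci_low": report.score["ci_low"],
                "ci_high": report.score["ci_high"],
            })
            p = out / "score_weights.csv"
            weights.to_csv(p, index=False)
            written.append(str(p))
        if report.association is not None:
            assoc = pd.DataFrame(report.association).T
            p = out / "association.csv"
            assoc.to_csv(p, index_label="model")
            written.append(str(p))
        return written
    raise ValueError(f"unknown report format {fmt!r}")


def _render_markdown(report: RunReport) -> str:
    lines = [f"# Bile-acid score run — outcome: {report.config['outcome']}", ""]
    prep = report.preprocessing
    removed = prep["removed_metabolites"]
    lines.append("## Preprocessing")
    lines.append(
        f"- removed for missingness > {prep['threshold']:.0%}: "
        + (", ".join(f"{k} ({v:.1%})" for k, v in removed.items())
           if removed else "none"))
    kept = [k for k in prep["missing_fractions"] if k not in removed]
    fr = [prep["missing_fractions"][k] for k in kept]
    lines.append(
        f"- remaining {len(kept)} metabolites: mean missingness "
        f"{100 * float(np.mean(fr)):.2f}% "
        f"(min {100 * min(fr):.2f}%, max {100 * max(fr):.2f}%)")
    lines.append("")
    lines.append("## Univariate screen (HR per 1 SD)")
    if report.screen:
        lines.append("| metabolite | crude HR (95% CI) | p | q | "
                     "adjusted HR (95% CI) | p | q |")
        lines.append("|---|---|---|---|---|---|---|")
        for r in report.screen:
            lines.append(
                "| {metabolite} | {chr:.2f} ({clo:.2f}, {chi:.2f}) | {cp:.3f} "
                "| {cq:.3f} | {ahr:.2f} ({alo:.2f}, {ahi:.2f}) | {ap:.3f} "
                "| {aq:.3f} |".format(
                    metabolite=r["metabolite"], chr=r["crude_hr"],
                    clo=r["crude_ci_low"], chi=r["crude_ci_high"],
                    cp=r["crude_p"], cq=r["crude_q"], ahr=r["adjusted_hr"],
                    alo=r["adjusted_ci_low"], ahi=r["adjusted_ci_high"],
                    ap=r["adjusted_p"], aq=r["adjusted_q"]))
    else:
        lines.append("(screen table empty)")
    lines.append("")
    lines.append("## Tuning")
    lines.append(f"- alpha* = {report.tune['alpha_star']:.2f}, "
                 f"lambda* = {report.tune['lambda_star']:.6g}, "
                 f"test C-index = {max(report.tune['test_cindex']):.3f}")
    lines.append("")
    lines.append(f"## Stability selection ({report.stability['n_iter']} iterations)")
    for name, cnt in sorted(zip(report.stability["names"],
                                report.stability["counts"]),
                            key=lambda x: -x[1]):
        lines.append(f"- {name}: {cnt}")
    lines.append("")
    lines.append("## Bile-acid score")
    if report.score is None:
        lines.append(f"**{report.status}** — no metabolite was selected in "
                     "every iteration.")
    else:
        ranked = sorted(zip(report.score["members"], report.score["weights"],
                            report.score["ci_low"], report.score["ci_high"]),
                        key=lambda x: -x[1])
        lines.append("Ranked mean coefficients (negative left, positive right):")
        lines.append("")
        lines.append("| metabolite | weight | 95% CI |")
        lines.append("|---|---|---|")
        for name, w, lo, hi in ranked:
            lines.append(f"| {name} | {w:+.4f} | ({lo:+.4f}, {hi:+.4f}) |")
        lines.append("")
        lines.append("### Score association (HR per 1 SD increment)")
        lines.append("| model | HR | 95% CI | p |")
        lines.append("|---|---|---|---|")
        for label in ("crude", "adjusted"):
            b = report.association[label]
            lines.append(f"| {label} | {b['hr_per_sd']:.2f} | "
                         f"({b['ci_low']:.2f}, {b['ci_high']:.2f}) | "
                         f"{b['p']:.4g} |")
    lines.append("")
    lines.append(f"fingerprint: `{report.fingerprint()}`")
    return "\n".join(lines) + "\n"
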