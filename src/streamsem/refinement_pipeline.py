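"""End-to-end workflow: preprocess, fit, prune insignificant paths, report.

The pipeline mirrors a standard covariance-structure analysis: descriptive
statistics and normality screening, log transformation of skewed variables,
standardization, ML fit of the hypothesized model, fit indices, critical-
ratio pruning of insignificant structural paths (|C.R.| < 1.96 by default),
refit, and effect decomposition of the refined model.

Pruning is stepwise by default — the single path with the smallest |C.R.|
below threshold is removed and the model refit before the next decision —
because batch removal can discard paths that regain significance after a
refit. ``batch=True`` removes all below-threshold paths at once per round.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from . import presets
from .bmi_index import bmi_per_site, read_taxa_csv
from .fit_indices import FitIndexReport, baseline_chi_square, compute_fit_indices
from .path_model import (
    EffectTable,
    FitError,
    FittedModel,
    PathModel,
    SampleMoments,
    fit_ml,
    parse_model,
)
from .preprocessing import NormalityResult, describe, ks_normality, log_transform, standardize
from .synthetic_data import simulate_standardized, to_raw_scale

logger = logging.getLogger(__name__)

__all__ = [
    "PruneStep",
    "AnalysisReport",
    "PipelineError",
    "prune_model",
    "run_pipeline",
    "render_tables",
]

SITE_COLUMNS = ["site_id", "urban_pct", "agri_pct", "bod", "tn", "tp", "bmi"]


class PipelineError(RuntimeError):
    """A stage-labelled pipeline failure."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


@dataclasses.dataclass(frozen=True)
class PruneStep:
    removed_path: str
    cr_at_removal: float
    p_at_removal: float
    refit_chi_square: float
    refit_df: int


def prune_model(
    model: PathModel,
    moments: SampleMoments,
    threshold: float = 1.96,
    *,
    batch: bool = False,
    initial_fit: FittedModel | None = None,
    **fit_kwargs,
) -> tuple[FittedModel, list[PruneStep]]:
    """Iteratively remove insignificant structural paths and refit.

    Only free path coefficients are candidates (never variances or
    exogenous covariances). Stepwise mode removes the path with the
    smallest |C.R.| below ``threshold`` per round; batch mode removes all
    below-threshold paths at once. Variables left without incident paths
    stay in the model with a free variance.
    """
    fitted = initial_fit if initial_fit is not None else fit_ml(model, moments, **fit_kwargs)
    if not fitted.converged:
        raise FitError("initial fit did not converge; cannot prune")
    log: list[PruneStep] = []
    while True:
        candidates = [
            (lab, fitted.cr[lab], fitted.p_value[lab])
            for lab in fitted.free_path_labels()
            if abs(fitted.cr[lab]) < threshold
        ]
        if not candidates:
            return fitted, log
        candidates.sort(key=lambda c: abs(c[1]))
        to_remove = candidates if batch else candidates[:1]
        new_model = fitted.model.without_edges([lab for lab, _, _ in to_remove])
        refitted = fit_ml(new_model, moments, **fit_kwargs)
        for lab, cr, p in to_remove:
            log.append(
                PruneStep(
                    removed_path=lab,
                    cr_at_removal=float(cr),
                    p_at_removal=float(p),
                    refit_chi_square=refitted.chi_square,
                    refit_df=refitted.df,
                )
            )
        if not refitted.converged:
            raise FitError(
                "refit after pruning did not converge; partial prune log: "
                + ", ".join(s.removed_path for s in log)
            )
        fitted = refitted


@dataclasses.dataclass
class AnalysisReport:
    descriptives: list
    normality: list[NormalityResult]
    initial_fit: FittedModel
    initial_indices: FitIndexReport
    prune_log: list[PruneStep]
    refined_fit: FittedModel
    refined_indices: FitIndexReport
    effects: EffectTable
    metadata: dict[str, Any]

    def to_dict(self) -> dict:
        def fit_dict(fit: FittedModel) -> dict:
            return {
                "estimates": fit.estimates,
                "se": fit.se,
                "cr": fit.cr,
                "p_value": fit.p_value,
                "standardized_estimates": fit.standardized_estimates,
                "chi_square": fit.chi_square,
                "df": fit.df,
                "converged": fit.converged,
                "iterations": fit.iterations,
                "n": fit.n,
                "implied": [[round(v, 12) for v in row] for row in fit.implied.tolist()],
            }

        return {
            "metadata": self.metadata,
            "descriptives": [dataclasses.asdict(r) for r in self.descriptives],
            "normality": [dataclasses.asdict(r) for r in self.normality],
            "initial": {"fit": fit_dict(self.initial_fit), "indices": self.initial_indices.to_dict()},
            "prune_log": [dataclasses.asdict(s) for s in self.prune_log],
            "refined": {"fit": fit_dict(self.refined_fit), "indices": self.refined_indices.to_dict()},
            "effects": {
                "names": self.effects.names,
                "direct": self.effects.direct.tolist(),
                "indirect": self.effects.indirect.tolist(),
                "total": self.effects.total.tolist(),
            },
        }


def _config_hash(config: Mapping[str, Any]) -> str:
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _load_sites(config: Mapping[str, Any]) -> tuple[pd.DataFrame, int | None]:
    if config.get("sites_csv"):
        df = pd.read_csv(config["sites_csv"])
        missing = [c for c in SITE_COLUMNS if c not in df.columns]
        if missing:
            raise PipelineError("load", f"site CSV missing columns: {missing}")
        return df[SITE_COLUMNS], None
    sim = config.get("simulate")
    if not sim:
        raise PipelineError("load", "config must provide either sites_csv or a simulate block")
    seed = int(sim.get("seed", config.get("seed", 0)))
    n = int(sim.get("n", presets.DEFAULT_N_SITES))
    if sim.get("model"):
        gen_model = parse_model(Path(sim["model"]).read_text())
    else:
        gen_model = presets.refined_population_model(
            float(sim.get("exog_corr", presets.DEFAULT_EXOG_CORR))
        )
    table = simulate_standardized(gen_model, n=n, seed=seed)
    if sim.get("raw", False):
        table = to_raw_scale(table, presets.MARGINAL_TARGETS, presets.LOGNORMAL_VARS)
    return table, seed


def run_pipeline(config: Mapping[str, Any]) -> AnalysisReport:
    """Execute the full workflow described by ``config``.

    Config keys: ``sites_csv`` or ``simulate {n, seed, raw, model,
    exog_corr}``, optional ``taxa_csv``, ``model`` (path to a model spec;
    default = bundled hypothesized model), ``log_vars``, ``threshold``,
    ``batch``, ``fit_on`` ("correlation" | "covariance"), ``outdir``.
    """
    config = dict(config)
    sites, sim_seed = _load_sites(config)
    variables = [c for c in sites.columns if c != "site_id"]

    if config.get("taxa_csv"):
        taxa = read_taxa_csv(config["taxa_csv"])
        scores, missing = bmi_per_site(taxa)
        if missing:
            logger.warning("taxa CSV has empty tables for sites: %s", missing)
        mapped = sites["site_id"].astype(str).map(scores)
        if mapped.isna().any():
            absent = sites.loc[mapped.isna(), "site_id"].tolist()
            raise PipelineError("bmi", f"taxa CSV lacks records for sites: {absent}")
        sites = sites.assign(bmi=mapped.to_numpy())

    data = sites[variables].astype(float)
    try:
        descriptives = describe(data)
    except ValueError as exc:
        raise PipelineError("describe", str(exc)) from None
    normality = [
        ks_normality(data[v].to_numpy(), variant="estimated", variable=v) for v in variables
    ]

    log_vars = config.get("log_vars")
    if log_vars is None:
        log_vars = list(variables)
    transformed = data.copy()
    for v in log_vars:
        if v not in transformed.columns:
            raise PipelineError("transform", f"log_vars names unknown variable {v!r}")
        try:
            transformed[v] = log_transform(transformed[v].to_numpy())
        except ValueError as exc:
            raise PipelineError("transform", f"{v}: {exc}") from None

    fit_on = config.get("fit_on", "correlation")
    try:
        z = standardize(transformed)
        kind = "correlation" if fit_on == "correlation" else "covariance"
        moments = SampleMoments.from_dataframe(z, kind=kind)
    except ValueError as exc:
        raise PipelineError("moments", str(exc)) from None

    model_path = config.get("model")
    model = parse_model(Path(model_path).read_text()) if model_path else presets.full_model()

    try:
        initial_fit = fit_ml(model, moments)
    except FitError as exc:
        raise PipelineError("fit", str(exc)) from None
    chi_b, df_b = baseline_chi_square(moments)
    initial_indices = compute_fit_indices(
        initial_fit.chi_square,
        initial_fit.df,
        chi_b,
        df_b,
        moments.n,
        S=initial_fit.moments.S,  # same variable order as the implied matrix
        sigma_hat=initial_fit.implied,
    )

    threshold = float(config.get("threshold", 1.96))
    try:
        refined_fit, prune_log = prune_model(
            model,
            moments,
            threshold,
            batch=bool(config.get("batch", False)),
            initial_fit=initial_fit,
        )
    except FitError as exc:
        raise PipelineError("prune", str(exc)) from None
    refined_indices = compute_fit_indices(
        refined_fit.chi_square,
        refined_fit.df,
        chi_b,
        df_b,
        moments.n,
        S=refined_fit.moments.S,
        sigma_hat=refined_fit.implied,
    )

    from . import __version__

    report = AnalysisReport(
        descriptives=descriptives,
        normality=normality,
        initial_fit=initial_fit,
        initial_indices=initial_indices,
        prune_log=prune_log,
        refined_fit=refined_fit,
        refined_indices=refined_indices,
        effects=refined_fit.effects(),
        metadata={
            "seed": sim_seed if sim_seed is not None else config.get("seed"),
            "config_hash": _config_hash(config),
            "streamsem_version": __version__,
            "n_sites": int(len(sites)),
            "fit_on": fit_on,
            "threshold": threshold,
        },
    )

    outdir = config.get("outdir")
    if outdir:
        _write_outputs(report, Path(outdir))
    return report


def _write_outputs(report: AnalysisReport, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "report.json").write_text(json.dumps(report.to_dict(), indent=2, sort_keys=True))
    (outdir / "tables.txt").write_text(render_tables(report))
    with open(outdir / "prune_log.tsv", "w") as fh:
        fh.write("removed_path\tcr_at_removal\tp_at_removal\trefit_chi_square\trefit_df\n")
        for s in report.prune_log:
            fh.write(
                f"{s.removed_path}\t{s.cr_at_removal:.6g}\t{s.p_at_removal:.6g}"
                f"\t{s.refit_chi_square:.6g}\t{s.refit_df}\n"
            )
    names = report.refined_fit.model.variables
    pd.DataFrame(report.refined_fit.implied, index=names, columns=names).to_csv(
        outdir / "refined_implied.csv"
    )
    pd.DataFrame(report.refined_fit.moments.S, index=names, columns=names).to_csv(
        outdir / "sample_moments.csv"
    )


def _fmt(x: float | None, nd: int = 3) -> str:
    return "n/a" if x is None else f"{x:.{nd}f}"


def render_tables(report: AnalysisReport) -> str:
    """Plain-text descriptives, index-comparison, path, and effect tables."""
    blocks: list[str] = []

    lines = ["Descriptive statistics", f"{'variable':<12}{'min':>9}{'max':>9}{'mean':>9}{'sd':>9}{'n':>6}"]
    for r in report.descriptives:
        lines.append(f"{r.variable:<12}{r.min:>9.2f}{r.max:>9.2f}{r.mean:>9.2f}{r.sd:>9.2f}{r.n:>6d}")
    blocks.append("\n".join(lines))

    lines = [
        "Model fit indices",
        f"{'index':<8}{'criterion':<12}{'initial':>10}{'refined':>10}",
    ]
    from .fit_indices import THRESHOLDS

    for name, (op, thr) in THRESHOLDS.items():
        ini = getattr(report.initial_indices, name)
        ref = getattr(report.refined_indices, name)
        lines.append(f"{name.upper():<8}{op + format(thr, '.2f'):<12}{_fmt(ini):>10}{_fmt(ref):>10}")
    blocks.append("\n".join(lines))

    lines = [
        "Refined model paths",
        f"{'path':<24}{'std.coef':>10}{'S.E.':>8}{'C.R.':>8}{'p':>8}",
    ]
    for row in report.refined_fit.summary_rows():
        lines.append(
            f"{row['path']:<24}{row['standardized']:>10.3f}{row['se']:>8.3f}"
            f"{row['cr']:>8.3f}{row['p']:>8.3f}"
        )
    blocks.append("\n".join(lines))

    eff = report.effects
    lines = ["Standardized effects on each variable (source -> target)"]
    for t in eff.names:
        for s in eff.names:
            vals = eff.of(s, t)
            if vals["total"] != 0.0:
                lines.append(
                    f"{s} -> {t}: direct {vals['direct']:.3f}, "
                    f"indirect {vals['indirect']:.3f}, total {vals['total']:.3f}"
                )
    blocks.append("\n".join(lines))

    return "\n\n".join(blocks) + "\n"
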