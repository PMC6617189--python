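"""End-to-end orchestration: read (or simulate) observation logs, filter to
dyadic aggression, compute weekly Elo ratings, assemble the modeling table,
compare the seven candidate mixed models by AICc, run drop-one
likelihood-ratio tests against the full model, Tukey contrasts on the best
activity-containing model, and binned-residual diagnostics.  Results are
rendered as JSON, CSV, or markdown tables."""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .errors import DomainError, RankwatchError
from . import elo as elo_mod
from . import glmm
from . import observations as obs
from .simulate import SyntheticConfig, generate

logger = logging.getLogger(__name__)


class StageError(RankwatchError):
    """Failure inside a named pipeline stage, carrying the manifest of
    stages that completed before the failure."""

    def __init__(self, stage: str, original: Exception, completed: list):
        self.stage = stage
        self.original = original
        self.completed = list(completed)
        super().__init__(f"pipeline stage '{stage}' failed: {original}")


@dataclass
class PipelineConfig:
    inputs: dict | None = None  # {individuals, sessions, agonistic, visitor}
    simulate: SyntheticConfig | None = None
    elo_params: elo_mod.EloParameters = field(default_factory=elo_mod.EloParameters)
    quadrature_nodes: int = 25
    tolerance: float = 1e-8
    random_slope: bool = False
    include_null: bool = False
    candidates: list | None = None  # list of term tuples overriding the default set
    seed: int = 0

    def __post_init__(self):
        if (self.inputs is None) == (self.simulate is None):
            raise DomainError("config must provide exactly one of 'inputs' or 'simulate'")

    @classmethod
    def from_dict(cls, raw: dict, seed: int | None = None) -> "PipelineConfig":
        sim = None
        if "simulate" in raw and raw["simulate"] is not None:
            sim_kwargs = dict(raw["simulate"])
            if "start_date" in sim_kwargs and isinstance(sim_kwargs["start_date"], str):
                sim_kwargs["start_date"] = date.fromisoformat(sim_kwargs["start_date"])
            sim = SyntheticConfig(**sim_kwargs)
        elo_kwargs = dict(raw.get("elo", {}) or {})
        model = dict(raw.get("model", {}) or {})
        cfg = cls(
            inputs=raw.get("inputs"),
            simulate=sim,
            elo_params=elo_mod.EloParameters(**elo_kwargs),
            quadrature_nodes=int(model.get("quadrature_nodes", 25)),
            tolerance=float(model.get("tolerance", 1e-8)),
            random_slope=bool(model.get("random_slope", False)),
            include_null=bool(model.get("include_null", False)),
            candidates=model.get("candidates"),
            seed=int(raw.get("seed", 0)),
        )
        if seed is not None:
            cfg.seed = seed
            if cfg.simulate is not None:
                cfg.simulate.seed = seed
        return cfg

    @classmethod
    def from_yaml(cls, path, seed: int | None = None) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw, seed=seed)

    def to_canonical_dict(self) -> dict:
        d: dict = {
            "seed": self.seed,
            "elo": {
                "start_rating": self.elo_params.start_rating,
                "k": self.elo_params.k,
                "expectation_form": self.elo_params.expectation_form,
                "expectation_scale": self.elo_params.expectation_scale,
            },
            "model": {
                "quadrature_nodes": self.quadrature_nodes,
                "tolerance": self.tolerance,
                "random_slope": self.random_slope,
                "include_null": self.include_null,
                "candidates": self.candidates,
            },
        }
        if self.inputs is not None:
            d["inputs"] = {k: str(v) for k, v in self.inputs.items()}
        if self.simulate is not None:
            sim = {
                k: (v.isoformat() if isinstance(v, date) else v)
                for k, v in self.simulate.__dict__.items()
                if k != "elo_params"
            }
            sim["activity_probs"] = list(self.simulate.activity_probs)
            sim["size_category_probs"] = list(self.simulate.size_category_probs)
            d["simulate"] = sim
        return d


@dataclass
class ReportBundle:
    summary: dict
    ratings: pd.DataFrame
    model_comparison: pd.DataFrame
    lrt: pd.DataFrame
    coefficients: pd.DataFrame
    sigma_b: float
    contrasts: pd.DataFrame
    diagnostics: pd.DataFrame
    exclusions: dict
    metadata: dict


def bundles_equal(a: ReportBundle, b: ReportBundle, atol: float = 1e-9) -> bool:
    """Content equality of two report bundles (used for round-trip checks)."""
    import numpy as np

    for name in ("ratings", "model_comparison", "lrt", "coefficients", "contrasts", "diagnostics"):
        fa, fb = getattr(a, name), getattr(b, name)
        if list(fa.columns) != list(fb.columns) or len(fa) != len(fb):
            return False
        for col in fa.columns:
            va, vb = fa[col].to_numpy(), fb[col].to_numpy()
            if va.dtype.kind in "fc" or vb.dtype.kind in "fc":
                ok = np.allclose(
                    va.astype(float), vb.astype(float), atol=atol, equal_nan=True
                )
            else:
                ok = (va.astype(str) == vb.astype(str)).all()
            if not ok:
                return False
    if not math.isclose(a.sigma_b, b.sigma_b, abs_tol=atol):
        return False
    return json.loads(json.dumps(a.summary)) == json.loads(json.dumps(b.summary))


def outcome_table_from_bundle(
    bundle,
    study_start: date,
    n_weeks: int,
    elo_params: elo_mod.EloParameters | None = None,
):
    """Run the rating stages on a dataset bundle and assemble the modeling
    table.  Returns ``(table, standardized weekly snapshots, exclusion report)``."""
    params = elo_params or elo_mod.EloParameters()
    dyadic, report = obs.filter_dyadic(bundle.agonistic_events)
    traj = elo_mod.run_sequence(dyadic, bundle.roster, params)
    snaps = elo_mod.standardize(
        elo_mod.weekly_snapshots(traj, study_start, n_weeks, bundle.roster, params)
    )
    table = obs.build_outcome_table(bundle.sessions, bundle.visitor_events, bundle.roster, snaps)
    return table, snaps, report


def _study_window(sessions):
    start = min(s.start.date() for s in sessions)
    end = max(s.start.date() for s in sessions)
    n_weeks = (end - start).days // 7 + 1
    return start, n_weeks


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Execute every stage in order and return the full report bundle."""
    completed: list = []

    def stage(name):
        completed.append(name)
        logger.info("pipeline stage: %s", name)

    try:
        stage("load")
        if config.simulate is not None:
            bundle, truth = generate(config.simulate)
            roster, sessions = bundle.roster, bundle.sessions
            agonistic, visitor = bundle.agonistic_events, bundle.visitor_events
            study_start, n_weeks = config.simulate.start_date, config.simulate.n_weeks
        else:
            paths = config.inputs
            roster = obs.read_roster(paths["individuals"])
            sessions = obs.read_sessions(paths["sessions"])
            agonistic = obs.read_agonistic(paths["agonistic"])
            visitor = obs.read_visitor_events(paths["visitor"], sessions)
            study_start, n_weeks = _study_window(sessions)
    except RankwatchError:
        raise
    except Exception as exc:  # pragma: no cover - defensive
        raise StageError("load", exc, completed) from exc

    try:
        stage("filter")
        dyadic, report = obs.filter_dyadic(agonistic)
        logger.info(
            "filter: %d events in, %d dyadic retained, %d excluded, %d contact",
            len(agonistic), report.n_retained, report.n_excluded_distinct, report.n_contact,
        )

        stage("rank")
        traj = elo_mod.run_sequence(dyadic, roster, config.elo_params)
        snaps = elo_mod.weekly_snapshots(traj, study_start, n_weeks, roster, config.elo_params)
        snaps = elo_mod.standardize(snaps)
        ratings = elo_mod.snapshots_to_frame(snaps)

        stage("table")
        table = obs.build_outcome_table(sessions, visitor, roster, snaps)
        summary = obs.summarize_dataset(agonistic, visitor, sessions, table, roster).to_dict()
        logger.info(
            "table: %d rows (%d dropped); %.1f%% of sessions with visitor-directed aggression",
            len(table), table.attrs.get("n_dropped", 0),
            summary["pct_sessions_with_aggression"],
        )
    except RankwatchError as exc:
        raise StageError(completed[-1], exc, completed[:-1]) from exc

    fit_kwargs = dict(quadrature_nodes=config.quadrature_nodes, tol=config.tolerance)
    try:
        stage("compare")
        if config.candidates is not None:
            cand = [
                glmm.ModelSpec(tuple(t), random_slope=config.random_slope)
                for t in config.candidates
            ]
        else:
            cand = [
                glmm.ModelSpec(s.fixed_terms, random_slope=config.random_slope)
                for s in glmm.default_candidates()
            ]
        if config.include_null:
            cand.append(glmm.ModelSpec((), random_slope=config.random_slope))
        comparison = glmm.compare_models(table, cand, **fit_kwargs)

        stage("lrt")
        full_spec = glmm.ModelSpec(glmm.FIXED_TERM_ORDER, random_slope=config.random_slope)
        fit_full = comparison.fits.get(full_spec.label) or glmm.fit_glmm(
            table, full_spec, **fit_kwargs
        )
        # intercept-plus-random-effect null fitted for nesting completeness
        null_fit = comparison.fits.get("Intercept only") or glmm.fit_glmm(
            table, glmm.ModelSpec((), random_slope=config.random_slope), **fit_kwargs
        )
        lrt_rows = []
        for term in glmm.FIXED_TERM_ORDER:
            reduced_terms = tuple(t for t in glmm.FIXED_TERM_ORDER if t != term)
            reduced_spec = glmm.ModelSpec(reduced_terms, random_slope=config.random_slope)
            fit_reduced = comparison.fits.get(reduced_spec.label) or glmm.fit_glmm(
                table, reduced_spec, **fit_kwargs
            )
            res = glmm.lrt(fit_full, fit_reduced)
            lrt_rows.append((term, res.chi2, res.df, res.p))
        lrt_df = pd.DataFrame(lrt_rows, columns=["dropped_term", "chi2", "df", "p"])

        stage("contrasts")
        ranked = comparison.table.dropna(subset=["rank"]).sort_values("rank")
        best_activity = None
        for _, row in ranked.iterrows():
            if "Crowd Activity" in row["model"]:
                best_activity = comparison.fits[row["model"]]
                break
        if best_activity is None:
            raise DomainError("no converged candidate includes crowd activity")
        contrasts = glmm.tukey_contrasts(best_activity)
        contrasts_df = pd.DataFrame(
            [
                {
                    "pair": f"{c.pair[0]} - {c.pair[1]}",
                    "estimate": c.estimate,
                    "se": c.se,
                    "z": c.z,
                    "p_unadj": c.p_unadjusted,
                    "p_adj": c.p_adjusted,
                }
                for c in contrasts
            ]
        )

        stage("diagnostics")
        best_fit = comparison.best()
        diag = glmm.residual_diagnostics(best_fit, table)
    except RankwatchError as exc:
        raise StageError(completed[-1], exc, completed[:-1]) from exc

    coef_df = best_activity.coefficient_frame()
    config_dict = config.to_canonical_dict()
    metadata = {
        "package_version": __version__,
        "seed": config.seed,
        "config": config_dict,
        "config_hash": hashlib.sha256(
            json.dumps(config_dict, sort_keys=True).encode()
        ).hexdigest(),
        "n_rows": int(len(table)),
        "n_dropped_rows": int(table.attrs.get("n_dropped", 0)),
        "best_model": best_fit.spec.label,
        "best_activity_model": best_activity.spec.label,
        "null_loglik": null_fit.loglik,
    }
    return ReportBundle(
        summary=summary,
        ratings=ratings,
        model_comparison=comparison.table,
        lrt=lrt_df,
        coefficients=coef_df,
        sigma_b=best_activity.sigma_b,
        contrasts=contrasts_df,
        diagnostics=diag,
        exclusions=report.__dict__,
        metadata=metadata,
    )


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

_CSV_TABLES = {
    "model_comparison.csv": "model_comparison",
    "lrt.csv": "lrt",
    "coefficients.csv": "coefficients",
    "contrasts.csv": "contrasts",
    "ratings.csv": "ratings",
    "diagnostics.csv": "diagnostics",
}


def render_report(bundle: ReportBundle, format: str, outdir) -> list:
    """Write the report in the requested format; returns the files written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    if format == "json":
        payload = {
            "summary": bundle.summary,
            "sigma_b": bundle.sigma_b,
            "exclusions": bundle.exclusions,
            "metadata": bundle.metadata,
        }
        for fname, attr in _CSV_TABLES.items():
            df = getattr(bundle, attr)
            payload[attr] = json.loads(df.to_json(orient="table", index=False))
        path = outdir / "report.json"
        path.write_text(json.dumps(payload, indent=2, default=str))
        written.append(path)
    elif format == "csv":
        for fname, attr in _CSV_TABLES.items():
            path = outdir / fname
            getattr(bundle, attr).to_csv(path, index=False)
            written.append(path)
        for fname, payload in (
            ("summary.json", bundle.summary),
            ("metadata.json", bundle.metadata),
            ("exclusions.json", bundle.exclusions),
        ):
            path = outdir / fname
            path.write_text(json.dumps(payload, indent=2, default=str))
            written.append(path)
    elif format == "markdown":
        lines = ["# Analysis report", ""]
        lines += ["## Candidate models (AICc)", ""]
        lines.append(bundle.model_comparison.to_markdown(index=False))
        lines += ["", "## Likelihood-ratio tests (drop-one vs full model)", ""]
        lines.append(bundle.lrt.to_markdown(index=False))
        lines += ["", "## Best activity-containing model coefficients", ""]
        lines.append(bundle.coefficients.to_markdown(index=False))
        lines.append(f"\nRandom-intercept SD: {bundle.sigma_b:.3f}")
        lines += ["", "## Tukey contrasts (crowd activity)", ""]
        lines.append(bundle.contrasts.to_markdown(index=False))
        path = outdir / "report.md"
        path.write_text("\n".join(lines) + "\n")
        written.append(path)
    else:
        raise DomainError(f"unknown report format {format!r}")
    return written


def load_report(path) -> ReportBundle:
    """Reload a ``report.json`` written by :func:`render_report`."""
    payload = json.loads(Path(path).read_text())
    frames = {}
    for attr in _CSV_TABLES.values():
        tbl = payload[attr]
        frames[attr] = pd.DataFrame(tbl["data"])[
            [f["name"] for f in tbl["schema"]["fields"] if f["name"] != "index"]
        ]
    return ReportBundle(
        summary=payload["summary"],
        ratings=frames["ratings"],
        model_comparison=frames["model_comparison"],
        lrt=frames["lrt"],
        coefficients=frames["coefficients"],
        sigma_b=payload["sigma_b"],
        contrasts=frames["contrasts"],
        diagnostics=frames["diagnostics"],
        exclusions=payload["exclusions"],
        metadata=payload["metadata"],
    )
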