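"""End-to-end orchestration: simulate -> evaluate -> reliability ->
associations -> report.

Each stage writes diffable text artifacts (CSV tables, JSON structures, one
delimited epoch matrix per dataset) into the output directory; a consolidated
report bundles the reliability tables, similarity summaries, trend
coefficients and provenance (config hash, seed, package version). Runs are
deterministic for a fixed seed: re-running from the recorded config
reproduces every number in the report.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .epoch_metrics import (
    acceptance_mask,
    average_included,
    label_pn,
    matched_table,
    similarity_table,
)
from .models import (
    ModelSpec,
    fit_glmm_logit_random_intercept,
    fit_lmm_random_intercept,
    lrt,
    pairwise_tukey,
    probability_curve,
)
from .preprocessing import EpochSet, FilterSpec, write_epoch_set
from .reliability import DESIGNS, reliability_report
from .synthetic import (
    CONDITIONS,
    SimulationConfig,
    child_rng,
    simulate_dataset,
    simulate_rater_decisions,
    simulate_rater_label,
)

__all__ = ["RunConfig", "ReportBundle", "run_pipeline", "validate_inputs", "STAGES"]

logger = logging.getLogger(__name__)

STAGES = ("simulate", "evaluate", "reliability", "associations", "report")

#: Intra-rater session pairings: within-day (1, 2) and across days (1, 3).
INTRA_PAIRS = {"intra_session": (1, 2), "inter_session": (1, 3)}


@dataclass
class RunConfig:
    """Configuration of a pipeline run."""

    stages: Sequence[str] = STAGES
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    filter: FilterSpec = field(default_factory=FilterSpec)
    pn_window_ms: tuple[float, float] = (-2000.0, 1500.0)
    alpha: float = 0.05
    outdir: str | Path = "mrcprel_out"
    seed: int | None = None
    log_level: str = "INFO"
    conditions: Sequence[str] = CONDITIONS
    fit_experience_model: bool = False

    def __post_init__(self) -> None:
        stages = tuple(self.stages)
        if stages != STAGES[: len(stages)]:
            raise ValueError(
                f"stages must form a prefix of {STAGES}, got {stages}"
            )
        self.stages = stages
        if self.seed is not None:
            self.sim = replace(self.sim, seed=int(self.seed))
        self.seed = self.sim.seed

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim_raw = raw.pop("sim", {})
        filt_raw = raw.pop("filter", {})
        sim = SimulationConfig(**sim_raw) if sim_raw else SimulationConfig()
        filt = FilterSpec(**filt_raw) if filt_raw else FilterSpec()
        if "pn_window_ms" in raw:
            raw["pn_window_ms"] = tuple(raw["pn_window_ms"])
        return cls(sim=sim, filter=filt, **raw)

    def digest(self) -> str:
        """Stable hash of the configuration for provenance."""
        payload = {
            "stages": list(self.stages),
            "sim": {
                k: v
                for k, v in asdict(self.sim).items()
                if k not in ("condition_params", "rater_profiles")
            },
            "condition_params": {
                c: asdict(p) for c, p in sorted(self.sim.condition_params.items())
            },
            "raters": [
                {**asdict(r), "accept_cs_slope": dict(r.accept_cs_slope)
                 if not isinstance(r.accept_cs_slope, float) else r.accept_cs_slope}
                for r in self.sim.rater_profiles
            ],
            "filter": asdict(self.filter),
            "pn_window_ms": list(self.pn_window_ms),
            "alpha": self.alpha,
            "conditions": list(self.conditions),
        }
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


@dataclass
class ReportBundle:
    """Consolidated results of a full run."""

    reliability: pd.DataFrame | None
    similarity_summary: pd.DataFrame | None
    lmm_contrasts: pd.DataFrame | None
    glmm_coefficients: pd.DataFrame | None
    glmm_lrt: dict | None
    provenance: dict


class StageError(RuntimeError):
    """An error in a named pipeline stage (partial outputs are retained)."""


def _simulate_stage(cfg: RunConfig, out: Path) -> dict:
    sim = cfg.sim
    datasets = {}
    truth = {}
    sim_dir = out / "datasets"
    sim_dir.mkdir(parents=True, exist_ok=True)
    for cond in cfg.conditions:
        for pid in range(sim.n_datasets_per_condition):
            ds = simulate_dataset(cond, pid, sim)
            datasets[ds.epochs.dataset_id] = ds
            write_epoch_set(ds.epochs, sim_dir / f"{ds.epochs.dataset_id}.txt")
            truth[ds.epochs.dataset_id] = {
                "condition": cond,
                "true_pn_latency_ms": ds.true_pn_latency_ms,
                "true_pn_amplitude": ds.true_pn_amplitude,
                "artefact_flags": ds.artefact_flags.astype(int).tolist(),
            }
    (out / "ground_truth.json").write_text(json.dumps(truth, indent=1))

    # similarity drives the simulated rater decisions
    sim_tables = {
        did: similarity_table(ds.epochs) for did, ds in datasets.items()
    }
    acc_frames = []
    label_rows = []
    for did, ds in datasets.items():
        cs = sim_tables[did]["cs"].values
        for profile in sim.rater_profiles:
            for session in range(1, sim.n_sessions + 1):
                rng = child_rng(sim.seed, "rater", did, profile.rater_id, session)
                acc = simulate_rater_decisions(ds.epochs, cs, profile, session, rng)
                acc_frames.append(acc)
                mask = acc["accept"].values.astype(bool)
                if not mask.any():
                    # a rater rejecting everything falls back to the grand
                    # average (they must still label a PN); flagged in the log
                    logger.warning(
                        "%s/%s/s%d accepted no epochs; labelling grand average",
                        did, profile.rater_id, session,
                    )
                    mask = np.ones(ds.epochs.n_epochs, dtype=bool)
                avg = average_included(ds.epochs, mask)
                pn = simulate_rater_label(
                    avg, profile, rng, window_ms=cfg.pn_window_ms
                )
                label_rows.append(
                    (did, ds.epochs.condition, profile.rater_id, session, pn)
                )
    acceptances = pd.concat(acc_frames, ignore_index=True)
    labels = pd.DataFrame(
        label_rows, columns=["dataset_id", "condition", "rater_id", "session", "pn_ms"]
    )
    acceptances.to_csv(out / "acceptances.csv", index=False)
    labels.to_csv(out / "labels.csv", index=False)
    return {"datasets": datasets, "acceptances": acceptances, "labels": labels}


def _evaluate_stage(cfg: RunConfig, out: Path, state: dict) -> None:
    datasets = state["datasets"]
    acceptances = state["acceptances"]
    sim_rows = []
    auto_rows = []
    for did, ds in datasets.items():
        st = similarity_table(ds.epochs)
        st.insert(1, "condition", ds.epochs.condition)
        sim_rows.append(st)
        avg = average_included(ds.epochs, np.ones(ds.epochs.n_epochs, dtype=bool))
        pn = label_pn(avg, window_ms=cfg.pn_window_ms)
        auto_rows.append((did, ds.epochs.condition, pn.pn_ms, pn.pn_amplitude))
    similarity = pd.concat(sim_rows, ignore_index=True)
    similarity.to_csv(out / "similarity.csv", index=False)
    pd.DataFrame(
        auto_rows, columns=["dataset_id", "condition", "pn_ms", "pn_amplitude"]
    ).to_csv(out / "auto_pn.csv", index=False)

    matched_frames = []
    raters = sorted(acceptances["rater_id"].unique())
    for design, (s1, s2) in INTRA_PAIRS.items():
        for r in raters:
            mt = matched_table(acceptances, ("intra", r, s1, s2))
            mt.insert(1, "rater_id", r)
            mt.insert(1, "design", design)
            matched_frames.append(mt)
    for session in sorted(acceptances["session"].unique()):
        mt = matched_table(acceptances, ("inter", int(session)))
        mt.insert(1, "rater_id", "all")
        mt.insert(1, "design", "inter_rater")
        matched_frames.append(mt)
    matched = pd.concat(matched_frames, ignore_index=True)
    matched.to_csv(out / "matched.csv", index=False)
    state["similarity"] = similarity
    state["matched"] = matched


def _reliability_stage(cfg: RunConfig, out: Path, state: dict) -> None:
    labels = state["labels"]
    frames = []
    for cond in cfg.conditions:
        for design in DESIGNS:
            frames.append(
                reliability_report(labels, design, cond, alpha=cfg.alpha)
            )
    rel = pd.concat(frames, ignore_index=True)
    rel.to_csv(out / "reliability.csv", index=False)
    state["reliability"] = rel


def _associations_stage(cfg: RunConfig, out: Path, state: dict) -> None:
    similarity = state["similarity"].query("valid")
    matched = state["matched"]

    # cosine similarity across conditions: random-intercept LMM + Tukey
    lmm_spec = ModelSpec(
        response="cs",
        fixed_terms=[f"C(condition, Treatment('{cfg.conditions[0]}'))"],
        cluster="dataset_id",
        family="gaussian",
    )
    lmm = fit_lmm_random_intercept(similarity, lmm_spec)
    contrasts = pairwise_tukey(lmm, "condition")
    contrast_df = pd.DataFrame(
        [
            {
                "level_a": c.pair[0],
                "level_b": c.pair[1],
                "estimate": c.estimate,
                "se": c.se,
                "t_stat": c.t_stat,
                "adjusted_p": c.adjusted_p,
                "df": c.df,
            }
            for c in contrasts
        ]
    )
    contrast_df.to_csv(out / "cs_condition_contrasts.csv", index=False)

    # matched-epoch probability vs similarity: random-intercept logistic GLMM,
    # pooling the intra-rater within-day comparison across raters
    intra = matched[matched["design"] == "intra_session"].merge(
        similarity[["dataset_id", "epoch_index", "condition", "cs"]],
        on=["dataset_id", "epoch_index"],
    )
    intra["matched"] = intra["matched"].astype(int)
    ref = cfg.conditions[0]
    cond_term = f"C(condition, Treatment('{ref}'))"
    full_spec = ModelSpec(
        response="matched",
        fixed_terms=[cond_term, f"cs:{cond_term}", "cs"],
        cluster="dataset_id",
        family="binomial",
    )
    reduced_spec = ModelSpec(
        response="matched",
        fixed_terms=[cond_term, "cs"],
        cluster="dataset_id",
        family="binomial",
    )
    full = fit_glmm_logit_random_intercept(intra, full_spec)
    reduced = fit_glmm_logit_random_intercept(intra, reduced_spec)
    interaction = lrt(full, reduced)

    coef = full.params.copy()
    coef.index.name = "term"
    coef = coef.reset_index()
    coef["random_intercept_sd"] = full.random_intercept_sd
    coef.to_csv(out / "matched_glmm_coefficients.csv", index=False)

    curves = []
    grid = np.round(np.linspace(-0.2, 1.0, 25), 4)
    for cond in cfg.conditions:
        cur = probability_curve(full, "cs", grid, at={"condition": cond})
        cur.insert(0, "condition", cond)
        curves.append(cur)
    pd.concat(curves, ignore_index=True).to_csv(out / "matched_probability_curves.csv", index=False)

    state["lmm"] = lmm
    state["lmm_contrasts"] = contrast_df
    state["glmm"] = full
    state["glmm_coefficients"] = coef
    state["glmm_lrt"] = {
        "chi2": interaction.chi2,
        "df": interaction.df,
        "p": interaction.p,
    }


def _report_stage(cfg: RunConfig, out: Path, state: dict) -> ReportBundle:
    similarity = state.get("similarity")
    summary = None
    if similarity is not None:
        summary = (
            similarity.query("valid")
            .groupby("condition", sort=True)["cs"]
            .agg(["mean", "std", "count"])
            .reset_index()
            .rename(columns={"count": "n_epochs"})
        )
        summary.to_csv(out / "similarity_summary.csv", index=False)
    provenance = {
        "seed": cfg.sim.seed,
        "config_digest": cfg.digest(),
        "package_version": __version__,
        "stages_run": list(cfg.stages),
    }
    bundle = ReportBundle(
        reliability=state.get("reliability"),
        similarity_summary=summary,
        lmm_contrasts=state.get("lmm_contrasts"),
        glmm_coefficients=state.get("glmm_coefficients"),
        glmm_lrt=state.get("glmm_lrt"),
        provenance=provenance,
    )
    report = {
        "provenance": provenance,
        "similarity_summary": None
        if summary is None
        else summary.to_dict(orient="records"),
        "reliability": None
        if bundle.reliability is None
        else bundle.reliability.to_dict(orient="records"),
        "cs_condition_contrasts": None
        if bundle.lmm_contrasts is None
        else bundle.lmm_contrasts.to_dict(orient="records"),
        "matched_glmm": None
        if bundle.glmm_coefficients is None
        else {
            "coefficients": bundle.glmm_coefficients.to_dict(orient="records"),
            "interaction_lrt": bundle.glmm_lrt,
        },
    }
    (out / "report.json").write_text(json.dumps(report, indent=1, default=float))
    return bundle


def run_pipeline(config: RunConfig) -> ReportBundle:
    """Execute the requested stage prefix, writing artifacts per stage.

    Stage errors propagate as :class:`StageError` naming the stage; outputs
    of completed stages are retained alongside a failure marker file.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    state: dict = {}
    bundle = ReportBundle(None, None, None, None, None, provenance={})
    runners = {
        "simulate": lambda: state.update(_simulate_stage(config, out)),
        "evaluate": lambda: _evaluate_stage(config, out, state),
        "reliability": lambda: _reliability_stage(config, out, state),
        "associations": lambda: _associations_stage(config, out, state),
    }
    for stage in config.stages:
        logger.info("running stage %s", stage)
        try:
            if stage == "report":
                bundle = _report_stage(config, out, state)
            else:
                runners[stage]()
        except Exception as exc:
            (out / "FAILED").write_text(f"stage={stage}\nerror={exc}\n")
            raise StageError(f"stage {stage!r} failed: {exc}") from exc
    return bundle


# ---------------------------------------------------------------------------
# Input validation
# ---------------------------------------------------------------------------

_SCHEMAS = {
    "acceptances.csv": {"dataset_id", "rater_id", "session", "epoch_index", "accept"},
    "labels.csv": {"dataset_id", "condition", "rater_id", "session", "pn_ms"},
    "similarity.csv": {"dataset_id", "epoch_index", "cs"},
    "matched.csv": {"dataset_id", "epoch_index", "comparison", "matched"},
}


def validate_inputs(
    outdir: str | Path, config: RunConfig | None = None
) -> list[dict]:
    """Schema/completeness checks over a pipeline output directory.

    Returns a machine-readable list of violations (empty when valid); an
    unreadable file becomes a violation entry, never a crash.
    """
    out = Path(outdir)
    violations: list[dict] = []

    def add(file: str, problem: str) -> None:
        violations.append({"file": file, "problem": problem})

    tables: dict[str, pd.DataFrame] = {}
    for fname, cols in _SCHEMAS.items():
        path = out / fname
        if not path.exists():
            continue
        try:
            df = pd.read_csv(path)
        except Exception as exc:
            add(fname, f"unreadable: {exc}")
            continue
        missing = cols - set(df.columns)
        if missing:
            add(fname, f"missing columns: {sorted(missing)}")
        else:
            tables[fname] = df

    n_samples = config.sim.n_samples if config is not None else None
    ds_dir = out / "datasets"
    if ds_dir.exists():
        for mat in sorted(ds_dir.glob("*.txt")):
            try:
                arr = np.atleast_2d(np.loadtxt(mat))
            except Exception as exc:
                add(str(mat.relative_to(out)), f"unreadable: {exc}")
                continue
            if config is not None:
                if arr.shape[0] != config.sim.n_epochs or arr.shape[1] != n_samples:
                    add(
                        str(mat.relative_to(out)),
                        f"dimension violation: {arr.shape} != "
                        f"({config.sim.n_epochs}, {n_samples})",
                    )

    if config is not None and "labels.csv" in tables:
        labels = tables["labels.csv"]
        expected_raters = [p.rater_id for p in config.sim.rater_profiles]
        sessions = range(1, config.sim.n_sessions + 1)
        for cond in config.conditions:
            for pid in range(config.sim.n_datasets_per_condition):
                did = f"{cond}-{pid:02d}"
                for r in expected_raters:
                    for s in sessions:
                        hit = labels[
                            (labels["dataset_id"] == did)
                            & (labels["rater_id"] == r)
                            & (labels["session"] == s)
                        ]
                        if hit.empty:
                            add(
                                "labels.csv",
                                f"missing cell: dataset={did}, rater={r}, session={s}",
                            )
    return violations
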