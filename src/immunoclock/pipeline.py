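"""End-to-end orchestration: simulate -> extract -> preprocess ->
univariate -> elastic net (LOOCV) -> bootstrap -> network/communities ->
confounders, with a JSON-serializable summary report.

Every stage is logged with the seed in use; rerunning with the same
configuration and seed reproduces the report bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import SimConfig, default_config
from .errors import PipelineStageError, ValidationError
from .features import assemble_features
from .model import DEFAULT_THRESHOLD_FRAC, ImmuneAgeModel
from .network import (
    build_network,
    community_coverage,
    detect_communities,
    direction_summary,
    mds_layout,
)
from .preprocess import preprocess, spearman_univariate
from .simulate import generate_cohort, simulate_events

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Settings for one end-to-end run."""

    sim: SimConfig = None
    seed: int = 0
    bootstrap_B: int = 1000
    bootstrap_threshold_frac: float = DEFAULT_THRESHOLD_FRAC
    network_threshold: float = 0.8
    fdr_cut: float = 0.1
    top_k_communities: int = 5
    nested_cv: bool = False
    compute_layout: bool = False

    def validate(self):
        if self.bootstrap_B < 1:
            raise ValidationError("bootstrap_B must be >= 1")
        if not 0 < self.network_threshold < 1:
            raise ValidationError("network_threshold must lie in (0, 1)")


def _config_hash(cfg: PipelineConfig) -> str:
    payload = {
        f.name: (getattr(cfg, f.name).to_dict() if f.name == "sim" else getattr(cfg, f.name))
        for f in dataclasses.fields(cfg)
    }
    blob = json.dumps(payload, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(config: PipelineConfig | None = None, out_dir=None) -> dict:
    """Execute the full analysis and return the report bundle.

    The report dict contains seven sections: ``simulation``, ``features``,
    ``preprocess``, ``univariate``, ``model``, ``network`` and
    ``confounders``, plus a run header with the seed and a configuration
    hash.  With ``out_dir`` set, all intermediate tables are also written
    as delimited text / JSON.
    """
    cfg = config or PipelineConfig()
    if cfg.sim is None:
        cfg.sim = default_config(seed=cfg.seed)
    cfg.validate()  # fail fast (e.g. B = 0) before any computation
    cfg.sim.validate()
    report: dict = {
        "seed": cfg.seed,
        "config_hash": _config_hash(cfg),
    }
    artifacts: dict = {}

    def stage(name, fn):
        try:
            return fn()
        except Exception as exc:  # noqa: BLE001 - re-tagged with the stage
            report["failed_stage"] = name
            report["partial_artifacts"] = sorted(artifacts)
            raise PipelineStageError(name, str(exc)) from exc

    cohort = stage("simulate", lambda: generate_cohort(cfg.sim, seed=cfg.seed))
    events = stage("simulate", lambda: simulate_events(cohort, cfg.sim, seed=cfg.seed))
    artifacts["cohort"] = cohort
    report["simulation"] = {
        "n_samples": int(len(cohort)),
        "n_term": int(cohort["term"].sum()),
        "n_preterm": int((~cohort["term"]).sum()),
        "events_per_condition": cfg.sim.events_per_condition,
    }

    fm = stage("extract", lambda: assemble_features(events, panel=cfg.sim.panel))
    artifacts["features"] = fm
    classes = fm.classes()
    report["features"] = {
        "n_features": len(fm.feature_ids),
        "n_frequency": int((classes == "frequency").sum()),
        "n_basal": int((classes == "basal").sum()),
        "n_response": int((classes == "response").sum()),
        "n_dropped_sparse": len(fm.dropped),
    }

    fmp, log = stage("preprocess", lambda: preprocess(fm))
    artifacts["preprocess_log"] = log
    report["preprocess"] = {
        "n_kept": int(log["kept"].sum()),
        "n_removed_variance": int((log["removed_by"] == "variance").sum()),
        "n_removed_median": int((log["removed_by"] == "median").sum()),
    }

    ga = cohort.set_index("sample_id")["ga_weeks"].reindex(fmp.sample_ids)
    uni = stage("univariate", lambda: spearman_univariate(fmp, ga))
    artifacts["univariate"] = uni
    report["univariate"] = {
        "n_tested": int(uni["p"].notna().sum()),
        "n_fdr_significant": int((uni["q"] < cfg.fdr_cut).sum()),
    }

    model = ImmuneAgeModel(fmp, ga)
    res = stage("fit", lambda: model.fit(nested=cfg.nested_cv))
    artifacts["model"] = res
    report["model"] = {
        "rho": res.rho,
        "p": res.pvalue,
        "alpha": res.alpha,
        "lambda": res.lam,
        "n_selected": len(res.selected_features),
    }

    tally = stage(
        "bootstrap",
        lambda: res.bootstrap(
            B=cfg.bootstrap_B,
            threshold_frac=cfg.bootstrap_threshold_frac,
            seed=cfg.seed,
        ),
    )
    artifacts["bootstrap"] = tally
    informative = tally.informative
    report["bootstrap"] = {
        "B": tally.B,
        "skipped": tally.skipped,
        "threshold": tally.threshold,
        "n_informative": len(informative),
    }

    def _network():
        net = build_network(fmp, threshold=cfg.network_threshold, node_weights=tally.counts)
        labels = detect_communities(net, informative, seed=cfg.seed)
        cov = community_coverage(labels, cfg.top_k_communities) if len(labels) else float("nan")
        layout = mds_layout(net, seed=cfg.seed) if cfg.compute_layout else None
        return net, labels, cov, layout

    net, labels, coverage, layout = stage("network", _network)
    dirs = stage(
        "network", lambda: direction_summary(informative, uni, classes, fdr_cut=cfg.fdr_cut)
    )
    artifacts["network"] = net
    report["network"] = {
        "n_nodes": net.number_of_nodes(),
        "n_edges": net.number_of_edges(),
        "n_communities": int(labels.nunique()) if len(labels) else 0,
        "top_k": cfg.top_k_communities,
        "top_k_coverage": coverage,
        "direction_summary": dirs,
    }

    conf = stage("confounders", lambda: res.confounder_analysis(cohort))
    artifacts["confounders"] = conf
    report["confounders"] = {
        "n_covariates": int(len(conf)),
        "max_prediction_p": float(conf["prediction_p"].max()),
        "any_confounder_significant": bool((conf["confounder_p"] < 0.05).any()),
        "table": conf.reset_index().to_dict(orient="records"),
    }

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        cohort.to_csv(out / "cohort.csv", index=False, na_rep="NA")
        fm.to_csv(out / "features.csv")
        fm.defs_to_json(out / "feature_defs.json")
        log.to_csv(out / "preprocess_log.csv")
        uni.to_csv(out / "univariate.csv")
        res.predictions.rename("ga_pred").to_csv(out / "predictions.csv")
        res.coef.to_csv(out / "coefficients.csv")
        tally.to_frame().to_csv(out / "bootstrap_counts.csv")
        nx_edges = pd.DataFrame(
            [(u, v, d["r"]) for u, v, d in net.edges(data=True)],
            columns=["source", "target", "r"],
        )
        nx_edges.to_csv(out / "network_edges.csv", index=False)
        labels.rename("community").to_csv(out / "communities.csv")
        if layout is not None:
            layout.to_csv(out / "layout.csv")
        conf.to_csv(out / "confounders.csv")
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=1, default=float)

    return report
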