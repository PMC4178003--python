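"""End-to-end synthetic-study driver.

Runs the full analysis on a generated cohort and emits every intermediate
product as a seeded, provenance-stamped TSV/JSON bundle: the cohort, the
group-wise correlation matrices, the stepwise selection trace, the
measure-versus-subset-size tables for the exhaustive and forward rankings,
single/pair measure tables, the fitted panel model, the forest importance
ranking and the longitudinal trajectories.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .cohort import GeneratorConfig, sample_cohort, write_cohort
from .ensemble import repeated_evaluation, subset_size_curve
from .errors import ConfigurationError
from .forest import fit_forest, mda_importance, oob_error
from .preprocess import group_correlations, normalize
from .scoring import load_published_model, score_cohort
from .selection import forward_selection, stepwise_trace
from .svm import class_penalties, fit_l1_svm


@dataclass
class PipelineConfig:
    """Settings for one full synthetic-study run."""

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    method: str = "cca"              # cca | fs
    k_max: int = 19
    B: int = 50                      # bagging ensemble size
    R: int = 100                     # repeated random splits
    n_trees: int = 1000
    seed: int = 42
    normalization: str = "global"    # global | train-only
    positive_upweighted: bool = True
    curve_k_max: int = 8             # evaluate measure-vs-k curves up to this k

    def validate(self) -> None:
        if self.method not in ("cca", "fs"):
            raise ConfigurationError(f"method must be 'cca' or 'fs', got {self.method!r}")
        for name in ("k_max", "B", "R", "n_trees", "curve_k_max"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be positive")
        if self.normalization not in ("global", "train-only"):
            raise ConfigurationError("normalization must be 'global' or 'train-only'")

    def config_hash(self) -> str:
        doc = asdict(self)
        doc["generator"]["scales"] = dict(doc["generator"]["scales"])
        return hashlib.sha256(json.dumps(doc, sort_keys=True, default=str)
                              .encode()).hexdigest()[:12]

    @classmethod
    def from_mapping(cls, doc: dict) -> "PipelineConfig":
        gen_keys = doc.get("generator", {})
        gen = GeneratorConfig(**gen_keys)
        rest = {k: v for k, v in doc.items() if k != "generator"}
        cfg = cls(generator=gen, **rest)
        cfg.validate()
        return cfg


def _header(cfg: PipelineConfig, stage: str) -> list[str]:
    return [f"sepsipanel {__version__} stage={stage}",
            f"seed={cfg.seed} config_hash={cfg.config_hash()}"]


def _write_table(frame: pd.DataFrame, path: Path, cfg: PipelineConfig, stage: str,
                 index: bool = False) -> None:
    with open(path, "w") as fh:
        for line in _header(cfg, stage):
            fh.write(f"# {line}\n")
        frame.to_csv(fh, sep="\t", index=index)


def run_pipeline(config: PipelineConfig, outdir) -> dict[str, Path]:
    """Run the full synthetic study; returns a name -> path report bundle."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    log: list[str] = []

    def emit(name: str, path: Path) -> None:
        paths[name] = path
        log.append(f"[{name}] wrote {path.name}")

    stage = "simulate"
    try:
        gen = config.generator.with_overrides(seed=config.seed)
        cohort = sample_cohort(gen)
        p = outdir / "cohort.tsv"
        write_cohort(cohort, p, header_lines=_header(config, stage))
        emit("cohort", p)

        stage = "correlations"
        X = cohort.features()
        y = cohort.labels()
        corr = group_correlations(X, y)
        for g, label in ((0, "nonsevere"), (1, "severe")):
            p = outdir / f"correlations_{label}.tsv"
            _write_table(corr[g], p, config, stage, index=True)
            emit(f"correlations_{label}", p)

        stage = "normalize"
        X_norm, _ = normalize(X)

        stage = "select"
        trace = stepwise_trace(X_norm, y, config.k_max)
        p = outdir / "selection_trace.tsv"
        trace.to_tsv(p, header_lines=_header(config, stage))
        emit("selection_trace", p)
        fs_order = forward_selection(X_norm, y, config.k_max)
        p = outdir / "forward_selection.tsv"
        _write_table(pd.DataFrame({"dim": range(1, len(fs_order) + 1),
                                   "feature": fs_order}), p, config, stage)
        emit("forward_selection", p)

        stage = "evaluate"
        if config.method == "cca":
            ranking = trace
            panel = trace.members_at(min(3, config.k_max))
        else:
            ranking = fs_order[: config.curve_k_max]
            panel = tuple(fs_order[:3])
        curve = subset_size_curve(X, y, _truncate(ranking, config.curve_k_max),
                                  B=config.B, R=config.R, seed=config.seed)
        p = outdir / "measures_vs_k.tsv"
        _write_table(curve, p, config, stage)
        emit("measures_vs_k", p)

        singles = []
        for feat in list(X.columns):
            res = repeated_evaluation(X, y, (feat,), B=config.B, R=config.R,
                                      seed=config.seed)
            for m in ("TPR", "TNR", "PPV", "NPV"):
                singles.append({"variable": feat, "measure": m,
                                "mean": res.mean(m), "se": res.se(m)})
        p = outdir / "single_biomarker_measures.tsv"
        _write_table(pd.DataFrame(singles), p, config, stage)
        emit("single_biomarker_measures", p)

        stage = "fit"
        Xp_norm, params = normalize(X.loc[:, list(panel)])
        penalties = class_penalties(y, config.positive_upweighted)
        model, diag = fit_l1_svm(Xp_norm, y, penalties=penalties, norm_params=params)
        p = outdir / "panel_model.json"
        model.to_json(p, provenance=f"seed={config.seed} panel={','.join(panel)} "
                                    f"objective={diag.objective_value:.6f}")
        emit("panel_model", p)

        stage = "importance"
        rf = fit_forest(X, y, n_trees=config.n_trees, seed=config.seed)
        ranking_rf = mda_importance(rf, X, y, seed=config.seed)
        rf_table = ranking_rf.entries.copy()
        rf_table["oob_error"] = oob_error(rf, X, y)
        p = outdir / "rf_importance.tsv"
        _write_table(rf_table, p, config, stage)
        emit("rf_importance", p)

        stage = "trajectory"
        traj = score_cohort(cohort, load_published_model())
        p = outdir / "trajectories.tsv"
        traj.to_tsv(p, header_lines=_header(config, stage))
        emit("trajectories", p)
        p = outdir / "trajectory_group_daily.tsv"
        _write_table(traj.group_daily, p, config, stage)
        emit("trajectory_group_daily", p)
    except Exception as exc:
        log.append(f"ABORTED at stage {stage}: {exc}")
        (outdir / "run_log.txt").write_text("\n".join(log) + "\n")
        raise

    log.append(f"done seed={config.seed} hash={config.config_hash()}")
    p = outdir / "run_log.txt"
    p.write_text("\n".join(log) + "\n")
    paths["run_log"] = p
    return paths


def _truncate(ranking, k_max: int):
    from .selection import SelectionTrace

    if isinstance(ranking, SelectionTrace):
        k = min(k_max, len(ranking.member_sets))
        return SelectionTrace(ranking.frame.iloc[:k], ranking.member_sets[:k])
    return list(ranking)[:k_max]
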