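"""Run configuration and the end-to-end pipeline orchestrator.

A :class:`RunConfig` (built in code or loaded from YAML) ties the
stages together: simulate or load a cohort, encode, mine, featurize,
fit one model per horizon, evaluate the three approaches, and write all
artifacts plus a manifest (seeds, config hash, package versions) into a
run directory.  Every random draw flows from the single config seed via
named substreams, so the manifest suffices to reproduce any artifact.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import yaml

from .cohort import (CohortParams, PlantedPattern, cohort_summary, generate_cohort,
                     read_cohort_csv, write_cohort_csv)
from .encoding import write_sequences_tsv
from .features import write_feature_matrix
from .mining import MiningParams, write_patterns_jsonl
from .model import DEFAULT_LAMBDAS, ResidualSurvivalModel, compare_approaches

__all__ = ["RunConfig", "run_pipeline", "substream"]

_ALLOWED_HORIZONS = (2, 6, 9)


def substream(seed: int, name: str) -> int:
    """Derive a named child seed (< 2**31) from the master seed."""
    digest = hashlib.sha256(f"{seed}:{name}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class RunConfig:
    """Configuration of one end-to-end experiment."""

    seed: int = 0
    out_dir: str = "runs/run0"
    # Either synthetic-cohort parameters or paths to an existing cohort.
    cohort: Optional[CohortParams] = None
    patients_csv: Optional[str] = None
    visits_csv: Optional[str] = None
    volume_representation: str = "rate_change"
    mining_grid: Tuple[MiningParams, ...] = (MiningParams(),)
    horizons: Tuple[int, ...] = (2, 6, 9)
    lambdas: Tuple[float, ...] = DEFAULT_LAMBDAS
    censor_policy: str = "exclude"
    train_frac: float = 0.75
    cv_folds: int = 10
    cv_repeats: int = 3
    bootstrap_replicates: int = 2000
    compare: bool = True

    def __post_init__(self):
        self.horizons = tuple(self.horizons)
        if not self.horizons or not set(self.horizons) <= set(_ALLOWED_HORIZONS):
            raise ValueError(f"horizons must be a non-empty subset of {_ALLOWED_HORIZONS}")
        if not self.mining_grid:
            raise ValueError("mining grid must be non-empty")
        self.mining_grid = tuple(
            m if isinstance(m, MiningParams) else MiningParams(**m) for m in self.mining_grid
        )
        if (self.patients_csv is None) != (self.visits_csv is None):
            raise ValueError("patients_csv and visits_csv must be given together")
        if self.cohort is None and self.patients_csv is None:
            self.cohort = CohortParams(seed=substream(self.seed, "cohort"))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: Dict) -> "RunConfig":
        raw = dict(raw)
        if "cohort" in raw and isinstance(raw["cohort"], dict):
            cohort = dict(raw["cohort"])
            if "planted_patterns" in cohort:
                cohort["planted_patterns"] = tuple(
                    PlantedPattern(
                        elements=tuple(dict(e) for e in p["elements"]),
                        hazard_log_odds=p.get("hazard_log_odds", 2.0),
                        prevalence=p.get("prevalence", 0.35),
                    )
                    for p in cohort["planted_patterns"]
                )
            raw["cohort"] = CohortParams(**cohort)
        if "mining_grid" in raw:
            raw["mining_grid"] = tuple(
                m if isinstance(m, MiningParams) else MiningParams(**m)
                for m in raw["mining_grid"]
            )
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> Dict:
        def _convert(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: _convert(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, (tuple, list)):
                return [_convert(v) for v in obj]
            if isinstance(obj, dict):
                return {k: _convert(v) for k, v in obj.items()}
            return obj

        return {f.name: _convert(getattr(self, f.name)) for f in dataclasses.fields(self)}

    def hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _load_records(config: RunConfig):
    if config.patients_csv is not None:
        return read_cohort_csv(config.patients_csv, config.visits_csv)
    return generate_cohort(config.cohort)


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full experiment; returns the run directory.

    Artifacts per horizon: mined patterns (JSONL), labeled feature
    matrix (CSV + JSON sidecar), fitted model (JSON), metrics (CSV),
    ranked pattern-statistics tables (CSV), a per-patient trajectory
    report, and — when ``compare`` is on — the three-approach AUC
    comparison with bootstrap CIs and pairwise p-values.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "setup"
    try:
        stage = "simulate"
        records = _load_records(config)
        write_cohort_csv(records, out)
        cohort_summary(records).to_csv(out / "cohort_summary.csv", index=False)

        metrics_rows = []
        for horizon in config.horizons:
            stage = f"fit-h{horizon}"
            model = ResidualSurvivalModel(
                records, horizon,
                volume_representation=config.volume_representation,
                mining_grid=config.mining_grid, lambdas=config.lambdas,
                censor_policy=config.censor_policy, train_frac=config.train_frac,
                cv_folds=config.cv_folds, cv_repeats=config.cv_repeats,
            )
            results = model.fit(seed=substream(config.seed, f"fit-h{horizon}"))
            prefix = out / f"h{horizon:02d}"
            write_patterns_jsonl(results.patterns, f"{prefix}_patterns.jsonl")
            write_feature_matrix(results.X_train, results.y_train, results.meta,
                                 f"{prefix}_features.csv", f"{prefix}_features.json")
            _write_model_json(results, f"{prefix}_model.json", config)
            stage = f"evaluate-h{horizon}"
            harmful, protective = results.rank_patterns()
            harmful.to_csv(f"{prefix}_patterns_le_horizon.csv", index=False)
            protective.to_csv(f"{prefix}_patterns_gt_horizon.csv", index=False)
            row = {
                "horizon_months": horizon,
                "cv_auc": results.cv_auc,
                "cv_average_precision": results.cv_average_precision,
                "test_auc": results.test_auc,
                "test_average_precision": results.test_average_precision,
                "n_patterns": len(results.patterns),
                "n_selected": len(results.fit_result.selected),
                "lambda": results.fit_result.lam,
                "threshold": results.threshold,
            }
            if config.compare:
                stage = f"compare-h{horizon}"
                comparison = compare_approaches(
                    records, horizon, seed=substream(config.seed, f"compare-h{horizon}"),
                    mining_grid=config.mining_grid, lambdas=config.lambdas,
                    n_replicates=config.bootstrap_replicates,
                    censor_policy=config.censor_policy, cv_folds=config.cv_folds,
                    cv_repeats=config.cv_repeats)
                _write_comparison(comparison, f"{prefix}_approaches.csv")
                for name, res in comparison["approaches"].items():
                    row[f"auc_{name}"] = res.auc
            metrics_rows.append(row)
            stage = f"report-h{horizon}"
            example = next((r for r in records if r.patient_id in set(results.test_ids)
                            and len(r.visits) >= 6), records[0])
            results.trajectory(example).to_csv(
                f"{prefix}_trajectory_{example.patient_id}.csv", index=False)

        import pandas as pd

        pd.DataFrame(metrics_rows).to_csv(out / "metrics.csv", index=False)
        _write_manifest(config, out, status="complete")
    except Exception as exc:
        _write_manifest(config, out, status=f"failed at stage {stage}: {exc}")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    return out


def _write_model_json(results, path, config: RunConfig) -> None:
    fr = results.fit_result
    payload = {
        "horizon_months": results.horizon.months,
        "mining_params": dataclasses.asdict(results.mining_params),
        "lambda": fr.lam,
        "threshold": fr.threshold,
        "intercept": fr.intercept,
        "coefficients": {n: float(c) for n, c in zip(fr.feature_names, fr.coefficients)
                         if c != 0},
        "pattern_definitions": results.meta,
        "scheme_fingerprint": results.scheme.fingerprint() if results.scheme else None,
        "seed": results.seed,
        "config_hash": config.hash(),
        "train_ids": results.train_ids,
        "test_ids": results.test_ids,
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2)


def _write_comparison(comparison, path) -> None:
    import pandas as pd

    rows = []
    for name, res in comparison["approaches"].items():
        rows.append({"approach": name, "auc": res.auc, "ci_low": res.ci_low,
                     "ci_high": res.ci_high,
                     "average_precision": res.average_precision})
    frame = pd.DataFrame(rows)
    for (a, b), p in comparison["p_values"].items():
        frame.loc[frame.approach == a, f"p_vs_{b}"] = p
    frame.to_csv(path, index=False)


def _write_manifest(config: RunConfig, out: Path, status: str) -> None:
    import pandas
    import scipy
    import sklearn

    manifest = {
        "status": status,
        "config": config.to_dict(),
        "config_hash": config.hash(),
        "versions": {
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pandas.__version__,
            "scipy": scipy.__version__,
            "scikit-learn": sklearn.__version__,
        },
    }
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, default=str)
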