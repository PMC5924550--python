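"""End-to-end orchestration: synth/load -> rank -> IFS (SNN and RF) -> rules.

A single :class:`RunConfig` drives the whole pipeline; one global seed
deterministically derives per-stage seeds (stable hash of stage name and
global seed), so any stage can be replayed in isolation. Every run writes
a manifest echoing the exact configuration and the resolved seeds.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from . import dataset as dio
from . import ifs as ifs_mod
from . import mcfs as mcfs_mod
from . import rules as rules_mod
from .classifiers import RFConfig, SNNConfig
from .synth import SyntheticSpec, generate_dataset

__all__ = ["RunConfig", "stage_seed", "run_pipeline"]

log = logging.getLogger("cnvsift")


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    digest = hashlib.sha256(f"{stage}:{global_seed}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class RunConfig:
    """Everything a pipeline run needs; fully serializable."""

    # input: either paths to a matrix + label table, or a synthetic spec
    matrix_path: str | None = None
    labels_path: str | None = None
    delimiter: str = "\t"
    synthetic: SyntheticSpec | None = field(
        default_factory=lambda: SyntheticSpec()
    )

    mcfs: mcfs_mod.MCFSParams = field(default_factory=mcfs_mod.MCFSParams)
    ifs_step: int = 10
    ifs_n_max: int = 500
    ifs_delta: float = 0.05
    ifs_budget: int = 3000
    cv_folds: int = 10
    snn: SNNConfig = field(default_factory=SNNConfig)
    rf: RFConfig = field(default_factory=RFConfig)
    rules_p: float = 1.0
    ripper: rules_mod.RipperParams = field(default_factory=rules_mod.RipperParams)
    seed: int = 0
    out_dir: str = "cnvsift_run"

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        for key, sub in (
            ("synthetic", SyntheticSpec),
            ("mcfs", mcfs_mod.MCFSParams),
            ("snn", SNNConfig),
            ("rf", RFConfig),
            ("ripper", rules_mod.RipperParams),
        ):
            if d.get(key) is not None and not isinstance(d[key], sub):
                d[key] = sub(**d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def _load_dataset(config: RunConfig) -> dio.CopyNumberDataset:
    if config.matrix_path:
        if not config.labels_path:
            raise ValueError("labels_path is required with matrix_path")
        ds = dio.read_matrix(config.matrix_path, config.delimiter)
        ds = dio.attach_labels(
            ds, dio.read_label_table(config.labels_path, config.delimiter)
        )
        return ds
    if config.synthetic is None:
        raise ValueError("either matrix_path or a synthetic spec is required")
    spec = dataclasses.replace(
        config.synthetic, seed=stage_seed(config.seed, "synth")
    )
    ds, truth = generate_dataset(spec)
    log.info("generated synthetic dataset with %d planted probes", len(truth))
    return ds


def run_pipeline(config: RunConfig) -> Path:
    """Run every stage; returns the output directory.

    Outputs: ``manifest.json``, ``ranking.tsv``, per-classifier stage-1 and
    stage-2 curves (TSV) and IFS result JSON, a comparison table
    (classifier, n_features, MCC, AUC), and the extracted rules with their
    evaluation statistics. A stage failure aborts with the stage name;
    earlier outputs are left on disk.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": config.to_dict(),
        "stage_seeds": {
            s: stage_seed(config.seed, s) for s in ("synth", "mcfs", "cv", "rules")
        },
        "stages": {},
    }

    def _finish_stage(name: str, t0: float) -> None:
        manifest["stages"][name] = {"seconds": round(time.time() - t0, 3)}
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))

    stage = "load"
    try:
        t0 = time.time()
        ds = _load_dataset(config)
        log.info(
            "dataset: %d probes x %d samples (%d case / %d control)",
            ds.n_probes, ds.n_samples, ds.n_case, ds.n_control,
        )
        _finish_stage(stage, t0)

        stage = "mcfs"
        t0 = time.time()
        params = dataclasses.replace(
            config.mcfs, seed=stage_seed(config.seed, "mcfs")
        )
        ranking = mcfs_mod.run_mcfs(ds, params)
        ranking.to_frame().to_csv(out / "ranking.tsv", sep="\t", index=False)
        _finish_stage(stage, t0)

        n_max = min(config.ifs_n_max, ds.n_probes)
        cv_seed = stage_seed(config.seed, "cv")
        comparison = []
        for kind, clf_config in (("snn", config.snn), ("rf", config.rf)):
            stage = f"ifs-{kind}"
            t0 = time.time()
            result = ifs_mod.run_ifs(
                ds, ranking, kind, clf_config,
                k=config.ifs_step, n_max=n_max, delta=config.ifs_delta,
                cv_k=config.cv_folds, cv_seed=cv_seed, budget=config.ifs_budget,
            )
            result.stage1.to_frame().to_csv(
                out / f"ifs_{kind}_stage1.tsv", sep="\t", index=False
            )
            result.stage2.to_frame().to_csv(
                out / f"ifs_{kind}_stage2.tsv", sep="\t", index=False
            )
            (out / f"ifs_{kind}_result.json").write_text(
                json.dumps(result.to_dict(), indent=2)
            )
            comparison.append(
                {
                    "classifier": kind.upper(),
                    "n_features": result.optimal_n,
                    "mcc": round(result.optimal_mcc, 6),
                    "auc": round(result.optimal_auc, 6),
                }
            )
            _finish_stage(stage, t0)

        stage = "comparison"
        t0 = time.time()
        with open(out / "comparison.tsv", "w") as fh:
            fh.write("classifier\tn_features\tmcc\tauc\n")
            for row in comparison:
                fh.write(
                    f"{row['classifier']}\t{row['n_features']}\t"
                    f"{row['mcc']}\t{row['auc']}\n"
                )
        _finish_stage(stage, t0)

        stage = "rules"
        t0 = time.time()
        informative = rules_mod.select_informative(ranking, config.rules_p)
        reduct = rules_mod.johnson_reduce(ds.subset(informative))
        rp = dataclasses.replace(
            config.ripper, seed=stage_seed(config.seed, "rules")
        )
        ruleset = rules_mod.ripper(ds.subset(reduct), rp)
        evaluation = rules_mod.evaluate_rules(ruleset, ds)
        (out / "rules.json").write_text(ruleset.to_json())
        (out / "rules.txt").write_text(ruleset.to_text() + "\n")
        (out / "rules_eval.json").write_text(evaluation.to_json())
        manifest["reduct"] = reduct
        _finish_stage(stage, t0)
    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {exc}") from exc

    return out
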