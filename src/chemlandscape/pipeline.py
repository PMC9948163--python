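"""End-to-end pipeline orchestration with a manifest of every stage.

``run_pipeline`` executes curate -> eda -> scaffolds -> landscape -> qsar
in order, writing each stage's tables under a run directory and recording
inputs, parameters, seeds, row counts at every filter and output checksums
in a single ``manifest.json``. A stage failure aborts the run with the
stage name; outputs of completed stages are preserved.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import descriptors, landscape, qsar, scaffolds, synthetic_data
from .errors import ConfigError, StageError
from .io_curation import (
    CuratedMolecule,
    curate,
    read_bioactivity_table,
    write_curated,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything one run needs; load from YAML with :meth:`from_yaml`."""

    input_csv: Optional[str] = None  # if None, a synthetic table is generated
    synth: synthetic_data.SynthConfig = field(
        default_factory=synthetic_data.SynthConfig
    )
    dedup: str = "first"
    fingerprints: Sequence[str] = ("ecfp4", "maccs", "pubchem")
    sim_threshold: float = 0.9
    act_threshold: float = 2.0
    min_gen_count: int = 2
    qsar_fingerprint: str = "pubchem"
    qsar_mode: str = "safe"
    qsar_folds: int = 10
    qsar_algorithms: Optional[Sequence[str]] = None
    n_estimators: int = 500
    seed: int = 42
    rgroup_scaffold: Optional[str] = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        synth = synthetic_data.SynthConfig(**data.pop("synth", {}))
        return cls(synth=synth, **data)

    def validate(self) -> None:
        if self.input_csv is not None and not Path(self.input_csv).exists():
            raise ConfigError(f"input file not found: {self.input_csv}")
        if not 0 < self.sim_threshold < 1:
            raise ConfigError("sim_threshold must lie in (0, 1)")
        if self.act_threshold <= 0:
            raise ConfigError("act_threshold must be positive")
        if self.qsar_mode not in ("safe", "paper-parity"):
            raise ConfigError(f"unknown qsar mode: {self.qsar_mode}")
        self.synth.validate()


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _register_outputs(manifest: dict, stage: str, stage_dir: Path) -> None:
    manifest["stages"][stage]["outputs"] = {
        p.name: _checksum(p) for p in sorted(stage_dir.glob("*")) if p.is_file()
    }


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Run all stages; returns the manifest (also written to manifest.json)."""
    config.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "parameters": {
            "dedup": config.dedup,
            "fingerprints": list(config.fingerprints),
            "sim_threshold": config.sim_threshold,
            "act_threshold": config.act_threshold,
            "qsar_mode": config.qsar_mode,
            "qsar_fingerprint": config.qsar_fingerprint,
        },
        "stages": {},
    }
    stage = "curate"
    try:
        t0 = time.time()
        stage_dir = out_dir / "curated"
        stage_dir.mkdir(exist_ok=True)
        if config.input_csv is not None:
            records = read_bioactivity_table(config.input_csv)
            manifest["input"] = str(config.input_csv)
        else:
            records, truth = synthetic_data.generate_dataset(config.synth)
            synthetic_data.write_dataset(
                records, stage_dir / "synthetic_input.csv", truth,
                stage_dir / "ground_truth.json",
            )
            manifest["input"] = "synthetic"
        curated, log = curate(records, dedup=config.dedup)
        write_curated(curated, stage_dir)
        manifest["stages"][stage] = {"counts": log.as_dict(),
                                     "elapsed_s": round(time.time() - t0, 2)}
        _register_outputs(manifest, stage, stage_dir)

        stage = "eda"
        t0 = time.time()
        stage_dir = out_dir / "eda"
        stage_dir.mkdir(exist_ok=True)
        summary = descriptors.summarize_groups(curated)
        summary.table.to_csv(stage_dir / "property_stats.csv")
        pd.Series(summary.u_pvalue, name="u_pvalue").rename_axis("property").to_csv(
            stage_dir / "u_pvalues.csv"
        )
        frame = descriptors.property_frame(curated)
        pca = descriptors.run_pca(frame[list(descriptors.PROPERTY_NAMES)])
        loadings = pca.loadings.copy()
        loadings.loc["cumulative_variance_pct"] = pca.cumulative_variance
        loadings.to_csv(stage_dir / "pca_loadings.csv")
        pd.DataFrame(
            pca.scores, index=frame.index, columns=pca.loadings.columns
        ).to_csv(stage_dir / "pca_scores.csv")
        manifest["stages"][stage] = {
            "counts": {"n_molecules": len(curated)},
            "cumulative_variance_pct": [round(v, 3) for v in pca.cumulative_variance],
            "elapsed_s": round(time.time() - t0, 2),
        }
        _register_outputs(manifest, stage, stage_dir)

        stage = "scaffolds"
        t0 = time.time()
        stage_dir = out_dir / "scaffolds"
        stage_dir.mkdir(exist_ok=True)
        table = scaffolds.build_scaffold_table(curated)
        pd.DataFrame(
            {
                "scaffold_smiles": [r.scaffold_smiles for r in table],
                "csk_smiles": [r.csk_smiles for r in table],
                "frequency": [r.frequency for r in table],
                "ef": [r.ef for r in table],
                "member_ids": [";".join(r.member_ids) for r in table],
            }
        ).to_csv(stage_dir / "scaffolds.csv", index=False)
        reports = scaffolds.diversity_metrics(curated)
        scaffolds.diversity_frame(reports).to_csv(stage_dir / "diversity.csv")
        if config.rgroup_scaffold:
            scaffolds.rgroup_table(curated, config.rgroup_scaffold).to_csv(
                stage_dir / "rgroups.csv"
            )
        manifest["stages"][stage] = {
            "counts": {k: v.as_row() for k, v in reports.items()},
            "elapsed_s": round(time.time() - t0, 2),
        }
        _register_outputs(manifest, stage, stage_dir)

        stage = "landscape"
        t0 = time.time()
        stage_dir = out_dir / "landscape"
        stage_dir.mkdir(exist_ok=True)
        result = landscape.run_landscape(
            curated,
            kinds=config.fingerprints,
            sim_threshold=config.sim_threshold,
            act_threshold=config.act_threshold,
            min_gen_count=config.min_gen_count,
        )
        for kind, pairs in result["pairs"].items():
            pairs.to_csv(stage_dir / f"pairs_{kind}.csv", index=False)
            pd.DataFrame(
                sorted(result["ac_sets"][kind]), columns=["id_a", "id_b"]
            ).to_csv(stage_dir / f"acs_{kind}.csv", index=False)
        if "consensus" in result:
            pd.DataFrame(
                sorted(result["consensus"]), columns=["id_a", "id_b"]
            ).to_csv(stage_dir / "consensus_acs.csv", index=False)
        landscape.generators_frame(result["generators"]).to_csv(
            stage_dir / "generators.csv", index=False
        )
        manifest["stages"][stage] = {
            "counts": {
                **{f"acs_{k}": len(v) for k, v in result["ac_sets"].items()},
                "consensus_acs": len(result.get("consensus", [])),
                "generators": len(result["generators"]),
            },
            "elapsed_s": round(time.time() - t0, 2),
        }
        _register_outputs(manifest, stage, stage_dir)

        stage = "qsar"
        t0 = time.time()
        stage_dir = out_dir / "qsar"
        stage_dir.mkdir(exist_ok=True)
        qres = qsar.run_qsar(
            curated,
            kind=config.qsar_fingerprint,
            mode=config.qsar_mode,
            seed=config.seed,
            folds=config.qsar_folds,
            n_estimators=config.n_estimators,
            algorithms=config.qsar_algorithms,
        )
        qsar.reports_frame(qres.reports).to_csv(stage_dir / "bench.csv", index=False)
        (stage_dir / "retained_features.json").write_text(
            json.dumps(asdict(qres.selection), indent=2)
        )
        manifest["stages"][stage] = {
            "counts": {
                "n_features_input": qres.selection.n_input,
                "n_after_variance": qres.selection.n_after_variance,
                "n_after_correlation": qres.selection.n_after_correlation,
                "n_train": int(len(qres.plan.train_idx)),
                "n_test": int(len(qres.plan.test_idx)),
            },
            "majority_baseline": qres.majority_baseline,
            "best_algorithm": qres.best().algorithm,
            "best_test_accuracy": qres.best().test.accuracy,
            "elapsed_s": round(time.time() - t0, 2),
        }
        _register_outputs(manifest, stage, stage_dir)
    except Exception as exc:
        raise StageError(stage, str(exc)) from exc

    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
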