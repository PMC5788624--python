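"""File-format contracts: CSV/JSON readers and writers, pipeline config,
and run manifests.

All tabular artifacts are CSV with a header row and stable column order;
configuration, thresholds and manifests are JSON; dendrograms are Newick.
Reruns with an identical config and seed produce byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import os
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import __version__
from .classifier import ClassifierThresholds
from .errors import SchemaError
from .synthetic import CohortConfig

EXPRESSION_ID_COLUMN = "sample_id"
ISH_COLUMNS = ["sample_id", "diagnosis", "mirna", "intensity", "pct_positive_cells"]
CT_COLUMNS = ["sample_id", "mirna", "replicate", "ct"]
DILUTION_COLUMNS = ["mirna", "copies", "ct"]


def _atomic_write_text(path: Path, text: str) -> None:
    """Write via a temp file + rename so readers never see partial output."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_csv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    _atomic_write_text(Path(path), df.to_csv(index=index))


def write_json(obj, path: Path) -> None:
    _atomic_write_text(Path(path), json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_expression_csv(path: Path, require_markers: Sequence[str] = ()) -> pd.DataFrame:
    """Read a samples x miRNAs copy matrix (sample_id index, optional subtype).

    Raises :class:`SchemaError` naming any missing required column.
    """
    df = pd.read_csv(path)
    if EXPRESSION_ID_COLUMN not in df.columns:
        raise SchemaError(f"expression CSV must have a {EXPRESSION_ID_COLUMN!r} column")
    for m in require_markers:
        if m not in df.columns:
            raise SchemaError(f"expression CSV missing required marker column {m!r}")
    return df.set_index(EXPRESSION_ID_COLUMN)


def write_expression_csv(df: pd.DataFrame, path: Path) -> None:
    out = df.reset_index() if df.index.name == EXPRESSION_ID_COLUMN else df
    write_csv(out, path)


def read_table_csv(path: Path, required: Sequence[str], kind: str) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{kind} CSV missing column(s) {missing}")
    return df


@dataclass
class PipelineConfig:
    """Everything a pipeline run needs, loadable from one JSON file."""

    output_dir: Path = Path("results")
    seed: int = 0
    cohort: CohortConfig = field(default_factory=CohortConfig)
    thresholds: ClassifierThresholds = field(default_factory=ClassifierThresholds)
    linkage: str = "average"
    pseudocount: float = 1.0
    ct_noise_sd: float = 0.15
    purity_target: float = 0.97

    @classmethod
    def from_json(cls, path: Path) -> "PipelineConfig":
        with open(path) as fh:
            d = json.load(fh)
        cfg = cls()
        if "output_dir" in d:
            cfg.output_dir = Path(d["output_dir"])
        cfg.seed = int(d.get("seed", cfg.seed))
        if "cohort" in d:
            cfg.cohort = CohortConfig.from_dict({**d["cohort"], "seed": d.get("seed", 0)})
        else:
            cfg.cohort = CohortConfig(seed=cfg.seed)
        if "thresholds" in d:
            cfg.thresholds = ClassifierThresholds.from_dict(d["thresholds"])
        cfg.linkage = d.get("linkage", cfg.linkage)
        cfg.pseudocount = float(d.get("pseudocount", cfg.pseudocount))
        cfg.ct_noise_sd = float(d.get("ct_noise_sd", cfg.ct_noise_sd))
        cfg.purity_target = float(d.get("purity_target", cfg.purity_target))
        return cfg

    def to_dict(self) -> dict:
        return {
            "output_dir": str(self.output_dir),
            "seed": self.seed,
            "cohort": {
                "group_sizes": dict(self.cohort.group_sizes),
                "group_means": {m: dict(v) for m, v in self.cohort.group_means.items()},
                "sigma": self.cohort.sigma
                if not isinstance(self.cohort.sigma, Mapping)
                else dict(self.cohort.sigma),
                "seed": self.cohort.seed,
            },
            "thresholds": self.thresholds.to_dict(),
            "linkage": self.linkage,
            "pseudocount": self.pseudocount,
            "ct_noise_sd": self.ct_noise_sd,
            "purity_target": self.purity_target,
        }


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the one global seed."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31 - 1)


def write_manifest(path: Path, config: PipelineConfig, inputs: Mapping[str, str], stage: str) -> None:
    """Record what produced an artifact set: config hash, seed, versions."""
    cfg = config.to_dict()
    cfg_hash = hashlib.sha256(json.dumps(cfg, sort_keys=True).encode()).hexdigest()
    write_json(
        {
            "stage": stage,
            "config": cfg,
            "config_sha256": cfg_hash,
            "seed": config.seed,
            "inputs": dict(inputs),
            "renalmir_version": __version__,
        },
        path,
    )
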