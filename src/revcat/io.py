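"""Run manifests, tidy outputs, and the learning-curve comparison plot.

A manifest is a small YAML document describing one reproducible experiment:
the configuration grid, the number of runs, and the single master seed from
which all randomness flows.  All outputs (per-run CSV, block summary, fit
report, JSON metadata) are deterministic functions of the manifest, so
re-running one reproduces the files byte-for-byte.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .agent import FIRST_COUNTS, FINST_SPANS, SECOND_COUNTS, ModelConfig, config_from_label, default_grid
from .simulator import BatchResult, N_RUNS_DEFAULT
from .stats import PARTICIPANT_CURVE, ReferenceCurve, report_table

MANIFEST_SCHEMA_VERSION = 1
FIXTURE_VERSION = "participant-curve-v1"

_KNOWN_KEYS = {"schema_version", "grid", "runs", "master_seed", "out_dir"}


@dataclass
class RunManifest:
    """Everything needed to reproduce one batch/sweep experiment."""

    grid: list[ModelConfig] = field(default_factory=default_grid)
    n_runs: int = N_RUNS_DEFAULT
    master_seed: int = 0
    out_dir: Path = Path("revcat-out")
    fixture_version: str = FIXTURE_VERSION

    def to_dict(self) -> dict:
        return {
            "schema_version": MANIFEST_SCHEMA_VERSION,
            "grid": [c.label for c in self.grid],
            "runs": self.n_runs,
            "master_seed": self.master_seed,
            "out_dir": str(self.out_dir),
        }


def _parse_grid_entry(entry) -> ModelConfig:
    if isinstance(entry, str):
        return config_from_label(entry)
    if isinstance(entry, dict):
        unknown = set(entry) - {"first_count", "second_count", "finst_span_s"}
        if unknown:
            raise ValueError(f"unknown grid keys: {sorted(unknown)}")
        return ModelConfig(
            first_count=int(entry.get("first_count", 3)),
            second_count=int(entry.get("second_count", 6)),
            finst_span_s=float(entry.get("finst_span_s", 100.0)),
        )
    if isinstance(entry, int):
        # YAML reads a bare 3_06_100 as the integer 306100
        raise ValueError(
            f"grid entry {entry!r} looks like an unquoted label; quote it, e.g. \"3_06_100\""
        )
    raise ValueError(f"grid entries must be labels or mappings, got {entry!r}")


def manifest_from_dict(data: dict | None) -> RunManifest:
    """Build a manifest from parsed YAML, filling defaults and validating."""
    data = data or {}
    if not isinstance(data, dict):
        raise ValueError("manifest must be a mapping")
    unknown = set(data) - _KNOWN_KEYS
    if unknown:
        raise ValueError(f"unknown manifest keys: {sorted(unknown)}")
    version = data.get("schema_version", MANIFEST_SCHEMA_VERSION)
    if version != MANIFEST_SCHEMA_VERSION:
        raise ValueError(f"unsupported schema_version {version!r}")
    runs = int(data.get("runs", N_RUNS_DEFAULT))
    if runs <= 0 or runs % 4 != 0:
        raise ValueError(f"'runs' must be a positive multiple of 4, got {runs}")
    grid_data = data.get("grid")
    grid = default_grid() if grid_data is None else [_parse_grid_entry(e) for e in grid_data]
    for config in grid:
        if (
            config.first_count not in FIRST_COUNTS
            or config.second_count not in SECOND_COUNTS
            or config.finst_span_s not in FINST_SPANS
        ):
            warnings.warn(
                f"config {config.label} lies outside the standard parameter grid",
                stacklevel=2,
            )
    return RunManifest(
        grid=grid,
        n_runs=runs,
        master_seed=int(data.get("master_seed", 0)),
        out_dir=Path(data.get("out_dir", "revcat-out")),
    )


def load_config(path: str | Path | None) -> RunManifest:
    """Load a YAML manifest; ``None`` or an empty file yields the defaults."""
    if path is None:
        return RunManifest()
    text = Path(path).read_text()
    return manifest_from_dict(yaml.safe_load(text))


def runs_frame(batches: list[BatchResult]) -> pd.DataFrame:
    """Tidy per-run data: one row per run x block."""
    rows = []
    for batch in batches:
        for run_index, run in enumerate(batch.runs):
            for block, prop in enumerate(run.block_props, start=1):
                rows.append(
                    {
                        "config": batch.config.label,
                        "run_index": run_index,
                        "order_id": run.order_id,
                        "block": block,
                        "prop_correct": prop,
                    }
                )
    return pd.DataFrame(rows)


def block_summary_frame(batches: list[BatchResult]) -> pd.DataFrame:
    """Across-run mean and SD per configuration and block."""
    rows = []
    for batch in batches:
        for block in range(1, 13):
            rows.append(
                {
                    "config": batch.config.label,
                    "block": block,
                    "mean": batch.block_means[block - 1],
                    "sd": batch.block_sds[block - 1],
                }
            )
    return pd.DataFrame(rows)


def write_outputs(
    batches: list[BatchResult],
    manifest: RunManifest,
    reference: ReferenceCurve | None = None,
) -> dict[str, Path]:
    """Write per-run CSV, block summary, fit report, and JSON metadata.

    Returns the mapping of artefact name to path.  Floats are written with
    fixed precision so identical manifests produce identical bytes.
    """
    out = Path(manifest.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["runs"] = out / "runs.csv"
    runs_frame(batches).to_csv(paths["runs"], index=False, float_format="%.6f")

    paths["block_summary"] = out / "block_summary.csv"
    block_summary_frame(batches).to_csv(
        paths["block_summary"], index=False, float_format="%.6f"
    )

    if reference is None:
        reference = PARTICIPANT_CURVE
    paths["fit_report"] = out / "fit_report.csv"
    report_table(batches, reference).to_csv(
        paths["fit_report"], index=False, float_format="%.6f"
    )

    paths["metadata"] = out / "metadata.json"
    metadata = {
        "manifest": manifest.to_dict(),
        "fixture_version": manifest.fixture_version,
        "package_version": __version__,
    }
    paths["metadata"].write_text(json.dumps(metadata, indent=2, sort_keys=True) + "\n")
    return paths


def plot_comparison(
    batch: BatchResult,
    reference: ReferenceCurve | None = None,
    path: str | Path = "learning_curves.png",
):
    """Mean +- SD learning curves of one configuration vs. the participants."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import numpy as np

    if reference is None:
        reference = PARTICIPANT_CURVE
    blocks = np.arange(1, 13)
    fig, ax = plt.subplots(figsize=(7, 4.5))
    ax.errorbar(
        blocks,
        reference.proportions() * 100,
        yerr=reference.sd_proportions() * 100,
        label="participants",
        marker="o",
        capsize=3,
    )
    ax.errorbar(
        blocks,
        batch.block_means * 100,
        yerr=batch.block_sds * 100,
        label=f"model {batch.config.label}",
        marker="s",
        capsize=3,
    )
    ax.axvline(6.5, color="gray", linestyle="--", linewidth=1)
    ax.set_xlabel("block (20 trials)")
    ax.set_ylabel("% correct")
    ax.set_ylim(0, 105)
    ax.legend()
    fig.tight_layout()
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)
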