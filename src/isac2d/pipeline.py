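"""End-to-end run orchestration: pre-align, classify, write a run directory."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import mrc
from .clustering import ClassConfig
from .polar_align import SearchGrid
from .prealignment import DEFAULT_PREALIGN_ITERS, prealign
from .stability import StabilityConfig, main_loop
from .stack_io import ParticleStack, read_stack
from .transforms import apply_transforms_batch

__all__ = ["RunConfig", "run_pipeline", "load_run_summary"]


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class RunConfig:
    """Validated configuration of a full classification run."""

    stack_path: str
    output_dir: str
    n_classes_target: int = 200
    n_max: int | None = None
    n_min: int | None = None
    s_max: int = 3
    shift_step: int = 1
    n_angular: int | None = None
    mirror: bool = True
    prealign_iters: int = DEFAULT_PREALIGN_ITERS
    k_means_reps: int = 5
    inner_max_iters: int = 20
    stability_reps: int = 5
    stability_align_iters: int = 30
    pixel_error_threshold: float = 1.0
    max_main_iters: int = 10
    seed: int = 0
    g_workers: int = 1
    budget_bytes: int = 2 * 1024**3
    memory_fraction: float = 0.95

    def validate(self) -> None:
        problems = []
        if not Path(self.stack_path).exists():
            problems.append(f"stack_path: no such file {self.stack_path!r}")
        for key in ("n_classes_target", "prealign_iters", "k_means_reps",
                    "stability_reps", "stability_align_iters", "max_main_iters",
                    "g_workers", "budget_bytes"):
            if getattr(self, key) < 1:
                problems.append(f"{key}: must be >= 1")
        if not 0 < self.memory_fraction <= 1:
            problems.append("memory_fraction: must be in (0, 1]")
        if problems:
            raise ConfigError("invalid configuration: " + "; ".join(problems))

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        data = json.loads(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        bad = sorted(set(data) - known)
        if bad:
            raise ConfigError(f"unknown configuration keys: {', '.join(bad)}")
        return cls(**data)


def run_pipeline(config: RunConfig) -> Path:
    """Execute pre-alignment and the main loop, writing all outputs.

    The run directory receives: a config snapshot (config.json), the
    pre-alignment parameter table (prealign_params.tsv) and global average
    (global_average.mrc), per-iteration JSON-lines log (iterations.jsonl),
    the final per-particle table (particle_table.tsv) and the accepted
    class-average stack (class_averages.mrcs).
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(json.dumps(dataclasses.asdict(config), indent=2))

    stack = read_stack(config.stack_path)
    grid = SearchGrid.for_box(
        stack.box,
        s_max=config.s_max,
        shift_step=config.shift_step,
        n_angular=config.n_angular,
        mirror=config.mirror,
    )

    pre = prealign(stack, grid, n_iters=config.prealign_iters)
    pre.to_dataframe().to_csv(out / "prealign_params.tsv", sep="\t", index=False)
    mrc.write_mrc(out / "global_average.mrc", pre.global_average, stack.pixel_size)

    # classification works on the pre-aligned (transformed) images
    aligned = apply_transforms_batch(stack.images.astype(float), pre.params)
    aligned_stack = ParticleStack(aligned, stack.pixel_size, stack.ids)

    class_cfg = ClassConfig(
        n_classes_target=config.n_classes_target,
        n_max=config.n_max,
        n_min=config.n_min,
        k_means_reps=config.k_means_reps,
        inner_max_iters=config.inner_max_iters,
    )
    stab_cfg = StabilityConfig(
        n_reps=config.stability_reps,
        n_align_iters=config.stability_align_iters,
        pixel_error_threshold=config.pixel_error_threshold,
    )
    result = main_loop(
        aligned_stack,
        grid,
        class_cfg,
        stab_cfg,
        max_main_iters=config.max_main_iters,
        seed=config.seed,
    )

    with open(out / "iterations.jsonl", "w") as fh:
        for entry in result.log:
            fh.write(json.dumps(entry) + "\n")

    table = pd.DataFrame(
        {
            "id": stack.ids,
            "class": result.labels,
            "sx": result.params["sx"],
            "sy": result.params["sy"],
            "theta": result.params["theta"],
            "mirror": result.params["mirror"],
            "peak": result.params["peak"],
            "pixel_error": result.pixel_errors,
            "accounted": (result.labels >= 0).astype(int),
        }
    )
    table.to_csv(out / "particle_table.tsv", sep="\t", index=False)

    if result.averages:
        mrc.write_mrc(
            out / "class_averages.mrcs", np.stack(result.averages), stack.pixel_size
        )
    summary = {
        "n_particles": int(stack.n),
        "n_classes": int(result.n_classes),
        "n_accounted": int(len(result.accounted)),
        "class_sizes": [int(s) for s in result.class_sizes],
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2))
    return out


def load_run_summary(run_dir: str | Path) -> dict:
    run_dir = Path(run_dir)
    path = run_dir / "summary.json"
    if not path.exists():
        raise FileNotFoundError(f"{run_dir} does not look like a run directory")
    return json.loads(path.read_text())
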