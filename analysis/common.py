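"""Shared plumbing for the numbered analysis drivers.

The dataset lives under scratch/ (large, regenerated on demand); the small
result tables the drivers produce go under results/.
"""
from __future__ import annotations

from pathlib import Path

ROOT = Path(__file__).resolve().parent.parent
SCRATCH = ROOT / "scratch"
RESULTS = ROOT / "results"


def dataset_dir(seed: int) -> Path:
    return SCRATCH / f"dataset_seed{seed}"


def ensure_dataset(seed: int) -> Path:
    """Simulate the default desk-scale study if it is not on disk yet."""
    from chipctrl.sim import SimConfig, write_dataset

    d = dataset_dir(seed)
    if not (d / "manifest.yaml").exists():
        print(f"simulating default study (seed={seed}) -> {d}")
        write_dataset(SimConfig(seed=seed), d)
    RESULTS.mkdir(exist_ok=True)
    return d


def run_config(seed: int):
    from chipctrl.pipeline import RunConfig

    return RunConfig.from_sim_dir(ensure_dataset(seed))
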