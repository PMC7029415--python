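"""Output writers: TIFF stacks, tidy CSV tables, config sidecars."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

from .cohort import GroundTruthTable
from .config import AcquisitionConfig
from .render import ImageStack


def write_simulation(
    out_dir: str | Path,
    stack: ImageStack | None,
    truth: GroundTruthTable,
    acq: AcquisitionConfig,
    extra_meta: dict | None = None,
) -> dict[str, Path]:
    """Write a simulated movie, its ground truth and the generating config.

    Returns the paths written. The stack may be None (truth-only runs for
    large cohorts where rendering is not needed).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    if stack is not None:
        paths["stack"] = out / "movie.ome.tif"
        stack.to_tiff(paths["stack"])
    paths["truth_frames"] = out / "truth_frames.csv"
    paths["truth_cells"] = out / "truth_cells.csv"
    truth.to_csv(paths["truth_frames"], paths["truth_cells"])
    meta = dataclasses.asdict(acq)
    meta["image_size"] = list(meta["image_size"])
    meta["channel_roles"] = list(meta["channel_roles"])
    if extra_meta:
        meta.update(extra_meta)
    paths["config"] = out / "simulation_config.json"
    paths["config"].write_text(json.dumps(meta, indent=2))
    return paths
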