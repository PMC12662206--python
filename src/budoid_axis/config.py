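"""Run configuration with every algorithm default in one place.

All defaults are the pipeline's canonical constants: segmentation disc
radii 50/20, border pad 100 with a 50 px trigger, crowding alpha 0.01,
polarization threshold 0.01, 4 axis bins, 200 profile bins, 180 detected
genes for QC, and the 1% gene-detection filter for PCA.  A config
round-trips losslessly through YAML.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    # input files (real data) — leave None to simulate instead
    mask_path: str | None = None
    cells_path: str | None = None
    matrix_dir: str | None = None
    # simulation parameters (used when mask_path is None)
    sim: dict = field(
        default_factory=lambda: {
            "length_px": 400,
            "width_px": 100,
            "curvature": 0.0,
            "n_cells": 600,
            "n_background_genes": 123,
            "base_rate": 2.0,
            "effect_size": 4.0,
            "dispersion": 0.0,
            "seed": 42,
        }
    )
    # segmentation
    close_radius: float = 50
    open_radius: float = 20
    pad: int = 100
    border_trigger: int = 50
    # projection
    alpha: float = 0.01
    # polarity
    threshold: float = 0.01
    n_axis_bins: int = 4
    target_sum: float = 1.0e4
    score_scope: str = "halves"
    score_seed: int = 0
    # QC / domain analysis
    min_genes: int = 180
    min_cell_fraction: float = 0.01
    # output
    out_dir: str = "budoid_axis_run"

    def validate(self) -> None:
        if self.alpha < 0:
            raise ValueError("alpha must be non-negative")
        if self.close_radius <= 0 or self.open_radius <= 0:
            raise ValueError("morphology radii must be positive")
        if self.n_axis_bins < 2 or self.n_axis_bins % 2:
            raise ValueError("n_axis_bins must be an even number >= 2")
        if self.score_scope not in ("halves", "whole"):
            raise ValueError("score_scope must be 'halves' or 'whole'")
        has_inputs = self.mask_path is not None
        if has_inputs and (self.cells_path is None or self.matrix_dir is None):
            raise ValueError("real-data runs need mask, cells and matrix paths")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
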