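"""End-to-end orchestration: simulate/load -> segment -> midline ->
project -> orient -> classify -> domain summaries, with a manifest.

Every stage writes its artifact to the output directory; the manifest
records all parameter values and the key results so a run is fully
traceable and reproducible (same config, same bytes).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, io
from .config import RunConfig
from .domains import detected_genes, summarize_domains
from .midline import extract_midline, segment_structure
from .morphometrics import compute_shape_metrics
from .polarity import normalize_expression, orient_and_scale, split_halves
from .projection import filter_cells_in_structure, project_cells
from .simulate import SimParams, simulate_organoid

logger = logging.getLogger(__name__)


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages and return a result bundle.

    The bundle holds the in-memory objects of each stage plus the path of
    the manifest written to ``config.out_dir``.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    stage = "inputs"
    try:
        if config.mask_path is None:
            organoid = simulate_organoid(SimParams(**config.sim))
            io.write_organoid(out / "simulation", organoid)
            cell_mask, cells, adata = organoid.mask, organoid.cells, organoid.counts
        else:
            organoid = None
            cell_mask = io.read_mask(config.mask_path)
            cells = io.read_cells(config.cells_path)
            adata = io.read_matrix(config.matrix_dir)

        stage = "shape"
        shape = compute_shape_metrics(cell_mask)

        stage = "segment"
        struct = segment_structure(
            cell_mask,
            close_radius=config.close_radius,
            open_radius=config.open_radius,
            pad=config.pad,
            border_trigger=config.border_trigger,
        )
        io.write_mask(out / "structure_mask.tif", struct)

        stage = "midline"
        midline = extract_midline(struct)
        io.write_midline(out / "midline.csv", midline)

        stage = "project"
        kept = filter_cells_in_structure(cells, struct)
        projection = project_cells(kept, midline, alpha=config.alpha)

        stage = "polarity"
        normalize_expression(adata, target_sum=config.target_sum)
        scores, s = orient_and_scale(
            projection,
            adata,
            n_axis_bins=config.n_axis_bins,
            threshold=config.threshold,
            score_scope=config.score_scope,
            seed=config.score_seed,
        )
        domains = split_halves(s)
        per_cell = pd.DataFrame(
            {
                "cell_id": s.index,
                "index": projection.assignment.to_numpy(),
                "s": s.to_numpy(),
                "domain": np.asarray(domains),
            }
        )
        per_cell.to_csv(out / "cells_axis.csv", index=False)
        (out / "polarity.json").write_text(
            json.dumps(dataclasses.asdict(scores), indent=2) + "\n"
        )

        stage = "domains"
        summaries = summarize_domains(adata, domains, sample_id=out.name)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest = {
        "version": __version__,
        "config": dataclasses.asdict(config),
        "n_cells_input": int(len(cells)),
        "n_cells_in_structure": int(len(kept)),
        "detected_genes": detected_genes(adata),
        "shape": dataclasses.asdict(shape),
        "midline_length_px": midline.length,
        "polarity": dataclasses.asdict(scores),
        "true_orientation": organoid.true_orientation if organoid else None,
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")

    return {
        "organoid": organoid,
        "shape": shape,
        "structure": struct,
        "midline": midline,
        "cells": kept,
        "projection": projection,
        "scores": scores,
        "s": s,
        "domains": domains,
        "summaries": summaries,
        "manifest_path": manifest_path,
    }
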