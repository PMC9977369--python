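"""End-to-end analysis pipeline over a study dataset.

Runs the full chain the package implements: grain classification, per-group
descriptive summaries, grain-count vs area regression, AMPA/GluN1 ratio
analysis, pose-normalized average density maps, radial profiles, null-model
simulations, and measured-vs-simulated comparisons. All outputs are CSV/JSON
plus a run manifest sufficient to reproduce the run.
"""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .density import DEFAULT_CELL_SIZE, average_maps, export_map_csv, grid_bin
from .geometry import normalize_pose, region_area, synaptic_count
from .model import RECEPTORS, StudyDataset, select
from .nulls import NULL_MODELS, NullSpec, simulate_profiles
from .radial import DEFAULT_BIN_WIDTH, profile_matrix, profiles_to_tidy, radial_profile
from .stats import (
    count_area_r2,
    density_per_um2,
    ranked_rm_anova_dunnett,
    receptor_ratio,
    summary_table,
)


@dataclass
class RunConfig:
    """Configuration of one analysis run."""

    output_dir: Path
    input_path: Path | None = None
    cell_size: float = DEFAULT_CELL_SIZE  # nm
    bin_width: float = DEFAULT_BIN_WIDTH  # nm
    models: tuple[str, ...] = NULL_MODELS
    sigma_frac: float = 1.0 / 3.0
    iterations: int = 100
    seed: int = 0
    grouping: tuple[str, ...] = ("layer", "target", "receptor")


def _groups(ds: StudyDataset):
    """Yield (label, sub-dataset) per (layer, target, receptor) cell with data."""
    layers = sorted({r.layer for r in ds.records})
    targets = sorted({r.target for r in ds.records})
    for layer in layers:
        for target in targets:
            for receptor in RECEPTORS:
                sub = select(ds, layer=layer, target=target, receptor=receptor)
                sub.records = [r for r in sub.records if r.particles]
                if sub.records:
                    yield f"{receptor} {layer} {target}", sub


def analyze(ds: StudyDataset, cfg: RunConfig) -> dict:
    """Run the full pipeline and write result files; returns the manifest."""
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[str] = []
    rng = np.random.default_rng(cfg.seed)

    # --- descriptive summaries (areas, counts, densities) ------------------
    area_groups, count_groups, dens_groups = {}, {}, {}
    for label, sub in _groups(ds):
        counts = [synaptic_count(r) for r in sub.records]
        areas = [region_area(r.region) for r in sub.records]
        dens = [density_per_um2(r) for r in sub.records]
        if len(sub.records) >= 2:
            area_groups[label] = areas
            count_groups[label] = counts
            dens_groups[label] = dens
    for name, groups in [("areas_um2", area_groups),
                         ("grains_per_psd", count_groups),
                         ("grains_per_um2", dens_groups)]:
        if groups:
            path = out / f"summary_{name}.csv"
            summary_table(groups).to_csv(path, index=False)
            written.append(path.name)

    # --- count vs area regression ------------------------------------------
    fits = []
    for label, sub in _groups(ds):
        if len(sub.records) >= 3:
            fit = count_area_r2(sub.records)
            fits.append(dict(group=label, r2=fit.r2, slope=fit.slope,
                             intercept=fit.intercept, n=fit.n))
    if fits:
        pd.DataFrame(fits).to_csv(out / "count_area_r2.csv", index=False)
        written.append("count_area_r2.csv")

    # --- AMPA/GluN1 ratios ---------------------------------------------------
    ratio_rows = []
    for layer in sorted({r.layer for r in ds.records}):
        for target in sorted({r.target for r in ds.records}):
            try:
                row = receptor_ratio(ds, layer, target)
            except ValueError:
                continue
            ratio_rows.append(dict(layer=row.layer, target=row.target,
                                   n_animals=len(row.ratios),
                                   grand_mean=row.grand_mean, sd=row.sd))
    if ratio_rows:
        pd.DataFrame(ratio_rows).to_csv(out / "receptor_ratio.csv", index=False)
        written.append("receptor_ratio.csv")

    # --- density maps, radial profiles, null comparisons per group ----------
    test_rows = []
    for label, sub in _groups(ds):
        slug = label.replace(" ", "_")
        normed = [normalize_pose(r)[0] for r in sub.records]
        avg = average_maps([grid_bin(r, cfg.cell_size) for r in normed])
        for p in export_map_csv(avg, out / f"map_{slug}"):
            written.append(Path(p).name)

        profiles = [radial_profile(r, cfg.bin_width) for r in sub.records]
        tidy = profiles_to_tidy(profiles, condition="measured")
        width = max(p.n_bins for p in profiles)
        sim_frames = []
        sims = {}
        for model in cfg.models:
            spec = NullSpec(model=model, sigma_frac=cfg.sigma_frac,
                            iterations=cfg.iterations, seed=cfg.seed)
            sim_profiles = []
            stack = np.full((len(sub.records), cfg.iterations, width), np.nan)
            for i, (rec, prof) in enumerate(zip(sub.records, profiles)):
                sim = simulate_profiles(
                    rec, spec, cfg.bin_width,
                    rng=np.random.default_rng(rng.integers(2**31)),
                    measured=prof,
                )
                sim_profiles.append(sim.profile)
                stack[i, :, : prof.n_bins] = sim.normalized_iterations
            sims[model] = stack
            sim_frames.append(profiles_to_tidy(
                sim_profiles, condition=model, iterations=cfg.iterations,
                seed=cfg.seed,
            ))
        pd.concat([tidy] + sim_frames, ignore_index=True).to_csv(
            out / f"radial_{slug}.csv", index=False
        )
        written.append(f"radial_{slug}.csv")

        if len(sub.records) >= 2 and sims:
            measured_m = profile_matrix([], profiles=profiles)
            res = ranked_rm_anova_dunnett(measured_m, sims)
            for cmp_ in res.comparisons:
                test_rows.append(dict(group=label, comparison=cmp_.comparison,
                                      statistic=cmp_.statistic,
                                      p_value=cmp_.p_value,
                                      p_adjusted=cmp_.p_adjusted,
                                      method=cmp_.method))
    if test_rows:
        pd.DataFrame(test_rows).to_csv(out / "profile_tests.csv", index=False)
        written.append("profile_tests.csv")

    manifest = dict(
        package_version=__version__,
        python=platform.python_version(),
        n_records=len(ds.records),
        config=dict(
            input_path=str(cfg.input_path) if cfg.input_path else None,
            cell_size_nm=cfg.cell_size, bin_width_nm=cfg.bin_width,
            models=list(cfg.models), sigma_frac=cfg.sigma_frac,
            iterations=cfg.iterations,
            seed=cfg.seed, grouping=list(cfg.grouping),
        ),
        missing_value_policy="bins absent for a PSD are excluded cell-wise",
        outputs=written,
    )
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
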