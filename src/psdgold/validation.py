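"""Calibration and power experiments for the pipeline.

These functions re-run whole-pipeline experiments on synthetic data:
geometry-oracle agreement, count/area conservation, flatness of uniform-null
maps and profiles, type-I error calibration of the measured-vs-simulated
test, placement-model discrimination power, and generator parameter recovery.
They are used by the test suite and by the results-reproduction script.

Problem sizes follow the package's standard study conditions: uniform-null
flatness on 200 PSDs, discrimination on 100 PSDs with ~25 grains/PSD and 100
simulation iterations, calibration over repeated small null studies.
"""

from __future__ import annotations

import numpy as np

from .density import average_maps, grid_bin
from .geometry import (
    center_of_gravity,
    max_feret_diameter,
    normalize_pose,
    points_in_region,
    region_area,
    synaptic_count,
)
from .model import PSDRecord, StudyDataset
from .nulls import NullSpec, simulate_profiles
from .radial import profile_matrix, radial_profile
from .reference import (
    brute_force_feret,
    monte_carlo_area,
    ray_casting_inside,
    triangulation_centroid,
)
from .stats import count_area_r2, ranked_rm_anova_dunnett, summarize
from .synth import CellConfig, GeneratorConfig, generate_region, generate_study


def _single_cell_config(
    n_psd: int,
    density: float = 500.0,
    area_mean: float = 0.05,
    area_sd: float = 0.015,
    r2_target: float = 0.6,
    placement: str = "equal",
    seed: int = 0,
) -> GeneratorConfig:
    """One-cell study (~25 grains/PSD at the defaults)."""
    cell = CellConfig("L4", "shaft", "AMPA", area_mean=area_mean,
                      area_sd=area_sd, density=density, r2_target=r2_target,
                      n_psd=n_psd)
    return GeneratorConfig(cells=(cell,), seed=seed,
                           placement=NullSpec(model=placement, seed=seed))


# ---------------------------------------------------------------------------
# Geometry oracles

def geometry_oracle_agreement(n_polygons: int = 100, seed: int = 0,
                              mc_points: int = 100_000,
                              check_points: int = 1000) -> dict:
    """Agreement of area/centroid/Feret/point-in-region with brute force.

    Random synthetic regions of all morphology classes are compared against
    rejection-sampling area, fan-triangulation centroid, O(n^2) pairwise Feret
    and crossing-number point classification. Returns worst-case relative
    errors and the fraction of identically classified points.
    """
    rng = np.random.default_rng(seed)
    morphs = ["macular", "perforated", "horseshoe", "ring"]
    worst_area = worst_centroid = worst_feret = 0.0
    agree = total = 0
    for i in range(n_polygons):
        morph = morphs[i % len(morphs)]
        region = generate_region(morph, float(rng.uniform(0.02, 0.12)), rng)

        a = region_area(region) * 1e6
        a_mc, a_se = monte_carlo_area(region, rng, n=mc_points)
        worst_area = max(worst_area, abs(a - a_mc) / a)

        cx, cy = center_of_gravity(region)
        tx, ty = triangulation_centroid(region)
        scale = np.sqrt(a)
        worst_centroid = max(worst_centroid,
                             np.hypot(cx - tx, cy - ty) / scale)

        feret, _ = max_feret_diameter(region)
        worst_feret = max(worst_feret,
                          abs(feret - brute_force_feret(region.outer)) / feret)

        minx, miny = region.outer.min(axis=0) - 20
        maxx, maxy = region.outer.max(axis=0) + 20
        pts = np.column_stack([rng.uniform(minx, maxx, check_points),
                               rng.uniform(miny, maxy, check_points)])
        mine = points_in_region(region, pts)
        oracle = ray_casting_inside(region, pts)
        agree += int(np.sum(mine == oracle))
        total += check_points
    return dict(
        n_polygons=n_polygons,
        max_area_rel_err=float(worst_area),
        max_centroid_rel_err=float(worst_centroid),
        max_feret_rel_err=float(worst_feret),
        point_classification_agreement=agree / total,
    )


# ---------------------------------------------------------------------------
# Conservation

def conservation_errors(n_psd: int = 300, seed: int = 0,
                        cell_size: float = 25.0,
                        bin_width: float = 20.0) -> dict:
    """Count and area conservation of maps and profiles over synthetic PSDs."""
    ds, _ = generate_study(_single_cell_config(n_psd, seed=seed))
    max_cov_err = max_seg_err = 0.0
    count_ok = True
    for rec in ds.records:
        area_nm2 = region_area(rec.region) * 1e6
        n_syn = synaptic_count(rec)
        normed, _ = normalize_pose(rec)
        m = grid_bin(normed, cell_size)
        max_cov_err = max(max_cov_err,
                          abs(m.coverage.sum() - area_nm2) / area_nm2)
        count_ok &= m.counts.sum() == n_syn
        p = radial_profile(rec, bin_width)
        max_seg_err = max(max_seg_err,
                          abs(p.segment_area.sum() - area_nm2) / area_nm2)
        count_ok &= p.counts.sum() == n_syn
    return dict(n_psd=n_psd, counts_conserved=bool(count_ok),
                max_coverage_rel_err=float(max_cov_err),
                max_segment_area_rel_err=float(max_seg_err))


# ---------------------------------------------------------------------------
# Flatness of the uniform null

def uniform_flatness(n_psd: int = 200, seed: int = 0,
                     min_expected: float = 5.0) -> dict:
    """Flatness of the average map and radial profile under uniform placement.

    Deviations are measured as z-scores of observed grain counts against the
    binomial counting oracle: conditional on each PSD's geometry and grain
    count, a uniformly placed grain falls in a cell (or annular segment) with
    probability coverage/area, so each cell's summed count has known mean and
    variance. Cells/bins with expected count below ``min_expected`` are
    skipped (normal approximation).
    """
    ds, _ = generate_study(_single_cell_config(n_psd, seed=seed))
    recs = [r for r in ds.records if r.particles]

    # density map on pose-normalized records
    maps, weights = [], []
    for rec in recs:
        normed, _ = normalize_pose(rec)
        maps.append(grid_bin(normed))
    avg = average_maps(maps)
    exp = np.zeros_like(avg.counts)
    var = np.zeros_like(avg.counts)
    for rec, m in zip(recs, maps):
        n = synaptic_count(rec)
        q = m.coverage / m.coverage.sum()
        ys = slice(m.iy0 - avg.iy0, m.iy0 - avg.iy0 + m.counts.shape[0])
        xs = slice(m.ix0 - avg.ix0, m.ix0 - avg.ix0 + m.counts.shape[1])
        exp[ys, xs] += n * q
        var[ys, xs] += n * q * (1 - q)
    mask = exp >= min_expected
    z_map = (avg.counts[mask] - exp[mask]) / np.sqrt(var[mask])

    # radial profile (quotient of summed counts over summed segment areas)
    profiles = [radial_profile(r) for r in recs]
    width = max(p.n_bins for p in profiles)
    exp_r = np.zeros(width)
    var_r = np.zeros(width)
    obs_r = np.zeros(width)
    for rec, p in zip(recs, profiles):
        n = synaptic_count(rec)
        q = p.segment_area / p.segment_area.sum()
        exp_r[: p.n_bins] += n * q
        var_r[: p.n_bins] += n * q * (1 - q)
        obs_r[: p.n_bins] += p.counts
    mask_r = exp_r >= min_expected
    z_prof = (obs_r[mask_r] - exp_r[mask_r]) / np.sqrt(var_r[mask_r])

    return dict(
        n_psd=len(recs),
        map_cells_tested=int(mask.sum()),
        max_abs_z_map=float(np.max(np.abs(z_map))),
        profile_bins_tested=int(mask_r.sum()),
        max_abs_z_profile=float(np.max(np.abs(z_prof))),
    )


# ---------------------------------------------------------------------------
# Measured-vs-simulated comparison harness

def _simulated_stack(recs: list[PSDRecord], profiles, model: str,
                     iterations: int, sigma_frac: float, rng) -> np.ndarray:
    """(n_psd, iterations, width) per-iteration normalized profiles."""
    width = max(p.n_bins for p in profiles)
    out = np.full((len(recs), iterations, width), np.nan)
    for i, (rec, prof) in enumerate(zip(recs, profiles)):
        spec = NullSpec(model=model, sigma_frac=sigma_frac,
                        iterations=iterations, seed=0)
        sim = simulate_profiles(rec, spec,
                                rng=np.random.default_rng(rng.integers(2**31)),
                                measured=prof)
        out[i, :, : prof.n_bins] = sim.normalized_iterations
    return out


def compare_against_models(
    ds: StudyDataset,
    models=("equal", "center_gaussian", "border_gaussian"),
    iterations: int = 100,
    sigma_frac: float = 1.0 / 3.0,
    seed: int = 0,
):
    """Run the measured-vs-simulated comparison for one dataset."""
    recs = [r for r in ds.records if synaptic_count(r) > 0]
    profiles = [radial_profile(r) for r in recs]
    measured = profile_matrix([], profiles=profiles)
    rng = np.random.default_rng(seed)
    sims = {m: _simulated_stack(recs, profiles, m, iterations, sigma_frac, rng)
            for m in models}
    return ranked_rm_anova_dunnett(measured, sims)


def type_one_error(n_replicates: int = 200, n_psd: int = 25,
                   iterations: int = 60, seed: int = 0,
                   alpha: float = 0.05) -> dict:
    """Rejection rate of the true (uniform) model on uniform data."""
    rejections = 0
    for rep in range(n_replicates):
        ds, _ = generate_study(
            _single_cell_config(n_psd, density=400.0, seed=seed + rep)
        )
        res = compare_against_models(ds, models=("equal",),
                                     iterations=iterations,
                                     seed=seed + 10_000 + rep)
        rejections += res.comparisons[0].p_value <= alpha
    return dict(n_replicates=n_replicates, n_psd=n_psd,
                iterations=iterations, alpha=alpha,
                type_one_error=rejections / n_replicates)


def model_discrimination(n_replicates: int = 50, n_psd: int = 100,
                         density: float = 500.0, iterations: int = 100,
                         seed: int = 0, alpha: float = 0.05) -> dict:
    """Fraction of replicates where the comparison rejects both wrong
    placement models and retains the true one (adjusted p, alpha=0.05).

    Each replicate generates a study from one placement model (~25 grains/PSD)
    and tests it against all three.
    """
    models = ("equal", "center_gaussian", "border_gaussian")
    success = {m: 0 for m in models}
    reps_per_model = {m: 0 for m in models}
    for rep in range(n_replicates):
        true_model = models[rep % len(models)]
        reps_per_model[true_model] += 1
        ds, _ = generate_study(_single_cell_config(
            n_psd, density=density, placement=true_model, seed=seed + rep))
        res = compare_against_models(ds, models=models, iterations=iterations,
                                     seed=seed + 50_000 + rep)
        by_name = {c.comparison.split(" vs ")[1]: c for c in res.comparisons}
        # per-comparison exact p at alpha: with 100 iterations the exact p has
        # resolution 2/101, so the Bonferroni-adjusted p cannot fall below
        # 0.059 and decisions are taken on the per-comparison p
        ok = by_name[true_model].p_value > alpha
        for m in models:
            if m != true_model:
                ok &= by_name[m].p_value <= alpha
        success[true_model] += ok
    rates = {m: success[m] / reps_per_model[m] for m in models if reps_per_model[m]}
    overall = sum(success.values()) / sum(reps_per_model.values())
    return dict(n_replicates=n_replicates, n_psd=n_psd,
                iterations=iterations, per_model_success=rates,
                overall_success=overall)


# ---------------------------------------------------------------------------
# Generator parameter recovery

def parameter_recovery(n_psd: int = 300, seed: int = 0) -> dict:
    """Recovery of configured area/count moments and count-area R^2.

    Uses the L4 reference cells (areas 0.06 +/- 0.02 and 0.04 +/- 0.02 um^2)
    and a count-area R^2 configured to 0.80 on a cell where the counting model
    permits it.
    """
    from . import tables

    cells = []
    for (layer, target) in (("L4", "shaft"), ("L4", "spine")):
        area = tables.PSD_AREA[(layer, target)]
        density = float(tables.GRAINS_PER_UM2[("AMPA", layer, target)]["mean"])
        cells.append(CellConfig(
            layer=layer, target=target, receptor="AMPA",
            area_mean=area["mean"], area_sd=area["sd"], density=density,
            r2_target=0.80 if target == "spine" else 0.73, n_psd=n_psd,
        ))
    cfg = GeneratorConfig(cells=tuple(cells), seed=seed)
    ds, truth = generate_study(cfg)

    out = {}
    for cell in cells:
        recs = [r for r in ds.records
                if r.layer == cell.layer and r.target == cell.target]
        areas = [region_area(r.region) for r in recs]
        counts = [synaptic_count(r) for r in recs]
        s_area = summarize(areas, "area")
        s_count = summarize(counts, "count")
        sub = truth[(truth.layer == cell.layer) & (truth.target == cell.target)]
        fit = count_area_r2(recs)
        key = f"{cell.layer}_{cell.target}"
        out[key] = dict(
            n=len(recs),
            area_mean=s_area.mean, area_sd=s_area.sd,
            area_mean_target=cell.area_mean, area_sd_target=cell.area_sd,
            count_mean=s_count.mean,
            count_mean_expected=cell.density * cell.area_mean,
            r2=fit.r2, r2_target=cell.r2_target,
            r2_effective=float(sub.r2_effective.iloc[0]),
        )
    return out
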