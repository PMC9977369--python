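"""Descriptive and inferential statistics for PSD grain data.

Covers per-group descriptive summaries (mean, SD, median, IQR, extremes,
skewness, variance, CV), nonparametric group comparisons (Mann-Whitney U,
Kruskal-Wallis H with post-hoc pairwise tests), grain-count vs area
regression, per-animal AMPA/GluN1 ratio analysis, and the comparison of
measured radial profiles against simulated null placements via a rank-based
repeated-measures layout with Dunnett-style control-vs-treatment comparisons.

The measured-vs-simulated test is an exact Monte-Carlo rank test with the
control-vs-treatments structure of a Dunnett post-hoc: for each simulated
condition the pool of profiles per PSD (the measured one plus every simulation
iteration) is iid under the null hypothesis that grains follow that placement
model, so holding out each iteration in turn as a pseudo-measured profile and
recomputing the statistic yields an exchangeable null distribution and an
exact p-value with resolution 1/(iterations+1). The statistic is
shape-sensitive: values of the tested profile and of the mean of the remaining
pool are rank-transformed jointly over the PSD x bin table, the rank
difference is averaged over PSDs per radial bin, and the absolute per-bin
deviations are averaged; it is large whenever the tested profile's radial
shape deviates from the condition in any direction, without cancellation
between center excess and border deficit. p-values are reported raw (exact)
and Bonferroni-adjusted over conditions.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .geometry import region_area, synaptic_count
from .model import PSDRecord, StudyDataset, select

SUMMARY_COLUMNS = ["group", "n_psd", "mean", "sd", "median", "iqr",
                   "min", "max", "skewness", "variance", "cv"]


@dataclass(frozen=True)
class SummaryRow:
    """Descriptive statistics of one group of values."""

    group: str
    n: int
    mean: float
    sd: float
    median: float
    iqr: float
    min: float
    max: float
    skewness: float
    variance: float
    cv: float


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    comparison: str
    method: str
    p_adjusted: float | None = None


@dataclass(frozen=True)
class RatioRow:
    """Per-animal AMPA/GluN1 grain-count ratios for one layer x target group."""

    layer: str
    target: str
    animal_ids: tuple[str, ...]
    ratios: tuple[float, ...]
    grand_mean: float  # mean over per-animal means
    sd: float


def summarize(values: Sequence[float], group: str = "") -> SummaryRow:
    """Descriptive summary; SD uses the n-1 denominator, skewness is the
    adjusted Fisher-Pearson estimator, quartiles use linear interpolation."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError(f"summarize needs n >= 2, got n={x.size}")
    mean = float(np.mean(x))
    sd = float(np.std(x, ddof=1))
    q1, q3 = np.percentile(x, [25, 75])
    # a constant sample has no asymmetry; avoids 0/0 in the skew estimator
    skew = float(sps.skew(x, bias=False)) if np.ptp(x) > 0 else 0.0
    return SummaryRow(
        group=group, n=int(x.size), mean=mean, sd=sd,
        median=float(np.median(x)), iqr=float(q3 - q1),
        min=float(np.min(x)), max=float(np.max(x)),
        skewness=skew,
        variance=sd**2, cv=sd / mean,
    )


def summary_table(groups: Mapping[str, Sequence[float]]) -> pd.DataFrame:
    """One summary row per group, in the standard column layout."""
    rows = [summarize(v, g) for g, v in groups.items()]
    return pd.DataFrame(
        [[r.group, r.n, r.mean, r.sd, r.median, r.iqr, r.min, r.max,
          r.skewness, r.variance, r.cv] for r in rows],
        columns=SUMMARY_COLUMNS,
    )


# ---------------------------------------------------------------------------
# Rank tests

def _u_statistic(ranks_a: np.ndarray, n_a: int) -> float:
    return float(np.sum(ranks_a)) - n_a * (n_a + 1) / 2.0


def mann_whitney_u(a: Sequence[float], b: Sequence[float],
                   comparison: str = "a vs b") -> TestResult:
    """Two-sided Mann-Whitney U test.

    Small samples (both n <= 8) use exact enumeration of all group
    assignments with mid-ranks, which is valid under ties; larger samples use
    the tie-corrected normal approximation.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("mann_whitney_u requires non-empty samples")
    n_a, n_b = a.size, b.size
    ranks = sps.rankdata(np.concatenate([a, b]))
    u_obs = _u_statistic(ranks[:n_a], n_a)
    mu = n_a * n_b / 2.0

    if max(n_a, n_b) <= 8:
        dev = abs(u_obs - mu)
        hits = total = 0
        for combo in itertools.combinations(range(n_a + n_b), n_a):
            u = _u_statistic(ranks[list(combo)], n_a)
            hits += abs(u - mu) >= dev - 1e-9
            total += 1
        p = hits / total
        method = "Mann-Whitney U (exact enumeration)"
    else:
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        p = float(res.pvalue)
        method = "Mann-Whitney U (tie-corrected normal approximation)"
    return TestResult(statistic=u_obs, p_value=min(p, 1.0),
                      comparison=comparison, method=method)


@dataclass(frozen=True)
class KruskalResult:
    omnibus: TestResult
    posthoc: tuple[TestResult, ...]


def kruskal_wallis_h(groups: Mapping[str, Sequence[float]]) -> KruskalResult:
    """Tie-corrected Kruskal-Wallis H test (chi-square approximation, k-1 df)
    with post-hoc pairwise Mann-Whitney U tests, reported raw and
    Bonferroni-adjusted."""
    labels = list(groups)
    samples = [np.asarray(groups[k], dtype=float) for k in labels]
    if len(samples) < 2:
        raise ValueError("kruskal_wallis_h needs >= 2 groups")
    for lab, s in zip(labels, samples):
        if s.size == 0:
            raise ValueError(f"group {lab!r} is empty")
    if np.ptp(np.concatenate(samples)) == 0:
        h, p = 0.0, 1.0  # all values identical: no evidence of any difference
    else:
        h, p = sps.kruskal(*samples)
    omnibus = TestResult(statistic=float(h), p_value=float(p),
                         comparison=" vs ".join(labels),
                         method="Kruskal-Wallis H (chi-square approx.)")
    pairs = list(itertools.combinations(range(len(labels)), 2))
    posthoc = []
    for i, j in pairs:
        r = mann_whitney_u(samples[i], samples[j],
                           comparison=f"{labels[i]} vs {labels[j]}")
        posthoc.append(TestResult(
            statistic=r.statistic, p_value=r.p_value, comparison=r.comparison,
            method=r.method, p_adjusted=min(1.0, r.p_value * len(pairs)),
        ))
    return KruskalResult(omnibus=omnibus, posthoc=tuple(posthoc))


# ---------------------------------------------------------------------------
# Measured vs simulated radial profiles

@dataclass
class RmAnovaResult:
    """Rank repeated-measures comparison of simulated conditions vs measured."""

    f_statistic: float  # one-way RM ANOVA on per-PSD mean ranks (descriptive)
    p_omnibus: float  # smallest adjusted p over conditions
    comparisons: tuple[TestResult, ...] = field(default_factory=tuple)
    n_psd: int = 0
    n_null: int = 0  # null replicates per condition (= simulation iterations)


def _as_iteration_array(cond, n_psd: int, name: str) -> np.ndarray:
    """Coerce one condition to (n_psd, iterations, bins) float array."""
    if isinstance(cond, pd.DataFrame):
        arr = cond.to_numpy(dtype=float)[:, None, :]
    else:
        arr = np.asarray(cond, dtype=float)
        if arr.ndim == 2:
            arr = arr[:, None, :]
    if arr.ndim != 3 or arr.shape[0] != n_psd:
        raise ValueError(
            f"condition {name!r}: expected (n_psd, iterations, bins) profiles "
            f"aligned with the measured matrix, got shape {arr.shape}"
        )
    return arr


def _profile_discrepancy(tested: np.ndarray, reference: np.ndarray,
                         valid: np.ndarray) -> float:
    """Mean over bins of |mean over PSDs of rank(tested) - rank(reference)|.

    Ranks are midranks over the joint (PSD, bin) tables of both profiles.
    Shape-sensitive: per-bin deviations do not cancel across bins.
    """
    both = np.concatenate([tested[valid], reference[valid]])
    ranks = sps.rankdata(both)
    n = int(valid.sum())
    rt = np.full(tested.shape, np.nan)
    rr = np.full(reference.shape, np.nan)
    rt[valid] = ranks[:n]
    rr[valid] = ranks[n:]
    with np.errstate(invalid="ignore"):
        per_bin = np.nanmean(rt - rr, axis=0)
    return float(np.nanmean(np.abs(per_bin)))


def ranked_rm_anova_dunnett(
    measured: pd.DataFrame,
    simulated: Mapping[str, np.ndarray | pd.DataFrame],
) -> RmAnovaResult:
    """Compare measured radial profiles against simulated placement models.

    ``measured`` is a profile matrix (rows = PSDs, columns = shared bin index,
    NaN for bins a PSD does not reach). Each ``simulated`` condition is the
    per-iteration profile stack for the same PSDs, shape
    (n_psd, iterations, bins): under the null hypothesis that the measured
    grains follow that placement model, the measured profile and every
    iteration profile are iid, so holding out each iteration as a
    pseudo-measured profile (compared, like the real one, against the mean of
    the remaining pool) gives an exact Monte-Carlo null for the mean-rank
    statistic. Cells missing in any condition are excluded cell-wise.
    p-values are reported raw (exact, resolution 1/(iterations+1)) and
    Bonferroni-adjusted over conditions.

    A 2D matrix may be passed for a condition (e.g. the measured matrix
    itself); it is treated as a single iteration.
    """
    if measured.shape[0] < 2:
        raise ValueError("need >= 2 PSDs")
    if not simulated:
        raise ValueError("need >= 1 simulated condition")
    m = measured.to_numpy(dtype=float)
    n_psd = m.shape[0]
    names = list(simulated)
    conds = {k: _as_iteration_array(simulated[k], n_psd, k) for k in names}

    width = max([m.shape[1]] + [c.shape[2] for c in conds.values()])

    def _pad(a, ndim3):
        target = (a.shape[0], a.shape[1], width) if ndim3 else (a.shape[0], width)
        out = np.full(target, np.nan)
        out[..., : a.shape[-1]] = a
        return out

    m = _pad(m, False)
    conds = {k: _pad(v, True) for k, v in conds.items()}

    comparisons = []
    min_iters = min(c.shape[1] for c in conds.values())
    stats_by_cond = {}
    for name in names:
        sims = conds[name]  # (psd, k, bins)
        k = sims.shape[1]
        valid = np.isfinite(m) & np.all(np.isfinite(sims), axis=1)
        if not valid.any():
            raise ValueError(f"condition {name!r}: no complete cells")
        pool_sum = m + sims.sum(axis=1)  # (psd, bins); pool size k+1
        t_obs = _profile_discrepancy(m, (pool_sum - m) / k, valid)
        t_null = np.empty(k)
        for j in range(k):
            xj = sims[:, j, :]
            t_null[j] = _profile_discrepancy(xj, (pool_sum - xj) / k, valid)
        # one-sided exceedance: the statistic measures discrepancy, and any
        # bias from comparing one noisy profile against a smooth average is
        # shared by the held-out null replicates
        p = (1 + np.sum(t_null >= t_obs - 1e-12)) / (k + 1)
        stats_by_cond[name] = t_obs
        comparisons.append(TestResult(
            statistic=t_obs, p_value=float(p),
            comparison=f"measured vs {name}",
            method="exact Monte-Carlo rank test (Dunnett-style hold-one-out)",
            p_adjusted=float(min(1.0, p * len(names))),
        ))

    # descriptive one-way RM ANOVA on ranks of per-PSD mean profile values
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)
        table = np.stack([np.where(np.isfinite(m), m, np.nan)]
                         + [np.nanmean(conds[k], axis=1) for k in names], axis=1)
    valid_all = np.all(np.isfinite(table), axis=1)
    table = np.where(valid_all[:, None, :], table, np.nan)
    flat = table[np.isfinite(table)]
    ranks = np.full_like(table, np.nan)
    if flat.size:
        ranks[np.isfinite(table)] = sps.rankdata(flat)
    cell_means = np.nanmean(ranks, axis=2)  # (psd, cond)
    n_cond = table.shape[1]
    grand = cell_means.mean()
    ss_cond = n_psd * np.sum((cell_means.mean(axis=0) - grand) ** 2)
    resid = (cell_means - cell_means.mean(axis=0)
             - cell_means.mean(axis=1)[:, None] + grand)
    ss_err = np.sum(resid**2)
    df_c, df_e = n_cond - 1, (n_cond - 1) * (n_psd - 1)
    if ss_err > 1e-12:
        f_stat = float((ss_cond / df_c) / (ss_err / df_e))
    else:
        f_stat = 0.0 if ss_cond <= 1e-12 else np.inf

    p_omni = min(c.p_adjusted for c in comparisons)
    return RmAnovaResult(
        f_statistic=f_stat, p_omnibus=float(p_omni),
        comparisons=tuple(comparisons), n_psd=n_psd, n_null=min_iters,
    )


# ---------------------------------------------------------------------------
# Count-area relation, densities, receptor ratios

@dataclass(frozen=True)
class CountAreaFit:
    r2: float
    slope: float  # grains per um^2
    intercept: float
    n: int


def count_area_r2(records: Sequence[PSDRecord]) -> CountAreaFit:
    """OLS of synaptic grain count on PSD area (um^2); R^2 = squared Pearson r."""
    if len(records) < 3:
        raise ValueError("count_area_r2 needs >= 3 records")
    areas = np.array([region_area(r.region) for r in records])
    counts = np.array([synaptic_count(r) for r in records], dtype=float)
    fit = sps.linregress(areas, counts)
    return CountAreaFit(r2=float(fit.rvalue**2), slope=float(fit.slope),
                        intercept=float(fit.intercept), n=len(records))


def density_per_um2(rec: PSDRecord) -> float:
    """Synaptic grains per um^2 of PSD area for one record.

    Group-level densities are means of these per-PSD values, not pooled
    count over pooled area.
    """
    area = region_area(rec.region)
    return synaptic_count(rec) / area


def receptor_ratio(ds: StudyDataset, layer: str, target: str) -> RatioRow:
    """Per-animal AMPA/GluN1 ratio for one layer x target group.

    For each animal: (mean synaptic AMPA grains per AMPA-labeled PSD) /
    (mean synaptic GluN1 grains per GluN1-labeled PSD). The grand mean is the
    mean over per-animal ratios (total mean over single means), +/- SD.
    """
    sub = select(ds, layer=layer, target=target)
    per_animal: dict[str, dict[str, list[int]]] = {}
    for rec in sub.records:
        slot = per_animal.setdefault(rec.animal_id, {"AMPA": [], "GluN1": []})
        for receptor in ("AMPA", "GluN1"):
            if any(p.receptor == receptor for p in rec.particles):
                # count only this receptor's grains inside the contour
                filtered = select(
                    StudyDataset(records=[rec]), receptor=receptor
                ).records[0]
                slot[receptor].append(synaptic_count(filtered))

    animals, ratios = [], []
    for animal in sorted(per_animal):
        slot = per_animal[animal]
        if slot["AMPA"] and slot["GluN1"]:
            mean_g = float(np.mean(slot["GluN1"]))
            if mean_g > 0:
                animals.append(animal)
                ratios.append(float(np.mean(slot["AMPA"])) / mean_g)
    if not ratios:
        raise ValueError(
            f"group layer={layer} target={target} lacks per-animal AMPA and "
            f"GluN1 single-label counts"
        )
    grand = float(np.mean(ratios))
    sd = float(np.std(ratios, ddof=1)) if len(ratios) > 1 else 0.0
    return RatioRow(layer=layer, target=target, animal_ids=tuple(animals),
                    ratios=tuple(ratios), grand_mean=grand, sd=sd)
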