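"""Reference group statistics for AMPA/GluN1 immunogold labeling at L4 and L5
PSDs of the adult rat somatosensory (barrel) cortex.

These are the published per-group descriptive statistics that the synthetic
generator is calibrated to emulate: PSD surface areas per layer and target
structure, grain counts per PSD and grain densities per um^2 for each
receptor, the grain-count vs area coefficients of determination, and the
per-animal AMPA/GluN1 ratios. They serve as configuration inputs (generator
targets) and as the reference for arithmetic-consistency checks such as
recomputing each group's CV from its mean and SD.

Keys are (layer, target) or (receptor, layer, target) tuples; units are noted
per table.
"""

from __future__ import annotations

# PSD surface areas [um^2], per (layer, target):
# n, mean, sd, median, iqr, min, max, skewness, cv
PSD_AREA = {
    ("L4", "shaft"): dict(n=293, mean=0.06, sd=0.02, median=0.05, iqr=0.03,
                          min=0.02, max=0.15, skewness=0.85, cv=0.33),
    ("L4", "spine"): dict(n=337, mean=0.04, sd=0.02, median=0.04, iqr=0.02,
                          min=0.01, max=0.13, skewness=-1.08, cv=0.50),
    ("L5", "shaft"): dict(n=335, mean=0.06, sd=0.02, median=0.06, iqr=0.04,
                          min=0.02, max=0.16, skewness=0.63, cv=0.33),
    ("L5", "spine"): dict(n=463, mean=0.04, sd=0.01, median=0.03, iqr=0.02,
                          min=0.02, max=0.08, skewness=0.54, cv=0.25),
}

# Gold grains per PSD, per (receptor, layer, target)
GRAINS_PER_PSD = {
    ("AMPA", "L4", "shaft"): dict(n=118, mean=22.70, sd=13.73, median=20.00,
                                  iqr=18.25, min=4, max=71, skewness=1.22,
                                  variance=188.47, cv=0.60),
    ("AMPA", "L4", "spine"): dict(n=182, mean=24.02, sd=13.38, median=22.00,
                                  iqr=14.25, min=4, max=76, skewness=1.51,
                                  variance=179.02, cv=0.56),
    ("AMPA", "L5", "shaft"): dict(n=166, mean=37.02, sd=21.58, median=33.50,
                                  iqr=25.00, min=5, max=131, skewness=1.37,
                                  variance=465.64, cv=0.58),
    ("AMPA", "L5", "spine"): dict(n=281, mean=30.29, sd=15.58, median=27.00,
                                  iqr=20.00, min=3, max=103, skewness=1.20,
                                  variance=242.83, cv=0.51),
    ("GluN1", "L4", "shaft"): dict(n=175, mean=30.19, sd=17.85, median=27.00,
                                   iqr=24.00, min=5, max=82, skewness=0.90,
                                   variance=318.59, cv=0.59),
    ("GluN1", "L4", "spine"): dict(n=155, mean=15.43, sd=9.04, median=14.00,
                                   iqr=11.00, min=3, max=47, skewness=1.24,
                                   variance=81.77, cv=0.59),
    ("GluN1", "L5", "shaft"): dict(n=169, mean=39.23, sd=24.02, median=35.00,
                                   iqr=31.00, min=5, max=139, skewness=1.34,
                                   variance=576.76, cv=0.61),
    ("GluN1", "L5", "spine"): dict(n=182, mean=21.67, sd=13.07, median=19.00,
                                   iqr=15.00, min=2, max=82, skewness=1.61,
                                   variance=170.76, cv=0.60),
}

# Gold grains per um^2, per (receptor, layer, target)
GRAINS_PER_UM2 = {
    ("AMPA", "L4", "shaft"): dict(mean=416, sd=214, median=390, iqr=306,
                                  min=79, max=1083, skewness=0.81, cv=0.51),
    ("AMPA", "L4", "spine"): dict(mean=653, sd=329, median=600, iqr=443,
                                  min=171, max=1777, skewness=0.80, cv=0.50),
    ("AMPA", "L5", "shaft"): dict(mean=634, sd=282, median=601, iqr=394,
                                  min=46, max=1421, skewness=0.30, cv=0.44),
    ("AMPA", "L5", "spine"): dict(mean=769, sd=284, median=756, iqr=348,
                                  min=108, max=1691, skewness=0.23, cv=0.37),
    ("GluN1", "L4", "shaft"): dict(mean=557, sd=264, median=539, iqr=425,
                                   min=101, max=1352, skewness=0.32, cv=0.47),
    ("GluN1", "L4", "spine"): dict(mean=429, sd=231, median=382, iqr=285,
                                   min=78, max=1369, skewness=1.00, cv=0.54),
    ("GluN1", "L5", "shaft"): dict(mean=622, sd=300, median=605, iqr=396,
                                   min=98, max=1472, skewness=0.45, cv=0.48),
    ("GluN1", "L5", "spine"): dict(mean=511, sd=287, median=447, iqr=392,
                                   min=29, skewness=0.81, cv=0.56),
}

# Grain count vs PSD area coefficients of determination, (receptor, layer, target)
COUNT_AREA_R2 = {
    ("AMPA", "L4", "shaft"): 0.81,
    ("GluN1", "L4", "shaft"): 0.81,
    ("AMPA", "L4", "spine"): 0.77,
    ("GluN1", "L4", "spine"): 0.78,
    ("AMPA", "L5", "shaft"): 0.73,
    ("GluN1", "L5", "shaft"): 0.79,
    ("AMPA", "L5", "spine"): 0.86,
    ("GluN1", "L5", "spine"): 0.80,
}

# Per-animal AMPA/GluN1 ratio (grand mean over animal means, SD), (layer, target)
AMPA_GLUN1_RATIO = {
    ("L4", "shaft"): dict(mean=0.72, sd=0.08),
    ("L4", "spine"): dict(mean=1.46, sd=0.25),
    ("L5", "shaft"): dict(mean=1.03, sd=0.02),
    ("L5", "spine"): dict(mean=1.54, sd=0.09),
}

# Morphology class proportions over all PSDs
MORPHOLOGY_PROPORTIONS = {
    "macular": 0.80,
    "perforated": 0.10,
    "horseshoe": 0.05,
    "ring": 0.05,
}


def cv_checks() -> list[dict]:
    """Recompute each group's CV as SD/mean and pair it with the printed CV."""
    out = []
    for name, table in [("psd_area", PSD_AREA),
                        ("grains_per_psd", GRAINS_PER_PSD),
                        ("grains_per_um2", GRAINS_PER_UM2)]:
        for key, row in table.items():
            out.append(dict(
                table=name, group="/".join(str(k) for k in key),
                cv_printed=row["cv"],
                cv_recomputed=row["sd"] / row["mean"],
            ))
    return out


def fold_changes() -> dict[str, dict]:
    """Ratios of published group means vs the stated approximate folds."""
    gpp = GRAINS_PER_PSD
    gpu = GRAINS_PER_UM2
    area = PSD_AREA
    ratio = AMPA_GLUN1_RATIO
    checks = {
        "area_shaft_vs_spine_L4": (
            area[("L4", "shaft")]["mean"] / area[("L4", "spine")]["mean"], 1.5),
        "area_shaft_vs_spine_L5": (
            area[("L5", "shaft")]["mean"] / area[("L5", "spine")]["mean"], 1.5),
        "ampa_per_um2_L4_spine_vs_shaft": (
            gpu[("AMPA", "L4", "spine")]["mean"]
            / gpu[("AMPA", "L4", "shaft")]["mean"], 1.6),
        "glun1_per_psd_L4_shaft_vs_spine": (
            gpp[("GluN1", "L4", "shaft")]["mean"]
            / gpp[("GluN1", "L4", "spine")]["mean"], 2.0),
        "glun1_per_um2_L4_shaft_vs_spine": (
            gpu[("GluN1", "L4", "shaft")]["mean"]
            / gpu[("GluN1", "L4", "spine")]["mean"], 1.3),
        "glun1_per_psd_L5_shaft_vs_spine": (
            gpp[("GluN1", "L5", "shaft")]["mean"]
            / gpp[("GluN1", "L5", "spine")]["mean"], 1.8),
        "ampa_per_psd_L5_vs_L4_shaft": (
            gpp[("AMPA", "L5", "shaft")]["mean"]
            / gpp[("AMPA", "L4", "shaft")]["mean"], 1.6),
        "ampa_per_psd_L5_vs_L4_spine": (
            gpp[("AMPA", "L5", "spine")]["mean"]
            / gpp[("AMPA", "L4", "spine")]["mean"], 1.3),
        "glun1_per_psd_L5_vs_L4_shaft": (
            gpp[("GluN1", "L5", "shaft")]["mean"]
            / gpp[("GluN1", "L4", "shaft")]["mean"], 1.3),
        "ampa_glun1_ratio_L4_spine_vs_shaft": (
            ratio[("L4", "spine")]["mean"] / ratio[("L4", "shaft")]["mean"], 2.0),
        "ampa_glun1_ratio_L5_spine_vs_shaft": (
            ratio[("L5", "spine")]["mean"] / ratio[("L5", "shaft")]["mean"], 1.5),
    }
    return {k: dict(computed=v[0], stated=v[1]) for k, v in checks.items()}
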