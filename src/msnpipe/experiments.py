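"""Study-level experiments: reference-table checks, parameter recovery,
type-I calibration and the small-world density profile.

These are the computations the analysis scripts and validation suite run;
each takes explicit sizes and seeds so it can be scaled and reproduced.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from msnpipe.atlas import synthetic_atlas
from msnpipe.metrics import is_connected, small_worldness
from msnpipe.msn import build_msn, extract_subnetwork, threshold_density
from msnpipe.pipeline import analyze_metrics, compute_metric_table
from msnpipe.stats import DesignSpec, pearson_chi_square, pooled_t_test, rm_ancova
from msnpipe.synthetic import (
    Effect,
    SimulationConfig,
    generate_cohort,
    generate_morphometry,
    subject_tables,
)

#: Published summary profile of the reference 111 DAT + 75 bvFTD cohort:
#: per-group (mean, sd) for continuous rows, per-group counts for
#: categorical rows.  These are inputs to the summary-statistic tests.
REFERENCE_COHORT_SUMMARY = {
    "age": {"DAT": (74.15, 7.53, 111), "bvFTD": (64.46, 7.03, 75)},
    "education": {"DAT": (15.24, 3.31, 111), "bvFTD": (16.05, 3.10, 75)},
    "sex_mf": {"DAT": (68, 43), "bvFTD": (51, 24)},
    "disinhibition_yes_no": {"DAT": (27, 84), "bvFTD": (62, 13)},
    "disinhibition_severity_0123": {"DAT": (84, 12, 13, 2), "bvFTD": (13, 15, 27, 20)},
    "scanner_siemens_ge_philips": {"DAT": (59, 32, 20), "bvFTD": (61, 14, 0)},
}


def reference_table_statistics() -> dict[str, float]:
    """Recompute the cohort-comparison statistics from the published
    per-group summaries: pooled t for age and education, Pearson chi-square
    for the four categorical rows."""
    s = REFERENCE_COHORT_SUMMARY
    out: dict[str, float] = {}
    for var in ("age", "education"):
        g1, g2 = s[var]["DAT"], s[var]["bvFTD"]
        t, _, _ = pooled_t_test(*g1, *g2)
        out[f"{var}_pooled_t"] = t
    for var, key in [
        ("sex_mf", "sex_chi2"),
        ("disinhibition_yes_no", "disinhibition_chi2"),
        ("disinhibition_severity_0123", "severity_chi2"),
        ("scanner_siemens_ge_philips", "scanner_chi2"),
    ]:
        chi2, _, _ = pearson_chi_square([list(s[var]["DAT"]), list(s[var]["bvFTD"])])
        out[key] = chi2
    return out


def recovery_config(seed: int, n_per_group: int = 50, attenuation: float = 0.5) -> SimulationConfig:
    """Parameter-recovery study: balanced diagnosis groups, disinhibition in
    half of each, and the configured within-CCN similarity attenuation for
    disinhibited subjects."""
    return SimulationConfig(
        n_dat=n_per_group,
        n_bvftd=n_per_group,
        seed=seed,
        disinhibition_rate_by_group={"DAT": 0.5, "bvFTD": 0.5},
        effect_map=(Effect("CCN", "disinhibition", attenuation),),
    )


def run_recovery_experiment(
    n_seeds: int = 20,
    n_per_group: int = 50,
    attenuation: float = 0.5,
    base_seed: int = 0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Across seeds, does the ANCOVA recover the injected CCN effect (and
    stay silent on the unaffected SN)?

    Returns one row per (seed, network, metric) with the disinhibition main
    effect's p value, adjusted direction and significance.
    """
    atlas = synthetic_atlas()
    rows = []
    for k in range(n_seeds):
        cfg = recovery_config(base_seed + k, n_per_group, attenuation)
        cohort = generate_cohort(cfg)
        morph = generate_morphometry(cohort, atlas, cfg)
        metric_table = compute_metric_table(morph, atlas)
        results = analyze_metrics(metric_table, cohort, DesignSpec())
        for key, rs in results.items():
            network, metric = key.split("_", 1)
            r = next(x for x in rs if x["effect"] == "disinhibition")
            rows.append(
                {
                    "seed": base_seed + k,
                    "network": network,
                    "metric": metric,
                    "p": r["p"],
                    "estimate": r["estimate"],
                    "significant_negative": bool(r["p"] < alpha and r["estimate"] < 0),
                    "significant": bool(r["p"] < alpha),
                }
            )
    return pd.DataFrame(rows)


def run_type1_experiment(
    n_reps: int = 500, n_per_group: int = 50, base_seed: int = 0, alpha: float = 0.05
) -> pd.DataFrame:
    """Type-I calibration of the between-subject tests.

    Each replicate draws a fresh cohort from the null generator and a
    metric response independent of every predictor, then fits the full
    covariate-adjusted model.  Returns per-effect rejection rates.
    """
    design = DesignSpec()
    hits = {"diagnosis": 0, "disinhibition": 0, "diagnosis:disinhibition": 0}
    for k in range(n_reps):
        cfg = SimulationConfig(
            n_dat=n_per_group,
            n_bvftd=n_per_group,
            seed=base_seed + k,
            disinhibition_rate_by_group={"DAT": 0.4, "bvFTD": 0.6},
        )
        cohort = generate_cohort(cfg)
        rng = np.random.default_rng(np.random.SeedSequence([base_seed + k, 17]))
        metrics = pd.DataFrame(
            [
                {"subject_id": sid, "density": d, "value": v}
                for sid in cohort.subject_id
                for d, v in zip(design.densities, rng.normal(size=len(design.densities)))
            ]
        )
        for r in rm_ancova(metrics, cohort, design):
            if r.effect in hits and r.p < alpha:
                hits[r.effect] += 1
    return pd.DataFrame(
        [{"effect": e, "rejections": h, "rate": h / n_reps} for e, h in hits.items()]
    )


def small_world_profile(
    n_subjects: int = 5,
    densities: tuple[float, ...] = (0.25, 0.45),
    n_null: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean small-world coefficient per network and density on a null cohort."""
    atlas = synthetic_atlas()
    cfg = SimulationConfig(n_dat=n_subjects, n_bvftd=0, seed=seed)
    cohort = generate_cohort(cfg)
    morph = generate_morphometry(cohort, atlas, cfg)
    from msnpipe.atlas import CCN_DEFINITION, SN_DEFINITION

    nodes = {"SN": atlas.network_nodes(SN_DEFINITION), "CCN": atlas.network_nodes(CCN_DEFINITION)}
    rows = []
    for i, (sid, table) in enumerate(subject_tables(morph)):
        msn = build_msn(table)
        for network, idx in nodes.items():
            sub = extract_subnetwork(msn, idx)
            for d in densities:
                thr = threshold_density(sub, d)
                if not is_connected(thr):
                    continue
                sigma = small_worldness(thr, n_null=n_null, seed=seed + 31 * i)
                rows.append(
                    {"subject_id": sid, "network": network, "density": d, "sigma": sigma}
                )
    return pd.DataFrame(rows)
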