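"""End-to-end orchestration: simulate → build MSNs → metrics → ANCOVA.

Every stage reads and writes only documented delimited-text or JSON
formats, so real FreeSurfer regional exports can replace the simulator:
a cohort table (one row per subject), a long-format morphometrics table
(subject_id, region_id, 7 features), and an atlas assignment table.

Outputs of a full run: per-subject subnetwork similarity matrices, a
long-format metric table (subject × network × density × metric), one
ANCOVA result set per network × metric, a demographic comparison table,
and a run manifest (config hash, seed, package/library versions, warning
tallies).  A fixed config and seed reproduce every output byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy
import statsmodels

import msnpipe
from msnpipe import atlas as atlas_mod
from msnpipe.atlas import CCN_DEFINITION, SN_DEFINITION, NetworkDefinition, ParcelAtlas
from msnpipe.errors import ConfigurationError, ValidationError
from msnpipe.metrics import (
    global_efficiency_weighted,
    is_connected,
    small_worldness,
    transitivity_weighted,
)
from msnpipe.msn import build_msn, extract_subnetwork, save_similarity_matrix, threshold_density
from msnpipe.stats import DesignSpec, pearson_chi_square, pooled_t_test, rm_ancova, welch_t_test
from msnpipe.synthetic import SimulationConfig, generate_cohort, generate_morphometry, subject_tables

logger = logging.getLogger(__name__)

DEFAULT_DENSITIES = (0.25, 0.30, 0.35, 0.40, 0.45)
ANALYZED_METRICS = ("transitivity", "global_efficiency")


@dataclass(frozen=True)
class PipelineConfig:
    """Configuration of one pipeline run."""

    output_dir: str | Path = "results/run"
    cohort_path: str | Path | None = None
    morphometrics_path: str | Path | None = None
    atlas_path: str | Path | None = None
    densities: tuple[float, ...] = DEFAULT_DENSITIES
    networks: tuple[NetworkDefinition, ...] = (SN_DEFINITION, CCN_DEFINITION)
    design: DesignSpec = field(default_factory=DesignSpec)
    simulation: SimulationConfig | None = None
    seed: int = 0
    compute_small_world: bool = False
    n_null: int = 10
    write_msns: bool = True
    log_level: str = "INFO"

    def validate(self) -> None:
        d = self.densities
        if not d or any(not 0 < x <= 1 for x in d) or list(d) != sorted(set(d)):
            raise ConfigurationError("densities must be strictly increasing values in (0, 1]")
        if self.simulation is None and (
            self.cohort_path is None or self.morphometrics_path is None
        ):
            raise ConfigurationError(
                "stage 'inputs': provide cohort_path and morphometrics_path, "
                "or a simulation config"
            )

    def config_hash(self) -> str:
        def default(o: object) -> object:
            if dataclasses.is_dataclass(o) and not isinstance(o, type):
                return dataclasses.asdict(o)
            if isinstance(o, frozenset):
                return sorted(o)
            if isinstance(o, Path):
                return str(o)
            raise TypeError(f"unhashable config element: {o!r}")

        payload = dataclasses.asdict(self)
        payload.pop("output_dir")  # where results land does not change what they are
        blob = json.dumps(payload, default=default, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()


def _load_atlas(config: PipelineConfig) -> ParcelAtlas:
    if config.atlas_path is not None:
        return atlas_mod.load_atlas(config.atlas_path)
    return atlas_mod.synthetic_atlas()


def _inputs(config: PipelineConfig, atlas: ParcelAtlas) -> tuple[pd.DataFrame, pd.DataFrame]:
    if config.simulation is not None:
        sim = dataclasses.replace(config.simulation, seed=config.seed)
        cohort = generate_cohort(sim)
        morph = generate_morphometry(cohort, atlas, sim)
        return cohort, morph
    cohort = pd.read_csv(config.cohort_path, sep="\t")
    morph = pd.read_csv(config.morphometrics_path, sep="\t")
    return cohort, morph


def compute_metric_table(
    morphometry: pd.DataFrame,
    atlas: ParcelAtlas,
    networks: tuple[NetworkDefinition, ...] = (SN_DEFINITION, CCN_DEFINITION),
    densities: tuple[float, ...] = DEFAULT_DENSITIES,
    compute_small_world: bool = False,
    n_null: int = 10,
    seed: int = 0,
    msn_dir: Path | None = None,
) -> pd.DataFrame:
    """Build each subject's MSN and tabulate subnetwork metrics.

    Returns a long-format table (subject_id, network, density, metric,
    value).  ``connected`` is recorded as 1.0/0.0; disconnected networks
    are flagged, never fatal.
    """
    node_sets = {net.name: atlas.network_nodes(net) for net in networks}
    rows = []
    disconnected = 0
    for sidx, (sid, table) in enumerate(subject_tables(morphometry)):
        msn = build_msn(table)
        for net in networks:
            sub = extract_subnetwork(msn, node_sets[net.name])
            if msn_dir is not None:
                save_similarity_matrix(sub, msn_dir / f"{sid}_{net.name}.tsv")
            for density in densities:
                thr = threshold_density(sub, density)
                connected = is_connected(thr)
                if not connected:
                    disconnected += 1
                values = {
                    "transitivity": transitivity_weighted(thr),
                    "global_efficiency": global_efficiency_weighted(thr),
                    "connected": float(connected),
                }
                if compute_small_world and connected:
                    sw_seed = int(
                        np.random.SeedSequence(
                            [seed, 3, sidx, round(density * 100)]
                        ).generate_state(1)[0] % (2**31)
                    )
                    values["small_worldness"] = small_worldness(thr, n_null=n_null, seed=sw_seed)
                for metric, value in values.items():
                    rows.append(
                        {
                            "subject_id": sid,
                            "network": net.name,
                            "density": density,
                            "metric": metric,
                            "value": value,
                        }
                    )
    if disconnected:
        logger.warning("%d (subject, network, density) graphs were disconnected", disconnected)
    return pd.DataFrame(rows)


#: Continuous/categorical variable split used by the demographic table.
_CONTINUOUS_VARS = ("age", "education", "cdr_sb", "tiv", "days_mri_npiq")
_CATEGORICAL_VARS = ("sex", "disinhibition_present", "disinhibition_severity", "scanner")


def demographics_table(cohort: pd.DataFrame) -> pd.DataFrame:
    """Group comparison table in the conventional cohort-description layout.

    Continuous variables use a pooled t by default, switching to Welch when
    a two-sided variance-ratio screen rejects equal variances at α = 0.05;
    categorical variables use an uncorrected Pearson chi-square over the
    observed levels.
    """
    groups = sorted(cohort["diagnosis"].unique())
    if len(groups) != 2:
        raise ValidationError(f"need exactly two diagnosis groups, got {groups}")
    g1 = cohort[cohort["diagnosis"] == groups[0]]
    g2 = cohort[cohort["diagnosis"] == groups[1]]
    rows = []
    for var in _CONTINUOUS_VARS:
        if var not in cohort.columns:
            continue
        m1, s1, n1 = g1[var].mean(), g1[var].std(ddof=1), len(g1)
        m2, s2, n2 = g2[var].mean(), g2[var].std(ddof=1), len(g2)
        fstat = (s1**2) / (s2**2)
        cdf = float(_f_cdf(fstat, n1 - 1, n2 - 1))
        p_var = 2 * min(cdf, 1 - cdf)
        if p_var < 0.05:
            t, df, p = welch_t_test(m1, s1, n1, m2, s2, n2)
            test = "welch_t"
        else:
            t, df, p = pooled_t_test(m1, s1, n1, m2, s2, n2)
            test = "pooled_t"
        rows.append(
            {
                "variable": var,
                groups[0]: f"{m1:.2f} ({s1:.2f})",
                groups[1]: f"{m2:.2f} ({s2:.2f})",
                "test": test,
                "statistic": t,
                "df": df,
                "p": p,
            }
        )
    for var in _CATEGORICAL_VARS:
        if var not in cohort.columns:
            continue
        tab = pd.crosstab(cohort["diagnosis"], cohort[var])
        tab = tab.loc[groups, tab.sum(axis=0) > 0]
        if tab.shape[1] < 2:
            continue  # constant variable: nothing to compare
        chi2, df, p = pearson_chi_square(tab.to_numpy())
        rows.append(
            {
                "variable": var,
                groups[0]: "/".join(str(int(v)) for v in tab.iloc[0]),
                groups[1]: "/".join(str(int(v)) for v in tab.iloc[1]),
                "test": "chi_square",
                "statistic": chi2,
                "df": df,
                "p": p,
            }
        )
    return pd.DataFrame(rows)


def _f_cdf(x: float, d1: int, d2: int) -> float:
    from scipy.stats import f

    return f.cdf(x, d1, d2)


def analyze_metrics(
    metric_table: pd.DataFrame,
    cohort: pd.DataFrame,
    design: DesignSpec,
    networks: tuple[str, ...] = ("SN", "CCN"),
    metrics: tuple[str, ...] = ANALYZED_METRICS,
) -> dict[str, list[dict[str, object]]]:
    """Run the repeated-measures ANCOVA for each network × metric."""
    out: dict[str, list[dict[str, object]]] = {}
    for network in networks:
        for metric in metrics:
            sub = metric_table[
                (metric_table["network"] == network) & (metric_table["metric"] == metric)
            ][["subject_id", "density", "value"]]
            results = rm_ancova(sub, cohort, design)
            out[f"{network}_{metric}"] = [r.as_dict() for r in results]
    return out


def run_pipeline(config: PipelineConfig) -> dict[str, object]:
    """Run every stage and write the report bundle under ``output_dir``.

    Idempotent for a fixed config: a second run rewrites byte-identical
    outputs.  On stage failure a FAILED marker naming the stage is written
    and the exception re-raised; outputs of completed stages are preserved.
    """
    config.validate()
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stage = "inputs"
    try:
        atlas = _load_atlas(config)
        cohort, morph = _inputs(config, atlas)
        cohort.to_csv(out_dir / "cohort.tsv", sep="\t", index=False, float_format="%.10g")

        stage = "metrics"
        msn_dir = None
        if config.write_msns:
            msn_dir = out_dir / "msn"
            msn_dir.mkdir(exist_ok=True)
        metric_table = compute_metric_table(
            morph,
            atlas,
            networks=config.networks,
            densities=config.densities,
            compute_small_world=config.compute_small_world,
            n_null=config.n_null,
            seed=config.seed,
            msn_dir=msn_dir,
        )
        metric_table.to_csv(
            out_dir / "metrics.tsv", sep="\t", index=False, float_format="%.10g"
        )

        stage = "analyze"
        ancova = analyze_metrics(metric_table, cohort, config.design)
        (out_dir / "ancova.json").write_text(json.dumps(ancova, indent=2, sort_keys=True))

        stage = "demographics"
        demo = demographics_table(cohort)
        demo.to_csv(out_dir / "demographics.tsv", sep="\t", index=False, float_format="%.10g")

        stage = "manifest"
        manifest = {
            "config_sha256": config.config_hash(),
            "seed": config.seed,
            "n_subjects": int(cohort.shape[0]),
            "densities": list(config.densities),
            "versions": {
                "msnpipe": msnpipe.__version__,
                "numpy": np.__version__,
                "pandas": pd.__version__,
                "scipy": scipy.__version__,
                "statsmodels": statsmodels.__version__,
            },
        }
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    except Exception as err:
        (out_dir / "FAILED").write_text(f"stage: {stage}\nerror: {err}\n")
        raise
    failed = out_dir / "FAILED"
    if failed.exists():
        failed.unlink()
    return {
        "output_dir": out_dir,
        "cohort": cohort,
        "metrics": metric_table,
        "ancova": ancova,
        "demographics": demo,
        "manifest": manifest,
    }
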