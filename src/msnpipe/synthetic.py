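"""Synthetic dementia cohorts with network-localized morphometric effects.

Emulates a two-diagnosis cohort (DAT, dementia of the Alzheimer's type;
bvFTD, behavioural variant frontotemporal dementia) with the demographic
and clinical structure of a typical multi-site study: per-group age,
education, dementia severity (CDR-SB), MRI-to-questionnaire interval,
intracranial volume, sex, scanner make, and an NPI-Q-style disinhibition
item (presence + severity 1-3).

Regional morphometrics are generated from a documented additive model.
Each region r of subject s gets the 7-feature vector

    x_sr = iid_archetype_r
           + A * (cos(phi_r) * u1 + sin(phi_r) * u2)       (archetype gradient)
           + lam_g * (cos(theta_r) * g1_s + sin(theta_r) * g2_s)   (subject gradient)
           + lam_f * (1 - a) * z_s,net(r)            (functional-network latent)
           + lam_c * (1 - a) * c_s,comp(r)           (composite SN/CCN latent)
           + noise.

The archetype terms are fixed per region and shared by all subjects; the
archetype gradient emulates the smooth spatial autocorrelation of cortical
features.  Its phase ``phi_r`` advances along each hemisphere and wraps
several full cycles (left/right twin regions share the same phase, giving
the strong homotopic similarity of real morphometric networks), so that
*any* contiguous subset of parcels — in particular each analyzed
subnetwork — spans the full phase circle: spatial neighbours and
contralateral twins correlate strongly, distant parcels decorrelate, and
proportional thresholding retains a banded, connected, subject-stable
backbone at the densities the analysis uses (0.25 and up).  The subject
gradient (one slow sweep per hemisphere, factors ``g1, g2`` redrawn per
subject) adds smooth individual variation on top.  ``z_s,net`` is a
subject-level latent shared by all regions of one functional network and
``c_s,comp`` one shared by all regions of a composite analysis network
(all 62 SN regions; all 73 CCN regions); together they add the long-range
within-network similarity that an effect rule attenuates (``a`` in [0, 1])
for matching subjects.  Attenuation therefore removes long-range
within-network "shortcut" edges — lowering expected within-network
similarity and thresholded-graph efficiency and clustering — without
touching the spatial backbone or any other network.  Raw features are
emitted on realistic per-feature scales (mm^3, mm^2, mm, dimensionless);
the affine rescaling is removed again by feature standardization during
MSN construction.  Note that any component constant across *all* regions
would be removed by the cross-region feature standardization, which is why
similarity is carried by region-varying loadings and region-subset latents
rather than a brain-wide term.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from msnpipe.atlas import ParcelAtlas, SN_DEFINITION, CCN_DEFINITION
from msnpipe.errors import ConfigurationError, ValidationError
from msnpipe.msn import FEATURES

DIAGNOSES = ("DAT", "bvFTD")

#: Per-feature (location, scale) used to place features on realistic units:
#: GM volume mm^3, surface area mm^2, thickness mm, curvatures and folding
#: indices dimensionless.
FEATURE_SCALES: Mapping[str, tuple[float, float]] = {
    "gm_volume": (5500.0, 600.0),
    "surface_area": (1800.0, 200.0),
    "cortical_thickness": (2.5, 0.12),
    "intrinsic_curvature": (0.15, 0.02),
    "mean_curvature": (0.13, 0.015),
    "curved_index": (3.0, 0.4),
    "folding_index": (15.0, 2.0),
}


@dataclass(frozen=True)
class CovariateSpec:
    """Per-group mean/SD pairs for the continuous covariates."""

    age: tuple[float, float]
    education: tuple[float, float]
    cdr_sb: tuple[float, float]
    tiv: tuple[float, float]
    days_mri_npiq: tuple[float, float]


@dataclass(frozen=True)
class Effect:
    """A network-localized similarity attenuation for a subject subgroup.

    ``network`` is "SN", "CCN" or a functional-network label; ``subgroup``
    is "disinhibition", "DAT" or "bvFTD"; ``attenuation`` in [0, 1] scales
    down the network-shared latent for matching subjects.
    """

    network: str
    subgroup: str
    attenuation: float


# Cohort-table defaults mirror the demographic profile of a 111 DAT + 75
# bvFTD multi-site dementia sample (means/SDs, disinhibition prevalence,
# scanner mix).  TIV has no tabulated reference; a typical adult value is
# used.
_DEFAULT_COVARIATES = {
    "DAT": CovariateSpec(
        age=(74.15, 7.53),
        education=(15.24, 3.31),
        cdr_sb=(5.38, 2.58),
        tiv=(1_450_000.0, 150_000.0),
        days_mri_npiq=(14.01, 55.81),
    ),
    "bvFTD": CovariateSpec(
        age=(64.46, 7.03),
        education=(16.05, 3.10),
        cdr_sb=(8.16, 3.94),
        tiv=(1_450_000.0, 150_000.0),
        days_mri_npiq=(4.03, 25.47),
    ),
}

_DEFAULT_DISINHIBITION_RATE = {"DAT": 27 / 111, "bvFTD": 62 / 75}
_DEFAULT_SEX_MALE_RATE = {"DAT": 68 / 111, "bvFTD": 51 / 75}
_DEFAULT_SCANNER_PROPS = {
    "DAT": (59 / 111, 32 / 111, 20 / 111),
    "bvFTD": (61 / 75, 14 / 75, 0.0),
}
#: Severity distribution over {1, 2, 3} among disinhibited subjects,
#: proportional to the bvFTD severity profile 15/27/20.
_DEFAULT_SEVERITY_PROBS = (15 / 62, 27 / 62, 20 / 62)

SCANNERS = ("Siemens", "GE", "Philips")


@dataclass(frozen=True)
class SimulationConfig:
    """Full description of one synthetic study; the seed determines everything."""

    n_dat: int = 111
    n_bvftd: int = 75
    disinhibition_rate_by_group: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_DISINHIBITION_RATE)
    )
    severity_probs: tuple[float, float, float] = _DEFAULT_SEVERITY_PROBS
    covariates: Mapping[str, CovariateSpec] = field(
        default_factory=lambda: dict(_DEFAULT_COVARIATES)
    )
    sex_male_rate_by_group: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_SEX_MALE_RATE)
    )
    scanner_props_by_group: Mapping[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_SCANNER_PROPS)
    )
    effect_map: tuple[Effect, ...] = ()
    archetype_sd: float = 0.25
    archetype_gradient_scale: float = 2.0
    archetype_wraps: int = 6
    gradient_scale: float = 0.25
    network_latent_scale: float = 0.5
    composite_latent_scale: float = 0.7
    noise_sd: float = 0.2
    n_regions: int = 360
    n_features: int = 7
    seed: int = 0

    def validate(self) -> None:
        if self.n_dat < 0 or self.n_bvftd < 0:
            raise ConfigurationError("group sizes must be non-negative")
        if self.n_dat + self.n_bvftd == 0:
            raise ConfigurationError("cohort must contain at least one subject")
        for grp, rate in self.disinhibition_rate_by_group.items():
            if not 0 <= rate <= 1:
                raise ConfigurationError(f"disinhibition rate for {grp} outside [0, 1]: {rate}")
        if abs(sum(self.severity_probs) - 1) > 1e-9 or min(self.severity_probs) < 0:
            raise ConfigurationError("severity_probs must be a distribution over {1,2,3}")
        for eff in self.effect_map:
            if not 0 <= eff.attenuation <= 1:
                raise ConfigurationError(f"attenuation outside [0, 1]: {eff}")
        if self.noise_sd <= 0:
            raise ConfigurationError("noise_sd must be positive")
        if self.n_features != len(FEATURES):
            raise ConfigurationError(f"n_features must be {len(FEATURES)}")


def _stream(seed: int, *key: int) -> np.random.Generator:
    """Deterministic sub-stream; per-subject keys derive from the subject id
    so generation is independent of cohort order."""
    return np.random.default_rng(np.random.SeedSequence([seed, *key]))


def _subject_key(subject_id: str) -> int:
    return zlib.crc32(subject_id.encode())


def generate_cohort(config: SimulationConfig) -> pd.DataFrame:
    """Draw the cohort table: one row per subject with diagnosis,
    disinhibition presence/severity and all model covariates."""
    config.validate()
    rng = _stream(config.seed, 0)
    rows = []
    counts = {"DAT": config.n_dat, "bvFTD": config.n_bvftd}
    idx = 0
    for diagnosis in DIAGNOSES:
        spec = config.covariates[diagnosis]
        p_dis = config.disinhibition_rate_by_group[diagnosis]
        p_male = config.sex_male_rate_by_group[diagnosis]
        scanner_p = np.asarray(config.scanner_props_by_group[diagnosis], dtype=float)
        scanner_p = scanner_p / scanner_p.sum()
        for _ in range(counts[diagnosis]):
            idx += 1
            disinhibited = bool(rng.random() < p_dis)
            severity = int(rng.choice([1, 2, 3], p=config.severity_probs)) if disinhibited else 0
            rows.append(
                {
                    "subject_id": f"sub-{idx:04d}",
                    "diagnosis": diagnosis,
                    "disinhibition_present": disinhibited,
                    "disinhibition_severity": severity,
                    "age": float(np.clip(rng.normal(*spec.age), 40.0, 100.0)),
                    "sex": "M" if rng.random() < p_male else "F",
                    "education": float(np.clip(rng.normal(*spec.education), 6.0, 24.0)),
                    "cdr_sb": float(np.clip(rng.normal(*spec.cdr_sb), 0.0, 18.0)),
                    "tiv": float(np.clip(rng.normal(*spec.tiv), 9e5, 2.2e6)),
                    "days_mri_npiq": float(rng.normal(*spec.days_mri_npiq)),
                    "scanner": str(rng.choice(SCANNERS, p=scanner_p)),
                }
            )
    return pd.DataFrame(rows)


def _network_labels(atlas: ParcelAtlas) -> tuple[np.ndarray, list[str]]:
    labels = atlas.table["functional_network"].to_numpy()
    uniq = sorted(set(labels))
    codes = np.array([uniq.index(v) for v in labels])
    return codes, uniq


_COMPOSITE = {
    "SN": SN_DEFINITION.member_networks,
    "CCN": CCN_DEFINITION.member_networks,
}


def _attenuation_for(
    subject: Mapping[str, object], label: str, effects: Sequence[Effect]
) -> float:
    """Largest configured attenuation applying to this subject and label."""
    a = 0.0
    for eff in effects:
        members = _COMPOSITE.get(eff.network, frozenset({eff.network}))
        if label in members and _subgroup_matches(subject, eff.subgroup):
            a = max(a, eff.attenuation)
    return a


def _subgroup_matches(subject: Mapping[str, object], subgroup: str) -> bool:
    if subgroup == "disinhibition":
        return bool(subject["disinhibition_present"])
    if subgroup in DIAGNOSES:
        return subject["diagnosis"] == subgroup
    raise ConfigurationError(f"unknown effect subgroup: {subgroup!r}")


def _attenuation_for_composite(
    subject: Mapping[str, object], composite: str, effects: Sequence[Effect]
) -> float:
    """Largest attenuation targeting this composite network for this subject."""
    a = 0.0
    for eff in effects:
        if eff.network == composite and _subgroup_matches(subject, eff.subgroup):
            a = max(a, eff.attenuation)
    return a


def generate_morphometry(
    cohort: pd.DataFrame, atlas: ParcelAtlas, config: SimulationConfig
) -> pd.DataFrame:
    """Generate per-subject regional morphometrics in long format.

    Returns a table with ``subject_id``, ``region_id`` and the 7 feature
    columns; exactly ``n_regions`` rows per subject, no missing values.
    """
    config.validate()
    if cohort.empty:
        raise ValidationError("cohort is empty")
    if len(atlas.region_ids) != config.n_regions:
        raise ValidationError(
            f"atlas has {len(atlas.region_ids)} regions but config expects {config.n_regions}"
        )
    p = config.n_features
    codes, uniq = _network_labels(atlas)
    labels = atlas.table["functional_network"].to_numpy()
    composite_members = {
        name: np.isin(labels, list(members)) for name, members in _COMPOSITE.items()
    }
    # Region archetypes are a property of the study, not of any subject.
    hemis = atlas.table["hemisphere"].to_numpy()
    t_pos = np.zeros(config.n_regions)  # 0..1 along each hemisphere; twins share it
    for h in np.unique(hemis):
        idx = np.nonzero(hemis == h)[0]
        t_pos[idx] = np.arange(idx.size) / max(idx.size - 1, 1)
    arch_rng = _stream(config.seed, 1)
    archetypes = arch_rng.normal(0.0, config.archetype_sd, size=(config.n_regions, p))
    u1 = arch_rng.normal(0.0, 1.0, size=p)
    u2 = arch_rng.normal(0.0, 1.0, size=p)
    phi = 2.0 * np.pi * config.archetype_wraps * t_pos
    archetypes += config.archetype_gradient_scale * (
        np.cos(phi)[:, None] * u1[None, :] + np.sin(phi)[:, None] * u2[None, :]
    )

    loc = np.array([FEATURE_SCALES[f][0] for f in FEATURES])
    scale = np.array([FEATURE_SCALES[f][1] for f in FEATURES])

    theta = np.pi * t_pos  # subject-gradient position: one slow sweep per hemisphere

    frames = []
    for subject in cohort.to_dict("records"):
        rng = _stream(config.seed, 2, _subject_key(str(subject["subject_id"])))
        x = archetypes.copy()
        g1 = rng.normal(0.0, 1.0, size=p)
        g2 = rng.normal(0.0, 1.0, size=p)
        x += config.gradient_scale * (
            np.cos(theta)[:, None] * g1[None, :] + np.sin(theta)[:, None] * g2[None, :]
        )
        for li, label in enumerate(uniq):
            z = rng.normal(0.0, 1.0, size=p) * config.network_latent_scale
            a = _attenuation_for(subject, label, config.effect_map)
            x[codes == li] += (1.0 - a) * z[None, :]
        for name, mask in composite_members.items():
            c = rng.normal(0.0, 1.0, size=p) * config.composite_latent_scale
            a = _attenuation_for_composite(subject, name, config.effect_map)
            x[mask] += (1.0 - a) * c[None, :]
        x = x + rng.normal(0.0, config.noise_sd, size=x.shape)
        frame = pd.DataFrame(loc + scale * x, columns=list(FEATURES))
        frame.insert(0, "region_id", atlas.region_ids)
        frame.insert(0, "subject_id", subject["subject_id"])
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)


def subject_tables(morphometry: pd.DataFrame) -> Iterator[tuple[str, pd.DataFrame]]:
    """Iterate (subject_id, per-subject morphometric table) in cohort order."""
    for sid, frame in morphometry.groupby("subject_id", sort=False):
        yield str(sid), frame.drop(columns="subject_id").reset_index(drop=True)


def null_config(**overrides: object) -> SimulationConfig:
    """Convenience: the default study with no injected network effects."""
    return replace(SimulationConfig(), effect_map=(), **overrides)  # type: ignore[arg-type]
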