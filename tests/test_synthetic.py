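import numpy as np
import pytest
from scipy import stats as sps

from msnpipe.atlas import CCN_DEFINITION
from msnpipe.errors import ConfigurationError
from msnpipe.msn import FEATURES, build_msn, extract_subnetwork
from msnpipe.synthetic import (
    Effect,
    SimulationConfig,
    generate_cohort,
    generate_morphometry,
    subject_tables,
)


def mean_within_network_similarity(morph, atlas, nodes) -> list[float]:
    out = []
    for _, table in subject_tables(morph):
        sub = extract_subnetwork(build_msn(table), nodes)
        iu = np.triu_indices(len(nodes), 1)
        out.append(float(sub.weights[iu].mean()))
    return out


class TestCohort:
    def test_group_sizes_and_invariants(self):
        cohort = generate_cohort(SimulationConfig(n_dat=111, n_bvftd=75, seed=3))
        assert len(cohort) == 186
        assert (cohort.diagnosis == "DAT").sum() == 111
        assert (cohort.diagnosis == "bvFTD").sum() == 75
        assert (cohort.disinhibition_present == (cohort.disinhibition_severity >= 1)).all()
        assert cohort.disinhibition_severity.isin([0, 1, 2, 3]).all()
        assert (cohort.age > 0).all() and (cohort.tiv > 0).all()
        assert cohort.scanner.isin(["Siemens", "GE", "Philips"]).all()

    def test_zero_rate_means_no_disinhibition(self):
        cfg = SimulationConfig(
            n_dat=30, n_bvftd=30, seed=1, disinhibition_rate_by_group={"DAT": 0, "bvFTD": 0}
        )
        cohort = generate_cohort(cfg)
        assert not cohort.disinhibition_present.any()
        assert (cohort.disinhibition_severity == 0).all()

    def test_byte_identical_under_same_seed(self):
        cfg = SimulationConfig(n_dat=20, n_bvftd=20, seed=9)
        a = generate_cohort(cfg).to_csv(index=False)
        b = generate_cohort(cfg).to_csv(index=False)
        assert a == b

    def test_covariate_marginals_match_config(self):
        cfg = SimulationConfig(n_dat=120, n_bvftd=120, seed=5)
        cohort = generate_cohort(cfg)
        for grp in ("DAT", "bvFTD"):
            sub = cohort[cohort.diagnosis == grp]
            for var in ("age", "education", "cdr_sb"):
                mean, sd = getattr(cfg.covariates[grp], var)
                se = sd / np.sqrt(len(sub))
                assert abs(sub[var].mean() - mean) < 3 * se

    def test_invalid_configs_rejected(self):
        with pytest.raises(ConfigurationError):
            generate_cohort(SimulationConfig(n_dat=-1))
        with pytest.raises(ConfigurationError):
            generate_cohort(
                SimulationConfig(disinhibition_rate_by_group={"DAT": 1.5, "bvFTD": 0.5})
            )
        with pytest.raises(ConfigurationError):
            SimulationConfig(effect_map=(Effect("CCN", "disinhibition", 2.0),)).validate()


class TestMorphometry:
    def test_shape_and_no_missing_values(self, atlas):
        cfg = SimulationConfig(n_dat=2, n_bvftd=1, seed=0)
        cohort = generate_cohort(cfg)
        morph = generate_morphometry(cohort, atlas, cfg)
        assert len(morph) == 3 * 360
        assert not morph[list(FEATURES)].isna().any().any()
        per_subject = morph.groupby("subject_id").size()
        assert (per_subject == 360).all()
        # non-zero variance in every feature column, per subject
        for _, table in subject_tables(morph):
            assert (table[list(FEATURES)].std() > 0).all()

    def test_subject_stream_independent_of_cohort_order(self, atlas):
        cfg = SimulationConfig(n_dat=3, n_bvftd=2, seed=4)
        cohort = generate_cohort(cfg)
        morph_fwd = generate_morphometry(cohort, atlas, cfg)
        morph_rev = generate_morphometry(cohort.iloc[::-1], atlas, cfg)
        one_fwd = morph_fwd[morph_fwd.subject_id == "sub-0002"].reset_index(drop=True)
        one_rev = morph_rev[morph_rev.subject_id == "sub-0002"].reset_index(drop=True)
        assert one_fwd.equals(one_rev)

    def test_null_attenuation_gives_exchangeable_groups(self, atlas):
        """With no injected effect, disinhibited and spared subjects have the
        same within-CCN similarity distribution (two-sample test rarely
        rejects across seeds)."""
        nodes = atlas.network_nodes(CCN_DEFINITION)
        rejections = 0
        n_seeds = 8
        for seed in range(n_seeds):
            cfg = SimulationConfig(
                n_dat=8,
                n_bvftd=8,
                seed=seed,
                disinhibition_rate_by_group={"DAT": 0.5, "bvFTD": 0.5},
            )
            cohort = generate_cohort(cfg)
            sims = np.array(
                mean_within_network_similarity(generate_morphometry(cohort, atlas, cfg), atlas, nodes)
            )
            dis = cohort.disinhibition_present.to_numpy()
            if dis.sum() >= 2 and (~dis).sum() >= 2:
                p = sps.ttest_ind(sims[dis], sims[~dis]).pvalue
                rejections += p < 0.05
        assert rejections <= 2

    def test_attenuation_lowers_within_network_similarity(self, atlas):
        nodes = atlas.network_nodes(CCN_DEFINITION)
        lower = 0
        n_seeds = 10
        for seed in range(n_seeds):
            cfg = SimulationConfig(
                n_dat=6,
                n_bvftd=6,
                seed=seed,
                disinhibition_rate_by_group={"DAT": 0.5, "bvFTD": 0.5},
                effect_map=(Effect("CCN", "disinhibition", 0.5),),
            )
            cohort = generate_cohort(cfg)
            sims = np.array(
                mean_within_network_similarity(generate_morphometry(cohort, atlas, cfg), atlas, nodes)
            )
            dis = cohort.disinhibition_present.to_numpy()
            if dis.any() and (~dis).any():
                lower += sims[dis].mean() < sims[~dis].mean()
        assert lower >= round(0.95 * n_seeds) - 1  # allow one seed off at tiny n

    def test_attenuation_monotone_in_expectation(self, atlas):
        """Stronger attenuation never raises mean within-network similarity."""
        nodes = atlas.network_nodes(CCN_DEFINITION)
        means = []
        for atten in (0.0, 0.4, 0.8):
            per_seed = []
            for seed in range(5):
                cfg = SimulationConfig(
                    n_dat=4,
                    n_bvftd=0,
                    seed=seed,
                    disinhibition_rate_by_group={"DAT": 1.0, "bvFTD": 1.0},
                    effect_map=(Effect("CCN", "disinhibition", atten),),
                )
                cohort = generate_cohort(cfg)
                per_seed.extend(
                    mean_within_network_similarity(
                        generate_morphometry(cohort, atlas, cfg), atlas, nodes
                    )
                )
            means.append(np.mean(per_seed))
        assert means[0] > means[1] > means[2]

    def test_noise_free_limit_shares_archetype_table(self, atlas):
        cfg = SimulationConfig(
            n_dat=2,
            n_bvftd=0,
            seed=11,
            noise_sd=1e-12,
            gradient_scale=0.0,
            network_latent_scale=0.0,
            composite_latent_scale=0.0,
        )
        cohort = generate_cohort(cfg)
        morph = generate_morphometry(cohort, atlas, cfg)
        tables = [t[list(FEATURES)].to_numpy() for _, t in subject_tables(morph)]
        np.testing.assert_allclose(tables[0], tables[1], atol=1e-6)

    def test_region_mismatch_rejected(self, atlas):
        cfg = SimulationConfig(n_dat=1, n_bvftd=0, seed=0, n_regions=100)
        cohort = generate_cohort(cfg)
        with pytest.raises(Exception, match="regions"):
            generate_morphometry(cohort, atlas, cfg)
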