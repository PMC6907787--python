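"""Tests of the synthetic-study generator against its recorded ground truth."""

import numpy as np
import pandas as pd
import pytest

from vaxbiome import abundance, diversity, immuno, simulate
from vaxbiome.errors import ConfigError


def test_same_seed_identical_tables(default_study):
    cfg, (counts, samples, taxonomy, truth) = default_study
    counts2, samples2, taxonomy2, truth2 = simulate.simulate_study(
        simulate.SimConfig(seed=42)
    )
    pd.testing.assert_frame_equal(counts, counts2)
    pd.testing.assert_frame_equal(taxonomy, taxonomy2)
    pd.testing.assert_frame_equal(truth.expected_composition, truth2.expected_composition)


def test_study_shape_and_truth_invariants(default_study):
    cfg, (counts, samples, taxonomy, truth) = default_study
    # 5 groups x 6 mice x 6 weeks + RB 5 mice x 8 weeks fecal; one cecal per mouse
    fecal = samples[samples["sample_type"] == "fecal"]
    assert len(fecal) == 5 * 6 * 6 + 5 * 8
    assert len(samples[samples["sample_type"] == "cecal"]) == 35
    assert not counts.index.duplicated().any()
    assert (counts.to_numpy() >= 0).all()
    np.testing.assert_allclose(truth.expected_composition.sum(axis=1), 1.0, atol=1e-9)
    rb_weeks = set(samples.loc[samples["treatment"] == "RB", "week"])
    assert {-1, 12} <= rb_weeks
    assert set(taxonomy.columns) == set(simulate.RANKS)
    # Firmicutes + Bacteroidetes dominate the lineage vocabulary
    top = taxonomy["phylum"].value_counts(normalize=True)
    assert top[["Firmicutes", "Bacteroidetes"]].sum() > 0.6


def test_depth_distribution(default_study):
    cfg, (counts, samples, _, _) = default_study
    sums = counts.sum(axis=1).to_numpy()[:100]
    sd = cfg.mean_depth * np.sqrt(np.exp(cfg.depth_dispersion**2) - 1.0)
    assert (np.abs(sums - cfg.mean_depth) < 5 * sd).all()


def test_degenerate_no_noise_converges_to_shared_composition():
    """mouse_sd=0, infinite concentration, flat trends: one composition per
    treatment, and sample proportions converge to it with depth."""
    flat = {t: (0.0, 0.0, 0.0, 0.0) for t in simulate.DEFAULT_TREATMENTS}
    cfg = simulate.SimConfig(
        seed=3, n_otus=60, mouse_sd=0.0, overdispersion=np.inf,
        trend_coefficients=flat, richness_mask_coefficients=flat,
        depth_dispersion=0.0, include_cecal=False,
        mice_per_group={t: 2 for t in simulate.DEFAULT_TREATMENTS},
    )
    counts, samples, _, truth = simulate.simulate_study(cfg)
    comp = truth.expected_composition
    for t, group in samples.groupby("treatment"):
        rows = comp.loc[group.index].to_numpy()
        assert np.allclose(rows, rows[0], atol=1e-12)
    props = counts.div(counts.sum(axis=1), axis=0).to_numpy()
    tv = 0.5 * np.abs(props - comp.to_numpy()).sum(axis=1)
    assert tv.mean() < 0.02  # depth 4e4 default is not needed; 5e3+ suffices at TV 0.02
    assert tv[:20].max() < 0.05


def test_dirichlet_multinomial_large_concentration_tv():
    cfg = simulate.SimConfig(
        seed=9, n_otus=100, overdispersion=1e9, mouse_sd=0.0,
        mice_per_group={t: 2 for t in simulate.DEFAULT_TREATMENTS},
        include_cecal=False, depth_dispersion=0.0,
    )
    counts, samples, _, truth = simulate.simulate_study(cfg)
    props = counts.div(counts.sum(axis=1), axis=0).to_numpy()[:20]
    expected = truth.expected_composition.to_numpy()[:20]
    tv = 0.5 * np.abs(props - expected).sum(axis=1)
    assert (tv < 0.02).all()


def test_masked_group_has_lower_observed_richness():
    """A group with 30% of OTUs masked shows lower mean observed richness
    than every other group at every shared week, over 20 replicates."""
    masks = {t: (0.0, 0.0, 0.0, 0.0) for t in simulate.DEFAULT_TREATMENTS}
    masks["RB"] = (0.3, 0.0, 0.0, 0.0)
    per_week_means = []
    for rep in range(20):
        cfg = simulate.SimConfig(
            seed=100 + rep, n_otus=100, mean_depth=4000,
            mice_per_group={t: 2 for t in simulate.DEFAULT_TREATMENTS},
            richness_mask_coefficients=masks, include_cecal=False,
            rb_extra_weeks=(),
        )
        counts, samples, _, _ = simulate.simulate_study(cfg)
        alpha = diversity.alpha_table(counts)
        joined = samples.join(alpha)
        per_week_means.append(
            joined.groupby(["treatment", "week"])["observed"].mean()
        )
    mean_over_reps = pd.concat(per_week_means, axis=1).mean(axis=1)
    for week in (0, 2, 4, 6, 8, 10):
        rb = mean_over_reps["RB", week]
        for t in simulate.DEFAULT_TREATMENTS:
            if t != "RB":
                assert rb < mean_over_reps[t, week]


def test_config_validation_errors():
    with pytest.raises(ConfigError):
        simulate.simulate_study(simulate.SimConfig(mean_depth=-1))
    with pytest.raises(ConfigError):
        simulate.simulate_study(simulate.SimConfig(weeks=()))
    with pytest.raises(ConfigError):
        simulate.SimConfig(spurious_max_count=-2).validate()


# ---------------------------------------------------------------- mock
def test_mock_spurious_bounds_and_determinism(small_config):
    cfg = simulate.SimConfig(
        seed=5, n_otus=80, spurious_max_count=7,
        mice_per_group=small_config.mice_per_group,
    )
    mock, members = simulate.simulate_mock_samples(cfg)
    non_members = [c for c in mock.columns if c not in set(members)]
    assert mock[non_members].to_numpy().max() <= 7
    assert len(members) == cfg.mock_members
    mock2, members2 = simulate.simulate_mock_samples(cfg)
    pd.testing.assert_frame_equal(mock, mock2)
    assert members == members2

    clean, members3 = simulate.simulate_mock_samples(
        simulate.SimConfig(seed=5, n_otus=80, spurious_max_count=0)
    )
    non_members3 = [c for c in clean.columns if c not in set(members3)]
    assert (clean[non_members3].to_numpy() == 0).all()
    assert (clean[members3].sum(axis=0) > 0).all()


# ----------------------------------------------------------------- IgA
def test_iga_zero_for_groups_without_epitope(default_study):
    cfg, (_, _, _, truth) = default_study
    iga = simulate.simulate_iga(cfg, truth)
    assert (iga.loc[iga["treatment"].isin(["NG", "WT"]), "mper_iga"] == 0).all()
    assert "RB" not in set(iga["treatment"])
    # cecal samples carry no IgA rows at all
    assert not iga.index.str.endswith(".cecal").any()


def test_noiseless_iga_equals_stored_cubic_and_ls_recovery():
    cfg = simulate.SimConfig(seed=21, iga_noise_sd=0.0, iga_mouse_sd=50.0)
    _, _, _, truth = simulate.simulate_study(cfg)
    iga = simulate.simulate_iga(cfg, truth)
    x = iga["week"].map(cfg.scaled_week).to_numpy()
    for (t, mouse), sub in iga.groupby(["treatment", "mouse"]):
        coef = np.array(truth.iga_coefficients[t])
        xm = sub["week"].map(cfg.scaled_week).to_numpy()
        expected = np.vander(xm, 4, increasing=True) @ coef + truth.iga_mouse_intercepts[mouse]
        np.testing.assert_allclose(sub["total_iga"].to_numpy(), expected, atol=1e-9)
        # least-squares oracle on the cubic design recovers the coefficients
        fit, *_ = np.linalg.lstsq(np.vander(xm, 4, increasing=True),
                                  sub["total_iga"].to_numpy(), rcond=None)
        np.testing.assert_allclose(fit[1:], coef[1:], atol=1e-8)
        np.testing.assert_allclose(
            fit[0], coef[0] + truth.iga_mouse_intercepts[mouse], atol=1e-8
        )


# --------------------------------------------------------------- ELISA
def test_noiseless_plate_exact_and_deterministic():
    cfg = simulate.SimConfig(seed=13, elisa_noise_sd=0.0, elisa_neg_sd=0.0)
    plate = simulate.simulate_elisa_plate(cfg)
    # standards decrease by factor 10, duplicates equal
    levels = sorted(plate.standards["concentration"].unique(), reverse=True)
    assert np.allclose(np.diff(np.log10(levels)), -1.0)
    for sid, titer in plate.true_titer.items():
        if titer == 0:
            sub = plate.samples[plate.samples["sample_id"] == sid].sort_values("dilution")
            cutoff = immuno.positivity_cutoff(plate.negatives["NG"])
            assert not (sub.iloc[0]["od"] > cutoff)
    plate2 = simulate.simulate_elisa_plate(cfg)
    pd.testing.assert_frame_equal(plate.samples, plate2.samples)
    pd.testing.assert_frame_equal(plate.standards, plate2.standards)
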