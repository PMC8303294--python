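"""Generators: determinism, distributional calibration, planted structure."""

import numpy as np
import pandas as pd
import pytest

from fibromir import clustering, de, scoring, seeds, synthetic


# ----------------------------------------------------------------- determinism
def test_cohort_determinism():
    params = synthetic.CohortParams(seed=7)
    a = synthetic.generate_cohort(params)
    b = synthetic.generate_cohort(params)
    pd.testing.assert_frame_equal(a[0], b[0])
    pd.testing.assert_frame_equal(a[1], b[1])
    pd.testing.assert_series_equal(a[2].latent_fibrosis, b[2].latent_fibrosis)


def test_design_determinism():
    params = synthetic.DesignParams(seed=3)
    a = synthetic.generate_design(params)
    b = synthetic.generate_design(params)
    pd.testing.assert_frame_equal(a[0], b[0])


def test_ct_and_utr_determinism():
    t1 = synthetic.generate_ct_table(5, 1.5, 0.3, seed=2)
    t2 = synthetic.generate_ct_table(5, 1.5, 0.3, seed=2)
    pd.testing.assert_frame_equal(t1, t2)
    u1, _ = synthetic.generate_utr_with_sites(300, "UGAGGUAGUAGGUUGUAUAGUU", [(50, "8mer")], seed=4)
    u2, _ = synthetic.generate_utr_with_sites(300, "UGAGGUAGUAGGUUGUAUAGUU", [(50, "8mer")], seed=4)
    assert u1 == u2


# ------------------------------------------------------------------ validation
def test_cohort_parameter_errors():
    with pytest.raises(ValueError):
        synthetic.generate_cohort(synthetic.CohortParams(depth=0))
    with pytest.raises(ValueError):
        synthetic.generate_cohort(synthetic.CohortParams(dispersion=-0.1))
    with pytest.raises(ValueError):
        synthetic.generate_cohort(
            synthetic.CohortParams(n_mirnas=10, n_fibromirs=8, n_myomirs=8)
        )


def test_design_parameter_errors():
    with pytest.raises(ValueError):
        synthetic.generate_design(synthetic.DesignParams(archetype_counts={"C9": 3}))
    with pytest.raises(ValueError):
        synthetic.generate_design(synthetic.DesignParams(n_replicates=0))
    with pytest.raises(ValueError):
        synthetic.generate_ct_table(3, 1.0, noise_sd=-1.0)


# --------------------------------------------------------------- cohort shape
def test_cohort_shapes_and_truth(small_cohort):
    params, counts, markers, truth = small_cohort
    n = params.n_control + params.n_dmd
    assert counts.shape == (params.n_mirnas, n)
    assert markers.shape == (n, 3)
    assert (counts.to_numpy() >= 0).all()
    assert counts.to_numpy().dtype.kind in "iu"
    assert truth.mirna_class.value_counts()["fibromiR"] == params.n_fibromirs
    assert truth.mirna_class.value_counts()["myomiR"] == params.n_myomirs
    assert (truth.latent_fibrosis >= 0).all()
    # controls are all Low; the planted DMD split is exactly 3 Low / 5 High
    dmd = truth.planted_stratum[truth.group == "DMD"]
    assert dmd.value_counts().to_dict() == {"High": 5, "Low": 3}
    assert (truth.planted_stratum[truth.group == "control"] == "Low").all()


@pytest.mark.parametrize("mu, alpha", [(80.0, 0.2), (15.0, 0.05), (200.0, 0.0)])
def test_nb_moments_match_parameterisation(rng, mu, alpha):
    """Empirical mean/variance of the count law match mu and mu + alpha*mu^2."""
    draws = synthetic._nb_draws(rng, np.full(10_000, mu), alpha)
    se_mean = np.sqrt((mu + alpha * mu**2) / 10_000)
    assert draws.mean() == pytest.approx(mu, abs=5 * se_mean)
    assert draws.var() == pytest.approx(mu + alpha * mu**2, rel=0.10)
    assert (draws >= 0).all()


def test_beta_zero_decouples_mirnas_from_fibrosis():
    """With beta=0 the planted miRNAs are uncorrelated with latent fibrosis."""
    rs = []
    for s in range(200):
        params = synthetic.CohortParams(
            n_control=12, n_dmd=12, n_mirnas=40, n_fibromirs=5, n_myomirs=5,
            beta=0.0, seed=s,
        )
        counts, _, truth = synthetic.generate_cohort(params)
        log_expr = np.log2(counts.iloc[:10] + 1.0)
        f = truth.latent_fibrosis.to_numpy()
        for row in log_expr.to_numpy():
            if row.std() > 0:
                rs.append(np.corrcoef(row, f)[0, 1])
    assert abs(np.mean(rs)) < 0.05


def test_planted_fibromirs_correlate_with_score():
    """beta=2, dispersion=0.05, 12+12 samples: >=90% of fibromiRs reach r > 0.5."""
    fracs = []
    for s in range(20):
        params = synthetic.CohortParams(
            n_control=12, n_dmd=12, beta=2.0, dispersion=0.05, seed=s
        )
        counts, markers, truth = synthetic.generate_cohort(params)
        fs = scoring.fibrotic_score(markers)
        log_expr = np.log2(de.normalize_counts(counts) + 1.0)
        table = scoring.correlate_with_score(log_expr, fs)
        planted = truth.mirna_class.index[truth.mirna_class == "fibromiR"]
        fracs.append((table.loc[planted, "r"] > 0.5).mean())
    assert np.mean(fracs) >= 0.9


# --------------------------------------------------------------------- design
def test_design_shapes_and_conditions(small_design):
    params, counts, truth = small_design
    assert counts.shape[1] == 4 * params.n_replicates
    assert set(truth.condition.unique()) == set(clustering.CONDITIONS)
    assert counts.shape[0] == sum(params.archetype_counts.values())


def test_null_design_is_unclassified():
    """All-background designs leave >=95% of miRNAs unclassified."""
    params = synthetic.DesignParams(
        archetype_counts={"C1": 0, "C2": 0, "C3": 0, "C4": 0, "background": 200}, seed=21
    )
    counts, truth = synthetic.generate_design(params)
    mean_expr = de.normalize_counts(counts).T.groupby(truth.condition).mean().T
    calls = clustering.classify_archetype(mean_expr)
    assert (calls["class"] == "unclassified").mean() >= 0.95


def test_planted_archetypes_recovered():
    """Default effect sizes: >=90% of each planted class classified correctly."""
    params = synthetic.DesignParams(seed=2)
    counts, truth = synthetic.generate_design(params)
    mean_expr = de.normalize_counts(counts).T.groupby(truth.condition).mean().T
    calls = clustering.classify_archetype(mean_expr)
    for cls in ("C1", "C2", "C3", "C4"):
        idx = truth.mirna_class.index[truth.mirna_class == cls]
        assert (calls.loc[idx, "class"] == cls).mean() >= 0.9


# ------------------------------------------------------------------------ UTR
def test_planted_sites_recovered_exactly():
    mirna = "UGAGGUAGUAGGUUGUAUAGUU"
    utr, truth = synthetic.generate_utr_with_sites(
        400, mirna, planted=[(10, "8mer"), (200, "6mer")], seed=13
    )
    found = [(s.start, s.site_type) for s in seeds.seed_sites(mirna, utr)]
    assert found == [(10, "8mer"), (200, "6mer")]
    assert list(truth["start"]) == [10, 200]


def test_plant_none_scans_clean():
    mirna = "UGAGGUAGUAGGUUGUAUAGUU"
    utr, truth = synthetic.generate_utr_with_sites(500, mirna, planted=[], seed=1)
    assert seeds.seed_sites(mirna, utr) == []
    assert truth.empty


def test_impossible_placement_rejected():
    mirna = "UGAGGUAGUAGGUUGUAUAGUU"
    with pytest.raises(ValueError):
        synthetic.generate_utr_with_sites(100, mirna, planted=[(98, "8mer")])
    with pytest.raises(ValueError):
        synthetic.generate_utr_with_sites(100, mirna, planted=[(10, "8mer"), (12, "6mer")])
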