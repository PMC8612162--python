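"""Generators: determinism, zero-noise exactness, printed-scale contrasts."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from ribotraits import allometry, qpcr, synthetic, variants
from ribotraits.errors import InsufficientDataError, InvalidInputError
from ribotraits.phenotype import Stage


def test_generators_are_seed_deterministic(steinii):
    a = synthetic.gen_cells(steinii, n_per_stage=4, seed=3)
    b = synthetic.gen_cells(steinii, n_per_stage=4, seed=3)
    pd.testing.assert_frame_equal(a, b)
    c = synthetic.gen_dilution_series(seed=3)
    d = synthetic.gen_dilution_series(seed=3)
    pd.testing.assert_frame_equal(c, d)
    e = synthetic.gen_growth_dataset(0.022, -0.474, 1.821, noise_sd_log10=0.1, seed=3)
    f = synthetic.gen_growth_dataset(0.022, -0.474, 1.821, noise_sd_log10=0.1, seed=3)
    pd.testing.assert_frame_equal(e, f)
    va = synthetic.gen_variant_pool(steinii, substitution_error_rate=0.01, seed=3)
    vb = synthetic.gen_variant_pool(steinii, substitution_error_rate=0.01, seed=3)
    assert va == vb


def test_zero_noise_cells_lie_on_generating_laws(steinii):
    table = synthetic.gen_cells(steinii, n_per_stage=6, noise_sd_log10=0.0, seed=1)
    veg = table[table.stage != Stage.RESTING_CYST.value]
    fit = allometry.fit_power_law(veg.cell_volume, veg.rdna_cnpc)
    assert fit.slope == pytest.approx(steinii.rdna_fit.slope, abs=1e-10)
    assert fit.intercept == pytest.approx(steinii.rdna_fit.intercept, abs=1e-10)
    assert fit.r_squared == pytest.approx(1.0, abs=1e-12)
    rfit = allometry.fit_power_law(veg.cell_volume, veg.rrna_cnpc)
    assert rfit.slope == pytest.approx(steinii.rrna_fit.slope, abs=1e-10)
    mfit = allometry.fit_power_law(
        table.cell_volume, table.macronuclear_volume, response="MV"
    )
    assert mfit.slope == pytest.approx(steinii.mv_exponent, abs=1e-10)


def test_resting_cyst_rrna_collapse_matches_printed_contrast(inflata):
    # C. inflata at 18°C: log-phase rRNA ≈ 1.3e8 vs resting-cyst ≈ 3.1e4,
    # a ~4,200× contrast inside the stated 200–5,000× band
    quiet = dataclasses.replace(inflata, cv_log10_sd=0.0)
    table = synthetic.gen_cells(quiet, n_per_stage=3, noise_sd_log10=0.0, seed=0)
    log_rrna = table[table.stage == "log"].rrna_cnpc.mean()
    cyst_rrna = table[table.stage == "resting_cyst"].rrna_cnpc.mean()
    assert cyst_rrna == pytest.approx(3.1e4, rel=0.05)
    assert 200 <= log_rrna / cyst_rrna <= 5000


def test_population_sweep_recovers_fraction_within_suppression(steinii):
    from ribotraits.dormancy import cyst_fraction

    baseline = steinii.ratio_baseline()
    for f in (0.0, 0.25, 0.5, 0.75, 1.0):
        pool, true_f = synthetic.gen_population(
            steinii, 200, f, esd=18.0, noise_sd_log10=0.0, seed=0
        )
        assert true_f == f
        est = cyst_fraction(pool, baseline)
        assert abs(est.fraction - f) <= steinii.cyst_rrna_suppression + 1e-12


def test_dilution_series_noise_free_slope_is_ideal():
    df = synthetic.gen_dilution_series(true_efficiency=1.0, ct_noise_sd=0.0, seed=0)
    curve = qpcr.fit_standard_curve(df.log10_copies, df.ct)
    assert curve.slope == pytest.approx(-1.0 / np.log10(2.0), rel=1e-12)
    assert curve.efficiency == pytest.approx(1.0, abs=1e-12)


def test_dilution_series_requires_three_decades():
    with pytest.raises(InsufficientDataError):
        synthetic.gen_dilution_series(log10_copies=())


def test_noisy_dilution_series_keeps_printed_r_squared_band():
    # CT noise sd 0.1 over 5 decades, triplicate: R² ≥ 0.998 in ≥95/100 runs
    hits = 0
    for seed in range(100):
        df = synthetic.gen_dilution_series(ct_noise_sd=0.1, seed=seed)
        hits += qpcr.fit_standard_curve(df.log10_copies, df.ct).r_squared >= 0.998
    assert hits >= 95


def test_variant_pool_degenerate_profiles(steinii):
    lone = dataclasses.replace(steinii, variant_divergences=(), dominant_fraction=1.0)
    pool = synthetic.gen_variant_pool(lone, seed=0)
    assert len(pool.variants) == 1
    assert variants.dominant_proportion(pool) == 1.0


def test_variant_pool_error_singletons_inflate_apparent_divergence(steinii):
    # true max divergence 10% + 1% residual error → leveling at 0.89
    noisy = synthetic.gen_variant_pool(steinii, substitution_error_rate=0.01, seed=2)
    clean = synthetic.gen_variant_pool(steinii, substitution_error_rate=0.0, seed=2)
    lev_noisy, _ = variants.leveling_threshold(variants.threshold_scan(noisy))
    lev_clean, _ = variants.leveling_threshold(variants.threshold_scan(clean))
    assert lev_clean == pytest.approx(0.90)
    assert lev_noisy == pytest.approx(0.89)
    assert variants.corrected_divergence(
        lev_noisy, noisy.residual_error_rate
    ) == pytest.approx(0.10)


def test_growth_design_is_full_rank_and_spans_two_decades():
    design = synthetic.DEFAULT_GROWTH_DESIGN
    log_x = [d[1] for d in design]
    assert max(log_x) - min(log_x) >= 2.0
    data = synthetic.gen_growth_dataset(0.055, 0.206, -1.92)
    from ribotraits.growth_model import fit_growth_model

    fit = fit_growth_model(data.growth_rate, data.temperature, data.predictor, "CV")
    assert fit.coef_x == pytest.approx(0.206, rel=1e-10)


def test_power_law_sample_respects_range_and_seed():
    x1, y1 = synthetic.gen_power_law_sample(0.87, 3.67, n=50, seed=4)
    x2, _ = synthetic.gen_power_law_sample(0.87, 3.67, n=50, seed=4)
    np.testing.assert_array_equal(x1, x2)
    assert (x1 >= 10**2.5).all() and (x1 <= 10**5.5).all()


def test_invalid_profile_parameters_rejected(steinii):
    with pytest.raises(InvalidInputError):
        dataclasses.replace(steinii, cyst_rrna_suppression=1.5)
    with pytest.raises(InvalidInputError):
        dataclasses.replace(steinii, variant_divergences=(0.5,))
    with pytest.raises(InvalidInputError):
        synthetic.gen_population(steinii, 10, cyst_fraction=1.2)
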