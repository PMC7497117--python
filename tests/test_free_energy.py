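"""TI quadrature, block errors, analytic restraint removal, cycle ledger."""

import numpy as np
import pytest
from scipy import stats

from duores.constants import KB, STANDARD_VOLUME
from duores.energetics import BoreschRestraints
from duores.errors import CoverageError, LedgerError
from duores.free_energy import (
    TIResult, assemble_cycle, block_error, boresch_analytic, ti_integrate,
)


# ---------------------------------------------------------------------------
# block averaging
# ---------------------------------------------------------------------------

def test_block_error_matches_direct_student_t_oracle(rng):
    series = rng.normal(size=4000)
    n_blocks = 4
    blocks = series[:4000].reshape(n_blocks, -1).mean(axis=1)
    t = stats.t.ppf(0.975, df=n_blocks - 1)
    oracle = t * blocks.std(ddof=1) / np.sqrt(n_blocks)
    assert np.isclose(block_error(series), oracle)


def test_block_error_is_zero_for_constant_series():
    assert block_error(np.full(100, 3.7)) == 0.0


def test_block_error_drops_trailing_remainder(rng):
    series = rng.normal(size=103)
    assert np.isclose(block_error(series), block_error(series[:100]))


def test_block_error_covers_the_true_mean_at_stated_confidence():
    # repeated draws: the 95% CI should contain the true mean ~95% of the time
    hits = 0
    trials = 200
    for seed in range(trials):
        series = np.random.default_rng(seed).normal(loc=1.0, size=256)
        if abs(series.mean() - 1.0) <= block_error(series):
            hits += 1
    assert hits / trials > 0.85


def test_block_error_input_validation(rng):
    with pytest.raises(ValueError):
        block_error(rng.normal(size=3))
    with pytest.raises(ValueError):
        block_error(rng.normal(size=(10, 2)))


# ---------------------------------------------------------------------------
# TI quadrature
# ---------------------------------------------------------------------------

def test_ti_matches_trapezoid_oracle_on_noiseless_series():
    lambdas = np.linspace(0.0, 1.0, 11)
    f = 3.0 * lambdas ** 2 + 1.0
    series = [np.full(16, v) for v in f]
    result = ti_integrate(series, lambdas)
    assert np.isclose(result.dg, np.trapezoid(f, lambdas))
    assert result.dg_error == 0.0
    assert np.allclose(result.means, f)


def test_ti_error_is_weighted_linear_sum_of_window_errors(rng):
    lambdas = np.array([0.0, 0.25, 0.5, 1.0])
    series = [rng.normal(size=64) for _ in lambdas]
    result = ti_integrate(series, lambdas)
    w = np.zeros(4)
    gaps = np.diff(lambdas)
    w[:-1] += 0.5 * gaps
    w[1:] += 0.5 * gaps
    oracle = sum(wi * block_error(s) for wi, s in zip(w, series))
    assert np.isclose(result.dg_error, oracle)


def test_ti_requires_endpoint_coverage_unless_partial():
    lambdas = np.linspace(0.1, 0.9, 5)
    series = [np.full(8, 1.0) for _ in lambdas]
    with pytest.raises(CoverageError):
        ti_integrate(series, lambdas)
    partial = ti_integrate(series, lambdas, allow_partial=True)
    assert np.isclose(partial.dg, 0.8)


def test_ti_rejects_malformed_schedules():
    with pytest.raises(ValueError):
        ti_integrate([np.ones(8)], [0.0])
    with pytest.raises(ValueError):
        ti_integrate([np.ones(8)] * 2, [0.5, 0.5])
    with pytest.raises(ValueError):
        ti_integrate([np.ones(8)] * 3, [0.0, 1.0], )
    with pytest.raises(ValueError):
        ti_integrate([np.ones(8), np.array([])], [0.0, 1.0])


def test_ti_result_csv_round_trip(tmp_path):
    import pandas as pd

    lambdas = np.linspace(0.0, 1.0, 5)
    result = ti_integrate([np.full(8, v) for v in lambdas], lambdas)
    path = tmp_path / "ti.csv"
    result.to_csv(path)
    df = pd.read_csv(path)
    assert np.allclose(df["lambda"], lambdas)
    assert np.allclose(df["mean_dudl"], lambdas)


# ---------------------------------------------------------------------------
# analytic restraint removal
# ---------------------------------------------------------------------------

def _restraints(k_r=4184.0, k_ang=41.84, k_dih=41.84, r0=0.5):
    return BoreschRestraints(
        protein_anchors=(0, 1, 2), ligand_anchors=(3, 4, 5),
        r0=r0, theta_a0=1.2, theta_b0=1.9,
        phi_a0=0.4, phi_b0=-1.1, phi_c0=2.2,
        k_r=k_r, k_theta_a=k_ang, k_theta_b=k_ang,
        k_phi_a=k_dih, k_phi_b=k_dih, k_phi_c=k_dih,
    )


def test_boresch_analytic_standard_volume_additivity():
    r = _restraints()
    t = 298.0
    for scale in (2.0, 10.0):
        dg0 = boresch_analytic(r, t, STANDARD_VOLUME)
        dgs = boresch_analytic(r, t, STANDARD_VOLUME * scale)
        assert np.isclose(dgs - dg0, -KB * t * np.log(scale), atol=1e-8)


def test_boresch_analytic_force_constant_scaling():
    t = 298.0
    for factor in (4.0, 25.0):
        dg0 = boresch_analytic(_restraints(), t)
        dgf = boresch_analytic(
            _restraints(k_r=4184.0 * factor, k_ang=41.84 * factor,
                        k_dih=41.84 * factor), t)
        assert np.isclose(dgf - dg0, -3.0 * KB * t * np.log(factor), atol=1e-8)


def test_boresch_analytic_rejects_degenerate_parameters():
    with pytest.raises(ValueError):
        boresch_analytic(_restraints(k_r=0.0))


# ---------------------------------------------------------------------------
# cycle assembly
# ---------------------------------------------------------------------------

def _terms():
    return {
        "restr_on_c": (3.6, 0.4), "coul_c": (145.2, 3.5), "lj_c": (44.2, 5.2),
        "coul_l": (-142.8, 1.7), "lj_l": (-9.1, 6.3), "restr_off": -31.3,
    }


def test_cycle_totals_are_sums_of_components():
    ledger = assemble_cycle(_terms())
    assert np.isclose(ledger.dg_compl, 193.0)
    assert np.isclose(ledger.dg_lig, -151.9)
    assert np.isclose(ledger.dg_bind, 9.8)
    # linear error addition
    assert np.isclose(ledger.dg_compl_err, 9.1)
    assert np.isclose(ledger.dg_lig_err, 8.0)
    assert np.isclose(ledger.dg_bind_err, 17.1)


def test_cycle_quadrature_combination_option():
    ledger = assemble_cycle(_terms(), error_combination="quadrature")
    assert np.isclose(ledger.dg_compl_err,
                      np.sqrt(0.4 ** 2 + 3.5 ** 2 + 5.2 ** 2))


def test_cycle_accepts_ti_results_and_scalars():
    lambdas = np.linspace(0.0, 1.0, 5)
    ti = TIResult(lambdas, np.full(5, 2.0), np.full(5, 0.1), 2.0, 0.1)
    terms = _terms()
    terms["restr_on_c"] = ti
    ledger = assemble_cycle(terms)
    assert np.isclose(ledger.component("restr_on_c")[0], 2.0)
    assert np.isclose(ledger.dg_compl, 145.2 + 44.2 + 2.0)


def test_cycle_supports_presummed_annihilation_legs():
    ledger = assemble_cycle(
        {"compl": (1315.2, 16.3), "lig": (-1275.3, 11.2), "restr_off": -31.3},
        mode="annihilation")
    assert np.isclose(ledger.dg_bind, 8.6)
    assert np.isclose(ledger.dg_bind_err, 27.5)


def test_missing_leg_is_named_in_the_error():
    terms = _terms()
    del terms["lj_c"]
    with pytest.raises(LedgerError, match="lj_c"):
        assemble_cycle(terms)
    with pytest.raises(LedgerError, match="restr_off"):
        assemble_cycle({k: v for k, v in _terms().items() if k != "restr_off"})


def test_restraint_removal_term_carries_no_uncertainty():
    terms = _terms()
    terms["restr_off"] = (-31.3, 99.0)  # any stated error is discarded
    ledger = assemble_cycle(terms)
    assert ledger.component("restr_off") == (-31.3, 0.0)


def test_ledger_csv_and_text_rendering(tmp_path):
    import pandas as pd

    ledger = assemble_cycle(_terms())
    path = tmp_path / "ledger.csv"
    ledger.to_csv(path)
    df = pd.read_csv(path).set_index("term")
    assert np.isclose(df.loc["dg_bind", "dg"], 9.8)
    text = str(ledger)
    assert "dG_bind" in text and "decoupling" in text
    with pytest.raises(LedgerError):
        ledger.component("nope")
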