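"""rH rank correlations and the aggregate sign statistics."""

import numpy as np
import pandas as pd
import pytest

from minirings.accretion_stats import (
    aggregate,
    chi_square_vs_half,
    compute_rh,
    percent_negative,
    rh_table,
)
from minirings.synthetic_data import SyntheticConfig, generate_ring_features, generate_subelement_table


# -- compute_rh -------------------------------------------------------------


def test_perfect_antimonotone_gives_minus_one():
    r, n = compute_rh([5.0, 4.0, 3.0, 2.0, 1.0], [1, 2, 3, 4, 5])
    assert n == 5 and r == pytest.approx(-1.0)


def test_rank_affine_invariance():
    z = [0.3, -0.2, 0.9, 0.1, -0.5]
    ranks = [1, 2, 3, 4, 5]
    r1, _ = compute_rh(z, ranks)
    r2, _ = compute_rh(z, [100 * r / 5 for r in ranks])
    assert r1 == pytest.approx(r2, abs=1e-12)


def test_pairwise_deletion_and_small_n():
    r, n = compute_rh([1.0, None, 3.0, 4.0], [4, 3, None, 1])
    assert n == 2 and r is None
    r2, n2 = compute_rh([1.0, 2.0, 3.0, None], [4, 3, 1, 2])
    assert n2 == 3 and r2 is not None


# -- percent_negative -------------------------------------------------------


def test_percent_negative_examples():
    assert percent_negative([-1, -0.5, -0.1])[0] == 100.0
    pct, counts = percent_negative([-0.1, 0.0, 0.2])
    assert pct == pytest.approx(33.3, abs=0.05)  # zero counts as non-negative
    assert counts["n_negative"] == 1 and counts["n_defined"] == 3
    pct_half, _ = percent_negative([-1] * 275 + [1] * 275)
    assert pct_half == 50.0


def test_percent_negative_undefined_handling():
    pct, counts = percent_negative([None, float("nan"), -0.2])
    assert pct == 100.0 and counts["n_undefined"] == 2
    pct2, counts2 = percent_negative([None, None])
    assert pct2 is None and counts2["n_defined"] == 0


# -- chi-square -------------------------------------------------------------


def test_chi_square_examples():
    stat, p, sig = chi_square_vs_half(275, 550)
    assert stat == 0.0 and p == 1.0 and not sig
    stat, p, sig = chi_square_vs_half(330, 550)
    assert stat == pytest.approx(22.0) and sig
    stat, p, sig = chi_square_vs_half(280, 550)
    assert stat == pytest.approx(2 * 25 / 275, abs=1e-12) and not sig


def test_chi_square_empty_raises():
    with pytest.raises(ValueError):
        chi_square_vs_half(0, 0)


# -- rh_table on fixtures ---------------------------------------------------


def test_ring25_thermus_extrema(thermus_rh):
    """The reference ring's published extrema for Thermus reproduce exactly."""
    assert len(thermus_rh) == 22
    assert 100 * thermus_rh["rh_phyl"].min() == pytest.approx(-46.1, abs=0.05)
    assert 100 * thermus_rh["rh_stru"].max() == pytest.approx(38.7, abs=0.05)
    assert (thermus_rh["n_phyl"] == 43).all()
    assert (thermus_rh["n_stru"] == 48).all()


def test_rh_table_is_deterministic(ring25_features, tables):
    a = rh_table(ring25_features, tables.subelements)
    b = rh_table(ring25_features, tables.subelements)
    pd.testing.assert_frame_equal(a, b)


def test_sign_flip_duality_between_log_modes(ring25_features, tables):
    """Switching printed z conventions flips every rH exactly."""
    f = rh_table(ring25_features, tables.subelements, z_mode="fisher")
    p = rh_table(ring25_features, tables.subelements, z_mode="paper_literal")
    assert np.allclose(f["rh_phyl"], -p["rh_phyl"], equal_nan=True)
    assert np.allclose(f["rh_stru"], -p["rh_stru"], equal_nan=True)


# -- aggregate --------------------------------------------------------------


@pytest.fixture(scope="module")
def synthetic_bundle():
    cfg = SyntheticConfig(n_subelements=30, n_rings=25, effect_size=0.5, noise_sd=10.0,
                          seed=5, reference_seed=5)
    rings = generate_ring_features(cfg)
    subs = pd.concat(
        [
            generate_subelement_table(
                SyntheticConfig(n_subelements=30, effect_size=0.5, noise_sd=10.0,
                                seed=6 + i, reference_seed=5, organism=f"org{i}")
            )
            for i in range(6)
        ],
        ignore_index=True,
    )
    rh = rh_table(rings, subs)
    return rings, subs, rh


def test_aggregate_counting_invariants(synthetic_bundle):
    rings, subs, rh = synthetic_bundle
    assert len(rh) == 6 * 25 * 22  # attempted triples per method
    rep = aggregate(rh)
    per_ring = rep.per_ring
    per_splicing = rep.per_splicing
    for method in ("phyl", "stru"):
        ring_total = (per_ring[f"n_{method}"] + per_ring[f"n_undefined_{method}"]).sum()
        splicing_total = (
            per_splicing[f"n_{method}"] + per_splicing[f"n_undefined_{method}"]
        ).sum()
        assert ring_total == splicing_total == 6 * 550
        assert (per_ring[f"n_{method}"] + per_ring[f"n_undefined_{method}"] == 132).all()
        assert (per_splicing[f"n_{method}"] + per_splicing[f"n_undefined_{method}"] == 150).all()
    assert len(per_ring) == 25 and len(per_splicing) == 22


def test_planted_negative_effect_yields_negative_majority(synthetic_bundle):
    """Pooled over organisms, both rank methods recover the planted sign."""
    _, _, rh = synthetic_bundle
    for method in ("phyl", "stru"):
        pct, _ = percent_negative(rh[f"rh_{method}"])
        assert pct > 50


def test_fixed_denominator_option(synthetic_bundle):
    _, _, rh = synthetic_bundle
    rep = aggregate(rh, fixed_denominator=550)
    pcts = rep.per_organism["pct_negative"]
    counts = rh.groupby("organism")["rh_phyl"].apply(lambda s: (s < 0).sum())
    row = rep.per_organism[rep.per_organism["method"] == "phyl"].set_index("organism")
    for org, n_neg in counts.items():
        assert row.loc[org, "pct_negative"] == pytest.approx(100 * n_neg / 550)


def test_aggregate_carries_no_correction_note(synthetic_bundle):
    _, _, rh = synthetic_bundle
    rep = aggregate(rh)
    assert any("multiple-testing" in n for n in rep.notes)
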