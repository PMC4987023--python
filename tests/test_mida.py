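"""Mass isotopomer envelopes, MIDA site fitting, fractional synthesis."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from turnoverlab import mida
from turnoverlab.errors import FitError, UnquantifiablePeptideError

from conftest import enumerate_isotopologues

POINT_MASS_H = mida.IsotopeTable({"H": ((0, 1.0),)})


# ---------------------------------------------------------------------------
# Elemental composition
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "peptide, kwargs, expected",
    [
        # free glycine: residue + water
        ("G", dict(cys_carbamidomethyl=False), (2, 5, 1, 2, 0)),
        ("GG", dict(cys_carbamidomethyl=False), (4, 8, 2, 3, 0)),
        # Cys + carbamidomethyl: C3H7NO2S + C2H3NO
        ("C", dict(cys_carbamidomethyl=True), (5, 10, 2, 3, 1)),
        # one oxidized Met adds one O to M (C5H11NO2S)
        ("M", dict(cys_carbamidomethyl=False, met_oxidized_count=1), (5, 11, 1, 3, 1)),
    ],
)
def test_composition_examples(peptide, kwargs, expected):
    comp = mida.composition_of(peptide, **kwargs)
    assert (comp.C, comp.H, comp.N, comp.O, comp.S) == expected


def test_composition_errors():
    with pytest.raises(Exception):
        mida.composition_of("GXG")
    with pytest.raises(ValueError):
        mida.composition_of("GMG", met_oxidized_count=2)


# ---------------------------------------------------------------------------
# Natural envelopes
# ---------------------------------------------------------------------------


def test_natural_distribution_two_carbons():
    """Binomial expansion (0.9891 + 0.0109)^2 over mass offsets."""
    d = mida.natural_distribution({"C": 2}, k_max=2)
    np.testing.assert_allclose(
        d.as_array(), [0.978319, 0.021562, 0.000119], atol=1e-6
    )


def test_natural_distribution_point_mass():
    d = mida.natural_distribution({"H": 4}, table=POINT_MASS_H, k_max=3)
    np.testing.assert_allclose(d.as_array(), [1.0, 0.0, 0.0, 0.0])


@pytest.mark.parametrize(
    "counts",
    [
        {"C": 2},
        {"C": 3, "H": 2, "O": 1},
        {"S": 2},
        {"C": 1, "N": 2, "S": 1, "O": 2},
        {"H": 2, "O": 2, "N": 1, "C": 1},
    ],
)
def test_natural_distribution_matches_exhaustive_enumeration(counts):
    """<=6-atom molecules: convolution equals per-atom isotopologue sums."""
    table = {el: list(pairs) for el, pairs in mida._DEFAULT_ABUNDANCES.items()}
    expected = enumerate_isotopologues(counts, table)
    got = mida.natural_distribution(counts, k_max=len(expected) - 1)
    np.testing.assert_allclose(got.as_array(), expected, atol=1e-9)


@settings(max_examples=40, derandomize=True)
@given(
    c=st.integers(0, 60),
    h=st.integers(2, 100),
    n=st.integers(0, 20),
    o=st.integers(1, 20),
    s=st.integers(0, 3),
    k_max=st.integers(1, 12),
)
def test_emitted_distributions_are_normalized(c, h, n, o, s, k_max):
    comp = mida.ElementalComposition(C=c, H=h, N=n, O=o, S=s)
    nat = mida.natural_distribution(comp, k_max=k_max)
    assert abs(sum(nat.channels) - 1.0) < 1e-12
    lab = mida.labeled_distribution(comp, min(10, h), 0.05, k_max=k_max)
    assert abs(sum(lab.channels) - 1.0) < 1e-12


# ---------------------------------------------------------------------------
# Labeled envelopes
# ---------------------------------------------------------------------------


def test_labeled_identity_cases():
    comp = mida.composition_of("PEPTIDE")
    nat = mida.natural_distribution(comp)
    for n_sites, p in [(0, 0.05), (17, 0.0)]:
        lab = mida.labeled_distribution(comp, n_sites, p, k_max=nat.k_max)
        np.testing.assert_allclose(lab.as_array(), nat.as_array(), atol=1e-15)


def test_labeled_pure_binomial():
    """With a point-mass natural envelope the labeled envelope is the
    Binomial(n, p) mass distribution itself."""
    lab = mida.labeled_distribution({"H": 2}, 2, 0.05, table=POINT_MASS_H, k_max=2)
    np.testing.assert_allclose(lab.as_array(), [0.9025, 0.0950, 0.0025], atol=1e-12)


def test_labeled_rejects_excess_sites():
    with pytest.raises(ValueError, match="exceeds"):
        mida.labeled_distribution({"H": 4, "O": 1}, 5, 0.05, k_max=3)


def test_labeled_convolution_consistency():
    """labeled(n1+n2, p) == labeled(n1, p) * Binomial(n2, p)."""
    from scipy import stats

    comp = mida.composition_of("SAMPLEK")
    n1, n2, p, k = 8, 5, 0.05, 30
    a = mida.labeled_distribution(comp, n1 + n2, p, k_max=k).as_array()
    b = mida.labeled_distribution(comp, n1, p, k_max=k).as_array()
    binom = stats.binom.pmf(np.arange(n2 + 1), n2, p)
    conv = np.convolve(b, binom)[: k + 1]
    np.testing.assert_allclose(a, conv / conv.sum(), atol=1e-12)


# ---------------------------------------------------------------------------
# RMSD and site fitting
# ---------------------------------------------------------------------------


def test_rmsd_identity_and_closed_form():
    d = mida.natural_distribution({"C": 5}, k_max=3)
    assert mida.distribution_rmsd(d, d) == 0.0
    assert mida.distribution_rmsd([1.0, 0.0], [0.0, 1.0]) == pytest.approx(1.0)
    # symmetric, and pads unequal channel counts
    a, b = [0.7, 0.3], [0.7, 0.2, 0.1]
    assert mida.distribution_rmsd(a, b) == pytest.approx(
        mida.distribution_rmsd(b, a)
    )


def test_fit_sites_self_consistency():
    comp = mida.composition_of("SAMPLEK")
    observed = mida.labeled_distribution(comp, 20, 0.05)
    fit = mida.fit_incorporation_sites(observed, comp, 0.05, (0, 58))
    assert fit.n_sites == 20
    assert fit.rmsd < 1e-12

    unlabeled = mida.natural_distribution(comp)
    fit0 = mida.fit_incorporation_sites(unlabeled, comp, 0.05, (0, 58))
    assert fit0.n_sites == 0


def test_fit_sites_empty_range_errors():
    comp = mida.composition_of("SAMPLEK")
    obs = mida.natural_distribution(comp)
    with pytest.raises(FitError):
        mida.fit_incorporation_sites(obs, comp, 0.05, (5, 4))
    with pytest.raises(FitError):
        mida.fit_incorporation_sites(obs, comp, 0.05, (0, comp.H + 1))


def test_fit_sites_rmsd_nonincreasing_as_range_grows():
    comp = mida.composition_of("SAMPLEK")
    observed = mida.labeled_distribution(comp, 20, 0.05)
    rmsds = [
        mida.fit_incorporation_sites(observed, comp, 0.05, (0, hi)).rmsd
        for hi in (5, 10, 15, 20, 30, 50)
    ]
    assert all(b <= a + 1e-15 for a, b in zip(rmsds, rmsds[1:]))


def test_fit_sites_noise_recovery_monte_carlo():
    """1 % multiplicative channel noise: n̂ within ±1 in >=95 % of 200 reps."""
    comp = mida.composition_of("SAMPLEK")
    true = mida.labeled_distribution(comp, 20, 0.05)
    rng = np.random.default_rng(42)
    hits = 0
    for _ in range(200):
        noisy = true.as_array() * (1 + rng.normal(0, 0.01, true.k_max + 1))
        obs = mida.MassIsotopomerDistribution.from_raw(np.clip(noisy, 0, None))
        fit = mida.fit_incorporation_sites(obs, comp, 0.05, (0, 58))
        hits += abs(fit.n_sites - 20) <= 1
    assert hits >= 190


def test_fit_plateau_mixture_recovers_n_and_fraction():
    comp = mida.composition_of("SAMPLEK")
    nat = mida.natural_distribution(comp)
    lab = mida.labeled_distribution(comp, 20, 0.05, k_max=nat.k_max)
    for lam_true in (0.2, 0.6, 0.95):
        obs = mida.MassIsotopomerDistribution.from_raw(
            (1 - lam_true) * nat.as_array() + lam_true * lab.as_array()
        )
        fit, lam = mida.fit_plateau_mixture(obs, comp, 0.05, (0, 58))
        assert fit.n_sites == 20
        assert lam[0] == pytest.approx(lam_true, abs=1e-9)


# ---------------------------------------------------------------------------
# Fractional synthesis
# ---------------------------------------------------------------------------


@pytest.fixture
def envelopes():
    comp = mida.composition_of("SAMPLEK")
    nat = mida.natural_distribution(comp)
    lab = mida.labeled_distribution(comp, 20, 0.05, k_max=nat.k_max)
    return nat, lab


@pytest.mark.parametrize("lam", [i / 10 for i in range(11)])
def test_fractional_synthesis_exact_on_linear_mixtures(envelopes, lam):
    nat, lab = envelopes
    obs = mida.MassIsotopomerDistribution.from_raw(
        (1 - lam) * nat.as_array() + lam * lab.as_array()
    )
    pt = mida.fractional_synthesis(obs, nat, lab)
    assert pt.f == pytest.approx(lam, abs=1e-12)
    assert pt.sd == pytest.approx(0.0, abs=1e-9)
    assert pt.n_informative >= 2


def test_fractional_synthesis_no_informative_channel(envelopes):
    nat, _ = envelopes
    with pytest.raises(UnquantifiablePeptideError):
        mida.fractional_synthesis(nat, nat, nat)


def test_fractional_synthesis_flags_out_of_range(envelopes):
    nat, lab = envelopes
    wild = mida.MassIsotopomerDistribution.from_raw(
        np.clip(2.0 * lab.as_array() - nat.as_array(), 1e-9, None)
    )
    pt = mida.fractional_synthesis(wild, nat, lab)
    if abs(pt.f - 0.5) > 0.5 + 5 * pt.sd + 1e-9:
        assert "f_out_of_range" in pt.qc_flags


# ---------------------------------------------------------------------------
# QC filter
# ---------------------------------------------------------------------------


def _pt(f, sd, t):
    return mida.FractionalSynthesisPoint(f=f, sd=sd, n_informative=3, time_h=t)


def test_qc_filter_reason_codes():
    crit = mida.QCCriteria(min_total_abundance=1e5, max_plateau_rmsd=0.01,
                           max_point_sd=0.15)
    series = [_pt(0.2, 0.01, 0.0), _pt(0.5, 0.30, 24.0)]

    kept, rejected = mida.qc_filter(series, crit, total_ion_abundance=1e6,
                                    plateau_rmsd=0.001)
    assert kept == [series[0]]
    assert [r.reason for r in rejected] == ["high_sd"]

    kept, rejected = mida.qc_filter(series, crit, total_ion_abundance=1e3)
    assert kept == []
    assert {r.reason for r in rejected} == {"low_abundance"}

    kept, rejected = mida.qc_filter(series, crit, plateau_rmsd=0.5)
    assert kept == []
    assert {r.reason for r in rejected} == {"high_rmsd"}


def test_qc_filter_passes_clean_series():
    crit = mida.QCCriteria()
    series = [_pt(0.1, 0.02, 0.0), _pt(0.6, 0.03, 24.0)]
    kept, rejected = mida.qc_filter(series, crit, total_ion_abundance=1e6,
                                    plateau_rmsd=0.001)
    assert kept == series
    assert rejected == []
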