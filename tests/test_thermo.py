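"""Nearest-neighbor engine: energies, Tm, equilibrium duplex concentration."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq

from hseprobe import thermo
from hseprobe.thermo import (DuplexParams, MissingParameterError, R_CAL,
                             complement, duplex_concentration, duplex_energy,
                             free_energy, gc_content, melting_curve,
                             melting_temperature, reverse_complement,
                             salt_corrected_entropy, simulate_pairing)

from conftest import random_seq


# ---------------------------------------------------------------------------
# G/C content
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "seq,expected",
    [
        ("TTTCAGAAATGAGTGTGACATCTTC", 36),  # published 25-mer design
        ("GAGTGTGACATCTTC", 47),            # 7/15 rounds to 47
        ("CTATCCATCTATCATCTATTTATC", 29),
        ("GAAATGAGTGTGACATCTTC", 40),
        ("GGGG", 100),
        ("ATAT", 0),
    ],
)
def test_gc_content_matches_hand_count(seq, expected):
    assert round(gc_content(seq)) == expected


def test_gc_content_rejects_bad_input():
    with pytest.raises(ValueError):
        gc_content("")
    with pytest.raises(ValueError):
        gc_content("ACGN")


# ---------------------------------------------------------------------------
# Energy summation
# ---------------------------------------------------------------------------

def test_duplex_energy_equals_hand_summed_stacks(nn_params):
    # 5-mer GCGTA vs perfect complement: manual per-stack total over the
    # published unified table plus two initiation terms.
    seq = "GCGTA"
    dh = (-9.8) + (-10.6) + (-8.4) + (-7.2) + 0.1 + 2.3
    ds = (-24.4) + (-27.2) + (-22.4) + (-21.3) + (-2.8) + 4.1
    got_h, got_s = duplex_energy(seq, complement(seq), nn_params)
    assert got_h == pytest.approx(dh, abs=1e-12)
    assert got_s == pytest.approx(ds, abs=1e-12)


def test_strand_swap_invariance(rng, nn_params):
    """A duplex's energy cannot depend on which strand is called the probe."""
    for _ in range(50):
        s = random_seq(rng, int(rng.integers(6, 30)))
        a = duplex_energy(s, complement(s), nn_params)
        b = duplex_energy(reverse_complement(s), complement(reverse_complement(s)),
                          nn_params)
        assert a == pytest.approx(b, abs=1e-9)


def test_terminal_mismatch_changes_only_one_stack(nn_params):
    """Match vs 3'-terminal mismatch differ exactly by swapping the terminal
    stack term (all other terms cancel in the difference)."""
    probe = "ATGAGTGTGACATCTTC"
    match = complement(probe)
    mm = match[:-1] + "A"  # C-A opposition at the probe 3' terminus
    dh_m, ds_m = duplex_energy(probe, match, nn_params)
    dh_x, ds_x = duplex_energy(probe, mm, nn_params)
    wc_h, wc_s = nn_params.stack(probe[-2:], match[-2:])
    tm_h, tm_s = nn_params.terminal_stack(probe[-2:], mm[-2:])
    assert dh_x - dh_m == pytest.approx(tm_h - wc_h, abs=1e-12)
    assert ds_x - ds_m == pytest.approx(tm_s - wc_s, abs=1e-12)


def test_penultimate_mismatch_changes_two_stacks(nn_params):
    probe = "ATGAGTGTGACATCTTC"
    match = complement(probe)
    i = len(probe) - 2
    mm = match[:i] + "G" + match[i + 1 :]
    dh_m, _ = duplex_energy(probe, match, nn_params)
    dh_x, _ = duplex_energy(probe, mm, nn_params)
    expected = (
        nn_params.stack(probe[i - 1 : i + 1], mm[i - 1 : i + 1])[0]
        + nn_params.stack(probe[i : i + 2], mm[i : i + 2])[0]
        - nn_params.stack(probe[i - 1 : i + 1], match[i - 1 : i + 1])[0]
        - nn_params.stack(probe[i : i + 2], match[i : i + 2])[0]
    )
    assert dh_x - dh_m == pytest.approx(expected, abs=1e-12)


def test_unsupported_geometries_rejected(nn_params):
    probe = "ACGTACGTACGT"
    match = complement(probe)
    with pytest.raises(ValueError):
        duplex_energy(probe, match[:-1], nn_params)  # length mismatch
    internal = match[:3] + "G" + match[4:]
    with pytest.raises(ValueError):
        duplex_energy(probe, internal, nn_params)  # deep internal mismatch
    double = match[:-2] + "GG"  # G-G and G-T oppositions
    with pytest.raises(ValueError):
        duplex_energy(probe, double, nn_params)  # two mismatches
    with pytest.raises(ValueError):
        duplex_energy("A", "T", nn_params)  # too short


def test_missing_parameter_raises_not_zero(nn_params):
    with pytest.raises(MissingParameterError):
        nn_params.stack("AA", "GG")  # two mismatched oppositions, no entry


def test_agreement_with_independent_nn_implementation(rng, assay):
    """Dual-route check: our summation + salt correction + CT/4 Tm against
    Biopython's independently coded Tm_NN, over all pairing geometries."""
    from Bio.SeqUtils import MeltingTemp as mt

    ct = assay.probe_conc_molar + assay.target_conc_molar
    dnac = ct / 2 * 1e9  # nM each; Bio's (dnac1 - dnac2/2) then equals CT/4
    for _ in range(40):
        L = int(rng.integers(8, 28))
        probe = random_seq(rng, L)
        target = complement(probe)
        mode = ["match", "tmm", "imm"][int(rng.integers(0, 3))]
        if mode != "match":
            pos = L - 1 if mode == "tmm" else L - 2
            options = [b for b in "ACGT"
                       if b != target[pos] and b != complement(probe[pos])]
            target = target[:pos] + options[int(rng.integers(0, len(options)))] + target[pos + 1 :]
        res = simulate_pairing(probe, target, assay)
        tm_bio = mt.Tm_NN(probe, c_seq=target, nn_table=mt.DNA_NN3,
                          dnac1=dnac, dnac2=dnac,
                          Na=assay.monovalent_molar * 1000,
                          Mg=assay.magnesium_molar * 1000, saltcorr=5)
        assert res.tm_celsius == pytest.approx(tm_bio, abs=0.01)


# ---------------------------------------------------------------------------
# Salt correction and Tm
# ---------------------------------------------------------------------------

def test_salt_correction_identity_at_reference():
    p = DuplexParams(monovalent_molar=1.0, magnesium_molar=0.0)
    assert salt_corrected_entropy(-200.0, 18, p) == -200.0


def test_salt_correction_destabilizes_at_low_salt():
    p = DuplexParams(monovalent_molar=0.05, magnesium_molar=0.0)
    assert salt_corrected_entropy(-200.0, 18, p) < -200.0


def test_salt_correction_formula_value():
    # independent recomputation: dS + 0.368 * 18 * ln(0.1)
    p = DuplexParams(monovalent_molar=0.1, magnesium_molar=0.0)
    expected = -200.0 + 0.368 * 18 * math.log(0.1)
    assert salt_corrected_entropy(-200.0, 18, p) == pytest.approx(expected, rel=1e-12)


def test_tm_closed_form_and_ct_dependence():
    dh, ds = -150.0, -400.0
    ct = 5e-6 + 3e-15
    expected = 1000 * dh / (ds + R_CAL * math.log(ct / 4)) - 273.15
    assert melting_temperature(dh, ds, 5e-6, 3e-15) == pytest.approx(expected, rel=1e-12)
    # doubling total strand concentration raises Tm
    assert melting_temperature(dh, ds, 1e-5, 6e-15) > expected


def test_tm_degenerate_denominator_is_none():
    assert melting_temperature(-10.0, 500.0, 5e-6, 3e-15) is None


def test_tm_and_dg_increase_with_length_in_trim_series(assay):
    """Stepwise 5' extension of the worked forward design adds a stabilizing
    stack at every length: Tm and |dG| strictly increase."""
    full = "TTTCAGAAATGAGTGTGACATCTTC"
    tms, dgs = [], []
    for L in range(9, 26):
        res = simulate_pairing(full[-L:], complement(full[-L:]), assay)
        tms.append(res.tm_celsius)
        dgs.append(abs(res.delta_g_at_t))
    assert all(b > a for a, b in zip(tms, tms[1:]))
    assert all(b > a for a, b in zip(dgs, dgs[1:]))


# ---------------------------------------------------------------------------
# Equilibrium solver
# ---------------------------------------------------------------------------

def _iterative_duplex(k, p0, t0):
    """Independent mass-action oracle: root of K(P0-x)(T0-x) - x on [0, min]."""
    if k == 0:
        return 0.0
    f = lambda x: k * (p0 - x) * (t0 - x) - x
    hi = min(p0, t0)
    if f(hi) == 0:
        return hi
    return brentq(f, 0.0, hi, xtol=1e-300, rtol=8.9e-16, maxiter=500)


def test_quadratic_solver_matches_iterative_oracle(rng):
    """Closed-form root agrees with the brute-force equilibrium solver to
    10 significant digits over 1,000 random (K, P0, T0) instances."""
    t_kelvin = 337.15
    for _ in range(1000):
        logk = rng.uniform(-6, 30)
        k = 10.0 ** logk
        p0 = 10.0 ** rng.uniform(-15, -3)
        t0 = 10.0 ** rng.uniform(-15, -3)
        dg = -R_CAL * t_kelvin * math.log(k) / 1000.0
        got = duplex_concentration(dg, p0, t0, t_kelvin)
        want = _iterative_duplex(k, p0, t0)
        assert got == pytest.approx(want, rel=1e-10)


def test_specific_equilibrium_instance():
    # K = 1e6, P0 = 5e-6, T0 = 3e-15: probe excess, mid-saturation
    t_kelvin = 337.15
    dg = -R_CAL * t_kelvin * math.log(1e6) / 1000.0
    got = duplex_concentration(dg, 5e-6, 3e-15, t_kelvin)
    want = _iterative_duplex(1e6, 5e-6, 3e-15)
    assert got == pytest.approx(want, rel=1e-10)


@settings(deadline=None, max_examples=200)
@given(
    logk=st.floats(-20, 35),
    logp=st.floats(-15, -3),
    logt=st.floats(-15, -3),
)
def test_duplex_concentration_bounds(logk, logp, logt):
    """0 <= [PT] <= min(P0, T0) across ~55 orders of magnitude in K."""
    t_kelvin = 310.15
    p0, t0 = 10.0 ** logp, 10.0 ** logt
    dg = -R_CAL * t_kelvin * logk * math.log(10) / 1000.0
    x = duplex_concentration(dg, p0, t0, t_kelvin)
    assert 0.0 <= x <= min(p0, t0)


def test_saturation_limits():
    t_kelvin = 337.15
    assert duplex_concentration(50.0, 5e-6, 3e-15, t_kelvin) == pytest.approx(0.0, abs=1e-30)
    sat = duplex_concentration(-50.0, 5e-6, 3e-15, t_kelvin)
    assert sat == pytest.approx(3e-15, rel=1e-9)


# ---------------------------------------------------------------------------
# Melting curve
# ---------------------------------------------------------------------------

def test_melting_curve_monotone_and_saturating(assay):
    probe = "GAAATGAGTGTGACATCTTC"
    curve = melting_curve(probe, complement(probe), assay,
                          t_range=np.arange(0, 101, 1.0))
    conc = curve[:, 1]
    assert np.all(np.diff(conc) <= 1e-25)  # non-increasing
    assert conc[0] == pytest.approx(min(assay.probe_conc_molar,
                                        assay.target_conc_molar), rel=0.01)
    assert conc[-1] < 1e-3 * conc[0]


def test_match_curve_dominates_mismatch_curve(assay):
    """Over the assay-relevant range the matched duplex is at least as
    abundant as the mismatched one at every temperature.  (Far above the
    melting transition enthalpy-entropy compensation can invert the free
    energy ordering, but only where both concentrations are vanishing.)"""
    probe = "GAAATGAGTGTGACATCTTC"
    match = complement(probe)
    mm = match[:-1] + "A"
    t_range = np.arange(0.0, 81.0, 1.0)
    cm = melting_curve(probe, match, assay, t_range)[:, 1]
    cx = melting_curve(probe, mm, assay, t_range)[:, 1]
    assert np.all(cm >= cx - 1e-25)


def test_melting_curve_rejects_bad_range(assay):
    probe = "GAAATGAGTGTGACATCTTC"
    with pytest.raises(ValueError):
        melting_curve(probe, complement(probe), assay, t_range=[])
    with pytest.raises(ValueError):
        melting_curve(probe, complement(probe), assay, t_range=[50, 40])


def test_thermo_result_internal_consistency(assay):
    probe = "GAAATGAGTGTGACATCTTC"
    res = simulate_pairing(probe, complement(probe), assay)
    assert res.delta_g_at_t == pytest.approx(
        res.delta_h - assay.temperature_kelvin * res.delta_s / 1000.0, rel=1e-12)
    assert 0 <= res.duplex_conc_molar <= min(assay.probe_conc_molar,
                                             assay.target_conc_molar)
    assert res.pairing_kind == "match"
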