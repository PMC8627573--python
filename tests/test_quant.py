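"""GC-MS quantitation: calibration, ion selection, closure, detection."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ctenofa.lipids import CompositionProfile
from ctenofa.quant import (
    IonizationCoefficients,
    MassSpectrum,
    PeakObservation,
    StandardSeries,
    UnresolvableCoelutionError,
    compute_mole_fractions,
    detect_significant_species,
    fit_standard_curve,
    integrate_peak,
    on_column_fraction,
    select_quant_ion,
)
from ctenofa.stats import holm_adjust


# -- calibration -------------------------------------------------------------

def series_on_line(slope, splits, molar_mass=250.0, noise=None):
    pts = []
    for i, s in enumerate(splits):
        y = slope * on_column_fraction(s)
        if noise is not None:
            y += noise[i]
        pts.append((s, y))
    return StandardSeries("X", molar_mass, tuple(pts))


def test_exact_line_recovers_slope_and_molar_coefficient():
    coef = fit_standard_curve(series_on_line(1000.0, [1, 2, 5, 10]))
    assert coef.mass_coefficient == pytest.approx(1000.0, abs=1e-9)
    assert coef.molar_coefficient == pytest.approx(4.0, abs=1e-12)
    assert coef.valid


def test_all_zero_integrals_flagged_invalid():
    s = StandardSeries("X", 250.0, ((1, 0.0), (2, 0.0), (5, 0.0)))
    coef = fit_standard_curve(s)
    assert coef.mass_coefficient == 0.0
    assert not coef.valid


def test_noisy_slope_close_to_truth():
    rng = np.random.default_rng(0)
    splits = [1, 2, 5, 10, 20, 25, 50, 100]
    noise = rng.normal(0.0, 1.0, size=8)
    coef = fit_standard_curve(series_on_line(1000.0, splits, noise=noise))
    # OLS through the origin: slope = sum(xy)/sum(x^2) on the same points
    x = np.array([on_column_fraction(s) for s in splits])
    y = 1000.0 * x + noise
    assert coef.mass_coefficient == pytest.approx(float(x @ y / (x @ x)), abs=1e-12)
    assert 990.0 <= coef.mass_coefficient <= 1010.0


def test_standard_series_validation():
    with pytest.raises(ValueError):
        StandardSeries("X", 250.0, ((5, 1.0),))  # one split setting
    with pytest.raises(ValueError):
        StandardSeries("X", 250.0, ((5, 1.0), (5, 2.0)))  # not distinct
    with pytest.raises(ValueError):
        StandardSeries("X", -1.0, ((1, 1.0), (2, 2.0)))  # bad molar mass


# -- quantitation ion selection ----------------------------------------------

def test_coeluting_pair_resolved_on_orthogonal_ion():
    target = MassSpectrum("A", {74: 1.0, 87: 0.6, 143: 0.2})
    coeluter = MassSpectrum("B", {74: 0.9, 87: 0.05, 55: 1.0})
    assert select_quant_ion(target, [coeluter]) == 87


def test_base_peak_used_without_coelution():
    assert select_quant_ion(MassSpectrum("A", {74: 1.0, 87: 0.6})) == 74


def test_identical_coeluter_is_unresolvable():
    spec = MassSpectrum("A", {74: 1.0, 87: 0.6})
    twin = MassSpectrum("B", {74: 1.0, 87: 0.6})
    with pytest.raises(UnresolvableCoelutionError, match="A"):
        select_quant_ion(spec, [twin])


@settings(deadline=None, derandomize=True, max_examples=60)
@given(st.data())
def test_selected_ion_always_satisfies_tenfold_rule(data):
    """Brute-force oracle: re-check the chosen ion against every coeluter."""
    mzs = data.draw(st.lists(st.integers(40, 400), min_size=2, max_size=8, unique=True))
    intens = data.draw(
        st.lists(st.floats(0.01, 1.0), min_size=len(mzs), max_size=len(mzs))
    )
    tgt = dict(zip(mzs, intens))
    peak = max(tgt.values())
    tgt = {m: v / peak for m, v in tgt.items()}
    co_mzs = data.draw(st.lists(st.integers(40, 400), min_size=1, max_size=8, unique=True))
    co_int = data.draw(
        st.lists(st.floats(0.01, 1.0), min_size=len(co_mzs), max_size=len(co_mzs))
    )
    co = dict(zip(co_mzs, co_int))
    co = {m: v / max(co.values()) for m, v in co.items()}
    target = MassSpectrum("T", tgt)
    coeluter = MassSpectrum("C", co)

    legal = [m for m, v in tgt.items() if v >= 10.0 * co.get(m, 0.0)]
    if not legal:
        with pytest.raises(UnresolvableCoelutionError):
            select_quant_ion(target, [coeluter])
    else:
        chosen = select_quant_ion(target, [coeluter])
        best = max(tgt[m] for m in legal)
        assert tgt[chosen] >= 10.0 * co.get(chosen, 0.0)
        assert tgt[chosen] == best
        assert chosen == min(m for m in legal if tgt[m] == best)


def test_share_rule_matches_ninefold_margin():
    # 0.9 share corresponds to a 9x margin, weaker than the tenfold default
    target = MassSpectrum("A", {74: 1.0, 87: 0.45})
    coeluter = MassSpectrum("B", {74: 1.0, 87: 0.048})
    # 0.45 / 0.048 = 9.4x: passes the 0.9-share rule, fails tenfold
    assert select_quant_ion(target, [coeluter], rule="share") == 87
    with pytest.raises(UnresolvableCoelutionError):
        select_quant_ion(target, [coeluter], rule="tenfold")


# -- peak integration ----------------------------------------------------------

def test_integrate_peak_geometry():
    flat = [(0.0, 0.0), (1.0, 0.0), (2.0, 0.0)]
    assert integrate_peak(flat, (0.0, 2.0)) == 0.0
    rect = [(0.0, 1.0), (1.0, 1.0), (2.0, 1.0)]
    assert integrate_peak(rect, (0.0, 2.0)) == pytest.approx(2.0)
    tri = [(0.0, 0.0), (1.5, 3.0), (3.0, 0.0)]  # height 3, base 3
    assert integrate_peak(tri, (0.0, 3.0)) == pytest.approx(4.5, abs=1e-9)
    assert integrate_peak(tri, (1.0, 1.0)) == 0.0
    with pytest.raises(ValueError):
        integrate_peak(tri, (2.0, 1.0))


# -- mole fractions -------------------------------------------------------------

def coefs(**kv):
    return {
        c: IonizationCoefficients(c, k * 100.0, k) for c, k in kv.items()
    }


def peaks(sid, **kv):
    return [PeakObservation(sid, c, 74, a) for c, a in kv.items()]


def test_mole_fraction_closure():
    prof = compute_mole_fractions(
        peaks("s", **{"C16:0": 100.0, "C18:1": 300.0}),
        coefs(**{"C16:0": 1.0, "C18:1": 3.0}),
    )
    assert prof["C16:0"] == pytest.approx(0.5)
    prof = compute_mole_fractions(
        peaks("s", **{"C16:0": 200.0, "C18:1": 100.0}),
        coefs(**{"C16:0": 1.0, "C18:1": 1.0}),
    )
    assert prof["C16:0"] == pytest.approx(2.0 / 3.0)
    prof = compute_mole_fractions(
        peaks("s", **{"C16:0": 55.5}), coefs(**{"C16:0": 2.0})
    )
    assert prof["C16:0"] == 1.0


def test_scale_invariance_of_mole_fractions():
    k = coefs(**{"C16:0": 1.3, "C18:1": 0.7, "C22:6": 2.1})
    base = {"C16:0": 120.0, "C18:1": 55.0, "C22:6": 310.0}
    ref = compute_mole_fractions(peaks("s", **base), k)
    for c in (1e-3, 7.0, 1e6):
        scaled = compute_mole_fractions(
            peaks("s", **{lab: a * c for lab, a in base.items()}), k
        )
        for sp, x in ref.entries.items():
            assert scaled[sp] == pytest.approx(x, abs=1e-12)


def test_unknown_compound_excluded_from_closure(caplog):
    prof = compute_mole_fractions(
        peaks("s", **{"C16:0": 100.0, "C18:1": 100.0}),
        coefs(**{"C16:0": 1.0}),
    )
    assert prof["C16:0"] == 1.0
    assert "no valid ionization coefficient" in caplog.text


def test_all_zero_integrals_error():
    with pytest.raises(ValueError):
        compute_mole_fractions(
            peaks("s", **{"C16:0": 0.0}), coefs(**{"C16:0": 1.0})
        )


# -- detection test ---------------------------------------------------------------

def detection_profiles(values_by_compound, n):
    """Profiles over the listed compounds plus a filler closing each to 1."""
    out = []
    for i in range(n):
        entries = {c: vals[i] for c, vals in values_by_compound.items()}
        entries["C16:0"] = 1.0 - sum(entries.values())
        out.append(CompositionProfile(f"s{i}", entries))
    return out


def test_present_compound_detected_absent_not():
    rng = np.random.default_rng(5)
    vals = np.abs(rng.normal(0.02, 0.001, size=20))
    profs = detection_profiles(
        {"C20:5": vals, "C22:6": np.zeros(20)}, 20
    )
    report = detect_significant_species(profs).set_index("compound")
    assert bool(report.loc["C20:5", "detected"])
    assert not bool(report.loc["C22:6", "detected"])


def test_six_sigma_spike_removed_before_testing():
    # 49 zeros and one 0.5: the spike sits 6.93 sample SDs from the mean,
    # is removed in the single pass, and the remaining zeros test null
    vals = np.zeros(50)
    vals[7] = 0.5
    profs = detection_profiles({"C17:0": vals}, 50)
    report = detect_significant_species(profs).set_index("compound")
    assert int(report.loc["C17:0", "n_outliers_removed"]) == 1
    assert int(report.loc["C17:0", "n_used"]) == 49
    assert not bool(report.loc["C17:0", "detected"])


def test_detection_needs_three_profiles():
    profs = detection_profiles({"C20:5": np.array([0.1, 0.1])}, 2)
    with pytest.raises(ValueError):
        detect_significant_species(profs)


# -- Holm adjustment -----------------------------------------------------------

def naive_holm(p):
    """Independent step-down oracle following the textbook definition."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    out = [0.0] * m
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, (m - rank) * p[i])
        out[i] = min(1.0, running)
    return out


def test_holm_worked_examples():
    assert holm_adjust([0.01, 0.04, 0.03]) == pytest.approx([0.03, 0.06, 0.06])
    assert holm_adjust([0.2]) == pytest.approx([0.2])
    assert holm_adjust([0.5, 0.5]) == pytest.approx([1.0, 1.0])


@settings(deadline=None, derandomize=True, max_examples=50)
@given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=12))
def test_holm_matches_independent_oracles(p):
    from statsmodels.stats.multitest import multipletests

    ours = holm_adjust(p)
    assert ours == pytest.approx(naive_holm(p), abs=1e-12)
    sm = multipletests(p, method="holm")[1]
    assert ours == pytest.approx(sm, abs=1e-12)
    assert np.all(ours >= np.asarray(p) - 1e-15)


def test_holm_rejects_invalid_p():
    with pytest.raises(ValueError):
        holm_adjust([0.5, 1.5])
    with pytest.raises(ValueError):
        holm_adjust([-0.1])
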