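"""Bennett-acceptance-ratio estimator, overlap diagnostic, synthetic work."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from pepgcm import (
    KB,
    WorkSamples,
    bar_at,
    bar_segment,
    bar_total,
    fermi,
    overlap,
    synth_work,
    zwanzig,
)
from pepgcm.errors import DomainError, EmptyDatasetError, PepGCMError

KT300 = KB * 300.0


def test_fermi_values():
    assert fermi(0.0, KT300) == pytest.approx(0.5)
    assert fermi(KT300 * math.log(3.0), KT300) == pytest.approx(0.25)
    with pytest.raises(DomainError):
        fermi(1.0, 0.0)


@given(x=st.floats(-50, 50))
def test_fermi_complement_identity(x):
    assert fermi(x, KT300) + fermi(-x, KT300) == pytest.approx(1.0, abs=1e-12)


def test_symmetric_states_give_zero():
    s = WorkSamples(forward=np.zeros(100), reverse=np.zeros(100), temperature=300.0)
    res = bar_segment(s)
    assert res.delta_g == pytest.approx(0.0, abs=1e-7 * KT300)
    assert res.converged


def test_hamiltonian_shift_invariance():
    s = synth_work(delta_f=1.0, sigma=1.5, n_forward=4000, n_reverse=4000, seed=21)
    base = bar_segment(s).delta_g
    c = 7.31  # kJ/mol
    shifted = WorkSamples(forward=s.forward + c, reverse=s.reverse - c,
                          temperature=s.temperature)
    assert bar_segment(shifted).delta_g == pytest.approx(base + c, abs=1e-6)


def test_free_energy_constant_identity():
    """dG = kT ln(Nj/Ni) + C holds exactly at the returned solution."""
    s = synth_work(delta_f=2.0, sigma=2.0, n_forward=3000, n_reverse=1000, seed=2)
    res = bar_segment(s)
    kT = s.kT
    assert res.delta_g == kT * math.log(1000 / 3000) + res.c_constant


def test_unequal_sample_counts_still_recover_truth():
    s = synth_work(delta_f=2.0, sigma=2.0, n_forward=40000, n_reverse=10000, seed=6)
    res = bar_segment(s)
    assert res.delta_g == pytest.approx(2.0 * s.kT, abs=3 * res.std_error)


def test_antisymmetry_under_direction_swap():
    s = synth_work(delta_f=1.5, sigma=2.0, n_forward=5000, n_reverse=2000, seed=9)
    fwd = bar_segment(s).delta_g
    swapped = WorkSamples(forward=s.reverse, reverse=s.forward, temperature=s.temperature)
    assert bar_segment(swapped).delta_g == pytest.approx(-fwd, abs=1e-6)


def test_sample_order_and_duplication_invariance():
    s = synth_work(delta_f=1.0, sigma=1.0, n_forward=2000, n_reverse=2000, seed=13)
    base = bar_segment(s).delta_g
    rng = np.random.default_rng(0)
    shuffled = WorkSamples(forward=rng.permutation(s.forward),
                           reverse=rng.permutation(s.reverse),
                           temperature=s.temperature)
    doubled = WorkSamples(forward=np.tile(s.forward, 2), reverse=np.tile(s.reverse, 2),
                          temperature=s.temperature)
    assert bar_segment(shuffled).delta_g == pytest.approx(base, abs=1e-7)
    assert bar_segment(doubled).delta_g == pytest.approx(base, abs=1e-7)


def test_one_sided_limit_reduces_to_forward_zwanzig():
    """With reverse samples far above the forward work and the shift constant
    pushed below the forward support, the single-pass estimate collapses to
    exponential averaging of the forward samples."""
    rng = np.random.default_rng(3)
    fwd = rng.normal(1.0, 1.0, size=5000) * KT300
    rev = rng.normal(80.0, 1.0, size=5000) * KT300  # >> kT above forward
    s = WorkSamples(forward=fwd, reverse=rev, temperature=300.0)
    c = -120.0 * KT300  # below -max(reverse), so every reverse Fermi weight is ~1
    assert bar_at(s, c) == pytest.approx(zwanzig(fwd, 300.0), abs=0.1 * KT300)


def test_bar_total_path():
    segs = [synth_work(delta_f=1.0, sigma=1.0, n_forward=2000, n_reverse=2000, seed=s)
            for s in range(5)]
    path = bar_total(segs)
    assert len(path.lambdas) == 6
    assert path.lambdas[0] == 0.0 and path.lambdas[-1] == 1.0
    assert path.delta_g == pytest.approx(sum(r.delta_g for r in path.segments))
    # identical segments: total is n copies of one estimate
    same = bar_total([segs[0]] * 5)
    one = bar_segment(segs[0]).delta_g
    assert same.delta_g == pytest.approx(5 * one, abs=5e-6)


def test_bar_total_additive_over_concatenation():
    segs = [synth_work(delta_f=0.5, sigma=1.0, n_forward=1500, n_reverse=1500, seed=s)
            for s in range(4)]
    whole = bar_total(segs).delta_g
    first = sum(bar_segment(s).delta_g for s in segs[:2])
    second = sum(bar_segment(s).delta_g for s in segs[2:])
    assert whole == pytest.approx(first + second, abs=1e-9)


def test_bar_total_count_mismatch():
    segs = [synth_work(delta_f=1.0, sigma=1.0, n_forward=100, n_reverse=100, seed=0)]
    with pytest.raises(PepGCMError):
        bar_total(segs, lambdas=[0.0, 0.5, 0.75, 1.0])


def test_overlap_extremes_and_selfconsistency():
    rng = np.random.default_rng(12)
    x = rng.normal(0, 1, size=5000)
    assert overlap(x, x.copy()) == pytest.approx(1.0)
    assert overlap(x, x + 1000.0) == pytest.approx(0.0, abs=1e-12)
    with pytest.raises(EmptyDatasetError):
        overlap(x, np.array([]))
    with pytest.raises(DomainError):
        overlap(x, x, n_bins=1)


def test_overlap_identical_distributions_scores_high():
    rng = np.random.default_rng(5)
    a = rng.normal(0, 1, size=100_000)
    b = rng.normal(0, 1, size=100_000)
    assert overlap(a, b, n_bins=50) >= 0.95


def test_synth_work_moments_and_validation():
    n = 100_000
    s = synth_work(delta_f=1.0, sigma=2.0, n_forward=n, n_reverse=n, seed=1)
    kT = s.kT
    se = 2.0 / math.sqrt(n)
    assert s.forward.mean() / kT == pytest.approx(1.0 + 2.0, abs=5 * se)
    assert s.reverse.mean() / kT == pytest.approx(-1.0 + 2.0, abs=5 * se)
    with pytest.raises(DomainError):
        synth_work(1.0, 0.0, 10, 10)
    with pytest.raises(DomainError):
        synth_work(1.0, 1.0, 0, 10)
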