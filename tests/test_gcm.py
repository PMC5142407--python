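"""Group-contribution energies, folding correction, and relative-error
validation."""

import pytest
from hypothesis import assume, given
from hypothesis import strategies as st

from pepgcm import (
    AlphaParameter,
    additive_sum,
    classify_residues,
    folding_correction,
    gcm_energy,
    predict,
    relative_error,
    turn_position_correlation,
    validate,
)
from pepgcm.errors import DomainError, EmptyDatasetError, SequenceTooShortError
from pepgcm.gcm import round_half_up

sequences = st.text(alphabet=sorted("ACDEFGHIKLMNPQRSTVWY"), min_size=2, max_size=30)


@pytest.mark.parametrize(
    "seq,expected",
    [("A", -164.27), ("AA", -328.54), ("AW", -333.05)],
)
def test_additive_sum(params, seq, expected):
    assert additive_sum(params, seq) == pytest.approx(expected, abs=1e-9)


def test_gcm_energy_dipeptide_modes(params):
    cls = classify_residues(params, "AA")
    assert gcm_energy(params, cls, "as_printed") == pytest.approx(2 * -164.27 / 8.42)
    assert round(gcm_energy(params, cls, "as_printed"), 2) == -39.02
    assert gcm_energy(params, cls, "reciprocal") == pytest.approx(2 * -164.27 * 8.42 / 100)
    assert round(gcm_energy(params, cls, "reciprocal"), 2) == -27.66


@given(seq=sequences)
def test_grouped_counts_equal_per_position_sum(params, seq):
    cls = classify_residues(params, seq)
    per_position = sum(
        params.dg(code) / params.alpha(code, label)
        for code, label in zip(cls.sequence, cls.classes)
    )
    assert gcm_energy(params, cls) == pytest.approx(per_position, rel=1e-12)


@given(seq=sequences)
def test_mode_equivalence_under_inverted_alphas(params, seq):
    """as_printed under alpha' = 100/alpha equals reciprocal under alpha."""
    inverted = params.with_alphas(
        [AlphaParameter(a.code, a.cls, 100.0 / a.alpha) for a in params.alphas.values()]
    )
    cls = classify_residues(params, seq)
    assert gcm_energy(inverted, cls, "as_printed") == pytest.approx(
        gcm_energy(params, cls, "reciprocal"), rel=1e-12
    )


@given(seq=sequences, extra=st.sampled_from(sorted("ACDEFGHIKLMNPQRSTVWY")))
def test_appending_a_residue_lowers_energy(params, seq, extra):
    """Extending a peptide adds a strictly negative term whenever the
    extension leaves the existing class labels untouched. (Appending may
    also reclassify the former terminal residue, in which case the total can
    move either way, so the monotone claim is restricted to the
    class-preserving case.)"""
    base_cls = classify_residues(params, seq)
    ext_cls = classify_residues(params, seq + extra)
    assume(ext_cls.classes[: len(seq)] == base_cls.classes)
    for mode in ("as_printed", "reciprocal"):
        assert gcm_energy(params, ext_cls, mode) < gcm_energy(params, base_cls, mode)


def test_turn_position_correlation(params):
    # propensities strictly increasing along ILE->VAL->LEU->MET->PHE? use a
    # designed run: I (0.47) < V (0.50) < L (0.59) < M (0.60) < C (1.19)
    assert turn_position_correlation(params, "IVLMC") > 0.8
    assert turn_position_correlation(params, "AAAA") == 0.0
    fwd = turn_position_correlation(params, "IVLMC")
    assert turn_position_correlation(params, "CMLVI") == pytest.approx(-fwd, rel=1e-12)
    with pytest.raises(SequenceTooShortError):
        turn_position_correlation(params, "A")


def test_perfect_affine_propensity_gives_unit_correlation(params, tmp_path):
    """A sequence whose turn propensities are an affine function of position
    correlates exactly +1 (and -1 when reversed)."""
    from pepgcm import load_parameters, write_parameters

    write_parameters(params, tmp_path)
    path = tmp_path / "residues.csv"
    rows = []
    scale = {code: float(10 + i) for i, code in enumerate(sorted(params.residues))}
    for line in path.read_text().splitlines():
        if line.startswith("code"):
            rows.append(line)
            continue
        parts = line.split(",")
        parts[5] = f"{scale[parts[0]]:.2f}"
        rows.append(",".join(parts))
    path.write_text("\n".join(rows))
    affine = load_parameters(tmp_path)
    seq = "".join(sorted(params.residues))  # propensity == position + 9
    assert turn_position_correlation(affine, seq) == pytest.approx(1.0)
    assert turn_position_correlation(affine, seq[::-1]) == pytest.approx(-1.0)


@pytest.mark.parametrize(
    "r,expected",
    [(0.40, 0.0), (0.39, 0.0), (-0.9, 0.0), (0.5, 59.8), (1.0, 206.2)],
)
def test_folding_correction_values(params, r, expected):
    assert folding_correction(params.constants, r) == pytest.approx(expected)


def test_folding_correction_domain(params):
    with pytest.raises(DomainError):
        folding_correction(params.constants, 1.5)


def test_predict_composition(params):
    res = predict(params, "AA", mode="as_printed", correction_sign="off")
    assert res.final_energy == pytest.approx(res.gcm_energy)
    assert round(res.final_energy, 2) == -39.02
    assert res.additive_sum == pytest.approx(-328.54)
    assert res.folding_correction == 0.0


@given(seq=sequences, sign=st.sampled_from(["add", "subtract", "off"]))
def test_predict_final_energy_identity(params, seq, sign):
    res = predict(params, seq, correction_sign=sign)
    assert res.folding_correction >= 0.0
    if sign == "add":
        assert res.final_energy == res.gcm_energy + res.folding_correction
    elif sign == "subtract":
        assert res.final_energy == res.gcm_energy - res.folding_correction
    else:
        assert res.final_energy == res.gcm_energy
    if res.pearson_r <= params.constants.pearson_threshold:
        assert res.final_energy == res.gcm_energy


def test_predict_reference_decapeptide_classification(params):
    res = predict(params, "KLGWSQYHDT")
    assert list(res.classification.classes) == [
        "C2", "C1", "C1", "C2", "C1", "C1", "C1", "C1", "C1", "C1",
    ]


@pytest.mark.parametrize(
    "sim,calc,expected",
    [(-489.5, -541.3, 10.6), (-8561.7, -14821.8, 73.1), (-100.0, -100.0, 0.0)],
)
def test_relative_error_examples(sim, calc, expected):
    assert round_half_up(relative_error(sim, calc), 1) == pytest.approx(expected)


def test_relative_error_zero_denominator():
    with pytest.raises(DomainError):
        relative_error(0.0, -5.0)


@given(
    a=st.floats(-1e4, 1e4).filter(lambda v: abs(v) > 1e-3),
    b=st.floats(-1e4, 1e4),
    c=st.floats(-100, 100).filter(lambda v: abs(v) > 1e-3),
)
def test_relative_error_scale_invariant(a, b, c):
    assert relative_error(c * a, c * b) == pytest.approx(relative_error(a, b), rel=1e-9)


def test_validate_reference_table(reference):
    peptides = reference[reference.id != "OmpA"]
    report = validate(list(zip(peptides.id, peptides.dg_simulated_kjmol, peptides.dg_calculated_kjmol)))
    assert round_half_up(report.mean_error_pct) == 16
    assert round_half_up(report.max_error_pct, 1) == 49.6
    assert report.min_error_pct <= report.mean_error_pct <= report.max_error_pct


def test_validate_degenerate_cases():
    report = validate([("only", -50.0, -50.0)])
    assert report.mean_error_pct == report.min_error_pct == report.max_error_pct == 0.0
    with pytest.raises(EmptyDatasetError):
        validate([])
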