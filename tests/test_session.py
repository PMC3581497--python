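"""Session orchestration, group statistics, dose-response, I/O and CLI."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats

from slowphase.metrics import InsufficientDataError
from slowphase.session import (MeasureDelta, SessionData, SessionResult,
                               compare_groups, dose_response, run_session,
                               sessions_to_frame, simulate_session,
                               t_from_summary)


def _result(deltas: dict, treatment="saline", volume=None, animal="a",
            pre=0.5) -> SessionResult:
    measures = {k: MeasureDelta(pre=pre, post=pre + d, n_pre=3, n_post=3)
                for k, d in deltas.items()}
    return SessionResult(animal=animal, cohort="young_mutant",
                         treatment=treatment, injection_volume=volume,
                         measures=measures)


# ---------------------------------------------------------------------------
# run_session
# ---------------------------------------------------------------------------

def test_null_session_deltas_near_zero():
    data = simulate_session(seed=1, stimuli=("vvor",), n_records=2)
    res = run_session(data)
    assert res.measures["vvor_gain"].delta == pytest.approx(0.0, abs=0.02)
    assert res.missing_phases == ()


def test_habituation_only_session():
    data = simulate_session(seed=2, stimuli=("vvor",), n_records=2,
                            habituation=-0.06)
    res = run_session(data)
    assert res.measures["vvor_gain"].delta == pytest.approx(-0.06, abs=0.02)


def test_treatment_on_top_of_habituation():
    data = simulate_session(seed=3, stimuli=("vvor",), n_records=2,
                            habituation=-0.06, treatment_effect=0.08,
                            treatment="drug_systemic")
    res = run_session(data)
    assert res.measures["vvor_gain"].delta == pytest.approx(0.02, abs=0.02)


def test_missing_phase_reported_not_fatal():
    data = simulate_session(seed=4, stimuli=("vvor",), n_records=1)
    data.records["post"] = []
    res = run_session(data)
    assert "post" in res.missing_phases
    assert math.isnan(res.measures["vvor_gain"].post)
    assert math.isnan(res.measures["vvor_gain"].delta)


def test_delta_antisymmetry_and_translation_invariance():
    md = MeasureDelta(pre=0.41, post=0.35)
    flipped = MeasureDelta(pre=md.post, post=md.pre)
    assert flipped.delta == pytest.approx(-md.delta)
    shifted = MeasureDelta(pre=md.pre + 1.0, post=md.post + 1.0)
    assert shifted.delta == pytest.approx(md.delta)


def test_pipeline_determinism():
    a = sessions_to_frame([run_session(simulate_session(seed=7, n_records=1))])
    b = sessions_to_frame([run_session(simulate_session(seed=7, n_records=1))])
    assert a.equals(b)


def test_session_vocabularies_enforced():
    with pytest.raises(ValueError):
        SessionData(animal="x", cohort="nope", treatment="saline", records={})
    with pytest.raises(ValueError):
        SessionData(animal="x", cohort="control", treatment="nope", records={})


# ---------------------------------------------------------------------------
# compare_groups
# ---------------------------------------------------------------------------

def test_identical_groups_t_zero_p_one():
    results = ([_result({"g": 0.1}, "saline") for _ in range(3)]
               + [_result({"g": 0.1}, "drug_systemic") for _ in range(3)])
    cmp = compare_groups(results, "g")
    assert cmp.t == 0.0
    assert cmp.p == 1.0
    assert cmp.degenerate


def test_summary_statistic_formula_matches_direct_computation():
    """Drawing samples that realize the reported means/SDs exactly, the
    p from the summary-statistic t formula equals scipy's direct test."""
    rng = np.random.default_rng(0)

    def sample(mean, sd, n):
        x = rng.normal(size=n)
        x = (x - x.mean()) / x.std(ddof=1)
        return mean + sd * x

    a = sample(-0.060, 0.060, 10)
    b = sample(+0.019, 0.076, 15)
    t_direct, p_direct = stats.ttest_ind(a, b)
    t_sum, p_sum = t_from_summary(a.mean(), a.std(ddof=1), len(a),
                                  b.mean(), b.std(ddof=1), len(b))
    assert t_sum == pytest.approx(t_direct, abs=1e-10)
    assert p_sum == pytest.approx(p_direct, abs=1e-10)

    results = ([_result({"g": v}, "saline") for v in a]
               + [_result({"g": v}, "drug_systemic") for v in b])
    cmp = compare_groups(results, "g")
    assert cmp.p == pytest.approx(p_direct, abs=1e-10)
    assert cmp.p < 0.05  # the habituation contrast is detectable


def test_compare_groups_agrees_with_permutation_reference():
    """On a small instance the t-test p is close to the exhaustive
    permutation p (sanity bound, not equality)."""
    a = [0.30, 0.25, 0.28, 0.33]
    b = [0.10, 0.15, 0.05, 0.12]
    results = ([_result({"g": v}, "saline") for v in a]
               + [_result({"g": v}, "drug_systemic") for v in b])
    cmp = compare_groups(results, "g")
    pooled = np.array(a + b)
    obs = abs(np.mean(a) - np.mean(b))
    count = 0
    combos = list(itertools.combinations(range(8), 4))
    for idx in combos:
        sel = np.zeros(8, dtype=bool)
        sel[list(idx)] = True
        if abs(pooled[sel].mean() - pooled[~sel].mean()) >= obs - 1e-12:
            count += 1
    p_perm = count / len(combos)
    assert abs(cmp.p - p_perm) < 0.15
    assert (cmp.p < 0.05) == (p_perm < 0.05)


def test_paired_constant_shift_is_degenerate():
    pre = [0.4, 0.5, 0.6]
    post = [v + 0.1 for v in pre]
    results = ([_result({"g": v}, "saline") for v in post]
               + [_result({"g": v}, "drug_systemic") for v in pre])
    cmp = compare_groups(results, "g", test="paired")
    assert cmp.degenerate
    assert cmp.p == 0.0 and math.isinf(cmp.t)


def test_excluded_sessions_are_skipped():
    results = ([_result({"g": 0.1}, "saline") for _ in range(3)]
               + [_result({"g": 0.3}, "drug_systemic") for _ in range(3)])
    results[0].excluded = True
    results[0].exclusion_reason = "anomalous pre-treatment gain"
    cmp = compare_groups(results, "g")
    assert cmp.ns == (2, 3) or cmp.ns == (3, 2)


def test_compare_groups_needs_two_groups():
    results = [_result({"g": 0.1}, "saline") for _ in range(4)]
    with pytest.raises(ValueError, match="two groups"):
        compare_groups(results, "g")


# ---------------------------------------------------------------------------
# dose-response
# ---------------------------------------------------------------------------

def test_exact_line_has_r2_one():
    results = [_result({"resting_v": 0.001 * v}, "drug_intrafloccular", volume=v)
               for v in (10.0, 100.0, 300.0, 700.0)]
    fit = dose_response(results, "resting_v")
    assert fit.r2 == pytest.approx(1.0, abs=1e-12)
    assert fit.slope == pytest.approx(0.001, rel=1e-9)


def test_degenerate_volumes_rejected():
    results = [_result({"g": 0.1}, "drug_intrafloccular", volume=100.0)
               for _ in range(4)]
    with pytest.raises(ValueError, match="identical"):
        dose_response(results, "g")
    with pytest.raises(InsufficientDataError):
        dose_response(results[:2], "g")


def test_saline_reference_band():
    rng = np.random.default_rng(1)
    controls = [_result({"g": float(rng.normal(-0.05, 0.02))}, "saline")
                for _ in range(10)]
    results = [_result({"g": 0.0}, "drug_intrafloccular", volume=v)
               for v in (10.0, 50.0, 200.0)]
    fit = dose_response(results, "g", controls=controls)
    lo, hi = fit.saline_band
    assert lo < fit.saline_mean < hi
    assert hi - lo == pytest.approx(4 * np.std(
        [c.measures["g"].delta for c in controls], ddof=1), rel=1e-9)


# ---------------------------------------------------------------------------
# file I/O and CLI
# ---------------------------------------------------------------------------

def test_manifest_round_trip(tmp_path):
    import yaml

    from slowphase.io import load_manifest, write_record
    from slowphase.simulate import SimTruth, simulate_sinusoidal_record
    from slowphase.stimuli import vvor_spec

    files = {}
    for phase, seed in (("pre", 1), ("post", 2)):
        rec = simulate_sinusoidal_record(vvor_spec(), SimTruth(gain=0.5, seed=seed))
        name = f"{phase}.tsv"
        write_record(rec, tmp_path / name)
        files[phase] = [name]
    manifest = {"sessions": [{
        "animal": "tg01", "cohort": "young_mutant", "treatment": "saline",
        "records": files}]}
    (tmp_path / "manifest.yaml").write_text(yaml.safe_dump(manifest))
    sessions = load_manifest(tmp_path / "manifest.yaml")
    assert len(sessions) == 1
    res = run_session(sessions[0])
    assert res.measures["vvor_gain"].delta == pytest.approx(0.0, abs=0.02)


def test_cli_pk_and_simulate_analyze(tmp_path):
    from click.testing import CliRunner

    from slowphase.cli import main

    runner = CliRunner()
    out = runner.invoke(main, ["pk", "--diameter", "100"])
    assert out.exit_code == 0
    assert "523.6" in out.output
    assert "1207" in out.output or "1206" in out.output
    assert "2.69" in out.output

    rec_path = tmp_path / "rec.tsv"
    out = runner.invoke(main, ["simulate", "--kind", "okr-roll",
                               "--gain", "0.5", "--seed", "3",
                               "--out", str(rec_path)])
    assert out.exit_code == 0, out.output
    out = runner.invoke(main, ["analyze", "--record", str(rec_path)])
    assert out.exit_code == 0, out.output
    assert "gain" in out.output
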