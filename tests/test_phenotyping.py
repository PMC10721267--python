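"""Gating rules, percentile gates, cytokine positivity and the frequency formula."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from iartcr import phenotyping, simulate
from iartcr.phenotyping import GateError

THR = {m: 100.0 for m in ["CD45RA", "CCR7", "CD95", "CXCR3", "CCR4", "CCR6",
                          "CD4", "CD45RO", "FOXP3", "CD25", "CD127", "CD137", "GMCSF"]}
THR["CD2_hi"] = 1000.0

HI, LO = 500.0, 10.0


def _event(**markers):
    base = {m: LO for m in THR if m != "CD2_hi"}
    base["CD2"] = LO
    base.update(markers)
    return base


@pytest.mark.parametrize(
    "markers,expected",
    [
        (dict(CD45RA=HI, CCR7=HI), "naive"),
        (dict(CD45RA=HI, CCR7=HI, CD95=HI), "TSCM"),
        (dict(CCR7=HI), "TCM"),
        (dict(), "TEM"),
        (dict(CD45RA=HI), "TEM"),  # CD45RA+ CCR7- folded into TEM
    ],
)
def test_maturation_rules(markers, expected):
    events = pd.DataFrame([_event(**markers)])
    assert phenotyping.classify_maturation(events, THR).iloc[0] == expected


def test_maturation_missing_marker_is_named():
    with pytest.raises(GateError, match="CD95"):
        phenotyping.classify_maturation(pd.DataFrame([{"CD45RA": 1, "CCR7": 1}]), THR)


@pytest.mark.parametrize(
    "markers,expected",
    [
        (dict(CXCR3=HI), "Th1"),
        (dict(CCR4=HI), "Th2"),
        (dict(CCR4=HI, CCR6=HI), "Th17"),
        (dict(CXCR3=HI, CCR4=HI, CCR6=HI), "Th17"),
        (dict(CXCR3=HI, CCR6=HI), "Th1_17"),
        (dict(CXCR3=HI, CCR4=HI), "other"),  # combination with no stated rule
        (dict(CCR6=HI), "other"),
    ],
)
def test_th_rules(markers, expected):
    events = pd.DataFrame([_event(**markers)])
    assert phenotyping.classify_th(events, THR).iloc[0] == expected


def test_th_rejects_naive_events():
    events = pd.DataFrame([_event(CD45RA=HI, CCR7=HI)])
    mat = phenotyping.classify_maturation(events, THR)
    with pytest.raises(GateError, match="naive"):
        phenotyping.classify_th(events, THR, maturation=mat)


def test_cluster3_gate_conjunction():
    positive = _event(CD4=HI, CD45RO=HI, CD25=HI, CD137=HI, CD2=2000.0)
    assert phenotyping.gate_cluster3_like(pd.DataFrame([positive]), THR).iloc[0]
    for flip in [dict(CD127=HI), dict(CD45RA=HI), dict(CD2=500.0), dict(FOXP3=HI)]:
        assert not phenotyping.gate_cluster3_like(pd.DataFrame([{**positive, **flip}]), THR).iloc[0]


def test_cluster3_gate_recall_precision(thresholds):
    cfg = simulate.SimConfig(seed=31)
    events = simulate.generate_flow_events(cfg, n_events=4000)
    flag = phenotyping.gate_cluster3_like(events, thresholds)
    truth = events["population"] == "cluster3_like"
    recall = (flag & truth).sum() / truth.sum()
    precision = (flag & truth).sum() / flag.sum()
    assert recall >= 0.9
    assert precision >= 0.9


def test_percentile_gate_cutoffs_and_inclusivity():
    ref = pd.DataFrame({"X": np.arange(1.0, 101.0)})
    labels, (lo, hi) = phenotyping.percentile_gate(ref, "X")
    assert lo == pytest.approx(np.percentile(np.arange(1.0, 101.0), 25))
    assert hi == pytest.approx(np.percentile(np.arange(1.0, 101.0), 75))
    probe = pd.DataFrame({"X": [lo, lo + 1e-9, hi, hi - 1e-9]})
    plabels, _ = phenotyping.percentile_gate(probe, "X", reference=ref)
    assert plabels.tolist() == ["lo", "mid", "hi", "mid"]
    # continuous reference: about a quarter of the reference in each tail
    assert (labels == "lo").mean() == pytest.approx(0.25, abs=0.01)
    assert (labels == "hi").mean() == pytest.approx(0.25, abs=0.01)


def test_percentile_gate_degenerate_and_errors():
    flat = pd.DataFrame({"X": np.ones(50)})
    with pytest.warns(UserWarning, match="degenerate"):
        labels, _ = phenotyping.percentile_gate(flat, "X")
    assert (labels == "mid").all()
    with pytest.raises(GateError, match="at least 4"):
        phenotyping.percentile_gate(pd.DataFrame({"X": [1.0, 2.0]}), "X")
    with pytest.raises(GateError, match="empty"):
        phenotyping.percentile_gate(flat, "X", reference=pd.DataFrame({"X": []}))


def test_percentile_gate_shifted_population_monotonicity(rng):
    ref = pd.DataFrame({"X": rng.normal(0, 1, 4000)})
    shifted = pd.DataFrame({"X": rng.normal(1.0, 1, 4000)})
    labels, _ = phenotyping.percentile_gate(shifted, "X", reference=ref)
    assert (labels == "hi").mean() > 0.25


def test_cytokine_positivity_null_and_shifted(rng):
    unstim = pd.DataFrame({"GMCSF": rng.normal(0, 1, 20_000)})
    stim_same = pd.DataFrame({"GMCSF": rng.normal(0, 1, 20_000)})
    frac, cutoff = phenotyping.cytokine_positivity(stim_same, unstim, "GMCSF", q=0.999)
    assert frac == pytest.approx(0.001, abs=0.001)
    stim_hi = pd.DataFrame({"GMCSF": rng.normal(8.0, 1, 5000)})
    frac_hi, _ = phenotyping.cytokine_positivity(stim_hi, unstim, "GMCSF", q=0.999)
    assert frac_hi > 0.99
    with pytest.raises(GateError, match="at least 100"):
        phenotyping.cytokine_positivity(stim_hi, unstim.iloc[:50], "GMCSF")
    with pytest.raises(GateError, match="TNFA"):
        phenotyping.cytokine_positivity(stim_hi, unstim, "TNFA")


def test_cytokine_coupling_recovered(thresholds):
    """BHLHE40-high memory events show higher GM-CSF positivity than
    BHLHE40-low events when a coupling is planted."""
    cfg = simulate.SimConfig(seed=32)
    events = simulate.generate_flow_events(cfg, n_events=6000)
    unstim = simulate.generate_flow_events(cfg, n_events=3000, stimulated=False)
    gate, _ = phenotyping.percentile_gate(events, "BHLHE40")
    hi_frac, _ = phenotyping.cytokine_positivity(events[gate == "hi"], unstim, "GMCSF")
    lo_frac, _ = phenotyping.cytokine_positivity(events[gate == "lo"], unstim, "GMCSF")
    assert hi_frac > lo_frac


def test_reactive_frequency_examples_and_errors():
    assert phenotyping.reactive_frequency(50, 100_000, 10) == 50.0
    assert phenotyping.reactive_frequency(0, 12_345, 3.3) == 0.0
    with pytest.raises(ValueError):
        phenotyping.reactive_frequency(5, 0, 1)
    with pytest.raises(ValueError):
        phenotyping.reactive_frequency(5, 100, 0)
    with pytest.raises(ValueError):
        phenotyping.reactive_frequency(-1, 100, 1)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    n=st.integers(0, 10_000),
    pre=st.integers(1, 10**7),
    dil=st.floats(0.1, 100, allow_nan=False),
)
def test_reactive_frequency_linearity_and_homogeneity(n, pre, dil):
    f = phenotyping.reactive_frequency(n, pre, dil)
    assert phenotyping.reactive_frequency(2 * n, pre, dil) == pytest.approx(2 * f)
    assert phenotyping.reactive_frequency(n, pre, 2 * dil) == pytest.approx(f / 2)


def test_population_frequencies_sum_to_one(thresholds):
    cfg = simulate.SimConfig(seed=33)
    events = simulate.generate_flow_events(cfg, n_events=1500)
    mat = phenotyping.population_frequencies(events, thresholds, "maturation")
    assert mat["fraction"].sum() == pytest.approx(1.0, abs=1e-12)
    th = phenotyping.population_frequencies(events, thresholds, "th")
    assert th["fraction"].sum() == pytest.approx(1.0, abs=1e-12)
    assert (th["denominator"] == "memory").all()


def test_population_frequencies_four_event_fixture():
    events = pd.DataFrame(
        [
            _event(CD45RA=HI, CCR7=HI),
            _event(CD45RA=HI, CCR7=HI, CD95=HI),
            _event(CCR7=HI),
            _event(),
        ]
    )
    out = phenotyping.population_frequencies(events, THR, "maturation")
    assert (out["fraction"] == 0.25).all()


def test_population_frequencies_match_truth(thresholds):
    cfg = simulate.SimConfig(seed=34)
    events = simulate.generate_flow_events(
        cfg, n_events=4000, composition={"naive": 0.3, "TSCM": 0.1, "TCM": 0.4, "TEM": 0.2}
    )
    out = phenotyping.population_frequencies(events, thresholds, "maturation").set_index("population")
    truth = events["population"].value_counts(normalize=True)
    for pop in ("naive", "TSCM", "TCM", "TEM"):
        assert out.loc[pop, "fraction"] == pytest.approx(truth[pop], abs=0.03)


def test_custom_gate_set_overlap_is_rejected():
    events = pd.DataFrame({"X": [1.0, 2.0, 3.0]})
    with pytest.raises(GateError, match="partition"):
        phenotyping.population_frequencies(
            events, gate_set={"a": [True, True, False], "b": [True, False, True]}
        )
    ok = phenotyping.population_frequencies(
        events, gate_set={"a": [True, False, False], "b": [False, True, True]}
    )
    assert ok["fraction"].sum() == pytest.approx(1.0)
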