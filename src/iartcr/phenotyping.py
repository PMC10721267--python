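"""Flow-style gating classifications and the antigen-reactive frequency formula.

Events are rows of a DataFrame whose columns are marker intensities in
arbitrary fluorescence units; thresholds are a flat mapping from marker name
to positivity cutoff (with ``"CD2_hi"`` as a separate, higher cutoff for the
CD2-bright gate). All gates are deterministic and order-independent.

Gating conventions:

* maturation (CD45RA / CCR7 / CD95): naive = RA+ CCR7+ CD95-,
  TSCM = RA+ CCR7+ CD95+, TCM = RA- CCR7+, TEM = RA- CCR7-. CD95 is not
  consulted for TCM/TEM, and the rare CD45RA+ CCR7- combination is folded
  into TEM so the gate set stays exhaustive.
* T helper polarization (CXCR3 / CCR4 / CCR6), applied to memory cells only:
  Th1 = CXCR3+ CCR4- CCR6-, Th2 = CCR4+ CCR6- CXCR3-, Th17 = CCR4+ CCR6+,
  Th1/17 = CXCR3+ CCR6+ CCR4-; anything else is "other". The CXCR3+ CCR4+
  CCR6- combination is deliberately left unclassified.
* cluster-3-like: CD4+ CD45RA- CD45RO+ FOXP3- CD2hi CD25+ CD127- CD137+.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "GateError",
    "FrequencyInput",
    "classify_maturation",
    "classify_th",
    "gate_cluster3_like",
    "percentile_gate",
    "cytokine_positivity",
    "reactive_frequency",
    "population_frequencies",
    "MATURATION_CLASSES",
    "TH_CLASSES",
]

MATURATION_CLASSES = ("naive", "TSCM", "TCM", "TEM")
TH_CLASSES = ("Th1", "Th2", "Th17", "Th1_17", "other")


class GateError(ValueError):
    pass


def _marker(events: pd.DataFrame, thresholds, name: str) -> tuple[pd.Series, float]:
    if name not in events.columns:
        raise GateError(f"events table is missing marker {name}")
    if name not in thresholds:
        raise GateError(f"no threshold configured for marker {name}")
    values = pd.to_numeric(events[name], errors="coerce")
    if values.isna().any() or np.isinf(values).any():
        raise GateError(f"non-finite intensities for marker {name}")
    return values, float(thresholds[name])


def classify_maturation(events: pd.DataFrame, thresholds) -> pd.Series:
    """Label each event naive / TSCM / TCM / TEM from CD45RA, CCR7 and CD95."""
    ra, ra_cut = _marker(events, thresholds, "CD45RA")
    ccr7, ccr7_cut = _marker(events, thresholds, "CCR7")
    cd95, cd95_cut = _marker(events, thresholds, "CD95")
    ra_pos = ra > ra_cut
    ccr7_pos = ccr7 > ccr7_cut
    cd95_pos = cd95 > cd95_cut
    labels = np.where(
        ra_pos & ccr7_pos,
        np.where(cd95_pos, "TSCM", "naive"),
        np.where(ccr7_pos, "TCM", "TEM"),
    )
    return pd.Series(labels, index=events.index, name="maturation")


def classify_th(events: pd.DataFrame, thresholds, maturation=None) -> pd.Series:
    """Label memory events Th1 / Th2 / Th17 / Th1_17 / other.

    Th subsets are defined as frequencies of *memory* cells; passing events
    labeled naive (via ``maturation``) is a contract violation and raises.
    """
    if maturation is not None:
        mat = pd.Series(maturation)
        if (mat == "naive").any():
            raise GateError("classify_th received naive events; gate memory cells only")
    x, x_cut = _marker(events, thresholds, "CXCR3")
    c4, c4_cut = _marker(events, thresholds, "CCR4")
    c6, c6_cut = _marker(events, thresholds, "CCR6")
    xp, c4p, c6p = x > x_cut, c4 > c4_cut, c6 > c6_cut
    labels = np.full(len(events), "other", dtype=object)
    labels[xp & ~c4p & ~c6p] = "Th1"
    labels[~xp & c4p & ~c6p] = "Th2"
    labels[c4p & c6p] = "Th17"
    labels[xp & ~c4p & c6p] = "Th1_17"
    return pd.Series(labels, index=events.index, name="th_subset")


def gate_cluster3_like(events: pd.DataFrame, thresholds) -> pd.Series:
    """The cluster-3-like surface gate (conjunction of eight conditions)."""
    cd4, cd4_cut = _marker(events, thresholds, "CD4")
    ra, ra_cut = _marker(events, thresholds, "CD45RA")
    ro, ro_cut = _marker(events, thresholds, "CD45RO")
    foxp3, foxp3_cut = _marker(events, thresholds, "FOXP3")
    cd25, cd25_cut = _marker(events, thresholds, "CD25")
    cd127, cd127_cut = _marker(events, thresholds, "CD127")
    cd137, cd137_cut = _marker(events, thresholds, "CD137")
    if "CD2" not in events.columns:
        raise GateError("events table is missing marker CD2")
    if "CD2_hi" not in thresholds:
        raise GateError("no threshold configured for marker CD2_hi")
    cd2 = pd.to_numeric(events["CD2"], errors="coerce")
    flag = (
        (cd4 > cd4_cut)
        & (ra <= ra_cut)
        & (ro > ro_cut)
        & (foxp3 <= foxp3_cut)
        & (cd2 > float(thresholds["CD2_hi"]))
        & (cd25 > cd25_cut)
        & (cd127 <= cd127_cut)
        & (cd137 > cd137_cut)
    )
    return pd.Series(flag, index=events.index, name="cluster3_like")


def percentile_gate(
    events: pd.DataFrame,
    marker: str,
    lo_pct: float = 25,
    hi_pct: float = 75,
    reference: pd.DataFrame | None = None,
) -> tuple[pd.Series, tuple[float, float]]:
    """Three-way lo / mid / hi gate at reference-population percentiles.

    Cutoffs are linear-interpolation percentiles of the reference population
    (default: the events themselves); labels use inclusive boundaries, lo for
    values at or below the low cutoff and hi for values at or above the high
    cutoff. A degenerate reference (both cutoffs equal) labels everything mid
    with a warning.
    """
    ref = events if reference is None else reference
    if marker not in ref.columns or marker not in events.columns:
        raise GateError(f"events table is missing marker {marker}")
    ref_values = pd.to_numeric(ref[marker], errors="coerce").dropna()
    if len(ref_values) == 0:
        raise GateError("reference population is empty")
    if len(ref_values) < 4:
        raise GateError("reference population needs at least 4 events")
    lo_cut = float(np.percentile(ref_values, lo_pct))
    hi_cut = float(np.percentile(ref_values, hi_pct))
    values = pd.to_numeric(events[marker], errors="coerce")
    if lo_cut == hi_cut:
        warnings.warn("degenerate reference distribution: all events labeled mid")
        labels = np.full(len(events), "mid", dtype=object)
    else:
        labels = np.where(values <= lo_cut, "lo", np.where(values >= hi_cut, "hi", "mid"))
    return pd.Series(labels, index=events.index, name=f"{marker}_level"), (lo_cut, hi_cut)


def cytokine_positivity(
    stim_events: pd.DataFrame,
    unstim_events: pd.DataFrame,
    cytokine: str,
    q: float = 0.999,
) -> tuple[float, float]:
    """Fraction of stimulated events above a control-derived cutoff.

    The cutoff is the q-quantile of the unstimulated (no-stimulation)
    control for that cytokine, approximating manual gating on the control.
    """
    if cytokine not in unstim_events.columns:
        raise GateError(f"control is missing the {cytokine} channel")
    if cytokine not in stim_events.columns:
        raise GateError(f"stimulated events are missing the {cytokine} channel")
    control = pd.to_numeric(unstim_events[cytokine], errors="coerce").dropna()
    if len(control) < 100:
        raise GateError("unstimulated control needs at least 100 events")
    cutoff = float(np.quantile(control, q))
    stim = pd.to_numeric(stim_events[cytokine], errors="coerce").dropna()
    return float((stim > cutoff).mean()), cutoff


@dataclass(frozen=True)
class FrequencyInput:
    n_enriched: int
    n_pre_cd4: int
    dilution_factor: float


def reactive_frequency(
    n_enriched: int, n_pre_cd4: int, dilution_factor: float
) -> float:
    """Antigen-reactive cells per 10^6 CD4+ T cells.

    frequency = n_enriched * 1e6 / (n_pre_cd4 * dilution_factor), relating
    the enriched CD154+CD69+ count to the pre-enrichment CD4+ count.
    """
    if n_enriched < 0 or n_pre_cd4 < 0:
        raise ValueError("counts must be nonnegative")
    if dilution_factor <= 0:
        raise ValueError("dilution_factor must be positive")
    if n_pre_cd4 == 0:
        raise ValueError("n_pre_cd4 must be positive")
    return n_enriched * 1e6 / (n_pre_cd4 * dilution_factor)


def population_frequencies(
    events: pd.DataFrame,
    thresholds=None,
    gate_set: str | dict = "maturation",
) -> pd.DataFrame:
    """Per-population fractions for an exhaustive gate set.

    Built-in sets: ``"maturation"`` (denominator: all events given),
    ``"th"`` (denominator: memory events only; naive are excluded) and
    ``"cluster3"`` (binary gate). A custom dict of name -> boolean mask is
    checked for exhaustive non-overlap (each event in exactly one gate).
    """
    if isinstance(gate_set, dict):
        masks = {k: np.asarray(v, dtype=bool) for k, v in gate_set.items()}
        coverage = np.sum(list(masks.values()), axis=0)
        if np.any(coverage != 1):
            raise GateError("custom gate set is not an exhaustive partition of events")
        n = len(events)
        rows = [
            {"population": k, "n": int(m.sum()), "fraction": m.sum() / n, "denominator": "events"}
            for k, m in masks.items()
        ]
        return pd.DataFrame(rows)

    if gate_set == "maturation":
        labels = classify_maturation(events, thresholds)
        denom, denom_name = len(labels), "all"
        classes = MATURATION_CLASSES
    elif gate_set == "th":
        mat = classify_maturation(events, thresholds)
        memory = events[mat != "naive"]
        labels = classify_th(memory, thresholds)
        denom, denom_name = len(labels), "memory"
        classes = TH_CLASSES
    elif gate_set == "cluster3":
        flag = gate_cluster3_like(events, thresholds)
        return pd.DataFrame(
            [
                {
                    "population": "cluster3_like",
                    "n": int(flag.sum()),
                    "fraction": float(flag.mean()) if len(flag) else np.nan,
                    "denominator": "all",
                }
            ]
        )
    else:
        raise GateError(f"unknown gate set {gate_set!r}")
    if denom == 0:
        raise GateError("no events in the denominator population")
    rows = [
        {
            "population": c,
            "n": int((labels == c).sum()),
            "fraction": float((labels == c).mean()),
            "denominator": denom_name,
        }
        for c in classes
    ]
    return pd.DataFrame(rows)
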