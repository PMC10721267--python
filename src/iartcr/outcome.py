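"""C-peptide decay rates and immune-feature / outcome correlation screening.

The rate of C-peptide change per participant is the slope of an exponential
decay of the 2-hour AUC: an ordinary least squares fit of log(AUC) on time,
optionally shrunk toward the cohort mean by empirical-Bayes precision
weighting (a one-level analog of a random-effects model, with the
between-participant variance estimated by method of moments). Immune
features (cluster composition, gated cell frequencies) are correlated with
the rates by Spearman rank correlation with permutation p-values within
each treatment arm, and BH-adjusted within arm across each feature family.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import phenotyping
from .stats import bh_adjust, spearman_perm

__all__ = [
    "decay_rate",
    "cluster_fractions",
    "correlate_by_arm",
    "bh_adjust",
    "biomarker_screen",
    "ScreenResult",
]


def decay_rate(series: pd.DataFrame, shrink: bool = False) -> pd.DataFrame:
    """Per-participant exponential decay rate of the C-peptide 2-hour AUC.

    ``series`` is long format with columns participant_id, month, auc.
    Nonpositive AUC values are floored at half the smallest positive value
    in that participant's series (flagged in the output) before the log
    transform. With ``shrink=True`` slopes are shrunk toward the
    precision-weighted cohort mean.

    Returns participant_id, rate (per month), se, n_points, floored, method.
    """
    rows = []
    for pid, sub in series.groupby("participant_id", sort=True):
        sub = sub.sort_values("month")
        t = sub["month"].to_numpy(dtype=float)
        auc = sub["auc"].to_numpy(dtype=float)
        if t.size < 3:
            raise ValueError(f"participant {pid}: need at least 3 time points")
        if np.any(np.diff(t) <= 0):
            raise ValueError(f"participant {pid}: times must be strictly increasing")
        floored = False
        if np.any(auc <= 0):
            positive = auc[auc > 0]
            if positive.size == 0:
                raise ValueError(f"participant {pid}: no positive AUC values")
            floor = positive.min() / 2.0
            warnings.warn(f"participant {pid}: flooring nonpositive AUC at {floor:g}")
            auc = np.where(auc <= 0, floor, auc)
            floored = True
        y = np.log(auc)
        X = np.column_stack([np.ones_like(t), t])
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ coef
        df = t.size - 2
        sigma2 = float(resid @ resid) / df if df > 0 else 0.0
        sxx = float(((t - t.mean()) ** 2).sum())
        se = float(np.sqrt(sigma2 / sxx))
        rows.append(
            {
                "participant_id": pid,
                "rate": float(coef[1]),
                "se": se,
                "n_points": int(t.size),
                "floored": floored,
                "method": "ols",
            }
        )
    out = pd.DataFrame(rows)
    if shrink and len(out) >= 3:
        b = out["rate"].to_numpy()
        v = out["se"].to_numpy() ** 2
        tau2 = max(0.0, float(np.var(b, ddof=1) - v.mean()))
        denom = v + tau2
        if np.all(denom == 0):  # noiseless cohort with no spread: nothing to shrink
            return out
        w = np.where(denom > 0, 1.0 / np.where(denom > 0, denom, 1.0), np.inf)
        if np.any(np.isinf(w)):  # exact slopes dominate the cohort mean
            mu = float(b[np.isinf(w)].mean())
        else:
            mu = float(np.sum(w * b) / np.sum(w))
        out["rate"] = np.where(denom > 0, (tau2 * b + v * mu) / np.where(denom > 0, denom, 1.0), b)
        out["se"] = np.sqrt(np.where(denom > 0, (v * tau2) / np.where(denom > 0, denom, 1.0), 0.0))
        out["method"] = "shrunk"
    return out


def cluster_fractions(
    cell_table: pd.DataFrame, clusters=(1, 2, 3, 4, 5), min_cells: int = 10
) -> pd.DataFrame:
    """Per-participant fractional distribution of cells over clusters.

    ``cell_table`` needs columns participant_id and cluster. Fractions sum
    to 1 per participant; participants with fewer than ``min_cells`` cells
    are flagged.
    """
    if cell_table.empty:
        raise ValueError("cell table is empty")
    counts = (
        cell_table.groupby(["participant_id", "cluster"]).size().unstack(fill_value=0)
    )
    counts = counts.reindex(columns=list(clusters), fill_value=0)
    totals = counts.sum(axis=1)
    empty = totals[totals == 0].index.tolist()
    if empty:
        warnings.warn(f"omitting participants with no cells: {empty}")
        counts = counts[totals > 0]
        totals = totals[totals > 0]
    fractions = counts.div(totals, axis=0)
    fractions.columns = [f"cluster_{c}" for c in fractions.columns]
    fractions["n_cells"] = totals
    fractions["low_cell_count"] = totals < min_cells
    return fractions


def correlate_by_arm(
    features: pd.DataFrame,
    rates,
    arm_map,
    n_permutations: int = 10_000,
    seed=None,
    min_per_arm: int = 5,
    feature_families=None,
) -> pd.DataFrame:
    """Spearman correlation of each feature with the decay rate, per arm.

    ``features`` is indexed by participant with one column per feature;
    ``rates`` and ``arm_map`` are participant-keyed. P-values come from
    exhaustive permutation for arms of 10 or fewer participants and from
    10,000 seeded Monte Carlo permutations otherwise, and are BH-adjusted
    within arm across each feature family (default: all features are one
    family). Features constant within an arm give an undefined correlation,
    reported as missing and excluded from the adjustment.
    """
    rates = pd.Series(rates)
    arms = pd.Series(arm_map)
    missing = sorted(set(features.index) - set(rates.index))
    if missing:
        raise ValueError(f"participants missing a decay rate: {missing}")
    missing = sorted(set(features.index) - set(arms.index))
    if missing:
        raise ValueError(f"participants missing an arm assignment: {missing}")
    families = dict(feature_families or {})
    base = seed if seed is not None else 0

    def _child_seed(arm: str, feat: str):
        # stable per (arm, feature) so results do not depend on which other
        # features are screened alongside
        import hashlib

        digest = hashlib.sha256(f"{arm}|{feat}".encode()).digest()
        return np.random.SeedSequence([int(base), int.from_bytes(digest[:4], "big")])

    rows = []
    for arm in sorted(arms.unique()):
        pids = [p for p in features.index if arms[p] == arm]
        if len(pids) < min_per_arm:
            raise ValueError(f"arm {arm!r} has fewer than {min_per_arm} participants")
        r = rates[pids].to_numpy(dtype=float)
        for feat in features.columns:
            x = features.loc[pids, feat].to_numpy(dtype=float)
            res = spearman_perm(
                x, r, n_permutations=n_permutations, seed=_child_seed(arm, feat)
            )
            rows.append(
                {
                    "feature": feat,
                    "family": families.get(feat, "all"),
                    "arm": arm,
                    "rho": res.rho,
                    "p": res.p,
                    "n": res.n,
                    "method": res.method,
                    "n_permutations": res.n_permutations,
                }
            )
    out = pd.DataFrame(rows)
    out["q"] = np.nan
    for (_, _), idx in out.groupby(["arm", "family"]).groups.items():
        sub = out.loc[idx]
        ok = sub["p"].notna()
        if ok.any():
            out.loc[sub.index[ok], "q"] = bh_adjust(sub.loc[ok, "p"].to_numpy())
    return out


@dataclass
class ScreenResult:
    decay: pd.DataFrame
    features: pd.DataFrame
    correlations: pd.DataFrame
    flags: pd.DataFrame  # one row per feature with arm-specificity call


def biomarker_screen(
    cell_table: pd.DataFrame,
    cpeptide: pd.DataFrame,
    arm_map,
    flow_table: pd.DataFrame | None = None,
    thresholds=None,
    iar_frequency=None,
    shrink: bool = False,
    alpha: float = 0.05,
    n_permutations: int = 10_000,
    seed=None,
) -> ScreenResult:
    """End-to-end biomarker screen against the C-peptide decay rate.

    Computes per-participant decay rates and cluster fractions, optionally
    per-participant maturation-subset frequencies from a flow-event table
    (column participant_id required) and a supplied total antigen-reactive
    frequency, then correlates every feature with the rate within each arm.
    BH adjustment is within arm and feature family. A feature is flagged
    arm-specific when it is significant (q < alpha) in the treated arm and
    not in the placebo arm.
    """
    arms = pd.Series(arm_map)
    decay = decay_rate(cpeptide, shrink=shrink)
    rates = decay.set_index("participant_id")["rate"]

    frac = cluster_fractions(cell_table)
    feature_cols = [c for c in frac.columns if c.startswith("cluster_")]
    features = frac[feature_cols].copy()
    families = {c: "cluster_fraction" for c in feature_cols}

    if flow_table is not None:
        if "participant_id" not in flow_table.columns:
            raise ValueError("flow table needs a participant_id column")
        if thresholds is None:
            raise ValueError("thresholds are required with a flow table")
        mat = phenotyping.classify_maturation(flow_table, thresholds)
        tab = (
            pd.crosstab(flow_table["participant_id"], mat, normalize="index")
            .reindex(columns=list(phenotyping.MATURATION_CLASSES), fill_value=0.0)
        )
        tab.columns = [f"freq_{c}" for c in tab.columns]
        features = features.join(tab, how="left")
        families.update({c: "maturation_frequency" for c in tab.columns})

    if iar_frequency is not None:
        features["iar_frequency"] = pd.Series(iar_frequency)
        families["iar_frequency"] = "iar_frequency"

    features = features.dropna()
    corr = correlate_by_arm(
        features,
        rates,
        arms,
        n_permutations=n_permutations,
        seed=seed,
        feature_families=families,
    )

    treated = corr[corr["arm"] == "treated"].set_index("feature")
    placebo = corr[corr["arm"] == "placebo"].set_index("feature")
    flag_rows = []
    for feat in features.columns:
        qt = treated["q"].get(feat, np.nan)
        qp = placebo["q"].get(feat, np.nan)
        flag_rows.append(
            {
                "feature": feat,
                "family": families.get(feat, "all"),
                "rho_treated": treated["rho"].get(feat, np.nan),
                "q_treated": qt,
                "rho_placebo": placebo["rho"].get(feat, np.nan),
                "q_placebo": qp,
                "arm_specific": bool(
                    np.isfinite(qt) and qt < alpha and not (np.isfinite(qp) and qp < alpha)
                ),
            }
        )
    flags = pd.DataFrame(flag_rows).sort_values("q_treated", kind="mergesort").reset_index(drop=True)
    return ScreenResult(decay=decay, features=features, correlations=corr, flags=flags)
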