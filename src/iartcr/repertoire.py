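"""TCR junction matching, clonal expansion, sharing, privacy and database lookup.

The matching rule is exact nucleotide identity of the CDR3 junction (the
segment from the conserved cysteine at IMGT position 104 to the J-region
Phe/Trp at position 118) within a locus: TRA only matches TRA, TRB only TRB.
A chain is *expanded* when it is detected in at least two cells; sharing is
*private* when it stays within one participant and *public* when it spans
two or more. An optional strict mode additionally requires gene-level V and
J call identity.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from Bio.Seq import Seq
from scipy import stats as sps

__all__ = [
    "AIRR_COLUMNS",
    "read_airr",
    "find_shared_chains",
    "detect_expanded",
    "ExpansionSummary",
    "classify_privacy",
    "PrivacySummary",
    "stratify_by_hla",
    "build_sharing_graph",
    "cluster_expansion_fractions",
    "compare_expansion_distribution",
    "KsResult",
    "match_database",
]

AIRR_COLUMNS = (
    "cell_id",
    "participant_id",
    "locus",
    "v_call",
    "j_call",
    "junction",
    "junction_aa",
    "productive",
)

_JUNCTION_AA_RE = re.compile(r"^C.*[FW]$")


class SchemaError(ValueError):
    pass


def _coerce_bool(series: pd.Series) -> pd.Series:
    if series.dtype == bool:
        return series
    return series.astype(str).str.strip().str.lower().isin(("true", "t", "1", "yes"))


def validate_junction(junction_nt: str, junction_aa: str) -> str | None:
    """Return a reason string if the productive junction is malformed, else None."""
    if not isinstance(junction_nt, str) or len(junction_nt) == 0:
        return "empty junction"
    if len(junction_nt) % 3 != 0:
        return "junction length not a multiple of 3"
    try:
        translated = str(Seq(junction_nt).translate())
    except Exception:
        return "untranslatable junction"
    if "*" in translated:
        return "junction contains a stop codon"
    if translated != junction_aa:
        return "junction_aa does not match the translated junction"
    if not _JUNCTION_AA_RE.match(junction_aa):
        return "junction_aa violates the C...F/W convention"
    return None


def read_airr(path) -> pd.DataFrame:
    """Read an AIRR-style rearrangement TSV of per-cell TCR chains.

    Rows are validated: productive chains whose junction does not translate
    to the stated amino-acid string, or whose amino-acid string violates the
    C104...F/W118 convention, are dropped with a warning. Nonproductive
    chains are retained (they are excluded from sharing downstream).
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = [c for c in AIRR_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"AIRR table missing required columns: {missing}")
    df = df[list(AIRR_COLUMNS)].copy()
    df["productive"] = _coerce_bool(df["productive"])
    bad_locus = ~df["locus"].isin(["TRA", "TRB"])
    if bad_locus.any():
        warnings.warn(f"dropping {int(bad_locus.sum())} rows with locus outside TRA/TRB")
        df = df[~bad_locus]

    reasons = [
        validate_junction(nt, aa) if prod else None
        for nt, aa, prod in zip(df["junction"], df["junction_aa"], df["productive"])
    ]
    bad = np.array([r is not None for r in reasons])
    if bad.any():
        examples = sorted({r for r in reasons if r is not None})
        warnings.warn(
            f"dropping {int(bad.sum())} malformed productive chains ({'; '.join(examples)})"
        )
        df = df[~bad]
    return df.reset_index(drop=True)


def find_shared_chains(
    chains: pd.DataFrame, scope: str = "all", strict_vj: bool = False
) -> pd.DataFrame:
    """Group productive chains by exact (locus, junction-nucleotide) identity.

    With ``scope="all"`` every distinct key forms one group (a partition of
    the productive chains). ``scope="within_participant"`` keeps groups in
    which some single participant contributes >= 2 cells;
    ``scope="between_participant"`` keeps groups spanning >= 2 participants.
    ``strict_vj`` adds gene-level V and J calls to the key. Output is sorted
    by (locus, junction) and deterministic.
    """
    if scope not in ("all", "within_participant", "between_participant"):
        raise ValueError(f"unknown scope {scope!r}")
    cols = ["locus", "junction"]
    if strict_vj:
        cols += ["v_gene", "j_gene"]
    prod = chains[_coerce_bool(chains["productive"])].copy()
    if prod.empty:
        return pd.DataFrame(
            columns=cols + ["cell_ids", "participant_ids", "n_cells", "n_participants", "expanded"]
        )
    if strict_vj:
        prod["v_gene"] = prod["v_call"].str.split("*").str[0]
        prod["j_gene"] = prod["j_call"].str.split("*").str[0]

    records = []
    for key, sub in prod.groupby(cols, sort=True):
        cell_ids = tuple(sorted(set(sub["cell_id"])))
        participant_ids = tuple(sorted(set(sub["participant_id"])))
        max_within = sub.groupby("participant_id")["cell_id"].nunique().max()
        rec = dict(zip(cols, key if isinstance(key, tuple) else (key,)))
        rec.update(
            cell_ids=cell_ids,
            participant_ids=participant_ids,
            n_cells=len(cell_ids),
            n_participants=len(participant_ids),
            expanded=len(cell_ids) >= 2,
            _max_within=int(max_within),
        )
        records.append(rec)
    groups = pd.DataFrame(records)
    if scope == "within_participant":
        groups = groups[groups["_max_within"] >= 2]
    elif scope == "between_participant":
        groups = groups[groups["n_participants"] >= 2]
    return groups.drop(columns="_max_within").reset_index(drop=True)


@dataclass
class ExpansionSummary:
    """Bookkeeping of shared chains mirroring the published sharing counts."""

    n_expanded_chains: int
    n_expanded_cells: int
    n_participants: int
    shared_chain_bins: dict  # per-cell count of shared chain groups, binned 1 / 2 / >2
    expanded_cells: tuple
    cell_shared_chain_counts: pd.Series


def detect_expanded(groups: pd.DataFrame) -> tuple[pd.DataFrame, ExpansionSummary]:
    """Filter groups to expanded ones and summarize the sharing bookkeeping."""
    expanded = groups[groups["expanded"]].reset_index(drop=True)
    counts: dict[str, int] = {}
    participants: set[str] = set()
    for _, row in expanded.iterrows():
        participants.update(row["participant_ids"])
        for cell in row["cell_ids"]:
            counts[cell] = counts.get(cell, 0) + 1
    per_cell = pd.Series(counts, dtype=int).sort_index()
    bins = {
        "1": int((per_cell == 1).sum()),
        "2": int((per_cell == 2).sum()),
        ">2": int((per_cell > 2).sum()),
    }
    summary = ExpansionSummary(
        n_expanded_chains=len(expanded),
        n_expanded_cells=len(per_cell),
        n_participants=len(participants),
        shared_chain_bins=bins,
        expanded_cells=tuple(per_cell.index),
        cell_shared_chain_counts=per_cell,
    )
    return expanded, summary


@dataclass
class PrivacySummary:
    n_private_chains: int
    n_public_chains: int
    n_private_cells: int
    n_public_cells: int


def classify_privacy(groups: pd.DataFrame) -> tuple[pd.DataFrame, PrivacySummary]:
    """Label expanded groups private (one participant) or public (>= 2).

    Chain-level tallies count each expanded group once. Cell-level tallies
    count each cell once: a cell in any public group is public, otherwise
    private (cells are not double-counted).
    """
    out = groups.copy()
    out["privacy"] = np.where(out["n_participants"] >= 2, "public", "private")
    out.loc[~out["expanded"], "privacy"] = None
    expanded = out[out["expanded"]]
    public_cells: set[str] = set()
    all_cells: set[str] = set()
    for _, row in expanded.iterrows():
        all_cells.update(row["cell_ids"])
        if row["privacy"] == "public":
            public_cells.update(row["cell_ids"])
    summary = PrivacySummary(
        n_private_chains=int((expanded["privacy"] == "private").sum()),
        n_public_chains=int((expanded["privacy"] == "public").sum()),
        n_private_cells=len(all_cells - public_cells),
        n_public_cells=len(public_cells),
    )
    return out, summary


def stratify_by_hla(
    chains: pd.DataFrame, hla_map, strict_vj: bool = False
) -> pd.DataFrame:
    """Run the sharing analysis separately within DR4 and non-DR4 strata.

    ``hla_map`` maps participant_id to an HLA group label. Reports per
    stratum the chain/cell totals, the expansion bookkeeping, and percent
    expanded on both the cell and the chain scale.
    """
    hla = pd.Series(hla_map)
    missing = sorted(set(chains["participant_id"]) - set(hla.index))
    if missing:
        raise ValueError(f"participants missing from hla_map: {missing}")
    rows = []
    for stratum in sorted(hla.unique()):
        participants = set(hla[hla == stratum].index)
        sub = chains[chains["participant_id"].isin(participants)]
        prod = sub[_coerce_bool(sub["productive"])] if not sub.empty else sub
        groups = find_shared_chains(sub, scope="all", strict_vj=strict_vj) if not sub.empty else None
        if groups is None or groups.empty:
            summary = ExpansionSummary(0, 0, 0, {"1": 0, "2": 0, ">2": 0}, (), pd.Series(dtype=int))
        else:
            _, summary = detect_expanded(groups)
        n_cells = int(sub["cell_id"].nunique())
        n_chains = int(len(prod))
        n_chains_in_expanded = (
            0
            if groups is None or groups.empty
            else int(groups.loc[groups["expanded"], "n_cells"].sum())
        )
        rows.append(
            {
                "stratum": stratum,
                "n_participants": len(participants & set(sub["participant_id"])),
                "n_cells": n_cells,
                "n_productive_chains": n_chains,
                "n_expanded_chains": summary.n_expanded_chains,
                "n_expanded_cells": summary.n_expanded_cells,
                "pct_cells_expanded": 100.0 * summary.n_expanded_cells / n_cells
                if n_cells
                else np.nan,
                "pct_chains_expanded": 100.0 * n_chains_in_expanded / n_chains
                if n_chains
                else np.nan,
            }
        )
    return pd.DataFrame(rows)


def build_sharing_graph(
    cell_clusters, groups: pd.DataFrame, cell_participants=None
) -> tuple[nx.Graph, pd.DataFrame]:
    """Cell-sharing graph: edge weight = number of shared chain groups.

    ``cell_clusters`` maps cell_id to a cluster label; every cell that is a
    member of an expanded group must be present. ``cell_participants``
    optionally maps cell_id to participant_id for the same-participant edge
    flag (cells in single-participant groups are inferred without it).
    Returns the graph and a chord-diagram-ready edge list.
    """
    clusters = pd.Series(cell_clusters)
    graph = nx.Graph()
    expanded = groups[groups["expanded"]]
    for _, row in expanded.iterrows():
        for cell in row["cell_ids"]:
            if cell not in clusters.index:
                raise ValueError(f"cell {cell} in a shared group has no cluster label")
    participant_of: dict[str, str] = (
        dict(pd.Series(cell_participants)) if cell_participants is not None else {}
    )
    if not participant_of:
        for _, row in expanded.iterrows():
            if len(row["participant_ids"]) == 1:
                for cell in row["cell_ids"]:
                    participant_of.setdefault(cell, row["participant_ids"][0])

    weights: dict[tuple[str, str], int] = {}
    for _, row in expanded.iterrows():
        cells = row["cell_ids"]
        for i in range(len(cells)):
            for j in range(i + 1, len(cells)):
                key = (cells[i], cells[j])
                weights[key] = weights.get(key, 0) + 1

    for cell in clusters.index:
        graph.add_node(cell, cluster=clusters[cell])
    edge_rows = []
    for (a, b), w in sorted(weights.items()):
        graph.add_edge(a, b, weight=w)
        edge_rows.append(
            {
                "cell_a": a,
                "cell_b": b,
                "weight": w,
                "same_cluster": bool(clusters[a] == clusters[b]),
                "same_participant": participant_of.get(a) is not None
                and participant_of.get(a) == participant_of.get(b),
            }
        )
    edges = pd.DataFrame(
        edge_rows, columns=["cell_a", "cell_b", "weight", "same_cluster", "same_participant"]
    )
    return graph, edges


def cluster_expansion_fractions(
    cell_clusters, expanded_cells, clusters=(1, 2, 3, 4, 5)
) -> pd.DataFrame:
    """Fraction of cells per cluster that belong to an expanded chain group.

    Clusters with no cells are reported with a missing (NaN) fraction rather
    than zero.
    """
    labels = pd.Series(cell_clusters)
    expanded = set(expanded_cells)
    rows = []
    for c in clusters:
        members = labels.index[labels == c]
        n = len(members)
        n_exp = sum(1 for cell in members if cell in expanded)
        rows.append(
            {
                "cluster": c,
                "n_cells": n,
                "n_expanded": n_exp,
                "fraction_expanded": (n_exp / n) if n else np.nan,
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class KsResult:
    d: float
    p_permutation: float
    p_asymptotic: float
    n_permutations: int


def compare_expansion_distribution(
    expanded_clusters,
    total_clusters,
    n_permutations: int = 10_000,
    seed=None,
    cluster_order=(1, 2, 3, 4, 5),
) -> KsResult:
    """Two-sample KS test of expanded versus total cells over ordered clusters.

    The cluster index is treated as ordinal along the maturation trajectory.
    Because the variable is discrete with heavy ties, the p-value is computed
    by permutation under the null that expanded cells are a uniform random
    subset of all cells (multivariate hypergeometric resampling of the
    per-cluster expanded counts); the asymptotic two-sample p is also
    reported for reference.
    """
    exp = np.asarray(expanded_clusters)
    tot = np.asarray(total_clusters)
    if exp.size < 2:
        raise ValueError("need at least 2 expanded cells")
    order = list(cluster_order)
    exp_counts = np.array([(exp == c).sum() for c in order], dtype=np.int64)
    tot_counts = np.array([(tot == c).sum() for c in order], dtype=np.int64)
    if exp_counts.sum() != exp.size or tot_counts.sum() != tot.size:
        raise ValueError("cluster labels outside cluster_order")
    if np.any(exp_counts > tot_counts):
        raise ValueError("expanded cells must be a subset of total cells")

    m, n = exp_counts.sum(), tot_counts.sum()
    ecdf_exp = np.cumsum(exp_counts) / m
    ecdf_tot = np.cumsum(tot_counts) / n
    d = float(np.max(np.abs(ecdf_exp - ecdf_tot)))

    rng = np.random.default_rng(seed)
    draws = rng.multivariate_hypergeometric(tot_counts, int(m), size=n_permutations)
    ecdf_perm = np.cumsum(draws, axis=1) / m
    d_perm = np.max(np.abs(ecdf_perm - ecdf_tot[None, :]), axis=1)
    p_perm = (1 + int(np.count_nonzero(d_perm >= d - 1e-12))) / (1 + n_permutations)

    # ordinal ranks carry the trajectory order for the asymptotic reference
    p_asym = float(sps.ks_2samp(exp.astype(float), tot.astype(float), method="asymp").pvalue)
    return KsResult(d, p_perm, p_asym, n_permutations)


def match_database(chains: pd.DataFrame, db: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Match chain junction amino-acid sequences against a specificity database.

    ``db`` needs columns junction_aa, v_call, j_call, epitope, antigen.
    A match on the amino-acid junction alone (within locus, inferred from
    the database V call) is ``junction_aa_only``; gene-level V and J
    agreement upgrades it to ``three_point``. The summary reports whether
    any single cell matches database records on both its TRA and TRB chain.
    """
    required = ["junction_aa", "v_call", "j_call", "epitope", "antigen"]
    missing = [c for c in required if c not in db.columns]
    if missing:
        raise SchemaError(f"specificity database missing columns: {missing}")
    if db.empty:
        return (
            pd.DataFrame(
                columns=["cell_id", "locus", "junction_aa", "epitope", "antigen", "match_level"]
            ),
            {"n_matched_chains": 0, "n_three_point": 0, "cells_matching_both_loci": 0},
        )
    db = db.copy()
    db["locus"] = db["v_call"].str[:3]
    db["v_gene"] = db["v_call"].str.split("*").str[0]
    db["j_gene"] = db["j_call"].str.split("*").str[0]

    prod = chains[_coerce_bool(chains["productive"])].copy()
    prod["v_gene"] = prod["v_call"].str.split("*").str[0]
    prod["j_gene"] = prod["j_call"].str.split("*").str[0]
    merged = prod.merge(
        db[["locus", "junction_aa", "v_gene", "j_gene", "epitope", "antigen"]],
        on=["locus", "junction_aa"],
        how="inner",
        suffixes=("", "_db"),
    )
    if merged.empty:
        matches = pd.DataFrame(
            columns=["cell_id", "locus", "junction_aa", "epitope", "antigen", "match_level"]
        )
    else:
        three = (merged["v_gene"] == merged["v_gene_db"]) & (
            merged["j_gene"] == merged["j_gene_db"]
        )
        merged["match_level"] = np.where(three, "three_point", "junction_aa_only")
        matches = merged[
            ["cell_id", "participant_id", "locus", "junction_aa", "epitope", "antigen", "match_level"]
        ].sort_values(["cell_id", "locus", "junction_aa"], kind="mergesort").reset_index(drop=True)

    per_cell_loci = matches.groupby("cell_id")["locus"].nunique() if not matches.empty else pd.Series(dtype=int)
    summary = {
        "n_matched_chains": int(matches[["locus", "junction_aa"]].drop_duplicates().shape[0])
        if not matches.empty
        else 0,
        "n_three_point": int((matches["match_level"] == "three_point").sum())
        if not matches.empty
        else 0,
        "cells_matching_both_loci": int((per_cell_loci >= 2).sum()),
    }
    return matches, summary
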