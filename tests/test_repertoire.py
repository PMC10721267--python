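"""Junction matching, expansion, privacy, sharing graph and database lookup."""

import warnings

import numpy as np
import pandas as pd
import pytest

from iartcr import repertoire, simulate
from iartcr.repertoire import SchemaError

from conftest import bruteforce_groups, random_chain_fixture


def _chain(cell, pid, locus, junction_nt, junction_aa, v="TRBV1", j="TRBJ1", productive=True):
    return {
        "cell_id": cell,
        "participant_id": pid,
        "locus": locus,
        "v_call": v,
        "j_call": j,
        "junction": junction_nt,
        "junction_aa": junction_aa,
        "productive": productive,
    }


# a valid junction pair used throughout: TGT GCA AGC AGC TTT -> CASSF
NT = "TGTGCAAGCAGCTTT"
AA = "CASSF"
NT2 = "TGTGCAAGCGGGTTT"
AA2 = "CASGF"


def test_read_airr_valid_and_roundtrip(tmp_path, default_dataset):
    path = tmp_path / "airr.tsv"
    default_dataset.chains.to_csv(path, sep="\t", index=False)
    with warnings.catch_warnings():
        warnings.simplefilter("error")
        chains = repertoire.read_airr(path)
    assert len(chains) == len(default_dataset.chains)


def test_read_airr_schema_and_validation(tmp_path):
    df = pd.DataFrame([_chain("c1", "P1", "TRB", NT, AA)])
    bad = tmp_path / "missing.tsv"
    df.drop(columns=["junction_aa"]).to_csv(bad, sep="\t", index=False)
    with pytest.raises(SchemaError, match="junction_aa"):
        repertoire.read_airr(bad)

    rows = [
        _chain("c1", "P1", "TRB", NT, AA),
        _chain("c2", "P1", "TRB", "GCAGCAAGCAGCTTT", "AASSF"),  # no leading C
        _chain("c3", "P1", "TRB", NT, AA, productive=False),
    ]
    path = tmp_path / "rows.tsv"
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    with pytest.warns(UserWarning, match="malformed"):
        chains = repertoire.read_airr(path)
    assert set(chains["cell_id"]) == {"c1", "c3"}  # nonproductive kept, malformed dropped


def test_two_cells_same_junction_form_one_expanded_group():
    chains = pd.DataFrame([_chain("c1", "P1", "TRB", NT, AA), _chain("c2", "P1", "TRB", NT, AA)])
    groups = repertoire.find_shared_chains(chains)
    assert len(groups) == 1
    assert groups.loc[0, "n_cells"] == 2
    assert bool(groups.loc[0, "expanded"])


def test_locus_restriction_keeps_identical_junctions_apart():
    chains = pd.DataFrame([_chain("c1", "P1", "TRA", NT, AA), _chain("c2", "P1", "TRB", NT, AA)])
    groups = repertoire.find_shared_chains(chains)
    assert len(groups) == 2
    assert not groups["expanded"].any()


def test_nonproductive_chains_excluded_from_sharing():
    chains = pd.DataFrame(
        [_chain("c1", "P1", "TRB", NT, AA), _chain("c2", "P1", "TRB", NT, AA, productive=False)]
    )
    groups = repertoire.find_shared_chains(chains)
    assert groups["n_cells"].tolist() == [1]


def test_scope_filters_and_empty_input():
    chains = pd.DataFrame(
        [
            _chain("c1", "P1", "TRB", NT, AA),
            _chain("c2", "P1", "TRB", NT, AA),
            _chain("c3", "P1", "TRB", NT2, AA2),
            _chain("c4", "P2", "TRB", NT2, AA2),
        ]
    )
    within = repertoire.find_shared_chains(chains, scope="within_participant")
    assert within["junction"].tolist() == [NT]
    between = repertoire.find_shared_chains(chains, scope="between_participant")
    assert between["junction"].tolist() == [NT2]
    assert repertoire.find_shared_chains(chains.iloc[:0]).empty


def test_strict_vj_mode_splits_on_gene_calls():
    chains = pd.DataFrame(
        [
            _chain("c1", "P1", "TRB", NT, AA, v="TRBV1*01"),
            _chain("c2", "P1", "TRB", NT, AA, v="TRBV2*01"),
        ]
    )
    assert len(repertoire.find_shared_chains(chains)) == 1
    assert len(repertoire.find_shared_chains(chains, strict_vj=True)) == 2


def test_grouping_matches_bruteforce_oracle(rng):
    chains = random_chain_fixture(rng, n_chains=200)
    groups = repertoire.find_shared_chains(chains)
    oracle = bruteforce_groups(chains)
    assert len(groups) == len(oracle)
    for got, want in zip(groups.itertuples(), oracle):
        assert (got.locus, got.junction) == (want["locus"], want["junction"])
        assert got.cell_ids == want["cell_ids"]
        assert got.participant_ids == want["participant_ids"]
        assert got.expanded == want["expanded"]


def test_detect_expanded_three_cell_clone_bins():
    rows = []
    for cell in ("c1", "c2", "c3"):
        rows.append(_chain(cell, "P1", "TRA", NT, AA, v="TRAV1", j="TRAJ1"))
        rows.append(_chain(cell, "P1", "TRB", NT2, AA2))
    groups = repertoire.find_shared_chains(pd.DataFrame(rows))
    expanded, summary = repertoire.detect_expanded(groups)
    assert summary.n_expanded_chains == 2
    assert summary.n_expanded_cells == 3
    assert summary.shared_chain_bins == {"1": 0, "2": 3, ">2": 0}
    assert summary.n_participants == 1


def test_detect_expanded_all_singletons():
    chains = pd.DataFrame([_chain("c1", "P1", "TRB", NT, AA), _chain("c2", "P1", "TRB", NT2, AA2)])
    _, summary = repertoire.detect_expanded(repertoire.find_shared_chains(chains))
    assert summary.n_expanded_chains == 0
    assert summary.n_expanded_cells == 0


def test_privacy_classification_examples():
    chains = pd.DataFrame(
        [
            _chain("c1", "P1", "TRB", NT, AA),
            _chain("c2", "P2", "TRB", NT, AA),
            _chain("c3", "P1", "TRB", NT2, AA2),
            _chain("c4", "P1", "TRB", NT2, AA2),
        ]
    )
    groups, summary = repertoire.classify_privacy(repertoire.find_shared_chains(chains))
    by_junction = groups.set_index("junction")["privacy"]
    assert by_junction[NT] == "public"
    assert by_junction[NT2] == "private"
    assert summary.n_public_chains == 1 and summary.n_private_chains == 1
    assert summary.n_public_cells == 2 and summary.n_private_cells == 2


def test_privacy_counts_match_truth_enumeration():
    """Cohort with elevated public seeding: privacy calls equal enumeration
    of detected chains in the generator's truth table."""
    cfg = simulate.SimConfig(seed=21, p_public=0.1, n_genes=40)
    ds = simulate.simulate_dataset(cfg)
    groups, summary = repertoire.classify_privacy(repertoire.find_shared_chains(ds.chains))
    detected = ds.truth.chains[ds.truth.chains["detected"]]
    truth_public = 0
    truth_private = 0
    for (_, _), sub in detected.groupby(["locus", "junction"]):
        if sub["cell_id"].nunique() < 2:
            continue
        if sub["participant_id"].nunique() >= 2:
            truth_public += 1
        else:
            truth_private += 1
    assert summary.n_public_chains == truth_public
    assert summary.n_private_chains == truth_private


def test_hla_stratification_partition_and_errors(default_dataset):
    ds = default_dataset
    hla = ds.cohort.set_index("participant_id")["hla_group"]
    strata = repertoire.stratify_by_hla(ds.chains, hla)
    assert set(strata["stratum"]) == {"DR4", "nonDR4"}
    assert strata["n_cells"].sum() == ds.chains["cell_id"].nunique()
    # expanded counts per stratum equal a direct within-stratum enumeration
    for _, row in strata.iterrows():
        pids = set(hla[hla == row["stratum"]].index)
        sub = ds.chains[ds.chains["participant_id"].isin(pids)]
        _, summary = repertoire.detect_expanded(repertoire.find_shared_chains(sub))
        assert row["n_expanded_cells"] == summary.n_expanded_cells
    with pytest.raises(ValueError, match="missing"):
        repertoire.stratify_by_hla(ds.chains, hla.iloc[:-3])


def test_hla_single_stratum_gives_empty_other():
    chains = pd.DataFrame([_chain("c1", "P1", "TRB", NT, AA), _chain("c2", "P1", "TRB", NT, AA)])
    strata = repertoire.stratify_by_hla(chains, {"P1": "DR4"})
    assert strata["stratum"].tolist() == ["DR4"]


def test_sharing_graph_trivial_shapes():
    rows = []
    for cell in ("c1", "c2"):
        rows.append(_chain(cell, "P1", "TRA", NT, AA, v="TRAV1", j="TRAJ1"))
        rows.append(_chain(cell, "P1", "TRB", NT2, AA2))
    groups = repertoire.find_shared_chains(pd.DataFrame(rows))
    clusters = pd.Series({"c1": 3, "c2": 4})
    graph, edges = repertoire.build_sharing_graph(clusters, groups)
    assert len(edges) == 1
    assert edges.loc[0, "weight"] == 2
    assert not edges.loc[0, "same_cluster"]

    rows = [_chain(c, "P1", "TRB", NT, AA) for c in ("c1", "c2", "c3")]
    groups = repertoire.find_shared_chains(pd.DataFrame(rows))
    graph, edges = repertoire.build_sharing_graph(pd.Series({"c1": 1, "c2": 1, "c3": 2}), groups)
    assert len(edges) == 3  # triangle
    assert graph.number_of_edges() == 3

    with pytest.raises(ValueError, match="cluster label"):
        repertoire.build_sharing_graph(pd.Series({"c1": 1}), groups)


def test_sharing_graph_matches_pairwise_oracle(rng):
    chains = random_chain_fixture(rng, n_chains=150)
    groups = repertoire.find_shared_chains(chains)
    cells = sorted(chains["cell_id"].unique())
    clusters = pd.Series({c: 1 + (i % 5) for i, c in enumerate(cells)})
    _, edges = repertoire.build_sharing_graph(clusters, groups)
    # oracle: for every cell pair count groups containing both
    oracle = {}
    expanded = bruteforce_groups(chains)
    for g in expanded:
        members = g["cell_ids"]
        if len(members) < 2:
            continue
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                oracle[(members[i], members[j])] = oracle.get((members[i], members[j]), 0) + 1
    got = {(r.cell_a, r.cell_b): r.weight for r in edges.itertuples()}
    assert got == oracle


def test_cluster_expansion_fraction_values():
    clusters = pd.Series({"c1": 1, "c2": 1, "c3": 1, "c4": 1, "c5": 2})
    out = repertoire.cluster_expansion_fractions(clusters, {"c1"}, clusters=(1, 2, 3))
    frac = out.set_index("cluster")["fraction_expanded"]
    assert frac[1] == 0.25
    assert frac[2] == 0.0
    assert np.isnan(frac[3])  # empty cluster is missing, not zero

    none = repertoire.cluster_expansion_fractions(clusters, set(), clusters=(1, 2))
    assert (none["fraction_expanded"] == 0).all()


def test_cluster_expansion_conservation(default_dataset):
    ds = default_dataset
    clusters = ds.truth.cells.set_index("cell_id")["cluster"]
    _, summary = repertoire.detect_expanded(repertoire.find_shared_chains(ds.chains))
    out = repertoire.cluster_expansion_fractions(clusters, summary.expanded_cells)
    weighted = (out["fraction_expanded"] * out["n_cells"]).sum() / out["n_cells"].sum()
    assert weighted == pytest.approx(summary.n_expanded_cells / len(clusters))
    assert out["fraction_expanded"].dropna().between(0, 1).all()


def test_ks_trivial_and_handworked_values():
    total = np.repeat([1, 2, 3, 4, 5], 20)
    same = repertoire.compare_expansion_distribution(total, total, n_permutations=200, seed=0)
    assert same.d == 0.0
    assert same.p_permutation > 0.99

    expanded = np.repeat(5, 20)
    res = repertoire.compare_expansion_distribution(expanded, total, n_permutations=500, seed=0)
    assert res.d == pytest.approx(0.8)  # max ECDF gap computed by hand
    assert res.p_permutation < 0.01

    with pytest.raises(ValueError, match="at least 2"):
        repertoire.compare_expansion_distribution(np.array([5]), total)


def test_ks_invariant_to_row_order(rng):
    total = rng.integers(1, 6, size=300)
    expanded = rng.choice(total, size=60, replace=False)
    a = repertoire.compare_expansion_distribution(expanded, total, seed=5)
    b = repertoire.compare_expansion_distribution(
        np.sort(expanded), rng.permutation(total), seed=5
    )
    assert a.d == b.d
    assert a.p_permutation == b.p_permutation


def _db_record(junction_aa, v, j, epitope="EP", antigen="virus"):
    return {"junction_aa": junction_aa, "v_call": v, "j_call": j, "epitope": epitope, "antigen": antigen}


def test_match_database_levels_and_summary():
    chains = pd.DataFrame(
        [
            _chain("c1", "P1", "TRB", NT, AA, v="TRBV1*01", j="TRBJ1*01"),
            _chain("c2", "P1", "TRB", NT2, AA2, v="TRBV1", j="TRBJ2"),
        ]
    )
    db = pd.DataFrame(
        [
            _db_record(AA, "TRBV1*02", "TRBJ1"),  # same genes after allele truncation
            _db_record(AA2, "TRBV1", "TRBJ5"),  # different J: junction only
        ]
    )
    matches, summary = repertoire.match_database(chains, db)
    level = matches.set_index("junction_aa")["match_level"]
    assert level[AA] == "three_point"
    assert level[AA2] == "junction_aa_only"
    assert summary["cells_matching_both_loci"] == 0

    empty, summary = repertoire.match_database(chains, db.iloc[:0])
    assert empty.empty and summary["n_matched_chains"] == 0


def test_match_database_bruteforce_oracle(rng):
    chains = random_chain_fixture(rng, n_chains=50, junction_pool=25)
    records = []
    gen = np.random.default_rng(99)
    pool = chains.sample(20, random_state=1)
    for _, row in pool.iterrows():
        v = row["v_call"] if gen.random() < 0.5 else f"{row['locus']}V9"
        records.append(_db_record(row["junction_aa"], v, row["j_call"]))
    db = pd.DataFrame(records)
    matches, _ = repertoire.match_database(chains, db)
    # oracle: all-pairs string comparison
    expected = []
    for ci, chain in chains.iterrows():
        for _, rec in db.iterrows():
            if rec["v_call"][:3] != chain["locus"]:
                continue
            if rec["junction_aa"] != chain["junction_aa"]:
                continue
            level = (
                "three_point"
                if rec["v_call"].split("*")[0] == chain["v_call"].split("*")[0]
                and rec["j_call"].split("*")[0] == chain["j_call"].split("*")[0]
                else "junction_aa_only"
            )
            expected.append((chain["cell_id"], chain["locus"], chain["junction_aa"], level))
    got = sorted(zip(matches["cell_id"], matches["locus"], matches["junction_aa"], matches["match_level"]))
    assert got == sorted(expected)


def test_groups_partition_conservation(default_dataset):
    """Every productive chain key appears in exactly one group, and group
    cell-memberships conserve the productive chain rows."""
    chains = default_dataset.chains
    groups = repertoire.find_shared_chains(chains)
    keys = set(zip(groups["locus"], groups["junction"]))
    prod = chains[chains["productive"]]
    assert keys == set(zip(prod["locus"], prod["junction"]))
    per_key_cells = prod.groupby(["locus", "junction"])["cell_id"].nunique()
    assert groups.set_index(["locus", "junction"])["n_cells"].sort_index().equals(
        per_key_cells.sort_index()
    )
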