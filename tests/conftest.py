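import numpy as np
import pandas as pd
import pytest

from iartcr import simulate


@pytest.fixture(scope="session")
def default_dataset():
    """One full synthetic cohort at the default study conditions."""
    return simulate.simulate_dataset(simulate.SimConfig(seed=1))


@pytest.fixture(scope="session")
def thresholds():
    return simulate.default_thresholds()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def random_chain_fixture(rng, n_chains=200, junction_pool=40, n_participants=6):
    """Random AIRR-style chain table with forced junction collisions."""
    pool = []
    gen = np.random.default_rng(rng.integers(2**31))
    for _ in range(junction_pool):
        nt, aa = simulate._random_junction(gen)
        pool.append((nt, aa))
    rows = []
    for i in range(n_chains):
        nt, aa = pool[int(gen.integers(junction_pool))]
        locus = "TRA" if gen.random() < 0.5 else "TRB"
        pid = f"P{int(gen.integers(n_participants)):02d}"
        rows.append(
            {
                "cell_id": f"{pid}_cell{int(gen.integers(n_chains // 2)):04d}",
                "participant_id": pid,
                "locus": locus,
                "v_call": f"{locus}V{int(gen.integers(1, 6))}",
                "j_call": f"{locus}J{int(gen.integers(1, 5))}",
                "junction": nt,
                "junction_aa": aa,
                "productive": True,
            }
        )
    return pd.DataFrame(rows)


def bruteforce_groups(chains: pd.DataFrame):
    """O(n^2) all-pairs junction comparison oracle.

    Union-find over chain rows joined whenever two rows have the same locus
    and identical junction strings; returns the same group structure as the
    production grouping, derived without any hashing or groupby machinery.
    """
    prod = chains[chains["productive"].astype(bool)].reset_index(drop=True)
    n = len(prod)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    loci = prod["locus"].to_list()
    juncs = prod["junction"].to_list()
    for i in range(n):
        for j in range(i + 1, n):
            if loci[i] == loci[j] and juncs[i] == juncs[j]:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[rj] = ri
    members: dict[int, list[int]] = {}
    for i in range(n):
        members.setdefault(find(i), []).append(i)
    groups = []
    for rows in members.values():
        cells = tuple(sorted({prod.loc[r, "cell_id"] for r in rows}))
        parts = tuple(sorted({prod.loc[r, "participant_id"] for r in rows}))
        groups.append(
            {
                "locus": prod.loc[rows[0], "locus"],
                "junction": prod.loc[rows[0], "junction"],
                "cell_ids": cells,
                "participant_ids": parts,
                "expanded": len(cells) >= 2,
            }
        )
    groups.sort(key=lambda g: (g["locus"], g["junction"]))
    return groups
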