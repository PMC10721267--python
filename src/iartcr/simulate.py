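"""Synthetic cohort generator for the baseline-biomarker pipeline.

Emulates the statistical structure of a small two-arm intervention cohort of
new-onset type 1 diabetes participants from whom rare islet antigen-reactive
(IAR) CD4+ T cells were single-cell sorted: a cohort table with treatment arm
and HLA group, per-cell transcript counts structured into five phenotype
clusters, clonally structured paired-chain TCRs with mostly private sharing,
flow-cytometry event tables for the gating rules, and longitudinal C-peptide
2-hour AUC series whose exponential decay rate is negatively coupled to the
cluster-3 fraction in the treated arm only.

Every generator is deterministic given ``SimConfig.seed``; independent seed
streams are derived per stage so adding or removing one stage does not
perturb the draws of another.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq

__all__ = [
    "SimConfig",
    "SimConfigError",
    "TruthLabels",
    "SyntheticDataset",
    "generate_cohort",
    "generate_cells",
    "generate_repertoire",
    "generate_flow_events",
    "generate_cpeptide",
    "exponential_series",
    "simulate_dataset",
    "DEFAULT_MARKER_PROGRAM",
    "MARKER_GENES",
]

CLUSTERS = (1, 2, 3, 4, 5)

# Per-cluster negative-binomial mean for the named marker genes
# (clusters 1-2 naive-like, 3 central-memory/activated with BHLHE40 and
# proinflammatory cytokines, 4-5 effector-memory with rising activation).
DEFAULT_MARKER_PROGRAM: dict[str, tuple[float, ...]] = {
    "CCR7": (9, 8, 6, 1, 0.5),
    "TCF7": (12, 2, 2, 0.7, 0.5),
    "CXCR4": (1, 14, 2, 1, 1),
    "CREBRF": (8, 1, 2, 0.8, 0.8),
    "IL7R": (4, 12, 0.8, 3, 3),
    "IL2RA": (0.4, 0.6, 7, 1.5, 1.5),
    "BHLHE40": (0.5, 0.8, 9, 2, 2),
    "TNFRSF9": (0.3, 0.4, 7, 1, 2),
    "CD2": (2, 2, 9, 4, 5),
    "CSF2": (0.2, 0.2, 5, 0.5, 2.5),
    "TNF": (0.4, 0.5, 6, 2, 3),
    "IL2": (0.3, 0.4, 5, 1, 5),
    "IFNG": (0.2, 0.3, 3, 0.8, 3.5),
    "IL17A": (0.1, 0.1, 1.2, 0.3, 0.4),
    "LYAR": (1, 1, 2, 8, 6),
    "NFKBID": (1, 1, 2, 8, 6),
    "CD40LG": (0.4, 0.8, 4, 2, 10),
    "CD69": (0.8, 2, 4, 2.5, 10),
    "CD44": (2, 2, 4, 5, 10),
}
MARKER_GENES = tuple(DEFAULT_MARKER_PROGRAM)


class SimConfigError(ValueError):
    """Raised when a SimConfig field is invalid; the message names the field."""


@dataclass
class SimConfig:
    """Study-condition parameters for the synthetic cohort.

    Defaults emulate the analyzed trial subset: 18 participants (11 treated,
    7 placebo; 13 DR4, 5 non-DR4), 56 sorted cells each (1,008 cells total),
    five expression clusters, geometric clone sizes biased toward
    memory-like clusters, and a 24-month C-peptide follow-up with visits
    every 6 months.
    """

    n_participants: int = 18
    n_treated: int = 11
    n_dr4: int = 13
    arm_assignment: Mapping[str, str] | None = None
    hla_group: Mapping[str, str] | None = None
    n_cells_per_participant: int = 56
    n_genes: int = 500
    cluster_proportions: Sequence[float] = (0.24, 0.10, 0.22, 0.22, 0.22)
    dirichlet_concentration: float = 6.0
    marker_gene_program: Mapping[str, Sequence[float]] = field(
        default_factory=lambda: dict(DEFAULT_MARKER_PROGRAM)
    )
    baseline_mean: float = 0.8
    dispersion: float = 0.4
    libsize_sigma: float = 0.25
    # geometric clone-size parameter; the expected fraction of cells in
    # clones of size >= 2 is 1 - p^2, so 0.93 puts ~12% of cells in
    # expanded clones (matching the observed singleton-heavy repertoire)
    p_clone: float = 0.93
    clone_size_probs: Sequence[float] | None = None
    expansion_weights: Sequence[float] = (1.0, 4.0, 8.0, 7.0, 10.0)
    # probability a clone reuses a clonotype seeded by another participant;
    # sharing in this assay is dominantly private, so cross-participant
    # seeding is rare
    p_public: float = 0.012
    p_second_tra: float = 0.10
    p_chain_dropout: float = 0.05
    base_rate: float = -0.015
    beta_cluster3: float = -0.10
    decay_noise_sd: float = 0.002
    auc_baseline_mean: float = 1.5
    auc_baseline_sigma: float = 0.3
    auc_noise_sd: float = 0.03
    cpeptide_times: Sequence[float] = (0.0, 6.0, 12.0, 18.0, 24.0)
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_participants", "n_cells_per_participant", "n_genes"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v <= 0:
                raise SimConfigError(f"{name} must be a positive integer")
        if not 0 <= self.n_treated <= self.n_participants:
            raise SimConfigError("n_treated must lie in [0, n_participants]")
        if not 0 <= self.n_dr4 <= self.n_participants:
            raise SimConfigError("n_dr4 must lie in [0, n_participants]")
        props = np.asarray(self.cluster_proportions, dtype=float)
        if props.size != len(CLUSTERS) or np.any(props < 0):
            raise SimConfigError("cluster_proportions must be 5 nonnegative values")
        if abs(props.sum() - 1.0) > 1e-12:
            raise SimConfigError("cluster_proportions must sum to 1")
        for name in ("p_clone", "p_public", "p_second_tra", "p_chain_dropout"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise SimConfigError(f"{name} must lie in [0, 1]")
        if self.p_clone == 0 and self.clone_size_probs is None:
            raise SimConfigError("p_clone must be positive for geometric clone sizes")
        if self.clone_size_probs is not None:
            cs = np.asarray(self.clone_size_probs, dtype=float)
            if np.any(cs < 0) or abs(cs.sum() - 1.0) > 1e-9:
                raise SimConfigError("clone_size_probs must be a probability vector")
        w = np.asarray(self.expansion_weights, dtype=float)
        if w.size != len(CLUSTERS) or np.any(w <= 0):
            raise SimConfigError("expansion_weights must be 5 positive values")
        for name in (
            "dirichlet_concentration",
            "dispersion",
            "libsize_sigma",
            "decay_noise_sd",
            "auc_baseline_sigma",
            "auc_noise_sd",
        ):
            if getattr(self, name) < 0:
                raise SimConfigError(f"{name} must be nonnegative")
        if self.baseline_mean <= 0:
            raise SimConfigError("baseline_mean must be positive")
        if self.auc_baseline_mean <= 0:
            raise SimConfigError("auc_baseline_mean must be positive")
        if self.n_genes < len(self.marker_gene_program):
            raise SimConfigError("n_genes smaller than the marker gene program")
        for gene, means in self.marker_gene_program.items():
            if len(means) != len(CLUSTERS) or np.any(np.asarray(means, float) < 0):
                raise SimConfigError(
                    f"marker_gene_program entry for {gene} must give 5 nonnegative means"
                )
        times = np.asarray(self.cpeptide_times, dtype=float)
        if times.size < 2 or np.any(np.diff(times) <= 0):
            raise SimConfigError("cpeptide_times must be strictly increasing")


@dataclass
class TruthLabels:
    """Ground-truth tables for recovery tests.

    participants: participant_id, arm, hla_group, decay_rate, cluster3_frac
        and the full per-participant cluster proportion vector.
    cells: cell_id, participant_id, cluster (1-5).
    chains: one row per generated chain with its clonotype id.
    """

    participants: pd.DataFrame
    cells: pd.DataFrame | None = None
    chains: pd.DataFrame | None = None


@dataclass
class SyntheticDataset:
    config: SimConfig
    cohort: pd.DataFrame
    counts: pd.DataFrame
    cell_meta: pd.DataFrame
    chains: pd.DataFrame
    flow: pd.DataFrame
    cpeptide: pd.DataFrame
    truth: TruthLabels


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(config.seed), stream]))


# ---------------------------------------------------------------------------
# cohort


def generate_cohort(config: SimConfig) -> tuple[pd.DataFrame, TruthLabels]:
    """Draw the participant table and plant the treatment-arm effect.

    The per-participant true decay rate is
    ``base_rate + beta_cluster3 * cluster3_frac * 1[arm == treated] +
    Normal(0, decay_noise_sd)`` where ``cluster3_frac`` is the participant's
    Dirichlet-drawn cluster-3 proportion.
    """
    config.validate()
    rng = _rng(config, 1)
    ids = [f"P{i + 1:03d}" for i in range(config.n_participants)]

    if config.arm_assignment is not None:
        missing = [p for p in ids if p not in config.arm_assignment]
        if missing:
            raise SimConfigError(f"arm_assignment missing participants {missing}")
        arms = np.array([config.arm_assignment[p] for p in ids])
        if not set(arms) <= {"treated", "placebo"}:
            raise SimConfigError("arm_assignment values must be treated/placebo")
    else:
        arms = np.array(["placebo"] * config.n_participants, dtype=object)
        arms[rng.permutation(config.n_participants)[: config.n_treated]] = "treated"

    if config.hla_group is not None:
        missing = [p for p in ids if p not in config.hla_group]
        if missing:
            raise SimConfigError(f"hla_group missing participants {missing}")
        hla = np.array([config.hla_group[p] for p in ids])
    else:
        hla = np.array(["nonDR4"] * config.n_participants, dtype=object)
        hla[rng.permutation(config.n_participants)[: config.n_dr4]] = "DR4"

    base = np.asarray(config.cluster_proportions, dtype=float)
    conc = config.dirichlet_concentration
    if conc > 0:
        props = rng.dirichlet(conc * base, size=config.n_participants)
    else:
        props = np.tile(base, (config.n_participants, 1))
    cluster3 = props[:, 2]
    noise = (
        rng.normal(0.0, config.decay_noise_sd, size=config.n_participants)
        if config.decay_noise_sd > 0
        else np.zeros(config.n_participants)
    )
    rates = (
        config.base_rate
        + config.beta_cluster3 * cluster3 * (arms == "treated")
        + noise
    )

    cohort = pd.DataFrame(
        {
            "participant_id": ids,
            "arm": arms,
            "hla_group": hla,
            "n_cells": config.n_cells_per_participant,
        }
    )
    truth_part = cohort.drop(columns="n_cells").copy()
    truth_part["decay_rate"] = rates
    truth_part["cluster3_frac"] = cluster3
    for k, c in enumerate(CLUSTERS):
        truth_part[f"prop_cluster_{c}"] = props[:, k]
    return cohort, TruthLabels(participants=truth_part)


# ---------------------------------------------------------------------------
# cells


def generate_cells(
    config: SimConfig, cohort: pd.DataFrame, truth: TruthLabels
) -> tuple[pd.DataFrame, pd.DataFrame, TruthLabels]:
    """Draw cluster labels and a cells x genes count matrix.

    Counts are negative binomial around the cluster's marker program, with
    log-normal library-size variation; ``dispersion == 0`` degenerates to
    Poisson.
    """
    config.validate()
    rng = _rng(config, 2)
    part = truth.participants.set_index("participant_id")

    marker_names = list(config.marker_gene_program)
    genes = marker_names + [
        f"GENE{i:04d}" for i in range(1, config.n_genes - len(marker_names) + 1)
    ]
    # mean profile per cluster over all genes
    prog = np.full((len(CLUSTERS), config.n_genes), config.baseline_mean)
    gene_index = {g: i for i, g in enumerate(genes)}
    for gene, means in config.marker_gene_program.items():
        prog[:, gene_index[gene]] = np.asarray(means, dtype=float)

    cell_rows, clusters_all = [], []
    for pid in cohort["participant_id"]:
        props = part.loc[pid, [f"prop_cluster_{c}" for c in CLUSTERS]].to_numpy(float)
        props = props / props.sum()
        n = int(cohort.set_index("participant_id").loc[pid, "n_cells"])
        cl = rng.choice(len(CLUSTERS), size=n, p=props) + 1
        clusters_all.append(cl)
        cell_rows.extend((f"{pid}_C{j + 1:03d}", pid) for j in range(n))
    clusters = np.concatenate(clusters_all)
    cell_ids = [r[0] for r in cell_rows]
    participants = [r[1] for r in cell_rows]

    lib = np.exp(rng.normal(0.0, config.libsize_sigma, size=len(cell_ids)))
    mu = prog[clusters - 1] * lib[:, None]
    if config.dispersion > 0:
        r = 1.0 / config.dispersion
        counts = rng.negative_binomial(r, r / (r + mu))
    else:
        counts = rng.poisson(mu)

    counts_df = pd.DataFrame(counts, index=pd.Index(cell_ids, name="cell_id"), columns=genes)
    arm_map = part["arm"]
    hla_map = part["hla_group"]
    meta = pd.DataFrame(
        {
            "cell_id": cell_ids,
            "participant_id": participants,
            "arm": [arm_map[p] for p in participants],
            "hla_group": [hla_map[p] for p in participants],
        }
    )
    cell_truth = pd.DataFrame(
        {"cell_id": cell_ids, "participant_id": participants, "cluster": clusters}
    )
    truth.cells = cell_truth
    return counts_df, meta, truth


# ---------------------------------------------------------------------------
# repertoire

_TRAV = tuple(f"TRAV{i}" for i in range(1, 9))
_TRAJ = tuple(f"TRAJ{i}" for i in range(1, 7))
_TRBV = tuple(f"TRBV{i}" for i in range(1, 9))
_TRBJ = tuple(f"TRBJ{i}" for i in range(1, 7))

_SENSE_CODONS = tuple(
    a + b + c
    for a in "TCAG"
    for b in "TCAG"
    for c in "TCAG"
    if a + b + c not in ("TAA", "TAG", "TGA")
)
_FW_CODONS = ("TTT", "TTC", "TGG")  # Phe / Trp terminal residue
_CYS_CODONS = ("TGT", "TGC")


def _random_junction(rng: np.random.Generator) -> tuple[str, str]:
    """A productive junction: C104 ... F/W118 with valid codon structure."""
    n_mid = int(rng.integers(10, 15))
    codons = [str(rng.choice(_CYS_CODONS))]
    codons += [str(c) for c in rng.choice(_SENSE_CODONS, size=n_mid)]
    codons.append(str(rng.choice(_FW_CODONS)))
    nt = "".join(codons)
    return nt, str(Seq(nt).translate())


def generate_repertoire(
    config: SimConfig, truth: TruthLabels
) -> tuple[pd.DataFrame, TruthLabels]:
    """Assign clonally structured paired TRA/TRB chains to the cells.

    Within each participant, cells are partitioned into clones with sizes
    from the configured distribution; clones of size >= 2 are placed
    preferentially in memory-like clusters (``expansion_weights``), public
    clonotypes are reused across participants with probability ``p_public``,
    a clone-level second TRA is added with probability ``p_second_tra``, and
    individual chains drop out with probability ``p_chain_dropout``.
    """
    config.validate()
    if truth.cells is None:
        raise ValueError("generate_cells must run before generate_repertoire")
    rng = _rng(config, 3)
    weights = np.asarray(config.expansion_weights, dtype=float)

    clone_probs = None
    if config.clone_size_probs is not None:
        clone_probs = np.asarray(config.clone_size_probs, dtype=float)
        clone_probs = clone_probs / clone_probs.sum()

    public_pool: list[dict] = []
    rows: list[dict] = []
    truth_rows: list[dict] = []
    clonotype_counter = 0

    for pid, sub in truth.cells.groupby("participant_id", sort=True):
        remaining = sub[["cell_id", "cluster"]].to_numpy(object)
        order = rng.permutation(len(remaining))
        remaining = remaining[order]
        while len(remaining):
            if clone_probs is not None:
                size = int(rng.choice(np.arange(1, len(clone_probs) + 1), p=clone_probs))
            else:
                size = int(rng.geometric(config.p_clone))
            size = min(size, len(remaining))
            if size >= 2:
                w = weights[np.asarray(remaining[:, 1], dtype=int) - 1]
                idx = rng.choice(len(remaining), size=size, replace=False, p=w / w.sum())
            else:
                idx = rng.choice(len(remaining), size=1, replace=False)
            members = remaining[idx]
            keep = np.ones(len(remaining), dtype=bool)
            keep[idx] = False
            remaining = remaining[keep]

            reuse = None
            if public_pool and rng.random() < config.p_public:
                candidates = [c for c in public_pool if c["origin"] != pid]
                if candidates:
                    reuse = candidates[int(rng.integers(len(candidates)))]
            if reuse is not None:
                clone = reuse
            else:
                clonotype_counter += 1
                tra_nt, tra_aa = _random_junction(rng)
                trb_nt, trb_aa = _random_junction(rng)
                clone = {
                    "clonotype_id": f"CT{clonotype_counter:05d}",
                    "origin": pid,
                    "chains": [
                        ("TRA", str(rng.choice(_TRAV)), str(rng.choice(_TRAJ)), tra_nt, tra_aa),
                        ("TRB", str(rng.choice(_TRBV)), str(rng.choice(_TRBJ)), trb_nt, trb_aa),
                    ],
                }
                if rng.random() < config.p_second_tra:
                    nt2, aa2 = _random_junction(rng)
                    clone["chains"].append(
                        ("TRA", str(rng.choice(_TRAV)), str(rng.choice(_TRAJ)), nt2, aa2)
                    )
                public_pool.append(clone)

            for cell_id, _cluster in members:
                for locus, v, j, nt, aa in clone["chains"]:
                    detected = rng.random() >= config.p_chain_dropout
                    truth_rows.append(
                        {
                            "cell_id": cell_id,
                            "participant_id": pid,
                            "locus": locus,
                            "junction": nt,
                            "clonotype_id": clone["clonotype_id"],
                            "detected": detected,
                        }
                    )
                    if detected:
                        rows.append(
                            {
                                "cell_id": cell_id,
                                "participant_id": pid,
                                "locus": locus,
                                "v_call": v,
                                "j_call": j,
                                "junction": nt,
                                "junction_aa": aa,
                                "productive": True,
                            }
                        )

    chains = pd.DataFrame(
        rows,
        columns=[
            "cell_id",
            "participant_id",
            "locus",
            "v_call",
            "j_call",
            "junction",
            "junction_aa",
            "productive",
        ],
    )
    chains = chains.sort_values(["cell_id", "locus", "junction"], kind="mergesort").reset_index(
        drop=True
    )
    truth.chains = pd.DataFrame(truth_rows)
    return chains, truth


# ---------------------------------------------------------------------------
# flow events

_NEG_MU, _POS_MU, _HI_MU = math.log(50.0), math.log(500.0), math.log(2000.0)
_FLOW_SIGMA = 0.4

_ALL_POS = ("CD3", "CD4", "CD154", "CD69")
_ALL_NEG = ("CD8", "CD14", "CD19", "CD56")

# surface profile per generated population; markers not listed default "neg"
_POP_PROFILES: dict[str, dict[str, str]] = {
    "naive": {"CD45RA": "pos", "CCR7": "pos", "CD127": "pos"},
    "TSCM": {"CD45RA": "pos", "CCR7": "pos", "CD95": "pos", "CD127": "pos"},
    "TCM": {"CD45RO": "pos", "CCR7": "pos", "CD95": "pos", "CD127": "pos"},
    "TEM": {"CD45RO": "pos", "CD95": "pos", "CD127": "pos"},
    "cluster3_like": {
        "CD45RO": "pos",
        "CCR7": "pos",
        "CD95": "pos",
        "CD2": "hi",
        "CD25": "pos",
        "CD137": "pos",
    },
}

DEFAULT_FLOW_COMPOSITION = {
    "naive": 0.36,
    "TSCM": 0.06,
    "TCM": 0.26,
    "TEM": 0.17,
    "cluster3_like": 0.15,
}

# fraction of each population drawn from the BHLHE40-high component; the
# cluster-3-like value plants the ~85% reported for that phenotype
DEFAULT_BHLHE40_HI = {
    "naive": 0.02,
    "TSCM": 0.20,
    "TCM": 0.30,
    "TEM": 0.40,
    "cluster3_like": 0.85,
}

_TH_MIX = {"Th1": 0.25, "Th2": 0.20, "Th17": 0.15, "Th1_17": 0.15, "other": 0.25}
_TH_STATES = {
    "Th1": {"CXCR3": "pos"},
    "Th2": {"CCR4": "pos"},
    "Th17": {"CCR4": "pos", "CCR6": "pos"},
    "Th1_17": {"CXCR3": "pos", "CCR6": "pos"},
    "other": {},
}

# positivity probability (BHLHE40-hi, BHLHE40-lo); GM-CSF and TNF-alpha are
# the cytokines coupled most strongly to the BHLHE40-high state
DEFAULT_CYTOKINE_POS = {
    "GMCSF": (0.40, 0.10),
    "TNFA": (0.55, 0.25),
    "IL2": (0.45, 0.30),
    "IFNG": (0.30, 0.22),
    "IL17A": (0.06, 0.04),
}

FLOW_MARKERS = tuple(
    ["CD3", "CD4", "CD8", "CD14", "CD19", "CD56", "CD45RA", "CD45RO", "CCR7", "CD95"]
    + ["CXCR3", "CCR4", "CCR6", "CD2", "CD25", "CD127", "CD137", "FOXP3", "CD154", "CD69"]
    + ["BHLHE40", "GMCSF", "TNFA", "IL2", "IFNG", "IL17A"]
)


def default_thresholds() -> dict[str, float]:
    """Positivity cutoffs matched to the generator's intensity components."""
    cuts = {m: math.exp((_NEG_MU + _POS_MU) / 2) for m in FLOW_MARKERS}
    cuts["CD2_hi"] = math.exp((_POS_MU + _HI_MU) / 2)
    return cuts


def _intensity(rng: np.random.Generator, state: str, size: int) -> np.ndarray:
    mu = {"neg": _NEG_MU, "pos": _POS_MU, "hi": _HI_MU}[state]
    return np.exp(rng.normal(mu, _FLOW_SIGMA, size=size))


def generate_flow_events(
    config: SimConfig,
    n_events: int = 5000,
    composition: Mapping[str, float] | None = None,
    bhlhe40_hi: Mapping[str, float] | None = None,
    cytokine_pos: Mapping[str, tuple[float, float]] | None = None,
    th_mix: Mapping[str, float] | None = None,
    stimulated: bool = True,
    cohort: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Draw flow events from log-normal mixtures per population.

    Each event carries every marker needed by the gating rules, plus truth
    columns ``population``, ``th_subset`` and ``bhlhe40_level``. With
    ``stimulated=False`` all cytokines are drawn from the negative component
    (a no-stimulation control). If a cohort table is given, events are
    assigned uniformly to participants.
    """
    config.validate()
    rng = _rng(config, 4)
    comp = dict(composition or DEFAULT_FLOW_COMPOSITION)
    hi_frac = {**DEFAULT_BHLHE40_HI, **(bhlhe40_hi or {})}
    cyt = dict(cytokine_pos or DEFAULT_CYTOKINE_POS)
    th = dict(th_mix or _TH_MIX)

    pops = list(comp)
    pvec = np.asarray([comp[p] for p in pops], dtype=float)
    pvec = pvec / pvec.sum()
    pop_draw = rng.choice(len(pops), size=n_events, p=pvec)
    pop_labels = np.array(pops, dtype=object)[pop_draw]

    th_names = list(th)
    th_p = np.asarray([th[t] for t in th_names], dtype=float)
    th_p = th_p / th_p.sum()
    th_draw = np.array(th_names, dtype=object)[rng.choice(len(th_names), size=n_events, p=th_p)]
    th_draw[pop_labels == "naive"] = "naive"

    hi = rng.random(n_events) < np.array([hi_frac.get(p, 0.0) for p in pop_labels])

    data: dict[str, np.ndarray] = {}
    for marker in FLOW_MARKERS:
        if marker in ("GMCSF", "TNFA", "IL2", "IFNG", "IL17A", "BHLHE40"):
            continue
        states = np.full(n_events, "neg", dtype=object)
        if marker in _ALL_POS:
            states[:] = "pos"
        for i, pop in enumerate(pops):
            profile = _POP_PROFILES[pop]
            mask = pop_draw == i
            if marker in profile:
                states[mask] = profile[marker]
        if marker in ("CXCR3", "CCR4", "CCR6"):
            for name, st in _TH_STATES.items():
                mask = th_draw == name
                states[mask] = st.get(marker, "neg")
        out = np.empty(n_events)
        for state in ("neg", "pos", "hi"):
            mask = states == state
            if mask.any():
                out[mask] = _intensity(rng, state, int(mask.sum()))
        data[marker] = out

    bh = np.where(hi, _HI_MU, _NEG_MU) + rng.normal(0.0, _FLOW_SIGMA, n_events)
    data["BHLHE40"] = np.exp(bh)

    for cytokine, (p_hi, p_lo) in cyt.items():
        if stimulated:
            p = np.where(hi, p_hi, p_lo)
            positive = rng.random(n_events) < p
        else:
            positive = np.zeros(n_events, dtype=bool)
        vals = _intensity(rng, "neg", n_events)
        if positive.any():
            vals[positive] = _intensity(rng, "pos", int(positive.sum()))
        data[cytokine] = vals

    events = pd.DataFrame(data)
    events.insert(0, "event_id", [f"E{i + 1:06d}" for i in range(n_events)])
    events["population"] = pop_labels
    events["th_subset"] = th_draw
    events["bhlhe40_level"] = np.where(hi, "hi", "lo")
    if cohort is not None:
        ids = cohort["participant_id"].to_numpy()
        events["participant_id"] = ids[rng.integers(len(ids), size=n_events)]
    return events


# ---------------------------------------------------------------------------
# C-peptide


def exponential_series(
    auc0: float,
    rate: float,
    times: Sequence[float],
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """AUC(t) = AUC(0) * exp(rate * t) * exp(measurement noise)."""
    if auc0 <= 0:
        raise ValueError("baseline AUC must be positive")
    t = np.asarray(times, dtype=float)
    noise = 0.0
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng()
        noise = rng.normal(0.0, noise_sd, size=t.size)
    return auc0 * np.exp(rate * t + noise)


def generate_cpeptide(
    config: SimConfig, truth: TruthLabels, times: Sequence[float] | None = None
) -> pd.DataFrame:
    """Longitudinal 2-hour AUC table (participant_id, month, auc)."""
    config.validate()
    rng = _rng(config, 5)
    t = np.asarray(times if times is not None else config.cpeptide_times, dtype=float)
    rows = []
    for _, row in truth.participants.iterrows():
        auc0 = float(
            np.exp(rng.normal(math.log(config.auc_baseline_mean), config.auc_baseline_sigma))
        )
        auc = exponential_series(auc0, float(row["decay_rate"]), t, config.auc_noise_sd, rng)
        rows.extend(
            {"participant_id": row["participant_id"], "month": m, "auc": a}
            for m, a in zip(t, auc)
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# orchestration


def simulate_dataset(config: SimConfig | None = None, **overrides) -> SyntheticDataset:
    """Run all generators in order and bundle outputs with their truth."""
    if config is None:
        config = SimConfig(**overrides)
    elif overrides:
        config = replace(config, **overrides)
    cohort, truth = generate_cohort(config)
    counts, meta, truth = generate_cells(config, cohort, truth)
    chains, truth = generate_repertoire(config, truth)
    flow = generate_flow_events(config, cohort=cohort)
    cpeptide = generate_cpeptide(config, truth)
    return SyntheticDataset(config, cohort, counts, meta, chains, flow, cpeptide, truth)
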