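"""Leakage-aware data partitioning for bipartite interaction data.

Near-duplicate metabolites (same fingerprint) and proteins (same sequence) are
collapsed first. Entities are then clustered by single-linkage on Euclidean
distance, with a per-entity distance threshold that depends linearly on a size
attribute (sequence length for proteins, from 7 at the shortest to 29 at the
longest; compound mass for metabolites, from 1.2 to 5) so that small species
do not all fall into one cluster. The double-blind split holds out whole
clusters of metabolites and proteins and routes each interacting pair to
train / protein-blind / metabolite-blind / double-blind by membership.

Negatives are drawn by frequency-respecting random pairing of the species seen
in the positives, discarding any candidate already present in the positive
set. Two randomization baselines corrupt the data on purpose: permuting the
pairing while preserving per-entity frequencies, and permuting the
id -> feature-vector assignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import json
import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import squareform, pdist

__all__ = [
    "InteractionTable",
    "read_interactions",
    "write_interactions",
    "collapse_duplicates",
    "threshold_schedule",
    "ClusterAssignment",
    "cluster_entities",
    "SplitFolds",
    "double_blind_split",
    "lenient_split",
    "sample_negatives",
    "corrupt_pairs",
    "corrupt_features",
    "PROTEIN_THRESHOLDS",
    "METABOLITE_THRESHOLDS",
]

#: default (min, max) clustering thresholds over the size attribute
PROTEIN_THRESHOLDS = (7.0, 29.0)
METABOLITE_THRESHOLDS = (1.2, 5.0)

MET_COL, PROT_COL, SCORE_COL, LABEL_COL = "metabolite_id", "protein_id", "score", "label"


@dataclass
class InteractionTable:
    """Rows of (metabolite_id, protein_id[, score][, label]); label 1 = positive."""

    frame: pd.DataFrame
    provenance: str = ""
    allow_duplicates: bool = False

    def __post_init__(self):
        for col in (MET_COL, PROT_COL):
            if col not in self.frame.columns:
                raise ValueError(f"interaction table lacks column {col!r}")
        if LABEL_COL not in self.frame.columns:
            self.frame = self.frame.assign(**{LABEL_COL: 1})
        if not self.allow_duplicates:
            for lab in (0, 1):
                sub = self.frame[self.frame[LABEL_COL] == lab]
                if sub.duplicated([MET_COL, PROT_COL]).any():
                    raise ValueError(f"duplicate pairs within label class {lab}")

    def __len__(self):
        return len(self.frame)

    @property
    def positives(self) -> pd.DataFrame:
        return self.frame[self.frame[LABEL_COL] == 1]

    def pair_set(self, label: int | None = 1) -> set:
        sub = self.frame if label is None else self.frame[self.frame[LABEL_COL] == label]
        return set(zip(sub[MET_COL], sub[PROT_COL]))


def read_interactions(path, provenance: str = "") -> InteractionTable:
    frame = pd.read_csv(path, sep="\t")
    return InteractionTable(frame=frame, provenance=provenance or str(path))


def write_interactions(table: InteractionTable, path) -> None:
    table.frame.to_csv(path, sep="\t", index=False)


# --------------------------------------------------------------------------
# Duplicate collapsing
# --------------------------------------------------------------------------


def collapse_duplicates(met_features: pd.DataFrame, sequences: dict,
                        interactions: InteractionTable):
    """Merge metabolites with identical feature rows and proteins with
    identical sequences; re-key interactions to the representatives.

    The representative of a duplicate group is its lexicographically smallest
    id. Returns (met_features, sequences, interactions, met_remap, prot_remap).
    """
    met_remap, prot_remap = {}, {}
    seen = {}
    for mid in met_features.index:
        key = tuple(np.nan_to_num(met_features.loc[mid].to_numpy(dtype=float),
                                  nan=np.inf))
        rep = seen.setdefault(key, mid)
        met_remap[mid] = rep
    seen = {}
    for pid in sorted(sequences):
        rep = seen.setdefault(sequences[pid], pid)
        prot_remap[pid] = rep
    kept_mets = sorted(set(met_remap.values()))
    kept_prots = sorted(set(prot_remap.values()))
    met_out = met_features.loc[kept_mets]
    seq_out = {p: sequences[p] for p in kept_prots}
    frame = interactions.frame.copy()
    frame[MET_COL] = frame[MET_COL].map(met_remap)
    frame[PROT_COL] = frame[PROT_COL].map(prot_remap)
    frame = frame.drop_duplicates([MET_COL, PROT_COL, LABEL_COL]).reset_index(drop=True)
    out = InteractionTable(frame=frame, provenance=interactions.provenance)
    return met_out, seq_out, out, met_remap, prot_remap


# --------------------------------------------------------------------------
# Threshold schedule and clustering
# --------------------------------------------------------------------------


def threshold_schedule(sizes: pd.Series, min_thr: float, max_thr: float) -> pd.Series:
    """Per-entity distance threshold, linear in the size attribute.

    thr(s) = min_thr + (max_thr - min_thr) * (s - s_min) / (s_max - s_min);
    if all sizes coincide every threshold is min_thr.
    """
    if min_thr > max_thr:
        raise ValueError(f"min_thr {min_thr} > max_thr {max_thr}")
    sizes = pd.Series(sizes, dtype=float)
    s_min, s_max = sizes.min(), sizes.max()
    if s_max == s_min:
        return pd.Series(min_thr, index=sizes.index)
    return min_thr + (max_thr - min_thr) * (sizes - s_min) / (s_max - s_min)


@dataclass
class ClusterAssignment:
    """entity_id -> cluster_id; clusters are connected components of the
    below-threshold link relation (single linkage / transitive closure)."""

    assignment: dict
    kind: str = ""
    params: dict = field(default_factory=dict)

    def cluster_of(self, entity_id) -> int:
        return self.assignment[entity_id]

    @property
    def n_clusters(self) -> int:
        return len(set(self.assignment.values()))

    def members(self) -> dict:
        out: dict = {}
        for e, c in self.assignment.items():
            out.setdefault(c, []).append(e)
        return out


def cluster_entities(features: pd.DataFrame, thresholds: pd.Series,
                     kind: str = "", pair_rule: str = "mean") -> ClusterAssignment:
    """Single-linkage clustering: a, b linked iff Euclidean distance < the
    pairwise threshold (mean of the two per-entity thresholds by default;
    ``pair_rule`` in {"mean", "min", "max"})."""
    ids = list(features.index)
    thr = pd.Series(thresholds).reindex(ids)
    if thr.isna().any():
        raise ValueError("thresholds do not cover all entities")
    X = features.to_numpy(dtype=float)
    if len(ids) == 1:
        return ClusterAssignment({ids[0]: 0}, kind=kind, params={"pair_rule": pair_rule})
    D = squareform(pdist(X, metric="euclidean"))
    t = thr.to_numpy()
    if pair_rule == "mean":
        T = (t[:, None] + t[None, :]) / 2.0
    elif pair_rule == "min":
        T = np.minimum(t[:, None], t[None, :])
    elif pair_rule == "max":
        T = np.maximum(t[:, None], t[None, :])
    else:
        raise ValueError(f"unknown pair_rule {pair_rule!r}")
    link = D < T
    np.fill_diagonal(link, True)
    _, labels = connected_components(csr_matrix(link), directed=False)
    return ClusterAssignment(dict(zip(ids, labels.tolist())), kind=kind,
                             params={"pair_rule": pair_rule})


# --------------------------------------------------------------------------
# Splits
# --------------------------------------------------------------------------


@dataclass
class SplitFolds:
    train: InteractionTable
    protein_blind: InteractionTable
    metabolite_blind: InteractionTable
    double_blind: InteractionTable
    heldout_met_clusters: set = field(default_factory=set)
    heldout_prot_clusters: set = field(default_factory=set)
    manifest: dict = field(default_factory=dict)

    def items(self):
        return [("train", self.train), ("protein_blind", self.protein_blind),
                ("metabolite_blind", self.metabolite_blind),
                ("double_blind", self.double_blind)]

    def write(self, outdir) -> None:
        import pathlib

        outdir = pathlib.Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, table in self.items():
            write_interactions(table, outdir / f"{name}.tsv")
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(self.manifest, fh, indent=1)


def double_blind_split(interactions: InteractionTable,
                       met_clusters: ClusterAssignment,
                       prot_clusters: ClusterAssignment,
                       holdout_frac_met: float = 0.3,
                       holdout_frac_prot: float = 0.3,
                       seed: int = 0) -> SplitFolds:
    """Hold out whole clusters of metabolites and proteins; route each pair by
    membership of its two entities (both held out -> double-blind, one ->
    the corresponding single-blind fold, neither -> train)."""
    for frac, name in ((holdout_frac_met, "holdout_frac_met"),
                       (holdout_frac_prot, "holdout_frac_prot")):
        if not 0.0 < frac < 1.0:
            raise ValueError(f"{name} must be in (0, 1), got {frac}")
    frame = interactions.frame
    missing_m = set(frame[MET_COL]) - set(met_clusters.assignment)
    missing_p = set(frame[PROT_COL]) - set(prot_clusters.assignment)
    if missing_m or missing_p:
        raise ValueError(f"entities without cluster: {sorted(missing_m)[:3]} "
                         f"{sorted(missing_p)[:3]}")
    rng = np.random.default_rng(seed)
    met_cl = sorted(set(met_clusters.assignment.values()))
    prot_cl = sorted(set(prot_clusters.assignment.values()))
    n_m = max(1, int(round(holdout_frac_met * len(met_cl))))
    n_p = max(1, int(round(holdout_frac_prot * len(prot_cl))))
    held_m = set(rng.choice(met_cl, size=n_m, replace=False).tolist())
    held_p = set(rng.choice(prot_cl, size=n_p, replace=False).tolist())

    m_out = frame[MET_COL].map(met_clusters.assignment).isin(held_m).to_numpy()
    p_out = frame[PROT_COL].map(prot_clusters.assignment).isin(held_p).to_numpy()
    folds = {
        "train": frame[~m_out & ~p_out],
        "protein_blind": frame[~m_out & p_out],
        "metabolite_blind": frame[m_out & ~p_out],
        "double_blind": frame[m_out & p_out],
    }
    held_met_entities = [e for e, c in met_clusters.assignment.items() if c in held_m]
    held_prot_entities = [e for e, c in prot_clusters.assignment.items() if c in held_p]
    manifest = {
        "seed": int(seed),
        "holdout_frac_met_clusters": holdout_frac_met,
        "holdout_frac_prot_clusters": holdout_frac_prot,
        "holdout_frac_met_entities": len(held_met_entities) / len(met_clusters.assignment),
        "holdout_frac_prot_entities": len(held_prot_entities) / len(prot_clusters.assignment),
        "n_met_clusters": len(met_cl),
        "n_prot_clusters": len(prot_cl),
        "fold_sizes": {k: int(len(v)) for k, v in folds.items()},
    }
    prov = interactions.provenance
    return SplitFolds(
        train=InteractionTable(folds["train"].reset_index(drop=True), prov),
        protein_blind=InteractionTable(folds["protein_blind"].reset_index(drop=True), prov),
        metabolite_blind=InteractionTable(folds["metabolite_blind"].reset_index(drop=True), prov),
        double_blind=InteractionTable(folds["double_blind"].reset_index(drop=True), prov),
        heldout_met_clusters=held_m, heldout_prot_clusters=held_p,
        manifest=manifest)


def lenient_split(interactions: InteractionTable, val_frac: float,
                  seed: int = 0):
    """Uniform pair-level split into (train, validation); pair-disjoint, but
    individual metabolites and proteins may appear on both sides."""
    if not 0.0 < val_frac < 1.0:
        raise ValueError(f"val_frac must be in (0, 1), got {val_frac}")
    frame = interactions.frame
    if len(frame) < 2:
        raise ValueError("need at least 2 pairs to split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(frame))
    n_val = max(1, int(round(val_frac * len(frame))))
    val_idx = order[:n_val]
    train_idx = order[n_val:]
    prov = interactions.provenance
    return (InteractionTable(frame.iloc[np.sort(train_idx)].reset_index(drop=True), prov),
            InteractionTable(frame.iloc[np.sort(val_idx)].reset_index(drop=True), prov))


# --------------------------------------------------------------------------
# Negatives and randomization baselines
# --------------------------------------------------------------------------

RETRY_FACTOR = 100


def sample_negatives(positives: InteractionTable, seed: int = 0,
                     n_negatives: int | None = None,
                     global_positives: set | None = None) -> InteractionTable:
    """Frequency-respecting random pairing of the species found in the
    positives; candidates present in the (global) positive set are discarded
    and redrawn. Output size defaults to the positive count (balanced 1:1).

    Duplicate negatives are also redrawn, but accepted once the retry budget
    (RETRY_FACTOR x target) is exhausted. If no negative pair exists at all
    (the bipartite graph is complete) an error is raised.
    """
    pos = positives.positives
    if len(pos) == 0:
        raise ValueError("positive table is empty")
    target = n_negatives if n_negatives is not None else len(pos)
    forbidden = set(global_positives) if global_positives is not None else positives.pair_set(1)
    mets, met_counts = np.unique(pos[MET_COL], return_counts=True)
    prots, prot_counts = np.unique(pos[PROT_COL], return_counts=True)
    if len(mets) * len(prots) <= len({(m, p) for m, p in forbidden
                                      if m in set(mets) and p in set(prots)}):
        raise ValueError("no negative pair exists: positive set covers the full bipartite graph")
    met_p = met_counts / met_counts.sum()
    prot_p = prot_counts / prot_counts.sum()
    rng = np.random.default_rng(seed)
    out, seen = [], set()
    cap = RETRY_FACTOR * target
    n_distinct_allowed = len(mets) * len(prots) - len(forbidden)
    # uniqueness is unattainable when the distinct negative space is smaller
    # than the request; skip straight to the duplicate-tolerant phase
    attempts = cap + 1 if target > n_distinct_allowed else 0
    while len(out) < target:
        m = mets[rng.choice(len(mets), p=met_p)]
        p = prots[rng.choice(len(prots), p=prot_p)]
        attempts += 1
        if (m, p) in forbidden:
            if attempts > 2 * cap:
                raise RuntimeError("negative sampling retry budget exhausted")
            continue
        if (m, p) in seen and attempts <= cap:
            continue
        seen.add((m, p))
        out.append((m, p))
    frame = pd.DataFrame(out, columns=[MET_COL, PROT_COL])
    frame[LABEL_COL] = 0
    # duplicates possible only if the retry budget ran out
    return InteractionTable(frame, provenance=positives.provenance,
                            allow_duplicates=True)


def attach_negatives(positives: InteractionTable, seed: int = 0,
                     global_positives: set | None = None) -> InteractionTable:
    """Positives plus an equally sized sampled negative set in one table."""
    negs = sample_negatives(positives, seed=seed, global_positives=global_positives)
    frame = pd.concat([positives.positives, negs.frame], ignore_index=True)
    # duplicate negatives are possible when a fold's bipartite graph is dense
    return InteractionTable(frame, provenance=positives.provenance,
                            allow_duplicates=True)


def corrupt_pairs(positives: InteractionTable, seed: int = 0) -> InteractionTable:
    """Randomize the pairing while preserving each entity's frequency exactly
    (a permutation of the protein column against the metabolite column)."""
    pos = positives.positives
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(pos))
    frame = pd.DataFrame({
        MET_COL: pos[MET_COL].to_numpy(),
        PROT_COL: pos[PROT_COL].to_numpy()[perm],
        LABEL_COL: 1,
    })
    if SCORE_COL in pos.columns:
        frame[SCORE_COL] = pos[SCORE_COL].to_numpy()
    # duplicates created by the permutation are kept: collapsing them would
    # change the frequency spectrum, and the duplicate artifact is part of
    # what this baseline measures
    return InteractionTable(frame, provenance=positives.provenance + "+pair-randomized",
                            allow_duplicates=True)


def corrupt_features(entity_features, seed: int = 0, kind: str = "metabolite"):
    """Permute the id -> feature-vector assignment uniformly at random.

    The multiset of feature vectors (rows of a DataFrame, or values of a
    sequence dict) is unchanged; only which id owns which vector moves.
    """
    if kind not in ("metabolite", "protein"):
        raise ValueError(f"kind must be metabolite|protein, got {kind!r}")
    rng = np.random.default_rng(seed)
    if isinstance(entity_features, pd.DataFrame):
        perm = rng.permutation(len(entity_features))
        out = entity_features.iloc[perm].copy()
        out.index = entity_features.index
        return out
    ids = list(entity_features)
    perm = rng.permutation(len(ids))
    return {ids[i]: entity_features[ids[perm[i]]] for i in range(len(ids))}
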