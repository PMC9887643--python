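"""End-to-end orchestration: featurize, cluster, split, train, evaluate.

These helpers tie the modules together for a full run on a cohort (synthetic
or read from FASTA/TSV inputs). Desk-scale defaults are used for the model:
sequences padded to 128 tokens, 32 residue-embedding features and a reduced
architecture, so a complete train/evaluate cycle runs in minutes on one CPU.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import featurize, partition
from .model import InteractionModel, ModelConfig
from .train import PairStore, TrainConfig, fit
from .evaluate import evaluate_folds

__all__ = [
    "DESK_MODEL_CONFIG",
    "DESK_TRAIN_CONFIG",
    "build_store",
    "cluster_cohort",
    "split_interactions",
    "attach_fold_negatives",
    "run_training",
    "PipelineResult",
]


def desk_model_config(**overrides) -> ModelConfig:
    """Reduced-dimension architecture for CPU-scale experiments."""
    base = dict(d_embed=32, n_transformer_layers=1, transformer_heads=2,
                ff_dim=64, attention_space=32, n_heads=8, n_residual_blocks=2,
                hidden_dim=64, met_hidden=128, dropout=0.1, seq_len=96,
                dtype="float32")
    base.update(overrides)
    return ModelConfig(**base)


def desk_train_config(**overrides) -> TrainConfig:
    base = dict(epochs=60, learning_rate=1e-3, weight_decay=1e-5,
                base_batch_size=32, milestones=(30, 45, 55), factor=2.0, seed=0)
    base.update(overrides)
    return TrainConfig(**base)


DESK_MODEL_CONFIG = desk_model_config()
DESK_TRAIN_CONFIG = desk_train_config()


def build_store(met_table: featurize.MetaboliteFeatureTable, sequences: dict,
                pad_to: int = 128, n_features: int = 32,
                standardize: bool = True):
    """Tokenize + embed proteins and assemble the shared feature store.

    Returns (PairStore, tokenized dict, rejection log). ``met_table`` must be
    processed (filtered/scaled/imputed). By default the embedding table is
    standardized over the corpus token frequencies before embedding.
    """
    if not met_table.processed:
        met_table = featurize.process_table(met_table)
    tokenized, rejected = featurize.tokenize_many(sequences, pad_to=pad_to)
    if not tokenized:
        raise ValueError("every protein sequence was rejected")
    table = featurize.ResidueEmbeddingTable(n_features=n_features)
    if standardize:
        table = featurize.standardize_table(table, tokenized.values())
    prot_ids = list(tokenized)
    embedded = np.stack([featurize.embed_residues(tokenized[p], table)
                         for p in prot_ids]).astype(np.float32)
    met_ids = met_table.ids
    store = PairStore(met_table.matrix.astype(np.float32), embedded,
                      {m: i for i, m in enumerate(met_ids)},
                      {p: i for i, p in enumerate(prot_ids)})
    return store, tokenized, rejected


def cluster_cohort(sequences: dict, met_frame: pd.DataFrame,
                   fingerprint_prefix: str = "fp_", mass_column: str = "mass",
                   pair_rule: str = "mean"):
    """Cluster proteins on residue-composition distance (thresholds linear in
    sequence length, 7..29) and metabolites on fingerprint distance
    (thresholds linear in mass, 1.2..5)."""
    comp = featurize.protein_composition(sequences)
    lengths = pd.Series({p: len(s) for p, s in sequences.items()})
    prot_thr = partition.threshold_schedule(lengths, *partition.PROTEIN_THRESHOLDS)
    prot_cl = partition.cluster_entities(comp, prot_thr, kind="protein",
                                         pair_rule=pair_rule)
    fp_cols = [c for c in met_frame.columns if c.startswith(fingerprint_prefix)]
    if not fp_cols:
        raise ValueError(f"no fingerprint columns with prefix {fingerprint_prefix!r}")
    met_thr = partition.threshold_schedule(met_frame[mass_column],
                                           *partition.METABOLITE_THRESHOLDS)
    met_cl = partition.cluster_entities(met_frame[fp_cols], met_thr,
                                        kind="metabolite", pair_rule=pair_rule)
    return met_cl, prot_cl


def split_interactions(positives: partition.InteractionTable, sequences: dict,
                       met_frame: pd.DataFrame, holdout_frac: float = 0.3,
                       seed: int = 0) -> partition.SplitFolds:
    met_cl, prot_cl = cluster_cohort(sequences, met_frame)
    return partition.double_blind_split(positives, met_cl, prot_cl,
                                        holdout_frac_met=holdout_frac,
                                        holdout_frac_prot=holdout_frac,
                                        seed=seed)


def attach_fold_negatives(folds: partition.SplitFolds, seed: int = 0) -> dict:
    """Balanced negatives per fold, all checked against the global positive set."""
    global_pos = set()
    for _, table in folds.items():
        global_pos |= table.pair_set(1)
    out = {}
    for i, (name, table) in enumerate(folds.items()):
        if len(table) == 0:
            continue
        try:
            out[name] = partition.attach_negatives(table, seed=seed + i,
                                                   global_positives=global_pos)
        except ValueError:
            # degenerate fold (its positives cover the whole bipartite grid);
            # it cannot be evaluated against sampled negatives
            continue
    return out


@dataclass
class PipelineResult:
    model: InteractionModel
    store: PairStore
    folds: partition.SplitFolds
    folds_with_negatives: dict
    history: object
    reports: dict = field(default_factory=dict)


def run_training(positives: partition.InteractionTable, sequences: dict,
                 met_frame: pd.DataFrame, model_config: ModelConfig | None = None,
                 train_config: TrainConfig | None = None,
                 holdout_frac: float = 0.3, variant: str = "T+AttP",
                 seed: int = 0, evaluate: bool = True, pretrained=None,
                 validation_frac: float = 0.0) -> PipelineResult:
    """Full pipeline on raw inputs: process features, split double-blind,
    sample negatives, train, and (optionally) evaluate every fold.

    When ``validation_frac`` is positive, a cluster-level validation subset
    is carved out of the training fold (a small double-blind split within
    train, so validation entities are unseen during fitting) and the
    checkpoint with the best validation AUC is restored before evaluation.
    The evaluation folds themselves are never used for model selection.
    """
    model_config = model_config or desk_model_config()
    train_config = train_config or desk_train_config(seed=seed)
    met_table = featurize.process_table(
        featurize.MetaboliteFeatureTable.from_dataframe(met_frame))
    store, _, _ = build_store(met_table, sequences,
                              pad_to=model_config.seq_len,
                              n_features=model_config.d_embed)
    folds = split_interactions(positives, sequences, met_frame,
                               holdout_frac=holdout_frac, seed=seed)
    with_negs = attach_fold_negatives(folds, seed=seed)
    model = InteractionModel(model_config, met_input_dim=store.met_matrix.shape[1],
                             seed=seed, variant=variant)
    if pretrained is not None:
        model.load_encoder(pretrained)

    train_table, val_table = with_negs["train"], None
    ckpt = None
    if validation_frac > 0:
        train_seqs = {p: sequences[p]
                      for p in set(folds.train.frame["protein_id"])}
        train_mets = met_frame.loc[sorted(set(folds.train.frame["metabolite_id"]))]
        inner = split_interactions(folds.train, train_seqs, train_mets,
                                   holdout_frac=validation_frac, seed=seed + 17)
        inner_train = inner.train
        val_pos = partition.InteractionTable(
            pd.concat([inner.double_blind.frame, inner.protein_blind.frame,
                       inner.metabolite_blind.frame], ignore_index=True))
        if len(val_pos) >= 10 and len(inner_train) > 0:
            global_pos = set()
            for _, t in folds.items():
                global_pos |= t.pair_set(1)
            train_table = partition.attach_negatives(
                inner_train, seed=seed + 31, global_positives=global_pos)
            val_table = partition.attach_negatives(
                val_pos, seed=seed + 32, global_positives=global_pos)
            import tempfile

            ckpt = tempfile.NamedTemporaryFile(suffix=".npz", delete=False).name

    model, history = fit(model, store, train_table, train_config,
                         val_table=val_table, checkpoint_path=ckpt)
    if ckpt is not None and history.best_epoch is not None:
        model = InteractionModel.load(ckpt)
        import os

        os.unlink(ckpt)
    reports = {}
    if evaluate:
        reports = evaluate_folds(model, store, with_negs)
    return PipelineResult(model=model, store=store, folds=folds,
                          folds_with_negatives=with_negs, history=history,
                          reports=reports)
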