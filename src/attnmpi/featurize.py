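"""Featurization of metabolites and proteins.

Metabolites arrive as feature tables (global physico-chemical properties plus
a decoded 2D substructure fingerprint). Processing follows the order
filter -> scale -> impute: non-informative columns (one value in more than
99% of rows) are dropped, continuous features are min-max scaled to [-3, 3],
and missing values are mean-imputed with a paired 0/1 missingness indicator
column. The fitted state (removed columns, per-column affine parameters,
imputation means) is kept so unseen metabolites can be transformed with the
same maps; transformed values outside the fitted range are clamped.

Proteins arrive as amino-acid sequences. Sequences longer than 1022 residues
are rejected; the rest are tokenized as BEGIN + residues + END and padded to a
fixed length (1024 by default). Each token is embedded with a 128-column
residue property table and a sinusoidal positional encoding is added.
"""

from __future__ import annotations

import base64
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "FingerprintDecodeError",
    "SequenceRejectedError",
    "decode_fingerprint",
    "encode_fingerprint",
    "FINGERPRINT_BITS",
    "MetaboliteFeatureTable",
    "filter_noninformative",
    "scale_continuous",
    "impute_missing",
    "process_table",
    "transform_records",
    "transform_from_state",
    "AA_ALPHABET",
    "UNK", "BEGIN", "END", "PAD", "MASK", "VOCAB_SIZE",
    "TokenizedProtein",
    "tokenize_protein",
    "tokenize_many",
    "ResidueEmbeddingTable",
    "standardize_table",
    "positional_encoding",
    "embed_residues",
    "read_fasta",
    "read_metabolite_table",
    "protein_composition",
]

# --------------------------------------------------------------------------
# Fingerprints
# --------------------------------------------------------------------------

#: Bit length of the standard public 2D substructure fingerprint.
FINGERPRINT_BITS = 881


class FingerprintDecodeError(ValueError):
    pass


def decode_fingerprint(raw, record_id: str = "?") -> np.ndarray:
    """Decode a 2D substructure fingerprint blob to a 0/1 vector.

    ``raw`` is either a base64 string whose decoded bytes start with a 4-byte
    big-endian bit-length prefix followed by MSB-first packed bits, or an
    already-decoded 0/1 sequence (returned as an int array unchanged).
    """
    if isinstance(raw, (list, tuple, np.ndarray)):
        vec = np.asarray(raw)
        if not np.isin(vec, (0, 1)).all():
            raise FingerprintDecodeError(
                f"record {record_id}: pre-decoded fingerprint has non-binary entries")
        return vec.astype(np.int8)
    if isinstance(raw, str):
        raw = raw.encode("ascii")
    try:
        blob = base64.b64decode(raw, validate=True)
    except Exception as exc:
        raise FingerprintDecodeError(f"record {record_id}: invalid base64 body") from exc
    if len(blob) < 4:
        raise FingerprintDecodeError(f"record {record_id}: blob shorter than length prefix")
    n_bits = int.from_bytes(blob[:4], "big")
    body = blob[4:]
    if len(body) * 8 < n_bits:
        raise FingerprintDecodeError(
            f"record {record_id}: truncated blob ({len(body) * 8} bits < {n_bits})")
    bits = np.unpackbits(np.frombuffer(body, dtype=np.uint8))
    return bits[:n_bits].astype(np.int8)


def encode_fingerprint(bits: np.ndarray) -> str:
    """Inverse of :func:`decode_fingerprint` for 0/1 vectors (testing/round-trips)."""
    bits = np.asarray(bits, dtype=np.uint8)
    body = np.packbits(bits).tobytes()
    return base64.b64encode(len(bits).to_bytes(4, "big") + body).decode("ascii")


# --------------------------------------------------------------------------
# Metabolite feature tables
# --------------------------------------------------------------------------

KIND_BINARY = "binary"
KIND_DISCRETE = "discrete"
KIND_CONTINUOUS = "continuous"
KIND_INDICATOR = "missingness-indicator"


@dataclass
class MetaboliteFeatureTable:
    """Per-metabolite numeric feature matrix with per-column kinds and state.

    ``frame`` is indexed by metabolite id. ``feature_kinds`` maps each column
    to binary / discrete / continuous / missingness-indicator. The fitted
    processing state lives in ``removed_columns`` (filter), ``scaler_state``
    (per-column (min, max)) and ``imputer_state`` (per-column mean).
    """

    frame: pd.DataFrame
    feature_kinds: dict = field(default_factory=dict)
    removed_columns: list = field(default_factory=list)
    scaler_state: dict = field(default_factory=dict)
    imputer_state: dict = field(default_factory=dict)
    filtered: bool = False
    scaled: bool = False
    imputed: bool = False

    SCALE_LO = -3.0
    SCALE_HI = 3.0

    @property
    def ids(self) -> list:
        return list(self.frame.index)

    @property
    def processed(self) -> bool:
        return self.filtered and self.scaled and self.imputed

    @property
    def matrix(self) -> np.ndarray:
        return self.frame.to_numpy(dtype=float)

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame,
                       feature_kinds: dict | None = None) -> "MetaboliteFeatureTable":
        if frame.index.has_duplicates:
            dupes = frame.index[frame.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate metabolite ids: {dupes[:5]}")
        frame = frame.astype(float)
        if feature_kinds is None:
            feature_kinds = {c: infer_kind(frame[c]) for c in frame.columns}
        return cls(frame=frame, feature_kinds=dict(feature_kinds))

    def copy(self) -> "MetaboliteFeatureTable":
        return MetaboliteFeatureTable(
            frame=self.frame.copy(), feature_kinds=dict(self.feature_kinds),
            removed_columns=list(self.removed_columns),
            scaler_state=dict(self.scaler_state), imputer_state=dict(self.imputer_state),
            filtered=self.filtered, scaled=self.scaled, imputed=self.imputed)

    # -- state serialization ------------------------------------------------

    def state_dict(self) -> dict:
        means = {c: float(self.frame[c].mean()) for c in self.frame.columns
                 if self.feature_kinds.get(c) != KIND_INDICATOR}
        return {
            "feature_kinds": self.feature_kinds,
            "removed_columns": self.removed_columns,
            "scaler_state": {c: list(v) for c, v in self.scaler_state.items()},
            "imputer_state": self.imputer_state,
            "columns": list(self.frame.columns),
            "column_means": means,
            "flags": {"filtered": self.filtered, "scaled": self.scaled,
                      "imputed": self.imputed},
        }

    def save_state(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.state_dict(), fh, indent=1)

    @staticmethod
    def load_state(path) -> dict:
        with open(path) as fh:
            return json.load(fh)


def infer_kind(col: pd.Series) -> str:
    vals = col.dropna().unique()
    if np.isin(vals, (0.0, 1.0)).all():
        return KIND_BINARY
    if np.allclose(vals, np.round(vals)):
        return KIND_DISCRETE
    return KIND_CONTINUOUS


def filter_noninformative(table: MetaboliteFeatureTable):
    """Drop columns whose modal value (missingness counted as a value) occupies
    strictly more than 99% of rows. Returns (table, removal_log)."""
    if len(table.frame) == 0:
        raise ValueError("cannot filter an empty table")
    if table.filtered:
        return table, []
    out = table.copy()
    n = len(out.frame)
    log = []
    for col in list(out.frame.columns):
        top = out.frame[col].value_counts(dropna=False).iloc[0]
        freq = top / n
        if freq > 0.99:
            log.append((col, float(freq)))
            out.frame.drop(columns=[col], inplace=True)
            out.feature_kinds.pop(col, None)
    out.removed_columns = [c for c, _ in log]
    out.filtered = True
    return out, log


def scale_continuous(table: MetaboliteFeatureTable) -> MetaboliteFeatureTable:
    """Min-max scale continuous (and discrete count) columns onto [-3, 3].

    The per-column affine parameters are stored so unseen metabolites can be
    transformed with the fitted map (and clamped into the range).
    """
    if table.scaled:
        return table
    out = table.copy()
    lo, hi = table.SCALE_LO, table.SCALE_HI
    for col in out.frame.columns:
        if out.feature_kinds.get(col) not in (KIND_CONTINUOUS, KIND_DISCRETE):
            continue
        vmin = out.frame[col].min(skipna=True)
        vmax = out.frame[col].max(skipna=True)
        if not np.isfinite(vmin) or vmax == vmin:
            raise ValueError(f"column {col!r}: constant or all-missing at scaling stage")
        scaled = lo + (out.frame[col] - vmin) * (hi - lo) / (vmax - vmin)
        out.frame[col] = scaled.clip(lo, hi)  # guard float round-off at the ends
        out.scaler_state[col] = (float(vmin), float(vmax))
    out.scaled = True
    return out


def impute_missing(table: MetaboliteFeatureTable) -> MetaboliteFeatureTable:
    """Replace missing entries by the column mean over observed entries and
    append a 0/1 missingness-indicator column per affected source column."""
    if table.imputed:
        return table
    out = table.copy()
    indicators = {}
    for col in list(out.frame.columns):
        mask = out.frame[col].isna()
        if not mask.any():
            continue
        if mask.all():
            raise ValueError(f"column {col!r} is entirely missing")
        mean = float(out.frame[col].mean(skipna=True))
        out.frame[col] = out.frame[col].fillna(mean)
        out.imputer_state[col] = mean
        indicators[f"{col}__missing"] = mask.astype(float)
    for name, ind in indicators.items():
        out.frame[name] = ind
        out.feature_kinds[name] = KIND_INDICATOR
    out.imputed = True
    return out


def process_table(table: MetaboliteFeatureTable) -> MetaboliteFeatureTable:
    """filter -> scale -> impute; a no-op on an already processed table."""
    t, _ = filter_noninformative(table)
    return impute_missing(scale_continuous(t))


def transform_records(fitted: MetaboliteFeatureTable,
                      frame: pd.DataFrame) -> pd.DataFrame:
    """Apply a fitted table's filter/scaler/imputer state to unseen records.

    Scaled values outside [-3, 3] (possible for out-of-range raw values) are
    clamped to the boundary.
    """
    if not fitted.processed:
        raise ValueError("transform_records requires a fully processed table")
    return transform_from_state(fitted.state_dict(), frame)


def transform_from_state(state: dict, frame: pd.DataFrame) -> pd.DataFrame:
    """Like :func:`transform_records`, but driven by a saved JSON state
    (see ``MetaboliteFeatureTable.save_state``/``load_state``)."""
    if not all(state["flags"].values()):
        raise ValueError("state does not describe a fully processed table")
    frame = frame.astype(float)
    frame = frame.drop(columns=[c for c in state["removed_columns"]
                                if c in frame.columns])
    lo, hi = MetaboliteFeatureTable.SCALE_LO, MetaboliteFeatureTable.SCALE_HI
    kinds = state["feature_kinds"]
    cols = {}
    for col in state["columns"]:
        if kinds.get(col) == KIND_INDICATOR:
            src = col[: -len("__missing")]
            cols[col] = (frame[src].isna().astype(float) if src in frame
                         else pd.Series(0.0, index=frame.index))
            continue
        if col not in frame.columns:
            raise KeyError(f"new records lack column {col!r}")
        vals = frame[col].copy()
        if col in state["scaler_state"]:
            vmin, vmax = state["scaler_state"][col]
            vals = lo + (vals - vmin) * (hi - lo) / (vmax - vmin)
            vals = vals.clip(lo, hi)
        if vals.isna().any():
            # columns with no missingness at fit time fall back to their mean
            fill = state["imputer_state"].get(col,
                                              state["column_means"].get(col))
            vals = vals.fillna(fill)
        cols[col] = vals
    return pd.DataFrame(cols, index=frame.index)


# --------------------------------------------------------------------------
# Protein tokenization and embedding
# --------------------------------------------------------------------------

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {aa: i for i, aa in enumerate(AA_ALPHABET)}
UNK = 20
BEGIN = 21
END = 22
PAD = 23
MASK = 24  # used only during masked pretraining
VOCAB_SIZE = 25

#: default padded length; raw sequences longer than DEFAULT_PAD_TO - 2 rejected
DEFAULT_PAD_TO = 1024


class SequenceRejectedError(ValueError):
    pass


@dataclass
class TokenizedProtein:
    id: str
    tokens: np.ndarray  # (pad_to,) int
    length_raw: int

    @property
    def pad_to(self) -> int:
        return len(self.tokens)


def tokenize_protein(protein_id: str, sequence: str,
                     pad_to: int = DEFAULT_PAD_TO) -> TokenizedProtein:
    """BEGIN + residues + END, right-padded with PAD to ``pad_to`` tokens.

    Characters outside the 20-letter alphabet map to the unknown token.
    Raises :class:`SequenceRejectedError` for sequences longer than
    ``pad_to - 2`` residues and ``ValueError`` for empty ones.
    """
    sequence = sequence.strip().upper()
    if not sequence:
        raise ValueError(f"protein {protein_id}: empty sequence")
    max_raw = pad_to - 2
    if len(sequence) > max_raw:
        raise SequenceRejectedError(
            f"protein {protein_id}: length {len(sequence)} exceeds {max_raw}")
    toks = np.full(pad_to, PAD, dtype=np.int64)
    toks[0] = BEGIN
    for i, ch in enumerate(sequence):
        toks[1 + i] = _AA_INDEX.get(ch, UNK)
    toks[1 + len(sequence)] = END
    return TokenizedProtein(id=protein_id, tokens=toks, length_raw=len(sequence))


def tokenize_many(sequences: dict, pad_to: int = DEFAULT_PAD_TO):
    """Tokenize a dict of id -> sequence; returns (tokenized dict, rejection log)."""
    accepted, rejected = {}, []
    for pid, seq in sequences.items():
        try:
            accepted[pid] = tokenize_protein(pid, seq, pad_to=pad_to)
        except SequenceRejectedError as exc:
            rejected.append((pid, str(exc)))
    return accepted, rejected


_TABLE_SEED = 20250128


class ResidueEmbeddingTable:
    """Per-token residue feature vectors (synthetic stand-in table).

    Sequences are one-hot encoded before being embedded with per-residue
    properties; this table keeps both parts of that representation. The
    first 20 channels are the raw one-hot identity channels, so residue
    identity stays linearly recoverable after any position-wise mixing or
    pooling. The remaining channels are a synthetic stand-in for a curated
    physico-chemical property catalogue (which is not shipped): a property
    matrix generated deterministically from a fixed seed and
    column-standardized over the 20 amino acids. The unknown token maps to
    the column means; BEGIN/END/PAD/MASK map to zero vectors.
    """

    N_IDENTITY = len(AA_ALPHABET)

    def __init__(self, n_features: int = 128, seed: int = _TABLE_SEED):
        if not self.N_IDENTITY + 1 <= n_features <= 1024:
            raise ValueError(
                f"n_features must lie in [{self.N_IDENTITY + 1}, 1024]")
        rng = np.random.default_rng(seed)
        n_props = n_features - self.N_IDENTITY
        raw = rng.normal(size=(self.N_IDENTITY, n_props))
        raw = (raw - raw.mean(axis=0)) / raw.std(axis=0)
        mat = np.zeros((VOCAB_SIZE, n_features))
        mat[: self.N_IDENTITY, : self.N_IDENTITY] = np.eye(self.N_IDENTITY)
        mat[: self.N_IDENTITY, self.N_IDENTITY:] = raw
        mat[UNK] = mat[: self.N_IDENTITY].mean(axis=0)
        self.matrix = mat
        self.n_features = n_features
        self.standardization = None  # set by standardize_table


def standardize_table(table: ResidueEmbeddingTable, tokenized,
                      eps: float = 1e-8) -> ResidueEmbeddingTable:
    """Standardize the embedding channels over a corpus of tokenized proteins.

    Each channel is centred and scaled by its mean and standard deviation
    across all token occurrences in the corpus (padding included), so rare
    but informative residues are amplified relative to abundant ones. The
    affine parameters are stored as the returned table's standardization
    state. Channels with (near-)zero variance are left unscaled.
    """
    counts = np.zeros(VOCAB_SIZE)
    for tp in tokenized:
        counts += np.bincount(tp.tokens, minlength=VOCAB_SIZE)
    if counts.sum() == 0:
        raise ValueError("empty corpus")
    w = counts / counts.sum()
    mean = w @ table.matrix
    std = np.sqrt(w @ (table.matrix - mean) ** 2)
    std = np.where(std < eps, 1.0, std)
    out = ResidueEmbeddingTable(n_features=table.n_features)
    out.matrix = (table.matrix - mean) / std
    out.standardization = {"mean": mean, "std": std}
    return out


def positional_encoding(n_positions: int, dim: int) -> np.ndarray:
    """Sinusoidal positional encoding: PE[p, 2k] = sin(p / 10000^(2k/dim)),
    PE[p, 2k+1] = cos(p / 10000^(2k/dim))."""
    pos = np.arange(n_positions)[:, None]
    k2 = np.arange(0, dim, 2)
    angle = pos / np.power(10000.0, k2 / dim)
    pe = np.zeros((n_positions, dim))
    pe[:, 0::2] = np.sin(angle)
    pe[:, 1::2] = np.cos(angle[:, : pe[:, 1::2].shape[1]])
    return pe


def embed_residues(tp: TokenizedProtein,
                   table: ResidueEmbeddingTable) -> np.ndarray:
    """Token embeddings plus positional encoding; shape (pad_to, n_features).

    Every position, padding included, receives its positional vector.
    """
    toks = tp.tokens
    if toks.min() < 0 or toks.max() >= table.matrix.shape[0]:
        raise KeyError(f"protein {tp.id}: token outside embedding table")
    return table.matrix[toks] + positional_encoding(len(toks), table.n_features)


# --------------------------------------------------------------------------
# Readers
# --------------------------------------------------------------------------


def read_fasta(path) -> dict:
    """FASTA -> {id: sequence}; id is the first whitespace-delimited header token."""
    seqs = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seqs[rec.id] = str(rec.seq)
    return seqs


def read_metabolite_table(path, sep: str | None = None) -> MetaboliteFeatureTable:
    """TSV/CSV (header row, first column = id, "NA"/empty = missing)."""
    if sep is None:
        sep = "," if str(path).endswith(".csv") else "\t"
    frame = pd.read_csv(path, sep=sep, index_col=0,
                        na_values=["NA", ""], keep_default_na=True)
    return MetaboliteFeatureTable.from_dataframe(frame)


def protein_composition(sequences: dict) -> pd.DataFrame:
    """Residue count vectors (rows = proteins, columns = the 20 amino acids).

    These are the clustering features for proteins: Euclidean distance between
    two count vectors measures the number of differing residues.
    """
    ids = list(sequences)
    mat = np.zeros((len(ids), len(AA_ALPHABET)), dtype=float)
    for r, pid in enumerate(ids):
        for ch in sequences[pid].upper():
            idx = _AA_INDEX.get(ch)
            if idx is not None:
                mat[r, idx] += 1
    return pd.DataFrame(mat, index=ids, columns=list(AA_ALPHABET))
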