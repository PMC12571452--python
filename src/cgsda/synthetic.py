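"""Seeded planted-structure bipartite datasets and fallback node features.

The generator emulates the shape of curated snoRNA-disease association
collections: a sparse 0/1 matrix whose disease margins are long-tailed
(a few hub diseases carry most associations) and per-side node features
that genuinely carry the planted association signal.  The mechanism is a
logistic low-rank model: latent factors ``U`` (snoRNAs) and ``V``
(diseases) are drawn i.i.d. normal, scaled so the planted logit
``U_i . V_j`` has standard deviation ``signal_sd``; the association
probability is ``p_ij = sigmoid(c + U_i . V_j)`` with the intercept ``c``
calibrated by bisection so the expected density matches the request, and
``A_ij ~ Bernoulli(p_ij)``.  Features expose the latent factors in their
leading columns, optionally corrupted by Gaussian noise, padded with pure
noise columns to the requested width — so a model that learns anything
must learn it from the graph and/or those noisy factors.

Also provides a k-mer frequency featurizer for the case where only RNA
sequences are available.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from pathlib import Path

import numpy as np
from Bio import SeqIO

from .data import (
    AssociationDataset,
    write_association_list,
    write_feature_matrix,
)

__all__ = ["SyntheticConfig", "generate_planted_bipartite", "kmer_featurize",
           "read_fasta", "write_fixture"]


@dataclass
class SyntheticConfig:
    """Parameters of the planted low-rank bipartite generator.

    Defaults give a graph of the same order of magnitude as the curated
    snoRNA-disease collections (a few hundred snoRNAs, tens of diseases,
    ~5% density) at a size where training stays fast.
    """

    n_s: int = 200
    n_d: int = 30
    rank: int = 4
    density: float = 0.05
    feature_noise: float = 0.1
    feature_dim: int = 32
    signal_sd: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.density < 1.0:
            raise ValueError("density must lie in (0, 1)")
        if self.rank < 1:
            raise ValueError("rank must be >= 1")
        if self.n_s < 2 or self.n_d < 2:
            raise ValueError("need at least two nodes per side")
        if self.signal_sd <= 0:
            raise ValueError("signal_sd must be positive")
        if self.feature_dim < self.rank:
            raise ValueError("feature_dim must be >= rank")


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _calibrate_intercept(logits: np.ndarray, density: float, tol: float = 1e-3) -> float:
    """Bisect the intercept c so that mean(sigmoid(c + logits)) ~ density."""
    lo, hi = -30.0, 30.0
    if not _sigmoid(lo + logits).mean() <= density <= _sigmoid(hi + logits).mean():
        raise ValueError("requested density unreachable by intercept calibration")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        mean_p = _sigmoid(mid + logits).mean()
        if abs(mean_p - density) <= tol:
            return mid
        if mean_p < density:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def generate_planted_bipartite(
    config: SyntheticConfig,
) -> tuple[AssociationDataset, np.ndarray, np.ndarray, dict[str, np.ndarray]]:
    """Draw a seeded planted-structure dataset.

    Returns the dataset, snoRNA features, disease features, and the latent
    truth (``U``, ``V``, ``P`` the Bernoulli probabilities) for oracle use
    in tests and fixture validation.
    """
    rng = np.random.default_rng(config.seed)
    # per-factor scale s with s^2 * sqrt(rank) = signal_sd, so the planted
    # logit U_i.V_j has standard deviation signal_sd
    scale = np.sqrt(config.signal_sd / np.sqrt(config.rank))
    U = rng.standard_normal((config.n_s, config.rank)) * scale
    V = rng.standard_normal((config.n_d, config.rank)) * scale
    logits = U @ V.T
    c = _calibrate_intercept(logits, config.density)
    P = _sigmoid(c + logits)
    A = (rng.random(P.shape) < P).astype(np.int8)

    def features(factors: np.ndarray) -> np.ndarray:
        n = factors.shape[0]
        out = np.zeros((n, config.feature_dim))
        out[:, : config.rank] = factors
        out[:, config.rank:] = rng.standard_normal(
            (n, config.feature_dim - config.rank)
        ) * config.feature_noise
        out[:, : config.rank] += rng.standard_normal(
            (n, config.rank)
        ) * config.feature_noise
        return out

    F_s = features(U)
    F_d = features(V)
    dataset = AssociationDataset(
        snorna_ids=[f"sno{i:04d}" for i in range(config.n_s)],
        disease_ids=[f"dis{j:03d}" for j in range(config.n_d)],
        A=A,
    )
    return dataset, F_s, F_d, {"U": U, "V": V, "P": P, "intercept": np.array(c)}


def kmer_featurize(sequences: dict[str, str], k: int) -> tuple[list[str], np.ndarray]:
    """k-mer frequency profiles of RNA/DNA sequences.

    One row per id, ``4**k`` columns in lexicographic k-mer order over
    the alphabet A,C,G,U (T read as U); each entry is the k-mer count
    divided by the window count ``len - k + 1``, so rows sum to 1.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    alphabet = "ACGU"
    kmers = ["".join(p) for p in product(alphabet, repeat=k)]
    index = {m: i for i, m in enumerate(kmers)}
    ids = list(sequences)
    out = np.zeros((len(ids), len(kmers)))
    for r, sid in enumerate(ids):
        seq = sequences[sid].upper().replace("T", "U")
        if len(seq) < k:
            raise ValueError(f"sequence {sid!r} shorter than k={k}")
        bad = set(seq) - set(alphabet)
        if bad:
            raise ValueError(f"sequence {sid!r} has illegal characters {sorted(bad)}")
        n_windows = len(seq) - k + 1
        for start in range(n_windows):
            out[r, index[seq[start : start + k]]] += 1.0
        out[r] /= n_windows
    return ids, out


def read_fasta(path: str | Path) -> dict[str, str]:
    """Sequences keyed by record id, for feeding kmer_featurize."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fixture(
    dataset: AssociationDataset,
    out_dir: str | Path,
    snorna_features: np.ndarray | None = None,
    disease_features: np.ndarray | None = None,
) -> dict[str, Path]:
    """Emit the dataset (and optional features) in the loader's text formats."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {"edges": write_association_list(dataset, out_dir / "associations.tsv")}
    if snorna_features is not None:
        paths["snorna_features"] = write_feature_matrix(
            dataset.snorna_ids, snorna_features, out_dir / "snorna_features.tsv"
        )
    if disease_features is not None:
        paths["disease_features"] = write_feature_matrix(
            dataset.disease_ids, disease_features, out_dir / "disease_features.tsv"
        )
    return paths
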