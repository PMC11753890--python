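"""Per-residue embedding providers with global average pooling.

The pipeline consumes a D x L matrix of per-residue representations per
protein and pools it to a single D-vector by averaging over positions (for
the ESM-1b protein language model, D = 1280 from the last hidden layer).

Three providers share this contract:

* :func:`mock_embed` — a deterministic, seeded stand-in used throughout the
  test suite: each column is the sum of a residue-type vector and a smooth
  positional encoding, so embeddings depend on residue identity and position
  but require no pretrained weights.
* :func:`load_precomputed` — verbatim loading of externally computed
  embedding matrices (e.g. dumped from the real language model).
* :func:`esm_embed` — an adapter for the ESM-1b model; it requires the
  optional ``torch``/``fair-esm`` stack and pretrained weights, and raises an
  actionable error pointing at the mock when those are absent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from targetclp.io_formats import AA_ORDER, ProteinRecord

ESM_DIM = 1280
#: ESM-1b positional limit (residues); longer sequences are truncated by the
#: default policy, recorded in provenance.
ESM_MAX_LEN = 1022


@dataclass
class EmbeddingMatrix:
    """D x L per-residue representations with provenance."""

    values: np.ndarray
    provenance: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("embedding matrix must be 2-D (D x L)")
        if not np.isfinite(self.values).all():
            raise ValueError("embedding matrix contains non-finite entries")


def mean_pool(emb: EmbeddingMatrix | np.ndarray) -> np.ndarray:
    """Global average pooling over sequence positions: D x L -> D."""
    values = emb.values if isinstance(emb, EmbeddingMatrix) else np.asarray(emb, dtype=float)
    return values.mean(axis=1)


def _positional_encoding(length: int, dim: int) -> np.ndarray:
    """Sinusoidal position features, (dim, length); deterministic."""
    pos = np.arange(length)[None, :]
    d = np.arange(dim)[:, None]
    angle = pos / np.power(10000.0, (2 * (d // 2)) / dim)
    out = np.where(d % 2 == 0, np.sin(angle), np.cos(angle))
    return out


def mock_embed(record: ProteinRecord, dim: int = ESM_DIM, seed: int = 0) -> EmbeddingMatrix:
    """Deterministic mock embedding: column j = residue-type vector + 0.1 x
    positional encoding.  Pure function of (sequence, dim, seed)."""
    rng = np.random.default_rng(seed)
    residue_vectors = rng.standard_normal((21, dim))  # 20 standard + X
    index = {aa: i for i, aa in enumerate(AA_ORDER + "X")}
    cols = np.stack([residue_vectors[index[res]] for res in record.sequence], axis=1)
    values = cols + 0.1 * _positional_encoding(len(record.sequence), dim)
    return EmbeddingMatrix(values, provenance=f"mock:d={dim}:seed={seed}")


def load_precomputed(path, expected_length: int | None = None) -> EmbeddingMatrix:
    """Load a precomputed D x L embedding matrix (.npy or whitespace text)."""
    path = str(path)
    values = np.load(path) if path.endswith(".npy") else np.loadtxt(path)
    if values.ndim == 1:
        values = values[:, None]
    if expected_length is not None and values.shape[1] != expected_length:
        raise ValueError(
            f"{path}: embedding has {values.shape[1]} positions, expected {expected_length}"
        )
    return EmbeddingMatrix(values, provenance=f"precomputed:{path}")


def esm_embed(record: ProteinRecord, model_name: str = "esm1b_t33_650M_UR50S") -> EmbeddingMatrix:
    """Adapter for real protein-language-model embeddings (last hidden layer,
    special tokens excluded from pooling).  Optional: needs torch + fair-esm
    and locally available pretrained weights."""
    try:
        import esm  # type: ignore
        import torch  # type: ignore
    except ImportError as exc:
        raise ImportError(
            "esm_embed requires the optional 'fair-esm' and 'torch' packages "
            "plus pretrained weights; for testing and offline use, call "
            "mock_embed() or load_precomputed() instead"
        ) from exc
    model, alphabet = esm.pretrained.load_model_and_alphabet(model_name)
    model.eval()
    seq = record.sequence[:ESM_MAX_LEN]
    batch_converter = alphabet.get_batch_converter()
    _, _, tokens = batch_converter([(record.id, seq)])
    with torch.no_grad():
        out = model(tokens, repr_layers=[model.num_layers])
    rep = out["representations"][model.num_layers][0, 1 : len(seq) + 1].T.numpy()
    provenance = f"{model_name}:layer={model.num_layers}"
    if len(seq) < len(record.sequence):
        provenance += f":truncated_to={ESM_MAX_LEN}"
    return EmbeddingMatrix(rep, provenance=provenance)
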