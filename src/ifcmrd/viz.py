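"""Low-dimensional projection of embeddings and projector-format export.

Penultimate-layer CNN embeddings (or classical feature vectors) are
projected with t-SNE or PCA for visual inspection of class structure, and
exported as the TSV pair (vectors without header, metadata with header)
that standard embedding-projector tools consume.  Rows are never
reordered; metadata stays aligned with coordinates end-to-end.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core import ValidationError


@dataclass
class EmbeddingMatrix:
    matrix: np.ndarray  # n_cells x d
    metadata: pd.DataFrame  # n_cells rows: cell_id, class labels, patient

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.ndim != 2:
            raise ValidationError("embedding matrix must be 2-D")
        if not np.isfinite(self.matrix).all():
            raise ValidationError("embedding matrix must be finite")
        if len(self.metadata) != self.matrix.shape[0]:
            raise ValidationError("metadata length must equal the number of rows")


def project(
    emb: EmbeddingMatrix,
    method: str = "tsne",
    perplexity: float = 30.0,
    iterations: int = 400,
    n_components: int = 2,
    seed: int = 0,
) -> np.ndarray:
    """Project to 2-3 dimensions (t-SNE stabilized at >=400 iterations,
    perplexity 30 by default; or deterministic PCA).

    PCA uses the sign convention that each component's largest-magnitude
    loading is positive, making the output reproducible across runs.
    """
    if n_components not in (2, 3):
        raise ValidationError("n_components must be 2 or 3")
    n = emb.matrix.shape[0]
    if method == "tsne":
        from sklearn.manifold import TSNE

        min_n = int(perplexity * 3) + 1
        if n < min_n:
            raise ValidationError(
                f"t-SNE at perplexity {perplexity} needs at least {min_n} cells, got {n}"
            )
        tsne = TSNE(
            n_components=n_components,
            perplexity=perplexity,
            max_iter=max(int(iterations), 400),
            init="pca",
            random_state=seed,
        )
        return np.asarray(tsne.fit_transform(emb.matrix))
    if method == "pca":
        from sklearn.decomposition import PCA

        pca = PCA(n_components=n_components, svd_solver="full")
        coords = pca.fit_transform(emb.matrix)
        # sign convention: largest-magnitude loading positive per component
        for k in range(n_components):
            loading = pca.components_[k]
            if loading[np.argmax(np.abs(loading))] < 0:
                coords[:, k] = -coords[:, k]
        return coords
    raise ValidationError(f"unknown method {method!r}; use 'tsne' or 'pca'")


def export_projector(
    emb: EmbeddingMatrix,
    coordinates: np.ndarray,
    directory: str | os.PathLike,
) -> dict[str, Path]:
    """Write vectors.tsv (no header), metadata.tsv (with header), and
    coordinates.tsv for interactive embedding-projector inspection."""
    coordinates = np.asarray(coordinates)
    if coordinates.shape[0] != emb.matrix.shape[0]:
        raise ValidationError("coordinates row count must match the embedding")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    vectors = directory / "vectors.tsv"
    np.savetxt(vectors, emb.matrix, delimiter="\t", fmt="%.6f")
    metadata = directory / "metadata.tsv"
    emb.metadata.to_csv(metadata, sep="\t", index=False)
    coords = directory / "coordinates.tsv"
    np.savetxt(coords, coordinates, delimiter="\t", fmt="%.6f")
    return {"vectors": vectors, "metadata": metadata, "coordinates": coords}
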