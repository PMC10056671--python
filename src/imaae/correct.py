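"""Apply a trained adversarial autoencoder to produce corrected outputs.

Inference is deterministic: the mean latent (eps = 0) is used, so repeated
runs agree bit for bit.  Cells of a type seen in only one batch are copied
through unchanged — correcting them toward the anchor would map them into a
region of expression space with no cross-batch support.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass

import numpy as np

from .anchor import TrainingMapping
from .datamodel import AnnotatedMatrix
from .model import TrainedAAE, decode, encode


@dataclass
class CorrectionResult:
    """Corrected expression (log-normalized space, >= 0) and latent embedding."""

    corrected_expression: np.ndarray
    latent: np.ndarray
    passthrough_mask: np.ndarray
    provenance: dict

    def counts_scale(self) -> np.ndarray:
        """expm1 back-transform of the corrected matrix, for count-scale tooling."""
        return np.expm1(self.corrected_expression)


def _model_hash(model: TrainedAAE) -> str:
    h = hashlib.sha256()
    for W, b in model.encoder_backbone + [model.encoder_mu, model.encoder_logvar] + model.decoder:
        h.update(np.ascontiguousarray(W).tobytes())
        h.update(np.ascontiguousarray(b).tobytes())
    return h.hexdigest()[:16]


def apply_correction(
    model: TrainedAAE,
    m: AnnotatedMatrix,
    mapping: TrainingMapping,
    sample_latent: bool = False,
    seed: int = 0,
) -> CorrectionResult:
    """Correct all cells: decode(encode_mu(x)) for mapped cells, identity for
    passthrough cells; the latent embedding covers every cell.

    ``sample_latent`` opts into a stochastic latent draw instead of the mean.
    """
    if model.gene_ids is not None:
        missing = [g for g in model.gene_ids if g not in set(m.gene_ids)]
        if missing or len(model.gene_ids) != m.n_genes:
            raise ValueError(
                f"gene set does not match the trained model; missing: {missing[:5]}"
            )
    if m.layer_tag != "lognormalized":
        raise ValueError("correction expects the preprocessed log-normalized matrix")
    X = np.asarray(m.values, dtype=float)
    rng = np.random.default_rng(seed) if sample_latent else None
    mu, _logvar, z = encode(
        (model.encoder_backbone, model.encoder_mu, model.encoder_logvar), X, rng=rng
    )
    latent = z if sample_latent else mu
    corrected = X.copy()
    non_pass = ~mapping.passthrough_mask
    if non_pass.any():
        corrected[non_pass] = decode(model.decoder, latent[non_pass])
    return CorrectionResult(
        corrected_expression=corrected,
        latent=latent,
        passthrough_mask=mapping.passthrough_mask.copy(),
        provenance={
            "model_hash": _model_hash(model),
            "config": json.loads(json.dumps(model.config.__dict__, default=str)),
            "sample_latent": sample_latent,
        },
    )


def export_embedding(r: CorrectionResult, n_dims: int) -> np.ndarray:
    """Latent embedding at a user-chosen dimension.

    Returns the latent itself when ``n_dims`` equals its width, else its first
    ``n_dims`` principal components.  Requesting more dimensions than the
    trained latent holds is an error (retrain with a larger latent space; very
    small latent spaces lose cell-type structure).
    """
    latent_dim = r.latent.shape[1]
    if n_dims < 1 or n_dims > latent_dim:
        raise ValueError(
            f"n_dims must be in [1, {latent_dim}] (the trained latent width); got {n_dims}"
        )
    if n_dims == latent_dim:
        return r.latent
    from sklearn.decomposition import PCA

    return PCA(n_components=n_dims, svd_solver="full").fit_transform(r.latent)
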