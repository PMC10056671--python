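"""Adversarial autoencoder: losses, networks and the training loop.

The encoder maps a log-normalized expression row to a Gaussian latent code via
the reparameterization trick (z = mu + exp(logvar/2) * eps); the decoder maps
the code back to expression space through a terminal ReLU, so corrected
expression can never be negative.  Training couples two objectives:

* reconstruction — the decoder output for cell i is pulled toward the cell's
  *mapped anchor profile* (not its own input), L_R = mean_i ||x_i - x~_i||²,
  which is what transports every batch onto the anchor batch;
* adversarial — a Wasserstein critic with gradient penalty pushes the encoder
  posterior q(z) toward the standard Gaussian prior p(z) = N(0, I): the
  critic's "real" samples are prior draws, its "fake" samples encoder outputs,
  and the encoder doubles as the generator (L_G = -E[D(z_fake)]).

Two ablation modes mirror the method's design study: ``ae_only`` drops the
critic entirely, ``gan_only`` drops the reconstruction pairing and instead
trains encoder+decoder as a generator against a critic on expression space
(real samples = mapped anchor profiles).

The critic is updated ``n_critic`` times per autoencoder update (default: the
number of batches in the data).  Everything runs on a hand-rolled float64
NumPy core (:mod:`imaae.nn`), so results are bit-reproducible under a fixed
seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .anchor import AnchorSet, TrainingMapping, resample_mapping
from .datamodel import AnnotatedMatrix

LOGVAR_MIN, LOGVAR_MAX = -20.0, 5.0


def default_encoder_widths(n_genes: int, latent_dim: int) -> list[int]:
    """Halving funnel from the gene count down to the latent width."""
    widths = [n_genes]
    w = n_genes
    while w // 2 > 2 * latent_dim:
        w //= 2
        widths.append(w)
    widths.append(latent_dim)
    return widths


def default_critic_widths(latent_dim: int) -> list[int]:
    widths = [latent_dim]
    for w in (latent_dim // 2, latent_dim // 4, 8):
        if w < widths[-1] and w >= 1:
            widths.append(w)
    widths.append(1)
    return widths


@dataclass
class AAEConfig:
    """Hyperparameters of the adversarial autoencoder.

    The published defaults are encoder widths 2000/1000/500/250, decoder the
    mirror image, critic 250/125/64/8/1, Adam(lr=2e-4, beta1=0.5, beta2=0.999),
    batch size 1024, 100 epochs, and n_critic equal to the number of batches.
    """

    encoder_widths: list[int] = field(default_factory=lambda: [2000, 1000, 500, 250])
    decoder_widths: list[int] | None = None   # default: reversed encoder widths
    critic_widths: list[int] | None = None    # default: funnel from latent_dim to 1
    latent_dim: int | None = None             # default: last encoder width
    learning_rate: float = 2e-4
    adam_beta1: float = 0.5
    adam_beta2: float = 0.999
    batch_size: int = 1024
    epochs: int = 100
    n_critic: int | None = None               # default: number of batches
    gp_weight: float = 10.0
    seed: int = 0
    mode: str = "full"                        # full | ae_only | gan_only
    resample_each_epoch: bool = True          # redraw random-mode targets per epoch

    def __post_init__(self) -> None:
        if self.latent_dim is None:
            self.latent_dim = self.encoder_widths[-1]
        if self.encoder_widths[-1] != self.latent_dim:
            raise ValueError("last encoder width must equal latent_dim")
        if self.decoder_widths is None:
            self.decoder_widths = list(reversed(self.encoder_widths))
        if self.critic_widths is None:
            self.critic_widths = default_critic_widths(self.latent_dim)
        if self.decoder_widths[0] != self.latent_dim:
            raise ValueError("first decoder width must equal latent_dim")
        if self.decoder_widths[-1] != self.encoder_widths[0]:
            raise ValueError("decoder must map back to the gene count")
        if self.critic_widths[-1] != 1:
            raise ValueError("critic must end in a single score unit")
        if self.critic_widths[0] != self.latent_dim:
            raise ValueError("first critic width must equal latent_dim")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.batch_size < 1 or self.epochs < 1:
            raise ValueError("batch_size and epochs must be >= 1")
        if self.n_critic is not None and self.n_critic < 1:
            raise ValueError("n_critic must be >= 1")
        if self.gp_weight < 0:
            raise ValueError("gradient-penalty weight must be non-negative")
        if self.mode not in ("full", "ae_only", "gan_only"):
            raise ValueError(f"unknown mode {self.mode!r}")

    @classmethod
    def for_data(cls, n_genes: int, latent_dim: int = 250, **kwargs) -> "AAEConfig":
        """Config with widths scaled to the data's gene count."""
        enc = default_encoder_widths(n_genes, latent_dim)
        return cls(encoder_widths=enc, latent_dim=latent_dim, **kwargs)


@dataclass
class TrainedAAE:
    """Learned parameters plus the per-epoch loss history."""

    encoder_backbone: nn.Params
    encoder_mu: tuple[np.ndarray, np.ndarray]
    encoder_logvar: tuple[np.ndarray, np.ndarray]
    decoder: nn.Params
    critic: nn.Params
    history: list[tuple[float, float, float]]   # (L_R, L_D, L_G) per epoch
    config: AAEConfig
    gene_ids: np.ndarray | None = None
    last_step: dict | None = None               # bookkeeping snapshot of the final step

    def save(self, path) -> None:
        import json

        arrays: dict[str, np.ndarray] = {}
        for i, (W, b) in enumerate(self.encoder_backbone):
            arrays[f"enc_bb_{i}_W"], arrays[f"enc_bb_{i}_b"] = W, b
        arrays["enc_mu_W"], arrays["enc_mu_b"] = self.encoder_mu
        arrays["enc_lv_W"], arrays["enc_lv_b"] = self.encoder_logvar
        for i, (W, b) in enumerate(self.decoder):
            arrays[f"dec_{i}_W"], arrays[f"dec_{i}_b"] = W, b
        for i, (W, b) in enumerate(self.critic):
            arrays[f"cri_{i}_W"], arrays[f"cri_{i}_b"] = W, b
        arrays["history"] = np.asarray(self.history, dtype=float)
        if self.gene_ids is not None:
            arrays["gene_ids"] = np.asarray([str(g) for g in self.gene_ids])
        cfg = {k: v for k, v in self.config.__dict__.items()}
        arrays["config_json"] = np.asarray(json.dumps(cfg))
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> "TrainedAAE":
        import json

        data = np.load(path, allow_pickle=False)
        cfg = AAEConfig(**json.loads(str(data["config_json"])))

        def layers(prefix: str) -> nn.Params:
            out = []
            i = 0
            while f"{prefix}_{i}_W" in data:
                out.append((data[f"{prefix}_{i}_W"], data[f"{prefix}_{i}_b"]))
                i += 1
            return out

        return cls(
            encoder_backbone=layers("enc_bb"),
            encoder_mu=(data["enc_mu_W"], data["enc_mu_b"]),
            encoder_logvar=(data["enc_lv_W"], data["enc_lv_b"]),
            decoder=layers("dec"),
            critic=layers("cri"),
            history=[tuple(row) for row in data["history"]],
            config=cfg,
            gene_ids=np.asarray(data["gene_ids"], dtype=object) if "gene_ids" in data else None,
        )


# ---------------------------------------------------------------------------
# network pieces
# ---------------------------------------------------------------------------

def _init_networks(config: AAEConfig, rng: np.random.Generator, critic_widths=None):
    backbone = nn.init_mlp(config.encoder_widths[:-1], rng)
    head_in = config.encoder_widths[-2]
    mu = (rng.normal(0, np.sqrt(2.0 / head_in), size=(head_in, config.latent_dim)),
          np.zeros(config.latent_dim))
    lv = (rng.normal(0, np.sqrt(2.0 / head_in), size=(head_in, config.latent_dim)),
          np.zeros(config.latent_dim))
    decoder = nn.init_mlp(config.decoder_widths, rng)
    critic = nn.init_mlp(critic_widths or config.critic_widths, rng)
    return backbone, mu, lv, decoder, critic


def encode(
    model_or_parts, x: np.ndarray, rng: np.random.Generator | None = None,
    eps: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Encoder forward pass: returns (mu, logvar, z) with z = mu + exp(logvar/2)·eps.

    ``eps`` defaults to draws from ``rng``; pass ``eps=0`` semantics by giving
    ``rng=None`` and ``eps=None`` to obtain the deterministic mean latent.
    """
    if isinstance(model_or_parts, TrainedAAE):
        backbone, mu_h, lv_h = (
            model_or_parts.encoder_backbone,
            model_or_parts.encoder_mu,
            model_or_parts.encoder_logvar,
        )
    else:
        backbone, mu_h, lv_h = model_or_parts
    x = np.asarray(x, dtype=float)
    if backbone and x.shape[1] != backbone[0][0].shape[0]:
        raise ValueError(
            f"input width {x.shape[1]} does not match encoder width {backbone[0][0].shape[0]}"
        )
    h, _ = nn.mlp_forward(backbone, x, final_relu=True) if backbone else (x, None)
    mu = h @ mu_h[0] + mu_h[1]
    logvar = np.clip(h @ lv_h[0] + lv_h[1], LOGVAR_MIN, LOGVAR_MAX)
    if eps is None:
        eps = rng.standard_normal(mu.shape) if rng is not None else np.zeros_like(mu)
    z = mu + np.exp(logvar / 2.0) * eps
    return mu, logvar, z


def decode(decoder_or_model, z: np.ndarray) -> np.ndarray:
    """Decoder forward pass; the terminal ReLU keeps every output >= 0."""
    decoder = decoder_or_model.decoder if isinstance(decoder_or_model, TrainedAAE) else decoder_or_model
    z = np.asarray(z, dtype=float)
    if z.shape[1] != decoder[0][0].shape[0]:
        raise ValueError(
            f"latent width {z.shape[1]} does not match decoder width {decoder[0][0].shape[0]}"
        )
    out, _ = nn.mlp_forward(decoder, z, final_relu=True)
    return out


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

def reconstruction_loss(x: np.ndarray, x_tilde: np.ndarray) -> float:
    """Mean over cells of the squared Euclidean distance to the target rows."""
    x = np.asarray(x, dtype=float)
    x_tilde = np.asarray(x_tilde, dtype=float)
    if x.shape != x_tilde.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {x_tilde.shape}")
    return float(np.mean(np.sum((x - x_tilde) ** 2, axis=1)))


def gradient_penalty(
    critic_params: nn.Params,
    z_real: np.ndarray,
    z_fake: np.ndarray,
    lam: float,
    rng: np.random.Generator,
) -> float:
    """λ · E[(‖∇_ẑ D(ẑ)‖₂ − 1)²] at per-row uniform interpolates ẑ."""
    z_real = np.asarray(z_real, dtype=float)
    z_fake = np.asarray(z_fake, dtype=float)
    if z_real.shape != z_fake.shape:
        raise ValueError("real and fake sample shapes must match")
    alpha = rng.uniform(size=(z_real.shape[0], 1))
    z_hat = alpha * z_real + (1 - alpha) * z_fake
    return nn.gradient_penalty_value(critic_params, z_hat, lam)


def critic_loss(
    critic_params: nn.Params,
    z_real: np.ndarray,
    z_fake: np.ndarray,
    lam: float,
    rng: np.random.Generator,
) -> float:
    """Wasserstein critic loss −E[D(real)] + E[D(fake)] + gradient penalty."""
    z_real = np.asarray(z_real, dtype=float)
    z_fake = np.asarray(z_fake, dtype=float)
    if z_real.shape != z_fake.shape:
        raise ValueError("real and fake sample shapes must match")
    d_real = nn.critic_score(critic_params, z_real)
    d_fake = nn.critic_score(critic_params, z_fake)
    gp = gradient_penalty(critic_params, z_real, z_fake, lam, rng)
    return float(-d_real.mean() + d_fake.mean() + gp)


def generator_loss(critic_params: nn.Params, z_fake: np.ndarray) -> float:
    """Generator objective −E[D(fake)]: raise the critic's score of the fakes."""
    return float(-nn.critic_score(critic_params, np.asarray(z_fake, dtype=float)).mean())


# ---------------------------------------------------------------------------
# gradient helpers for the training loop
# ---------------------------------------------------------------------------

def _critic_step_grads(critic, z_real, z_fake, lam, rng):
    """Loss value and critic parameter gradients for one critic update."""
    n = z_real.shape[0]
    out_r, cache_r = nn.mlp_forward(critic, z_real, final_relu=False)
    out_f, cache_f = nn.mlp_forward(critic, z_fake, final_relu=False)
    g_r, _ = nn.mlp_backward(critic, cache_r, np.full_like(out_r, -1.0 / n))
    g_f, _ = nn.mlp_backward(critic, cache_f, np.full_like(out_f, +1.0 / n))
    alpha = rng.uniform(size=(n, 1))
    z_hat = alpha * z_real + (1 - alpha) * z_fake
    gp, g_gp = nn.gradient_penalty_param_grads(critic, z_hat, lam)
    grads = nn.add_params(nn.add_params(g_r, g_f), g_gp)
    loss = float(-out_r.mean() + out_f.mean() + gp)
    return loss, grads


def _encode_with_cache(backbone, mu_h, lv_h, x, eps):
    h, cache = nn.mlp_forward(backbone, x, final_relu=True) if backbone else (x, None)
    mu = h @ mu_h[0] + mu_h[1]
    raw_lv = h @ lv_h[0] + lv_h[1]
    logvar = np.clip(raw_lv, LOGVAR_MIN, LOGVAR_MAX)
    z = mu + np.exp(logvar / 2.0) * eps
    return h, cache, mu, raw_lv, logvar, z


def _encoder_backward(backbone, mu_h, lv_h, h, cache, raw_lv, logvar, eps, grad_mu, grad_logvar_from_z):
    # clamp passes no gradient outside its range
    in_range = (raw_lv > LOGVAR_MIN) & (raw_lv < LOGVAR_MAX)
    grad_lv = grad_logvar_from_z * in_range
    g_mu_W, g_mu_b = h.T @ grad_mu, grad_mu.sum(axis=0)
    g_lv_W, g_lv_b = h.T @ grad_lv, grad_lv.sum(axis=0)
    grad_h = grad_mu @ mu_h[0].T + grad_lv @ lv_h[0].T
    if backbone:
        g_bb, _ = nn.mlp_backward(backbone, cache, grad_h)
    else:
        g_bb = []
    return g_bb, (g_mu_W, g_mu_b), (g_lv_W, g_lv_b)


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------

def train(
    m: AnnotatedMatrix,
    mapping: TrainingMapping,
    anchors: AnchorSet,
    config: AAEConfig,
) -> TrainedAAE:
    """Train the adversarial autoencoder on the mapped (source, anchor) pairs.

    Only mapped cells enter training; passthrough and anchor-uncovered cells
    are handled at correction time.  Per minibatch the critic takes
    ``n_critic`` Adam steps, then encoder+decoder take one step on
    L_R + L_G (mode-dependent).  Fully deterministic under ``config.seed``.
    """
    if config.encoder_widths[0] != m.n_genes:
        raise ValueError(
            f"first encoder width {config.encoder_widths[0]} must equal the "
            f"gene count {m.n_genes}; use AAEConfig.for_data"
        )
    rng = np.random.default_rng(config.seed)
    n_critic = config.n_critic if config.n_critic is not None else max(1, len(m.batches()))

    mapped_cells = np.asarray(sorted(c for c, _ in mapping.pairs), dtype=int)
    if len(mapped_cells) == 0:
        raise ValueError("no mapped cells to train on")
    X_all = np.asarray(m.values, dtype=float)
    target_idx_full = mapping.target_index(m.n_cells)

    batch_size = config.batch_size
    if batch_size > len(mapped_cells):
        warnings.warn(
            f"batch_size {batch_size} exceeds {len(mapped_cells)} training cells; "
            "using full-batch updates"
        )
        batch_size = len(mapped_cells)

    gan_only = config.mode == "gan_only"
    critic_widths = None
    if gan_only:
        base = default_critic_widths(config.latent_dim)
        critic_widths = [m.n_genes] + base[1:]
    backbone, mu_h, lv_h, decoder, critic = _init_networks(config, rng, critic_widths)
    # start the decoder at the mean anchor profile (output-mean initialisation):
    # the net then only has to learn deviations, not the output scale itself
    W_last, _ = decoder[-1]
    decoder[-1] = (W_last, anchors.anchor_profiles.mean(axis=0).astype(float))

    ae_arrays = nn.flatten(backbone) + [mu_h[0], mu_h[1], lv_h[0], lv_h[1]] + nn.flatten(decoder)
    opt_ae = nn.Adam(ae_arrays, config.learning_rate, config.adam_beta1, config.adam_beta2)
    opt_cr = nn.Adam(nn.flatten(critic), config.learning_rate, config.adam_beta1, config.adam_beta2)

    lam = config.gp_weight
    history: list[tuple[float, float, float]] = []
    last_step: dict | None = None

    for epoch in range(config.epochs):
        if mapping.stochastic and config.resample_each_epoch and epoch > 0:
            target_idx_full = resample_mapping(m, anchors, mapping, rng)
        order = rng.permutation(mapped_cells)
        ep_lr, ep_ld, ep_lg, n_steps = 0.0, 0.0, 0.0, 0
        for start in range(0, len(order), batch_size):
            mb = order[start:start + batch_size]
            x = X_all[mb]
            t = anchors.anchor_profiles[target_idx_full[mb]]
            nb = len(mb)

            # ---- critic updates -------------------------------------------
            step_ld = 0.0
            if config.mode == "full":
                for _ in range(n_critic):
                    eps = rng.standard_normal((nb, config.latent_dim))
                    _, _, _, _, _, z_fake = _encode_with_cache(backbone, mu_h, lv_h, x, eps)
                    z_real = rng.standard_normal(z_fake.shape)
                    step_ld, gcr = _critic_step_grads(critic, z_real, z_fake, lam, rng)
                    opt_cr.step(nn.flatten(gcr))
            elif gan_only:
                for _ in range(n_critic):
                    eps = rng.standard_normal((nb, config.latent_dim))
                    _, _, _, _, _, z = _encode_with_cache(backbone, mu_h, lv_h, x, eps)
                    fake_x = decode(decoder, z)
                    step_ld, gcr = _critic_step_grads(critic, t, fake_x, lam, rng)
                    opt_cr.step(nn.flatten(gcr))

            # ---- autoencoder / generator update ---------------------------
            eps = rng.standard_normal((nb, config.latent_dim))
            h, cache, mu, raw_lv, logvar, z = _encode_with_cache(backbone, mu_h, lv_h, x, eps)
            x_tilde, dec_cache = nn.mlp_forward(decoder, z, final_relu=True)
            step_lr = float(np.mean(np.sum((t - x_tilde) ** 2, axis=1)))

            grad_xt = np.zeros_like(x_tilde)
            if config.mode in ("full", "ae_only"):
                grad_xt += 2.0 * (x_tilde - t) / nb
            step_lg = 0.0
            if gan_only:
                step_lg = float(-nn.critic_score(critic, x_tilde).mean())
                grad_xt += -nn.critic_input_grad(critic, x_tilde) / nb
            g_dec, grad_z = nn.mlp_backward(decoder, dec_cache, grad_xt)
            if config.mode == "full":
                step_lg = float(-nn.critic_score(critic, z).mean())
                grad_z = grad_z - nn.critic_input_grad(critic, z) / nb
            grad_mu = grad_z
            grad_lv_from_z = grad_z * eps * 0.5 * np.exp(logvar / 2.0)
            g_bb, g_mu, g_lv = _encoder_backward(
                backbone, mu_h, lv_h, h, cache, raw_lv, logvar, eps, grad_mu, grad_lv_from_z
            )
            opt_ae.step(nn.flatten(g_bb) + [g_mu[0], g_mu[1], g_lv[0], g_lv[1]] + nn.flatten(g_dec))

            if not np.isfinite(step_lr) or not np.isfinite(step_ld) or not np.isfinite(step_lg):
                raise RuntimeError(f"non-finite loss at epoch {epoch}")
            ep_lr += step_lr
            ep_ld += step_ld
            ep_lg += step_lg
            n_steps += 1
            last_step = {
                "z_fake": x_tilde.copy() if gan_only else z.copy(),
                "l_g": step_lg,
            }
        history.append((ep_lr / n_steps, ep_ld / n_steps, ep_lg / n_steps))

    return TrainedAAE(
        encoder_backbone=backbone,
        encoder_mu=mu_h,
        encoder_logvar=lv_h,
        decoder=decoder,
        critic=critic,
        history=history,
        config=config,
        gene_ids=m.gene_ids,
        last_step=last_step,
    )
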