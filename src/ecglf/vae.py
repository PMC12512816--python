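"""Convolutional beta-VAE over 8-lead median beats.

The encoder stacks stride-2 1-D convolutions with increasing filter counts
and decreasing kernel sizes toward the latent space; the decoder mirrors it
with transposed convolutions.  The latent space is capped at 30 dimensions;
in practice the model leaves a subset of them collapsed, and the active
subset is detected from the across-subject variance of the posterior means.

Training minimises a symmetric mean absolute percentage error (SMAPE)
reconstruction loss plus ``beta`` times the Kullback–Leibler divergence of
the approximate posterior from the standard-normal prior.  ``beta`` trades
reconstruction fidelity against disentanglement and is selected over the
grid {0.1, 0.25, 0.5, 1, 3, 5, 10} by validation reconstruction
correlation.
"""

from __future__ import annotations

import json
import pathlib
import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from ecglf import _nn
from ecglf.containers import BEAT_SAMPLES, LEAD_NAMES, LatentRepresentation, MedianBeatSet

__all__ = [
    "BETA_GRID",
    "BetaVAE",
    "smape_loss",
    "kl_loss",
    "total_loss",
    "reconstruction_correlation",
    "select_beta",
    "active_latents",
    "save_model",
    "load_model",
]

#: candidate KL weights for model selection
BETA_GRID = (0.1, 0.25, 0.5, 1.0, 3.0, 5.0, 10.0)

#: SMAPE denominator offset (mV) guarding 0/0 at zero-padded samples
SMAPE_EPS = 1e-4

_N_INPUT = len(LEAD_NAMES) * BEAT_SAMPLES


def smape_loss(x: np.ndarray, xhat: np.ndarray, eps: float = SMAPE_EPS) -> float:
    """Symmetric mean absolute percentage error in percent, bounded [0, 200].

    ``100 * mean(|x - xhat| / ((|x| + |xhat|) / 2 + eps))`` over all
    elements.
    """
    x = np.asarray(x, dtype=float)
    xhat = np.asarray(xhat, dtype=float)
    if x.shape != xhat.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {xhat.shape}")
    denom = (np.abs(x) + np.abs(xhat)) / 2.0 + eps
    return float(100.0 * np.mean(np.abs(x - xhat) / denom))


def kl_loss(mu: np.ndarray, logvar: np.ndarray) -> float:
    """KL divergence of N(mu, exp(logvar)) from N(0, I): summed over latent
    dimensions, averaged over the batch.  Always nonnegative; zero iff the
    posterior is exactly standard normal."""
    mu = np.atleast_2d(np.asarray(mu, dtype=float))
    logvar = np.atleast_2d(np.asarray(logvar, dtype=float))
    if not (np.isfinite(mu).all() and np.isfinite(logvar).all()):
        raise ValueError("non-finite posterior parameters")
    per_dim = -0.5 * (1.0 + logvar - mu**2 - np.exp(logvar))
    return float(per_dim.sum(axis=-1).mean())


def total_loss(x, xhat, mu, logvar, beta: float, eps: float = SMAPE_EPS) -> float:
    """SMAPE reconstruction loss plus ``beta`` times the KL term."""
    if beta <= 0:
        raise ValueError("beta must be positive")
    return smape_loss(x, xhat, eps=eps) + beta * kl_loss(mu, logvar)


def _as_array(beats) -> np.ndarray:
    if isinstance(beats, MedianBeatSet):
        return beats.beats
    arr = np.asarray(beats, dtype=float)
    if arr.ndim == 2 and arr.shape[1] == _N_INPUT:
        arr = arr.reshape(-1, len(LEAD_NAMES), BEAT_SAMPLES)
    if arr.ndim == 2 and arr.shape == (len(LEAD_NAMES), BEAT_SAMPLES):
        arr = arr[None]
    if arr.ndim != 3 or arr.shape[1:] != (len(LEAD_NAMES), BEAT_SAMPLES):
        raise ValueError(f"expected (n, {len(LEAD_NAMES)}, {BEAT_SAMPLES}) beats, got {arr.shape}")
    return arr


class _Network:
    """Forward/backward wiring of encoder, reparameterisation and decoder."""

    def __init__(self, rng, latent_dim: int, conv_spec, logvar_clip: float = 8.0):
        self.latent_dim = latent_dim
        self.conv_spec = tuple((int(f), int(k)) for f, k in conv_spec)
        self.logvar_clip = logvar_clip
        c_prev = len(LEAD_NAMES)
        length = BEAT_SAMPLES
        self.enc = []
        for filters, kernel in self.conv_spec:
            self.enc += [_nn.Conv1d(rng, c_prev, filters, kernel, stride=2), _nn.ELU()]
            c_prev = filters
            length //= 2
        self.bottom_channels, self.bottom_len = c_prev, length
        flat = c_prev * length
        self.mu_head = _nn.Dense(rng, flat, latent_dim)
        self.lv_head = _nn.Dense(rng, flat, latent_dim)
        self.dec_dense = _nn.Dense(rng, latent_dim, flat)
        self.dec_act = _nn.ELU()
        self.dec = []
        rev = self.conv_spec[::-1]
        for i, (filters, kernel) in enumerate(rev):
            c_out = rev[i + 1][0] if i + 1 < len(rev) else len(LEAD_NAMES)
            self.dec.append(_nn.ConvTranspose1d(rng, filters, c_out, kernel, stride=2))
            if i + 1 < len(rev):
                self.dec.append(_nn.ELU())

    @property
    def layers(self):
        return [*self.enc, self.mu_head, self.lv_head, self.dec_dense, self.dec_act, *self.dec]

    def parameters(self):
        params, grads = [], []
        for layer in self.layers:
            params += layer.params
            grads += layer.grads
        return params, grads

    def encode(self, x: np.ndarray):
        h = x.astype(_nn.DTYPE)
        for layer in self.enc:
            h = layer.forward(h)
        flat = h.reshape(h.shape[0], -1)
        mu = self.mu_head.forward(flat)
        lv_raw = self.lv_head.forward(flat)
        lv = np.clip(lv_raw, -self.logvar_clip, self.logvar_clip)
        self._lv_mask = (np.abs(lv_raw) < self.logvar_clip).astype(_nn.DTYPE)
        return mu, lv

    def decode(self, z: np.ndarray) -> np.ndarray:
        g = self.dec_act.forward(self.dec_dense.forward(z.astype(_nn.DTYPE)))
        h = g.reshape(-1, self.bottom_channels, self.bottom_len)
        for layer in self.dec:
            h = layer.forward(h)
        return h

    def backward(self, dxhat: np.ndarray, dmu_extra, dlv_extra, eps_noise, lv):
        h = dxhat.astype(_nn.DTYPE)
        for layer in reversed(self.dec):
            h = layer.backward(h)
        dg = h.reshape(h.shape[0], -1)
        dz = self.dec_dense.backward(self.dec_act.backward(dg))
        dmu = dz + dmu_extra
        dlv = (dz * eps_noise * 0.5 * np.exp(0.5 * lv) + dlv_extra) * self._lv_mask
        dflat = self.mu_head.backward(dmu.astype(_nn.DTYPE)) + self.lv_head.backward(
            dlv.astype(_nn.DTYPE)
        )
        h = dflat.reshape(-1, self.bottom_channels, self.bottom_len)
        for layer in reversed(self.enc):
            h = layer.backward(h)


class BetaVAE(TransformerMixin, BaseEstimator):
    """Beta-weighted variational autoencoder over 8-lead median beats.

    Parameters
    ----------
    latent_dim : int, default 30
        Maximum number of latent features; the model typically uses fewer.
    beta : float, default 0.25
        Weight on the KL term of the training objective.
    conv_spec : sequence of (filters, kernel)
        Encoder convolution blocks (stride 2 each); filters must be
        nondecreasing and kernels nonincreasing toward the latent space.
        The decoder mirrors the spec with transposed convolutions.
    epochs, batch_size, learning_rate
        Plain Adam training schedule (no scheduler, no early stopping).
    seed : int
        Controls weight initialisation, shuffling and the reparameterisation
        noise; identical seeds give identical trained weights.

    Attributes
    ----------
    history_ : DataFrame with per-epoch train (and validation) losses.
    active_latents_ : indices of latent dimensions whose posterior-mean
        variance across the training set exceeds ``active_threshold``.
    """

    def __init__(self, latent_dim: int = 30, beta: float = 0.25,
                 conv_spec=((16, 15), (32, 9), (64, 5), (128, 3)),
                 epochs: int = 150, batch_size: int = 32,
                 learning_rate: float = 1e-3, smape_eps: float = SMAPE_EPS,
                 active_threshold: float = 0.01, seed: int = 0):
        self.latent_dim = latent_dim
        self.beta = beta
        self.conv_spec = conv_spec
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.smape_eps = smape_eps
        self.active_threshold = active_threshold
        self.seed = seed

    def _validate_params_(self):
        if self.latent_dim < 1:
            raise ValueError("latent_dim must be at least 1")
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        filters = [f for f, _ in self.conv_spec]
        kernels = [k for _, k in self.conv_spec]
        if any(b < a for a, b in zip(filters, filters[1:])):
            raise ValueError("conv_spec filters must be nondecreasing toward the latent space")
        if any(b > a for a, b in zip(kernels, kernels[1:])):
            raise ValueError("conv_spec kernels must be nonincreasing toward the latent space")

    # ------------------------------------------------------------------
    def fit(self, X, y=None, X_val=None):
        """Train the VAE on beats of shape (n, 8, 400).

        ``X_val`` (optional) adds per-epoch validation losses to the
        history.  Raises ``RuntimeError`` with a diagnostic if the loss
        becomes non-finite.
        """
        self._validate_params_()
        x = _as_array(X)
        xv = _as_array(X_val) if X_val is not None else None
        rng = np.random.default_rng(self.seed)
        net = _Network(rng, self.latent_dim, self.conv_spec)
        params, grads = net.parameters()
        opt = _nn.Adam(params, grads, lr=self.learning_rate)

        n = x.shape[0]
        bs = min(self.batch_size, n)
        history = []
        for epoch in range(self.epochs):
            order = rng.permutation(n)
            ep_recon, ep_kl, n_batches = 0.0, 0.0, 0
            for start in range(0, n, bs):
                xb = x[order[start:start + bs]].astype(_nn.DTYPE)
                mu, lv = net.encode(xb)
                if not (np.isfinite(mu).all() and np.isfinite(lv).all()):
                    raise RuntimeError(
                        f"non-finite posterior at epoch {epoch}: check the input "
                        "for NaN/inf or reduce the learning rate"
                    )
                eps_noise = rng.standard_normal(mu.shape).astype(_nn.DTYPE)
                z = mu + np.exp(0.5 * lv) * eps_noise
                xhat = net.decode(z)

                recon = smape_loss(xb, xhat, eps=self.smape_eps)
                kl = kl_loss(mu, lv)
                if not np.isfinite(recon + kl):
                    raise RuntimeError(
                        f"non-finite loss at epoch {epoch}: recon={recon}, kl={kl}; "
                        "reduce the learning rate or check the input scale"
                    )
                b = xb.shape[0]
                denom = (np.abs(xb) + np.abs(xhat)) / 2.0 + self.smape_eps
                diff = xhat - xb
                dxhat = (100.0 / diff.size) * (
                    np.sign(diff) / denom
                    - np.abs(diff) * np.sign(xhat) / (2.0 * denom**2)
                )
                dmu_extra = self.beta * mu / b
                dlv_extra = self.beta * 0.5 * (np.exp(lv) - 1.0) / b
                net.backward(dxhat, dmu_extra, dlv_extra, eps_noise, lv)
                opt.step()
                ep_recon += recon
                ep_kl += kl
                n_batches += 1
            row = {
                "epoch": epoch,
                "train_recon": ep_recon / n_batches,
                "train_kl": ep_kl / n_batches,
            }
            row["train_total"] = row["train_recon"] + self.beta * row["train_kl"]
            if xv is not None:
                mu_v, lv_v = net.encode(xv.astype(_nn.DTYPE))
                xhat_v = net.decode(mu_v)
                row["val_recon"] = smape_loss(xv, xhat_v, eps=self.smape_eps)
                row["val_kl"] = kl_loss(mu_v, lv_v)
                row["val_total"] = row["val_recon"] + self.beta * row["val_kl"]
            history.append(row)

        self._net = net
        self.history_ = pd.DataFrame(history)
        mu_train, _ = net.encode(x.astype(_nn.DTYPE))
        self.active_latents_ = active_latents(mu_train, self.active_threshold)
        self.n_features_in_ = _N_INPUT
        return self

    def _check_fitted(self):
        if not hasattr(self, "_net"):
            raise RuntimeError("model is not trained; call fit first")

    def encode(self, X) -> LatentRepresentation:
        """Deterministic (posterior-mean) encoding of beats."""
        self._check_fitted()
        x = _as_array(X)
        mu, lv = self._net.encode(x.astype(_nn.DTYPE))
        ids = X.subject_ids if isinstance(X, MedianBeatSet) else np.arange(x.shape[0])
        return LatentRepresentation(mu.astype(float), lv.astype(float),
                                    np.asarray(ids), self.active_latents_)

    def transform(self, X) -> np.ndarray:
        """Posterior means, shape (n, latent_dim)."""
        return self.encode(X).mu

    def inverse_transform(self, Z) -> np.ndarray:
        """Decode latent vectors to beats of shape (n, 8, 400)."""
        self._check_fitted()
        z = np.atleast_2d(np.asarray(Z, dtype=float))
        if z.shape[1] != self.latent_dim:
            raise ValueError(f"expected latent dimension {self.latent_dim}, got {z.shape[1]}")
        return self._net.decode(z).astype(float)

    def reconstruct(self, X) -> np.ndarray:
        return self.inverse_transform(self.transform(X))

    def score(self, X, y=None) -> float:
        """Mean per-record Pearson correlation between input and
        reconstruction."""
        r, mean_r, _ = reconstruction_correlation(self, X)
        return mean_r


def reconstruction_correlation(model: BetaVAE, beats):
    """Per-record Pearson r between each beat and its reconstruction.

    Computed over the flattened 8 x 400 signal.  Zero-variance records give
    NaN (reported missing).  Returns ``(r, mean_r, sd_r)`` with the
    summaries taken over the defined entries.
    """
    x = _as_array(beats)
    xhat = model.reconstruct(x)
    xf = x.reshape(x.shape[0], -1)
    hf = xhat.reshape(x.shape[0], -1)
    xc = xf - xf.mean(axis=1, keepdims=True)
    hc = hf - hf.mean(axis=1, keepdims=True)
    denom = np.sqrt((xc**2).sum(axis=1) * (hc**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, (xc * hc).sum(axis=1) / denom, np.nan)
    return r, float(np.nanmean(r)), float(np.nanstd(r))


def active_latents(latents, threshold: float = 0.01) -> np.ndarray:
    """Indices of latent dimensions whose across-subject posterior-mean
    variance exceeds ``threshold`` (sorted ascending)."""
    mu = latents.mu if isinstance(latents, LatentRepresentation) else np.asarray(latents)
    if mu.ndim != 2 or mu.shape[0] < 2:
        raise ValueError("need posterior means from at least 2 subjects")
    var = mu.var(axis=0)
    return np.flatnonzero(var > threshold)


def select_beta(candidates, train_beats, val_beats, **vae_params):
    """Train one model per beta candidate (shared seed) and pick the one
    with the highest mean validation reconstruction correlation.

    Ties break toward the smaller beta.  Candidates that fail to train are
    recorded with NaN score and excluded with a warning.

    Returns
    -------
    best_beta : float
    table : DataFrame with columns beta, val_recon_r, status.
    """
    candidates = list(candidates)
    if not candidates:
        raise ValueError("no beta candidates supplied")
    rows = []
    for beta in candidates:
        try:
            model = BetaVAE(beta=beta, **vae_params).fit(train_beats)
            _, mean_r, _ = reconstruction_correlation(model, val_beats)
            rows.append({"beta": beta, "val_recon_r": mean_r, "status": "ok"})
        except Exception as exc:  # noqa: BLE001 - candidate failure is data, not fatal
            warnings.warn(f"beta={beta} failed to train: {exc}")
            rows.append({"beta": beta, "val_recon_r": np.nan, "status": f"failed: {exc}"})
    table = pd.DataFrame(rows)
    ok = table.dropna(subset=["val_recon_r"])
    if ok.empty:
        raise RuntimeError("every beta candidate failed to train")
    best_score = ok["val_recon_r"].max()
    best_beta = ok.loc[ok["val_recon_r"] == best_score, "beta"].min()
    return float(best_beta), table


# ---------------------------------------------------------------------------
# persistence: weights as .npz plus a JSON config sidecar
# ---------------------------------------------------------------------------

def save_model(model: BetaVAE, directory) -> None:
    model._check_fitted()
    directory = pathlib.Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    params, _ = model._net.parameters()
    np.savez(directory / "weights.npz", **{f"p{i}": p for i, p in enumerate(params)})
    config = model.get_params()
    config["conv_spec"] = [list(c) for c in config["conv_spec"]]
    config["active_latents"] = model.active_latents_.tolist()
    (directory / "config.json").write_text(json.dumps(config, indent=2))
    model.history_.to_csv(directory / "history.csv", index=False)


def load_model(directory) -> BetaVAE:
    directory = pathlib.Path(directory)
    config = json.loads((directory / "config.json").read_text())
    active = np.asarray(config.pop("active_latents"), dtype=int)
    config["conv_spec"] = tuple(tuple(c) for c in config["conv_spec"])
    model = BetaVAE(**config)
    model._validate_params_()
    net = _Network(np.random.default_rng(0), model.latent_dim, model.conv_spec)
    params, _ = net.parameters()
    with np.load(directory / "weights.npz") as data:
        for i, p in enumerate(params):
            p[...] = data[f"p{i}"]
    model._net = net
    model.active_latents_ = active
    model.history_ = pd.read_csv(directory / "history.csv")
    model.n_features_in_ = _N_INPUT
    return model
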