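"""Subsequence autoencoders: the mapping psi from multichannel windows to a
low-dimensional latent space (and its decoder phi).

Two architectures are provided:

* ``fully_connected`` — encoder ``d -> d/2 -> d/4 -> latent`` on the
  flattened window (``d = NC*NW``), sigmoid activations, decoder mirrored
  with transposed (tied) weights and a linear output layer so inputs of any
  scale are reconstructible; ``latent = max(1, round(0.1 * d))`` (a 10:1
  bottleneck).
* ``convolutional`` — two stride-2 convolutions (NC -> 2NC -> 4NC, kernel 3,
  padding 1), flatten, three dense layers halving down to
  ``latent = round(NC*NW/6)``, all ReLU; decoder mirrors with tied dense
  layers and transposed convolutions, final activation linear.

Training minimizes reconstruction MSE with Adam, early-stopping on a held
out validation split.  Inputs are scaled per channel with statistics from
the training data only (scaler choice is a config option).  All randomness
flows from the config seed, so two runs with the same data are bitwise
identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from . import nn
from .signal import TimeSeries

__all__ = [
    "AutoencoderSpec",
    "TrainingConfig",
    "LatentSet",
    "TrainedAutoencoder",
    "build_autoencoder",
    "train_autoencoder",
    "encode_all",
]

_SCALERS = ("none", "standard", "minmax", "robust", "maxabs")


@dataclass(frozen=True)
class AutoencoderSpec:
    """Architecture description for a subsequence autoencoder."""

    kind: str               # "fully_connected" | "convolutional"
    nc: int                 # input channels
    nw: int                 # subsequence length
    latent_dim: int
    layer_plan: tuple[str, ...] = ()
    tied_decoder: bool = True


@dataclass(frozen=True)
class TrainingConfig:
    """Hyperparameters for autoencoder training.

    ``val_fraction`` defaults to 0.2: 80 % of the training windows are used
    as training examples, the rest to validate/early-stop.  ``train_stride``
    subsamples training windows (stride 1 keeps every window; larger strides
    decorrelate examples and speed training up).
    """

    learning_rate: float = 1e-3
    max_epochs: int = 200
    batch_size: int = 64
    val_fraction: float = 0.2
    seed: int = 0
    train_stride: int = 1
    patience: int = 20
    scaler: str = "standard"

    def __post_init__(self) -> None:
        if not (0.0 < self.val_fraction < 1.0):
            raise ValueError("val_fraction must be in (0, 1)")
        if self.train_stride < 1:
            raise ValueError("train_stride must be >= 1")
        if self.scaler not in _SCALERS:
            raise ValueError(f"scaler must be one of {_SCALERS}")


@dataclass(frozen=True)
class LatentSet:
    """The latent all-subsequence set F: one latent row per window position."""

    F: np.ndarray           # (n - m + 1, latent_dim)
    m: int
    provenance: AutoencoderSpec | None = None

    def __post_init__(self) -> None:
        F = np.asarray(self.F, dtype=np.float64)
        if not np.all(np.isfinite(F)):
            raise ValueError("latent set contains non-finite values")
        object.__setattr__(self, "F", F)

    def __len__(self) -> int:
        return self.F.shape[0]


def build_autoencoder(kind: str, nc: int, nw: int) -> AutoencoderSpec:
    """Build the architecture spec for ``kind`` on ``(nw, nc)`` windows.

    Raises
    ------
    ValueError
        convolutional: ``nw`` not divisible by 4 (two stride-2 layers);
        fully connected: ``nc*nw < 10`` (no room for a 10:1 bottleneck).
        The message suggests padding or changing ``nw``.
    """
    d = nc * nw
    if kind == "fully_connected":
        if d < 10:
            raise ValueError(
                f"fully connected autoencoder needs NC*NW >= 10, got {d}; "
                "use a longer subsequence (NW) or more channels")
        latent = max(1, round(0.1 * d))
        plan = (f"dense {d}->{d // 2} sigmoid",
                f"dense {d // 2}->{d // 4} sigmoid",
                f"dense {d // 4}->{latent} sigmoid",
                f"dense-tied {latent}->{d // 4} sigmoid",
                f"dense-tied {d // 4}->{d // 2} sigmoid",
                f"dense-tied {d // 2}->{d} linear")
        return AutoencoderSpec(kind, nc, nw, latent, plan)
    if kind == "convolutional":
        if nw % 4 != 0:
            raise ValueError(
                f"convolutional autoencoder needs NW divisible by 4, got NW={nw}; "
                "pad the window or choose a different NW")
        latent = max(1, round(d / 6))
        plan = (f"conv {nc}->{2 * nc} k3 s2 p1 relu",
                f"conv {2 * nc}->{4 * nc} k3 s2 p1 relu",
                f"flatten -> {d}",
                f"dense {d}->{d // 2} relu",
                f"dense {d // 2}->{d // 4} relu",
                f"dense {d // 4}->{latent} relu",
                f"dense-tied {latent}->{d // 4} relu",
                f"dense-tied {d // 4}->{d // 2} relu",
                f"dense-tied {d // 2}->{d} relu",
                f"unflatten -> ({4 * nc}, {nw // 4})",
                f"convT {4 * nc}->{2 * nc} k3 s2 p1 op1 relu",
                f"convT {2 * nc}->{nc} k3 s2 p1 op1 linear")
        return AutoencoderSpec(kind, nc, nw, latent, plan)
    raise ValueError(f"unknown autoencoder kind {kind!r}")


def _build_networks(spec: AutoencoderSpec,
                    rng: np.random.Generator) -> tuple[nn.Sequential, nn.Sequential]:
    d = spec.nc * spec.nw
    if spec.kind == "fully_connected":
        e1 = nn.Dense(rng, d, d // 2)
        e2 = nn.Dense(rng, d // 2, d // 4)
        e3 = nn.Dense(rng, d // 4, spec.latent_dim)
        enc = nn.Sequential([e1, nn.Sigmoid(), e2, nn.Sigmoid(), e3, nn.Sigmoid()])
        dec = nn.Sequential([nn.DenseTransposed(e3), nn.Sigmoid(),
                             nn.DenseTransposed(e2), nn.Sigmoid(),
                             nn.DenseTransposed(e1), nn.Identity()])
        return enc, dec
    c1 = nn.Conv1d(rng, spec.nc, 2 * spec.nc)
    c2 = nn.Conv1d(rng, 2 * spec.nc, 4 * spec.nc)
    f1 = nn.Dense(rng, d, d // 2)
    f2 = nn.Dense(rng, d // 2, d // 4)
    f3 = nn.Dense(rng, d // 4, spec.latent_dim)
    enc = nn.Sequential([c1, nn.ReLU(), c2, nn.ReLU(), nn.Flatten(),
                         f1, nn.ReLU(), f2, nn.ReLU(), f3, nn.ReLU()])
    dec = nn.Sequential([nn.DenseTransposed(f3), nn.ReLU(),
                         nn.DenseTransposed(f2), nn.ReLU(),
                         nn.DenseTransposed(f1), nn.ReLU(),
                         nn.Unflatten(4 * spec.nc, spec.nw // 4),
                         nn.ConvTranspose1d(rng, 4 * spec.nc, 2 * spec.nc), nn.ReLU(),
                         nn.ConvTranspose1d(rng, 2 * spec.nc, spec.nc), nn.Identity()])
    return enc, dec


# ---------------------------------------------------------------------------
# channel scalers (statistics fitted on training data only)

def _fit_scaler(kind: str, rows: np.ndarray) -> dict:
    """Fit a per-channel scaler on ``(N, NC)`` training rows.

    Uses scikit-learn's scaler implementations; the fitted statistics are
    extracted into plain arrays so models serialize without pickling.
    """
    if kind == "none":
        return {"kind": kind}
    from sklearn.preprocessing import (MaxAbsScaler, MinMaxScaler,
                                       RobustScaler, StandardScaler)
    cls = {"standard": StandardScaler, "minmax": MinMaxScaler,
           "robust": RobustScaler, "maxabs": MaxAbsScaler}[kind]
    s = cls().fit(rows)
    if kind == "standard":
        return {"kind": kind, "center": s.mean_, "scale": s.scale_}
    if kind == "minmax":
        return {"kind": kind, "center": -s.min_ / s.scale_, "scale": 1.0 / s.scale_}
    if kind == "robust":
        return {"kind": kind, "center": s.center_, "scale": s.scale_}
    return {"kind": kind, "center": np.zeros(rows.shape[1]), "scale": s.max_abs_}


def _apply_scaler(sc: dict, x: np.ndarray) -> np.ndarray:
    """Apply a fitted scaler to data whose last axis is the channel axis."""
    if sc["kind"] == "none":
        return np.asarray(x, dtype=np.float64)
    return (np.asarray(x, dtype=np.float64) - sc["center"]) / sc["scale"]


# ---------------------------------------------------------------------------

class TrainedAutoencoder:
    """A trained model handle: spec + networks + scaler + training config."""

    def __init__(self, spec: AutoencoderSpec, encoder: nn.Sequential,
                 decoder: nn.Sequential, scaler: dict, cfg: TrainingConfig):
        self.spec = spec
        self.encoder = encoder
        self.decoder = decoder
        self.scaler = scaler
        self.cfg = cfg

    # -- layout helpers ----------------------------------------------------
    def _prep(self, windows: np.ndarray) -> np.ndarray:
        """Scale ``(B, NW, NC)`` windows and lay them out for the network."""
        x = _apply_scaler(self.scaler, windows)
        if self.spec.kind == "fully_connected":
            return x.reshape(x.shape[0], -1)
        return x.transpose(0, 2, 1)  # (B, NC, NW)

    def encode(self, windows: np.ndarray, batch: int = 1024) -> np.ndarray:
        """psi: map ``(B, NW, NC)`` windows to ``(B, latent_dim)`` rows."""
        x = self._prep(np.asarray(windows))
        out = [self.encoder.forward(x[j:j + batch]) for j in range(0, len(x), batch)]
        return np.concatenate(out, axis=0)

    def reconstruct(self, windows: np.ndarray) -> np.ndarray:
        """phi(psi(x)) in the scaled input layout (for loss computation)."""
        x = self._prep(np.asarray(windows))
        return self.decoder.forward(self.encoder.forward(x))

    def reconstruction_mse(self, windows: np.ndarray) -> float:
        x = self._prep(np.asarray(windows))
        y = self.decoder.forward(self.encoder.forward(x))
        return float(np.mean((y - x) ** 2))

    @property
    def n_params(self) -> int:
        return sum(p.value.size for p in nn.unique_params(self.encoder, self.decoder))

    # -- persistence -------------------------------------------------------
    FORMAT_VERSION = 1

    def config_hash(self) -> str:
        import hashlib
        blob = json.dumps({"spec": asdict(self.spec), "cfg": asdict(self.cfg)},
                          sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def save(self, path) -> None:
        """Save spec, parameters, scaler statistics and config (with its
        hash, for provenance) to one ``.npz`` archive."""
        meta = {"format_version": self.FORMAT_VERSION,
                "spec": asdict(self.spec), "cfg": asdict(self.cfg),
                "config_hash": self.config_hash(),
                "scaler_kind": self.scaler["kind"]}
        arrays = {f"param_{k}": p.value
                  for k, p in enumerate(nn.unique_params(self.encoder, self.decoder))}
        if self.scaler["kind"] != "none":
            arrays["scaler_center"] = np.asarray(self.scaler["center"])
            arrays["scaler_scale"] = np.asarray(self.scaler["scale"])
        np.savez(path, meta=json.dumps(meta), **arrays)

    @classmethod
    def load(cls, path) -> "TrainedAutoencoder":
        with np.load(path, allow_pickle=False) as z:
            meta = json.loads(str(z["meta"]))
            if meta["format_version"] != cls.FORMAT_VERSION:
                raise ValueError(f"unsupported model format {meta['format_version']}")
            spec_d = meta["spec"]
            spec_d["layer_plan"] = tuple(spec_d["layer_plan"])
            spec = AutoencoderSpec(**spec_d)
            cfg = TrainingConfig(**meta["cfg"])
            enc, dec = _build_networks(spec, np.random.default_rng(0))
            params = nn.unique_params(enc, dec)
            for k, p in enumerate(params):
                p.value[...] = z[f"param_{k}"]
            if meta["scaler_kind"] == "none":
                scaler = {"kind": "none"}
            else:
                scaler = {"kind": meta["scaler_kind"],
                          "center": z["scaler_center"], "scale": z["scaler_scale"]}
        return cls(spec, enc, dec, scaler, cfg)


def _training_windows(series: list[TimeSeries], nw: int, stride: int) -> np.ndarray:
    chunks = []
    for ts in series:
        if ts.n >= nw:
            w = sliding_window_view(ts.values, nw, axis=0).transpose(0, 2, 1)
            chunks.append(w[::stride])
    if not chunks:
        raise ValueError(f"no series long enough for NW={nw} windows")
    return np.concatenate(chunks, axis=0)


def train_autoencoder(spec: AutoencoderSpec,
                      train_ts: TimeSeries | list[TimeSeries],
                      cfg: TrainingConfig) -> tuple[TrainedAutoencoder, dict]:
    """Train an autoencoder to reconstruct subsequences of ``train_ts``.

    Windows are sampled with ``cfg.train_stride``, scaled with per-channel
    statistics fitted on the training rows, split into train/validation by a
    seeded shuffle, and optimized with Adam on the MSE objective.  The
    parameters achieving the best validation MSE are returned (early
    stopping after ``cfg.patience`` epochs without improvement).

    Returns
    -------
    (model, history)
        ``history`` has per-epoch ``train``, ``val`` and best-so-far
        ``best_val`` loss lists.
    """
    series = [train_ts] if isinstance(train_ts, TimeSeries) else list(train_ts)
    for ts in series:
        if ts.n_channels != spec.nc:
            raise ValueError(
                f"series has {ts.n_channels} channels, spec expects {spec.nc}")
    windows = _training_windows(series, spec.nw, cfg.train_stride)
    N = len(windows)
    n_val = max(1, round(cfg.val_fraction * N))
    if N - n_val < 1:
        raise ValueError(
            f"only {N} windows: not enough for a train/validation split")

    rng = np.random.default_rng(cfg.seed)
    perm = rng.permutation(N)
    val_idx, tr_idx = perm[:n_val], perm[n_val:]

    scaler = _fit_scaler(cfg.scaler, np.concatenate([ts.values for ts in series]))
    enc, dec = _build_networks(spec, rng)
    model = TrainedAutoencoder(spec, enc, dec, scaler, cfg)

    X = model._prep(windows)
    Xtr, Xval = X[tr_idx], X[val_idx]
    opt = nn.Adam(nn.unique_params(enc, dec), lr=cfg.learning_rate)

    def val_loss() -> float:
        return float(np.mean((dec.forward(enc.forward(Xval)) - Xval) ** 2))

    history: dict[str, list[float]] = {"train": [], "val": [], "best_val": []}
    best = val_loss()
    best_params = [p.value.copy() for p in opt.params]
    best_epoch = -1
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(len(Xtr))
        ep_loss, n_batches = 0.0, 0
        for b0 in range(0, len(Xtr), cfg.batch_size):
            xb = Xtr[order[b0:b0 + cfg.batch_size]]
            opt.zero_grad()
            y = dec.forward(enc.forward(xb))
            loss, dy = nn.mse_loss(y, xb)
            enc.backward(dec.backward(dy))
            opt.step()
            ep_loss += loss
            n_batches += 1
        v = val_loss()
        history["train"].append(ep_loss / max(n_batches, 1))
        history["val"].append(v)
        if v < best:
            best = v
            best_params = [p.value.copy() for p in opt.params]
            best_epoch = epoch
        history["best_val"].append(best)
        if epoch - best_epoch >= cfg.patience:
            break
    for p, w in zip(opt.params, best_params):
        p.value[...] = w
    return model, history


def encode_all(model: TrainedAutoencoder, ts: TimeSeries, m: int) -> LatentSet:
    """Encode every stride-1 window of ``ts``: the latent all-subsequence set.

    ``m`` must equal the subsequence length the model was trained on and the
    channel counts must match.
    """
    if m != model.spec.nw:
        raise ValueError(f"m={m} does not match model NW={model.spec.nw}")
    if ts.n_channels != model.spec.nc:
        raise ValueError(
            f"series has {ts.n_channels} channels, model expects {model.spec.nc}")
    if ts.n < m:
        raise ValueError(f"series length {ts.n} shorter than NW={m}")
    windows = sliding_window_view(ts.values, m, axis=0).transpose(0, 2, 1)
    F = model.encode(windows)
    return LatentSet(F=F, m=m, provenance=model.spec)
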