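"""Artefact-correction U-Net: construction, training, prediction.

The network maps a max-|value|-normalized mBF image to an estimate of the
artefact-free absorption map.  Architecture: a U-Net with dropout and
batch normalization in every scale block, a single-filter 1x1 output
convolution, and no final activation (the target is a real-valued image).
Training minimizes mean squared error with Adam (lr 5e-4, beta1 0.8,
batches of 8) and early stopping on the validation loss, with the
best-validation weights restored.

Presets
-------
``full``     depth 4, base 64, 128x128 inputs — the reference architecture,
             ~3.1e7 trainable parameters.
``reduced``  depth 4, base 16, 64x64 inputs — CPU desk scale.
``tiny``     depth 3, base 8, 32x32 inputs — used by the fast experiment
             sweeps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import Adam, UNet

__all__ = ["UNetSpec", "TrainConfig", "TrainedModel", "PRESETS",
           "build_unet", "train", "predict", "pretrain_finetune",
           "normalize_input", "save_model", "load_model"]


@dataclass(frozen=True)
class UNetSpec:
    depth: int = 4
    base_filters: int = 64
    dropout_rate: float = 0.5
    use_batchnorm: bool = True
    out_channels: int = 1
    final_activation: str | None = None

    def __post_init__(self):
        if self.out_channels != 1:
            raise ValueError("the output is a single image: out_channels must be 1")
        if self.final_activation is not None:
            raise ValueError("the output layer is linear: no final activation")


# desk presets run with a lower dropout rate: at 8-16 base filters and a
# few hundred gradient steps, the reference 50% rate removes too much
# capacity to converge (the full-scale preset keeps it)
PRESETS = {
    "full": UNetSpec(depth=4, base_filters=64),
    "reduced": UNetSpec(depth=4, base_filters=16, dropout_rate=0.2),
    "tiny": UNetSpec(depth=3, base_filters=8, dropout_rate=0.2),
}


@dataclass
class TrainConfig:
    lr: float = 5e-4
    beta1: float = 0.8  # the stated optimizer momentum, as a fraction
    batch_size: int = 8
    max_epochs: int = 100
    early_stopping_patience: int = 20
    seed: int = 0

    def __post_init__(self):
        if self.batch_size < 1 or self.lr < 0:
            raise ValueError("batch_size >= 1 and lr >= 0 required")


@dataclass
class TrainedModel:
    net: UNet
    spec: UNetSpec
    history: dict = field(default_factory=lambda: {"train_loss": [], "val_loss": []})
    provenance: dict = field(default_factory=dict)

    def n_parameters(self) -> int:
        return self.net.n_parameters()


def build_unet(spec: UNetSpec, seed: int = 0) -> TrainedModel:
    """Instantiate an untrained model from its architecture spec."""
    net = UNet(depth=spec.depth, base_filters=spec.base_filters,
               dropout_rate=spec.dropout_rate, use_batchnorm=spec.use_batchnorm,
               seed=seed)
    return TrainedModel(net, spec, provenance={"init_seed": seed})


def normalize_input(img: np.ndarray) -> np.ndarray:
    """Scale an mBF image by its maximum absolute value (no-op if zero)."""
    img = np.asarray(img, dtype=np.float32)
    m = np.max(np.abs(img))
    return img / m if m > 0 else img


def _epoch_loss(net, x, y, batch_size):
    tot, n = 0.0, 0
    for i in range(0, len(x), batch_size):
        xb, yb = x[i:i + batch_size], y[i:i + batch_size]
        pred = net.forward(xb, training=False)
        tot += float(np.mean((pred[:, 0] - yb) ** 2)) * len(xb)
        n += len(xb)
    return tot / max(n, 1)


def train(model: TrainedModel, dataset, cfg: TrainConfig,
          train_split: str = "train", val_split: str | None = "val",
          verbose: bool = False) -> TrainedModel:
    """MSE training with Adam and early stopping on the validation loss.

    ``dataset`` is a PairedDataset (or any object with ``subset``).  When a
    validation split is present, the weights achieving the lowest
    validation loss are restored at the end; the loss history of every
    epoch is kept in ``model.history``.
    """
    x_tr, y_tr = dataset.subset(train_split)
    has_val = val_split is not None and val_split in getattr(dataset, "splits", {})
    if has_val:
        x_va, y_va = dataset.subset(val_split)
    net = model.net
    opt = Adam(net.params(), lr=cfg.lr, beta1=cfg.beta1)
    rng = np.random.default_rng(cfg.seed)
    best_val, best_weights, since_best = np.inf, None, 0

    for epoch in range(cfg.max_epochs):
        order = rng.permutation(len(x_tr))
        ep_loss, n_seen = 0.0, 0
        for i in range(0, len(order), cfg.batch_size):
            idx = order[i:i + cfg.batch_size]
            xb = x_tr[idx]
            yb = y_tr[idx]
            pred = net.forward(xb, training=True, rng=rng)
            resid = pred[:, 0] - yb
            loss = float(np.mean(resid ** 2))
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"NaN/inf training loss at epoch {epoch}, batch {i // cfg.batch_size}")
            opt.zero_grad()
            net.backward((2.0 / resid.size * resid)[:, None].astype(np.float32))
            opt.step()
            ep_loss += loss * len(idx)
            n_seen += len(idx)
        model.history["train_loss"].append(ep_loss / max(n_seen, 1))
        if has_val:
            vl = _epoch_loss(net, x_va, y_va, cfg.batch_size)
            model.history["val_loss"].append(vl)
            if vl < best_val:
                best_val, best_weights, since_best = vl, net.get_weights(), 0
            else:
                since_best += 1
                if since_best >= cfg.early_stopping_patience:
                    break
        if verbose:
            msg = f"epoch {epoch}: train {model.history['train_loss'][-1]:.5f}"
            if has_val:
                msg += f" val {model.history['val_loss'][-1]:.5f}"
            print(msg)
    if has_val and best_weights is not None:
        net.set_weights(best_weights)
    model.provenance.update({"train_seed": cfg.seed, "epochs_run":
                             len(model.history["train_loss"])})
    return model


def predict(model: TrainedModel, mbf) -> np.ndarray:
    """Deterministic prediction: dropout off, batch norm in inference mode.

    ``mbf`` may be a 2D array, an (N, H, W) stack, or a ReconImage; inputs
    are max-|value|-normalized before entering the network.
    """
    arr = getattr(mbf, "values", mbf)
    arr = np.asarray(arr, dtype=np.float32)
    single = arr.ndim == 2
    if single:
        arr = arr[None]
    arr = np.stack([normalize_input(a) for a in arr])
    out = model.net.forward(arr, training=False)[:, 0]
    return out[0] if single else out


def save_model(model: TrainedModel, path: str) -> None:
    """Checkpoint: weights in an .npz plus a JSON sidecar with the spec,
    training history and provenance."""
    import json
    from dataclasses import asdict

    weights = model.net.get_weights()
    flat = {}
    for i, w in enumerate(weights):
        if isinstance(w, tuple):  # batch-norm running stats
            flat[f"bn{i}_mean"], flat[f"bn{i}_var"] = w
        else:
            flat[f"p{i}"] = w
    np.savez(path if path.endswith(".npz") else path + ".npz", **flat)
    side = {"spec": asdict(model.spec), "history": model.history,
            "provenance": {k: v for k, v in model.provenance.items()
                           if isinstance(v, (int, float, str, list, dict))}}
    with open((path[:-4] if path.endswith(".npz") else path) + ".json", "w") as f:
        json.dump(side, f, indent=2, default=str)


def load_model(path: str) -> TrainedModel:
    import json

    base = path[:-4] if path.endswith(".npz") else path
    with open(base + ".json") as f:
        side = json.load(f)
    spec = UNetSpec(**side["spec"])
    model = build_unet(spec)
    with np.load(base + ".npz") as data:
        n_p = len(model.net.params())
        weights = [data[f"p{i}"] for i in range(n_p)]
        i = n_p
        while f"bn{i}_mean" in data:
            weights.append((data[f"bn{i}_mean"], data[f"bn{i}_var"]))
            i += 1
    model.net.set_weights(weights)
    model.history = side.get("history", model.history)
    model.provenance = side.get("provenance", {})
    return model


def pretrain_finetune(model: TrainedModel, sim_dataset, exp_dataset,
                      cfg: TrainConfig, finetune_cfg: TrainConfig | None = None
                      ) -> TrainedModel:
    """Train on the simulated domain, then fine-tune all weights on the
    target domain; both loss histories are kept side by side."""
    model = train(model, sim_dataset, cfg)
    pre_hist = {k: list(v) for k, v in model.history.items()}
    model.history = {"train_loss": [], "val_loss": []}
    fcfg = finetune_cfg or cfg
    x_ft, _ = exp_dataset.subset("train") if "train" in exp_dataset.splits else (np.empty(0),) * 2
    if len(x_ft) > 0 and fcfg.lr > 0 and fcfg.max_epochs > 0:
        model = train(model, exp_dataset, fcfg)
    model.provenance["pretrain_history"] = pre_hist
    return model
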