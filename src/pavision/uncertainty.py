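"""Prediction-uncertainty estimation.

Two complementary pixel-wise variability maps are produced:

* **MC dropout** — the trained network is made stochastic by keeping its
  dropout layers active at inference; repeated forward passes with
  different masks sample an approximate predictive distribution whose
  pixel-wise mean is the reported image and whose standard deviation is
  the uncertainty map;
* **acquisition noise** — repeated noisy acquisitions of the same object
  are each beamformed and predicted deterministically; the spread across
  acquisitions isolates the sensitivity of the pipeline to RF noise.

The calibration report quantifies the co-location of uncertainty and
actual error: the Spearman rank correlation between the std map and the
absolute-error map over foreground pixels, and the ratio of the mean std
inside the top error decile to that inside the bottom decile.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats

from .network import TrainedModel, normalize_input, predict

__all__ = ["UncertaintyMaps", "mc_dropout_predict", "noise_variability_map",
           "abs_error_map", "uncertainty_calibration"]


@dataclass
class UncertaintyMaps:
    mean: np.ndarray
    std: np.ndarray
    n_samples: int
    source: str  # "mc_dropout" | "acquisition_noise"

    def __post_init__(self):
        if np.any(self.std < 0):
            raise ValueError("std map must be non-negative")
        if self.mean.shape != self.std.shape:
            raise ValueError("mean and std maps must share a shape")


def mc_dropout_predict(model: TrainedModel, mbf, n: int = 20,
                       seed: int = 0) -> UncertaintyMaps:
    """Pixel-wise mean/std over ``n`` stochastic forward passes.

    Dropout layers stay active (at the model's dropout rate) while batch
    normalization runs in inference mode; each pass draws its mask stream
    from a per-inference seed spawned from ``seed``.
    """
    if n < 2:
        raise ValueError("at least 2 stochastic inferences are required")
    arr = np.asarray(getattr(mbf, "values", mbf), dtype=np.float32)
    x = normalize_input(arr)
    # all inferences run as one batch: each sample draws its own dropout
    # masks from the seeded stream, and a single batched pass keeps the
    # arithmetic bit-reproducible across samples
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    batch = np.broadcast_to(x, (n,) + x.shape)
    samples = _stochastic_forward(model, batch, rng)
    mean, std = _moments(samples)
    return UncertaintyMaps(mean, std, n, "mc_dropout")


def _moments(samples: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pixel-wise mean/std via deviations from the first sample.

    The shifted computation is numerically stabler and, crucially, yields
    an exactly zero std when all samples are bit-identical.
    """
    d = (samples - samples[0:1]).astype(np.float64)
    dm = d.mean(axis=0)
    std = np.sqrt(((d - dm) ** 2).mean(axis=0))
    return samples[0] + dm, std


def _stochastic_forward(model: TrainedModel, x: np.ndarray, rng) -> np.ndarray:
    """Forward pass with live dropout but frozen batch-norm statistics."""
    net = model.net
    h = np.ascontiguousarray(np.asarray(x, dtype=np.float32)[..., None])
    skips = []
    for enc, pool in zip(net.enc, net.pools):
        h = _block_stochastic(enc, h, rng)
        skips.append(h)
        h = pool.forward(h, training=False)
    h = _block_stochastic(net.bottleneck, h, rng)
    for up, dec, skip in zip(net.ups, net.dec, reversed(skips)):
        h = up.forward(h, training=False)
        h = np.concatenate([skip, h], axis=-1)
        h = _block_stochastic(dec, h, rng)
    return net.head.forward(h, training=False)[..., 0]


def _block_stochastic(block, h, rng):
    for lay in block.layers:
        h = lay.forward(h, training=False)  # BN uses running stats
    return block.drop.forward(h, training=True, rng=rng)


def noise_variability_map(model: TrainedModel, rf_acquisitions, grid,
                          probe) -> UncertaintyMaps:
    """Variability across repeated acquisitions, network deterministic."""
    from .beamform import das_mbf

    rfs = list(rf_acquisitions)
    if len(rfs) < 2:
        raise ValueError("need at least 2 acquisitions")
    mbfs = np.stack([das_mbf(rf, grid, probe).values for rf in rfs])
    # one batched deterministic pass: identical acquisitions then yield
    # bit-identical predictions and an exactly zero std map
    preds = predict(model, mbfs)
    mean, std = _moments(preds)
    return UncertaintyMaps(mean, std, len(rfs), "acquisition_noise")


def abs_error_map(pred_mean: np.ndarray, truth: np.ndarray) -> np.ndarray:
    """|truth - prediction| after max-normalizing both images."""
    p = np.asarray(getattr(pred_mean, "values", pred_mean), dtype=float)
    t = np.asarray(getattr(truth, "values", truth), dtype=float)
    if p.shape != t.shape:
        raise ValueError("prediction and truth must share a grid")
    pm, tm = np.max(np.abs(p)), np.max(np.abs(t))
    if pm > 0:
        p = p / pm
    if tm > 0:
        t = t / tm
    return np.abs(t - p)


def uncertainty_calibration(std_map: np.ndarray, error_map: np.ndarray,
                            truth: np.ndarray | None = None,
                            pred: np.ndarray | None = None,
                            fg_threshold: float = 0.1) -> dict:
    """Do high-uncertainty pixels coincide with high-error pixels?

    Statistics are computed over a foreground mask (union of truth and
    prediction supports, dilated by 2 px) when ``truth``/``pred`` are
    given, else over all pixels; background clutter would otherwise
    dominate the rank statistics.  Returns the Spearman correlation
    between std and error and the top/bottom error-decile mean-std ratio.
    """
    s = np.asarray(std_map, dtype=float)
    e = np.asarray(error_map, dtype=float)
    if s.shape != e.shape:
        raise ValueError("maps must share a shape")
    if truth is not None or pred is not None:
        mask = np.zeros(s.shape, dtype=bool)
        for img in (truth, pred):
            if img is not None:
                a = np.asarray(getattr(img, "values", img), dtype=float)
                m = np.max(np.abs(a))
                if m > 0:
                    mask |= np.abs(a) / m > fg_threshold
        mask = ndimage.binary_dilation(mask, iterations=2)
    else:
        mask = np.ones(s.shape, dtype=bool)
    sv, ev = s[mask], e[mask]
    report = {"n_pixels": int(mask.sum())}
    if np.ptp(sv) == 0 or np.ptp(ev) == 0:
        report["spearman"] = None
        report["note"] = "constant map: correlation undefined"
    else:
        report["spearman"] = float(stats.spearmanr(sv, ev).statistic)
    lo, hi = np.quantile(ev, [0.1, 0.9])
    top, bot = sv[ev >= hi], sv[ev <= lo]
    mb = float(bot.mean()) if bot.size else np.nan
    mt = float(top.mean()) if top.size else np.nan
    report["decile_ratio"] = float(mt / mb) if mb > 0 else np.inf
    report["mean_std_top_decile"] = mt
    report["mean_std_bottom_decile"] = mb
    return report
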