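"""Desk-scale orchestration of the study's comparative experiments.

Two experiments are driven from here:

* the **learning curve**: reconstruction quality (mean test sSSIM) as a
  function of the target-domain training-set size, for a model trained
  from scratch versus one pretrained on a simulated-domain dataset and
  fine-tuned — the transfer-learning comparison;
* the **input comparison**: twin models trained under identical seeds and
  budgets on mBF versus dmBF inputs.

The simulated-vs-target domain shift is controlled: the target domain
perturbs the transducer model (+10% bandwidth, +5% central frequency),
adds RF noise at the hardware-like amplitude SNR of 60, and simulates
propagation at 1480 m/s while the beamformer still assumes 1500 m/s.
This emulates the model/ground-truth mismatch between simulation and
acquisition without requiring acquired data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np

from .forward import NoiseConfig, ProbeConfig
from .metrics import evaluate_set
from .network import PRESETS, TrainConfig, build_unet, predict, train
from .phantoms import PhantomConfig, build_dataset

__all__ = ["LearningCurveConfig", "target_domain_probe", "run_learning_curve",
           "run_simulation_benchmark", "compare_inputs"]


def target_domain_probe(base: ProbeConfig) -> ProbeConfig:
    """Perturbed transducer standing in for the physical system."""
    return replace(base,
                   f_c_MHz=base.f_c_MHz * 1.05,
                   fractional_bandwidth=base.fractional_bandwidth * 1.1,
                   c_m_per_s=1480.0)


@dataclass
class LearningCurveConfig:
    set_sizes: tuple = (10, 25, 50, 100, 200)
    n_repeats: int = 5
    pretrain: bool = True
    pretrain_pairs: int = 300
    n_test: int = 15
    val_fraction: float = 0.2
    preset: str = "tiny"
    train_cfg: TrainConfig = field(default_factory=lambda: TrainConfig(
        lr=2e-3, max_epochs=12, early_stopping_patience=12))
    seed: int = 0

    def __post_init__(self):
        sizes = tuple(self.set_sizes)
        if list(sizes) != sorted(sizes) or min(sizes) < 1:
            raise ValueError("set sizes must be positive and sorted")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")


def _train_eval(spec, ds_pool, subset_idx, x_test, y_test, cfg: TrainConfig,
                init_weights=None, seed=0):
    """Train on a subset of the pool (with a val tail) and score the test set."""
    from .phantoms import PairedDataset

    n_val = max(int(len(subset_idx) * 0.2), 1)
    tr, va = subset_idx[:-n_val], subset_idx[-n_val:]
    ds = PairedDataset(ds_pool.inputs, ds_pool.targets,
                       {"train": tr, "val": va}, ds_pool.pixel_pitch_um,
                       ds_pool.pair_seeds, ds_pool.probe_hash)
    model = build_unet(spec, seed=seed)
    if init_weights is not None:
        model.net.set_weights(init_weights)
    model = train(model, ds, cfg)
    preds = predict(model, x_test)
    rep = evaluate_set(list(zip(preds, y_test)))
    return rep, model


def run_learning_curve(cfg: LearningCurveConfig, phantom_cfg: PhantomConfig,
                       probe: ProbeConfig, out_csv: str | None = None,
                       plot_path: str | None = None, verbose: bool = False):
    """Mean test sSSIM per training-set size, scratch vs pretrained arms.

    Each repeat draws a disjoint random subset of a fixed target-domain
    pool for training/validation; the test set is common to all runs.
    Returns a list of row dicts (size, arm, repeat, sssim, ncc) plus the
    per-(size, arm) means.
    """
    spec = PRESETS[cfg.preset]
    rng = np.random.default_rng(cfg.seed)
    target_probe = target_domain_probe(probe)
    pool_size = max(cfg.set_sizes) + max(int(max(cfg.set_sizes) * 0.25), 2)
    pool = build_dataset(pool_size + cfg.n_test, phantom_cfg, target_probe,
                         noise=NoiseConfig(60.0, seed=cfg.seed),
                         seed=cfg.seed, recon_probe=probe,
                         splits={"train": pool_size, "test": cfg.n_test})
    x_test, y_test = pool.subset("test")
    pool_idx = pool.splits["train"]

    pre_weights = None
    if cfg.pretrain:
        sim = build_dataset(cfg.pretrain_pairs, phantom_cfg, probe,
                            noise=None, seed=cfg.seed + 1,
                            splits={"train": int(cfg.pretrain_pairs * 0.85),
                                    "val": cfg.pretrain_pairs -
                                    int(cfg.pretrain_pairs * 0.85)})
        pre_model = build_unet(spec, seed=cfg.seed)
        pre_model = train(pre_model, sim, cfg.train_cfg)
        pre_weights = pre_model.net.get_weights()

    rows = []
    arms = ["scratch"] + (["pretrained"] if cfg.pretrain else [])
    for size in cfg.set_sizes:
        for rep_i in range(cfg.n_repeats):
            subset = rng.choice(pool_idx, size=size, replace=False)
            for arm in arms:
                report, _ = _train_eval(
                    spec, pool, subset, x_test, y_test, cfg.train_cfg,
                    init_weights=pre_weights if arm == "pretrained" else None,
                    seed=cfg.seed + 13 * rep_i)
                rows.append({"size": int(size), "arm": arm, "repeat": rep_i,
                             "sssim": report.mean_sssim, "ncc": report.mean_ncc})
                if verbose:
                    print(rows[-1])

    means = {}
    for arm in arms:
        means[arm] = {s: float(np.mean([r["sssim"] for r in rows
                                        if r["arm"] == arm and r["size"] == s]))
                      for s in cfg.set_sizes}
    if out_csv:
        import csv

        with open(out_csv, "w", newline="") as f:
            w = csv.DictWriter(f, fieldnames=["size", "arm", "repeat", "sssim", "ncc"])
            w.writeheader()
            w.writerows(rows)
    if plot_path:
        _plot_curve(means, plot_path)
    return rows, means


def _plot_curve(means: dict, path: str) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.5))
    colors = {"scratch": "tab:red", "pretrained": "tab:blue"}
    for arm, vals in means.items():
        ax.plot(list(vals), list(vals.values()), "o-", color=colors.get(arm),
                label=arm)
    ax.set_xlabel("target-domain training pairs")
    ax.set_ylabel("mean test sSSIM")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def run_simulation_benchmark(phantom_cfg: PhantomConfig, probe: ProbeConfig,
                             n_train: int = 150, n_val: int = 15, n_test: int = 15,
                             preset: str = "reduced", snr: float = 60.0,
                             train_cfg: TrainConfig | None = None, seed: int = 0):
    """End-to-end simulation study: DAS (dmBF) versus the trained network.

    Builds a seeded paired dataset (with the envelope images of the same
    acquisitions kept as the conventional baseline), trains the U-Net on
    the mBF inputs, and evaluates both reconstructions against the ground
    truth on the held-out test pairs.  Returns a dict with the trained
    model, the dataset, and the two metric reports.
    """
    cfg = train_cfg or TrainConfig(lr=2e-3, max_epochs=40,
                                   early_stopping_patience=10, seed=seed)
    ds = build_dataset(n_train + n_val + n_test, phantom_cfg, probe,
                       noise=NoiseConfig(snr, seed=seed), seed=seed,
                       splits={"train": n_train, "val": n_val, "test": n_test},
                       keep_dmbf=True)
    model = build_unet(PRESETS[preset], seed=seed)
    model = train(model, ds, cfg)
    x_te, y_te = ds.subset("test")
    preds = predict(model, x_te)
    report_net = evaluate_set(list(zip(preds, y_te)))
    report_das = evaluate_set(list(zip(ds.dmbf[ds.splits["test"]], y_te)))
    return {"model": model, "dataset": ds, "network": report_net,
            "das": report_das, "predictions": preds}


def compare_inputs(phantom_cfg: PhantomConfig, probe: ProbeConfig,
                   n_pairs: int = 60, n_test: int = 10, preset: str = "tiny",
                   train_cfg: TrainConfig | None = None, seed: int = 0,
                   out_json: str | None = None) -> dict:
    """Train twin models on mBF vs dmBF inputs and compare test scores.

    Both arms see the same phantoms, the same RF realizations (identical
    per-pair seeds), the same initialization seed and the same training
    budget; only the beamformed representation differs.
    """
    cfg = train_cfg or TrainConfig(lr=2e-3, max_epochs=12,
                                    early_stopping_patience=12)
    n_val = max(int(n_pairs * 0.15), 2)
    splits = {"train": n_pairs - n_val, "val": n_val, "test": n_test}
    report = {}
    for kind in ("mbf", "dmbf"):
        ds = build_dataset(n_pairs + n_test, phantom_cfg, probe, noise=None,
                           seed=seed, splits=splits, input_kind=kind)
        model = build_unet(PRESETS[preset], seed=seed)
        model = train(model, ds, cfg)
        x_te, y_te = ds.subset("test")
        preds = predict(model, x_te)
        rep = evaluate_set(list(zip(preds, y_te)))
        report[kind] = {"mean_ncc": rep.mean_ncc, "std_ncc": rep.std_ncc,
                        "mean_sssim": rep.mean_sssim, "std_sssim": rep.std_sssim}
    report["provenance"] = {"seed": seed, "n_pairs": n_pairs, "n_test": n_test,
                            "preset": preset, "probe_hash": probe.hash()}
    if out_json:
        with open(out_json, "w") as f:
            json.dump(report, f, indent=2)
    return report
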