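"""Synthetic branching-vessel phantoms and paired-dataset assembly.

The generator draws a recursive random binary tree of quadratic Bezier
segments with widths tapering at each branching level.  Such trees emulate
the venation of a leaf skeleton — the class of objects whose conventional
photoacoustic images suffer limited-view artefacts — while giving full
control over orientation statistics: the first primary branch is steered
close to vertical so that every phantom contains structures inside the
blind angular range of a linear array.

Ground-truth maps live on a metric grid (pixel pitch in micrometres,
origin at the center of pixel (0, 0), row-major (z, x) indexing) and are
max-normalized to [0, 1] with an exact-zero background.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

__all__ = [
    "PhantomConfig",
    "AbsorptionMap",
    "generate_branching_phantom",
    "augment",
    "threshold_background",
    "extract_patch",
    "build_dataset",
    "PairedDataset",
    "save_dataset_h5",
    "load_dataset_h5",
]


@dataclass(frozen=True)
class PhantomConfig:
    """Parameters of the branching-tree generator.

    The defaults reproduce the study geometry: absorbers are laid out on a
    1 x 1 cm field, of which a 5.12 x 5.12 mm patch (128 px at 40 um) is
    later imaged, so that structures outside the patch still contribute RF
    signal.
    """

    field_size_mm: float = 10.0
    patch_size_mm: float = 5.12
    pixel_pitch_um: float = 40.0
    n_primary_branches: int = 3
    branch_depth: int = 4
    vein_width_px_range: tuple[float, float] = (1.0, 3.5)
    angle_jitter_deg: float = 25.0
    seed: int = 0

    def __post_init__(self):
        if self.field_size_mm < self.patch_size_mm:
            raise ValueError("field must be at least as large as the patch")
        if min(self.vein_width_px_range) < 0.5:
            raise ValueError("vein half-widths below 1 px are not resolvable")

    @property
    def n_px(self) -> int:
        return int(round(self.field_size_mm * 1e3 / self.pixel_pitch_um))


@dataclass
class AbsorptionMap:
    """Non-negative 2D map of optical absorbers on a metric grid."""

    values: np.ndarray
    pixel_pitch_um: float
    origin_mm: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("absorption map must be 2D")
        if np.any(self.values < 0):
            raise ValueError("absorption values must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def max_normalized(self) -> "AbsorptionMap":
        m = self.values.max()
        vals = self.values / m if m > 0 else self.values.copy()
        return AbsorptionMap(vals, self.pixel_pitch_um, self.origin_mm)


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _stamp_curve(canvas: np.ndarray, p0, p1, p2, w0: float, w1: float) -> None:
    """Rasterize one quadratic Bezier with linearly tapering half-width.

    Anti-aliased by stamping soft discs (plateau 1, linear 1-px falloff) at
    sub-pixel sample spacing, combined with a running maximum.
    """
    n_px = canvas.shape[0]
    chord = np.linalg.norm(p2 - p0) + np.linalg.norm(p1 - p0)
    n_s = max(int(chord * 3), 4)
    t = np.linspace(0.0, 1.0, n_s)[:, None]
    pts = (1 - t) ** 2 * p0 + 2 * t * (1 - t) * p1 + t ** 2 * p2
    widths = w0 + (w1 - w0) * t[:, 0]
    for (cz, cx), w in zip(pts, widths):
        r = int(np.ceil(w + 1.0))
        z0, z1 = int(np.floor(cz)) - r, int(np.floor(cz)) + r + 1
        x0, x1 = int(np.floor(cx)) - r, int(np.floor(cx)) + r + 1
        if z1 <= 0 or x1 <= 0 or z0 >= n_px or x0 >= n_px:
            continue
        zc0, zc1 = max(z0, 0), min(z1, n_px)
        xc0, xc1 = max(x0, 0), min(x1, n_px)
        zz, xx = np.meshgrid(np.arange(zc0, zc1), np.arange(xc0, xc1), indexing="ij")
        d = np.sqrt((zz - cz) ** 2 + (xx - cx) ** 2)
        disc = np.clip(w + 0.5 - d, 0.0, 1.0)
        patch = canvas[zc0:zc1, xc0:xc1]
        np.maximum(patch, disc, out=patch)


def _grow(canvas, rng, cfg: PhantomConfig, start, angle, length, width, level) -> None:
    if level >= cfg.branch_depth or length < 2.0 or width < 0.5:
        return
    end = start + length * np.array([np.cos(angle), np.sin(angle)])  # (z, x)
    perp = np.array([-np.sin(angle), np.cos(angle)])
    mid = (start + end) / 2.0 + perp * rng.normal(0.0, 0.12) * length
    w_end = width * 0.78
    _stamp_curve(canvas, start, mid, end, width, w_end)
    jitter = np.deg2rad(cfg.angle_jitter_deg)
    base_split = np.deg2rad(28.0)
    for sign in (+1.0, -1.0):
        child_angle = angle + sign * base_split + rng.uniform(-jitter, jitter)
        child_len = length * rng.uniform(0.6, 0.75)
        _grow(canvas, rng, cfg, end, child_angle, child_len, w_end, level + 1)


def generate_branching_phantom(config: PhantomConfig) -> AbsorptionMap:
    """Draw a seeded branching-tree absorption map on the full field.

    Deterministic in (config, seed).  The first primary branch is oriented
    within a narrow cone around vertical (depth axis), guaranteeing
    structures that a linear aperture cannot see; remaining primaries are
    uniformly oriented.
    """
    n_px = config.n_px
    if n_px < 16:
        raise ValueError("degenerate grid: field smaller than 16 px")
    canvas = np.zeros((n_px, n_px))
    rng = np.random.default_rng(config.seed)
    w_lo, w_hi = config.vein_width_px_range
    for b in range(config.n_primary_branches):
        margin = 0.18 * n_px
        start = rng.uniform(margin, n_px - margin, size=2)  # (z, x)
        if b == 0:
            # steep primary: within ~8 degrees of the depth axis
            angle = rng.uniform(-np.deg2rad(8.0), np.deg2rad(8.0))
            angle += np.pi if rng.random() < 0.5 else 0.0
        else:
            angle = rng.uniform(0.0, 2.0 * np.pi)
        length = n_px * rng.uniform(0.26, 0.40)
        width = rng.uniform(0.75 * w_hi, w_hi)
        _grow(canvas, rng, config, start, angle, length, max(width, w_lo), 0)
    return AbsorptionMap(np.clip(canvas, 0.0, 1.0), config.pixel_pitch_um)


# ---------------------------------------------------------------------------
# transforms
# ---------------------------------------------------------------------------

def augment(img: AbsorptionMap, spec: tuple) -> AbsorptionMap:
    """Apply one named geometric augmentation on the same grid.

    ``spec`` is ``(name, params)`` with name in {"rotation", "mirror",
    "shear", "center_scale"}:
    rotation(angle_deg), mirror(axis in {"horizontal","vertical"}),
    shear(axis, factor), center_scale(factor).  Output is resampled onto
    the input grid and clipped to [0, 1].
    """
    name, params = spec[0], (spec[1] if len(spec) > 1 else {})
    v = img.values
    if name == "rotation":
        ang = float(params.get("angle_deg", 0.0))
        out = v if ang == 0.0 else ndimage.rotate(v, ang, reshape=False, order=1,
                                                  mode="constant", cval=0.0)
    elif name == "mirror":
        axis = params.get("axis", "horizontal")
        if axis not in ("horizontal", "vertical"):
            raise ValueError(f"unknown mirror axis {axis!r}")
        out = v[:, ::-1] if axis == "horizontal" else v[::-1, :]
    elif name == "shear":
        axis = params.get("axis", "horizontal")
        f = float(params.get("factor", 0.0))
        c = (np.array(v.shape) - 1) / 2.0
        mat = np.eye(2)
        if axis == "horizontal":
            mat[1, 0] = f  # x' depends on z
        elif axis == "vertical":
            mat[0, 1] = f
        else:
            raise ValueError(f"unknown shear axis {axis!r}")
        offset = c - mat @ c
        out = ndimage.affine_transform(v, mat, offset=offset, order=1,
                                       mode="constant", cval=0.0)
    elif name == "center_scale":
        f = float(params.get("factor", 1.0))
        if f <= 0:
            raise ValueError("center_scale factor must be positive")
        c = (np.array(v.shape) - 1) / 2.0
        mat = np.eye(2) / f
        offset = c - mat @ c
        out = ndimage.affine_transform(v, mat, offset=offset, order=1,
                                       mode="constant", cval=0.0)
    else:
        raise ValueError(f"unknown transform {name!r}")
    return AbsorptionMap(np.clip(out, 0.0, 1.0), img.pixel_pitch_um, img.origin_mm)


def threshold_background(img: AbsorptionMap, thr: float) -> AbsorptionMap:
    """Zero out pixels below ``thr``; pixels at or above it are unchanged."""
    if thr < 0:
        raise ValueError("threshold must be non-negative")
    out = img.values.copy()
    out[out < thr] = 0.0
    return AbsorptionMap(out, img.pixel_pitch_um, img.origin_mm)


def extract_patch(img: AbsorptionMap, center_mm: tuple[float, float],
                  size_mm: float) -> AbsorptionMap:
    """Cut a square metric patch; pixel pitch preserved, origin updated."""
    p = img.pixel_pitch_um * 1e-3
    n = int(round(size_mm * 1e3 / img.pixel_pitch_um))
    cx = (center_mm[0] - img.origin_mm[0]) / p
    cz = (center_mm[1] - img.origin_mm[1]) / p
    x0 = int(round(cx - (n - 1) / 2.0))
    z0 = int(round(cz - (n - 1) / 2.0))
    nz, nx = img.values.shape
    if x0 < 0 or z0 < 0 or x0 + n > nx or z0 + n > nz:
        raise ValueError("requested patch extends outside the field")
    vals = img.values[z0:z0 + n, x0:x0 + n].copy()
    origin = (img.origin_mm[0] + x0 * p, img.origin_mm[1] + z0 * p)
    return AbsorptionMap(vals, img.pixel_pitch_um, origin)


# ---------------------------------------------------------------------------
# dataset assembly
# ---------------------------------------------------------------------------

@dataclass
class PairedDataset:
    """In-memory paired dataset: network inputs and ground-truth targets.

    ``inputs``/``targets`` are (N, H, W) float32; inputs are mBF images
    normalized by their maximum absolute value, targets are [0, 1]
    absorption patches.  ``splits`` maps split name to index array.
    """

    inputs: np.ndarray
    targets: np.ndarray
    splits: dict
    pixel_pitch_um: float
    pair_seeds: np.ndarray
    probe_hash: str = ""
    dmbf: np.ndarray | None = None  # envelope images of the same acquisitions

    def subset(self, split: str) -> tuple[np.ndarray, np.ndarray]:
        idx = self.splits[split]
        return self.inputs[idx], self.targets[idx]


def build_dataset(n_pairs: int, config: PhantomConfig, probe, noise=None,
                  seed: int = 0, splits: dict | None = None,
                  standoff_mm: float = 2.0, background_thr: float = 0.05,
                  out_path: str | None = None, recon_probe=None,
                  input_kind: str = "mbf", keep_dmbf: bool = False,
                  min_patch_foreground: float = 0.02) -> PairedDataset:
    """Generate ``n_pairs`` (mBF input, ground-truth patch) pairs.

    Per pair: draw a phantom on the full field placed ``standoff_mm`` below
    the probe face and laterally centered, simulate limited-view RF from
    the whole field, beamform the mBF image on the central patch grid, and
    crop the matching ground-truth patch.  Waves from absorbers outside the
    patch therefore still pollute the reconstruction, as in acquisition.

    ``splits`` maps names to sizes, e.g. {"train": 500, "val": 93,
    "test": 15}; sizes must sum to ``n_pairs``.  Defaults to a single
    "train" split.  If ``out_path`` is given the dataset is also written to
    HDF5.  ``recon_probe`` lets the beamformer assume a (possibly wrong)
    probe model different from the one that produced the RF — e.g. a
    speed-of-sound mismatch — which is how a controlled simulation-vs-
    experiment domain shift is created.
    """
    from .beamform import ReconGrid, das_dmbf, das_mbf
    from .forward import NoiseConfig, calibration_amplitude, simulate_rf

    if input_kind not in ("mbf", "dmbf"):
        raise ValueError("input_kind must be 'mbf' or 'dmbf'")
    beamformer = das_mbf if input_kind == "mbf" else das_dmbf
    if splits is None:
        splits = {"train": n_pairs}
    if sum(splits.values()) != n_pairs:
        raise ValueError("split sizes must sum to n_pairs")

    seeds = np.random.SeedSequence(seed).generate_state(n_pairs)
    n_patch = int(round(config.patch_size_mm * 1e3 / config.pixel_pitch_um))
    # lateral origin so the field is centered on the array axis
    p_mm = config.pixel_pitch_um * 1e-3
    origin = (-(config.n_px - 1) / 2.0 * p_mm, standoff_mm)
    center = (0.0, standoff_mm + (config.n_px - 1) / 2.0 * p_mm)
    grid = ReconGrid.for_patch(center, config.patch_size_mm, config.pixel_pitch_um)

    cal = calibration_amplitude(probe) if noise is not None else None
    inputs = np.empty((n_pairs, n_patch, n_patch), dtype=np.float32)
    targets = np.empty((n_pairs, n_patch, n_patch), dtype=np.float32)
    dmbf_stack = np.empty_like(inputs) if keep_dmbf else None
    bf_probe = recon_probe if recon_probe is not None else probe
    for i, s in enumerate(seeds):
        # redraw until the imaged patch actually contains structure, as an
        # acquisition protocol would; attempt seeds derive from the pair seed
        for attempt in range(32):
            cfg_i = replace(config, seed=(int(s) + attempt * 0x9E3779B9) % 2 ** 31)
            amap = generate_branching_phantom(cfg_i)
            amap = threshold_background(amap.max_normalized(), background_thr)
            amap = AbsorptionMap(amap.values, amap.pixel_pitch_um, origin)
            patch_fg = (extract_patch(amap, center, config.patch_size_mm).values
                        > 0).mean()
            if patch_fg >= min_patch_foreground:
                break
        noise_i = None
        if noise is not None:
            noise_i = NoiseConfig(noise.target_snr, seed=int(s) ^ 0x5EED)
        rf = simulate_rf(amap, probe, noise=noise_i, calibration=cal)
        mbf = beamformer(rf, grid, bf_probe)
        inputs[i] = mbf.normalized().astype(np.float32)
        targets[i] = extract_patch(amap, center, config.patch_size_mm).values.astype(np.float32)
        if keep_dmbf:
            dmbf_stack[i] = das_dmbf(rf, grid, bf_probe).normalized().astype(np.float32)

    rng = np.random.default_rng(seeds[0])
    order = rng.permutation(n_pairs)
    split_idx, k = {}, 0
    for name, size in splits.items():
        split_idx[name] = np.sort(order[k:k + size])
        k += size
    ds = PairedDataset(inputs, targets, split_idx, config.pixel_pitch_um,
                       seeds, probe.hash(), dmbf=dmbf_stack)
    if out_path is not None:
        save_dataset_h5(ds, out_path)
    return ds


def save_dataset_h5(ds: PairedDataset, path: str) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.attrs["pixel_pitch_um"] = ds.pixel_pitch_um
        f.attrs["probe_hash"] = ds.probe_hash
        f.attrs["pair_seeds"] = ds.pair_seeds
        for name, idx in ds.splits.items():
            g = f.create_group(name)
            g.create_dataset("input", data=ds.inputs[idx])
            g.create_dataset("target", data=ds.targets[idx])


def load_dataset_h5(path: str) -> PairedDataset:
    import h5py

    with h5py.File(path, "r") as f:
        inputs, targets, splits = [], [], {}
        k = 0
        for name in f:
            x = f[name]["input"][...]
            y = f[name]["target"][...]
            splits[name] = np.arange(k, k + len(x))
            inputs.append(x)
            targets.append(y)
            k += len(x)
        return PairedDataset(np.concatenate(inputs), np.concatenate(targets),
                             splits, float(f.attrs["pixel_pitch_um"]),
                             np.asarray(f.attrs["pair_seeds"]),
                             str(f.attrs["probe_hash"]))
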