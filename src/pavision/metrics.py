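"""Reconstruction quality metrics and test-set aggregation.

Two scores are computed between a reconstruction and its ground truth,
both after max-normalization of each image:

* **NCC** — normalized 2D cross-correlation with local-sum normalization
  (the template-matching normalization), scalarized as the maximum of the
  correlation map inside a small displacement window (+-3 px by default)
  so that sub-pixel registration residue does not penalize the score;
* **sSSIM** — the structural similarity index computed after the best
  least-squares intensity scaling and shift of the prediction, so that a
  reconstruction differing from the truth only by an affine intensity map
  scores 1.

A similarity-transform registration (rotation + translation + isotropic
scale, maximizing the Pearson correlation) is provided for aligning
reference/moving image pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, optimize
from skimage.feature import match_template
from skimage.metrics import structural_similarity
from skimage.registration import phase_cross_correlation

__all__ = ["MetricsReport", "SimilarityTransform", "ncc", "sssim",
           "evaluate_set", "register_similarity"]


@dataclass
class SimilarityTransform:
    rotation_deg: float = 0.0
    translation_px: tuple[float, float] = (0.0, 0.0)  # (dx, dz)
    scale: float = 1.0

    def __post_init__(self):
        if self.scale <= 0:
            raise ValueError("scale must be positive")


@dataclass
class MetricsReport:
    per_pair: list
    mean_ncc: float
    std_ncc: float
    mean_sssim: float
    std_sssim: float
    failures: list

    def to_dict(self) -> dict:
        return {
            "per_pair": [{"ncc": a, "sssim": b} for a, b in self.per_pair],
            "mean_ncc": self.mean_ncc, "std_ncc": self.std_ncc,
            "mean_sssim": self.mean_sssim, "std_sssim": self.std_sssim,
            "failures": self.failures,
        }


def _normalize(img) -> np.ndarray:
    img = np.asarray(getattr(img, "values", img), dtype=float)
    m = np.max(np.abs(img))
    return img / m if m > 0 else img


def ncc(pred, truth, max_shift_px: int = 3) -> float:
    """Local-sum-normalized cross-correlation, max over a +-3 px window.

    With ``max_shift_px=0`` this reduces to the zero-lag Pearson
    correlation.  Raises on constant images, whose correlation is
    undefined.
    """
    p, t = _normalize(pred), _normalize(truth)
    if p.shape != t.shape:
        raise ValueError("images must share a shape")
    if np.ptp(p) == 0 or np.ptp(t) == 0:
        raise ValueError("NCC undefined for a constant image")
    if max_shift_px == 0:
        pc, tc = p - p.mean(), t - t.mean()
        return float(np.sum(pc * tc) / np.sqrt(np.sum(pc ** 2) * np.sum(tc ** 2)))
    # slide the prediction interior over the truth: a pure displacement of
    # up to max_shift_px then scores exactly 1
    k = max_shift_px
    interior = p[k:-k, k:-k]
    if np.ptp(interior) == 0:
        raise ValueError("NCC undefined for a constant image interior")
    corr = match_template(t, interior, pad_input=False)
    return float(np.max(corr))


def sssim(pred, truth, win_size: int = 11) -> float:
    """SSIM after least-squares intensity scaling/shift of the prediction.

    The affine fit (a, b) minimizes ||a*pred + b - truth||^2; the SSIM is
    then computed with a Gaussian 11x11 window and the truth's dynamic
    range, so the score is insensitive to global intensity calibration.
    """
    p, t = _normalize(pred), _normalize(truth)
    if p.shape != t.shape:
        raise ValueError("images must share a shape")
    var = float(np.var(p))
    if var == 0:
        raise ValueError("sSSIM undefined for a zero-variance prediction")
    a = float(np.cov(p.ravel(), t.ravel())[0, 1] / var)
    b = float(t.mean() - a * p.mean())
    fitted = a * p + b
    dr = float(t.max() - t.min())
    return float(structural_similarity(t, fitted, win_size=win_size,
                                       gaussian_weights=True, sigma=1.5,
                                       data_range=dr))


def evaluate_set(pairs) -> MetricsReport:
    """Per-pair NCC/sSSIM plus mean and standard deviation over the set.

    Pairs whose metrics are undefined are recorded in ``failures`` with
    the error message instead of being silently dropped.
    """
    pairs = list(pairs)
    if not pairs:
        raise ValueError("empty evaluation set")
    per_pair, failures = [], []
    for i, (pred, truth) in enumerate(pairs):
        try:
            per_pair.append((ncc(pred, truth), sssim(pred, truth)))
        except ValueError as e:
            failures.append({"index": i, "error": str(e)})
    if per_pair:
        arr = np.asarray(per_pair)
        return MetricsReport(per_pair, float(arr[:, 0].mean()), float(arr[:, 0].std()),
                             float(arr[:, 1].mean()), float(arr[:, 1].std()), failures)
    return MetricsReport([], np.nan, np.nan, np.nan, np.nan, failures)


# ---------------------------------------------------------------------------
# registration
# ---------------------------------------------------------------------------

def _warp(moving: np.ndarray, rot_deg: float, scale: float,
          shift: tuple[float, float]) -> np.ndarray:
    """Rotate about the center, scale about the center, then translate."""
    c = (np.array(moving.shape) - 1) / 2.0
    th = np.deg2rad(rot_deg)
    # inverse map: output coord -> input coord
    rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    mat = rot.T / scale
    offset = c - mat @ (c + np.array([shift[1], shift[0]]))
    return ndimage.affine_transform(moving, mat, offset=offset, order=1,
                                    mode="constant", cval=0.0)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    ac, bc = a - a.mean(), b - b.mean()
    d = np.sqrt(np.sum(ac ** 2) * np.sum(bc ** 2))
    return float(np.sum(ac * bc) / d) if d > 0 else 0.0


def register_similarity(reference, moving, rot_range_deg: float = 12.0,
                        scale_range: tuple[float, float] = (0.9, 1.1)):
    """Recover the similarity transform aligning ``moving`` onto
    ``reference`` by maximizing the Pearson correlation coefficient.

    Coarse grid search over rotation and scale with FFT translation
    estimation at each node, followed by Nelder-Mead refinement of all
    four parameters.  Returns ``(transform, registered_image,
    correlation)``; if refinement fails the best grid point is returned.
    """
    ref = _normalize(reference)
    mov = _normalize(moving)
    best = (-np.inf, 0.0, 1.0, (0.0, 0.0))
    for rot in np.arange(-rot_range_deg, rot_range_deg + 1e-9, 1.5):
        for sc in np.arange(scale_range[0], scale_range[1] + 1e-9, 0.025):
            w = _warp(mov, rot, sc, (0.0, 0.0))
            if np.ptp(w) == 0:
                continue
            dz_dx, _, _ = phase_cross_correlation(ref, w, upsample_factor=8,
                                                  normalization=None)
            shift = (float(dz_dx[1]), float(dz_dx[0]))
            score = _pearson(ref, _warp(mov, rot, sc, shift))
            if score > best[0]:
                best = (score, rot, sc, shift)

    def negcorr(p):
        rot, sc, dx, dz = p
        if sc <= 0.5 or sc >= 2.0:
            return 1.0
        return -_pearson(ref, _warp(mov, rot, sc, (dx, dz)))

    x0 = [best[1], best[2], best[3][0], best[3][1]]
    res = optimize.minimize(negcorr, x0, method="Nelder-Mead",
                            options={"xatol": 1e-3, "fatol": 1e-7, "maxiter": 400})
    if res.success and -res.fun >= best[0]:
        rot, sc, dx, dz = res.x
        corr = -res.fun
    else:
        (corr, rot, sc, (dx, dz)) = best
    tf = SimilarityTransform(float(rot), (float(dx), float(dz)), float(sc))
    return tf, _warp(mov, tf.rotation_deg, tf.scale, tf.translation_px), float(corr)
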