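"""Image-quality metrics and cross-method statistics.

PSNR and SSIM follow their standard definitions (SSIM via the Gaussian-
weighted 11x11 window formulation); runs are summarized as mean +/- sample
standard deviation, and methods are compared with the Friedman rank test
(rank k = best within each image, average ranks on ties).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats
from skimage.metrics import structural_similarity

from .image import GrayImage

__all__ = [
    "PSNR_CAP_DB",
    "psnr",
    "ssim",
    "aggregate_runs",
    "friedman_test",
    "FriedmanResult",
    "EvalReport",
    "evaluate_pairs",
]

PSNR_CAP_DB = 100.0  # reported for a zero-MSE (identical) pair
_SSIM_WIN = 11


def _check_pair(reference: GrayImage, test: GrayImage) -> None:
    if reference.pixels.shape != test.pixels.shape:
        raise ValueError(
            f"shape mismatch: reference {reference.pixels.shape} vs test {test.pixels.shape}"
        )
    if reference.scale != test.scale:
        raise ValueError(
            f"scale mismatch: reference {reference.scale.value} vs test {test.scale.value}"
        )


def psnr(reference: GrayImage, test: GrayImage) -> float:
    """Peak signal-to-noise ratio in dB; identical images report the 100 dB cap."""
    _check_pair(reference, test)
    mse = float(np.mean(np.square(reference.pixels - test.pixels)))
    if mse == 0.0:
        return PSNR_CAP_DB
    return min(float(10.0 * np.log10(reference.vmax**2 / mse)), PSNR_CAP_DB)


def ssim(reference: GrayImage, test: GrayImage) -> float:
    """Mean structural similarity (Gaussian-weighted 11x11 window, sigma 1.5)."""
    _check_pair(reference, test)
    h, w = reference.pixels.shape
    if min(h, w) < _SSIM_WIN:
        raise ValueError(f"SSIM needs images of at least {_SSIM_WIN}px per side, got {h}x{w}")
    return float(
        structural_similarity(
            reference.pixels,
            test.pixels,
            data_range=reference.vmax,
            gaussian_weights=True,
            sigma=1.5,
            use_sample_covariance=False,
            win_size=_SSIM_WIN,
        )
    )


def aggregate_runs(values) -> dict:
    """Mean and n-1 sample standard deviation across repeated runs.

    A single run has no dispersion estimate; its ``std`` is reported as None.
    """
    arr = np.asarray(list(values), dtype=np.float64)
    if arr.ndim != 1 or arr.size == 0:
        raise ValueError("aggregate_runs expects a nonempty 1-D sequence")
    return {
        "mean": float(arr.mean()),
        "std": float(arr.std(ddof=1)) if arr.size > 1 else None,
        "n": int(arr.size),
    }


@dataclass(frozen=True)
class FriedmanResult:
    statistic: float
    p_value: float
    mean_ranks: tuple[float, ...]
    n_blocks: int
    n_methods: int


def friedman_test(scores, higher_is_better: bool = True) -> FriedmanResult:
    """Friedman rank test over a ``(n_images, k_methods)`` score table.

    Within each image the best method receives rank k — a higher mean rank
    means better performance (ties share average ranks), and the per-method
    mean ranks always sum to k(k+1)/2.  The
    chi-square statistic and p-value use the tie-corrected form.  A table in
    which every image ties all methods carries no ranking information and is
    reported as statistic 0, p = 1.
    """
    table = np.asarray(scores, dtype=np.float64)
    if table.ndim != 2 or table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("friedman_test needs a 2-D table with >= 2 images and >= 2 methods")
    n, k = table.shape
    keyed = table if higher_is_better else -table
    ranks = np.apply_along_axis(stats.rankdata, 1, keyed)  # average ranks on ties
    mean_ranks = tuple(float(r) for r in ranks.mean(axis=0))
    if np.all(table == table[:, :1]):
        return FriedmanResult(0.0, 1.0, mean_ranks, n, k)
    if k >= 3:
        statistic, p_value = stats.friedmanchisquare(*(table[:, j] for j in range(k)))
    else:
        # scipy requires >= 3 methods; for k = 2 use the same tie-corrected
        # chi-square formula directly (df = k - 1)
        col_sums = ranks.sum(axis=0)
        ties = 0.0
        for row in keyed:
            _, counts = np.unique(row, return_counts=True)
            ties += float(np.sum(counts**3 - counts))
        correction = 1.0 - ties / (n * (k**3 - k))
        raw = 12.0 / (n * k * (k + 1)) * float(np.sum(col_sums**2)) - 3.0 * n * (k + 1)
        statistic = raw / correction
        p_value = stats.chi2.sf(statistic, df=k - 1)
    return FriedmanResult(float(statistic), float(p_value), mean_ranks, n, k)


@dataclass
class EvalReport:
    """Per-method metric summaries plus optional cross-method statistics."""

    methods: dict = field(default_factory=dict)  # name -> {"psnr": {...}, "ssim": {...}}
    friedman: dict = field(default_factory=dict)  # metric name -> FriedmanResult fields

    def add_method(self, name: str, psnr_values, ssim_values) -> None:
        self.methods[name] = {
            "psnr": aggregate_runs(psnr_values),
            "ssim": aggregate_runs(ssim_values),
        }

    def add_friedman(self, metric: str, result: FriedmanResult) -> None:
        self.friedman[metric] = {
            "statistic": result.statistic,
            "p_value": result.p_value,
            "mean_ranks": list(result.mean_ranks),
            "n_blocks": result.n_blocks,
            "n_methods": result.n_methods,
        }

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps({"methods": self.methods, "friedman": self.friedman}, indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def evaluate_pairs(references: list[GrayImage], tests: list[GrayImage]) -> dict:
    """Per-image PSNR/SSIM lists for index-aligned (reference, test) image lists."""
    if len(references) != len(tests) or not references:
        raise ValueError("evaluate_pairs needs two nonempty index-aligned lists")
    return {
        "psnr": [psnr(r, t) for r, t in zip(references, tests)],
        "ssim": [ssim(r, t) for r, t in zip(references, tests)],
    }
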