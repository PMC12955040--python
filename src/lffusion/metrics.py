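"""PSNR / SSIM metrics and the evaluation harness.

Conventions (the literature rarely states them, so they are fixed and
recorded in every report): PSNR uses the per-sample ground-truth maximum as
the data range; SSIM is computed per z-slice with a 7x7 Gaussian window
(K1=0.01, K2=0.03) and averaged over depth.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from time import perf_counter

import numpy as np
from skimage.metrics import structural_similarity

from .optics import InvalidConfigError

__all__ = ["MetricReport", "psnr", "ssim", "evaluate_volumes", "evaluate_suite"]


@dataclass
class MetricReport:
    """Per-sample metrics and their aggregates for one method/configuration."""

    method: str
    sample_ids: list[str] = field(default_factory=list)
    psnr_db: list[float] = field(default_factory=list)
    ssim: list[float] = field(default_factory=list)
    runtime_s: list[float] = field(default_factory=list)
    errors: list[str] = field(default_factory=list)
    conventions: dict = field(
        default_factory=lambda: {
            "psnr_data_range": "per-sample ground-truth max",
            "ssim_window": "7x7 Gaussian per z-slice, averaged over depth",
        }
    )

    @property
    def mean_psnr(self) -> float:
        finite = [v for v in self.psnr_db if math.isfinite(v)]
        return float(np.mean(finite)) if finite else float("nan")

    @property
    def mean_ssim(self) -> float:
        return float(np.mean(self.ssim)) if self.ssim else float("nan")

    def write_csv(self, path: str | Path):
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["sample_id", "psnr_db", "ssim", "runtime_s"])
            for sid, p, s, t in zip(
                self.sample_ids, self.psnr_db, self.ssim, self.runtime_s
            ):
                writer.writerow([sid, p, s, t])
            writer.writerow(["mean", self.mean_psnr, self.mean_ssim, ""])


def psnr(x: np.ndarray, ref: np.ndarray, data_range: float) -> float:
    """10 log10(data_range^2 / MSE); +inf for identical inputs."""
    x = np.asarray(x, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if x.shape != ref.shape:
        raise InvalidConfigError(f"shape mismatch: {x.shape} vs {ref.shape}")
    if data_range <= 0:
        raise InvalidConfigError("data_range must be positive")
    mse = float(np.mean((x - ref) ** 2))
    if mse == 0.0:
        return float("inf")
    return float(10.0 * np.log10(data_range**2 / mse))


def ssim(x: np.ndarray, ref: np.ndarray, data_range: float | None = None) -> float:
    """Structural similarity, per z-slice with a 7x7 Gaussian window,
    averaged over depth.  Symmetric in its arguments; 1 iff identical."""
    x = np.asarray(x, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if x.shape != ref.shape:
        raise InvalidConfigError(f"shape mismatch: {x.shape} vs {ref.shape}")
    if x.ndim == 2:
        x = x[None]
        ref = ref[None]
    if data_range is None:
        lo = min(x.min(), ref.min())
        hi = max(x.max(), ref.max())
        data_range = float(hi - lo) or 1.0
    vals = [
        structural_similarity(
            x[k],
            ref[k],
            win_size=7,
            gaussian_weights=True,
            sigma=1.0,
            use_sample_covariance=False,
            K1=0.01,
            K2=0.03,
            data_range=data_range,
        )
        for k in range(x.shape[0])
    ]
    return float(np.mean(vals))


def evaluate_volumes(
    method: str,
    pairs: list[tuple[str, np.ndarray, np.ndarray]],
) -> MetricReport:
    """Score (sample_id, estimate, ground_truth) triples."""
    report = MetricReport(method=method)
    for sid, est, gt in pairs:
        t0 = perf_counter()
        dr = float(np.max(gt)) or 1.0
        report.sample_ids.append(sid)
        report.psnr_db.append(psnr(est, gt, dr))
        report.ssim.append(ssim(est, gt, data_range=dr))
        report.runtime_s.append(perf_counter() - t0)
    return report


def evaluate_suite(
    reconstruct,
    test_set,
    method: str = "model",
    out_csv: str | Path | None = None,
) -> MetricReport:
    """Run ``reconstruct(sample) -> volume`` over a test set and score it.

    Per-sample failures are recorded and the sample skipped; if every sample
    fails, an error is raised.
    """
    if not test_set:
        raise InvalidConfigError("test set is empty")
    report = MetricReport(method=method)
    for sample in test_set:
        t0 = perf_counter()
        try:
            est = np.asarray(reconstruct(sample))
            gt = sample.ground_truth.data
            if est.shape != gt.shape:
                raise InvalidConfigError(
                    f"estimate shape {est.shape} does not match gt {gt.shape}"
                )
        except Exception as exc:  # noqa: BLE001 - recorded per sample
            report.errors.append(f"{sample.sample_id}: {exc}")
            continue
        dr = float(np.max(gt)) or 1.0
        report.sample_ids.append(sample.sample_id)
        report.psnr_db.append(psnr(est, gt, dr))
        report.ssim.append(ssim(est, gt, data_range=dr))
        report.runtime_s.append(perf_counter() - t0)
    if not report.sample_ids:
        raise RuntimeError(
            "evaluation failed for every sample: " + "; ".join(report.errors)
        )
    if out_csv is not None:
        report.write_csv(out_csv)
    return report
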