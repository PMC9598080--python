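"""Image fidelity metrics: Pearson correlation, normalized l1, SSIM, pSNR.

Both images are scaled by the 99th percentile of the reference before
any metric is computed, which makes all four metrics invariant under a
joint positive rescaling.  The pSNR peak is 1 after scaling, and
identical images are capped at 99 dB.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.metrics import structural_similarity

__all__ = ["MetricsRecord", "evaluate_pair", "PSNR_CAP_DB"]

PSNR_CAP_DB = 99.0


@dataclass
class MetricsRecord:
    corr: float
    l1: float
    ssim: float
    psnr: float
    n_pixels: int
    normalization: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "corr": self.corr,
            "l1": self.l1,
            "ssim": self.ssim,
            "psnr": self.psnr,
            "n_pixels": self.n_pixels,
            "normalization": self.normalization,
        }


def evaluate_pair(
    pred: np.ndarray, ref: np.ndarray, mask: np.ndarray | None = None
) -> MetricsRecord:
    """Evaluate a predicted image against a reference.

    Scaling: both images divided by the 99th percentile of ``ref``.
    corr is the Pearson coefficient over all (or masked) pixels; l1 the
    mean absolute difference after scaling; SSIM uses a Gaussian window
    (sigma 1.5, K1=0.01, K2=0.03, data range 1); pSNR = 20 log10(1/rmse),
    capped at 99 dB for identical inputs.  ``mask`` restricts corr and
    l1 and the rmse to the masked pixels; SSIM is always computed on the
    full grid (it is window-based) unless a mask is given, in which case
    the local SSIM map is averaged over the mask.
    """
    pred = np.asarray(pred, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if pred.shape != ref.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs ref {ref.shape}")
    scale = float(np.percentile(ref, 99))
    if scale <= 0:
        raise ValueError("reference image has non-positive 99th percentile; cannot scale")
    p = pred / scale
    r = ref / scale

    if mask is None:
        pv, rv = p.ravel(), r.ravel()
    else:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != ref.shape:
            raise ValueError("mask shape mismatch")
        pv, rv = p[mask], r[mask]

    if np.std(rv) == 0 or np.std(pv) == 0:
        corr = 1.0 if np.array_equal(pv, rv) else 0.0
    else:
        corr = float(np.corrcoef(pv, rv)[0, 1])
    l1 = float(np.mean(np.abs(pv - rv)))

    _, ssim_map = structural_similarity(
        r, p, data_range=1.0, gaussian_weights=True, sigma=1.5,
        use_sample_covariance=False, K1=0.01, K2=0.03, full=True,
    )
    ssim = float(ssim_map.mean() if mask is None else ssim_map[mask].mean())

    rmse = float(np.sqrt(np.mean((pv - rv) ** 2)))
    psnr = PSNR_CAP_DB if rmse == 0 else min(20.0 * np.log10(1.0 / rmse), PSNR_CAP_DB)

    return MetricsRecord(
        corr=corr,
        l1=l1,
        ssim=ssim,
        psnr=float(psnr),
        n_pixels=int(pv.size),
        normalization={"scale": scale, "convention": "ref-99th-percentile", "psnr_peak": 1.0},
    )
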