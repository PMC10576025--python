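"""Applying a trained model to exons of other lengths and other assays.

Two adaptations are needed: (1) the position-bias matrices are defined on
the training window's position axis, so predicting a different exon length
requires resampling them — done with a Lanczos kernel (windowed sinc,
parameter a=3) under a proportional endpoint-to-endpoint position mapping;
(2) assays differ in splice sites, flanking context and cell type, which
is absorbed by a single scalar basal-strength correction fitted per assay
by minimising mean Bernoulli KL with all other parameters frozen.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .model import EncodedDataset, ModelParams, ScmParams, model_forward_batch
from .training import bernoulli_kl


def lanczos_kernel(x, a: int = 3):
    """Lanczos window: sinc(x) * sinc(x/a) for |x| < a, else 0."""
    x = np.asarray(x, dtype=float)
    out = np.sinc(x) * np.sinc(x / a)
    return np.where(np.abs(x) < a, out, 0.0)


def resample_position_bias(beta: np.ndarray, new_row_count: int, a: int = 3) -> np.ndarray:
    """Resample each filter's position-bias column to a new position count.

    Positions map proportionally end to end (old = new * (n_old - 1) /
    (n_new - 1)); source indices outside the column are clamped to the
    edges and the kernel weights are renormalised so constants are
    reproduced at any length.  Identity at the native length (the Lanczos
    kernel is exact at integer shifts).
    """
    beta = np.asarray(beta, dtype=float)
    n_old = beta.shape[0]
    if new_row_count < 1:
        raise ValueError("new_row_count must be >= 1")
    if new_row_count == 1:
        if n_old > 1:
            warnings.warn(
                "resampling a multi-position bias to a single position: using the mean",
                RuntimeWarning,
            )
        return beta.mean(axis=0, keepdims=True)
    if n_old == 1:
        return np.repeat(beta, new_row_count, axis=0)

    out = np.zeros((new_row_count,) + beta.shape[1:])
    scale = (n_old - 1) / (new_row_count - 1)
    for t in range(new_row_count):
        x = t * scale
        lo = int(np.floor(x)) - a + 1
        idx = np.arange(lo, lo + 2 * a)
        w = lanczos_kernel(x - idx, a)
        idx = np.clip(idx, 0, n_old - 1)
        w_sum = w.sum()
        out[t] = (w[:, None] * beta[idx]).sum(axis=0) / w_sum
    return out


@dataclass
class AssayAdapter:
    """A trained model adapted to a different exon length and assay context."""

    params: ModelParams  # resampled parameter set (delta_b NOT yet applied)
    target_d: int
    delta_b: float = 0.0

    def predict(self, enc: EncodedDataset):
        psi_hat, delta = _forward_with_shift(self.params, enc, self.delta_b)
        return psi_hat, delta


def adapt_model(params: ModelParams, exon_length: int, flank: int = 10, a: int = 3) -> AssayAdapter:
    """Resample every SCM's position bias to a new window length."""
    d_new = exon_length + 2 * flank
    scms = {}
    for key, scm in params.scms.items():
        beta_new = resample_position_bias(scm.beta, d_new - scm.w + 1, a=a)
        scms[key] = ScmParams(scm.side, scm.channels, scm.alpha.copy(), beta_new)
    new_params = ModelParams(scms=scms, B=params.B, tuner=params.tuner.copy(), d=d_new)
    return AssayAdapter(params=new_params, target_d=d_new)


def filter_external_exons(records: pd.DataFrame, wt_sequence: str) -> pd.DataFrame:
    """Keep substitution-only variants matching WT at the first/last 3 nt."""
    wt = wt_sequence.upper().replace("T", "U")
    L = len(wt)

    def ok(seq: str) -> bool:
        s = seq.upper().replace("T", "U")
        return len(s) == L and s[:3] == wt[:3] and s[-3:] == wt[-3:]

    keep = records["sequence"].map(ok)
    return records.loc[keep].reset_index(drop=True)


def _forward_with_shift(params: ModelParams, enc: EncodedDataset, delta_b: float):
    _, delta = model_forward_batch(enc.X_seq, enc.X_struct, params)
    delta = delta + delta_b
    psi_hat = np.asarray(params.tuner(delta), dtype=float)
    return psi_hat, delta


def fit_assay_correction(
    params: ModelParams,
    enc: EncodedDataset,
    bounds: tuple[float, float] = (-10.0, 10.0),
    xatol: float = 1e-4,
    eps: float = 1e-6,
) -> float:
    """Fit the per-assay basal-strength correction by bounded scalar search.

    Minimises the mean Bernoulli KL between measured and predicted PSI
    over a shift added to delta, all other parameters frozen.  The
    returned shift never has higher loss than zero shift.
    """
    _, delta0 = model_forward_batch(enc.X_seq, enc.X_struct, params)

    def loss(shift: float) -> float:
        q = np.asarray(params.tuner(delta0 + shift), dtype=float)
        val = float(np.mean(bernoulli_kl(enc.psi, q, eps=eps)))
        if not np.isfinite(val):
            raise RuntimeError(f"non-finite loss at shift {shift}")
        return val

    res = minimize_scalar(loss, bounds=bounds, method="bounded", options={"xatol": xatol})
    best = float(res.x)
    if loss(best) > loss(0.0):
        best = 0.0
    return best


def predict_assay(
    params: ModelParams,
    records: pd.DataFrame,
    exon_length: int,
    flank: int = 10,
    fit_correction: bool = True,
) -> tuple[pd.DataFrame, AssayAdapter]:
    """End-to-end cross-assay prediction: resample, fit delta-B, predict."""
    from .model import encode_dataset

    adapter = adapt_model(params, exon_length, flank=flank)
    enc = encode_dataset(records)
    if enc.d != adapter.target_d:
        raise ValueError(f"records have window length {enc.d}, expected {adapter.target_d}")
    if fit_correction and "psi" in records.columns and records["psi"].notna().all():
        adapter.delta_b = fit_assay_correction(adapter.params, enc)
    psi_hat, delta = adapter.predict(enc)
    out = records.copy()
    out["psi_hat"] = psi_hat
    out["delta"] = delta
    out["delta_b"] = adapter.delta_b
    return out, adapter
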