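"""Interpretable additive splicing-strength model.

The network scores a 90-nt exon window with four strength-computation
modules (SCMs), one per (side, channel-set) combination::

    f(x) = Sum( Softplus( Convolution(x; alpha) + beta ) )

Sequence SCMs see the one-hot sequence (4 channels, 20 filters of width 6);
structure SCMs see sequence + dot-bracket + wobble indicator (8 channels,
8 filters of width 30).  The prediction is

    psi_hat = Tuner( f_incl_seq + f_incl_struct - f_skip_seq - f_skip_struct + B )

where B is a learnable basal strength and the Tuner maps the net strength
difference (delta) to PSI — either the affine sigmoid ``Tuner'`` used in
early training stages, or a small residual MLP followed by a sigmoid.

Every per-position, per-filter strength is retained, so any prediction
decomposes exactly into a balance of named feature strengths.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

from .sequences import one_hot_sequence, one_hot_structure

SIDES = ("incl", "skip")
CHANNEL_SETS = ("seq", "struct")
SCM_KEYS = ("incl_seq", "incl_struct", "skip_seq", "skip_struct")
#: sign of each SCM's total in the delta-strength sum
SCM_SIGNS = {"incl_seq": 1.0, "incl_struct": 1.0, "skip_seq": -1.0, "skip_struct": -1.0}


def softplus(t):
    t = np.asarray(t, dtype=float)
    return np.logaddexp(0.0, t)


def sigmoid(t):
    t = np.asarray(t, dtype=float)
    return 1.0 / (1.0 + np.exp(-t))


# ---------------------------------------------------------------------------
# encoding


@dataclass
class EncodedInput:
    """Numeric encoding of one exon window."""

    x_seq: np.ndarray  # (d, 4) one-hot over A, C, G, U
    x_struct: np.ndarray  # (d, 3) one-hot over '(', '.', ')'
    x_wobble: np.ndarray  # (d,) binary

    @property
    def d(self) -> int:
        return self.x_seq.shape[0]

    @property
    def struct_input(self) -> np.ndarray:
        """(d, 8) channel concatenation [seq(4), struct(3), wobble(1)]."""
        return np.concatenate(
            [self.x_seq, self.x_struct, self.x_wobble[:, None]], axis=1
        )


def encode_input(sequence: str, structure: str, wobble=None) -> EncodedInput:
    x_seq = one_hot_sequence(sequence)
    x_struct = one_hot_structure(structure)
    if x_seq.shape[0] != x_struct.shape[0]:
        raise ValueError("sequence/structure length mismatch")
    if wobble is None:
        x_wobble = np.zeros(x_seq.shape[0])
    else:
        x_wobble = np.asarray(
            [float(c) for c in wobble] if isinstance(wobble, str) else wobble,
            dtype=float,
        )
        if x_wobble.shape[0] != x_seq.shape[0]:
            raise ValueError("wobble length mismatch")
    return EncodedInput(x_seq=x_seq, x_struct=x_struct, x_wobble=x_wobble)


@dataclass
class EncodedDataset:
    """Stacked encodings for many records plus their measured PSI."""

    X_seq: np.ndarray  # (N, d, 4)
    X_struct: np.ndarray  # (N, d, 8)
    psi: np.ndarray  # (N,)
    ids: np.ndarray | None = None

    def __len__(self) -> int:
        return self.X_seq.shape[0]

    @property
    def d(self) -> int:
        return self.X_seq.shape[1]


def encode_dataset(df: pd.DataFrame, dtype=np.float32) -> EncodedDataset:
    """Encode a dataset table (columns sequence/structure/wobble/psi)."""
    n = len(df)
    if n == 0:
        raise ValueError("empty dataset")
    d = len(df["sequence"].iloc[0])
    X_seq = np.zeros((n, d, 4), dtype=dtype)
    X_struct = np.zeros((n, d, 8), dtype=dtype)
    for i, rec in enumerate(df.itertuples(index=False)):
        enc = encode_input(rec.sequence, rec.structure, getattr(rec, "wobble", None))
        X_seq[i] = enc.x_seq
        X_struct[i] = enc.struct_input
    psi = df["psi"].to_numpy(dtype=float) if "psi" in df.columns else np.full(n, np.nan)
    ids = df["id"].to_numpy() if "id" in df.columns else None
    return EncodedDataset(X_seq=X_seq, X_struct=X_struct, psi=psi, ids=ids)


# ---------------------------------------------------------------------------
# parameters


@dataclass
class ScmParams:
    """One strength-computation module's learnable state."""

    side: str  # "incl" | "skip"
    channels: str  # "seq" | "struct"
    alpha: np.ndarray  # (w, c, k) convolution kernels
    beta: np.ndarray  # (d - w + 1, k) position bias

    def __post_init__(self):
        if self.side not in SIDES:
            raise ValueError(f"side must be one of {SIDES}")
        if self.channels not in CHANNEL_SETS:
            raise ValueError(f"channels must be one of {CHANNEL_SETS}")
        if self.alpha.ndim != 3 or self.beta.ndim != 2:
            raise ValueError("alpha must be (w, c, k) and beta (d-w+1, k)")
        if self.alpha.shape[2] != self.beta.shape[1]:
            raise ValueError("alpha and beta disagree on filter count")

    @property
    def w(self) -> int:
        return self.alpha.shape[0]

    @property
    def c(self) -> int:
        return self.alpha.shape[1]

    @property
    def k(self) -> int:
        return self.alpha.shape[2]

    @property
    def n_positions(self) -> int:
        return self.beta.shape[0]

    def copy(self) -> "ScmParams":
        return ScmParams(self.side, self.channels, self.alpha.copy(), self.beta.copy())


@dataclass
class TunerPrime:
    """Affine-sigmoid link: delta -> sigmoid(nu * delta + eta)."""

    nu: float = 1.0
    eta: float = 0.0

    def __call__(self, delta):
        return sigmoid(self.nu * np.asarray(delta, dtype=float) + self.eta)

    def copy(self) -> "TunerPrime":
        return TunerPrime(self.nu, self.eta)


@dataclass
class TunerFull:
    """3-layer MLP with an input-to-output residual, then a sigmoid.

    With zero output weights, residual ``r`` and bias ``b3`` this reduces
    exactly to ``TunerPrime(nu=r, eta=b3)`` — which is how stage 3 is
    initialised from stage 2.
    """

    w1: np.ndarray  # (h1,)
    b1: np.ndarray  # (h1,)
    W2: np.ndarray  # (h2, h1)
    b2: np.ndarray  # (h2,)
    w3: np.ndarray  # (h2,)
    b3: float
    r: float

    def __call__(self, delta):
        delta = np.asarray(delta, dtype=float)
        scalar = delta.ndim == 0
        x = np.atleast_1d(delta)
        a1 = np.tanh(x[:, None] * self.w1 + self.b1)
        a2 = np.tanh(a1 @ self.W2.T + self.b2)
        u = a2 @ self.w3 + self.b3 + self.r * x
        out = sigmoid(u)
        return float(out[0]) if scalar else out

    def copy(self) -> "TunerFull":
        return TunerFull(
            self.w1.copy(), self.b1.copy(), self.W2.copy(), self.b2.copy(),
            self.w3.copy(), float(self.b3), float(self.r),
        )

    @classmethod
    def from_prime(
        cls, prime: TunerPrime, hidden: tuple[int, int] = (10, 10), seed: int = 0
    ) -> "TunerFull":
        """Initialise so the full tuner reproduces ``prime`` exactly."""
        h1, h2 = hidden
        rng = np.random.default_rng(seed)
        return cls(
            w1=rng.normal(0.0, 0.5, h1),
            b1=rng.normal(0.0, 0.5, h1),
            W2=rng.normal(0.0, 0.5 / np.sqrt(h1), (h2, h1)),
            b2=rng.normal(0.0, 0.5, h2),
            w3=np.zeros(h2),
            b3=float(prime.eta),
            r=float(prime.nu),
        )


@dataclass
class ModelParams:
    """The full learnable state theta."""

    scms: dict[str, ScmParams]
    B: float
    tuner: TunerPrime | TunerFull
    d: int

    def __post_init__(self):
        for key in self.scms:
            if key not in SCM_KEYS:
                raise ValueError(f"unknown SCM key {key!r}")
        for key, scm in self.scms.items():
            if scm.n_positions != self.d - scm.w + 1:
                raise ValueError(
                    f"SCM {key}: beta rows {scm.n_positions} != d-w+1 = {self.d - scm.w + 1}"
                )

    @property
    def has_structure(self) -> bool:
        return "incl_struct" in self.scms

    def copy(self) -> "ModelParams":
        return ModelParams(
            scms={k: v.copy() for k, v in self.scms.items()},
            B=float(self.B),
            tuner=self.tuner.copy(),
            d=self.d,
        )

    @classmethod
    def default(
        cls,
        d: int = 90,
        k_seq: int = 20,
        k_struct: int = 8,
        w_seq: int = 6,
        w_struct: int = 30,
        include_structure: bool = True,
        init_scale: float = 0.5,
        beta_init: float = -3.0,
        seq_init: str = "kmer",
        seed: int = 0,
    ) -> "ModelParams":
        """Randomly initialised model with the published architecture sizes.

        ``beta_init`` starts the position bias negative so that only strong
        kernel matches clear the softplus at initialisation; this puts the
        units in a rectifier-like regime where motif-specific gradients are
        available from the first step.

        ``seq_init='kmer'`` seeds every sequence filter with the (scaled)
        one-hot pattern of a uniformly random 6-mer plus small noise, so
        kernels start translation-sharp and refine by single-base moves;
        diffuse Gaussian kernels (``'normal'``) tend to smear a motif over
        several alignments before locking, which can trap self-overlapping
        motifs in a shifted register.
        """
        rng = np.random.default_rng(seed)
        scms: dict[str, ScmParams] = {}
        for side in SIDES:
            if seq_init == "kmer":
                alpha_seq = rng.normal(0.0, 0.1, (w_seq, 4, k_seq))
                for f in range(k_seq):
                    for i in range(w_seq):
                        alpha_seq[i, rng.integers(0, 4), f] += 1.0
            elif seq_init == "normal":
                alpha_seq = rng.normal(0.0, init_scale, (w_seq, 4, k_seq))
            else:
                raise ValueError("seq_init must be 'kmer' or 'normal'")
            scms[f"{side}_seq"] = ScmParams(
                side, "seq",
                alpha=alpha_seq,
                beta=np.full((d - w_seq + 1, k_seq), float(beta_init)),
            )
            if include_structure:
                scms[f"{side}_struct"] = ScmParams(
                    side, "struct",
                    alpha=rng.normal(0.0, init_scale, (w_struct, 8, k_struct)),
                    beta=np.full((d - w_struct + 1, k_struct), float(beta_init)),
                )
        return cls(scms=scms, B=0.0, tuner=TunerPrime(1.0, 0.0), d=d)


# ---------------------------------------------------------------------------
# forward pass


def convolve(x: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Valid-mode cross-correlation: (d, c) x (w, c, k) -> (d-w+1, k) raw strengths."""
    x = np.asarray(x, dtype=float)
    w = alpha.shape[0]
    if w > x.shape[0]:
        raise ValueError(f"kernel width {w} exceeds input length {x.shape[0]}")
    if x.shape[1] != alpha.shape[1]:
        raise ValueError("channel count mismatch")
    win = sliding_window_view(x, w, axis=0)  # (d-w+1, c, w)
    return np.einsum("pcw,wcf->pf", win, alpha)


def convolve_batch(X: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """(N, d, c) x (w, c, k) -> (N, d-w+1, k)."""
    w = alpha.shape[0]
    win = sliding_window_view(X, w, axis=1)  # (N, d-w+1, c, w)
    return np.einsum("npcw,wcf->npf", win, alpha, optimize=True)


def scm_forward(x: np.ndarray, params: ScmParams) -> tuple[np.ndarray, float]:
    """Strength map softplus(z + beta) and its scalar total for one record."""
    z = convolve(x, params.alpha)
    strengths = softplus(z + params.beta)
    return strengths, float(strengths.sum())


def tuner_prime(delta, nu: float, eta: float):
    return sigmoid(nu * np.asarray(delta, dtype=float) + eta)


def tuner_full(delta, gamma: TunerFull):
    return gamma(delta)


def model_forward(encoded: EncodedInput, params: ModelParams):
    """Predict PSI for one record, returning full diagnostics.

    Returns ``(psi_hat, diagnostics)`` where diagnostics carries every
    per-position per-filter strength map, the four totals, and delta.
    """
    if encoded.d != params.d:
        raise ValueError(f"input length {encoded.d} != model d {params.d}")
    inputs = {"seq": encoded.x_seq, "struct": encoded.struct_input}
    strength_maps: dict[str, np.ndarray] = {}
    totals: dict[str, float] = {}
    delta = params.B
    for key, scm in params.scms.items():
        smap, total = scm_forward(inputs[scm.channels], scm)
        strength_maps[key] = smap
        totals[key] = total
        delta += SCM_SIGNS[key] * total
    psi_hat = float(params.tuner(delta))
    return psi_hat, {"strength_maps": strength_maps, "totals": totals, "delta": delta}


def model_forward_batch(
    X_seq: np.ndarray, X_struct: np.ndarray, params: ModelParams, return_maps: bool = False
):
    """Vectorised prediction over N records.

    Returns ``(psi_hat (N,), delta (N,))`` and, when ``return_maps`` is
    true, the per-SCM strength maps ``(N, P, k)`` as a third element.
    """
    inputs = {"seq": X_seq, "struct": X_struct}
    n = X_seq.shape[0]
    delta = np.full(n, params.B, dtype=float)
    maps: dict[str, np.ndarray] = {}
    for key, scm in params.scms.items():
        z = convolve_batch(inputs[scm.channels], scm.alpha)
        s = softplus(z + scm.beta)
        delta += SCM_SIGNS[key] * s.sum(axis=(1, 2))
        if return_maps:
            maps[key] = s
    psi_hat = np.asarray(params.tuner(delta), dtype=float)
    if return_maps:
        return psi_hat, delta, maps
    return psi_hat, delta


# ---------------------------------------------------------------------------
# statsmodels-style front end


class SplicingStrengthModel:
    """Additive splicing-strength model bound to a preprocessed dataset.

    Parameters
    ----------
    dataset : pandas.DataFrame
        Columns ``sequence`` (90-nt), ``structure`` (dot-bracket),
        ``wobble`` (0/1 string, optional) and ``psi``.
    k_seq, k_struct, w_seq, w_struct : int
        Architecture sizes; defaults are 20 sequence filters of width 6
        and 8 structure filters of width 30.

    Examples
    --------
    >>> model = SplicingStrengthModel.from_dataframe(df)
    >>> res = model.fit(seed=0)
    >>> print(res.summary())
    """

    def __init__(
        self,
        dataset: pd.DataFrame,
        k_seq: int = 20,
        k_struct: int = 8,
        w_seq: int = 6,
        w_struct: int = 30,
    ):
        self.dataset = dataset.reset_index(drop=True)
        self.k_seq = k_seq
        self.k_struct = k_struct
        self.w_seq = w_seq
        self.w_struct = w_struct
        self.d = len(self.dataset["sequence"].iloc[0])
        self._encoded: EncodedDataset | None = None

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "SplicingStrengthModel":
        return cls(df, **kwargs)

    @property
    def encoded(self) -> EncodedDataset:
        if self._encoded is None:
            self._encoded = encode_dataset(self.dataset)
        return self._encoded

    def fit(
        self,
        config=None,
        stages: tuple[int, ...] = (1, 2, 3),
        train_fraction: float = 0.8,
        seed: int = 0,
        verbose: bool = False,
    ):
        """Run the staged training schedule and return a results object.

        Stage 1 fits the sequence SCMs with the affine-sigmoid link; stage 2
        adds the structure SCMs (sequence weights warm-started); stage 3
        replaces the link with the full tuner.  ``stages`` may truncate the
        schedule, e.g. ``(1, 2)``.
        """
        from . import training as tr  # local import to avoid a cycle
        from .preprocess import train_test_split

        if config is None:
            config = tr.TrainConfig(seed=seed)
        train_df, test_df = train_test_split(self.dataset, train_fraction, seed=config.seed)
        train_enc = encode_dataset(train_df)
        test_enc = encode_dataset(test_df)

        params = None
        history: list[dict] = []
        if 1 in stages:
            params, h = tr.train_stage1(
                train_enc, config, heldout=test_enc,
                k_seq=self.k_seq, w_seq=self.w_seq, verbose=verbose,
            )
            history.extend(h)
        if 2 in stages:
            params, h = tr.train_stage2(
                params, train_enc, config, heldout=test_enc,
                k_struct=self.k_struct, w_struct=self.w_struct, verbose=verbose,
            )
            history.extend(h)
        if 3 in stages:
            params, h = tr.train_stage3(
                params, train_enc, config, heldout=test_enc, verbose=verbose
            )
            history.extend(h)
        return SplicingStrengthResults(
            model=self, params=params, config=config, history=history,
            train_data=train_df, test_data=test_df,
        )


class SplicingStrengthResults:
    """Fitted model: parameters, diagnostics, prediction and interpretation."""

    def __init__(self, model, params: ModelParams, config, history, train_data, test_data):
        self.model = model
        self.params = params
        self.config = config
        self.history = history
        self.train_data = train_data
        self.test_data = test_data

    # -- prediction ---------------------------------------------------------

    def predict(self, data: pd.DataFrame | None = None) -> np.ndarray:
        """Predicted PSI for ``data`` (default: the held-out test set)."""
        df = self.test_data if data is None else data
        enc = encode_dataset(df)
        psi_hat, _ = model_forward_batch(enc.X_seq, enc.X_struct, self.params)
        return psi_hat

    def predict_delta(self, data: pd.DataFrame | None = None) -> np.ndarray:
        df = self.test_data if data is None else data
        enc = encode_dataset(df)
        _, delta = model_forward_batch(enc.X_seq, enc.X_struct, self.params)
        return delta

    # -- diagnostics --------------------------------------------------------

    def heldout_kl(self) -> float:
        from .training import bernoulli_kl

        q = self.predict()
        p = self.test_data["psi"].to_numpy(dtype=float)
        return float(np.mean(bernoulli_kl(p, q, eps=self.config.eps_clip)))

    def heldout_pearson_r(self, truth: np.ndarray | None = None) -> float:
        """Pearson r between predictions and measured (or supplied true) PSI."""
        q = self.predict()
        p = self.test_data["psi"].to_numpy(dtype=float) if truth is None else np.asarray(truth)
        return float(np.corrcoef(q, p)[0, 1])

    def summary(self) -> str:
        lines = [
            "Splicing strength model (additive inclusion/skipping balance)",
            "=" * 62,
            f"records (train/test): {len(self.train_data)}/{len(self.test_data)}",
            f"window length d: {self.params.d}",
            f"basal strength B: {self.params.B:+.4f}",
            f"tuner: {type(self.params.tuner).__name__}",
        ]
        for key, scm in self.params.scms.items():
            lines.append(
                f"  SCM {key:12s} k={scm.k:2d} w={scm.w:2d} c={scm.c}  "
                f"|alpha|max={np.abs(scm.alpha).max():.3f}"
            )
        lines.append(f"held-out mean KL: {self.heldout_kl():.4f}")
        lines.append(f"held-out Pearson r (vs measured PSI): {self.heldout_pearson_r():.4f}")
        return "\n".join(lines)

    # -- interpretation (delegates) -----------------------------------------

    def balance_summary(self, record: pd.Series):
        from .interpret import balance_summary

        return balance_summary(record, self.params)

    def cluster_filters(self, data: pd.DataFrame | None = None, **kwargs):
        from .interpret import cluster_filters

        df = self.train_data if data is None else data
        return cluster_filters(self.params, df, **kwargs)

    def filter_logo(self, scm_key: str, filter_id: int, **kwargs):
        from .interpret import filter_logo

        return filter_logo(self.params, scm_key, filter_id, **kwargs)

    def nucleotide_relevance(self, record: pd.Series, scm_key: str, filter_id: int):
        from .interpret import nucleotide_relevance

        return nucleotide_relevance(record, self.params, scm_key, filter_id)

    def save(self, path) -> None:
        from .io import save_model

        save_model(path, self.params)
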