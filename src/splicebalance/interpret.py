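"""Model interpretation: balance plots, filter clustering, logos, relevance,
seed stability, mutant design and the sequencing-artifact rule-out check.

Everything here consumes a trained :class:`~splicebalance.model.ModelParams`
and exposes the model's internal strengths, which is what makes the network
interpretable: a prediction is, exactly, a signed sum of per-filter
strengths passed through the tuner.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import mannwhitneyu

from .model import (
    SCM_SIGNS,
    EncodedInput,
    ModelParams,
    encode_dataset,
    encode_input,
    model_forward,
    model_forward_batch,
)
from .sequences import RNA_ALPHABET, normalize_rna, wobble_vector


def _encode_record(record) -> EncodedInput:
    wob = record.get("wobble") if hasattr(record, "get") else getattr(record, "wobble", None)
    if wob is None:
        wob = wobble_vector(record["sequence"], record["structure"])
    return encode_input(record["sequence"], record["structure"], wob)


# ---------------------------------------------------------------------------
# balance plots


@dataclass
class BalanceSummary:
    """One prediction decomposed into per-filter strength bars.

    ``bars`` has columns (scm, filter, side, value>=0); the basal strength
    ``B`` is assigned to the inclusion side when nonnegative, else to
    skipping.  The signed bar sum reproduces delta exactly, and
    ``psi_hat = tuner(delta)``.
    """

    bars: pd.DataFrame
    B: float
    delta: float
    psi_hat: float

    def signed_sum(self) -> float:
        sign = np.where(self.bars["side"] == "inclusion", 1.0, -1.0)
        return float((sign * self.bars["value"]).sum()) + self.B


def balance_summary(record, params: ModelParams) -> BalanceSummary:
    """Per-filter total strengths for one record (Fig.-style balance plot data)."""
    enc = _encode_record(record)
    psi_hat, diag = model_forward(enc, params)
    rows = []
    for key, smap in diag["strength_maps"].items():
        side = "inclusion" if SCM_SIGNS[key] > 0 else "skipping"
        per_filter = smap.sum(axis=0)  # sum over positions
        for f, val in enumerate(per_filter):
            rows.append({"scm": key, "filter": int(f), "side": side, "value": float(val)})
    bars = pd.DataFrame(rows)
    return BalanceSummary(bars=bars, B=float(params.B), delta=float(diag["delta"]), psi_hat=psi_hat)


def plot_balance(summary: BalanceSummary, ax=None, min_bar: float = 0.0):
    """Stacked-bar rendering of a balance summary (matplotlib)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    for i, side in enumerate(("inclusion", "skipping")):
        sub = summary.bars[(summary.bars["side"] == side) & (summary.bars["value"] > min_bar)]
        vals = sub.sort_values("value", ascending=False)["value"].to_numpy()
        extra = [max(summary.B, 0.0)] if (side == "inclusion" and summary.B >= 0) else (
            [-min(summary.B, 0.0)] if (side == "skipping" and summary.B < 0) else []
        )
        heights = np.concatenate([extra, vals]) if len(extra) else vals
        bottom = 0.0
        for h in heights:
            ax.bar(i, h, bottom=bottom, width=0.6,
                   color="tab:blue" if side == "inclusion" else "tab:red",
                   edgecolor="white", linewidth=0.5)
            bottom += h
    ax.set_xticks([0, 1], ["inclusion", "skipping"])
    ax.set_ylabel("total strength (a.u.)")
    ax.set_title(f"delta = {summary.delta:+.2f}, predicted PSI = {summary.psi_hat:.2f}")
    return ax


# ---------------------------------------------------------------------------
# filter clustering


@dataclass
class FilterCluster:
    members: list[tuple[str, int]]  # (scm key, filter index)
    representative: tuple[str, int]  # strongest member
    mean_strengths: dict[tuple[str, int], float]


def filter_strength_vectors(
    params: ModelParams, dataset: pd.DataFrame, scm_keys=("incl_seq", "skip_seq")
) -> tuple[list[tuple[str, int]], np.ndarray]:
    """Per-exon total strength of every filter: (labels, matrix n_filters x n_exons)."""
    enc = encode_dataset(dataset)
    _, _, maps = model_forward_batch(enc.X_seq, enc.X_struct, params, return_maps=True)
    labels, rows = [], []
    for key in scm_keys:
        if key not in maps:
            continue
        totals = maps[key].sum(axis=1)  # (N, k)
        for f in range(totals.shape[1]):
            labels.append((key, f))
            rows.append(totals[:, f])
    return labels, np.asarray(rows)


def cluster_filters(
    params: ModelParams,
    dataset: pd.DataFrame,
    threshold: float = 0.3,
    method: str = "average",
    scm_keys=("incl_seq", "skip_seq"),
    merge: list[list[tuple[str, int]]] | None = None,
) -> list[FilterCluster]:
    """Group redundant filters by the correlation of their strength vectors.

    Agglomerative clustering (correlation distance, average linkage by
    default) cut at ``threshold``; the member with the largest mean
    strength represents each cluster.  Filters with (near-)constant
    strength vectors are placed in singleton clusters.  ``merge`` allows
    manually pre-merging listed filter groups (e.g. stem-loop variants
    that differ only in loop length).
    """
    labels, X = filter_strength_vectors(params, dataset, scm_keys)
    if len(labels) < 2:
        raise ValueError("need at least two filters to cluster")
    sd = X.std(axis=1)
    variable = sd > 1e-12
    corr = np.corrcoef(X[variable]) if variable.sum() >= 2 else np.ones((variable.sum(),) * 2)
    dist = np.clip(1.0 - corr, 0.0, 2.0)
    np.fill_diagonal(dist, 0.0)

    assignments: dict[tuple[str, int], int] = {}
    if variable.sum() >= 2:
        Z = linkage(squareform(dist, checks=False), method=method)
        flat = fcluster(Z, t=threshold, criterion="distance")
        var_labels = [lab for lab, v in zip(labels, variable) if v]
        for lab, c in zip(var_labels, flat):
            assignments[lab] = int(c)
    next_id = max(assignments.values(), default=0)
    for lab, v in zip(labels, variable):
        if not v:
            next_id += 1
            assignments[lab] = next_id

    if merge:
        for group in merge:
            target = assignments[tuple(group[0])]
            for lab in group[1:]:
                assignments[tuple(lab)] = target

    mean_strength = {lab: float(X[i].mean()) for i, lab in enumerate(labels)}
    clusters: list[FilterCluster] = []
    for cid in sorted(set(assignments.values())):
        members = [lab for lab, c in assignments.items() if c == cid]
        rep = max(members, key=lambda lab: mean_strength[lab])
        clusters.append(
            FilterCluster(
                members=members, representative=rep,
                mean_strengths={m: mean_strength[m] for m in members},
            )
        )
    return clusters


# ---------------------------------------------------------------------------
# logos


def _all_kmers(k: int):
    for tup in itertools.product(RNA_ALPHABET, repeat=k):
        yield "".join(tup)


def filter_logo(
    params: ModelParams,
    scm_key: str,
    filter_id: int,
    mode: str = "enumerate",
    dataset: pd.DataFrame | None = None,
    top_fraction: float = 0.01,
) -> pd.DataFrame:
    """Position-frequency (or enrichment) matrix describing one filter.

    ``enumerate`` mode scores all 4^w k-mers on the sequence channels and
    returns the base-frequency matrix of those whose best position-adjusted
    pre-activation (max over positions of z + beta) is positive — feasible
    for the short sequence filters.  ``sample`` mode, intended for the long
    structure filters, scores dataset subsequences and returns the
    log2-enrichment of activating versus background base frequencies.
    """
    scm = params.scms[scm_key]
    if mode == "enumerate":
        if scm.w > 8:
            raise ValueError("enumerate mode is only tractable for short filters")
        alpha_seq = scm.alpha[:, :4, filter_id]  # (w, 4)
        beta_max = float(scm.beta[:, filter_id].max())
        counts = np.zeros((scm.w, 4))
        n_activating = 0
        for kmer in _all_kmers(scm.w):
            idx = [RNA_ALPHABET.index(c) for c in kmer]
            z = float(alpha_seq[np.arange(scm.w), idx].sum())
            if z + beta_max > 0:
                n_activating += 1
                for i, j in enumerate(idx):
                    counts[i, j] += 1.0
        if n_activating == 0:
            warnings.warn(
                f"filter {scm_key}[{filter_id}] has no activating {scm.w}-mer",
                RuntimeWarning,
            )
            freq = counts
        else:
            freq = counts / n_activating
        return pd.DataFrame(freq, columns=list(RNA_ALPHABET))

    if mode == "sample":
        if dataset is None:
            raise ValueError("sample mode requires a dataset")
        enc = encode_dataset(dataset)
        X = enc.X_seq if scm.channels == "seq" else enc.X_struct
        from numpy.lib.stride_tricks import sliding_window_view

        win = sliding_window_view(X, scm.w, axis=1)  # (N, P, c, w)
        z = np.einsum("npcw,wcf->np", win, scm.alpha[:, :, [filter_id]], optimize=True)
        score = z + scm.beta[:, filter_id]
        flat = score.ravel()
        order = np.argsort(-flat)
        n_top = max(1, int(top_fraction * flat.size))
        seq_win = win[:, :, :4, :]  # base identity channels
        flat_seq = seq_win.reshape(-1, 4, scm.w)
        top_freq = flat_seq[order[:n_top]].mean(axis=0).T  # (w, 4)
        bg_freq = flat_seq.mean(axis=0).T
        enrich = np.log2((top_freq + 1e-3) / (bg_freq + 1e-3))
        return pd.DataFrame(enrich, columns=list(RNA_ALPHABET))

    raise ValueError("mode must be 'enumerate' or 'sample'")


# ---------------------------------------------------------------------------
# per-nucleotide relevance


def nucleotide_relevance(
    record, params: ModelParams, scm_key: str, filter_id: int, eps: float = 1e-6
) -> np.ndarray:
    """Apportion one filter's total strength onto input positions.

    Each window's post-softplus strength is redistributed onto the window's
    positions proportionally to the magnitude of their contribution
    x[p+i, ch] * alpha[i, ch, f] to the raw strength (epsilon-stabilised);
    the redistribution conserves the filter's total strength exactly.
    """
    enc = _encode_record(record)
    scm = params.scms[scm_key]
    x = enc.x_seq if scm.channels == "seq" else enc.struct_input
    from .model import convolve, softplus

    z = convolve(x, scm.alpha)[:, filter_id]
    s = softplus(z + scm.beta[:, filter_id])
    relevance = np.zeros(x.shape[0])
    w = scm.w
    for p in range(len(z)):
        contrib = np.einsum("ic,ic->i", x[p: p + w], scm.alpha[:, :, filter_id])
        weights = np.abs(contrib)
        total = weights.sum()
        if total < eps:
            weights = np.full(w, 1.0 / w)
        else:
            weights = weights / total
        relevance[p: p + w] += s[p] * weights
    return relevance


# ---------------------------------------------------------------------------
# seed stability


def seed_stability(
    models: list[ModelParams], dataset: pd.DataFrame, scm_keys=("incl_seq", "skip_seq")
) -> pd.DataFrame:
    """Greedy bipartite matching of filters across independently trained models.

    Filters are represented by their per-exon total-strength vectors on a
    common dataset; each pair of models is matched greedily by descending
    correlation.  Returns one row per matched pair (model_a, model_b,
    filter_a, filter_b, correlation) plus unmatched filters with NaN.
    """
    if len(models) < 2:
        raise ValueError("need at least two models")
    vecs = [filter_strength_vectors(m, dataset, scm_keys) for m in models]
    rows = []
    for a in range(len(models)):
        for b in range(a + 1, len(models)):
            labels_a, Xa = vecs[a]
            labels_b, Xb = vecs[b]
            with np.errstate(invalid="ignore"):
                corr = np.corrcoef(np.vstack([Xa, Xb]))[: len(labels_a), len(labels_a):]
            corr = np.nan_to_num(corr, nan=-1.0)
            used_a: set[int] = set()
            used_b: set[int] = set()
            order = np.dstack(np.unravel_index(np.argsort(-corr, axis=None), corr.shape))[0]
            for i, j in order:
                if i in used_a or j in used_b:
                    continue
                used_a.add(int(i))
                used_b.add(int(j))
                rows.append(
                    {"model_a": a, "model_b": b,
                     "filter_a": str(labels_a[i]), "filter_b": str(labels_b[j]),
                     "correlation": float(corr[i, j])}
                )
            for i, lab in enumerate(labels_a):
                if i not in used_a:
                    rows.append({"model_a": a, "model_b": b, "filter_a": str(lab),
                                 "filter_b": None, "correlation": np.nan})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# mutant design


@dataclass
class MutantProposal:
    name: str
    sequence: str
    structure: str
    target_strength: float
    target_change: float
    max_other_change: float
    psi_hat: float
    accepted: bool


def _filter_strength(params: ModelParams, scm_key: str, filter_id: int, sequence, structure):
    wob = wobble_vector(sequence, structure)
    enc = encode_input(sequence, structure, wob)
    psi_hat, diag = model_forward(enc, params)
    strengths = {
        (key, f): float(diag["strength_maps"][key][:, f].sum())
        for key in params.scms
        for f in range(params.scms[key].k)
    }
    return strengths[(scm_key, filter_id)], strengths, psi_hat


def design_mutants(
    record,
    params: ModelParams,
    target: tuple[str, int],
    mode: str = "stem",
    fold=None,
    max_other_change: float | None = None,
    max_other_change_fraction: float = 0.1,
) -> list[MutantProposal]:
    """Propose validation mutants for a stem-loop or G-poor feature carrier.

    Stem mode: two single-base mutants, each breaking one arm of the
    record's (single) helix, plus the double compensatory mutant restoring
    complementarity.  G-poor mode: one C->G substitution at the centre of
    the filter's most activating window.  Structures of mutants are
    recomputed with ``fold`` (default: the toy maximum-pairing folder).
    Proposals whose maximal absolute strength change over non-target
    filters exceeds the threshold (default 10% of the target filter's
    change) are marked rejected.  Substitutions only — length is never
    altered.
    """
    from .folding import fold_toy
    from .sequences import helices

    fold = fold or fold_toy
    scm_key, filter_id = target
    sequence = normalize_rna(record["sequence"])
    structure = record["structure"]
    base_target, base_all, _ = _filter_strength(params, scm_key, filter_id, sequence, structure)

    candidates: list[tuple[str, str]] = []
    if mode == "stem":
        hx = helices(structure)
        if len(hx) != 1:
            return []  # eligibility: exactly one stem activation
        helix = hx[0]
        i, j = helix[len(helix) // 2]  # mutate a mid-stem pair
        up = _break_pair(sequence, i, j)
        down = _break_pair(sequence, j, i)
        both = _compensate(sequence, i, j)
        candidates = [("upstream_mut", up), ("downstream_mut", down), ("double_mut", both)]
    elif mode == "gpoor":
        scm = params.scms[scm_key]
        enc = encode_input(sequence, structure, wobble_vector(sequence, structure))
        from .model import convolve

        x = enc.x_seq if scm.channels == "seq" else enc.struct_input
        score = convolve(x, scm.alpha)[:, filter_id] + scm.beta[:, filter_id]
        if (score > 0).sum() == 0:
            return []
        p = int(np.argmax(score))
        window = range(p, p + scm.w)
        c_positions = [i for i in window if sequence[i] == "C"]
        if not c_positions:
            return []
        centre = p + scm.w // 2
        at = min(c_positions, key=lambda i: abs(i - centre))
        mut = sequence[:at] + "G" + sequence[at + 1:]
        candidates = [("c_to_g", mut)]
    else:
        raise ValueError("mode must be 'stem' or 'gpoor'")

    proposals = []
    for name, mut_seq in candidates:
        mut_struct = fold(mut_seq)
        t_strength, all_strengths, psi_hat = _filter_strength(
            params, scm_key, filter_id, mut_seq, mut_struct
        )
        t_change = t_strength - base_target
        other = max(
            (abs(all_strengths[k] - base_all[k]) for k in all_strengths if k != target),
            default=0.0,
        )
        limit = (
            max_other_change
            if max_other_change is not None
            else max_other_change_fraction * max(abs(t_change), 1e-12)
        )
        proposals.append(
            MutantProposal(
                name=name, sequence=mut_seq, structure=mut_struct,
                target_strength=t_strength, target_change=t_change,
                max_other_change=other, psi_hat=psi_hat,
                accepted=other <= limit,
            )
        )
    return proposals


def _break_pair(seq: str, i: int, j: int) -> str:
    """Mutate position i so it no longer pairs with position j."""
    partner = seq[j]
    pairs_with = {b for a, b in (("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"),
                                 ("G", "U"), ("U", "G")) if a == partner}
    for base in "ACGU":
        if base != seq[i] and base not in pairs_with:
            return seq[:i] + base + seq[i + 1:]
    raise RuntimeError("unreachable")  # pragma: no cover


def _compensate(seq: str, i: int, j: int) -> str:
    """Mutate both arms to a new complementary pair (A-U unless already)."""
    new_i = _break_pair(seq, i, j)[i]
    comp = {"A": "U", "U": "A", "G": "C", "C": "G"}[new_i]
    out = list(seq)
    out[i], out[j] = new_i, comp
    return "".join(out)


# ---------------------------------------------------------------------------
# sequencing-artifact rule-out


def artifact_check(
    records: pd.DataFrame, feature_flag, alpha: float = 0.05, min_group: int = 10
) -> dict:
    """Classify a feature's read-count signature as splicing or artifact.

    A bona fide skipping feature lowers inclusion reads *and raises*
    skipping reads; an enzymatic/sequencing artifact (feature-bearing
    molecules failing to amplify) lowers inclusion reads while leaving
    skipping reads unchanged.  Group locations are compared with
    Mann-Whitney U tests on raw counts.
    """
    flag = np.asarray(feature_flag, dtype=bool)
    pos = records.loc[flag]
    neg = records.loc[~flag]
    if len(pos) < min_group or len(neg) < min_group:
        return {"pattern": "inconclusive", "reason": "group too small",
                "n_pos": int(len(pos)), "n_neg": int(len(neg))}

    out = {"n_pos": int(len(pos)), "n_neg": int(len(neg))}
    for col in ("n_inclusion", "n_skipping"):
        a, b = pos[col].to_numpy(float), neg[col].to_numpy(float)
        stat, p_greater = mannwhitneyu(a, b, alternative="greater")
        _, p_less = mannwhitneyu(a, b, alternative="less")
        if p_less < alpha:
            direction = "down"
        elif p_greater < alpha:
            direction = "up"
        else:
            direction = "unchanged"
        out[col] = {"direction": direction, "median_pos": float(np.median(a)),
                    "median_neg": float(np.median(b)),
                    "p_greater": float(p_greater), "p_less": float(p_less)}

    incl, skip = out["n_inclusion"]["direction"], out["n_skipping"]["direction"]
    if incl == "down" and skip == "up":
        out["pattern"] = "bona fide"
    elif incl == "down" and skip == "unchanged":
        out["pattern"] = "artifact-like"
    else:
        out["pattern"] = "inconclusive"
    return out
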