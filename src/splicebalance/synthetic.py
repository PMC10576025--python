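"""Synthetic splicing reporter assays with known additive ground truth.

Every exon is a random 70-mer flanked by 10 fixed nucleotides on each side
(the 90-nt model window).  A :class:`GroundTruthRule` plants sequence
motifs, a short GC-rich stem loop and a long G-poor stretch, each carrying
an additive strength on the inclusion or skipping side; the net strength
difference is mapped to a true PSI through an affine-sigmoid link, and
per-barcode read counts are drawn binomially.  Because the rule is known,
every downstream stage (preprocessing, training, interpretation) can be
tested by parameter recovery instead of against downloads.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .folding import fold_toy
from .sequences import helices, normalize_rna

#: Fixed flanking decanucleotides shared by every reporter window.
FLANK_5 = "GGCGUGGAUG"
FLANK_3 = "GACGGCAUGG"
EXON_LEN = 70
WINDOW_LEN = len(FLANK_5) + EXON_LEN + len(FLANK_3)

_RC = {"A": "U", "U": "A", "G": "C", "C": "G"}


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


@dataclass(frozen=True)
class MotifFeature:
    """A planted 6-mer with a side, a strength and a position profile.

    ``position_profile`` multiplies the strength by where the motif starts
    in the 90-nt window (length = window − k + 1); ``None`` means uniform.
    """

    kmer: str
    side: str  # "inclusion" | "skipping"
    strength: float
    position_profile: np.ndarray | None = None

    def __post_init__(self):
        if self.side not in ("inclusion", "skipping"):
            raise ValueError(f"side must be inclusion/skipping, got {self.side!r}")
        if self.strength < 0:
            raise ValueError("strength must be nonnegative")
        object.__setattr__(self, "kmer", normalize_rna(self.kmer))

    def profile_at(self, start: int, n_starts: int) -> float:
        if self.position_profile is None:
            return 1.0
        prof = np.asarray(self.position_profile, dtype=float)
        if len(prof) != n_starts:
            raise ValueError(
                f"position_profile length {len(prof)} != window starts {n_starts}"
            )
        return float(prof[start])


@dataclass(frozen=True)
class StemFeature:
    """Skipping strength contributed by each short GC-rich helix."""

    min_stem_len: int = 5
    max_stem_len: int = 7
    strength: float = 2.5


@dataclass(frozen=True)
class GPoorFeature:
    """Skipping strength contributed when a long G-poor window exists."""

    window_len: int = 30
    max_g_count: int = 2
    strength: float = 2.0


@dataclass(frozen=True)
class Link:
    """Affine-sigmoid strength-to-PSI link: psi = sigma(nu * delta + eta)."""

    nu: float = 1.0
    eta: float = 0.0

    def __post_init__(self):
        if self.nu <= 0:
            raise ValueError("nu must be > 0")


def piecewise_linear_profile(n_starts: int, knots: list[tuple[float, float]]) -> np.ndarray:
    """Piecewise-linear multiplier profile from (fraction, value) knots."""
    fracs, vals = zip(*sorted(knots))
    x = np.linspace(0.0, 1.0, n_starts)
    return np.interp(x, fracs, vals)


@dataclass(frozen=True)
class GroundTruthRule:
    motifs: tuple[MotifFeature, ...]
    stem_feature: StemFeature = StemFeature()
    gpoor_feature: GPoorFeature = GPoorFeature()
    link: Link = Link()


def default_rule(window_len: int = WINDOW_LEN) -> GroundTruthRule:
    """Three inclusion and three skipping 6-mers plus the two structure features.

    Motif choices are loosely modelled on known exonic elements: purine-rich
    enhancer-like motifs on the inclusion side; hnRNP/PTB-like and
    branch-point-like motifs on the skipping side.  Profiles are
    piecewise-linear: uniform, a 5'->3' ramp, and a mid-exon peak.
    """
    n = window_len - 6 + 1
    ramp = piecewise_linear_profile(n, [(0.0, 0.5), (1.0, 1.5)])
    peak = piecewise_linear_profile(n, [(0.0, 0.5), (0.5, 1.5), (1.0, 0.5)])
    return GroundTruthRule(
        motifs=(
            MotifFeature("GAAGAA", "inclusion", 2.0),
            MotifFeature("CACACG", "inclusion", 1.6, ramp),
            MotifFeature("UCCUCA", "inclusion", 1.2, peak),
            MotifFeature("UAGGGU", "skipping", 2.0),
            MotifFeature("CUCUCU", "skipping", 1.6, ramp),
            MotifFeature("ACUAAC", "skipping", 1.2, peak),
        )
    )


# ---------------------------------------------------------------------------
# elementary generators


def generate_exon(rng: np.random.Generator, length: int) -> str:
    """Uniform i.i.d. random RNA string of ``length`` letters."""
    if length < 1:
        raise ValueError("length must be >= 1")
    return "".join(rng.choice(list("ACGU"), size=length))


def plant_stem_loop(
    seq: str,
    stem_len: int,
    loop_len: int,
    at: int,
    rng: np.random.Generator,
    gc_fraction: float = 0.8,
) -> tuple[str, str]:
    """Overwrite ``seq`` with a GC-rich hairpin; return (sequence, dot-bracket).

    The upstream arm is drawn GC-rich, the downstream arm is its exact
    reverse complement, and the returned structure marks exactly the
    planted pairs (everything else unpaired).
    """
    if loop_len < 3:
        raise ValueError("loop_len must be >= 3 (minimum hairpin loop)")
    total = 2 * stem_len + loop_len
    if at < 0 or at + total > len(seq):
        raise ValueError("stem loop does not fit in the sequence")
    p_gc = gc_fraction / 2.0
    p_au = (1.0 - gc_fraction) / 2.0
    arm5 = "".join(rng.choice(list("GCAU"), size=stem_len, p=[p_gc, p_gc, p_au, p_au]))
    arm3 = "".join(_RC[c] for c in reversed(arm5))
    loop = "".join(rng.choice(list("ACU"), size=loop_len))  # loop never pairs with arms
    new = seq[:at] + arm5 + loop + arm3 + seq[at + total:]
    struct = (
        "." * at
        + "(" * stem_len
        + "." * loop_len
        + ")" * stem_len
        + "." * (len(seq) - at - total)
    )
    return new, struct


def plant_motif(seq: str, kmer: str, at: int) -> str:
    if at < 0 or at + len(kmer) > len(seq):
        raise ValueError("motif does not fit at the requested position")
    return seq[:at] + kmer + seq[at + len(kmer):]


def plant_gpoor(seq: str, at: int, length: int, rng: np.random.Generator) -> str:
    """Overwrite a stretch with G-free letters."""
    if at < 0 or at + length > len(seq):
        raise ValueError("G-poor stretch does not fit")
    stretch = "".join(rng.choice(list("ACU"), size=length))
    return seq[:at] + stretch + seq[at + length:]


# ---------------------------------------------------------------------------
# ground-truth evaluation


def true_delta_strength(
    seq: str, struct: str, rule: GroundTruthRule
) -> tuple[float, list[dict]]:
    """Net inclusion-minus-skipping strength and its per-feature breakdown.

    Every occurrence of a rule motif contributes ``strength x profile[start]``
    on its side; every helix whose length falls in the stem feature's range
    contributes the stem strength to skipping; the G-poor feature contributes
    once if any window of the stated length has at most ``max_g_count`` G's.
    The breakdown entries carry signed values that sum exactly to delta.
    """
    seq = normalize_rna(seq)
    if len(seq) != len(struct):
        raise ValueError("sequence/structure length mismatch")
    breakdown: list[dict] = []

    for motif in rule.motifs:
        k = len(motif.kmer)
        n_starts = len(seq) - k + 1
        sign = 1.0 if motif.side == "inclusion" else -1.0
        for p in range(n_starts):
            if seq[p: p + k] == motif.kmer:
                val = motif.strength * motif.profile_at(p, n_starts)
                breakdown.append(
                    {"feature": f"motif:{motif.kmer}", "side": motif.side,
                     "position": p, "value": sign * val}
                )

    sf = rule.stem_feature
    if sf is not None and sf.strength > 0:
        for helix in helices(struct):
            if sf.min_stem_len <= len(helix) <= sf.max_stem_len:
                breakdown.append(
                    {"feature": "stem_loop", "side": "skipping",
                     "position": helix[0][0], "value": -sf.strength}
                )

    gf = rule.gpoor_feature
    if gf is not None and gf.strength > 0 and len(seq) >= gf.window_len:
        g_counts = np.convolve(
            np.frombuffer(seq.encode(), dtype=np.uint8) == ord("G"),
            np.ones(gf.window_len), mode="valid",
        )
        hits = np.flatnonzero(g_counts <= gf.max_g_count)
        if hits.size:
            breakdown.append(
                {"feature": "g_poor", "side": "skipping",
                 "position": int(hits[0]), "value": -gf.strength}
            )

    delta = float(sum(b["value"] for b in breakdown))
    return delta, breakdown


def psi_from_delta(delta, nu: float = 1.0, eta: float = 0.0):
    """Sigmoid link sigma(nu * delta + eta); strictly increasing in delta."""
    if nu <= 0:
        raise ValueError("nu must be > 0")
    return _sigmoid(nu * np.asarray(delta, dtype=float) + eta)


def sample_counts(psi: float, depth: int, rng: np.random.Generator) -> tuple[int, int]:
    """Binomial inclusion reads out of ``depth``; remainder are skipping."""
    if not 0.0 <= psi <= 1.0:
        raise ValueError("psi must be in [0, 1]")
    if depth < 0:
        raise ValueError("depth must be >= 0")
    n_incl = int(rng.binomial(depth, psi))
    return n_incl, depth - n_incl


# ---------------------------------------------------------------------------
# full assay


@dataclass
class SyntheticAssay:
    """Index-aligned count table and ground-truth sidecar."""

    counts: pd.DataFrame  # barcode, exon_seq, replicate, n_inclusion, n_skipping, n_other
    truth: pd.DataFrame  # barcode, sequence (90 nt), structure, true_delta, true_psi, active_features
    rule: GroundTruthRule

    @property
    def n_exons(self) -> int:
        return len(self.truth)


@dataclass(frozen=True)
class PlantingScheme:
    """Per-exon planting probabilities defining the study conditions."""

    p_motif: float = 0.08  # per motif, independently
    p_stem: float = 0.15
    p_gpoor: float = 0.10


def build_synthetic_assay(
    rule: GroundTruthRule | None = None,
    n_exons: int = 1000,
    depth: int = 200,
    seed: int = 0,
    planting: PlantingScheme = PlantingScheme(),
    structure_mode: str = "planted",
    n_replicates: int = 1,
    other_read_rate: float = 0.02,
    depth_distribution=None,
) -> SyntheticAssay:
    """Generate a reproducible assay of ``n_exons`` barcoded reporters.

    ``structure_mode='planted'`` annotates exactly the planted stem pairs
    (the default, so the structure channel and the truth sidecar agree);
    ``'fold'`` runs the toy maximum-pairing folder on the full window.
    ``depth_distribution``, if given, is called as ``f(rng) -> int`` per
    exon; otherwise the constant ``depth`` is used.
    """
    if n_exons < 1:
        raise ValueError("n_exons must be >= 1")
    if structure_mode not in ("planted", "fold"):
        raise ValueError("structure_mode must be 'planted' or 'fold'")
    rule = rule if rule is not None else default_rule()
    rng = np.random.default_rng(seed)
    flank_len = len(FLANK_5)

    barcodes = _unique_barcodes(rng, n_exons)
    count_rows, truth_rows = [], []
    for idx in range(n_exons):
        exon = generate_exon(rng, EXON_LEN)
        planted: list[str] = []
        stem_struct_var = None

        gf = rule.gpoor_feature
        if gf is not None and gf.strength > 0 and rng.random() < planting.p_gpoor:
            at = int(rng.integers(0, EXON_LEN - gf.window_len + 1))
            exon = plant_gpoor(exon, at, gf.window_len, rng)
            planted.append("g_poor")
        for motif in rule.motifs:
            if rng.random() < planting.p_motif:
                at = int(rng.integers(0, EXON_LEN - len(motif.kmer) + 1))
                exon = plant_motif(exon, motif.kmer, at)
                planted.append(f"motif:{motif.kmer}")
        sf = rule.stem_feature
        if sf is not None and sf.strength > 0 and rng.random() < planting.p_stem:
            stem_len = int(rng.integers(sf.min_stem_len, sf.max_stem_len + 1))
            loop_len = int(rng.integers(4, 7))
            total = 2 * stem_len + loop_len
            at = int(rng.integers(0, EXON_LEN - total + 1))
            exon, stem_struct_var = plant_stem_loop(exon, stem_len, loop_len, at, rng)
            planted.append("stem_loop")

        window = FLANK_5 + exon + FLANK_3
        if structure_mode == "fold":
            struct = fold_toy(window)
        elif stem_struct_var is not None:
            struct = "." * flank_len + stem_struct_var + "." * len(FLANK_3)
        else:
            struct = "." * len(window)

        delta, breakdown = true_delta_strength(window, struct, rule)
        psi = float(psi_from_delta(delta, rule.link.nu, rule.link.eta))

        this_depth = int(depth_distribution(rng)) if depth_distribution else depth
        per_rep = _split_depth(this_depth, n_replicates, rng)
        for rep, rep_depth in enumerate(per_rep, start=1):
            n_incl, n_skip = sample_counts(psi, rep_depth, rng)
            n_other = int(rng.poisson(other_read_rate * rep_depth))
            count_rows.append(
                (barcodes[idx], _to_dna(exon), rep, n_incl, n_skip, n_other)
            )
        truth_rows.append(
            (barcodes[idx], window, struct, delta, psi, json.dumps(planted))
        )

    counts = pd.DataFrame(
        count_rows,
        columns=["barcode", "exon_seq", "replicate", "n_inclusion", "n_skipping", "n_other"],
    )
    truth = pd.DataFrame(
        truth_rows,
        columns=["barcode", "sequence", "structure", "true_delta", "true_psi", "active_features"],
    )
    return SyntheticAssay(counts=counts, truth=truth, rule=rule)


def _unique_barcodes(rng: np.random.Generator, n: int, length: int = 20) -> list[str]:
    seen: set[str] = set()
    out: list[str] = []
    while len(out) < n:
        bc = "".join(rng.choice(list("ACGT"), size=length))
        if bc not in seen:
            seen.add(bc)
            out.append(bc)
    return out


def _split_depth(depth: int, n_replicates: int, rng: np.random.Generator) -> list[int]:
    if n_replicates == 1:
        return [depth]
    return list(rng.multinomial(depth, np.full(n_replicates, 1.0 / n_replicates)))


def _to_dna(seq: str) -> str:
    return seq.replace("U", "T")


def write_assay(assay: SyntheticAssay, out_dir) -> dict[str, str]:
    """Write counts TSV, 90-nt window FASTA, Vienna structures and truth TSV."""
    from pathlib import Path

    from . import io as sbio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": str(out / "counts.tsv"),
        "windows": str(out / "windows.fasta"),
        "structures": str(out / "structures.txt"),
        "truth": str(out / "truth.tsv"),
    }
    sbio.write_tsv(assay.counts, paths["counts"])
    sbio.write_fasta(
        list(zip(assay.truth["barcode"], assay.truth["sequence"])), paths["windows"]
    )
    sbio.write_structures(
        list(zip(assay.truth["barcode"], assay.truth["sequence"], assay.truth["structure"])),
        paths["structures"],
    )
    sbio.write_tsv(assay.truth, paths["truth"])
    return paths
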