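"""From per-barcode splicing-outcome counts to the model-ready dataset.

The pipeline starts at classified counts (one row per barcode x replicate
with inclusion / skipping / other outcome counts) and applies, in order:
barcode-to-exon resolution, replicate merging, read-quality filters,
PSI computation, structure/wobble annotation and a seeded 80/20 split.
Coordinates are 0-based half-open; the 70-nt variable exon occupies
[10, 80) of the 90-nt window.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .sequences import normalize_rna, reverse_complement_dna, wobble_vector

#: Esp3I (BsmBI) recognition site, written on the DNA strand.
ESP3I_SITE = "CGTCTC"

COUNT_COLUMNS = ["n_inclusion", "n_skipping", "n_other"]


def resolve_barcode_map(pairs) -> dict[str, str]:
    """Resolve barcodes to unique exon sequences from (barcode, exon, dna_reads).

    Exon sequences observed exactly once under a barcode are ignored as
    likely sequencing errors.  A barcode maps to an exon iff exactly one
    exon remains after that step and the barcode's total DNA reads are >= 2.
    """
    df = pd.DataFrame(list(pairs), columns=["barcode", "exon_seq", "dna_reads"])
    grouped = (
        df.groupby(["barcode", "exon_seq"], sort=False)["dna_reads"].sum().reset_index()
    )
    out: dict[str, str] = {}
    for barcode, sub in grouped.groupby("barcode", sort=False):
        kept = sub[sub["dna_reads"] > 1]  # single-read exons: sequencing errors
        if len(kept) != 1:
            continue
        if sub["dna_reads"].sum() < 2:
            continue
        out[barcode] = kept["exon_seq"].iloc[0]
    return out


def merge_replicates(counts: pd.DataFrame) -> pd.DataFrame:
    """Sum outcome counts across replicates per barcode (missing = zero)."""
    count_cols = [c for c in counts.columns if c.startswith("n_")]
    if (counts[count_cols] < 0).any().any():
        raise ValueError("negative outcome counts")
    keys = ["barcode"]
    if "exon_seq" in counts.columns:
        n_seq = counts.groupby("barcode")["exon_seq"].nunique()
        if (n_seq > 1).any():
            bad = n_seq[n_seq > 1].index[0]
            raise ValueError(f"barcode {bad!r} has inconsistent exon sequences")
        keys.append("exon_seq")
    merged = counts.groupby(keys, sort=False, as_index=False)[count_cols].sum()
    return merged


def filter_barcodes(
    records: pd.DataFrame,
    min_total_reads: int = 60,
    site: str = ESP3I_SITE,
    min_incl_skip_fraction: float = 0.8,
) -> pd.DataFrame:
    """Apply the three retention predicates to merged per-barcode counts.

    A record survives iff (1) total reads across all outcome categories is
    at least ``min_total_reads``; (2) neither the exon nor the barcode
    contains ``site`` on either strand; and (3) inclusion plus skipping
    reads make up at least ``min_incl_skip_fraction`` of all reads.
    """
    count_cols = [c for c in records.columns if c.startswith("n_")]
    total = records[count_cols].sum(axis=1)
    incl_skip = records["n_inclusion"] + records["n_skipping"]

    site_dna = site.upper().replace("U", "T")
    site_rc = reverse_complement_dna(site_dna)

    def clean(s: str) -> bool:
        s = s.upper().replace("U", "T")
        return site_dna not in s and site_rc not in s

    seq_ok = records["exon_seq"].map(clean)
    if "barcode" in records.columns:
        seq_ok &= records["barcode"].map(clean)

    with np.errstate(invalid="ignore"):
        frac_ok = incl_skip >= min_incl_skip_fraction * total
    keep = (total >= min_total_reads) & seq_ok & frac_ok
    return records.loc[keep].reset_index(drop=True)


def compute_psi(n_inclusion, n_skipping):
    """PSI = n_inclusion / (n_inclusion + n_skipping)."""
    n_inclusion = np.asarray(n_inclusion, dtype=float)
    n_skipping = np.asarray(n_skipping, dtype=float)
    denom = n_inclusion + n_skipping
    if np.any(denom <= 0):
        raise ValueError("PSI undefined: no inclusion or skipping reads")
    return n_inclusion / denom


def build_dataset(
    filtered: pd.DataFrame,
    windows: dict[str, str],
    structures: dict[str, str],
) -> pd.DataFrame:
    """Join filtered counts with 90-nt windows and structures; add PSI and wobble.

    ``windows`` and ``structures`` are keyed by barcode.  Sequences are
    normalised to RNA; the wobble indicator is serialised as a 0/1 string.
    """
    rows = []
    for _, rec in filtered.iterrows():
        bc = rec["barcode"]
        if bc not in windows or bc not in structures:
            continue
        seq = normalize_rna(windows[bc])
        struct = structures[bc]
        if len(seq) != len(struct):
            raise ValueError(f"record {bc}: sequence/structure length mismatch")
        wob = wobble_vector(seq, struct)
        psi = float(compute_psi(rec["n_inclusion"], rec["n_skipping"]))
        rows.append(
            {
                "id": bc,
                "sequence": seq,
                "structure": struct,
                "wobble": "".join(str(int(v)) for v in wob),
                "n_inclusion": int(rec["n_inclusion"]),
                "n_skipping": int(rec["n_skipping"]),
                "psi": psi,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["id", "sequence", "structure", "wobble", "n_inclusion", "n_skipping", "psi"],
    )


def _round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


def train_test_split(
    records: pd.DataFrame, train_fraction: float = 0.8, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Disjoint, exhaustive, seeded split; |train| = round(train_fraction * N)."""
    n = len(records)
    n_train = _round_half_away(train_fraction * n)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    train = records.iloc[perm[:n_train]].reset_index(drop=True)
    test = records.iloc[perm[n_train:]].reset_index(drop=True)
    return train, test


def preprocess_counts(
    counts: pd.DataFrame,
    windows: dict[str, str],
    structures: dict[str, str],
    min_total_reads: int = 60,
    site: str = ESP3I_SITE,
    min_incl_skip_fraction: float = 0.8,
) -> pd.DataFrame:
    """Convenience pipeline: merge replicates, filter, and build the dataset."""
    merged = merge_replicates(counts)
    filtered = filter_barcodes(
        merged,
        min_total_reads=min_total_reads,
        site=site,
        min_incl_skip_fraction=min_incl_skip_fraction,
    )
    return build_dataset(filtered, windows, structures)
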