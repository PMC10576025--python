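"""Shared file formats: FASTA, Vienna dot-bracket, TSV, model container.

All TSV outputs carry a ``#`` tool-version comment line followed by a
header.  The model container is a single ``.npz`` archive holding every
parameter array plus a JSON metadata blob (dimensions, channel orders,
tuner variant, format version); load/save round-trips bit-exactly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import __version__
from .model import ModelParams, ScmParams, TunerFull, TunerPrime
from .sequences import normalize_rna, pair_table

MODEL_FORMAT_VERSION = 1


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path) -> list[tuple[str, str]]:
    """Order-preserving (id, sequence) pairs; sequences normalised to RNA."""
    out: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id {rec.id!r}")
        seen.add(rec.id)
        out.append((rec.id, normalize_rna(str(rec.seq))))
    return out


def write_fasta(records, path) -> None:
    seq_records = [
        SeqRecord(Seq(seq), id=str(rid), description="") for rid, seq in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Vienna-style structures


def read_structures(path) -> list[tuple[str, str]]:
    """(id, dot-bracket) pairs from Vienna triplets or two-column TSV.

    Vienna triplets are ``>id`` / sequence / structure lines; the TSV
    dialect has an id column and a structure column.  Every structure is
    validated (balanced brackets; length matched to the sequence when one
    is present) and errors name the offending record.
    """
    text = Path(path).read_text()
    lines = [ln.rstrip("\n") for ln in text.splitlines() if ln.strip()]
    if not lines:
        return []
    out: list[tuple[str, str]] = []
    if lines[0].startswith(">"):
        i = 0
        while i < len(lines):
            if not lines[i].startswith(">"):
                raise ValueError(f"expected header at line {i + 1}")
            rid = lines[i][1:].split()[0]
            if i + 2 >= len(lines):
                raise ValueError(f"truncated record {rid!r}")
            seq, struct = lines[i + 1], lines[i + 2]
            _validate_structure(rid, struct, seq)
            out.append((rid, struct))
            i += 3
    else:
        start = 1 if lines[0].lower().startswith(("id", "#")) else 0
        for ln in lines[start:]:
            parts = ln.split("\t")
            if len(parts) < 2:
                raise ValueError(f"malformed structure line: {ln!r}")
            rid, struct = parts[0], parts[-1]
            _validate_structure(rid, struct, None)
            out.append((rid, struct))
    return out


def _validate_structure(rid: str, struct: str, seq: str | None) -> None:
    try:
        pair_table(struct)
    except ValueError as exc:
        raise ValueError(f"record {rid!r}: {exc}") from exc
    if seq is not None and len(seq) != len(struct):
        raise ValueError(f"record {rid!r}: sequence/structure length mismatch")


def write_structures(records, path) -> None:
    """Write (id, sequence, structure) triplets in Vienna style."""
    with open(path, "w") as fh:
        for rid, seq, struct in records:
            fh.write(f">{rid}\n{seq}\n{struct}\n")


# ---------------------------------------------------------------------------
# TSV


def write_tsv(df: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# splicebalance v{__version__}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_tsv(path) -> pd.DataFrame:
    # wobble is a 0/1 indicator string; numeric parsing would drop leading zeros
    return pd.read_csv(path, sep="\t", comment="#", dtype={"wobble": "string"})


# ---------------------------------------------------------------------------
# model container


def save_model(path, params: ModelParams) -> None:
    arrays: dict[str, np.ndarray] = {}
    meta: dict = {
        "format_version": MODEL_FORMAT_VERSION,
        "tool_version": __version__,
        "d": params.d,
        "B": float(params.B),
        "channel_order_seq": "ACGU",
        "channel_order_struct": "(.)",
        "struct_input_order": ["seq(4)", "struct(3)", "wobble(1)"],
        "scms": {},
    }
    for key, scm in params.scms.items():
        arrays[f"scm_{key}_alpha"] = scm.alpha
        arrays[f"scm_{key}_beta"] = scm.beta
        meta["scms"][key] = {
            "side": scm.side, "channels": scm.channels,
            "w": scm.w, "c": scm.c, "k": scm.k,
        }
    tuner = params.tuner
    if isinstance(tuner, TunerPrime):
        meta["tuner"] = {"variant": "prime", "nu": float(tuner.nu), "eta": float(tuner.eta)}
    elif isinstance(tuner, TunerFull):
        meta["tuner"] = {"variant": "full", "b3": float(tuner.b3), "r": float(tuner.r)}
        for name in ("w1", "b1", "W2", "b2", "w3"):
            arrays[f"tuner_{name}"] = getattr(tuner, name)
    else:  # pragma: no cover - defensive
        raise TypeError(f"unknown tuner type {type(tuner)}")
    arrays["_meta"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(str(path), **arrays)


def load_model(path) -> ModelParams:
    try:
        with np.load(str(path)) as data:
            arrays = {k: data[k] for k in data.files}
    except Exception as exc:
        raise ValueError(f"cannot read model file {path}: {exc}") from exc
    if "_meta" not in arrays:
        raise ValueError(f"{path} is not a splicebalance model file")
    meta = json.loads(arrays["_meta"].tobytes().decode())
    version = meta.get("format_version")
    if version != MODEL_FORMAT_VERSION:
        raise ValueError(
            f"model format version {version} not supported "
            f"(this build reads version {MODEL_FORMAT_VERSION})"
        )
    scms = {
        key: ScmParams(
            info["side"], info["channels"],
            alpha=arrays[f"scm_{key}_alpha"], beta=arrays[f"scm_{key}_beta"],
        )
        for key, info in meta["scms"].items()
    }
    tinfo = meta["tuner"]
    if tinfo["variant"] == "prime":
        tuner = TunerPrime(tinfo["nu"], tinfo["eta"])
    else:
        tuner = TunerFull(
            w1=arrays["tuner_w1"], b1=arrays["tuner_b1"],
            W2=arrays["tuner_W2"], b2=arrays["tuner_b2"],
            w3=arrays["tuner_w3"], b3=tinfo["b3"], r=tinfo["r"],
        )
    return ModelParams(scms=scms, B=meta["B"], tuner=tuner, d=meta["d"])
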