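"""Readers and writers: probe tables, model files, MEME export, FASTA,
GO annotations.

The model file is plain text: a small key/value header, then one section
per binding mode holding the L x 4 relative-affinity matrix (PSAM,
entries exp(-ddG/RT)), an optional (L-1) x 16 dinucleotide section, and
the per-view gamma profile.  write -> read is the identity on all
free-energy values to better than 1e-12.
"""

from __future__ import annotations

import hashlib
import logging
from pathlib import Path
from typing import Dict, List, Sequence, Union

import numpy as np
import pandas as pd
from Bio import SeqIO

from . import __version__
from .core import (
    BASES,
    FeatureModel,
    IntensityModel,
    PositionalBias,
    ProbeTable,
)
from .fitting import FitState
from .multimode import BindingModeSet, as_mode_set

logger = logging.getLogger(__name__)

__all__ = [
    "read_probe_table",
    "write_probe_table",
    "write_model",
    "read_model",
    "write_meme",
    "read_fasta",
    "read_annotation",
    "config_hash",
]

MODEL_FORMAT_VERSION = 1
_DI_COLS = [a + b for a in BASES for b in BASES]


def config_hash(config) -> str:
    """Short stable hash of a fit configuration, for output provenance."""
    text = repr(sorted(vars(config).items())) if hasattr(config, "__dict__") else repr(
        config
    )
    return hashlib.md5(text.encode()).hexdigest()[:10]


def _comment_header(extra: str = "") -> str:
    line = f"# pbmkit v{__version__}"
    if extra:
        line += f" {extra}"
    return line + "\n"


def read_probe_table(path: Union[str, Path]) -> ProbeTable:
    """Read a TSV probe table with header probe_id/sequence/intensity.

    Sequences are upper-cased; CRLF input is accepted.  Ragged rows,
    duplicate probe IDs, non-ACGT sequences and non-numeric intensities
    raise errors naming the offending line (1-based, header = line 1).
    """
    path = Path(path)
    rows: List[List[str]] = []
    numbers: List[int] = []
    with open(path, newline="") as fh:
        lines = fh.read().splitlines()
    header_no = None
    for i, raw in enumerate(lines, start=1):
        line = raw.rstrip("\r")
        if not line or line.startswith("#"):
            continue
        if header_no is None:
            header = line.split("\t")
            if header[:3] != ["probe_id", "sequence", "intensity"]:
                raise ValueError(
                    f"{path}: line {i}: expected header "
                    "'probe_id\\tsequence\\tintensity'"
                )
            header_no = i
            continue
        rows.append(line.split("\t"))
        numbers.append(i)
    if header_no is None:
        raise ValueError(f"{path}: missing header line")
    ids, seqs, vals = [], [], []
    seen = set()
    for fields, i in zip(rows, numbers):
        if len(fields) < 3:
            raise ValueError(f"{path}: line {i}: expected 3 tab-separated fields")
        pid, seq, inten = fields[0], fields[1].upper(), fields[2]
        if pid in seen:
            raise ValueError(f"{path}: line {i}: duplicate probe_id {pid!r}")
        seen.add(pid)
        bad = set(seq) - set(BASES)
        if bad:
            raise ValueError(
                f"{path}: line {i}: non-ACGT character(s) {sorted(bad)} in sequence"
            )
        try:
            val = float(inten)
        except ValueError:
            raise ValueError(
                f"{path}: line {i}: non-numeric intensity {inten!r}"
            ) from None
        ids.append(pid)
        seqs.append(seq)
        vals.append(val)
    return ProbeTable(ids, seqs, np.asarray(vals))


def write_probe_table(
    table: ProbeTable, path: Union[str, Path], extra_comment: str = ""
) -> None:
    df = pd.DataFrame(
        {
            "probe_id": table.probe_ids,
            "sequence": table.sequences,
            "intensity": table.intensities,
        }
    )
    with open(path, "w") as fh:
        fh.write(_comment_header(extra_comment))
        df.to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Model files


def _fmt(x: float) -> str:
    return format(float(x), ".17g")


def write_model(
    obj: Union[FitState, BindingModeSet, FeatureModel],
    path: Union[str, Path],
    extra_comment: str = "",
) -> None:
    """Serialise a fit result (or bare model) to the plain-text format."""
    if isinstance(obj, FitState):
        ms = as_mode_set(obj)
    elif isinstance(obj, FeatureModel):
        ms = BindingModeSet(
            modes=[obj],
            rel_ka=np.array([1.0]),
            biases=[PositionalBias(np.array([1.0]))],
            im=IntensityModel(),
        )
    else:
        ms = obj
    im = ms.im
    with open(path, "w") as fh:
        fh.write(_comment_header(extra_comment))
        fh.write(f"format_version: {MODEL_FORMAT_VERSION}\n")
        fh.write(f"n_modes: {ms.n_modes}\n")
        fh.write(f"beta0: {_fmt(im.beta0)}\n")
        fh.write(f"beta1: {_fmt(im.beta1)}\n")
        fh.write(f"saturating: {str(im.saturating).lower()}\n")
        if im.ddG_ns_over_RT is not None:
            fh.write(f"ddG_ns: {_fmt(im.ddG_ns_over_RT)}\n")
            fh.write(f"protein_scale: {_fmt(im.protein_scale)}\n")
        for j, (model, ka, bias) in enumerate(
            zip(ms.modes, ms.rel_ka, ms.biases), start=1
        ):
            fh.write(f"\n>mode {j}\n")
            fh.write(f"reference_seq: {model.reference_seq}\n")
            fh.write(f"rel_Ka: {_fmt(ka)}\n")
            fh.write(f"symmetric: {str(model.symmetric).lower()}\n")
            fh.write(f"strand_policy: {model.strand_policy}\n")
            fh.write(">psam\t" + "\t".join(BASES) + "\n")
            for row in np.exp(-model.mono):
                fh.write("\t".join(_fmt(v) for v in row) + "\n")
            if model.has_di:
                fh.write(">dinucleotides\t" + "\t".join(_DI_COLS) + "\n")
                for row in np.exp(-model.di):
                    fh.write("\t".join(_fmt(v) for v in row) + "\n")
            fh.write(">gamma\n")
            fh.write("\t".join(_fmt(v) for v in bias.gamma) + "\n")


def read_model(path: Union[str, Path]) -> BindingModeSet:
    """Read a model file back into a BindingModeSet; raises on version
    mismatch or truncation, never returning a partial model."""
    path = Path(path)
    lines = [
        ln.rstrip("\r")
        for ln in path.read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    header: Dict[str, str] = {}
    i = 0
    while i < len(lines) and not lines[i].startswith(">"):
        if ":" not in lines[i]:
            raise ValueError(f"{path}: malformed header line {lines[i]!r}")
        k, v = lines[i].split(":", 1)
        header[k.strip()] = v.strip()
        i += 1
    if header.get("format_version") != str(MODEL_FORMAT_VERSION):
        raise ValueError(
            f"{path}: unsupported model format version "
            f"{header.get('format_version')!r}"
        )
    n_modes = int(header["n_modes"])
    saturating = header.get("saturating", "false") == "true"
    im = IntensityModel(
        beta0=float(header["beta0"]),
        beta1=float(header["beta1"]),
        ddG_ns_over_RT=float(header["ddG_ns"]) if "ddG_ns" in header else None,
        protein_scale=float(header.get("protein_scale", 1.0)),
        saturating=saturating,
    )
    modes, kas, biases = [], [], []
    while i < len(lines):
        if not lines[i].startswith(">mode"):
            raise ValueError(f"{path}: expected '>mode' at line {lines[i]!r}")
        i += 1
        meta: Dict[str, str] = {}
        while i < len(lines) and not lines[i].startswith(">"):
            k, v = lines[i].split(":", 1)
            meta[k.strip()] = v.strip()
            i += 1
        ref = meta["reference_seq"]
        L = len(ref)

        def read_matrix(tag: str, nrows: int, ncols: int):
            nonlocal i
            if i >= len(lines) or not lines[i].startswith(">" + tag):
                raise ValueError(f"{path}: missing {tag} section")
            i += 1
            rows = []
            for _ in range(nrows):
                if i >= len(lines) or lines[i].startswith(">"):
                    raise ValueError(f"{path}: truncated {tag} section")
                vals = [float(x) for x in lines[i].split("\t")]
                if len(vals) != ncols:
                    raise ValueError(f"{path}: {tag} row has {len(vals)} columns")
                rows.append(vals)
                i += 1
            return np.array(rows)

        psam = read_matrix("psam", L, 4)
        di = None
        if i < len(lines) and lines[i].startswith(">dinucleotides"):
            di = -np.log(read_matrix("dinucleotides", L - 1, 16))
        if i >= len(lines) or not lines[i].startswith(">gamma"):
            raise ValueError(f"{path}: missing gamma section")
        i += 1
        if i >= len(lines) or lines[i].startswith(">"):
            raise ValueError(f"{path}: truncated gamma section")
        gamma = np.array([float(x) for x in lines[i].split("\t")])
        i += 1
        model = FeatureModel(
            ref,
            -np.log(psam),
            di,
            symmetric=meta.get("symmetric", "false") == "true",
            strand_policy=meta.get("strand_policy", "both"),
        )
        modes.append(model)
        kas.append(float(meta.get("rel_Ka", 1.0)))
        biases.append(PositionalBias(gamma))
    if len(modes) != n_modes:
        raise ValueError(
            f"{path}: header declares {n_modes} modes, found {len(modes)}"
        )
    return BindingModeSet(modes=modes, rel_ka=np.array(kas), biases=biases, im=im)


def write_meme(
    obj: Union[FitState, BindingModeSet, FeatureModel],
    path: Union[str, Path],
    name: str = "motif",
) -> None:
    """Minimal MEME-format export: each mode's PSAM column is normalised
    to a probability distribution."""
    if isinstance(obj, FitState):
        ms = as_mode_set(obj)
    elif isinstance(obj, FeatureModel):
        ms = BindingModeSet(
            [obj], np.array([1.0]), [PositionalBias(np.array([1.0]))],
            IntensityModel(),
        )
    else:
        ms = obj
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write("Background letter frequencies\n")
        fh.write("A 0.25 C 0.25 G 0.25 T 0.25\n")
        for j, model in enumerate(ms.modes, start=1):
            aff = np.exp(-model.mono)
            prob = aff / aff.sum(axis=1, keepdims=True)
            fh.write(f"\nMOTIF {name}_{j} {model.reference_seq}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {model.L} "
                "nsites= 20 E= 0\n"
            )
            for row in prob:
                fh.write(" " + " ".join(f"{v:.6f}" for v in row) + "\n")


def read_fasta(path: Union[str, Path]) -> Dict[str, str]:
    """FASTA sequences keyed by the first token of each header."""
    seqs: Dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seqs[rec.id] = str(rec.seq).upper()
    return seqs


def write_fasta(seqs: Dict[str, str], path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        for name, s in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(s), 70):
                fh.write(s[i : i + 70] + "\n")


def read_annotation(path: Union[str, Path]) -> Dict[str, List[str]]:
    """Two-column TSV (gene, category) -> gene -> list of categories."""
    ann: Dict[str, List[str]] = {}
    with open(path) as fh:
        for i, raw in enumerate(fh, start=1):
            line = raw.rstrip("\r\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}: line {i}: expected 2 columns")
            ann.setdefault(fields[0], []).append(fields[1])
    return ann


def write_annotation(ann: Dict[str, List[str]], path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        for g, cats in ann.items():
            for c in cats:
                fh.write(f"{g}\t{c}\n")
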