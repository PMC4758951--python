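"""Feature-based free-energy model of protein-DNA binding and the forward
prediction of probe fluorescence intensity.

The model describes transcription-factor binding specificity through
dimensionless free-energy differences ddG/RT relative to a reference
(highest-affinity) sequence.  The relative association constant of a
length-L window S is

    Ka(S) / Ka(S_ref) = exp(-ddG(S)/RT),

where ddG(S)/RT is a sum over sequence *features* of S: one mononucleotide
feature per position (a "block" of 4 mutually exclusive features) and,
optionally, one adjacent-dinucleotide feature per pair of neighbouring
positions (blocks of 16).  The exponentiated mononucleotide blocks form a
position-specific affinity matrix (PSAM); adding dinucleotide blocks yields
a feature-specific affinity model (FSAM).

A probe of length P offers 2*(P-L+1) "views" to the protein: every offset
on the forward strand plus the reverse complement of each forward window.
Measured probe intensity is modelled as

    y(S) = beta0 + beta1 * sum_v gamma_v * exp(-ddG(S_v)/RT)        (linear)

or, allowing binding saturation and non-specific binding,

    y(S) = beta0 + beta1 * sum_v x_v / (1 + x_v),
    x_v  = p * gamma_v * exp(-ddG(S_v)/RT) + exp(-ddG_ns/RT)        (saturating)

where gamma_v >= 0 is a per-view positional/orientational bias shared
across probes (max-normalised to 1), p is a free-protein concentration
scale and ddG_ns/RT accounts for non-specific binding.

Conventions used throughout the package:

* coordinates are 0-based, half-open;
* views are ordered all-forward then all-reverse, ascending offset; the
  reverse view at offset o is the reverse complement of the forward window
  at offset o;
* free energies are always stored as the dimensionless ratio ddG/RT.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import List, NamedTuple, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "BASES",
    "ProbeTable",
    "FeatureKey",
    "FeatureModel",
    "PositionalBias",
    "IntensityModel",
    "encode_sequences",
    "revcomp",
    "enumerate_views",
    "features_of",
    "ddG_over_RT",
    "relative_affinity",
    "predict_intensity",
    "view_codes",
    "view_ddG",
    "predict_batch",
    "n_views",
]

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

STRAND_BOTH = "both"
STRAND_FORWARD = "forward_only"
STRAND_REVERSE = "reverse_only"
_STRAND_POLICIES = (STRAND_BOTH, STRAND_FORWARD, STRAND_REVERSE)


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string over {A,C,G,T}."""
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


def _check_dna(seq: str) -> None:
    bad = set(seq) - set(BASES)
    if bad:
        raise ValueError(f"non-ACGT character(s) in sequence: {sorted(bad)}")


def encode_sequences(seqs: Sequence[str]) -> np.ndarray:
    """Encode equal-length DNA strings as an (n, len) uint8 array (A=0..T=3)."""
    if len(seqs) == 0:
        return np.zeros((0, 0), dtype=np.uint8)
    n, plen = len(seqs), len(seqs[0])
    raw = np.frombuffer("".join(seqs).encode("ascii"), dtype=np.uint8)
    if raw.size != n * plen:
        raise ValueError("sequences must all have the same length")
    lut = np.full(256, 255, dtype=np.uint8)
    for b, i in _BASE_INDEX.items():
        lut[ord(b)] = i
    enc = lut[raw].reshape(n, plen)
    if (enc == 255).any():
        raise ValueError("non-ACGT character in sequences")
    return enc


@dataclass
class ProbeTable:
    """A protein binding microarray probe table: IDs, equal-length DNA
    sequences, and background-subtracted fluorescence intensities."""

    probe_ids: List[str]
    sequences: List[str]
    intensities: np.ndarray

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if not (len(self.probe_ids) == len(self.sequences) == len(self.intensities)):
            raise ValueError("probe_ids, sequences and intensities must align")
        if len(self.sequences) > 0:
            plen = len(self.sequences[0])
            if any(len(s) != plen for s in self.sequences):
                raise ValueError("all probe sequences must have one fixed length")
            for s in self.sequences:
                _check_dna(s)
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities must be finite")

    def __len__(self) -> int:
        return len(self.probe_ids)

    @property
    def probe_length(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    def encoded(self) -> np.ndarray:
        return encode_sequences(self.sequences)


class FeatureKey(NamedTuple):
    """A single sequence feature: the identity of one base (order='mono')
    or of two adjacent bases (order='di') at a 0-based motif position."""

    order: str  # "mono" or "di"
    position: int
    bases: str


def features_of(window: str, include_di: bool = False) -> set:
    """The feature set of a length-L window: L mono keys and, if requested,
    L-1 adjacent-dinucleotide keys."""
    _check_dna(window)
    keys = {FeatureKey("mono", i, b) for i, b in enumerate(window)}
    if include_di:
        keys |= {
            FeatureKey("di", i, window[i : i + 2]) for i in range(len(window) - 1)
        }
    return keys


# dinucleotide pair code = 4*first + second; column order AA,AC,...,TT
DI_PAIRS = [a + b for a in BASES for b in BASES]


@dataclass
class FeatureModel:
    """Free-energy model over a length-L binding window.

    mono : (L, 4) array of ddG/RT, columns ordered A,C,G,T; by convention
        the reference base in each column has ddG = 0 (PSAM anchoring).
    di : optional (L-1, 16) array of ddG/RT for adjacent dinucleotides,
        pair columns ordered AA,AC,...,TT.  Dinucleotide values follow the
        beta_PSAM normalisation and are not zero-anchored.
    """

    reference_seq: str
    mono: np.ndarray
    di: Optional[np.ndarray] = None
    symmetric: bool = False
    strand_policy: str = STRAND_BOTH

    def __post_init__(self) -> None:
        _check_dna(self.reference_seq)
        self.mono = np.asarray(self.mono, dtype=float)
        L = len(self.reference_seq)
        if self.mono.shape != (L, 4):
            raise ValueError(f"mono block shape {self.mono.shape} != ({L}, 4)")
        if self.di is not None:
            self.di = np.asarray(self.di, dtype=float)
            if self.di.shape != (L - 1, 16):
                raise ValueError(f"di block shape {self.di.shape} != ({L - 1}, 16)")
        if self.strand_policy not in _STRAND_POLICIES:
            raise ValueError(f"unknown strand policy {self.strand_policy!r}")

    @property
    def L(self) -> int:
        return len(self.reference_seq)

    @property
    def has_di(self) -> bool:
        return self.di is not None

    @classmethod
    def from_reference(
        cls,
        reference_seq: str,
        off_reference_ddG: float = 1.0,
        include_di: bool = False,
        strand_policy: str = STRAND_BOTH,
    ) -> "FeatureModel":
        """Seed-anchored initial model: ddG=0 for reference bases, a common
        positive value elsewhere; dinucleotide blocks start at zero."""
        L = len(reference_seq)
        mono = np.full((L, 4), float(off_reference_ddG))
        for i, b in enumerate(reference_seq):
            mono[i, _BASE_INDEX[b]] = 0.0
        di = np.zeros((L - 1, 16)) if include_di else None
        return cls(reference_seq, mono, di, strand_policy=strand_policy)

    def copy(self) -> "FeatureModel":
        return replace(
            self,
            mono=self.mono.copy(),
            di=None if self.di is None else self.di.copy(),
        )

    def affinity_matrix(self) -> np.ndarray:
        """The PSAM: exp(-ddG/RT), shape (L, 4)."""
        return np.exp(-self.mono)


@dataclass
class PositionalBias:
    """Per-view multiplicative bias gamma_v >= 0, max-normalised to 1.

    The vector is indexed in view order (all forward offsets ascending,
    then all reverse offsets ascending) for one (probe length, L,
    strand policy) combination.
    """

    gamma: np.ndarray

    def __post_init__(self) -> None:
        self.gamma = np.asarray(self.gamma, dtype=float)
        if self.gamma.ndim != 1 or self.gamma.size == 0:
            raise ValueError("gamma must be a non-empty vector")
        if (self.gamma < 0).any():
            raise ValueError("gamma values must be >= 0")
        if not (self.gamma > 0).any():
            raise ValueError("at least one gamma must be > 0")

    @classmethod
    def flat(cls, n: int) -> "PositionalBias":
        return cls(np.ones(n))

    def normalised(self) -> "PositionalBias":
        return PositionalBias(self.gamma / self.gamma.max())


@dataclass
class IntensityModel:
    """Probe intensity response: intercept beta0, scale beta1 > 0 and, for
    the saturating form, a non-specific term ddG_ns/RT and a free-protein
    concentration scale (dimensionless [P]*Ka(S_ref))."""

    beta0: float = 0.0
    beta1: float = 1.0
    ddG_ns_over_RT: Optional[float] = None
    protein_scale: float = 1.0
    saturating: bool = False

    def __post_init__(self) -> None:
        if self.beta1 <= 0:
            raise ValueError("beta1 must be > 0")
        if self.saturating and self.ddG_ns_over_RT is None:
            raise ValueError("saturating model requires ddG_ns_over_RT")


def n_views(probe_len: int, L: int, strand_policy: str = STRAND_BOTH) -> int:
    per_strand = probe_len - L + 1
    return per_strand * (2 if strand_policy == STRAND_BOTH else 1)


def enumerate_views(
    probe_seq: str, L: int, strand_policy: str = STRAND_BOTH
) -> List[Tuple[int, str, str]]:
    """All placements of a length-L window on a probe.

    Returns (offset, strand, window) triples: forward windows at offsets
    0..len-L, then reverse windows (reverse complement of the forward
    window at the same offset), both in ascending offset order.
    """
    _check_dna(probe_seq)
    if L > len(probe_seq):
        raise ValueError("motif longer than probe")
    fwd = [(o, "+", probe_seq[o : o + L]) for o in range(len(probe_seq) - L + 1)]
    rev = [(o, "-", revcomp(w)) for o, _, w in fwd]
    if strand_policy == STRAND_FORWARD:
        return fwd
    if strand_policy == STRAND_REVERSE:
        return rev
    return fwd + rev


def ddG_over_RT(window: str, model: FeatureModel) -> float:
    """Sum of the model's feature free energies over a length-L window."""
    _check_dna(window)
    if len(window) != model.L:
        raise ValueError(f"window length {len(window)} != motif length {model.L}")
    idx = [_BASE_INDEX[b] for b in window]
    total = float(sum(model.mono[i, c] for i, c in enumerate(idx)))
    if model.has_di:
        total += float(
            sum(model.di[i, 4 * idx[i] + idx[i + 1]] for i in range(model.L - 1))
        )
    return total


def relative_affinity(window: str, model: FeatureModel) -> float:
    """Ka(window)/Ka(reference) = exp(-ddG/RT); 1 for the reference window
    of a mono-only model."""
    return float(np.exp(-ddG_over_RT(window, model)))


def _saturating_terms(x: np.ndarray) -> np.ndarray:
    # x/(1+x), stable for large x
    return x / (1.0 + x)


def predict_intensity(
    probe_seq: str,
    model: FeatureModel,
    bias: PositionalBias,
    im: IntensityModel,
) -> float:
    """Predicted intensity for one probe under the linear or saturating
    intensity model."""
    views = enumerate_views(probe_seq, model.L, model.strand_policy)
    if bias.gamma.size != len(views):
        raise ValueError(
            f"bias has {bias.gamma.size} gammas but probe has {len(views)} views"
        )
    aff = np.array([relative_affinity(w, model) for _, _, w in views])
    if im.saturating:
        x = im.protein_scale * bias.gamma * aff + np.exp(-im.ddG_ns_over_RT)
        return float(im.beta0 + im.beta1 * _saturating_terms(x).sum())
    return float(im.beta0 + im.beta1 * (bias.gamma * aff).sum())


# ---------------------------------------------------------------------------
# Vectorised engine used by the fitting stages.


def view_codes(
    enc: np.ndarray, L: int, strand_policy: str = STRAND_BOTH
) -> np.ndarray:
    """Base codes of every view of every probe: (n, V, L) uint8.

    View order matches :func:`enumerate_views`.
    """
    n, plen = enc.shape
    if L > plen:
        raise ValueError("motif longer than probe")
    k = plen - L + 1
    # forward windows via stride tricks on a contiguous copy
    s0, s1 = enc.strides
    fwd = np.lib.stride_tricks.as_strided(enc, shape=(n, k, L), strides=(s0, s1, s1))
    rev = (3 - fwd)[:, :, ::-1]
    if strand_policy == STRAND_FORWARD:
        return np.ascontiguousarray(fwd)
    if strand_policy == STRAND_REVERSE:
        return np.ascontiguousarray(rev)
    return np.concatenate([fwd, rev], axis=1)


_POS_IDX_CACHE: dict = {}


def view_ddG(codes: np.ndarray, model: FeatureModel) -> np.ndarray:
    """ddG/RT of every view: (n, V) float array."""
    L = model.L
    if codes.shape[-1] != L:
        raise ValueError("view codes do not match motif length")
    pos = np.arange(L)
    total = model.mono[pos, codes].sum(axis=-1)
    if model.has_di:
        pair = 4 * codes[..., :-1].astype(np.intp) + codes[..., 1:]
        total = total + model.di[np.arange(L - 1), pair].sum(axis=-1)
    return total


def predict_batch(
    enc: np.ndarray,
    model: FeatureModel,
    gamma: np.ndarray,
    im: IntensityModel,
    codes: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Vectorised :func:`predict_intensity` over encoded probes."""
    if codes is None:
        codes = view_codes(enc, model.L, model.strand_policy)
    aff = np.exp(-view_ddG(codes, model))
    if gamma.shape[0] != aff.shape[1]:
        raise ValueError("gamma length does not match number of views")
    if im.saturating:
        x = im.protein_scale * gamma[None, :] * aff + np.exp(-im.ddG_ns_over_RT)
        return im.beta0 + im.beta1 * _saturating_terms(x).sum(axis=1)
    return im.beta0 + im.beta1 * (aff * gamma[None, :]).sum(axis=1)
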