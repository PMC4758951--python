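"""Independent brute-force oracles used by the tests.

These deliberately avoid the package's vectorised machinery: windows are
extracted with plain string slicing, reverse complements are built with a
local table, and free energies are summed feature-by-feature from
dictionaries, so that agreement with the library is a real cross-check.
"""

from __future__ import annotations

import math

import numpy as np

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def rc(seq: str) -> str:
    return "".join(_COMP[b] for b in seq[::-1])


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


def oracle_ddG(window: str, mono: dict, di: dict | None) -> float:
    """Sum of per-feature free energies from plain dictionaries keyed by
    (position, base) and (position, pair)."""
    total = sum(mono[(i, b)] for i, b in enumerate(window))
    if di is not None:
        total += sum(
            di[(i, window[i : i + 2])] for i in range(len(window) - 1)
        )
    return total


def model_as_dicts(model):
    mono = {
        (p, b): float(model.mono[p, i])
        for p in range(model.L)
        for i, b in enumerate("ACGT")
    }
    di = None
    if model.di is not None:
        di = {
            (p, a + b): float(model.di[p, 4 * i + j])
            for p in range(model.L - 1)
            for i, a in enumerate("ACGT")
            for j, b in enumerate("ACGT")
        }
    return mono, di


def oracle_predict(
    probe: str,
    model,
    gamma,
    beta0: float,
    beta1: float,
    saturating: bool = False,
    ddG_ns: float | None = None,
    protein_scale: float = 1.0,
) -> float:
    """Brute-force probe intensity: loop over every substring and its
    reverse complement (forward block first, then reverse, ascending
    offset), matching no internal code path of the package."""
    mono, di = model_as_dicts(model)
    L = model.L
    windows = [probe[o : o + L] for o in range(len(probe) - L + 1)]
    if model.strand_policy == "both":
        views = windows + [rc(w) for w in windows]
    elif model.strand_policy == "forward_only":
        views = windows
    else:
        views = [rc(w) for w in windows]
    total = 0.0
    for g, w in zip(gamma, views):
        aff = math.exp(-oracle_ddG(w, mono, di))
        if saturating:
            x = protein_scale * g * aff + math.exp(-ddG_ns)
            total += x / (1.0 + x)
        else:
            total += g * aff
    return beta0 + beta1 * total


def random_model(rng: np.random.Generator, L: int, with_di: bool = False):
    from pbmkit.core import FeatureModel

    ref = random_dna(rng, L)
    mono = rng.uniform(0.0, 3.0, size=(L, 4))
    for i, b in enumerate(ref):
        mono[i, "ACGT".index(b)] = 0.0
    di = rng.uniform(-0.5, 0.5, size=(L - 1, 16)) if with_di else None
    return FeatureModel(ref, mono, di)
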