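"""Post-fit structural refinement of a binding model.

Three refinements: (1) palindrome detection — separate forward-only and
reverse-only PSAM fits are compared under the L1 norm on the affinity
scale, and if close the model is rebuilt from the best symmetric seed
with reverse-complement-tied parameters; (2) motif-length selection —
columns are greedily added to either side of the PSAM while held-out R^2
keeps improving; (3) the poly-G/C strand rule — motifs with runs of four
or more G (or C) are modelled from a single strand because probe
synthesis biases such sequences.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import replace
from typing import Optional, Tuple, Union

import numpy as np

from .core import (
    STRAND_FORWARD,
    STRAND_REVERSE,
    FeatureModel,
    IntensityModel,
    PositionalBias,
    ProbeTable,
    revcomp,
    view_codes,
    view_ddG,
)
from .fitting import (
    FitConfig,
    FitState,
    _cycle_blocks,
    _fit_scale,
    _reanchor_mono,
    polyGC_strand_policy,
    r_squared,
)

logger = logging.getLogger(__name__)

__all__ = [
    "detect_palindrome",
    "symmetrize",
    "select_motif_length",
    "apply_polyGC_rule",
]

_RC_MONO = [3, 2, 1, 0]  # column permutation A,C,G,T -> T,G,C,A
# dinucleotide pair (a,b) -> (comp b, comp a)
_RC_DI = [4 * (3 - (c % 4)) + (3 - (c // 4)) for c in range(16)]


def _rc_mono_matrix(mono: np.ndarray) -> np.ndarray:
    return mono[::-1][:, _RC_MONO]


def _rc_di_matrix(di: np.ndarray) -> np.ndarray:
    return di[::-1][:, _RC_DI]


def _subset(probes: ProbeTable, idx: np.ndarray) -> ProbeTable:
    return ProbeTable(
        probe_ids=[probes.probe_ids[i] for i in idx],
        sequences=[probes.sequences[i] for i in idx],
        intensities=probes.intensities[idx],
    )


def _mono_fit_from(
    reference: str,
    probes: ProbeTable,
    config: FitConfig,
    strand_policy: str,
    init_mono: Optional[np.ndarray] = None,
    project=None,
    reanchor: bool = True,
    symmetric: bool = False,
) -> FitState:
    """Mono-only block-cycling fit anchored at a given reference; used by
    the refinement steps, which control seed, strand policy and parameter
    tying themselves."""
    model = FeatureModel.from_reference(
        reference, config.off_reference_init, strand_policy=strand_policy
    )
    model.symmetric = symmetric
    if init_mono is not None:
        model.mono = init_mono.copy()
    enc = probes.encoded()
    codes = view_codes(enc, model.L, strand_policy)
    state = FitState(
        model=model,
        bias=PositionalBias.flat(codes.shape[1]),
        im=IntensityModel(),
        weights=np.ones(len(probes)),
        seed=reference,
    )
    _cycle_blocks("mono", state, codes, probes.intensities, config, "mono",
                  project=project)
    if reanchor:
        _reanchor_mono(state)
    _fit_scale(state, codes, probes.intensities, config)
    state.beta_psam = state.im.beta1
    return state


def detect_palindrome(
    probes: ProbeTable, state: FitState, config: FitConfig
) -> Tuple[bool, float]:
    """Fit strand-specific PSAMs and compare them.

    The reverse-strand PSAM is reverse-complemented and compared with the
    forward-strand PSAM as relative affinities; the motif is flagged
    palindromic when the mean per-column L1 distance is within the
    configured tolerance.
    """
    ref = state.model.reference_seq
    cheap = replace(config, max_outer_rounds=min(config.max_outer_rounds, 10))
    st_f = _mono_fit_from(ref, probes, cheap, STRAND_FORWARD,
                          init_mono=state.model.mono)
    st_r = _mono_fit_from(ref, probes, cheap, STRAND_REVERSE,
                          init_mono=state.model.mono)
    af = st_f.model.affinity_matrix()
    ar = _rc_mono_matrix(st_r.model.mono)
    ar = np.exp(-(ar - ar.min(axis=1, keepdims=True)))  # re-anchor columns
    af = np.exp(
        -(st_f.model.mono - st_f.model.mono.min(axis=1, keepdims=True))
    )
    dist = float(np.abs(af - ar).sum(axis=1).mean())
    return dist <= config.palindrome_tol, dist


def _symmetric_candidates(L: int):
    if L % 2 == 0:
        for half in itertools.product("ACGT", repeat=L // 2):
            w = "".join(half)
            yield w + revcomp(w)
    else:
        for half in itertools.product("ACGT", repeat=L // 2):
            w = "".join(half)
            for c in "ACGT":
                yield w + c + revcomp(w)


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def symmetrize(
    state: FitState, probes: ProbeTable, config: FitConfig
) -> FitState:
    """Rebuild the model with exact reverse-complement symmetry.

    The best symmetric seed within Hamming distance 2 of the current
    reference (highest affinity under the current model) re-anchors the
    fit, and after every block round the matrix is projected onto the
    tied subspace ddG(p, b) == ddG(L-1-p, complement(b)).  For odd L this
    also ties the centre column's complementary base pairs, which is what
    makes affinity(S) == affinity(revcomp(S)) hold exactly.  If no
    symmetric seed is close enough the untied state is returned.
    """
    from .core import ddG_over_RT

    model = state.model
    best, best_aff = None, -np.inf
    for cand in _symmetric_candidates(model.L):
        if _hamming(cand, model.reference_seq) <= 2:
            aff = -ddG_over_RT(cand, model)
            if aff > best_aff:
                best, best_aff = cand, aff
    if best is None:
        logger.warning(
            "no symmetric seed within Hamming distance 2 of %s; keeping "
            "untied model",
            model.reference_seq,
        )
        return state

    def project(m: FeatureModel) -> None:
        m.mono = 0.5 * (m.mono + _rc_mono_matrix(m.mono))
        if m.di is not None:
            m.di = 0.5 * (m.di + _rc_di_matrix(m.di))

    new = _mono_fit_from(
        best, probes, config, model.strand_policy, project=project,
        reanchor=False, symmetric=True,
    )
    project(new.model)
    if model.has_di:
        enc = probes.encoded()
        codes = view_codes(enc, new.model.L, new.model.strand_policy)
        new.model.di = np.zeros((new.model.L - 1, 16))
        _cycle_blocks("di", new, codes, probes.intensities, config, "di",
                      project=project)
        _fit_scale(new, codes, probes.intensities, config)
    new.model.symmetric = True
    new.history = state.history + new.history
    return new


def _holdout_r2(
    state: FitState, probes: ProbeTable, idx: np.ndarray
) -> float:
    """R^2 of the specific-signal regression on held-out probes."""
    sub = _subset(probes, idx)
    codes = view_codes(sub.encoded(), state.model.L, state.model.strand_policy)
    F = (state.bias.gamma[None, :] * np.exp(-view_ddG(codes, state.model))).sum(1)
    y = sub.intensities
    X = np.column_stack([np.ones(len(y)), F])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    return r_squared(y, X @ coef)


def select_motif_length(
    probes: ProbeTable, state: FitState, config: FitConfig
) -> FitState:
    """Greedy motif-length selection.

    Columns are added one at a time to either side of the PSAM; after
    each growth the model is refit on a training split and kept only if
    R^2 on a held-out split (seeded 10% of probes) improves.  Growth on a
    side stops at the first decrease or at the probe boundary.
    """
    rng = np.random.default_rng(config.rng_seed)
    n = len(probes)
    hold = rng.choice(n, size=max(1, int(round(config.holdout_frac * n))),
                      replace=False)
    train = np.setdiff1d(np.arange(n), hold)
    train_probes = _subset(probes, train)

    def refit(reference: str, init_mono: np.ndarray) -> FitState:
        return _mono_fit_from(
            reference, train_probes, config, state.model.strand_policy,
            init_mono=init_mono,
        )

    current = refit(state.model.reference_seq, state.model.mono)
    current_r2 = _holdout_r2(current, probes, hold)
    open_side = {"left": True, "right": True}
    while any(open_side.values()):
        for side in ("left", "right"):
            if not open_side[side]:
                continue
            m = current.model
            if m.L + 1 > probes.probe_length:
                logger.info("growth on %s side refused: probe boundary", side)
                open_side[side] = False
                continue
            zero = np.zeros((1, 4))
            if side == "left":
                ref, mono = "A" + m.reference_seq, np.vstack([zero, m.mono])
            else:
                ref, mono = m.reference_seq + "A", np.vstack([m.mono, zero])
            grown = refit(ref, mono)
            r2 = _holdout_r2(grown, probes, hold)
            logger.info(
                "grow %s: L=%d held-out R2 %.4f -> %.4f", side, grown.model.L,
                current_r2, r2,
            )
            if r2 > current_r2:
                current, current_r2 = grown, r2
            else:
                open_side[side] = False
    if current.model.L == state.model.L and state.model.has_di:
        return state
    if state.model.has_di:
        enc = probes.encoded()
        codes = view_codes(enc, current.model.L, current.model.strand_policy)
        current.model.di = np.zeros((current.model.L - 1, 16))
        _cycle_blocks("di", current, codes, probes.intensities, config, "di")
        _fit_scale(current, codes, probes.intensities, config)
    return current


def apply_polyGC_rule(seed_or_model: Union[str, FeatureModel]) -> str:
    """Strand policy for a motif: >= 4 consecutive C -> forward only,
    >= 4 consecutive G -> reverse only, otherwise both strands."""
    seq = (
        seed_or_model
        if isinstance(seed_or_model, str)
        else seed_or_model.reference_seq
    )
    return polyGC_strand_policy(seq)
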