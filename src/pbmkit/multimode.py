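"""Forward selection and joint refinement of multiple binding modes.

Oligomeric factors can engage DNA in distinct geometries (e.g. bZIP
dimers binding half-sites with or without a 1-bp overlap).  Each mode
gets its own free-energy model; the combined intensity model is additive,

    y(S) = beta0 + beta1 * sum_m relKa_m * sum_v gamma_v exp(-ddG_m(S_v)/RT),

with mode 1 anchored at relative Ka 1.  The procedure: (i) fit a single
mode; (ii) fit further modes to the residuals of the current combined
model; (iii) iteratively re-fit each mode against the signal left over by
the others, blending old and new free energies with step alpha; (iv) a
final robust multiple regression yields the relative Ka coefficients and
per-mode significance, dropping non-significant modes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import List, Optional, Tuple

import numpy as np
import statsmodels.api as sm

from .core import (
    FeatureModel,
    IntensityModel,
    PositionalBias,
    ProbeTable,
    enumerate_views,
    revcomp,
    view_codes,
    view_ddG,
)
from .fitting import FitConfig, FitState, fit_model, irls_fit, r_squared

logger = logging.getLogger(__name__)

__all__ = ["BindingModeSet", "fit_multimode", "dominant_mode", "as_mode_set"]


@dataclass
class BindingModeSet:
    """One or more binding modes sharing a single intensity response.

    rel_ka[0] == 1 by construction; rel_ka[m] is the association constant
    of mode m's reference site relative to mode 1's.
    """

    modes: List[FeatureModel]
    rel_ka: np.ndarray
    biases: List[PositionalBias]
    im: IntensityModel
    mode_pvalues: Optional[np.ndarray] = None
    r2_train: float = float("nan")

    def __post_init__(self) -> None:
        self.rel_ka = np.asarray(self.rel_ka, dtype=float)
        if len(self.modes) != len(self.rel_ka) or len(self.modes) != len(self.biases):
            raise ValueError("modes, rel_ka and biases must align")
        if abs(self.rel_ka[0] - 1.0) > 1e-12:
            raise ValueError("mode 1 must be anchored at relative Ka 1")
        if (self.rel_ka <= 0).any():
            raise ValueError("relative Ka must be > 0")

    @property
    def n_modes(self) -> int:
        return len(self.modes)

    def mode_signals(self, probes: ProbeTable) -> np.ndarray:
        """Per-mode specific signal F_m(S), shape (n_probes, n_modes)."""
        enc = probes.encoded()
        F = np.empty((len(probes), self.n_modes))
        for j, (model, bias) in enumerate(zip(self.modes, self.biases)):
            codes = view_codes(enc, model.L, model.strand_policy)
            F[:, j] = (bias.gamma[None, :] * np.exp(-view_ddG(codes, model))).sum(1)
        return F

    def predict(self, probes: ProbeTable) -> np.ndarray:
        F = self.mode_signals(probes)
        return self.im.beta0 + self.im.beta1 * (F * self.rel_ka[None, :]).sum(1)


def as_mode_set(state: FitState) -> BindingModeSet:
    """Wrap a single-mode fit as a one-mode BindingModeSet."""
    return BindingModeSet(
        modes=[state.model],
        rel_ka=np.array([1.0]),
        biases=[state.bias],
        im=state.im,
        r2_train=state.r2_train,
    )


def _duplicate(a: FeatureModel, b: FeatureModel, tol: float = 0.05) -> bool:
    if a.reference_seq in (b.reference_seq, revcomp(b.reference_seq)):
        return True
    if a.L == b.L:
        if np.abs(a.mono - b.mono).mean() < tol:
            return True
        rc = b.mono[::-1][:, [3, 2, 1, 0]]
        if np.abs(a.mono - rc).mean() < tol:
            return True
    return False


def _joint_regression(
    y: np.ndarray, F: np.ndarray, config: FitConfig
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Robust multiple regression of y on per-mode signals.

    Returns (coefficients incl. intercept, weights, p-values of the mode
    coefficients from the weighted final fit)."""
    X = np.column_stack([np.ones(len(y)), F])
    coef, w = irls_fit(X, y, config)
    keep = w > 0
    res = sm.WLS(y[keep], X[keep], weights=w[keep]).fit()
    return res.params, w, res.pvalues[1:]


def fit_multimode(
    probes: ProbeTable,
    config: Optional[FitConfig] = None,
    max_modes: int = 2,
) -> BindingModeSet:
    """Forward selection of up to `max_modes` binding modes.

    Residual fits that rediscover an existing mode (same or reverse-
    complement seed, or mono free energies within 0.05 mean L1) stop the
    selection.  Modes whose final-regression p-value exceeds the
    configured threshold (default 0.01), or whose coefficient is not
    positive, are dropped.
    """
    if max_modes < 1:
        raise ValueError("max_modes must be >= 1")
    config = config or FitConfig()
    y = probes.intensities

    state1 = fit_model(probes, config)
    states: List[FitState] = [state1]
    if max_modes == 1:
        return as_mode_set(state1)

    sub_cfg = replace(config, symmetry="off", grow_motif=False, saturation=False)

    def signals(sts: List[FitState]) -> np.ndarray:
        F = np.empty((len(probes), len(sts)))
        enc = probes.encoded()
        for j, st in enumerate(sts):
            codes = view_codes(enc, st.model.L, st.model.strand_policy)
            F[:, j] = (
                st.bias.gamma[None, :] * np.exp(-view_ddG(codes, st.model))
            ).sum(1)
        return F

    # (ii) fit additional modes to residuals of the current combined model
    while len(states) < max_modes:
        F = signals(states)
        coef, _, _ = _joint_regression(y, F, config)
        resid = y - coef[0] - F @ coef[1:]
        cand = fit_model(
            ProbeTable(probes.probe_ids, probes.sequences, resid), sub_cfg
        )
        dup = any(_duplicate(cand.model, st.model) for st in states)
        if not dup:
            # a shifted or partial rediscovery of an existing mode has a
            # near-identical per-probe signal even though the matrices
            # differ; compare explanatory signals directly
            Fc = signals([cand])[:, 0]
            dup = any(
                np.corrcoef(Fc, F[:, j])[0, 1] > 0.9
                for j in range(F.shape[1])
            )
        if dup:
            logger.info("no additional mode: residual fit duplicates an "
                        "existing mode (%s)", cand.model.reference_seq)
            break
        states.append(cand)

    # (iii) iterative refinement: re-fit each mode against what the other
    # modes leave unexplained, blending on the ddG/RT scale
    from .refine import _mono_fit_from

    for it in range(config.mode_max_iter):
        if len(states) == 1:
            break
        F = signals(states)
        coef, _, _ = _joint_regression(y, F, config)
        max_delta = 0.0
        for j, st in enumerate(states):
            others = coef[0] + F @ coef[1:] - coef[1 + j] * F[:, j]
            target = y - others
            refit = _mono_fit_from(
                st.model.reference_seq,
                ProbeTable(probes.probe_ids, probes.sequences, target),
                sub_cfg,
                st.model.strand_policy,
                init_mono=st.model.mono,
            )
            new_mono = (1 - config.alpha) * st.model.mono + config.alpha * (
                refit.model.mono
            )
            new_mono -= new_mono.min(axis=1, keepdims=True)
            max_delta = max(max_delta, float(np.abs(new_mono - st.model.mono).max()))
            st.model.mono = new_mono
            st.bias = refit.bias
        logger.info("mode refinement iter %d: max|d ddG|=%.3g", it + 1, max_delta)
        if max_delta < config.mode_tol:
            break

    # (iv) final joint robust regression: relative Ka and significance.
    # A retained mode must be individually significant AND contribute a
    # non-trivial share of explained variance — residual-stage selection
    # makes raw p-values optimistic on the training data.
    F = signals(states)
    coef, w, pvals = _joint_regression(y, F, config)
    X_full = np.column_stack([np.ones(len(y)), F])
    r2_full = r_squared(y, X_full @ coef, w)
    incr = np.empty(len(states))
    for j in range(len(states)):
        Xj = np.delete(X_full, 1 + j, axis=1)
        cj = np.linalg.lstsq(Xj * np.sqrt(w)[:, None], y * np.sqrt(w),
                             rcond=None)[0]
        incr[j] = r2_full - r_squared(y, Xj @ cj, w)
    keep = [
        j
        for j in range(len(states))
        if coef[1 + j] > 0
        and pvals[j] <= config.mode_pvalue
        and incr[j] >= config.mode_min_r2
    ]
    if not keep:
        keep = [int(np.argmax(coef[1:]))]
    dropped = [j for j in range(len(states)) if j not in keep]
    for j in dropped:
        logger.info(
            "mode %d (%s) dropped: coef=%.3g p=%.3g",
            j + 1, states[j].model.reference_seq, coef[1 + j], pvals[j],
        )
    order = sorted(keep, key=lambda j: -coef[1 + j])
    c = coef[1 + np.array(order)]
    modeset = BindingModeSet(
        modes=[states[j].model for j in order],
        rel_ka=c / c[0],
        biases=[states[j].bias for j in order],
        im=IntensityModel(beta0=float(coef[0]), beta1=float(c[0])),
        mode_pvalues=pvals[np.array(order)],
    )
    modeset.r2_train = r_squared(y, modeset.predict(probes), w)
    return modeset


def dominant_mode(seq: str, modeset: BindingModeSet) -> int:
    """Index of the mode with the largest relKa-weighted best-view
    affinity on this sequence; ties break toward the lowest index."""
    if len(seq) < min(m.L for m in modeset.modes):
        raise ValueError("sequence shorter than every mode")
    best_idx, best_score = 0, -np.inf
    for j, model in enumerate(modeset.modes):
        if model.L > len(seq):
            continue
        from .core import relative_affinity

        score = modeset.rel_ka[j] * max(
            relative_affinity(w, model)
            for _, _, w in enumerate_views(seq, model.L, model.strand_policy)
        )
        if score > best_score + 1e-15:
            best_idx, best_score = j, score
    return best_idx
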