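"""Robust block-wise estimation of the free-energy model from PBM data.

The workflow: (1) a trimmed-mean K-mer fit picks the seed; (2) with the
seed as reference, each mononucleotide block (PSAM column) is re-estimated
in turn by robust linear regression; (3) the positional bias profile
gamma_v is re-estimated each round; (4) optionally, the saturating
intensity model (free-protein scale and non-specific binding term) is fit
by Levenberg-Marquardt; (5) dinucleotide blocks are fit after the PSAM has
converged; rounds repeat until the free energies stabilise.

Block regression.  Holding all other free energies fixed, probe intensity
is linear in the per-feature coefficients beta_phi of one block B:

    y(S) = beta0 + sum_{phi in B} beta_phi
                   * sum_{v in V_phi(S)} gamma_v exp(-(ddG(S_v) - ddG_phi)/RT)

where V_phi(S) are the views of S containing feature phi.  The fitted
coefficients convert back to free energies via

    ddG_phi/RT = -log(beta_phi / beta_PSAM),

with beta_PSAM the overall scale beta1 recorded when only mononucleotide
features are fit.  Mononucleotide blocks are then re-anchored so the
reference base sits at ddG = 0; dinucleotide blocks keep the beta_PSAM
normalisation, which leaves most of their values near zero.

Robust regression is iteratively reweighted least squares with Huber
weights plus hard trimming of the worst 20% of probes, which protects the
fit from bright-spot outliers and other heavy-tailed artifacts.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from typing import List, Optional, Tuple

import numpy as np
from scipy.optimize import least_squares

from .core import (
    STRAND_BOTH,
    STRAND_FORWARD,
    STRAND_REVERSE,
    FeatureModel,
    IntensityModel,
    PositionalBias,
    ProbeTable,
    view_codes,
    view_ddG,
)
from .seed import find_seed

logger = logging.getLogger(__name__)

__all__ = [
    "FitConfig",
    "FitState",
    "irls_fit",
    "fit_block",
    "fit_positional_bias",
    "fit_nonlinear",
    "fit_model",
    "polyGC_strand_policy",
    "r_squared",
]


@dataclass
class FitConfig:
    """Hyperparameters of the fitting pipeline.

    trim_probes_frac : fraction of probes hard-trimmed (zero weight) per
        robust regression, default 0.20.
    seed_trim_frac : per-value trim in the seed-discovery stage (0.15).
    alpha : step size of the trimmed-mean seed update and of the
        multi-mode blending, default 0.1.
    huber_c : Huber tuning constant for the IRLS weights (1.345 gives 95%
        efficiency under Gaussian noise).
    robust : when False every regression falls back to ordinary least
        squares with no trimming (used for method contrasts).
    """

    K_seed: int = 8
    trim_probes_frac: float = 0.20
    seed_trim_frac: float = 0.15
    alpha: float = 0.1
    huber_c: float = 1.345
    max_outer_rounds: int = 20
    block_tol: float = 1e-4
    seed_tol: float = 1e-6
    seed_max_iter: int = 200
    rng_seed: int = 0
    include_di: bool = False
    saturation: bool = False
    robust: bool = True
    ddG_ceiling: float = 10.0
    off_reference_init: float = 1.0
    max_irls_iter: int = 50
    irls_tol: float = 1e-8
    fit_bias: bool = True
    polygc_rule: bool = True
    symmetry: str = "off"  # off | auto | on
    grow_motif: bool = False
    palindrome_tol: float = 0.1  # mean per-column L1 on the affinity scale
    holdout_frac: float = 0.1  # held-out split for motif-length selection
    max_modes: int = 1
    mode_pvalue: float = 0.01
    mode_min_r2: float = 0.01  # minimum incremental R^2 to retain a mode
    mode_tol: float = 1e-3
    mode_max_iter: int = 10

    def __post_init__(self) -> None:
        for name in ("trim_probes_frac", "seed_trim_frac"):
            v = getattr(self, name)
            if not 0 <= v < 0.5:
                raise ValueError(f"{name} must be in [0, 0.5)")
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must be in (0, 1]")
        if self.symmetry not in ("off", "auto", "on"):
            raise ValueError("symmetry must be off|auto|on")


@dataclass
class FitState:
    """Everything produced by a fit: the free-energy model, positional
    bias, intensity response, per-probe robustness weights, the frozen
    mono-only scale beta_PSAM and the training R^2."""

    model: FeatureModel
    bias: PositionalBias
    im: IntensityModel
    weights: np.ndarray
    beta_psam: Optional[float] = None
    r2_train: float = float("nan")
    history: List[dict] = field(default_factory=list)
    seed: Optional[str] = None

    def predict(self, probes: ProbeTable) -> np.ndarray:
        from .core import predict_batch

        return predict_batch(
            probes.encoded(), self.model, self.bias.gamma, self.im
        )


def r_squared(y: np.ndarray, yhat: np.ndarray, weights=None) -> float:
    """Coefficient of determination, optionally weighted."""
    y = np.asarray(y, float)
    yhat = np.asarray(yhat, float)
    w = np.ones_like(y) if weights is None else np.asarray(weights, float)
    sw = w.sum()
    ybar = (w * y).sum() / sw
    ss_res = (w * (y - yhat) ** 2).sum()
    ss_tot = (w * (y - ybar) ** 2).sum()
    return float(1.0 - ss_res / ss_tot) if ss_tot > 0 else float("nan")


# ---------------------------------------------------------------------------
# Robust linear regression


def _wls(X: np.ndarray, y: np.ndarray, w: np.ndarray) -> np.ndarray:
    sw = np.sqrt(w)
    coef, _, rank, _ = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)
    return coef


def _check_rank(X: np.ndarray) -> None:
    # identify (near-)collinear columns so the error is actionable
    _, s, vt = np.linalg.svd(X, full_matrices=False)
    tol = s.max() * max(X.shape) * np.finfo(float).eps if s.size else 0.0
    rank = int((s > tol).sum())
    if rank < X.shape[1]:
        null = np.abs(vt[rank:]).max(axis=0)
        cols = np.where(null > 1e-8)[0].tolist()
        raise ValueError(f"rank-deficient design: collinear columns {cols}")


def irls_fit(
    X: np.ndarray, y: np.ndarray, config: FitConfig
) -> Tuple[np.ndarray, np.ndarray]:
    """Iteratively reweighted least squares with Huber weights and hard
    trimming of the highest-residual probes.

    `X` is the full design matrix (include an intercept column if one is
    wanted).  Returns (coefficients, final per-probe weights in [0, 1]).
    With ``config.robust`` False this is plain least squares and all
    weights are 1.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n, p = X.shape
    if n < p + 1:
        raise ValueError("need at least cols+1 observations")
    _check_rank(X)
    w = np.ones(n)
    coef = _wls(X, y, w)
    if not config.robust:
        return coef, w
    n_trim = int(np.floor(config.trim_probes_frac * n))
    for _ in range(config.max_irls_iter):
        r = y - X @ coef
        absr = np.abs(r)
        sigma = 1.4826 * np.median(absr)
        if sigma <= 1e-12 * max(1.0, float(np.median(np.abs(y)))):
            w = np.ones(n)  # an (essentially) exact fit: nothing to trim
            break
        w = np.minimum(1.0, config.huber_c * sigma / np.maximum(absr, 1e-300))
        if n_trim > 0:
            w[np.argpartition(absr, n - n_trim)[n - n_trim :]] = 0.0
        new_coef = _wls(X, y, w)
        if np.max(np.abs(new_coef - coef)) <= config.irls_tol * max(
            1.0, np.max(np.abs(coef))
        ):
            coef = new_coef
            break
        coef = new_coef
    return coef, w


# ---------------------------------------------------------------------------
# Block updates


def _block_design(
    codes: np.ndarray,
    model: FeatureModel,
    gamma: np.ndarray,
    kind: str,
    position: int,
) -> np.ndarray:
    """Per-probe regressors for every feature of one block.

    Column for feature phi: sum over the views containing phi of
    gamma_v * exp(-(ddG(S_v) - ddG_phi)/RT).
    """
    E = gamma[None, :] * np.exp(-view_ddG(codes, model))  # (n, V)
    if kind == "mono":
        obs = codes[:, :, position]
        old = model.mono[position]
        k = 4
    elif kind == "di":
        obs = 4 * codes[:, :, position].astype(np.intp) + codes[:, :, position + 1]
        old = model.di[position]
        k = 16
    else:
        raise ValueError(kind)
    R = np.empty((codes.shape[0], k))
    for f in range(k):
        R[:, f] = (E * (obs == f)).sum(axis=1) * np.exp(old[f])
    return R


def fit_block(
    position: int,
    kind: str,
    state: FitState,
    codes: np.ndarray,
    y: np.ndarray,
    config: FitConfig,
) -> np.ndarray:
    """Re-estimate the free energies of one block (mono column or di pair
    column) by robust regression, holding all other blocks fixed.

    Mono blocks are re-anchored so the reference base has ddG = 0; di
    blocks convert through the frozen beta_PSAM scale.  A coefficient
    beta_phi <= 0 (feature never observed bound) maps to the configured
    ddG ceiling.  Returns the new block values and updates the model.
    """
    model = state.model
    R = _block_design(codes, model, state.bias.gamma, kind, position)
    dead = ~(R != 0).any(axis=0)
    if dead.any():
        raise ValueError(
            f"feature(s) {np.where(dead)[0].tolist()} of {kind} block "
            f"{position} absent from every probe view"
        )
    # features carried only by negligible-affinity views give vanishing
    # regressors; they are unmeasurable and pinned at the ceiling
    norms = np.linalg.norm(R, axis=0)
    weak = norms < 1e-9 * norms.max()
    X = np.column_stack([np.ones(len(y)), R[:, ~weak]])
    coef, _ = irls_fit(X, y, config)
    beta = np.full(R.shape[1], -np.inf)
    beta[~weak] = coef[1:]
    if kind == "mono":
        from .core import _BASE_INDEX

        ref = _BASE_INDEX[model.reference_seq[position]]
        anchor = beta[ref]
        if anchor <= 0:
            anchor = beta.max()
            logger.warning(
                "mono block %d: reference-base coefficient <= 0; anchoring at max",
                position,
            )
        if anchor <= 0:
            raise ValueError(f"mono block {position}: all coefficients <= 0")
        new = np.where(
            beta > 0, -np.log(np.maximum(beta, 1e-300) / anchor), config.ddG_ceiling
        )
        new = np.clip(new, -config.ddG_ceiling, config.ddG_ceiling)
        model.mono[position] = new
    else:
        scale = state.beta_psam
        if scale is None or scale <= 0:
            raise ValueError("di block fit requires a recorded beta_PSAM > 0")
        new = np.where(
            beta > 0, -np.log(np.maximum(beta, 1e-300) / scale), config.ddG_ceiling
        )
        new = np.clip(new, -config.ddG_ceiling, config.ddG_ceiling)
        model.di[position] = new
    return new


def fit_positional_bias(
    state: FitState, codes: np.ndarray, y: np.ndarray, config: FitConfig
) -> PositionalBias:
    """Estimate the per-view bias profile gamma_v by robust regression of
    intensities on the per-view affinities exp(-ddG(S_v)/RT), clipping
    negatives to zero and max-normalising; the scale folds into beta1.

    For an exactly reverse-complement-symmetric model the two strands of
    an offset carry identical affinities, so gamma is tied per offset."""
    A = np.exp(-view_ddG(codes, state.model))  # (n, V)
    n, V = A.shape
    tie = state.model.symmetric and state.model.strand_policy == STRAND_BOTH
    if tie:
        k = V // 2
        A = A[:, :k] + A[:, k:]
    if n < A.shape[1] + 2:
        raise ValueError(
            "fewer probes than views: pool offsets or smooth the gamma profile"
        )
    X = np.column_stack([np.ones(n), A])
    coef, w = irls_fit(X, y, config)
    g = np.maximum(coef[1:], 0.0)
    if tie:
        g = np.concatenate([g, g])
    if g.max() <= 0:
        logger.warning("all gamma estimates <= 0; keeping a flat profile")
        return PositionalBias.flat(V)
    scale = g.max()
    state.im = replace(state.im, beta0=float(coef[0]), beta1=float(scale))
    state.weights = w
    return PositionalBias(g / scale)


def _fit_scale(
    state: FitState, codes: np.ndarray, y: np.ndarray, config: FitConfig
) -> Tuple[float, float]:
    """Robust regression of y on the total specific signal; updates beta0,
    beta1 and the probe weights; returns (r2, trimmed mse)."""
    F = (state.bias.gamma[None, :] * np.exp(-view_ddG(codes, state.model))).sum(axis=1)
    X = np.column_stack([np.ones(len(y)), F])
    coef, w = irls_fit(X, y, config)
    beta0, beta1 = float(coef[0]), float(coef[1])
    if beta1 <= 0:
        logger.warning("non-positive beta1 in scale fit; clamping")
        beta1 = max(beta1, 1e-12)
    state.im = replace(state.im, beta0=beta0, beta1=beta1)
    state.weights = w
    yhat = beta0 + beta1 * F
    r2 = r_squared(y, yhat, w)
    state.r2_train = r2
    resid2 = np.sort((y - yhat) ** 2)
    keep = len(y) - int(np.floor(config.trim_probes_frac * len(y)))
    tmse = float(resid2[:keep].mean())
    return r2, tmse


def _cycle_blocks(
    kind: str,
    state: FitState,
    codes: np.ndarray,
    y: np.ndarray,
    config: FitConfig,
    phase: str,
    project=None,
) -> None:
    """Round-robin block updates with per-round gamma re-estimation until
    the free energies stabilise.  `kind` is "mono", "di", or "full" (all
    mono then all di blocks in each round).  `project`, if given, is
    applied to the model after every round (e.g. the reverse-complement-
    symmetry tie)."""
    L = state.model.L
    if kind == "mono":
        blocks = [("mono", p) for p in range(L)]
    elif kind == "di":
        blocks = [("di", p) for p in range(L - 1)]
    else:
        blocks = [("mono", p) for p in range(L)] + [
            ("di", p) for p in range(L - 1)
        ]

    def snapshot():
        parts = [state.model.mono.ravel()]
        if state.model.has_di:
            parts.append(state.model.di.ravel())
        return np.concatenate(parts)

    for rnd in range(1, config.max_outer_rounds + 1):
        before = snapshot()
        for k, p in blocks:
            fit_block(p, k, state, codes, y, config)
        if project is not None:
            project(state.model)
        if config.fit_bias:
            state.bias = fit_positional_bias(state, codes, y, config)
        delta = float(np.max(np.abs(snapshot() - before)))
        r2, tmse = _fit_scale(state, codes, y, config)
        state.history.append(
            {"phase": phase, "round": rnd, "max_delta": delta, "r2": r2,
             "trimmed_mse": tmse}
        )
        logger.info(
            "%s round %d: max|d ddG|=%.3g R2=%.4f", phase, rnd, delta, r2
        )
        if delta < config.block_tol:
            break


def _reanchor_mono(state: FitState) -> None:
    """Shift each mono column so its minimum is 0 and make the minimum
    base the reference; the column shifts are absorbed into beta1."""
    model = state.model
    mins = model.mono.min(axis=1)
    model.mono -= mins[:, None]
    shift = float(mins.sum())
    state.im = replace(state.im, beta1=state.im.beta1 * float(np.exp(-shift)))
    ref = []
    for p in range(model.L):
        col = model.mono[p]
        old = "ACGT".index(model.reference_seq[p])
        best = int(np.argmin(col))
        ref.append(model.reference_seq[p] if col[old] == col[best] else "ACGT"[best])
    model.reference_seq = "".join(ref)


def polyGC_strand_policy(seq: str) -> str:
    """Strand restriction for motifs with poly-G/C runs: probe synthesis
    replaces runs of >= 4 G on the printed strand, so a motif with >= 4
    consecutive C is modelled from the forward strand only, and one with
    >= 4 consecutive G from the reverse strand only."""
    if re.search("C{4}", seq):
        return STRAND_FORWARD
    if re.search("G{4}", seq):
        return STRAND_REVERSE
    return STRAND_BOTH


def fit_nonlinear(
    state: FitState, codes: np.ndarray, y: np.ndarray, config: FitConfig
) -> IntensityModel:
    """Levenberg-Marquardt fit of the saturating intensity model.

    Free parameters: beta0, beta1, the log free-protein scale and
    ddG_ns/RT (initialised large, i.e. near-zero non-specific binding).
    Probe weights from the robust linear stage are carried over.  If the
    optimiser fails the linear-stage parameters are returned unchanged.
    """
    A = state.bias.gamma[None, :] * np.exp(-view_ddG(codes, state.model))
    sw = np.sqrt(state.weights)

    def resid(p):
        b0, b1, log_s, ddg_ns = p
        x = np.exp(np.clip(log_s, -30.0, 30.0)) * A + np.exp(
            -np.clip(ddg_ns, -30.0, 700.0)
        )
        pred = b0 + b1 * (x / (1.0 + x)).sum(axis=1)
        return sw * (pred - y)

    # the cost surface has a near-linear local optimum at small protein
    # scale; start LM from several concentration regimes and keep the best
    best = None
    for log_s in (-2.0, 0.0, 2.0, 4.0):
        x0 = np.array([state.im.beta0, 2.0 * state.im.beta1, log_s, 10.0])
        try:
            res = least_squares(resid, x0, method="lm", max_nfev=500 * len(x0))
        except Exception as exc:  # pragma: no cover - defensive
            logger.warning("nonlinear fit raised %s", exc)
            continue
        if res.success and res.x[1] > 0 and (best is None or res.cost < best.cost):
            best = res
    res, ok = best, best is not None
    if not ok:
        logger.warning(
            "saturating fit did not converge; keeping linear-stage parameters"
        )
        return replace(state.im, saturating=False)
    b0, b1, log_s, ddg_ns = res.x
    return IntensityModel(
        beta0=float(b0),
        beta1=float(b1),
        ddG_ns_over_RT=float(ddg_ns),
        protein_scale=float(np.exp(log_s)),
        saturating=True,
    )


def fit_model(
    probes: ProbeTable,
    config: Optional[FitConfig] = None,
    *,
    seed_kmer: Optional[str] = None,
    seed_table=None,
) -> FitState:
    """Full single-mode fitting pipeline.

    Seed discovery -> seed-anchored initial model -> mono block rounds
    with per-round gamma re-estimation (converged PSAM, beta_PSAM frozen)
    -> optional dinucleotide rounds -> optional saturating fit -> optional
    structural refinement (palindromic symmetrisation, motif-length
    growth) as configured.  Pass ``seed_kmer`` to skip seed discovery.
    """
    config = config or FitConfig()
    if len(probes) == 0:
        raise ValueError("no probes")
    y = probes.intensities
    if seed_kmer is None:
        seed_kmer, seed_table = find_seed(
            probes,
            config.K_seed,
            alpha=config.alpha,
            trim_frac=config.seed_trim_frac,
            tol=config.seed_tol,
            max_iter=config.seed_max_iter,
        )
        logger.info("seed: %s", seed_kmer)
    policy = polyGC_strand_policy(seed_kmer) if config.polygc_rule else STRAND_BOTH
    model = FeatureModel.from_reference(
        seed_kmer, config.off_reference_init, strand_policy=policy
    )
    enc = probes.encoded()
    codes = view_codes(enc, model.L, policy)
    V = codes.shape[1]
    state = FitState(
        model=model,
        bias=PositionalBias.flat(V),
        im=IntensityModel(beta0=0.0, beta1=1.0),
        weights=np.ones(len(probes)),
        seed=seed_kmer,
    )

    _cycle_blocks("mono", state, codes, y, config, "mono")
    _reanchor_mono(state)
    r2, _ = _fit_scale(state, codes, y, config)
    state.beta_psam = state.im.beta1
    logger.info("mono phase done: R2=%.4f beta_PSAM=%.4g", r2, state.beta_psam)

    if config.include_di:
        # after the PSAM phase, rounds cycle over all blocks (mono and
        # di): a di feature's marginal effect is first soaked up by the
        # PSAM, and only re-fitting mono with the di terms in place
        # separates main effects from interactions
        state.model.di = np.zeros((state.model.L - 1, 16))
        _cycle_blocks("full", state, codes, y, config, "di")
        _fit_scale(state, codes, y, config)

    if config.saturation:
        state.im = fit_nonlinear(state, codes, y, config)
        if state.im.saturating:
            from .core import predict_batch

            yhat = predict_batch(enc, state.model, state.bias.gamma, state.im,
                                 codes=codes)
            state.r2_train = r_squared(y, yhat, state.weights)

    if config.symmetry != "off" or config.grow_motif:
        from . import refine

        if config.symmetry == "on":
            state = refine.symmetrize(state, probes, config)
        elif config.symmetry == "auto":
            is_sym, dist = refine.detect_palindrome(probes, state, config)
            logger.info("palindrome check: symmetric=%s L1=%.3f", is_sym, dist)
            if is_sym:
                state = refine.symmetrize(state, probes, config)
        if config.grow_motif:
            state = refine.select_motif_length(probes, state, config)

    return state
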