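"""Synthetic PBM data with known ground truth.

Every inference stage in this package has a parameter-recovery test, so
the generator emulates the structure of a universal-design PBM
experiment: fixed-length random double-stranded probes, intensities from
the linear or saturating intensity model with a positional-bias profile,
Gaussian noise scaled to the signal, and a configurable fraction of
multiplicative "bright spot" outliers.  A fraction of probes carries an
exact copy of the reference site at a random (or fixed) offset and
strand, mirroring designs that plant the same motif at different offsets.

All randomness flows from a single integer seed; a dataset ships with a
machine-readable truth record (free-energy tables, gamma profile,
response coefficients, outlier flags) so tests never re-derive it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from .core import (
    STRAND_BOTH,
    FeatureModel,
    IntensityModel,
    ProbeTable,
    encode_sequences,
    predict_batch,
    revcomp,
)

__all__ = [
    "SimSpec",
    "GOSimSpec",
    "example_psam",
    "example_symmetric_psam",
    "example_asymmetric_psam",
    "gamma_profile",
    "make_probes",
    "simulate_intensities",
    "simulate_dataset",
    "make_genome_fixture",
]

_EXAMPLE_DDG = np.array(
    # reference GCACGTGC (E-box core with flanks); columns A, C, G, T
    [
        [0.5, 0.8, 0.0, 0.6],
        [1.2, 0.0, 1.5, 1.0],
        [0.0, 2.5, 2.0, 2.2],
        [2.8, 0.0, 3.0, 2.6],
        [3.0, 2.7, 0.0, 2.9],
        [2.2, 2.4, 2.6, 0.0],
        [1.4, 1.6, 0.0, 1.2],
        [0.6, 0.0, 0.9, 0.4],
    ]
)


def example_psam() -> FeatureModel:
    """A fixed, realistic 8-bp energy matrix (strong core, soft flanks)
    around the E-box-like reference GCACGTGC."""
    return FeatureModel("GCACGTGC", _EXAMPLE_DDG.copy())


def example_symmetric_psam() -> FeatureModel:
    """The example matrix projected onto exact reverse-complement
    symmetry (palindromic E-box)."""
    m = _EXAMPLE_DDG.copy()
    rc = m[::-1][:, [3, 2, 1, 0]]
    return FeatureModel("GCACGTGC", (m + rc) / 2.0, symmetric=True)


def example_asymmetric_psam() -> FeatureModel:
    """A deliberately one-sided matrix: all specificity in the first four
    positions, the rest nearly neutral (reference TGACTAAC)."""
    mono = np.array(
        [
            [2.6, 2.9, 3.1, 0.0],
            [2.8, 2.5, 0.0, 2.7],
            [0.0, 2.4, 2.6, 2.9],
            [2.7, 0.0, 2.5, 2.8],
            [1.5, 1.7, 1.6, 0.0],
            [0.0, 0.15, 0.1, 0.05],
            [0.1, 0.05, 0.15, 0.0],
            [0.05, 0.0, 0.1, 0.15],
        ]
    )
    return FeatureModel("TGACTAAC", mono)


def _symmetric_mono(reference: str, weak: float, strong: float,
                    core: slice) -> np.ndarray:
    """Mono ddG matrix with `strong` penalties inside the core slice and
    `weak` outside, projected onto exact reverse-complement symmetry."""
    L = len(reference)
    mono = np.full((L, 4), weak)
    mono[core] = strong
    for i, b in enumerate(reference):
        mono[i, "ACGT".index(b)] = 0.0
    rc = mono[::-1][:, [3, 2, 1, 0]]
    return (mono + rc) / 2.0


def example_two_mode_truth() -> List[Tuple[FeatureModel, float]]:
    """Two dimeric binding geometries with distinct palindromic
    consensus sites; the secondary mode binds with 25% of the primary
    mode's association constant."""
    m1 = FeatureModel(
        "TGACGTCA", _symmetric_mono("TGACGTCA", 1.2, 2.6, slice(2, 6))
    )
    m2 = FeatureModel(
        "CCAATTGG", _symmetric_mono("CCAATTGG", 1.2, 2.6, slice(2, 6))
    )
    return [(m1, 1.0), (m2, 0.25)]


@dataclass
class SimSpec:
    """Conditions of one simulated PBM experiment.

    modes : list of (FeatureModel, relative Ka) pairs; the first entry is
        the primary mode and should carry relative Ka 1.
    gamma_profile : "flat", "ramp", "end_dip", or an explicit vector (one
        value per offset, shared by both strands, max-normalised).
    noise_sd_frac : Gaussian noise sd as a fraction of the noiseless
        signal's standard deviation.
    outlier_frac/outlier_factor : a seeded subset of probes is multiplied
        by the factor, emulating bright-spot artifacts.
    planted_frac : fraction of probes receiving an exact reference site
        (modes round-robin) at planted_offset or a random offset/strand.
    """

    n_probes: int = 5000
    probe_len: int = 36
    modes: Optional[List[Tuple[FeatureModel, float]]] = None
    gamma_profile: Union[str, np.ndarray, Sequence[float]] = "ramp"
    beta0: float = 100.0
    beta1: float = 2000.0
    noise_sd_frac: float = 0.05
    outlier_frac: float = 0.0
    outlier_factor: float = 10.0
    planted_frac: float = 0.35
    planted_offset: Optional[int] = None
    plant_mode: str = "boltzmann"  # "exact" or "boltzmann"
    plant_temperature: float = 0.85
    saturating: bool = False
    protein_scale: float = 1.0
    ddG_ns: float = 10.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_probes <= 0:
            raise ValueError("n_probes must be > 0")
        for name in ("noise_sd_frac", "outlier_frac", "planted_frac"):
            v = getattr(self, name)
            if not 0 <= v < 1 and not (name == "planted_frac" and v == 1.0):
                if not 0 <= v <= 1:
                    raise ValueError(f"{name} must be in [0, 1)")
        if self.modes is None:
            self.modes = [(example_psam(), 1.0)]


def gamma_profile(
    profile: Union[str, np.ndarray, Sequence[float]],
    probe_len: int,
    L: int,
    strand_policy: str = STRAND_BOTH,
) -> np.ndarray:
    """Materialise a named or explicit bias profile as a per-view vector
    (forward offsets then reverse offsets), max-normalised to 1."""
    k = probe_len - L + 1
    if isinstance(profile, str):
        if profile == "flat":
            g = np.ones(k)
        elif profile == "ramp":
            g = np.linspace(0.3, 1.0, k)
        elif profile == "end_dip":
            g = np.ones(k)
            g[-3:] = 0.4
        else:
            raise ValueError(f"unknown gamma profile {profile!r}")
    else:
        g = np.asarray(profile, dtype=float)
        if g.size == k * 2 and strand_policy == STRAND_BOTH:
            return g / g.max()
        if g.size != k:
            raise ValueError(f"custom gamma must have {k} offsets")
    g = g / g.max()
    if strand_policy == STRAND_BOTH:
        g = np.concatenate([g, g])
    return g


def _sample_site(
    model: FeatureModel, temperature: float, rng: np.random.Generator
) -> str:
    """Draw a site with per-position base probabilities proportional to
    the Boltzmann weights exp(-ddG/(RT*temperature)); emulates the graded
    affinity landscape a binding experiment actually probes (strong sites
    are rare, near-matches common)."""
    out = []
    for p in range(model.L):
        w = np.exp(-model.mono[p] / temperature)
        out.append("ACGT"[rng.choice(4, p=w / w.sum())])
    return "".join(out)


def make_probes(spec: SimSpec, rng: Optional[np.random.Generator] = None) -> List[str]:
    """i.i.d. uniform-random probe sequences, with binding sites planted
    in a `planted_frac` subset (random strand; offsets as configured).

    Planted sites are either exact reference copies ("exact") or draws
    from the model's per-position Boltzmann distribution ("boltzmann",
    the default)."""
    rng = rng or np.random.default_rng(spec.rng_seed)
    enc = rng.integers(0, 4, size=(spec.n_probes, spec.probe_len))
    seqs = ["".join("ACGT"[b] for b in row) for row in enc]
    n_plant = int(round(spec.planted_frac * spec.n_probes))
    if n_plant:
        which = rng.choice(spec.n_probes, size=n_plant, replace=False)
        for j, i in enumerate(which):
            model, _ = spec.modes[j % len(spec.modes)]
            if spec.plant_mode == "boltzmann":
                site = _sample_site(model, spec.plant_temperature, rng)
            else:
                site = model.reference_seq
            if rng.random() < 0.5:
                site = revcomp(site)
            max_off = spec.probe_len - len(site)
            off = (
                spec.planted_offset
                if spec.planted_offset is not None
                else int(rng.integers(0, max_off + 1))
            )
            s = seqs[i]
            seqs[i] = s[:off] + site + s[off + len(site) :]
    return seqs


def _noiseless(seqs: List[str], spec: SimSpec) -> Tuple[np.ndarray, Dict]:
    enc = encode_sequences(seqs)
    total = np.zeros(len(seqs))
    gammas = {}
    for model, rel_ka in spec.modes:
        g = gamma_profile(
            spec.gamma_profile, spec.probe_len, model.L, model.strand_policy
        )
        gammas[model.reference_seq] = g
        im = IntensityModel(
            beta0=0.0,
            beta1=1.0,
            ddG_ns_over_RT=spec.ddG_ns if spec.saturating else None,
            protein_scale=spec.protein_scale,
            saturating=spec.saturating,
        )
        total += rel_ka * predict_batch(enc, model, g, im)
    y = spec.beta0 + spec.beta1 * total
    return y, gammas


def simulate_intensities(
    seqs: List[str], spec: SimSpec, rng: Optional[np.random.Generator] = None
) -> Tuple[ProbeTable, Dict]:
    """Intensities from the forward model plus noise and outliers.

    Returns the probe table and a truth record with the noiseless signal,
    gamma profiles, outlier flags, and the generating models.
    """
    rng = rng or np.random.default_rng(spec.rng_seed + 1)
    y_clean, gammas = _noiseless(seqs, spec)
    sd = spec.noise_sd_frac * y_clean.std()
    y = y_clean + (rng.normal(0.0, sd, size=len(seqs)) if sd > 0 else 0.0)
    n_out = int(round(spec.outlier_frac * len(seqs)))
    mask = np.zeros(len(seqs), dtype=bool)
    if n_out:
        idx = rng.choice(len(seqs), size=n_out, replace=False)
        mask[idx] = True
        y[idx] *= spec.outlier_factor
    table = ProbeTable(
        probe_ids=[f"probe_{i:06d}" for i in range(len(seqs))],
        sequences=list(seqs),
        intensities=y,
    )
    truth = {
        "spec": spec,
        "modes": spec.modes,
        "gamma": gammas,
        "beta0": spec.beta0,
        "beta1": spec.beta1,
        "y_clean": y_clean,
        "noise_sd": sd,
        "outlier_mask": mask,
    }
    return table, truth


def simulate_dataset(spec: SimSpec) -> Tuple[ProbeTable, Dict]:
    """Probes + intensities in one call, all randomness from spec.rng_seed."""
    rng = np.random.default_rng(spec.rng_seed)
    seqs = make_probes(spec, rng)
    return simulate_intensities(seqs, spec, rng)


@dataclass
class GOSimSpec:
    """Conditions for the promoter/GO fixture: random promoters, a set of
    gene categories, and extra reference sites planted in the genes of
    one category (if any)."""

    n_genes: int = 500
    promoter_len: int = 600
    n_categories: int = 20
    category_size: int = 30
    planted_category: Optional[int] = 0
    sites_per_gene: int = 3
    model: Optional[FeatureModel] = None
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.model is None:
            self.model = example_psam()


def make_genome_fixture(
    spec: GOSimSpec,
) -> Tuple[Dict[str, str], Dict[str, List[str]], Dict]:
    """Random promoter sequences plus a gene -> GO-category mapping.

    Genes of the planted category receive `sites_per_gene` extra copies of
    the model's reference site at random non-overlapping-ish positions.
    Returns (promoters, annotation, truth).
    """
    rng = np.random.default_rng(spec.rng_seed)
    genes = [f"gene_{i:04d}" for i in range(spec.n_genes)]
    promoters = {
        g: "".join(
            "ACGT"[b] for b in rng.integers(0, 4, size=spec.promoter_len)
        )
        for g in genes
    }
    annotation: Dict[str, List[str]] = {g: [] for g in genes}
    categories = [f"GO:{i:07d}" for i in range(spec.n_categories)]
    members: Dict[str, List[str]] = {}
    for c in categories:
        chosen = rng.choice(spec.n_genes, size=spec.category_size, replace=False)
        members[c] = [genes[i] for i in chosen]
        for i in chosen:
            annotation[genes[i]].append(c)
    planted_genes: List[str] = []
    if spec.planted_category is not None:
        cat = categories[spec.planted_category]
        planted_genes = members[cat]
        site = spec.model.reference_seq
        for g in planted_genes:
            s = promoters[g]
            for _ in range(spec.sites_per_gene):
                off = int(rng.integers(0, spec.promoter_len - len(site) + 1))
                if rng.random() < 0.5:
                    s = s[:off] + revcomp(site) + s[off + len(site) :]
                else:
                    s = s[:off] + site + s[off + len(site) :]
            promoters[g] = s
    truth = {
        "spec": spec,
        "categories": categories,
        "members": members,
        "planted_category": (
            categories[spec.planted_category]
            if spec.planted_category is not None
            else None
        ),
        "planted_genes": planted_genes,
    }
    return promoters, annotation, truth
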