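"""Binomial correction of photobleaching step histograms for incomplete labeling.

A particle of true oligomer order N whose subunits are each labeled
independently with probability P_f shows m bleaching steps with probability

    P_Nm = C(N, m) P_f^m (1 - P_f)^(N - m).

Particles with m = 0 are invisible, so the observation model conditions on
visibility: the probability that a *visible* order-i particle shows m steps
is A[m, i] = P_im / (1 - (1 - P_f)^i). Stacking these into a column-
stochastic matrix A gives the linear system A w = R relating visible-
particle true-order weights w to the observed step-fraction vector R; the
corrected particle fractions follow by undoing the visibility weighting and
renormalizing. Inversion uses non-negative least squares so noisy histograms
still yield valid distributions (when the NNLS solution is interior it
coincides with the direct solve).

The truncation default keeps monomer through pentamer (N_max = 5).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from math import comb

import numpy as np
import pandas as pd
from scipy import optimize

from .steps import ObservedStepHistogram

__all__ = [
    "LabelingModel",
    "ObservationMatrix",
    "OligomerDistribution",
    "EntityDistribution",
    "CorrectionResult",
    "binomial_label_prob",
    "build_observation_matrix",
    "forward_observe",
    "solve_corrected_fractions",
    "particle_to_entity",
    "group_fractions",
    "bootstrap_ci",
    "receptors_per_cell",
    "fold_over_reference",
]

DEFAULT_GROUPING = {1: "monomer", 2: "dimer", 3: "oligomer", 4: "oligomer", 5: "oligomer"}


@dataclass(frozen=True)
class LabelingModel:
    """Per-subunit labeling efficiency and oligomer-order truncation.

    ``visibility_conditioned=True`` (default) restricts the observation model
    to particles with at least one labeled subunit — the convention under
    which A x = R is well-posed for observed histograms, since zero-step
    particles are never detected. The unconditional variant (columns sum to
    the visibility 1-(1-P_f)^i instead of 1) is kept for sensitivity analysis.
    """

    p_f: float = 0.8
    n_max: int = 5
    visibility_conditioned: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.p_f <= 1.0):
            raise ValueError("labeling efficiency p_f must be in (0, 1]")
        if self.n_max < 1:
            raise ValueError("n_max must be >= 1")

    def visibility(self) -> np.ndarray:
        """P(>=1 labeled subunit) per order 1..n_max."""
        i = np.arange(1, self.n_max + 1)
        return 1.0 - (1.0 - self.p_f) ** i


@dataclass
class ObservationMatrix:
    entries: np.ndarray                     # A[m-1, i-1]
    p_f: float
    n_max: int

    def __post_init__(self) -> None:
        a = np.asarray(self.entries, dtype=float)
        if a.shape != (self.n_max, self.n_max):
            raise ValueError("observation matrix must be n_max x n_max")
        if np.any(a < -1e-12) or np.any(a > 1 + 1e-12):
            raise ValueError("observation probabilities must lie in [0, 1]")
        self.entries = a


def _check_fractions(fractions, tol: float = 1e-9) -> np.ndarray:
    f = np.asarray(fractions, dtype=float)
    if np.any(f < -tol) or abs(f.sum() - 1.0) > tol:
        raise ValueError("fractions must be non-negative and sum to 1")
    return np.clip(f, 0.0, None)


@dataclass
class OligomerDistribution:
    """Particle-level fractions over orders 1..N_max (truth or corrected)."""

    fractions: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.fractions = _check_fractions(self.fractions)

    @property
    def n_max(self) -> int:
        return self.fractions.size


@dataclass
class EntityDistribution:
    """Subunit-level fractions: what share of receptor protomers sits in each order."""

    fractions: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.fractions = _check_fractions(self.fractions)


@dataclass
class CorrectionResult:
    corrected: OligomerDistribution
    residual_norm: float
    condition_indicator: float
    ci_table: pd.DataFrame | None = None
    n_particles: int = 0
    warnings: list[str] = field(default_factory=list)


def binomial_label_prob(order: int, observed: int, p_f: float) -> float:
    """P(an order-N particle carries exactly m labels) = C(N,m) P_f^m (1-P_f)^(N-m)."""
    if not (0.0 < p_f <= 1.0):
        raise ValueError("labeling efficiency p_f must be in (0, 1]")
    if observed < 0 or observed > order:
        raise ValueError("observed step count must satisfy 0 <= m <= order")
    return comb(order, observed) * p_f**observed * (1.0 - p_f) ** (order - observed)


def build_observation_matrix(model: LabelingModel) -> ObservationMatrix:
    """Observation matrix A with A[m,i] = P(m steps | order i, visible)."""
    n = model.n_max
    a = np.zeros((n, n))
    vis = model.visibility()
    for i in range(1, n + 1):
        for m in range(1, i + 1):
            p = binomial_label_prob(i, m, model.p_f)
            a[m - 1, i - 1] = p / vis[i - 1] if model.visibility_conditioned else p
    return ObservationMatrix(a, model.p_f, n)


def forward_observe(truth: OligomerDistribution | np.ndarray,
                    model: LabelingModel) -> np.ndarray:
    """Expected observed step-fraction vector R for a true distribution.

    Visible-particle weights are w_i proportional to (1-(1-P_f)^i) x_i; the
    result R = A w sums to 1 (fractions among detected particles)."""
    x = truth.fractions if isinstance(truth, OligomerDistribution) else _check_fractions(truth)
    if x.size != model.n_max:
        raise ValueError("distribution length must equal model.n_max")
    a = build_observation_matrix(model).entries
    if model.visibility_conditioned:
        w = model.visibility() * x
        w = w / w.sum()
        return a @ w
    return a @ x


def solve_corrected_fractions(observed, model: LabelingModel) -> CorrectionResult:
    """Invert an observed step histogram to corrected true-order fractions.

    Solves A w = R by non-negative least squares, maps visible weights back
    to particle fractions (x_i proportional to w_i / (1-(1-P_f)^i)), and
    renormalizes. Reports the NNLS residual norm and the condition number of
    A; a poorly conditioned model (very small P_f) attaches a warning.
    """
    if isinstance(observed, ObservedStepHistogram):
        if observed.total == 0:
            raise ValueError("degenerate histogram: total count is zero")
        if observed.n_max != model.n_max:
            raise ValueError("histogram length must equal model.n_max")
        r = observed.fractions()
        n_particles = observed.total
    else:
        r = np.asarray(observed, dtype=float)
        if r.size != model.n_max:
            raise ValueError("observed vector length must equal model.n_max")
        if np.any(r < 0) or r.sum() <= 0:
            raise ValueError("observed fractions must be non-negative with positive sum")
        r = r / r.sum()
        n_particles = 0
    a = build_observation_matrix(model).entries
    w, rnorm = optimize.nnls(a, r)
    cond = float(np.linalg.cond(a))
    notes: list[str] = []
    if cond > 1e3:
        msg = f"observation matrix is ill-conditioned (cond={cond:.3g}); corrected fractions are unstable"
        warnings.warn(msg, stacklevel=2)
        notes.append(msg)
    if model.visibility_conditioned:
        x = w / model.visibility()
    else:
        x = w
    total = x.sum()
    if total <= 0:
        raise ValueError("inversion produced an all-zero solution")
    corrected = OligomerDistribution(x / total, label="corrected")
    return CorrectionResult(corrected, float(rnorm), cond, n_particles=n_particles,
                            warnings=notes)


def particle_to_entity(particles: OligomerDistribution) -> EntityDistribution:
    """Weight particle fractions by subunit count: E_i = i x_i / sum_j j x_j."""
    i = np.arange(1, particles.n_max + 1)
    w = i * particles.fractions
    return EntityDistribution(w / w.sum(), label=particles.label)


def group_fractions(dist, grouping: dict[int, str] | None = None) -> dict[str, float]:
    """Sum fractions within named order groups (default monomer/dimer/oligomer)."""
    fractions = dist.fractions if hasattr(dist, "fractions") else np.asarray(dist, float)
    n = fractions.size
    if grouping is None:
        grouping = {i: DEFAULT_GROUPING.get(i, "oligomer") for i in range(1, n + 1)}
    missing = [i for i in range(1, n + 1) if i not in grouping]
    if missing:
        raise ValueError(f"grouping does not cover orders {missing}")
    out: dict[str, float] = {}
    for i in range(1, n + 1):
        out[grouping[i]] = out.get(grouping[i], 0.0) + float(fractions[i - 1])
    return out


def bootstrap_ci(histogram: ObservedStepHistogram, model: LabelingModel,
                 b: int = 1000, seed: int = 0,
                 percentiles: tuple[float, float] = (2.5, 97.5)) -> pd.DataFrame:
    """Percentile bootstrap intervals for the corrected fractions.

    Particles are resampled with replacement (multinomial over the observed
    histogram) ``b`` times and the inversion is re-solved per replicate.
    """
    if b < 100:
        raise ValueError("use at least 100 bootstrap replicates")
    if histogram.total == 0:
        raise ValueError("degenerate histogram: total count is zero")
    rng = np.random.default_rng(seed)
    p = histogram.fractions()
    samples = np.empty((b, model.n_max))
    for k in range(b):
        counts = rng.multinomial(histogram.total, p)
        rep = ObservedStepHistogram(counts)
        samples[k] = solve_corrected_fractions(rep, model).corrected.fractions
    lo, hi = np.percentile(samples, percentiles, axis=0)
    return pd.DataFrame({
        "order": np.arange(1, model.n_max + 1),
        "ci_low": lo,
        "ci_high": hi,
    })


def receptors_per_cell(density: float, cell_area: float = 1200.0) -> int:
    """Particle density (per um^2) times cell surface area, rounded to tens."""
    if density < 0 or cell_area <= 0:
        raise ValueError("density must be >= 0 and cell_area > 0")
    return int(round(density * cell_area / 10.0) * 10)


def fold_over_reference(bmax: float, reference: float) -> float:
    """Expression level as a fold ratio over a physiological reference density."""
    if reference <= 0:
        raise ValueError("reference must be positive")
    return bmax / reference
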