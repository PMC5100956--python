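"""Closed-form theory for neutral introgressed alleles under linked purifying selection.

A neutral allele that entered the recipient population in a single admixture
pulse, riding on the same haplotype as a deleterious allele, is lost from the
population faster than an unlinked neutral allele.  The classic barrier-locus
result expresses its expected present-day frequency as ``p_t = p0 * f(r, s, t)``
where ``r`` is the recombination fraction between the neutral and the selected
site, ``s`` the selection coefficient against a heterozygous (autosomes) or
hemizygous (X) carrier, and ``t`` the number of generations since the pulse.
At large ``t``, ``f`` converges to the gene flow factor of Bengtsson-style
barrier theory.

Because the location of the selected site is unknown, the genome-wide model
treats each exonic base as harboring a deleterious allele independently with
probability ``mu`` and mixes over which exon in a window around the focal site
carries the *nearest* selected site (with the selected site placed at the exon
midpoint).  :func:`expected_frequency` composes these pieces.

All powers of ``(1-s)`` and ``(1-r)`` are evaluated in log space so that
horizon times up to 1e7 generations are numerically exact.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Union

import numpy as np

__all__ = [
    "ModelParams",
    "LinkedExonContext",
    "f_autosome",
    "f_autosome_equilibrium",
    "f_xchr",
    "recursion_oracle",
    "nearest_exon_weights",
    "expected_frequency",
    "X_MALE_RECOMB_WEIGHT",
]

#: Fraction of its history an X-linked allele spends in females, where the
#: non-PAR X recombines; in males it does not, hence the effective female map
#: distance is scaled by 2/3.
X_MALE_RECOMB_WEIGHT = 2.0 / 3.0

TimeLike = Union[int, float]


def _check_rs(r, s) -> tuple[np.ndarray, np.ndarray]:
    r = np.asarray(r, dtype=float)
    s = np.asarray(s, dtype=float)
    if np.any(r < 0) or np.any(r > 0.5):
        raise ValueError("recombination fraction r must lie in [0, 0.5]")
    if np.any(s < 0) or np.any(s >= 1):
        raise ValueError("selection coefficient s must lie in [0, 1)")
    return r, s


def _check_t(t: TimeLike) -> float:
    t = float(t)
    if math.isnan(t) or t < 0:
        raise ValueError("time t must be non-negative (or math.inf)")
    return t


def _f_core(r: np.ndarray, s: np.ndarray, t: float) -> np.ndarray:
    """Shared kernel: f = (s(1-r) * lam^t + r) / (s(1-r) + r), lam=(1-s)(1-r).

    ``s(1-r) + r`` equals ``1 - (1-s)(1-r)``; the identity keeps the expression
    stable for small r and s.  At r = s = 0 the ratio is taken in the limit,
    which is 1 for any finite t.
    """
    b = s * (1.0 - r)
    denom = b + r
    if math.isinf(t):
        lam_t = np.zeros(np.broadcast(r, s).shape)
    else:
        lam_t = np.exp(t * (np.log1p(-s) + np.log1p(-r)))
    with np.errstate(invalid="ignore", divide="ignore"):
        f = (b * lam_t + r) / denom
    return np.where(denom > 0, f, 1.0)


def f_autosome(r, s, t: TimeLike):
    """Expected retention factor of a neutral autosomal allele linked to a
    selected site at recombination fraction ``r``, after ``t`` generations.

    Returns ``f`` such that ``E[p_t] = p0 * f``.  ``t = math.inf`` routes to
    the equilibrium (gene flow factor) form.
    """
    r, s = _check_rs(r, s)
    t = _check_t(t)
    if math.isinf(t):
        return f_autosome_equilibrium(r, s)
    out = _f_core(r, s, t)
    return out if out.ndim else float(out)


def f_autosome_equilibrium(r, s):
    """Gene flow factor: limit of :func:`f_autosome` as t -> infinity.

    Equals ``r / (1 - (1-s)(1-r))``.  Undefined at r = s = 0 (no selection and
    complete linkage give no information), which raises ``ValueError``.
    """
    r, s = _check_rs(r, s)
    denom = s * (1.0 - r) + r
    if np.any(denom == 0):
        raise ValueError("equilibrium is undefined at r = s = 0")
    out = r / denom
    return out if out.ndim else float(out)


def f_xchr(r, s, t: TimeLike):
    """X-chromosomal analogue of :func:`f_autosome`.

    ``r`` is the *female* recombination fraction; the non-PAR X does not
    recombine in males, and an X-linked allele spends 2/3 of its time in
    females, so the effective per-generation recombination fraction is
    ``(2/3) r``.  Selection acts on heterozygous females and hemizygous males
    with the same coefficient ``s``.
    """
    r, s = _check_rs(r, s)
    t = _check_t(t)
    r_eff = X_MALE_RECOMB_WEIGHT * r
    if math.isinf(t):
        denom = s * (1.0 - r_eff) + r_eff
        if np.any(denom == 0):
            raise ValueError("equilibrium is undefined at r = s = 0")
        out = r_eff / denom
    else:
        out = _f_core(r_eff, s, t)
    return out if out.ndim else float(out)


def recursion_oracle(r, s, t: int, p0: float = 1.0, mode: str = "autosome"):
    """Iterate the deterministic two-locus haplotype recursion for ``t``
    generations and return the frequency of the neutral introgressed allele.

    This is the validation oracle for the closed forms.  Two linked loci: a
    neutral locus (introgressed allele N1) and a selected locus (introgressed
    allele S1, fixed in the donor, heterozygote fitness 1-s).  The admixture
    pulse introduces the N1-S1 haplotype at frequency ``p0``.  Each
    generation the lineage recombines onto the resident background with
    probability ``r`` (escaping selection from then on) or stays and pays the
    heterozygote cost.

    mode="autosome"
        Single-pool lineage recursion; its closed form is :func:`f_autosome`.
    mode="X"
        Tracks female and male haplotype pools explicitly, with recombination
        in females only and hemizygous male selection ``1-s``.  The closed
        form :func:`f_xchr` replaces this two-sex system by its leading
        eigenvalue (the 2/3 time-averaging), so agreement is to O(r^2 t), not
        to machine precision; see docs/methods.md.
    """
    r, s = _check_rs(r, s)
    if not float(p0) >= 0 or float(p0) > 1:
        raise ValueError("p0 must lie in [0, 1]")
    t = int(t)
    if t < 0:
        raise ValueError("t must be a non-negative integer")
    shape = np.broadcast(r, s).shape
    r = np.broadcast_to(r, shape).astype(float)
    s = np.broadcast_to(s, shape).astype(float)
    if mode == "autosome":
        # x: N1 still linked to S1; y: N1 escaped onto the resident background.
        x = np.full(shape, float(p0))
        y = np.zeros(shape)
        decay = (1.0 - r) * (1.0 - s)
        for _ in range(t):
            y = y + r * x
            x = x * decay
        out = x + y
    elif mode == "X":
        # q_*: linked N1-S1 frequency among female/male X copies;
        # e_*: escaped N1 frequency.  Daughters draw one X from each parent,
        # sons draw their X from the mother; recombination happens only in
        # female meiosis; carriers of S1 (het females, hemizygous males) have
        # fitness 1-s.
        q_f = np.full(shape, float(p0))
        q_m = np.full(shape, float(p0))
        e_f = np.zeros(shape)
        e_m = np.zeros(shape)
        for _ in range(t):
            q_from_mother = (1.0 - r) * (1.0 - s) * q_f
            e_from_mother = e_f + r * q_f
            q_f, q_m, e_f, e_m = (
                0.5 * (q_from_mother + (1.0 - s) * q_m),
                q_from_mother,
                0.5 * (e_from_mother + e_m),
                e_from_mother,
            )
        out = (2.0 * (q_f + e_f) + (q_m + e_m)) / 3.0
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class ModelParams:
    """Parameters of the linked-selection introgression model.

    p0
        Effective initial admixture proportion (after the rapid early purging
        by unlinked deleterious alleles), in [0, 1].
    s
        Selection coefficient against a heterozygous (autosome) or
        heterozygous-female/hemizygous-male (X) carrier, in [0, 1).
    t
        Generations since the admixture pulse; ``math.inf`` selects the
        equilibrium (gene flow factor) model.
    mu
        Probability that any given exonic base harbors a deleterious
        introgressed allele, in [0, 1].
    mode
        "autosome" or "X".
    """

    p0: float
    s: float
    t: TimeLike
    mu: float
    mode: str = "autosome"

    def __post_init__(self) -> None:
        if not 0.0 <= self.p0 <= 1.0:
            raise ValueError("p0 must lie in [0, 1]")
        if not 0.0 <= self.s < 1.0:
            raise ValueError("s must lie in [0, 1)")
        if not 0.0 <= self.mu <= 1.0:
            raise ValueError("mu must lie in [0, 1]")
        if not (self.t >= 0):
            raise ValueError("t must be non-negative")
        if self.mode not in ("autosome", "X"):
            raise ValueError("mode must be 'autosome' or 'X'")

    @property
    def is_equilibrium(self) -> bool:
        return math.isinf(float(self.t))

    def f(self, r):
        """Retention factor at recombination fraction ``r`` under this mode."""
        if self.mode == "X":
            return f_xchr(r, self.s, self.t)
        return f_autosome(r, self.s, self.t)


@dataclass(frozen=True)
class LinkedExonContext:
    """Exons in the window around one focal neutral site.

    distances_r
        Recombination fractions between the focal site and the exon midpoints,
        sorted ascending (nearest exon first).
    lengths_l
        Matching exon lengths in base pairs.
    """

    distances_r: np.ndarray
    lengths_l: np.ndarray

    def __post_init__(self) -> None:
        r = np.asarray(self.distances_r, dtype=float)
        l = np.asarray(self.lengths_l, dtype=float)
        object.__setattr__(self, "distances_r", r)
        object.__setattr__(self, "lengths_l", l)
        if r.shape != l.shape or r.ndim != 1:
            raise ValueError("distances_r and lengths_l must be matching 1-D arrays")
        if np.any(r < 0) or np.any(r > 0.5):
            raise ValueError("recombination fractions must lie in [0, 0.5]")
        if np.any(l <= 0):
            raise ValueError("exon lengths must be positive")
        if np.any(np.diff(r) < 0):
            raise ValueError("exons must be ordered by increasing distance")

    def __len__(self) -> int:
        return self.distances_r.size


def nearest_exon_weights(ctx: LinkedExonContext, mu: float) -> np.ndarray:
    """Mixture weights over which exon carries the nearest selected site.

    Exon ``i`` (in order of increasing genetic distance) carries it with
    probability ``mu*l_i * prod_{j<i}(1 - mu*l_j)``; the trailing entry of the
    returned array is the residual probability that no exon in the window
    carries one.  The weights sum to 1 by construction (telescoping product).

    ``mu*l`` values above 1 are clamped to 1 with a warning: the model's
    ``P(exon carries a selected site) ~ mu*l`` approximation assumes mu*l << 1.
    """
    if not 0.0 <= mu <= 1.0:
        raise ValueError("mu must lie in [0, 1]")
    ml = mu * ctx.lengths_l
    if np.any(ml > 1.0):
        warnings.warn(
            "mu * length exceeds 1 for some exons; clamping to 1 "
            "(the nearest-exon model assumes mu*l << 1)",
            RuntimeWarning,
            stacklevel=2,
        )
        ml = np.minimum(ml, 1.0)
    none_closer = np.concatenate([[1.0], np.cumprod(1.0 - ml)])
    weights = np.empty(ml.size + 1)
    weights[:-1] = ml * none_closer[:-1]
    weights[-1] = none_closer[-1]
    return weights


def expected_frequency(ctx: LinkedExonContext, params: ModelParams) -> float:
    """Expected present-day frequency of the neutral introgressed allele at a
    focal site with linked-exon context ``ctx``: ``p0 * g`` where ``g`` mixes
    the retention factor over the nearest-selected-exon distribution.

    Equals ``p0`` exactly when ``mu = 0`` or the window holds no exons.
    """
    if len(ctx) == 0 or params.mu == 0.0:
        return params.p0
    weights = nearest_exon_weights(ctx, params.mu)
    f_vals = params.f(ctx.distances_r)
    g = float(np.dot(weights[:-1], np.atleast_1d(f_vals)) + weights[-1])
    return params.p0 * g
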