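"""Forward Wright-Fisher simulation of deleterious alleles in two diverging
populations of unequal effective size.

The hypothesis under test: alleles that are effectively neutral in a small
donor population (|s| < 1/(2*Ne_donor)) drift to fixation there, while the
same alleles are held at low frequency or lost in a larger recipient
population.  At secondary contact, the donor therefore carries an excess of
population-specific fixed, weakly deleterious alleles — exactly the
"fixed in the donor" configuration the introgression inference assumes.

Each site evolves independently (no linkage): per generation, deterministic
genic selection (genotype fitnesses 1, 1-s, 1-2s — no dominance), one-way
mutation wild-type -> deleterious at rate ``u`` per copy, then binomial
resampling of 2*Ne allele copies.  Selection coefficients are drawn from a
gamma distribution of fitness effects.  Standing variation at the split is
produced by a burn-in in an ancestral population of the recipient's size.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "SplitSimConfig",
    "SplitSimResult",
    "sample_dfe",
    "simulate_split",
    "evolve_frequencies",
    "classify_fixed_differences",
]

#: Truncation point for DFE draws; keeps homozygote fitness 1-2s non-negative.
_S_MAX = 0.5


def sample_dfe(
    n: int,
    shape: float = 0.184,
    mean: float = 0.03,
    seed=None,
) -> np.ndarray:
    """Draw ``n`` selection coefficients from a gamma DFE (additive, no
    dominance).

    ``shape`` and ``mean`` parametrize the gamma; defaults are the widely
    used point estimate for new deleterious amino-acid mutations in humans.
    Draws above 0.5 (a sub-percent tail) are truncated to 0.5 so that the
    homozygote fitness 1-2s stays non-negative.
    """
    if shape <= 0 or not 0 < mean < 1:
        raise ValueError("gamma DFE needs shape > 0 and mean in (0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    s = rng.gamma(shape, mean / shape, size=int(n))
    return np.minimum(s, _S_MAX)


@dataclass
class SplitSimConfig:
    """Two-population split simulation settings.

    ne_donor, ne_recipient
        Diploid effective sizes after the split (donor is the small,
        Neanderthal-like population).
    t_split
        Generations between the split and secondary contact.
    n_sites
        Number of independently simulated exonic sites.
    u
        One-way mutation rate (wild-type -> deleterious) per copy per
        generation, per simulated site.
    dfe_shape, dfe_mean
        Gamma distribution of fitness effects.
    burn_in
        Generations of evolution in the ancestral population (size
        ``ne_recipient``) before the split; ``None`` means
        ``10 * ne_recipient``.
    bottleneck
        Optional ``(duration, size)`` bottleneck applied to the recipient for
        the last ``duration`` generations before contact (the studied range
        of durations is 10-1000 generations).
    """

    ne_donor: int = 1000
    ne_recipient: int = 10000
    t_split: int = 20000
    n_sites: int = 10000
    u: float = 1e-6
    dfe_shape: float = 0.184
    dfe_mean: float = 0.03
    burn_in: Optional[int] = None
    bottleneck: Optional[tuple] = None
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.ne_donor < 2 or self.ne_recipient < 2:
            raise ValueError("effective sizes must be >= 2")
        if self.t_split <= 0:
            raise ValueError("t_split must be positive")
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        if not 0 <= self.u < 1:
            raise ValueError("mutation rate must lie in [0, 1)")
        if not 0 < self.dfe_mean < 1 or self.dfe_shape <= 0:
            raise ValueError("invalid DFE parameters")
        if self.bottleneck is not None:
            duration, size = self.bottleneck
            if duration < 1 or size < 2:
                raise ValueError("bottleneck needs duration >= 1 and size >= 2")
            if duration >= self.t_split:
                raise ValueError("bottleneck must be shorter than t_split")

    @property
    def effective_burn_in(self) -> int:
        return int(self.burn_in) if self.burn_in is not None else 10 * self.ne_recipient


@dataclass
class SplitSimResult:
    """Per-site outcome at the time of contact."""

    s: np.ndarray
    freq_donor: np.ndarray
    freq_recipient: np.ndarray
    config: Optional[SplitSimConfig] = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"s": self.s, "freq_donor": self.freq_donor, "freq_recipient": self.freq_recipient}
        )


def evolve_frequencies(
    x: np.ndarray,
    s: np.ndarray,
    ne: int,
    u: float,
    generations: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Evolve allele frequencies for ``generations`` WF generations."""
    two_n = 2 * int(ne)
    for _ in range(generations):
        # deterministic genic selection; fixed classes (x=0, x=1) are inert
        denom = 1.0 - 2.0 * s * x
        with np.errstate(invalid="ignore", divide="ignore"):
            x = np.where(x >= 1.0, 1.0, x * (1.0 - s - s * x) / denom)
        if u > 0.0:
            x = x + u * (1.0 - x)
        x = rng.binomial(two_n, np.clip(x, 0.0, 1.0)) / two_n
    return x


def simulate_split(config: SplitSimConfig) -> SplitSimResult:
    """Simulate deleterious-allele frequencies through a population split.

    Pipeline per site: burn-in in the ancestral population (size
    ``ne_recipient``) from an initially mutation-free state, split into donor
    and recipient populations sharing the standing variation, then
    independent evolution for ``t_split`` generations (with the optional
    recipient bottleneck immediately before contact).
    """
    rng = np.random.default_rng(config.seed)
    s = sample_dfe(config.n_sites, config.dfe_shape, config.dfe_mean, rng)
    x0 = np.zeros(config.n_sites)
    x0 = evolve_frequencies(x0, s, config.ne_recipient, config.u, config.effective_burn_in, rng)

    donor = evolve_frequencies(x0.copy(), s, config.ne_donor, config.u, config.t_split, rng)

    if config.bottleneck is None:
        recipient = evolve_frequencies(
            x0.copy(), s, config.ne_recipient, config.u, config.t_split, rng
        )
    else:
        duration, size = config.bottleneck
        recipient = evolve_frequencies(
            x0.copy(), s, config.ne_recipient, config.u, config.t_split - int(duration), rng
        )
        recipient = evolve_frequencies(recipient, s, int(size), config.u, int(duration), rng)

    return SplitSimResult(s=s, freq_donor=donor, freq_recipient=recipient, config=config)


def classify_fixed_differences(result: SplitSimResult, s_bins) -> pd.DataFrame:
    """Fractions of population-specific fixed deleterious alleles by s bin.

    A site is a donor-specific fixed difference when the deleterious allele
    is fixed in the donor (frequency exactly 1) and absent from the recipient
    (exactly 0); mirrored for recipient-specific.  Denominators count *all*
    simulated sites in the bin, monomorphic ones included.
    """
    s_bins = np.asarray(s_bins, dtype=float)
    if s_bins.ndim != 1 or s_bins.size < 2 or np.any(np.diff(s_bins) <= 0):
        raise ValueError("s_bins must be an increasing 1-D array of bin edges")
    donor_fixed = (result.freq_donor == 1.0) & (result.freq_recipient == 0.0)
    recip_fixed = (result.freq_recipient == 1.0) & (result.freq_donor == 0.0)
    which = np.digitize(result.s, s_bins) - 1
    rows = []
    for b in range(s_bins.size - 1):
        in_bin = which == b
        n = int(in_bin.sum())
        rows.append(
            {
                "s_low": s_bins[b],
                "s_high": s_bins[b + 1],
                "n_sites": n,
                "frac_donor_specific": donor_fixed[in_bin].sum() / n if n else np.nan,
                "frac_recipient_specific": recip_fixed[in_bin].sum() / n if n else np.nan,
            }
        )
    return pd.DataFrame(rows)
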