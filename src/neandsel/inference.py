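"""Grid-search RSS inference of (p0, s, mu) from introgressed-allele frequencies.

The model predicts the expected introgressed-allele frequency at SNP ``l`` as
``E[p_l] = p0 * g_l(r, s, t, mu)``, where ``g_l`` mixes the linked-selection
retention factor over which exon in a window around the SNP carries the
nearest selected site.  Fitting minimizes the residual sum of squares

    RSS(p0, s, mu) = sum_l (p_nl - p0 * g_l)^2

over a coarse-then-fine grid of (s, mu); at each grid cell the optimal p0 is
available in closed form, ``p0 = sum(p_n g) / sum(g^2)`` (clamped to [0, 1]),
so the surface shown is the profile RSS.

The public entry point is :class:`LinkedSelectionModel`, a scikit-learn-style
estimator; ``g_vector``, ``p0_analytic``, ``rss`` and ``grid_fit`` are thin
functional wrappers kept for convenience and for composing custom pipelines.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from ._kernels import g_per_snp, grid_block_sums
from .bootstrap import BlockSums, make_blocks
from .genome import CallTable, ExonAnnotation, GeneticMap, WindowSet, build_windows
from .model import X_MALE_RECOMB_WEIGHT

__all__ = [
    "GEngine",
    "RSSGrid",
    "LinkedSelectionModel",
    "g_vector",
    "p0_analytic",
    "rss",
    "grid_fit",
    "exon_density_diagnostic",
    "DensityDiagnostic",
]


class GEngine:
    """Vectorized evaluation of per-SNP g values over flattened exon windows.

    Precomputes everything that depends only on window geometry and ``t`` so
    that a grid of (s, mu) combinations costs only cheap element-wise passes:
    powers of (1-r) are taken once, and per generation-time the retention
    factor factorizes as ``lam^t = (1-s)^t * (1-r)^t``.
    """

    def __init__(self, windows: WindowSet, t, mode: str = "autosome"):
        if mode not in ("autosome", "X"):
            raise ValueError("mode must be 'autosome' or 'X'")
        self.windows = windows
        self.mode = mode
        self.t = float(t)
        r = windows.r if mode == "autosome" else windows.r * X_MALE_RECOMB_WEIGHT
        self.r = r
        self.omr = 1.0 - r
        self.length = windows.length
        self.ptr = windows.ptr
        self._starts = windows.ptr[:-1]
        self._ends = windows.ptr[1:]
        self._counts = self._ends - self._starts
        self._k_max = int(self._counts.max()) if self._counts.size else 0
        if not math.isinf(self.t):
            self._pow_omr_t = np.exp(self.t * np.log1p(-r))
        else:
            self._pow_omr_t = None
        # float32 entry arrays consumed by the fused grid kernel
        self._r32 = r.astype(np.float32)
        self._omr32 = self.omr.astype(np.float32)
        self._l32 = self.length.astype(np.float32)
        self._e32 = (
            self._pow_omr_t.astype(np.float32)
            if self._pow_omr_t is not None
            else np.ones_like(self._r32)
        )

    def _a_of_s(self, s: float) -> float:
        """(1-s)^t as a scalar; 0 selects the equilibrium form."""
        if math.isinf(self.t):
            return 0.0
        return math.exp(self.t * math.log1p(-s))

    @property
    def n_snps(self) -> int:
        return self.windows.n_snps

    def f_of_s(self, s: float) -> np.ndarray:
        """Retention factor at every window entry for a single s."""
        if not 0.0 <= s < 1.0:
            raise ValueError("s must lie in [0, 1)")
        if s == 0.0:
            return np.ones_like(self.r)
        b = s * self.omr
        denom = b + self.r
        if self._pow_omr_t is None:
            num = self.r.copy()
        else:
            lam_t = math.exp(self.t * math.log1p(-s)) * self._pow_omr_t
            num = b * lam_t + self.r
        # denom > 0 whenever s > 0
        return num / denom

    def weights_of_mu(self, mu: float) -> tuple[np.ndarray, np.ndarray]:
        """Nearest-selected-exon weights per entry and per-SNP residual.

        Returns ``(w, residual)`` with ``w_i = mu*l_i * prod_{j<i}(1-mu*l_j)``
        within each SNP's window (distance-ordered) and ``residual`` the
        per-SNP probability that no window exon carries a selected site.
        ``mu*l`` is clamped to 1.
        """
        if not 0.0 <= mu <= 1.0:
            raise ValueError("mu must lie in [0, 1]")
        n = self.n_snps
        if mu == 0.0 or self.length.size == 0:
            return np.zeros_like(self.length), np.ones(n)
        # clamp mu*l into [0, 1) so the log stays finite; 1 - 1e-12 puts the
        # weight of anything behind a saturated exon at ~0, as it should be
        ml = np.minimum(mu * self.length, 1.0 - 1e-12)
        a = np.log1p(-ml)
        cs = np.cumsum(a)
        pre = cs - a  # exclusive cumsum
        starts_safe = np.minimum(self._starts, self.length.size - 1)
        base = np.repeat(pre[starts_safe], self._counts)
        w = ml * np.exp(pre - base)
        log_tot = np.zeros(n)
        nz = self._counts > 0
        log_tot[nz] = cs[self._ends[nz] - 1] - pre[self._starts[nz]]
        residual = np.exp(log_tot)
        return w, residual

    def g(self, s: float, mu: float) -> np.ndarray:
        """Per-SNP g for one (s, mu) combination (fused kernel path)."""
        if not 0.0 <= s < 1.0:
            raise ValueError("s must lie in [0, 1)")
        if not 0.0 <= mu <= 1.0:
            raise ValueError("mu must lie in [0, 1]")
        return g_per_snp(
            self._r32, self._l32, self._e32, self._omr32, self.ptr,
            float(s), self._a_of_s(s), float(mu),
        )

    def g_reference(self, s: float, mu: float) -> np.ndarray:
        """Pure-numpy float64 g, for cross-checking the kernel."""
        w, residual = self.weights_of_mu(mu)
        if mu == 0.0:
            return residual
        f = self.f_of_s(s)
        cs = np.concatenate([[0.0], np.cumsum(w * f)])
        return cs[self._ends] - cs[self._starts] + residual


@dataclass
class RSSGrid:
    """Profile RSS surface over a (s, mu) grid.

    ``rss[i, j]`` and ``p0[i, j]`` correspond to ``s_values[i]``,
    ``mu_values[j]``; each cell is minimized analytically over p0.
    """

    s_values: np.ndarray
    mu_values: np.ndarray
    rss: np.ndarray
    p0: np.ndarray

    def __post_init__(self) -> None:
        self.s_values = np.asarray(self.s_values, dtype=float)
        self.mu_values = np.asarray(self.mu_values, dtype=float)

    @property
    def best_index(self) -> tuple[int, int]:
        # first occurrence in row-major order = smallest s, then smallest mu
        flat = int(np.argmin(self.rss))
        return np.unravel_index(flat, self.rss.shape)

    @property
    def best(self) -> tuple[float, float, float, float]:
        """(s, mu, p0, rss) at the grid minimum."""
        i, j = self.best_index
        return (
            float(self.s_values[i]),
            float(self.mu_values[j]),
            float(self.p0[i, j]),
            float(self.rss[i, j]),
        )

    @property
    def scaled(self) -> np.ndarray:
        """RSS_min - RSS; <= 0 everywhere, 0 at the best cell."""
        return float(np.min(self.rss)) - self.rss

    def to_frame(self) -> pd.DataFrame:
        s_col = np.repeat(self.s_values, self.mu_values.size)
        mu_col = np.tile(self.mu_values, self.s_values.size)
        return pd.DataFrame(
            {
                "s": s_col,
                "mu": mu_col,
                "p0_min": self.p0.ravel(),
                "rss": self.rss.ravel(),
            }
        )


def p0_analytic(g, p_n) -> float:
    """RSS-minimizing initial admixture proportion for fixed g, in closed form.

    ``p0 = sum(p_n * g) / sum(g^2)``, then clamped to [0, 1] (the analytic
    minimizer of the quadratic is unconstrained).
    """
    g = np.asarray(g, dtype=float)
    p_n = np.asarray(p_n, dtype=float)
    if g.size == 0:
        raise ValueError("p0_analytic requires at least one SNP")
    if g.shape != p_n.shape:
        raise ValueError("g and p_n must have equal length")
    den = float(np.dot(g, g))
    if den <= 0:
        raise ValueError("sum of g^2 must be positive")
    return float(min(1.0, max(0.0, np.dot(p_n, g) / den)))


def rss(p_n, g, p0: float) -> float:
    """Residual sum of squares ``sum (p_n - p0*g)^2``."""
    p_n = np.asarray(p_n, dtype=float)
    g = np.asarray(g, dtype=float)
    if g.shape != p_n.shape:
        raise ValueError("g and p_n must have equal length")
    resid = p_n - p0 * g
    return float(np.dot(resid, resid))


def _evaluate_grid(
    engine: GEngine,
    p_n: np.ndarray,
    s_values: np.ndarray,
    mu_values: np.ndarray,
    block_of_snp: np.ndarray,
    n_blocks: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-cell, per-block sums of ``p_n*g`` (num) and ``g^2`` (den).

    Shapes (S, U, B).  Loops mu in the outer loop (weights computed once per
    mu) and caches the per-entry retention factor per s lazily.
    """
    s_values = np.ascontiguousarray(s_values, dtype=float)
    mu_values = np.ascontiguousarray(mu_values, dtype=float)
    a_values = np.array([engine._a_of_s(s) for s in s_values])
    return grid_block_sums(
        engine._r32, engine._l32, engine._e32, engine._omr32, engine.ptr,
        np.ascontiguousarray(p_n, dtype=float),
        np.ascontiguousarray(block_of_snp, dtype=np.int64),
        n_blocks, s_values, a_values, mu_values, engine._k_max,
    )


def _grid_from_sums(
    s_values: np.ndarray,
    mu_values: np.ndarray,
    num: np.ndarray,
    den: np.ndarray,
    spp_total: float,
) -> RSSGrid:
    num_t = num.sum(axis=-1)
    den_t = den.sum(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p0 = np.clip(num_t / den_t, 0.0, 1.0)
    p0 = np.nan_to_num(p0)
    rss_grid = spp_total - 2.0 * p0 * num_t + p0 * p0 * den_t
    np.maximum(rss_grid, 0.0, out=rss_grid)  # guard tiny negative round-off
    return RSSGrid(s_values, mu_values, rss_grid, p0)


def _refined_grid(values: np.ndarray, i: int, n: int) -> np.ndarray:
    """Log-spaced grid of ``n`` points spanning one coarse cell either side of
    ``values[i]``, always containing ``values[i]`` itself."""
    c = float(values[i])
    lo = float(values[i - 1]) if i > 0 else c
    hi = float(values[i + 1]) if i < values.size - 1 else c
    if lo == hi:
        return np.full(1, c)
    if c <= 0 or lo <= 0:
        grid = np.linspace(lo, hi, n)
        return np.unique(np.append(grid, c))
    if lo == c:
        return np.geomspace(c, hi, n)
    if hi == c:
        return np.geomspace(lo, c, n)
    n_left = n // 2
    left = np.geomspace(lo, c, n_left)
    right = np.geomspace(c, hi, n - n_left + 1)[1:]
    return np.concatenate([left, right])


class LinkedSelectionModel(BaseEstimator):
    """Estimator of genome-wide purifying selection against introgression.

    Fits the effective initial admixture proportion ``p0``, the selection
    coefficient ``s`` against a heterozygous carrier of a linked deleterious
    introgressed allele, and the per-exonic-base density ``mu`` of such
    alleles, by profile-RSS grid search.

    Parameters
    ----------
    t : int or math.inf
        Generations since the admixture pulse; ``math.inf`` fits the
        equilibrium (gene flow factor) model.
    mode : {"autosome", "X"}
        Transmission rules; X mode scales recombination by 2/3 (no male
        recombination in the non-PAR region).
    window_cm : float
        Size of the exon window around each focal SNP, in cM.
    s_bounds, mu_bounds : (low, high)
        Ranges of the default logarithmic coarse grid.
    coarse_size, fine_size : int
        Points per axis of the coarse grid and of the refinement grid (the
        refinement spans one coarse cell either side of the coarse optimum).
    s_grid, mu_grid : array-like, optional
        Explicit coarse grids (override the bounds; may contain 0).
    refine : bool
        Whether to run the fine stage.
    block_cm : float
        Block length (cM) for the blockwise sums kept for bootstrapping.
    weighted : bool
        Weight each residual by ``1 / (phat (1 - phat))`` with ``phat`` the
        model mean (robustness variant; default off).

    Attributes
    ----------
    p0_, s_, mu_, mus_ : float
        Best-fit parameters (``mus_ = mu_ * s_``).
    rss_ : float
        RSS at the optimum.
    grid_ : RSSGrid
        Fine-stage profile surface (coarse surface in ``coarse_grid_``).
    block_sums_ : BlockSums
        Per-block sufficient statistics on the fine grid, for bootstrapping.
    g_ : ndarray
        Per-SNP g at the best-fit (s, mu).
    """

    def __init__(
        self,
        t=2000,
        mode: str = "autosome",
        window_cm: float = 1.0,
        s_bounds: tuple = (1e-5, 4e-3),
        mu_bounds: tuple = (1e-6, 1e-3),
        coarse_size: int = 13,
        fine_size: int = 26,
        s_grid=None,
        mu_grid=None,
        refine: bool = True,
        block_cm: float = 5.0,
        weighted: bool = False,
    ):
        self.t = t
        self.mode = mode
        self.window_cm = window_cm
        self.s_bounds = s_bounds
        self.mu_bounds = mu_bounds
        self.coarse_size = coarse_size
        self.fine_size = fine_size
        self.s_grid = s_grid
        self.mu_grid = mu_grid
        self.refine = refine
        self.block_cm = block_cm
        self.weighted = weighted

    # -- fitting ---------------------------------------------------------

    def _coarse_grids(self) -> tuple[np.ndarray, np.ndarray]:
        if self.s_grid is not None:
            s_values = np.sort(np.asarray(self.s_grid, dtype=float))
        else:
            s_values = np.geomspace(*self.s_bounds, self.coarse_size)
        if self.mu_grid is not None:
            mu_values = np.sort(np.asarray(self.mu_grid, dtype=float))
        else:
            mu_values = np.geomspace(*self.mu_bounds, self.coarse_size)
        if np.any(s_values < 0) or np.any(mu_values < 0):
            raise ValueError("grid values must be non-negative")
        return s_values, mu_values

    def fit(self, calls: CallTable, exons: ExonAnnotation, genetic_map: GeneticMap):
        """Fit the model to a call table given exons and a genetic map."""
        if len(calls) == 0:
            raise ValueError("cannot fit an empty call table")
        windows = build_windows(calls, exons, genetic_map, self.window_cm)
        engine = GEngine(windows, self.t, self.mode)
        p_n = calls.p
        block_of_snp, block_chrom = make_blocks(
            windows.snp_cm, windows.snp_chrom, self.block_cm
        )
        n_blocks = block_chrom.size
        spp_blocks = np.bincount(block_of_snp, weights=p_n * p_n, minlength=n_blocks)
        n_snp_blocks = np.bincount(block_of_snp, minlength=n_blocks)
        spp_total = float(spp_blocks.sum())

        s_values, mu_values = self._coarse_grids()
        num, den = _evaluate_grid(engine, p_n, s_values, mu_values, block_of_snp, n_blocks)
        coarse = _grid_from_sums(s_values, mu_values, num, den, spp_total)
        if self.weighted:
            coarse = self._reweighted_grid(engine, p_n, coarse)
        self.coarse_grid_ = coarse

        if self.refine:
            i, j = coarse.best_index
            fine_s = _refined_grid(s_values, i, self.fine_size)
            fine_mu = _refined_grid(mu_values, j, self.fine_size)
            num, den = _evaluate_grid(engine, p_n, fine_s, fine_mu, block_of_snp, n_blocks)
            fine = _grid_from_sums(fine_s, fine_mu, num, den, spp_total)
            if self.weighted:
                fine = self._reweighted_grid(engine, p_n, fine)
        else:
            fine = coarse
        self.grid_ = fine
        self.block_sums_ = BlockSums(
            s_values=fine.s_values,
            mu_values=fine.mu_values,
            num=num,
            den=den,
            spp=spp_blocks,
            n_snps=n_snp_blocks,
            chrom=block_chrom,
        )
        self.s_, self.mu_, self.p0_, self.rss_ = fine.best
        self.mus_ = self.s_ * self.mu_
        self.g_ = engine.g(self.s_, self.mu_)
        self.n_snps_ = len(calls)
        self._engine = engine
        self._calls = calls
        self._exons = exons
        self._gmap = genetic_map
        return self

    def _reweighted_grid(self, engine: GEngine, p_n: np.ndarray, grid: RSSGrid) -> RSSGrid:
        """Variance-weighted profile surface: residuals weighted by
        ``1/(phat(1-phat))`` with ``phat`` the (unweighted-p0) model mean."""
        S, U = grid.rss.shape
        w_rss = np.empty((S, U))
        w_p0 = np.empty((S, U))
        for i, s in enumerate(grid.s_values):
            for j, mu in enumerate(grid.mu_values):
                g = engine.g(s, mu)
                phat = np.clip(grid.p0[i, j] * g, 1e-12, 1 - 1e-12)
                w = 1.0 / (phat * (1.0 - phat))
                den = float(np.dot(w * g, g))
                p0 = min(1.0, max(0.0, float(np.dot(w * p_n, g)) / den)) if den > 0 else 0.0
                resid = p_n - p0 * g
                w_rss[i, j] = float(np.dot(w, resid * resid))
                w_p0[i, j] = p0
        return RSSGrid(grid.s_values, grid.mu_values, w_rss, w_p0)

    # -- prediction ------------------------------------------------------

    def predict(
        self,
        calls: Optional[CallTable] = None,
        exons: Optional[ExonAnnotation] = None,
        genetic_map: Optional[GeneticMap] = None,
    ) -> np.ndarray:
        """Expected introgressed-allele frequency per SNP at the fitted
        parameters (fitted data by default)."""
        self._check_fitted()
        if calls is None:
            return self.p0_ * self.g_
        exons = exons if exons is not None else self._exons
        genetic_map = genetic_map if genetic_map is not None else self._gmap
        windows = build_windows(calls, exons, genetic_map, self.window_cm)
        engine = GEngine(windows, self.t, self.mode)
        return self.p0_ * engine.g(self.s_, self.mu_)

    def score(self, calls: CallTable, exons=None, genetic_map=None) -> float:
        """Negative RSS at the fitted parameters on the given data."""
        pred = self.predict(calls, exons, genetic_map)
        resid = calls.p - pred
        return -float(np.dot(resid, resid))

    def _check_fitted(self) -> None:
        if not hasattr(self, "p0_"):
            raise RuntimeError("model is not fitted; call fit() first")

    def summary(self) -> dict:
        self._check_fitted()
        return {
            "p0": self.p0_,
            "s": self.s_,
            "mu": self.mu_,
            "mus": self.mus_,
            "rss": self.rss_,
            "t": None if math.isinf(float(self.t)) else float(self.t),
            "mode": self.mode,
            "window_cm": self.window_cm,
            "n_snps": self.n_snps_,
        }


# -- functional wrappers -------------------------------------------------


def g_vector(
    calls: CallTable,
    exons: ExonAnnotation,
    genetic_map: GeneticMap,
    s: float,
    t,
    mu: float,
    mode: str = "autosome",
    window_cm: float = 1.0,
) -> np.ndarray:
    """Per-SNP g values at a single parameter combination."""
    windows = build_windows(calls, exons, genetic_map, window_cm)
    return GEngine(windows, t, mode).g(s, mu)


def grid_fit(
    calls: CallTable,
    exons: ExonAnnotation,
    genetic_map: GeneticMap,
    t=2000,
    mode: str = "autosome",
    window_cm: float = 1.0,
    coarse_grid: Optional[tuple] = None,
    fine_size: int = 26,
    **kwargs,
) -> LinkedSelectionModel:
    """Convenience wrapper: construct, fit and return the estimator.

    ``coarse_grid`` may be a ``(s_values, mu_values)`` pair.
    """
    s_grid = mu_grid = None
    if coarse_grid is not None:
        s_grid, mu_grid = coarse_grid
    model = LinkedSelectionModel(
        t=t,
        mode=mode,
        window_cm=window_cm,
        s_grid=s_grid,
        mu_grid=mu_grid,
        fine_size=fine_size,
        **kwargs,
    )
    return model.fit(calls, exons, genetic_map)


@dataclass
class DensityDiagnostic:
    """Observed vs predicted mean frequency by exon-density rank."""

    table: pd.DataFrame  # bin, n_segments, mean_exonic_bases, observed, predicted
    pearson_r: float  # segment-level correlation of observed vs predicted means


def exon_density_diagnostic(
    calls: CallTable,
    exons: ExonAnnotation,
    genetic_map: GeneticMap,
    model: LinkedSelectionModel,
    segment_cm: float = 1.0,
    n_bins: int = 10,
) -> DensityDiagnostic:
    """Model-fit diagnostic: split the genome into ``segment_cm`` segments,
    rank them by exonic-base count, group into ``n_bins`` equal-count bins,
    and compare mean observed and predicted frequencies per bin.

    Bins whose segments all carry zero exonic bases are collapsed into one.
    Also reports the segment-level Pearson correlation between observed and
    predicted means.
    """
    pred = model.predict(calls, exons, genetic_map)
    obs = calls.p
    df = calls.df
    seg_ids = np.empty(len(df), dtype=np.int64)
    seg_exonic: list[float] = []
    offset = 0
    for chrom, sub in df.groupby("chrom", sort=False):
        cm = genetic_map.interpolate(chrom, sub["pos"].to_numpy())
        lo, hi = genetic_map.span_cm(chrom)
        idx = np.floor((cm - lo) / segment_cm).astype(np.int64)
        n_seg = int(max(np.ceil((hi - lo) / segment_cm), idx.max() + 1 if idx.size else 1))
        seg_ids[sub.index.to_numpy()] = offset + idx
        mids = exons.midpoints(chrom)
        if mids.size:
            mid_cm = genetic_map.interpolate(chrom, mids)
            mid_seg = np.clip(np.floor((mid_cm - lo) / segment_cm).astype(np.int64), 0, n_seg - 1)
            ex_counts = np.bincount(mid_seg, weights=exons.lengths(chrom), minlength=n_seg)
        else:
            ex_counts = np.zeros(n_seg)
        seg_exonic.extend(ex_counts.tolist())
        offset += n_seg
    seg_exonic_arr = np.asarray(seg_exonic)
    # keep segments that contain SNPs
    n_all = offset
    snp_counts = np.bincount(seg_ids, minlength=n_all)
    keep = snp_counts > 0
    seg_obs = np.bincount(seg_ids, weights=obs, minlength=n_all)[keep] / snp_counts[keep]
    seg_pred = np.bincount(seg_ids, weights=pred, minlength=n_all)[keep] / snp_counts[keep]
    seg_ex = seg_exonic_arr[keep]

    n_seg = seg_ex.size
    if n_seg < n_bins:
        warnings.warn(
            f"only {n_seg} usable segments; reducing bins from {n_bins}",
            RuntimeWarning,
            stacklevel=2,
        )
        n_bins = max(n_seg, 1)
    order = np.argsort(seg_ex, kind="stable")
    groups = np.array_split(order, n_bins)
    # collapse leading all-zero-exon bins into one
    zero_bins = [k for k, grp in enumerate(groups) if seg_ex[grp].max() == 0]
    if len(zero_bins) > 1:
        merged = np.concatenate([groups[k] for k in zero_bins])
        groups = [merged] + [g for k, g in enumerate(groups) if k not in zero_bins]
    rows = []
    for k, grp in enumerate(groups):
        rows.append(
            {
                "bin": k,
                "n_segments": int(grp.size),
                "mean_exonic_bases": float(seg_ex[grp].mean()),
                "observed": float(seg_obs[grp].mean()),
                "predicted": float(seg_pred[grp].mean()),
            }
        )
    if n_seg >= 2 and np.std(seg_obs) > 0 and np.std(seg_pred) > 0:
        r = float(np.corrcoef(seg_obs, seg_pred)[0, 1])
    else:
        r = float("nan")
    return DensityDiagnostic(table=pd.DataFrame(rows), pearson_r=r)
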