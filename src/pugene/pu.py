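"""SCAR positive-unlabeled learning core.

Given a PU dataset (labeled positives vs. unlabeled), this module

1. produces out-of-fold classifier probabilities via cross-fitting with
   a gradient-boosted tree learner (:func:`oof_scores`),
2. estimates the class prior ``alpha`` — the fraction of true positives
   hidden in the unlabeled set — under the SCAR assumption from the two
   score distributions (:func:`estimate_alpha`),
3. rescales the unlabeled scores into calibrated probabilities whose
   mean equals ``alpha`` (:func:`calibrate_probabilities`), and
4. promotes the top ``ceil(alpha * |U|)`` unlabeled genes to probable
   positives (:func:`impute_probable_positives`).

The alpha estimator is an excess-mass rule: with boundary-corrected
kernel density estimates ``f_p`` (labeled-positive scores) and ``f_u``
(unlabeled scores), the mixture model ``f_u = alpha*f_p + (1-alpha)*f_n``
with a nonnegative ``f_n`` implies ``alpha*f_p <= f_u`` everywhere, so

    err(alpha) = integral of max(0, alpha*f_p - f_u)

must vanish for any feasible alpha.  We report the largest alpha on a
grid for which err stays within an epsilon that reflects the sampling
noise of the density estimate (a multinomial bootstrap of ``f_u``).
SCAR makes this the identifiable "largest feasible mixing proportion":
hidden positives score like labeled ones, so wherever negatives vanish
the ratio f_u/f_p approaches alpha from above.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import scipy.stats
from scipy.ndimage import gaussian_filter1d
from sklearn.model_selection import StratifiedKFold
from xgboost import XGBClassifier

from .labels import PUDataset

logger = logging.getLogger(__name__)

GRID_SIZE = 1001  # default resolution for both the score grid and the alpha grid


@dataclass(frozen=True)
class LearnerConfig:
    """Gradient-boosted tree settings (fixed, documented defaults)."""

    max_depth: int = 6
    n_estimators: int = 200
    learning_rate: float = 0.1
    tree_method: str = "hist"
    n_jobs: int = 1

    def make(self, seed: int) -> XGBClassifier:
        return XGBClassifier(
            max_depth=self.max_depth,
            n_estimators=self.n_estimators,
            learning_rate=self.learning_rate,
            tree_method=self.tree_method,
            n_jobs=self.n_jobs,
            objective="binary:logistic",
            random_state=seed,
            verbosity=0,
        )


DEFAULT_LEARNER = LearnerConfig()


@dataclass
class ScoreSet:
    """Out-of-fold predicted probabilities, split by PU label."""

    scores_pos: np.ndarray
    scores_unl: np.ndarray
    fold_assignment: np.ndarray
    seed: int


@dataclass
class AlphaEstimate:
    alpha: float
    per_iteration_alphas: np.ndarray
    ci95: tuple[float, float]


@dataclass
class CalibratedGeneScores:
    gene_ids: list[str]
    calibrated: np.ndarray          # (n_iterations, n_unlabeled)
    mean_calibrated: np.ndarray     # (n_unlabeled,)
    imputed_positives: list[str]


# ---------------------------------------------------------------------
# cross-fitted scoring
# ---------------------------------------------------------------------


def oof_scores(
    dataset: PUDataset,
    n_folds: int = 5,
    learner_config: LearnerConfig | None = None,
    seed: int = 0,
) -> ScoreSet:
    """Stratified out-of-fold probabilities for every instance.

    Each instance is scored exactly once, by a model whose training
    folds never contained it.  Deterministic for a fixed seed.
    """
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    y = np.asarray(dataset.y)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    cfg = learner_config or DEFAULT_LEARNER
    scores, folds = _oof_once(dataset.X, y, n_folds, cfg, seed)
    if scores is None:
        # one reshuffle retry before the hard error
        scores, folds = _oof_once(dataset.X, y, n_folds, cfg, seed + 1000003)
        if scores is None:
            raise RuntimeError(
                "a cross-validation fold contained a single class even after "
                "reshuffling; reduce n_folds or rebalance the dataset"
            )
    return ScoreSet(
        scores_pos=scores[y == 1],
        scores_unl=scores[y == 0],
        fold_assignment=folds,
        seed=seed,
    )


def _oof_once(X, y, n_folds, cfg: LearnerConfig, seed: int):
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    scores = np.empty(len(y), dtype=float)
    folds = np.empty(len(y), dtype=np.int64)
    for k, (tr, te) in enumerate(skf.split(np.zeros(len(y)), y)):
        if len(np.unique(y[tr])) < 2:
            return None, None
        clf = cfg.make(seed)
        clf.fit(X[tr], y[tr])
        scores[te] = clf.predict_proba(X[te])[:, 1]
        folds[te] = k
    return np.clip(scores, 0.0, 1.0), folds


# ---------------------------------------------------------------------
# bounded kernel density estimation on [0, 1]
# ---------------------------------------------------------------------


def kde_grid(grid_size: int = GRID_SIZE) -> np.ndarray:
    return np.linspace(0.0, 1.0, grid_size)


def silverman_bandwidth(scores: np.ndarray) -> float:
    """Silverman's rule of thumb, robust to zero spread (floored later)."""
    s = np.asarray(scores, dtype=float)
    sd = s.std(ddof=1) if s.size > 1 else 0.0
    iqr = np.subtract(*np.percentile(s, [75, 25])) / 1.34
    spread = min(x for x in (sd, iqr) if x > 0) if max(sd, iqr) > 0 else 0.0
    return 0.9 * spread * s.size ** (-0.2)


def _hist_counts(scores: np.ndarray, grid_size: int) -> np.ndarray:
    idx = np.rint(scores * (grid_size - 1)).astype(np.int64)
    return np.bincount(idx, minlength=grid_size).astype(float)


def _smooth_normalize(counts: np.ndarray, sigma_bins: float, grid: np.ndarray) -> np.ndarray:
    # edge-inclusive reflection at 0 and 1: mass binned exactly at a
    # boundary keeps its reflected copy, so no probability leaks outside
    # the unit interval ("mirror" would drop half of a boundary spike)
    if sigma_bins > 0:
        dens = gaussian_filter1d(counts, sigma=sigma_bins, mode="reflect")
    else:
        dens = counts.copy()
    area = np.trapezoid(dens, grid)
    if area <= 0:
        raise ValueError("degenerate density: no mass on the grid")
    return dens / area


def bounded_kde(
    scores: Sequence[float],
    grid_size: int = GRID_SIZE,
    bandwidth: float | str = "auto",
) -> np.ndarray:
    """Boundary-corrected Gaussian KDE of scores on a uniform [0,1] grid.

    Scores are binned to the grid and smoothed with a Gaussian kernel
    using mirror reflection at both boundaries, then renormalized so the
    trapezoid-rule integral is exactly 1.  ``bandwidth="auto"`` applies
    Silverman's rule, floored at two grid steps so a point mass becomes
    a narrow spike instead of a delta.
    """
    s = np.asarray(scores, dtype=float)
    if s.size < 10:
        raise ValueError("bounded_kde requires at least 10 scores")
    if np.any((s < 0) | (s > 1)):
        raise ValueError("scores must lie in [0, 1]")
    dx = 1.0 / (grid_size - 1)
    h = silverman_bandwidth(s) if bandwidth == "auto" else float(bandwidth)
    if bandwidth != "auto" and h <= 0:
        raise ValueError("bandwidth must be positive")
    h = max(h, 2 * dx)
    counts = _hist_counts(s, grid_size)
    return _smooth_normalize(counts, h / dx, kde_grid(grid_size))


# ---------------------------------------------------------------------
# alpha estimation
# ---------------------------------------------------------------------


def excess_mass(alpha_grid: np.ndarray, f_p: np.ndarray, f_u: np.ndarray,
                grid: np.ndarray) -> np.ndarray:
    """err(alpha) = integral max(0, alpha*f_p - f_u), vectorized over alphas."""
    diff = alpha_grid[:, None] * f_p[None, :] - f_u[None, :]
    np.maximum(diff, 0.0, out=diff)
    return np.trapezoid(diff, grid, axis=1)


def _boot_density(
    scores: np.ndarray,
    sigma_bins: float,
    grid: np.ndarray,
    n_boot: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Binned KDE plus its pointwise bootstrap SD (multinomial resampling)."""
    counts = _hist_counts(scores, grid.size)
    dens = _smooth_normalize(counts, sigma_bins, grid)
    probs = counts / counts.sum()
    boot = rng.multinomial(int(counts.sum()), probs, size=n_boot).astype(float)
    boot = gaussian_filter1d(boot, sigma=max(sigma_bins, 1e-9), mode="reflect", axis=1)
    boot /= np.trapezoid(boot, grid, axis=1)[:, None]
    return dens, boot


def estimate_alpha(
    scores_pos: Sequence[float],
    scores_unl: Sequence[float],
    grid_size: int = GRID_SIZE,
    bandwidth: float | str = "auto",
    n_boot: int = 100,
    alpha_grid_size: int = GRID_SIZE,
    seed: int = 0,
    return_se: bool = False,
) -> float | tuple[float, float]:
    """Largest feasible mixing proportion of positives in the unlabeled set.

    Both score densities are smoothed with a *common* bandwidth taken
    from the labeled-positive scores (Silverman's rule): under SCAR the
    positive component of ``f_u`` is a scaled copy of ``f_p``, and equal
    smoothing keeps that proportionality exact (convolution is linear),
    whereas per-sample bandwidths distort the ratio — and Silverman's
    rule can collapse entirely on the heavily skewed unlabeled sample.

    Feasibility of a candidate ``alpha`` is judged by comparing the
    observed excess ``err(alpha)`` with its expected value if the true
    unlabeled density were the *nearest feasible* one,
    ``min(alpha*f_p, f_u)``: pointwise, a bin with observed violation
    contributes the half-Gaussian mean ``sigma*phi(0)`` and a bin with
    slack ``s`` contributes ``sigma*phi(s/sigma) - s*SF(s/sigma)``,
    where ``sigma(x, alpha)`` combines the bootstrap SDs of both KDEs
    (``n_boot`` multinomial resamples each).  The reported alpha is the
    largest grid value whose observed excess does not exceed that
    noise-expected excess plus one bootstrap standard error of the
    excess statistic (and plus ``err(0)``, which is identically 0).
    The SE margin keeps a fully feasible configuration — unlabeled
    scores distributed exactly like positive scores — from being
    rejected by a coin-flip fluctuation of the observed excess.

    With ``return_se=True`` the function also returns a bootstrap
    standard error of the estimate: the SD of the feasibility crossing
    recomputed on each bootstrap density pair.  This captures the
    score-sampling uncertainty of a single estimate, which repeated
    fold-reshuffled iterations (same genes, same scores law) cannot
    see; :func:`run_pu_iterations` folds it into the aggregate CI.
    """
    s_p = np.asarray(scores_pos, dtype=float)
    s_u = np.asarray(scores_unl, dtype=float)
    grid = kde_grid(grid_size)
    dx = 1.0 / (grid_size - 1)
    for s in (s_p, s_u):
        if s.size < 10:
            raise ValueError("estimate_alpha requires >= 10 scores per class")
        if np.any((s < 0) | (s > 1)):
            raise ValueError("scores must lie in [0, 1]")
    h = silverman_bandwidth(s_p) if bandwidth == "auto" else float(bandwidth)
    if bandwidth != "auto" and h <= 0:
        raise ValueError("bandwidth must be positive")
    h = max(h, 2 * dx)
    rng = np.random.default_rng(seed)
    f_p, boot_p = _boot_density(s_p, h / dx, grid, n_boot, rng)
    f_u, boot_u = _boot_density(s_u, h / dx, grid, n_boot, rng)
    sd_p = boot_p.std(axis=0, ddof=1)
    sd_u = boot_u.std(axis=0, ddof=1)

    alpha_grid = np.linspace(0.0, 1.0, alpha_grid_size)
    diff = alpha_grid[:, None] * f_p[None, :] - f_u[None, :]
    err = np.trapezoid(np.maximum(diff, 0.0), grid, axis=1)
    sigma = np.sqrt((alpha_grid[:, None] * sd_p[None, :]) ** 2 + sd_u[None, :] ** 2)
    sigma = np.maximum(sigma, 1e-12)
    slack = np.maximum(-diff, 0.0)
    z = slack / sigma
    expected_noise_excess = np.trapezoid(
        sigma * scipy.stats.norm.pdf(z) - slack * scipy.stats.norm.sf(z),
        grid, axis=1,
    )
    # one bootstrap SE of the excess statistic, evaluated on a coarse
    # alpha grid (the SD varies smoothly in alpha) and interpolated
    coarse = np.linspace(0.0, 1.0, 51)
    se_coarse = np.empty(coarse.size)
    dev_p = f_p[None, :] - boot_p
    dev_u = f_u[None, :] - boot_u
    for i, a in enumerate(coarse):
        nearest_feasible = np.minimum(a * f_p, f_u)
        t_b = np.trapezoid(
            np.maximum(nearest_feasible[None, :] - f_u[None, :]
                       - a * dev_p + dev_u, 0.0),
            grid, axis=1,
        )
        se_coarse[i] = t_b.std(ddof=1)
    excess_se = np.interp(alpha_grid, coarse, se_coarse)
    threshold = err[0] + expected_noise_excess + excess_se
    feasible = err <= threshold
    alpha_hat = float(alpha_grid[feasible][-1]) if feasible.any() else 0.0
    alpha_hat = min(max(alpha_hat, 0.0), 1.0)
    if not return_se:
        return alpha_hat
    # bootstrap distribution of the crossing itself (coarse alpha grid)
    coarse_fine = np.linspace(0.0, 1.0, 251)
    thr_c = np.interp(coarse_fine, alpha_grid, threshold)
    alpha_b = np.empty(n_boot)
    for b in range(n_boot):
        diff_b = coarse_fine[:, None] * boot_p[b][None, :] - boot_u[b][None, :]
        err_b = np.trapezoid(np.maximum(diff_b, 0.0), grid, axis=1)
        feas_b = err_b <= thr_c
        alpha_b[b] = coarse_fine[feas_b][-1] if feas_b.any() else 0.0
    return alpha_hat, float(alpha_b.std(ddof=1))


def elkan_noto_alpha(
    scores_pos: Sequence[float], scores_unl: Sequence[float]
) -> float:
    """Classical SCAR estimator: mean unlabeled score / mean positive score.

    The mean labeled-positive score estimates the labeling propensity
    ``c``; under SCAR, mean(scores_unl)/c estimates the class prior.
    Used as an internal cross-check for :func:`estimate_alpha`.
    """
    mp = float(np.mean(scores_pos))
    if mp <= 0:
        raise ValueError("mean of positive scores must be > 0")
    return float(np.clip(np.mean(scores_unl) / mp, 0.0, 1.0))


# ---------------------------------------------------------------------
# calibration and imputation
# ---------------------------------------------------------------------


def calibrate_probabilities(
    scores_unl: Sequence[float], alpha: float, tol: float = 1e-9
) -> np.ndarray:
    """Monotone, rank-preserving probabilities with mean exactly ``alpha``.

    Scores are mapped to tie-averaged normalized ranks ``u`` in (0, 1]
    and raised to a power ``gamma`` solved by bisection so the mean of
    ``u**gamma`` equals ``alpha``.  The power transform is strictly
    monotone, so the calibrated ranking equals the raw-score ranking,
    and it cannot saturate at 1 the way a clipped linear rescale would.
    """
    s = np.asarray(scores_unl, dtype=float)
    if s.size == 0:
        raise ValueError("scores_unl must be non-empty")
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    if alpha == 0.0:
        logger.info("alpha = 0: all calibrated probabilities are 0")
        return np.zeros_like(s)
    if alpha == 1.0:
        logger.info("alpha = 1: all calibrated probabilities are 1")
        return np.ones_like(s)
    u = scipy.stats.rankdata(s, method="average") / s.size
    lo, hi = -60.0, 60.0  # gamma = exp(t); bisect on t for numeric range
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        m = float(np.mean(u ** np.exp(mid)))
        if m > alpha:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-14:
            break
    gamma = np.exp(0.5 * (lo + hi))
    cal = u ** gamma
    if abs(float(cal.mean()) - alpha) > max(tol, 1e-9):
        # unreachable target (e.g. extreme ties); degenerate fallback
        logger.warning("calibration fell back to the constant solution")
        return np.full_like(s, alpha)
    return np.clip(cal, 0.0, 1.0)


def impute_probable_positives(
    gene_ids: Sequence[str],
    calibrated_mean: Sequence[float],
    alpha: float,
) -> list[str]:
    """Top ``ceil(alpha * |U|)`` genes by calibrated probability.

    Ties at the cutoff break lexicographically by gene id (smaller id
    wins), making the imputed set deterministic.
    """
    ids = list(gene_ids)
    p = np.asarray(calibrated_mean, dtype=float)
    if len(ids) != p.size:
        raise ValueError("gene_ids and calibrated_mean lengths differ")
    k = int(np.ceil(alpha * len(ids)))
    if k == 0:
        logger.warning("alpha * |U| rounds to zero: imputing no genes")
        return []
    order = sorted(range(len(ids)), key=lambda i: (-p[i], ids[i]))
    return [ids[i] for i in order[:k]]


# ---------------------------------------------------------------------
# repeated-iteration driver
# ---------------------------------------------------------------------


def run_pu_iterations(
    dataset: PUDataset,
    n_iterations: int = 40,
    n_folds: int = 5,
    base_seed: int = 0,
    learner_config: LearnerConfig | None = None,
    grid_size: int = GRID_SIZE,
    n_boot: int = 100,
) -> tuple[AlphaEstimate, CalibratedGeneScores]:
    """Full PU pass: repeat score→alpha→calibrate, then aggregate.

    Iteration ``i`` uses seed ``base_seed + i`` for every stochastic
    step (fold split, learner, bootstrap).  The probable positives are
    imputed once, from the mean calibrated probabilities with the mean
    alpha.

    The 95% CI combines the spread of per-iteration alphas with the
    mean per-iteration bootstrap SE: iterations reshuffle folds over
    the *same* genes, so their spread alone understates the sampling
    uncertainty of the estimate (it would shrink to zero with more
    iterations while the score-sampling error stayed put).
    """
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    unl_ids = dataset.unlabeled_ids()
    alphas = np.empty(n_iterations)
    ses = np.empty(n_iterations)
    cal = np.empty((n_iterations, len(unl_ids)))
    for i in range(1, n_iterations + 1):
        seed = base_seed + i
        try:
            sc = oof_scores(dataset, n_folds, learner_config, seed)
            a, se = estimate_alpha(
                sc.scores_pos, sc.scores_unl,
                grid_size=grid_size, n_boot=n_boot, seed=seed,
                return_se=True,
            )
            cal[i - 1] = calibrate_probabilities(sc.scores_unl, a)
            alphas[i - 1] = a
            ses[i - 1] = se
        except Exception as exc:
            raise RuntimeError(f"PU iteration {i} failed: {exc}") from exc
        logger.info("iteration %d/%d: alpha = %.4f", i, n_iterations, a)
    alpha_mean = float(alphas.mean())
    if n_iterations == 1:
        interval = (alpha_mean, alpha_mean)
    else:
        half = 1.96 * float(
            np.sqrt(alphas.var(ddof=1) / n_iterations + np.mean(ses**2))
        )
        interval = (max(alpha_mean - half, 0.0), min(alpha_mean + half, 1.0))
    est = AlphaEstimate(
        alpha=alpha_mean,
        per_iteration_alphas=alphas,
        ci95=interval,
    )
    mean_cal = cal.mean(axis=0)
    imputed = impute_probable_positives(unl_ids, mean_cal, alpha_mean)
    scores = CalibratedGeneScores(
        gene_ids=unl_ids,
        calibrated=cal,
        mean_calibrated=mean_cal,
        imputed_positives=imputed,
    )
    logger.info(
        "alpha = %.4f (95%% CI %.4f-%.4f); imputed %d/%d unlabeled genes",
        est.alpha, est.ci95[0], est.ci95[1], len(imputed), len(unl_ids),
    )
    return est, scores
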