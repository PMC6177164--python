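"""Synthetic trees and trait tables with known ground truth.

Trees are pure-birth (Yule) with depth rescaled to 1.  Traits follow the
generative model PGLS assumes: a Brownian-motion predictor x on the tree and
a response y = b0 + b1 x + e with e ~ MVN(0, sigma2 * C(lambda)).  The
life-history mode maps the simulated pair monotonically onto the magnitudes
of the study system: lifespans of order 1e2-1e4 days, rearing periods a
small fraction of lifespan, and percentages bounded in [0, 100].
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .pgls import design_matrix, profile_lambda
from .tree import Node, Phylogeny, VCVMatrix, lambda_transform, vcv

__all__ = ["SyntheticConfig", "simulate_tree", "simulate_traits",
           "recovery_experiment"]

# Table-1-like printed ranges used by life_history_mode
_LIFESPAN_RANGE = (700.0, 22000.0)
_REARING_RANGE = (15.0, 2000.0)


@dataclass(frozen=True)
class SyntheticConfig:
    n_tips: int = 31
    branching_rate: float = 1.0
    true_beta: tuple = (0.0, 1.0)
    true_lambda: float = 1.0
    true_sigma2: float = 1.0
    life_history_mode: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.n_tips < 3:
            raise ValueError("need at least 3 tips")
        if self.branching_rate <= 0:
            raise ValueError("branching_rate must be positive")
        if not 0.0 <= self.true_lambda <= 1.0:
            raise ValueError("true_lambda must lie in [0, 1]")
        if self.true_sigma2 < 0:
            raise ValueError("true_sigma2 must be >= 0")

    def rng(self, *stream) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence(self.seed, spawn_key=tuple(stream))
        )


def simulate_tree(cfg: SyntheticConfig) -> Phylogeny:
    """Pure-birth ultrametric tree with ``cfg.n_tips`` tips and depth 1."""
    rng = cfg.rng(0)
    t = 0.0
    root = Node()
    active: list[tuple[Node, float]] = []  # (node, birth time)
    for _ in range(2):
        ch = Node()
        root.children.append(ch)
        active.append((ch, 0.0))
    while len(active) < cfg.n_tips:
        t += rng.exponential(1.0 / (cfg.branching_rate * len(active)))
        i = rng.integers(len(active))
        nd, born = active.pop(i)
        nd.length = t - born
        for _ in range(2):
            ch = Node()
            nd.children.append(ch)
            active.append((ch, t))
    t += rng.exponential(1.0 / (cfg.branching_rate * len(active)))
    depth = t if t > 0 else 1.0
    for k, (nd, born) in enumerate(active):
        nd.length = t - born
        nd.name = f"t{k + 1}"
    # rescale depth to 1
    stack = [root]
    while stack:
        nd = stack.pop()
        if nd.length is not None:
            nd.length /= depth
        stack.extend(nd.children)
    return Phylogeny(root)


def _draw_mvn(rng, cov: np.ndarray) -> np.ndarray:
    L = np.linalg.cholesky(cov)
    return L @ rng.standard_normal(cov.shape[0])


def simulate_traits(tree: Phylogeny, cfg: SyntheticConfig):
    """Simulate (x, y) tip traits on *tree* under the PGLS generative model.

    Returns a DataFrame keyed by species with columns x, y and, in
    life-history mode, the mapped lifespan_days, fw_days and cylinder_pct
    columns (monotone in x and y respectively, rearing < lifespan).
    """
    rng = cfg.rng(1)
    C = vcv(tree)
    x = _draw_mvn(rng, C.values)  # Brownian motion, unit rate, zero root state
    b0, b1 = cfg.true_beta
    V = lambda_transform(C, cfg.true_lambda).values
    if cfg.true_sigma2 > 0:
        eps = _draw_mvn(rng, cfg.true_sigma2 * V)
    else:
        eps = np.zeros(C.n)
    y = b0 + b1 * x + eps
    df = pd.DataFrame({"species": C.species_order, "x": x, "y": y})
    if cfg.life_history_mode:
        lo, hi = _LIFESPAN_RANGE
        u = stats.norm.cdf(stats.zscore(x, ddof=1))
        lifespan = lo + (hi - lo) * u
        rlo, rhi = _REARING_RANGE
        w = stats.norm.cdf(stats.zscore(y, ddof=1))
        rearing = rlo + (rhi - rlo) * w
        rearing = np.minimum(rearing, 0.5 * lifespan)  # keep rearing < lifespan
        pct = 100.0 * stats.norm.cdf(stats.zscore(y, ddof=1))
        df["lifespan_days"] = lifespan
        df["fw_days"] = rearing
        df["cylinder_pct"] = pct
    return df


def _fit_cell(cfg: SyntheticConfig):
    tree = simulate_tree(cfg)
    df = simulate_traits(tree, cfg)
    C = vcv(tree)
    X = design_matrix(C.species_order, x=df["x"].to_numpy())
    return profile_lambda(df["y"].to_numpy(), X, C)


def recovery_experiment(cells, n_reps: int, base_seed: int = 0,
                        alpha: float = 0.05) -> pd.DataFrame:
    """Monte-Carlo bias/RMSE/coverage of the slope and lambda estimators.

    *cells* is an iterable of :class:`SyntheticConfig`; each is replicated
    ``n_reps`` times with seeds derived deterministically from
    (base_seed, cell index, replicate index).  Failed fits are counted, not
    fatal.  Coverage is for the nominal (1 - alpha) t-interval of the slope;
    ``reject_rate`` is the slope-test rejection rate at level alpha (the
    empirical type-I error when the true slope is zero).
    """
    rows = []
    for ci, cell in enumerate(cells):
        b1_hat, lam_hat, covered, rejected = [], [], 0, 0
        failures = 0
        crit = stats.t.ppf(1 - alpha / 2, df=cell.n_tips - 2)
        for rep in range(n_reps):
            cfg = replace(cell, seed=int(
                np.random.SeedSequence(base_seed, spawn_key=(ci, rep)).generate_state(1)[0] % (2**31)
            ))
            try:
                fit = _fit_cell(cfg)
            except Exception:
                failures += 1
                continue
            b1 = fit.coefficients[1]
            se = fit.std_errors[1]
            b1_hat.append(b1)
            lam_hat.append(fit.lambda_hat)
            true_b1 = cell.true_beta[1]
            if abs(b1 - true_b1) <= crit * se:
                covered += 1
            if fit.p_values[1] < alpha:
                rejected += 1
        b1_hat = np.asarray(b1_hat)
        lam_hat = np.asarray(lam_hat)
        k = len(b1_hat)
        rows.append({
            "n_tips": cell.n_tips,
            "true_beta1": cell.true_beta[1],
            "true_lambda": cell.true_lambda,
            "n_ok": k,
            "n_failed": failures,
            "beta1_mean": b1_hat.mean() if k else np.nan,
            "beta1_bias": b1_hat.mean() - cell.true_beta[1] if k else np.nan,
            "beta1_rmse": float(np.sqrt(np.mean((b1_hat - cell.true_beta[1]) ** 2))) if k else np.nan,
            "beta1_mc_se": b1_hat.std(ddof=1) / np.sqrt(k) if k > 1 else np.nan,
            "beta1_coverage": covered / k if k else np.nan,
            "reject_rate": rejected / k if k else np.nan,
            "lambda_mean": lam_hat.mean() if k else np.nan,
            "lambda_bias": lam_hat.mean() - cell.true_lambda if k else np.nan,
            "lambda_rmse": float(np.sqrt(np.mean((lam_hat - cell.true_lambda) ** 2))) if k else np.nan,
        })
    return pd.DataFrame(rows)
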