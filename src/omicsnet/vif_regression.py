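"""Streamwise variable selection with variance-inflation-corrected tests and
alpha-investing, applied per target gene over all miRNA / methylation / CNV
candidates.

For one target gene the procedure is a single randomized pass over the
candidate stream.  Each candidate z is scored by the cheap marginal
t-statistic of the current residual on z; because that statistic is
under-dispersed when z is correlated with the variables already in the model,
it is corrected by the square root of the candidate's variance inflation
factor — the ratio of its marginal variance to its partial variance given the
current model — estimated on a fixed random subsample of size m.  The
corrected two-sided p-value is compared against an alpha-investing threshold:
a wealth w starts at w0, each test i spends alpha_i = w_i / (1 + i - f)
(f = index of the most recent acceptance), wealth decreases by the spent
alpha on a failure and earns a payout dw on an acceptance.  After the pass the
selected set is refit jointly by ordinary least squares and reported with its
adjusted R^2.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .io_formats import MultiOmicsDataset
from .networks import node_id

_MIN_SAMPLES = 10
_VAR_EPS = 1e-12


@dataclass
class VIFConfig:
    subsample_size: int = 200     # m; capped at n
    w0: float = 0.50              # initial alpha-investing wealth
    dw: float = 0.05              # payout per acceptance
    max_selected: int = 50
    standardize: bool = True
    n_passes: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.w0 < 1.0:
            raise ValueError("w0 must lie in (0, 1)")
        if self.dw <= 0:
            raise ValueError("dw must be positive")
        if self.subsample_size < 1 or self.max_selected < 1:
            raise ValueError("subsample_size and max_selected must be >= 1")
        if self.n_passes < 1:
            raise ValueError("n_passes must be >= 1")


@dataclass
class RegressionResult:
    target_gene: str
    selected: list[tuple[str, float]] = field(default_factory=list)
    intercept: float = 0.0
    adj_r2: float = 0.0
    n_used: int = 0
    n_candidates: int = 0
    n_tests: int = 0
    usable: bool = True
    message: str = ""

    def selected_nodes(self) -> list[str]:
        return [node for node, _ in self.selected]


def count_candidates(dataset: MultiOmicsDataset) -> int:
    """Total number of predictor variables across the regulator layers."""
    return sum(layer.n_features for layer in dataset.regulator_layers())


def adjusted_r2(r2: float, n: int, p: int) -> float:
    """1 - (1 - R^2)(n - 1)/(n - p - 1)."""
    if n - p - 1 < 1:
        raise ValueError(f"adjusted R^2 undefined for n={n}, p={p}")
    if not 0.0 <= r2 <= 1.0:
        raise ValueError("r2 must lie in [0, 1]")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


def candidate_design(dataset: MultiOmicsDataset
                     ) -> tuple[list[str], np.ndarray]:
    """Stack the three regulator layers into (node list, n x p matrix)."""
    nodes: list[str] = []
    blocks = []
    for layer in dataset.regulator_layers():
        nodes.extend(node_id(layer.layer_tag, f) for f in layer.feature_ids)
        blocks.append(layer.values.to_numpy())
    if not blocks or sum(b.shape[0] for b in blocks) == 0:
        return nodes, np.empty((dataset.n_samples, 0))
    return nodes, np.vstack(blocks).T.copy()


def _gene_rng(global_seed: int, gene: str) -> np.random.Generator:
    """Deterministic per-gene stream, independent of batch order and worker
    count."""
    key = zlib.crc32(gene.encode("utf-8"))
    return np.random.default_rng(
        np.random.SeedSequence([int(global_seed) & 0x7FFFFFFF, key]))


def _ols(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least squares of y on [1, X]; returns (coefs incl. intercept, resid)."""
    design = np.column_stack([np.ones(len(y)), X])
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    return beta, y - design @ beta


def _stream_select(y: np.ndarray, Z: np.ndarray, cfg: VIFConfig,
                   rng: np.random.Generator) -> tuple[list[int], int]:
    """Run the streamwise pass(es); returns (selected column indices, number
    of hypothesis tests spent).  ``y`` and columns of ``Z`` are standardized.
    """
    n, p = Z.shape
    m = min(cfg.subsample_size, n)
    sub = rng.choice(n, size=m, replace=False)
    order = rng.permutation(p)
    variances = Z.var(axis=0)
    testable = variances > _VAR_EPS

    selected: list[int] = []
    w = cfg.w0
    f = 0
    i_test = 0

    def _stats(remaining: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Marginal t and subsample VIF of every remaining candidate against
        the current model."""
        Xs = Z[:, selected]
        _, r = _ols(y, Xs)
        rss = float(r @ r)
        if rss < 1e-12:
            return np.zeros(len(remaining)), np.ones(len(remaining))
        Zr = Z[:, remaining]
        corr = Zr.T @ r
        # rho^2 of each candidate on the current model, on the m-subsample
        Zc = Zr[sub] - Zr[sub].mean(axis=0)
        denom = (Zc ** 2).sum(axis=0)
        if selected:
            Xc = Xs[sub] - Xs[sub].mean(axis=0)
            q, _ = np.linalg.qr(Xc)
            proj = q.T @ Zc
            rho2 = (proj ** 2).sum(axis=0) / np.maximum(denom, _VAR_EPS)
        else:
            rho2 = np.zeros(len(remaining))
        rho2 = np.clip(rho2, 0.0, 1.0 - 1e-6)
        vif = 1.0 / (1.0 - rho2)
        # Exact t of the would-be coefficient: the candidate's partial norm
        # is its marginal norm deflated by the (subsample-estimated) VIF, and
        # the error variance comes from the model including the candidate.
        zp2 = np.maximum((Zr ** 2).sum(axis=0) / vif, _VAR_EPS)
        dof = max(n - len(selected) - 2, 1)
        with np.errstate(invalid="ignore", divide="ignore"):
            sigma2 = np.maximum(rss - corr ** 2 / zp2, 1e-12) / dof
            t_corr = corr / np.sqrt(zp2 * sigma2)
        return t_corr, np.where(denom <= _VAR_EPS, np.inf, vif)

    for _ in range(cfg.n_passes):
        pending = [j for j in order if testable[j] and j not in selected]
        while pending:
            remaining = np.asarray(pending)
            t_corr, vif = _stats(remaining)
            if np.all(t_corr == 0):       # perfect fit: nothing left to test
                return selected, i_test
            accepted_here = False
            for pos, j in enumerate(remaining):
                i_test += 1
                alpha = w / (1.0 + i_test - f)
                if not np.isfinite(vif[pos]):
                    # degenerate on the subsample: untestable, spend anyway
                    w -= alpha
                    continue
                pval = 2.0 * stats.norm.sf(abs(t_corr[pos]))
                if pval < alpha and len(selected) < cfg.max_selected:
                    selected.append(int(j))
                    w += cfg.dw
                    f = i_test
                    # resume the stream after j with the enlarged model
                    pending = list(remaining[pos + 1:])
                    accepted_here = True
                    break
                w -= alpha
            if not accepted_here:
                pending = []
    return selected, i_test


def fit_gene(dataset: MultiOmicsDataset, target_gene: str,
             cfg: VIFConfig | None = None,
             _design: tuple[list[str], np.ndarray] | None = None
             ) -> RegressionResult:
    """Select regulators of one gene's expression and report the joint refit.

    Raises ``KeyError`` if the gene is absent from the expression layer.
    Regressions with fewer than 10 complete-case samples are returned flagged
    unusable; a constant target yields an empty selection with adjusted R^2 0.
    """
    cfg = cfg or VIFConfig()
    if target_gene not in dataset.mrna.values.index:
        raise KeyError(f"target gene {target_gene!r} not in expression layer")
    nodes, X = _design if _design is not None else candidate_design(dataset)
    y_full = dataset.mrna.values.loc[target_gene].to_numpy()

    # complete cases over the target and every participating candidate
    mask = np.isfinite(y_full)
    if X.shape[1]:
        mask &= np.isfinite(X).all(axis=1)
    y = y_full[mask]
    n_used = int(mask.sum())
    result = RegressionResult(target_gene=target_gene, n_used=n_used,
                              n_candidates=len(nodes))
    if n_used < _MIN_SAMPLES:
        result.usable = False
        result.message = f"only {n_used} complete cases (< {_MIN_SAMPLES})"
        return result
    if y.var() < _VAR_EPS:
        result.message = "constant target expression"
        return result
    Xm = X[mask]

    sd = Xm.std(axis=0)
    mu = Xm.mean(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        Zs = np.where(sd > _VAR_EPS, (Xm - mu) / np.where(sd > 0, sd, 1.0),
                      0.0)
    ys = (y - y.mean()) / y.std() if cfg.standardize else y

    rng = _gene_rng(cfg.seed, target_gene)
    sel_idx, n_tests = _stream_select(ys if cfg.standardize else y,
                                      Zs if cfg.standardize else Xm,
                                      cfg, rng)
    result.n_tests = n_tests
    if not sel_idx:
        return result

    beta, resid = _ols(y, Xm[:, sel_idx])           # refit on original scale
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = max(0.0, min(1.0, 1.0 - ss_res / ss_tot))
    p = len(sel_idx)
    if n_used - p - 1 < 1:
        result.usable = False
        result.message = "selection too large for adjusted R^2"
        return result
    result.intercept = float(beta[0])
    result.selected = [(nodes[j], float(b))
                       for j, b in zip(sel_idx, beta[1:])]
    result.adj_r2 = adjusted_r2(r2, n_used, p)
    return result


def fit_all(dataset: MultiOmicsDataset, cfg: VIFConfig | None = None,
            gene_subset: list[str] | None = None,
            n_jobs: int = 1) -> list[RegressionResult]:
    """One regression per (requested) gene; per-gene errors are reported as
    flagged results rather than aborting the batch.

    Results are independent of execution order and worker count because each
    gene draws its randomness from a seed derived from (global seed, gene id).
    """
    cfg = cfg or VIFConfig()
    genes = (list(gene_subset) if gene_subset is not None
             else dataset.mrna.feature_ids)
    design = candidate_design(dataset)

    def _one(gene: str) -> RegressionResult:
        try:
            return fit_gene(dataset, gene, cfg, _design=design)
        except Exception as exc:
            return RegressionResult(target_gene=gene, usable=False,
                                    message=f"{type(exc).__name__}: {exc}",
                                    n_candidates=len(design[0]))

    if n_jobs != 1:
        from joblib import Parallel, delayed
        return Parallel(n_jobs=n_jobs)(delayed(_one)(g) for g in genes)
    return [_one(g) for g in genes]
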