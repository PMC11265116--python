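"""The three-stage multiview selection model.

Stage 1 (:class:`MultiViewModel`): jointly learn a shared latent code Z
(n x K, a free optimization variable — there is no encoder) and per-view
decoders G_d by minimizing

    sum_d ||X^(d) - G_d(Z)||_{2,1} + lambda^d ||G_d(Z) A^(d)||_{2,1}

where A^(d) is the identity (plain variant) or the normalized graph Laplacian
of a prior feature network (smoothing variant).  The column-wise l2,1 penalty
shrinks reconstructed columns of irrelevant features toward zero; features are
then *ranked* by reconstructed column norm (shrinkage under autodiff-style
subgradients is not exact, so selection is by ranking, not by exact zeros).

Stage 2 (:class:`RefitModel`): refit fresh decoders R_d and a new code Z' on
the selected features only, minimizing plain Frobenius reconstruction error
subject to unit-norm rows of Z' (projected gradient).  The row constraint
removes the scale indeterminacy of jointly optimized (R_d, Z').

Stage 3 (:meth:`RefitResults.predict_latent`): infer codes for new samples by
optimizing Z'_test against the frozen stage-2 decoders, rows unit-norm.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

logger = logging.getLogger("mvselect")

from .data import MultiViewDataset
from .decoder import DecoderSpec, DecoderParams, init_params, forward, forward_cached, backward
from .graph import GraphPrior
from .norms import column_norms
from .optim import Adam, OptimizerConfig, early_stop


def _smooth_col_norms(M: np.ndarray, eps: float) -> np.ndarray:
    """sqrt(column sums of squares + eps): the eps-smoothed column norms."""
    return np.sqrt((M * M).sum(axis=0) + eps)


def _check_finite(loss: float, epoch: int, stage: str) -> None:
    if not np.isfinite(loss):
        raise RuntimeError(
            f"{stage}: loss became non-finite at epoch {epoch}; "
            "the learning rate is likely too high for this instance"
        )


def default_latent_dim(labels: np.ndarray | None) -> int:
    """2 x (number of classes) when labels exist, else 20."""
    if labels is None:
        return 20
    return 2 * len(np.unique(labels))


# --------------------------------------------------------------------------
# stage 1


class MultiViewModel:
    """Joint latent-code / sparse-decoder model for feature selection.

    Parameters
    ----------
    dataset : MultiViewDataset
        Standardized training data (each feature mean 0, variance 1).
    lambdas : float or sequence of float
        Sparsity penalty per view; a scalar is broadcast to all views.
    latent_dim : int, optional
        K; defaults to 2 x n_classes when the dataset has labels, else 20.
    depth, hidden_width, activation :
        Decoder architecture shared across views (the output width is
        per-view automatically).
    priors : sequence of GraphPrior or None, optional
        Per-view feature networks; where given, the penalty smooths the
        reconstruction with the network's normalized Laplacian.
    smoothing_eps : float
        eps in sqrt(. + eps) smoothing the l2,1 terms at zero columns.
    """

    def __init__(
        self,
        dataset: MultiViewDataset,
        lambdas: float | list[float] = 0.1,
        latent_dim: int | None = None,
        depth: int = 3,
        hidden_width: int = 256,
        activation: str = "relu",
        priors: list[GraphPrior | None] | None = None,
        smoothing_eps: float = 1e-8,
    ):
        self.dataset = dataset
        D = dataset.n_views
        if np.isscalar(lambdas):
            lambdas = [float(lambdas)] * D
        if len(lambdas) != D:
            raise ValueError(f"need {D} lambdas, got {len(lambdas)}")
        if any(l < 0 for l in lambdas):
            raise ValueError("lambdas must be nonnegative")
        self.lambdas = [float(l) for l in lambdas]
        self.latent_dim = latent_dim or default_latent_dim(dataset.labels)
        self.specs = [
            DecoderSpec(self.latent_dim, p, depth, hidden_width, activation)
            for p in dataset.n_features
        ]
        if priors is None:
            priors = [None] * D
        if len(priors) != D:
            raise ValueError(f"need {D} priors (or None), got {len(priors)}")
        for d, pr in enumerate(priors):
            if pr is not None and pr.n_vertices != dataset.n_features[d]:
                raise ValueError(
                    f"view {d}: prior has {pr.n_vertices} vertices but the view "
                    f"has {dataset.n_features[d]} features"
                )
        self.priors = list(priors)
        self.smoothing_eps = float(smoothing_eps)
        # Cache each view's penalty operator: the normalized Laplacian acts on
        # the graph-covered features; isolated features (degree 0) fall back
        # to the plain column penalty, otherwise they would escape shrinkage
        # entirely and outrank true signals.
        self._penalty_ops = []
        for pr in self.priors:
            if pr is None:
                self._penalty_ops.append(None)
            else:
                A = pr.normalized_laplacian
                covered = np.flatnonzero(pr.degrees > 0)
                isolated = np.flatnonzero(pr.degrees == 0)
                self._penalty_ops.append(
                    (A[np.ix_(covered, covered)], covered, isolated)
                )

    # -- objective -------------------------------------------------------

    def _view_loss_grad(
        self, d: int, G: np.ndarray
    ) -> tuple[float, np.ndarray]:
        """Loss contribution and d(loss)/dG for view d."""
        eps = self.smoothing_eps
        X = self.dataset.views[d]
        R = X - G
        nu_r = _smooth_col_norms(R, eps)
        loss = float(nu_r.sum())
        gG = -(R / nu_r)
        lam = self.lambdas[d]
        if lam > 0:
            op = self._penalty_ops[d]
            if op is None:
                nu_g = _smooth_col_norms(G, eps)
                loss += lam * float(nu_g.sum())
                gG = gG + lam * (G / nu_g)
            else:
                A, covered, isolated = op
                P = G[:, covered] @ A
                nu_p = _smooth_col_norms(P, eps)
                loss += lam * float(nu_p.sum())
                gG[:, covered] += lam * ((P / nu_p) @ A)  # A symmetric
                if isolated.size:
                    Gi = G[:, isolated]
                    nu_i = _smooth_col_norms(Gi, eps)
                    loss += lam * float(nu_i.sum())
                    gG[:, isolated] += lam * (Gi / nu_i)
        return loss, gG

    def objective(self, Z: np.ndarray, decoders: list[DecoderParams]) -> float:
        total = 0.0
        for d, params in enumerate(decoders):
            G = forward(params, Z)
            total += self._view_loss_grad(d, G)[0]
        return total

    # -- fitting ---------------------------------------------------------

    def fit(
        self,
        opt_config: OptimizerConfig | None = None,
        seed: int = 0,
        collapse_retries: int = 2,
    ) -> "SelectionResults":
        """Fit Z and all decoders by penalized full-batch gradient descent.

        The all-zero reconstruction is a degenerate optimum of the penalized
        objective that some initializations fall into; if any view ends with
        a near-zero mean reconstructed column norm the fit is retried with a
        fresh seed (up to ``collapse_retries`` times).  If every retry
        collapses, the penalty is consistently too strong for that instance
        and one final fit is run at half the penalty.  The effective
        penalties are recorded on the results.
        """
        result = self._fit_once(opt_config, seed)
        for attempt in range(collapse_retries):
            if not self._collapsed(result):
                break
            logger.info("stage 1: collapsed reconstruction, retry %d", attempt + 1)
            result = self._fit_once(opt_config, seed + 10007 * (attempt + 1))
        if collapse_retries > 0 and self._collapsed(result) and any(l > 0 for l in self.lambdas):
            original = self.lambdas
            try:
                self.lambdas = [l / 2 for l in original]
                logger.info("stage 1: still collapsed, refitting at lambda/2")
                result = self._fit_once(opt_config, seed + 77003)
            finally:
                result.effective_lambdas = list(self.lambdas)
                self.lambdas = original
        return result

    def _collapsed(self, result: "SelectionResults") -> bool:
        # full collapse: everything near zero; partial collapse: even the
        # top-ranked column is far below the scale of a reconstructed
        # standardized signal column (~sqrt(n))
        root_n = np.sqrt(self.dataset.n_samples)
        return any(
            cn.mean() < 0.02 * root_n or cn.max() < 0.1 * root_n
            for cn in result.column_norms
        )

    def _fit_once(
        self, opt_config: OptimizerConfig | None = None, seed: int = 0
    ) -> "SelectionResults":
        cfg = opt_config or OptimizerConfig()
        rng = np.random.default_rng(seed)
        n = self.dataset.n_samples
        K = self.latent_dim
        Z = rng.normal(size=(n, K)) / np.sqrt(K)
        decoders = [init_params(spec, rng) for spec in self.specs]

        flat = [Z] + [a for p in decoders for a in p.flat()]
        adam = Adam(flat, cfg)
        trace: list[float] = []
        full_lambdas = list(self.lambdas)
        warmup = min(cfg.warmup, cfg.epochs // 2)
        for epoch in range(cfg.epochs):
            # gradients follow the warm-up schedule (penalty off early); the
            # recorded trace is always the full penalized objective
            in_warmup = epoch < warmup
            self.lambdas = [0.0] * len(full_lambdas) if in_warmup else full_lambdas
            loss = 0.0
            gZ = np.zeros_like(Z)
            grads = [gZ]
            recorded = 0.0
            for d, params in enumerate(decoders):
                G, cache = forward_cached(params, Z)
                l_d, gG = self._view_loss_grad(d, G)
                loss += l_d
                gW, gb, dZ = backward(params, cache, gG)
                gZ += dZ
                grads.extend(gW + gb)
                if in_warmup:
                    self.lambdas = full_lambdas
                    recorded += self._view_loss_grad(d, G)[0]
                    self.lambdas = [0.0] * len(full_lambdas)
                else:
                    recorded += l_d
            _check_finite(loss, epoch, "stage 1")
            trace.append(recorded)
            adam.step(grads)
            if epoch >= warmup and early_stop(trace[warmup:], cfg):
                break
        self.lambdas = full_lambdas
        return SelectionResults(self, Z, decoders, trace, seed)


@dataclass
class SelectionResults:
    """Fitted stage-1 model: latent code, decoders, and feature ranking."""

    model: MultiViewModel
    Z: np.ndarray
    decoders: list[DecoderParams]
    loss_trace: list[float]
    seed: int
    selected: list[np.ndarray] | None = None
    selection_rate: float | int | None = None
    effective_lambdas: list[float] | None = None

    def __post_init__(self) -> None:
        self.reconstructions = [forward(p, self.Z) for p in self.decoders]
        self.column_norms = [column_norms(G) for G in self.reconstructions]
        self.ranks = [_ranks_from_norms(cn) for cn in self.column_norms]

    def select(self, r: float | int) -> list[np.ndarray]:
        """Select the top ``r`` (count) or ``r`` fraction of features per view;
        stores and returns the sorted 0-based index sets."""
        self.selected = select_top(self.ranks, r)
        self.selection_rate = r
        return self.selected

    def selected_dataset(self, dataset: MultiViewDataset | None = None) -> MultiViewDataset:
        """Restrict a dataset (default: the training data) to the selection."""
        if self.selected is None:
            raise ValueError("call select() first")
        return (dataset or self.model.dataset).subset_features(self.selected)

    def summary(self) -> str:
        lines = [
            "Multiview sparse-decoder selection (stage 1)",
            f"  views: {self.model.dataset.n_views}   samples: {self.model.dataset.n_samples}"
            f"   latent dim: {self.model.latent_dim}",
            f"  lambdas: {self.model.lambdas}",
            f"  priors: {['graph' if p is not None else '-' for p in self.model.priors]}",
            f"  epochs run: {len(self.loss_trace)}   final objective: {self.loss_trace[-1]:.4f}",
        ]
        for d, cn in enumerate(self.column_norms):
            top = np.argsort(self.ranks[d], kind="stable")[:5]
            names = [self.model.dataset.feature_names[d][j] for j in top]
            lines.append(f"  view {d}: top features by reconstructed norm: {names}")
            if self.selected is not None:
                lines.append(f"           selected: {len(self.selected[d])} features")
        return "\n".join(lines)


def _ranks_from_norms(norms: np.ndarray) -> np.ndarray:
    """Rank features 1..p by descending norm; ties by ascending index."""
    order = np.argsort(-norms, kind="stable")
    ranks = np.empty(len(norms), dtype=int)
    ranks[order] = np.arange(1, len(norms) + 1)
    return ranks


def rank_features(results: SelectionResults) -> list[np.ndarray]:
    """Per-view rank vectors (1 = largest reconstructed column norm)."""
    return results.ranks


def select_top(ranks: list[np.ndarray], r: float | int) -> list[np.ndarray]:
    """Indices of the top-ranked features per view, sorted ascending.

    ``r`` is either a fraction in (0, 1] (keep ceil(r * p) features) or an
    integer count in [1, p].
    """
    out = []
    for rk in ranks:
        p = len(rk)
        if isinstance(r, (int, np.integer)):
            if not 1 <= r <= p:
                raise ValueError(f"count r={r} out of range [1, {p}]")
            k = int(r)
        else:
            if not 0 < r <= 1:
                raise ValueError(f"fraction r={r} out of range (0, 1]")
            k = int(np.ceil(r * p))
        out.append(np.sort(np.flatnonzero(rk <= k)))
    return out


# --------------------------------------------------------------------------
# latent inference against frozen decoders (shared by tuning and stage 3)


def _infer_latent(
    decoders: list[DecoderParams],
    views: list[np.ndarray],
    Z0: np.ndarray,
    cfg: OptimizerConfig,
    unit_rows: bool,
) -> tuple[np.ndarray, float, list[float]]:
    """Minimize sum_d ||X^(d) - G_d(Z)||_F^2 over Z with decoders frozen.

    With ``unit_rows`` the rows of Z are projected to the unit sphere after
    every step.  Returns the best-objective Z seen, its objective, and the
    loss trace.
    """
    Z = Z0.copy()
    if unit_rows:
        Z = _project_rows(Z)
    adam = Adam([Z], cfg)
    trace: list[float] = []
    best = np.inf
    best_Z = Z.copy()
    for epoch in range(cfg.epochs):
        loss = 0.0
        gZ = np.zeros_like(Z)
        for params, X in zip(decoders, views):
            G, cache = forward_cached(params, Z)
            R = G - X
            loss += float((R * R).sum())
            gZ += backward(params, cache, 2.0 * R)[2]
        _check_finite(loss, epoch, "latent inference")
        trace.append(loss)
        if loss < best:
            best = loss
            best_Z = Z.copy()
        adam.step([gZ])
        if unit_rows:
            Z[:] = _project_rows(Z)
        if early_stop(trace, cfg):
            break
    return best_Z, best, trace


def _project_rows(Z: np.ndarray) -> np.ndarray:
    """Project each row onto the unit sphere (zero rows -> first basis vector)."""
    norms = np.linalg.norm(Z, axis=1, keepdims=True)
    out = np.divide(Z, norms, out=np.zeros_like(Z), where=norms > 0)
    zero = norms[:, 0] == 0
    if zero.any():
        out[zero, 0] = 1.0
    return out


# --------------------------------------------------------------------------
# stage 2


class RefitModel:
    """Frobenius refit on selected features with unit-norm latent rows.

    ``dataset`` holds the training views restricted to the selected feature
    columns (already standardized).  Decoders are freshly initialized — the
    refit is a new model on the reduced data, not a warm start of stage 1 —
    and no sparsity penalty is applied (non-sparse reconstruction is fine
    once selection is done).
    """

    def __init__(
        self,
        dataset: MultiViewDataset,
        latent_dim: int | None = None,
        depth: int = 3,
        hidden_width: int = 256,
        activation: str = "relu",
    ):
        for d, p in enumerate(dataset.n_features):
            if p == 0:
                raise ValueError(f"view {d}: empty feature selection")
        self.dataset = dataset
        self.latent_dim = latent_dim or default_latent_dim(dataset.labels)
        self.specs = [
            DecoderSpec(self.latent_dim, p, depth, hidden_width, activation)
            for p in dataset.n_features
        ]

    def fit(
        self, opt_config: OptimizerConfig | None = None, seed: int = 0
    ) -> "RefitResults":
        cfg = opt_config or OptimizerConfig()
        rng = np.random.default_rng(seed)
        n, K = self.dataset.n_samples, self.latent_dim
        Z = _project_rows(rng.normal(size=(n, K)))
        decoders = [init_params(spec, rng) for spec in self.specs]
        flat = [Z] + [a for p in decoders for a in p.flat()]
        adam = Adam(flat, cfg)
        trace: list[float] = []
        for epoch in range(cfg.epochs):
            loss = 0.0
            gZ = np.zeros_like(Z)
            grads = [gZ]
            for d, params in enumerate(decoders):
                G, cache = forward_cached(params, Z)
                R = G - self.dataset.views[d]
                loss += float((R * R).sum())
                gW, gb, dZ = backward(params, cache, 2.0 * R)
                gZ += dZ
                grads.extend(gW + gb)
            _check_finite(loss, epoch, "stage 2")
            trace.append(loss)
            adam.step(grads)
            Z[:] = _project_rows(Z)  # projected gradient: exact row constraint
            if early_stop(trace, cfg):
                break
        Z[:] = _project_rows(Z)
        objective = sum(
            float(((forward(p, Z) - X) ** 2).sum())
            for p, X in zip(decoders, self.dataset.views)
        )
        return RefitResults(self, Z, decoders, trace, objective, seed)


@dataclass
class RefitResults:
    """Fitted stage-2 model: unit-row latent code Z' and decoders R_d."""

    model: RefitModel
    Z: np.ndarray
    decoders: list[DecoderParams]
    loss_trace: list[float]
    objective: float
    seed: int

    def reconstructions(self) -> list[np.ndarray]:
        return [forward(p, self.Z) for p in self.decoders]

    def predict_latent(
        self,
        test_dataset: MultiViewDataset,
        opt_config: OptimizerConfig | None = None,
        seed: int = 0,
        restarts: int = 3,
    ) -> "PredictionResult":
        """Stage 3: infer unit-row latent codes for new samples.

        The decoders stay frozen; only Z'_test is optimized.  The first
        restart initializes each test row at the training code of its
        nearest training neighbor in concatenated feature space; remaining
        restarts start uniformly on the sphere.  The best objective wins.
        """
        _check_feature_match(self.model.dataset, test_dataset)
        cfg = opt_config or OptimizerConfig()
        rng = np.random.default_rng(seed)
        views = test_dataset.views
        n_test, K = test_dataset.n_samples, self.model.latent_dim

        train_cat = np.hstack(self.model.dataset.views)
        test_cat = np.hstack(views)
        d2 = ((test_cat[:, None, :] - train_cat[None, :, :]) ** 2).sum(-1) \
            if train_cat.shape[0] * n_test <= 4_000_000 else None
        if d2 is not None:
            nn_init = self.Z[np.argmin(d2, axis=1)]
        else:  # chunked nearest neighbour for large problems
            idx = np.empty(n_test, dtype=int)
            for start in range(0, n_test, 512):
                block = test_cat[start : start + 512]
                dd = ((block[:, None, :] - train_cat[None, :, :]) ** 2).sum(-1)
                idx[start : start + 512] = np.argmin(dd, axis=1)
            nn_init = self.Z[idx]

        best = None
        for r in range(max(1, restarts)):
            Z0 = nn_init if r == 0 else _project_rows(
                rng.normal(size=(n_test, K))
            )
            Z, obj, trace = _infer_latent(self.decoders, views, Z0, cfg, unit_rows=True)
            if best is None or obj < best[1]:
                best = (Z, obj, trace)
        Z, obj, trace = best
        residuals = [
            float(((forward(p, Z) - X) ** 2).sum())
            for p, X in zip(self.decoders, views)
        ]
        return PredictionResult(Z, residuals, trace, obj)

    def summary(self) -> str:
        row_norms = np.linalg.norm(self.Z, axis=1)
        return "\n".join(
            [
                "Multiview Frobenius refit (stage 2)",
                f"  views: {self.model.dataset.n_views}   samples: {self.model.dataset.n_samples}"
                f"   latent dim: {self.model.latent_dim}",
                f"  selected widths: {self.model.dataset.n_features}",
                f"  epochs run: {len(self.loss_trace)}   objective: {self.objective:.6f}",
                f"  max |row norm - 1|: {np.abs(row_norms - 1).max():.2e}",
            ]
        )


@dataclass
class PredictionResult:
    """Stage-3 output: inferred unit-row test codes and reconstruction residuals."""

    Z: np.ndarray
    residuals: list[float]
    loss_trace: list[float]
    objective: float


def _check_feature_match(train: MultiViewDataset, test: MultiViewDataset) -> None:
    if train.n_views != test.n_views:
        raise ValueError(
            f"train has {train.n_views} views but test has {test.n_views}"
        )
    for d, (a, b) in enumerate(zip(train.feature_names, test.feature_names)):
        missing = [x for x in a if x not in set(b)]
        if missing:
            raise ValueError(f"view {d}: test data missing selected features {missing}")
        if list(a) != list(b):
            raise ValueError(
                f"view {d}: test feature order differs from training; "
                "restrict the test views with the same index sets"
            )


# --------------------------------------------------------------------------
# lambda tuning


def tune_lambda(
    dataset: MultiViewDataset,
    candidate_lambdas: list,
    method: str = "kfold",
    k: int = 5,
    seed: int = 0,
    tune_dataset: MultiViewDataset | None = None,
    model_kwargs: dict | None = None,
    opt_config: OptimizerConfig | None = None,
    infer_config: OptimizerConfig | None = None,
) -> tuple[list[float], np.ndarray]:
    """Choose per-view penalties by held-out reconstruction error.

    For each candidate (a scalar or a per-view sequence), a stage-1 model is
    fit on the training portion, held-out codes are inferred against the
    frozen decoders, and the criterion is the summed Frobenius reconstruction
    error of the held-out views.  ``method='kfold'`` averages the criterion
    over k folds whose sizes differ by at most one; ``method='holdout'`` uses
    the supplied ``tune_dataset`` (the train/tune/test simulation design).

    Returns the winning candidate (as a per-view list) and the criterion
    value per candidate.  Deterministic given ``seed``.
    """
    if len(candidate_lambdas) == 0:
        raise ValueError("empty candidate set")
    if method not in ("kfold", "holdout"):
        raise ValueError(f"unknown method {method!r}")
    if method == "holdout" and tune_dataset is None:
        raise ValueError("holdout tuning needs a tune_dataset")
    model_kwargs = dict(model_kwargs or {})
    cfg = opt_config or OptimizerConfig()
    icfg = infer_config or replace(cfg, epochs=max(200, cfg.epochs // 4))
    rng = np.random.default_rng(seed)
    D = dataset.n_views

    def as_list(cand):
        return [float(cand)] * D if np.isscalar(cand) else [float(c) for c in cand]

    if method == "holdout":
        splits = [(dataset, tune_dataset)]
    else:
        n = dataset.n_samples
        perm = rng.permutation(n)
        folds = np.array_split(perm, k)
        splits = [
            (
                dataset.subset_samples(np.setdiff1d(perm, fold)),
                dataset.subset_samples(fold),
            )
            for fold in folds
        ]

    criteria = np.zeros(len(candidate_lambdas))
    for ci, cand in enumerate(candidate_lambdas):
        lams = as_list(cand)
        total = 0.0
        for si, (train, val) in enumerate(splits):
            model = MultiViewModel(train, lambdas=lams, **model_kwargs)
            res = model.fit(cfg, seed=seed + 1000 * si)
            K = model.latent_dim
            Z0 = np.random.default_rng(seed + ci).normal(
                size=(val.n_samples, K)
            ) / np.sqrt(K)
            Zv, obj, _ = _infer_latent(res.decoders, val.views, Z0, icfg, unit_rows=False)
            total += obj
        criteria[ci] = total / len(splits)
    best = int(np.argmin(criteria))
    return as_list(candidate_lambdas[best]), criteria
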