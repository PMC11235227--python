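"""Gated soft-attention multi-instance learning with quality weighting.

A slide (bag) is a variable-length set of tissue instances with a single
slide-level label.  Each instance's feature vector is embedded by a one-
hidden-layer network into ``h``; a gated attention head scores instances

    s_k = w^T (tanh(V h_k) * sigmoid(U h_k))

and the bag representation is the attention-weighted average
``z = sum_k a_k h_k`` with ``a = softmax(s)``, fed to a softmax classifier.
The gate (sigmoid branch) enhances the non-linearity of tanh for small
inputs; an un-gated variant drops it.  When quality weighting is enabled the
raw scores are scaled by the per-instance segmentation-quality weight
``g_k`` in [0, 1] *before* the softmax — at both training and test time — so
instances the segmentation ensemble disagrees on lose influence.  A
max-pooling instance-level classifier is provided as the classical MIL
baseline.

The model is a small numpy network with hand-derived gradients and an Adam
optimiser; everything is seeded and reproducible.  Interface follows the
model/results convention: :class:`AttentionMIL` holds bags and
configuration, ``fit`` returns an :class:`AttentionMILResults` carrying the
parameters, training history and prediction/summary methods.
"""

from __future__ import annotations

import copy
import itertools
from dataclasses import dataclass, field, replace
from typing import Any, Sequence

import numpy as np
import pandas as pd

from .containers import Bag, BagSet
from .evaluation import macro_ovr_auc, weighted_roc


@dataclass(frozen=True)
class ModelConfig:
    """Hyperparameters and training protocol for the attention model.

    ``patience`` implements the stagnation rule: training stops once the
    validation AUC has not improved by more than ``min_delta`` for
    ``patience`` consecutive epochs, restoring the best checkpoint.
    """

    n_features: int = 10
    n_classes: int = 2
    embed_width: int = 32
    attn_width: int = 16
    gated: bool = True
    mode: str = "attention"  # "attention" | "milmax"
    learning_rate: float = 2e-3
    weight_decay: float = 1e-3
    max_epochs: int = 150
    patience: int = 40
    min_delta: float = 1e-4
    use_quality_weights: bool = False
    include_g_feature: bool = False
    paper_literal_weighting: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if self.patience <= 0:
            raise ValueError("patience must be > 0")
        if self.mode not in ("attention", "milmax"):
            raise ValueError("mode must be 'attention' or 'milmax'")
        if self.mode == "milmax" and self.n_classes != 2:
            raise ValueError("the max-pooling baseline is binary only")


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _softmax(s: np.ndarray, order: np.ndarray | None = None) -> np.ndarray:
    """Stable softmax; the normalising sum runs in ``order`` if given, making
    the result invariant to the input permutation (max is order-free)."""
    e = np.exp(s - s.max())
    denom = e[order].sum() if order is not None else e.sum()
    return e / denom


def _canonical_order(X: np.ndarray) -> np.ndarray:
    """A permutation-invariant total order on instance rows (lexicographic on
    feature values); equal rows may land in any relative order, which cannot
    affect any reduction."""
    return np.lexsort(X.T)


def gated_attention(
    h: np.ndarray,
    V: np.ndarray,
    U: np.ndarray | None,
    w: np.ndarray,
    g: np.ndarray | None = None,
    gated: bool = True,
    paper_literal: bool = False,
    order: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Attention weights over instance embeddings ``h`` (K, E).

    Returns ``(a, raw_scores)``.  With ``g`` given, raw scores are scaled by
    ``g`` before the softmax; ``g = 1`` everywhere reproduces the unweighted
    attention bit-for-bit.  ``paper_literal`` keeps the printed form in which
    the denominator re-uses the numerator's own ``g_k`` (weights then do not
    normalise); the default shares the softmax denominator over ``g_j``.
    """
    if h.ndim != 2 or h.shape[0] < 1:
        raise ValueError("need >= 1 embedding")
    T = np.tanh(h @ V.T)
    if gated:
        if U is None:
            raise ValueError("gated attention requires U")
        m = T * _sigmoid(h @ U.T)
    else:
        m = T
    s = m @ w
    if g is None:
        return _softmax(s, order), s
    g = np.asarray(g, dtype=float)
    if g.shape != s.shape:
        raise ValueError("g must have one entry per instance")
    if g.min() < 0 or g.max() > 1:
        raise ValueError("g must lie in [0, 1]")
    if paper_literal:
        # a_k = exp(s_k g_k) / sum_j exp(s_j g_k): one denominator per k
        a = np.array([_softmax(s * gk, order)[k] for k, gk in enumerate(g)])
        return a, s
    return _softmax(s * g, order), s


def class_balanced_sampling_probs(labels: np.ndarray, n_classes: int) -> np.ndarray:
    """Per-bag sampling probabilities inversely proportional to class
    frequency, so rarer classes are drawn as often as common ones."""
    counts = np.bincount(labels, minlength=n_classes).astype(float)
    p = (1.0 / counts)[labels]
    return p / p.sum()


def _init_params(config: ModelConfig, rng: np.random.Generator) -> dict[str, np.ndarray]:
    D = config.n_features + (1 if config.include_g_feature else 0)
    E, A, C = config.embed_width, config.attn_width, config.n_classes
    p = {
        "W1": rng.normal(0.0, 1.0 / np.sqrt(D), (D, E)),
        "b1": np.zeros(E),
        "V": rng.normal(0.0, 1.0 / np.sqrt(E), (A, E)),
        "U": rng.normal(0.0, 1.0 / np.sqrt(E), (A, E)),
        "w": rng.normal(0.0, 1.0 / np.sqrt(A), A),
        "Wc": rng.normal(0.0, 1.0 / np.sqrt(E), (E, C)),
        "bc": np.zeros(C),
    }
    return p


def _bag_matrix(bag: Bag, config: ModelConfig) -> tuple[np.ndarray, np.ndarray | None]:
    X = bag.features
    g = None
    if config.use_quality_weights or config.include_g_feature:
        if bag.g is None:
            raise ValueError(f"bag {bag.bag_id} has no quality weights g")
        g = bag.g
    if config.include_g_feature:
        X = np.concatenate([X, g[:, None]], axis=1)
    return X, (g if config.use_quality_weights else None)


def _forward_attention(params, X, g, config: ModelConfig, order=None):
    h = np.tanh(X @ params["W1"] + params["b1"])
    a, s = gated_attention(
        h,
        params["V"],
        params["U"] if config.gated else None,
        params["w"],
        g=g,
        gated=config.gated,
        paper_literal=config.paper_literal_weighting,
        order=order,
    )
    if order is not None:
        z = (a[order, None] * h[order]).sum(axis=0)
    else:
        z = a @ h
    logits = z @ params["Wc"] + params["bc"]
    probs = _softmax(logits)
    return probs, a, h, z, s


def _forward_milmax(params, X):
    h = np.tanh(X @ params["W1"] + params["b1"])
    logits = h @ params["Wc"] + params["bc"]
    logits = logits - logits.max(axis=1, keepdims=True)
    P = np.exp(logits)
    P /= P.sum(axis=1, keepdims=True)
    k_star = int(np.argmax(P[:, 1]))
    return P, k_star, h


def _backward_attention(params, X, g, y, config: ModelConfig, grads):
    """Accumulate gradients of the cross-entropy loss for one bag."""
    h = np.tanh(X @ params["W1"] + params["b1"])
    T = np.tanh(h @ params["V"].T)
    if config.gated:
        S = _sigmoid(h @ params["U"].T)
        m = T * S
    else:
        S = None
        m = T
    s = m @ params["w"]
    se = s * g if g is not None else s
    a = _softmax(se)
    z = a @ h
    logits = z @ params["Wc"] + params["bc"]
    p = _softmax(logits)
    loss = -float(np.log(max(p[y], 1e-300)))

    dlogits = p.copy()
    dlogits[y] -= 1.0
    grads["Wc"] += np.outer(z, dlogits)
    grads["bc"] += dlogits
    dz = params["Wc"] @ dlogits
    da = h @ dz
    dh = a[:, None] * dz[None, :]
    dse = a * (da - float(a @ da))
    ds = dse * g if g is not None else dse
    dm = ds[:, None] * params["w"][None, :]
    if config.gated:
        dT = dm * S
        dS = dm * T
        du = dS * S * (1.0 - S)
        grads["U"] += du.T @ h
        dh += du @ params["U"]
    else:
        dT = dm
    dt = dT * (1.0 - T * T)
    grads["V"] += dt.T @ h
    grads["w"] += m.T @ ds
    dh += dt @ params["V"]
    dZ1 = dh * (1.0 - h * h)
    grads["W1"] += X.T @ dZ1
    grads["b1"] += dZ1.sum(axis=0)
    return loss


def _backward_milmax(params, X, y, grads):
    P, k_star, h = _forward_milmax(params, X)
    p = P[k_star]
    loss = -float(np.log(max(p[y], 1e-300)))
    dlogits = p.copy()
    dlogits[y] -= 1.0
    grads["Wc"] += np.outer(h[k_star], dlogits)
    grads["bc"] += dlogits
    dh = params["Wc"] @ dlogits
    dZ1 = dh * (1.0 - h[k_star] * h[k_star])
    grads["W1"] += np.outer(X[k_star], dZ1)
    grads["b1"] += dZ1
    return loss


class _Adam:
    def __init__(self, params, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for k in params:
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * grads[k]
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * grads[k] ** 2
            params[k] -= self.lr * (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + self.eps)


class AttentionMIL:
    """Bag-level attention classifier over a collection of bags.

    Parameters
    ----------
    bags
        The full bag collection; ``fit`` selects training/validation subsets
        by index.
    config
        Model and protocol configuration.
    """

    def __init__(self, bags: Sequence[Bag] | BagSet, config: ModelConfig):
        self.bags: list[Bag] = list(bags)
        if not self.bags:
            raise ValueError("need at least one bag")
        self.config = config
        widths = {b.features.shape[1] for b in self.bags}
        if widths != {config.n_features}:
            raise ValueError(
                f"bag feature widths {sorted(widths)} do not match config.n_features"
            )

    def _default_split(self, seed: int) -> tuple[list[int], list[int]]:
        donors = sorted({b.donor_id for b in self.bags})
        rng = np.random.default_rng(seed)
        donors = list(rng.permutation(donors))
        n_val = max(1, len(donors) // 5)
        val_donors = set(donors[:n_val])
        tr = [i for i, b in enumerate(self.bags) if b.donor_id not in val_donors]
        va = [i for i, b in enumerate(self.bags) if b.donor_id in val_donors]
        return tr, va

    def fit(
        self,
        train_idx: Sequence[int] | None = None,
        val_idx: Sequence[int] | None = None,
        seed: int | None = None,
    ) -> "AttentionMILResults":
        """Train with class-balanced weighted sampling and AUC early stopping.

        Bags are sampled with probability inversely proportional to their
        class frequency (one bag per optimiser step).  The validation macro
        AUC is monitored every epoch; training stops ``patience`` epochs
        after it stagnates and the best-validation checkpoint is restored.
        """
        config = self.config
        seed = config.seed if seed is None else seed
        if train_idx is None or val_idx is None:
            train_idx, val_idx = self._default_split(seed)
        train_idx = list(train_idx)
        val_idx = list(val_idx)
        if set(train_idx) & set(val_idx):
            raise ValueError("train and validation indices overlap")
        y_tr = np.array([self.bags[i].label for i in train_idx])
        y_va = np.array([self.bags[i].label for i in val_idx])
        classes = np.arange(config.n_classes)
        if set(classes) - set(y_tr):
            raise ValueError("every class must be present in the training set")
        if set(classes) - set(y_va):
            raise ValueError("validation set is missing a class")

        rng = np.random.default_rng(seed)
        params = _init_params(config, rng)
        opt = _Adam(params, config.learning_rate)
        p_sample = class_balanced_sampling_probs(y_tr, config.n_classes)

        cached = [_bag_matrix(self.bags[i], config) for i in train_idx]
        best = {"auc": -np.inf, "epoch": -1, "params": copy.deepcopy(params)}
        history = []
        stale = 0
        for epoch in range(config.max_epochs):
            order = rng.choice(len(train_idx), size=len(train_idx), p=p_sample)
            total = 0.0
            for j in order:
                X, g = cached[j]
                grads = {k: np.zeros_like(v) for k, v in params.items()}
                if config.mode == "attention":
                    total += _backward_attention(params, X, g, y_tr[j], config, grads)
                else:
                    total += _backward_milmax(params, X, y_tr[j], grads)
                for k in ("W1", "V", "U", "w", "Wc"):
                    grads[k] += config.weight_decay * params[k]
                opt.step(params, grads)
            val_auc = self._val_auc(params, val_idx, y_va)
            history.append(
                {"epoch": epoch, "train_loss": total / len(order), "val_auc": val_auc}
            )
            if val_auc > best["auc"] + config.min_delta:
                best = {"auc": val_auc, "epoch": epoch, "params": copy.deepcopy(params)}
                stale = 0
            else:
                stale += 1
                if stale >= config.patience:
                    break
        return AttentionMILResults(
            model=self,
            config=config,
            params=best["params"],
            history=pd.DataFrame(history),
            best_epoch=best["epoch"],
            best_val_auc=float(best["auc"]),
            seed=seed,
            train_idx=train_idx,
            val_idx=val_idx,
        )

    def _val_auc(self, params, val_idx, y_va) -> float:
        scores = np.vstack(
            [self._predict_with(params, self.bags[i])[0] for i in val_idx]
        )
        return macro_ovr_auc(y_va, scores, np.ones(len(val_idx)))

    def _predict_with(self, params, bag: Bag) -> tuple[np.ndarray, np.ndarray]:
        config = self.config
        X, g = _bag_matrix(bag, config)
        if config.mode == "milmax":
            P, k_star, _ = _forward_milmax(params, X)
            a = np.zeros(X.shape[0])
            a[k_star] = 1.0
            return P[k_star], a
        order = _canonical_order(X)
        probs, a, _, _, _ = _forward_attention(params, X, g, config, order=order)
        return probs, a


@dataclass
class AttentionMILResults:
    """Fitted attention-MIL model: parameters, history and predictions."""

    model: AttentionMIL
    config: ModelConfig
    params: dict[str, np.ndarray]
    history: pd.DataFrame
    best_epoch: int
    best_val_auc: float
    seed: int
    train_idx: list[int] = field(default_factory=list)
    val_idx: list[int] = field(default_factory=list)

    def predict(self, bag: Bag) -> tuple[np.ndarray, np.ndarray]:
        """Class probabilities and attention weights for one bag.

        The softmax normalisation and the attention pooling both reduce in a
        canonical (value-sorted) instance order, so the output is invariant
        to instance permutation bit-for-bit.
        """
        return self.model._predict_with(self.params, bag)

    def predict_many(self, bags: Sequence[Bag]) -> pd.DataFrame:
        rows = []
        for b in bags:
            probs, _ = self.predict(b)
            row = {"bag_id": b.bag_id, "label": b.label, "n_tissues": b.n_tissues}
            for c, p in enumerate(probs):
                row[f"score_{c}"] = p
            rows.append(row)
        return pd.DataFrame(rows)

    def attend(self, bag: Bag) -> np.ndarray:
        return self.predict(bag)[1]

    def summary(self) -> str:
        c = self.config
        lines = [
            "Attention-MIL results",
            "=" * 54,
            f"mode:               {c.mode} ({'gated' if c.gated else 'un-gated'})",
            f"classes:            {c.n_classes}",
            f"features:           {c.n_features}"
            + (" + g" if c.include_g_feature else ""),
            f"embedding width:    {c.embed_width}  attention width: {c.attn_width}",
            f"quality weighting:  {c.use_quality_weights}",
            f"epochs run:         {len(self.history)} (best epoch {self.best_epoch})",
            f"best val macro AUC: {self.best_val_auc:.4f}",
            f"train/val bags:     {len(self.train_idx)}/{len(self.val_idx)}",
            f"seed:               {self.seed}",
            "=" * 54,
        ]
        return "\n".join(lines)


def train(
    bags: Sequence[Bag] | BagSet,
    config: ModelConfig,
    split: tuple[Sequence[int], Sequence[int]] | None = None,
    seed: int | None = None,
) -> AttentionMILResults:
    """Functional wrapper: build the model and fit one split."""
    model = AttentionMIL(bags, config)
    if split is None:
        return model.fit(seed=seed)
    return model.fit(split[0], split[1], seed=seed)


def donor_folds(
    bags: Sequence[Bag], n_folds: int, seed: int
) -> list[tuple[list[int], list[int], list[int]]]:
    """Donor-grouped fold assignment: folds partition donors, never bags.

    Fold ``f`` uses donor group ``f`` for testing, group ``f+1`` (cyclic) for
    validation and the rest for training — a 3:1:1 split at five folds.
    """
    donors = sorted({b.donor_id for b in bags})
    if len(donors) < n_folds:
        raise ValueError("too few donors for the requested folds")
    rng = np.random.default_rng(seed)
    perm = list(rng.permutation(donors))
    groups = [set(g) for g in np.array_split(perm, n_folds)]
    out = []
    for f in range(n_folds):
        test_d = groups[f]
        val_d = groups[(f + 1) % n_folds]
        tr = [i for i, b in enumerate(bags) if b.donor_id not in test_d | val_d]
        va = [i for i, b in enumerate(bags) if b.donor_id in val_d]
        te = [i for i, b in enumerate(bags) if b.donor_id in test_d]
        out.append((tr, va, te))
    return out


@dataclass
class CrossValidationResults:
    """Per-(fold, seed) models and pooled out-of-fold test predictions."""

    models: dict[tuple[int, int], AttentionMILResults]
    predictions: pd.DataFrame
    fold_donors: list[set]
    config: ModelConfig
    n_folds: int
    n_seeds: int

    def auc_per_model(self) -> pd.DataFrame:
        """Tissue-count-weighted test AUC for each of the fold x seed models."""
        rows = []
        score_cols = [c for c in self.predictions.columns if c.startswith("score_")]
        for (fold, seed), grp in self.predictions.groupby(["fold", "seed"]):
            y = grp["label"].to_numpy()
            w = grp["n_tissues"].to_numpy(float)
            S = grp[score_cols].to_numpy(float)
            if self.config.n_classes == 2:
                auc = weighted_roc(y, S[:, 1], w).auc
            else:
                auc = macro_ovr_auc(y, S, w)
            rows.append({"fold": fold, "seed": seed, "auc": auc})
        return pd.DataFrame(rows)

    def summary(self) -> str:
        aucs = self.auc_per_model()["auc"]
        se = aucs.std(ddof=1) / np.sqrt(len(aucs)) if len(aucs) > 1 else np.nan
        return (
            f"Cross-validation: {self.n_folds} folds x {self.n_seeds} seeds = "
            f"{len(self.models)} models\n"
            f"weighted test ROC-AUC: {aucs.mean():.4f} +/- {se:.4f} (se over models)"
        )


def cross_validate(
    bags: Sequence[Bag] | BagSet,
    config: ModelConfig,
    n_folds: int = 5,
    n_seeds: int = 5,
    seed: int = 0,
) -> CrossValidationResults:
    """Donor-grouped cross-validation: 3:1:1 folds x seeded initialisations.

    All bags of a donor share a fold; per (fold, seed) one model is trained
    and its out-of-fold test predictions are pooled in ``predictions``.
    """
    bags = list(bags)
    labels = np.array([b.label for b in bags])
    for c in range(config.n_classes):
        donors_c = {b.donor_id for b, y in zip(bags, labels) if y == c}
        if len(donors_c) < n_folds:
            raise ValueError(
                f"class {c} has only {len(donors_c)} donors; need >= {n_folds}"
            )
    folds = donor_folds(bags, n_folds, seed)
    model = AttentionMIL(bags, config)
    models: dict[tuple[int, int], AttentionMILResults] = {}
    rows = []
    for f, (tr, va, te) in enumerate(folds):
        for s in range(n_seeds):
            fit_seed = (seed * 9973 + f * 101 + s) % (2**31)
            res = model.fit(tr, va, seed=fit_seed)
            models[(f, s)] = res
            for i in te:
                probs, _ = res.predict(bags[i])
                row = {
                    "bag_id": bags[i].bag_id,
                    "donor_id": bags[i].donor_id,
                    "fold": f,
                    "seed": s,
                    "label": bags[i].label,
                    "n_tissues": bags[i].n_tissues,
                }
                for c, p in enumerate(probs):
                    row[f"score_{c}"] = p
                rows.append(row)
    fold_donors = [set(b.donor_id for i, b in enumerate(bags) if i in set(te)) for (_, _, te) in folds]
    return CrossValidationResults(
        models=models,
        predictions=pd.DataFrame(rows),
        fold_donors=fold_donors,
        config=config,
        n_folds=n_folds,
        n_seeds=n_seeds,
    )


def tune_hyperparameters(
    bags: Sequence[Bag] | BagSet,
    search_space: dict[str, Sequence[Any]],
    budget: int,
    base_config: ModelConfig,
    seed: int = 0,
) -> ModelConfig:
    """Config-driven random search maximising validation macro AUC.

    Intended to run on the trivial instance-count task (all bags labelled),
    after which the chosen configuration is frozen for the real tasks.  A
    degenerate one-point space is returned without training twice; if the
    whole space is smaller than the budget it is enumerated once.
    """
    if budget < 1:
        raise ValueError("budget must be >= 1")
    if not search_space or any(len(v) == 0 for v in search_space.values()):
        raise ValueError("search space is empty")
    keys = sorted(search_space)
    grid = list(itertools.product(*(search_space[k] for k in keys)))
    rng = np.random.default_rng(seed)
    if len(grid) == 1:
        return replace(base_config, **dict(zip(keys, grid[0])))
    if len(grid) > budget:
        pick = rng.choice(len(grid), size=budget, replace=False)
        grid = [grid[i] for i in pick]
    best_cfg, best_auc = None, -np.inf
    for values in grid:
        cfg = replace(base_config, **dict(zip(keys, values)))
        res = train(bags, cfg, seed=seed)
        if res.best_val_auc > best_auc:
            best_auc, best_cfg = res.best_val_auc, cfg
    return best_cfg
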