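"""Bayesian additive regression trees (probit link) for binary outcomes.

A sum-of-trees model ``P(y=1|x) = Phi(offset + sum_t g_t(x))`` sampled by
MCMC: Albert-Chib truncated-normal latent augmentation for the probit link,
grow/prune Metropolis-Hastings moves on each tree's structure under the
Chipman-George-McCulloch depth prior ``p_split(d) = alpha (1+d)^(-beta)``,
and conjugate Gaussian leaf updates. Variable importance is the posterior
proportion of splitting rules that use each predictor.

The implementation is self-contained and deterministic given ``random_state``.
"""

from __future__ import annotations

import numpy as np
from scipy.special import ndtr, ndtri
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

__all__ = ["BartClassifier"]


class _Tree:
    """Flat-array binary tree; node i is a leaf iff left[i] == -1.

    Pruned-away nodes are tombstoned with left == -9 and skipped everywhere;
    array slots are never reused within one tree's lifetime.
    """

    __slots__ = ("var", "thr", "left", "right", "depth", "value", "leaf_of")

    def __init__(self, n_points: int):
        self.var = [-1]
        self.thr = [0.0]
        self.left = [-1]
        self.right = [-1]
        self.depth = [0]
        self.value = [0.0]
        self.leaf_of = np.zeros(n_points, dtype=np.int64)

    # -- structure queries ----------------------------------------------------

    def leaves(self) -> list[int]:
        return [i for i, l in enumerate(self.left) if l == -1]

    def nog_nodes(self) -> list[int]:
        """Internal nodes whose two children are both leaves."""
        return [
            i
            for i, l in enumerate(self.left)
            if l >= 0 and self.left[l] == -1 and self.left[self.right[i]] == -1
        ]

    def is_stump(self) -> bool:
        return self.left[0] < 0

    def split_vars(self) -> list[int]:
        return [v for v, l in zip(self.var, self.left) if l >= 0]

    # -- evaluation -------------------------------------------------------------

    def fits(self) -> np.ndarray:
        vals = np.asarray(self.value)
        return vals[self.leaf_of]

    def predict(self, X: np.ndarray) -> np.ndarray:
        out = np.empty(X.shape[0])
        stack = [(0, np.arange(X.shape[0]))]
        while stack:
            node, idx = stack.pop()
            if self.left[node] < 0:
                out[idx] = self.value[node]
                continue
            go_left = X[idx, self.var[node]] <= self.thr[node]
            stack.append((self.left[node], idx[go_left]))
            stack.append((self.right[node], idx[~go_left]))
        return out

    def snapshot(self) -> tuple:
        return (
            np.array(self.var),
            np.array(self.thr),
            np.array(self.left),
            np.array(self.right),
            np.array(self.value),
        )


def _predict_snapshot(snap: tuple, X: np.ndarray) -> np.ndarray:
    var, thr, left, right, value = snap
    out = np.empty(X.shape[0])
    stack = [(0, np.arange(X.shape[0]))]
    while stack:
        node, idx = stack.pop()
        if left[node] < 0:
            out[idx] = value[node]
            continue
        go_left = X[idx, var[node]] <= thr[node]
        stack.append((left[node], idx[go_left]))
        stack.append((right[node], idx[~go_left]))
    return out


def _leaf_loglik(n: float, s: float, tau2: float) -> float:
    """Integrated Gaussian leaf likelihood (sigma=1), dropping terms that cancel."""
    c = 1.0 + n * tau2
    return -0.5 * np.log(c) + tau2 * s * s / (2.0 * c)


class BartClassifier(ClassifierMixin, BaseEstimator):
    """Probit BART binary classifier.

    Parameters
    ----------
    n_trees : number of trees in the ensemble.
    n_draws, n_burn : posterior draws kept / discarded.
    alpha, beta : depth prior; P(split at depth d) = alpha * (1+d)^(-beta).
    k : leaf shrinkage; leaf prior sd = 3 / (k * sqrt(n_trees)).
    max_snapshots : at most this many kept draws are stored for prediction
        (evenly thinned); importance uses every kept draw.
    random_state : seed for the entire chain.

    Attributes
    ----------
    importance_ : posterior proportion of splitting rules using each feature;
        non-negative, sums to 1 (uniform when no draw contains any split).
    """

    def __init__(
        self,
        n_trees: int = 50,
        n_draws: int = 2000,
        n_burn: int = 500,
        alpha: float = 0.95,
        beta: float = 2.0,
        k: float = 2.0,
        max_snapshots: int = 200,
        random_state: int = 0,
    ):
        self.n_trees = n_trees
        self.n_draws = n_draws
        self.n_burn = n_burn
        self.alpha = alpha
        self.beta = beta
        self.k = k
        self.max_snapshots = max_snapshots
        self.random_state = random_state

    # -------------------------------------------------------------------------

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        n, p = X.shape
        classes = np.unique(y)
        if set(classes) - {0, 1}:
            raise ValueError("y must be binary 0/1")
        if len(classes) < 2:
            raise ValueError("both classes must be present")
        self.classes_ = np.array([0, 1])
        rng = np.random.default_rng(self.random_state)
        tau = 3.0 / (self.k * np.sqrt(self.n_trees))
        tau2 = tau * tau
        offset = float(ndtri(np.clip(y.mean(), 0.05, 0.95)))

        trees = [_Tree(n) for _ in range(self.n_trees)]
        total_fit = np.zeros(n)
        z = offset + np.where(y == 1, 0.5, -0.5)  # latent init

        split_counts = np.zeros(p)
        total_splits = 0.0
        snapshots: list[list[tuple]] = []
        keep_every = max(1, (self.n_draws - 1) // self.max_snapshots + 1)
        self._snapshot_draws = 0

        total = self.n_burn + self.n_draws
        for it in range(total):
            resid_base = z - offset
            for tree in trees:
                tree_fit = tree.fits()
                R = resid_base - (total_fit - tree_fit)
                self._update_tree(tree, X, R, tau2, rng)
                self._draw_leaf_values(tree, R, tau2, rng)
                total_fit += tree.fits() - tree_fit
            # Albert-Chib latent update
            mu = total_fit + offset
            u = rng.random(n)
            lo = ndtr(-mu)  # P(z < 0)
            pos = y == 1
            z = np.empty(n)
            z[pos] = mu[pos] + ndtri(lo[pos] + u[pos] * (1.0 - lo[pos]))
            z[~pos] = mu[~pos] + ndtri(u[~pos] * lo[~pos])
            z = np.clip(z, mu - 6.0, mu + 6.0)

            if it >= self.n_burn:
                kept = it - self.n_burn
                for tree in trees:
                    for v in tree.split_vars():
                        split_counts[v] += 1.0
                        total_splits += 1.0
                if kept % keep_every == 0:
                    snapshots.append([t.snapshot() for t in trees])

        self.offset_ = offset
        self.snapshots_ = snapshots
        if total_splits > 0:
            self.importance_ = split_counts / total_splits
        else:
            self.importance_ = np.full(p, 1.0 / p)
        self.n_features_in_ = p
        return self

    # -- MH structure move -----------------------------------------------------

    def _p_split(self, depth: int) -> float:
        return self.alpha * (1.0 + depth) ** (-self.beta)

    def _update_tree(self, tree: _Tree, X, R, tau2, rng) -> None:
        grow_prob = 1.0 if tree.is_stump() else 0.5
        if rng.random() < grow_prob:
            self._try_grow(tree, X, R, tau2, rng, grow_prob)
        else:
            self._try_prune(tree, X, R, tau2, rng)

    def _try_grow(self, tree, X, R, tau2, rng, grow_prob) -> None:
        leaves = tree.leaves()
        leaf = leaves[rng.integers(len(leaves))]
        idx = np.flatnonzero(tree.leaf_of == leaf)
        if idx.size < 2:
            return
        avail = [v for v in range(X.shape[1]) if np.unique(X[idx, v]).size >= 2]
        if not avail:
            return
        v = avail[rng.integers(len(avail))]
        cuts = np.unique(X[idx, v])[:-1]
        c = cuts[rng.integers(len(cuts))]
        go_left = X[idx, v] <= c

        s = R[idx].sum()
        sl = R[idx[go_left]].sum()
        nl = int(go_left.sum())
        nr = idx.size - nl
        log_lik = (
            _leaf_loglik(nl, sl, tau2)
            + _leaf_loglik(nr, s - sl, tau2)
            - _leaf_loglik(idx.size, s, tau2)
        )
        d = tree.depth[leaf]
        ps, ps_child = self._p_split(d), self._p_split(d + 1)
        # structure prior ratio; the split-rule prior (uniform over available
        # variables and cutpoints) cancels the matching proposal terms exactly
        log_prior = np.log(ps) + 2.0 * np.log(1.0 - ps_child) - np.log(1.0 - ps)
        parent_is_nog = any(
            tree.left[i] == leaf or tree.right[i] == leaf for i in tree.nog_nodes()
        )
        n_nog_after = len(tree.nog_nodes()) + (0 if parent_is_nog else 1)
        log_forward = np.log(grow_prob) - np.log(len(leaves))
        log_reverse = np.log(0.5) - np.log(max(n_nog_after, 1))
        if np.log(rng.random()) < log_lik + log_prior + log_reverse - log_forward:
            tree.var[leaf] = v
            tree.thr[leaf] = float(c)
            l_id, r_id = len(tree.var), len(tree.var) + 1
            tree.left[leaf], tree.right[leaf] = l_id, r_id
            for _ in range(2):
                tree.var.append(-1)
                tree.thr.append(0.0)
                tree.left.append(-1)
                tree.right.append(-1)
                tree.depth.append(d + 1)
                tree.value.append(0.0)
            tree.leaf_of[idx[go_left]] = l_id
            tree.leaf_of[idx[~go_left]] = r_id

    def _try_prune(self, tree, X, R, tau2, rng) -> None:
        nogs = tree.nog_nodes()
        if not nogs:
            return
        node = nogs[rng.integers(len(nogs))]
        l_id, r_id = tree.left[node], tree.right[node]
        idx_l = np.flatnonzero(tree.leaf_of == l_id)
        idx_r = np.flatnonzero(tree.leaf_of == r_id)
        sl, sr = R[idx_l].sum(), R[idx_r].sum()
        nl, nr = idx_l.size, idx_r.size
        log_lik = (
            _leaf_loglik(nl + nr, sl + sr, tau2)
            - _leaf_loglik(nl, sl, tau2)
            - _leaf_loglik(nr, sr, tau2)
        )
        d = tree.depth[node]
        ps, ps_child = self._p_split(d), self._p_split(d + 1)
        log_prior = np.log(1.0 - ps) - np.log(ps) - 2.0 * np.log(1.0 - ps_child)
        # reverse move is the grow that re-creates this split; the split-rule
        # prior cancels the variable/cutpoint proposal terms as in _try_grow
        idx = np.concatenate([idx_l, idx_r])
        n_leaves_after = len(tree.leaves()) - 1
        grow_prob_after = 1.0 if n_leaves_after == 1 else 0.5
        log_forward = np.log(0.5) - np.log(len(nogs))
        log_reverse = np.log(grow_prob_after) - np.log(n_leaves_after)
        if np.log(rng.random()) < log_lik + log_prior + log_reverse - log_forward:
            tree.leaf_of[idx] = node
            tree.left[l_id] = -9
            tree.left[r_id] = -9
            tree.left[node] = -1
            tree.right[node] = -1
            tree.var[node] = -1

    def _draw_leaf_values(self, tree, R, tau2, rng) -> None:
        leaf_ids = tree.leaves()
        remap = {lid: i for i, lid in enumerate(leaf_ids)}
        compact = np.array([remap[l] for l in tree.leaf_of])
        counts = np.bincount(compact, minlength=len(leaf_ids)).astype(float)
        sums = np.bincount(compact, weights=R, minlength=len(leaf_ids))
        post_var = tau2 / (1.0 + counts * tau2)
        post_mean = post_var * sums
        draws = post_mean + np.sqrt(post_var) * rng.standard_normal(len(leaf_ids))
        for lid, val in zip(leaf_ids, draws):
            tree.value[lid] = float(val)

    # -------------------------------------------------------------------------

    def predict_proba(self, X):
        check_is_fitted(self, "snapshots_")
        X = np.asarray(X, dtype=float)
        acc = np.zeros(X.shape[0])
        for snaps in self.snapshots_:
            g = np.zeros(X.shape[0])
            for snap in snaps:
                g += _predict_snapshot(snap, X)
            acc += ndtr(g + self.offset_)
        p1 = acc / len(self.snapshots_)
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] > 0.5).astype(int)
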