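"""Inner loops for feature bagging: bag drawing and cross-validated accuracy.

The bagging statistic requires tens of millions of (bag, leave-one-out fold)
classifier evaluations, so the default linear classifier is a least-squares
SVM (ridge regression on +/-1 labels with an unpenalized intercept) whose
leave-one-out predictions are exact in closed form via the PRESS identity
for linear smoothers::

    yhat_i^{(-i)} = (yhat_i - h_ii * y_i) / (1 - h_ii)

with ``h_ii`` the hat-matrix diagonal.  Numba-jitted kernels evaluate one
bag in a few thousand floating point operations; NumPy batched
implementations of the same math serve as the fallback and as an
independent check in the test-suite.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    NUMBA_AVAILABLE = True
except ImportError:  # pragma: no cover
    NUMBA_AVAILABLE = False

    def njit(*args, **kwargs):
        if len(args) == 1 and callable(args[0]):
            return args[0]

        def deco(func):
            return func

        return deco


# ---------------------------------------------------------------------------
# bag sampling (Floyd's algorithm; unbiased distinct draws without replacement)
# ---------------------------------------------------------------------------


def draw_bags(rng: np.random.Generator, n_draw: int, n_features: int,
              bag_size: int) -> np.ndarray:
    """Draw ``n_draw`` bags of ``bag_size`` distinct feature indices."""
    if not 1 <= bag_size <= n_features:
        raise ValueError(f"bag_size {bag_size} outside [1, {n_features}]")
    cols = [
        rng.integers(0, n_features - bag_size + j + 1, size=n_draw)
        for j in range(bag_size)
    ]
    rand_ints = np.column_stack(cols).astype(np.int64)
    out = np.empty((n_draw, bag_size), dtype=np.int64)
    _floyd_fill(rand_ints, n_features, bag_size, out)
    return out


@njit(cache=True)
def _floyd_fill(rand_ints, n_features, bag_size, out):  # pragma: no cover - jitted
    n_draw = out.shape[0]
    for b in range(n_draw):
        count = 0
        for j in range(bag_size):
            candidate = rand_ints[b, j]
            taken = False
            for q in range(count):
                if out[b, q] == candidate:
                    taken = True
                    break
            if taken:
                out[b, count] = n_features - bag_size + j
            else:
                out[b, count] = candidate
            count += 1


# ---------------------------------------------------------------------------
# least-squares SVM with exact closed-form leave-one-out
# ---------------------------------------------------------------------------


def lssvm_loo_accuracy(X, y, bags, lam):
    """LOO-CV accuracy of the least-squares SVM for each bag.

    X: (n_subjects, n_features) standardized; y: +/-1; bags: (B, s) int64.
    The feature Gram matrix, column sums and X^T y are computed once and
    gathered per bag, which avoids rebuilding the normal equations from the
    data for every bag.
    """
    X = np.ascontiguousarray(X)
    gram = X.T @ X
    col_sums = X.sum(axis=0)
    xty = X.T @ y
    return _lssvm_loo_gram(X, y, gram, col_sums, xty, float(y.sum()), bags, lam)


@njit(cache=True)
def _lssvm_loo_gram(X, y, gram, col_sums, xty, y_sum, bags, lam):  # pragma: no cover
    n = X.shape[0]
    n_bags, s = bags.shape
    d = s + 1
    acc = np.empty(n_bags)
    Z = np.empty((n, d))
    A = np.empty((d, d))
    zty = np.empty(d)
    coef = np.empty(d)
    buf = np.empty(d)
    for b in range(n_bags):
        for i in range(n):
            for j in range(s):
                Z[i, j] = X[i, bags[b, j]]
            Z[i, s] = 1.0
        for j in range(s):
            fj = bags[b, j]
            for k in range(j + 1):
                A[j, k] = gram[fj, bags[b, k]]
            A[s, j] = col_sums[fj]
            zty[j] = xty[fj]
        A[s, s] = n
        zty[s] = y_sum
        for j in range(s):
            A[j, j] += lam
        # in-place lower Cholesky
        ok = True
        for j in range(d):
            t = A[j, j]
            for k in range(j):
                t -= A[j, k] * A[j, k]
            if t <= 1e-12:
                ok = False
                break
            A[j, j] = np.sqrt(t)
            inv_d = 1.0 / A[j, j]
            for i in range(j + 1, d):
                t2 = A[i, j]
                for k in range(j):
                    t2 -= A[i, k] * A[j, k]
                A[i, j] = t2 * inv_d
        if not ok:
            acc[b] = 0.5
            continue
        # solve (L L^T) coef = zty
        for j in range(d):
            t = zty[j]
            for k in range(j):
                t -= A[j, k] * buf[k]
            buf[j] = t / A[j, j]
        for j in range(d - 1, -1, -1):
            t = buf[j]
            for k in range(j + 1, d):
                t -= A[k, j] * coef[k]
            coef[j] = t / A[j, j]
        correct = 0
        for i in range(n):
            h = 0.0
            for j in range(d):
                t = Z[i, j]
                for k in range(j):
                    t -= A[j, k] * buf[k]
                buf[j] = t / A[j, j]
                h += buf[j] * buf[j]
            yhat = 0.0
            for j in range(d):
                yhat += Z[i, j] * coef[j]
            denom = 1.0 - h
            if denom < 1e-10:
                loo = 0.0
            else:
                loo = (yhat - h * y[i]) / denom
            pred = 1.0 if loo >= 0.0 else -1.0
            if pred * y[i] > 0.0:
                correct += 1
        acc[b] = correct / n
    return acc


def lssvm_loo_accuracy_np(X, y, bags, lam, chunk=4096):
    """Batched NumPy implementation of :func:`lssvm_loo_accuracy`."""
    n = X.shape[0]
    n_bags, s = bags.shape
    d = s + 1
    reg = np.zeros((d, d))
    reg[np.arange(s), np.arange(s)] = lam
    acc = np.empty(n_bags)
    for start in range(0, n_bags, chunk):
        bc = bags[start : start + chunk]
        Xb = X[:, bc]  # (n, C, s)
        Z = np.concatenate([Xb, np.ones((n, bc.shape[0], 1))], axis=2)
        Z = np.ascontiguousarray(Z.transpose(1, 0, 2))  # (C, n, d)
        A = np.einsum("cnd,cne->cde", Z, Z) + reg
        Ainv = np.linalg.inv(A)
        AZt = Ainv @ Z.transpose(0, 2, 1)  # (C, d, n)
        h = np.einsum("cnd,cdn->cn", Z, AZt)
        zty = np.einsum("cnd,n->cd", Z, y)
        coef = np.einsum("cde,ce->cd", Ainv, zty)
        yhat = np.einsum("cnd,cd->cn", Z, coef)
        denom = 1.0 - h
        safe = denom > 1e-10
        loo = np.where(safe, (yhat - h * y[None, :]) / np.where(safe, denom, 1.0), 0.0)
        pred = np.where(loo >= 0.0, 1.0, -1.0)
        acc[start : start + bc.shape[0]] = (pred == y[None, :]).mean(axis=1)
    return acc


def lssvm_fit(X, y, lam):
    """Fit the least-squares SVM on all rows; returns (weights, intercept)."""
    n, s = X.shape
    Z = np.concatenate([X, np.ones((n, 1))], axis=1)
    A = Z.T @ Z
    A[np.arange(s), np.arange(s)] += lam
    coef = np.linalg.solve(A, Z.T @ y)
    return coef[:s], coef[s]


def lssvm_kfold_accuracy_np(X, y, bags, lam, fold_ids, chunk=2048):
    """k-fold CV accuracy (explicit per-fold refits, batched over bags)."""
    n = X.shape[0]
    n_bags, s = bags.shape
    d = s + 1
    reg = np.zeros((d, d))
    reg[np.arange(s), np.arange(s)] = lam
    acc = np.zeros(n_bags)
    for start in range(0, n_bags, chunk):
        bc = bags[start : start + chunk]
        Xb = X[:, bc]
        Z = np.concatenate([Xb, np.ones((n, bc.shape[0], 1))], axis=2)
        Z = np.ascontiguousarray(Z.transpose(1, 0, 2))  # (C, n, d)
        correct = np.zeros(bc.shape[0])
        for f in np.unique(fold_ids):
            test = fold_ids == f
            Ztr = Z[:, ~test, :]
            ytr = y[~test]
            A = np.einsum("cnd,cne->cde", Ztr, Ztr) + reg
            rhs = np.einsum("cnd,n->cd", Ztr, ytr)
            coef = np.linalg.solve(A, rhs[..., None])[..., 0]
            yhat = np.einsum("cnd,cd->cn", Z[:, test, :], coef)
            pred = np.where(yhat >= 0.0, 1.0, -1.0)
            correct += (pred == y[test][None, :]).sum(axis=1)
        acc[start : start + bc.shape[0]] = correct / n
    return acc


# ---------------------------------------------------------------------------
# nearest-centroid classifier (Gaussian, shared isotropic covariance)
# ---------------------------------------------------------------------------


@njit(cache=True)
def centroid_loo_accuracy(X, y, bags):  # pragma: no cover - jitted
    n = X.shape[0]
    n_bags, s = bags.shape
    acc = np.empty(n_bags)
    n_pos = 0
    for i in range(n):
        if y[i] > 0:
            n_pos += 1
    n_neg = n - n_pos
    sum_pos = np.empty(s)
    sum_neg = np.empty(s)
    for b in range(n_bags):
        for j in range(s):
            sp = 0.0
            sn = 0.0
            for i in range(n):
                v = X[i, bags[b, j]]
                if y[i] > 0:
                    sp += v
                else:
                    sn += v
            sum_pos[j] = sp
            sum_neg[j] = sn
        correct = 0
        for i in range(n):
            if y[i] > 0:
                np_i, nn_i = n_pos - 1, n_neg
            else:
                np_i, nn_i = n_pos, n_neg - 1
            dp = 0.0
            dn = 0.0
            for j in range(s):
                v = X[i, bags[b, j]]
                if y[i] > 0:
                    cp = (sum_pos[j] - v) / np_i
                    cn = sum_neg[j] / nn_i
                else:
                    cp = sum_pos[j] / np_i
                    cn = (sum_neg[j] - v) / nn_i
                dp += (v - cp) ** 2
                dn += (v - cn) ** 2
            if dp < dn:
                pred = 1.0
            elif dn < dp:
                pred = -1.0
            else:  # tie: majority class of the training fold
                pred = 1.0 if np_i >= nn_i else -1.0
            if pred * y[i] > 0.0:
                correct += 1
        acc[b] = correct / n
    return acc


def centroid_loo_accuracy_np(X, y, bags, chunk=4096):
    """Batched NumPy implementation of :func:`centroid_loo_accuracy`."""
    n = X.shape[0]
    n_bags = bags.shape[0]
    ispos = (y > 0).astype(np.float64)
    isneg = 1.0 - ispos
    n_pos, n_neg = ispos.sum(), isneg.sum()
    acc = np.empty(n_bags)
    for start in range(0, n_bags, chunk):
        bc = bags[start : start + chunk]
        Xb = np.ascontiguousarray(X[:, bc].transpose(1, 0, 2))  # (C, n, s)
        sum_pos = np.einsum("cns,n->cs", Xb, ispos)
        sum_neg = np.einsum("cns,n->cs", Xb, isneg)
        np_i = (n_pos - ispos)[None, :, None]
        nn_i = (n_neg - isneg)[None, :, None]
        cp = (sum_pos[:, None, :] - Xb * ispos[None, :, None]) / np_i
        cn = (sum_neg[:, None, :] - Xb * isneg[None, :, None]) / nn_i
        dp = ((Xb - cp) ** 2).sum(axis=2)
        dn = ((Xb - cn) ** 2).sum(axis=2)
        maj = np.where(np_i[:, :, 0] >= nn_i[:, :, 0], 1.0, -1.0)
        pred = np.where(dp < dn, 1.0, np.where(dn < dp, -1.0, maj))
        acc[start : start + bc.shape[0]] = (pred == y[None, :]).mean(axis=1)
    return acc


# ---------------------------------------------------------------------------
# diagonal linear discriminant (pooled per-feature variances)
# ---------------------------------------------------------------------------


def dlda_loo_accuracy_np(X, y, bags, chunk=2048, eps=1e-12):
    """Diagonal-covariance LDA with exact LOO (pooled variances recomputed
    without the held-out subject)."""
    n = X.shape[0]
    n_bags = bags.shape[0]
    ispos = (y > 0).astype(np.float64)
    isneg = 1.0 - ispos
    n_pos, n_neg = ispos.sum(), isneg.sum()
    acc = np.empty(n_bags)
    for start in range(0, n_bags, chunk):
        bc = bags[start : start + chunk]
        Xb = np.ascontiguousarray(X[:, bc].transpose(1, 0, 2))  # (C, n, s)
        Xb2 = Xb**2
        sp = np.einsum("cns,n->cs", Xb, ispos)
        sn = np.einsum("cns,n->cs", Xb, isneg)
        sp2 = np.einsum("cns,n->cs", Xb2, ispos)
        sn2 = np.einsum("cns,n->cs", Xb2, isneg)
        np_i = (n_pos - ispos)[None, :, None]
        nn_i = (n_neg - isneg)[None, :, None]
        cp = (sp[:, None, :] - Xb * ispos[None, :, None]) / np_i
        cn = (sn[:, None, :] - Xb * isneg[None, :, None]) / nn_i
        ssq_p = (sp2[:, None, :] - Xb2 * ispos[None, :, None]) - np_i * cp**2
        ssq_n = (sn2[:, None, :] - Xb2 * isneg[None, :, None]) - nn_i * cn**2
        var = np.maximum((ssq_p + ssq_n) / (np_i + nn_i - 2.0), eps)
        score = ((Xb - 0.5 * (cp + cn)) * (cp - cn) / var).sum(axis=2)
        maj = np.where(np_i[:, :, 0] >= nn_i[:, :, 0], 1.0, -1.0)
        pred = np.where(score > 0, 1.0, np.where(score < 0, -1.0, maj))
        acc[start : start + bc.shape[0]] = (pred == y[None, :]).mean(axis=1)
    return acc


# ---------------------------------------------------------------------------
# decision-stump ensemble (one midpoint stump per bagged feature, vote)
# ---------------------------------------------------------------------------


def stump_loo_accuracy_np(X, y, bags, chunk=2048):
    n = X.shape[0]
    n_bags = bags.shape[0]
    ispos = (y > 0).astype(np.float64)
    isneg = 1.0 - ispos
    n_pos, n_neg = ispos.sum(), isneg.sum()
    acc = np.empty(n_bags)
    for start in range(0, n_bags, chunk):
        bc = bags[start : start + chunk]
        Xb = np.ascontiguousarray(X[:, bc].transpose(1, 0, 2))  # (C, n, s)
        sp = np.einsum("cns,n->cs", Xb, ispos)
        sn = np.einsum("cns,n->cs", Xb, isneg)
        np_i = (n_pos - ispos)[None, :, None]
        nn_i = (n_neg - isneg)[None, :, None]
        cp = (sp[:, None, :] - Xb * ispos[None, :, None]) / np_i
        cn = (sn[:, None, :] - Xb * isneg[None, :, None]) / nn_i
        thr = 0.5 * (cp + cn)
        direction = np.sign(cp - cn)
        votes = (np.sign(Xb - thr) * direction).sum(axis=2)
        maj = np.where(np_i[:, :, 0] >= nn_i[:, :, 0], 1.0, -1.0)
        pred = np.where(votes > 0, 1.0, np.where(votes < 0, -1.0, maj))
        acc[start : start + bc.shape[0]] = (pred == y[None, :]).mean(axis=1)
    return acc
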