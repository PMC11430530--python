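"""Numba kernels for balanced leave-one-subject-out SVM decoding.

The linear SVM is solved in the dual by coordinate descent (the liblinear
L1-loss algorithm of Hsieh et al.) on the augmented feature vector
``[x, 1]``, i.e. the intercept is L2-regularized exactly as in liblinear's
default parametrization.  Problem sizes here are tiny (tens of samples, tens
of features) but the permutation tests need millions of fits, which rules out
per-fit Python overhead; sklearn's LinearSVC serves as the cross-check oracle
in the test suite.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=False)
def svm_dual_cd(X, y, C, max_epochs, tol):
    """L1-loss linear SVM via dual coordinate descent.

    X is (n, d) with the bias column already appended; y is +/-1 floats.
    Returns the weight vector (d,).
    """
    n, d = X.shape
    alpha = np.zeros(n)
    w = np.zeros(d)
    qii = np.empty(n)
    for i in range(n):
        s = 0.0
        for j in range(d):
            s += X[i, j] * X[i, j]
        qii[i] = s
    order = np.arange(n)
    for _ in range(max_epochs):
        max_delta = 0.0
        for oi in range(n):
            i = order[oi]
            g = 0.0
            for j in range(d):
                g += w[j] * X[i, j]
            g = g * y[i] - 1.0
            pg = g
            if alpha[i] <= 0.0 and g > 0.0:
                pg = 0.0
            elif alpha[i] >= C and g < 0.0:
                pg = 0.0
            if pg != 0.0:
                old = alpha[i]
                a_new = old - g / qii[i]
                if a_new < 0.0:
                    a_new = 0.0
                elif a_new > C:
                    a_new = C
                alpha[i] = a_new
                diff = (a_new - old) * y[i]
                for j in range(d):
                    w[j] += diff * X[i, j]
                step = abs(a_new - old)
                if step > max_delta:
                    max_delta = step
        if max_delta < tol:
            break
    return w


@njit(cache=False)
def _zscore_train_apply(Xtr, xte):
    """Z-score columns on the training draw; zero constant columns.

    Returns standardized copies of Xtr and the test row.
    """
    n, d = Xtr.shape
    mu = np.empty(d)
    sd = np.empty(d)
    for j in range(d):
        s = 0.0
        for i in range(n):
            s += Xtr[i, j]
        mu[j] = s / n
        v = 0.0
        for i in range(n):
            diff = Xtr[i, j] - mu[j]
            v += diff * diff
        sd[j] = np.sqrt(v / (n - 1))
    Z = np.empty((n, d))
    zte = np.empty(d)
    for j in range(d):
        if sd[j] > 0.0:
            for i in range(n):
                Z[i, j] = (Xtr[i, j] - mu[j]) / sd[j]
            zte[j] = (xte[j] - mu[j]) / sd[j]
        else:
            for i in range(n):
                Z[i, j] = 0.0
            zte[j] = 0.0
    return Z, zte


@njit(cache=False)
def loocv_decisions(X, y01, draws, C, standardize):
    """Balanced LOOCV decision values and the summed Haufe pattern.

    X: (n, d) feature table; y01: 0/1 labels; draws: (n_reps, n, m) training
    row indices per repetition and held-out subject (m = 2*n_per_class).
    Returns (decisions (n_reps, n), haufe_sum (d,), weight_sum (d,),
    n_iterations).
    """
    n_reps, n, m = draws.shape
    d = X.shape[1]
    decisions = np.empty((n_reps, n))
    haufe = np.zeros(d)
    wsum = np.zeros(d)
    count = 0
    Xa = np.empty((m, d + 1))
    for r in range(n_reps):
        for hold in range(n):
            for t in range(m):
                row = draws[r, hold, t]
                for j in range(d):
                    Xa[t, j] = X[row, j]
            if standardize:
                Z, zte = _zscore_train_apply(Xa[:, :d], X[hold])
                for t in range(m):
                    for j in range(d):
                        Xa[t, j] = Z[t, j]
            else:
                zte = X[hold].copy()
            for t in range(m):
                Xa[t, d] = 1.0
            ysigned = np.empty(m)
            for t in range(m):
                ysigned[t] = 1.0 if y01[draws[r, hold, t]] == 1 else -1.0
            w = svm_dual_cd(Xa, ysigned, C, 400, 1e-8)
            dec = w[d]
            for j in range(d):
                dec += w[j] * zte[j]
            decisions[r, hold] = dec
            for j in range(d):
                wsum[j] += w[j]
            # Haufe activation pattern: training covariance times weights
            for j in range(d):
                mu_j = 0.0
                for t in range(m):
                    mu_j += Xa[t, j]
                mu_j /= m
                acc = 0.0
                for k in range(d):
                    mu_k = 0.0
                    for t in range(m):
                        mu_k += Xa[t, k]
                    mu_k /= m
                    cov_jk = 0.0
                    for t in range(m):
                        cov_jk += (Xa[t, j] - mu_j) * (Xa[t, k] - mu_k)
                    cov_jk /= m - 1
                    acc += cov_jk * w[k]
                haufe[j] += acc
            count += 1
    return decisions, haufe, wsum, count
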