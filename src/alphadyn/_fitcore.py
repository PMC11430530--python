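"""Numba kernels for per-window spectral parametrization.

The model fitted to each windowed log10 power spectrum is

    log10 S(f) = [b - x*log10(f)] + sum_k a_k * exp(-(f - c_k)^2 / (2 w_k^2))

fitted in three stages: robust aperiodic fit (peak-resistant percentile
masking), iterative Gaussian peak extraction on the flattened spectrum with a
joint damped Gauss-Newton refit, and a final plain least-squares aperiodic fit
on the peak-subtracted spectrum.  Written as numba kernels because cohort-level
analyses fit millions of windows; scipy-based fits validate these kernels in
the test suite.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# status codes for window fits
OK = 0
FAILED = 1


@njit(cache=False)
def _ols(lf, y):
    """OLS of y ~ b - x*lf. Returns (b, x)."""
    n = lf.size
    sx = 0.0
    sy = 0.0
    sxx = 0.0
    sxy = 0.0
    for i in range(n):
        sx += lf[i]
        sy += y[i]
        sxx += lf[i] * lf[i]
        sxy += lf[i] * y[i]
    denom = n * sxx - sx * sx
    slope = (n * sxy - sx * sy) / denom
    intercept = (sy - slope * sx) / n
    return intercept, -slope


@njit(cache=False)
def _masked_ols(lf, y, mask):
    n = 0
    sx = 0.0
    sy = 0.0
    sxx = 0.0
    sxy = 0.0
    for i in range(lf.size):
        if mask[i]:
            n += 1
            sx += lf[i]
            sy += y[i]
            sxx += lf[i] * lf[i]
            sxy += lf[i] * y[i]
    if n < 4:
        return _ols(lf, y)
    denom = n * sxx - sx * sx
    if denom <= 0.0:
        return _ols(lf, y)
    slope = (n * sxy - sx * sy) / denom
    intercept = (sy - slope * sx) / n
    return intercept, -slope


@njit(cache=False)
def _quantile(a, q):
    """Linear-interpolation quantile of a 1-D array (q in [0, 1])."""
    b = np.sort(a)
    pos = q * (b.size - 1)
    lo = int(np.floor(pos))
    hi = int(np.ceil(pos))
    if lo == hi:
        return b[lo]
    frac = pos - lo
    return b[lo] * (1.0 - frac) + b[hi] * frac


@njit(cache=False)
def robust_aperiodic(lf, y, robust_percentile):
    """Peak-resistant aperiodic fit.

    Initial OLS; positive residuals are floored at zero and the fit is redone
    on the bins at or below the given percentile of the floored residuals,
    which discards peak bins while keeping the sub-model bulk.
    """
    b, x = _ols(lf, y)
    flat = np.empty(lf.size)
    for i in range(lf.size):
        r = y[i] - (b - x * lf[i])
        flat[i] = r if r > 0.0 else 0.0
    thr = _quantile(flat, robust_percentile / 100.0)
    mask = flat <= thr
    return _masked_ols(lf, y, mask)


@njit(cache=False)
def _std(a):
    m = 0.0
    for i in range(a.size):
        m += a[i]
    m /= a.size
    v = 0.0
    for i in range(a.size):
        d = a[i] - m
        v += d * d
    return np.sqrt(v / a.size)


@njit(cache=False)
def guess_peaks(
    freqs, flat, max_n, min_height, peak_threshold, w_lo, w_hi, guesses
):
    """Iterative maximum-finding peak guesses on the flattened spectrum.

    Each guess's width comes from its half-height extent (one-sided if the
    other side never crosses), clipped to [w_lo, w_hi]; the guess Gaussian is
    subtracted before the next iteration.  Returns the number of guesses and
    fills ``guesses`` (max_n x 3: center, height, width).
    """
    work = flat.copy()
    df = freqs[1] - freqs[0]
    n_guess = 0
    for _ in range(max_n):
        i = int(np.argmax(work))
        h = work[i]
        thr = peak_threshold * _std(work)
        if min_height > thr:
            thr = min_height
        if h < thr:
            break
        half = h / 2.0
        dr = -1.0
        for j in range(i + 1, freqs.size):
            if work[j] < half:
                dr = freqs[j] - freqs[i]
                break
        dl = -1.0
        for j in range(i - 1, -1, -1):
            if work[j] < half:
                dl = freqs[i] - freqs[j]
                break
        if dr < 0.0 and dl < 0.0:
            hwhm = df
        elif dr < 0.0:
            hwhm = dl
        elif dl < 0.0:
            hwhm = dr
        else:
            hwhm = dr if dr < dl else dl
        w = 2.0 * hwhm / 2.3548200450309493  # FWHM -> Gaussian SD
        if w < w_lo:
            w = w_lo
        elif w > w_hi:
            w = w_hi
        guesses[n_guess, 0] = freqs[i]
        guesses[n_guess, 1] = h
        guesses[n_guess, 2] = w
        n_guess += 1
        for j in range(freqs.size):
            d = freqs[j] - freqs[i]
            work[j] -= h * np.exp(-(d * d) / (2.0 * w * w))
    return n_guess


@njit(cache=False)
def _chol_solve(A, b, n):
    """Solve A x = b for SPD A (in place on copies); returns x or NaNs."""
    L = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1):
            s = A[i, j]
            for k in range(j):
                s -= L[i, k] * L[j, k]
            if i == j:
                if s <= 0.0:
                    return np.full(n, np.nan)
                L[i, i] = np.sqrt(s)
            else:
                L[i, j] = s / L[j, j]
    x = np.empty(n)
    for i in range(n):
        s = b[i]
        for k in range(i):
            s -= L[i, k] * x[k]
        x[i] = s / L[i, i]
    for i in range(n - 1, -1, -1):
        s = x[i]
        for k in range(i + 1, n):
            s -= L[k, i] * x[k]
        x[i] = s / L[i, i]
    return x


@njit(cache=False)
def _peak_model(freqs, peaks, k, out):
    for j in range(freqs.size):
        out[j] = 0.0
    for p in range(k):
        c = peaks[p, 0]
        a = peaks[p, 1]
        w = peaks[p, 2]
        for j in range(freqs.size):
            d = freqs[j] - c
            out[j] += a * np.exp(-(d * d) / (2.0 * w * w))


@njit(cache=False)
def _sse(freqs, flat, peaks, k, scratch):
    _peak_model(freqs, peaks, k, scratch)
    s = 0.0
    for j in range(freqs.size):
        d = flat[j] - scratch[j]
        s += d * d
    return s


@njit(cache=False)
def refit_peaks_gn(freqs, flat, peaks, k, w_lo, w_hi, max_iter):
    """Joint bounded refit of k Gaussians by damped Gauss-Newton.

    Bounds are enforced by projection after each accepted step: each center
    stays within 1.5 guess-widths of its guessed position (and inside the
    fitted range), heights non-negative, widths in [w_lo, w_hi].  The center
    constraint keeps a peak from sliding onto neighbouring structure when the
    flattened background is locally elevated.  Modifies ``peaks`` in place;
    returns True on a finite solution.
    """
    nf = freqs.size
    npar = 3 * k
    c_lo = np.empty(k)
    c_hi = np.empty(k)
    for p in range(k):
        lo = peaks[p, 0] - 1.5 * peaks[p, 2]
        hi = peaks[p, 0] + 1.5 * peaks[p, 2]
        c_lo[p] = lo if lo > freqs[0] else freqs[0]
        c_hi[p] = hi if hi < freqs[nf - 1] else freqs[nf - 1]
    J = np.empty((nf, npar))
    g = np.empty(nf)
    scratch = np.empty(nf)
    lam = 1e-3
    sse = _sse(freqs, flat, peaks, k, scratch)
    trial = np.empty((k, 3))
    for _ in range(max_iter):
        # residual and Jacobian at current params
        _peak_model(freqs, peaks, k, g)
        for p in range(k):
            c = peaks[p, 0]
            a = peaks[p, 1]
            w = peaks[p, 2]
            inv2w2 = 1.0 / (2.0 * w * w)
            for j in range(nf):
                d = freqs[j] - c
                e = np.exp(-d * d * inv2w2)
                J[j, 3 * p] = a * e * d / (w * w)
                J[j, 3 * p + 1] = e
                J[j, 3 * p + 2] = a * e * d * d / (w * w * w)
        jtj = np.empty((npar, npar))
        jtr = np.empty(npar)
        for u in range(npar):
            s = 0.0
            for j in range(nf):
                s += J[j, u] * (flat[j] - g[j])
            jtr[u] = s
            for v in range(u, npar):
                s2 = 0.0
                for j in range(nf):
                    s2 += J[j, u] * J[j, v]
                jtj[u, v] = s2
                jtj[v, u] = s2
        improved = False
        for _try in range(6):
            A = jtj.copy()
            for u in range(npar):
                A[u, u] += lam * (jtj[u, u] + 1e-12)
            delta = _chol_solve(A, jtr, npar)
            ok = True
            for u in range(npar):
                if not np.isfinite(delta[u]):
                    ok = False
            if ok:
                for p in range(k):
                    c = peaks[p, 0] + delta[3 * p]
                    a = peaks[p, 1] + delta[3 * p + 1]
                    w = peaks[p, 2] + delta[3 * p + 2]
                    if c < c_lo[p]:
                        c = c_lo[p]
                    elif c > c_hi[p]:
                        c = c_hi[p]
                    if a < 0.0:
                        a = 0.0
                    if w < w_lo:
                        w = w_lo
                    elif w > w_hi:
                        w = w_hi
                    trial[p, 0] = c
                    trial[p, 1] = a
                    trial[p, 2] = w
                new_sse = _sse(freqs, flat, trial, k, scratch)
                if new_sse < sse:
                    for p in range(k):
                        peaks[p, 0] = trial[p, 0]
                        peaks[p, 1] = trial[p, 1]
                        peaks[p, 2] = trial[p, 2]
                    rel = (sse - new_sse) / (sse + 1e-30)
                    sse = new_sse
                    lam *= 0.3
                    if lam < 1e-9:
                        lam = 1e-9
                    improved = True
                    if rel < 1e-7:
                        return True
                    break
            lam *= 10.0
        if not improved:
            break
    for p in range(k):
        for q in range(3):
            if not np.isfinite(peaks[p, q]):
                return False
    return True


@njit(cache=False)
def prune_peaks(freqs, peaks, k, proximity):
    """Drop edge-hugging peaks and overlaps (keep the larger).

    A peak goes if its center is within ``proximity * width`` of either edge
    of the fitted range, or within ``proximity * (larger peak's width)`` of a
    larger kept peak.  Compacts ``peaks`` in place; returns the kept count.
    """
    order = np.argsort(-peaks[:k, 1])
    kept = np.empty((k, 3))
    n_kept = 0
    f0 = freqs[0]
    f1 = freqs[freqs.size - 1]
    for oi in range(k):
        p = order[oi]
        c = peaks[p, 0]
        a = peaks[p, 1]
        w = peaks[p, 2]
        if a <= 0.0:
            continue
        if c - f0 < proximity * w or f1 - c < proximity * w:
            continue
        clash = False
        for q in range(n_kept):
            if abs(c - kept[q, 0]) < proximity * kept[q, 2]:
                clash = True
                break
        if not clash:
            kept[n_kept, 0] = c
            kept[n_kept, 1] = a
            kept[n_kept, 2] = w
            n_kept += 1
    for q in range(n_kept):
        peaks[q, 0] = kept[q, 0]
        peaks[q, 1] = kept[q, 1]
        peaks[q, 2] = kept[q, 2]
    return n_kept


@njit(cache=False)
def fit_window(
    freqs,
    lf,
    logp,
    max_n,
    min_height,
    peak_threshold,
    w_lo,
    w_hi,
    proximity,
    robust_percentile,
    peaks_out,
):
    """Full single-window parametrization.

    Returns (b, x, n_peaks, mse, r_squared, status); fitted peaks are written
    to ``peaks_out`` (max_n x 3).
    """
    nf = freqs.size
    b, x = robust_aperiodic(lf, logp, robust_percentile)
    flat = np.empty(nf)
    for j in range(nf):
        flat[j] = logp[j] - (b - x * lf[j])
    k = guess_peaks(
        freqs, flat, max_n, min_height, peak_threshold, w_lo, w_hi, peaks_out
    )
    if k > 0:
        ok = refit_peaks_gn(freqs, flat, peaks_out, k, w_lo, w_hi, 12)
        if not ok:
            return b, x, 0, np.nan, np.nan, FAILED
        k = prune_peaks(freqs, peaks_out, k, proximity)
    # final aperiodic fit on the peak-subtracted original spectrum
    resid = np.empty(nf)
    pk = np.empty(nf)
    _peak_model(freqs, peaks_out, k, pk)
    for j in range(nf):
        resid[j] = logp[j] - pk[j]
    b, x = _ols(lf, resid)
    mse = 0.0
    mean_y = 0.0
    for j in range(nf):
        model = b - x * lf[j] + pk[j]
        d = logp[j] - model
        mse += d * d
        mean_y += logp[j]
    mse /= nf
    mean_y /= nf
    var_y = 0.0
    for j in range(nf):
        d = logp[j] - mean_y
        var_y += d * d
    var_y /= nf
    r2 = 1.0 - mse / var_y if var_y > 0.0 else np.nan
    if not (np.isfinite(b) and np.isfinite(x)):
        return b, x, 0, np.nan, np.nan, FAILED
    return b, x, k, mse, r2, OK


@njit(cache=False)
def fit_windows(
    freqs,
    logp,
    max_n,
    min_height,
    peak_threshold,
    w_lo,
    w_hi,
    proximity,
    robust_percentile,
):
    """Fit every row of ``logp`` (windows x freqs).

    Returns (offset, exponent, n_peaks, mse, r2, status, peaks) with peaks of
    shape (windows, max_n, 3).
    """
    nw = logp.shape[0]
    lf = np.log10(freqs)
    offs = np.empty(nw)
    exps = np.empty(nw)
    nps = np.empty(nw, dtype=np.int64)
    mses = np.empty(nw)
    r2s = np.empty(nw)
    status = np.empty(nw, dtype=np.int64)
    peaks = np.zeros((nw, max_n, 3))
    for w in range(nw):
        b, x, k, mse, r2, st = fit_window(
            freqs,
            lf,
            logp[w],
            max_n,
            min_height,
            peak_threshold,
            w_lo,
            w_hi,
            proximity,
            robust_percentile,
            peaks[w],
        )
        offs[w] = b
        exps[w] = x
        nps[w] = k
        mses[w] = mse
        r2s[w] = r2
        status[w] = st
    return offs, exps, nps, mses, r2s, status, peaks
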