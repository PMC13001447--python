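"""Per-cytosine methylation state calling with a two-state HMM.

Hidden states are *unmethylated* and *methylated*; the emission at a site
with ``total`` reads of which ``meth`` are methylated is Binomial(total,
level_s) with a per-state methylation level in (0, 1).  Transitions run
along the site index within each chromosome (distance-independent chain).
Parameters are estimated by EM (Baum-Welch) and states are assigned by
posterior (forward-backward) decoding; zero-depth sites carry no emission
information and are reported as *missing* rather than imputed.

The forward-backward recursion is numba-compiled; everything else is numpy.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from numba import njit
from scipy.special import gammaln
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .io import STATE_MISSING, MethylomeSample


@njit(cache=False)
def _forward_backward(emis, trans, start):
    """Scaled forward-backward for one sequence.

    emis: (n, 2) emission likelihoods (rows may be scaled arbitrarily),
    trans: (2, 2), start: (2,).  Returns (loglik, posterior (n, 2),
    xi_sum (2, 2) of expected transition counts).
    """
    n = emis.shape[0]
    alpha = np.empty((n, 2))
    scale = np.empty(n)
    for s in range(2):
        alpha[0, s] = start[s] * emis[0, s]
    scale[0] = alpha[0, 0] + alpha[0, 1]
    alpha[0, 0] /= scale[0]
    alpha[0, 1] /= scale[0]
    for t in range(1, n):
        for s in range(2):
            alpha[t, s] = (alpha[t - 1, 0] * trans[0, s] + alpha[t - 1, 1] * trans[1, s]) * emis[t, s]
        scale[t] = alpha[t, 0] + alpha[t, 1]
        if scale[t] <= 0.0:
            scale[t] = 1e-300
        alpha[t, 0] /= scale[t]
        alpha[t, 1] /= scale[t]

    beta = np.empty((n, 2))
    beta[n - 1, 0] = 1.0
    beta[n - 1, 1] = 1.0
    xi = np.zeros((2, 2))
    for t in range(n - 2, -1, -1):
        for s in range(2):
            beta[t, s] = (
                trans[s, 0] * emis[t + 1, 0] * beta[t + 1, 0]
                + trans[s, 1] * emis[t + 1, 1] * beta[t + 1, 1]
            ) / scale[t + 1]
        denom = 0.0
        for a in range(2):
            for b in range(2):
                denom += alpha[t, a] * trans[a, b] * emis[t + 1, b] * beta[t + 1, b]
        if denom > 0.0:
            for a in range(2):
                for b in range(2):
                    xi[a, b] += alpha[t, a] * trans[a, b] * emis[t + 1, b] * beta[t + 1, b] / denom

    post = alpha * beta
    for t in range(n):
        tot = post[t, 0] + post[t, 1]
        if tot > 0.0:
            post[t, 0] /= tot
            post[t, 1] /= tot
    loglik = 0.0
    for t in range(n):
        loglik += np.log(scale[t])
    return loglik, post, xi


def _emissions(meth, total, levels, log_binom):
    """(n, 2) emission likelihoods, scaled per row; depth-0 rows are flat."""
    levels = np.clip(levels, 1e-6, 1 - 1e-6)
    ll = (
        log_binom[:, None]
        + meth[:, None] * np.log(levels)[None, :]
        + (total - meth)[:, None] * np.log1p(-levels)[None, :]
    )
    ll[total == 0] = 0.0
    ll -= ll.max(axis=1, keepdims=True)
    return np.exp(ll)


class BinomialHMM(BaseEstimator):
    """Two-state HMM with binomial emissions for methylation calling.

    ``fit(X)`` takes ``X`` of shape (n_sites, 2) = (meth_count,
    total_count) ordered by genomic position; ``lengths`` splits the rows
    into independent per-chromosome sequences.  EM stops when the
    log-likelihood improves by less than ``tol`` or after ``n_iter``
    rounds (non-convergence warns and keeps the best model so far).

    Attributes
    ----------
    levels_ : (2,) emission methylation levels, unmethylated first
    transmat_ : (2, 2) transition matrix
    startprob_ : (2,) stationary start distribution
    loglik_ : final log-likelihood
    converged_ : bool
    """

    def __init__(self, n_iter=500, tol=1e-6, init_levels=(0.05, 0.7), init_stay=0.9):
        self.n_iter = n_iter
        self.tol = tol
        self.init_levels = init_levels
        self.init_stay = init_stay

    @staticmethod
    def _split(X, lengths):
        X = np.asarray(X)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError("X must be (n_sites, 2) = (meth, total)")
        if lengths is None:
            return [slice(0, len(X))]
        if sum(lengths) != len(X):
            raise ValueError("lengths do not sum to n_sites")
        out, k = [], 0
        for L in lengths:
            out.append(slice(k, k + L))
            k += L
        return out

    @staticmethod
    def _stationary(trans):
        # stationary distribution of a 2x2 chain
        a, b = trans[0, 1], trans[1, 0]
        if a + b == 0:
            return np.array([0.5, 0.5])
        return np.array([b / (a + b), a / (a + b)])

    def fit(self, X, y=None, lengths=None):
        X = np.asarray(X, dtype=np.int64)
        segments = self._split(X, lengths)
        meth, total = X[:, 0].astype(float), X[:, 1].astype(float)
        if np.all(total == 0):
            raise ValueError("all sites have zero depth")
        if np.count_nonzero(total > 0) < 100:
            warnings.warn("fewer than 100 covered sites; HMM fit may be unstable", RuntimeWarning, stacklevel=2)
        log_binom = gammaln(total + 1) - gammaln(meth + 1) - gammaln(total - meth + 1)

        levels = np.array(self.init_levels, dtype=float)
        trans = np.array(
            [[self.init_stay, 1 - self.init_stay], [1 - self.init_stay, self.init_stay]], dtype=float
        )
        prev_ll = -np.inf
        self.converged_ = False
        for it in range(self.n_iter):
            post = np.empty((len(X), 2))
            xi = np.zeros((2, 2))
            ll = 0.0
            start = self._stationary(trans)
            for seg in segments:
                emis = _emissions(meth[seg], total[seg], levels, log_binom[seg])
                l, p, x = _forward_backward(emis, trans, start)
                ll += l
                post[seg] = p
                xi += x
            # M-step
            denom = post.T @ total
            numer = post.T @ meth
            new_levels = np.where(denom > 0, numer / np.maximum(denom, 1e-300), levels)
            row = xi.sum(axis=1, keepdims=True)
            new_trans = np.where(row > 0, xi / np.maximum(row, 1e-300), trans)
            new_trans = np.clip(new_trans, 1e-8, 1 - 1e-8)
            new_trans /= new_trans.sum(axis=1, keepdims=True)
            levels, trans = new_levels, new_trans
            if ll - prev_ll < self.tol and it > 0:
                self.converged_ = True
                prev_ll = ll
                break
            prev_ll = ll
        if not self.converged_:
            warnings.warn("EM did not converge; returning best-so-far model", RuntimeWarning, stacklevel=2)
        order = np.argsort(levels)  # enforce unmethylated < methylated
        self.levels_ = levels[order]
        self.transmat_ = trans[np.ix_(order, order)]
        self.startprob_ = self._stationary(self.transmat_)
        self.loglik_ = float(prev_ll)
        self.n_iter_ = it + 1
        return self

    def predict_proba(self, X, lengths=None):
        check_is_fitted(self, "levels_")
        X = np.asarray(X, dtype=np.int64)
        segments = self._split(X, lengths)
        meth, total = X[:, 0].astype(float), X[:, 1].astype(float)
        log_binom = gammaln(total + 1) - gammaln(meth + 1) - gammaln(total - meth + 1)
        post = np.empty((len(X), 2))
        for seg in segments:
            emis = _emissions(meth[seg], total[seg], self.levels_, log_binom[seg])
            _, p, _ = _forward_backward(emis, self.transmat_, self.startprob_)
            post[seg] = p
        return post

    def predict(self, X, lengths=None, impute=False):
        """Posterior-decoded states (1 methylated, 0 unmethylated, -1 missing).

        Zero-depth sites are reported missing unless ``impute=True``, in
        which case the chain's posterior fills them in.
        """
        X = np.asarray(X, dtype=np.int64)
        post = self.predict_proba(X, lengths=lengths)
        states = (post[:, 1] > post[:, 0]).astype(np.int8)
        if not impute:
            states[X[:, 1] == 0] = STATE_MISSING
        return states


def fit_hmm(sample: MethylomeSample, context: str, **kwargs) -> BinomialHMM:
    """Fit a calling model on one sample's sites of a given context."""
    mask = (sample.sites["context"] == context).to_numpy()
    if np.count_nonzero(mask & (sample.total > 0)) < 100:
        raise ValueError(f"need >= 100 covered {context} sites to fit the HMM")
    X, lengths, _ = _context_matrix(sample, mask)
    model = BinomialHMM(**kwargs).fit(X, lengths=lengths)
    model.context_ = context
    return model


def _context_matrix(sample, mask):
    """Rows of (meth, total) for masked sites, per-chromosome, position-ordered."""
    sub = sample.sites[mask]
    chrom = sub["chrom"].to_numpy()
    idx = np.flatnonzero(mask)
    frames = []
    lengths = []
    for c in pd.unique(chrom):
        sel = idx[chrom == c]
        sel = sel[np.argsort(sample.sites["pos"].to_numpy()[sel], kind="stable")]
        frames.append(sel)
        lengths.append(len(sel))
    sel_all = np.concatenate(frames) if frames else np.array([], dtype=int)
    X = np.column_stack([sample.meth[sel_all], sample.total[sel_all]])
    return X, lengths, sel_all


def call_states(sample: MethylomeSample, model: BinomialHMM, impute=False) -> np.ndarray:
    """Decode one context's states into ``sample.state`` (in place) and return it.

    The model must have been fitted for the matching context.
    """
    context = getattr(model, "context_", None)
    if context is None:
        raise ValueError("model has no context_ attribute; fit it through fit_hmm")
    mask = (sample.sites["context"] == context).to_numpy()
    if not mask.any():
        raise ValueError(f"sample has no {context} sites")
    X, lengths, sel = _context_matrix(sample, mask)
    states = model.predict(X, lengths=lengths, impute=impute)
    sample.state[sel] = states
    return sample.state
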