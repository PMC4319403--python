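"""Shared statistical machinery: permutation p-values, exact binomial group
test, Wilcoxon maps, Benjamini-Hochberg FDR."""

from __future__ import annotations

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "permutation_p",
    "binomial_tail_p",
    "group_binomial",
    "wilcoxon_map",
    "bh_fdr",
]


def permutation_p(observed: float | np.ndarray, null: np.ndarray) -> float | np.ndarray:
    """Add-one permutation p-value, p = (1 + #{null >= observed}) / (1 + n).

    ``null`` has permutations on axis 0; ``observed`` may be scalar or a
    vector matching the remaining axes.
    """
    null = np.asarray(null)
    n = null.shape[0]
    return (1.0 + (null >= np.asarray(observed)[None]).sum(axis=0)) / (1.0 + n)


def binomial_tail_p(k: int | np.ndarray, n: int, p0: float) -> float | np.ndarray:
    """Exact upper tail P(X >= k) for X ~ Binomial(n, p0)."""
    return sps.binom.sf(np.asarray(k) - 1, n, p0)


def group_binomial(subject_sig: np.ndarray, p0: float = 0.05,
                   alpha: float = 0.05) -> dict[str, np.ndarray]:
    """Group-level inference from per-subject significance flags.

    For each of the W columns of the subjects x W boolean array, counts the
    subjects that reached individual significance and compares the count
    against Binomial(n_subjects, p0); the resulting p-values are FDR
    (Benjamini-Hochberg) corrected across columns at level ``alpha``.

    Returns a dict with ``k`` (counts), ``p`` (raw group p), ``sig_raw``
    (p < alpha) and ``sig_fdr``.
    """
    subject_sig = np.asarray(subject_sig, dtype=bool)
    if subject_sig.ndim != 2:
        raise ValueError("subject_sig must be subjects x windows")
    n = subject_sig.shape[0]
    k = subject_sig.sum(axis=0)
    p = binomial_tail_p(k, n, p0)
    sig_fdr, _ = bh_fdr(p, alpha=alpha)
    return {"k": k, "p": p, "sig_raw": p < alpha, "sig_fdr": sig_fdr}


def wilcoxon_map(values: np.ndarray, mu: float = 0.0,
                 alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Two-sided Wilcoxon signed-rank test of each column against ``mu``,
    FDR-corrected.

    ``values`` is subjects x points (points may be multi-dimensional; the
    test runs over axis 0).  Columns where every subject equals ``mu``
    carry no evidence and get p = 1.  Returns ``(sig_fdr_mask, pvals)``
    with the input point shape.
    """
    values = np.asarray(values, dtype=float)
    if values.shape[0] < 6:
        raise ValueError("need >= 6 subjects for a meaningful signed-rank test")
    point_shape = values.shape[1:]
    flat = values.reshape(values.shape[0], -1) - mu
    pvals = np.ones(flat.shape[1])
    for j in range(flat.shape[1]):
        d = flat[:, j]
        if np.allclose(d, 0.0):
            continue
        # zero differences dropped (classic signed-rank convention)
        res = sps.wilcoxon(d[d != 0], alternative="two-sided", method="auto")
        pvals[j] = res.pvalue
    sig, _ = bh_fdr(pvals, alpha=alpha)
    return sig.reshape(point_shape), pvals.reshape(point_shape)


def bh_fdr(pvals: np.ndarray, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg FDR: returns (reject mask, adjusted p-values)."""
    pvals = np.asarray(pvals, dtype=float)
    reject, p_adj, _, _ = multipletests(pvals.ravel(), alpha=alpha, method="fdr_bh")
    return reject.reshape(pvals.shape), p_adj.reshape(pvals.shape)
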