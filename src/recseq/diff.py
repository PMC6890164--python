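"""Replicate-aware differential enrichment on count bins.

The test is a conditional negative-binomial (NB) exact test with a common
method-of-moments dispersion, the classical two-group exact strategy for
small replicate numbers: library sizes are equalized by median-ratio
scaling, a common dispersion phi is estimated from pooled within-group
variability, and each bin's group-A total is tested against the conditional
null distribution given the bin total,

    P(S_A = k | T) ∝ C(k + r_A - 1, k) · C(T - k + r_B - 1, T - k),

with r_g = n_g / phi (the NB mean parameter cancels under conditioning).
The two-sided p-value sums probabilities of splits as or less likely than
the observed one. With phi = 0 the conditional law reduces to the binomial
(Poisson exact test). This is a defined stand-in for the exact-test
machinery of count-based differential-expression packages, not a
re-implementation of any one of them: the scientific output is a
locus-specific enrichment flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from scipy.stats import false_discovery_control

from .errors import EstimationError, InputError


@dataclass
class CountMatrix:
    """bins x libraries integer counts with group labels."""

    counts: np.ndarray
    groups: list[str]
    library_ids: list[str] = field(default_factory=list)
    bin_meta: pd.DataFrame | None = None  # optional contig/start/end/label per bin

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise InputError("counts must be 2-D (bins x libraries)")
        if np.any(self.counts < 0):
            raise InputError("counts must be non-negative")
        if len(self.groups) != self.counts.shape[1]:
            raise InputError("one group label per library required")
        if len(set(self.groups)) != 2:
            raise InputError("exactly two groups required")
        if not self.library_ids:
            self.library_ids = [f"lib{i}" for i in range(self.counts.shape[1])]

    @property
    def group_names(self) -> tuple[str, str]:
        seen: list[str] = []
        for g in self.groups:
            if g not in seen:
                seen.append(g)
        return tuple(seen)  # type: ignore[return-value]

    def group_columns(self, name: str) -> np.ndarray:
        return np.asarray([i for i, g in enumerate(self.groups) if g == name])


def median_ratio_size_factors(counts: np.ndarray) -> np.ndarray:
    """Median-of-ratios library size factors (geometric-mean reference)."""
    counts = np.asarray(counts, dtype=float)
    pos = (counts > 0).all(axis=1)
    if pos.sum() >= 10:
        logg = np.log(counts[pos]).mean(axis=1, keepdims=True)
        sf = np.exp(np.median(np.log(counts[pos]) - logg, axis=0))
    else:  # too few everywhere-positive bins: fall back to total-count ratios
        tot = counts.sum(axis=0)
        sf = tot / np.exp(np.mean(np.log(np.maximum(tot, 1.0))))
    return sf / np.exp(np.mean(np.log(sf)))


def equalize_counts(cm: CountMatrix) -> np.ndarray:
    """Counts scaled to equal effective library size, rounded to integers."""
    sf = median_ratio_size_factors(cm.counts)
    return np.rint(cm.counts / sf[None, :]).astype(np.int64)


def estimate_common_dispersion(cm: CountMatrix, min_mean: float = 5.0) -> float:
    """Common NB dispersion: median of per-bin method-of-moments estimates.

    Per bin, on size-equalized counts: m is the grand mean, s^2 the pooled
    within-group sample variance, and phi_b = max(0, (s^2 - m) / m^2); the
    common value is the median over bins with m >= ``min_mean``.
    """
    scaled = cm.counts / median_ratio_size_factors(cm.counts)[None, :]
    groups = cm.group_names
    m = scaled.mean(axis=1)
    ss = np.zeros(scaled.shape[0])
    df = 0
    for g in groups:
        cols = cm.group_columns(g)
        if len(cols) < 2:
            continue
        gm = scaled[:, cols].mean(axis=1, keepdims=True)
        ss += ((scaled[:, cols] - gm) ** 2).sum(axis=1)
        df += len(cols) - 1
    if df == 0:
        raise EstimationError("need >= 2 libraries in at least one group")
    s2 = ss / df
    use = m >= min_mean
    if not use.any():
        raise EstimationError(
            f"no bin with mean >= {min_mean}; simulate or sequence deeper"
        )
    phi_b = np.maximum(0.0, (s2[use] - m[use]) / m[use] ** 2)
    return float(np.median(phi_b))


def _conditional_logpmf(T: int, nA: int, nB: int, phi: float) -> np.ndarray:
    """log P(S_A = k | S_A + S_B = T) for k = 0..T under a shared mean."""
    k = np.arange(T + 1, dtype=float)
    if phi <= 0:
        p = nA / (nA + nB)
        lp = (
            gammaln(T + 1)
            - gammaln(k + 1)
            - gammaln(T - k + 1)
            + k * np.log(p)
            + (T - k) * np.log1p(-p)
        )
    else:
        rA, rB = nA / phi, nB / phi
        lp = (
            gammaln(k + rA)
            - gammaln(k + 1)
            - gammaln(rA)
            + gammaln(T - k + rB)
            - gammaln(T - k + 1)
            - gammaln(rB)
        )
        lp = lp - logsumexp(lp)
    return lp


def nb_exact_test(
    counts_a: np.ndarray, counts_b: np.ndarray, phi: float, equalized: bool = True
) -> float:
    """Two-sided conditional exact test on equalized library counts.

    ``counts_a``/``counts_b`` are the per-library counts of one bin in each
    group (already scaled to equal library sizes). Returns the p-value: the
    total conditional probability of group-A sums as or less likely than the
    observed one.
    """
    if not equalized:
        raise InputError("counts must be library-size equalized before testing")
    if phi < 0:
        raise InputError("dispersion must be >= 0")
    a = np.atleast_1d(np.asarray(counts_a))
    b = np.atleast_1d(np.asarray(counts_b))
    if np.any(a < 0) or np.any(b < 0):
        raise InputError("negative counts")
    sA = int(a.sum())
    T = sA + int(b.sum())
    if T == 0:
        return 1.0
    lp = _conditional_logpmf(T, len(a), len(b), phi)
    obs = lp[sA]
    p = float(np.exp(logsumexp(lp[lp <= obs + 1e-10])))
    return min(p, 1.0)


def run_differential(
    cm: CountMatrix,
    alpha: float = 0.05,
    correction: str = "none",
    dispersion: float | None = None,
) -> pd.DataFrame:
    """Per-bin exact tests; returns a table sorted by p-value.

    ``correction='none'`` flags bins with raw p < alpha; ``'BH'`` applies
    Benjamini-Hochberg before flagging.
    """
    if correction not in ("none", "BH"):
        raise InputError(f"unknown correction {correction!r}")
    if not 0.0 <= alpha <= 1.0:
        raise InputError("alpha must be in [0, 1]")
    phi = estimate_common_dispersion(cm) if dispersion is None else float(dispersion)
    eq = equalize_counts(cm)
    gA, gB = cm.group_names
    colsA, colsB = cm.group_columns(gA), cm.group_columns(gB)
    meanA = eq[:, colsA].mean(axis=1)
    meanB = eq[:, colsB].mean(axis=1)
    nbins = eq.shape[0]
    pvals = np.empty(nbins)
    for i in range(nbins):
        pvals[i] = nb_exact_test(eq[i, colsA], eq[i, colsB], phi)
    padj = false_discovery_control(pvals, method="bh") if correction == "BH" else pvals
    out = pd.DataFrame(
        {
            "mean_" + gA: meanA,
            "mean_" + gB: meanB,
            "log2_fold_change": np.log2((meanA + 0.5) / (meanB + 0.5)),
            "dispersion": phi,
            "p_value": pvals,
            "p_adjusted": padj,
            "significant": padj < alpha,
        }
    )
    if cm.bin_meta is not None:
        out = pd.concat([cm.bin_meta.reset_index(drop=True), out], axis=1)
    return out.sort_values("p_value", kind="stable").reset_index(drop=True)


def write_differential_tsv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)
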