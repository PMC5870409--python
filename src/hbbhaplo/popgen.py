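"""Allele frequencies, Hardy-Weinberg testing, pairwise Fst and cline trends.

Implements the frequency-level population comparisons used when only
per-population allele frequencies (not genotypes) are available for some
populations: per-SNP minor allele frequencies with an exact conditional
Hardy-Weinberg test, Wright's two-population F-statistic computed from a
pair of allele frequencies, a population x population differentiation
matrix averaged over SNPs, and a permutation trend test for a monotone
(geographic) gradient in MAF along an ordered list of populations.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

__all__ = [
    "GenotypeCounts",
    "FreqResult",
    "FstMatrix",
    "TrendResult",
    "estimate_freq",
    "hwe_exact",
    "hwe_chisq",
    "pairwise_fst",
    "weir_cockerham_fst",
    "fst_matrix",
    "cline_trend",
]


@dataclass(frozen=True)
class GenotypeCounts:
    """Genotype counts for one biallelic SNP in one population."""

    n_AA: int
    n_Aa: int
    n_aa: int

    def __post_init__(self) -> None:
        if min(self.n_AA, self.n_Aa, self.n_aa) < 0:
            raise ValueError("genotype counts must be non-negative")
        if self.n == 0:
            raise ValueError("at least one individual required")

    @property
    def n(self) -> int:
        return self.n_AA + self.n_Aa + self.n_aa

    @property
    def n_A(self) -> int:
        return 2 * self.n_AA + self.n_Aa


@dataclass(frozen=True)
class FreqResult:
    """Allele frequency, MAF and HWE p-value for one SNP in one population."""

    p: float
    maf: float
    hwe_p: float
    n_chromosomes: int
    monomorphic: bool = False


def estimate_freq(counts: GenotypeCounts) -> FreqResult:
    """Allele frequency p = (2 n_AA + n_Aa) / 2n and MAF = min(p, 1-p)."""
    n2 = 2 * counts.n
    p = counts.n_A / n2
    return FreqResult(
        p=p,
        maf=min(p, 1.0 - p),
        hwe_p=hwe_exact(counts),
        n_chromosomes=n2,
        monomorphic=(counts.n_A in (0, n2)),
    )


def _het_log_probs(n: int, n_A: int) -> tuple[np.ndarray, np.ndarray]:
    """Conditional distribution of the heterozygote count given allele totals.

    Given n individuals with n_A copies of allele A, the possible
    heterozygote counts share the parity of n_A; the probability of h
    heterozygotes is proportional to  n! / (nAA! h! naa!) * 2^h.
    Returns (het counts, normalized log-probabilities).
    """
    n_a = 2 * n - n_A
    h_max = min(n_A, n_a)
    hs = np.arange(n_A % 2, h_max + 1, 2)
    n_AA = (n_A - hs) // 2
    n_aa = (n_a - hs) // 2
    logw = (
        gammaln(n + 1)
        - gammaln(n_AA + 1)
        - gammaln(hs + 1)
        - gammaln(n_aa + 1)
        + hs * math.log(2.0)
    )
    logw -= logw.max()
    logp = logw - math.log(np.exp(logw).sum())
    return hs, logp


def hwe_exact(counts: GenotypeCounts) -> float:
    """Exact conditional Hardy-Weinberg test.

    Conditions on the observed allele totals and sums the probabilities of
    all heterozygote counts no more probable than the observed one.  A
    monomorphic SNP is degenerate and returns p = 1.0.
    """
    if counts.n_A == 0 or counts.n_A == 2 * counts.n:
        return 1.0
    hs, logp = _het_log_probs(counts.n, counts.n_A)
    p_obs = logp[hs == counts.n_Aa][0]
    # small tolerance so equal-probability configurations are included
    mask = logp <= p_obs + 1e-12
    return float(min(1.0, np.exp(logp[mask]).sum()))


def hwe_chisq(counts: GenotypeCounts) -> float:
    """One-degree-of-freedom chi-square Hardy-Weinberg test (no correction)."""
    n = counts.n
    p = counts.n_A / (2 * n)
    if p in (0.0, 1.0):
        return 1.0
    exp = np.array([n * p * p, 2 * n * p * (1 - p), n * (1 - p) ** 2])
    obs = np.array([counts.n_AA, counts.n_Aa, counts.n_aa])
    x2 = ((obs - exp) ** 2 / exp).sum()
    return float(stats.chi2.sf(x2, df=1))


def pairwise_fst(p1: float, p2: float) -> float:
    """Wright's two-population F-statistic from a pair of allele frequencies.

    F = Var(p) / (pbar (1 - pbar)) with the population variance of the two
    frequencies; returns 0 when both populations are fixed for the same
    allele (no variation to apportion).
    """
    for p in (p1, p2):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"allele frequency {p} outside [0, 1]")
    pbar = (p1 + p2) / 2.0
    denom = pbar * (1.0 - pbar)
    if denom == 0.0:
        return 0.0
    var = ((p1 - pbar) ** 2 + (p2 - pbar) ** 2) / 2.0
    return var / denom


def weir_cockerham_fst(c1: GenotypeCounts, c2: GenotypeCounts) -> float:
    """Weir & Cockerham's theta for two populations at one biallelic SNP.

    Uses the standard variance-components estimator from genotype counts
    (sample-size and heterozygosity corrected); for users with full genotype
    data rather than published frequencies.
    """
    n_i = np.array([c1.n, c2.n], dtype=float)
    p_i = np.array([c1.n_A / (2 * c1.n), c2.n_A / (2 * c2.n)])
    h_i = np.array([c1.n_Aa / c1.n, c2.n_Aa / c2.n])
    r = 2
    nbar = n_i.mean()
    nc = (r * nbar - (n_i**2).sum() / (r * nbar)) / (r - 1)
    pbar = (n_i * p_i).sum() / (r * nbar)
    s2 = (n_i * (p_i - pbar) ** 2).sum() / ((r - 1) * nbar)
    hbar = (n_i * h_i).sum() / (r * nbar)
    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
    )
    c = hbar / 2
    denom = a + b + c
    return 0.0 if denom == 0 else float(a / denom)


@dataclass(frozen=True)
class FstMatrix:
    """Per-SNP pairwise differentiation matrices and their mean across SNPs."""

    populations: list[str]
    per_snp: dict[str, pd.DataFrame]
    mean: pd.DataFrame
    missing_pairs: list[tuple[str, str, str]] = field(default_factory=list)


def fst_matrix(freqs: pd.DataFrame) -> FstMatrix:
    """Pairwise Fst matrices from a population x SNP allele-frequency table.

    ``freqs`` has one row per population (index = population label, order
    preserved) and one column per SNP; NaN cells mark missing frequencies,
    whose pairs are flagged and excluded from the across-SNP mean.
    """
    if freqs.shape[0] < 2 or freqs.shape[1] < 1:
        raise ValueError("need >=2 populations and >=1 SNP")
    pops = list(freqs.index)
    per_snp: dict[str, pd.DataFrame] = {}
    missing: list[tuple[str, str, str]] = []
    stack = []
    for snp in freqs.columns:
        m = pd.DataFrame(np.zeros((len(pops), len(pops))), index=pops, columns=pops)
        for a, b in itertools.combinations(pops, 2):
            pa, pb = freqs.loc[a, snp], freqs.loc[b, snp]
            if pd.isna(pa) or pd.isna(pb):
                m.loc[a, b] = m.loc[b, a] = np.nan
                missing.append((a, b, str(snp)))
            else:
                m.loc[a, b] = m.loc[b, a] = pairwise_fst(float(pa), float(pb))
        per_snp[str(snp)] = m
        stack.append(m.to_numpy())
    mean = pd.DataFrame(
        np.nanmean(np.stack(stack), axis=0), index=pops, columns=pops
    )
    np.fill_diagonal(mean.values, 0.0)
    return FstMatrix(populations=pops, per_snp=per_snp, mean=mean,
                     missing_pairs=missing)


@dataclass(frozen=True)
class TrendResult:
    """Rank-correlation trend of MAF along an ordered population axis."""

    statistic: float
    p_value: float
    n_permutations: int
    method: str  # "exact" or "monte-carlo"
    degenerate: bool = False


def _spearman(x_ranks: np.ndarray, y_ranks: np.ndarray) -> float:
    xc = x_ranks - x_ranks.mean()
    yc = y_ranks - y_ranks.mean()
    denom = math.sqrt((xc**2).sum() * (yc**2).sum())
    return float((xc * yc).sum() / denom) if denom else 0.0

def cline_trend(
    mafs: "list[float] | np.ndarray",
    max_exact: int = 8,
    n_monte_carlo: int = 100_000,
    seed: int = 0,
) -> TrendResult:
    """Spearman rank correlation between geographic order and MAF.

    The populations are taken in the order given (e.g. equatorial to
    southern); ties get midranks.  The two-sided p-value enumerates all
    orderings of the MAF vector when there are at most ``max_exact``
    populations, otherwise a seeded Monte-Carlo sample is used.  A constant
    MAF vector is degenerate: statistic 0, p-value 1.
    """
    maf = np.asarray(mafs, dtype=float)
    k = maf.size
    if k < 3:
        raise ValueError("cline trend requires at least 3 populations")
    if np.all(maf == maf[0]):
        return TrendResult(0.0, 1.0, 0, "degenerate", degenerate=True)
    x = stats.rankdata(np.arange(k))
    y = stats.rankdata(maf)
    obs = _spearman(x, y)
    tol = 1e-12
    if k <= max_exact:
        hits = total = 0
        for perm in itertools.permutations(y):
            total += 1
            if abs(_spearman(x, np.array(perm))) >= abs(obs) - tol:
                hits += 1
        return TrendResult(obs, hits / total, total, "exact")
    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(y) for _ in range(n_monte_carlo)])
    xc = x - x.mean()
    yc = perms - perms.mean(axis=1, keepdims=True)
    r = (yc @ xc) / np.sqrt((xc**2).sum() * (yc**2).sum(axis=1))
    # add-one correction keeps the Monte-Carlo p-value in (0, 1]
    p = (1 + int((np.abs(r) >= abs(obs) - tol).sum())) / (n_monte_carlo + 1)
    return TrendResult(obs, p, n_monte_carlo, "monte-carlo")
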