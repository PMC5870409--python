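"""Two-locus LD statistics, D' confidence intervals and haplotype blocks.

Reproduces the Plink/Haploview-style LD workflow as library code: two-locus
haplotype frequencies (direct counting for phased chromosomes, EM over the
cis/trans ambiguity of double heterozygotes for unphased genotypes), the
classical LD measures D, D' and r^2, a likelihood-grid confidence interval
on |D'|, and Gabriel-style haplotype-block detection with per-block
haplotype frequencies.

Gabriel rule (Haploview defaults, all configurable): a marker pair is in
"strong LD" when the one-sided 90% CI on |D'| has lower bound >= 0.70 and
upper bound >= 0.98; it shows "strong evidence of recombination" when the
upper bound is < 0.90.  A span of markers is a block when at least 95% of
its informative pairs are in strong LD; maximal non-overlapping spans are
chosen greedily, longest first, ties to the leftmost start.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MISSING_ALLELE",
    "HaplotypePanel",
    "TwoLocusCounts",
    "LDStats",
    "EMResult",
    "GabrielParams",
    "HaploBlock",
    "two_locus_counts",
    "em_haplotype_freq",
    "ld_pair",
    "dprime_ci",
    "pairwise_ld_table",
    "gabriel_blocks",
    "block_haplotype_freqs",
]

MISSING_ALLELE = -1


@dataclass
class HaplotypePanel:
    """Biallelic markers for a set of chromosomes (phased) or individuals.

    ``data`` is (n_chromosomes x n_markers) with alleles 0/1 when phased,
    or (n_individuals x n_markers) with genotype dosages 0/1/2 when
    unphased; -1 marks missing.  Positions are 1-based.
    """

    markers: list[str]
    positions: np.ndarray
    data: np.ndarray
    phased: bool = True
    population: str | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.data = np.asarray(self.data, dtype=np.int8)
        if self.data.ndim != 2 or self.data.shape[1] != len(self.markers):
            raise ValueError("data must be 2-D with one column per marker")
        if self.positions.size != len(self.markers):
            raise ValueError("need one position per marker")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("marker positions must be strictly increasing")
        hi = 1 if self.phased else 2
        vals = self.data[self.data != MISSING_ALLELE]
        if vals.size and (vals.min() < 0 or vals.max() > hi):
            raise ValueError(f"allele codes must be in 0..{hi} or -1 (missing)")

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def n_chromosomes(self) -> int:
        if not self.phased:
            raise ValueError("unphased panel has no chromosome axis")
        return self.data.shape[0]

    def marker_index(self, marker: str) -> int:
        try:
            return self.markers.index(marker)
        except ValueError:
            raise KeyError(f"unknown marker: {marker!r}") from None

    def maf(self, i: int) -> float:
        col = self.data[:, i]
        col = col[col != MISSING_ALLELE]
        if col.size == 0:
            return 0.0
        p = col.sum() / (col.size * (1 if self.phased else 2))
        return float(min(p, 1.0 - p))

    def subsample(self, n: int, seed: int) -> "HaplotypePanel":
        """Seeded random subsample of n chromosomes (phased panels only)."""
        if not self.phased:
            raise ValueError("subsampling is defined on phased panels")
        rng = np.random.default_rng(seed)
        idx = rng.choice(self.n_chromosomes, size=n, replace=False)
        return HaplotypePanel(
            self.markers, self.positions.copy(), self.data[np.sort(idx)],
            phased=True, population=self.population,
        )


@dataclass(frozen=True)
class TwoLocusCounts:
    """Observed data for one marker pair.

    Phased input: haplotype counts (n00, n01, n10, n11).  Unphased input:
    the 3x3 genotype cross-table with dosage of allele 1 at marker i as
    rows and marker j as columns.
    """

    phased: bool
    haplotypes: tuple[int, int, int, int] | None = None
    genotype_table: np.ndarray | None = None

    @property
    def total(self) -> int:
        if self.phased:
            return int(sum(self.haplotypes))
        return int(self.genotype_table.sum())


def two_locus_counts(panel: HaplotypePanel, marker_i: str | int,
                     marker_j: str | int) -> TwoLocusCounts:
    """Tally a marker pair, excluding chromosomes/individuals with missing data."""
    i = marker_i if isinstance(marker_i, int) else panel.marker_index(marker_i)
    j = marker_j if isinstance(marker_j, int) else panel.marker_index(marker_j)
    a, b = panel.data[:, i], panel.data[:, j]
    keep = (a != MISSING_ALLELE) & (b != MISSING_ALLELE)
    a, b = a[keep].astype(np.int64), b[keep].astype(np.int64)
    if panel.phased:
        counts = np.bincount(2 * a + b, minlength=4)
        return TwoLocusCounts(True, haplotypes=tuple(int(c) for c in counts))
    table = np.zeros((3, 3), dtype=np.int64)
    np.add.at(table, (a, b), 1)
    return TwoLocusCounts(False, genotype_table=table)


@dataclass(frozen=True)
class EMResult:
    """EM-estimated two-locus haplotype frequencies (p00, p01, p10, p11)."""

    freqs: tuple[float, float, float, float]
    n_iterations: int
    log_likelihood: float
    converged: bool
    unidentifiable: bool = False


def _unphased_loglik(freqs: np.ndarray, table: np.ndarray) -> float:
    p00, p01, p10, p11 = freqs
    ll = 0.0
    for gi in range(3):
        for gj in range(3):
            n = table[gi, gj]
            if n == 0:
                continue
            if gi == 1 and gj == 1:
                prob = 2 * (p00 * p11 + p01 * p10)
            else:
                # genotype factorizes into an unambiguous haplotype pair
                hi = (0 if gi == 0 else 1, 0 if gi < 2 else 1)
                hj = (0 if gj == 0 else 1, 0 if gj < 2 else 1)
                f1 = freqs[2 * hi[0] + hj[0]]
                f2 = freqs[2 * hi[1] + hj[1]]
                prob = f1 * f2 * (2.0 if (gi == 1) != (gj == 1) else 1.0)
            ll += n * np.log(max(prob, 1e-300))
    return float(ll)


def em_haplotype_freq(
    table: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> EMResult:
    """Two-locus haplotype frequencies from a 3x3 genotype table by EM.

    Only double heterozygotes are phase-ambiguous (cis 00/11 vs trans
    01/10); every other genotype contributes fixed haplotype counts.  EM
    iterates the expected cis fraction until the largest frequency change
    drops below ``tol``.  A table consisting solely of double heterozygotes
    carries no phase information; the initialization (all 0.25) is returned
    flagged unidentifiable.
    """
    table = np.asarray(table, dtype=float)
    if table.shape != (3, 3):
        raise ValueError("genotype table must be 3x3")
    n = table.sum()
    if n == 0:
        raise ValueError("empty genotype table")
    n_dh = table[1, 1]

    # fixed haplotype contributions from unambiguous genotypes
    base = np.zeros(4)  # order 00, 01, 10, 11
    for gi in range(3):
        for gj in range(3):
            if gi == 1 and gj == 1:
                continue
            cnt = table[gi, gj]
            if cnt == 0:
                continue
            # the two (unambiguous) haplotypes of the individual: a het
            # locus contributes alleles 0 and 1, a hom locus its allele twice
            h1 = (0 if gi < 2 else 1, 0 if gj < 2 else 1)
            h2 = (0 if gi < 1 else 1, 0 if gj < 1 else 1)
            base[2 * h1[0] + h1[1]] += cnt
            base[2 * h2[0] + h2[1]] += cnt

    if n_dh == n:
        freqs = np.full(4, 0.25)
        return EMResult(tuple(freqs), 0, _unphased_loglik(freqs, table),
                        converged=True, unidentifiable=True)

    freqs = np.full(4, 0.25)
    ll = -np.inf
    for it in range(1, max_iter + 1):
        cis = freqs[0] * freqs[3]
        trans = freqs[1] * freqs[2]
        frac_cis = 0.5 if cis + trans == 0 else cis / (cis + trans)
        new = base.copy()
        new[[0, 3]] += n_dh * frac_cis
        new[[1, 2]] += n_dh * (1 - frac_cis)
        new /= 2 * n
        delta = np.abs(new - freqs).max()
        freqs = new
        ll = _unphased_loglik(freqs, table)
        if delta < tol:
            return EMResult(tuple(freqs), it, ll, converged=True)
    return EMResult(tuple(freqs), max_iter, ll, converged=False)


@dataclass(frozen=True)
class LDStats:
    """Classical two-locus LD measures for one marker pair."""

    D: float
    d_prime: float | None
    r_squared: float | None
    p_A: float
    p_B: float
    defined: bool = True


def ld_pair(freqs: "tuple[float, float, float, float] | np.ndarray") -> LDStats:
    """D, D' and r^2 from four haplotype frequencies (p00, p01, p10, p11).

    Allele 1 frequencies p_A (first marker) and p_B (second) are the
    marginals; D = p11 - p_A p_B.  If either marker is monomorphic the
    normalized measures are undefined and flagged.
    """
    f = np.asarray(freqs, dtype=float)
    if f.shape != (4,) or np.any(f < -1e-12):
        raise ValueError("need four non-negative haplotype frequencies")
    if abs(f.sum() - 1.0) > 1e-6:
        raise ValueError(f"haplotype frequencies sum to {f.sum()}, not 1")
    p00, p01, p10, p11 = f
    pA = p10 + p11
    pB = p01 + p11
    D = p11 - pA * pB
    denom = pA * (1 - pA) * pB * (1 - pB)
    if denom <= 0:
        return LDStats(D=float(D), d_prime=None, r_squared=None,
                       p_A=float(pA), p_B=float(pB), defined=False)
    if D > 0:
        d_max = min(pA * (1 - pB), (1 - pA) * pB)
    else:
        d_max = min(pA * pB, (1 - pA) * (1 - pB))
    d_prime = 0.0 if d_max == 0 else abs(D) / d_max
    return LDStats(D=float(D), d_prime=float(min(d_prime, 1.0)),
                   r_squared=float(D * D / denom), p_A=float(pA), p_B=float(pB))


def _freqs_at_dprime(dp: float, sign: float, pA: float, pB: float) -> np.ndarray:
    if sign >= 0:
        d_max = min(pA * (1 - pB), (1 - pA) * pB)
    else:
        d_max = min(pA * pB, (1 - pA) * (1 - pB))
    D = sign * dp * d_max
    p11 = pA * pB + D
    return np.array([
        (1 - pA) * (1 - pB) + D,
        (1 - pA) * pB - D,
        pA * (1 - pB) - D,
        p11,
    ])


def dprime_ci(counts: TwoLocusCounts, grid: int = 101) -> tuple[float, float]:
    """Likelihood-grid confidence bounds on |D'| (Gabriel/Haploview style).

    Allele frequencies are fixed at their sample estimates; the likelihood
    of the data is evaluated at ``grid`` equally spaced |D'| values in
    [0, 1] with the sign of D taken from its point estimate, then
    normalized to sum to one.  The lower bound is the smallest grid value
    whose cumulative (from 0) likelihood reaches 5%; the upper bound the
    largest whose upper-tail reaches 5%.
    Raises on a monomorphic marker (|D'| undefined).
    """
    if counts.phased:
        n = np.asarray(counts.haplotypes, dtype=float)
        tot = n.sum()
        if tot == 0:
            raise ValueError("no informative chromosomes")
        f = n / tot
        pA, pB = f[2] + f[3], f[1] + f[3]
        point = ld_pair(f)
    else:
        table = counts.genotype_table
        tot = table.sum()
        if tot == 0:
            raise ValueError("empty genotype table")
        row = table.sum(axis=1)
        col = table.sum(axis=0)
        pA = (row[1] + 2 * row[2]) / (2 * tot)
        pB = (col[1] + 2 * col[2]) / (2 * tot)
        em = em_haplotype_freq(table)
        point = ld_pair(np.asarray(em.freqs))
    if not point.defined:
        raise ValueError("|D'| undefined: a marker is monomorphic")
    sign = 1.0 if point.D >= 0 else -1.0

    dps = np.linspace(0.0, 1.0, grid)
    logl = np.empty(grid)
    for k, dp in enumerate(dps):
        f = np.clip(_freqs_at_dprime(dp, sign, pA, pB), 1e-12, None)
        if counts.phased:
            logl[k] = float((n * np.log(f)).sum())
        else:
            logl[k] = _unphased_loglik(f, counts.genotype_table)
    like = np.exp(logl - logl.max())
    like /= like.sum()
    cum = np.cumsum(like)
    lower = float(dps[np.searchsorted(cum, 0.05)])
    tail = np.cumsum(like[::-1])[::-1]  # upper-tail mass from each grid point
    upper_idx = np.nonzero(tail >= 0.05)[0]
    upper = float(dps[upper_idx[-1]]) if upper_idx.size else 0.0
    return lower, upper


@dataclass(frozen=True)
class GabrielParams:
    """Thresholds of the Gabriel block rule (Haploview defaults)."""

    strong_low: float = 0.70
    strong_high: float = 0.98
    recomb_high: float = 0.90
    strong_fraction: float = 0.95
    ci_grid: int = 101


@dataclass(frozen=True)
class HaploBlock:
    """A haplotype block: inclusive marker-index span plus member markers."""

    start: int
    end: int
    markers: tuple[str, ...]

    @property
    def n_markers(self) -> int:
        return self.end - self.start + 1


def _pair_ci_matrix(panel: HaplotypePanel, params: GabrielParams):
    m = panel.n_markers
    informative = np.zeros((m, m), dtype=bool)
    strong = np.zeros((m, m), dtype=bool)
    for i, j in itertools.combinations(range(m), 2):
        if panel.maf(i) == 0.0 or panel.maf(j) == 0.0:
            continue
        counts = two_locus_counts(panel, i, j)
        lo, hi = dprime_ci(counts, grid=params.ci_grid)
        informative[i, j] = True
        strong[i, j] = lo >= params.strong_low and hi >= params.strong_high
    return informative, strong


def gabriel_blocks(
    panel: HaplotypePanel,
    params: GabrielParams = GabrielParams(),
) -> list[HaploBlock]:
    """Detect haplotype blocks by the Gabriel D'-confidence-interval rule.

    Candidate spans (>=2 markers, >=1 informative pair) qualify when at
    least ``strong_fraction`` of their informative pairs are in strong LD;
    maximal non-overlapping spans are kept greedily longest-first, ties by
    leftmost start.  Fewer than 2 markers yields an empty list.
    """
    m = panel.n_markers
    if m < 2:
        return []
    informative, strong = _pair_ci_matrix(panel, params)
    candidates: list[tuple[int, int]] = []
    for a in range(m - 1):
        for b in range(a + 1, m):
            sub_inf = informative[a:b + 1, a:b + 1]
            n_inf = int(sub_inf.sum())
            if n_inf == 0:
                continue
            n_strong = int(strong[a:b + 1, a:b + 1].sum())
            if n_strong / n_inf >= params.strong_fraction:
                candidates.append((a, b))
    candidates.sort(key=lambda ab: (-(ab[1] - ab[0]), ab[0]))
    chosen: list[tuple[int, int]] = []
    for a, b in candidates:
        if all(b < ca or a > cb for ca, cb in chosen):
            chosen.append((a, b))
    chosen.sort()
    return [
        HaploBlock(a, b, tuple(panel.markers[a:b + 1])) for a, b in chosen
    ]


def block_haplotype_freqs(
    panel: HaplotypePanel, block: HaploBlock
) -> dict[str, float]:
    """Haplotype frequencies within a block, over complete chromosomes.

    Phased panels only: multi-marker haplotype frequencies from unphased
    genotypes would need a multi-locus EM, which is out of scope here.
    """
    if not panel.phased:
        raise ValueError(
            "block haplotype frequencies require phased data; multi-marker EM "
            "phasing of unphased genotypes is not supported"
        )
    sub = panel.data[:, block.start:block.end + 1]
    keep = np.all(sub != MISSING_ALLELE, axis=1)
    sub = sub[keep]
    if sub.shape[0] == 0:
        raise ValueError("no chromosomes without missing data in block")
    strings = ["".join(map(str, row)) for row in sub]
    n = len(strings)
    out: dict[str, float] = {}
    for s in sorted(set(strings)):
        out[s] = strings.count(s) / n
    return out


def pairwise_ld_table(panel: HaplotypePanel) -> "pd.DataFrame":
    """Long-format table of D, D' and r^2 for every marker pair."""
    import pandas as pd

    rows = []
    for i, j in itertools.combinations(range(panel.n_markers), 2):
        counts = two_locus_counts(panel, i, j)
        if counts.phased:
            tot = counts.total
            f = (np.asarray(counts.haplotypes, float) / tot if tot else
                 np.full(4, np.nan))
        else:
            f = np.asarray(em_haplotype_freq(counts.genotype_table).freqs)
        stats = ld_pair(f) if not np.any(np.isnan(f)) else None
        rows.append({
            "marker_i": panel.markers[i],
            "marker_j": panel.markers[j],
            "D": stats.D if stats else np.nan,
            "d_prime": (stats.d_prime if stats and stats.defined else np.nan),
            "r_squared": (stats.r_squared if stats and stats.defined else np.nan),
        })
    return pd.DataFrame(rows)
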