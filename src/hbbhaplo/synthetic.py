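"""Synthetic cohorts, sequences and phased panels for the full pipeline.

Generates data with the statistical structure the downstream analysis
assumes, so every stage runs end-to-end without external downloads:

* diploid cohorts with a per-population HbS allele frequency, a mixture of
  beta-globin haplotype backgrounds (realized as five-site RFLP patterns
  from the active haplotype table) and unlinked marker SNPs drawn under
  exact Hardy-Weinberg equilibrium at specified MAFs;
* per-chromosome amplicon sequences in which each RFLP site state and the
  codon-6 HbA/HbS allele are realized as the cut or uncut local sequence
  variant, so an in-silico digest reproduces the cohort exactly;
* phased marker panels with block-structured LD built by copying founder
  haplotypes within blocks and randomizing founder choice across
  recombination breakpoints.

Randomness is explicit: every spec carries a seed, and ``derive_seed``
gives stable per-stage seeds from one master seed by hashing stage names.
"""

from __future__ import annotations

import dataclasses
import hashlib
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .haplotypes import HaplotypeTable, default_table
from .ld import HaplotypePanel
from .popgen import GenotypeCounts
from .rflp import CODON6_LOCUS, CUT, LOCI, UNCUT, RFLPProfile

__all__ = [
    "derive_seed",
    "CohortSpec",
    "ClineSpec",
    "RegionSpec",
    "Cohort",
    "SequenceTemplate",
    "default_template",
    "cohort_from_labels",
    "simulate_cohort",
    "simulate_cline",
    "simulate_region_panel",
    "emit_sequences",
    "default_study_cohorts",
    "default_cline",
]

#: HbS orientation at HBB codon 6: allele A (cut DdeI site) encodes HbA,
#: allele T (site lost) the sickling HbS form.
HBA_ALLELE, HBS_ALLELE = "A", "T"

#: Roles of the three unlinked malaria-associated marker SNPs.
DEFAULT_SNP_ROLES = ("ABO_proxy", "HBB_proxy", "MARVELD3_proxy")


def derive_seed(master_seed: int, stage: str) -> int:
    """Stable per-stage seed: hash of the stage name mixed with the master."""
    h = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of one simulated population cohort."""

    population_name: str
    n_individuals: int
    hbs_allele_freq: float
    haplotype_mixture: Mapping[str, float]
    snp_mafs: Mapping[str, float] = field(
        default_factory=lambda: {r: 0.2 for r in DEFAULT_SNP_ROLES}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be >= 1")
        if not 0.0 <= self.hbs_allele_freq <= 1.0:
            raise ValueError("hbs_allele_freq must be in [0, 1]")
        total = sum(self.haplotype_mixture.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(
                f"haplotype mixture proportions sum to {total}, expected 1"
            )
        if any(v < 0 for v in self.haplotype_mixture.values()):
            raise ValueError("mixture proportions must be non-negative")
        for role, maf in self.snp_mafs.items():
            if not 0.0 <= maf <= 0.5:
                raise ValueError(f"MAF for {role!r} must be in [0, 0.5]")


@dataclass(frozen=True)
class ClineSpec:
    """An ordered series of cohorts (equatorial to southern) with per-SNP
    MAF sequences along that order."""

    ordered_populations: Sequence[CohortSpec]
    gradient: Mapping[str, Sequence[float]]

    def __post_init__(self) -> None:
        k = len(self.ordered_populations)
        for role, mafs in self.gradient.items():
            if len(mafs) != k:
                raise ValueError(
                    f"gradient for {role!r} has {len(mafs)} values for {k} populations"
                )


@dataclass(frozen=True)
class RegionSpec:
    """Geometry of a simulated phased marker panel around a core SNP."""

    n_markers: int
    core_index: int
    recomb_breakpoints: tuple[int, ...] = ()
    founder_haplotypes_per_block: int = 2
    n_individuals: int = 100
    window_length: int = 100_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_markers < 2:
            raise ValueError("need at least 2 markers")
        if not 0 <= self.core_index < self.n_markers:
            raise ValueError("core_index outside marker range")
        bps = tuple(self.recomb_breakpoints)
        if any(b2 <= b1 for b1, b2 in zip(bps, bps[1:])):
            raise ValueError("breakpoints must be strictly increasing")
        if bps and not (0 < bps[0] and bps[-1] < self.n_markers):
            raise ValueError("breakpoints must fall strictly inside the marker range")
        if self.founder_haplotypes_per_block < 1:
            raise ValueError("need at least one founder haplotype per block")
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be >= 1")
        if self.window_length < self.n_markers:
            raise ValueError("window shorter than the number of markers")

    @property
    def n_blocks(self) -> int:
        return len(self.recomb_breakpoints) + 1

    @property
    def block_bounds(self) -> list[tuple[int, int]]:
        edges = [0, *self.recomb_breakpoints, self.n_markers]
        return list(zip(edges, edges[1:]))


class Cohort:
    """A simulated diploid cohort, one row per chromosome.

    Columns: individual, chromosome (1/2), haplotype label, the five site
    states, hbs_allele (A/T) and one 0/1 minor-allele column per marker SNP.
    """

    def __init__(self, df: pd.DataFrame, population: str,
                 snp_roles: Sequence[str]) -> None:
        self.df = df
        self.population = population
        self.snp_roles = list(snp_roles)

    @property
    def n_individuals(self) -> int:
        return self.df["individual"].nunique()

    @property
    def n_chromosomes(self) -> int:
        return len(self.df)

    def profiles(self) -> list[RFLPProfile]:
        return [
            RFLPProfile(tuple(row)) for row in self.df[list(LOCI)].to_numpy()
        ]

    def haplotype_labels(self) -> list[str]:
        return list(self.df["haplotype"])

    def codon6_states(self) -> list[str]:
        """DdeI codon-6 site state per chromosome: HbA cuts, HbS does not."""
        return [CUT if a == HBA_ALLELE else UNCUT for a in self.df["hbs_allele"]]

    def hbs_genotypes(self) -> pd.Series:
        from .rflp import genotype_hbs

        def _per_ind(group: pd.DataFrame) -> str:
            s = [CUT if a == HBA_ALLELE else UNCUT for a in group["hbs_allele"]]
            return genotype_hbs(s[0], s[1])

        return self.df.groupby("individual", sort=False).apply(
            _per_ind, include_groups=False
        )

    def hbs_allele_frequency(self) -> float:
        return float((self.df["hbs_allele"] == HBS_ALLELE).mean())

    def genotype_counts(self, snp_role: str) -> GenotypeCounts:
        """Genotype counts for one marker SNP; allele A = the major allele."""
        dosage = self.df.groupby("individual", sort=False)[snp_role].sum()
        return GenotypeCounts(
            n_AA=int((dosage == 0).sum()),
            n_Aa=int((dosage == 1).sum()),
            n_aa=int((dosage == 2).sum()),
        )

    def to_tsv(self, path: str | Path) -> None:
        self.df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, population: str = "") -> "Cohort":
        df = pd.read_csv(path, sep="\t", dtype={"individual": str})
        roles = [c for c in df.columns
                 if c not in ("individual", "chromosome", "haplotype",
                              "hbs_allele", *LOCI)]
        return cls(df, population, roles)


def cohort_from_labels(
    labels: Sequence[str],
    table: HaplotypeTable | None = None,
    population: str = "synthetic",
    hbs_alleles: Sequence[str] | None = None,
    snp_mafs: Mapping[str, float] | None = None,
    seed: int = 0,
) -> Cohort:
    """Build a cohort from an explicit per-chromosome haplotype-label list.

    ``labels`` has length 2n, chromosomes of one individual adjacent.  Each
    label must exist in the haplotype table (its five-site pattern is
    realized verbatim).  ``hbs_alleles`` optionally fixes the codon-6 allele
    per chromosome (default: all HbA); marker-SNP alleles are drawn at
    ``snp_mafs`` with the given seed.
    """
    if len(labels) % 2 != 0:
        raise ValueError("need an even number of chromosomes")
    table = table or default_table()
    patterns = []
    for lab in labels:
        patterns.append(table.pattern(lab))  # KeyError names the label
    n_chrom = len(labels)
    if hbs_alleles is None:
        hbs_alleles = [HBA_ALLELE] * n_chrom
    if len(hbs_alleles) != n_chrom:
        raise ValueError("hbs_alleles must match the number of chromosomes")
    bad = set(hbs_alleles) - {HBA_ALLELE, HBS_ALLELE}
    if bad:
        raise ValueError(f"hbs alleles must be A or T, got {sorted(bad)}")
    snp_mafs = dict(snp_mafs or {})
    rng = np.random.default_rng(seed)
    n_ind = n_chrom // 2
    width = len(str(n_ind))
    # no whitespace in ids: they become FASTA record ids
    prefix = population.replace(" ", "_")
    data = {
        "individual": [f"{prefix}-{i // 2 + 1:0{width}d}" for i in range(n_chrom)],
        "chromosome": [i % 2 + 1 for i in range(n_chrom)],
        "haplotype": list(labels),
    }
    for k, locus in enumerate(LOCI):
        data[locus] = [pat[k] for pat in patterns]
    data["hbs_allele"] = list(hbs_alleles)
    for role, maf in snp_mafs.items():
        data[role] = rng.binomial(1, maf, size=n_chrom)
    return Cohort(pd.DataFrame(data), population, list(snp_mafs))


def _exact_counts(proportions: Sequence[float], total: int) -> list[int]:
    """Largest-remainder apportionment of ``total`` into the proportions."""
    raw = [p * total for p in proportions]
    counts = [int(x) for x in raw]
    short = total - sum(counts)
    order = sorted(range(len(raw)), key=lambda i: raw[i] - counts[i], reverse=True)
    for i in order[:short]:
        counts[i] += 1
    return counts


def simulate_cohort(
    spec: CohortSpec,
    table: HaplotypeTable | None = None,
    allocation: str = "multinomial",
) -> Cohort:
    """Simulate a diploid cohort per its spec.

    Haplotype labels are drawn from the mixture (multinomially, or with
    exact largest-remainder counts when allocation="exact"); HbS alleles
    are binomial at the spec frequency; marker-SNP alleles are independent
    binomial draws per chromosome, i.e. genotypes are under exact HWE.
    Haplotype background and HbS allele are drawn independently.
    """
    table = table or default_table()
    for lab in spec.haplotype_mixture:
        table.pattern(lab)  # raises naming an unknown label
    rng = np.random.default_rng(spec.seed)
    n_chrom = 2 * spec.n_individuals
    mix_labels = list(spec.haplotype_mixture)
    mix_p = np.array([spec.haplotype_mixture[l] for l in mix_labels])
    if allocation == "multinomial":
        labels = [mix_labels[i] for i in rng.choice(len(mix_labels), size=n_chrom,
                                                    p=mix_p)]
    elif allocation == "exact":
        counts = _exact_counts(mix_p, n_chrom)
        labels = [lab for lab, c in zip(mix_labels, counts) for _ in range(c)]
        labels = [labels[i] for i in rng.permutation(n_chrom)]
    else:
        raise ValueError(f"unknown allocation: {allocation!r}")
    hbs = np.where(
        rng.random(n_chrom) < spec.hbs_allele_freq, HBS_ALLELE, HBA_ALLELE
    )
    return cohort_from_labels(
        labels,
        table=table,
        population=spec.population_name,
        hbs_alleles=list(hbs),
        snp_mafs=spec.snp_mafs,
        seed=int(rng.integers(2**31)),
    )


def simulate_cline(
    spec: ClineSpec, table: HaplotypeTable | None = None
) -> list[Cohort]:
    """Simulate the ordered cohorts with the gradient's MAFs substituted in."""
    cohorts = []
    for k, cspec in enumerate(spec.ordered_populations):
        mafs = {role: seq[k] for role, seq in spec.gradient.items()}
        cohorts.append(
            simulate_cohort(dataclasses.replace(cspec, snp_mafs=mafs), table)
        )
    return cohorts


def simulate_region_panel(
    spec: RegionSpec,
    founders: Sequence[np.ndarray] | None = None,
) -> HaplotypePanel:
    """Phased panel with block-structured LD by founder copying.

    Within each block (delimited by ``recomb_breakpoints``) every
    chromosome carries one of the block's founder haplotypes; founder
    choice is independent across blocks, so LD is complete-ish within
    blocks and decays to zero across breakpoints.  ``founders`` optionally
    fixes the founder haplotypes (one array of shape
    (founders_per_block, block_length) per block); by default distinct
    random founders are drawn.
    """
    rng = np.random.default_rng(spec.seed)
    bounds = spec.block_bounds
    if founders is None:
        founders = []
        for a, b in bounds:
            seg_len = b - a
            k = spec.founder_haplotypes_per_block
            if k > 2**seg_len:
                raise ValueError(
                    f"cannot draw {k} distinct founders over {seg_len} markers"
                )
            seen: set[tuple[int, ...]] = set()
            while len(seen) < k:
                seen.add(tuple(rng.integers(0, 2, size=seg_len)))
            founders.append(np.array(sorted(seen), dtype=np.int8))
    else:
        founders = [np.asarray(f, dtype=np.int8) for f in founders]
        if len(founders) != len(bounds):
            raise ValueError(f"need one founder set per block ({len(bounds)})")
        for f, (a, b) in zip(founders, bounds):
            if f.shape[1] != b - a:
                raise ValueError("founder width does not match block length")

    n_chrom = 2 * spec.n_individuals
    data = np.empty((n_chrom, spec.n_markers), dtype=np.int8)
    for f, (a, b) in zip(founders, bounds):
        pick = rng.integers(0, f.shape[0], size=n_chrom)
        data[:, a:b] = f[pick]
    spacing = spec.window_length / spec.n_markers
    positions = np.array(
        [int(round((i + 1) * spacing)) for i in range(spec.n_markers)],
        dtype=np.int64,
    )
    width = len(str(spec.n_markers))
    markers = [f"m{i + 1:0{width}d}" for i in range(spec.n_markers)]
    return HaplotypePanel(markers, positions, data, phased=True)


# ---------------------------------------------------------------------------
# Sequence templates and emission

# Cut / uncut local sequence variants per locus.  The uncut variant differs
# from the cut one by a single base that destroys the recognition site, and
# none of the variants re-creates its enzyme's site at another offset, even
# followed by the AC-repeat spacer (which contains no G or T and therefore
# no recognition site of any enzyme used here).
_SITE_VARIANTS: dict[str, tuple[str, str]] = {
    CODON6_LOCUS: ("CCTGAGGAG", "CCTGTGGAG"),  # HbA (DdeI cut) / HbS
    "XmnI_Ggamma": ("GAACCCCTTC", "GAACCCCTAC"),
    "HindIII_Ggamma": ("AAGCTT", "AAGCTA"),
    "HindIII_Agamma": ("AAGCTT", "AAGCTA"),
    "HincII_psibeta3": ("GTTAAC", "GTTAAG"),
    "HinfI_beta5": ("GACTC", "GACTG"),
}

_SPACER = "AC" * 10


@dataclass(frozen=True)
class SequenceTemplate:
    """An amplicon template: one placeholder window per locus.

    ``windows`` maps locus name to a 0-based half-open interval; rendering
    a chromosome fills each window with the cut or uncut variant according
    to its profile (and the codon-6 window per its HbA/HbS allele).
    """

    length: int
    windows: Mapping[str, tuple[int, int]]
    variants: Mapping[str, tuple[str, str]]

    def render(self, profile: RFLPProfile, hbs_allele: str) -> str:
        states = dict(zip(LOCI, profile.states))
        states[CODON6_LOCUS] = CUT if hbs_allele == HBA_ALLELE else UNCUT
        seq = list((_SPACER * (self.length // len(_SPACER) + 1))[: self.length])
        for locus, (start, end) in self.windows.items():
            cut_seq, uncut_seq = self.variants[locus]
            state = states[locus]
            if state not in (CUT, UNCUT):
                raise ValueError(
                    f"cannot emit sequence for missing state at {locus}"
                )
            var = cut_seq if state == CUT else uncut_seq
            seq[start:end] = var
        return "".join(seq)


def default_template() -> SequenceTemplate:
    """The packaged template: codon-6 window then the five RFLP loci, each
    separated by an AC-repeat spacer."""
    windows: dict[str, tuple[int, int]] = {}
    pos = len(_SPACER)
    for locus in (CODON6_LOCUS, *LOCI):
        w = len(_SITE_VARIANTS[locus][0])
        windows[locus] = (pos, pos + w)
        pos += w + len(_SPACER)
    return SequenceTemplate(length=pos, windows=windows, variants=_SITE_VARIANTS)


def emit_sequences(
    cohort: Cohort, template: SequenceTemplate | None = None
) -> list[tuple[str, str]]:
    """Per-chromosome sequences realizing each chromosome's site states.

    Returns (record id, sequence) pairs with ids "individual|chromosome".
    Digesting the sequences reproduces the cohort's profiles and HbS
    alleles exactly (round-trip guarantee).
    """
    template = template or default_template()
    for locus in (CODON6_LOCUS, *LOCI):
        if locus not in template.windows:
            raise ValueError(f"template lacks a window for locus {locus!r}")
    out = []
    profiles = cohort.profiles()
    for (_, row), profile in zip(cohort.df.iterrows(), profiles):
        rec_id = f"{row['individual']}|{row['chromosome']}"
        out.append((rec_id, template.render(profile, row["hbs_allele"])))
    return out


def write_fasta(records: Sequence[tuple[str, str]], path: str | Path) -> None:
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    seqio_write(
        [SeqRecord(Seq(seq), id=rid, description="") for rid, seq in records],
        str(path),
        "fasta",
    )


# ---------------------------------------------------------------------------
# Default study conditions

def default_study_cohorts(seed: int = 0) -> list[CohortSpec]:
    """The three Southern African cohorts: sample sizes and HbS frequencies
    match the reported cohort compositions; haplotype mixtures put the
    atypical group at roughly two-thirds (South Africa, Zimbabwe) and half
    (Malawi) of chromosomes, with Benin and Cameroon the leading classical
    forms."""
    return [
        CohortSpec(
            "South Africa", 50, 0.0,
            {"atypical I": 0.32, "atypical II": 0.18, "atypical III": 0.18,
             "Benin": 0.18, "Cameroon": 0.14},
            snp_mafs={"ABO_proxy": 0.12, "HBB_proxy": 0.10, "MARVELD3_proxy": 0.25},
            seed=derive_seed(seed, "cohort:South Africa"),
        ),
        CohortSpec(
            "Zimbabwe", 50, 0.06,
            {"atypical I": 0.38, "atypical II": 0.14, "atypical III": 0.14,
             "Benin": 0.18, "Cameroon": 0.16},
            snp_mafs={"ABO_proxy": 0.15, "HBB_proxy": 0.13, "MARVELD3_proxy": 0.25},
            seed=derive_seed(seed, "cohort:Zimbabwe"),
        ),
        CohortSpec(
            "Malawi", 58, 0.035,
            {"atypical I": 0.39, "atypical II": 0.12, "Benin": 0.30,
             "Cameroon": 0.19},
            snp_mafs={"ABO_proxy": 0.18, "HBB_proxy": 0.16, "MARVELD3_proxy": 0.25},
            seed=derive_seed(seed, "cohort:Malawi"),
        ),
    ]


def default_cline(seed: int = 0, n_individuals: int = 500) -> ClineSpec:
    """Six populations ordered equatorial to southern with decreasing MAFs
    for the ABO and HBB proxy SNPs and a flat MAF for the MARVELD3 proxy
    (the two gradients and one non-gradient the analysis contrasts)."""
    names = ["Gambia", "Nigeria-YRI", "Nigeria-ESN", "Malawi", "Zimbabwe",
             "South Africa"]
    mixture = {"atypical I": 0.5, "Benin": 0.3, "Cameroon": 0.2}
    pops = [
        CohortSpec(nm, n_individuals, 0.0, mixture,
                   seed=derive_seed(seed, f"cline:{nm}"))
        for nm in names
    ]
    gradient = {
        "ABO_proxy": [0.35, 0.32, 0.30, 0.18, 0.15, 0.12],
        "HBB_proxy": [0.30, 0.28, 0.26, 0.16, 0.13, 0.10],
        "MARVELD3_proxy": [0.25, 0.25, 0.25, 0.25, 0.25, 0.25],
    }
    return ClineSpec(ordered_populations=pops, gradient=gradient)
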