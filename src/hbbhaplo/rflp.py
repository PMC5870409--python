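"""In-silico restriction analysis of the beta-globin gene cluster.

The beta-globin haplotype background of a chromosome is read from the
presence (+) or absence (-) of five diagnostic restriction sites spread
across the cluster: XmnI at 5'G-gamma, HindIII at G-gamma, HindIII at
A-gamma, HincII at 3'-psi-beta and HinfI at 5'-beta.  The sickle mutation
itself (rs334, HBB codon 6, A>T) abolishes a DdeI recognition site, so the
HbA/HbS allele of a chromosome is called from a DdeI digest of the codon-6
amplicon.

This module provides IUPAC-aware single-strand site scanning, fragment
prediction, per-locus cut/uncut calling within amplicon windows, and HbS
genotyping from a pair of codon-6 DdeI calls.  Coordinates are 0-based,
half-open throughout.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

__all__ = [
    "IUPAC",
    "RestrictionEnzyme",
    "RFLPProfile",
    "SiteCallResult",
    "DDEI",
    "XMNI",
    "HINDIII",
    "HINCII",
    "HINFI",
    "LOCI",
    "LOCUS_ENZYMES",
    "CODON6_LOCUS",
    "find_sites",
    "digest",
    "call_site_state",
    "profile_from_calls",
    "profile_sequence",
    "genotype_hbs",
]

# IUPAC nucleotide codes -> the set of concrete bases they stand for.
# A sequence "N" (unknown base) matches only the pattern code N, never a
# concrete or degenerate code: an unknown base must not create a site call.
IUPAC: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGTN"),
}

_SEQ_ALPHABET = frozenset("ACGTN")


@dataclass(frozen=True)
class RestrictionEnzyme:
    """A restriction endonuclease: IUPAC recognition pattern and cut offset.

    ``cut_offset`` is the number of bases between the start of the
    recognition match and the scission point on the scanned strand
    (e.g. DdeI C^TNAG has offset 1).
    """

    name: str
    recognition: str
    cut_offset: int

    def __post_init__(self) -> None:
        pat = self.recognition.upper()
        bad = set(pat) - set(IUPAC)
        if bad:
            raise ValueError(f"{self.name}: non-IUPAC codes in pattern: {sorted(bad)}")
        if not 0 <= self.cut_offset <= len(pat):
            raise ValueError(
                f"{self.name}: cut offset {self.cut_offset} outside pattern of length {len(pat)}"
            )
        object.__setattr__(self, "recognition", pat)

    @property
    def site_length(self) -> int:
        return len(self.recognition)

    def _regex(self) -> re.Pattern[str]:
        # Lookahead so overlapping matches are all reported.
        parts = []
        for code in self.recognition:
            bases = sorted(IUPAC[code])
            parts.append(bases[0] if len(bases) == 1 else "[" + "".join(bases) + "]")
        return re.compile("(?=" + "".join(parts) + ")")


# The enzyme set used for beta-globin haplotyping and HbS genotyping.
DDEI = RestrictionEnzyme("DdeI", "CTNAG", 1)
XMNI = RestrictionEnzyme("XmnI", "GAANNNNTTC", 5)
HINDIII = RestrictionEnzyme("HindIII", "AAGCTT", 1)
HINCII = RestrictionEnzyme("HincII", "GTYRAC", 3)
HINFI = RestrictionEnzyme("HinfI", "GANTC", 1)

#: Fixed locus order of a five-site haplotype profile, 5' to 3' across the
#: cluster: XmnI 5'G-gamma, HindIII G-gamma, HindIII A-gamma,
#: HincII 3'-psi-beta, HinfI 5'-beta.
LOCI: tuple[str, ...] = (
    "XmnI_Ggamma",
    "HindIII_Ggamma",
    "HindIII_Agamma",
    "HincII_psibeta3",
    "HinfI_beta5",
)

LOCUS_ENZYMES: dict[str, RestrictionEnzyme] = {
    "XmnI_Ggamma": XMNI,
    "HindIII_Ggamma": HINDIII,
    "HindIII_Agamma": HINDIII,
    "HincII_psibeta3": HINCII,
    "HinfI_beta5": HINFI,
}

#: The codon-6 DdeI locus used for HbS genotyping (not part of the profile).
CODON6_LOCUS = "DdeI_codon6"

#: Site states: cut, uncut, missing.
CUT, UNCUT, MISSING = "+", "-", "."
_STATES = frozenset((CUT, UNCUT, MISSING))


@dataclass(frozen=True)
class RFLPProfile:
    """Cut/uncut/missing states at the five diagnostic loci, in LOCI order."""

    states: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.states) != len(LOCI):
            raise ValueError(
                f"profile needs exactly {len(LOCI)} states, got {len(self.states)}"
            )
        bad = set(self.states) - _STATES
        if bad:
            raise ValueError(f"invalid site states: {sorted(bad)}")

    @property
    def has_missing(self) -> bool:
        return MISSING in self.states

    def __str__(self) -> str:
        return "".join(self.states)

    @classmethod
    def from_string(cls, s: str) -> "RFLPProfile":
        return cls(tuple(s))


@dataclass(frozen=True)
class SiteCallResult:
    """Cut/uncut call for one locus; ``evidence`` holds match start positions."""

    locus: str
    state: str
    evidence: tuple[int, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if (self.state == CUT) != bool(self.evidence):
            raise ValueError("state '+' requires non-empty evidence and vice versa")


def _validate_sequence(sequence: str) -> str:
    seq = sequence.upper()
    bad = set(seq) - _SEQ_ALPHABET
    if bad:
        raise ValueError(f"invalid nucleotide characters: {sorted(bad)}")
    return seq


def find_sites(sequence: str, enzyme: RestrictionEnzyme) -> list[int]:
    """All 0-based positions where the recognition pattern matches.

    Scans the given strand only; overlapping matches are all reported.
    An empty sequence yields an empty list.
    """
    seq = _validate_sequence(sequence)
    return [m.start() for m in enzyme._regex().finditer(seq)]


def digest(sequence: str, enzyme: RestrictionEnzyme) -> list[int]:
    """Ordered fragment lengths from a complete digest.

    The cut is placed ``cut_offset`` bases into each recognition match;
    fragment lengths always sum to the sequence length.
    """
    seq = _validate_sequence(sequence)
    if not seq:
        return [0]
    cuts = sorted(
        {p + enzyme.cut_offset for p in find_sites(seq, enzyme)
         if 0 < p + enzyme.cut_offset < len(seq)}
    )
    bounds = [0, *cuts, len(seq)]
    return [b - a for a, b in zip(bounds, bounds[1:])]


def call_site_state(
    sequence: str,
    locus_window: tuple[int, int],
    enzyme: RestrictionEnzyme,
    locus: str = "",
) -> SiteCallResult:
    """Call a locus cut (+) iff >=1 recognition match *starts* in the window.

    ``locus_window`` is 0-based half-open; matches may extend past the window
    end but a match starting exactly at the end is outside it.
    """
    start, end = locus_window
    seq = _validate_sequence(sequence)
    if not (0 <= start <= end <= len(seq)):
        raise ValueError(
            f"window [{start}, {end}) outside sequence of length {len(seq)}"
        )
    hits = tuple(p for p in find_sites(seq, enzyme) if start <= p < end)
    return SiteCallResult(
        locus=locus or enzyme.name,
        state=CUT if hits else UNCUT,
        evidence=hits,
    )


def profile_from_calls(calls: dict[str, SiteCallResult]) -> RFLPProfile:
    """Assemble an RFLPProfile from per-locus calls; absent loci are missing."""
    return RFLPProfile(
        tuple(calls[l].state if l in calls else MISSING for l in LOCI)
    )


def profile_sequence(
    sequence: str, windows: dict[str, tuple[int, int]]
) -> tuple[RFLPProfile, str]:
    """Digest one chromosome sequence into its five-site profile and
    codon-6 DdeI state.

    ``windows`` maps locus names (the five LOCI plus CODON6_LOCUS) to
    0-based half-open amplicon windows; loci without a window are called
    missing.
    """
    calls = {
        locus: call_site_state(sequence, windows[locus], LOCUS_ENZYMES[locus], locus)
        for locus in LOCI
        if locus in windows
    }
    if CODON6_LOCUS in windows:
        codon6 = call_site_state(sequence, windows[CODON6_LOCUS], DDEI, CODON6_LOCUS).state
    else:
        codon6 = MISSING
    return profile_from_calls(calls), codon6


def genotype_hbs(chrom1_codon6_state: str, chrom2_codon6_state: str) -> str:
    """Sickle genotype from the two codon-6 DdeI site states.

    A cut site (+) is the HbA allele; loss of the site (-) is HbS.
    Symmetric in its arguments; any missing state gives "unknown".
    """
    states = (chrom1_codon6_state, chrom2_codon6_state)
    bad = set(states) - _STATES
    if bad:
        raise ValueError(f"invalid site states: {sorted(bad)}")
    if MISSING in states:
        return "unknown"
    n_hbs = states.count(UNCUT)
    return ("HbAA", "HbAS", "HbSS")[n_hbs]
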