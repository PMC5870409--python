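"""VCF/FASTA/TSV interfaces and the end-to-end pipeline runner.

Coordinates follow samtools/VCF conventions at the boundary (1-based,
regions inclusive) and are 0-based half-open internally.  Numeric results
go to files under the run's output directory; log lines go to stderr with
a stage tag.  A run manifest records the configuration hash, seeds and
package version so any run can be reproduced exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import re
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .bifurcation import build_bifurcation, ehh, serialize_tree
from .haplotypes import (
    HaplotypeTable,
    classify,
    default_table,
    haplotype_frequencies,
    pair_combinations,
)
from .ld import GabrielParams, HaplotypePanel, gabriel_blocks, block_haplotype_freqs, pairwise_ld_table
from .popgen import cline_trend, estimate_freq, fst_matrix
from .rflp import CODON6_LOCUS, LOCI, RFLPProfile, genotype_hbs, profile_sequence
from .synthetic import (
    Cohort,
    default_cline,
    default_study_cohorts,
    default_template,
    derive_seed,
    emit_sequences,
    simulate_cline,
    simulate_cohort,
    simulate_region_panel,
    write_fasta,
    RegionSpec,
)

__all__ = [
    "VariantTable",
    "RunConfig",
    "parse_region",
    "read_vcf_region",
    "write_vcf",
    "read_fasta",
    "digest_fasta",
    "run_pipeline",
]

_REGION_RE = re.compile(r"^([^:]+):(\d+)-(\d+)$")


def _stage_logger(stage: str) -> logging.Logger:
    logger = logging.getLogger(f"hbbhaplo.{stage}")
    if not logger.handlers and not logging.getLogger().handlers:
        h = logging.StreamHandler(sys.stderr)
        h.setFormatter(logging.Formatter("[%(name)s] %(levelname)s: %(message)s"))
        logger.addHandler(h)
        logger.setLevel(logging.INFO)
    return logger


def parse_region(region: str) -> tuple[str, int, int]:
    """Parse "chrom:start-end" (1-based inclusive) to (chrom, start0, end)."""
    m = _REGION_RE.match(region)
    if not m:
        raise ValueError(f"malformed region {region!r}; expected chrom:start-end")
    chrom, start, end = m.group(1), int(m.group(2)), int(m.group(3))
    if start < 1 or end < start:
        raise ValueError(f"invalid region bounds in {region!r}")
    return chrom, start - 1, end


def format_region(chrom: str, start0: int, end: int) -> str:
    """Inverse of parse_region (internal 0-based half-open to 1-based)."""
    return f"{chrom}:{start0 + 1}-{end}"


@dataclass
class VariantTable:
    """Biallelic SNP genotypes for named samples, with population labels.

    The genotype matrix has one row per chromosome (two adjacent rows per
    sample) and one column per marker; -1 is missing.  Positions are
    0-based internally and converted at VCF boundaries.
    """

    markers: list[str]
    chrom: str
    positions0: np.ndarray
    ref: list[str]
    alt: list[str]
    genotypes: np.ndarray
    samples: list[str]
    phased: bool = True
    populations: dict[str, str] = field(default_factory=dict)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def positions1(self) -> np.ndarray:
        return self.positions0 + 1

    def to_panel(self, population: str | None = None) -> HaplotypePanel:
        rows = np.ones(self.genotypes.shape[0], dtype=bool)
        if population is not None:
            keep = {s for s, p in self.populations.items() if p == population}
            rows = np.array([s in keep for s in self.samples for _ in (0, 1)])
        return HaplotypePanel(
            markers=list(self.markers),
            positions=self.positions1,
            data=self.genotypes[rows],
            phased=True,
            population=population,
        )


def read_vcf_region(path: str | Path, region: str | None = None) -> VariantTable:
    """Read biallelic SNPs from a VCF, optionally restricted to a region.

    Multi-allelic and non-SNP records are dropped (with a logged count).
    Phase flags are preserved: the table is marked phased only if every
    genotype in it is phased.  An empty region yields an empty table
    (flagged in the log).
    """
    import pysam

    log = _stage_logger("vcf")
    want = parse_region(region) if region else None
    vf = pysam.VariantFile(str(path))
    samples = list(vf.header.samples)
    markers, pos0, ref, alt, rows = [], [], [], [], []
    dropped = 0
    phased = True
    for rec in vf:
        if want is not None:
            chrom, start0, end = want
            if rec.chrom != chrom or not (start0 < rec.pos <= end):
                continue
        alts = rec.alts or ()
        if len(alts) != 1 or len(rec.ref) != 1 or len(alts[0]) != 1 or \
                rec.ref not in "ACGT" or alts[0] not in "ACGT":
            dropped += 1
            continue
        col = []
        for s in samples:
            call = rec.samples[s]
            gt = call["GT"]
            if gt is None or len(gt) != 2:
                col.extend([-1, -1])
            else:
                col.extend(-1 if a is None else int(a) for a in gt)
            if not call.phased:
                phased = False
        markers.append(rec.id or f"{rec.chrom}:{rec.pos}")
        pos0.append(rec.pos - 1)  # pysam rec.pos is 1-based
        ref.append(rec.ref)
        alt.append(alts[0])
        rows.append(col)
    vf.close()
    if dropped:
        log.info("dropped %d non-biallelic-SNP records", dropped)
    if not markers:
        log.warning("no variants in requested region")
        geno = np.zeros((2 * len(samples), 0), dtype=np.int8)
    else:
        geno = np.array(rows, dtype=np.int8).T
    chrom = want[0] if want else (rec.chrom if markers else "")
    return VariantTable(
        markers=markers,
        chrom=chrom,
        positions0=np.array(pos0, dtype=np.int64),
        ref=ref,
        alt=alt,
        genotypes=geno,
        samples=samples,
        phased=phased,
    )


def write_vcf(
    panel: HaplotypePanel,
    path: str | Path,
    chrom: str = "11",
    sample_prefix: str = "S",
    ref_alt: tuple[str, str] = ("A", "T"),
) -> None:
    """Write a phased panel as a minimal VCF v4.2 (GT only, "|" separators)."""
    if not panel.phased:
        raise ValueError("write_vcf expects a phased panel")
    if panel.n_chromosomes % 2 != 0:
        raise ValueError("panel must hold an even number of chromosomes")
    n_samples = panel.n_chromosomes // 2
    width = len(str(n_samples))
    samples = [f"{sample_prefix}{i + 1:0{width}d}" for i in range(n_samples)]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source=hbbhaplo {__version__}\n")
        fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples) + "\n"
        )
        for j, (marker, pos) in enumerate(zip(panel.markers, panel.positions)):
            col = panel.data[:, j]
            gts = "\t".join(
                f"{_gt(col[2 * i])}|{_gt(col[2 * i + 1])}" for i in range(n_samples)
            )
            fh.write(
                f"{chrom}\t{pos}\t{marker}\t{ref_alt[0]}\t{ref_alt[1]}\t.\tPASS\t.\tGT\t{gts}\n"
            )


def _gt(a: int) -> str:
    return "." if a < 0 else str(int(a))


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    from Bio import SeqIO

    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def digest_fasta(
    path: str | Path, windows: dict[str, tuple[int, int]]
) -> pd.DataFrame:
    """Digest per-chromosome FASTA records (ids "individual|chromosome")
    into a profile table."""
    rows = []
    for rec_id, seq in read_fasta(path):
        ind, _, chrom = rec_id.partition("|")
        profile, codon6 = profile_sequence(seq, windows)
        rows.append({
            "individual": ind,
            "chromosome": int(chrom) if chrom else 1,
            **dict(zip(LOCI, profile.states)),
            CODON6_LOCUS: codon6,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Pipeline orchestration

@dataclass(frozen=True)
class RunConfig:
    """Configuration of an end-to-end run."""

    out_dir: str
    seed: int = 0
    stages: tuple[str, ...] = (
        "simulate", "digest", "haplotype", "freqs", "fst", "trend",
        "ld", "blocks", "bifurcate",
    )
    n_markers: int = 12
    core_index: int = 5
    recomb_breakpoints: tuple[int, ...] = (4, 8)
    n_panel_individuals: int = 200
    gabriel: GabrielParams = GabrielParams()
    make_figures: bool = True

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def run_pipeline(config: RunConfig, table: HaplotypeTable | None = None) -> dict:
    """Run simulate -> digest -> haplotype -> stats -> LD -> bifurcation.

    Writes every stage's outputs under the output directory and returns the
    manifest (also written as manifest.json).  A rerun with the same config
    reproduces all numeric outputs exactly.
    """
    table = table or default_table()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    template = default_template()
    artifacts: dict[str, str] = {}
    log = _stage_logger("pipeline")

    def _write_json(name: str, obj) -> None:
        (out / name).write_text(json.dumps(obj, indent=2, default=str))
        artifacts[name] = str(out / name)

    cohorts: list[Cohort] = []
    if "simulate" in config.stages:
        log.info("simulating study cohorts")
        for spec in default_study_cohorts(config.seed):
            cohort = simulate_cohort(spec, table)
            cohort.to_tsv(out / f"cohort_{spec.population_name.replace(' ', '_')}.tsv")
            write_fasta(
                emit_sequences(cohort, template),
                out / f"sequences_{spec.population_name.replace(' ', '_')}.fasta",
            )
            cohorts.append(cohort)

    profile_tables: dict[str, pd.DataFrame] = {}
    if "digest" in config.stages and cohorts:
        log.info("digesting emitted sequences")
        for cohort in cohorts:
            fasta = out / f"sequences_{cohort.population.replace(' ', '_')}.fasta"
            df = digest_fasta(fasta, template.windows)
            df.to_csv(out / f"profiles_{cohort.population.replace(' ', '_')}.tsv",
                      sep="\t", index=False)
            profile_tables[cohort.population] = df

    if "haplotype" in config.stages and profile_tables:
        log.info("classifying haplotypes")
        freq_rows, combo_rows, hbs_rows = [], [], []
        for pop, df in profile_tables.items():
            calls = [
                classify(RFLPProfile(tuple(r)), table)
                for r in df[list(LOCI)].to_numpy()
            ]
            coarse = haplotype_frequencies(
                calls, "classical-vs-atypical", table, population=pop
            )
            for lab, cnt in sorted(coarse.counts.items()):
                freq_rows.append({
                    "population": pop, "haplotype": lab, "count": cnt,
                    "denominator": coarse.denominator,
                    "percent": coarse.percent(lab),
                })
            by_ind: dict[str, list] = {}
            for (_, row), call in zip(df.iterrows(), calls):
                by_ind.setdefault(row["individual"], []).append(call)
            _, combos = pair_combinations(by_ind, table)
            for lab, cnt in sorted(combos.counts.items()):
                combo_rows.append({
                    "population": pop, "combination": lab, "count": cnt,
                    "denominator": combos.denominator,
                    "percent": combos.percent(lab),
                })
            by_ind_states: dict[str, list] = {}
            for _, row in df.iterrows():
                by_ind_states.setdefault(row["individual"], []).append(row[CODON6_LOCUS])
            genos = [genotype_hbs(*st) for st in by_ind_states.values()]
            for g in ("HbAA", "HbAS", "HbSS"):
                hbs_rows.append({
                    "population": pop, "genotype": g, "count": genos.count(g),
                    "denominator": len(genos),
                    "percent": round(100 * genos.count(g) / len(genos), 1),
                })
        pd.DataFrame(freq_rows).to_csv(out / "haplotype_frequencies.tsv",
                                       sep="\t", index=False)
        pd.DataFrame(combo_rows).to_csv(out / "haplotype_combinations.tsv",
                                        sep="\t", index=False)
        pd.DataFrame(hbs_rows).to_csv(out / "hbs_genotypes.tsv",
                                      sep="\t", index=False)

    cline = default_cline(derive_seed(config.seed, "cline"), n_individuals=500)
    cline_cohorts = None
    if {"freqs", "fst", "trend"} & set(config.stages):
        log.info("simulating MAF cline cohorts")
        cline_cohorts = simulate_cline(cline, table)

    maf_table = None
    if "freqs" in config.stages and cline_cohorts:
        rows = []
        for cohort in cline_cohorts:
            for role in cohort.snp_roles:
                fr = estimate_freq(cohort.genotype_counts(role))
                rows.append({
                    "population": cohort.population, "snp": role, "p": fr.p,
                    "maf": fr.maf, "hwe_p": fr.hwe_p,
                    "n_chromosomes": fr.n_chromosomes,
                })
        freq_df = pd.DataFrame(rows)
        freq_df.to_csv(out / "freq_results.tsv", sep="\t", index=False)
        maf_table = freq_df.pivot(index="population", columns="snp", values="maf")
        maf_table = maf_table.reindex([c.population for c in cline_cohorts])

    if "fst" in config.stages and maf_table is not None:
        fst = fst_matrix(maf_table)
        fst.mean.to_csv(out / "fst_matrix.tsv", sep="\t")
        _write_json("fst_matrix.json", {
            "populations": fst.populations,
            "mean": fst.mean.to_numpy().tolist(),
            "per_snp": {k: v.to_numpy().tolist() for k, v in fst.per_snp.items()},
        })
        if config.make_figures:
            from .viz import fst_heatmap
            fst_heatmap(fst.mean, out / "fst_heatmap.png")

    if "trend" in config.stages and maf_table is not None:
        trends = {}
        for role in maf_table.columns:
            tr = cline_trend(maf_table[role].to_numpy())
            trends[str(role)] = {
                "statistic": tr.statistic, "p_value": tr.p_value,
                "method": tr.method, "n_permutations": tr.n_permutations,
                "degenerate": tr.degenerate,
            }
        _write_json("cline_trend.json", trends)

    panel = None
    if {"ld", "blocks", "bifurcate"} & set(config.stages):
        log.info("simulating phased region panel")
        spec = RegionSpec(
            n_markers=config.n_markers,
            core_index=config.core_index,
            recomb_breakpoints=config.recomb_breakpoints,
            founder_haplotypes_per_block=2,
            n_individuals=config.n_panel_individuals,
            seed=derive_seed(config.seed, "panel"),
        )
        # complementary founder pairs keep every marker (incl. the core)
        # polymorphic, so both core alleles have carriers for the trees
        rng = np.random.default_rng(derive_seed(config.seed, "panel-founders"))
        founders = [
            np.array([f, 1 - f])
            for f in (rng.integers(0, 2, size=b - a) for a, b in spec.block_bounds)
        ]
        panel = simulate_region_panel(spec, founders=founders)
        write_vcf(panel, out / "panel.vcf")

    if "ld" in config.stages and panel is not None:
        pairwise_ld_table(panel).to_csv(out / "ld_pairs.tsv", sep="\t", index=False)

    blocks = None
    if "blocks" in config.stages and panel is not None:
        blocks = gabriel_blocks(panel, config.gabriel)
        _write_json("blocks.json", [
            {"start": b.start, "end": b.end, "markers": list(b.markers),
             "haplotype_freqs": block_haplotype_freqs(panel, b)}
            for b in blocks
        ])
        if config.make_figures:
            from .viz import ld_triangle
            ld_triangle(panel, out / "ld_triangle.png")

    if "bifurcate" in config.stages and panel is not None:
        core = panel.markers[config.core_index]
        trees = {}
        ehh_rows = []
        for allele, name in ((1, "derived"), (0, "ancestral")):
            for direction in ("proximal", "distal"):
                tree = build_bifurcation(panel, core, allele, direction)
                trees[f"{name}_{direction}"] = tree
                (out / f"bifurcation_{name}_{direction}.json").write_text(
                    serialize_tree(tree)
                )
                max_d = len(tree.markers)
                for d in range(max_d + 1):
                    ehh_rows.append({
                        "core_allele": name, "direction": direction, "depth": d,
                        "ehh": ehh(panel, core, allele, d, direction),
                    })
        pd.DataFrame(ehh_rows).to_csv(out / "ehh.tsv", sep="\t", index=False)
        if config.make_figures:
            from .viz import bifurcation_figure
            bifurcation_figure(
                trees["derived_proximal"], trees["derived_distal"],
                trees["ancestral_proximal"], trees["ancestral_distal"],
                out / "bifurcation.png",
            )

    manifest = {
        "package_version": __version__,
        "config": config.to_dict(),
        "config_hash": config.config_hash,
        "haplotype_table_version": table.version,
        "stage_seeds": {
            "cline": derive_seed(config.seed, "cline"),
            "panel": derive_seed(config.seed, "panel"),
        },
        "artifacts": sorted({p.name for p in out.iterdir()} | {"manifest.json"}),
    }
    _write_json("manifest.json", manifest)
    return manifest
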