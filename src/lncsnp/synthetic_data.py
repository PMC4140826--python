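"""Fixture generators with known ground truth for every pipeline stage.

Each generator is a pure function of its configuration (seed included):
identical configuration yields an identical bundle.  Ground truth is built by
construction — lncRNAs are *placed* to satisfy their assigned positional
category, hairpin fixtures *embed* a perfect stem whose mid-stem substitution
is disruptive by design, dosage pairs are *simulated from haplotype
frequencies* chosen to hit a target r-squared — so recovery tests are exact.

The default configuration emulates the statistical shape of the study inputs:
a strand-mixed gene/lncRNA architecture on a few chromosomes, GWAS p-value
mixtures with a nominal fraction below 0.01, foldable transcripts around the
40 percent GC typical of lncRNAs, and FPKM matrices with planted host-lncRNA
rank correlation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .core_io import (
    COMPLEMENT,
    GeneModel,
    GenomicInterval,
    LncRNAGene,
    RepeatRecord,
    ValidationError,
    Variant,
    write_fasta,
    write_gene_bed,
    write_repeatmasker_out,
    write_tsv,
    write_variant_table,
)
from .expression_profiles import ExpressionMatrix
from .variant_map import transcript_offset

CATEGORY_NAMES = ("sense_exonic", "sense_non_exonic", "antisense", "intergenic")

DEFAULT_MIX = {
    "sense_exonic": 0.30,
    "sense_non_exonic": 0.20,
    "antisense": 0.25,
    "intergenic": 0.25,
}


class ConfigError(ValueError):
    """Infeasible simulation configuration."""


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    n_genes: int = 200
    n_lncs: int = 500
    category_mix: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_MIX))
    flank: int = 5000
    gc_target: float = 0.42
    n_variants: int = 2000
    frac_nominal: float = 0.5
    frac_in_lnc: float = 0.08
    n_planted_disruptive: int = 5
    n_tissues: int = 14
    planted_rho: float = 0.8
    ld_targets: tuple[float, ...] = (0.0, 0.5, 1.0)
    ld_n_individuals: int = 10_000
    stem_len: int = 10
    transcript_len: tuple[int, int] = (220, 350)
    diseases: tuple[str, ...] = ("IBD", "T1D")
    frac_selected: float = 0.1
    n_repeats: int = 600

    def __post_init__(self) -> None:
        if abs(sum(self.category_mix.values()) - 1.0) > 1e-9:
            raise ConfigError("category_mix proportions must sum to 1")
        if any(p < 0 for p in self.category_mix.values()):
            raise ConfigError("category_mix proportions must be >= 0")
        sense = sum(
            self.category_mix.get(c, 0.0)
            for c in ("sense_exonic", "sense_non_exonic", "antisense", "intergenic")
        )
        if self.n_genes == 0 and sense > 0 and self.n_lncs > 0:
            raise ConfigError("cannot place gene-associated lncRNAs with n_genes = 0")
        for t in self.ld_targets:
            if not (0.0 <= t <= 1.0):
                raise ConfigError(f"LD target r^2 {t} outside [0, 1]")
        if self.stem_len < 6:
            raise ConfigError("stem_len must be >= 6")


@dataclass
class FixtureBundle:
    genes: list[GeneModel]
    lncs: list[LncRNAGene]
    variants: list[Variant]
    truth: dict
    regulome: pd.DataFrame
    eqtl: pd.DataFrame
    ihs: pd.DataFrame
    tss: pd.DataFrame
    dosages: dict[float, tuple[np.ndarray, np.ndarray]]
    repeats: list[RepeatRecord]
    fpkm: ExpressionMatrix

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Write the bundle as the BED/TSV/FASTA files the pipeline reads."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "genes_bed": out / "genes.bed",
            "lncs_bed": out / "lncs.bed",
            "transcripts_fasta": out / "transcripts.fa",
            "variants_tsv": out / "variants.tsv",
            "regulome_tsv": out / "regulome.tsv",
            "eqtl_tsv": out / "eqtl.tsv",
            "ihs_tsv": out / "ihs.tsv",
            "tss_tsv": out / "tss.tsv",
            "repeats_out": out / "repeats.out",
            "fpkm_tsv": out / "fpkm.tsv",
        }
        write_gene_bed(self.genes, paths["genes_bed"])
        write_gene_bed(self.lncs, paths["lncs_bed"])
        write_fasta(
            {l.gene_id: l.transcript_seq for l in self.lncs if l.transcript_seq},
            paths["transcripts_fasta"],
        )
        write_variant_table(self.variants, paths["variants_tsv"])
        write_tsv(self.regulome, paths["regulome_tsv"])
        write_tsv(self.eqtl, paths["eqtl_tsv"])
        write_tsv(self.ihs, paths["ihs_tsv"])
        write_tsv(self.tss, paths["tss_tsv"])
        write_repeatmasker_out(self.repeats, paths["repeats_out"])
        self.fpkm.to_tsv(paths["fpkm_tsv"])
        return paths


# ---------------------------------------------------------------------------
# sequence helpers
# ---------------------------------------------------------------------------

def random_rna(length: int, gc: float, rng: np.random.Generator) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G U
    return "".join(rng.choice(list("ACGU"), size=length, p=probs))


def genomic_position(lnc: LncRNAGene, offset: int) -> int:
    """Genomic coordinate of transcript offset (inverse of splicing)."""
    if not (0 <= offset < lnc.exonic_length):
        raise ValidationError("offset outside transcript")
    forward = offset
    if lnc.interval.strand == "-":
        forward = lnc.exonic_length - 1 - offset
    for exon in lnc.exons:
        if forward < len(exon):
            return exon.start + forward
        forward -= len(exon)
    raise AssertionError("unreachable")


def plus_strand_base(lnc: LncRNAGene, offset: int) -> str:
    """Genomic plus-strand DNA base under transcript offset ``offset``."""
    base = lnc.transcript_seq[offset]
    dna = base.replace("U", "T")
    if lnc.interval.strand == "-":
        dna = COMPLEMENT[base]  # complement of RNA base is already DNA-safe
    return dna


# ---------------------------------------------------------------------------
# locus architecture
# ---------------------------------------------------------------------------

_GENE_SPACING = 60_000
_CHROMS = ("chr1", "chr2", "chr3", "chr4")


def _make_gene(gene_id: str, chrom: str, start: int, strand: str,
               rng: np.random.Generator) -> GeneModel:
    # three exons of 200-400 bp separated by 12-16 kb introns
    exon_sizes = rng.integers(200, 401, size=3)
    intron_sizes = rng.integers(12_000, 16_001, size=2)
    exons = []
    pos = start
    for i in range(3):
        exons.append(GenomicInterval(chrom, pos, pos + int(exon_sizes[i]), strand))
        if i < 2:
            pos += int(exon_sizes[i]) + int(intron_sizes[i])
        else:
            pos += int(exon_sizes[i])
    interval = GenomicInterval(chrom, start, pos, strand)
    return GeneModel(gene_id=gene_id, interval=interval, exons=tuple(exons),
                     biotype="protein_coding")


def _make_lnc(lnc_id: str, chrom: str, strand: str, span: tuple[int, int],
              t_len: int, gc: float, rng: np.random.Generator,
              two_exons: bool) -> LncRNAGene:
    start, end_limit = span
    if two_exons and t_len >= 80:
        e1 = t_len // 2
        e2 = t_len - e1
        intron = int(rng.integers(2500, 7001))
        total = e1 + intron + e2
        if start + total > end_limit:
            intron = max(60, end_limit - start - t_len)
            total = e1 + intron + e2
        exons = (
            GenomicInterval(chrom, start, start + e1, strand),
            GenomicInterval(chrom, start + e1 + intron, start + e1 + intron + e2, strand),
        )
        interval = GenomicInterval(chrom, start, start + total, strand)
    else:
        exons = (GenomicInterval(chrom, start, start + t_len, strand),)
        interval = exons[0]
    seq = random_rna(t_len, gc, rng)
    return LncRNAGene(gene_id=lnc_id, interval=interval, exons=exons,
                      transcript_seq=seq)


def generate_locus_fixture(
    cfg: SimulationConfig,
) -> tuple[list[GeneModel], list[LncRNAGene], dict[str, str], dict[str, str]]:
    """Genes plus lncRNAs placed to satisfy their planted positional category.

    Genes are spaced far enough apart (60 kb, >> flank) that each lncRNA
    relates to exactly the gene it was placed against, so the planted category
    is exact under the classifier's definitions.  Returns
    ``(genes, lncs, categories, hosts)`` where ``hosts`` maps each lncRNA to
    the gene it was placed against.
    """
    rng = np.random.default_rng(_stage_seed(cfg.seed, "locus"))
    genes = []
    for g in range(cfg.n_genes):
        chrom = _CHROMS[g % len(_CHROMS)]
        slot = g // len(_CHROMS)
        start = 20_000 + slot * _GENE_SPACING
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(_make_gene(f"GENE{g:04d}", chrom, start, strand, rng))

    cats = []
    for cat in CATEGORY_NAMES:
        cats.extend([cat] * int(round(cfg.category_mix.get(cat, 0.0) * cfg.n_lncs)))
    while len(cats) < cfg.n_lncs:
        cats.append("intergenic")
    cats = cats[: cfg.n_lncs]
    rng.shuffle(cats)

    lncs: list[LncRNAGene] = []
    truth: dict[str, str] = {}
    hosts: dict[str, str] = {}
    for i, cat in enumerate(cats):
        gene = genes[i % len(genes)] if genes else None
        lnc_id = f"LNC{i:05d}"
        t_len = int(rng.integers(cfg.transcript_len[0], cfg.transcript_len[1] + 1))
        gi = gene.interval
        # most lncRNAs are spliced; their genomic span then dwarfs the exons
        two_exons = bool(rng.random() < 0.9)
        if cat == "sense_exonic":
            # overlap the first exon of the gene on the same strand; a third
            # straddle the gene start so intersecting != fully-overlapping
            exon = gene.exons[0]
            if rng.random() < 0.3:
                start = exon.start - int(rng.integers(50, t_len // 2))
            else:
                start = exon.start + int(rng.integers(0, max(1, len(exon) - 20)))
            lnc = _make_lnc(lnc_id, gi.chrom, gi.strand, (start, gi.end + 40_000),
                            t_len, cfg.gc_target, rng, two_exons)
        elif cat == "sense_non_exonic":
            # wholly inside the first intron, same strand
            intron_start = gene.exons[0].end
            intron_end = gene.exons[1].start
            margin = intron_end - intron_start - (t_len + 7500)
            if margin <= 1:
                raise ConfigError("intron too small for a sense non-exonic lncRNA")
            start = intron_start + 1 + int(rng.integers(0, margin))
            lnc = _make_lnc(lnc_id, gi.chrom, gi.strand, (start, intron_end - 1),
                            t_len, cfg.gc_target, rng, two_exons)
            if lnc.interval.end >= intron_end:  # keep strictly inside the intron
                lnc = _make_lnc(lnc_id, gi.chrom, gi.strand, (start, intron_end - 1),
                                t_len, cfg.gc_target, rng, False)
        elif cat == "antisense":
            opp = "-" if gi.strand == "+" else "+"
            start = gi.start + int(rng.integers(0, max(1, len(gi) - t_len)))
            lnc = _make_lnc(lnc_id, gi.chrom, opp, (start, gi.end + 40_000),
                            t_len, cfg.gc_target, rng, two_exons)
        else:  # intergenic: upstream of the gene, gap in [1, flank]
            strand = "+" if rng.random() < 0.5 else "-"
            gap = int(rng.integers(1, cfg.flank + 1))
            # single exon anchored so the lncRNA ends exactly `gap` bp
            # before the gene start (two-exon spans would widen the gap)
            end = gi.start - gap
            lnc = _make_lnc(lnc_id, gi.chrom, strand, (end - t_len, end),
                            t_len, cfg.gc_target, rng, False)
        lncs.append(lnc)
        truth[lnc_id] = cat
        hosts[lnc_id] = gene.gene_id
    return genes, lncs, truth, hosts


# ---------------------------------------------------------------------------
# structure fixture
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StructureFixture:
    lnc: LncRNAGene
    disruptive: Variant
    neutral: Variant
    stem_span: tuple[int, int]  # transcript offsets [start, end) of the hairpin


def generate_structure_fixture(
    cfg: SimulationConfig, length: int = 200
) -> StructureFixture:
    """A transcript with a planted GC hairpin, plus one disruptive and one
    neutral variant.

    The background is pure poly-A, which cannot base-pair with itself or with
    the stem arms, so the perfect GC stem-loop is the only wild-type structure
    and the wild-type pair matrix is zero outside the stem.  The disruptive
    variant converts a mid-stem G to A; the neutral variant sits in the poly-A
    background well away from the stem, where its substitution can at most
    offer lone (hence forbidden) pairs.
    """
    rng = np.random.default_rng(_stage_seed(cfg.seed, "structure"))
    s = cfg.stem_len
    loop = "A" * 4
    hairpin = "G" * s + loop + "C" * s
    polya_at = length - 40
    stem_at = int(rng.integers(20, length // 2 - len(hairpin)))
    bg = ["A"] * length
    seq = "".join(bg[:stem_at]) + hairpin + "".join(bg[stem_at + len(hairpin) :])
    lnc = LncRNAGene(
        gene_id="LNC_HAIRPIN",
        interval=GenomicInterval("chrS", 0, length, "+"),
        exons=(GenomicInterval("chrS", 0, length, "+"),),
        transcript_seq=seq,
    )
    mid = stem_at + s // 2  # a mid-stem G
    disruptive = Variant(
        id="rs_disruptive", chrom="chrS", pos=mid, ref="G", alt="A",
        assoc_p={d: 1e-4 for d in cfg.diseases},
    )
    neutral_pos = polya_at + 5
    neutral = Variant(
        id="rs_neutral", chrom="chrS", pos=neutral_pos, ref="A", alt="G",
        assoc_p={d: 1e-4 for d in cfg.diseases},
    )
    return StructureFixture(
        lnc=lnc, disruptive=disruptive, neutral=neutral,
        stem_span=(stem_at, stem_at + len(hairpin)),
    )


# ---------------------------------------------------------------------------
# variants
# ---------------------------------------------------------------------------

def _draw_pvalue(nominal: bool, rng: np.random.Generator) -> float:
    if nominal:
        return float(10 ** rng.uniform(-6, math.log10(0.01)))
    return float(rng.uniform(0.0100001, 1.0))


def _plant_hairpin(lnc: LncRNAGene, stem_len: int,
                   rng: np.random.Generator) -> tuple[LncRNAGene, int]:
    """Embed a GC stem-loop into a transcript; returns (new lnc, mid-stem offset).

    The rest of the transcript is rebuilt as poly-A (pairing-free), mimicking
    a lncRNA whose conserved hairpin sits in an otherwise accessible,
    low-structure context; in a uniformly random transcript a single broken
    stem pair is indistinguishable from the background ensemble fluctuations,
    and no planted truth would exist.
    """
    seq = lnc.transcript_seq
    hairpin = "G" * stem_len + "AAAA" + "C" * stem_len
    at = int(rng.integers(10, len(seq) - len(hairpin) - 10))
    new_seq = "A" * at + hairpin + "A" * (len(seq) - at - len(hairpin))
    new = LncRNAGene(
        gene_id=lnc.gene_id, interval=lnc.interval, exons=lnc.exons,
        transcript_seq=new_seq,
    )
    return new, at + stem_len // 2


def generate_variant_fixture(
    cfg: SimulationConfig,
    genes: Sequence[GeneModel],
    lncs: list[LncRNAGene],
) -> tuple[list[Variant], dict]:
    """Variant table with planted structure-disruptive variants.

    ``n_planted_disruptive`` exonic variants sit mid-stem in hairpins embedded
    into the transcripts of distinct lncRNAs (the lnc list is modified in
    place to carry the hairpin transcripts); a fraction ``frac_in_lnc`` of the
    remaining variants land inside lncRNA spans; the rest are placed between
    loci.  ``frac_nominal`` of p-values fall below 0.01.
    """
    rng = np.random.default_rng(_stage_seed(cfg.seed, "variants"))
    variants: list[Variant] = []
    disruptive_ids: list[str] = []
    vid = 0

    # plant in the first lncRNAs, which sit on distinct host genes, so the
    # planted loci never overlap each other
    n_plant = min(cfg.n_planted_disruptive, len(lncs))
    for k in range(n_plant):
        idx = k
        lnc, offset = _plant_hairpin(lncs[idx], cfg.stem_len, rng)
        lncs[idx] = lnc
        pos = genomic_position(lnc, offset)
        ref = plus_strand_base(lnc, offset)
        alt_rna = "A"  # G -> A mid-stem on the transcript
        alt = alt_rna if lnc.interval.strand == "+" else COMPLEMENT[alt_rna]
        v = Variant(
            id=f"rsP{vid:05d}", chrom=lnc.interval.chrom, pos=pos, ref=ref, alt=alt,
            assoc_p={d: _draw_pvalue(True, rng) for d in cfg.diseases},
        )
        variants.append(v)
        disruptive_ids.append(v.id)
        vid += 1

    n_rest = max(0, cfg.n_variants - len(variants))
    n_in_lnc = int(round(cfg.frac_in_lnc * n_rest))
    lncs_with_seq = [l for l in lncs if l.transcript_seq]
    for _ in range(n_in_lnc):
        lnc = lncs_with_seq[int(rng.integers(len(lncs_with_seq)))]
        pos = int(rng.integers(lnc.interval.start, lnc.interval.end))
        offset = transcript_offset(lnc, pos)
        if offset is not None:
            ref = plus_strand_base(lnc, offset)
        else:
            ref = "ACGT"[int(rng.integers(4))]
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        assoc = {
            d: _draw_pvalue(bool(rng.random() < cfg.frac_nominal), rng)
            for d in cfg.diseases
            if rng.random() < 0.9
        }
        variants.append(Variant(id=f"rsL{vid:05d}", chrom=lnc.interval.chrom,
                                pos=pos, ref=ref, alt=alt, assoc_p=assoc))
        vid += 1

    # remaining variants: between loci, clear of every lncRNA span
    spans = sorted((l.interval.chrom, l.interval.start, l.interval.end) for l in lncs)
    for _ in range(n_rest - n_in_lnc):
        chrom = _CHROMS[int(rng.integers(len(_CHROMS)))]
        while True:
            pos = int(rng.integers(0, 20_000 + (cfg.n_genes // len(_CHROMS) + 1)
                                   * _GENE_SPACING))
            if not any(c == chrom and s <= pos < e for c, s, e in spans):
                break
        ref = "ACGT"[int(rng.integers(4))]
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        assoc = {
            d: _draw_pvalue(bool(rng.random() < cfg.frac_nominal), rng)
            for d in cfg.diseases
            if rng.random() < 0.9
        }
        variants.append(Variant(id=f"rsG{vid:05d}", chrom=chrom, pos=pos,
                                ref=ref, alt=alt, assoc_p=assoc))
        vid += 1
    truth = {"disruptive_variants": disruptive_ids}
    return variants, truth


# ---------------------------------------------------------------------------
# evidence tables
# ---------------------------------------------------------------------------

def simulate_dosage_pair(
    target_r2: float, n: int, rng: np.random.Generator,
    maf: float = 0.5, maf_b: Optional[float] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Genotype dosages at two loci with haplotype LD tuned to ``target_r2``.

    Haplotype frequencies are set from ``D = r * sqrt(p(1-p)q(1-q))`` with
    allele frequencies ``p = maf`` and ``q = maf_b`` (default equal);
    individuals are random unions of two haplotypes (HWE), so the composite
    dosage correlation estimates the haplotype r.  A positive-D target is
    unreachable when it would drive a haplotype frequency negative (only
    possible for unequal allele frequencies).
    """
    p = maf
    q = maf if maf_b is None else maf_b
    r = math.sqrt(target_r2)
    d_max = min(p * (1 - q), (1 - p) * q)
    D = r * math.sqrt(p * (1 - p) * q * (1 - q))
    if D > d_max + 1e-12:
        raise ConfigError(
            f"r^2 {target_r2} unreachable at allele frequencies {p}/{q}"
        )
    freqs = np.array([
        p * q + D,            # hap 11
        p * (1 - q) - D,      # hap 10
        (1 - p) * q - D,      # hap 01
        (1 - p) * (1 - q) + D # hap 00
    ])
    if (freqs < -1e-12).any():
        raise ConfigError(f"r^2 {target_r2} unreachable at maf {maf}")
    freqs = np.clip(freqs, 0, None)
    freqs /= freqs.sum()
    haps = rng.choice(4, size=(n, 2), p=freqs)
    a_allele = (haps == 0) | (haps == 1)  # locus A carries the '1' allele
    b_allele = (haps == 0) | (haps == 2)
    return a_allele.sum(axis=1).astype(int), b_allele.sum(axis=1).astype(int)


def generate_evidence_fixture(
    cfg: SimulationConfig,
    genes: Sequence[GeneModel],
    variants: Sequence[Variant],
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame,
           dict[float, tuple[np.ndarray, np.ndarray]]]:
    """Regulatory-score / cis-eQTL / iHS / TSS tables and LD dosage pairs."""
    rng = np.random.default_rng(_stage_seed(cfg.seed, "evidence"))
    from .evidence_rank import DEFAULT_REGULOME_ORDER

    tss_rows = []
    for g in genes:
        iv = g.interval
        tss_rows.append({
            "gene_id": g.gene_id,
            "chrom": iv.chrom,
            "tss_pos": iv.start if iv.strand == "+" else iv.end - 1,
        })
    tss = pd.DataFrame(tss_rows, columns=["gene_id", "chrom", "tss_pos"])

    tissues = [f"tissue{t:02d}" for t in range(9)]
    reg_rows, ihs_rows, eqtl_rows = [], [], []
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.interval.chrom, []).append(g)
    for v in variants:
        if rng.random() < 0.6:
            reg_rows.append({
                "variant_id": v.id,
                "score": DEFAULT_REGULOME_ORDER[int(rng.integers(len(DEFAULT_REGULOME_ORDER)))],
            })
        if rng.random() < 0.5:
            if rng.random() < cfg.frac_selected:
                val = float(rng.choice([-1, 1]) * rng.uniform(2.5, 4.0))
            else:
                val = float(rng.normal(0.0, 1.0))
            ihs_rows.append({"variant_id": v.id, "ihs": round(val, 4)})
        if rng.random() < 0.3:
            nearby = [g for g in by_chrom.get(v.chrom, [])
                      if abs(v.pos - g.interval.start) <= 2_000_000]
            if nearby:
                g = nearby[int(rng.integers(len(nearby)))]
                eqtl_rows.append({
                    "variant_id": v.id,
                    "gene_id": g.gene_id,
                    "tissue": tissues[int(rng.integers(len(tissues)))],
                    "p": float(10 ** rng.uniform(-12, -5)),
                })
    regulome = pd.DataFrame(reg_rows, columns=["variant_id", "score"])
    ihs = pd.DataFrame(ihs_rows, columns=["variant_id", "ihs"])
    eqtl = pd.DataFrame(eqtl_rows, columns=["variant_id", "gene_id", "tissue", "p"])
    dosages = {
        t: simulate_dosage_pair(t, cfg.ld_n_individuals, rng) for t in cfg.ld_targets
    }
    return regulome, eqtl, ihs, tss, dosages


# ---------------------------------------------------------------------------
# repeats
# ---------------------------------------------------------------------------

_REPEAT_MIX = (
    ("SINE", 0.34), ("LINE", 0.27), ("LTR", 0.13), ("DNA", 0.09),
    ("Simple", 0.09), ("Low_complexity", 0.08),
)


def generate_repeat_fixture(
    cfg: SimulationConfig, lncs: Sequence[LncRNAGene]
) -> list[RepeatRecord]:
    """Repeats with the interspersed-family class mix typical of lncRNA loci.

    About 80 percent of repeats are dropped onto lncRNA spans (so most lncRNAs
    harbor at least one), the rest fall between loci.
    """
    rng = np.random.default_rng(_stage_seed(cfg.seed, "repeats"))
    classes = [c for c, _ in _REPEAT_MIX] + ["Other"]
    probs = [p for _, p in _REPEAT_MIX]
    probs.append(1.0 - sum(probs))
    records = []
    for i in range(cfg.n_repeats):
        cls = str(rng.choice(classes, p=probs))
        length = int(rng.integers(80, 400))
        if lncs and rng.random() < 0.8:
            lnc = lncs[int(rng.integers(len(lncs)))]
            iv = lnc.interval
            start = int(rng.integers(iv.start, max(iv.start + 1, iv.end - 10)))
        else:
            chrom = _CHROMS[int(rng.integers(len(_CHROMS)))]
            start = int(rng.integers(0, 5_000_000))
            iv = GenomicInterval(chrom, start, start + length, "+")
        records.append(RepeatRecord(
            interval=GenomicInterval(iv.chrom, start, start + length,
                                     "+" if rng.random() < 0.5 else "-"),
            repeat_class=cls,
            repeat_name=f"{cls}_rep{i}",
        ))
    return records


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def spearman_to_pearson(rho_s: float) -> float:
    """Pearson correlation of a bivariate normal with Spearman target ``rho_s``."""
    return 2.0 * math.sin(math.pi * rho_s / 6.0)


def generate_expression_fixture(
    cfg: SimulationConfig,
    lncs: Sequence[LncRNAGene],
    genes: Sequence[GeneModel],
    planted_pairs: Sequence[tuple[str, str]] = (),
) -> tuple[ExpressionMatrix, list[tuple[str, str, float]]]:
    """Log-normal FPKM matrix with planted lncRNA-host rank correlations.

    Planted pairs share a latent per-tissue effect whose loading is set from
    the Spearman-to-Pearson conversion for bivariate normals, so the expected
    rank correlation equals ``planted_rho``.  Unplanted rows are independent;
    lncRNA rows are centred lower than gene rows (lncRNAs are generally the
    weaker-expressed class), leaving a nontrivial not-detected fraction.
    """
    if cfg.n_tissues < 3:
        raise ConfigError("need >= 3 tissues")
    rng = np.random.default_rng(_stage_seed(cfg.seed, "expression"))
    tissues = [f"tissue{t:02d}" for t in range(cfg.n_tissues)]
    lam = spearman_to_pearson(cfg.planted_rho)
    planted = set(planted_pairs)
    planted_ids = {x for pair in planted for x in pair}
    rows = {}
    truths: list[tuple[str, str, float]] = []
    for lnc_id, gene_id in planted_pairs:
        z = rng.normal(size=cfg.n_tissues)
        for member, mu in ((lnc_id, 0.4), (gene_id, 0.8)):
            eps = rng.normal(size=cfg.n_tissues)
            log10_fpkm = mu + 0.6 * (math.sqrt(lam) * z + math.sqrt(1 - lam) * eps)
            rows[member] = 10.0 ** log10_fpkm
        truths.append((lnc_id, gene_id, cfg.planted_rho))
    for lnc in lncs:
        if lnc.gene_id in planted_ids or lnc.gene_id in rows:
            continue
        mu = -1.0 if rng.random() < 0.6 else 0.3  # many lncRNAs undetected
        rows[lnc.gene_id] = 10.0 ** rng.normal(mu, 0.6, size=cfg.n_tissues)
    for g in genes:
        if g.gene_id in planted_ids or g.gene_id in rows:
            continue
        rows[g.gene_id] = 10.0 ** rng.normal(0.8, 0.6, size=cfg.n_tissues)
    df = pd.DataFrame.from_dict(rows, orient="index", columns=tissues)
    df = df.sort_index()
    return ExpressionMatrix(df.round(5)), truths


# ---------------------------------------------------------------------------
# full bundle
# ---------------------------------------------------------------------------

def generate_fixture_bundle(cfg: SimulationConfig) -> FixtureBundle:
    """The complete synthetic study: every input file the pipeline consumes."""
    genes, lncs, categories, hosts = generate_locus_fixture(cfg)
    variants, variant_truth = generate_variant_fixture(cfg, genes, lncs)
    regulome, eqtl, ihs, tss, dosages = generate_evidence_fixture(cfg, genes, variants)
    repeats = generate_repeat_fixture(cfg, lncs)
    pairs = [
        (lnc_id, hosts[lnc_id])
        for lnc_id, cat in sorted(categories.items())
        if cat == "sense_exonic"
    ][:10]
    fpkm, rho_truth = generate_expression_fixture(cfg, lncs, genes, pairs)
    truth = {
        "categories": categories,
        "disruptive_variants": variant_truth["disruptive_variants"],
        "planted_rho_pairs": rho_truth,
        "ld_targets": list(cfg.ld_targets),
    }
    return FixtureBundle(
        genes=genes, lncs=lncs, variants=variants, truth=truth,
        regulome=regulome, eqtl=eqtl, ihs=ihs, tss=tss, dosages=dosages,
        repeats=repeats, fpkm=fpkm,
    )


def _stage_seed(seed: int, stage: str) -> int:
    """Stable per-stage seed fan-out (adding a stage never shifts another's draws)."""
    import hashlib

    digest = hashlib.blake2b(f"{seed}:{stage}".encode(), digest_size=4).digest()
    return int.from_bytes(digest, "big") % (2**31)
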