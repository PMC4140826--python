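"""End-to-end orchestration: classify -> map -> score -> annotate -> rank ->
composition stats -> expression, with deterministic TSV outputs and a run
manifest.

A single global seed fans out to per-stage seeds by stable hashing
(blake2b of ``"seed:stage"``), so adding a stage never perturbs another
stage's random draws.  Re-running with the same configuration produces
byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from . import __version__
from .core_io import (
    LncRNAGene,
    read_fasta,
    read_gene_bed,
    read_repeatmasker_out,
    read_table,
    read_variant_table,
    write_tsv,
)
from .evidence_rank import attach_evidence, rank_variants, ranked_to_frame
from .expression_profiles import (
    ExpressionMatrix,
    correlations_to_frame,
    expressed_across_all,
    host_lnc_correlations,
    not_detected_fraction,
)
from .locus_classify import associations_to_frame, build_association_table
from .seq_composition import (
    chisq_enrichment,
    class_percentages,
    composition_summary,
    gc_content,
    repeat_composition,
    welch_t_test,
)
from .structure_disruption import (
    NotScoreableError,
    ReferenceMismatchError,
    ScoreConfig,
    results_to_frame,
    score_variant,
)
from .variant_map import assignments_to_frame, filter_nominal, map_variants

logger = logging.getLogger("lncsnp")


def stage_seed(seed: int, stage: str) -> int:
    digest = hashlib.blake2b(f"{seed}:{stage}".encode(), digest_size=4).digest()
    return int.from_bytes(digest, "big") % (2**31)


@dataclass
class PipelineConfig:
    genes_bed: str
    lncs_bed: str
    transcripts_fasta: str
    variants_tsv: str
    out_dir: str
    regulome_tsv: Optional[str] = None
    eqtl_tsv: Optional[str] = None
    ihs_tsv: Optional[str] = None
    tss_tsv: Optional[str] = None
    repeats_out: Optional[str] = None
    fpkm_tsv: Optional[str] = None
    alpha: float = 0.01
    flank: int = 5000
    window_radius: int = 200
    min_region: int = 50
    p_threshold: float = 0.2
    n_background: int = 200
    cis_window: int = 1_000_000
    ihs_threshold: float = 2.5
    fpkm_threshold: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        checks = [
            0.0 < self.alpha <= 1.0,
            self.flank >= 0,
            self.window_radius >= 1,
            1 <= self.min_region,
            0.0 < self.p_threshold <= 1.0,
            self.n_background >= 19,
            self.cis_window >= 0,
            self.ihs_threshold >= 0,
            self.fpkm_threshold >= 0,
        ]
        if not all(checks):
            raise ValueError("pipeline threshold outside its documented range")

    def content_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


@dataclass
class PipelineResult:
    associations: pd.DataFrame
    association_summary: pd.DataFrame
    assignments: dict[str, pd.DataFrame]
    disruption: dict[str, pd.DataFrame]
    ranked: dict[str, pd.DataFrame]
    composition: pd.DataFrame
    expression: pd.DataFrame
    skipped: dict[str, list[str]]
    manifest: dict = field(default_factory=dict)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and offending record."""


def _load_lncs(cfg: PipelineConfig) -> list[LncRNAGene]:
    lncs = read_gene_bed(cfg.lncs_bed, biotype="lncRNA")
    seqs = read_fasta(cfg.transcripts_fasta)
    out = []
    for lnc in lncs:
        seq = seqs.get(lnc.gene_id)
        out.append(
            LncRNAGene(
                gene_id=lnc.gene_id,
                interval=lnc.interval,
                exons=lnc.exons,
                transcript_seq=seq,
            )
        )
    return out


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    """Run every stage on the configured inputs; write TSVs plus a manifest."""
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    def _stage(name):
        logger.info("stage: %s", name)

    try:
        _stage("load")
        genes = read_gene_bed(cfg.genes_bed, biotype="protein_coding")
        lncs = _load_lncs(cfg)
        variants = read_variant_table(cfg.variants_tsv)
    except Exception as exc:
        raise StageError(f"load: {exc}") from exc
    by_id = {v.id: v for v in variants}
    diseases = sorted({d for v in variants for d in v.assoc_p})

    _stage("classify")
    records, summary = build_association_table(lncs, genes, cfg.flank)
    associations = associations_to_frame(records)
    write_tsv(associations, out_dir / "associations.tsv")
    write_tsv(summary, out_dir / "association_summary.tsv")
    associated_lnc_ids = {r.lnc_id for r in records}

    assignments: dict[str, pd.DataFrame] = {}
    disruption: dict[str, pd.DataFrame] = {}
    ranked: dict[str, pd.DataFrame] = {}
    skipped: dict[str, list[str]] = {}
    lnc_by_id = {l.gene_id: l for l in lncs}

    regulome = read_table(cfg.regulome_tsv, {"variant_id": str, "score": str}) \
        if cfg.regulome_tsv else None
    eqtl = read_table(cfg.eqtl_tsv,
                      {"variant_id": str, "gene_id": str, "tissue": str, "p": float}) \
        if cfg.eqtl_tsv else None
    ihs = read_table(cfg.ihs_tsv, {"variant_id": str, "ihs": float}) \
        if cfg.ihs_tsv else None
    tss = read_table(cfg.tss_tsv, {"gene_id": str, "tss_pos": int}) \
        if cfg.tss_tsv else None

    for disease in diseases:
        _stage(f"map:{disease}")
        nominal = filter_nominal(variants, disease, cfg.alpha)
        assigned = map_variants(nominal, lncs)
        # keep only lncRNAs associated with candidate-gene loci
        assigned = [a for a in assigned if a.lnc_id in associated_lnc_ids]
        assignments[disease] = assignments_to_frame(assigned)
        write_tsv(assignments[disease], out_dir / f"assignments_{disease}.tsv")

        _stage(f"score:{disease}")
        score_cfg = ScoreConfig(
            radius=cfg.window_radius,
            min_region=cfg.min_region,
            n_background=cfg.n_background,
            p_threshold=cfg.p_threshold,
            seed=stage_seed(cfg.seed, f"score:{disease}"),
        )
        results = []
        skipped_ids: list[str] = []
        for a in assigned:
            lnc = lnc_by_id[a.lnc_id]
            v = by_id[a.variant_id]
            try:
                results.append(score_variant(lnc, a, v.ref, v.alt, score_cfg))
            except (NotScoreableError, ReferenceMismatchError) as exc:
                skipped_ids.append(f"{a.variant_id}/{a.lnc_id}: {exc}")
        skipped[disease] = skipped_ids
        disruption[disease] = results_to_frame(results)
        write_tsv(disruption[disease], out_dir / f"disruption_{disease}.tsv")

        _stage(f"rank:{disease}")
        significant = [r for r in results if r.p_value <= cfg.p_threshold]
        sig_variants = [by_id[r.variant_id] for r in significant]
        evidence = attach_evidence(
            sig_variants, regulome, eqtl, ihs, tss,
            cis_window=cfg.cis_window, ihs_threshold=cfg.ihs_threshold,
        )
        ranked_list = rank_variants(significant, evidence, by_id, cfg.p_threshold)
        ranked[disease] = ranked_to_frame(ranked_list)
        write_tsv(ranked[disease], out_dir / f"ranked_{disease}.tsv")

    _stage("stats")
    associated = [lnc_by_id[i] for i in sorted(associated_lnc_ids)]
    rows = []
    summary_all = composition_summary(lncs)
    summary_assoc = composition_summary(associated)
    rows.append({"set": "all_lncRNAs", **summary_all})
    rows.append({"set": "loci_associated", **summary_assoc})
    composition = pd.DataFrame(rows)
    if cfg.repeats_out:
        repeats = read_repeatmasker_out(cfg.repeats_out)
        bg_counts, bg_frac = repeat_composition(repeats, lncs)
        obs_counts, obs_frac = repeat_composition(repeats, associated)
        composition["repeat_harboring_frac"] = [bg_frac, obs_frac]
        pct_bg = class_percentages(bg_counts)
        pct_obs = class_percentages(obs_counts)
        for cls in pct_bg:
            composition[f"pct_{cls}"] = [pct_bg[cls], pct_obs[cls]]
        try:
            chi = chisq_enrichment(obs_counts, bg_counts)
            composition["chisq_stat"] = [float("nan"), chi.statistic]
            composition["chisq_p"] = [float("nan"), chi.p_value]
        except Exception:
            pass
    gcs_all = [gc_content(l.transcript_seq) for l in lncs if l.transcript_seq]
    gcs_assoc = [gc_content(l.transcript_seq) for l in associated if l.transcript_seq]
    if len(gcs_all) >= 2 and len(gcs_assoc) >= 2:
        try:
            t = welch_t_test(gcs_assoc, gcs_all)
            composition["gc_welch_t"] = [float("nan"), t.statistic]
            composition["gc_welch_p"] = [float("nan"), t.p_value]
        except Exception:
            pass
    write_tsv(composition, out_dir / "composition.tsv")

    _stage("expression")
    if cfg.fpkm_tsv:
        fpkm = ExpressionMatrix.from_tsv(cfg.fpkm_tsv)
        expressed = expressed_across_all(fpkm, cfg.fpkm_threshold)
        sense_pairs = sorted(
            {
                (r.lnc_id, r.gene_id)
                for r in records
                if r.relation in ("sense_intersecting", "sense_full_overlap")
            }
        )
        corrs, corr_skipped = host_lnc_correlations(fpkm, sense_pairs)
        expression = correlations_to_frame(corrs)
        expression["expressed_across_all"] = [
            pair[0] in expressed for pair in [(r.pair[0], r.pair[1]) for r in corrs]
        ]
        skipped["expression"] = [f"{a}/{b}" for a, b in corr_skipped]
        meta = pd.DataFrame(
            [{
                "n_expressed_across_all": len(expressed),
                "not_detected_fraction": not_detected_fraction(fpkm, cfg.fpkm_threshold),
            }]
        )
        write_tsv(meta, out_dir / "expression_summary.tsv")
    else:
        expression = pd.DataFrame(columns=["id_a", "id_b", "r_s", "n"])
    write_tsv(expression, out_dir / "expression_correlations.tsv")

    _stage("manifest")
    manifest = {
        "config": asdict(cfg),
        "config_hash": cfg.content_hash(),
        "seed": cfg.seed,
        "version": __version__,
        "n_genes": len(genes),
        "n_lncs": len(lncs),
        "n_variants": len(variants),
        "diseases": diseases,
        "skipped": skipped,
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")

    return PipelineResult(
        associations=associations,
        association_summary=summary,
        assignments=assignments,
        disruption=disruption,
        ranked=ranked,
        composition=composition,
        expression=expression,
        skipped=skipped,
        manifest=manifest,
    )
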