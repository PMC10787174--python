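"""End-to-end orchestration over a data directory of standard-format files.

The pipeline expects a directory containing::

    genome.fa                     reference sequence
    genes.gtf                     gene models (gene + exon features)
    cnes.bed / cnes_meta.tsv      conserved elements + (id, type, score)
    peaks_<tissue>_<stage>_rep<i>.bed   replicate peak sets per condition
    samples.tsv                   sample metadata
    expression.tsv / openness.tsv paired matrices
    motifs.jaspar                 TF motif models
    tes.bed                       transposable-element annotation
    rsegs.txt / tf_catalog.txt    trait-specific genes and TF catalog

and runs the stages in dependency order: active elements -> specificity ->
toolkit-TF filter -> motif hits -> upstream fits -> downstream screen ->
influence ranking -> differential sub-network -> TE summary.  Every stage
output is a TSV/JSON in the run directory; a manifest records the config
echo, a config hash and input checksums so a run is reproducible from the
manifest alone.
"""

from __future__ import annotations

import glob
import hashlib
import json
import logging
import os
import re
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import (active_cne, differential, grn, influence, matrices, motif,
               specificity, te, ttf)
from .regions import RegionSet, read_bed, read_gene_models, write_bed

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Thresholds and dialect flags; defaults are the method's published ones."""

    indir: str = "."
    outdir: str = "run"
    focal_tissue: str = "rumen"
    reference_tissue: str = "esophagus"
    flank: int = 1_000_000          # window around a TSS for element pairing
    min_overlap: int = 1            # bp for the element x OCR activity call
    rho_min: float = 0.6            # upstream TF ~ TTF Spearman gate
    gamma_min: float = 0.7          # downstream triplet Spearman gate
    q_max: float = 0.01             # BH FDR for both correlation screens
    fpkm_min: float = 1.0           # expressed-gene gate
    top_k: int = 50                 # specificity rank gate
    de_q: float = 0.05              # differential-call FDR
    de_log2fc: float = 1.0
    y1_fpkm: float = 2.0            # single-replicate-stage rules
    y1_fc: float = 2.0
    enrich_neglog10p: float = 6.0   # differential-TF motif enrichment gate
    motif_p: float = 1e-4           # per-match scan threshold
    region_id_dialect: str = "start-length"
    gamma_transform: str = "power2"
    jms_exponent: float = 1.0 / 3.0
    jms_epsilon: float = 1e-6
    consensus_span: str = "union"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


class StageError(RuntimeError):
    def __init__(self, stage: str, err: Exception) -> None:
        super().__init__(f"stage {stage!r} failed: {err}")
        self.stage = stage
        self.code = f"E_{stage.upper().replace('-', '_')}"


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages; returns the manifest dict (also written to disk)."""
    cfg = config
    os.makedirs(cfg.outdir, exist_ok=True)
    handler = logging.FileHandler(os.path.join(cfg.outdir, "run.log"))
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
    root = logging.getLogger("cnegrn")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    manifest: dict = {"config": asdict(cfg), "stages": {}, "inputs": {}}
    manifest["config_hash"] = hashlib.sha256(
        json.dumps(asdict(cfg), sort_keys=True).encode()).hexdigest()
    stage = "load-inputs"
    try:
        ind = cfg.indir
        for name in ("genome.fa", "genes.gtf", "cnes.bed", "cnes_meta.tsv",
                     "samples.tsv", "expression.tsv", "openness.tsv",
                     "motifs.jaspar", "tes.bed", "rsegs.txt",
                     "tf_catalog.txt"):
            path = os.path.join(ind, name)
            manifest["inputs"][name] = _sha256(path)
        gene_models = read_gene_models(os.path.join(ind, "genes.gtf"))
        model_of = {g.gene_id: g for g in gene_models}
        cnes = active_cne.read_cnes(os.path.join(ind, "cnes.bed"),
                                    os.path.join(ind, "cnes_meta.tsv"))
        meta = matrices.read_sample_sheet(os.path.join(ind, "samples.tsv"))
        expr = matrices.read_matrix(os.path.join(ind, "expression.tsv"))
        opn = matrices.read_matrix(os.path.join(ind, "openness.tsv"))
        motifs = motif.read_motifs(os.path.join(ind, "motifs.jaspar"))
        tes = read_bed(os.path.join(ind, "tes.bed"))
        rsegs = [l.strip() for l in open(os.path.join(ind, "rsegs.txt"))
                 if l.strip()]
        tf_catalog = [l.strip() for l in
                      open(os.path.join(ind, "tf_catalog.txt")) if l.strip()]

        stage = "active-cne"
        peak_files = sorted(glob.glob(os.path.join(ind, "peaks_*_rep*.bed")))
        by_cond: dict[tuple[str, str], list[str]] = {}
        for pf in peak_files:
            m = re.match(r"peaks_(.+)_(.+)_rep(\d+)\.bed",
                         os.path.basename(pf))
            if not m:
                raise ValueError(f"unrecognised peak file name {pf}")
            by_cond.setdefault((m.group(1), m.group(2)), []).append(pf)
        ocrs_by_cond = {
            cond: active_cne.reproducible_peaks(
                [read_bed(p) for p in paths], span=cfg.consensus_span)
            for cond, paths in sorted(by_cond.items())}
        calls = active_cne.call_active_cnes(
            ocrs_by_cond, cnes, min_overlap=cfg.min_overlap,
            gene_models=gene_models)
        calls_df = active_cne.calls_to_frame(calls)
        calls_df.to_csv(os.path.join(cfg.outdir, "active_calls.tsv"),
                        sep="\t", index=False)
        active_ids = sorted(set(calls_df["cne_id"]))
        cne_of = {c.id: c for c in cnes}
        active_set = RegionSet([cne_of[i].region for i in active_ids])
        write_bed(active_set, os.path.join(cfg.outdir, "active_cnes.bed"),
                  scores={i: cne_of[i].conservation for i in active_ids})
        n_i, n_ii, ratio = active_cne.type_composition(calls, cnes)
        manifest["stages"]["active-cne"] = {
            "outputs": ["active_calls.tsv", "active_cnes.bed"],
            "n_active": len(active_ids), "n_type_I": n_i,
            "n_type_II": n_ii, "type_ratio": ratio}

        stage = "specificity"
        spec_table = specificity.specificity_table(
            expr, meta, epsilon=cfg.jms_epsilon, exponent=cfg.jms_exponent)
        spec_table.to_csv(os.path.join(cfg.outdir, "specificity.tsv"),
                          sep="\t", index=False)
        manifest["stages"]["specificity"] = {"outputs": ["specificity.tsv"]}

        stage = "ttf"
        focal_cols = list(meta.loc[meta["tissue"] == cfg.focal_tissue,
                                   "sample_id"])
        audit = ttf.identify_ttfs(
            rsegs, tf_catalog, active_set, model_of, expr[focal_cols],
            spec_table, flank=cfg.flank, fpkm_min=cfg.fpkm_min,
            top_k=cfg.top_k)
        audit.to_csv(os.path.join(cfg.outdir, "ttf_audit.tsv"), sep="\t",
                     index=False)
        ttfs = sorted(audit.loc[audit["is_ttf"], "gene_id"])
        manifest["stages"]["ttf"] = {"outputs": ["ttf_audit.tsv"],
                                     "n_ttfs": len(ttfs)}

        stage = "motif-hits"
        from pyfaidx import Fasta
        fasta = Fasta(os.path.join(ind, "genome.fa"))
        seqs = {r.id: str(fasta[r.chrom][r.start:r.end]) for r in active_set}
        recs = motif.scan_regions(seqs, motifs, p_threshold=cfg.motif_p)
        hit_table = motif.aggregate_B(recs)
        hit_table.to_csv(os.path.join(cfg.outdir, "hit_table.tsv"), sep="\t",
                         index=False)
        manifest["stages"]["motif-hits"] = {"outputs": ["hit_table.tsv"],
                                            "n_pairs": len(hit_table)}

        stage = "upstream"
        up_frames = []
        for t in ttfs:
            gm = model_of[t]
            near = [r.id for r in active_set.overlapping(
                gm.chrom, max(0, gm.tss - cfg.flank), gm.tss + cfg.flank + 1)]
            tf_pool = sorted((set(tf_catalog) - {t}) & set(expr.index))
            mb = grn.candidate_upstream_tfs(
                expr.loc[t], expr.loc[tf_pool], hit_table, near,
                rho_min=cfg.rho_min, q_max=cfg.q_max)
            terms = {c: (opn.loc[c], expr.loc[m]) for c, m in mb.items()}
            fit = grn.fit_upstream_model(t, expr.loc[t], terms)
            up_frames.append(fit.to_frame())
        up_frames = [f for f in up_frames if len(f)]
        upstream_df = (pd.concat(up_frames, ignore_index=True) if up_frames
                       else pd.DataFrame(columns=["ttf", "cne", "tf_member",
                                                  "beta", "p", "retained"]))
        upstream_df.to_csv(os.path.join(cfg.outdir, "upstream_network.tsv"),
                           sep="\t", index=False)
        manifest["stages"]["upstream"] = {
            "outputs": ["upstream_network.tsv"],
            "n_edges": int(upstream_df["retained"].sum())
            if len(upstream_df) else 0}

        stage = "downstream"
        pairs = motif.hit_pairs(hit_table)
        expressed = set(expr.index[(expr[focal_cols] > cfg.fpkm_min
                                    ).any(axis=1)])
        target_pool = sorted((set(rsegs) & expressed) - set(ttfs))
        candidates = []
        for t in ttfs:
            bound = sorted(r for r, tfname in pairs if tfname == t)
            for c in bound:
                region = active_set[c]
                mid = (region.start + region.end) // 2
                for g in target_pool:
                    gm = model_of.get(g)
                    if gm is None or gm.chrom != region.chrom:
                        continue
                    if abs(gm.tss - mid) <= cfg.flank:
                        candidates.append((t, c, g))
        down = grn.infer_downstream(
            expr.loc[ttfs, focal_cols] if ttfs else expr.iloc[:0],
            opn[focal_cols], expr.loc[target_pool, focal_cols],
            candidates, gamma_min=cfg.gamma_min, q_max=cfg.q_max)
        down.to_csv(os.path.join(cfg.outdir, "downstream_network.tsv"),
                    sep="\t", index=False)
        manifest["stages"]["downstream"] = {
            "outputs": ["downstream_network.tsv"],
            "n_tested": len(down),
            "n_retained": int(down["retained"].sum()) if len(down) else 0}

        stage = "influence"
        sub_meta = meta[meta["tissue"] == cfg.focal_tissue]
        samples_by_time = {
            s: list(sub_meta.loc[sub_meta["stage"] == s, "sample_id"])
            for s in sub_meta["stage"].unique()}
        conservation = {c.id: (c.cne_type, c.conservation) for c in cnes}
        if len(down) and down["retained"].any():
            inf = influence.influence_table(
                down, opn, hit_table, expr, expr, samples_by_time,
                conservation, gamma_transform=cfg.gamma_transform)
        else:
            inf = pd.DataFrame(columns=["cne_id", "type", "R", "C", "W",
                                        "rank_within_type"])
        inf.to_csv(os.path.join(cfg.outdir, "influence.tsv"), sep="\t",
                   index=False)
        manifest["stages"]["influence"] = {"outputs": ["influence.tsv"],
                                           "n_ranked": len(inf)}

        stage = "differential"
        de_frames, da_frames = [], []
        for s in meta["stage"].unique():
            n_f = (sub_meta["stage"] == s).sum()
            n_r = ((meta["tissue"] == cfg.reference_tissue)
                   & (meta["stage"] == s)).sum()
            if n_f >= 2 and n_r >= 2:
                de_frames.append(differential.de_genes(
                    expr, meta, s, cfg.focal_tissue, cfg.reference_tissue,
                    q_max=cfg.de_q, log2fc_min=cfg.de_log2fc))
                da_frames.append(differential.de_genes(
                    opn, meta, s, cfg.focal_tissue, cfg.reference_tissue,
                    mode="two-sided-peaks", q_max=cfg.de_q,
                    log2fc_min=cfg.de_log2fc))
            elif n_f == 1 and n_r == 1:
                de_frames.append(differential.de_genes_single_replicate(
                    expr, meta, s, cfg.focal_tissue, cfg.reference_tissue,
                    fpkm_min=cfg.y1_fpkm, fc_min=cfg.y1_fc))
                da_frames.append(differential.de_genes_single_replicate(
                    opn, meta, s, cfg.focal_tissue, cfg.reference_tissue,
                    fpkm_min=cfg.y1_fpkm, fc_min=cfg.y1_fc))
            else:
                logger.warning("stage %s: unsupported replicate design "
                               "(%d vs %d); skipped", s, n_f, n_r)
        de_all = pd.concat(de_frames, ignore_index=True)
        da_all = pd.concat(da_frames, ignore_index=True)
        de_all.to_csv(os.path.join(cfg.outdir, "de_genes.tsv"), sep="\t",
                      index=False)
        da_all.to_csv(os.path.join(cfg.outdir, "da_peaks.tsv"), sep="\t",
                      index=False)
        de_genes_set = set(de_all.loc[de_all["passed"], "entity"])
        da_ids = sorted(set(da_all.loc[da_all["passed"], "entity"])
                        & set(active_ids))
        if da_ids:
            enr = motif.motif_enrichment(
                da_ids, active_ids, hit_table,
                neglog10p_threshold=cfg.enrich_neglog10p)
        else:
            enr = pd.DataFrame(columns=["tf", "neglog10p", "enriched"])
        enr.to_csv(os.path.join(cfg.outdir, "motif_enrichment.tsv"),
                   sep="\t", index=False)
        de_tfs = de_genes_set & set(tf_catalog)
        diff_ttfs = differential.differential_ttfs(
            ttfs, de_tfs, enr, neglog10p_threshold=cfg.enrich_neglog10p)
        subnet = differential.extract_subnetwork(down, diff_ttfs,
                                                 de_genes_set)
        subnet.to_csv(os.path.join(cfg.outdir, "subnetwork.tsv"), sep="\t",
                      index=False)
        manifest["stages"]["differential"] = {
            "outputs": ["de_genes.tsv", "da_peaks.tsv",
                        "motif_enrichment.tsv", "subnetwork.tsv"],
            "n_diff_ttfs": len(diff_ttfs), "n_sub_edges": len(subnet)}

        stage = "te"
        up_cnes = sorted(set(upstream_df.loc[upstream_df["retained"], "cne"])
                         ) if len(upstream_df) else []
        down_cnes = sorted(set(down.loc[down["retained"], "cne"])
                           ) if len(down) else []
        flags = te.flag_te_derived(active_set, tes)
        summary: dict = {}
        if up_cnes and down_cnes:
            up_ret = upstream_df[upstream_df["retained"]]
            ttf_te = {row.ttf for row in up_ret.itertuples()
                      if flags.get(row.cne)}
            tgt_all = sorted(set(down.loc[down["retained"], "target"]))
            tgt_te = {row.target for row in down[down["retained"]].itertuples()
                      if flags.get(row.cne)}
            result = te.enrichment_summary(
                {"upstream": (len(up_cnes),
                              sum(flags.get(c, False) for c in up_cnes)),
                 "downstream": (len(down_cnes),
                                sum(flags.get(c, False) for c in down_cnes))},
                {"upstream": (len(ttfs), len(ttf_te)),
                 "downstream": (len(tgt_all), len(tgt_te))})
            summary = {"sets": [asdict(s) for s in result["sets"]],
                       "element_folds": result["element_folds"],
                       "gene_folds": result["gene_folds"]}
        with open(os.path.join(cfg.outdir, "te_summary.json"), "w") as fh:
            json.dump(summary, fh, indent=1)
        manifest["stages"]["te"] = {"outputs": ["te_summary.json"]}

    except Exception as err:  # noqa: BLE001 - re-raised with stage context
        root.removeHandler(handler)
        raise StageError(stage, err) from err
    root.removeHandler(handler)
    with open(os.path.join(cfg.outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return manifest
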