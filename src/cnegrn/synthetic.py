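"""Seeded synthetic multi-omics bundle with planted regulatory structure.

The generator emulates the study design the package targets: two epithelial
tissues (a focal organ and its developmental predecessor) sampled at five
stages (E60, D1, D7, D28, Y1) with three biological replicates per
condition (one at Y1), in two library batches, with paired gene expression
(FPKM) and chromatin openness per conserved element.

Planted structure, all recorded in ground-truth tables:

- toolkit TFs whose expression follows the upstream linear model (a sum of
  member-TF-expression x element-openness terms with known coefficients);
- downstream triplets (TTF, element, target) in which the target's
  log-expression is a monotone function of sqrt(log2(TTF+1) * log2(O+1))
  plus Gaussian noise calibrated so the planted Spearman coupling is about
  0.9 — the strength of coupling the screen is designed to call;
- decoy triplets whose element carries a genuine TTF motif (bound) but
  whose target is developmentally flat noise (unregulated);
- motif consensus sequences physically inserted into the genome inside
  bound elements, so sequence scanning rediscovers the planted binding.

Everything is drawn from one seeded generator in documented order, so a
given seed yields a byte-identical bundle.  Features of real data that are
NOT emulated: read-level sampling, mappability artefacts, TF families with
similar motifs, and correlated decoy expression programs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .active_cne import Cne
from .matrices import STAGE_ORDER
from .motif import MotifModel
from .regions import GeneModel, GenomicRegion, RegionSet

__all__ = ["SyntheticSpec", "SyntheticBundle", "generate",
           "make_upstream_dataset", "make_null_screen"]

_BASES = "ACGT"


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic study; defaults mirror the target design."""

    seed: int = 7
    n_chromosomes: int = 2
    chrom_length: int = 1_000_000
    tissues: tuple[str, ...] = ("rumen", "esophagus")
    stages: tuple[str, ...] = STAGE_ORDER
    replicates: int = 3                  # per condition; Y1 has one
    single_replicate_stage: str = "Y1"
    n_batches: int = 2
    n_tfs: int = 12                      # upstream regulator pool
    n_ttfs: int = 3
    n_planted_triplets: int = 10
    n_decoy_triplets: int = 90
    n_inactive_cnes: int = 14
    upstream_cnes_per_ttf: int = 2
    members_per_upstream_cne: int = 2
    motif_width: int = 8
    type_i_fraction: float = 0.26        # active elements skew type II
    target_slope: float = 3.0            # planted log-scale coupling slope
    target_noise_sd: float = 0.5         # log2 sd; yields gamma ~ 0.9
    upstream_noise_frac: float = 0.1     # Gaussian sd as fraction of signal sd
    batch_offset_sd: float = 0.3         # log2 additive batch shift
    n_tes: int = 15


@dataclass
class SyntheticBundle:
    spec: SyntheticSpec
    genome: dict[str, str]
    gene_models: list[GeneModel]
    cnes: list[Cne]
    tes: RegionSet
    replicate_peaks: dict[tuple[str, str], list[RegionSet]]
    meta: pd.DataFrame
    expression: pd.DataFrame
    openness: pd.DataFrame
    motifs: list[MotifModel]
    ttf_ids: list[str]
    tf_catalog: list[str]
    rseg_ids: list[str]
    truth_triplets: pd.DataFrame         # planted + decoys, flagged
    truth_upstream: pd.DataFrame
    motif_of_cne: dict[str, str] = field(default_factory=dict)

    def focal_samples(self, tissue: str | None = None) -> list[str]:
        t = tissue or self.spec.tissues[0]
        return list(self.meta.loc[self.meta["tissue"] == t, "sample_id"])

    def samples_by_stage(self, tissue: str | None = None
                         ) -> dict[str, list[str]]:
        t = tissue or self.spec.tissues[0]
        sub = self.meta[self.meta["tissue"] == t]
        return {s: list(sub.loc[sub["stage"] == s, "sample_id"])
                for s in self.spec.stages}

    def write(self, outdir: str | Path) -> None:
        """Write the bundle in standard text formats (FASTA/GTF/BED/TSV)."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "genome.fa", "w") as fh:
            for chrom, seq in self.genome.items():
                fh.write(f">{chrom}\n")
                for i in range(0, len(seq), 80):
                    fh.write(seq[i:i + 80] + "\n")
        with open(out / "genes.gtf", "w") as fh:
            for g in self.gene_models:
                attrs = f'gene_id "{g.gene_id}";'
                fh.write("\t".join([g.chrom, "synthetic", "gene",
                                    str(g.start + 1), str(g.end), ".",
                                    g.strand, ".", attrs]) + "\n")
                for s, e in g.exons:
                    fh.write("\t".join([g.chrom, "synthetic", "exon",
                                        str(s + 1), str(e), ".", g.strand,
                                        ".", attrs]) + "\n")
        with open(out / "cnes.bed", "w") as fh:
            for c in self.cnes:
                r = c.region
                fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.id}\n")
        pd.DataFrame(
            [(c.id, c.cne_type, c.conservation) for c in self.cnes],
            columns=["id", "type", "conservation_score"],
        ).to_csv(out / "cnes_meta.tsv", sep="\t", index=False)
        with open(out / "tes.bed", "w") as fh:
            for r in self.tes:
                fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.id}\n")
        for (tissue, stage), reps in self.replicate_peaks.items():
            for i, rs in enumerate(reps, start=1):
                with open(out / f"peaks_{tissue}_{stage}_rep{i}.bed", "w") as fh:
                    for r in rs:
                        fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.id}\n")
        self.meta.to_csv(out / "samples.tsv", sep="\t", index=False)
        self.expression.to_csv(out / "expression.tsv", sep="\t",
                               index_label="gene_id")
        self.openness.to_csv(out / "openness.tsv", sep="\t",
                             index_label="cne_id")
        from .motif import write_jaspar
        write_jaspar(self.motifs, str(out / "motifs.jaspar"))
        self.truth_triplets.to_csv(out / "truth_triplets.tsv", sep="\t",
                                   index=False)
        self.truth_upstream.to_csv(out / "truth_upstream.tsv", sep="\t",
                                   index=False)
        (out / "rsegs.txt").write_text("\n".join(self.rseg_ids) + "\n")
        (out / "tf_catalog.txt").write_text("\n".join(self.tf_catalog) + "\n")
        with open(out / "truth_genes.json", "w") as fh:
            json.dump({"ttfs": self.ttf_ids, "tf_catalog": self.tf_catalog,
                       "rsegs": self.rseg_ids,
                       "motif_of_cne": self.motif_of_cne}, fh, indent=1)


def _consensus_pfm(consensus: str, strength: float = 0.94) -> np.ndarray:
    w = len(consensus)
    pfm = np.full((4, w), (1 - strength) / 3 * 100)
    for j, base in enumerate(consensus):
        pfm[_BASES.index(base), j] = strength * 100
    return pfm


def _stage_profile(rng: np.random.Generator, n_stages: int,
                   lo: float = 2.0, hi: float = 40.0) -> np.ndarray:
    """A smooth positive profile over stages with real dynamic range."""
    walk = np.cumsum(rng.normal(0, 1, n_stages))
    walk = (walk - walk.min()) / max(np.ptp(walk), 1e-9)
    return lo + (hi - lo) * walk


def generate(spec: SyntheticSpec | None = None) -> SyntheticBundle:
    """Generate the full bundle; identical spec (incl. seed) => identical bundle."""
    spec = spec or SyntheticSpec()
    rng = np.random.default_rng(spec.seed)
    chroms = [f"chr{i + 1}" for i in range(spec.n_chromosomes)]
    stages = list(spec.stages)
    tissues = list(spec.tissues)
    focal = tissues[0]

    # --- gene layout -----------------------------------------------------
    ttf_ids = [f"TTF{i + 1}" for i in range(spec.n_ttfs)]
    tf_ids = [f"TF{i + 1:02d}" for i in range(spec.n_tfs)]
    target_ids = [f"TG{i + 1:02d}" for i in range(spec.n_planted_triplets)]
    n_decoy_targets = max(1, spec.n_decoy_triplets // 3)
    decoy_ids = [f"DG{i + 1:02d}" for i in range(n_decoy_targets)]
    all_gene_ids = ttf_ids + tf_ids + target_ids + decoy_ids

    gene_models: list[GeneModel] = []
    spacing = 30_000
    for i, gid in enumerate(all_gene_ids):
        chrom = chroms[i % len(chroms)]
        start = 20_000 + (i // len(chroms)) * spacing
        if start + 6_000 > spec.chrom_length:
            raise ValueError("chromosome too short for the requested genes")
        strand = "+" if rng.random() < 0.5 else "-"
        end = start + 5_000
        exons = [(start, start + 1_200), (end - 1_500, end)]
        gene_models.append(GeneModel(gid, chrom, start, end, strand, exons))
    model_of = {g.gene_id: g for g in gene_models}

    # --- motifs ----------------------------------------------------------
    scan_tfs = ttf_ids + tf_ids
    consensi: dict[str, str] = {}
    used = set()
    for tf in scan_tfs:
        while True:
            cons = "".join(rng.choice(list(_BASES), spec.motif_width))
            if cons not in used:
                used.add(cons)
                consensi[tf] = cons
                break
    motifs = [MotifModel(tf, _consensus_pfm(consensi[tf])) for tf in scan_tfs]

    # --- element layout --------------------------------------------------
    cne_specs: list[dict] = []   # id later; holds placement + role

    def _place_near(gene_id: str, tag: str) -> tuple[str, int, int]:
        g = model_of[gene_id]
        offset = int(rng.integers(6_000, 20_000))
        side = -1 if rng.random() < 0.5 else 1
        length = int(rng.integers(100, 300))
        start = max(0, g.tss + side * offset)
        return g.chrom, start, start + length

    planted = []
    for i in range(spec.n_planted_triplets):
        ttf = ttf_ids[i % spec.n_ttfs]
        target = target_ids[i]
        chrom, s, e = _place_near(target, "planted")
        cne_specs.append({"chrom": chrom, "start": s, "end": e,
                          "role": "planted", "motif_tf": ttf,
                          "target": target, "ttf": ttf})
    for i in range(spec.n_decoy_triplets):
        ttf = ttf_ids[i % spec.n_ttfs]
        target = decoy_ids[i % n_decoy_targets]
        chrom, s, e = _place_near(target, "decoy")
        cne_specs.append({"chrom": chrom, "start": s, "end": e,
                          "role": "decoy", "motif_tf": ttf,
                          "target": target, "ttf": ttf})
    upstream_terms = []
    for ttf in ttf_ids:
        member_pool = list(rng.permutation(tf_ids))
        for j in range(spec.upstream_cnes_per_ttf):
            chrom, s, e = _place_near(ttf, "upstream")
            members = sorted(member_pool[j * spec.members_per_upstream_cne:
                                         (j + 1) * spec.members_per_upstream_cne])
            cne_specs.append({"chrom": chrom, "start": s, "end": e,
                              "role": "upstream", "motif_tf": members,
                              "ttf": ttf})
            upstream_terms.append({"ttf": ttf, "members": members,
                                   "beta": float(rng.uniform(0.01, 0.05))})
    for i in range(spec.n_inactive_cnes):
        chrom = chroms[int(rng.integers(len(chroms)))]
        start = int(rng.integers(0, spec.chrom_length - 400))
        cne_specs.append({"chrom": chrom, "start": start,
                          "end": start + int(rng.integers(80, 250)),
                          "role": "inactive", "motif_tf": None})

    # deterministic ids in printed start-length style
    cnes: list[Cne] = []
    motif_of_cne: dict[str, str] = {}
    for cs in cne_specs:
        rid = f"{cs['chrom']}:{cs['start'] + 1}-{cs['end'] - cs['start']}"
        cs["id"] = rid
        is_type_i = rng.random() < spec.type_i_fraction
        cne_type = "I" if is_type_i else "II"
        cons = (float(rng.uniform(0.5, 1.0)) if is_type_i
                else float(rng.uniform(0.5, 5.0)))
        cnes.append(Cne(GenomicRegion(cs["chrom"], cs["start"], cs["end"],
                                      rid), cne_type, cons))

    # --- genome sequence with planted motif instances --------------------
    genome = {c: "".join(rng.choice(list(_BASES), spec.chrom_length))
              for c in chroms}
    seq_arrays = {c: list(genome[c]) for c in chroms}
    for cs in cne_specs:
        tf_field = cs["motif_tf"]
        if tf_field is None:
            continue
        tfs = tf_field if isinstance(tf_field, list) else [tf_field]
        mid = (cs["start"] + cs["end"]) // 2
        pos = cs["start"] + 5
        for tf in tfs:
            cons = consensi[tf]
            seq_arrays[cs["chrom"]][pos:pos + len(cons)] = list(cons)
            motif_of_cne.setdefault(cs["id"], tf)
            pos += len(cons) + 3
        assert pos <= cs["end"], "element too short for its motifs"
    genome = {c: "".join(seq_arrays[c]) for c in chroms}

    # --- samples ---------------------------------------------------------
    rows = []
    for tissue in tissues:
        for stage in stages:
            n_rep = 1 if stage == spec.single_replicate_stage else spec.replicates
            for rep in range(1, n_rep + 1):
                batch = f"b{1 + (rep - 1) % spec.n_batches}"
                rows.append((f"{tissue}_{stage}_r{rep}", tissue, stage, rep,
                             batch))
    meta = pd.DataFrame(rows, columns=["sample_id", "tissue", "stage",
                                       "replicate", "batch"])
    samples = list(meta["sample_id"])
    stage_of = dict(zip(meta["sample_id"], meta["stage"]))
    tissue_of = dict(zip(meta["sample_id"], meta["tissue"]))

    # --- openness --------------------------------------------------------
    active_roles = {"planted", "decoy", "upstream"}
    openness = pd.DataFrame(0.0, index=[c.id for c in cnes], columns=samples)
    base_open: dict[str, dict[tuple[str, str], float]] = {}
    for cs in cne_specs:
        if cs["role"] not in active_roles:
            continue
        prof = {}
        for tissue in tissues:
            levels = _stage_profile(rng, len(stages), lo=1.0, hi=20.0)
            for stage, level in zip(stages, levels):
                prof[(tissue, stage)] = level
        base_open[cs["id"]] = prof
    for s in samples:
        key = (tissue_of[s], stage_of[s])
        for cid, prof in base_open.items():
            openness.loc[cid, s] = prof[key] * 2.0 ** rng.normal(0, 0.2)

    # --- expression ------------------------------------------------------
    expression = pd.DataFrame(0.0, index=all_gene_ids, columns=samples)
    # regulator TFs: smooth stage/tissue profiles with replicate noise
    for tf in tf_ids:
        prof = {}
        for tissue in tissues:
            levels = _stage_profile(rng, len(stages), lo=5.0, hi=50.0)
            for stage, level in zip(stages, levels):
                prof[(tissue, stage)] = level
        for s in samples:
            expression.loc[tf, s] = (prof[(tissue_of[s], stage_of[s])]
                                     * 2.0 ** rng.normal(0, 0.2))
    # toolkit TFs follow the upstream linear model
    terms_by_ttf: dict[str, list[dict]] = {}
    for term, cs in zip(upstream_terms,
                        [c for c in cne_specs if c["role"] == "upstream"]):
        term["cne"] = cs["id"]
        terms_by_ttf.setdefault(term["ttf"], []).append(term)
    for ttf in ttf_ids:
        beta0 = 2.0
        signal = np.full(len(samples), beta0)
        for term in terms_by_ttf[ttf]:
            tf_sum = expression.loc[term["members"]].sum(axis=0).to_numpy()
            signal = signal + term["beta"] * tf_sum * openness.loc[
                term["cne"]].to_numpy()
        noise = rng.normal(0, spec.upstream_noise_frac * np.std(signal),
                           len(samples))
        expression.loc[ttf] = np.maximum(signal + noise, 0.01)
    # planted targets: monotone in the screen's log-scale predictor
    for cs in cne_specs:
        if cs["role"] != "planted":
            continue
        pred = np.sqrt(np.log2(expression.loc[cs["ttf"]].to_numpy() + 1)
                       * np.log2(openness.loc[cs["id"]].to_numpy() + 1))
        log_expr = (1.0 + spec.target_slope * pred
                    + rng.normal(0, spec.target_noise_sd, len(samples)))
        expression.loc[cs["target"]] = np.maximum(2.0 ** log_expr - 1, 0.0)
    # decoy targets: developmentally flat noise around a gene-level base
    for gid in decoy_ids:
        base = float(rng.uniform(2, 6))
        expression.loc[gid] = np.maximum(
            2.0 ** (base + rng.normal(0, spec.target_noise_sd, len(samples)))
            - 1, 0.0)
    # additive log-scale batch offsets applied multiplicatively on FPKM
    batch_shift = {f"b{i + 1}": (0.0 if i == 0 else
                                 float(rng.normal(0, spec.batch_offset_sd)))
                   for i in range(spec.n_batches)}
    batch_of = dict(zip(meta["sample_id"], meta["batch"]))
    for s in samples:
        expression[s] = np.maximum(
            (expression[s] + 1) * 2.0 ** batch_shift[batch_of[s]] - 1, 0.0)

    # --- replicate peak sets over active elements ------------------------
    replicate_peaks: dict[tuple[str, str], list[RegionSet]] = {}
    active_cne_specs = [c for c in cne_specs if c["role"] in active_roles]
    for tissue in tissues:
        for stage in stages:
            reps = []
            for rep in range(spec.replicates):
                regions = []
                for cs in active_cne_specs:
                    pad_l = int(rng.integers(50, 150))
                    pad_r = int(rng.integers(50, 150))
                    regions.append(GenomicRegion(
                        cs["chrom"], max(0, cs["start"] - pad_l),
                        cs["end"] + pad_r,
                        f"pk_{tissue}_{stage}_r{rep}_{cs['id']}"))
                # one irreproducible peak per replicate, away from elements
                start = int(rng.integers(spec.chrom_length - 50_000,
                                         spec.chrom_length - 1_000))
                regions.append(GenomicRegion(chroms[0], start, start + 300,
                                             f"noise_{tissue}_{stage}_{rep}"))
                reps.append(RegionSet(regions))
            replicate_peaks[(tissue, stage)] = reps

    # --- transposable elements -------------------------------------------
    te_regions = []
    te_covered = [c for c in cne_specs if c["role"] in active_roles][:5]
    for i, cs in enumerate(te_covered):
        te_regions.append(GenomicRegion(cs["chrom"], max(0, cs["start"] - 20),
                                        cs["end"] + 20, f"TE{i + 1:02d}"))
    for i in range(len(te_covered), spec.n_tes):
        chrom = chroms[int(rng.integers(len(chroms)))]
        start = int(rng.integers(0, spec.chrom_length - 1_000))
        te_regions.append(GenomicRegion(chrom, start,
                                        start + int(rng.integers(200, 800)),
                                        f"TE{i + 1:02d}"))
    tes = RegionSet(te_regions)

    # --- ground truth ----------------------------------------------------
    trip_rows = [(cs["ttf"], cs["id"], cs["target"], cs["role"] == "planted")
                 for cs in cne_specs if cs["role"] in {"planted", "decoy"}]
    truth_triplets = pd.DataFrame(trip_rows,
                                  columns=["ttf", "cne", "target", "planted"])
    up_rows = [(t["ttf"], t["cne"], ",".join(t["members"]), t["beta"])
               for t in upstream_terms]
    truth_upstream = pd.DataFrame(up_rows,
                                  columns=["ttf", "cne", "members", "beta"])

    return SyntheticBundle(
        spec=spec, genome=genome, gene_models=gene_models, cnes=cnes,
        tes=tes, replicate_peaks=replicate_peaks, meta=meta,
        expression=expression.round(6), openness=openness.round(6),
        motifs=motifs, ttf_ids=ttf_ids,
        tf_catalog=ttf_ids + tf_ids,
        rseg_ids=ttf_ids + target_ids + decoy_ids,
        truth_triplets=truth_triplets, truth_upstream=truth_upstream,
        motif_of_cne=motif_of_cne)


def make_upstream_dataset(rng: np.random.Generator, n_samples: int = 20,
                          n_terms: int = 3, n_members: int = 2,
                          noise_frac: float = 0.1
                          ) -> tuple[pd.Series, dict, dict[str, float]]:
    """A small regression instance drawn from the upstream model itself.

    Returns (ttf_expr, terms, true_betas) ready for
    :func:`cnegrn.grn.fit_upstream_model`; noise is Gaussian with sd =
    ``noise_frac`` x sd of the noise-free signal (0 => exact recovery).
    """
    samples = [f"s{i}" for i in range(n_samples)]
    terms: dict[str, tuple[pd.Series, pd.DataFrame]] = {}
    true_betas: dict[str, float] = {}
    signal = np.full(n_samples, 2.0)
    for i in range(n_terms):
        cne = f"cne{i + 1}"
        o = pd.Series(rng.lognormal(1.0, 0.6, n_samples), index=samples)
        members = pd.DataFrame(rng.lognormal(2.0, 0.5, (n_members, n_samples)),
                               index=[f"tf{i + 1}_{j}" for j in range(n_members)],
                               columns=samples)
        beta = float(rng.uniform(0.05, 0.3))
        terms[cne] = (o, members)
        true_betas[cne] = beta
        signal = signal + beta * members.sum(axis=0).to_numpy() * o.to_numpy()
    sd = noise_frac * np.std(signal)
    y = signal + (rng.normal(0, sd, n_samples) if sd > 0 else 0.0)
    return pd.Series(y, index=samples), terms, true_betas


def make_null_screen(rng: np.random.Generator, n_triplets: int,
                     n_samples: int = 13
                     ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame,
                                list[tuple[str, str, str]]]:
    """Inputs for the downstream screen in which every target is null.

    One TTF/element pair per triplet with lognormal positive profiles and a
    target drawn independently, for false-positive calibration of the
    (gamma, q) gate.
    """
    samples = [f"s{i}" for i in range(n_samples)]
    ttfs = [f"ttf{i}" for i in range(n_triplets)]
    cnes = [f"cne{i}" for i in range(n_triplets)]
    tgts = [f"tg{i}" for i in range(n_triplets)]
    ttf_expr = pd.DataFrame(rng.lognormal(2.0, 1.0, (n_triplets, n_samples)),
                            index=ttfs, columns=samples)
    opn = pd.DataFrame(rng.lognormal(1.0, 1.0, (n_triplets, n_samples)),
                       index=cnes, columns=samples)
    tgt = pd.DataFrame(rng.lognormal(2.0, 1.0, (n_triplets, n_samples)),
                       index=tgts, columns=samples)
    trips = list(zip(ttfs, cnes, tgts))
    return ttf_expr, opn, tgt, trips
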