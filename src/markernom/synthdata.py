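"""Synthetic multi-omics bundle with planted ground truth.

Emulates the statistical structure of a multi-entity tumor cohort in which
one entity overexpresses a small set of driver-regulated biomarker genes:

* bulk log2 expression (Gaussian background, planted one-vs-rest shift),
* a coexpression module tracking the anchor biomarker,
* replicate-level knockdown proteomics for two cell lines with planted
  concordant down-regulation,
* fusion-factor binding peaks placed near planted biomarker TSSs (decoys
  near unrelated genes only, so the triple intersection is decided by the
  statistics, not by construction),
* an H3K27ac enhancer peak set whose stitched signal vector has a heavy
  hockey-stick tail with planted super-enhancer regions,
* a CpG beta matrix with planted target-entity hypomethylation at the
  anchor locus,
* negative-binomial single-cell counts with the coexpression program
  elevated in tumor cells,
* an IHC cohort whose target-entity immunoreactive scores lie in the high
  range [6, 12] while mimics score near zero.

Every artifact is a deterministic function of the seed.
"""
from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (
    BED_COLUMNS,
    ExpressionMatrix,
    GeneAnnotation,
    IRSRecord,
    MethylationMatrix,
    PeakSet,
    irs_frame,
)
from . import io as mio

__all__ = [
    "TruthParams",
    "SyntheticTruth",
    "SyntheticBundle",
    "generate_multiomics",
    "generate_irs_cohort",
    "generate_methylation_cohort",
    "write_bundle",
]


@dataclass
class TruthParams:
    """Knobs of the generator; defaults are the study conditions.

    The cohort is a scaled-down mirror of a ~50-sample, genome-wide study:
    8 entities x 10 samples, 2,000 genes, two planted biomarkers with a +4
    log2 one-vs-rest shift, a 50-gene coexpression module around the anchor,
    and a -2 log2 knockdown effect on the planted proteins in both lines.
    """

    # cohort
    n_entities: int = 8
    samples_per_entity: int = 10
    n_genes: int = 2000
    target_entity: str = "DSRCT"
    # planted transcriptome truth
    n_biomarkers: int = 2
    module_size: int = 50
    expression_effect: float = 4.0        # log2 shift in the target entity
    anchor_extra_effect: float = 2.0      # additional shift of the anchor, so
                                          # prioritization is decisive
    background_mean: float = 6.0
    background_sd: float = 1.0
    module_noise_sd: float = 0.5
    # knockdown proteomics
    cell_lines: tuple[str, ...] = ("LINE_A", "LINE_B")
    n_proteins: int = 1000
    n_replicates: int = 4
    dep_effect: float = 2.0               # |log2FC| upon knockdown (down)
    kd_program_size: int = 40             # module proteins sharing the effect
    dep_background_sd: float = 0.3        # per-protein true effect noise
    dep_replicate_sd: float = 0.1
    # genome / peaks
    n_chromosomes: int = 4
    gene_spacing: int = 250_000
    gene_length: int = 10_000
    genome_offset: int = 1_000_000
    n_decoy_peaks: int = 200
    peak_width: int = 1_000
    biomarker_peak_offset: int = 5_000    # bp from TSS to the planted peak
    decoy_max_offset: int = 50_000
    # H3K27ac enhancer landscape
    n_enhancer_regions: int = 400
    n_super_planted: int = 12
    enhancer_chrom: str = "chr5"
    background_signal_scale: float = 5.0
    super_signal_range: tuple[float, float] = (80.0, 200.0)
    # methylation
    n_cpgs: int = 300
    n_anchor_cpgs: int = 12
    n_hypo_cpgs: int = 10
    beta_shift: float = 0.3
    # single cell
    n_tumor_cells: int = 200
    n_normal_cells: int = 200
    sc_dispersion: float = 0.5
    sc_program_fold: float = 8.0
    sc_base_mean: float = 0.3
    # IHC cohort
    n_irs_target: int = 61
    n_irs_mimics: int = 249
    n_irs_mimic_entities: int = 18
    irs_contamination: float = 0.02
    seed: int = 42

    def validate(self) -> None:
        if self.expression_effect < 0 or self.dep_effect < 0 \
                or self.anchor_extra_effect < 0:
            raise ValueError("effect sizes must be >= 0")
        if self.samples_per_entity < 3:
            raise ValueError("need >= 3 samples per entity")
        if self.n_biomarkers < 1:
            raise ValueError("need >= 1 planted biomarker")
        if not (0 <= self.irs_contamination < 1):
            raise ValueError("contamination must lie in [0, 1)")
        if self.n_biomarkers + self.module_size > self.n_genes:
            raise ValueError("planted genes exceed the gene universe")


@dataclass
class SyntheticTruth:
    """What was planted, for downstream recovery checks."""

    planted_biomarkers: list[str]
    anchor_gene: str
    target_entity: str
    expression_effect: float
    dep_effect: float
    coexpression_module: list[str]
    kd_program_proteins: list[str]
    hypomethylated_cpgs: list[str]
    se_regions: list[str]
    seed: int

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        return cls(**json.loads(Path(path).read_text()))


@dataclass
class SyntheticBundle:
    expression: ExpressionMatrix
    genes: GeneAnnotation
    kd_tables: dict[str, tuple[pd.DataFrame, pd.DataFrame]]
    peaks: PeakSet
    h3k27ac: PeakSet
    methylation: MethylationMatrix
    sc_counts: pd.DataFrame
    cell_labels: pd.Series
    irs_records: list[IRSRecord]
    truth: SyntheticTruth
    params: TruthParams = field(repr=False, default=None)


# --------------------------------------------------------------------------
# pieces
# --------------------------------------------------------------------------

def _gene_annotation(p: TruthParams) -> GeneAnnotation:
    ids = [f"G{i:04d}" for i in range(1, p.n_genes + 1)]
    per_chrom = -(-p.n_genes // p.n_chromosomes)
    rows = []
    for i, gid in enumerate(ids):
        chrom = f"chr{i // per_chrom + 1}"
        start = p.genome_offset + (i % per_chrom) * p.gene_spacing
        strand = "+" if i % 2 == 0 else "-"
        rows.append((gid, chrom, start, start + p.gene_length, strand))
    return GeneAnnotation(pd.DataFrame(
        rows, columns=["gene_id", "chrom", "start", "end", "strand"]))


def _expression(p: TruthParams, rng: np.random.Generator,
                gene_ids: list[str], biomarkers: list[str],
                module: list[str]) -> ExpressionMatrix:
    entities = [p.target_entity] + [f"MIMIC_{i}" for i in
                                    range(1, p.n_entities)]
    samples, labels = [], []
    for e in entities:
        for j in range(p.samples_per_entity):
            samples.append(f"{e}_S{j + 1:02d}")
            labels.append(e)
    label_s = pd.Series(labels, index=samples, name="entity")
    x = rng.normal(p.background_mean, p.background_sd,
                   (p.n_genes, len(samples)))
    values = pd.DataFrame(x, index=gene_ids, columns=samples)
    in_target = (label_s == p.target_entity).to_numpy()
    values.loc[biomarkers, in_target] += p.expression_effect
    values.loc[biomarkers[0], in_target] += p.anchor_extra_effect
    anchor = values.loc[biomarkers[0]].to_numpy()
    for g in module:
        values.loc[g] = anchor + rng.normal(0, p.module_noise_sd, len(samples))
    return ExpressionMatrix(values=values, entity_labels=label_s)


def _kd_tables(p: TruthParams, rng: np.random.Generator,
               proteins: list[str], planted: set[str],
               ) -> dict[str, tuple[pd.DataFrame, pd.DataFrame]]:
    out = {}
    planted_mask = np.array([prot in planted for prot in proteins])
    for line in p.cell_lines:
        base = rng.normal(p.background_mean, p.background_sd, len(proteins))
        effect = rng.normal(0, p.dep_background_sd, len(proteins))
        effect[planted_mask] = -p.dep_effect
        ctrl = base[:, None] + rng.normal(
            0, p.dep_replicate_sd, (len(proteins), p.n_replicates))
        kd = (base + effect)[:, None] + rng.normal(
            0, p.dep_replicate_sd, (len(proteins), p.n_replicates))
        out[line] = (
            pd.DataFrame(ctrl, index=proteins,
                         columns=[f"ctrl_{i+1}" for i in range(p.n_replicates)]),
            pd.DataFrame(kd, index=proteins,
                         columns=[f"kd_{i+1}" for i in range(p.n_replicates)]),
        )
    return out


def _fusion_peaks(p: TruthParams, rng: np.random.Generator,
                  genes: GeneAnnotation, biomarkers: list[str],
                  module: list[str]) -> PeakSet:
    gdf = genes.df.set_index("gene_id")
    rows = []
    for i, gid in enumerate(biomarkers):
        tss = int(gdf.loc[gid, "tss"])
        start = tss + p.biomarker_peak_offset
        rows.append((gdf.loc[gid, "chrom"], start, start + p.peak_width,
                     f"planted_peak_{i + 1}", float(rng.uniform(5, 20))))
    # decoys only near genes outside the planted program: module genes pass
    # the expression and proteomics gates by design, so a decoy peak there
    # would add intersection members by construction rather than chance
    forbidden = set(biomarkers) | set(module)
    eligible = [g for g in gdf.index if g not in forbidden]
    decoy_genes = rng.choice(eligible, size=min(p.n_decoy_peaks, len(eligible)),
                             replace=False)
    offsets = rng.integers(-p.decoy_max_offset, p.decoy_max_offset,
                           len(decoy_genes))
    for i, (gid, off) in enumerate(zip(decoy_genes, offsets)):
        tss = int(gdf.loc[gid, "tss"])
        start = max(0, tss + int(off))
        rows.append((gdf.loc[gid, "chrom"], start, start + p.peak_width,
                     f"decoy_peak_{i + 1}", float(rng.uniform(1, 10))))
    return PeakSet(pd.DataFrame(rows, columns=BED_COLUMNS)).sorted()


def _h3k27ac(p: TruthParams, rng: np.random.Generator,
             ) -> tuple[PeakSet, list[str]]:
    """Clustered enhancer peaks; returns the peak set and the stitched
    region ids of the planted super-enhancers."""
    super_idx = set(rng.choice(p.n_enhancer_regions, p.n_super_planted,
                               replace=False).tolist())
    rows, se_ids = [], []
    spacing = 50_000
    width, step = 2_000, 3_000
    for r in range(p.n_enhancer_regions):
        base = p.genome_offset + r * spacing
        n_peaks = int(rng.integers(1, 4))
        if r in super_idx:
            total = float(rng.uniform(*p.super_signal_range))
        else:
            total = float(rng.exponential(p.background_signal_scale) + 1.0)
        shares = rng.dirichlet(np.ones(n_peaks))
        for j in range(n_peaks):
            s = base + j * step
            rows.append((p.enhancer_chrom, s, s + width,
                         f"enh_{r + 1}_{j + 1}", float(total * shares[j])))
        region_end = base + (n_peaks - 1) * step + width
        if r in super_idx:
            se_ids.append(f"{p.enhancer_chrom}:{base}-{region_end}")
    return PeakSet(pd.DataFrame(rows, columns=BED_COLUMNS)), sorted(se_ids)


def _beta_from_gaussian(rng: np.random.Generator, shape: tuple[int, ...],
                        loc: float = 0.6, scale: float = 0.5) -> np.ndarray:
    z = rng.normal(loc, scale, shape)
    return 1.0 / (1.0 + np.exp(-z))


def _methylation(p: TruthParams, rng: np.random.Generator,
                 genes: GeneAnnotation, anchor_gene: str,
                 labels: pd.Series) -> tuple[MethylationMatrix, list[str]]:
    gdf = genes.df.set_index("gene_id")
    a_chrom = gdf.loc[anchor_gene, "chrom"]
    a_start, a_end = int(gdf.loc[anchor_gene, "start"]), int(
        gdf.loc[anchor_gene, "end"])
    anchor_pos = np.sort(rng.choice(
        np.arange(a_start, a_end), p.n_anchor_cpgs, replace=False))
    other_genes = rng.choice([g for g in gdf.index if g != anchor_gene],
                             p.n_cpgs - p.n_anchor_cpgs, replace=True)
    rows = [("cg%05d" % (i + 1), a_chrom, int(pos))
            for i, pos in enumerate(anchor_pos)]
    for j, g in enumerate(other_genes):
        pos = int(gdf.loc[g, "start"]) + int(rng.integers(0, p.gene_length))
        rows.append(("cg%05d" % (p.n_anchor_cpgs + j + 1),
                     gdf.loc[g, "chrom"], pos))
    coords = pd.DataFrame(rows, columns=["cpg_id", "chrom", "position"])
    hypo = sorted(rng.choice(coords["cpg_id"][:p.n_anchor_cpgs],
                             p.n_hypo_cpgs, replace=False).tolist())
    beta = _beta_from_gaussian(rng, (p.n_cpgs, len(labels)))
    beta = pd.DataFrame(beta, index=coords["cpg_id"].to_numpy(),
                        columns=labels.index)
    in_target = (labels == p.target_entity).to_numpy()
    beta.loc[hypo, in_target] = np.clip(
        beta.loc[hypo, in_target] - p.beta_shift, 0.0, 1.0)
    return MethylationMatrix(beta=beta, coords=coords,
                             entity_labels=labels.copy()), hypo


def _single_cell(p: TruthParams, rng: np.random.Generator,
                 gene_ids: list[str], program: list[str],
                 ) -> tuple[pd.DataFrame, pd.Series]:
    n_cells = p.n_tumor_cells + p.n_normal_cells
    cells = ([f"T{i + 1:04d}" for i in range(p.n_tumor_cells)]
             + [f"N{i + 1:04d}" for i in range(p.n_normal_cells)])
    labels = pd.Series(["tumor"] * p.n_tumor_cells
                       + ["normal"] * p.n_normal_cells,
                       index=cells, name="cell_type")
    mu = rng.lognormal(np.log(p.sc_base_mean), 1.0, len(gene_ids))
    mu_mat = np.tile(mu[:, None], (1, n_cells))
    prog_mask = np.isin(gene_ids, program)
    mu_mat[np.ix_(prog_mask, np.arange(p.n_tumor_cells))] *= p.sc_program_fold
    r = 1.0 / p.sc_dispersion
    counts = rng.negative_binomial(r, r / (r + mu_mat))
    return pd.DataFrame(counts, index=gene_ids, columns=cells), labels


# factorizations irs -> feasible (intensity, category) pairs
_FACTORS = {
    s: [(i, c) for i in range(1, 4) for c in range(1, 5) if i * c == s]
    for s in range(1, 13)
}
# sample a percent-positive value inside a proportion-category band
_BAND_RANGES = {1: (1.0, 9.0), 2: (10.0, 50.0), 3: (51.0, 80.0),
                4: (81.0, 100.0)}


def _record_with_irs(rng: np.random.Generator, sample_id: str, entity: str,
                     irs: int) -> IRSRecord:
    if irs == 0:
        return IRSRecord(sample_id, entity, intensity=int(rng.integers(0, 2)),
                         percent_positive=0.0)
    intensity, cat = _FACTORS[irs][int(rng.integers(len(_FACTORS[irs])))]
    lo, hi = _BAND_RANGES[cat]
    return IRSRecord(sample_id, entity, intensity=intensity,
                     percent_positive=float(np.round(rng.uniform(lo, hi), 1)))


def generate_irs_cohort(n_target: int = 61, n_mimics: int = 249,
                        contamination: float = 0.02, seed: int = 7,
                        n_mimic_entities: int = 18,
                        target_entity: str = "DSRCT") -> list[IRSRecord]:
    """IHC cohort: target-entity scores uniform over {6, 8, 9, 12}, mimics
    scoring 0-1 except a ``contamination`` fraction scoring 2-4."""
    if n_target < 1 or n_mimics < 1:
        raise ValueError("cohort sizes must be >= 1")
    if not (0 <= contamination < 1):
        raise ValueError("contamination must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    records = []
    high_scores = np.array([6, 8, 9, 12])
    for i in range(n_target):
        irs = int(high_scores[rng.integers(len(high_scores))])
        records.append(_record_with_irs(rng, f"{target_entity}_{i + 1:03d}",
                                        target_entity, irs))
    for i in range(n_mimics):
        entity = f"MIMIC_{i % n_mimic_entities + 1:02d}"
        if rng.random() < contamination:
            irs = int(rng.integers(2, 5))
        else:
            irs = int(rng.random() < 0.1)    # mostly 0, occasionally 1
        records.append(_record_with_irs(rng, f"{entity}_{i + 1:03d}",
                                        entity, irs))
    return records


def generate_methylation_cohort(n_target: int = 24, n_mimics: int = 192,
                                n_mimic_entities: int = 13, seed: int = 0,
                                params: TruthParams | None = None,
                                ) -> tuple[MethylationMatrix, list[str], str]:
    """Standalone beta-value cohort with planted target hypomethylation.

    Mirrors the methylation comparison of a small target cohort against a
    large mimic panel. Returns (matrix, hypomethylated CpG ids, anchor gene).
    """
    p = params or TruthParams(seed=seed)
    rng = np.random.default_rng(seed)
    genes = _gene_annotation(p)
    anchor = genes.df["gene_id"].iloc[int(rng.integers(p.n_genes))]
    samples = [f"{p.target_entity}_M{i + 1:03d}" for i in range(n_target)]
    entities = [p.target_entity] * n_target
    for i in range(n_mimics):
        entity = f"MIMIC_{i % n_mimic_entities + 1:02d}"
        samples.append(f"{entity}_M{i + 1:03d}")
        entities.append(entity)
    labels = pd.Series(entities, index=samples, name="entity")
    meth, hypo = _methylation(p, rng, genes, anchor, labels)
    return meth, hypo, anchor


def generate_multiomics(params: TruthParams | None = None,
                        seed: int | None = None) -> SyntheticBundle:
    """Generate the full multi-omics bundle; deterministic given the seed."""
    p = params or TruthParams()
    if seed is not None:
        p = TruthParams(**{**asdict(p), "seed": seed})
    p.validate()
    rng = np.random.default_rng(p.seed)
    genes = _gene_annotation(p)
    gene_ids = genes.df["gene_id"].tolist()

    chosen = rng.choice(gene_ids, p.n_biomarkers + p.module_size,
                        replace=False)
    biomarkers = sorted(chosen[:p.n_biomarkers].tolist())
    module = sorted(chosen[p.n_biomarkers:].tolist())
    anchor = biomarkers[0]

    expression = _expression(p, rng, gene_ids, biomarkers, module)

    kd_program = sorted(rng.choice(module, min(p.kd_program_size,
                                               len(module)),
                                   replace=False).tolist())
    planted_proteins = set(biomarkers) | set(kd_program)
    background_pool = [g for g in gene_ids if g not in planted_proteins]
    proteins = sorted(
        list(planted_proteins)
        + rng.choice(background_pool,
                     p.n_proteins - len(planted_proteins),
                     replace=False).tolist())
    kd_tables = _kd_tables(p, rng, proteins, planted_proteins)

    peaks = _fusion_peaks(p, rng, genes, biomarkers, module)
    h3k27ac, se_ids = _h3k27ac(p, rng)
    methylation, hypo = _methylation(p, rng, genes, anchor,
                                     expression.entity_labels)
    sc_counts, cell_labels = _single_cell(p, rng, gene_ids,
                                          module + biomarkers)
    irs_records = generate_irs_cohort(
        p.n_irs_target, p.n_irs_mimics, p.irs_contamination,
        seed=int(rng.integers(2 ** 31)),
        n_mimic_entities=p.n_irs_mimic_entities,
        target_entity=p.target_entity)

    truth = SyntheticTruth(
        planted_biomarkers=biomarkers,
        anchor_gene=anchor,
        target_entity=p.target_entity,
        expression_effect=p.expression_effect,
        dep_effect=p.dep_effect,
        coexpression_module=module,
        kd_program_proteins=kd_program,
        hypomethylated_cpgs=hypo,
        se_regions=se_ids,
        seed=p.seed,
    )
    return SyntheticBundle(
        expression=expression, genes=genes, kd_tables=kd_tables, peaks=peaks,
        h3k27ac=h3k27ac, methylation=methylation, sc_counts=sc_counts,
        cell_labels=cell_labels, irs_records=irs_records, truth=truth,
        params=p)


def write_bundle(bundle: SyntheticBundle, outdir: str | Path) -> None:
    """Serialize the bundle as plain-text files a fresh pipeline run can read."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    mio.write_expression_matrix(bundle.expression, out / "expression.tsv",
                                out / "labels.tsv")
    mio.write_gene_annotation(bundle.genes, out / "genes.tsv")
    for line, (ctrl, kd) in bundle.kd_tables.items():
        mio.write_kd_table(ctrl, kd, out / f"kd_{line}.tsv")
    mio.write_bed(bundle.peaks, out / "peaks.bed")
    mio.write_bed(bundle.h3k27ac, out / "h3k27ac.bed")
    mio.write_methylation(bundle.methylation, out / "beta.tsv",
                          out / "cpg_annotation.bed", out / "meth_labels.tsv")
    bundle.sc_counts.to_csv(out / "sc_counts.tsv", sep="\t",
                            index_label="gene")
    bundle.cell_labels.rename("entity").rename_axis("sample").to_csv(
        out / "cell_labels.tsv", sep="\t")
    irs_frame(bundle.irs_records).to_csv(out / "irs.tsv", sep="\t",
                                         index=False)
    bundle.truth.to_json(out / "truth.json")
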