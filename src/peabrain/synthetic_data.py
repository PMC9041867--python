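"""Synthetic study worlds written as standard FASTA/TSV/BED/VCF files, with
exported ground truth for recovery tests.

Two worlds are generated:

* **Stage-1 world** — a toy genome of promoter windows in which each gene's
  mean expression is determined by the number of planted copies of a
  regulatory motif plus the state of an annotated enhancer interval, with
  configurable Gaussian noise.  Planted motifs are marked in a BED track
  (the class-B annotation analogue), and a second BED track carries the
  enhancer state, which is *only* visible through annotation channels.
* **Stage-2 world** — a single-gene window and a cohort of unrelated
  individuals with Hardy-Weinberg genotypes at biallelic SNPs, a subset of
  which are causal with linear effects on expression.

Both are deterministic given the seed; re-running with the same parameters
reproduces byte-identical files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genome_io import (AnnotationTrack, GeneModel, load_gene_models,
                        reverse_complement)

__all__ = ["Stage1World", "Stage2World", "make_stage1_world",
           "make_stage2_world", "read_fasta", "count_motif"]

_BASES = np.array(list("ACGT"))


def read_fasta(path) -> dict:
    """Plain FASTA reader returning chrom -> uppercase sequence string."""
    seqs = {}
    name, chunks = None, []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                if name is not None:
                    seqs[name] = "".join(chunks).upper()
                name = line[1:].split()[0]
                chunks = []
            elif line:
                chunks.append(line)
    if name is not None:
        seqs[name] = "".join(chunks).upper()
    return seqs


def _write_fasta(path, seqs, width=80):
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def count_motif(seq: str, motif: str) -> int:
    """Overlap-counting scan for motif occurrences in a string."""
    count = start = 0
    while True:
        hit = seq.find(motif, start)
        if hit < 0:
            return count
        count += 1
        start = hit + 1


@dataclass
class Stage1World:
    directory: Path
    genome_path: Path
    genes_path: Path
    motif_bed: Path
    enhancer_bed: Path
    means_path: Path
    truth_path: Path
    motif: str
    halfwidth: int
    seed: int

    def load_genome(self):
        return read_fasta(self.genome_path)

    def load_genes(self):
        return load_gene_models(self.genes_path)

    def load_tracks(self):
        return [AnnotationTrack.from_bed(self.motif_bed, name="motif_mark"),
                AnnotationTrack.from_bed(self.enhancer_bed, name="enhancer")]

    def load_means(self) -> pd.DataFrame:
        return pd.read_csv(self.means_path, sep="\t", index_col=0)

    def load_truth(self) -> pd.DataFrame:
        return pd.read_csv(self.truth_path, sep="\t", index_col=0)


def make_stage1_world(out_dir, n_genes: int = 500, halfwidth: int = 2000,
                      motif: str = "TGACGTCA", motif_effect: float = 1.0,
                      enhancer_effect: float = 1.0, sigma: float = 0.25,
                      max_motifs: int = 4, enhancer_prob: float = 0.5,
                      neg_strand_fraction: float = 0.5,
                      seed: int = 0) -> Stage1World:
    """Write a Stage-1 world to ``out_dir``.

    Mean expression for gene g is
    ``motif_effect * (motif count in promoter) + enhancer_effect * e_g +
    Normal(0, sigma)`` where ``e_g`` indicates an annotated enhancer
    interval.  The truth table records the *realized* motif count (a
    brute-force scan of the emitted promoter, so chance occurrences in the
    random background are included), the enhancer state and the noiseless
    mean.
    """
    if n_genes < 20:
        raise ValueError("need at least 20 genes")
    if len(motif) > 2 * halfwidth:
        raise ValueError("motif longer than the promoter window")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    window = 2 * halfwidth
    gap = 200
    slot = window + gap
    chrom = "chr1"
    chrom_len = n_genes * slot + gap
    genome = rng.choice(4, size=chrom_len)
    seq = np.array(list("ACGT"))[genome]

    genes, motif_ivs, enh_ivs, truth_rows = [], [], [], []
    enh_len = 200
    for g in range(n_genes):
        gene_id = f"G{g:04d}"
        win_start = gap // 2 + g * slot
        strand = "-" if rng.random() < neg_strand_fraction else "+"
        tss0 = win_start + halfwidth
        # plant motifs at non-overlapping oriented offsets
        n_plant = int(rng.integers(0, max_motifs + 1))
        taken = []
        for _ in range(n_plant):
            for _attempt in range(50):
                off = int(rng.integers(0, window - len(motif) + 1))
                if all(abs(off - t) >= len(motif) for t in taken):
                    taken.append(off)
                    break
        for off in taken:
            if strand == "+":
                s = win_start + off
                planted = motif
            else:
                # oriented offset measured from the right-hand genomic edge
                s = win_start + window - off - len(motif)
                planted = reverse_complement(motif)
            seq[s:s + len(motif)] = list(planted)
            motif_ivs.append((chrom, s, s + len(motif)))
        has_enh = rng.random() < enhancer_prob
        if has_enh:
            e_off = int(rng.integers(0, window - enh_len + 1))
            e_start = win_start + e_off
            enh_ivs.append((chrom, e_start, e_start + enh_len))
        genes.append((gene_id, chrom, tss0 + 1, strand))
        truth_rows.append((gene_id, int(has_enh), n_plant))

    full_seq = "".join(seq)
    _write_fasta(out / "genome.fa", {chrom: full_seq})
    genes_df = pd.DataFrame(genes, columns=["gene_id", "chrom", "tss", "strand"])
    genes_df["biotype"] = "protein_coding"
    genes_df.to_csv(out / "genes.tsv", sep="\t", index=False)
    for name, ivs in (("motif.bed", motif_ivs), ("enhancer.bed", enh_ivs)):
        with open(out / name, "w") as fh:
            for c, s, e in sorted(ivs):
                fh.write(f"{c}\t{s}\t{e}\n")

    # realized motif counts from a scan of the emitted promoters
    truth = []
    for (gene_id, chrom_, tss, strand), (_, has_enh, n_plant) in zip(genes, truth_rows):
        start = tss - 1 - halfwidth
        prom = full_seq[start:start + window]
        if strand == "-":
            prom = reverse_complement(prom)
        count = count_motif(prom, motif)
        mean0 = motif_effect * count + enhancer_effect * has_enh
        truth.append((gene_id, count, n_plant, has_enh, mean0))
    truth_df = pd.DataFrame(truth, columns=["gene_id", "motif_count",
                                            "planted_count", "enhancer",
                                            "mean_noiseless"]).set_index("gene_id")
    noise = rng.normal(0, sigma, size=n_genes) if sigma > 0 else np.zeros(n_genes)
    means = truth_df["mean_noiseless"].values + noise
    pd.DataFrame({"mean_rpkm": means}, index=truth_df.index)\
        .to_csv(out / "means.tsv", sep="\t")
    truth_df.to_csv(out / "truth.tsv", sep="\t")
    return Stage1World(directory=out, genome_path=out / "genome.fa",
                       genes_path=out / "genes.tsv",
                       motif_bed=out / "motif.bed",
                       enhancer_bed=out / "enhancer.bed",
                       means_path=out / "means.tsv",
                       truth_path=out / "truth.tsv", motif=motif,
                       halfwidth=halfwidth, seed=seed)


@dataclass
class Stage2World:
    directory: Path
    genome_path: Path
    vcf_path: Path
    expression_path: Path
    truth_path: Path
    gene: GeneModel
    window: int
    individual_ids: list
    seed: int

    def load_genome(self):
        return read_fasta(self.genome_path)

    def load_expression(self) -> pd.Series:
        df = pd.read_csv(self.expression_path, sep="\t", index_col=0)
        return df.iloc[0]

    def load_truth(self) -> pd.DataFrame:
        return pd.read_csv(self.truth_path, sep="\t")


def make_stage2_world(out_dir, n_individuals: int = 60, window: int = 10000,
                      m_variants: int = 50, c_causal: int = 5,
                      beta_scale: float = 0.5, sigma: float = 0.1,
                      maf_range=(0.05, 0.5), seed: int = 0) -> Stage2World:
    """Write a Stage-2 world to ``out_dir``.

    One gene with TSS at the centre of a ``window``-bp region; ``m_variants``
    biallelic SNPs at distinct positions with minor-allele frequencies drawn
    uniformly from ``maf_range`` and Hardy-Weinberg genotypes; ``c_causal``
    of them carry effects beta ~ Normal(0, beta_scale).  Expression is
    ``sum_j beta_j * dosage_ij + Normal(0, sigma)``.
    """
    if n_individuals < 20:
        raise ValueError("need at least 20 individuals")
    if not 1 <= c_causal <= m_variants:
        raise ValueError("need m_variants >= c_causal >= 1")
    lo, hi = maf_range
    if not 0 < lo <= hi <= 0.5:
        raise ValueError("allele frequencies must lie in (0, 0.5]")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    chrom = "chr1"
    margin = 100
    chrom_len = window + 2 * margin
    seq = _BASES[rng.choice(4, size=chrom_len)]
    tss0 = margin + window // 2
    gene = GeneModel(gene_id="G0000", chrom=chrom, tss=tss0 + 1, strand="+")

    positions = np.sort(rng.choice(
        np.arange(margin, margin + window), size=m_variants, replace=False))
    mafs = rng.uniform(lo, hi, size=m_variants)
    refs = [seq[p] for p in positions]
    alts = []
    for p in positions:
        others = [b for b in "ACGT" if b != seq[p]]
        alts.append(others[int(rng.integers(0, 3))])
    # Hardy-Weinberg genotypes: two independent allele draws per individual
    alleles = rng.random((n_individuals, m_variants, 2)) < mafs[None, :, None]
    dosages = alleles.sum(axis=2)  # individuals x variants in {0,1,2}

    causal_idx = np.sort(rng.choice(m_variants, size=c_causal, replace=False))
    betas = np.zeros(m_variants)
    betas[causal_idx] = rng.normal(0, beta_scale, size=c_causal)
    noise = rng.normal(0, sigma, size=n_individuals) if sigma > 0 else 0.0
    expression = dosages @ betas + noise

    ids = [f"IND{i:03d}" for i in range(n_individuals)]
    _write_fasta(out / "genome.fa", {chrom: "".join(seq)})
    with open(out / "cohort.vcf", "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={chrom},length={chrom_len}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(ids) + "\n")
        for j, p in enumerate(positions):
            gts = []
            for i in range(n_individuals):
                a, b = alleles[i, j]
                gts.append(f"{int(a)}/{int(b)}")
            fh.write(f"{chrom}\t{p + 1}\tv{j}\t{refs[j]}\t{alts[j]}\t.\tPASS"
                     f"\t.\tGT\t" + "\t".join(gts) + "\n")
    pd.DataFrame([expression], index=[gene.gene_id], columns=ids)\
        .to_csv(out / "expression.tsv", sep="\t")
    truth = pd.DataFrame({
        "variant_id": [f"v{j}" for j in range(m_variants)],
        "chrom": chrom, "pos": positions + 1, "ref": refs, "alt": alts,
        "maf": mafs, "beta": betas, "causal": betas != 0})
    truth.to_csv(out / "truth.tsv", sep="\t", index=False)
    return Stage2World(directory=out, genome_path=out / "genome.fa",
                       vcf_path=out / "cohort.vcf",
                       expression_path=out / "expression.tsv",
                       truth_path=out / "truth.tsv", gene=gene,
                       window=window, individual_ids=ids, seed=seed)
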