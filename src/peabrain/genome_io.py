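"""Genome, gene-model, annotation, variant and expression-table I/O, and the
encoded sequence tensors consumed by the models.

Conventions used throughout the package:

* coordinates are 0-based half-open internally; VCF positions (1-based) and a
  gene model's TSS (1-based) are converted at the boundary; BED is native
  0-based half-open;
* DNA channel order is fixed to A, C, G, T; an N base encodes as an all-zero
  DNA column;
* negative-strand promoters are reverse-complemented so that transcription
  always proceeds left-to-right in the matrix ("upstream" is matrix-left),
  and annotation channels are flipped together with the sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DNA_CHANNELS = ("A", "C", "G", "T")
_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GeneModel:
    """A gene anchored at its transcription start site.

    ``tss`` is 1-based genomic; ``strand`` is '+' or '-'.
    """

    gene_id: str
    chrom: str
    tss: int
    strand: str
    biotype: str = "protein_coding"

    def __post_init__(self):
        if self.tss < 1:
            raise ValueError(f"{self.gene_id}: tss must be >= 1")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")


def load_gene_models(path) -> list[GeneModel]:
    """Read gene models from a tab-separated table with columns
    gene_id, chrom, tss, strand (and optionally biotype)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    genes = []
    for row in df.itertuples(index=False):
        genes.append(GeneModel(
            gene_id=row.gene_id, chrom=str(row.chrom), tss=int(row.tss),
            strand=row.strand,
            biotype=getattr(row, "biotype", "protein_coding")))
    ids = [g.gene_id for g in genes]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate gene_id in gene model table")
    return genes


def _merge_intervals(intervals):
    merged = {}
    by_chrom = {}
    for chrom, start, end in intervals:
        if end <= start:
            raise ValueError(f"empty interval {chrom}:{start}-{end}")
        by_chrom.setdefault(chrom, []).append((int(start), int(end)))
    for chrom, ivs in by_chrom.items():
        ivs.sort()
        out = [list(ivs[0])]
        for s, e in ivs[1:]:
            if s <= out[-1][1]:
                out[-1][1] = max(out[-1][1], e)
            else:
                out.append([s, e])
        merged[chrom] = [tuple(iv) for iv in out]
    return merged


@dataclass
class AnnotationTrack:
    """A named set of genomic intervals (0-based half-open), stored merged
    and non-overlapping per chromosome."""

    name: str
    intervals: dict = field(default_factory=dict)

    @classmethod
    def from_intervals(cls, name, intervals):
        return cls(name=name, intervals=_merge_intervals(intervals))

    @classmethod
    def from_bed(cls, path, name=None):
        ivs = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                chrom, start, end = line.split("\t")[:3]
                ivs.append((chrom, int(start), int(end)))
        if name is None:
            name = str(path)
        return cls.from_intervals(name, ivs)

    def mask(self, chrom, start, end) -> np.ndarray:
        """Boolean per-base membership over [start, end) in genome space."""
        out = np.zeros(end - start, dtype=bool)
        for s, e in self.intervals.get(chrom, []):
            lo, hi = max(s, start), min(e, end)
            if lo < hi:
                out[lo - start:hi - start] = True
        return out


@dataclass
class EncodedSequence:
    """Position x channel matrix for one gene window.

    The first four channels are the DNA letters A, C, G, T; the remainder are
    annotation channels.  Row 0 is the transcriptionally-upstream end of the
    window (for '-' strand genes that is the right-hand genomic edge).
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    anchor: int  # 0-based genomic TSS position
    strand: str
    matrix: np.ndarray
    channel_names: tuple

    def __post_init__(self):
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("encoded matrix contains non-finite values")

    @property
    def length(self):
        return self.matrix.shape[0]

    def genomic_position(self, offset: int) -> int:
        """Map a matrix row offset back to a 0-based genomic position."""
        if not 0 <= offset < self.length:
            raise IndexError(f"offset {offset} outside window of length {self.length}")
        if self.strand == "+":
            return self.start + offset
        return self.end - 1 - offset


def load_genome(path):
    """Open an (indexed) FASTA for random access via pyfaidx; the returned
    object serves as the reference-sequence source for all extraction
    functions (a plain ``{chrom: sequence}`` mapping works too)."""
    from pyfaidx import Fasta

    return Fasta(str(path), sequence_always_upper=True)


def _fetch(genome, chrom, start, end) -> str:
    """Fetch [start, end) (0-based) from a pyfaidx.Fasta or a plain mapping
    of chromosome name to sequence string."""
    try:
        record = genome[chrom]
    except KeyError as exc:
        raise KeyError(f"unknown chromosome {chrom!r}") from exc
    chunk = record[start:end]
    seq = chunk if isinstance(chunk, str) else chunk.seq
    return seq.upper()


def _chrom_length(genome, chrom):
    record = genome[chrom]
    return len(record)


def extract_promoter_window(gene: GeneModel, genome, halfwidth: int,
                            clip: bool = False):
    """Extract the core promoter window of ``2*halfwidth`` bp centred on the
    TSS, oriented so transcription proceeds left to right.

    Returns ``(seq, (chrom, start, end))`` with the window reported in genome
    space.  Windows running off a chromosome end raise unless ``clip`` is
    set, in which case the missing flank is filled with N.
    """
    tss0 = gene.tss - 1
    start, end = tss0 - halfwidth, tss0 + halfwidth
    chrom_len = _chrom_length(genome, gene.chrom)
    if start < 0 or end > chrom_len:
        if not clip:
            raise ValueError(
                f"{gene.gene_id}: window [{start},{end}) outside chromosome "
                f"{gene.chrom} of length {chrom_len}")
        left_pad = max(0, -start)
        right_pad = max(0, end - chrom_len)
        seq = "N" * left_pad + _fetch(genome, gene.chrom, max(0, start),
                                      min(end, chrom_len)) + "N" * right_pad
    else:
        seq = _fetch(genome, gene.chrom, start, end)
    if gene.strand == "-":
        seq = reverse_complement(seq)
    return seq, (gene.chrom, start, end)


def one_hot_encode(seq: str, tracks=(), window=None, strand="+",
                   gene_id="", anchor=None) -> EncodedSequence:
    """One-hot encode a DNA string plus binary annotation channels.

    ``seq`` must already be oriented (upstream first); ``window`` gives the
    genome-space coordinates ``(chrom, start, end)`` the string came from.
    Annotation channels are computed in genome space and flipped for '-'
    strand genes together with the sequence.
    """
    if window is None:
        window = ("", 0, len(seq))
    chrom, start, end = window
    if len(seq) != end - start:
        raise ValueError(f"sequence length {len(seq)} != window length {end - start}")
    seq = seq.upper()
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"non-DNA characters in sequence: {sorted(bad)}")
    L = len(seq)
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    mat = np.zeros((L, 4 + len(tracks)), dtype=np.float32)
    for j, base in enumerate(DNA_CHANNELS):
        mat[:, j] = arr == ord(base)
    names = list(DNA_CHANNELS)
    for j, track in enumerate(tracks):
        mask = track.mask(chrom, start, end)
        if strand == "-":
            mask = mask[::-1]
        mat[:, 4 + j] = mask
        names.append(track.name)
    if anchor is None:
        anchor = (start + end) // 2
    return EncodedSequence(gene_id=gene_id, chrom=chrom, start=start, end=end,
                           anchor=anchor, strand=strand, matrix=mat,
                           channel_names=tuple(names))


def encode_gene(gene: GeneModel, genome, halfwidth: int, tracks=(),
                clip: bool = False) -> EncodedSequence:
    """Convenience wrapper: extract the promoter window and encode it."""
    seq, window = extract_promoter_window(gene, genome, halfwidth, clip=clip)
    return one_hot_encode(seq, tracks=tracks, window=window,
                          strand=gene.strand, gene_id=gene.gene_id,
                          anchor=gene.tss - 1)


@dataclass(frozen=True)
class VariantCall:
    """One biallelic variant call for one individual.

    ``pos`` is 1-based (VCF convention); ``gt`` is the pair of allele
    indices (0 = ref, 1 = alt); ``phased`` marks whether the pair is ordered.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    gt: tuple
    phased: bool = False


def _haplotype_alleles(call: VariantCall):
    """Assign the two alleles to haplotypes.  Unphased heterozygotes place
    the alt allele on haplotype 1 deterministically; the diploid channel sum
    is invariant to this choice."""
    a1, a2 = call.gt
    if call.phased:
        return a1, a2
    if a1 + a2 == 1:
        return 1, 0
    return a1, a2


def _apply_variants(ref_seq: str, seg_start: int, calls, hap_index: int) -> str:
    """Substitute one haplotype's alt alleles into ``ref_seq`` (which covers
    genome positions [seg_start, seg_start+len))."""
    chosen = []
    for call in calls:
        alleles = _haplotype_alleles(call)
        if alleles[hap_index] == 1:
            chosen.append(call)
    chosen.sort(key=lambda c: c.pos)
    out = []
    cursor = 0
    last_end = -1
    for call in chosen:
        p0 = call.pos - 1 - seg_start
        if p0 < last_end:
            raise ValueError(f"overlapping variant records at position {call.pos}")
        observed = ref_seq[p0:p0 + len(call.ref)]
        if observed != call.ref.upper():
            raise ValueError(
                f"reference mismatch at {call.chrom}:{call.pos}: VCF ref "
                f"{call.ref!r} vs genome {observed!r}")
        out.append(ref_seq[cursor:p0])
        out.append(call.alt.upper())
        cursor = p0 + len(call.ref)
        last_end = cursor
    out.append(ref_seq[cursor:])
    return "".join(out)


def reconstruct_haplotypes(gene: GeneModel, genome, calls, halfwidth: int):
    """Rebuild an individual's two promoter-window haplotype strings.

    Each haplotype equals the reference window with that haplotype's
    alternate alleles substituted.  Indels change segment length, so each
    flank is re-anchored at the TSS: truncated or N-padded at its outer edge
    back to ``halfwidth``.  Output strings are oriented like
    :func:`extract_promoter_window` (upstream first).
    """
    tss0 = gene.tss - 1
    start, end = tss0 - halfwidth, tss0 + halfwidth
    for call in calls:
        if call.chrom != gene.chrom:
            raise ValueError(f"variant on {call.chrom} outside gene chromosome")
        if not (start < call.pos <= end):
            raise ValueError(
                f"variant at {call.pos} outside window [{start + 1},{end}]")
        if call.pos - 1 < tss0 and call.pos - 1 + len(call.ref) > tss0:
            raise ValueError(
                f"variant at {call.pos} spans the TSS anchor; unsupported")
    left_ref = _fetch(genome, gene.chrom, start, tss0)
    right_ref = _fetch(genome, gene.chrom, tss0, end)
    left_calls = [c for c in calls if c.pos - 1 < tss0]
    right_calls = [c for c in calls if c.pos - 1 >= tss0]
    haps = []
    for h in (0, 1):
        left = _apply_variants(left_ref, start, left_calls, h)
        right = _apply_variants(right_ref, tss0, right_calls, h)
        left = ("N" * max(0, halfwidth - len(left)) + left)[-halfwidth:]
        right = (right + "N" * max(0, halfwidth - len(right)))[:halfwidth]
        hap = left + right
        if gene.strand == "-":
            hap = reverse_complement(hap)
        haps.append(hap)
    return haps[0], haps[1]


def encode_diploid(hap1: str, hap2: str, tracks=(), window=None, strand="+",
                   gene_id="", anchor=None) -> EncodedSequence:
    """Sum of the one-hot encodings of the two haplotypes: DNA column sums
    are 2 except at N bases; invariant to swapping the haplotypes."""
    if len(hap1) != len(hap2):
        raise ValueError("haplotype length mismatch")
    e1 = one_hot_encode(hap1, tracks=tracks, window=window, strand=strand,
                        gene_id=gene_id, anchor=anchor)
    e2 = one_hot_encode(hap2, tracks=tracks, window=window, strand=strand,
                        gene_id=gene_id, anchor=anchor)
    e1.matrix = e1.matrix + e2.matrix
    return e1


def difference_sequence(a: EncodedSequence, b: EncodedSequence) -> EncodedSequence:
    """Element-wise difference a - b of two (diploid) encodings of the same
    window; the Stage-2 model input."""
    if a.matrix.shape != b.matrix.shape or a.channel_names != b.channel_names:
        raise ValueError("shape/channel mismatch between encoded sequences")
    if (a.chrom, a.start, a.end) != (b.chrom, b.start, b.end):
        raise ValueError("window mismatch between encoded sequences")
    return EncodedSequence(gene_id=a.gene_id, chrom=a.chrom, start=a.start,
                           end=a.end, anchor=a.anchor, strand=a.strand,
                           matrix=a.matrix - b.matrix,
                           channel_names=a.channel_names)


def load_cohort_calls(vcf_path, chrom=None, start=None, end=None):
    """Read per-individual variant calls from a VCF.

    Returns ``(individual_ids, calls)`` where ``calls[sample_id]`` is a list
    of :class:`VariantCall`.  Only biallelic records are supported; records
    with missing genotypes are treated as homozygous reference.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    calls = {s: [] for s in samples}
    for rec in vcf:
        if chrom is not None and rec.CHROM != chrom:
            continue
        if start is not None and not (start < rec.POS <= end):
            continue
        if len(rec.ALT) != 1:
            raise ValueError(
                f"multi-allelic record at {rec.CHROM}:{rec.POS}; split first")
        for i, s in enumerate(samples):
            g = rec.genotypes[i]
            a1 = max(g[0], 0)
            a2 = max(g[1], 0)
            if a1 or a2:
                calls[s].append(VariantCall(
                    chrom=rec.CHROM, pos=rec.POS, ref=rec.REF,
                    alt=rec.ALT[0], gt=(a1, a2), phased=bool(g[2])))
    return samples, calls


def load_dosage_matrix(vcf_path, chrom=None, start=None, end=None):
    """Individuals x variants matrix of alternate-allele counts {0,1,2},
    plus a variant metadata frame (chrom, pos, ref, alt)."""
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    rows, meta = [], []
    for rec in vcf:
        if chrom is not None and rec.CHROM != chrom:
            continue
        if start is not None and not (start < rec.POS <= end):
            continue
        if len(rec.ALT) != 1:
            raise ValueError(
                f"multi-allelic record at {rec.CHROM}:{rec.POS}; split first")
        dos = [max(g[0], 0) + max(g[1], 0) for g in rec.genotypes]
        rows.append(dos)
        meta.append((rec.CHROM, rec.POS, rec.REF, rec.ALT[0]))
    dosages = np.array(rows, dtype=np.float64).T if rows else np.zeros((len(samples), 0))
    meta = pd.DataFrame(meta, columns=["chrom", "pos", "ref", "alt"])
    return samples, dosages, meta


def cohort_diploid_encodings(vcf_path, gene: GeneModel, genome,
                             halfwidth: int, tracks=()) -> dict:
    """Diploid encoded matrices for every individual in a cohort VCF.

    Reconstructs both haplotypes of the gene window per individual and sums
    their one-hot encodings.  Returns ``{individual_id: (L x C) matrix}``.
    """
    tss0 = gene.tss - 1
    start, end = tss0 - halfwidth, tss0 + halfwidth
    samples, calls = load_cohort_calls(vcf_path, chrom=gene.chrom,
                                       start=start, end=end)
    window = (gene.chrom, start, end)
    out = {}
    for s in samples:
        h1, h2 = reconstruct_haplotypes(gene, genome, calls[s], halfwidth)
        enc = encode_diploid(h1, h2, tracks=tracks, window=window,
                             strand=gene.strand, gene_id=gene.gene_id,
                             anchor=tss0)
        out[s] = enc.matrix
    return out


def load_expression_matrix(path) -> pd.DataFrame:
    """Genes x samples expression TSV with gene ids in the first column."""
    return pd.read_csv(path, sep="\t", index_col=0)
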