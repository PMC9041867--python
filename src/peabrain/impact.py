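"""Per-position ablation impact scores and single-variant effect scoring.

The impact of a genomic position is the absolute change in predicted mean
abundance when the whole input column at that position (DNA and annotation
channels alike) is zeroed.  Positions shared by overlapping promoters take
the maximum impact across genes; the non-specific score averages per-tissue
impact tracks position-wise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome_io import (EncodedSequence, GeneModel, VariantCall,
                        encode_diploid, difference_sequence,
                        extract_promoter_window, reconstruct_haplotypes)

__all__ = ["ImpactTrack", "VariantEffect", "position_impact",
           "positional_impacts", "gene_impact_track", "merge_tracks",
           "nonspecific_score", "variant_effect_stage2"]


@dataclass
class ImpactTrack:
    """Per genomic position ablation impact for one tissue/model.

    ``positions`` maps (chrom, 0-based position) -> (impact, gene_id).
    """

    model_id: str = ""
    positions: dict = field(default_factory=dict)

    def merge_max(self, other: "ImpactTrack"):
        """In-place merge: overlapping positions take the maximum impact."""
        for key, (imp, gid) in other.positions.items():
            if key not in self.positions or imp > self.positions[key][0]:
                self.positions[key] = (imp, gid)
        return self

    def to_frame(self) -> pd.DataFrame:
        rows = [(c, p, imp, gid)
                for (c, p), (imp, gid) in sorted(self.positions.items())]
        return pd.DataFrame(rows, columns=["chrom", "pos", "impact", "gene_id"])

    def to_bedgraph(self, path):
        with open(path, "w") as fh:
            for (c, p), (imp, _gid) in sorted(self.positions.items()):
                fh.write(f"{c}\t{p}\t{p + 1}\t{imp:.6g}\n")

    def series(self) -> pd.Series:
        idx, vals = [], []
        for (c, p), (imp, _gid) in sorted(self.positions.items()):
            idx.append((c, p))
            vals.append(imp)
        return pd.Series(vals, index=pd.MultiIndex.from_tuples(idx) if idx else None)


@dataclass(frozen=True)
class VariantEffect:
    chrom: str
    pos: int
    ref: str
    alt: str
    gene_id: str
    effect: float  # signed: prediction on the (alt - ref) difference input


def position_impact(model, enc: EncodedSequence, offset: int) -> float:
    """|predict(enc) - predict(enc with column ``offset`` zeroed)|."""
    if not 0 <= offset < enc.length:
        raise IndexError(f"offset {offset} outside input of length {enc.length}")
    base = float(model.predict(enc.matrix)[0])
    ablated = enc.matrix.copy()
    ablated[offset, :] = 0
    return abs(base - float(model.predict(ablated)[0]))


def positional_impacts(model, enc: EncodedSequence,
                       batch_size: int = 64) -> np.ndarray:
    """Impact at every offset, batching the ablated forward passes."""
    base = float(model.predict(enc.matrix)[0])
    L = enc.length
    out = np.empty(L)
    for i in range(0, L, batch_size):
        n = min(batch_size, L - i)
        block = np.repeat(enc.matrix[None], n, axis=0)
        for j in range(n):
            block[j, i + j, :] = 0
        out[i:i + n] = np.abs(base - model.predict(block))
    return out


def gene_impact_track(model, enc: EncodedSequence, gene: GeneModel,
                      model_id: str = "") -> ImpactTrack:
    """Impact at every offset of a gene's promoter window, mapped back to
    genomic coordinates (strand-aware)."""
    if enc.gene_id and gene.gene_id and enc.gene_id != gene.gene_id:
        raise ValueError("encoding and gene model disagree on gene_id")
    impacts = positional_impacts(model, enc)
    track = ImpactTrack(model_id=model_id)
    for offset, imp in enumerate(impacts):
        pos = enc.genomic_position(offset)
        track.positions[(enc.chrom, pos)] = (float(imp), gene.gene_id)
    return track


def merge_tracks(tracks, model_id: str = "") -> ImpactTrack:
    """Union of per-gene fragments; overlapping positions take the maximum
    impact across genes."""
    merged = ImpactTrack(model_id=model_id)
    for t in tracks:
        merged.merge_max(t)
    return merged


def nonspecific_score(tracks) -> ImpactTrack:
    """Position-wise arithmetic mean of impact over tissue tracks; positions
    missing from some tissues are averaged over the tissues scoring them."""
    tracks = list(tracks)
    if not tracks:
        raise ValueError("need at least one tissue track")
    sums, counts, gids = {}, {}, {}
    for t in tracks:
        for key, (imp, gid) in t.positions.items():
            sums[key] = sums.get(key, 0.0) + imp
            counts[key] = counts.get(key, 0) + 1
            gids.setdefault(key, gid)
    out = ImpactTrack(model_id="nonspecific")
    for key in sums:
        out.positions[key] = (sums[key] / counts[key], gids[key])
    return out


def variant_effect_stage2(model, gene: GeneModel, genome, variant,
                          tracks=()) -> VariantEffect:
    """Score one variant with a trained Stage-2 model.

    Builds homozygous-reference and homozygous-alternate diploid encodings
    of the gene window that differ only at the variant, and scores the
    (alt - ref) difference sequence d as the odd part of the network output,
    ``(predict(d) - predict(-d)) / 2``.  Training on both pair directions
    drives the network towards an odd function of the difference input, and
    symmetrizing makes the contract exact: the effect is 0 when alt equals
    ref and swapping ref/alt negates it.  Indels follow the TSS-anchored
    reconstruction policy.
    """
    chrom, pos, ref, alt = variant
    halfwidth = model.config.window_length // 2
    ref_seq, window = extract_promoter_window(gene, genome, halfwidth)
    observed = _reference_allele(gene, genome, halfwidth, pos, len(ref))
    if observed != ref.upper():
        raise ValueError(
            f"reference mismatch at {chrom}:{pos}: variant ref {ref!r} vs "
            f"genome {observed!r}")
    ref_enc = encode_diploid(ref_seq, ref_seq, tracks=tracks, window=window,
                             strand=gene.strand, gene_id=gene.gene_id,
                             anchor=gene.tss - 1)
    call = VariantCall(chrom=chrom, pos=pos, ref=ref, alt=alt, gt=(1, 1))
    h1, h2 = reconstruct_haplotypes(gene, genome, [call], halfwidth)
    alt_enc = encode_diploid(h1, h2, tracks=tracks, window=window,
                             strand=gene.strand, gene_id=gene.gene_id,
                             anchor=gene.tss - 1)
    diff = difference_sequence(alt_enc, ref_enc)
    effect = 0.5 * (float(model.predict(diff.matrix)[0])
                    - float(model.predict(-diff.matrix)[0]))
    return VariantEffect(chrom=chrom, pos=pos, ref=ref, alt=alt,
                         gene_id=gene.gene_id, effect=effect)


def _reference_allele(gene, genome, halfwidth, pos, ref_len):
    from .genome_io import _fetch
    return _fetch(genome, gene.chrom, pos - 1, pos - 1 + ref_len)
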