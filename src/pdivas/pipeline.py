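"""Binds a reference bundle and a scorer into a per-variant annotator.

All sequence work is done in transcript orientation: for minus-strand genes
the reference and alternate windows are reverse-complemented before scoring,
which maps a genomically left-anchored allele onto the same left-anchored
offset contract the gain functions expect (the anchor offset L - o - len(ref)
is shared between the oriented ref and alt frames).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .variant_io import ConstraintTrack, TranscriptModel, Variant
from .genomic_context import classify_region, RegionCall
from .splice_features import (
    DEFAULT_SEARCH_DISTANCE, ACCEPTOR_WINDOW, FeatureVector, MotifModel,
    PWMSiteScorer, SiteScorer, assemble_features, constraint_lookup,
    default_motif_model, masked_gain_features, mes_variant_feature,
)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class GenomeSource:
    """Uniform access to a genome held as pyfaidx.Fasta or dict of strings."""

    def __init__(self, genome):
        self._genome = genome

    def fetch(self, chrom: str, start0: int, end0: int) -> str:
        """Sequence over [start0, end0) 0-based, clipped at contig ends."""
        seq = self._genome[chrom]
        n = len(seq)
        start0, end0 = max(0, start0), min(n, end0)
        return str(seq[start0:end0]).upper()

    def length(self, chrom: str) -> int:
        return len(self._genome[chrom])


@dataclass
class AnnotationPipeline:
    """Per-variant feature extraction over one reference bundle.

    Parameters: the genome, picked transcript models, the constraint track, a
    site scorer (PWM by default), the motif model for the motif-gain feature,
    the gain search distance d, and the raw-gain aggregation rule.
    """

    genome: object
    transcripts: list
    constraint: ConstraintTrack
    scorer: SiteScorer = None
    motif_model: MotifModel = None
    d: int = DEFAULT_SEARCH_DISTANCE
    raw_gain_agg: str = "mean"

    def __post_init__(self):
        if not isinstance(self.genome, GenomeSource):
            self.genome = GenomeSource(self.genome)
        if self.scorer is None:
            self.scorer = PWMSiteScorer()
        if self.motif_model is None:
            self.motif_model = default_motif_model()
        self._by_chrom = {}
        for t in self.transcripts:
            self._by_chrom.setdefault(t.chrom, []).append(t)
        for ts in self._by_chrom.values():
            ts.sort(key=lambda t: t.span)

    def locate(self, v: Variant) -> TranscriptModel | None:
        """The transcript whose span contains the variant, if any."""
        for t in self._by_chrom.get(v.chrom, ()):
            lo, hi = t.span
            if lo <= v.pos <= hi:
                return t
        return None

    def region(self, v: Variant) -> RegionCall:
        t = self.locate(v)
        if t is None:
            return RegionCall("outside_gene", None)
        return classify_region(v, t)

    def _oriented_windows(self, v: Variant, t: TranscriptModel):
        """Build transcript-oriented ref/alt windows and the offset frame."""
        margin = self.d + ACCEPTOR_WINDOW
        ref_len, alt_len = len(v.ref), len(v.alt)
        w_start0 = max(0, v.pos - 1 - margin)
        w_end0 = min(self.genome.length(v.chrom), v.pos - 1 + ref_len + margin)
        ref_seq = self.genome.fetch(v.chrom, w_start0, w_end0)
        var_off = v.pos - 1 - w_start0
        if ref_seq[var_off:var_off + ref_len] != v.ref:
            raise ValueError(
                f"reference mismatch at {v.chrom}:{v.pos}: genome has "
                f"{ref_seq[var_off:var_off + ref_len]!r}, variant says {v.ref!r}")
        alt_seq = ref_seq[:var_off] + v.alt + ref_seq[var_off + ref_len:]
        sites = [(p - 1 - w_start0, kind) for p, kind in t.splice_sites()
                 if w_start0 <= p - 1 < w_end0]
        if t.strand == "+":
            return (ref_seq, alt_seq, var_off, sites,
                    v.chrom, w_start0)
        L = len(ref_seq)
        o_var = L - var_off - ref_len
        o_sites = [(L - 1 - off, kind) for off, kind in sites]
        return (revcomp(ref_seq), revcomp(alt_seq), o_var, o_sites, None, None)

    def feature_vector(self, v: Variant) -> FeatureVector:
        """The five features for one variant (may be incomplete)."""
        t = self.locate(v)
        if t is None:
            raise ValueError(f"variant {v.key} outside all transcripts")
        ref_seq, alt_seq, var_off, sites, chrom, start = self._oriented_windows(v, t)
        gains = masked_gain_features(
            self.scorer, ref_seq, alt_seq, var_off, annotated_sites=sites,
            d=self.d, ref_len=len(v.ref), alt_len=len(v.alt),
            chrom=chrom, window_start=start,
        )
        mes = mes_variant_feature(ref_seq, alt_seq, var_off,
                                  ref_len=len(v.ref), alt_len=len(v.alt),
                                  model=self.motif_model)
        constraint = constraint_lookup(v, self.constraint)
        return assemble_features(v, gains, mes, constraint,
                                 raw_gain_agg=self.raw_gain_agg)

    def feature_frame(self, variants) -> "pd.DataFrame":
        """Feature rows for many variants; incomplete rows carry NaN."""
        import pandas as pd
        from .splice_features import FEATURE_NAMES

        rows = []
        for v in variants:
            fv = self.feature_vector(v)
            rows.append(fv.to_array())
        return pd.DataFrame(np.array(rows).reshape(-1, len(FEATURE_NAMES)),
                            columns=list(FEATURE_NAMES))
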