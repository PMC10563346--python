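"""Position of a variant relative to transcript structure, and rarity filters.

A "deep intron" is any intronic position at least 50 bases from the nearest
annotated splice site of the flanking exons; the boundary is inclusive, so a
variant exactly 50 intronic bases from a site is deep-intronic. Distances are
counted in intronic bases including the variant's own base (the first base of
an intron is at distance 1).
"""

from __future__ import annotations

from dataclasses import dataclass

from .variant_io import TranscriptModel, Variant

DEEP_INTRON_MIN_DISTANCE = 50
DONOR_EXONIC, DONOR_INTRONIC = 3, 6  # 9-mer donor motif window
ACCEPTOR_INTRONIC, ACCEPTOR_EXONIC = 20, 3  # 23-mer acceptor motif window

RARE_AF_CUTOFF = 0.01
COMMON_AF_CUTOFF = 0.05


class OutsideGeneError(ValueError):
    """Variant position falls outside the transcript span."""


@dataclass(frozen=True)
class RegionCall:
    zone: str  # exonic | near_splice_intronic | deep_intronic | outside_gene
    distance_bp: int | None = None


@dataclass(frozen=True)
class MotifRegionCall:
    region: str  # donor_motif | acceptor_motif | outside


def nearest_splice_distance(v: Variant, t: TranscriptModel) -> int:
    """Distance in intronic bases from the variant to the nearest splice site.

    Exonic positions return 0. For deletions the most splice-proximal deleted
    base anchors the distance, so an indel is deep-intronic only when it lies
    wholly deep. Raises :class:`OutsideGeneError` outside the transcript span.
    """
    positions = range(v.pos, v.pos + len(v.ref))
    dists = []
    for pos in positions:
        if not t.contains(pos):
            raise OutsideGeneError(
                f"{v.chrom}:{pos} outside transcript {t.transcript_id} span {t.span}")
        if t.exonic(pos):
            return 0
        for s, e in t.introns:
            if s <= pos <= e:
                dists.append(min(pos - s + 1, e - pos + 1))
                break
    return min(dists)


def classify_region(v: Variant, t: TranscriptModel) -> RegionCall:
    """Assign exactly one zone to a variant.

    Intronic positions are split at the 50-base rule: ``deep_intronic`` iff
    the distance to the nearest splice site is >= 50, else
    ``near_splice_intronic``.
    """
    try:
        d = nearest_splice_distance(v, t)
    except OutsideGeneError:
        return RegionCall("outside_gene", None)
    if d == 0:
        return RegionCall("exonic", 0)
    zone = "deep_intronic" if d >= DEEP_INTRON_MIN_DISTANCE else "near_splice_intronic"
    return RegionCall(zone, d)


def classify_motif_region(variant_pos: int, site: tuple) -> MotifRegionCall:
    """Locate a position relative to one splice site's scoring motif window.

    ``site`` is ``(position, kind, strand)`` where position is the genomic
    coordinate of the junction base in the scorer convention (donor: last
    exonic base; acceptor: first exonic base, both in transcript orientation).
    The donor window covers 3 exonic + 6 intronic bases; the acceptor window
    20 intronic + 3 exonic. Windows are laid out in transcript orientation and
    mirrored on the minus strand.
    """
    pos, kind, strand = site
    if kind not in ("donor", "acceptor"):
        raise ValueError(f"unknown site kind {kind!r}")
    if kind == "donor":
        if strand == "+":
            lo, hi = pos - (DONOR_EXONIC - 1), pos + DONOR_INTRONIC
        else:
            lo, hi = pos - DONOR_INTRONIC, pos + (DONOR_EXONIC - 1)
        region = "donor_motif"
    else:
        if strand == "+":
            lo, hi = pos - ACCEPTOR_INTRONIC, pos + (ACCEPTOR_EXONIC - 1)
        else:
            lo, hi = pos - (ACCEPTOR_EXONIC - 1), pos + ACCEPTOR_INTRONIC
        region = "acceptor_motif"
    if lo <= variant_pos <= hi:
        return MotifRegionCall(region)
    return MotifRegionCall("outside")


def passes_rare_filter(v: Variant, sources, cutoff: float = RARE_AF_CUTOFF) -> bool:
    """True iff AF < cutoff in every listed source; missing AF counts as 0.

    A variant absent from population databases is treated as novel, hence
    rare — the convention of diagnostic filtering.
    """
    return all(v.af.get(src, 0.0) < cutoff for src in sources)


def passes_common_filter(v: Variant, sources, cutoff: float = COMMON_AF_CUTOFF) -> bool:
    """True iff AF >= cutoff in every listed source (missing AF fails)."""
    return all(v.af.get(src, 0.0) >= cutoff for src in sources)
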