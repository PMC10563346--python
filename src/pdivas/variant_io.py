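"""Reading and writing the standard formats the pipeline touches.

Internal conventions: variant positions are 1-based (VCF); exon intervals are
1-based closed; all interval arithmetic against BED-style tracks converts to
0-based half-open here and nowhere else.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import gffutils
import numpy as np
import pandas as pd
import pysam

log = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGT")


class VcfParseError(ValueError):
    """Malformed VCF content; message carries the offending line number."""


@dataclass(frozen=True)
class Variant:
    """One normalized, biallelic VCF record.

    ``af`` maps a population-source name (e.g. ``"gnomAD"``, ``"KGP"``) to an
    allele frequency in [0, 1]; absent keys mean the variant was not observed
    in that source.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    af: dict = field(default_factory=dict)
    gene_id: str | None = None
    transcript_id: str | None = None

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if not self.ref or not self.alt:
            raise ValueError("ref and alt must be nonempty")
        for allele, name in ((self.ref, "ref"), (self.alt, "alt")):
            if not set(allele) <= VALID_BASES:
                raise ValueError(f"{name} allele {allele!r} not over ACGT")
        if self.ref == self.alt:
            raise ValueError("ref and alt must differ")
        for src, value in self.af.items():
            if value is not None and not 0.0 <= value <= 1.0:
                raise ValueError(f"AF {src}={value} outside [0,1]")

    @property
    def key(self) -> tuple:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    def with_gene(self, gene_id: str, transcript_id: str) -> "Variant":
        return replace(self, gene_id=gene_id, transcript_id=transcript_id)


@dataclass(frozen=True)
class TranscriptModel:
    """A single transcript: ordered exons on one strand.

    Exons are 1-based closed genomic intervals, sorted ascending regardless of
    strand. Splice sites are derived: for every intron, the donor sits on the
    last transcribed exonic base before the intron and the acceptor on the
    first transcribed exonic base after it (in transcript orientation).
    """

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    exons: tuple

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if len(self.exons) < 1:
            raise ValueError("transcript needs at least one exon")
        prev_end = None
        for start, end in self.exons:
            if start > end:
                raise ValueError(f"exon ({start},{end}) has start > end")
            if prev_end is not None and start <= prev_end:
                raise ValueError("exons overlap or are unsorted")
            prev_end = end

    @property
    def span(self) -> tuple:
        return (self.exons[0][0], self.exons[-1][1])

    @property
    def introns(self) -> list:
        """1-based closed intronic intervals between consecutive exons."""
        out = []
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            out.append((e1 + 1, s2 - 1))
        return out

    def splice_sites(self) -> list:
        """All annotated splice sites as (genomic position, kind).

        Positions follow the scorer convention: a donor is reported at the
        last exonic base of its junction, an acceptor at the first exonic
        base. Kind is assigned in transcript orientation, so on the minus
        strand the genomically-right junction of an intron is the donor.
        """
        sites = []
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if self.strand == "+":
                sites.append((e1, "donor"))
                sites.append((s2, "acceptor"))
            else:
                sites.append((s2, "donor"))
                sites.append((e1, "acceptor"))
        return sites

    def contains(self, pos: int) -> bool:
        lo, hi = self.span
        return lo <= pos <= hi

    def exonic(self, pos: int) -> bool:
        return any(s <= pos <= e for s, e in self.exons)


@dataclass
class ConstraintTrack:
    """Splicing-constraint scores over non-overlapping genomic intervals.

    Intervals are BED-style: 0-based half-open, score in [0, 1].
    """

    intervals: list

    def __post_init__(self):
        self._by_chrom = {}
        for chrom, start, end, score in self.intervals:
            if not 0.0 <= score <= 1.0:
                raise ValueError(f"constraint score {score} outside [0,1]")
            if start >= end:
                raise ValueError(f"empty interval ({start},{end})")
            self._by_chrom.setdefault(chrom, []).append((start, end, score))
        self._index = {}
        for chrom, ivals in self._by_chrom.items():
            ivals.sort()
            for (s1, e1, _), (s2, e2, _) in zip(ivals, ivals[1:]):
                if s2 < e1:
                    raise ValueError(
                        f"overlapping constraint intervals on {chrom}: "
                        f"({s1},{e1}) and ({s2},{e2})"
                    )
            starts = np.array([s for s, _, _ in ivals])
            ends = np.array([e for _, e, _ in ivals])
            scores = np.array([sc for _, _, sc in ivals])
            self._index[chrom] = (starts, ends, scores)

    def score_at(self, chrom: str, pos: int) -> float | None:
        """Score of the interval covering 1-based position ``pos``, else None."""
        if chrom not in self._index:
            return None
        starts, ends, scores = self._index[chrom]
        p0 = pos - 1  # to 0-based
        i = int(np.searchsorted(starts, p0, side="right")) - 1
        if i >= 0 and starts[i] <= p0 < ends[i]:
            return float(scores[i])
        return None


# ---------------------------------------------------------------------------
# VCF


def _is_simple_allele(allele: str) -> bool:
    return bool(allele) and set(allele) <= VALID_BASES


def read_vcf(path, af_sources=()) -> list:
    """Read a VCF into normalized :class:`Variant` records.

    Multi-allelic records are decomposed into one Variant per alternate
    allele. Symbolic alleles (``<DEL>`` etc.), breakends and any allele not a
    plain A/C/G/T string are skipped and counted; the skip count is logged and
    available via the ``.skipped`` attribute on the returned list.

    ``af_sources`` names INFO keys carrying per-allele allele frequencies.
    """
    variants = []
    skipped = 0
    try:
        vcf = pysam.VariantFile(str(path))
    except Exception as exc:  # pragma: no cover - pysam error text varies
        raise VcfParseError(f"cannot parse VCF {path}: {exc}") from exc
    with vcf:
        for rec in vcf:
            alts = rec.alts or ()
            for ai, alt in enumerate(alts):
                if not _is_simple_allele(rec.ref) or alt is None or not _is_simple_allele(alt):
                    skipped += 1
                    continue
                af = {}
                for src in af_sources:
                    if src in rec.info:
                        val = rec.info[src]
                        if isinstance(val, tuple):
                            val = val[ai] if ai < len(val) else None
                        if val is not None:
                            af[src] = float(val)
                gene = rec.info.get("GENE") if "GENE" in rec.info else None
                if isinstance(gene, tuple):
                    gene = gene[0]
                variants.append(
                    Variant(rec.chrom, rec.pos, rec.ref, alt, af=af, gene_id=gene)
                )
    if skipped:
        log.info("read_vcf: skipped %d non-simple allele(s) in %s", skipped, path)

    class _VariantList(list):
        pass

    out = _VariantList(variants)
    out.skipped = skipped
    return out


def _vcf_header(contigs, af_sources=()) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for contig, length in contigs:
        header.contigs.add(contig, length=length)
    header.info.add("PDIVAS", "1", "String",
                    "Deep-intronic pathogenicity score: gene_id|score")
    header.info.add("GENE", "1", "String", "Gene identifier")
    for src in af_sources:
        header.info.add(src, "A", "Float", f"Allele frequency in {src}")
    return header


def write_vcf_scores(variants, scores, path, contigs=None, af_sources=None) -> None:
    """Write variants with a ``PDIVAS=<gene>|<score>`` INFO annotation.

    ``scores`` is keyed by ``(chrom, pos, ref, alt)``; variants without an
    entry are emitted with ``PDIVAS=.|.``. Scores are rounded to 3 decimals.
    """
    if af_sources is None:
        af_sources = sorted({src for v in variants for src in v.af})
    if contigs is None:
        seen = {}
        for v in variants:
            seen[v.chrom] = max(seen.get(v.chrom, 0), v.pos + len(v.ref) + 1000)
        contigs = sorted(seen.items())
    header = _vcf_header(contigs, af_sources)
    order = {c: i for i, (c, _) in enumerate(contigs)}
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for v in sorted(variants, key=lambda v: (order.get(v.chrom, 1 << 30), v.pos)):
            rec = out.new_record(
                contig=v.chrom, start=v.pos - 1, stop=v.pos - 1 + len(v.ref),
                alleles=(v.ref, v.alt),
            )
            score = scores.get(v.key)
            if score is None:
                rec.info["PDIVAS"] = ".|."
            else:
                rec.info["PDIVAS"] = f"{v.gene_id or '.'}|{score:.3f}"
            if v.gene_id:
                rec.info["GENE"] = v.gene_id
            for src in af_sources:
                if src in v.af:
                    rec.info[src] = v.af[src]
            out.write(rec)


def parse_score_info(info_value: str) -> tuple:
    """Split a ``gene|score`` PDIVAS INFO value; missing fields become None."""
    gene, _, score = info_value.partition("|")
    return (None if gene == "." else gene,
            None if score in (".", "") else float(score))


# ---------------------------------------------------------------------------
# Gene models


def _coding_span(exons) -> int:
    return sum(e - s + 1 for s, e in exons)


def _pick_one_per_gene(transcripts) -> list:
    """Retain one transcript per gene: the longest total exonic span.

    Deterministic stand-in for a consequence-picker's one-transcript-per-gene
    behavior; ties break on transcript_id.
    """
    by_gene = {}
    for t in transcripts:
        by_gene.setdefault(t.gene_id, []).append(t)
    picked = []
    for gene_id in sorted(by_gene):
        cands = sorted(by_gene[gene_id],
                       key=lambda t: (-_coding_span(t.exons), t.transcript_id))
        picked.append(cands[0])
    return picked


def read_gtf(path) -> list:
    """Parse a GTF (GENCODE dialect) into one TranscriptModel per gene."""
    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True,
        disable_infer_genes=True, disable_infer_transcripts=True,
    )
    transcripts = []
    for tr in db.features_of_type("transcript"):
        exons = sorted(
            (f.start, f.end)
            for f in db.children(tr, featuretype="exon")
        )
        transcripts.append(TranscriptModel(
            gene_id=tr.attributes["gene_id"][0],
            transcript_id=tr.attributes["transcript_id"][0],
            chrom=tr.seqid, strand=tr.strand, exons=tuple(exons),
        ))
    return _pick_one_per_gene(transcripts)


def read_bed12(path) -> list:
    """Parse a BED12 file into one TranscriptModel per gene.

    The BED ``name`` field carries ``gene_id:transcript_id`` (or just an id
    used for both). Block coordinates (0-based half-open) are converted to
    1-based closed exons.
    """
    cols = ["chrom", "start", "end", "name", "score", "strand",
            "thickStart", "thickEnd", "rgb", "blockCount",
            "blockSizes", "blockStarts"]
    df = pd.read_csv(path, sep="\t", header=None, names=cols, comment="#")
    transcripts = []
    for row in df.itertuples(index=False):
        if ":" in str(row.name):
            gene_id, transcript_id = str(row.name).split(":", 1)
        else:
            gene_id = transcript_id = str(row.name)
        sizes = [int(x) for x in str(row.blockSizes).rstrip(",").split(",")]
        starts = [int(x) for x in str(row.blockStarts).rstrip(",").split(",")]
        exons = tuple(
            (row.start + bs + 1, row.start + bs + sz)
            for bs, sz in zip(starts, sizes)
        )
        transcripts.append(TranscriptModel(
            gene_id=gene_id, transcript_id=transcript_id,
            chrom=row.chrom, strand=row.strand, exons=exons,
        ))
    return _pick_one_per_gene(transcripts)


def read_gene_models(path) -> list:
    """Read transcript models from GTF or BED12, keyed on file extension."""
    p = str(path)
    if p.endswith((".bed", ".bed12")):
        return read_bed12(p)
    return read_gtf(p)


def read_constraint_bed(path) -> ConstraintTrack:
    """Read a BED4 constraint track (chrom, start, end, score)."""
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "score"], comment="#")
    return ConstraintTrack(
        [(r.chrom, int(r.start), int(r.end), float(r.score))
         for r in df.itertuples(index=False)]
    )


def read_gene_list(path) -> set:
    """Read a plain-text gene list, one identifier per line."""
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}
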