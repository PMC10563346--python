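"""Synthetic reference, cohort and feature-table generators.

The generator builds a desk-scale world with the structure the method needs:
multi-exon genes with consensus splice junctions, deep introns hosting
"cryptic" splice motifs one mutation away from activation, a constraint track
that is high over a designated disease-gene subset and low elsewhere, common
and novel benign variants, and class-conditional feature tables whose
separations mirror the qualitative structure of curated pathogenic/benign
deep-intronic sets (most pathogenic variants have high splice-gain deltas; a
~10% hard stratum has low delta but a strong motif score; benign constraint
mass sits below 0.2).

One global seed fans out to independent per-stage child seeds, so every stage
is reproducible on its own.
"""

from __future__ import annotations

import textwrap
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .variant_io import ConstraintTrack, TranscriptModel, Variant
from .cohort import CohortSample
from .pipeline import revcomp

AF_SOURCES = ("gnomAD", "KGP")

# transcript-oriented junction consensus
_DONOR_EXON_TAIL = "CAG"
_DONOR_INTRON_HEAD = "GTAAGT"
_ACCEPTOR_TRACT = "TCTTTCTTTCTCTTTCTT"  # 18-base pyrimidine tract
_ACCEPTOR_INTRON_TAIL = _ACCEPTOR_TRACT + "AG"
_ACCEPTOR_EXON_HEAD = "G"

# cryptic donor: consensus CAGGTAAGT broken at the near-invariant T (+2) and
# one weak position; the restoring SNV flips the +2 base back to T
_CRYPTIC_DONOR = "CAGGCAAGA"
_CRYPTIC_DONOR_FIX = (4, "C", "T")  # (offset in motif, ref base, alt base)
# deletion-type cryptic donor: consensus with one extra base inside;
# deleting it restores the full 9-mer
_CRYPTIC_DONOR_INS = "CAGGC" + "TAAGT"  # deleting the C at offset 4 restores
_CRYPTIC_DONOR_DEL = 4

# cryptic acceptor: tract + AG with the near-invariant G broken; restoring
# SNV flips it back
_CRYPTIC_ACCEPTOR = _ACCEPTOR_TRACT + "AC" + "G"
_CRYPTIC_ACCEPTOR_FIX = (19, "C", "G")


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the generated world (defaults are the stated world)."""

    seed: int = 0
    n_genes: int = 20
    exons_per_gene: int = 3
    exon_len: int = 90
    intron_len_range: tuple = (260, 400)
    spacer_len: int = 300
    disease_gene_frac: float = 0.5
    cryptic_per_intron: int = 2
    deletion_site_frac: float = 0.3
    n_samples: int = 50
    benign_common_per_sample: int = 25
    benign_rare_per_sample: int = 15
    pathogenic_per_sample: int = 0
    n_benign_variants: int = 400
    n_pathogenic_rows: int = 50
    n_benign_rows: int = 500
    hard_fraction: float = 0.10
    af_sources: tuple = AF_SOURCES

    def __post_init__(self):
        if min(self.n_genes, self.exons_per_gene, self.exon_len,
               self.n_samples) < 1:
            raise ValueError("all counts must be >= 1")
        if not 0.0 <= self.hard_fraction <= 1.0:
            raise ValueError("hard_fraction must be in [0,1]")

    def child_seed(self, stage: str) -> np.random.Generator:
        stages = ("reference", "cohort", "table", "variants")
        if stage not in stages:
            raise ValueError(f"unknown stage {stage!r}")
        child = np.random.SeedSequence(self.seed).spawn(len(stages))
        return np.random.default_rng(child[stages.index(stage)])


@dataclass(frozen=True)
class CrypticSite:
    """A deep-intronic near-miss splice motif and its activating variant."""

    gene_id: str
    kind: str  # donor | acceptor
    variant: Variant  # the activating (pathogenic) variant, AF absent = 0


@dataclass
class SyntheticReference:
    genome: dict
    transcripts: list
    constraint: ConstraintTrack
    gene_list: set
    cryptic_sites: list
    spec: SyntheticSpec

    def transcript_of(self, gene_id: str) -> TranscriptModel:
        return next(t for t in self.transcripts if t.gene_id == gene_id)


def _random_seq(rng, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


def _build_gene(rng, spec: SyntheticSpec, gene_id: str, plant_cryptic: bool):
    """Assemble one gene in transcript orientation.

    Returns (sequence, exon oriented intervals (0-based closed), cryptic
    records as (oriented offset of variant, ref, alt, kind)).
    """
    lo, hi = spec.intron_len_range
    if lo < 120:
        raise ValueError("introns must be >= 120 bases to host deep positions")
    parts = []
    exons = []
    cryptics = []
    cursor = 0
    for i in range(spec.exons_per_gene):
        exon = _random_seq(rng, spec.exon_len)
        if i > 0:
            exon = _ACCEPTOR_EXON_HEAD + exon[1:]
        if i < spec.exons_per_gene - 1:
            exon = exon[:-len(_DONOR_EXON_TAIL)] + _DONOR_EXON_TAIL
        parts.append(exon)
        exons.append((cursor, cursor + len(exon) - 1))
        cursor += len(exon)
        if i == spec.exons_per_gene - 1:
            break
        ilen = int(rng.integers(lo, hi + 1))
        intron = list(_random_seq(rng, ilen))
        intron[:len(_DONOR_INTRON_HEAD)] = _DONOR_INTRON_HEAD
        intron[-len(_ACCEPTOR_INTRON_TAIL):] = _ACCEPTOR_INTRON_TAIL
        if plant_cryptic:
            # deep zone: >= 50 bases from both splice sites, with margin for
            # the motif itself
            zone_lo, zone_hi = 55, ilen - 55 - 23
            slots = np.sort(rng.choice(
                np.arange(zone_lo, zone_hi, 40), size=spec.cryptic_per_intron,
                replace=False))
            for slot in (int(s) for s in slots):
                r = rng.random()
                if r < spec.deletion_site_frac:
                    # deleting the extra base restores the full donor 9-mer
                    motif = _CRYPTIC_DONOR_INS
                    intron[slot:slot + len(motif)] = motif
                    cryptics.append(
                        ("del", cursor + slot + _CRYPTIC_DONOR_DEL, None, None,
                         "donor"))
                elif r < (1.0 + spec.deletion_site_frac) / 2:
                    motif = _CRYPTIC_DONOR
                    o, rb, ab = _CRYPTIC_DONOR_FIX
                    intron[slot:slot + len(motif)] = motif
                    cryptics.append(("snv", cursor + slot + o, rb, ab, "donor"))
                else:
                    motif = _CRYPTIC_ACCEPTOR
                    o, rb, ab = _CRYPTIC_ACCEPTOR_FIX
                    intron[slot:slot + len(motif)] = motif
                    cryptics.append(("snv", cursor + slot + o, rb, ab,
                                     "acceptor"))
        parts.append("".join(intron))
        cursor += ilen
    return "".join(parts), exons, cryptics


def gen_reference(spec: SyntheticSpec) -> SyntheticReference:
    """Toy genome, transcripts, constraint track, gene list, cryptic sites.

    Genes alternate between the two strands; the first
    ``disease_gene_frac`` of genes form the Mendelian gene list, carry the
    cryptic splice motifs, and get high constraint scores (>= 0.5); the rest
    score < 0.2. Deterministic per seed.
    """
    rng = spec.child_seed("reference")
    n_disease = max(1, round(spec.n_genes * spec.disease_gene_frac))
    chrom_seqs = {"chr1": [], "chr2": []}
    cursors = {"chr1": 0, "chr2": 0}
    transcripts = []
    constraint_intervals = []
    cryptic_sites = []
    gene_list = set()

    for g in range(spec.n_genes):
        gene_id = f"GENE{g + 1}"
        chrom = "chr1" if g % 2 == 0 else "chr2"
        strand = "+" if g % 4 < 2 else "-"
        is_disease = g < n_disease
        seq, oriented_exons, cryptics = _build_gene(rng, spec, gene_id,
                                                    plant_cryptic=is_disease)
        spacer = _random_seq(rng, spec.spacer_len)
        chrom_seqs[chrom].append(spacer)
        cursors[chrom] += spec.spacer_len
        g_start0 = cursors[chrom]  # 0-based start of the oriented gene block
        L = len(seq)
        if strand == "+":
            chrom_seqs[chrom].append(seq)
            exons = tuple((g_start0 + a + 1, g_start0 + b + 1)
                          for a, b in oriented_exons)
        else:
            chrom_seqs[chrom].append(revcomp(seq))
            exons = tuple(sorted(
                (g_start0 + (L - 1 - b) + 1, g_start0 + (L - 1 - a) + 1)
                for a, b in oriented_exons))
        cursors[chrom] += L
        t = TranscriptModel(gene_id=gene_id, transcript_id=f"{gene_id}.t1",
                            chrom=chrom, strand=strand, exons=exons)
        transcripts.append(t)

        score = (rng.uniform(0.6, 0.95) if is_disease
                 else rng.uniform(0.02, 0.18))
        constraint_intervals.append(
            (chrom, max(0, g_start0 - 100), g_start0 + L + 100, round(score, 3)))
        if is_disease:
            gene_list.add(gene_id)
            comp = dict(zip("ACGT", "TGCA"))
            for vtype, o_off, rb, ab, kind in cryptics:
                if vtype == "snv":
                    if strand == "+":
                        pos = g_start0 + o_off + 1
                        ref, alt = rb, ab
                    else:
                        pos = g_start0 + (L - 1 - o_off) + 1
                        ref, alt = comp[rb], comp[ab]
                else:  # single-base deletion at oriented offset o_off
                    if strand == "+":
                        pos = g_start0 + o_off  # 1-based anchor at o_off - 1
                        ref = seq[o_off - 1] + seq[o_off]
                        alt = seq[o_off - 1]
                    else:
                        g = L - 1 - o_off  # genomic 0-based offset of deleted base
                        pos = g_start0 + g  # anchor at genomic offset g - 1
                        anchor = comp[seq[L - 1 - (g - 1)]]
                        deleted = comp[seq[o_off]]
                        ref, alt = anchor + deleted, anchor
                cryptic_sites.append(CrypticSite(
                    gene_id=gene_id, kind=kind,
                    variant=Variant(chrom, pos, ref, alt, af={},
                                    gene_id=gene_id,
                                    transcript_id=t.transcript_id)))
    genome = {c: "".join(parts) + _random_seq(rng, spec.spacer_len)
              for c, parts in chrom_seqs.items()}
    return SyntheticReference(
        genome=genome, transcripts=transcripts,
        constraint=ConstraintTrack(constraint_intervals),
        gene_list=gene_list, cryptic_sites=cryptic_sites, spec=spec,
    )


def _deep_positions(t: TranscriptModel, margin: int = 52) -> list:
    """Deep-intronic 1-based positions of a transcript, with a safety margin."""
    out = []
    for s, e in t.introns:
        out.extend(range(s + margin, e - margin + 1))
    return out


def _benign_snv(rng, reference: SyntheticReference, t: TranscriptModel,
                pos: int, common: bool) -> Variant:
    base = reference.genome[t.chrom][pos - 1]
    alts = [b for b in "ACGT" if b != base]
    alt = alts[int(rng.integers(0, 3))]
    if common:
        af = {src: float(np.round(rng.uniform(0.05, 0.5), 4))
              for src in reference.spec.af_sources}
    else:
        af = {}
    return Variant(t.chrom, pos, base, alt, af=af, gene_id=t.gene_id,
                   transcript_id=t.transcript_id)


def _cryptic_exclusion(reference: SyntheticReference) -> set:
    """Positions to keep benign variants away from (cryptic motif windows)."""
    excl = set()
    for site in reference.cryptic_sites:
        v = site.variant
        for p in range(v.pos - 30, v.pos + 31):
            excl.add((v.chrom, p))
    return excl


def gen_labeled_variants(reference: SyntheticReference) -> tuple:
    """Sequence-level labeled variant set for end-to-end training.

    Pathogenic variants are the cryptic-site activators (novel, AF absent);
    benign variants are random deep-intronic substitutions with common allele
    frequencies (>= 5% in both sources). Returns (variants, labels array).
    """
    spec = reference.spec
    rng = spec.child_seed("variants")
    excl = _cryptic_exclusion(reference)
    variants = [site.variant for site in reference.cryptic_sites]
    labels = ["pathogenic"] * len(variants)
    per_gene = {t.gene_id: _deep_positions(t) for t in reference.transcripts}
    genes = [t for t in reference.transcripts]
    made = 0
    used = set()
    while made < spec.n_benign_variants:
        t = genes[int(rng.integers(0, len(genes)))]
        pool = per_gene[t.gene_id]
        pos = int(pool[int(rng.integers(0, len(pool)))])
        if (t.chrom, pos) in excl or (t.chrom, pos) in used:
            continue
        used.add((t.chrom, pos))
        variants.append(_benign_snv(rng, reference, t, pos, common=True))
        labels.append("benign")
        made += 1
    return variants, np.array(labels)


def gen_cohort(spec: SyntheticSpec, reference: SyntheticReference) -> tuple:
    """Per-sample variant sets and a truth table.

    Each sample carries ``benign_common_per_sample`` common deep-intronic
    substitutions (AF >= 5% in both sources), ``benign_rare_per_sample`` novel
    ones (AF absent), and ``pathogenic_per_sample`` cryptic-site activators.
    Returns (list of CohortSample, truth DataFrame).
    """
    rng = spec.child_seed("cohort")
    excl = _cryptic_exclusion(reference)
    per_gene = {t.gene_id: _deep_positions(t) for t in reference.transcripts}
    genes = list(reference.transcripts)
    samples = []
    truth_rows = []
    for s in range(spec.n_samples):
        sample_id = f"S{s + 1:03d}"
        variants = []
        used = set()
        for is_common, count in ((True, spec.benign_common_per_sample),
                                 (False, spec.benign_rare_per_sample)):
            made = 0
            while made < count:
                t = genes[int(rng.integers(0, len(genes)))]
                pool = per_gene[t.gene_id]
                pos = int(pool[int(rng.integers(0, len(pool)))])
                if (t.chrom, pos) in excl or (t.chrom, pos) in used:
                    continue
                used.add((t.chrom, pos))
                v = _benign_snv(rng, reference, t, pos, common=is_common)
                variants.append(v)
                truth_rows.append({"sample_id": sample_id, "chrom": v.chrom,
                                   "pos": v.pos, "ref": v.ref, "alt": v.alt,
                                   "gene_id": v.gene_id, "label": "benign"})
                made += 1
        if spec.pathogenic_per_sample:
            picks = rng.choice(len(reference.cryptic_sites),
                               size=spec.pathogenic_per_sample, replace=False)
            for i in picks:
                v = reference.cryptic_sites[int(i)].variant
                variants.append(v)
                truth_rows.append({"sample_id": sample_id, "chrom": v.chrom,
                                   "pos": v.pos, "ref": v.ref, "alt": v.alt,
                                   "gene_id": v.gene_id, "label": "pathogenic"})
        samples.append(CohortSample(sample_id, variants))
    return samples, pd.DataFrame(truth_rows)


def gen_feature_table(spec: SyntheticSpec) -> tuple:
    """Class-conditional five-feature table: (X DataFrame, labels array).

    Pathogenic rows split into a typical stratum (high acceptor/donor delta
    gains; 70% pseudoexon-like with both sites gained, 30% extension-like
    with one) and a ``hard_fraction`` motif-only stratum (delta gain <= 0.2,
    strong motif score). Benign rows have low deltas with a small SAV-like
    minority, mostly-zero motif scores, and constraint mass below 0.2.
    Deterministic per seed.
    """
    rng = spec.child_seed("table")
    n_p, n_b = spec.n_pathogenic_rows, spec.n_benign_rows
    n_hard = round(spec.hard_fraction * n_p)

    def raw_from(delta, a, b):
        return delta + (1.0 - delta) * rng.beta(a, b, size=delta.shape)

    rows = []
    # pathogenic typical
    n_typ = n_p - n_hard
    pseudo = rng.random(n_typ) < 0.7
    acc = np.where(pseudo, rng.beta(6, 1.5, n_typ), 0.0)
    don = np.where(pseudo, rng.beta(6, 1.5, n_typ), 0.0)
    one_site = rng.beta(6, 1.5, n_typ)
    donor_side = rng.random(n_typ) < 0.5
    acc = np.where(pseudo, acc, np.where(donor_side, 0.0, one_site))
    don = np.where(pseudo, don, np.where(donor_side, one_site, 0.0))
    mes = np.where(rng.random(n_typ) < 0.7, rng.beta(4, 2, n_typ),
                   rng.beta(1, 6, n_typ))
    rows.append(pd.DataFrame({
        "spliceai_del_gain_mean": (acc + don) / 2,
        "spliceai_del_gain_max": np.maximum(acc, don),
        "spliceai_raw_gain_mean": (raw_from(acc, 1.5, 6) + raw_from(don, 1.5, 6)) / 2,
        "consplice": rng.beta(5, 2.2, n_typ),
        "maxentscan": mes,
        "label": "pathogenic",
    }))
    # pathogenic hard stratum: motif-only
    acc = 0.2 * rng.beta(2, 2, n_hard)
    don = 0.2 * rng.beta(2, 2, n_hard)
    rows.append(pd.DataFrame({
        "spliceai_del_gain_mean": (acc + don) / 2,
        "spliceai_del_gain_max": np.maximum(acc, don),
        "spliceai_raw_gain_mean": (raw_from(acc, 2, 4) + raw_from(don, 2, 4)) / 2,
        "consplice": rng.beta(5, 2.2, n_hard),
        "maxentscan": rng.beta(8, 2, n_hard),
        "label": "pathogenic",
    }))
    # benign
    savlike = rng.random(n_b) < 0.05
    acc = np.where(savlike, rng.beta(3, 3, n_b), rng.beta(1.2, 12, n_b))
    don = np.where(savlike, rng.beta(3, 3, n_b), rng.beta(1.2, 12, n_b))
    mes = np.where(rng.random(n_b) < 0.7, 0.0, rng.beta(1.2, 8, n_b))
    rows.append(pd.DataFrame({
        "spliceai_del_gain_mean": (acc + don) / 2,
        "spliceai_del_gain_max": np.maximum(acc, don),
        "spliceai_raw_gain_mean": (raw_from(acc, 1.2, 8) + raw_from(don, 1.2, 8)) / 2,
        "consplice": rng.beta(1.6, 9, n_b),
        "maxentscan": mes,
        "label": "benign",
    }))
    table = pd.concat(rows, ignore_index=True)
    y = table.pop("label").to_numpy()
    return table, y


# ---------------------------------------------------------------------------
# File emission (standard formats only)


def write_fasta(genome: dict, path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(genome):
            fh.write(f">{chrom}\n")
            fh.write(textwrap.fill(genome[chrom], 70))
            fh.write("\n")


def write_gtf(transcripts, path) -> None:
    with open(path, "w") as fh:
        for t in transcripts:
            lo, hi = t.span
            attrs = f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}";'
            fh.write(f"{t.chrom}\tsynthetic\tgene\t{lo}\t{hi}\t.\t{t.strand}\t.\t{attrs}\n")
            fh.write(f"{t.chrom}\tsynthetic\ttranscript\t{lo}\t{hi}\t.\t{t.strand}\t.\t{attrs}\n")
            for s, e in t.exons:
                fh.write(f"{t.chrom}\tsynthetic\texon\t{s}\t{e}\t.\t{t.strand}\t.\t{attrs}\n")


def write_bed12(transcripts, path) -> None:
    with open(path, "w") as fh:
        for t in transcripts:
            lo, hi = t.span
            sizes = ",".join(str(e - s + 1) for s, e in t.exons)
            starts = ",".join(str(s - lo) for s, e in t.exons)
            fh.write("\t".join(map(str, [
                t.chrom, lo - 1, hi, f"{t.gene_id}:{t.transcript_id}", 0,
                t.strand, lo - 1, hi, "0,0,0", len(t.exons), sizes, starts,
            ])) + "\n")


def write_constraint_bed(track: ConstraintTrack, path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, score in track.intervals:
            fh.write(f"{chrom}\t{start}\t{end}\t{score}\n")


def write_gene_list(gene_list, path) -> None:
    with open(path, "w") as fh:
        for g in sorted(gene_list):
            fh.write(g + "\n")


def write_reference(reference: SyntheticReference, outdir) -> dict:
    """Write FASTA/GTF/BED/gene-list files; returns the path map."""
    import os

    paths = {
        "fasta": os.path.join(outdir, "genome.fa"),
        "gtf": os.path.join(outdir, "genes.gtf"),
        "constraint": os.path.join(outdir, "constraint.bed"),
        "gene_list": os.path.join(outdir, "mendelian_genes.txt"),
    }
    write_fasta(reference.genome, paths["fasta"])
    write_gtf(reference.transcripts, paths["gtf"])
    write_constraint_bed(reference.constraint, paths["constraint"])
    write_gene_list(reference.gene_list, paths["gene_list"])
    return paths
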