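"""Clinical application layer: per-individual prioritization and spike-ins.

Prioritization mirrors the diagnostic funnel: deep-intronic variants in
protein-coding genes, restricted to a Mendelian-disease gene list, rare in
every population source, scorable (all five features present), and finally
thresholded and sorted by descending score. The spike-in benchmark plants one
known pathogenic variant into each background individual and reports the rank
of the spiked variant among all scored candidates (threshold-free); ties take
the pessimistic (largest) rank so diagnostic performance is never overstated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .variant_io import Variant
from .genomic_context import passes_rare_filter
from .classifier import PDIVASClassifier

PRIORITIZE_STAGES = ("input", "deep_intronic", "mendelian_gene", "rare",
                     "scored", "above_threshold")


@dataclass
class CohortSample:
    sample_id: str
    variants: list

    def __post_init__(self):
        keys = [v.key for v in self.variants]
        if len(set(keys)) != len(keys):
            raise ValueError(f"duplicate variant keys in sample {self.sample_id}")


@dataclass
class SimulatedPatient:
    """One spike-in: a background individual plus one causative variant."""

    sample_id: str
    spiked: Variant
    rank: int | None = None  # None = not yet ranked / undetected


def score_candidates(variants, pipeline, model: PDIVASClassifier) -> pd.DataFrame:
    """Score a variant list; unscorable (incomplete-feature) rows get NaN."""
    rows = []
    for v in variants:
        fv = pipeline.feature_vector(v)
        if fv.is_complete:
            score = model.score_one(fv)
        else:
            score = np.nan
        rows.append({"chrom": v.chrom, "pos": v.pos, "ref": v.ref,
                     "alt": v.alt, "gene_id": v.gene_id, "score": score})
    return pd.DataFrame(rows,
                        columns=["chrom", "pos", "ref", "alt", "gene_id", "score"])


def prioritize(sample: CohortSample, gene_list, pipeline, model,
               threshold: float, af_sources=("gnomAD", "KGP")) -> tuple:
    """Filter and rank one individual's variants.

    Returns (candidates DataFrame sorted by descending score, stage counts).
    Stage counts are ordered and non-increasing along the funnel; unscorable
    variants are logged out at the scoring stage.
    """
    counts = {}
    current = list(sample.variants)
    counts["input"] = len(current)

    kept = []
    for v in current:
        t = pipeline.locate(v)
        if t is None:
            continue
        call = pipeline.region(v)
        if call.zone == "deep_intronic":
            kept.append(v.with_gene(t.gene_id, t.transcript_id))
    current = kept
    counts["deep_intronic"] = len(current)

    current = [v for v in current if v.gene_id in gene_list]
    counts["mendelian_gene"] = len(current)

    current = [v for v in current if passes_rare_filter(v, af_sources)]
    counts["rare"] = len(current)

    table = score_candidates(current, pipeline, model)
    table = table.dropna(subset=["score"])
    counts["scored"] = len(table)

    table = table[table["score"] >= threshold]
    counts["above_threshold"] = len(table)
    table = table.sort_values("score", ascending=False, kind="mergesort")
    return table.reset_index(drop=True), counts


def simulate_patients(test_savs, cohort) -> list:
    """The full cross product of causative variants and background samples."""
    if not test_savs or not cohort:
        raise ValueError("need at least one causative variant and one sample")
    return [SimulatedPatient(sample.sample_id, sav)
            for sav in test_savs for sample in cohort]


def rank_of_score(spike_score: float, background_scores) -> int:
    """Pessimistic 1-based rank of the spike among background scores.

    Every background score >= the spike's (ties included) outranks it.
    """
    bg = np.asarray(background_scores, dtype=float)
    bg = bg[~np.isnan(bg)]
    return int((bg >= spike_score).sum()) + 1


def rank_causative(patient: SimulatedPatient, sample: CohortSample,
                   gene_list, pipeline, model,
                   af_sources=("gnomAD", "KGP"),
                   background_scores=None) -> int | None:
    """Rank the spiked variant among all scored candidates of the patient.

    The merged variant set runs through the same funnel as
    :func:`prioritize` but threshold-free: all scored candidates are ranked.
    Returns None (undetected) when the spiked variant itself is filtered out
    or unscorable. ``background_scores`` may carry the precomputed candidate
    scores of the background sample to avoid rescoring it per spike.
    """
    spiked = patient.spiked
    if any(v.key == spiked.key for v in sample.variants):
        raise ValueError("spiked variant already present in background sample")
    if background_scores is None:
        table, _ = prioritize(sample, gene_list, pipeline, model,
                              threshold=0.0, af_sources=af_sources)
        background_scores = table["score"].to_numpy()

    t = pipeline.locate(spiked)
    if t is None or pipeline.region(spiked).zone != "deep_intronic":
        return None
    if t.gene_id not in gene_list:
        return None
    if not passes_rare_filter(spiked, af_sources):
        return None
    fv = pipeline.feature_vector(spiked)
    if not fv.is_complete:
        return None
    spike_score = model.score_one(fv)
    return rank_of_score(spike_score, background_scores)


def undiagnosed_rate(ranks, cutoffs) -> dict:
    """Fraction of patients not diagnosed within each top-k cutoff.

    ``ranks`` holds 1-based ranks or None for undetected; an undetected
    causative variant counts beyond every cutoff.
    """
    n = len(ranks)
    if n == 0:
        raise ValueError("no ranks given")
    out = {}
    for c in cutoffs:
        missed = sum(1 for r in ranks if r is None or r > c)
        out[int(c)] = missed / n
    return out


def cohort_candidate_counts(samples, gene_list, pipeline, model,
                            thresholds, af_sources=("gnomAD", "KGP")) -> pd.DataFrame:
    """Mean candidates per individual at each threshold (cohort summary)."""
    score_lists = []
    for sample in samples:
        table, _ = prioritize(sample, gene_list, pipeline, model,
                              threshold=0.0, af_sources=af_sources)
        score_lists.append(table["score"].to_numpy())
    rows = []
    for t in thresholds:
        counts = [(s >= t).sum() for s in score_lists]
        rows.append({"threshold": float(t),
                     "mean_candidates": float(np.mean(counts))})
    return pd.DataFrame(rows)
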