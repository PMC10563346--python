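"""The five input features for deep-intronic pathogenicity scoring.

Three features come from masked splice-gain scoring over a pluggable
per-position splice-site scorer (the stand-in contract for a neural splice
predictor): the mean and max of the acceptor/donor delta gain scores and the
mean of the raw (pre-subtraction) gain scores. Delta scores at annotated
splice sites of the gene are masked to zero so that re-recognition of an
existing junction never counts as a gain. The fourth feature is a
maximum-entropy-style motif score of the variant's best created splice window,
normalized to [0, 1]; the fifth is a lookup into a regional splicing
constraint track.

Scores are searched within ``d`` bases of the variant (default 300).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .variant_io import ConstraintTrack, Variant

DEFAULT_SEARCH_DISTANCE = 300
DONOR_WINDOW = 9  # 3 exonic + 6 intronic bases
ACCEPTOR_WINDOW = 23  # 20 intronic + 3 exonic bases
DEFAULT_MES_CAP = 12.0  # bits; normalization cap for motif log-odds

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}

FEATURE_NAMES = (
    "spliceai_del_gain_mean",
    "spliceai_del_gain_max",
    "spliceai_raw_gain_mean",
    "consplice",
    "maxentscan",
)


def encode_seq(seq: str) -> np.ndarray:
    """Map a nucleotide string to integer codes; unknown bases become -1."""
    out = np.full(len(seq), -1, dtype=np.int64)
    for base, idx in _BASE_INDEX.items():
        out[np.frombuffer(seq.encode(), dtype=np.uint8) == ord(base)] = idx
    return out


# ---------------------------------------------------------------------------
# Motif models and scorers


@dataclass(frozen=True)
class MotifModel:
    """First-order (independent-position) donor/acceptor motif model.

    ``donor`` is a 9x4 and ``acceptor`` a 23x4 matrix of per-position base
    probabilities; ``background`` a length-4 probability vector; ``cap`` the
    normalization ceiling in bits used to map log-odds onto [0, 1].
    """

    donor: np.ndarray
    acceptor: np.ndarray
    background: np.ndarray
    cap: float = DEFAULT_MES_CAP

    def __post_init__(self):
        if self.donor.shape != (DONOR_WINDOW, 4):
            raise ValueError("donor model must be 9x4")
        if self.acceptor.shape != (ACCEPTOR_WINDOW, 4):
            raise ValueError("acceptor model must be 23x4")
        if not np.allclose(self.background.sum(), 1.0):
            raise ValueError("background must be a probability distribution")
        if not (np.allclose(self.donor.sum(axis=1), 1.0)
                and np.allclose(self.acceptor.sum(axis=1), 1.0)):
            raise ValueError("motif rows must be probability distributions")

    def matrix(self, kind: str) -> np.ndarray:
        if kind == "donor":
            return self.donor
        if kind == "acceptor":
            return self.acceptor
        raise ValueError(f"unknown kind {kind!r}")

    def log_odds(self, kind: str) -> np.ndarray:
        return np.log2(self.matrix(kind) / self.background[None, :])


def _consensus_matrix(consensus: str, strong: float, invariant_at=(),
                      invariant_p: float = 0.95) -> np.ndarray:
    m = np.full((len(consensus), 4), 0.0)
    for i, base in enumerate(consensus):
        p = invariant_p if i in invariant_at else strong
        m[i, :] = (1.0 - p) / 3.0
        m[i, _BASE_INDEX[base]] = p
    return m


def default_motif_model(cap: float = DEFAULT_MES_CAP) -> MotifModel:
    """A plausible human-like donor/acceptor PWM pair.

    Donor consensus CAG|GTAAGT with near-invariant GT at the first two
    intronic positions; acceptor: an 18-base pyrimidine-rich tract, a
    near-invariant AG, then 3 weakly-constrained exonic bases.
    """
    donor = _consensus_matrix("CAGGTAAGT", strong=0.70, invariant_at=(3, 4))
    acceptor = np.zeros((ACCEPTOR_WINDOW, 4))
    for i in range(18):  # polypyrimidine tract
        acceptor[i] = [0.12, 0.34, 0.09, 0.45]
    acceptor[18] = [0.95, 0.05 / 3, 0.05 / 3, 0.05 / 3]  # A
    acceptor[19] = [0.05 / 3, 0.05 / 3, 0.95, 0.05 / 3]  # G
    acceptor[20] = [0.25, 0.15, 0.45, 0.15]  # first exonic base, G-leaning
    acceptor[21] = [0.25, 0.25, 0.25, 0.25]
    acceptor[22] = [0.25, 0.25, 0.25, 0.25]
    return MotifModel(donor=donor, acceptor=acceptor,
                      background=np.full(4, 0.25), cap=cap)


def mes_score(window: str, model: MotifModel, kind: str) -> float:
    """Log-odds (bits) of a single motif window under the first-order model.

    With independent positions this is the per-position log-odds sum; negative
    values are permitted. Raises on wrong window length or non-ACGT bases.
    """
    expected = DONOR_WINDOW if kind == "donor" else ACCEPTOR_WINDOW
    lo = model.log_odds(kind)
    if len(window) != expected:
        raise ValueError(f"{kind} window must be {expected} bases, got {len(window)}")
    codes = encode_seq(window)
    if (codes < 0).any():
        raise ValueError(f"non-ACGT base in window {window!r}")
    return float(lo[np.arange(expected), codes].sum())


class SiteScorer:
    """Contract: per-position acceptor and donor splice-site scores in [0, 1].

    ``score(seq)`` returns two arrays the length of ``seq``. The donor score
    at position i evaluates the 9-mer whose junction places i as the last
    exonic base (3 exonic bases ending at i, 6 intronic after); the acceptor
    score at i evaluates the 23-mer placing i as the first exonic base
    (20 intronic before, 3 exonic from i). Positions whose window runs off
    either end score 0. Output must be deterministic for fixed input.
    """

    def score(self, seq: str, chrom: str | None = None,
              start: int | None = None) -> tuple:
        raise NotImplementedError


class PWMSiteScorer(SiteScorer):
    """Scores every position by sliding the motif PWMs over the sequence.

    Log-odds are clipped to [0, cap] and divided by cap so outputs live in
    [0, 1]; windows containing unknown bases score 0.
    """

    def __init__(self, model: MotifModel | None = None):
        self.model = model or default_motif_model()

    def _scan(self, codes: np.ndarray, kind: str) -> np.ndarray:
        lo = self.model.log_odds(kind)
        w = lo.shape[0]
        n = len(codes)
        out = np.zeros(n)
        if n < w:
            return out
        windows = np.lib.stride_tricks.sliding_window_view(codes, w)
        valid = (windows >= 0).all(axis=1)
        safe = np.where(windows >= 0, windows, 0)
        bits = lo[np.arange(w)[None, :], safe].sum(axis=1)
        bits = np.where(valid, bits, -np.inf)
        scores = np.clip(bits, 0.0, self.model.cap) / self.model.cap
        # window j covers codes[j : j+w]; map its score to the junction base
        if kind == "donor":
            anchor = 2  # last exonic base is window offset 2
        else:
            anchor = 20  # first exonic base is window offset 20
        out[anchor:anchor + len(scores)] = scores
        return out

    def score(self, seq: str, chrom=None, start=None) -> tuple:
        codes = encode_seq(seq.upper())
        return self._scan(codes, "acceptor"), self._scan(codes, "donor")


class TableSiteScorer(SiteScorer):
    """Looks up precomputed per-position scores from a table.

    Built from a DataFrame (or TSV) with columns chrom, pos (1-based), acc,
    don — the ingestion path for production neural-predictor output. Scoring
    requires the genomic frame (``chrom``, ``start``: 0-based offset of
    ``seq[0]``); positions absent from the table score 0.
    """

    def __init__(self, table):
        import pandas as pd

        if not hasattr(table, "itertuples"):
            table = pd.read_csv(table, sep="\t")
        self._acc = {}
        self._don = {}
        for row in table.itertuples(index=False):
            key = (row.chrom, int(row.pos))
            self._acc[key] = float(row.acc)
            self._don[key] = float(row.don)

    def score(self, seq: str, chrom=None, start=None) -> tuple:
        if chrom is None or start is None:
            raise ValueError("TableSiteScorer needs chrom and start context")
        n = len(seq)
        acc = np.zeros(n)
        don = np.zeros(n)
        for i in range(n):
            key = (chrom, start + i + 1)
            if key in self._acc:
                acc[i] = self._acc[key]
                don[i] = self._don[key]
        return acc, don


# ---------------------------------------------------------------------------
# Masked gain features


@dataclass(frozen=True)
class SpliceGainFeatures:
    """Acceptor/donor gain scores for one variant, masked and aggregated."""

    acc_delta_gain: float
    don_delta_gain: float
    acc_raw_gain: float
    don_raw_gain: float

    @property
    def delta_gain_max(self) -> float:
        return max(self.acc_delta_gain, self.don_delta_gain)

    @property
    def delta_gain_mean(self) -> float:
        return (self.acc_delta_gain + self.don_delta_gain) / 2.0

    @property
    def raw_gain_mean(self) -> float:
        return (self.acc_raw_gain + self.don_raw_gain) / 2.0

    @property
    def raw_gain_max(self) -> float:
        return max(self.acc_raw_gain, self.don_raw_gain)


def map_alt_to_ref(p: int, var_offset: int, ref_len: int, alt_len: int) -> int | None:
    """Map an alt-frame position to its ref-frame counterpart.

    Alleles are left-anchored: positions before the variant map identically,
    positions past the alt allele shift by the length difference, and inserted
    bases inside the allele have no reference counterpart (None).
    """
    if p < var_offset + min(ref_len, alt_len):
        return p
    if p >= var_offset + alt_len:
        return p + (ref_len - alt_len)
    return None


def map_ref_to_alt(p: int, var_offset: int, ref_len: int, alt_len: int) -> int | None:
    """Inverse of :func:`map_alt_to_ref` (deleted ref bases map to None)."""
    if p < var_offset + min(ref_len, alt_len):
        return p
    if p >= var_offset + ref_len:
        return p + (alt_len - ref_len)
    return None


def masked_gain_features(scorer: SiteScorer, ref_seq: str, alt_seq: str,
                         var_offset: int, annotated_sites=(),
                         d: int = DEFAULT_SEARCH_DISTANCE,
                         ref_len: int = 1, alt_len: int | None = None,
                         chrom: str | None = None,
                         window_start: int | None = None) -> SpliceGainFeatures:
    """Masked delta and raw splice-gain scores around one variant.

    ``ref_seq``/``alt_seq`` cover the variant ± d (clipped at contig ends);
    ``var_offset`` is the 0-based offset of the variant's anchor base in both
    frames (alleles are left-anchored, so the frames agree up to there).
    ``annotated_sites`` holds (ref-frame offset, kind) pairs for every
    annotated splice site of the gene inside the window.

    For each site kind, the raw gain is the maximum alt-sequence score within
    d of the variant; the delta at an alt position is the alt score minus the
    ref score at the corresponding ref position (0 where an inserted base has
    no counterpart), forced to 0 at annotated sites of the same kind, and the
    delta gain is the maximum masked delta floored at 0.
    """
    if alt_len is None:
        alt_len = len(alt_seq) - (len(ref_seq) - ref_len)
    if len(ref_seq) < var_offset + ref_len or len(alt_seq) < var_offset + alt_len:
        raise ValueError("sequence window shorter than the variant extent")
    acc_ref, don_ref = scorer.score(ref_seq, chrom=chrom, start=window_start)
    # alt frame keeps the same genomic anchor for table lookups
    acc_alt, don_alt = scorer.score(alt_seq, chrom=chrom, start=window_start)

    lo = max(0, var_offset - d)
    hi = min(len(alt_seq), var_offset + alt_len + d)  # exclusive
    positions = np.arange(lo, hi)

    # ref scores aligned into the alt frame (no counterpart -> 0)
    ref_idx = np.array([map_alt_to_ref(int(p), var_offset, ref_len, alt_len)
                        for p in positions], dtype=object)
    has_ref = np.array([i is not None and 0 <= i < len(ref_seq) for i in ref_idx])
    ref_pos = np.array([i if ok else 0 for i, ok in zip(ref_idx, has_ref)], dtype=int)

    masked = {"acceptor": np.zeros(len(positions), dtype=bool),
              "donor": np.zeros(len(positions), dtype=bool)}
    for site_ref, kind in annotated_sites:
        site_alt = map_ref_to_alt(int(site_ref), var_offset, ref_len, alt_len)
        if site_alt is not None and lo <= site_alt < hi:
            masked[kind][site_alt - lo] = True

    out = {}
    for kind, alt_arr, ref_arr in (("acceptor", acc_alt, acc_ref),
                                   ("donor", don_alt, don_ref)):
        alt_scores = alt_arr[positions]
        raw_gain = float(alt_scores.max()) if len(alt_scores) else 0.0
        ref_scores = np.where(has_ref, ref_arr[ref_pos], 0.0)
        delta = alt_scores - ref_scores
        delta[masked[kind]] = 0.0
        delta_gain = float(max(0.0, delta.max())) if len(delta) else 0.0
        out[kind] = (delta_gain, raw_gain)
    return SpliceGainFeatures(
        acc_delta_gain=out["acceptor"][0], don_delta_gain=out["donor"][0],
        acc_raw_gain=out["acceptor"][1], don_raw_gain=out["donor"][1],
    )


# ---------------------------------------------------------------------------
# Motif-based variant feature


def _window_max(seq: str, span_lo: int, span_hi: int, model: MotifModel,
                kind: str) -> float:
    """Max motif log-odds over every window overlapping [span_lo, span_hi)."""
    w = DONOR_WINDOW if kind == "donor" else ACCEPTOR_WINDOW
    best = -np.inf
    for start in range(max(0, span_lo - w + 1), min(span_hi, len(seq) - w + 1)):
        window = seq[start:start + w]
        if set(window) <= set("ACGT"):
            best = max(best, mes_score(window, model, kind))
    return best


def mes_variant_feature(ref_seq: str, alt_seq: str, var_offset: int,
                        ref_len: int = 1, alt_len: int = 1,
                        model: MotifModel | None = None) -> float:
    """Motif-gain feature in [0, 1] for one variant.

    For each site kind, every donor 9-mer / acceptor 23-mer overlapping the
    variant is scored in the ref and alt frames; with ``a`` the best alt and
    ``r`` the best ref window, a kind contributes 0 unless the variant creates
    score (a > r and a > 0, with a 1e-9-bit tie tolerance so equal-scoring
    windows reached by different summation orders never count as gains), in
    which case it contributes min(a, cap)/cap. The feature is the max over
    the two kinds.
    """
    model = model or default_motif_model()
    feature = 0.0
    tol = 1e-9  # bits; guards exact ties against float summation order
    for kind in ("donor", "acceptor"):
        r = _window_max(ref_seq, var_offset, var_offset + ref_len, model, kind)
        a = _window_max(alt_seq, var_offset, var_offset + alt_len, model, kind)
        if a <= r + tol or a <= tol:
            continue
        feature = max(feature, min(a, model.cap) / model.cap)
    return feature


# ---------------------------------------------------------------------------
# Constraint and assembly


def constraint_lookup(v: Variant, track: ConstraintTrack) -> float | None:
    """Constraint score of the interval covering the variant, else None.

    A variant with no covering interval is unscorable downstream (all five
    features are required), mirroring the exclusion of regions the constraint
    model does not cover.
    """
    return track.score_at(v.chrom, v.pos)


@dataclass(frozen=True)
class FeatureVector:
    """The five classifier inputs for one variant; None marks a missing value."""

    spliceai_del_gain_mean: float | None
    spliceai_del_gain_max: float | None
    spliceai_raw_gain_mean: float | None
    consplice: float | None
    maxentscan: float | None

    @property
    def is_complete(self) -> bool:
        return all(getattr(self, name) is not None for name in FEATURE_NAMES)

    def to_array(self) -> np.ndarray:
        return np.array([np.nan if getattr(self, n) is None else getattr(self, n)
                         for n in FEATURE_NAMES])


def assemble_features(v: Variant, gains: SpliceGainFeatures, mes: float | None,
                      constraint: float | None,
                      raw_gain_agg: str = "mean") -> FeatureVector:
    """Bundle the per-variant feature computations into one vector.

    ``raw_gain_agg`` selects mean (default) or max aggregation of the raw
    acceptor/donor gains; only vectors with all five values present are
    scorable downstream.
    """
    if raw_gain_agg == "mean":
        raw = gains.raw_gain_mean
    elif raw_gain_agg == "max":
        raw = gains.raw_gain_max
    else:
        raise ValueError(f"raw_gain_agg must be 'mean' or 'max', got {raw_gain_agg!r}")
    return FeatureVector(
        spliceai_del_gain_mean=gains.delta_gain_mean,
        spliceai_del_gain_max=gains.delta_gain_max,
        spliceai_raw_gain_mean=raw,
        consplice=constraint,
        maxentscan=mes,
    )
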