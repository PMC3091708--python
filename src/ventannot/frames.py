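"""Tiered reading-frame assignment.

The cascade mirrors a de novo EST annotation flow: (1) a strict homology
tier keeps queries with a protein hit at E <= 1e-6 and adopts the best
hit's frame; (2) a relaxed tier repeats the assignment at E <= 1e-2 for
the remainder; (3) contigs still unassigned are handed to a coding
scanner — an order-0 codon-usage log-odds model trained on the frames
called by tiers 1-2, scored over the best stop-free window in each of
the six frames. Scan calls require a conceptual peptide of at least 30
amino acids and a score above a null-calibrated threshold.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table

from .errors import ConfigError, InputError, TrainingError

BASES = "ACGT"
CODONS = [a + b + c for a in BASES for b in BASES for c in BASES]
STOP_CODONS = set(standard_dna_table.stop_codons)

# codon -> amino acid, stops rendered '*', anything ambiguous 'X'
CODON_TO_AA = dict(standard_dna_table.forward_table)
for _stop in STOP_CODONS:
    CODON_TO_AA[_stop] = "*"

# amino acid -> synonymous codon family (includes the '*' family)
AA_FAMILIES: dict[str, list[str]] = {}
for _codon in CODONS:
    AA_FAMILIES.setdefault(CODON_TO_AA[_codon], []).append(_codon)

FRAMES = (1, 2, 3, -1, -2, -3)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

DEFAULT_MIN_PEPTIDE = 30
TIER_STRICT = "strict"
TIER_RELAXED = "relaxed"
TIER_SCAN = "scan"
TIER_UNASSIGNED = "unassigned"


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def translate(sequence: str, frame: int) -> str:
    """Conceptual translation in one of the six frames.

    Negative frames read the reverse complement; codons containing any
    non-ACGT character translate to X; stops are rendered '*'.
    """
    if frame not in FRAMES:
        raise InputError(f"frame must be one of ±1..±3, got {frame}")
    seq = sequence.upper()
    if frame < 0:
        seq = reverse_complement(seq)
    off = abs(frame) - 1
    return "".join(
        CODON_TO_AA.get(seq[i:i + 3], "X")
        for i in range(off, len(seq) - 2, 3)
    )


def _frame_codons(sequence: str, frame: int) -> list[str]:
    """Codon list of a frame; masked (lowercase) bases are read as N so
    that masked regions never contribute coding signal."""
    seq = "".join(b if b.isupper() else "N" for b in sequence)
    if frame < 0:
        seq = reverse_complement(seq)
    off = abs(frame) - 1
    return [seq[i:i + 3] for i in range(off, len(seq) - 2, 3)]


@dataclass
class FrameCall:
    """A contig's assigned frame, the tier that assigned it, and the
    conceptual peptide. ``support`` is the best-hit E-value for homology
    tiers and the window log-odds score for the scan tier."""

    contig_id: str
    frame: int = 0
    tier: str = TIER_UNASSIGNED
    peptide: str = ""
    support: float = float("nan")

    @property
    def assigned(self) -> bool:
        return self.tier != TIER_UNASSIGNED


def validate_hit_ranks(hits: pd.DataFrame) -> None:
    """Check that within each query ranks are consecutive from 1 and
    E-values are non-decreasing with rank."""
    if hits.empty:
        return
    ranked = hits.assign(
        rank=hits.groupby("qseqid", sort=False).cumcount() + 1)
    for qid, grp in ranked.groupby("qseqid", sort=False):
        ev = grp["evalue"].to_numpy()
        if np.any(np.diff(ev) < 0):
            raise InputError(f"E-values not sorted by rank for query {qid}")


def assign_frames_homology(hits: pd.DataFrame, e_cutoff: float,
                           tier_label: str,
                           contigs: Optional[Mapping[str, str]] = None,
                           ) -> tuple[dict[str, FrameCall], set[str]]:
    """Assign frames from ranked homology hits.

    A query is assigned iff it has at least one hit with
    ``evalue <= e_cutoff``; the frame comes from the qualifying hit with
    the lowest E-value (ties broken by higher bit score, then lower
    rank). Returns the calls plus the set of unassigned query ids.
    """
    if e_cutoff <= 0:
        raise ConfigError(f"e_cutoff must be positive, got {e_cutoff}")
    hits = hits.assign(rank=hits.groupby("qseqid", sort=False).cumcount() + 1)
    validate_hit_ranks(hits)

    calls: dict[str, FrameCall] = {}
    qualifying = hits[hits["evalue"] <= e_cutoff]
    if not qualifying.empty:
        best = (qualifying
                .sort_values(["evalue", "bitscore", "rank"],
                             ascending=[True, False, True], kind="mergesort")
                .groupby("qseqid", sort=False)
                .head(1))
        for row in best.itertuples():
            frame = int(row.sframe)
            peptide = ""
            if contigs is not None and row.qseqid in contigs:
                peptide = translate(contigs[row.qseqid], frame)
            calls[row.qseqid] = FrameCall(
                contig_id=row.qseqid, frame=frame, tier=tier_label,
                peptide=peptide, support=float(row.evalue))
    unassigned = set(hits["qseqid"].unique()) - set(calls)
    return calls, unassigned


@dataclass
class CodonModel:
    """Order-0 codon log-odds model against a mononucleotide background.

    ``log_odds[c] = ln(p_coding(c) / p_background(c))`` where the coding
    frequencies come from pseudocount-smoothed codon counts and the
    background codon probability is the product of the base frequencies
    (which sums to 1 over the 64 codons).
    """

    log_odds: dict[str, float]
    background: dict[str, float]
    pseudocount: float
    training_codons: int
    counts: dict[str, int] = field(default_factory=dict)

    def family_frequencies(self) -> dict[str, float]:
        """Codon frequencies normalised within each synonymous family
        (relative synonymous usage)."""
        freqs: dict[str, float] = {}
        for fam in AA_FAMILIES.values():
            tot = sum(self.counts.get(c, 0) + self.pseudocount for c in fam)
            for c in fam:
                freqs[c] = (self.counts.get(c, 0) + self.pseudocount) / tot
        return freqs

    def codon_frequencies(self, smoothed: bool = False) -> dict[str, float]:
        """Estimated codon frequency table over all 64 codons (sums to 1),
        comparable with a planted joint usage table. Unsmoothed by
        default so unobserved codons (e.g. stops) report exactly 0."""
        if smoothed:
            denom = self.training_codons + 64 * self.pseudocount
            return {c: (self.counts.get(c, 0) + self.pseudocount) / denom
                    for c in CODONS}
        total = self.training_codons
        return {c: self.counts.get(c, 0) / total for c in CODONS}


def _longest_stop_free(codons: Sequence[str]) -> list[str]:
    best: list[str] = []
    current: list[str] = []
    for c in codons:
        if c in STOP_CODONS:
            if len(current) > len(best):
                best = current
            current = []
        else:
            current.append(c)
    return current if len(current) > len(best) else best


def train_codon_model(contigs: Mapping[str, str],
                      calls: Mapping[str, FrameCall],
                      pseudocount: float = 1.0,
                      background: Optional[dict[str, float]] = None,
                      ) -> CodonModel:
    """Estimate codon usage from frame-called contigs (tiers 1-2).

    Each training contig is read in its called frame and the longest
    stop-free codon stretch is counted; codons containing N (or masked
    bases) are skipped. The background mononucleotide model defaults to
    the base composition of the training contigs.
    """
    if pseudocount <= 0:
        raise ConfigError("pseudocount must be positive")
    counts = {c: 0 for c in CODONS}
    base_counts = {b: 0 for b in BASES}
    total = 0
    for cid, call in calls.items():
        if call.tier not in (TIER_STRICT, TIER_RELAXED):
            continue
        seq = contigs[cid]
        for b in seq.upper():
            if b in base_counts:
                base_counts[b] += 1
        stretch = _longest_stop_free(_frame_codons(seq, call.frame))
        for codon in stretch:
            if codon in counts:  # skips any codon with N
                counts[codon] += 1
                total += 1
    if total == 0:
        raise TrainingError("no training codons from tier-1/2 calls")
    if background is None:
        bt = sum(base_counts.values())
        background = {b: base_counts[b] / bt for b in BASES}
    denom = total + 64 * pseudocount
    log_odds = {}
    for codon in CODONS:
        p_cod = (counts[codon] + pseudocount) / denom
        p_bg = (background[codon[0]] * background[codon[1]]
                * background[codon[2]])
        log_odds[codon] = math.log(p_cod / p_bg)
    return CodonModel(log_odds=log_odds, background=background,
                      pseudocount=pseudocount, training_codons=total,
                      counts=counts)


def _best_window(sequence: str, model: CodonModel, min_peptide: int,
                 ) -> tuple[float, int, int]:
    """Best-scoring stop-free window of >= min_peptide codons across the
    six frames. Returns (score, frame, window_codons); score is -inf if
    no window qualifies. N codons contribute 0 and count toward length."""
    best = (-math.inf, 0, 0)
    lo = model.log_odds
    for frame in FRAMES:
        codons = _frame_codons(sequence, frame)
        start = 0
        for i in range(len(codons) + 1):
            if i == len(codons) or codons[i] in STOP_CODONS:
                window = codons[start:i]
                if len(window) >= min_peptide:
                    score = sum(lo.get(c, 0.0) for c in window)
                    if score > best[0]:
                        best = (score, frame, len(window))
                start = i + 1
    return best


def scan_coding(contig_id: str, sequence: str, model: CodonModel,
                min_peptide: int = DEFAULT_MIN_PEPTIDE,
                score_threshold: float = 0.0) -> FrameCall:
    """Codon-usage coding scan over six frames.

    Calls the frame of the best stop-free window iff the window spans at
    least ``min_peptide`` codons and its summed log-odds reaches
    ``score_threshold``; otherwise the contig stays unassigned. Windows
    shorter than the peptide floor are never candidates.
    """
    if len(sequence) < 3 * min_peptide:
        return FrameCall(contig_id=contig_id)
    score, frame, _n = _best_window(sequence, model, min_peptide)
    if frame == 0 or score < score_threshold:
        return FrameCall(contig_id=contig_id)
    return FrameCall(contig_id=contig_id, frame=frame, tier=TIER_SCAN,
                     peptide=translate(sequence, frame), support=score)


def calibrate_null_threshold(model: CodonModel,
                             lengths: Sequence[int],
                             n_sims: int = 1000,
                             percentile: float = 99.0,
                             min_peptide: int = DEFAULT_MIN_PEPTIDE,
                             seed: int = 0) -> float:
    """Score threshold as a percentile of the score distribution on
    sequences simulated from the model's background; lengths are drawn
    from the supplied length pool so calibration matches the inputs."""
    rng = np.random.default_rng(seed)
    bases = np.array(list(BASES))
    probs = np.array([model.background[b] for b in BASES])
    probs = probs / probs.sum()
    lengths = np.asarray(lengths, dtype=int)
    scores = np.empty(n_sims)
    for i in range(n_sims):
        length = int(lengths[rng.integers(len(lengths))])
        seq = "".join(rng.choice(bases, size=length, p=probs))
        scores[i] = _best_window(seq, model, min_peptide)[0]
    finite = scores[np.isfinite(scores)]
    if finite.size == 0:
        return 0.0
    # 'higher' keeps the threshold at an attained order statistic
    return float(np.percentile(scores, percentile, method="higher"))


@dataclass
class CascadeParams:
    tier1_e: float = 1e-6
    tier2_e: float = 1e-2
    min_peptide: int = DEFAULT_MIN_PEPTIDE
    pseudocount: float = 1.0
    score_threshold: Optional[float] = None  # None -> null calibration
    null_sims: int = 1000
    null_percentile: float = 99.0
    seed: int = 0


@dataclass
class CascadeResult:
    calls: dict[str, FrameCall]
    accounting: dict[str, int]
    model: Optional[CodonModel]
    score_threshold: Optional[float]

    def tier_ids(self, tier: str) -> set[str]:
        return {cid for cid, c in self.calls.items() if c.tier == tier}


def run_cascade(contigs: Mapping[str, str],
                hits_tier1: pd.DataFrame,
                hits_tier2: Optional[pd.DataFrame] = None,
                params: Optional[CascadeParams] = None) -> CascadeResult:
    """Run the three tiers; every contig lands in exactly one bucket.

    ``hits_tier2`` defaults to the tier-1 table re-screened at the
    relaxed cutoff (the re-query against the same database).
    """
    params = params or CascadeParams()
    if hits_tier2 is None:
        hits_tier2 = hits_tier1
    ids = set(contigs)

    t1 = hits_tier1[hits_tier1["qseqid"].isin(ids)]
    calls, _ = assign_frames_homology(t1, params.tier1_e, TIER_STRICT, contigs)

    remaining = ids - set(calls)
    t2 = hits_tier2[hits_tier2["qseqid"].isin(remaining)]
    tier2_calls, _ = assign_frames_homology(t2, params.tier2_e, TIER_RELAXED,
                                            contigs)
    calls.update(tier2_calls)

    remaining = sorted(ids - set(calls))
    model = None
    threshold = params.score_threshold
    if any(c.tier in (TIER_STRICT, TIER_RELAXED) for c in calls.values()):
        model = train_codon_model({cid: contigs[cid] for cid in calls},
                                  calls, params.pseudocount)
        if threshold is None:
            pool = [len(contigs[cid]) for cid in remaining] or \
                   [len(s) for s in contigs.values()]
            threshold = calibrate_null_threshold(
                model, pool, n_sims=params.null_sims,
                percentile=params.null_percentile,
                min_peptide=params.min_peptide, seed=params.seed)
        for cid in remaining:
            calls[cid] = scan_coding(cid, contigs[cid], model,
                                     params.min_peptide, threshold)
    else:
        warnings.warn("no tier-1/2 frame calls: codon model untrainable, "
                      "coding scan skipped", stacklevel=2)
        for cid in remaining:
            calls[cid] = FrameCall(contig_id=cid)

    accounting = {
        TIER_STRICT: sum(c.tier == TIER_STRICT for c in calls.values()),
        TIER_RELAXED: sum(c.tier == TIER_RELAXED for c in calls.values()),
        TIER_SCAN: sum(c.tier == TIER_SCAN for c in calls.values()),
        TIER_UNASSIGNED: sum(not c.assigned for c in calls.values()),
    }
    accounting["total_translated"] = (accounting[TIER_STRICT]
                                      + accounting[TIER_RELAXED]
                                      + accounting[TIER_SCAN])
    return CascadeResult(calls=calls, accounting=accounting, model=model,
                         score_threshold=threshold)


def calls_table(calls: Mapping[str, FrameCall]) -> pd.DataFrame:
    rows = [(c.contig_id, c.tier, c.frame, c.support, len(c.peptide))
            for c in (calls[k] for k in sorted(calls))]
    return pd.DataFrame(rows, columns=["contig_id", "tier", "frame",
                                       "support", "peptide_length"])
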