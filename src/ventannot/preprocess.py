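"""Contig cleanup before frame annotation.

Three operations applied in a fixed order: adapter trimming (terminal
occurrences removed, internal occurrences flagged), terminal poly-A /
poly-T masking (lowercased, excluded from the effective length), and a
minimum-length gate (default 40 bp, the assembler's minimum consensus
length; a contig of exactly 40 effective bases is kept).
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

from .errors import ConfigError

DEFAULT_MIN_LENGTH = 40
DEFAULT_MIN_POLYA_RUN = 10

KEPT = "kept"
DISCARDED_SHORT = "discarded_short"
DISCARDED_EMPTY = "discarded_empty"


@dataclass
class Contig:
    """An assembled transcript sequence.

    Lowercase bases are masked (poly-A/T); ``read_count == 1`` marks a
    singleton.
    """

    id: str
    sequence: str
    read_count: int = 1
    status: str = KEPT

    @property
    def effective_length(self) -> int:
        """Number of unmasked (uppercase) bases."""
        return sum(1 for b in self.sequence if not b.islower())


@dataclass
class TrimEvent:
    """One adapter action; coordinates are 0-based half-open, in the
    coordinates of the sequence at the time of the action."""

    contig_id: str
    action: str  # trim_leading | trim_trailing | internal_flag
    start: int
    end: int


@dataclass
class PreprocessResult:
    kept: list[Contig] = field(default_factory=list)
    discarded: list[Contig] = field(default_factory=list)
    events: list[TrimEvent] = field(default_factory=list)
    # removed leading/trailing base counts per contig, for coordinate lifting
    trim_offsets: dict[str, tuple[int, int]] = field(default_factory=dict)


def _hamming_le(a: str, b: str, limit: int) -> bool:
    if len(a) != len(b):
        return False
    mism = 0
    for x, y in zip(a, b):
        if x != y:
            mism += 1
            if mism > limit:
                return False
    return True


def trim_adapters(contig: Contig, adapters, max_mismatch: int = 1,
                  ) -> tuple[Contig, list[TrimEvent]]:
    """Remove terminal adapter occurrences; flag internal ones.

    Terminal matches tolerate up to ``max_mismatch`` substitutions
    (Hamming, no indels). Repeated terminal occurrences are all removed,
    which makes the operation idempotent. Internal occurrences are
    reported but the sequence is left intact.
    """
    adapters = list(adapters)
    if not adapters:
        raise ConfigError("at least one adapter sequence is required")
    for ad in adapters:
        if len(ad) < 10:
            raise ConfigError(f"adapter shorter than 10 nt: {ad!r}")
    seq = contig.sequence
    events: list[TrimEvent] = []

    changed = True
    while changed:
        changed = False
        for ad in adapters:
            la = len(ad)
            if len(seq) >= la and _hamming_le(seq[:la].upper(), ad.upper(), max_mismatch):
                events.append(TrimEvent(contig.id, "trim_leading", 0, la))
                seq = seq[la:]
                changed = True
            if len(seq) >= la and _hamming_le(seq[-la:].upper(), ad.upper(), max_mismatch):
                events.append(TrimEvent(contig.id, "trim_trailing", len(seq) - la, len(seq)))
                seq = seq[:-la]
                changed = True

    # internal occurrences: report, do not cut
    for ad in adapters:
        la = len(ad)
        adu = ad.upper()
        for pos in range(1, len(seq) - la):
            if _hamming_le(seq[pos:pos + la].upper(), adu, max_mismatch):
                events.append(TrimEvent(contig.id, "internal_flag", pos, pos + la))

    status = contig.status
    if not seq:
        status = DISCARDED_EMPTY
    return replace(contig, sequence=seq, status=status), events


def mask_polya(contig: Contig, min_run: int = DEFAULT_MIN_POLYA_RUN) -> Contig:
    """Lowercase terminal A-runs (3') and T-runs (5') of length >= min_run.

    A fully masked contig is marked ``discarded_empty``. Internal
    homopolymer runs are untouched.
    """
    if min_run < 5:
        raise ConfigError(f"min_run must be >= 5, got {min_run}")
    seq = contig.sequence
    n = len(seq)

    head = 0
    while head < n and seq[head].upper() == "T":
        head += 1
    tail = 0
    while tail < n - head and seq[n - 1 - tail].upper() == "A":
        tail += 1

    out = seq
    if tail >= min_run:
        out = out[:n - tail] + out[n - tail:].lower()
    if head >= min_run:
        out = out[:head].lower() + out[head:]
    new = replace(contig, sequence=out)
    if new.effective_length == 0 and new.status == KEPT:
        new = replace(new, status=DISCARDED_EMPTY)
    return new


def length_filter(contigs, min_len: int = DEFAULT_MIN_LENGTH,
                  ) -> tuple[list[Contig], list[Contig]]:
    """Partition contigs by effective length; the boundary length is kept.

    Contigs already flagged discarded (empty) go to the discarded
    partition unchanged.
    """
    if min_len < 1:
        raise ConfigError(f"min_len must be >= 1, got {min_len}")
    kept: list[Contig] = []
    discarded: list[Contig] = []
    for c in contigs:
        if c.status == DISCARDED_EMPTY:
            discarded.append(c)
        elif c.effective_length < min_len:
            discarded.append(replace(c, status=DISCARDED_SHORT))
        else:
            kept.append(c)
    return kept, discarded


def preprocess_contigs(contigs, adapters, max_mismatch: int = 1,
                       min_polya_run: int = DEFAULT_MIN_POLYA_RUN,
                       min_len: int = DEFAULT_MIN_LENGTH) -> PreprocessResult:
    """The composed pass: trim -> mask -> length gate.

    Every input contig appears exactly once across kept/discarded, and
    re-running the pass on the kept set is a no-op.
    """
    result = PreprocessResult()
    processed = []
    for contig in contigs:
        original_len = len(contig.sequence)
        trimmed, events = trim_adapters(contig, adapters, max_mismatch)
        result.events.extend(events)
        leading = sum(e.end - e.start for e in events if e.action == "trim_leading")
        trailing = original_len - leading - len(trimmed.sequence)
        result.trim_offsets[contig.id] = (leading, trailing)
        processed.append(mask_polya(trimmed, min_polya_run))
    result.kept, result.discarded = length_filter(processed, min_len)
    return result


def events_table(events):
    """Trim events as a plain table (contig id, action, start, end)."""
    import pandas as pd

    return pd.DataFrame(
        [(e.contig_id, e.action, e.start, e.end) for e in events],
        columns=["contig_id", "action", "start", "end"],
    )
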