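"""AGAA binding-site scoring and PTC/NMD consequence prediction.

Tra2-family splicing factors recognise short AGAA/GAA-rich exonic
enhancer elements.  A random 256-bp stretch of sequence contains one
AGAA on average, so the binding-site frequency of an exon is calibrated
to that length:

    F = 256 * count / exon_length

(one site in a 256-bp exon gives F = 1).  Candidate exons must carry at
least one site and F above a threshold (default 1.5) to survive the
motif filter.

For a surviving cassette exon, skipping consequences are predicted by
rebuilding the exon-skipped mRNA, translating from the original start
codon and counting premature termination codons (PTCs) — in-frame stops
appearing strictly upstream of the original stop.  Nonsense-mediated
decay is predicted by the classical rule: the first PTC must sit more
than 50 nt upstream of the last exon-exon junction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .splicing import ExonCandidate
from .synthetic import MOTIF_CALIBRATION_BP, TranscriptModel

logger = logging.getLogger("exonscreen")

_STOPS = {"TAA", "TAG", "TGA"}


@dataclass
class MotifScore:
    motif: str
    count: int
    exon_length: int
    frequency: float


@dataclass
class NmdCall:
    """Predicted consequence of skipping one exon."""

    skipped_exon_index: int
    n_ptcs: int
    first_ptc_pos: int | None
    distance_to_last_junction: int | None
    nmd_predicted: bool


def count_motif(seq: str, motif: str = "AGAA") -> int:
    """Count (possibly overlapping) sense-strand occurrences of ``motif``.

    Case-insensitive; an N never matches anything.
    """
    if not motif:
        raise ValueError("motif must be non-empty")
    seq = seq.upper()
    motif = motif.upper()
    if "N" in motif:
        return 0
    count, start = 0, 0
    while True:
        i = seq.find(motif, start)
        if i < 0:
            return count
        count += 1
        start = i + 1  # overlapping matches count


def motif_frequency(count: int, exon_length: int, motif_len: int = 4,
                    convention: str = "calibrated") -> float:
    """Binding-site frequency of an exon.

    ``"calibrated"`` (default) uses F = 256*count/length, anchored so
    that one site per 256 nt equals a frequency of 1; ``"literal"``
    uses count*length/256 (the two agree only at length 256).
    """
    if exon_length < motif_len:
        raise ValueError("exon shorter than the motif")
    if count < 0:
        raise ValueError("count must be non-negative")
    if convention == "calibrated":
        return MOTIF_CALIBRATION_BP * count / exon_length
    if convention == "literal":
        return count * exon_length / MOTIF_CALIBRATION_BP
    raise ValueError(f"unknown frequency convention {convention!r}")


def score_motif(seq: str, motif: str = "AGAA",
                convention: str = "calibrated") -> MotifScore:
    c = count_motif(seq, motif)
    return MotifScore(motif=motif, count=c, exon_length=len(seq),
                      frequency=motif_frequency(c, len(seq), len(motif),
                                                convention))


def apply_motif_filter(cands: list[ExonCandidate], min_count: int = 1,
                       min_freq: float = 1.5, motif: str = "AGAA",
                       convention: str = "calibrated",
                       ) -> list[ExonCandidate]:
    """Keep candidates with >= min_count motif sites and F >= min_freq.

    Populates agaa_count / agaa_freq from each candidate's exon
    sequence; candidates without a sequence are dropped with a warning.
    """
    survivors = []
    for c in cands:
        if not c.exon_seq:
            logger.warning("candidate %s dropped: no exon sequence",
                           c.probeset_id)
            continue
        score = score_motif(c.exon_seq, motif, convention)
        c.agaa_count = score.count
        c.agaa_freq = score.frequency
        c.exon_length = score.exon_length
        c.passed_motif = score.count >= min_count and score.frequency >= min_freq
        if c.passed_motif:
            survivors.append(c)
    return survivors


# ---------------------------------------------------------------------------
# PTC / NMD prediction
# ---------------------------------------------------------------------------

def _scan_stops(seq: str, start: int, end: int) -> list[int]:
    """In-frame stop codon positions in seq[start:end), frame of ``start``."""
    return [p for p in range(start, min(end, len(seq) - 2), 3)
            if seq[p: p + 3] in _STOPS]


def predict_ptcs(tx: TranscriptModel, skip_exon_index: int,
                 junction_rule_nt: int = 50) -> NmdCall:
    """Predict PTCs and NMD susceptibility of skipping one exon.

    The exon-skipped mRNA is rebuilt, translation starts at the original
    start codon (skipping the exon that carries it is an error), and
    stops encountered strictly before the position of the original stop
    codon — mapped into the new transcript, or end-of-sequence if the
    stop itself was skipped — count as PTCs.  NMD is predicted when the
    first PTC lies more than ``junction_rule_nt`` upstream of the last
    exon-exon junction of the skipped transcript.
    """
    if not 0 <= skip_exon_index < tx.n_exons:
        raise ValueError(f"exon index {skip_exon_index} out of range")
    start_exon = tx.exon_containing(tx.cds_start)
    if skip_exon_index == start_exon:
        raise ValueError("cannot skip the exon containing the start codon")
    skip_lo, skip_hi = tx.exons[skip_exon_index]
    skip_len = skip_hi - skip_lo

    new_seq = "".join(s for i, s in enumerate(tx.sequences)
                      if i != skip_exon_index)

    def remap(pos: int) -> int:
        return pos - skip_len if pos >= skip_hi else pos

    new_start = remap(tx.cds_start)
    if skip_lo <= tx.cds_stop < skip_hi:
        old_stop_new = len(new_seq)  # original stop removed: all stops premature
    else:
        old_stop_new = remap(tx.cds_stop)

    ptcs = _scan_stops(new_seq, new_start, old_stop_new)
    n_ptcs = len(ptcs)
    first = ptcs[0] if ptcs else None

    remaining = [(s, e) for i, (s, e) in enumerate(tx.exons)
                 if i != skip_exon_index]
    cum, junctions = 0, []
    for s, e in remaining[:-1]:
        cum += e - s
        junctions.append(cum)
    last_junction = junctions[-1] if junctions else None

    distance = None
    nmd = False
    if first is not None and last_junction is not None:
        distance = last_junction - first
        nmd = distance > junction_rule_nt
    return NmdCall(
        skipped_exon_index=skip_exon_index,
        n_ptcs=n_ptcs,
        first_ptc_pos=first,
        distance_to_last_junction=distance,
        nmd_predicted=nmd,
    )


def nmd_report(models: list[TranscriptModel], cands: list[ExonCandidate],
               junction_rule_nt: int = 50) -> list[tuple[ExonCandidate, NmdCall | None]]:
    """predict_ptcs for each candidate exon that can legally be skipped."""
    by_id = {m.transcript_id: m for m in models}
    out = []
    for c in cands:
        tx = by_id.get(c.transcript_id)
        if tx is None:
            out.append((c, None))
            continue
        try:
            out.append((c, predict_ptcs(tx, c.exon_index, junction_rule_nt)))
        except ValueError:
            out.append((c, None))
    return out
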