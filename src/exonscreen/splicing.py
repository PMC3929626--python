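"""Exon-level inclusion screening via the splicing index.

Exon arrays do not measure isoforms directly; inclusion is proxied by
the splicing index SI = exon signal / parent-gene signal, computed per
sample on the linear scale.  The group-mean SI is the inclusion index
PSI, and candidates are screened on the KO/CTRL PSI ratio: exons inside
the (2/3, 1.5) ratio window or with a two-sample t-test p above the cut
are dropped, and exons sitting on transcripts already called
differentially expressed are flagged as expression artifacts and
excluded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import ttest_ind

from .diffexpr import GroupDesign, moderated_t_table
from .preprocess import EXON, GENE, SummaryMatrix

logger = logging.getLogger("exonscreen")

PSI_LOW_CUT = 2.0 / 3.0
PSI_HIGH_CUT = 1.5


@dataclass
class ExonCandidate:
    """One screened exon (mirrors the candidate-table columns)."""

    probeset_id: str
    transcript_id: str
    exon_index: int
    psi_ctrl: float
    psi_ko: float
    psi_ratio: float
    p_value: float
    exon_length: int = 0
    agaa_count: int = 0
    agaa_freq: float = 0.0
    probeset_seq: str = ""
    exon_seq: str = ""
    passed_initial: bool = False
    de_overlap: bool = False
    passed_motif: bool = False


@dataclass
class FilterCounts:
    """Survivor counts after each stage of the candidate cascade."""

    total: int = 0
    after_initial: int = 0
    after_de_exclusion: int = 0
    after_motif: int = 0
    details: dict = field(default_factory=dict)


def compute_psi_ratio(exon_s: SummaryMatrix, gene_s: SummaryMatrix,
                      design: GroupDesign, *, test: str = "student",
                      ) -> list[ExonCandidate]:
    """Per-exon PSI ratio and two-group test on log2 splicing indices.

    Exons whose parent gene was removed by the expression filter are
    dropped (with a logged count) rather than treated as errors.  The
    per-exon p-value comes from a two-sided two-sample Student's t on
    the per-sample log2 SI values; ``test="moderated"`` switches to the
    empirical-Bayes moderated t.
    """
    ctrl, ko = design.split(exon_s.values.columns)
    gene_by_tx = {}
    for fid in gene_s.values.index:
        row = gene_s.meta.loc[fid]
        if row["kind"] == GENE:
            gene_by_tx[str(row["feature_id"])] = fid
    si_rows, kept_ids, dropped = [], [], 0
    for fid in exon_s.values.index:
        row = exon_s.meta.loc[fid]
        if row["kind"] != EXON:
            continue
        gene_fid = gene_by_tx.get(str(row["feature_id"]))
        if gene_fid is None:
            dropped += 1
            continue
        si_rows.append(exon_s.values.loc[fid] - gene_s.values.loc[gene_fid])
        kept_ids.append(fid)
    if dropped:
        logger.info("compute_psi_ratio dropped %d exons without a retained "
                    "parent gene", dropped)
    if not kept_ids:
        return []
    log_si = pd.DataFrame(si_rows, index=kept_ids)
    si = 2.0 ** log_si
    psi_c = si[ctrl].mean(axis=1)
    psi_k = si[ko].mean(axis=1)
    if test == "student":
        _, p = ttest_ind(log_si[ko], log_si[ctrl], axis=1, equal_var=True)
        p = np.asarray(p)
    elif test == "moderated":
        sub = SummaryMatrix(log_si, exon_s.meta.loc[kept_ids])
        p = np.array([r.p_value for r in moderated_t_table(sub, design)])
    else:
        raise ValueError(f"unknown exon test {test!r}")
    p = np.where(np.isnan(p), 1.0, p)
    cands = []
    for i, fid in enumerate(kept_ids):
        row = exon_s.meta.loc[fid]
        cands.append(ExonCandidate(
            probeset_id=str(fid),
            transcript_id=str(row["feature_id"]),
            exon_index=int(row["exon_index"]),
            psi_ctrl=float(psi_c.iloc[i]),
            psi_ko=float(psi_k.iloc[i]),
            psi_ratio=float(psi_k.iloc[i] / psi_c.iloc[i]),
            p_value=float(p[i]),
        ))
    return cands


def filter_splicing_candidates(cands: list[ExonCandidate],
                               de_list: list[str],
                               low_cut: float = PSI_LOW_CUT,
                               high_cut: float = PSI_HIGH_CUT,
                               p_cut: float = 0.05,
                               ) -> tuple[list[ExonCandidate], FilterCounts]:
    """Apply the ratio-window + p-value filter, then the DE-artifact
    exclusion.

    Keeps exons with psi_ratio <= low_cut or >= high_cut and p <= p_cut;
    among those, exons on a differentially expressed transcript are
    flagged ``de_overlap`` and removed (expression change masquerading
    as splicing).  Returns survivors plus per-stage counts.
    """
    de_set = set(de_list)
    counts = FilterCounts(total=len(cands))
    survivors = []
    for c in cands:
        outside = c.psi_ratio <= low_cut or c.psi_ratio >= high_cut
        c.passed_initial = bool(outside and c.p_value <= p_cut)
        if not c.passed_initial:
            continue
        counts.after_initial += 1
        c.de_overlap = c.transcript_id in de_set
        if c.de_overlap:
            continue
        counts.after_de_exclusion += 1
        survivors.append(c)
    return survivors, counts


def attach_sequences(cands: list[ExonCandidate], sequences: dict[str, str],
                     probeset_region: int = 96) -> list[ExonCandidate]:
    """Fill exon_seq/exon_length (and a central probeset region) from a
    ``"transcript|exonIndex" -> sequence`` mapping."""
    for c in cands:
        seq = sequences.get(f"{c.transcript_id}|{c.exon_index}")
        if seq is None:
            continue
        c.exon_seq = seq.upper()
        c.exon_length = len(seq)
        if len(seq) > probeset_region:
            lo = (len(seq) - probeset_region) // 2
            c.probeset_seq = c.exon_seq[lo: lo + probeset_region]
        else:
            c.probeset_seq = c.exon_seq
    return cands
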