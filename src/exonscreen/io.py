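"""File formats, configuration and the end-to-end screen.

Tables travel as TSV (candidate tables use the supplementary-dataset
column dialect: PROBESET_ID, PSI[KOvsCTRL], p-value, EXON_LENGTH,
AGAA_COUNT, AGAA_FREQ, PROBESET_SEQ, EXON_SEQ plus flag columns);
sequences as FASTA with ``transcriptID|exonIndex`` headers; the config
as a flat key=value text file.  Coordinates are 0-based half-open
internally and 1-based inclusive in human-readable reports.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field, fields
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import diffexpr, motifs, preprocess, splicing, synthetic
from .diffexpr import GroupDesign
from .preprocess import ProbeMatrix
from .splicing import ExonCandidate
from .synthetic import SimulationDesign, TranscriptModel

logger = logging.getLogger("exonscreen")

CANDIDATE_COLUMNS = [
    "PROBESET_ID", "PSI[KOvsCTRL]", "p-value", "EXON_LENGTH",
    "AGAA_COUNT", "AGAA_FREQ", "PROBESET_SEQ", "EXON_SEQ",
]
FLAG_COLUMNS = ["TRANSCRIPT_ID", "EXON_INDEX", "PSI_CTRL", "PSI_KO",
                "PASSED_INITIAL", "DE_OVERLAP", "PASSED_MOTIF"]


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """FASTA -> {id: sequence}; ids cut at first whitespace, multi-line
    records concatenated.  Structural problems raise with a line number."""
    path = Path(path)
    with open(path) as fh:
        lines = fh.readlines()
    seen_header = False
    for lineno, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        if line.startswith(">"):
            if not line[1:].strip():
                raise ValueError(f"{path}:{lineno}: FASTA header without an id")
            seen_header = True
        elif not seen_header:
            raise ValueError(f"{path}:{lineno}: sequence data before any header")
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(path, "fasta")}


def write_exon_fasta(models: list[TranscriptModel], path: str | Path) -> None:
    """One record per exon, headers ``transcriptID|exonIndex``."""
    records = [
        SeqRecord(Seq(seq), id=f"{m.transcript_id}|{i}", description="")
        for m in models for i, seq in enumerate(m.sequences)
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# matrices and tables
# ---------------------------------------------------------------------------

def write_probe_matrix(m: ProbeMatrix, prefix: str | Path) -> None:
    """TSVs: <prefix>.intensities.tsv (probes x samples),
    <prefix>.probe_map.tsv, <prefix>.probeset_map.tsv."""
    prefix = Path(prefix)
    m.values.to_csv(f"{prefix}.intensities.tsv", sep="\t",
                    index_label="PROBE_ID", float_format="%.17g")
    m.probe_to_probeset.rename("PROBESET_ID").to_csv(
        f"{prefix}.probe_map.tsv", sep="\t", index_label="PROBE_ID")
    m.probeset_to_feature.to_csv(f"{prefix}.probeset_map.tsv", sep="\t",
                                 index_label="PROBESET_ID")


def read_probe_matrix(prefix: str | Path) -> ProbeMatrix:
    prefix = Path(prefix)
    values = pd.read_csv(f"{prefix}.intensities.tsv", sep="\t",
                         index_col="PROBE_ID")
    p2ps = pd.read_csv(f"{prefix}.probe_map.tsv", sep="\t",
                       index_col="PROBE_ID")["PROBESET_ID"]
    meta = pd.read_csv(f"{prefix}.probeset_map.tsv", sep="\t",
                       index_col="PROBESET_ID")
    return ProbeMatrix(values, p2ps, meta)


def candidates_to_frame(cands: list[ExonCandidate]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "PROBESET_ID": [c.probeset_id for c in cands],
            "PSI[KOvsCTRL]": [c.psi_ratio for c in cands],
            "p-value": [c.p_value for c in cands],
            "EXON_LENGTH": [c.exon_length for c in cands],
            "AGAA_COUNT": [c.agaa_count for c in cands],
            "AGAA_FREQ": [c.agaa_freq for c in cands],
            "PROBESET_SEQ": [c.probeset_seq for c in cands],
            "EXON_SEQ": [c.exon_seq for c in cands],
            "TRANSCRIPT_ID": [c.transcript_id for c in cands],
            "EXON_INDEX": [c.exon_index for c in cands],
            "PSI_CTRL": [c.psi_ctrl for c in cands],
            "PSI_KO": [c.psi_ko for c in cands],
            "PASSED_INITIAL": [c.passed_initial for c in cands],
            "DE_OVERLAP": [c.de_overlap for c in cands],
            "PASSED_MOTIF": [c.passed_motif for c in cands],
        },
        columns=CANDIDATE_COLUMNS + FLAG_COLUMNS,
    )


def write_candidate_table(cands: list[ExonCandidate], path: str | Path) -> None:
    candidates_to_frame(cands).to_csv(path, sep="\t", index=False,
                                      float_format="%.17g")


def read_candidate_table(path: str | Path) -> list[ExonCandidate]:
    df = pd.read_csv(path, sep="\t", dtype={"PROBESET_SEQ": str,
                                            "EXON_SEQ": str},
                     keep_default_na=True, float_precision="round_trip")
    extras = [c for c in df.columns
              if c not in CANDIDATE_COLUMNS + FLAG_COLUMNS]
    if extras:
        logger.warning("candidate table %s carries unknown columns %s "
                       "(preserved as extras)", path, extras)
    def _s(v) -> str:
        return "" if pd.isna(v) else str(v)
    out = []
    for _, r in df.iterrows():
        out.append(ExonCandidate(
            probeset_id=str(r["PROBESET_ID"]),
            transcript_id=_s(r.get("TRANSCRIPT_ID", "")),
            exon_index=int(r.get("EXON_INDEX", -1)),
            psi_ctrl=float(r.get("PSI_CTRL", float("nan"))),
            psi_ko=float(r.get("PSI_KO", float("nan"))),
            psi_ratio=float(r["PSI[KOvsCTRL]"]),
            p_value=float(r["p-value"]),
            exon_length=int(r["EXON_LENGTH"]),
            agaa_count=int(r["AGAA_COUNT"]),
            agaa_freq=float(r["AGAA_FREQ"]),
            probeset_seq=_s(r["PROBESET_SEQ"]),
            exon_seq=_s(r["EXON_SEQ"]),
            passed_initial=bool(r.get("PASSED_INITIAL", False)),
            de_overlap=bool(r.get("DE_OVERLAP", False)),
            passed_motif=bool(r.get("PASSED_MOTIF", False)),
        ))
    return out


def refilter_candidate_table(cands: list[ExonCandidate], de_list: list[str],
                             low_cut: float = splicing.PSI_LOW_CUT,
                             high_cut: float = splicing.PSI_HIGH_CUT,
                             p_cut: float = 0.05, min_count: int = 1,
                             min_freq: float = 1.5) -> list[ExonCandidate]:
    """Re-apply the full cascade (window+p, DE exclusion, motif rules) to
    an already-scored candidate table, using its own AGAA columns when a
    sequence is unavailable."""
    survivors, _ = splicing.filter_splicing_candidates(
        cands, de_list, low_cut, high_cut, p_cut)
    out = []
    for c in survivors:
        if c.exon_seq:
            score = motifs.score_motif(c.exon_seq)
            c.agaa_count, c.agaa_freq = score.count, score.frequency
        c.passed_motif = c.agaa_count >= min_count and c.agaa_freq >= min_freq
        if c.passed_motif:
            out.append(c)
    return out


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class ScreenConfig:
    """Every knob of the end-to-end screen in one place."""

    # gene-level DE thresholds
    gene_fold_cut: float = 1.5
    gene_p_cut: float = 0.05
    # exon-level screen
    psi_low_cut: float = splicing.PSI_LOW_CUT
    psi_high_cut: float = splicing.PSI_HIGH_CUT
    exon_p_cut: float = 0.05
    exon_test: str = "student"
    # motif filter
    motif: str = "AGAA"
    motif_min_count: int = 1
    motif_min_freq: float = 1.5
    freq_convention: str = "calibrated"
    # expression floors
    gene_linear_floor: float = 25.0
    exon_log2_floor: float = 3.0
    # NMD
    junction_rule_nt: int = 50
    # simulation
    n_transcripts: int = 200
    design: SimulationDesign = field(default_factory=SimulationDesign)
    seed: int = 0
    out_dir: str = "screen_out"

    def __post_init__(self) -> None:
        if not 0 < self.psi_low_cut < 1 < self.psi_high_cut:
            raise ValueError("PSI window must satisfy low < 1 < high")
        for name in ("gene_fold_cut", "gene_p_cut", "exon_p_cut",
                     "motif_min_freq"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        # one seed drives everything
        self.design = dataclasses.replace(self.design, seed=self.seed)

    def flat_items(self) -> list[tuple[str, str]]:
        items = []
        for f in fields(self):
            v = getattr(self, f.name)
            if f.name == "design":
                for g in fields(v):
                    items.append((f"design.{g.name}", repr(getattr(v, g.name))))
            else:
                items.append((f.name, repr(v)))
        return sorted(items)

    def config_hash(self) -> str:
        text = "\n".join(f"{k}={v}" for k, v in self.flat_items())
        return hashlib.sha256(text.encode()).hexdigest()[:16]

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for k, v in self.flat_items():
                fh.write(f"{k}={v}\n")


def read_config(path: str | Path, **overrides) -> ScreenConfig:
    """Flat key=value config file; keyword overrides win."""
    import ast

    raw: dict[str, object] = {}
    design_kw: dict[str, object] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            k, _, v = line.partition("=")
            k, v = k.strip(), ast.literal_eval(v.strip())
            if k.startswith("design."):
                design_kw[k[len("design."):]] = v
            else:
                raw[k] = v
    raw.update(overrides)
    if design_kw:
        raw["design"] = SimulationDesign(**design_kw)
    return ScreenConfig(**raw)


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

@dataclass
class PipelineReport:
    config: ScreenConfig
    models: list[TranscriptModel]
    truth: synthetic.SimTruth
    de_calls: list[str]
    candidates: list[ExonCandidate]
    survivors: list[ExonCandidate]
    counts: splicing.FilterCounts
    nmd: list
    out_dir: Path | None


def run_pipeline(config: ScreenConfig, probe_matrix: ProbeMatrix | None = None,
                 models: list[TranscriptModel] | None = None,
                 write_outputs: bool = True) -> PipelineReport:
    """simulate/ingest -> preprocess -> DE -> PSI screen -> motif -> NMD.

    When no probe matrix is supplied the synthetic generator provides
    one under ``config.design``.  Outputs (candidate tables in the
    supplementary-dataset dialects, DE table, NMD report, run log) land
    in ``config.out_dir``.
    """
    stage = "simulate/ingest"
    try:
        truth = synthetic.SimTruth()
        if probe_matrix is None:
            models, truth, probe_matrix = synthetic.simulate_experiment(
                config.n_transcripts, config.design)
        if models is None:
            raise ValueError("transcript models required for the motif/NMD stages")
        design = GroupDesign(synthetic.group_design(probe_matrix))

        stage = "preprocess"
        summary, removed = preprocess.preprocess_pipeline(
            probe_matrix,
            gene_linear_floor=config.gene_linear_floor,
            exon_log2_floor=config.exon_log2_floor)

        stage = "diffexpr"
        gene_s = summary.subset(preprocess.GENE)
        stats = diffexpr.moderated_t_table(gene_s, design)
        de_calls = diffexpr.call_differential(stats, config.gene_fold_cut,
                                              config.gene_p_cut)

        stage = "splicing_screen"
        exon_s = summary.subset(preprocess.EXON)
        cands = splicing.compute_psi_ratio(exon_s, gene_s, design,
                                           test=config.exon_test)
        seqs = {f"{m.transcript_id}|{i}": s
                for m in models for i, s in enumerate(m.sequences)}
        splicing.attach_sequences(cands, seqs)
        survivors, counts = splicing.filter_splicing_candidates(
            cands, de_calls, config.psi_low_cut, config.psi_high_cut,
            config.exon_p_cut)

        stage = "motif_filter"
        survivors = motifs.apply_motif_filter(
            survivors, config.motif_min_count, config.motif_min_freq,
            config.motif, config.freq_convention)
        counts.after_motif = len(survivors)
        # scored-but-dropped candidates still get their motif columns filled
        for c in cands:
            if c.exon_seq and c.agaa_count == 0 and c.agaa_freq == 0.0:
                sc = motifs.score_motif(c.exon_seq, config.motif,
                                        config.freq_convention)
                c.agaa_count, c.agaa_freq = sc.count, sc.frequency

        stage = "nmd"
        nmd = motifs.nmd_report(models, survivors, config.junction_rule_nt)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    out_dir = None
    if write_outputs:
        out_dir = Path(config.out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_candidate_table(cands, out_dir / "candidates_all.tsv")
        write_candidate_table(survivors, out_dir / "candidates_filtered.tsv")
        diffexpr.stats_table(stats).to_csv(out_dir / "de_table.tsv", sep="\t",
                                           index=False, float_format="%.17g")
        pd.DataFrame(
            [
                {
                    "PROBESET_ID": c.probeset_id,
                    "TRANSCRIPT_ID": c.transcript_id,
                    # 1-based exon number for the human-readable report
                    "EXON_NUMBER": c.exon_index + 1,
                    "N_PTCS": call.n_ptcs if call else "",
                    "FIRST_PTC_POS": ("" if not call or call.first_ptc_pos is None
                                      else call.first_ptc_pos + 1),
                    "NMD_PREDICTED": call.nmd_predicted if call else "",
                }
                for c, call in nmd
            ]
        ).to_csv(out_dir / "nmd_report.tsv", sep="\t", index=False)
        write_exon_fasta(models, out_dir / "exons.fasta")
        config.write(out_dir / "run_config.txt")
        with open(out_dir / "run_log.txt", "w") as fh:
            fh.write(f"config_hash={config.config_hash()}\n")
            fh.write(f"seed={config.seed}\n")
            fh.write(f"features_removed_by_floor={len(removed)}\n")
            fh.write(f"exons_total={counts.total}\n")
            fh.write(f"exons_after_initial={counts.after_initial}\n")
            fh.write(f"exons_after_de_exclusion={counts.after_de_exclusion}\n")
            fh.write(f"exons_after_motif={counts.after_motif}\n")
            fh.write(f"de_transcripts_called={len(de_calls)}\n")
    return PipelineReport(config, models, truth, de_calls, cands, survivors,
                          counts, nmd, out_dir)
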