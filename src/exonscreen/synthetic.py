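"""Synthetic exon-array data with planted expression and splicing effects.

Emulates a two-genotype (CTRL vs conditional-KO) exon-array experiment:
random transcript models with controllable AGAA motif content, planted
transcript-level fold changes and exon-level inclusion (PSI) changes,
probe-level intensities with fixed probe affinities, Gaussian log-scale
noise and additive background, and a mosaicism fraction that mixes the
unedited (CTRL) expression state into every KO sample — the situation in
a conditional knockout tissue where cells escaping recombination dilute
the molecular effect.

All randomness flows from one integer seed through
``numpy.random.SeedSequence`` spawning; no global RNG state is touched.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocess import EXON, GENE, ProbeMatrix

_STOPS = ("TAA", "TAG", "TGA")
MOTIF = "AGAA"
#: calibration length: one motif per this many bp gives frequency 1
MOTIF_CALIBRATION_BP = 256


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class TranscriptModel:
    """A sense-strand transcript: ordered exons with sequences and a CDS.

    Coordinates are transcript-local, 0-based half-open.  ``cds_start``
    is the first base of the start codon, ``cds_stop`` the first base of
    the stop codon; the CDS (start codon through stop codon inclusive)
    has length divisible by 3 and spans at least two exons.
    """

    transcript_id: str
    exons: list[tuple[int, int]]
    sequences: list[str]
    cds_start: int
    cds_stop: int

    def __post_init__(self) -> None:
        prev_end = 0
        for (s, e), seq in zip(self.exons, self.sequences):
            if s < prev_end or e <= s:
                raise ValueError("exons must be ordered and non-overlapping")
            if len(seq) != e - s:
                raise ValueError("exon sequence length must equal end - start")
            prev_end = e
        if not self.cds_start < self.cds_stop:
            raise ValueError("cds_start must precede cds_stop")
        if (self.cds_stop - self.cds_start) % 3 != 0:
            raise ValueError("CDS length must be divisible by 3")

    @property
    def sequence(self) -> str:
        """Full mRNA sequence (exons are contiguous in transcript space)."""
        return "".join(self.sequences)

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    def exon_containing(self, pos: int) -> int:
        for i, (s, e) in enumerate(self.exons):
            if s <= pos < e:
                return i
        raise ValueError(f"position {pos} outside transcript")


@dataclass
class SimulationDesign:
    """Parameters of one simulated two-group exon-array experiment.

    Defaults reproduce the study design: 4 CTRL vs 4 KO arrays and
    log2-scale probe noise of 0.25 sd.  ``mosaic_fraction`` m mixes the
    CTRL expression state into the expected KO signal on the linear
    scale: E[KO] = (1-m)*KO_state + m*CTRL_state.
    """

    n_ctrl: int = 4
    n_ko: int = 4
    frac_de: float = 0.1
    de_fold_range: tuple[float, float] = (1.5, 3.0)
    frac_as: float = 0.1
    as_ratio_range: tuple[float, float] = (0.4, 2.5)
    mosaic_fraction: float = 0.0
    noise_sd: float = 0.25
    probes_per_probeset: int = 4
    background_mean: float = 30.0
    background_sd: float = 10.0
    seed: int = 0
    #: optional discrete set of planted PSI ratios (overrides the range)
    as_ratio_values: tuple[float, ...] | None = None
    #: when set, planted AS exons get AGAA motifs added until their
    #: binding-site frequency F reaches at least this value
    as_min_motif_freq: float | None = None
    #: unexpressed (pure background) probesets as a fraction of the real
    #: ones, emulating the absent features that dominate a real array
    #: and anchor the background estimate; removed by the expression floors
    decoy_fraction: float = 1.0

    def __post_init__(self) -> None:
        for name in ("frac_de", "frac_as", "mosaic_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        for name in ("de_fold_range", "as_ratio_range"):
            lo, hi = getattr(self, name)
            if lo <= 0 or hi <= 0 or lo > hi:
                raise ValueError(f"{name} must be a positive interval")
        if self.probes_per_probeset < 2:
            raise ValueError("probes_per_probeset must be >= 2")
        if self.n_ctrl < 2 or self.n_ko < 2:
            raise ValueError("need at least two samples per group")
        if self.noise_sd < 0 or self.background_sd < 0 or self.background_mean < 0:
            raise ValueError("noise/background parameters must be non-negative")
        if self.decoy_fraction < 0:
            raise ValueError("decoy_fraction must be non-negative")


@dataclass
class SimTruth:
    """Ground truth of planted effects.

    ``de_transcripts`` maps transcript_id -> planted linear KO/CTRL
    expression fold; ``as_exons`` maps (transcript_id, exon_index) ->
    planted PSI ratio.  The two sets of transcripts are disjoint by
    construction, so planted splicing truth never collides with the
    screen's DE-exclusion rule.
    """

    de_transcripts: dict[str, float] = field(default_factory=dict)
    as_exons: dict[tuple[str, int], float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# sequence construction
# ---------------------------------------------------------------------------

def _random_motif_free(rng: np.random.Generator, n: int) -> np.ndarray:
    """Random sequence over ACGT with every AGAA occurrence scrubbed."""
    arr = rng.choice(np.frombuffer(b"ACGT", dtype="S1"), size=n)
    s = arr.tobytes()
    while True:
        i = s.find(b"AGAA")
        if i < 0:
            return np.frombuffer(s, dtype="S1").copy()
        # a C can never create a new AGAA occurrence
        s = s[: i + 3] + b"C" + s[i + 4:]


def _plant_motifs(rng: np.random.Generator, seq: np.ndarray, k: int) -> np.ndarray:
    """Overwrite k non-overlapping windows with AGAA, repairing any extra
    occurrences created at window boundaries."""
    n = len(seq)
    if k <= 0 or n < 4:
        return seq
    k = min(k, n // 4)
    # sample non-overlapping start positions by spacing k windows in n
    gaps = rng.multinomial(n - 4 * k, np.ones(k + 1) / (k + 1))
    starts, pos = [], 0
    for i in range(k):
        pos += gaps[i]
        starts.append(pos)
        pos += 4
    motif = np.frombuffer(b"AGAA", dtype="S1")
    for st in starts:
        seq[st: st + 4] = motif
    planted = set(starts)
    s = seq.tobytes()
    i = s.find(b"AGAA")
    while i >= 0:
        if i not in planted:
            # mutate a base of this spurious occurrence lying outside all
            # planted windows; C destroys it and cannot create another
            for off in range(4):
                p = i + off
                if not any(st <= p < st + 4 for st in planted):
                    seq[p] = b"C"
                    break
            s = seq.tobytes()
            i = s.find(b"AGAA", i)
        else:
            i = s.find(b"AGAA", i + 1)
    return seq


def _write_codon(seq: np.ndarray, pos: int, codon: str) -> None:
    seq[pos: pos + 3] = np.frombuffer(codon.encode(), dtype="S1")


def generate_transcriptome(n_transcripts: int,
                           exons_per_tx: tuple[int, int] = (4, 8),
                           exon_len: tuple[int, int] = (60, 300),
                           motif_rate: float = 1.0,
                           seed: int = 0) -> list[TranscriptModel]:
    """Generate random transcript models with controlled AGAA content.

    ``motif_rate`` is the expected number of AGAA sites per 256 bp of
    exon sequence (the field's calibration length); the background
    sequence is scrubbed of chance occurrences, then a Poisson number
    of sites is planted per exon, so ``motif_rate=0`` yields exactly
    zero occurrences.  Each transcript carries a clean ORF (ATG ...
    stop, no internal in-frame stops) spanning at least two exons.
    """
    if n_transcripts <= 0:
        raise ValueError("n_transcripts must be positive")
    if exons_per_tx[0] < 2 or exons_per_tx[0] > exons_per_tx[1]:
        raise ValueError("exons_per_tx must be a range with lower bound >= 2")
    if exon_len[0] < 10 or exon_len[0] > exon_len[1]:
        raise ValueError("exon_len must be a range with lower bound >= 10")
    if motif_rate < 0:
        raise ValueError("motif_rate must be non-negative")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    models = []
    for t in range(n_transcripts):
        n_ex = int(rng.integers(exons_per_tx[0], exons_per_tx[1] + 1))
        lengths = rng.integers(exon_len[0], exon_len[1] + 1, size=n_ex)
        seqs = []
        for ln in lengths:
            seq = _random_motif_free(rng, int(ln))
            k = rng.poisson(motif_rate * ln / MOTIF_CALIBRATION_BP)
            seq = _plant_motifs(rng, seq, int(k))
            seqs.append(seq)
        boundaries = np.concatenate(([0], np.cumsum(lengths)))
        exons = [(int(boundaries[i]), int(boundaries[i + 1]))
                 for i in range(n_ex)]
        total = int(boundaries[-1])
        full = np.concatenate(seqs)
        # CDS: start codon early in exon 0, stop codon inside the last exon,
        # so the ORF spans every exon junction
        cds_start = int(rng.integers(0, min(12, lengths[0] - 6)))
        last_lo, last_hi = exons[-1]
        stop_max = total - 3
        stop_min = last_lo
        # align stop to the reading frame of cds_start
        candidates = [p for p in range(stop_min, stop_max + 1)
                      if (p - cds_start) % 3 == 0]
        cds_stop = int(rng.choice(candidates))
        _write_codon(full, cds_start, "ATG")
        _write_codon(full, cds_stop, "TAA")
        # scrub internal in-frame stops; stops always start with T, which
        # never lies inside an AGAA, so mutating the first base to C is
        # motif-safe and cannot create a new stop or motif
        for p in range(cds_start + 3, cds_stop, 3):
            codon = full[p: p + 3].tobytes().decode()
            if codon in _STOPS:
                full[p] = b"C"
        if motif_rate == 0:
            # codon writes may complete an AGA prefix into AGAA; such an
            # occurrence can only touch the start codon via its last base,
            # so mutating its first base to C is always safe and cannot
            # create a stop codon (stops contain no C)
            s = full.tobytes()
            i = s.find(b"AGAA")
            while i >= 0:
                full[i] = b"C"
                s = full.tobytes()
                i = s.find(b"AGAA", i)
        seqs = [full[s:e] for s, e in exons]
        models.append(TranscriptModel(
            transcript_id=f"TX{t:05d}",
            exons=exons,
            sequences=[s.tobytes().decode() for s in seqs],
            cds_start=cds_start,
            cds_stop=cds_stop,
        ))
    return models


# ---------------------------------------------------------------------------
# effect planting
# ---------------------------------------------------------------------------

_PSI_WINDOW = (2.0 / 3.0, 1.5)  # planted ratios never fall strictly inside


def _sample_as_ratio(rng: np.random.Generator,
                     design: SimulationDesign) -> float:
    if design.as_ratio_values is not None:
        vals = [v for v in design.as_ratio_values
                if not _PSI_WINDOW[0] < v < _PSI_WINDOW[1]]
        if not vals:
            raise ValueError("as_ratio_values all lie inside the PSI "
                             "exclusion window (2/3, 1.5)")
        return float(rng.choice(vals))
    lo, hi = design.as_ratio_range
    seg_lo = (lo, min(hi, _PSI_WINDOW[0]))
    seg_hi = (max(lo, _PSI_WINDOW[1]), hi)
    segs = [s for s in (seg_lo, seg_hi) if s[0] <= s[1]]
    if not segs:
        raise ValueError("as_ratio_range lies entirely inside the PSI "
                         "exclusion window (2/3, 1.5)")
    widths = np.array([s[1] - s[0] for s in segs])
    if widths.sum() == 0:
        probs = np.ones(len(segs)) / len(segs)
    else:
        probs = widths / widths.sum()
    s = segs[int(rng.choice(len(segs), p=probs))]
    return float(rng.uniform(s[0], s[1])) if s[1] > s[0] else float(s[0])


def _enrich_exon_motifs(rng: np.random.Generator, tx: TranscriptModel,
                        exon_index: int, min_freq: float) -> None:
    """Plant extra AGAA sites into one exon until F >= min_freq.

    The start/stop codons and the cleanliness of the ORF are preserved;
    placements that collide with the codons are resampled.
    """
    from .motifs import count_motif  # deferred: avoid import cycle at load

    lo, hi = tx.exons[exon_index]
    length = hi - lo
    need = int(np.ceil(min_freq * length / MOTIF_CALIBRATION_BP))
    if count_motif(tx.sequences[exon_index]) >= need:
        return
    for _ in range(25):
        seq = np.frombuffer(tx.sequences[exon_index].encode(), dtype="S1").copy()
        seq = _plant_motifs(rng, seq, need)  # replants to exactly `need` sites
        full = np.frombuffer(tx.sequence.encode(), dtype="S1").copy()
        full[lo:hi] = seq
        _write_codon(full, tx.cds_start, "ATG")
        _write_codon(full, tx.cds_stop, "TAA")
        for p in range(tx.cds_start + 3, tx.cds_stop, 3):
            if full[p: p + 3].tobytes().decode() in _STOPS:
                full[p] = b"C"  # the T of the stop; never inside an AGAA
        if count_motif(full[lo:hi].tobytes().decode()) >= need:
            for i, (s, e) in enumerate(tx.exons):
                tx.sequences[i] = full[s:e].tobytes().decode()
            return
    raise RuntimeError(f"could not enrich exon {exon_index} of "
                       f"{tx.transcript_id} to F >= {min_freq}")


def plant_effects(models: list[TranscriptModel],
                  design: SimulationDesign) -> SimTruth:
    """Choose planted DE transcripts and AS exons.

    Exactly ``round(frac_de * n_transcripts)`` transcripts get a linear
    expression fold (direction random); ``round(frac_as * n_exons)``
    exons on the *remaining* transcripts get a PSI ratio drawn outside
    the (2/3, 1.5) screening window, so planted truth is disjoint from
    the DE-exclusion rule by construction.
    """
    rng = np.random.default_rng(np.random.SeedSequence(design.seed).spawn(1)[0])
    n_de = round(design.frac_de * len(models))
    de_idx = rng.choice(len(models), size=n_de, replace=False) if n_de else []
    de_ids = {models[i].transcript_id for i in de_idx}
    truth = SimTruth()
    for i in de_idx:
        lo, hi = design.de_fold_range
        fold = float(rng.uniform(lo, hi))
        if rng.random() < 0.5:
            fold = 1.0 / fold
        truth.de_transcripts[models[i].transcript_id] = fold
    all_exons = [(m, j) for m in models for j in range(m.n_exons)]
    eligible = [(m, j) for m, j in all_exons
                if m.transcript_id not in de_ids]
    n_as = min(round(design.frac_as * len(all_exons)), len(eligible))
    if n_as:
        pick = rng.choice(len(eligible), size=n_as, replace=False)
        for idx in pick:
            m, j = eligible[idx]
            ratio = _sample_as_ratio(rng, design)
            truth.as_exons[(m.transcript_id, j)] = ratio
            if design.as_min_motif_freq is not None:
                _enrich_exon_motifs(rng, m, j, design.as_min_motif_freq)
    return truth


# ---------------------------------------------------------------------------
# probe-level simulation
# ---------------------------------------------------------------------------

def simulate_probe_matrix(models: list[TranscriptModel], truth: SimTruth,
                          design: SimulationDesign) -> ProbeMatrix:
    """Simulate the linear-scale probe intensity matrix.

    Per transcript, a baseline log2 expression is drawn once; expected
    linear signals per group are formed from planted folds and PSI
    ratios, KO expectations are diluted by the mosaic fraction on the
    linear scale, and each probe observes
    ``2**(log2(expected) + affinity + N(0, noise_sd))`` plus additive
    truncated-Normal background.  Probe affinities are drawn once per
    probe and shared across samples, as on a real array.
    """
    known = {m.transcript_id for m in models}
    for tx_id in truth.de_transcripts:
        if tx_id not in known:
            raise ValueError(f"truth references unknown transcript {tx_id}")
    for tx_id, j in truth.as_exons:
        if tx_id not in known:
            raise ValueError(f"truth references unknown transcript {tx_id}")
    ss = np.random.SeedSequence(design.seed).spawn(3)
    rng_base = np.random.default_rng(ss[1])
    rng_noise = np.random.default_rng(ss[2])
    m_frac = design.mosaic_fraction
    n_s = design.n_ctrl + design.n_ko
    samples = ([f"CTRL_{i+1}" for i in range(design.n_ctrl)]
               + [f"KO_{i+1}" for i in range(design.n_ko)])
    ko_mask = np.array([False] * design.n_ctrl + [True] * design.n_ko)

    probe_ids, probeset_of_probe = [], []
    ps_rows: list[tuple[str, str, str, int]] = []  # probeset, feature, kind, exon_idx
    expected = []  # per probeset: (ctrl_lin, ko_lin)
    ppp = design.probes_per_probeset
    for mdl in models:
        base = float(rng_base.uniform(6.0, 10.0))  # log2 baseline
        g_ctrl = 2.0 ** base
        fold = truth.de_transcripts.get(mdl.transcript_id, 1.0)
        g_ko_pure = g_ctrl * fold
        g_ko = (1 - m_frac) * g_ko_pure + m_frac * g_ctrl
        ps = f"PSR_g_{mdl.transcript_id}"
        ps_rows.append((ps, mdl.transcript_id, GENE, -1))
        expected.append((g_ctrl, g_ko))
        for p in range(ppp):
            probe_ids.append(f"{ps}_p{p}")
            probeset_of_probe.append(ps)
        for j in range(mdl.n_exons):
            ratio = truth.as_exons.get((mdl.transcript_id, j), 1.0)
            e_ctrl = g_ctrl  # baseline inclusion index 1
            e_ko = (1 - m_frac) * g_ko_pure * ratio + m_frac * g_ctrl
            ps = f"PSR_e_{mdl.transcript_id}_{j}"
            ps_rows.append((ps, mdl.transcript_id, EXON, j))
            expected.append((e_ctrl, e_ko))
            for p in range(ppp):
                probe_ids.append(f"{ps}_p{p}")
                probeset_of_probe.append(ps)

    # unexpressed decoy probesets: pure background, no transcript model;
    # they anchor the per-array background estimate and exercise the
    # expression floors, like the absent features on a real array
    n_decoy = round(design.decoy_fraction * len(models))
    for d in range(n_decoy):
        tid = f"DECOY{d:05d}"
        for ps, kind, idx in ([(f"PSR_g_{tid}", GENE, -1)]
                              + [(f"PSR_e_{tid}_{j}", EXON, j)
                                 for j in range(3)]):
            ps_rows.append((ps, tid, kind, idx))
            expected.append((0.0, 0.0))
            for p in range(ppp):
                probe_ids.append(f"{ps}_p{p}")
                probeset_of_probe.append(ps)

    n_probes = len(probe_ids)
    affinities = rng_base.normal(0.0, 0.3, size=n_probes)
    exp_lin = np.repeat(np.asarray(expected, dtype=float), ppp, axis=0)
    with np.errstate(divide="ignore"):
        mean_log2 = np.where(ko_mask[None, :], np.log2(exp_lin[:, 1:2]),
                             np.log2(exp_lin[:, 0:1]))
    log2_vals = (mean_log2 + affinities[:, None]
                 + rng_noise.normal(0.0, design.noise_sd, size=(n_probes, n_s)))
    values = 2.0 ** log2_vals  # -inf baselines (decoys) give exactly 0 signal
    if design.background_mean > 0 or design.background_sd > 0:
        bg = rng_noise.normal(design.background_mean, design.background_sd,
                              size=(n_probes, n_s))
        values = values + np.maximum(bg, 0.0)

    values_df = pd.DataFrame(values, index=probe_ids, columns=samples)
    p2ps = pd.Series(probeset_of_probe, index=probe_ids, name="probeset")
    ps_meta = pd.DataFrame(
        [(f, k, e) for _, f, k, e in ps_rows],
        index=[r[0] for r in ps_rows],
        columns=["feature_id", "kind", "exon_index"],
    )
    return ProbeMatrix(values_df, p2ps, ps_meta)


def simulate_experiment(n_transcripts: int, design: SimulationDesign,
                        exons_per_tx: tuple[int, int] = (4, 8),
                        exon_len: tuple[int, int] = (60, 300),
                        motif_rate: float = 1.0,
                        ) -> tuple[list[TranscriptModel], SimTruth, ProbeMatrix]:
    """Convenience wrapper: transcriptome -> planted truth -> probe matrix."""
    models = generate_transcriptome(n_transcripts, exons_per_tx, exon_len,
                                    motif_rate, seed=design.seed)
    truth = plant_effects(models, design)
    matrix = simulate_probe_matrix(models, truth, design)
    return models, truth, matrix


def group_design(matrix: ProbeMatrix) -> dict[str, str]:
    """Sample -> group labels inferred from the simulated sample names."""
    return {s: ("KO" if s.startswith("KO") else "CTRL")
            for s in matrix.values.columns}
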