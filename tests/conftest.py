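import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("reproducible", derandomize=True, deadline=None)
settings.load_profile("reproducible")

from exonscreen.preprocess import EXON, GENE, ProbeMatrix, SummaryMatrix
from exonscreen.synthetic import TranscriptModel


def make_summary(values: dict[str, list[float]], kinds: dict[str, str],
                 feature_ids: dict[str, str] | None = None,
                 exon_index: dict[str, int] | None = None) -> SummaryMatrix:
    """Build a SummaryMatrix from {feature: per-sample log2 values}."""
    df = pd.DataFrame(values).T
    df.columns = [f"S{i+1}" for i in range(df.shape[1])]
    meta = pd.DataFrame(
        {
            "feature_id": [
                (feature_ids or {}).get(f, f) for f in df.index],
            "kind": [kinds[f] for f in df.index],
            "exon_index": [(exon_index or {}).get(f, -1) for f in df.index],
        },
        index=df.index,
    )
    return SummaryMatrix(df, meta)


def make_probe_matrix(values: np.ndarray, probes_per_set: int = 2,
                      kind: str = GENE,
                      probe_gc: np.ndarray | None = None) -> ProbeMatrix:
    """Wrap a raw probes x samples array with sequential probeset maps."""
    n_probes, n_samples = values.shape
    probe_ids = [f"p{i}" for i in range(n_probes)]
    probesets = [f"ps{i // probes_per_set}" for i in range(n_probes)]
    df = pd.DataFrame(values, index=probe_ids,
                      columns=[f"S{j+1}" for j in range(n_samples)])
    p2ps = pd.Series(probesets, index=probe_ids)
    uniq = sorted(set(probesets), key=probesets.index)
    meta = pd.DataFrame(
        {"feature_id": uniq, "kind": kind, "exon_index": -1}, index=uniq)
    gc = pd.Series(probe_gc, index=probe_ids) if probe_gc is not None else None
    return ProbeMatrix(df, p2ps, meta, probe_gc=gc)


def make_transcript(exon_seqs: list[str], cds_start: int,
                    cds_stop: int, tid: str = "TX") -> TranscriptModel:
    bounds, pos = [], 0
    for s in exon_seqs:
        bounds.append((pos, pos + len(s)))
        pos += len(s)
    return TranscriptModel(transcript_id=tid, exons=bounds,
                          sequences=list(exon_seqs),
                          cds_start=cds_start, cds_stop=cds_stop)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
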