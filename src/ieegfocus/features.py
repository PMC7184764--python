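"""Segment -> multiband entropy feature extraction.

Each 20-s segment is pre-filtered to the global 100-600 Hz band,
decomposed into the N = 10 subbands, and reduced to the 8-entropy
vector per subband.  Results are returned as a tidy table with one row
per (channel, segment, subband, entropy) value, plus helpers to pivot
the table into the per-subband H x D matrices the selection and
classification stages consume.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .entropy import ENTROPY_NAMES, EntropyParams, entropy_vector
from .filterbank import BandDefinition, bandpass, decompose, make_filterbank
from .io import Recording, segment_recording

__all__ = [
    "extract_features",
    "feature_matrices",
    "channel_segment_index",
]


def extract_features(
    rec: Recording,
    bands: list[BandDefinition] | None = None,
    params: EntropyParams = EntropyParams(),
    segment_seconds: float = 20.0,
    prefilter: bool = True,
) -> pd.DataFrame:
    """Extract the tidy entropy feature table of a recording.

    Returns a DataFrame with columns ``channel``, ``channel_index``,
    ``segment``, ``label`` (focal flag), ``subband`` (1-based),
    ``entropy`` (one of ``ENTROPY_NAMES``) and ``value``.
    """
    if bands is None:
        bands = make_filterbank()
    segments = segment_recording(rec, segment_seconds)
    rows: list[dict] = []
    for seg in segments:
        x = seg.x
        if prefilter:
            x = bandpass(x, bands[0].low_edge, bands[-1].high_edge, rec.fs,
                         order=bands[0].order)
        sub = decompose(x, bands, rec.fs)
        for bi, band in enumerate(bands):
            vec = entropy_vector(sub[bi], params)
            for name, value in zip(ENTROPY_NAMES, vec):
                rows.append(
                    {
                        "channel": seg.channel_id,
                        "channel_index": seg.channel_index,
                        "segment": seg.segment_index,
                        "label": seg.label,
                        "subband": band.index,
                        "entropy": name,
                        "value": value,
                    }
                )
    return pd.DataFrame(rows)


def channel_segment_index(features: pd.DataFrame) -> pd.DataFrame:
    """Unique (channel, segment) rows with labels, in stable order."""
    cols = ["channel", "channel_index", "segment", "label"]
    idx = features[cols].drop_duplicates().sort_values(
        ["channel_index", "segment"], kind="stable"
    )
    return idx.reset_index(drop=True)


def feature_matrices(
    features: pd.DataFrame, dropna: bool = True
) -> tuple[dict[int, np.ndarray], pd.DataFrame]:
    """Pivot the tidy table into per-subband H x D matrices.

    Returns ``(matrices, rows)`` where ``matrices[n]`` is the H x 8
    matrix of subband ``n`` (columns in ``ENTROPY_NAMES`` order) and
    ``rows`` the H-row (channel, segment, label) index shared by all
    subbands.  Rows containing any NaN (undefined estimator) are
    dropped with a warning.
    """
    wide = features.pivot_table(
        index=["channel_index", "channel", "segment", "label"],
        columns=["subband", "entropy"],
        values="value",
        sort=True,
    )
    subbands = sorted(features["subband"].unique())
    ordered = [(n, e) for n in subbands for e in ENTROPY_NAMES]
    wide = wide.reindex(columns=pd.MultiIndex.from_tuples(ordered))
    bad = wide.isna().any(axis=1)
    if bad.any():
        warnings.warn(
            f"dropping {int(bad.sum())} channel-segment rows with undefined entropies"
        )
        wide = wide[~bad]
    rows = wide.index.to_frame(index=False)[
        ["channel", "channel_index", "segment", "label"]
    ]
    matrices = {n: wide[n][list(ENTROPY_NAMES)].to_numpy() for n in subbands}
    return matrices, rows
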