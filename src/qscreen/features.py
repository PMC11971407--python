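"""Cohort-level feature assembly.

Glue between the modality extractors and the selection pipeline: walk a
cohort, extract the gait (12), tapping (17), voice (20 scalar + 26 raw
MFCC summary) and demographic (3) features per participant, and replace
the raw MFCC summaries with the 10 training-fitted principal components.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import AccelerometerTrace, AudioClip, CohortTable, TapEventSeries
from .motion import gait_feature_block, tapping_feature_block
from .voice import MfccPca, mfcc_summary, voice_feature_block

MFCC_RAW_COLUMNS = tuple(
    [f"voice_mfcc_mean_{i + 1}" for i in range(13)]
    + [f"voice_mfcc_std_{i + 1}" for i in range(13)]
)

DEMOGRAPHIC_FEATURES = ("demo_age", "demo_gender", "demo_smoker")


def demographic_features(record) -> dict[str, float]:
    """Age in years plus {0,1} encodings of gender and smoking history."""
    return {
        "demo_age": float(record.age),
        "demo_gender": 1.0 if record.gender == "female" else 0.0,
        "demo_smoker": 1.0 if record.smoker else 0.0,
    }


def participant_features(record, gait_trace: AccelerometerTrace,
                         taps: TapEventSeries,
                         tap_trace: AccelerometerTrace,
                         clip: AudioClip) -> dict[str, float]:
    """All per-participant features (raw MFCC summaries included)."""
    feats: dict[str, float] = {}
    feats.update(gait_feature_block(gait_trace))
    feats.update(tapping_feature_block(taps, tap_trace))
    feats.update(voice_feature_block(clip))
    feats.update(dict(zip(MFCC_RAW_COLUMNS, mfcc_summary(clip))))
    feats.update(demographic_features(record))
    return feats


def extract_features(cohort: CohortTable, modality_data: dict) -> pd.DataFrame:
    """Feature table for a cohort.

    ``modality_data`` maps participant_id to a dict with keys ``gait``
    (AccelerometerTrace), ``taps`` (TapEventSeries), ``tap_accel``
    (AccelerometerTrace) and ``voice`` (AudioClip).  Returns a DataFrame
    indexed by participant_id with feature columns plus ``label`` and
    ``split``.
    """
    rows = {}
    for rec in cohort.records:
        d = modality_data[rec.participant_id]
        feats = participant_features(rec, d["gait"], d["taps"],
                                     d["tap_accel"], d["voice"])
        feats["label"] = rec.label
        feats["split"] = rec.split
        rows[rec.participant_id] = feats
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "participant_id"
    return df


def apply_mfcc_pca(df: pd.DataFrame, n_components: int = 10
                   ) -> tuple[pd.DataFrame, MfccPca]:
    """Replace the 26 raw MFCC summary columns with 10 principal components.

    The projection is fitted on training rows only so test metrics stay
    honest; all rows are then projected.
    """
    raw = df[list(MFCC_RAW_COLUMNS)].to_numpy(dtype=float)
    train_mask = (df["split"] == "train").to_numpy()
    pca = MfccPca(n_components=n_components).fit(raw[train_mask])
    proj = pca.transform(raw)
    out = df.drop(columns=list(MFCC_RAW_COLUMNS))
    for i in range(n_components):
        out[f"voice_mfcc_pc{i + 1}"] = proj[:, i]
    # keep label/split as the trailing columns
    meta = [c for c in ("label", "split") if c in out.columns]
    cols = [c for c in out.columns if c not in meta] + meta
    return out[cols], pca
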