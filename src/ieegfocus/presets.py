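"""Reference-cohort presets.

The method was developed against an eight-patient clinical cohort of
interictal subdural iEEG recordings (focal cortical dysplasia, 2 kHz
sampling, 30-minute excerpts, 36-76 electrodes of which 3-9 were
annotated as seizure onset zone).  The recordings themselves are not
publicly available; these presets capture the cohort's published
structure (electrode and SOZ counts per patient), the per-patient
sparsity settings, and the reported segment- and channel-level
performance, so that synthetic stand-ins can mirror the cohort's shape
and reported summary arithmetic can be recomputed.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "PatientProfile",
    "PATIENT_PROFILES",
    "SLDA_DELTA1",
    "REFERENCE_SEGMENT_METRICS",
    "REFERENCE_CHANNEL_AUC",
]


@dataclass(frozen=True)
class PatientProfile:
    """Electrode layout of one reference patient."""

    n_channels: int
    soz_channels: tuple[int, ...]  # 1-based electrode numbers

    @property
    def n_soz(self) -> int:
        return len(self.soz_channels)


PATIENT_PROFILES: dict[str, PatientProfile] = {
    "Pt1": PatientProfile(60, (10, 11, 16)),
    "Pt2": PatientProfile(50, (9, 10, 13, 14, 17, 18, 26, 32, 38)),
    "Pt3": PatientProfile(42, (7, 8, 9, 10, 11, 17, 18)),
    "Pt4": PatientProfile(36, (16, 22, 23)),
    "Pt5": PatientProfile(60, (34, 40, 41)),
    "Pt6": PatientProfile(70, (9, 10, 11, 12, 32, 37)),
    "Pt7": PatientProfile(71, (15, 16, 29, 30, 35, 36, 42, 48)),
    "Pt8": PatientProfile(76, (6, 7, 8)),
}

#: Per-patient sparsity control delta1 (|delta1| = number of entropies kept).
SLDA_DELTA1: dict[str, int] = {
    "Pt1": -5, "Pt2": -5, "Pt3": -3, "Pt4": -5,
    "Pt5": -3, "Pt6": -4, "Pt7": -6, "Pt8": -3,
}

#: Reported per-patient segment-level results of the full pipeline
#: (filter bank + feature selection + ADASYN): sensitivity, specificity,
#: precision and fall-out in percent, F-score as a fraction.
REFERENCE_SEGMENT_METRICS: dict[str, dict[str, float]] = {
    "Pt1": {"sen": 23.70, "spe": 96.26, "ppv": 25.00, "fpr": 3.74, "f1": 0.24},
    "Pt2": {"sen": 45.93, "spe": 86.64, "ppv": 43.01, "fpr": 13.36, "f1": 0.44},
    "Pt3": {"sen": 37.46, "spe": 82.83, "ppv": 30.37, "fpr": 17.18, "f1": 0.34},
    "Pt4": {"sen": 42.96, "spe": 84.07, "ppv": 19.69, "fpr": 15.93, "f1": 0.27},
    "Pt5": {"sen": 79.25, "spe": 97.50, "ppv": 62.57, "fpr": 2.50, "f1": 0.70},
    "Pt6": {"sen": 54.82, "spe": 96.42, "ppv": 58.96, "fpr": 3.58, "f1": 0.57},
    "Pt7": {"sen": 49.02, "spe": 83.76, "ppv": 27.71, "fpr": 16.24, "f1": 0.35},
    "Pt8": {"sen": 88.52, "spe": 98.54, "ppv": 71.34, "fpr": 1.46, "f1": 0.79},
}

#: Reported per-patient channel-level AUC (10-fold CV mean) of the full
#: pipeline.
REFERENCE_CHANNEL_AUC: dict[str, float] = {
    "Pt1": 0.90, "Pt2": 0.79, "Pt3": 0.71, "Pt4": 0.79,
    "Pt5": 0.96, "Pt6": 0.94, "Pt7": 0.81, "Pt8": 0.99,
}
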