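"""Patient-cohort enumeration statistics.

Whole-slide CTC counts become CTCs per mL of blood; the cohort detection
rate is the percentage of patients above the healthy-control ceiling (zero
in a well-calibrated assay); and tumour-derived EV burden is the
double-positive percentage of total tetraspanin-positive EVs with the
paired healthy-control baseline subtracted and clipped at zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._utils import as_rng

__all__ = [
    "SampleResult",
    "CohortTable",
    "ctcs_per_ml",
    "detection_rate",
    "gbm_ev_percent",
    "simulate_cohort_counts",
]


@dataclass
class SampleResult:
    """Enumeration results for one blood/plasma sample."""

    sample_id: str
    group: str  # "patient" | "healthy"
    ctc_count: int = 0
    blood_volume_ml: float = 7.5
    ev_total: int | None = None  # tetraspanin-positive particles, sampled FOVs
    ev_double: int | None = None  # tumour-marker + tetraspanin double positives
    fovs_sampled: int = 4

    def __post_init__(self) -> None:
        if self.group not in ("patient", "healthy"):
            raise ValueError("group must be 'patient' or 'healthy'")
        if self.ctc_count < 0:
            raise ValueError("ctc_count must be >= 0")
        if self.blood_volume_ml <= 0:
            raise ValueError("blood_volume_ml must be positive")

    @property
    def ctcs_per_ml(self) -> float:
        return ctcs_per_ml(self.ctc_count, self.blood_volume_ml)


def ctcs_per_ml(ctc_count: int, blood_volume_ml: float) -> float:
    """Whole-slide CTC count divided by the initial blood volume (CTCs/mL)."""
    if blood_volume_ml <= 0:
        raise ValueError("blood volume must be positive")
    if ctc_count < 0:
        raise ValueError("ctc_count must be >= 0")
    return float(ctc_count) / float(blood_volume_ml)


def detection_rate(
    samples: list[SampleResult],
    threshold_ctcs_per_ml: float | None = None,
) -> float:
    """Percentage of patients with CTCs/mL above the positivity threshold.

    The threshold defaults to the maximum healthy-control rate (zero when
    imaging conditions are calibrated so healthy donors yield no CTCs);
    the result is rounded to an integer percentage.
    """
    patients = [s for s in samples if s.group == "patient"]
    if not patients:
        raise ValueError("cohort contains no patient samples")
    if threshold_ctcs_per_ml is None:
        healthy = [s.ctcs_per_ml for s in samples if s.group == "healthy"]
        threshold_ctcs_per_ml = max(healthy) if healthy else 0.0
    positive = sum(1 for s in patients if s.ctcs_per_ml > threshold_ctcs_per_ml)
    return float(round(100.0 * positive / len(patients)))


def gbm_ev_percent(
    ev_double: int, ev_total: int, healthy_baseline_pct: float
) -> float:
    """Baseline-adjusted tumour-EV percentage, clipped at zero.

    ``max(0, 100 * ev_double / ev_total - healthy_baseline_pct)``; samples
    whose raw double-positive percentage falls below the healthy-control
    baseline are reported as zero.
    """
    if ev_total <= 0:
        raise ValueError("ev_total must be positive (sample not evaluable)")
    if not 0.0 <= healthy_baseline_pct <= 100.0:
        raise ValueError("healthy_baseline_pct must be in [0, 100]")
    if ev_double < 0:
        raise ValueError("ev_double must be >= 0")
    return max(0.0, 100.0 * ev_double / ev_total - healthy_baseline_pct)


@dataclass
class CohortTable:
    """Cohort-level table with derived per-sample rates and summaries."""

    samples: list[SampleResult]
    healthy_baseline_pct: float = 0.0
    baseline_mode: str = "max"  # how multiple healthy controls combine

    @classmethod
    def from_samples(
        cls,
        samples: list[SampleResult],
        baseline_mode: str = "max",
    ) -> "CohortTable":
        """Build the table, deriving the healthy EV baseline from controls.

        With several healthy controls the baseline is their max (default,
        conservative) or mean of raw double-positive percentages.
        """
        if baseline_mode not in ("max", "mean"):
            raise ValueError("baseline_mode must be 'max' or 'mean'")
        raw = [
            100.0 * s.ev_double / s.ev_total
            for s in samples
            if s.group == "healthy" and s.ev_total
        ]
        if raw:
            baseline = max(raw) if baseline_mode == "max" else float(np.mean(raw))
        else:
            baseline = 0.0
        return cls(samples=samples, healthy_baseline_pct=baseline, baseline_mode=baseline_mode)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for s in self.samples:
            pct = None
            if s.ev_total:
                pct = gbm_ev_percent(s.ev_double or 0, s.ev_total, self.healthy_baseline_pct)
            rows.append(
                {
                    "sample_id": s.sample_id,
                    "group": s.group,
                    "ctc_count": s.ctc_count,
                    "blood_volume_ml": s.blood_volume_ml,
                    "ctcs_per_ml": s.ctcs_per_ml,
                    "ev_total": s.ev_total,
                    "ev_double": s.ev_double,
                    "fovs_sampled": s.fovs_sampled,
                    "pct_gbm_ev": pct,
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> dict:
        df = self.to_dataframe()
        patients = df[df["group"] == "patient"]
        healthy = df[df["group"] == "healthy"]
        out = {
            "n_patients": int(len(patients)),
            "n_healthy": int(len(healthy)),
            "detection_rate_pct": detection_rate(self.samples),
            "healthy_baseline_pct": self.healthy_baseline_pct,
            "mean_ctcs_per_ml": float(patients["ctcs_per_ml"].mean()) if len(patients) else None,
            "max_ctcs_per_ml": float(patients["ctcs_per_ml"].max()) if len(patients) else None,
        }
        return out


def simulate_cohort_counts(
    densities_per_ml,
    blood_volume_ml: float = 7.5,
    seed: int | np.random.Generator = 0,
) -> list[SampleResult]:
    """Poisson whole-slide CTC counts for samples with known CTC densities.

    A lightweight cohort generator for end-to-end rank-recovery checks:
    count ~ Poisson(density * volume) per sample.
    """
    rng = as_rng(seed)
    samples = []
    for k, dens in enumerate(densities_per_ml):
        if dens < 0:
            raise ValueError("densities must be non-negative")
        count = int(rng.poisson(dens * blood_volume_ml))
        samples.append(
            SampleResult(
                sample_id=f"S{k:02d}",
                group="patient",
                ctc_count=count,
                blood_volume_ml=blood_volume_ml,
            )
        )
    return samples
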