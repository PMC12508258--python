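"""Two-channel colocalization and cross-reactivity analytics.

Particles detected independently in two channels of the same field of view
are matched by centroid distance (maximum-cardinality, minimum-total-distance
assignment), classified single/double positive, and summarised as
percentages of the union. Normalized EV counts compare a probe-only control
condition against the complete two-plex protocol (complete protocol = 100%),
which is how residual-HRP cross-reactivity is quantified; the inter-channel
correlation of double-positive log-intensities measures co-expression.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist
from scipy.stats import pearsonr

from .detection import Particle

__all__ = [
    "ColocResult",
    "NormalizedCounts",
    "match_particles",
    "classify_positivity",
    "normalized_counts_percent",
    "intensity_correlation",
]


@dataclass
class ColocResult:
    """Single/double-positive composition of a two-channel field."""

    n_total: int
    n_a_only: int
    n_b_only: int
    n_double: int
    pairs: list = field(default_factory=list)  # (a_id, b_id, distance_px)
    r: float | None = None
    r_flag: str = ""

    @property
    def pct_a_only(self) -> float:
        return 100.0 * self.n_a_only / self.n_total

    @property
    def pct_b_only(self) -> float:
        return 100.0 * self.n_b_only / self.n_total

    @property
    def pct_double(self) -> float:
        return 100.0 * self.n_double / self.n_total

    def summary(self) -> dict:
        return {
            "n_total": self.n_total,
            "n_a_only": self.n_a_only,
            "n_b_only": self.n_b_only,
            "n_double": self.n_double,
            "pct_a_only": self.pct_a_only,
            "pct_b_only": self.pct_b_only,
            "pct_double": self.pct_double,
            "r": self.r,
        }


def _centroids(particles: list[Particle]) -> np.ndarray:
    return np.array([p.centroid for p in particles], dtype=float).reshape(-1, 2)


def match_particles(
    particles_a: list[Particle],
    particles_b: list[Particle],
    match_radius_px: float,
):
    """Match channel-A to channel-B particles by centroid distance.

    Computes the maximum-cardinality assignment of pairs with centroid
    distance <= ``match_radius_px`` that minimises the total matched
    distance; each particle is matched at most once and ties are broken
    deterministically by (distance, a-index, b-index). Sub-diffraction EVs
    have PSF-dominated masks, so centroid distance is the appropriate
    colocalization criterion (default radius ~2 PSF sigma in pixels).

    Returns ``(pairs, unmatched_a, unmatched_b)`` where pairs are
    ``(a_index, b_index, distance)`` tuples sorted by distance.
    """
    if match_radius_px < 0:
        raise ValueError("match_radius_px must be >= 0")
    na, nb = len(particles_a), len(particles_b)
    if na == 0 or nb == 0:
        return [], list(range(na)), list(range(nb))
    d = cdist(_centroids(particles_a), _centroids(particles_b))
    allowed = d <= match_radius_px
    if not allowed.any():
        return [], list(range(na)), list(range(nb))
    # large constant makes disallowed pairs strictly worse than any set of
    # allowed ones, so cardinality is maximised before total distance
    big = (d[allowed].max() + match_radius_px + 1.0) * (min(na, nb) + 1)
    cost = np.where(allowed, d, big)
    rows, cols = linear_sum_assignment(cost)
    pairs = [
        (int(i), int(j), float(d[i, j]))
        for i, j in zip(rows, cols)
        if allowed[i, j]
    ]
    pairs.sort(key=lambda t: (t[2], t[0], t[1]))
    matched_a = {i for i, _, _ in pairs}
    matched_b = {j for _, j, _ in pairs}
    unmatched_a = [i for i in range(na) if i not in matched_a]
    unmatched_b = [j for j in range(nb) if j not in matched_b]
    return pairs, unmatched_a, unmatched_b


def classify_positivity(
    pairs: list,
    unmatched_a: list,
    unmatched_b: list,
    intensities_a: np.ndarray | None = None,
    intensities_b: np.ndarray | None = None,
) -> ColocResult:
    """Counts and percentages of A-only / B-only / double-positive particles.

    ``intensities_a/b`` are per-particle background-subtracted integrated
    intensities indexed like the particle lists given to
    :func:`match_particles`; when provided (and >= 3 double positives exist),
    the Pearson correlation of double-positive log-intensities is attached.
    """
    n_double = len(pairs)
    n_a_only = len(unmatched_a)
    n_b_only = len(unmatched_b)
    n_total = n_double + n_a_only + n_b_only
    if n_total == 0:
        raise ValueError("no particles in either channel")
    res = ColocResult(
        n_total=n_total,
        n_a_only=n_a_only,
        n_b_only=n_b_only,
        n_double=n_double,
        pairs=list(pairs),
    )
    if intensities_a is not None and intensities_b is not None and n_double >= 3:
        ia = np.asarray(intensities_a, dtype=float)[[i for i, _, _ in pairs]]
        ib = np.asarray(intensities_b, dtype=float)[[j for _, j, _ in pairs]]
        try:
            res.r = intensity_correlation(ia, ib)
        except ValueError as exc:
            res.r = None
            res.r_flag = str(exc)
    return res


@dataclass
class NormalizedCounts:
    """Per-condition EV counts normalised to the complete-protocol mean.

    ``normalized_pct`` holds 100 * count / mean(reference counts) per FOV;
    the complete protocol therefore averages 100%, and the mean normalized
    percentage of a probe-only condition estimates the cross-reactivity
    fraction (in percent).
    """

    reference_condition: str
    reference_mean: float
    table: pd.DataFrame  # columns: condition, fov, count, normalized_pct

    def condition_mean(self, condition: str) -> float:
        sel = self.table[self.table["condition"] == condition]
        if sel.empty:
            raise KeyError(f"unknown condition {condition!r}")
        return float(sel["normalized_pct"].mean())

    @property
    def cross_reactivity_pct(self) -> float | None:
        others = [
            c for c in self.table["condition"].unique() if c != self.reference_condition
        ]
        if len(others) != 1:
            return None
        return self.condition_mean(others[0])


def normalized_counts_percent(
    counts_by_condition: dict,
    reference_condition: str = "TSA complete",
) -> NormalizedCounts:
    """Normalise per-FOV EV counts to the complete-protocol mean (x100).

    ``counts_by_condition`` maps condition label -> iterable of per-FOV
    counts. Raw counts are divided by the mean count of the reference
    (complete-protocol) condition and multiplied by 100, per FOV, then
    averaged per condition.
    """
    if reference_condition not in counts_by_condition:
        raise ValueError(
            f"reference condition {reference_condition!r} missing from counts"
        )
    ref_counts = [float(c) for c in counts_by_condition[reference_condition]]
    if len(ref_counts) == 0:
        raise ValueError("reference condition has no FOVs")
    ref_mean = float(np.mean(ref_counts))
    if ref_mean <= 0:
        raise ValueError("reference condition mean count is zero")
    rows = []
    for cond, counts in counts_by_condition.items():
        for k, c in enumerate(counts):
            rows.append(
                {
                    "condition": cond,
                    "fov": k,
                    "count": float(c),
                    "normalized_pct": 100.0 * float(c) / ref_mean,
                }
            )
    return NormalizedCounts(
        reference_condition=reference_condition,
        reference_mean=ref_mean,
        table=pd.DataFrame(rows, columns=["condition", "fov", "count", "normalized_pct"]),
    )


def intensity_correlation(
    intensities_a: np.ndarray,
    intensities_b: np.ndarray,
    log: bool = True,
) -> float:
    """Pearson correlation of double-positive intensities across channels.

    Computed on log-transformed background-subtracted integrated intensities
    by default (single-EV intensity distributions are strongly right-skewed);
    non-positive values cannot be log-transformed and are dropped pairwise.
    """
    a = np.asarray(intensities_a, dtype=float)
    b = np.asarray(intensities_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("intensity vectors must have equal length")
    if log:
        keep = (a > 0) & (b > 0)
        a, b = np.log(a[keep]), np.log(b[keep])
    if a.size < 3:
        raise ValueError("need at least 3 double-positive pairs for correlation")
    if np.allclose(a, a[0]) or np.allclose(b, b[0]):
        raise ValueError("zero variance; correlation undefined")
    return float(pearsonr(a, b)[0])
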