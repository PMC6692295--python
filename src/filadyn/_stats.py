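"""Shared per-position significance test and run-length region scan."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats

__all__ = ["RegionCriterion", "SignificantRegion", "scan_regions"]


@dataclass
class RegionCriterion:
    """Threshold triple for region detection.

    A position qualifies when the per-position two-sample t-test gives
    ``p < p_threshold`` and the absolute mean difference exceeds the
    effect threshold; regions are maximal runs of at least
    ``min_run_length`` consecutive qualifying positions.
    """

    p_threshold: float = 0.001
    effect_threshold: Optional[float] = None  # None: derived from data (sigma rule)
    min_run_length: int = 3
    welch: bool = True

    def __post_init__(self):
        if not 0 < self.p_threshold < 1:
            raise ValueError("p_threshold must lie in (0, 1)")
        if self.min_run_length < 1:
            raise ValueError("min_run_length must be >= 1")


@dataclass
class SignificantRegion:
    """A maximal run of qualifying residues with the sign of the difference."""

    start: int          # first residue id
    end: int            # last residue id (inclusive)
    sign: int           # +1: mean(B) > mean(A); -1: mean(A) > mean(B)
    length: int
    min_p: float
    mean_delta: float   # mean over the run of (mean_B - mean_A)


def scan_regions(
    values_a: np.ndarray,
    values_b: np.ndarray,
    residue_ids: np.ndarray,
    criterion: RegionCriterion,
    effect_threshold: float,
) -> list:
    """Run the per-position t-test / effect / run-length scan.

    ``values_a`` and ``values_b`` are (n_models, n_positions) arrays of a
    per-position quantity across ensemble members.  Returns a list of
    :class:`SignificantRegion` over contiguous residue ids.
    """
    A = np.asarray(values_a, float)
    B = np.asarray(values_b, float)
    residue_ids = np.asarray(residue_ids, int)
    _, pvals = stats.ttest_ind(A, B, axis=0, equal_var=not criterion.welch)
    delta = B.mean(axis=0) - A.mean(axis=0)
    qual = (pvals < criterion.p_threshold) & (np.abs(delta) > effect_threshold)
    # positions with NaN p (zero variance, identical values) never qualify
    qual &= np.isfinite(pvals)

    regions = []
    n = len(qual)
    i = 0
    while i < n:
        if not qual[i]:
            i += 1
            continue
        j = i
        # a run must be contiguous in residue numbering as well
        while (
            j + 1 < n
            and qual[j + 1]
            and residue_ids[j + 1] == residue_ids[j] + 1
        ):
            j += 1
        length = j - i + 1
        if length >= criterion.min_run_length:
            d = delta[i : j + 1]
            regions.append(
                SignificantRegion(
                    start=int(residue_ids[i]),
                    end=int(residue_ids[j]),
                    sign=int(np.sign(d.mean())),
                    length=length,
                    min_p=float(np.min(pvals[i : j + 1])),
                    mean_delta=float(d.mean()),
                )
            )
        i = j + 1
    return regions
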