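"""HDX-MS uptake model, relative fractional uptake and state comparison.

Deuterium uptake follows first-order exchange at per-residue rates,
scaled by the deuterium fraction of the labeling mix (78.6% for the
default 15 uL sample + 55 uL buffer).  No back-exchange correction is
applied anywhere.  Two states are compared per peptide with Wald tests
on a fixed-effects linear model (state + time + state:time on
replicate-level uptake), Benjamini-Hochberg adjusted across peptides;
significant peptides are classified by their maximum fractional-uptake
difference (major > 10%, minor 5-10%).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "LabelingConditions",
    "HDXPeptide",
    "UptakeTable",
    "HDXComparison",
    "deuterium_fraction",
    "count_exchangeable",
    "peptide_uptake_model",
    "relative_fractional_uptake",
    "compare_states",
    "DEFAULT_TIME_POINTS_MIN",
]

#: Default labeling time course in minutes (0.16 min is the 10 s point).
DEFAULT_TIME_POINTS_MIN = (0.16, 1.0, 10.0, 30.0, 60.0, 120.0, 180.0)

#: Classification thresholds on the maximum fractional-uptake difference.
MAJOR_THRESHOLD = 0.10
MINOR_THRESHOLD = 0.05


def deuterium_fraction(sample_volume: float, buffer_volume: float) -> float:
    """Molar deuterium fraction after mixing: buffer / (sample + buffer)."""
    if sample_volume <= 0 or buffer_volume <= 0:
        raise ValueError("volumes must be positive")
    return buffer_volume / (sample_volume + buffer_volume)


@dataclass(frozen=True)
class LabelingConditions:
    """Labeling mix volumes, time course and environment."""

    sample_volume: float = 15.0      # uL
    buffer_volume: float = 55.0      # uL
    time_points: Sequence[float] = DEFAULT_TIME_POINTS_MIN  # minutes
    temperature: float = 20.0        # Celsius
    pD: float = 7.0

    def __post_init__(self):
        if self.sample_volume <= 0 or self.buffer_volume <= 0:
            raise ValueError("volumes must be positive")

    @property
    def d_fraction(self) -> float:
        return deuterium_fraction(self.sample_volume, self.buffer_volume)


def count_exchangeable(sequence: str, skip_n_terminal: int = 1) -> int:
    """Maximum exchangeable backbone amides of a peptide.

    Convention: subtract the first ``skip_n_terminal`` residues (fast
    back exchange at the N-terminus) and every proline at the remaining
    positions (no backbone amide hydrogen).
    """
    if not sequence:
        raise ValueError("empty sequence")
    rest = sequence[skip_n_terminal:]
    return len(rest) - rest.count("P")


@dataclass(frozen=True)
class HDXPeptide:
    """A peptic peptide: 1-based inclusive residue span and sequence."""

    start: int
    end: int
    sequence: str

    def __post_init__(self):
        if self.end < self.start:
            raise ValueError("end must be >= start")
        if len(self.sequence) != self.end - self.start + 1:
            raise ValueError("sequence length must equal end - start + 1")

    @property
    def n_exchangeable(self) -> int:
        return count_exchangeable(self.sequence)

    def exchangeable_residue_ids(self, skip_n_terminal: int = 1) -> np.ndarray:
        """Residue ids (1-based, global) carrying an exchangeable amide."""
        ids = []
        for off, aa in enumerate(self.sequence):
            if off < skip_n_terminal or aa == "P":
                continue
            ids.append(self.start + off)
        return np.array(ids, dtype=int)


def peptide_uptake_model(
    peptide: HDXPeptide,
    per_residue_rates: np.ndarray,
    conditions: LabelingConditions,
    t: float,
) -> float:
    """Deuterium uptake (Da) at labeling time ``t`` (minutes).

    ``uptake(t) = d_fraction * sum_i (1 - exp(-k_i t))`` over the
    peptide's exchangeable residues, with ``k_i`` in 1/min indexed by
    1-based residue id.  Saturates at ``n_exchangeable * d_fraction``.
    """
    rates = np.asarray(per_residue_rates, float)
    ids = peptide.exchangeable_residue_ids()
    k = rates[ids - 1]
    if np.any(k < 0):
        raise ValueError("exchange rates must be >= 0")
    return float(conditions.d_fraction * np.sum(1.0 - np.exp(-k * t)))


def relative_fractional_uptake(
    uptake: float, peptide: HDXPeptide, conditions: LabelingConditions
) -> Tuple[float, bool]:
    """Uptake divided by the theoretical maximum; flags values above 1.05.

    Returns ``(fraction, clipped_flag)``; the value itself is not clipped.
    """
    n_ex = peptide.n_exchangeable
    if n_ex == 0:
        raise ValueError("peptide has no exchangeable amides")
    frac = uptake / (n_ex * conditions.d_fraction)
    return frac, frac > 1.05


@dataclass
class UptakeTable:
    """Replicate-level uptake for one protein state.

    ``data`` columns: start, end, sequence, time_min, replicate, uptake_Da.
    """

    data: pd.DataFrame
    state: str = ""
    conditions: LabelingConditions = field(default_factory=LabelingConditions)

    _REQUIRED = ("start", "end", "sequence", "time_min", "replicate", "uptake_Da")

    def __post_init__(self):
        missing = [c for c in self._REQUIRED if c not in self.data.columns]
        if missing:
            raise ValueError(f"uptake table missing columns: {missing}")
        if (self.data["uptake_Da"] < 0).any():
            raise ValueError("uptake must be >= 0")

    @classmethod
    def from_records(cls, records, state: str = "",
                     conditions: Optional[LabelingConditions] = None) -> "UptakeTable":
        return cls(
            data=pd.DataFrame.from_records(records),
            state=state,
            conditions=conditions or LabelingConditions(),
        )

    @classmethod
    def read_tsv(cls, path, state: str = "") -> "UptakeTable":
        df = pd.read_csv(path, sep=None, engine="python")
        return cls(data=df, state=state)

    def write_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index=False, float_format="%.6g")

    def peptides(self) -> list:
        out = []
        for (s, e, seq), _ in self.data.groupby(["start", "end", "sequence"], sort=True):
            out.append(HDXPeptide(start=int(s), end=int(e), sequence=seq))
        return out

    @property
    def time_points(self) -> np.ndarray:
        return np.sort(self.data["time_min"].unique())


@dataclass
class HDXComparison:
    """Per-peptide and per-residue outcome of a two-state comparison."""

    peptide_table: pd.DataFrame   # per peptide: p-values, delta RFU, class
    residue_table: pd.DataFrame   # per residue: aggregated class
    alpha: float


def _wald_ols(y: np.ndarray, state: np.ndarray, time_codes: np.ndarray):
    """Wald tests on a fixed-effects model y ~ state + time + state:time.

    Sum-coded (centered) time dummies make the state coefficient the
    average state offset across the time course (magnitude test); the
    interaction block tests time-course shape differences (kinetics).
    F-distributed statistics under normal errors.  Returns
    (p_magnitude, p_kinetics, delta_means_by_time).
    """
    n = len(y)
    times = np.unique(time_codes)
    T = len(times)
    # sum-coded dummies for the first T-1 time levels
    Z = np.zeros((n, T - 1))
    for j, t in enumerate(times[:-1]):
        Z[time_codes == t, j] = 1.0
    Z[time_codes == times[-1], :] = -1.0
    s = np.where(state, 1.0, -1.0)[:, None]  # effect-coded state
    X = np.hstack([np.ones((n, 1)), s, Z, s * Z])
    p = X.shape[1]
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = n - p
    if dof <= 0:
        raise ValueError("not enough replicates for the Wald test")
    sigma2 = float(resid @ resid) / dof
    XtX_inv = np.linalg.inv(X.T @ X)
    cov = sigma2 * XtX_inv

    # magnitude: single state coefficient
    b = beta[1]
    if cov[1, 1] > 0:
        f_mag = b * b / cov[1, 1]
    else:  # zero residual variance: exact fit, effect present iff b != 0
        f_mag = np.inf if abs(b) > 1e-12 else 0.0
    p_mag = float(stats.f.sf(f_mag, 1, dof))

    # kinetics: joint test on the T-1 interaction coefficients
    idx = np.arange(1 + 1 + (T - 1), p)
    bi = beta[idx]
    ci = cov[np.ix_(idx, idx)]
    try:
        f_kin = float(bi @ np.linalg.solve(ci, bi)) / len(idx)
        p_kin = float(stats.f.sf(f_kin, len(idx), dof))
    except np.linalg.LinAlgError:
        p_kin = 1.0
    return p_mag, p_kin


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    from statsmodels.stats.multitest import multipletests

    if len(p) == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def compare_states(
    table_a: UptakeTable,
    table_b: UptakeTable,
    alpha: float = 0.01,
    conditions: Optional[LabelingConditions] = None,
) -> HDXComparison:
    """Two-state HDX comparison with per-peptide Wald tests.

    Per peptide, a linear model on replicate uptake with state, time and
    state:time effects gives a magnitude p-value (state main effect) and
    a kinetics p-value (interaction); both are BH-adjusted across
    peptides and a peptide is significant when either adjusted p-value
    is below ``alpha``.  Significant peptides are classified by
    ``max |delta RFU|`` over time points (major > 0.10, minor > 0.05);
    each residue inherits the most severe class among significant
    peptides covering it.
    """
    if conditions is None:
        conditions = table_a.conditions
    peps_a = table_a.peptides()
    peps_b = table_b.peptides()
    if [(p.start, p.end) for p in peps_a] != [(p.start, p.end) for p in peps_b]:
        raise ValueError("peptide maps differ between states")
    times_a, times_b = table_a.time_points, table_b.time_points
    if not np.array_equal(times_a, times_b):
        raise ValueError("time points differ between states")

    rows = []
    for pep in peps_a:
        sel_a = table_a.data[
            (table_a.data["start"] == pep.start) & (table_a.data["end"] == pep.end)
        ]
        sel_b = table_b.data[
            (table_b.data["start"] == pep.start) & (table_b.data["end"] == pep.end)
        ]
        if sel_a["replicate"].nunique() < 2 or sel_b["replicate"].nunique() < 2:
            raise ValueError(
                f"peptide {pep.start}-{pep.end}: need >= 2 replicates per state"
            )
        y = np.concatenate([sel_a["uptake_Da"].to_numpy(), sel_b["uptake_Da"].to_numpy()])
        state = np.concatenate(
            [np.zeros(len(sel_a), bool), np.ones(len(sel_b), bool)]
        )
        tcodes = np.concatenate(
            [sel_a["time_min"].to_numpy(), sel_b["time_min"].to_numpy()]
        )
        p_mag, p_kin = _wald_ols(y, state, tcodes)

        denom = pep.n_exchangeable * conditions.d_fraction
        drfu = {}
        for t in times_a:
            ua = sel_a.loc[sel_a["time_min"] == t, "uptake_Da"].mean()
            ub = sel_b.loc[sel_b["time_min"] == t, "uptake_Da"].mean()
            drfu[t] = (ub - ua) / denom
        max_abs_drfu = max(abs(v) for v in drfu.values())
        rows.append(
            {
                "start": pep.start,
                "end": pep.end,
                "sequence": pep.sequence,
                "n_exchangeable": pep.n_exchangeable,
                "p_magnitude": p_mag,
                "p_kinetics": p_kin,
                "max_abs_delta_rfu": max_abs_drfu,
                "mean_delta_rfu": float(np.mean(list(drfu.values()))),
            }
        )
    pt = pd.DataFrame(rows)
    pt["p_magnitude_adj"] = _bh_adjust(pt["p_magnitude"].to_numpy())
    pt["p_kinetics_adj"] = _bh_adjust(pt["p_kinetics"].to_numpy())
    pt["significant"] = (pt["p_magnitude_adj"] < alpha) | (pt["p_kinetics_adj"] < alpha)

    def classify(row):
        if not row["significant"]:
            return "none"
        if row["max_abs_delta_rfu"] > MAJOR_THRESHOLD:
            return "major"
        if row["max_abs_delta_rfu"] > MINOR_THRESHOLD:
            return "minor"
        return "none"

    pt["class"] = pt.apply(classify, axis=1)

    severity = {"none": 0, "minor": 1, "major": 2}
    last_res = int(pt["end"].max())
    res_class = np.zeros(last_res + 1, dtype=int)
    for _, row in pt.iterrows():
        if row["class"] == "none":
            continue
        res_class[int(row["start"]) : int(row["end"]) + 1] = np.maximum(
            res_class[int(row["start"]) : int(row["end"]) + 1],
            severity[row["class"]],
        )
    inv = {v: k for k, v in severity.items()}
    rt = pd.DataFrame(
        {
            "residue": np.arange(1, last_res + 1),
            "class": [inv[c] for c in res_class[1:]],
        }
    )
    return HDXComparison(peptide_table=pt, residue_table=rt, alpha=alpha)
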