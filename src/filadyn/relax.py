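"""Lipari-Szabo model-free analysis of 15N relaxation under anisotropic tumbling.

Forward model: the spectral density combines internal motion (order
parameter S2, internal correlation time tau_e) with global rotational
diffusion described by a fully anisotropic tensor (Woessner five-term
form); reduced rate equations give T1, T2 and the heteronuclear NOE.
Fitting proceeds per residue over the nested model ladder
m1:(S2) -> m2:(S2,tau_e) / m3:(S2,Rex) -> m4:(S2,tau_e,Rex) with
error-weighted least squares and an F-test selection rule.  The
diffusion tensor itself is estimated from T1/T2 ratios of rigid
residues.  Chemical-shift perturbations use the weighted-average
combination with a 15N weight of 0.159.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
from scipy import optimize, stats
from scipy.spatial.transform import Rotation

__all__ = [
    "SpinConstants",
    "DiffusionTensor",
    "ModelFreeParams",
    "RelaxationDataset",
    "spectral_density",
    "predict_relaxation",
    "fit_model_free",
    "estimate_diffusion_tensor",
    "csp",
]

_MU0 = 4e-7 * np.pi          # T m / A
_H_PLANCK = 6.62607015e-34   # J s


@dataclass(frozen=True)
class SpinConstants:
    """Field and interaction constants for the 15N relaxation equations.

    Defaults: 14.1 T (600 MHz 1H), standard gyromagnetic ratios, 1.02 A
    N-H bond length and -160 ppm 15N CSA.
    """

    B0: float = 14.1                      # Tesla
    gammaH: float = 2.6752218744e8        # rad s^-1 T^-1
    gammaN: float = -2.7126e7             # rad s^-1 T^-1
    rNH: float = 1.02                     # Angstrom
    deltaSigma: float = -160.0            # ppm

    def __post_init__(self):
        if self.B0 <= 0 or self.rNH <= 0:
            raise ValueError("B0 and rNH must be positive")

    @property
    def omegaH(self) -> float:
        return self.gammaH * self.B0

    @property
    def omegaN(self) -> float:
        return self.gammaN * self.B0

    @property
    def dipolar(self) -> float:
        """Dipolar constant d = mu0 h gammaH gammaN / (8 pi^2 rNH^3), rad/s."""
        r = self.rNH * 1e-10
        return _MU0 * _H_PLANCK * self.gammaH * self.gammaN / (8 * np.pi**2 * r**3)

    @property
    def csa(self) -> float:
        """CSA constant c = omegaN * deltaSigma / sqrt(3), rad/s."""
        return self.omegaN * self.deltaSigma * 1e-6 / np.sqrt(3.0)


@dataclass
class DiffusionTensor:
    """Rotational diffusion tensor: principal values (s^-1) and orientation.

    ``rotation`` maps molecule-frame vectors into the tensor principal
    frame (``v_pf = rotation @ v_mol``).  Principal values are stored in
    ascending order ``Dx <= Dy <= Dz``.
    """

    Dx: float
    Dy: float
    Dz: float
    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self):
        if min(self.Dx, self.Dy, self.Dz) <= 0:
            raise ValueError("all diffusion components must be positive")
        d = np.array([self.Dx, self.Dy, self.Dz])
        order = np.argsort(d)
        R = np.asarray(self.rotation, float)
        if not np.all(order == np.arange(3)):
            d = d[order]
            R = R[order, :]
            if np.linalg.det(R) < 0:
                R[2, :] *= -1
            self.Dx, self.Dy, self.Dz = d
        self.rotation = R

    @classmethod
    def isotropic(cls, D: float) -> "DiffusionTensor":
        return cls(D, D, D)

    @classmethod
    def from_euler(cls, Dx: float, Dy: float, Dz: float,
                   alpha: float, beta: float, gamma: float) -> "DiffusionTensor":
        """Construct from z-y-z Euler angles (radians, molecule -> tensor)."""
        R = Rotation.from_euler("zyz", [alpha, beta, gamma]).as_matrix()
        return cls(Dx, Dy, Dz, rotation=R)

    @property
    def Diso(self) -> float:
        return (self.Dx + self.Dy + self.Dz) / 3.0

    @property
    def tau_m(self) -> float:
        """Effective isotropic correlation time 1/(6 Diso), s."""
        return 1.0 / (6.0 * self.Diso)

    @property
    def anisotropy(self) -> float:
        return 2 * self.Dz / (self.Dx + self.Dy)


@dataclass
class ModelFreeParams:
    """Fitted internal-dynamics parameters for one residue."""

    S2: float
    tau_e: float = 0.0   # s
    Rex: float = 0.0     # s^-1
    model_id: str = "m1"
    chi2: float = np.nan

    def __post_init__(self):
        if not -1e-9 <= self.S2 <= 1 + 1e-9:
            raise ValueError("S2 must lie in [0, 1]")
        if self.tau_e < 0 or self.Rex < 0:
            raise ValueError("tau_e and Rex must be >= 0")


@dataclass
class RelaxationDataset:
    """Per-residue (T1, T2, NOE) observations with errors and N-H vectors."""

    residue_ids: np.ndarray
    T1: np.ndarray
    T1_err: np.ndarray
    T2: np.ndarray
    T2_err: np.ndarray
    noe: np.ndarray
    noe_err: np.ndarray
    nh_vectors: np.ndarray

    def __post_init__(self):
        n = len(self.residue_ids)
        for name in ("T1", "T1_err", "T2", "T2_err", "noe", "noe_err"):
            arr = np.asarray(getattr(self, name), float)
            setattr(self, name, arr)
            if len(arr) != n:
                raise ValueError(f"{name} length mismatch")
        if np.any(self.T1 <= 0) or np.any(self.T2 <= 0):
            raise ValueError("T1 and T2 must be positive")
        if np.any(self.T1_err <= 0) or np.any(self.T2_err <= 0) or np.any(self.noe_err <= 0):
            raise ValueError("errors must be positive")
        self.nh_vectors = np.asarray(self.nh_vectors, float)
        if self.nh_vectors.shape != (n, 3):
            raise ValueError("nh_vectors must be (n, 3)")

    @property
    def n_residues(self) -> int:
        return len(self.residue_ids)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "residue": self.residue_ids,
                "T1": self.T1, "T1_err": self.T1_err,
                "T2": self.T2, "T2_err": self.T2_err,
                "NOE": self.noe, "NOE_err": self.noe_err,
            }
        )

    @classmethod
    def from_frame(cls, df, nh_vectors) -> "RelaxationDataset":
        return cls(
            residue_ids=df["residue"].to_numpy(int),
            T1=df["T1"].to_numpy(float), T1_err=df["T1_err"].to_numpy(float),
            T2=df["T2"].to_numpy(float), T2_err=df["T2_err"].to_numpy(float),
            noe=df["NOE"].to_numpy(float), noe_err=df["NOE_err"].to_numpy(float),
            nh_vectors=np.asarray(nh_vectors, float),
        )


# ---------------------------------------------------------------------------
# Spectral density (Woessner five-term anisotropic form)
# ---------------------------------------------------------------------------

def _woessner_terms(tensor: DiffusionTensor, nh_vector: np.ndarray):
    """Correlation times tau_k and amplitudes A_k for an N-H orientation.

    Amplitudes satisfy sum(A_k) = 1.  In the isotropic limit all five
    correlation times coincide with 1/(6 Diso) and the spectral density
    reduces exactly to the isotropic Lipari-Szabo form.
    """
    v = np.asarray(nh_vector, float)
    nrm = np.linalg.norm(v)
    if not np.isclose(nrm, 1.0, atol=1e-6):
        raise ValueError("nh_vector must be a unit vector")
    x, y, z = tensor.rotation @ (v / nrm)

    D = np.array([tensor.Dx, tensor.Dy, tensor.Dz])
    Diso = tensor.Diso
    L2 = (D[0] * D[1] + D[0] * D[2] + D[1] * D[2]) / 3.0
    disc = Diso**2 - L2
    if disc < -1e-8 * Diso**2:
        raise ValueError("invalid tensor: Diso^2 < L^2")
    Dr = np.sqrt(max(disc, 0.0))

    inv_tau = np.array([
        4 * D[0] + D[1] + D[2],
        D[0] + 4 * D[1] + D[2],
        D[0] + D[1] + 4 * D[2],
        6 * Diso + 6 * Dr,
        6 * Diso - 6 * Dr,
    ])
    taus = 1.0 / inv_tau

    x2, y2, z2 = x * x, y * y, z * z
    A = np.empty(5)
    A[0] = 3 * y2 * z2
    A[1] = 3 * x2 * z2
    A[2] = 3 * x2 * y2
    quartic = 0.25 * (3 * (x2**2 + y2**2 + z2**2) - 1.0)
    if Dr > 1e-12 * Diso:
        delta = (D - Diso) / Dr
        e = (
            delta[0] * (3 * x2**2 + 6 * y2 * z2 - 1)
            + delta[1] * (3 * y2**2 + 6 * x2 * z2 - 1)
            + delta[2] * (3 * z2**2 + 6 * x2 * y2 - 1)
        ) / 12.0
    else:
        e = 0.0
    A[3] = quartic - e
    A[4] = quartic + e
    return taus, A


def _j_from_terms(omega, S2: float, tau_e: float, taus: np.ndarray, A: np.ndarray):
    """Evaluate J(omega) given precomputed Woessner terms; omega may be an array."""
    w = np.atleast_1d(np.asarray(omega, float))
    w2 = w[:, None] ** 2
    if tau_e > 0:
        tau_p = taus * tau_e / (taus + tau_e)
    else:
        tau_p = np.zeros_like(taus)
    terms = S2 * taus / (1.0 + w2 * taus**2) + (1.0 - S2) * tau_p / (
        1.0 + w2 * tau_p**2
    )
    J = 0.4 * (terms @ A)
    return J if np.ndim(omega) else float(J[0])


def spectral_density(
    omega,
    S2: float,
    tau_e: float,
    tensor: DiffusionTensor,
    nh_vector: np.ndarray,
    constants: Optional[SpinConstants] = None,
):
    """Model-free spectral density J(omega) under anisotropic tumbling (s/rad).

    ``J = (2/5) sum_k A_k [S2 tau_k / (1 + (w tau_k)^2)
    + (1 - S2) tau'_k / (1 + (w tau'_k)^2)]`` with
    ``1/tau'_k = 1/tau_k + 1/tau_e``.
    """
    if not 0 <= S2 <= 1:
        raise ValueError("S2 must lie in [0, 1]")
    if tau_e < 0:
        raise ValueError("tau_e must be >= 0")
    taus, A = _woessner_terms(tensor, nh_vector)
    return _j_from_terms(omega, S2, tau_e, taus, A)


def predict_relaxation(
    S2: float,
    tau_e: float,
    Rex: float,
    tensor: DiffusionTensor,
    nh_vector: np.ndarray,
    constants: Optional[SpinConstants] = None,
) -> Tuple[float, float, float]:
    """T1 (s), T2 (s) and heteronuclear NOE from model-free parameters.

    Reduced rate equations for an amide 15N relaxed by the N-H dipolar
    interaction and 15N CSA; Rex adds to R2.
    """
    if constants is None:
        constants = SpinConstants()
    taus, A = _woessner_terms(tensor, nh_vector)
    return _predict_from_terms(S2, tau_e, Rex, taus, A, constants)


def _predict_from_terms(
    S2: float, tau_e: float, Rex: float,
    taus: np.ndarray, A: np.ndarray, constants: SpinConstants,
) -> Tuple[float, float, float]:
    wH, wN = constants.omegaH, constants.omegaN
    d2 = constants.dipolar**2
    c2 = constants.csa**2

    freqs = np.abs(np.array([wH - wN, wN, wH + wN, wH, 0.0]))
    JhmN, JN, JhpN, Jh, J0 = _j_from_terms(freqs, S2, tau_e, taus, A)

    R1 = (d2 / 4.0) * (JhmN + 3 * JN + 6 * JhpN) + c2 * JN
    R2 = (
        (d2 / 8.0) * (4 * J0 + JhmN + 3 * JN + 6 * Jh + 6 * JhpN)
        + (c2 / 6.0) * (4 * J0 + 3 * JN)
        + Rex
    )
    noe = 1.0 + (d2 / (4.0 * R1)) * (constants.gammaH / constants.gammaN) * (
        6 * JhpN - JhmN
    )
    return 1.0 / R1, 1.0 / R2, noe


# ---------------------------------------------------------------------------
# Model-free fitting
# ---------------------------------------------------------------------------

_MODEL_PARAMS = {
    "m1": ("S2",),
    "m2": ("S2", "tau_e"),
    "m3": ("S2", "Rex"),
    "m4": ("S2", "tau_e", "Rex"),
}
_BOUNDS = {"S2": (0.0, 1.0), "tau_e": (0.0, 5e-9), "Rex": (0.0, 20.0)}
_N_OBS = 3


# tau_e is optimized in nanoseconds so finite-difference steps stay
# resolvable in float64
_PARAM_SCALE = {"S2": 1.0, "tau_e": 1e-9, "Rex": 1.0}


def _residuals(theta, names, obs, errs, taus, A, constants):
    p = dict(S2=0.0, tau_e=0.0, Rex=0.0)
    for name, val in zip(names, theta):
        p[name] = val * _PARAM_SCALE[name]
    pred = _predict_from_terms(p["S2"], p["tau_e"], p["Rex"], taus, A, constants)
    return (np.array(pred) - obs) / errs


def _fit_one_model(model_id, obs, errs, taus, A, constants):
    names = _MODEL_PARAMS[model_id]
    lo = np.array([_BOUNDS[n][0] / _PARAM_SCALE[n] for n in names])
    hi = np.array([_BOUNDS[n][1] / _PARAM_SCALE[n] for n in names])
    s2_grid = (0.4, 0.7, 0.9)
    te_grid = (0.001, 0.05, 0.5)  # ns
    if names == ("S2",):
        starts = [[s] for s in (0.3, 0.5, 0.7, 0.85, 0.95)]
    elif names == ("S2", "tau_e"):
        starts = [[s, t] for s in s2_grid for t in te_grid]
    elif names == ("S2", "Rex"):
        starts = [[s, r] for s in s2_grid for r in (0.5, 3.0, 10.0)]
    else:
        starts = [[s, t, 2.0] for s in (0.4, 0.6, 0.8, 0.9, 0.95) for t in te_grid]
    best = None
    for x0 in starts:
        try:
            res = optimize.least_squares(
                _residuals, np.clip(x0, lo, hi), bounds=(lo, hi),
                args=(names, obs, errs, taus, A, constants),
                method="trf", xtol=1e-14, ftol=1e-14, gtol=1e-14,
                x_scale=[0.1 if n == "S2" else (0.05 if n == "tau_e" else 1.0) for n in names],
                max_nfev=3000,
            )
        except Exception:
            continue
        chi2 = float(2 * res.cost)
        if best is None or chi2 < best[0]:
            best = (chi2, res.x)
    if best is None:
        raise RuntimeError(f"model {model_id} failed to fit")
    chi2, theta = best
    p = dict(S2=0.0, tau_e=0.0, Rex=0.0)
    for name, val in zip(names, theta):
        p[name] = val * _PARAM_SCALE[name]
    return ModelFreeParams(
        S2=min(max(p["S2"], 0.0), 1.0), tau_e=p["tau_e"], Rex=p["Rex"],
        model_id=model_id, chi2=chi2,
    )


def _chi2_acceptable(fit: ModelFreeParams, alpha: float) -> bool:
    dof = _N_OBS - len(_MODEL_PARAMS[fit.model_id])
    if dof <= 0:
        return True
    return stats.chi2.sf(fit.chi2, dof) > alpha


def _f_test_improves(simple: ModelFreeParams, complex_: ModelFreeParams,
                     alpha: float) -> bool:
    """Is the chi-square drop from simple to complex significant (F-test)?"""
    dof_s = _N_OBS - len(_MODEL_PARAMS[simple.model_id])
    dof_c = _N_OBS - len(_MODEL_PARAMS[complex_.model_id])
    if dof_c <= 0:
        return True
    if complex_.chi2 <= 0:
        return True
    f = ((simple.chi2 - complex_.chi2) / (dof_s - dof_c)) / (complex_.chi2 / dof_c)
    return stats.f.sf(f, dof_s - dof_c, dof_c) < alpha


def _select_model(fits: Dict[str, ModelFreeParams], alpha: float) -> ModelFreeParams:
    """Ladder m1 -> {m2, m3} -> m4.

    A simple model is kept when its chi-square goodness of fit is
    acceptable at level ``alpha``; otherwise the ladder steps up,
    requiring the F-test to confirm the improvement where the richer
    model has residual degrees of freedom.  (A pure pairwise F-test
    ladder fails here: with both tau_e and Rex present, every
    two-parameter model misfits and the F statistic against the equally
    poor one-parameter model stays small.)
    """
    if _chi2_acceptable(fits["m1"], alpha):
        return fits["m1"]
    step2 = min((fits["m2"], fits["m3"]), key=lambda f: f.chi2)
    if _chi2_acceptable(step2, alpha) and _f_test_improves(fits["m1"], step2, alpha):
        return step2
    return fits["m4"]


def fit_model_free(
    data: RelaxationDataset,
    tensor: DiffusionTensor,
    constants: Optional[SpinConstants] = None,
    alpha: float = 0.20,
) -> Dict[int, ModelFreeParams]:
    """Per-residue model-free fit over the m1-m4 ladder.

    chi2 = sum(((obs - pred) / err)^2) over (T1, T2, NOE); bounded
    multi-start least squares with a fixed start grid; the simplest model
    not rejected by the F-test at level ``alpha`` is selected.
    """
    if constants is None:
        constants = SpinConstants()
    out = {}
    for i in range(data.n_residues):
        obs = np.array([data.T1[i], data.T2[i], data.noe[i]])
        errs = np.array([data.T1_err[i], data.T2_err[i], data.noe_err[i]])
        if not np.all(np.isfinite(obs)):
            import warnings

            warnings.warn(f"residue {data.residue_ids[i]}: missing observable, skipped")
            continue
        taus, A = _woessner_terms(tensor, data.nh_vectors[i])
        fits = {m: _fit_one_model(m, obs, errs, taus, A, constants)
                for m in ("m1", "m2", "m3", "m4")}
        out[int(data.residue_ids[i])] = _select_model(fits, alpha)
    return out


# ---------------------------------------------------------------------------
# Diffusion-tensor estimation
# ---------------------------------------------------------------------------

def rigid_residue_mask(data: RelaxationDataset, noe_min: float = 0.65,
                       trim: float = 0.1) -> np.ndarray:
    """Rigidity filter: NOE above threshold and T2 within 1 std of the
    10%-trimmed mean."""
    t2m = stats.trim_mean(data.T2, trim)
    t2s = data.T2.std(ddof=1) if data.n_residues > 1 else 0.0
    return (data.noe > noe_min) & (np.abs(data.T2 - t2m) <= t2s)


def estimate_diffusion_tensor(
    data: RelaxationDataset,
    noe_min: float = 0.65,
    min_rigid: int = 15,
    S2_fixed: float = 0.9,
) -> DiffusionTensor:
    """Fit (Dx, Dy, Dz, orientation) to T1/T2 ratios of rigid residues.

    Residues passing the rigidity filter contribute their T1/T2 ratio;
    internal motion is held fixed (S2 = 0.9, tau_e = 0, Rex = 0) during
    the tensor fit.  The result is orientation-invariant up to axis
    permutation sign; components are returned ascending.
    """
    mask = rigid_residue_mask(data, noe_min=noe_min)
    if mask.sum() < min_rigid:
        raise ValueError(
            f"only {int(mask.sum())} rigid residues pass the filter; need {min_rigid}"
        )
    nh = data.nh_vectors[mask]
    ratio_obs = data.T1[mask] / data.T2[mask]
    ratio_err = ratio_obs * np.sqrt(
        (data.T1_err[mask] / data.T1[mask]) ** 2
        + (data.T2_err[mask] / data.T2[mask]) ** 2
    )
    constants = SpinConstants()

    # isotropic initialisation from the mean ratio
    def iso_ratio(D):
        t1, t2, _ = predict_relaxation(S2_fixed, 0.0, 0.0,
                                       DiffusionTensor.isotropic(D),
                                       np.array([0.0, 0.0, 1.0]), constants)
        return t1 / t2

    target = float(np.mean(ratio_obs))
    lo, hi = 1e6, 1e9
    for _ in range(80):
        mid = np.sqrt(lo * hi)
        if iso_ratio(mid) > target:
            lo = mid
        else:
            hi = mid
    D0 = np.sqrt(lo * hi)

    def resid(theta):
        lDx, lDy, lDz, a, b, g = theta
        tensor = DiffusionTensor.from_euler(np.exp(lDx), np.exp(lDy), np.exp(lDz), a, b, g)
        out = np.empty(mask.sum())
        for i in range(mask.sum()):
            t1, t2, _ = predict_relaxation(S2_fixed, 0.0, 0.0, tensor, nh[i], constants)
            out[i] = (t1 / t2 - ratio_obs[i]) / ratio_err[i]
        return out

    best = None
    l0 = np.log(D0)
    for a0, b0, g0 in [(0.1, 0.2, 0.1), (0.5, 1.0, 0.5), (1.5, 0.8, 2.0), (2.5, 1.8, 1.0)]:
        x0 = np.array([l0 - 0.05, l0, l0 + 0.05, a0, b0, g0])
        res = optimize.least_squares(resid, x0, method="lm", xtol=1e-12, ftol=1e-12)
        if best is None or res.cost < best.cost:
            best = res
    lDx, lDy, lDz, a, b, g = best.x
    return DiffusionTensor.from_euler(np.exp(lDx), np.exp(lDy), np.exp(lDz), a, b, g)


# ---------------------------------------------------------------------------
# Chemical-shift perturbation
# ---------------------------------------------------------------------------

#: 15N weight in the combined shift difference.
CSP_N_WEIGHT = 0.159


def csp(ddH, ddN):
    """Weighted-average 1H/15N shift difference:
    ``sqrt(ddH^2 + (0.159 ddN)^2)`` (ppm)."""
    ddH = np.asarray(ddH, float)
    ddN = np.asarray(ddN, float)
    return np.sqrt(ddH**2 + (CSP_N_WEIGHT * ddN) ** 2)
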