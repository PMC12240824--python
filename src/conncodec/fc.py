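"""Functional connectivity estimation from regional fMRI time series.

Implements the three FC flavors used throughout the package:

* ``pearson`` — Pearson correlation of (censored, filtered, confound-
  regressed) regional time series;
* ``gsr`` — Pearson correlation after additionally regressing the mean
  ("global") signal and its backward temporal derivative from every region;
* ``pcorr`` — Tikhonov-regularized partial correlation: the precision
  matrix (FC + lambda I)^-1 rescaled to partial correlations, with lambda
  chosen to pull each subject's regularized precision toward the population
  mean of the unregularized precision matrices.

Time-series hygiene (outlier censoring at |z| > 5 of the global signal or
motion derivative > 0.9 mm, DCT high-pass filtering, nuisance regression)
operates only on non-censored timepoints; censored rows are carried through
unchanged but stay flagged in the outlier mask.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .flavors import ConnectomeMatrix, FlavorSpec, ValidationError

__all__ = [
    "RegionalTimeseries", "PrecisionTarget",
    "detect_outliers", "regress_confounds", "dct_highpass",
    "pearson_fc", "gsr_fc", "tikhonov_partial_corr",
    "population_precision_target", "fit_lambda", "default_lambda_grid",
    "estimate_fc",
]

GLOBAL_SIGNAL_Z_THRESHOLD = 5.0
MOTION_DERIVATIVE_THRESHOLD_MM = 0.9


@dataclass
class RegionalTimeseries:
    """T x n_regions regional time series with censoring mask and confounds."""

    subject_id: str
    atlas: str
    data: np.ndarray
    sampling_interval: float = 1.0           # seconds (TR)
    outlier_mask: np.ndarray | None = None   # True = censored
    confounds: np.ndarray | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValidationError("time series must be T x n_regions")
        T = self.data.shape[0]
        if self.outlier_mask is None:
            self.outlier_mask = np.zeros(T, dtype=bool)
        else:
            self.outlier_mask = np.asarray(self.outlier_mask, dtype=bool)
            if self.outlier_mask.shape != (T,):
                raise ValidationError("outlier mask length mismatch")
        if self.confounds is not None:
            self.confounds = np.atleast_2d(np.asarray(self.confounds, dtype=float))
            if self.confounds.shape[0] != T:
                raise ValidationError("confound rows do not match T")
        if (~self.outlier_mask).sum() < 3:
            raise ValidationError("need at least 3 non-censored timepoints")

    @property
    def n_regions(self) -> int:
        return self.data.shape[1]

    def with_data(self, data: np.ndarray) -> "RegionalTimeseries":
        return RegionalTimeseries(self.subject_id, self.atlas, data,
                                  self.sampling_interval,
                                  self.outlier_mask.copy(),
                                  None if self.confounds is None else self.confounds.copy())


@dataclass
class PrecisionTarget:
    """Population-mean unregularized precision matrix and fitted lambda."""

    omega_bar: np.ndarray
    used_pseudoinverse: bool
    lambda_star: float
    atlas: str = ""

    def __post_init__(self):
        self.omega_bar = np.asarray(self.omega_bar, dtype=float)
        if np.max(np.abs(self.omega_bar - self.omega_bar.T)) > 1e-8:
            raise ValidationError("omega_bar must be symmetric")
        if self.lambda_star < 0:
            raise ValidationError("lambda_star must be >= 0")


def detect_outliers(ts: RegionalTimeseries, global_signal: np.ndarray,
                    motion_derivative: np.ndarray) -> np.ndarray:
    """Flag timepoints with extreme global signal or motion.

    True where |z(global signal)| > 5 or the framewise motion derivative
    exceeds 0.9 mm.
    """
    T = ts.data.shape[0]
    gs = np.asarray(global_signal, dtype=float).ravel()
    md = np.asarray(motion_derivative, dtype=float).ravel()
    if gs.shape != (T,) or md.shape != (T,):
        raise ValidationError("global signal / motion derivative length mismatch")
    sd = gs.std()
    z = np.zeros(T) if sd == 0 else (gs - gs.mean()) / sd
    return (np.abs(z) > GLOBAL_SIGNAL_Z_THRESHOLD) | (md > MOTION_DERIVATIVE_THRESHOLD_MM)


def _ols_residuals(Y: np.ndarray, X: np.ndarray, keep: np.ndarray) -> np.ndarray:
    """Residualize Y on X using only rows where keep; all rows transformed."""
    beta, *_ = np.linalg.lstsq(X[keep], Y[keep], rcond=None)
    out = Y.copy()
    out[keep] = Y[keep] - X[keep] @ beta
    return out


def regress_confounds(ts: RegionalTimeseries,
                      confounds: np.ndarray | None = None,
                      mask: np.ndarray | None = None,
                      demean: bool = True) -> RegionalTimeseries:
    """Least-squares nuisance regression on non-censored timepoints.

    Censored rows pass through unchanged (they remain flagged and are
    excluded again at correlation time). An intercept is always included
    when ``demean``.
    """
    if confounds is None:
        confounds = ts.confounds
    keep = ~(ts.outlier_mask if mask is None else np.asarray(mask, dtype=bool))
    if confounds is None or np.size(confounds) == 0:
        return ts.with_data(ts.data.copy())
    C = np.atleast_2d(np.asarray(confounds, dtype=float))
    if C.shape[0] != ts.data.shape[0]:
        raise ValidationError("confound rows do not match time series length")
    X = np.column_stack([np.ones(C.shape[0]), C]) if demean else C
    if np.linalg.matrix_rank(X[keep]) < X.shape[1]:
        warnings.warn("rank-deficient confounds: using least-norm solution")
    return ts.with_data(_ols_residuals(ts.data, X, keep))


def _dct_basis(T: int, n_basis: int) -> np.ndarray:
    """First n_basis DCT-II basis functions (including the constant), columns."""
    t = np.arange(T)
    cols = [np.ones(T) / np.sqrt(T)]
    for k in range(1, n_basis):
        cols.append(np.sqrt(2.0 / T) * np.cos(np.pi * k * (2 * t + 1) / (2.0 * T)))
    return np.column_stack(cols)


def dct_highpass(ts: RegionalTimeseries, cutoff_hz: float,
                 mask: np.ndarray | None = None) -> RegionalTimeseries:
    """High-pass filter by projecting out low-frequency DCT components.

    DCT basis function k spans frequency k / (2 T TR); all components below
    ``cutoff_hz`` (plus the constant) are regressed out, fit on non-censored
    rows only. A cutoff above Nyquist is a no-op with a warning.
    """
    if cutoff_hz <= 0:
        raise ValidationError("cutoff_hz must be > 0")
    T = ts.data.shape[0]
    tr = ts.sampling_interval
    nyquist = 0.5 / tr
    if cutoff_hz >= nyquist:
        warnings.warn(f"cutoff {cutoff_hz} Hz is above Nyquist ({nyquist:.4g} Hz); no-op")
        return ts.with_data(ts.data.copy())
    # number of DCT components with frequency < cutoff: k/(2 T tr) < cutoff
    n_drop = int(np.floor(2.0 * T * tr * cutoff_hz))
    n_basis = min(n_drop + 1, T)  # constant + drifts below cutoff
    keep = ~(ts.outlier_mask if mask is None else np.asarray(mask, dtype=bool))
    X = _dct_basis(T, n_basis)
    return ts.with_data(_ols_residuals(ts.data, X, keep))


def _corr_with_zero_variance(D: np.ndarray) -> np.ndarray:
    """Pearson correlation of columns of D; zero-variance columns -> r = 0."""
    sd = D.std(axis=0)
    const = sd < 1e-14
    if np.any(const):
        warnings.warn(f"{int(const.sum())} zero-variance region(s): correlations set to 0")
    Dc = D - D.mean(axis=0)
    denom = np.linalg.norm(Dc, axis=0)
    denom[const] = 1.0
    Dn = Dc / denom
    R = Dn.T @ Dn
    R[const, :] = 0.0
    R[:, const] = 0.0
    np.fill_diagonal(R, np.where(const, 0.0, 1.0))
    return np.clip(R, -1.0, 1.0)


def _fc_flavor(ts: RegionalTimeseries, variant: str) -> FlavorSpec:
    return FlavorSpec(name=f"{ts.atlas}_FC{'' if variant == 'pearson' else variant}",
                      modality="FC", atlas=ts.atlas, n_regions=ts.n_regions,
                      fc_variant=variant)


def pearson_fc(ts: RegionalTimeseries) -> ConnectomeMatrix:
    """Pearson FC on non-censored timepoints (unit diagonal)."""
    keep = ~ts.outlier_mask
    R = _corr_with_zero_variance(ts.data[keep])
    return ConnectomeMatrix(ts.subject_id, _fc_flavor(ts, "pearson"), R)


def gsr_fc(ts: RegionalTimeseries) -> ConnectomeMatrix:
    """Global-signal-regressed Pearson FC.

    Regresses the mean regional signal and its backward derivative (first
    difference, first element 0) from every region before correlating.
    """
    keep = ~ts.outlier_mask
    gs = ts.data.mean(axis=1)
    dgs = np.diff(gs, prepend=gs[0])  # backward derivative, first element 0
    X = np.column_stack([np.ones_like(gs), gs, dgs])
    resid = _ols_residuals(ts.data, X, keep)
    R = _corr_with_zero_variance(resid[keep])
    m = ConnectomeMatrix(ts.subject_id, _fc_flavor(ts, "gsr"), R)
    return m


def tikhonov_partial_corr(fc: ConnectomeMatrix | np.ndarray,
                          lam: float) -> ConnectomeMatrix | np.ndarray:
    """Regularized partial correlation from an FC matrix.

    Omega = (FC + lam I)^-1; output(i,j) = -Omega_ij / sqrt(Omega_ii
    Omega_jj), diagonal 1.
    """
    if lam < 0:
        raise ValidationError("lambda must be >= 0")
    is_cm = isinstance(fc, ConnectomeMatrix)
    C = fc.values if is_cm else np.asarray(fc, dtype=float)
    A = C + lam * np.eye(C.shape[0])
    try:
        omega = np.linalg.inv(A)
    except np.linalg.LinAlgError as e:
        raise ValidationError(
            "FC + lambda I is singular; increase lambda (or use the "
            "pseudoinverse precision target)") from e
    d = np.sqrt(np.abs(np.diag(omega)))
    d[d < 1e-14] = 1.0
    P = -omega / np.outer(d, d)
    P = 0.5 * (P + P.T)
    np.fill_diagonal(P, 1.0)
    if not is_cm:
        return P
    fl = fc.flavor
    out_flavor = FlavorSpec(name=f"{fl.atlas}_FCpcorr", modality="FC",
                            atlas=fl.atlas, n_regions=fl.n_regions,
                            fc_variant="pcorr")
    return ConnectomeMatrix(fc.subject_id, out_flavor, P)


def population_precision_target(fcs: list, use_pseudoinverse: bool = False,
                                atlas: str = "") -> PrecisionTarget:
    """Population mean of the unregularized (pseudo)inverted FC matrices."""
    if not fcs:
        raise ValidationError("need at least one subject FC")
    mats = [f.values if isinstance(f, ConnectomeMatrix) else np.asarray(f, dtype=float)
            for f in fcs]
    n = mats[0].shape[0]
    acc = np.zeros((n, n))
    for i, C in enumerate(mats):
        if use_pseudoinverse:
            acc += np.linalg.pinv(C)
        else:
            if np.linalg.matrix_rank(C) < n:
                sid = fcs[i].subject_id if isinstance(fcs[i], ConnectomeMatrix) else str(i)
                raise ValidationError(
                    f"subject {sid}: FC is singular; set use_pseudoinverse=True")
            acc += np.linalg.inv(C)
    omega_bar = 0.5 * (acc + acc.T) / len(mats)
    return PrecisionTarget(omega_bar, use_pseudoinverse, 0.0, atlas=atlas)


def default_lambda_grid() -> np.ndarray:
    """0 plus 40 log-spaced values in 10^-3 .. 10^1."""
    return np.concatenate([[0.0], np.logspace(-3, 1, 40)])


def fit_lambda(fcs: list, target: PrecisionTarget,
               grid: np.ndarray | None = None) -> float:
    """Grid-search lambda minimizing sum_a ||(FC_a + lam I)^-1 - omega_bar||_F.

    Ties break toward smaller lambda. Singular grid points are skipped; it
    is an error if every grid value is singular.
    """
    if grid is None:
        grid = default_lambda_grid()
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValidationError("lambda grid is empty")
    if np.any(grid < 0):
        raise ValidationError("lambda grid must be nonnegative")
    mats = [f.values if isinstance(f, ConnectomeMatrix) else np.asarray(f, dtype=float)
            for f in fcs]
    best_lam, best_loss = None, np.inf
    for lam in np.sort(grid):
        loss = 0.0
        ok = True
        for C in mats:
            A = C + lam * np.eye(C.shape[0])
            try:
                omega = np.linalg.inv(A)
            except np.linalg.LinAlgError:
                ok = False
                break
            loss += np.linalg.norm(omega - target.omega_bar, "fro")
        if not ok:
            continue
        loss /= len(mats)
        if loss < best_loss - 1e-15:  # strict improvement; ties keep smaller lam
            best_lam, best_loss = float(lam), loss
    if best_lam is None:
        raise ValidationError("every lambda in the grid gave a singular matrix")
    return best_lam


def estimate_fc(ts: RegionalTimeseries, variant: str,
                lam: float | str = "auto",
                precision_target: PrecisionTarget | None = None,
                highpass_hz: float | None = None) -> ConnectomeMatrix:
    """One-stop FC estimation for a single subject.

    For ``pcorr`` with ``lam="auto"`` a precomputed ``precision_target``
    with its fitted ``lambda_star`` is required (lambda is a population-level
    parameter, fitted once on training subjects).
    """
    if highpass_hz is not None:
        ts = dct_highpass(ts, highpass_hz)
    if ts.confounds is not None:
        ts = regress_confounds(ts)
    if variant == "pearson":
        return pearson_fc(ts)
    if variant == "gsr":
        return gsr_fc(ts)
    if variant == "pcorr":
        base = pearson_fc(ts)
        if lam == "auto":
            if precision_target is None:
                raise ValidationError(
                    "pcorr with lam='auto' needs a fitted PrecisionTarget")
            lam = precision_target.lambda_star
        return tikhonov_partial_corr(base, float(lam))
    raise ValidationError(f"unknown FC variant {variant!r}")
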