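"""First-level fMRI GLM with belief/uncertainty parametric modulators.

Cue-phase event regressors are built separately for Choice and noChoice
trials, each paired with a parametric modulator carrying that condition's
belief (``mu``) or uncertainty (``sigma``) trajectory, mean-centered within
condition before convolution with a canonical double-gamma HRF.  Selection
and Outcome phases are modelled as events of no interest; a discrete-cosine
drift basis implements the high-pass filter.  Two separate GLMs are built —
one for beliefs (SE-B: mu_self > mu_other), one for uncertainties (SE-U:
sigma_self > sigma_other) — because belief and uncertainty trajectories are
correlated within subject.

The module operates on one or a few synthetic voxels: it validates regressor
construction and contrast logic, not whole-brain voxelwise inference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import lfilter
from scipy.stats import gamma as gamma_dist
from scipy.stats import t as t_dist

__all__ = [
    "ScanParams",
    "DesignMatrix",
    "ContrastResult",
    "canonical_hrf",
    "build_design",
    "simulate_bold",
    "fit_first_level",
    "extract_eigenvariate",
]


@dataclass(frozen=True)
class ScanParams:
    """Acquisition parameters: TR 1.4 s, 483 volumes, 128 s high-pass."""

    tr_s: float = 1.4
    n_volumes: int = 483
    highpass_s: float = 128.0
    microtime_bins: int = 16

    def __post_init__(self) -> None:
        if self.tr_s <= 0 or self.n_volumes <= 0 or self.microtime_bins < 1:
            raise ValueError("invalid scan parameters")

    @property
    def duration_s(self) -> float:
        return self.tr_s * self.n_volumes


def canonical_hrf(dt: float, length_s: float = 32.0) -> np.ndarray:
    """Canonical double-gamma haemodynamic response function.

    Peak at 6 s, undershoot at 16 s, peak:undershoot ratio 6; sampled at
    ``dt`` and normalized to unit peak.
    """
    t = np.arange(0.0, length_s, dt)
    h = gamma_dist.pdf(t, 6.0) - gamma_dist.pdf(t, 16.0) / 6.0
    return h / h.max()


@dataclass
class DesignMatrix:
    """Volumes x regressors design with named columns."""

    X: np.ndarray
    columns: list[str]
    modulator_kind: str
    scan: ScanParams

    def column(self, name: str) -> np.ndarray:
        return self.X[:, self.columns.index(name)]


def _event_regressor(onsets, durations, amplitudes, scan: ScanParams,
                     hrf: np.ndarray) -> np.ndarray:
    dt = scan.tr_s / scan.microtime_bins
    n_fine = scan.n_volumes * scan.microtime_bins
    stick = np.zeros(n_fine)
    for o, d, a in zip(onsets, durations, amplitudes):
        i0 = int(round(o / dt))
        i1 = max(i0 + 1, int(round((o + d) / dt)))
        if i0 >= n_fine:
            raise ValueError(f"event onset {o:.1f}s beyond scan end")
        stick[i0:min(i1, n_fine)] += a
    conv = np.convolve(stick, hrf)[:n_fine]
    return conv[:: scan.microtime_bins]


def _dct_basis(n: int, tr: float, highpass_s: float) -> np.ndarray:
    k_max = int(np.floor(2.0 * n * tr / highpass_s))
    i = np.arange(n)
    cols = [np.cos(np.pi * k * (2 * i + 1) / (2.0 * n)) * np.sqrt(2.0 / n)
            for k in range(1, k_max + 1)]
    return np.column_stack(cols) if cols else np.empty((n, 0))


def build_design(session, beliefs, modulator_kind: str,
                 scan: ScanParams | None = None,
                 nuisance: np.ndarray | None = None,
                 standardize_modulators: bool = False) -> DesignMatrix:
    """Build the first-level design for one session.

    ``modulator_kind='mu'`` modulates the Cue phase with the belief
    trajectories (SE-B GLM); ``'sigma'`` with the uncertainty trajectories
    (SE-U GLM).  Modulator values are mean-centered within condition (or
    z-scored when ``standardize_modulators``) before convolution, so the
    modulated column is orthogonal to its unmodulated parent at event level.
    """
    scan = scan or ScanParams()
    if modulator_kind not in ("mu", "sigma"):
        raise ValueError("modulator_kind must be 'mu' or 'sigma'")
    if modulator_kind == "mu":
        mod_c, mod_n = beliefs.mu_self, beliefs.mu_other
    else:
        mod_c, mod_n = beliefs.sigma_self, beliefs.sigma_other

    cond_trials = {
        "Choice": [t for t in session.trials if t.condition == "Choice"],
        "noChoice": [t for t in session.trials if t.condition == "noChoice"],
    }
    if len(cond_trials["Choice"]) != len(mod_c) or \
            len(cond_trials["noChoice"]) != len(mod_n):
        raise ValueError("modulator trajectories misaligned with session trials")

    hrf = canonical_hrf(scan.tr_s / scan.microtime_bins)
    cfg = session.config
    cols, names = [], []
    for cond, mod in (("Choice", mod_c), ("noChoice", mod_n)):
        trials = cond_trials[cond]
        onsets = [t.onset_cue_s for t in trials]
        durs = [cfg.cue_dur_s] * len(trials)
        mod = np.asarray(mod, float)
        centered = mod - mod.mean()
        if standardize_modulators:
            sd = centered.std()
            if sd > 0:
                centered = centered / sd
        cols.append(_event_regressor(onsets, durs, np.ones(len(trials)), scan, hrf))
        names.append(f"cue_{cond}")
        cols.append(_event_regressor(onsets, durs, centered, scan, hrf))
        names.append(f"cue_{cond}_x_{modulator_kind}")
    for phase, attr, dur in (("selection", "onset_selection_s", cfg.selection_dur_s),
                             ("outcome", "onset_outcome_s", cfg.outcome_dur_s)):
        onsets = [getattr(t, attr) for t in session.trials]
        cols.append(_event_regressor(onsets, [dur] * len(onsets),
                                     np.ones(len(onsets)), scan, hrf))
        names.append(phase)

    dct = _dct_basis(scan.n_volumes, scan.tr_s, scan.highpass_s)
    for k in range(dct.shape[1]):
        cols.append(dct[:, k])
        names.append(f"dct_{k + 1}")
    if nuisance is not None:
        nuisance = np.atleast_2d(np.asarray(nuisance, float))
        if nuisance.shape[0] != scan.n_volumes:
            nuisance = nuisance.T
        for k in range(nuisance.shape[1]):
            cols.append(nuisance[:, k])
            names.append(f"nuisance_{k + 1}")
    cols.append(np.ones(scan.n_volumes))
    names.append("intercept")
    return DesignMatrix(np.column_stack(cols), names, modulator_kind, scan)


def simulate_bold(design: DesignMatrix, true_betas, noise_sigma: float = 1.0,
                  ar1_phi: float = 0.0, seed: int = 0) -> np.ndarray:
    """Synthetic BOLD: ``y = X beta + eps`` with AR(1) Gaussian noise.

    ``true_betas`` is a mapping column-name -> effect (unnamed columns get
    0) or a full per-column vector.
    """
    if isinstance(true_betas, dict):
        unknown = set(true_betas) - set(design.columns)
        if unknown:
            raise ValueError(f"betas refer to unknown columns: {sorted(unknown)}")
        beta = np.array([true_betas.get(c, 0.0) for c in design.columns])
    else:
        beta = np.asarray(true_betas, float)
        if beta.shape != (design.X.shape[1],):
            raise ValueError("beta length does not match design columns")
    rng = np.random.default_rng(seed)
    n = design.X.shape[0]
    white = rng.standard_normal(n) * noise_sigma
    if ar1_phi != 0.0:
        eps = lfilter([1.0], [1.0, -ar1_phi], white)
        eps *= np.sqrt(1.0 - ar1_phi**2)  # keep stationary variance = sigma^2
    else:
        eps = white
    return design.X @ beta + eps


@dataclass
class ContrastResult:
    beta: dict[str, float]
    contrast_value: float
    t_stat: float
    F_stat: float
    dof: int
    p: float
    ar1_phi_hat: float = 0.0


def _ols(y: np.ndarray, X: np.ndarray):
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return beta, resid, rank


def fit_first_level(bold: np.ndarray, design: DesignMatrix,
                    contrast: str | np.ndarray = "self_gt_other",
                    prewhiten: bool = True) -> ContrastResult:
    """OLS fit of one voxel/region series with optional AR(1) prewhitening.

    The default contrast is the modulator-beta difference self - other
    (SE-B for a ``mu`` design, SE-U for a ``sigma`` design).  AR(1)
    prewhitening estimates phi from the lag-1 autocorrelation of the OLS
    residuals and refits on the transformed model (one iteration).
    """
    y = np.asarray(bold, float)
    X = design.X
    if y.shape[0] != X.shape[0]:
        raise ValueError("series and design lengths differ")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = np.corrcoef(X, rowvar=False)
        np.fill_diagonal(corr, 0.0)
        i, j = np.unravel_index(np.nanargmax(np.abs(corr)), corr.shape)
        raise ValueError(
            f"rank-deficient design (rank {rank} < {X.shape[1]}); most "
            f"collinear pair: {design.columns[i]!r}, {design.columns[j]!r}"
        )

    if isinstance(contrast, str):
        if contrast != "self_gt_other":
            raise ValueError(f"unknown contrast {contrast!r}")
        c = np.zeros(X.shape[1])
        kind = design.modulator_kind
        c[design.columns.index(f"cue_Choice_x_{kind}")] = 1.0
        c[design.columns.index(f"cue_noChoice_x_{kind}")] = -1.0
    else:
        c = np.asarray(contrast, float)

    beta, resid, _ = _ols(y, X)
    phi = 0.0
    if prewhiten:
        denom = float(resid @ resid)
        if denom > 0:
            phi = float(resid[1:] @ resid[:-1] / denom)
            phi = float(np.clip(phi, -0.99, 0.99))
        if abs(phi) > 1e-8:
            yw = y.copy()
            Xw = X.copy()
            yw[1:] = y[1:] - phi * y[:-1]
            Xw[1:] = X[1:] - phi * X[:-1]
            yw[0] *= np.sqrt(1 - phi**2)
            Xw[0] *= np.sqrt(1 - phi**2)
            y, X = yw, Xw
            beta, resid, _ = _ols(y, X)

    n, p = X.shape
    dof = n - rank
    sigma2 = float(resid @ resid) / dof
    XtX_inv = np.linalg.pinv(X.T @ X)
    cval = float(c @ beta)
    var_c = sigma2 * float(c @ XtX_inv @ c)
    t_stat = cval / np.sqrt(var_c) if var_c > 0 else np.inf * np.sign(cval)
    p_val = 2.0 * t_dist.sf(abs(t_stat), dof)
    return ContrastResult(
        beta=dict(zip(design.columns, beta)),
        contrast_value=cval,
        t_stat=float(t_stat),
        F_stat=float(t_stat**2),
        dof=int(dof),
        p=float(p_val),
        ar1_phi_hat=phi,
    )


def extract_eigenvariate(values: np.ndarray) -> np.ndarray:
    """First eigenvariate of a subjects x voxels matrix.

    The first left singular vector of the column-centered matrix, scaled by
    its singular value over sqrt(n_voxels), sign-aligned so that it
    correlates positively with the subject-wise row mean.
    """
    V = np.asarray(values, float)
    if V.ndim == 1:
        V = V[:, None]
    if V.size == 0 or not np.any(V != 0):
        raise ValueError("eigenvariate of an empty or all-zero matrix")
    Vc = V - V.mean(axis=0, keepdims=True)
    U, S, _ = np.linalg.svd(Vc, full_matrices=False)
    scores = U[:, 0] * S[0] / np.sqrt(V.shape[1])
    rowmean = Vc.mean(axis=1)
    if float(scores @ rowmean) < 0:
        scores = -scores
    return scores
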