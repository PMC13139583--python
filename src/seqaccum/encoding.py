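"""Population encoding and decoding analyses of position-binned activity.

Four analyses probe how accumulated evidence is represented beyond the
single-neuron tuning fits:

* **Cue response kernels** — a ridge-regularized linear encoding model of
  the right-minus-left preferring population activity difference, with
  each cue onset convolved against a cubic B-spline basis (7 degrees of
  freedom).  Step-like, sustained kernels of opposite sign for right and
  left cues are the signature of integration.
* **Evidence-vs-choice regression** — per neuron and position bin,
  FR = b0 + b1*e + b2*c on correct and incorrect trials, with one-sided
  partial F-tests per coefficient at the 1% level; the fraction of active
  neurons significant for evidence or for choice traces the shift from
  graded evidence coding to binary choice coding along the maze.
* **Linear evidence decoding** — per position bin, ridge regression from
  the active population to the evidence with nested five-fold
  cross-validation, fit separately for trials with evidence >= 0 and
  <= 0 (or strictly >/<, to rule out sign-of-evidence shortcuts), scored
  by the Pearson correlation between decoded and actual evidence, against
  within-sign shuffle controls.
* **Population-averaged maps** — mean rates in position x preferred-
  evidence bins (each neuron's evidence axis reflected so its fitted
  evidence mean is positive), with occupancy masking.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import BSpline
from sklearn.linear_model import Ridge
from sklearn.model_selection import GridSearchCV, KFold

from .maze import MazeGeometry, Trial, final_evidence
from .tuning import BinnedSession

__all__ = [
    "KernelFit",
    "cubic_spline_basis",
    "population_difference_trace",
    "fit_cue_kernels",
    "evidence_choice_regression",
    "linear_evidence_decoder",
    "population_average_map",
    "population_response_by_final_evidence",
]

DECODER_ALPHA_GRID = (0.0001, 0.001, 0.01, 0.1, 1.0, 10.0, 100.0, 1000.0)


def cubic_spline_basis(length: float, step: float, df: int = 7) -> np.ndarray:
    """Cubic B-spline basis on [0, length] sampled every ``step`` cm.

    Returns (n_samples, df).  Knots are clamped at the ends with df - 4
    evenly spaced interior knots, the standard construction for a
    ``df``-dimensional cubic spline space.
    """
    if df < 4:
        raise ValueError("cubic basis needs df >= 4")
    x = np.arange(0.0, length + 0.5 * step, step)
    interior = np.linspace(0, length, df - 2)[1:-1]
    t = np.r_[[0.0] * 4, interior, [length] * 4]
    B = BSpline.design_matrix(x, t, 3, extrapolate=False).toarray()
    return B


@dataclass
class KernelFit:
    """Fitted cue response kernels and the underlying spline coefficients."""

    support: np.ndarray          # positions 0..width (cm)
    K_L: np.ndarray
    K_R: np.ndarray
    beta_L: np.ndarray
    beta_R: np.ndarray
    intercept: float
    r2: float
    group: str = "all"


def _preference_masks(fits: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    sig = fits[fits["significant"]]
    right = sig.loc[sig["mu_e"] > 0, "neuron"].to_numpy(int)
    left = sig.loc[sig["mu_e"] < 0, "neuron"].to_numpy(int)
    return left, right


def population_difference_trace(
    binned: BinnedSession, fits: pd.DataFrame
) -> np.ndarray:
    """Right-preferring minus left-preferring mean activity, (trials, bins).

    Uses the significantly evidence-tuned neurons only; preference is the
    sign of the fitted evidence mean.
    """
    left, right = _preference_masks(fits)
    if left.size == 0 or right.size == 0:
        raise ValueError("need at least one significant neuron per preference")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        mr = np.nanmean(binned.rates[right], axis=0)
        ml = np.nanmean(binned.rates[left], axis=0)
    return mr - ml


def _cue_groups(trial: Trial, side: str, split: str, geometry: MazeGeometry):
    """Yield (group label, cue position) pairs under the requested split."""
    cues = trial.left_cues if side == "left" else trial.right_cues
    if split == "none":
        for c in cues:
            yield "all", c
        return
    if split == "position":
        for c in cues:
            if c < 70:
                yield "early", c
            elif c <= 140:
                yield "middle", c
            else:
                yield "late", c
        return
    if split == "evidence":
        # evidence accumulated before the cue appears
        merged = sorted(
            [(c, +1) for c in trial.right_cues] + [(c, -1) for c in trial.left_cues]
        )
        run = 0
        prior = {}
        for c, s in merged:
            prior[(c, s)] = run
            run += s
        for c in cues:
            s = -1 if side == "left" else +1
            e = abs(prior[(c, s)])
            if e <= 1:
                yield "low", c
            elif e <= 4:
                yield "medium", c
            else:
                yield "high", c
        return
    raise ValueError(f"unknown split {split!r}")


KERNEL_WIDTHS = {
    "none": {"all": 300.0},
    "evidence": {"low": 300.0, "medium": 200.0, "high": 200.0},
    "position": {"early": 300.0, "middle": 230.0, "late": 160.0},
}


def fit_cue_kernels(
    traces: np.ndarray,
    trials: Sequence[Trial],
    bin_centers: np.ndarray,
    df: int = 7,
    alpha: float = 1.0,
    onset_lead: float = 10.0,
    split: str = "none",
    widths: dict | None = None,
) -> list[KernelFit]:
    """Fit left/right cue response kernels by ridge regression.

    ``traces`` is (n_trials, n_bins): the population activity difference
    per trial on the position bins ``bin_centers``.  Each cue contributes
    a binary onset regressor at the bin where it becomes visible
    (``onset_lead`` cm before the tower position), convolved with each of
    the ``df`` spline basis functions; left and right cues get separate
    coefficients (and separate groups under the prior-evidence or
    cue-position splits).  The ridge intercept is unpenalized.
    """
    traces = np.asarray(traces, dtype=float)
    n_trials, n_bins = traces.shape
    step = float(bin_centers[1] - bin_centers[0])
    widths = widths or KERNEL_WIDTHS[split]
    groups = sorted(widths)
    bases = {g: cubic_spline_basis(widths[g], step, df) for g in groups}
    geometry = MazeGeometry()

    cols = []
    col_meta = []
    for side in ("left", "right"):
        for g in groups:
            B = bases[g]
            X_part = np.zeros((n_trials, n_bins, df))
            for k, tr in enumerate(trials):
                onset_bins = [
                    int(np.clip(np.searchsorted(bin_centers, c - onset_lead), 0, n_bins - 1))
                    for gg, c in _cue_groups(tr, side, split, geometry)
                    if gg == g
                ]
                for ob in onset_bins:
                    span = min(B.shape[0], n_bins - ob)
                    X_part[k, ob : ob + span, :] += B[:span]
            cols.append(X_part.reshape(n_trials * n_bins, df))
            col_meta.extend((side, g, j) for j in range(df))
    X = np.concatenate(cols, axis=1)
    y = traces.reshape(-1)
    ok = np.isfinite(y)
    model = Ridge(alpha=alpha, fit_intercept=True)
    model.fit(X[ok], y[ok])
    r2 = model.score(X[ok], y[ok])

    out = []
    coef = model.coef_
    meta = np.array(col_meta, dtype=object)
    for g in groups:
        B = bases[g]
        support = np.arange(0.0, widths[g] + 0.5 * step, step)
        bl = coef[[i for i, m in enumerate(col_meta) if m[0] == "left" and m[1] == g]]
        br = coef[[i for i, m in enumerate(col_meta) if m[0] == "right" and m[1] == g]]
        out.append(
            KernelFit(
                support=support,
                K_L=B @ bl,
                K_R=B @ br,
                beta_L=bl,
                beta_R=br,
                intercept=float(model.intercept_),
                r2=float(r2),
                group=g,
            )
        )
    return out


def _ols_partial_f(X: np.ndarray, Y: np.ndarray):
    """Vectorized OLS of many responses on one design.

    Returns (beta, one-sided partial-F p-values), each (n_params,
    n_responses).  The partial F for one coefficient equals the squared t
    statistic, F(1, n - k); its upper-tail p-value is reported.
    """
    n, k = X.shape
    XtX_inv = np.linalg.pinv(X.T @ X)
    beta = XtX_inv @ X.T @ Y
    resid = Y - X @ beta
    dof = n - k
    s2 = np.sum(resid**2, axis=0) / dof
    var = np.outer(np.diag(XtX_inv), s2)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = beta**2 / var
    p = stats.f.sf(F, 1, dof)
    return beta, p


def evidence_choice_regression(
    binned: BinnedSession,
    fits: pd.DataFrame,
    alpha: float = 0.01,
    position_bins: Sequence[int] | None = None,
) -> pd.DataFrame:
    """Single-neuron evidence vs. choice encoding model, per position bin.

    FR_i = b0 + b1 * e(p) + b2 * c is fit by OLS on all trials (correct
    and incorrect); c codes the upcoming choice (left = 0, right = 1).
    Neurons are "active" at a bin when |p - mu_p| < sigma_p from the joint
    tuning fit.  Returns one row per (bin, neuron) with coefficients,
    p-values, and significance flags at ``alpha``.
    """
    if len(set(binned.choices)) < 2:
        raise ValueError("need both choices present in the session")
    centers = binned.bin_centers
    c_code = (binned.choices == "right").astype(float)
    fit_idx = fits.set_index("neuron")
    bins = range(len(centers)) if position_bins is None else position_bins
    rows = []
    for b in bins:
        p = centers[b]
        active = [
            int(u)
            for u in fit_idx.index
            if abs(p - fit_idx.at[u, "mu_p"]) < fit_idx.at[u, "sigma_p"]
        ]
        if not active:
            continue
        e = binned.evidence[:, b].astype(float)
        X = np.column_stack([np.ones_like(e), e, c_code])
        Y = binned.rates[active, :, b].T  # (trials, active neurons)
        ok = np.all(np.isfinite(Y), axis=1) & np.isfinite(e)
        if ok.sum() < 5:
            continue
        beta, pvals = _ols_partial_f(X[ok], Y[ok])
        for j, u in enumerate(active):
            rows.append(
                {
                    "bin": b,
                    "position": p,
                    "neuron": u,
                    "beta0": beta[0, j],
                    "beta_evidence": beta[1, j],
                    "beta_choice": beta[2, j],
                    "p_evidence": pvals[1, j],
                    "p_choice": pvals[2, j],
                    "sig_evidence": pvals[1, j] < alpha,
                    "sig_choice": pvals[2, j] < alpha,
                }
            )
    return pd.DataFrame(rows)


def fraction_significant(encoding: pd.DataFrame) -> pd.DataFrame:
    """Fraction of active neurons significant for evidence/choice per bin."""
    return (
        encoding.groupby(["bin", "position"])[["sig_evidence", "sig_choice"]]
        .mean()
        .reset_index()
        .rename(
            columns={"sig_evidence": "frac_evidence", "sig_choice": "frac_choice"}
        )
    )


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if a.size < 2 or np.std(a) == 0 or np.std(b) == 0:
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


def linear_evidence_decoder(
    binned: BinnedSession,
    fits: pd.DataFrame,
    strict: bool = False,
    n_outer: int = 5,
    n_inner: int = 5,
    alphas: Sequence[float] = DECODER_ALPHA_GRID,
    n_shuffles: int = 5,
    position_bins: Sequence[int] | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Cross-validated linear decoding of evidence per position bin.

    Correct trials only.  Two decoders per bin: evidence >= 0 and <= 0
    (or strictly > / < 0 when ``strict``), so that decoding accuracy
    cannot come from predicting the choice or the sign of the evidence.
    Nested CV: the outer five folds score held-out Pearson correlation;
    the inner five folds select the ridge regularization from ``alphas``.
    Shuffle controls permute evidence across trials of the same sign.
    """
    rng = rng if rng is not None else np.random.default_rng()
    centers = binned.bin_centers
    correct = binned.correct
    fit_idx = fits.set_index("neuron")
    bins = range(len(centers)) if position_bins is None else position_bins
    rows = []
    for b in bins:
        p = centers[b]
        active = [
            int(u)
            for u in fit_idx.index
            if abs(p - fit_idx.at[u, "mu_p"]) < fit_idx.at[u, "sigma_p"]
        ]
        if not active:
            continue
        e_all = binned.evidence[:, b].astype(float)
        for branch, mask in (
            ("positive", e_all > 0 if strict else e_all >= 0),
            ("negative", e_all < 0 if strict else e_all <= 0),
        ):
            sel = mask & correct
            X = binned.rates[active][:, sel, b].T
            y = e_all[sel]
            ok = np.all(np.isfinite(X), axis=1)
            X, y = X[ok], y[ok]
            if y.size < 2 * n_outer or np.std(y) == 0:
                rows.append(
                    {"bin": b, "position": p, "branch": branch,
                     "correlation": np.nan, "shuffle_correlation": np.nan,
                     "n_trials": int(y.size), "n_neurons": len(active)}
                )
                continue
            corr = _nested_cv_corr(X, y, alphas, n_outer, n_inner, rng)
            shuf = []
            for _ in range(n_shuffles):
                y_s = y.copy()
                rng.shuffle(y_s)
                shuf.append(_nested_cv_corr(X, y_s, alphas, n_outer, n_inner, rng))
            rows.append(
                {"bin": b, "position": p, "branch": branch,
                 "correlation": corr,
                 "shuffle_correlation": float(np.nanmean(shuf)),
                 "n_trials": int(y.size), "n_neurons": len(active)}
            )
    return pd.DataFrame(rows)


def _nested_cv_corr(X, y, alphas, n_outer, n_inner, rng) -> float:
    outer = KFold(n_splits=n_outer, shuffle=True,
                  random_state=int(rng.integers(2**31)))
    scores = []
    for tr, te in outer.split(X):
        gs = GridSearchCV(
            Ridge(),
            {"alpha": list(alphas)},
            cv=KFold(n_splits=min(n_inner, len(tr)), shuffle=True,
                     random_state=int(rng.integers(2**31))),
            scoring="neg_mean_squared_error",
        )
        gs.fit(X[tr], y[tr])
        scores.append(_pearson(gs.predict(X[te]), y[te]))
    return float(np.nanmean(scores))


def population_average_map(
    sessions: Sequence[tuple[BinnedSession, pd.DataFrame]],
    min_obs: int = 3,
    session_frac: float = 0.1,
    ev_range: tuple[int, int] = (-15, 15),
) -> dict:
    """Mean rate of evidence-tuned neurons in position x preferred-evidence
    bins, averaged across neurons from all sessions.

    The evidence axis of each left-preferring neuron (fitted mu_e < 0) is
    reflected so all neurons share a preferred-evidence axis.  A neuron
    contributes to a bin only when it has >= ``min_obs`` observations
    there; bins sampled that often in fewer than ``session_frac`` of
    sessions are masked in the output.
    """
    first = sessions[0][0]
    n_bins = first.bin_centers.size
    lo, hi = ev_range
    n_ev = hi - lo + 1
    total = np.zeros((n_bins, n_ev))
    count = np.zeros((n_bins, n_ev))
    sess_ok = np.zeros((n_bins, n_ev))
    for binned, fits in sessions:
        sig = fits[fits["significant"]]
        sess_any = np.zeros((n_bins, n_ev), bool)
        for _, row in sig.iterrows():
            u = int(row["neuron"])
            flip = -1 if row["mu_e"] < 0 else 1
            ev = flip * binned.evidence  # (trials, bins) in preferred units
            r = binned.rates[u]
            for b in range(n_bins):
                eb = ev[:, b]
                rb = r[:, b]
                ok = np.isfinite(rb) & (eb >= lo) & (eb <= hi)
                if ok.sum() == 0:
                    continue
                idx = (eb[ok] - lo).astype(int)
                cnt = np.bincount(idx, minlength=n_ev)
                means = np.where(
                    cnt >= min_obs,
                    np.bincount(idx, weights=rb[ok], minlength=n_ev)
                    / np.maximum(cnt, 1),
                    np.nan,
                )
                use = cnt >= min_obs
                total[b, use] += means[use]
                count[b, use] += 1
                sess_any[b, use] = True
        sess_ok += sess_any
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = total / count
    masked = sess_ok < max(1, int(np.ceil(session_frac * len(sessions))))
    mean[masked] = np.nan
    return {
        "map": mean,
        "bin_centers": first.bin_centers,
        "preferred_evidence": np.arange(lo, hi + 1),
        "n_contributing": count,
    }


def map_cross_sections(pop_map: dict, positions: Sequence[float]) -> pd.DataFrame:
    """Cross-sections of the population map at the requested positions."""
    centers = pop_map["bin_centers"]
    rows = []
    for p in positions:
        b = int(np.argmin(np.abs(centers - p)))
        for j, e in enumerate(pop_map["preferred_evidence"]):
            rows.append(
                {"position": centers[b], "preferred_evidence": e,
                 "rate": pop_map["map"][b, j]}
            )
    return pd.DataFrame(rows)


def population_response_by_final_evidence(
    binned: BinnedSession,
    fits: pd.DataFrame,
    encoding: pd.DataFrame,
    bands: dict | None = None,
) -> pd.DataFrame:
    """Right-minus-left preferring population difference per position,
    split by the trial's final |evidence| band (correct trials only).

    A neuron contributes at a bin when it is active there (|p - mu_p| <
    sigma_p) and carries a significant evidence coefficient at any bin of
    the encoding model.
    """
    bands = bands or {"low": (1, 3), "medium": (4, 6), "high": (7, np.inf)}
    sig_ev_neurons = set(
        encoding.loc[encoding["sig_evidence"], "neuron"].astype(int)
    )
    fit_idx = fits.set_index("neuron")
    centers = binned.bin_centers
    finals = np.array([final_evidence(t) for t in binned.trials])
    correct = binned.correct
    rows = []
    for band, (blo, bhi) in bands.items():
        tr_mask = correct & (np.abs(finals) >= blo) & (np.abs(finals) <= bhi)
        if tr_mask.sum() == 0:
            for b, p in enumerate(centers):
                rows.append({"band": band, "bin": b, "position": p,
                             "difference": np.nan, "n_trials": 0})
            continue
        # signed difference: right-final-evidence trials keep sign, left flip
        sign = np.sign(finals)
        for b, p in enumerate(centers):
            active = [
                u for u in sig_ev_neurons
                if u in fit_idx.index
                and abs(p - fit_idx.at[u, "mu_p"]) < fit_idx.at[u, "sigma_p"]
            ]
            right = [u for u in active if fit_idx.at[u, "mu_e"] > 0]
            left = [u for u in active if fit_idx.at[u, "mu_e"] < 0]
            if not right or not left:
                rows.append({"band": band, "bin": b, "position": p,
                             "difference": np.nan, "n_trials": int(tr_mask.sum())})
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                diff = np.nanmean(binned.rates[right][:, tr_mask, b]) - np.nanmean(
                    binned.rates[left][:, tr_mask, b]
                )
                # express in the direction of the trial's majority side
                d_signed = np.nanmean(
                    sign[tr_mask]
                    * (
                        np.nanmean(binned.rates[right][:, tr_mask, b], axis=0)
                        - np.nanmean(binned.rates[left][:, tr_mask, b], axis=0)
                    )
                )
            rows.append({"band": band, "bin": b, "position": p,
                         "difference": float(d_signed),
                         "n_trials": int(tr_mask.sum())})
    return pd.DataFrame(rows)
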