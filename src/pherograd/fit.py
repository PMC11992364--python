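"""Binning, joint Hill-response fitting and parameter-recovery experiments.

The analysis pipeline mirrors the half-domain experiment: single-cell
readouts are binned along the axis perpendicular to the light-dark border
(100-μm bins, per-bin mean and standard error, a left margin trimmed to
avoid reflective-wall accumulation), and both readout channels — the n = 1
gene-expression channel and the switch-like morphology channel — are fitted
simultaneously by least squares to

    θ̂_g(x) = A_g · θ(x; λ, C, n=1)  + b_g
    θ̂_m(x) = A_m · θ(x; λ, C, n_m) + b_m

with the gradient parameters λ (decay length) and C (far-field concentration
in EC50 units) shared between channels. The morphology Hill coefficient n_m
is selected by exhaustive minimization over the integers 1–7. Sharing λ and
C across two channels with different Hill coefficients is what makes the
amplitude A and the concentration scale C separately identifiable.

The perfect-sink geometry is then a zero-parameter prediction: the same
fitted (λ, C, A_m, b_m, n_m) pushed through the sink profile, with nothing
refitted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .profiles import (
    GradientShape,
    ResponseParams,
    source_profile,
    sink_profile,
    hill_response,
)
from .simulate import PopulationConfig, NoiseConfig, generate_dataset

__all__ = [
    "BinnedProfile",
    "FitResult",
    "bin_cells",
    "joint_fit",
    "normalize_profile",
    "predict_sink_response",
    "recovery_experiment",
    "orientation_enrichment",
]

LAMBDA_BOUNDS = (10.0, 5000.0)
C_BOUNDS = (0.01, 100.0)
#: coarse multi-start grid over the nonlinear parameters
_LAMBDA_STARTS = (50.0, 200.0, 800.0, 3000.0)
_C_STARTS = (0.3, 3.0)

_CHANNEL_COLUMNS = {"gfp": "gfp_au", "length": "length_um"}


@dataclass(frozen=True)
class BinnedProfile:
    """Per-bin summary of one readout channel along the experimental axis."""

    bin_centers: np.ndarray
    means: np.ndarray
    sems: np.ndarray
    counts: np.ndarray
    bin_width: float
    channel: str = ""

    def __post_init__(self) -> None:
        n = len(self.bin_centers)
        if not (len(self.means) == len(self.sems) == len(self.counts) == n):
            raise ValueError("BinnedProfile arrays must have equal length")
        if np.any(self.counts < 1):
            raise ValueError("retained bins must contain at least one cell")
        if np.any(self.sems < 0):
            raise ValueError("SEMs must be nonnegative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_center_um": self.bin_centers,
                "mean": self.means,
                "sem": self.sems,
                "count": self.counts,
            }
        )


@dataclass(frozen=True)
class FitResult:
    """Joint-fit output: shared gradient parameters, per-channel response
    parameters, the selected morphology Hill coefficient and the SSE
    landscape over the integer-n grid."""

    lambda_: float
    C: float
    A_g: float
    b_g: float
    A_m: float
    b_m: float
    n_m: int
    sse_total: float
    sse_by_n: dict[int, float]
    diagnostics: dict = field(default_factory=dict)

    @property
    def shape(self) -> GradientShape:
        return GradientShape(lambda_=self.lambda_, C=self.C)

    @property
    def resp_g(self) -> ResponseParams:
        return ResponseParams(n=1, A=self.A_g, b=self.b_g)

    @property
    def resp_m(self) -> ResponseParams:
        return ResponseParams(n=self.n_m, A=self.A_m, b=self.b_m)


def bin_cells(
    records: pd.DataFrame,
    channel: str,
    width: float = 100.0,
    trim_left: float = 100.0,
) -> BinnedProfile:
    """Bin receiver-cell readouts into contiguous spatial bins.

    Bins start at the leftmost cell and advance by ``width``; empty bins are
    dropped, and bins intersecting the trimmed left margin (default one bin:
    the experiment discards cells at the leftmost border where reflection
    inflates the concentration) are excluded. SEM = sd/√count, defined as 0
    for singleton bins (flagged via count == 1).
    """
    if width <= 0:
        raise ValueError("bin width must be strictly positive")
    if channel not in _CHANNEL_COLUMNS:
        raise ValueError(f"unknown channel {channel!r}; expected 'gfp' or 'length'")
    col = _CHANNEL_COLUMNS[channel]
    sub = records[(records["identity"] == "receiver") & records[col].notna()]
    if sub.empty:
        raise ValueError(f"no receiver cells with {channel} readout to bin")

    x = sub["x_um"].to_numpy(dtype=float)
    y = sub[col].to_numpy(dtype=float)
    lo = x.min()
    nbins = max(1, int(np.ceil((x.max() - lo) / width)))
    idx = np.clip(np.floor((x - lo) / width).astype(int), 0, nbins - 1)

    centers, means, sems, counts = [], [], [], []
    for b in range(nbins):
        left = lo + b * width
        if left < lo + trim_left - 1e-9:
            continue
        sel = idx == b
        n = int(sel.sum())
        if n == 0:
            continue
        vals = y[sel]
        centers.append(left + width / 2.0)
        means.append(vals.mean())
        sems.append(vals.std(ddof=1) / np.sqrt(n) if n > 1 else 0.0)
        counts.append(n)
    if not centers:
        raise ValueError("all bins empty after trimming")
    return BinnedProfile(
        bin_centers=np.asarray(centers),
        means=np.asarray(means),
        sems=np.asarray(sems),
        counts=np.asarray(counts, dtype=int),
        bin_width=width,
        channel=channel,
    )


def _fit_single_n(gfp, length, n_m, weights_g, weights_m):
    """Bounded least squares for one morphology Hill coefficient, with a
    coarse multi-start over (λ, C). Returns (sse, params, result) or None."""

    y_g, y_m = gfp.means, length.means
    x_g, x_m = gfp.bin_centers, length.bin_centers

    def residuals(p):
        lam, C, A_g, b_g, A_m, b_m = p
        c_g = C * np.asarray(source_profile(x_g, lam))
        c_m = C * np.asarray(source_profile(x_m, lam))
        mg = A_g * c_g / (1.0 + c_g) + b_g
        cn = c_m ** n_m
        mm = A_m * cn / (1.0 + cn) + b_m
        return np.concatenate(((mg - y_g) * weights_g, (mm - y_m) * weights_m))

    lo = [LAMBDA_BOUNDS[0], C_BOUNDS[0], 1e-9, -np.inf, 1e-9, -np.inf]
    hi = [LAMBDA_BOUNDS[1], C_BOUNDS[1], np.inf, np.inf, np.inf, np.inf]

    best = None
    for lam0 in _LAMBDA_STARTS:
        for C0 in _C_STARTS:
            theta_max_g = C0 / (1.0 + C0)
            theta_max_m = C0 ** n_m / (1.0 + C0 ** n_m)
            A_g0 = max((y_g.max() - y_g.min()) / max(theta_max_g, 1e-3), 1e-6)
            A_m0 = max((y_m.max() - y_m.min()) / max(theta_max_m, 1e-3), 1e-6)
            p0 = [lam0, C0, A_g0, y_g.min(), A_m0, y_m.min()]
            try:
                res = least_squares(
                    residuals,
                    p0,
                    bounds=(lo, hi),
                    x_scale=[100.0, 1.0, max(A_g0, 1e-3), 1.0, max(A_m0, 1e-3), 1.0],
                )
            except Exception:
                continue
            sse = float(np.sum(res.fun ** 2))
            if best is None or sse < best[0] - 1e-15:
                best = (sse, res.x.copy(), res)
    return best


def joint_fit(
    gfp_profile: BinnedProfile,
    length_profile: BinnedProfile,
    weighted: bool = True,
    n_candidates=range(1, 8),
) -> FitResult:
    """Joint least-squares fit of both channels with shared λ and C.

    For each candidate integer morphology Hill coefficient the six
    continuous parameters (λ, C, A_g, b_g, A_m, b_m) are fitted by bounded
    nonlinear least squares (multi-start); the coefficient with minimal SSE
    wins, ties broken toward the smaller (more parsimonious) n.

    Residuals are weighted by 1/SEM by default. The two channels live in
    incommensurate units (fluorescence a.u. vs μm) with very different
    amplitudes; an unweighted sum of squares is dominated by the
    larger-amplitude morphology channel, which by itself cannot separate
    (λ, C, n) — inverse-SEM weighting restores each channel's statistical
    share of the loss. ``weighted=False`` gives the raw unweighted SSE.
    When all SEMs are zero (noiseless data) the weights fall back to 1.

    Diagnostics flag boundary-pinned λ or C and a degenerate (flat) SSE
    landscape over n (e.g. when the morphology channel carries no signal).
    """

    def _weights(profile):
        if not weighted:
            return np.ones_like(profile.means)
        sems = profile.sems.copy()
        positive = sems[sems > 0]
        floor = positive.min() if positive.size else 1.0
        sems[sems <= 0] = floor
        return 1.0 / sems

    w_g, w_m = _weights(gfp_profile), _weights(length_profile)

    sse_by_n: dict[int, float] = {}
    best_by_n: dict[int, np.ndarray] = {}
    messages: dict[int, str] = {}
    for n_m in n_candidates:
        fit = _fit_single_n(gfp_profile, length_profile, int(n_m), w_g, w_m)
        if fit is None:
            messages[int(n_m)] = "all starts failed"
            continue
        sse, params, res = fit
        sse_by_n[int(n_m)] = sse
        best_by_n[int(n_m)] = params
        messages[int(n_m)] = res.message
    if not sse_by_n:
        raise RuntimeError(
            f"joint fit failed for every Hill coefficient: {messages}"
        )

    # smallest n wins ties (iterate ascending, strict improvement required)
    n_best, sse_best = None, np.inf
    for n_m in sorted(sse_by_n):
        if sse_by_n[n_m] < sse_best * (1.0 - 1e-12):
            n_best, sse_best = n_m, sse_by_n[n_m]
    params = best_by_n[n_best]
    lam, C, A_g, b_g, A_m, b_m = params

    sses = np.array(list(sse_by_n.values()))
    scale = max(sses.max(), 1e-300)
    diagnostics = {
        "lambda_at_bound": bool(
            lam < LAMBDA_BOUNDS[0] * 1.001 or lam > LAMBDA_BOUNDS[1] * 0.999
        ),
        "C_at_bound": bool(C < C_BOUNDS[0] * 1.001 or C > C_BOUNDS[1] * 0.999),
        "n_degenerate": bool((sses.max() - sses.min()) / scale < 1e-9),
        "weighted": weighted,
        "messages": messages,
    }
    return FitResult(
        lambda_=float(lam),
        C=float(C),
        A_g=float(A_g),
        b_g=float(b_g),
        A_m=float(A_m),
        b_m=float(b_m),
        n_m=int(n_best),
        sse_total=float(sse_best),
        sse_by_n=sse_by_n,
        diagnostics=diagnostics,
    )


def normalize_profile(profile: BinnedProfile, resp: ResponseParams) -> BinnedProfile:
    """Baseline-subtract and rescale a binned profile: (mean − b)/A.

    Puts the gene-expression and morphology channels in the same
    dimensionless units so their spatial shapes can be compared directly.
    """
    if not resp.A > 0:
        raise ValueError("normalization requires amplitude A > 0")
    return BinnedProfile(
        bin_centers=profile.bin_centers.copy(),
        means=(profile.means - resp.b) / resp.A,
        sems=profile.sems / resp.A,
        counts=profile.counts.copy(),
        bin_width=profile.bin_width,
        channel=profile.channel,
    )


def predict_sink_response(fit: FitResult, x) -> np.ndarray:
    """Zero-parameter morphology prediction for the perfect-sink geometry.

    Pushes the source-experiment fit through the sink profile with no
    refitting: flat at the baseline b_m for x > 0 (concentration clamped to
    zero there), rising toward the same plateau as the source fit for
    x → −∞.
    """
    x_arr = np.asarray(x, dtype=float)
    g = np.asarray(sink_profile(x_arr, fit.lambda_))
    theta = np.asarray(hill_response(fit.C * g, fit.n_m))
    return fit.A_m * theta + fit.b_m


def recovery_experiment(
    shape: GradientShape,
    resp_g: ResponseParams,
    resp_m: ResponseParams,
    pop: PopulationConfig,
    noise: NoiseConfig,
    n_seeds: int,
    base_seed: int = 0,
    bin_width: float = 100.0,
    trim_left: float = 100.0,
) -> dict:
    """Generate → bin → fit across seeds; summarize estimator quality.

    Returns a dict with ``per_seed`` (one fitted parameter set per seed),
    ``summary`` (mean, bias and RMSE per parameter against the generator
    truth), ``n_m_counts``, ``modal_n_m`` and a list of failed seeds.
    """
    if n_seeds < 2:
        raise ValueError("recovery_experiment requires n_seeds >= 2")
    rows, failures = [], []
    for i in range(n_seeds):
        seed = base_seed + 1000 * i
        df = generate_dataset(pop, shape, resp_g, resp_m, noise, seed)
        try:
            gfp = bin_cells(df, "gfp", bin_width, trim_left)
            length = bin_cells(df, "length", bin_width, trim_left)
            fit = joint_fit(gfp, length)
        except Exception as exc:  # noqa: BLE001 — per-seed failures recorded
            failures.append({"seed": seed, "error": str(exc)})
            continue
        rows.append(
            {
                "seed": seed,
                "lambda_": fit.lambda_,
                "C": fit.C,
                "A_g": fit.A_g,
                "b_g": fit.b_g,
                "A_m": fit.A_m,
                "b_m": fit.b_m,
                "n_m": fit.n_m,
                "sse_total": fit.sse_total,
            }
        )
    per_seed = pd.DataFrame(rows)
    truth = {
        "lambda_": shape.lambda_,
        "C": shape.C,
        "A_g": resp_g.A,
        "b_g": resp_g.b,
        "A_m": resp_m.A,
        "b_m": resp_m.b,
    }
    summary_rows = []
    for name, true_val in truth.items():
        est = per_seed[name].to_numpy(dtype=float) if len(per_seed) else np.array([])
        summary_rows.append(
            {
                "parameter": name,
                "truth": true_val,
                "mean": est.mean() if est.size else np.nan,
                "bias": est.mean() - true_val if est.size else np.nan,
                "rmse": float(np.sqrt(np.mean((est - true_val) ** 2)))
                if est.size
                else np.nan,
            }
        )
    n_counts = (
        per_seed["n_m"].value_counts().to_dict() if len(per_seed) else {}
    )
    modal = max(n_counts, key=lambda k: (n_counts[k], -k)) if n_counts else None
    return {
        "per_seed": per_seed,
        "summary": pd.DataFrame(summary_rows),
        "n_m_counts": {int(k): int(v) for k, v in n_counts.items()},
        "modal_n_m": int(modal) if modal is not None else None,
        "failures": failures,
    }


def orientation_enrichment(
    records: pd.DataFrame, area_cutoff: float = 200.0
) -> dict:
    """Rayleigh test of gradient alignment among large (elongated) cells.

    Filters receiver cells by segmented area above ``area_cutoff`` pixels
    (a proxy for elongation), doubles the axial orientation angles to map
    (0, 180] onto the circle, and applies the Rayleigh uniformity test.
    A small p-value indicates orientations clustered toward the gradient
    axis; uniform (unaligned) populations are non-significant.
    """
    import pingouin  # heavy import, deferred

    sub = records[
        (records["identity"] == "receiver")
        & records["orientation_deg"].notna()
        & (records["area_px"] > area_cutoff)
    ]
    n = len(sub)
    if n < 20:
        raise ValueError(
            f"only {n} cells above the area cutoff; need at least 20"
        )
    angles = np.deg2rad(2.0 * sub["orientation_deg"].to_numpy(dtype=float))
    z, pval = pingouin.circ_rayleigh(angles)
    return {"statistic": float(z), "pvalue": float(pval), "n": n}
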