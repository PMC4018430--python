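"""Variance-stabilizing normalization and univariate probe screening.

The normalization implements the affine + generalized-log model: each array
is calibrated to a common scale with a per-array affine map and then passed
through a glog2 transform whose shape parameter is estimated from the data's
additive/multiplicative error structure. This is an independent
re-implementation of the glog/affine model; numerical equality with other
VSN implementations is not claimed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from eggprint.dataio import ExpressionMatrix, PhenotypeTable

__all__ = ["VsnParameters", "ScreenResult", "vsn_normalize", "probe_screen", "glog2"]

_VARIANCE_FLOOR = 1e-8


class PreprocessError(ValueError):
    pass


def glog2(y: np.ndarray, c: float) -> np.ndarray:
    """Generalized log2: log2(y + sqrt(y^2 + c^2)) - 1.

    Behaves like log2(y) for y >> c and is linear (hence finite and
    variance-stabilizing) near and below zero.
    """
    y = np.asarray(y, dtype=float)
    return np.log2(y + np.sqrt(y * y + c * c)) - 1.0


@dataclass
class VsnParameters:
    """Fitted per-array affine parameters and the global glog shape ``c``.

    The transform for array i is ``h_i(x) = glog2(scale[i] * x - offset[i], c)``.
    """

    scale: np.ndarray
    offset: np.ndarray
    c: float
    n_iterations: int


def vsn_normalize(
    raw: ExpressionMatrix,
    trim: float = 0.10,
    n_iter: int = 5,
) -> tuple[ExpressionMatrix, VsnParameters]:
    """Variance-stabilizing normalization of raw intensities.

    Each array is affinely calibrated (scale, offset) against a consensus
    profile by trimmed least squares, iterated so that the consensus and the
    calibrations converge jointly; ``trim`` is the fraction of probes with
    the largest residuals excluded from each refit, which protects the fit
    from the minority of differential probes. The glog shape parameter ``c``
    is estimated from the mean-variance relation of the calibrated
    intensities (variance ~ sigma_add^2 + sigma_mult^2 * mean^2 gives
    c = sigma_add / sigma_mult, the intensity below which additive noise
    dominates).
    """
    if raw.scale_flag != "raw":
        raise PreprocessError("vsn_normalize expects a raw-scale matrix")
    x = raw.values
    n_probes, n_arrays = x.shape
    if n_arrays < 2:
        raise PreprocessError("need at least 2 arrays")

    array_sd = x.std(axis=0, ddof=1)
    if np.all(array_sd == 0):
        # degenerate but well-defined: constant matrix maps to a constant
        if not np.allclose(x, x[0, 0]):
            raise PreprocessError("arrays constant at different levels")
        params = VsnParameters(np.ones(n_arrays), np.zeros(n_arrays), 1.0, 0)
        return _apply(raw, params), params
    if np.any(array_sd == 0):
        raise PreprocessError(
            f"all-constant array(s): {[raw.sample_ids[i] for i in np.flatnonzero(array_sd == 0)]}"
        )

    scale = np.ones(n_arrays)
    offset = np.zeros(n_arrays)
    it = 0
    for it in range(1, n_iter + 1):
        calibrated = scale[None, :] * x - offset[None, :]
        ref = calibrated.mean(axis=1)
        new_scale = np.empty(n_arrays)
        new_offset = np.empty(n_arrays)
        for j in range(n_arrays):
            s, o = _trimmed_affine(x[:, j], ref, trim)
            if s <= 0:
                raise PreprocessError(
                    f"negative fitted scale for array {raw.sample_ids[j]}"
                )
            new_scale[j] = s
            new_offset[j] = o
        # anchor the overall scale: geometric mean of scales = 1
        anchor = np.exp(np.mean(np.log(new_scale)))
        new_scale /= anchor
        new_offset /= anchor
        if np.allclose(new_scale, scale, atol=1e-10) and np.allclose(
            new_offset, offset, atol=1e-8
        ):
            scale, offset = new_scale, new_offset
            break
        scale, offset = new_scale, new_offset

    calibrated = scale[None, :] * x - offset[None, :]
    m0, c = _estimate_noise_model(calibrated)
    # fold the common background level into the per-array offsets so the
    # glog argument is centered on the true signal
    offset = offset + m0
    params = VsnParameters(scale, offset, c, it)
    return _apply(raw, params), params


def _apply(raw: ExpressionMatrix, params: VsnParameters) -> ExpressionMatrix:
    values = glog2(params.scale[None, :] * raw.values - params.offset[None, :], params.c)
    return ExpressionMatrix(
        probe_ids=list(raw.probe_ids),
        sample_ids=list(raw.sample_ids),
        values=values,
        scale_flag="normalized",
    )


def _trimmed_affine(x: np.ndarray, ref: np.ndarray, trim: float) -> tuple[float, float]:
    """Least-squares fit ref ~= s*x - o, refit after dropping the ``trim``
    fraction of probes with the largest absolute residuals."""
    keep = np.ones(len(x), dtype=bool)
    s = o = 0.0
    for _ in range(3):
        xv, rv = x[keep], ref[keep]
        vx = xv.var()
        if vx == 0:
            raise PreprocessError("constant array during affine calibration")
        s = np.cov(xv, rv, ddof=0)[0, 1] / vx
        o = s * xv.mean() - rv.mean()
        resid = np.abs(s * x - o - ref)
        cut = np.quantile(resid, 1.0 - trim)
        keep = resid <= cut
    return float(s), float(o)


def _estimate_noise_model(calibrated: np.ndarray) -> tuple[float, float]:
    """Estimate the additive/multiplicative error structure of calibrated
    intensities: fit var_g = a + b * (mean_g - m0)^2 across probes, where
    m0 is the common background level, a the additive noise variance and b
    the squared multiplicative coefficient of variation. Returns (m0, c)
    with c = sqrt(a / b), the intensity below which additive noise
    dominates (the glog shape parameter)."""
    from scipy.optimize import least_squares

    m = calibrated.mean(axis=1)
    v = calibrated.var(axis=1, ddof=1)
    ok = v > 0
    m, v = m[ok], v[ok]
    if len(m) < 10:
        pos = m[m > 0]
        return 0.0, float(np.quantile(pos, 0.01)) if len(pos) else 1.0
    if len(m) > 5000:  # fit on a deterministic thinning for speed
        step = len(m) // 5000 + 1
        order = np.argsort(m)
        m, v = m[order][::step], v[order][::step]

    m0_0 = float(np.quantile(m, 0.005))
    dim = m <= np.quantile(m, 0.05)
    a0 = max(float(np.median(v[dim])), 1e-12)
    bright = m > np.median(m)
    with np.errstate(divide="ignore", invalid="ignore"):
        b_samples = (v[bright] - a0) / (m[bright] - m0_0) ** 2
    b0 = max(float(np.median(b_samples)), 1e-12)

    def resid(theta):
        log_a, log_b, m0 = theta
        pred = np.exp(log_a) + np.exp(log_b) * (m - m0) ** 2
        return np.log(pred) - np.log(v)

    try:
        fit = least_squares(
            resid, x0=[np.log(a0), np.log(b0), m0_0], method="lm", max_nfev=200
        )
        a = float(np.exp(fit.x[0]))
        b = float(np.exp(fit.x[1]))
        m0 = float(fit.x[2])
    except Exception:
        a, b, m0 = a0, b0, m0_0
    if not (np.isfinite(a) and np.isfinite(b)) or a <= 0 or b <= 0:
        pos = m[m > 0]
        return 0.0, float(np.quantile(pos, 0.01)) if len(pos) else 1.0
    return m0, float(np.sqrt(a / b))


# ---------------------------------------------------------------------------
# probe screening


@dataclass
class ScreenResult:
    """Ranked univariate screen over all probes.

    ``table`` columns: probe_id, statistic, p_value, rank (1 = smallest p),
    selected (p <= cutoff), flagged (variance floor applied). ``selected``
    holds probe ids ordered by rank.
    """

    table: pd.DataFrame
    selected: list[str]
    mode: str
    p_cutoff: float


def probe_screen(
    expr: ExpressionMatrix,
    pheno: PhenotypeTable,
    mode: str = "binary",
    p_cutoff: float = 0.10,
    target: str = "pct_4h_viable",
) -> ScreenResult:
    """Per-probe univariate association screen at a permissive raw-p cutoff.

    ``binary`` mode runs a two-sided Welch t-test of high- vs low-quality
    samples (intermediate/unassigned samples are excluded); ``continuous``
    mode tests the simple-regression slope of expression on the target
    phenotype. No multiple-testing correction is applied: the screen is a
    deliberate dimensionality-reduction device, and under a pure null it
    retains ~``p_cutoff`` of probes by construction. Ties in p are broken by
    probe_id so ranks are a permutation.
    """
    if expr.scale_flag != "normalized":
        raise PreprocessError("probe_screen expects normalized expression")
    labels = pheno.table.set_index("sample_id")["quality_label"]
    x = expr.values
    flagged = np.zeros(expr.n_probes, dtype=bool)

    if mode == "binary":
        hi = [i for i, s in enumerate(expr.sample_ids) if labels.get(s) == "high"]
        lo = [i for i, s in enumerate(expr.sample_ids) if labels.get(s) == "low"]
        if len(hi) < 2 or len(lo) < 2:
            raise PreprocessError("binary screen needs >= 2 samples per class")
        a, b = x[:, hi], x[:, lo]
        va = a.var(axis=1, ddof=1) / len(hi)
        vb = b.var(axis=1, ddof=1) / len(lo)
        se2 = va + vb
        flagged = se2 < _VARIANCE_FLOOR
        se2 = np.maximum(se2, _VARIANCE_FLOOR)
        t = (a.mean(axis=1) - b.mean(axis=1)) / np.sqrt(se2)
        # Welch-Satterthwaite df; degenerate probes get the floor df of 1
        with np.errstate(divide="ignore", invalid="ignore"):
            df = se2**2 / (
                va**2 / (len(hi) - 1) + vb**2 / (len(lo) - 1)
            )
        df = np.where(np.isfinite(df), df, 1.0)
        p = 2.0 * stats.t.sf(np.abs(t), df)
    elif mode == "continuous":
        y = pheno.target(target).reindex(expr.sample_ids).to_numpy(dtype=float)
        if np.isnan(y).any():
            raise PreprocessError("continuous target has missing values")
        n = len(y)
        if n < 3:
            raise PreprocessError("continuous screen needs >= 3 samples")
        xc = x - x.mean(axis=1, keepdims=True)
        yc = y - y.mean()
        sx = np.sqrt((xc * xc).sum(axis=1))
        sy = np.sqrt((yc * yc).sum())
        denom = sx * sy
        flagged = denom < _VARIANCE_FLOOR
        r = (xc @ yc) / np.maximum(denom, _VARIANCE_FLOOR)
        r = np.clip(r, -1.0, 1.0)
        with np.errstate(divide="ignore"):
            t = r * np.sqrt((n - 2) / np.maximum(1.0 - r * r, _VARIANCE_FLOOR))
        p = 2.0 * stats.t.sf(np.abs(t), n - 2)
        p = np.where(flagged, 1.0, p)
    else:
        raise PreprocessError(f"unknown screen mode {mode!r}")

    order = np.lexsort((expr.probe_ids, p))
    rank = np.empty(len(p), dtype=int)
    rank[order] = np.arange(1, len(p) + 1)
    table = pd.DataFrame(
        {
            "probe_id": expr.probe_ids,
            "statistic": t,
            "p_value": p,
            "rank": rank,
            "selected": p <= p_cutoff,
            "flagged": flagged,
        }
    ).sort_values("rank", kind="stable").reset_index(drop=True)
    selected = table.loc[table["selected"], "probe_id"].tolist()
    return ScreenResult(table=table, selected=selected, mode=mode, p_cutoff=p_cutoff)
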