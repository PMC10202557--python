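"""Directed (Granger) coupling between ROI current series.

Granger causality from x to y is the log-ratio of the residual variance of
a reduced autoregressive model (y predicted from its own past alone) to
that of the full model (y predicted from its own and x's past):

    GC(x -> y) = ln( var[e_reduced] / var[e_full] )  >= 0.

Band-restricted values use the Geweke spectral decomposition of the
fitted bivariate model rather than pre-filtering, because filtering before
autoregressive fitting is known to distort causality estimates; the
spectral measure is averaged over the band's frequencies (theta for the
analyses this package targets).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .bands import get_band

#: The canonical 22-link directed roster over the seven ROIs:
#: pgACC <-> each sensory/parahippocampal ROI (12), within-hemisphere
#: AUD<->PHC and SOM<->PHC (8), and interhemispheric PHC<->PHC (2).
def link_roster() -> list[tuple[str, str]]:
    links: list[tuple[str, str]] = []
    for roi in ("L_AUD", "R_AUD", "L_SOM", "R_SOM", "L_PHC", "R_PHC"):
        links.append(("pgACC", roi))
        links.append((roi, "pgACC"))
    for hemi in ("L", "R"):
        for sens in ("AUD", "SOM"):
            links.append((f"{hemi}_{sens}", f"{hemi}_PHC"))
            links.append((f"{hemi}_PHC", f"{hemi}_{sens}"))
    links.append(("L_PHC", "R_PHC"))
    links.append(("R_PHC", "L_PHC"))
    assert len(links) == 22 and len(set(links)) == 22
    return links


@dataclass
class MVARModel:
    """Least-squares multivariate autoregressive fit."""

    A: np.ndarray          # (p, k, k): y_t = sum_l A[l] y_{t-l-1} + e_t
    Sigma: np.ndarray      # (k, k) residual covariance
    order: int
    n_obs: int
    ic_values: dict[int, float] = field(default_factory=dict)

    @property
    def k(self) -> int:
        return self.Sigma.shape[0]

    def companion(self) -> np.ndarray:
        p, k = self.order, self.k
        C = np.zeros((k * p, k * p))
        C[:k] = np.concatenate(list(self.A), axis=1)
        if p > 1:
            C[k:, : k * (p - 1)] = np.eye(k * (p - 1))
        return C

    @property
    def spectral_radius(self) -> float:
        return float(np.max(np.abs(np.linalg.eigvals(self.companion()))))

    @property
    def is_stable(self) -> bool:
        return self.spectral_radius < 1.0


def _segments(series) -> list[np.ndarray]:
    """Normalise input to a list of (k, T) float segments, demeaned per segment."""
    if isinstance(series, (list, tuple)):
        segs = [np.atleast_2d(np.asarray(s, float)) for s in series]
    else:
        segs = [np.atleast_2d(np.asarray(series, float))]
    return [s - s.mean(axis=1, keepdims=True) for s in segs]


def _design(segs: list[np.ndarray], p: int) -> tuple[np.ndarray, np.ndarray]:
    """Stack lagged design/response over segments, excluding boundaries."""
    Xs, Ys = [], []
    for s in segs:
        k, T = s.shape
        if T <= p:
            continue
        Y = s[:, p:].T                                   # (T-p, k)
        X = np.concatenate([s[:, p - l - 1 : T - l - 1].T for l in range(p)], axis=1)
        Xs.append(X)
        Ys.append(Y)
    if not Xs:
        raise ValueError("series too short for the requested order")
    return np.concatenate(Xs), np.concatenate(Ys)


def _ls_fit(segs: list[np.ndarray], p: int) -> tuple[np.ndarray, np.ndarray, int]:
    X, Y = _design(segs, p)
    n, k = Y.shape
    B, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ B
    Sigma = resid.T @ resid / (n - p * k)
    A = np.stack([B[l * k : (l + 1) * k].T for l in range(p)])
    return A, Sigma, n


def fit_mvar(series, order: "int | str" = "auto",
             order_range: tuple[int, int] = (2, 20),
             check_stability: bool = True) -> MVARModel:
    """Fit a (multi)variate autoregressive model by least squares.

    ``series`` is a (k, T) array or a list of such segments (epochs are
    demeaned individually and boundary samples never enter the design).
    ``order="auto"`` selects the order in ``order_range`` minimising the
    BIC, ln|Sigma| + k^2 p ln(n)/n.
    """
    segs = _segments(series)
    k = segs[0].shape[0]
    total = sum(s.shape[1] for s in segs)
    ic_values: dict[int, float] = {}
    if order == "auto":
        best, best_ic = None, np.inf
        for p in range(order_range[0], order_range[1] + 1):
            if total < 10 * k * p:
                break
            _, Sigma, n = _ls_fit(segs, p)
            sign, logdet = np.linalg.slogdet(Sigma)
            ic = logdet + (k * k * p) * np.log(n) / n if sign > 0 else np.inf
            ic_values[p] = ic
            if ic < best_ic:
                best, best_ic = p, ic
        if best is None:
            raise ValueError("series too short for any candidate order")
        order = best
    else:
        order = int(order)
        if total < 10 * k * order:
            raise ValueError(
                f"series too short: need >= 10*k*p = {10 * k * order} samples, have {total}")
    A, Sigma, n = _ls_fit(segs, order)
    model = MVARModel(A=A, Sigma=Sigma, order=order, n_obs=n, ic_values=ic_values)
    if check_stability and not model.is_stable:
        raise ValueError(
            f"fitted VAR({order}) is unstable (spectral radius "
            f"{model.spectral_radius:.3f}); try a higher order or more data")
    return model


def _univariate_resid_var(segs: list[np.ndarray], p: int) -> float:
    _, Sigma, _ = _ls_fit(segs, p)
    return float(Sigma[0, 0])


def geweke_spectral_gc(model: MVARModel, source: int, target: int,
                       freqs_hz: np.ndarray, fs: float) -> np.ndarray:
    """Geweke's frequency-domain causality from a bivariate VAR, per frequency."""
    if model.k != 2:
        raise ValueError("spectral decomposition implemented for bivariate models")
    S_full = model.Sigma
    sxx = S_full[source, source]
    sxy = S_full[source, target]
    syy = S_full[target, target]
    partial = sxx - sxy**2 / syy
    out = np.empty(len(freqs_hz))
    I = np.eye(2)
    for fi, f in enumerate(freqs_hz):
        z = np.exp(-2j * np.pi * f / fs)
        Az = I - sum(model.A[l] * z ** (l + 1) for l in range(model.order))
        H = np.linalg.inv(Az)
        S = H @ S_full @ H.conj().T
        s_t = np.real(S[target, target])
        denom = s_t - partial * np.abs(H[target, source]) ** 2
        out[fi] = np.log(s_t / denom) if denom > 0 else np.inf
    return out


def granger_pair(series, source: int = 0, target: int = 1,
                 band=None, fs: float | None = None,
                 order: "int | str" = "auto", n_freqs: int = 32,
                 ) -> tuple[float, MVARModel, bool]:
    """Granger causality source -> target from a bivariate fit.

    With ``band=None`` returns the time-domain log variance ratio; with a
    band (name or BandSpec) returns the Geweke spectral value averaged over
    ``n_freqs`` frequencies inside the band (``fs`` required).  Values are
    floored at zero; the returned flag is True when flooring occurred.
    """
    if source == target:
        raise ValueError("source and target must differ")
    segs = _segments(series)
    if segs[0].shape[0] != 2:
        segs = [s[[source, target]] for s in segs]
        source, target = 0, 1
    model = fit_mvar(segs, order=order, check_stability=False)
    if band is None:
        red = _univariate_resid_var([s[[target]] for s in segs], model.order)
        gc = float(np.log(red / model.Sigma[target, target]))
    else:
        if fs is None:
            raise ValueError("fs is required for band-restricted causality")
        b = get_band(band)
        if b.hi > fs / 2:
            raise ValueError(f"band {b.name!r} exceeds Nyquist at fs={fs}")
        freqs = np.linspace(b.lo, b.hi, n_freqs, endpoint=False)
        gc = float(np.mean(geweke_spectral_gc(model, source, target, freqs, fs)))
    floored = gc < 0
    return (max(gc, 0.0), model, floored)


def conditional_gc(series, source: int, target: int, order: "int | str" = "auto") -> float:
    """Time-domain causality source -> target conditional on all other channels."""
    segs = _segments(series)
    k = segs[0].shape[0]
    full = fit_mvar(segs, order=order, check_stability=False)
    keep = [i for i in range(k) if i != source]
    red_segs = [s[keep] for s in segs]
    t_red = keep.index(target)
    _, Sigma_red, _ = _ls_fit(red_segs, full.order)
    return max(float(np.log(Sigma_red[t_red, t_red] / full.Sigma[target, target])), 0.0)


def gc_table(roi_series: dict[str, np.ndarray], fs: float, band="theta",
             order: "int | str" = 5, conditional: bool = False):
    """Fill the 22-link directed roster for one subject.

    ``roi_series`` maps ROI name -> 1-D series (or a list of segments).
    Returns a DataFrame with columns source_roi, target_roi, band, gc,
    order_p, stable, floored.
    """
    import pandas as pd

    roster = link_roster()
    needed = {r for pair in roster for r in pair}
    missing = sorted(needed - set(roi_series))
    if missing:
        raise ValueError(f"missing ROI series: {missing}")
    band_name = get_band(band).name if band is not None else "broadband"
    rows = []
    if conditional:
        names = sorted(needed)
        stack = _roi_stack(roi_series, names)
        model = fit_mvar(stack, order=order, check_stability=False)
        for src, tgt in roster:
            gc = conditional_gc(stack, names.index(src), names.index(tgt), order=model.order)
            rows.append({"source_roi": src, "target_roi": tgt, "band": "broadband",
                         "gc": gc, "order_p": model.order,
                         "stable": model.is_stable, "floored": False})
        return pd.DataFrame(rows)
    for src, tgt in roster:
        pair = _roi_stack(roi_series, (src, tgt))
        gc, model, floored = granger_pair(pair, 0, 1, band=band, fs=fs, order=order)
        rows.append({"source_roi": src, "target_roi": tgt, "band": band_name,
                     "gc": gc, "order_p": model.order,
                     "stable": model.is_stable, "floored": floored})
    return pd.DataFrame(rows)


def _roi_stack(roi_series: dict[str, np.ndarray], names) -> "list[np.ndarray] | np.ndarray":
    first = roi_series[names[0]]
    if isinstance(first, (list, tuple)):
        return [np.vstack([np.asarray(roi_series[n][s], float) for n in names])
                for s in range(len(first))]
    return np.vstack([np.asarray(roi_series[n], float) for n in names])
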