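"""Neural-network sensitivity of transpiration rate to weather variables.

A small multi-output feed-forward network (5 weather predictors -> one
hidden layer of 5 rectified-linear units -> one linear output per genotype
cluster) is trained on the time-of-day averaged experiment: predictors and
per-cluster mean TR are averaged across days at fixed 15-min clock time,
min-max scaled to [0, 1], split 70/30 into training and validation rows,
and fitted full-batch with a quasi-Newton (L-BFGS) optimiser; the weights
at the epoch with minimum validation MSE are kept.

The profile method then probes the fitted surface: all predictors but one
are held at a quantile of their distribution (the 0, 20, ..., 100% splits)
while the remaining predictor sweeps its observed range on a fine grid.
The first-segment slope of the normalized response curve is the
sensitivity index (SI, %), and for VPD the point where the curve's tangent
slope collapses toward zero marks the breakpoint where maximum TR is
reached — the onset of transpiration restriction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

PREDICTORS = ["T", "RH", "vpd", "RAD", "WS"]
SPLITS_DEFAULT = (0, 20, 40, 60, 80, 100)


@dataclass
class MinMaxScaler:
    lo: np.ndarray
    hi: np.ndarray

    @classmethod
    def fit(cls, X):
        X = np.asarray(X, dtype=float)
        return cls(lo=X.min(axis=0), hi=X.max(axis=0))

    def transform(self, X):
        span = np.where(self.hi > self.lo, self.hi - self.lo, 1.0)
        return (np.asarray(X, dtype=float) - self.lo) / span

    def inverse(self, Xs):
        return np.asarray(Xs, dtype=float) * (self.hi - self.lo) + self.lo


def build_training_set(weather: pd.DataFrame, cluster_tr: pd.DataFrame):
    """Time-of-day averages of weather predictors and per-cluster TR.

    Both tables are datetime-indexed on the same 15-min grid; values at the
    same clock time are averaged across days, giving one row per step of the
    day (96 for 15-min data).  Returns ``(X, Y)`` DataFrames indexed by
    clock hour.
    """
    w = weather.copy()
    if "vpd" not in w.columns:
        from .refet import vpd as _vpd
        w["vpd"] = _vpd(w["T"], w["RH"])
    if not w.index.equals(cluster_tr.index):
        raise ValueError("weather and TR tables must share one time grid")
    tod = w.index.hour + w.index.minute / 60.0
    X = w[PREDICTORS].groupby(tod).mean()
    Y = cluster_tr.groupby(tod).mean()
    return X, Y


# ---------------------------------------------------------------------------
# The network
# ---------------------------------------------------------------------------

def _unpack(theta, n_in, n_hidden, n_out):
    i = 0
    W1 = theta[i:i + n_in * n_hidden].reshape(n_in, n_hidden); i += n_in * n_hidden
    b1 = theta[i:i + n_hidden]; i += n_hidden
    W2 = theta[i:i + n_hidden * n_out].reshape(n_hidden, n_out); i += n_hidden * n_out
    b2 = theta[i:i + n_out]
    return W1, b1, W2, b2


def _forward(theta, X, n_hidden, n_out):
    W1, b1, W2, b2 = _unpack(theta, X.shape[1], n_hidden, n_out)
    H = np.maximum(X @ W1 + b1, 0.0)
    return H @ W2 + b2, H


def _loss_grad(theta, X, Y, n_hidden):
    n, n_out = Y.shape
    W1, b1, W2, b2 = _unpack(theta, X.shape[1], n_hidden, n_out)
    Z = X @ W1 + b1
    H = np.maximum(Z, 0.0)
    Yhat = H @ W2 + b2
    R = Yhat - Y
    loss = (R ** 2).mean()
    scale = 2.0 / R.size
    gW2 = scale * H.T @ R
    gb2 = scale * R.sum(axis=0)
    dH = scale * R @ W2.T
    dZ = dH * (Z > 0)
    gW1 = X.T @ dZ
    gb1 = dZ.sum(axis=0)
    grad = np.concatenate([gW1.ravel(), gb1, gW2.ravel(), gb2])
    return loss, grad


@dataclass
class NNModel:
    """A fitted TR-response network with its scaling and training history."""

    theta: np.ndarray = field(repr=False)
    n_hidden: int
    n_out: int
    x_scaler: MinMaxScaler = field(repr=False)
    y_scaler: MinMaxScaler = field(repr=False)
    X_scaled: np.ndarray = field(repr=False)   # full scaled training inputs
    history: pd.DataFrame = field(repr=False)  # train/validation MSE per epoch
    best_epoch: int = 0
    r_validation: np.ndarray = None            # per-output correlation R
    output_names: list = None
    predictor_names: list = None

    def predict_scaled(self, Xs):
        out, _ = _forward(self.theta, np.asarray(Xs, dtype=float),
                          self.n_hidden, self.n_out)
        return out

    def predict(self, X):
        Xs = self.x_scaler.transform(X)
        return self.y_scaler.inverse(self.predict_scaled(Xs))


def train_nn(X: pd.DataFrame, Y: pd.DataFrame, hidden: int = 5,
             val_fraction: float = 0.3, max_epochs: int = 1500,
             seed: int = 0, n_restarts: int = 10) -> NNModel:
    """Fit the multi-output ReLU network by full-batch quasi-Newton descent.

    Inputs and outputs are min-max scaled to [0, 1]; rows are split 70/30
    into training and validation by a seeded permutation; weights start
    uniform in [-0.5, 0.5].  One L-BFGS iteration is one epoch; the training
    and validation MSE are recorded per epoch and the weights at the
    validation minimum kept.  Quasi-Newton training of a ReLU network is
    prone to poor local minima, so ``n_restarts`` seeded initialisations are
    trained and the one with the lowest best-epoch validation MSE returned,
    together with the per-output correlation R between predictions and
    validation targets.
    """
    Xv = np.asarray(X, dtype=float)
    Yv = np.asarray(Y, dtype=float)
    if Yv.ndim == 1:
        Yv = Yv[:, None]
    n = Xv.shape[0]
    if n < 20:
        raise ValueError("need at least 20 rows to train")
    xs = MinMaxScaler.fit(Xv)
    ys = MinMaxScaler.fit(Yv)
    Xs, Ys = xs.transform(Xv), ys.transform(Yv)

    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_val = max(1, int(round(val_fraction * n)))
    val_idx, train_idx = perm[:n_val], perm[n_val:]
    Xt, Yt = Xs[train_idx], Ys[train_idx]
    Xval, Yval = Xs[val_idx], Ys[val_idx]

    n_in, n_out = Xs.shape[1], Ys.shape[1]
    n_par = n_in * hidden + hidden + hidden * n_out + n_out

    overall = None
    for _ in range(max(1, n_restarts)):
        theta0 = rng.uniform(-0.5, 0.5, size=n_par)
        history = []
        best = {"mse": np.inf, "theta": theta0.copy(), "epoch": 0}

        def record(theta, history=history, best=best):
            tr_mse = float(np.mean((_forward(theta, Xt, hidden, n_out)[0] - Yt) ** 2))
            val_mse = float(np.mean((_forward(theta, Xval, hidden, n_out)[0] - Yval) ** 2))
            history.append((tr_mse, val_mse))
            if val_mse < best["mse"]:
                best.update(mse=val_mse, theta=np.array(theta),
                            epoch=len(history) - 1)

        record(theta0)  # epoch 0: the untrained network
        minimize(_loss_grad, theta0, args=(Xt, Yt, hidden), jac=True,
                 method="L-BFGS-B", callback=record,
                 options={"maxiter": max_epochs - 1, "ftol": 0.0,
                          "gtol": 1e-12})
        if overall is None or best["mse"] < overall[0]["mse"]:
            overall = (best, history)

    best, history = overall
    theta = best["theta"]
    pred_val = _forward(theta, Xval, hidden, n_out)[0]
    r = np.array([
        np.corrcoef(pred_val[:, j], Yval[:, j])[0, 1]
        if np.std(pred_val[:, j]) > 0 and np.std(Yval[:, j]) > 0 else np.nan
        for j in range(n_out)
    ])
    hist = pd.DataFrame(history, columns=["train_mse", "val_mse"])
    hist.index.name = "epoch"
    out_names = list(Y.columns) if hasattr(Y, "columns") else None
    pred_names = list(X.columns) if hasattr(X, "columns") else None
    return NNModel(theta=theta, n_hidden=hidden, n_out=n_out, x_scaler=xs,
                   y_scaler=ys, X_scaled=Xs, history=hist,
                   best_epoch=best["epoch"], r_validation=r,
                   output_names=out_names, predictor_names=pred_names)


# ---------------------------------------------------------------------------
# Profile-method sensitivity
# ---------------------------------------------------------------------------

def sensitivity_profiles(model: NNModel, predictor, splits=SPLITS_DEFAULT,
                         n_grid: int = 101) -> pd.DataFrame:
    """Predicted TR curves while one predictor sweeps its observed range.

    For each quantile split s, every other predictor is fixed at its
    empirical s-quantile (of the training rows) while ``predictor`` varies
    over ``n_grid`` points between its observed minimum and maximum; the
    model's responses are returned in original units as a tidy frame with
    columns predictor, split, grid (original units), output, value.
    """
    names = model.predictor_names or list(range(model.X_scaled.shape[1]))
    if predictor not in names:
        raise ValueError(f"unknown predictor {predictor!r}")
    j = names.index(predictor)
    Xs = model.X_scaled
    grid_s = np.linspace(Xs[:, j].min(), Xs[:, j].max(), n_grid)
    out_names = model.output_names or [f"Y{i+1}" for i in range(model.n_out)]
    rows = []
    for s in splits:
        base = np.quantile(Xs, s / 100.0, axis=0)
        Xg = np.tile(base, (n_grid, 1))
        Xg[:, j] = grid_s
        Ys = model.predict_scaled(Xg)
        Y = model.y_scaler.inverse(Ys)
        grid_orig = grid_s * (model.x_scaler.hi[j] - model.x_scaler.lo[j]) + model.x_scaler.lo[j]
        for oi, oname in enumerate(out_names):
            for gi in range(n_grid):
                rows.append((predictor, s, grid_orig[gi], oname, Y[gi, oi]))
    return pd.DataFrame(rows, columns=["predictor", "split", "grid",
                                       "output", "value"])


def sensitivity_index(x, y) -> float:
    """First-segment slope (%) of a two-piece linear fit to a response curve.

    Both axes are normalized to [0, 1]; a continuous two-segment piecewise
    linear model (hinge basis 1, x, max(0, x - b)) is fitted by least
    squares with the breakpoint b searched over the grid; the slope of the
    first segment x 100 is the SI.  A flat curve has SI = 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.ptp(y) == 0:
        return 0.0
    xn = (x - x.min()) / np.ptp(x)
    yn = (y - y.min()) / np.ptp(y)
    best = (np.inf, 0.0)
    for b in xn[1:-1]:
        A = np.column_stack([np.ones_like(xn), xn, np.maximum(xn - b, 0.0)])
        coef, res, *_ = np.linalg.lstsq(A, yn, rcond=None)
        rss = float(((A @ coef - yn) ** 2).sum())
        if rss < best[0] - 1e-15:
            best = (rss, coef[1])
    return float(100.0 * best[1])


def vpd_breakpoint(vpd_grid, y, vpd_max: float, eps: float = 0.05):
    """VPD level where the TR response's tangent slope approaches zero.

    The numerical derivative along the curve is compared with ``eps`` times
    its maximum; the breakpoint is the smallest grid VPD from which the
    derivative stays at or below that threshold through the curve maximum.
    Returned as (percent of ``vpd_max``, kPa).  A curve whose slope never
    collapses reports 100% (unrestricted).
    """
    v = np.asarray(vpd_grid, dtype=float)
    y = np.asarray(y, dtype=float)
    dy = np.gradient(y, v)
    dmax = dy.max()
    if dmax <= 0:
        return 100.0, vpd_max
    thr = eps * dmax
    # a curve still rising at full rate at the end of the observed range
    # never attains its maximum: unrestricted
    i_last_max = int(y.size - 1 - np.argmax(y[::-1]))
    if i_last_max == y.size - 1 and dy[-1] > thr:
        return 100.0, vpd_max
    # "maximum TR attained" is read with a small amplitude tolerance so a
    # sub-threshold creep along a plateau does not defer the peak to the
    # grid edge
    y_eff = y.max() - 0.005 * np.ptp(y)
    i_peak = int(np.argmax(y >= y_eff))
    # smallest grid index from which the slope stays collapsed up to the
    # peak (the centred gradient at the peak itself mixes both sides of a
    # kink and is not tested)
    idx = i_peak
    for i in range(i_peak - 1, -1, -1):
        if dy[i] <= thr:
            idx = i
        else:
            break
    frac = 100.0 * v[idx] / vpd_max
    return float(frac), float(v[idx])


def fraction_to_kpa(fraction_percent: float,
                    vpd_max: float) -> float:
    """Convert a breakpoint expressed as % of maximum VPD into kPa."""
    return fraction_percent / 100.0 * vpd_max


def breakpoint_table(model: NNModel, vpd_max: float,
                     splits=SPLITS_DEFAULT, eps: float = 0.05,
                     predictor: str = "vpd") -> pd.DataFrame:
    """Per-cluster, per-split VPD breakpoints from the fitted network."""
    prof = sensitivity_profiles(model, predictor, splits=splits)
    rows = []
    for (s, out), sub in prof.groupby(["split", "output"]):
        frac, kpa = vpd_breakpoint(sub["grid"].to_numpy(),
                                   sub["value"].to_numpy(), vpd_max, eps=eps)
        si = sensitivity_index(sub["grid"].to_numpy(), sub["value"].to_numpy())
        rows.append({"output": out, "split": s, "breakpoint_pct": frac,
                     "breakpoint_kpa": kpa, "SI": si})
    return pd.DataFrame(rows)


def median_breakpoint_table(X, Y, vpd_max: float, n_models: int = 9,
                            splits=SPLITS_DEFAULT, eps: float = 0.05,
                            seed: int = 0, hidden: int = 5,
                            max_epochs: int = 1500,
                            n_restarts: int = 8):
    """Breakpoints and SI as medians over replicate network fits.

    The weather predictors of a single experiment are strongly collinear,
    so an individual network's off-manifold profile (and hence its
    breakpoint at the extreme quantile splits) varies between equally
    well-fitting solutions.  Training ``n_models`` networks from
    independent seeded initialisations and taking the per-cluster,
    per-split median breakpoint gives a stable estimate; the model with the
    lowest validation MSE is returned for inspection alongside the table.
    """
    rng = np.random.default_rng(seed)
    tables, models = [], []
    for _ in range(n_models):
        m = train_nn(X, Y, hidden=hidden, max_epochs=max_epochs,
                     seed=int(rng.integers(2 ** 31 - 1)),
                     n_restarts=n_restarts)
        models.append(m)
        tables.append(breakpoint_table(m, vpd_max, splits=splits, eps=eps))
    allt = pd.concat(tables, ignore_index=True)
    med = (allt.groupby(["output", "split"], as_index=False)
           [["breakpoint_pct", "breakpoint_kpa", "SI"]].median())
    best = min(models,
               key=lambda m: float(m.history.val_mse.iloc[m.best_epoch]))
    return med, best
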