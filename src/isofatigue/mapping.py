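"""Power-loss mapping from percent-normalized sEMG features.

Two families of maps are compared on the same data:

* **linear** — univariate ordinary least squares per feature, and
  forward-stepwise multiple linear regression over the six predictors
  {RMS%, MAV%, MNF%, MDF%, IMNF%, IMDF%};
* **non-linear** — a single-hidden-layer perceptron (inputs → 10 tanh
  units → 1 linear output) trained with Levenberg–Marquardt damped
  Gauss–Newton steps, with early stopping on a validation block.

Goodness of fit is reported as Pearson's r between actual (AV) and
estimated (EV) percent power, R², and a signal-to-noise ratio in dB: the
actual series' sum of squares about its mean over the residual sum of
squares.  The MLP is evaluated by five-fold rotation over contiguous
blocks (four training segments, one validation segment), pooling the
out-of-fold estimates.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from . import stats as ifstats

__all__ = [
    "MlpConfig",
    "MlpModel",
    "MappingResult",
    "CrossValSplit",
    "snr",
    "univariate_map",
    "stepwise_mlr",
    "make_folds",
    "train_mlp",
    "predict_mlp",
    "cross_validated_mlp",
    "compare_linear_nonlinear",
    "format_equation",
]

SNR_CAP_DB = 100.0


@dataclass(frozen=True)
class MlpConfig:
    """Hyperparameters of the power-loss perceptron.

    ``mse_goal`` applies to the z-scored training targets.  ``max_fail``
    is the number of consecutive validation-error increases tolerated
    before early stopping.  ``learning_rate`` is only used by the plain
    gradient-descent fallback (``use_lm=False``); Levenberg–Marquardt
    itself has no learning rate — its trust region is controlled by the
    damping factor (start 1e-3, ×10 on a rejected step, ÷10 on an
    accepted one).
    """

    n_hidden: int = 10
    max_epochs: int = 100
    mse_goal: float = 0.00004
    learning_rate: float = 0.1
    max_fail: int = 18
    seed: int = 0
    use_lm: bool = True

    def __post_init__(self) -> None:
        if min(self.n_hidden, self.max_epochs, self.max_fail) < 1:
            raise ValueError("n_hidden, max_epochs and max_fail must be >= 1")
        if self.mse_goal <= 0 or self.learning_rate <= 0:
            raise ValueError("mse_goal and learning_rate must be positive")


@dataclass
class MlpModel:
    """Fitted perceptron: weights, input/target standardization, history."""

    W1: np.ndarray  # (n_hidden, n_inputs)
    b1: np.ndarray  # (n_hidden,)
    w2: np.ndarray  # (n_hidden,)
    b2: float
    x_mean: np.ndarray
    x_std: np.ndarray
    y_mean: float
    y_std: float
    config: MlpConfig
    history: list[dict] = field(default_factory=list)

    @property
    def n_inputs(self) -> int:
        return self.W1.shape[1]


@dataclass
class MappingResult:
    """Actual-vs-estimated percent power with its scores."""

    actual_pct: np.ndarray
    estimated_pct: np.ndarray
    pearson_r: float
    r_squared: float
    snr_dB: float
    coefficients: dict[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class CrossValSplit:
    """K disjoint index blocks; each validates exactly once while the
    remaining blocks train."""

    blocks: tuple[np.ndarray, ...]

    def __post_init__(self) -> None:
        all_idx = np.concatenate(self.blocks)
        if np.unique(all_idx).size != all_idx.size:
            raise ValueError("blocks overlap")

    @property
    def k(self) -> int:
        return len(self.blocks)

    def folds(self):
        """Yield (train_idx, val_idx) pairs, one per block."""
        for i in range(self.k):
            train = np.concatenate([b for j, b in enumerate(self.blocks) if j != i])
            yield np.sort(train), self.blocks[i]


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

def snr(actual: np.ndarray, estimated: np.ndarray, cap_dB: float = SNR_CAP_DB) -> float:
    """Signal-to-noise ratio in dB: 10·log10(Σ(aᵢ−ā)² / Σ(aᵢ−eᵢ)²).

    Capped at ``cap_dB`` when the residual is numerically zero; exactly
    0 dB when the estimate is the constant mean of the actual series.
    """
    a = np.asarray(actual, dtype=float)
    e = np.asarray(estimated, dtype=float)
    if a.size != e.size or a.size < 2:
        raise ValueError("need equal-length series of at least two points")
    ss_signal = float(np.sum((a - a.mean()) ** 2))
    if ss_signal <= 0:
        raise ValueError("actual series has zero variance; SNR undefined")
    ss_resid = float(np.sum((a - e) ** 2))
    if ss_resid <= ss_signal * 10.0 ** (-cap_dB / 10.0):
        return cap_dB
    return min(cap_dB, 10.0 * np.log10(ss_signal / ss_resid))


def _result(actual: np.ndarray, estimated: np.ndarray,
            r_squared: float | None = None,
            coefficients: dict[str, float] | None = None) -> MappingResult:
    a = np.asarray(actual, dtype=float)
    e = np.asarray(estimated, dtype=float)
    if np.std(e) == 0:
        r = 0.0
    else:
        r = float(sps.pearsonr(a, e)[0])
    return MappingResult(
        actual_pct=a,
        estimated_pct=e,
        pearson_r=r,
        r_squared=float(r * r) if r_squared is None else float(r_squared),
        snr_dB=snr(a, e),
        coefficients=coefficients or {},
    )


# ---------------------------------------------------------------------------
# linear maps
# ---------------------------------------------------------------------------

def univariate_map(x_pct: np.ndarray, y_pct: np.ndarray) -> MappingResult:
    """Ordinary least squares of percent power on one percent feature."""
    x = np.asarray(x_pct, dtype=float)
    y = np.asarray(y_pct, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need at least three paired points")
    if np.std(x) == 0:
        raise ValueError("predictor has zero variance; fit is degenerate")
    fit = sps.linregress(x, y)
    est = fit.intercept + fit.slope * x
    result = _result(
        y, est,
        r_squared=fit.rvalue**2,
        coefficients={"slope": float(fit.slope), "intercept": float(fit.intercept)},
    )
    # report the signed feature-vs-power correlation (the fitted-vs-actual
    # correlation is its absolute value by construction)
    result.pearson_r = float(fit.rvalue)
    return result


def stepwise_mlr(
    X_pct: pd.DataFrame,
    y_pct: np.ndarray,
    p_enter: float = 0.05,
    p_remove: float = 0.10,
) -> tuple[MappingResult, list[str]]:
    """Forward-stepwise multiple linear regression with backward pruning.

    At each step the candidate with the smallest partial-t p-value enters
    if below ``p_enter``; included predictors whose p-value rises above
    ``p_remove`` are dropped.  When nothing qualifies, an intercept-only
    model is returned (with an empty selection).  Exact duplicates of an
    already-included predictor never enter (their partial p is 1 by
    convention for a singular fit).
    """
    y = np.asarray(y_pct, dtype=float)
    if len(X_pct) != y.size or y.size < 10:
        raise ValueError("need at least 10 aligned points")
    candidates = list(X_pct.columns)
    selected: list[str] = []

    def fit(cols: list[str]):
        design = sm.add_constant(X_pct[cols].to_numpy(), has_constant="add")
        return sm.OLS(y, design).fit()

    while True:
        changed = False
        # forward step
        best_p, best_col = None, None
        for col in candidates:
            if col in selected:
                continue
            trial = selected + [col]
            design = X_pct[trial].to_numpy()
            if np.linalg.matrix_rank(np.column_stack([np.ones(y.size), design])) < len(trial) + 1:
                continue  # candidate is collinear with what is already in
            try:
                res = fit(trial)
            except np.linalg.LinAlgError:
                continue
            p = float(res.pvalues[-1])
            if not np.isfinite(p):
                continue
            if best_p is None or p < best_p:
                best_p, best_col = p, col
        if best_col is not None and best_p < p_enter:
            selected.append(best_col)
            changed = True
        # backward step
        if len(selected) > 1:
            res = fit(selected)
            pvals = res.pvalues[1:]  # skip intercept
            worst = int(np.argmax(pvals))
            if float(pvals[worst]) > p_remove:
                selected.pop(worst)
                changed = True
        if not changed:
            break

    if not selected:
        est = np.full_like(y, y.mean())
        result = MappingResult(
            actual_pct=y,
            estimated_pct=est,
            pearson_r=0.0,
            r_squared=0.0,
            snr_dB=0.0,
            coefficients={"intercept": float(y.mean())},
        )
        return result, []

    res = fit(selected)
    est = np.asarray(res.fittedvalues)
    coeffs = {"intercept": float(res.params[0])}
    coeffs.update({c: float(b) for c, b in zip(selected, res.params[1:])})
    return _result(y, est, r_squared=res.rsquared, coefficients=coeffs), selected


def format_equation(coefficients: dict[str, float], target: str = "Power%") -> str:
    """Render a fitted linear map as e.g.
    ``Power% = 0.176 × IMNF% + 0.064 × MNF% + 32.473``."""
    pieces: list[str] = []
    for name, beta in coefficients.items():
        if name == "intercept":
            continue
        pretty = name.replace("_pct", "%")
        sign = "-" if beta < 0 else "+"
        term = f"{abs(beta):.3f} × {pretty}"
        if not pieces:
            pieces.append(term if sign == "+" else f"-{term}")
        else:
            pieces.append(f"{sign} {term}")
    intercept = coefficients.get("intercept", 0.0)
    if pieces:
        pieces.append(f"{'-' if intercept < 0 else '+'} {abs(intercept):.3f}")
    else:
        pieces.append(f"{intercept:.3f}")
    return f"{target} = {' '.join(pieces)}"


# ---------------------------------------------------------------------------
# the perceptron
# ---------------------------------------------------------------------------

def make_folds(
    n_points: int, k: int = 5, seed: int | None = None, shuffle: bool = False
) -> CrossValSplit:
    """Split ``n_points`` into ``k`` near-equal blocks.

    Blocks are contiguous in repetition order by default (the data are
    ordered fatigue trajectories, so contiguous "segments" respect their
    serial structure); ``shuffle=True`` permutes indices first using
    ``seed``.
    """
    if n_points < k:
        raise ValueError("need at least k points")
    idx = np.arange(n_points)
    if shuffle:
        idx = np.random.default_rng(seed).permutation(idx)
    return CrossValSplit(blocks=tuple(np.array_split(idx, k)))


def _unpack(theta: np.ndarray, n_in: int, n_hid: int):
    i = 0
    W1 = theta[i : i + n_hid * n_in].reshape(n_hid, n_in); i += n_hid * n_in
    b1 = theta[i : i + n_hid]; i += n_hid
    w2 = theta[i : i + n_hid]; i += n_hid
    b2 = theta[i]
    return W1, b1, w2, b2


def _forward(theta: np.ndarray, X: np.ndarray, n_hid: int):
    W1, b1, w2, b2 = _unpack(theta, X.shape[1], n_hid)
    H = np.tanh(X @ W1.T + b1)
    yhat = H @ w2 + b2
    return yhat, H, w2


def _jacobian(theta: np.ndarray, X: np.ndarray, n_hid: int) -> np.ndarray:
    """Jacobian of the network output w.r.t. the parameter vector."""
    n, n_in = X.shape
    _, H, w2 = _forward(theta, X, n_hid)
    dtanh = (1.0 - H**2) * w2  # (n, n_hid)
    J = np.empty((n, theta.size))
    # dW1[j, k] = w2_j (1 - h_j^2) x_k
    J[:, : n_hid * n_in] = (dtanh[:, :, None] * X[:, None, :]).reshape(n, -1)
    J[:, n_hid * n_in : n_hid * n_in + n_hid] = dtanh  # db1
    J[:, n_hid * n_in + n_hid : n_hid * n_in + 2 * n_hid] = H  # dw2
    J[:, -1] = 1.0  # db2
    return J


def train_mlp(
    train_X: np.ndarray,
    train_y: np.ndarray,
    val_X: np.ndarray,
    val_y: np.ndarray,
    cfg: MlpConfig | None = None,
) -> MlpModel:
    """Fit the perceptron by damped Gauss–Newton (Levenberg–Marquardt).

    Inputs and targets are z-scored on the training data only.  Each
    epoch solves (JᵀJ + λI)δ = −Jᵀr and accepts the step only if the
    training MSE decreases (λ ÷10 on accept, ×10 and retry on reject),
    so the training MSE is non-increasing across accepted steps.
    Training stops at ``max_epochs``, when the training MSE reaches
    ``mse_goal``, after ``max_fail`` consecutive validation-MSE
    increases, or when damping escalation cannot find a downhill step.
    The returned weights are those with the best validation MSE.
    """
    cfg = cfg or MlpConfig()
    X = np.atleast_2d(np.asarray(train_X, dtype=float))
    if X.shape[0] == 1 and np.asarray(train_y).size != 1:
        X = X.T
    y = np.asarray(train_y, dtype=float).ravel()
    Xv = np.atleast_2d(np.asarray(val_X, dtype=float))
    if Xv.shape[0] == 1 and np.asarray(val_y).size != 1:
        Xv = Xv.T
    yv = np.asarray(val_y, dtype=float).ravel()
    if X.shape[0] != y.size or Xv.shape[0] != yv.size:
        raise ValueError("design/target sizes do not match")

    x_mean = X.mean(axis=0)
    x_std = np.where(X.std(axis=0) > 0, X.std(axis=0), 1.0)
    y_mean = float(y.mean())
    y_std = float(y.std()) or 1.0
    Xs = (X - x_mean) / x_std
    ys = (y - y_mean) / y_std
    Xvs = (Xv - x_mean) / x_std
    yvs = (yv - y_mean) / y_std

    n_in, n_hid = Xs.shape[1], cfg.n_hidden
    n_par = n_hid * n_in + 2 * n_hid + 1
    rng = np.random.default_rng(cfg.seed)
    theta = rng.uniform(-0.5, 0.5, size=n_par)

    def mse(t: np.ndarray, A: np.ndarray, b: np.ndarray) -> float:
        return float(np.mean((_forward(t, A, n_hid)[0] - b) ** 2))

    lam = 1e-3
    train_mse = mse(theta, Xs, ys)
    val_mse = mse(theta, Xvs, yvs)
    best_theta, best_val = theta.copy(), val_mse
    fails = 0
    history = [{"epoch": 0, "train_mse": train_mse, "val_mse": val_mse, "lambda": lam}]

    for epoch in range(1, cfg.max_epochs + 1):
        if train_mse <= cfg.mse_goal:
            break
        if cfg.use_lm:
            r = _forward(theta, Xs, n_hid)[0] - ys
            J = _jacobian(theta, Xs, n_hid)
            JtJ = J.T @ J
            g = J.T @ r
            accepted = False
            while lam <= 1e10:
                try:
                    delta = np.linalg.solve(JtJ + lam * np.eye(n_par), -g)
                except np.linalg.LinAlgError:
                    lam *= 10.0
                    continue
                cand = theta + delta
                cand_mse = mse(cand, Xs, ys)
                if cand_mse < train_mse:
                    theta, train_mse = cand, cand_mse
                    lam = max(lam / 10.0, 1e-12)
                    accepted = True
                    break
                lam *= 10.0
            if not accepted:
                break  # trust region collapsed: no downhill step exists
        else:
            r = _forward(theta, Xs, n_hid)[0] - ys
            J = _jacobian(theta, Xs, n_hid)
            theta = theta - cfg.learning_rate * (2.0 / Xs.shape[0]) * (J.T @ r)
            train_mse = mse(theta, Xs, ys)

        val_mse = mse(theta, Xvs, yvs)
        history.append(
            {"epoch": epoch, "train_mse": train_mse, "val_mse": val_mse, "lambda": lam}
        )
        if val_mse < best_val:
            best_val = val_mse
            best_theta = theta.copy()
            fails = 0
        else:
            fails += 1
            if fails >= cfg.max_fail:
                break

    W1, b1, w2, b2 = _unpack(best_theta, n_in, n_hid)
    return MlpModel(
        W1=W1.copy(), b1=b1.copy(), w2=w2.copy(), b2=float(b2),
        x_mean=x_mean, x_std=x_std, y_mean=y_mean, y_std=y_std,
        config=cfg, history=history,
    )


def predict_mlp(model: MlpModel, X: np.ndarray) -> np.ndarray:
    """Deterministic forward pass on new inputs (standardization applied
    from the stored training statistics)."""
    A = np.atleast_2d(np.asarray(X, dtype=float))
    if A.shape[1] != model.n_inputs:
        if A.shape[0] == model.n_inputs:
            A = A.T
        else:
            raise ValueError(
                f"expected {model.n_inputs} input columns, got {A.shape[1]}"
            )
    Xs = (A - model.x_mean) / model.x_std
    H = np.tanh(Xs @ model.W1.T + model.b1)
    return (H @ model.w2 + model.b2) * model.y_std + model.y_mean


def cross_validated_mlp(
    X: pd.DataFrame | np.ndarray,
    y: np.ndarray,
    folds: CrossValSplit,
    cfg: MlpConfig | None = None,
) -> MappingResult:
    """Five-fold rotation of the perceptron: for each fold, four blocks
    train (the held-out block doubles as the early-stopping validation
    segment) and the held-out block is predicted.  The pooled out-of-fold
    estimates — exactly one per data point — are scored against the
    actual series."""
    cfg = cfg or MlpConfig()
    A = X.to_numpy() if isinstance(X, pd.DataFrame) else np.asarray(X, dtype=float)
    yy = np.asarray(y, dtype=float)
    est = np.full(yy.size, np.nan)
    for i, (tr, va) in enumerate(folds.folds()):
        model = train_mlp(
            A[tr], yy[tr], A[va], yy[va], dataclasses.replace(cfg, seed=cfg.seed + i)
        )
        est[va] = predict_mlp(model, A[va])
    assert not np.any(np.isnan(est))
    return _result(yy, est)


def compare_linear_nonlinear(
    features_pct: pd.DataFrame,
    power_pct: np.ndarray,
    n_folds: int = 5,
    cfg: MlpConfig | None = None,
    predictors: list[str] | None = None,
) -> dict:
    """Head-to-head comparison of the stepwise linear map and the
    cross-validated perceptron on one channel's pooled data.

    Returns the stepwise result (with its selected predictors and
    rendered equation), the pooled out-of-fold perceptron result, and the
    slope/intercept F-tests comparing the two actual-versus-estimated
    regression lines.
    """
    from .features import PERCENT_FEATURES

    cfg = cfg or MlpConfig()
    cols = predictors or [c for c in PERCENT_FEATURES if c in features_pct.columns]
    y = np.asarray(power_pct, dtype=float)
    if y.size < 25:
        raise ValueError("need at least 25 points for the comparison")
    X = features_pct[cols]

    mlr_result, selected = stepwise_mlr(X, y)
    folds = make_folds(y.size, k=n_folds, seed=cfg.seed)
    mlp_result = cross_validated_mlp(X, y, folds, cfg)

    lines = ifstats.compare_regression_lines(
        mlr_result.estimated_pct, y, mlp_result.estimated_pct, y
    )
    return {
        "mlr": mlr_result,
        "mlr_selected": selected,
        "mlr_equation": format_equation(mlr_result.coefficients),
        "mlp": mlp_result,
        "line_comparison": lines,
    }
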