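"""Kolmogorov-Arnold network (KAN) with cubic B-spline edges.

Every edge of the network is a learnable univariate function

    Phi(x) = sum_k c_k B_k^3(x),   x in [0, 1],

where B_k^3 are uniform cubic B-splines on a knot grid with G intervals
(G + 3 basis functions per edge), and node values are plain sums of their
incoming edge outputs. Raw features are min-max scaled to [0, 1] (the
domain of the Kolmogorov-Arnold representation); hidden activations are
clamped back to [0, 1] before the next spline layer.

Training standardizes the target internally and minimises

    L = MSE + lam * (mu1 * sum_edges ||c||_1 + mu2 * S),

where ||c||_1 is the per-edge coefficient L1 norm and S is the attribution
entropy across each layer's edges (small when few edges carry the layer's
weight), using L-BFGS with analytic gradients. After training, edges whose
normalized importance (coefficient L1 norm scaled by the edge's output
standard deviation on the training inputs, relative to the layer maximum)
falls below a threshold are pruned and the survivors refit; surviving edges
are then compressed to closed forms c*g(a*x + b) + d drawn from the library
{x, x^2, exp, log, sin, const} under a complexity penalty.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, asdict
from importlib import resources

import numpy as np
from scipy import optimize

logger = logging.getLogger(__name__)

FAMILIES: tuple[str, ...] = ("x", "x2", "exp", "log", "sin", "const")
#: Number of free parameters per family: the complexity C(g).
FAMILY_COMPLEXITY: dict[str, int] = {
    "const": 1, "x": 2, "x2": 3, "exp": 3, "log": 4, "sin": 4,
}

_ENTROPY_FLOOR = 1e-12


# ---------------------------------------------------------------------------
# Spline basis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SplineGrid:
    """Uniform cubic B-spline grid on [0, 1] with G = n_intervals knot
    intervals, extended by 3 knots on each side; G + 3 basis functions."""

    n_intervals: int = 5
    degree: int = 3

    def __post_init__(self) -> None:
        if self.n_intervals < 1:
            raise ValueError("n_intervals must be >= 1")
        if self.degree != 3:
            raise ValueError("only cubic (degree 3) splines are supported")

    @property
    def h(self) -> float:
        return 1.0 / self.n_intervals

    @property
    def n_basis(self) -> int:
        return self.n_intervals + 3

    @property
    def knots(self) -> np.ndarray:
        return np.linspace(-3 * self.h, 1 + 3 * self.h, self.n_intervals + 7)


def _cardinal_cubic(s: np.ndarray) -> np.ndarray:
    """Uniform cubic B-spline in local knot units s = (x - t_i)/h in [0, 4)."""
    v = np.zeros_like(s)
    m = (s >= 0) & (s < 1)
    u = s[m]
    v[m] = u ** 3 / 6.0
    m = (s >= 1) & (s < 2)
    u = s[m] - 1.0
    v[m] = (-3 * u ** 3 + 3 * u ** 2 + 3 * u + 1) / 6.0
    m = (s >= 2) & (s < 3)
    u = s[m] - 2.0
    v[m] = (3 * u ** 3 - 6 * u ** 2 + 4) / 6.0
    m = (s >= 3) & (s < 4)
    u = s[m] - 3.0
    v[m] = (1 - u) ** 3 / 6.0
    return v


def _cardinal_cubic_deriv(s: np.ndarray) -> np.ndarray:
    v = np.zeros_like(s)
    m = (s >= 0) & (s < 1)
    u = s[m]
    v[m] = u ** 2 / 2.0
    m = (s >= 1) & (s < 2)
    u = s[m] - 1.0
    v[m] = (-9 * u ** 2 + 6 * u + 3) / 6.0
    m = (s >= 2) & (s < 3)
    u = s[m] - 2.0
    v[m] = (9 * u ** 2 - 12 * u) / 6.0
    m = (s >= 3) & (s < 4)
    u = s[m] - 3.0
    v[m] = -(1 - u) ** 2 / 2.0
    return v


def _clamp01(x: np.ndarray, warn: bool = False) -> np.ndarray:
    out = np.clip(x, 0.0, 1.0)
    if warn and (np.any(x < 0) or np.any(x > 1)):
        logger.warning("spline input outside [0, 1]; clamped")
    return out


def basis_matrix(x: np.ndarray, grid: SplineGrid) -> np.ndarray:
    """All basis values at x (any shape); result shape = x.shape + (n_basis,)."""
    x = _clamp01(np.asarray(x, dtype=float))
    t0 = grid.knots[: grid.n_basis]
    s = (x[..., None] - t0) / grid.h
    return _cardinal_cubic(s)


def basis_matrix_deriv(x: np.ndarray, grid: SplineGrid) -> np.ndarray:
    x = _clamp01(np.asarray(x, dtype=float))
    t0 = grid.knots[: grid.n_basis]
    s = (x[..., None] - t0) / grid.h
    return _cardinal_cubic_deriv(s) / grid.h


def bspline_basis(x, grid: SplineGrid, i: int):
    """Value of basis function i at x; x outside [0, 1] is clamped (warned)."""
    if not 0 <= i < grid.n_basis:
        raise ValueError(f"basis index {i} out of range 0..{grid.n_basis - 1}")
    x = np.asarray(x, dtype=float)
    scalar = x.ndim == 0
    x = _clamp01(np.atleast_1d(x), warn=True)
    s = (x - grid.knots[i]) / grid.h
    v = _cardinal_cubic(s)
    return float(v[0]) if scalar else v


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------

@dataclass
class TrainConfig:
    """Training hyper-parameters.

    lam, mu1, mu2 weight the sparsity/entropy regulariser; iterations is
    the number of outer L-BFGS steps, each running up to inner_iterations
    internal L-BFGS iterations with strong-Wolfe line search.
    """

    lam: float = 0.01
    mu1: float = 1.0
    mu2: float = 10.0
    iterations: int = 20
    inner_iterations: int = 20
    seed: int = 0
    prune_threshold: float = 0.2
    widths: tuple[int, ...] = (9, 5, 3, 1)
    grid: int = 5
    #: random restarts of the train/prune/refit path; the candidate with the
    #: lowest penalized TRAINING objective is kept (no validation peeking)
    n_starts: int = 3
    #: maximum prune -> refit rounds (stops earlier at a mask fixed point)
    prune_refit_rounds: int = 3

    def __post_init__(self) -> None:
        if min(self.lam, self.mu1, self.mu2) < 0:
            raise ValueError("lam, mu1, mu2 must be >= 0")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")


@dataclass
class LossBreakdown:
    mse: float
    l1_term: float
    entropy_term: float
    total: float


@dataclass
class KANModel:
    """Spline-edge network: coeffs[l] has shape (n_in, n_out, n_basis)."""

    widths: tuple[int, ...]
    grids: list[SplineGrid]
    coeffs: list[np.ndarray]
    masks: list[np.ndarray]
    scaler_min: np.ndarray | None = None
    scaler_max: np.ndarray | None = None
    #: affine output transform y = out_mean + out_scale * z fitted on the
    #: training targets, so the regularization weights act on a
    #: unit-variance problem regardless of the outcome's units
    out_mean: float = 0.0
    out_scale: float = 1.0

    # -- construction ------------------------------------------------------
    @classmethod
    def init(cls, widths=(9, 5, 3, 1), grid: int = 5, seed: int = 0,
             init_sd: float = 0.1, identity: bool = True) -> "KANModel":
        """Seed-reproducible initialisation.

        Coefficients are Normal(0, init_sd) noise around an
        identity-preserving ramp (the Greville abscissae divided by the
        layer fan-in, so each node starts near the mean of its inputs).
        Pure-spline edges have no residual base function, and with a
        zero-mean init half of every node's activation mass starts
        clamped at 0 where gradients vanish; the ramp keeps activations
        inside the spline domain. identity=False gives the plain
        zero-mean init.
        """
        widths = tuple(int(w) for w in widths)
        if len(widths) < 2 or min(widths) < 1:
            raise ValueError("widths must list >= 2 positive layer sizes")
        rng = np.random.default_rng(seed)
        g = SplineGrid(grid)
        grids = [g] * (len(widths) - 1)
        t = g.knots
        # Greville abscissae: sum_k t*_k B_k(x) = x on [0, 1]
        grev = np.array([(t[k + 1] + t[k + 2] + t[k + 3]) / 3.0
                         for k in range(g.n_basis)])
        coeffs = []
        for l in range(len(widths) - 1):
            c = rng.normal(0.0, init_sd, size=(widths[l], widths[l + 1], g.n_basis))
            if identity:
                c += grev[None, None, :] / widths[l]
            coeffs.append(c)
        masks = [np.ones((widths[l], widths[l + 1]), dtype=bool)
                 for l in range(len(widths) - 1)]
        return cls(widths=widths, grids=grids, coeffs=coeffs, masks=masks)

    @property
    def n_layers(self) -> int:
        return len(self.widths) - 1

    def copy(self) -> "KANModel":
        return KANModel(widths=self.widths, grids=list(self.grids),
                        coeffs=[c.copy() for c in self.coeffs],
                        masks=[m.copy() for m in self.masks],
                        scaler_min=None if self.scaler_min is None else self.scaler_min.copy(),
                        scaler_max=None if self.scaler_max is None else self.scaler_max.copy(),
                        out_mean=self.out_mean, out_scale=self.out_scale)

    # -- scaling -----------------------------------------------------------
    def fit_scaler(self, X: np.ndarray) -> "KANModel":
        """Fit the per-feature min-max scaler (training fold only)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        lo, hi = X.min(axis=0), X.max(axis=0)
        hi = np.where(hi > lo, hi, lo + 1.0)  # guard constant features
        self.scaler_min, self.scaler_max = lo, hi
        return self

    def scale(self, X: np.ndarray) -> np.ndarray:
        if self.scaler_min is None:
            raise ValueError("scaler not fitted; call fit_scaler on the training fold")
        return np.clip((X - self.scaler_min) / (self.scaler_max - self.scaler_min),
                       0.0, 1.0)

    # -- forward -----------------------------------------------------------
    def _forward_internals(self, X: np.ndarray):
        """Returns (activations A_l per layer, basis B_l, pre-clamp Z_l)."""
        A = [self.scale(np.atleast_2d(np.asarray(X, dtype=float)))]
        Bs, Zs = [], []
        for l in range(self.n_layers):
            B = basis_matrix(A[l], self.grids[l])          # (N, n_in, K)
            C = self.coeffs[l] * self.masks[l][..., None]  # (n_in, n_out, K)
            Z = np.einsum("nik,iok->no", B, C)
            Bs.append(B)
            Zs.append(Z)
            A.append(np.clip(Z, 0.0, 1.0) if l < self.n_layers - 1 else Z)
        return A, Bs, Zs

    def forward(self, X: np.ndarray) -> np.ndarray:
        A, _, _ = self._forward_internals(X)
        return self.out_mean + self.out_scale * A[-1][:, 0]

    # -- serialization -----------------------------------------------------
    def to_json(self) -> str:
        payload = {
            "widths": list(self.widths),
            "grids": [g.n_intervals for g in self.grids],
            "coeffs": [c.tolist() for c in self.coeffs],
            "masks": [m.tolist() for m in self.masks],
            "scaler_min": None if self.scaler_min is None else self.scaler_min.tolist(),
            "scaler_max": None if self.scaler_max is None else self.scaler_max.tolist(),
            "out_mean": self.out_mean,
            "out_scale": self.out_scale,
        }
        return json.dumps(payload, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "KANModel":
        d = json.loads(text)
        return cls(
            widths=tuple(d["widths"]),
            grids=[SplineGrid(g) for g in d["grids"]],
            coeffs=[np.asarray(c, dtype=float) for c in d["coeffs"]],
            masks=[np.asarray(m, dtype=bool) for m in d["masks"]],
            scaler_min=None if d["scaler_min"] is None else np.asarray(d["scaler_min"]),
            scaler_max=None if d["scaler_max"] is None else np.asarray(d["scaler_max"]),
            out_mean=d.get("out_mean", 0.0),
            out_scale=d.get("out_scale", 1.0),
        )


def kan_forward(model: KANModel, X: np.ndarray) -> np.ndarray:
    """Predict velocities for raw feature rows X (n, d) or a single row (d,)."""
    X = np.asarray(X, dtype=float)
    single = X.ndim == 1
    y = model.forward(np.atleast_2d(X))
    return float(y[0]) if single else y


# ---------------------------------------------------------------------------
# Loss and training
# ---------------------------------------------------------------------------

def edge_entropy(coeffs: np.ndarray) -> float:
    """Entropy of one edge's normalised squared-coefficient distribution,
    S = -sum_k p_k log p_k with p_k = c_k^2 / sum_j c_j^2 (0*log0 := 0).

    Diagnostic measure of how many basis functions an edge uses; one
    dominant coefficient gives 0, K equal-magnitude coefficients give
    log K.
    """
    c = np.asarray(coeffs, dtype=float).ravel()
    s = float((c ** 2).sum())
    if s <= 1e-300:
        return 0.0
    p = c ** 2 / s
    logp = np.log(np.maximum(p, _ENTROPY_FLOOR))
    return float(-(p * logp).sum())


def _edge_regularizer(C: np.ndarray, mask: np.ndarray):
    """Sparsity terms (and gradients) for one layer's coefficients.

    The L1 term sums the per-edge coefficient L1 norms ||Phi_ij||_1 =
    sum_k |c_ijk|; the entropy term is the attribution entropy ACROSS the
    layer's edges, S = -sum_ij p_ij log p_ij with p_ij = ||Phi_ij||_1 /
    sum ||Phi||_1, which is minimal when few edges carry the layer's
    weight (the sparsification the penalty is meant to induce).
    """
    Cm = C * mask[..., None]
    l1_edge = np.abs(Cm).sum(axis=-1, keepdims=True)  # (n_in, n_out, 1)
    l1 = float(l1_edge.sum())
    g_l1 = np.sign(Cm)
    if l1 <= 1e-300:
        return l1, g_l1, 0.0, np.zeros_like(Cm)
    p = l1_edge / l1
    logp = np.log(np.maximum(p, _ENTROPY_FLOOR))
    S = float(-(p * logp).sum())
    # dS/d l1_ij = -(log p_ij + S)/l1; d l1_ij/dc = sign(c)
    g_ent = -(logp + S) / l1 * g_l1
    return l1, g_l1, S, g_ent


def loss(model: KANModel, X: np.ndarray, y: np.ndarray,
         cfg: TrainConfig | None = None) -> LossBreakdown:
    """Loss breakdown: total = mse + lam*(mu1*l1 + mu2*entropy)."""
    cfg = cfg or TrainConfig()
    y = np.asarray(y, dtype=float)
    yhat = model.forward(X)
    mse = float(np.mean((yhat - y) ** 2))
    l1 = ent = 0.0
    for C, m in zip(model.coeffs, model.masks):
        a, _, b, _ = _edge_regularizer(C, m)
        l1 += a
        ent += b
    total = mse + cfg.lam * (cfg.mu1 * l1 + cfg.mu2 * ent)
    return LossBreakdown(mse=mse, l1_term=float(l1), entropy_term=float(ent),
                         total=float(total))


def _objective(theta: np.ndarray, model: KANModel, X: np.ndarray,
               yz: np.ndarray, cfg: TrainConfig):
    """Total loss (standardized-output units) and analytic gradient wrt the
    flattened coefficients; yz are the targets on the network's output
    scale, (y - out_mean) / out_scale."""
    _set_flat(model, theta)
    N = len(yz)
    A, Bs, Zs = model._forward_internals(X)
    yhat = A[-1][:, 0]
    resid = yhat - yz
    mse = float(np.mean(resid ** 2))
    grads = [np.zeros_like(c) for c in model.coeffs]
    G = (2.0 / N) * resid[:, None]  # dL/dZ_last, (N, 1)
    total = mse
    for l in range(model.n_layers - 1, -1, -1):
        C = model.coeffs[l] * model.masks[l][..., None]
        grads[l] = np.einsum("nik,no->iok", Bs[l], G) * model.masks[l][..., None]
        if l > 0:
            Bd = basis_matrix_deriv(A[l], model.grids[l])
            dA = np.einsum("no,iok,nik->ni", G, C, Bd)
            inside = (Zs[l - 1] > 0.0) & (Zs[l - 1] < 1.0)
            G = dA * inside
    for l in range(model.n_layers):
        l1, g_l1, ent, g_ent = _edge_regularizer(model.coeffs[l], model.masks[l])
        total += cfg.lam * (cfg.mu1 * l1 + cfg.mu2 * ent)
        grads[l] += cfg.lam * (cfg.mu1 * g_l1 + cfg.mu2 * g_ent)
    return total, np.concatenate([g.ravel() for g in grads])


def _get_flat(model: KANModel) -> np.ndarray:
    return np.concatenate([c.ravel() for c in model.coeffs])


def _set_flat(model: KANModel, theta: np.ndarray) -> None:
    pos = 0
    for l, c in enumerate(model.coeffs):
        n = c.size
        model.coeffs[l] = theta[pos:pos + n].reshape(c.shape)
        pos += n


def train(model: KANModel, X: np.ndarray, y: np.ndarray,
          cfg: TrainConfig | None = None) -> tuple[KANModel, list[float]]:
    """L-BFGS training; returns (trained model, per-step total-loss history).

    The history starts with the initial loss and appends the loss after
    each of the cfg.iterations outer steps; the line search guarantees a
    non-increasing trajectory across accepted steps.
    """
    cfg = cfg or TrainConfig()
    model = model.copy()
    if model.scaler_min is None:
        model.fit_scaler(X)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    # scale-free training: standardize the target so lam/mu1/mu2 weigh a
    # unit-variance regression problem whatever the outcome's units
    model.out_mean = float(y.mean())
    sd = float(y.std())
    model.out_scale = sd if sd > 0 else 1.0
    yz = (y - model.out_mean) / model.out_scale
    theta = _get_flat(model)
    history = [float(_objective(theta, model, X, yz, cfg)[0])]
    for _ in range(cfg.iterations):
        res = optimize.minimize(
            _objective, theta, args=(model, X, yz, cfg), jac=True,
            method="L-BFGS-B",
            options={"maxiter": cfg.inner_iterations, "maxcor": 10},
        )
        if not np.isfinite(res.fun):
            raise RuntimeError("non-finite loss during training; inspect inputs")
        theta = res.x
        history.append(float(res.fun))
        if res.status == 0:  # converged
            break
    _set_flat(model, theta)
    return model, history


def fit_kan(X: np.ndarray, y: np.ndarray, cfg: TrainConfig | None = None,
            prune_model: bool = True) -> tuple["KANModel", dict]:
    """Full fitting path: scale -> train -> prune -> refit, with restarts.

    Runs cfg.n_starts random restarts; within each, after basic training
    the model is pruned and refit repeatedly until the edge masks stop
    changing (at most cfg.prune_refit_rounds rounds). Among all candidates
    the one with the lowest penalized training objective is returned
    (selection never sees held-out data). info reports the winning
    restart, round and objective.
    """
    cfg = cfg or TrainConfig()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    best = None
    for s in range(cfg.n_starts):
        model = KANModel.init(cfg.widths, cfg.grid, seed=cfg.seed + 7919 * s)
        model.fit_scaler(X)
        model, hist = train(model, X, y, cfg)
        candidates = [(hist[-1], model, s, 0)]
        cur = model
        if prune_model:
            for r in range(1, cfg.prune_refit_rounds + 1):
                try:
                    pruned = prune(cur, X, cfg.prune_threshold)
                except ValueError:
                    break
                if all(np.array_equal(a, b)
                       for a, b in zip(pruned.masks, cur.masks)):
                    break
                pruned, hist = train(pruned, X, y, cfg)
                candidates.append((hist[-1], pruned, s, r))
                cur = pruned
        for cand in candidates:
            if best is None or cand[0] < best[0]:
                best = cand
    obj, model, start, rnd = best
    return model, {"objective": float(obj), "start": int(start), "round": int(rnd)}


def r_squared(predictions: np.ndarray, truths: np.ndarray) -> float:
    """Coefficient of determination 1 - SS_res/SS_tot (may be negative)."""
    yhat = np.asarray(predictions, dtype=float)
    y = np.asarray(truths, dtype=float)
    if y.size < 2:
        raise ValueError("need at least 2 observations")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("truths have zero variance; R^2 undefined")
    return 1.0 - float(np.sum((y - yhat) ** 2)) / ss_tot


# ---------------------------------------------------------------------------
# Pruning
# ---------------------------------------------------------------------------

def edge_importance(model: KANModel, X: np.ndarray,
                    normalize: bool = False) -> list[np.ndarray]:
    """Per-edge importance: coefficient L1 norm x output std on inputs X.

    With normalize=True each layer's importances are divided by the
    layer's maximum, putting them on the [0, 1] attribution scale that
    the pruning threshold refers to.
    """
    A, Bs, _ = model._forward_internals(X)
    out = []
    for l in range(model.n_layers):
        phi = np.einsum("nik,iok->nio", Bs[l], model.coeffs[l])  # (N, n_in, n_out)
        std = phi.std(axis=0)
        l1 = np.abs(model.coeffs[l]).sum(axis=-1)
        w = l1 * std * model.masks[l]
        if normalize and w.max() > 0:
            w = w / w.max()
        out.append(w)
    return out


def prune(model: KANModel, X: np.ndarray, threshold: float = 0.2) -> KANModel:
    """Mask edges whose normalized importance is <= threshold; drop dead
    nodes.

    The forward pass of the pruned model equals the unpruned forward with
    the masked coefficients set to zero.
    """
    model = model.copy()
    imp = edge_importance(model, X, normalize=True)
    for l in range(model.n_layers):
        model.masks[l] = model.masks[l] & (imp[l] > threshold)
    # Remove nodes with no active incoming or outgoing edges (fixed point).
    changed = True
    while changed:
        changed = False
        for l in range(model.n_layers - 1):
            has_in = model.masks[l].any(axis=0)
            has_out = model.masks[l + 1].any(axis=1)
            dead = ~(has_in & has_out)
            if (model.masks[l][:, dead].any() or model.masks[l + 1][dead, :].any()):
                model.masks[l][:, dead] = False
                model.masks[l + 1][dead, :] = False
                changed = True
    if not model.masks[-1].any():
        raise ValueError("pruning removed every edge into the output; "
                         "lower the threshold")
    return model


def surviving_inputs(model: KANModel) -> list[int]:
    """Indices of input features with at least one active outgoing edge."""
    return [int(i) for i in np.where(model.masks[0].any(axis=1))[0]]


# ---------------------------------------------------------------------------
# Symbolic compression
# ---------------------------------------------------------------------------

@dataclass
class SymbolicTerm:
    """One edge replaced by c * g(a*x + b) + d (family 'const' is just d)."""

    family: str
    layer: int
    i: int | None
    j: int
    a: float
    b: float
    c: float
    d: float


@dataclass
class SymbolicModel:
    """Closed-form network: terms grouped by layer, summed at nodes."""

    widths: tuple[int, ...]
    terms: list[SymbolicTerm]
    scaler_min: list | None = None
    scaler_max: list | None = None
    out_mean: float = 0.0
    out_scale: float = 1.0

    def to_json(self) -> str:
        return json.dumps({
            "widths": list(self.widths),
            "scaler_min": self.scaler_min,
            "scaler_max": self.scaler_max,
            "out_mean": self.out_mean,
            "out_scale": self.out_scale,
            "terms": [asdict(t) for t in self.terms],
        }, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SymbolicModel":
        d = json.loads(text)
        terms = [SymbolicTerm(**{k: t[k] for k in
                                 ("family", "layer", "i", "j", "a", "b", "c", "d")})
                 for t in d["terms"]]
        return cls(widths=tuple(d["widths"]), terms=terms,
                   scaler_min=d.get("scaler_min"), scaler_max=d.get("scaler_max"),
                   out_mean=d.get("out_mean", 0.0),
                   out_scale=d.get("out_scale", 1.0))


def _eval_family(family: str, a: float, b: float, c: float, d: float,
                 x: np.ndarray) -> np.ndarray:
    z = a * x + b
    if family == "x":
        return c * z + d
    if family == "x2":
        return c * z ** 2 + d
    if family == "exp":
        return c * np.exp(np.clip(z, -700, 700)) + d
    if family == "log":
        if np.any(z <= 0):
            raise ValueError("log family evaluated at non-positive argument")
        return c * np.log(z) + d
    if family == "sin":
        return c * np.sin(z) + d
    if family == "const":
        return np.full_like(x, d, dtype=float)
    raise ValueError(f"unknown family {family!r}")


def predict_symbolic(sym: SymbolicModel, X: np.ndarray) -> np.ndarray:
    """Evaluate the closed-form model on raw feature rows."""
    if not sym.terms:
        raise ValueError("empty symbolic model")
    X = np.asarray(X, dtype=float)
    single = X.ndim == 1
    A = np.atleast_2d(X)
    if sym.scaler_min is not None:
        lo = np.asarray(sym.scaler_min, dtype=float)
        hi = np.asarray(sym.scaler_max, dtype=float)
        A = np.clip((A - lo) / (hi - lo), 0.0, 1.0)
    n_layers = len(sym.widths) - 1
    by_layer: dict[int, list[SymbolicTerm]] = {}
    for t in sym.terms:
        by_layer.setdefault(t.layer, []).append(t)
    for l in range(n_layers):
        out = np.zeros((A.shape[0], sym.widths[l + 1]))
        for t in by_layer.get(l, []):
            if t.family == "const":
                out[:, t.j] += t.d
            else:
                out[:, t.j] += _eval_family(t.family, t.a, t.b, t.c, t.d, A[:, t.i])
        A = np.clip(out, 0.0, 1.0) if l < n_layers - 1 else out
    y = sym.out_mean + sym.out_scale * A[:, 0]
    return float(y[0]) if single else y


def load_reference_equation() -> SymbolicModel:
    """Packaged closed-form feature-to-velocity equation (m/s)."""
    text = resources.files("sprintkan.data").joinpath("sprint_equation.json").read_text()
    return SymbolicModel.from_json(text)


def equation_string(sym: SymbolicModel, ndigits: int = 4) -> str:
    """Human-readable rendering; additive for single-layer models, nested
    otherwise."""

    def fmt(v):
        return f"{v:.{ndigits}g}"

    def term_str(t: SymbolicTerm, arg: str) -> str:
        inner = arg
        if t.a != 1.0 or t.b != 0.0:
            inner = f"{fmt(t.a)}*{arg}" + (f" + {fmt(t.b)}" if t.b else "")
        if t.family == "const":
            return fmt(t.d)
        body = {"x": inner, "x2": f"({inner})^2", "exp": f"exp({inner})",
                "log": f"log({inner})", "sin": f"sin({inner})"}[t.family]
        s = f"{fmt(t.c)}*{body}"
        if t.d:
            s += f" + {fmt(t.d)}"
        return s

    n_layers = len(sym.widths) - 1
    names = [f"x{i + 1}" for i in range(sym.widths[0])]
    for l in range(n_layers):
        nxt = []
        for j in range(sym.widths[l + 1]):
            parts = [term_str(t, names[t.i] if t.i is not None else "")
                     for t in sym.terms if t.layer == l and t.j == j]
            expr = " + ".join(parts) if parts else "0"
            nxt.append(expr if n_layers == 1 else f"({expr})")
        names = nxt
    return "y = " + names[0]


def _lin_fit(design: np.ndarray, ys: np.ndarray):
    """Least-squares c, d for ys ~ c*design + d; returns (c, d, mse)."""
    Adm = np.column_stack([design, np.ones_like(design)])
    sol, *_ = np.linalg.lstsq(Adm, ys, rcond=None)
    resid = ys - Adm @ sol
    return float(sol[0]), float(sol[1]), float(np.mean(resid ** 2))


def _fit_family(family: str, xs: np.ndarray, ys: np.ndarray):
    """Best (a, b, c, d, mse) of one family, or None if inapplicable."""
    if family == "const":
        d = float(np.mean(ys))
        return 0.0, 0.0, 0.0, d, float(np.var(ys))
    if family == "x":
        c, d, mse = _lin_fit(xs, ys)
        return 1.0, 0.0, c, d, mse
    if family == "x2":
        coef = np.polyfit(xs, ys, 2)
        if abs(coef[0]) < 1e-12:
            return None
        c = float(coef[0])
        b = float(coef[1] / (2 * c))
        d = float(coef[2] - c * b ** 2)
        resid = ys - (c * (xs + b) ** 2 + d)
        return 1.0, b, c, d, float(np.mean(resid ** 2))
    if family == "exp":
        best = None
        for a in np.linspace(-6, 6, 49):
            if abs(a) < 0.05:
                continue
            c, d, mse = _lin_fit(np.exp(np.clip(a * xs, -50, 50)), ys)
            if best is None or mse < best[4]:
                best = (a, 0.0, c, d, mse)
        a = best[0]

        def nmse_exp(av):
            return _lin_fit(np.exp(np.clip(av * xs, -50, 50)), ys)[2]

        res = optimize.minimize_scalar(nmse_exp, bracket=None,
                                       bounds=(a - 0.5, a + 0.5), method="bounded")
        a = float(res.x)
        c, d, mse = _lin_fit(np.exp(np.clip(a * xs, -50, 50)), ys)
        return a, 0.0, c, d, mse
    if family == "log":
        lo, hi = float(xs.min()), float(xs.max())
        best = None
        for a in np.linspace(-8, 8, 33):
            if abs(a) < 0.05:
                continue
            for margin in (0.02, 0.05, 0.2, 0.5, 1.0):
                b = margin - min(a * lo, a * hi)
                c, d, mse = _lin_fit(np.log(a * xs + b), ys)
                if best is None or mse < best[4]:
                    best = (float(a), float(b), c, d, mse)
        a0, b0 = best[0], best[1]

        def resid_log(p):
            arg = p[0] * xs + p[1]
            if np.any(arg <= 1e-9):
                return np.full_like(ys, 1e6)
            c, d, _ = _lin_fit(np.log(arg), ys)
            return ys - (c * np.log(arg) + d)

        res = optimize.least_squares(resid_log, x0=[a0, b0], method="lm",
                                     max_nfev=200)
        a, b = float(res.x[0]), float(res.x[1])
        if np.all(a * xs + b > 0):
            c, d, mse = _lin_fit(np.log(a * xs + b), ys)
            if mse < best[4]:
                best = (a, b, c, d, mse)
        return best
    if family == "sin":
        best = None
        for a in np.arange(0.5, 12.01, 0.25):
            za = a * xs
            for b in np.linspace(0, 2 * np.pi, 13, endpoint=False):
                c, d, mse = _lin_fit(np.sin(za + b), ys)
                if best is None or mse < best[4]:
                    best = (float(a), float(b), c, d, mse)
        a0, b0 = best[0], best[1]

        def resid_sin(p):
            c, d, _ = _lin_fit(np.sin(p[0] * xs + p[1]), ys)
            return ys - (c * np.sin(p[0] * xs + p[1]) + d)

        res = optimize.least_squares(resid_sin, x0=[a0, b0], method="lm",
                                     max_nfev=200)
        a, b = float(res.x[0]), float(res.x[1])
        c, d, mse = _lin_fit(np.sin(a * xs + b), ys)
        # canonical form: a >= 0, c >= 0, b in [0, 2*pi)
        if a < 0:
            a, b, c = -a, -b, -c
        if c < 0:
            b, c = b + math.pi, -c
        b = b % (2 * math.pi)
        return a, b, c, d, mse
    raise ValueError(f"unknown family {family!r}")


def fit_edge_symbolic(xs: np.ndarray, ys: np.ndarray, lam_c: float = 0.02,
                      families: tuple[str, ...] = FAMILIES):
    """Pick the penalized-best closed form for samples (xs, ys).

    Score = mse/var(ys) + lam_c * C(g); a degenerate (near-constant) edge
    maps to the 'const' family directly.
    """
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    var = float(np.var(ys))
    if var < 1e-14:
        return "const", (0.0, 0.0, 0.0, float(np.mean(ys))), 0.0
    best = None
    for fam in families:
        fit = _fit_family(fam, xs, ys)
        if fit is None:
            continue
        a, b, c, d, mse = fit
        score = mse / var + lam_c * FAMILY_COMPLEXITY[fam]
        if best is None or score < best[2]:
            best = (fam, (a, b, c, d), score)
    return best


def symbolize(model: KANModel, X: np.ndarray, lam_c: float = 0.02,
              families: tuple[str, ...] = FAMILIES) -> SymbolicModel:
    """Replace every surviving edge with its best library closed form.

    Each active edge Phi_{l,i,j} is sampled at the realized node inputs on
    X and refit as c*g(a*x + b) + d; the result is a closed-form network
    with the same topology (additive when the model has a single layer).
    """
    A, Bs, _ = model._forward_internals(X)
    terms: list[SymbolicTerm] = []
    for l in range(model.n_layers):
        for i in range(model.widths[l]):
            for j in range(model.widths[l + 1]):
                if not model.masks[l][i, j]:
                    continue
                xs = A[l][:, i]
                ys = Bs[l][:, i, :] @ model.coeffs[l][i, j]
                fam, (a, b, c, d), _score = fit_edge_symbolic(xs, ys, lam_c, families)
                terms.append(SymbolicTerm(family=fam, layer=l, i=i, j=j,
                                          a=a, b=b, c=c, d=d))
    return SymbolicModel(
        widths=model.widths, terms=terms,
        scaler_min=None if model.scaler_min is None else model.scaler_min.tolist(),
        scaler_max=None if model.scaler_max is None else model.scaler_max.tolist(),
        out_mean=model.out_mean, out_scale=model.out_scale,
    )
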