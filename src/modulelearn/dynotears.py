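"""Structure learning of a structural vector autoregressive model (SVAR)
with a smooth acyclicity constraint — the DYNOTEARS estimator.

The model for a d-dimensional series is

    x_t = W^T x_t + A^T [x_{t-1}, ..., x_{t-p}] + eps_t

where W (d x d) holds contemporaneous (intra-slice) links and A (dp x d)
holds lagged (inter-slice) links.  Both matrices are estimated jointly by
minimizing the penalized least-squares score

    0.5/M * ||X - X W - Y A||_F^2 + lambda_w ||W||_1 + lambda_a ||A||_1

subject to the continuous acyclicity constraint h(W) = 0, where

    h(W) = trace(exp(W o W)) - d          (o = elementwise product)

vanishes exactly when the weighted digraph of W has no directed cycle.
The constrained problem is solved with an augmented Lagrangian: each outer
iteration minimizes the score plus 0.5*rho*h^2 + alpha*h with L-BFGS-B over
the non-negative split W = W+ - W-, A = A+ - A- (which makes the L1 terms
smooth), then updates (rho, alpha) until h falls below tolerance.

Discrete event sequences enter as one-hot binary panels over the event
index (see :func:`encode_binary_panel`); columns are standardized inside
the fit so the L1 penalties are scale-free, and coefficients are mapped
back to the original scale before thresholding.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import scipy.linalg
import scipy.optimize

from .datatypes import RuleGraph, SequenceDataset, TemporalRule, START_ID, STOP_ID

logger = logging.getLogger(__name__)


@dataclass
class DesignMatrices:
    """Pooled regression panel: current-slice X and lagged Y.

    Rows are (t, t-1..t-p) windows pooled over patients; windows never span
    two patients.  ``concepts`` names the d coordinates; Y column ``l*d + j``
    is concept j at lag ``l+1``.
    """

    X: np.ndarray  # M x d
    Y: np.ndarray  # M x (d*p)
    p: int
    concepts: list[int]

    @property
    def M(self) -> int:
        return self.X.shape[0]

    @property
    def d(self) -> int:
        return self.X.shape[1]


@dataclass
class SVARModel:
    """Estimated (or ground-truth) SVAR coefficient matrices."""

    W: np.ndarray  # d x d intra-slice
    A: np.ndarray  # (d*p) x d inter-slice
    p: int = 1
    lambda_w: float = 0.1
    lambda_a: float = 0.1
    threshold: float = 0.3
    converged: bool = True
    h_value: float = 0.0
    objective_history: list[dict] = field(default_factory=list)

    @property
    def d(self) -> int:
        return self.W.shape[0]

    def A_lag(self, lag: int) -> np.ndarray:
        """The d x d inter-slice block for a given lag (1-based)."""
        d = self.d
        return self.A[(lag - 1) * d : lag * d, :]


def encode_binary_panel(
    dataset: SequenceDataset,
    top_k: Optional[int] = 100,
    p: int = 1,
) -> DesignMatrices:
    """One-hot encode event sequences into a pooled lagged regression panel.

    Each modelled concept becomes one binary coordinate.  When ``top_k`` is
    given, only the top_k most frequent non-sentinel concepts are modelled
    (sentinels are always kept); events outside the modelled set are dropped
    from the sequence before windowing.  Sequences left shorter than p+1
    events are skipped with a warning.
    """
    if p < 1:
        raise ValueError("lag order p must be >= 1")
    freq: Counter[int] = Counter()
    for seq in dataset:
        for cid in seq.concept_ids:
            if cid not in (START_ID, STOP_ID):
                freq[cid] += 1
    kept = sorted(freq, key=lambda c: (-freq[c], c))
    if top_k is not None:
        kept = kept[:top_k]
    concepts = [START_ID, STOP_ID] + sorted(kept)
    ix = {cid: i for i, cid in enumerate(concepts)}
    d = len(concepts)

    x_rows: list[np.ndarray] = []
    y_rows: list[np.ndarray] = []
    n_skipped = 0
    for seq in dataset:
        ids = [cid for cid in seq.concept_ids if cid in ix]
        if len(ids) < p + 1:
            n_skipped += 1
            continue
        for t in range(p, len(ids)):
            x = np.zeros(d)
            x[ix[ids[t]]] = 1.0
            y = np.zeros(d * p)
            for lag in range(1, p + 1):
                y[(lag - 1) * d + ix[ids[t - lag]]] = 1.0
            x_rows.append(x)
            y_rows.append(y)
    if n_skipped:
        logger.warning("skipped %d sequences shorter than p+1 after filtering", n_skipped)
    if not x_rows:
        raise ValueError("no usable windows; all sequences shorter than p+1")
    return DesignMatrices(X=np.array(x_rows), Y=np.array(y_rows), p=p, concepts=concepts)


def h_acyclicity(W: np.ndarray) -> float:
    """Smooth acyclicity score h(W) = trace(exp(W o W)) - d; zero iff acyclic."""
    W = np.asarray(W, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError("W must be square")
    E = scipy.linalg.expm(W * W)
    return float(np.trace(E)) - W.shape[0]


def _h_and_grad(W: np.ndarray) -> tuple[float, np.ndarray]:
    E = scipy.linalg.expm(W * W)
    return float(np.trace(E)) - W.shape[0], E.T * 2.0 * W


def fit_dynotears(
    dm: DesignMatrices,
    lambda_w: float = 0.1,
    lambda_a: float = 0.1,
    max_outer: int = 100,
    h_tol: float = 1e-8,
    rho_max: float = 1e16,
    standardize: bool = True,
    threshold: float = 0.3,
) -> SVARModel:
    """Fit the SVAR by augmented-Lagrangian continuous optimization.

    Deterministic: initialization is W = A = 0 and every step is exact
    arithmetic on the inputs.  Columns with zero variance (e.g. the START
    indicator, which never occurs in the current slice) receive zero
    coefficients.  If ``max_outer`` iterations do not bring h(W) below
    ``h_tol`` the best iterate is returned with ``converged=False``.
    """
    if dm.M == 0:
        raise ValueError("design matrices are empty")
    X = np.asarray(dm.X, dtype=float)
    Y = np.asarray(dm.Y, dtype=float)
    M, d = X.shape
    dp = Y.shape[1]

    if standardize:
        x_mu, y_mu = X.mean(axis=0), Y.mean(axis=0)
        x_sd = X.std(axis=0)
        y_sd = Y.std(axis=0)
        x_scale = np.where(x_sd > 0, x_sd, 1.0)
        y_scale = np.where(y_sd > 0, y_sd, 1.0)
        Xs = (X - x_mu) / x_scale
        Ys = (Y - y_mu) / y_scale
    else:
        x_scale = np.ones(d)
        y_scale = np.ones(dp)
        Xs, Ys = X, Y

    # Gram matrices make each gradient evaluation O(d^3) instead of O(M d^2).
    Sxx = Xs.T @ Xs
    Sxy = Xs.T @ Ys
    Syy = Ys.T @ Ys

    n_w = d * d
    n_a = dp * d

    def unpack(z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        W = (z[:n_w] - z[n_w : 2 * n_w]).reshape(d, d)
        A = (z[2 * n_w : 2 * n_w + n_a] - z[2 * n_w + n_a :]).reshape(dp, d)
        return W, A

    def objective(z: np.ndarray, rho: float, alpha: float) -> tuple[float, np.ndarray]:
        W, A = unpack(z)
        IW = np.eye(d) - W
        # 0.5/M ||Xs(I-W) - Ys A||_F^2 via Gram matrices
        quad = (
            np.einsum("ij,ij->", IW, Sxx @ IW)
            - 2.0 * np.einsum("ij,ij->", IW, Sxy @ A)
            + np.einsum("ij,ij->", A, Syy @ A)
        )
        loss = 0.5 / M * quad
        g_w = -(Sxx @ IW - Sxy @ A) / M
        g_a = -(Sxy.T @ IW - Syy @ A) / M
        h, g_h = _h_and_grad(W)
        pen = 0.5 * rho * h * h + alpha * h
        g_w = g_w + (rho * h + alpha) * g_h
        l1 = lambda_w * np.sum(z[: 2 * n_w]) + lambda_a * np.sum(z[2 * n_w :])
        grad = np.concatenate(
            [
                (g_w + lambda_w).ravel(),
                (-g_w + lambda_w).ravel(),
                (g_a + lambda_a).ravel(),
                (-g_a + lambda_a).ravel(),
            ]
        )
        return loss + pen + l1, grad

    bounds = []
    for sign in range(2):  # W+ then W-
        for i in range(d):
            for j in range(d):
                bounds.append((0.0, 0.0) if i == j else (0.0, None))
    bounds.extend([(0.0, None)] * (2 * n_a))

    z = np.zeros(2 * n_w + 2 * n_a)
    rho, alpha, h = 1.0, 0.0, np.inf
    history: list[dict] = []
    converged = False
    for outer in range(max_outer):
        z_new, h_new = z, None
        while rho < rho_max:
            f0 = objective(z, rho, alpha)[0]
            res = scipy.optimize.minimize(
                objective,
                z,
                args=(rho, alpha),
                jac=True,
                method="L-BFGS-B",
                bounds=bounds,
                # tight tolerances keep the fit permutation-equivariant
                options={"ftol": 1e-14, "gtol": 1e-10, "maxiter": 5000},
            )
            z_cand = res.x if res.fun <= f0 else z
            f_end = min(float(res.fun), f0)
            W_cand, _ = unpack(z_cand)
            h_new = h_acyclicity(W_cand)
            if h_new > 0.25 * h:
                rho *= 10.0
            else:
                z_new = z_cand
                history.append(
                    {"outer": outer, "rho": rho, "alpha": alpha,
                     "f_start": f0, "f_end": f_end, "h": h_new}
                )
                break
        else:
            # rho exhausted: accept the best candidate found
            z_new = z_cand
            history.append(
                {"outer": outer, "rho": rho, "alpha": alpha,
                 "f_start": f0, "f_end": f_end, "h": h_new}
            )
        z = z_new
        h = h_new if h_new is not None else h
        alpha += rho * h
        if h <= h_tol:
            converged = True
            break
        if rho >= rho_max:
            break

    W_std, A_std = unpack(z)
    # Map standardized coefficients back: x_j = sum_i W_ij x_i + sum_k A_kj y_k
    W = W_std * x_scale[None, :] / x_scale[:, None]
    A = A_std * x_scale[None, :] / y_scale[:, None]
    if not converged:
        logger.warning("augmented Lagrangian did not reach h_tol (h=%.3g)", h)
    return SVARModel(
        W=W, A=A, p=dm.p, lambda_w=lambda_w, lambda_a=lambda_a,
        threshold=threshold, converged=converged, h_value=float(h),
        objective_history=history,
    )


def svar_to_rules(
    model: SVARModel,
    concepts: Sequence[int],
    threshold: float = 0.3,
    dataset_tag: str = "",
) -> RuleGraph:
    """Threshold the coefficient matrices into a rule graph.

    Inter-slice entries |A| > threshold become temporal rules i -> j
    (provenance ``dynotears-inter``); lags beyond 1 are collapsed onto the
    same edge keeping the largest magnitude.  Intra-slice entries become
    same-slice co-occurrence rules (provenance ``dynotears-intra``).  Edges
    out of STOP or into START are structural impossibilities and skipped.
    """
    d = model.d
    if len(concepts) != d:
        raise ValueError("concept list does not match model dimension")
    graph = RuleGraph(algorithm="dynotears", dataset_tag=dataset_tag)

    inter_best: dict[tuple[int, int], float] = {}
    for lag in range(1, model.p + 1):
        block = model.A_lag(lag)
        for i in range(d):
            for j in range(d):
                w = abs(float(block[i, j]))
                if w > threshold:
                    key = (concepts[i], concepts[j])
                    if w > inter_best.get(key, 0.0):
                        inter_best[key] = w
    for (a, c), w in sorted(inter_best.items()):
        if a == STOP_ID or c == START_ID:
            continue
        graph.add_rule(TemporalRule(antecedent=a, consequent=c, weight=w, provenance="dynotears-inter"))

    for i in range(d):
        for j in range(d):
            w = abs(float(model.W[i, j]))
            if w > threshold:
                a, c = concepts[i], concepts[j]
                if a == STOP_ID or c == START_ID or (a, c) in graph.edges:
                    continue
                graph.add_rule(TemporalRule(antecedent=a, consequent=c, weight=w, provenance="dynotears-intra"))
    return graph


def structural_hamming_distance(
    est: SVARModel,
    truth: SVARModel,
    threshold: Optional[float] = None,
) -> int:
    """SHD between a thresholded estimate and a ground-truth structure.

    Intra-slice edges are compared per unordered node pair (a reversed edge
    costs 1); inter-slice edges are directed by construction and compared by
    symmetric difference, per lag.
    """
    thr = est.threshold if threshold is None else threshold
    Bw_est = np.abs(est.W) > thr
    Bw_true = np.abs(truth.W) > 0
    Ba_est = np.abs(est.A) > thr
    Ba_true = np.abs(truth.A) > 0
    d = est.d
    shd = 0
    for i in range(d):
        for j in range(i + 1, d):
            if (Bw_est[i, j], Bw_est[j, i]) != (Bw_true[i, j], Bw_true[j, i]):
                shd += 1
    shd += int(np.sum(Ba_est != Ba_true))
    return shd


def write_matrices_tsv(model: SVARModel, labels: Sequence[str], out_prefix: str | Path) -> None:
    """Dump W and A as labeled TSV matrices (<prefix>.W.tsv / <prefix>.A.tsv)."""
    out_prefix = str(out_prefix)
    header = "\t".join([""] + list(labels))
    with open(out_prefix + ".W.tsv", "w") as fh:
        fh.write(header + "\n")
        for lbl, row in zip(labels, model.W):
            fh.write(lbl + "\t" + "\t".join(f"{v:.6g}" for v in row) + "\n")
    with open(out_prefix + ".A.tsv", "w") as fh:
        fh.write(header + "\n")
        for lag in range(1, model.p + 1):
            for lbl, row in zip(labels, model.A_lag(lag)):
                fh.write(f"{lbl}[t-{lag}]\t" + "\t".join(f"{v:.6g}" for v in row) + "\n")
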