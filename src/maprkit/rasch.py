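"""Holistic preference-response (Rasch) model with CML estimation.

Measurement model: person p with latent health value theta_p judges
comparator state i with value beta_i; the probability of preferring the
own state (response Y_ip = 1) is

    pi_ip = exp(theta_p - beta_i) / (1 + exp(theta_p - beta_i)).

The person raw score R_p = sum_i Y_ip is sufficient for theta_p, so the
item values beta can be estimated by conditional maximum likelihood (CML)
without any assumption on the distribution of person values.  The
conditional likelihood is normalized by elementary symmetric functions
gamma_r of eps_i = exp(-beta_i); this module computes them with the
numerically stable summation recursion in log space.

Person values are estimated in a second step by plain maximum likelihood
with the item values held fixed; the variance of theta_hat is the inverse
of the Fisher information sum_i P_i(theta)(1 - P_i(theta)).  Persons with
extreme raw scores (0 or I) carry no information and receive an infinite
point value with an `extreme` flag.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.special import expit

from .exceptions import ConvergenceError, IllConditionedError, ValidationError

logger = logging.getLogger("maprkit")

__all__ = [
    "ResponseMatrix",
    "RaschFit",
    "PersonFit",
    "prob_prefer_own",
    "preference_logit",
    "elementary_symmetric",
    "fit_rasch_cml",
    "fit_persons_ml",
    "person_se",
    "conditional_loglik",
]


# ---------------------------------------------------------------------------
# Response data container
# ---------------------------------------------------------------------------

@dataclass
class ResponseMatrix:
    """Binary person x item preference responses.

    Y[p, i] = 1 when person p prefers their own health over comparator
    item i.  Complete data only: any entry other than 0/1 is rejected.
    """

    persons: list[str]
    items: list[str]
    Y: np.ndarray

    def __post_init__(self):
        self.persons = [str(p) for p in self.persons]
        self.items = [str(i) for i in self.items]
        Y = np.asarray(self.Y)
        if Y.ndim != 2 or Y.shape != (len(self.persons), len(self.items)):
            raise ValidationError(
                f"Y shape {Y.shape} does not match {len(self.persons)} persons "
                f"x {len(self.items)} items"
            )
        if np.isnan(Y.astype(float)).any():
            raise ValidationError(
                "missing responses are not supported; incomplete designs can "
                "bias CML estimates when missingness is informative"
            )
        if not np.isin(Y, (0, 1)).all():
            bad = Y[~np.isin(Y, (0, 1))].ravel()[0]
            raise ValidationError(f"responses must be 0/1, found {bad!r}")
        if len(set(self.persons)) != len(self.persons):
            raise ValidationError("person ids must be unique")
        if len(set(self.items)) != len(self.items):
            raise ValidationError("item ids must be unique")
        self.Y = Y.astype(np.int8)

    # -- basic views -------------------------------------------------------
    @property
    def P(self) -> int:
        return self.Y.shape[0]

    @property
    def I(self) -> int:
        return self.Y.shape[1]

    @property
    def raw_scores(self) -> np.ndarray:
        """R_p = number of comparators judged worse than the own state."""
        return self.Y.sum(axis=1)

    @property
    def item_totals(self) -> np.ndarray:
        return self.Y.sum(axis=0)

    def extreme_person_mask(self) -> np.ndarray:
        r = self.raw_scores
        return (r == 0) | (r == self.I)

    def constant_item_mask(self) -> np.ndarray:
        t = self.item_totals
        return (t == 0) | (t == self.P)

    def subset(self, person_mask=None, item_mask=None) -> "ResponseMatrix":
        pm = np.ones(self.P, bool) if person_mask is None else np.asarray(person_mask, bool)
        im = np.ones(self.I, bool) if item_mask is None else np.asarray(item_mask, bool)
        return ResponseMatrix(
            persons=[p for p, keep in zip(self.persons, pm) if keep],
            items=[i for i, keep in zip(self.items, im) if keep],
            Y=self.Y[np.ix_(pm, im)],
        )

    def fingerprint(self) -> str:
        h = hashlib.sha256()
        h.update("\x1f".join(self.persons).encode())
        h.update(b"\x1e")
        h.update("\x1f".join(self.items).encode())
        h.update(b"\x1e")
        h.update(np.ascontiguousarray(self.Y, dtype=np.uint8).tobytes())
        return h.hexdigest()

    # -- CSV dialect: first column person id, remaining headers item ids ----
    @classmethod
    def from_csv(cls, path: str | Path) -> "ResponseMatrix":
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        if df.shape[1] < 2:
            raise ValidationError("response CSV needs a person column and >= 1 item column")
        persons = df.iloc[:, 0].tolist()
        items = list(df.columns[1:])
        cells = df.iloc[:, 1:].to_numpy()
        Y = np.empty(cells.shape, dtype=np.int8)
        for (p, i), val in np.ndenumerate(cells):
            if val == "0":
                Y[p, i] = 0
            elif val == "1":
                Y[p, i] = 1
            else:
                raise ValidationError(
                    f"cell ({persons[p]!r}, {items[i]!r}) must be 0 or 1, got {val!r}"
                )
        return cls(persons=persons, items=items, Y=Y)

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.Y, columns=self.items)
        df.insert(0, "person", self.persons)
        df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Model probabilities
# ---------------------------------------------------------------------------

def preference_logit(theta, beta):
    """Logit of the own-state preference probability: eta = theta - beta."""
    return np.asarray(theta, float) - np.asarray(beta, float)


def prob_prefer_own(theta, beta):
    """P(person with value theta prefers own state over comparator beta).

    Overflow-safe logistic of theta - beta; +/-infinity map to the 1/0
    limits.  At theta == beta the probability is exactly one half: equal
    quality means a fifty-fifty choice.
    """
    theta = np.asarray(theta, float)
    beta = np.asarray(beta, float)
    with np.errstate(invalid="ignore"):
        eta = theta - beta
    # inf - inf (both latent values at the same infinite limit) is resolved
    # in favor of the person side: theta = +inf always prefers own.
    bad = np.isnan(eta) & (np.isinf(theta) | np.isinf(beta))
    if np.any(bad):
        tb = np.broadcast_to(theta, np.shape(eta))
        eta = np.where(bad, np.where(np.isposinf(tb), np.inf, -np.inf), eta)
    out = expit(eta)
    return float(out) if np.ndim(out) == 0 else out


# ---------------------------------------------------------------------------
# Elementary symmetric functions (log-space summation recursion)
# ---------------------------------------------------------------------------

def _log_esf(log_eps: np.ndarray) -> np.ndarray:
    """log gamma_r for r = 0..I via the stable summation recursion."""
    I = log_eps.shape[0]
    lg = np.full(I + 1, -np.inf)
    lg[0] = 0.0
    for le in log_eps:
        lg[1:] = np.logaddexp(lg[1:], le + lg[:-1])
    return lg


def _log_esf_loo(log_eps: np.ndarray) -> np.ndarray:
    """Leave-one-out table: out[i, r] = log gamma_r of eps without item i."""
    I = log_eps.shape[0]
    out = np.full((I, I), -np.inf)
    for i in range(I):
        out[i, :] = _log_esf(np.delete(log_eps, i))[:I]
    return out


def _log_esf_loo2(log_eps: np.ndarray) -> np.ndarray:
    """Leave-two-out table: out[i, l, r] = log gamma_r without items i and l."""
    I = log_eps.shape[0]
    out = np.full((I, I, max(I - 1, 1)), -np.inf)
    for i in range(I):
        for l in range(i + 1, I):
            lg = _log_esf(np.delete(log_eps, [i, l]))
            out[i, l, :] = lg
            out[l, i, :] = lg
    return out


def elementary_symmetric(eps, r: int):
    """Elementary symmetric function gamma_r of positive weights eps.

    gamma_r is the sum over all size-r subsets of products of the eps_i;
    it normalizes the conditional likelihood of a response pattern given a
    raw score of r.  Returns ``(gamma_r, loo)`` where ``loo[i]`` is the
    leave-one-out value gamma_{r-1}^{(i)} (over all items except i),
    needed for the conditional item probabilities
    P(Y_i = 1 | R = r) = eps_i * gamma_{r-1}^{(i)} / gamma_r.
    """
    eps = np.asarray(eps, float)
    I = eps.shape[0]
    if np.any(eps <= 0) or not np.all(np.isfinite(eps)):
        raise ValidationError("eps must be positive finite reals")
    if not 0 <= r <= I:
        raise ValidationError(f"order r={r} out of range 0..{I}")
    log_eps = np.log(eps)
    lg = _log_esf(log_eps)
    loo = _log_esf_loo(log_eps)
    gamma_r = float(np.exp(lg[r]))
    if r == 0:
        loo_vals = np.zeros(I)  # gamma_{-1} convention: no size-(-1) subsets
    else:
        loo_vals = np.exp(loo[:, r - 1])
    return gamma_r, loo_vals


def _cond_item_probs(log_eps, lg, loo, r: int) -> np.ndarray:
    """pi_i(r) = P(Y_i = 1 | R = r) for one raw score r."""
    I = log_eps.shape[0]
    if r == 0:
        return np.zeros(I)
    if r == I:
        return np.ones(I)
    return np.exp(log_eps + loo[:, r - 1] - lg[r])


# ---------------------------------------------------------------------------
# Conditioning (existence of CML estimates)
# ---------------------------------------------------------------------------

def _conditioning_witness(Y: np.ndarray):
    """None if well conditioned, else a violating bipartition of item indices.

    Directed item graph: edge i -> j iff some person responded 1 on i and
    0 on j.  The partition condition holds for every bipartition iff the
    graph is strongly connected.  A returned witness (A, B) has no person
    with a 1 in A and a 0 in B.
    """
    Y = np.asarray(Y)
    I = Y.shape[1]
    if I < 2:
        return None
    E = (Y.T.astype(np.int64) @ (1 - Y).astype(np.int64)) > 0
    np.fill_diagonal(E, False)
    n_comp, labels = connected_components(csr_matrix(E), directed=True, connection="strong")
    if n_comp == 1:
        return None
    # find a sink component (no outgoing edges to other components)
    for c in range(n_comp):
        in_c = labels == c
        if not E[np.ix_(in_c, ~in_c)].any():
            A = np.where(in_c)[0].tolist()
            B = np.where(~in_c)[0].tolist()
            return A, B
    return None  # pragma: no cover - a finite DAG always has a sink


# ---------------------------------------------------------------------------
# CML Newton-Raphson core (shared by the holistic and attribute models)
# ---------------------------------------------------------------------------

def _cml_derivs(b: np.ndarray, s: np.ndarray, r_vals: np.ndarray, m_r: np.ndarray,
                need_hessian: bool = True):
    """Conditional log-likelihood, gradient and (negative) Hessian in beta.

    b       item values (length I)
    s       observed item margins sum_p y_ip over retained persons
    r_vals  distinct raw scores present (all strictly between 0 and I)
    m_r     person counts per distinct raw score
    Returns (logCL, score, H) with score_i = d logCL / d b_i and
    H = -Hessian = sum over persons of the conditional covariance of Y | R.
    """
    I = b.shape[0]
    log_eps = -b
    lg = _log_esf(log_eps)
    loo = _log_esf_loo(log_eps)
    logcl = -float(s @ b) - float(m_r @ lg[r_vals])
    expected = np.zeros(I)
    H = np.zeros((I, I)) if need_hessian else None
    loo2 = _log_esf_loo2(log_eps) if need_hessian and I >= 2 else None
    for r, m in zip(r_vals, m_r):
        pi = _cond_item_probs(log_eps, lg, loo, int(r))
        expected += m * pi
        if need_hessian:
            if r >= 2 and I >= 2:
                pi2 = np.exp(log_eps[:, None] + log_eps[None, :]
                             + loo2[:, :, int(r) - 2] - lg[int(r)])
            else:
                pi2 = np.zeros((I, I))
            np.fill_diagonal(pi2, pi)
            H += m * (pi2 - np.outer(pi, pi))
    score = -s + expected
    return logcl, score, H


def _newton_cml(Y: np.ndarray, W: np.ndarray | None = None, tol: float = 1e-8,
                max_iter: int = 100):
    """Maximize the conditional log-likelihood by damped Newton-Raphson.

    With ``W`` None the free parameters are the item values anchored at
    b_0 = 0 (re-anchored by the caller); otherwise the item values are
    constrained to b = W @ x and the gradient/information are chain-ruled
    through W.  Returns (x, logcl, H_free, iterations, converged) where
    H_free is the information matrix of the free parameters at the
    optimum.
    """
    Y = np.asarray(Y)
    P, I = Y.shape
    r_all = Y.sum(axis=1)
    if np.any((r_all == 0) | (r_all == I)):
        raise ValidationError("extreme-score persons must be removed before CML")
    s = Y.sum(axis=0).astype(float)
    r_vals, m_r = np.unique(r_all, return_counts=True)

    if W is None:
        K = I - 1
        to_beta = lambda x: np.concatenate(([0.0], x))
        reduce_g = lambda g: g[1:]
        reduce_H = lambda H: H[1:, 1:]
    else:
        W = np.asarray(W, float)
        if W.shape[0] != I:
            raise ValidationError(f"design has {W.shape[0]} rows for {I} items")
        K = W.shape[1]
        to_beta = lambda x: W @ x
        reduce_g = lambda g: W.T @ g
        reduce_H = lambda H: W.T @ H @ W

    x = np.zeros(K)
    logcl, score, H = _cml_derivs(to_beta(x), s, r_vals, m_r)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        g = reduce_g(score)
        if np.max(np.abs(g)) < tol:
            converged = True
            break
        Hf = reduce_H(H)
        try:
            step = np.linalg.solve(Hf, g)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError(
                "singular conditional information matrix; the model is not "
                "identified on these data", last_iterate=to_beta(x)
            ) from exc
        # damped ascent: halve until the conditional likelihood improves;
        # the tolerance is relative to |logCL| so that final Newton steps
        # whose true gain sits below floating-point resolution still pass
        t = 1.0
        ll_slack = 1e-12 * max(1.0, abs(logcl))
        for _ in range(50):
            x_new = x + t * step
            logcl_new, score_new, H_new = _cml_derivs(to_beta(x_new), s, r_vals, m_r)
            if np.isfinite(logcl_new) and logcl_new >= logcl - ll_slack:
                break
            t /= 2.0
        else:
            raise ConvergenceError(
                "line search failed: conditional likelihood not improving",
                last_iterate=to_beta(x),
            )
        x, logcl, score, H = x_new, logcl_new, score_new, H_new
    if not converged:
        g = reduce_g(score)
        if np.max(np.abs(g)) < tol:
            converged = True
        else:
            raise ConvergenceError(
                f"Newton-Raphson did not converge in {max_iter} iterations "
                f"(max |score| = {np.max(np.abs(g)):.3g})",
                last_iterate=to_beta(x),
            )
    return x, logcl, reduce_H(H), it, converged


# ---------------------------------------------------------------------------
# Fits
# ---------------------------------------------------------------------------

@dataclass
class RaschFit:
    """Item values from the holistic model with CML standard errors.

    ``anchor`` records the identification: ``"sum_zero"`` (default,
    sum of beta = 0) or ``("item", code)`` fixing one item at 0.  Only
    differences of item values are meaningful across anchorings.
    """

    items: list[str]
    beta: np.ndarray
    se_beta: np.ndarray
    cov_beta: np.ndarray
    log_cl: float
    n_persons_used: int
    dropped_persons: list[str] = field(default_factory=list)
    dropped_items: list[str] = field(default_factory=list)
    iterations: int = 0
    converged: bool = False
    anchor: object = "sum_zero"
    data_fingerprint: str = ""

    @property
    def beta_series(self) -> pd.Series:
        return pd.Series(self.beta, index=self.items, name="beta")

    def reanchor(self, reference_item: str) -> "RaschFit":
        """Shift the scale so that *reference_item* has value 0."""
        if reference_item not in self.items:
            raise ValidationError(f"unknown reference item {reference_item!r}")
        k = self.items.index(reference_item)
        I = len(self.items)
        B = np.eye(I)
        B[:, k] -= 1.0
        cov = B @ self.cov_beta @ B.T
        return RaschFit(
            items=list(self.items),
            beta=self.beta - self.beta[k],
            se_beta=np.sqrt(np.clip(np.diag(cov), 0.0, None)),
            cov_beta=cov,
            log_cl=self.log_cl,
            n_persons_used=self.n_persons_used,
            dropped_persons=list(self.dropped_persons),
            dropped_items=list(self.dropped_items),
            iterations=self.iterations,
            converged=self.converged,
            anchor=("item", reference_item),
            data_fingerprint=self.data_fingerprint,
        )


@dataclass
class PersonFit:
    """Maximum likelihood person values given fixed item values."""

    raw_scores: np.ndarray
    theta: np.ndarray
    se_theta: np.ndarray
    extreme: np.ndarray
    persons: list[str] | None = None


def _reduce_for_cml(data: ResponseMatrix, drop_constant_items: bool = True):
    """Iteratively drop extreme-score persons and constant item columns."""
    cur = data
    dropped_persons: list[str] = []
    dropped_items: list[str] = []
    while True:
        pm = ~cur.extreme_person_mask()
        if not pm.all():
            dropped_persons += [p for p, keep in zip(cur.persons, pm) if not keep]
            cur = cur.subset(person_mask=pm)
            continue
        if drop_constant_items:
            im = ~cur.constant_item_mask()
            if not im.all():
                dropped_items += [i for i, keep in zip(cur.items, im) if not keep]
                logger.warning(
                    "dropping constant item columns (no finite CML estimate): %s",
                    [i for i, keep in zip(cur.items, im) if not keep],
                )
                cur = cur.subset(item_mask=im)
                continue
        break
    return cur, dropped_persons, dropped_items


def fit_rasch_cml(
    data: ResponseMatrix,
    anchor: object = "sum_zero",
    tol: float = 1e-8,
    max_iter: int = 100,
) -> RaschFit:
    """CML estimation of item values under the holistic model.

    Persons with extreme raw scores (0 or I) are excluded — they carry no
    conditional information; item columns that are constant over the
    retained persons are excluded with a warning.  The fitted values solve
    the CML estimation equations (observed item margins = expected
    conditional margins) and are centered to sum to zero by default;
    ``anchor=("item", code)`` fixes one item at 0 instead.  Standard
    errors come from the inverse of the conditional information matrix.
    """
    reduced, dropped_p, dropped_i = _reduce_for_cml(data)
    if reduced.I < 2:
        raise ValidationError("need at least 2 informative items for CML")
    witness = _conditioning_witness(reduced.Y)
    if witness is not None:
        A, B = witness
        raise IllConditionedError(
            "response matrix is ill-conditioned: no person responded 1 on "
            f"{[reduced.items[i] for i in A]} and 0 on "
            f"{[reduced.items[i] for i in B]}",
            witness=([reduced.items[i] for i in A], [reduced.items[i] for i in B]),
        )
    x, logcl, H_free, iters, conv = _newton_cml(reduced.Y, None, tol=tol, max_iter=max_iter)
    I = reduced.I
    b = np.concatenate(([0.0], x))
    cov = np.zeros((I, I))
    cov[1:, 1:] = np.linalg.inv(H_free)
    if anchor == "sum_zero":
        A = np.eye(I) - np.full((I, I), 1.0 / I)
        beta = A @ b
        cov = A @ cov @ A.T
        anchor_out: object = "sum_zero"
    else:
        if not (isinstance(anchor, tuple) and len(anchor) == 2 and anchor[0] == "item"):
            raise ValidationError(f"anchor must be 'sum_zero' or ('item', code), got {anchor!r}")
        code = anchor[1]
        if code not in reduced.items:
            raise ValidationError(f"anchor item {code!r} not among fitted items")
        k = reduced.items.index(code)
        B = np.eye(I)
        B[:, k] -= 1.0
        beta = b - b[k]
        cov = B @ cov @ B.T
        anchor_out = ("item", code)
    return RaschFit(
        items=list(reduced.items),
        beta=beta,
        se_beta=np.sqrt(np.clip(np.diag(cov), 0.0, None)),
        cov_beta=cov,
        log_cl=logcl,
        n_persons_used=reduced.P,
        dropped_persons=dropped_p,
        dropped_items=dropped_i,
        iterations=iters,
        converged=conv,
        anchor=anchor_out,
        data_fingerprint=data.fingerprint(),
    )


# ---------------------------------------------------------------------------
# Person estimation (two-step: item values held fixed)
# ---------------------------------------------------------------------------

def person_se(theta, beta: np.ndarray):
    """SE of the ML person estimate: 1 / sqrt(sum_i P_i(theta)(1-P_i(theta))).

    Because x(1-x) <= 0.25, the SE can never fall below
    sqrt(1 / (0.25 * I)); precision is best when comparators sit close to
    the person's own value.
    """
    theta = np.asarray(theta, float)
    beta = np.asarray(beta, float)
    p = expit(theta[..., None] - beta)
    info = np.sum(p * (1.0 - p), axis=-1)
    with np.errstate(divide="ignore"):
        return 1.0 / np.sqrt(info)


def fit_persons_ml(raw_scores, beta, persons: list[str] | None = None) -> PersonFit:
    """ML estimation of person values from raw scores, item values fixed.

    For 0 < R < I, theta_hat solves R = sum_i pi_i(theta) (a strictly
    increasing function of theta, so the root is unique).  Extreme scores
    R in {0, I} have no finite ML estimate: the point value is -inf/+inf
    with ``extreme`` flagged and an infinite SE.
    """
    beta = np.asarray(beta, float)
    I = beta.shape[0]
    r = np.asarray(raw_scores)
    if np.any((r < 0) | (r > I)):
        raise ValidationError(f"raw scores must lie in 0..{I}")
    theta = np.empty(r.shape, float)
    se = np.empty(r.shape, float)
    extreme = (r == 0) | (r == I)
    lo = float(beta.min() - 50.0)
    hi = float(beta.max() + 50.0)
    roots: dict[int, float] = {}
    for rv in np.unique(r[~extreme]):
        f = lambda t: float(np.sum(expit(t - beta)) - rv)
        roots[int(rv)] = brentq(f, lo, hi, xtol=1e-12)
    for idx, rv in np.ndenumerate(r):
        if rv == 0:
            theta[idx], se[idx] = -np.inf, np.inf
        elif rv == I:
            theta[idx], se[idx] = np.inf, np.inf
        else:
            t = roots[int(rv)]
            theta[idx] = t
            se[idx] = float(person_se(np.array(t), beta))
    return PersonFit(raw_scores=r, theta=theta, se_theta=se, extreme=extreme,
                     persons=persons)


# ---------------------------------------------------------------------------
# Conditional log-likelihood at arbitrary item values
# ---------------------------------------------------------------------------

def conditional_loglik(data: ResponseMatrix, beta) -> float:
    """Conditional log-likelihood sum_p [ -sum_i y_ip beta_i - log gamma_{r_p} ].

    Persons with extreme raw scores contribute zero (their conditional
    likelihood is identically 1).  Invariant to adding a constant to all
    item values.
    """
    beta = np.asarray(beta, float)
    if beta.shape[0] != data.I:
        raise ValidationError(f"{beta.shape[0]} item values for {data.I} items")
    r = data.raw_scores
    keep = (r > 0) & (r < data.I)
    if not keep.any():
        return 0.0
    Y = data.Y[keep]
    lg = _log_esf(-beta)
    return float(-(Y @ beta).sum() - lg[r[keep]].sum())
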