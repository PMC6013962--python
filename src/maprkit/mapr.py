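"""Attribute-parameterized preference model (LLTM).

Instead of one free value per comparator state, the value of state
x_i = (x_i1, ..., x_iJ) is a linear function of dummy-coded attribute
levels,

    beta_i = f(x_i) = sum_j sum_{k>=2} alpha_{jk} d_{jk}(x_ij),

with alpha_{j1} = 0 for every attribute, which anchors perfect health
(1, ..., 1) at value 0.  The alpha are estimated by the same conditional
likelihood as the holistic model, with gradient and information
chain-ruled through the design matrix.  Because the model is nested in
the holistic one, its conditional log-likelihood can never exceed the
holistic fit on the same data, and a saturated design reproduces the
holistic estimates exactly.

The fitted weights predict a value for every state the classification
system can describe — including states never shown to any respondent —
and hence predicted preferences (own value vs comparator value), whose
agreement with observed responses is summarized by Cohen's kappa.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.inter_rater import cohens_kappa

from .classification import (
    ClassificationSystem,
    DesignMatrix,
    HealthState,
    build_design_matrix,
    encode_state,
    parse_state,
)
from .exceptions import ValidationError
from .rasch import ResponseMatrix, _conditioning_witness, _newton_cml, _reduce_for_cml

logger = logging.getLogger("maprkit")

__all__ = [
    "AttributeWeights",
    "LLTMFit",
    "KappaResult",
    "STUDY_WEIGHTS_EQ5D3L",
    "beta_from_alpha",
    "fit_mapr_cml",
    "predict_preferences",
    "kappa_agreement",
    "check_monotonicity",
]


@dataclass(frozen=True)
class AttributeWeights:
    """Main-effect attribute-level weights alpha_{jk} on one system.

    ``values[attribute][level]`` holds alpha for levels k >= 2; level 1 of
    every attribute is the reference with weight 0.
    """

    system: ClassificationSystem
    values: dict

    def __post_init__(self):
        names = set(self.system.attribute_names)
        for attr, by_level in self.values.items():
            if attr not in names:
                raise ValidationError(f"unknown attribute {attr!r} in weights")
            n = self.system.attributes[self.system.attribute_names.index(attr)].n_levels
            for k in by_level:
                if not 2 <= int(k) <= n:
                    raise ValidationError(
                        f"weight level {k} out of range 2..{n} for attribute {attr!r}"
                    )

    def weight(self, attribute: str, level: int) -> float:
        if level == 1:
            return 0.0
        try:
            return float(self.values[attribute][level])
        except KeyError as exc:
            raise ValidationError(
                f"no weight for attribute {attribute!r} level {level}"
            ) from exc

    def as_vector(self, columns) -> np.ndarray:
        """Weights aligned to main-effect design columns 'attr:k'."""
        out = []
        for col in columns:
            attr, k = col.rsplit(":", 1)
            out.append(self.weight(attr, int(k)))
        return np.array(out)

    def as_table(self) -> pd.DataFrame:
        rows = []
        for attr in self.system.attributes:
            for k in range(1, attr.n_levels + 1):
                rows.append({"attribute": attr.name, "level": k,
                             "alpha": self.weight(attr.name, k)})
        return pd.DataFrame(rows)


def _study_weights() -> "AttributeWeights":
    from .classification import EQ5D3L

    # Main-effect level weights estimated in the instrument's empirical
    # valuation study (n = 163 patients, 17 comparator states); used as
    # the default generating truth for simulations.
    return AttributeWeights(
        system=EQ5D3L,
        values={
            "mobility": {2: -0.274, 3: -2.909},
            "self_care": {2: -1.626, 3: -3.554},
            "usual_activities": {2: -0.548, 3: -1.479},
            "pain_discomfort": {2: -0.752, 3: -3.548},
            "anxiety_depression": {2: -1.527, 3: -3.352},
        },
    )


STUDY_WEIGHTS_EQ5D3L = _study_weights()


def beta_from_alpha(state, alpha: AttributeWeights) -> float:
    """Value of a health state under main-effect weights: sum_j alpha_{j, x_j}.

    ``state`` may be a HealthState or a code string on the weights'
    system.  The all-reference state has value 0 exactly.
    """
    if isinstance(state, str):
        state = parse_state(state, alpha.system)
    if len(state.levels) != alpha.system.J:
        raise ValidationError(
            f"state {state.code!r} has {len(state.levels)} attributes; "
            f"system has {alpha.system.J}"
        )
    return float(
        sum(alpha.weight(a.name, lev)
            for a, lev in zip(alpha.system.attributes, state.levels))
    )


@dataclass
class LLTMFit:
    """Fitted attribute-level weights with the conditional likelihood.

    The scale is anchored by alpha_{j1} = 0: the implied value of the
    all-reference state is 0 exactly.  ``implied_beta`` holds the values
    W @ alpha of the fitted item set; ``implied_value`` evaluates any
    state of the system.
    """

    system: ClassificationSystem
    columns: tuple[str, ...]
    alpha: np.ndarray
    se_alpha: np.ndarray
    cov_alpha: np.ndarray
    log_cl: float
    items: list[str]
    states: tuple[HealthState, ...]
    implied_beta: np.ndarray
    n_persons_used: int
    dropped_persons: list[str] = field(default_factory=list)
    iterations: int = 0
    converged: bool = False
    interactions: tuple[tuple[str, str], ...] = ()
    data_fingerprint: str = ""

    @property
    def n_params(self) -> int:
        return len(self.columns)

    @property
    def alpha_series(self) -> pd.Series:
        return pd.Series(self.alpha, index=list(self.columns), name="alpha")

    def weights(self) -> AttributeWeights:
        """Main-effect weights view (only valid without interaction terms)."""
        if self.interactions:
            raise ValidationError(
                "fit has interaction terms; use implied_value() instead"
            )
        vals: dict = {}
        for col, a in zip(self.columns, self.alpha):
            attr, k = col.rsplit(":", 1)
            vals.setdefault(attr, {})[int(k)] = float(a)
        return AttributeWeights(system=self.system, values=vals)

    def implied_value(self, state) -> float:
        """Implied value f(x) of any state of the system."""
        if isinstance(state, str):
            state = parse_state(state, self.system)
        dm = build_design_matrix([state], self.system,
                                 interactions=list(self.interactions) or None)
        return float(dm.matrix[0] @ self.alpha)

    def value_table(self) -> pd.DataFrame:
        """Implied values of every describable state, in code order."""
        from .classification import enumerate_states

        states = enumerate_states(self.system)
        dm = build_design_matrix(states, self.system,
                                 interactions=list(self.interactions) or None)
        return pd.DataFrame({
            "state": [encode_state(s, self.system) for s in states],
            "value": dm.matrix @ self.alpha,
        })


def fit_mapr_cml(
    data: ResponseMatrix,
    system: ClassificationSystem,
    states: list[HealthState] | None = None,
    interactions=None,
    design_matrix: DesignMatrix | None = None,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> LLTMFit:
    """CML estimation of attribute-level weights.

    Item codes of ``data`` are parsed as states of ``system`` unless
    ``states`` is given.  ``design_matrix`` overrides the dummy design
    entirely (used e.g. for a saturated design).  Persons with extreme raw
    scores are excluded; items with constant response columns are kept —
    under the attribute parameterization they still inform the weights
    through the conditional likelihood, and excluding them could leave
    rare severe levels unidentified.

    Raises a ``ValidationError`` when the design is rank deficient or the
    constant vector lies in its column span (either breaks
    identification).
    """
    interactions = tuple(interactions) if interactions else ()
    if design_matrix is None:
        if states is None:
            states = [parse_state(c, system) for c in data.items]
        if len(states) != data.I:
            raise ValidationError(f"{len(states)} states for {data.I} items")
        dm = build_design_matrix(states, system, interactions=list(interactions) or None)
    else:
        dm = design_matrix
        states = list(dm.states)
        if dm.matrix.shape[0] != data.I:
            raise ValidationError(
                f"design has {dm.matrix.shape[0]} rows for {data.I} items"
            )
    W = dm.matrix
    K = W.shape[1]
    if K >= data.I:
        raise ValidationError(
            f"{K} free parameters for {data.I} items; the attribute model "
            "must have fewer parameters than comparator states"
        )
    if np.linalg.matrix_rank(W) < K:
        raise ValidationError(
            f"design matrix is rank deficient (rank {np.linalg.matrix_rank(W)} "
            f"< {K}); collinear columns among {list(dm.columns)}"
        )
    if np.linalg.matrix_rank(np.column_stack([W, np.ones(W.shape[0])])) <= K:
        raise ValidationError(
            "constant vector lies in the design column span; the scale "
            "origin is not identified (include a state at the reference "
            "level of at least one attribute)"
        )

    reduced, dropped_p, _ = _reduce_for_cml(data, drop_constant_items=False)
    if reduced.P < 1:
        raise ValidationError("no informative persons left after extreme-score removal")
    if _conditioning_witness(reduced.Y) is not None:
        logger.info(
            "response matrix is ill-conditioned in the holistic sense; "
            "weights remain estimable only through the attribute structure"
        )
    x, logcl, H, iters, conv = _newton_cml(reduced.Y, W=W, tol=tol, max_iter=max_iter)
    cov = np.linalg.inv(H)
    return LLTMFit(
        system=system,
        columns=dm.columns,
        alpha=x,
        se_alpha=np.sqrt(np.clip(np.diag(cov), 0.0, None)),
        cov_alpha=cov,
        log_cl=logcl,
        items=list(reduced.items),
        states=tuple(states),
        implied_beta=W @ x,
        n_persons_used=reduced.P,
        dropped_persons=dropped_p,
        iterations=iters,
        converged=conv,
        interactions=interactions,
        data_fingerprint=data.fingerprint(),
    )


def predict_preferences(own_value, comparator_values):
    """Deterministic preference predictions: 1 iff own value >= comparator.

    Ties predict 1 ("prefer own"): at equality the model probability is
    exactly one half and a documented deterministic convention is needed
    for agreement statistics.
    """
    own = np.asarray(own_value, float)
    comp = np.asarray(comparator_values, float)
    return (own >= comp).astype(int)


@dataclass(frozen=True)
class KappaResult:
    kappa: float
    se: float
    ci_low: float
    ci_high: float
    percent_agreement: float
    label: str
    table: np.ndarray

    @property
    def defined(self) -> bool:
        return np.isfinite(self.kappa)


def _kappa_label(kappa: float) -> str:
    if not np.isfinite(kappa):
        return "undefined"
    if kappa > 0.75:
        return "excellent"
    if kappa >= 0.4:
        return "fair to good"
    return "poor"


def kappa_agreement(observed, predicted) -> KappaResult:
    """Cohen's kappa between observed and predicted binary preferences.

    Chance-corrected agreement (p_o - p_e) / (1 - p_e) from the 2x2
    table, with a large-sample 95% CI.  Benchmarks: above 0.75 is
    excellent, 0.4-0.75 fair to good.  When expected agreement p_e = 1
    (both vectors constant and equal classes) kappa is undefined and
    reported as NaN.
    """
    obs = np.asarray(observed).ravel()
    pred = np.asarray(predicted).ravel()
    if obs.shape != pred.shape or obs.size < 1:
        raise ValidationError("observed/predicted must be equal-length, non-empty")
    if not (np.isin(obs, (0, 1)).all() and np.isin(pred, (0, 1)).all()):
        raise ValidationError("observed/predicted must be binary 0/1")
    table = np.zeros((2, 2))
    for o in (0, 1):
        for p in (0, 1):
            table[o, p] = np.sum((obs == o) & (pred == p))
    n = table.sum()
    p_o = float(np.trace(table) / n)
    p_e = float((table.sum(1) * table.sum(0)).sum() / n**2)
    if p_e >= 1.0 - 1e-15:
        return KappaResult(np.nan, np.nan, np.nan, np.nan, p_o,
                           "undefined", table)
    res = cohens_kappa(table, return_results=True)
    return KappaResult(
        kappa=float(res.kappa),
        se=float(res.std_kappa),
        ci_low=float(res.kappa_low),
        ci_high=float(res.kappa_upp),
        percent_agreement=p_o,
        label=_kappa_label(float(res.kappa)),
        table=table,
    )


def check_monotonicity(weights: AttributeWeights) -> dict:
    """Report whether weights respect the within-attribute level ordering.

    Under the negative-value convention (worse levels more negative) a
    monotone attribute has alpha_{j2} >= alpha_{j3} >= ...; monotone
    weights for every attribute imply that implied state values respect
    the partial order of the classification system.  The ordering is
    reported, not enforced during estimation.
    """
    out = {}
    for attr in weights.system.attributes:
        if attr.name not in weights.values:
            continue
        seq = [weights.weight(attr.name, k) for k in range(1, attr.n_levels + 1)]
        out[attr.name] = all(a >= b for a, b in zip(seq, seq[1:]))
    return out
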