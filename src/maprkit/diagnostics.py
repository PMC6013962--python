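"""Model checking for preference-response fits.

Covers Andersen's likelihood-ratio test of item-parameter invariance
across person score groups (the standard Rasch fit test), the nested
likelihood-ratio test of the attribute-parameterized model against the
holistic one, the well-conditioning check that governs existence of CML
estimates, the Guttman scalogram, and person-item map data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import chi2

from .exceptions import IllConditionedError, ValidationError
from .mapr import LLTMFit
from .rasch import (
    PersonFit,
    RaschFit,
    ResponseMatrix,
    _conditioning_witness,
    _newton_cml,
)

logger = logging.getLogger("maprkit")

__all__ = [
    "TestResult",
    "ScalogramReport",
    "PersonItemMap",
    "andersen_test",
    "lr_test_nested",
    "check_well_conditioned",
    "guttman_scalogram",
    "person_item_map",
]


@dataclass(frozen=True)
class TestResult:
    """A chi-square test: statistic (clipped at 0), df, upper-tail p."""

    statistic: float
    df: int
    p_value: float
    description: str = ""
    groups: tuple = ()

    def to_dict(self) -> dict:
        return {
            "statistic": self.statistic,
            "df": self.df,
            "p_value": self.p_value,
            "description": self.description,
            "groups": list(self.groups),
        }


def _fit_group_logcl(Y: np.ndarray, tol: float = 1e-8) -> float:
    """Maximized conditional log-likelihood of one person group.

    Extreme rows contribute exactly zero to the conditional likelihood
    and are removed before optimization.
    """
    I = Y.shape[1]
    r = Y.sum(axis=1)
    Y = Y[(r > 0) & (r < I)]
    if Y.shape[0] == 0:
        return 0.0
    witness = _conditioning_witness(Y)
    if witness is not None:
        raise IllConditionedError(
            "a score group is ill-conditioned; consider removing items "
            f"(violating bipartition by column index: {witness})",
            witness=witness,
        )
    _, logcl, _, _, _ = _newton_cml(Y, tol=tol)
    return logcl


def andersen_test(data: ResponseMatrix, split="median", tol: float = 1e-8) -> TestResult:
    """Andersen's likelihood-ratio test of item-value invariance.

    Persons are partitioned into score groups (default: raw score at or
    below the median vs above); item values are estimated by CML within
    each group and pooled.  Under a fitting model the statistic
    2 [ sum_g logCL_g(beta_g) - logCL(beta_pooled) ] is approximately
    chi-square with (G - 1)(I - 1) degrees of freedom.

    Items with a constant response column within any group are dropped
    from every group (logged), mirroring the usual practice of removing
    states judged worse by essentially everyone.
    """
    reduced = data.subset(person_mask=~data.extreme_person_mask())
    if reduced.P < 2:
        raise ValidationError("not enough informative persons for the Andersen test")
    r = reduced.raw_scores
    if isinstance(split, str) and split == "median":
        med = np.median(r)
        labels = (r > med).astype(int)
    elif callable(split):
        labels = np.asarray(split(reduced), int)
    else:
        labels = np.asarray(split, int)
        if labels.shape[0] != reduced.P:
            raise ValidationError(
                f"{labels.shape[0]} group labels for {reduced.P} retained persons"
            )
    group_ids = np.unique(labels)
    if group_ids.size < 2:
        raise ValidationError("the split rule produced fewer than 2 groups")

    # shared item set: drop items constant within any group, iterating
    # because removals can create new extreme persons within groups
    item_keep = np.ones(reduced.I, bool)
    while True:
        changed = False
        for g in group_ids:
            Yg = reduced.Y[labels == g][:, item_keep]
            rg = Yg.sum(axis=1)
            Yg = Yg[(rg > 0) & (rg < Yg.shape[1])]
            if Yg.shape[0] == 0:
                continue
            tot = Yg.sum(axis=0)
            const = (tot == 0) | (tot == Yg.shape[0])
            if const.any():
                idx = np.where(item_keep)[0][const]
                logger.warning(
                    "Andersen test: dropping items constant within a group: %s",
                    [reduced.items[i] for i in idx],
                )
                item_keep[idx] = False
                changed = True
        if not changed:
            break
    I_shared = int(item_keep.sum())
    if I_shared < 2:
        raise ValidationError(
            "fewer than 2 items remain after within-group constancy removal"
        )
    Y = reduced.Y[:, item_keep]
    logcl_pooled = _fit_group_logcl(Y, tol)
    logcl_groups = [_fit_group_logcl(Y[labels == g], tol) for g in group_ids]
    stat = max(0.0, 2.0 * (sum(logcl_groups) - logcl_pooled))
    G = group_ids.size
    df = (G - 1) * (I_shared - 1)
    return TestResult(
        statistic=stat,
        df=df,
        p_value=float(chi2.sf(stat, df)),
        description="Andersen LR test of item-value invariance across score groups",
        groups=tuple(
            {"label": int(g), "n_persons": int(np.sum(labels == g))} for g in group_ids
        ),
    )


def lr_test_nested(rasch: RaschFit, mapr: LLTMFit) -> TestResult:
    """Likelihood-ratio test of the attribute model against the holistic one.

    Both fits must come from the identical response matrix and item set.
    The deviance 2 (logCL_holistic - logCL_attribute) is approximately
    chi-square with df = (I - 1) - (number of free weights).  A
    significant result indicates the comparator states are not
    sufficiently described by the dummy-coded attributes.
    """
    if rasch.data_fingerprint != mapr.data_fingerprint:
        raise ValidationError(
            "fits come from different response matrices (fingerprint mismatch)"
        )
    if list(rasch.items) != list(mapr.items):
        raise ValidationError(
            "fits use different item sets; refit on the shared items "
            f"({sorted(set(rasch.items) ^ set(mapr.items))} differ)"
        )
    I = len(rasch.items)
    df = (I - 1) - mapr.n_params
    if df < 0:
        raise ValidationError(
            f"negative df {df}: the attribute model is not a proper "
            "restriction of the holistic model"
        )
    stat = max(0.0, 2.0 * (rasch.log_cl - mapr.log_cl))
    # df = 0: saturated design, an exact reparameterization; the deviance
    # is numerical noise and there is nothing to test.
    p = float(chi2.sf(stat, df)) if df > 0 else 1.0
    return TestResult(
        statistic=stat,
        df=df,
        p_value=p,
        description="nested LR test: holistic vs attribute-parameterized model",
        groups=("holistic", "attribute"),
    )


def check_well_conditioned(data: ResponseMatrix):
    """Check the partition condition for existence of CML estimates.

    Returns ``(flag, witness)``: ``flag`` is True when in every
    bipartition of the items into two non-empty subsets some person
    responded 1 on an item of the first part and 0 on an item of the
    second.  The check runs on the matrix after extreme-score person
    removal (extreme persons never contribute discordant pairs).  When
    ill-conditioned, ``witness`` is a violating bipartition as two lists
    of item ids.
    """
    reduced = data.subset(person_mask=~data.extreme_person_mask())
    if reduced.I < 2:
        return True, None
    w = _conditioning_witness(reduced.Y)
    if w is None:
        return True, None
    A, B = w
    return False, ([reduced.items[i] for i in A], [reduced.items[i] for i in B])


@dataclass(frozen=True)
class ScalogramReport:
    """Guttman scalogram of the sorted response matrix.

    Persons are sorted by raw score (descending, stable), items by column
    total (descending, stable).  A perfect Guttman pattern has every row
    equal to a staircase: ones on the r easiest items, zeros after.
    Misfit cells are cells disagreeing with the staircase implied by the
    row's raw score; the count is zero iff the sorted matrix is a perfect
    Guttman pattern.
    """

    person_order: tuple
    item_order: tuple
    sorted_matrix: np.ndarray
    misfit_count: int
    misfit_cells: tuple = field(default_factory=tuple)


def guttman_scalogram(data: ResponseMatrix) -> ScalogramReport:
    """Sort rows/columns and count deviations from the Guttman staircase.

    Ties in raw scores / column totals are broken by person / item id, so
    the report is canonical: permuting the input rows or columns never
    changes the misfit count.
    """
    r = data.raw_scores
    t = data.item_totals
    p_order = np.lexsort((np.array(data.persons), -r))
    i_order = np.lexsort((np.array(data.items), -t))
    S = data.Y[np.ix_(p_order, i_order)]
    ideal = (np.arange(data.I)[None, :] < r[p_order][:, None]).astype(np.int8)
    mis = S != ideal
    cells = tuple(
        (data.persons[p_order[p]], data.items[i_order[i]])
        for p, i in zip(*np.nonzero(mis))
    )
    return ScalogramReport(
        person_order=tuple(data.persons[i] for i in p_order),
        item_order=tuple(data.items[i] for i in i_order),
        sorted_matrix=S,
        misfit_count=int(mis.sum()),
        misfit_cells=cells,
    )


@dataclass(frozen=True)
class PersonItemMap:
    """Joint display data: person-value histogram and item locations.

    ``fraction_own_better`` is the share of (person, item) pairs with the
    estimated person value above the item value — in the motivating study
    more than half of the judged comparators fell below the patients.
    """

    bin_edges: np.ndarray
    theta_counts: np.ndarray
    beta: np.ndarray
    items: tuple
    fraction_own_better: float


def person_item_map(rasch: RaschFit, persons: PersonFit, n_bins: int = 20) -> PersonItemMap:
    """Histogram of person values next to item locations on the shared scale."""
    theta = np.asarray(persons.theta, float)
    beta = np.asarray(rasch.beta, float)
    finite_theta = theta[np.isfinite(theta)]
    pool = np.concatenate([finite_theta, beta]) if finite_theta.size else beta
    lo, hi = float(pool.min()), float(pool.max())
    if hi <= lo:
        hi = lo + 1.0
    edges = np.linspace(lo, hi, n_bins + 1)
    counts, _ = np.histogram(finite_theta, bins=edges)
    frac = float(np.mean(theta[:, None] > beta[None, :]))
    return PersonItemMap(
        bin_edges=edges,
        theta_counts=counts,
        beta=beta,
        items=tuple(rasch.items),
        fraction_own_better=frac,
    )
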