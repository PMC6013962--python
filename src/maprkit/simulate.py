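"""Seeded synthetic preference-response data.

Generates binary better/worse responses under the holistic and
attribute-parameterized models so that every estimator and diagnostic can
be exercised without external data.  Local independence holds by
construction: given a person's latent value, responses are independent
Bernoulli draws with probability expit(theta_p - beta_i).

Seeding uses one master seed with per-person substreams
(``numpy.random.SeedSequence.spawn``): growing the number of persons
never reshuffles the responses of earlier persons, and an identical
scenario yields a byte-identical response matrix.

The default scenario mirrors the motivating empirical study: 163
patients judging the same 17 EQ-5D-3L comparator states, person values
derived from a sampled own-state classification whose marginals follow
the study population, with item values given by the study's main-effect
weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml
from scipy.special import expit

from .classification import ClassificationSystem, EQ5D3L, HealthState
from .exceptions import ValidationError
from .mapr import AttributeWeights, STUDY_WEIGHTS_EQ5D3L, beta_from_alpha
from .rasch import ResponseMatrix, person_se

__all__ = [
    "PersonDistribution",
    "SimulationScenario",
    "SimulationResult",
    "AdaptiveResult",
    "STUDY_ITEM_CODES",
    "STUDY_OWN_LEVEL_PROBS",
    "study_scenario",
    "simulate_responses",
    "simulate_adaptive",
    "select_adaptive_comparators",
    "rankings_to_binary",
]

# The 17 fixed EQ-5D-3L comparator states of the motivating study design.
STUDY_ITEM_CODES: tuple[str, ...] = (
    "11111", "11211", "21111", "11121", "11112", "12111", "11113", "11131",
    "13311", "22222", "32211", "11133", "32313", "33323", "23232", "32223",
    "33333",
)

# Marginal level probabilities of patients' own classifications,
# approximating the study population's distribution per attribute.
STUDY_OWN_LEVEL_PROBS: dict[str, tuple[float, ...]] = {
    "mobility": (0.58, 0.38, 0.04),
    "self_care": (0.82, 0.16, 0.02),
    "usual_activities": (0.47, 0.48, 0.05),
    "pain_discomfort": (0.40, 0.55, 0.05),
    "anxiety_depression": (0.73, 0.24, 0.03),
}


@dataclass(frozen=True)
class PersonDistribution:
    """Distribution of latent person values theta.

    Families
    --------
    ``"normal"``  : theta ~ Normal(loc, scale).
    ``"skewed"``  : negated log-normal, theta = loc - scale * LogNormal(0, sdlog);
                    patient health-value distributions are typically not
                    normal, with a long tail of severely ill persons.
    ``"own-state"``: theta = f(own classification) + Normal(0, noise_sd)
                    where the own state is sampled per attribute from
                    ``level_probs`` and valued with ``weights``.
    """

    family: str = "normal"
    loc: float = 0.0
    scale: float = 1.0
    sdlog: float = 0.6
    noise_sd: float = 0.5
    level_probs: dict | None = None
    weights: AttributeWeights | None = None

    def sample(self, rng: np.random.Generator):
        """Draw one (theta, own_state_or_None) pair."""
        if self.family == "normal":
            return float(rng.normal(self.loc, self.scale)), None
        if self.family == "skewed":
            return float(self.loc - self.scale * rng.lognormal(0.0, self.sdlog)), None
        if self.family == "own-state":
            if self.weights is None:
                raise ValidationError("own-state sampling needs attribute weights")
            probs = self.level_probs or {}
            levels = []
            for attr in self.weights.system.attributes:
                p = probs.get(attr.name)
                if p is None:
                    p = np.full(attr.n_levels, 1.0 / attr.n_levels)
                p = np.asarray(p, float)
                if p.shape[0] != attr.n_levels:
                    raise ValidationError(
                        f"{p.shape[0]} level probabilities for attribute "
                        f"{attr.name!r} with {attr.n_levels} levels"
                    )
                levels.append(int(rng.choice(attr.n_levels, p=p / p.sum())) + 1)
            own = HealthState(tuple(levels))
            theta = beta_from_alpha(own, self.weights)
            if self.noise_sd > 0:
                theta += float(rng.normal(0.0, self.noise_sd))
            return theta, own
        raise ValidationError(f"unknown person distribution family {self.family!r}")


@dataclass(frozen=True)
class SimulationScenario:
    """Full parameter set of one simulated preference study."""

    item_codes: tuple[str, ...]
    item_values: tuple[float, ...]
    n_persons: int
    seed: int
    persons: PersonDistribution = field(default_factory=PersonDistribution)
    system: ClassificationSystem | None = None

    def __post_init__(self):
        if self.n_persons < 1:
            raise ValidationError("n_persons must be >= 1")
        if len(self.item_codes) != len(self.item_values):
            raise ValidationError("item_codes and item_values lengths differ")
        if not all(np.isfinite(v) for v in self.item_values):
            raise ValidationError("item values must be finite")

    def to_dict(self) -> dict:
        d = {
            "item_codes": list(self.item_codes),
            "item_values": [float(v) for v in self.item_values],
            "n_persons": self.n_persons,
            "seed": self.seed,
            "persons": {
                "family": self.persons.family,
                "loc": self.persons.loc,
                "scale": self.persons.scale,
                "sdlog": self.persons.sdlog,
                "noise_sd": self.persons.noise_sd,
            },
        }
        if self.system is not None:
            d["system"] = self.system.to_dict()
        return d

    @classmethod
    def from_config(cls, path) -> "SimulationScenario":
        with open(path, "r", encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
        system = (ClassificationSystem.from_dict(doc["system"])
                  if "system" in doc else None)
        pd_doc = doc.get("persons", {})
        persons = PersonDistribution(
            family=pd_doc.get("family", "normal"),
            loc=float(pd_doc.get("loc", 0.0)),
            scale=float(pd_doc.get("scale", 1.0)),
            sdlog=float(pd_doc.get("sdlog", 0.6)),
            noise_sd=float(pd_doc.get("noise_sd", 0.5)),
        )
        return cls(
            item_codes=tuple(str(c) for c in doc["item_codes"]),
            item_values=tuple(float(v) for v in doc["item_values"]),
            n_persons=int(doc["n_persons"]),
            seed=int(doc["seed"]),
            persons=persons,
            system=system,
        )


def study_scenario(seed: int, n_persons: int = 163) -> SimulationScenario:
    """The default scenario: the empirical study's design and population.

    163 patients, the 17 fixed EQ-5D-3L comparator states, item values
    implied by the study's main-effect weights, and person values derived
    from sampled own-state classifications (study marginals) with a small
    holistic noise term.
    """
    weights = STUDY_WEIGHTS_EQ5D3L
    values = tuple(beta_from_alpha(c, weights) for c in STUDY_ITEM_CODES)
    return SimulationScenario(
        item_codes=STUDY_ITEM_CODES,
        item_values=values,
        n_persons=n_persons,
        seed=seed,
        persons=PersonDistribution(
            family="own-state",
            noise_sd=0.5,
            level_probs=STUDY_OWN_LEVEL_PROBS,
            weights=weights,
        ),
        system=EQ5D3L,
    )


@dataclass
class SimulationResult:
    """Simulated data plus the generating truth for recovery tests."""

    data: ResponseMatrix
    theta: np.ndarray
    beta: np.ndarray
    scenario: SimulationScenario
    own_states: list[HealthState | None] | None = None

    def truth_dict(self) -> dict:
        return {
            "theta": [float(t) for t in self.theta],
            "beta": {c: float(b) for c, b in zip(self.data.items, self.beta)},
            "own_states": (
                [s.code if s is not None else None for s in self.own_states]
                if self.own_states is not None else None
            ),
            "scenario": self.scenario.to_dict(),
        }


def simulate_responses(scenario: SimulationScenario) -> SimulationResult:
    """Draw a response matrix under the model: Y_ip ~ Bernoulli(pi_ip)."""
    beta = np.asarray(scenario.item_values, float)
    I = beta.shape[0]
    P = scenario.n_persons
    children = np.random.SeedSequence(scenario.seed).spawn(P)
    theta = np.empty(P)
    Y = np.empty((P, I), dtype=np.int8)
    own_states: list[HealthState | None] = []
    for p in range(P):
        rng = np.random.default_rng(children[p])
        t, own = scenario.persons.sample(rng)
        theta[p] = t
        own_states.append(own)
        Y[p] = (rng.random(I) < expit(t - beta)).astype(np.int8)
    data = ResponseMatrix(
        persons=[f"p{p + 1:04d}" for p in range(P)],
        items=list(scenario.item_codes),
        Y=Y,
    )
    has_own = any(s is not None for s in own_states)
    return SimulationResult(
        data=data, theta=theta, beta=beta, scenario=scenario,
        own_states=own_states if has_own else None,
    )


# ---------------------------------------------------------------------------
# Adaptive comparator selection
# ---------------------------------------------------------------------------

def select_adaptive_comparators(
    own_value: float,
    bank_codes,
    bank_values,
    k: int,
    exclude: str | None = None,
    balance: bool = False,
):
    """Pick the k bank states whose values are closest to the own value.

    Person values are estimated most precisely from comparators near the
    own state (the per-item information x(1-x) peaks at probability 0.5),
    so the adaptive rule is value proximity on the latent scale.  Ties
    are broken by bank order.  ``exclude`` removes the person's own state
    code from the candidates.  With ``balance=True`` states are picked by
    alternating between the nearest remaining state above and below the
    own value, falling back to one side when the other is exhausted.
    """
    codes = list(bank_codes)
    values = np.asarray(bank_values, float)
    if len(codes) != values.shape[0]:
        raise ValidationError("bank codes and values lengths differ")
    if exclude is not None:
        keep = [i for i, c in enumerate(codes) if c != exclude]
        codes = [codes[i] for i in keep]
        values = values[keep]
    if len(codes) == 0:
        raise ValidationError("empty comparator bank")
    if not 1 <= k <= len(codes):
        raise ValidationError(f"k={k} out of range 1..{len(codes)}")
    order = np.argsort(np.abs(values - own_value), kind="stable")
    if not balance:
        chosen = sorted(order[:k])
        return [codes[i] for i in chosen]
    above = [i for i in order if values[i] >= own_value]
    below = [i for i in order if values[i] < own_value]
    chosen_idx: list[int] = []
    take_above = True
    while len(chosen_idx) < k:
        pool = above if (take_above and above) or not below else below
        chosen_idx.append(pool.pop(0))
        take_above = not take_above
    return [codes[i] for i in sorted(chosen_idx)]


@dataclass
class AdaptiveResult:
    """Per-person individualized comparator sets and responses."""

    persons: list[str]
    own_codes: list[str]
    theta: np.ndarray
    comparators: list[list[str]]
    values: list[np.ndarray]
    responses: list[np.ndarray]

    def mean_person_se(self) -> float:
        """Mean SE of the person estimate evaluated at the true value."""
        ses = [float(person_se(np.array(t), v))
               for t, v in zip(self.theta, self.values)]
        return float(np.mean(ses))


def simulate_adaptive(
    scenario: SimulationScenario,
    bank_codes,
    bank_values,
    k: int,
    balance: bool = False,
) -> AdaptiveResult:
    """Simulate the adaptive design: individualized comparator subsets.

    Each person's own classification fixes their value (own-state person
    family); the k bank states nearest that value are shown and judged.
    """
    if scenario.persons.family != "own-state":
        raise ValidationError("adaptive simulation requires the own-state person family")
    bank_codes = list(bank_codes)
    bank_values = np.asarray(bank_values, float)
    children = np.random.SeedSequence(scenario.seed).spawn(scenario.n_persons)
    persons, own_codes, comparators, values, responses = [], [], [], [], []
    theta = np.empty(scenario.n_persons)
    lookup = dict(zip(bank_codes, bank_values))
    for p in range(scenario.n_persons):
        rng = np.random.default_rng(children[p])
        t, own = scenario.persons.sample(rng)
        theta[p] = t
        own_code = own.code
        comps = select_adaptive_comparators(
            t, bank_codes, bank_values, k, exclude=own_code, balance=balance
        )
        vals = np.array([lookup[c] for c in comps])
        y = (rng.random(k) < expit(t - vals)).astype(np.int8)
        persons.append(f"p{p + 1:04d}")
        own_codes.append(own_code)
        comparators.append(comps)
        values.append(vals)
        responses.append(y)
    return AdaptiveResult(
        persons=persons, own_codes=own_codes, theta=theta,
        comparators=comparators, values=values, responses=responses,
    )


# ---------------------------------------------------------------------------
# Ranking-task conversion
# ---------------------------------------------------------------------------

def rankings_to_binary(
    rankings: dict,
    own_label: str = "own",
    exclude: tuple = ("dead",),
) -> ResponseMatrix:
    """Convert per-person best-to-worst rankings into binary responses.

    In the card-sorting protocol each person ranks the same deck of
    comparator states plus a card for their own description (and possibly
    'dead').  Y_ip = 1 iff comparator i is ranked *below* (worse than)
    the own card.  The own card and excluded labels become no columns.
    Every ranking must be a permutation of the same label set containing
    the own label exactly once; duplicates or missing labels are
    rejected per person.
    """
    if not rankings:
        raise ValidationError("no rankings given")
    persons = list(rankings.keys())
    item_set: list[str] | None = None
    rows = []
    for person in persons:
        ranking = [str(x) for x in rankings[person]]
        if len(set(ranking)) != len(ranking):
            dup = [x for x in ranking if ranking.count(x) > 1][0]
            raise ValidationError(f"person {person!r}: duplicate entry {dup!r}")
        if ranking.count(own_label) != 1:
            raise ValidationError(
                f"person {person!r}: ranking must contain {own_label!r} exactly once"
            )
        items = [x for x in ranking if x != own_label and x not in exclude]
        if item_set is None:
            item_set = sorted(items)
        elif sorted(items) != item_set:
            raise ValidationError(
                f"person {person!r}: ranked items differ from the common deck"
            )
        own_pos = ranking.index(own_label)
        below = {x for x in ranking[own_pos + 1:]}
        rows.append([1 if item in below else 0 for item in item_set])
    return ResponseMatrix(persons=persons, items=list(item_set), Y=np.array(rows))
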