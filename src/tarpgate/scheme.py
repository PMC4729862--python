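"""Kinetic schemes for AMPA receptor gating with and without TARPs.

The receptor is modelled as a continuous-time Markov chain over a small set
of conformational states. The basal ("TARP-silent") layer is a single
binding-site scheme:

    R  <-> AR   (glutamate binding, k+ * c / k-)
    AR <-> AR*  (channel gating, beta / alpha)
    AR <-> AD1  (entry to shallow desensitization, d1+ / d1-)
    AD1 <-> AD2 (deepening of desensitization, d2+ / d2-)
    R  <-> RD   (resting desensitization, d0+ / d0-)
    R  <-> AD1  (binding straight into the desensitized branch, k+ * c
                 forward, concerted unbinding-and-recovery kd- backward)

The TARP model duplicates every state into a second layer in which the
auxiliary subunit is in its active conformation: channel opening is boosted
(beta_s replaces beta), the deep desensitized exit differs (d2* replaces
d2), and the open state conducts 2.5-fold more. The two layers are coupled
by TARP activation steps: s+/s- on every closed pair and s*+/s*- on the
open pair. Enforcing microscopic reversibility then *requires* s*+ >> s+,
i.e. channel opening promotes the TARP into its active state; this is the
thermodynamic engine behind superactivation.

State names follow the lower/upper-case convention for the TARP layer:
``ARs*`` is the open channel with the TARP basal, ``ARS*`` with the TARP
active.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np

__all__ = [
    "RATE_NAMES",
    "DEFAULT_RATES",
    "MUTANT_TRIALS",
    "WILD_TYPE_TRIAL",
    "VARIANTS",
    "RateSet",
    "StateDef",
    "TransitionDef",
    "KineticScheme",
    "MutantTrial",
    "build_scheme",
    "apply_mutant_trial",
    "enforce_microscopic_reversibility",
    "cycle_imbalance",
    "generator_matrix",
    "equilibrium_occupancy",
]

# ---------------------------------------------------------------------------
# Rate constants
# ---------------------------------------------------------------------------

#: Canonical rate names. All units s^-1 except the association rate "k+"
#: (M^-1 s^-1); ligand-dependent transitions multiply "k+" by concentration.
RATE_NAMES = (
    "s*+", "s*-", "s+", "s-",
    "beta", "alpha", "beta_s",
    "d2*+", "d2*-", "d2+", "d2-",
    "d1+", "d1-", "d0+", "d0-",
    "k+", "k-", "kd-",
)

#: Published baseline rates, before microscopic-reversibility adjustment.
DEFAULT_RATES = {
    "s*+": 15.0,
    "s*-": 3.0,
    "s+": 0.07,
    "s-": 1.0,
    "beta": 8_000.0,
    "alpha": 3_000.0,
    "beta_s": 500_000.0,
    "d2*+": 120.0,
    "d2*-": 2.0,
    "d2+": 120.0,
    "d2-": 5.0,
    "d1+": 300.0,
    "d1-": 25.0,
    "d0+": 1.0,
    "d0-": 3.0,
    "k+": 5_000_000.0,
    "k-": 40_000.0,
    "kd-": 2_500.0,
}

#: Cyclothiazide blocks desensitization: the named entry rates collapse to
#: 0.1 s^-1. The basal-layer deep entry d2+ is left untouched by default
#: (exposed as an option in :func:`build_scheme`).
CTZ_RATE = 0.1
CTZ_TARGETS = ("d0+", "d1+", "d2*+")

#: Kainate is a weak partial agonist: reduced opening rates, faster shutting,
#: weaker desensitization, and a five-fold smaller basal open conductance.
KAINATE_OVERRIDES = {
    "beta": 1_600.0,
    "alpha": 30_000.0,
    "d2+": 12.0,
    "d2-": 30.0,
    "d2*-": 12.0,
    "d1-": 300.0,
    "beta_s": 100_000.0,
}
KAINATE_BASAL_CONDUCTANCE = 0.08

#: Mutant series: (d2-, d2*-) per trial. Trial 7 is the wild-type proxy.
MUTANT_TRIALS = {
    0: (0.16, 0.18),
    1: (0.32, 0.29),
    2: (0.63, 0.47),
    3: (1.26, 0.76),
    4: (2.51, 1.23),
    5: (5.0, 2.0),
    6: (10.0, 3.24),
    7: (19.9, 5.26),
    8: (39.7, 8.53),
}
WILD_TYPE_TRIAL = 7

VARIANTS = (
    "noTARP", "TARP", "TARP+CTZ", "kainate",
    "alt-binding", "alt-equal-conductance",
)

#: Normalized open-state conductances.
BASAL_OPEN_CONDUCTANCE = 0.4
ACTIVE_OPEN_CONDUCTANCE = 1.0

#: Factor by which the alternate "slow unbinding" model scales glutamate
#: dissociation (k- and kd-) in the TARP-active layer. The published
#: rejection of this geometry quotes no number; 10x is the package default.
ALT_BINDING_UNBIND_FACTOR = 0.1

#: Association into the desensitized branch (R -> AD1) is far slower than
#: into the resting cleft: entering a desensitized conformation
#: concertedly with binding carries a large kinetic penalty. The
#: reversibility adjustment scales the paired unbinding rate (kd-) to
#: match, so the branch's equilibrium is unaffected.
DESENSE_BINDING_PENALTY = 0.025

#: Macroscopic deactivation rates (s^-1) of reference receptors spanning
#: the mutant series: a slow-recovering double mutant, wild-type GluA2 and
#: a fast-recovering mutant, indexed by the deep-desensitized exit rate
#: d2-. The mutant series' channel-shutting compensation is anchored to
#: these (log-log interpolation): mutations that stabilize desensitization
#: also slow deactivation.
DEACTIVATION_ANCHORS = ((0.16, 270.0), (19.9, 1000.0), (39.7, 3100.0))


def mutant_alpha(d2_minus: float, rates: "RateSet | None" = None) -> float:
    """Basal channel-shutting rate for a mutant with the given deep exit.

    The macroscopic deactivation rate of a bursting channel is the shutting
    rate reduced by the re-opening probability, k_deact ~ alpha * k- /
    (k- + beta + d1+); inverting that burst correction maps the anchored
    deactivation rates onto shutting rates.
    """
    r = rates if rates is not None else DEFAULT_RATES
    burst = (r["k-"] + r["beta"] + r["d1+"]) / r["k-"]
    (x0, y0), (x1, y1), (x2, y2) = DEACTIVATION_ANCHORS
    x = math.log(d2_minus)
    pts = [(math.log(x0), math.log(y0)), (math.log(x1), math.log(y1)),
           (math.log(x2), math.log(y2))]
    i = 0 if x < pts[1][0] else 1
    (xa, ya), (xb, yb) = pts[i], pts[i + 1]
    return burst * math.exp(ya + (yb - ya) * (x - xa) / (xb - xa))

_BALANCE_RTOL = 1e-10


class RateSet(dict):
    """A complete, strictly positive set of named rate constants."""

    def __init__(self, values=None, **overrides):
        base = dict(DEFAULT_RATES)
        if values is not None:
            base.update(values)
        base.update(overrides)
        unknown = set(base) - set(RATE_NAMES)
        if unknown:
            raise KeyError(f"unknown rate name(s): {sorted(unknown)}")
        missing = set(RATE_NAMES) - set(base)
        if missing:
            raise KeyError(f"missing rate name(s): {sorted(missing)}")
        for name, value in base.items():
            if not (value > 0) or not math.isfinite(value):
                raise ValueError(f"rate {name!r} must be strictly positive, got {value}")
        super().__init__(base)

    def with_overrides(self, **overrides) -> "RateSet":
        return RateSet(self, **overrides)


@dataclass(frozen=True)
class StateDef:
    name: str
    layer: str            # "s" (TARP basal / no TARP) or "S" (TARP active)
    state_class: str      # resting | bound-closed | open | desensitized
    conductance: float = 0.0

    def __post_init__(self):
        if self.conductance > 0 and self.state_class != "open":
            raise ValueError(f"{self.name}: only open states conduct")
        if self.state_class == "open" and self.conductance <= 0:
            raise ValueError(f"{self.name}: open state needs conductance > 0")


@dataclass(frozen=True)
class TransitionDef:
    """A reversible edge. ``ligand`` means the forward rate scales with
    agonist concentration (forward rate name is always ``k+``).

    ``fwd_value``/``bwd_value`` hold edge-local numeric overrides installed
    by the reversibility adjustment; when None the named rate applies.
    """

    source: str
    target: str
    fwd: str
    bwd: str
    ligand: bool = False
    fwd_value: float | None = None
    bwd_value: float | None = None

    def rates(self, rate_set: RateSet) -> tuple[float, float]:
        f = self.fwd_value if self.fwd_value is not None else rate_set[self.fwd]
        b = self.bwd_value if self.bwd_value is not None else rate_set[self.bwd]
        return f, b

    def label(self) -> str:
        return f"{self.fwd}[{self.source}-{self.target}]"


@dataclass(frozen=True)
class MutantTrial:
    trial_id: int
    d2_minus: float
    d2_star_minus: float

    @classmethod
    def from_id(cls, trial_id: int) -> "MutantTrial":
        if trial_id not in MUTANT_TRIALS:
            raise ValueError(f"trial id must be 0-8, got {trial_id}")
        d2m, d2sm = MUTANT_TRIALS[trial_id]
        return cls(trial_id, d2m, d2sm)


@dataclass(frozen=True)
class KineticScheme:
    states: tuple[StateDef, ...]
    transitions: tuple[TransitionDef, ...]
    rates: RateSet
    variant: str
    balanced: bool = False
    trial_id: int | None = None

    # -- basic introspection -------------------------------------------------

    @property
    def state_names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.states)

    @property
    def conductances(self) -> np.ndarray:
        return np.array([s.conductance for s in self.states])

    @property
    def n_states(self) -> int:
        return len(self.states)

    def state_index(self, name: str) -> int:
        return self.state_names.index(name)

    def open_states(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.states if s.state_class == "open")

    def unliganded_active_states(self) -> tuple[str, ...]:
        """Unliganded states with the TARP in its active layer — the pool
        that is superactive at rest, primed for high-conductance opening."""
        return tuple(
            s.name for s in self.states
            if s.layer == "S" and not s.name.startswith("A")
        )

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.state_names)
        for t in self.transitions:
            g.add_edge(t.source, t.target, transition=t)
        return g

    def validate(self) -> None:
        names = self.state_names
        if len(set(names)) != len(names):
            raise ValueError("duplicate state names")
        for t in self.transitions:
            if t.source not in names or t.target not in names:
                raise ValueError(f"transition references unknown state: {t}")
            if t.ligand and t.fwd != "k+":
                raise ValueError("ligand-dependent transitions must use 'k+' forward")
        if not nx.is_connected(self.graph()):
            raise ValueError("state graph is not connected")


# ---------------------------------------------------------------------------
# Scheme construction
# ---------------------------------------------------------------------------

def _layer_states(suffix_closed: str, suffix_open: str, layer: str,
                  open_conductance: float) -> list[StateDef]:
    # suffix encodes the TARP layer: "" for the TARP-less model,
    # "s"/"S" for basal/active layers of the TARP model.
    c, o = suffix_closed, suffix_open
    return [
        StateDef(f"R{c}", layer, "resting"),
        StateDef(f"AR{c}", layer, "bound-closed"),
        StateDef(f"AR{o}*", layer, "open", open_conductance),
        StateDef(f"AD{c}1", layer, "desensitized"),
        StateDef(f"AD{c}2", layer, "desensitized"),
        StateDef(f"AD{c}0", layer, "desensitized"),
    ]


def _layer_transitions(c: str, o: str, beta_name: str, d2f: str, d2b: str,
                       k_assoc_desense: float,
                       alpha_value: float | None = None) -> list[TransitionDef]:
    return [
        TransitionDef(f"R{c}", f"AR{c}", "k+", "k-", ligand=True),
        TransitionDef(f"AR{c}", f"AR{o}*", beta_name, "alpha",
                      bwd_value=alpha_value),
        TransitionDef(f"AR{c}", f"AD{c}1", "d1+", "d1-"),
        TransitionDef(f"AD{c}1", f"AD{c}2", d2f, d2b),
        # Slow shallow desensitization of the bound-closed receptor; a
        # small dead-end pool (the CTZ modification throttles its entry).
        TransitionDef(f"AR{c}", f"AD{c}0", "d0+", "d0-"),
        # Concerted binding into / unbinding out of the desensitized branch:
        # the recovery exit from shallow desensitization at zero glutamate.
        # Association carries the desensitized-conformation penalty.
        TransitionDef(f"R{c}", f"AD{c}1", "k+", "kd-", ligand=True,
                      fwd_value=k_assoc_desense),
    ]


def build_scheme(variant: str, rates: RateSet | None = None, *,
                 trial: int | None = None,
                 ctz_block_deep_basal: bool = False) -> KineticScheme:
    """Construct one of the model variants.

    Parameters
    ----------
    variant
        One of ``noTARP``, ``TARP``, ``TARP+CTZ``, ``kainate``,
        ``alt-binding``, ``alt-equal-conductance``.
    rates
        Baseline rate constants; defaults to the published set.
    trial
        Optional mutant-trial id (0-8). Substitutes the trial's deep
        desensitized exit rates (d2-, d2*-) and applies the series'
        channel-shutting compensation: the basal-layer shutting rate
        becomes :func:`mutant_alpha` of the trial's d2-, while the
        superactive complex's shutting is a TARP-complex property pinned
        to the wild-type proxy's value. Enforcing microscopic
        reversibility afterwards turns this into a trial-dependent TARP
        activation rate s*+ — the stronger the mutant gates, the less
        opening promotes the TARP's active state.
    ctz_block_deep_basal
        If True, the CTZ variant additionally sets the basal deep entry
        ``d2+`` to 0.1 s^-1 (the published CTZ list names only d0+, d1+ and
        d2*+; off by default).
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; expected one of {VARIANTS}")
    rates = RateSet(rates) if rates is not None else RateSet()

    alpha_basal = alpha_active = None
    if trial is not None:
        if trial not in MUTANT_TRIALS:
            raise ValueError(f"trial id must be 0-8, got {trial}")
        d2m, d2sm = MUTANT_TRIALS[trial]
        rates = rates.with_overrides(**{"d2-": d2m, "d2*-": d2sm})
        alpha_basal = mutant_alpha(d2m, rates)
        alpha_active = mutant_alpha(MUTANT_TRIALS[WILD_TYPE_TRIAL][0], rates)

    basal_g = BASAL_OPEN_CONDUCTANCE
    active_g = ACTIVE_OPEN_CONDUCTANCE

    if variant == "kainate":
        rates = rates.with_overrides(**KAINATE_OVERRIDES)
        basal_g = KAINATE_BASAL_CONDUCTANCE
    elif variant == "TARP+CTZ":
        overrides = {name: CTZ_RATE for name in CTZ_TARGETS}
        if ctz_block_deep_basal:
            overrides["d2+"] = CTZ_RATE
        rates = rates.with_overrides(**overrides)
    elif variant == "alt-equal-conductance":
        active_g = basal_g

    k_ad = DESENSE_BINDING_PENALTY * rates["k+"]

    if variant == "noTARP":
        states = _layer_states("", "", "s", basal_g)
        transitions = _layer_transitions("", "", "beta", "d2+", "d2-", k_ad,
                                         alpha_basal)
        scheme = KineticScheme(tuple(states), tuple(transitions), rates,
                               variant, trial_id=trial)
        scheme.validate()
        return scheme

    # Two-layer TARP models.
    if variant == "alt-binding":
        # The rejected "slow unbinding" geometry: the TARP-active layer has
        # the same opening rate as the basal layer but 10x slower glutamate
        # dissociation (k- and kd-); conductances stay 0.4 / 1.0.
        active_beta = "beta"
    else:
        active_beta = "beta_s"

    states = (_layer_states("s", "s", "s", basal_g)
              + _layer_states("S", "S", "S", active_g))
    transitions = (_layer_transitions("s", "s", "beta", "d2+", "d2-", k_ad,
                                      alpha_basal)
                   + _layer_transitions("S", "S", active_beta,
                                        "d2*+", "d2*-", k_ad, alpha_active))

    if variant == "alt-binding":
        # Slow glutamate dissociation from the TARP-active open/bound pool.
        # The desensitized-branch unbinding (kd-) in that layer is left to
        # the reversibility adjustment, which slows it by the same factor.
        slowed = []
        for t in transitions:
            if t.source.endswith("S") and t.ligand and t.bwd == "k-":
                f, b = t.rates(rates)
                slowed.append(replace(t, bwd_value=b * ALT_BINDING_UNBIND_FACTOR))
            else:
                slowed.append(t)
        transitions = slowed

    inter = [
        TransitionDef("Rs", "RS", "s+", "s-"),
        TransitionDef("ARs", "ARS", "s+", "s-"),
        TransitionDef("ARs*", "ARS*", "s*+", "s*-"),
        TransitionDef("ADs1", "ADS1", "s+", "s-"),
        TransitionDef("ADs2", "ADS2", "s+", "s-"),
        TransitionDef("ADs0", "ADS0", "s+", "s-"),
    ]
    scheme = KineticScheme(tuple(states), tuple(transitions) + tuple(inter),
                           rates, variant, trial_id=trial)
    scheme.validate()
    return scheme


def apply_mutant_trial(scheme: KineticScheme,
                       trial: MutantTrial | int) -> KineticScheme:
    """Substitute the trial's deep-desensitized exit rates (d2-, d2*-).

    Clears the balanced flag: the caller must re-enforce microscopic
    reversibility afterwards.
    """
    if isinstance(trial, int):
        trial = MutantTrial.from_id(trial)
    if trial.trial_id not in MUTANT_TRIALS:
        raise ValueError(f"trial id must be 0-8, got {trial.trial_id}")
    if scheme.variant not in ("noTARP", "TARP"):
        raise ValueError(f"mutant trials apply to noTARP/TARP schemes, "
                         f"not {scheme.variant!r}")
    # Rebuild from scratch: structural edge overrides (including the
    # trial's shutting-rate compensation) are regenerated, stale balancing
    # adjustments are discarded.
    return build_scheme(scheme.variant, scheme.rates, trial=trial.trial_id)


# ---------------------------------------------------------------------------
# Microscopic reversibility
# ---------------------------------------------------------------------------

def default_dependent_rates(scheme: KineticScheme) -> list[str]:
    """Rates adjusted to close the thermodynamic cycles.

    ``s*+`` (TARP activation from the open state) absorbs the open-pair
    cycle, the deepest desensitized pair's inter-layer forward rate absorbs
    the d2/d2* asymmetry, and ``kd-`` closes the binding/desensitization
    cycle present in every layer.
    """
    deps = ["kd-"]
    if scheme.variant != "noTARP":
        deps.append("s*+")
        deps.append("s+[ADs2-ADS2]")
        if scheme.variant == "alt-binding":
            # Slowed unbinding in the active layer unbalances the binding
            # squares; their inter-layer forward rates take up the slack,
            # and the active layer's desensitized unbinding gets its own
            # edge-local solution instead of the shared kd-.
            deps.append("s+[ARs-ARS]")
            deps.append("s+[ADs1-ADS1]")
            deps.append("s+[ADs0-ADS0]")
            deps.append("kd-[RS-ADS1]")
    return deps


def _match_dep(t: TransitionDef, dependent_rates: list[str]) -> str | None:
    """Edge-qualified labels 'name[src-tgt]' claim their edge first; bare
    rate names claim any remaining edge carrying that name."""
    loc = f"{t.source}-{t.target}"
    for d in dependent_rates:
        if "[" in d:
            name, _, where = d.partition("[")
            if where.rstrip("]") == loc and name in (t.fwd, t.bwd):
                return d
    for d in dependent_rates:
        if "[" not in d and d in (t.fwd, t.bwd):
            return d
    return None


def enforce_microscopic_reversibility(
        scheme: KineticScheme,
        dependent_rates: list[str] | None = None,
) -> tuple[KineticScheme, list[tuple[str, float, float]]]:
    """Adjust the dependent rates so every cycle obeys detailed balance.

    Thermodynamic consistency is imposed via state potentials: a spanning
    tree of non-dependent edges defines log-equilibrium potentials
    (ligand edges taken at 1 M reference — every cycle here binds and
    unbinds equally often, so the choice cancels); each remaining edge is
    then either verified or solved for its single dependent rate.

    Returns the balanced scheme and a report of
    ``(rate label, printed value, balanced value)``.

    Raises
    ------
    ValueError
        If a chord cycle contains no dependent rate and is out of balance,
        or if a shared dependent rate is given conflicting solutions.
    """
    scheme.validate()
    if dependent_rates is None:
        dependent_rates = default_dependent_rates(scheme)

    dep_edges: list[TransitionDef] = []
    free_edges: list[TransitionDef] = []
    for t in scheme.transitions:
        if _match_dep(t, dependent_rates) is not None:
            dep_edges.append(t)
        else:
            free_edges.append(t)

    # Spanning tree over non-dependent edges.
    g = nx.Graph()
    g.add_nodes_from(scheme.state_names)
    for t in free_edges:
        g.add_edge(t.source, t.target, transition=t)
    if not nx.is_connected(g):
        raise ValueError("non-dependent edges do not span the state graph; "
                         "cannot anchor equilibrium potentials")
    tree = nx.minimum_spanning_tree(g)
    tree_edges = {frozenset(e): g.edges[e]["transition"] for e in tree.edges}

    # Log-potentials phi with phi proportional to log pi (at c = 1 M).
    phi = {scheme.state_names[0]: 0.0}
    order = list(nx.bfs_edges(tree, scheme.state_names[0]))
    for u, v in order:
        t = tree_edges[frozenset((u, v))]
        f, b = t.rates(scheme.rates)
        step = math.log(f / b)
        if (u, v) == (t.source, t.target):
            phi[v] = phi[u] + step
        else:
            phi[v] = phi[u] - step

    report: list[tuple[str, float, float]] = []
    solved: dict[str, float] = {}
    new_transitions: list[TransitionDef] = []

    # Verify non-dependent chords.
    for t in free_edges:
        f, b = t.rates(scheme.rates)
        imbalance = math.log(f / b) - (phi[t.target] - phi[t.source])
        if abs(imbalance) > 1e-9:
            raise ValueError(
                f"cycle through {t.source}-{t.target} is unbalanced "
                f"(log imbalance {imbalance:.3g}) but contains no dependent rate")

    for t in scheme.transitions:
        if t not in dep_edges:
            new_transitions.append(t)
            continue
        f, b = t.rates(scheme.rates)
        dphi = phi[t.target] - phi[t.source]
        dep = _match_dep(t, dependent_rates)
        name = dep.partition("[")[0]
        if name == t.fwd:
            new_val, old_val, is_fwd = b * math.exp(dphi), f, True
        else:
            new_val, old_val, is_fwd = f * math.exp(-dphi), b, False
        if dep in solved:
            if not math.isclose(solved[dep], new_val, rel_tol=1e-9):
                raise ValueError(
                    f"dependent rate {dep!r} is shared by cycles with "
                    f"conflicting solutions: {solved[dep]:g} vs {new_val:g}")
            new_transitions.append(t)
            continue
        solved[dep] = new_val
        report.append((dep, old_val, new_val))
        if "[" in dep:
            # Edge-local override; the other side's structural override
            # (if any) is kept.
            new_transitions.append(replace(
                t, fwd_value=new_val if is_fwd else t.fwd_value,
                bwd_value=t.bwd_value if is_fwd else new_val))
        else:
            new_transitions.append(t)

    rates = scheme.rates
    named = {n: v for n, v in solved.items() if "[" not in n}
    if named:
        rates = rates.with_overrides(**named)

    balanced = replace(scheme, rates=rates,
                       transitions=tuple(new_transitions), balanced=True)
    residual = max((abs(r - 1.0) for _, r in cycle_imbalance(balanced)),
                   default=0.0)
    if residual > _BALANCE_RTOL:
        raise ValueError(f"balancing failed: residual cycle ratio error {residual:g}")
    return balanced, report


def cycle_imbalance(scheme: KineticScheme) -> list[tuple[list[str], float]]:
    """Forward/backward rate-product ratio around each fundamental cycle.

    Ratios of 1.0 (within tolerance) mean the scheme satisfies the
    Kolmogorov criterion for microscopic reversibility. Ligand steps are
    evaluated at 1 M; every cycle in these schemes carries equal numbers of
    binding steps in each direction, so the ratio is concentration-free.
    """
    g = scheme.graph()
    out = []
    for cycle in nx.cycle_basis(g):
        fwd_prod = 1.0
        bwd_prod = 1.0
        n_lig = 0
        for a, b in zip(cycle, cycle[1:] + cycle[:1]):
            t: TransitionDef = g.edges[a, b]["transition"]
            f, r = t.rates(scheme.rates)
            if (a, b) == (t.source, t.target):
                fwd_prod *= f
                bwd_prod *= r
                n_lig += t.ligand
            else:
                fwd_prod *= r
                bwd_prod *= f
                n_lig -= t.ligand
        if n_lig != 0:
            raise ValueError(f"cycle {cycle} is not concentration-neutral")
        out.append((cycle, fwd_prod / bwd_prod))
    return out


# ---------------------------------------------------------------------------
# Master-equation plumbing
# ---------------------------------------------------------------------------

def generator_matrix(scheme: KineticScheme, concentration: float) -> np.ndarray:
    """Q-matrix at the given agonist concentration (molar).

    Row convention: Q[i, j] is the rate i -> j for i != j; diagonal entries
    make each row sum to zero, so occupancy evolves as dp/dt = p Q.
    """
    if concentration < 0:
        raise ValueError("concentration must be >= 0")
    n = scheme.n_states
    idx = {name: i for i, name in enumerate(scheme.state_names)}
    q = np.zeros((n, n))
    for t in scheme.transitions:
        f, b = t.rates(scheme.rates)
        if t.ligand:
            f = f * concentration
        i, j = idx[t.source], idx[t.target]
        q[i, j] += f
        q[j, i] += b
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    # One corrective pass squeezes the diagonal round-off so rows sum to
    # zero to ~1e-12 even when rates span eight orders of magnitude.
    np.fill_diagonal(q, q.diagonal() - q.sum(axis=1))
    return q


def equilibrium_occupancy(scheme: KineticScheme,
                          concentration: float) -> np.ndarray:
    """Stationary distribution of the generator matrix.

    Computed from the null space of Q^T; entries are clipped of numerical
    dust and normalized to sum exactly to 1.
    """
    q = generator_matrix(scheme, concentration)
    # Solve pi Q = 0, sum(pi) = 1 as an augmented least-squares system.
    n = q.shape[0]
    a = np.vstack([q.T, np.ones(n)])
    rhs = np.zeros(n + 1)
    rhs[-1] = 1.0
    pi, *_ = np.linalg.lstsq(a, rhs, rcond=None)
    if np.min(pi) < -1e-9:
        raise ValueError("stationary distribution solve produced negative mass")
    pi = np.clip(pi, 0.0, None)
    total = pi.sum()
    if not math.isclose(total, 1.0, abs_tol=1e-8):
        raise ValueError("stationary distribution does not normalize")
    return pi / total


def basal_superactive_fraction(scheme: KineticScheme) -> float:
    """Equilibrium occupancy (fraction) of TARP-active unliganded states at
    zero agonist — the pool that is 'primed' for high-conductance opening."""
    pi = equilibrium_occupancy(scheme, 0.0)
    names = scheme.state_names
    sel = [names.index(s) for s in scheme.unliganded_active_states()]
    return float(pi[sel].sum())
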