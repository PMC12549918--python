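"""Synthetic cognitive cohorts and fixture graphs.

Real cognitive batteries of the kind this package analyses live in
access-controlled registries, so the generator here produces cohorts
with the statistical structure the analysis assumes: several diagnostic
groups of unequal size, measures organized into six cognitive domains
with strong within-domain and weaker between-domain correlations,
covariate effects of age, sex and education, skewed and inverted
(higher = worse) raw measures, and per-measure missingness.

The generative model is a latent-factor model: each measure loads on
its domain factor (within-domain correlation) and on one shared global
factor (between-domain correlation), with Gaussian unique noise, and
the implied variance is normalized to 1 before covariate effects are
added. Group topology profiles rescale the loadings — a "smallworld"
group keeps strong within-domain blocks against a weak between-domain
background, while a "degraded" group shrinks both loadings towards the
uniformly weak correlations seen in advanced disease. This is a
stand-in for real cohort structure, not a model of any registry's
marginal distributions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .connectome import BinaryGraph
from .datasets import COVARIATES, GROUP_COL, CognitiveDataset, MeasureMeta


class ConfigError(ValueError):
    pass


DOMAINS = (
    "visuoconstructive",
    "memory",
    "executive",
    "attention",
    "language",
    "orientation",
)

# Covariate simulation: age and education as bounded Gaussians, sex binary.
AGE_MEAN, AGE_SD, AGE_MIN, AGE_MAX = 72.0, 9.0, 45.0, 95.0
EDU_MEAN, EDU_SD, EDU_MIN, EDU_MAX = 16.0, 3.0, 6.0, 24.0

DEFAULT_COVARIATE_EFFECTS = {"age": -0.02, "sex": 0.10, "education": 0.03}

# Per-domain mean offsets (z units, reference group at 0) emulating the
# graded impairment of prodromal and dementia-stage groups.
DEFAULT_MEAN_SHIFTS: dict[str, dict[str, float]] = {
    "hc": {},
    "mci_lb": {
        "visuoconstructive": -0.8,
        "memory": -0.7,
        "executive": -0.3,
        "attention": -0.7,
        "language": -0.3,
        "orientation": -0.4,
    },
    "mci_ad": {
        "visuoconstructive": -0.4,
        "memory": -1.0,
        "executive": -0.3,
        "attention": -0.3,
        "language": -0.4,
        "orientation": -1.2,
    },
    "dlb": {
        "visuoconstructive": -1.8,
        "memory": -1.5,
        "executive": -0.9,
        "attention": -2.1,
        "language": -1.0,
        "orientation": -3.1,
    },
}


@dataclass(frozen=True)
class TopologyProfile:
    """Scales applied to the factor loadings of one group.

    ``smallwold`` keeps the configured loadings (strong within-domain
    blocks, weak between-domain background); ``degraded`` shrinks both,
    yielding uniformly weak correlations; ``intermediate`` sits between.
    """

    label: str
    within_scale: float
    between_scale: float


TOPOLOGY_PROFILES = {
    "smallworld": TopologyProfile("smallworld", 1.0, 1.0),
    "intermediate": TopologyProfile("intermediate", 0.65, 0.65),
    "degraded": TopologyProfile("degraded", 0.30, 0.30),
}


@dataclass(frozen=True)
class GroupSpec:
    """One diagnostic group: name, size, topology, optional planted effects.

    ``domain_within_scale`` multiplies the within-domain loading of the
    named domains for this group only — used to plant a selective
    decorrelation of one cognitive domain.
    """

    name: str
    n: int
    topology: str = "smallworld"
    domain_within_scale: Mapping[str, float] = field(default_factory=dict)

    def profile(self) -> TopologyProfile:
        if self.topology not in TOPOLOGY_PROFILES:
            raise ConfigError(
                f"unknown topology {self.topology!r}; "
                f"choose from {sorted(TOPOLOGY_PROFILES)}"
            )
        return TOPOLOGY_PROFILES[self.topology]


def default_battery(n_per_domain: int = 4) -> dict[str, str]:
    """Measure -> domain map: six domains, ``n_per_domain`` measures each."""
    return {
        f"{dom}_{i}": dom for dom in DOMAINS for i in range(1, n_per_domain + 1)
    }


def _default_groups() -> list[GroupSpec]:
    return [
        GroupSpec("hc", 300, "smallworld"),
        GroupSpec("mci_lb", 88, "intermediate"),
        GroupSpec("mci_ad", 300, "intermediate"),
        GroupSpec("dlb", 104, "degraded"),
    ]


@dataclass
class CohortConfig:
    """Configuration of a synthetic cohort.

    Loadings are on the correlation scale: two measures of the same
    domain have Pearson correlation ``within_loading**2 +
    between_loading**2``; measures of different domains correlate at
    ``between_loading**2`` (before topology scaling).
    """

    groups: list[GroupSpec] = field(default_factory=_default_groups)
    n_measures: int = 24
    domain_map: dict[str, str] = field(default_factory=default_battery)
    within_loading: float = 0.75
    between_loading: float = 0.40
    covariate_effects: dict[str, dict[str, float]] | None = None
    mean_shifts: dict[str, dict[str, float]] | None = None
    missing_rates: dict[str, float] = field(default_factory=dict)
    skewed_measures: Sequence[str] = ("attention_1",)
    inverted_measures: Sequence[str] = ("attention_1", "executive_4")
    free_measures: Sequence[str] = ()
    sex_prevalence: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_measures != len(self.domain_map):
            raise ConfigError(
                f"n_measures={self.n_measures} inconsistent with domain_map "
                f"of size {len(self.domain_map)}"
            )
        for g in self.groups:
            if g.n < 2:
                raise ConfigError(f"group {g.name!r} has n={g.n}; need >= 2")
        for name, val in (
            ("within_loading", self.within_loading),
            ("between_loading", self.between_loading),
        ):
            if not (0 <= val <= 1):
                raise ConfigError(f"{name} must lie in [0, 1]")
        for m, rate in self.missing_rates.items():
            if not (0 <= rate <= 1):
                raise ConfigError(f"missing rate for {m!r} outside [0, 1]")
        unknown = [m for m in self.skewed_measures if m not in self.domain_map]
        unknown += [m for m in self.inverted_measures if m not in self.domain_map]
        unknown += [m for m in self.free_measures if m not in self.domain_map]
        if unknown:
            raise ConfigError(f"measures not in domain_map: {sorted(set(unknown))}")
        if self.covariate_effects is None:
            self.covariate_effects = {
                m: dict(DEFAULT_COVARIATE_EFFECTS) for m in self.domain_map
            }
        if self.mean_shifts is None:
            self.mean_shifts = {
                g.name: dict(DEFAULT_MEAN_SHIFTS.get(g.name, {}))
                for g in self.groups
            }

    @property
    def measures(self) -> list[str]:
        return list(self.domain_map)

    @property
    def domains(self) -> list[str]:
        seen: list[str] = []
        for d in self.domain_map.values():
            if d not in seen:
                seen.append(d)
        return seen


def _loadings(config: CohortConfig, group: GroupSpec) -> tuple[np.ndarray, np.ndarray]:
    prof = group.profile()
    a = np.empty(config.n_measures)
    b = np.empty(config.n_measures)
    for j, m in enumerate(config.measures):
        dom = config.domain_map[m]
        if m in config.free_measures:
            # pure unique noise: barely correlated with the whole battery
            a[j] = 0.0
            b[j] = 0.0
            continue
        scale = group.domain_within_scale.get(dom, 1.0)
        a[j] = config.within_loading * prof.within_scale * scale
        b[j] = config.between_loading * prof.between_scale
    if np.any(a**2 + b**2 > 1 + 1e-12):
        raise ConfigError(
            "within and between loadings imply variance > 1; "
            "reduce within_loading/between_loading"
        )
    return a, b


def generate_cohort(config: CohortConfig) -> CognitiveDataset:
    """Simulate a cohort under the latent-factor model.

    For participant i with domain factors f and global factor g, the
    latent score of measure j in domain d(j) is

        x_ij = a_j * f_{i,d(j)} + b_j * g_i + sqrt(1 - a_j^2 - b_j^2) * e_ij

    (unit variance), shifted by the group/domain mean offset, then
    covariate effects are added on centred covariates. Skewed measures
    are passed through the monotone convex transform exp(x/2) and
    inverted measures are negated (raw orientation higher = worse),
    before per-measure MCAR missingness is injected.
    """
    rng = np.random.default_rng(config.seed)
    measures = config.measures
    domains = config.domains
    dom_idx = {d: k for k, d in enumerate(domains)}
    frames = []
    pid = 0
    for group in config.groups:
        n = group.n
        a, b = _loadings(config, group)
        age = np.clip(rng.normal(AGE_MEAN, AGE_SD, n), AGE_MIN, AGE_MAX)
        sex = (rng.random(n) < config.sex_prevalence).astype(float)
        edu = np.clip(rng.normal(EDU_MEAN, EDU_SD, n), EDU_MIN, EDU_MAX)
        f = rng.normal(size=(n, len(domains)))
        gfac = rng.normal(size=n)
        noise = rng.normal(size=(n, config.n_measures))
        shifts = config.mean_shifts.get(group.name, {})
        x = np.empty((n, config.n_measures))
        for j, m in enumerate(measures):
            dom = config.domain_map[m]
            sd_u = np.sqrt(max(0.0, 1.0 - a[j] ** 2 - b[j] ** 2))
            x[:, j] = (
                a[j] * f[:, dom_idx[dom]]
                + b[j] * gfac
                + sd_u * noise[:, j]
                + shifts.get(dom, 0.0)
            )
            eff = config.covariate_effects.get(m, {})
            x[:, j] += (
                eff.get("age", 0.0) * (age - AGE_MEAN)
                + eff.get("sex", 0.0) * (sex - config.sex_prevalence)
                + eff.get("education", 0.0) * (edu - EDU_MEAN)
            )
        for j, m in enumerate(measures):
            if m in config.skewed_measures:
                x[:, j] = np.exp(x[:, j] / 2.0)
            if m in config.inverted_measures:
                x[:, j] = -x[:, j]
            rate = config.missing_rates.get(m, 0.0)
            if rate > 0:
                mask = rng.random(n) < rate
                x[mask, j] = np.nan
        frame = pd.DataFrame(x, columns=measures)
        frame.insert(0, GROUP_COL, group.name)
        frame.insert(1, "age", age)
        frame.insert(2, "sex", sex)
        frame.insert(3, "education", edu)
        frame.index = pd.Index(range(pid, pid + n), name="participant_id")
        pid += n
        frames.append(frame)
    table = pd.concat(frames)
    meta = {
        m: MeasureMeta(
            domain=config.domain_map[m],
            orientation=(
                "higher_worse" if m in config.inverted_measures else "higher_better"
            ),
            scale_type="continuous",
            instrument="synthetic_battery",
        )
        for m in measures
    }
    return CognitiveDataset(table=table, measure_meta=meta)


# ---------------------------------------------------------------------------
# fixture graphs with known closed-form metric values


def fixture_graph(name: str, n: int) -> BinaryGraph:
    """Deterministic small graphs with documented metric values.

    - ``complete``: K_n (transitivity 1, efficiencies 1)
    - ``star``: hub + n-1 leaves (triangle-free, transitivity 0)
    - ``path``: P_n
    - ``ring``: cycle C_n
    - ``modular``: two cliques bridged by a single edge
    - ``k4_minus_edge``: K4 with one edge removed (transitivity 0.75)
    """
    import networkx as nx

    if n < 2:
        raise ConfigError("fixture graphs need n >= 2")
    if name == "complete":
        g = nx.complete_graph(n)
    elif name == "star":
        g = nx.star_graph(n - 1)
    elif name == "path":
        g = nx.path_graph(n)
    elif name == "ring":
        g = nx.cycle_graph(n)
    elif name == "modular":
        half = n // 2
        g = nx.disjoint_union(nx.complete_graph(n - half), nx.complete_graph(half))
        g.add_edge(0, n - 1)
    elif name == "k4_minus_edge":
        if n != 4:
            raise ConfigError("k4_minus_edge requires n=4")
        g = nx.complete_graph(4)
        g.remove_edge(2, 3)
    else:
        raise ConfigError(f"unknown fixture graph {name!r}")
    adj = nx.to_numpy_array(g, nodelist=range(g.number_of_nodes()), dtype=np.uint8)
    labels = tuple(f"n{i}" for i in range(g.number_of_nodes()))
    return BinaryGraph(adjacency=adj, node_labels=labels)
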