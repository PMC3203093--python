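"""Monte-Carlo generator: latent factor plus position-dependent error.

Each simulated respondent i carries a single latent factor score
``f_i ~ N(0, 1)`` shared by all scale items; each item t adds an
independent error ``e_it ~ N(0, sigma_t^2)`` whose standard deviation
changes *linearly* with questionnaire position, from ``a`` at the first
scale item to ``b`` at the last:

    sigma_t = a + (b - a) * (t - t_f) / (t_l - t_f)
    y_it    = (f_i + e_it) / sqrt(1 + sigma_t^2)

The division standardises every item to unit total variance, so a drift
in the per-item ICC can only come from the changing error share — the
reliability of item t is 1 / (1 + sigma_t^2).  Rising error (a < b)
emulates respondents satisficing as they tire; a > b emulates warming
up; a = b is the constant-reliability null.

Scenario defaults (a, b): the decreasing-reliability scenario uses
(0.5, 2.0), the null (1.0, 1.0) and the increasing one (2.0, 0.5) —
symmetric error ranges around sigma = 1 that make the effect visible at
a few hundred replicates.  Scale items are spread evenly over 50
questionnaire positions and n = 600 respondents are drawn, the reference
study design; everything is configurable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .awareness import _slope_from_values
from .data_io import AnalysisConfig, ResponseMatrix, ScaleSpec
from .errors import ConfigError, DegenerateDataError, UnscreenableError

logger = logging.getLogger("awarescreen")

__all__ = [
    "SimulationScenario",
    "SimulatedDataset",
    "ScenarioSummary",
    "sigma_profile",
    "item_positions",
    "simulate_dataset",
    "run_scenario",
    "plot_scenarios",
    "make_fixture",
    "scale_from_positions",
    "DEFAULT_SCENARIOS",
]


@dataclass(frozen=True)
class SimulationScenario:
    """One simulation condition: error profile, scale length, sample size."""

    a: float
    b: float
    q: int = 13
    total_positions: int = 50
    n: int = 600
    replicates: int = 10000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.a < 0 or self.b < 0:
            raise ConfigError("error SDs a, b must be non-negative")
        if not 3 <= self.q <= self.total_positions:
            raise ConfigError("q must be between 3 and total_positions")
        if self.n < 4:
            raise ConfigError("need at least 4 subjects")
        if self.replicates < 1:
            raise ConfigError("replicates must be >= 1")

    @property
    def positions(self) -> np.ndarray:
        return item_positions(self.q, self.total_positions)


@dataclass(frozen=True)
class SimulatedDataset:
    """One draw from the generative model, with the truth kept alongside."""

    values: np.ndarray       # n x q standardized responses
    positions: np.ndarray    # questionnaire positions of the q items
    true_sigma: np.ndarray   # error SD per item
    factor_scores: np.ndarray  # latent f_i per subject


@dataclass(frozen=True)
class ScenarioSummary:
    """Distribution of the awareness measure across scenario replicates."""

    scenario: SimulationScenario
    slopes: np.ndarray
    failures: int

    @property
    def mean(self) -> float:
        return float(self.slopes.mean())

    @property
    def sd(self) -> float:
        return float(self.slopes.std(ddof=1))

    @property
    def quartiles(self) -> tuple[float, float, float]:
        q1, q2, q3 = np.quantile(self.slopes, [0.25, 0.5, 0.75])
        return float(q1), float(q2), float(q3)

    @property
    def mc_se(self) -> float:
        """Monte-Carlo standard error of the mean slope."""
        return self.sd / np.sqrt(self.slopes.size)

    def to_dict(self) -> dict:
        q1, q2, q3 = self.quartiles
        return {
            "a": self.scenario.a,
            "b": self.scenario.b,
            "q": self.scenario.q,
            "n": self.scenario.n,
            "replicates": self.scenario.replicates,
            "failures": self.failures,
            "mean_slope": self.mean,
            "sd_slope": self.sd,
            "q1": q1,
            "median": q2,
            "q3": q3,
        }


def sigma_profile(a: float, b: float, t, t_f: float, t_l: float):
    """Error SD at position t: linear from a (at t_f) to b (at t_l)."""
    if t_l <= t_f:
        raise ValueError("t_l must exceed t_f")
    t = np.asarray(t, dtype=float)
    if np.any(t < t_f) or np.any(t > t_l):
        raise ValueError("position outside [t_f, t_l]")
    out = a + (b - a) * (t - t_f) / (t_l - t_f)
    return out if out.ndim else float(out)


def item_positions(q: int, total_positions: int) -> np.ndarray:
    """q integer positions spread evenly over 1..total_positions.

    ``t_j = round(1 + (j - 1) * (total - 1) / (q - 1))``; if rounding
    ever collides (possible only when q approaches the total), the later
    item is bumped to the next free position.
    """
    if q > total_positions:
        raise ValueError("q cannot exceed total_positions")
    if q < 2:
        raise ValueError("need at least 2 positions")
    raw = np.rint(1 + np.arange(q) * (total_positions - 1) / (q - 1)).astype(int)
    for j in range(1, q):
        if raw[j] <= raw[j - 1]:
            raw[j] = raw[j - 1] + 1
    if raw[-1] > total_positions:
        raise ValueError("could not place q distinct positions")
    return raw


def simulate_dataset(scenario: SimulationScenario, seed=None) -> SimulatedDataset:
    """Draw one n x q response matrix from the factor-plus-error model."""
    rng = np.random.default_rng(scenario.seed if seed is None else seed)
    pos = scenario.positions
    sigma = sigma_profile(
        scenario.a, scenario.b, pos, t_f=pos[0], t_l=pos[-1]
    )
    f = rng.standard_normal(scenario.n)
    e = rng.standard_normal((scenario.n, scenario.q)) * sigma
    values = (f[:, None] + e) / np.sqrt(1.0 + sigma ** 2)
    return SimulatedDataset(
        values=values, positions=pos, true_sigma=np.asarray(sigma), factor_scores=f
    )


def run_scenario(
    scenario: SimulationScenario, config: AnalysisConfig | None = None
) -> ScenarioSummary:
    """Replicate the scenario: simulate, screen, collect the slope.

    Per replicate: draw a dataset, run the full awareness pipeline
    (clustering included; no bootstrap inside the loop) and record the
    slope.  Replicates where the pipeline is degenerate or unscreenable
    are dropped and counted.  Reproducible given the scenario seed.
    """
    config = config or AnalysisConfig(seed=scenario.seed)
    children = np.random.SeedSequence(scenario.seed).spawn(scenario.replicates)
    slopes = np.empty(scenario.replicates)
    used = failures = 0
    for child in children:
        ds = simulate_dataset(scenario, seed=child)
        try:
            slopes[used], _ = _slope_from_values(
                ds.values, ds.positions, config.estimator
            )
            used += 1
        except (DegenerateDataError, UnscreenableError):
            failures += 1
    if failures:
        logger.warning(
            "scenario (a=%g, b=%g, q=%d): %d of %d replicates failed",
            scenario.a, scenario.b, scenario.q, failures, scenario.replicates,
        )
    if used == 0:
        raise UnscreenableError("every scenario replicate failed")
    return ScenarioSummary(scenario=scenario, slopes=slopes[:used], failures=failures)


def plot_scenarios(summaries: dict, path=None):
    """Boxplots of the awareness-measure distribution per scenario.

    ``summaries`` maps display labels to ScenarioSummary objects.
    Requires matplotlib; returns the figure (saved to ``path`` if given).
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(1.5 + 1.2 * len(summaries), 4))
    ax.boxplot([s.slopes for s in summaries.values()],
               tick_labels=list(summaries.keys()), showfliers=False)
    ax.axhline(0.0, color="grey", lw=0.8, ls="--")
    ax.set_ylabel("awareness measure (ICC per position)")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
    return fig


DEFAULT_SCENARIOS = {
    "decreasing": SimulationScenario(a=0.5, b=2.0),
    "constant": SimulationScenario(a=1.0, b=1.0),
    "increasing": SimulationScenario(a=2.0, b=0.5),
}


def scale_from_positions(name: str, positions, label_fmt: str = "item{:02d}") -> ScaleSpec:
    """Build a ScaleSpec whose labels encode the questionnaire positions."""
    return ScaleSpec(
        scale_name=name, items=[(label_fmt.format(int(t)), int(t)) for t in positions]
    )


def make_fixture(
    n: int,
    total_items: int,
    scales: list[ScaleSpec],
    seed: int,
    a: float = 1.0,
    b: float = 1.0,
) -> ResponseMatrix:
    """Synthesize an ordinal questionnaire emulating a long coping-style
    instrument: ``n`` respondents, ``total_items`` four-category (0-3)
    items, each scale driven by its own latent factor.

    Each scale's items are simulated continuously from the factor model
    (error SD running from ``a`` at the scale's first position to ``b``
    at its last) and discretized at the per-item empirical quartiles, so
    categories are balanced.  Items belonging to no scale are filler:
    independent uniform draws over {0, 1, 2, 3}.
    """
    taken: dict[int, str] = {}
    for spec in scales:
        for _, pos in spec.items:
            if pos in taken:
                raise ConfigError(
                    f"position {pos} used by both {taken[pos]!r} and {spec.scale_name!r}"
                )
            if not 1 <= pos <= total_items:
                raise ConfigError(f"position {pos} outside 1..{total_items}")
            taken[pos] = spec.scale_name

    rng = np.random.default_rng(seed)
    values = rng.integers(0, 4, size=(n, total_items)).astype(float)  # filler
    labels = [f"item{t:02d}" for t in range(1, total_items + 1)]
    for spec in scales:
        pos = spec.positions
        # simulate on the scale's own positions, not the even grid
        sigma = sigma_profile(a, b, pos, t_f=pos[0], t_l=pos[-1])
        f = rng.standard_normal(n)
        cont = (f[:, None] + rng.standard_normal((n, spec.q)) * sigma) / np.sqrt(
            1.0 + np.asarray(sigma) ** 2
        )
        cuts = np.quantile(cont, [0.25, 0.5, 0.75], axis=0)
        ordinal = (cont > cuts[0]).astype(float)
        ordinal += cont > cuts[1]
        ordinal += cont > cuts[2]
        for j, (label, p) in enumerate(spec.items):
            values[:, p - 1] = ordinal[:, j]
            labels[p - 1] = label
    return ResponseMatrix(
        subject_ids=[f"s{i:04d}" for i in range(1, n + 1)],
        item_labels=labels,
        values=values,
    )
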