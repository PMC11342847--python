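"""Trial-by-trial learning models and the shared softmax decision stage.

Four models operate on outcomes rescaled to the unit interval (card 1 ->
0.01, card 13 -> 0.99; prior expectation 0.5):

* ``rw1`` -- Rescorla-Wagner with a single learning rate: V <- V + a*(R - V).
* ``rw2`` -- asymmetric Rescorla-Wagner with separate rates for positive and
  negative prediction errors; the positive learning bias a+/(a+ + a-) biases
  learned values upward for high-variance options when it exceeds 0.5.
* ``peirs`` -- tracks expected value V and expected outcome spread S
  (exponential average of |prediction error|); spread is added to or
  subtracted from decision values through tanh(omega * d), where d is how
  much the offered pair's mean value exceeds the 0.5 global mean.
* ``cvar`` -- a distributional Bayesian learner: the belief is an estimate of
  the deck's whole value distribution on a discrete grid over the unit
  interval.  Formally it is the posterior mean of a uniform Dirichlet prior
  (concentration 1, the flat Beta(1,1) start) over the discretized outcome
  distribution, with each observed outcome entering as a Beta evidence
  kernel of fixed variance ``updatevar`` centred on the outcome.  Decision
  values are a Conditional Value at Risk readout of that belief: the mean of
  its lower tail (eta < 0), upper tail (eta > 0), or the whole belief
  (eta = 0), so eta tunes the agent from risk averse to risk seeking.

Under full feedback both decks are updated every trial regardless of choice.
Choice probabilities come from a softmax on the two decision values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

DEFAULT_UPDATEVAR = 0.009
DEFAULT_GRID_SIZE = 481

MODELS = ("rw1", "rw2", "peirs", "cvar")


# ---------------------------------------------------------------------------
# Parameter bundles

@dataclass(frozen=True)
class RW1Params:
    alpha: float
    beta: float


@dataclass(frozen=True)
class RW2Params:
    alpha_pos: float
    alpha_neg: float
    beta: float


@dataclass(frozen=True)
class PEIRSParams:
    alpha_q: float
    alpha_s: float
    omega: float
    s0: float
    beta: float


@dataclass(frozen=True)
class CVaRParams:
    eta: float
    beta: float
    updatevar: float = DEFAULT_UPDATEVAR


PARAM_CLASSES = {"rw1": RW1Params, "rw2": RW2Params,
                 "peirs": PEIRSParams, "cvar": CVaRParams}


def make_params(model: str, params: dict):
    """Build the model's parameter bundle from a name->value mapping."""
    cls = PARAM_CLASSES[model]
    names = cls.__dataclass_fields__.keys()
    return cls(**{k: params[k] for k in names if k in params})


# ---------------------------------------------------------------------------
# Softmax decision stage

def softmax_prob(value_a: float, value_b: float, beta: float) -> float:
    """P(choose a) = 1 / (1 + exp(-beta * (V_a - V_b)))."""
    if not (np.isfinite(value_a) and np.isfinite(value_b) and np.isfinite(beta)):
        raise ValueError("softmax_prob requires finite inputs")
    if beta < 0:
        raise ValueError("beta must be >= 0")
    x = beta * (value_a - value_b)
    # guard exp overflow for large beta
    if x >= 0:
        return 1.0 / (1.0 + np.exp(-x))
    e = np.exp(x)
    return e / (1.0 + e)


# ---------------------------------------------------------------------------
# Rescorla-Wagner family

def _check_outcome(outcome: float) -> None:
    if not 0.01 - 1e-12 <= outcome <= 0.99 + 1e-12:
        raise ValueError(f"rescaled outcome {outcome} outside [0.01, 0.99]")


@dataclass
class RWState:
    """Per-deck expected values V (and, for PEIRS, expected spreads S).

    Values start at the 0.5 prior expectation; spreads start at S_0.
    """

    v: np.ndarray = field(default_factory=lambda: np.array([0.5, 0.5]))
    s: np.ndarray | None = None

    @classmethod
    def initial(cls, model: str, params=None) -> "RWState":
        v = np.array([0.5, 0.5])
        if model == "peirs":
            return cls(v=v, s=np.array([params.s0, params.s0], dtype=float))
        return cls(v=v)


def rw1_step(state: RWState, deck: int, outcome: float, params: RW1Params) -> RWState:
    """Single-rate delta-rule update of one deck's expected value."""
    _check_outcome(outcome)
    v = state.v.copy()
    v[deck] += params.alpha * (outcome - v[deck])
    return RWState(v=v, s=None if state.s is None else state.s.copy())


def rw2_step(state: RWState, deck: int, outcome: float, params: RW2Params) -> RWState:
    """Asymmetric update: a+ for delta >= 0 (ties included), a- for delta < 0."""
    _check_outcome(outcome)
    v = state.v.copy()
    delta = outcome - v[deck]
    alpha = params.alpha_pos if delta >= 0 else params.alpha_neg
    v[deck] += alpha * delta
    return RWState(v=v, s=None if state.s is None else state.s.copy())


def positive_learning_bias(alpha_pos: float, alpha_neg: float) -> float:
    """a+ / (a+ + a-): > 0.5 weights positive prediction errors more."""
    if alpha_pos < 0 or alpha_neg < 0 or alpha_pos + alpha_neg == 0:
        raise ValueError("learning rates must be nonnegative with positive sum")
    return alpha_pos / (alpha_pos + alpha_neg)


def peirs_step(state: RWState, deck: int, outcome: float, params: PEIRSParams) -> RWState:
    """Joint value/spread update: V tracks outcomes, S tracks |delta|."""
    _check_outcome(outcome)
    v, s = state.v.copy(), state.s.copy()
    delta = outcome - v[deck]
    v[deck] += params.alpha_q * delta
    s[deck] += params.alpha_s * (abs(delta) - s[deck])
    return RWState(v=v, s=s)


def peirs_decision_values(state: RWState, params: PEIRSParams) -> tuple[float, float]:
    """Spread-modulated decision values V' = V + tanh(omega * d) * S.

    d = (V_a + V_b)/2 - 0.5 is the offered pair's advantage over the global
    mean: when both options look better than 0.5, positive omega adds the
    learned spread to decision values (risk seeking in good environments),
    and subtracts it when they look worse.
    """
    d = (state.v[0] + state.v[1]) / 2.0 - 0.5
    mod = np.tanh(params.omega * d)
    return (float(state.v[0] + mod * state.s[0]),
            float(state.v[1] + mod * state.s[1]))


# ---------------------------------------------------------------------------
# Bayesian learner with CVaR readout

@dataclass
class BeliefGrid:
    """Normalized belief density on a fixed grid strictly inside (0, 1).

    ``weight`` is the belief's effective observation count (prior counts as
    one): the Dirichlet concentration that sets how much one more outcome
    moves the estimate.
    """

    grid: np.ndarray
    density: np.ndarray
    weight: float = 1.0

    @classmethod
    def flat(cls, n: int = DEFAULT_GRID_SIZE, lo: float = 0.01, hi: float = 0.99) -> "BeliefGrid":
        """Uniform Beta(1,1) initial belief on an n-point grid over [lo, hi].

        The default 481-point grid on [0.01, 0.99] contains every rescaled
        card value exactly.
        """
        grid = np.linspace(lo, hi, n)
        return cls(grid=grid, density=np.full(n, 1.0 / n), weight=1.0)

    def mean(self) -> float:
        return float(np.dot(self.grid, self.density))

    def normalized(self) -> bool:
        return abs(self.density.sum() - 1.0) <= 1e-9


def event_density_params(outcome: float, updatevar: float = DEFAULT_UPDATEVAR) -> tuple[float, float]:
    """Shape pair of the Beta evidence density with mean R and variance updatevar.

    Inverts the Beta moment map: with nu = R(1-R)/updatevar - 1,
    alpha = R*nu and beta = (1-R)*nu.  Feasibility requires
    updatevar < R(1-R).
    """
    _check_outcome(outcome)
    if updatevar <= 0:
        raise ValueError("updatevar must be > 0")
    nu = outcome * (1.0 - outcome) / updatevar - 1.0
    if nu <= 0:
        raise ValueError(
            f"updatevar={updatevar} infeasible for outcome R={outcome}: "
            "requires updatevar < R(1-R)"
        )
    return outcome * nu, (1.0 - outcome) * nu


def evidence_kernel(grid: np.ndarray, outcome: float,
                    updatevar: float = DEFAULT_UPDATEVAR) -> np.ndarray:
    """Discretized Beta evidence density on the grid for one outcome.

    Each grid point receives the Beta probability mass of its cell (CDF
    difference between neighbouring midpoints; the first and last cells
    absorb the remaining tails to 0 and 1).  Cell masses, unlike pointwise
    density values, stay faithful for extreme outcomes whose Beta shapes
    fall below 1 and whose density diverges at the support edges.
    """
    from scipy.stats import beta as beta_dist
    a, b = event_density_params(outcome, updatevar)
    edges = np.empty(grid.size + 1)
    edges[1:-1] = 0.5 * (grid[1:] + grid[:-1])
    edges[0], edges[-1] = 0.0, 1.0
    k = np.diff(beta_dist.cdf(edges, a, b))
    total = k.sum()
    if total <= 0 or not np.isfinite(total):
        raise FloatingPointError(
            f"evidence density for R={outcome} vanished on the grid")
    return k / total


def bayes_update(belief: BeliefGrid, outcome: float,
                 updatevar: float = DEFAULT_UPDATEVAR) -> BeliefGrid:
    """Fold one outcome's Beta evidence kernel into the belief.

    Conjugate Dirichlet update of the estimated value distribution: with
    effective count c, the new belief is (c * old + kernel) / (c + 1), so the
    estimate converges to the kernel-smoothed empirical outcome distribution
    while the flat prior washes out as 1/t.  Always renormalized to sum 1.
    """
    if not belief.normalized():
        raise ValueError("belief density is not normalized")
    k = evidence_kernel(belief.grid, outcome, updatevar)
    c = belief.weight
    post = (c * belief.density + k) / (c + 1.0)
    return BeliefGrid(grid=belief.grid, density=post / post.sum(),
                      weight=c + 1.0)


def _var_index(belief: BeliefGrid, eta: float) -> int:
    if not -1.0 < eta < 1.0:
        raise ValueError(f"eta must lie in (-1, 1), got {eta}")
    cdf = np.cumsum(belief.density)
    cdf = cdf / cdf[-1]
    q = 1.0 + eta if eta <= 0 else eta
    idx = int(np.searchsorted(cdf, q - 1e-12, side="left"))
    return min(idx, len(cdf) - 1)


def value_at_risk(belief: BeliefGrid, eta: float) -> float:
    """The VaR quantile: smallest grid point whose CDF reaches 1 + eta
    (eta <= 0) or eta (eta > 0)."""
    return float(belief.grid[_var_index(belief, eta)])


def cvar_readout(belief: BeliefGrid, eta: float) -> float:
    """Conditional Value at Risk of the discrete belief at level eta.

    The belief-weighted mean of the tail at or below the VaR point
    (eta <= 0) or at or above it (eta > 0), inclusive of the VaR point on
    both branches.  eta = 0 therefore returns the mean of the whole belief.
    """
    idx = _var_index(belief, eta)
    tail = slice(0, idx + 1) if eta <= 0 else slice(idx, None)
    w = belief.density[tail]
    return float(np.dot(belief.grid[tail], w) / w.sum())
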