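"""Card-deck magnitude-learning task: deck distributions, blocks and cohorts.

The task presents two decks of poker cards (values 1--13, ace to king) per
block.  Deck value distributions differ in mean (high = 8, low = 6, around a
global mean of 7) and in shape (narrow, broad or bimodal).  Feedback is full:
both decks' drawn cards are revealed every trial, and the signed point gain
is the difference between the chosen and unchosen card.

Eight block types of 30 trials each make up a session.  In the four
different-mean blocks the decks differ in mean; in the four same-mean blocks
they share a mean but differ in variance, which is where a pro-variance bias
(preference for the broader deck) can express itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import norm

CARD_VALUES = np.arange(1, 14)

HIGH_MEAN = 8.0
LOW_MEAN = 6.0
NARROW_SD = 1.0
BROAD_SD = 2.5
BIMODAL_MODES = (3.0, 12.0)

DIFF_MEAN_BLOCKS = ("BHBL", "NHNL", "BHNL", "NHBL")
SAME_MEAN_BLOCKS = ("BHNH", "BLNL", "BiHNH", "BiLNL")
BLOCK_TYPES = DIFF_MEAN_BLOCKS + SAME_MEAN_BLOCKS
UNIMODAL_SAME_MEAN_BLOCKS = ("BHNH", "BLNL")
BIMODAL_SAME_MEAN_BLOCKS = ("BiHNH", "BiLNL")

DEFAULT_N_TRIALS = 30

#: deck label -> (deck_a name, deck_b name); option "a" is the higher-mean
#: deck, or the broader deck when means are equal.
BLOCK_DECKS = {
    "BHBL": ("broad_high", "broad_low"),
    "NHNL": ("narrow_high", "narrow_low"),
    "BHNL": ("broad_high", "narrow_low"),
    "NHBL": ("narrow_high", "broad_low"),
    "BHNH": ("broad_high", "narrow_high"),
    "BLNL": ("broad_low", "narrow_low"),
    "BiHNH": ("bimodal_high", "narrow_high"),
    "BiLNL": ("bimodal_low", "narrow_low"),
}

CHOICE_COLUMNS = (
    "subject_id", "block_type", "trial", "choice",
    "outcome_a", "outcome_b", "points",
)


def rescale_card(v):
    """Map card values 1..13 linearly onto [0.01, 0.99].

    1 -> 0.01, 13 -> 0.99; the global card mean 7 maps to 0.5, the prior
    expected value of every learning model.
    """
    arr = np.asarray(v, dtype=float)
    if np.any(arr < 1) or np.any(arr > 13):
        raise ValueError(f"card value outside [1, 13]: {v!r}")
    out = 0.01 + (arr - 1.0) * (0.98 / 12.0)
    return out if out.ndim else float(out)


def unscale_card(r):
    """Inverse of :func:`rescale_card`."""
    arr = np.asarray(r, dtype=float)
    out = 1.0 + (arr - 0.01) * (12.0 / 0.98)
    return out if out.ndim else float(out)


def _tilt_to_mean(pmf: np.ndarray, target: float) -> np.ndarray:
    """Exponentially tilt a pmf on CARD_VALUES so its mean is exactly target.

    Discretizing and truncating a Gaussian shifts its mean by a small amount;
    the tilt p_i * exp(lam * x_i) restores the mean exactly while perturbing
    the shape minimally.
    """
    x = CARD_VALUES.astype(float)

    def mean_at(lam: float) -> float:
        w = pmf * np.exp(lam * (x - target))
        return float(np.dot(w, x) / w.sum()) - target

    if abs(mean_at(0.0)) < 1e-14:
        return pmf / pmf.sum()
    lam = brentq(mean_at, -2.0, 2.0, xtol=1e-15, rtol=1e-15)
    w = pmf * np.exp(lam * (x - target))
    return w / w.sum()


def _discretized_gaussian(mean: float, sd: float,
                          symmetric_support: bool = False) -> np.ndarray:
    """Gaussian density sampled on 1..13, renormalized, tilted to exact mean.

    With ``symmetric_support`` the pmf is restricted to mean +/- 5 cards
    (3..13 for the high decks, 1..11 for the low), which makes the
    distribution exactly symmetric: the task manipulates variance at fixed
    mean, and a skew-free deck keeps variance the only thing that differs
    between the two options of a same-mean block.
    """
    x = CARD_VALUES.astype(float)
    p = norm.pdf(x, loc=mean, scale=sd)
    if symmetric_support:
        p = np.where(np.abs(x - mean) <= 5.0 + 1e-9, p, 0.0)
    return _tilt_to_mean(p / p.sum(), mean)


def _bimodal_pmf(target_mean: float, modes=BIMODAL_MODES, sd: float = 1.0) -> np.ndarray:
    """Two-component mixture with modes at the extremes, exact mixture mean.

    Each component is a discretized Gaussian tilted to have its mode value as
    exact mean; the mixture weight then fixes the overall mean exactly.
    """
    lo, hi = modes
    comp_lo = _discretized_gaussian(lo, sd)
    comp_hi = _discretized_gaussian(hi, sd)
    w = (hi - target_mean) / (hi - lo)
    if not 0.0 < w < 1.0:
        raise ValueError(f"target mean {target_mean} outside mode range {modes}")
    return w * comp_lo + (1.0 - w) * comp_hi


def default_deck_pmfs() -> dict[str, np.ndarray]:
    """The six default deck distributions on the 1..13 card scale."""
    return {
        "narrow_high": _discretized_gaussian(HIGH_MEAN, NARROW_SD, symmetric_support=True),
        "narrow_low": _discretized_gaussian(LOW_MEAN, NARROW_SD, symmetric_support=True),
        "broad_high": _discretized_gaussian(HIGH_MEAN, BROAD_SD, symmetric_support=True),
        "broad_low": _discretized_gaussian(LOW_MEAN, BROAD_SD, symmetric_support=True),
        "bimodal_high": _bimodal_pmf(HIGH_MEAN),
        "bimodal_low": _bimodal_pmf(LOW_MEAN),
    }


def pmf_mean(pmf: np.ndarray) -> float:
    return float(np.dot(pmf, CARD_VALUES))


def pmf_var(pmf: np.ndarray) -> float:
    m = pmf_mean(pmf)
    return float(np.dot(pmf, (CARD_VALUES - m) ** 2))


def _n_local_modes(pmf: np.ndarray) -> int:
    n = 0
    for i in range(len(pmf)):
        left = pmf[i - 1] if i > 0 else -np.inf
        right = pmf[i + 1] if i < len(pmf) - 1 else -np.inf
        if pmf[i] > left and pmf[i] > right:
            n += 1
    return n


@dataclass(frozen=True)
class BlockSpec:
    """Two deck pmfs over card values 1..13 plus a block-type label.

    ``deck_a`` is the higher-mean deck, or the broader deck when means are
    equal; invariants (mean = 8 or 6 exactly, variance ordering, bimodality)
    are validated on construction.
    """

    block_type: str
    deck_a: np.ndarray
    deck_b: np.ndarray
    n_trials: int = DEFAULT_N_TRIALS

    def __post_init__(self):
        if self.block_type not in BLOCK_TYPES:
            raise ValueError(f"unknown block type {self.block_type!r}")
        object.__setattr__(self, "deck_a", np.asarray(self.deck_a, dtype=float))
        object.__setattr__(self, "deck_b", np.asarray(self.deck_b, dtype=float))
        for name, pmf in (("deck_a", self.deck_a), ("deck_b", self.deck_b)):
            if pmf.shape != (13,):
                raise ValueError(f"{name} must have 13 entries")
            if np.any(pmf < 0):
                raise ValueError(f"{name} has negative mass")
            if abs(pmf.sum() - 1.0) > 1e-12:
                raise ValueError(f"{name} does not sum to 1")
        name_a, name_b = BLOCK_DECKS[self.block_type]
        target_a = HIGH_MEAN if "high" in name_a else LOW_MEAN
        target_b = HIGH_MEAN if "high" in name_b else LOW_MEAN
        if abs(pmf_mean(self.deck_a) - target_a) > 1e-9:
            raise ValueError(f"deck_a mean {pmf_mean(self.deck_a)} != {target_a}")
        if abs(pmf_mean(self.deck_b) - target_b) > 1e-9:
            raise ValueError(f"deck_b mean {pmf_mean(self.deck_b)} != {target_b}")
        if self.is_same_mean and pmf_var(self.deck_a) <= pmf_var(self.deck_b):
            raise ValueError("same-mean block requires var(deck_a) > var(deck_b)")
        for name, deck_name, pmf in (
            ("deck_a", name_a, self.deck_a), ("deck_b", name_b, self.deck_b)
        ):
            if deck_name.startswith("bimodal") and _n_local_modes(pmf) < 2:
                raise ValueError(f"{name} labelled bimodal but has one mode")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")

    @property
    def is_same_mean(self) -> bool:
        return self.block_type in SAME_MEAN_BLOCKS


def make_block_spec(block_type: str, config: dict | None = None) -> BlockSpec:
    """Build the BlockSpec for a block type, honouring config overrides.

    ``config`` may carry ``n_trials`` and a ``decks`` mapping of deck name
    (e.g. ``broad_high``) to a 13-entry pmf replacing the default.
    """
    config = config or {}
    if block_type not in BLOCK_DECKS:
        raise ValueError(f"unknown block type {block_type!r}")
    pmfs = default_deck_pmfs()
    for name, pmf in (config.get("decks") or {}).items():
        if name not in pmfs:
            raise ValueError(f"unknown deck name {name!r}")
        pmfs[name] = np.asarray(pmf, dtype=float)
    name_a, name_b = BLOCK_DECKS[block_type]
    return BlockSpec(
        block_type=block_type,
        deck_a=pmfs[name_a],
        deck_b=pmfs[name_b],
        n_trials=int(config.get("n_trials", DEFAULT_N_TRIALS)),
    )


def default_block_specs(config: dict | None = None) -> dict[str, BlockSpec]:
    return {bt: make_block_spec(bt, config) for bt in BLOCK_TYPES}


def sample_trial_outcomes(spec: BlockSpec, seed) -> tuple[np.ndarray, np.ndarray]:
    """Draw the paired card streams for one block (i.i.d. per deck).

    Returns integer card values on the 1..13 scale, one array per deck,
    reproducible under ``seed`` (an int or a numpy Generator).
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    a = rng.choice(CARD_VALUES, size=spec.n_trials, p=spec.deck_a)
    b = rng.choice(CARD_VALUES, size=spec.n_trials, p=spec.deck_b)
    return a, b


# ---------------------------------------------------------------------------
# Cohorts

@dataclass(frozen=True)
class TraitLink:
    """Linear link from the risk parameter eta to a trait score.

    trait = intercept + slope * eta + N(0, noise_sd^2).  The default slope is
    negative, emulating a cohort in which higher rumination-like trait scores
    go with more risk-averse (lower eta) agents.
    """

    intercept: float = 55.0
    slope: float = -30.0
    noise_sd: float = 8.0

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def _default_samplers(model: str):
    if model == "rw1":
        return {"alpha": (0.1, 0.9), "beta": (2.0, 10.0)}
    if model == "rw2":
        return {"alpha_pos": (0.05, 0.85), "alpha_neg": (0.05, 0.85),
                "beta": (2.0, 10.0)}
    if model == "peirs":
        return {"alpha_q": (0.1, 0.9), "alpha_s": (0.1, 0.9),
                "omega": (-8.0, 8.0), "s0": (0.02, 0.5), "beta": (2.0, 10.0)}
    if model == "cvar":
        return {"eta": (-0.8, 0.8), "beta": (2.0, 10.0)}
    raise ValueError(f"unknown model {model!r}")


@dataclass(frozen=True)
class CohortSpec:
    """Recipe for a synthetic cohort of simulated agents.

    ``param_sampler`` maps parameter name to a (lo, hi) uniform range on the
    natural scale; unspecified parameters use per-model defaults.  The trait
    link applies to eta for CVaR cohorts; cohorts of other models get an
    uncorrelated trait drawn around the link intercept (null control).
    """

    n_agents: int
    model: str = "cvar"
    param_sampler: dict | None = None
    trait_link: TraitLink = field(default_factory=TraitLink)
    seed: int = 0

    def __post_init__(self):
        if self.n_agents < 0:
            raise ValueError("n_agents must be >= 0")
        _default_samplers(self.model)  # validates the model name
        for name, (lo, hi) in (self.param_sampler or {}).items():
            if not lo < hi:
                raise ValueError(f"empty sampler range for {name!r}")


def generate_cohort(
    cohort: CohortSpec, config: dict | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate a cohort through all eight blocks.

    Returns (choice table, trait table, generating-parameter table).  Each
    agent's RNG stream is derived deterministically from the cohort seed, so
    the whole cohort is bit-reproducible.
    """
    from .simulate import simulate_block  # local import to avoid a cycle

    specs = default_block_specs(config)
    samplers = dict(_default_samplers(cohort.model))
    samplers.update(cohort.param_sampler or {})

    root = np.random.SeedSequence(cohort.seed)
    param_seq, trait_seq, agent_seq = root.spawn(3)
    prng = np.random.default_rng(param_seq)
    trng = np.random.default_rng(trait_seq)
    agent_seeds = agent_seq.spawn(cohort.n_agents)

    rows, traits, gen_params = [], [], []
    for i in range(cohort.n_agents):
        sid = f"agent{i:03d}"
        params = {k: prng.uniform(lo, hi) for k, (lo, hi) in samplers.items()}
        link = cohort.trait_link
        eta_for_trait = params["eta"] if cohort.model == "cvar" else 0.0
        trait = link.intercept + link.slope * eta_for_trait
        if link.noise_sd > 0:
            trait += trng.normal(0.0, link.noise_sd)
        arng = np.random.default_rng(agent_seeds[i])
        for bt in BLOCK_TYPES:
            res = simulate_block(cohort.model, params, specs[bt], arng)
            for t in range(specs[bt].n_trials):
                ch = "a" if res.choices[t] == 0 else "b"
                oa, ob = int(res.outcomes_a[t]), int(res.outcomes_b[t])
                pts = (oa - ob) if ch == "a" else (ob - oa)
                rows.append((sid, bt, t + 1, ch, oa, ob, pts))
        traits.append((sid, trait))
        gen_params.append({"subject_id": sid, "model": cohort.model, **params})

    choices = pd.DataFrame(rows, columns=list(CHOICE_COLUMNS))
    trait_df = pd.DataFrame(traits, columns=["subject_id", "trait_score"])
    param_df = pd.DataFrame(gen_params)
    return choices, trait_df, param_df


# ---------------------------------------------------------------------------
# Choice-table IO

def validate_choice_data(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in CHOICE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"choice table missing columns: {missing}")
    df = df.copy()
    for col in ("outcome_a", "outcome_b"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | (vals != vals.round()) | (vals < 1) | (vals > 13)
        if bad.any():
            row = int(df.index[bad][0])
            raise ValueError(
                f"row {row}: {col}={df[col].iloc[row]!r} is not an integer card "
                "value in [1, 13]"
            )
        df[col] = vals.astype(int)
    bad = ~df["choice"].isin(["a", "b"])
    if bad.any():
        row = int(df.index[bad][0])
        raise ValueError(f"row {row}: choice={df['choice'].iloc[row]!r} not in {{a, b}}")
    bad = ~df["block_type"].isin(BLOCK_TYPES)
    if bad.any():
        row = int(df.index[bad][0])
        raise ValueError(f"row {row}: unknown block_type {df['block_type'].iloc[row]!r}")
    df["trial"] = pd.to_numeric(df["trial"]).astype(int)
    df["points"] = pd.to_numeric(df["points"]).astype(int)
    return df[list(CHOICE_COLUMNS)]


def read_choice_data(path) -> pd.DataFrame:
    return validate_choice_data(pd.read_csv(path))


def write_choice_data(df: pd.DataFrame, path) -> None:
    validate_choice_data(df).to_csv(path, index=False)


def read_trait_data(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in ("subject_id", "trait_score") if c not in df.columns]
    if missing:
        raise ValueError(f"trait table missing columns: {missing}")
    return df


def write_trait_data(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)
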