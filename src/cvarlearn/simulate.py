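"""Block simulation and the four-condition parameter-sweep study.

The sweep reproduces a simulation design with four conditions -- both-narrow
(NHNL), both-broad (BHBL), both-high (BHNH) and both-low (BLNL) -- with 500
blocks of 30 trials per condition.  For a swept parameter, the reported
percentage of option-a choices (higher-mean option in different-mean
conditions, broader option in same-mean conditions) is averaged over blocks
and marginalized evenly over the model's other free parameters on a lattice
spanning their transformed prior ranges.

Because feedback is full (both outcomes shown every trial), learning does not
depend on the agent's own choices; value/belief trajectories are therefore
computed once per learning-parameter setting and shared across the decision
parameters, and the same outcome streams (derived only from the seed and the
condition) are reused across models and parameter settings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit


from . import task
from .agents import (
    DEFAULT_GRID_SIZE,
    DEFAULT_UPDATEVAR,
    BeliefGrid,
    RWState,
    bayes_update,
    cvar_readout,
    evidence_kernel,
    make_params,
    peirs_decision_values,
    peirs_step,
    rw1_step,
    rw2_step,
    softmax_prob,
)

CONDITION_BLOCKS = {
    "both-narrow": "NHNL",
    "both-broad": "BHBL",
    "both-high": "BHNH",
    "both-low": "BLNL",
}

SWEPT_PARAM = {"rw1": "alpha", "rw2": "lr_pos_bias", "peirs": "omega", "cvar": "eta"}


@dataclass
class BlockResult:
    """One agent's pass through one block."""

    choices: np.ndarray      # 0 = option a, 1 = option b
    p_a: np.ndarray          # per-trial probability of choosing a
    outcomes_a: np.ndarray   # card values 1..13
    outcomes_b: np.ndarray


def simulate_block(model: str, params, spec: task.BlockSpec, seed) -> BlockResult:
    """Play one block: softmax choice each trial, full-feedback updates.

    ``params`` is a per-model bundle or a name->value dict.  ``seed`` is an
    int or a numpy Generator; the same seed reproduces the same outcomes and
    choices exactly.
    """
    if model not in SWEPT_PARAM:
        raise ValueError(f"unknown model {model!r}")
    p = make_params(model, params) if isinstance(params, dict) else params
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cards_a, cards_b = task.sample_trial_outcomes(spec, rng)
    u = rng.random(spec.n_trials)
    out_a = np.asarray(task.rescale_card(cards_a))
    out_b = np.asarray(task.rescale_card(cards_b))

    p_a = np.empty(spec.n_trials)
    if model == "cvar":
        beliefs = [BeliefGrid.flat(), BeliefGrid.flat()]
        for t in range(spec.n_trials):
            va = cvar_readout(beliefs[0], p.eta)
            vb = cvar_readout(beliefs[1], p.eta)
            p_a[t] = softmax_prob(va, vb, p.beta)
            beliefs[0] = bayes_update(beliefs[0], out_a[t], p.updatevar)
            beliefs[1] = bayes_update(beliefs[1], out_b[t], p.updatevar)
    else:
        state = RWState.initial(model, p)
        step = {"rw1": rw1_step, "rw2": rw2_step, "peirs": peirs_step}[model]
        for t in range(spec.n_trials):
            if model == "peirs":
                va, vb = peirs_decision_values(state, p)
            else:
                va, vb = state.v[0], state.v[1]
            p_a[t] = softmax_prob(va, vb, p.beta)
            state = step(state, 0, out_a[t], p)
            state = step(state, 1, out_b[t], p)

    choices = (u >= p_a).astype(int)  # u < p_a -> a (0)
    return BlockResult(choices=choices, p_a=p_a,
                       outcomes_a=cards_a, outcomes_b=cards_b)


# ---------------------------------------------------------------------------
# Vectorized sweep machinery (blocks on the leading axis)

def _condition_events(condition: str, n_blocks: int, n_trials: int, seed: int,
                      config=None):
    """Outcome streams and choice uniforms for one condition.

    Derived only from (seed, condition), so every model and parameter setting
    sees the same events; the shared uniforms act as common random numbers
    across parameter settings.
    """
    spec = task.make_block_spec(CONDITION_BLOCKS[condition],
                                {**(config or {}), "n_trials": n_trials})
    idx = list(CONDITION_BLOCKS).index(condition)
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(4)[idx])
    cards = np.empty((n_blocks, n_trials, 2), dtype=np.int64)
    cards[..., 0] = rng.choice(task.CARD_VALUES, size=(n_blocks, n_trials), p=spec.deck_a)
    cards[..., 1] = rng.choice(task.CARD_VALUES, size=(n_blocks, n_trials), p=spec.deck_b)
    u = rng.random((n_blocks, n_trials))
    return cards, u


def _rw1_value_diffs(out: np.ndarray, alpha: float) -> np.ndarray:
    """Pre-choice V_a - V_b per block and trial for the 1lr-RW model."""
    n_blocks, n_trials, _ = out.shape
    v = np.full((n_blocks, 2), 0.5)
    d = np.empty((n_blocks, n_trials))
    for t in range(n_trials):
        d[:, t] = v[:, 0] - v[:, 1]
        v += alpha * (out[:, t, :] - v)
    return d


def _rw2_value_diffs(out: np.ndarray, alpha_pos: float, alpha_neg: float) -> np.ndarray:
    n_blocks, n_trials, _ = out.shape
    v = np.full((n_blocks, 2), 0.5)
    d = np.empty((n_blocks, n_trials))
    for t in range(n_trials):
        d[:, t] = v[:, 0] - v[:, 1]
        delta = out[:, t, :] - v
        v += np.where(delta >= 0, alpha_pos, alpha_neg) * delta
    return d


def _peirs_trajectories(out: np.ndarray, alpha_q: float, alpha_s: float, s0: float):
    """Pre-choice V and S stacks (n_blocks, n_trials, 2) for PEIRS."""
    n_blocks, n_trials, _ = out.shape
    v = np.full((n_blocks, 2), 0.5)
    s = np.full((n_blocks, 2), s0)
    vs = np.empty((n_blocks, n_trials, 2))
    ss = np.empty((n_blocks, n_trials, 2))
    for t in range(n_trials):
        vs[:, t] = v
        ss[:, t] = s
        delta = out[:, t, :] - v
        v = v + alpha_q * delta
        s = s + alpha_s * (np.abs(delta) - s)
    return vs, ss


def _card_kernels(grid: np.ndarray, updatevar: float) -> np.ndarray:
    """Evidence-kernel rows (cell masses) for each of the 13 card values."""
    rows = np.empty((13, grid.size))
    for i, card in enumerate(task.CARD_VALUES):
        rows[i] = evidence_kernel(grid, float(task.rescale_card(card)), updatevar)
    return rows


def _cvar_tail_means(density: np.ndarray, grid: np.ndarray, eta: float) -> np.ndarray:
    """CVaR readout for a stack of normalized densities (rows)."""
    cdf = np.cumsum(density, axis=-1)
    cdf = cdf / cdf[..., -1:]
    s1 = np.cumsum(density * grid, axis=-1)
    q = 1.0 + eta if eta <= 0 else eta
    idx = np.argmax(cdf >= q - 1e-12, axis=-1)
    rows = np.arange(density.shape[0])
    if eta <= 0:
        return s1[rows, idx] / cdf[rows, idx]
    prev = idx - 1
    f_prev = np.where(idx > 0, cdf[rows, np.maximum(prev, 0)], 0.0)
    s_prev = np.where(idx > 0, s1[rows, np.maximum(prev, 0)], 0.0)
    return (s1[:, -1] - s_prev) / (1.0 - f_prev)


def _cvar_readout_stack(cards: np.ndarray, etas: np.ndarray,
                        updatevar: float = DEFAULT_UPDATEVAR,
                        grid_size: int = DEFAULT_GRID_SIZE) -> np.ndarray:
    """Pre-choice CVaR values, shape (n_blocks, n_trials, 2 decks, n_etas).

    Belief trajectories do not depend on eta or beta, so all readout levels
    are computed in one pass over the trials.
    """
    n_blocks, n_trials, _ = cards.shape
    grid = BeliefGrid.flat(grid_size).grid
    kernels = _card_kernels(grid, updatevar)
    out = np.empty((n_blocks, n_trials, 2, etas.size))
    for deck in range(2):
        density = np.full((n_blocks, grid.size), 1.0 / grid.size)
        for t in range(n_trials):
            for j, eta in enumerate(etas):
                out[:, t, deck, j] = _cvar_tail_means(density, grid, float(eta))
            density = (density * (t + 1.0) + kernels[cards[:, t, deck] - 1]) / (t + 2.0)
            density /= density.sum(axis=1, keepdims=True)
    return out


def _pct_choose_a(diff: np.ndarray, beta: float, u: np.ndarray) -> float:
    p_a = expit(beta * diff)
    return 100.0 * float(np.mean(u < p_a))


def _logit_lattice(lo_t: float, hi_t: float, n: int, kind: str,
                   out_lo: float = 0.0, out_hi: float = 1.0) -> np.ndarray:
    x = np.linspace(lo_t, hi_t, n)
    if kind == "logit":
        return out_lo + (out_hi - out_lo) * expit(x)
    if kind == "log":
        return np.exp(x)
    return x


def run_parameter_sweep(
    model: str,
    conditions="all",
    sweep_values: np.ndarray | None = None,
    n_blocks: int = 500,
    n_trials: int = 30,
    nuisance_points: int = 9,
    sweep_points: int = 9,
    seed: int = 0,
    config: dict | None = None,
) -> pd.DataFrame:
    """Sweep a model's signature parameter across the four conditions.

    Swept parameters: ``alpha`` (rw1, logit-spaced over its prior range),
    ``lr_pos_bias`` (rw2, 0.1..0.9), ``omega`` (peirs, -10..10) and ``eta``
    (cvar, -0.95..0.95).  All other free parameters are marginalized on an
    even lattice of ``nuisance_points`` values over their transformed prior
    ranges; rw2 marginalizes the overall learning-rate scale.

    Returns a tidy frame: model, condition, param_name, param_value,
    pct_choose_a, n_blocks.
    """
    if model not in SWEPT_PARAM:
        raise ValueError(f"unknown model {model!r}")
    if conditions == "all":
        conditions = list(CONDITION_BLOCKS)
    for c in conditions:
        if c not in CONDITION_BLOCKS:
            raise ValueError(f"unknown condition {c!r}")

    if sweep_values is None:
        sweep_values = {
            "rw1": _logit_lattice(-4.6, 4.6, sweep_points, "logit"),
            "rw2": np.linspace(0.1, 0.9, sweep_points),
            "peirs": np.linspace(-10.0, 10.0, sweep_points),
            "cvar": np.linspace(-0.95, 0.95, sweep_points),
        }[model]
    sweep_values = np.asarray(sweep_values, dtype=float)
    if sweep_values.size == 0:
        raise ValueError("empty sweep grid")
    betas = _logit_lattice(-3.0, 3.0, nuisance_points, "log")

    rows = []
    for cond in conditions:
        cards, u = _condition_events(cond, n_blocks, n_trials, seed, config)
        out = np.asarray(task.rescale_card(cards))
        pct = np.zeros(sweep_values.size)

        if model == "rw1":
            for i, alpha in enumerate(sweep_values):
                d = _rw1_value_diffs(out, float(alpha))
                pct[i] = np.mean([_pct_choose_a(d, b, u) for b in betas])
        elif model == "rw2":
            abar = np.linspace(0.05, 0.45, nuisance_points)
            for i, pb in enumerate(sweep_values):
                vals = []
                for a in abar:
                    d = _rw2_value_diffs(out, 2 * a * float(pb), 2 * a * (1 - float(pb)))
                    vals.extend(_pct_choose_a(d, b, u) for b in betas)
                pct[i] = np.mean(vals)
        elif model == "peirs":
            aqs = _logit_lattice(-4.6, 4.6, nuisance_points, "logit")
            ass = _logit_lattice(-4.6, 4.6, nuisance_points, "logit")
            s0s = _logit_lattice(-4.6, 0.0, nuisance_points, "log")
            acc = np.zeros(sweep_values.size)
            count = 0
            for aq in aqs:
                for a_s in ass:
                    for s0 in s0s:
                        vs, ss = _peirs_trajectories(out, float(aq), float(a_s), float(s0))
                        dopt = vs.mean(axis=2) - 0.5
                        base = vs[..., 0] - vs[..., 1]
                        sdiff = ss[..., 0] - ss[..., 1]
                        for i, omega in enumerate(sweep_values):
                            d = base + np.tanh(omega * dopt) * sdiff
                            acc[i] += np.mean([_pct_choose_a(d, b, u) for b in betas])
                        count += 1
            pct = acc / count
        else:  # cvar
            cv = _cvar_readout_stack(cards, sweep_values)
            for i in range(sweep_values.size):
                d = cv[:, :, 0, i] - cv[:, :, 1, i]
                pct[i] = np.mean([_pct_choose_a(d, b, u) for b in betas])

        for val, p in zip(sweep_values, pct):
            rows.append((model, cond, SWEPT_PARAM[model], float(val), float(p), n_blocks))

    return pd.DataFrame(rows, columns=[
        "model", "condition", "param_name", "param_value", "pct_choose_a", "n_blocks",
    ])
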