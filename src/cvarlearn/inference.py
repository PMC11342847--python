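"""Per-subject model fitting, BIC comparison and parameter recovery.

Fitting uses only the four same-mean blocks (the different-mean blocks are
close to ceiling and carry little information about risk preferences).
Estimation is bounded maximum a posteriori with uniform priors over the
transformed parameter ranges -- i.e. the stated prior ranges act as hard box
bounds -- using multi-start L-BFGS-B in the transformed space.  Model
comparison uses BIC = k*ln(n) - 2*ln(L-hat), summed across subjects, against
a k = 0 random baseline whose per-trial choice probability is 0.5.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, logit
from scipy.stats import beta as beta_dist

from . import task
from .agents import DEFAULT_UPDATEVAR
from .simulate import _card_kernels

PROB_FLOOR = 1e-12


# ---------------------------------------------------------------------------
# Parameter transforms

@dataclass(frozen=True)
class ParamSpec:
    """One fitted parameter: its transform and transformed box bounds."""

    name: str
    transform: str          # "logit" | "log" | "identity"
    lo: float               # bounds in transformed space
    hi: float
    out_lo: float = 0.0     # natural range for the logit transform
    out_hi: float = 1.0

    def to_natural(self, x: float) -> float:
        if self.transform == "logit":
            return self.out_lo + (self.out_hi - self.out_lo) * float(expit(x))
        if self.transform == "log":
            return float(np.exp(x))
        return float(x)

    def to_transformed(self, v: float) -> float:
        if self.transform == "logit":
            return float(logit((v - self.out_lo) / (self.out_hi - self.out_lo)))
        if self.transform == "log":
            return float(np.log(v))
        return float(v)


_BETA = ParamSpec("beta", "log", -3.0, 3.0)

MODEL_PARAM_SPECS: dict[str, tuple[ParamSpec, ...]] = {
    "rw1": (ParamSpec("alpha", "logit", -4.6, 4.6), _BETA),
    "rw2": (ParamSpec("alpha_pos", "logit", -4.6, 4.6),
            ParamSpec("alpha_neg", "logit", -4.6, 4.6), _BETA),
    "peirs": (ParamSpec("alpha_q", "logit", -4.6, 4.6),
              ParamSpec("alpha_s", "logit", -4.6, 4.6),
              ParamSpec("omega", "identity", -10.0, 10.0),
              ParamSpec("s0", "log", -4.6, 0.0), _BETA),
    "cvar": (ParamSpec("eta", "logit", -7.0, 7.0, out_lo=-1.0, out_hi=1.0), _BETA),
}


def n_free_params(model: str) -> int:
    return len(MODEL_PARAM_SPECS[model])


# ---------------------------------------------------------------------------
# Likelihood

def _prep_blocks(data: pd.DataFrame):
    """Extract (rescaled outcomes, a-choice flags) per same-mean block."""
    present = set(data["block_type"].unique())
    missing = [b for b in task.SAME_MEAN_BLOCKS if b not in present]
    if missing:
        raise ValueError(f"subject data missing same-mean blocks: {missing}")
    blocks = []
    for bt in task.SAME_MEAN_BLOCKS:
        blk = data[data["block_type"] == bt].sort_values("trial")
        cards = blk[["outcome_a", "outcome_b"]].to_numpy(dtype=np.int64)
        out = np.asarray(task.rescale_card(cards))
        blocks.append((cards, out, (blk["choice"] == "a").to_numpy()))
    return blocks


def _probs_rw1(out: np.ndarray, alpha: float, beta: float) -> np.ndarray:
    va = vb = 0.5
    p = np.empty(out.shape[0])
    for t in range(out.shape[0]):
        p[t] = expit(beta * (va - vb))
        va += alpha * (out[t, 0] - va)
        vb += alpha * (out[t, 1] - vb)
    return p


def _probs_rw2(out: np.ndarray, ap: float, an: float, beta: float) -> np.ndarray:
    va = vb = 0.5
    p = np.empty(out.shape[0])
    for t in range(out.shape[0]):
        p[t] = expit(beta * (va - vb))
        da = out[t, 0] - va
        db = out[t, 1] - vb
        va += (ap if da >= 0 else an) * da
        vb += (ap if db >= 0 else an) * db
    return p


def _probs_peirs(out: np.ndarray, aq: float, a_s: float, omega: float,
                 s0: float, beta: float) -> np.ndarray:
    va = vb = 0.5
    sa = sb = s0
    p = np.empty(out.shape[0])
    for t in range(out.shape[0]):
        mod = np.tanh(omega * ((va + vb) / 2.0 - 0.5))
        p[t] = expit(beta * ((va + mod * sa) - (vb + mod * sb)))
        da = out[t, 0] - va
        db = out[t, 1] - vb
        va += aq * da
        vb += aq * db
        sa += a_s * (abs(da) - sa)
        sb += a_s * (abs(db) - sb)
    return p


class _CVaRCache:
    """Pre-update belief CDF and first-moment partial sums per trial/deck.

    The belief trajectory depends only on the outcome stream and the fixed
    updatevar hyperparameter, never on (eta, beta); caching it makes
    likelihood evaluation during optimization O(trials) per call.
    """

    def __init__(self, cards: np.ndarray, updatevar: float = DEFAULT_UPDATEVAR,
                 grid_size: int = 481):
        self.grid = np.linspace(0.01, 0.99, grid_size)
        kernels = _card_kernels(self.grid, updatevar)
        n = cards.shape[0]
        self.F = np.empty((n, 2, grid_size))
        self.S1 = np.empty((n, 2, grid_size))
        for deck in range(2):
            density = np.full(grid_size, 1.0 / grid_size)
            for t in range(n):
                cdf = np.cumsum(density)
                self.F[t, deck] = cdf / cdf[-1]
                self.S1[t, deck] = np.cumsum(density * self.grid)
                density = (density * (t + 1.0) + kernels[cards[t, deck] - 1]) / (t + 2.0)
                density /= density.sum()

    def value_diffs(self, eta: float) -> np.ndarray:
        q = 1.0 + eta if eta <= 0 else eta
        idx = np.argmax(self.F >= q - 1e-12, axis=-1)      # (trials, 2)
        t_ix = np.arange(self.F.shape[0])[:, None]
        d_ix = np.arange(2)[None, :]
        if eta <= 0:
            cv = self.S1[t_ix, d_ix, idx] / self.F[t_ix, d_ix, idx]
        else:
            prev = np.maximum(idx - 1, 0)
            f_prev = np.where(idx > 0, self.F[t_ix, d_ix, prev], 0.0)
            s_prev = np.where(idx > 0, self.S1[t_ix, d_ix, prev], 0.0)
            cv = (self.S1[..., -1] - s_prev) / (1.0 - f_prev)
        return cv[:, 0] - cv[:, 1]


def _block_choice_probs(model: str, params: dict, cards: np.ndarray,
                        out: np.ndarray, cache: _CVaRCache | None = None) -> np.ndarray:
    if model == "rw1":
        return _probs_rw1(out, params["alpha"], params["beta"])
    if model == "rw2":
        return _probs_rw2(out, params["alpha_pos"], params["alpha_neg"], params["beta"])
    if model == "peirs":
        return _probs_peirs(out, params["alpha_q"], params["alpha_s"],
                            params["omega"], params["s0"], params["beta"])
    if model == "cvar":
        if cache is None:
            cache = _CVaRCache(cards, params.get("updatevar", DEFAULT_UPDATEVAR))
        return expit(params["beta"] * cache.value_diffs(params["eta"]))
    raise ValueError(f"unknown model {model!r}")


def _nll_from_blocks(model: str, params: dict, blocks, caches=None) -> float:
    nll = 0.0
    clipped = False
    for i, (cards, out, is_a) in enumerate(blocks):
        p_a = _block_choice_probs(model, params, cards, out,
                                  None if caches is None else caches[i])
        p_choice = np.where(is_a, p_a, 1.0 - p_a)
        if np.any(p_choice < PROB_FLOOR):
            clipped = True
            p_choice = np.maximum(p_choice, PROB_FLOOR)
        nll -= float(np.log(p_choice).sum())
    if clipped:
        warnings.warn("choice probabilities clamped at 1e-12 in likelihood",
                      RuntimeWarning, stacklevel=2)
    return nll


def negative_log_likelihood(model: str, params: dict, data: pd.DataFrame) -> float:
    """-sum(log P(choice)) over the subject's same-mean-block trials.

    State resets at each block start (V = 0.5, S = S_0, flat belief).
    ``params`` holds natural-scale values; for the CVaR model, ``updatevar``
    may be included to override the 0.009 default.
    """
    return _nll_from_blocks(model, params, _prep_blocks(data))


# ---------------------------------------------------------------------------
# Fitting

@dataclass
class FitResult:
    model: str
    params: dict
    loglik: float
    k: int
    n: int
    bic: float
    converged: bool
    n_restarts: int


def bic_score(k: int, n: int, loglik: float) -> float:
    """BIC = k*ln(n) - 2*ln(L-hat)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return k * np.log(n) - 2.0 * loglik


def bic(fit: FitResult) -> float:
    return bic_score(fit.k, fit.n, fit.loglik)


def random_model_bic(n: int) -> float:
    """BIC of the k = 0 baseline choosing each option with probability 0.5."""
    return bic_score(0, n, n * np.log(0.5))


def fit_subject(model: str, data: pd.DataFrame, restarts: int = 10,
                seed: int = 0, updatevar: float = DEFAULT_UPDATEVAR) -> FitResult:
    """Multi-start bounded MAP fit of one subject's same-mean-block choices.

    Starts at the centre of the transformed box plus ``restarts - 1`` uniform
    draws; returns the best local optimum.  Deterministic under ``seed``.

    Local optimization uses bounded Powell line searches: the CVaR readout is
    piecewise constant in eta (the VaR index moves only when the belief CDF
    crosses a mass threshold), which defeats finite-difference gradient
    methods but not direction-set search.
    """
    specs = MODEL_PARAM_SPECS[model]
    blocks = _prep_blocks(data)
    n = sum(len(b[2]) for b in blocks)
    caches = None
    if model == "cvar":
        caches = [_CVaRCache(cards, updatevar) for cards, _, _ in blocks]

    def objective(x: np.ndarray) -> float:
        params = {s.name: s.to_natural(xi) for s, xi in zip(specs, x)}
        if model == "cvar":
            params["updatevar"] = updatevar
        return _nll_from_blocks(model, params, blocks, caches)

    bounds = [(s.lo, s.hi) for s in specs]
    rng = np.random.default_rng(seed)
    centre = np.array([(s.lo + s.hi) / 2.0 for s in specs])
    starts = [centre] + [
        np.array([rng.uniform(lo, hi) for lo, hi in bounds])
        for _ in range(max(restarts - 1, 0))
    ]

    best, converged = None, False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for x0 in starts:
            res = minimize(objective, x0, method="Powell", bounds=bounds,
                           options={"xtol": 1e-4, "ftol": 1e-7})
            converged = converged or bool(res.success)
            if best is None or res.fun < best.fun:
                best = res
    params = {s.name: s.to_natural(xi) for s, xi in zip(specs, best.x)}
    if model == "cvar":
        params["updatevar"] = updatevar
    loglik = -float(best.fun)
    k = len(specs)
    return FitResult(model=model, params=params, loglik=loglik, k=k, n=n,
                     bic=bic_score(k, n, loglik), converged=converged,
                     n_restarts=len(starts))


def fit_dataset(model: str, data: pd.DataFrame, restarts: int = 10,
                seed: int = 0) -> pd.DataFrame:
    """Fit every subject in a choice table; one row per subject."""
    rows = []
    subjects = sorted(data["subject_id"].unique())
    seeds = np.random.SeedSequence(seed).spawn(len(subjects))
    for sid, ss in zip(subjects, seeds):
        sub = data[data["subject_id"] == sid]
        fit = fit_subject(model, sub, restarts=restarts,
                          seed=int(ss.generate_state(1)[0] % (2**31)))
        row = {"subject_id": sid, "model": model, **{
            k: v for k, v in fit.params.items() if k != "updatevar"}}
        row.update(loglik=fit.loglik, k=fit.k, n=fit.n, bic=fit.bic,
                   converged=fit.converged)
        rows.append(row)
    return pd.DataFrame(rows)


def compare_models(fits: dict[str, list[FitResult]] | pd.DataFrame) -> pd.DataFrame:
    """Summed-BIC table with delta BIC relative to the best model.

    Accepts either a mapping model -> list of per-subject FitResult, or a
    tidy frame with model/subject_id/bic columns.  Every subject must be fit
    under every model.
    """
    if isinstance(fits, pd.DataFrame):
        counts = fits.groupby("model")["subject_id"].nunique()
        if counts.nunique() != 1:
            raise ValueError("ragged fit sets: unequal subject counts per model")
        summed = fits.groupby("model")["bic"].sum()
    else:
        sizes = {m: len(v) for m, v in fits.items()}
        if len(set(sizes.values())) != 1:
            raise ValueError(f"ragged fit sets: {sizes}")
        summed = pd.Series({m: sum(f.bic for f in v) for m, v in fits.items()})
    out = summed.rename("sum_bic").reset_index().rename(columns={"index": "model"})
    out["delta_bic"] = out["sum_bic"] - out["sum_bic"].min()
    return out.sort_values("sum_bic").reset_index(drop=True)


def parameter_recovery(model: str, cohort: "task.CohortSpec",
                       restarts: int = 10, seed: int = 0,
                       config: dict | None = None
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a cohort, refit every agent, and summarize recovery.

    Returns (per-parameter summary with Pearson r and mean signed error,
    per-agent generating-vs-fitted table).
    """
    choices, _, gen = task.generate_cohort(cohort, config)
    if cohort.n_agents == 0:
        return (pd.DataFrame(columns=["param", "r", "mean_signed_error", "n"]),
                pd.DataFrame())
    fits = fit_dataset(model, choices, restarts=restarts, seed=seed)
    merged = gen.merge(fits, on="subject_id", suffixes=("_gen", "_fit"))
    names = [s.name for s in MODEL_PARAM_SPECS[model]]
    rows = []
    for name in names:
        g = merged[f"{name}_gen"].to_numpy(dtype=float)
        f = merged[f"{name}_fit"].to_numpy(dtype=float)
        r = np.nan
        if len(g) >= 3 and np.std(g) > 0 and np.std(f) > 0:
            r = float(np.corrcoef(g, f)[0, 1])
        rows.append({"param": name, "r": r,
                     "mean_signed_error": float(np.mean(f - g)), "n": len(g)})
    return pd.DataFrame(rows), merged
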