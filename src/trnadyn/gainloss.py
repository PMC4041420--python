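"""Two-state (presence/absence) continuous-time Markov model on a phylogeny.

Each tRNA species evolves independently with a gain rate (0 -> 1) and a loss
rate (1 -> 0) per unit branch length, optionally modulated by K discrete-gamma
branch-rate multipliers. The module provides the likelihood (Felsenstein
pruning), per-species maximum-likelihood rates, marginal ancestral posteriors
(up-down algorithm), stochastic mapping by uniformization to estimate the
probability of at least one gain/loss per branch, event calling at a
probability threshold, genome-wide rate sums, and a closed-form alternative
for the branch event probabilities used as an independent cross-check.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import gammainc
from scipy.stats import gamma as gamma_dist, poisson

from .phylo import TreeIndex

logger = logging.getLogger(__name__)


def discrete_gamma_rates(shape: float, k: int) -> np.ndarray:
    """Mean rates of k equal-probability discrete-gamma categories (mean 1)."""
    if shape <= 0 or k < 1:
        raise ValueError("shape must be > 0 and k >= 1")
    bounds = gamma_dist.ppf(np.linspace(0, 1, k + 1), shape, scale=1 / shape)
    upper = gammainc(shape + 1, shape * bounds[1:])
    lower = gammainc(shape + 1, shape * bounds[:-1])
    rates = k * (upper - lower)
    return rates / rates.mean()


@dataclass
class TwoStateModel:
    """Gain/loss rates with optional gamma rate variation and root prior.

    ``root_prior`` defaults to the stationary distribution of the rates.
    """

    gain: float
    loss: float
    root_prior: np.ndarray | None = None
    gamma_shape: float | None = None
    n_categories: int = 4

    def __post_init__(self):
        if self.gain < 0 or self.loss < 0 or self.gain + self.loss <= 0:
            raise ValueError("rates must be non-negative with positive sum")
        if self.root_prior is not None:
            self.root_prior = np.asarray(self.root_prior, dtype=float)
            if not np.isclose(self.root_prior.sum(), 1.0):
                raise ValueError("root prior must sum to 1")

    @property
    def stationary(self) -> np.ndarray:
        tot = self.gain + self.loss
        return np.array([self.loss / tot, self.gain / tot])

    @property
    def prior(self) -> np.ndarray:
        return self.stationary if self.root_prior is None else self.root_prior

    @property
    def category_rates(self) -> np.ndarray:
        if self.gamma_shape is None:
            return np.ones(1)
        return discrete_gamma_rates(self.gamma_shape, self.n_categories)


def transition_matrix(model: TwoStateModel, t: float, rate_multiplier: float = 1.0) -> np.ndarray:
    """2x2 transition probabilities over a branch of length ``t``."""
    if t < 0:
        raise ValueError("branch length must be non-negative")
    g = model.gain * rate_multiplier
    l = model.loss * rate_multiplier
    tot = g + l
    decay = np.exp(-tot * t)
    p01 = g / tot * (1 - decay)
    p10 = l / tot * (1 - decay)
    return np.array([[1 - p01, p01], [p10, 1 - p10]])


def _tip_state_array(idx: TreeIndex, tip_states) -> np.ndarray:
    if isinstance(tip_states, dict):
        missing = [lab for lab in idx.tip_labels if lab not in tip_states]
        if missing:
            raise ValueError(f"missing tip states: {missing[:5]}")
        arr = np.array([tip_states[lab] for lab in idx.tip_labels], dtype=int)
    else:
        arr = np.asarray(tip_states, dtype=int)
        if arr.size != len(idx.tip_labels):
            raise ValueError("tip state vector length mismatch")
    if not np.isin(arr, (0, 1)).all():
        raise ValueError("tip states must be 0/1")
    return arr


def _branch_matrices(model: TwoStateModel, idx: TreeIndex, rate: float) -> np.ndarray:
    """Transition matrix of every branch (indexed by child node)."""
    P = np.empty((idx.n_nodes, 2, 2))
    for i in range(idx.n_nodes):
        if idx.parent[i] >= 0:
            P[i] = transition_matrix(model, idx.branch_length[i], rate)
        else:
            P[i] = np.eye(2)
    return P


def _up_pass(idx: TreeIndex, P: np.ndarray, tips: np.ndarray):
    """Scaled partial likelihoods L[node, state] with per-node log scale."""
    L = np.zeros((idx.n_nodes, 2))
    logscale = 0.0
    state_by_node = {int(t): s for t, s in zip(idx.tips, tips)}
    for i in idx.postorder():
        if idx.is_tip(i):
            L[i, state_by_node[i]] = 1.0
        else:
            vals = np.ones(2)
            for c in idx.children[i]:
                vals = vals * (P[c] @ L[c])
            s = vals.sum()
            if s <= 0:
                raise ValueError("zero likelihood during pruning")
            L[i] = vals / s
            logscale += np.log(s)
    return L, logscale


def pruning_loglik(model: TwoStateModel, tree, tip_states) -> float:
    """Felsenstein pruning log-likelihood of one species' tip states,
    averaged over gamma rate categories when the model has them."""
    idx = tree if isinstance(tree, TreeIndex) else TreeIndex(tree)
    tips = _tip_state_array(idx, tip_states)
    logliks = []
    for rate in model.category_rates:
        P = _branch_matrices(model, idx, rate)
        L, logscale = _up_pass(idx, P, tips)
        logliks.append(np.log(model.prior @ L[idx.root]) + logscale)
    logliks = np.asarray(logliks)
    m = logliks.max()
    return float(m + np.log(np.mean(np.exp(logliks - m))))


def _down_pass(idx: TreeIndex, P: np.ndarray, L: np.ndarray, prior: np.ndarray) -> np.ndarray:
    """Outside probabilities D[node, state]: evidence from everything except
    the node's own subtree, including the root prior."""
    D = np.zeros((idx.n_nodes, 2))
    D[idx.root] = prior
    for i in idx.preorder():
        if idx.is_tip(i):
            continue
        msgs = {c: P[c] @ L[c] for c in idx.children[i]}
        for c in idx.children[i]:
            sib = np.ones(2)
            for c2 in idx.children[i]:
                if c2 != c:
                    sib = sib * msgs[c2]
            D[c] = (D[i] * sib) @ P[c]
    return D


def _category_weights(model: TwoStateModel, idx: TreeIndex, tips: np.ndarray):
    """Posterior weight of each gamma category plus cached (P, L, logscale)."""
    cache = []
    logliks = []
    for rate in model.category_rates:
        P = _branch_matrices(model, idx, rate)
        L, logscale = _up_pass(idx, P, tips)
        cache.append((P, L))
        logliks.append(np.log(model.prior @ L[idx.root]) + logscale)
    logliks = np.asarray(logliks)
    w = np.exp(logliks - logliks.max())
    return w / w.sum(), cache


def marginal_posteriors(model: TwoStateModel, tree, tip_states) -> np.ndarray:
    """P(state = 1) for every node (tips reproduce the observed states)."""
    idx = tree if isinstance(tree, TreeIndex) else TreeIndex(tree)
    tips = _tip_state_array(idx, tip_states)
    weights, cache = _category_weights(model, idx, tips)
    post = np.zeros(idx.n_nodes)
    for w, (P, L) in zip(weights, cache):
        D = _down_pass(idx, P, L, model.prior)
        joint = D * L
        joint /= joint.sum(axis=1, keepdims=True)
        post += w * joint[:, 1]
    return post


def _no_event_prob(g: float, l: float, t: float):
    """Closed-form P(no gain | endpoints) and P(no loss | endpoints) for the
    two-state chain on a branch of length t, as 2x2 arrays indexed [a, b]."""
    tot = g + l
    decay = np.exp(-tot * t)
    P = np.array([[l + g * decay, g * (1 - decay)],
                  [l * (1 - decay), g + l * decay]]) / tot
    eg, el = np.exp(-g * t), np.exp(-l * t)
    if np.isclose(g, l):
        cross_gain = l * t * np.exp(-l * t)   # 1 -> 0 with a single loss
        cross_loss = g * t * np.exp(-g * t)   # 0 -> 1 with a single gain
    else:
        cross_gain = l * (eg - el) / (l - g)
        cross_loss = g * (el - eg) / (g - l)
    with np.errstate(divide="ignore", invalid="ignore"):
        nogain = np.array([[eg / P[0, 0], 0.0],
                           [cross_gain / P[1, 0], el / P[1, 1]]])
        noloss = np.array([[eg / P[0, 0], cross_loss / P[0, 1]],
                           [0.0, el / P[1, 1]]])
    nogain = np.nan_to_num(np.clip(nogain, 0, 1), nan=1.0)
    noloss = np.nan_to_num(np.clip(noloss, 0, 1), nan=1.0)
    return nogain, noloss


@dataclass
class Reconstruction:
    """Ancestral reconstruction of one species: node posteriors, per-branch
    event probabilities (indexed by the branch's child node) and the model."""

    species: str
    model: TwoStateModel
    node_posterior: np.ndarray
    p_gain: np.ndarray
    p_loss: np.ndarray
    loglik: float
    method: str = "stochastic_map"
    extra: dict = field(default_factory=dict)

    @property
    def root_posterior(self) -> float:
        return float(self.node_posterior[-1])


def branch_event_probs_exact(model: TwoStateModel, tree, tip_states):
    """Exact P(>= 1 gain) and P(>= 1 loss) per branch.

    Combines the joint posterior of branch endpoint states (up-down
    algorithm) with the closed-form probability that the conditioned
    two-state path contains no transition of the given type.
    """
    idx = tree if isinstance(tree, TreeIndex) else TreeIndex(tree)
    tips = _tip_state_array(idx, tip_states)
    weights, cache = _category_weights(model, idx, tips)
    p_gain = np.zeros(idx.n_nodes)
    p_loss = np.zeros(idx.n_nodes)
    for w, ((P, L), rate) in zip(weights, zip(cache, model.category_rates)):
        D = _down_pass(idx, P, L, model.prior)
        for c in range(idx.n_nodes):
            par = idx.parent[c]
            if par < 0:
                continue
            # joint endpoint distribution J[a, b] for the branch above c
            msgs = np.ones(2)
            for c2 in idx.children[par]:
                if c2 != c:
                    msgs = msgs * (P[c2] @ L[c2])
            J = (D[par] * msgs)[:, None] * P[c] * L[c][None, :]
            J = J / J.sum()
            nogain, noloss = _no_event_prob(model.gain * rate, model.loss * rate,
                                            idx.branch_length[c])
            p_gain[c] += w * (1 - (J * nogain).sum())
            p_loss[c] += w * (1 - (J * noloss).sum())
    return p_gain, p_loss


def _sample_paths_on_branch(rng, a, b, t, g, l, collect_events=True):
    """Vectorized endpoint-conditioned path sampling by uniformization.

    ``a``, ``b`` are arrays of endpoint states; returns boolean arrays
    (any_gain, any_loss) per sample.
    """
    n = a.size
    any_gain = np.zeros(n, dtype=bool)
    any_loss = np.zeros(n, dtype=bool)
    if t <= 0 or (g == 0 and l == 0):
        return any_gain, any_loss
    lam = 1.05 * max(g, l) + 1e-12
    Q = np.array([[-g, g], [l, -l]])
    R = np.eye(2) + Q / lam
    mean_jumps = lam * t
    n_max = int(poisson.ppf(1 - 1e-12, mean_jumps)) + 2
    powers = np.empty((n_max + 1, 2, 2))
    powers[0] = np.eye(2)
    for k in range(1, n_max + 1):
        powers[k] = powers[k - 1] @ R
    pois = poisson.pmf(np.arange(n_max + 1), mean_jumps)
    # P(N = k | a, b) propto pois[k] * R^k[a, b]
    n_jumps = np.zeros(n, dtype=int)
    for ea in (0, 1):
        for eb in (0, 1):
            mask = (a == ea) & (b == eb)
            if not mask.any():
                continue
            pmf = pois * powers[:, ea, eb]
            total = pmf.sum()
            if total <= 0:
                if ea != eb:
                    raise ValueError("non-convergent uniformization on branch")
                continue
            cdf = np.cumsum(pmf / total)
            n_jumps[mask] = np.searchsorted(cdf, rng.random(mask.sum()))
    if not collect_events:
        return n_jumps
    state = a.copy()
    max_jumps = int(n_jumps.max()) if n else 0
    for j in range(1, max_jumps + 1):
        active = n_jumps >= j
        if not active.any():
            break
        s = state[active]
        rem = n_jumps[active] - j
        # P(next virtual state = 1) given current state and remaining jumps to b
        num = R[s, 1] * powers[rem, 1, b[active]]
        den = powers[rem + 1, s, b[active]]
        with np.errstate(divide="ignore", invalid="ignore"):
            p1 = np.where(den > 0, num / den, 0.0)
        new = (rng.random(active.sum()) < p1).astype(int)
        moved_gain = (s == 0) & (new == 1)
        moved_loss = (s == 1) & (new == 0)
        gi = np.flatnonzero(active)
        any_gain[gi[moved_gain]] = True
        any_loss[gi[moved_loss]] = True
        state[active] = new
    return any_gain, any_loss


def stochastic_map(model: TwoStateModel, tree, tip_states, n_maps: int = 1000,
                   seed: int = 17, return_samples: bool = False):
    """Monte-Carlo stochastic mapping conditional on the tip states.

    Samples ``n_maps`` joint ancestral-state configurations, then
    endpoint-conditioned paths on every branch by uniformization, and reports
    per branch the fraction of maps containing at least one gain and at least
    one loss. Reproducible for a given seed.
    """
    if n_maps < 1:
        raise ValueError("n_maps must be positive")
    idx = tree if isinstance(tree, TreeIndex) else TreeIndex(tree)
    tips = _tip_state_array(idx, tip_states)
    rng = np.random.default_rng(seed)
    weights, cache = _category_weights(model, idx, tips)
    k_cat = rng.choice(len(weights), size=n_maps, p=weights)
    states = np.zeros((idx.n_nodes, n_maps), dtype=int)
    tip_pos = {int(t): s for t, s in zip(idx.tips, tips)}
    p_gain = np.zeros(idx.n_nodes)
    p_loss = np.zeros(idx.n_nodes)
    for k, (w, (P, L)) in enumerate(zip(weights, cache)):
        sel = np.flatnonzero(k_cat == k)
        if sel.size == 0:
            continue
        # sample node states top-down
        root_p1 = model.prior * L[idx.root]
        root_p1 = root_p1[1] / root_p1.sum()
        states[idx.root, sel] = rng.random(sel.size) < root_p1
        for i in idx.preorder():
            if i == idx.root:
                continue
            if idx.is_tip(i):
                states[i, sel] = tip_pos[i]
                continue
            ps = states[idx.parent[i], sel]
            w0 = P[i][ps, 0] * L[i, 0]
            w1 = P[i][ps, 1] * L[i, 1]
            states[i, sel] = rng.random(sel.size) < w1 / (w0 + w1)
        rate = model.category_rates[k]
        for c in range(idx.n_nodes):
            if idx.parent[c] < 0:
                continue
            a = states[idx.parent[c], sel]
            b = states[c, sel]
            g_flag, l_flag = _sample_paths_on_branch(
                rng, a, b, idx.branch_length[c],
                model.gain * rate, model.loss * rate)
            p_gain[c] += g_flag.sum()
            p_loss[c] += l_flag.sum()
    p_gain /= n_maps
    p_loss /= n_maps
    if return_samples:
        return p_gain, p_loss, states
    return p_gain, p_loss


def fit_rates(tree, matrix, gamma_shape: float | None = None,
              uniform_root_prior: bool = False,
              bounds: tuple[float, float] = (1e-3, 200.0)):
    """Per-species maximum-likelihood gain/loss rates.

    Constant presence columns are unidentifiable and skipped with a flag.
    Returns ``(models, skipped)`` where ``models`` maps species to a fitted
    :class:`TwoStateModel`. A warning is issued below 20 tips.
    """
    idx = tree if isinstance(tree, TreeIndex) else TreeIndex(tree)
    if len(idx.tip_labels) < 20:
        warnings.warn("fewer than 20 tips: rate estimates will be unstable")
    models: dict[str, TwoStateModel] = {}
    skipped: list[str] = []
    lo, hi = np.log(bounds[0]), np.log(bounds[1])
    prior = np.array([0.5, 0.5]) if uniform_root_prior else None
    for s_idx, species in enumerate(matrix.species):
        col = matrix.values[[matrix.organisms.index(lab) for lab in idx.tip_labels], s_idx] \
            if matrix.organisms != idx.tip_labels else matrix.values[:, s_idx]
        if col.min() == col.max():
            skipped.append(species)
            logger.info("species %s constant: rates unidentifiable, skipped", species)
            continue

        def neg_ll(logr, col=col):
            m = TwoStateModel(np.exp(logr[0]), np.exp(logr[1]), root_prior=prior,
                              gamma_shape=gamma_shape)
            return -pruning_loglik(m, idx, col)

        best = None
        for start in ((0.0, 0.0), (np.log(0.2), np.log(1.0))):
            res = minimize(neg_ll, start, method="L-BFGS-B",
                           bounds=[(lo, hi), (lo, hi)])
            if best is None or res.fun < best.fun:
                best = res
        g, l = np.exp(best.x)
        models[species] = TwoStateModel(g, l, root_prior=prior, gamma_shape=gamma_shape)
    return models, skipped


def reconstruct(tree, matrix, models: dict | None = None, n_maps: int = 1000,
                seed: int = 17, method: str = "stochastic_map",
                gamma_shape: float | None = None) -> dict[str, Reconstruction]:
    """Full per-species reconstruction: fitted rates, node posteriors and
    branch event probabilities (stochastic mapping by default, or the exact
    closed form with ``method='exact'``)."""
    idx = tree if isinstance(tree, TreeIndex) else TreeIndex(tree)
    if models is None:
        models, _ = fit_rates(idx, matrix, gamma_shape=gamma_shape)
    recons: dict[str, Reconstruction] = {}
    order = [matrix.organisms.index(lab) for lab in idx.tip_labels]
    for k, (species, model) in enumerate(sorted(models.items())):
        col = matrix.values[order, matrix.species.index(species)]
        post = marginal_posteriors(model, idx, col)
        ll = pruning_loglik(model, idx, col)
        if method == "exact":
            p_gain, p_loss = branch_event_probs_exact(model, idx, col)
        else:
            p_gain, p_loss = stochastic_map(model, idx, col, n_maps=n_maps,
                                            seed=seed + k)
        recons[species] = Reconstruction(species, model, post, p_gain, p_loss,
                                         ll, method=method)
    return recons


def call_events(recons: dict[str, Reconstruction], threshold: float = 0.8) -> pd.DataFrame:
    """Events with per-branch probability >= ``threshold`` (inclusive),
    attributed to the branch's child node. Columns: species, node, event,
    probability."""
    rows = []
    for species, rec in sorted(recons.items()):
        for c in range(rec.p_gain.size):
            pg, pl = rec.p_gain[c], rec.p_loss[c]
            if pg >= threshold:
                rows.append(dict(species=species, node=c, event="gain", probability=float(pg)))
            if pl >= threshold:
                rows.append(dict(species=species, node=c, event="loss", probability=float(pl)))
            if pg >= threshold and pl >= threshold:
                logger.warning("both gain and loss called for %s on branch %d", species, c)
    return pd.DataFrame(rows, columns=["species", "node", "event", "probability"])


def total_rates(recons: dict[str, Reconstruction]) -> pd.DataFrame:
    """Per species, the sum of branch gain and loss probabilities over the
    whole tree (the genome-wide gain/loss rate summary)."""
    rows = [dict(species=s, gain_sum=float(r.p_gain.sum()), loss_sum=float(r.p_loss.sum()))
            for s, r in sorted(recons.items())]
    return pd.DataFrame(rows, columns=["species", "gain_sum", "loss_sum"])


def root_report(recons: dict[str, Reconstruction]) -> pd.DataFrame:
    """Per-species posterior probability of presence at the root."""
    rows = [dict(species=s, root_presence=float(r.node_posterior[-1]))
            for s, r in sorted(recons.items())]
    return pd.DataFrame(rows, columns=["species", "root_presence"])
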