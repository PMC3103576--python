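"""EM estimation of reversible substitution models from annotated alignments.

E-step
    For every branch and column the posterior expectations of the number of
    i->j substitution events and of the dwell time in each state are obtained
    in closed form from the eigendecomposition of the generator: with
    Q = U diag(w) Uinv, the path integral over a branch of length T reduces to
    the auxiliary matrix J_kl = (exp(w_k T) - exp(w_l T)) / (w_k - w_l)
    (T exp(w_k T) on the diagonal / for coincident eigenvalues).  Endpoint
    posteriors come from combined inside ("down") and outside ("up") pruning
    passes, so the whole E-step is a handful of dense 20x20 products per
    branch and rate class.

M-step
    pi_i proportional to dwell w_i (floored, renormalized);
    s_ij = (c_ij + c_ji) / (w_i pi_j + w_j pi_i); the model is rebuilt and
    renormalized to unit mean rate.  This is the standard reversible update
    whose fixed point is the ML estimate.

Among-site rate heterogeneity uses k equal-probability discrete-gamma
classes whose shape is fitted once under a preliminary single-rate model.
By default the E-step integrates over classes with their per-column
posteriors (mixture EM, ``rate_mode='soft'``); ``rate_mode='hard'``
conditions each column on its most probable class instead, mirroring the
two-stage assign-then-estimate procedure, at the cost of a small downward
bias on rarely observed exchangeabilities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import logsumexp

from .alignment import DISORDERED, ORDERED, AnnotatedAlignment, split_by_mask
from .alphabet import Alphabet
from .likelihood import (
    RateClassModel,
    _branch_matrices,
    _down_pass,
    _leaf_partial_map,
    _root_log_likelihoods,
    _up_pass,
    assign_rate_classes,
    total_log_likelihood,
)
from .substitution import ReversibleModel, build_model, jukes_cantor_like
from .tree import Phylogeny

__all__ = [
    "SufficientStatistics",
    "EMConfig",
    "EMError",
    "EMResult",
    "DOFit",
    "expected_sufficient_statistics",
    "m_step_update",
    "em_fit",
    "fit_do_model",
    "free_parameter_count",
]


class EMError(RuntimeError):
    """Raised when the EM iteration violates its monotonicity guarantee."""


@dataclass(eq=False)
class SufficientStatistics:
    """Expected substitution counts c_ij (off-diagonal) and dwell times w_i."""

    counts: np.ndarray
    dwell: np.ndarray
    log_likelihood: float

    def __add__(self, other: "SufficientStatistics") -> "SufficientStatistics":
        return SufficientStatistics(
            counts=self.counts + other.counts,
            dwell=self.dwell + other.dwell,
            log_likelihood=self.log_likelihood + other.log_likelihood,
        )


@dataclass
class EMConfig:
    max_iterations: int = 200
    log_likelihood_tolerance: float = 1e-3
    frequency_floor: float = 1e-6
    exchangeability_pseudocount: float = 2.0
    seed: int = 0
    rate_classes: int = 4
    rate_mode: str = "soft"  # "soft": mixture EM; "hard": condition on class
    reassign_interval: int = 0  # 0: assign once under the initial model

    def __post_init__(self) -> None:
        if self.log_likelihood_tolerance <= 0:
            raise ValueError("tolerance must be positive")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.rate_classes < 1:
            raise ValueError("rate_classes must be >= 1")
        if self.rate_mode not in ("soft", "hard"):
            raise ValueError("rate_mode must be 'soft' or 'hard'")


def _accumulate_branches(
    ct, model, rate, w, U, Uinv, out, oscales, partials, scales, col_ll,
    counts, dwell, col_weights=None,
):
    """Add one (group, rate-class) pass's branch expectations into counts/dwell."""
    for v in range(ct.n_nodes):
        if ct.parent[v] < 0:
            continue
        T = ct.lengths[v] * rate
        if T <= 0:
            continue
        # V_ab = sum_cols weight * out_v(a) L_v(b) / column likelihood
        wcol = np.exp(oscales[v] + scales[v] - col_ll)
        if col_weights is not None:
            wcol = wcol * col_weights
        V = (out[v] * wcol[:, None]).T @ partials[v]
        J = _pair_J(w, T)
        M = U.T @ V @ Uinv.T
        core = Uinv.T @ (M * J) @ U.T
        # dwell on the rate-scaled clock (what the M-step divides by)
        dwell += np.diag(core)
        C = model.Q * core
        np.fill_diagonal(C, 0.0)
        counts += C


def _pair_J(w: np.ndarray, T: float) -> np.ndarray:
    """J_kl = int_0^T exp(w_k s + w_l (T - s)) ds, with the coincident limit."""
    ew = np.exp(w * T)
    diff = w[:, None] - w[None, :]
    num = ew[:, None] - ew[None, :]
    near = np.abs(diff) < 1e-12
    J = np.where(near, T * ew[:, None], num / np.where(near, 1.0, diff))
    return J


def expected_sufficient_statistics(
    alns: list[AnnotatedAlignment],
    trees: list[Phylogeny],
    model: ReversibleModel,
    rate_models: list[RateClassModel] | None = None,
) -> SufficientStatistics:
    """E-step: accumulate expected counts/dwell over branches, columns, groups.

    Branch lengths are multiplied by the column's class rate; dwell times are
    reported on the rate-scaled clock (the quantity the M-step divides counts
    by), so dwell sums to (tree length x columns) when all rates are 1.
    """
    if len(alns) != len(trees):
        raise ValueError("alignments and trees must be paired")
    n = model.size
    counts = np.zeros((n, n))
    dwell = np.zeros(n)
    loglik = 0.0
    w, U, Uinv = model.eigensystem()

    for g, (aln, tree) in enumerate(zip(alns, trees)):
        ct = tree.compiled()
        rm = rate_models[g] if rate_models is not None else None
        if rm is None:
            class_rates = np.ones(1)
            assignment = np.zeros(aln.n_cols, dtype=int)
            soft = False
        else:
            class_rates = rm.class_rates
            assignment = rm.column_assignment
            soft = rm.soft

        if soft:
            # mixture E-step: every column contributes to every class with
            # its posterior class weight
            k = len(class_rates)
            col_ll_per_class = np.empty((aln.n_cols, k))
            per_class = []
            all_idx = np.arange(aln.n_cols)
            leaf_L = _leaf_partial_map(ct, aln, all_idx)
            for c, rate in enumerate(class_rates):
                P = _branch_matrices(ct, model, float(rate))
                partials, scales = _down_pass(ct, P, leaf_L, n)
                col_ll_per_class[:, c] = _root_log_likelihoods(
                    ct, partials, scales, model.pi
                )
                per_class.append((P, partials, scales))
            mix_ll = logsumexp(col_ll_per_class - np.log(k), axis=1)
            loglik += float(mix_ll.sum())
            resp = np.exp(col_ll_per_class - np.log(k) - mix_ll[:, None])
            for c, rate in enumerate(class_rates):
                P, partials, scales = per_class[c]
                col_ll = col_ll_per_class[:, c]
                out, oscales = _up_pass(ct, P, partials, scales, model.pi)
                _accumulate_branches(
                    ct, model, float(rate), w, U, Uinv,
                    out, oscales, partials, scales, col_ll,
                    counts, dwell, col_weights=resp[:, c],
                )
            continue

        for c, rate in enumerate(class_rates):
            idx = np.flatnonzero(assignment == c)
            if idx.size == 0:
                continue
            leaf_L = _leaf_partial_map(ct, aln, idx)
            P = _branch_matrices(ct, model, float(rate))
            partials, scales = _down_pass(ct, P, leaf_L, n)
            col_ll = _root_log_likelihoods(ct, partials, scales, model.pi)
            loglik += float(col_ll.sum())
            out, oscales = _up_pass(ct, P, partials, scales, model.pi)
            _accumulate_branches(
                ct, model, float(rate), w, U, Uinv,
                out, oscales, partials, scales, col_ll,
                counts, dwell,
            )
    np.clip(counts, 0.0, None, out=counts)
    np.clip(dwell, 0.0, None, out=dwell)
    return SufficientStatistics(counts=counts, dwell=dwell, log_likelihood=loglik)


def m_step_update(
    stats: SufficientStatistics,
    floor: float = 1e-6,
    alphabet: Alphabet | None = None,
    name: str = "",
    pseudocount: float = 0.0,
) -> ReversibleModel:
    """Reversible M-step: pi from dwell times, s from symmetrized counts.

    ``pseudocount`` adds that many virtual substitution events per residue
    pair, shrinking weakly observed exchangeabilities toward the neutral
    value 1 instead of letting them collapse to 0 (MAP-style regularization;
    irrelevant for well-observed pairs, keeps the generator irreducible).
    """
    if np.any(stats.counts < 0) or np.any(stats.dwell < 0):
        raise ValueError("sufficient statistics must be nonnegative")
    total_dwell = stats.dwell.sum()
    if total_dwell <= 0:
        raise ValueError("total dwell time is zero")
    if not np.any(stats.counts > 0):
        raise ValueError("all expected counts are zero: no signal to estimate from")
    pi = stats.dwell / total_dwell
    pi = np.maximum(pi, floor)
    pi = pi / pi.sum()
    sym = stats.counts + stats.counts.T + pseudocount
    # denom_ij = w_i pi_j + w_j pi_i
    denom = np.outer(stats.dwell, pi) + np.outer(stats.dwell, pi).T + pseudocount
    with np.errstate(divide="ignore", invalid="ignore"):
        s = np.where(denom > 0, sym / np.where(denom > 0, denom, 1.0), 0.0)
    np.fill_diagonal(s, 0.0)
    s = 0.5 * (s + s.T)  # exact symmetry against rounding
    kwargs = {} if alphabet is None else {"alphabet": alphabet}
    if alphabet is None and pi.shape[0] != 20:
        raise ValueError("non-20-state statistics require an explicit alphabet")
    return build_model(pi, s, name=name, **kwargs)


@dataclass(eq=False)
class EMResult:
    model: ReversibleModel
    trace: list[float]
    stats: SufficientStatistics
    rate_models: list[RateClassModel] | None
    converged: bool
    final_log_likelihood: float = field(default=np.nan)


def _monotonicity_slack(ll: float) -> float:
    # fixed-point M-step overshoot and the exchangeability prior can nudge the
    # *data* log-likelihood down by a hair while the ascent objective still
    # improves; genuine E-step defects produce far larger drops than this
    return 1e-6 + 1e-4 * abs(ll)


def em_fit(
    alns: list[AnnotatedAlignment],
    trees: list[Phylogeny],
    config: EMConfig,
    initial_model: ReversibleModel | None = None,
    rate_models: list[RateClassModel] | None = None,
    name: str = "",
) -> EMResult:
    """Alternate E and M steps until the log-likelihood gain drops below
    tolerance.  The trace records the per-iteration log-likelihood (each
    evaluated under the model *entering* the iteration) and must be
    non-decreasing; a decrease beyond numerical slack aborts with EMError.
    """
    if not alns:
        raise ValueError("no alignments")
    alphabet = alns[0].alphabet
    model = initial_model or jukes_cantor_like(alphabet=alphabet, name=name)
    if rate_models is None and config.rate_classes > 1:
        if initial_model is None:
            # rate-class assignment under a uniform matrix tracks raw column
            # diversity and biases rare exchangeabilities; bootstrap a rough
            # single-rate fit first and assign classes under it
            pre = replace(config, rate_classes=1, max_iterations=20,
                          log_likelihood_tolerance=max(
                              1.0, config.log_likelihood_tolerance))
            model = em_fit(alns, trees, pre, name=name).model
        rate_models = [
            assign_rate_classes(a, t, model, config.rate_classes,
                                soft=config.rate_mode == "soft")
            for a, t in zip(alns, trees)
        ]
    trace: list[float] = []
    stats = None
    converged = False
    for it in range(config.max_iterations):
        if (
            config.reassign_interval
            and it > 0
            and it % config.reassign_interval == 0
            and config.rate_classes > 1
        ):
            rate_models = [
                assign_rate_classes(a, t, model, config.rate_classes,
                                    soft=config.rate_mode == "soft")
                for a, t in zip(alns, trees)
            ]
        new_stats = expected_sufficient_statistics(alns, trees, model, rate_models)
        ll = new_stats.log_likelihood
        if trace:
            gain = ll - trace[-1]
            if gain < -max(1000 * config.log_likelihood_tolerance,
                           _monotonicity_slack(ll)):
                raise EMError(
                    f"log-likelihood decreased at iteration {it}: "
                    f"{trace[-1]:.6f} -> {ll:.6f} (E-step defect?)"
                )
            if gain < config.log_likelihood_tolerance:
                # the reversible M-step is a fixed-point update, not an exact
                # maximizer: near the optimum it can overshoot by less than
                # the tolerance.  Reject such a step and keep the better model.
                if gain >= 0:
                    trace.append(ll)
                    stats = new_stats
                else:
                    model = prev_model
                converged = True
                break
        trace.append(ll)
        stats = new_stats
        prev_model = model
        model = m_step_update(
            new_stats, floor=config.frequency_floor, alphabet=alphabet, name=name,
            pseudocount=config.exchangeability_pseudocount,
        )
    final_ll = total_log_likelihood(alns, trees, model, rate_models)
    return EMResult(
        model=model,
        trace=trace,
        stats=stats,
        rate_models=rate_models,
        converged=converged,
        final_log_likelihood=final_ll,
    )


def free_parameter_count(n_states: int = 20) -> int:
    """Free parameters of one reversible matrix under the unit-rate constraint:
    n(n-1)/2 - 1 exchangeabilities plus n - 1 frequencies (208 for n = 20)."""
    return n_states * (n_states - 1) // 2 - 1 + n_states - 1


@dataclass(eq=False)
class DOFit:
    """Joint result of the mixed DO fit and the single-matrix fit."""

    model_d: ReversibleModel
    model_o: ReversibleModel
    model_single: ReversibleModel
    lnl_do: float
    lnl_single: float
    aic_do: float
    aic_single: float
    n_parameters_do: int
    n_parameters_single: int
    stats_d: SufficientStatistics
    stats_o: SufficientStatistics
    result_d: EMResult
    result_o: EMResult
    result_single: EMResult


def fit_do_model(
    alns: list[AnnotatedAlignment],
    trees: list[Phylogeny],
    config: EMConfig,
    initial_model: ReversibleModel | None = None,
) -> DOFit:
    """Fit D and O matrices on mask-split columns, plus a single matrix on all
    annotated columns, and compare by AIC.

    Rate classes (and the gamma shape) are assigned per group on all annotated
    columns under the initial model, then inherited by both sub-alignments and
    by the single fit, so the DO likelihood nests the single-model likelihood.
    The D and O fits start from the fitted single matrix: EM monotonicity then
    guarantees lnL_DO >= lnL_single.
    """
    alphabet = alns[0].alphabet
    base = initial_model or jukes_cantor_like(alphabet=alphabet)

    annotated_alns: list[AnnotatedAlignment] = []
    rate_models: list[RateClassModel] | None = [] if config.rate_classes > 1 else None
    d_alns, o_alns, d_trees, o_trees = [], [], [], []
    d_rms: list[RateClassModel] | None = [] if config.rate_classes > 1 else None
    o_rms: list[RateClassModel] | None = [] if config.rate_classes > 1 else None
    for aln, tree in zip(alns, trees):
        keep = np.flatnonzero(aln.mask != 2)
        ann = AnnotatedAlignment(
            names=list(aln.names),
            codes=aln.codes[:, keep],
            mask=aln.mask[keep],
            group_id=aln.group_id,
            alphabet=aln.alphabet,
        )
        annotated_alns.append(ann)
        rm = None
        if config.rate_classes > 1:
            rm = assign_rate_classes(ann, tree, base, config.rate_classes,
                                     soft=config.rate_mode == "soft")
            rate_models.append(rm)
        o_part, d_part = split_by_mask(ann)
        if o_part.n_cols:
            o_alns.append(o_part)
            o_trees.append(tree)
            if rm is not None:
                o_rms.append(rm.subset(np.flatnonzero(ann.mask == ORDERED)))
        if d_part.n_cols:
            d_alns.append(d_part)
            d_trees.append(tree)
            if rm is not None:
                d_rms.append(rm.subset(np.flatnonzero(ann.mask == DISORDERED)))
    if not d_alns or not o_alns:
        raise ValueError("one region class is absent from every group")

    res_single = em_fit(
        annotated_alns, trees, config, initial_model=base,
        rate_models=rate_models, name="single",
    )
    res_d = em_fit(
        d_alns, d_trees, config, initial_model=res_single.model,
        rate_models=d_rms, name="D",
    )
    res_o = em_fit(
        o_alns, o_trees, config, initial_model=res_single.model,
        rate_models=o_rms, name="O",
    )

    k1 = free_parameter_count(alphabet.size)
    lnl_do = res_d.final_log_likelihood + res_o.final_log_likelihood
    lnl_single = res_single.final_log_likelihood
    if lnl_do < lnl_single - 1e-6:
        warnings.warn(
            f"DO log-likelihood {lnl_do:.3f} below single-model "
            f"{lnl_single:.3f}; EM under-converged"
        )
    return DOFit(
        model_d=res_d.model,
        model_o=res_o.model,
        model_single=res_single.model,
        lnl_do=lnl_do,
        lnl_single=lnl_single,
        aic_do=2 * (2 * k1) - 2 * lnl_do,
        aic_single=2 * k1 - 2 * lnl_single,
        n_parameters_do=2 * k1,
        n_parameters_single=k1,
        stats_d=res_d.stats,
        stats_o=res_o.stats,
        result_d=res_d,
        result_o=res_o,
        result_single=res_single,
    )
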