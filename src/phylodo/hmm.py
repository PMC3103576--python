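"""Phylogenetic HMM annotation of ordered / disordered alignment columns.

Architecture: four states (start, order-emitting, disorder-emitting, end).
Emissions of the two emitting states are phylogenetic column likelihoods
under the O and D models (with the same discrete-gamma rate-class handling
as estimation); transitions are trained by Baum-Welch with emissions frozen.
A frequency-only variant (emissions ignore the tree and multiply stationary
frequencies over the column's residues) serves as the sequence-HMM baseline.

All dynamic programs run in log space; forward and backward total
log-likelihoods agree to 1e-8 and per-column posteriors over the two
emitting states sum to one.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.special import logsumexp

from .alignment import DISORDERED, ORDERED, AnnotatedAlignment
from .likelihood import (
    RateClassModel,
    assign_rate_classes,
    per_column_log_likelihoods,
)
from .substitution import ReversibleModel, jukes_cantor_like
from .tree import Phylogeny

__all__ = [
    "PhyloHmm",
    "DecodeResult",
    "ConfusionSummary",
    "make_phylo_hmm",
    "make_frequency_hmm",
    "column_emissions",
    "train_transitions",
    "decode_alignment",
    "evaluate_annotation",
    "split_groups",
]

# state indices
ORDER_STATE, DISORDER_STATE = 0, 1
N_EMIT = 2


@dataclass(eq=False)
class PhyloHmm:
    """Order/disorder annotation HMM with frozen phylogenetic emissions.

    ``start`` (length 2), ``trans`` (2x2) and ``end`` (length 2) hold the
    probabilities start->emitter, emitter->emitter and emitter->end;
    start->emitter plus nothing else leaves start, and every emitting state's
    outgoing mass (trans row + end) sums to 1.
    """

    model_o: ReversibleModel
    model_d: ReversibleModel
    start: np.ndarray
    trans: np.ndarray
    end: np.ndarray
    rate_classes: int = 4
    emission_kind: str = "phylo"  # or "frequency"

    def __post_init__(self) -> None:
        if abs(self.start.sum() - 1) > 1e-12:
            raise ValueError("start probabilities must sum to 1")
        rows = self.trans.sum(axis=1) + self.end
        if np.any(np.abs(rows - 1) > 1e-12):
            raise ValueError("emitting-state outgoing probabilities must sum to 1")


def make_phylo_hmm(
    model_o: ReversibleModel,
    model_d: ReversibleModel,
    rate_classes: int = 4,
    self_transition: float = 0.95,
    end_probability: float = 0.01,
) -> PhyloHmm:
    stay = self_transition
    leave = 1.0 - stay - end_probability
    if leave <= 0:
        raise ValueError("self_transition + end_probability must be < 1")
    return PhyloHmm(
        model_o=model_o,
        model_d=model_d,
        start=np.array([0.5, 0.5]),
        trans=np.array([[stay, leave], [leave, stay]]),
        end=np.array([end_probability, end_probability]),
        rate_classes=rate_classes,
    )


def make_frequency_hmm(
    model_o: ReversibleModel, model_d: ReversibleModel, **kwargs
) -> PhyloHmm:
    """The sequence-only baseline: same chain, frequency-product emissions."""
    hmm = make_phylo_hmm(model_o, model_d, **kwargs)
    return replace(hmm, emission_kind="frequency")


def column_emissions(
    hmm: PhyloHmm, aln: AnnotatedAlignment, tree: Phylogeny | None
) -> np.ndarray:
    """(n_cols, 2) log emission likelihoods for the two emitting states.

    Phylo emissions: pruning likelihood at the column's rate class, classes
    assigned once under a uniform reference model so both states share one
    assignment.  Frequency emissions: sum of log stationary frequencies over
    the column's non-gap residues (gaps/ambiguity contribute nothing).
    Entirely-gapped columns emit probability 1 in both states.
    """
    if hmm.emission_kind == "frequency":
        E = np.zeros((aln.n_cols, N_EMIT))
        for st, model in ((ORDER_STATE, hmm.model_o), (DISORDER_STATE, hmm.model_d)):
            logpi = np.log(model.pi)
            obs = aln.codes >= 0
            vals = np.zeros_like(aln.codes, dtype=float)
            vals[obs] = logpi[aln.codes[obs].astype(int)]
            E[:, st] = vals.sum(axis=0)
        return E
    if tree is None:
        raise ValueError("phylo emissions require a tree")
    if hmm.rate_classes > 1:
        ref = jukes_cantor_like(alphabet=aln.alphabet)
        rm = assign_rate_classes(aln, tree, ref, hmm.rate_classes)
        rates = rm.class_rates
        pick = rm.column_assignment
    else:
        rates = np.ones(1)
        pick = np.zeros(aln.n_cols, dtype=int)
    E = np.empty((aln.n_cols, N_EMIT))
    rows = np.arange(aln.n_cols)
    for st, model in ((ORDER_STATE, hmm.model_o), (DISORDER_STATE, hmm.model_d)):
        ll = per_column_log_likelihoods(aln, tree, model, rates)
        E[:, st] = ll[rows, pick]
    return E


# ---------------------------------------------------------------------------
# log-space dynamic programs


def _forward(hmm: PhyloHmm, E: np.ndarray):
    T = E.shape[0]
    with np.errstate(divide="ignore"):
        ls, lt, le = np.log(hmm.start), np.log(hmm.trans), np.log(hmm.end)
    f = np.empty((T, N_EMIT))
    f[0] = ls + E[0]
    for t in range(1, T):
        f[t] = logsumexp(f[t - 1][:, None] + lt, axis=0) + E[t]
    total = logsumexp(f[T - 1] + le)
    return f, float(total)


def _backward(hmm: PhyloHmm, E: np.ndarray):
    T = E.shape[0]
    with np.errstate(divide="ignore"):
        ls, lt, le = np.log(hmm.start), np.log(hmm.trans), np.log(hmm.end)
    b = np.empty((T, N_EMIT))
    b[T - 1] = le
    for t in range(T - 2, -1, -1):
        b[t] = logsumexp(lt + (E[t + 1] + b[t + 1])[None, :], axis=1)
    total = logsumexp(ls + E[0] + b[0])
    return b, float(total)


@dataclass(eq=False)
class DecodeResult:
    """Per-column order/disorder decode of one alignment."""

    labels: np.ndarray  # ORDERED / DISORDERED per column
    posterior_disorder: np.ndarray
    log_likelihood: float
    log_likelihood_backward: float
    path_log_probability: float | None = None


def decode_alignment(
    hmm: PhyloHmm,
    aln: AnnotatedAlignment,
    tree: Phylogeny | None,
    mode: str = "posterior",
) -> DecodeResult:
    """Posterior (max per-column posterior) or Viterbi decode."""
    if mode not in ("posterior", "viterbi"):
        raise ValueError(f"unknown mode {mode!r}")
    E = column_emissions(hmm, aln, tree)
    f, fl = _forward(hmm, E)
    b, bl = _backward(hmm, E)
    post = f + b
    post = np.exp(post - logsumexp(post, axis=1, keepdims=True))
    posterior_disorder = post[:, DISORDER_STATE]
    path_lp = None
    if mode == "posterior":
        states = np.argmax(post, axis=1)
    else:
        with np.errstate(divide="ignore"):
            ls, lt, le = np.log(hmm.start), np.log(hmm.trans), np.log(hmm.end)
        T = E.shape[0]
        v = np.empty((T, N_EMIT))
        ptr = np.zeros((T, N_EMIT), dtype=int)
        v[0] = ls + E[0]
        for t in range(1, T):
            cand = v[t - 1][:, None] + lt
            ptr[t] = np.argmax(cand, axis=0)
            v[t] = cand[ptr[t], np.arange(N_EMIT)] + E[t]
        last = int(np.argmax(v[T - 1] + le))
        path_lp = float((v[T - 1] + le)[last])
        states = np.empty(T, dtype=int)
        states[T - 1] = last
        for t in range(T - 2, -1, -1):
            states[t] = ptr[t + 1][states[t + 1]]
    labels = np.where(states == DISORDER_STATE, DISORDERED, ORDERED).astype(np.int8)
    return DecodeResult(
        labels=labels,
        posterior_disorder=posterior_disorder,
        log_likelihood=fl,
        log_likelihood_backward=bl,
        path_log_probability=path_lp,
    )


def train_transitions(
    hmm: PhyloHmm,
    alns: list[AnnotatedAlignment],
    trees: list[Phylogeny | None],
    tolerance: float = 1e-4,
    max_iterations: int = 200,
) -> tuple[PhyloHmm, list[float]]:
    """Baum-Welch on transition parameters only (emissions frozen).

    Returns the trained HMM and the per-iteration total log-likelihood
    trace (non-decreasing).
    """
    if not alns:
        raise ValueError("no training alignments")
    emissions = [column_emissions(hmm, a, t) for a, t in zip(alns, trees)]
    if any(np.all(np.isinf(E)) for E in emissions):
        raise ValueError("a training alignment is impossible under both models")
    trace: list[float] = []
    current = hmm
    for _ in range(max_iterations):
        with np.errstate(divide="ignore"):
            lt = np.log(current.trans)
            le = np.log(current.end)
        total_ll = 0.0
        exp_start = np.zeros(N_EMIT)
        exp_trans = np.zeros((N_EMIT, N_EMIT))
        exp_end = np.zeros(N_EMIT)
        for E in emissions:
            f, fl = _forward(current, E)
            b, _ = _backward(current, E)
            total_ll += fl
            g0 = f[0] + b[0] - fl
            exp_start += np.exp(g0)
            T = E.shape[0]
            for t in range(T - 1):
                xi = f[t][:, None] + lt + (E[t + 1] + b[t + 1])[None, :] - fl
                exp_trans += np.exp(xi)
            exp_end += np.exp(f[T - 1] + le - fl)
        if trace and total_ll - trace[-1] < tolerance:
            trace.append(total_ll)
            break
        trace.append(total_ll)
        start = exp_start / exp_start.sum()
        out = exp_trans.sum(axis=1) + exp_end
        trans = exp_trans / out[:, None]
        end = exp_end / out
        current = replace(current, start=start, trans=trans, end=end)
    return current, trace


# ---------------------------------------------------------------------------
# evaluation


@dataclass(frozen=True)
class ConfusionSummary:
    """Group-size-normalized confusion counts (disordered = positive).

    Each group's column-level counts are divided by its number of sequences
    before summing, so large groups do not dominate the benchmark; the raw
    (unnormalized) totals are kept alongside.
    """

    tp: float
    tn: float
    fp: float
    fn: float
    raw: dict

    @property
    def total(self) -> float:
        return self.tp + self.tn + self.fp + self.fn

    @property
    def precision(self) -> float | None:
        d = self.tp + self.fp
        return self.tp / d if d > 0 else None

    @property
    def recall(self) -> float | None:
        d = self.tp + self.fn
        return self.tp / d if d > 0 else None

    @property
    def accuracy(self) -> float | None:
        return (self.tp + self.tn) / self.total if self.total > 0 else None


def evaluate_annotation(
    decodes: list[np.ndarray],
    truth_masks: list[np.ndarray],
    group_sizes: list[int],
) -> tuple[ConfusionSummary, list[dict]]:
    """Confusion summary over groups, normalized by group size.

    Columns whose truth label is UNANNOTATED are excluded.  Returns the
    pooled summary and a per-group table of normalized counts.
    """
    tp = tn = fp = fn = 0.0
    raw = {"tp": 0.0, "tn": 0.0, "fp": 0.0, "fn": 0.0}
    per_group = []
    for pred, truth, size in zip(decodes, truth_masks, group_sizes):
        pred = np.asarray(pred)
        truth = np.asarray(truth)
        if pred.shape != truth.shape:
            raise ValueError("decode and truth lengths differ")
        use = truth != 2
        p, tr = pred[use], truth[use]
        g_tp = float(np.sum((p == DISORDERED) & (tr == DISORDERED)))
        g_tn = float(np.sum((p == ORDERED) & (tr == ORDERED)))
        g_fp = float(np.sum((p == DISORDERED) & (tr == ORDERED)))
        g_fn = float(np.sum((p == ORDERED) & (tr == DISORDERED)))
        for key, val in (("tp", g_tp), ("tn", g_tn), ("fp", g_fp), ("fn", g_fn)):
            raw[key] += val
        w = 1.0 / size
        tp += g_tp * w
        tn += g_tn * w
        fp += g_fp * w
        fn += g_fn * w
        per_group.append(
            {"tp": g_tp * w, "tn": g_tn * w, "fp": g_fp * w, "fn": g_fn * w,
             "n_sequences": size}
        )
    return ConfusionSummary(tp=tp, tn=tn, fp=fp, fn=fn, raw=raw), per_group


def split_groups(
    group_ids: list[str], test_fraction: float, seed: int
) -> tuple[list[str], list[str]]:
    """Group-level train/test split so training and evaluation never share
    a homologous group."""
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    ids = list(group_ids)
    perm = rng.permutation(len(ids))
    n_test = max(1, int(round(test_fraction * len(ids))))
    test = sorted(ids[i] for i in perm[:n_test])
    train = sorted(ids[i] for i in perm[n_test:])
    return train, test
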